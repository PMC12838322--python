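# Methods

This note documents the models and numerical choices behind `stabscan`: what
each stage computes, the parameters that matter and their defaults, what the
synthetic-data generator does and does not emulate, and the limitations a
user should keep in mind when moving from synthetic fixtures to real
structure models.

## Structure model and PDB handling

The in-memory model is chains → residues → heavy atoms with coordinates in
ångströms. Author residue numbering and insertion codes are preserved
verbatim; for mature proteases numbered from the first residue of the
processed chain this means the analysis speaks the same residue language as
the wet lab. Parsing (via gemmi) discards hydrogens and waters, resolves
alternate locations to the highest-occupancy conformer (ties broken
alphabetically), and routes metal HETATM records (Ca, Zn, Na, Mg, K) to a
separate ion list. Ions are kept out of the polymer because every
calcium-site analysis treats ion coordinates as explicit inputs — whether a
predicted model carries ions, and where, depends on how it was produced, so
downstream code never assumes them. Coordinate fields are validated before
parsing so a malformed number is reported with its line number; the writer
refuses coordinates that overflow the fixed-width PDB field (|x| ≥ 10⁴ Å).
No bond perception, protonation, or symmetry expansion is attempted.

Torsion angles use the IUPAC sign convention (trans = +180°, cis = 0°,
range (−180°, 180°]); a collinear bounding triple raises an error rather
than returning an arbitrary value.

## Synthetic peptide builder

Backbones are grown by sequential natural extension (NeRF): each atom is
placed from the previous three by (bond, angle, torsion), so prescribed
φ/ψ/ω enter the coordinates exactly and measuring them back reproduces the
specification to ~1e-13 degrees. The covalent geometry table (N–Cα 1.458 Å,
Cα–C 1.525 Å, C–N 1.329 Å; N-Cα-C 111.2°, Cα-C-N 116.6°, C-N-Cα 121.7°;
carbonyl O in the peptide plane anti to the next N) is Engh–Huber-style;
any self-consistent set would serve, because every test is a round-trip or
a relative comparison. Side chains come from rigid canonical templates
(extended χ angles, all twenty standard types except the Gly null case);
they are adequate for planting distances and computing reference areas, not
for packing or energetics.

Fixture factories place fragments rigidly and solve the planted quantity
directly:

- **Ion-pair fixture**: two Gly-X-Gly tripeptides are oriented head-on and
  the separation along the charged-group axis is solved by scalar root
  finding (Brent) so the *minimum* acidic-O/basic-N distance equals the
  target; the achieved value is exact to ~1e-9 Å, far inside the 0.05 Å
  contract. Targets outside [2.5, 15] Å, or reachable only with an
  inter-fragment heavy-atom contact below 2.5 Å, are rejected.
- **Burial fixture**: a lone residue whose side chain is surrounded by
  `shell` dummy blocker clusters placed on three staggered radii
  (r, r−1.6, r−3.2 Å, floored at 4.5 Å) in deterministic quasi-uniform
  (golden-spiral) directions; each cluster spreads five atoms in a tangential
  cross so ≥30 blockers at 6–8 Å occlude the central side chain to well
  under 5% RASA, while `shell=0` leaves it maximally exposed. Blocker
  orientation uses a seeded generator (default seed 0); fixtures are
  bit-reproducible given the seed.
- **Coordination fixture**: 1–8 carboxylate oxygens at an exact radius from
  an origin calcium ion along near-octahedral directions, with host-residue
  atoms strung radially outward so nothing else enters a 3 Å shell.

The generator emulates geometry only. It does not emulate realistic packing
density, solvation, conformational ensembles, or crystallographic noise, so
passing tests demonstrate that the detectors implement their stated
geometric rules exactly — not that a real predicted structure model will
yield any particular census. On real models the counts inherit all of the
model's own uncertainty.

## SASA and relative accessibility

The accessible area of an atom is computed by the sphere-point method: the
atom's van der Waals sphere is inflated by the probe radius (default 1.4 Å,
water) and sampled with a deterministic golden-spiral point set (default
960 points); the area is the fraction of points outside every neighbour's
inflated sphere times 4π(r+p)². There is no RNG, so results are bitwise
reproducible, and refinement is a parameter (`n_points`). Verification is
against closed forms (isolated sphere exact; two overlapping spheres vs the
spherical-cap formula to well under 2%), against the same algorithm at
10,000 points, and against an independent implementation (biotite) with the
same radius table. The shipped radii are C 1.70, N 1.55, O 1.52, S 1.80 Å
(plus halogens, P, Se, and common metal ions); unknown elements raise an
error naming the atom. Metal ions are excluded from surface and occlusion
by default (`include_ions=True` reverses this) since ion placement is a
modelling input.

RASA normalizes the side-chain area by a per-type reference: the side-chain
area of X in an extended Gly-X-Gly tripeptide (φ = −140°, ψ = 135°,
canonical rotamer) computed once by this same code and cached. This makes
RASA self-consistent — the reference conformation scores exactly 100% — but
the absolute scale can differ by a few percent from programs that use their
own (often unpublished) random-coil tables; borderline residues near the
20% exposure threshold may therefore classify differently between tools.
Values above 100% are legitimate for conformations more exposed than the
reference. Glycine uses its Cα as side-chain proxy, a common convention.
Non-glycine residues modelled without side-chain atoms have undefined RASA
and are excluded from exposure calls rather than defaulted.

## Ion pairs, networks, exposure

Charged atoms are the carboxylate oxygens of Asp/Glu versus Nζ of Lys and
Nε/Nη1/Nη2 of Arg. Histidine and chain termini are excluded by default —
the Lys/Arg-only accounting matches how surface-charge censuses of
subtilases are usually reported — with `include_his=True` available. The
pair distance is the minimum over side-chain O–N atom pairs (atom-distance
behaviour, not charge-group centroids), one pair per residue pair
regardless of how many atomic contacts exist. Boundaries are inclusive:
d = 4.0 Å is a salt bridge, d = 8.0 Å a long-range pair. Networks are
connected components of the residue/pair graph with at least two pairs;
components with one pair are reported separately as singletons, so a census
of thirteen pairs can legitimately read "twelve of them form three
networks". Pair exposure is the arithmetic mean of the members' RASA,
≥ 20% inclusive. Detection is verified against an exhaustive all-pairs
enumeration (exact distances and categories) and network assembly against
an independent union-find, including input-order independence.

## Turns, proline candidates, calcium sites

Backbone dihedrals are computed per chain over runs of residues that are
peptide-bonded (C–N ≤ 2.0 Å) with complete N/Cα/C backbones; numbering gaps
or chain breaks sever a run. A four-residue window is a turn candidate when
d(Cα_i, Cα_i+3) ≤ 7.0 Å. The helix veto excludes windows whose central two
residues lie within 40° of (φ,ψ) = (−63°,−42°) *and* belong to a run of at
least four consecutive such residues; it is a deliberately simple stand-in
for a full secondary-structure assignment and can be switched off
(`helix_veto=False`). Typing uses the classical ideal quadruples
(I, II, I′, II′, VIII in fixed precedence order; IV otherwise) with ±30°
tolerance and at most one angle allowed ±45°. Overlapping turns are all
reported. Because real turn censuses depend on the structure model and on
the annotator's secondary-structure pass, counts within ±1 of a published
census should be considered consistent.

Proline candidates are the i+1 positions of Type I turns that are not
already proline and are not in a caller-supplied exclusion set; the tool
does not infer function, so calcium-ligand turns and catalytic residues
(for a subtilase, the Asp-His-Ser triad) must be excluded explicitly.

Calcium-site analysis reports every oxygen within the cutoff (default
3.0 Å; typical Ca–O coordination distances are 2.3–2.6 Å, so 3.0 Å is
inclusive without pulling in second-shell atoms) of a supplied ion
coordinate, labelled side-chain (name starting Oδ/Oε/Oγ/Oη) or main-chain
carbonyl, sorted by distance. Graft verification is a set comparison of
(residue, atom, role) triples: the verdict is "satisfied" iff no expected
ligand is missing; extra observed ligands are listed but do not fail the
graft.

## Consensus and the surface-acidic scan

Predictor tables are a minimal interchange TSV (`wt`, `position`, `mut`)
because the native exports of stability-prediction web services vary by
version. Merging is by (position, wt, mut) with a hard error when two tools
disagree about the wild-type residue at a position. The consensus filter
keeps records supported by ≥ k tools (default 2) and orders them by support,
then position, then substitution; it is verified against a brute-force
filter for every k.

The surface-acidic scan is a deliberately permissive feasibility test: a
candidate position must be exposed (RASA ≥ 20%), not Gly/Pro/Cys, not
already acidic, not excluded, and its Cβ must lie within 8 Å + reach of a
basic residue's nearest charged nitrogen, where reach is the
Cβ-to-carboxylate-oxygen span of the proposed residue in an extended
rotamer (Asp 2.5 Å, Glu 3.9 Å). No rotamer search or energy model is used;
the output is a superset for human triage, mirroring how such shortlists
are used in engineering campaigns, and is monotone in the exposure
threshold. No statistical scoring or multiple-testing machinery is applied:
ranking is by tool support and deterministic sort keys only.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on synthetic inputs:
peptides of 3–8 residues, randomized charged arrangements of ≤ 500 atoms
(25 structures), 1,000 random pair graphs, and burial shells of ≤ 50
five-atom blockers. These sizes were chosen so each verification is
exhaustive or statistically redundant at desk scale. All randomness flows
through explicit seeds; SASA sampling and fixture construction contain no
hidden RNG.

## Known limitations

- Analytic (exact) SASA is not implemented; accuracy is controlled by the
  point count, with ~1% per-residue noise at 960 points.
- RASA absolute values are tied to this package's own reference table (see
  above); cross-tool comparisons should use rank or threshold behaviour,
  not absolute percentages.
- The helix veto is a (φ,ψ)-window heuristic, not DSSP.
- Cis-proline turn types (VIa/VIb) are not assigned.
- No Ca²⁺ placement or affinity estimation: ion coordinates are always
  inputs.
- Side-chain templates are rigid; the builder does not relax clashes beyond
  the 2.5 Å guard in the ion-pair fixture.
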