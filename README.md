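# stabscan

Structure-based thermostability analysis for subtilisin-like proteases and
other enzymes engineered for heat resistance.

Engineering an enzyme such as a keratinolytic subtilase to survive near the
boiling point combines several structure-derived signals: solvent-exposed
ion pairs and ionic networks, turn-rigidifying proline substitutions,
calcium-binding sites (native, modified, or grafted from thermophilic
homologs), and mutations proposed independently by several computational
stability predictors. `stabscan` implements each of these analyses as a
tested, reusable library over plain PDB coordinate models, plus a synthetic
peptide builder that plants every feature with known geometry so the whole
pipeline is verifiable without any external structure.

## What it computes

- **Ion pairs and ionic networks.** An acidic residue (Asp/Glu) and a basic
  residue (Lys/Arg) form a *salt bridge* when the minimum charged-atom
  distance min over O∈{Oδ1,Oδ2,Oε1,Oε2}, N∈{Nζ,Nε,Nη1,Nη2} of d(O,N) is
  ≤ 4.0 Å, and a *long-range ion pair* when 4.0 < d ≤ 8.0 Å. Connected
  components of the pair graph with ≥ 2 pairs are *ionic networks*; Lys/Arg
  outside every pair are reported as unpaired (they are prime targets for
  designing new partners).
- **Accessible surface and RASA.** Sphere-point (Shrake–Rupley-style) SASA
  with a 1.4 Å water probe and a deterministic spiral point set. Relative
  solvent accessibility of a residue is
  RASA = 100 · A_sidechain / A_ref(type), where A_ref is the side-chain area
  of X in an extended Gly-X-Gly tripeptide computed by the same code.
  Residues or pairs (mean of the two members) with RASA ≥ 20% count as
  exposed.
- **β-turns and proline design.** Four consecutive residues with
  d(Cα_i, Cα_i+3) ≤ 7 Å; the type follows the classical (φ,ψ) taxonomy at
  i+1/i+2 — Type I ideal (−60,−30,−90,0) — with ±30° tolerance and one angle
  allowed ±45°. Type I turns without proline at i+1 become X→P candidates
  (proline lowers the unfolding entropy of the turn).
- **Ca²⁺ sites and grafts.** The coordination shell of an ion coordinate:
  every oxygen within 3.0 Å, labelled side-chain (Oδ/Oε/Oγ/Oη) or main-chain
  carbonyl. A graft (e.g. transplanting a homolog's site by two point
  mutations) is verified by set comparison of expected vs observed
  (residue, atom, role) ligand triples.
- **Predictor consensus.** Mutation tables from multiple stability
  predictors (TSV columns `wt`, `position`, `mut`, one file per tool) are
  merged by (position, wt, mut); mutations supported by ≥ k tools (default
  k = 2) survive the consensus filter.
- **Surface-acidic scan.** Exposed residues (not Gly/Pro/Cys, not already
  acidic, not catalytic) whose Cβ lies within 8 Å + reach of a basic
  residue's charged nitrogen (reach: Asp 2.5 Å, Glu 3.9 Å) are proposed for
  X→Asp/Glu substitution to create new ion pairs.

## Worked example

Plant a salt bridge at a prescribed 3.5 Å minimum O–N distance and run the
detector with exposure annotation:

```python
from stabscan.synth import make_salt_bridge_fixture
from stabscan.interactions import detect_ion_pairs, annotate_exposure
from stabscan.sasa import compute_sasa, compute_rasa

fixture, log = make_salt_bridge_fixture("ASP", "LYS", target_min_on=3.5)
pairs = detect_ion_pairs(fixture)
rasa = compute_rasa(compute_sasa(fixture))
annotate_exposure(pairs, rasa)
for p in pairs:
    print(f"{p.label}: {p.min_distance:.2f} A  {p.category}  "
          f"pair RASA {p.pair_rasa:.1f}%  exposed={p.exposed}")
```

prints

```
K2-D2: 3.50 A  salt_bridge  pair RASA 82.7%  exposed=True
```

i.e. the lysine at position 2 of chain B and the aspartate at position 2 of
chain A sit 3.50 Å apart at their closest charged atoms (≤ 4 Å ⇒ salt
bridge), and with a mean relative accessibility of 82.7% (≥ 20%) the pair is
solvent-exposed. The same stages are exposed as a CLI:

```sh
stabscan sasa model.pdb --tsv rasa.tsv
stabscan ionpairs model.pdb
stabscan turns model.pdb
stabscan casite model.pdb --ion 15.0,7.0,-5.0 --cutoff 3.0
stabscan run model.pdb --predictors pross pross.tsv --exclude-residues 37,70,224
```

## Documentation

`docs/methods.md` describes the algorithms, parameter choices, synthetic
data model, and known limitations.
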