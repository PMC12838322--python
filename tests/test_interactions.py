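"""Ion pairs, ionic networks, exposure: oracles and planted fixtures."""

import numpy as np
import pytest

from stabscan.interactions import (
    ACIDIC_ATOMS,
    BASIC_ATOMS,
    IonPair,
    annotate_exposure,
    build_ionic_networks,
    detect_ion_pairs,
    unpaired_basic_residues,
)
from stabscan.structure import Residue, Structure, residue_id
from stabscan.synth import build_peptide, make_salt_bridge_fixture

from .conftest import apply_rigid, random_rigid_transform


def brute_force_ion_pairs(structure, salt_cutoff=4.0, long_cutoff=8.0):
    """Exhaustive all-pairs oracle: plain loops over charged atoms."""
    found = {}
    residues = [r for r in structure.amino_acids()]
    for ares in residues:
        if ares.name not in ACIDIC_ATOMS:
            continue
        for bres in residues:
            if bres.name not in BASIC_ATOMS:
                continue
            best = None
            for oname in ACIDIC_ATOMS[ares.name]:
                for nname in BASIC_ATOMS[bres.name]:
                    oc, nc = ares.coord(oname), bres.coord(nname)
                    if oc is None or nc is None:
                        continue
                    d = float(np.sqrt(((oc - nc) ** 2).sum()))
                    if best is None or d < best:
                        best = d
            if best is not None and best <= long_cutoff:
                cat = "salt_bridge" if best <= salt_cutoff else "long_range"
                found[(residue_id(ares), residue_id(bres))] = (best, cat)
    return found


def random_charged_structure(rng, n_residues=6):
    """Charged residues scattered by random rigid placement, one per chain."""
    structure = Structure()
    names = rng.choice(["ASP", "GLU", "LYS", "ARG"], size=n_residues)
    for i, name in enumerate(names):
        chain_id = chr(ord("A") + i)
        frag = build_peptide(["GLY", str(name), "GLY"], chain_id=chain_id)
        rot, _ = random_rigid_transform(rng)
        shift = rng.uniform(-9.0, 9.0, size=3)
        apply_rigid(frag, rot, shift)
        structure.chains[chain_id] = frag.chains[chain_id]
    return structure


class TestDetection:
    @pytest.mark.parametrize(
        "target,category",
        [(3.5, "salt_bridge"), (4.0, "salt_bridge"), (6.0, "long_range"), (8.0, "long_range")],
    )
    def test_planted_pair_classified(self, target, category):
        fixture, _ = make_salt_bridge_fixture("ASP", "LYS", target)
        pairs = detect_ion_pairs(fixture)
        assert len(pairs) == 1
        assert pairs[0].category == category
        assert pairs[0].min_distance == pytest.approx(target, abs=0.05)

    def test_beyond_cutoff_reports_nothing(self):
        fixture, _ = make_salt_bridge_fixture("ASP", "LYS", 9.0)
        assert detect_ion_pairs(fixture) == []

    def test_category_flip_across_salt_cutoff(self):
        below, _ = make_salt_bridge_fixture("GLU", "ARG", 3.95)
        above, _ = make_salt_bridge_fixture("GLU", "ARG", 4.05)
        assert detect_ion_pairs(below)[0].category == "salt_bridge"
        assert detect_ion_pairs(above)[0].category == "long_range"

    def test_matches_exhaustive_oracle_on_random_structures(self):
        rng = np.random.default_rng(42)
        for _ in range(12):
            structure = random_charged_structure(rng)
            assert structure.n_atoms <= 500
            oracle = brute_force_ion_pairs(structure)
            detected = {
                (residue_id(p.acidic), residue_id(p.basic)): (p.min_distance, p.category)
                for p in detect_ion_pairs(structure)
            }
            assert set(detected) == set(oracle)
            for key, (d, cat) in oracle.items():
                assert detected[key][0] == pytest.approx(d, abs=1e-9)
                assert detected[key][1] == cat

    def test_one_pair_per_residue_pair(self):
        # ARG offers three charged nitrogens; still a single reported pair
        fixture, _ = make_salt_bridge_fixture("ASP", "ARG", 3.0)
        assert len(detect_ion_pairs(fixture)) == 1

    def test_bad_cutoffs_rejected(self):
        fixture, _ = make_salt_bridge_fixture("ASP", "LYS", 3.5)
        with pytest.raises(ValueError):
            detect_ion_pairs(fixture, salt_cutoff=8.0, long_cutoff=4.0)


def make_pair(a_num, b_num):
    acidic = Residue("A", a_num, "ASP")
    basic = Residue("A", b_num, "LYS")
    return IonPair(acidic, basic, 3.0, "salt_bridge")


def union_find_components(edges):
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for a, b in edges:
        union(a, b)
    comps = {}
    for node in parent:
        comps.setdefault(find(node), set()).add(node)
    return sorted(map(frozenset, comps.values()), key=lambda s: min(s))


class TestNetworks:
    def test_chain_component_is_one_network(self):
        pairs = [make_pair(1, 2), make_pair(3, 2)]
        networks, singles = build_ionic_networks(pairs)
        assert len(networks) == 1 and not singles
        assert len(networks[0].members) == 3
        assert len(networks[0].pairs) == 2

    def test_disconnected_pairs_are_singletons(self):
        pairs = [make_pair(1, 2), make_pair(3, 4)]
        networks, singles = build_ionic_networks(pairs)
        assert networks == [] and len(singles) == 2

    def test_triangle_plus_singleton(self):
        pairs = [make_pair(1, 2), make_pair(3, 2), make_pair(3, 4), make_pair(5, 6)]
        # residues 1-2-3-4 connected via 3 pairs; 5-6 isolated
        networks, singles = build_ionic_networks(pairs)
        assert len(networks) == 1 and len(networks[0].pairs) == 3
        assert len(singles) == 1

    def test_matches_union_find_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n_nodes = int(rng.integers(4, 16))
            max_edges = n_nodes * (n_nodes - 1) // 2
            n_edges = int(rng.integers(1, min(12, max_edges + 1)))
            edges = set()
            while len(edges) < n_edges:
                a, b = rng.integers(1, n_nodes + 1, size=2)
                if a != b:
                    edges.add((int(min(a, b)), int(max(a, b)) + 100))
            pairs = [make_pair(a, b) for a, b in edges]
            networks, singles = build_ionic_networks(pairs)
            oracle = union_find_components(edges)
            edge_count = {
                comp: sum(1 for e in edges if e[0] in comp) for comp in oracle
            }
            expected = sorted(
                (comp for comp in oracle if edge_count[comp] >= 2),
                key=lambda s: sorted(s),
            )
            got = sorted(
                (frozenset(r.number for r in net.members) for net in networks),
                key=lambda s: sorted(s),
            )
            assert got == expected
            assert len(singles) == sum(1 for c in oracle if edge_count[c] == 1)

    def test_order_independence(self):
        rng = np.random.default_rng(13)
        pairs = [make_pair(1, 2), make_pair(3, 2), make_pair(4, 5), make_pair(6, 7), make_pair(6, 8)]
        ref_networks, ref_singles = build_ionic_networks(pairs)
        for _ in range(5):
            shuffled = list(pairs)
            rng.shuffle(shuffled)
            networks, singles = build_ionic_networks(shuffled)
            assert [n.label for n in networks] == [n.label for n in ref_networks]
            assert [p.label for p in singles] == [p.label for p in ref_singles]


class TestExposure:
    def test_mean_and_inclusive_threshold(self):
        pairs = [make_pair(1, 2), make_pair(3, 4), make_pair(5, 6)]
        rasa = {
            ("A", 1, ""): 30.0, ("A", 2, ""): 14.0,   # mean 22 -> exposed
            ("A", 3, ""): 10.0, ("A", 4, ""): 10.0,   # mean 10 -> buried
            ("A", 5, ""): 20.0, ("A", 6, ""): 20.0,   # mean 20 -> exposed (inclusive)
        }
        annotate_exposure(pairs, rasa)
        assert pairs[0].pair_rasa == pytest.approx(22.0) and pairs[0].exposed
        assert not pairs[1].exposed
        assert pairs[2].exposed

    def test_missing_rasa_flags_unknown(self):
        pairs = [make_pair(1, 2)]
        annotate_exposure(pairs, {("A", 1, ""): 30.0})
        assert pairs[0].exposed is None and pairs[0].pair_rasa is None


class TestUnpairedBasics:
    def test_lone_lysine_reported(self):
        structure = build_peptide(["GLY", "LYS", "GLY"])
        out = unpaired_basic_residues(structure, [])
        assert [r.label for r in out] == ["K2"]

    def test_planted_partner_not_reported(self):
        fixture, _ = make_salt_bridge_fixture("ASP", "LYS", 3.5)
        pairs = detect_ion_pairs(fixture)
        assert unpaired_basic_residues(fixture, pairs) == []

    def test_beyond_cutoff_partner_is_unpaired(self):
        fixture, _ = make_salt_bridge_fixture("ASP", "LYS", 9.0)
        pairs = detect_ion_pairs(fixture)
        assert [r.label for r in unpaired_basic_residues(fixture, pairs)] == ["K2"]
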