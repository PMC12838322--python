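"""Beta-turn detection/typing, proline proposals, calcium-site analysis."""

import numpy as np
import pytest

from stabscan.motifs import (
    TURN_IDEALS,
    BetaTurn,
    GraftSpec,
    analyze_ca_site,
    check_graft,
    classify_turn_type,
    detect_beta_turns,
    propose_proline_candidates,
)
from stabscan.structure import Residue
from stabscan.synth import ResidueSpec, build_backbone, make_coordination_fixture

from .conftest import apply_rigid, random_rigid_transform


class TestClassification:
    @pytest.mark.parametrize("name,ideal", TURN_IDEALS)
    def test_ideal_quadruples_map_to_own_type(self, name, ideal):
        assert classify_turn_type(*ideal) == name

    def test_single_angle_allowance(self):
        # psi2 at 40 deg from ideal uses the one-angle +/-45 allowance
        assert classify_turn_type(-60.0, -30.0, -90.0, 40.0) == "I"

    def test_two_angles_beyond_30_demote(self):
        assert classify_turn_type(-60.0, -70.0, -90.0, 40.0) == "IV"

    def test_single_angle_beyond_45_demotes(self):
        for idx in range(4):
            angles = list(TURN_IDEALS[0][1])
            angles[idx] += 46.0
            assert classify_turn_type(*angles) != "I"

    def test_unmatched_angles_are_type_iv(self):
        assert classify_turn_type(0.0, 0.0, 0.0, 90.0) == "IV"


class TestDetection:
    def test_planted_type1_turn_found_once(self, type1_turn_structure):
        turns = detect_beta_turns(type1_turn_structure)
        assert len(turns) == 1
        assert turns[0].type == "I"
        assert turns[0].ca_distance <= 7.0

    def test_extended_chain_has_no_turns(self, extended_hexapeptide):
        assert detect_beta_turns(extended_hexapeptide) == []

    def test_type2_fixture(self):
        spec = [
            ResidueSpec("GLY", -140.0, 135.0),
            ResidueSpec("ALA", -60.0, 120.0),
            ResidueSpec("GLY", 80.0, 0.0),
            ResidueSpec("GLY", -140.0, 135.0),
        ]
        turns = detect_beta_turns(build_backbone(spec))
        assert [t.type for t in turns] == ["II"]

    def test_helix_vetoed_but_switchable(self):
        helix = build_backbone(
            [ResidueSpec("ALA", -63.0, -42.0) for _ in range(8)]
        )
        assert detect_beta_turns(helix) == []
        unvetoed = detect_beta_turns(helix, helix_veto=False)
        assert len(unvetoed) > 0

    def test_rigid_body_invariance(self, type1_turn_structure):
        before = detect_beta_turns(type1_turn_structure)
        rng = np.random.default_rng(5)
        rot, shift = random_rigid_transform(rng)
        apply_rigid(type1_turn_structure, rot, shift)
        after = detect_beta_turns(type1_turn_structure)
        assert [t.type for t in after] == [t.type for t in before]
        assert after[0].phi1 == pytest.approx(before[0].phi1, abs=1e-6)
        assert after[0].ca_distance == pytest.approx(before[0].ca_distance, abs=1e-6)

    def test_chain_break_skipped(self, type1_turn_structure):
        # push the last residue away: the peptide bond check severs the window
        last = type1_turn_structure.chains["A"][-1]
        for a in last.atoms:
            a.coord = a.coord + np.array([50.0, 0.0, 0.0])
        assert detect_beta_turns(type1_turn_structure) == []


class TestProlineCandidates:
    def test_type1_turn_yields_one_candidate(self, type1_turn_structure):
        turns = detect_beta_turns(type1_turn_structure)
        cands = propose_proline_candidates(turns)
        assert [c.notation for c in cands] == ["S2P"]
        assert cands[0].category == "turn_pro"

    def test_native_proline_excluded(self):
        spec = [
            ResidueSpec("GLY", -140.0, 135.0),
            ResidueSpec("PRO", -60.0, -30.0),
            ResidueSpec("GLY", -90.0, 0.0),
            ResidueSpec("GLY", -140.0, 135.0),
        ]
        turns = detect_beta_turns(build_backbone(spec))
        assert [t.type for t in turns] == ["I"]
        assert propose_proline_candidates(turns) == []

    def test_explicit_exclusions_respected(self, type1_turn_structure):
        turns = detect_beta_turns(type1_turn_structure)
        assert propose_proline_candidates(turns, exclusions={2}) == []

    def test_candidates_subset_of_type1_i1_positions(self):
        spec = [
            ResidueSpec("GLY", -140.0, 135.0),
            ResidueSpec("SER", -60.0, -30.0),
            ResidueSpec("GLY", -90.0, 0.0),
            ResidueSpec("ALA", -60.0, 120.0),
            ResidueSpec("GLY", 80.0, 0.0),
            ResidueSpec("GLY", -140.0, 135.0),
        ]
        turns = detect_beta_turns(build_backbone(spec))
        i1_type1 = {t.i1.number for t in turns if t.type == "I"}
        cands = propose_proline_candidates(turns)
        assert {c.position for c in cands} <= i1_type1


class TestCaSite:
    def test_planted_shell_recovered(self):
        structure, ion, _ = make_coordination_fixture(6, 2.4)
        site = analyze_ca_site(structure, ion, cutoff=3.0)
        assert len(site.ligands) == 6
        assert all(lg.role == "side_chain" for lg in site.ligands)
        assert all(lg.distance == pytest.approx(2.4, abs=1e-9) for lg in site.ligands)

    def test_ligand_outside_cutoff_ignored(self):
        structure, ion, _ = make_coordination_fixture(1, 3.5)
        assert analyze_ca_site(structure, ion, cutoff=3.0).ligands == []

    def test_main_chain_carbonyl_role(self):
        structure, ion, _ = make_coordination_fixture(1, 2.4)
        # move the host's backbone carbonyl oxygen into the shell
        res = structure.chains["A"][0]
        res.atom("O").coord = ion + np.array([0.0, 2.5, 0.0])
        site = analyze_ca_site(structure, ion, cutoff=3.0)
        roles = {(lg.atom_name, lg.role) for lg in site.ligands}
        assert ("O", "main_chain_carbonyl") in roles
        assert ("OD1", "side_chain") in roles

    def test_rigid_body_invariance(self):
        structure, ion, _ = make_coordination_fixture(4, 2.4)
        before = analyze_ca_site(structure, ion)
        rng = np.random.default_rng(9)
        rot, shift = random_rigid_transform(rng)
        apply_rigid(structure, rot, shift)
        after = analyze_ca_site(structure, rot @ ion + shift)
        assert len(after.ligands) == len(before.ligands)
        for a, b in zip(after.ligands, before.ligands):
            assert a.distance == pytest.approx(b.distance, abs=1e-9)


class TestGraft:
    def make_site_and_structure(self, n=3, d=2.4):
        structure, ion, _ = make_coordination_fixture(n, d)
        return analyze_ca_site(structure, ion), structure

    def test_identical_sets_satisfied(self):
        site, structure = self.make_site_and_structure()
        expected = sorted(site.ligand_triples())
        spec = GraftSpec(mutations=[(1, "Q", "D")], expected_ligands=expected)
        report = check_graft(site, spec, structure)
        assert report.verdict == "satisfied"
        assert report.missing == [] and report.extra == []

    def test_out_of_cutoff_ligand_reported_missing(self):
        structure, ion, _ = make_coordination_fixture(2, 3.4)
        site = analyze_ca_site(structure, ion, cutoff=3.0)
        spec = GraftSpec(
            mutations=[], expected_ligands=[(1, "OD1", "side_chain")]
        )
        report = check_graft(site, spec, structure)
        assert report.verdict == "unsatisfied"
        assert (1, "OD1", "side_chain") in report.missing

    def test_extra_ligands_do_not_spoil_verdict(self):
        site, structure = self.make_site_and_structure(n=3)
        spec = GraftSpec(
            mutations=[], expected_ligands=[(1, "OD1", "side_chain")]
        )
        report = check_graft(site, spec, structure)
        assert report.verdict == "satisfied"
        assert len(report.extra) == 2

    def test_unknown_position_rejected(self):
        site, structure = self.make_site_and_structure()
        spec = GraftSpec(
            mutations=[(99, "Q", "D")], expected_ligands=[(1, "OD1", "side_chain")]
        )
        with pytest.raises(ValueError, match="99"):
            check_graft(site, spec, structure)
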