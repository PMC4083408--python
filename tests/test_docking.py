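import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import interface_ca_rmsd
from structppi.docking import (PredictionConfig, SizeRuleRejection, clash_filter,
                               match_side, predict_interaction, score_energy,
                               ternary_compatibility, PredictedComplex)
from structppi.errors import LibraryError, StructPPIError
from structppi.geometry import RigidTransform
from structppi.potentials import DEFAULT_POTENTIAL
from structppi.structure import Atom, Chain, Residue, ResidueID, Structure
from structppi.synthetic import FixtureSpec, make_complex, make_helix

CFG = PredictionConfig()


def strand(n, chain_id="E", aa3="SER"):
    ch = Chain(id=chain_id)
    for i in range(n):
        pos = np.array([3.6 * i, 0.3 * (i % 2), 0.0])
        ch.residues.append(Residue(ResidueID(chain_id, i + 1, ""), aa3, i, [
            Atom("N", "N", pos + [-1.2, 0.4, 0]), Atom("CA", "C", pos),
            Atom("C", "C", pos + [1.2, 0.5, 0]), Atom("O", "O", pos + [1.2, 1.7, 0]),
            Atom("CB", "C", pos + [0.0, -1.4, 0.6])]))
    return ch


class TestMatchSide:
    def test_source_chain_matches_own_side_fully(self, truth1):
        m = match_side(truth1.structure["A"], truth1.template.side_a, CFG,
                       truth1.template.hotspots_a)
        assert m is not None
        assert m.matched_fraction == pytest.approx(1.0)
        assert m.hotspot_matches >= 1

    def test_short_peptide_hits_size_rule(self, truth1):
        # a 10-residue peptide raises the size rule, a distinct signal from a
        # geometric non-match (which returns None)
        peptide = make_helix(20)
        peptide.residues = peptide.residues[:10]
        with pytest.raises(SizeRuleRejection):
            match_side(peptide, truth1.template.side_a, CFG)

    def test_unrelated_fold_is_rejected(self, truth1):
        assert match_side(strand(40), truth1.template.side_a, CFG,
                          truth1.template.hotspots_a) is None


class TestClashFilter:
    def test_far_apart_passes(self):
        s = Structure(entry_id="far")
        s.add_chain(make_helix(20, (0, 0, 0), "A"))
        s.add_chain(make_helix(20, (20, 0, 0), "B"))
        assert clash_filter(s, CFG) == (True, 0)

    def test_superposed_chains_fail(self):
        s = Structure(entry_id="overlap")
        s.add_chain(make_helix(20, (0, 0, 0), "A"))
        s.add_chain(make_helix(20, (0.1, 0, 0), "B"))
        ok, n = clash_filter(s, CFG)
        assert not ok and n > CFG.max_clashes

    def test_designed_pose_counts_exact_pairs(self):
        # two 16-residue strands with exactly 3 atom pairs pushed under 2.5 A:
        # each repositioned partner CB sits 2.0 A from one backbone O and more
        # than 2.5 A from every other atom of the first chain
        a = strand(16, "A")
        b = strand(16, "B")
        for r in b.residues:
            for atom in r.atoms:
                atom.position = atom.position + np.array([0.0, 8.0, 0.0])
        for i in (3, 7, 11):
            o_a = a.residues[i].atom("O")
            cb_b = b.residues[i].atom("CB")
            cb_b.position = o_a.position + np.array([0.0, 2.0, 0.0])
        s = Structure(entry_id="three")
        s.add_chain(a)
        s.add_chain(b)
        ok, n = clash_filter(s, CFG)
        assert (ok, n) == (True, 3)


class TestScoreEnergy:
    def test_out_of_range_pose_scores_zero(self):
        s = Structure(entry_id="far")
        s.add_chain(make_helix(20, (0, 0, 0), "A"))
        s.add_chain(make_helix(20, (30, 0, 0), "B"))
        assert score_energy(s) == 0.0

    def test_single_ala_ala_contact_equals_table_entry(self):
        s = Structure(entry_id="pair")
        for cid, x in (("A", 0.0), ("B", 5.0)):
            ch = Chain(id=cid)
            ch.residues.append(Residue(ResidueID(cid, 1, ""), "ALA", 0, [
                Atom("CA", "C", np.array([x, 0, 0])),
                Atom("CB", "C", np.array([x, 1.5, 0]))]))
            s.add_chain(ch)
        assert score_energy(s) == pytest.approx(DEFAULT_POTENTIAL.get("A", "A"))

    def test_matches_brute_force_double_loop(self, truth1):
        pose = truth1.structure
        total = 0.0
        for ra in pose["A"].residues:
            aa = ra.atom("CB") or ra.atom("CA")
            for rb in pose["B"].residues:
                ab = rb.atom("CB") or rb.atom("CA")
                if np.linalg.norm(aa.position - ab.position) < 6.5:
                    total += DEFAULT_POTENTIAL.get(ra.aa1, rb.aa1)
        assert score_energy(pose) == pytest.approx(total, abs=1e-9)

    def test_symmetric_under_chain_swap(self, truth1):
        s = truth1.structure
        swapped = Structure(entry_id="sw")
        swapped.add_chain(s["B"].copy())
        swapped.add_chain(s["A"].copy())
        assert score_energy(swapped) == pytest.approx(score_energy(s), abs=1e-9)

    def test_rigid_invariance(self, truth1):
        moved = truth1.structure.copy()
        R = Rotation.from_euler("xyz", [30, 60, 10], degrees=True).as_matrix()
        for ch in moved.chains.values():
            for r in ch.residues:
                for a in r.atoms:
                    a.position = R @ a.position + np.array([5.0, -3.0, 2.0])
        assert score_energy(moved) == pytest.approx(score_energy(truth1.structure),
                                                    abs=1e-6)
        assert clash_filter(moved, CFG) == clash_filter(truth1.structure, CFG)


class TestPredictInteraction:
    def test_self_template_reconstruction(self, truth1):
        st = truth1.structure
        lib = {truth1.template.template_id: truth1.template}
        pred = predict_interaction([st["A"]], [st["B"]], lib)
        assert pred is not None
        assert pred.energy_score < 0
        assert interface_ca_rmsd(pred, truth1) < 1.0
        assert pred.clash_count <= CFG.max_clashes

    def test_unrelated_fold_gives_none(self, truth1):
        lib = {truth1.template.template_id: truth1.template}
        assert predict_interaction([strand(40)], [truth1.structure["B"]], lib) is None

    def test_duplicate_conformers_idempotent(self, truth1):
        st = truth1.structure
        lib = {truth1.template.template_id: truth1.template}
        one = predict_interaction([st["A"]], [st["B"]], lib)
        two = predict_interaction([st["A"], st["A"].copy()], [st["B"]], lib)
        assert one.energy_score == two.energy_score
        assert one.template_id == two.template_id

    def test_empty_library_errors(self, truth1):
        with pytest.raises(LibraryError):
            predict_interaction([truth1.structure["A"]], [truth1.structure["B"]], {})

    def test_deterministic_bitwise(self, truth1):
        st = truth1.structure
        lib = {truth1.template.template_id: truth1.template}
        p1 = predict_interaction([st["A"]], [st["B"]], lib)
        p2 = predict_interaction([st["A"]], [st["B"]], lib)
        assert p1.energy_score == p2.energy_score
        for c1, c2 in zip(p1.pose.chains.values(), p2.pose.chains.values()):
            for r1, r2 in zip(c1.residues, c2.residues):
                for a1, a2 in zip(r1.atoms, r2.atoms):
                    assert np.array_equal(a1.position, a2.position)

    def test_truncating_contacting_region_abolishes_or_worsens(self, truth1):
        from structppi.structure import truncate_chain
        st = truth1.structure
        lib = {truth1.template.template_id: truth1.template}
        wt = predict_interaction([st["A"]], [st["B"]], lib)
        cut = min(r.author_number for r in truth1.template.side_b.contacting)
        try:
            truncated = truncate_chain(st["B"], cut)
            mut = predict_interaction([st["A"]], [truncated], lib)
        except StructPPIError:
            mut = None
        assert mut is None or mut.energy_score > wt.energy_score


def _pose(chain_a, chain_b):
    s = Structure(entry_id="t")
    s.add_chain(chain_a)
    s.add_chain(chain_b)
    ident = RigidTransform.identity()
    return PredictedComplex(chain_a.id, chain_b.id, "tpl", ident, ident, s,
                            -1.0, 1.0, 1.0, 0, 0)


class TestTernaryCompatibility:
    def test_opposite_faces_are_compatible(self):
        ab = _pose(make_helix(20, (0, 0, 0), "A"), make_helix(20, (9, 0, 0), "B"))
        ac = _pose(make_helix(20, (0, 0, 0), "A"), make_helix(20, (-9, 0, 0), "C"))
        ok, n = ternary_compatibility(ab, ac, "A")
        assert ok and n == 0

    def test_same_face_clashes(self):
        ab = _pose(make_helix(20, (0, 0, 0), "A"), make_helix(20, (9, 0, 0), "B"))
        ac = _pose(make_helix(20, (0, 0, 0), "A"), make_helix(20, (9.2, 0.3, 0), "C"))
        ok, n = ternary_compatibility(ab, ac, "A")
        assert not ok and n > CFG.max_clashes

    def test_pose_against_itself_fully_overlaps(self):
        ab = _pose(make_helix(20, (0, 0, 0), "A"), make_helix(20, (9, 0, 0), "B"))
        ac = _pose(make_helix(20, (0, 0, 0), "A"), make_helix(20, (9, 0, 0), "C"))
        ok, _ = ternary_compatibility(ab, ac, "A")
        assert not ok

    def test_shared_chain_sequence_mismatch_errors(self):
        ab = _pose(make_helix(20, (0, 0, 0), "A"), make_helix(20, (9, 0, 0), "B"))
        ac = _pose(make_helix(20, (0, 0, 0), "A", sequence="W" * 20),
                   make_helix(20, (-9, 0, 0), "C"))
        with pytest.raises(StructPPIError):
            ternary_compatibility(ab, ac, "A")


def test_min_residues_is_protocol_fixed():
    with pytest.raises(ValueError):
        PredictionConfig(min_residues=10)
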