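import numpy as np
import pytest

from structppi.docking import predict_interaction
from structppi.errors import (FormatError, MappingError, MutationParseError,
                              TotalTruncationError)
from structppi.mutations import (MutationRecord, StructureMapping, apply_missense,
                                 apply_nonsense, classify_location,
                                 evaluate_effect, map_mutation,
                                 parse_protein_change, read_mutation_table)
from structppi.sidechains import HEAVY_ATOM_COUNT
from structppi.structure import Structure
from structppi.synthetic import make_helix


@pytest.mark.parametrize("text,expected", [
    ("R198W", ("R", 198, "W")),
    ("Q56*", ("Q", 56, "*")),
    ("E41*", ("E", 41, "*")),
    ("p.R945Q", ("R", 945, "Q")),
    ("R236L", ("R", 236, "L")),
])
def test_parse_protein_change(text, expected):
    assert parse_protein_change(text) == expected


@pytest.mark.parametrize("bad", ["X99Z", "R198", "198W", "RR98W", "B12C", ""])
def test_parse_protein_change_rejects_malformed(bad):
    with pytest.raises(MutationParseError):
        parse_protein_change(bad)


MUT_CSV = """gene,protein_change,mclass,histology,source
IL10RB,R198W,missense,endometrioid carcinoma,COSMIC
IL10RB,p.E41*,nonsense,lung adenocarcinoma,TCGA
IL10,Q56*,nonsense,lung adenocarcinoma,COSMIC
"""


class TestReadMutationTable:
    def test_three_row_fixture(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(MUT_CSV)
        recs = read_mutation_table(p)
        assert len(recs) == 3
        assert recs[0].gene == "IL10RB"
        assert recs[0].mclass == "missense"
        assert recs[1].protein_change == "E41*"  # "p." prefix stripped
        assert recs[1].mclass == "nonsense"

    def test_duplicated_rows_preserved(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(MUT_CSV + "IL10,Q56*,nonsense,lung adenocarcinoma,COSMIC\n")
        assert len(read_mutation_table(p)) == 4

    def test_missing_column_errors(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("gene,histology\nIL10,carcinoma\n")
        with pytest.raises(FormatError):
            read_mutation_table(p)

    def test_unparseable_change_kept_but_flagged(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(MUT_CSV + "IL10,X99Z!,other,carcinoma,other\n")
        recs = read_mutation_table(p)
        assert len(recs) == 4
        assert not recs[3].parse_ok
        assert all(r.parse_ok for r in recs[:3])


class TestMapMutation:
    def test_maps_with_offset(self):
        chain = make_helix(30, first_author_number=190, sequence="A" * 10 + "R" + "A" * 19)
        s = Structure(entry_id="m")
        s.add_chain(chain)
        rec = MutationRecord("G1", "R200W", "missense")
        rid = map_mutation(rec, StructureMapping("G1", "m", "A", 0), s)
        assert rid is not None and rid.author_number == 200

    def test_position_outside_model_is_unresolved(self):
        s = Structure(entry_id="m")
        s.add_chain(make_helix(20))
        rec = MutationRecord("G1", "A99V", "missense")
        assert map_mutation(rec, StructureMapping("G1", "m", "A", 0), s) is None

    def test_wild_type_identity_mismatch_is_hard_error(self):
        s = Structure(entry_id="m")
        s.add_chain(make_helix(20))  # poly-Ala
        rec = MutationRecord("G1", "R5W", "missense")
        with pytest.raises(MappingError):
            map_mutation(rec, StructureMapping("G1", "m", "A", 0), s)


def test_classify_location(truth1):
    tpl = truth1.template
    contacting = next(iter(tpl.side_a.contacting))
    nearby = next(iter(tpl.side_a.nearby))
    far = truth1.structure["A"].residues[0].id
    assert classify_location(contacting, tpl) == "contacting"
    assert classify_location(nearby, tpl) == "nearby"
    assert classify_location(far, tpl) == "non-interface"


class TestApplyMissense:
    def test_ala_to_gly_removes_cb(self, truth1):
        st = truth1.structure
        res = next(r for r in st["A"].residues if r.aa3 == "ALA")
        before = len(res.atoms)
        mutated = apply_missense(st, res.id, "G")
        after = mutated["A"].residue(res.id)
        assert after.aa3 == "GLY"
        assert len(after.atoms) == before - 1
        assert after.atom("CB") is None

    def test_identity_mutation_is_noop(self, truth1):
        st = truth1.structure
        res = next(r for r in st["A"].residues if r.aa3 == "ALA")
        mutated = apply_missense(st, res.id, "A")
        after = mutated["A"].residue(res.id)
        assert [a.name for a in after.atoms] == [a.name for a in res.atoms]
        for a1, a2 in zip(res.atoms, after.atoms):
            assert np.array_equal(a1.position, a2.position)

    def test_rebuilt_sidechain_has_full_atom_count(self, truth1):
        st = truth1.structure
        res = next(r for r in st["A"].residues if r.aa3 == "ALA")
        mutated = apply_missense(st, res.id, "R")
        after = mutated["A"].residue(res.id)
        assert after.aa3 == "ARG"
        assert len(after.atoms) == HEAVY_ATOM_COUNT["ARG"]
        # backbone untouched
        for name in ("N", "CA", "C", "O"):
            assert np.array_equal(after.atom(name).position,
                                  res.atom(name).position)

    def test_hotspot_swap_worsens_score(self, truth1):
        # tryptophan hot spot -> glycine: the pair potential prescribes a
        # strictly weaker interface
        st = truth1.structure
        lib = {truth1.template.template_id: truth1.template}
        wt = predict_interaction([st["A"]], [st["B"]], lib)
        rid = next(iter(truth1.hotspots["A"]))
        mutated = apply_missense(st, rid, "G")
        mut = predict_interaction([mutated["A"]], [st["B"]], lib)
        assert mut is not None
        assert mut.energy_score > wt.energy_score

    def test_missing_backbone_errors(self, truth1):
        st = truth1.structure.copy()
        res = st["A"].residues[5]
        res.atoms = [a for a in res.atoms if a.name != "CA"]
        with pytest.raises(MappingError):
            apply_missense(st, res.id, "W")


class TestApplyNonsense:
    def test_truncates_at_stop(self):
        s = Structure(entry_id="m")
        s.add_chain(make_helix(217, first_author_number=19))
        rid = s["A"].residue_by_number(41).id
        out = apply_nonsense(s, rid)
        assert len(out["A"]) == 22

    def test_stop_after_last_residue_keeps_chain(self):
        s = Structure(entry_id="m")
        s.add_chain(make_helix(20))
        out = apply_nonsense(s, s["A"].residues[-1].id)
        assert len(out["A"]) == 19

    def test_stop_before_first_residue_is_total_loss(self):
        s = Structure(entry_id="m")
        s.add_chain(make_helix(20, first_author_number=19))
        from structppi.structure import ResidueID
        with pytest.raises(TotalTruncationError):
            apply_nonsense(s, ResidueID("A", 19, ""))


class TestEvaluateEffect:
    def test_silent_record_never_changes_score(self, truth1):
        st = truth1.structure
        lib = {truth1.template.template_id: truth1.template}
        rec = MutationRecord("PROTA", "A1A", "coding-silent")
        eff = evaluate_effect([st["A"]], [st["B"]], "a", [], lib, record=rec,
                              location="non-interface")
        assert eff.verdict == "unchanged"
        assert eff.delta == 0.0

    def test_not_applicable_without_wild_type_prediction(self, truth1):
        from structppi.synthetic import make_helix as mh
        lib = {truth1.template.template_id: truth1.template}
        strandish = mh(40, (100, 0, 0), "A", sequence="S" * 40)
        eff = evaluate_effect([strandish], [strandish.copy()], "a", [], lib)
        assert eff.verdict == "not-applicable"
        assert eff.wt_score is None
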