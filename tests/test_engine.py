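import numpy as np
import pytest

from ptmpatch import (
    PeptideSpec,
    apply_all,
    apply_modification,
    make_peptide,
    parse_selection,
    render_sequence,
    renumber_structure,
    write_pdb,
)
from ptmpatch.engine import SelectionSpec
from ptmpatch.errors import (
    DuplicateSelectionError,
    NonCanonicalResidueError,
    SelectionError,
    StructuralIncompletenessError,
    ValidationError,
)
from ptmpatch.geometry import measure_internal
from ptmpatch.structure import AtomRecord

# (reaction_id, host sequence, 1-based position); hosts chosen so each
# executable plan has its parent residue available
DIRECT_PLANS = [
    ("phosphorylation", "GSG", 2),
    ("phosphorylation", "GTG", 2),
    ("phosphorylation", "GYG", 2),
    ("acetylation", "GKG", 2),
    ("methylation", "GKG", 2),
    ("dimethylation", "GKG", 2),
    ("trimethylation", "GKG", 2),
    ("methylation", "GRG", 2),
    ("hydroxylation", "GPG", 2),
    ("carboxylation", "GEG", 2),
    ("nitration", "GYG", 2),
    ("carbonylation", "GKG", 2),
    ("carbonylation", "GRG", 2),
    ("carbonylation", "GPG", 2),
    ("carbonylation", "GTG", 2),
    ("deamidation", "GNG", 2),
    ("deamidation", "GQG", 2),
    ("amidation", "GDG", 2),
    ("amidation", "GEG", 2),
    ("oxidation", "GMG", 2),
    ("oxidation", "GCG", 2),
    ("acetylation", "AGG", 1),  # N-terminal acetylation on Ala
]


class TestApplyModification:
    @pytest.mark.parametrize("reaction,seq,pos", DIRECT_PLANS)
    def test_atom_count_identity(self, registry, reaction, seq, pos):
        base = make_peptide(PeptideSpec(seq), registry)
        res = base.first_model.find_residue("A", pos)
        plan = registry.lookup_reaction(res.name, reaction)
        n = base.atom_count()
        mod = apply_modification(base, SelectionSpec("A", pos, "", reaction),
                                 plan, registry)
        expected = n - len(plan.deletions) + len(plan.additions)
        assert mod.atom_count() == expected
        assert mod.first_model.find_residue("A", pos).name == plan.product_code

    @pytest.mark.parametrize("reaction,seq,pos", DIRECT_PLANS)
    def test_added_atoms_match_template_internal_coordinates(
            self, registry, reaction, seq, pos):
        base = make_peptide(PeptideSpec(seq), registry)
        res = base.first_model.find_residue("A", pos)
        plan = registry.lookup_reaction(res.name, reaction)
        mod = apply_modification(base, SelectionSpec("A", pos, "", reaction),
                                 plan, registry)
        mres = mod.first_model.find_residue("A", pos)
        for add in plan.additions:
            d = mres.atom(add.name).position
            a = mres.atom(add.ic.ref_dihedral).position
            b = mres.atom(add.ic.ref_angle).position
            c = mres.atom(add.ic.ref_bond).position
            r, theta, phi = measure_internal(a, b, c, d)
            dphi = (phi - add.ic.phi + 180.0) % 360.0 - 180.0
            assert abs(r - add.ic.r) < 1e-6
            assert abs(theta - add.ic.theta) < 1e-6
            assert abs(dphi) < 1e-6

    def test_untouched_atoms_bit_identical(self, registry, ala_ser_ala):
        plan = registry.lookup_reaction("SER", "phosphorylation")
        mod = apply_modification(ala_ser_ala, SelectionSpec("A", 2, "", "x"),
                                 plan, registry)
        for resseq in (1, 3):
            before = ala_ser_ala.first_model.find_residue("A", resseq)
            after = mod.first_model.find_residue("A", resseq)
            for x, y in zip(before.atoms, after.atoms):
                assert np.array_equal(x.position, y.position)

    def test_record_kind_stays_atom(self, registry, ala_ser_ala):
        plan = registry.lookup_reaction("SER", "phosphorylation")
        mod = apply_modification(ala_ser_ala, SelectionSpec("A", 2), plan, registry)
        res = mod.first_model.find_residue("A", 2)
        assert all(a.record_kind == "ATOM" for a in res.atoms)

    def test_non_canonical_residue_rejected(self, registry, ala_ser_ala):
        s = ala_ser_ala.copy()
        res = s.first_model.find_residue("A", 2)
        res.name = "XYZ"
        res.non_canonical = True
        plan = registry.lookup_reaction("SER", "phosphorylation")
        with pytest.raises(NonCanonicalResidueError, match="cannot be modified"):
            apply_modification(s, SelectionSpec("A", 2), plan, registry)

    def test_missing_reference_atom_named(self, registry, ala_ser_ala):
        s = ala_ser_ala.copy()
        res = s.first_model.find_residue("A", 2)
        res.atoms = [a for a in res.atoms if a.name != "OG"]
        plan = registry.lookup_reaction("SER", "phosphorylation")
        with pytest.raises(StructuralIncompletenessError):
            apply_modification(s, SelectionSpec("A", 2), plan, registry)

    def test_nterm_reaction_rejected_mid_chain(self, registry):
        base = make_peptide(PeptideSpec("GAG"), registry)
        plan = registry.lookup_reaction("ALA", "acetylation")
        with pytest.raises(SelectionError, match="N-terminus"):
            apply_modification(base, SelectionSpec("A", 2), plan, registry)


class TestApplyAll:
    def test_empty_selection_identity(self, registry, ala_ser_ala):
        out, log = apply_all(ala_ser_ala, [], registry)
        assert write_pdb(out) == write_pdb(ala_ser_ala)
        assert log.entries == []

    def test_two_modifications_logged_in_order(self, registry):
        base = make_peptide(PeptideSpec("AKSA"), registry)
        sels = [parse_selection("A:2:carbonylation"),
                parse_selection("A:3:phosphorylation")]
        out, log = apply_all(base, sels, registry)
        assert [e.reaction_id for e in log.entries] == [
            "carbonylation", "phosphorylation"]
        assert [e.product_code for e in log.entries] == ["KAS", "SEP"]

    def test_duplicate_selection_rejected_before_edit(self, registry, ala_ser_ala):
        before = write_pdb(ala_ser_ala)
        sels = [parse_selection("A:2:phosphorylation"),
                parse_selection("A:2:oxidation")]
        with pytest.raises(DuplicateSelectionError):
            apply_all(ala_ser_ala, sels, registry)
        assert write_pdb(ala_ser_ala) == before

    def test_transactional_on_failure(self, registry, ala_ser_ala):
        before = write_pdb(ala_ser_ala)
        sels = [parse_selection("A:2:phosphorylation"),
                parse_selection("A:9:phosphorylation")]  # no residue 9
        with pytest.raises(SelectionError):
            apply_all(ala_ser_ala, sels, registry)
        assert write_pdb(ala_ser_ala) == before

    def test_chained_methylations(self, registry):
        base = make_peptide(PeptideSpec("GKG"), registry)
        out1, _ = apply_all(base, [parse_selection("A:2:methylation")], registry)
        out2, _ = apply_all(out1, [parse_selection("A:2:methylation")], registry)
        out3, _ = apply_all(out2, [parse_selection("A:2:methylation")], registry)
        assert out3.first_model.find_residue("A", 2).name == "M3L"

    def test_registry_reverse_restores_canonical_residue(self, registry):
        base = make_peptide(PeptideSpec("GNG"), registry)
        res0 = base.first_model.find_residue("A", 2)
        names0 = sorted(res0.atom_names())
        fwd, _ = apply_all(base, [parse_selection("A:2:deamidation")], registry)
        back, _ = apply_all(fwd, [parse_selection("A:2:amidation")], registry)
        res = back.first_model.find_residue("A", 2)
        assert res.name == "ASN"
        assert sorted(res.atom_names()) == names0

    def test_rmsd_of_unmodified_atoms_zero(self, registry):
        base = make_peptide(PeptideSpec("AKSA"), registry)
        out, _ = apply_all(base, [parse_selection("A:3:phosphorylation")], registry)
        for seq in (1, 2, 4):
            b = base.first_model.find_residue("A", seq)
            m = out.first_model.find_residue("A", seq)
            d = np.array([x.position for x in b.atoms]) - np.array(
                [x.position for x in m.atoms])
            assert np.max(np.abs(d)) == 0.0


class TestRenumber:
    def test_idempotent(self, ala_ser_ala):
        once = renumber_structure(ala_ser_ala)
        twice = renumber_structure(once)
        assert [a.serial for a in once.first_model.atoms()] == [
            a.serial for a in twice.first_model.atoms()]

    def test_gapless_after_deletion(self, registry, ala_ser_ala):
        s = ala_ser_ala.copy()
        res = s.first_model.find_residue("A", 2)
        res.atoms = res.atoms[:-1]
        out = renumber_structure(s)
        serials = [a.serial for a in out.first_model.atoms()]
        assert serials == list(range(1, len(serials) + 1))

    def test_het_after_protein(self, ala_ser_ala):
        s = ala_ser_ala.copy()
        s.first_model.het_records.append(
            AtomRecord("HETATM", 1, "O", "", "HOH", "A", 90, "",
                       np.array([3.0, 3, 3]), element="O"))
        out = renumber_structure(s)
        max_atom = max(a.serial for a in out.first_model.atoms())
        assert out.first_model.het_records[0].serial > max_atom


class TestRenderSequence:
    def test_modified_sequence_uses_product_code(self, registry, ala_ser_ala):
        out, _ = apply_all(ala_ser_ala,
                           [parse_selection("A:2:phosphorylation")], registry)
        assert render_sequence(out) == "A: ALA SEP ALA\n"

    def test_unmodified_sequence(self, ala_ser_ala):
        assert render_sequence(ala_ser_ala) == "A: ALA SER ALA\n"

    def test_unknown_residue_shown_as_exclamation_mark(self, ala_ser_ala):
        s = ala_ser_ala.copy()
        res = s.first_model.find_residue("A", 2)
        res.name = "XYZ"
        res.non_canonical = True
        assert render_sequence(s) == "A: ALA ! ALA\n"


class TestParseSelection:
    def test_basic(self):
        sel = parse_selection("A:58:phosphorylation")
        assert sel == SelectionSpec("A", 58, "", "phosphorylation")

    def test_insertion_code(self):
        sel = parse_selection("B:12A:oxidation")
        assert (sel.chain_id, sel.res_seq, sel.i_code) == ("B", 12, "A")

    @pytest.mark.parametrize("bad", ["A:x:phos", "A:1", "AB:1:phos", "A:1:"])
    def test_invalid_tokens(self, bad):
        with pytest.raises(ValidationError):
            parse_selection(bad)
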