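from fractions import Fraction

import pytest

import pedrel as pr
from pedrel.pedigree import Diagnostic, Member, Pedigree


class TestReadPed:
    def test_minimal_single_founder(self):
        ped = pr.read_ped("1 0 0 1\n")
        assert len(ped) == 1
        m = ped.member("1")
        assert m.is_founder and m.sex == "male"

    def test_incest_pedigree_parses(self, incest):
        assert len(incest) == 5
        assert sorted(incest.founders) == ["1", "2"]
        child = incest.member("5")
        assert (child.father_id, child.mother_id) == ("1", "3")

    def test_comments_blank_lines_and_header_skipped(self):
        text = "# a comment\nid fid mid sex\n\n1 0 0 1\n2 0 0 2\n"
        assert len(pr.read_ped(text)) == 2

    def test_six_column_plink_dialect_drops_family_id(self):
        ped = pr.read_ped("FAM 1 0 0 1 2\nFAM 2 0 0 2 1\n")
        assert ped.ids == ["1", "2"]
        assert "affected" in ped.member("1").statuses
        assert "affected" not in ped.member("2").statuses

    def test_affection_column(self):
        ped = pr.read_ped("1 0 0 1 2\n2 0 0 2 -9\n")
        assert "affected" in ped.member("1").statuses
        assert ped.member("2").statuses == frozenset()

    @pytest.mark.parametrize("text, exc", [
        ("1 0 0\n", pr.MalformedLine),                      # wrong column count
        ("1 0 0 5\n", pr.MalformedLine),                    # bad sex code
        ("3 1 0 2\n1 0 0 1\n", pr.SingleParent),            # father only
        ("1 0 0 1\n1 0 0 2\n", pr.DuplicateId),
        ("1 0 0 1\n3 1 9 1\n", pr.UnknownParent),           # mother not a row
        ("1 0 0 2\n2 0 0 2\n3 1 2 1\n", pr.SexConflict),    # female father
    ])
    def test_malformed_inputs_raise_named_errors(self, text, exc):
        with pytest.raises(exc):
            pr.read_ped(text)

    def test_error_messages_name_the_offender(self):
        with pytest.raises(pr.SingleParent, match="'3'"):
            pr.read_ped("1 0 0 1\n3 1 0 2\n")
        with pytest.raises(pr.UnknownParent, match="'9'"):
            pr.read_ped("1 0 0 1\n3 1 9 1\n")


class TestWritePed:
    def test_single_founder_line(self):
        ped = pr.read_ped("1 0 0 1\n")
        assert pr.write_ped(ped).strip() == "1 0 0 1"

    def test_incest_serialisation(self, incest):
        lines = pr.write_ped(incest).strip().splitlines()
        assert len(lines) == 5
        assert lines[4].split()[:3] == ["5", "1", "3"]

    @pytest.mark.parametrize("name", pr.FIXTURE_NAMES)
    def test_roundtrip_identity_on_all_fixtures(self, name):
        ped = pr.builtin(name)
        assert pr.read_ped(pr.write_ped(ped)) == ped


class TestValidate:
    @pytest.mark.parametrize("name", pr.FIXTURE_NAMES)
    def test_fixtures_have_no_violations(self, name):
        diags = pr.validate(pr.builtin(name))
        assert [d for d in diags if d.level == "error"] == []

    def test_sex_conflict_reported(self):
        members = [Member(id="1", sex="female"), Member(id="2", sex="female"),
                   Member(id="3", father_id="1", mother_id="2", sex="male")]
        diags = pr.validate(Pedigree(members, validated=False))
        assert [d.code for d in diags if d.level == "error"] == ["SexConflict"]

    def test_two_components_warned(self):
        ped = pr.read_ped("1 0 0 1\n2 0 0 2\n3 1 2 1\n9 0 0 1\n")
        warn = [d for d in pr.validate(ped) if d.code == "Disconnected"]
        assert len(warn) == 1 and "2" in warn[0].message

    def test_cycle_detected(self):
        members = [Member(id="1", father_id="3", mother_id="2", sex="male"),
                   Member(id="2", sex="female"),
                   Member(id="3", father_id="1", mother_id="2", sex="male")]
        diags = pr.validate(Pedigree(members, validated=False))
        assert any(d.code == "CycleError" for d in diags)
        with pytest.raises(pr.CycleError):
            Pedigree(members)


class TestStructure:
    def test_ancestors_of_founder_empty(self, fig1):
        assert fig1.ancestors("1") == set()

    def test_ancestors_fig1(self, fig1):
        assert fig1.ancestors("6") == {"4", "5", "1", "2", "3"}

    def test_ancestors_incest(self, incest):
        assert incest.ancestors("5") == {"1", "2", "3"}

    def test_never_own_ancestor(self, habsburg):
        for i in habsburg.ids:
            assert i not in habsburg.ancestors(i)

    def test_unknown_member(self, fig1):
        with pytest.raises(pr.UnknownMember):
            fig1.ancestors("99")

    def test_lenient_name_lookup(self, habsburg):
        assert habsburg.member("Philip IV").id == "Philip_IV"


class TestBuiltin:
    def test_catalogue_contains_required_names(self):
        required = {"trio", "full-siblings", "half-siblings", "grandparent",
                    "aunt-nephew", "first-cousins", "second-cousins",
                    "quadruple-half-first-cousins", "fig1-example",
                    "figS1-incest", "habsburg"}
        assert required <= set(pr.FIXTURE_NAMES)

    def test_fig1_structure_forced_by_path_list(self, fig1):
        assert len(fig1) == 7
        assert sorted(fig1.founders) == ["1", "2", "3"]
        four, five = fig1.member("4"), fig1.member("5")
        assert (four.father_id, four.mother_id) == ("1", "2")
        assert (five.father_id, five.mother_id) == ("3", "2")
        for c in ("6", "7"):
            m = fig1.member(c)
            assert (m.father_id, m.mother_id) == ("4", "5")

    def test_second_cousins_grandparents_are_full_siblings(self):
        ped = pr.builtin("second-cousins")
        a, b = pr.FIXTURE_PAIRS["second-cousins"]
        pa = ped.member(a)
        pb = ped.member(b)
        gpa = {pa_p for p in (pa.father_id, pa.mother_id)
               for pa_p in (ped.member(p).father_id, ped.member(p).mother_id)
               if pa_p}
        gpb = {pb_p for p in (pb.father_id, pb.mother_id)
               for pb_p in (ped.member(p).father_id, ped.member(p).mother_id)
               if pb_p}
        sibs = [(x, y) for x in gpa for y in gpb
                if x != y
                and ped.member(x).father_id is not None
                and ped.member(x).father_id == ped.member(y).father_id
                and ped.member(x).mother_id == ped.member(y).mother_id]
        assert sibs, "no pair of full-sibling grandparents found"

    def test_habsburg_members_present(self, habsburg):
        for name in ("Philip_IV", "Mariana", "Charles_II", "William_V", "Renata"):
            assert name in habsburg

    def test_unknown_fixture_lists_names(self):
        with pytest.raises(pr.UnknownFixture, match="habsburg"):
            pr.builtin("nope")

    def test_status_annotations_roundtrip(self, fig1):
        assert fig1.member("2").statuses == frozenset({"carrier"})
        assert fig1.member("1").statuses == frozenset({"deceased"})
        assert fig1.member("6").statuses == frozenset({"affected"})
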