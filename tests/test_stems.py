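import pytest
from hypothesis import given, settings, strategies as st

from innlint import (
    classify_compliance,
    compliance_rate,
    load_lexicon,
    match_stems,
    resolve_position_sense,
    write_lexicon,
)
from innlint.stems import (
    LexiconError,
    Spelling,
    StemEntry,
    StemLexicon,
    preferred_stem_nodes,
)


class TestLexiconStructure:
    def test_ast_taxon(self, lexicon):
        assert set(lexicon.children("ast")) == {"lukast", "milast", "trodast", "zolast"}
        assert lexicon.depth("ast") == 0
        assert lexicon.depth("lukast") == 1
        assert lexicon.root("lukast") == "ast"

    def test_lone_stems_have_no_parent(self, lexicon):
        for sid in ("astine", "azepide", "cromil"):
            assert lexicon[sid].parent is None

    def test_allomorphs_share_one_entry(self, lexicon):
        texts = {s.text for s in lexicon["profen"].spellings}
        assert texts == {"profen", "profene"}
        assert {s.text for s in lexicon["metasone"].spellings} == {"metasone", "methasone"}

    def test_self_parent_is_a_load_error(self):
        with pytest.raises(LexiconError, match="cycle|unknown"):
            StemLexicon([StemEntry("x", [Spelling("x", "suffix")], parent="x")])

    def test_cycle_is_a_load_error(self):
        with pytest.raises(LexiconError, match="cycle"):
            StemLexicon(
                [
                    StemEntry("a", [Spelling("aa", "suffix")], parent="b"),
                    StemEntry("b", [Spelling("bb", "suffix")], parent="a"),
                ]
            )

    def test_unknown_parent_is_a_load_error(self):
        with pytest.raises(LexiconError, match="unknown parent"):
            StemLexicon([StemEntry("a", [Spelling("aa", "suffix")], parent="ghost")])

    def test_duplicate_stem_id_is_a_load_error(self):
        with pytest.raises(LexiconError, match="duplicate"):
            StemLexicon(
                [
                    StemEntry("a", [Spelling("aa", "suffix")]),
                    StemEntry("a", [Spelling("ab", "suffix")]),
                ]
            )

    def test_linter_flags_single_letter_distinctions(self, lexicon):
        assert any("'fenin'" in w and "'fenine'" in w for w in lexicon.warnings)
        assert any("'micin'" in w and "'mycin'" in w for w in lexicon.warnings)

    def test_linter_flags_non_extending_substems(self, lexicon):
        assert any("'viroc'" in w and "does not extend" in w for w in lexicon.warnings)
        # -lukast extends -ast, so it is not flagged
        assert not any("'lukast'" in w and "does not extend" in w for w in lexicon.warnings)

    def test_round_trip(self, lexicon, tmp_path):
        p = tmp_path / "lex.tsv"
        write_lexicon(lexicon, p)
        again = load_lexicon(p)
        assert set(again.entries) == set(lexicon.entries)
        for sid, e in lexicon.entries.items():
            f = again[sid]
            assert set(f.spellings) == set(e.spellings)
            assert f.parent == e.parent
            assert f.definition == e.definition
            assert f.position_senses == e.position_senses


class TestMatchStems:
    def test_montelukast(self, lexicon):
        ids = [(m.stem_id, m.position, m.specificity) for m in match_stems("montelukast", lexicon)]
        assert ids[0] == ("lukast", "suffix", 1)
        assert ("ast", "suffix", 0) in ids

    def test_maraviroc_implies_vir_by_taxonomy(self, lexicon):
        ms = match_stems("maraviroc", lexicon)
        assert [m.stem_id for m in ms][:2] == ["viroc", "vir"]
        # vir also literally occurs inside the name, so it is a direct hit
        vir = next(m for m in ms if m.stem_id == "vir")
        assert (vir.start, vir.end, vir.implied) == (4, 7, False)

    def test_implied_without_literal_occurrence(self):
        lex = StemLexicon(
            [
                StemEntry("vir", [Spelling("vir", "freefix")]),
                StemEntry("teravir", [Spelling("oc", "suffix")], parent="vir"),
            ]
        )
        ms = match_stems("maoc", lex)
        assert [(m.stem_id, m.implied) for m in ms] == [("teravir", False), ("vir", True)]

    def test_virginiamycin_freefix_false_positive(self, lexicon):
        ms = match_stems("virginiamycin", lexicon)
        ids = {m.stem_id for m in ms}
        assert {"vir", "mycin"} <= ids  # vir matches although the name is an antibiotic

    def test_lone_stem(self, lexicon):
        ms = match_stems("nedocromil", lexicon)
        assert [m.stem_id for m in ms] == ["cromil"]

    def test_riodipine_ambiguity(self, lexicon):
        ms = match_stems("riodipine", lexicon)
        flags = {m.stem_id: m.ambiguous for m in ms}
        assert flags["dipine"] and flags["pine"]

    def test_affix_constraints(self, lexicon):
        # suffix stem not at the end does not match
        assert not any(m.stem_id == "ast" for m in match_stems("astiline", lexicon))
        # prefix stem not at the start does not match
        assert not any(m.stem_id == "arte" for m in match_stems("bioarte", lexicon))

    def test_input_validation(self, lexicon):
        with pytest.raises(ValueError):
            match_stems("Montelukast", lexicon)

    @given(st.text(alphabet="abcdefgilmnoprstuvz", min_size=1, max_size=14))
    @settings(max_examples=1500, deadline=None)
    def test_matcher_equals_brute_force_oracle(self, name):
        lex = self.lex  # set in setup below
        got = {(m.stem_id, m.start, m.end) for m in match_stems(name, lex) if not m.implied}
        expected = set()
        for e in lex.entries.values():
            for sp in e.spellings:
                k = len(sp.text)
                for i in range(len(name) - k + 1):
                    if name[i : i + k] != sp.text:
                        continue
                    if sp.affix_class == "suffix" and i + k != len(name):
                        continue
                    if sp.affix_class == "prefix" and i != 0:
                        continue
                    if sp.affix_class == "infix" and not (0 < i and i + k < len(name)):
                        continue
                    expected.add((e.stem_id, i, i + k))
        assert got == expected

    @pytest.fixture(autouse=True)
    def _share_lexicon(self, lexicon):
        type(self).lex = lexicon

    @given(st.text(alphabet="abcdefgilmnoprstuvz", min_size=1, max_size=14))
    @settings(max_examples=800, deadline=None)
    def test_position_soundness_and_hyperonym_closure(self, name):
        lex = self.lex
        ms = match_stems(name, lex)
        ids = {m.stem_id for m in ms}
        for m in ms:
            assert name[m.start : m.end] == m.spelling or m.implied
            if m.position == "suffix":
                assert m.end == len(name)
            if m.position == "prefix":
                assert m.start == 0
            for anc in lex.ancestors(m.stem_id):
                assert anc in ids


class TestPositionSenses:
    def test_fos_suffix_is_the_hyperonym_sense(self, lexicon):
        m = next(m for m in match_stems("uredofos", lexicon) if m.stem_id == "fos")
        assert m.position == "suffix"
        assert "insecticides" in resolve_position_sense(m, lexicon)

    def test_fos_infix_is_the_sub_sense(self, lexicon):
        m = next(m for m in match_stems("benfosformin", lexicon) if m.stem_id == "fos")
        assert m.position == "infix"
        assert "other than" in resolve_position_sense(m, lexicon)

    def test_grel_sense_is_position_invariant(self, lexicon):
        suffix = next(m for m in match_stems("anagrel", lexicon) if m.stem_id == "grel")
        infix = next(m for m in match_stems("tigrelor", lexicon) if m.stem_id == "grel")
        assert suffix.position == "suffix" and infix.position == "infix"
        assert resolve_position_sense(suffix, lexicon) == resolve_position_sense(infix, lexicon)


class TestCompliance:
    def test_direct_suffix_match_is_compliant(self, lexicon):
        assert classify_compliance("montelukast", "lukast", lexicon).verdict == "compliant"

    def test_missing_expected_stem_is_noncompliant(self, lexicon):
        assert classify_compliance("clortermine", "orex", lexicon).verdict == "noncompliant"

    def test_compliant_with_ambiguity_note(self, lexicon):
        v = classify_compliance("riodipine", "dipine", lexicon)
        assert v.verdict == "compliant"
        assert "pine" in v.ambiguous_with

    def test_no_expectation_is_unlisted(self, lexicon):
        assert classify_compliance("abacavir", None, lexicon).verdict == "unlisted"

    def test_unknown_stem_id_raises(self, lexicon):
        with pytest.raises(ValueError):
            classify_compliance("abacavir", "nonexistent", lexicon)

    def test_rate_all_compliant(self, lexicon):
        rate, verdicts = compliance_rate(
            [("montelukast", "lukast"), ("maraviroc", "viroc"), ("amikacin", "kacin")],
            lexicon,
        )
        assert rate == 0.0
        assert all(v.verdict == "compliant" for v in verdicts)

    def test_rate_counts_noncompliant_and_unlisted(self, lexicon):
        rate, _ = compliance_rate(
            [("montelukast", "lukast"), ("clortermine", "orex"), ("abacavir", None)],
            lexicon,
        )
        assert rate == pytest.approx(2 / 3)

    def test_empty_sample_raises(self, lexicon):
        with pytest.raises(ValueError):
            compliance_rate([], lexicon)


def test_preferred_nodes_shadow_contained_unrelated_readings(lexicon):
    all_ids, deep = preferred_stem_nodes("giractide", lexicon)
    assert "actide" in all_ids and "tide" not in all_ids
    all_ids, _ = preferred_stem_nodes("riodipine", lexicon)
    assert "dipine" in all_ids and "pine" not in all_ids
    # same-taxon containment is kept (vir inside viroc)
    all_ids, deep = preferred_stem_nodes("maraviroc", lexicon)
    assert {"viroc", "vir"} <= all_ids and "viroc" in deep
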