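import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from innlint import (
    SimilarPair,
    annotate_shared_stems,
    levenshtein,
    make_corpus,
    screen_pairs,
    summarize,
)
from innlint.similarity import levenshtein_capped


def led_recursive(a, b):
    """Memo-free exponential recursion; the independent definition of LED."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        led_recursive(a[1:], b) + 1,
        led_recursive(a, b[1:]) + 1,
        led_recursive(a[1:], b[1:]) + (a[0] != b[0]),
    )


@pytest.mark.parametrize(
    "a, b, d",
    [
        ("book", "back", 2),
        ("mercaptopurine", "mercaptamine", 4),
        ("arterolane", "arteflene", 3),
        ("salazosulfadimidine", "salazosulfamide", 4),
        ("siplizumab", "ruplizumab", 2),
        ("siplizumab", "teplizumab", 2),
        ("alverine", "salverine", 1),
        ("peplomycin", "peliomycin", 2),
        ("amezepine", "mezepine", 1),
        ("x", "", 1),
        ("", "", 0),
        ("same", "same", 0),
    ],
)
def test_worked_examples(a, b, d):
    assert levenshtein(a, b) == d
    assert levenshtein(b, a) == d


def test_exhaustive_recursive_oracle_short_strings():
    strings = [
        "".join(t)
        for n in range(4)
        for t in itertools.product("abc", repeat=n)
    ]
    for a, b in itertools.combinations_with_replacement(strings, 2):
        assert levenshtein(a, b) == led_recursive(a, b)


def test_edlib_cross_check_random_strings():
    import edlib

    rng = np.random.default_rng(1234)
    alphabet = "abc"
    strings = [
        "".join(rng.choice(list(alphabet), size=rng.integers(0, 7)))
        for _ in range(300)
    ]
    for a, b in itertools.combinations(strings, 2):
        if not a or not b:
            continue  # edlib requires non-empty queries
        assert levenshtein(a, b) == edlib.align(a, b)["editDistance"]


@given(
    st.text(alphabet="abcde", max_size=10),
    st.text(alphabet="abcde", max_size=10),
    st.text(alphabet="abcde", max_size=10),
)
@settings(max_examples=1000, deadline=None)
def test_metric_axioms(a, b, c):
    dab = levenshtein(a, b)
    assert (dab == 0) == (a == b)
    assert dab == levenshtein(b, a)
    assert dab <= levenshtein(a, c) + levenshtein(c, b)
    assert abs(len(a) - len(b)) <= dab <= max(len(a), len(b))


@given(
    st.text(alphabet="abcd", max_size=12),
    st.text(alphabet="abcd", max_size=12),
    st.integers(1, 6),
)
@settings(max_examples=500, deadline=None)
def test_capped_variant_is_behaviourally_identical(a, b, cap):
    full = levenshtein(a, b)
    capped = levenshtein_capped(a, b, cap)
    assert capped == (full if full <= cap else cap + 1)


class TestScreenPairs:
    def test_paper_example_pairs_found(self, lexicon):
        sample = make_corpus([("alverine", 1958)])
        universe = make_corpus(
            [("alverine", 1958), ("salverine", 1961), ("unrelatedone", 2000)]
        )
        res = screen_pairs(sample, universe)
        assert [(p.name_a, p.name_b, p.led) for p in res.pairs] == [
            ("alverine", "salverine", 1)
        ]

    def test_one_sample_name_two_neighbours(self):
        sample = make_corpus([("siplizumab", 2000)])
        universe = make_corpus(
            [("ruplizumab", 1999), ("teplizumab", 2001), ("siplizumab", 2000)]
        )
        res = screen_pairs(sample, universe)
        assert {(p.name_a, p.name_b) for p in res.pairs} == {
            ("ruplizumab", "siplizumab"),
            ("siplizumab", "teplizumab"),
        }
        assert all(p.led == 2 for p in res.pairs)

    def test_self_pairs_excluded(self):
        c = make_corpus([("aaa", 2000)])
        res = screen_pairs(c, c)
        assert res.pairs == []
        assert res.comparisons == 1
        assert res.comparisons_excluding_self == 0

    def test_count_conservation_and_dedup(self):
        sample = make_corpus([("abcde", 2000), ("abcdf", 2001)])
        universe = make_corpus([("abcde", 2000), ("abcdf", 2001), ("zzzzz", 2002)])
        res = screen_pairs(sample, universe)
        # (abcde, abcdf) arises twice but is kept once
        assert [(p.name_a, p.name_b, p.led) for p in res.pairs] == [("abcde", "abcdf", 1)]
        assert res.comparisons == 6
        assert res.comparisons_excluding_self == 4
        assert res.retained + res.discarded == res.comparisons_excluding_self

    def test_raising_max_led_only_adds_pairs(self):
        rng = np.random.default_rng(5)
        names = ["".join(rng.choice(list("abcd"), size=6)) for _ in range(40)]
        c = make_corpus(((n, 2000) for n in set(names)))
        low = screen_pairs(c, c, max_led=2)
        high = screen_pairs(c, c, max_led=4)
        low_set = {(p.name_a, p.name_b, p.led) for p in low.pairs}
        high_set = {(p.name_a, p.name_b, p.led) for p in high.pairs}
        assert low_set <= high_set

    def test_invalid_max_led(self):
        c = make_corpus([("abc", 2000)])
        with pytest.raises(ValueError):
            screen_pairs(c, c, max_led=0)


class TestAnnotation:
    def test_prefixal_stem_shared(self, lexicon):
        [p] = annotate_shared_stems([SimilarPair("arteflene", "arterolane", 3)], lexicon)
        assert p.shares_stem and not p.shares_substem

    def test_terminal_letters_without_common_stem(self, lexicon):
        [p] = annotate_shared_stems([SimilarPair("giractide", "lagatide", 4)], lexicon)
        assert not p.shares_stem and not p.shares_substem

    def test_mab_pair_shares_stem_and_substems(self, lexicon):
        [p] = annotate_shared_stems([SimilarPair("siplizumab", "teplizumab", 2)], lexicon)
        assert p.shares_stem and p.shares_substem

    def test_allomorph_pair_shares_stem(self, lexicon):
        [p] = annotate_shared_stems([SimilarPair("diprofene", "indoprofen", 4)], lexicon)
        assert p.shares_stem

    def test_substem_implies_stem(self, lexicon):
        pairs = [
            SimilarPair("montelukast", "zafirlukast", 4),
            SimilarPair("cilomilast", "montelukast", 4),
        ]
        for p in annotate_shared_stems(pairs, lexicon):
            assert not p.shares_substem or p.shares_stem


class TestSummarize:
    def test_toy_counts(self, lexicon):
        pairs = [
            SimilarPair("a" * 5, "b" * 5, 1, shares_stem=True, shares_substem=False),
            SimilarPair("c" * 5, "d" * 5, 1, shares_stem=True, shares_substem=True),
        ]
        s = summarize(pairs)
        row = s.row(1)
        assert (row.frequency, row.pct_sharing_stem, row.pct_sharing_stem_and_substem) == (
            2,
            100.0,
            50.0,
        )

    def test_empty_input(self):
        s = summarize([], max_led=4)
        assert [r.frequency for r in s.rows] == [0, 0, 0, 0]
        assert all(r.pct_sharing_stem is None for r in s.rows)
        assert s.rows[0].render() == (1, 0, "—", "—")

    def test_percent_ordering_invariant(self):
        rng = np.random.default_rng(9)
        pairs = []
        for _ in range(200):
            led = int(rng.integers(1, 5))
            sub = bool(rng.integers(2))
            stem = sub or bool(rng.integers(2))
            pairs.append(SimilarPair(f"a{rng.integers(10**6)}", "zzz", led, stem, sub))
        for row in summarize(pairs, 4).rows:
            if row.frequency:
                assert row.pct_sharing_stem >= row.pct_sharing_stem_and_substem
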