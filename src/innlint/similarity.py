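"""Levenshtein edit distance and stem-stratified pair screening.

The screen compares a sample of names against a whole corpus, retains
pairs whose Levenshtein edit distance (LED: minimum number of
single-character insertions, deletions or substitutions) falls in
``[1, max_led]``, annotates each retained pair with whether the two
names share a stem or additionally a sub-stem, and summarises the
stem-sharing percentages per LED value.  The qualitative finding this
reproduces: the closer two names are orthographically, the more likely
they are to share a stem — the taxonomy that conveys pharmacology is
itself a driver of look-alike confusion risk.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .corpus import Corpus


def levenshtein(a: str, b: str) -> int:
    """Classic unit-cost edit distance (no transposition).

    Symmetric, and bounded by ``|len(a)-len(b)| <= d <= max(len(a), len(b))``.
    """
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


def levenshtein_capped(a: str, b: str, cap: int) -> int:
    """Edit distance if it is ``<= cap``, else ``cap + 1``.

    Behaviourally identical to :func:`levenshtein` within the cap; the
    length pre-check and row-minimum early exit only prune distances
    that are already known to exceed it.
    """
    if abs(len(a) - len(b)) > cap:
        return cap + 1
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a) if len(a) <= cap else cap + 1
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        if min(cur) > cap:
            return cap + 1
        prev = cur
    return prev[-1] if prev[-1] <= cap else cap + 1


@dataclass(frozen=True)
class SimilarPair:
    """Two distinct names with their LED and stem-sharing flags.

    Stored canonically with ``name_a < name_b``; ``shares_substem``
    implies ``shares_stem``.
    """

    name_a: str
    name_b: str
    led: int
    shares_stem: bool = False
    shares_substem: bool = False


@dataclass
class ScreenResult:
    """Retained pairs plus the comparison accounting of the screen."""

    pairs: list[SimilarPair]
    comparisons: int  # |sample| x |universe|, the paper-style product
    comparisons_excluding_self: int
    retained: int
    discarded: int
    max_led: int


def screen_pairs(sample: Corpus, universe: Corpus, max_led: int = 4) -> ScreenResult:
    """LED-screen every (sample, universe) pair, keeping LED in [1, max_led].

    Self-pairs (identical names) are excluded; a pair arising twice
    (both members in the sample) is kept once, canonically ordered.
    """
    if max_led < 1:
        raise ValueError("max_led must be >= 1")
    sample_names = sample.names
    universe_names = universe.names
    seen: set[tuple[str, str]] = set()
    pairs: list[SimilarPair] = []
    overlap = 0
    for s in sample_names:
        for u in universe_names:
            if s == u:
                overlap += 1
                continue
            key = (s, u) if s < u else (u, s)
            if key in seen:
                continue
            d = levenshtein_capped(s, u, max_led)
            seen.add(key)
            if 1 <= d <= max_led:
                pairs.append(SimilarPair(name_a=key[0], name_b=key[1], led=d))
    total = len(sample_names) * len(universe_names)
    pairs.sort(key=lambda p: (p.led, p.name_a, p.name_b))
    return ScreenResult(
        pairs=pairs,
        comparisons=total,
        comparisons_excluding_self=total - overlap,
        retained=len(pairs),
        discarded=(total - overlap) - len(pairs),
        max_led=max_led,
    )


def annotate_shared_stems(pairs: Sequence[SimilarPair], lex) -> list[SimilarPair]:
    """Set the stem-sharing flags of each pair using the taxonomy matcher.

    Sharing is by taxonomy node identity (stem_id), not spelling, so
    allomorph pairs (indoprofen/diprofene) share a stem.  A shared node
    at depth >= 1 additionally sets ``shares_substem``; implied
    hyperonym matches count, so two names carrying different sub-stems
    of one taxon share the root stem.  Sharing uses preferred readings
    (:func:`innlint.stems.preferred_stem_nodes`): common terminal
    letters that are merely a shadowed reading of a longer unrelated
    stem (giractide's ``-tide`` inside ``-actide``) do not count.
    """
    from .stems import preferred_stem_nodes

    cache: dict[str, tuple[frozenset, frozenset]] = {}

    def node_sets(name: str):
        if name not in cache:
            cache[name] = preferred_stem_nodes(name, lex)
        return cache[name]

    out = []
    for p in pairs:
        a_all, a_deep = node_sets(p.name_a)
        b_all, b_deep = node_sets(p.name_b)
        shares = bool(a_all & b_all)
        shares_sub = bool(a_deep & b_deep)
        out.append(replace(p, shares_stem=shares, shares_substem=shares_sub))
    return out


@dataclass(frozen=True)
class SimilarityRow:
    led: int
    frequency: int
    pct_sharing_stem: Optional[float]  # None when the bin is empty
    pct_sharing_stem_and_substem: Optional[float]

    def render(self) -> tuple:
        fmt = lambda v: "—" if v is None else f"{v:.1f}"
        return (self.led, self.frequency, fmt(self.pct_sharing_stem), fmt(self.pct_sharing_stem_and_substem))


@dataclass
class SimilaritySummary:
    rows: list[SimilarityRow]

    def row(self, led: int) -> SimilarityRow:
        return next(r for r in self.rows if r.led == led)


def summarize(pairs: Sequence[SimilarPair], max_led: Optional[int] = None) -> SimilaritySummary:
    """Per-LED frequency and stem-sharing percentages (0-100 scale).

    Empty LED bins report frequency 0 with undefined percentages
    (``None``; rendered as an em dash in tables).
    """
    if max_led is None:
        max_led = max((p.led for p in pairs), default=0)
    rows = []
    for led in range(1, max_led + 1):
        bin_pairs = [p for p in pairs if p.led == led]
        n = len(bin_pairs)
        if n == 0:
            rows.append(SimilarityRow(led, 0, None, None))
            continue
        stem = 100.0 * sum(p.shares_stem for p in bin_pairs) / n
        sub = 100.0 * sum(p.shares_substem for p in bin_pairs) / n
        rows.append(SimilarityRow(led, n, stem, sub))
    return SimilaritySummary(rows=rows)
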