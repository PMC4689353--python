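"""Orthographic compliance checks and word-length statistics.

Two of the WHO naming principles are purely orthographic:

* isolated letters, isolated numbers and hyphens are undesirable in a
  name (they are easily misread as footnote markers, doses, or line
  breaks);
* the graphs/digraphs ``ph``, ``th``, ``ae``, ``oe``, ``y``, ``h`` and
  ``k`` should be avoided (they map poorly onto the phonologies of the
  official WHO languages), *unless* the offending letters sit inside a
  recommended pharmacological stem (e.g. the ``k`` of ``-kacin`` in
  amikacin).

This module scans single-word names for the prohibited patterns,
aggregates the counts into per-pattern and per-decade tables, inspects
multi-word names for isolated elements, and computes character-count
statistics with an outlier list.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .corpus import Corpus, MULTI, SINGLE

#: Two-character prohibited patterns, tried before single characters.
DIGRAPHS: tuple[str, ...] = ("ph", "th", "ae", "oe")
#: Single-character prohibited patterns.
MONOGRAPHS: tuple[str, ...] = ("y", "h", "k")
#: All prohibited patterns, in canonical reporting order.
PROHIBITED_PATTERNS: tuple[str, ...] = DIGRAPHS + MONOGRAPHS

_LOWER_ALPHA = re.compile(r"^[a-z]+$")


@dataclass(frozen=True)
class DigraphHit:
    """One occurrence of a prohibited (di)graph in a normalized name.

    ``exempt`` is true when the hit lies inside a recommended-stem
    occurrence (only computed when a lexicon is supplied to the scan).
    """

    pattern: str
    start: int
    exempt: bool = False

    @property
    def end(self) -> int:
        return self.start + len(self.pattern)


def scan_prohibited(name: str, lexicon=None) -> list[DigraphHit]:
    """Scan a lowercase alphabetic name for prohibited (di)graphs.

    The scan is left-to-right and greedy: at each offset the two-letter
    patterns are tried before the single letters, and the scan advances
    past a match, so hits never overlap.  In particular an ``h`` inside
    a matched ``ph``/``th`` is not additionally reported, while an ``h``
    elsewhere (e.g. in ``ch``) is.

    If ``lexicon`` (a :class:`~innlint.stems.StemLexicon`) is given,
    hits whose span lies fully inside a matched stem occurrence are
    marked ``exempt=True`` but still returned.
    """
    if not _LOWER_ALPHA.match(name):
        raise ValueError(f"expected a lowercase alphabetic name, got {name!r}")
    hits: list[tuple[str, int]] = []
    i = 0
    n = len(name)
    while i < n:
        matched = None
        for pat in DIGRAPHS:
            if name.startswith(pat, i):
                matched = pat
                break
        if matched is None:
            for pat in MONOGRAPHS:
                if name.startswith(pat, i):
                    matched = pat
                    break
        if matched is None:
            i += 1
        else:
            hits.append((matched, i))
            i += len(matched)

    if lexicon is None:
        return [DigraphHit(pattern=p, start=s) for p, s in hits]

    from .stems import match_stems  # local import: avoid module cycle

    spans = [(m.start, m.end) for m in match_stems(name, lexicon)]
    out = []
    for p, s in hits:
        exempt = any(s >= a and s + len(p) <= b for a, b in spans)
        out.append(DigraphHit(pattern=p, start=s, exempt=exempt))
    return out


@dataclass
class DigraphTable:
    """Per-pattern prohibited-(di)graph accounting over a corpus.

    For each pattern: the number of names containing at least one hit,
    the total number of hit instances, and how many of those instances
    are stem-exempt.  Both the raw grand total and the exempt-excluded
    total are exposed, since a compliance policy may or may not excuse
    stem-borne hits.
    """

    names_containing: dict[str, int]
    total_instances: dict[str, int]
    exempt_instances: dict[str, int]

    @property
    def grand_total(self) -> int:
        return sum(self.total_instances.values())

    @property
    def grand_total_nonexempt(self) -> int:
        return self.grand_total - sum(self.exempt_instances.values())

    @property
    def names_with_any(self) -> int:
        return self._names_with_any

    _names_with_any: int = 0

    def rows(self) -> list[tuple[str, int, int, int]]:
        return [
            (
                p,
                self.names_containing[p],
                self.total_instances[p],
                self.exempt_instances[p],
            )
            for p in PROHIBITED_PATTERNS
        ]


def digraph_table(c: Corpus, lexicon=None) -> DigraphTable:
    """Tabulate prohibited-(di)graph hits over a single-word corpus."""
    names_containing = {p: 0 for p in PROHIBITED_PATTERNS}
    total = {p: 0 for p in PROHIBITED_PATTERNS}
    exempt = {p: 0 for p in PROHIBITED_PATTERNS}
    names_with_any = 0
    for rec in c:
        hits = scan_prohibited(rec.norm_name, lexicon)
        if hits:
            names_with_any += 1
        counts = Counter(h.pattern for h in hits)
        for p, k in counts.items():
            names_containing[p] += 1
            total[p] += k
        for h in hits:
            if h.exempt:
                exempt[h.pattern] += 1
    table = DigraphTable(
        names_containing=names_containing,
        total_instances=total,
        exempt_instances=exempt,
    )
    table._names_with_any = names_with_any
    return table


def digraphs_by_decade(c: Corpus, lexicon=None) -> dict[int, int]:
    """Prohibited-(di)graph instance counts bucketed by publication decade.

    Records without a year are excluded (with a warning); bucket counts
    sum to the corresponding :func:`digraph_table` grand total.
    """
    import logging

    log = logging.getLogger("innlint.orthography")
    out: dict[int, int] = {}
    for rec in c:
        if rec.decade is None:
            log.warning("record %r has no year; excluded from decade table", rec.norm_name)
            continue
        k = len(scan_prohibited(rec.norm_name, lexicon))
        if k:
            out[rec.decade] = out.get(rec.decade, 0) + k
    return dict(sorted(out.items()))


@dataclass(frozen=True)
class IsolatedElementReport:
    """Isolated-element flags for a (raw) multi-word or hyphenated name."""

    has_hyphen: bool = False
    has_isolated_letter: bool = False
    has_isolated_number: bool = False
    has_alphanumeric_word: bool = False

    @property
    def any_flag(self) -> bool:
        return (
            self.has_hyphen
            or self.has_isolated_letter
            or self.has_isolated_number
            or self.has_alphanumeric_word
        )


def isolated_elements(raw_name: str) -> IsolatedElementReport:
    """Inspect a raw name for hyphens, isolated letters/numbers and
    alphanumeric words.

    Tokens are whitespace-delimited; hyphenated tokens are further split
    so that ``lambda-1a`` exposes the alphanumeric sub-token ``1a``.
    Plain single words yield an all-false report.
    """
    stripped = raw_name.strip()
    if all(ch.isalnum() for ch in stripped):
        # plain single word: the checks do not apply
        return IsolatedElementReport()
    tokens: list[str] = []
    for tok in stripped.split():
        tokens.extend(t for t in tok.split("-") if t)
    has_letter = any(len(t) == 1 and t.isalpha() for t in tokens)
    has_number = any(len(t) == 1 and t.isdigit() for t in tokens)
    has_alnum = any(
        any(ch.isalpha() for ch in t) and any(ch.isdigit() for ch in t) for t in tokens
    )
    return IsolatedElementReport(
        has_hyphen="-" in stripped,
        has_isolated_letter=has_letter,
        has_isolated_number=has_number,
        has_alphanumeric_word=has_alnum,
    )


@dataclass
class LengthStats:
    """Character-count statistics for a single-word corpus."""

    n: int
    mean: float
    sd: float
    median: float
    mode: int
    q1: float
    q3: float
    outlier_threshold: int
    outliers: list[tuple[str, int]] = field(default_factory=list)


def length_stats(
    c: Corpus, outlier_threshold: int = 20, *, sample_sd: bool = False
) -> LengthStats:
    """Compute length statistics over ``norm_name`` character counts.

    The SD is the population SD by default (``sample_sd=True`` switches
    to the n-1 denominator).  The mode breaks ties toward the smallest
    length.  Outliers are names strictly longer than
    ``outlier_threshold``, sorted ascending by length then name.
    """
    if len(c) == 0:
        raise ValueError("cannot compute length statistics on an empty corpus")
    lengths = np.array([len(r.norm_name) for r in c])
    counts = Counter(lengths.tolist())
    best = max(counts.values())
    mode = min(k for k, v in counts.items() if v == best)
    q1, q3 = np.percentile(lengths, [25, 75])
    outliers = sorted(
        ((r.norm_name, len(r.norm_name)) for r in c if len(r.norm_name) > outlier_threshold),
        key=lambda t: (t[1], t[0]),
    )
    return LengthStats(
        n=len(c),
        mean=float(lengths.mean()),
        sd=float(lengths.std(ddof=1 if sample_sd else 0)),
        median=float(np.median(lengths)),
        mode=int(mode),
        q1=float(q1),
        q3=float(q3),
        outlier_threshold=outlier_threshold,
        outliers=outliers,
    )


def length_by_decade(c: Corpus) -> dict[int, float]:
    """Mean character count of names bucketed by publication decade."""
    import logging

    log = logging.getLogger("innlint.orthography")
    sums: dict[int, list[int]] = {}
    for rec in c:
        if rec.decade is None:
            log.warning("record %r has no year; excluded from decade table", rec.norm_name)
            continue
        sums.setdefault(rec.decade, []).append(len(rec.norm_name))
    return {d: float(np.mean(v)) for d, v in sorted(sums.items())}
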