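"""Name-corpus ingestion, normalization, partitioning, and subsampling.

A corpus is an ordered collection of generic drug names (e.g. WHO
International Nonproprietary Names), each with its year of publication.
Names are normalized to lowercase and classified as *single-word*
(purely alphanumeric, no internal whitespace) or *multi-word* (anything
containing whitespace or a non-alphanumeric character such as a hyphen).
Single-word names feed the orthographic, stem and similarity analyses;
multi-word names feed the isolated-element checks.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("innlint.corpus")

SINGLE = "single"
MULTI = "multi"


class CorpusFormatError(ValueError):
    """A corpus file does not conform to the configured dialect."""


def classify_word(raw_name: str) -> str:
    """Classify a raw name as ``single`` or ``multi``.

    A name is multi-word iff it contains whitespace or any character
    that is not alphanumeric (digits count as alphanumeric, so a code
    like ``131I`` makes a name multi-word through its separating space,
    not through the digits themselves).
    """
    stripped = raw_name.strip()
    if any(not ch.isalnum() for ch in stripped):
        return MULTI
    return SINGLE


@dataclass(frozen=True)
class INNRecord:
    """One published name.

    ``norm_name`` is ``raw_name`` lowercased with surrounding whitespace
    stripped; ``word_class`` follows :func:`classify_word`.
    """

    raw_name: str
    year: Optional[int]
    norm_name: str = field(default="")
    word_class: str = field(default="")
    list_id: Optional[str] = None

    def __post_init__(self) -> None:
        norm = self.raw_name.strip().lower()
        if not norm:
            raise ValueError("record with empty name")
        object.__setattr__(self, "norm_name", norm)
        object.__setattr__(self, "word_class", classify_word(self.raw_name))

    @property
    def decade(self) -> Optional[int]:
        if self.year is None:
            return None
        return (self.year // 10) * 10


@dataclass
class Corpus:
    """Ordered collection of :class:`INNRecord` with a provenance label."""

    records: list[INNRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[INNRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def names(self) -> list[str]:
        return [r.norm_name for r in self.records]


def _coerce_year(value, row_number: int) -> Optional[int]:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    text = str(value).strip()
    if not text or text.lower() == "nan":
        return None
    try:
        return int(float(text))
    except ValueError:
        raise CorpusFormatError(
            f"row {row_number}: unparseable year {text!r}"
        ) from None


def make_corpus(
    rows: Iterable[tuple],
    provenance: str = "",
    dedup: bool = True,
) -> Corpus:
    """Build a corpus from ``(name, year[, list_id])`` tuples.

    Duplicate normalized names are collapsed, keeping the first
    occurrence (hence the earliest publication when rows are in list
    order); each collapse is logged as a warning.
    """
    records: list[INNRecord] = []
    seen: dict[str, int] = {}
    for row in rows:
        name, year = row[0], row[1]
        list_id = row[2] if len(row) > 2 else None
        rec = INNRecord(raw_name=str(name), year=year, list_id=list_id)
        if dedup and rec.norm_name in seen:
            log.warning("duplicate name %r collapsed (first occurrence kept)", rec.norm_name)
            continue
        seen[rec.norm_name] = len(records)
        records.append(rec)
    return Corpus(records=records, provenance=provenance)


def read_corpus(
    path: str | Path,
    *,
    delimiter: str = ",",
    name_col: str = "name",
    year_col: str = "year",
    list_col: Optional[str] = None,
    header: bool = True,
    dedup: bool = True,
) -> Corpus:
    """Read a delimited-text corpus (default: CSV with ``name,year`` header).

    Empty files yield an empty corpus.  A missing required column is a
    :class:`CorpusFormatError`; an unparseable year is reported with its
    row number.  Input order is preserved.
    """
    path = Path(path)
    try:
        if header:
            frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
        else:
            frame = pd.read_csv(
                path, sep=delimiter, dtype=str, header=None, keep_default_na=False
            )
            frame.columns = [name_col, year_col][: len(frame.columns)]
    except pd.errors.EmptyDataError:
        return Corpus(records=[], provenance=str(path))

    for col in (name_col, year_col):
        if col not in frame.columns:
            raise CorpusFormatError(
                f"{path}: required column {col!r} not found (have {list(frame.columns)})"
            )

    names = frame[name_col].tolist()
    years = frame[year_col].tolist()
    lists = frame[list_col].tolist() if list_col else [None] * len(names)
    rows = []
    first_data_row = 2 if header else 1
    for i, (name, year, list_id) in enumerate(zip(names, years, lists), start=first_data_row):
        name = str(name).strip()
        if not name:
            continue
        rows.append((name, _coerce_year(year, i), list_id))
    return make_corpus(rows, provenance=str(path), dedup=dedup)


def write_corpus(c: Corpus, path: str | Path) -> None:
    """Write ``name,year,word_class`` CSV (UTF-8, header included)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "year", "word_class"])
        for rec in c:
            writer.writerow([rec.raw_name, "" if rec.year is None else rec.year, rec.word_class])


def partition_corpus(c: Corpus) -> tuple[Corpus, Corpus]:
    """Split into (single-word, multi-word) sub-corpora.

    The two halves are disjoint and their sizes sum to ``len(c)``.
    """
    single = [r for r in c if r.word_class == SINGLE]
    multi = [r for r in c if r.word_class == MULTI]
    return (
        Corpus(records=single, provenance=f"{c.provenance}[single]"),
        Corpus(records=multi, provenance=f"{c.provenance}[multi]"),
    )


def sample_fraction(c: Corpus, fraction: float, seed: int) -> Corpus:
    """Uniform random subsample without replacement of ``round(fraction*n)`` records.

    Reproducible: the same ``seed`` yields the same member set.  Records
    are returned in their original corpus order.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(c)
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(n, size=k, replace=False)) if n else []
    return Corpus(
        records=[c.records[i] for i in idx],
        provenance=f"{c.provenance}[sample fraction={fraction} seed={seed}]",
    )
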