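"""Monoclonal-antibody name grammar.

Names in the ``-mab`` class are built, in fixed order, from a random
prefix, a target/disease-class infix, a source-class infix, and the
stem ``mab``:

    tras | tu | zu | mab      (tumour target, humanised source)
    volo | ci | xi | mab      (cardiovascular target, chimeric source)

Target infixes carry an optional trailing vowel (``-tox(a)-``,
``-c(i)-``, ...) which by convention is dropped before a vowel-initial
source infix.  The parser strips ``mab``, then takes the *longest*
source infix ending at the strip point (so ``xizu`` beats ``zu``),
then the longest target infix ending where the source begins (trying
the vowel-bearing form first); whatever precedes the target (at least
one letter) is the prefix.  Failures are returned as values naming the
failed stage, never raised.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

#: Names coined before the grammar was fixed; they do not parse and are
#: reported as pre-convention exceptions rather than grammar failures.
PRE_CONVENTION = frozenset({"muromonab"})


@dataclass(frozen=True)
class TargetInfix:
    base: str
    vowel: str  # optional trailing vowel, "" if none
    meaning: str

    @property
    def forms(self) -> tuple[str, ...]:
        """Spellings, vowel-bearing form first."""
        return (self.base + self.vowel, self.base) if self.vowel else (self.base,)


@dataclass
class InfixTable:
    """Source- and target-infix inventories for the ``-mab`` grammar."""

    source_infixes: dict[str, str]  # spelling -> meaning
    target_infixes: list[TargetInfix]

    def __post_init__(self) -> None:
        spellings = [f for t in self.target_infixes for f in t.forms]
        if len(set(spellings)) != len(spellings):
            raise ValueError("duplicate target-infix spellings")
        if len(set(self.source_infixes)) != len(self.source_infixes):  # pragma: no cover
            raise ValueError("duplicate source-infix spellings")

    def target_for(self, spelling: str) -> Optional[TargetInfix]:
        for t in self.target_infixes:
            if spelling in t.forms:
                return t
        return None


def load_infix_table(path: str | Path) -> InfixTable:
    """Load an infix table from TSV (columns kind, base, vowel, meaning)."""
    sources: dict[str, str] = {}
    targets: list[TargetInfix] = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for raw in reader:
            row = {k: (v or "").strip() for k, v in raw.items() if k}
            if row["kind"] == "source":
                sources[row["base"]] = row["meaning"]
            elif row["kind"] == "target":
                targets.append(TargetInfix(row["base"], row.get("vowel", ""), row["meaning"]))
            else:
                raise ValueError(f"unknown infix kind {row['kind']!r}")
    return InfixTable(source_infixes=sources, target_infixes=targets)


def load_default_infix_table() -> InfixTable:
    from importlib.resources import files

    return load_infix_table(Path(str(files("innlint").joinpath("data/mab_infixes.tsv"))))


@dataclass(frozen=True)
class MabParse:
    """Successful decomposition prefix + target + source + ``mab``."""

    name: str
    prefix: str
    target: str
    source: str
    target_meaning: str
    source_meaning: str
    stem: str = "mab"
    #: alternative (prefix, target, source) segmentations, if any
    alternatives: tuple[tuple[str, str, str], ...] = ()

    @property
    def ambiguous(self) -> bool:
        return bool(self.alternatives)


@dataclass(frozen=True)
class MabFailure:
    """Structured parse failure: which stage of the grammar failed."""

    name: str
    stage: str  # pre-convention | no-mab | no-source | no-target | empty-prefix


MabResult = Union[MabParse, MabFailure]


def _segmentations(rest: str, t: InfixTable) -> list[tuple[str, str, str]]:
    """All (prefix, target, source) splits of ``name[:-3]`` valid under
    the grammar, ignoring longest-match preference."""
    out = []
    for src in t.source_infixes:
        if not rest.endswith(src):
            continue
        mid = rest[: -len(src)]
        for tgt in t.target_infixes:
            for form in tgt.forms:
                if mid.endswith(form) and len(mid) > len(form):
                    out.append((mid[: -len(form)], form, src))
    return out


def parse_mab(name: str, t: Optional[InfixTable] = None) -> MabResult:
    """Parse a normalized single-word name against the ``-mab`` grammar.

    Longest-match at each stage; target vowel-bearing forms are tried
    before bare forms.  Returns :class:`MabParse` on success, otherwise
    a :class:`MabFailure` naming the failed stage.  Alternative valid
    segmentations (the grammar's single-letter infixes make some names
    genuinely ambiguous) are attached to the parse, not adjudicated.
    """
    if t is None:
        t = load_default_infix_table()
    if name in PRE_CONVENTION:
        return MabFailure(name=name, stage="pre-convention")
    if not name.endswith("mab"):
        return MabFailure(name=name, stage="no-mab")
    rest = name[: -len("mab")]

    source = None
    for src in sorted(t.source_infixes, key=len, reverse=True):
        if rest.endswith(src):
            source = src
            break
    if source is None:
        return MabFailure(name=name, stage="no-source")
    mid = rest[: -len(source)]

    target_form = None
    target = None
    candidates = sorted(
        ((form, tgt) for tgt in t.target_infixes for form in tgt.forms),
        key=lambda fw: (-len(fw[0]), fw[0] != fw[1].base + fw[1].vowel, fw[0]),
    )
    for form, tgt in candidates:
        if mid.endswith(form):
            target_form, target = form, tgt
            break
    if target is None:
        return MabFailure(name=name, stage="no-target")
    prefix = mid[: -len(target_form)]
    if not prefix:
        return MabFailure(name=name, stage="empty-prefix")

    chosen = (prefix, target_form, source)
    alternatives = tuple(s for s in _segmentations(rest, t) if s != chosen)
    return MabParse(
        name=name,
        prefix=prefix,
        target=target_form,
        source=source,
        target_meaning=target.meaning,
        source_meaning=t.source_infixes[source],
        alternatives=alternatives,
    )


def assemble_mab(
    prefix: str, target: str, source: str, t: Optional[InfixTable] = None
) -> str:
    """Concatenate prefix + target + source + ``mab``.

    ``target`` and ``source`` must be valid spellings from the table;
    when the chosen spellings are unambiguous under longest-match,
    :func:`parse_mab` recovers the same triple.
    """
    if t is None:
        t = load_default_infix_table()
    if not prefix:
        raise ValueError("prefix must be non-empty")
    if t.target_for(target) is None:
        raise ValueError(f"unknown target infix {target!r}")
    if source not in t.source_infixes:
        raise ValueError(f"unknown source infix {source!r}")
    return f"{prefix}{target}{source}mab"


def conventional_form(target: TargetInfix, source: str) -> str:
    """The target spelling convention actually used in coined names:
    the optional vowel is dropped before a vowel-initial source."""
    if target.vowel and source[0] in "aeiou":
        return target.base
    return target.base + target.vowel
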