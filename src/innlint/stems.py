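"""WHO-style stem taxonomy: lexicon model, linter, and name matcher.

Pharmacological relationships between generic drug names are signalled
by shared *stems*: letter sequences attached as a suffix (``-ast``,
antiasthmatics), prefix (``arte-``, artemisinin antimalarials), infix
(``-pristal-``) or "freefix" (``vir``, antivirals — legal anywhere in
the name).  Stems form shallow taxonomies: a hyperonym stem such as
``-ast`` has hyponym sub-stems such as ``-lukast`` (leukotriene
receptor antagonists).  One stem may have several spellings
(*allomorphy*: ``-profen``/``-profene``), and a few stems change
meaning with their position in the word (``fos`` as a suffix vs as an
infix/prefix).

The lexicon is a table of :class:`StemEntry` keyed by ``stem_id``; the
matcher locates every spelling in a name subject to its affix-class
constraint and additionally reports the implied hyperonyms of every
matched sub-stem (by taxonomy link, not string containment — the
sub-stem ``-viroc`` implies ``vir`` even though "maraviroc" does not
end in ``vir``).
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

AFFIX_CLASSES = ("prefix", "suffix", "infix", "freefix")

_LOWER_ALPHA = re.compile(r"^[a-z]+$")


class LexiconError(ValueError):
    """The lexicon file is structurally invalid (cycles, bad parents...)."""


@dataclass(frozen=True)
class Spelling:
    """One spelling of a stem together with its affix class."""

    text: str
    affix_class: str

    def __post_init__(self) -> None:
        if not _LOWER_ALPHA.match(self.text):
            raise LexiconError(f"spelling must be lowercase alphabetic: {self.text!r}")
        if self.affix_class not in AFFIX_CLASSES:
            raise LexiconError(f"unknown affix class {self.affix_class!r}")


@dataclass
class StemEntry:
    """One stem or sub-stem of the taxonomy.

    ``position_senses`` maps an affix position (``prefix``/``infix``/
    ``suffix``) to an alternate pharmacological definition, for stems
    whose meaning depends on where they appear (e.g. ``fos``).
    """

    stem_id: str
    spellings: list[Spelling]
    parent: Optional[str] = None
    definition: str = ""
    position_senses: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class StemMatch:
    """An occurrence of a stem in a name.

    ``specificity`` is the depth of the stem in its taxon (root = 0).
    ``implied`` marks hyperonyms reported because one of their
    descendants matched, rather than by their own spelling.
    ``ambiguous`` marks matches that overlap a match from a different
    taxon (e.g. ``-dipine`` vs ``-pine`` in riodipine).
    """

    stem_id: str
    spelling: str
    start: int
    end: int
    position: str
    specificity: int
    implied: bool = False
    ambiguous: bool = False


@dataclass(frozen=True)
class ComplianceVerdict:
    """Whether a name carries the stem its pharmacological class expects."""

    name: str
    expected_stem_id: Optional[str]
    verdict: str  # compliant | noncompliant | unlisted
    matches: tuple[StemMatch, ...] = ()
    ambiguous_with: tuple[str, ...] = ()


class StemLexicon:
    """Validated stem taxonomy with linter diagnostics."""

    def __init__(self, entries: Iterable[StemEntry]):
        self.entries: dict[str, StemEntry] = {}
        for e in entries:
            if e.stem_id in self.entries:
                raise LexiconError(f"duplicate stem_id {e.stem_id!r}")
            self.entries[e.stem_id] = e
        self._validate()
        self.warnings: list[str] = self._lint()

    # -- structure ----------------------------------------------------
    def _validate(self) -> None:
        for e in self.entries.values():
            if not e.spellings:
                raise LexiconError(f"stem {e.stem_id!r} has no spellings")
            if e.parent is not None and e.parent not in self.entries:
                raise LexiconError(f"stem {e.stem_id!r} has unknown parent {e.parent!r}")
        for e in self.entries.values():
            seen = {e.stem_id}
            cur = e.parent
            while cur is not None:
                if cur in seen:
                    raise LexiconError(f"cycle in parent links at {cur!r}")
                seen.add(cur)
                cur = self.entries[cur].parent

    def __contains__(self, stem_id: str) -> bool:
        return stem_id in self.entries

    def __getitem__(self, stem_id: str) -> StemEntry:
        return self.entries[stem_id]

    def __len__(self) -> int:
        return len(self.entries)

    def depth(self, stem_id: str) -> int:
        d = 0
        cur = self.entries[stem_id].parent
        while cur is not None:
            d += 1
            cur = self.entries[cur].parent
        return d

    def root(self, stem_id: str) -> str:
        cur = stem_id
        while self.entries[cur].parent is not None:
            cur = self.entries[cur].parent
        return cur

    def ancestors(self, stem_id: str) -> list[str]:
        out = []
        cur = self.entries[stem_id].parent
        while cur is not None:
            out.append(cur)
            cur = self.entries[cur].parent
        return out

    def children(self, stem_id: str) -> list[str]:
        return [e.stem_id for e in self.entries.values() if e.parent == stem_id]

    # -- linter -------------------------------------------------------
    def _lint(self) -> list[str]:
        from .similarity import levenshtein  # deferred: avoid import cycle

        warnings: list[str] = []
        entries = list(self.entries.values())
        # single-letter-distinguished spellings of taxonomically unrelated stems
        for i, a in enumerate(entries):
            a_line = {a.stem_id, *self.ancestors(a.stem_id)}
            for b in entries[i + 1 :]:
                if b.stem_id in a_line or a.stem_id in {b.stem_id, *self.ancestors(b.stem_id)}:
                    continue
                for sa in a.spellings:
                    for sb in b.spellings:
                        if levenshtein(sa.text, sb.text) == 1:
                            warnings.append(
                                "single-letter distinction between unrelated stems "
                                f"{a.stem_id!r} ({sa.text}) and {b.stem_id!r} ({sb.text})"
                            )
        # suffix sub-stems should extend their hyperonym's spelling
        for e in entries:
            if e.parent is None:
                continue
            parent = self.entries[e.parent]
            parent_texts = [s.text for s in parent.spellings]
            for s in e.spellings:
                if s.affix_class == "suffix" and not any(
                    s.text.endswith(p) for p in parent_texts
                ):
                    warnings.append(
                        f"sub-stem {e.stem_id!r} ({s.text}) does not extend its "
                        f"hyperonym {e.parent!r} ({'/'.join(parent_texts)})"
                    )
        return warnings


# ---------------------------------------------------------------------------
# I/O: columnar TSV (primary) and JSON (alternative)
# ---------------------------------------------------------------------------

TSV_COLUMNS = (
    "stem_id",
    "spelling",
    "affix_class",
    "parent",
    "definition",
    "position_sense_key",
    "position_sense_text",
)


def load_lexicon(path: str | Path) -> StemLexicon:
    """Load a lexicon from TSV (``.tsv``) or JSON (``.json``).

    The TSV has one row per (spelling, affix class); rows sharing a
    ``stem_id`` are merged into one entry (allomorphs).  Spellings are
    stored without hyphens.
    """
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        entries = [
            StemEntry(
                stem_id=e["stem_id"],
                spellings=[Spelling(s["text"], s["affix_class"]) for s in e["spellings"]],
                parent=e.get("parent"),
                definition=e.get("definition", ""),
                position_senses=e.get("position_senses", {}),
            )
            for e in payload
        ]
        return StemLexicon(entries)

    merged: dict[str, StemEntry] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        missing = set(TSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise LexiconError(f"{path}: missing columns {sorted(missing)}")
        for raw_row in reader:
            row = {k: (v or "") for k, v in raw_row.items() if k}
            sid = row["stem_id"].strip()
            if not sid:
                continue
            entry = merged.get(sid)
            if entry is None:
                entry = StemEntry(stem_id=sid, spellings=[])
                merged[sid] = entry
                order.append(sid)
            sp_text = row["spelling"].strip().replace("-", "")
            if sp_text:
                sp = Spelling(sp_text, row["affix_class"].strip())
                if sp not in entry.spellings:
                    entry.spellings.append(sp)
            parent = row["parent"].strip()
            if parent:
                if entry.parent is not None and entry.parent != parent:
                    raise LexiconError(f"{sid!r}: conflicting parents {entry.parent!r}/{parent!r}")
                entry.parent = parent
            if row["definition"].strip() and not entry.definition:
                entry.definition = row["definition"].strip()
            key = row["position_sense_key"].strip()
            if key:
                entry.position_senses[key] = row["position_sense_text"].strip()
    return StemLexicon(merged[s] for s in order)


def write_lexicon(lex: StemLexicon, path: str | Path) -> None:
    """Write a lexicon back to TSV; ``load_lexicon`` round-trips it."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(TSV_COLUMNS)
        for e in lex.entries.values():
            senses = list(e.position_senses.items()) or [("", "")]
            rows_needed = max(len(e.spellings), len(senses))
            for i in range(rows_needed):
                sp = e.spellings[i] if i < len(e.spellings) else None
                key, text = senses[i] if i < len(senses) else ("", "")
                writer.writerow(
                    [
                        e.stem_id,
                        sp.text if sp else "",
                        sp.affix_class if sp else "",
                        e.parent or "" if i == 0 else (e.parent or ""),
                        e.definition if i == 0 else "",
                        key,
                        text,
                    ]
                )


def load_default_lexicon() -> StemLexicon:
    """Load the lexicon fixture shipped with the package.

    It encodes the stem taxa and individually named stems discussed in
    the WHO naming-principles literature (the ``-ast``, ``vir`` and
    ``-mab`` taxa plus ~30 further stems); the full WHO Stembook is out
    of scope but loadable through the same format.
    """
    from importlib.resources import files

    return load_lexicon(Path(str(files("innlint").joinpath("data/stems.tsv"))))


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def _position_of(start: int, end: int, n: int, affix_class: str) -> str:
    if end == n and affix_class != "prefix":
        return "suffix"
    if start == 0:
        return "prefix"
    return "infix"


def _legal(start: int, end: int, n: int, affix_class: str) -> bool:
    if affix_class == "suffix":
        return end == n
    if affix_class == "prefix":
        return start == 0
    if affix_class == "infix":
        return start > 0 and end < n
    return True  # freefix


def _occurrences(name: str, sub: str) -> Iterable[int]:
    i = name.find(sub)
    while i != -1:
        yield i
        i = name.find(sub, i + 1)


def match_stems(name: str, lex: StemLexicon) -> list[StemMatch]:
    """Locate every lexicon stem in ``name``, most specific first.

    Direct matches respect the affix-class constraint of each spelling
    (suffix must end the name, prefix must start it, infix must be
    strictly interior, freefix may sit anywhere).  For every direct
    match the full hyperonym chain is also reported; ancestors with no
    direct occurrence of their own are flagged ``implied`` and carry
    the descendant's span.  Matches that overlap a match from a
    different taxon are flagged ``ambiguous``.
    """
    if not _LOWER_ALPHA.match(name):
        raise ValueError(f"expected a lowercase alphabetic name, got {name!r}")
    n = len(name)
    direct: dict[tuple[str, int, int], StemMatch] = {}
    for e in lex.entries.values():
        for sp in e.spellings:
            for i in _occurrences(name, sp.text):
                j = i + len(sp.text)
                if not _legal(i, j, n, sp.affix_class):
                    continue
                key = (e.stem_id, i, j)
                if key not in direct:
                    direct[key] = StemMatch(
                        stem_id=e.stem_id,
                        spelling=sp.text,
                        start=i,
                        end=j,
                        position=_position_of(i, j, n, sp.affix_class),
                        specificity=lex.depth(e.stem_id),
                    )

    matched_ids = {m.stem_id for m in direct.values()}
    implied: list[StemMatch] = []
    implied_ids: set[str] = set()
    for m in sorted(direct.values(), key=lambda m: (-m.specificity, m.start)):
        for anc in lex.ancestors(m.stem_id):
            if anc in matched_ids or anc in implied_ids:
                continue
            implied_ids.add(anc)
            implied.append(
                StemMatch(
                    stem_id=anc,
                    spelling=m.spelling,
                    start=m.start,
                    end=m.end,
                    position=m.position,
                    specificity=lex.depth(anc),
                    implied=True,
                )
            )

    matches = list(direct.values()) + implied

    # flag cross-taxon overlaps
    flagged: list[StemMatch] = []
    for m in matches:
        amb = any(
            lex.root(o.stem_id) != lex.root(m.stem_id)
            and m.start < o.end
            and o.start < m.end
            for o in matches
            if o is not m
        )
        flagged.append(
            StemMatch(**{**m.__dict__, "ambiguous": amb}) if amb != m.ambiguous else m
        )

    flagged.sort(key=lambda m: (-m.specificity, -(m.end - m.start), m.stem_id, m.start))
    return flagged


def preferred_stem_nodes(name: str, lex: StemLexicon) -> tuple[frozenset, frozenset]:
    """Taxonomy nodes a name is taken to carry, under preferred readings.

    Direct matches whose span is strictly contained in a direct match
    from a *different* taxon are shadowed (the terminal ``-tide`` of
    giractide is shadowed by ``-actide``; the ``-pine`` of riodipine by
    ``-dipine``): the longer reading is the name's actual stem and the
    shorter one is the mistaken interpretation.  Returns ``(all_nodes,
    substem_nodes)`` where each kept match contributes itself plus its
    hyperonym chain, and substem nodes are those at depth >= 1.
    """
    direct = [m for m in match_stems(name, lex) if not m.implied]
    kept = [
        m
        for m in direct
        if not any(
            o is not m
            and lex.root(o.stem_id) != lex.root(m.stem_id)
            and o.start <= m.start
            and m.end <= o.end
            and (o.end - o.start) > (m.end - m.start)
            for o in direct
        )
    ]
    ids = {m.stem_id for m in kept}
    for m in kept:
        ids.update(lex.ancestors(m.stem_id))
    return frozenset(ids), frozenset(i for i in ids if lex.depth(i) >= 1)


def resolve_position_sense(m: StemMatch, lex: StemLexicon) -> str:
    """Definition of a matched stem, honouring position-dependent senses."""
    entry = lex[m.stem_id]
    return entry.position_senses.get(m.position, entry.definition)


def classify_compliance(
    name: str, expected_stem_id: Optional[str], lex: StemLexicon
) -> ComplianceVerdict:
    """Check whether ``name`` carries its expected stem.

    ``expected_stem_id=None`` means no expectation is recorded for the
    name (verdict ``unlisted``); an id absent from the lexicon is an
    argument error.  A verdict of ``compliant`` carries an ambiguity
    note when the expected stem's span overlaps stems of other taxa
    (e.g. ``-dipine`` vs ``-pine`` in riodipine).
    """
    matches = tuple(match_stems(name, lex))
    if expected_stem_id is None:
        return ComplianceVerdict(name, None, "unlisted", matches)
    if expected_stem_id not in lex:
        raise ValueError(f"unknown stem_id {expected_stem_id!r}")
    own = [m for m in matches if m.stem_id == expected_stem_id and not m.implied]
    if not own:
        return ComplianceVerdict(name, expected_stem_id, "noncompliant", matches)
    overlapping = tuple(
        sorted(
            {
                m.stem_id
                for m in matches
                for o in own
                if m.stem_id != expected_stem_id
                and lex.root(m.stem_id) != lex.root(expected_stem_id)
                and m.start < o.end
                and o.start < m.end
            }
        )
    )
    return ComplianceVerdict(name, expected_stem_id, "compliant", matches, overlapping)


def compliance_rate(
    sample: Sequence[tuple[str, Optional[str]]], lex: StemLexicon
) -> tuple[float, list[ComplianceVerdict]]:
    """Fraction of a (name, expected stem) sample that is noncompliant
    or unlisted, with the per-name verdicts."""
    if not sample:
        raise ValueError("cannot compute a compliance rate on an empty sample")
    verdicts = [classify_compliance(nm, sid, lex) for nm, sid in sample]
    bad = sum(1 for v in verdicts if v.verdict in ("noncompliant", "unlisted"))
    return bad / len(verdicts), verdicts
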