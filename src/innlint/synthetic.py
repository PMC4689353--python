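"""Synthetic INN-like corpus generator with known ground truth.

The real WHO name database is public but not redistributable in bulk,
so every pipeline stage is exercised against generated corpora whose
properties are known by construction and mirror the empirical structure
of the real nomenclature: unimodal name lengths (mean 10.5, SD 1.7
characters), a configurable prevalence of embedded pharmacological
stems, a configurable rate of names that *should* carry a stem but do
not (noncompliance), optional injection of the prohibited (di)graphs at
per-decade rates, and near-miss name pairs planted at a controlled
number of edits.

Filler text is drawn from an alternating consonant/vowel model over a
20-letter alphabet that excludes ``h``, ``k``, ``y``, ``w``, ``j`` and
``q``, so prohibited patterns appear only where injected (or inside an
embedded stem) and injection-rate recovery is exact.  Every generated
name is validated against the analysis modules (scan and matcher)
before acceptance; accidental stem or (di)graph occurrences trigger a
bounded resample.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Optional, Union

import numpy as np

from .corpus import Corpus, INNRecord
from .orthography import scan_prohibited, PROHIBITED_PATTERNS
from .similarity import levenshtein
from .stems import StemLexicon, load_default_lexicon, match_stems

CONSONANTS = "bcdfglmnprstvxz"
VOWELS = "aeiou"
ALPHABET = sorted(CONSONANTS + VOWELS)

DEFAULT_DECADE_WEIGHTS = {d: 1 / 6 for d in range(1950, 2010, 10)}

_MAX_RETRIES = 100


class GenerationError(RuntimeError):
    """The spec cannot be realized (or retries were exhausted)."""


@dataclass
class SyntheticSpec:
    """Parameters of a generated corpus.

    ``digraph_injection`` maps a prohibited pattern to a per-name
    injection probability, either a single float or a decade -> float
    map.  ``stem_prevalence`` maps lexicon stem ids to the proportion
    of names assigned that stem; ``noncompliance_rate`` is the
    proportion of stem-assigned names generated *without* their stem.
    """

    n_names: int
    length_mean: float = 10.5
    length_sd: float = 1.7
    stem_prevalence: dict[str, float] = field(default_factory=dict)
    noncompliance_rate: float = 0.0
    digraph_injection: dict[str, Union[float, dict[int, float]]] = field(default_factory=dict)
    decade_weights: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_DECADE_WEIGHTS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_names < 0:
            raise ValueError("n_names must be >= 0")
        if sum(self.stem_prevalence.values()) > 1 + 1e-9:
            raise ValueError("stem prevalences must sum to <= 1")
        for v in self.stem_prevalence.values():
            if not 0 <= v <= 1:
                raise ValueError("prevalences must be in [0, 1]")
        if not 0 <= self.noncompliance_rate <= 1:
            raise ValueError("noncompliance_rate must be in [0, 1]")
        for p in self.digraph_injection:
            if p not in PROHIBITED_PATTERNS:
                raise ValueError(f"unknown prohibited pattern {p!r}")


@dataclass
class NameTruth:
    name: str
    year: int
    decade: int
    stem_id: Optional[str]
    spelling: Optional[str]
    compliant: bool
    injected: list[tuple[str, int]]  # (pattern, start)


@dataclass
class PairTruth:
    base: str
    variant: str
    planted_edits: int
    true_led: int


@dataclass
class GroundTruth:
    names: list[NameTruth] = field(default_factory=list)
    pairs: list[PairTruth] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"names": [asdict(n) for n in self.names], "pairs": [asdict(p) for p in self.pairs]},
            indent=1,
        )

    # -- realized parameters, for recovery checks --------------------
    def realized_stem_prevalence(self, stem_id: str) -> float:
        carriers = sum(1 for n in self.names if n.stem_id == stem_id and n.compliant)
        return carriers / len(self.names) if self.names else 0.0

    def realized_noncompliance(self) -> float:
        assigned = [n for n in self.names if n.stem_id is not None]
        if not assigned:
            return 0.0
        return sum(1 for n in assigned if not n.compliant) / len(assigned)


def _filler(rng: np.random.Generator, length: int, start_with_vowel: bool) -> str:
    out = []
    vowel = start_with_vowel
    for _ in range(length):
        pool = VOWELS if vowel else CONSONANTS
        out.append(pool[rng.integers(len(pool))])
        vowel = not vowel
    return "".join(out)


def _resolve_prob(value: Union[float, dict[int, float]], decade: int) -> float:
    if isinstance(value, dict):
        return float(value.get(decade, 0.0))
    return float(value)


def _stem_hit_patterns(spelling: str) -> Counter:
    """Prohibited hits contributed by an embedded stem spelling itself
    (e.g. the k of -kacin), counted pattern-wise."""
    padded = spelling  # spellings are lowercase alphabetic by construction
    return Counter(h.pattern for h in scan_prohibited(padded))


def generate_corpus(
    spec: SyntheticSpec, lexicon: Optional[StemLexicon] = None
) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus realizing ``spec``; fully reproducible under its seed.

    Stem-carrying names embed a spelling of their stem at a position
    legal for its affix class; injected (di)graphs overwrite filler
    outside the stem span.  Each name is validated: its prohibited-hit
    multiset equals the injected hits plus the stem's own letters, the
    assigned stem is matched iff the name is compliant, and no
    prevalence-map stem occurs where it was not assigned.
    """
    if lexicon is None:
        lexicon = load_default_lexicon()
    for sid in spec.stem_prevalence:
        if sid not in lexicon:
            raise GenerationError(f"stem {sid!r} not in lexicon")
        if min(len(s.text) for s in lexicon[sid].spellings) + 2 > 25:
            raise GenerationError(f"stem {sid!r} is too long to embed in a 25-character name")

    rng = np.random.default_rng(spec.seed)
    decades = sorted(spec.decade_weights)
    weights = np.array([spec.decade_weights[d] for d in decades], dtype=float)
    weights = weights / weights.sum() if len(weights) else weights

    stem_ids = sorted(spec.stem_prevalence)
    stem_probs = np.array([spec.stem_prevalence[s] for s in stem_ids], dtype=float)

    monitored = set(stem_ids)
    records: list[INNRecord] = []
    truths: list[NameTruth] = []
    seen: set[str] = set()

    for _ in range(spec.n_names):
        decade = int(decades[rng.choice(len(decades), p=weights)]) if decades else 2000
        year = decade + int(rng.integers(10))

        u = rng.random()
        acc = 0.0
        assigned: Optional[str] = None
        for sid, p in zip(stem_ids, stem_probs):
            acc += p
            if u < acc:
                assigned = sid
                break
        compliant = True
        if assigned is not None and rng.random() < spec.noncompliance_rate:
            compliant = False

        inject = [
            pat
            for pat in PROHIBITED_PATTERNS
            if pat in spec.digraph_injection
            and rng.random() < _resolve_prob(spec.digraph_injection[pat], decade)
        ]

        name = None
        truth = None
        for _attempt in range(_MAX_RETRIES):
            length = int(round(rng.normal(spec.length_mean, spec.length_sd)))
            length = min(max(length, 4), 25)
            built = _attempt_name(rng, length, assigned if compliant else None, lexicon, inject)
            if built is None:
                continue
            cand, spelling, injected_at = built
            if cand in seen:
                continue
            if not _validate(cand, assigned, compliant, spelling, injected_at, lexicon, monitored):
                continue
            name = cand
            truth = NameTruth(
                name=cand,
                year=year,
                decade=decade,
                stem_id=assigned,
                spelling=spelling,
                compliant=compliant if assigned is not None else True,
                injected=injected_at,
            )
            break
        if name is None:
            raise GenerationError(
                f"could not realize a name (stem={assigned!r}, inject={inject}) "
                f"after {_MAX_RETRIES} retries"
            )
        seen.add(name)
        records.append(INNRecord(raw_name=name, year=year))
        truths.append(truth)

    corpus = Corpus(records=records, provenance=f"synthetic(seed={spec.seed}, n={spec.n_names})")
    return corpus, GroundTruth(names=truths)


def _attempt_name(rng, length, stem_id, lexicon, inject):
    """One attempt at composing a name; returns (name, spelling, injected) or None."""
    spelling = None
    stem_span = (0, 0)
    if stem_id is not None:
        entry = lexicon[stem_id]
        sp = entry.spellings[rng.integers(len(entry.spellings))]
        k = len(sp.text)
        need = k + (2 if sp.affix_class == "infix" else 1)
        length = max(length, min(need, 25))
        if need > 25:
            raise GenerationError(f"stem {stem_id!r} spelling {sp.text!r} too long to embed")
        fill = length - k
        if sp.affix_class == "suffix":
            pos = fill
        elif sp.affix_class == "prefix":
            pos = 0
        elif sp.affix_class == "infix":
            pos = int(rng.integers(1, fill))
        else:  # freefix
            pos = int(rng.integers(0, fill + 1))
        left = _filler(rng, pos, start_with_vowel=bool(rng.integers(2)))
        right = _filler(rng, fill - pos, start_with_vowel=bool(rng.integers(2)))
        name = left + sp.text + right
        spelling = sp.text
        stem_span = (pos, pos + k)
    else:
        name = _filler(rng, length, start_with_vowel=bool(rng.integers(2)))

    injected_at: list[tuple[str, int]] = []
    occupied = [stem_span] if stem_id is not None else []
    chars = list(name)
    for pat in inject:
        legal = [
            i
            for i in range(len(chars) - len(pat) + 1)
            if all(i + len(pat) <= a or i >= b for a, b in occupied)
        ]
        if not legal:
            return None
        i = int(legal[rng.integers(len(legal))])
        chars[i : i + len(pat)] = pat
        occupied.append((i, i + len(pat)))
        injected_at.append((pat, i))
    return "".join(chars), spelling, injected_at


def _validate(name, assigned, compliant, spelling, injected_at, lexicon, monitored):
    expected = Counter(p for p, _ in injected_at)
    if compliant and spelling is not None:
        expected += _stem_hit_patterns(spelling)
    if Counter(h.pattern for h in scan_prohibited(name)) != expected:
        return False
    matched = {m.stem_id for m in match_stems(name, lexicon) if not m.implied}
    if assigned is not None and compliant:
        if assigned not in matched:
            return False
        # the assigned stem's own hyperonyms may legitimately co-match
        extraneous = (matched & monitored) - {assigned} - set(lexicon.ancestors(assigned))
    else:
        extraneous = matched & monitored
    return not extraneous


def plant_near_miss_pairs(
    c: Corpus, k_edits: int, n_pairs: int, seed: int
) -> tuple[Corpus, list[PairTruth]]:
    """Append ``n_pairs`` near-miss variants of existing names.

    Each variant applies ``k_edits`` random single-character edits
    (insert/delete/substitute over the generator alphabet) to a
    randomly chosen base name.  Degenerate variants (edits cancel to
    LED 0) and collisions with existing names are resampled; the
    recorded ``true_led`` is recomputed with the similarity module and
    may be smaller than ``k_edits``.
    """
    if k_edits < 1:
        raise ValueError("k_edits must be >= 1")
    if len(c) == 0:
        raise ValueError("cannot plant pairs in an empty corpus")
    rng = np.random.default_rng(seed)
    existing = set(c.names)
    records = list(c.records)
    truths: list[PairTruth] = []
    for _ in range(n_pairs):
        ok = False
        for _attempt in range(_MAX_RETRIES):
            base = records[int(rng.integers(len(c)))]  # base drawn from original corpus
            chars = list(base.norm_name)
            for _e in range(k_edits):
                op = ("insert", "delete", "substitute")[rng.integers(3)]
                if op == "delete" and len(chars) <= 4:
                    op = "substitute"
                if op == "insert":
                    i = int(rng.integers(len(chars) + 1))
                    chars.insert(i, ALPHABET[rng.integers(len(ALPHABET))])
                elif op == "delete":
                    del chars[int(rng.integers(len(chars)))]
                else:
                    i = int(rng.integers(len(chars)))
                    chars[i] = ALPHABET[rng.integers(len(ALPHABET))]
            variant = "".join(chars)
            if variant in existing:
                continue
            true_led = levenshtein(base.norm_name, variant)
            if true_led == 0:  # pragma: no cover - excluded by the collision check
                continue
            existing.add(variant)
            records.append(INNRecord(raw_name=variant, year=base.year))
            truths.append(
                PairTruth(
                    base=base.norm_name,
                    variant=variant,
                    planted_edits=k_edits,
                    true_led=true_led,
                )
            )
            ok = True
            break
        if not ok:
            raise GenerationError(
                f"could not plant a collision-free variant after {_MAX_RETRIES} retries"
            )
    augmented = Corpus(records=records, provenance=f"{c.provenance}+planted(k={k_edits}, n={n_pairs})")
    return augmented, truths
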