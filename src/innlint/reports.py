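"""End-to-end analysis pipeline and structured report bundle.

Runs the five screening questions over a corpus in order — isolated
elements in multi-word names, prohibited (di)graphs, word-length
statistics, stem usage on a random subsample, and the LED similarity
screen with stem-sharing stratification — and writes each report as
TSV with a JSON mirror, plus a run manifest recording the seed and the
record counts at every stage.  Identical config and seed reproduce a
byte-identical bundle (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .corpus import Corpus, partition_corpus, read_corpus, sample_fraction
from .orthography import (
    digraph_table,
    digraphs_by_decade,
    isolated_elements,
    length_by_decade,
    length_stats,
    PROHIBITED_PATTERNS,
)
from .similarity import annotate_shared_stems, screen_pairs, summarize
from .stems import StemLexicon, compliance_rate, load_default_lexicon, load_lexicon, match_stems

log = logging.getLogger("innlint.reports")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    corpus_path: Optional[str] = None
    lexicon_path: Optional[str] = None
    output_dir: str = "innlint-out"
    max_led: int = 4
    outlier_threshold: int = 20
    sample_frac: float = 0.01
    seed: int = 0
    #: optional map norm_name -> expected stem_id for the compliance check
    expected_stems: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _write_tsv(path: Path, header: list[str], rows: list[tuple]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")


def run_full_analysis(
    cfg: RunConfig,
    corpus: Optional[Corpus] = None,
    lexicon: Optional[StemLexicon] = None,
) -> dict:
    """Run the five-question pipeline; returns the report bundle as a dict
    and writes it under ``cfg.output_dir``.

    A stage failure writes a ``FAILED`` marker naming the stage, keeps
    any reports already produced, and raises :class:`StageError`.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    manifest: dict = {"version": __version__, "seed": cfg.seed, "counts": {}, "warnings": []}
    stage = "setup"
    try:
        if corpus is None:
            if cfg.corpus_path is None:
                raise ValueError("no corpus given (set corpus_path or pass a Corpus)")
            corpus = read_corpus(cfg.corpus_path)
        if lexicon is None:
            lexicon = load_lexicon(cfg.lexicon_path) if cfg.lexicon_path else load_default_lexicon()
        manifest["warnings"].extend(lexicon.warnings)

        stage = "partition"
        single, multi = partition_corpus(corpus)
        manifest["counts"].update(
            {"total": len(corpus), "single_word": len(single), "multi_word": len(multi)}
        )

        stage = "q1-isolated-elements"
        q1_rows = []
        for rec in multi:
            rep = isolated_elements(rec.raw_name)
            q1_rows.append(
                (
                    rec.raw_name,
                    rep.has_hyphen,
                    rep.has_isolated_letter,
                    rep.has_isolated_number,
                    rep.has_alphanumeric_word,
                )
            )
        bundle["q1_isolated_elements"] = q1_rows
        _write_tsv(
            outdir / "q1_isolated_elements.tsv",
            ["name", "hyphen", "isolated_letter", "isolated_number", "alphanumeric_word"],
            q1_rows,
        )

        stage = "q2-digraphs"
        table = digraph_table(single, lexicon)
        decades = digraphs_by_decade(single, lexicon)
        bundle["q2_digraph_table"] = table
        bundle["q2_by_decade"] = decades
        _write_tsv(
            outdir / "q2_digraph_table.tsv",
            ["pattern", "names_containing", "total_instances", "exempt_instances"],
            table.rows()
            + [("total", table.names_with_any, table.grand_total, table.grand_total - table.grand_total_nonexempt)],
        )
        _write_tsv(outdir / "q2_by_decade.tsv", ["decade", "instances"], sorted(decades.items()))
        manifest["counts"]["digraph_instances"] = table.grand_total

        stage = "q3-length"
        stats = length_stats(single, cfg.outlier_threshold)
        bundle["q3_length_stats"] = stats
        bundle["q3_by_decade"] = length_by_decade(single)
        _write_json(
            outdir / "q3_length_stats.json",
            {
                "n": stats.n,
                "mean": stats.mean,
                "sd": stats.sd,
                "median": stats.median,
                "mode": stats.mode,
                "q1": stats.q1,
                "q3": stats.q3,
                "outlier_threshold": stats.outlier_threshold,
                "outliers": stats.outliers,
            },
        )
        _write_tsv(
            outdir / "q3_by_decade.tsv",
            ["decade", "mean_length"],
            [(d, f"{m:.2f}") for d, m in bundle["q3_by_decade"].items()],
        )
        manifest["counts"]["length_outliers"] = len(stats.outliers)

        stage = "q4-stems"
        sampled = sample_fraction(single, cfg.sample_frac, cfg.seed)
        manifest["counts"]["q4_sample"] = len(sampled)
        q4_rows = []
        for rec in sampled:
            for m in match_stems(rec.norm_name, lexicon):
                q4_rows.append(
                    (rec.norm_name, m.stem_id, m.spelling, m.start, m.end, m.position,
                     m.specificity, m.implied, m.ambiguous)
                )
        bundle["q4_matches"] = q4_rows
        _write_tsv(
            outdir / "q4_stem_matches.tsv",
            ["name", "stem_id", "spelling", "start", "end", "position", "specificity",
             "implied", "ambiguous"],
            q4_rows,
        )
        pairs_for_rate = [
            (rec.norm_name, cfg.expected_stems.get(rec.norm_name)) for rec in sampled
        ]
        if pairs_for_rate:
            rate, verdicts = compliance_rate(pairs_for_rate, lexicon)
            bundle["q4_noncompliance_rate"] = rate
            _write_json(
                outdir / "q4_compliance.json",
                {
                    "noncompliant_or_unlisted_rate": rate,
                    "verdicts": [
                        {"name": v.name, "expected": v.expected_stem_id, "verdict": v.verdict}
                        for v in verdicts
                    ],
                },
            )

        stage = "q5-similarity"
        screen = screen_pairs(sampled, single, cfg.max_led)
        annotated = annotate_shared_stems(screen.pairs, lexicon)
        summary = summarize(annotated, cfg.max_led)
        bundle["q5_pairs"] = annotated
        bundle["q5_summary"] = summary
        bundle["q5_screen"] = screen
        _write_tsv(
            outdir / "q5_pairs.tsv",
            ["name_a", "name_b", "led", "shares_stem", "shares_substem"],
            [(p.name_a, p.name_b, p.led, p.shares_stem, p.shares_substem) for p in annotated],
        )
        _write_tsv(
            outdir / "q5_summary.tsv",
            ["led", "frequency", "pct_sharing_stem", "pct_sharing_stem_and_substem"],
            [r.render() for r in summary.rows],
        )
        manifest["counts"].update(
            {
                "q5_comparisons": screen.comparisons,
                "q5_comparisons_excluding_self": screen.comparisons_excluding_self,
                "q5_retained": screen.retained,
                "q5_discarded": screen.discarded,
            }
        )
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{stage}\n", encoding="utf-8")
        manifest["failed_stage"] = stage
        _write_json(outdir / "manifest.json", manifest)
        raise StageError(stage, exc) from exc

    _write_json(outdir / "manifest.json", manifest)
    bundle["manifest"] = manifest
    return bundle
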