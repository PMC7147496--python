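"""End-to-end orchestration of the miRNA mining funnel.

Stages run in the published order: homology screen against the
reference matures, redundancy removal, coding-sequence exclusion,
hairpin excision/validation, and (optionally) target prediction
against a transcript set.  Every stage's input/output count is kept in
the run report so the funnel's monotone narrowing can be audited, and
the resolved configuration is embedded in all outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coding import classify_coding
from .hairpin import assess_hit
from .homology import dedupe, find_hits
from .io import (
    ReferenceMiRNA,
    SequenceRecord,
    load_reference_mirnas,
    parse_mirna_family,
    read_fasta,
)
from .targets import scan_transcripts

logger = logging.getLogger("estmir")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage thresholds plus input/output paths."""

    refs_fasta: str = ""
    ests_fasta: str = ""
    transcripts_fasta: str | None = None
    blastx_table: str | None = None
    out_dir: str = "estmir_out"

    max_mismatches: int = 2
    word_size: int = 7
    min_mature_len: int = 19
    mature_len_range: tuple[int, int] = (19, 21)
    mfei_min: float = 0.5
    star_mm_max: int = 5
    min_stem_pairs: int = 15
    expectation_max: float = 3.0
    target_max_mismatches: int = 2
    orf_aa_threshold: int = 80
    flank: int = 100
    precursor_len_range: tuple[int, int] = (60, 300)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "max_mismatches",
            "word_size",
            "min_mature_len",
            "mfei_min",
            "star_mm_max",
            "expectation_max",
            "orf_aa_threshold",
            "flank",
        ):
            if getattr(self, name) <= 0 and name != "max_mismatches":
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("mature_len_range", "precursor_len_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


@dataclass
class RunReport:
    config: dict
    funnel: dict[str, int] = field(default_factory=dict)
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)
    targets: pd.DataFrame = field(default_factory=pd.DataFrame)
    family_summary: dict[str, int] = field(default_factory=dict)
    mature_length_range: tuple[int, int] | None = None
    precursor_length_range: tuple[int, int] | None = None
    delta_g_range_kcal_mol: tuple[float, float] | None = None

    def summary_dict(self) -> dict:
        return {
            "config": self.config,
            "funnel": self.funnel,
            "family_summary": self.family_summary,
            "mature_length_range": self.mature_length_range,
            "precursor_length_range": self.precursor_length_range,
            "delta_g_range_kcal_mol": self.delta_g_range_kcal_mol,
        }


def _candidate_row(cand, report, hit) -> dict:
    return {
        "accession": cand.est_id,
        "mirna_id": cand.mirna_id,
        "family": parse_mirna_family(cand.mirna_id)[1],
        "mature_seq": cand.mature_seq,
        "est_start": hit.est_start,
        "est_end": hit.est_end,
        "strand": hit.strand,
        "precursor_length": cand.precursor_length,
        "gc_percent": cand.gc_percent,
        "mfe": cand.mfe,
        "amfe": cand.amfe,
        "mfei": cand.mfei,
        "arm": cand.arm,
        "duplex_mismatches": cand.duplex_mismatches,
        "passed": report.passed,
        "reasons": ",".join(report.reasons),
    }


def run_pipeline(
    config: PipelineConfig,
    refs: list[ReferenceMiRNA] | None = None,
    ests: list[SequenceRecord] | None = None,
    transcripts: list[SequenceRecord] | None = None,
) -> RunReport:
    """Execute the funnel; inputs may be passed in memory or via paths."""
    try:
        if refs is None:
            refs = load_reference_mirnas(config.refs_fasta)
        if ests is None:
            ests = read_fasta(config.ests_fasta)
        if transcripts is None and config.transcripts_fasta:
            transcripts = read_fasta(config.transcripts_fasta)
    except Exception as exc:
        raise RuntimeError(f"input stage failed: {exc}") from exc

    report = RunReport(config=config.to_dict())
    report.funnel["references"] = len(refs)
    report.funnel["ests"] = len(ests)

    hits = find_hits(
        refs,
        ests,
        max_mismatches=config.max_mismatches,
        word_size=config.word_size,
        min_length=config.min_mature_len,
    )
    report.funnel["homology_hits"] = len(hits)
    logger.info("homology: %d hits", len(hits))

    hits = dedupe(hits)
    report.funnel["after_dedupe"] = len(hits)

    est_by_id = {e.id: e for e in ests}
    hit_ests = [est_by_id[i] for i in sorted({h.est_id for h in hits})]
    verdicts = classify_coding(
        hit_ests,
        orf_aa_threshold=config.orf_aa_threshold,
        external=config.blastx_table,
    )
    noncoding = {v.est_id for v in verdicts if not v.is_coding}
    hits = [h for h in hits if h.est_id in noncoding]
    report.funnel["after_coding_filter"] = len(hits)
    logger.info("coding filter: %d hits on non-coding ESTs", len(hits))

    rows = []
    min_len, max_len = config.precursor_len_range
    for hit in hits:
        assessed = assess_hit(
            est_by_id[hit.est_id],
            hit,
            flank=config.flank,
            min_len=min_len,
            max_len=max_len,
            mfei_min=config.mfei_min,
            star_mm_max=config.star_mm_max,
            mature_len_range=config.mature_len_range,
            min_stem_pairs=config.min_stem_pairs,
        )
        if assessed is None:
            continue
        cand, crit = assessed
        rows.append(_candidate_row(cand, crit, hit))
        if not crit.passed:
            logger.debug("rejected %s @%s: %s", hit.est_id, hit.est_start, crit.reasons)
    report.candidates = pd.DataFrame(rows)
    passed = report.candidates[report.candidates["passed"]] if rows else pd.DataFrame()
    report.funnel["candidates_evaluated"] = len(rows)
    report.funnel["candidates_passed"] = int(len(passed))

    if len(passed):
        report.family_summary = passed["family"].value_counts().to_dict()
        lens = passed["mature_seq"].str.len()
        report.mature_length_range = (int(lens.min()), int(lens.max()))
        report.precursor_length_range = (
            int(passed["precursor_length"].min()),
            int(passed["precursor_length"].max()),
        )
        report.delta_g_range_kcal_mol = (
            -float(passed["mfe"].max()),
            -float(passed["mfe"].min()),
        )

    if transcripts is not None and len(passed):
        mature_refs = [
            ReferenceMiRNA(id=r.mirna_id, seq=r.mature_seq)
            for r in passed.itertuples()
        ]
        # one scan per distinct mature sequence
        unique = {r.seq: r for r in mature_refs}
        calls = scan_transcripts(
            sorted(unique.values(), key=lambda r: r.id),
            transcripts,
            expectation_max=config.expectation_max,
            max_mismatches=config.target_max_mismatches,
        )
        report.targets = pd.DataFrame(
            [
                {
                    "mirna_id": c.alignment.mirna_id,
                    "target_accession": c.alignment.transcript_id,
                    "start": c.alignment.transcript_span[0],
                    "end": c.alignment.transcript_span[1],
                    "expectation": c.alignment.expectation,
                    "inhibition": c.inhibition,
                }
                for c in calls
            ]
        )
        report.funnel["target_calls"] = len(report.targets)

    return report


def write_report(report: RunReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
    if len(report.targets):
        report.targets.to_csv(out / "targets.tsv", sep="\t", index=False)
    (out / "report.json").write_text(json.dumps(report.summary_dict(), indent=1))
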