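"""Protein-coding EST exclusion.

Candidate pre-miRNAs must come from non-coding transcripts.  Two
evidence routes are supported behind one interface: a built-in
six-frame ORF-length heuristic (default), or ingestion of external
protein-homology results in the standard 12-column BLASTX tabular
dialect, which takes precedence when supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .io import SequenceRecord, revcomp

__all__ = ["CodingVerdict", "longest_orf_aa", "classify_coding", "read_blastx_tabular"]

_STOPS = {"TAA", "TAG", "TGA"}

#: columns of the de facto standard BLAST tabular output (-outfmt 6)
BLASTX_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class CodingVerdict:
    est_id: str
    is_coding: bool
    evidence: str  # "orf_heuristic" | "external_blastx"
    detail: str


def longest_orf_aa(seq: str) -> int:
    """Longest ATG-initiated, stop-terminated ORF over all six frames, in aa.

    The count includes the initial Met and excludes the stop codon;
    an open reading without an in-frame stop does not count as an ORF.
    """
    best = 0
    for strand_seq in (seq, revcomp(seq)):
        n = len(strand_seq)
        for frame in range(3):
            start: int | None = None
            for pos in range(frame, n - 2, 3):
                codon = strand_seq[pos : pos + 3]
                if codon in _STOPS:
                    if start is not None:
                        best = max(best, (pos - start) // 3)
                        start = None
                elif codon == "ATG" and start is None:
                    start = pos
    return best


def read_blastx_tabular(path: str | Path) -> dict[str, tuple[str, float]]:
    """Parse BLASTX ``-outfmt 6`` output into {query: (best subject, e-value)}."""
    best: dict[str, tuple[str, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(BLASTX_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected "
                    f"{len(BLASTX_COLUMNS)} tab-separated fields, got {len(fields)}"
                )
            qseqid, sseqid = fields[0], fields[1]
            try:
                evalue = float(fields[10])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: bad e-value {fields[10]!r}"
                ) from exc
            if qseqid not in best or evalue < best[qseqid][1]:
                best[qseqid] = (sseqid, evalue)
    return best


def classify_coding(
    ests: Sequence[SequenceRecord],
    orf_aa_threshold: int = 80,
    external: str | Path | None = None,
    external_evalue_max: float = 1e-3,
) -> list[CodingVerdict]:
    """One verdict per EST; external protein hits override the heuristic."""
    if orf_aa_threshold <= 0:
        raise ValueError("orf_aa_threshold must be positive")
    hits = read_blastx_tabular(external) if external is not None else None
    verdicts = []
    for est in ests:
        if hits is not None:
            found = hits.get(est.id)
            if found is not None:
                sseqid, evalue = found
                verdicts.append(
                    CodingVerdict(
                        est_id=est.id,
                        is_coding=evalue <= external_evalue_max,
                        evidence="external_blastx",
                        detail=f"best hit {sseqid} e-value {evalue:g}",
                    )
                )
                continue
            # queries absent from the table had no protein hit
            verdicts.append(
                CodingVerdict(
                    est_id=est.id,
                    is_coding=False,
                    evidence="external_blastx",
                    detail="no hit in external table",
                )
            )
            continue
        aa = longest_orf_aa(est.seq)
        verdicts.append(
            CodingVerdict(
                est_id=est.id,
                is_coding=aa >= orf_aa_threshold,
                evidence="orf_heuristic",
                detail=f"longest ORF {aa} aa",
            )
        )
    return verdicts
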