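"""Mismatch-bounded homology search of mature miRNAs against ESTs.

The screen emulates a short-word BLASTN pass: a candidate locus must
share at least one exact word of ``word_size`` with the mature, and the
mature must then match the EST end-to-end (both strands considered)
with at most ``max_mismatches`` substitutions.  Gaps are not modeled —
the operative published filter is the mismatch bound, and observed
mature/precursor length parity indicates ungapped matches.  Because two
mismatches can break every 7-mer of a 19–22 nt mature (pigeonhole:
longest clean run can be as short as ceil((L-2)/3)), seeding is only a
prefilter when the mature is at least ``3*word_size + 2`` long;
otherwise the scan is exhaustive, so no valid hit is ever lost.

Matches of N against anything count as mismatches (conservative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import ReferenceMiRNA, SequenceRecord, revcomp

__all__ = ["HomologyHit", "find_hits", "dedupe", "brute_force_hits"]


@dataclass(frozen=True)
class HomologyHit:
    """A full-length mature-vs-EST match on the forward EST coordinates."""

    est_id: str
    mirna: ReferenceMiRNA
    est_start: int  # 0-based inclusive
    est_end: int  # 0-based exclusive
    strand: str  # "+" or "-"
    mismatches: int

    @property
    def matched_length(self) -> int:
        return self.est_end - self.est_start

    def sort_key(self) -> tuple:
        return (self.est_id, self.est_start, self.strand, self.mirna.id)


def _encode(seq: str) -> np.ndarray:
    # N maps to a code that matches nothing, so N always mismatches
    table = np.full(256, 4, dtype=np.int8)
    for i, base in enumerate("ACGT"):
        table[ord(base)] = i
    out = table[np.frombuffer(seq.encode(), dtype=np.uint8)]
    out[out == 4] = -1
    return out


def _mismatch_profile(est: np.ndarray, mat: np.ndarray) -> np.ndarray:
    """Mismatch count of ``mat`` at every offset of ``est`` (vectorized)."""
    L = len(mat)
    if len(est) < L:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(est, L)
    eq = (windows == mat) & (mat >= 0)[None, :] & (windows >= 0)
    return L - eq.sum(axis=1)


def _word_set(seq: str, w: int) -> set[str]:
    return {seq[i : i + w] for i in range(len(seq) - w + 1)}


def find_hits(
    refs: Sequence[ReferenceMiRNA],
    ests: Sequence[SequenceRecord],
    max_mismatches: int = 2,
    word_size: int = 7,
    min_length: int = 19,
) -> list[HomologyHit]:
    """Scan every EST (both strands) for end-to-end mature matches.

    Matures shorter than ``min_length`` are excluded up front.  Hits on
    the minus strand report coordinates on the forward EST.  Output
    order is (est_id, est_start, strand, mirna.id).
    """
    if not refs:
        raise ValueError("empty reference miRNA set")
    if word_size < 4:
        raise ValueError("word_size must be >= 4")
    kept = [r for r in refs if len(r) >= min_length]
    hits: list[HomologyHit] = []
    enc_mats = {r.id: _encode(r.seq) for r in kept}
    for est in ests:
        n = len(est)
        fwd = _encode(est.seq)
        rev = _encode(revcomp(est.seq))
        est_words: set[str] | None = None
        for ref in kept:
            L = len(ref)
            if L > n:
                continue
            # seed prefilter is lossless only when a clean word must survive
            if L >= 3 * word_size + 2:
                if est_words is None:
                    both = est.seq + "~" + revcomp(est.seq)
                    est_words = _word_set(both, word_size)
                if not (_word_set(ref.seq, word_size) & est_words):
                    continue
            mat = enc_mats[ref.id]
            for strand, enc in (("+", fwd), ("-", rev)):
                profile = _mismatch_profile(enc, mat)
                for off in np.flatnonzero(profile <= max_mismatches):
                    off = int(off)
                    if strand == "+":
                        start, end = off, off + L
                    else:
                        start, end = n - off - L, n - off
                    hits.append(
                        HomologyHit(
                            est_id=est.id,
                            mirna=ref,
                            est_start=start,
                            est_end=end,
                            strand=strand,
                            mismatches=int(profile[off]),
                        )
                    )
    hits.sort(key=HomologyHit.sort_key)
    return hits


def brute_force_hits(
    refs: Sequence[ReferenceMiRNA],
    ests: Sequence[SequenceRecord],
    max_mismatches: int = 2,
    min_length: int = 19,
) -> list[HomologyHit]:
    """Independent sliding-window oracle: per-offset character counting."""
    if not refs:
        raise ValueError("empty reference miRNA set")
    hits = []
    for est in ests:
        n = len(est)
        for ref in refs:
            L = len(ref)
            if L < min_length or L > n:
                continue
            for strand in "+-":
                target = est.seq if strand == "+" else revcomp(est.seq)
                for off in range(n - L + 1):
                    mm = 0
                    for a, b in zip(ref.seq, target[off : off + L]):
                        if a != b or a == "N" or b == "N":
                            mm += 1
                            if mm > max_mismatches:
                                break
                    if mm <= max_mismatches:
                        start = off if strand == "+" else n - off - L
                        hits.append(
                            HomologyHit(est.id, ref, start, start + L, strand, mm)
                        )
    hits.sort(key=HomologyHit.sort_key)
    return hits


def dedupe(hits: Iterable[HomologyHit]) -> list[HomologyHit]:
    """Collapse hits sharing (est_id, est_start, strand, mature sequence).

    Among duplicates the fewest-mismatch hit wins; ties go to the
    lexicographically smallest miRNA id, so reference sets listing the
    same mature under several names yield one locus record.
    """
    best: dict[tuple, HomologyHit] = {}
    for hit in hits:
        key = (hit.est_id, hit.est_start, hit.strand, hit.mirna.seq)
        cur = best.get(key)
        if cur is None or (hit.mismatches, hit.mirna.id) < (
            cur.mismatches,
            cur.mirna.id,
        ):
            best[key] = hit
    out = list(best.values())
    out.sort(key=HomologyHit.sort_key)
    return out
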