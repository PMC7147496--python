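"""miRNA target prediction by complementarity expectation scoring.

The scorer follows the plant-target-server convention: the miRNA
(5'->3') is aligned against the reverse-complement sense of a
transcript window and accumulates penalties — 1 per mismatch, 0.5 per
G:U wobble, 2 per gap — doubled inside the seed region (miRNA
positions 2-13).  Sites at or below the expectation cutoff (3 in this
pipeline) are reported; a pairing defect at the central positions 10
or 11 marks the site as translational repression, otherwise cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .io import ReferenceMiRNA, SequenceRecord, revcomp

__all__ = [
    "DuplexAlignment",
    "TargetCall",
    "score_duplex",
    "classify_inhibition",
    "scan_transcripts",
    "PENALTY_MISMATCH",
    "PENALTY_WOBBLE",
    "PENALTY_GAP",
    "SEED_RANGE",
]

PENALTY_MISMATCH = 1.0
PENALTY_WOBBLE = 0.5
PENALTY_GAP = 2.0
#: miRNA positions (1-based, 5' end = 1) where penalties double
SEED_RANGE = (2, 13)
SEED_MULTIPLIER = 2.0

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _codes(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int8)


def _sub_state(m: str, r: str) -> str:
    """State of miRNA base vs reverse-complemented target base."""
    if m == r and m != "N":
        return "match"
    if (m == "G" and r == "A") or (m == "T" and r == "C"):
        return "wobble"
    return "mismatch"


def _seed_factor(pos: int) -> float:
    lo, hi = SEED_RANGE
    return SEED_MULTIPLIER if lo <= pos <= hi else 1.0


@dataclass(frozen=True)
class DuplexAlignment:
    """A scored miRNA/target duplex.

    ``pairs`` lists per-column states from the miRNA 5' end over
    {match, mismatch, wobble, gap_mirna, gap_target}; ``gap_mirna``
    columns carry a bulged target base and no miRNA position.
    """

    mirna_id: str
    transcript_id: str
    transcript_span: tuple[int, int]
    pairs: tuple[str, ...]
    expectation: float

    @property
    def n_gaps(self) -> int:
        return sum(1 for s in self.pairs if s.startswith("gap"))

    @property
    def n_mismatch_states(self) -> int:
        return sum(1 for s in self.pairs if s == "mismatch")

    @property
    def n_wobbles(self) -> int:
        return sum(1 for s in self.pairs if s == "wobble")

    def state_at_position(self, pos: int) -> str:
        """State at a 1-based miRNA position; bulged target bases are
        attributed to the following miRNA position."""
        consumed = 0
        for s in self.pairs:
            if s == "gap_mirna":
                if consumed + 1 == pos:
                    return s
            else:
                consumed += 1
                if consumed == pos:
                    return s
        raise IndexError(f"miRNA position {pos} beyond alignment")


@dataclass(frozen=True)
class TargetCall:
    alignment: DuplexAlignment
    inhibition: str  # "Cleavage" | "Translation"


def _align(mir: str, rc_window: str) -> tuple[float, tuple[str, ...]]:
    """Global minimum-penalty alignment with traceback (pure Python)."""
    L, W = len(mir), len(rc_window)
    INF = float("inf")
    D = [[INF] * (W + 1) for _ in range(L + 1)]
    D[0][0] = 0.0
    for j in range(1, W + 1):
        D[0][j] = j * PENALTY_GAP  # bulges before the miRNA 5' end: no seed
    for i in range(1, L + 1):
        D[i][0] = D[i - 1][0] + PENALTY_GAP * _seed_factor(i)
        for j in range(1, W + 1):
            state = _sub_state(mir[i - 1], rc_window[j - 1])
            sub_pen = {"match": 0.0, "wobble": PENALTY_WOBBLE, "mismatch": PENALTY_MISMATCH}[
                state
            ] * _seed_factor(i)
            gap_t = PENALTY_GAP * _seed_factor(i)  # miRNA base i unopposed
            gap_m = PENALTY_GAP * _seed_factor(i)  # bulged target before base i...
            D[i][j] = min(
                D[i - 1][j - 1] + sub_pen,
                D[i - 1][j] + gap_t,
                D[i][j - 1] + gap_m,
            )
    # traceback, preferring substitution columns (fewest gaps)
    states: list[str] = []
    i, j = L, W
    eps = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            state = _sub_state(mir[i - 1], rc_window[j - 1])
            sub_pen = {"match": 0.0, "wobble": PENALTY_WOBBLE, "mismatch": PENALTY_MISMATCH}[
                state
            ] * _seed_factor(i)
            if abs(D[i][j] - (D[i - 1][j - 1] + sub_pen)) < eps:
                states.append(state)
                i, j = i - 1, j - 1
                continue
        if i > 0 and abs(D[i][j] - (D[i - 1][j] + PENALTY_GAP * _seed_factor(i))) < eps:
            states.append("gap_target")
            i -= 1
            continue
        states.append("gap_mirna")
        j -= 1
    return D[L][W], tuple(reversed(states))


def score_duplex(
    mirna: ReferenceMiRNA, window: str, transcript_id: str = "", span: tuple[int, int] = (0, 0)
) -> DuplexAlignment:
    """Score the miRNA against one transcript window (target sense)."""
    L = len(mirna)
    if not (L - 2 <= len(window) <= L + 5):
        raise ValueError(
            f"window length {len(window)} outside [{L - 2}, {L + 5}] for {mirna.id}"
        )
    expectation, states = _align(mirna.seq, revcomp(window))
    if span == (0, 0):
        span = (0, len(window))
    return DuplexAlignment(
        mirna_id=mirna.id,
        transcript_id=transcript_id,
        transcript_span=span,
        pairs=states,
        expectation=expectation,
    )


def classify_inhibition(
    alignment: DuplexAlignment, central_positions: tuple[int, int] = (10, 11)
) -> str:
    """Translation iff positions 10/11 carry any non-match state."""
    for pos in central_positions:
        if alignment.state_at_position(pos) != "match":
            return "Translation"
    return "Cleavage"


@njit(cache=False)
def _scan_kernel(mir, rct, w_min, w_max, pen_mm, pen_wob, pen_gap, seed_lo, seed_hi, mult):
    # pragma: no cover - numba
    L = mir.shape[0]
    n = rct.shape[0]
    n_w = w_max - w_min + 1
    out = np.full((n, n_w), 1e30)
    D = np.empty((L + 1, w_max + 1))
    for p in range(n):
        for wi in range(n_w):
            w = w_min + wi
            if p + w > n:
                continue
            D[0, 0] = 0.0
            for j in range(1, w + 1):
                D[0, j] = j * pen_gap
            for i in range(1, L + 1):
                f = mult if seed_lo <= i <= seed_hi else 1.0
                D[i, 0] = D[i - 1, 0] + pen_gap * f
                m = mir[i - 1]
                for j in range(1, w + 1):
                    r = rct[p + j - 1]
                    if m == r and m != 4:
                        sub = 0.0
                    elif (m == 2 and r == 0) or (m == 3 and r == 1):
                        sub = pen_wob * f
                    else:
                        sub = pen_mm * f
                    v = D[i - 1, j - 1] + sub
                    v2 = D[i - 1, j] + pen_gap * f
                    if v2 < v:
                        v = v2
                    v3 = D[i, j - 1] + pen_gap * f
                    if v3 < v:
                        v = v3
                    D[i, j] = v
            out[p, wi] = D[L, w]
    return out


def scan_transcripts(
    mirnas: Sequence[ReferenceMiRNA],
    transcripts: Sequence[SequenceRecord],
    expectation_max: float = 3.0,
    max_mismatches: int = 2,
    count_wobble_as_mismatch: bool = False,
) -> list[TargetCall]:
    """Exhaustively score every window of every transcript.

    Window widths range over [L-2, L+5].  Overlapping qualifying spans
    of one miRNA on one transcript are reduced to the best one
    (lowest expectation, then fewest gaps, then leftmost).  Calls are
    sorted by (mirna_id, expectation, transcript_id).
    """
    calls: list[TargetCall] = []
    for tx in transcripts:
        n = len(tx)
        rct = _codes(revcomp(tx.seq))
        for mir in mirnas:
            L = len(mir)
            w_min, w_max = max(1, L - 2), L + 5
            if w_min > n:
                continue
            w_max = min(w_max, n)
            if w_max < w_min:
                continue
            scores = _scan_kernel(
                _codes(mir.seq),
                rct,
                w_min,
                w_max,
                PENALTY_MISMATCH,
                PENALTY_WOBBLE,
                PENALTY_GAP,
                SEED_RANGE[0],
                SEED_RANGE[1],
                SEED_MULTIPLIER,
            )
            candidates = []
            for p, wi in zip(*np.nonzero(scores <= expectation_max + 1e-9)):
                w = w_min + int(wi)
                p = int(p)
                span = (n - p - w, n - p)  # map rc offset to forward coords
                window = tx.seq[span[0] : span[1]]
                aln = score_duplex(mir, window, transcript_id=tx.id, span=span)
                n_mm = aln.n_mismatch_states
                if count_wobble_as_mismatch:
                    n_mm += aln.n_wobbles
                if aln.expectation <= expectation_max + 1e-9 and n_mm <= max_mismatches:
                    candidates.append(aln)
            candidates.sort(
                key=lambda a: (a.expectation, a.n_gaps, a.transcript_span)
            )
            kept: list[DuplexAlignment] = []
            for aln in candidates:
                lo, hi = aln.transcript_span
                if all(hi <= k_lo or lo >= k_hi for k_lo, k_hi in (k.transcript_span for k in kept)):
                    kept.append(aln)
            for aln in kept:
                calls.append(TargetCall(alignment=aln, inhibition=classify_inhibition(aln)))
    calls.sort(
        key=lambda c: (c.alignment.mirna_id, c.alignment.expectation, c.alignment.transcript_id, c.alignment.transcript_span)
    )
    return calls
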