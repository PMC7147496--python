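"""Bundled stacking-aware RNA secondary-structure folder.

A dynamic program over pseudoknot-free structures that minimizes a
simple nearest-neighbour-flavoured energy proxy: each base pair
contributes a pair energy (Watson-Crick G:C strongest, A:U, then the
weak G:U wobble) and every directly stacked pair (i, j) on
(i+1, j-1) earns an additional stacking bonus.  Hairpin loops must
contain at least three unpaired bases.  The proxy is deliberately much
simpler than full Turner-parameter folding: it is exact for its own
scoring model (verifiable by exhaustive enumeration on short
sequences) and adequate for ranking stem-loops by stability, while
externally computed structures can be supplied through
:func:`estmir.io.read_structure` when published energies must be
reproduced bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .io import StructureRecord, normalize_seq

__all__ = ["fold", "PAIR_ENERGY", "STACK_BONUS", "MIN_HAIRPIN_LOOP"]

#: energy proxy per closed pair, kcal/mol
PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "T"): -2.0,
    ("T", "A"): -2.0,
    ("G", "T"): -0.3,
    ("T", "G"): -0.3,
}
#: extra stabilization when (i, j) sits directly on (i+1, j-1)
STACK_BONUS = -0.5
#: minimum unpaired bases closed by a hairpin pair
MIN_HAIRPIN_LOOP = 3

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

_PAIR_MATRIX = np.zeros((5, 5), dtype=np.float64)
for (a, b), e in PAIR_ENERGY.items():
    _PAIR_MATRIX[_CODE[a], _CODE[b]] = e

_EPS = 1e-9


@njit(cache=False)
def _fill(codes, pair_e, stack, min_loop):  # pragma: no cover - numba
    n = codes.shape[0]
    big = 1e30
    best = np.zeros((n, n))
    paired = np.full((n, n), big)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            e = pair_e[codes[i], codes[j]]
            if e < 0.0:
                inner = 0.0
                if j - i - 2 > min_loop:
                    inner = best[i + 1, j - 1]
                    v = paired[i + 1, j - 1] + stack
                    if v < inner:
                        inner = v
                paired[i, j] = e + inner
            b = best[i, j - 1]
            for k in range(i, j - min_loop):
                if paired[k, j] < big:
                    left = best[i, k - 1] if k > i else 0.0
                    v = left + paired[k, j]
                    if v < b:
                        b = v
            best[i, j] = b
    return best, paired


def _traceback(codes, best, paired, min_loop):
    n = len(codes)
    struct = ["."] * n
    stack: list[tuple[int, int, bool]] = [(0, n - 1, False)]
    while stack:
        i, j, is_pair = stack.pop()
        if is_pair:
            struct[i], struct[j] = "(", ")"
            if j - i - 2 > min_loop:
                e = _PAIR_MATRIX[codes[i], codes[j]]
                target = paired[i, j] - e
                if paired[i + 1, j - 1] + STACK_BONUS <= target + _EPS:
                    stack.append((i + 1, j - 1, True))
                else:
                    stack.append((i + 1, j - 1, False))
            continue
        if j - i <= min_loop:
            continue
        # prefer closing a pair on j (more pairs at equal score)
        placed = False
        for k in range(i, j - min_loop):
            if paired[k, j] >= 1e29:
                continue
            left = best[i, k - 1] if k > i else 0.0
            if left + paired[k, j] <= best[i, j] + _EPS:
                if k > i:
                    stack.append((i, k - 1, False))
                stack.append((k, j, True))
                placed = True
                break
        if not placed:
            stack.append((i, j - 1, False))
    return "".join(struct)


def fold(seq: str) -> StructureRecord:
    """Fold a sequence with the bundled energy model.

    Returns a :class:`StructureRecord` whose ``energy_kcal_mol`` is the
    minimum proxy energy (<= 0; 0 for a structure with no pairs).
    """
    s = normalize_seq(seq)
    if not 10 <= len(s) <= 1000:
        raise ValueError(f"fold expects 10..1000 nt, got {len(s)}")
    codes = np.array([_CODE[c] for c in s], dtype=np.int8)
    best, paired = _fill(codes, _PAIR_MATRIX, STACK_BONUS, MIN_HAIRPIN_LOOP)
    energy = float(best[0, len(s) - 1])
    dotbracket = _traceback(codes, best, paired, MIN_HAIRPIN_LOOP)
    # energy is exact for the scoring model; guard against drift
    return StructureRecord(
        seq=s,
        dotbracket=dotbracket,
        energy_kcal_mol=round(energy, 6),
        source="bundled_fold",
    )
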