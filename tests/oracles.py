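"""Independent reference implementations used only to cross-check the
package: exhaustive enumeration and naive scans, written without
reusing the production code paths."""

from __future__ import annotations

from functools import lru_cache

from estmir.fold import MIN_HAIRPIN_LOOP, PAIR_ENERGY, STACK_BONUS
from estmir.io import revcomp
from estmir.targets import (
    PENALTY_GAP,
    PENALTY_MISMATCH,
    PENALTY_WOBBLE,
    SEED_MULTIPLIER,
    SEED_RANGE,
)

_STOPS = {"TAA", "TAG", "TGA"}


# --- folding: enumerate every pseudoknot-free structure -------------------

def _pairable(a: str, b: str) -> bool:
    return (a, b) in PAIR_ENERGY


def enumerate_min_energy(seq: str) -> float:
    """Minimum score over all valid structures by explicit enumeration.

    Structures are generated recursively as nested pair sets; scoring
    adds the pair energies plus a stacking bonus whenever (i, j) and
    (i+1, j-1) are both present.
    """

    def structures(i: int, j: int) -> list[frozenset]:
        # all pair sets over seq[i..j] inclusive
        if j - i < MIN_HAIRPIN_LOOP + 1:
            return [frozenset()]
        out = list(structures(i, j - 1))  # j unpaired
        for k in range(i, j - MIN_HAIRPIN_LOOP):
            if _pairable(seq[k], seq[j]):
                lefts = structures(i, k - 1) if k > i else [frozenset()]
                inners = structures(k + 1, j - 1)
                for left in lefts:
                    for inner in inners:
                        out.append(left | inner | {(k, j)})
        return out

    def score(pairs: frozenset) -> float:
        total = sum(PAIR_ENERGY[(seq[i], seq[j])] for i, j in pairs)
        total += STACK_BONUS * sum(1 for i, j in pairs if (i + 1, j - 1) in pairs)
        return total

    return min(score(p) for p in structures(0, len(seq) - 1))


# --- coding: naive six-frame ORF scan -------------------------------------

def naive_longest_orf_aa(seq: str) -> int:
    best = 0
    for s in (seq, revcomp(seq)):
        for frame in range(3):
            codons = [s[k : k + 3] for k in range(frame, len(s) - 2, 3)]
            for a, start in enumerate(codons):
                if start != "ATG":
                    continue
                for b in range(a + 1, len(codons)):
                    if codons[b] in _STOPS:
                        best = max(best, b - a)
                        break
    return best


# --- target scoring: per-window DP, memoized recursion --------------------

def _state(m: str, r: str) -> str:
    if m == r and m != "N":
        return "match"
    if (m == "G" and r == "A") or (m == "T" and r == "C"):
        return "wobble"
    return "mismatch"


def _factor(pos: int) -> float:
    return SEED_MULTIPLIER if SEED_RANGE[0] <= pos <= SEED_RANGE[1] else 1.0


def naive_duplex_expectation(mirna_seq: str, window: str) -> float:
    """Minimum penalty of a global miRNA-vs-revcomp(window) alignment."""
    rc = revcomp(window)
    L, W = len(mirna_seq), len(rc)

    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> float:
        if i == 0:
            return j * PENALTY_GAP
        if j == 0:
            return go(i - 1, 0) + PENALTY_GAP * _factor(i)
        sub = {"match": 0.0, "wobble": PENALTY_WOBBLE, "mismatch": PENALTY_MISMATCH}[
            _state(mirna_seq[i - 1], rc[j - 1])
        ] * _factor(i)
        return min(
            go(i - 1, j - 1) + sub,
            go(i - 1, j) + PENALTY_GAP * _factor(i),
            go(i, j - 1) + PENALTY_GAP * _factor(i),
        )

    result = go(L, W)
    go.cache_clear()
    return result


def naive_scan(mirna, transcript, expectation_max=3.0):
    """All (span, expectation) site candidates of one miRNA on one
    transcript, before mismatch filtering and overlap suppression."""
    L, n = len(mirna.seq), len(transcript.seq)
    found = []
    for w in range(max(1, L - 2), min(L + 5, n) + 1):
        for start in range(n - w + 1):
            exp = naive_duplex_expectation(mirna.seq, transcript.seq[start : start + w])
            if exp <= expectation_max + 1e-9:
                found.append(((start, start + w), exp))
    return found
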