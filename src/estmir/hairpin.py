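"""Precursor excision, hairpin validation and stability metrics.

A candidate pre-miRNA is a window of an EST around a homology hit.
Windows are folded and screened with the four classical plant miRNA
homolog criteria:

1. the window folds into a proper stem-loop (a single terminal loop
   closed by a helix carrying enough cumulative base pairs),
2. the mature sits on one arm of that hairpin,
3. the mature/star duplex has at most five mismatches,
4. the minimal folding free energy index (MFEI) is at least 0.5.

Reported metrics follow the EST-mining literature: MFE is the positive
magnitude of the folding ΔG, AMFE normalizes it per 100 nt of
precursor, and MFEI = AMFE / GC%.  All three are reported truncated
(not rounded) to two decimals, which is the convention the published
tables follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .fold import fold
from .homology import HomologyHit
from .io import SequenceRecord, StructureRecord, revcomp

__all__ = [
    "truncate2",
    "gc_percent",
    "amfe",
    "mfei",
    "PrecursorWindow",
    "excise_precursor",
    "locate_arm",
    "derive_star_and_mismatches",
    "HairpinCandidate",
    "CriteriaReport",
    "make_candidate",
    "evaluate_candidate",
    "assess_hit",
    "FAILURE_REASONS",
]

FAILURE_REASONS = (
    "no_stem_loop",
    "mature_spans_loop",
    "star_mismatches_gt5",
    "mfei_lt_threshold",
    "length_out_of_range",
)


def truncate2(x: float) -> float:
    """Truncate toward zero to two decimals (42.55*100/107 -> 39.76)."""
    return math.floor(x * 100 + 1e-9) / 100


def gc_percent(seq: str) -> float:
    """(G+C) percentage of a sequence, truncated to two decimals.

    N bases count in the denominator but never in the numerator.
    """
    if not seq:
        raise ValueError("gc_percent of empty sequence")
    gc = seq.count("G") + seq.count("C")
    return truncate2(100.0 * gc / len(seq))


def amfe(mfe: float, precursor_length: int) -> float:
    """Adjusted MFE: MFE * 100 / precursor length, truncated to 2 dp."""
    if precursor_length <= 0:
        raise ValueError("precursor length must be positive")
    if mfe < 0:
        raise ValueError("MFE is a positive magnitude (-dG)")
    return truncate2(mfe * 100.0 / precursor_length)


def mfei(amfe_value: float, gc: float) -> float:
    """Minimal folding free energy index: AMFE / GC%, truncated to 2 dp."""
    if gc <= 0:
        raise ValueError("undefined MFEI: GC percent must be positive")
    return truncate2(amfe_value / gc)


@dataclass(frozen=True)
class PrecursorWindow:
    """An excised precursor candidate, mature given 5'->3' in the window."""

    seq: str
    mature_span: tuple[int, int]
    est_interval: tuple[int, int]  # on the strand the window was cut from
    strand: str

    def __len__(self) -> int:
        return len(self.seq)


def excise_precursor(
    est: SequenceRecord,
    hit: HomologyHit,
    flank: int = 100,
    min_len: int = 60,
    max_len: int = 300,
) -> list[PrecursorWindow]:
    """Windows around a hit: a total flank budget split asymmetrically.

    Budgets of 2*flank, flank and flank/2 extra nucleotides are each
    distributed between the two sides in quarter steps, clipped to the
    EST; duplicates and windows outside [min_len, max_len] are dropped.
    Minus-strand hits are excised from the reverse complement so the
    mature reads 5'->3' in every window.
    """
    n = len(est)
    if not (0 <= hit.est_start < hit.est_end <= n):
        raise ValueError(
            f"hit {hit.est_start}..{hit.est_end} outside EST {est.id} (len {n})"
        )
    if hit.strand == "+":
        seq = est.seq
        start, end = hit.est_start, hit.est_end
    else:
        seq = revcomp(est.seq)
        start, end = n - hit.est_end, n - hit.est_start

    seen: set[tuple[int, int]] = set()
    windows: list[PrecursorWindow] = []
    for budget in (2 * flank, flank, flank // 2):
        for num in range(5):
            left = budget * num // 4
            right = budget - left
            lo = max(0, start - left)
            hi = min(n, end + right)
            if not min_len <= hi - lo <= max_len or (lo, hi) in seen:
                continue
            seen.add((lo, hi))
            windows.append(
                PrecursorWindow(
                    seq=seq[lo:hi],
                    mature_span=(start - lo, end - lo),
                    est_interval=(lo, hi),
                    strand=hit.strand,
                )
            )
    return windows


def _terminal_loops(structure: StructureRecord) -> list[tuple[int, int]]:
    """(i, j) hairpin-closing pairs: no other pair nested inside."""
    pt = structure.pair_table()
    loops = []
    for i, j in enumerate(pt):
        if j > i and all(pt[k] == -1 for k in range(i + 1, j)):
            loops.append((i, j))
    return loops


def locate_arm(structure: StructureRecord, mature_span: tuple[int, int]) -> str:
    """Which hairpin arm holds the mature: ``5p``, ``3p`` or ``loop_spanning``."""
    a, b = mature_span
    pt = structure.pair_table()
    partners = [pt[k] for k in range(a, b) if pt[k] != -1]
    if not partners:
        return "loop_spanning"
    for i, j in _terminal_loops(structure):
        apex = (i + j) // 2
        if a <= apex < b:
            return "loop_spanning"
    if all(p >= b for p in partners):
        return "5p"
    if all(p < a for p in partners):
        return "3p"
    return "loop_spanning"


def derive_star_and_mismatches(
    structure: StructureRecord, mature_span: tuple[int, int]
) -> tuple[tuple[int, int], int]:
    """Star interval under the structure and the duplex mismatch count.

    The star is the region pairing with the mature, extended by the
    conventional 2-nt 3' overhang.  Mismatches are mature positions
    left unpaired in the duplex; star nucleotides bulged beyond those
    add one each.
    """
    a, b = mature_span
    pt = structure.pair_table()
    partners = sorted(pt[k] for k in range(a, b) if pt[k] != -1)
    if not partners:
        raise ValueError("no duplex: mature is entirely unpaired")
    p_min, p_max = partners[0], partners[-1]
    # star's 3' end (high coordinate on either arm) gets the 2-nt overhang
    star_end = min(p_max + 3, len(structure.seq))
    if p_max < a:  # star upstream of a 3p mature: do not run into the mature
        star_end = min(star_end, a)
    star_span = (p_min, star_end)
    mature_unpaired = (b - a) - len(partners)
    star_core = p_max + 1 - p_min
    star_unpaired = star_core - len(partners)
    duplex_mismatches = mature_unpaired + max(0, star_unpaired - mature_unpaired)
    return star_span, duplex_mismatches


@dataclass(frozen=True)
class HairpinCandidate:
    """A folded precursor window with the published stability metrics."""

    est_id: str
    mirna_id: str
    mature_seq: str
    precursor_seq: str
    structure: StructureRecord
    mature_span: tuple[int, int]
    est_interval: tuple[int, int]
    strand: str
    arm: str
    star_span: tuple[int, int] | None
    duplex_mismatches: int | None
    gc_percent: float
    mfe: float
    amfe: float
    mfei: float

    @property
    def precursor_length(self) -> int:
        return len(self.precursor_seq)


@dataclass(frozen=True)
class CriteriaReport:
    passed: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        assert self.passed == (not self.reasons)


def make_candidate(est_id: str, mirna_id: str, window: PrecursorWindow) -> HairpinCandidate:
    """Fold a window and populate every metric of a hairpin candidate."""
    structure = fold(window.seq)
    arm = locate_arm(structure, window.mature_span)
    star_span: tuple[int, int] | None = None
    duplex_mm: int | None = None
    if arm in ("5p", "3p"):
        try:
            star_span, duplex_mm = derive_star_and_mismatches(
                structure, window.mature_span
            )
        except ValueError:
            pass
    gc = gc_percent(window.seq)
    mfe_val = -structure.energy_kcal_mol
    amfe_val = amfe(mfe_val, len(window.seq))
    mfei_val = mfei(amfe_val, gc) if gc > 0 else 0.0
    a, b = window.mature_span
    return HairpinCandidate(
        est_id=est_id,
        mirna_id=mirna_id,
        mature_seq=window.seq[a:b],
        precursor_seq=window.seq,
        structure=structure,
        mature_span=window.mature_span,
        est_interval=window.est_interval,
        strand=window.strand,
        arm=arm,
        star_span=star_span,
        duplex_mismatches=duplex_mm,
        gc_percent=gc,
        mfe=mfe_val,
        amfe=amfe_val,
        mfei=mfei_val,
    )


def _has_stem_loop(
    candidate: HairpinCandidate, min_stem_pairs: int
) -> bool:
    """Criterion 1: a single-terminal-loop helix of enough cumulative pairs
    whose span covers every paired mature base."""
    structure = candidate.structure
    pt = structure.pair_table()
    if structure.n_pairs == 0:
        return False
    a, b = candidate.mature_span
    mature_pairs = [k for k in range(a, b) if pt[k] != -1]
    loops = _terminal_loops(structure)
    pairs = [(i, j) for i, j in enumerate(pt) if j > i]
    for i, j in pairs:
        n_loops = sum(1 for li, lj in loops if i <= li and lj <= j)
        if n_loops != 1:
            continue
        cumulative = sum(1 for pi, pj in pairs if i <= pi and pj <= j)
        if cumulative < min_stem_pairs:
            continue
        if mature_pairs and all(
            i <= k <= j and i <= pt[k] <= j for k in mature_pairs
        ):
            return True
    return False


def evaluate_candidate(
    candidate: HairpinCandidate,
    mfei_min: float = 0.5,
    star_mm_max: int = 5,
    mature_len_range: tuple[int, int] = (19, 21),
    min_stem_pairs: int = 15,
) -> CriteriaReport:
    """Apply the four homolog criteria plus the mature length gate.

    Reasons list every failed criterion.  When the mature spans the
    loop, no mature/star duplex exists, so the duplex mismatch
    criterion is not separately reported.
    """
    reasons: list[str] = []
    if not _has_stem_loop(candidate, min_stem_pairs):
        reasons.append("no_stem_loop")
    if candidate.arm == "loop_spanning":
        reasons.append("mature_spans_loop")
    elif candidate.duplex_mismatches is None or candidate.duplex_mismatches > star_mm_max:
        reasons.append("star_mismatches_gt5")
    if candidate.mfei < mfei_min:
        reasons.append("mfei_lt_threshold")
    lo, hi = mature_len_range
    if not lo <= len(candidate.mature_seq) <= hi:
        reasons.append("length_out_of_range")
    return CriteriaReport(passed=not reasons, reasons=tuple(reasons))


def assess_hit(
    est: SequenceRecord,
    hit: HomologyHit,
    flank: int = 100,
    min_len: int = 60,
    max_len: int = 300,
    mfei_min: float = 0.5,
    star_mm_max: int = 5,
    mature_len_range: tuple[int, int] = (19, 21),
    min_stem_pairs: int = 15,
) -> tuple[HairpinCandidate, CriteriaReport] | None:
    """Evaluate every window around a hit and pick the reported precursor.

    Among passing windows the highest-MFEI one wins (ties: shorter
    precursor).  If no window passes, the longest window is reported so
    the rejection is judged on the fullest available precursor context.
    Returns ``None`` when the EST affords no window of legal length.
    """
    windows = excise_precursor(est, hit, flank=flank, min_len=min_len, max_len=max_len)
    if not windows:
        return None
    evaluated = []
    for w in windows:
        cand = make_candidate(est.id, hit.mirna.id, w)
        report = evaluate_candidate(
            cand,
            mfei_min=mfei_min,
            star_mm_max=star_mm_max,
            mature_len_range=mature_len_range,
            min_stem_pairs=min_stem_pairs,
        )
        evaluated.append((cand, report))
    passing = [(c, r) for c, r in evaluated if r.passed]
    if passing:
        passing.sort(key=lambda cr: (-cr[0].mfei, cr[0].precursor_length))
        return passing[0]
    evaluated.sort(key=lambda cr: (-cr[0].precursor_length, -cr[0].mfei))
    return evaluated[0]
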