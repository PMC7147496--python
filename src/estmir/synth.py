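"""Synthetic ESTs, reference sets, hairpins and transcriptomes with
planted ground truth.

Every planted item is constructed to a structural design (stem
mismatch count, loop length, GC target, violated criterion) and then
*verified* against the package's own folding and evaluation before it
is emitted: draws whose random context folds degenerately are
rejection-sampled away.  The emitted truth manifest therefore records
properties the data provably have, not merely intended ones.
Generation is fully deterministic under (seed, parameters).

Background ESTs emulate a neutral null — uniform ACGT with no planted
mature within two mismatches on either strand — so any downstream call
on them is a genuine false positive.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .hairpin import (
    PrecursorWindow,
    assess_hit,
    evaluate_candidate,
    make_candidate,
)
from .homology import _encode, _mismatch_profile, find_hits
from .io import ReferenceMiRNA, SequenceRecord, revcomp
from .targets import SEED_MULTIPLIER, SEED_RANGE, PENALTY_GAP, PENALTY_MISMATCH, PENALTY_WOBBLE

__all__ = [
    "HairpinSpec",
    "TargetSpec",
    "PlantedHairpin",
    "PlantedTarget",
    "TruthManifest",
    "make_reference_set",
    "plant_hairpin",
    "make_est_collection",
    "plant_target_sites",
    "full_preset",
    "smoke_preset",
]

_BASES = np.array(list("ACGT"))
#: partner sets under the folding model (Watson-Crick + G:U)
_PARTNERS = {"A": {"T"}, "C": {"G"}, "G": {"C", "T"}, "T": {"A", "G"}}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE_SUB = {"G": "T", "T": "G"}  # target base giving a G:U pair
_MISMATCH_SUB = {"A": "C", "C": "A", "G": "A", "T": "C"}  # neither pairs nor wobbles

_MAX_TRIES = 200


def _rand_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _ca_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    """C/A-alphabet filler: carries GC content but cannot pair with itself."""
    return "".join(rng.choice(["C", "A"], size=n, p=[gc, 1 - gc]))


def _loop_seq(rng: np.random.Generator, n: int) -> str:
    """Terminal-loop filler: poly-A, the most inert choice under the
    folding model (a C-containing loop readily nucleates a competing
    helix against star G's)."""
    return "A" * n


@dataclass(frozen=True)
class HairpinSpec:
    """Design parameters for one planted pre-miRNA."""

    mature_len: int = 21
    stem_mismatches: int = 0
    loop_len: int = 8
    flank_gc: float = 0.5  # GC target of the intra-precursor flanks
    est_flank: int = 40  # random EST sequence on each side of the precursor
    strand: str = "+"
    precursor_target_len: int = 110
    violation: str | None = None  # one CriteriaReport reason, or None


@dataclass(frozen=True)
class TargetSpec:
    """One planted target site: per-position deviations from a perfect duplex."""

    mirna_index: int  # which reference miRNA binds here
    profile: dict[int, str] = field(default_factory=dict)  # pos (1-based) -> state


@dataclass(frozen=True)
class PlantedHairpin:
    est_id: str
    mature_seq: str
    mirna_id: str
    offset: int  # mature start on the forward EST
    strand: str
    precursor_interval: tuple[int, int]
    engineered_duplex_mismatches: int
    designed_gc_percent: float
    violation: str | None


@dataclass(frozen=True)
class PlantedTarget:
    transcript_id: str
    mirna_id: str
    offset: int
    span: tuple[int, int]
    profile: dict[int, str]
    expected_expectation: float
    expected_mismatch_states: int
    expected_inhibition: str
    qualifies: bool  # meets both the expectation and the mismatch cutoffs


@dataclass
class TruthManifest:
    seed: int
    generator_params: dict
    planted_hairpins: list[PlantedHairpin] = field(default_factory=list)
    planted_targets: list[PlantedTarget] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "generator_params": self.generator_params,
            "planted_hairpins": [asdict(h) for h in self.planted_hairpins],
            "planted_targets": [asdict(t) for t in self.planted_targets],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        raw = json.loads(Path(path).read_text())
        return cls(
            seed=raw["seed"],
            generator_params=raw["generator_params"],
            planted_hairpins=[
                PlantedHairpin(
                    **{
                        **h,
                        "precursor_interval": tuple(h["precursor_interval"]),
                    }
                )
                for h in raw["planted_hairpins"]
            ],
            planted_targets=[
                PlantedTarget(
                    **{
                        **t,
                        "span": tuple(t["span"]),
                        "profile": {int(k): v for k, v in t["profile"].items()},
                    }
                )
                for t in raw["planted_targets"]
            ],
        )


def make_reference_set(
    n: int, length_range: tuple[int, int] = (19, 24), seed: int = 0
) -> list[ReferenceMiRNA]:
    """A miRBase-like synthetic mature set with >= 2 families for n >= 2."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    refs = []
    for k in range(n):
        fam = 100 + k // 2
        letter = "ab"[k % 2] if n > 1 else "a"
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        refs.append(
            ReferenceMiRNA(
                id=f"syn-miR{fam}{letter}-5p",
                seq=_rand_seq(rng, L),
            )
        )
    return refs


def _make_star(
    mature: str, stem_mismatches: int, rng: np.random.Generator
) -> str:
    """Reverse complement of the mature with engineered non-pairing subs."""
    star = list(revcomp(mature))
    L = len(mature)
    if stem_mismatches == 0:
        return "".join(star)
    if not 0 <= stem_mismatches <= 8:
        raise ValueError("stem_mismatches must be in [0, 8]")
    # Mismatch positions sit at interior mature C/A bases when possible:
    # a freed C or A cannot re-pair with the C/A flanks or the A-rich
    # loop, so the engineered defect survives folding.  Two paired bases
    # are kept at each duplex end.
    interior = list(range(2, L - 2))
    preferred = [i for i in interior if mature[i] in "CA"]
    rest = [i for i in interior if i not in preferred]
    pool = preferred + rest
    if stem_mismatches > len(pool):
        raise ValueError("mature too short for the requested mismatch count")
    if len(preferred) >= stem_mismatches:
        take = np.round(
            np.linspace(0, len(preferred) - 1, stem_mismatches)
        ).astype(int)
        positions = sorted({preferred[t] for t in take})
        while len(positions) < stem_mismatches:
            extra = preferred[int(rng.integers(len(preferred)))]
            if extra not in positions:
                positions = sorted(positions + [extra])
    else:
        positions = sorted(pool[:stem_mismatches])
    for mp in positions:
        k = L - 1 - mp  # star index opposite mature position mp
        neighborhood = {mature[q] for q in range(max(0, mp - 1), min(L, mp + 2))}
        forbidden = {star[k]}
        for m in neighborhood:
            forbidden |= {b for b in "ACGT" if m in _PARTNERS[b]}
        # prefer substitutions that are themselves inert against the
        # C/A environment (A and C pair nothing the flanks offer)
        allowed = [b for b in "ACTG" if b not in forbidden]
        if not allowed:
            allowed = [
                b
                for b in "ACTG"
                if b != star[k] and mature[mp] not in _PARTNERS[b]
            ]
        star[k] = allowed[0] if allowed[0] in "AC" else allowed[
            int(rng.integers(len(allowed)))
        ]
    return "".join(star)


def plant_hairpin(
    mature: str,
    stem_mismatches: int,
    loop_len: int,
    flank_gc_target: float,
    seed: int,
    precursor_target_len: int = 110,
) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """Assemble flank + mature + loop + star + flank.

    Flanks and loop use the C/A alphabet (no self-pairing) with the C
    fraction set by ``flank_gc_target`` (a percentage if > 1).  Returns
    the precursor, the mature span and the designed star span.
    """
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    gc = flank_gc_target / 100 if flank_gc_target > 1 else flank_gc_target
    if not 0 <= gc <= 1:
        raise ValueError("infeasible GC target")
    rng = np.random.default_rng(seed)
    L = len(mature)
    last = None
    for _ in range(_MAX_TRIES):
        star = _make_star(mature, stem_mismatches, rng)
        fill = max(0, precursor_target_len - 2 * L - loop_len)
        lf, rf = fill // 2, fill - fill // 2
        left = _ca_seq(rng, lf, gc)
        loop = _loop_seq(rng, loop_len)
        right = _ca_seq(rng, rf, gc)
        precursor = left + mature + loop + star + right
        mature_span = (lf, lf + L)
        star_span = (lf + L + loop_len, lf + L + loop_len + L)
        last = (precursor, mature_span, star_span)
        if stem_mismatches > 3:
            # alternative foldings may absorb some engineered mismatches;
            # the duplex property is only guaranteed up to 3
            break
        cand = make_candidate(
            "planted", "syn-miR0a-5p",
            PrecursorWindow(seq=precursor, mature_span=mature_span,
                            est_interval=(0, len(precursor)), strand="+"),
        )
        if cand.arm == "5p" and cand.duplex_mismatches == stem_mismatches:
            break
    else:
        raise RuntimeError("could not realize the designed duplex; infeasible spec")
    return last


def _build_precursor(
    spec: HairpinSpec, rng: np.random.Generator
) -> tuple[str, str, tuple[int, int], int]:
    """(precursor, mature, mature_span, engineered_mm) for one spec."""
    if spec.violation == "mature_spans_loop":
        stem = _rand_seq(rng, 20, gc=0.5)
        loop = "".join(rng.choice(["C", "A"], size=5))
        flank = _ca_seq(rng, 25, 0.45)
        flank2 = _ca_seq(rng, 25, 0.45)
        precursor = flank + stem + loop + revcomp(stem) + flank2
        mature = stem[-8:] + loop + revcomp(stem)[:8]
        span = (len(flank) + 12, len(flank) + 12 + 21)
        return precursor, mature, span, 0
    if spec.violation == "mfei_lt_threshold":
        # an all-wobble (G:U) duplex: fully paired yet thermodynamically
        # feeble, in a G-only context that offers nothing stronger to pair
        mature = "".join(rng.choice(["G", "T"], size=21))
        star = "".join(_WOBBLE_SUB[b] for b in mature)[::-1]
        left, loop, right = "G" * 22, "G" * 9, "G" * 22
        precursor = left + mature + loop + star + right
        span = (22, 43)
        return precursor, mature, span, 0
    mature = _rand_seq(rng, spec.mature_len, gc=0.5)
    precursor, span, _ = plant_hairpin(
        mature,
        spec.stem_mismatches,
        spec.loop_len,
        spec.flank_gc,
        seed=int(rng.integers(2**31)),
        precursor_target_len=spec.precursor_target_len,
    )
    return precursor, mature, span, spec.stem_mismatches


def _expected_reasons(spec: HairpinSpec) -> tuple[str, ...]:
    return () if spec.violation is None else (spec.violation,)


def _planted_est_ok(
    est: SequenceRecord,
    ref: ReferenceMiRNA,
    mature_offset: int,
    strand: str,
    spec: HairpinSpec,
    precursor: str,
    mature_span: tuple[int, int],
) -> bool:
    """Verify the planted EST behaves as engineered end to end."""
    # the exact precursor window must evaluate to the engineered outcome
    cand = make_candidate(est.id, ref.id, PrecursorWindow(
        seq=precursor,
        mature_span=mature_span,
        est_interval=(0, len(precursor)),
        strand="+",
    ))
    report = evaluate_candidate(cand)
    if report.reasons != _expected_reasons(spec):
        return False
    if spec.violation is None and spec.stem_mismatches <= 3:
        if cand.duplex_mismatches != spec.stem_mismatches:
            return False
    hits = find_hits([ref], [est])
    designed = [
        h
        for h in hits
        if h.strand == strand and h.est_start == mature_offset and h.mismatches == 0
    ]
    if not designed:
        return False
    if spec.violation is None:
        assessed = assess_hit(est, designed[0])
        return assessed is not None and assessed[1].passed
    for h in hits:
        assessed = assess_hit(est, h)
        if assessed is None or assessed[1].reasons != _expected_reasons(spec):
            return False
    return True


def _clean_background(
    rng: np.random.Generator,
    length_range: tuple[int, int],
    mature_codes: list[np.ndarray],
    max_tries: int = _MAX_TRIES,
) -> str:
    """A random EST with no planted mature within 2 mismatches, both strands."""
    for _ in range(max_tries):
        n = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _rand_seq(rng, n)
        fwd, rev = _encode(seq), _encode(revcomp(seq))
        clean = True
        for mat in mature_codes:
            for enc in (fwd, rev):
                prof = _mismatch_profile(enc, mat)
                if prof.size and prof.min() <= 2:
                    clean = False
                    break
            if not clean:
                break
        if clean:
            return seq
    raise RuntimeError(
        "background rejection sampling exhausted; use longer matures"
    )


def make_est_collection(
    n_background: int,
    planted: Sequence[HairpinSpec],
    est_length_range: tuple[int, int] = (200, 500),
    seed: int = 0,
    decoy_refs: Sequence[ReferenceMiRNA] = (),
) -> tuple[list[SequenceRecord], list[ReferenceMiRNA], TruthManifest]:
    """Generate planted + background ESTs and the matching reference set.

    Returns (ests, reference miRNAs for the planted matures, manifest).
    Planted constructs are re-drawn until their EST verifies end to end
    (hairpin evaluation yields exactly the engineered outcome).
    """
    rng = np.random.default_rng(seed)
    manifest = TruthManifest(
        seed=seed,
        generator_params={
            "n_background": n_background,
            "n_planted": len(planted),
            "est_length_range": list(est_length_range),
        },
    )
    refs: list[ReferenceMiRNA] = []
    planted_ests: list[SequenceRecord] = []
    for idx, spec in enumerate(planted):
        est_id = f"synEST{idx:04d}"
        ref_id = f"syn-miR{200 + idx}a-5p"
        ok = False
        for _ in range(_MAX_TRIES):
            try:
                precursor, mature, span, eng_mm = _build_precursor(spec, rng)
            except RuntimeError:
                continue  # that mature draw was infeasible; redraw
            ref = ReferenceMiRNA(id=ref_id, seq=mature)
            lf = _rand_seq(rng, spec.est_flank) if spec.est_flank else ""
            rf = _rand_seq(rng, spec.est_flank) if spec.est_flank else ""
            fwd_est = lf + precursor + rf
            if spec.strand == "+":
                est = SequenceRecord(id=est_id, seq=fwd_est)
                offset = len(lf) + span[0]
                interval = (len(lf), len(lf) + len(precursor))
            else:
                est = SequenceRecord(id=est_id, seq=revcomp(fwd_est))
                n = len(fwd_est)
                offset = n - (len(lf) + span[1])
                interval = (n - len(lf) - len(precursor), n - len(lf))
            if _planted_est_ok(est, ref, offset if spec.strand == "+" else offset,
                               spec.strand, spec, precursor, span):
                # recompute designed offset on forward EST coordinates
                if spec.strand == "-":
                    offset = len(est) - (len(lf) + span[1])
                ok = True
                break
        if not ok:
            raise RuntimeError(f"could not realize planted hairpin {idx} ({spec})")
        refs.append(ref)
        planted_ests.append(est)
        manifest.planted_hairpins.append(
            PlantedHairpin(
                est_id=est_id,
                mature_seq=mature,
                mirna_id=ref_id,
                offset=offset,
                strand=spec.strand,
                precursor_interval=interval,
                engineered_duplex_mismatches=eng_mm,
                designed_gc_percent=round(
                    100 * (precursor.count("G") + precursor.count("C")) / len(precursor), 2
                ),
                violation=spec.violation,
            )
        )
    mature_codes = [_encode(r.seq) for r in refs] + [_encode(r.seq) for r in decoy_refs]
    background = [
        SequenceRecord(
            id=f"synEST{len(planted) + i:04d}",
            seq=_clean_background(rng, est_length_range, mature_codes),
        )
        for i in range(n_background)
    ]
    return planted_ests + background, refs, manifest


def _profile_expectation(profile: dict[int, str]) -> float:
    pen = {"match": 0.0, "wobble": PENALTY_WOBBLE, "mismatch": PENALTY_MISMATCH,
           "gap_target": PENALTY_GAP}
    total = 0.0
    for pos, state in profile.items():
        f = SEED_MULTIPLIER if SEED_RANGE[0] <= pos <= SEED_RANGE[1] else 1.0
        total += pen[state] * f
    return total


def _site_sequence(mirna: ReferenceMiRNA, profile: dict[int, str]) -> str:
    """Target-sense site: reverse complement with engineered deviations."""
    L = len(mirna)
    site = [""] * L
    for i, m in enumerate(mirna.seq, start=1):
        state = profile.get(i, "match")
        if state == "match":
            b = _COMPLEMENT[m]
        elif state == "wobble":
            if m not in _WOBBLE_SUB:
                raise ValueError(f"no G:U wobble possible at position {i} (base {m})")
            b = _WOBBLE_SUB[m]
        elif state == "mismatch":
            b = _MISMATCH_SUB[m]
        else:
            raise ValueError(f"unsupported planted state {state!r}")
        site[L - i] = b  # antiparallel: miRNA 5' end pairs the site's 3' end
    return "".join(site)


def plant_target_sites(
    transcripts: int,
    sites: Sequence[TargetSpec],
    mirnas: Sequence[ReferenceMiRNA],
    seed: int = 0,
    tx_length_range: tuple[int, int] = (400, 700),
    expectation_max: float = 3.0,
    max_mismatches: int = 2,
) -> tuple[list[SequenceRecord], TruthManifest]:
    """Random transcripts with engineered miRNA binding sites.

    Each site's expectation score is computed directly from its state
    profile and recorded; ``qualifies`` marks sites meeting both the
    expectation and mismatch cutoffs.  Overlapping placements raise.
    The transcript backgrounds are verified (and redrawn if necessary)
    so that a scan recovers exactly the qualifying planted sites.
    """
    from .targets import scan_transcripts  # deferred: avoids import cycle

    rng = np.random.default_rng(seed)
    manifest = TruthManifest(
        seed=seed,
        generator_params={
            "transcripts": transcripts,
            "n_sites": len(sites),
            "tx_length_range": list(tx_length_range),
        },
    )
    for _ in range(_MAX_TRIES):
        txs: list[str] = [
            _rand_seq(rng, int(rng.integers(*tx_length_range))) for _ in range(transcripts)
        ]
        placements: list[tuple[int, int, int, TargetSpec, str]] = []
        occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(transcripts)}
        feasible = True
        for k, spec in enumerate(sites):
            mir = mirnas[spec.mirna_index]
            profile = _feasible_profile(mir, spec.profile)
            site_seq = _site_sequence(mir, profile)
            t_idx = k % transcripts
            placed = False
            for _ in range(_MAX_TRIES):
                off = int(rng.integers(0, len(txs[t_idx]) - len(site_seq)))
                span = (off, off + len(site_seq))
                if all(span[1] <= a or span[0] >= b for a, b in occupied[t_idx]):
                    occupied[t_idx].append(span)
                    placements.append((k, t_idx, off, spec, profile, site_seq))
                    placed = True
                    break
            if not placed:
                raise ValueError("overlapping planted sites: transcript too crowded")
        for k, t_idx, off, spec, profile, site_seq in placements:
            s = txs[t_idx]
            txs[t_idx] = s[:off] + site_seq + s[off + len(site_seq):]
        records = [
            SequenceRecord(id=f"synTX{i:03d}", seq=s) for i, s in enumerate(txs)
        ]
        expected_calls = set()
        planted_records = []
        for k, t_idx, off, spec, profile, site_seq in placements:
            mir = mirnas[spec.mirna_index]
            exp = _profile_expectation(profile)
            n_mm = sum(1 for s in profile.values() if s == "mismatch")
            central = any(
                profile.get(p, "match") != "match" for p in (10, 11)
            )
            qualifies = exp <= expectation_max and n_mm <= max_mismatches
            rec = PlantedTarget(
                transcript_id=records[t_idx].id,
                mirna_id=mir.id,
                offset=off,
                span=(off, off + len(site_seq)),
                profile=dict(profile),
                expected_expectation=exp,
                expected_mismatch_states=n_mm,
                expected_inhibition="Translation" if central else "Cleavage",
                qualifies=qualifies,
            )
            planted_records.append(rec)
            if qualifies:
                expected_calls.add((mir.id, rec.transcript_id, rec.span))
        found = scan_transcripts(
            mirnas, records, expectation_max=expectation_max, max_mismatches=max_mismatches
        )
        found_keys = {
            (c.alignment.mirna_id, c.alignment.transcript_id, c.alignment.transcript_span)
            for c in found
        }
        if found_keys == expected_calls:
            manifest.planted_targets = planted_records
            return records, manifest
    raise RuntimeError("could not realize a clean planted transcriptome")


# ---------------------------------------------------------------------------
# presets

def _full_hairpin_specs() -> list[HairpinSpec]:
    compliant = []
    for i in range(15):
        compliant.append(
            HairpinSpec(
                mature_len=19 + i % 3,
                stem_mismatches=i % 4,
                loop_len=6 + i % 6,
                flank_gc=0.40 + 0.02 * (i % 8),
                est_flank=(20 + 7 * i) % 80,
                strand="-" if i % 5 == 4 else "+",
                precursor_target_len=79 + (90 * i) // 14,
            )
        )
    violators = [
        HairpinSpec(mature_len=24, stem_mismatches=1, violation="length_out_of_range",
                    est_flank=0),
        HairpinSpec(mature_len=21, stem_mismatches=6, violation="star_mismatches_gt5",
                    est_flank=0),
        HairpinSpec(mature_len=19, stem_mismatches=5, violation="no_stem_loop",
                    est_flank=0, precursor_target_len=90),
        HairpinSpec(violation="mature_spans_loop", est_flank=0),
        HairpinSpec(violation="mfei_lt_threshold", est_flank=0),
    ]
    return compliant + violators


def _feasible_profile(
    mir: ReferenceMiRNA, profile: dict[int, str]
) -> dict[int, str]:
    """Relocate wobble states onto G/T miRNA bases (G:U needs G or U).

    A wobble is moved to the nearest free G/T position on the same side
    of the seed boundary; with no such position it degrades to a
    mismatch in place.  Non-wobble states are kept verbatim.
    """
    out: dict[int, str] = {p: s for p, s in profile.items() if s != "wobble"}
    lo, hi = SEED_RANGE
    for pos in (p for p, s in sorted(profile.items()) if s == "wobble"):
        in_seed = lo <= pos <= hi
        candidates = [
            q
            for q in range(1, len(mir) + 1)
            if mir.seq[q - 1] in "GT"
            and q not in out
            and (lo <= q <= hi) == in_seed
        ]
        if candidates:
            out[min(candidates, key=lambda q: abs(q - pos))] = "wobble"
        else:
            out[pos] = "mismatch"
    return out


def _full_target_specs() -> list[TargetSpec]:
    specs = []
    profiles: list[dict[int, str]] = [
        {},  # perfect duplex, cleavage
        {15: "wobble"},  # 0.5
        {5: "mismatch"},  # seed mismatch, 2.0
        {10: "mismatch"},  # central: translation, 2.0
        {11: "wobble"},  # central wobble: translation, 1.0
        {1: "mismatch", 16: "mismatch"},  # 2.0, two mismatches (at the cap)
        {3: "wobble", 15: "wobble"},  # 1.5
        {9: "wobble"},  # seed wobble, 1.0
        {14: "mismatch"},  # 1.0
        {2: "mismatch", 7: "mismatch"},  # 4.0 > cutoff: must not be called
        {1: "mismatch", 14: "mismatch", 16: "mismatch"},  # 3 mismatches: excluded
        {18: "wobble", 19: "wobble"},
    ]
    for k in range(20):
        specs.append(TargetSpec(mirna_index=k % 5, profile=profiles[k % len(profiles)]))
    return specs


def full_preset(seed: int = 42):
    """The standard recovery benchmark: 200 background ESTs, 20 planted
    hairpins (15 compliant, 5 single-criterion violators), 20 planted
    target sites, plus 10 decoy reference miRNAs that hit nothing."""
    rng = np.random.default_rng(seed)
    decoys = make_reference_set(10, seed=int(rng.integers(2**31)))
    ests, refs, hp_manifest = make_est_collection(
        n_background=200,
        planted=_full_hairpin_specs(),
        est_length_range=(200, 500),
        seed=int(rng.integers(2**31)),
        decoy_refs=decoys,
    )
    target_mirnas = refs[:5]
    txs, tx_manifest = plant_target_sites(
        transcripts=8,
        sites=_full_target_specs(),
        mirnas=target_mirnas,
        seed=int(rng.integers(2**31)),
    )
    manifest = TruthManifest(
        seed=seed,
        generator_params={
            "preset": "full",
            **hp_manifest.generator_params,
            **tx_manifest.generator_params,
        },
        planted_hairpins=hp_manifest.planted_hairpins,
        planted_targets=tx_manifest.planted_targets,
    )
    return refs + decoys, ests, txs, manifest


def smoke_preset(seed: int = 42):
    """A seconds-scale variant: 20 background ESTs, 4 planted hairpins."""
    rng = np.random.default_rng(seed)
    specs = [
        HairpinSpec(mature_len=21, stem_mismatches=0, est_flank=30),
        HairpinSpec(mature_len=20, stem_mismatches=2, est_flank=0),
        HairpinSpec(mature_len=21, stem_mismatches=6, violation="star_mismatches_gt5",
                    est_flank=0),
        HairpinSpec(mature_len=24, stem_mismatches=1, violation="length_out_of_range",
                    est_flank=0),
    ]
    ests, refs, manifest = make_est_collection(
        n_background=20,
        planted=specs,
        est_length_range=(150, 300),
        seed=int(rng.integers(2**31)),
    )
    txs, tx_manifest = plant_target_sites(
        transcripts=3,
        sites=[TargetSpec(mirna_index=0), TargetSpec(mirna_index=1, profile={10: "mismatch"})],
        mirnas=refs[:2],
        seed=int(rng.integers(2**31)),
    )
    manifest.planted_targets = tx_manifest.planted_targets
    manifest.generator_params["preset"] = "smoke"
    return refs, ests, txs, manifest
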