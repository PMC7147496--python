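import pytest

from estmir.hairpin import (
    PrecursorWindow,
    amfe,
    derive_star_and_mismatches,
    evaluate_candidate,
    excise_precursor,
    gc_percent,
    locate_arm,
    make_candidate,
    mfei,
    truncate2,
)
from estmir.homology import HomologyHit
from estmir.io import ReferenceMiRNA, SequenceRecord, StructureRecord, revcomp
from estmir.synth import plant_hairpin

from conftest import random_seq


# --- reported-value arithmetic (truncation convention) --------------------

@pytest.mark.parametrize(
    "mfe, length, expected",
    [(42.55, 107, 39.76), (47.8, 169, 28.28), (42.95, 106, 40.51), (0.0, 100, 0.0)],
)
def test_amfe_truncates_to_published_values(mfe, length, expected):
    assert amfe(mfe, length) == expected


@pytest.mark.parametrize(
    "amfe_v, gc, expected",
    [(28.28, 47.93, 0.59), (40.76, 41.44, 0.98), (46.71, 51.3, 0.91), (39.76, 43.0, 0.92)],
)
def test_mfei_truncates_to_published_values(amfe_v, gc, expected):
    assert mfei(amfe_v, gc) == expected


def test_truncation_not_rounding():
    assert truncate2(40.519) == 40.51
    assert truncate2(39.766) == 39.76


def test_mfei_scaling_identity():
    assert mfei(42.0, 100.0) == truncate2(42.0 / 100)


def test_metric_preconditions():
    with pytest.raises(ValueError):
        amfe(10.0, 0)
    with pytest.raises(ValueError):
        mfei(10.0, 0.0)


def test_gc_percent_counts():
    assert gc_percent("GCGC") == 100.0
    assert gc_percent("ATAT") == 0.0
    assert gc_percent("GCNN") == 50.0  # N dilutes but never counts as G/C


def test_mfei_invariant_under_duplication():
    # doubling the precursor doubles MFE, leaving AMFE/GC and hence MFEI fixed
    m, L, gc = 42.55, 107, 43.0
    assert mfei(amfe(m, L), gc) == mfei(amfe(2 * m, 2 * L), gc)


# --- excision -------------------------------------------------------------

def _hit(est, start, end, strand="+"):
    mature = est.seq[start:end] if strand == "+" else revcomp(est.seq[start:end])
    return HomologyHit(
        est_id=est.id,
        mirna=ReferenceMiRNA(id="syn-miR900a-5p", seq=mature),
        est_start=start,
        est_end=end,
        strand=strand,
        mismatches=0,
    )


def test_excise_window_bounds(rng):
    est = SequenceRecord(id="e", seq=random_seq(rng, 400))
    windows = excise_precursor(est, _hit(est, 100, 121), flank=100)
    ivals = {w.est_interval for w in windows}
    assert {(0, 221), (100, 321), (50, 271)} <= ivals
    for w in windows:
        assert 60 <= len(w) <= 300
        a, b = w.mature_span
        assert w.seq[a:b] == est.seq[100:121]


def test_excise_clips_at_est_start(rng):
    est = SequenceRecord(id="e", seq=random_seq(rng, 300))
    windows = excise_precursor(est, _hit(est, 5, 26), flank=100)
    assert min(w.est_interval[0] for w in windows) == 0


def test_excise_can_produce_published_length_range(rng):
    est = SequenceRecord(id="e", seq=random_seq(rng, 500))
    lengths = {len(w) for w in excise_precursor(est, _hit(est, 200, 221), flank=100)}
    assert any(79 <= L <= 169 for L in lengths)


def test_excise_minus_strand_mature_reads_forward(rng):
    fwd = random_seq(rng, 300)
    est = SequenceRecord(id="e", seq=fwd)
    h = _hit(est, 100, 121, strand="-")
    for w in excise_precursor(est, h, flank=50):
        a, b = w.mature_span
        assert w.seq[a:b] == h.mirna.seq


def test_excise_rejects_out_of_bounds(rng):
    est = SequenceRecord(id="e", seq=random_seq(rng, 100))
    bad = HomologyHit(
        est_id="e",
        mirna=ReferenceMiRNA(id="syn-miR900a-5p", seq=random_seq(rng, 21)),
        est_start=90,
        est_end=111,
        strand="+",
        mismatches=0,
    )
    with pytest.raises(ValueError):
        excise_precursor(est, bad)


# --- arm calls and star derivation ----------------------------------------

def _perfect_hairpin_structure(stem=30, loop=4):
    seq = "G" * stem + "A" * loop + "C" * stem
    db = "(" * stem + "." * loop + ")" * stem
    return StructureRecord(seq=seq, dotbracket=db, energy_kcal_mol=-50.0)


def test_mature_on_ascending_strand_is_5p():
    s = _perfect_hairpin_structure()
    assert locate_arm(s, (2, 23)) == "5p"


def test_mature_on_descending_strand_is_3p():
    s = _perfect_hairpin_structure()
    assert locate_arm(s, (40, 61)) == "3p"


def test_mature_across_apex_is_loop_spanning():
    s = _perfect_hairpin_structure()
    assert locate_arm(s, (20, 44)) == "loop_spanning"


def test_unpaired_structure_is_loop_spanning():
    s = StructureRecord(seq="A" * 40, dotbracket="." * 40, energy_kcal_mol=0.0)
    assert locate_arm(s, (5, 26)) == "loop_spanning"


def test_perfectly_paired_mature_has_zero_duplex_mismatches():
    s = _perfect_hairpin_structure()
    span, mm = derive_star_and_mismatches(s, (0, 21))
    assert mm == 0
    assert span[0] >= 34  # pairs into the 3' arm


def test_fully_unpaired_mature_raises_no_duplex():
    s = _perfect_hairpin_structure(stem=10, loop=30)
    with pytest.raises(ValueError, match="no duplex"):
        derive_star_and_mismatches(s, (12, 33))


@pytest.mark.parametrize("engineered", [0, 1, 2, 3])
def test_planted_stem_mismatches_recovered(engineered, rng):
    precursor, span, _ = plant_hairpin(
        random_seq(rng, 21), engineered, loop_len=8, flank_gc_target=45.0,
        seed=int(rng.integers(2**31)), precursor_target_len=110,
    )
    cand = make_candidate(
        "e", "syn-miR901a-5p",
        PrecursorWindow(seq=precursor, mature_span=span,
                        est_interval=(0, len(precursor)), strand="+"),
    )
    assert cand.arm == "5p"
    assert cand.duplex_mismatches == engineered


def test_six_engineered_mismatches_fail_star_criterion(rng):
    # >3 engineered mismatches are only lower-bounded (the fold may take
    # an alternative register), so look over draws for a clean realization
    for seed in range(30):
        precursor, span, _ = plant_hairpin(
            random_seq(rng, 21), 6, loop_len=8, flank_gc_target=45.0, seed=seed,
        )
        cand = make_candidate(
            "e", "syn-miR901a-5p",
            PrecursorWindow(seq=precursor, mature_span=span,
                            est_interval=(0, len(precursor)), strand="+"),
        )
        if cand.arm in ("5p", "3p") and cand.duplex_mismatches == 6:
            break
    else:
        pytest.fail("no clean 6-mismatch realization in 30 draws")
    report = evaluate_candidate(cand)
    assert "star_mismatches_gt5" in report.reasons


# --- criteria -------------------------------------------------------------

def _passing_candidate(rng):
    precursor, span, _ = plant_hairpin(
        random_seq(rng, 20), 1, loop_len=8, flank_gc_target=50.0, seed=11,
    )
    return make_candidate(
        "e", "syn-miR902a-5p",
        PrecursorWindow(seq=precursor, mature_span=span,
                        est_interval=(0, len(precursor)), strand="+"),
    )


def test_compliant_candidate_passes(rng):
    cand = _passing_candidate(rng)
    report = evaluate_candidate(cand)
    assert report.passed and report.reasons == ()


def test_mfei_boundary_is_strict(rng):
    import dataclasses

    cand = _passing_candidate(rng)
    low = dataclasses.replace(cand, mfei=0.49)
    assert evaluate_candidate(low).reasons == ("mfei_lt_threshold",)
    at = dataclasses.replace(cand, mfei=0.5)
    assert evaluate_candidate(at).passed


def test_mature_length_gate(rng):
    precursor, span, _ = plant_hairpin(
        random_seq(rng, 24), 0, loop_len=8, flank_gc_target=50.0, seed=3,
        precursor_target_len=120,
    )
    cand = make_candidate(
        "e", "syn-miR903a-5p",
        PrecursorWindow(seq=precursor, mature_span=span,
                        est_interval=(0, len(precursor)), strand="+"),
    )
    assert evaluate_candidate(cand).reasons == ("length_out_of_range",)
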