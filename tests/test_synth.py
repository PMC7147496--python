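import numpy as np
import pytest

from estmir.hairpin import PrecursorWindow, evaluate_candidate, make_candidate
from estmir.homology import find_hits
from estmir.io import parse_mirna_family
from estmir.synth import (
    HairpinSpec,
    TargetSpec,
    TruthManifest,
    make_est_collection,
    make_reference_set,
    plant_hairpin,
    plant_target_sites,
    smoke_preset,
)

from conftest import random_seq


def test_reference_set_deterministic_and_parsable():
    a = make_reference_set(5, seed=1)
    b = make_reference_set(5, seed=1)
    assert a == b
    for r in a:
        prefix, family = parse_mirna_family(r.id)
        assert prefix == "syn" and family.startswith("miR")
    assert len({r.family for r in a}) >= 2
    assert len(make_reference_set(1, seed=0)) == 1


def test_plant_hairpin_duplex_property(rng):
    for mm in (0, 2, 3):
        # some matures cannot realize the design (self-similar registers);
        # the planter raises for those and a fresh mature is drawn
        for _ in range(20):
            try:
                precursor, span, star_span = plant_hairpin(
                    random_seq(rng, 21), mm, loop_len=9, flank_gc_target=50.0,
                    seed=int(rng.integers(2**31)),
                )
                break
            except RuntimeError:
                continue
        else:
            pytest.fail("no realizable mature in 20 draws")
        cand = make_candidate(
            "e", "syn-miR1a-5p",
            PrecursorWindow(seq=precursor, mature_span=span,
                            est_interval=(0, len(precursor)), strand="+"),
        )
        assert cand.duplex_mismatches == mm
        a, b = span
        assert star_span[0] >= b  # star downstream of a 5' arm mature


def test_plant_hairpin_precursor_lengths_span_published_range(rng):
    for target in (79, 120, 169):
        precursor, _, _ = plant_hairpin(
            random_seq(rng, 21), 0, loop_len=8, flank_gc_target=50.0,
            seed=3, precursor_target_len=target,
        )
        assert len(precursor) == pytest.approx(target, abs=1)


def test_plant_hairpin_rejects_bad_parameters(rng):
    with pytest.raises(ValueError):
        plant_hairpin(random_seq(rng, 21), 0, loop_len=2, flank_gc_target=50.0, seed=0)
    with pytest.raises(ValueError):
        plant_hairpin(random_seq(rng, 21), 0, loop_len=8, flank_gc_target=150.0, seed=0)


def test_est_collection_deterministic_and_clean_background():
    ests1, refs1, m1 = make_est_collection(
        30, [HairpinSpec(mature_len=21, stem_mismatches=1, est_flank=20)], seed=5
    )
    ests2, refs2, m2 = make_est_collection(
        30, [HairpinSpec(mature_len=21, stem_mismatches=1, est_flank=20)], seed=5
    )
    assert [e.seq for e in ests1] == [e.seq for e in ests2]
    assert m1.planted_hairpins == m2.planted_hairpins
    # background carries no hits at all: the null experiment is truly null
    background = ests1[1:]
    assert find_hits(refs1, background) == []


def test_null_collection_yields_no_candidates():
    ests, refs, manifest = make_est_collection(25, [], seed=9)
    assert manifest.planted_hairpins == []
    assert len(ests) == 25
    decoys = make_reference_set(5, seed=9)
    assert all(
        h.mismatches <= 2 for h in find_hits(decoys, ests)
    )  # any chance hit still respects the bound


def test_manifest_round_trips_through_json(tmp_path):
    _, _, manifest = make_est_collection(
        5, [HairpinSpec(mature_len=20, stem_mismatches=2, est_flank=10)], seed=11
    )
    path = tmp_path / "truth.json"
    manifest.to_json(path)
    back = TruthManifest.from_json(path)
    assert back.planted_hairpins == manifest.planted_hairpins
    assert back.seed == manifest.seed


def test_planted_target_manifest_scores_by_hand():
    mirnas = make_reference_set(3, length_range=(21, 21), seed=2)
    txs, manifest = plant_target_sites(
        transcripts=2,
        sites=[
            TargetSpec(mirna_index=0),  # perfect
            TargetSpec(mirna_index=1, profile={5: "mismatch"}),  # seed x2
        ],
        mirnas=mirnas,
        seed=4,
    )
    perfect, seeded = manifest.planted_targets
    assert perfect.expected_expectation == 0.0
    assert seeded.expected_expectation == 2.0
    assert perfect.expected_inhibition == "Cleavage"
    for t in manifest.planted_targets:
        tx = {r.id: r for r in txs}[t.transcript_id]
        assert 0 <= t.span[0] < t.span[1] <= len(tx)


def test_planted_targets_empty_site_list():
    mirnas = make_reference_set(2, seed=3)
    txs, manifest = plant_target_sites(2, [], mirnas, seed=3)
    assert manifest.planted_targets == [] and len(txs) == 2


def test_smoke_preset_covers_pass_and_fail(rng):
    refs, ests, txs, manifest = smoke_preset(7)
    assert any(h.violation is None for h in manifest.planted_hairpins)
    assert any(h.violation is not None for h in manifest.planted_hairpins)
    # engineered reasons are realized, not just intended
    for h in manifest.planted_hairpins:
        est = {e.id: e for e in ests}[h.est_id]
        a, b = h.precursor_interval
        assert 0 <= a < b <= len(est)
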