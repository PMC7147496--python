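import numpy as np
import pytest

from estmir.io import ReferenceMiRNA, SequenceRecord, revcomp
from estmir.targets import classify_inhibition, scan_transcripts, score_duplex

from conftest import random_seq
from oracles import naive_duplex_expectation, naive_scan


def _mirna(rng, L=21, id="syn-miR700a-5p"):
    return ReferenceMiRNA(id=id, seq=random_seq(rng, L))


def _site_with(mirna, changes):
    """Target-sense site from per-position target-base overrides."""
    L = len(mirna.seq)
    site = list(revcomp(mirna.seq))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for pos, base in changes.items():
        site[L - pos] = base
    return "".join(site)


def test_perfect_complement_scores_zero(rng):
    mir = _mirna(rng)
    aln = score_duplex(mir, revcomp(mir.seq))
    assert aln.expectation == 0.0
    assert set(aln.pairs) == {"match"}


def test_wobble_outside_seed_costs_half(rng):
    rng2 = np.random.default_rng(5)
    while True:
        mir = _mirna(rng2)
        if mir.seq[14] in "GT":  # position 15 supports a G:U pair
            break
    wob = {"G": "T", "T": "G"}[mir.seq[14]]
    aln = score_duplex(mir, _site_with(mir, {15: wob}))
    assert aln.expectation == 0.5
    assert aln.state_at_position(15) == "wobble"


def test_seed_mismatch_costs_double(rng):
    mir = _mirna(rng)
    bad = {"A": "C", "C": "A", "G": "A", "T": "C"}[mir.seq[4]]
    aln = score_duplex(mir, _site_with(mir, {5: bad}))
    assert aln.expectation == 2.0
    assert aln.state_at_position(5) == "mismatch"


def test_window_length_precondition(rng):
    mir = _mirna(rng)
    with pytest.raises(ValueError):
        score_duplex(mir, "ACGT")


def test_classification_rules(rng):
    mir = _mirna(rng)
    perfect = score_duplex(mir, revcomp(mir.seq))
    assert classify_inhibition(perfect) == "Cleavage"
    bad10 = {"A": "C", "C": "A", "G": "A", "T": "C"}[mir.seq[9]]
    central = score_duplex(mir, _site_with(mir, {10: bad10}))
    assert classify_inhibition(central) == "Translation"
    bad9 = {"A": "C", "C": "A", "G": "A", "T": "C"}[mir.seq[8]]
    outside = score_duplex(mir, _site_with(mir, {9: bad9}))
    assert classify_inhibition(outside) == "Cleavage"


def test_expectation_monotone_in_penalized_states(rng):
    mir = _mirna(rng)
    sub = {"A": "C", "C": "A", "G": "A", "T": "C"}
    site = _site_with(mir, {})
    prev = score_duplex(mir, site).expectation
    for pos in (15, 16, 17):
        site = _site_with(
            mir, {p: sub[mir.seq[p - 1]] for p in range(15, pos + 1)}
        )
        cur = score_duplex(mir, site).expectation
        assert cur >= prev
        prev = cur


def test_scan_finds_planted_site_and_filters_mismatch_heavy(rng):
    mir = _mirna(rng)
    sub = {"A": "C", "C": "A", "G": "A", "T": "C"}
    good = _site_with(mir, {})
    heavy = _site_with(mir, {14: sub[mir.seq[13]], 16: sub[mir.seq[15]], 18: sub[mir.seq[17]]})
    tx = SequenceRecord(
        id="t", seq=random_seq(rng, 150) + good + random_seq(rng, 80) + heavy + random_seq(rng, 60)
    )
    calls = scan_transcripts([mir], [tx])
    spans = {c.alignment.transcript_span for c in calls}
    assert (150, 150 + len(good)) in spans
    # 3 mismatch states exceed the cap even though expectation == 3
    assert (150 + len(good) + 80, 150 + len(good) + 80 + len(heavy)) not in spans


def test_scan_equals_naive_window_scorer(rng):
    """The production scanner must agree with an independent per-window
    brute-force scorer on which loci qualify and at what expectation."""
    rng2 = np.random.default_rng(99)
    mirs = [_mirna(rng2, id=f"syn-miR70{i}a-5p") for i in range(2)]
    txs = []
    for i in range(3):
        seq = random_seq(rng2, 180)
        seq = seq[:50] + revcomp(mirs[i % 2].seq) + seq[50 + len(mirs[i % 2]):]
        txs.append(SequenceRecord(id=f"t{i}", seq=seq))
    calls = scan_transcripts(mirs, txs, expectation_max=3.0, max_mismatches=21)
    got = {
        (c.alignment.mirna_id, c.alignment.transcript_id): c.alignment.expectation
        for c in calls
    }
    for mir in mirs:
        for tx in txs:
            naive = naive_scan(mir, tx, expectation_max=3.0)
            if not naive:
                assert (mir.id, tx.id) not in got
                continue
            best = min(e for _, e in naive)
            assert got[(mir.id, tx.id)] == pytest.approx(best)


def test_double_scan_invariant_under_reverse_complement(rng):
    """The scanner reads one sense only, so both-strand coverage comes
    from an explicit double scan; that combined call set must be stable
    (up to coordinate reflection) under reverse-complementing the input."""
    mir = _mirna(rng)
    tx = SequenceRecord(
        id="t", seq=random_seq(rng, 70) + revcomp(mir.seq) + random_seq(rng, 40)
    )
    n = len(tx)

    def double_scan(record):
        fwd = scan_transcripts([mir], [record])
        rev = scan_transcripts(
            [mir], [SequenceRecord(id=record.id, seq=revcomp(record.seq))]
        )
        calls = {(c.alignment.transcript_span, "+", c.alignment.expectation) for c in fwd}
        calls |= {
            ((n - b, n - a), "-", c.alignment.expectation)
            for c in rev
            for a, b in [c.alignment.transcript_span]
        }
        return calls

    flip = {"+": "-", "-": "+"}
    original = double_scan(tx)
    reflected = {
        ((n - b, n - a), flip[s], e)
        for (a, b), s, e in double_scan(SequenceRecord(id="t", seq=revcomp(tx.seq)))
    }
    assert original == reflected
    assert ((70, 70 + len(mir)), "+", 0.0) in original


def test_empty_transcripts_empty_result(rng):
    assert scan_transcripts([_mirna(rng)], []) == []
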