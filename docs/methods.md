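# Methods

`estmir` re-implements, as a tested library, the classical EST-based
homology pipeline for plant miRNA discovery: known mature miRNAs are
matched against an EST collection, coding ESTs are excluded, candidate
precursors are excised and folded, hairpins are screened with the
standard homolog criteria and stability metrics, and the surviving
matures are scanned against transcripts for complementarity-based
target sites. This note records the models, the parameters that
matter, and the design choices made where the procedure is
conventionally under-specified.

## Homology screen

A locus is a hit when the full mature (19–25 nt) matches the EST or
its reverse complement end-to-end with at most `max_mismatches`
substitutions (default 2). Gaps are not modeled: the operative filter
in this class of pipeline is the mismatch bound, and mature/precursor
length parity in published candidate tables indicates ungapped
matches. A BLAST-style exact-word prefilter (`word_size`, default 7)
is applied only when it is provably lossless — a mature of length L
with k mismatches must retain a clean run of ⌈(L−k)/(k+1)⌉ bases, so
for L < 3·word_size + 2 the scan falls back to an exhaustive
vectorized sweep. Consequence: with the defaults, 19–22 nt matures are
scanned exhaustively, and the hit set equals a brute-force
sliding-window oracle by construction (asserted in tests). `N` never
matches anything. Redundancy removal keeps one hit per
(EST, offset, strand, mature sequence), preferring fewer mismatches,
then the lexicographically smallest miRNA name — reference sets list
identical matures under many species names, and those collapse to one
locus.

An e-value threshold is deliberately not used for filtering: e-values
depend on database-size statistics and are not reproducible across
reference releases, whereas the mismatch bound is.

## Coding filter

Hairpin candidates must come from non-coding ESTs. Two evidence routes
sit behind one interface: by default, a six-frame longest-ORF
heuristic (ATG-initiated, stop-terminated; threshold 80 aa, a common
non-coding-transcript cut-off), or, when available, external protein
homology results in the 12-column BLASTX tabular dialect, where any
hit at e-value ≤ 1e-3 marks the EST as coding and overrides the
heuristic. Raising the ORF threshold can only move verdicts from
coding to non-coding (anti-monotone; property-tested).

## Folding model

The bundled folder is a dynamic program over pseudoknot-free
structures minimizing a stacking-aware energy proxy:

| term | value (kcal/mol) |
|---|---|
| G:C pair | −3.0 |
| A:U pair | −2.0 |
| G:U wobble | −0.3 |
| stack bonus, (i,j) on (i+1,j−1) | −0.5 |
| minimum hairpin loop | 3 nt unpaired |

The DP is exact for this model — verified against exhaustive
enumeration of every valid structure on short sequences — and O(n³)
via a numba-compiled kernel (precursor windows are ≤ 300 nt). The
proxy ranks stem-loops by stability; it is not Turner-parameter
folding, so absolute energies differ from mfold/RNAfold. When
published energies must be reproduced exactly, externally computed
structures can be supplied in the Vienna-style three-line dialect
(sequence / dot-bracket / `(-35.50)`), bypassing the folder. The weak
G:U term reflects the marginal thermodynamic stability of wobble
pairs; it also makes an all-wobble duplex the canonical example of a
fully paired but feeble hairpin, which the synthetic generator uses to
exercise the MFEI gate in isolation.

Internally everything is DNA alphabet (U→T on ingest); RNA is a
display convention.

## Hairpin criteria and metrics

Candidate precursors are windows around a hit: a total flank budget of
2·`flank`, `flank` and `flank`/2 extra nucleotides, each split between
the two sides in quarter steps, clipped to the EST, lengths
restricted to [60, 300] nt (published plant pre-miRNAs in this setting
run ~70–170 nt). Minus-strand hits are excised from the reverse
complement so the mature always reads 5'→3'.

Each window is folded and screened:

1. **stem-loop**: some closing pair encloses exactly one terminal loop,
   carries ≥ 15 cumulative base pairs, and spans every paired mature
   base. The count is configurable; 15 accepts every hairpin at the
   published length scale while rejecting incidental structure.
2. **one arm**: all mature partners lie strictly downstream (5p) or
   upstream (3p); a mature containing the loop apex or pairing in both
   directions is `loop_spanning`.
3. **duplex mismatches ≤ 5**: unpaired mature positions, plus
   star-side unpaired positions in excess of those (so a substitution
   counts once and a bulged star base counts once). The star interval
   is the mature's partner range extended by the conventional 2-nt 3'
   overhang. When the mature spans the loop no duplex exists and this
   criterion is not separately reported.
4. **MFEI ≥ 0.5**, where MFE = −ΔG (a positive magnitude),
   AMFE = MFE·100/precursor-length, MFEI = AMFE/GC%. GC% is computed
   on the precursor, per the MFEI literature.

plus a mature length gate, default [19, 21] nt. All reported metrics
are **truncated** (not rounded) to two decimals — the convention the
published candidate tables demonstrably follow (e.g. 4255/107 = 39.766
printed as 39.76). Among passing windows the highest-MFEI one is
reported (ties: shorter precursor); when none passes, the longest
window is reported so the rejection is judged on the fullest precursor
context.

## Target scoring

The scanner follows the plant small-RNA target-server convention:
align the miRNA 5'→3' against the reverse-complement sense of a
transcript window, accumulating penalties — mismatch 1, G:U wobble
0.5, gap 2 — doubled inside the seed (miRNA positions 2–13). These
constants are the scheme's published defaults and are configurable;
alignment is a global minimum-penalty DP (numba kernel for the scan,
with a traceback path for reported sites). Every span of width
[L−2, L+5] at every offset is scored; sites qualify at expectation
≤ 3 with at most 2 mismatch states (wobbles do not count as
mismatches by default), and overlapping qualifying spans of one miRNA
on one transcript reduce to the best (lowest expectation, fewest gaps,
leftmost). A non-match state at miRNA position 10 or 11 — the
cleavage-site positions — classifies the site as translational
repression; otherwise cleavage. The scanner reads the given sense
only; both-strand coverage is an explicit double scan.

## Synthetic data and what it shows

The generator plants parameterized truth into neutral backgrounds:

- **hairpins**: flank + mature + loop + star, where the star is the
  reverse complement of the mature with an exact number of engineered
  non-pairing substitutions. Flanks use a C/A alphabet (no self-pairing
  under the model) with the C fraction setting the GC target; the loop
  is poly-A (inert). Engineered mismatches sit at mature C/A positions
  so the freed bases cannot re-pair with the flanks. Constructs are
  *validated*: each draw is folded and evaluated, and redrawn until the
  engineered outcome (duplex mismatch count, or exactly one violated
  criterion) is realized — for ≤ 3 mismatches this converges quickly;
  pathological matures (self-similar registers) are redrawn.
- **single-criterion violators**, one per failure reason: an over-long
  mature (24 nt); a 6-mismatch star; a 19 nt mature with 5 mismatches
  (14 pairs, under the stem threshold); a mature laid across the loop
  apex of a designed stem; and an all-G:U-wobble duplex in a G-only
  context (fully paired, arm-clean, but MFEI < 0.5 in every window).
- **backgrounds**: uniform ACGT, rejection-sampled so no reference
  mature matches within 2 mismatches on either strand — any downstream
  call on them is a genuine false positive.
- **target sites**: reverse-complement sites with per-position
  engineered states; the expected expectation score is computed
  directly from the profile and recorded in the manifest, and the
  transcript background is redrawn until a scan recovers exactly the
  qualifying planted sites.

Everything is deterministic under (seed, parameters) and serialized to
a JSON truth manifest. The standard benchmark (`full_preset`, seed 42)
is 200 background ESTs, 20 planted hairpins (15 compliant, 5
violators), 10 decoy references and 20 planted target sites on 8
transcripts.

What passing these tests shows: the machinery finds exactly what is
planted, rejects for exactly the engineered reason, and calls no false
positives on a neutral null. What it does not show: behavior on real
EST data with sequencing error, chimerism, biased composition, repeat
families, or genuine borderline hairpins — and the published
real-data discovery counts depend on specific reference-database
releases and are not reproduced here; only the funnel logic (each
stage narrows the candidate set) and the report formats are
guaranteed.

## Problem sizes and numerical notes

Default test/benchmark scales are desk-sized by design: homology
oracle checks run 30 instances of 15 ESTs × ≤400 nt × 10 references;
folder-vs-enumeration checks use sequences of 10–12 nt (the folder's
documented minimum input is 10 nt); scan-vs-brute-force checks use
3 transcripts × 160 nt. Floating-point comparisons in DP tracebacks
use an absolute epsilon of 1e-9; reported metrics add 1e-9 before
truncation so exact decimal boundaries do not truncate down
spuriously. All randomness flows from numpy `default_rng` seeds;
reruns are byte-identical.
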