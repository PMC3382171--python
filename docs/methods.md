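# Methods

This note documents the models implemented in `resistkit`, the conventions
chosen where a convention had to be declared, the synthetic-data generators
and what they do and do not emulate, and the numerical choices that affect
results. Nothing here states an empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Dose-response (module `doseresponse`)

**TGI.** Raw endpoint counts are normalized as
`TGI = 1 − (treated − b̄)/(ū − b̄)` with `b̄` the mean of day-1 baseline
wells and `ū` the mean of endpoint untreated wells. TGI = 0 is growth
indistinguishable from untreated, TGI = 1 growth stasis at the seeding
level; values above 1 (net kill) and below 0 (stimulation) are retained in
dose-response output but clipped into [0, 1] before any Bliss arithmetic,
since Bliss treats inhibitions as probabilities. A plate whose adjusted
untreated signal is non-positive is rejected with the offending wells named.

**4PL.** `TGI(x) = L + (U − L)/(1 + (IC50/x)^h)` with `h > 0`, so response
rises with dose and IC50 is the inflection (a *relative* IC50, i.e.
half-maximal fitted effect, not 50% of full scale). Fitting minimizes
squared error over `(L, U, log10 IC50, h)` with `scipy.optimize.least_squares`
(trust-region reflective) under box constraints `L ∈ [−0.5, 1]`,
`U ∈ [0, 1.5]`, `h ∈ (0, 10]`, `IC50 ∈ [lowest dose/100, top dose × 100]`.
Three deterministic starts (log-IC50 at the 25/50/75% quantiles of the
tested log-doses, `h = 1`, asymptotes from the data range) make the fit
reproducible without stochastic restarts; the best converged start wins, and
if none converges a `FitFailureError` carrying the per-start diagnostics is
raised rather than returning a silent number. Replicate wells at the same
dose are averaged with uniform weight before fitting.

**Censoring.** When the fitted span `U − L` falls below `min_span`
(default 0.2 TGI units) or the fitted inflection exceeds the top tested
dose, the curve is reported as `censored = "greater_than_top"` with the top
dose as the bound — the reporting style used for resistant lines whose
IC50 is simply "greater than the highest dose tested". The 0.2 default
says: an effect spanning less than 20% of the inhibition scale over the
whole ladder is not a resolvable sigmoid.

**Ladders.** `ladder[i] = top / fold^i`, exact arithmetic; a display helper
rounds to 3 significant figures with unit selection (so the ninth 4-fold
point below 10 µM prints as 153 pM). Ratios of consecutive points equal the
fold exactly by construction.

## Bliss synergy (module `synergy`)

Expected combined inhibition under independence is `E = A + B − A·B`, with
the single-agent inhibitions `A`, `B` taken from the measured zero-dose
edges of the same dose matrix — not from fitted curves — so surface and
edges always refer to the same plate. ΔBLISS is `observed − expected`
floored at 0 (the stated 0 = additive, 1 = synergistic scale forces this
orientation); the signed excess is kept in a companion matrix so antagonism
(negative excess) remains inspectable. Observed values are clipped into
[0, 1] first.

**Synergy window.** The dose window of near-maximal synergy is the lowest
grid corner `(a, b)` (both nonzero) such that *every* cell with
`dose_a ≥ a` and `dose_b ≥ b` has `Δ ≥ 0.9 × max(Δ)` (threshold
configurable); among valid corners the one with the smallest dose product
wins, with smaller `dose_a` as the tie-break. If `max(Δ) = 0` an explicit
empty-window result is returned. This corner rule is a declared convention
— the underlying "maximal synergy occurs above (X, Y)" style of statement
does not itself define one — and it is verified in tests against an
exhaustive scan over all corners.

## Fusion detection (module `mapping`, `fusion`)

**Coordinates.** 1-based, inclusive, on the transcript sense strand
throughout. A fusion is `prefix(tx5, J5) + suffix(tx3, J3)`: J5 is the last
retained 5'-partner base, J3 the first retained 3'-partner base.

**Mapper.** A deliberately toy-scale aligner for fixture-sized references:
every k-mer (default k = 20) of every transcript is indexed; a read is
seeded at its two ends and middle (both orientations), extended without
gaps, and soft-clipped where matching stops. A mismatch is absorbed into
the matched span (budget: 4% of read length) only when the next three
bases continue to match, so extension cannot creep across a fusion
junction on chance matches; the matched window always ends on a matching
base. Only reads with a unique best placement (span, then mismatches)
count as mapped; equal-best placements on different transcripts are
recorded as ambiguous and excluded from chimeric counts but tallied.
Reverse-strand hits are reported in transcript orientation. Externally
aligned reads can be substituted via the minimal-SAM reader (six columns,
M/S CIGAR ops only). No spliced or gapped alignment is attempted.

**Chimeric pairs.** Pairs whose mates map uniquely to two different
transcripts, tallied per unordered transcript pair and sorted by support.
A junction-spanning mate maps to the partner holding the majority of its
bases (the minority side is clipped), so a pair only counts as chimeric
when its mates genuinely sit on opposite sides.

**Assembly.** Supporting reads (chimeric-pair mates plus reads with a soft
clip of ≥ 10 bases on either candidate partner, all already in transcript
orientation) are assembled with a k-mer de Bruijn graph (default k = 31);
maximal unambiguous paths become contigs, sorted by length. No contig
reaching 2k bases is reported as *assembly failure*, distinct from an
absence of fusion evidence.

**Junction localization.** For each split point `s` of the contig
(anchors ≥ 25 bases on each side), the score is the longest exact match of
a suffix of `contig[:s]` within tx5 plus the longest exact match of a
prefix of `contig[s:]` within tx3; the split maximizing the score is
reported. When junction bases are shared by both partners the split can
slide without changing the fusion sequence; the 5'-most split is reported
together with the `homology_interval` (the length of the slide). The
implementation (binary search over match lengths) is checked
property-style against a brute-force linear scan of every split.

**RBM.** Per-base coverage of a transcript from all uniquely mapped mate
intervals, scaled by `10^6 / total reads in the library` (total, not
mapped — "per million reads"). Region folds are ratios of mean RBM over a
1-based inclusive interval with an additive pseudocount (default 0.1 RBM)
for sparsely covered regions.

**Fusion ORF.** With annotated CDS starts `c5`, `c3`, the junction is in
frame iff `(J5 − c5 + 1) ≡ 0 (mod 3)` and `(J3 − c3) ≡ 0 (mod 3)`. The 5'
protein range is `1 .. (J5 − c5 + 1)/3`; the 3' range starts at
`(J3 − c3)/3 + 1` and runs to the 3' partner's annotated stop. A junction
upstream of the CDS start is reported as junction-in-UTR, not an error;
out-of-frame junctions are flagged with no protein ranges.

## Copy-number segmentation (module `cnv`)

Recursive binary segmentation minimizes within-segment squared error; a
split is accepted only when its cost reduction exceeds the BIC-style
penalty `2σ̂² log n`, with `σ̂ = median|Δ| / 0.954` estimated from
successive probe differences (robust to the true jumps; 0.954 is the
median of |N(0, √2)|). Minimum segment size is 5 probes. On noiseless
piecewise-constant tracks `σ̂ = 0` and every true changepoint is recovered
exactly. On noisy tracks binary segmentation occasionally places an extra
micro-segment straddling a jump; the accuracy metric used in tests is
therefore changepoint *localization*: each true changepoint must have a
recovered breakpoint within ±2 probes, and the fold of the amplified
segment is read from the segment covering the amplification's center.

Breakpoint positions are midpoints between the flanking probes. Gene
intervals are 1-based inclusive; a breakpoint strictly inside a gene span
reports the exons immediately 5' and 3' of the break in transcription
order (on the minus strand the genomic flanking exons swap roles), a
breakpoint exactly at an exon edge belongs to the adjacent intron, and a
breakpoint inside exon k reports (k, k).

## Matrix preprocessing (module `matrixprep`)

Per-analyte (row) median centering — the default, since absolute antibody
intensities are not comparable across analytes — with the axis exposed;
then saturation into [−3, 3]. "Scaling to a range" is implemented as
clipping, not affine rescaling: the range is display-oriented for heatmap
shading, in-range values must survive unchanged, and the operation is
idempotent.

## Synthetic data (module `synth`)

The generators define the study conditions used throughout the tests and
the acceptance script; all are deterministic per seed and return a
`SimTruth` record (JSON round-trippable) sufficient to recompute every
expected value.

- **Plates.** Treated counts are
  `baseline + (untreated − baseline)(1 − TGI(dose))`, each well multiplied
  by unit-mean lognormal noise of the given CV (default 5%, matching
  typical luminescence-assay repeatability); defaults 50,000 baseline /
  400,000 untreated counts emulate ~8-fold growth over a 3-day endpoint,
  3 replicate wells per dose. Zero noise makes the TGI round trip exact.
  With 5% CV the single-plate IC50 estimate scatters by several percent,
  so recovery over seeds is summarized by the geometric mean of the fitted
  IC50s (the natural aggregate for a log-scale parameter).
- **Combination surfaces.** `bliss` reproduces the independence surface
  exactly; `rescue` gives each single agent its own (typically flat) curve
  while combination cells with both doses above configurable gates follow
  a rescue curve evaluated on drug A's dose — an artifact construction
  that generates surfaces with known ΔBLISS structure (up to the ceiling
  of 1), not a mechanistic model of why a combination kills resistant
  cells; `antagonism` is `0.8·max(A, B)`, below independence wherever both
  act.
- **Fusion transcriptome.** A 3522-base 5' partner cut at base 2006 joined
  to a 2947-base 3' partner resuming at base 1202 (fusion length 3752).
  At most two bases flanking the junction are substituted so the junction
  carries zero micro-homology; this makes the reported J5/J3 single-valued,
  which is the regime in which a single printed coordinate is meaningful.
  Wild-type partners plus an optional background pool form the reference.
- **Reads.** 75-base mates from opposite ends of Gaussian fragments
  (250 ± 30), fragment counts multinomial with probability ∝ molar
  abundance × effective length (`length − mean insert + 1`), inserts
  clamped into [read length, transcript length]. Error-free by default —
  the statistics under test concern fusion evidence and coverage, not
  aligner robustness; `error_rate > 0` exists for stress tests only.
- **Coverage folds.** Expected per-base coverage is proportional to molar
  abundance divided by the library's total abundance-weight, so in a
  library containing only the two partners and the fusion, RBM
  normalization (by *total* reads) caps the achievable 3'-suffix fold near
  1.7 — adding fusion reads proportionally depletes everything else. Real
  libraries do not behave this way because a fusion is a tiny mass
  fraction of a transcriptome, so the generator includes a background pool
  (default 12 × 2 kb transcripts at abundance 10 each) emulating the rest
  of the library, and `fusion_abundance_for_region_fold` solves the exact
  abundance for a requested expected fold (20 by default). The pool size
  balances realism against sampling noise on the sparsely covered
  wild-type 3' partner.
- **CNV tracks.** Unit-spaced probes, piecewise-constant means plus
  Gaussian noise; the study condition is a 4-fold amplification
  (mean log2 = 2, 80 probes) between 200-probe neutral flanks at σ = 0.25.

What the generators do *not* emulate: sequencing base-quality models, PCR
duplicates, intron-containing genomic alignment, array probe-affinity
effects, or plate spatial artifacts. Passing recovery tests therefore
demonstrates correctness of the statistics and the pipeline plumbing under
clean data at realistic effect sizes, not robustness to every artifact of
production data.

## Problem sizes and runtime

The acceptance script uses the full stated conditions: 20,000 read pairs
for junction recovery, two 200,000-pair libraries for the RBM fold, 20
seeded tracks of 480 probes for CNV recovery, 60-cell combination grids,
and 9-point curves; it completes in well under a minute on one CPU. The
test suite uses the same conditions at reduced library sizes (6,000–60,000
pairs) chosen to keep the sampling error comfortably inside each test's
tolerance.

## Known limitations

- The mapper is exact-seeded and ungapped; indels or heavy error rates
  defeat it by design (substitute external alignments via minimal SAM).
- Junction localization assumes the contig orientation matches one of the
  two partner orderings tried; multi-fusion isoforms are not resolved.
- Binary segmentation reports no per-breakpoint confidence and can
  over-segment at jumps (see the localization metric above); permutation
  p-values as in circular binary segmentation are out of scope.
- ΔBLISS is computed from measured edges, so noise on the single-agent
  edges propagates into the whole expected surface.
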