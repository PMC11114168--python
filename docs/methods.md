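# Methods

## What the package computes

`vaeeg` analyses 16-channel scalp EEG recorded while a subject receives
either manual acupuncture (MA) at the Zusanli (ST36) acupoint or a
VR-presented simulation of the same procedure (virtual acupuncture, VA).
The scientific question is whether the VA events evoke EEG activity that
is statistically indistinguishable from the MA events. The analysis
chain is:

1. **Session layout.** Two recording days. Day 1: a 6-minute fixation
   block (1 min closed-eye + 5 min open-eye rest), then
   MA1/rest/MA2/rest and, after an unrecorded 20-minute intermission,
   VA1/rest/VA2/rest. Day 2: fixation, then VA3/rest/VA4/rest. Every
   treatment event and rest is 300 s, so the two days give exactly
   4,320 s (72 min) of recorded EEG.
2. **Preprocessing.** A linear-phase FIR bandpass (0.5–50 Hz, Hamming
   taper, default order 4142) applied with exact group-delay
   compensation, followed by a 16-component FastICA in which at most
   two blink-like components are zeroed before reconstruction.
3. **Segmentation and spectra.** Each 5-minute event is cut into
   non-overlapping 2-s windows (150 per event). Per window and channel
   a Hamming-tapered periodogram is evaluated on the window's DFT grid
   (0.5 Hz spacing) restricted to 1–50 Hz, with the plain `1/Q`
   amplitude normalization (a deliberate statistic convention, not a
   density convention — all downstream comparisons are internal to it).
4. **Scores.** The per-segment score is the frequency-weighted power
   averaged over channels, `S_n = (1/M) Σ_m Σ_f f · p[n,m,f]`
   (units Hz·µV²); the per-channel topography score swaps the averaging,
   `S_m = (1/N) Σ_n Σ_f f · p[n,m,f]`. Restricting the frequency sum
   to delta (1–4 Hz), theta (4–8), alpha (8–13), beta (13–30) or gamma
   (30–50) gives band scores; bands are half-open `[lo, hi)` with the
   50 Hz ceiling closed, so the five bands partition 1–50 Hz and band
   scores add exactly to the full-range score.
5. **Testing.** A Kolmogorov–Smirnov screen against a normal fitted to
   each event's scores motivates the nonparametric choice; the
   comparisons themselves are two-sided Mann–Whitney U-tests: one pooled
   MA_T vs VA_T test (all MA segments vs all VA segments) and eight
   pairwise MA-event vs VA-event tests. Decisions use `p ≥ 0.05` ⇒
   "no significant difference" (ns). No multiple-testing correction is
   applied, matching the published analysis; a Benjamini–Hochberg side
   output can be derived from the exported p-values if wanted.
6. **Aggregation.** Proportions of ns cells overall, per recording day
   and per sex; the count of subjects with all eight pairwise cells ns;
   and the band-vs-raw decision similarity
   `similarity = (AG + AL) / AN`, where AG counts subjects significant
   in both the band and the full range, AL counts subjects
   non-significant in both, and AN = 24.

## Statistical choices

- **U-test.** The published formulas for the test are schematic
  rank-sum expressions that do not reduce to the U statistic; the
  implementation follows the standard two-sample two-sided Mann–Whitney
  U-test, which is the test named in the analysis. Exact p-values are
  computed by full enumeration of all `C(n1+n2, n1)` group assignments
  (midranks handle ties) for pooled sizes up to 16; larger samples use
  the normal approximation with tie and continuity corrections. At the
  default 150 segments per event the approximation branch is always
  taken.
- **Segments as observations.** Segment scores within an event are
  treated as independent observations, as in the published analysis.
  For real EEG this is a simplification (neighbouring windows are
  correlated); the synthetic generator redraws oscillation parameters
  every window so its segments genuinely are independent, which is what
  makes the type-I calibration test meaningful.
- **KS screen.** The default mode fits the normal's mean and standard
  deviation from the same sample and takes the p-value from the
  Kolmogorov distribution, mirroring the published screening practice.
  This inflates p (the Lilliefors problem); `mode="lilliefors"` applies
  the corrected reference distribution for users who want the
  statistically proper screen.
- **Decision rule.** `ns ⇔ p ≥ 0.05`, evaluated on unrounded values.
  The packaged table transcriptions keep the published bold markup
  separately: two pairwise cells are bolded at 0.03/0.04 in print,
  contradicting the stated convention, and only the numeric rule
  reproduces the cross-checkable aggregates.
- **Component-removal cap.** The artifact-rejection budget is at most
  two of the sixteen independent components (configurable), reading the
  published "restricted to <2" as "at most 2" since blink removal
  demonstrably occurred.

## The synthetic session generator

The study's raw recordings are not deposited, so signal-level stages
are validated on simulated sessions with known ground truth.

- **Model.** Per frequency band, one sinusoid whose frequency (uniform
  inside the band, with a 1 Hz interior margin) and phase are redrawn
  every 2-s block, projected to the channels through a fixed random
  spatial gain vector (uniform 0.6–1.4 per channel), plus per-channel
  Gaussian background noise with a `1/f` spectral slope (default
  exponent 1, RMS 5 µV). The margin keeps a Hamming-windowed tone's
  energy ≥95% inside its nominal band; the shared spatial projection
  mimics volume conduction and keeps the latent source count below the
  channel count, without which no unmixing vector can isolate an
  artifact source (with fully independent per-channel sinusoids, blink
  recovery empirically plateaus at r ≈ 0.82 regardless of duration or
  amplitude).
- **Default amplitudes** (µV): delta 20, theta 12, alpha 10, beta 5,
  gamma 2 for every treatment event — a deliberate *null*
  configuration, since no effect sizes are published; rest/fixation
  blocks use a slightly alpha-heavier profile. Effect configurations
  scale one band in the MA events only
  (`contrast_band_powers("alpha", 3.0)`). These are free parameters of
  the simulation, not estimates of the study's effects.
- **Blinks.** Raised-cosine pulses, 300 ms, default peak 100 µV, at
  Poisson onsets (default 12/min), projected frontally (Fp1/Fp2 weight
  1.0, F3/F4/F7/F8 0.5, others 0.05). Ground-truth onsets are returned
  for testing.
- **What it does not emulate:** no biophysical head model, no needle-
  response dynamics, no non-stationarity beyond the block redraws, no
  channel cross-talk beyond the shared band projections, no muscle or
  line-noise artifacts. Passing calibration tests therefore shows the
  statistical machinery is correct under the stated model, not that the
  pipeline is robust to every real-world artifact.

## Preprocessing details

- **Filter.** `scipy.signal.firwin` Hamming design, odd tap count,
  applied by centered convolution (zero net phase). The configured
  order (default 4142, matching the published high-order design) is
  honored whenever the recording is longer than the filter; shorter
  recordings fall back to an order derived from a 0.25 Hz transition
  band at the low edge via the Hamming rule (order ≈ 3.3·rate/0.25),
  and recordings shorter than even that are rejected with advice to pad
  or shorten the filter.
- **ICA.** scikit-learn FastICA, deterministic in the seed, with a
  fixed iteration budget; sign/permutation indeterminacy is
  canonicalized (dominant mixing entry positive, components ordered by
  explained variance) so decompositions are reproducible. Rank-deficient
  input and sample counts below `n_components²` are rejected.
- **Blink score.** frontal dominance of the mixing column (share of
  absolute weight on Fp1/Fp2/F3/F4/F7/F8) × fraction of source power
  below 4 Hz × a burstiness factor `k/(k+3)` from the source's excess
  kurtosis. On synthetic sessions blink components score ≈ 0.6 and the
  largest null-session score stays ≤ 0.08 over 20 seeds, so the
  flagging threshold is fixed at 0.2 (midway on the log-gap). The
  published study selected components manually; this automated criterion
  is pluggable.

## Numerical and calibration choices

- **Frequency grid:** DFT bins of the 2-s window (0.5 Hz spacing at any
  rate); the 1–50 Hz range is read as a range, not an integer grid, so
  no interpolation is needed.
- **Problem sizes.** The type-I and power studies run 200 replicates
  each of a six-event subject at 150 segments per event with 4-channel
  sessions: the compared statistic is the channel-averaged `S_n`, whose
  null distribution does not depend on the channel count, and 4
  channels keep the simulation light. Measured null rejection rate:
  13/200 with the 99% binomial band [3, 19]; the 3× alpha contrast is
  detected in 200/200 replicates.
- **EDF I/O.** Recordings interchange as EDF+ (16-bit, 1-s records,
  annotations channel); a minimal writer is built in and reading goes
  through MNE. 16-bit quantization bounds round-trip fidelity at about
  1.5 × 10⁻⁵ of the physical range per channel; CSV round-trips
  exactly and is preferred for human-readable fixtures.
- **Seed fan-out.** A single pipeline seed is hashed (BLAKE2) with the
  stage name and subject ID into per-stage sub-seeds below 2³¹, so
  cohorts are reproducible and extensible without seed collisions.

## Known limitations and discrepancies in the published tables

The packaged transcriptions preserve the published tables verbatim,
including their internal inconsistencies; the reconciliation
(`vaeeg reproduce-tables`) recomputes every aggregate and labels the
known discrepancies:

- the "21/24 = 87.50% of subjects had >50% consistent events" claim is
  not recomputable from the pairwise table under any natural threshold
  (natural rules give 13, 17 or 20 subjects);
- the alpha/beta/gamma similarity footer values (70.83 / 54.17 / 62.50%)
  do not re-derive from the band table's own columns (recounts give
  66.67 / 58.33 / 66.67%); only the delta and theta rates (both 79.17%)
  are corroborated by the surrounding text and used as acceptance
  quantities;
- the day-1 proportion 57/96 is printed as 59.36% (it is 59.375%) and
  the male proportion 58/96 as 60.41% (it is 60.42% at 2 decimals);
  counts, not the misprinted percentages, are asserted;
- the band-wise table's raw column disagrees with the pairwise table's
  pooled column for several subjects (e.g. Sub07: 0.20 vs 0.02), so
  similarity is always computed within the band table itself.
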