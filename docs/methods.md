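# Methods

## Signal model and preprocessing

The unit of analysis is the *EM series*: the eye-movement velocity
between two successive stimulus appearances in a jumping-point
experiment. Velocity is obtained by two-point differentiation of the
horizontal position, implemented as the **forward** difference scaled
by the sampling rate, `v[i] = (x[i+1] − x[i]) · fs`. Forward rather
than central differencing is the literal two-point reading and keeps
the velocity causally aligned with the stimulus onset. Position units
are not mandated (normalised screen coordinates or degrees); velocity
inherits them per second, and since the entropy tolerance is
SD-relative, units cancel throughout.

A 3 s trial at 1000 Hz yields 3000 samples; the series is truncated to
the **first** `NEMr = 2048` samples after the onset sample (the nearest
sample at or after the scheduled onset time). Start-anchored truncation
is chosen because the phenomenon of interest — latency followed by the
saccade — occupies the first few hundred milliseconds; the discarded
tail is steady fixation. Timestamps are validated (strictly increasing,
spacing within half a sample period of `1000/fs`) but segmentation is
sample-index based. Stimulus intervals too short to supply `NEMr + 1`
position samples are skipped with a warning rather than aborting the
session, since isolated defective series are a normal feature of real
recordings.

## Approximate entropy

The regularity statistic is the classical ApEn estimator
`Φ_m(r) − Φ_{m+1}(r)` with these fixed conventions:

- **Natural logarithm.** The only base supported, matching the common
  R implementation of the estimator.
- **Self-matches included** in the template counts, so every
  `C_i^m(r) ≥ 1/(N−m+1)` and no logarithm of zero can occur.
- **Per-dimension normalisation.** `Φ_{m+1}` averages over the
  `N−m` template vectors that exist at dimension `m+1`, not over
  `N−m+1`.
- **Sample SD** (`ddof = 1`) converts the multiplier into the
  tolerance `r`, matching `sd()` of R.

A consequence of the differing normalisers worth knowing: ApEn can be
*slightly negative* for short, perfectly regular series where every
template matches only itself — e.g. the ramp `1..8` with `m = 2`,
`r = 0.5` gives exactly `log(6/7) ≈ −0.154`. The implementation and its
brute-force test oracle agree with the standard R implementation on
this point, so map cells are validated as finite, not as non-negative.

Defaults are `m = 2` (the customary choice for biological signals) and
`r = 0.2 × SD`; multipliers in 0.1–0.25 give statistically valid
estimates and are accepted. Two tolerance policies exist because "the
SD of the entire time series" is ambiguous once a series is segmented:
`per_segment` (default) derives `r` from each window's own SD, which is
what calling the entropy routine independently per segment produces;
`global` uses the SD of the full 2048-sample series for every window.
A zero-SD (constant) window is defined to have ApEn 0 — a constant
signal is maximally regular — and is flagged degenerate rather than
raising, so pathological trials degrade gracefully.

## The Multilevel Entropy Map

Level *l* of the dyadic grid covers the series with contiguous,
non-overlapping windows of `Nss · 2^(l−1)` samples; the default
`NEMr = 2048`, `Nss = 64`, `L = 6` gives 32, 16, 8, 4, 2, 1 segments
per level (63 cells). `Nss = 64` is the finest window that keeps the
estimator's recommended minimum series length (~75 samples) roughly in
reach while maximising temporal resolution under the powers-of-two
rule. Levels and segments are 1-based everywhere, including serialized
JSON/CSV, so `MEM(l, s)` in code matches `MEM(l, s)` in reports.

Averaging across maps is a cellwise arithmetic mean with a cellwise SD
companion (sample SD by default). Degenerate cells contribute their 0
value by default — no exclusion rule is assumed — with an opt-in
`exclude_degenerate` for sensitivity analysis. Rendering colours cells
by eight fixed entropy bands (`< 0.4` green up to `≥ 1` red); the band
intervals are uniformly left-closed/right-open.

## Features, classes and the knn protocol

A feature set `setX_Y_Z` with finest size `X` produces `NEMr / X`
elements per map. Element *i* carries class label *i* (its time window,
reported with its sample range, e.g. `129-256`) and the feature vector
`[MEM(level(S), ceil(i·X/S)) for S in sizes]` — each coarser component
is the ancestor window containing element *i*. With the default grid
this yields 32 classes for sets with finest size 64, 16 for 128, 8 for
256 and 4 for 512.

Cross-validation leaves one participant-session out: all elements from
one session's maps form the test fold, one fold per session. Because
every complete map contributes one element per class, folds are
class-balanced by construction, and the fold-averaged per-class
accuracy equals pooled per-class accuracy.

knn uses Euclidean distance on the raw entropy features (they share a
scale, so no normalisation) and is implemented directly rather than via
a library classifier because full determinism is part of the contract:
equidistant neighbours are taken in training-row order (stable sort),
vote ties go to the class with the smaller summed neighbour distance,
then to the lower class index. The implementation is cross-checked in
the tests against both a brute-force enumeration and scikit-learn in
tie-free settings.

Segment-level statistics use one-way ANOVA across segment positions
(observations = per-map cell values) followed by all-pairs Tukey HSD at
a 95% family-wise confidence level, via scipy; the tests cross-check
the Tukey table against statsmodels.

## The synthetic generator

`SynthConfig` emulates the jumping-point paradigm the method targets,
and its defaults are the study conditions: 24 participants × 2 sessions
× 29 stimulus positions, 3 s trials at 1000 Hz. Per trial the gaze
holds at the previous target through a saccadic latency drawn from
U[100, 250] ms, then moves to the new target with a raised-cosine
velocity pulse of duration U[30, 80] ms whose discrete integral equals
the target step exactly, then fixates. Remaining defaults are the
package's own choices of realistic magnitudes: target steps of
U[0.15, 0.4] normalised screen units (large enough that peak saccade
velocity clears the velocity-noise floor by several standard
deviations); fixational white position noise of SD 5·10⁻⁴ units
(≈0.01–0.03° on a typical screen, a quiet research-grade tracker);
a per-sample random-walk drift of SD 2·10⁻⁵ units resetting each
trial; per-participant latency-mean offsets of SD 10 ms (clipped at
3 SD) to model idiosyncratic reaction speed; microsaccades available
(small raised-cosine pulses at a Poisson rate) but off by default.
A raised cosine is used instead of a physiological main-sequence model
because only segment-level distinguishability matters to the method,
not oculomotor realism.

What the generator does **not** emulate — and hence what passing tests
cannot certify about real data: corrective/overshoot saccades, blinks
and tracker dropouts, tremor's spectral structure, coloured measurement
noise, amplitude-dependent saccade durations, and vertical movement.
Results on synthetic cohorts demonstrate that the pipeline recovers the
saccade-bearing window when one exists; they do not predict absolute
accuracy on human recordings.

## Numerical choices and problem sizes

- The ApEn kernel precomputes the `|u_i − u_j|` matrix once and forms
  Chebyshev distances by shifted maxima, `O(N²m)` time and `O(N²)`
  memory (32 MB at `N = 2048`); it is validated against a pure-Python
  double-loop oracle to 1e-12.
- Affine invariance (`ApEn(a·u + b) = ApEn(u)` for `a > 0` under
  SD-relative `r`) is exact in real arithmetic and asserted to 1e-9 to
  absorb borderline match flips in floating point.
- Validation cohorts use 5 participants × 2 sessions × 10 stimulus
  positions (100 maps), a size at which the saccade-window detection
  pattern is already unambiguous: per-segment accuracy 0.71 for the
  saccade-bearing window vs ≈0.08 for fixation-only windows
  (set128_256_512, k = 31).
- CSV round-trips write floats as `%.17g` and parse with pandas'
  round-trip parser, so simulated recordings survive text serialization
  bit-exactly.

## Limitations

- The finest reliable localisation is one MEM window (64 ms) and in
  practice the useful sets work at 128 ms — wider than a saccade
  (30–80 ms), so this localises the saccadic *period*, not its onset.
- ApEn on 64-sample windows sits below the estimator's recommended
  series length; level-1 cells are noisier than coarser levels and the
  tolerance-policy ambiguity matters most there.
- LOSO folds treat sessions as exchangeable; the simulator's
  idiosyncrasy model (a latency offset) is far simpler than real
  between-subject variability.
- Only the horizontal channel is analysed.
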