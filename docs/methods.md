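# Methods

This note documents the models, estimators and design choices behind
fhrkit, in the spirit of the methods documentation that accompanies
statistical packages: what is computed, under which assumptions, with
which defaults, and what the synthetic-data tests do and do not show.

## Signal model and preprocessing

A record is a uniformly sampled fetal heart rate (FHR) trace in beats per
minute, nominally at 4 Hz as produced by Doppler cardiotocography.
Missing samples are encoded as 0 bpm. The analysis segment is fixed at
20 minutes (4800 samples), the standard length for continuous CTG
assessment.

Artifact removal proceeds in a fixed order:

1. **Stable start.** The first window of 5 adjacent samples whose range is
   at most 10 bpm, containing no missing samples and lying strictly inside
   (50, 200) bpm, anchors the analysis. Everything before it is discarded.
2. **Gap excision.** Zero-runs lasting at least 10 s are deleted outright
   and the trace concatenated across the gap (interpolating across a
   multi-second dropout would fabricate signal). Shorter zero-runs are
   left to the spike rule.
3. **Spike removal.** Samples ≤ 50 or ≥ 200 bpm (bounds inclusive) are
   replaced by linear interpolation between the nearest valid neighbors;
   boundary spikes extend the nearest valid value.
4. **Jump repair.** Scanning left to right, a sample differing by more
   than 25 bpm (strictly) from the last *accepted* value is replaced by a
   natural cubic spline through the four nearest stable neighbors on each
   side. Comparing against the last accepted value rather than the raw
   predecessor stops a single outlier from cascading into rejecting the
   rest of the trace.

Steps 3–4 iterate to a fixed point (at most 10 rounds) so the output
contracts hold unconditionally: values strictly inside (50, 200) bpm,
adjacent steps ≤ 25 bpm, and idempotence of the whole pass. The first
4800 clean samples are kept; a record with fewer clean samples is
rejected rather than padded.

## Morphological analysis

**Baseline.** The baseline is the resting FHR level with transient
episodes excluded. The estimator is an iteratively trimmed moving
average:

* seed: a rolling median over 3× the averaging window (default 720 s),
  edge-padded with the global median, so that even prolonged
  decelerations are a minority of every window;
* trim: samples deviating more than 10 bpm from the current estimate are
  excluded; exclusion gaps shorter than 15 s (the episode time scale) are
  closed, so noise dips inside an event stay excluded;
* average: a 240-s centered moving mean over retained samples, with
  shrinking windows at the edges; windows retaining under 25 % of their
  width (the interior of long excluded events) are bridged by linear
  interpolation; three passes suffice for convergence.

The 240-s window is long enough that 15-s events cannot register as
baseline shifts and short enough to track clinical drift. Mean baseline
categories follow FIGO bands: reassuring 110–160 bpm, non-reassuring
100–109 or 161–180 bpm, abnormal otherwise.

On noise-free constructions the estimate is within 2 bpm of truth
everywhere; on noisy synthetic records the mean absolute error is
≈ 0.4 bpm with a pointwise tail up to ≈ 3 bpm caused by variability
leaking through the averaging window and by linear bridging across long
decelerations — not by estimator bias.

**Episodes.** An acceleration is signal ≥ baseline + 15 bpm sustained
≥ 15 s; a deceleration is signal < baseline − 15 bpm (strict) for ≥ 15 s,
classed by duration as mild (< 120 s), prolonged (120–300 s, inclusive)
or severe (> 300 s). Detection thresholds the deviation smoothed over
5 s (episodes are 15-s-scale patterns; sample-scale noise should not
fragment them), merges supra-threshold runs separated by < 10 s, and then
extends each qualified run to baseline return (raw deviation > 2 bpm):
clinically an episode ends when the trace returns to the baseline, not
when it re-crosses the 15-bpm qualification offset. Without the
extension rule, realistic 1/f variability regularly splits a single
20-bpm deceleration into fragments. Indices are 0-based, intervals
half-open.

## Time-domain features

The FHR trace converts sample-wise to an epoch-level RR series
RR = 60000/FHR (ms); Doppler CTG has no true beat-to-beat intervals, so
all HRV measures are epoch-level surrogates. Population (ddof = 0)
standard deviations are used throughout. Defaults: NNx/pNNx threshold
x = 50 ms (the adult convention; configurable), SDANN/SDNNi segments
5 min (4 per record), STV/II/LTI epochs 2.5 s following the
Arduini/de Haan family of fetal variability indices, histogram bin
width 7.8125 ms (1/128 s) for the triangular index and TINN. TINN is the
base width of the least-squares triangular fit to the RR histogram,
searched exhaustively over bin-edge pairs around the modal bin.

## Frequency-domain features

Fetal spectral bands: VLF 0–0.03, LF 0.03–0.15, MF 0.15–0.50,
HF 0.50–1.00 Hz, half-open and contiguous, so trapezoidal band powers sum
exactly to the total; Ratio_Band = LF/(MF+HF) indexes sympathovagal
balance (capped at 1e6 with a flag when MF+HF vanishes). The RR series
inherits the uniform 4-Hz grid, so no resampling stage is needed. Three
PSD backends over the detrended series: Welch (1024-sample Hamming
segments, 50 % overlap), Burg autoregressive order 16 evaluated on a
1024-point grid (coefficients via the standard Burg recursion), and
Lomb–Scargle at the sample timestamps on the same grid, scaled to
one-sided density units. PSDs are computed on RR in ms² (the HRV scale),
not on bpm.

## Nonlinear features

* **Higuchi fractal dimension** (kmax = 32): curve-length scaling over
  subsampled lags with the standard (N−1)/(⌊(N−m)/k⌋·k²) normalization;
  −slope of log⟨L(k)⟩ vs log k, clipped to [1, 2]. Calibration: 1.00 for
  a line, 2.0 ± 0.1 for white noise at n = 4800.
* **ApEn / SampEn** (m = 2, r = 0.15 × population sd, Euclidean metric by
  default with Chebyshev available): template matching via k-d trees;
  ApEn includes self-matches, SampEn excludes them over the common
  N − m template set and returns the ln(B) upper bound when no
  (m+1)-match exists. Both agree exactly with exhaustive O(N²)
  pair-counting oracles on small inputs. Self-matches bias ApEn *below*
  SampEn on irregular data.
* **Lempel-Ziv complexity**: successive differences ternary-encoded
  (equal → 2, rise → 1, fall → 0), parsed by the 1976 sequential scheme
  (an unfinished terminal phrase counts), normalized
  C(n) = c(n)·log2(n)/n. With the log2 normalization the i.i.d. uniform
  ternary limit is log2(3) ≈ 1.585, and FHR-typical values near 1.1 are
  expected.
* **Hurst exponent**: rescaled-range analysis over dyadic windows from 32
  to N/2 with the Anis–Lloyd–Peters finite-sample correction. Short
  windows carry the largest R/S transient bias for persistent signals,
  hence the 32-sample floor; plain 16..N/4 windows under-recover H = 0.8
  by ≈ 0.08 on exact fractional Gaussian noise. Even corrected, R/S
  recovers H = 0.8 as ≈ 0.75 ± 0.03 at n = 4800 — calibration is
  therefore assessed as parameter recovery averaged over a few seeded
  replicates.
* **DFA** (order 1): scales 4–64 (alpha), 4–16 (alpha1), 16–64 (alpha2);
  0.5 white noise, ≈ 1.0 1/f noise, 1.5 random walk. The single exported
  "alpha" feature is the 4–64 fit.
* **PRSA** (T = 1, L = 10): increase/decrease anchors, [−L, L) window
  averaging, quartet capacities (P(0)+P(1)−P(−1)−P(−2))/4 and
  least-squares slopes over τ ∈ [−2, 2].
* **Poincaré SD1/SD2**: SD1 is the RMS (not mean-subtracted sd) of
  successive differences /√2 — successive RR differences scatter around
  zero, and only this form satisfies SD1 = RMSSD/√2 exactly; SD2 is the
  population sd of successive sums /√2.

## Feature table, normalization, selection

The canonical vector concatenates 8 morphological + 17 time-domain +
10 frequency-domain + 12 nonlinear = 47 features in fixed order; guarded
degenerate cases produce finite values with warning flags, never NaN.

Gestational age shifts many HRV parameters, so each feature can be
regressed on GA (ordinary least squares) and replaced by residual +
training grand mean. Normalization (GA or min-max) is fitted on training
rows only and applied to held-out rows — the global-fit variant is
available as "paper mode" for protocol comparison, but leaks test
information and is not the default.

Selection: per-feature two-sided Mann–Whitney U (exact enumeration for
≤ 20 per class without ties, tie-corrected normal approximation
otherwise; no multiplicity correction by default, Benjamini–Hochberg
behind a flag), per-feature ROC AUC oriented as max(A, 1−A) with default
threshold 0.71 or top-k, and PCA on z-scored features retaining the
smallest leading set reaching 95 % explained variance. AUC equals
U/(n₁n₂) from the same U statistic — the identity is covered by a test
against an independent ROC implementation.

## Classification and evaluation

Labels follow the umbilical-artery pH rule: pathological iff pH < 7.15.
The positive class is *normal*. Stratified k-fold (default 10) with a
fixed seed; per fold, normalization and selection are refitted on the
training rows. Classifier defaults: entropy-split decision tree with
cost-complexity pruning (ccp_alpha 0.005); RBF-kernel SVM, C = 1,
gamma = "scale", balanced class weights; AdaBoost with 100 depth-1 trees
(SAMME weighting). The metric suite is Acc, Se, Sp, Precision, F-measure,
BER, QI = √(Se·Sp) and MCC, with every 0/0 guarded to 0 plus a flag.
The default BER places its numerators as (FP/(FN+TP) + FN/(FP+TN))/2;
the conventional swapped-numerator form is available via
`ber_standard=True`.

## Synthetic data

`generate_record` builds: baseline (constant + one slow sinusoidal drift
cycle, default 140 ± 5 bpm), variability as a 1/f colored-noise process of
sd 10 ms synthesized in the RR domain and mapped through RR = 60000/FHR
(band-limited to periods < 3 min — slower wander is indistinguishable
from baseline drift, which the generator models explicitly), episodes as
±20 bpm plateaus with 10-s raised-cosine ramps (accelerations 20–45 s;
decelerations 30–90 s mild, 150–260 s prolonged, 330–400 s severe —
plateau ranges keep baseline-return durations inside their class bounds),
single-sample spikes outside [50, 200] bpm at a Poisson rate, and
configurable zero-run dropouts. Records are 25 min so that 20 clean
minutes survive cleaning. The exact injected ground truth is returned.

`generate_cohort` synthesizes a labeled *feature matrix* directly:
class-conditional independent Gaussians anchored to empirical feature
statistics from a small bank of simulated records (12, with jittered
generator parameters), a linear GA trend injected on all features
(0.1 sd/week over GA 37–43), pH drawn per class around the 7.15 rule,
and a configurable class effect (in sd units) applied to nine designated
discriminative features with clinically plausible signs (pathological:
higher baseline, shorter RR, lower short-term variability, lower fractal
dimension and complexity). Selection-calibration and cross-validation
checks are statistical properties of the feature matrix and need hundreds
of replicates, which signal-level synthesis cannot afford;
`generate_cohort_records` provides true signal-level cohorts at small n
for end-to-end runs.

**What the synthetic tests do not show.** Feature draws are independent
Gaussians: real HRV features are heavily correlated and non-Gaussian, so
classifier accuracies on synthetic cohorts say nothing about clinical
discriminability — they validate the harness (fold composition,
leakage-free normalization, metric arithmetic), not the medicine. The
record generator has no uterine-contraction coupling, no maternal heart
rate confusion, and episode shapes are stylized plateaus.

## Numerical conventions

Population sd wherever a tolerance or variability index is derived;
0-based half-open index intervals; all estimators deterministic given
input and configuration; degenerate inputs (constant series, zero power,
empty denominators) return defined values with warning flags rather than
NaN. Problem sizes in tests and in the acceptance script (4800-sample
records, 100–200 selection replicates, a single 552-row cohort) were
chosen to make every stochastic check stable at fixed seeds.

## Known limitations

WFDB input is not supported in this build; CSV (time_s, fhr_bpm) plus a
JSON metadata sidecar is the interchange format. R/S Hurst retains a
small negative bias for strongly persistent signals even after
correction. TINN's exhaustive triangular fit assumes a unimodal RR
histogram. The paper-mode (global) normalization exists only for
protocol comparison.
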