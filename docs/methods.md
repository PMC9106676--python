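# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `cuffbp`.

## Estimation models

**PAT-log.** `SBP = a + b ln(PAT)`, fitted by ordinary least squares on
per-beat (PAT, SBP) pairs from the calibration segments. PAT is the delay
from the ECG R-peak to the first crossing of 50% of the PPG foot-to-peak
amplitude within the beat interval `[t_rpeak, next t_rpeak)`. The foot is
the PPG minimum preceding the pulse peak in that window. The 64-Hz PPG is
upsampled to 256 Hz (cubic spline by default; configurable) and the
crossing is refined by linear interpolation between grid points, so the
PAT resolution is well below 1/256 s on clean signals. A fit with constant
PAT is singular and raises; nonpositive PAT at prediction time yields a
missing estimate.

**Direct ANN.** Per-beat inputs are the 19-sample (0.3 s at 64 Hz) ECG and
z-normalized PPG windows ending at the beat's R-peak (input width 38).
Members are scikit-learn `MLPRegressor`s: one hidden tanh layer of 19
units, L-BFGS, L2 penalty 1e-4, targets z-scaled internally. Five members
are bootstrap-ensembled (resampling rows with replacement); the prediction
is the member mean. With 19 hidden units the member has 761 weights, the
same few-hundred-parameter scale as the NARX member below; the hidden size
is configurable.

**NARX.** Same member architecture with input width 40: the two 19-sample
exogenous windows plus BP at steps k-1 and k-2 (799 weights at H=19).
Training is series-parallel (teacher forcing with measured BP) on the
per-sample regression frame of the calibration segments; deployment is
parallel (free-run), feeding back the ensemble-mean output. The free-run
recursion is a chunked numpy forward pass over the stored member weights;
with measured feedback substituted it reproduces teacher-forced
predictions exactly (tested), and it aborts with a diagnostic if the
output leaves ±350 mmHg. Free-run is initialized from the first two
reference BP samples of the segment when available, else the training-mean
BP.

The training-iteration cap (60 L-BFGS iterations per NARX member, 200 for
the direct ANN) is a deliberate regularizer: tighter one-step fits lean
harder on the BP feedback terms and degrade free-run (parallel-mode)
tracking — the familiar series-parallel/parallel generalization gap. The
exact optimizer budget is configuration-visible, not a tuned constant.

Per-beat errors for the NARX are computed from free-run estimates on the
calibration segments themselves (not teacher-forced ones), so the PI model
learns the error distribution of the deployment mode.

## Prediction-interval model

One `OneClassSVM` (RBF kernel, ν = 0.5) per (model, target, input
configuration), trained on standardized per-beat features: the last
`19n` samples (τ = 0.3n s, n = 1..5) of ECG and z-PPG ending at the
R-peak, optionally followed by the estimated BP — the estimated waveform
segment of the same length for the NARX, the scalar estimate for ANN and
PAT-log. The kernel bandwidth uses the median-pairwise-distance heuristic
(γ = 1/(2 d_med²), distances on ≤2000 subsampled rows).

Fixing ν = 0.5 while asking for outlier fractions 0–99% is contradictory
under the standard ν-parameterization, so the 100 hyperplanes are realized
as empirical percentiles of the training decision scores: the X% threshold
is the ⌈Xn/100⌉-th order statistic, which makes the regions nested by
construction and the outlier fractions exact up to ties. A point's *depth*
is the largest X whose hyperplane still encloses it; depth is the cluster
label. Cluster i ≤ 90 spans depths [i, i+9]; clusters 91–99 are "inside
the i% hyperplane"; scores below the 0% threshold form the outlier
cluster, which carries no PI because no training point lies there. Each
non-outlier cluster's PI is the sample SD (n−1) of the signed training
errors of its members; empty bands are interpolated from neighbours with
a warning. The overlapping bands make single-cluster assignment ambiguous
in principle; assigning label = depth and reading the band starting at
that depth matches the "percentage of outliers (lower bound)" convention
and is the choice made here.

**MeRCI.** λᵢ = |errᵢ|/σᵢ; the score is the α-th percentile of {λᵢ}
(linear interpolation between order statistics) times the mean σ, α = 99.7
by default. Outlier-cluster beats are excluded before scoring. For a
perfectly calibrated Gaussian PI the score divided by the mean PI tends to
3 (two-sided 3-SD coverage); this limit is recomputed by
`scripts/acceptance.py` and asserted at ±0.15 over 100,000 draws.
Candidate input configurations (five τ values × with/without BP) are
ranked by held-out MeRCI, ascending, ties in declaration order.

## Fusion

Covariance intersection on scalars with P = PI² (PI is an error SD; the
mapping P = PI is selectable). Exact minimization of P_c over the weight
simplex is degenerate for scalars — it puts all weight on the
minimum-variance input — so the default strategy is inverse-variance
weighting (ω ∝ 1/P), which blends models; the degenerate `min_pc` vertex
solution is implemented and cross-checked against a 1e-4 grid search in
tests. Per beat, models in the outlier cluster are excluded; if every
model is an outlier the fused value falls back to the unweighted mean with
a flag and no PI. The fused PI is √P_c. Beat series produced by the
pipeline are inherently aligned; the standalone aligner matches R-peak
times nearest-neighbour within 50 ms.

## Synthetic-data generator

The generator emulates the layout of an ambulatory monitoring study: a
6.5-h session (configurable) at 64 Hz with 15-min calibration segments at
the start and end, and sitting/standing/walking blocks in between.

- **Beat times**: heart rate wanders (OU process, ~2-min time constant)
  inside 60–100 bpm; R-peak times are snapped to the sample grid.
- **BP**: per-beat SBP is a mean-reverting (OU) walk around 120 mmHg with
  stationary SD 10 mmHg and 60-s time constant — ±30 mmHg daily range at
  3 SD — plus offsets for standing (+3) and walking (+8) and, inside the
  calibration segments, a commanded ±15 mmHg slow sinusoidal sweep
  emulating the high-variability training procedure. DBP follows 0.6× the
  SBP deviation plus its own small OU term, floored 15 mmHg below SBP.
- **Coupling**: true PAT inverts `SBP = 35 − 60 ln PAT` (PAT ≈ 0.25 s at
  120 mmHg), clipped to [0.08, 0.47] s, plus Gaussian timing jitter of
  10 ms × the activity artifact multiplier (sitting 1, standing 1.5,
  walking 5). The PAT-log model is therefore exactly identifiable on
  noiseless data (parameter-recovery tests) and misspecified only through
  injected noise; the ANN/NARX must learn the same relation from the
  waveforms.
- **Waveforms**: the ECG is a Gaussian R-wave (σ = 20 ms, peak exactly on
  the beat sample) plus a small T-wave; the PPG is a raised-cosine
  upstroke whose 50% crossing sits exactly at `t_rpeak + PAT`, decaying
  smoothly to the next foot, with ±10% per-beat amplitude variation; the
  BP channel is shaped so its per-beat max/min equal the ground-truth
  SBP/DBP exactly. Additive white noise (SD 0.02 a.u. × activity
  multiplier) is applied to ECG/PPG, plus band-limited (0.5–5 Hz) motion
  artifact on the PPG and baseline wander on the ECG during movement. The
  reference BP channel is left clean (it plays the role of the ground-
  truth device).

What this does *not* emulate: real pulse morphology (dicrotic notch,
reflected waves), pre-ejection-period variability that decouples PAT from
transit time, sensor-specific artifacts, missing data, or inter-subject
variability. Passing tests therefore demonstrate the method's internal
consistency and its behavior under controlled heteroscedastic noise, not
clinical accuracy on recorded data.

## Problem sizes and numerical choices

The benchmark used by the heavier end-to-end checks is a 4.5-h session
(~20,000 beats, 15-min calibration segments, fixed seed); unit tests use
minutes-long sessions. On this benchmark walking error SD is roughly 3–4×
the sitting SD for every model, which is what makes the σ_T filter and the
PI-weighted fusion measurably effective.

- Sample (n−1) SDs everywhere; 0-based sample indexing with
  `t = t0 + k/fs`; beat intervals half-open.
- z-normalization statistics always come from the training segments and
  are applied unchanged to test data (no leakage; verified by a
  test-span-splice test).
- ΔP binning uses the reference test-set mean as the common centre
  (configurable), bins [5m, 5(m+1)) for m ∈ −6..6 (SBP) or −4..4 (DBP).
- Standards flags default to |μ_Err| ≤ 5, σ_Err ≤ 8, MAE ≤ 6 mmHg; the
  8 mmHg error-SD value is the anchored limit, the others are
  conventional defaults and configurable.
- The R-peak detector is a simple adaptive-threshold local-maximum
  detector with a 0.3-s refractory period (recorded-device studies would
  use device-provided peaks); it is swappable.

## Known limitations

- The NARX free-run is fragile on long horizons: one-step training does
  not control accumulated feedback error, so its waveform can drift or
  oscillate. The PI model prices this honestly (large clusters' σ_Err),
  and fusion down-weights it; still, single-model NARX accuracy is the
  weakest of the three on the synthetic benchmark.
- Scalar covariance intersection with exact P_c minimization is
  degenerate; the inverse-variance default is a pragmatic, documented
  choice rather than the unique optimum.
- OCSVM training is O(n²) in calibration beats; kernel approximation
  would be needed far beyond the ~2,000-beat calibration scale used here.
- Population-level (cross-subject) models are out of scope; all models
  are subject-specific.
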