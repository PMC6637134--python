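# Methods

This note documents the models, parameter choices and numerical
decisions behind `vistrack`, and what the synthetic fixtures do and do
not establish about real recordings.

## Tracking model

The animal is assumed to be the only moving object against a static
background imaged by a fixed camera. Foreground extraction thresholds
the absolute background difference (default 15 grey levels on 8-bit
images) and applies a morphological opening with a 3 px disc; the
opening removes any connected structure smaller than the disc, which in
practice means droppings and sensor speckle, at the cost of eroding
~1 px of body outline. An empty foreground is carried as a flagged
missing value, never an exception, because stimulus hardware can
occasionally blank a frame.

Landmarks are Harris corners (k = 0.04, per-level relative threshold
0.01, 3×3 non-maximum suppression) detected on a 6-level pyramid built
by 13-tap Gaussian smoothing (σ = 1.25) and resampling by 1.25 per
level. Detecting on the pyramid multiplies the landmark yield: coarse
levels respond to ear- and haunch-scale structure that the base level
misses. Level-l coordinates are mapped to base pixels by the realised
(not nominal) cumulative resize factor, and detections within 1 base px
of a stronger detection at another level are merged, so one physical
corner enters the speed distribution once. The region analysed is the
foreground bounding box extended by 16 px of real image context
(edge-replicated at frame borders) before detection; responses are
cropped back to the box before thresholding. Without that context the
detector's internal zero-padding both creates spurious border maxima and
couples the relative threshold to the mean image intensity — detection
counts are intensity-offset invariant only because of this cropping.
When a foreground mask is supplied, detections outside the mask dilated
by 2 px are discarded, which keeps background-texture corners out of
the speed distribution.

Matching maximises the Pearson correlation of 11×11 intensity patches
between landmarks within a 30 px search radius, accepted greedily in
decreasing correlation (ties broken by smaller displacement), giving a
one-to-one assignment; pairs under r = 0.5 are dropped. The search
radius bounds plausible inter-frame motion at 15 Hz; all three values
are engineering defaults exposed in the configuration, not measured
constants.

## Clustered rigid motion and MDL selection

Between two frames the body is modelled as K rigid pieces. Landmark
coordinates (previous frame only — spatial position, not displacement,
is what delineates a body part) are clustered by seeded k-means++ with
10 restarts; each cluster gets a rotation+translation fitted by RANSAC
(2-point minimal samples — the minimum that determines a 2-D rigid
transform — 200 iterations, inlier threshold 10 px, least-squares refit
on the consensus set). With ≤ 50% outliers, 200 iterations give a
>99.9% chance of sampling at least one clean pair. The k-means is a
small vectorised implementation rather than a library call because the
selection loop runs it ~50 times per frame pair on a few dozen points,
where per-call overhead dominates; a unit test checks it against
scikit-learn's objective on the same data.

K = 1…5 is selected by minimum description length, in nats:

    L_which_model = N·log2(K+1)/ln 2          — cluster/outlier labels
    L_outlier     = N_outlier·log2(Nx·Ny)/ln 2 — outliers as free positions
                                                 in the animal's bounding box
    L_model       = 3/(2 ln 2)·log2(∏ N_i)     — 3 parameters per transform
    L_residuals   = Σ_i N_i/2[ln 2πσ²_x + ln 2πσ²_y] + quadratic terms

with per-cluster, per-axis empirical means and maximum-likelihood SDs of
the signed residuals. The formula is evaluated exactly as written,
including the redundant log2(·)/ln 2 conversions. Two choices the
criterion leaves open: the residual mean is taken empirically (a
`mu_zero` switch fixes it at zero; the difference is a fraction of a nat
per cluster), and per-cluster RANSAC outliers are pooled into the single
outlier term. σ is floored at 0.1 px purely so noise-free synthetic
input cannot send ln(2πσ²) to −∞; real residuals never reach the floor.
Ties in DL break toward smaller K.

## Speed quantiles

Per-frame landmark speeds (Euclidean displacement, px/frame) are reduced
to the 0.10/0.30/0.50/0.70/0.90 quantiles by linear interpolation of
order statistics — the estimator is fixed so results are bit-stable.
Channels from two cameras are averaged for speed statistics and kept
separate for segmentation. Frames without matches are bridged by the
previous valid value, because the segmentation cost requires a complete
series; such frames are rare and logged. The truncated log transform
v → ln(max(v, 0.5 px/frame)) is applied for freeze-type analyses: raw
speed distributions are right-skewed, which biases mean-shift detection
toward movement increases; the log compresses the upper tail so
decreases stand out. The floor (half a pixel per frame) is the smallest
displacement the tracker can meaningfully resolve.

## Changepoint detection

The segmentation objective is the within-segment sum of squared
deviations from the segment mean plus β per changepoint. PELT computes
the exact global optimum; pruning with constant 0 is valid because the
cost is subadditive under splitting. Segment costs come from prefix
sums of y and y² in O(1), clamped at 0 against cancellation; equality
comparisons use 1e-9 absolute tolerance. The minimum segment length
defaults to 1 — with a mean-only cost the penalty alone controls
overfitting. A changepoint is the last index of a segment (0-based);
since tracked speed is a backward difference, a response beginning at
the onset frame first affects the sample at onset+1 and therefore
produces a changepoint at the onset frame itself.

CROPS finds all optimal segmentations over [β_min, β_max]: whenever the
counts at two penalties differ by more than one, the interval is split
at the crossing point of the two penalised costs and solved there. The
collected segmentations' lower cost envelope then yields the exact
intervals of optimality; the envelope construction also guarantees the
reported m(β) is non-increasing. The default range is data-driven:
from 0.1× a robust (median-absolute-difference) noise-variance estimate
up to n·var(y), below which everything and above which nothing is
segmented.

The knee of m(β) is fitted with the two-line model
E[m] = aβ + b(β−ψ)₊ + c by Muggeo's iterative linearisation (regressors
β, (β−ψ̂)₊ and the −1{β>ψ̂} indicator whose coefficient, divided by the
slope difference, is the ψ update). Iteration stops at |Δψ| < 1e-6 or
when the SSE stops improving for three updates — the raw iteration can
oscillate between two near-optimal ψ values, in which case the best SSE
iterate is returned as converged. |b| ≈ 0 flags a kneeless (single
line) path as degenerate rather than an error. The (β, m) support for
the fit is m(β) evaluated through the path on a uniform 101-point grid:
sampling at the CROPS interval boundaries instead concentrates support
in the over-fitting arm (where optimal segmentations change fastest)
and drags the fitted knee toward β ≈ 0; on a three-segment demo series
the boundary-sampled knee kept 47 changepoints while the uniform-grid
knee kept 5. Per trial, the per-channel counts are summed on a common
grid before fitting; the study-level penalty is the median of per-trial
knees, robust to the occasional degenerate trial.

## Trial statistics

Windows are frame-aligned and half-open: pre = [onset−w, onset),
post = [onset, onset+w), with w rounded to whole frames (0.6 s at 15 Hz
is exactly 9 frames; the speed window of 0.53 s rounds to 8 frames).
Positive values always mean an increase after the stimulus (post −
pre); a `literal_sign` flag negates both statistics for compatibility
with conventions that report pre − post. Note the two statistics
dissociate on freezes: speed drops, but the transition itself adds
changepoints, so the changepoint rate typically *rises* for any
detected response regardless of its direction.

The sign test is the exact binomial two-sided test,
p = min(1, 2·min(P(X≤k), P(X≥k))), zeros dropped. The habituation
test's statistic is mean(early-repetition values) − mean(late); the
null shuffles repetition labels within each animal (equivalently,
permutes each animal's values), preserving per-animal trial counts, and
the one-sided p is the plain fraction of surrogates ≥ the observed
statistic.

## Synthetic data: what it emulates and what it does not

The rendered trials place a 2:1 ellipse (body length 8% of arena width)
carrying a fixed high-contrast speckle texture on a mildly textured
static background, with additive Gaussian pixel noise (SD 1 grey level)
in the body region. Behaviour scripts tile the trial into modes:
locomotion/flight translate the body (direction reflecting off walls),
`head_move` rocks the anterior 40% of the ellipse about the body centre
(exercising K > 1 motion models), freeze/still hold it fixed. Trials
default to the recording protocol geometry: 200 frames at 15 Hz with
stimulus onset at frame 90, in a 640×640 px arena (a scaled-down frame;
the mouse-to-arena ratio, and hence landmark count, is preserved).

What passing tests on these fixtures shows: the tracker recovers
scripted speeds to within half a pixel per frame, the segmentation
stack finds the scripted transitions, and the statistics have their
nominal size under exchangeable nulls. What they cannot show:
robustness to fur articulation, shadows, occlusion, reflections,
grooming (non-rigid motion at every landmark), multi-animal scenes, or
camera jitter — none of which the renderer produces. Parameters tuned
on fixtures (Harris threshold, correlation cut-off) should be revisited
on real video.

For the knee-recovery experiments the synthetic count-vs-penalty curves
use ψ = 5 with slopes a = −10, b = 9.5 over β ∈ [0.5, 12] and Gaussian
noise (SD 2) on the counts: real penalty paths fall by hundreds of
changepoints across the narrow under-fitting arm and by almost nothing
across the over-fitting arm, so the left slope is set an order of
magnitude steeper than the right. With a shallow slope pair (e.g.
a = −2, b = 1.9) the knee is statistically unidentifiable at that noise
level — an exhaustive SSE grid search misses it by ~0.5 on average — so
such data test the estimator's failure mode, not its accuracy.

## Problem sizes

The test suite and the acceptance script run at sizes chosen to
exercise each claim while staying desk-sized: 200 random series (n ≤
20) against exhaustive enumeration; 10–20 series of n = 50 against a
200-point penalty grid; 100 seeded repetitions for knee, RANSAC and MDL
recovery; 100–200 repetitions × 1000 permutations for test calibration;
and 14–26 rendered 200-frame trials for the end-to-end experiment.
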