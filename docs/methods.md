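# Methods

## The selection problem

Spatial ICA decomposes a resting-state fMRI run into `X = A S + E`: `A`
(N time points × K components) holds component time courses, `S`
(K × M in-brain voxels) holds spatial maps, `E` is additive Gaussian noise.
ICA returns components unordered and unlabelled: resting-state networks
(default-mode, visual, attention, sensorimotor, …) are mixed in with
scanner artifacts, motion residue and physiological noise. `rsnselect`
classifies the K components automatically using four cheap, interpretable
statistics instead of expert visual inspection.

The package consumes an existing decomposition (e.g. MELODIC output) plus
tissue-probability maps; it never estimates the decomposition or the
segmentation itself. Whether the spatial maps fed in are raw or
posterior-probability thresholded is the caller's choice; all statistics
operate on whatever values the `S` matrix contains, restricted to the brain
mask.

## The four steps

**1. Skewness filter (per component).** The value distribution of a
noise-driven map is symmetric about zero; a genuine network map has a heavy
positive tail of active voxels. Pearson's median skewness coefficient
`3·(mean − median)/σ` (sample σ, zero returned for constant rows) measures
this. The rejection threshold TH is data-driven: the median of the K
per-component coefficients; components strictly below TH are rejected, so
exact ties (and the K = 1 case) survive. By default the comparison uses
|coefficient|, because "noise-like" is a statement about magnitude and a
strongly left-skewed map (a network anti-correlated with its time course)
is still structured; a `signed` mode is available. Since TH is a median,
step 1 always passes roughly half the components; its job is triage, not
final classification.

**2. Cluster filter (per voxel).** Within each surviving map, voxel values
are clustered by one-dimensional k-means (Euclidean distance on activation
values; k-means++ seeding, 10 restarts, ≤ 300 iterations, tolerance 1e-6,
fixed seed). The number of clusters is chosen by maximising the mean
silhouette index `(b − a)/max(a, b)` over candidate k ∈ {2,…,9} (the range
is configurable; 1-D problems saturate quickly), ties broken toward smaller
k. The cluster whose centroid is nearest zero in absolute value — the
low-activation voxels — is removed; all other clusters, including
negative-valued ones far from zero, are kept. Silhouette evaluation is
exact up to 5000 points; above that a deterministic fixed-seed subsample of
points is scored, with distances still taken to all points (evaluated in
O(n log n) via sorted prefix sums rather than pairwise distance matrices).
Points alone in their cluster score 0 by the usual convention.

**3. Tissue filter (per voxel).** Voxels with at least 90% probability of
white matter or CSF are cancelled (`wm ≥ 0.9 OR csf ≥ 0.9` per map; a
`summed` rule on `wm + csf` is available), restricting maps to gray matter
and suppressing ventricle pulsation. A component stripped of every voxel is
rejected as empty.

**4. Spectral filter (per component).** Each surviving component's voxel
time courses `x[:, m] = A[:, i]·S[i, m]` over the retained voxels are
baseline-corrected, detrended (linear by default; polynomial degree
configurable) and averaged. The plain unwindowed periodogram of the mean
time course is split at f1 = 0.01 Hz and f2 = 0.1 Hz into fractions P1, P2,
P3 of the total power over (0, Nyquist]; resting-state BOLD fluctuations
concentrate in P2. Components with P2 < 50% **or** P1 + P2 < 90% are
rejected; the rest are selected. The OR logic is the stricter reading of
the two criteria and matches the precedent of discarding components with
half their power above 0.1 Hz; an AND mode exists.

Numerical conventions in step 4: the DC bin is excluded from every band and
from the total (the series is demeaned, so it carries no information); bins
are assigned to bands half-open by center frequency, `[0, f1)`, `[f1, f2)`,
`[f2, Nyquist]`, so no bin is double-counted; the upper integration bound
is the Nyquist frequency 1/(2·TR), the only physically meaningful limit for
a sampled series. Per-voxel detrending before averaging is implemented
literally even though, detrending being linear, the order does not change
the result. Because every voxel time course is a scalar multiple of one
mixing column, retained voxels with mixed-sign map values can cancel in the
average; a warning is logged when the retained values are nearly
sign-balanced (|mean| < 1e-3 · mean|·|) and the computation proceeds.

Components progress one way through `candidate → rejected_* / selected`;
a rejected component is never re-examined, and each component's rejection
stage, voxel counts per stage and band powers are kept in the report for
audit. A failure confined to one component (degenerate values, zero
spectrum) demotes that component with a logged reason; only structural
errors (grid mismatches, invalid configuration) abort a run.

## Evaluation

Against a reference labelling (expert networks or synthetic ground truth),
the selected set yields TP/FP/FN/TN counts with
`accuracy = (TP+TN)/(TP+TN+FP+FN)` and `precision = TP/(TP+FP)`; values are
available at full precision and as nearest-integer percent. False negatives
are the costly error: a missed network is information lost, while a false
positive merely costs a second look.

Cross-session reproducibility is supported by greedy one-to-one matching of
selected maps on spatial Pearson correlation (pairs below r = 0.4 dropped).
This is an objective surrogate for per-network expert judgement and is not
claimed to reproduce any expert-labelled reproducibility figures, which
depend on specific data and human raters.

## Synthetic ground truth

`make_decomposition` builds (A, S) directly with known class labels rather
than mixing data and running ICA, so the selector is tested independently
of ICA's run-to-run instability. Defaults emulate a typical acquisition:
N = 197 time points at TR = 2 s, 20×20×20 grid (≈ 3700 brain voxels inside
an ellipsoidal mask), 3 network + 7 noise + 2 CSF components in seeded
random order.

* Tissue fields are smooth concentric sigmoids: CSF ventricle core
  (probability > 0.9 at the center), WM shell, GM cortex, renormalised to
  sum ≤ 1.
* Network maps: folded-Gaussian (|N(0, 4)|) amplitudes inside 2–3
  ellipsoidal blobs of radius 3.2–4.2 voxels centered in gray matter, over
  N(0, 0.2) background. The skewness coefficient grows as the square root
  of the active-volume fraction, and this blob-volume floor keeps every
  network map above coefficient 0.5 while noise maps stay near 0
  (sampling s.d. ≈ 0.04 at this voxel count). Time courses are
  random-phase series with ≈ 99% of power in 0.01–0.1 Hz.
* Noise maps are i.i.d. N(0, 1) with white time courses; CSF maps are
  folded-Gaussian blobs confined to voxels with CSF probability ≥ 0.9,
  with time courses above 0.12 Hz.

What the generator does *not* emulate: hemodynamic response shape, head
motion, spatial autocorrelation of noise, EPI distortion, partial-volume
mixtures of network and artifact within one component. Passing the
parameter-recovery tests therefore shows the selection logic implements its
definitions and separates these idealised classes at high SNR — not that
the same error rates hold on scanner data, where the published evaluation
relied on expert labels.

Because TH is the median coefficient, about half the noise components
always clear step 1 when noise is the majority class (with 7 noise among 12
components, the single largest-coefficient noise map always lands above the
median); such survivors are caught by the spectral step, so the class-level
guarantee is pipeline-level rejection, not step-1 rejection.

## Problem sizes and runtime

Test-suite and acceptance experiments use the default 20³ grid and 197
time points: 50 generator seeds for parameter recovery, 100 random
instances (≤ 8 points each) for the exhaustive clustering oracle, 1000
random series for spectral invariants. The full suite runs in ≈ 5 minutes
and the acceptance script in ≈ 3.5 minutes on one CPU.

## Known limitations

* The skewness threshold being a run-internal median means the method's
  behaviour depends on the component mix; it cannot reject *all* components
  of a pure-noise decomposition at step 1 (the spectral step does that).
* Exact silhouette above the subsample cap is approximated by a fixed-seed
  point subsample (distances to all points); results remain deterministic
  but can differ from the exact mean silhouette on maps with > 5000
  candidate voxels.
* Near the 0.1 Hz band edge, spectral leakage of the finite boxcar window
  (window length N·TR) blurs band assignment by one to two bins; this is a
  property of the periodogram, not of the implementation.
* Greedy correlation matching is order-optimal only when correlations are
  distinct; it is a surrogate for, not a reproduction of, expert
  reproducibility scoring.
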