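# Methods notes

## The generative model

Analyses of bipolar-cell calcium imaging make statistical assumptions —
center–surround receptive fields, indicator-filtered kinetics,
AR(1)-correlated noise, repeat structure, distance-correlated signals
along axon arbors — and the synthetic module generates data with
exactly those properties so each downstream estimator can be tested
against known ground truth.

**Model cell.** A linear–nonlinear cascade: Gaussian-weighted center
(SD = `center_radius`/2) minus `surround_weight` times the mean of an
annular surround (between `center_radius` and `surround_radius`); a
200 ms response latency; a first-order high-pass (subtracting an
exponential moving average with time constant `transience_tau`)
controlling the transient–sustained balance; rectification with
headroom (clipped at −baseline, so strong suppression reads as a dip
below baseline rather than clipping to zero — this is what makes
response inversion of strongly suppressed types visible); convolution
with the GCaMP6f kernel `(1 − e^{−t/τ_r}) e^{−t/τ_d}` (τ_r = 49.5 ms,
τ_d = 156 ms); resampling to the acquisition rate (9.5 Hz default);
and additive AR(1) noise.

Defaults: `center_radius` 25 µm and `surround_radius` 300 µm. These
radii are chosen so the center response saturates by 150 µm spot
diameter and the surround by 600 µm, which is what makes the two-size
spot averages of the surround-strength statistic faithful proxies for
"center" and "surround" drive; they are also anatomically reasonable
for mouse bipolar cells.

**Type set-points.** The seven default parameter sets implement the
population's qualitative organisation: the four upper-block types
(BC5o, BC5i, BC5t, XBC) share strong surround suppression —
`surround_weight` is calibrated analytically (solving the linear spot
drive for two diameters) so the 800 µm response is 34% of the 150 µm
response — while spanning the transient-to-sustained axis
(`transience_tau` 0.18 s for XBC up to 8 s for BC5t). The three
lower-block types share sustained kinetics (τ 3–4 s) and differ in
surround strength, with BC7 inverting (target ratio −0.20, giving
S ≈ 1.2). IPL depths run from 0.47 (BC5o) to 0.88 (BC8/9). These
values are generator conditions, not fitted quantities.

**Stimuli.** Spots of 20–800 µm diameter, 1.5 s ON / 1.5 s OFF, five
consecutive repeats per size, 1.5 s gaps, seeded pseudorandom size
order; sinusoidal spots at 0.5–16 Hz for 2 s, five repeats each, in
150 and 800 µm diameters; 15×20 binary checkerboards of 20 µm squares,
900 unique frames shown twice; and a naturalistic surrogate — a static
1/f² (power-law) luminance field viewed through a window that
translates rigidly during specified motion segments. Movies are stored
as contrast in [−0.5, 0.5] around the adapting background.

**Arbors.** A random planar tree (minimum spanning tree of points in a
disk of the requested equivalent diameter). Node signals follow a
Markov process along the tree: each child node's trace is
`ρ·parent + √(1−ρ²)·innovation` with `ρ = e^{−ℓ/λ}` for edge length ℓ,
so the correlation between any two nodes is exactly `e^{−d/λ}` in path
distance d. λ = ∞ makes every ROI carry the shared signal. Per-repeat
traces add independent Gaussian noise.

**What the generator does not emulate.** Photoreceptor adaptation,
rod input, chromatic pathways, projector optics, scan artifacts,
neuropil contamination, z-drift, and the frequency-dependent
suppressive baseline (F0) responses observed in real recordings, whose
mechanism is unresolved — deliberately left out rather than invented.
Passing tests therefore certify the estimators against the stated
statistical structure, not against every nuisance of real data.

## Pipeline choices

- **Registration**: integer-pixel phase correlation against a
  reference frame. At ~1 µm/px sampling of bouton-scale structures,
  subpixel refinement buys nothing; the same shifts apply to a paired
  (transmitted-light) channel.
- **Segmentation**: local maxima of the temporal-SD image above a
  threshold (default: its 75th percentile) seed ROIs; pixels are
  assigned to the nearest peak by geodesic distance *within* the
  above-threshold mask (multi-source Dijkstra on the 4-connected pixel
  graph), which guarantees each ROI is connected. Ties break toward
  the lower peak index. Manual seeds snap to the brightest of their 12
  nearest pixels. The threshold is an exposed parameter because in
  practice it is tuned by inspection; border peaks are kept.
- **Reliability**: all balanced half-splits are enumerated up to 200
  splits, beyond which a seeded subsample is used (the count grows
  combinatorially while the median stabilises long before).
- **ROI consolidation**: k-means (k-means++, 50 restarts, fixed seed)
  on z-scored unit-norm traces — for which squared Euclidean distance
  is proportional to correlation distance — with k chosen by
  `BIC = n ln(RSS/n) + k ln(n)`, RSS being summed correlation
  distances to centroids. RSS is floored at n·10⁻⁶: below the
  numerical noise of correlation estimates, splitting identical traces
  would shrink ln(RSS) without bound and defeat the penalty.
- **F1 analysis**: band-limited (Fourier) resampling to 189.4 Hz; one
  DFT bin when the stimulus frequency is on the frequency grid (within
  2%, absorbing resampling jitter), else the sum of the two nearest
  bins. Phases are unit vectors averaged across trials and adjacent
  bins; a pure sine reads −90°. The indicator correction simulates the
  kernel's response to each modulation (1 s pads at 0.5 for edge
  stability), runs it through the identical F1 path, peak-normalizes
  and subtracts — so correcting the simulation itself gives exactly
  zero.
- **Spot statistics**: epoch peaks are taken over the full epoch (ON
  and OFF), so OFF-dominated responses normalize consistently; missing
  spot sizes fall back to the nearest size with a warning. Window
  arithmetic is half-open `[t0, t1)`.
- **Peak analysis**: one dominant peak per trial, detected with
  prominence ≥ 3× the pre-stimulus noise SD; multimodality scored by
  Hartigan's dip statistic (in-package implementation) with a
  Monte-Carlo p-value under the uniform null.
- **Classifier**: distance to a type is the *median* distance to its
  exemplars (robust; the pure nearest-exemplar rule is an option).
  The gamma "probability metric" is the survival function 1 − CDF
  (monotone, 1 at distance 0); maximum-likelihood fit with location
  fixed at 0. Depth probabilities come from per-type stratification
  densities smoothed with a 21-point moving average and normalized
  across types at each depth. Outliers are the lower 5% tail of a
  gamma fit to all combined probabilities. Ties break toward the lower
  type index and are flagged.
- **MDS**: weighted nonmetric SMACOF written in-package because the
  3-SD zero-weight mask is part of the contract and library
  implementations accept no weights. Isotonic regression supplies the
  disparities, a weighted Guttman transform (with the pseudo-inverse
  of the weight Laplacian) the updates; Kruskal stress-1 is the
  reported criterion. Initialisation: classical MDS plus four seeded
  random restarts, best stress kept; 2000-iteration cap with a warning
  on non-convergence. The embedding is rotated to principal axes and
  coordinates are ordered by single-coordinate explained variance
  (squared correlation between masked input distances and
  sub-coordinate Euclidean distances); zero-variance coordinates score
  zero. Triangle-inequality violations of correlation distances are
  tolerated by the nonmetric formulation and logged.
- **JSD / batch effects**: Gaussian KDE (Silverman bandwidth by
  default) on a shared grid padded 25% beyond the data range; natural
  log, so JSD ≤ ln 2. The batch test compares whole-batch splits with
  random point splits; the p-value is one-sided — the fraction of
  random-split JSDs at least as large as the median batch-split JSD —
  because only an excess of batch-split divergence indicates a batch
  effect.
- **Naturalistic features**: all feature traces share one code path —
  mask-weighted frame dot products, the indicator convolution `g`, a
  200 ms shift, and box-averaging into response bins — so sensitivity
  ratios cancel the filtering. `g` is a 4 s kernel whose head is the
  2 s GCaMP6f response, kept causal so the feature lags the stimulus
  the way the recorded response does, and area-normalized (steady-state
  gain 1). The center mask is a truncated bivariate normal with
  covariance 2πr·I (µm²), max-normalized, zero outside the radius.
  In-center contrast multiplies the center mask by a diagonal linear
  ramp through the center, responding to luminance gradients within
  the center; the blend weight β is found by a 0.01 coarse grid plus
  bounded refinement, floored at 10⁻³ before log₁₀. Horn–Schunck
  optical flow (smoothness 3, 100 iterations, standard averaging
  kernel) is implemented in-package; the coherence statistic uses
  `O_v = |mean flow vector|` (vector sum ÷ pixel count) so
  `O_a − O_v ≥ 0` vanishes exactly for rigid translation — the raw
  vector-sum magnitude, dimensionally incompatible with `O_a`, remains
  available behind a flag.
- **Receptive fields**: correlation maps over a 21×21 grid of 4 µm
  steps (441 positions, 80 µm disks), refined by bicubic spline
  interpolation at 0.25 µm; peaks on the grid border are returned
  unrefined and flagged, as are qualities below R² = 0.1.
- **Arbors**: centroids attach to the nearest skeleton point sampled
  at 0.1 µm along edges; attachment nodes split their edge so path
  distances are exact. With more than two repeats, q and k average
  over repeat pairs; with clip boundaries, correlations are computed
  per clip and averaged. The λ profile is evaluated on a log grid
  (1–1000 µm plus ∞).

### Length-constant bias

Both q and k are products of **two** correlation coefficients. For
pairwise response correlation r and per-ROI reliabilities, the
expectation is `k ≈ r²·q`, so fitting `r_λ ⊙ q` to k places the
profile peak at the decay length of r² — exactly half the decay length
of r, since `e^{−2d/λ} = e^{−d/(λ/2)}`. The estimator therefore
reports both the raw profile argmax (`lambda`, used for the
homogeneity verdict against the equivalent diameter — conservative,
since the raw value understates λ) and the analytically corrected
response-correlation decay length (`lambda_corrected = 2·λ*`), which
parameter-recovery tests confirm is approximately unbiased (median
relative error ~5–7% at λ ∈ {15, 30, 60} µm with 50 ROIs).

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to keep each
estimator comfortably in its working regime: spot movies at 10 fps
with 8 µm pixels; checkerboards of 300 unique frames for RF mapping;
surrogate movies of 64–72 px at 30–60 fps; populations of 35 reference
cells (5 per type); 24 simulated arbors of 50 ROIs for λ recovery; 100–
200 null replicates for calibration checks. The statistics themselves
are size-agnostic.

## Known limitations

- The anatomical classification tree used for morphological typing is
  represented only as a user-supplied threshold table; no image-based
  morphology is computed.
- Registration is rigid and integer-pixel; non-rigid motion and
  z-drift are out of scope (z-drift rejection is a QC flag upstream).
- The temperature adjustment of the literature GCaMP6f time constants
  is not published; the printed constants are used as-is and an
  adjustment factor is exposed as a parameter.
- KDE-based JSD estimates carry bandwidth-dependent smoothing bias;
  comparisons should use a fixed bandwidth (tests validate against
  bandwidth-matched analytic densities).
- The spot-response normalization uses the full-epoch peak; when
  responses peak in the OFF phase this choice (documented above) can
  scale S and T differently than peak-ON normalization.
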