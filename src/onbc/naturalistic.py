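"""Feature sensitivities for naturalistic movies and RF mapping.

Responses to naturalistic movie clips are compared against candidate
stimulus features extracted at the cell's receptive field: local
luminance (100 um Gaussian-weighted center), center-minus-surround
contrast (600 um surround), band- vs low-pass temporal contrast,
coherent motion (Horn-Schunck optical flow in a 200 um mask), and
in-center contrast (a linear-ramp gradient across the center).  Every
feature trace passes through the same indicator convolution ``g`` and
a 200 ms response-delay shift before correlation with the response,
so sensitivity ratios compare features, not filtering artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline
from scipy.signal import fftconvolve

from .imaging import repeat_reliability
from .synthetic import StimulusMovie
from .temporal import gcamp_kernel

__all__ = [
    "ReceptiveField",
    "gaussian_center_mask",
    "movie_feature_trace",
    "spatial_contrast_sensitivity",
    "temporal_contrast_sensitivity",
    "horn_schunck_flow",
    "motion_coherence_trace",
    "motion_sensitivity",
    "in_center_contrast_sensitivity",
    "map_receptive_field",
    "luminance_explained_variance",
    "feature_spatial_autocorrelation",
    "visual_angle_extent",
    "temporal_bandpass_kernel",
    "temporal_lowpass_kernel",
]

#: default diameters, um
CENTER_DIAMETER_UM = 100.0
SURROUND_DIAMETER_UM = 600.0
MOTION_MASK_DIAMETER_UM = 200.0
RF_DISK_DIAMETER_UM = 80.0

#: response-delay shift applied to all contrast traces, ms
RESPONSE_SHIFT_MS = 200.0

#: band-pass temporal kernel: (mean s, SD s, weight) Gaussian components
F_B_COMPONENTS = ((0.08, 0.05, 1.0), (0.12, 0.12, -0.5))
#: low-pass temporal kernel components
F_L_COMPONENTS = ((0.24, 0.10, 1.0), (0.30, 0.24, -0.001))


@dataclass
class ReceptiveField:
    """Receptive field center (um from the display center) and quality."""

    center: tuple[float, float]
    quality: float = 1.0
    flagged: bool = False


# ---------------------------------------------------------------------------
# masks and feature traces
# ---------------------------------------------------------------------------


def gaussian_center_mask(
    radius_um: float,
    pixel_size: float,
    shape: tuple[int, int],
    center_um: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Truncated bivariate-normal weights, max-normalized.

    The covariance is ``2 * pi * r`` times the identity (um^2), and any
    weight beyond the receptive-field radius is set to zero.
    """
    if radius_um < pixel_size:
        raise ValueError("radius below one pixel")
    h, w = shape
    yy, xx = np.indices((h, w), dtype=float)
    y_um = (yy - (h - 1) / 2) * pixel_size - center_um[1]
    x_um = (xx - (w - 1) / 2) * pixel_size - center_um[0]
    r2 = y_um**2 + x_um**2
    sigma2 = 2.0 * np.pi * radius_um
    weights = np.exp(-r2 / (2.0 * sigma2))
    weights[r2 > radius_um**2] = 0.0
    m = weights.max()
    if m > 0:
        weights /= m
    return weights


def _g_kernel(rate: float, total_s: float = 4.0, response_s: float = 2.0) -> np.ndarray:
    """The 4 s convolution kernel built around the 2 s GCaMP response.

    The response function occupies the head of the window and the
    remainder is zero, keeping the filter causal so that the feature
    trace lags the stimulus the same way the indicator makes the
    recorded response lag it; area normalization gives steady-state
    gain 1.
    """
    n = int(round(total_s * rate))
    k = np.zeros(n)
    resp = gcamp_kernel(rate=rate, duration=response_s).kernel
    k[: resp.size] = resp[:n]
    return k / k.sum()


def apply_g(trace: np.ndarray, rate: float) -> np.ndarray:
    """Convolve a contrast trace with the indicator kernel ``g`` (causal)."""
    k = _g_kernel(rate)
    return fftconvolve(trace, k, mode="full")[: trace.size]


def _shift(trace: np.ndarray, rate: float, shift_ms: float) -> np.ndarray:
    k = int(round(shift_ms / 1000.0 * rate))
    if k <= 0:
        return trace
    return np.concatenate([np.full(k, trace[0]), trace[:-k]])


def _bin_to(trace: np.ndarray, n_out: int) -> np.ndarray:
    """Box-average a movie-rate trace into response-rate bins."""
    if n_out >= trace.size:
        t_in = np.linspace(0, 1, trace.size)
        return np.interp(np.linspace(0, 1, n_out), t_in, trace)
    edges = np.linspace(0, trace.size, n_out + 1).astype(int)
    return np.array([trace[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])


def _ramp_mask(radius_um: float, pixel_size: float, shape, center_um) -> np.ndarray:
    """Gaussian center weights multiplied by a diagonal linear ramp.

    The ramp crosses zero at the center, splitting the receptive field
    center into opposing quadrant pairs; the dot product with a frame
    then measures the luminance gradient (in-center contrast) rather
    than the mean.
    """
    g = gaussian_center_mask(radius_um, pixel_size, shape, center_um)
    h, w = shape
    yy, xx = np.indices((h, w), dtype=float)
    y_um = (yy - (h - 1) / 2) * pixel_size - center_um[1]
    x_um = (xx - (w - 1) / 2) * pixel_size - center_um[0]
    ramp = (x_um + y_um) / (np.sqrt(2.0) * radius_um)
    return g * ramp


def movie_feature_trace(
    movie: StimulusMovie,
    rf: ReceptiveField | tuple[float, float],
    kind: str = "luminance_center",
    apply_g_flag: bool = True,
    shift_ms: float = RESPONSE_SHIFT_MS,
) -> np.ndarray:
    """Weighted-mask contrast trace of a movie at a receptive field.

    ``kind`` is one of ``luminance_center`` (100 um center),
    ``surround`` (600 um), ``center_minus_surround`` or ``in_center``
    (linear-ramp gradient across the center).  Each frame's value is
    the dot product of its pixels with the mask divided by the sum of
    the weights; the optional indicator convolution and the 200 ms
    delay shift follow.
    """
    center = rf.center if isinstance(rf, ReceptiveField) else tuple(rf)
    h_um, w_um = movie.extent_um()
    if abs(center[0]) > w_um / 2 or abs(center[1]) > h_um / 2:
        raise ValueError("receptive field outside the movie")
    shape = movie.shape
    px = movie.pixel_size

    def weighted(mask: np.ndarray, norm: float | None = None) -> np.ndarray:
        flat = movie.frames.reshape(movie.frames.shape[0], -1)
        denom = norm if norm is not None else mask.sum()
        return flat @ mask.ravel() / denom

    if kind == "luminance_center":
        trace = weighted(gaussian_center_mask(CENTER_DIAMETER_UM / 2, px, shape, center))
    elif kind == "surround":
        trace = weighted(gaussian_center_mask(SURROUND_DIAMETER_UM / 2, px, shape, center))
    elif kind == "center_minus_surround":
        trace = weighted(gaussian_center_mask(CENTER_DIAMETER_UM / 2, px, shape, center)) \
            - weighted(gaussian_center_mask(SURROUND_DIAMETER_UM / 2, px, shape, center))
    elif kind == "in_center":
        mask = _ramp_mask(CENTER_DIAMETER_UM / 2, px, shape, center)
        trace = weighted(mask, norm=np.abs(mask).sum())
    else:
        raise ValueError(f"unknown feature kind '{kind}'")
    if apply_g_flag:
        trace = apply_g(trace, movie.frame_rate)
    return _shift(trace, movie.frame_rate, shift_ms)


def _gauss_membership(t: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mean) / sd) ** 2)


def _temporal_kernel(components, rate: float, window_s: float = 1.0) -> np.ndarray:
    t = np.arange(int(round(window_s * rate))) / rate
    k = np.zeros_like(t)
    for mean, sd, weight in components:
        k += weight * _gauss_membership(t, mean, sd)
    return k


def temporal_bandpass_kernel(rate: float, window_s: float = 1.0) -> np.ndarray:
    """Band-pass kernel ``f_b``: difference of two Gaussian memberships."""
    return _temporal_kernel(F_B_COMPONENTS, rate, window_s)


def temporal_lowpass_kernel(rate: float, window_s: float = 1.0) -> np.ndarray:
    """Low-pass kernel ``f_l``."""
    return _temporal_kernel(F_L_COMPONENTS, rate, window_s)


# ---------------------------------------------------------------------------
# sensitivities
# ---------------------------------------------------------------------------


def _corr2(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def _align(trace: np.ndarray, n_out: int) -> np.ndarray:
    return _bin_to(trace, n_out)


def spatial_contrast_sensitivity(movie: StimulusMovie, rf, response: np.ndarray) -> float:
    """``S = ln(Corr(g(S_c - S_s), R)^2 / Corr(g(S_c), R)^2)``.

    Positive values mean the response tracks center-surround contrast
    better than plain local luminance.
    """
    response = np.asarray(response, dtype=float)
    cs = _align(movie_feature_trace(movie, rf, "center_minus_surround"), response.size)
    c = _align(movie_feature_trace(movie, rf, "luminance_center"), response.size)
    num, den = _corr2(cs, response), _corr2(c, response)
    if num == 0 or den == 0:
        warnings.warn("zero correlation: spatial sensitivity undefined", stacklevel=2)
        return float("nan")
    return float(np.log(num / den))


def temporal_contrast_sensitivity(movie: StimulusMovie, rf, response: np.ndarray) -> float:
    """``T = ln(Corr(g(f_b(S_c)), R)^2 / Corr(g(f_b(S_c) - f_l(S_c)), R)^2)``."""
    response = np.asarray(response, dtype=float)
    rate = movie.frame_rate
    sc = movie_feature_trace(movie, rf, "luminance_center", apply_g_flag=False, shift_ms=0)
    fb = fftconvolve(sc, temporal_bandpass_kernel(rate), mode="same")
    fl = fftconvolve(sc, temporal_lowpass_kernel(rate), mode="same")
    top = _shift(apply_g(fb, rate), rate, RESPONSE_SHIFT_MS)
    bot = _shift(apply_g(fb - fl, rate), rate, RESPONSE_SHIFT_MS)
    num = _corr2(_align(top, response.size), response)
    den = _corr2(_align(bot, response.size), response)
    if num == 0 or den == 0:
        warnings.warn("zero correlation: temporal sensitivity undefined", stacklevel=2)
        return float("nan")
    return float(np.log(num / den))


def horn_schunck_flow(
    frame_t: np.ndarray,
    frame_t1: np.ndarray,
    smoothness: float = 3.0,
    n_iter: int = 100,
) -> np.ndarray:
    """Horn-Schunck optical flow between two frames.

    Returns a (rows, cols, 2) array of (u, v) = (x, y) flow in pixels
    per frame.  The global smoothness term couples every pixel, so
    coherent translation produces a near-uniform field; constant
    frames yield exactly zero flow.
    """
    a = np.asarray(frame_t, dtype=float)
    b = np.asarray(frame_t1, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must share a shape")
    kx = np.array([[-0.25, 0.25], [-0.25, 0.25]])
    ky = np.array([[-0.25, -0.25], [0.25, 0.25]])
    kt = np.full((2, 2), 0.25)
    # correlation, not convolution: the derivative masks are directional
    ix = ndimage.correlate(a, kx, mode="nearest") + ndimage.correlate(b, kx, mode="nearest")
    iy = ndimage.correlate(a, ky, mode="nearest") + ndimage.correlate(b, ky, mode="nearest")
    it = ndimage.correlate(b, kt, mode="nearest") - ndimage.correlate(a, kt, mode="nearest")
    avg = np.array([[1 / 12, 1 / 6, 1 / 12], [1 / 6, 0, 1 / 6], [1 / 12, 1 / 6, 1 / 12]])
    u = np.zeros_like(a)
    v = np.zeros_like(a)
    denom = smoothness**2 + ix**2 + iy**2
    for _ in range(n_iter):
        ub = ndimage.convolve(u, avg, mode="nearest")
        vb = ndimage.convolve(v, avg, mode="nearest")
        common = (ix * ub + iy * vb + it) / denom
        u = ub - ix * common
        v = vb - iy * common
    return np.stack([u, v], axis=-1)


def motion_coherence_trace(
    movie: StimulusMovie,
    rf,
    smoothness: float = 3.0,
    n_iter: int = 100,
    normalized_vector_sum: bool = True,
) -> np.ndarray:
    """Per-frame incoherence statistic ``O_a - O_v`` in a 200 um mask.

    ``O_a`` is the mean flow-vector magnitude and ``O_v`` the magnitude
    of the mean flow vector over the masked pixels; their difference
    vanishes for coherent (rigid) motion and grows with incoherent
    flow.  With ``normalized_vector_sum=False``, ``O_v`` is the raw
    vector-sum magnitude instead.
    """
    center = rf.center if isinstance(rf, ReceptiveField) else tuple(rf)
    h, w = movie.shape
    yy, xx = np.indices((h, w), dtype=float)
    y_um = (yy - (h - 1) / 2) * movie.pixel_size - center[1]
    x_um = (xx - (w - 1) / 2) * movie.pixel_size - center[0]
    mask = (y_um**2 + x_um**2) <= (MOTION_MASK_DIAMETER_UM / 2) ** 2
    n_pix = max(mask.sum(), 1)
    out = np.zeros(movie.frames.shape[0])
    for i in range(movie.frames.shape[0] - 1):
        flow = horn_schunck_flow(movie.frames[i], movie.frames[i + 1], smoothness, n_iter)
        vecs = flow[mask]
        o_a = float(np.linalg.norm(vecs, axis=1).mean())
        vsum = vecs.sum(axis=0)
        o_v = float(np.linalg.norm(vsum / n_pix if normalized_vector_sum else vsum))
        out[i + 1] = o_a - o_v
    out[0] = out[1] if out.size > 1 else 0.0
    return out


def motion_sensitivity(
    movie: StimulusMovie,
    rf,
    response: np.ndarray,
    smoothness: float = 3.0,
    n_iter: int = 100,
) -> float:
    """``M = ln(1 / Corr(g(O_a - O_v), R)^2)``.

    Small values mean the response closely tracks the incoherence of
    motion through the receptive field; uncorrelated responses give
    large M.
    """
    response = np.asarray(response, dtype=float)
    o = motion_coherence_trace(movie, rf, smoothness, n_iter)
    o = _shift(apply_g(o, movie.frame_rate), movie.frame_rate, RESPONSE_SHIFT_MS)
    c2 = _corr2(_align(o, response.size), response)
    if c2 == 0:
        warnings.warn("zero correlation: motion sensitivity infinite", stacklevel=2)
        return float("inf")
    return float(np.log(1.0 / c2))


def in_center_contrast_sensitivity(
    movie: StimulusMovie,
    rf,
    response: np.ndarray,
    beta_floor: float = 1e-3,
) -> tuple[float, float]:
    """``I = log10(beta)`` for the optimal center/in-center blend.

    ``beta`` maximizes ``Corr(beta * g(S_cin) + (1 - beta) * g(S_c), R)``
    over [0, 1] (coarse grid plus golden-section refinement); the floor
    prevents ``log10(0)`` when the in-center term contributes nothing.
    Returns (I, beta).
    """
    from scipy.optimize import minimize_scalar

    response = np.asarray(response, dtype=float)
    c = _align(movie_feature_trace(movie, rf, "luminance_center"), response.size)
    cin = _align(movie_feature_trace(movie, rf, "in_center"), response.size)

    def neg_corr(beta: float) -> float:
        blend = beta * cin + (1 - beta) * c
        if blend.std() == 0 or response.std() == 0:
            return 0.0
        return -float(np.corrcoef(blend, response)[0, 1])

    grid = np.linspace(0.0, 1.0, 101)
    vals = [neg_corr(b) for b in grid]
    b0 = grid[int(np.argmin(vals))]
    lo, hi = max(0.0, b0 - 0.02), min(1.0, b0 + 0.02)
    res = minimize_scalar(neg_corr, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-5})
    beta = float(res.x) if res.fun <= min(vals) else float(b0)
    if beta <= beta_floor or beta >= 1.0 - 1e-6:
        warnings.warn("blend optimum at the boundary", stacklevel=2)
    beta_eff = max(beta, beta_floor)
    return float(np.log10(beta_eff)), beta


# ---------------------------------------------------------------------------
# receptive-field mapping and spatial statistics
# ---------------------------------------------------------------------------


def _offset_grid(half_um: float, step_um: float) -> np.ndarray:
    g = np.arange(-half_um, half_um + step_um / 2, step_um)
    return np.array([(x, y) for y in g for x in g])


def _traces_at_offsets(
    movie: StimulusMovie,
    offsets: np.ndarray,
    kind: str,
    disk_diameter_um: float,
) -> np.ndarray:
    """Feature traces (g-filtered, shifted) at many RF offsets, vectorized."""
    shape = movie.shape
    px = movie.pixel_size
    masks = []
    for x, y in offsets:
        if kind == "in_center":
            m = _ramp_mask(disk_diameter_um / 2, px, shape, (x, y))
            masks.append(m.ravel() / max(np.abs(m).sum(), 1e-12))
        else:
            m = gaussian_center_mask(disk_diameter_um / 2, px, shape, (x, y))
            masks.append(m.ravel() / max(m.sum(), 1e-12))
    masks = np.asarray(masks).T  # (pixels, n_offsets)
    flat = movie.frames.reshape(movie.frames.shape[0], -1)
    traces = flat @ masks  # (frames, n_offsets)
    k = _g_kernel(movie.frame_rate)
    traces = fftconvolve(traces, k[:, None], mode="full", axes=0)[: flat.shape[0]]
    shift_n = int(round(RESPONSE_SHIFT_MS / 1000.0 * movie.frame_rate))
    if shift_n > 0:
        traces = np.vstack([np.tile(traces[0], (shift_n, 1)), traces[:-shift_n]])
    return traces


def map_receptive_field(
    response: np.ndarray,
    movie: StimulusMovie,
    half_um: float = 40.0,
    step_um: float = 4.0,
    disk_diameter_um: float = RF_DISK_DIAMETER_UM,
    quality_floor: float = 0.1,
) -> ReceptiveField:
    """Locate the receptive field from white-noise responses.

    Local luminance ``g(S_c)`` in 80 um disks is computed at a grid of
    positions (by default 441 positions, 4 um apart, covering +/-40 um)
    and correlated with the response; the correlation-map peak, refined
    by 2-D spline interpolation, is the receptive field center.  The
    quality is the peak squared correlation; centers with quality below
    ``quality_floor`` are flagged.
    """
    response = np.asarray(response, dtype=float)
    offsets = _offset_grid(half_um, step_um)
    traces = _traces_at_offsets(movie, offsets, "luminance_center", disk_diameter_um)
    n_grid = int(round(2 * half_um / step_um)) + 1
    corr = np.empty(len(offsets))
    for i in range(len(offsets)):
        tr = _align(traces[:, i], response.size)
        c = np.corrcoef(tr, response)[0, 1] if tr.std() > 0 and response.std() > 0 else 0.0
        corr[i] = c
    cmap = corr.reshape(n_grid, n_grid)  # rows: y, cols: x
    iy, ix = np.unravel_index(np.argmax(cmap), cmap.shape)
    axis = np.linspace(-half_um, half_um, n_grid)
    quality = float(cmap[iy, ix] ** 2)
    flagged = quality < quality_floor
    if iy in (0, n_grid - 1) or ix in (0, n_grid - 1):
        warnings.warn("correlation peak on the grid border: no spline refinement",
                      stacklevel=2)
        return ReceptiveField((float(axis[ix]), float(axis[iy])), quality, True)
    spline = RectBivariateSpline(axis, axis, cmap, kx=3, ky=3)
    fine = np.arange(axis[iy - 1], axis[iy + 1] + 0.25, 0.25)
    fine_x = np.arange(axis[ix - 1], axis[ix + 1] + 0.25, 0.25)
    patch = spline(fine, fine_x)
    jy, jx = np.unravel_index(np.argmax(patch), patch.shape)
    return ReceptiveField((float(fine_x[jx]), float(fine[jy])), quality, flagged)


def luminance_explained_variance(
    response: np.ndarray,
    movie: StimulusMovie,
    rf,
    repeats: np.ndarray | None = None,
) -> dict:
    """R^2 of the response against shifted, filtered local luminance.

    When repeated trials are supplied, the half-split repeat
    reliability is reported as the ceiling on explainable variance;
    the luminance R^2 can legitimately exceed neither 1 nor, in
    expectation, that ceiling.
    """
    response = np.asarray(response, dtype=float)
    lum = _align(movie_feature_trace(movie, rf, "luminance_center"), response.size)
    r2 = _corr2(lum, response)
    ceiling = None
    if repeats is not None and len(repeats) >= 2:
        ceiling = repeat_reliability(np.asarray(repeats))
    return {"r2": r2, "ceiling": ceiling}


def feature_spatial_autocorrelation(
    movie: StimulusMovie,
    kind: str = "luminance_center",
    half_um: float = 40.0,
    step_um: float = 4.0,
    bin_um: float = 2.0,
    max_bin_center_um: float = 76.0,
    disk_diameter_um: float = CENTER_DIAMETER_UM,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlation of a movie feature as a function of RF distance.

    Feature traces are computed on the offset grid; for every position
    pair the trace correlation and the spatial distance are binned
    (2 um bins, centers from 1 um) and the median correlation per bin
    returned.  Smooth (power-law) movies give monotonically decaying
    profiles whose decay scale differs between features.
    """
    offsets = _offset_grid(half_um, step_um)
    if kind == "motion":
        traces = []
        for x, y in offsets:
            traces.append(motion_coherence_trace(movie, (x, y), n_iter=20))
        traces = np.asarray(traces).T
    else:
        traces = _traces_at_offsets(movie, offsets, kind, disk_diameter_um)
    ok = traces.std(axis=0) > 0
    c = np.corrcoef(traces[:, ok].T)
    pos = offsets[ok]
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    iu = np.triu_indices(pos.shape[0], 1)
    d, r = dist[iu], c[iu]
    centers = np.arange(1.0, max_bin_center_um + bin_um / 2, bin_um)
    meds = np.full(centers.size, np.nan)
    for i, ctr in enumerate(centers):
        sel = np.abs(d - ctr) <= bin_um / 2
        if sel.any():
            meds[i] = np.median(r[sel])
    keep = np.isfinite(meds)
    return centers[keep], meds[keep]


def visual_angle_extent(
    pixels: int,
    um_per_px: float,
    um_per_deg: float = 32.5,
    round_deg: bool = True,
) -> float:
    """Convert a pixel extent on the retina to degrees of visual angle.

    One degree of visual angle covers 32.5 um on the mouse retina.
    """
    if pixels <= 0 or um_per_px <= 0 or um_per_deg <= 0:
        raise ValueError("all inputs must be positive")
    deg = pixels * um_per_px / um_per_deg
    return float(round(deg)) if round_deg else float(deg)
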