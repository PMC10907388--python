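"""Calcium image-series preprocessing and ROI extraction.

The pipeline mirrors standard practice for two-photon recordings of
bipolar cell axon terminals: rigid frame registration, 3-D median
filtering, an activity mask from the temporal standard deviation,
region growing from local peaks into morphological ROIs, epoching by
stimulus condition with baseline subtraction, half-split repeat
reliability, and k-means/BIC consolidation of redundant ROIs recorded
in the same imaging plane.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation
from sklearn.cluster import KMeans

__all__ = [
    "ImageSeries",
    "ROIMap",
    "EpochedResponses",
    "ClusterResult",
    "register_rigid",
    "preprocess",
    "segment_rois",
    "extract_epoched_traces",
    "repeat_reliability",
    "consolidate_rois",
]


@dataclass
class ImageSeries:
    """A registered calcium movie: frames x rows x cols."""

    data: np.ndarray
    frame_rate: float
    pixel_size: float
    channel: str = "fluorescence"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ImageSeries data must be frames x rows x cols")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in image series")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class ROIMap:
    """Labeled pixel partition (0 = background) with per-ROI peaks."""

    labels: np.ndarray
    peaks: list[tuple[int, int]]
    pixel_size: float = 1.0

    @property
    def n_rois(self) -> int:
        return len(self.peaks)

    @property
    def areas(self) -> np.ndarray:
        """ROI areas in square micrometers."""
        counts = np.bincount(self.labels.ravel(), minlength=self.n_rois + 1)[1:]
        return counts * self.pixel_size**2


@dataclass
class EpochedResponses:
    """Per (ROI, condition, repeat) traces aligned to stimulus onset.

    ``traces[(roi, condition)]`` is a (n_repeats, n_samples) array
    cut from ``pre_s`` before onset to ``post_s`` after; the mean of
    the pre-onset baseline window has been subtracted.
    """

    traces: dict[tuple[int, str], np.ndarray]
    times: np.ndarray  # seconds relative to onset
    frame_rate: float
    condition_values: dict[str, float] = field(default_factory=dict)

    def rois(self) -> list[int]:
        return sorted({r for r, _ in self.traces})

    def conditions(self) -> list[str]:
        return sorted({c for _, c in self.traces})


@dataclass
class ClusterResult:
    k: int
    assignment: np.ndarray
    bic: float
    bic_curve: dict[int, float] = field(default_factory=dict)


def register_rigid(
    series: ImageSeries,
    reference: int = 0,
    max_shift: int | None = None,
) -> tuple[ImageSeries, np.ndarray]:
    """Integer-pixel rigid translation onto a reference frame.

    Shifts maximize the cross-correlation with the reference frame
    (phase correlation); the same shifts can be applied to a paired
    channel.  Returns the registered series and per-frame (dy, dx).
    """
    data = series.data
    if data.shape[0] < 2:
        raise ValueError("need at least 2 frames to register")
    ref = data[reference].astype(float)
    shifts = np.zeros((data.shape[0], 2), dtype=int)
    out = np.empty_like(data)
    for i, frame in enumerate(data):
        if not np.any(frame):
            warnings.warn(f"frame {i} is all zero: shift set to (0, 0)", stacklevel=2)
            out[i] = frame
            continue
        (dy, dx), _, _ = phase_cross_correlation(
            ref, frame.astype(float), upsample_factor=1, normalization=None
        )
        dy, dx = int(round(dy)), int(round(dx))
        if max_shift is not None:
            dy = int(np.clip(dy, -max_shift, max_shift))
            dx = int(np.clip(dx, -max_shift, max_shift))
        shifts[i] = (dy, dx)
        out[i] = np.roll(frame, (dy, dx), axis=(0, 1))
    registered = ImageSeries(out, series.frame_rate, series.pixel_size, series.channel)
    return registered, shifts


def apply_shifts(series: ImageSeries, shifts: np.ndarray) -> ImageSeries:
    """Apply previously estimated shifts to a paired channel."""
    out = np.empty_like(series.data)
    for i, (frame, (dy, dx)) in enumerate(zip(series.data, shifts)):
        out[i] = np.roll(frame, (int(dy), int(dx)), axis=(0, 1))
    return ImageSeries(out, series.frame_rate, series.pixel_size, series.channel)


def preprocess(
    series: ImageSeries,
    percentile: float = 75.0,
) -> tuple[ImageSeries, np.ndarray, np.ndarray]:
    """3-D median filter plus a temporal-SD activity mask.

    A 3x3x3 median filter (reflect padding) suppresses acquisition
    noise; the mask keeps the top ``percentile`` percent of pixels by
    temporal standard deviation (default: top 75%).  Returns the
    filtered series, the boolean mask and the SD image.
    """
    if series.n_frames < 3:
        raise ValueError("need at least 3 frames for the 3-D median filter")
    filtered = ndimage.median_filter(series.data.astype(float), size=3, mode="reflect")
    sd = filtered.std(axis=0)
    if np.allclose(sd, sd.flat[0]):
        warnings.warn("constant series: empty activity mask", stacklevel=2)
        mask = np.zeros_like(sd, dtype=bool)
    else:
        mask = sd >= np.percentile(sd, 100.0 - percentile)
    out = ImageSeries(filtered, series.frame_rate, series.pixel_size, series.channel)
    return out, mask, sd


def _snap_seed(sd_image: np.ndarray, seed: tuple[int, int], n_nearest: int = 12):
    """Snap a manual seed to the peak position among its 12 nearest pixels."""
    rows, cols = np.indices(sd_image.shape)
    dist2 = (rows - seed[0]) ** 2 + (cols - seed[1]) ** 2
    order = np.argsort(dist2.ravel(), kind="stable")[:n_nearest]
    best = order[np.argmax(sd_image.ravel()[order])]
    return np.unravel_index(best, sd_image.shape)


def segment_rois(
    sd_image: np.ndarray,
    threshold: float | None = None,
    manual_seeds: list[tuple[int, int]] | None = None,
    min_distance: int = 2,
    pixel_size: float = 1.0,
) -> ROIMap:
    """Region-growing segmentation of the temporal-SD image.

    Local maxima above ``threshold`` (default: the 75th percentile of
    all pixel values) seed the ROIs; every above-threshold pixel is
    assigned to its nearest peak by geodesic distance within the mask,
    which guarantees a continuous connection between each pixel and its
    peak.  Manual seeds are snapped to the peak among their 12 nearest
    pixels.  Ties go to the lower peak index.
    """
    sd_image = np.asarray(sd_image, dtype=float)
    if threshold is None:
        threshold = float(np.percentile(sd_image, 75.0))
    mask = sd_image > threshold
    peaks = [
        tuple(p)
        for p in peak_local_max(sd_image, min_distance=min_distance,
                                threshold_abs=threshold, exclude_border=False)
    ]
    if manual_seeds:
        for s in manual_seeds:
            snapped = _snap_seed(sd_image, s)
            if snapped not in peaks:
                peaks.append(snapped)
    labels = np.zeros(sd_image.shape, dtype=np.int32)
    peaks = [p for p in peaks if mask[p]]
    if not peaks:
        return ROIMap(labels, [], pixel_size)

    # 4-connected graph over mask pixels, unit edge weights scaled by
    # pixel size; multi-source Dijkstra gives geodesic nearest-peak.
    idx = -np.ones(sd_image.shape, dtype=np.int64)
    ys, xs = np.nonzero(mask)
    idx[ys, xs] = np.arange(ys.size)
    rows_g, cols_g = [], []
    for dy, dx in ((0, 1), (1, 0)):
        y2, x2 = ys + dy, xs + dx
        ok = (y2 < mask.shape[0]) & (x2 < mask.shape[1])
        ok[ok] &= mask[y2[ok], x2[ok]]
        rows_g.extend(idx[ys[ok], xs[ok]])
        cols_g.extend(idx[y2[ok], x2[ok]])
    n = ys.size
    w = np.ones(len(rows_g))
    graph = sparse.coo_matrix((w, (rows_g, cols_g)), shape=(n, n))
    graph = graph + graph.T
    sources = [idx[p] for p in peaks]
    dist = dijkstra(graph.tocsr(), directed=False, indices=sources)
    # argmin over peaks; ties resolved by lower peak index (argmin rule)
    nearest = np.argmin(dist, axis=0)
    reachable = np.isfinite(dist[nearest, np.arange(n)])
    labels[ys[reachable], xs[reachable]] = nearest[reachable] + 1
    return ROIMap(labels, peaks, pixel_size)


def extract_epoched_traces(
    series: ImageSeries,
    roi_map: ROIMap,
    stimulus_log: list[tuple[str, float, float]],
    baseline_s: float = 0.5,
    post_s: float | None = None,
    mask: np.ndarray | None = None,
    subtract_baseline: bool = True,
    condition_values: dict[str, float] | None = None,
) -> EpochedResponses:
    """Cut per-ROI traces into condition-aligned, baseline-subtracted epochs.

    The ROI trace is the mean over the ROI's pixels (intersected with
    the activity ``mask`` when given); each log entry becomes one
    epoch running from ``baseline_s`` before onset to the epoch offset
    (or ``post_s`` after onset).  The mean of the pre-onset baseline
    window is subtracted.
    """
    rate = series.frame_rate
    n_frames = series.n_frames
    label_counts: dict[str, int] = {}
    # per-ROI traces
    traces = {}
    for r in range(1, roi_map.n_rois + 1):
        sel = roi_map.labels == r
        if mask is not None:
            inter = sel & mask
            if inter.any():
                sel = inter
        traces[r] = series.data[:, sel].mean(axis=1)

    pre = int(round(baseline_s * rate))
    # group epochs by condition label
    grouped: dict[str, list[tuple[int, int]]] = {}
    for label, onset, offset in stimulus_log:
        i0 = int(round(onset * rate))
        i1 = int(round(((onset + post_s) if post_s is not None else offset) * rate))
        if i1 > n_frames:
            warnings.warn(f"epoch '{label}' extends past series end: truncated", stacklevel=2)
            i1 = n_frames
        if i0 >= n_frames or i0 < 0:
            raise ValueError(f"epoch '{label}' outside the recording")
        grouped.setdefault(label, []).append((i0, i1))

    n_len = min(i1 - i0 for eps in grouped.values() for i0, i1 in eps)
    out: dict[tuple[int, str], np.ndarray] = {}
    for label, eps in grouped.items():
        for r, tr in traces.items():
            rows = []
            for i0, i1 in eps:
                lo = max(i0 - pre, 0)
                seg = tr[lo : i0 + n_len]
                if lo == 0 and i0 - pre < 0:
                    seg = np.concatenate([np.full(pre - i0, seg[0]), seg])
                if subtract_baseline and pre > 0:
                    seg = seg - seg[:pre].mean()
                rows.append(seg)
            out[(r, label)] = np.asarray(rows)
    times = (np.arange(pre + n_len) - pre) / rate
    return EpochedResponses(out, times, rate, condition_values or {})


def repeat_reliability(
    trials: np.ndarray | list[np.ndarray],
    max_splits: int = 200,
) -> float:
    """Median squared correlation between half-split trial averages.

    All balanced splits of the trials into two halves are evaluated;
    for each, the two half-averages are correlated and the squared
    coefficient retained; the median over splits is returned.  With two
    trials there is exactly one split.  Beyond ``max_splits`` possible
    splits (the count grows combinatorially), a deterministic random
    subsample of splits is used.
    """
    trials = np.asarray(trials, dtype=float)
    n = trials.shape[0]
    if n < 2:
        raise ValueError("need at least 2 trials")
    half = n // 2
    r2s = []
    rest = set(range(n))
    n_splits = comb(n - 1, half - 1)
    if n_splits <= max_splits:
        combos = itertools.combinations(range(1, n), half - 1)
    else:
        rng = np.random.default_rng(0)
        combos = {tuple(sorted(rng.choice(range(1, n), half - 1, replace=False)))
                  for _ in range(max_splits)}
    # fix trial 0 in the first half to avoid double-counting complements
    for combo in combos:
        a = (0,) + tuple(combo)
        b = tuple(rest - set(a))
        ma, mb = trials[list(a)].mean(axis=0), trials[list(b)].mean(axis=0)
        if ma.std() == 0 or mb.std() == 0:
            warnings.warn("zero-variance half-average: split scored 0", stacklevel=2)
            r2s.append(0.0)
        else:
            r2s.append(float(np.corrcoef(ma, mb)[0, 1] ** 2))
    return float(np.median(r2s))


def _correlation_rss(traces: np.ndarray, assignment: np.ndarray, k: int) -> float:
    """Sum of correlation distances from each trace to its cluster centroid."""
    rss = 0.0
    for c in range(k):
        members = traces[assignment == c]
        if members.shape[0] == 0:
            continue
        centroid = members.mean(axis=0)
        if centroid.std() == 0:
            rss += float(members.shape[0])
            continue
        for m in members:
            if m.std() == 0:
                rss += 1.0
            else:
                rss += 1.0 - float(np.corrcoef(m, centroid)[0, 1])
    return rss


def consolidate_rois(
    responses: np.ndarray,
    k_max: int = 10,
    planes: np.ndarray | None = None,
    seed: int = 0,
    n_init: int = 50,
) -> tuple[ClusterResult, np.ndarray]:
    """Merge functionally redundant ROIs via k-means and BIC.

    ROI response traces are clustered on their correlation structure
    (k-means on z-scored, unit-norm traces, for which squared Euclidean
    distance is proportional to correlation distance).  The number of
    clusters minimizes ``BIC = n ln(RSS/n) + k ln(n)`` where RSS is the
    summed correlation distance of traces to their cluster centroids.
    ROIs in the same cluster (and the same imaging plane, when plane
    ids are given) are merged by averaging.
    """
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    n = responses.shape[0]
    if n == 0:
        raise ValueError("no ROIs to consolidate")
    k_max = min(k_max, n)
    sd = responses.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (responses - responses.mean(axis=1, keepdims=True)) / sd
    z /= np.linalg.norm(z, axis=1, keepdims=True)

    best: ClusterResult | None = None
    curve: dict[int, float] = {}
    for k in range(1, k_max + 1):
        if k == 1:
            assignment = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
            assignment = km.fit_predict(z)
        rss = _correlation_rss(responses, assignment, k)
        # floor the RSS at the numerical noise of correlation estimates:
        # below it, splitting identical traces would shrink ln(RSS)
        # without bound and overwhelm the k ln(n) penalty
        bic = n * np.log(max(rss, n * 1e-6) / n) + k * np.log(n)
        curve[k] = float(bic)
        if best is None or bic < best.bic:
            best = ClusterResult(k, assignment, float(bic))
    best.bic_curve = curve

    if planes is None:
        planes = np.zeros(n, dtype=int)
    merged = []
    for c in range(best.k):
        for p in np.unique(planes):
            members = responses[(best.assignment == c) & (planes == p)]
            if members.shape[0]:
                merged.append(members.mean(axis=0))
    return best, np.asarray(merged)
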