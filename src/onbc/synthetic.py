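"""Synthetic stimuli, model cells, rendered recordings and axon arbors.

Raw recordings for this kind of study are rarely deposited, so every
downstream analysis stage is exercised against a generative model that
reproduces the statistical structure the analyses assume: spots of
varying size driving center-surround receptive fields, sinusoidal
modulation filtered through GCaMP6f kinetics, AR(1)-correlated noise,
repeated-trial structure, spatially correlated naturalistic surrogates
with coherent-motion segments, and axon-arbor skeletons whose ROIs
share a common signal with a distance-dependent correlation.

Movies are stored in contrast units on [-0.5, 0.5] around the adapting
background (0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import distance_matrix

from .imaging import ImageSeries
from .temporal import gcamp_kernel

__all__ = [
    "StimulusMovie",
    "CellParams",
    "ArborModel",
    "SPOT_SIZES_UM",
    "SINE_FREQS_HZ",
    "default_cell_params",
    "generate_spot_stimulus",
    "generate_freq_stimulus",
    "generate_checkerboard",
    "generate_naturalistic_surrogate",
    "simulate_cell_response",
    "render_image_series",
    "generate_arbor",
]

#: spot diameters of the varying-size spot protocol, um
SPOT_SIZES_UM = (20.0, 50.0, 100.0, 200.0, 400.0, 600.0, 800.0)
#: temporal frequencies of the sinusoidal protocol, Hz
SINE_FREQS_HZ = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)


@dataclass
class StimulusMovie:
    """Luminance movie with a stimulus log.

    ``frames`` holds contrast values in [-0.5, 0.5]; ``log`` lists
    (condition label, onset s, offset s) epochs, non-overlapping and
    within the movie duration.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size: float
    log: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def duration(self) -> float:
        return self.frames.shape[0] / self.frame_rate

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def epochs(self, prefix: str = "") -> list[tuple[str, float, float]]:
        return [e for e in self.log if e[0].startswith(prefix)]

    def extent_um(self) -> tuple[float, float]:
        """Field of view (height, width) in micrometers."""
        return (self.frames.shape[1] * self.pixel_size, self.frames.shape[2] * self.pixel_size)

    def save(self, path: str | Path) -> None:
        """Write frames as multi-page TIFF with a JSON sidecar."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.frames.astype(np.float32))
        meta = {
            "frame_rate": self.frame_rate,
            "pixel_size": self.pixel_size,
            "log": [list(e) for e in self.log],
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "StimulusMovie":
        import tifffile

        path = Path(path)
        frames = tifffile.imread(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        log = [(str(l), float(a), float(b)) for l, a, b in meta["log"]]
        return cls(frames, meta["frame_rate"], meta["pixel_size"], log)


@dataclass
class CellParams:
    """Parameters of a linear-nonlinear model bipolar cell.

    The receptive field is a Gaussian center (SD = center_radius / 2)
    opposed by an annular surround; ``transience_tau`` sets the
    high-pass (adaptation) time constant, so small values give
    transient and large values sustained step responses.
    """

    type_label: str
    center_radius: float = 25.0  # um
    surround_radius: float = 300.0  # um
    surround_weight: float = 0.5
    transience_tau: float = 1.0  # s
    latency_s: float = 0.2  # response delay between stimulus and drive
    motion_gain: float = 0.0
    baseline: float = 1.0
    noise_phi: float = 0.5
    noise_sd: float = 0.02
    rf_center: tuple[float, float] = (0.0, 0.0)  # um from field center
    ipl_depth: float = 0.5

    def __post_init__(self) -> None:
        if self.surround_radius <= self.center_radius:
            raise ValueError("surround_radius must exceed center_radius")
        if not 0.0 <= self.ipl_depth <= 1.0:
            raise ValueError("ipl_depth must lie in [0, 1]")
        if not -1.0 < self.noise_phi < 1.0:
            raise ValueError("noise_phi must lie in (-1, 1)")


@dataclass
class ArborModel:
    """Planar tree skeleton with ROI attachment nodes.

    ``length_constant`` may be ``inf``, meaning a perfectly homogeneous
    arbor whose ROIs all carry the shared signal.
    """

    nodes: np.ndarray  # (n, 3) um
    edges: list[tuple[int, int]]
    roi_nodes: np.ndarray  # indices into nodes
    diameter: float  # equivalent diameter of the arbor territory, um
    shared_signal: np.ndarray
    local_noise_sd: float
    length_constant: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")

    @property
    def roi_positions(self) -> np.ndarray:
        return self.nodes[self.roi_nodes]


# ---------------------------------------------------------------------------
# stimulus generators
# ---------------------------------------------------------------------------


def _disk_mask(shape: tuple[int, int], pixel_size: float, diameter: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.indices((h, w), dtype=float)
    y_um = (yy - (h - 1) / 2) * pixel_size
    x_um = (xx - (w - 1) / 2) * pixel_size
    return y_um**2 + x_um**2 <= (diameter / 2) ** 2


def _default_field(max_diameter: float, pixel_size: float) -> tuple[int, int]:
    n = int(np.ceil(max_diameter * 1.06 / pixel_size))
    return (n, n)


def generate_spot_stimulus(
    sizes: tuple[float, ...] = SPOT_SIZES_UM,
    on_s: float = 1.5,
    off_s: float = 1.5,
    repeats: int = 5,
    frame_rate: float = 10.0,
    pixel_size: float = 8.0,
    gap_s: float = 1.5,
    shape: tuple[int, int] | None = None,
    seed: int = 0,
) -> StimulusMovie:
    """Varying-size spot protocol.

    Spot sizes are presented in a seeded pseudorandom order; each size
    runs ``repeats`` consecutive ON (bright disk, +0.5) / OFF (dark
    disk, -0.5) cycles, with ``gap_s`` of background between sizes.
    The log records one entry per ON and per OFF phase, labelled
    ``spot{size}_on`` / ``spot{size}_off``.
    """
    sizes = tuple(float(s) for s in sizes)
    if any(s <= 0 for s in sizes):
        raise ValueError("spot sizes must be positive")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if on_s <= 0 or off_s <= 0:
        raise ValueError("phase durations must be positive")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sizes))
    if shape is None:
        shape = _default_field(max(sizes), pixel_size)

    total = len(sizes) * repeats * (on_s + off_s) + (len(sizes) - 1) * gap_s
    n_frames = int(round(total * frame_rate))
    frames = np.zeros((n_frames,) + shape, dtype=np.float32)
    log: list[tuple[str, float, float]] = []
    masks = {s: _disk_mask(shape, pixel_size, s) for s in sizes}

    t = 0.0
    for block, si in enumerate(order):
        size = sizes[si]
        for _ in range(repeats):
            for phase, dur, value in (("on", on_s, 0.5), ("off", off_s, -0.5)):
                i0, i1 = int(round(t * frame_rate)), int(round((t + dur) * frame_rate))
                frames[i0:i1, masks[size]] = value
                log.append((f"spot{size:g}_{phase}", t, t + dur))
                t += dur
        if block < len(sizes) - 1:
            t += gap_s
    return StimulusMovie(frames, frame_rate, pixel_size, log)


def generate_freq_stimulus(
    freqs: tuple[float, ...] = SINE_FREQS_HZ,
    diameters: tuple[float, ...] = (150.0, 800.0),
    dur_s: float = 2.0,
    frame_rate: float = 52.5,
    repeats: int = 5,
    gap_s: float = 1.5,
    pixel_size: float = 8.0,
    shape: tuple[int, int] | None = None,
    seed: int = 0,
) -> StimulusMovie:
    """Sinusoidally modulated spots at several temporal frequencies.

    For each spot diameter, every frequency appears ``repeats`` times in
    a seeded pseudorandom sequence with background gaps.  The sinusoid
    spans the full contrast range (amplitude 0.5 around background).
    """
    freqs = tuple(float(f) for f in freqs)
    if any(f >= frame_rate / 2 for f in freqs):
        raise ValueError("all frequencies must be below the Nyquist rate")
    if dur_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    if shape is None:
        shape = _default_field(max(diameters), pixel_size)

    n_ep = len(freqs) * repeats
    total = len(diameters) * (n_ep * (dur_s + gap_s))
    n_frames = int(round(total * frame_rate))
    frames = np.zeros((n_frames,) + shape, dtype=np.float32)
    log: list[tuple[str, float, float]] = []
    t = 0.0
    for diam in diameters:
        mask = _disk_mask(shape, pixel_size, diam)
        seq = rng.permutation(np.repeat(freqs, repeats))
        for f in seq:
            i0, i1 = int(round(t * frame_rate)), int(round((t + dur_s) * frame_rate))
            tt = np.arange(i1 - i0) / frame_rate
            frames[i0:i1, mask] = (0.5 * np.sin(2 * np.pi * f * tt))[:, None].astype(np.float32)
            log.append((f"sine{f:g}Hz_d{diam:g}", t, t + dur_s))
            t += dur_s + gap_s
    return StimulusMovie(frames, frame_rate, pixel_size, log)


def generate_checkerboard(
    n_unique: int = 900,
    square_um: float = 20.0,
    grid: tuple[int, int] = (15, 20),
    p_on: float = 0.5,
    frame_rate: float = 5.0,
    pixels_per_square: int = 2,
    seed: int = 0,
) -> StimulusMovie:
    """Binary checkerboard white noise, shown twice.

    Each frame is a ``grid`` of ``square_um`` squares set ON (+0.5)
    with probability ``p_on``; the ``n_unique`` frame sequence is
    repeated once more to gauge response quality, with the repeat
    recorded in the per-frame log labels.
    """
    if not 0 < p_on < 1:
        raise ValueError("p_on must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    unique = rng.random((n_unique,) + grid) < p_on
    frames_small = np.where(unique, 0.5, -0.5).astype(np.float32)
    frames_small = np.concatenate([frames_small, frames_small])
    frames = np.kron(frames_small, np.ones((1, pixels_per_square, pixels_per_square), np.float32))
    dt = 1.0 / frame_rate
    log = [
        (f"check_rep{1 + i // n_unique}_frame{i % n_unique}", i * dt, (i + 1) * dt)
        for i in range(2 * n_unique)
    ]
    return StimulusMovie(frames, frame_rate, square_um / pixels_per_square, log)


def generate_naturalistic_surrogate(
    duration_s: float,
    motion_segments: list[tuple[float, float, float, float]] | None = None,
    spatial_exponent: float = 2.0,
    frame_rate: float = 60.0,
    shape: tuple[int, int] = (64, 64),
    pixel_size: float = 2.0,
    seed: int = 0,
) -> StimulusMovie:
    """Power-law-correlated luminance field with rigid-motion segments.

    A static 1/f^``spatial_exponent`` random field is sampled through a
    window that translates rigidly at (vx, vy) um/s during each
    ``(t0, t1, vx, vy)`` motion segment and stays put elsewhere.
    Luminance is rescaled to [-0.5, 0.5].  The log records one entry
    per motion segment (``motion``) and per static interval
    (``static``).
    """
    if frame_rate <= 0 or duration_s <= 0:
        raise ValueError("duration and frame rate must be positive")
    motion_segments = sorted(motion_segments or [])
    for (a0, a1, *_), (b0, b1, *_) in zip(motion_segments, motion_segments[1:]):
        if b0 < a1:
            raise ValueError("motion segments must not overlap")
    for t0, t1, *_ in motion_segments:
        if t0 < 0 or t1 > duration_s or t1 <= t0:
            raise ValueError("motion segments must lie within the duration")

    n_frames = int(round(duration_s * frame_rate))
    dt = 1.0 / frame_rate
    # integrate the displacement path (pixels)
    disp = np.zeros((n_frames, 2))
    for t0, t1, vx, vy in motion_segments:
        tm = np.arange(n_frames) * dt
        active = np.clip(np.minimum(tm + dt, t1) - np.maximum(tm, t0), 0, None)
        disp[:, 0] += np.cumsum(active * vy / pixel_size)
        disp[:, 1] += np.cumsum(active * vx / pixel_size)

    pad = int(np.ceil(np.abs(disp).max())) + 4 if n_frames else 4
    rng = np.random.default_rng(seed)
    big = _power_law_field((shape[0] + 2 * pad, shape[1] + 2 * pad), spatial_exponent, rng)

    yy, xx = np.indices(shape, dtype=float)
    frames = np.empty((n_frames,) + shape, dtype=np.float32)
    for i in range(n_frames):
        coords = np.array([yy + pad + disp[i, 0], xx + pad + disp[i, 1]])
        frames[i] = ndimage.map_coordinates(big, coords, order=3, mode="reflect")
    lo, hi = frames.min(), frames.max()
    if hi > lo:
        frames[:] = (frames - lo) / (hi - lo) - 0.5

    log: list[tuple[str, float, float]] = []
    t_cursor = 0.0
    for t0, t1, vx, vy in motion_segments:
        if t0 > t_cursor:
            log.append(("static", t_cursor, t0))
        log.append((f"motion_vx{vx:g}_vy{vy:g}", t0, t1))
        t_cursor = t1
    if t_cursor < duration_s:
        log.append(("static", t_cursor, duration_s))
    return StimulusMovie(frames, frame_rate, pixel_size, log)


def _power_law_field(shape: tuple[int, int], exponent: float, rng: np.random.Generator):
    """Random field with an isotropic 1/f^exponent amplitude spectrum."""
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f = np.sqrt(fy**2 + fx**2)
    f[0, 0] = 1.0
    amp = f ** (-exponent / 2.0)
    amp[0, 0] = 0.0
    phase = rng.uniform(0, 2 * np.pi, shape)
    spec = amp * np.exp(1j * phase)
    return np.real(np.fft.ifft2(spec))


# ---------------------------------------------------------------------------
# model-cell simulation and rendering
# ---------------------------------------------------------------------------


def _rf_weights(cell: CellParams, movie: StimulusMovie):
    """Center Gaussian weights and surround-annulus mask on the movie grid."""
    h, w = movie.shape
    yy, xx = np.indices((h, w), dtype=float)
    y_um = (yy - (h - 1) / 2) * movie.pixel_size - cell.rf_center[1]
    x_um = (xx - (w - 1) / 2) * movie.pixel_size - cell.rf_center[0]
    r2 = y_um**2 + x_um**2
    sigma = cell.center_radius / 2.0
    center = np.exp(-r2 / (2 * sigma**2))
    surround = (r2 > cell.center_radius**2) & (r2 <= cell.surround_radius**2)
    return center, surround


def spot_drive_components(
    cell: CellParams, diameter: float, pixel_size: float, shape: tuple[int, int] | None = None
) -> tuple[float, float]:
    """Steady-state center and surround activation of a +0.5 contrast spot.

    Useful for calibrating ``surround_weight`` analytically: the linear
    drive to a spot of a given diameter is ``0.5 * (c - w * s)`` with
    (c, s) the values returned here.
    """
    if shape is None:
        shape = _default_field(max(diameter, cell.surround_radius * 2), pixel_size)
    frame = np.where(_disk_mask(shape, pixel_size, diameter), 1.0, 0.0)
    movie = StimulusMovie(frame[None], 1.0, pixel_size)
    center, surround = _rf_weights(cell, movie)
    c = float((center * frame).sum() / center.sum())
    s = float(frame[surround].mean()) if surround.any() else 0.0
    return c, s


def calibrate_surround_weight(
    cell: CellParams,
    target_ratio: float,
    small_um: float = 150.0,
    large_um: float = 800.0,
    pixel_size: float = 8.0,
) -> float:
    """Surround weight giving a target large/small spot response ratio.

    Solves ``(c_L - w s_L) / (c_S - w s_S) = target_ratio`` for w using
    the steady-state drives of the two spot diameters; a ratio of 0.34
    reproduces the strong suppression of upper-block cells, negative
    ratios the response inversion of strongly suppressed types.
    """
    c_s, s_s = spot_drive_components(cell, small_um, pixel_size)
    c_l, s_l = spot_drive_components(cell, large_um, pixel_size)
    return (c_l - target_ratio * c_s) / (s_l - target_ratio * s_s)


def default_cell_params(pixel_size: float = 8.0) -> dict[str, CellParams]:
    """Model parameters for the seven ON cone bipolar cell types.

    Set-points follow the qualitative organisation of the population:
    the four upper-block types (BC5o, BC5i, BC5t, XBC) share strong
    surround suppression (large/small spot ratio 0.34) but span the
    transient-to-sustained axis, whereas the three lower-block types
    share sustained kinetics but differ in surround strength, with BC7
    inverting its response to large spots.
    """
    set_points = {
        #  label     ratio  tau    depth
        "BC5o": (0.34, 0.45, 0.47),
        "BC5i": (0.34, 0.80, 0.53),
        "BC5t": (0.34, 8.00, 0.58),
        "XBC": (0.34, 0.18, 0.62),
        "BC6": (0.60, 3.00, 0.70),
        "BC7": (-0.20, 3.50, 0.78),
        "BC8/9": (0.55, 4.00, 0.88),
    }
    out = {}
    for label, (ratio, tau, depth) in set_points.items():
        cell = CellParams(type_label=label, transience_tau=tau, ipl_depth=depth)
        w = calibrate_surround_weight(cell, ratio, pixel_size=pixel_size)
        out[label] = replace(cell, surround_weight=w)
    return out


def _ema(x: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """First-order exponential moving average (discrete low-pass)."""
    from scipy.signal import lfilter

    alpha = dt / (tau + dt)
    return lfilter([alpha], [1.0, alpha - 1.0], x)


def simulate_cell_response(
    cell: CellParams,
    movie: StimulusMovie,
    sampling_rate: float = 9.5,
    seed: int = 0,
    gain: float = 1.0,
) -> np.ndarray:
    """Simulate a calcium trace of a model cell viewing a movie.

    Linear center-surround drive (Gaussian-weighted center minus
    ``surround_weight`` times the surround-annulus mean), high-pass
    filtered with ``transience_tau``, rectified, convolved with the
    GCaMP6f kernel, resampled to the acquisition rate, and summed with
    the baseline and AR(1) noise.  Deterministic given the seed.
    """
    half_h, half_w = (s * movie.pixel_size / 2 for s in movie.shape)
    if abs(cell.rf_center[0]) > half_w or abs(cell.rf_center[1]) > half_h:
        raise ValueError("receptive field lies outside the movie extent")
    center, surround = _rf_weights(cell, movie)
    flat = movie.frames.reshape(movie.frames.shape[0], -1)
    c = flat @ (center.ravel() / center.sum())
    s = flat[:, surround.ravel()].mean(axis=1) if surround.any() else np.zeros(flat.shape[0])
    drive = c - cell.surround_weight * s

    dt = 1.0 / movie.frame_rate
    lat = int(round(cell.latency_s * movie.frame_rate))
    if lat > 0:
        drive = np.concatenate([np.full(lat, drive[0]), drive[:-lat]])
    hp = drive - _ema(drive, cell.transience_tau, dt)
    # rectify with headroom: calcium can dip below baseline, so strong
    # suppression (e.g. large-spot drives of inverting types) remains
    # visible as a negative deflection rather than clipping to zero
    rect = np.clip(hp, -cell.baseline, None)

    kern = gcamp_kernel(rate=movie.frame_rate, duration=1.5).kernel
    kern = kern / kern.sum()
    resp = np.convolve(rect, kern)[: rect.size]

    n_out = int(round(movie.duration * sampling_rate))
    t_out = np.arange(n_out) / sampling_rate
    t_in = np.arange(resp.size) * dt
    resampled = np.interp(t_out, t_in, resp)

    rng = np.random.default_rng(seed)
    noise = np.zeros(n_out)
    if cell.noise_sd > 0:
        from scipy.signal import lfilter

        innov_sd = cell.noise_sd * np.sqrt(1 - cell.noise_phi**2)
        eps = rng.normal(0.0, innov_sd, n_out)
        noise = lfilter([1.0], [1.0, -cell.noise_phi], eps)
    return cell.baseline + gain * resampled + noise


def render_image_series(
    roi_positions_um: np.ndarray,
    responses: np.ndarray,
    frame_rate: float,
    pixel_size: float = 1.0,
    shape: tuple[int, int] = (32, 32),
    blob_sigma_um: float = 2.0,
    photon_noise_sd: float = 0.0,
    seed: int = 0,
) -> ImageSeries:
    """Render per-ROI traces into a movie of Gaussian blobs plus noise.

    Each ROI becomes a max-normalized 2-D Gaussian at its position
    (um, relative to the field center) whose intensity follows its
    trace; i.i.d. Gaussian noise is added.  Bit-identical for a given
    seed.
    """
    roi_positions_um = np.atleast_2d(np.asarray(roi_positions_um, dtype=float))
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    if roi_positions_um.shape[0] != responses.shape[0]:
        raise ValueError("one trace per ROI required")
    h, w = shape
    yy, xx = np.indices((h, w), dtype=float)
    blobs = []
    for x_um, y_um in roi_positions_um:
        if abs(x_um) > w * pixel_size / 2 or abs(y_um) > h * pixel_size / 2:
            raise ValueError("ROI position outside the field of view")
        cy = (h - 1) / 2 + y_um / pixel_size
        cx = (w - 1) / 2 + x_um / pixel_size
        g = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) * pixel_size**2) / (2 * blob_sigma_um**2))
        blobs.append(g)
    blobs = np.asarray(blobs)
    frames = np.tensordot(responses.T, blobs, axes=(1, 0))
    if photon_noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, photon_noise_sd, frames.shape)
    return ImageSeries(frames.astype(np.float64), frame_rate, pixel_size)


# ---------------------------------------------------------------------------
# axon arbors
# ---------------------------------------------------------------------------


def generate_arbor(
    n_rois: int,
    diameter: float,
    length_constant: float,
    shared_signal: np.ndarray,
    local_noise_sd: float = 0.3,
    n_repeats: int = 2,
    seed: int = 0,
) -> tuple[ArborModel, np.ndarray]:
    """Random planar tree arbor with distance-correlated ROI signals.

    Skeleton nodes are sampled in a disk of the given equivalent
    diameter and joined by their minimum spanning tree.  Node signals
    follow a Markov process along the tree in which the correlation
    between any two nodes equals ``exp(-d / length_constant)`` with d
    the path distance; ``inf`` makes every ROI carry the shared signal
    exactly.  Per-ROI, per-repeat traces add independent local noise.

    Returns the arbor and a (n_rois, n_repeats, n_samples) trace array.
    """
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    if np.isfinite(length_constant) and length_constant <= 0:
        raise ValueError("finite length_constant must be positive")
    rng = np.random.default_rng(seed)
    shared = np.asarray(shared_signal, dtype=float)
    z = (shared - shared.mean()) / shared.std()

    n_nodes = max(40, 2 * n_rois)
    r = diameter / 2 * np.sqrt(rng.random(n_nodes))
    th = rng.uniform(0, 2 * np.pi, n_nodes)
    nodes = np.column_stack([r * np.cos(th), r * np.sin(th), rng.normal(0, 0.5, n_nodes)])
    mst = minimum_spanning_tree(distance_matrix(nodes, nodes)).tocoo()
    edges = list(zip(mst.row.tolist(), mst.col.tolist()))

    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_nodes)}
    for u, v in edges:
        d = float(np.linalg.norm(nodes[u] - nodes[v]))
        adj[u].append((v, d))
        adj[v].append((u, d))

    signals = np.empty((n_nodes, z.size))
    signals[0] = z
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v, d in adj[u]:
            if v in seen:
                continue
            rho = np.exp(-d / length_constant) if np.isfinite(length_constant) else 1.0
            innov = rng.normal(0.0, 1.0, z.size)
            signals[v] = rho * signals[u] + np.sqrt(max(0.0, 1 - rho**2)) * innov
            seen.add(v)
            stack.append(v)

    roi_nodes = rng.choice(n_nodes, size=n_rois, replace=False)
    traces = (
        signals[roi_nodes][:, None, :]
        + rng.normal(0.0, local_noise_sd, (n_rois, n_repeats, z.size))
    )
    arbor = ArborModel(
        nodes=nodes,
        edges=edges,
        roi_nodes=roi_nodes,
        diameter=diameter,
        shared_signal=shared,
        local_noise_sd=local_noise_sd,
        length_constant=length_constant,
    )
    return arbor, traces
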