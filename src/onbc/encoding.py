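"""Population encoding space and feature-axis geometry.

Pairwise correlation distances between response traces are embedded by
weighted nonmetric multidimensional scaling (MDS) into a 16-dimensional
encoding space; outlying distances receive zero weight, per-coordinate
explained variance orders the axes, the Jensen-Shannon divergence (JSD)
of kernel-smoothed 2-D densities tests for batch effects, and feature
gradients through the space are summarised as vectors whose mutual
angles quantify how independently features are encoded.

Nonmetric MDS is solved by SMACOF with isotonic disparities; the
in-package solver exists because the weight mask is part of the
contract and off-the-shelf implementations do not accept one.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import gaussian_kde
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "DistanceMatrix",
    "EncodingSpace",
    "masked_distance_matrix",
    "nonmetric_mds",
    "coordinate_explained_variance",
    "jsd_2d",
    "batch_effect_test",
    "feature_axis",
    "vector_angle",
    "angle_subsample_distribution",
]


@dataclass
class DistanceMatrix:
    """Symmetric correlation-distance matrix with a binary weight mask."""

    d: np.ndarray
    w: np.ndarray
    masked_fraction: float = 0.0
    triangle_violation_rate: float = 0.0

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class EncodingSpace:
    """Principal coordinates ordered by explained variance."""

    coords: np.ndarray  # (n, dims)
    stress: float
    explained_r2: np.ndarray  # per coordinate, cumulative basis-free
    converged: bool = True
    distance: DistanceMatrix | None = field(default=None, repr=False)


def _triangle_violation_rate(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 3:
        return 0.0
    viol = total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += 1
        if np.any(d[i] + d[j] < d[i, j] - 1e-12):
            viol += 1
    return viol / total


def masked_distance_matrix(
    responses: np.ndarray,
    n_sd: float = 3.0,
) -> DistanceMatrix:
    """Pairwise correlation distances with a 3-SD outlier weight mask.

    Distances deviating from the mean by more than ``n_sd`` standard
    deviations get zero weight; zero-variance units are dropped with a
    warning.  The masked fraction and the rate of triangle-inequality
    violations (tolerated by the nonmetric embedding) are recorded.
    """
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    keep = responses.std(axis=1) > 0
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} zero-variance units", stacklevel=2)
        responses = responses[keep]
    n = responses.shape[0]
    if n < 3:
        raise ValueError("need at least 3 units")
    d = squareform(pdist(responses, metric="correlation"))
    np.fill_diagonal(d, 0.0)
    tri = d[np.triu_indices(n, 1)]
    mu, sd = tri.mean(), tri.std()
    w = np.ones_like(d)
    if sd > 0:
        outlier = np.abs(d - mu) > n_sd * sd
        w[outlier] = 0.0
    np.fill_diagonal(w, 0.0)
    masked = float(np.mean(w[np.triu_indices(n, 1)] == 0.0))
    return DistanceMatrix(d, w, masked, _triangle_violation_rate(d))


def _classical_mds(d: np.ndarray, dims: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def _stress1(d_emb: np.ndarray, disp: np.ndarray, w: np.ndarray) -> float:
    num = np.sum(w * (d_emb - disp) ** 2)
    den = np.sum(w * d_emb**2)
    return float(np.sqrt(num / den)) if den > 0 else 0.0


def _smacof_weighted(
    d: np.ndarray, w: np.ndarray, x0: np.ndarray, max_iter: int, tol: float = 1e-7
) -> tuple[np.ndarray, float, bool]:
    """Weighted nonmetric SMACOF: isotonic disparities + Guttman updates."""
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    wf = w[iu]
    df = d[iu]
    active = wf > 0
    order = np.argsort(df[active], kind="stable")
    iso = IsotonicRegression(increasing=True)
    v = np.diag(w.sum(axis=1)) - w
    v_pinv = np.linalg.pinv(v)
    x = x0.copy()
    prev = np.inf
    stress = np.inf
    converged = False
    for _ in range(max_iter):
        d_emb = squareform(pdist(x))
        de = d_emb[iu][active]
        # monotone regression of embedded distances on dissimilarity rank
        disp_act = iso.fit_transform(df[active][order], de[order])
        disp_f = np.zeros_like(df)
        tmp = np.empty_like(disp_act)
        tmp[order] = disp_act
        disp_f[active] = tmp
        # normalize disparities to the scale of the embedded distances
        scale = np.sqrt(np.sum(wf * de**2) / max(np.sum(wf * disp_f[active] ** 2), 1e-300))
        disp_f = disp_f * scale
        disp = squareform(disp_f)
        stress = _stress1(d_emb, disp, w)
        if prev - stress < tol:
            converged = True
            break
        prev = stress
        # weighted Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d_emb > 0, disp / np.where(d_emb > 0, d_emb, 1.0), 0.0)
        b = -w * ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = v_pinv @ (b @ x)
    return x, stress, converged


def coordinate_explained_variance(
    distance: DistanceMatrix,
    coords: np.ndarray,
    subset: list[int] | np.ndarray,
) -> float:
    """Squared correlation between input and sub-coordinate distances.

    Euclidean distances in the selected coordinate subset are compared
    with the masked entries of the input distance matrix; masked pairs
    are excluded on both sides.
    """
    subset = np.atleast_1d(np.asarray(subset, dtype=int))
    if subset.size == 0:
        raise ValueError("subset must be non-empty")
    iu = np.triu_indices(distance.n, 1)
    keep = distance.w[iu] > 0
    if not keep.any():
        raise ValueError("all pairs masked")
    d_sub = pdist(coords[:, subset])
    return float(np.corrcoef(distance.d[iu][keep], d_sub[keep])[0, 1] ** 2)


def nonmetric_mds(
    distance: DistanceMatrix,
    dims: int = 16,
    max_iter: int = 2000,
    n_restarts: int = 4,
    seed: int = 0,
) -> EncodingSpace:
    """Weighted nonmetric MDS of a masked distance matrix.

    Starts from the classical-MDS solution plus ``n_restarts`` random
    initialisations, keeps the lowest-stress embedding, rotates it to
    its principal axes and orders the coordinates by the variance each
    explains of the masked input distances.
    """
    rng = np.random.default_rng(seed)
    dims = min(dims, distance.n - 1)
    inits = [_classical_mds(distance.d, dims)]
    scale = distance.d.max() if distance.d.max() > 0 else 1.0
    inits += [rng.normal(0, scale / 4, (distance.n, dims)) for _ in range(n_restarts)]
    best = None
    for x0 in inits:
        x, stress, conv = _smacof_weighted(distance.d, distance.w, x0, max_iter)
        if best is None or stress < best[1]:
            best = (x, stress, conv)
    x, stress, conv = best
    if not conv:
        warnings.warn(f"MDS did not converge within {max_iter} iterations "
                      f"(final stress {stress:.4f})", stacklevel=2)
    x = x - x.mean(axis=0)
    # rotate to principal axes, then order by explained variance;
    # degenerate (zero-variance) coordinates explain nothing
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    r2 = np.array([
        coordinate_explained_variance(distance, x, [i]) if x[:, i].std() > 1e-12
        else 0.0
        for i in range(x.shape[1])
    ])
    r2 = np.nan_to_num(r2, nan=0.0)
    order = np.argsort(r2, kind="stable")[::-1]
    return EncodingSpace(x[:, order], stress, r2[order], conv, distance)


# ---------------------------------------------------------------------------
# Jensen-Shannon divergence and batch effects
# ---------------------------------------------------------------------------


def _kde_on_grid(points: np.ndarray, grid: np.ndarray, bandwidth) -> np.ndarray:
    kde = gaussian_kde(points.T, bw_method=bandwidth)
    p = kde(grid)
    s = p.sum()
    if s <= 0:
        raise ValueError("degenerate density")
    return p / s


def _kl(p: np.ndarray, m: np.ndarray) -> float:
    sel = p > 0
    return float(np.sum(p[sel] * np.log(p[sel] / m[sel])))


def jsd_2d(
    a: np.ndarray,
    b: np.ndarray,
    bandwidth: float | str | None = None,
    grid_size: int = 60,
    pad: float = 0.25,
) -> float:
    """Jensen-Shannon divergence of two 2-D point sets.

    Each set is kernel-smoothed (Gaussian KDE, Silverman bandwidth by
    default) on a shared grid covering both; the discrete JSD
    ``0.5 * KL(P||M) + 0.5 * KL(Q||M)`` with ``M = (P + Q) / 2`` is
    returned in nats, bounded by ln 2.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] < 5 or b.shape[0] < 5:
        raise ValueError("need at least 5 points per set")
    if np.allclose(a.std(axis=0), 0) or np.allclose(b.std(axis=0), 0):
        raise ValueError("degenerate (all-identical) point set")
    both = np.vstack([a, b])
    lo, hi = both.min(axis=0), both.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    lo, hi = lo - pad * span, hi + pad * span
    gx, gy = np.meshgrid(np.linspace(lo[0], hi[0], grid_size),
                         np.linspace(lo[1], hi[1], grid_size))
    grid = np.vstack([gx.ravel(), gy.ravel()])
    bw = bandwidth if bandwidth is not None else "silverman"
    p = _kde_on_grid(a, grid, bw)
    q = _kde_on_grid(b, grid, bw)
    m = 0.5 * (p + q)
    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def batch_effect_test(
    coords: np.ndarray,
    batch_labels: np.ndarray,
    n_batch_splits: int = 2000,
    n_random: int = 20000,
    seed: int = 0,
    grid_size: int = 40,
) -> dict:
    """Test whether recording batches shape the encoding-space density.

    Batch splits partition whole batches into two groups and measure
    the JSD between the two point clouds (first two coordinates);
    random splits partition the pooled points irrespective of batch.
    Under the null hypothesis that batch identity does not shape the
    distribution, batch-split JSDs resemble random-split JSDs; the
    one-sided p-value is the fraction of random-split JSDs at least as
    large as the median batch-split JSD.
    """
    coords = np.asarray(coords, dtype=float)[:, :2]
    batch_labels = np.asarray(batch_labels)
    batches = np.unique(batch_labels)
    if batches.size < 4:
        raise ValueError("need at least 4 batches")
    rng = np.random.default_rng(seed)
    n = coords.shape[0]

    def _jsd(mask: np.ndarray) -> float | None:
        a, b = coords[mask], coords[~mask]
        if a.shape[0] < 5 or b.shape[0] < 5:
            return None
        try:
            return jsd_2d(a, b, grid_size=grid_size)
        except ValueError:
            return None

    batch_jsd = []
    attempts = 0
    while len(batch_jsd) < n_batch_splits and attempts < 10 * n_batch_splits:
        attempts += 1
        side = rng.random(batches.size) < 0.5
        if side.all() or not side.any():
            continue
        mask = np.isin(batch_labels, batches[side])
        v = _jsd(mask)
        if v is not None:
            batch_jsd.append(v)
    random_jsd = []
    attempts = 0
    while len(random_jsd) < n_random and attempts < 10 * n_random:
        attempts += 1
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, n // 2, replace=False)] = True
        v = _jsd(mask)
        if v is not None:
            random_jsd.append(v)
    batch_jsd, random_jsd = np.asarray(batch_jsd), np.asarray(random_jsd)
    med = float(np.median(batch_jsd))
    p = float((1 + np.sum(random_jsd >= med)) / (1 + random_jsd.size))
    return {"p": p, "median_batch_jsd": med, "batch_jsd": batch_jsd,
            "random_jsd": random_jsd}


# ---------------------------------------------------------------------------
# feature axes
# ---------------------------------------------------------------------------


def feature_axis(coords: np.ndarray, feature: np.ndarray) -> np.ndarray:
    """Mean pairwise feature-gradient vector through the encoding space.

    ``v = (1/n) * sum_{i,j} (w_i - w_j)(v_i - v_j)`` over all ordered
    point pairs, where w is the feature value and v the position in
    the (typically 3-D) encoding space.  Points with larger feature
    values pull the vector toward their side of the cloud.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    feature = np.asarray(feature, dtype=float)
    if not np.all(np.isfinite(feature)):
        raise ValueError("feature values must be finite")
    n = coords.shape[0]
    if feature.std() == 0:
        warnings.warn("constant feature: zero axis vector", stacklevel=2)
        return np.zeros(coords.shape[1])
    total = 2.0 * (n * (feature[:, None] * coords).sum(axis=0)
                   - feature.sum() * coords.sum(axis=0))
    return total / n


def vector_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("angle undefined for a zero vector")
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def angle_subsample_distribution(
    coords: np.ndarray,
    feature: np.ndarray,
    n_pairs: int = 90,
    n_iter: int = 1000,
    seed: int = 0,
    cone_deg: float = 20.0,
) -> dict:
    """Angular spread of subsampled feature axes around the population axis.

    Each iteration draws ``n_pairs`` distinct point pairs, computes the
    pair-restricted feature-gradient vector and its angle to the
    full-data axis.  A tight angle distribution (most subsamples within
    ``cone_deg``) indicates that the feature organises the population
    rather than a few extreme cells.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    all_pairs = list(itertools.combinations(range(n), 2))
    if n_pairs > len(all_pairs):
        warnings.warn(f"n_pairs capped at {len(all_pairs)} available pairs", stacklevel=2)
        n_pairs = len(all_pairs)
    v_full = feature_axis(coords, feature)
    rng = np.random.default_rng(seed)
    pair_arr = np.asarray(all_pairs)
    angles = np.empty(n_iter)
    for it in range(n_iter):
        sel = pair_arr[rng.choice(len(all_pairs), n_pairs, replace=False)]
        dv = coords[sel[:, 0]] - coords[sel[:, 1]]
        dw = feature[sel[:, 0]] - feature[sel[:, 1]]
        v_sub = (dw[:, None] * dv).sum(axis=0) / n_pairs
        angles[it] = vector_angle(v_sub, v_full)
    return {
        "angles": angles,
        "within_cone_fraction": float(np.mean(angles <= cone_deg)),
        "population_axis": v_full,
    }
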