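"""Axon-arbor homogeneity analysis.

Tests whether a single bipolar cell axon arbor behaves as one
computational unit: ROI centroids are attached to the reconstructed
skeleton, pairwise path distances are measured along it, paired
response consistencies (expected ``q`` from repeat reliability,
observed ``k`` from cross-ROI/cross-repeat correlations) are compared
against an exponential-decay model ``r = exp(-d / lambda)``, and the
length constant maximizing the agreement is contrasted with the
arbor's equivalent diameter: a length constant exceeding the diameter
means signals are effectively homogeneous across the arbor.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "PathGraph",
    "link_rois_to_skeleton",
    "pairwise_path_distances",
    "paired_consistency",
    "estimate_length_constant",
    "default_lambda_grid",
    "read_swc",
    "write_swc",
]


@dataclass
class PathGraph:
    """Skeleton graph with ROI attachment nodes.

    Node attributes carry 3-D positions (um); edge weights are the
    Euclidean separations of their endpoints.  ``roi_nodes[i]`` is the
    graph node to which ROI centroid i is attached.
    """

    graph: nx.Graph
    roi_nodes: list = field(default_factory=list)

    def positions(self) -> dict:
        return nx.get_node_attributes(self.graph, "pos")


def _skeleton_graph(nodes: np.ndarray, edges: list[tuple[int, int]]) -> nx.Graph:
    g = nx.Graph()
    for i, p in enumerate(nodes):
        g.add_node(i, pos=np.asarray(p, dtype=float))
    for u, v in edges:
        g.add_edge(u, v, weight=float(np.linalg.norm(nodes[u] - nodes[v])))
    return g


def link_rois_to_skeleton(
    roi_centroids: np.ndarray,
    nodes: np.ndarray,
    edges: list[tuple[int, int]],
    step_um: float = 0.1,
) -> PathGraph:
    """Attach each ROI centroid to its nearest skeleton point.

    Every edge is sampled in ``step_um`` increments; the nearest sample
    to each centroid becomes an attachment node splitting the edge, and
    the centroid joins the graph via a link edge of length equal to its
    distance from the skeleton.
    """
    nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
    roi_centroids = np.atleast_2d(np.asarray(roi_centroids, dtype=float))
    g = _skeleton_graph(nodes, edges)
    if not nx.is_connected(g):
        comps = [len(c) for c in nx.connected_components(g)]
        raise ValueError(f"skeleton is disconnected (component sizes: {comps})")

    # sample all edges at step_um resolution
    samples, sample_edges, sample_ts = [], [], []
    for u, v in g.edges:
        pu, pv = g.nodes[u]["pos"], g.nodes[v]["pos"]
        length = np.linalg.norm(pv - pu)
        n = max(int(np.ceil(length / step_um)), 1)
        ts = np.linspace(0.0, 1.0, n + 1)
        for t in ts:
            samples.append(pu + t * (pv - pu))
            sample_edges.append((u, v))
            sample_ts.append(float(t))
    samples = np.asarray(samples)

    roi_nodes = []
    next_id = max(g.nodes) + 1
    for ci, c in enumerate(roi_centroids):
        d = np.linalg.norm(samples - c, axis=1)
        best = int(np.argmin(d))
        (u, v), t = sample_edges[best], sample_ts[best]
        foot = samples[best]
        if t <= 1e-9:
            attach = u
        elif t >= 1 - 1e-9:
            attach = v
        else:
            attach = next_id
            next_id += 1
            g.add_node(attach, pos=foot)
            w_uv = g.edges[u, v]["weight"] if g.has_edge(u, v) else None
            if w_uv is not None:
                g.remove_edge(u, v)
            g.add_edge(u, attach, weight=float(np.linalg.norm(foot - g.nodes[u]["pos"])))
            g.add_edge(attach, v, weight=float(np.linalg.norm(g.nodes[v]["pos"] - foot)))
        roi_id = next_id
        next_id += 1
        g.add_node(roi_id, pos=np.asarray(c, dtype=float))
        g.add_edge(roi_id, attach, weight=float(d[best]))
        roi_nodes.append(roi_id)
    return PathGraph(g, roi_nodes)


def pairwise_path_distances(pg: PathGraph) -> tuple[np.ndarray, np.ndarray]:
    """Shortest path distances along the skeleton between all ROI pairs.

    Returns (path, euclidean) matrices in um; path distances are always
    at least as large as the straight-line distances.
    """
    n = len(pg.roi_nodes)
    path = np.zeros((n, n))
    euc = np.zeros((n, n))
    pos = pg.positions()
    lengths = dict(nx.all_pairs_dijkstra_path_length(pg.graph, weight="weight"))
    for i, j in itertools.combinations(range(n), 2):
        a, b = pg.roi_nodes[i], pg.roi_nodes[j]
        path[i, j] = path[j, i] = lengths[a][b]
        euc[i, j] = euc[j, i] = float(np.linalg.norm(pos[a] - pos[b]))
    return path, euc


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def paired_consistency(
    traces: np.ndarray,
    clip_edges: list[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected (q) and observed (k) paired response consistencies.

    ``traces`` has shape (n_rois, n_repeats, n_samples).  For a pair
    (i, j), ``q = |Corr(R_i1, R_i2) * Corr(R_j1, R_j2)|`` is what the
    pair correlation should be if both ROIs carry the same signal
    degraded only by their own noise, and
    ``k = |Corr(R_i1, R_j2) * Corr(R_j1, R_i2)|`` is what is actually
    observed across ROIs and repeats.  With more than two repeats all
    repeat pairs are averaged.  When clip boundaries are given,
    correlations are computed per clip and averaged.
    """
    traces = np.asarray(traces, dtype=float)
    n, n_rep, _ = traces.shape
    if n_rep < 2:
        raise ValueError("need at least 2 repeats")
    if n_rep > 2:
        warnings.warn("more than 2 repeats: averaging over repeat pairs", stacklevel=2)
    segments = clip_edges or [(0, traces.shape[2])]

    def seg_corr(a: np.ndarray, b: np.ndarray) -> float:
        vals = [_corr(a[s0:s1], b[s0:s1]) for s0, s1 in segments]
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else np.nan

    rep_pairs = list(itertools.combinations(range(n_rep), 2))
    q = np.full((n, n), np.nan)
    k = np.full((n, n), np.nan)
    rel = {}
    for i in range(n):
        rel[i] = np.mean([seg_corr(traces[i, a], traces[i, b]) for a, b in rep_pairs])
    for i, j in itertools.combinations(range(n), 2):
        q[i, j] = q[j, i] = abs(rel[i] * rel[j])
        kv = np.mean([
            seg_corr(traces[i, a], traces[j, b]) * seg_corr(traces[j, a], traces[i, b])
            for a, b in rep_pairs
        ])
        k[i, j] = k[j, i] = abs(kv)
        if not np.isfinite(q[i, j]) or not np.isfinite(k[i, j]):
            warnings.warn(f"pair ({i}, {j}) has a zero-variance repeat: flagged",
                          stacklevel=2)
    return q, k


def default_lambda_grid(n: int = 40, lo: float = 1.0, hi: float = 1000.0) -> np.ndarray:
    """Log-spaced length-constant grid in um, with infinity appended."""
    return np.concatenate([np.geomspace(lo, hi, n), [np.inf]])


def estimate_length_constant(
    distances: np.ndarray,
    q: np.ndarray,
    k: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    equivalent_diameter: float | None = None,
) -> dict:
    """Length constant maximizing ``Corr(r_lambda * q, k)`` over pairs.

    ``r_lambda = exp(-d / lambda)`` scales the expected consistency of
    each ROI pair by its separation; the profile of the correlation
    between the scaled expectation and the observed consistency peaks
    at the length constant best describing the data.  When the peak
    exceeds the arbor's equivalent diameter, responses are homogeneous
    at the scale of the arbor.

    Because q and k are each the product of two correlation
    coefficients, the observed consistency scales with the *square* of
    the pairwise response correlation (``k ~ r^2 q``), so the profile
    peak sits at half the decay length of r itself:
    ``exp(-2d/lam) = exp(-d/(lam/2))``.  The result therefore carries
    both the raw profile argmax (``lambda``, used for the homogeneity
    verdict, conservatively) and the bias-corrected decay length of the
    response correlation (``lambda_corrected = 2 * lambda``).
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    iu = np.triu_indices(distances.shape[0], 1)
    d, qv, kv = distances[iu], q[iu], k[iu]
    ok = np.isfinite(qv) & np.isfinite(kv)
    d, qv, kv = d[ok], qv[ok], kv[ok]
    if d.size < 10:
        raise ValueError("need at least 10 valid ROI pairs")
    profile = np.empty(lambda_grid.size)
    for i, lam in enumerate(lambda_grid):
        r = np.exp(-d / lam) if np.isfinite(lam) else np.ones_like(d)
        profile[i] = _corr(r * qv, kv)
    finite = np.isfinite(profile)
    if not finite.any() or np.nanstd(profile) < 1e-12:
        warnings.warn("flat correlation profile: length constant unbounded", stacklevel=2)
        best_lambda = np.inf
        unbounded = True
    else:
        best_lambda = float(lambda_grid[np.nanargmax(profile)])
        unbounded = not np.isfinite(best_lambda)
    result = {
        "lambda": best_lambda,
        "lambda_corrected": 2.0 * best_lambda,
        "profile": profile,
        "lambda_grid": lambda_grid,
        "unbounded": unbounded,
        "n_pairs": int(d.size),
    }
    if equivalent_diameter is not None:
        result["equivalent_diameter"] = float(equivalent_diameter)
        result["homogeneous"] = bool(best_lambda > equivalent_diameter)
    return result


# ---------------------------------------------------------------------------
# SWC input/output
# ---------------------------------------------------------------------------


def write_swc(path: str | Path, nodes: np.ndarray, edges: list[tuple[int, int]],
              radius: float = 0.5) -> None:
    """Write a tree skeleton to SWC (1-based ids, -1 parent for the root)."""
    nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
    parent = {0: -1}
    adj: dict[int, list[int]] = {i: [] for i in range(len(nodes))}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    stack = [0]
    seen = {0}
    order = []
    while stack:
        u = stack.pop()
        order.append(u)
        for v in adj[u]:
            if v not in seen:
                parent[v] = u
                seen.add(v)
                stack.append(v)
    lines = []
    for u in order:
        x, y, z = nodes[u]
        p = parent[u]
        lines.append(f"{u + 1} 0 {x:.3f} {y:.3f} {z:.3f} {radius:.3f} "
                     f"{p + 1 if p >= 0 else -1}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path: str | Path) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Read an SWC skeleton into (nodes, edges)."""
    nodes = []
    edges = []
    ids: dict[int, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        nid, x, y, z, parent = int(f[0]), float(f[2]), float(f[3]), float(f[4]), int(f[6])
        ids[nid] = len(nodes)
        nodes.append((x, y, z))
        if parent != -1:
            edges.append((ids[parent], ids[nid]))
    return np.asarray(nodes), edges
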