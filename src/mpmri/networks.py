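"""Connectivity matrices and binary graphs.

Functional networks are per-subject Pearson correlation matrices of ROI time
series; structural covariance networks are per-group across-subject
correlation matrices of regional thickness or (supratentorially normalized)
volume. Matrices are binarized by keeping the strongest positive
correlations at a requested edge fraction (sparsity), and compared against
degree-preserving random graphs obtained by double edge swaps.

Only positive correlations are eligible as edges: anti-correlations never
enter the ranking. Fisher z is not applied before thresholding (it is
rank-preserving, so the binarized graph is unchanged).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: default sparsity sweep: connected-yet-sparse regime
DEFAULT_SPARSITY_GRID = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))


@dataclass
class ConnectivityMatrix:
    """Labeled symmetric correlation matrix with zeroed diagonal."""

    weights: np.ndarray
    labels: list[str]
    kind: str = "functional"   # functional | thickness_covariance | volume_covariance

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric within 1e-10")
        if np.nanmax(np.abs(w)) > 1 + 1e-8:
            raise ValueError("correlation weights must lie in [-1, 1]")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class BinaryGraph:
    """Undirected simple graph as a symmetric 0/1 adjacency matrix."""

    adjacency: np.ndarray
    sparsity: float = field(default=0.0)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        self.adjacency = a.astype(np.uint8)
        n = a.shape[0]
        if n >= 2:
            self.sparsity = float(a.sum() / (n * (n - 1)))

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edge_array(self) -> np.ndarray:
        iu, ju = np.nonzero(np.triu(self.adjacency, 1))
        return np.column_stack([iu, ju])


def functional_connectivity_matrix(ts: np.ndarray,
                                   labels: list[str] | None = None) -> ConnectivityMatrix:
    """Pearson correlation of each ROI pair of a (n_roi, T) time-series matrix."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("need a 2-D matrix with at least 3 timepoints")
    sds = ts.std(axis=1)
    constant = np.nonzero(sds == 0)[0]
    if constant.size:
        raise ValueError(f"constant time series for ROI index {constant[0]}")
    r = np.corrcoef(ts)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    labels = labels if labels is not None else [f"roi_{k}" for k in range(ts.shape[0])]
    return ConnectivityMatrix(r, labels, kind="functional")


def structural_covariance_matrix(cohort, measure: str, group: str) -> ConnectivityMatrix:
    """Across-subject region-by-region correlation for one group.

    ``measure`` is "thickness" (raw mm) or "volume" (supratentorially
    normalized, which leaves the correlations scale-invariant).
    """
    if measure not in ("thickness", "volume"):
        raise ValueError(f"unknown measure {measure!r}")
    if measure == "thickness":
        data = pd.DataFrame(cohort.thickness_matrix(group),
                            columns=cohort.cortical_regions)
        kind = "thickness_covariance"
    else:
        data = cohort.volume_matrix(group, normalized=True)
        kind = "volume_covariance"
    return covariance_from_table(data, kind=kind)


def covariance_from_table(data: pd.DataFrame, kind: str = "thickness_covariance") -> ConnectivityMatrix:
    """Across-subject correlation matrix from a (subjects x regions) table."""
    if data.shape[0] < 4:
        raise ValueError("need at least 4 subjects for a covariance network")
    sds = data.std(axis=0, ddof=0)
    dead = sds[sds == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance region(s): {dead}")
    r = np.corrcoef(data.to_numpy(dtype=float), rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r, list(data.columns), kind=kind)


def threshold_at_sparsity(m: ConnectivityMatrix, s: float) -> BinaryGraph:
    """Keep the ``floor(s * n(n-1)/2)`` strongest positive correlations.

    Ties are broken deterministically by (lower row index, lower column
    index), which makes the edge sets nested across sparsities.
    """
    if not 0 < s <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    n = m.n
    iu, ju = np.triu_indices(n, 1)
    w = m.weights[iu, ju]
    n_edges = int(np.floor(s * len(w)))
    if n_edges < 1:
        raise ValueError(f"sparsity {s} yields zero edges for n={n}")
    order = np.lexsort((ju, iu, -w))
    keep = order[:n_edges]
    if np.any(w[keep] <= 0):
        n_pos = int((w > 0).sum())
        raise ValueError(f"requested {n_edges} edges but only {n_pos} positive "
                         f"correlations are available")
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return BinaryGraph(adj)


def _swap_kernel_py(adj: np.ndarray, e1: np.ndarray, e2: np.ndarray,
                    picks: np.ndarray, flips: np.ndarray, n_swaps: int) -> int:
    """Double-edge-swap inner loop on a boolean adjacency matrix.

    Mutates adj/e1/e2 in place; returns the number of accepted swaps.
    The numba-compiled variant executes the same draws in the same order,
    so both paths produce identical graphs.
    """
    accepted = 0
    for t in range(picks.shape[0]):
        x = picks[t, 0]
        y = picks[t, 1]
        if x == y:
            continue
        a, b = e1[x], e2[x]
        if flips[t]:
            c, d = e2[y], e1[y]
        else:
            c, d = e1[y], e2[y]
        if a == d or c == b or a == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = True
        adj[c, b] = adj[b, c] = True
        e1[x], e2[x] = (a, d) if a < d else (d, a)
        e1[y], e2[y] = (c, b) if c < b else (b, c)
        accepted += 1
        if accepted >= n_swaps:
            break
    return accepted


try:  # optional JIT acceleration; the fallback is semantically identical
    from numba import njit as _njit

    _swap_kernel = _njit(cache=True)(_swap_kernel_py)
except ImportError:  # pragma: no cover
    _swap_kernel = _swap_kernel_py


def degree_matched_random(g: BinaryGraph, n_swaps: int | None = None,
                          seed: int = 0, max_tries_factor: int = 50) -> BinaryGraph:
    """Degree-preserving randomization via double edge swaps.

    Two edges (a,b), (c,d) are rewired to (a,d), (c,b); swaps that would
    create self-loops or multi-edges are rejected and retried. The degree
    sequence is preserved exactly. ``n_swaps`` counts accepted swaps
    (default 10x the edge count); the attempt budget is
    ``max_tries_factor * n_swaps``, after which the current graph is
    returned (e.g. a triangle admits no swap at all and comes back intact).
    """
    edges = g.edge_array()
    m = len(edges)
    if m < 2:
        return BinaryGraph(g.adjacency.copy())
    if n_swaps is None:
        n_swaps = 10 * m
    rng = np.random.default_rng(seed)
    adj = g.adjacency.astype(bool)
    e1 = np.ascontiguousarray(edges[:, 0])
    e2 = np.ascontiguousarray(edges[:, 1])
    remaining = int(n_swaps)
    tries_left = max_tries_factor * n_swaps
    chunk = max(2 * n_swaps, 1024)
    while remaining > 0 and tries_left > 0:
        k = min(chunk, tries_left)
        picks = rng.integers(0, m, size=(k, 2))
        flips = rng.integers(0, 2, size=k).astype(bool)
        remaining -= _swap_kernel(adj, e1, e2, picks, flips, remaining)
        tries_left -= k
    return BinaryGraph(adj.astype(np.uint8))


# ---------------------------------------------------------------------------
# I/O: matrices as labeled TSV, graphs as edge list + JSON sidecar

def write_matrix(m: ConnectivityMatrix, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(m.weights, index=m.labels, columns=m.labels).to_csv(path, sep="\t")
    return path


def read_matrix(path: str | Path, kind: str = "functional") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(df.to_numpy(dtype=float), list(df.columns), kind=kind)


def write_graph(g: BinaryGraph, path: str | Path) -> Path:
    import json
    path = Path(path)
    pd.DataFrame(g.edge_array(), columns=["i", "j"]).to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"n": g.n, "sparsity": g.sparsity}))
    return path


def read_graph(path: str | Path) -> BinaryGraph:
    import json
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    edges = pd.read_csv(path, sep="\t")
    adj = np.zeros((meta["n"], meta["n"]), dtype=np.uint8)
    adj[edges["i"], edges["j"]] = 1
    adj |= adj.T
    return BinaryGraph(adj)
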