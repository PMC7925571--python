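"""Weighted graph-topology core.

Proportional thresholding at sparsity S keeps the floor(S * n(n-1)/2)
strongest undirected edges with their original weights. Metrics follow the
standard weighted conventions: edge length = 1/weight for distances,
Latora-Marchiori global efficiency, Onnela geometric-mean clustering on
max-normalized weights, and local efficiency as the global efficiency of
the neighbour-induced subgraph. A sparsity sweep aggregates each metric
curve into a trapezoidal AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectome_io import ConnectivityMatrix, ParcellationAtlas, ValidationError

logger = logging.getLogger(__name__)

#: default sparsity grid: 5% to 30% inclusive in 1% steps (26 levels)
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(
    np.round(np.arange(5, 31) / 100.0, 2)
)

#: strict open-interval reading of the same range (24 levels)
STRICT_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(6, 30) / 100.0, 2))


@dataclass
class ThresholdedGraph:
    """Edge subset of a connectivity matrix at sparsity ``sparsity``."""

    weights: np.ndarray
    sparsity: float

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))


@dataclass
class MetricCurve:
    """A metric evaluated over the sparsity grid plus its trapezoidal AUC.

    Non-finite values (e.g. infinite path length on a disconnected graph)
    are stored as NaN and excluded from the AUC, which then integrates only
    over segments whose two endpoints are both finite.
    """

    thresholds: tuple[float, ...]
    values: tuple[float, ...]
    auc: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.values):
            raise ValidationError("thresholds/values length mismatch")
        t = np.asarray(self.thresholds, dtype=float)
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValidationError("thresholds must be strictly increasing")
        self.auc = _finite_trapezoid(t, np.asarray(self.values, dtype=float))


def _finite_trapezoid(t: np.ndarray, v: np.ndarray) -> float:
    finite = np.isfinite(v)
    auc = 0.0
    for i in range(len(t) - 1):
        if finite[i] and finite[i + 1]:
            auc += 0.5 * (v[i] + v[i + 1]) * (t[i + 1] - t[i])
    return auc


@dataclass
class GraphMetricsResult:
    """Per-subject metric curves: 3 global + one local-efficiency curve per region."""

    subject_id: str
    regions: tuple[str, ...]
    global_efficiency: MetricCurve
    char_path_length: MetricCurve
    mean_clustering: MetricCurve
    local_efficiency: dict[str, MetricCurve]

    def local_efficiency_aucs(self) -> dict[str, float]:
        return {r: c.auc for r, c in self.local_efficiency.items()}


class PathLengthResult(NamedTuple):
    value: float
    n_infinite_pairs: int


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def normalize_weights(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Divide every weight by the matrix maximum so the largest weight is 1."""
    wmax = float(np.max(m.weights))
    if wmax <= 0:
        raise ValidationError("cannot normalize an all-zero matrix")
    return ConnectivityMatrix(
        subject_id=m.subject_id, regions=m.regions, weights=m.weights / wmax
    )


def proportional_threshold(m: ConnectivityMatrix, S: float) -> ThresholdedGraph:
    """Keep the floor(S * n(n-1)/2) strongest undirected edges.

    Ties at the cut weight are broken deterministically by ascending
    (row, column) index of the upper-triangle entry.
    """
    if not 0 < S <= 1:
        raise ValidationError(f"sparsity S={S} outside (0, 1]")
    w = m.weights
    n = w.shape[0]
    iu, ju = np.triu_indices(n, 1)
    vals = w[iu, ju]
    k = int(np.floor(S * n * (n - 1) / 2))
    # stable sort on descending weight; equal weights keep (row, col) order
    order = np.argsort(-vals, kind="stable")
    keep = order[:k]
    keep = keep[vals[keep] > 0]  # never create edges out of zeros
    out = np.zeros_like(w)
    out[iu[keep], ju[keep]] = vals[keep]
    out += out.T
    return ThresholdedGraph(weights=out, sparsity=float(S))


def _all_pairs_distances(lengths: np.ndarray) -> np.ndarray:
    """All-pairs distances from an edge-length matrix (0 = no edge)."""
    n = lengths.shape[0]
    if n > 128:
        d = shortest_path(csr_matrix(lengths), method="D", directed=False)
        np.fill_diagonal(d, 0.0)
        return d
    # vectorized min-plus relaxation; faster than sparse conversion at this size
    d = np.where(lengths > 0, lengths, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :], out=d)
    return d


def shortest_distances(
    g: ThresholdedGraph, path_mode: str = "weighted"
) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/weight.

    ``path_mode="binary"`` uses unit edge lengths (hop counts) instead.
    Unreachable pairs are +inf; the diagonal is 0.
    """
    w = g.weights
    if path_mode == "weighted":
        lengths = np.zeros_like(w)
        nz = w > 0
        lengths[nz] = 1.0 / w[nz]
    elif path_mode == "binary":
        lengths = (w > 0).astype(float)
    else:
        raise ValidationError(f"unknown path_mode: {path_mode!r}")
    return _all_pairs_distances(lengths)


def characteristic_path_length(d: np.ndarray) -> PathLengthResult:
    """Mean finite off-diagonal distance, with the number of infinite pairs.

    Returns +inf only when no finite pair exists.
    """
    n = d.shape[0]
    if n < 2:
        raise ValidationError("characteristic path length requires n >= 2")
    off = ~np.eye(n, dtype=bool)
    vals = d[off]
    finite = np.isfinite(vals)
    n_inf = int(np.sum(~finite))
    if not np.any(finite):
        return PathLengthResult(np.inf, n_inf)
    return PathLengthResult(float(np.mean(vals[finite])), n_inf)


def global_efficiency(d: np.ndarray) -> float:
    """Latora-Marchiori efficiency: mean of 1/d over ordered pairs, 1/inf = 0."""
    n = d.shape[0]
    if n < 2:
        raise ValidationError("global efficiency requires n >= 2")
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(np.sum(inv[off]) / (n * (n - 1)))


def weighted_clustering(g: ThresholdedGraph) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering per node and its mean over all nodes.

    C_i = (1 / (k_i (k_i - 1))) * [(W^(1/3))^3]_ii with k_i the binary
    degree; nodes with k_i < 2 get C_i = 0. Weights are expected in [0, 1].
    """
    w = g.weights
    cbrt = np.cbrt(w)
    tri = np.diagonal(cbrt @ cbrt @ cbrt)  # 2x the weighted triangle count per node
    k = np.count_nonzero(w, axis=1)
    denom = k * (k - 1)
    c = np.zeros(w.shape[0])
    ok = denom > 0
    c[ok] = tri[ok] / denom[ok]
    return c, float(np.mean(c))


def local_efficiency(
    g: ThresholdedGraph, i: int, path_mode: str = "weighted"
) -> float:
    """Global efficiency of the subgraph induced by node i's neighbours.

    Node i itself is removed; original weights are retained. Nodes with
    fewer than two neighbours score 0.
    """
    n = g.n
    if not 0 <= i < n:
        raise ValidationError(f"node index {i} out of range for n={n}")
    nb = np.flatnonzero(g.weights[i] > 0)
    if len(nb) < 2:
        return 0.0
    sub = ThresholdedGraph(
        weights=g.weights[np.ix_(nb, nb)], sparsity=g.sparsity
    )
    return global_efficiency(shortest_distances(sub, path_mode=path_mode))


def network_of(atlas: ParcellationAtlas, region: str) -> str:
    """Functional-system label (Yeo-7 or subcortical) for a region name."""
    return atlas.network_of(region)


# ---------------------------------------------------------------------------
# Sparsity sweep
# ---------------------------------------------------------------------------


def sweep_metrics(
    m: ConnectivityMatrix,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    normalize: bool = True,
    path_mode: str = "weighted",
) -> GraphMetricsResult:
    """Evaluate all metrics across the sparsity grid and aggregate to AUCs."""
    t = np.asarray(thresholds, dtype=float)
    if len(t) < 2:
        raise ValidationError("at least two thresholds are required")
    if not np.all(np.diff(t) > 0):
        raise ValidationError("thresholds must be strictly increasing")
    if normalize:
        m = normalize_weights(m)
    n = m.n
    ge_vals, cpl_vals, clu_vals = [], [], []
    leff_vals = np.zeros((len(t), n))
    n_inf_total = 0
    for row, S in enumerate(t):
        g = proportional_threshold(m, float(S))
        d = shortest_distances(g, path_mode=path_mode)
        ge_vals.append(global_efficiency(d))
        cpl = characteristic_path_length(d)
        n_inf_total += cpl.n_infinite_pairs
        cpl_vals.append(cpl.value if np.isfinite(cpl.value) else np.nan)
        clu_vals.append(weighted_clustering(g)[1])
        for i in range(n):
            leff_vals[row, i] = local_efficiency(g, i, path_mode=path_mode)
    if n_inf_total:
        logger.info(
            "subject %s: %d infinite node pairs excluded across the sweep",
            m.subject_id,
            n_inf_total,
        )
    tt = tuple(float(x) for x in t)
    return GraphMetricsResult(
        subject_id=m.subject_id,
        regions=m.regions,
        global_efficiency=MetricCurve(tt, tuple(ge_vals)),
        char_path_length=MetricCurve(tt, tuple(cpl_vals)),
        mean_clustering=MetricCurve(tt, tuple(clu_vals)),
        local_efficiency={
            r: MetricCurve(tt, tuple(leff_vals[:, i]))
            for i, r in enumerate(m.regions)
        },
    )


def global_efficiency_auc(
    m: ConnectivityMatrix,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    normalize: bool = True,
) -> float:
    """AUC of global efficiency alone (cheaper than a full sweep)."""
    t = np.asarray(thresholds, dtype=float)
    if normalize:
        m = normalize_weights(m)
    vals = []
    for S in t:
        g = proportional_threshold(m, float(S))
        vals.append(global_efficiency(shortest_distances(g)))
    return MetricCurve(tuple(float(x) for x in t), tuple(vals)).auc


def metrics_to_row(res: GraphMetricsResult) -> dict[str, float]:
    """Flatten a result into one table row of AUC scalars."""
    row: dict[str, float] = {
        "subject_id": res.subject_id,
        "global_efficiency_auc": res.global_efficiency.auc,
        "char_path_length_auc": res.char_path_length.auc,
        "mean_clustering_auc": res.mean_clustering.auc,
    }
    for region, curve in res.local_efficiency.items():
        row[f"leff_{region}_auc"] = curve.auc
    return row
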