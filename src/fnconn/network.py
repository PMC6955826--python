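"""Functional network connectivity matrices and their graph characterization.

The per-subject FNC matrix is a symmetric 10 x 10 weighted matrix whose
entry ``c_ij`` is the lag-maximized distance correlation between the
representative time-courses of networks i and j.  Rows and columns of
components flagged non-neuronal are set to zero (no interaction).  Since
the estimator is strictly positive in finite samples, "nonzero
correlation" is operationalized by an explicit edge-retention mask, by
default the surrogate-rotation significance rule, alternatively a fixed
threshold.

Five nodal measures characterize the retained weighted graph —
integration (degree, strength), segregation (weighted clustering
coefficient, Onnela form), and centrality (betweenness on 1/w path
lengths, eigenvector centrality) — together with their network averages
over all 10 nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .lagged import _PreparedSeries, _lagged_from_prepared, _surrogate_null, surrogate_pvalue
from .timecourses import TimeCourseSet

__all__ = [
    "FNCMatrix",
    "NodalMetrics",
    "SurrogateEdgeRule",
    "FixedEdgeRule",
    "build_fnc",
    "degree",
    "strength",
    "clustering_coefficient",
    "betweenness",
    "eigenvector_centrality",
    "compute_metrics",
    "network_summary",
    "metrics_to_records",
]

MEASURES = ("degree", "strength", "clustering", "betweenness", "eigencentrality")


@dataclass(frozen=True)
class SurrogateEdgeRule:
    """Retain an edge when its lagged dCor exceeds the (1 - alpha) quantile
    of a circular-rotation surrogate null built per pair."""

    alpha: float = 0.05
    n_surrogates: int = 100
    seed: int = 0


@dataclass(frozen=True)
class FixedEdgeRule:
    """Retain an edge when its lagged dCor exceeds a fixed threshold."""

    threshold: float


@dataclass
class FNCMatrix:
    """Symmetric weighted connectivity matrix over labelled networks.

    ``weights[i, j]`` holds the lag-maximized dCor for neuronal pairs and
    exactly zero elsewhere (diagonal, and any row/column of a non-neuronal
    node).  ``retained`` marks the edges that passed the edge rule; only
    retained edges enter the graph measures.  ``lags`` records the
    maximizing lag per pair and ``pvalues`` the surrogate p-values when
    the surrogate rule was used.
    """

    labels: list[str]
    weights: np.ndarray
    retained: np.ndarray
    neuronal: np.ndarray
    lags: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.retained = np.asarray(self.retained, dtype=bool)
        self.neuronal = np.asarray(self.neuronal, dtype=bool)
        n = len(self.labels)
        if self.weights.shape != (n, n) or self.retained.shape != (n, n):
            raise InvalidArgumentError("weights/retained must be square over labels")
        if not np.allclose(self.weights, self.weights.T):
            raise InvalidArgumentError("weights must be symmetric")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def masked_weights(self) -> np.ndarray:
        """Weights restricted to retained edges."""
        return np.where(self.retained, self.weights, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.labels, columns=self.labels)


def build_fnc(
    tcs: TimeCourseSet,
    max_lag: int = 3,
    edge_rule: SurrogateEdgeRule | FixedEdgeRule = SurrogateEdgeRule(),
) -> FNCMatrix:
    """Assemble the FNC matrix of one subject.

    Every unordered pair of neuronal components gets the lag-maximized
    distance correlation of its two time-courses; pairs involving a
    non-neuronal component are fixed at zero and never retained.  The
    edge-retention mask comes from ``edge_rule``.  Surrogate seeds are
    derived deterministically per pair from ``edge_rule.seed``, so the
    result is a pure function of its inputs.
    """
    n = tcs.n_components
    if n < 2:
        raise InvalidArgumentError("need at least two components")
    weights = np.zeros((n, n))
    retained = np.zeros((n, n), dtype=bool)
    lags = np.zeros((n, n), dtype=int)
    pvalues = np.full((n, n), np.nan)

    prepared: dict[int, _PreparedSeries] = {
        i: _PreparedSeries(tcs.data[:, i]) for i in range(n) if tcs.neuronal[i]
    }
    surrogate = isinstance(edge_rule, SurrogateEdgeRule)

    for i in range(n):
        for j in range(i + 1, n):
            if not (tcs.neuronal[i] and tcs.neuronal[j]):
                continue
            res = _lagged_from_prepared(prepared[i], prepared[j], max_lag)
            weights[i, j] = weights[j, i] = res.dcor
            lags[i, j] = res.best_lag
            lags[j, i] = -res.best_lag
            if surrogate:
                pair_seed = np.random.SeedSequence(
                    entropy=edge_rule.seed, spawn_key=(i, j)
                )
                null = _surrogate_null(
                    prepared[i],
                    prepared[j],
                    max_lag,
                    edge_rule.n_surrogates,
                    np.random.default_rng(pair_seed),
                )
                thr = float(np.quantile(null, 1.0 - edge_rule.alpha, method="higher"))
                keep = res.dcor > thr
                pvalues[i, j] = pvalues[j, i] = surrogate_pvalue(null, res.dcor)
            else:
                keep = res.dcor > edge_rule.threshold
            retained[i, j] = retained[j, i] = keep
    return FNCMatrix(
        labels=list(tcs.labels),
        weights=weights,
        retained=retained,
        neuronal=tcs.neuronal.copy(),
        lags=lags,
        pvalues=pvalues,
        meta=dict(tcs.meta),
    )


def degree(fnc: FNCMatrix) -> np.ndarray:
    """Number of retained incident edges per node (0..n-1)."""
    return fnc.retained.sum(axis=1).astype(int)


def strength(fnc: FNCMatrix) -> np.ndarray:
    """Sum of retained incident edge weights per node."""
    return fnc.masked_weights().sum(axis=1)


def clustering_coefficient(fnc: FNCMatrix) -> np.ndarray:
    """Weighted clustering coefficient, Onnela's geometric-mean form.

    C_i = sum_{j != h} (w_ij w_ih w_jh)^{1/3} / (k_i (k_i - 1)) over
    retained edges, with raw weights (already bounded by 1, no per-subject
    renormalization); nodes of degree < 2 score 0.
    """
    w3 = np.cbrt(fnc.masked_weights())
    triangle_paths = np.diagonal(w3 @ w3 @ w3)  # counts each triangle twice
    k = degree(fnc)
    out = np.zeros(fnc.n_nodes)
    has = k >= 2
    out[has] = triangle_paths[has] / (k[has] * (k[has] - 1))
    return out


def _retained_graph(fnc: FNCMatrix) -> tuple[nx.Graph, np.ndarray]:
    """Graph over neuronal nodes with retained edges; lengths are 1/w."""
    idx = np.flatnonzero(fnc.neuronal)
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in idx)
    for a_pos, i in enumerate(idx):
        for j in idx[a_pos + 1:]:
            if fnc.retained[i, j]:
                w = fnc.weights[i, j]
                g.add_edge(int(i), int(j), weight=w, length=1.0 / w)
    return g, idx


def betweenness(fnc: FNCMatrix) -> np.ndarray:
    """Betweenness centrality on shortest paths with edge length 1/weight.

    Fractional (Brandes) credit for tied geodesics, normalized by
    (n - 1)(n - 2) / 2 with n the neuronal node count, so values lie in
    [0, 1].  Non-neuronal and isolated nodes score 0.
    """
    g, _ = _retained_graph(fnc)
    out = np.zeros(fnc.n_nodes)
    if g.number_of_nodes() < 3:
        return out
    bc = nx.betweenness_centrality(g, weight="length", normalized=True)
    for node, value in bc.items():
        out[node] = value
    return out


def eigenvector_centrality(
    fnc: FNCMatrix, tol: float = 1e-10, max_iter: int = 100_000
) -> np.ndarray:
    """Leading eigenvector of the retained weighted adjacency.

    Restricted to neuronal nodes, oriented nonnegative and scaled to unit
    Euclidean norm.  Power iteration from a uniform positive start; for a
    disconnected graph this converges to the global leading eigenpair.
    An all-zero adjacency yields all-zero centralities with a warning.
    """
    idx = np.flatnonzero(fnc.neuronal)
    out = np.zeros(fnc.n_nodes)
    if idx.size == 0:
        warnings.warn("no neuronal nodes; eigenvector centrality is all zero")
        return out
    a = fnc.masked_weights()[np.ix_(idx, idx)]
    if not a.any():
        warnings.warn("empty retained graph; eigenvector centrality is all zero")
        return out
    # spectral shift: adding s*I keeps eigenvectors but makes the Perron
    # eigenvalue strictly dominant (a bipartite component has -lambda_max
    # in its spectrum, which would otherwise make the iteration oscillate)
    shift = a.sum(axis=1).max()
    a = a + shift * np.eye(idx.size)
    v = np.full(idx.size, 1.0 / np.sqrt(idx.size))
    for _ in range(max_iter):
        nxt = a @ v
        nxt /= np.linalg.norm(nxt)
        if np.linalg.norm(nxt - v) <= tol:
            v = nxt
            break
        v = nxt
    v = np.abs(v)
    n2 = np.linalg.norm(v)
    if n2 > 0:
        v = v / n2
    out[idx] = v
    return out


@dataclass
class NodalMetrics:
    """Per-node graph measures of one FNC matrix plus network averages."""

    labels: list[str]
    degree: np.ndarray
    strength: np.ndarray
    clustering: np.ndarray
    betweenness: np.ndarray
    eigencentrality: np.ndarray
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "degree": self.degree,
            "strength": self.strength,
            "clustering": self.clustering,
            "betweenness": self.betweenness,
            "eigencentrality": self.eigencentrality,
        }


def compute_metrics(fnc: FNCMatrix) -> NodalMetrics:
    """All five nodal measures of one FNC matrix."""
    return NodalMetrics(
        labels=list(fnc.labels),
        degree=degree(fnc),
        strength=strength(fnc),
        clustering=clustering_coefficient(fnc),
        betweenness=betweenness(fnc),
        eigencentrality=eigenvector_centrality(fnc),
        meta=dict(fnc.meta),
    )


def network_summary(metrics: NodalMetrics) -> dict[str, float]:
    """Arithmetic mean of each nodal measure over all nodes.

    Zeroed (non-neuronal or isolated) nodes are included, mirroring the
    convention that a suppressed component contributes zero interaction.
    """
    return {name: float(np.mean(values)) for name, values in metrics.as_dict().items()}


def metrics_to_records(metrics: NodalMetrics) -> pd.DataFrame:
    """Tidy long-format table: one row per (node-or-average, measure)."""
    rows = []
    base = {k: metrics.meta.get(k) for k in ("subject", "group") if k in metrics.meta}
    for measure, values in metrics.as_dict().items():
        for label, value in zip(metrics.labels, values):
            rows.append({**base, "node": label, "measure": measure, "value": float(value)})
    for measure, value in network_summary(metrics).items():
        rows.append({**base, "node": "average", "measure": measure, "value": value})
    return pd.DataFrame(rows)
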