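"""Weighted feature networks and normalized centralities.

CR and nMIR matrices yield undirected networks (degree and eigenvector
centrality); TE matrices yield directed networks (in/out strength, Katz,
PageRank). The adjacency convention for directed networks is
``a(i, j)`` = weight of the link from node ``j`` to node ``i``. Self-loops
are removed (zero diagonal) before any centrality. Every centrality vector
is normalized by its maximum, so the most central node scores 1; an all-zero
vector stays all-zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectivity import RelationMatrix

UNDIRECTED_CENTRALITIES = ("degree", "eigenvector")
DIRECTED_CENTRALITIES = ("in_degree", "out_degree", "katz", "pagerank")


@dataclass
class WeightedNetwork:
    """Adjacency over ``K`` feature nodes; zero diagonal, weights >= 0."""

    adjacency: np.ndarray
    directed: bool
    feature_labels: list[str]
    class_label: str = ""
    scheme: str = ""
    measure: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if (a < 0).any():
            raise ValueError("negative edge weights")
        if not self.directed and not np.allclose(a, a.T):
            raise ValueError("undirected network requires a symmetric adjacency")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class CentralityVector:
    """Raw and max-normalized centralities for one measure."""

    measure: str
    raw: np.ndarray
    normalized: np.ndarray
    feature_labels: list[str]


def build_network(rm: RelationMatrix) -> WeightedNetwork:
    """Relation matrix -> weighted network: diagonal zeroed (no self-loops),
    zero entries mean no edge; CR/nMIR undirected, TE directed."""
    a = np.array(rm.values, dtype=float)
    if (a < 0).any():
        raise ValueError(f"{rm.measure} matrix has negative entries")
    np.fill_diagonal(a, 0.0)
    return WeightedNetwork(a, directed=(rm.measure == "TE"),
                           feature_labels=rm.feature_labels,
                           class_label=rm.class_label, scheme=rm.scheme,
                           measure=rm.measure)


def normalize(raw: np.ndarray) -> np.ndarray:
    """Divide by the maximum; an all-zero vector maps to all zeros."""
    raw = np.asarray(raw, dtype=float)
    if (raw < 0).any():
        raise ValueError("centralities must be non-negative")
    top = raw.max()
    return raw / top if top > 0 else np.zeros_like(raw)


def _power_iteration(a: np.ndarray, tol: float = 1e-14,
                     max_iter: int = 100000) -> np.ndarray:
    """Leading (Perron) eigenvector of a non-negative matrix, max-norm 1."""
    k = a.shape[0]
    y = np.full(k, 1.0 / k)
    for _ in range(max_iter):
        z = a @ y
        top = np.abs(z).max()
        if top == 0:
            return np.zeros(k)
        z /= top
        if np.abs(z - y).max() < tol:
            y = z
            break
        y = z
    y = np.abs(y)  # Perron orientation: non-negative
    return y / y.max()


def undirected_centralities(net: WeightedNetwork) -> dict[str, CentralityVector]:
    """Degree (strength) and eigenvector centrality of an undirected network."""
    if net.directed:
        raise ValueError("network is directed")
    a = net.adjacency
    degree = a.sum(axis=0)
    if degree.max() == 0:
        warnings.warn("all-zero adjacency; centralities are all zero")
        eig = np.zeros(net.n_nodes)
    else:
        eig = _power_iteration(a)
    return {
        "degree": CentralityVector("degree", degree, normalize(degree),
                                   net.feature_labels),
        "eigenvector": CentralityVector("eigenvector", eig, normalize(eig),
                                        net.feature_labels),
    }


def directed_centralities(net: WeightedNetwork,
                          katz_attenuation: float = 0.9,
                          pagerank_damping: float = 0.85,
                          ) -> dict[str, CentralityVector]:
    """In/out strength, Katz, and PageRank of a directed network.

    With the ``a(i, j) = j -> i`` convention, node ``j``'s in-strength is the
    ``j``-th row sum and its out-strength the ``j``-th column sum. Katz uses
    ``y = (I - alpha A)^{-1} 1`` with ``alpha = katz_attenuation / k_1``
    (``k_1`` the leading eigenvalue magnitude; ``alpha = 0`` for an empty
    network). PageRank uses ``y = D (D - alpha A)^{-1} 1`` with
    ``d_ii = max(1, out_i)`` and ``alpha = pagerank_damping``.
    """
    if not net.directed:
        raise ValueError("network is undirected")
    if not 0 < katz_attenuation < 1:
        raise ValueError("katz_attenuation must be in (0, 1)")
    if not 0 < pagerank_damping < 1:
        raise ValueError("pagerank_damping must be in (0, 1)")
    a = net.adjacency
    k = net.n_nodes
    in_deg = a.sum(axis=1)
    out_deg = a.sum(axis=0)

    k1 = np.abs(np.linalg.eigvals(a)).max() if a.any() else 0.0
    alpha = katz_attenuation / k1 if k1 > 0 else 0.0
    katz = _solve_attenuated(np.eye(k) - alpha * a, np.ones(k), a, alpha)

    d = np.maximum(1.0, out_deg)
    pr = d * _solve_attenuated(np.diag(d) - pagerank_damping * a, np.ones(k),
                               a, pagerank_damping, diag=d)
    return {
        "in_degree": CentralityVector("in_degree", in_deg, normalize(in_deg),
                                      net.feature_labels),
        "out_degree": CentralityVector("out_degree", out_deg, normalize(out_deg),
                                       net.feature_labels),
        "katz": CentralityVector("katz", katz, normalize(katz),
                                 net.feature_labels),
        "pagerank": CentralityVector("pagerank", pr, normalize(pr),
                                     net.feature_labels),
    }


def _solve_attenuated(system: np.ndarray, b: np.ndarray, a: np.ndarray,
                      alpha: float, diag: np.ndarray | None = None,
                      ) -> np.ndarray:
    """Solve the (usually well-posed) attenuated linear system; on a singular
    system retry once with alpha halved, then raise."""
    try:
        return np.linalg.solve(system, b)
    except np.linalg.LinAlgError:
        half = alpha * 0.5
        base = np.eye(a.shape[0]) if diag is None else np.diag(diag)
        return np.linalg.solve(base - half * a, b)


def centralities_for(rm: RelationMatrix,
                     katz_attenuation: float = 0.9,
                     pagerank_damping: float = 0.85,
                     ) -> dict[str, CentralityVector]:
    """Relation matrix -> network -> the centralities its type supports."""
    net = build_network(rm)
    if net.directed:
        return directed_centralities(net, katz_attenuation, pagerank_damping)
    return undirected_centralities(net)
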