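"""Pairwise connectivity between feature series.

Three measures are computed from each ``N_s x K`` feature matrix:

* ``CR`` — absolute Pearson correlation; symmetric linear dependence in
  [0, 1], diagonal 1.
* ``nMIR`` — plug-in mutual information on discretized series, normalized by
  the largest Shannon entropy among the series; symmetric, in [0, 1];
  diagonal entries are ``H(X_i)/H_max`` so the maximum-entropy series has
  diagonal 1.
* ``TE`` — transfer entropy, the conditional mutual information
  ``I(target_{n+1}; source-embedding | target-embedding)`` estimated by the
  Kraskov-Stoegbauer-Grassberger nearest-neighbor method (Frenzel-Pompe
  conditional form, Chebyshev norm), bias-corrected by subtracting the
  maximum TE against ``q`` randomized surrogates of the target and clipping
  at zero. Directed: matrix entry ``(i, j)`` holds the influence of series
  ``j`` on series ``i``.

Natural logarithms are used throughout (nMIR's normalization cancels the
base; TE is in nats).
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .feature_extraction import FeatureMatrix

logger = logging.getLogger("featnet")

MEASURES = ("CR", "nMIR", "TE")


@dataclass(frozen=True)
class ConnectivityParams:
    """Estimator settings.

    bins, binning
        Discretization for the entropy/MI plug-in estimator: ``bins``
        equal-frequency (default) or equal-width states.
    l, k
        Source and target embedding lengths for transfer entropy
        (``l = k`` is required for information-transfer detection; default 5).
    knn
        Neighbor count of the KSG estimator.
    q, surrogate
        Surrogate count and style for TE bias correction: ``shuffle``
        (default; full random permutation of the target) or ``shift``
        (circular time shift by a random offset in [T/4, 3T/4], which
        preserves marginals and autocorrelation). For serially independent
        feature series the shuffled target and the true target are fully
        exchangeable, so a null pair survives correction with probability
        exactly 1/(q+1).
    seed
        Seeds surrogate generation and the tie-breaking jitter of the KSG
        estimator.
    """

    bins: int = 10
    binning: str = "equal_frequency"
    l: int = 5
    k: int = 5
    knn: int = 4
    q: int = 10
    surrogate: str = "shuffle"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l != self.k:
            raise ValueError("l = k is required for information-transfer detection")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.q < 1:
            raise ValueError("surrogate count q must be >= 1")
        if self.binning not in ("equal_frequency", "equal_width"):
            raise ValueError(f"unknown binning {self.binning!r}")
        if self.surrogate not in ("shift", "shuffle"):
            raise ValueError(f"unknown surrogate style {self.surrogate!r}")


@dataclass
class RelationMatrix:
    """``K x K`` connectivity matrix for one feature matrix and one measure.

    For TE the direction convention is: entry ``(i, j)`` = influence of
    feature ``j`` on feature ``i``.
    """

    values: np.ndarray
    measure: str
    feature_labels: list[str]
    class_label: str = ""
    scheme: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        k = self.values.shape[0]
        if self.values.shape != (k, k):
            raise ValueError("relation matrix must be square")

    @property
    def symmetric(self) -> bool:
        return self.measure in ("CR", "nMIR")

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=self.feature_labels,
                            columns=self.feature_labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, measure: str, class_label: str = "",
                 scheme: str = "") -> "RelationMatrix":
        import pandas as pd
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), measure, list(df.columns), class_label, scheme)


# ---------------------------------------------------------------------------
# absolute correlation
# ---------------------------------------------------------------------------

def correlation_matrix(fm: FeatureMatrix) -> RelationMatrix:
    """Absolute Pearson correlation between all feature-series pairs.

    Constant columns make the correlation undefined; their off-diagonal
    entries are set to 0 with a warning.
    """
    x = fm.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 rows for correlation")
    sd = x.std(axis=0)
    constant = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.abs(r)
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant feature series; "
                      "their correlations set to 0")
        r[constant, :] = 0.0
        r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    return RelationMatrix(r, "CR", fm.feature_labels, fm.class_label, fm.scheme)


# ---------------------------------------------------------------------------
# discretization and nMIR
# ---------------------------------------------------------------------------

def discretize(series: np.ndarray, params: ConnectivityParams) -> np.ndarray:
    """Map a real series to integer states.

    ``equal_frequency`` places quantile edges so bins hold (near-)equal
    counts; tied values always share a state, so the output is invariant
    under any permutation of the series. ``equal_width`` partitions
    ``[min, max]`` uniformly. A series with fewer than two distinct values
    collapses to a single state with a warning.
    """
    x = np.asarray(series, dtype=float)
    if x.size < params.bins:
        raise ValueError(f"series length {x.size} < bins {params.bins}")
    if np.unique(x).size < 2:
        warnings.warn("constant series discretized to a single state")
        return np.zeros(x.size, dtype=np.intp)
    if params.binning == "equal_frequency":
        edges = np.quantile(x, np.arange(1, params.bins) / params.bins)
    else:
        edges = np.linspace(x.min(), x.max(), params.bins + 1)[1:-1]
    return np.searchsorted(edges, x, side="right").astype(np.intp)


def _entropy(states: np.ndarray) -> float:
    counts = np.bincount(states)
    p = counts[counts > 0] / states.size
    return float(-(p * np.log(p)).sum())


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    nb = b.max() + 1
    joint = np.bincount(a * nb + b, minlength=(a.max() + 1) * nb).astype(float)
    joint = joint[joint > 0] / a.size
    return _entropy(a) + _entropy(b) + float((joint * np.log(joint)).sum())


def nmir_matrix(fm: FeatureMatrix,
                params: ConnectivityParams = ConnectivityParams(),
                ) -> RelationMatrix:
    """Normalized mutual information between all feature-series pairs.

    Off-diagonal entries are ``I(X_i; X_j) / H_max``, diagonal entries
    ``H(X_i) / H_max``, with ``H_max`` the largest entropy among the series.
    Raises if every series is constant (``H_max = 0``).
    """
    states = [discretize(fm.values[:, j], params) for j in range(fm.n_features)]
    h = np.array([_entropy(s) for s in states])
    h_max = h.max()
    if h_max == 0:
        raise ValueError("all feature series are constant; H_max = 0")
    k = fm.n_features
    m = np.zeros((k, k))
    for i in range(k):
        m[i, i] = h[i]
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = _mutual_information(states[i], states[j])
    return RelationMatrix(m / h_max, "nMIR", fm.feature_labels,
                          fm.class_label, fm.scheme)


# ---------------------------------------------------------------------------
# transfer entropy (KSG conditional mutual information)
# ---------------------------------------------------------------------------

def _embed(x: np.ndarray, m: int, t: int) -> np.ndarray:
    """Lag-embedding: row ``n`` is ``(x[n+m-1], ..., x[n])`` for ``t`` rows."""
    return np.column_stack([x[m - 1 - d: m - 1 - d + t] for d in range(m)])


def _count_within(points: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Per point, how many other points lie within its radius (max-norm)."""
    tree = cKDTree(points)
    counts = tree.query_ball_point(points, radii, p=np.inf, return_length=True)
    return counts - 1  # remove the point itself


def transfer_entropy(source: np.ndarray, target: np.ndarray,
                     params: ConnectivityParams = ConnectivityParams(),
                     ) -> float:
    """Raw (uncorrected) transfer entropy from ``source`` to ``target``.

    Computed as the KSG estimate of
    ``I(target_{n+1}; source_n^{(l)} | target_n^{(k)})`` with ``knn``
    neighbors and the Chebyshev norm. A tiny jitter (1e-10 of each series'
    scale) breaks the distance ties that discrete-valued feature series
    would otherwise produce; the jitter is a deterministic function of the
    series' values and ``params.seed``, so identical series receive
    identical jitter and TE of a series against an exact copy of itself
    cancels to zero by construction. The raw estimate may be negative;
    correction and clipping happen in :func:`te_matrix_bias_corrected`.
    """
    x = np.asarray(source, dtype=float)
    y = np.asarray(target, dtype=float)
    m = max(params.l, params.k)
    n = x.size
    if n != y.size:
        raise ValueError("source and target must have equal length")
    if n <= m + 1:
        raise ValueError(f"series length {n} too short for embedding {m}")

    def jitter(a: np.ndarray) -> np.ndarray:
        scale = a.std()
        if scale == 0:
            scale = 1.0
        rng = np.random.default_rng([params.seed, zlib.crc32(a.tobytes())])
        return a + rng.normal(0, 1e-10 * scale, a.shape)

    x, y = jitter(x), jitter(y)
    t = n - m  # usable time points
    y_fut = y[m:][:, None]
    y_past = _embed(y, params.k, t)
    x_past = _embed(x, params.l, t)

    joint = np.hstack([y_fut, x_past, y_past])
    tree = cKDTree(joint)
    # distance to the knn-th neighbor in the full joint space
    eps = tree.query(joint, k=params.knn + 1, p=np.inf)[0][:, -1]
    # shrink infinitesimally so counts are strictly-within, as KSG requires
    radii = eps * (1 - 1e-12)

    n_yz = _count_within(np.hstack([y_fut, y_past]), radii)
    n_xz = _count_within(np.hstack([x_past, y_past]), radii)
    n_z = _count_within(y_past, radii)
    te = (digamma(params.knn)
          - np.mean(digamma(n_yz + 1) + digamma(n_xz + 1) - digamma(n_z + 1)))
    return float(te)


def _surrogate(y: np.ndarray, params: ConnectivityParams,
               rng: np.random.Generator) -> np.ndarray:
    if params.surrogate == "shuffle":
        return rng.permutation(y)
    n = y.size
    offset = rng.integers(n // 4, 3 * n // 4 + 1)
    return np.roll(y, offset)


def te_pair_corrected(source: np.ndarray, target: np.ndarray,
                      params: ConnectivityParams,
                      rng: np.random.Generator) -> float:
    """Bias-corrected TE for one ordered pair: subtract the maximum TE over
    ``q`` surrogates of the target, clip negatives to 0."""
    raw = transfer_entropy(source, target, params)
    sur = [transfer_entropy(source, _surrogate(target, params, rng), params)
           for _ in range(params.q)]
    return max(raw - max(sur), 0.0)


def te_matrix_bias_corrected(fm: FeatureMatrix,
                             params: ConnectivityParams = ConnectivityParams(),
                             ) -> RelationMatrix:
    """Bias-corrected TE between all ordered feature-series pairs.

    Entry ``(i, j)`` holds the corrected TE from series ``j`` to series
    ``i``; the diagonal is 0.
    """
    k = fm.n_features
    rng = np.random.default_rng(params.seed)
    m = np.zeros((k, k))
    for j in range(k):  # source
        for i in range(k):  # target
            if i == j:
                continue
            m[i, j] = te_pair_corrected(fm.values[:, j], fm.values[:, i],
                                        params, rng)
    return RelationMatrix(m, "TE", fm.feature_labels, fm.class_label, fm.scheme)


def relation_matrices(fm: FeatureMatrix,
                      params: ConnectivityParams = ConnectivityParams(),
                      measures: tuple[str, ...] = MEASURES,
                      ) -> dict[str, RelationMatrix]:
    """All requested relation matrices for one feature matrix."""
    out: dict[str, RelationMatrix] = {}
    if "CR" in measures:
        out["CR"] = correlation_matrix(fm)
    if "nMIR" in measures:
        out["nMIR"] = nmir_matrix(fm, params)
    if "TE" in measures:
        out["TE"] = te_matrix_bias_corrected(fm, params)
    return out
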