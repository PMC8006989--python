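"""Permutation ensembles, robustness tables, and Welch significance ordering.

The centrality analysis is repeated over ``P`` seeded joint row permutations
of each feature matrix (the first permutation is the identity). CR and nMIR
are exactly permutation-invariant, so their per-feature standard deviations
over the ensemble sit at floating-point noise; the nearest-neighbor TE
estimator is order-dependent, so its centralities genuinely vary. Per
(connectivity, centrality) pair, the robustness statistic is the SD over
permutations, averaged over features, then averaged over classes.

Treating the ``P`` normalized centralities of each feature as samples,
features are ordered by pairwise one-sided Welch T-tests (a Levene check
first documents that the variances are heterogeneous, which is why Welch
rather than a pooled-variance test is used). A feature's score is the number
of features with significantly lower centrality; no multiple-testing
correction is applied across the pairs — the significance level ``theta`` is
swept instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityParams, MEASURES, relation_matrices
from .feature_extraction import FeatureMatrix
from .network_centrality import centralities_for

#: Default significance-level sweep.
THETA_SWEEP = (0.25, 0.1, 0.05, 0.025, 0.01, 0.005)


@dataclass
class CentralitySamples:
    """``P x K`` normalized centralities across permutations for one
    (class, scheme, connectivity measure, centrality measure)."""

    samples: np.ndarray
    measure: str          # connectivity measure: CR / nMIR / TE
    centrality: str       # degree / eigenvector / in_degree / ...
    scheme: str
    class_label: str
    feature_labels: list[str]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise ValueError("samples must be P x K with P >= 1")

    @property
    def n_permutations(self) -> int:
        return self.samples.shape[0]

    @property
    def n_features(self) -> int:
        return self.samples.shape[1]

    def feature_sd(self) -> np.ndarray:
        """Per-feature sample SD over permutations (ddof=1; 0 when P=1)."""
        if self.n_permutations == 1:
            return np.zeros(self.n_features)
        return self.samples.std(axis=0, ddof=1)


def permutation_ensemble(fm: FeatureMatrix, P: int, seed: int,
                         params: ConnectivityParams = ConnectivityParams(),
                         measures: tuple[str, ...] = MEASURES,
                         katz_attenuation: float = 0.9,
                         pagerank_damping: float = 0.85,
                         ) -> dict[tuple[str, str], CentralitySamples]:
    """Recompute relation matrices, networks, and normalized centralities for
    ``P`` joint row permutations of ``fm``.

    Permutation 1 is the identity ordering. One master seed spawns
    independent per-permutation substreams, so any single permutation is
    reproducible in isolation. Returns samples keyed by
    ``(connectivity measure, centrality measure)``.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(P)
    collected: dict[tuple[str, str], list[np.ndarray]] = {}
    for p in range(P):
        rng = np.random.default_rng(seeds[p])
        order = (np.arange(fm.n_proteins) if p == 0
                 else rng.permutation(fm.n_proteins))
        perm_fm = fm.permuted(order)
        perm_params = ConnectivityParams(
            bins=params.bins, binning=params.binning, l=params.l, k=params.k,
            knn=params.knn, q=params.q, surrogate=params.surrogate,
            seed=int(seeds[p].generate_state(1)[0] % (2 ** 31)))
        for measure, rm in relation_matrices(perm_fm, perm_params, measures).items():
            for cname, cv in centralities_for(rm, katz_attenuation,
                                              pagerank_damping).items():
                collected.setdefault((measure, cname), []).append(cv.normalized)
    return {
        key: CentralitySamples(np.vstack(rows), key[0], key[1],
                               fm.scheme, fm.class_label, fm.feature_labels)
        for key, rows in collected.items()
    }


def robustness_table(samples_by_class: list[CentralitySamples]) -> pd.DataFrame:
    """Mean standard deviation per (connectivity, centrality) and scheme.

    Per sample set: SD over permutations per feature, averaged over the
    features; then averaged over the classes sharing the same
    (connectivity, centrality, scheme). Rows are (connectivity, centrality)
    pairs, columns are schemes — one cell per robustness-table entry.
    """
    rows = [{"measure": s.measure, "centrality": s.centrality,
             "scheme": s.scheme, "mean_sd": float(s.feature_sd().mean())}
            for s in samples_by_class]
    df = pd.DataFrame(rows)
    table = df.groupby(["measure", "centrality", "scheme"])["mean_sd"].mean()
    return table.unstack("scheme")


# ---------------------------------------------------------------------------
# significance machinery
# ---------------------------------------------------------------------------

def levene_test(samples: CentralitySamples, theta: float) -> dict:
    """Levene's homogeneity-of-variance check across the K feature groups
    (mean-centered absolute deviations, upper-tail F at level ``theta``)."""
    if samples.n_features < 2:
        raise ValueError("need at least 2 feature groups")
    if samples.n_permutations < 2:
        raise ValueError("need at least 2 samples per group")
    groups = [samples.samples[:, j] for j in range(samples.n_features)]
    n_total = samples.n_permutations * samples.n_features
    df = (samples.n_features - 1, n_total - samples.n_features)
    if all(np.ptp(g) == 0 for g in groups):
        # every group constant: zero spread everywhere, trivially homogeneous
        return {"F": 0.0, "df": df, "p": 1.0, "homogeneous": True}
    f_stat, p_value = stats.levene(*groups, center="mean")
    return {"F": float(f_stat), "df": df, "p": float(p_value),
            "homogeneous": bool(p_value >= theta)}


@dataclass
class SignificanceOrder:
    """Pairwise Welch decisions at one significance level.

    ``decisions[i, j]`` is +1 when feature ``i``'s centrality is
    significantly higher than feature ``j``'s, -1 when significantly lower,
    0 otherwise (antisymmetric by construction). ``scores[i]`` counts the
    features significantly lower than ``i``; ``order`` lists features by
    descending score, ties sharing a score.
    """

    theta: float
    decisions: np.ndarray
    scores: np.ndarray
    order: list[str]
    feature_labels: list[str]

    @property
    def n_decisions(self) -> int:
        """Number of resolved ordered pairs (higher decisions)."""
        return int((self.decisions > 0).sum())


def welch_df(s2_i, s2_j, n_i: int, n_j: int):
    """Welch-Satterthwaite degrees of freedom; collapses to
    ``n_i + n_j - 2`` when the sample variances are equal."""
    se_i, se_j = np.asarray(s2_i) / n_i, np.asarray(s2_j) / n_j
    return (se_i + se_j) ** 2 / (se_i ** 2 / (n_i - 1) + se_j ** 2 / (n_j - 1))


def welch_pairwise(samples: CentralitySamples, theta: float,
                   ) -> SignificanceOrder:
    """Order features by pairwise one-sided Welch T-tests at level ``theta``.

    For each ordered pair, ``T = (m_i - m_j) / sqrt(S_i^2/n + S_j^2/n)`` with
    Welch-Satterthwaite degrees of freedom; ``T >= t_theta(v)`` declares
    ``i`` higher, ``T <= -t_theta(v)`` lower, otherwise no difference. A pair
    with zero variance on both sides is decided by exact mean comparison
    (identical means -> no difference).
    """
    y = samples.samples
    n = samples.n_permutations
    if n < 2:
        raise ValueError("need at least 2 permutations per feature")
    mean = y.mean(axis=0)
    var = y.var(axis=0, ddof=1)

    se_i = var[:, None] / n
    se_j = var[None, :] / n
    se2 = se_i + se_j
    diff = mean[:, None] - mean[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = diff / np.sqrt(se2)
        v = welch_df(var[:, None], var[None, :], n, n)
        t_crit = stats.t.ppf(1 - theta, v)

    decisions = np.zeros_like(t_stat, dtype=int)
    regular = se2 > 0
    decisions[regular & (t_stat >= t_crit)] = 1
    decisions[regular & (t_stat <= -t_crit)] = -1
    # both variances zero: deterministic values, decide by the means alone
    degen = ~regular
    decisions[degen & (diff > 0)] = 1
    decisions[degen & (diff < 0)] = -1
    np.fill_diagonal(decisions, 0)

    scores = (decisions > 0).sum(axis=1)
    rank = np.argsort(-scores, kind="stable")
    order = [samples.feature_labels[i] for i in rank]
    return SignificanceOrder(theta, decisions, scores, order,
                             samples.feature_labels)


@dataclass
class SignificanceSweep:
    """Welch orderings at every swept significance level, with a nestedness
    report: decisions at a smaller theta must be a subset of those at any
    larger theta."""

    orders: dict[float, SignificanceOrder]
    decision_counts: dict[float, int] = field(init=False)
    monotone: bool = field(init=False)

    def __post_init__(self) -> None:
        thetas = sorted(self.orders, reverse=True)
        self.decision_counts = {t: self.orders[t].n_decisions for t in thetas}
        self.monotone = True
        for big, small in zip(thetas, thetas[1:]):
            d_big = self.orders[big].decisions
            d_small = self.orders[small].decisions
            if ((d_small == 1) & (d_big != 1)).any():
                self.monotone = False


def significance_sweep(samples: CentralitySamples,
                       thetas: tuple[float, ...] = THETA_SWEEP,
                       ) -> SignificanceSweep:
    """Run :func:`welch_pairwise` at every level in ``thetas``."""
    for t in thetas:
        if not 0 < t < 0.5:
            raise ValueError(f"theta {t} outside (0, 0.5)")
    return SignificanceSweep({t: welch_pairwise(samples, t) for t in thetas})
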