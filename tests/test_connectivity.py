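"""Correlation, mutual-information, and transfer-entropy estimators."""

from __future__ import annotations

import numpy as np
import pytest

import featnet as fn
from featnet.connectivity import (ConnectivityParams, _entropy,
                                  _mutual_information, te_pair_corrected)
from featnet.feature_extraction import FeatureMatrix


def make_fm(values, scheme="sim", labels=None):
    values = np.asarray(values, dtype=float)
    k = values.shape[1]
    return FeatureMatrix(values, scheme,
                         labels or [f"X{j+1}" for j in range(k)],
                         [f"s{i}" for i in range(values.shape[0])], "test")


class TestCorrelationMatrix:
    def test_perfect_linear_and_sign_folding(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        fm = make_fm(np.column_stack([x, 2 * x, -x]))
        r = fn.correlation_matrix(fm).values
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(1.0)  # |r| folds the sign
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)

    def test_recovers_planted_correlation(self):
        rho = np.array([[1, 0.8], [0.8, 1.0]])
        fm = fn.simulate_feature_series(
            fn.SeriesSimSpec(n=2000, structure="correlated", n_features=2,
                             rho=rho, seed=5))
        r = fn.correlation_matrix(fm).values
        assert r[0, 1] == pytest.approx(0.8, abs=0.05)

    def test_constant_column_zeroed_with_warning(self):
        rng = np.random.default_rng(1)
        fm = make_fm(np.column_stack([rng.standard_normal(30),
                                      np.full(30, 3.0)]))
        with pytest.warns(UserWarning, match="constant"):
            r = fn.correlation_matrix(fm).values
        assert r[0, 1] == 0.0 and r[1, 1] == 1.0

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError):
            fn.correlation_matrix(make_fm(np.ones((2, 3))))

    def test_null_offdiagonal_scale(self):
        """Mean |r| of independent standard-normal columns tracks the
        sqrt(2/(pi n)) half-normal scaling."""
        n, k = 400, 12
        fm = fn.simulate_feature_series(
            fn.SeriesSimSpec(n=n, structure="independent", n_features=k, seed=9))
        r = fn.correlation_matrix(fm).values
        off = r[~np.eye(k, dtype=bool)]
        expected = np.sqrt(2 / (np.pi * n))
        assert off.mean() == pytest.approx(expected, rel=0.25)


class TestDiscretize:
    def test_equal_frequency_uniform_grid(self):
        x = np.arange(1, 101, dtype=float)
        s = fn.discretize(x, ConnectivityParams(bins=10))
        counts = np.bincount(s)
        assert (counts == 10).all()

    def test_equal_width_matches_equal_frequency_on_even_grid(self):
        x = np.linspace(0, 1, 60)
        ef = fn.discretize(x, ConnectivityParams(bins=6))
        ew = fn.discretize(x, ConnectivityParams(bins=6, binning="equal_width"))
        assert np.array_equal(ef, ew)

    def test_constant_series_single_state(self):
        with pytest.warns(UserWarning):
            s = fn.discretize(np.full(50, 2.0), ConnectivityParams())
        assert set(s) == {0}

    def test_permutation_invariance_with_ties(self):
        """Tied values always land in the same state, so the state histogram
        is identical for any reordering."""
        rng = np.random.default_rng(3)
        x = rng.integers(0, 7, 200).astype(float)  # heavy ties
        s1 = fn.discretize(x, ConnectivityParams())
        perm = rng.permutation(200)
        s2 = fn.discretize(x[perm], ConnectivityParams())
        assert np.array_equal(s1[perm], s2)

    def test_short_series_raises(self):
        with pytest.raises(ValueError):
            fn.discretize(np.arange(5.0), ConnectivityParams(bins=10))


class TestNmirMatrix:
    def test_copy_of_max_entropy_column_scores_one(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        fm = make_fm(np.column_stack([x, x.copy(), rng.standard_normal(500)]))
        m = fn.nmir_matrix(fm).values
        assert m[0, 1] == pytest.approx(1.0)
        assert np.allclose(m, m.T)
        assert m.max() <= 1 + 1e-12

    def test_max_entropy_diagonal_is_one(self):
        rng = np.random.default_rng(4)
        fm = make_fm(rng.standard_normal((300, 4)))
        m = fn.nmir_matrix(fm).values
        assert np.diag(m).max() == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        fm = fn.simulate_feature_series(
            fn.SeriesSimSpec(n=5000, structure="independent", n_features=2,
                             seed=7))
        m = fn.nmir_matrix(fm).values
        assert m[0, 1] <= 0.05

    def test_all_constant_raises(self):
        fm = make_fm(np.ones((50, 3)))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="H_max"):
                fn.nmir_matrix(fm)

    def test_plugin_entropy_and_mi_identities(self):
        """H and I from the plug-in agree with direct formulas on a small
        fully enumerated joint distribution."""
        a = np.array([0, 0, 1, 1, 2, 2, 0, 1], dtype=np.intp)
        b = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=np.intp)
        p_a = np.bincount(a) / a.size
        h_direct = -(p_a * np.log(p_a)).sum()
        assert _entropy(a) == pytest.approx(h_direct, abs=1e-12)
        # I(X;X) = H(X); I >= 0
        assert _mutual_information(a, a) == pytest.approx(_entropy(a), abs=1e-12)
        assert _mutual_information(a, b) >= -1e-12


def discrete_te_oracle(source, target, l=1):
    """Plug-in transfer entropy by exhaustive enumeration of discrete
    states: empirical conditional mutual information
    I(y_{t+1}; x_t | y_t) in nats (l = k = 1)."""
    x = np.asarray(source, dtype=int)
    y = np.asarray(target, dtype=int)
    trip = np.column_stack([y[1:], x[:-1], y[:-1]])
    n = trip.shape[0]

    def h(cols):
        _, counts = np.unique(trip[:, cols], axis=0, return_counts=True)
        p = counts / n
        return -(p * np.log(p)).sum()

    return h([0, 2]) + h([1, 2]) - h([2]) - h([0, 1, 2])


class TestTransferEntropy:
    def test_self_copy_vanishes(self):
        """TE of a series against an exact copy of itself is zero: the
        source embedding adds nothing beyond the target's own past."""
        x = np.random.default_rng(11).standard_normal(400)
        te = fn.transfer_entropy(x, x.copy(), ConnectivityParams(seed=11))
        assert abs(te) <= 1e-10

    def test_independent_null_is_small(self):
        params = ConnectivityParams(seed=0)
        vals = []
        for s in range(20):
            rng = np.random.default_rng(s)
            vals.append(fn.transfer_entropy(rng.standard_normal(1000),
                                            rng.standard_normal(1000), params))
        assert max(abs(v) for v in vals) <= 0.05

    def test_directed_coupling_asymmetry(self):
        """Y driven by X's past gives TE(X->Y) > TE(Y->X) for almost all
        seeds."""
        wins = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            n = 1000
            x = rng.standard_normal(n)
            eps = rng.standard_normal(n)
            y = np.empty(n)
            y[0] = eps[0]
            y[1:] = 0.8 * x[:-1] + 0.2 * eps[1:]
            params = ConnectivityParams(seed=s)
            wins += (fn.transfer_entropy(x, y, params)
                     > fn.transfer_entropy(y, x, params))
        assert wins >= 19

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            fn.transfer_entropy(np.arange(6.0), np.arange(6.0),
                                ConnectivityParams())

    def test_l_equals_k_enforced(self):
        with pytest.raises(ValueError):
            ConnectivityParams(l=3, k=5)

    def test_ksg_matches_discrete_plugin_on_markov_chain(self):
        """On a coupled binary Markov pair with unit embeddings, the
        nearest-neighbor estimate tracks the exhaustive-enumeration plug-in
        conditional mutual information within 10%."""
        rng = np.random.default_rng(21)
        n = 4000
        x = (rng.random(n) < 0.5).astype(float)
        flip = rng.random(n) < 0.15
        y = np.empty(n)
        y[0] = 0.0
        y[1:] = np.where(flip[1:], 1 - x[:-1], x[:-1])  # noisy copy of x's past
        params = ConnectivityParams(l=1, k=1, knn=4, seed=21)
        ksg = fn.transfer_entropy(x, y, params)
        oracle = discrete_te_oracle(x, y)
        assert ksg == pytest.approx(oracle, rel=0.10)


class TestBiasCorrectedMatrix:
    def test_planted_direction_recovered(self):
        fm = fn.simulate_feature_series(
            fn.SeriesSimSpec(n=1000, structure="var_coupled", n_features=2,
                             edges=[(0, 1, 0.8)], noise_sd=0.2, seed=0))
        rm = fn.te_matrix_bias_corrected(fm, ConnectivityParams(seed=0))
        assert rm.values[1, 0] > 0      # influence of X1 on X2
        assert rm.values[0, 1] == 0.0   # reverse direction clipped
        assert np.diag(rm.values).sum() == 0.0

    def test_clipping_is_nonnegative(self):
        fm = fn.simulate_feature_series(
            fn.SeriesSimSpec(n=200, structure="independent", n_features=4,
                             seed=3))
        rm = fn.te_matrix_bias_corrected(fm, ConnectivityParams(seed=3, q=3))
        assert (rm.values >= 0).all()

    def test_pair_correction_subtracts_surrogate_max(self):
        """Corrected value never exceeds raw minus any single surrogate."""
        rng = np.random.default_rng(5)
        fm = fn.simulate_feature_series(
            fn.SeriesSimSpec(n=300, structure="var_coupled", n_features=2,
                             edges=[(0, 1, 0.8)], noise_sd=0.3, seed=5))
        params = ConnectivityParams(seed=5)
        raw = fn.transfer_entropy(fm.values[:, 0], fm.values[:, 1], params)
        corrected = te_pair_corrected(fm.values[:, 0], fm.values[:, 1],
                                      params, rng)
        assert corrected <= max(raw, 0) + 1e-12
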