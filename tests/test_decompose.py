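import numpy as np
import pandas as pd
import pytest

from speccurve.decompose import (CurveVarianceDecomposition,
                                 decompose_variance,
                                 rerun_without_predictor)


def _grid(rng, sig, n_levels, sig_e):
    """Balanced fully crossed grid with known variance components."""
    effects = [rng.normal(0, np.sqrt(s), L) for s, L in zip(sig, n_levels)]
    shape = tuple(n_levels)
    y = rng.normal(0, np.sqrt(sig_e), shape)
    for axis, u in enumerate(effects):
        dims = [1] * len(n_levels)
        dims[axis] = n_levels[axis]
        y = y + u.reshape(dims)
    idx = np.meshgrid(*[np.arange(L) for L in n_levels], indexing="ij")
    cols = {f"c{k}": i.ravel() for k, i in enumerate(idx)}
    cols["beta"] = y.ravel()
    return pd.DataFrame(cols)


def _henderson_two_way(y):
    """ANOVA (Henderson) estimator for a balanced two-way crossed grid."""
    a, b = y.shape
    gbar = y.mean()
    msa = b * ((y.mean(axis=1) - gbar) ** 2).sum() / (a - 1)
    msb = a * ((y.mean(axis=0) - gbar) ** 2).sum() / (b - 1)
    mse = ((y - y.mean(axis=1, keepdims=True)
            - y.mean(axis=0, keepdims=True) + gbar) ** 2).sum() \
        / ((a - 1) * (b - 1))
    return (msa - mse) / b, (msb - mse) / a, mse


class TestReml:
    def test_matches_henderson_on_balanced_grid(self):
        rng = np.random.default_rng(0)
        df = _grid(rng, [0.03, 0.01], [8, 6], 0.005)
        res = decompose_variance(df, classes={"A": "c0", "B": "c1"})
        y = df["beta"].to_numpy().reshape(8, 6)
        hA, hB, he = _henderson_two_way(y)
        assert abs(res.components["A"] - hA) < 1e-3
        assert abs(res.components["B"] - hB) < 1e-3
        assert abs(res.residual - he) < 1e-3

    def test_degenerate_identical_betas(self):
        df = pd.DataFrame({"beta": np.ones(24),
                           "c0": np.repeat(np.arange(4), 6),
                           "c1": np.tile(np.arange(6), 4)})
        res = decompose_variance(df, classes={"A": "c0", "B": "c1"})
        assert res.degenerate
        assert all(v == 0.0 for v in res.components.values())
        assert all(v == 0.0 for v in res.shares.values())

    def test_single_level_class_fixed_at_zero(self):
        rng = np.random.default_rng(2)
        df = _grid(rng, [0.02], [12], 0.002)
        df["const"] = "only"
        res = decompose_variance(df, classes={"A": "c0", "B": "const"})
        assert res.components["B"] == 0.0
        assert res.components["A"] > 0.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        df = _grid(rng, [0.02, 0.008], [10, 10], 0.002)
        res1 = decompose_variance(df, classes={"A": "c0", "B": "c1"})
        df2 = df.assign(beta=df["beta"] + 5.0)
        res2 = decompose_variance(df2, classes={"A": "c0", "B": "c1"})
        for k in res1.shares:
            assert res1.shares[k] == pytest.approx(res2.shares[k], abs=1e-6)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        df = _grid(rng, [0.02, 0.008], [10, 10], 0.002)
        res1 = decompose_variance(df, classes={"A": "c0", "B": "c1"})
        df2 = df.assign(beta=3.0 * df["beta"])
        res2 = decompose_variance(df2, classes={"A": "c0", "B": "c1"})
        for k in res1.components:
            assert res2.components[k] == pytest.approx(
                9.0 * res1.components[k], rel=1e-4, abs=1e-10)
            assert res1.shares[k] == pytest.approx(res2.shares[k], abs=1e-6)

    def test_single_nonzero_class_dominates(self):
        rng = np.random.default_rng(5)
        df = _grid(rng, [0.05, 0.0], [12, 12], 1e-4)
        res = decompose_variance(df, classes={"A": "c0", "B": "c1"})
        assert res.shares["A"] >= 0.95

    def test_icc_and_share_normalization(self):
        rng = np.random.default_rng(6)
        df = _grid(rng, [0.02, 0.01, 0.005], [8, 8, 8], 0.003)
        res = decompose_variance(
            df, classes={"A": "c0", "B": "c1", "C": "c2"})
        total = sum(res.components.values()) + res.residual
        for k, v in res.components.items():
            assert res.icc[k] == pytest.approx(v / total)
            assert 0.0 <= res.icc[k] <= 1.0
        assert sum(res.shares.values()) == pytest.approx(1.0)

    def test_missing_columns_rejected(self):
        with pytest.raises(KeyError):
            CurveVarianceDecomposition(pd.DataFrame({"beta": [1.0]}),
                                       classes={"A": "absent"})


class TestRerunWithoutPredictor:
    def test_spec_counts_after_filter(self, curve_results):
        res = rerun_without_predictor(curve_results, "odba")
        assert res.n == 972 - 108  # 3 x 8 x 18 x 2 models remain
        assert sum(res.shares.values()) == pytest.approx(1.0)

    def test_constructed_offset_anomaly(self):
        rng = np.random.default_rng(8)
        df = _grid(rng, [0.01, 0.001], [6, 10], 0.0005)
        df = df.rename(columns={"c0": "outcome", "c1": "predictor"})
        df["covariates"] = "none"
        df["outliers"] = "include"
        df.loc[df["predictor"] == 0, "beta"] -= 0.15
        full = decompose_variance(df)
        reduced = rerun_without_predictor(df, 0)
        assert reduced.shares["predictor"] < full.shares["predictor"]

    def test_no_information_removal(self):
        rng = np.random.default_rng(9)
        df = _grid(rng, [0.02, 0.0], [6, 9], 1e-6)
        df = df.rename(columns={"c0": "outcome", "c1": "predictor"})
        df["covariates"] = "none"
        df["outliers"] = "include"
        # predictor level 0 sits at the grand mean structure already
        full = decompose_variance(df)
        reduced = rerun_without_predictor(df, 0)
        for k in ("outcome", "predictor"):
            assert abs(full.shares[k] - reduced.shares[k]) < 0.01

    def test_absent_predictor_rejected(self, curve_results):
        with pytest.raises(KeyError):
            rerun_without_predictor(curve_results, "not_a_scale")
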