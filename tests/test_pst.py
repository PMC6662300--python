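"""Variance partitioning and the PST statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pstfst.pst import (
    PstConfig,
    VarianceComponents,
    pairwise_pst_matrix,
    partition_variance,
    pst_value,
    sensitivity_grid,
    standardize_columns,
)


def brute_force_traces(X, ponds):
    """Between/within cross-product traces from group means (oracle)."""
    X = np.asarray(X, float)
    grand = X.mean(axis=0)
    ss_b = ss_w = 0.0
    for p in np.unique(ponds):
        sub = X[np.asarray(ponds) == p]
        m = sub.mean(axis=0)
        ss_b += len(sub) * ((m - grand) ** 2).sum()
        ss_w += ((sub - m) ** 2).sum()
    return ss_b, ss_w


class TestPstValue:
    @pytest.mark.parametrize(
        "gb, gw, h2, c, expected",
        [
            (0.0, 1.0, 0.5, 1.0, 0.0),
            (1.0, 1.0, 0.5, 1.0, 0.5),
            (1.0, 1.0, 0.5, 0.5, 1.0 / 3.0),
            (1.0, 0.0, 0.3, 0.7, 1.0),
            (2.0, 1.0, 1.0, 1.0, 0.5),
        ],
    )
    def test_closed_form(self, gb, gw, h2, c, expected):
        vc = VarianceComponents(gb, gw, 1, 10)
        assert pst_value(vc, PstConfig(h2=h2, c=c)) == pytest.approx(expected)

    def test_degenerate_components_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            pst_value(VarianceComponents(0.0, 0.0, 1, 10))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PstConfig(h2=0.0)
        with pytest.raises(ValueError):
            PstConfig(c=1.5)

    @given(
        gb=st.floats(1e-6, 1e3),
        gw=st.floats(1e-6, 1e3),
        h2=st.floats(0.05, 1.0),
        c=st.floats(0.05, 1.0),
    )
    @settings(max_examples=250, deadline=None, derandomize=True)
    def test_monotonicity_and_range(self, gb, gw, h2, c):
        vc = VarianceComponents(gb, gw, 1, 10)
        v = pst_value(vc, PstConfig(h2=h2, c=c))
        assert 0.0 <= v <= 1.0
        h2b = min(h2 + 0.05, 1.0)
        cb = min(c + 0.05, 1.0)
        if h2b - h2 > 1e-9:
            assert pst_value(vc, PstConfig(h2=h2b, c=c)) < v
        if cb - c > 1e-9:
            assert pst_value(vc, PstConfig(h2=h2, c=cb)) > v


class TestPartitionVariance:
    @pytest.mark.parametrize("trial", range(30))
    def test_matches_bruteforce_traces(self, trial):
        rng = np.random.default_rng(trial)
        n1, n2 = rng.integers(2, 20, size=2)
        p = int(rng.integers(1, 6))
        X = rng.normal(size=(n1 + n2, p))
        ponds = np.array(["A"] * n1 + ["B"] * n2)
        ss_b, ss_w = brute_force_traces(X, ponds)
        vc = partition_variance(X, ponds, convention="inertia")
        N = n1 + n2
        assert vc.delta2_gb == pytest.approx(ss_b / (N - 1), rel=1e-10)
        assert vc.delta2_gw == pytest.approx(ss_w / (N - 1), rel=1e-10)
        # components convention vs method-of-moments from the same traces
        vcc = partition_variance(X, ponds, convention="components")
        ms_b, ms_w = ss_b / 1, ss_w / (N - 2)
        n0 = (N - (n1**2 + n2**2) / N) / 1
        assert vcc.delta2_gw == pytest.approx(ms_w, rel=1e-10)
        assert vcc.delta2_gb == pytest.approx(max((ms_b - ms_w) / n0, 0.0), rel=1e-10, abs=1e-12)

    def test_trace_conservation(self, rng):
        X = rng.normal(size=(25, 4))
        ponds = np.array(["A"] * 10 + ["B"] * 15)
        ss_b, ss_w = brute_force_traces(X, ponds)
        Xc = X - X.mean(axis=0)
        assert ss_b + ss_w == pytest.approx((Xc**2).sum(), rel=1e-10)

    def test_identical_means_give_zero_between(self):
        base = np.array([[1.0, 2.0], [3.0, 0.0], [2.0, 1.0]])
        X = np.vstack([base, base])  # pond means identical by construction
        ponds = np.array(["A"] * 3 + ["B"] * 3)
        for conv in ("components", "inertia"):
            vc = partition_variance(X, ponds, convention=conv)
            assert vc.delta2_gb == pytest.approx(0.0, abs=1e-12)

    def test_univariate_equals_anova_components(self, rng):
        y = np.concatenate([rng.normal(0, 1, 8), rng.normal(1, 1, 12)])
        ponds = np.array(["A"] * 8 + ["B"] * 12)
        vc = partition_variance(y[:, None], ponds, convention="components")
        # closed-form one-way ANOVA method-of-moments components
        m1, m2, grand = y[:8].mean(), y[8:].mean(), y.mean()
        ss_b = 8 * (m1 - grand) ** 2 + 12 * (m2 - grand) ** 2
        ss_w = ((y[:8] - m1) ** 2).sum() + ((y[8:] - m2) ** 2).sum()
        ms_b, ms_w = ss_b, ss_w / 18
        n0 = (20 - (64 + 144) / 20) / 1
        assert vc.delta2_gw == pytest.approx(ms_w, rel=1e-10)
        assert vc.delta2_gb == pytest.approx(max((ms_b - ms_w) / n0, 0), rel=1e-10)

    def test_small_pond_rejected(self):
        X = np.ones((3, 2)) + np.arange(3)[:, None]
        with pytest.raises(ValueError, match=">=2 individuals"):
            partition_variance(X, np.array(["A", "B", "B"]))

    def test_three_ponds_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        with pytest.raises(ValueError, match="exactly 2"):
            partition_variance(X, np.array(["A", "A", "B", "B", "C", "C"]))


class TestPairwiseMatrix:
    def test_pair_count_for_study_design(self, study_dataset):
        X, ponds = study_dataset.traits.group_matrix("defense")
        m = pairwise_pst_matrix(X, ponds)
        assert m.n_ponds == 19
        assert m.offdiag().size == 171

    def test_identically_distributed_ponds_near_zero(self):
        rng = np.random.default_rng(8)
        n_pond, n = 5, 400
        X = rng.normal(size=(n_pond * n, 3))
        ponds = np.repeat([f"P{i}" for i in range(n_pond)], n)
        m = pairwise_pst_matrix(X, ponds)
        assert np.mean(m.offdiag()) < 0.01

    def test_common_scale_invariance(self, rng):
        X = rng.normal(size=(40, 3)) + np.repeat([0, 1], 20)[:, None]
        ponds = np.repeat(["A", "B"], 20)
        m1 = pairwise_pst_matrix(X, ponds)
        m2 = pairwise_pst_matrix(X * 7.3, ponds)
        np.testing.assert_allclose(m1.values, m2.values, rtol=1e-10)

    def test_standardization_uses_within_pond_scale(self, rng):
        X = rng.normal(size=(30, 2))
        X[:15] += 5.0  # big between-pond shift
        ponds = np.repeat(["A", "B"], 15)
        Z = standardize_columns(X, ponds)
        # pooled within-pond variance of each column is one
        for col in range(2):
            ss = sum(
                ((Z[ponds == p, col] - Z[ponds == p, col].mean()) ** 2).sum()
                for p in "AB"
            )
            assert ss / 28 == pytest.approx(1.0, rel=1e-9)


class TestSensitivityGrid:
    def test_default_grid_has_100_cells(self, small_dataset):
        X, ponds = small_dataset.traits.group_matrix("defense")
        g = sensitivity_grid(X, ponds)
        assert g.surface.shape == (10, 10)

    def test_monotone_along_both_axes(self, small_dataset):
        X, ponds = small_dataset.traits.group_matrix("feeding")
        g = sensitivity_grid(X, ponds)
        assert np.all(np.diff(g.surface, axis=0) <= 1e-12)  # h2 rows decrease
        assert np.all(np.diff(g.surface, axis=1) >= -1e-12)  # c columns increase

    def test_reference_cell_matches_default_config(self, small_dataset):
        X, ponds = small_dataset.traits.group_matrix("swimming")
        g = sensitivity_grid(X, ponds)
        m = pairwise_pst_matrix(X, ponds, PstConfig(h2=0.5, c=1.0))
        i = list(np.round(g.h2_values, 10)).index(0.5)
        j = list(np.round(g.c_values, 10)).index(1.0)
        assert g.surface[i, j] == pytest.approx(np.mean(m.offdiag()), abs=1e-12)

    def test_out_of_range_grid_rejected(self, small_dataset):
        X, ponds = small_dataset.traits.group_matrix("defense")
        with pytest.raises(ValueError):
            sensitivity_grid(X, ponds, h2_values=[0.0, 0.5])
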