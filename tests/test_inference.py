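"""Comparison layer: regressions, level tests, regime labels, pipeline."""

import numpy as np
import pandas as pd
import pytest
import yaml

from pstfst import (
    DivergenceModel,
    SimConfig,
    classify_regime,
    compare_levels,
    regress_means,
    run_pipeline,
    simulate_metapopulation,
    write_dataset,
)


def series(vals, labels=None):
    labels = labels or [f"P{i}" for i in range(len(vals))]
    return pd.Series(vals, index=labels, dtype=float)


class TestRegressMeans:
    def test_exact_linear_relationship(self):
        x = series(np.linspace(0.01, 0.1, 8))
        y = 2.0 * x + 0.03
        r = regress_means(y, x)
        assert r.slope == pytest.approx(2.0)
        assert r.r2_adj == pytest.approx(1.0)
        assert r.p_value < 1e-10
        assert r.df_resid == 6

    def test_five_point_normal_equations_oracle(self):
        xv = np.array([0.02, 0.04, 0.05, 0.07, 0.09])
        yv = np.array([0.03, 0.02, 0.06, 0.05, 0.08])
        r = regress_means(series(yv), series(xv))
        b = ((xv - xv.mean()) * (yv - yv.mean())).sum() / ((xv - xv.mean()) ** 2).sum()
        a = yv.mean() - b * xv.mean()
        resid = yv - (a + b * xv)
        ss_res, ss_tot = (resid**2).sum(), ((yv - yv.mean()) ** 2).sum()
        f = (ss_tot - ss_res) / 1 / (ss_res / 3)
        assert r.slope == pytest.approx(b, rel=1e-10)
        assert r.intercept == pytest.approx(a, rel=1e-10)
        assert r.f_stat == pytest.approx(f, rel=1e-9)
        assert r.r2_adj == pytest.approx(1 - (ss_res / 3) / (ss_tot / 4), rel=1e-9)

    def test_null_adjusted_r2_centered_and_often_negative(self):
        # independence null: E[R2] = 1/(n-1), so the (n-1)/(n-2) adjustment
        # centers adjusted R2 exactly on 0 while individual draws go negative
        # (the behaviour that distinguishes adjusted from plain R2)
        rng = np.random.default_rng(6)
        n = 20
        vals = np.array([
            regress_means(series(rng.normal(size=n)), series(rng.normal(size=n))).r2_adj
            for _ in range(400)
        ])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se
        assert (vals < 0).mean() > 0.4  # negative values are routine

    def test_affine_rescaling_of_predictor(self):
        rng = np.random.default_rng(2)
        x = series(rng.random(10))
        y = series(rng.random(10))
        r1 = regress_means(y, x)
        r2 = regress_means(y, 10 * x + 3)
        assert r2.slope == pytest.approx(r1.slope / 10, rel=1e-9)
        assert r2.r2_adj == pytest.approx(r1.r2_adj, rel=1e-9)
        assert r2.p_value == pytest.approx(r1.p_value, rel=1e-9)

    def test_constant_predictor_raises(self):
        with pytest.raises(ValueError, match="constant"):
            regress_means(series([1, 2, 3]), series([5, 5, 5]))

    def test_misaligned_labels_raise(self):
        y = series([1, 2, 3], labels=["A", "B", "C"])
        x = series([1, 2, 3], labels=["A", "B", "D"])
        with pytest.raises(ValueError, match="labels"):
            regress_means(y, x)


class TestCompareLevels:
    def test_identical_vectors_give_f_zero(self):
        v = series([0.1, 0.2, 0.3, 0.4])
        lc = compare_levels(v, v.copy())
        assert lc.f_stat == pytest.approx(0.0, abs=1e-18)
        assert lc.p_value == pytest.approx(1.0)

    def test_equals_squared_t_statistic(self):
        import scipy.stats

        rng = np.random.default_rng(4)
        a = series(rng.normal(0.05, 0.01, 12))
        b = series(rng.normal(0.08, 0.01, 12))
        lc = compare_levels(a, b)
        t, p = scipy.stats.ttest_ind(a.to_numpy(), b.to_numpy())
        assert lc.f_stat == pytest.approx(t**2, rel=1e-9)
        assert lc.p_value == pytest.approx(p, rel=1e-9)

    def test_outlier_exclusion_reduces_n(self):
        rng = np.random.default_rng(1)
        labels = [f"P{i}" for i in range(19)]
        p = series(rng.normal(0.06, 0.01, 19), labels)
        f = series(rng.normal(0.06, 0.01, 19), labels)
        lc = compare_levels(p, f, n_outliers=2)
        assert lc.n_pst == 17
        assert lc.n_fst == 19
        assert lc.df_den == 17 + 19 - 2
        assert len(lc.excluded) == 2
        # excluded = most extreme deviations from the median
        dev = (p - p.median()).abs().sort_values(ascending=False)
        assert set(lc.excluded) == set(dev.index[:2])

    def test_type_one_error_near_alpha_on_iid_nulls(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            p = series(rng.normal(0.06, 0.02, 19))
            f = series(rng.normal(0.06, 0.02, 19))
            if compare_levels(p, f).p_value < 0.05:
                rejections += 1
        rate = rejections / n_sim
        assert 0.02 < rate < 0.09

    def test_too_few_ponds_after_exclusion_raises(self):
        v = series([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="fewer than 3"):
            compare_levels(v, v.copy(), exclude=["P0"])


class TestClassifyRegime:
    @pytest.mark.parametrize(
        "pst, fst, p, expected",
        [
            (0.10, 0.05, 0.01, "divergent-selection-or-plasticity"),
            (0.02, 0.06, 0.01, "stabilizing-selection"),
            (0.10, 0.05, 0.40, "drift-consistent"),
            (0.02, 0.06, 0.40, "drift-consistent"),
        ],
    )
    def test_rule(self, pst, fst, p, expected):
        label, caveat = classify_regime(pst, fst, p)
        assert label == expected
        assert "plasticity" in caveat


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    ds = simulate_metapopulation(
        SimConfig(n_ponds=6, n_per_pond=(12, 18), n_generations=60, seed=21)
    )
    write_dataset(ds, out)
    return out


@pytest.fixture(scope="module")
def config_file(fixture_dir):
    cfg = {
        "traits": str(fixture_dir / "traits.csv"),
        "genepop": str(fixture_dir / "genotypes.gen"),
        "tps": str(fixture_dir / "landmarks.tps"),
        "env": str(fixture_dir / "environment.csv"),
        "counts": str(fixture_dir / "counts.csv"),
        "n_perm": 199,
        "seed": 17,
    }
    path = fixture_dir / "cfg.yaml"
    path.write_text(yaml.safe_dump(cfg))
    return path


class TestPipeline:
    def test_report_bundle_layout(self, config_file, tmp_path):
        res = run_pipeline(config_file, out_dir=tmp_path / "out")
        assert set(res.pst_matrices) == {"feeding", "swimming", "defense", "shape"}
        assert set(res.est_matrices) == {"biotic", "diet", "abiotic"}
        assert res.fst.n_ponds == 6
        assert set(res.regimes) == set(res.pst_matrices)
        written = {p.name for p in (tmp_path / "out").iterdir()}
        assert "fst_matrix.tsv" in written
        assert "summary.json" in written
        assert len([n for n in written if n.startswith("pst_")]) == 4
        assert len([n for n in written if n.startswith("est_")]) == 3

    def test_rerun_is_byte_identical(self, config_file, tmp_path):
        run_pipeline(config_file, out_dir=tmp_path / "a")
        run_pipeline(config_file, out_dir=tmp_path / "b")
        for p in sorted((tmp_path / "a").iterdir()):
            assert p.read_bytes() == (tmp_path / "b" / p.name).read_bytes()

    def test_stage_error_names_the_stage(self, config_file, tmp_path):
        cfg = yaml.safe_load(config_file.read_text())
        cfg["genepop"] = str(tmp_path / "missing.gen")
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(cfg))
        with pytest.raises(RuntimeError, match="stage 'load'"):
            run_pipeline(bad)

    def test_summary_mentions_every_group(self, config_file, tmp_path):
        res = run_pipeline(config_file)
        text = res.summary()
        for g in ("feeding", "swimming", "defense", "shape"):
            assert g in text

    def test_sensitivity_grid_from_results(self, config_file):
        res = run_pipeline(config_file)
        grid = res.sensitivity_grid("defense")
        assert grid.surface.shape == (10, 10)
        assert np.isfinite(grid.surface).all()
        grid_shape = res.sensitivity_grid("shape")
        assert np.isfinite(grid_shape.surface).all()
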