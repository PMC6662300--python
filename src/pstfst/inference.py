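"""The comparison layer: PST vs FST vs EST.

`DivergenceModel` bundles the study inputs (trait table, genotypes,
landmark shapes, environment and prey-count tables) and `fit()` runs the
whole analysis — size correction, trait tests, Procrustes pipeline,
pairwise PST/FST/EST matrices, pond means, mean-based regressions and
level tests, and the drift/selection regime classification — returning a
`DivergenceResults` object with a `summary()` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from . import est as est_mod
from . import popgen, pst, shape, traits as traits_mod
from .matrices import PairwiseMatrix, pond_means

__all__ = [
    "RegressionResult",
    "LevelComparison",
    "regress_means",
    "compare_levels",
    "classify_regime",
    "DivergenceModel",
    "DivergenceResults",
    "run_pipeline",
]

PLASTICITY_CAVEAT = (
    "wild-caught phenotypes: divergent selection and phenotypic plasticity "
    "are confounded"
)


@dataclass
class RegressionResult:
    """OLS fit of one per-pond mean divergence measure on another."""

    slope: float
    intercept: float
    r2_adj: float
    f_stat: float
    df_resid: int
    p_value: float
    n: int
    response: str = "y"
    predictor: str = "x"


def regress_means(
    y: pd.Series, x: pd.Series, response: str = "PST", predictor: str = "FST"
) -> RegressionResult:
    """Ordinary least squares on aligned per-pond mean vectors.

    Reports adjusted R^2 (which can be negative for uninformative
    predictors).  Pond labels must match between the two series.
    """
    if len(y) != len(x):
        raise ValueError("pond vectors have different lengths")
    if list(y.index) != list(x.index):
        if set(y.index) != set(x.index):
            raise ValueError("pond labels of y and x do not match")
        x = x.reindex(y.index)
    if len(y) < 3:
        raise ValueError("need >=3 ponds for a regression")
    xv = x.to_numpy(dtype=float)
    if np.ptp(xv) == 0:
        raise ValueError("constant predictor; regression undefined")
    yv = y.to_numpy(dtype=float)
    if np.ptp(yv) == 0:
        # degenerate response (e.g. saturated divergence): no relationship
        return RegressionResult(
            slope=0.0, intercept=float(yv[0]), r2_adj=0.0, f_stat=0.0,
            df_resid=len(y) - 2, p_value=1.0, n=len(y),
            response=response, predictor=predictor,
        )
    X = sm.add_constant(xv)
    fit = sm.OLS(y.to_numpy(dtype=float), X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2_adj=float(fit.rsquared_adj),
        f_stat=float(fit.fvalue),
        df_resid=int(fit.df_resid),
        p_value=float(fit.f_pvalue),
        n=len(y),
        response=response,
        predictor=predictor,
    )


@dataclass
class LevelComparison:
    """One-way ANOVA of stacked pond-mean PST and FST values."""

    pst_mean: float
    fst_mean: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    excluded: list[str] = field(default_factory=list)
    n_pst: int = 0
    n_fst: int = 0


def _median_outliers(values: pd.Series, k: int) -> list[str]:
    """Labels of the k values most distant from the median."""
    if k <= 0:
        return []
    dev = (values - values.median()).abs().sort_values(ascending=False)
    return [str(i) for i in dev.index[:k]]


def compare_levels(
    pst_means: pd.Series,
    fst_means: pd.Series,
    exclude: list[str] | None = None,
    n_outliers: int = 0,
    exclude_from_fst: bool = False,
) -> LevelComparison:
    """Test whether pond-mean PST and FST differ in level.

    Stacks the two pond-mean vectors with a two-level group factor and runs
    a one-way ANOVA.  ``exclude`` drops named ponds from the PST vector
    (and, when ``exclude_from_fst``, from the FST vector too); when
    ``exclude`` is None and ``n_outliers`` > 0, the outliers are the
    n_outliers PST means most distant from the PST median.
    """
    if set(pst_means.index) != set(fst_means.index):
        raise ValueError("pond labels of the two mean vectors do not match")
    fst_means = fst_means.reindex(pst_means.index)
    if exclude is None:
        exclude = _median_outliers(pst_means, n_outliers)
    else:
        exclude = [str(e) for e in exclude]
        bad = set(exclude) - set(map(str, pst_means.index))
        if bad:
            raise ValueError(f"unknown ponds in exclude list: {sorted(bad)}")
    p = pst_means.drop(exclude)
    f = fst_means.drop(exclude) if exclude_from_fst else fst_means
    if len(p) < 3 or len(f) < 3:
        raise ValueError("fewer than 3 ponds remaining after exclusions")
    values = np.concatenate([p.to_numpy(float), f.to_numpy(float)])
    groups = np.array([0] * len(p) + [1] * len(f))
    grand = values.mean()
    ss_b = sum(
        (values[groups == g].mean() - grand) ** 2 * (groups == g).sum()
        for g in (0, 1)
    )
    ss_w = sum(
        ((values[groups == g] - values[groups == g].mean()) ** 2).sum()
        for g in (0, 1)
    )
    df_num, df_den = 1, len(values) - 2
    if ss_w == 0:
        f_stat, p_value = (0.0, 1.0) if ss_b == 0 else (np.inf, 0.0)
    else:
        f_stat = (ss_b / df_num) / (ss_w / df_den)
        import scipy.stats

        p_value = float(scipy.stats.f.sf(f_stat, df_num, df_den))
    return LevelComparison(
        pst_mean=float(p.mean()),
        fst_mean=float(f.mean()),
        f_stat=float(f_stat),
        df_num=df_num,
        df_den=df_den,
        p_value=float(p_value),
        excluded=exclude,
        n_pst=len(p),
        n_fst=len(f),
    )


def classify_regime(
    pst_mean: float, fst_mean: float, level_p: float, alpha: float = 0.05
) -> tuple[str, str]:
    """QST-FST interpretation rule applied to the level test.

    Returns (label, caveat): significantly PST > FST suggests divergent
    selection (or plasticity, for wild-collected phenotypes); significantly
    PST < FST stabilizing selection; otherwise drift-consistent.
    """
    if level_p < alpha and pst_mean > fst_mean:
        return "divergent-selection-or-plasticity", PLASTICITY_CAVEAT
    if level_p < alpha and pst_mean < fst_mean:
        return "stabilizing-selection", PLASTICITY_CAVEAT
    return "drift-consistent", PLASTICITY_CAVEAT


# ---------------------------------------------------------------------------
# Model / Results


class DivergenceModel:
    """PST-FST-EST divergence analysis of one pond metapopulation.

    Parameters
    ----------
    traits : TraitTable
        Individual phenotypes with the trait-group registry.
    genotypes : GenotypeTable
        Multilocus microsatellite calls for the FST side.
    landmarks : LandmarkSet, optional
        Raw landmark configurations for the body-shape group.
    environment : EnvTable, optional
        Per-pond abiotic table (pH, TDS, area) for the abiotic EST axis.
    counts : DataFrame, optional
        Long-format prey counts (pond, context, individual, taxon, count,
        total_aliquots) for the diet and prey-availability EST axes.
    size_correct : bool
        Apply pooled log-log residual size correction to length traits.
    """

    def __init__(
        self,
        traits: traits_mod.TraitTable,
        genotypes: popgen.GenotypeTable,
        landmarks: shape.LandmarkSet | None = None,
        environment: est_mod.EnvTable | None = None,
        counts: pd.DataFrame | None = None,
        size_correct: bool = True,
    ) -> None:
        self.traits = traits
        self.genotypes = genotypes
        self.landmarks = landmarks
        self.environment = environment
        self.counts = counts
        self.size_correct = size_correct

    @classmethod
    def from_files(
        cls,
        traits_csv,
        genepop,
        tps=None,
        env_csv=None,
        counts_csv=None,
        groups: dict[str, list[str]] | None = None,
        size_correct: bool = True,
    ) -> "DivergenceModel":
        tt = traits_mod.TraitTable.from_csv(traits_csv, groups=groups)
        gt = popgen.read_genepop(genepop)
        lm = shape.read_tps(tps).with_metadata(tt.data) if tps else None
        envt = est_mod.EnvTable.from_csv(env_csv) if env_csv else None
        cts = pd.read_csv(counts_csv, keep_default_na=False) if counts_csv else None
        return cls(tt, gt, lm, envt, cts, size_correct=size_correct)

    @classmethod
    def from_dataset(cls, ds, size_correct: bool = True) -> "DivergenceModel":
        """Build from a SyntheticDataset."""
        return cls(
            traits=ds.traits, genotypes=ds.genotypes, landmarks=ds.landmarks,
            environment=ds.environment, counts=ds.counts,
            size_correct=size_correct,
        )

    def fit(
        self,
        h2: float = 0.5,
        c: float = 1.0,
        convention: str = "components",
        n_perm: int = 1000,
        alpha: float = 0.05,
        n_outliers: int = 2,
        seed: int = 0,
        fst_as_response: bool = False,
        run_trait_tests: bool = True,
    ) -> "DivergenceResults":
        cfg = pst.PstConfig(h2=h2, c=c)
        tt = (
            traits_mod.size_correct_table(self.traits)
            if self.size_correct
            else self.traits
        )

        # trait-group PST matrices
        pst_matrices: dict[str, PairwiseMatrix] = {}
        for gname in tt.groups:
            X, ponds = tt.group_matrix(gname)
            pst_matrices[gname] = pst.pairwise_pst_matrix(
                X, ponds, cfg, convention=convention
            )

        # shape group
        aligned = scores = proc_tab = None
        if self.landmarks is not None:
            aligned = shape.gpa(self.landmarks)
            scores, evals = shape.shape_pca(aligned)
            # GPA fixes 4 degrees of freedom (translation x2, rotation,
            # scale), so aligned shapes live in a 2k-4 dimensional space to
            # first order; the trailing components are superimposition
            # round-off and are dropped before PST.
            n_shape_dims = scores.shape[1] - 4
            keep = np.zeros(scores.shape[1], dtype=bool)
            keep[:n_shape_dims] = evals[:n_shape_dims] > 1e-12 * max(evals[0], 1e-300)
            # PCA scores are an isometric rotation of the Procrustes
            # coordinates and share one scale, so no per-column
            # standardization (which would distort the shape-space geometry).
            pst_matrices["shape"] = pst.pairwise_pst_matrix(
                scores[:, keep], aligned.ponds, cfg, convention=convention,
                standardize=False,
            )
            if run_trait_tests:
                proc_tab = shape.procrustes_anova(aligned, n_perm=n_perm, seed=seed)

        # FST
        fst = popgen.fst_matrix(self.genotypes)

        # EST axes
        est_axes: dict[str, pd.Series] = {}
        est_matrices: dict[str, PairwiseMatrix] = {}
        if self.counts is not None:
            inv_samples, diet_samples = _count_samples(self.counts)
            inv_props = {}
            for pond, sample in inv_samples.items():
                inv_props[pond] = est_mod.limnetic_proportion(sample)
            est_axes["biotic"] = pd.Series(inv_props, name="pond_limnetic")
            est_axes["diet"] = est_mod.diet_pond_proportions(diet_samples)
        if self.environment is not None:
            est_axes["abiotic"] = est_mod.abiotic_pc1(self.environment)
        for axis, vals in est_axes.items():
            est_matrices[axis] = est_mod.pairwise_est(
                vals.reindex(fst.labels), kind="EST"
            )

        # pond means
        means = pd.DataFrame({"FST": pond_means(fst)})
        for gname, m in pst_matrices.items():
            means[f"PST_{gname}"] = pond_means(m)
        for axis, m in est_matrices.items():
            means[f"EST_{axis}"] = pond_means(m)

        # regressions and level tests
        regressions: dict[str, RegressionResult] = {}
        level_tests: dict[str, LevelComparison] = {}
        level_tests_rescreen: dict[str, LevelComparison] = {}
        regimes: dict[str, str] = {}
        for gname in pst_matrices:
            pm, fm = means[f"PST_{gname}"], means["FST"]
            if fst_as_response:
                regressions[f"{gname}~FST"] = regress_means(
                    fm, pm, response="FST", predictor=f"PST_{gname}"
                )
            else:
                regressions[f"{gname}~FST"] = regress_means(
                    pm, fm, response=f"PST_{gname}", predictor="FST"
                )
            lt = compare_levels(pm, fm)
            level_tests[gname] = lt
            level_tests_rescreen[gname] = compare_levels(
                pm, fm, n_outliers=n_outliers
            )
            regimes[gname], _ = classify_regime(
                lt.pst_mean, lt.fst_mean, lt.p_value, alpha=alpha
            )
            for axis in est_matrices:
                regressions[f"{gname}~EST_{axis}"] = regress_means(
                    pm, means[f"EST_{axis}"],
                    response=f"PST_{gname}", predictor=f"EST_{axis}",
                )

        # univariate/multivariate trait tests
        manova = {}
        anovas = {}
        if run_trait_tests:
            for gname in tt.groups:
                manova[gname] = traits_mod.manova_pillai(tt, gname)
                for col in tt.groups[gname]:
                    anovas[col] = traits_mod.anova_trait(tt, col)

        return DivergenceResults(
            model=self,
            config=cfg,
            convention=convention,
            alpha=alpha,
            corrected_traits=tt,
            pst_matrices=pst_matrices,
            fst=fst,
            est_axes=est_axes,
            est_matrices=est_matrices,
            pond_mean_table=means,
            regressions=regressions,
            level_tests=level_tests,
            level_tests_rescreen=level_tests_rescreen,
            regimes=regimes,
            manova=manova,
            anovas=anovas,
            procrustes_anova=proc_tab,
            aligned_shapes=aligned,
            shape_scores=scores,
        )


def _count_samples(counts: pd.DataFrame):
    """Split a long-format count table into pond and per-fish CountSamples."""
    inv: dict[str, est_mod.CountSample] = {}
    diet: list[est_mod.CountSample] = []
    pond_rows = counts[counts["context"] == "pond_invertebrates"]
    for pond, grp in pond_rows.groupby("pond", sort=False):
        inv[str(pond)] = est_mod.CountSample(
            pond=str(pond), context="pond_invertebrates",
            counts=dict(zip(grp["taxon"], grp["count"].astype(float))),
        )
    diet_rows = counts[counts["context"] == "diet"]
    for (pond, fish), grp in diet_rows.groupby(["pond", "individual"], sort=False):
        diet.append(
            est_mod.CountSample(
                pond=str(pond), context="diet", individual=str(fish),
                counts=dict(zip(grp["taxon"], grp["count"].astype(float))),
            )
        )
    return inv, diet


@dataclass
class DivergenceResults:
    """Fitted divergence analysis: matrices, means, tests and labels."""

    model: DivergenceModel
    config: pst.PstConfig
    convention: str
    alpha: float
    corrected_traits: traits_mod.TraitTable
    pst_matrices: dict[str, PairwiseMatrix]
    fst: PairwiseMatrix
    est_axes: dict[str, pd.Series]
    est_matrices: dict[str, PairwiseMatrix]
    pond_mean_table: pd.DataFrame
    regressions: dict[str, RegressionResult]
    level_tests: dict[str, LevelComparison]
    level_tests_rescreen: dict[str, LevelComparison]
    regimes: dict[str, str]
    manova: dict
    anovas: dict
    procrustes_anova: pd.DataFrame | None
    aligned_shapes: shape.AlignedShapes | None
    shape_scores: np.ndarray | None

    def sensitivity_grid(
        self, group: str, h2_values=None, c_values=None
    ) -> pst.SensitivityGrid:
        """Mean-PST surface over the h2 x c grid for one trait group."""
        tt = self.corrected_traits
        standardize = True
        if group == "shape":
            if self.shape_scores is None:
                raise ValueError("model was fitted without landmarks")
            X, ponds = self.shape_scores[:, : self.shape_scores.shape[1] - 4], (
                self.aligned_shapes.ponds
            )
            standardize = False
        else:
            X, ponds = tt.group_matrix(group)
        return pst.sensitivity_grid(
            X, ponds, h2_values, c_values,
            fst_mean=float(pond_means(self.fst).mean()),
            convention=self.convention,
            standardize=standardize,
        )

    def summary(self) -> str:
        """Human-readable report of the fitted comparisons."""
        lines = []
        lines.append("PST-FST-EST divergence analysis")
        lines.append("=" * 64)
        lines.append(
            f"ponds: {self.fst.n_ponds}   h2 = {self.config.h2:g}   "
            f"c = {self.config.c:g}   convention = {self.convention}"
        )
        fst_means = pond_means(self.fst)
        lines.append(
            f"mean pairwise FST = {np.mean(self.fst.offdiag()):.4f} "
            f"(pond means {fst_means.min():.4f}-{fst_means.max():.4f})"
        )
        lines.append("")
        lines.append(
            f"{'group':<10}{'mean PST':>10}{'mean FST':>10}{'level p':>10}"
            f"{'R2adj(PST~FST)':>16}{'p':>10}  regime"
        )
        for g, lt in self.level_tests.items():
            reg = self.regressions[f"{g}~FST"]
            lines.append(
                f"{g:<10}{lt.pst_mean:>10.4f}{lt.fst_mean:>10.4f}"
                f"{lt.p_value:>10.3g}{reg.r2_adj:>16.3f}{reg.p_value:>10.3g}"
                f"  {self.regimes[g]}"
            )
        if self.est_matrices:
            lines.append("")
            lines.append("PST ~ EST regressions (adjusted R2 / p):")
            for g in self.pst_matrices:
                parts = []
                for axis in self.est_matrices:
                    r = self.regressions[f"{g}~EST_{axis}"]
                    parts.append(f"{axis} {r.r2_adj:+.3f}/{r.p_value:.3g}")
                lines.append(f"  {g:<10}" + "   ".join(parts))
        lines.append("")
        lines.append(f"note: {PLASTICITY_CAVEAT}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, out_dir) -> list[str]:
        """Write matrices, pond means, test tables and a JSON summary."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []

        def _w(name, writer):
            writer(out / name)
            written.append(name)

        _w("fst_matrix.tsv", self.fst.to_tsv)
        for g, m in self.pst_matrices.items():
            _w(f"pst_{g}_matrix.tsv", m.to_tsv)
        for axis, m in self.est_matrices.items():
            _w(f"est_{axis}_matrix.tsv", m.to_tsv)
        _w(
            "pond_means.tsv",
            lambda p: self.pond_mean_table.to_csv(p, sep="\t", float_format="%.10g"),
        )
        summary = {
            "h2": self.config.h2,
            "c": self.config.c,
            "convention": self.convention,
            "alpha": self.alpha,
            "mean_fst": float(np.mean(self.fst.offdiag())),
            "regimes": self.regimes,
            "regressions": {
                k: vars(v).copy() for k, v in self.regressions.items()
            },
            "level_tests": {
                k: vars(v).copy() for k, v in self.level_tests.items()
            },
            "level_tests_rescreen": {
                k: vars(v).copy() for k, v in self.level_tests_rescreen.items()
            },
        }
        _w(
            "summary.json",
            lambda p: Path(p).write_text(json.dumps(summary, indent=1, sort_keys=True)),
        )
        _w("summary.txt", lambda p: Path(p).write_text(self.summary() + "\n"))
        return written


# ---------------------------------------------------------------------------
# Pipeline entry point


def run_pipeline(config, out_dir=None) -> DivergenceResults:
    """Run the end-to-end analysis from a YAML config (path or dict).

    Config keys: traits, genepop, tps, env, counts (file paths), groups,
    h2, c, convention, n_perm, alpha, n_outliers, seed, fst_as_response.
    Any stage failure is re-raised annotated with the stage name.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    model = stage(
        "load",
        lambda: DivergenceModel.from_files(
            traits_csv=config["traits"],
            genepop=config["genepop"],
            tps=config.get("tps"),
            env_csv=config.get("env"),
            counts_csv=config.get("counts"),
            groups=config.get("groups"),
            size_correct=config.get("size_correct", True),
        ),
    )
    results = stage(
        "fit",
        lambda: model.fit(
            h2=config.get("h2", 0.5),
            c=config.get("c", 1.0),
            convention=config.get("convention", "components"),
            n_perm=config.get("n_perm", 1000),
            alpha=config.get("alpha", 0.05),
            n_outliers=config.get("n_outliers", 2),
            seed=config.get("seed", 0),
            fst_as_response=config.get("fst_as_response", False),
        ),
    )
    if out_dir is not None:
        stage("save", lambda: results.save(out_dir))
    return results
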