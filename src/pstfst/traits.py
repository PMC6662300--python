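"""Per-individual phenotypes: size correction and among-pond trait tests.

Traits come in three functional groups (feeding, swimming, defense).
Length-type traits scale allometrically with body size and are replaced by
Reist-style residuals from a pooled log10-log10 regression on body length
before any divergence analysis; meristic counts are used raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "DEFAULT_GROUPS",
    "LENGTH_TRAITS",
    "TraitTable",
    "ManovaResult",
    "size_correct",
    "size_correct_table",
    "manova_pillai",
    "anova_trait",
]

# Trait-group registry.  Feeding: gill raker number/length/gap width and gill
# arc length; swimming: pectoral fin length plus dorsal/tail/pectoral fin ray
# counts; defense: dorsal spine length and lateral plate number.
DEFAULT_GROUPS: dict[str, list[str]] = {
    "feeding": ["GRN", "GRL", "GW", "AL"],
    "swimming": ["PFL", "DFRN", "TFRN", "PFRN"],
    "defense": ["DSL", "LPN"],
}

# Length-type (mm) traits that correlate with body size and get size-corrected;
# meristic counts do not.
LENGTH_TRAITS = frozenset({"GRL", "GW", "AL", "PFL", "DSL"})

REQUIRED_COLUMNS = ("id", "pond", "sex", "body_length_mm")


@dataclass
class TraitTable:
    """Individual-level phenotype records with a named trait-group registry."""

    data: pd.DataFrame
    groups: dict[str, list[str]] = field(default_factory=lambda: dict(DEFAULT_GROUPS))

    def __post_init__(self) -> None:
        for col in REQUIRED_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"trait table missing required column {col!r}")
        if (self.data["body_length_mm"] <= 0).any():
            raise ValueError("body_length_mm must be strictly positive")
        bad_sex = set(self.data["sex"].unique()) - {"M", "F"}
        if bad_sex:
            raise ValueError(f"sex must be M or F, found {sorted(bad_sex)}")
        for gname, cols in self.groups.items():
            missing = [c for c in cols if c not in self.data.columns]
            if missing:
                raise ValueError(f"group {gname!r} columns missing: {missing}")
        if self.data["pond"].nunique() < 2:
            raise ValueError("trait table needs >=2 ponds")

    @property
    def ponds(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.data["pond"].astype(str):
            seen.setdefault(p, None)
        return list(seen)

    def group_matrix(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        """(values, pond labels) for one trait group, complete cases only."""
        cols = self.groups[group]
        sub = self.data[["pond", *cols]].dropna()
        return sub[cols].to_numpy(dtype=float), sub["pond"].astype(str).to_numpy()

    @classmethod
    def from_csv(cls, path, groups: dict[str, list[str]] | None = None) -> "TraitTable":
        return cls(pd.read_csv(path), groups=groups or dict(DEFAULT_GROUPS))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def size_correct(
    table: TraitTable, trait: str, log: bool = True
) -> pd.Series:
    """Reist size-correction residuals for one trait.

    Ordinary least squares of log10(trait) on log10(body length), fitted over
    all individuals pooled (a common slope keeps residuals comparable across
    ponds); the residuals replace the trait downstream.  ``log=False`` fits on
    the raw scale instead.
    """
    y = table.data[trait].to_numpy(dtype=float)
    x = table.data["body_length_mm"].to_numpy(dtype=float)
    mask = ~np.isnan(y)
    if log:
        bad = np.where(mask & (y <= 0))[0]
        if bad.size:
            raise ValueError(
                f"trait {trait!r} has non-positive values at rows {bad.tolist()[:10]}; "
                "cannot log-transform"
            )
        yv, xv = np.log10(y[mask]), np.log10(x[mask])
    else:
        yv, xv = y[mask], x[mask]
    if np.ptp(xv) == 0:
        raise ValueError("body length has zero variance; cannot size-correct")
    slope, intercept = np.polyfit(xv, yv, 1)
    resid = np.full_like(y, np.nan)
    resid[mask] = yv - (intercept + slope * xv)
    return pd.Series(resid, index=table.data.index, name=trait)


def size_correct_table(table: TraitTable, log: bool = True) -> TraitTable:
    """Return a copy with every length-type trait replaced by its residuals."""
    df = table.data.copy()
    for gcols in table.groups.values():
        for col in gcols:
            if col in LENGTH_TRAITS:
                df[col] = size_correct(table, col, log=log)
    return TraitTable(data=df, groups=dict(table.groups))


@dataclass
class ManovaResult:
    term: str
    pillai: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


def _design_blocks(df: pd.DataFrame) -> list[np.ndarray]:
    """Sequential design blocks: intercept, pond dummies, sex dummy."""
    n = len(df)
    intercept = np.ones((n, 1))
    pond = pd.get_dummies(df["pond"].astype(str), drop_first=True).to_numpy(float)
    sex = pd.get_dummies(df["sex"].astype(str), drop_first=True).to_numpy(float)
    return [intercept, pond, sex]


def _sequential_projections(blocks: list[np.ndarray]) -> list[np.ndarray]:
    """Hat matrices of the nested designs X0, [X0 X1], [X0 X1 X2], ..."""
    hats = []
    X = np.empty((blocks[0].shape[0], 0))
    for b in blocks:
        X = np.hstack([X, b])
        Q, _ = np.linalg.qr(X)
        hats.append(Q @ Q.T)
    return hats


def manova_pillai(table: TraitTable, group: str) -> list[ManovaResult]:
    """MANOVA with Pillai's trace for pond and sex (additive model).

    Sequential (Type I) decomposition with pond entered before sex and no
    pond x sex interaction.  For each term, Pillai's trace is
    tr(H (H + E)^-1) with H the term and E the residual cross-product
    matrices; the standard F approximation supplies p-values.
    """
    cols = table.groups[group]
    sub = table.data[["pond", "sex", *cols]].dropna()
    Y = sub[cols].to_numpy(dtype=float)
    n, p = Y.shape
    blocks = _design_blocks(sub)
    dfs = [b.shape[1] for b in blocks]  # ranks of the blocks (dummies are full rank)
    df_model = sum(dfs)
    if n <= p + df_model:
        raise ValueError("too few rows for the MANOVA design")
    hats = _sequential_projections(blocks)
    E = Y.T @ (np.eye(n) - hats[-1]) @ Y
    df_e = n - df_model
    results = []
    term_names = ["pond", "sex"]
    for t, name in enumerate(term_names, start=1):
        H = Y.T @ (hats[t] - hats[t - 1]) @ Y
        q = dfs[t]
        try:
            V = float(np.trace(H @ np.linalg.inv(H + E)))
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular residual cross-product matrix; remove redundant traits"
            ) from exc
        s = min(p, q)
        m = (abs(p - q) - 1) / 2.0
        nn = (df_e - p - 1) / 2.0
        df1 = int(s * (2 * m + s + 1))
        df2 = int(s * (2 * nn + s + 1))
        denom = s - V
        f_stat = ((2 * nn + s + 1) / (2 * m + s + 1)) * (V / denom) if denom > 0 else np.inf
        p_value = float(scipy.stats.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
        results.append(
            ManovaResult(
                term=name, pillai=V, f_stat=float(f_stat),
                df_num=df1, df_den=df2, p_value=p_value,
            )
        )
    return results


def anova_trait(table: TraitTable, trait: str) -> pd.DataFrame:
    """Sequential (Type I) ANOVA of one trait on pond then sex.

    Returns a table with sum_sq, df, mean_sq, F and p per term plus the
    residual row, mirroring a pond-identity-first additive model.
    """
    sub = table.data[["pond", "sex", trait]].dropna().rename(columns={trait: "y"})
    if sub["y"].nunique() <= 1:
        raise ValueError(f"trait {trait!r} is constant; ANOVA undefined")
    model = smf.ols("y ~ C(pond) + C(sex)", data=sub).fit()
    tab = anova_lm(model, typ=1)
    tab = tab.rename(
        index={"C(pond)": "pond", "C(sex)": "sex", "Residual": "residual"}
    )
    tab["mean_sq"] = tab["sum_sq"] / tab["df"]
    return tab[["df", "sum_sq", "mean_sq", "F", "PR(>F)"]].rename(
        columns={"PR(>F)": "p_value"}
    )
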