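"""PST: phenotypic divergence from multivariate variance partitioning.

PST is the field proxy for QST when breeding designs are unavailable:

    PST = c * d2_GB / (c * d2_GB + 2 * h2 * d2_GW)

where d2_GB and d2_GW are the between- and within-pond variance of a
multivariate trait matrix, h2 is the assumed narrow-sense heritability and
c the assumed additive proportion of between-population variance.  The
between/within split is the constrained (group-membership) decomposition a
redundancy analysis performs with population as the sole predictor; it is
identical to the one-way multivariate sums-of-squares decomposition.

Interpretation follows the QST-FST logic: PST > FST suggests divergent
selection (or plasticity for wild-caught phenotypes), PST = FST drift,
PST < FST stabilizing selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import PairwiseMatrix

__all__ = [
    "VarianceComponents",
    "PstConfig",
    "SensitivityGrid",
    "standardize_columns",
    "partition_variance",
    "pst_value",
    "pairwise_pst_matrix",
    "sensitivity_grid",
]


@dataclass
class VarianceComponents:
    """Between- and within-pond variance for one pond pair (or pond set)."""

    delta2_gb: float
    delta2_gw: float
    df_between: int
    df_within: int
    convention: str = "components"
    truncated: bool = False  # negative method-of-moments estimate clipped to 0


@dataclass
class PstConfig:
    """Assumed heritability h2 and additive proportion c, both in (0, 1]."""

    h2: float = 0.5
    c: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.h2 <= 1):
            raise ValueError("h2 must be in (0, 1]")
        if not (0 < self.c <= 1):
            raise ValueError("c must be in (0, 1]")


def standardize_columns(X: np.ndarray, ponds: np.ndarray | None = None) -> np.ndarray:
    """Zero-mean columns scaled to unit variance so mm lengths and counts mix fairly.

    When pond labels are supplied, each column is divided by its pooled
    *within-pond* standard deviation rather than the total one.  Scaling by
    the total sd would shrink columns in proportion to their realized
    between-pond variance and thereby distort the between/within ratio the
    PST statistic measures; within-pond scaling leaves each column's ratio
    intact while still equalizing measurement units.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    if ponds is None:
        sd = X.std(axis=0, ddof=1)
    else:
        ponds = np.asarray(ponds)
        ss = np.zeros(X.shape[1])
        df = 0
        for p in np.unique(ponds):
            sub = X[ponds == p]
            ss += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
            df += len(sub) - 1
        sd = np.sqrt(ss / df)
    if np.any(sd == 0):
        raise ValueError("constant trait column; cannot standardize")
    return (X - mu) / sd


def partition_variance(
    X: np.ndarray, ponds: np.ndarray, convention: str = "components"
) -> VarianceComponents:
    """Between/within variance decomposition for exactly two ponds.

    The constrained decomposition projects the centered trait matrix onto
    pond membership: tr(SS_B) + tr(SS_W) = tr(SS_T).  Columns are expected
    pre-standardized (see ``pairwise_pst_matrix``).

    convention="components" converts mean squares to method-of-moments
    variance components with the unbalanced-design coefficient n0
    (negative between-component truncated to 0); convention="inertia"
    divides the raw traces by N-1.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 1:
        X = X[:, None]
    ponds = np.asarray(ponds)
    labels = np.unique(ponds)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 pond labels, got {len(labels)}")
    counts = np.array([(ponds == l).sum() for l in labels], dtype=float)
    if (counts < 2).any():
        raise ValueError("each pond needs >=2 individuals")
    N, g = len(ponds), 2

    # constrained (RDA-style) projection onto group membership
    G = np.stack([(ponds == l).astype(float) for l in labels], axis=1)
    hat = G @ np.diag(1.0 / counts) @ G.T
    Xc = X - X.mean(axis=0)
    fitted = hat @ Xc
    ss_b = float((fitted**2).sum())
    ss_w = float(((Xc - fitted) ** 2).sum())
    if ss_b + ss_w == 0:
        raise ValueError("zero total variance")

    df_b, df_w = g - 1, N - g
    if convention == "components":
        ms_b = ss_b / df_b
        ms_w = ss_w / df_w
        n0 = (N - (counts**2).sum() / N) / (g - 1)
        gb = (ms_b - ms_w) / n0
        truncated = gb < 0
        return VarianceComponents(
            delta2_gb=max(gb, 0.0), delta2_gw=ms_w,
            df_between=df_b, df_within=df_w,
            convention=convention, truncated=bool(truncated),
        )
    elif convention == "inertia":
        return VarianceComponents(
            delta2_gb=ss_b / (N - 1), delta2_gw=ss_w / (N - 1),
            df_between=df_b, df_within=df_w, convention=convention,
        )
    raise ValueError(f"unknown convention {convention!r}")


def pst_value(vc: VarianceComponents, cfg: PstConfig | None = None) -> float:
    """PST = c*d2_GB / (c*d2_GB + 2*h2*d2_GW)."""
    cfg = cfg or PstConfig()
    gb, gw = vc.delta2_gb, vc.delta2_gw
    if gb < 0 or gw < 0:
        raise ValueError("variance components must be non-negative")
    denom = cfg.c * gb + 2 * cfg.h2 * gw
    if denom == 0:
        raise ValueError("degenerate variance: both components are zero")
    return float(cfg.c * gb / denom)


def pairwise_pst_matrix(
    X: np.ndarray,
    ponds: np.ndarray,
    cfg: PstConfig | None = None,
    convention: str = "components",
    standardize: bool = True,
) -> PairwiseMatrix:
    """Pairwise PST over all unordered pond pairs of a trait matrix.

    Columns are standardized once over all individuals (not per pair) so
    every pair is measured on a common scale.
    """
    cfg = cfg or PstConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    ponds = np.asarray(ponds).astype(str)
    labels: list[str] = []
    for p in ponds:
        if p not in labels:
            labels.append(p)
    if len(labels) < 2:
        raise ValueError("need >=2 ponds")
    if standardize:
        X = standardize_columns(X, ponds)
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = (ponds == labels[i]) | (ponds == labels[j])
            vc = partition_variance(X[mask], ponds[mask], convention=convention)
            vals[i, j] = vals[j, i] = pst_value(vc, cfg)
    return PairwiseMatrix(labels=labels, values=vals, kind="PST")


@dataclass
class SensitivityGrid:
    """Mean-PST surface over an h2 x c grid, with the FST reference level."""

    h2_values: np.ndarray
    c_values: np.ndarray
    surface: np.ndarray  # (len(h2), len(c)) grand-mean PST
    fst_mean: float | None = None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.surface,
            index=pd.Index(self.h2_values, name="h2"),
            columns=pd.Index(self.c_values, name="c"),
        )
        return df

    def plot(self, ax=None, title: str | None = None):
        """One line per h2, mean PST vs c, with the FST reference dashed."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, h2 in enumerate(self.h2_values):
            ax.plot(self.c_values, self.surface[i], label=f"h2={h2:g}")
        if self.fst_mean is not None:
            ax.axhline(self.fst_mean, ls=":", color="k", label="mean FST")
        ax.set_xlabel("c (additive proportion)")
        ax.set_ylabel("mean PST")
        if title:
            ax.set_title(title)
        ax.legend(fontsize="x-small", ncol=2)
        return ax


def sensitivity_grid(
    X: np.ndarray,
    ponds: np.ndarray,
    h2_values=None,
    c_values=None,
    fst_mean: float | None = None,
    convention: str = "components",
    standardize: bool = True,
) -> SensitivityGrid:
    """Grand-mean pairwise PST at every (h2, c) combination.

    Default grid is 0.1 to 1.0 in 0.1 increments on both axes.  The
    variance components per pond pair do not depend on (h2, c), so they are
    computed once and the formula re-evaluated per cell.
    """
    h2_values = np.asarray(
        h2_values if h2_values is not None else np.round(np.arange(0.1, 1.01, 0.1), 10)
    )
    c_values = np.asarray(
        c_values if c_values is not None else np.round(np.arange(0.1, 1.01, 0.1), 10)
    )
    if np.any((h2_values <= 0) | (h2_values > 1)) or np.any((c_values <= 0) | (c_values > 1)):
        raise ValueError("grid values must lie in (0, 1]")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    ponds = np.asarray(ponds).astype(str)
    Xs = standardize_columns(X, ponds) if standardize else X
    labels = list(dict.fromkeys(ponds))
    pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    comps = []
    for i, j in pairs:
        mask = (ponds == labels[i]) | (ponds == labels[j])
        comps.append(partition_variance(Xs[mask], ponds[mask], convention=convention))
    surface = np.empty((len(h2_values), len(c_values)))
    for a, h2 in enumerate(h2_values):
        for b, c in enumerate(c_values):
            cfg = PstConfig(h2=float(h2), c=float(c))
            surface[a, b] = np.mean([pst_value(vc, cfg) for vc in comps])
    return SensitivityGrid(
        h2_values=h2_values, c_values=c_values, surface=surface, fst_mean=fst_mean
    )
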