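"""Environmental divergence (EST) axes and pairwise matrices.

Three per-pond ecological axes are built: the limnetic proportion of the
pond invertebrate community (prey availability), the mean limnetic
proportion of stomach contents (diet), and the first principal component of
the abiotic variables (pH, log10 total dissolved solids, surface area; TDS
and area min-max scaled).  Pairwise EST between two ponds is the absolute
difference of their axis values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrices import PairwiseMatrix

__all__ = [
    "PREY_CATEGORIES",
    "CountSample",
    "EnvTable",
    "aliquot_total",
    "classify_prey",
    "limnetic_proportion",
    "diet_pond_proportions",
    "abiotic_pc1",
    "pairwise_est",
]

# Fixed taxon registry: limnetic (open-water) vs benthic (bottom) vs other.
PREY_CATEGORIES: dict[str, str] = {
    "copepoda": "limnetic",
    "cladocera": "limnetic",
    "mollusca": "benthic",
    "nematoda": "benthic",
    "acari": "benthic",
    "coleoptera_larvae": "benthic",
    "chironomidae_larvae": "benthic",
    "trichoptera_larvae": "benthic",
    "collembola": "other",
    "hymenoptera": "other",
    "aphidoidea": "other",
}


def classify_prey(taxon: str) -> str:
    """Limnetic / benthic / other category for a taxon (case-insensitive)."""
    key = taxon.strip().lower().replace(" ", "_")
    try:
        return PREY_CATEGORIES[key]
    except KeyError:
        valid = ", ".join(sorted(PREY_CATEGORIES))
        raise KeyError(f"unknown taxon {taxon!r}; valid taxa: {valid}") from None


def aliquot_total(per_aliquot_counts, total_aliquots: int) -> float:
    """Estimated total invertebrate count from sub-sampled aliquots.

    Samples of 200 or fewer individuals are counted in full (pass the full
    count as a single-element list with total_aliquots=1).  Otherwise
    aliquots are accumulated until the cumulative count exceeds 200, and the
    total is extrapolated as (cumulative / aliquots counted) * total aliquots.
    """
    counts = list(per_aliquot_counts)
    if not counts:
        raise ValueError("empty aliquot count list")
    if any(c < 0 for c in counts):
        raise ValueError("aliquot counts must be non-negative")
    if total_aliquots < 1 or total_aliquots < len(counts):
        raise ValueError("total_aliquots must be >= number of counted aliquots")
    if total_aliquots == 1:
        return float(counts[0])
    cum = 0
    used = 0
    for c in counts:
        cum += c
        used += 1
        if cum > 200:
            break
    return (cum / used) * total_aliquots


@dataclass
class CountSample:
    """Per-taxon counts for one pond, from the pond net sample or one stomach."""

    pond: str
    context: str  # "pond_invertebrates" or "diet"
    counts: dict[str, float]
    individual: str | None = None  # fish id, diet context only

    def __post_init__(self) -> None:
        if self.context not in ("pond_invertebrates", "diet"):
            raise ValueError("context must be 'pond_invertebrates' or 'diet'")
        for taxon, c in self.counts.items():
            classify_prey(taxon)  # validates
            if c < 0:
                raise ValueError(f"negative count for {taxon!r}")

    def category_totals(self) -> dict[str, float]:
        out = {"limnetic": 0.0, "benthic": 0.0, "other": 0.0}
        for taxon, c in self.counts.items():
            out[classify_prey(taxon)] += c
        return out


def limnetic_proportion(sample: CountSample) -> float:
    """limnetic / (limnetic + benthic); 'other' taxa excluded."""
    cat = sample.category_totals()
    denom = cat["limnetic"] + cat["benthic"]
    if denom == 0:
        raise ValueError(
            f"no limnetic or benthic prey counted ({sample.context}, pond {sample.pond})"
        )
    return cat["limnetic"] / denom


def diet_pond_proportions(samples: list[CountSample]) -> pd.Series:
    """Per-pond mean of per-fish limnetic diet proportions.

    Fish whose stomach held neither limnetic nor benthic prey are skipped.
    """
    rows = []
    for s in samples:
        if s.context != "diet":
            raise ValueError("diet_pond_proportions expects diet samples")
        cat = s.category_totals()
        if cat["limnetic"] + cat["benthic"] == 0:
            continue
        rows.append((s.pond, limnetic_proportion(s)))
    if not rows:
        raise ValueError("no usable diet samples")
    df = pd.DataFrame(rows, columns=["pond", "prop"])
    return df.groupby("pond", sort=False)["prop"].mean().rename("diet_limnetic")


@dataclass
class EnvTable:
    """Per-pond abiotic measurements: pH, total dissolved solids (ppm), area (m2)."""

    data: pd.DataFrame  # columns: pond, pH, tds_ppm, area_m2

    def __post_init__(self) -> None:
        for col in ("pond", "pH", "tds_ppm", "area_m2"):
            if col not in self.data.columns:
                raise ValueError(f"environment table missing column {col!r}")
        if self.data["pond"].duplicated().any():
            raise ValueError("one row per pond required")
        if (self.data["tds_ppm"] <= 0).any() or (self.data["area_m2"] <= 0).any():
            raise ValueError("TDS and area must be strictly positive")

    @classmethod
    def from_csv(cls, path) -> "EnvTable":
        return cls(pd.read_csv(path))


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant column; min-max scaling undefined")
    return (x - lo) / (hi - lo)


def abiotic_pc1(env: EnvTable, scale_ph: bool = False) -> pd.Series:
    """First principal component of the processed abiotic variables.

    TDS is log10-transformed then min-max scaled; area min-max scaled; pH is
    left on its native scale by default (``scale_ph=True`` min-max scales it
    too).  Covariance PCA on centered columns; PC1 sign is fixed so the
    largest-|loading| variable loads positively.
    """
    df = env.data
    if len(df) < 3:
        raise ValueError("need >=3 ponds for a PCA")
    cols = {}
    try:
        cols["tds"] = _minmax(np.log10(df["tds_ppm"].to_numpy(float)))
    except ValueError:
        raise ValueError("constant column: tds_ppm") from None
    try:
        cols["area"] = _minmax(df["area_m2"].to_numpy(float))
    except ValueError:
        raise ValueError("constant column: area_m2") from None
    ph = df["pH"].to_numpy(float)
    if np.ptp(ph) == 0:
        raise ValueError("constant column: pH")
    cols["pH"] = _minmax(ph) if scale_ph else ph
    M = np.column_stack([cols["pH"], cols["tds"], cols["area"]])
    Mc = M - M.mean(axis=0)
    cov = Mc.T @ Mc / (len(df) - 1)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    scores = Mc @ v
    return pd.Series(scores, index=df["pond"].astype(str).to_numpy(), name="abiotic_pc1")


def pairwise_est(values: pd.Series, kind: str = "EST") -> PairwiseMatrix:
    """EST(i, j) = |v_i - v_j| for a per-pond scalar ecological axis."""
    if values.isna().any():
        missing = values.index[values.isna()].tolist()
        raise ValueError(f"missing axis value for ponds: {missing}")
    labels = [str(i) for i in values.index]
    v = values.to_numpy(dtype=float)
    vals = np.abs(v[:, None] - v[None, :])
    return PairwiseMatrix(labels=labels, values=vals, kind=kind)
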