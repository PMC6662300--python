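"""Symmetric pond-by-pond divergence matrices (FST, PST, EST) and pond means."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PairwiseMatrix", "pond_means"]


@dataclass
class PairwiseMatrix:
    """A symmetric matrix of pairwise divergence values between ponds.

    Parameters
    ----------
    labels : list of str
        Ordered pond identifiers.
    values : ndarray of shape (n_ponds, n_ponds)
        Symmetric divergence values with a zero diagonal.
    kind : {"FST", "PST", "EST"}
        Which divergence statistic the matrix holds.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "PST"

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("pairwise matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("pairwise matrix must have a zero diagonal")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pairwise matrix has non-finite entries")

    @property
    def n_ponds(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(str(a)), self.labels.index(str(b))
        return float(self.values[i, j])

    def offdiag(self) -> np.ndarray:
        """Unique off-diagonal values (upper triangle), row-major order."""
        iu = np.triu_indices(self.n_ponds, k=1)
        return self.values[iu]

    def pond_means(self) -> pd.Series:
        return pond_means(self)

    def pond_sems(self) -> pd.Series:
        """Descriptive standard error of each pond's pairwise values."""
        n = self.n_ponds
        out = {}
        for i, lab in enumerate(self.labels):
            row = np.delete(self.values[i], i)
            out[lab] = float(row.std(ddof=1) / np.sqrt(len(row)))
        return pd.Series(out, name=f"{self.kind}_sem")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "pond"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, kind: str = "PST") -> "PairwiseMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=list(df.index.astype(str)), values=df.to_numpy(), kind=kind)

    @classmethod
    def from_condensed(
        cls, labels, condensed, kind: str = "PST"
    ) -> "PairwiseMatrix":
        """Build from upper-triangle values in row-major (i<j) order."""
        n = len(labels)
        vals = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        condensed = np.asarray(condensed, dtype=float)
        if condensed.size != iu[0].size:
            raise ValueError("condensed length does not match label count")
        vals[iu] = condensed
        vals = vals + vals.T
        return cls(labels=list(labels), values=vals, kind=kind)


def pond_means(m: PairwiseMatrix) -> pd.Series:
    """Mean of each pond's off-diagonal pairwise values.

    With 19 ponds each pond mean averages its 18 pairings; this is the
    per-pond summary used for the mean-based PST/FST/EST comparisons.
    """
    if m.n_ponds < 2:
        raise ValueError("need at least 2 ponds")
    n = m.n_ponds
    sums = m.values.sum(axis=1)  # diagonal is zero
    means = sums / (n - 1)
    return pd.Series(means, index=m.labels, name=f"{m.kind}_mean")
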