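"""Geometric morphometrics: TPS I/O, generalized Procrustes analysis,
shape PCA, and permutation-based (residual-randomization) Procrustes ANOVA.

Landmark configurations (k fixed landmarks x 2 coordinates per specimen)
are superimposed by iterative translation, unit-centroid-size scaling and
optimal rotation (reflections disallowed), yielding size-free Procrustes
coordinates.  Among-group differences in those coordinates are tested with
a distance-based sequential ANOVA whose p-values come from residual
randomization under the reduced model (RRPP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkSet",
    "AlignedShapes",
    "read_tps",
    "write_tps",
    "centroid_size",
    "gpa",
    "shape_pca",
    "procrustes_anova",
]


@dataclass
class LandmarkSet:
    """Specimens x landmarks x 2 raw coordinate configurations."""

    ids: list[str]
    coords: np.ndarray  # (n, k, 2)
    ponds: np.ndarray | None = None
    sexes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (n_specimens, k, 2)")
        if self.coords.shape[0] != len(self.ids):
            raise ValueError("one id per specimen required")
        if self.coords.shape[1] < 3:
            raise ValueError("need k >= 3 landmarks")
        if np.isnan(self.coords).any():
            raise ValueError("missing landmarks are not supported")
        if np.any(centroid_size(self.coords) == 0):
            raise ValueError("specimen with zero centroid size")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def with_metadata(self, meta: pd.DataFrame) -> "LandmarkSet":
        """Attach pond/sex per specimen by joining on the id column."""
        m = meta.set_index(meta["id"].astype(str))
        ponds = np.array([str(m.loc[i, "pond"]) for i in self.ids])
        sexes = np.array([str(m.loc[i, "sex"]) for i in self.ids])
        return LandmarkSet(ids=list(self.ids), coords=self.coords.copy(),
                           ponds=ponds, sexes=sexes)


def centroid_size(coords: np.ndarray) -> np.ndarray:
    """sqrt of summed squared landmark distances from the centroid.

    Accepts (k, 2) or (n, k, 2); returns a scalar array accordingly.
    """
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    centered = coords - coords.mean(axis=1, keepdims=True)
    cs = np.sqrt((centered**2).sum(axis=(1, 2)))
    return cs[0] if single else cs


# ---------------------------------------------------------------------------
# TPS I/O

def read_tps(path) -> LandmarkSet:
    """Parse a TPS landmark file (LM=, coordinate lines, ID=; SCALE= ignored)."""
    ids: list[str] = []
    configs: list[np.ndarray] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    rec = 0
    k_expected = None
    while i < len(lines):
        if not lines[i].upper().startswith("LM="):
            raise ValueError(f"record {rec}: expected LM=, got {lines[i]!r}")
        k = int(lines[i].split("=", 1)[1])
        i += 1
        pts = []
        for _ in range(k):
            if i >= len(lines) or "=" in lines[i]:
                raise ValueError(f"record {rec}: fewer than LM={k} coordinate lines")
            x, y = lines[i].split()
            pts.append((float(x), float(y)))
            i += 1
        rec_id = f"specimen_{rec}"
        while i < len(lines) and "=" in lines[i] and not lines[i].upper().startswith("LM="):
            key, val = lines[i].split("=", 1)
            if key.upper() == "ID":
                rec_id = val.strip()
            elif key.upper() == "SCALE":
                warnings.warn("TPS SCALE= field ignored", stacklevel=2)
            i += 1
        if k_expected is None:
            k_expected = k
        elif k != k_expected:
            raise ValueError(f"record {rec}: LM={k} inconsistent with LM={k_expected}")
        ids.append(rec_id)
        configs.append(np.array(pts))
        rec += 1
    if not configs:
        raise ValueError("empty TPS file")
    return LandmarkSet(ids=ids, coords=np.stack(configs))


def write_tps(ls: LandmarkSet, path) -> None:
    with open(path, "w") as fh:
        for i, sid in enumerate(ls.ids):
            fh.write(f"LM={ls.k}\n")
            for x, y in ls.coords[i]:
                fh.write(f"{x:.17g} {y:.17g}\n")
            fh.write(f"ID={sid}\n")


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis

def _optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rotation matrix R (det +1) minimizing ||A R - B||; reflections disallowed."""
    U, _, Vt = np.linalg.svd(A.T @ B)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return R


def _principal_axes(config: np.ndarray) -> np.ndarray:
    """Rotation (det +1) taking a centered configuration to its principal axes.

    The 180-degree ambiguity is resolved by making the configuration's
    third moment along the major axis positive (falls back to the minor
    axis for symmetric shapes).
    """
    cov = config.T @ config
    evals, evecs = np.linalg.eigh(cov)
    R = evecs[:, ::-1]  # major axis first
    if np.linalg.det(R) < 0:
        R[:, 1] *= -1
    rotated = config @ R
    skew = (rotated**3).sum(axis=0)
    axis = 0 if abs(skew[0]) > 1e-12 else 1
    if skew[axis] < 0:
        R = R @ np.array([[-1.0, 0.0], [0.0, -1.0]])  # rotate 180 degrees
    return R


@dataclass
class AlignedShapes:
    """Procrustes-superimposed configurations at unit centroid size."""

    ids: list[str]
    coords: np.ndarray  # (n, k, 2) aligned
    centroid_sizes: np.ndarray  # original-scale sizes
    consensus: np.ndarray  # (k, 2)
    n_iter: int
    converged: bool
    ponds: np.ndarray | None = None
    sexes: np.ndarray | None = None

    def flat(self) -> np.ndarray:
        """(n, 2k) flattened coordinate matrix (x1, y1, x2, y2, ...)."""
        n = self.coords.shape[0]
        return self.coords.reshape(n, -1)


def gpa(ls: LandmarkSet, tol: float = 1e-8, max_iter: int = 100) -> AlignedShapes:
    """Generalized Procrustes superimposition.

    Each configuration is centered, scaled to unit centroid size, and
    iteratively rotated to the running consensus (mean shape, itself
    renormalized to unit size) until the consensus moves less than ``tol``.
    """
    X = ls.coords - ls.coords.mean(axis=1, keepdims=True)
    sizes = centroid_size(ls.coords)
    X = X / sizes[:, None, None]

    consensus = X[0].copy()
    n_iter = 0
    delta = np.inf
    for n_iter in range(1, max_iter + 1):
        for i in range(X.shape[0]):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus)
        new_consensus = X.mean(axis=0)
        new_consensus = new_consensus - new_consensus.mean(axis=0)
        new_consensus = new_consensus / centroid_size(new_consensus)
        delta = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations (last delta {delta:.3e})"
        )
    # final rotation pass against the converged consensus
    for i in range(X.shape[0]):
        X[i] = X[i] @ _optimal_rotation(X[i], consensus)
    # canonical orientation: principal axes of the consensus, so the output
    # does not inherit an arbitrary rotation from the starting specimen
    R = _principal_axes(consensus)
    consensus = consensus @ R
    for i in range(X.shape[0]):
        X[i] = X[i] @ R
    return AlignedShapes(
        ids=list(ls.ids),
        coords=X,
        centroid_sizes=sizes,
        consensus=X.mean(axis=0),
        n_iter=n_iter,
        converged=True,
        ponds=None if ls.ponds is None else np.asarray(ls.ponds),
        sexes=None if ls.sexes is None else np.asarray(ls.sexes),
    )


def shape_pca(aligned: AlignedShapes) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the flattened Procrustes coordinates.

    Returns (scores, eigenvalues) in decreasing-eigenvalue order; each
    component's sign is fixed so its largest-magnitude loading is positive.
    The full score matrix preserves inter-specimen distances and serves as
    the body-shape trait matrix for PST.
    """
    Y = aligned.flat()
    if Y.shape[0] < 2:
        raise ValueError("need >=2 specimens for PCA")
    Yc = Y - Y.mean(axis=0)
    cov = Yc.T @ Yc / (Y.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] *= -1
    scores = Yc @ evecs
    return scores, evals


# ---------------------------------------------------------------------------
# Procrustes ANOVA (distance-based, sequential, RRPP p-values)

def _hats_for_factors(ponds: np.ndarray, sexes: np.ndarray) -> list[np.ndarray]:
    n = len(ponds)
    blocks = [np.ones((n, 1))]
    blocks.append(pd.get_dummies(pd.Series(ponds).astype(str), drop_first=True).to_numpy(float))
    if sexes is not None:
        blocks.append(pd.get_dummies(pd.Series(sexes).astype(str), drop_first=True).to_numpy(float))
    hats, dfs = [], []
    X = np.empty((n, 0))
    for b in blocks:
        X = np.hstack([X, b])
        Q, _ = np.linalg.qr(X)
        hats.append(Q @ Q.T)
        dfs.append(b.shape[1])
    return hats, dfs


def procrustes_anova(
    aligned: AlignedShapes,
    n_perm: int = 1000,
    seed: int | None = 0,
    include_sex: bool = True,
) -> pd.DataFrame:
    """Sequential distance-based ANOVA of Procrustes coordinates.

    Terms are pond then (optionally) sex; sums of squares are squared
    distances of the flattened coordinate vectors under the nested linear
    models.  For each term, the reduced-model residuals are permuted across
    specimens (RRPP), the term F recomputed, and
    p = (#{F* >= F} + 1) / (n_perm + 1).
    """
    if aligned.ponds is None:
        raise ValueError("aligned shapes carry no pond labels")
    if len(np.unique(aligned.ponds)) < 2:
        raise ValueError("need >=2 ponds")
    if n_perm < 99:
        raise ValueError("n_perm < 99 gives too coarse a p-value resolution")
    sexes = aligned.sexes if include_sex else None
    Y = aligned.flat()
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    hats, dfs = _hats_for_factors(aligned.ponds, sexes)
    df_model = sum(dfs)
    df_resid = n - df_model
    ss_total = float((Yc**2).sum())
    rng = np.random.default_rng(seed)

    term_names = ["pond"] + (["sex"] if sexes is not None else [])
    rows = []
    resid_full = Y - hats[-1] @ Y
    ss_resid = float((resid_full**2).sum())
    for t, name in enumerate(term_names, start=1):
        P_term = hats[t] - hats[t - 1]
        ss_term = float(((P_term @ Y) ** 2).sum())
        ms_term = ss_term / dfs[t]
        ms_resid = ss_resid / df_resid
        f_obs = ms_term / ms_resid
        # RRPP: permute residuals of the reduced model (terms before this one)
        fitted_red = hats[t - 1] @ Y
        resid_red = Y - fitted_red
        count = 0
        P_resid = np.eye(n) - hats[-1]
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Ystar = fitted_red + resid_red[perm]
            ss_t = float(((P_term @ Ystar) ** 2).sum())
            ss_r = float(((P_resid @ Ystar) ** 2).sum())
            f_star = (ss_t / dfs[t]) / (ss_r / df_resid)
            if f_star >= f_obs:
                count += 1
        p = (count + 1) / (n_perm + 1)
        rows.append((name, dfs[t], ss_term, ms_term, f_obs, p))
    rows.append(("residual", df_resid, ss_resid, ss_resid / df_resid, np.nan, np.nan))
    rows.append(("total", n - 1, ss_total, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["term", "df", "sum_sq", "mean_sq", "F", "p_value"]
    ).set_index("term")
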