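"""Synthetic pond-metapopulation datasets with known ground truth.

The generator emulates a system of 19 small, semi-connected ponds of
threespine stickleback: finite-island Wright-Fisher genetics at 12
microsatellite loci, functional trait groups (feeding, swimming, defense)
whose pond means drift/respond to selection, 11-landmark body shapes, and
per-pond environment / invertebrate / diet tables.  Every downstream stage
of the PST-FST-EST pipeline therefore has a recoverable target.

Neutral trait dynamics are coupled to the genetic process through an
explicit additive (infinitesimal) basis: each trait's additive value is a
fixed random-sign linear function of an individual's allele dosages at the
simulated neutral loci, so pond trait means drift with the same realized
Wright-Fisher histories that produce FST.  For neutral additive traits
built this way the classical identity E[QST] = FST holds exactly
(between-pond additive variance 2*theta*V_A against within-pond
(1-theta)*V_A), which makes the drift null of the PST-FST comparison a
quantitative benchmark rather than a qualitative one.  Selection regimes
are applied as a reduced-form blend of pond means toward environment-
dependent (divergent) or common (stabilizing) optima.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import popgen, shape
from .traits import DEFAULT_GROUPS, LENGTH_TRAITS, TraitTable
from .est import EnvTable, PREY_CATEGORIES

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "expected_fst",
    "simulate_metapopulation",
    "write_dataset",
    "read_dataset",
    "TEMPLATE_LANDMARKS",
]

# 11 fixed landmarks on a stickleback-like left-side outline (snout, eye,
# head, dorsal spine bases, dorsal/caudal/anal fin insertions, pelvic girdle,
# pectoral fin base), unit-centroid-size scale.
TEMPLATE_LANDMARKS = np.array(
    [
        [-0.50, 0.00],   # snout tip
        [-0.42, 0.06],   # eye
        [-0.28, 0.12],   # rear of head, dorsal
        [-0.10, 0.16],   # first dorsal spine base
        [0.05, 0.17],    # second dorsal spine base
        [0.22, 0.13],    # dorsal fin insertion
        [0.48, 0.02],    # caudal peduncle, dorsal
        [0.46, -0.06],   # caudal peduncle, ventral
        [0.20, -0.12],   # anal fin insertion
        [-0.05, -0.15],  # pelvic girdle
        [-0.30, -0.10],  # pectoral fin base
    ]
)
TEMPLATE_LANDMARKS = TEMPLATE_LANDMARKS - TEMPLATE_LANDMARKS.mean(axis=0)
TEMPLATE_LANDMARKS = TEMPLATE_LANDMARKS / shape.centroid_size(TEMPLATE_LANDMARKS)

# Trait baselines (population-level typical values) and within-pond latent
# scales used to map the unit-variance latent process onto measurement units.
_TRAIT_BASE = {
    "GRN": 13.1, "GRL": 0.89, "GW": 0.19, "AL": 1.56,
    "PFL": 6.22, "DFRN": 11.3, "TFRN": 12.2, "PFRN": 10.3,
    "DSL": 3.1, "LPN": 3.0,
}
_COUNT_SD = 1.5       # within-pond sd of meristic counts before rounding
_LOG_RESID_SD = 0.05  # within-pond sd of length traits on the log10 scale
_ALLOMETRY = {"GRL": 0.9, "GW": 0.8, "AL": 1.0, "PFL": 1.0, "DSL": 0.9}

ALL_TRAITS = list(_TRAIT_BASE)


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic metapopulation.

    Defaults mirror the emulated field system: 19 ponds sampled at 15-47
    fish each, 12 microsatellite loci starting from 4 equifrequent alleles,
    small effective sizes (Ne = 50, mid-range of the system's 12-86), and a
    migration rate of 0.0575 whose island-model equilibrium
    1/(1 + 4*Ne*m) = 0.08 matches the system's mean pairwise FST scale.
    """

    n_ponds: int = 19
    n_per_pond: tuple[int, int] | int = (15, 47)
    n_loci: int = 12
    n_alleles: int = 4
    ne: int = 50
    migration_rate: float | np.ndarray | None = None
    n_generations: int = 100
    h2_true: float = 0.5
    regime: str = "neutral"  # neutral | divergent | stabilizing
    selection_strength: float = 0.0
    selected_group: str = "defense"
    env_gradient: np.ndarray | None = None
    n_landmarks: int = 11
    shape_noise: float = 0.005  # within-pond landmark sd, unit-centroid-size scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ponds < 2:
            raise ValueError("n_ponds must be >= 2")
        if isinstance(self.n_per_pond, int):
            self.n_per_pond = (self.n_per_pond, self.n_per_pond)
        lo, hi = self.n_per_pond
        if lo < 3 or hi < lo:
            raise ValueError("n_per_pond must satisfy 3 <= min <= max")
        if hi > self.ne:
            raise ValueError(
                f"cannot sample up to {hi} individuals from a pond of Ne={self.ne}"
            )
        if self.migration_rate is None:
            # Default connectivity profile: the emulated system spans strongly
            # structured to admixed ponds.  Per-pond immigration rates are set
            # so the local equilibrium divergence 1/(1 + 4*Ne*m_i) is
            # log-spaced from 0.012 to 0.25 along the pond sequence, giving a
            # mean pairwise FST near 0.08 with a wide pond-mean spread.
            f_local = np.geomspace(0.012, 0.25, self.n_ponds)
            self.migration_rate = (1.0 / f_local - 1.0) / (4.0 * self.ne)
        m = np.asarray(self.migration_rate, dtype=float)
        if m.ndim == 1 and m.size != self.n_ponds:
            raise ValueError("per-pond migration_rate needs one value per pond")
        if np.any((m < 0) | (m > 1)):
            raise ValueError("migration_rate must be in [0, 1]")
        if not (0 < self.h2_true <= 1):
            raise ValueError("h2_true must be in (0, 1]")
        if self.regime not in ("neutral", "divergent", "stabilizing"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be non-negative")
        for name, v in (("n_loci", self.n_loci), ("n_alleles", self.n_alleles),
                        ("ne", self.ne), ("n_generations", self.n_generations),
                        ("n_landmarks", self.n_landmarks)):
            if v < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.env_gradient is not None:
            self.env_gradient = np.asarray(self.env_gradient, dtype=float)
            if len(self.env_gradient) != self.n_ponds:
                raise ValueError("env_gradient needs one value per pond")


@dataclass
class SyntheticDataset:
    """One realized metapopulation with its ground-truth record."""

    config: SimConfig
    genotypes: popgen.GenotypeTable
    traits: TraitTable
    landmarks: shape.LandmarkSet
    environment: EnvTable
    counts: pd.DataFrame  # long format: pond, context, individual, taxon, count, aliquots
    truth: dict


def expected_fst(ne: int, migration_rate: float, n_generations: int) -> float:
    """Closed-form island-model FST approximation (validation oracle).

    Pure drift (m = 0): FST(t) = 1 - (1 - 1/(2*Ne))^t.  With migration the
    classical equilibrium 1/(1 + 4*Ne*m) is relaxed toward at the
    per-generation rate a = (1-m)^2 (1 - 1/(2*Ne)):

        FST(t) = FST_eq * (1 - a^t)

    so short horizons are handled too; for large t this reduces to the
    familiar equilibrium value.  An approximation throughout
    (infinite-island, no mutation).
    """
    if ne < 1:
        raise ValueError("ne must be >= 1")
    if migration_rate == 0:
        return 1.0 - (1.0 - 1.0 / (2.0 * ne)) ** n_generations
    f_eq = 1.0 / (1.0 + 4.0 * ne * migration_rate)
    if not np.isfinite(ne):
        return 0.0
    a = (1.0 - migration_rate) ** 2 * (1.0 - 1.0 / (2.0 * ne))
    return f_eq * (1.0 - a**n_generations)


def _wright_fisher_freqs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Island-model WF allele counts: (n_ponds, n_loci, n_alleles) of 2*Ne copies."""
    P, L, A = cfg.n_ponds, cfg.n_loci, cfg.n_alleles
    two_ne = 2 * cfg.ne
    # equifrequent start
    base = np.full(A, two_ne // A)
    base[: two_ne % A] += 1
    counts = np.tile(base, (P, L, 1)).astype(float)
    m = np.broadcast_to(
        np.asarray(cfg.migration_rate, dtype=float).reshape(-1, 1, 1), (P, 1, 1)
    ) if np.ndim(cfg.migration_rate) else float(cfg.migration_rate)
    for _ in range(cfg.n_generations):
        freqs = counts / two_ne
        pool = freqs.mean(axis=0, keepdims=True)
        post = (1 - m) * freqs + m * pool
        # multinomial sampling of the next generation's 2Ne gene copies
        flat = post.reshape(-1, A)
        flat = flat / flat.sum(axis=1, keepdims=True)
        counts = rng.multinomial(two_ne, flat).reshape(P, L, A).astype(float)
    return counts


def _sample_genotypes(
    cfg: SimConfig, counts: np.ndarray, n_per_pond: np.ndarray,
    rng: np.random.Generator,
) -> popgen.GenotypeTable:
    """Draw individuals' diploid calls from each pond's 2*Ne gene copies."""
    P, L, A = counts.shape
    individuals, ponds, rows = [], [], []
    for p in range(P):
        pond = f"P{p + 1:02d}"
        for i in range(n_per_pond[p]):
            individuals.append(f"{pond}_{i + 1:03d}")
            ponds.append(pond)
    calls = np.zeros((len(individuals), L, 2), dtype=np.int64)
    row0 = 0
    for p in range(P):
        n = n_per_pond[p]
        for l in range(L):
            copies = np.repeat(np.arange(1, A + 1), counts[p, l].astype(int))
            picks = rng.choice(copies, size=2 * n, replace=False)
            calls[row0 : row0 + n, l, 0] = picks[:n]
            calls[row0 : row0 + n, l, 1] = picks[n:]
        row0 += n
    # store unordered pairs consistently (low, high)
    calls = np.sort(calls, axis=2)
    return popgen.GenotypeTable(
        individuals=individuals, ponds=np.array(ponds),
        loci=[f"Loc{l + 1:02d}" for l in range(L)], calls=calls,
    )


def _dosage_matrix(calls: np.ndarray) -> np.ndarray:
    """Allele-dosage columns (one per locus x allele) from diploid calls."""
    n, L, _ = calls.shape
    cols = []
    for l in range(L):
        alleles = np.unique(calls[:, l, :])
        for al in alleles:
            cols.append((calls[:, l, :] == al).sum(axis=1).astype(float))
    return np.column_stack(cols)


def _pooled_within_var(X: np.ndarray, pond_idx: np.ndarray) -> np.ndarray:
    """Pooled within-pond variance per column."""
    ss = np.zeros(X.shape[1])
    df = 0
    for p in np.unique(pond_idx):
        sub = X[pond_idx == p]
        ss += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
        df += len(sub) - 1
    return ss / df


def _additive_latent(
    calls: np.ndarray, pond_idx: np.ndarray, n_dims: int,
    h2: float, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent trait matrix (N, n_dims) with additive share h2 of within-pond
    variance, the additive part drawn from the neutral-locus dosage basis.

    Each latent dimension's additive value is sum_c s_c * dosage_c with
    random signs s_c; the additive part is rescaled to within-pond variance
    h2 and Gaussian environmental noise of variance 1 - h2 is added, giving
    unit within-pond phenotypic variance on the latent scale.
    Returns (latent, additive_part, environmental_part).
    """
    D = _dosage_matrix(calls)
    Dc = D - D.mean(axis=0)
    signs = rng.choice([-1.0, 1.0], size=(D.shape[1], n_dims))
    A = Dc @ signs
    vw = _pooled_within_var(A, pond_idx)
    if np.any(vw <= 0):
        raise ValueError(
            "degenerate additive basis: a latent dimension has zero "
            "within-pond variance (all informative loci fixed)"
        )
    A = A * np.sqrt(h2 / vw)
    E = rng.normal(0.0, np.sqrt(1.0 - h2), size=A.shape) if h2 < 1 else np.zeros_like(A)
    return A + E, A, E


def _selection_blend(
    latent: np.ndarray, pond_idx: np.ndarray, optima: np.ndarray | None,
    weight: float,
) -> np.ndarray:
    """Shift pond means toward their optima by ``weight`` (reduced form)."""
    if optima is None or weight == 0:
        return latent
    out = latent.copy()
    for p in np.unique(pond_idx):
        mask = pond_idx == p
        m = out[mask].mean(axis=0)
        out[mask] += weight * (optima[p] - m)
    return out


def _trait_optima(cfg: SimConfig, gradient: np.ndarray, traits: list[str]) -> np.ndarray | None:
    if cfg.regime == "neutral" or cfg.selection_strength == 0:
        return None
    if cfg.regime == "stabilizing":
        return np.zeros((cfg.n_ponds, len(traits)))
    # divergent: optima track the (standardized) environmental gradient,
    # spread to +-2 within-pond sd at the gradient extremes
    g = (gradient - gradient.mean()) / gradient.std()
    sel = set(DEFAULT_GROUPS[cfg.selected_group])
    opt = np.zeros((cfg.n_ponds, len(traits)))
    for j, t in enumerate(traits):
        if t in sel:
            opt[:, j] = 2.0 * g
    return opt


def simulate_metapopulation(config: SimConfig) -> SyntheticDataset:
    """Generate one full synthetic dataset; deterministic given config.seed.

    Sub-streams for genetics, traits, shapes, sampling and ecology are split
    from the single seed via numpy's SeedSequence.spawn, so adding draws to
    one component never perturbs the others.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_gen, rng_trait, rng_shape, rng_sample, rng_eco = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    lo, hi = cfg.n_per_pond
    n_per_pond = rng_sample.integers(lo, hi + 1, size=cfg.n_ponds)

    gradient = (
        cfg.env_gradient
        if cfg.env_gradient is not None
        else np.linspace(-1.0, 1.0, cfg.n_ponds)
    )

    # --- genetics -----------------------------------------------------------
    counts = _wright_fisher_freqs(cfg, rng_gen)
    genotypes = _sample_genotypes(cfg, counts, n_per_pond, rng_gen)

    # --- traits (latent scale: within-pond phenotypic variance 1) ----------
    N = int(n_per_pond.sum())
    pond_idx = np.repeat(np.arange(cfg.n_ponds), n_per_pond)
    latent, additive, environ = _additive_latent(
        genotypes.calls, pond_idx, len(ALL_TRAITS), cfg.h2_true, rng_trait
    )
    optima = _trait_optima(cfg, gradient, ALL_TRAITS)
    sel_weight = 1.0 - (1.0 - min(cfg.selection_strength, 1.0)) ** cfg.n_generations
    latent = _selection_blend(latent, pond_idx, optima, sel_weight)

    sexes = np.where(rng_trait.random(N) < 0.5, "M", "F")
    pond_len_offset = rng_trait.normal(0.0, 3.0, size=cfg.n_ponds)
    base_len = np.where(sexes == "M", 47.9, 51.9)
    body_len = base_len + pond_len_offset[pond_idx] + rng_trait.normal(0.0, 4.0, size=N)
    body_len = np.clip(body_len, 31.0, None)

    data = {
        "id": genotypes.individuals,
        "pond": [str(p) for p in genotypes.ponds],
        "sex": sexes,
        "body_length_mm": np.round(body_len, 1),
    }
    log_len_c = np.log10(body_len) - np.log10(body_len).mean()
    for j, t in enumerate(ALL_TRAITS):
        if t in LENGTH_TRAITS:
            logv = (
                np.log10(_TRAIT_BASE[t])
                + _ALLOMETRY[t] * log_len_c
                + _LOG_RESID_SD * latent[:, j]
            )
            data[t] = np.round(10.0**logv, 4)
        else:
            vals = np.round(_TRAIT_BASE[t] + _COUNT_SD * latent[:, j])
            data[t] = np.clip(vals, 0, None).astype(int)
    traits = TraitTable(data=pd.DataFrame(data))

    # --- landmarks ----------------------------------------------------------
    k = cfg.n_landmarks
    if k == TEMPLATE_LANDMARKS.shape[0]:
        template = TEMPLATE_LANDMARKS
    else:  # resample the outline for non-default landmark counts
        theta = np.linspace(0, 2 * np.pi, k, endpoint=False)
        template = np.column_stack([0.5 * np.cos(theta), 0.17 * np.sin(theta)])
        template -= template.mean(axis=0)
        template /= shape.centroid_size(template)
    n_dims = 2 * k
    shape_latent, _, _ = _additive_latent(
        genotypes.calls, pond_idx, n_dims, cfg.h2_true, rng_shape
    )
    if cfg.regime == "divergent" and cfg.selected_group == "shape":
        g = (gradient - gradient.mean()) / gradient.std()
        shape_opt = np.zeros((cfg.n_ponds, n_dims))
        shape_opt[:, :4] = 2.0 * g[:, None]
        shape_latent = _selection_blend(shape_latent, pond_idx, shape_opt, sel_weight)
    elif cfg.regime == "stabilizing":
        shape_latent = _selection_blend(
            shape_latent, pond_idx, np.zeros((cfg.n_ponds, n_dims)), sel_weight
        )
    s = cfg.shape_noise
    scale_px = body_len * 10.0  # ~10 px per mm digitization scale
    coords = (
        template[None, :, :] + s * shape_latent.reshape(N, k, 2)
    ) * scale_px[:, None, None]
    landmarks = shape.LandmarkSet(
        ids=list(genotypes.individuals), coords=coords,
        ponds=genotypes.ponds.astype(str), sexes=sexes,
    )

    # --- environment --------------------------------------------------------
    g_std = (gradient - gradient.mean()) / (gradient.std() or 1.0)
    ponds_lab = [f"P{p + 1:02d}" for p in range(cfg.n_ponds)]
    ph = np.round(8.3 + 0.5 * g_std + rng_eco.normal(0, 0.2, cfg.n_ponds), 2)
    tds = np.round(10 ** (-0.95 + 0.2 * g_std + rng_eco.normal(0, 0.1, cfg.n_ponds)), 3)
    area = np.round(10 ** (3.5 + 0.5 * g_std + rng_eco.normal(0, 0.4, cfg.n_ponds)), 0)
    environment = EnvTable(
        data=pd.DataFrame(
            {"pond": ponds_lab, "pH": ph, "tds_ppm": tds, "area_m2": area}
        )
    )

    # --- invertebrates and diet --------------------------------------------
    counts_rows = []
    logit = lambda p: np.log(p / (1 - p))
    inv_logit = lambda x: 1 / (1 + np.exp(-x))
    pond_limn = inv_logit(logit(0.887) + 0.8 * g_std + rng_eco.normal(0, 0.4, cfg.n_ponds))
    diet_limn = inv_logit(logit(0.43) + 0.8 * g_std + rng_eco.normal(0, 0.5, cfg.n_ponds))
    limn_taxa = [t for t, c in PREY_CATEGORIES.items() if c == "limnetic"]
    benth_taxa = [t for t, c in PREY_CATEGORIES.items() if c == "benthic"]
    other_taxa = [t for t, c in PREY_CATEGORIES.items() if c == "other"]
    for p, pond in enumerate(ponds_lab):
        total = int(rng_eco.integers(150, 3000))
        n_aliquots = 1 if total <= 200 else int(rng_eco.integers(4, 12))
        pl = pond_limn[p]
        probs = np.concatenate([
            pl * 0.92 * np.ones(len(limn_taxa)) / len(limn_taxa),
            (1 - pl) * 0.92 * np.ones(len(benth_taxa)) / len(benth_taxa),
            0.08 * np.ones(len(other_taxa)) / len(other_taxa),
        ])
        draw = rng_eco.multinomial(total, probs / probs.sum())
        for taxon, c in zip(limn_taxa + benth_taxa + other_taxa, draw):
            counts_rows.append(
                (pond, "pond_invertebrates", "", taxon, int(c), n_aliquots)
            )
    row0 = 0
    for p, pond in enumerate(ponds_lab):
        for i in range(n_per_pond[p]):
            fish = genotypes.individuals[row0 + i]
            n_prey = int(rng_eco.integers(3, 40))
            dl = float(np.clip(diet_limn[p] + rng_eco.normal(0, 0.1), 0.02, 0.98))
            probs = np.concatenate([
                dl * 0.95 * np.ones(len(limn_taxa)) / len(limn_taxa),
                (1 - dl) * 0.95 * np.ones(len(benth_taxa)) / len(benth_taxa),
                0.05 * np.ones(len(other_taxa)) / len(other_taxa),
            ])
            draw = rng_eco.multinomial(n_prey, probs / probs.sum())
            for taxon, c in zip(limn_taxa + benth_taxa + other_taxa, draw):
                if c > 0:
                    counts_rows.append((pond, "diet", fish, taxon, int(c), 1))
        row0 += n_per_pond[p]
    counts_df = pd.DataFrame(
        counts_rows,
        columns=["pond", "context", "individual", "taxon", "count", "total_aliquots"],
    )

    # --- truth record -------------------------------------------------------
    pond_mu = np.stack(
        [latent[pond_idx == p].mean(axis=0) for p in range(cfg.n_ponds)]
    )
    gw_pooled = _pooled_within_var(latent, pond_idx)
    group_truth = {}
    group_cols = {**{g: c for g, c in DEFAULT_GROUPS.items()}}
    trait_pos = {t: j for j, t in enumerate(ALL_TRAITS)}
    for gname, cols in group_cols.items():
        idx = [trait_pos[t] for t in cols]
        gb = float(pond_mu[:, idx].var(axis=0, ddof=1).mean())
        gw = float(gw_pooled[idx].mean())
        group_truth[gname] = {
            "delta2_gb": gb,
            "delta2_gw": gw,
            "expected_pst": gb / (gb + 2 * cfg.h2_true * gw),
        }
    add_w = _pooled_within_var(additive, pond_idx).mean()
    env_w = _pooled_within_var(environ, pond_idx).mean()
    if np.ndim(cfg.migration_rate):
        # heterogeneous immigration: mean pairwise FST approximates the mean
        # of the per-pond local equilibrium divergences
        exp_fst = float(
            np.mean(1.0 / (1.0 + 4.0 * cfg.ne * np.asarray(cfg.migration_rate)))
        )
    else:
        exp_fst = expected_fst(cfg.ne, float(cfg.migration_rate), cfg.n_generations)
    truth = {
        "expected_fst": exp_fst,
        "sigma2_additive": cfg.h2_true,
        "sigma2_environmental": 1.0 - cfg.h2_true,
        "realized_h2": float(add_w / (add_w + env_w)),
        "groups": group_truth,
        "pond_mean_latent": pond_mu.tolist(),
        "n_per_pond": n_per_pond.tolist(),
        "regime": cfg.regime,
        "selected_group": cfg.selected_group,
        "env_gradient": np.asarray(gradient, dtype=float).tolist(),
    }
    return SyntheticDataset(
        config=cfg, genotypes=genotypes, traits=traits, landmarks=landmarks,
        environment=environment, counts=counts_df, truth=truth,
    )


MANIFEST_FILES = (
    "genotypes.gen",
    "landmarks.tps",
    "traits.csv",
    "environment.csv",
    "counts.csv",
    "truth.json",
)


def write_dataset(ds: SyntheticDataset, out_dir) -> list[str]:
    """Write the six dataset files; returns the manifest (relative names)."""
    if ds.genotypes.calls.shape[0] == 0 or len(ds.traits.data) == 0:
        raise ValueError("refusing to write an empty dataset")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    popgen.write_genepop(ds.genotypes, out / "genotypes.gen")
    shape.write_tps(ds.landmarks, out / "landmarks.tps")
    ds.traits.to_csv(out / "traits.csv")
    ds.environment.data.to_csv(out / "environment.csv", index=False)
    ds.counts.to_csv(out / "counts.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(ds.truth, fh, indent=1)
    return list(MANIFEST_FILES)


def read_dataset(in_dir) -> SyntheticDataset:
    """Round-trip reader for a written dataset (config is not reconstructed)."""
    d = Path(in_dir)
    genotypes = popgen.read_genepop(d / "genotypes.gen")
    traits = TraitTable.from_csv(d / "traits.csv")
    landmarks = shape.read_tps(d / "landmarks.tps").with_metadata(traits.data)
    environment = EnvTable.from_csv(d / "environment.csv")
    counts = pd.read_csv(d / "counts.csv", keep_default_na=False)
    with open(d / "truth.json") as fh:
        truth = json.load(fh)
    return SyntheticDataset(
        config=None, genotypes=genotypes, traits=traits, landmarks=landmarks,
        environment=environment, counts=counts, truth=truth,
    )
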