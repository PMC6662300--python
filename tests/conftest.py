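import numpy as np
import pandas as pd
import pytest

from pstfst import SimConfig, simulate_metapopulation
from pstfst.popgen import GenotypeTable
from pstfst.shape import LandmarkSet
from pstfst.traits import TraitTable


@pytest.fixture(scope="session")
def small_config():
    """Reduced pond system: quick to simulate, still structured."""
    return SimConfig(n_ponds=6, n_per_pond=(12, 20), n_generations=60, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_metapopulation(small_config)


@pytest.fixture(scope="session")
def study_dataset():
    """Full 19-pond study-design dataset (one replicate)."""
    return simulate_metapopulation(SimConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_genotypes(rng, n_ponds=2, n_per_pond=10, n_loci=3, n_alleles=3):
    """Small random genotype table for estimator tests."""
    individuals, ponds, calls = [], [], []
    for p in range(n_ponds):
        pond = f"P{p + 1}"
        for i in range(n_per_pond):
            individuals.append(f"{pond}_{i + 1:03d}")
            ponds.append(pond)
            calls.append(
                rng.integers(1, n_alleles + 1, size=(n_loci, 2))
            )
    return GenotypeTable(
        individuals=individuals,
        ponds=np.array(ponds),
        loci=[f"L{l}" for l in range(n_loci)],
        calls=np.array(calls),
    )


@pytest.fixture()
def toy_traits():
    """Hand-sized trait table: 3 ponds x 8 fish, both sexes."""
    rng = np.random.default_rng(9)
    rows = []
    for p, shift in zip("ABC", (0.0, 0.5, 1.0)):
        for i in range(8):
            sex = "M" if i % 2 == 0 else "F"
            L = 45 + 10 * rng.random()
            rows.append(
                {
                    "id": f"{p}{i}",
                    "pond": p,
                    "sex": sex,
                    "body_length_mm": L,
                    "x": shift + rng.normal(0, 1),
                    "y": rng.normal(0, 1),
                }
            )
    return TraitTable(pd.DataFrame(rows), groups={"xy": ["x", "y"]})


def rigid_transform(coords, rng, allow_reflection=False):
    """Random rotation + translation + positive scaling of one configuration."""
    theta = rng.uniform(0, 2 * np.pi)
    R = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    s = rng.uniform(0.2, 5.0)
    t = rng.normal(0, 10, size=2)
    return coords @ R.T * s + t
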