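"""Neutral genetic divergence from codominant multilocus genotypes.

Implements the Weir & Cockerham (1984) method-of-moments FST estimator
(theta) for microsatellite data, combined across loci and alleles as a
ratio of sums, plus GenePop I/O.  Pairwise theta between ponds is the
neutral yardstick against which phenotypic divergence (PST) is judged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import PairwiseMatrix, pond_means

__all__ = [
    "GenotypeTable",
    "allele_frequencies",
    "pairwise_fst_wc",
    "fst_matrix",
    "pond_means",
    "read_genepop",
    "write_genepop",
]

MISSING = 0  # GenePop convention: allele code 0 / "000" marks a missing call


@dataclass
class GenotypeTable:
    """Diploid microsatellite calls for individuals grouped into ponds.

    calls[i, l] is the unordered allele pair (2 positive integer codes)
    of individual i at locus l; 0 marks a missing allele.
    """

    individuals: list[str]
    ponds: np.ndarray  # pond label per individual
    loci: list[str]
    calls: np.ndarray  # (n_individuals, n_loci, 2) integer allele codes

    def __post_init__(self) -> None:
        self.ponds = np.asarray(self.ponds)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(f"calls shape {self.calls.shape} != ({n}, {L}, 2)")
        if len(self.ponds) != n:
            raise ValueError("one pond label required per individual")
        if (self.calls < 0).any():
            raise ValueError("allele codes must be non-negative (0 = missing)")

    @property
    def pond_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.ponds:
            seen.setdefault(str(p), None)
        return list(seen)

    def subset_pond(self, pond) -> np.ndarray:
        mask = self.ponds.astype(str) == str(pond)
        if not mask.any():
            raise KeyError(f"pond {pond!r} not present")
        return self.calls[mask]


def allele_frequencies(g: GenotypeTable, locus, pond) -> tuple[dict[int, float], int]:
    """Observed allele frequencies and diploid sample size for one locus x pond.

    Missing calls are dropped per gene copy (complete-gene-copy counting);
    the returned n is the number of individuals with at least one scored
    allele... strictly, the diploid count n = (#non-missing copies) / 2.
    """
    li = g.loci.index(locus) if isinstance(locus, str) else int(locus)
    calls = g.subset_pond(pond)[:, li, :].ravel()
    calls = calls[calls != MISSING]
    if calls.size == 0:
        raise ValueError(f"all calls missing at locus {g.loci[li]!r} in pond {pond!r}")
    alleles, counts = np.unique(calls, return_counts=True)
    total = counts.sum()
    freqs = {int(a): float(c) / total for a, c in zip(alleles, counts)}
    return freqs, int(total // 2)


def _wc_components(calls_a: np.ndarray, calls_b: np.ndarray) -> tuple[float, float, float]:
    """Weir-Cockerham a, b, c variance components for one locus, two ponds.

    Sums over alleles.  Returns (a, b, c); the locus contributes
    a / (a + b + c) information to the multilocus ratio-of-sums.
    Complete-case per locus: individuals with any missing allele at this
    locus are excluded.
    """
    r = 2
    pops = []
    for calls in (calls_a, calls_b):
        ok = (calls != MISSING).all(axis=1)
        pops.append(calls[ok])
    n_i = np.array([len(p) for p in pops], dtype=float)
    if (n_i < 2).any():
        raise ValueError("each pond needs >=2 complete genotypes at every used locus")

    alleles = np.unique(np.concatenate([p.ravel() for p in pops]))
    if alleles.size < 2:
        return 0.0, 0.0, 0.0  # monomorphic across the pair: uninformative

    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)

    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p_i = np.array([(p == al).sum() / (2 * len(p)) for p in pops])
        h_i = np.array([((p == al).sum(axis=1) == 1).mean() for p in pops])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def pairwise_fst_wc(g: GenotypeTable, pond_a, pond_b) -> float:
    """Multilocus Weir-Cockerham theta between two ponds.

    Combined across loci as ratio of sums: sum(a) / sum(a+b+c).  Loci
    monomorphic across the pair contribute nothing.  The estimate may be
    slightly negative by construction and is reported as computed.
    """
    calls_a = g.subset_pond(pond_a)
    calls_b = g.subset_pond(pond_b)
    if len(calls_a) < 2 or len(calls_b) < 2:
        raise ValueError("both ponds need >=2 genotyped individuals")
    num = den = 0.0
    for li in range(len(g.loci)):
        a, b, c = _wc_components(calls_a[:, li, :], calls_b[:, li, :])
        num += a
        den += a + b + c
    if den == 0.0:
        raise ValueError("no informative loci")
    return float(num / den)


def fst_matrix(g: GenotypeTable) -> PairwiseMatrix:
    """Pairwise theta over all unordered pond pairs."""
    labels = g.pond_labels
    if len(labels) < 2:
        raise ValueError("need >=2 ponds")
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pairwise_fst_wc(g, labels[i], labels[j])
    return PairwiseMatrix(labels=labels, values=vals, kind="FST")


# ---------------------------------------------------------------------------
# GenePop I/O

def _parse_genepop_geno(tok: str, digits: int) -> tuple[int, int]:
    tok = tok.strip()
    if len(tok) != 2 * digits:
        raise ValueError(f"genotype token {tok!r} is not {2 * digits} digits")
    return int(tok[:digits]), int(tok[digits:])


def read_genepop(path) -> GenotypeTable:
    """Read a GenePop file (2- or 3-digit dialect, POP-delimited).

    Pond labels are taken from the identifier of the first individual in
    each POP block (the customary GenePop convention).
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError("empty GenePop file")
    # line 0: title; locus names until the first POP (one per line or comma-sep)
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if not loci:
        raise ValueError("no locus names before first POP")

    individuals: list[str] = []
    ponds: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    digits = None
    pop_label = None
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.upper() == "POP":
            pop_label = None
            continue
        if "," not in line:
            raise ValueError(f"malformed GenePop individual line: {line!r}")
        ind_id, geno_part = line.split(",", 1)
        ind_id = ind_id.strip()
        toks = geno_part.split()
        if len(toks) != len(loci):
            raise ValueError(
                f"individual {ind_id!r} has {len(toks)} genotypes, expected {len(loci)}"
            )
        if digits is None:
            digits = len(toks[0]) // 2
            if digits not in (2, 3):
                raise ValueError("only 2- and 3-digit GenePop dialects supported")
        if pop_label is None:
            # Customary GenePop convention: the first individual's id names
            # the population.  Ids of the form "<pond>_<n>" keep only <pond>.
            pop_label = ind_id.split("_")[0]
        individuals.append(ind_id)
        ponds.append(pop_label)
        rows.append([_parse_genepop_geno(t, digits) for t in toks])
    if not rows:
        raise ValueError("GenePop file contains no individuals")
    calls = np.array(rows, dtype=np.int64)
    return GenotypeTable(
        individuals=individuals, ponds=np.array(ponds), loci=loci, calls=calls
    )


def write_genepop(g: GenotypeTable, path, title: str = "pstfst export") -> None:
    """Write 3-digit GenePop; pond label doubles as the first-individual id prefix."""
    if (g.calls > 999).any():
        raise ValueError("allele codes exceed the 3-digit GenePop dialect")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for loc in g.loci:
            fh.write(loc + "\n")
        current = None
        for idx, ind in enumerate(g.individuals):
            pond = str(g.ponds[idx])
            if pond != current:
                fh.write("POP\n")
                current = pond
            genos = " ".join(
                f"{a:03d}{b:03d}" for a, b in g.calls[idx]
            )
            fh.write(f"{ind} , {genos}\n")
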