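"""Hybrid genotypic classes and gamete-sampling simulation.

Hybrid cohorts are built by multinomial gamete sampling: each offspring
draws, at every locus independently, one allele from each of two gamete
pools.  A pool is either a reference population's observed allele
frequencies or the empirical frequencies of a previously simulated cohort,
which yields the crossing tree F1 = P1 x P2, F2 = F1 x F1,
first-generation backcross = P1 x F1, second-generation backcross =
P1 x (first backcross), with the mirrored classes toward the second
parental pool.

Each class carries its gene-origin vector (z11, z12, z22): the probability
that a random genotype carries both copies from species 1, one copy from
each, or both from species 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genotypes import (
    GenotypeError,
    GenotypeTable,
    Locus,
    allele_freqs,
    concat_tables,
)


@dataclass(frozen=True)
class HybridClass:
    """A genotypic class with its expected gene-origin probabilities."""

    label: str
    z: tuple[float, float, float]  # (z11, z12, z22)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.z) or abs(sum(self.z) - 1.0) > 1e-12:
            raise ValueError("z must be a probability vector")

    @property
    def pool1_share(self) -> float:
        """Expected fraction of gene copies from species-1 (alpha)."""
        return self.z[0] + self.z[1] / 2.0


HYBRID_CLASSES: dict[str, HybridClass] = {
    "P1": HybridClass("P1", (1.0, 0.0, 0.0)),
    "P2": HybridClass("P2", (0.0, 0.0, 1.0)),
    "F1": HybridClass("F1", (0.0, 1.0, 0.0)),
    "F2": HybridClass("F2", (0.25, 0.5, 0.25)),
    "P1_bx": HybridClass("P1_bx", (0.5, 0.5, 0.0)),
    "P1_bx1": HybridClass("P1_bx1", (0.75, 0.25, 0.0)),
    "P2_bx": HybridClass("P2_bx", (0.0, 0.5, 0.5)),
    "P2_bx1": HybridClass("P2_bx1", (0.0, 0.25, 0.75)),
}

PARENTAL_LABELS = ("P1", "P2")
HYBRID_LABELS = tuple(l for l in HYBRID_CLASSES if l not in PARENTAL_LABELS)


class GenePool:
    """Per-locus gamete (allele) frequencies over a shared locus panel."""

    def __init__(self, loci: Sequence[Locus], freqs: Sequence[np.ndarray]) -> None:
        if len(loci) != len(freqs):
            raise GenotypeError("loci / frequency length mismatch")
        self.loci = list(loci)
        self.freqs = []
        for locus, f in zip(loci, freqs):
            f = np.asarray(f, float)
            if f.shape != (locus.n_alleles,) or np.any(~np.isfinite(f)):
                raise GenotypeError(f"bad frequency vector at {locus.name}")
            if abs(f.sum() - 1.0) > 1e-9:
                raise GenotypeError(f"frequencies at {locus.name} do not sum to 1")
            self.freqs.append(f / f.sum())

    @classmethod
    def from_table(cls, table: GenotypeTable, pop: str | None = None) -> "GenePool":
        if pop is not None:
            table = table.restrict_pops([pop])
        af = allele_freqs(table)
        only = af.populations[0] if pop is None else pop
        if len(af.populations) != 1:
            raise GenotypeError("pool source must be a single population")
        return cls(table.loci, af.pool(only))

    def same_panel(self, other: "GenePool") -> bool:
        return [(l.name, l.alleles) for l in self.loci] == [
            (l.name, l.alleles) for l in other.loci
        ]


def hybridise(
    pool_a: GenePool,
    pool_b: GenePool,
    n: int,
    seed: int | None = None,
    pop_label: str = "HYB",
    id_prefix: str = "hyb",
) -> GenotypeTable:
    """Simulate *n* offspring drawing one gamete per locus from each pool.

    Gametes are multinomial over each pool's allele frequencies and loci
    are independent (free recombination, matching unlinked microsatellites).
    """
    if not pool_a.same_panel(pool_b):
        raise GenotypeError("locus panels differ between pools")
    rng = np.random.default_rng(seed)
    L = len(pool_a.loci)
    calls = np.zeros((n, L, 2), dtype=np.int32)
    for j in range(L):
        calls[:, j, 0] = rng.choice(len(pool_a.freqs[j]), size=n, p=pool_a.freqs[j])
        calls[:, j, 1] = rng.choice(len(pool_b.freqs[j]), size=n, p=pool_b.freqs[j])
    ids = [f"{id_prefix}_{i}" for i in range(n)]
    return GenotypeTable(ids, [pop_label] * n, pool_a.loci, calls)


def simulate_class(
    label: str,
    pool1: GenePool,
    pool2: GenePool,
    n: int,
    seed: int | None = None,
) -> GenotypeTable:
    """Simulate a cohort of one genotypic class via the crossing tree.

    Intermediate cohorts (F1 for F2 and backcrosses, first backcross for
    the second) are simulated at the same size *n* and their empirical
    allele frequencies serve as the next stage's gamete pool.
    """
    if label not in HYBRID_CLASSES:
        raise ValueError(f"unknown class {label!r}")
    rng = np.random.default_rng(seed)

    def sub() -> int:
        return int(rng.integers(0, 2**31 - 1))

    def pool_of(cohort: GenotypeTable) -> GenePool:
        return GenePool.from_table(cohort)

    def cross(pa: GenePool, pb: GenePool) -> GenotypeTable:
        return hybridise(pa, pb, n, seed=sub(), pop_label=label,
                         id_prefix=label.lower())

    if label == "P1":
        return cross(pool1, pool1)
    if label == "P2":
        return cross(pool2, pool2)
    if label == "F1":
        return cross(pool1, pool2)
    f1 = hybridise(pool1, pool2, n, seed=sub(), pop_label="F1", id_prefix="f1")
    if label == "F2":
        return cross(pool_of(f1), pool_of(f1))
    if label == "P1_bx":
        return cross(pool1, pool_of(f1))
    if label == "P2_bx":
        return cross(pool2, pool_of(f1))
    if label == "P1_bx1":
        bx = hybridise(pool1, pool_of(f1), n, seed=sub(), pop_label="P1_bx",
                       id_prefix="bx")
        return cross(pool1, pool_of(bx))
    # P2_bx1
    bx = hybridise(pool2, pool_of(f1), n, seed=sub(), pop_label="P2_bx",
                   id_prefix="bx")
    return cross(pool2, pool_of(bx))


DEFAULT_S1_ROSTER: dict[str, int] = {
    "P1": 100,
    "F1": 100,
    "F2": 100,
    "P1_bx": 100,
    "P1_bx1": 100,
}


@dataclass
class MixtureScenario:
    """A simulated mixture assembled with untouched reference populations."""

    table: GenotypeTable  # references + mixture (mixture pop label 'MIX')
    mixture_pop: str
    truth: list[str]  # ground-truth class per mixture individual (in order)
    pool_truth: list[str]  # truth for the full simulated pool
    pool: GenotypeTable

    @property
    def mixture_ids(self) -> list[str]:
        mask = [p == self.mixture_pop for p in self.table.pops]
        return [i for i, m in zip(self.table.ids, mask) if m]


def sample_mixture(
    pool: GenotypeTable,
    labels: Sequence[str],
    n: int,
    seed: int | None = None,
) -> tuple[GenotypeTable, list[str]]:
    """Uniform sample without replacement from a labelled simulated pool."""
    if len(labels) != pool.n_individuals:
        raise GenotypeError("labels length mismatch")
    if n > pool.n_individuals:
        raise GenotypeError("mixture size exceeds simulated pool")
    rng = np.random.default_rng(seed)
    idx = rng.choice(pool.n_individuals, size=n, replace=False)
    return pool.subset(individuals=idx), [labels[i] for i in idx]


def build_s1(
    references: GenotypeTable,
    ref1: str,
    ref2: str,
    roster: Mapping[str, int] | None = None,
    mixture: int = 50,
    seed: int | None = None,
    mixture_pop: str = "MIX",
) -> MixtureScenario:
    """Hatchery-hybridisation scenario: simulate a class roster from two
    reference populations, sample a mixed cohort, and assemble it with the
    untouched references for analysis."""
    roster = dict(roster or DEFAULT_S1_ROSTER)
    if any(c <= 0 for c in roster.values()):
        raise GenotypeError("roster counts must be positive")
    total = sum(roster.values())
    if mixture > total:
        raise GenotypeError("mixture size exceeds simulated pool")
    rng = np.random.default_rng(seed)
    pool1 = GenePool.from_table(references, ref1)
    pool2 = GenePool.from_table(references, ref2)
    cohorts = []
    pool_truth: list[str] = []
    for label, count in roster.items():
        cohort = simulate_class(label, pool1, pool2, count,
                                seed=int(rng.integers(0, 2**31 - 1)))
        cohorts.append(cohort)
        pool_truth.extend([label] * count)
    pool = concat_tables(cohorts)
    mix, truth = sample_mixture(pool, pool_truth, mixture,
                                seed=int(rng.integers(0, 2**31 - 1)))
    mix = GenotypeTable(
        [f"mix_{i}" for i in range(mix.n_individuals)],
        [mixture_pop] * mix.n_individuals,
        mix.loci,
        mix.calls,
    )
    refs = references.restrict_pops([ref1, ref2])
    table = concat_tables([refs, mix])
    return MixtureScenario(table, mixture_pop, truth, pool_truth, pool)
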