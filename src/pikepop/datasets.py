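"""Synthetic study generator.

Emulates the sampling design the pipeline targets: four pike populations —
three southern-pike samples (FLU N=58, TRA N=20, CAR N=28) and one
northern-pike sample (DRA N=22) — genotyped at a 16-locus microsatellite
panel of which 11 loci are analysable (one locus monomorphic, four with
>12% missing data in at least one population), within-population expected
heterozygosity in the 0.38-0.58 band, and between-species divergence with
theta in the 0.32-0.48 band.

Population allele frequencies follow a hierarchical F-model: species pools
diverge from a common ancestral frequency vector as
Dirichlet(theta_species * ancestral) and populations within a species
diverge from their species pool as Dirichlet(theta_pop * species pool);
under the island-model identity F = 1/(1 + theta) the defaults put
between-species divergence near 0.4 and within-species divergence near
0.2.  Genotypes are drawn with a per-population inbreeding coefficient
(negative values give the heterozygote excess typical of small supportive-
bred samples), and allelic dropout is overlaid on a few loci with the same
observation model the dropout estimator assumes: high-dropout loci are the
ones that also fail the missing-data filter, except one moderate (0.15)
locus retained in the analysable panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeTable, Locus

DEFAULT_SIZES = {"FLU": 58, "TRA": 20, "CAR": 28, "DRA": 22}
SOUTHERN = ("FLU", "TRA", "CAR")
NORTHERN = ("DRA",)

# F-model concentrations, chosen so the realised divergences match the
# study design (between-species theta ~0.43, within-species ~0.19,
# global ~0.31, mean H_E ~0.49)
THETA_SPECIES = 2.5
THETA_POP = 4.0

# per-population inbreeding coefficients of the generated genotypes
DEFAULT_FIS = {"FLU": -0.04, "TRA": -0.22, "CAR": -0.04, "DRA": 0.04}


@dataclass
class SyntheticStudy:
    """A generated study: raw 16-locus panel and the 11-locus clean panel."""

    raw: GenotypeTable
    clean: GenotypeTable
    pop_freqs: dict  # population -> list of per-locus frequency vectors
    dropout_rates: dict  # locus name -> simulated dropout rate
    seed: int


def _genotype_probs(p: np.ndarray, fis: float) -> np.ndarray:
    """Unordered genotype probability matrix with inbreeding coefficient.

    P(aa) = p_a^2 + F p_a (1 - p_a); P(ab) = 2 p_a p_b (1 - F); negative F
    beyond feasibility is clamped by zero-truncation and renormalisation.
    """
    k = len(p)
    g = 2.0 * np.outer(p, p) * (1.0 - fis)
    np.fill_diagonal(g, p**2 + fis * p * (1.0 - p))
    g = np.triu(g)
    g = np.maximum(g, 0.0)
    return g / g.sum()


def _sample_genotypes(
    rng: np.random.Generator, freqs: np.ndarray, n: int, fis: float
) -> np.ndarray:
    k = len(freqs)
    g = _genotype_probs(freqs, fis)
    flat = g.ravel()
    draw = rng.choice(k * k, size=n, p=flat)
    pairs = np.stack([draw // k, draw % k], axis=1)
    return np.sort(pairs, axis=1)


def synthetic_study(
    seed: int = 0,
    sizes: dict[str, int] | None = None,
    fis: dict[str, float] | None = None,
    n_loci_raw: int = 16,
    n_monomorphic: int = 1,
    n_high_missing: int = 4,
    high_missing_rate: float = 0.2,
    base_missing_rate: float = 0.01,
    retained_dropout: float = 0.15,
    removed_dropout: tuple[float, ...] = (0.25, 0.3, 0.39),
    theta_species: float = THETA_SPECIES,
    theta_pop: float = THETA_POP,
) -> SyntheticStudy:
    """Generate the default study conditions (see module docstring)."""
    sizes = dict(sizes or DEFAULT_SIZES)
    fis = dict(fis or DEFAULT_FIS)
    rng = np.random.default_rng(seed)
    n_clean = n_loci_raw - n_monomorphic - n_high_missing

    # hierarchical F-model frequencies
    pools1, pools2, ks = [], [], []
    for _ in range(n_loci_raw):
        k = int(rng.integers(5, 17))
        ancestral = rng.dirichlet(np.full(k, 2.0))
        pools1.append(rng.dirichlet(np.maximum(theta_species * ancestral, 1e-6)))
        pools2.append(rng.dirichlet(np.maximum(theta_species * ancestral, 1e-6)))
        ks.append(k)
    pop_freqs: dict[str, list[np.ndarray]] = {}
    for pop in sizes:
        pool = pools1 if pop in SOUTHERN else pools2
        pop_freqs[pop] = [
            rng.dirichlet(np.maximum(theta_pop * pool[j], 1e-6))
            for j in range(n_loci_raw)
        ]

    # panel layout: clean loci first, then the monomorphic locus, then the
    # high-missing (removed) loci; dropout rates follow the study pattern
    mono_idx = set(range(n_clean, n_clean + n_monomorphic))
    highmiss_idx = sorted(range(n_clean + n_monomorphic, n_loci_raw))
    rates = {j: float(rng.uniform(0.0, 0.05)) for j in range(n_loci_raw)}
    if n_clean:
        rates[int(rng.integers(0, n_clean))] = retained_dropout
    for j, d in zip(highmiss_idx, removed_dropout):
        rates[j] = float(d)

    names = [f"Msat{j + 1:02d}" for j in range(n_loci_raw)]
    ids: list[str] = []
    pops: list[str] = []
    raw_calls = []
    for pop, n in sizes.items():
        block = np.zeros((n, n_loci_raw, 2), dtype=np.int32)
        for j in range(n_loci_raw):
            if j in mono_idx:
                continue
            block[:, j, :] = _sample_genotypes(
                rng, pop_freqs[pop][j], n, fis.get(pop, 0.0)
            )
            d = rates[j]
            if d > 0:  # dropout overlay: copies drop independently
                drop = rng.random((n, 2)) < d
                both = drop.all(axis=1)
                one = drop.any(axis=1) & ~both
                if one.any():
                    keep = np.where(drop[one, 0], block[one, j, 1],
                                    block[one, j, 0])
                    block[one, j, 0] = keep
                    block[one, j, 1] = keep
                block[both, j, :] = MISSING
            miss = rng.random(n) < base_missing_rate
            block[miss, j, :] = MISSING
        ids.extend(f"{pop}_{i + 1}" for i in range(n))
        pops.extend([pop] * n)
        raw_calls.append(block)
    raw_calls = np.concatenate(raw_calls)

    # implant >12% missing in one population for the designated loci
    pop_slices = {}
    start = 0
    for pop, n in sizes.items():
        pop_slices[pop] = slice(start, start + n)
        start += n
    pop_cycle = list(sizes)
    for i, j in enumerate(highmiss_idx):
        pop = pop_cycle[i % len(pop_cycle)]
        sl = pop_slices[pop]
        n = sl.stop - sl.start
        n_miss = max(int(np.ceil(high_missing_rate * n)), int(0.13 * n) + 1)
        rows = sl.start + rng.choice(n, size=n_miss, replace=False)
        raw_calls[rows, j, :] = MISSING

    # allele labels: fragment sizes on a 2-bp grid starting near 100
    loci = []
    for j in range(n_loci_raw):
        k = 1 if j in mono_idx else ks[j]
        labels = tuple(100 + 2 * a for a in range(k))
        loci.append(Locus(names[j], labels))
    raw = GenotypeTable(ids, pops, loci, raw_calls)
    clean = raw.subset(loci=list(range(n_clean)))
    named_rates = {names[j]: r for j, r in rates.items()}
    return SyntheticStudy(raw, clean, pop_freqs, named_rates, seed)
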