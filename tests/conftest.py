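"""Shared fixtures and independent brute-force oracles.

The oracle functions here are deliberately written as plain-Python direct
transcriptions of the defining formulas (loops, math.comb, explicit sums)
so they stay independent of the vectorised library implementations they
check.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from pikepop.genotypes import MISSING, GenotypeTable, Locus


# ----------------------------------------------------------------------
# table builders
# ----------------------------------------------------------------------


def make_table(pop_genos: dict[str, list[list[tuple[int, int] | None]]],
               n_alleles: int | list[int] = 4) -> GenotypeTable:
    """Build a table from {pop: [per-individual list of per-locus pairs]}.

    Pairs are allele indices; None is a missing call.
    """
    pops_order = list(pop_genos)
    n_loci = len(next(iter(pop_genos.values()))[0])
    if isinstance(n_alleles, int):
        n_alleles = [n_alleles] * n_loci
    loci = [Locus(f"L{j + 1}", tuple(100 + 2 * a for a in range(n_alleles[j])))
            for j in range(n_loci)]
    ids, pops, rows = [], [], []
    for pop in pops_order:
        for i, genos in enumerate(pop_genos[pop]):
            ids.append(f"{pop}_{i}")
            pops.append(pop)
            row = np.full((n_loci, 2), MISSING, dtype=np.int32)
            for j, g in enumerate(genos):
                if g is not None:
                    row[j] = g
            rows.append(row)
    return GenotypeTable(ids, pops, loci, np.stack(rows))


def random_table(rng: np.random.Generator, n_pops=2, n_ind=(3, 8),
                 n_loci=(2, 4), n_alleles=(2, 4), p_missing=0.1) -> GenotypeTable:
    L = int(rng.integers(n_loci[0], n_loci[1] + 1))
    ks = [int(rng.integers(n_alleles[0], n_alleles[1] + 1)) for _ in range(L)]
    pop_genos = {}
    for p in range(n_pops):
        n = int(rng.integers(n_ind[0], n_ind[1] + 1))
        inds = []
        for _ in range(n):
            genos = []
            for j in range(L):
                if rng.random() < p_missing:
                    genos.append(None)
                else:
                    a, b = sorted(rng.integers(0, ks[j], size=2).tolist())
                    genos.append((a, b))
            inds.append(genos)
        pop_genos[f"P{p + 1}"] = inds
    return make_table(pop_genos, n_alleles=ks)


@pytest.fixture(scope="session")
def study():
    from pikepop.datasets import synthetic_study

    return synthetic_study(seed=2)


@pytest.fixture(scope="session")
def fixed_diff_panel():
    """Two reference pops of 20 fixed for alternative alleles at 10 loci."""
    from pikepop.genotypes import concat_tables
    from pikepop.hybrids import GenePool, hybridise

    loci = [Locus(f"L{j}", (100, 102)) for j in range(10)]
    pool1 = GenePool(loci, [np.array([1.0, 0.0])] * 10)
    pool2 = GenePool(loci, [np.array([0.0, 1.0])] * 10)
    r1 = hybridise(pool1, pool1, 20, seed=31, pop_label="R1", id_prefix="r1")
    r2 = hybridise(pool2, pool2, 20, seed=32, pop_label="R2", id_prefix="r2")
    return concat_tables([r1, r2]), pool1, pool2


# ----------------------------------------------------------------------
# oracles
# ----------------------------------------------------------------------


def levene_exact_p(genos: list[tuple[int, int]], direction: str) -> float:
    """One-sided HW exact p by complete enumeration of genotype tables with
    the observed allele counts (Levene conditional distribution), ordered by
    heterozygote count."""
    copies = [a for g in genos for a in g]
    n = len(genos)
    m = Counter(copies)

    def tables(counts):
        counts = {k: v for k, v in counts.items() if v}
        if not counts:
            yield ()
            return
        ks = sorted(counts)
        a = ks[0]
        for b in ks:
            if a == b and counts[a] < 2:
                continue
            c2 = dict(counts)
            c2[a] -= 1
            c2[b] -= 1
            for rest in tables(c2):
                yield tuple(sorted(((a, b),) + rest))

    seen = {}
    for t in set(tables(dict(m))):
        cnt = Counter(t)
        het = sum(v for k, v in cnt.items() if k[0] != k[1])
        logp = (
            math.lgamma(n + 1)
            - sum(math.lgamma(v + 1) for v in cnt.values())
            + het * math.log(2)
            + sum(math.lgamma(v + 1) for v in m.values())
            - math.lgamma(2 * n + 1)
        )
        seen[t] = (math.exp(logp), het)
    total = sum(p for p, _ in seen.values())
    obs_het = sum(1 for g in genos if g[0] != g[1])
    if direction == "deficit":
        keep = sum(p for p, h in seen.values() if h <= obs_het)
    else:
        keep = sum(p for p, h in seen.values() if h >= obs_het)
    return keep / total


def he_oracle(counts: list[int]) -> float:
    g = sum(counts)
    s = sum((c / g) ** 2 for c in counts)
    return g / (g - 1) * (1 - s)


def ar_oracle(counts: list[int], g: int) -> float:
    total = sum(counts)
    return sum(
        1 - math.comb(total - c, g) / math.comb(total, g)
        for c in counts if c > 0
    )


def _pop_locus_data(table: GenotypeTable, pop: str, j: int):
    pairs = []
    for i in range(table.n_individuals):
        if table.pops[i] != pop:
            continue
        a, b = table.calls[i, j]
        if a != MISSING:
            pairs.append((int(a), int(b)))
    return pairs


def wc_theta_oracle(table: GenotypeTable, pops: list[str]) -> float:
    """Weir-Cockerham theta: plain-loop transcription of the a, b, c
    variance components, summed over loci and alleles before the ratio."""
    r = len(pops)
    A = B = C = 0.0
    for j, locus in enumerate(table.loci):
        data = {pop: _pop_locus_data(table, pop, j) for pop in pops}
        n_i = [len(data[pop]) for pop in pops]
        if any(n < 1 for n in n_i):
            continue
        nbar = sum(n_i) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(n**2 for n in n_i) / (r * nbar)) / (r - 1)
        for a in range(locus.n_alleles):
            p_i, h_i = [], []
            for pop in pops:
                pairs = data[pop]
                n = len(pairs)
                cnt = sum((x == a) + (y == a) for x, y in pairs)
                p_i.append(cnt / (2 * n))
                h_i.append(sum(1 for x, y in pairs if x != y and a in (x, y)) / n)
            pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
            A += (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            B += (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            C += hbar / 2
    denom = A + B + C
    return A / denom if denom != 0 else float("nan")


def jost_d_locus_oracle(table: GenotypeTable, pops: list[str], j: int) -> float:
    """Jost's D at one locus, plain-loop Nei & Chesser unbiased estimators."""
    r = len(pops)
    k = table.loci[j].n_alleles
    p, n, ho = [], [], []
    for pop in pops:
        pairs = _pop_locus_data(table, pop, j)
        n.append(len(pairs))
        if not pairs:
            return float("nan")
        freq = [sum((x == a) + (y == a) for x, y in pairs) / (2 * len(pairs))
                for a in range(k)]
        p.append(freq)
        ho.append(sum(1 for x, y in pairs if x != y) / len(pairs))
    nh = r / sum(1.0 / ni for ni in n)
    hs_plug = 1 - sum(sum(f**2 for f in p[i]) for i in range(r)) / r
    ho_bar = sum(ho) / r
    hs = (nh / (nh - 1)) * (hs_plug - ho_bar / (2 * nh))
    pbar = [sum(p[i][a] for i in range(r)) / r for a in range(k)]
    ht = 1 - sum(f**2 for f in pbar) + hs / (nh * r) - ho_bar / (2 * nh * r)
    if 1 - hs <= 0:
        return float("nan")
    return (r / (r - 1)) * (ht - hs) / (1 - hs)
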