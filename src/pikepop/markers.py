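"""Marker validation: exact tests, excess-of-significance checks, FDR,
and maximum-likelihood allelic-dropout correction.

Hardy-Weinberg departures are tested with a Markov-chain Monte Carlo exact
test conditional on the observed allele counts (a chain over random pairings
of the gene copies, whose stationary law is the Levene conditional
distribution), one-sided for heterozygote deficit or excess.  Genotypic
linkage disequilibrium is a Monte-Carlo permutation test of independence on
the two-locus genotype contingency table, assuming no phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotypes import MISSING, GenotypeError, GenotypeTable


@dataclass
class ExactTestResult:
    p: float
    se: float
    direction: str
    defined: bool = True


class UndefinedTest(Exception):
    """The test is undefined (e.g. monomorphic locus); excluded from batteries."""


def _pop_locus_copies(table: GenotypeTable, pop: str, locus: str) -> np.ndarray:
    """Flat array of gene copies (allele indices), paired (2i, 2i+1)."""
    j = table.locus_index(locus)
    mask = table.pop_mask(pop)
    pair = table.calls[mask, j, :]
    pair = pair[pair[:, 0] != MISSING]
    return pair.ravel()


def hw_exact_test(
    table: GenotypeTable,
    pop: str,
    locus: str,
    direction: str = "deficit",
    demem: int = 10_000,
    batches: int = 100,
    iters: int = 10_000,
    seed: int | None = None,
) -> ExactTestResult:
    """One-sided Hardy-Weinberg exact test via Markov-chain Monte Carlo.

    The chain performs random transpositions of gene copies between
    individuals; every reachable pairing is equally likely at stationarity,
    which is exactly the conditional (Levene) distribution of genotype tables
    given the allele counts.  The ordering statistic is the heterozygote
    count; ``direction='deficit'`` accumulates P(het <= observed),
    ``'excess'`` P(het >= observed).  The standard error comes from batch
    means.

    Raises :class:`UndefinedTest` for monomorphic or near-empty samples.
    """
    if direction not in ("deficit", "excess"):
        raise ValueError("direction must be 'deficit' or 'excess'")
    copies = _pop_locus_copies(table, pop, locus)
    n = copies.size // 2
    if n < 2 or np.unique(copies).size < 2:
        raise UndefinedTest(f"HW test undefined for ({pop}, {locus})")
    rng = np.random.default_rng(seed)
    state = copies.copy()
    obs_het = int(np.sum(state[0::2] != state[1::2]))
    het = obs_het

    def sweep(k: int) -> float:
        """Run k transposition steps; return fraction of extreme states."""
        nonlocal het
        hits = 0
        u = rng.integers(0, state.size, size=k)
        v = rng.integers(0, state.size, size=k)
        for t in range(k):
            a, b = u[t], v[t]
            if state[a] != state[b]:
                ia, ib = a // 2, b // 2
                # heterozygosity delta of affected individuals
                before = int(state[2 * ia] != state[2 * ia + 1]) + int(
                    state[2 * ib] != state[2 * ib + 1]
                )
                state[a], state[b] = state[b], state[a]
                after = int(state[2 * ia] != state[2 * ia + 1]) + int(
                    state[2 * ib] != state[2 * ib + 1]
                )
                het += after - before
            if direction == "deficit":
                hits += het <= obs_het
            else:
                hits += het >= obs_het
        return hits / k

    sweep(demem)
    batch_p = np.array([sweep(iters) for _ in range(batches)])
    return ExactTestResult(
        p=float(batch_p.mean()),
        se=float(batch_p.std(ddof=1) / math.sqrt(batches)),
        direction=direction,
    )


def ld_exact_test(
    table: GenotypeTable,
    pop: str,
    locus_a: str,
    locus_b: str,
    reps: int = 10_000,
    seed: int | None = None,
) -> ExactTestResult:
    """Monte-Carlo exact test of genotypic linkage disequilibrium.

    Tests independence of the two-locus genotype contingency table by
    permuting one locus' genotypes across individuals; the statistic is the
    log-likelihood-ratio G.  No gametic phase is assumed.
    """
    ja, jb = table.locus_index(locus_a), table.locus_index(locus_b)
    mask = table.pop_mask(pop)
    pa = table.calls[mask, ja, :]
    pb = table.calls[mask, jb, :]
    ok = (pa[:, 0] != MISSING) & (pb[:, 0] != MISSING)
    pa, pb = pa[ok], pb[ok]
    if len(pa) < 2:
        raise UndefinedTest(f"LD test undefined for ({pop}, {locus_a}-{locus_b})")
    ga = _genotype_codes(pa)
    gb = _genotype_codes(pb)
    if np.unique(ga).size < 2 or np.unique(gb).size < 2:
        raise UndefinedTest(f"LD test undefined for ({pop}, {locus_a}-{locus_b})")
    rng = np.random.default_rng(seed)
    _, ga = np.unique(ga, return_inverse=True)
    _, gb = np.unique(gb, return_inverse=True)
    na, nb = ga.max() + 1, gb.max() + 1

    def g_stat(x: np.ndarray, y: np.ndarray) -> float:
        tab = np.bincount(x * nb + y, minlength=na * nb).astype(float)
        tab = tab.reshape(na, nb)
        exp = tab.sum(1, keepdims=True) @ tab.sum(0, keepdims=True) / tab.sum()
        nz = tab > 0
        return float(2.0 * np.sum(tab[nz] * np.log(tab[nz] / exp[nz])))

    obs = g_stat(ga, gb)
    hits = 0
    for _ in range(reps):
        hits += g_stat(ga, rng.permutation(gb)) >= obs - 1e-12
    p = (hits + 1) / (reps + 1)
    return ExactTestResult(p=float(p), se=float(math.sqrt(p * (1 - p) / reps)),
                           direction="two-sided")


def _genotype_codes(pairs: np.ndarray) -> np.ndarray:
    """Integer code per unordered genotype pair."""
    m = int(pairs.max()) + 1
    return pairs[:, 0] * m + pairs[:, 1]


# -- excess-of-significance and FDR ---------------------------------------


def binomial_excess(k: int, n: int, alpha: float = 0.05) -> tuple[float, int]:
    """Cumulative-binomial check for an excess of significant tests.

    Returns ``(p_exceed, critical_count)`` where ``p_exceed = P(X >= k)``
    with X ~ Binomial(n, alpha), and ``critical_count`` is the largest k0
    such that P(X >= k0 + 1) > alpha (observing more than ``critical_count``
    significant tests is itself significant at *alpha*).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    p_exceed = float(stats.binom.sf(k - 1, n, alpha))
    critical = 0
    while stats.binom.sf(critical, n, alpha) > alpha:  # P(X >= critical+1)
        critical += 1
    critical -= 1
    return p_exceed, int(max(critical, 0))


def min_significant_count(n: int, alpha: float = 0.05) -> int:
    """Smallest k with P(X >= k) <= alpha — the complementary convention."""
    k = 0
    while stats.binom.sf(k - 1, n, alpha) > alpha:
        k += 1
    return k


def by_fdr(
    pvalues: list[float] | np.ndarray,
    groups: list | np.ndarray | None = None,
) -> np.ndarray:
    """Benjamini-Yekutieli FDR adjustment, applied within each group.

    Valid under arbitrary dependence between tests; adjusted values are
    >= the raw p-values and capped at 1.
    """
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if groups is None:
        groups = np.zeros(len(p), dtype=int)
    groups = np.asarray(groups)
    adjusted = np.empty_like(p)
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        if idx.size == 0:
            continue
        adjusted[idx] = multipletests(p[idx], method="fdr_by")[1]
    return adjusted


# -- test batteries --------------------------------------------------------


@dataclass
class TestBattery:
    """Grouped exact-test results with B-Y-adjusted p-values."""

    frame: pd.DataFrame  # columns: group, test, p, se, adjusted, significant
    alpha: float = 0.05
    n_defined: int = 0
    n_undefined: int = 0

    def significant_count(self, adjusted: bool = False) -> int:
        col = "adjusted" if adjusted else "p"
        return int((self.frame[col] < self.alpha).sum())

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def hw_battery(
    table: GenotypeTable,
    direction: str = "deficit",
    alpha: float = 0.05,
    demem: int = 1_000,
    batches: int = 20,
    iters: int = 1_000,
    seed: int | None = None,
) -> TestBattery:
    """All defined (population x locus) HW tests, grouped by population."""
    rng = np.random.default_rng(seed)
    rows = []
    undefined = 0
    for pop in table.populations:
        for locus in table.loci:
            s = int(rng.integers(0, 2**31 - 1))
            try:
                r = hw_exact_test(
                    table, pop, locus.name, direction,
                    demem=demem, batches=batches, iters=iters, seed=s,
                )
            except UndefinedTest:
                undefined += 1
                continue
            rows.append(
                {"group": pop, "test": locus.name, "p": r.p, "se": r.se, "seed": s}
            )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["adjusted"] = by_fdr(frame["p"].to_numpy(), frame["group"].to_numpy())
        frame["significant"] = frame["adjusted"] < alpha
    return TestBattery(frame, alpha, n_defined=len(frame), n_undefined=undefined)


def ld_battery(
    table: GenotypeTable,
    alpha: float = 0.05,
    reps: int = 2_000,
    seed: int | None = None,
) -> TestBattery:
    """All defined (population x locus pair) LD tests, grouped by locus pair."""
    rng = np.random.default_rng(seed)
    rows = []
    undefined = 0
    names = [l.name for l in table.loci]
    for pop in table.populations:
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                s = int(rng.integers(0, 2**31 - 1))
                try:
                    r = ld_exact_test(table, pop, names[a], names[b],
                                      reps=reps, seed=s)
                except UndefinedTest:
                    undefined += 1
                    continue
                rows.append(
                    {
                        "group": f"{names[a]}-{names[b]}",
                        "test": pop,
                        "p": r.p,
                        "se": r.se,
                        "seed": s,
                    }
                )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["adjusted"] = by_fdr(frame["p"].to_numpy(), frame["group"].to_numpy())
        frame["significant"] = frame["adjusted"] < alpha
    return TestBattery(frame, alpha, n_defined=len(frame), n_undefined=undefined)


# -- allelic dropout -------------------------------------------------------


@dataclass
class DropoutModel:
    """Per-locus allelic-dropout rates estimated by EM.

    The observation model: each of an individual's two allele copies drops
    independently with the locus rate *d*.  A heterozygote with one dropped
    copy is scored as a homozygote for the surviving allele; two dropped
    copies yield a missing call.  True genotype frequencies are free
    per-population parameters, so no Hardy-Weinberg assumption is made.
    """

    rates: dict[str, float]
    converged: dict[str, bool]
    missingness_homozygosity_r: float = float("nan")
    missingness_homozygosity_p: float = float("nan")
    genotype_freqs: dict = field(default_factory=dict, repr=False)

    @property
    def max_rate(self) -> tuple[str, float]:
        name = max(self.rates, key=self.rates.get)
        return name, self.rates[name]


def _genotype_space(k: int) -> list[tuple[int, int]]:
    return [(a, b) for a in range(k) for b in range(a, k)]


def estimate_dropout(
    table: GenotypeTable,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> DropoutModel:
    """EM estimate of per-locus dropout rates (see :class:`DropoutModel`).

    Also reports the Pearson correlation across individuals between the
    number of missing calls and the number of homozygous calls, a simple
    diagnostic of dropout acting genome-wide.
    """
    if table.n_loci < 2:
        raise GenotypeError("dropout estimation needs >= 2 loci")
    rates: dict[str, float] = {}
    conv: dict[str, bool] = {}
    gfreqs: dict[str, dict[str, np.ndarray]] = {}
    for j, locus in enumerate(table.loci):
        d, ok, pi = _dropout_em_locus(table, j, max_iter, tol)
        rates[locus.name] = d
        conv[locus.name] = ok
        gfreqs[locus.name] = pi
    miss = table.missing_mask()
    hom = (table.calls[:, :, 0] == table.calls[:, :, 1]) & ~miss
    n_miss = miss.sum(axis=1).astype(float)
    n_hom = hom.sum(axis=1).astype(float)
    if np.std(n_miss) > 0 and np.std(n_hom) > 0:
        r, pv = stats.pearsonr(n_miss, n_hom)
    else:
        r, pv = float("nan"), float("nan")
    return DropoutModel(rates, conv, float(r), float(pv), gfreqs)


def _dropout_em_locus(
    table: GenotypeTable, j: int, max_iter: int, tol: float
) -> tuple[float, bool, dict[str, np.ndarray]]:
    k = table.loci[j].n_alleles
    space = _genotype_space(k)
    gindex = {g: i for i, g in enumerate(space)}
    pops = table.populations
    # observations per population: list of (obs_type, a, b)
    obs_by_pop: dict[str, np.ndarray] = {}
    for pop in pops:
        mask = table.pop_mask(pop)
        obs_by_pop[pop] = table.calls[mask, j, :]
    # init: empirical genotype freqs with smoothing, d from missing fraction
    pi = {}
    for pop in pops:
        counts = np.ones(len(space)) * 0.5
        pair = obs_by_pop[pop]
        for a, b in pair[pair[:, 0] != MISSING]:
            counts[gindex[(min(a, b), max(a, b))]] += 1
        pi[pop] = counts / counts.sum()
    total_n = sum(len(v) for v in obs_by_pop.values())
    d = max(
        1e-4,
        math.sqrt(
            sum((v[:, 0] == MISSING).sum() for v in obs_by_pop.values())
            / max(total_n, 1)
        ),
    )
    d = min(d, 0.95)
    prev_ll = -np.inf
    ok = False
    for _ in range(max_iter):
        exp_drops = 0.0
        new_counts = {pop: np.zeros(len(space)) for pop in pops}
        ll = 0.0
        for pop in pops:
            for a, b in obs_by_pop[pop]:
                lik = np.zeros(len(space))
                drops = np.zeros(len(space))
                if a == MISSING:
                    lik[:] = d * d
                    drops[:] = 2.0
                elif a != b:
                    g = gindex[(a, b)]
                    lik[g] = (1 - d) ** 2
                    drops[g] = 0.0
                else:
                    for gi, (x, y) in enumerate(space):
                        if x == a and y == a:
                            lik[gi] = 1 - d * d
                            drops[gi] = 2 * d / (1 + d)
                        elif x == a or y == a:
                            lik[gi] = d * (1 - d)
                            drops[gi] = 1.0
                w = pi[pop] * lik
                tot = w.sum()
                if tot <= 0:
                    continue
                ll += math.log(tot)
                w /= tot
                new_counts[pop] += w
                exp_drops += float(w @ drops)
        d_new = min(max(exp_drops / (2 * total_n), 0.0), 0.95)
        for pop in pops:
            s = new_counts[pop].sum()
            if s > 0:
                pi[pop] = new_counts[pop] / s
        if abs(ll - prev_ll) < tol * (1 + abs(ll)) and abs(d_new - d) < 1e-6:
            d = d_new
            ok = True
            break
        d = d_new
        prev_ll = ll
    return float(d), ok, pi


def correct_genotypes(
    table: GenotypeTable,
    model: DropoutModel,
    seed: int | None = None,
) -> GenotypeTable:
    """Impute the most probable true genotype under the dropout model.

    Only observed homozygotes (possible dropped heterozygotes) and missing
    calls can change; a called heterozygote is never altered.  Ties are
    broken at random with *seed*.
    """
    rng = np.random.default_rng(seed)
    calls = table.calls.copy()
    for j, locus in enumerate(table.loci):
        d = model.rates[locus.name]
        pi = model.genotype_freqs.get(locus.name)
        if pi is None:
            continue
        space = _genotype_space(locus.n_alleles)
        for pop in table.populations:
            pvec = pi[pop]
            for i in np.flatnonzero(table.pop_mask(pop)):
                a, b = calls[i, j]
                if a != MISSING and a != b:
                    continue
                lik = np.zeros(len(space))
                if a == MISSING:
                    lik[:] = d * d
                else:
                    for gi, (x, y) in enumerate(space):
                        if x == a and y == a:
                            lik[gi] = 1 - d * d
                        elif x == a or y == a:
                            lik[gi] = d * (1 - d)
                post = pvec * lik
                if post.sum() <= 0:
                    continue
                best = np.flatnonzero(post == post.max())
                g = space[int(rng.choice(best))]
                calls[i, j] = g
    return GenotypeTable(table.ids, table.pops, table.loci, calls)
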