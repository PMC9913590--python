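"""Within-population diversity and between-population differentiation.

Summary statistics (N_A, allelic richness by rarefaction, unbiased expected
heterozygosity, observed heterozygosity, F_IS) and differentiation
estimators: Weir & Cockerham's variance-components theta, Jost's D with
unbiased gene-diversity estimators, and Monte-Carlo exact G tests of
genotypic differentiation with Fisher combination across loci.

Confidence intervals are percentile bootstrap over loci (the convention of
the diversity packages this mirrors); negative estimates are reported as
computed, never truncated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeError, GenotypeTable


# -- building blocks -------------------------------------------------------


def _pop_locus_counts(table: GenotypeTable, pop: str, j: int) -> np.ndarray:
    """Allele-copy counts over the locus-j registry for one population."""
    pair = table.calls[table.pop_mask(pop), j, :]
    pair = pair[pair[:, 0] != MISSING]
    return np.bincount(pair.ravel(), minlength=table.loci[j].n_alleles)


def unbiased_he(counts: np.ndarray) -> float:
    """Nei's unbiased expected heterozygosity, (2n/(2n-1)) (1 - sum p^2)."""
    g = counts.sum()
    if g < 2:
        return float("nan")
    p = counts / g
    return float(g / (g - 1) * (1.0 - np.sum(p**2)))


def observed_het(table: GenotypeTable, pop: str, j: int) -> float:
    pair = table.calls[table.pop_mask(pop), j, :]
    pair = pair[pair[:, 0] != MISSING]
    if len(pair) == 0:
        return float("nan")
    return float(np.mean(pair[:, 0] != pair[:, 1]))


def allelic_richness(counts: np.ndarray, g: int) -> float:
    """Expected number of alleles in a rarefied sample of g gene copies.

    A_R = sum_a [1 - C(G - G_a, g) / C(G, g)] over alleles with G_a copies
    out of G total.
    """
    total = int(counts.sum())
    if g > total:
        raise GenotypeError(f"rarefaction size {g} exceeds gene copies {total}")
    denom = math.comb(total, g)
    ar = 0.0
    for ga in counts:
        ga = int(ga)
        if ga == 0:
            continue
        ar += 1.0 - math.comb(total - ga, g) / denom
    return ar


# -- summary statistics ----------------------------------------------------


@dataclass
class SummaryStats:
    """Per-population diversity table (Table-1 style)."""

    frame: pd.DataFrame
    g: int  # rarefaction gene copies

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


def summary_stats(
    table: GenotypeTable,
    g: int | None = None,
    boot: int = 10_000,
    seed: int | None = None,
) -> SummaryStats:
    """N, N_A, A_R, H_E, H_O (mean +/- SD over loci) and F_IS per population.

    The rarefaction size defaults to the smallest per-(population, locus)
    gene-copy count in the dataset, making A_R comparable across unequal
    sample sizes.  F_IS is 1 - sum(H_O) / sum(H_E) over loci, with a 95%
    percentile bootstrap over loci.
    """
    rng = np.random.default_rng(seed)
    pops = table.populations
    counts = {
        (pop, j): _pop_locus_counts(table, pop, j)
        for pop in pops
        for j in range(table.n_loci)
    }
    if g is None:
        gmin = min(int(c.sum()) for c in counts.values() if c.sum() > 0)
        g = gmin
    rows = {}
    for pop in pops:
        na, ar, he, ho = [], [], [], []
        for j, locus in enumerate(table.loci):
            c = counts[(pop, j)]
            if c.sum() == 0:
                continue
            na.append(int((c > 0).sum()))
            ar.append(allelic_richness(c, g))
            he.append(unbiased_he(c))
            ho.append(observed_het(table, pop, j))
        na, ar, he, ho = map(np.asarray, (na, ar, he, ho))
        fis = 1.0 - ho.sum() / he.sum() if he.sum() > 0 else float("nan")
        # percentile bootstrap over loci
        if len(he) > 1 and boot > 0:
            idx = rng.integers(0, len(he), size=(boot, len(he)))
            denom = he[idx].sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                fb = 1.0 - ho[idx].sum(axis=1) / denom
            fb = fb[np.isfinite(fb)]
            lo, hi = np.percentile(fb, [2.5, 97.5])
        else:
            lo = hi = float("nan")
        mask = table.pop_mask(pop)
        rows[pop] = {
            "N": int(mask.sum()),
            "NA_mean": na.mean(),
            "NA_sd": na.std(ddof=1) if len(na) > 1 else 0.0,
            "AR_mean": ar.mean(),
            "AR_sd": ar.std(ddof=1) if len(ar) > 1 else 0.0,
            "HE_mean": np.nanmean(he),
            "HE_sd": np.nanstd(he, ddof=1) if len(he) > 1 else 0.0,
            "HO_mean": np.nanmean(ho),
            "HO_sd": np.nanstd(ho, ddof=1) if len(ho) > 1 else 0.0,
            "FIS": fis,
            "FIS_lo": lo,
            "FIS_hi": hi,
        }
    return SummaryStats(pd.DataFrame(rows).T, g=g)


# -- Weir & Cockerham theta ------------------------------------------------


def _wc_components_locus(
    table: GenotypeTable, pops: list[str], j: int
) -> tuple[float, float, float]:
    """Sum of the a, b, c variance components over alleles at locus j."""
    k = table.loci[j].n_alleles
    r = len(pops)
    n_i = np.zeros(r)
    p_ia = np.zeros((r, k))
    h_ia = np.zeros((r, k))  # observed freq of heterozygotes carrying allele a
    for i, pop in enumerate(pops):
        pair = table.calls[table.pop_mask(pop), j, :]
        pair = pair[pair[:, 0] != MISSING]
        n_i[i] = len(pair)
        if len(pair) == 0:
            continue
        cnt = np.bincount(pair.ravel(), minlength=k)
        p_ia[i] = cnt / (2 * len(pair))
        het = pair[pair[:, 0] != pair[:, 1]]
        for a in range(k):
            h_ia[i, a] = np.sum((het == a).any(axis=1)) / len(pair)
    if np.any(n_i < 1) or n_i.sum() == 0:
        return 0.0, 0.0, 0.0
    nbar = n_i.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    A = B = C = 0.0
    for a in range(k):
        pbar = (n_i * p_ia[:, a]).sum() / (r * nbar)
        s2 = (n_i * (p_ia[:, a] - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_ia[:, a]).sum() / (r * nbar)
        a_comp = (nbar / nc) * (
            s2
            - 1.0 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
        )
        b_comp = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c_comp = hbar / 2.0
        A += a_comp
        B += b_comp
        C += c_comp
    return A, B, C


@dataclass
class DiffResult:
    estimate: float
    ci_low: float
    ci_high: float
    per_locus: np.ndarray
    defined: bool = True


def wc_theta(
    table: GenotypeTable,
    pops: list[str] | None = None,
    boot: int = 10_000,
    seed: int | None = None,
) -> DiffResult:
    """Weir & Cockerham's theta (F_ST), components summed over loci and
    alleles before the ratio; 95% percentile bootstrap over loci."""
    pops = pops or table.populations
    if len(pops) < 2:
        raise GenotypeError("theta needs >= 2 populations")
    comps = np.array(
        [_wc_components_locus(table, pops, j) for j in range(table.n_loci)]
    )
    A, B, C = comps.sum(axis=0)
    denom = A + B + C
    if denom == 0:
        return DiffResult(float("nan"), float("nan"), float("nan"),
                          np.full(table.n_loci, np.nan), defined=False)
    theta = A / denom
    with np.errstate(divide="ignore", invalid="ignore"):
        per_locus = comps[:, 0] / comps.sum(axis=1)
    lo, hi = _bootstrap_ratio(comps[:, 0], comps.sum(axis=1), boot, seed)
    return DiffResult(float(theta), lo, hi, per_locus)


def _bootstrap_ratio(
    num: np.ndarray, den: np.ndarray, boot: int, seed: int | None
) -> tuple[float, float]:
    if boot <= 0 or len(num) < 2:
        return float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(num), size=(boot, len(num)))
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = num[idx].sum(axis=1) / den[idx].sum(axis=1)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return float("nan"), float("nan")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


# -- Jost's D --------------------------------------------------------------


def _jost_d_locus(table: GenotypeTable, pops: list[str], j: int) -> float:
    """Jost's D at one locus with Nei & Chesser unbiased estimators."""
    r = len(pops)
    k = table.loci[j].n_alleles
    p = np.zeros((r, k))
    n = np.zeros(r)
    ho = np.zeros(r)
    for i, pop in enumerate(pops):
        pair = table.calls[table.pop_mask(pop), j, :]
        pair = pair[pair[:, 0] != MISSING]
        n[i] = len(pair)
        if len(pair):
            p[i] = np.bincount(pair.ravel(), minlength=k) / (2 * len(pair))
            ho[i] = np.mean(pair[:, 0] != pair[:, 1])
    if np.any(n < 1):
        return float("nan")
    nh = r / np.sum(1.0 / n)  # harmonic mean sample size
    hs_plug = 1.0 - np.mean(np.sum(p**2, axis=1))
    ho_bar = ho.mean()
    hs = (nh / (nh - 1.0)) * (hs_plug - ho_bar / (2.0 * nh))
    pbar = p.mean(axis=0)
    ht_plug = 1.0 - np.sum(pbar**2)
    ht = ht_plug + hs / (nh * r) - ho_bar / (2.0 * nh * r)
    if 1.0 - hs <= 0:
        return float("nan")
    return float((r / (r - 1.0)) * (ht - hs) / (1.0 - hs))


def _combine_d(values: np.ndarray) -> float:
    """Harmonic-mean combination across loci (arithmetic fallback when any
    per-locus value is non-positive, where the harmonic mean is undefined)."""
    values = values[np.isfinite(values)]
    if len(values) == 0:
        return float("nan")
    if np.all(values > 0):
        return float(len(values) / np.sum(1.0 / values))
    return float(values.mean())


def jost_d(
    table: GenotypeTable,
    pops: list[str] | None = None,
    boot: int = 10_000,
    seed: int | None = None,
) -> DiffResult:
    """Jost's D_EST across loci with 95% percentile bootstrap over loci."""
    pops = pops or table.populations
    if len(pops) < 2:
        raise GenotypeError("D needs >= 2 populations")
    per_locus = np.array(
        [_jost_d_locus(table, pops, j) for j in range(table.n_loci)]
    )
    d = _combine_d(per_locus)
    finite = per_locus[np.isfinite(per_locus)]
    if boot > 0 and len(finite) > 1:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(finite), size=(boot, len(finite)))
        vals = np.array([_combine_d(finite[row]) for row in idx])
        vals = vals[np.isfinite(vals)]
        lo, hi = np.percentile(vals, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return DiffResult(float(d), float(lo), float(hi), per_locus)


def pairwise_matrix(
    table: GenotypeTable,
    statistic=wc_theta,
    boot: int = 1_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise differentiation: point estimates below the diagonal, 95% CI
    tuples above (Table-3 layout)."""
    pops = table.populations
    rng = np.random.default_rng(seed)
    mat = pd.DataFrame(index=pops, columns=pops, dtype=object)
    for i, p1 in enumerate(pops):
        for k2 in range(i + 1, len(pops)):
            p2 = pops[k2]
            r = statistic(table, [p1, p2], boot=boot,
                          seed=int(rng.integers(0, 2**31 - 1)))
            mat.loc[p2, p1] = round(r.estimate, 4)
            mat.loc[p1, p2] = (round(r.ci_low, 4), round(r.ci_high, 4))
    return mat


# -- exact G tests of differentiation --------------------------------------


@dataclass
class GTestResult:
    per_locus_p: dict[str, float]
    chi2: float
    df: int
    p: float


def exact_g_diff(
    table: GenotypeTable,
    pops: list[str] | None = None,
    reps: int = 2_000,
    seed: int | None = None,
) -> GTestResult:
    """Monte-Carlo exact G test of genotypic differentiation per locus,
    combined across loci by Fisher's method (chi2 = -2 sum ln p, df = 2L)."""
    pops = pops or table.populations
    if len(pops) < 2:
        raise GenotypeError("differentiation test needs >= 2 populations")
    rng = np.random.default_rng(seed)
    sub = table.restrict_pops(pops)
    pvals: dict[str, float] = {}
    for j, locus in enumerate(sub.loci):
        pair = sub.calls[:, j, :]
        ok = pair[:, 0] != MISSING
        if ok.sum() < 2:
            continue
        labels = np.array(sub.pops)[ok]
        m = int(pair[ok].max()) + 1
        geno = pair[ok, 0] * m + pair[ok, 1]
        if np.unique(geno).size < 2 or np.unique(labels).size < 2:
            continue
        _, lab = np.unique(labels, return_inverse=True)
        _, gen = np.unique(geno, return_inverse=True)
        obs = _g_stat(lab, gen)
        hits = 0
        for _ in range(reps):
            hits += _g_stat(lab, rng.permutation(gen)) >= obs - 1e-12
        pvals[locus.name] = (hits + 1) / (reps + 1)
    if not pvals:
        raise GenotypeError("no locus defines a differentiation test")
    chi2 = -2.0 * sum(math.log(p) for p in pvals.values())
    df = 2 * len(pvals)
    return GTestResult(pvals, float(chi2), df, float(stats.chi2.sf(chi2, df)))


def _g_stat(x: np.ndarray, y: np.ndarray) -> float:
    """Log-likelihood-ratio G of a contingency table given integer codes."""
    nx, ny = x.max() + 1, y.max() + 1
    tab = np.bincount(x * ny + y, minlength=nx * ny).astype(float).reshape(nx, ny)
    exp = tab.sum(1, keepdims=True) @ tab.sum(0, keepdims=True) / tab.sum()
    nz = tab > 0
    return float(2.0 * np.sum(tab[nz] * np.log(tab[nz] / exp[nz])))
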