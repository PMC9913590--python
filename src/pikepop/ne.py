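"""Contemporary effective population size from linkage disequilibrium.

Single-sample LD method: Burrows' composite disequilibrium between all
pairs of loci, squared correlations corrected for the sampling-induced
expectation at sample size S (random-mating formulas, separate branches for
S >= 30 and S < 30), and the quadratic inversion to Ne.  Singleton alleles
(one copy in one heterozygote) are screened out before pairing; confidence
intervals are jackknife over loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeError, GenotypeTable


@dataclass
class NeResult:
    """LD-based Ne estimate for one population sample."""

    ne: float  # point estimate; inf when drift signal is absent
    ci_low: float
    ci_high: float
    s: float  # (harmonic mean) sample size behind the estimate
    r2_mean: float
    r2_expected: float
    n_comparisons: int
    screened: list[tuple[str, int]] = field(default_factory=list)
    subsampled: bool = False

    def __repr__(self) -> str:
        return (
            f"<NeResult Ne={self.ne:.1f} CI95=({self.ci_low:.1f}, "
            f"{self.ci_high:.1f}) S={self.s:.1f}>"
        )


def _expected_r2(s: float) -> float:
    """E[r^2] under no disequilibrium for sample size s (random mating)."""
    if s >= 30:
        return 1.0 / s + 3.19 / s**2
    return 0.0018 + 0.907 / s + 4.44 / s**2


def _ne_from_r2(r2: float, s: float) -> float:
    """Invert the drift expectation r2' ~ 1/(3Ne) + 1/S for Ne."""
    r2p = r2 - _expected_r2(s)
    if r2p <= 0:
        return float("inf")
    if s >= 30:
        disc = max(1.0 / 9.0 - 2.76 * r2p, 0.0)
        return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2p)
    disc = max(0.308**2 - 2.08 * r2p, 0.0)
    return (0.308 + math.sqrt(disc)) / (2.0 * r2p)


def screen_singletons(
    dose: np.ndarray, labels: tuple[int, ...]
) -> tuple[np.ndarray, list[int]]:
    """Drop alleles present as a single copy (necessarily in a heterozygote).

    *dose* is individuals x alleles dosage (0/1/2, NaN for missing); returns
    the retained columns and the removed allele labels.  Idempotent.
    """
    copies = np.nansum(dose, axis=0)
    keep = copies != 1
    removed = [labels[a] for a in np.flatnonzero(~keep)]
    return dose[:, keep], removed


def estimate_ne(
    table: GenotypeTable,
    pop: str,
    screen: bool = True,
    subsample_s: int | None = None,
    n_subsamples: int = 100,
    seed: int | None = None,
    jackknife: str = "individuals",
) -> NeResult:
    """LD-method Ne for one population (see module docstring).

    With *subsample_s*, the estimate is repeated on random subsamples of
    that many individuals and the harmonic mean across runs is reported
    (the convention used to compare populations at a common sample size).
    """
    mask = table.pop_mask(pop)
    sub = table.subset(individuals=mask)
    if subsample_s is not None:
        if subsample_s > sub.n_individuals:
            raise GenotypeError("subsample size exceeds population size")
        if subsample_s == sub.n_individuals:
            return estimate_ne(table, pop, screen=screen, seed=seed)
        rng = np.random.default_rng(seed)
        runs = []
        for _ in range(n_subsamples):
            idx = rng.choice(sub.n_individuals, size=subsample_s, replace=False)
            runs.append(_estimate_ne_sample(sub.subset(individuals=idx), screen, jackknife))
        return NeResult(
            ne=_harmonic([r.ne for r in runs]),
            ci_low=_harmonic([r.ci_low for r in runs]),
            ci_high=_harmonic([r.ci_high for r in runs]),
            s=float(np.mean([r.s for r in runs])),
            r2_mean=float(np.mean([r.r2_mean for r in runs])),
            r2_expected=float(np.mean([r.r2_expected for r in runs])),
            n_comparisons=runs[0].n_comparisons,
            screened=runs[0].screened,
            subsampled=True,
        )
    return _estimate_ne_sample(sub, screen, jackknife)


def _harmonic(values: list[float]) -> float:
    inv = [1.0 / v if np.isfinite(v) and v > 0 else 0.0 for v in values]
    m = np.mean(inv)
    return float(1.0 / m) if m > 0 else float("inf")


def _locus_dosage(table: GenotypeTable, j: int) -> np.ndarray:
    """Individuals x alleles dosage matrix, NaN rows for missing calls."""
    k = table.loci[j].n_alleles
    pair = table.calls[:, j, :]
    dose = np.zeros((table.n_individuals, k))
    ok = pair[:, 0] != MISSING
    for c in range(2):
        np.add.at(dose, (np.flatnonzero(ok), pair[ok, c]), 1.0)
    dose[~ok] = np.nan
    return dose


def _prepare_doses(
    sub: GenotypeTable, screen: bool
) -> tuple[list[np.ndarray], list[int], list[tuple[str, int]]]:
    doses: list[np.ndarray] = []
    locus_of: list[int] = []
    screened: list[tuple[str, int]] = []
    for j, locus in enumerate(sub.loci):
        dose = _locus_dosage(sub, j)
        labels = locus.alleles
        if screen:
            dose, removed = screen_singletons(dose, labels)
            screened.extend((locus.name, a) for a in removed)
        # usable alleles: polymorphic among non-missing individuals
        ok = ~np.isnan(dose[:, 0]) if dose.shape[1] else np.zeros(0, bool)
        cols = []
        for a in range(dose.shape[1]):
            col = dose[ok, a]
            if col.size and 0 < col.sum() < 2 * col.size:
                cols.append(dose[:, a])
        if len(cols) >= 2:
            doses.append(np.column_stack(cols))
            locus_of.append(j)
    return doses, locus_of, screened


def _weighted_r2(
    doses: list[np.ndarray],
    skip_individual: int | None = None,
    skip_locus: int | None = None,
) -> tuple[float, float, int]:
    """Information-weighted mean r^2 across allele-pair comparisons.

    Each comparison is weighted by p(1-p)q(1-q), giving low-information
    rare-allele comparisons proportionally less influence; returns
    (mean r2, weighted harmonic-mean sample size, comparison count).
    """
    num = den = swn = 0.0
    count = 0
    for a in range(len(doses)):
        if a == skip_locus:
            continue
        for b in range(a + 1, len(doses)):
            if b == skip_locus:
                continue
            both = ~np.isnan(doses[a][:, 0]) & ~np.isnan(doses[b][:, 0])
            if skip_individual is not None:
                both[skip_individual] = False
            s = int(both.sum())
            if s < 2:
                continue
            xa = doses[a][both]
            xb = doses[b][both]
            pa = xa.mean(axis=0) / 2.0
            pb = xb.mean(axis=0) / 2.0
            # Burrows composite disequilibrium for every allele pair
            cross = xa.T @ xb / s  # mean of x*y per pair
            delta = (s / (s - 1.0)) * (cross / 2.0 - 2.0 * np.outer(pa, pb))
            denom = np.outer(pa * (1 - pa), pb * (1 - pb))
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = delta**2 / denom
            ok = np.isfinite(r2)
            num += float((denom[ok] * r2[ok]).sum())
            den += float(denom[ok].sum())
            swn += float((denom[ok] / s).sum())
            count += int(ok.sum())
    if den <= 0:
        raise GenotypeError("no usable locus-pair comparisons")
    return num / den, den / swn, count


def _estimate_ne_sample(
    sub: GenotypeTable, screen: bool, jackknife: str = "individuals"
) -> NeResult:
    doses, _, screened = _prepare_doses(sub, screen)
    if len(doses) < 2:
        raise GenotypeError("fewer than 2 usable polymorphic loci after screening")
    r2_mean, s_harm, count = _weighted_r2(doses)
    exp_r2 = _expected_r2(s_harm)
    ne = _ne_from_r2(r2_mean, s_harm)

    # delete-one jackknife -> chi-square CI on the mean r^2 with effective
    # degrees of freedom n' = 2 (r2)^2 / Var_jack(r2)
    if jackknife == "individuals":
        units = range(sub.n_individuals)
        pseudo = [
            _weighted_r2(doses, skip_individual=i)[0] for i in units
        ]
    elif jackknife == "loci":
        pseudo = [
            _weighted_r2(doses, skip_locus=l)[0] for l in range(len(doses))
        ]
    else:
        raise ValueError("jackknife must be 'individuals' or 'loci'")
    ne_lo = ne_hi = float("nan")
    if len(pseudo) > 1 and r2_mean > 0:
        arr = np.asarray(pseudo)
        m = len(arr)
        var = (m - 1) / m * np.sum((arr - arr.mean()) ** 2)
        if var > 0:
            from scipy.stats import chi2

            ndf = 2.0 * r2_mean**2 / var
            r2_hi = ndf * r2_mean / chi2.ppf(0.025, ndf)
            r2_lo = ndf * r2_mean / chi2.ppf(0.975, ndf)
            lo, hi = _ne_from_r2(r2_hi, s_harm), _ne_from_r2(r2_lo, s_harm)
            ne_lo, ne_hi = (lo, hi) if lo <= hi else (hi, lo)
    return NeResult(
        ne=float(ne),
        ci_low=float(ne_lo),
        ci_high=float(ne_hi),
        s=float(s_harm),
        r2_mean=float(r2_mean),
        r2_expected=float(exp_r2),
        n_comparisons=count,
        screened=screened,
    )
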