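"""Individual assignment engines, exposed as Model/Results pairs.

Three engines assign individuals to parental or hybrid genotypic classes:

``NewHybridsModel``
    Bayesian model-based clustering over genotype-frequency classes.  A
    Gibbs sampler alternates between latent per-individual class labels,
    latent per-locus gene-copy origins, and the two species' allele
    frequencies (Jeffreys Dirichlet(1/2) priors).  The genotype likelihood
    of class z at a locus is ``z11 P(g|pool1) + z12 P(one copy from each
    pool) + z22 P(g|pool2)``; the posterior membership q is the class-label
    frequency after burn-in.

``SnapclustModel``
    Maximum-likelihood EM in which each class is a hybridity coefficient
    alpha (the expected share of gene copies from pool 1: parents 1 and 0,
    F1 1/2, first backcross 3/4, second backcross 7/8, mirrored toward
    pool 2).  Every gene copy is drawn from pool 1 with probability alpha,
    so F2 is indistinguishable from F1 (both are alpha = 1/2) and is not in
    the default class roster.

``DAPC``
    Discriminant analysis of principal components: genotypes coded as
    allele dosages, PCA, then linear discriminants on the retained PCs,
    with the PC count picked by stratified cross-validation.

Missing genotypes contribute likelihood 1 at their locus (marginalised) in
both likelihood engines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .genotypes import MISSING, GenotypeError, GenotypeTable
from .hybrids import HYBRID_CLASSES

_MIRROR = {
    "P1": "P2", "P2": "P1", "F1": "F1", "F2": "F2",
    "P1_bx": "P2_bx", "P2_bx": "P1_bx",
    "P1_bx1": "P2_bx1", "P2_bx1": "P1_bx1",
}


def _locus_arrays(table: GenotypeTable) -> list[np.ndarray]:
    """Per-locus (n, 2) index arrays (MISSING kept as -1)."""
    return [table.calls[:, j, :].copy() for j in range(table.n_loci)]


# ======================================================================
# NewHybrids-style Bayesian MCMC
# ======================================================================


class NewHybridsModel:
    """Bayesian genotype-frequency-class assignment (see module docstring).

    Parameters
    ----------
    table : mixture plus reference populations, one shared locus panel.
    classes : class labels to include (default: all eight).
    ref1, ref2 : population labels used only to anchor pool 1 / pool 2
        after sampling (label-switching resolution); individuals from these
        populations are analysed like any other unless *fix_references*.
    fix_references : if True, reference individuals' class labels are
        clamped to P1 / P2 during sampling (the known-origin option).
    fixed_frequencies : optional ``(freqs1, freqs2)`` per-locus frequency
        vectors; when given, allele frequencies are held fixed (used for
        validation against exact enumeration).
    """

    def __init__(
        self,
        table: GenotypeTable,
        classes: tuple[str, ...] = tuple(HYBRID_CLASSES),
        ref1: str | None = None,
        ref2: str | None = None,
        fix_references: bool = False,
        fixed_frequencies: tuple[list[np.ndarray], list[np.ndarray]] | None = None,
    ) -> None:
        unknown = [c for c in classes if c not in HYBRID_CLASSES]
        if unknown:
            raise ValueError(f"unknown classes {unknown}")
        self.table = table
        self.classes = [HYBRID_CLASSES[c] for c in classes]
        self.ref1, self.ref2 = ref1, ref2
        self.fix_references = fix_references
        self.fixed_frequencies = fixed_frequencies
        self._geno = _locus_arrays(table)
        self._z = np.array([c.z for c in self.classes])  # (C, 3)

    def fit(
        self,
        iters: int = 500_000,
        burn: int = 100_000,
        seed: int | None = None,
        thin: int = 1,
    ) -> "NewHybridsResults":
        rng = np.random.default_rng(seed)
        table = self.table
        n, L, C = table.n_individuals, table.n_loci, len(self.classes)
        k = [table.loci[j].n_alleles for j in range(L)]
        fixed = self.fixed_frequencies is not None
        if fixed:
            theta = [
                [np.asarray(v, float) for v in self.fixed_frequencies[0]],
                [np.asarray(v, float) for v in self.fixed_frequencies[1]],
            ]
        else:
            theta = [
                [rng.dirichlet(np.ones(k[j])) for j in range(L)] for _ in range(2)
            ]
        labels = np.zeros(n, dtype=int)
        fixed_class = np.full(n, -1)
        if self.fix_references:
            cl = {c.label: i for i, c in enumerate(self.classes)}
            for i, pop in enumerate(table.pops):
                if pop == self.ref1 and "P1" in cl:
                    fixed_class[i] = cl["P1"]
                elif pop == self.ref2 and "P2" in cl:
                    fixed_class[i] = cl["P2"]
        tallies = np.zeros((n, C))
        het = [self._geno[j][:, 0] != self._geno[j][:, 1] for j in range(L)]
        ok = [self._geno[j][:, 0] != MISSING for j in range(L)]
        kept = 0
        switch_trace = []
        for sweep in range(iters + burn):
            # component probabilities per locus: (n, 3)
            loglik = np.zeros((n, C))
            comps = []
            for j in range(L):
                a = self._geno[j][:, 0]
                b = self._geno[j][:, 1]
                t1, t2 = theta[0][j], theta[1][j]
                comp = np.ones((n, 3))
                oj, hj = ok[j], het[j]
                a_, b_ = a[oj], b[oj]
                mult = np.where(hj[oj], 2.0, 1.0)
                p1 = t1[a_] * t1[b_] * mult
                p2 = t2[a_] * t2[b_] * mult
                p12 = np.where(
                    hj[oj],
                    t1[a_] * t2[b_] + t1[b_] * t2[a_],
                    t1[a_] * t2[a_],
                )
                comp[oj, 0], comp[oj, 1], comp[oj, 2] = p1, p12, p2
                comps.append(comp)
                loglik += np.log(np.maximum(comp @ self._z.T, 1e-300))
            # sample class labels
            m = loglik.max(axis=1, keepdims=True)
            w = np.exp(loglik - m)
            w /= w.sum(axis=1, keepdims=True)
            u = rng.random(n)
            labels = (w.cumsum(axis=1) < u[:, None]).sum(axis=1)
            clamp = fixed_class >= 0
            labels[clamp] = fixed_class[clamp]
            zi = self._z[labels]  # (n, 3)
            if not fixed:
                counts = [
                    [np.full(k[j], 0.5) for j in range(L)] for _ in range(2)
                ]
                for j in range(L):
                    comp = comps[j]
                    a, b = self._geno[j][:, 0], self._geno[j][:, 1]
                    post = zi * comp
                    post /= post.sum(axis=1, keepdims=True)
                    u2 = rng.random(n)
                    origin = (post.cumsum(axis=1) < u2[:, None]).sum(axis=1)
                    oj = ok[j]
                    both1 = oj & (origin == 0)
                    both2 = oj & (origin == 2)
                    mix = oj & (origin == 1)
                    np.add.at(counts[0][j], a[both1], 1.0)
                    np.add.at(counts[0][j], b[both1], 1.0)
                    np.add.at(counts[1][j], a[both2], 1.0)
                    np.add.at(counts[1][j], b[both2], 1.0)
                    if mix.any():
                        am, bm = a[mix], b[mix]
                        t1, t2 = theta[0][j], theta[1][j]
                        # orientation: which copy came from pool 1
                        w1 = t1[am] * t2[bm]
                        w2 = t1[bm] * t2[am]
                        pick = rng.random(mix.sum()) < w1 / np.maximum(w1 + w2, 1e-300)
                        np.add.at(counts[0][j], np.where(pick, am, bm), 1.0)
                        np.add.at(counts[1][j], np.where(pick, bm, am), 1.0)
                    theta[0][j] = rng.dirichlet(counts[0][j])
                    theta[1][j] = rng.dirichlet(counts[1][j])
            if sweep >= burn and (sweep - burn) % thin == 0:
                rows = np.arange(n)
                tallies[rows, labels] += 1
                kept += 1
                if self.ref1 is not None:
                    p1_idx = [i for i, c in enumerate(self.classes)
                              if c.label == "P1"]
                    if p1_idx:
                        refmask = np.array(
                            [p == self.ref1 for p in table.pops]
                        )
                        switch_trace.append(
                            float(np.mean(labels[refmask] == p1_idx[0]))
                        )
        q = tallies / kept
        q_frame = pd.DataFrame(
            q, index=table.ids, columns=[c.label for c in self.classes]
        )
        res = NewHybridsResults(
            model=self,
            q=q_frame,
            iters=iters,
            burn=burn,
            seed=seed,
            switch_trace=np.asarray(switch_trace),
        )
        if self.ref1 is not None and self.ref2 is not None and not fixed:
            res = res.anchored()
        return res

    def fit_replicates(
        self, n_replicates: int = 5, iters: int = 500_000,
        burn: int = 100_000, seed: int | None = None,
    ) -> list["NewHybridsResults"]:
        """Independent replicate runs, reported separately (replicate
        disagreement is a finding, not an artefact to merge away)."""
        rng = np.random.default_rng(seed)
        return [
            self.fit(iters=iters, burn=burn, seed=int(rng.integers(0, 2**31 - 1)))
            for _ in range(n_replicates)
        ]


@dataclass
class NewHybridsResults:
    model: NewHybridsModel
    q: pd.DataFrame
    iters: int
    burn: int
    seed: int | None
    switch_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    swapped: bool = False

    def anchored(self) -> "NewHybridsResults":
        """Anchor pool 1 to ref1: if ref1 individuals sit mostly in the
        pool-2 classes, mirror all class labels."""
        t = self.model.table
        mask1 = np.array([p == self.model.ref1 for p in t.pops])
        cols = list(self.q.columns)
        share1 = sum(
            self.q.loc[mask1, c].mean()
            for c in cols if c in ("P1", "P1_bx", "P1_bx1")
        )
        share2 = sum(
            self.q.loc[mask1, c].mean()
            for c in cols if c in ("P2", "P2_bx", "P2_bx1")
        )
        if share2 > share1:
            mirrored = self.q.rename(columns=_MIRROR)
            q = mirrored[cols]
            return NewHybridsResults(
                self.model, q, self.iters, self.burn, self.seed,
                self.switch_trace, swapped=True,
            )
        return self

    @property
    def mixing_warning(self) -> bool:
        """True when the parental pools traded places during sampling."""
        if self.switch_trace.size == 0:
            return False
        return bool(0.05 < self.switch_trace.mean() < 0.95)

    def summary(self) -> str:
        lines = [
            "NewHybrids-style Bayesian assignment",
            f"  individuals: {len(self.q)}  classes: {list(self.q.columns)}",
            f"  iterations: {self.iters} (+{self.burn} burn-in), seed={self.seed}",
            f"  pools swapped for anchoring: {self.swapped}",
            "",
            self.q.round(3).to_string(max_rows=20),
        ]
        return "\n".join(lines)


def enumerate_class_posteriors(
    table: GenotypeTable,
    classes: tuple[str, ...],
    freqs1: list[np.ndarray],
    freqs2: list[np.ndarray],
) -> pd.DataFrame:
    """Exact per-individual class posteriors with known, fixed allele
    frequencies (flat class prior) — the closed-form counterpart of the
    MCMC with *fixed_frequencies*."""
    geno = _locus_arrays(table)
    z = np.array([HYBRID_CLASSES[c].z for c in classes])
    n = table.n_individuals
    loglik = np.zeros((n, len(classes)))
    for j in range(table.n_loci):
        a, b = geno[j][:, 0], geno[j][:, 1]
        ok = a != MISSING
        het = a != b
        t1 = np.asarray(freqs1[j], float)
        t2 = np.asarray(freqs2[j], float)
        comp = np.ones((n, 3))
        mult = np.where(het[ok], 2.0, 1.0)
        comp[ok, 0] = t1[a[ok]] * t1[b[ok]] * mult
        comp[ok, 2] = t2[a[ok]] * t2[b[ok]] * mult
        comp[ok, 1] = np.where(
            het[ok], t1[a[ok]] * t2[b[ok]] + t1[b[ok]] * t2[a[ok]],
            t1[a[ok]] * t2[a[ok]],
        )
        loglik += np.log(np.maximum(comp @ z.T, 1e-300))
    w = np.exp(loglik - loglik.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    return pd.DataFrame(w, index=table.ids, columns=list(classes))


# ======================================================================
# snapclust-style EM
# ======================================================================


DEFAULT_EM_CLASSES = ("P1", "P2", "F1", "P1_bx", "P1_bx1", "P2_bx", "P2_bx1")


class SnapclustModel:
    """EM maximum-likelihood assignment with hybridity coefficients.

    Initialisation follows the geometric rule: individuals are split by the
    sign of their first principal-component score (allele-dosage coding)
    and the two groups seed the parental pool frequencies.
    """

    def __init__(
        self,
        table: GenotypeTable,
        classes: tuple[str, ...] = DEFAULT_EM_CLASSES,
        ref1: str | None = None,
        ref2: str | None = None,
    ) -> None:
        self.table = table
        self.class_labels = list(classes)
        self.alpha = np.array(
            [HYBRID_CLASSES[c].pool1_share for c in classes]
        )
        self.ref1, self.ref2 = ref1, ref2
        self._geno = _locus_arrays(table)

    def _init_pools(self, rng: np.random.Generator, random_split: bool = False):
        table = self.table
        if random_split:
            group1 = rng.random(table.n_individuals) < 0.5
        else:
            x = table.allele_count_matrix()
            x = x - x.mean(axis=0)
            score = PCA(n_components=1, random_state=0).fit_transform(x)[:, 0]
            group1 = score >= np.median(score)
        theta = [[], []]
        for j, locus in enumerate(table.loci):
            for s, grp in enumerate((group1, ~group1)):
                pair = table.calls[grp, j, :]
                pair = pair[pair[:, 0] != MISSING]
                cnt = np.bincount(pair.ravel(), minlength=locus.n_alleles) + 0.5
                theta[s].append(cnt / cnt.sum())
        return theta

    def fit(
        self,
        max_iter: int = 500,
        tol: float = 1e-8,
        seed: int | None = None,
        max_restarts: int = 5,
    ) -> "SnapclustResults":
        rng = np.random.default_rng(seed)
        for attempt in range(max_restarts + 1):
            theta = self._init_pools(rng, random_split=attempt > 0)
            out = self._run_em(theta, max_iter, tol)
            if out is not None:
                q, trace, theta = out
                break
        else:
            raise GenotypeError("EM failed to keep both parental pools occupied")
        res = SnapclustResults(
            model=self,
            q=pd.DataFrame(q, index=self.table.ids, columns=self.class_labels),
            loglik_trace=np.asarray(trace),
            converged=len(trace) < max_iter
            or (len(trace) > 1 and trace[-1] - trace[-2] < tol * (1 + abs(trace[-1]))),
            seed=seed,
            restarts=attempt,
        )
        if self.ref1 is not None and self.ref2 is not None:
            res = res.anchored()
        return res

    def _run_em(self, theta, max_iter, tol):
        table = self.table
        n, L, C = table.n_individuals, table.n_loci, len(self.alpha)
        trace: list[float] = []
        q = np.full((n, C), 1.0 / C)
        for it in range(max_iter):
            loglik = np.zeros((n, C))
            for j in range(L):
                a, b = self._geno[j][:, 0], self._geno[j][:, 1]
                ok = a != MISSING
                het = (a != b) & ok
                t1, t2 = theta[0][j], theta[1][j]
                # mixture allele prob per class: (n_ok, C)
                ma = np.outer(t1[a[ok]], self.alpha) + np.outer(
                    t2[a[ok]], 1 - self.alpha
                )
                mb = np.outer(t1[b[ok]], self.alpha) + np.outer(
                    t2[b[ok]], 1 - self.alpha
                )
                lik = ma * mb
                lik[het[ok]] *= 2.0
                loglik[ok] += np.log(np.maximum(lik, 1e-300))
            m = loglik.max(axis=1, keepdims=True)
            w = np.exp(loglik - m)
            tot = w.sum(axis=1, keepdims=True)
            q = w / tot
            ll = float(np.sum(np.log(tot.ravel() / C) + m.ravel()))
            trace.append(ll)
            # M-step: copy-level posterior origin, membership-weighted counts
            new_theta = [[], []]
            for j in range(L):
                a, b = self._geno[j][:, 0], self._geno[j][:, 1]
                ok = a != MISSING
                k = table.loci[j].n_alleles
                c1 = np.full(k, 0.01)
                c2 = np.full(k, 0.01)
                t1, t2 = theta[0][j], theta[1][j]
                for copies in (a, b):
                    al = copies[ok]
                    num = np.outer(t1[al], self.alpha)
                    den = num + np.outer(t2[al], 1 - self.alpha)
                    pc1 = num / np.maximum(den, 1e-300)  # (n_ok, C)
                    w1 = (q[ok] * pc1).sum(axis=1)
                    np.add.at(c1, al, w1)
                    np.add.at(c2, al, 1.0 - w1)
                new_theta[0].append(c1 / c1.sum())
                new_theta[1].append(c2 / c2.sum())
            # guard: a parental pool losing all weight means a degenerate fit
            w_pool1 = float((q @ self.alpha).sum())
            w_pool2 = float((q @ (1 - self.alpha)).sum())
            if min(w_pool1, w_pool2) < 1e-6 * n:
                return None
            theta = new_theta
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (
                1 + abs(trace[-1])
            ):
                break
        return q, trace, theta


@dataclass
class SnapclustResults:
    model: SnapclustModel
    q: pd.DataFrame
    loglik_trace: np.ndarray
    converged: bool
    seed: int | None
    restarts: int = 0
    swapped: bool = False

    def anchored(self) -> "SnapclustResults":
        t = self.model.table
        mask1 = np.array([p == self.model.ref1 for p in t.pops])
        cols = list(self.q.columns)
        alpha = self.model.alpha
        mean_alpha_ref1 = float(
            (self.q.loc[mask1].to_numpy() @ alpha).sum() / mask1.sum()
        )
        if mean_alpha_ref1 < 0.5:
            mirrored = self.q.rename(columns=_MIRROR)
            keep = [c for c in cols if c in mirrored.columns]
            return SnapclustResults(
                self.model, mirrored[keep], self.loglik_trace,
                self.converged, self.seed, self.restarts, swapped=True,
            )
        return self

    def summary(self) -> str:
        return "\n".join(
            [
                "snapclust-style EM assignment",
                f"  individuals: {len(self.q)}  classes: {list(self.q.columns)}",
                f"  log-likelihood: {self.loglik_trace[-1]:.3f} "
                f"({len(self.loglik_trace)} iterations, converged={self.converged})",
                "",
                self.q.round(3).to_string(max_rows=20),
            ]
        )


# ======================================================================
# DAPC
# ======================================================================


class DAPC:
    """Discriminant analysis of principal components.

    Genotypes are coded as centred/scaled allele dosages; PCA reduces them
    and a linear discriminant analysis separates the groups on the retained
    PCs.  The PC count is chosen by stratified cross-validated held-out
    reassignment when not given.
    """

    def __init__(self, table: GenotypeTable, groups: list[str] | None = None):
        self.table = table
        self.groups = list(groups) if groups is not None else list(table.pops)
        if len(self.groups) != table.n_individuals:
            raise GenotypeError("group labels length mismatch")
        uniq, counts = np.unique(self.groups, return_counts=True)
        if len(uniq) < 2:
            raise GenotypeError("DAPC needs >= 2 groups")
        if counts.min() < 3:
            raise GenotypeError("DAPC needs >= 3 individuals per group")

    def _design(self) -> np.ndarray:
        x = self.table.allele_count_matrix()
        x = x - x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        return x / sd

    def fit(
        self,
        n_pca: int | None = None,
        cv_folds: int = 5,
        seed: int | None = None,
    ) -> "DapcResults":
        x = self._design()
        y = np.asarray(self.groups)
        n = len(y)
        max_pc = int(min(n - 1, x.shape[1], np.linalg.matrix_rank(x)))
        pca = PCA(n_components=max_pc, random_state=0).fit(x)
        scores = pca.transform(x)
        # negligible deterministic jitter keeps the within-group scatter
        # non-singular when groups are perfectly separated (clone groups)
        scale = scores.std() or 1.0
        scores = scores + 1e-7 * scale * np.random.default_rng(0).standard_normal(
            scores.shape
        )
        cv_table = None
        if n_pca is None:
            n_pca, cv_table = self._cross_validate(scores, y, max_pc, cv_folds, seed)
        n_pca = int(min(n_pca, max_pc))
        n_da = min(len(np.unique(y)) - 1, n_pca)
        lda = LinearDiscriminantAnalysis(n_components=n_da)
        lda.fit(scores[:, :n_pca], y)
        coords = lda.transform(scores[:, :n_pca])
        ev = getattr(lda, "explained_variance_ratio_", np.ones(n_da) / n_da)
        post = lda.predict_proba(scores[:, :n_pca])
        return DapcResults(
            model=self,
            n_pca=n_pca,
            n_da=n_da,
            ind_coords=pd.DataFrame(
                coords, index=self.table.ids,
                columns=[f"DF{i + 1}" for i in range(coords.shape[1])],
            ),
            assignments=pd.Series(lda.predict(scores[:, :n_pca]),
                                  index=self.table.ids),
            posterior=pd.DataFrame(post, index=self.table.ids, columns=lda.classes_),
            explained=np.asarray(ev),
            cv_table=cv_table,
            pca_explained=pca.explained_variance_ratio_[:n_pca].sum(),
        )

    def _cross_validate(self, scores, y, max_pc, folds, seed):
        _, counts = np.unique(y, return_counts=True)
        folds = int(min(folds, counts.min()))
        grid = sorted({max(1, round(f * max_pc)) for f in
                       (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)})
        rows = []
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for npc in grid:
            accs = []
            for tr, te in skf.split(scores, y):
                n_da = min(len(np.unique(y[tr])) - 1, npc)
                lda = LinearDiscriminantAnalysis(n_components=n_da)
                lda.fit(scores[tr][:, :npc], y[tr])
                accs.append(float(np.mean(lda.predict(scores[te][:, :npc]) == y[te])))
            rows.append({"n_pca": npc, "accuracy": float(np.mean(accs))})
        frame = pd.DataFrame(rows)
        best = frame.loc[frame["accuracy"].idxmax(), "n_pca"]
        return int(best), frame


@dataclass
class DapcResults:
    model: DAPC
    n_pca: int
    n_da: int
    ind_coords: pd.DataFrame
    assignments: pd.Series
    posterior: pd.DataFrame
    explained: np.ndarray
    cv_table: pd.DataFrame | None
    pca_explained: float

    def reassignment_rate(self) -> float:
        return float(np.mean(self.assignments.to_numpy() ==
                             np.asarray(self.model.groups)))

    def summary(self) -> str:
        lines = [
            "Discriminant analysis of principal components",
            f"  retained PCs: {self.n_pca} "
            f"({self.pca_explained:.1%} of variance), discriminants: {self.n_da}",
            f"  reassignment rate: {self.reassignment_rate():.1%}",
            f"  DF explained shares: {np.round(self.explained, 3).tolist()}",
        ]
        return "\n".join(lines)


def find_clusters(
    table: GenotypeTable,
    k_range: range | list[int] | None = None,
    rule: str = "diffNgroup",
    n_pca: int | None = None,
    seed: int | None = None,
) -> tuple[int, np.ndarray, pd.DataFrame]:
    """Infer the number of genetic clusters by k-means on PCA scores.

    BIC(k) treats k-means as a spherical equal-variance Gaussian mixture;
    the ``diffNgroup`` rule keeps the k reached after the last sharp BIC
    decrease (successive differences split into two groups by 1-D 2-means).
    Returns (k, labels, BIC curve).
    """
    x = table.allele_count_matrix()
    x = x - x.mean(axis=0)
    n = x.shape[0]
    max_pc = int(min(n - 1, x.shape[1], np.linalg.matrix_rank(x)))
    if n_pca is None:
        n_pca = max_pc
    scores = PCA(n_components=min(n_pca, max_pc), random_state=0).fit_transform(x)
    if k_range is None:
        k_range = range(1, min(11, n // 3 + 1))
    ks = [k for k in k_range if 1 <= k <= n - 1]
    if not ks:
        raise GenotypeError("empty k range")
    bics, labelings = [], {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(scores)
        w = max(float(km.inertia_), 1e-12)
        # dimension-free k-means BIC (the convention of the R packages
        # this mirrors): n ln(WSS/n) + k ln(n)
        bic = n * np.log(w / n) + k * np.log(n)
        bics.append(bic)
        labelings[k] = km.labels_
    curve = pd.DataFrame({"k": ks, "BIC": bics})
    if rule == "min":
        k_sel = ks[int(np.argmin(bics))]
    elif rule == "diffNgroup":
        k_sel = _diff_n_group(ks, np.asarray(bics), n)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return k_sel, labelings[k_sel], curve


def _diff_n_group(ks: list[int], bics: np.ndarray, n: int) -> int:
    if len(ks) < 2:
        return ks[0]
    # no structure: the best achievable drop is within one penalty unit
    if bics[0] - bics.min() <= np.log(n):
        return ks[0]
    diffs = bics[:-1] - bics[1:]  # decrease from k to k+1
    if diffs.max() <= 0:
        return ks[0]
    # split decreases into sharp/flat by 1-D 2-means
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(diffs.reshape(-1, 1))
    sharp = int(np.argmax(km.cluster_centers_.ravel()))
    sharp_idx = np.flatnonzero((km.labels_ == sharp) & (diffs > 0))
    if sharp_idx.size == 0:
        return ks[0]
    return ks[sharp_idx.max() + 1]
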