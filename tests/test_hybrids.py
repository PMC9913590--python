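"""Hybrid-class simulation by gamete sampling."""

import numpy as np
import pytest
from scipy import stats

from pikepop.genotypes import GenotypeError
from pikepop.hybrids import (
    DEFAULT_S1_ROSTER,
    HYBRID_CLASSES,
    GenePool,
    build_s1,
    hybridise,
    sample_mixture,
    simulate_class,
)


class TestHybridise:
    def test_fixed_difference_f1_all_heterozygous(self, fixed_diff_panel):
        _, pool1, pool2 = fixed_diff_panel
        f1 = hybridise(pool1, pool2, 50, seed=0)
        assert np.all(f1.calls[:, :, 0] != f1.calls[:, :, 1])

    def test_panel_mismatch_rejected(self, fixed_diff_panel):
        _, pool1, _ = fixed_diff_panel
        other = GenePool(pool1.loci[:5], pool1.freqs[:5])
        with pytest.raises(GenotypeError, match="panels differ"):
            hybridise(pool1, other, 10)

    def test_f2_segregates_one_two_one(self, fixed_diff_panel):
        _, pool1, pool2 = fixed_diff_panel
        f2 = simulate_class("F2", pool1, pool2, 10_000, seed=1)
        het = (f2.calls[:, 0, 0] != f2.calls[:, 0, 1]).mean()
        hom1 = ((f2.calls[:, 0, :] == 0).all(axis=1)).mean()
        hom2 = ((f2.calls[:, 0, :] == 1).all(axis=1)).mean()
        n = 10_000
        for obs, exp in ((het, 0.5), (hom1, 0.25), (hom2, 0.25)):
            se = np.sqrt(exp * (1 - exp) / n)
            assert abs(obs - exp) < 3 * se

    @pytest.mark.parametrize(
        "label", ["P1", "P2", "F1", "F2", "P1_bx", "P1_bx1", "P2_bx", "P2_bx1"]
    )
    def test_class_z_vectors_match_mendelian_expectation(
        self, label, fixed_diff_panel
    ):
        _, pool1, pool2 = fixed_diff_panel
        cohort = simulate_class(label, pool1, pool2, 10_000, seed=7)
        # at fixed-difference loci allele 0 marks species-1 origin
        z11 = (cohort.calls == 0).all(axis=2).mean()
        z12 = (cohort.calls[:, :, 0] != cohort.calls[:, :, 1]).mean()
        z22 = (cohort.calls == 1).all(axis=2).mean()
        expected = HYBRID_CLASSES[label].z
        for obs, exp in zip((z11, z12, z22), expected):
            se = np.sqrt(max(exp * (1 - exp), 1e-6) / (10_000 * 10))
            # pool re-estimation adds a little extra variance at each stage
            assert abs(obs - exp) < max(5 * se, 0.02)

    def test_p1_cohort_frequencies_converge_to_source(self, study):
        from pikepop.genotypes import allele_freqs

        pool = GenePool.from_table(study.clean, "TRA")
        tv = []
        for n in (100, 5000):
            cohort = simulate_class("P1", pool, pool, n, seed=3)
            emp = allele_freqs(cohort)
            dist = np.mean(
                [
                    0.5 * np.abs(emp.freqs["P1"][j] - pool.freqs[j]).sum()
                    for j in range(len(pool.loci))
                ]
            )
            tv.append(dist)
        assert tv[1] < tv[0]


class TestMixture:
    def test_identity_when_n_equals_pool(self, fixed_diff_panel):
        refs, pool1, pool2 = fixed_diff_panel
        cohort = simulate_class("F1", pool1, pool2, 10, seed=0)
        labels = ["F1"] * 10
        mix, lab = sample_mixture(cohort, labels, 10, seed=1)
        assert sorted(mix.ids) == sorted(cohort.ids)
        assert lab == ["F1"] * 10

    def test_empty_sample_allowed(self, fixed_diff_panel):
        _, pool1, pool2 = fixed_diff_panel
        cohort = simulate_class("F1", pool1, pool2, 5, seed=0)
        mix, lab = sample_mixture(cohort, ["F1"] * 5, 0, seed=1)
        assert mix.n_individuals == 0 and lab == []

    def test_oversampling_rejected(self, fixed_diff_panel):
        _, pool1, pool2 = fixed_diff_panel
        cohort = simulate_class("F1", pool1, pool2, 5, seed=0)
        with pytest.raises(GenotypeError):
            sample_mixture(cohort, ["F1"] * 5, 6)

    def test_class_counts_hypergeometric(self, fixed_diff_panel):
        _, pool1, pool2 = fixed_diff_panel
        cohort = simulate_class("F1", pool1, pool2, 40, seed=0)
        labels = ["X"] * 15 + ["Y"] * 25
        rng = np.random.default_rng(5)
        counts = [
            sample_mixture(cohort, labels, 10,
                           seed=int(rng.integers(2**31)))[1].count("X")
            for _ in range(1000)
        ]
        # chi-square against the hypergeometric pmf
        ks = np.arange(0, 11)
        pmf = stats.hypergeom.pmf(ks, 40, 15, 10)
        obs = np.bincount(counts, minlength=11)[:11]
        keep = pmf * 1000 >= 5
        chi = ((obs[keep] - 1000 * pmf[keep]) ** 2 / (1000 * pmf[keep])).sum()
        assert stats.chi2.sf(chi, keep.sum() - 1) > 0.001


class TestBuildS1:
    def test_bookkeeping_and_roster_variants(self, fixed_diff_panel):
        refs, _, _ = fixed_diff_panel
        sc = build_s1(refs, "R1", "R2", mixture=50, seed=1)
        assert len(sc.truth) == 50
        assert len(sc.pool_truth) == sum(DEFAULT_S1_ROSTER.values()) == 500
        assert sc.table.populations == ["R1", "R2", "MIX"]
        # four-class roster (no F1): 400-strong pool
        roster4 = {k: v for k, v in DEFAULT_S1_ROSTER.items() if k != "F1"}
        sc4 = build_s1(refs, "R1", "R2", roster=roster4, mixture=50, seed=1)
        assert len(sc4.pool_truth) == 400

    def test_determinism_and_variation(self, fixed_diff_panel):
        refs, _, _ = fixed_diff_panel
        a = build_s1(refs, "R1", "R2", mixture=30, seed=9)
        b = build_s1(refs, "R1", "R2", mixture=30, seed=9)
        c = build_s1(refs, "R1", "R2", mixture=30, seed=10)
        assert a.table == b.table and a.truth == b.truth
        assert a.truth != c.truth or a.table != c.table

    def test_mixture_larger_than_pool_rejected(self, fixed_diff_panel):
        refs, _, _ = fixed_diff_panel
        with pytest.raises(GenotypeError):
            build_s1(refs, "R1", "R2", roster={"P1": 10}, mixture=11)
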