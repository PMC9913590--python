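"""Diversity and differentiation estimators against brute-force oracles."""

import numpy as np
import pytest

from conftest import (
    ar_oracle,
    he_oracle,
    jost_d_locus_oracle,
    make_table,
    random_table,
    wc_theta_oracle,
)
from pikepop.diversity import (
    _jost_d_locus,
    allelic_richness,
    exact_g_diff,
    jost_d,
    summary_stats,
    unbiased_he,
    wc_theta,
)
from pikepop.genotypes import GenotypeError


class TestSummaryStats:
    def test_rarefaction_direct_combinatorics(self):
        # copies (3,1) in G=4 rarefied to g=2:
        # (1 - C(1,2)/C(4,2)) + (1 - C(3,2)/C(4,2)) = 1 + 0.5 = 1.5
        assert allelic_richness(np.array([3, 1]), 2) == pytest.approx(1.5)

    def test_monomorphic_locus(self):
        t = make_table({"P": [[(0, 0)], [(0, 0)]]}, n_alleles=1)
        s = summary_stats(t, boot=0)
        row = s.frame.loc["P"]
        assert row["HE_mean"] == 0 and row["HO_mean"] == 0
        assert row["AR_mean"] == pytest.approx(1.0)

    def test_identity_rarefaction_equals_allele_count(self):
        counts = np.array([5, 3, 2])
        assert allelic_richness(counts, 10) == pytest.approx(3.0)

    def test_rarefaction_monotone_in_g(self):
        counts = np.array([7, 2, 1])
        vals = [allelic_richness(counts, g) for g in range(1, 11)]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_g_larger_than_copies_raises(self):
        t = make_table({"P": [[(0, 1)], [(0, 1)]]}, n_alleles=2)
        with pytest.raises(GenotypeError, match="rarefaction"):
            summary_stats(t, g=10, boot=0)

    @pytest.mark.parametrize("seed", range(10))
    def test_he_and_ar_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_pops=1, p_missing=0.0)
        from pikepop.diversity import _pop_locus_counts

        for j in range(t.n_loci):
            c = _pop_locus_counts(t, "P1", j)
            assert unbiased_he(c) == pytest.approx(
                he_oracle(c.tolist()), abs=1e-12
            )
            assert allelic_richness(c, 2) == pytest.approx(
                ar_oracle(c.tolist(), 2), abs=1e-12
            )


class TestWcTheta:
    def test_fixed_difference_gives_one(self):
        t = make_table(
            {"A": [[(0, 0)]] * 5, "B": [[(1, 1)]] * 5}, n_alleles=2
        )
        assert wc_theta(t, boot=0).estimate == pytest.approx(1.0)

    def test_identical_copies_nonpositive(self):
        genos = [[(0, 1)], [(0, 0)], [(1, 1)], [(0, 1)]]
        t = make_table({"A": genos, "B": genos}, n_alleles=2)
        assert wc_theta(t, boot=0).estimate <= 0

    def test_two_pop_toy_matches_hand_components(self):
        t = make_table(
            {"A": [[(0, 0)], [(0, 0)], [(0, 1)]],
             "B": [[(1, 1)], [(0, 1)], [(1, 1)]]},
            n_alleles=2,
        )
        r = wc_theta(t, boot=0)
        assert r.estimate == pytest.approx(wc_theta_oracle(t, ["A", "B"]),
                                           abs=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = random_table(rng)
        r = wc_theta(t, boot=0)
        expected = wc_theta_oracle(t, t.populations)
        if np.isnan(expected):
            assert not r.defined or np.isnan(r.estimate)
        else:
            assert r.estimate == pytest.approx(expected, abs=1e-12)

    def test_bootstrap_ci_brackets_point(self, study):
        r = wc_theta(study.clean, boot=500, seed=1)
        assert r.ci_low <= r.estimate <= r.ci_high


class TestJostD:
    def test_identical_pools_near_zero(self):
        genos = [[(0, 1)], [(0, 0)], [(1, 1)], [(0, 1)], [(0, 1)]]
        t = make_table({"A": genos, "B": genos}, n_alleles=2)
        assert abs(jost_d(t, boot=0).estimate) < 0.15

    def test_fixed_difference_gives_one(self):
        t = make_table({"A": [[(0, 0)]] * 5, "B": [[(1, 1)]] * 5}, n_alleles=2)
        assert jost_d(t, boot=0).estimate == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_per_locus_matches_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        t = random_table(rng, p_missing=0.0)
        for j in range(t.n_loci):
            mine = _jost_d_locus(t, t.populations, j)
            theirs = jost_d_locus_oracle(t, t.populations, j)
            if np.isnan(theirs):
                assert np.isnan(mine)
            else:
                assert mine == pytest.approx(theirs, abs=1e-12)


class TestExactG:
    def test_fixed_difference_floors_p(self):
        t = make_table({"A": [[(0, 0)]] * 8, "B": [[(1, 1)]] * 8}, n_alleles=2)
        r = exact_g_diff(t, reps=500, seed=0)
        assert r.per_locus_p["L1"] == pytest.approx(1 / 501)
        assert r.p < 0.01

    def test_df_is_twice_defined_loci(self, study):
        r = exact_g_diff(study.clean, reps=100, seed=0)
        assert r.df == 2 * len(r.per_locus_p)
        assert r.df == 2 * study.clean.n_loci == 22

    def test_panmictic_null_p_uniform(self):
        from scipy import stats as sps

        rng = np.random.default_rng(9)
        ps = []
        for _ in range(60):
            pool = rng.dirichlet(np.ones(3))
            genos = {
                pop: [
                    [tuple(sorted(rng.choice(3, 2, p=pool).tolist()))]
                    for _ in range(15)
                ]
                for pop in ("A", "B")
            }
            r = exact_g_diff(make_table(genos, n_alleles=3), reps=200,
                             seed=int(rng.integers(2**31)))
            ps.append(r.per_locus_p["L1"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestStudyPatterns:
    """The synthetic study reproduces the printed design bands."""

    def test_summary_bands(self, study):
        s = summary_stats(study.clean, boot=300, seed=0)
        f = s.frame
        assert f["HE_mean"].between(0.3, 0.65).all()
        assert (f["AR_mean"] <= f["NA_mean"] + 1e-9).all()
        assert f.loc["TRA", "FIS"] < 0  # implanted heterozygote excess
        assert (f["FIS"].abs() <= 1).all()

    def test_global_theta_band(self, study):
        r = wc_theta(study.clean, boot=300, seed=0)
        assert 0.2 < r.estimate < 0.45
        between = wc_theta(study.clean, ["TRA", "DRA"], boot=0)
        assert 0.3 < between.estimate < 0.55
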