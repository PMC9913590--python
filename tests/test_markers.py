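"""Exact tests, multiple-testing machinery and dropout correction."""

import numpy as np
import pytest
from scipy import stats

from conftest import levene_exact_p, make_table
from pikepop.genotypes import MISSING
from pikepop.markers import (
    UndefinedTest,
    binomial_excess,
    by_fdr,
    correct_genotypes,
    estimate_dropout,
    hw_battery,
    hw_exact_test,
    ld_exact_test,
    min_significant_count,
)


class TestHwExact:
    def test_monomorphic_is_undefined(self):
        t = make_table({"P": [[(0, 0)]] * 5}, n_alleles=2)
        with pytest.raises(UndefinedTest):
            hw_exact_test(t, "P", "L1", "deficit", seed=0)

    @pytest.mark.parametrize(
        "genos",
        [
            [(0, 0), (0, 1), (0, 1), (1, 1), (0, 0)],
            [(0, 1), (0, 2), (1, 2), (0, 0), (1, 1), (2, 2)],
            [(0, 0), (1, 1), (0, 0), (1, 1)],
        ],
    )
    @pytest.mark.parametrize("direction", ["deficit", "excess"])
    def test_matches_enumeration_on_small_tables(self, genos, direction):
        t = make_table({"P": [[g] for g in genos]}, n_alleles=3)
        r = hw_exact_test(t, "P", "L1", direction,
                          demem=2000, batches=20, iters=2000, seed=7)
        exact = levene_exact_p(genos, direction)
        assert abs(r.p - exact) <= 3 * max(r.se, 2e-3)

    def test_battery_excludes_undefined_and_counts(self, study):
        bat = hw_battery(study.clean, demem=200, batches=5, iters=200, seed=0)
        mono = 0
        for pop in study.clean.populations:
            for j in range(study.clean.n_loci):
                pairs = study.clean.calls[study.clean.pop_mask(pop), j, :]
                pairs = pairs[pairs[:, 0] != MISSING]
                if np.unique(pairs).size < 2:
                    mono += 1
        assert bat.n_defined + bat.n_undefined == 4 * study.clean.n_loci
        assert bat.n_undefined == mono
        assert ((bat.frame["adjusted"] >= bat.frame["p"] - 1e-12).all())


class TestLdExact:
    def test_duplicated_locus_maximal_dependence(self):
        rng = np.random.default_rng(0)
        genos = [tuple(sorted(rng.integers(0, 2, 2).tolist())) for _ in range(30)]
        t = make_table({"P": [[g, g] for g in genos]}, n_alleles=2)
        r = ld_exact_test(t, "P", "L1", "L2", reps=2000, seed=1)
        assert r.p < 0.01

    def test_monomorphic_partner_undefined(self):
        t = make_table({"P": [[(0, 1), (0, 0)]] * 6}, n_alleles=2)
        with pytest.raises(UndefinedTest):
            ld_exact_test(t, "P", "L1", "L2", seed=0)

    def test_null_p_values_roughly_uniform(self):
        """Independent equilibrium loci: p ~ U(0,1) over replicates (KS)."""
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(120):
            genos = [
                [tuple(sorted(rng.integers(0, 2, 2).tolist())),
                 tuple(sorted(rng.integers(0, 2, 2).tolist()))]
                for _ in range(25)
            ]
            try:
                r = ld_exact_test(make_table({"P": genos}, n_alleles=2),
                                  "P", "L1", "L2", reps=200,
                                  seed=int(rng.integers(2**31)))
            except UndefinedTest:
                continue
            ps.append(r.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBinomialExcess:
    def test_zero_significant_gives_p_one(self):
        p, _ = binomial_excess(0, 10)
        assert p == 1.0

    def test_against_direct_pmf_sum(self):
        n, alpha = 63, 0.05
        for k in (0, 3, 5, 10, 25):
            p, crit = binomial_excess(k, n, alpha)
            direct = sum(
                stats.binom.pmf(x, n, alpha) for x in range(k, n + 1)
            )
            assert abs(p - direct) < 1e-10
        # critical count: largest k0 with P(X >= k0+1) > alpha
        _, crit = binomial_excess(5, n, alpha)
        assert stats.binom.sf(crit, n, alpha) > alpha
        assert stats.binom.sf(crit + 1, n, alpha) <= alpha

    def test_excess_declared_for_78_of_480(self):
        p, _ = binomial_excess(78, 480, 0.05)
        assert p < 0.05

    def test_both_count_conventions_exposed(self):
        # the 'critical count' and 'smallest significant k' differ by >= 1
        _, crit = binomial_excess(10, 63)
        k_min = min_significant_count(63)
        assert k_min > crit

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_excess(1, 0)
        with pytest.raises(ValueError):
            binomial_excess(5, 3)


class TestByFdr:
    def test_single_p_unchanged(self):
        assert by_fdr([0.03])[0] == pytest.approx(0.03)

    def test_three_p_step_up_formula(self):
        # B-Y with m=3: c(3) = 1 + 1/2 + 1/3 = 11/6
        p = np.array([0.01, 0.02, 0.05])
        c3 = 11 / 6
        raw = p * 3 * c3 / np.array([1, 2, 3])
        # step-up monotonicity from the largest rank down
        expected = np.minimum.accumulate(raw[::-1])[::-1]
        np.testing.assert_allclose(by_fdr(p), np.minimum(expected, 1), atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_dominates_bh_and_raw(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.random(25)
        adj = by_fdr(p)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.all(adj >= bh - 1e-12)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1 + 1e-12)

    def test_groupwise_adjustment_is_permutation_invariant(self):
        rng = np.random.default_rng(3)
        p = rng.random(12)
        groups = np.array([0, 1] * 6)
        adj = by_fdr(p, groups)
        perm = rng.permutation(12)
        adj_perm = by_fdr(p[perm], groups[perm])
        np.testing.assert_allclose(adj[perm], adj_perm)


class TestDropout:
    def _simulate(self, rng, n, d, k=4, n_loci=3):
        pop_genos = []
        freqs = rng.dirichlet(np.ones(k))
        for _ in range(n):
            genos = []
            for j in range(n_loci):
                a, b = sorted(rng.choice(k, 2, p=freqs).tolist())
                if j == 0:  # dropout only on the first locus
                    drop = rng.random(2) < d
                    if drop.all():
                        genos.append(None)
                        continue
                    if drop.any():
                        keep = b if drop[0] else a
                        a = b = keep
                genos.append((a, b))
            pop_genos.append(genos)
        return make_table({"P": pop_genos}, n_alleles=k)

    def test_clean_equilibrium_data_gives_near_zero_rates(self):
        rng = np.random.default_rng(1)
        t = self._simulate(rng, 150, d=0.0)
        model = estimate_dropout(t)
        assert all(r < 0.02 for r in model.rates.values())

    def test_recovers_planted_rate(self):
        rng = np.random.default_rng(2)
        t = self._simulate(rng, 200, d=0.2)
        model = estimate_dropout(t)
        assert abs(model.rates["L1"] - 0.2) < 0.05
        assert model.rates["L2"] < 0.05

    def test_correction_invariants(self):
        rng = np.random.default_rng(3)
        t = self._simulate(rng, 100, d=0.25)
        model = estimate_dropout(t)
        fixed = correct_genotypes(t, model, seed=0)
        assert fixed.missing_mask().sum() <= t.missing_mask().sum()
        for i in range(t.n_individuals):
            for j in range(t.n_loci):
                before = t.call_labels(i, j)
                after = fixed.call_labels(i, j)
                if before is not None and before[0] != before[1]:
                    assert after == before  # heterozygotes never touched
                if before is not None and before[0] == before[1]:
                    assert after is not None and before[0] in after

    def test_study_rates_pattern(self, study):
        """Elevated-dropout loci recovered above the background loci."""
        model = estimate_dropout(study.raw)
        truth = study.dropout_rates
        high = [l for l, d in truth.items() if d >= 0.15]
        low = [l for l, d in truth.items() if d < 0.05]
        est_high = np.mean([model.rates[l] for l in high])
        est_low = np.mean([model.rates[l] for l in low])
        assert est_high > est_low + 0.05
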