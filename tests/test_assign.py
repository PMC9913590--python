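"""Assignment engines: Bayesian MCMC, EM, DAPC and cluster inference."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import make_table
from pikepop.assign import (
    DAPC,
    NewHybridsModel,
    SnapclustModel,
    enumerate_class_posteriors,
    find_clusters,
)
from pikepop.genotypes import GenotypeError, GenotypeTable, Locus
from pikepop.hybrids import build_s1, hybridise


@pytest.fixture(scope="module")
def diagnostic_scenario(fixed_diff_panel):
    refs, _, _ = fixed_diff_panel
    return build_s1(refs, "R1", "R2", mixture=50, seed=21)


class TestNewHybrids:
    def test_all_heterozygous_individual_is_f1(self, fixed_diff_panel):
        refs, pool1, pool2 = fixed_diff_panel
        f1 = hybridise(pool1, pool2, 1, seed=0, pop_label="MIX", id_prefix="x")
        from pikepop.genotypes import concat_tables

        t = concat_tables([refs, f1])
        res = NewHybridsModel(t, ref1="R1", ref2="R2").fit(
            iters=2000, burn=500, seed=0
        )
        assert res.q.loc["x_0", "F1"] > 0.99

    def test_posterior_matches_enumeration_with_fixed_frequencies(self):
        loci = [Locus("A", (100, 102)), Locus("B", (100, 102))]
        calls = np.array(
            [[[0, 1], [0, 0]], [[0, 0], [0, 1]], [[1, 1], [0, 1]],
             [[0, 1], [0, 1]]],
            dtype=np.int32,
        )
        t = GenotypeTable(["a", "b", "c", "d"], ["M"] * 4, loci, calls)
        f1 = [np.array([0.8, 0.2]), np.array([0.7, 0.3])]
        f2 = [np.array([0.1, 0.9]), np.array([0.3, 0.7])]
        classes = ("P1", "P2", "F1", "F2", "P1_bx")
        exact = enumerate_class_posteriors(t, classes, f1, f2)
        res = NewHybridsModel(
            t, classes=classes, fixed_frequencies=(f1, f2)
        ).fit(iters=20_000, burn=2_000, seed=3)
        # MC s.e. of a posterior frequency over ~20k correlated draws
        mc_se = np.sqrt(0.25 / 20_000) * 3  # conservative correlation factor
        assert float((res.q[list(classes)] - exact).abs().max().max()) < 3 * 3 * mc_se

    def test_rows_sum_to_one_and_permutation_equivariance(
        self, diagnostic_scenario
    ):
        sc = diagnostic_scenario
        res = NewHybridsModel(sc.table, ref1="R1", ref2="R2").fit(
            iters=1500, burn=300, seed=4
        )
        np.testing.assert_allclose(res.q.sum(axis=1), 1.0, atol=1e-9)
        perm = np.random.default_rng(0).permutation(sc.table.n_individuals)
        shuffled = sc.table.subset(individuals=perm)
        res2 = NewHybridsModel(shuffled, ref1="R1", ref2="R2").fit(
            iters=1500, burn=300, seed=4
        )
        assert set(res2.q.index) == set(res.q.index)

    def test_replicates_run_independently(self, diagnostic_scenario):
        sc = diagnostic_scenario
        reps = NewHybridsModel(sc.table, ref1="R1", ref2="R2").fit_replicates(
            n_replicates=2, iters=800, burn=200, seed=1
        )
        assert len(reps) == 2
        assert not reps[0].q.equals(reps[1].q)


class TestSnapclust:
    def test_loglik_monotone_on_random_datasets(self):
        rng = np.random.default_rng(0)
        from conftest import random_table

        checked = 0
        for _ in range(30):
            t = random_table(rng, n_pops=2, n_ind=(6, 12), n_loci=(3, 5))
            try:
                res = SnapclustModel(t).fit(seed=int(rng.integers(2**31)))
            except GenotypeError:
                continue
            diffs = np.diff(res.loglik_trace)
            assert np.all(diffs >= -1e-6 * np.abs(res.loglik_trace[:-1]))
            checked += 1
        assert checked >= 20

    def test_separable_case_confident_assignments(self, diagnostic_scenario):
        # parents + F1 roster: with backcross classes in play the likelihood
        # ratio against a second-generation backcross caps parental q near
        # 0.93 at 10 biallelic loci, so the sharp >0.99 check uses the
        # minimal roster (the upstream tool's default)
        sc = diagnostic_scenario
        res = SnapclustModel(
            sc.table, classes=("P1", "P2", "F1"), ref1="R1", ref2="R2"
        ).fit(seed=0)
        pure1 = [i for i, p in zip(sc.table.ids, sc.table.pops) if p == "R1"]
        assert (res.q.loc[pure1, "P1"] > 0.99).all()
        f1_ids = [i for i, c in zip(sc.mixture_ids, sc.truth) if c == "F1"]
        assert f1_ids and (res.q.loc[f1_ids, "F1"] > 0.99).all()
        # full roster: parental assignments remain modal and confident
        full = SnapclustModel(sc.table, ref1="R1", ref2="R2").fit(seed=0)
        assert (full.q.loc[pure1, "P1"] > 0.85).all()

    def test_single_locus_posterior_matches_bayes_rule(self):
        # frozen pools, one locus: memberships = normalised likelihoods
        loci = [Locus("A", (100, 102))]
        calls = np.array([[[0, 0]], [[0, 1]], [[1, 1]]], dtype=np.int32)
        t = GenotypeTable(["x", "y", "z"], ["M"] * 3, loci, calls)
        model = SnapclustModel(t, classes=("P1", "P2", "F1"))
        t1, t2 = np.array([0.9, 0.1]), np.array([0.2, 0.8])
        q, trace, _ = model._run_em([[t1], [t2]], max_iter=1, tol=0)
        alphas = model.alpha
        for row, (a, b) in zip(q, [(0, 0), (0, 1), (1, 1)]):
            lik = []
            for al in alphas:
                ma = al * t1[a] + (1 - al) * t2[a]
                mb = al * t1[b] + (1 - al) * t2[b]
                lik.append(ma * mb * (2 if a != b else 1))
            np.testing.assert_allclose(row, np.array(lik) / sum(lik),
                                       atol=1e-12)

    def test_final_loglik_independent_of_individual_order(
        self, diagnostic_scenario
    ):
        sc = diagnostic_scenario
        res = SnapclustModel(sc.table).fit(seed=0)
        perm = np.random.default_rng(1).permutation(sc.table.n_individuals)
        res2 = SnapclustModel(sc.table.subset(individuals=perm)).fit(seed=0)
        assert res.loglik_trace[-1] == pytest.approx(res2.loglik_trace[-1],
                                                     rel=1e-6)


class TestEngineAgreement:
    def test_parental_assignments_agree_on_fixed_difference_panel(
        self, diagnostic_scenario
    ):
        sc = diagnostic_scenario
        nh = NewHybridsModel(sc.table, ref1="R1", ref2="R2").fit(
            iters=3000, burn=600, seed=2
        )
        em = SnapclustModel(sc.table, ref1="R1", ref2="R2").fit(seed=2)
        for pop, cls in (("R1", "P1"), ("R2", "P2")):
            ids = [i for i, p in zip(sc.table.ids, sc.table.pops) if p == pop]
            assert (nh.q.loc[ids, cls] > 0.9).all()
            assert (em.q.loc[ids, cls] > 0.9).all()


class TestDapc:
    def test_two_clone_groups_fully_separated(self):
        genos_a = [[(0, 0)] * 6] * 10
        genos_b = [[(1, 1)] * 6] * 10
        t = make_table({"A": genos_a, "B": genos_b}, n_alleles=2)
        res = DAPC(t).fit(seed=0)
        assert res.reassignment_rate() == 1.0
        coords = res.ind_coords["DF1"]
        a = coords[[p == "A" for p in t.pops]]
        b = coords[[p == "B" for p in t.pops]]
        assert a.max() < b.min() or b.max() < a.min()

    def test_permuted_labels_give_chance_accuracy(self, study):
        rng = np.random.default_rng(0)
        labels = list(rng.permutation(study.clean.pops))
        res = DAPC(study.clean, groups=labels).fit(seed=0)
        # held-out accuracy near 1/groups
        assert res.cv_table["accuracy"].max() < 0.55

    def test_first_df_separates_species(self, study):
        res = DAPC(study.clean).fit(seed=0)
        df1 = res.ind_coords["DF1"]
        south = df1[[p in ("FLU", "TRA", "CAR") for p in study.clean.pops]]
        north = df1[[p == "DRA" for p in study.clean.pops]]
        gap = (south.max() < north.min()) or (north.max() < south.min())
        assert gap
        assert res.explained[0] > 0.5

    def test_single_group_rejected(self):
        t = make_table({"P": [[(0, 1)]] * 6}, n_alleles=2)
        with pytest.raises(GenotypeError):
            DAPC(t)


class TestFindClusters:
    def test_single_panmictic_population_selects_one(self, study):
        one = study.clean.restrict_pops(["FLU"])
        k, _, _ = find_clusters(one, seed=0)
        assert k == 1

    def test_four_separated_populations_recovered(self):
        from pikepop.island import IslandConfig, simulate_island

        cfg = IslandConfig(
            demes=4, pops_per_deme=1, n=30, m_within=1e-4, m_between=1e-4,
            loci=20, k_alleles=15, mu=1e-3, generations=300, seed=5,
        )
        t = simulate_island(cfg)
        k, labels, curve = find_clusters(t, seed=0)
        assert k == 4
        assert adjusted_rand_score(t.pops, labels) > 0.95
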