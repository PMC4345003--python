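import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiqtl.refine import (
    compare_models,
    distance_distribution_test,
    group_redundant,
    stepwise_aic,
)

from conftest import make_genotypes, random_dosages


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["probe_id", "snp_a", "snp_b", "beta3"])


def ld_cohort(rng, n=200):
    """6 SNPs: s0,s1,s2 in near-perfect LD; s3 independent; s4 shared trans; s5 independent."""
    base = random_dosages(rng, n, 0.45)
    cols = []
    for _ in range(3):
        c = base.copy()
        flip = rng.random(n) < 0.02
        c[flip] = random_dosages(rng, int(flip.sum()), 0.45)
        cols.append(c)
    cols += [random_dosages(rng, n, 0.45) for _ in range(3)]
    return make_genotypes(np.column_stack(cols))


class TestGrouping:
    def test_ld_cluster_sharing_partner_collapses_to_one_group(self, rng):
        gm = ld_cohort(rng)
        hits = hits_frame([
            ("p", "s0", "s4", 1.0), ("p", "s1", "s4", 0.8), ("p", "s2", "s4", 0.9),
        ])
        grouped = group_redundant(hits, gm, 0.5)
        assert grouped["group_id"].nunique() == 1

    def test_opposite_signs_split_groups(self, rng):
        gm = ld_cohort(rng)
        hits = hits_frame([("p", "s0", "s4", 1.0), ("p", "s1", "s4", -0.8)])
        grouped = group_redundant(hits, gm, 0.5)
        assert grouped["group_id"].nunique() == 2

    def test_independent_pairs_stay_singletons(self, rng):
        gm = ld_cohort(rng)
        hits = hits_frame([("p", "s0", "s4", 1.0), ("p", "s3", "s5", 1.0)])
        grouped = group_redundant(hits, gm, 0.5)
        assert grouped["group_id"].nunique() == 2

    def test_grouping_is_a_partition(self, rng):
        gm = ld_cohort(rng)
        hits = hits_frame([
            ("p", "s0", "s4", 1.0), ("p", "s1", "s4", 1.0),
            ("p", "s3", "s5", -1.0), ("q", "s0", "s4", 1.0),
        ])
        grouped = group_redundant(hits, gm, 0.5)
        assert len(grouped) == len(hits)
        assert grouped["group_id"].notna().all()
        # different probes never share a group
        probes_per_group = grouped.groupby("group_id")["probe_id"].nunique()
        assert (probes_per_group == 1).all()


class TestStepwiseAic:
    def build_terms(self, rng, n=500):
        mains = {f"g{k}": random_dosages(rng, n, 0.45) for k in range(4)}
        interactions = {
            "g0:g1": ("g0", "g1"), "g2:g3": ("g2", "g3"), "g0:g2": ("g0", "g2"),
        }
        return mains, interactions

    def test_strong_planted_interaction_retained(self):
        kept_count = 0
        for seed in range(10):
            rng = np.random.default_rng(6000 + seed)
            mains, interactions = self.build_terms(rng)
            y = (
                0.5 * mains["g0"] + 0.5 * mains["g1"]
                + 0.8 * mains["g0"] * mains["g1"] + rng.normal(size=500)
            )
            ranks = stats.rankdata(y)
            kept = stepwise_aic(ranks, mains, interactions)
            kept_count += "g0:g1" in kept
        assert kept_count >= 9

    def test_noise_rarely_retains_interactions(self):
        retained = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(7000 + seed)
            mains = {f"g{k}": random_dosages(rng, 300, 0.45) for k in range(2)}
            interactions = {"g0:g1": ("g0", "g1")}
            kept = stepwise_aic(stats.rankdata(rng.normal(size=300)), mains,
                                interactions)
            retained += "g0:g1" in kept
        # AIC keeps a 1-df noise term when its LRT exceeds 2 (~16% of draws)
        assert retained / n_seeds < 0.35

    def test_duplicated_interaction_keeps_exactly_one_alias(self, rng):
        mains = {"g0": random_dosages(rng, 300, 0.45),
                 "g1": random_dosages(rng, 300, 0.45)}
        interactions = {"int_a": ("g0", "g1"), "int_b": ("g0", "g1")}
        y = 0.4 * mains["g0"] + 0.4 * mains["g1"] \
            + 0.8 * mains["g0"] * mains["g1"] + rng.normal(size=300)
        kept = stepwise_aic(stats.rankdata(y), mains, interactions)
        assert sum(name in kept for name in ("int_a", "int_b")) == 1

    def test_never_worse_than_full_model(self, rng):
        from epiqtl.refine import _aic
        from epiqtl.regression import design_with_intercept, ols_fit

        mains, interactions = self.build_terms(rng, n=200)
        y = stats.rankdata(rng.normal(size=200))
        kept = stepwise_aic(y, mains, interactions)
        vectors = dict(mains)
        for name, (a, b) in interactions.items():
            vectors[name] = mains[a] * mains[b]

        def aic_of(terms):
            X = design_with_intercept(*[vectors[t] for t in terms]) \
                if terms else np.ones((200, 1))
            fit = ols_fit(y, X)
            return _aic(fit.rss, 200, X.shape[1])

        assert aic_of(kept) <= aic_of(list(vectors)) + 1e-9

    def test_hierarchy_rule_enforced(self, rng):
        mains = {"g0": random_dosages(rng, 300, 0.45),
                 "g1": random_dosages(rng, 300, 0.45)}
        interactions = {"g0:g1": ("g0", "g1")}
        # response driven purely by the product
        y = 1.5 * mains["g0"] * mains["g1"] + rng.normal(size=300)
        kept = stepwise_aic(stats.rankdata(y), mains, interactions, hierarchy=True)
        if "g0:g1" in kept:
            assert {"g0", "g1"} <= set(kept)


class TestModelComparison:
    def test_aliased_interaction_gives_null_lrt(self, rng):
        # no individual carries both minor alleles: the product term is
        # identically zero, so the nested models coincide
        a = np.array([1.0] * 50 + [0.0] * 100)
        b = np.array([0.0] * 50 + [1.0] * 50 + [0.0] * 50)
        y = stats.rankdata(0.5 * a + rng.normal(size=150))
        cmp_ = compare_models(y, a, b)
        assert cmp_.lrt_stat == 0.0
        assert cmp_.lrt_p == 1.0

    def test_planted_partial_r2_recovered(self):
        from epiqtl.simulate import beta3_for_partial_r2

        shares = []
        for seed in range(10):
            rng = np.random.default_rng(8000 + seed)
            a = random_dosages(rng, 500, 0.45)
            b = random_dosages(rng, 500, 0.45)
            beta3 = beta3_for_partial_r2(a, b, 1.0, 0.05)
            y = 0.5 * a + 0.5 * b + beta3 * a * b + rng.normal(size=500)
            # raw-scale comparison: the planted partial R^2 is defined on
            # the raw response (ranking attenuates the share roughly 2x)
            cmp_ = compare_models(y, a, b)
            shares.append(cmp_.interaction_variance_share)
        assert np.mean(shares) == pytest.approx(0.05, abs=0.02)

    def test_agrees_with_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        a = random_dosages(rng, 150, 0.45)
        b = random_dosages(rng, 150, 0.45)
        y = stats.rankdata(0.4 * a + 0.3 * b + 0.5 * a * b + rng.normal(size=150))
        cmp_ = compare_models(y, a, b)
        X_main = sm.add_constant(np.column_stack([a, b]))
        X_full = sm.add_constant(np.column_stack([a, b, a * b]))
        fit_main = sm.OLS(y, X_main).fit()
        fit_full = sm.OLS(y, X_full).fit()
        assert cmp_.adj_r2_main == pytest.approx(fit_main.rsquared_adj, abs=1e-8)
        assert cmp_.adj_r2_full == pytest.approx(fit_full.rsquared_adj, abs=1e-8)
        expected_lrt = 150 * np.log(fit_main.ssr / fit_full.ssr)
        assert cmp_.lrt_stat == pytest.approx(expected_lrt, abs=1e-8)

    def test_noiseless_limit_has_unit_adjusted_r2(self, rng):
        a = random_dosages(rng, 100, 0.45)
        b = random_dosages(rng, 100, 0.45)
        y = 1.0 * a + 2.0 * b + 3.0 * a * b
        cmp_ = compare_models(y, a, b)
        assert cmp_.adj_r2_full == pytest.approx(1.0)
        assert cmp_.adj_r2_full <= 1.0 + 1e-12


class TestDistanceDistribution:
    def test_identical_sets_are_indistinguishable(self, rng):
        d = rng.uniform(1e5, 1e7, 300)
        stat, p = distance_distribution_test(d, d)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_shortest_decile_detected(self, rng):
        tested = np.sort(rng.uniform(1e5, 1e7, 2000))
        significant = tested[:200]
        _, p = distance_distribution_test(significant, tested)
        assert p < 1e-4

    def test_null_subsampling_not_systematically_significant(self):
        small = 0
        for seed in range(20):
            rng = np.random.default_rng(9000 + seed)
            tested = rng.uniform(1e5, 1e7, 1000)
            significant = rng.choice(tested, 100, replace=False)
            _, p = distance_distribution_test(significant, tested)
            small += p < 0.05
        assert small <= 4

    def test_empty_set_rejected(self, rng):
        with pytest.raises(ValueError):
            distance_distribution_test(np.array([]), rng.uniform(0, 1, 10))
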