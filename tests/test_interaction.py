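import numpy as np
import pandas as pd
import pytest

from epiqtl.config import PipelineConfig
from epiqtl.datatypes import ExpressionMatrix
from epiqtl.interaction import (
    bonferroni_threshold,
    cell_count_filter,
    enumerate_pairs_cis_cis,
    enumerate_pairs_cis_trans,
    interaction_test,
    ld_r2,
    scan_interactions,
)
from epiqtl.regression import RankDeficientError

from conftest import make_genotypes, random_dosages

NA = np.nan


def table_to_columns(table):
    """Expand a 3x3 genotype-count table into two dosage vectors."""
    a, b = [], []
    for i in range(3):
        for j in range(3):
            a.extend([float(i)] * int(table[i][j]))
            b.extend([float(j)] * int(table[i][j]))
    return np.array(a), np.array(b)


def counting_r2(table):
    """Direct haplotype-count r^2 for phase-unambiguous tables (no double het)."""
    hap = np.zeros((2, 2))
    for i in range(3):
        for j in range(3):
            nij = table[i][j]
            if i == 1 and j == 1:
                if nij:
                    raise ValueError("ambiguous table")
                continue
            if i == 1:
                hap[0, j // 2] += nij
                hap[1, j // 2] += nij
            elif j == 1:
                hap[i // 2, 0] += nij
                hap[i // 2, 1] += nij
            else:
                hap[i // 2, j // 2] += 2 * nij
    f = hap / hap.sum()
    pa, pb = f[1].sum(), f[:, 1].sum()
    d = f[1, 1] - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


class TestLdR2:
    def test_duplicated_column_is_perfect_ld(self, rng):
        g = random_dosages(rng, 200, 0.3)
        assert ld_r2(g, g) == pytest.approx(1.0, abs=1e-6)

    def test_symmetric(self, rng):
        a = random_dosages(rng, 300, 0.3)
        b = random_dosages(rng, 300, 0.4)
        assert abs(ld_r2(a, b) - ld_r2(b, a)) < 1e-12

    def test_independent_snps_have_low_r2(self):
        low = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(2000 + seed)
            a = random_dosages(rng, 500, 0.3)
            b = random_dosages(rng, 500, 0.3)
            low += ld_r2(a, b) < 0.05
        assert low / n_seeds >= 0.99

    def test_em_matches_counting_oracle_on_unambiguous_tables(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 200:
            table = rng.integers(0, 8, size=(3, 3))
            table[1, 1] = 0
            a, b = table_to_columns(table)
            if a.size < 20 or a.std() == 0 or b.std() == 0:
                continue
            expected = counting_r2(table)
            assert ld_r2(a, b) == pytest.approx(expected, abs=1e-8)
            checked += 1

    def test_monomorphic_margin_returns_zero_with_warning(self, rng):
        a = random_dosages(rng, 100, 0.3)
        with pytest.warns(UserWarning, match="monomorphic"):
            assert ld_r2(a, np.zeros(100)) == 0.0

    def test_too_few_complete_individuals_rejected(self, rng):
        a = random_dosages(rng, 10, 0.3)
        with pytest.raises(ValueError, match="complete"):
            ld_r2(a, a)

    def test_composite_estimator_available(self, rng):
        a = random_dosages(rng, 300, 0.4)
        comp = ld_r2(a, a, estimator="composite")
        assert comp == pytest.approx(1.0)


class TestPairEnumeration:
    def build(self, rng):
        # 6 SNPs: s0..s2 on chr1, s3..s5 on chr2; s2 duplicates s0 (r2=1)
        cols = [random_dosages(rng, 200, 0.4) for _ in range(6)]
        cols[2] = cols[0].copy()
        return make_genotypes(
            np.column_stack(cols),
            chrom=["1", "1", "1", "2", "2", "2"],
            positions=[1_000_000, 2_500_000, 1_050_000,
                       1_000_000, 1_200_000, 9_000_000],
        )

    def gated(self, rows):
        return pd.DataFrame(rows, columns=["probe_id", "snp_id", "eqtl_class"])

    def test_product_count_for_cis_trans(self, rng):
        gm = self.build(rng)
        gated = self.gated([
            ("p", "s0", "cis"), ("p", "s1", "cis"),
            ("p", "s3", "trans"), ("p", "s4", "trans"), ("p", "s5", "trans"),
        ])
        pairs = enumerate_pairs_cis_trans(gated, gm, PipelineConfig())
        assert len(pairs) == 6  # 2 cis x 3 trans, all inter-chromosomal

    def test_intra_chromosomal_pair_in_ld_excluded(self, rng):
        gm = self.build(rng)
        gated = self.gated([("p", "s0", "cis"), ("p", "s2", "trans")])
        pairs = enumerate_pairs_cis_trans(gated, gm, PipelineConfig())
        assert pairs.empty  # r2 = 1 >= 0.01

    def test_inter_chromosomal_pair_exempt_from_ld_filter(self, rng):
        gm = self.build(rng)
        # s3 duplicates nothing but make it perfectly correlated with s0
        values = gm.values.copy()
        values[:, 3] = values[:, 0]
        gm2 = make_genotypes(values, chrom=[s.chromosome for s in gm.snps],
                             positions=[s.position for s in gm.snps])
        gated = self.gated([("p", "s0", "cis"), ("p", "s3", "trans")])
        pairs = enumerate_pairs_cis_trans(gated, gm2, PipelineConfig())
        assert len(pairs) == 1
        assert np.isnan(pairs["r2"].iloc[0])

    def test_snp_never_paired_with_itself(self, rng):
        gm = self.build(rng)
        gated = self.gated([("p", "s0", "cis"), ("p", "s0", "trans")])
        assert enumerate_pairs_cis_trans(gated, gm, PipelineConfig()).empty

    def test_cis_cis_distance_band(self, rng):
        cols = [random_dosages(rng, 200, 0.4) for _ in range(4)]
        gm = make_genotypes(
            np.column_stack(cols), chrom=["3"] * 4,
            positions=[1_000_000, 1_050_000, 1_100_000, 12_000_000],
        )
        cfg = PipelineConfig(strategy="cis_cis")
        gated = self.gated([("p", s, "cis") for s in ["s0", "s1", "s2", "s3"]])
        pairs = enumerate_pairs_cis_cis(gated, gm, cfg)
        got = {tuple(sorted(t)) for t in zip(pairs["snp_a"], pairs["snp_b"])}
        # s0-s1 (50 kb) too close; s0-s3 (11 Mb) too far; s2-s0 exactly 100 kb kept
        assert ("s0", "s1") not in got
        assert ("s0", "s3") not in got
        assert ("s0", "s2") in got

    def test_cis_cis_unordered_pair_count(self, rng):
        # large n keeps sampling r2 (~1/n) far below the 0.01 LD gate
        cols = [random_dosages(rng, 2000, 0.4) for _ in range(4)]
        gm = make_genotypes(
            np.column_stack(cols), chrom=["3"] * 4,
            positions=[1_000_000, 1_200_000, 1_400_000, 1_600_000],
        )
        cfg = PipelineConfig(strategy="cis_cis")
        gated = self.gated([("p", s, "cis") for s in ["s0", "s1", "s2", "s3"]])
        pairs = enumerate_pairs_cis_cis(gated, gm, cfg)
        assert len(pairs) == 6  # C(4,2), all mutually eligible


class TestCellCountFilter:
    def test_pass_and_fail_boundaries(self):
        table = np.full((3, 3), 10)
        a, b = (np.repeat(np.arange(3.0), 30), np.tile(np.repeat(np.arange(3.0), 10), 3))
        assert cell_count_filter(a, b, 10) == (10, True)
        # remove one individual from one cell -> 9 -> fail
        assert cell_count_filter(a[1:], b[1:], 10) == (9, False)

    def test_strong_ld_depletes_double_minor_cell(self):
        failed = 0
        for seed in range(10):
            rng = np.random.default_rng(3000 + seed)
            a = random_dosages(rng, 300, 0.4)
            # copy with light mutation: r2 well above 0.5
            b = a.copy()
            flip = rng.random(300) < 0.05
            b[flip] = random_dosages(rng, int(flip.sum()), 0.4)
            assert ld_r2(a, b) > 0.5
            failed += not cell_count_filter(a, b, 10)[1]
        assert failed >= 8


class TestInteractionTest:
    def test_product_coding_values(self):
        for ga, gb, expected in [(2, 2, 4), (1, 2, 2), (0, 2, 0), (0, 0, 0), (1, 1, 1)]:
            assert ga * gb == expected  # coding used by the model term

    def test_pure_main_effects_give_zero_interaction(self, rng):
        from epiqtl.regression import design_with_intercept, ols_fit

        a = random_dosages(rng, 400, 0.4)
        b = random_dosages(rng, 400, 0.4)
        # noiseless additive response: the fitted product coefficient is 0
        y = 3.0 * a + 2.0 * b
        fit = ols_fit(y, design_with_intercept(a, b, a * b))
        assert abs(fit.beta[-1]) < 1e-8

    def test_invariant_to_monotone_transform_of_expression(self, rng):
        a = random_dosages(rng, 300, 0.4)
        b = random_dosages(rng, 300, 0.4)
        y = 0.5 * a + 0.4 * b + 0.3 * a * b + rng.normal(size=300)
        base = interaction_test(a, b, y)
        for transform in (np.exp, lambda v: v**3, lambda v: np.arctan(v) * 5):
            res = interaction_test(a, b, transform(y))
            assert res["p"] == base["p"]
            assert res["beta3"] == base["beta3"]

    def test_planted_interaction_detected(self):
        # a raw-scale partial R^2 of 0.05 is attenuated by the rank
        # transform (~2x) but still clears the per-run Bonferroni level
        # of a pair search with tens of fitted tests
        from epiqtl.simulate import beta3_for_partial_r2

        pvals = []
        for seed in range(20):
            rng = np.random.default_rng(4000 + seed)
            a = random_dosages(rng, 500, 0.45)
            b = random_dosages(rng, 500, 0.45)
            beta3 = beta3_for_partial_r2(a, b, 1.0, 0.05)
            y = 0.5 * a + 0.5 * b + beta3 * a * b + rng.normal(size=500)
            pvals.append(interaction_test(a, b, y)["p"])
        assert np.median(pvals) < 2e-3
        assert max(pvals) < 0.05

    def test_aliased_design_raises(self, rng):
        a = random_dosages(rng, 100, 0.4)
        with pytest.raises(RankDeficientError):
            interaction_test(a, a * 0 + 1, rng.normal(size=100))


class TestBonferroni:
    @pytest.mark.parametrize(
        "n_tests, expected",
        [(10349, 4.83e-6), (14226, 3.51e-6), (1, 0.05)],
    )
    def test_printed_thresholds(self, n_tests, expected):
        assert bonferroni_threshold(n_tests, 0.05) == pytest.approx(expected, rel=5e-3)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 0.05)


class TestNullCalibration:
    @pytest.mark.parametrize("noise", ["gaussian", "lognormal"])
    def test_global_null_rejection_rate_near_nominal(self, noise):
        from epiqtl.calibration import null_interaction_pvalues

        p = null_interaction_pvalues(n_reps=2000, noise=noise, seed=42)
        rate = (p < 0.05).mean()
        sd = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < 3 * sd


class TestFilterOrdering:
    def test_surviving_pairs_independent_of_filter_order(self, rng):
        from itertools import permutations

        cols = [random_dosages(rng, 300, 0.45) for _ in range(5)]
        cols[1] = cols[0].copy()  # one pair in perfect LD
        gm = make_genotypes(
            np.column_stack(cols), chrom=["1"] * 5,
            positions=[1_000_000, 1_150_000, 1_300_000, 3_000_000, 9_000_000],
        )
        cfg = PipelineConfig(strategy="cis_cis")
        all_pairs = [(f"s{i}", f"s{j}") for i in range(5) for j in range(i + 1, 5)]

        def ld_ok(p):
            return ld_r2(gm.column(p[0]), gm.column(p[1])) < cfg.ld_r2_max

        def dist_ok(p):
            d = abs(gm.meta(p[0]).position - gm.meta(p[1]).position)
            return cfg.pair_min_distance <= d <= cfg.cis_window

        def cell_ok(p):
            return cell_count_filter(gm.column(p[0]), gm.column(p[1]), 5)[1]

        reference = None
        for order in permutations([ld_ok, dist_ok, cell_ok]):
            surviving = list(all_pairs)
            for f in order:
                surviving = [p for p in surviving if f(p)]
            if reference is None:
                reference = surviving
            assert surviving == reference


def test_scan_reports_all_fitted_pairs_with_shared_threshold(rng):
    cols = [random_dosages(rng, 300, 0.45) for _ in range(4)]
    gm = make_genotypes(
        np.column_stack(cols), chrom=["1", "1", "2", "2"],
        positions=[1_000_000, 5_000_000, 1_000_000, 5_000_000],
    )
    y = 0.5 * gm.values[:, 0] + rng.normal(size=300)
    em = ExpressionMatrix(y[:, None], gm.individuals, ["p"])
    candidates = pd.DataFrame(
        [("p", "s0", "s2", False, np.nan, np.nan), ("p", "s1", "s3", False, np.nan, np.nan)],
        columns=["probe_id", "snp_a", "snp_b", "same_chromosome", "distance", "r2"],
    )
    out = scan_interactions(candidates, gm, em, min_cell=5, alpha=0.05)
    assert len(out) == 2
    assert (out["bonferroni_threshold"] == 0.025).all()
    assert out["significant"].equals(out["p"] < 0.025)
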