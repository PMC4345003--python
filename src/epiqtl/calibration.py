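"""Simulation studies of the scan's statistical behaviour.

These routines are the package's own calibration experiments: type-I
error of the rank-transform interaction test under normal and skewed
noise, end-to-end recovery of planted interactions through the full
pipeline, and the distance-shift Kolmogorov-Smirnov comparison. They
are used both by the test suite and by the results-reproduction script.
"""

from __future__ import annotations

import numpy as np

from .config import CIS_TRANS, PipelineConfig
from .interaction import interaction_test
from .pipeline import run_pipeline
from .refine import distance_distribution_test
from .simulate import (
    PlantedEffect,
    SimulationConfig,
    beta3_for_partial_r2,
    simulate_expression,
    simulate_genotypes,
)


def _draw_genotype(rng: np.random.Generator, n: int, maf: float) -> np.ndarray:
    return (rng.random(n) < maf).astype(float) + (rng.random(n) < maf)


def interaction_type1_error(
    n_reps: int = 2000,
    n: int = 500,
    maf: float = 0.3,
    beta_main: float = 0.5,
    noise: str = "gaussian",
    noise_scale: float = 1.0,
    alpha: float = 0.05,
    seed: int = 0,
    rank_response: bool = True,
) -> float:
    """Fraction of null pairs (beta3 = 0, main effects present) with p < alpha.

    Each replicate draws two independent SNPs and an expression vector
    carrying both main effects but no interaction, then fits the
    interaction model. ``rank_response=False`` fits the same model on
    the raw expression scale, for contrasting the transform's
    robustness.
    """
    from scipy import stats

    from .regression import design_with_intercept, ols_fit
    from .simulate import _draw_noise

    rng = np.random.default_rng(seed)
    n_reject = 0
    for _ in range(n_reps):
        ga = _draw_genotype(rng, n, maf)
        gb = _draw_genotype(rng, n, maf)
        y = beta_main * ga + beta_main * gb + _draw_noise(rng, noise, noise_scale, n)
        if rank_response:
            p = interaction_test(ga, gb, y)["p"]
        else:
            fit = ols_fit(y, design_with_intercept(ga, gb, ga * gb))
            p = fit.p[-1]
        if p < alpha:
            n_reject += 1
    return n_reject / n_reps


def null_interaction_pvalues(
    n_reps: int = 2000,
    n: int = 500,
    maf: float = 0.3,
    noise: str = "gaussian",
    noise_scale: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Interaction p-values under the global null (no genotype effect at all)."""
    from .simulate import _draw_noise

    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for r in range(n_reps):
        ga = _draw_genotype(rng, n, maf)
        gb = _draw_genotype(rng, n, maf)
        y = _draw_noise(rng, noise, noise_scale, n)
        out[r] = interaction_test(ga, gb, y)["p"]
    return out


def recovery_scenario_config(seed: int) -> SimulationConfig:
    """Study conditions for the end-to-end planted-pair recovery runs.

    n = 500 individuals, 60 SNPs on two chromosomes in LD blocks; the
    two causal SNPs sit on different chromosomes (an inter-chromosomal
    cis-trans pair) and are pinned to MAF 0.45 -- the common-variant
    regime the 9-cell minimum-count filter effectively restricts the
    scan to.
    """
    return SimulationConfig(
        n_individuals=500,
        n_snps=60,
        n_chromosomes=2,
        chrom_length=50_000_000,
        maf_range=(0.25, 0.5),
        ld_block_size=5,
        ld_rho=0.5,
        missing_rate=0.02,
        maf_overrides={10: 0.45, 40: 0.45},
        seed=seed,
    )


def run_planted_recovery(
    seed: int,
    target_partial_r2: float = 0.05,
    beta_main: float = 0.5,
    noise: str = "gaussian",
    noise_scale: float = 1.0,
) -> bool:
    """One end-to-end run; True when the planted pair is Bonferroni-significant.

    The planted interaction's coefficient is chosen to give the target
    partial R^2 (defaults to 0.05, inside the interaction
    variance-share range the scan is meant to detect) at the realised
    genotypes.
    """
    sim_cfg = recovery_scenario_config(seed)
    gm = simulate_genotypes(sim_cfg)
    snp_a = gm.snps[10].snp_id  # chromosome 1 -> cis to the planted probe
    snp_b = gm.snps[40].snp_id  # chromosome 2 -> trans
    beta3 = beta3_for_partial_r2(
        gm.column(snp_a), gm.column(snp_b), noise_scale, target_partial_r2
    )
    effect = PlantedEffect("probe_planted", snp_a, snp_b,
                           beta1=beta_main * noise_scale,
                           beta2=beta_main * noise_scale,
                           beta3=beta3)
    em, probes = simulate_expression(
        gm, [effect], n_probes=5, noise=noise, noise_scale=noise_scale,
        seed=seed + 1,
    )
    cfg = PipelineConfig(strategy=CIS_TRANS, iqr_top_fraction=0.4, seed=seed)
    result = run_pipeline(gm, em, probes, cfg)
    sig = result.interactions[result.interactions["significant"]]
    found = (
        (sig["probe_id"] == "probe_planted")
        & (sig["snp_a"] == snp_a)
        & (sig["snp_b"] == snp_b)
    ).any()
    return bool(found)


def planted_recovery_rate(
    n_seeds: int = 100,
    seed: int = 0,
    target_partial_r2: float = 0.05,
) -> float:
    """Fraction of seeded end-to-end runs recovering the planted pair."""
    hits = sum(
        run_planted_recovery(seed * 10_000 + k, target_partial_r2)
        for k in range(n_seeds)
    )
    return hits / n_seeds


def distance_shift_experiment(
    seed: int = 0,
    n_significant: int = 150,
    n_tested: int = 3000,
    sig_max_distance: int = 2_000_000,
    min_distance: int = 100_000,
    max_distance: int = 10_000_000,
) -> tuple[float, float]:
    """KS comparison of short significant-pair distances vs the tested background.

    Tested pair distances are uniform over the cis-cis search band
    [100 kb, 10 Mb]; the significant subset is drawn below
    ``sig_max_distance``, emulating interactions concentrated near the
    transcript.
    """
    rng = np.random.default_rng(seed)
    tested = rng.uniform(min_distance, max_distance, n_tested)
    significant = rng.uniform(min_distance, sig_max_distance, n_significant)
    return distance_distribution_test(significant, tested)
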