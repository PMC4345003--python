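"""Pairwise interaction scan.

Candidate SNP pairs come from the gated marginal hits of one probe
(cis x trans, or unordered cis x cis). Pairs on one chromosome must be
out of linkage disequilibrium (EM-estimated r-squared below
``ld_r2_max``); cis-cis pairs must additionally be at least
``pair_min_distance`` apart and within the cis window of each other.
Every pair must populate all nine two-locus genotype cells with at
least ``min_cell_count`` complete-case individuals.

The interaction model regresses expression ranks on the two additive
dosages plus their product (values 0, 1, 2 or 4 across the nine
genotype combinations) and any covariates; significance is the two-sided
t test of the product coefficient, Bonferroni-corrected across all
tests actually fitted in the run.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats

from .config import CIS_CIS, CIS_TRANS, PipelineConfig
from .datatypes import ExpressionMatrix, GenotypeMatrix
from .marginal import CIS, TRANS
from .regression import RankDeficientError, design_with_intercept, ols_fit

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "probe_id", "snp_a", "snp_b", "same_chromosome", "distance", "r2",
    "min_cell", "n_used", "beta3", "se", "t", "p", "bonferroni_threshold",
    "significant",
]


def ld_r2(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    estimator: str = "em",
    min_n: int = 20,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> float:
    """Squared LD correlation between two SNPs from unphased genotypes.

    The default estimator obtains maximum-likelihood haplotype
    frequencies by EM over the 3x3 genotype table (the double
    heterozygote is the only phase-ambiguous cell) and returns
    ``D^2 / (pA(1-pA) pB(1-pB))``. A monomorphic margin makes r2
    undefined; 0 is returned with a warning. ``estimator="composite"``
    uses the squared Pearson correlation of the dosage vectors instead.
    """
    a = np.asarray(geno_a, dtype=float)
    b = np.asarray(geno_b, dtype=float)
    mask = np.isfinite(a) & np.isfinite(b)
    n = int(mask.sum())
    if n < min_n:
        raise ValueError(f"ld_r2 needs >= {min_n} complete individuals, got {n}")
    a, b = a[mask], b[mask]

    if estimator == "composite":
        if a.std() == 0 or b.std() == 0:
            warnings.warn("monomorphic SNP: r2 undefined, returning 0")
            return 0.0
        return float(np.corrcoef(a, b)[0, 1] ** 2)
    if estimator != "em":
        raise ValueError(f"unknown LD estimator: {estimator!r}")

    table = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            table[i, j] = np.sum((a == i) & (b == j))

    pa = (table.sum(axis=1) @ np.array([0, 1, 2])) / (2 * n)
    pb = (table.sum(axis=0) @ np.array([0, 1, 2])) / (2 * n)
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        warnings.warn("monomorphic SNP: r2 undefined, returning 0")
        return 0.0

    # fixed haplotype counts from the 8 phase-unambiguous cells:
    # genotype i at A contributes alleles (0,0)/(0,1)/(1,1); pairing with
    # the B alleles is determined unless both loci are heterozygous.
    c = np.zeros((2, 2))
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            nij = table[i, j]
            if nij == 0:
                continue
            if i == 1:  # het at A, homozygous at B
                c[0, j // 2] += nij
                c[1, j // 2] += nij
            elif j == 1:  # het at B, homozygous at A
                c[i // 2, 0] += nij
                c[i // 2, 1] += nij
            else:
                c[i // 2, j // 2] += 2 * nij
    n_dh = table[1, 1]

    # EM over the double-het phase: start from linkage equilibrium
    f = np.array(
        [[(1 - pa) * (1 - pb), (1 - pa) * pb], [pa * (1 - pb), pa * pb]]
    )
    for _ in range(max_iter):
        denom = f[0, 0] * f[1, 1] + f[0, 1] * f[1, 0]
        x = 0.5 if denom == 0 else f[0, 0] * f[1, 1] / denom
        new = c.copy()
        new[0, 0] += x * n_dh
        new[1, 1] += x * n_dh
        new[0, 1] += (1 - x) * n_dh
        new[1, 0] += (1 - x) * n_dh
        new /= 2 * n
        if np.abs(new - f).max() < tol:
            f = new
            break
        f = new

    p1a = f[1, 0] + f[1, 1]
    p1b = f[0, 1] + f[1, 1]
    denom = p1a * (1 - p1a) * p1b * (1 - p1b)
    if denom <= 0:
        warnings.warn("degenerate haplotype frequencies: r2 undefined, returning 0")
        return 0.0
    d = f[1, 1] - p1a * p1b
    return float(d * d / denom)


def cell_count_filter(
    geno_a: np.ndarray, geno_b: np.ndarray, min_cell: int
) -> tuple[int, bool]:
    """Minimum count over the 9 two-locus genotype cells (complete cases)."""
    a = np.asarray(geno_a, dtype=float)
    b = np.asarray(geno_b, dtype=float)
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    counts = [
        int(np.sum((a == i) & (b == j))) for i in range(3) for j in range(3)
    ]
    smallest = min(counts) if counts else 0
    return smallest, smallest >= min_cell


def enumerate_pairs_cis_trans(
    gated_hits: pd.DataFrame, genotypes: GenotypeMatrix, cfg: PipelineConfig
) -> pd.DataFrame:
    """All (cis-eQTL, trans-eQTL) combinations per probe, LD-filtered.

    Intra-chromosomal pairs are retained only when r2 < ``ld_r2_max``;
    inter-chromosomal pairs are exempt (r2 undefined across chromosomes).
    A SNP qualifying as both cis and trans for one probe is never paired
    with itself.
    """
    rows = []
    for pid, sub in gated_hits.groupby("probe_id", sort=True):
        cis_snps = sorted(sub.loc[sub["eqtl_class"] == CIS, "snp_id"])
        trans_snps = sorted(sub.loc[sub["eqtl_class"] == TRANS, "snp_id"])
        for sa, sb in product(cis_snps, trans_snps):
            if sa == sb:
                continue
            ma, mb = genotypes.meta(sa), genotypes.meta(sb)
            same_chrom = ma.chromosome == mb.chromosome
            distance = abs(ma.position - mb.position) if same_chrom else np.nan
            r2 = np.nan
            if same_chrom:
                r2 = ld_r2(genotypes.column(sa), genotypes.column(sb))
                if not r2 < cfg.ld_r2_max:
                    continue
            rows.append((pid, sa, sb, same_chrom, distance, r2))
    return pd.DataFrame(
        rows,
        columns=["probe_id", "snp_a", "snp_b", "same_chromosome", "distance", "r2"],
    )


def enumerate_pairs_cis_cis(
    gated_hits: pd.DataFrame, genotypes: GenotypeMatrix, cfg: PipelineConfig
) -> pd.DataFrame:
    """Unordered cis-eQTL pairs per probe under the distance and LD rules.

    Both SNPs sit on the probe's chromosome; they must be within
    ``cis_window`` of each other, at least ``pair_min_distance`` apart
    (both bounds inclusive) and have r2 < ``ld_r2_max``.
    """
    rows = []
    for pid, sub in gated_hits.groupby("probe_id", sort=True):
        cis_snps = sorted(sub.loc[sub["eqtl_class"] == CIS, "snp_id"])
        for sa, sb in combinations(cis_snps, 2):
            ma, mb = genotypes.meta(sa), genotypes.meta(sb)
            if ma.chromosome != mb.chromosome:
                continue
            distance = abs(ma.position - mb.position)
            if distance > cfg.cis_window or distance < cfg.pair_min_distance:
                continue
            r2 = ld_r2(genotypes.column(sa), genotypes.column(sb))
            if not r2 < cfg.ld_r2_max:
                continue
            rows.append((pid, sa, sb, True, distance, r2))
    return pd.DataFrame(
        rows,
        columns=["probe_id", "snp_a", "snp_b", "same_chromosome", "distance", "r2"],
    )


def interaction_test(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    expression: np.ndarray,
    covariates: np.ndarray | None = None,
) -> dict:
    """Fit rank(expr) ~ gA + gB + gA*gB (+ covariates), complete-case.

    Returns the interaction coefficient (the reported effect size), its
    standard error, t and two-sided p, and the sample size used. Raises
    :class:`RankDeficientError` when the design is collinear.
    """
    a = np.asarray(geno_a, dtype=float)
    b = np.asarray(geno_b, dtype=float)
    y = np.asarray(expression, dtype=float)
    mask = np.isfinite(a) & np.isfinite(b) & np.isfinite(y)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        mask &= np.isfinite(covariates).all(axis=1)
    a, b, y = a[mask], b[mask], y[mask]
    ranks = stats.rankdata(y, method="average")
    prod = a * b
    X = (
        design_with_intercept(covariates[mask], a, b, prod)
        if covariates is not None
        else design_with_intercept(a, b, prod)
    )
    fit = ols_fit(ranks, X)
    return {
        "beta3": float(fit.beta[-1]),
        "se": float(fit.se[-1]),
        "t": float(fit.t[-1]),
        "p": float(fit.p[-1]),
        "n_used": int(mask.sum()),
    }


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / n_tests over the fitted tests."""
    if n_tests < 1:
        raise ValueError("bonferroni_threshold needs at least one test")
    return alpha / n_tests


def scan_interactions(
    candidates: pd.DataFrame,
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    covariates: np.ndarray | None = None,
    min_cell: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cell-filter, fit and Bonferroni-correct all candidate pairs.

    Returns every *fitted* pair (the non-significant ones form the
    enrichment background); the Bonferroni denominator is the number of
    tests fitted, excluding cell-filtered and rank-deficient pairs.
    """
    if genotypes.individuals != expression.individuals:
        raise ValueError("genotype and expression individuals must be aligned")
    rows = []
    n_cell_failed = n_deficient = 0
    for cand in candidates.itertuples(index=False):
        ga = genotypes.column(cand.snp_a)
        gb = genotypes.column(cand.snp_b)
        expr = expression.column(cand.probe_id)
        obs = np.isfinite(expr)
        if covariates is not None:
            obs &= np.isfinite(np.asarray(covariates, dtype=float)).all(axis=1)
        min_cell_obs, ok = cell_count_filter(
            np.where(obs, ga, np.nan), np.where(obs, gb, np.nan), min_cell
        )
        if not ok:
            n_cell_failed += 1
            continue
        try:
            res = interaction_test(ga, gb, expr, covariates)
        except RankDeficientError:
            n_deficient += 1
            logger.info("rank-deficient pair skipped: %s x %s for %s",
                        cand.snp_a, cand.snp_b, cand.probe_id)
            continue
        rows.append(
            (
                cand.probe_id, cand.snp_a, cand.snp_b, cand.same_chromosome,
                cand.distance, cand.r2, min_cell_obs, res["n_used"],
                res["beta3"], res["se"], res["t"], res["p"],
            )
        )
    logger.info(
        "interaction scan: %d fitted, %d cell-filtered, %d rank-deficient",
        len(rows), n_cell_failed, n_deficient,
    )
    out = pd.DataFrame(
        rows,
        columns=["probe_id", "snp_a", "snp_b", "same_chromosome", "distance",
                 "r2", "min_cell", "n_used", "beta3", "se", "t", "p"],
    )
    if len(out):
        thr = bonferroni_threshold(len(out), alpha)
        out["bonferroni_threshold"] = thr
        out["significant"] = out["p"] < thr
    else:
        out["bonferroni_threshold"] = np.nan
        out["significant"] = pd.Series(dtype=bool)
    return out[RESULT_COLUMNS]


def enumerate_pairs(
    gated_hits: pd.DataFrame, genotypes: GenotypeMatrix, cfg: PipelineConfig
) -> pd.DataFrame:
    if cfg.strategy == CIS_TRANS:
        return enumerate_pairs_cis_trans(gated_hits, genotypes, cfg)
    if cfg.strategy == CIS_CIS:
        return enumerate_pairs_cis_cis(gated_hits, genotypes, cfg)
    raise ValueError(f"unknown strategy {cfg.strategy!r}")
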