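"""Marginal eQTL scan with rank-transform regression.

Each (probe, SNP) test regresses the within-test ranks of expression on
the additive genotype dosage plus the population-structure covariates.
Ranking only the response confers robustness to non-normal expression
while keeping the familiar linear-model t test. Tests are labelled cis
or trans by the distance of the SNP from the probe midpoint, and the
two classes are corrected for multiple testing separately with the
Benjamini-Hochberg step-up procedure; the downstream pair search then
gates on a deliberately liberal FDR.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, GenotypeMatrix, ProbeAnnotation, SnpMeta
from .regression import RankDeficientError, design_with_intercept, ols_fit

logger = logging.getLogger(__name__)

CIS = "cis"
TRANS = "trans"

HIT_COLUMNS = ["probe_id", "snp_id", "n_used", "beta", "se", "t", "p", "q",
               "eqtl_class"]


def rank_transform(values: np.ndarray) -> np.ndarray:
    """Map non-missing values to ranks 1..m (midranks for ties); NaN stays NaN."""
    values = np.asarray(values, dtype=float)
    mask = np.isfinite(values)
    if mask.sum() < 2:
        raise ValueError("rank transform needs at least 2 non-missing values")
    out = np.full(values.shape, np.nan)
    out[mask] = stats.rankdata(values[mask], method="average")
    return out


def classify_cis_trans(snp: SnpMeta, probe: ProbeAnnotation, window: int) -> str:
    """cis iff same chromosome and |position - probe midpoint| <= window."""
    if window <= 0:
        raise ValueError("window must be positive")
    if snp.chromosome == probe.chromosome and abs(snp.position - probe.midpoint) <= window:
        return CIS
    return TRANS


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def marginal_scan(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    probes: dict[str, ProbeAnnotation],
    covariates: np.ndarray | None = None,
    window: int = 1_000_000,
    probe_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Test every (selected probe, SNP) combination; returns an EqtlHit table.

    Each test is complete-case: individuals missing that SNP, that probe
    or any covariate are dropped, and the expression ranks are computed
    within the retained subset. ``covariates`` is an individuals x k
    array aligned to the genotype individual order. BH q-values are
    assigned separately within the cis and the trans test pools.
    """
    if genotypes.individuals != expression.individuals:
        raise ValueError("genotype and expression individuals must be aligned")
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.shape[0] != genotypes.n_individuals:
            raise ValueError("covariates not aligned to individuals")
        cov_ok = np.isfinite(covariates).all(axis=1)
        n_cov = covariates.shape[1]
    else:
        cov_ok = np.ones(genotypes.n_individuals, dtype=bool)
        n_cov = 0

    probe_ids = probe_ids if probe_ids is not None else expression.probe_ids
    rows = []
    n_skipped = 0
    for pid in probe_ids:
        probe = probes.get(pid)
        if probe is None:
            logger.warning("probe %s has no annotation; skipped", pid)
            continue
        expr = expression.column(pid)
        expr_ok = np.isfinite(expr)
        for j, snp in enumerate(genotypes.snps):
            geno = genotypes.values[:, j]
            mask = expr_ok & np.isfinite(geno) & cov_ok
            n_used = int(mask.sum())
            if n_used < n_cov + 3:
                n_skipped += 1
                continue
            y = stats.rankdata(expr[mask], method="average")
            g = geno[mask]
            X = (
                design_with_intercept(covariates[mask], g)
                if covariates is not None
                else design_with_intercept(g)
            )
            try:
                fit = ols_fit(y, X)
            except RankDeficientError:
                n_skipped += 1
                continue
            rows.append(
                (
                    pid, snp.snp_id, n_used,
                    fit.beta[-1], fit.se[-1], fit.t[-1], fit.p[-1],
                    classify_cis_trans(snp, probe, window),
                )
            )
    if n_skipped:
        logger.info("marginal scan: %d test(s) skipped", n_skipped)
    hits = pd.DataFrame(
        rows, columns=["probe_id", "snp_id", "n_used", "beta", "se", "t", "p",
                       "eqtl_class"],
    )
    hits["q"] = np.nan
    for cls in (CIS, TRANS):
        idx = hits.index[hits["eqtl_class"] == cls]
        if len(idx):
            hits.loc[idx, "q"] = bh_fdr(hits.loc[idx, "p"].to_numpy())
    return hits[HIT_COLUMNS]


def gate_eqtls(hits: pd.DataFrame, fdr_threshold: float) -> pd.DataFrame:
    """Retain hits with q strictly below the FDR threshold."""
    if hits.empty:
        return hits.copy()
    return hits[hits["q"] < fdr_threshold].reset_index(drop=True)
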