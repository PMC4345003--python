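"""End-to-end pipeline orchestration.

Stage order: SNP QC on the full cohort -> PCA with iterative outlier
removal and Tracy-Widom component testing -> re-check of the SNP
filters on the outlier-free cohort -> probe selection -> rank-transform
marginal scan with the PC scores as covariates -> liberal FDR gating ->
pair enumeration under the strategy's constraints -> interaction scan
with Bonferroni correction over the fitted tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datatypes import ExpressionMatrix, GenotypeMatrix, ProbeAnnotation
from .interaction import enumerate_pairs, scan_interactions
from .marginal import gate_eqtls, marginal_scan
from .popstruct import PcaResult, run_pca_stage
from .qc import (
    ProbeSelection,
    SnpQcRecord,
    filter_snps,
    remove_blacklisted_probes,
    select_variable_transcripts,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    snp_qc: list[SnpQcRecord]
    probe_selection: list[ProbeSelection]
    pca: PcaResult
    n_pcs_used: int
    marginal_hits: pd.DataFrame
    gated_hits: pd.DataFrame
    candidates: pd.DataFrame
    interactions: pd.DataFrame
    stage_counts: dict = field(default_factory=dict)


def run_pipeline(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    probes: list[ProbeAnnotation],
    cfg: PipelineConfig,
    snp_catalogue: list[tuple[str, int]] | None = None,
) -> PipelineResult:
    """Run one tissue-strategy analysis from raw matrices to interactions."""
    counts: dict[str, int] = {
        "individuals_in": genotypes.n_individuals,
        "snps_in": genotypes.n_snps,
        "probes_in": expression.n_probes,
    }

    # SNP QC on the full cohort
    filtered, snp_qc = filter_snps(genotypes, cfg)
    counts["snps_pass_qc"] = filtered.n_snps
    if filtered.n_snps < 2:
        raise ValueError("fewer than 2 SNPs survive QC")

    # stratification: outlier removal + PCA + Tracy-Widom
    pca = run_pca_stage(filtered, alpha=cfg.alpha)
    keep = [i for i in filtered.individuals if i not in set(pca.outliers)]
    counts["outliers_removed"] = len(pca.outliers)
    counts["individuals_clean"] = len(keep)
    clean_geno = filtered.subset_individuals(keep)
    clean_expr = expression.subset_individuals(keep)
    if clean_geno.individuals != clean_expr.individuals:
        raise ValueError("genotype/expression individuals diverged after QC")

    # re-check SNP filters on the outlier-free cohort
    clean_geno, _ = filter_snps(clean_geno, cfg)
    counts["snps_pass_recheck"] = clean_geno.n_snps

    n_pcs = pca.n_significant if cfg.n_pcs == "auto" else int(cfg.n_pcs)
    n_pcs = min(n_pcs, pca.scores.shape[1])
    counts["n_pcs_used"] = n_pcs
    covariates = pca.scores[:, :n_pcs] if n_pcs > 0 else None

    # probe selection
    blacklist = remove_blacklisted_probes(probes, snp_catalogue)
    selection = select_variable_transcripts(
        clean_expr, cfg.iqr_top_fraction, blacklist
    )
    selected_ids = [s.probe_id for s in selection if s.selected]
    counts["probes_selected"] = len(selected_ids)

    probe_map = {p.probe_id: p for p in probes}
    hits = marginal_scan(
        clean_geno, clean_expr, probe_map, covariates,
        window=cfg.cis_window, probe_ids=selected_ids,
    )
    counts["marginal_tests"] = len(hits)
    gated = gate_eqtls(hits, cfg.fdr_threshold)
    counts["gated_eqtls"] = len(gated)

    candidates = enumerate_pairs(gated, clean_geno, cfg)
    counts["candidate_pairs"] = len(candidates)
    interactions = scan_interactions(
        candidates, clean_geno, clean_expr, covariates,
        min_cell=cfg.min_cell_count, alpha=cfg.alpha,
    )
    counts["interaction_tests"] = len(interactions)
    counts["significant_interactions"] = int(interactions["significant"].sum()) \
        if len(interactions) else 0
    for name, value in counts.items():
        logger.info("pipeline %s = %s", name, value)

    return PipelineResult(
        config=cfg,
        snp_qc=snp_qc,
        probe_selection=selection,
        pca=pca,
        n_pcs_used=n_pcs,
        marginal_hits=hits,
        gated_hits=gated,
        candidates=candidates,
        interactions=interactions,
        stage_counts=counts,
    )
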