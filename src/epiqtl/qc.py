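"""SNP quality control and variable-transcript selection.

SNP filters (all applied jointly):

* autosomal chromosome label;
* minor allele frequency strictly greater than ``maf_min`` (the high
  default of 0.2 keeps the two-locus genotype cells populated);
* missingness at most ``miss_max``;
* Hardy-Weinberg equilibrium chi-squared p at least ``hwe_alpha``.

Probe selection keeps the most variable transcripts by interquartile
range (IQR), a spread measure insensitive to a few extreme samples,
and can blacklist probes whose genomic footprint contains a known SNP
(polymorphism inside a probe distorts hybridisation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .datatypes import ExpressionMatrix, GenotypeMatrix, ProbeAnnotation, is_autosome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnpQcRecord:
    snp_id: str
    maf: float
    missingness: float
    hwe_chi2: float
    hwe_p: float
    autosomal: bool
    passed: bool


@dataclass(frozen=True)
class ProbeSelection:
    probe_id: str
    iqr: float
    selected: bool
    blacklist_hit: bool = False


def compute_maf(genotype_column: np.ndarray) -> float:
    """Minor allele frequency: minor-allele count / (2 x non-missing), folded to <= 0.5.

    All-missing columns return NaN (the SNP then fails QC).
    """
    col = np.asarray(genotype_column, dtype=float)
    obs = col[np.isfinite(col)]
    if obs.size == 0:
        return float("nan")
    freq = obs.sum() / (2.0 * obs.size)
    return float(min(freq, 1.0 - freq))


def compute_missingness(genotype_column: np.ndarray) -> float:
    col = np.asarray(genotype_column, dtype=float)
    if col.size == 0:
        return float("nan")
    return float(np.mean(~np.isfinite(col)))


def hwe_test(genotype_column: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared test of Hardy-Weinberg proportions (1 df).

    Expected counts are ``n*p^2, 2npq, n*q^2`` from the observed allele
    frequency; no continuity correction. Monomorphic columns carry no
    evidence of departure and return ``(0.0, 1.0)``.
    """
    col = np.asarray(genotype_column, dtype=float)
    obs = col[np.isfinite(col)]
    n = obs.size
    if n == 0:
        return float("nan"), float("nan")
    counts = np.array([(obs == g).sum() for g in (0.0, 1.0, 2.0)], dtype=float)
    q = (counts[1] + 2 * counts[2]) / (2.0 * n)  # frequency of the coded allele
    p = 1.0 - q
    if q == 0.0 or p == 0.0:
        return 0.0, 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def snp_qc_record(snp_id: str, chromosome: str, column: np.ndarray,
                  cfg: PipelineConfig) -> SnpQcRecord:
    maf = compute_maf(column)
    missingness = compute_missingness(column)
    if np.isfinite(column).sum() == 0:
        chi2, p = float("nan"), float("nan")
        passed = False
    else:
        chi2, p = hwe_test(column)
        passed = (
            maf > cfg.maf_min
            and missingness <= cfg.miss_max
            and p >= cfg.hwe_alpha
            and is_autosome(chromosome)
        )
    return SnpQcRecord(snp_id, maf, missingness, chi2, p,
                       is_autosome(chromosome), bool(passed))


def filter_snps(
    gm: GenotypeMatrix, cfg: PipelineConfig
) -> tuple[GenotypeMatrix, list[SnpQcRecord]]:
    """Apply all SNP filters; returns the retained matrix and per-SNP records."""
    records = [
        snp_qc_record(s.snp_id, s.chromosome, gm.values[:, j], cfg)
        for j, s in enumerate(gm.snps)
    ]
    keep = [r.snp_id for r in records if r.passed]
    logger.info("SNP QC: %d / %d retained", len(keep), gm.n_snps)
    return gm.subset_snps(keep), records


def remove_blacklisted_probes(
    probes: list[ProbeAnnotation],
    snp_positions: list[tuple[str, int]] | None,
) -> dict[str, bool]:
    """Flag probes whose interval contains any catalogue SNP.

    ``snp_positions`` is a variant catalogue of (chromosome, 1-based
    position); it need not be limited to genotyped SNPs. With no
    catalogue, nothing is flagged (a warning is logged).
    """
    if snp_positions is None:
        logger.warning("no SNP catalogue supplied; probe blacklist skipped")
        return {p.probe_id: False for p in probes}
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in snp_positions:
        by_chrom.setdefault(chrom, [])
        by_chrom[chrom].append(pos)
    by_chrom = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}
    flags = {}
    for p in probes:
        pos = by_chrom.get(p.chromosome)
        if pos is None:
            flags[p.probe_id] = False
            continue
        # 1-based position q is inside [start, end) iff start <= q-1 < end
        lo = np.searchsorted(pos, p.start + 1, side="left")
        hi = np.searchsorted(pos, p.end, side="right")
        flags[p.probe_id] = bool(hi > lo)
    return flags


def probe_iqr(values: np.ndarray) -> float:
    """IQR over non-missing values, linear-interpolation (type-7) quartiles."""
    obs = np.asarray(values, dtype=float)
    obs = obs[np.isfinite(obs)]
    if obs.size == 0:
        return float("nan")
    q1, q3 = np.percentile(obs, [25.0, 75.0])
    return float(q3 - q1)


def select_variable_transcripts(
    em: ExpressionMatrix,
    top_fraction: float,
    blacklist: dict[str, bool] | None = None,
) -> list[ProbeSelection]:
    """Keep the ``ceil(top_fraction * n_probes)`` probes of largest IQR.

    Blacklisted probes are excluded before ranking. Ties at the cutoff
    break by probe id lexical order.
    """
    if em.n_probes == 0:
        raise ValueError("expression matrix has no probes")
    blacklist = blacklist or {}
    eligible = [
        (pid, probe_iqr(em.values[:, j]))
        for j, pid in enumerate(em.probe_ids)
        if not blacklist.get(pid, False)
    ]
    k = math.ceil(top_fraction * len(eligible))
    ranked = sorted(eligible, key=lambda t: (-t[1], t[0]))
    chosen = {pid for pid, _ in ranked[:k]}
    out = []
    for j, pid in enumerate(em.probe_ids):
        hit = blacklist.get(pid, False)
        out.append(
            ProbeSelection(pid, probe_iqr(em.values[:, j]),
                           selected=(pid in chosen), blacklist_hit=hit)
        )
    return out
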