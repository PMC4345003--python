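"""Synthetic genotype/expression/annotation generator.

The generator produces cohorts with the statistical structure the
pipeline assumes, so every stage is testable without external data:

* biallelic autosomal SNPs at evenly spaced positions, with a
  configurable MAF spectrum and block-wise linkage disequilibrium from
  a first-order haplotype copying process (within a block each
  haplotype allele copies its left neighbour with probability
  ``ld_rho`` and is otherwise drawn fresh at the block allele
  frequency, so adjacent-SNP haplotype correlation equals ``ld_rho``);
* optional discrete population structure via the Balding-Nichols
  construction (subpopulation allele frequencies drawn from a Beta
  distribution centred on the ancestral frequency with spread set by
  ``fst``);
* expression built from planted additive and product-coded interaction
  effects on the raw scale plus configurable, optionally non-normal,
  noise -- the rank transform downstream is thereby exercised
  nontrivially;
* toy Hi-C contact tables and promoter/enhancer tracks in which causal
  SNP pairs are over-represented by a chosen fold.

All outputs are bit-reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    ExpressionMatrix,
    GenotypeMatrix,
    HiCPair,
    Interval,
    ProbeAnnotation,
    SnpMeta,
)
from .regression import design_with_intercept, ols_fit

NOISE_KINDS = ("gaussian", "lognormal", "t3")

#: standard deviation of LogNormal(0, 1), used to standardise that noise
_LOGNORMAL_SD = math.sqrt((math.e - 1.0) * math.e)


@dataclass(frozen=True)
class PlantedEffect:
    """One probe whose expression carries two main effects and an interaction.

    Effects are on the raw expression scale: ``beta1``/``beta2`` per
    minor-allele copy, ``beta3`` per unit of the genotype product.
    """

    probe_id: str
    snp_a: str
    snp_b: str
    beta1: float
    beta2: float
    beta3: float

    def __post_init__(self) -> None:
        if self.snp_a == self.snp_b:
            raise ValueError("planted effect needs two distinct SNPs")


@dataclass
class SimulationConfig:
    n_individuals: int = 500
    n_snps: int = 100
    n_chromosomes: int = 1
    chrom_length: int = 100_000_000
    maf_range: tuple[float, float] = (0.2, 0.5)
    ld_block_size: int = 5
    ld_rho: float = 0.0
    missing_rate: float = 0.0
    n_subpops: int = 1
    fst: float = 0.0
    maf_overrides: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def _balding_nichols(rng: np.random.Generator, p: float, fst: float) -> float:
    """Subpopulation frequency draw; resampled into (0.01, 0.99)."""
    if fst <= 0.0:
        return p
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    for _ in range(100):
        draw = rng.beta(a, b)
        if 0.01 < draw < 0.99:
            return float(draw)
    raise RuntimeError(
        f"could not draw a feasible subpopulation frequency for p={p}, fst={fst}"
    )


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """Generate a genotype matrix with block LD and optional structure.

    SNPs are placed at evenly spaced 1-based positions on
    ``n_chromosomes`` chromosomes. One ancestral MAF per LD block is
    drawn uniformly from ``maf_range``; ``maf_overrides`` (SNP index ->
    MAF) pins individual SNPs, which then sit outside the copying chain
    so their frequency is exact in expectation.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_individuals, cfg.n_snps

    per_chrom = [m // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(m % cfg.n_chromosomes):
        per_chrom[i] += 1
    snps: list[SnpMeta] = []
    chrom_of = np.empty(m, dtype=int)
    new_block = np.zeros(m, dtype=bool)
    j = 0
    for c, count in enumerate(per_chrom):
        spacing = cfg.chrom_length // (count + 1)
        for k in range(count):
            snps.append(
                SnpMeta(f"snp{j:04d}", str(c + 1), (k + 1) * spacing, "A", "a")
            )
            chrom_of[j] = c
            new_block[j] = (k % cfg.ld_block_size == 0)
            j += 1

    # ancestral allele frequency per SNP (shared within a block)
    p_anc = np.empty(m)
    block_p = 0.0
    for j in range(m):
        if new_block[j]:
            block_p = rng.uniform(*cfg.maf_range)
        p_anc[j] = block_p
    override = np.zeros(m, dtype=bool)
    for idx, maf in cfg.maf_overrides.items():
        if not 0.0 < maf <= 0.5:
            raise ValueError(f"maf override for SNP {idx} outside (0, 0.5]")
        p_anc[idx] = maf
        override[idx] = True

    # subpopulation frequencies (Balding-Nichols)
    subpop_of = np.arange(n) % cfg.n_subpops
    p_sub = np.empty((cfg.n_subpops, m))
    for j in range(m):
        if cfg.n_subpops == 1 or cfg.fst <= 0.0:
            p_sub[:, j] = p_anc[j]
        else:
            for s in range(cfg.n_subpops):
                p_sub[s, j] = _balding_nichols(rng, p_anc[j], cfg.fst)

    # copying is legal between adjacent SNPs of one block with equal
    # frequency (overrides break the chain so marginals stay exact)
    can_copy = np.zeros(m, dtype=bool)
    for j in range(1, m):
        can_copy[j] = (
            not new_block[j]
            and chrom_of[j] == chrom_of[j - 1]
            and not override[j]
            and not override[j - 1]
            and p_anc[j] == p_anc[j - 1]
        )

    genotype = np.zeros((n, m))
    for _hap in range(2):
        hap = np.empty((n, m))
        for j in range(m):
            p_j = p_sub[subpop_of, j]
            fresh = (rng.random(n) < p_j).astype(float)
            if can_copy[j] and cfg.ld_rho > 0.0:
                copy = rng.random(n) < cfg.ld_rho
                hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
            else:
                hap[:, j] = fresh
        genotype += hap

    if cfg.missing_rate > 0.0:
        miss = rng.random((n, m)) < cfg.missing_rate
        genotype = np.where(miss, np.nan, genotype)

    individuals = [f"ind{i:04d}" for i in range(n)]
    return GenotypeMatrix(genotype, individuals, snps)


def beta3_for_partial_r2(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    noise_scale: float,
    target_partial_r2: float,
) -> float:
    """Interaction coefficient giving the wanted partial R^2 of the product.

    The partial R^2 of the product term is ``beta3^2 v / (beta3^2 v +
    sigma^2)`` where ``v`` is the variance of the product residualised
    on (1, gA, gB); invert for beta3.
    """
    if not 0.0 < target_partial_r2 < 1.0:
        raise ValueError("target partial R^2 must be in (0, 1)")
    a = np.asarray(geno_a, dtype=float)
    b = np.asarray(geno_b, dtype=float)
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    fit = ols_fit(a * b, design_with_intercept(a, b))
    v = fit.rss / a.size
    if v <= 0:
        raise ValueError("product term is aliased to the main effects")
    return float(
        noise_scale * math.sqrt(target_partial_r2 / (1.0 - target_partial_r2) / v)
    )


def _draw_noise(rng: np.random.Generator, kind: str, scale: float, size: int) -> np.ndarray:
    if kind == "gaussian":
        return rng.normal(0.0, scale, size)
    if kind == "lognormal":
        return (rng.lognormal(0.0, 1.0, size) - math.exp(0.5)) / _LOGNORMAL_SD * scale
    if kind == "t3":
        return rng.standard_t(3, size) / math.sqrt(3.0) * scale
    raise ValueError(f"unknown noise kind {kind!r}; choose from {NOISE_KINDS}")


def simulate_expression(
    genotypes: GenotypeMatrix,
    effects: list[PlantedEffect],
    n_probes: int = 10,
    noise: str = "gaussian",
    noise_scale: float = 1.0,
    seed: int = 0,
    probe_length: int = 60,
) -> tuple[ExpressionMatrix, list[ProbeAnnotation]]:
    """Expression from planted effects plus noise; unplanted probes are noise.

    A planted probe's value is ``beta1*gA + beta2*gB + beta3*gA*gB +
    eps``; individuals missing either causal genotype receive a
    noise-only value (the scan's complete-case handling must drop
    them). Planted probes are annotated at their cis SNP's position so
    that SNP classifies as cis; null probes are spread evenly over
    chromosome 1.
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_individuals
    probe_ids: list[str] = []
    probes: list[ProbeAnnotation] = []
    columns: list[np.ndarray] = []

    for eff in effects:
        ga = genotypes.column(eff.snp_a)
        gb = genotypes.column(eff.snp_b)
        signal = eff.beta1 * ga + eff.beta2 * gb + eff.beta3 * ga * gb
        eps = _draw_noise(rng, noise, noise_scale, n)
        columns.append(np.where(np.isfinite(signal), signal + eps, eps))
        probe_ids.append(eff.probe_id)
        meta = genotypes.meta(eff.snp_a)
        half = probe_length // 2
        start = max(0, meta.position - half)
        probes.append(
            ProbeAnnotation(eff.probe_id, meta.chromosome, start, start + probe_length)
        )

    n_null = max(0, n_probes - len(effects))
    max_pos = max((s.position for s in genotypes.snps), default=1_000_000)
    for k in range(n_null):
        pid = f"null_probe{k:03d}"
        columns.append(_draw_noise(rng, noise, noise_scale, n))
        probe_ids.append(pid)
        start = 1 + (k + 1) * max_pos // (n_null + 1)
        probes.append(ProbeAnnotation(pid, "1", start, start + probe_length))

    em = ExpressionMatrix(
        np.column_stack(columns), list(genotypes.individuals), probe_ids
    )
    return em, probes


def simulate_annotations(
    genotypes: GenotypeMatrix,
    causal_pairs: list[tuple[str, str]],
    enrichment_fold: float,
    seed: int = 0,
    background_pairs: list[tuple[str, str]] | None = None,
    base_rate: float = 0.1,
    n_decoy_pairs: int = 50,
    snp_window: int = 5000,
) -> tuple[list[HiCPair], dict[str, list[Interval]]]:
    """Toy Hi-C contacts and promoter/enhancer tracks with planted enrichment.

    Each causal SNP pair receives a Hi-C fragment pair (both fragment
    starts within ``snp_window`` of their SNP) with probability
    ``enrichment_fold * base_rate``; background pairs at ``base_rate``;
    ``n_decoy_pairs`` contacts are placed uniformly. The promoter track
    covers causal-pair SNPs at the enriched rate and all other SNPs at
    the base rate; the enhancer track covers every SNP at the base rate
    (no planted enrichment).
    """
    if enrichment_fold < 1.0:
        raise ValueError("enrichment_fold must be >= 1")
    if enrichment_fold * base_rate > 1.0:
        raise ValueError("enrichment_fold x base_rate exceeds 1")
    rng = np.random.default_rng(seed)
    background_pairs = background_pairs or []

    def fragment_near(snp_id: str) -> tuple[str, int]:
        meta = genotypes.meta(snp_id)
        off = int(rng.integers(-snp_window, snp_window + 1))
        return meta.chromosome, max(1, meta.position + off)

    hic: list[HiCPair] = []
    for pairs, rate in ((causal_pairs, enrichment_fold * base_rate),
                        (background_pairs, base_rate)):
        for sa, sb in pairs:
            if rng.random() < rate:
                ca, pa = fragment_near(sa)
                cb, pb = fragment_near(sb)
                hic.append(HiCPair(ca, pa, cb, pb))
    max_pos = max(s.position for s in genotypes.snps)
    chroms = sorted({s.chromosome for s in genotypes.snps})
    for _ in range(n_decoy_pairs):
        hic.append(
            HiCPair(
                str(rng.choice(chroms)), int(rng.integers(1, max_pos)),
                str(rng.choice(chroms)), int(rng.integers(1, max_pos)),
            )
        )

    causal_snps = {s for pair in causal_pairs for s in pair}
    promoter: list[Interval] = []
    enhancer: list[Interval] = []
    for snp in genotypes.snps:
        rate = enrichment_fold * base_rate if snp.snp_id in causal_snps else base_rate
        if rng.random() < rate:
            promoter.append(
                Interval(snp.chromosome, max(0, snp.position - 201),
                         snp.position + 200, "promoter")
            )
        if rng.random() < base_rate:
            enhancer.append(
                Interval(snp.chromosome, max(0, snp.position - 201),
                         snp.position + 200, "enhancer")
            )
    return hic, {"promoter": promoter, "enhancer": enhancer}
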