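"""Core data containers for the epistatic eQTL pipeline.

Coordinate conventions used throughout the package:

* SNP positions are 1-based base-pair coordinates (MAP/VCF convention).
* Intervals (probes, regulatory tracks, Hi-C fragments) are 0-based
  half-open ``[start, end)`` (BED convention).
* A SNP at 1-based position ``p`` lies inside a BED interval ``[s, e)``
  iff ``s <= p - 1 < e``.

Genotypes are stored as counts of the minor allele (0 = major homozygote,
1 = heterozygote, 2 = minor homozygote) in a float array, with ``NaN``
marking missing calls.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

_AUTOSOME_RE = re.compile(r"^(chr)?([1-9]|1[0-9]|2[0-2])$", re.IGNORECASE)


def is_autosome(chromosome: str) -> bool:
    """True for human autosome labels ('1'..'22', optionally 'chr'-prefixed)."""
    return bool(_AUTOSOME_RE.match(str(chromosome).strip()))


@dataclass(frozen=True)
class SnpMeta:
    """Identity and genomic location of one biallelic SNP."""

    snp_id: str
    chromosome: str
    position: int  # 1-based
    major_allele: str = "A"
    minor_allele: str = "a"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"SNP {self.snp_id}: position must be >= 1, got {self.position}"
            )


@dataclass(frozen=True)
class ProbeAnnotation:
    """Genomic footprint of an expression probe (0-based half-open)."""

    probe_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"probe {self.probe_id}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def midpoint(self) -> int:
        """Floor of the interval centre; the anchor for cis/trans windows."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Interval:
    """A labelled genomic interval, 0-based half-open (BED semantics)."""

    chromosome: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"interval {self.chromosome}:{self.start}-{self.end}: start must be < end"
            )

    def contains_position(self, position_1based: int) -> bool:
        """Whether a 1-based SNP coordinate falls inside this interval."""
        return self.start <= position_1based - 1 < self.end


@dataclass(frozen=True)
class HiCPair:
    """One pair of spatially proximal loci; starts are alignment start sites."""

    chrom_a: str
    start_a: int
    chrom_b: str
    start_b: int


class GenotypeMatrix:
    """Individuals x SNPs minor-allele dosage matrix with locus metadata.

    ``values`` is float with entries in {0, 1, 2} and NaN for missing.
    """

    def __init__(self, values: np.ndarray, individuals: list[str], snps: list[SnpMeta]):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("genotype values must be 2-dimensional")
        if values.shape != (len(individuals), len(snps)):
            raise ValueError(
                f"shape {values.shape} does not match {len(individuals)} individuals "
                f"x {len(snps)} SNPs"
            )
        ids = [s.snp_id for s in snps]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate SNP id(s): {dup}")
        finite = values[np.isfinite(values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(finite[~np.isin(finite, (0.0, 1.0, 2.0))]))
            raise ValueError(f"genotype values outside {{0,1,2,NaN}}: {bad[:5]}")
        self.values = values
        self.individuals = list(individuals)
        self.snps = list(snps)
        self._index = {s.snp_id: j for j, s in enumerate(snps)}

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage vector for one SNP (copy)."""
        try:
            j = self._index[snp_id]
        except KeyError:
            raise KeyError(f"unknown SNP id: {snp_id}") from None
        return self.values[:, j].copy()

    def meta(self, snp_id: str) -> SnpMeta:
        return self.snps[self._index[snp_id]]

    def subset_individuals(self, keep: list[str]) -> "GenotypeMatrix":
        keep_set = set(keep)
        idx = [i for i, ind in enumerate(self.individuals) if ind in keep_set]
        return GenotypeMatrix(
            self.values[idx, :], [self.individuals[i] for i in idx], self.snps
        )

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        cols = [self._index[s] for s in snp_ids]
        return GenotypeMatrix(
            self.values[:, cols], self.individuals, [self.snps[c] for c in cols]
        )


class ExpressionMatrix:
    """Individuals x probes matrix of continuous (pre-adjusted) expression."""

    def __init__(self, values: np.ndarray, individuals: list[str], probe_ids: list[str]):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(individuals), len(probe_ids)):
            raise ValueError(
                f"shape {values.shape} does not match {len(individuals)} individuals "
                f"x {len(probe_ids)} probes"
            )
        if len(set(probe_ids)) != len(probe_ids):
            raise ValueError("duplicate probe ids")
        self.values = values
        self.individuals = list(individuals)
        self.probe_ids = list(probe_ids)
        self._index = {p: j for j, p in enumerate(probe_ids)}

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def column(self, probe_id: str) -> np.ndarray:
        try:
            j = self._index[probe_id]
        except KeyError:
            raise KeyError(f"unknown probe id: {probe_id}") from None
        return self.values[:, j].copy()

    def subset_individuals(self, keep: list[str]) -> "ExpressionMatrix":
        keep_set = set(keep)
        idx = [i for i, ind in enumerate(self.individuals) if ind in keep_set]
        return ExpressionMatrix(
            self.values[idx, :], [self.individuals[i] for i in idx], self.probe_ids
        )

    def subset_probes(self, probe_ids: list[str]) -> "ExpressionMatrix":
        cols = [self._index[p] for p in probe_ids]
        return ExpressionMatrix(self.values[:, cols], self.individuals, list(probe_ids))
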