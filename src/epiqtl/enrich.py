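"""Enrichment of epistatic SNPs in Hi-C contacts and regulatory tracks.

A pair of epistatic SNPs "maps" to a Hi-C contact when the two SNPs lie
one each within +/- ``window`` bp (default 5 kb, bounds inclusive) of
the two fragment alignment start sites, in either orientation. A SNP
maps to a promoter/enhancer track when its position falls inside any
interval (half-open BED convention). Enrichment of the epistatic set
over the tested background is a 2x2 Pearson chi-squared test of
independence (1 df, no continuity correction); odds ratios apply the
Haldane-Anscombe +0.5 correction only when a cell is zero, and only to
the odds ratio, never to the test statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import HiCPair, Interval, SnpMeta


@dataclass(frozen=True)
class EnrichmentResult:
    a: int  # epistatic, mapped
    b: int  # epistatic, unmapped
    c: int  # background, mapped
    d: int  # background, unmapped
    odds_ratio: float
    chi2: float
    p: float
    corrected_alpha: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.p < self.corrected_alpha


def map_pair_to_hic(
    snp_a: tuple[str, int],
    snp_b: tuple[str, int],
    hic_pairs: list[HiCPair],
    window: int = 5000,
) -> bool:
    """Whether the SNP pair lands one-each on the loci of any Hi-C contact."""
    if window <= 0:
        raise ValueError("window must be positive")
    (ca, pa), (cb, pb) = snp_a, snp_b
    for h in hic_pairs:
        near_a1 = ca == h.chrom_a and abs(pa - h.start_a) <= window
        near_b2 = cb == h.chrom_b and abs(pb - h.start_b) <= window
        near_a2 = ca == h.chrom_b and abs(pa - h.start_b) <= window
        near_b1 = cb == h.chrom_a and abs(pb - h.start_a) <= window
        if (near_a1 and near_b2) or (near_a2 and near_b1):
            return True
    return False


def map_snp_to_intervals(snp: SnpMeta, track: list[Interval]) -> bool:
    """Whether the SNP position falls inside any interval of the track."""
    return any(
        iv.chromosome == snp.chromosome and iv.contains_position(snp.position)
        for iv in track
    )


def enrichment_2x2(a: int, b: int, c: int, d: int,
                   corrected_alpha: float = float("nan")) -> EnrichmentResult:
    """Odds ratio and chi-squared independence test for a 2x2 table.

    Rows are (epistatic, background); columns are (mapped, unmapped).
    """
    if a + b < 1 or c + d < 1:
        raise ValueError("each row of the 2x2 table needs at least one count")
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    odds_ratio = (aa * dd) / (bb * cc)
    n = a + b + c + d
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * col1 * col2)
        p = float(stats.chi2.sf(chi2, df=1))
    return EnrichmentResult(a, b, c, d, float(odds_ratio), float(chi2), p,
                            corrected_alpha)


def hic_enrichment(
    significant_pairs: list[tuple[tuple[str, int], tuple[str, int]]],
    background_pairs: list[tuple[tuple[str, int], tuple[str, int]]],
    hic_pairs: list[HiCPair],
    window: int = 5000,
) -> EnrichmentResult:
    """Pair-level Hi-C mapping enrichment of significant vs tested pairs."""
    a = sum(map_pair_to_hic(x, y, hic_pairs, window) for x, y in significant_pairs)
    c = sum(map_pair_to_hic(x, y, hic_pairs, window) for x, y in background_pairs)
    return enrichment_2x2(
        a, len(significant_pairs) - a, c, len(background_pairs) - c
    )


def enrichment_sweep(
    epistatic_snps: list[SnpMeta],
    background_snps: list[SnpMeta],
    tracks: dict[str, list[Interval]],
    alpha: float = 0.05,
    n_combinations: int | None = None,
) -> pd.DataFrame:
    """One 2x2 enrichment per named track, Bonferroni-corrected.

    The correction denominator is the number of track x query-tissue
    combinations in the whole sweep; pass ``n_combinations`` when the
    sweep spans several calls (e.g. 7 tracks x 3 tissues = 21). SNP sets
    use set semantics: a SNP appearing in several interactions counts
    once, and the two sets must be disjoint.
    """
    epi_ids = {s.snp_id for s in epistatic_snps}
    bg_ids = {s.snp_id for s in background_snps}
    if epi_ids & bg_ids:
        raise ValueError(
            f"epistatic and background SNP sets overlap: {sorted(epi_ids & bg_ids)[:5]}"
        )
    epi = list({s.snp_id: s for s in epistatic_snps}.values())
    bg = list({s.snp_id: s for s in background_snps}.values())
    m = n_combinations if n_combinations is not None else len(tracks)
    corrected = alpha / m if m else alpha
    rows = []
    for name in sorted(tracks):
        track = tracks[name]
        a = sum(map_snp_to_intervals(s, track) for s in epi)
        c = sum(map_snp_to_intervals(s, track) for s in bg)
        res = enrichment_2x2(a, len(epi) - a, c, len(bg) - c, corrected)
        rows.append(
            (name, res.a, res.b, res.c, res.d, res.odds_ratio, res.chi2,
             res.p, res.corrected_alpha, res.significant)
        )
    return pd.DataFrame(
        rows,
        columns=["track", "a", "b", "c", "d", "odds_ratio", "chi2", "p",
                 "corrected_alpha", "significant"],
    )
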