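"""Readers and writers for the on-disk formats.

Genotypes travel either as a TSV (header of SNP ids, one row per
individual, values 0/1/2/NA, with a sibling ``<stem>.snps.tsv`` holding
locus metadata) or as PED/MAP allele-pair files. Expression is a TSV of
individuals x probes. Annotation tracks are BED3+; Hi-C contacts are a
four-column pair table.

Whatever the dialect, loaded genotypes always count the *minor* allele:
any column whose coded allele turns out to have observed frequency
above 0.5 is flipped (2 <-> 0) and its allele labels swapped, so that
0 = major homozygote everywhere downstream.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GenotypeMatrix,
    HiCPair,
    Interval,
    ProbeAnnotation,
    SnpMeta,
)

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"

SNP_META_COLUMNS = ["snp_id", "chromosome", "position", "major_allele", "minor_allele"]


def _meta_path_for(path: Path) -> Path:
    return path.with_suffix(".snps.tsv")


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(
    path: str | Path,
    dialect: str = "tsv",
    meta_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Load a genotype matrix, recoding to minor-allele counts.

    ``dialect="tsv"`` expects a value matrix plus a SNP-metadata sibling
    (``<stem>.snps.tsv`` unless ``meta_path`` is given). ``dialect="ped_map"``
    treats ``path`` as a PLINK-style prefix and reads ``<prefix>.ped`` /
    ``<prefix>.map``; the minor allele is the rarer observed allele.
    """
    path = Path(path)
    if dialect == "tsv":
        gm = _read_genotypes_tsv(path, Path(meta_path) if meta_path else _meta_path_for(path))
    elif dialect == "ped_map":
        gm = _read_ped_map(path)
    else:
        raise ValueError(f"unknown genotype dialect: {dialect!r}")
    return _orient_to_minor(gm)


def _read_genotypes_tsv(path: Path, meta_path: Path) -> GenotypeMatrix:
    if not path.exists():
        raise FileNotFoundError(path)
    if not meta_path.exists():
        raise FileNotFoundError(
            f"SNP metadata file not found: {meta_path} (required for TSV genotypes)"
        )
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    snp_ids = header[1:]
    dup = sorted({s for s in snp_ids if snp_ids.count(s) > 1})
    if dup:
        raise ValueError(f"duplicate SNP id(s) in {path}: {dup}")

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    individuals = df.iloc[:, 0].tolist()
    values = np.full((len(individuals), len(snp_ids)), np.nan)
    for j, snp in enumerate(snp_ids):
        col = df.iloc[:, j + 1]
        for i, raw in enumerate(col):
            if raw == MISSING_TOKEN or raw == "":
                continue
            if raw not in ("0", "1", "2"):
                raise ValueError(
                    f"{path}: malformed genotype {raw!r} at individual "
                    f"{individuals[i]!r} (row {i + 2}), SNP {snp!r}"
                )
            values[i, j] = float(raw)

    meta_df = pd.read_csv(meta_path, sep="\t", dtype=str)
    missing_cols = set(SNP_META_COLUMNS) - set(meta_df.columns)
    if missing_cols:
        raise ValueError(f"{meta_path}: missing columns {sorted(missing_cols)}")
    meta_by_id = {
        r.snp_id: SnpMeta(r.snp_id, r.chromosome, int(r.position),
                          r.major_allele, r.minor_allele)
        for r in meta_df.itertuples()
    }
    absent = [s for s in snp_ids if s not in meta_by_id]
    if absent:
        raise ValueError(f"{meta_path}: no metadata for SNP(s) {absent[:5]}")
    return GenotypeMatrix(values, individuals, [meta_by_id[s] for s in snp_ids])


def _read_ped_map(prefix: Path) -> GenotypeMatrix:
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    for p in (ped_path, map_path):
        if not p.exists():
            raise FileNotFoundError(p)

    map_df = pd.read_csv(
        map_path, sep=r"\s+", header=None, dtype=str,
        names=["chromosome", "snp_id", "cm", "position"],
    )
    ids = map_df["snp_id"].tolist()
    dup = sorted({s for s in ids if ids.count(s) > 1})
    if dup:
        raise ValueError(f"duplicate SNP id(s) in {map_path}: {dup}")
    n_snps = len(map_df)

    individuals: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}: row {lineno} has {len(fields)} fields, "
                    f"expected {6 + 2 * n_snps}"
                )
            individuals.append(fields[1])
            allele_rows.append(
                [(fields[6 + 2 * j], fields[7 + 2 * j]) for j in range(n_snps)]
            )

    values = np.full((len(individuals), n_snps), np.nan)
    snps: list[SnpMeta] = []
    for j in range(n_snps):
        pairs = [row[j] for row in allele_rows]
        observed = [a for pair in pairs for a in pair if a != "0"]
        alleles = sorted(set(observed))
        if len(alleles) > 2:
            raise ValueError(
                f"{ped_path}: SNP {ids[j]!r} has >2 alleles: {alleles}"
            )
        if not alleles:
            major, minor = "0", "0"
        elif len(alleles) == 1:
            major, minor = alleles[0], alleles[0]
        else:
            counts = {a: observed.count(a) for a in alleles}
            # rarer allele is minor; on an exact tie the lexically
            # smaller allele is taken as major
            if counts[alleles[0]] == counts[alleles[1]]:
                major, minor = alleles
            else:
                minor = min(alleles, key=lambda a: counts[a])
                major = alleles[0] if minor == alleles[1] else alleles[1]
        for i, (a1, a2) in enumerate(pairs):
            if a1 == "0" or a2 == "0":
                continue
            values[i, j] = (a1 == minor) + (a2 == minor)
        row = map_df.iloc[j]
        snps.append(SnpMeta(row.snp_id, row.chromosome, int(row.position), major, minor))
    return GenotypeMatrix(values, individuals, snps)


def _orient_to_minor(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Flip any SNP whose coded allele has observed frequency > 0.5."""
    values = gm.values.copy()
    snps = list(gm.snps)
    for j, snp in enumerate(snps):
        col = values[:, j]
        obs = col[np.isfinite(col)]
        if obs.size == 0:
            continue
        freq = obs.mean() / 2.0
        if freq > 0.5:
            values[:, j] = 2.0 - col
            snps[j] = SnpMeta(
                snp.snp_id, snp.chromosome, snp.position,
                major_allele=snp.minor_allele, minor_allele=snp.major_allele,
            )
            logger.info(
                "flipped SNP %s to minor-allele coding (coded-allele freq %.3f)",
                snp.snp_id, freq,
            )
    return GenotypeMatrix(values, gm.individuals, snps)


def write_genotypes_tsv(
    gm: GenotypeMatrix, path: str | Path, meta_path: str | Path | None = None
) -> None:
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else _meta_path_for(path)
    with open(path, "w") as fh:
        fh.write("individual_id\t" + "\t".join(gm.snp_ids) + "\n")
        for i, ind in enumerate(gm.individuals):
            row = [
                MISSING_TOKEN if not np.isfinite(v) else str(int(v))
                for v in gm.values[i]
            ]
            fh.write(ind + "\t" + "\t".join(row) + "\n")
    pd.DataFrame(
        [
            (s.snp_id, s.chromosome, s.position, s.major_allele, s.minor_allele)
            for s in gm.snps
        ],
        columns=SNP_META_COLUMNS,
    ).to_csv(meta_path, sep="\t", index=False)


def write_ped_map(gm: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for s in gm.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, ind in enumerate(gm.individuals):
            fields = [ind, ind, "0", "0", "0", "-9"]
            for j, s in enumerate(gm.snps):
                v = gm.values[i, j]
                if not np.isfinite(v):
                    fields += ["0", "0"]
                elif v == 0:
                    fields += [s.major_allele, s.major_allele]
                elif v == 1:
                    fields += [s.major_allele, s.minor_allele]
                else:
                    fields += [s.minor_allele, s.minor_allele]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str | Path, individuals: list[str]) -> ExpressionMatrix:
    """Load expression and restrict/order it to the genotyped individuals.

    Returns the matrix over the intersection, in genotype order; the
    number of expression-only individuals dropped is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    probe_ids = list(df.columns[1:])
    expr_individuals = df.iloc[:, 0].tolist()
    values = np.full((len(expr_individuals), len(probe_ids)), np.nan)
    for j, probe in enumerate(probe_ids):
        for i, raw in enumerate(df.iloc[:, j + 1]):
            if raw == MISSING_TOKEN or raw == "":
                continue
            try:
                values[i, j] = float(raw)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric expression {raw!r} at individual "
                    f"{expr_individuals[i]!r} (row {i + 2}), probe {probe!r}"
                ) from None

    geno_set = set(individuals)
    shared = [ind for ind in expr_individuals if ind in geno_set]
    if not shared:
        raise ValueError(
            f"{path}: no individuals shared with the genotype matrix"
        )
    dropped = len(expr_individuals) - len(shared)
    if dropped:
        logger.info("dropped %d expression-only individual(s)", dropped)
    row_of = {ind: i for i, ind in enumerate(expr_individuals)}
    order = [row_of[ind] for ind in individuals if ind in row_of]
    kept = [ind for ind in individuals if ind in row_of]
    return ExpressionMatrix(values[order, :], kept, probe_ids)


def write_expression_tsv(em: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual_id\t" + "\t".join(em.probe_ids) + "\n")
        for i, ind in enumerate(em.individuals):
            row = [
                MISSING_TOKEN if not np.isfinite(v) else repr(float(v))
                for v in em.values[i]
            ]
            fh.write(ind + "\t" + "\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# intervals, probes, Hi-C


def read_intervals(path: str | Path) -> list[Interval]:
    """Read a BED3+ file; coordinates are kept 0-based half-open verbatim."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: start ({start}) >= end ({end})"
                )
            label = fields[3] if len(fields) > 3 else ""
            intervals.append(Interval(chrom, start, end, label))
    return intervals


def write_intervals(intervals: list[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def read_probe_annotations(path: str | Path) -> list[ProbeAnnotation]:
    """Probe footprints as BED4 (name column = probe id)."""
    probes = []
    for iv in read_intervals(path):
        if not iv.label:
            raise ValueError(f"{path}: probe BED requires a name column")
        probes.append(ProbeAnnotation(iv.label, iv.chromosome, iv.start, iv.end))
    return probes


def write_probe_annotations(probes: list[ProbeAnnotation], path: str | Path) -> None:
    write_intervals(
        [Interval(p.chromosome, p.start, p.end, p.probe_id) for p in probes], path
    )


def read_hic_pairs(path: str | Path) -> list[HiCPair]:
    """Read a Hi-C contact table (chromA, startA, chromB, startB; TSV)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str, 2: str})
    if df.shape[1] < 4:
        raise ValueError(f"{path}: expected 4 columns (chromA startA chromB startB)")
    return [
        HiCPair(str(r.iloc[0]), int(r.iloc[1]), str(r.iloc[2]), int(r.iloc[3]))
        for _, r in df.iterrows()
    ]


def write_hic_pairs(pairs: list[HiCPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom_a\tstart_a\tchrom_b\tstart_b\n")
        for p in pairs:
            fh.write(f"{p.chrom_a}\t{p.start_a}\t{p.chrom_b}\t{p.start_b}\n")
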