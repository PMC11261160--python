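"""Readers, writers and QC filters for SNP genotype data.

Supported formats: VCF (read via cyvcf2, written as plain v4.2 text),
Genepop in its 2- and 3-digit allele dialects, and a TSV genotype table.
All readers produce a :class:`~ldne.matrix.GenotypeMatrix` of
alternate-allele counts with ``-1`` for missing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import MISSING, EmptyDataError, FilterReport, GenotypeMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, population: str = "pop1", cohort: str = "cohort1") -> GenotypeMatrix:
    """Read diploid genotypes from a VCF file.

    Only biallelic SNP records are retained; multiallelic or non-SNP records
    are skipped (the count is logged).  ``./.`` genotypes map to missing.
    Population and cohort labels are attached uniformly; callers with
    per-sample metadata overwrite ``individual_meta`` afterwards.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except OSError as exc:  # pragma: no cover - cyvcf2 raises on bad paths
        raise OSError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    chroms: list[str] = []
    pos: list[int] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        # cyvcf2 gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt = np.where(gt == 2, MISSING, np.where(gt == 3, 2, gt))
        rows.append(gt)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        pos.append(int(var.POS))
    if n_skipped:
        log.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if not rows:
        raise EmptyDataError(f"no biallelic SNP records in {path}")
    genotypes = np.stack(rows, axis=1)
    locus_meta = pd.DataFrame({"id": ids, "chrom": chroms, "pos": pos})
    individual_meta = pd.DataFrame(
        {"id": samples, "population": population, "cohort": cohort}
    )
    return GenotypeMatrix(genotypes, locus_meta, individual_meta)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as minimal VCF v4.2 text (GT field only)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in matrix.locus_meta["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(header + list(matrix.individual_meta["id"].astype(str))) + "\n")
        g = matrix.genotypes
        for j, locus in matrix.locus_meta.iterrows():
            fields = [
                str(locus["chrom"]), str(int(locus["pos"])), str(locus["id"]),
                "A", "G", ".", "PASS", ".", "GT",
            ]
            fields += [gt_str[int(v)] for v in g[:, j]]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def read_genepop(path: str | Path) -> GenotypeMatrix:
    """Read a Genepop file (2- or 3-digit allele coding).

    Allele ``01`` is taken as reference and ``02`` as alternate;
    ``0000``/``000000`` encodes missing.  ``Pop`` blocks become population
    labels ``pop1``, ``pop2``, ...  Loci with more than two alleles raise a
    format error (the container is strictly biallelic).
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError(f"{path}: not a Genepop file (too short)")
    # line 0: title; then locus names until the first "Pop"
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        # locus names may be comma-separated on one line
        locus_names.extend(s.strip() for s in lines[i].split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise ValueError(f"{path}: no 'Pop' line found")
    n_loci = len(locus_names)
    width: int | None = None
    genotype_rows: list[list[tuple[int, int]]] = []
    indiv_ids: list[str] = []
    pops: list[str] = []
    pop_idx = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise ValueError(f"{path}: individual line lacks comma: {line!r}")
        name, geno = line.split(",", 1)
        alleles = geno.split()
        if len(alleles) != n_loci:
            raise ValueError(
                f"{path}: individual {name.strip()!r} has {len(alleles)} loci, expected {n_loci}"
            )
        row: list[tuple[int, int]] = []
        for tok in alleles:
            if len(tok) not in (4, 6):
                raise ValueError(f"{path}: bad allele token {tok!r}")
            w = len(tok) // 2
            if width is None:
                width = w
            elif w != width:
                raise ValueError(f"{path}: mixed 2- and 3-digit coding")
            row.append((int(tok[:w]), int(tok[w:])))
        genotype_rows.append(row)
        indiv_ids.append(name.strip())
        pops.append(f"pop{pop_idx}")
    if not genotype_rows:
        raise EmptyDataError(f"{path}: no individuals")

    n = len(genotype_rows)
    g = np.full((n, n_loci), MISSING, dtype=np.int8)
    for j in range(n_loci):
        alleles_seen = sorted(
            {a for row in genotype_rows for a in row[j] if a != 0}
        )
        if len(alleles_seen) > 2:
            raise ValueError(f"{path}: locus {locus_names[j]} has >2 alleles")
        # alternate = the larger allele code; a monomorphic locus keeps code 0
        alt = alleles_seen[-1] if len(alleles_seen) == 2 else None
        for k, row in enumerate(genotype_rows):
            a, b = row[j]
            if a == 0 or b == 0:
                continue
            g[k, j] = (0 if alt is None else (a == alt) + (b == alt))
    locus_meta = pd.DataFrame(
        {"id": locus_names, "chrom": ["unknown"] * n_loci, "pos": np.arange(1, n_loci + 1)}
    )
    individual_meta = pd.DataFrame({"id": indiv_ids, "population": pops, "cohort": pops})
    return GenotypeMatrix(g, locus_meta, individual_meta)


def write_genepop(matrix: GenotypeMatrix, path: str | Path, title: str = "ldne export") -> None:
    """Write 2-digit Genepop; allele 01 = reference, 02 = alternate."""
    code = {0: "0101", 1: "0102", 2: "0202", MISSING: "0000"}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for name in matrix.locus_meta["id"]:
            fh.write(str(name) + "\n")
        for label, sub in matrix.split_by("population").items():
            fh.write("Pop\n")
            for k in range(sub.n_individuals):
                toks = " ".join(code[int(v)] for v in sub.genotypes[k])
                fh.write(f"{sub.individual_meta['id'].iloc[k]}, {toks}\n")


# ---------------------------------------------------------------------------
# TSV genotype table
# ---------------------------------------------------------------------------

def write_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Individuals x loci table of allele counts, 'NA' for missing."""
    cells = matrix.genotypes.astype(object)
    cells[matrix.genotypes == MISSING] = "NA"
    df = pd.DataFrame(
        cells,
        index=matrix.individual_meta["id"],
        columns=matrix.locus_meta["id"],
    )
    df.to_csv(path, sep="\t", index_label="individual")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_individuals(
    matrix: GenotypeMatrix, max_missing: float = 0.20
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop individuals with missingness strictly above ``max_missing``.

    Missingness is computed over the loci present in ``matrix`` at call
    time, i.e. after any locus-level QC already applied.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    frac = matrix.missingness_per_individual()
    keep = frac <= max_missing
    if not keep.any():
        raise EmptyDataError("all individuals exceed the missingness threshold")
    removed = [
        (str(matrix.individual_meta["id"].iloc[k]), float(frac[k]))
        for k in np.flatnonzero(~keep)
    ]
    report = FilterReport(
        individuals_removed=removed,
        individuals_before=matrix.n_individuals,
        individuals_after=int(keep.sum()),
        loci_before=matrix.n_loci,
        loci_after=matrix.n_loci,
    )
    return matrix.take_individuals(np.flatnonzero(keep)), report


def drop_loci(matrix: GenotypeMatrix, locus_ids: list[str]) -> GenotypeMatrix:
    """Remove named loci (e.g. an externally supplied outlier list)."""
    ids = matrix.locus_meta["id"]
    unknown = set(locus_ids) - set(ids)
    if unknown:
        raise KeyError(f"unknown locus ids: {sorted(unknown)[:5]}")
    keep = ~ids.isin(locus_ids).to_numpy()
    return matrix.take_loci(np.flatnonzero(keep))


def filter_loci(
    matrix: GenotypeMatrix,
    min_call_rate: float = 0.8,
    min_mac: int = 1,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Locus-level QC: call rate and minor-allele-count screening.

    Defaults (call rate >= 0.8, MAC >= 1) are this package's own QC
    defaults; every removal is recorded in the report.
    """
    call_rate = matrix.called.mean(axis=0)
    mac = matrix.minor_allele_count()
    keep = (call_rate >= min_call_rate) & (mac >= min_mac)
    if not keep.any():
        raise EmptyDataError("all loci removed by QC")
    removed = []
    for j in np.flatnonzero(~keep):
        reason = "call-rate" if call_rate[j] < min_call_rate else "minor-allele"
        removed.append((str(matrix.locus_meta["id"].iloc[j]), reason))
    report = FilterReport(
        loci_removed=removed,
        individuals_before=matrix.n_individuals,
        individuals_after=matrix.n_individuals,
        loci_before=matrix.n_loci,
        loci_after=int(keep.sum()),
    )
    return matrix.take_loci(np.flatnonzero(keep)), report
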