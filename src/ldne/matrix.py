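"""Genotype container shared by every stage of the pipeline.

Genotypes are stored as the per-individual count of the alternate allele
(0, 1, 2) in an ``int8`` array, with ``-1`` marking a missing call.  Locus
and individual metadata travel with the matrix as pandas DataFrames so that
filtering operations can never desynchronise data and annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: columns required in locus metadata
LOCUS_COLS = ("id", "chrom", "pos")
#: columns required in individual metadata ("age" is optional)
INDIV_COLS = ("id", "population", "cohort")


class EmptyDataError(ValueError):
    """Raised when a filter or reader leaves no usable data."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic SNP genotypes for one or more population samples.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_loci)`` array of alternate-allele counts;
        ``-1`` encodes a missing genotype.
    locus_meta
        One row per locus with columns ``id``, ``chrom``, ``pos`` (1-based).
    individual_meta
        One row per individual with columns ``id``, ``population``,
        ``cohort`` and optionally ``age``.
    """

    genotypes: np.ndarray
    locus_meta: pd.DataFrame
    individual_meta: pd.DataFrame

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D array")
        if not np.isin(g, (0, 1, 2, MISSING)).all():
            raise ValueError("genotypes must be 0, 1, 2 or -1 (missing)")
        self.genotypes = g.astype(np.int8, copy=False)
        self.locus_meta = pd.DataFrame(self.locus_meta).reset_index(drop=True)
        self.individual_meta = pd.DataFrame(self.individual_meta).reset_index(drop=True)
        for col in LOCUS_COLS:
            if col not in self.locus_meta.columns:
                raise ValueError(f"locus_meta lacks column {col!r}")
        for col in INDIV_COLS:
            if col not in self.individual_meta.columns:
                raise ValueError(f"individual_meta lacks column {col!r}")
        if len(self.locus_meta) != g.shape[1]:
            raise ValueError("locus_meta length != number of loci")
        if len(self.individual_meta) != g.shape[0]:
            raise ValueError("individual_meta length != number of individuals")
        if self.locus_meta["id"].duplicated().any():
            raise ValueError("duplicated locus identifiers")
        if self.individual_meta["id"].duplicated().any():
            raise ValueError("duplicated individual identifiers")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotype cells."""
        return self.genotypes != MISSING

    def missingness_per_individual(self) -> np.ndarray:
        """Fraction of missing calls per individual, in [0, 1]."""
        return 1.0 - self.called.mean(axis=1)

    # -- frequencies ----------------------------------------------------
    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus (alternate-allele count, called-allele count)."""
        called = self.called
        alt = np.where(called, self.genotypes, 0).sum(axis=0)
        tot = 2 * called.sum(axis=0)
        return alt.astype(np.int64), tot.astype(np.int64)

    def alt_freq(self) -> np.ndarray:
        """Per-locus alternate-allele frequency among called genotypes."""
        alt, tot = self.allele_counts()
        with np.errstate(invalid="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    def minor_allele_count(self) -> np.ndarray:
        """Per-locus copy number of the rarer allele."""
        alt, tot = self.allele_counts()
        return np.minimum(alt, tot - alt)

    # -- subsetting -----------------------------------------------------
    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.genotypes[index, :],
            self.locus_meta.copy(),
            self.individual_meta.iloc[index].reset_index(drop=True),
        )

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.genotypes[:, index],
            self.locus_meta.iloc[index].reset_index(drop=True),
            self.individual_meta.copy(),
        )

    def split_by(self, column: str = "population") -> dict[str, "GenotypeMatrix"]:
        """Partition individuals by a metadata column, preserving order."""
        out: dict[str, GenotypeMatrix] = {}
        for label in self.individual_meta[column].unique():
            idx = np.flatnonzero((self.individual_meta[column] == label).to_numpy())
            out[str(label)] = self.take_individuals(idx)
        return out


@dataclass
class FilterReport:
    """Record of a filtering step: who was removed and why."""

    individuals_removed: list[tuple[str, float]] = field(default_factory=list)
    loci_removed: list[tuple[str, str]] = field(default_factory=list)
    individuals_before: int = 0
    individuals_after: int = 0
    loci_before: int = 0
    loci_after: int = 0

    def __post_init__(self) -> None:
        assert self.individuals_after == self.individuals_before - len(self.individuals_removed)
        assert self.loci_after == self.loci_before - len(self.loci_removed)
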