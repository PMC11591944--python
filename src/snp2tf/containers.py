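"""In-memory containers shared across the pipeline.

Genotypes are held as an ``n_animals x n_snps`` integer matrix of minor-allele
counts (0/1/2), with ``-1`` marking a missing call.  SNP metadata travels in a
pandas DataFrame sorted by (chromosome, position), so the matrix columns are
always in genome order.  Phenotypes are plain DataFrames indexed by animal id
with one column per trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The seven milk traits analysed per animal: dry matter percentage, days of
#: milk production, fat percentage, lactose percentage, 210-day milk yield,
#: protein percentage and somatic cell count.
TRAITS = ("DM", "DPM", "FP", "LP", "MY", "PP", "SCC")

MISSING = -1

#: Columns required in the SNP metadata frame.
SNP_COLUMNS = ("snp_id", "chrom", "pos", "a1", "a2")

_NON_AUTOSOMES = {"X", "Y", "MT", "M", "W", "Z"}


def is_autosome(chrom: str) -> bool:
    """True for numeric chromosome names, with or without a ``chr`` prefix."""
    name = str(chrom)
    if name.lower().startswith("chr"):
        name = name[3:]
    return name.upper() not in _NON_AUTOSOMES and name.isdigit()


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for a cohort of animals.

    Parameters
    ----------
    animal_ids
        One id per row of ``codes``.
    snps
        DataFrame with columns ``snp_id, chrom, pos, a1, a2`` (1-based
        positions; ``a1`` is the minor/counted allele), one row per column of
        ``codes``, sorted by (chrom, pos).
    codes
        Integer matrix of minor-allele counts in {0, 1, 2}, ``-1`` = missing.
    """

    animal_ids: list[str]
    snps: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.snps = self.snps.reset_index(drop=True)
        if self.codes.shape != (len(self.animal_ids), len(self.snps)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.animal_ids)} animals x {len(self.snps)} SNPs"
            )
        missing_cols = set(SNP_COLUMNS) - set(self.snps.columns)
        if missing_cols:
            raise ValueError(f"snps frame lacks columns {sorted(missing_cols)}")
        if len(self.snps) and (self.snps["pos"] < 1).any():
            raise ValueError("SNP positions must be >= 1 (1-based)")
        bad = ~np.isin(self.codes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        order = np.lexsort(
            (self.snps["pos"].to_numpy(), self.snps["chrom"].astype(str).to_numpy())
        )
        if not np.array_equal(order, np.arange(len(self.snps))):
            self.snps = self.snps.iloc[order].reset_index(drop=True)
            self.codes = self.codes[:, order]

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset(self, animal_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """Row/column subset preserving metadata alignment."""
        animal_idx = (
            np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        )
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            animal_ids=[self.animal_ids[i] for i in animal_idx],
            snps=self.snps.iloc[snp_idx].reset_index(drop=True),
            codes=self.codes[np.ix_(animal_idx, snp_idx)],
        )

    def impute_mode(self) -> np.ndarray:
        """Missing calls replaced by the per-SNP modal genotype (float array).

        Forests and MI estimators downstream need complete data; the modal
        genotype is the most conservative single-value fill.  Ties resolve to
        the smallest code.
        """
        X = self.codes.astype(float)
        for j in range(self.n_snps):
            col = X[:, j]
            miss = col == MISSING
            if not miss.any():
                continue
            obs = col[~miss].astype(int)
            if obs.size == 0:
                X[:, j] = 0.0
                continue
            mode = np.bincount(obs, minlength=3).argmax()
            col[miss] = mode
        return X

    def call_rate_animals(self) -> np.ndarray:
        """Fraction of non-missing calls per animal."""
        return (self.codes != MISSING).mean(axis=1)

    def call_rate_snps(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        return (self.codes != MISSING).mean(axis=0)


@dataclass
class TraitGeneSets:
    """Candidate genes for one trait from the two association routes."""

    trait: str
    rf_genes: set = field(default_factory=set)
    epistasis_genes: set = field(default_factory=set)

    @property
    def common(self) -> set:
        return self.rf_genes & self.epistasis_genes

    @property
    def combined(self) -> set:
        return self.rf_genes | self.epistasis_genes
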