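"""Animal- and SNP-level quality control for SNP-array genotypes.

Filters follow standard array QC practice for association cohorts: animals
must have a recorded phenotype for the analysed trait and a genotype call
rate above threshold; SNPs must be autosomal, polymorphic (MAF > 0.01), not
deviate from Hardy-Weinberg equilibrium (exact-test p > 1e-6) and have a
call rate above threshold.  All thresholds are strict inequalities.

Per-SNP statistics are computed on the post-animal-filter cohort, so QC is
trait-specific when traits have different missingness patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, is_autosome


@dataclass
class QCThresholds:
    """Strict (">") retention thresholds."""

    autosomes_only: bool = True
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    snp_call_min: float = 0.90
    animal_call_min: float = 0.90

    def __post_init__(self) -> None:
        for name in ("maf_min", "hwe_p_min", "snp_call_min", "animal_call_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    """Counts of (hom-ref, het, hom-alt) among non-missing calls."""
    col = np.asarray(column)
    obs = col[col != MISSING]
    return int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())


def compute_maf(column: np.ndarray) -> float:
    """Minor allele frequency among non-missing calls (folded, so <= 0.5)."""
    n0, n1, n2 = genotype_counts(column)
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("cannot compute MAF: all genotypes missing")
    p = (2 * n2 + n1) / (2 * n)
    return min(p, 1.0 - p)


def hwe_het_distribution(n: int, rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count.

    Given ``n`` genotypes carrying ``rare`` copies of the minor allele, all
    feasible heterozygote counts (sharing the parity of ``rare``) and their
    probabilities conditional on the allele counts.  Computed with the
    numerically stable recurrence over heterozygote counts (Wigginton,
    Cutler & Abecasis style), so only ratios of consecutive configuration
    probabilities are ever formed.
    """
    h_min = rare % 2
    h_max = min(rare, 2 * n - rare)
    hets = np.arange(h_min, h_max + 1, 2)
    probs = np.empty(hets.size)
    probs[0] = 1.0
    for i in range(1, hets.size):
        h = hets[i]
        hom_r_prev = (rare - (h - 2)) // 2
        hom_c_prev = n - (h - 2) - hom_r_prev
        # P(h) / P(h-2) = 4 * hom_r_prev * hom_c_prev / (h * (h - 1))
        probs[i] = probs[i - 1] * 4.0 * hom_r_prev * hom_c_prev / (h * (h - 1.0))
    probs /= probs.sum()
    return hets, probs


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts no more probable than the observed one.

    Returns 1.0 for monomorphic columns (a single feasible configuration).
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("need at least one genotype")
    rare = 2 * min(n_hom_major, n_hom_minor) + n_het  # minor allele copies
    if rare == 0:
        return 1.0
    hets, probs = hwe_het_distribution(n, rare)
    p_obs = probs[(n_het - hets[0]) // 2]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def snp_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP MAF, exact-HWE p-value, call rate and autosome flag."""
    mafs = np.empty(G.n_snps)
    hwe = np.empty(G.n_snps)
    for j in range(G.n_snps):
        n0, n1, n2 = genotype_counts(G.codes[:, j])
        total = n0 + n1 + n2
        if total == 0:
            mafs[j], hwe[j] = 0.0, 1.0
            continue
        p_alt = (2 * n2 + n1) / (2 * total)
        mafs[j] = min(p_alt, 1 - p_alt)
        # fold so the exact test sees (common hom, het, rare hom)
        hwe[j] = hwe_exact_test(max(n0, n2), n1, min(n0, n2))
    out = G.snps[["snp_id", "chrom", "pos"]].copy()
    out["maf"] = mafs
    out["hwe_p"] = hwe
    out["snp_call_rate"] = G.call_rate_snps()
    out["autosomal"] = [is_autosome(c) for c in G.snps["chrom"]]
    return out


def filter_animals(
    G: GenotypeMatrix,
    traits: pd.DataFrame,
    trait: str,
    thresholds: QCThresholds | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Keep animals genotyped, phenotyped for *trait* and well called.

    Returns the filtered genotypes, the matching phenotype rows, and a report
    frame (animal_id, reason) listing every removal.
    """
    thr = thresholds or QCThresholds()
    if trait not in traits.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    call = G.call_rate_animals()
    removals: list[tuple[str, str]] = []
    keep_idx = []
    for i, aid in enumerate(G.animal_ids):
        if aid not in traits.index:
            removals.append((aid, "missing_phenotype_record"))
        elif pd.isna(traits.loc[aid, trait]):
            removals.append((aid, "missing_phenotype"))
        elif not call[i] > thr.animal_call_min:
            removals.append((aid, "low_call_rate"))
        else:
            keep_idx.append(i)
    for aid in traits.index.difference(G.animal_ids):
        removals.append((aid, "missing_genotype_record"))
    if not keep_idx:
        raise ValueError("no animals remain after filtering")
    G_out = G.subset(animal_idx=keep_idx)
    T_out = traits.loc[G_out.animal_ids]
    report = pd.DataFrame(removals, columns=["animal_id", "reason"])
    return G_out, T_out, report


#: Order in which failed criteria are attributed in the removal report; a SNP
#: failing several is counted once, under the first.
_SNP_CRITERIA = ("non_autosomal", "low_maf", "hwe_deviation", "low_call_rate")


def filter_snps(
    G: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame, dict[str, int]]:
    """Apply the conjunctive SNP filters.

    Returns the filtered matrix, the per-SNP stats table (with a ``kept``
    column and the attributed ``removal_reason``) and per-criterion removal
    counts that, together with the kept count, partition the input.
    """
    thr = thresholds or QCThresholds()
    stats = snp_stats(G)
    fails = {
        "non_autosomal": ~stats["autosomal"].to_numpy()
        if thr.autosomes_only
        else np.zeros(len(stats), bool),
        "low_maf": ~(stats["maf"].to_numpy() > thr.maf_min),
        "hwe_deviation": ~(stats["hwe_p"].to_numpy() > thr.hwe_p_min),
        "low_call_rate": ~(stats["snp_call_rate"].to_numpy() > thr.snp_call_min),
    }
    reason = np.full(len(stats), "", dtype=object)
    for crit in reversed(_SNP_CRITERIA):
        reason[fails[crit]] = crit
    kept = reason == ""
    if not kept.any():
        raise ValueError("no SNPs remain after filtering")
    stats["kept"] = kept
    stats["removal_reason"] = reason
    counts = {crit: int((reason == crit).sum()) for crit in _SNP_CRITERIA}
    counts["kept"] = int(kept.sum())
    return G.subset(snp_idx=np.flatnonzero(kept)), stats, counts
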