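"""Map trait-associated SNPs to candidate genes and compare gene sets.

A SNP is assigned to every gene whose body, extended by a symmetric window
(default 25 kb, inclusive bounds), contains the SNP position.  Gene sets
from the single-SNP and the epistasis routes are intersected/united per
trait, and exclusive cross-trait overlaps are tabulated UpSet-style.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import TraitGeneSets

DEFAULT_WINDOW = 25_000


def map_snps_to_genes(
    snps: pd.DataFrame,
    annotation: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
) -> dict[str, set[str]]:
    """SNP -> set of gene ids within ``window`` bases of the gene body.

    ``snps`` needs columns snp_id, chrom, pos; ``annotation`` needs
    gene_id, chrom, start, end.  SNPs on chromosomes absent from the
    annotation are skipped with a warning.
    """
    out: dict[str, set[str]] = {}
    ann_by_chrom = {str(c): g for c, g in annotation.groupby("chrom")}
    unknown = set()
    for rec in snps.itertuples(index=False):
        chrom = str(rec.chrom)
        genes = ann_by_chrom.get(chrom)
        if genes is None:
            unknown.add(chrom)
            out[rec.snp_id] = set()
            continue
        lo = genes["start"].to_numpy() - window
        hi = genes["end"].to_numpy() + window
        mask = (rec.pos >= lo) & (rec.pos <= hi)
        out[rec.snp_id] = set(genes["gene_id"].to_numpy()[mask])
    if unknown:
        warnings.warn(
            f"SNP chromosomes absent from annotation, skipped: {sorted(unknown)}",
            stacklevel=2,
        )
    return out


def genes_for_snps(snp_ids, snp_to_genes: dict[str, set[str]]) -> set[str]:
    """Union of mapped genes over SNPs; pair members contribute jointly."""
    out: set[str] = set()
    for s in snp_ids:
        out |= snp_to_genes.get(s, set())
    return out


def build_trait_gene_sets(
    trait: str,
    rf_snps,
    pair_snps,
    snp_to_genes: dict[str, set[str]],
) -> TraitGeneSets:
    """Gene sets for one trait from the two association routes.

    ``pair_snps`` may be pair tuples or a flat iterable of SNP ids; genes of
    a pair are the union over both members.
    """
    flat_pairs: list[str] = []
    for p in pair_snps:
        if isinstance(p, (tuple, list)):
            flat_pairs.extend(p)
        else:
            flat_pairs.append(p)
    return TraitGeneSets(
        trait=trait,
        rf_genes=genes_for_snps(rf_snps, snp_to_genes),
        epistasis_genes=genes_for_snps(flat_pairs, snp_to_genes),
    )


def upset_counts(sets_by_trait: dict[str, set[str]]) -> pd.DataFrame:
    """Exclusive-intersection counts over trait gene sets.

    One row per non-empty trait combination actually realised, with boolean
    membership columns, the count of genes belonging to *exactly* that
    combination, and the combination's degree.  Counts partition the union.
    """
    traits = list(sets_by_trait)
    if len(traits) < 2:
        raise ValueError("need >= 2 sets")
    union = set().union(*sets_by_trait.values())
    combos: dict[tuple[bool, ...], int] = {}
    for gene in union:
        key = tuple(gene in sets_by_trait[t] for t in traits)
        combos[key] = combos.get(key, 0) + 1
    rows = []
    for key, count in combos.items():
        row = dict(zip(traits, key))
        row["count"] = count
        row["degree"] = sum(key)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["degree", "count"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)


def plot_upset(counts: pd.DataFrame, traits: list[str], path: str) -> None:
    """Minimal matrix-layout plot of exclusive intersections (bar + dot matrix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = counts.sort_values("count", ascending=False).reset_index(drop=True)
    fig, (ax_bar, ax_dot) = plt.subplots(
        2, 1, figsize=(max(6, 0.4 * len(df)), 5), sharex=True,
        gridspec_kw={"height_ratios": [2, 1]},
    )
    ax_bar.bar(range(len(df)), df["count"], color="0.2")
    ax_bar.set_ylabel("genes")
    for i, rec in df.iterrows():
        for j, t in enumerate(traits):
            ax_dot.plot(i, j, "o", color="0.2" if rec[t] else "0.85", ms=6)
    ax_dot.set_yticks(range(len(traits)), traits)
    ax_dot.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
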