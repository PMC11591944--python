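"""Orchestration: QC -> (RF selection, MI epistasis) -> gene mapping ->
promoter scan -> TF cooperation, per trait, with file-based intermediates
and a manifest sufficient to re-run bit-identically.

Stages communicate only via plain-text files so any stage can be re-run
standalone; all randomness is funnelled through seeds derived from the run
seed, recorded in the manifest.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cooperation as coop
from . import epistasis as epi
from . import genes as genemod
from . import io as sio
from . import motifs as mot
from . import qc as qcmod
from . import rf as rfmod
from .containers import TRAITS


@dataclass
class RunConfig:
    """Declarative configuration of a full run (YAML-loadable)."""

    genotypes: str
    phenotypes: str
    genome: str
    annotation: str
    pwms: str
    outdir: str
    traits: list[str] = field(default_factory=lambda: list(TRAITS))
    seed: int = 0
    # stage parameter blocks
    qc: dict = field(default_factory=dict)  # QCThresholds fields
    rf: dict = field(
        default_factory=lambda: {
            "n_trees": 100, "max_iter": 50, "alpha": 0.01,
            "max_k": 30, "cv_folds": 5, "importance": "impurity",
        }
    )
    epistasis: dict = field(
        default_factory=lambda: {
            "screen_fraction": 0.01, "min_screen": 50, "k": 3,
            "ifs_max_k": 20, "n_pairs_default": 10,
        }
    )
    genes: dict = field(default_factory=lambda: {"window": 25_000})
    scan: dict = field(
        default_factory=lambda: {"up": 500, "down": 100, "mss": 0.95, "css": 0.90}
    )
    cooperation: dict = field(
        default_factory=lambda: {"d_min": 5, "d_max": 20, "z": 3.0}
    )

    def validate(self) -> None:
        if not self.traits:
            raise ValueError("traits must be non-empty")
        for name in ("genotypes", "phenotypes", "genome", "annotation", "pwms"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name} path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


class PipelineRun:
    """Shared state across traits (loaded inputs, per-cohort QC cache)."""

    def __init__(self, cfg: RunConfig):
        cfg.validate()
        self.cfg = cfg
        self.G = sio.read_vcf(cfg.genotypes)
        self.traits_table = sio.read_phenotypes(cfg.phenotypes)
        self.genome = sio.read_fasta(cfg.genome)
        self.annotation = sio.read_gff3(cfg.annotation)
        self.pwms = sio.read_transfac(cfg.pwms)
        self._qc_cache: dict = {}

    # -- stages ------------------------------------------------------------

    def _qc(self, trait: str):
        thr = qcmod.QCThresholds(**self.cfg.qc)
        G1, T1, animal_report = qcmod.filter_animals(
            self.G, self.traits_table, trait, thr
        )
        cohort = tuple(G1.animal_ids)  # QC depends only on the retained cohort
        if cohort in self._qc_cache:
            G2, stats, counts = self._qc_cache[cohort]
        else:
            G2, stats, counts = qcmod.filter_snps(G1, thr)
            self._qc_cache[cohort] = (G2, stats, counts)
        return G2, T1, animal_report, stats, counts

    def run_trait(self, trait: str) -> dict:
        cfg = self.cfg
        out = Path(cfg.outdir) / trait
        out.mkdir(parents=True, exist_ok=True)
        try:
            G, T, animal_report, snp_report, qc_counts = self._qc(trait)
            sio.write_vcf(G, out / "genotypes.qc.vcf")
            _write_tsv(animal_report, out / "qc_animals.tsv")
            _write_tsv(snp_report, out / "qc_snps.tsv")

            y = T[trait].to_numpy(dtype=float)
            X = G.impute_mode()
            ids = list(G.snps["snp_id"])
            seed = cfg.seed + 101

            rfp = cfg.rf
            ranking = rfmod.boruta_select(
                X, y, ids, max_iter=rfp.get("max_iter", 50),
                alpha=rfp.get("alpha", 0.01), n_trees=rfp.get("n_trees", 100),
                seed=seed, importance=rfp.get("importance", "impurity"),
            )
            max_k = min(rfp.get("max_k", 30), len(ids))
            curve = rfmod.incremental_feature_selection(
                X, y, ranking, ids, max_k=max_k,
                cv_folds=rfp.get("cv_folds", 5), seed=seed,
                n_trees=rfp.get("n_trees", 100),
            )
            best_k = rfmod.select_optimal_k(curve)
            rf_snps = ranking.snp_ids[:best_k]
            _write_tsv(ranking.to_frame(), out / "rf_ranking.tsv")
            _write_tsv(curve.to_frame(), out / "rf_ifs.tsv")
            _write_tsv(pd.DataFrame({"snp_id": rf_snps}), out / "rf_selected.tsv")

            epp = cfg.epistasis
            pairs, pair_curve = epi.detect_epistasis(
                X, y, ids,
                screen_fraction=epp.get("screen_fraction", 0.01),
                min_screen=epp.get("min_screen", 50),
                k=epp.get("k", 3), seed=seed,
                ifs_max_k=epp.get("ifs_max_k", 20),
                cv_folds=rfp.get("cv_folds", 5), n_trees=rfp.get("n_trees", 100),
            )
            if pair_curve is not None:
                n_pairs = rfmod.select_optimal_k(pair_curve)
                _write_tsv(pair_curve.to_frame(), out / "pair_ifs.tsv")
            else:
                n_pairs = min(epp.get("n_pairs_default", 10), len(pairs))
            sel_pairs = pairs[:n_pairs]
            _write_tsv(
                pd.DataFrame(
                    [
                        {"snp_a": p.snp_a, "snp_b": p.snp_b, "mi": p.mi_pair,
                         "corrected": p.corrected, "rank": p.rank}
                        for p in pairs
                    ]
                ),
                out / "epistasis_pairs.tsv",
            )

            snp_map = genemod.map_snps_to_genes(
                G.snps, self.annotation, window=cfg.genes.get("window", 25_000)
            )
            gene_sets = genemod.build_trait_gene_sets(
                trait, rf_snps, [(p.snp_a, p.snp_b) for p in sel_pairs], snp_map
            )
            _write_tsv(
                pd.DataFrame(
                    {
                        "gene_id": sorted(gene_sets.combined),
                        "in_rf": [g in gene_sets.rf_genes for g in sorted(gene_sets.combined)],
                        "in_epistasis": [
                            g in gene_sets.epistasis_genes for g in sorted(gene_sets.combined)
                        ],
                    }
                ),
                out / "genes.tsv",
            )

            sel_ann = self.annotation[
                self.annotation["gene_id"].isin(gene_sets.combined)
            ].reset_index(drop=True)
            promoters = mot.extract_promoters(
                sel_ann, self.genome,
                up=cfg.scan.get("up", 500), down=cfg.scan.get("down", 100),
            )
            sio.write_fasta(
                dict(zip(promoters["gene_id"], promoters["sequence"])),
                out / "promoters.fasta",
            )
            hits = mot.match_scan(
                promoters, self.pwms,
                mss_cutoff=cfg.scan.get("mss", 0.95),
                css_cutoff=cfg.scan.get("css", 0.90),
            )
            hits = mot.resolve_overlaps(hits)
            _write_tsv(hits, out / "tfbs_hits.tsv")

            cpar = cfg.cooperation
            table = coop.count_cooccurrences(
                hits, d_min=cpar.get("d_min", 5), d_max=cpar.get("d_max", 20)
            )
            pmi = coop.pmi_scores(table) if table.total_sites else {}
            scores = coop.significance(pmi, table, z_threshold=cpar.get("z", 3.0))
            network = coop.build_network(scores, trait)
            _write_tsv(
                pd.DataFrame(
                    [
                        {"tf_a": s.tf_a, "tf_b": s.tf_b, "events": s.events,
                         "pmi": s.pmi, "z": s.z, "significant": s.significant}
                        for s in scores
                    ],
                    columns=["tf_a", "tf_b", "events", "pmi", "z", "significant"],
                ),
                out / "tf_pairs.tsv",
            )
            _write_tsv(network.edges_frame(), out / "network_edges.tsv")
            import networkx as nx

            nx.write_graphml(network.graph, out / "network.graphml")

            manifest = {
                "trait": trait,
                "seed": cfg.seed,
                "inputs": {
                    os.path.basename(getattr(cfg, k)): sio.sha256_file(getattr(cfg, k))
                    for k in ("genotypes", "phenotypes", "genome", "annotation", "pwms")
                },
                "params": {
                    "qc": cfg.qc, "rf": cfg.rf, "epistasis": cfg.epistasis,
                    "genes": cfg.genes, "scan": cfg.scan,
                    "cooperation": cfg.cooperation,
                },
                "stages": {
                    "animals_kept": G.n_animals,
                    "snps_kept": G.n_snps,
                    "qc_removals": qc_counts,
                    "rf_selected": len(rf_snps),
                    "pairs_scored": len(pairs),
                    "pairs_selected": len(sel_pairs),
                    "genes_rf": len(gene_sets.rf_genes),
                    "genes_epistasis": len(gene_sets.epistasis_genes),
                    "genes_common": len(gene_sets.common),
                    "genes_combined": len(gene_sets.combined),
                    "promoters": len(promoters),
                    "tfbs_hits": len(hits),
                    "tf_pairs_scored": len(scores),
                    "tf_pairs_significant": network.n_pairs,
                    "tfs_in_network": network.n_tfs,
                },
            }
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=1, sort_keys=True)
            return {
                "trait": trait,
                "gene_sets": gene_sets,
                "network": network,
                "scores": scores,
                "manifest": manifest,
                "outdir": str(out),
            }
        except Exception as exc:  # annotate with stage context
            raise RuntimeError(f"pipeline failed for trait {trait}: {exc}") from exc


def run_all(cfg: RunConfig) -> dict:
    """Run every configured trait, then the cross-trait comparisons."""
    run = PipelineRun(cfg)
    results = {t: run.run_trait(t) for t in cfg.traits}
    out = Path(cfg.outdir)
    if len(cfg.traits) >= 2:
        combined = {t: results[t]["gene_sets"].combined for t in cfg.traits}
        upset = genemod.upset_counts(combined)
        _write_tsv(upset, out / "gene_upset.tsv")
        summary = coop.cross_trait_summary([results[t]["network"] for t in cfg.traits])
        _write_tsv(summary["partner_table"], out / "tf_partners.tsv")
        with open(out / "tf_cross_trait.json", "w") as fh:
            json.dump(
                {k: v for k, v in summary.items() if k != "partner_table"},
                fh, indent=1, sort_keys=True,
            )
        results["cross_trait"] = summary
    gene_table, tf_table = report(results, cfg.traits)
    _write_tsv(gene_table, out / "report_genes.tsv")
    _write_tsv(tf_table, out / "report_tfs.tsv")
    results["report"] = (gene_table, tf_table)
    return results


def report(results: dict, traits: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trait summary tables: association counts and TF-network counts."""
    gene_rows, tf_rows = [], []
    for t in traits:
        r = results[t]
        st = r["manifest"]["stages"]
        gene_rows.append(
            {
                "trait": t,
                "rf_snps": st["rf_selected"],
                "rf_genes": st["genes_rf"],
                "snp_pairs": st["pairs_selected"],
                "pair_genes": st["genes_epistasis"],
                "common_genes": st["genes_common"],
            }
        )
        top = [
            f"[{s.tf_a}-{s.tf_b}]"
            for s in r["scores"]
            if s.significant
        ][:3]
        tf_rows.append(
            {
                "trait": t,
                "n_tfs": st["tfs_in_network"],
                "n_pairs": st["tf_pairs_significant"],
                "top_pairs": "; ".join(top),
            }
        )
    return pd.DataFrame(gene_rows), pd.DataFrame(tf_rows)


# ---------------------------------------------------------------------------
# One-command synthetic demo


def make_demo(
    outdir: str,
    seed: int = 0,
    n_animals: int = 150,
    n_snps: int = 120,
    n_genes: int = 30,
    traits: tuple[str, ...] = TRAITS,
    plant_fraction: float = 0.7,
    motif_pair: tuple[str, str] = ("TATAATAA", "GGGCGGAA"),
) -> RunConfig:
    """Write a self-contained synthetic input set and return its RunConfig.

    Genomes get the cooperating motif pair planted into a fraction of gene
    promoters (strand-aware, 5-20 bp spacer) so the downstream TF stage has
    signal to find; the PWM library holds the two planted matrices plus
    random decoys.
    """
    from . import simulate as sim

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_sim = sim.SimConfig(
        n_animals=n_animals, n_snps=n_snps, maf_range=(0.1, 0.5),
        missing_rate=0.01, n_additive=3, n_epistatic_pairs=1,
        additive_effect=1.0, epistasis_model="product", heritability=0.6,
        n_chromosomes=2, seed=seed,
    )
    G = sim.simulate_genotypes(cfg_sim)
    table, truths = sim.simulate_trait_table(G, cfg_sim, traits=traits,
                                             missing_fraction=0.1)
    span = int(G.snps["pos"].max()) + 30_000
    genes, genome = sim.simulate_annotation(
        n_genes, [span, span], seed=seed + 1
    )

    rng = np.random.default_rng(seed + 2)
    decoy_motifs, decoy_pwm_list = sim.decoy_library(16, length=8, seed=seed + 3)

    def write_at_promoter_offset(rec, offset: int, motif: str) -> None:
        """Insert a motif at a promoter-coordinate offset, strand-aware."""
        contig = genome[rec.chrom]
        L = len(motif)
        if rec.strand == "+":
            g0 = (rec.start - 1 - 500) + offset
            ins = motif
        else:
            # promoter offset o maps to genome index (end + 499 - o - L + 1)
            g0 = rec.end + 500 - offset - L
            ins = mot.reverse_complement(motif)
        genome[rec.chrom] = contig[:g0] + ins + contig[g0 + L:]

    planted = []
    a, b = motif_pair
    for rec in genes.itertuples(index=False):
        occupied: list[tuple[int, int]] = []
        if rng.random() < plant_fraction:
            spacer = int(rng.integers(5, 21))
            block = a + "".join(rng.choice(list("ACGT"), size=spacer)) + b
            off = 50  # well inside the -500..+100 window
            write_at_promoter_offset(rec, off, block)
            occupied.append((off, off + len(block)))
            planted.append(rec.gene_id)
        for motif in decoy_motifs:  # scattered non-cooperating sites
            if rng.random() >= 0.5:
                continue
            for _ in range(10):
                off = int(rng.integers(0, 600 - len(motif) + 1))
                if all(off + len(motif) <= o0 or off >= o1 for o0, o1 in occupied):
                    write_at_promoter_offset(rec, off, motif)
                    occupied.append((off, off + len(motif)))
                    break

    pwm_a = mot.consensus_to_pwm(a, 0.0, matrix_id="M_A", tf_name="TF_A")
    pwm_b = mot.consensus_to_pwm(b, 0.0, matrix_id="M_B", tf_name="TF_B")
    library = [pwm_a, pwm_b] + decoy_pwm_list

    sio.write_vcf(G, out / "genotypes.vcf")
    sio.write_phenotypes(table, out / "phenotypes.tsv")
    sio.write_fasta(genome, out / "genome.fasta")
    sio.write_gff3(genes, out / "annotation.gff3")
    sio.write_transfac(library, out / "pwms.transfac")
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "traits": {
                    t: {
                        "additive_snps": tr["additive_snps"],
                        "epistatic_pairs": [list(p) for p in tr["epistatic_pairs"]],
                    }
                    for t, tr in truths.items()
                },
                "planted_promoter_genes": planted,
                "motif_pair": list(motif_pair),
            },
            fh, indent=1, sort_keys=True,
        )
    return RunConfig(
        genotypes=str(out / "genotypes.vcf"),
        phenotypes=str(out / "phenotypes.tsv"),
        genome=str(out / "genome.fasta"),
        annotation=str(out / "annotation.gff3"),
        pwms=str(out / "pwms.transfac"),
        outdir=str(out / "results"),
        traits=list(traits),
        seed=seed,
        epistasis={"screen_fraction": 0.2, "min_screen": 20, "k": 3,
                   "ifs_max_k": 10, "n_pairs_default": 5},
        rf={"n_trees": 100, "max_iter": 30, "alpha": 0.01, "max_k": 15,
            "cv_folds": 3, "importance": "impurity"},
    )
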