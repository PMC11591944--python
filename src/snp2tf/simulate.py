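"""Synthetic genotype / phenotype / genome / promoter generators.

The real study cohort (hundreds of dairy goats genotyped on a 50K SNP array,
seven milk traits) is not redistributable, so every downstream stage is
exercised on simulated data carrying the statistical structure the pipeline
assumes: SNPs in Hardy-Weinberg proportions, quantitative traits with
additive and pairwise-epistatic genetic effects plus Gaussian noise, toy
genomes with annotated genes, and promoters with planted cooperating motif
pairs at a controlled spacing.  Every generator is reproducible under a
seed, and every planted truth is returned (and written) alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, TRAITS, GenotypeMatrix
from .motifs import PWM, consensus_to_pwm, reverse_complement

__all__ = [
    "SimConfig",
    "MotifPlantConfig",
    "ConfigError",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_trait_table",
    "simulate_annotation",
    "plant_promoters",
    "consensus_to_pwm",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimConfig:
    """Genotype/phenotype simulation settings.

    Defaults emulate the scale of a single-breed dairy association cohort
    (order 10^2-10^3 animals on a mid-density array, thinned to desk scale)
    with a handful of additive QTL and epistatic pairs per trait.
    """

    n_animals: int = 822
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    n_additive: int = 5
    n_epistatic_pairs: int = 3
    additive_effect: float = 1.0
    #: "per_allele": constant effect per minor-allele copy (variance share
    #: then scales with 2p(1-p)); "standardized": effects scaled so every
    #: causal SNP contributes equal variance, the convention for planting
    #: uniformly strong QTL
    effect_scaling: str = "per_allele"
    epistasis_model: str = "xor"  # or "product"
    heritability: float = 0.5
    n_chromosomes: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ConfigError("n_animals must be >= 1")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0.01 <= lo <= hi <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.n_additive + 2 * self.n_epistatic_pairs > self.n_snps:
            raise ConfigError("n_additive + 2*n_epistatic_pairs exceeds n_snps")
        if self.epistasis_model not in ("product", "xor"):
            raise ConfigError("epistasis_model must be 'product' or 'xor'")
        if self.effect_scaling not in ("per_allele", "standardized"):
            raise ConfigError("effect_scaling must be 'per_allele' or 'standardized'")
        if not 0.0 <= self.heritability <= 1.0:
            raise ConfigError("heritability must lie in [0, 1]")
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw unlinked biallelic SNPs in Hardy-Weinberg proportions.

    Each SNP's minor-allele frequency is sampled uniformly from
    ``cfg.maf_range``; genotypes are drawn from (q^2, 2pq, p^2) where p is
    the minor-allele frequency; calls are masked missing at
    ``cfg.missing_rate``.  SNPs are spread over ``n_chromosomes`` with sorted
    positions.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)
    probs = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)
    u = rng.random((cfg.n_animals, cfg.n_snps))
    cum = probs.cumsum(axis=1)
    codes = (u[:, :, None] > cum[None, :, :-1]).sum(axis=2).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.random(codes.shape) < cfg.missing_rate
        codes[mask] = MISSING

    chrom_of = np.arange(cfg.n_snps) % cfg.n_chromosomes
    pos = np.zeros(cfg.n_snps, dtype=int)
    for c in range(cfg.n_chromosomes):
        idx = np.flatnonzero(chrom_of == c)
        gaps = rng.integers(500, 5000, size=idx.size)
        pos[idx] = 1000 + gaps.cumsum()
    alleles = rng.choice(list("ACGT"), size=(cfg.n_snps, 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j:05d}" for j in range(cfg.n_snps)],
            "chrom": (chrom_of + 1).astype(str),
            "pos": pos,
            "a1": alleles[:, 0],
            "a2": alleles[:, 1],
        }
    )
    animal_ids = [f"goat{i:04d}" for i in range(cfg.n_animals)]
    return GenotypeMatrix(animal_ids=animal_ids, snps=snps, codes=codes)


def _balanced_indicator(g: np.ndarray) -> np.ndarray:
    """Dichotomize genotypes by the split with frequency closest to 1/2.

    Candidates are carrier ({1,2}), recessive ({2}) and heterozygote ({1})
    groupings.  The xor construction below has zero marginal single-SNP
    signal exactly when the partner indicator is balanced, so the split
    closest to 0.5 minimises marginal leakage; at MAF 0.5 under HWE the
    heterozygote split is exactly balanced.
    """
    splits = [g >= 1, g >= 2, g == 1]
    means = [s.mean() for s in splits]
    best = int(np.argmin([abs(m - 0.5) for m in means]))
    return splits[best].astype(float)


def _epistatic_term(ga: np.ndarray, gb: np.ndarray, model: str, effect: float) -> np.ndarray:
    if model == "product":
        return effect * ga * gb
    # xor of balanced genotype indicators: +e when exactly one of the two
    # indicators fires, -e otherwise -> the pair's 9-cell means differ while
    # each single SNP carries (near-)zero marginal signal.
    ca = _balanced_indicator(ga)
    cb = _balanced_indicator(gb)
    return effect * (2.0 * np.logical_xor(ca, cb) - 1.0)


def simulate_phenotype(
    G: GenotypeMatrix, cfg: SimConfig, trait_seed: int | None = None
) -> tuple[pd.Series, dict]:
    """One standardized quantitative trait with planted genetic architecture.

    y = sum(additive effects) + sum(epistatic terms) + Gaussian noise, with
    the noise variance set so var(genetic)/var(total) = ``cfg.heritability``;
    the result is centred and scaled to unit variance.  Returns the phenotype
    and the planted truth: causal SNP ids, causal pairs and the model used.
    """
    cfg.validate()
    n_causal = cfg.n_additive + 2 * cfg.n_epistatic_pairs
    if G.n_snps < n_causal:
        raise ConfigError("n_snps too small for the requested causal structure")
    if not 0.0 <= cfg.heritability <= 1.0:
        raise ConfigError("heritability must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed if trait_seed is None else trait_seed)
    causal = rng.choice(G.n_snps, size=n_causal, replace=False)
    additive_idx = causal[: cfg.n_additive]
    pair_idx = causal[cfg.n_additive :].reshape(cfg.n_epistatic_pairs, 2)

    X = G.impute_mode()
    genetic = np.zeros(G.n_animals)
    for j in additive_idx:
        g = X[:, j]
        centred = g - g.mean()
        if cfg.effect_scaling == "standardized" and centred.std() > 0:
            centred = centred / centred.std()
        genetic += cfg.additive_effect * centred
    for a, b in pair_idx:
        term = _epistatic_term(X[:, a], X[:, b], cfg.epistasis_model, cfg.additive_effect)
        genetic += term - term.mean()

    h2 = cfg.heritability
    if h2 == 0.0:
        y = rng.normal(0.0, 1.0, size=G.n_animals)
    else:
        var_g = genetic.var()
        if h2 == 1.0 or var_g == 0.0:
            y = genetic.copy()
        else:
            noise_sd = np.sqrt(var_g * (1.0 - h2) / h2)
            y = genetic + rng.normal(0.0, noise_sd, size=G.n_animals)
    y = y - y.mean()
    sd = y.std()
    if sd > 0:
        y = y / sd
    ids = G.snps["snp_id"]
    truth = {
        "additive_snps": [ids.iloc[j] for j in additive_idx],
        "epistatic_pairs": [
            tuple(sorted((ids.iloc[a], ids.iloc[b]))) for a, b in pair_idx
        ],
        "epistasis_model": cfg.epistasis_model,
        "heritability": h2,
    }
    return pd.Series(y, index=pd.Index(G.animal_ids, name="animal_id")), truth


def simulate_trait_table(
    G: GenotypeMatrix, cfg: SimConfig, traits: tuple[str, ...] = TRAITS,
    missing_fraction: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate all traits, each with its own causal architecture.

    ``missing_fraction`` of animals per trait are set NA, emulating
    incomplete phenotype records.
    """
    cols, truths = {}, {}
    for t_i, trait in enumerate(traits):
        y, truth = simulate_phenotype(G, cfg, trait_seed=cfg.seed + 1000 * (t_i + 1))
        if missing_fraction > 0:
            rng = np.random.default_rng(cfg.seed + 7000 + t_i)
            n_miss = int(round(missing_fraction * len(y)))
            drop = rng.choice(len(y), size=n_miss, replace=False)
            y.iloc[drop] = np.nan
        cols[trait] = y
        truths[trait] = truth
    return pd.DataFrame(cols), truths


# ---------------------------------------------------------------------------
# Toy genome + annotation


def simulate_annotation(
    n_genes: int,
    chrom_lengths: list[int],
    seed: int = 0,
    gene_length_range: tuple[int, int] = (500, 2000),
    upstream_clearance: int = 600,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Random genome FASTA plus non-overlapping gene annotation.

    Genes are placed uniformly on both strands with at least
    ``upstream_clearance`` bases of promoter room inside the contig; 1-based
    inclusive coordinates as in GFF3.  Raises when the requested genes cannot
    be packed.
    """
    rng = np.random.default_rng(seed)
    # chromosome names match the genotype simulator ("1", "2", ...) so SNPs
    # and genes share a namespace
    chroms = {f"{i + 1}": int(L) for i, L in enumerate(chrom_lengths)}
    max_len = gene_length_range[1]
    slot = max_len + 2 * upstream_clearance
    capacity = sum(max(0, L // slot) for L in chroms.values())
    if n_genes > capacity:
        raise ValueError(
            f"cannot pack {n_genes} genes with {upstream_clearance} bp clearance "
            f"into chromosomes of lengths {chrom_lengths} (capacity {capacity})"
        )
    # deterministic slot assignment: round-robin over chromosome slots
    slots = []
    for name, L in chroms.items():
        for s in range(L // slot):
            slots.append((name, s * slot))
    pick = rng.choice(len(slots), size=n_genes, replace=False)
    rows = []
    for g, si in enumerate(sorted(pick)):
        chrom, offset = slots[si]
        length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
        start = offset + upstream_clearance + 1  # 1-based
        end = start + length - 1
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"gene{g:04d}", chrom, start, end, strand))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    genome = {
        name: "".join(rng.choice(list("ACGT"), size=L)) for name, L in chroms.items()
    }
    return genes, genome


# ---------------------------------------------------------------------------
# Promoters with planted motif pairs


@dataclass
class MotifPlantConfig:
    """Settings for promoters with planted cooperating motif pairs.

    The spacer between the two planted sites is drawn uniformly from
    ``spacer_range`` (edge-to-edge), whose default matches the distance
    window used when counting co-occurrences downstream.
    """

    n_promoters: int = 200
    promoter_length: int = 600
    motif_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("TATAAT", "GGGCGG")]
    )
    spacer_range: tuple[int, int] = (5, 20)
    plant_fraction: float = 0.5
    background_gc: float = 0.42
    #: independent decoy motifs scattered at random positions (no distance
    #: preference), emulating the many non-cooperating TFBSs of a real
    #: promoter; each is planted per promoter with probability decoy_rate
    decoy_motifs: list[str] = field(default_factory=list)
    decoy_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_promoters < 1:
            raise ConfigError("n_promoters must be >= 1")
        if not 0.0 <= self.plant_fraction <= 1.0:
            raise ConfigError("plant_fraction must lie in [0, 1]")
        if not 0.0 < self.background_gc < 1.0:
            raise ConfigError("background_gc must lie in (0, 1)")
        lo, hi = self.spacer_range
        if not 0 <= lo <= hi:
            raise ConfigError("spacer_range must satisfy 0 <= lo <= hi")
        if not 0.0 <= self.decoy_rate <= 1.0:
            raise ConfigError("decoy_rate must lie in [0, 1]")
        for m in self.decoy_motifs:
            if len(m) > self.promoter_length:
                raise ConfigError("promoter_length shorter than decoy motif")
        for a, b in self.motif_pairs:
            need = len(a) + len(b) + hi
            if need > self.promoter_length:
                raise ConfigError(
                    f"promoter_length {self.promoter_length} too short for motif "
                    f"pair ({a}, {b}) with spacer up to {hi} (needs {need})"
                )


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def plant_promoters(cfg: MotifPlantConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate background promoters, planting motif pairs in a fraction.

    In each selected promoter every configured pair is embedded with a
    uniform edge-to-edge spacer, random left/right order and random strand
    (both sites of a pair go on the same strand).  Returns the sequences and
    a ground-truth table (promoter, motif, start, end, strand, pair index;
    0-based half-open).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    seqs: dict[str, str] = {}
    truth_rows = []
    for i in range(cfg.n_promoters):
        name = f"prom{i:04d}"
        seq = list(_random_seq(rng, cfg.promoter_length, cfg.background_gc))
        occupied: list[tuple[int, int]] = []
        if rng.random() < cfg.plant_fraction:
            for p_i, (a, b) in enumerate(cfg.motif_pairs):
                spacer = int(rng.integers(cfg.spacer_range[0], cfg.spacer_range[1] + 1))
                first, second = (a, b) if rng.random() < 0.5 else (b, a)
                strand = "+" if rng.random() < 0.5 else "-"
                block = len(first) + spacer + len(second)
                start = int(rng.integers(0, cfg.promoter_length - block + 1))
                occupied.append((start, start + block))
                for motif, s in ((first, start), (second, start + len(first) + spacer)):
                    ins = motif if strand == "+" else reverse_complement(motif)
                    seq[s : s + len(motif)] = list(ins)
                    truth_rows.append(
                        (name, motif, s, s + len(motif), strand, p_i, spacer)
                    )
        for motif in cfg.decoy_motifs:
            if rng.random() >= cfg.decoy_rate:
                continue
            L = len(motif)
            for _attempt in range(10):  # avoid clobbering planted sites
                s = int(rng.integers(0, cfg.promoter_length - L + 1))
                if all(s + L <= o0 or s >= o1 for o0, o1 in occupied):
                    strand = "+" if rng.random() < 0.5 else "-"
                    ins = motif if strand == "+" else reverse_complement(motif)
                    seq[s : s + L] = list(ins)
                    occupied.append((s, s + L))
                    truth_rows.append((name, motif, s, s + L, strand, -1, -1))
                    break
        seqs[name] = "".join(seq)
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "name", "start", "end", "strand", "pair", "spacer"],
    )[["chrom", "start", "end", "name", "pair", "strand", "spacer"]]
    return seqs, truth


def decoy_library(n: int, length: int = 8, seed: int = 0) -> tuple[list[str], list[PWM]]:
    """Random consensus motifs plus their (sharp) PWMs, for decoy TFs."""
    rng = np.random.default_rng(seed)
    motifs, pwms = [], []
    for i in range(n):
        consensus = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
        motifs.append(consensus)
        pwms.append(
            consensus_to_pwm(consensus, pseudocount=0.0,
                             matrix_id=f"DECOY{i:02d}", tf_name=f"DECOY{i:02d}")
        )
    return motifs, pwms


def decoy_pwms(n: int, length: int = 8, seed: int = 0) -> list[PWM]:
    """Random sharp consensus PWMs used as non-planted scan decoys."""
    return decoy_library(n, length=length, seed=seed)[1]
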