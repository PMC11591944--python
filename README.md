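# snp2tf

From SNP genotypes to trait-specific transcription-factor cooperation
networks.

`snp2tf` is a reusable pipeline for dissecting quantitative traits (built
around the seven standard dairy milk traits: DM, DPM, FP, LP, MY, PP, SCC)
in genotyped cohorts, combining two complementary association routes with a
downstream regulatory analysis:

1. **Genotype QC** — animal filters (phenotype completeness, call rate
   > 0.90) and SNP filters (autosomal, MAF > 0.01, exact Hardy–Weinberg
   p > 1e−6, call rate > 0.90).
2. **Single-SNP selection** — Boruta-style shadow-feature confirmation with
   regression forests, then incremental feature selection (IFS): nested
   top-k subsets scored by out-of-fold Pearson r, smallest k with the best
   score wins.
3. **Epistasis detection** — mutual information between SNP-pair composite
   genotypes and the trait via the k-nearest-neighbour estimator for mixed
   discrete–continuous data,
   I = ψ(N) − ⟨ψ(N_c)⟩ + ⟨ψ(k_i)⟩ − ⟨ψ(m_i)⟩,
   with average-product correction (APC) removing shared background signal
   before ranking.
4. **Gene mapping** — SNPs (and pair members) map to genes within ±25 kb,
   inclusive; per-trait gene sets from both routes are intersected, united,
   and compared across traits as exclusive (UpSet-style) intersections.
5. **Promoter scanning** — −500..+100 windows around each candidate gene's
   TSS scanned with TRANSFAC-format PWMs under the Match convention
   (information-weighted matrix and core similarity scores, defaults
   MSS ≥ 0.95, CSS ≥ 0.90).
6. **TF cooperation** — co-occurring binding-site pairs with edge-to-edge
   gaps of 5–20 bp are scored by pointwise mutual information,
   PMI(A;B) = log2 p(A,B)/(κ p(A) p(B)), z-standardised per trait;
   pairs with z ≥ 3 form the trait's cooperation network.

A first-class synthetic-data module generates genotypes in Hardy–Weinberg
proportions, traits with planted additive and epistatic architectures, toy
genomes with annotated genes, and promoters with planted cooperating motif
pairs — so the whole pipeline runs, and is validated, without any external
data. See `docs/methods.md` for the full model description and the design
choices.

## Worked example

Generate a synthetic input set and run the full pipeline for two traits:

```python
from snp2tf.pipeline import make_demo, run_all

cfg = make_demo("demo", seed=5, traits=("MY", "FP"))
results = run_all(cfg)
gene_table, tf_table = results["report"]
print(gene_table.to_string(index=False))
print(tf_table.to_string(index=False))
```

```
trait  rf_snps  rf_genes  snp_pairs  pair_genes  common_genes
   MY        5        14         10          28            14
   FP       12        27         10          30            27
trait  n_tfs  n_pairs   top_pairs
   MY      2        1 [TF_A-TF_B]
   FP      2        1 [TF_A-TF_B]
```

Reading the tables: for milk yield (MY) the forest route selected 5 SNPs
mapping to 14 candidate genes, the epistasis route retained 10 SNP pairs
mapping to 28 genes (all 14 forest genes among them), and scanning the
combined candidate promoters found exactly one significant cooperating TF
pair — the pair whose binding motifs the demo generator planted 5–20 bp
apart in 70% of gene promoters (TF_A–TF_B), recovered at z ≈ 4.6 against
the scattered decoy-site background. Every stage's intermediates (filtered
VCF, rankings, IFS curves, pair tables, gene lists, TFBS hits, network
GraphML, manifest) are written under `demo/results/<trait>/`.

The same stages are available as CLI subcommands:

```bash
snp2tf simulate --outdir demo --seed 5
snp2tf run-all --config demo/run_config.yaml
snp2tf qc --genotypes g.vcf --phenotypes ph.tsv --trait MY --out qc/
snp2tf scan --annotation ann.gff3 --genome genome.fasta --pwms lib.transfac --out scan/
```

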