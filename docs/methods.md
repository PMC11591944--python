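# Methods

`snp2tf` implements a two-step genotype–phenotype association analysis for
quantitative (milk) traits — random-forest feature selection for single-SNP
effects and mutual-information scoring for epistatic SNP pairs — followed by
a regulatory analysis of the candidate genes: promoter extraction, PWM
scanning, and detection of cooperating transcription-factor (TF) pairs from
distance-constrained binding-site co-occurrence. Because the motivating
cohort (hundreds of dairy goats genotyped on a 50K array, seven milk traits)
is not redistributable, the package ships a synthetic-data module that
generates every input with planted ground truth, and all validation is
against that truth.

## Genotype quality control

Genotypes are coded 0/1/2 copies of the minor allele, −1 for missing.
Animals are kept when they have a recorded value for the analysed trait and
a genotype call rate > 0.90. SNPs are kept when they are autosomal, have
minor allele frequency > 0.01, exact-test Hardy–Weinberg p > 1e−6, and call
rate > 0.90. All thresholds are strict inequalities. Per-SNP statistics are
computed on the post-animal-filter cohort, so QC is trait-specific when
missingness differs between traits; results are cached per cohort. Missing
calls are excluded from MAF/HWE denominators (no imputation at QC time). A
SNP failing several criteria is reported once, under the first failing
criterion in the order autosome → MAF → HWE → call rate, so the removal
counts plus the kept count always partition the input.

The HWE test is the exact conditional test: given the allele counts, the
probability of each feasible heterozygote count is computed by the stable
ratio recurrence, and the p-value sums all configurations no more probable
than the observed one (with a 1+1e−12 tie guard). The test suite checks the
full distribution against an independent log-gamma enumeration for every
configuration with up to 200 genotypes.

## Random-forest SNP selection

`rf_importance` ranks SNPs with a regression forest (`sqrt(p)` candidate
features per split). Permutation importance is measured on a held-out 30%
split; scored on the training data, a fully grown forest credits even
pure-noise columns, which would defeat the null-behaviour contract.

`boruta_select` runs the shadow-feature scheme: each iteration appends a
shuffled copy of every active column, refits the forest, and counts a "hit"
for every real column whose importance beats the best shadow. A two-sided
binomial tally over iterations (Bonferroni-corrected across the original p
columns) confirms or rejects each SNP; undecided survivors stay tentative
and are ranked after the confirmed set. Within the shadow loop the forest's
impurity importance is used by default: every feature shares the same
three-level coding, so the cardinality bias that motivates permutation
importance does not arise, the shadow contrast calibrates any residual
bias, and the loop stays ~20× cheaper — the same trade the reference Python
Boruta implementation makes. Permutation importance remains available via
`importance="permutation"`.

The single-SNP recovery study plants 5 additive QTL among 100 SNPs at
n=500 with standardized (equal-variance) effects jointly explaining half
the phenotypic variance — the usual convention for planting uniformly
strong QTL; with a constant per-allele effect, a MAF-0.1 QTL carries a
5× smaller variance share than a MAF-0.5 one and is not a strong signal.
Success means every planted QTL is confirmed (max_iter=50) and the IFS
optimum falls in a plausible band around the true signal size.

Incremental feature selection (IFS) walks the ranking: for each k the
top-k SNPs are fed to a forest and scored by the Pearson correlation
between out-of-fold (k-fold CV) predictions and the trait; the selected
size is the smallest k attaining the maximum score. The sweep is dense up
to k=200 and stepped by 10 beyond, keeping array-scale sweeps tractable.
Note the curve typically plateaus once all informative SNPs are included,
and the argmax wanders over the plateau at the level of CV noise; sweeps
should extend modestly beyond the expected signal size, not far beyond.

## Mutual-information epistasis

For a continuous trait, the MI between a genotype (or the 9-state composite
genotype of a SNP pair) and the phenotype is estimated with the
k-nearest-neighbour estimator for mixed discrete–continuous data
(default k=3, reported in bits): for each observation, the distance to its
k-th neighbour within its genotype class defines a ball, and

  I = ψ(N) − ⟨ψ(N_c)⟩ + ⟨ψ(k_i)⟩ − ⟨ψ(m_i)⟩,

with N_c the class size and m_i the number of observations of any class in
the ball. Classes smaller than k+1 shrink k locally; singleton classes are
dropped. The trait is standardized internally (MI is affine-invariant) and
a seeded jitter of 1e−10 breaks exact ties; the ball boundary is handled
with an absolute 1e−13 shrink so neighbour counts are bit-stable under
rescaling of the trait. When the trait itself is effectively discrete
(≤ 32 distinct values and ≤ 10% of the sample size — e.g. a noiseless
two-class planted architecture), the estimator dispatches to the plug-in on
the exact values, where the continuous-density assumption would otherwise
bias the neighbour counts. The estimator is validated against an
independent implementation (scikit-learn's mixed-data MI) and calibrated on
independent data (|mean bias| < 0.02 bits at n=2000).

Pair detection: (1) a single-SNP MI screen keeps the top fraction of SNPs
(default 1%, minimum 50 — small panels are scanned exhaustively);
(2) all within-screen pairs are scored by composite-genotype MI;
(3) scores are clamped at zero and background-corrected with the
average-product correction, corrected(i,j) = MI(i,j) − mean_i·mean_j /
mean_all. The clamp matters: the APC ratio is only meaningful for a
non-negative score matrix, and a near-zero global mean otherwise amplifies
estimator noise into spurious top ranks. (4) pairs are ranked by corrected
score; (5) optionally, IFS over the ranked pairs (forests on composite pair
codes) suggests how many pairs to retain.

The planted-pair benchmark uses a pure-epistatic xor architecture: each
SNP is dichotomized by the genotype split whose frequency is closest to 1/2
(the heterozygote indicator at MAF 0.5, where the split is exactly
balanced), and the trait takes +e when exactly one indicator fires, −e
otherwise. The xor of two balanced indicators has provably zero marginal
per-SNP signal, giving a regime only the pair stage can see; a carrier
(dominance) split does not have this property (at MAF 0.5 its frequency is
0.75 and the marginal correlation is ≈ −0.37 by enumeration). The recovery
study plants 3 such pairs among 200 SNPs at n=1000 with heritability 0.75
(each interaction explains 25% of phenotypic variance, the strong-signal
regime typical of planted epistasis benchmarks); recovery means all three
pairs rank in the corrected top 10.

## Gene mapping

A SNP maps to every gene whose body extended by a symmetric window
(default 25 kb) contains it, inclusive bounds at both edges; genes for a
SNP pair are the union over both members. Per trait, the single-SNP route
and the pair route give two gene sets; their intersection and union are
reported, and cross-trait overlaps are tabulated as exclusive intersections
(UpSet-style): each gene in the union is counted once, under exactly the
combination of traits containing it, so the counts partition the union.

## Promoter scanning

Promoters are the window −500..+100 around the TSS, taken as the annotated
gene start (+ strand) or end (− strand), reverse-complemented on the minus
strand; windows clipped at contig edges are flagged. Scanning follows the
TRANSFAC/Match convention: per-position information I(i) = Σ_b f(i,b)
ln(4 f(i,b)); window score Σ_i I(i)·f(i,b_i), min–max normalised per matrix
to the matrix similarity score (MSS); a core similarity score over the 5
most informative consecutive positions must also pass. Defaults
mss ≥ 0.95, css ≥ 0.90 (a minimise-false-positives profile; downstream TF
counts are cutoff-sensitive, so both are configuration). Frequencies get a
pseudocount of 1% of the column total spread over the four bases. The
min/max normalisation bounds are computed by scoring the best/worst
windows through the same accumulation path as real windows, so a consensus
window scores exactly 1.0. Same-TF hits overlapping by more than half the
shorter site are collapsed to the best-scoring one.

## TF cooperation

A co-occurrence event is an unordered pair of non-overlapping binding sites
in one promoter whose edge-to-edge gap lies in [5, 20] bp, boundaries
inclusive; same-TF pairs count as self-pairs (cooperative homotypic sites
are a real phenomenon and must be representable). Pairs are scored by
pointwise mutual information, PMI(A;B) = log2[p(A,B)/(κ·p(A)·p(B))], with
p(A,B) the pair's share of all events, p(A) the TF's share of all sites,
and κ=2 for heterotypic pairs (either ordering realises the unordered
pair), κ=1 for self-pairs. Unobserved pairs are unscored (their PMI is
−∞ and irrelevant to an upper-tail cut). PMI values are z-standardised
within each trait's scored-pair population; cooperation is significant at
z ≥ 3. Fewer than 3 scored pairs, or a zero-variance population, yields no
significant pair — note the largest attainable z in a population of m
pairs is ≈ √m, so a meaningful background population of pairs is a
prerequisite for any call. Networks take significant pairs as edges
(self-loops allowed); the cross-trait summary reports TFs present in every
trait's network, union counts, and per-TF partner sets per trait.

The recovery study plants one cooperating pair (uniform 5–20 bp spacer,
random order and strand) in half of 200 promoters, with 20 decoy TFs
scattered at random positions (no distance preference, ~10 decoy sites per
promoter) as the background population — emulating the many
non-cooperating TFBSs of a real promoter. Success means the planted pair
reaches z ≥ 3 while no decoy–decoy pair does.

## Synthetic data

SNPs are unlinked and drawn from Hardy–Weinberg proportions at a MAF
sampled uniformly from a configured range; missing calls are masked at a
configured rate. Traits are standardized (mean 0, SD 1 — the source data's
trait scales are not characterized) sums of additive effects, epistatic
terms and Gaussian noise, with the noise variance set so the genetic
fraction equals the configured heritability; each trait draws its own
causal SNPs. Additive effects are per-allele by default or standardized to
equal variance shares (`effect_scaling="standardized"`). Defaults (822 animals, 2000 SNPs, h²=0.5, 5 additive QTL,
3 epistatic pairs) emulate a single-breed dairy cohort at desk scale.
The toy genome packs non-overlapping genes on both strands with 600 bp
promoter clearance into fixed-size slots; chromosome names match the
genotype simulator so SNPs and genes share a namespace.

What the generator does **not** emulate: linkage disequilibrium, pedigree
and relatedness structure, farm/batch fixed effects, realistic allele
frequency spectra, higher-order sequence composition (backgrounds are
i.i.d.), or overlapping/nested genes. Passing the recovery studies
therefore demonstrates the machinery is correct and calibrated under its
own assumptions, not that power carries over to LD-structured real cohorts.

## The demo and problem sizes

`make_demo` writes a complete synthetic input set (VCF, phenotype TSV,
genome FASTA, GFF3, TRANSFAC library, truth JSON) and a matching run
configuration. Demo sizes — 150 animals × 120 SNPs, 30 genes, 7 traits,
a planted motif pair in 70% of gene promoters plus 16 scattered decoy
TFs — are chosen so a full 7-trait run finishes in about a minute while
every stage still has signal to find. Validation studies use the larger
stage-specific sizes stated above. All randomness flows through seeds
derived from the run seed; reruns with the same configuration are
byte-identical, which the acceptance suite verifies file by file.

## Known limitations

- The screening step (single-SNP MI) can in principle drop members of a
  purely epistatic pair on large panels; the exhaustive `screen_fraction=1`
  setting used in the benchmark sidesteps this, and the O(m²) pair scan is
  the price.
- The PMI convention (site-frequency marginals, κ ordering correction,
  per-trait z-standardisation) is one concrete, testable choice among the
  several used by cooperation-finding tools; it is isolated behind
  `pmi_scores` so an alternative can be swapped in.
- IFS argmax wander on plateaus (see above) makes the "optimal" k noisy
  beyond the true signal size; the curve itself is always reported.
- Boruta decisions at the default α=0.01 with Bonferroni are conservative;
  on small panels some null SNPs end tentative rather than rejected within
  the iteration budget.
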