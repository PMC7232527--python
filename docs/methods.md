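# Methods

## The synthetic study

All analyses are exercised on synthetic data with known ground truth; no
external downloads are required. The generator (`hybridase.simulate`)
emulates a two-species hybrid transcriptomics study:

**Genomes.** The Sc parent gets `n_genes` random coding-like genes (ATG
start, TAA stop) with log-normal lengths floored at 300 bp, laid on two
chromosomes with 300 bp random spacers. Each Su ortholog is the Sc sequence
mutated i.i.d. at the configured per-site `divergence` (default 0.05,
roughly the coding divergence of the *S. cerevisiae*/*S. uvarum* pair);
a fraction `frac_one_to_many` (default 0.02) of Sc genes receives a second,
independently diverged Su copy — the planted one-to-many orthologs.
Divergence above 0.5 is rejected: gene identity would be lost. Mitochondrial
COX2/COX3-like markers share a backbone scrubbed of HinfI/HindIII motifs;
the discriminative restriction site is engineered into exactly one parent
per marker (HinfI site in Sc COX2, HindIII site in Su COX3), so RFLP
patterns are discriminative by construction.

**Design and counts.** The sample sheet mirrors the study shape: 2 diploid
parents and 2 hybrid mitotypes (HMtSc, HMtSu) × 4 conditions (YPD /
YP-glycerol × 28 °C / 16 °C) × 3 replicates = 48 samples. Parents contribute
only their own species' allele rows; hybrids contribute both. Log2 mean
expression per allele is a gene baseline (Normal, log2 mean 7, sd 1) plus
per-factor shifts with random signs on designated gene fractions: medium
±2 log2 on 30% of genes, temperature ±1.5 on 20%, subgenome ±1 on 10%, and
a mitotype×allele interaction of +2 on 5% of genes, applied only to Su
alleles of HMtSc hybrids in YP-glycerol at 28 °C (the condition where the
retained mtDNA matters most in this system). Counts are drawn
NB(mean = true mean × library factor, dispersion α = 0.1); library factors
are log-normal (sd 0.15) and expression is calibrated so the average
expected library is `lib_size_mean` (default 200,000 counts/sample; the
analysis drivers and benchmarks use 40,000–60,000, a desk-scale depth chosen
so that per-allele means stay in the regime where the NB engine is
exercised meaningfully). True means exclude the library factor, so planted
fold-ratios are exact in the truth table and the library factor is exactly
what size-factor normalization must recover.

**Reads.** One single-end read per counted transcript copy, uniform start
within the gene, i.i.d. substitution errors at `seq_error_rate` (default
0.005), constant quality. Headers encode the true origin for evaluation
only. Limitations by design: no introns/splicing, no indels (the assignment
stage is substitution-based), no strandedness, no quality modelling, no
3'/coverage bias, no dosage difference between diploid parents and hybrid
subgenomes. Passing tests therefore demonstrate the pipeline's correctness
under its own model assumptions, not robustness to artefacts of real
libraries (mapping bias, GC effects, batch structure).

## Read assignment

The combined reference concatenates both genomes with species-namespaced
chromosome ids; coordinates are 0-based half-open internally, converted to
1-based inclusive in GFF3 I/O. K-mers (default k = 31) are packed 2 bits per
base into int64 and indexed by sorted arrays with binary search. A read is
seeded at three offsets (both strands), candidate loci are verified over the
full read, and the read is `unique` only when a single locus has strictly
fewer mismatches (≤ `max_mismatch`, default 2 for 75 bp) than every other
candidate; tied loci — including the exact twin gene in the other
subgenome — make it `multimapped` and it is discarded, never broken
randomly. Consequences tested: at zero divergence the genic unique fraction
is exactly 0; at 5% divergence > 99% of unique assignments land on the true
subgenome. Counting is union-style: a unique read overlapping exactly one
annotated gene (strand-blind) increments it; 0 or ≥ 2 overlaps become
`ambiguous_feature`. A read with all three seeds corrupted by errors is
reported `unmapped`; at the default error rate this loses < 2% of reads.

## Orthology

Genes are compared by the Jaccard index of their k-mer sets (k = 15, shorter
than the assignment k because tolerance to divergence matters more than
specificity here), computed sparsely via an inverted k-mer index. Reciprocal
best hits above a 0.05 score floor become one-to-one pairs; a leftover gene
whose best partner is already paired attaches to it as one-to-many if it
clears the floor. Exact best-hit ties disqualify a gene from RBH (reported
unpaired with a tie flag) — determinism over recall. The analysis universe
for all allele comparisons is the paired set only.

## The NB differential-expression engine

Size factors are median-of-ratios over genes positive in every sample, with
a library-size fallback (warned) when no such gene exists. Dispersion:
per-gene method-of-moments `α̂ = max(0, (s² − m̄)/m̄²)` with the variance
pooled within replicate groups, a gamma-family regression of `α̂` on the
mean fitting the trend `α(m) = a₁ + a₀/m`, and shrinkage of log α̂ toward
the log trend with weight 0.2 on the per-gene value (raw estimates floored
at 5% of the trend first, so `α̂ = 0` genes land just below the trend
instead of collapsing to the 1e-8 floor). The weight reflects that 3v3
replication carries little per-gene information; it leaves the 3v3 null
type-I error at the nominal 5% (measured ≈ 0.05 across seeds) while keeping
power ≥ 0.8 for 4-fold changes at mean 100.

The test is the exact conditional NB construction: group sums are modelled
as NB with a common per-unit mean `q` fitted from the pooled data, means
`q·Σs_j` and variances `Σ(q s_j + α q² s_j²)`; conditional on the observed
total `T`, the two-sided p-value is the mass of all splits `(a, T−a)` whose
joint probability does not exceed the observed one (a `1 + 1e-7` relative
tolerance guards floating-point ties; Poisson is used when the variance
does not exceed the mean). Zero totals give p = 1. Log2 fold changes use
normalized group means with pseudocount 0.5. Significance is `p < 0.05` and
`|log₂FC| > 1` on raw p-values — deliberately no multiple-testing gate,
matching the thresholds this battery is anchored on; BH-adjusted values are
emitted alongside for users who want them. Scale invariance holds at the
decision level: multiplying one sample's counts by a constant leaves calls
essentially unchanged, though individual p-values shift slightly because
the test conditions on integer totals.

## Allele comparisons

For each condition and subgenome the panel tests hybrid-vs-parent
(per mitotype) and mitotype-vs-mitotype. Diploid parents and single hybrid
subgenomes differ in gene dose; every subgenome column is normalized as a
full sample and the dosage difference is deliberately left uncorrected — a
documented caveat of the comparison, not a bug. A missing condition is
reported absent, not zero. Allele preference treats the Sc-allele and
Su-allele rows of the same hybrid samples as two sample groups under the NB
machinery (the pairing of columns is ignored by the test — a conservative
construction of our own, stated as such). Sample structure uses PCA (SVD of
the gene-centered log2-normalized matrix) and average-linkage clustering on
1 − Pearson distance, serialized as Newick; the subgenome-expanded matrix
(one column per sample × subgenome over pair anchors) is the intended
input, so each subgenome is a point, and the dominant planted factor
(medium) separates on PC1.

## Co-expression network

Profiles are per-allele log2(hybrid/parent) means over the 8 condition ×
mitotype cells, replicates averaged after normalization (whether the
original analysis correlated per-replicate or averaged profiles is unstated;
averaging is our documented choice). Edges require Pearson r ≥ 0.98 and
two-sided p ≤ 0.05 from the t-transform with n−2 df; at n = 8 cells the r
threshold is binding (r = 0.98 gives p ≈ 2 × 10⁻⁵), so the p threshold is
effectively decorative — retained for fidelity to the stated rule. The
graph is unweighted; zero-variance profiles are excluded with a warning;
isolated nodes are dropped. At desk scale with this strict threshold the
demo network is small and sparse — consistent with the original analysis,
where only ~1000 of ~10,600 alleles entered the network.

Communities come from igraph's Pons–Latapy walktrap (steps = 13, cut at
maximum modularity); nodes are sorted lexicographically before graph
construction so labels are invariant to input order. On all ≤ 8-node
fixture graphs the chosen cut reaches ≥ 90% (measured: 100%) of the
exhaustive maximum modularity over all set partitions. Degree distributions
are fitted by the discrete power-law MLE (zeta-normalized likelihood,
x_min = 1 to cover the full degree range; x_min selection by KS
minimization is available), with goodness assessed by a parametric KS
bootstrap at 20–50 replicates — enough for a coarse plausibility p-value,
which is all a goodness test of this kind supports. Note the discrete MLE
is not invariant under support rescaling (doubling all degrees with
x_min = 2 shifts γ̂); that invariance belongs to the continuous Pareto
family only. Cluster composition is tested against the network-wide Sc:Su
ratio by exact binomial test, flagging clusters > 90% one allele type;
enrichment is the hypergeometric tail with BH adjustment over user-supplied
annotation.

## Mitotype tools

Restriction digestion scans the forward strand with IUPAC expansion and a
regex lookahead (overlapping sites are all found), cutting `offset` bases
into each site; for the built-in enzymes this loses nothing (GANTC is its
own reverse complement, AAGCTT is palindromic). Fragment patterns must
match a parent exactly by default (`tolerance` accommodates gel-estimated
lengths). A hybrid is called for the parent all informative markers agree
on; marker disagreement → recombinant; a pattern matching neither parent →
undetermined; markers with identical parental patterns are excluded as
uninformative. Retention splits are tested against a 50:50 null with the
exact binomial goodness-of-fit test in the two-sided minlike convention
(sum of point probabilities ≤ the observed one — the convention of standard
exact-test implementations); the one-sided tail p is reported alongside,
because published significance stars for such tables are not always
reproducible under a single convention. The packaged cross table (2 media ×
3 temperatures; 202 crosses, 82 hybrids) ships as TSV and drives the
inheritance summary.

## Problem sizes and numerical choices

Benchmarks and tests run at fixed desk-scale sizes chosen once: 1000 genes
for assignment and orthology recovery, 2000 null + 1000 planted genes for
DE calibration, 1000 genes with a 10% interaction fraction (= 100 planted
Su alleles) for the panel recovery, 2000 draws for power-law recovery, 50
synthetic hybrids for RFLP calls. Dispersion floor 1e-8; k-mer packing
limits k ≤ 31; RBH score floor 0.05; pseudocount 0.5 on normalized means;
community tie-breaks by lexicographic node id. All randomness flows from a
single seed through spawned generators; identical configurations produce
byte-identical FASTA/GFF3/FASTQ output.

## Known limitations

No GLM with covariates, shrunken fold changes, or outlier refitting in the
DE engine; no spliced or indel-tolerant alignment; no protein-level or
synteny-aware orthology; no gel-image analysis or mtDNA assembly. The
synthetic generator's fidelity limits are listed above; conclusions about
real hybrid RNA-seq data require the usual caution about mapping bias and
dosage.
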