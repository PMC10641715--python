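# Methods

This note records the statistical conventions, the synthetic-data model and
the numerical choices behind `rgenescape`, in the spirit of a methods
appendix: what each stage computes, under which assumptions, and what the
tests do and do not demonstrate.

## Data model

The unit of analysis is a gene × library matrix of TPM (transcripts per
million). TPM is length- and depth-normalized, so every library column sums
to 10^6; the package treats that invariant as a contract (`is_tpm_normalized`,
relative tolerance 1e-6) and re-establishes it after simulation
(`renormalize_to_tpm`). Because TPM is compositional, any per-library scalar
effect cancels under normalization — a point that shapes both the simulator
(batch effects must be gene-specific) and the interpretation of fold
changes (a strong responder dilutes every other gene in its library).

Metadata carries the experimental factors used as ANOSIM groupings:
BioProject (the archive-level submission, i.e. the lab/batch factor),
tissue, treatment class (mock / pathogen / beneficial), organism and its
kingdom/lifecycle, days post infection, cultivar status, sequencing layout
and a 5-level relative depth category. Mock libraries must carry the null
organism. Gene annotation stores 0-based half-open coordinates (readers
convert 1-based inclusive genome-browser tables behind a flag) plus the
R-gene and full-length (NBS+LRR) flags. Genes without a known chromosome
can never be assigned a physical-cluster status other than "unknown".

Outlier libraries are removed only via an explicit exclusion list passed to
`validate_dataset` — never automatically — so a re-run of a published
analysis states its exclusions in config.

## Expression profiling

* **Off rule.** TPM < 1 is "off" and set to zero; TPM = 1 is kept.
* **Classes.** Six lower-inclusive bins: [0,1), [1,10), [10,50), [50,200),
  [200,1000), [1000,∞). They partition the non-negative reals; per-library
  class counts must sum to the gene count (tested).
* **Breadth and core.** Breadth = fraction of libraries with TPM ≥ 1.
  The core set uses a strict breadth > 0.90. Raising the cutoff can only
  shrink the set (tested monotonicity).
* **Resampling.** For each library and each of 100 replicates, a random
  gene set of the size of the R-gene repertoire is drawn uniformly without
  replacement from all genes (R-genes included by default; an
  `exclude_gene_ids` argument removes them). The replicate statistic is the
  mean TPM of the expressed (TPM ≥ 1) sampled genes by default — a flag
  switches to all sampled genes, since either reading of "average TPM of
  expressed genes" is defensible. The observed focal-set mean is located
  within the replicate distribution as an empirical quantile per library.
* **Gated two-sample test.** Normality per sample via Shapiro–Wilk
  (n ≤ 5000) or Anderson–Darling (n > 5000) at a 0.05 gate; if both pass, a
  t-test whose pooled/Welch choice follows Levene's test at 0.05 (the
  variance test in the original workflow is not identifiable, Levene is the
  declared stand-in); otherwise a two-sided Mann–Whitney U (exact for
  tie-free samples with both n ≤ 8, normal approximation with tie
  correction otherwise). A constant sample is treated as non-normal.
* **Spearman correlations** use average ranks; constant input returns a
  missing rho with a warning rather than raising, so batch runs survive
  degenerate libraries.

## ANOSIM

Distances are Euclidean on log10(x+1)-transformed TPM, optionally
restricted to a gene subset (e.g. the R-gene repertoire). The base of the
log only rescales distances; since R is rank-based it is invariant under
any strictly monotone transform (tested by squaring the distances). All
M = N(N−1)/2 distances are ranked with average ranks for ties and

    R = (mean between-group rank − mean within-group rank) / (M/2).

The permutation test shuffles labels uniformly; p = (1 + #{R_perm ≥
R_obs}) / (1 + n_perm) so p is never 0. When the number of distinct label
assignments (a multinomial coefficient) is ≤ 10 000, the full distribution
is enumerated instead and p is exact; comparisons count R_perm ≥ R_obs with
a 1e-12 tolerance to absorb float noise in tied ranks. Groups of size 1 are
dropped per factor with a warning; factors left with fewer than two groups
are skipped. Every factor in a screen shares the same distance matrix.
Agreement of the R statistic with scikit-bio's independent implementation
is asserted to 1e-12 in the tests; scikit-bio is never used in the
computation itself.

## Physical clustering

R-genes with known positions are sorted by (chromosome, start) and chained
whenever consecutive start-to-start distances are ≤ 200 kb (single
linkage). Chains of ≥ 2 genes are clusters (`chrom:index` ids); the rest
are singletons. Start-to-start single-linkage chaining is declared
explicitly because "within a 200-kb region" admits several readings; the
transitive closure means two cluster members can be farther apart than the
window. The implementation is tested against a brute-force
connected-components oracle on the pairwise ≤-window graph (1000 random
annotations) and for row-order invariance and window monotonicity.

## miRNA target scoring

The scorer (`mir482_v1`) aligns the miRNA 5'→3' against the reverse
complement of a candidate site and sums penalties: mismatch 1.0, G:U wobble
0.5, gap 2.0 (at most one gap, i.e. site length within ±1 of the miRNA),
with penalties at miRNA positions 2–13 (the seed) multiplied by 1.5. A
perfect reverse-complement site scores 0, and any mismatch strictly
increases the score. Predictions keep the minimum-score window per
(miRNA, CDS) pair at expectation ≤ 3. The scheme is an explicit, versioned
approximation of the public psRNATarget-style scoring family — the exact
server internals are not reproducible — so its parameters live in a config
object rather than constants. Enrichment of target status against gene
categories uses Pearson's χ² on 2×2 tables, uncorrected by default (a
Yates flag exists because conventions differ), df = 1.

## Differential expression stand-in

Transcript-level count models need quantifier bootstrap output that a TPM
table no longer carries. The stand-in (`welch_log2tpm_v1`) is therefore a
fully specified gene-level procedure: within each (BioProject, tissue, dpi)
stratum with ≥ 2 replicates per arm, a Welch t-test on log2(TPM+1) between
treated and mock, per-arm variances floored at 1e-8 so clean separations
yield finite statistics, genes with equal means and zero variance assigned
p = 1 (kept, so the BH family size is stable), Benjamini–Hochberg across
all tested genes, directions called at FDR ≤ 0.05. The test is
antisymmetric under arm swap and BH is monotone (both tested). Summaries
pool gene × contrast occurrences: proportion DE among R-genes vs the rest,
up/down balance among DE R-genes with an exact two-sided binomial test of
0.5, and |log2FC| comparisons via the gated two-sample test.

## Population genetics

π is the average pairwise proportion of differing sites (no n/(n−1)
correction; the convention is stated here and in output metadata), skipping
sites with a gap or N in either member of a pair. Between-group divergence
K averages pairwise p over all between-group pairs and applies the
Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3) to the mean (undefined and
reported missing at p ≥ 0.75). Nei–Gojobori counting uses unweighted
pathways: synonymous site fractions per codon position (changes to stop
codons count as nonsynonymous), site counts averaged over the two
sequences, differences averaged over all orderings of the changed
positions with pathways through stop codons excluded (falling back to all
pathways only if every ordering is blocked). Codons with a gap or N in
either sequence are skipped; a shared terminal stop codon is dropped; an
internal stop is an error. dN/dS agree with Biopython's NG86 implementation
to 1e-9 on random stop-free pairs (test-only cross-check). πa/πs averages
uncorrected pairwise pN and pS over within-species pairs; the ratio is
missing when πs = 0.

## Synthetic data model

Raw abundance of gene g in library l is log-normal with additive log-scale
effects:

    a_gl = exp(μ_g + b_{g,B(l)} + t_{g,T(l)} + ε_gl) · 2^{s_g·fc·I[l treated]}

* μ_g ~ Normal(0, 1.5) for the genomic bulk; R-genes are shifted down by 3
  ln-units (most of the repertoire sits near or below detection — with the
  defaults ~36% of R-gene × library cells are below TPM 1 and per-library
  expressed fractions resemble the 30–50% range seen in crop compendia).
* planted core genes (default 6.25% of R-genes) draw μ from
  Normal(5.7, 0.5), keeping them far above TPM 1 in every library; planted
  off genes (default 20%) are exactly 0 everywhere.
* b (gene × BioProject) ~ Normal(0, 1.0) and t (gene × tissue) ~
  Normal(0, 0.5): effects are gene-specific because uniform per-library
  shifts cancel under TPM renormalization.
* ε ~ Normal(0, 0.25) per cell; planted responders (default 40 R-genes)
  get a ±2 log2 fold change in non-mock libraries, 72.5% of them upward,
  applied before TPM renormalization so compositional distortion is
  present as in real data.

Libraries are allocated evenly to BioProjects; within a BioProject they
come in blocks of one mock arm and one pathogen arm (default 3 replicates
each) sharing tissue and dpi, so DE pairing always finds complete strata.
Only pathogen arms are simulated by default; "beneficial" remains a valid
metadata category exercised on constructed tables. All randomness flows
from one `numpy` generator seeded by the config, and identical configs
yield bitwise-identical datasets.

What the generator does **not** emulate: count-level sampling noise
(abundances are continuous), quantifier uncertainty, correlated gene
modules, library-size pathologies, or annotation errors. Passing recovery
tests therefore demonstrates correctness of the analysis logic under the
declared model, not robustness to every failure mode of real compendia.

## Problem sizes and benchmark scenarios

* **Core-set recovery** uses a high-separation study (4000 genes, 400
  R-genes, 100 libraries, 25 planted core / 80 planted off, baseline sd
  0.5, R-gene shift −6): separations are large enough that no bulk R-gene
  can reach breadth > 0.9 by chance (max observed 0.44), so recovery of
  exactly the planted 25 is a sharp pass/fail. The package defaults keep a
  heavier tail, under which a realistic "emergent" core larger than the
  planted set appears (see the README example).
* **Factor-ordering benchmark**: 600 genes / 150 R-genes / 36 libraries /
  4 BioProjects / 3 tissues with planted effect hierarchy bioproject
  (sd 1.5) > tissue (sd 0.6) > treatment (log2FC 1 on 30 genes);
  R(bioproject) > R(tissue) > R(treatment) must hold in ≥ 15 of 20 seeds.
* **DE power benchmark**: |log2FC| = 2, noise sd 0.5, 4 vs 4 replicates on
  a 400-gene panel with 100 responders; sensitivity at FDR 0.05 is ≈ 0.88
  (asserted ≥ 0.8 over 20 seeds). The responder fraction matters: the BH
  threshold scales with the discovery count, and at a 4–5% responder
  fraction this effect size cannot reach 0.8 sensitivity with n = 4 — the
  panel design mirrors a focused contrast rather than a genome-wide scan.
  The null-calibration benchmark is genome-scale: 2000 genes, 3 vs 3, 20
  seeds, mean discovery fraction ≤ 0.05.
* **Permutation-p calibration**: sampled (999-permutation) p is compared
  with the exhaustively enumerated p on 200 random ≤ 6-library instances;
  individual deviations are bounded by 3 Monte-Carlo standard errors plus
  the add-one bias, allowing the ≤ 2 excursions expected by chance among
  200 three-sigma bounds.

All benchmark sizes were chosen to make the full test suite run in well
under a minute of CPU on a single core while keeping every stochastic
assertion far from its threshold.

## Known limitations

* The DE stand-in ignores quantifier uncertainty and transcript-level
  structure; its summaries are validated on synthetic data only.
* The miRNA scorer approximates, but does not reproduce, any specific
  public server's output; only the ranking behaviour and the ≤ 3 cutoff
  semantics are contractual.
* ANOSIM assumes exchangeability of libraries under the null within the
  screened factor; with confounded factors (BioProject vs cultivar vs
  organism, as in real compendia) high R values identify association, not
  cause.
* The 200-kb rule is strand-agnostic and start-based; tiling-window
  variants would produce different partitions.
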