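# rgenescape

Meta-analysis toolkit for the expression of plant resistance genes
(*R*-genes, chiefly NBS-LRRs) across heterogeneous bulk RNA-seq libraries.

Cross-lab transcriptome compendia make it possible to ask whether *R*-genes
are induced by pathogen attack or constitutively expressed — but the answer
hinges on careful descriptive statistics over TPM matrices collected under
wildly different designs. `rgenescape` packages that analysis as a tested,
reusable pipeline for anyone profiling defence-gene repertoires across
public libraries:

- **Expression profiling** — the TPM < 1 "off" rule, six ordered expression
  classes (`[0,1) [1,10) [10,50) [50,200) [200,1000) [1000,∞)`), per-gene
  expression breadth, and the **core set**: genes expressed (TPM ≥ 1) in
  more than 90% of libraries. Random-gene-set resampling (100 replicate
  sets per library) compares the *R*-gene repertoire against size-matched
  random sets, with a normality-gated two-sample test (Shapiro–Wilk /
  Anderson–Darling gate, then t-test or Mann–Whitney U) and Spearman
  correlations.
- **ANOSIM** — analysis of similarities from first principles: log10(x+1)
  transform, Euclidean distances between libraries, tie-aware ranking, the
  statistic R = (r̄_between − r̄_within)/(M/2) ∈ [−1, 1], and a permutation
  test (999 label shuffles by default, exhaustive enumeration on small
  designs), screened factor by factor (BioProject, tissue, treatment, dpi, …).
- **Differential expression** — treated-vs-mock contrasts per
  (BioProject, tissue, dpi) stratum, a fully specified gene-level stand-in
  test (Welch t on log2(TPM+1), `welch_log2tpm_v1`), Benjamini–Hochberg FDR,
  and the downstream summaries (proportion DE, up/down balance with an
  exact binomial test, |log2FC| comparisons).
- **Physical clustering** — the 200-kb chaining rule: two or more *R*-genes
  whose starts chain at ≤ 200 kb on one chromosome form a cluster.
- **miRNA targeting** — an expectation-style penalty scorer for
  miR482/2118-family sites on CDS sequences (mismatch 1, G:U wobble 0.5,
  gap 2, seed positions 2–13 ×1.5, expectation ≤ 3 cutoff) plus χ²
  enrichment tests of target status against gene categories.
- **Population genetics** — π, Jukes–Cantor-corrected divergence K, and
  Nei–Gojobori πa/πs / Ka/Ks for the wild-relative sub-analysis.
- **Synthetic data** — a seeded generator of full studies (TPM matrix +
  metadata + annotation) with planted core/off/responder genes and
  gene-specific BioProject and tissue effects, so every stage can be tested
  against known ground truth.

## Worked example

```python
from rgenescape import SimulationConfig, simulate_dataset
from rgenescape.profiling import expression_breadth, core_set
from rgenescape.anosim import factor_screen

cfg = SimulationConfig(n_genes=1000, n_r_genes=200, n_libraries=48,
                       n_bioprojects=4, n_de_r_genes=20, seed=7)
dataset, truth = simulate_dataset(cfg)

breadth = expression_breadth(dataset.matrix)          # TPM >= 1 rule
core = core_set(breadth.loc[dataset.r_gene_ids()])    # breadth > 0.90
print(f"core R-genes: {len(core)} (planted: {len(truth.core_gene_ids)})")

results = factor_screen(dataset, ["bioproject", "tissue", "treatment_class"],
                        gene_subset=dataset.r_gene_ids(),
                        n_permutations=999, seed=0)
for r in results:
    print(f"{r.factor:16s} R = {r.r:6.3f}   p = {r.p_value:.3f}")
```

prints

```
core R-genes: 82 (planted: 12)
bioproject       R =  1.000   p = 0.001
tissue           R =  0.639   p = 0.001
treatment_class  R =  0.168   p = 0.001
```

The core set contains all 12 planted always-on genes plus *R*-genes whose
log-normal baselines happen to clear TPM ≥ 1 in >90% of libraries — exactly
how a core emerges from real data. The factor screen recovers the planted
effect hierarchy: the batch factor (BioProject) dominates, tissue is
intermediate, and the treatment signal (carried by only 20 responder genes)
is weak — the qualitative picture that motivates treating cross-lab batch
structure, not infection status, as the first-order driver of *R*-gene
expression variation.

The same stages are available from the shell:

```bash
rgenescape simulate --seed 3 --out-prefix sim/
rgenescape profile  --matrix sim/matrix.tsv --meta sim/metadata.tsv \
                    --annot sim/annotation.tsv --out-prefix prof/
rgenescape anosim   --matrix sim/matrix.tsv --meta sim/metadata.tsv \
                    --annot sim/annotation.tsv --perms 999 --seed 1 --out anosim.tsv
rgenescape de       --matrix sim/matrix.tsv --meta sim/metadata.tsv \
                    --annot sim/annotation.tsv --out-prefix de/
rgenescape clusters --annot sim/annotation.tsv --out clusters.tsv
```

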