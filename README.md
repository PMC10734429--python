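# forageome

Analysis pipeline linking individual **foraging phenotype** to **gut-microbiome
structure and body-condition gain** in a longitudinal 16S rRNA ASV study of
spring-staging geese, plus a synthetic-study generator that reproduces the
study design so every stage can be verified against known ground truth.

## The scientific problem

Spring-staging geese split into three foraging phenotypes: **marine
specialists** (intertidal eelgrass/algae), **terrestrial specialists**
(managed grassland), and **switchers** that move between both. The pipeline
asks, from faecal 16S ASV counts and field observations:

1. Does richness differ across phenotypes? (rarefaction, balanced bootstrap)
2. Does community composition differ, and how variable is each group?
   (CLR + Euclidean PERMANOVA, PCA, multivariate dispersion)
3. How are taxa shared among phenotypes? (bootstrap Venn partition,
   bipartite network, permutational Jaccard *t*-tests, IndVal)
4. Are individual microbiomes stable over time? (distances to individual
   centroids, bird-blocked permutation test)
5. Does phenotype predict the rate of body-mass gain? (random-intercept LMM
   of the abdominal profile index, AICc dredge with six-unit and nesting
   rules)

## Core statistics

- **CLR transform**: clr(x)ᵢ = ln((xᵢ+c)/g(x+c)) with pseudocount c = 1;
  Euclidean distance on CLR coordinates is the Aitchison geometry, so no
  reads are discarded to rarefying.
- **PERMANOVA**: SS partition on squared distances (Anderson), pseudo-F =
  (SS_B/df_B)/(SS_W/df_W), p = (b+1)/(m+1) over label permutations.
- **Dispersion**: per-sample distance to the group centroid in the
  principal-coordinate embedding; one-way F with permutation p, Tukey HSD
  pairwise CIs with Bonferroni adjustment.
- **Jaccard t-tests**: Welch t between categories of sample pairs
  (same-phenotype, switcher–specialist, different-specialist), null built by
  permuting phenotype labels over *birds* so repeat samples move together.
- **IndVal** (Dufrêne–Legendre): specificity × fidelity, permutation p.
- **LMM engine**: Gaussian random-intercept models fitted by profile
  likelihood over λ = σ²_bird/σ²_resid; ML for AICc/LRT, REML available;
  AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting fixed effects + 2
  variance parameters.

## Worked example

Generate a default synthetic study and run the full analysis:

```bash
python analysis/01_simulate_study.py
python analysis/02_filter_and_phenotype.py
python analysis/03_alpha_diversity.py
python analysis/04_beta_diversity.py
python analysis/05_taxa_sharing.py
python analysis/06_stability.py
python analysis/07_condition_model.py
```

Representative output (seed 17072020):

```
[filtering] removed 6 chloroplast/mitochondria/archaea ASVs
[filtering] flagged 15 negative contaminant ASVs
[filtering] removed 19 samples with < 5000 reads
richness ordering (balanced bootstrap means): marine > switcher > terrestrial
[beta] PERMANOVA F=18.809 R2=0.260 p=0.001
mean distance to group centroid (tightest first):
terrestrial    14.77
switcher       25.52
marine         32.78
per-bird mean PC1 ~ prop_marine: slope 26.39 (95% CI 22.90-29.88, n = 56 birds)
  phenotype  slope_zday    se
     marine       0.538 0.159
terrestrial       1.213 0.087
   switcher       0.579 0.106
phenotype x day interaction: X2 = 24.686, df = 2, p = 4.36e-06
```

Reading this: the three phenotypes differ in composition (PERMANOVA
R² = 0.26), terrestrial communities are the least variable (smallest mean
distance to centroid), birds using more marine habitat sit higher on PC1
(positive slope), and terrestrial specialists gain condition fastest over
the staging window (largest day slope), with a clearly supported
phenotype × day interaction.

The same analysis runs as one command through the CLI:

```bash
forageome run --simulate --out results/run
forageome stage beta --out results/run      # re-run a single stage
```

On real data, supply the four input TSVs instead:

```bash
forageome run --asv-table counts.tsv --taxonomy tax.tsv \
    --metadata meta.tsv --resightings resight.tsv --out results/real
```

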