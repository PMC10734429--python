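# Methods

This note documents the models, numerical choices and design decisions
behind the pipeline, and what the synthetic-data generator does and does not
emulate.

## Study design being modelled

A spring-staging population of individually marked geese is observed daily
over a ~31-day May window (day of year 121–151). Each bird accumulates
resighting events (habitat: marine or terrestrial); birds seen at least five
times are classified as marine specialists, terrestrial specialists
(one habitat only) or switchers (both habitats at least once). Faecal
samples (1–4 per bird) are sequenced for 16S ASV counts; negative extraction
controls are sequenced alongside. Each sample carries the bird's abdominal
profile index (API, ordinal 1–7), sex, day and habitat at collection.

## Filtering

1. **Taxonomic pruning** removes ASVs whose taxonomy matches chloroplast,
   mitochondria or archaea at any rank, case-insensitively.
2. **Contaminant identification** follows the prevalence logic of
   decontam: for each ASV a 2×2 presence table (negative controls vs true
   samples) is scored by a one-sided chi-square test, or Fisher's exact test
   when any expected cell is below 5, oriented so ASVs over-represented in
   controls get low scores. An ASV is removed when its score is below the
   threshold (default 0.5) *and* its control prevalence exceeds its sample
   prevalence. The direction condition matters: abundant real taxa bleed
   into blanks at trace levels, and without it they would be flagged.
3. **Depth filtering** removes samples with fewer than 5,000 reads; a
   sample with exactly 5,000 is retained ("fewer than" is strict). The
   common rarefaction depth equals this threshold, the point where
   sample-coverage curves plateau in data of this kind. This is an
   interpretation: the original coverage plateau is not stated numerically.

## Alpha diversity

Richness is standardised by hypergeometric rarefaction (interpolation
only): E[S_m] = Σᵢ [1 − C(n−nᵢ, m)/C(n, m)], evaluated with log-gamma.
Sample coverage is the Good–Turing estimator
Ĉ = 1 − (f₁/n)·[(n−1)f₁/((n−1)f₁+2f₂)]. Group comparisons are balanced to
the minimum group size: per iteration, min-group-size birds per phenotype
are drawn **without replacement** and one random sample per chosen bird
contributes, with fresh randomness across the 1,000 iterations. (Whether
the subsample of birds should be with or without replacement is
under-determined for this step; without replacement makes each iteration a
genuine subsample of distinct birds. The taxa-sharing bootstrap, by
contrast, draws birds **with** replacement, as a bootstrap.) The group-level
inference on richness uses the same Gaussian random-intercept engine as the
condition model rather than a Bayesian fit; contrasts and intervals are
Wald-based. This is a documented deviation: the scientific quantity (group
contrasts with uncertainty) is the same.

## Beta diversity

Counts are CLR-transformed after adding a pseudocount of 1 (the simplest
reproducible convention; exposed in `RunConfig`). ASVs with zero total
count are dropped first. All distances are Euclidean on CLR coordinates.

- **PERMANOVA** uses Anderson's direct SS partition on squared distances.
  Permutations are free (unrestricted) by default, treating repeat samples
  of a bird as exchangeable — matching the common adonis2 usage for this
  design — with an optional `strata` argument restricting permutations
  within blocks for sensitivity analyses. p-values use (b+1)/(m+1), so a
  permutation p is never exactly zero.
- **Pairwise PERMANOVA** runs the same machinery on each unordered pair of
  phenotypes with per-pair derived seed streams and Bonferroni adjustment.
- **Dispersion** embeds the distance matrix by PCoA (negative-eigenvalue
  axes subtract in squared distance, as in betadisper), measures each
  sample's distance to its group **centroid** (not spatial median), tests
  the omnibus with a one-way F whose null distribution comes from permuting
  those distances, and reports pairwise Tukey HSD differences with 95% CIs
  plus Bonferroni-multiplied p-values. Both raw Tukey and Bonferroni values
  are emitted because the combined error-rate handling of "Tukey with
  Bonferroni correction" is ambiguous; readers can use either.
- **PCA** is the eigendecomposition of the CLR sample covariance. The PC1
  sign is fixed so terrestrial-collected samples have negative mean score;
  without a convention the sign is arbitrary and the PC1~prop_marine slope
  would be irreproducible.

## Shared and unique taxa

The Venn partition of ASVs into the seven subsets (M, T, S, MT, MS, TS,
MTS) is estimated by bootstrap: each of 1,000 iterations draws
min-group-size birds per phenotype **with replacement**, one random sample
per drawn bird, pools presence per phenotype, and classifies every ASV
present that iteration. Percentages are of ASVs present in that iteration,
so cells sum to 100% exactly. One iteration is flagged for the bipartite
network export (phenotype and ASV nodes; an edge when the ASV occurs in any
pooled sample of that phenotype).

Jaccard indices use presence = count > 0; two identically empty samples
have J = 1 by convention. The three pair categories are same-phenotype
(marine–marine / terrestrial–terrestrial), switcher–specialist, and
different-specialist (marine–terrestrial); within-individual pairs are
removed and switcher–switcher pairs belong to no category. The test
statistic is a Welch two-sample t between category means; the null permutes
phenotype labels **over birds**, not over pairs or samples, because pairs
sharing a sample are dependent and a pair-level shuffle would destroy that
structure (a sample-level permutation is available behind a flag for
comparison). Permutations that empty a category are redrawn and counted.
Two-sided p-values throughout. The conventional seed 17072020 is the
default stream seed for this stage.

Core taxa require presence at ≥ 1e-5 relative abundance ("0.001%" read
literally as the fraction 1e-5 — this choice changes the core set and is
flagged prominently) in ≥ 70% of samples, computed on unrarefied presence.
IndVal is reported on the 0–1 scale with a percentage convenience column;
its permutation null is bird-blocked for the same reason as the Jaccard
test.

## Within-individual stability

For birds with ≥ 2 retained samples, each sample's Euclidean distance to
the bird's own CLR centroid measures short-term turnover. Group differences
are modelled as distance ~ phenotype with a bird random intercept; the
omnibus statistic is the Wald F of the phenotype coefficients with p from a
bird-blocked label permutation. Distances are strictly positive; the model
is Gaussian on the raw scale by default with a log-transform option (the
choice is recorded in the output). Denominator degrees of freedom are
reported from the data supplied, not forced to any particular value.

## Condition (API) model

API is treated as Gaussian despite being ordinal 1–7, matching standard
practice for this index; an ordinal extension is out of scope. Day of year
is z-standardised on the analysis subset (sample sd, n−1) and the transform
stored so predictions are expressed on raw days. The global model is

    api ~ phenotype + sex + zday + zday² + phenotype:zday + (1 | bird)

The dredge enumerates all 16 marginality-respecting term subsets
(zday² requires zday; the interaction requires both mains), fits each by
ML, ranks by AICc with k = fixed effects + 2 variance parameters (the MuMIn
convention — rankings depend on k, so this is stated explicitly), retains
models within six AICc units of the best, and then applies the nesting
rule: a retained model is dropped if a retained strict subset of its terms
has lower AICc. ML is used for selection and likelihood-ratio tests; REML
is available for reporting final variance components.

The engine itself profiles the likelihood over λ = σ²_bird/σ²_resid. For
fixed λ, V⁻¹ is a per-group rank-one update of the identity, so X'V⁻¹X,
X'V⁻¹y and y'V⁻¹y are computed from group sums in O(np²) and the GLS
solution is closed-form; λ is optimised by bounded scalar search on log λ
over [e⁻¹², e⁸] with the λ = 0 boundary checked explicitly. Wald SEs come
from σ̂²(X'V⁻¹X)⁻¹. Degenerate fits (zero residual variance) are floored at
a 1e-10 relative residual to keep the likelihood finite.

## The synthetic-data generator

Defaults emulate the study conditions: ~60 sequenced birds (phenotype
probabilities 0.16/0.52/0.32 marine/terrestrial/switcher, each represented
phenotype forced to ≥ 6 birds — the smallest real group), 1–4 samples per
bird with mean 2.05, a 121–151 day grid, six negative controls, seven
planted contaminants (prevalence 0.9 in controls, 0.15 in true samples),
six planted chloroplast/mitochondria/archaea ASVs, and ~15% of samples
forced below the 5,000-read threshold.

Counts are Dirichlet-multinomial: a sample's composition is drawn from
Dirichlet(c·p) with phenotype-specific concentration c (marine 50,
terrestrial 250, switcher 60) and then multinomially thinned to a lognormal
read depth. Larger c means tighter communities, which plants the dispersion
ordering (terrestrial least variable). The base compositions are built from
blocks over 500 ASVs: an abundant shared core (40 ASVs), a rare shared tail
(phenotype-weighted mass — marine 0.32, terrestrial 0.05, with terrestrial
bases supporting only 18% of the tail's taxa), and small truly exclusive
pools (60/30/40 marine/terrestrial/switcher). Switcher means are a convex
combination (1−w)·marine + w·terrestrial with w the exponentially
recency-weighted terrestrial fraction of the bird's habitat sequence
(decay 0.7 per day), plus a 12% admixture of the switcher-exclusive pool;
the specialists' exclusive pools enter switcher means only at a 15%
"leak", reflecting that habitat-endemic taxa need sustained exposure.
Under pure convex mixing every specialist taxon would appear in switcher
samples and the unique/shared partition could not reproduce the observed
structure; the leak plus the phenotype-weighted tail plant the unique-share
ordering (marine > switcher > terrestrial) and make marine–switcher the
largest shared cell. Where the real study gives no effect sizes, these
block masses were chosen once for comfortable power at ~100 samples and
are documented here as design constants.

API values come from the exact random-intercept model (intercept 3.2,
female +0.44, zday +0.8, zday² −0.15, terrestrial day-slope +0.5 and
switcher −0.25 relative to marine, σ_bird 0.4, σ_resid 0.5), rounded and
clipped to the 1–7 field scale.

What the generator does **not** emulate: real taxonomic strings beyond
placeholder ranks, sequence-level artefacts (chimeras, length variation),
flock-size behavioural dynamics, temporal autocorrelation of communities
within a bird beyond the switcher mixing weight, and observation error in
API scoring. Passing tests therefore demonstrate that the *methods* behave
correctly under the study's sampling design and effect structure, not that
any particular field dataset will show these effects.

## Verification strategy and problem sizes

- Permutation machinery is checked against independent oracles: the
  Gower-trace SS formula and full enumeration of label assignments on
  8-sample instances; IndVal and centroid distances against naive
  brute-force implementations.
- Type-I error of PERMANOVA, the dispersion omnibus, the bird-blocked
  Jaccard t-tests and the interaction LRT is measured over 500 null
  simulations each, with 199-permutation inner tests (p-granularity 1/200
  makes the nominal 0.05 level exact under exchangeability); the LRT
  harness uses 100 birds, where its asymptotic χ² reference is accurate.
- The LMM engine is checked against closed-form ANOVA components
  (balanced case), OLS in the degenerate one-observation-per-bird limit,
  statsmodels MixedLM, and a 200-replicate parameter-recovery study.
- Pattern recovery (dispersion ordering, unique-share ordering, PC1 slope
  sign, API slope ordering) is measured over 100 default synthetic studies
  with a 200-iteration share bootstrap per study — iteration counts chosen
  so the whole suite runs comfortably on a laptop; the estimates are means
  over iterations, so the reduced count only widens their Monte-Carlo
  noise slightly.

## Known limitations

- The reader requires a `bird_id` for every non-control sample; samples
  that cannot be attributed to a ringed bird must be dropped upstream
  (stricter than field protocols may have been).
- Sightings are counted at day level (same bird, same day, same habitat
  collapses to one sighting); event-level counting would classify a few
  borderline birds differently.
- Free permutation in PERMANOVA treats repeat samples as exchangeable;
  the strata option exists but is not the default.
- The LMM engine supports a single random intercept only — by design, as
  every model used here is of that form.
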