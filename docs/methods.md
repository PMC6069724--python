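# Methods

This note records the statistical model, the algorithmic and numerical
choices, and what the simulation-based validation does and does not show.

## Pairwise interaction model

For a variant pair (i, j) the package fits

    y = μ + β₁ gᵢ + β₂ gⱼ + β₃ (gᵢ·gⱼ) + ε,

the "heterogeneity" form with both main effects and a multiplicative
interaction.  β₃ is the quantity of interest throughout: its magnitude
feeds the network, its two-sided test (t-test with n−4 degrees of freedom
for the linear model, Wald z for the GLM) feeds the significance-based
visualizations.

**Encodings.**  `minor_dominant` codes genotypes as minor-allele dosage
0/1/2 and hypothesizes synergy between minor alleles.  `gradient` codes
them 1/1.5/2 so both allele pairs participate; it is more expressive but
harder to fit, and it has no label-reversal counterpart.  The minor allele
is determined per variant from the observed data, with an exact 50/50
frequency tie broken toward the lexicographically smaller allele character
so encodings are reproducible across runs and file orderings.

**Label reversal.**  Swapping the homozygote labels at the second locus
(gⱼ → 2−gⱼ) expresses the minor×major interaction hypothesis.  Because
gᵢ(2−gⱼ) = 2gᵢ − gᵢgⱼ, the reversed design spans the same column space as
the standard one: the fitted values, the interaction standard error and the
interaction p-value are identical, and β₃ merely flips sign (μ, β₁, β₂
transform as μ+2β₂, β₁+2β₃, −β₂).  The package therefore computes the
standard fit once, derives the reversed parameterization analytically, and
reports each pair in the orientation that carries a positive β₃ — a
deterministic rule that is equivalent to "keep the more significant fit"
under any tie-break, and that keeps null p-values exactly uniform (a
min-over-two-fits rule with floating-point ties would instead randomize
coefficient signs).  A unit test confirms the analytic reversal equals an
explicit refit.

**Linear solver.**  The 4-column design never changes, so ordinary least
squares is solved in closed form from per-pair sufficient statistics (sums
and cross-products of gᵢ, gⱼ, gᵢgⱼ, y), batched across thousands of pairs
per numpy call.  Rank deficiency is detected from the eigenvalue spread of
the 4×4 normal matrix (smallest eigenvalue ≤ 1e−10 × largest); such pairs —
e.g. a monomorphic locus, or an interaction column collinear with a main
effect — are flagged `degenerate`, excluded from the network, and never
crash the scan.  Agreement with statsmodels OLS is enforced in tests at
1e−8 relative on coefficients and 1e−6 on p-values.

**Binary traits.**  Case–control phenotypes (1/0) use a binomial GLM fitted
by IRLS.  The default probit link matches the liability-threshold reading
of a binary trait: a case is a latent Gaussian liability exceeding a
threshold, which is also exactly how the synthetic generator produces
binary phenotypes, making parameter recovery interpretable (a planted
liability-scale β₃ is recovered on the same scale).  Logit is available as
an option.  IRLS stops when the deviance change falls below 1e−10 *and*
the relative coefficient step falls below 1e−8 (deviance alone can flatten
before the coefficients settle on quasi-separated data), capped at 25
iterations; non-convergence or separation (diverging coefficients, fitted
probabilities saturating at the class labels) flags the pair `unstable`
with a missing p-value.  Covariates for binary traits enter this design
directly, because residual pre-adjustment is not valid for 0/1 outcomes.

**Missing genotypes** are dropped case-wise per pair (no imputation): each
pair's model uses exactly the samples with calls at both loci and a
phenotype.  This is the simplest contract consistent with independent
per-pair regressions; fits with fewer than 5 (linear) / 10 (GLM) usable
samples are flagged degenerate.

**p-value floor.**  Exact fits would give p = 0; p-values are floored at
1e−300 so −log₁₀(p) stays finite for the summed-score visualizations.

## Preprocessing

Continuous phenotypes are adjusted once, up front, by ordinary least
squares on the non-genetic fixed effects (sex, age, batch, …): the adjusted
value is the residual plus the grand mean, so the trait keeps its original
scale.  Categorical covariates expand to indicator contrasts; a
rank-deficient covariate design is reported with the names of the collinear
columns.  The optional association pre-filter fits y = μ + βg per variant
(probit GLM for binary traits) and keeps variants with p ≤ a user
threshold; there is deliberately no default threshold — the filter is a
dimensionality-reduction tool, and the appropriate stringency depends on
the computing budget, not on a statistical rule.

## LD filtering

LD is measured as the squared Pearson correlation of genotype dosages over
pairwise-complete samples (composite r²): ped/tped data are unphased, so
haplotype-based measures are unavailable, and for the purpose of removing
redundant interaction models the observed dosage correlation is the
relevant quantity.  Blocks grow greedily left-to-right within each
chromosome: the next variant joins while the mean r² over *all* pairs in
the candidate block stays at or above the threshold; otherwise the block
closes and a new one starts.  Blocks are strictly contiguous and never span
chromosomes.  The member with the highest average r² to its co-members
represents the block (tie → lowest genomic index); the running pair-sum is
maintained incrementally and verified against full recomputation in tests.
A constant dosage vector has undefined r²; block logic treats it as 0.

## Network and modules

**Rescaling.**  β₃ values map to a correlation-like similarity in [−1, 1]:
positives divide by the largest positive β₃, negatives by the magnitude of
the most negative, so the extremes land exactly on ±1 while near-zero
coefficients stay near zero — max-normalization per sign, invariant to any
positive rescaling of the coefficient set.  Degenerate/unstable/absent
pairs contribute 0; the diagonal is 1.

**Adjacency.**  TOM expects a non-negative adjacency with zero diagonal, so
an explicit bridge is inserted: unsigned a = |s|^power (default power 1 — a
pure pass-through of the similarity magnitudes) or signed
a = ((1+s)/2)^power.  Soft powers > 1 suppress background noise the way
soft thresholding does in co-expression analysis.

**TOM.**  tom_ij = (Σᵤ a_iu a_uj + a_ij) / (min(kᵢ, kⱼ) + 1 − a_ij) with
kᵢ = Σᵤ a_iu, computed by one matrix product; an isolated pair with zero
denominator gets 0, the diagonal is 1.  A brute-force triple-loop oracle
bounds the error at 1e−10 in tests.

**Module detection.**  Average-linkage clustering on 1 − TOM, then a
three-stage cut (all stages deterministic):

1. *Adaptive height*: every candidate height between consecutive merge
   levels is scored by the weighted Newman modularity of the resulting
   partition on the TOM graph, and the best height wins.  A fixed fraction
   of the tree height (the common default) proved unable to separate tight
   branches from a connected noise background on realistic scans.
2. *Recursive branch splitting*: each cluster at least twice the minimum
   module size is re-clustered on its own subgraph; the split is accepted
   only if it produces at least two clusters of module size and a
   modularity gain above 0.02 — the guard prevents shattering homogeneous
   modules on noise.
3. *Connectivity cleanup* (the strip/rescue idea of hybrid tree cutting):
   members whose mean within-module TOM falls below 70% of the module
   average are stripped to the unassigned label; unassigned variants at
   least that connected to some module are pulled in; repeated to a fixed
   point (≤5 rounds).

Clusters below `min_module_size` (default 10) end in label 0 (unassigned);
surviving modules are labelled 1, 2, … by decreasing size.  A fixed
`cut_height` bypasses stage 1 for a classic static cut.  The 0.02 gain and
70% connectivity constants were chosen by validating recovery of planted
partitions and are deliberately conservative (favouring fewer, cleaner
modules); they are not exposed as tuning knobs.

**Module–trait correlation.**  Each module is summarized by the mean dosage
of its members and Pearson-correlated with the (adjusted) phenotype.  The
first-principal-component summary used for co-expression modules is
available (`summary="pc1"`), but it is *not* the default here: variants
grouped by interaction need not be mutually correlated in genotype space,
in which case PC1 of their standardized dosages is an arbitrary noise
direction — empirically, a perfectly recovered driver module can show a
PC1–trait correlation of ~0 while its mean dosage correlates at ~0.3
through the marginal associations induced by the interaction terms.
Missing calls are mean-imputed within the summary only.  A single-member
module uses that variant's dosage.

## Synthetic data

The generator emulates the features of array data that the pipeline
actually exercises: biallelic variants under Hardy–Weinberg equilibrium
with configurable MAF range, contiguous LD blocks, uniform missingness, and
phenotypes generated from the same heterogeneity model the scan fits
(planted main effects, planted interactions in either label orientation,
covariate effects, Gaussian noise; binary traits by thresholding the
liability).  LD blocks use copy-with-resample noise: every member copies a
shared latent Hardy–Weinberg genotype with per-sample probability
r²_target^¼, otherwise redrawing at the same allele frequency, so any two
members correlate at √r²_target and every within-block pair has expected
r² equal to the target while the allele frequency is preserved exactly.
Phenotypes are computed from the complete pre-masking dosage matrix, so
missingness is purely an observation process and truth records stay exact.
Everything is deterministic under the spec's seed; dosage columns are
oriented to count the observed minor allele so an in-memory table and its
ped/tped round trip agree bit-for-bit.

What the generator does *not* emulate: realistic demography or coalescent
LD decay (block structure is idealized), genotyping-error models beyond
uniform missingness, allele-frequency spectra, or population structure and
relatedness.  Passing recovery tests therefore demonstrate the
correctness of the machinery under its own model assumptions, not
robustness to confounding in real cohorts — a mixed-model layer for
structure correction is out of scope.

## Validation scenarios and problem sizes

The test suite and `scripts/acceptance.py` use fixed scenario sizes chosen
to give stable statistics on a single CPU: fitter/reference agreement on
1000 random 50-sample instances; planted-effect recovery over 200
replicates (β₃ = 1 at n = 500 for the linear model; liability β₃ = 0.8 at
n = 2000 for the probit GLM); type-I calibration over 2000 null replicates
and p-value uniformity over ~5000 null pairs; module recovery on a
constructed two-block similarity (within 0.9, between 0.05, 20+20
variants, 20 seeds).  The end-to-end planted-module scenario plants a
driver set of 8 variants with 16 circulant interaction pairs (β₃ = 1,
σ = 1, MAF 0.2–0.5) among 60 variants at n = 2000, analyzed at soft power
2 with min_module_size 5; n = 500 is genuinely underpowered there, because
overlapping planted pairs inflate every single-pair fit's residual
variance, and the larger cohort matches the probit recovery scenario.  The
top-|r| module recovers the driver set with Jaccard ≥ 0.6 in ~85% of
replicates — an honest end-to-end number, limited by module-boundary noise
rather than by detection failures.

## Known limitations

- Only first-order (pairwise) interactions; no three-way models.
- Text ped/tped only; no binary PLINK or VCF input, no imputation.
- The GLM path is a dense per-pair IRLS, roughly half the speed of the
  closed-form linear path.
- The greedy LD pass cannot skip a single low-r² variant inside an
  otherwise coherent block (strict contiguity).
- Module detection constants (modularity gain 0.02, connectivity fraction
  0.7) are validated on planted scenarios, not derived from theory.
- Runtime extrapolation from `runtime_probe` assumes the per-model cost is
  size-independent, which holds for the batched linear path but only
  approximately for the GLM.
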