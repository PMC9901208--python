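# Methods

This note documents the models, estimators and numerical choices behind
`netqtl`, and what the synthetic-data studies do and do not demonstrate.

## Compositional correlation (SparCC)

Sequencing counts are compositional: only relative abundances are
observed, so naive Pearson correlations between taxa are distorted by
the closure constraint. The SparCC estimator works on log-ratio
variances, which are invariant to per-sample depth. With a pseudocount
`c` (default 1) added to all counts, the variation matrix is
`t_ij = Var[log((x_i + c)/(x_j + c))]`. Under the model
`t_ij = ω_i + ω_j − 2 r_ij √(ω_i ω_j)` and the sparsity assumption that
correlations mostly cancel in row sums, the basis variances solve the
linear system `M ω = rowsums(T)` with `M = 1·1ᵀ + (D−2) I`. Correlations
are `r_ij = (ω_i + ω_j − t_ij)/(2 √(ω_i ω_j))`, clipped to `[−1, 1]`.
The estimator then iteratively removes the most strongly correlated
pair above a threshold (default 0.1) from the basis system and
re-solves, for up to 10 rounds; components excluded from almost all
pairs leave the system. Negative basis variances (possible when the
sparsity assumption is badly violated) are floored at a small positive
value. Dirichlet resampling, which the original tool offers for
averaging over count uncertainty, is omitted for determinism; the
pseudocount alone regularises zeros.

Requirements: at least 4 genera (the basis system is otherwise
unsolvable) and at least 3 samples; all-zero genus columns must be
filtered beforehand.

## Network, clustering, dynamic tree cut

The signed adjacency is `a_ij = ((1 + r_ij)/2)^β` with `β = 4` by
default. The paper-facing default β is not published for this workflow;
a scale-free-fit helper (`pick_soft_threshold`) reports the signed
R² of the log-log degree-distribution fit for candidate β and can pick
the smallest adequate value. Clustering uses average linkage (UPGMA) on
`1 − TOM` where TOM is the topological overlap of the signed adjacency
(`(A² + A) / (min(k_i,k_j) + 1 − a_ij)`); plain `1 − a` is available.

Module extraction is a dynamic (adaptive-height) tree cut, the core of
the "dynamic hybrid" algorithm without the PAM refinement stage.
Merges are processed bottom-up; when two branches meet at height `h`,
both are kept as separate modules only if each is *viable*:

* size ≥ `min_module_size` (default 10),
* core scatter — the mean of the branch's earliest
  `min_module_size − 1` merge heights — at most
  `h_min + m(d)·(h_max − h_min)`, with `m(d) = 0.64 + d·(0.95−0.64)/4`
  for `deepSplit d ∈ {0..4}` (the published sensitivity presets),
* gap `h − core scatter` at least `(1 − m(d))·0.75·(h_max − h_min)`.

A non-viable branch is absorbed by its sibling (the "trunk": a
core-qualified branch beats an unqualified one, otherwise the larger
side), and its leaves are stamped with the absorbing height. After all
clusters are closed, leaves absorbed above the core-scatter threshold
are trimmed back to unassigned — this plays the role of the hybrid
variant's outlier exclusion and is what keeps uncorrelated background
genera out of modules. Labels are integers in decreasing size order;
0 means unassigned.

## Preservation statistics and permutation test

For a module of `m` nodes evaluated in a test cohort:

* **average edge weight** — mean off-diagonal test adjacency within the
  module;
* **coherence** — proportion of the module's (standardized) test-data
  variance explained by its summary profile; computed as `λ₁/m` of the
  node correlation submatrix, which equals the SVD definition for
  standardized data and avoids one SVD per permutation;
* **average node contribution** — mean |correlation(node, summary)| =
  mean of `√λ₁ |v₁|`;
* **correlation density** — mean |test correlation| over within-module
  pairs (using the SparCC matrix, matching how the network is built).

The null draws random node sets of the module's size from *all* test
nodes; one-sided p-values use the add-one convention
`p = (1 + #{null ≥ obs})/(1 + n_perm)` so p = 0 cannot occur. With
α = 0.05 over four statistics the decision threshold is reported as
0.012 (0.05/4 truncated to three decimals, matching the published
rule): *strong* if all four p-values are below it, *weak* if at least
one is, *none* otherwise. Default 10,000 permutations.

## Module quantitative traits

Module abundances are transformed as `log(1 + 10⁴ · relative
abundance)` (depth-normalised log counts; the transform is recorded in
the PCA model's provenance and is the one open choice here — raw or
CLR-scale PCA are plausible alternatives and would change QT units but
not the pipeline's logic). PCA is fitted on the control cohort only;
PC1's sign is fixed so its loading sum is nonnegative, because the
orientation is otherwise arbitrary and silently flips every downstream
effect direction. Projection subtracts the control means, so a sample
sitting at the control mean profile scores 0. Samples with all-zero
module genera collapse to a single projected point (the straight-line
artifact familiar from sparse microbiome PCA plots).

Group comparisons respect family structure: control-vs-group tests use
a two-sided Mann-Whitney U with one randomly selected individual per
family; the affected-vs-unaffected contrast uses a two-sided Wilcoxon
signed-rank over one random affected/unaffected pair per family
(families without such a pair are skipped and counted). Rank tests use
exact enumeration up to 25 pairs and the continuity-corrected normal
approximation beyond. The per-family sampling is seeded and never
alters the QT values themselves.

## Pedigrees, kinship, multipoint IBD

Pedigrees are loop-free and assumed non-inbred; kinship uses the
recursive tabular algorithm over a topological order, giving the
standard identities (self 0.5, parent-offspring 0.25, full sibs 0.25,
half sibs / avuncular / grandparental 0.125).

Multipoint IBD is a Lander-Green HMM over inheritance vectors: one bit
per meiosis selects the transmitted parental allele; transitions
between adjacent markers flip each bit independently with the Haldane
recombination fraction `θ = (1 − e^(−2d/100))/2`; the emission is the
probability of the observed unphased genotypes given the vector,
marginalised over founder-allele assignments. The marginalisation
enumerates the phase of each heterozygous genotyped individual — for
non-inbred pedigrees this enumeration is injective in the slot
assignment, so no configuration is double-counted — and multiplies
founder allele frequencies (counted from founders with a 0.01 floor;
the support always covers every allele observed anywhere in the sample
so a missing founder genotype can never zero out an offspring allele).
The full `2^(2n)` state space is kept rather than collapsing
founder-phase symmetry: at the supported family sizes (bit limit 10
meioses by default) the full space is cheap, and posteriors stay
directly comparable to brute-force enumeration, which the test suite
exploits (agreement to 1e-10 on random sib-pair instances). Families
over the bit limit are skipped and reported. Mendelian-inconsistent
families are skipped by default, or the offending marker dropped.

Posteriors are evaluated at marker positions and optionally on a
uniform cM grid; off-marker evaluation is exact (forward and backward
messages propagated through the extra transition), not interpolated.
From the state posterior we report `P(IBD = 0,1,2)` and
`π̂ = P₁/2 + P₂` per relative pair, plus the posterior covariance of π
across pairs (used by the linkage weighting below). With no genotype
data the posterior reduces to the pedigree prior, e.g. (¼, ½, ¼) for
full sibs.

## Regression-based linkage

The scan statistic follows the reversed-regression idea for general
pedigrees: regress IBD sharing on trait configuration, so that trait
selection does not bias the test. Per family, with the trait
standardized by the trait model's mean and variance, form for each
informative relative pair the squared sum `s = (y_i + y_j)²` and
squared difference `d = (y_i − y_j)²`. Under multivariate normality
with pair correlation `r_ij = 2φ_ij h²` their null means are
`2(1 ± r)` and their covariance has closed-form fourth-moment entries
(`Cov(s_ij, s_kl) = 2(r_ik + r_il + r_jk + r_jl)²` and sign-flipped
analogues). Conditional moments give
`Cov(π̂_ij, s_kl) = 2Q · Cov(π̂_ij, π̂_kl)` where `Q` is the QTL
variance; generalised least squares across families yields

```
Q̂ = Σ_f x_fᵀ Σππ⁻¹ Π̂_f / Σ_f x_fᵀ Σππ⁻¹ x_f,
x_f = 2 [Σππ | −Σππ] Σ_Y⁻¹ (Y_f − μ_f),
```

with `Π̂_f = π̂ − 2φ`. The χ²(1)-scale statistic is `T = Q̂²·Σ x'Σ⁻¹x`,
signed toward positive sharing-similarity, and
`LOD = max(T, 0)/(2 ln 10)` with negative-direction estimates truncated
to zero (the standard one-sided QTL convention). `Σππ`, the sampling
covariance of `π̂` under the null, is obtained by the law of total
variance as the exact prior covariance of π (uniform inheritance
vectors) minus the mean posterior covariance over families of identical
structure; fully informative markers recover the full prior variance,
and positions with no marker information give `Σππ = 0`, hence a zero
statistic — the correct degenerate limit. Pairs are restricted to
first- and second-degree relatives (`2φ ≥ 0.25`) whose sharing has
positive prior variance; parent-offspring and spouse pairs are thereby
excluded (their π̂ is constant). The trait model (mean, variance,
heritability) defaults to full-sample estimates with h² from the REML
fit; it is an explicit input because misspecifying it rescales, but
does not invalidate, the statistic (LOD is invariant to consistent
affine rescaling, which the tests check).

Peaks are local maxima with LOD above the threshold (default 3); a
support interval is the maximal contiguous run around the peak with
LOD above `max − 2`, endpoints snapped outward to the flanking
evaluated positions and annotated with flanking marker ids.

## Heritability and mixed-model association

Variance components are fitted by REML with
`Ω = σ² (h²·2Φ + (1−h²) I)`: the kinship matrix is block-diagonal by
family, so its eigendecomposition is computed block-wise, and the REML
criterion is profiled over `h² ∈ [0, 1]` by bounded scalar
minimisation, with explicit endpoint comparison so boundary estimates
(pure noise → 0, family-duplicated traits → 1) are returned exactly.
The standard error comes from a central second difference of the REML
curve. Covariates enter as fixed effects; the pipeline residualises
traits on sex, age, BMI, smoking and disease status before linkage
(keeping the linkage estimator in its published form — the difference
from modelling covariates inside the regression is second order).

Association inside support intervals uses the exact-profile-REML
linear mixed model: the eigendecomposition of `2Φ` is done once and
reused across SNPs; per SNP the variance ratio is re-profiled in the
rotated space and the Wald p-value reported, with a per-interval
Bonferroni threshold `0.05/#SNPs`. With identity kinship the estimates
reduce to OLS exactly. Monomorphic SNPs are skipped and reported.

## Single-taxon comparison

Per-genus traits are rank-based inverse-normal transformed (Blom
offset 3/8), covariate-adjusted, and scanned with the same linkage
statistic. The comparison statistic for a module signal is the mean
over module genera of each genus's maximum LOD inside the support
interval. Its null is built from genomic regions of the same genetic
length sampled uniformly over valid start positions (discretized to
the scan grid, since the statistic only changes there), with
chromosomes weighted by their number of valid starts so no region
spans a boundary; the p-value is the plain proportion of random
regions exceeding the observed value — deliberately *without* the
add-one correction, following the "relative number of times" phrasing
of the rule this implements, while the permutation module keeps
add-one per its own convention. The observed region is not excluded
from the null (the rule does not say to exclude it; inclusion is
conservative).

## The synthetic-data generator

The generator emulates the target study design: two population control
cohorts sharing planted modules, and disease families of first- and
second-degree relatives. Per sample, each module has a standard-normal
latent factor; genus log-signals are `baseline + loading·factor +
noise`; counts are multinomial from the softmax of the log-signals at a
fixed expected depth (20,000 by default — the simplest compositional
mechanism consistent with the log-ratio correlation model), and zero
inflation is applied afterwards as independent per-genus dropout.
Defaults — four modules of 40/30/20/15 genera among 200, loading 2.0,
noise SD 1.0, baseline SD 1.5, dropout 0.1 — were calibrated once so
that module PC1 explains ≈ 40–50 % of control variance, the level the
real control data are reported to show; with these settings ~15 % of
entries are zero.

Families default to nuclear with two offspring (matching the target
cohort's ≈ 4 members per family); a three-generation structure adds
grandparental and avuncular second-degree pairs. Genotypes are gene-
dropped founder alleles with Haldane-distance recombination;
founder-origin labels are tracked, providing both an internal
Mendelian-consistency oracle and an exact ("fully informative") IBD
profile. The family module factor decomposes as
`f = √Q·(standardized QTL dosage) + g + c'x + e` with
`g ~ MVN(0, 2Φ·h²_poly)` per family and `e` filling the remaining unit
variance; covariate effects and a disease shift are added on top. The
QTL locus is inserted into the genetic map and gene-dropped **jointly**
with the markers so trait and marker inheritance cosegregate (an
independently dropped QTL would, by construction, show no linkage).

What the generator does *not* emulate: taxonomic structure, linkage
disequilibrium between founder haplotypes, abundance-dependent dropout,
batch effects, and assortative family ascertainment. Passing the
validation studies therefore demonstrates correctness and calibration
of the estimators under the stated model, not robustness to every
feature of real 16S data.

## Study sizes used in validation

The test suite and `scripts/acceptance.py` run: module recovery and
preservation on 2 × 800 samples × 200 genera (1000 permutations for
classification, 200 × 200 for null calibration); the IBD oracle on 100
random 3-marker sib-pair instances; linkage null calibration on 200
replicates of 500 sib-pair families; planted-QTL power on 25
replicates of 300 sibships of five with exact inheritance information
(an a-priori power calculation — sib-pair NCP ≈
`Q²/16·[1/(1+r)² + 1/(1−r)²]` — shows 300 two-offspring families would
have ≈ 20 % power at Q = 0.3, so the family size, which the design
leaves free, was fixed at five before running the study); heritability
recovery on 50 replicates of 300 nuclear families; and the
randomization null on 40 replicates of 500-region draws. All
randomness derives from named substreams of a single seed.

## Known limitations

* The exact HMM is restricted to ≤ 10 meioses per family (1024 states);
  larger families are skipped rather than approximated.
* The linkage estimator discards parental trait values along with the
  uninformative parent-offspring pairs; the fullest general-pedigree
  formulation would condition on them and gain some efficiency.
* SparCC assumes a sparse true correlation network; very dense planted
  structure can bias basis variances (mitigated but not removed by the
  exclusion iterations).
* The dynamic tree cut implements the hybrid algorithm's core
  behaviour, not a line-by-line port; on fixtures with clear module
  separation it reproduces planted partitions exactly, but branch-level
  decisions on borderline dendrograms may differ from other
  implementations.
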