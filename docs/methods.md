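# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the known limitations of `pstfst`.

## The divergence statistics

**FST.** Pairwise neutral divergence between two ponds is the
Weir–Cockerham (1984) method-of-moments estimator θ from codominant
multilocus genotypes: for each locus and allele the a (among-population),
b (among-individual) and c (within-individual) variance components are
computed with the finite-sample corrections, summed over alleles and loci,
and combined as θ = Σa / Σ(a+b+c) (ratio of sums). Loci monomorphic across
a pair contribute nothing; per-locus complete-case sample sizes absorb
missing calls; slightly negative estimates are reported as computed, since
truncating them would bias pond means upward. θ is invariant to allele
relabeling and individual order, and on simulated island-model data its
mean tracks the closed-form expectation (see below).

**PST.** For one pond pair, the multivariate trait matrix is decomposed by
projecting onto pond membership — the constrained step of a redundancy
analysis with population as the sole predictor, identical to the one-way
multivariate sums-of-squares split tr(SS_T) = tr(SS_B) + tr(SS_W). Two
conventions convert the traces into the δ² components:

- `components` (default): MS_B = tr(SS_B)/(g−1), MS_W = tr(SS_W)/(N−g),
  δ²GB = max(0, (MS_B − MS_W)/n₀) with the unbalanced-design coefficient
  n₀ = (N − Σnᵢ²/N)/(g−1), δ²GW = MS_W. This is the convention under which
  the neutral benchmark E[QST] = FST actually holds, because it removes the
  within-pond sampling contribution from the between-pond mean square;
  negative method-of-moments estimates are truncated at zero and flagged.
- `inertia`: raw traces divided by N−1, the literal "variance explained"
  reading of an ordination. Provided for comparison; it overstates
  between-pond variance at small n.

PST = c·δ²GB/(c·δ²GB + 2·h²·δ²GW), with h², c ∈ (0, 1], default
h² = 0.5, c = 1. PST is strictly decreasing in h² and increasing in c
whenever both components are positive, which the sensitivity surface
(default 10×10 grid over 0.1–1.0) makes visible; the variance components
are computed once per pair and only the formula is re-evaluated per cell,
so the (0.5, 1.0) cell reproduces the default analysis identically.

**Column scaling.** Trait groups mix millimetre lengths with integer
counts, so columns are centered and divided by their pooled *within-pond*
standard deviation before partitioning. Scaling by the total sd instead
would shrink each column in proportion to its realized between-pond
variance and systematically deflate the between/within ratio; within-pond
scaling equalizes units while leaving each column's ratio intact. Shape
PCA scores are an isometric rotation of the Procrustes coordinates and
already share one scale, so they are deliberately *not* per-column
standardized (doing so inflates the near-degenerate trailing components
and distorts shape-space geometry).

**EST.** Three per-pond ecological axes: the limnetic proportion
limnetic/(limnetic+benthic) of the pooled pond invertebrate sample;
the per-fish limnetic diet proportion averaged within ponds ("other" taxa
are excluded from the denominator — a ratio including them would not be a
proportion); and the first principal component of pH (native scale),
log₁₀ TDS (min–max scaled) and pond area (min–max scaled). Pairwise
EST(i,j) = |vᵢ − vⱼ|, the absolute difference along the axis. Invertebrate
totals from sub-sampled jars follow the aliquot rule: samples of ≤200
individuals are counted fully; otherwise aliquots are accumulated until
the cumulative count exceeds 200 and the total is extrapolated by
(cumulative / aliquots counted) × total aliquots, which is unbiased under
well-mixed (multinomial) aliquoting.

## Trait and shape testing

Length-type traits are size-corrected before any analysis by pooled
ordinary least squares of log₁₀(trait) on log₁₀(body length) over all
individuals (a common slope keeps residuals comparable across ponds, the
standard Reist-style residual approach); meristic counts are used raw.
A raw-scale variant is available.

Group-level pond and sex effects use MANOVA with Pillai's trace under the
additive model with pond entered before sex (sequential, Type I — no
pond × sex interaction, as unbalanced sex ratios in small ponds make the
interaction untestable), with the standard F approximation. Per-trait
ANOVAs use the same sequential model. For body shape, the Procrustes
ANOVA computes sums of squares of the flattened Procrustes coordinates
under the same sequential model and draws p-values from residual
randomization under the reduced model (RRPP): the reduced-model residuals
are permuted across specimens, the term F recomputed, and
p = (#{F* ≥ F} + 1)/(n_perm + 1). For the pond term the reduced model is
the intercept, making the procedure an exact permutation test; its null
p-values are verified uniform in the suite. Fewer than 99 permutations are
refused (p-resolution too coarse).

**GPA.** Generalized Procrustes superimposition centers each
configuration, scales it to unit centroid size, and iteratively rotates to
the running consensus (SVD rotation with reflections disallowed,
determinant +1 — all specimens are photographed from the same side) until
the consensus moves by less than 1e-8. The output is put into a canonical
orientation (principal axes of the consensus, 180° ambiguity resolved by
the third moment along the major axis) so results do not depend on input
order. Shapes are analysed in full Procrustes form without tangent-space
projection; at the small deformations involved the difference is second
order. GPA fixes four degrees of freedom, so downstream shape analyses
keep the first 2k−4 PCA score columns (k = 11 landmarks → 18 dimensions);
the retained scores preserve inter-specimen Procrustes distances exactly.

## The comparison layer

Pairwise matrices are summarized as unweighted per-pond means (each pond
averaged over its 18 pairings) before any model fitting, avoiding the
non-independence of raw pairwise values. Regressions of pond-mean PST on
pond-mean FST (and on each EST axis) report adjusted R² — which can be
negative, the expected outcome for an uninformative predictor. PST is the
response by default for internal consistency across the PST~FST and
PST~EST families; a flag swaps the direction. The level test stacks the
two pond-mean vectors and runs a one-way two-level ANOVA; an outlier
rescreen drops the k = 2 pond-mean PSTs most distant from the PST median
(from the PST vector only, configurable) and is reported alongside the
full-sample test, which is the one used for classification. Labels follow
the standard rule at α = 0.05: significantly PST > FST → divergent
selection or plasticity (confounded for wild-caught phenotypes — every
report carries that caveat), significantly PST < FST → stabilizing
selection, otherwise drift-consistent. No multiple-testing correction is
applied across the 4 groups × 3 EST axes by default (a Holm option
exists), matching how such batteries are conventionally reported.

## The synthetic metapopulation generator

The generator emulates a system of 19 small, semi-connected ponds:
15–47 fish sampled per pond, 12 microsatellite loci starting from 4
equifrequent alleles, Ne = 50 per pond, 100 non-overlapping generations.
Genetics follow a finite-island Wright–Fisher model: each generation every
pond's allele frequencies are mixed with the common migrant pool at its
immigration rate and 2Ne gene copies are resampled multinomially.
Mutation is omitted — at these horizons drift dominates and the loci stay
polymorphic. The default connectivity is heterogeneous: per-pond
immigration rates are set so the local equilibrium divergence
1/(1 + 4·Ne·mᵢ) is log-spaced from 0.012 to 0.25, reproducing both the
~0.08 mean pairwise FST and the wide pond-to-pond spread of a
structured-to-admixed pond system; a scalar rate gives the homogeneous
island model, validated against the closed form
FST(t) = FST_eq·(1 − aᵗ), a = (1−m)²(1 − 1/(2Ne)) (pure drift:
1 − (1 − 1/(2Ne))ᵗ).

Traits are built on an explicit additive (infinitesimal) basis over the
simulated loci: each of the 10 meristic/morphometric traits and 22 shape
coordinates has a fixed random-sign loading on the individual allele
dosages, rescaled so the pooled within-pond additive variance is h²_true,
plus Gaussian environmental noise of variance 1 − h²_true (unit
within-pond phenotypic variance on the latent scale). Because pond trait
means then drift with the same realized locus histories that produce FST,
the neutral identity E[QST] = FST holds exactly (between-pond additive
variance 2θV_A against within-pond (1−θ)V_A) and realized PST and FST are
coupled within each replicate, not just in expectation. Selection regimes
are reduced-form: pond means are blended toward environment-tracking
optima (divergent; optima at ±2 within-pond sd across the gradient, on the
selected group only) or a common optimum (stabilizing) with weight
1 − (1 − κ)ᵗ, κ = `selection_strength`; per-locus selection dynamics are
deliberately not modeled. The truth record stores realized between/within
latent variances per group, the expected FST, and the realized additive
share (which matches h²_true to within ±0.05).

Latent traits map to measurement units with realistic baselines: length
traits get allometric log-log scaling against body length (so the size
correction has real work to do) with residual sd 0.05 log₁₀ units; count
traits are rounded to integers around their baselines with within-pond
latent sd 1.5. Landmarks are a stickleback-like 11-point template plus
0.5%-of-centroid-size latent deformations, digitized at ~10 px/mm with
per-fish size variation. Environment, pond invertebrate and stomach-count
tables follow the study's scales (pH ~7.3–9.4, TDS ~0.04–0.3 ppm log-scale,
areas ~600–10⁵ m², pond limnetic proportions centered near 0.89, diet near
0.43) with multinomial counts over the 11-taxon registry and aliquot
structure for large samples; all ecological gradients are tied to one
per-pond environmental axis so divergent regimes are environment-coupled.

What the generator does *not* emulate: linkage and sex chromosomes,
spatially explicit connectivity (migration is pool-mixing), measurement
error beyond discretization, landmark digitization artifacts, and
selection acting on allele frequencies. Passing tests therefore show the
statistics recover the generating process under an idealized island-model
world; they do not certify performance under spatial network structure or
trait architectures with few loci of large effect.

## Numerical choices and degenerate inputs

Single global seed; sub-streams for genetics, traits, shapes, sampling and
ecology are split via `SeedSequence.spawn`, so outputs are byte-identical
across runs and extending one component never perturbs another. GPA
tolerance 1e-8, max 100 iterations (non-convergence raises). PCA via
eigendecomposition of the covariance with eigenvalue-descending order and
largest-|loading|-positive sign convention. Degenerate inputs raise with
named culprits: all-missing locus×pond cells, no informative loci,
constant trait columns or predictors, zero variance partitions, ponds with
fewer than two individuals, TPS records with inconsistent landmark
counts. δ²GB = δ²GW = 0 is an error ("degenerate variance"), not PST = 0.

## Known limitations

- Pairwise δ²GB rests on a single between-pond degree of freedom per pair,
  so pairwise PST is noisy at n = 15–47 and only pond means are stable;
  the PST ratio is mildly concave in that noisy numerator, giving a small
  (~2–4% relative) downward bias that is visible in tight neutral
  calibrations. Integer meristics add ~1/12 discretization variance to
  δ²GW with the same small downward effect — real count data share this
  property.
- The level test treats pond means as independent observations; with 19
  exchangeable ponds the realized between-pond variance of a 2–4-trait
  group is an average of at most a few χ²₁₈-like draws, so even under pure
  drift a minority of replicates show group PST genuinely displaced from
  FST and get non-drift labels. This is an information limit of the
  mean-based design, not an estimator defect; the suite quantifies it.
- h² and c are assumptions, not estimates: PST conclusions should be read
  off the sensitivity surface, not the single default cell.
- EST axes are simple scalar gradients; multivariate environmental
  divergence is out of scope.
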