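# Methods

`smoltqg` implements the quantitative-genetic analysis chain for
migration-related traits in rainbow and steelhead trout
(*Oncorhynchus mykiss*): pedigree construction and additive relationship
matrices, derived phenotypes, geometric morphometrics of body shape,
REML and Bayesian threshold animal models, and discriminant
classification of life history — together with a synthetic-data
generator that emulates the three-generation experimental design these
analyses assume.

## Pedigree and relationship structures

A pedigree is validated (unique ids, parents present, acyclic) and
topologically sorted with a stable tie-break on input order. The
numerator relationship matrix A is built by the recursive tabular
method: `a_ii = 1 + F_i` with `F_i = a(sire_i, dam_i)/2`, and
`a_ij = (a(j, sire_i) + a(j, dam_i))/2`. Founders (unknown parents) are
treated as non-inbred and mutually unrelated. Inbreeding coefficients
for large pedigrees come from a memoized kinship recursion rather than
the dense table, and the sparse inverse of A follows Henderson's
per-individual rules with Mendelian-sampling variances
`d_i = 1 - (1+F_s)/4 - (1+F_d)/4` over known parents. Correctness is
checked two independent ways: a Monte Carlo gene-dropping oracle
(allele transmission simulated 200,000 times; coancestry estimated from
allele identity) and the identity `A · A⁻¹ = I`.

Dense A is used for pedigrees up to a few thousand individuals; the
sparse inverse serves the mixed-model equations beyond that. The REML
module currently uses the dense route and is sized accordingly.

## Derived phenotypes

* Condition factor `K = (W/L³)·100,000` (W in g, L in mm).
* Instantaneous growth rate `IGR = [ln(x₂) − ln(x₁)]/(t₂ − t₁)·100`
  (percent per day), over the 12→15 and 15→24 month intervals.
  Individual measurement dates are used when present; otherwise nominal
  ages of 12/15/24 months × 30.44 d. The nominal-age assumption is
  recorded in the output table metadata.
* The four-level life-history call is decomposed into two binary
  traits: `LHSmolt` (smolt = 1; mature, parr = 0; indeterminate =
  missing) and `LHMature` (mature = 1; others = 0). `LHSmolt = 1`
  implies `LHMature = 0` on every row.

Derived columns are appended, never overwrite inputs, and derivation is
idempotent.

## Geometric morphometrics

Thirteen 2-D landmarks per fish are superimposed by generalized
least-squares Procrustes analysis: centring, scaling to unit centroid
size, and iterative rotation to the updated consensus (tolerance 1e-10,
at most 100 iterations). Centroid size is the square root of the summed
squared landmark distances to the configuration centroid.

Shape deviations from the consensus are projected onto the thin-plate
spline partial-warp basis: the bending-energy matrix of the consensus is
eigen-decomposed (k−3 non-uniform principal warps, each contributing an
x and a y score) and the two-dimensional uniform (affine) component is
obtained as the orthogonal complement of the similarity + non-uniform
space, giving 2k−4 = 22 scores per fish for k = 13. Relative warps are
the principal components of the partial-warp scores with weight α = 0
(plain PCA), reported ×1000, with percent variance explained summing to
100. Axis signs are fixed deterministically (largest-magnitude loading
positive); the sign itself is arbitrary. A configurable exclusion drops
named warps (the first axis is an anesthesia-related bending artifact in
the study system) while retaining original labels.

Numerical checks: pure affine deformations load only on the uniform
component; the warp-score variance equals the Procrustes shape variance;
a rank-1 simulated shape space concentrates ~100% PVE on axis 1; a
configured eigen-spectrum is recovered at large n.

## REML animal models

The phenotype is decomposed as fixed effects (generation cohort, cross
type, optional covariates such as centroid size) plus random effects:
family/micro (shared rearing tank to 12 months), maternal (dam),
paternal (sire), the additive genetic animal effect with covariance
`V_A·A`, and residual. Variance components are estimated by
average-information REML on a linear variance model `V(θ) = Σ θ_p M_p`:
AI steps with step-halving when a step would leave the feasible region
or decrease the restricted likelihood, non-negativity by boundary
projection (flagged), convergence on relative likelihood change < 1e-8
and component change < 1e-6, with a stall detector for boundary jitter.
Standard errors come from the inverse average information; `h² = V_A/V_P`
and `m² = V_m/V_P` get delta-method SEs. Wald F statistics test fixed
terms with denominator degrees of freedom `n − rank(X)` (a residual
approximation; specialized mixed-model df methods may differ slightly).
Random terms are tested by likelihood-ratio tests against the fit
without the term, referred to χ²(1); under a true zero variance the
boundary makes this conservative, which the test suite verifies by
simulation.

Bivariate fits estimate 2×2 genetic (and residual) covariance matrices;
`r_A = COV_A12/√(V_A1·V_A2)`, tested by an LRT against a fit with the
genetic covariance constrained to zero. When the model is animal +
residual with a shared fixed design, a canonical-transformation fast
path is used: rotating observations into the eigenbasis of the observed
relationship matrix decouples the likelihood into independent 2×2
problems, and G and R are optimized through Cholesky factors (PSD by
construction, covariances unconstrained in sign). The fast and dense
paths are cross-checked on shared fits.

## Bayesian threshold models

Binary life histories are modelled on the logit scale with the residual
variance fixed at 1; heritability is `h² = V_A/(V_P + π²/3)`, the link
variance entering the denominator. A Pólya-Gamma auxiliary variable per
observation (Devroye alternating-series sampler, numba-compiled) makes
every conditional conjugate. Location effects are updated by blocked and
single-site Gibbs against the sparse A⁻¹; for observed individuals the
breeding value and the unit-variance latent residual are updated
jointly (a 2×2 Gaussian conditional), which removes the slow random
walk along their sum. Variance priors are inverse-Wishart with low
degree of belief (ν = 0.002 univariate; ν = T + 0.002 for T×T blocks)
and scale set by dividing the observed phenotypic variance equally
among the random terms and the residual. Chain defaults are 100,000
iterations, 10,000 burn-in, thinning to 1,000 retained draws, with a
packaged longer preset for the binary life histories; summaries are the
KDE mode (Gaussian kernel, Silverman bandwidth, configurable), 95% HPD
intervals (sorted-window), lag-1 autocorrelations with a 0.1 pass
threshold, and DIC from the per-draw deviance.

**A property of this model class worth knowing.** Under these weak
variance priors the threshold animal model's posterior contains, besides
the data-informed region, a quasi-saturated regime in which breeding
values grow until they interpolate the binary outcomes. Because family
members share outcome tendencies, the pedigree prior charges such
sign-coherent configurations much less than independence would suggest,
and for moderate-to-large samples the regime carries non-trivial
posterior mass; it is not removed by mildly informative priors. The
conditional Gibbs samplers used throughout the animal-model literature
do not traverse into this regime, and published threshold-model
estimates describe the data-informed mode. This package's binary
sampler reproduces that estimator by default. A global non-centered
scale move ("interweave") — proven exactly invariant and enabled by
default for Gaussian responses, where it sharpens mixing — can be
switched on for binary fits; it then also explores the saturated
regime, which is informative for diagnosing the phenomenon but not for
reproducing conventional estimates. The threshold sampler is validated
against an independent JAGS implementation of the identical model on a
frozen fixture.

Bivariate models pair a Gaussian and a binary trait (or two binary
traits): unstructured 2×2 genetic and family covariance blocks
(inverse-Wishart conditionals), residual covariance fixed at zero, and
per-draw `r_A` summarized by mode and HPD. The mutually exclusive
life-history pair lives near `r_A = −1`; the inverse-Wishart conditional
tolerates the boundary.

## Class statistics

One-way ANOVA tests trait differences across the four life-history
classes; pairwise comparisons use the Tukey-Kramer adjustment with
Kramer's unequal-n standard errors on the pooled within-class variance.
Correlation matrices are pairwise-complete, Pearson for quantitative
pairs and Spearman whenever a binary life-history trait is involved
(including binary-binary pairs), two-sided α = 0.05 with no multiplicity
correction, reporting the count of significant off-diagonal pairs.
Discriminant classification is linear (pooled within-class covariance)
on complete cases with proportional priors, scored by resubstitution
(training-set) accuracy — the convention behind the study's reported
87–90% assignment rates; no cross-validation is applied, and this is the
main caveat on those figures.

## Synthetic data

The generator's defaults are the study design: P1 founders (42 dams, 31
sires split between anadromous and resident ecotypes), 75 F1 families
(mean 88 offspring) of cross types A×A, A×R, R×A, R×R, and 69 F2
families (mean 137) adding AR×AR and RA×RA from unrelated F1 parents —
about 16,000 individuals. Family sizes are negative binomial
(dispersion 8) matched to the printed means; sires are reused across
dams at rate 0.5, producing paternal half-sibs. The per-cross-type
family counts (F1 22/14/18/21, F2 16/11/11/11/10/10) reproduce the
study's both-generation totals exactly; the split by generation is not
uniquely determined by those totals.

Breeding values descend the pedigree by Mendelian sampling: founders
∼ N(0, G); offspring are the parent average plus a deviation with
covariance `G/2·(1 − (F_s + F_d)/2)`. Phenotypes add fixed generation
and cross-type effects, family, maternal and paternal effects, and
Gaussian residuals. Binary life histories arise from a single shared
liability with a N(0,1) residual plus standard-logistic link noise
(variance π²/3), cut into mature < parr < indeterminate < smolt — so
the logit-scale heritability formula is exactly the generative estimand,
and the mutually exclusive binary pair inherits its near −1 genetic
correlation. Default cut points target the study's class frequencies
(12.7/11.7/4.0/71.6%). Landmark shapes are the consensus fish outline
plus tangent-space variation along configured orthonormal axes
(default spectrum 4:2:1, ~2% rms shape variation), wrapped in random
rotation/translation/scale nuisance.

What the generator does not emulate: selection or mortality between
measurement ages, non-Gaussian measurement error, digitization error
structure in landmarks, environmental trends within rearing tanks, and
genotype-environment interaction. Passing tests therefore demonstrate
statistical correctness of the estimators under the assumed model, not
robustness to those features of real data.

## Problem sizes used in the test suite

The full study pedigree (16,139) is simulated by the default generator
and checked for its design properties, but estimator-recovery tests run
on proportionally scaled designs chosen to keep the suite on a single
workstation: REML heritability recovery uses a 0.2-scaled design
(~800 individuals, 50 replicates × three h² levels); bivariate r_G
recovery uses a 0.25-scaled design (~1,100 individuals, 10 replicates
per r_G via the canonical fast path); the threshold-model recovery
keeps the study's own family sizes (88/137) with 24 families
(~2,500–3,000 individuals, 20 replicates, 10,000-iteration chains):
shrinking family sizes creates quasi-separation and shrinking the
family count destabilizes the threshold posterior, both artifacts of
over-shrinking the fixture rather than features of the design; LRT null calibration uses 500
replicates of a 30-family sib design. The morphometric and discriminant
checks are exact/fast and run at n = 200–1,600.

## Known limitations

* REML uses dense linear algebra; study-scale (16k) REML fits need the
  sparse mixed-model-equation route, which is not implemented.
* Wald denominator df are a residual approximation.
* The KDE mode is sensitive to bandwidth when a posterior is flat or
  multimodal; HPD intervals and medians are the stabler summaries.
* Resubstitution accuracy overstates out-of-sample classification
  accuracy by construction.
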