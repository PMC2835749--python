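# Methods

This package implements the comparative-phylogenetics machinery needed to
ask whether migratory passerines have relatively smaller brains than
resident ones, and in which direction the association evolved: trait
coding rules, phylogenetic generalized least squares with Pagel's λ,
Pagel's correlated-evolution test for two binary characters (maximum
likelihood, Metropolis–Hastings MCMC, reversible-jump model averaging,
Bayes factors, ancestral root states), and a path-analytic decomposition
of the brain–migration correlation. Everything is exercised end-to-end
on synthetic studies with recorded ground truth.

## Trees and the Brownian covariance

Phylogenies are stored flat (postorder parent pointers) with polytomies
allowed throughout; Newick I/O goes through dendropy. Ultrametricity is
never enforced: the unit-branch-length convention used by the headline
analyses breaks it on most topologies, and the operations that assume
contemporaneous tips say so.

Three branch-length assignment rules are provided:

* **unit** — every branch is 1.
* **grafen** — node height = (number of descendant tips − 1), i.e.
  Grafen's rule with ρ = 1, rescaled so root-to-tip depth is 1.
* **pagel** — node height = number of internal nodes in the node's
  subtree (itself included), tips at height 0. The literature describes
  this method loosely; this is the formula implemented here, chosen
  because it yields contemporaneous tips and unit spacing between
  internal "levels" on caterpillar trees.

The Brownian tip covariance V has V[i,j] = root-to-MRCA shared path
length and tip depths on the diagonal. Pagel's λ multiplies the
off-diagonal entries only; λ = 0 is a star phylogeny, λ = 1 pure
Brownian motion. For λ ∈ [0,1] the transform is a convex combination of
V and its diagonal, so positive semi-definiteness is preserved.

## Trait coding

* Endocranial volume → brain mass at the fresh-tissue density
  1.036 g/ml; a literature mass, when present, takes precedence over a
  converted volume.
* Ordinal migratory distance: 0 none, 1 altitudinal/local (< 100 km),
  2 [100, 700) km, 3 [700, 1500) km, 4 ≥ 1500 km. Category bounds are
  half-open with inclusive lower bounds; the verbal rule ("between 100
  and 700") does not fix boundary membership, so this is a documented
  convention. Coding is monotone in distance.
* Residual brain size: ordinary (non-phylogenetic) least-squares
  residuals of log brain on log body mass. Binarization: large brain =
  strictly positive residual (an exact zero codes as 0 with a warning);
  migratory = category ≥ 2 (movements over 100 km).
* Repeatability: among-species variance component of a one-way
  random-effects ANOVA as a percentage of total, with negative component
  estimates truncated at zero and the all-identical case defined as
  100%.

## λ-PGLS

The regression error covariance is σ²·V(λ). σ² is profiled out
analytically; λ is maximized on a 101-point grid over [0,1] followed by
bounded refinement to 1e-6, so flat or multimodal profiles cannot trap a
purely local search (a flat profile within 1e-6 log-likelihood units is
flagged, not an error). ML is the default; REML is an option.
Coefficient SEs use the (n − p)-denominator variance estimate and
p-values come from t with n − p degrees of freedom (p counting the
intercept). A profile-curvature SE for λ̂ is reported from a central
second difference kept inside [0,1].

Partial R² for a focal predictor is (RSS_reduced − RSS_full)/RSS_reduced
in the GLS-whitened space; the pipeline fits the reduced model at the
full model's λ̂ so the two residual sums are on the same scale.
Ordinal migration enters as a numeric predictor by default, with a
binary recode (resident {0,1} vs migratory {2,3,4}) available. λ for a
binary trait is computed by treating the 0/1 indicator as continuous —
an approximation, stated as such.

Simulation calibration (reproduced by the test suite): with the study
generator's defaults the migration coefficient is recovered within 2 SE
in ≥ 90% of replicates, and the type-I error of the focal test is
5% ± 2.5%. The recovery z-scores are mildly overdispersed (sd ≈ 1.1)
because λ-estimation uncertainty is not propagated into the coefficient
SEs; this is the standard behavior of plug-in λ PGLS.

## Correlated evolution of two binary traits

Joint states are 1=(0,0), 2=(0,1), 3=(1,0), 4=(1,1) with **trait 1 =
migratory, trait 2 = large brain**; q43 is therefore the rate of losing
a large brain while migratory and q13 the rate of gaining migration
while small-brained. The independent model has 4 rates (gain/loss per
trait, ignoring the other trait); the dependent model frees all 8
single-change rates; simultaneous double changes have rate 0. The
independent model is the dependent model constrained so each trait's
rates ignore the background state — the likelihood nesting is verified
to 1e-8 in the tests.

The likelihood is Felsenstein pruning over the 4-state chain with
per-branch transition matrices exp(Qt) (scaling-and-squaring; an
eigendecomposition route was rejected because near-defective generators
arise routinely during optimization). Branch lengths are deduplicated,
so unit-branch trees need one matrix exponential per evaluation; the
tree pass is a numba-compiled kernel with per-node rescaling. Zero
branches contribute identity transitions. The root prior is uniform
over the four states by default (equilibrium optional) — the reference
software's default is not documented, so this is an explicit choice.
ML fitting is multi-start L-BFGS-B on log rates bounded by
rate_max = 100 expected changes per unit branch length;
non-convergence is flagged on the result, not raised.

Simulation is exact Gillespie within branches (exponential waiting
times between single-trait flips), used both as the generator for
synthetic studies and as the probe of the transition-matrix code (tip
frequencies match exp(Qt) within Monte-Carlo error).

## Bayesian machinery

Priors: exponential with mean 10 on every rate (the hyperparameter is
not pinned down by the methods this mirrors; 10 is generous relative to
the ~0.05–0.5 changes per unit branch that unit-branch trees imply) and
uniform over models (rate partitions) in the reversible jump.

The fixed-dimension sampler updates one rate per iteration with a
multiplicative random-walk proposal whose step adapts toward ~30%
acceptance during burn-in only. Chains start at rate 0.1 rather than a
prior draw: the diffuse prior routinely proposes saturated-rate
plateaus that short chains are slow to leave. With the likelihood
switched off the sampler reproduces its exponential prior
(Kolmogorov–Smirnov distance < 0.05 at 10,000 draws) — the standard
sampler-correctness check. Chains are bit-reproducible under a fixed
seed.

The reversible-jump chain's state is a partition of the 8 dependent
rates into value-sharing bins plus a zero bin; one "reassign" kernel
(move a rate to another bin, a fresh bin with a prior-drawn value, or
the zero bin, target chosen uniformly) covers the split/merge/zero
moves. Because fresh values are proposed from their prior, all density
terms cancel and acceptance is L′/L × n_options(current)/n_options
(proposed); the dimension-changing move is an independence draw from
the prior, so its Jacobian is 1. This replaces a three-way
split/merge/toggle kernel with fixed probabilities: the move space is
the same and the acceptance algebra is easier to verify.

Marginal likelihoods use the harmonic-mean estimator, computed stably
in log space, because that is the comparison the analyses this package
reproduces were built on; its infinite-variance pathology is real, and
a trimmed variant is available behind a `stabilized` flag. The
log-Bayes factor is the symmetric 2 × Δ(log marginal likelihood) with
interpretation bands at 2/5/10 (positive/strong/very strong). (The
printed formula in the source literature multiplies only one term by
2; that reads as a typographical slip and is not replicated.)

Root-state posteriors average the normalized pruning-partials × prior
over posterior draws and report mean ± SD for the two marginal
questions (large brain at root; resident at root). Rate-inequality
summaries are strict-inequality posterior frequencies. Ten independent
chains in the original workflow are a pipeline loop (`chains:` in the
config), not an operation-level feature.

Chain-length defaults are desk-scale (1,010,000 iterations, 10,000
burn-in, thin 100 — two orders of magnitude below the original runs,
which remain one config line away); the tests and analysis drivers use
shorter explicit settings (4,000–20,000 iterations), which the
calibration results below show are sufficient at these data sizes.

## Path analysis

Recursive path models over observed variables only (no latent
variables, no feedback), fitted on standardized data so coefficients
are standardized effects. Complete-data ML minimizes the usual
discrepancy F = log|Σ(θ)| + tr(SΣ⁻¹) − log|S| − p with χ² = (n−1)F;
with missing data, full-information ML sums per-case multinormal
log-densities over observed patterns with free means, and χ² is twice
the gap to a saturated FIML fit. Brain, Body and Incubation are log
transformed before standardization; ordinal Migration is treated as
continuous. SEs come from the numerical Hessian at the optimum.

A fitted correlation decomposes exactly (tracing rule) into direct (the
single arrow), indirect (sum of directed-chain products), and
unanalyzed/spurious (everything routed through exogenous covariances or
shared causes); the identity direct + indirect + unanalyzed = implied
correlation is exact by construction and is cross-checked in the tests
against an independent Wright's-rules recursion. Phylogenetic
non-independence is handled as a cross-check, not a phylogenetic SEM:
each significant path is refitted as a bivariate PGLS.

The four candidate diagrams (A–D) are **reconstructed** presets — the
published figure's arrow sets are only partially recoverable — and are
plain-text-editable (`A -> B` arrows, `A ~~ B` exogenous covariances).

## Synthetic studies

`StudyTruth` defaults define the study conditions: 600 tips (the
analysis drivers and calibration suites use 300 to keep desk runs
short), allometric slope 0.633, λ_true 0.78, migration effect −0.025
per category, brain noise σ² 0.018 (chosen so the migration effect
explains a few percent of relative brain size, the order reported for
real data), log-normal body mass (ln mean 3.0, sd 0.8 g), and dependent
CTMC rates 0.05 with q43 = 0.5 (10× asymmetry) and q13 = 0, root
resident + large-brained, on unit branch lengths. Pure-birth trees are
simulated exactly (inter-event Exp(kλ) construction; expected
root-to-tip depth Σ_{k=2..n} 1/(kλ) is the test oracle); birth–death
with extinction delegates to dendropy. Migratory tips draw their
ordinal category uniformly from {2,3,4}, residents from {0,1}.
Missingness is MCAR by default with an MAR-on-body-mass option.
A consistency validator rejects truths whose parameters make the
migration effect unidentifiable (e.g. no migration gains possible from
a resident root).

The generator emulates the statistical structure the analyses assume —
multinormal λ-structured noise, a single CTMC pair, MCAR gaps. It does
not emulate measurement error in distances, body-mass sexual
dimorphism, biogeography, or correlated missingness across sources, so
passing tests show the estimators work under their own assumptions, not
that real data meet them. The continuous brain trait and the binary
brain state are generated independently given migration (the binary
pair comes from the CTMC, the continuous trait from the allometry), so
analyses that need the binary truth read the study's
`binary_states.csv` rather than re-binarizing the continuous trait.

A separate generator (`simulate_path_data`) draws multinormal data from
a path-diagram truth whose exact direct/indirect/unanalyzed split is
computed algebraically; its default coefficients put ≈ 69% of the
Migration–Brain correlation on the direct arrow.

## Numerical choices and degenerate inputs

* λ and SEM variance parameters are optimized on transformed scales
  (bounded refinement for λ, log for variances).
* Pruning partials are rescaled per node when they underflow; the
  likelihood of an impossible configuration returns −inf, and bounded
  optimizers see a large finite penalty instead.
* Exactly-zero residuals, zero-length branches, flat λ profiles and
  sub-floor subset sizes are all defined, non-fatal cases (see the
  module docstrings).
* Ties in rate inequalities count as "not greater" (strict
  inequality), so forced-equal rates give frequency 0.

## Problem sizes used by the validation suites

The test and calibration suites run at: 200 enumeration-oracle
instances (≤ 6 tips), 500 null PGLS replicates (100 tips), 100
recovery replicates (300 tips), 50 dependent-evolution replicates and
20 null Bayes-factor replicates (300/100 tips, 8,000-iteration
chains), 15 FIML path replicates (n = 600, 20% missing). These sizes
give the calibration assertions comfortable Monte-Carlo margins while
keeping a full run in the minutes range.

## Known limitations

* The harmonic-mean marginal likelihood is noisy by nature; Bayes
  factors from short chains should be read through the 2/5/10 bands,
  not as precise numbers.
* Root-state posteriors are weakly identified when a transition rate is
  exactly zero (whole regions of state space become unreachable from
  parts of the tree); single realizations can favor a root other than
  the generating one.
* Plug-in λ coefficient SEs ignore λ uncertainty (mild overdispersion,
  see above).
* FIML assumes multinormality and missingness at random; the MAR
  stress option exists but non-ignorable missingness is out of scope.
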