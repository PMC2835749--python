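# migbrain

Comparative-phylogenetics toolkit for the question of whether migratory
passerines have relatively smaller brains than resident ones — and, if
so, which trait changed first. It provides, as one tested package, the
three analyses that question needs:

1. **Prospective (λ-PGLS).** Generalized least squares of log brain mass
   on ordinal migratory distance with log body mass (and optional
   ecological covariates), with error covariance σ²·V(λ): V is the
   Brownian tip covariance of the phylogeny and Pagel's λ ∈ [0,1] scales
   its off-diagonal, estimated by profile maximum likelihood. Reports
   coefficients, t, p, λ̂ and the partial R² of migration.
2. **Retrospective (correlated evolution of binary traits).** Both
   traits binarized (large brain = positive residual of log brain on
   log body; migratory = movements over 100 km), then modelled as a
   4-state continuous-time Markov chain over joint states
   1=(0,0) … 4=(1,1) (trait 1 = migratory, trait 2 = large brain).
   The 4-rate independent model is tested against the 8-rate dependent
   model by maximum likelihood and by MCMC: harmonic-mean marginal
   likelihoods, log-Bayes factor 2·Δlog ML with 2/5/10 evidence bands,
   reversible-jump averaging over rate partitions (including a
   rate-is-zero bin), root-state posteriors and posterior rate
   inequalities such as P(q43 > q34) — the probability that migratory
   lineages lose large brains faster than they gain them.
3. **Path analysis.** Recursive structural equation models over
   Latitude, Body, BMR, Incubation, Migration and Brain, fitted by ML
   (full-information ML under missingness), ranked by χ² fit; the
   Migration→Brain correlation decomposes exactly into direct +
   indirect + unanalyzed components by the tracing rule.

A synthetic-study generator with recorded ground truth (birth–death
trees, allometric brain masses with λ-structured noise, a dependent
CTMC binary pair, covariates, missingness) makes every estimator
testable without any external data. See `docs/methods.md` for the full
model descriptions and design choices.

## Layout

```
src/migbrain/      tree.py traits.py pgls.py ctmc.py mcmc.py sem.py
                   simulate.py pipeline.py cli.py
analysis/          numbered drivers: 01 simulate study, 02 prospective
                   PGLS, 03 retrospective CTMC, 04 path analysis
tests/             pytest suites incl. calibration checks
scripts/           acceptance.py
```

## Worked example

Generate a 300-tip synthetic study and run the three analyses:

```bash
python analysis/01_simulate_study.py --seed 1
python analysis/02_prospective_pgls.py
python analysis/03_retrospective_discrete.py
python analysis/04_path_analysis.py
```

Output of step 02 (a single 300-species realization, generating truth:
migration effect −0.025 per category, λ_true 0.78):

```
n = 300 species
migration coefficient = -0.0167 (SE 0.0129, t = -1.29, P = 0.2)
lambda_hat = 0.899, partial R^2 = 0.006
```

The coefficient is negative and within 2 SE of the truth (−0.025) but
not individually significant at this effect size and sample size — the
calibration suite shows recovery within 2 SE in ≥ 90% of replicates.
λ̂ ≈ 0.9 reflects the strong phylogenetic signal the generator injects.

Step 03, using the study's simulated binary pair (truth: q43 = 10·q34,
q13 = 0, i.e. migratory lineages lose large brains quickly and
small-brained residents never gain migration):

```
n = 300 species
log Bayes factor = 4.27 (positive)
LR statistic (ML) = 14.17
P(root large brain) = 0.750 +/- 0.163
rate inequalities: {"q43>q34": 0.988, "q43>q21": 0.992, "q24>q13": 0.936}
RJ zero-bin occupancy: {"q13": 0.979, ... "q43": 0.21, others ~0}
```

The dependent model is favored (logBF > 2), q43 > q34 in 98.8% of
posterior draws, and the reversible-jump chain pins q13 into the zero
bin 97.9% of the time — the generating dynamics, read back from tip
data alone.

Step 04 ranks the four candidate path diagrams, keeps the good-fitting
one and decomposes the Migration–Brain correlation:

```
best model: D
Migration->Brain decomposition: direct=0.213, indirect=0.000,
unanalyzed=0.050, total=0.263   (percent direct = 81.0%)
```

The same pipelines run on real inputs (a Newick tree plus a CSV/TSV
trait table; column names documented in `migbrain.traits.TRAIT_COLUMNS`)
through the CLI:

```bash
migbrain prospective config.yaml
migbrain retrospective config.yaml
migbrain path config.yaml
migbrain synth config.yaml
```

with a single YAML config holding paths, the branch-length rule
(`unit`, `grafen`, `pagel`), model formulas, MCMC settings (iterations,
burn-in, thinning, chains, prior mean, seed) and subset definitions.
Every run writes its resolved config and seeds next to its outputs.

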