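"""Configuration-driven analysis pipelines.

Three study-level analyses are wired here from the library modules:

* prospective: lambda-PGLS regressions of log brain mass on migratory
  distance with body mass and optional covariates, plus sex/family subset
  fits and the residual-based partial-R^2 summary;
* retrospective: binarization of both traits, maximum-likelihood and
  Bayesian (MH + reversible-jump) fits of the independent and dependent
  CTMC models, log-Bayes factors, root-state posteriors and rate
  inequalities;
* path: candidate structural path models compared by fit, the direct /
  indirect / unanalyzed decomposition of the brain-migration correlation,
  and a PGLS cross-check of each significant path.

Each run writes its resolved configuration (seeds included) next to its
outputs, logs one line per stage with input/output counts, and is
bit-reproducible from that file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ctmc, mcmc, pgls, sem, simulate, traits as tc
from .tree import read_newick_file, transform_branch_lengths

logger = logging.getLogger(__name__)

#: breeding-range latitude (degrees) above which a species counts as
#: non-tropical (the Tropic line)
TROPICAL_LATITUDE_DEG = 23.44


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _write_resolved_config(cfg: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _load_inputs(cfg: dict):
    tree = read_newick_file(cfg["tree"])
    table = tc.read_trait_table(cfg["traits"])
    method = cfg.get("branch_lengths", "unit")
    if method != "asis":
        tree = transform_branch_lengths(tree, method)
    in_tree = table["species"].isin(tree.tip_labels)
    dropped = table.loc[~in_tree, "species"].tolist()
    if dropped:
        logger.info("dropped %d species absent from the tree: %s%s",
                    len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")
    table = table[in_tree].reset_index(drop=True)
    logger.info("inputs: %d tree tips, %d species with traits",
                tree.n_tips, len(table))
    return tree, table, dropped


def _model_frame(table: pd.DataFrame) -> pd.DataFrame:
    t = tc.effective_brain_mass(table)
    t = t.dropna(subset=["brain_mass_g", "body_mass_g"])
    t = t[(t["brain_mass_g"] > 0) & (t["body_mass_g"] > 0)]
    t["log_brain"] = np.log(t["brain_mass_g"])
    t["log_body"] = np.log(t["body_mass_g"])
    return t


def run_prospective(cfg: dict) -> dict:
    """PGLS fits of brain size on migratory distance (overall, covariate
    model, by sex, by family)."""
    outdir = Path(cfg.get("output_dir", "results/prospective"))
    _write_resolved_config(cfg, outdir)
    tree, table, dropped = _load_inputs(cfg)
    pcfg = cfg.get("prospective", {})
    t = _model_frame(table)

    covariates = pcfg.get("covariates", [])
    binary_recode = bool(pcfg.get("binary_migration", False))
    t = t.dropna(subset=["migration_category"] + covariates)
    logger.info("prospective: %d species with complete records", len(t))
    mig = (t["migration_category"] >= 2).astype(float) if binary_recode \
        else t["migration_category"].astype(float)

    X = pd.DataFrame({"migration": mig.to_numpy(),
                      "log_body": t["log_body"].to_numpy()},
                     index=t["species"])
    for c in covariates:
        X[c] = t[c].to_numpy()
    fit = pgls.pgls_fit(t["log_brain"].to_numpy(), X, tree,
                        species=list(t["species"]))
    # reduced model at the full model's lambda so the whitened residual
    # sums are comparable
    red = pgls.pgls_fit(t["log_brain"].to_numpy(),
                        X.drop(columns=["migration"]), tree,
                        species=list(t["species"]),
                        estimate_lambda=False, lam=fit.lambda_hat)
    pr2 = pgls.partial_r2(fit, red)

    report = {
        "n_species": fit.n_species,
        "lambda_hat": fit.lambda_hat,
        "partial_r2_migration": pr2,
        "dropped_not_in_tree": dropped,
        "table": fit.summary().reset_index().to_dict(orient="records"),
    }
    fit.summary().to_csv(outdir / "pgls_table.csv")

    sub_table = t.assign(
        brain_residual=lambda d: tc.residual_brain_size(d).reindex(
            d["species"]).to_numpy()
    )
    subsets = {}
    for grouping in pcfg.get("subsets", []):
        if grouping not in t.columns:
            logger.warning("subset grouping %r absent; skipped", grouping)
            continue
        res = pgls.subset_analysis(
            sub_table, tree, grouping,
            response="brain_residual",
            predictors=["migration_category"],
            min_species=int(pcfg.get("min_subset_species", 10)),
        )
        subsets[grouping] = {
            level: (r if isinstance(r, str) else {
                "n": r.n_species,
                "coef": float(r.coefficients[1]),
                "t": float(r.t_statistics[1]),
                "p": float(r.p_values[1]),
                "lambda_hat": r.lambda_hat,
            })
            for level, r in res.items()
        }
    report["subsets"] = subsets
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    logger.info("prospective: wrote %s", outdir / "report.json")
    return report


def _binary_states(table: pd.DataFrame, non_tropical_only: bool):
    t = _model_frame(table)
    if non_tropical_only:
        before = len(t)
        t = t.dropna(subset=["latitude_deg"])
        t = t[t["latitude_deg"] > TROPICAL_LATITUDE_DEG]
        logger.info("non-tropical filter: %d -> %d species", before, len(t))
    resid = tc.residual_brain_size(t)
    pairs = tc.binarize(t, resid)
    return ctmc.JointTraitStates.from_binary(pairs), [p.species for p in pairs]


def run_retrospective(cfg: dict) -> dict:
    """Correlated-evolution analysis of the binary brain/migration pair."""
    outdir = Path(cfg.get("output_dir", "results/retrospective"))
    _write_resolved_config(cfg, outdir)
    tree, table, _ = _load_inputs(cfg)
    rcfg = cfg.get("retrospective", {})
    seed = int(cfg.get("seed", 0))

    if "binary_states" in rcfg:
        # precomputed binary pair (e.g. a synthetic study's simulated truth)
        bs = pd.read_csv(rcfg["binary_states"])
        bs = bs[bs["species"].isin(tree.tip_labels)]
        states = ctmc.JointTraitStates.from_table(bs)
        species = list(bs["species"])
        logger.info("retrospective: binary states read from %s",
                    rcfg["binary_states"])
    else:
        states, species = _binary_states(
            table, bool(rcfg.get("non_tropical_only", False)))
    if set(species) != set(tree.tip_labels):
        from .tree import prune_to_taxa

        tree = prune_to_taxa(tree, species)
        method = cfg.get("branch_lengths", "unit")
        if method != "asis":
            tree = transform_branch_lengths(tree, method)
    logger.info("retrospective: %d species in the binary analysis",
                tree.n_tips)

    chain_kw = dict(
        prior_rate_mean=float(rcfg.get("prior_rate_mean", 10.0)),
        iterations=int(rcfg.get("iterations", 50_000)),
        burn_in=int(rcfg.get("burn_in", 5_000)),
        thinning=int(rcfg.get("thinning", 10)),
    )
    n_chains = int(rcfg.get("chains", 2))

    dep_chains = [mcmc.mcmc_sample(tree, states, "dependent",
                                   seed=seed + 10 * c, **chain_kw)
                  for c in range(n_chains)]
    ind_chains = [mcmc.mcmc_sample(tree, states, "independent",
                                   seed=seed + 10 * c + 5, **chain_kw)
                  for c in range(n_chains)]
    ev = mcmc.log_bayes_factor(dep_chains[0], ind_chains[0])

    rj = mcmc.rj_mcmc(tree, states, seed=seed + 999, **chain_kw)
    root = mcmc.root_state_posterior(dep_chains[0], tree, states)
    ineq = mcmc.rate_inequality_summary(
        dep_chains[0],
        [("q43", "q34"), ("q43", "q21"), ("q24", "q13")],
    )
    ml_dep = ctmc.ml_fit(tree, states, "dependent", seed=seed)
    ml_ind = ctmc.ml_fit(tree, states, "independent", seed=seed)

    dep_chains[0].to_frame().to_csv(outdir / "dependent_chain.csv", index=False)
    ind_chains[0].to_frame().to_csv(outdir / "independent_chain.csv", index=False)
    rj.to_frame().to_csv(outdir / "rj_chain.csv", index=False)

    report = {
        "n_species": tree.n_tips,
        "log_bayes_factor": ev.log_bayes_factor,
        "evidence_band": ev.band,
        "log_marginal_dependent": ev.log_marginal_dependent,
        "log_marginal_independent": ev.log_marginal_independent,
        "ml_loglik_dependent": ml_dep.log_likelihood,
        "ml_loglik_independent": ml_ind.log_likelihood,
        "ml_rates_dependent": ml_dep.model.rates,
        "lr_statistic": 2 * (ml_dep.log_likelihood - ml_ind.log_likelihood),
        "root_posterior": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                           for k, v in root.items()},
        "rate_inequalities": ineq,
        "rj_zero_bin_occupancy": rj.zero_bin_occupancy(),
        "posterior_rate_means": {
            n: float(m) for n, m in zip(dep_chains[0].rate_names,
                                        dep_chains[0].rates.mean(axis=0))
        },
        "chain_acceptance": [c.acceptance_rate for c in dep_chains],
        "chain_warnings": [c.warning for c in dep_chains + ind_chains
                           if c.warning],
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    logger.info("retrospective: logBF=%.2f (%s); wrote %s",
                ev.log_bayes_factor, ev.band, outdir / "report.json")
    return report


#: trait-table columns backing each path-model variable; Brain, Body and
#: Incubation are log transformed before standardization
PATH_VARIABLE_COLUMNS = {
    "Latitude": ("latitude_deg", False),
    "Body": ("body_mass_g", True),
    "BMR": ("bmr_kcal_d", True),
    "Incubation": ("incubation_d", True),
    "Migration": ("migration_category", False),
    "Brain": ("brain_mass_g", True),
}


def path_data(table: pd.DataFrame) -> pd.DataFrame:
    t = tc.effective_brain_mass(table)
    out = pd.DataFrame(index=t.index)
    for var, (col, log) in PATH_VARIABLE_COLUMNS.items():
        if col not in t.columns:
            out[var] = np.nan
            continue
        x = t[col].astype(float)
        out[var] = np.log(x.where(x > 0)) if log else x
    out["species"] = t["species"].to_numpy()
    return out


def run_path(cfg: dict) -> dict:
    """Candidate path models, effect decomposition and PGLS cross-check."""
    outdir = Path(cfg.get("output_dir", "results/path"))
    _write_resolved_config(cfg, outdir)
    tree, table, _ = _load_inputs(cfg)
    pcfg = cfg.get("path", {})
    data = path_data(table)
    use_missing = bool(pcfg.get("use_missing", True))

    models = sem.candidate_models()
    wanted = pcfg.get("presets")
    if wanted:
        models = [m for m in models if m.name in wanted]
    if "model_text" in pcfg:
        models.append(sem.parse_model(pcfg["model_text"], name="custom"))

    ranking = sem.compare_candidate_models(models, data, use_missing=use_missing)
    ranking.drop(columns=[], inplace=False).to_csv(
        outdir / "model_ranking.csv", index=False)
    fits = ranking.attrs["fits"]
    best_name = next((r["model"] for _, r in ranking.iterrows()
                      if r["model"] in fits), None)
    report = {"ranking": ranking.drop(columns=[]).to_dict(orient="records")}
    if best_name is not None:
        best = fits[best_name]
        source = pcfg.get("source", "Migration")
        target = pcfg.get("target", "Brain")
        decomp = sem.effect_decomposition(best, source, target)
        report["best_model"] = best_name
        report["decomposition"] = decomp
        report["coefficients"] = {
            f"{s}->{t}": {"coef": c, "se": best.coefficient_se[(s, t)],
                          "significant": best.significant[(s, t)]}
            for (s, t), c in best.coefficients.items()
        }
        report["pgls_cross_check"] = _pgls_cross_check(best, data, tree)
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    logger.info("path: best model %s; wrote %s", report.get("best_model"),
                outdir / "report.json")
    return report


def _pgls_cross_check(fit: sem.PathFit, data: pd.DataFrame, tree) -> dict:
    """Refit each significant path as a bivariate PGLS; reports whether the
    phylogenetic fit agrees on significance at alpha = 0.05."""
    out = {}
    for (s, t), significant in fit.significant.items():
        if not significant:
            continue
        sub = data.dropna(subset=[s, t])
        sub = sub[sub["species"].isin(tree.tip_labels)]
        if len(sub) < 10:
            out[f"{s}->{t}"] = "skipped: <10 species"
            continue
        try:
            f = pgls.pgls_fit(sub[t].to_numpy(),
                              sub[[s]].set_index(sub["species"]),
                              tree, species=list(sub["species"]))
            out[f"{s}->{t}"] = {
                "pgls_p": float(f.p_values[1]),
                "agrees": bool(f.p_values[1] < 0.05),
            }
        except Exception as exc:
            out[f"{s}->{t}"] = f"failed: {exc}"
    return out


def run_synthetic(cfg: dict) -> Path:
    """Generate and persist a synthetic study directory."""
    outdir = Path(cfg.get("output_dir", "results/synthetic"))
    scfg = dict(cfg.get("synthetic", {}))
    scfg.setdefault("seed", int(cfg.get("seed", 0)))
    truth = simulate.StudyTruth(**scfg)
    study = simulate.simulate_study(truth)
    study.write(outdir)
    _write_resolved_config(cfg, outdir)
    logger.info("synthetic: wrote study with %d tips to %s",
                truth.n_tips, outdir)
    return outdir
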