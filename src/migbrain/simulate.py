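"""Synthetic comparative studies with known ground truth.

A study is a birth-death phylogeny plus a per-species trait table and a
binary (migratory, brain_large) pair, generated so that every analysis in
the package can be exercised against a recorded truth:

* body mass: log-normal across species;
* brain mass: allometric in log body mass (default slope 0.633) plus a
  migration effect and multinormal noise with Pagel's-lambda phylogenetic
  structure;
* migration / brain binary states: a joint 4-state CTMC evolved down the
  tree (so the retrospective analyses see genuinely tree-generated data);
* ordinal migration categories: migratory tips draw from {2,3,4},
  residents from {0,1};
* covariates (latitude, diet, forest, monogamy, incubation, fledging,
  BMR) with simple configurable correlations, plus MCAR (optionally MAR)
  missingness.

Every output records the seed and a truth fingerprint.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ctmc
from .tree import Phylogeny, lambda_transform, phylo_vcv, read_newick, write_newick

logger = logging.getLogger(__name__)


# -- trees ------------------------------------------------------------------

def simulate_tree(n_tips: int, birth: float = 1.0, death: float = 0.0,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None) -> Phylogeny:
    """Birth-death tree conditioned on the number of extant tips.

    Pure-birth (Yule) trees are drawn directly: starting from two lineages
    at the root, waiting times between speciations are Exp(k*birth) while
    k lineages exist, the splitting lineage is uniform, and the final
    stretch to the present is the Exp(n*birth) time that would have
    produced tip n+1.  With extinction (death > 0) the tree is delegated
    to dendropy's birth-death sampler.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if rng is None:
        rng = np.random.default_rng(seed)
    if death == 0.0:
        return _yule_tree(n_tips, birth, rng)
    import dendropy
    from dendropy.simulate import treesim
    import random as _random

    pyrng = _random.Random(int(rng.integers(2**31)))
    dtree = treesim.birth_death_tree(
        birth_rate=birth, death_rate=death, num_extant_tips=n_tips,
        rng=pyrng,
    )
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1}"
    return read_newick(dtree.as_string(schema="newick").strip())


def _yule_tree(n_tips: int, birth: float,
               rng: np.random.Generator) -> Phylogeny:
    # event times: speciation while k lineages exist, k = 2..n-1; plus the
    # final Exp(n*birth) stretch to the present
    times = [0.0]
    t = 0.0
    for k in range(2, n_tips):
        t += rng.exponential(1.0 / (birth * k))
        times.append(t)
    present = t + rng.exponential(1.0 / (birth * n_tips))

    # node bookkeeping: each lineage is a (node_id, start_time) pair
    parent_of: dict[int, int] = {}
    start: dict[int, float] = {}
    end: dict[int, float] = {}
    root_id = 0
    start[root_id] = 0.0
    end[root_id] = 0.0
    next_id = 1
    lineages: list[int] = []
    for _ in range(2):
        parent_of[next_id] = root_id
        start[next_id] = 0.0
        lineages.append(next_id)
        next_id += 1
    for ev in range(1, n_tips - 1):
        t_ev = times[ev]
        i = int(rng.integers(len(lineages)))
        node = lineages[i]
        end[node] = t_ev
        d1, d2 = next_id, next_id + 1
        next_id += 2
        for d in (d1, d2):
            parent_of[d] = node
            start[d] = t_ev
        lineages[i] = d1
        lineages.append(d2)
    for node in lineages:
        end[node] = present

    # assemble postorder arrays
    children: dict[int, list[int]] = {}
    for c, p in parent_of.items():
        children.setdefault(p, []).append(c)
    order: list[int] = []
    stack = [root_id]
    while stack:  # iterative postorder
        nd = stack.pop()
        order.append(nd)
        stack.extend(children.get(nd, []))
    order.reverse()
    idx = {nd: i for i, nd in enumerate(order)}
    n_nodes = len(order)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    bl = np.full(n_nodes, np.nan)
    tip_labels: list[str] = []
    tip_nodes: list[int] = []
    tip_counter = 0
    for nd in order:
        i = idx[nd]
        if nd != root_id:
            parent[i] = idx[parent_of[nd]]
            bl[i] = end[nd] - start[nd]
        if nd not in children:
            tip_counter += 1
            tip_labels.append(f"sp{tip_counter}")
            tip_nodes.append(i)
    return Phylogeny(parent=parent, branch_lengths=bl, tip_labels=tip_labels,
                     tip_nodes=np.asarray(tip_nodes, dtype=np.int64))


def yule_expected_depth(n_tips: int, birth: float) -> float:
    """Closed-form expected root-to-tip depth of the Yule construction:
    sum_{k=2}^{n} 1/(k*birth)."""
    return float(sum(1.0 / (k * birth) for k in range(2, n_tips + 1)))


# -- continuous traits ------------------------------------------------------

def simulate_continuous(tree: Phylogeny, lambda_true: float, sigma2: float,
                        fixed_effects: np.ndarray | float = 0.0,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None) -> pd.Series:
    """Multinormal tip values with covariance sigma2 * V(lambda) plus a
    fixed-effects surface; indexed by tip label."""
    if not 0.0 <= lambda_true <= 1.0:
        raise ValueError("lambda_true must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    V = lambda_transform(phylo_vcv(tree), lambda_true).matrix
    n = tree.n_tips
    mean = np.broadcast_to(np.asarray(fixed_effects, dtype=float), (n,))
    if sigma2 == 0.0:
        vals = mean.copy()
    else:
        L = np.linalg.cholesky(sigma2 * V + 1e-12 * np.eye(n))
        vals = mean + L @ rng.standard_normal(n)
    return pd.Series(vals, index=pd.Index(tree.tip_labels, name="species"))


# -- whole studies ----------------------------------------------------------

@dataclass
class StudyTruth:
    """Generating parameters of a synthetic study."""

    n_tips: int = 600
    birth: float = 1.0
    death: float = 0.0
    #: log-log brain~body allometry
    allometry_intercept: float = -1.3
    allometry_slope: float = 0.633
    #: phylogenetic signal of the brain noise
    lambda_true: float = 0.78
    #: effect of one ordinal migration category on log brain mass
    beta_true: float = -0.025
    sigma2_brain: float = 0.018
    #: log body mass distribution (natural log, grams)
    log_body_mean: float = 3.0
    log_body_sd: float = 0.8
    #: joint CTMC generating rates, trait1=migratory, trait2=brain_large
    ctmc_rates: dict = field(default_factory=lambda: {
        "q12": 0.05, "q13": 0.0, "q21": 0.05, "q24": 0.05,
        "q31": 0.05, "q34": 0.05, "q42": 0.05, "q43": 0.5,
    })
    root_state: int = 2              # resident + large brain
    #: CTMC runs on unit branch lengths (the headline convention)
    unit_branch_ctmc: bool = True
    #: multinomial over categories {2,3,4} for migratory tips
    migratory_category_probs: tuple = (1 / 3, 1 / 3, 1 / 3)
    missing_fraction: dict = field(default_factory=lambda: {
        "latitude_deg": 0.0, "incubation_d": 0.0, "fledging_d": 0.0,
        "bmr_kcal_d": 0.0, "brain_mass_g": 0.0,
    })
    mar_on_body_mass: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true outside [0, 1]")
        if any(v < 0 for v in self.ctmc_rates.values()):
            raise ValueError("negative CTMC rate")
        gain = self.ctmc_rates.get("q13", 0) + self.ctmc_rates.get("q24", 0)
        if gain == 0 and self.root_state in (1, 2) and self.beta_true != 0:
            raise ValueError(
                "no migration gains possible from a resident root but "
                "beta_true is nonzero: the migration effect would be "
                "unidentifiable"
            )
        if not np.isclose(sum(self.migratory_category_probs), 1.0):
            raise ValueError("migratory_category_probs must sum to 1")

    def fingerprint(self) -> str:
        import hashlib

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SyntheticStudy:
    tree: Phylogeny
    table: pd.DataFrame
    binary: pd.DataFrame          # species, migratory, brain_large (truth)
    truth: StudyTruth
    states: ctmc.JointTraitStates

    def write(self, outdir) -> None:
        """Persist as Newick + CSV + JSON truth record."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(write_newick(self.tree) + "\n")
        self.table.to_csv(out / "traits.csv", index=False)
        self.binary.to_csv(out / "binary_states.csv", index=False)
        record = dataclasses.asdict(self.truth)
        record["fingerprint"] = self.truth.fingerprint()
        (out / "truth.json").write_text(json.dumps(record, indent=2, default=str))


def simulate_study(truth: StudyTruth) -> SyntheticStudy:
    """Generate a complete synthetic study from a truth record."""
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    tree = simulate_tree(truth.n_tips, truth.birth, truth.death, rng=rng)

    from .tree import transform_branch_lengths

    ctmc_tree = (transform_branch_lengths(tree, "unit")
                 if truth.unit_branch_ctmc else tree)
    model = ctmc.PairedBinaryModel(kind="dependent", rates=dict(truth.ctmc_rates))
    states = ctmc.simulate_pair(ctmc_tree, model, root_state=truth.root_state,
                                rng=rng)
    mig = states.marginal("migratory")
    brn = states.marginal("brain_large")

    sp = tree.tip_labels
    n = len(sp)
    migratory = np.array([mig[s] for s in sp])
    cats = np.where(
        migratory == 1,
        rng.choice([2, 3, 4], size=n, p=truth.migratory_category_probs),
        rng.choice([0, 1], size=n),
    )

    log_body = rng.normal(truth.log_body_mean, truth.log_body_sd, size=n)
    mean_brain = (truth.allometry_intercept
                  + truth.allometry_slope * log_body
                  + truth.beta_true * cats)
    log_brain = simulate_continuous(
        tree, truth.lambda_true, truth.sigma2_brain,
        fixed_effects=mean_brain, rng=rng,
    ).to_numpy()

    # covariates: latitude higher for migratory species; BMR and incubation
    # allometric in body mass with noise; binary ecology flags
    latitude = np.clip(
        rng.normal(18 + 22 * migratory + 4 * cats, 10), 0, 70
    )
    bmr = np.exp(-1.0 + 0.7 * log_body + rng.normal(0, 0.15, n))
    incubation = np.exp(2.2 + 0.08 * log_body + rng.normal(0, 0.1, n))
    fledging = np.exp(2.5 + 0.1 * log_body + rng.normal(0, 0.12, n))
    table = pd.DataFrame({
        "species": sp,
        "brain_mass_g": np.exp(log_brain),
        "body_mass_g": np.exp(log_body),
        "migration_category": cats,
        "latitude_deg": latitude,
        "insectivore": rng.integers(0, 2, n),
        "frugivore": rng.integers(0, 2, n),
        "forest": rng.integers(0, 2, n),
        "monogamous": rng.integers(0, 2, n),
        "incubation_d": incubation,
        "fledging_d": fledging,
        "bmr_kcal_d": bmr,
        "family": [f"fam{chr(65 + i % 6)}" for i in range(n)],
    })

    for col, frac in truth.missing_fraction.items():
        if frac <= 0 or col not in table:
            continue
        if truth.mar_on_body_mass:
            # heavier species more likely measured: missingness decreasing
            # in log body mass
            r = log_body - log_body.min()
            w = 1.0 - r / max(r.max(), 1e-9)
            p = frac * w / w.mean()
            mask = rng.uniform(size=n) < np.clip(p, 0, 1)
        else:
            mask = rng.uniform(size=n) < frac
        table.loc[mask, col] = np.nan

    binary = pd.DataFrame({
        "species": sp,
        "migratory": migratory,
        "brain_large": [brn[s] for s in sp],
    })
    table.attrs["seed"] = truth.seed
    table.attrs["truth_fingerprint"] = truth.fingerprint()
    return SyntheticStudy(tree=tree, table=table, binary=binary,
                          truth=truth, states=states)


def calibrate_beta_for_partial_r2(target_r2: float, truth: StudyTruth,
                                  n_search: int = 25) -> float:
    """Solve (bisection on |beta|) for the migration effect size giving an
    expected PGLS partial R^2 near ``target_r2`` under the study's other
    settings, using the analytic whitened-variance ratio on one simulated
    design."""
    from .pgls import partial_r2, pgls_fit

    def mean_r2(beta: float, reps: int = 3) -> float:
        vals = []
        for r in range(reps):
            t2 = dataclasses.replace(truth, beta_true=beta, seed=truth.seed + 7 * r)
            st = simulate_study(t2)
            tab = st.table.dropna(subset=["brain_mass_g", "body_mass_g"])
            y = np.log(tab["brain_mass_g"].to_numpy())
            X = tab[["migration_category"]].copy()
            X["log_body"] = np.log(tab["body_mass_g"])
            X.index = tab["species"]
            full = pgls_fit(y, X, st.tree, species=list(tab["species"]))
            red = pgls_fit(y, X[["log_body"]], st.tree,
                           species=list(tab["species"]))
            vals.append(partial_r2(full, red))
        return float(np.mean(vals))

    lo, hi = 0.0, 0.5
    for _ in range(n_search):
        mid = 0.5 * (lo + hi)
        if mean_r2(-mid) < target_r2:
            lo = mid
        else:
            hi = mid
    return -0.5 * (lo + hi)


# -- path-analysis data -----------------------------------------------------

#: generating standardized coefficients of the default path-shaped study:
#: (source, target) -> coefficient; exogenous correlation listed separately.
PATH_TRUTH_COEFFICIENTS = {
    ("Body", "BMR"): 0.7,
    ("Body", "Incubation"): 0.5,
    ("Body", "Brain"): 0.6,
    ("Latitude", "Migration"): 0.6,
    ("BMR", "Migration"): 0.1,
    ("Incubation", "Brain"): 0.15,
    ("Migration", "Brain"): -0.3,
}
PATH_TRUTH_EXO_CORR = {("Latitude", "Body"): -0.45}


def path_truth_decomposition(source: str = "Migration",
                             target: str = "Brain",
                             coefficients: dict | None = None,
                             exo_corr: dict | None = None) -> dict:
    """Exact direct/indirect/unanalyzed decomposition implied by the
    generating coefficients (linear algebra on the standardized system)."""
    coefs = coefficients or PATH_TRUTH_COEFFICIENTS
    exo = exo_corr or PATH_TRUTH_EXO_CORR
    variables = sorted({v for e in coefs for v in e}
                       | {v for e in exo for v in e})
    pos = {v: i for i, v in enumerate(variables)}
    p = len(variables)
    B = np.zeros((p, p))
    for (s, t), c in coefs.items():
        B[pos[t], pos[s]] = c
    targets = {t for _, t in coefs}
    Psi = np.zeros((p, p))
    for v in variables:
        if v not in targets:
            Psi[pos[v], pos[v]] = 1.0
    for (a, b), r in exo.items():
        Psi[pos[a], pos[b]] = Psi[pos[b], pos[a]] = r
    # solve error variances so every implied variance is 1 (standardized
    # system); endogenous variables in topological order
    A = np.linalg.inv(np.eye(p) - B)
    for v in variables:
        if v in targets:
            Psi[pos[v], pos[v]] = 0.0
    for v in _topo_order(variables, coefs):
        if v not in targets:
            continue
        Sigma = A @ Psi @ A.T
        evar = 1.0 - Sigma[pos[v], pos[v]]
        if evar <= 0:
            raise ValueError(f"coefficients imply variance > 1 for {v}")
        Psi[pos[v], pos[v]] = evar
    Sigma = A @ Psi @ A.T
    direct = B[pos[target], pos[source]]
    T = A - np.eye(p)
    indirect = T[pos[target], pos[source]] - direct
    total = Sigma[pos[target], pos[source]]
    out = {
        "direct": float(direct),
        "indirect": float(indirect),
        "unanalyzed": float(total - direct - indirect),
        "total": float(total),
        "Sigma": Sigma,
        "variables": variables,
        "Psi": Psi,
        "B": B,
    }
    if total != 0:
        out["percent_direct"] = 100.0 * direct / total
    return out


def _topo_order(variables, coefs):
    incoming = {v: {s for (s, t) in coefs if t == v} for v in variables}
    out, ready = [], [v for v in variables if not incoming[v]]
    while ready:
        v = ready.pop()
        out.append(v)
        for w in variables:
            if v in incoming[w]:
                incoming[w].discard(v)
                if not incoming[w]:
                    ready.append(w)
    return out


def simulate_path_data(n: int, seed: int | None = None,
                       missing_fraction: float = 0.0,
                       coefficients: dict | None = None,
                       exo_corr: dict | None = None):
    """Multinormal draws from the standardized path-shaped truth, with
    optional MCAR missingness.  Returns (DataFrame, truth dict) where the
    truth holds the generating coefficients and the exact decomposition
    of the Migration-Brain correlation."""
    truth = path_truth_decomposition(coefficients=coefficients,
                                     exo_corr=exo_corr)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(truth["Sigma"] + 1e-12 * np.eye(len(truth["variables"])))
    X = rng.standard_normal((n, len(truth["variables"]))) @ L.T
    df = pd.DataFrame(X, columns=truth["variables"])
    if missing_fraction > 0:
        mask = rng.uniform(size=df.shape) < missing_fraction
        df = df.mask(mask)
    truth = dict(truth)
    truth["coefficients"] = dict(coefficients or PATH_TRUTH_COEFFICIENTS)
    truth["exo_corr"] = dict(exo_corr or PATH_TRUTH_EXO_CORR)
    truth["seed"] = seed
    return df, truth
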