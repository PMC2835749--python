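"""Phylogenetic generalized least squares with maximum-likelihood
estimation of Pagel's lambda.

The regression error covariance is sigma^2 * V(lambda), where V is the
Brownian tip variance-covariance matrix of the phylogeny and V(lambda)
multiplies its off-diagonal entries by lambda in [0, 1].  sigma^2 is
profiled out analytically; lambda is maximized on a grid over [0, 1]
followed by bounded local refinement, so flat or multimodal profiles
cannot trap a purely local search.

Coefficient standard errors use the (n - p)-denominator variance estimate
and two-sided p-values come from the t distribution with n - p degrees of
freedom, p counting all design columns including the intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .tree import Phylogeny, PhyloCovariance, lambda_transform, phylo_vcv, prune_to_taxa

logger = logging.getLogger(__name__)

LAMBDA_GRID_POINTS = 101
LAMBDA_TOL = 1e-6
#: profile treated as flat when the best and worst grid log-likelihood differ
#: by less than this
FLAT_PROFILE_TOL = 1e-6


@dataclass
class PGLSFit:
    """Result of a single PGLS fit."""

    names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    lambda_hat: float
    log_likelihood: float
    n_species: int
    df_resid: int
    rss_whitened: float          # residual sum of squares in whitened space
    sigma2_ml: float
    species: list[str] = field(default_factory=list)
    lambda_se: float | None = None
    lambda_profile_flat: bool = False
    reml: bool = False

    def summary(self) -> pd.DataFrame:
        """Tidy per-predictor table (Parameter, SE, t, P)."""
        return pd.DataFrame(
            {
                "Parameter": self.coefficients,
                "SE": self.standard_errors,
                "t": self.t_statistics,
                "P": self.p_values,
            },
            index=pd.Index(self.names, name="Variable"),
        )


def _gls_profile(y: np.ndarray, X: np.ndarray, V: np.ndarray, reml: bool):
    """GLS estimates and profile log-likelihood for fixed covariance V.

    Returns (beta, rss_whitened, sigma2_ml, loglik, XtViX_inv, logdetV).
    """
    n, p = X.shape
    L = np.linalg.cholesky(V)
    wy = solve_triangular(L, y, lower=True)
    wX = solve_triangular(L, X, lower=True)
    XtX = wX.T @ wX
    beta = np.linalg.solve(XtX, wX.T @ wy)
    resid = wy - wX @ beta
    rss = float(resid @ resid)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    if reml:
        sigma2 = rss / (n - p)
        sign, logdetXtX = np.linalg.slogdet(XtX)
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi * sigma2)
            + logdetV
            + logdetXtX
            + (n - p)
        )
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdetV + n)
    return beta, rss, sigma2, ll, np.linalg.inv(XtX), logdetV


def pgls_fit(
    y,
    X,
    tree: Phylogeny | None = None,
    *,
    V: PhyloCovariance | None = None,
    species: list[str] | None = None,
    names: list[str] | None = None,
    estimate_lambda: bool = True,
    lam: float = 1.0,
    reml: bool = False,
    add_intercept: bool = True,
) -> PGLSFit:
    """Fit a PGLS regression of ``y`` on ``X`` under the phylogeny.

    Parameters
    ----------
    y, X
        Response vector and predictor matrix/DataFrame.  When ``X`` is a
        DataFrame its columns name the predictors and its index (or
        ``species``) names the species; species must match the tree's tips
        exactly (after pruning the tree to the modelled species).
    tree, V
        Either a phylogeny (its Brownian VCV is computed and, if needed,
        pruned/reordered) or a precomputed :class:`PhyloCovariance`.
    estimate_lambda
        Maximize the profile likelihood over lambda in [0, 1]; otherwise
        fit at the fixed value ``lam``.
    reml
        Use restricted maximum likelihood for the profile; default ML.
    """
    if isinstance(X, pd.DataFrame):
        if species is None:
            species = [str(s) for s in X.index]
        if names is None:
            names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(np.asarray(y)):
        X = X.T
    y = np.asarray(y, dtype=float)
    n = len(y)
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values in y/X; apply listwise deletion first")
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        names = ["(Intercept)"] + names
    p = X.shape[1]
    if n <= p + 1:
        raise ValueError(f"too few species (n={n}) for {p} parameters")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular design matrix")

    if V is None:
        if tree is None:
            raise ValueError("provide a tree or a covariance matrix")
        if species is None:
            raise ValueError("species labels are required with a tree")
        tree_sp = set(tree.tip_labels)
        miss = [s for s in species if s not in tree_sp]
        if miss:
            raise ValueError(f"species not in tree: {miss}")
        if set(species) != tree_sp:
            tree = prune_to_taxa(tree, list(species))
        V = phylo_vcv(tree).reorder(list(species))
    elif species is not None and V.labels != list(species):
        V = V.reorder(list(species))
    V0 = V.matrix
    if V0.shape[0] != n:
        raise ValueError("covariance dimension does not match data")

    def profile(lmb: float):
        Vl = V0 * lmb
        np.fill_diagonal(Vl, np.diag(V0))
        return _gls_profile(y, X, Vl, reml)

    flat = False
    if estimate_lambda:
        grid = np.linspace(0.0, 1.0, LAMBDA_GRID_POINTS)
        lls = np.array([profile(g)[3] for g in grid])
        k = int(np.argmax(lls))
        flat = (lls.max() - lls.min()) < FLAT_PROFILE_TOL
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, LAMBDA_GRID_POINTS - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda g: -profile(g)[3],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": LAMBDA_TOL},
            )
            lam_hat = float(res.x)
            if profile(lam_hat)[3] < lls[k]:
                lam_hat = float(grid[k])
        else:
            lam_hat = float(grid[k])
        if flat:
            logger.warning("lambda profile is flat within tolerance; "
                           "lambda_hat=%.3f is weakly identified", lam_hat)
    else:
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        lam_hat = float(lam)

    lambda_se = None
    if estimate_lambda:
        # curvature of the profile log-likelihood around lambda_hat,
        # evaluated on a stencil kept inside [0, 1]
        h = 1e-3
        c = min(max(lam_hat, h), 1.0 - h)
        d2 = (profile(c + h)[3] - 2.0 * profile(c)[3] + profile(c - h)[3]) / h**2
        if d2 < 0:
            lambda_se = float(1.0 / np.sqrt(-d2))

    beta, rss, sigma2_ml, ll, XtX_inv, _ = profile(lam_hat)
    df = n - p
    sigma2_unbiased = rss / df
    se = np.sqrt(np.diag(XtX_inv) * sigma2_unbiased)
    tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    return PGLSFit(
        names=names,
        coefficients=beta,
        standard_errors=se,
        t_statistics=tstat,
        p_values=pvals,
        lambda_hat=lam_hat,
        log_likelihood=float(ll),
        n_species=n,
        df_resid=df,
        rss_whitened=rss,
        sigma2_ml=sigma2_ml,
        species=list(species) if species is not None else [],
        lambda_se=lambda_se,
        lambda_profile_flat=flat,
        reml=reml,
    )


def partial_r2(fit_full: PGLSFit, fit_reduced: PGLSFit) -> float:
    """Proportion of GLS-whitened residual variance explained by the focal
    predictor: (RSS_reduced - RSS_full) / RSS_reduced.

    Both fits must be on the same species; the reduced model is the full
    model minus the focal predictor(s).
    """
    if fit_full.n_species != fit_reduced.n_species:
        raise ValueError("fits are on different species sets")
    if len(fit_reduced.names) >= len(fit_full.names):
        raise ValueError("reduced model is not nested in the full model")
    r = (fit_reduced.rss_whitened - fit_full.rss_whitened) / fit_reduced.rss_whitened
    return float(max(r, 0.0))


def subset_analysis(
    table: pd.DataFrame,
    tree: Phylogeny,
    grouping: str,
    response: str,
    predictors: list[str],
    min_species: int = 10,
    **fit_kwargs,
) -> dict[str, "PGLSFit | str"]:
    """One PGLS fit per level of a grouping column (family or sex), each on
    the tree pruned to that group's species.

    Groups with fewer complete-record species than ``min_species`` are
    reported as skipped (string reason) rather than fitted.
    """
    if grouping not in table.columns:
        raise ValueError(f"grouping column {grouping!r} absent from table")
    results: dict[str, PGLSFit | str] = {}
    cols = [response] + predictors
    for level, sub in table.groupby(grouping):
        sub = sub.dropna(subset=cols)
        sub = sub[sub["species"].isin(tree.tip_labels)]
        if len(sub) < min_species:
            results[str(level)] = f"skipped: {len(sub)} species < floor {min_species}"
            continue
        fit = pgls_fit(
            sub[response].to_numpy(),
            sub[predictors],
            tree,
            species=list(sub["species"]),
            names=predictors,
            **fit_kwargs,
        )
        results[str(level)] = fit
    return results
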