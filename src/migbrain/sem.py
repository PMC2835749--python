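"""Linear path analysis (recursive structural equation models over
observed variables) fitted by maximum likelihood with multinormal errors,
with full-information ML (FIML) for incomplete rows.

The models here are Wright-style path diagrams: directed arrows among
named observed variables, free covariances among the exogenous variables
("unanalyzed" associations), and one error term per endogenous variable.
All variables are standardized before fitting, so path coefficients are
standardized effects and the model-implied covariance matrix is an
implied correlation matrix.  A fitted correlation between two variables
decomposes exactly into

    direct   (the single arrow, if present)
  + indirect (sum over directed chains of coefficient products)
  + unanalyzed/spurious (every remaining tracing path: chains passing
    through exogenous covariances or shared causes)

which is the classical tracing-rule decomposition.

Model fit uses the ML discrepancy F = log|S(th)| + tr(S S(th)^-1)
- log|S| - p with chi-square = (n - 1) F on complete data; with FIML the
chi-square is twice the log-likelihood gap to the saturated multinormal
model (means free in both, mirroring the missing-data treatment of
standard SEM software).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


# -- model specification ----------------------------------------------------

@dataclass
class PathModel:
    """A recursive path diagram over observed variables."""

    variables: list[str]
    edges: list[tuple[str, str]]                 # (source, target)
    covariances: list[tuple[str, str]] = field(default_factory=list)
    name: str = "model"

    def __post_init__(self) -> None:
        known = set(self.variables)
        for s, t in self.edges:
            if s not in known or t not in known:
                raise ValueError(f"edge {s}->{t} uses unknown variable")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        self._check_acyclic()
        endo = self.endogenous()
        for a, b in self.covariances:
            if a in endo or b in endo:
                raise ValueError(
                    f"free covariance {a}~~{b} involves an endogenous variable"
                )

    def endogenous(self) -> list[str]:
        tgt = {t for _, t in self.edges}
        return [v for v in self.variables if v in tgt]

    def exogenous(self) -> list[str]:
        tgt = {t for _, t in self.edges}
        return [v for v in self.variables if v not in tgt]

    def _check_acyclic(self) -> None:
        order: list[str] = []
        incoming = {v: {s for s, t in self.edges if t == v} for v in self.variables}
        ready = [v for v in self.variables if not incoming[v]]
        while ready:
            v = ready.pop()
            order.append(v)
            for w in self.variables:
                if v in incoming[w]:
                    incoming[w].discard(v)
                    if not incoming[w]:
                        ready.append(w)
        if len(order) != len(self.variables):
            raise ValueError("path model contains a cycle")

    def n_free_params(self) -> int:
        n_exo = len(self.exogenous())
        return len(self.edges) + n_exo + len(self.covariances) + len(self.endogenous())

    def degrees_of_freedom(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2 - self.n_free_params()


def parse_model(text: str, name: str = "model") -> PathModel:
    """Parse a plain-text model block.

    One statement per line: ``A -> B`` (directed effect) or ``A ~~ B``
    (free covariance between exogenous variables); ``#`` starts a comment.
    The variable set is inferred from the statements.
    """
    edges: list[tuple[str, str]] = []
    covs: list[tuple[str, str]] = []
    variables: list[str] = []

    def note(v: str) -> None:
        if v not in variables:
            variables.append(v)

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "->" in line:
            s, t = (x.strip() for x in line.split("->", 1))
            if not s or not t:
                raise ValueError(f"line {lineno}: malformed edge {raw!r}")
            note(s), note(t)
            edges.append((s, t))
        elif "~~" in line:
            a, b = (x.strip() for x in line.split("~~", 1))
            note(a), note(b)
            covs.append((a, b))
        else:
            raise ValueError(f"line {lineno}: cannot parse {raw!r}")
    return PathModel(variables=variables, edges=edges, covariances=covs, name=name)


# -- fitting ----------------------------------------------------------------

@dataclass
class PathFit:
    model: PathModel
    coefficients: dict[tuple[str, str], float]        # standardized
    coefficient_se: dict[tuple[str, str], float]
    significant: dict[tuple[str, str], bool]          # |z| test at alpha=.05
    exo_covariances: dict[tuple[str, str], float]
    error_variances: dict[str, float]
    chi_square: float
    df: int
    p_value: float
    implied_correlation: pd.DataFrame
    n_effective: int
    log_likelihood: float | None = None
    used_fiml: bool = False
    converged: bool = True

    @property
    def good_fit(self) -> bool:
        return self.p_value > 0.05

    def coefficient_matrix(self) -> np.ndarray:
        """B with B[target, source] = standardized coefficient."""
        v = self.model.variables
        pos = {x: i for i, x in enumerate(v)}
        B = np.zeros((len(v), len(v)))
        for (s, t), c in self.coefficients.items():
            B[pos[t], pos[s]] = c
        return B


class _Parameterization:
    """Packs/unpacks the free parameters.

    Layout: edge coefficients (free), exogenous log-variances, exogenous
    covariances (free), endogenous log error variances.
    """

    def __init__(self, model: PathModel):
        self.model = model
        self.exo = model.exogenous()
        self.endo = model.endogenous()
        self.k = model.n_free_params()
        self.pos = {v: i for i, v in enumerate(model.variables)}

    def start(self) -> np.ndarray:
        x = np.zeros(self.k)
        i = len(self.model.edges)
        x[i:i + len(self.exo)] = 0.0          # log var = 0 -> var 1
        i += len(self.exo) + len(self.model.covariances)
        x[i:] = np.log(0.5)                   # error variances
        x[: len(self.model.edges)] = 0.1
        return x

    def matrices(self, x: np.ndarray):
        p = len(self.model.variables)
        B = np.zeros((p, p))
        i = 0
        for (s, t) in self.model.edges:
            B[self.pos[t], self.pos[s]] = x[i]
            i += 1
        Psi = np.zeros((p, p))
        for v in self.exo:
            Psi[self.pos[v], self.pos[v]] = np.exp(x[i])
            i += 1
        for (a, b) in self.model.covariances:
            Psi[self.pos[a], self.pos[b]] = x[i]
            Psi[self.pos[b], self.pos[a]] = x[i]
            i += 1
        for v in self.endo:
            Psi[self.pos[v], self.pos[v]] = np.exp(x[i])
            i += 1
        return B, Psi

    def implied_sigma(self, x: np.ndarray) -> np.ndarray:
        B, Psi = self.matrices(x)
        A = np.linalg.inv(np.eye(len(self.model.variables)) - B)
        return A @ Psi @ A.T


def _standardize(data: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    z = data[variables].astype(float).copy()
    for c in variables:
        sd = z[c].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"variable {c!r} has zero or undefined variance")
        z[c] = (z[c] - z[c].mean()) / sd
    return z


def _ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    p = S.shape[0]
    sign, logdet_sigma = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf
    sign_s, logdet_s = np.linalg.slogdet(S)
    return float(logdet_sigma + np.trace(S @ np.linalg.inv(Sigma))
                 - logdet_s - p)


def _fiml_loglik(means, Sigma, patterns) -> float:
    """Sum of per-case multinormal log-densities over missingness patterns.

    ``patterns`` is a list of (observed-column index array, data block)."""
    ll = 0.0
    for idx, block in patterns:
        mu = means[idx]
        Sub = Sigma[np.ix_(idx, idx)]
        sign, logdet = np.linalg.slogdet(Sub)
        if sign <= 0:
            return -np.inf
        inv = np.linalg.inv(Sub)
        d = block - mu
        q = np.einsum("ij,jk,ik->i", d, inv, d)
        ll += float(-0.5 * (len(idx) * np.log(2 * np.pi) + logdet) * len(block)
                    - 0.5 * q.sum())
    return ll


def _patterns(z: pd.DataFrame):
    X = z.to_numpy(dtype=float)
    obs_mask = ~np.isnan(X)
    out = []
    keys, inverse = np.unique(obs_mask, axis=0, return_inverse=True)
    for k, key in enumerate(keys):
        if not key.any():
            continue
        rows = X[inverse == k][:, key]
        out.append((np.flatnonzero(key), rows))
    return out


def _saturated_fiml_loglik(z: pd.DataFrame) -> float:
    """FIML log-likelihood of the saturated multinormal model (free mean
    vector and unstructured covariance), fitted by direct optimization of
    the Cholesky factor."""
    p = z.shape[1]
    pats = _patterns(z)
    tri = np.tril_indices(p)

    def unpack(x):
        mu = x[:p]
        Lm = np.zeros((p, p))
        Lm[tri] = x[p:]
        d = np.arange(p)
        Lm[d, d] = np.exp(Lm[d, d])
        return mu, Lm @ Lm.T

    cc = z.dropna()
    if len(cc) > p + 1:
        S0 = np.cov(cc.to_numpy(dtype=float), rowvar=False, ddof=1)
        mu0 = cc.mean().to_numpy()
    else:
        S0 = np.eye(p)
        mu0 = np.zeros(p)
    L0 = np.linalg.cholesky(S0 + 1e-6 * np.eye(p))
    start = L0[tri].copy()
    diag_positions = [np.flatnonzero((tri[0] == i) & (tri[1] == i))[0]
                      for i in range(p)]
    for i, pos in enumerate(diag_positions):
        start[pos] = np.log(max(L0[i, i], 1e-6))  # log-diagonal parameterization
    x0 = np.concatenate([mu0, start])

    def neg(x):
        mu, Sig = unpack(x)
        ll = _fiml_loglik(mu, Sig, pats)
        return -ll if np.isfinite(ll) else 1e10

    res = optimize.minimize(neg, x0, method="L-BFGS-B")
    return -float(res.fun)


def sem_fit(model: PathModel, data: pd.DataFrame,
            use_missing: bool = False) -> PathFit:
    """Fit the path model by maximum likelihood.

    Parameters
    ----------
    model
        The path diagram; every variable must be a numeric column of
        ``data``.
    data
        One row per case.  Missing values are NaN.  Without
        ``use_missing`` rows with any missing modelled variable are
        dropped (listwise); with it, full-information ML uses every row
        through its observed pattern, with free means.
    """
    if len(model.variables) < 3:
        raise ValueError("need at least 3 observed variables")
    if model.degrees_of_freedom() < 0:
        raise ValueError(
            f"model not identified: {model.n_free_params()} free parameters "
            f"exceed the {len(model.variables) * (len(model.variables) + 1) // 2} "
            "observed moments"
        )
    missing_cols = [v for v in model.variables if v not in data.columns]
    if missing_cols:
        raise ValueError(f"data lacks modelled variables: {missing_cols}")
    z = _standardize(data, model.variables)
    par = _Parameterization(model)
    p = len(model.variables)

    if not use_missing:
        z = z.dropna()
        n = len(z)
        if n <= p + 1:
            raise ValueError("too few complete cases")
        S = np.cov(z.to_numpy(dtype=float), rowvar=False, ddof=1)
        sign, _ = np.linalg.slogdet(S)
        if sign <= 0:
            eig = np.linalg.eigvalsh(S)
            bad = [model.variables[i] for i in np.argsort(eig)[:2]]
            raise ValueError(
                "sample covariance is not positive definite; check collinear "
                f"variables (smallest-eigenvalue directions involve {bad})"
            )

        def objective(x):
            f = _ml_discrepancy(S, par.implied_sigma(x))
            return f if np.isfinite(f) else 1e10

        res = optimize.minimize(objective, par.start(), method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 2000})
        if not np.isfinite(res.fun):
            raise ValueError("optimization diverged")
        xh = res.x
        F = float(objective(xh))
        chi2 = (n - 1) * F
        loglik = None
        # asymptotic covariance of parameters: 2/(n-1) * H^{-1}
        H = _numerical_hessian(objective, xh)
        try:
            cov = 2.0 / (n - 1) * np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            cov = np.full((par.k, par.k), np.nan)
        used_fiml = False
        converged = bool(res.success or res.status == 2)  # precision loss ok
    else:
        pats = _patterns(z)
        n = int(sum(len(b) for _, b in pats))

        def negll(x):
            mu = x[:p]
            Sigma = par.implied_sigma(x[p:])
            ll = _fiml_loglik(mu, Sigma, pats)
            return -ll if np.isfinite(ll) else 1e10

        x0 = np.concatenate([np.zeros(p), par.start()])
        res = optimize.minimize(negll, x0, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 3000})
        xh = res.x[p:]
        loglik = -float(res.fun)
        ll_sat = _saturated_fiml_loglik(z)
        chi2 = max(2.0 * (ll_sat - loglik), 0.0)
        H = _numerical_hessian(negll, res.x)
        try:
            cov_full = np.linalg.pinv(H)
            cov = cov_full[p:, p:]
        except np.linalg.LinAlgError:
            cov = np.full((par.k, par.k), np.nan)
        used_fiml = True
        converged = bool(res.success or res.status == 2)

    df = model.degrees_of_freedom()
    pval = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    Sigma = par.implied_sigma(xh)
    dsd = np.sqrt(np.diag(Sigma))
    implied_corr = Sigma / np.outer(dsd, dsd)

    B, Psi = par.matrices(xh)
    coefs: dict[tuple[str, str], float] = {}
    ses: dict[tuple[str, str], float] = {}
    sig: dict[tuple[str, str], bool] = {}
    posv = par.pos
    for i, (s, t) in enumerate(model.edges):
        raw = xh[i]
        scale = dsd[posv[s]] / dsd[posv[t]]
        coefs[(s, t)] = float(raw * scale)
        se = float(np.sqrt(max(cov[i, i], 0.0)) * scale) if np.isfinite(
            cov[i, i]) else np.nan
        ses[(s, t)] = se
        sig[(s, t)] = bool(se > 0 and abs(raw / np.sqrt(max(cov[i, i], 1e-300)))
                           > stats.norm.ppf(0.975))
    exo_cov = {}
    i0 = len(model.edges) + len(par.exo)
    for j, (a, b) in enumerate(model.covariances):
        # report as correlation of the exogenous pair
        va = Psi[posv[a], posv[a]]
        vb = Psi[posv[b], posv[b]]
        exo_cov[(a, b)] = float(xh[i0 + j] / np.sqrt(va * vb))
    err_var = {v: float(Psi[posv[v], posv[v]] / Sigma[posv[v], posv[v]])
               for v in par.endo}

    return PathFit(
        model=model,
        coefficients=coefs,
        coefficient_se=ses,
        significant=sig,
        exo_covariances=exo_cov,
        error_variances=err_var,
        chi_square=float(chi2),
        df=df,
        p_value=pval,
        implied_correlation=pd.DataFrame(
            implied_corr, index=model.variables, columns=model.variables
        ),
        n_effective=n,
        log_likelihood=loglik,
        used_fiml=used_fiml,
        converged=converged,
    )


def _numerical_hessian(f, x, eps: float = 1e-5) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps**2)
    return H


# -- effect decomposition ---------------------------------------------------

def effect_decomposition(fit: PathFit, source: str, target: str) -> dict:
    """Split the implied source-target correlation into direct, indirect
    and unanalyzed/spurious components (standardized tracing rule).

    direct: the source->target arrow's coefficient (0 if absent);
    indirect: sum over directed chains source -> ... -> target of
    coefficient products; unanalyzed: everything else in the implied
    correlation (paths through exogenous covariances or common causes).
    The three terms sum to the implied correlation exactly.
    """
    v = fit.model.variables
    if source not in v or target not in v:
        raise ValueError("source/target not in the model")
    if target not in fit.model.endogenous():
        raise ValueError(f"target {target!r} is not endogenous")
    pos = {x: i for i, x in enumerate(v)}
    B = fit.coefficient_matrix()
    T = np.linalg.inv(np.eye(len(v)) - B) - np.eye(len(v))  # all directed chains
    direct = float(B[pos[target], pos[source]])
    indirect = float(T[pos[target], pos[source]] - direct)
    total = float(fit.implied_correlation.loc[target, source])
    unanalyzed = total - direct - indirect
    out = {
        "direct": direct,
        "indirect": indirect,
        "unanalyzed": unanalyzed,
        "total": total,
    }
    if total != 0:
        out["percent_direct"] = 100.0 * direct / total
    return out


def compare_candidate_models(models: list[PathModel], data: pd.DataFrame,
                             use_missing: bool = False) -> pd.DataFrame:
    """Fit each candidate and rank by chi-square p-value (ties by df).

    A model whose fit fails is kept in the table with the error message;
    ``good_fit`` flags p > 0.05.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 candidate models")
    rows = []
    fits: dict[str, PathFit] = {}
    for m in models:
        try:
            fit = sem_fit(m, data, use_missing=use_missing)
            fits[m.name] = fit
            rows.append({
                "model": m.name, "chi_square": fit.chi_square, "df": fit.df,
                "p_value": fit.p_value, "good_fit": fit.good_fit, "error": "",
            })
        except Exception as exc:  # per-model failure is data, not fatal
            rows.append({
                "model": m.name, "chi_square": np.nan, "df": np.nan,
                "p_value": np.nan, "good_fit": False, "error": str(exc),
            })
    df = pd.DataFrame(rows).sort_values(
        ["p_value", "df"], ascending=[False, True]
    ).reset_index(drop=True)
    df.attrs["fits"] = fits
    return df


# -- presets ----------------------------------------------------------------

FIG4_VARIABLES = ["Latitude", "Body", "BMR", "Incubation", "Migration", "Brain"]

_PRESET_TEXT = {
    # Reconstructed from the published diagram's structure; the exact arrow
    # sets are only partially recoverable from the legend, so these are
    # editable starting points, not ground truth.
    "A": """
        Body -> BMR
        Body -> Incubation
        Body -> Brain
        Latitude -> Migration
        BMR -> Migration
        Incubation -> Brain
        Migration -> Brain
        Latitude ~~ Body
    """,
    "B": """  # no direct migration->brain arrow
        Body -> BMR
        Body -> Incubation
        Body -> Brain
        Latitude -> Migration
        BMR -> Migration
        Incubation -> Brain
        Latitude ~~ Body
    """,
    "C": """  # brain causes migration (reversed direction)
        Body -> BMR
        Body -> Incubation
        Body -> Brain
        Incubation -> Brain
        Latitude -> Migration
        BMR -> Migration
        Brain -> Migration
        Latitude ~~ Body
    """,
    "D": """  # developmental route: incubation drives migration
        Body -> BMR
        Body -> Incubation
        Body -> Brain
        Latitude -> Migration
        Incubation -> Migration
        Incubation -> Brain
        Migration -> Brain
        Latitude ~~ Body
    """,
}


def candidate_models() -> list[PathModel]:
    """The four reconstructed candidate path diagrams (A-D)."""
    return [parse_model(text, name=name) for name, text in _PRESET_TEXT.items()]
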