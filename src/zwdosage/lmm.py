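"""Crossed random-intercept mixed models with AICc selection.

The dosage analyses fit normalized expression against sex, Z-linkage and
their interaction, with random intercepts for transcript and individual
(and, when controlling for ancestral expression, for the distinct
(ancestral male mean, ancestral female mean) pair of each ortholog).
All fits use maximum likelihood, not REML, because the candidate models
differ in their fixed effects and are compared by AICc.

Two fitting routes share one interface:

* a fast exact route for the complete transcript x individual layout the
  pipeline produces, where the two crossed covariance structures are
  simultaneously diagonalized by Helmert bases, reducing each likelihood
  evaluation to a weighted least squares with four distinct weights;
* a generic dense route via the Woodbury identity for unbalanced data or
  grouping structures the fast route cannot express.

When the ancestral grouping has exactly one level per transcript (the
usual case: outgroup means are continuous) its variance is not separately
identified from the transcript variance; the fit merges the two, reports
the merged estimate under transcript with the ancestral component at the
boundary, and flags the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import helmert
from scipy.optimize import minimize
from scipy.stats import norm

FIXED_STRUCTURES = ("null", "sex", "z", "sex+z", "full")
_TERMS = {
    "null": [],
    "sex": ["sex_male"],
    "z": ["z_linked"],
    "sex+z": ["sex_male", "z_linked"],
    "full": ["sex_male", "z_linked", "sex_male:z_linked"],
}
INTERACTION = "sex_male:z_linked"

_LOG_GAMMA_FLOOR = -30.0  # variance ratios below exp(-30) count as boundary


@dataclass(frozen=True)
class LmmSpec:
    """One candidate model: which condition and which fixed effects.

    condition 'balance' uses transcript + individual random intercepts;
    'compensation' adds the ancestral male:female grouping.
    """
    condition: str  # 'balance' | 'compensation'
    fixed: str      # one of FIXED_STRUCTURES

    def __post_init__(self):
        if self.condition not in ("balance", "compensation"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.fixed not in FIXED_STRUCTURES:
            raise ValueError(f"unknown fixed structure {self.fixed!r}")

    @property
    def terms(self) -> list:
        return ["intercept"] + _TERMS[self.fixed]

    @property
    def n_vc(self) -> int:
        return 3 if self.condition == "compensation" else 2


@dataclass
class ModelFitResult:
    spec: LmmSpec
    params: dict
    se: dict
    pvalues: dict
    vc: dict                 # variance components incl. residual
    loglik: float
    k: int                   # fixed effects + variance components + residual
    nobs: int
    aicc: float
    converged: bool
    method: str
    flags: list = field(default_factory=list)
    delta_aicc: Optional[float] = None
    weight: Optional[float] = None

    @property
    def interaction(self) -> Optional[float]:
        return self.params.get(INTERACTION)

    @property
    def interaction_p(self) -> Optional[float]:
        return self.pvalues.get(INTERACTION)

    @property
    def model_label(self) -> str:
        labels = {"null": "Null", "sex": "Sex", "z": "Z_linkage",
                  "sex+z": "Sex + Z_linkage",
                  "full": "Sex + Z_linkage + Sex * Z_linkage"}
        return labels[self.spec.fixed]


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _design(data: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = []
    for t in terms:
        if t == "intercept":
            cols.append(np.ones(len(data)))
        elif t == INTERACTION:
            cols.append((data["sex_male"] * data["z_linked"]).to_numpy(float))
        else:
            cols.append(data[t].to_numpy(float))
    return np.column_stack(cols)


def _required_columns(data: pd.DataFrame, spec: LmmSpec) -> None:
    need = {"y", "sex_male", "z_linked", "transcript", "individual"}
    if spec.condition == "compensation":
        need.add("anc_group")
    missing = need - set(data.columns)
    if missing:
        raise ValueError(f"data lacks columns {sorted(missing)}")


def fit_lmm(data: pd.DataFrame, spec: LmmSpec) -> ModelFitResult:
    """ML fit of one crossed random-intercept model.

    ``data`` holds one row per transcript x sample observation with
    columns y, sex_male (0/1), z_linked (0/1), transcript, individual and
    (compensation) anc_group.
    """
    _required_columns(data, spec)
    flags = []
    counts = data.groupby(["transcript", "individual"], observed=True).size()
    n_tr = data["transcript"].nunique()
    n_ind = data["individual"].nunique()
    balanced = ((counts == 1).all() and len(counts) == n_tr * n_ind
                and n_tr > 1 and n_ind > 1)

    anc_confounded = False
    if spec.condition == "compensation":
        per_tr = data.groupby("transcript", observed=True)["anc_group"].nunique()
        if (per_tr != 1).any():
            raise ValueError("anc_group must be constant within transcript")
        tr_per_group = data.groupby("anc_group", observed=True)["transcript"].nunique()
        anc_confounded = (tr_per_group == 1).all()

    if balanced and (spec.condition == "balance" or anc_confounded):
        res = _fit_balanced(data, spec)
    else:
        res = _fit_general(data, spec)
    if anc_confounded:
        res.flags.append("anc_confounded_with_transcript")
    res.flags.extend(flags)
    return res


def _wald(beta, cov, terms):
    se = np.sqrt(np.diag(cov))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2.0 * norm.sf(np.abs(z))
    return (dict(zip(terms, beta)), dict(zip(terms, se)), dict(zip(terms, p)))


def _fit_balanced(data: pd.DataFrame, spec: LmmSpec) -> ModelFitResult:
    """Exact-eigenbasis ML for the complete G x S crossed layout."""
    df = data.sort_values(["transcript", "individual"], kind="stable")
    transcripts = pd.Index(df["transcript"].unique())
    individuals = pd.Index(df["individual"].unique())
    G, S = len(transcripts), len(individuals)
    n = G * S
    Y = df["y"].to_numpy(float).reshape(G, S)
    terms = spec.terms
    X = _design(df, terms)  # n x p in (transcript, individual) order
    p = X.shape[1]

    HG = helmert(G, full=True)
    HS = helmert(S, full=True)
    Yt = (HG @ Y @ HS.T).ravel()
    Xt = np.column_stack([(HG @ X[:, j].reshape(G, S) @ HS.T).ravel()
                          for j in range(p)])

    # weight pattern: component (i, j) has variance
    #   sigma2 * (1 + g_t * S * [j == 0] + g_i * G * [i == 0])
    col0 = np.zeros((G, S)); col0[:, 0] = 1.0
    row0 = np.zeros((G, S)); row0[0, :] = 1.0
    col0 = col0.ravel(); row0 = row0.ravel()

    def profile(theta):
        g_t, g_i = np.exp(theta)
        d = 1.0 + g_t * S * col0 + g_i * G * row0
        w = 1.0 / d
        Xw = Xt * w[:, None]
        M = Xt.T @ Xw
        b = Xw.T @ Yt
        beta = np.linalg.solve(M, b)
        resid = Yt - Xt @ beta
        rss = float(np.dot(w * resid, resid))
        sigma2 = rss / n
        nll2 = n * np.log(2.0 * np.pi * sigma2) + float(np.sum(np.log(d))) + n
        return 0.5 * nll2, beta, sigma2, M

    def objective(theta):
        theta = np.clip(theta, _LOG_GAMMA_FLOOR, 30.0)
        return profile(theta)[0]

    starts = [np.array([a, b]) for a in (-6.0, -1.0, 1.0) for b in (-6.0, -1.0)]
    best = None
    for x0 in starts:
        r = minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 600})
        if best is None or r.fun < best.fun:
            best = r
    theta = np.clip(best.x, _LOG_GAMMA_FLOOR, 30.0)
    nll, beta, sigma2, M = profile(theta)
    g_t, g_i = np.exp(theta)
    cov = sigma2 * np.linalg.inv(M)
    params, se, pv = _wald(beta, cov, terms)

    flags = []
    if min(theta) <= _LOG_GAMMA_FLOOR + 1e-6 or g_t < 1e-7 or g_i < 1e-7:
        flags.append("variance_component_boundary")
    vc = {"residual": sigma2, "transcript": g_t * sigma2,
          "individual": g_i * sigma2}
    if spec.condition == "compensation":
        vc["anc_group"] = 0.0  # confounded with transcript; see module docstring
    k = len(terms) + spec.n_vc + 1
    return ModelFitResult(
        spec=spec, params=params, se=se, pvalues=pv, vc=vc,
        loglik=-nll, k=k, nobs=n, aicc=aicc(-nll, k, n),
        converged=bool(best.success), method="balanced-eigen", flags=flags)


def _fit_general(data: pd.DataFrame, spec: LmmSpec) -> ModelFitResult:
    """Dense Woodbury-identity ML for arbitrary crossed groupings."""
    df = data.reset_index(drop=True)
    n = len(df)
    terms = spec.terms
    X = _design(df, terms)
    y = df["y"].to_numpy(float)

    group_cols = ["transcript", "individual"]
    if spec.condition == "compensation":
        group_cols.append("anc_group")
    blocks, sizes = [], []
    for c in group_cols:
        codes, levels = pd.factorize(df[c], sort=True)
        U = np.zeros((n, len(levels)))
        U[np.arange(n), codes] = 1.0
        blocks.append(U)
        sizes.append(len(levels))
    U = np.hstack(blocks)
    UtU = U.T @ U
    UtX = U.T @ X
    Uty = U.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def expand(gammas):
        return np.concatenate([np.full(s, g) for s, g in zip(sizes, gammas)])

    def profile(theta):
        gammas = np.exp(np.clip(theta, _LOG_GAMMA_FLOOR, 30.0))
        gdiag = expand(gammas)
        sq = np.sqrt(gdiag)
        K = np.eye(U.shape[1]) + (sq[:, None] * UtU) * sq[None, :]
        cho = np.linalg.cholesky(K)
        logdetK = 2.0 * float(np.sum(np.log(np.diag(cho))))

        def apply_pinv(VtM, M):  # M - U G^{1/2} K^{-1} G^{1/2} Ut M, via precomputed Ut M
            t = sq[:, None] * VtM if VtM.ndim == 2 else sq * VtM
            s1 = np.linalg.solve(cho, t)
            s2 = np.linalg.solve(cho.T, s1)
            return s2

        sX = apply_pinv(UtX, X)
        sy = apply_pinv(Uty, y)
        A = XtX - (sq[:, None] * UtX).T @ sX
        b = Xty - (sq[:, None] * UtX).T @ sy
        c = yty - float((sq * Uty) @ sy)
        beta = np.linalg.solve(A, b)
        rss = c - float(b @ beta)
        sigma2 = rss / n
        nll2 = n * np.log(2.0 * np.pi * sigma2) + logdetK + n
        return 0.5 * nll2, beta, sigma2, A

    def objective(theta):
        try:
            return profile(theta)[0]
        except np.linalg.LinAlgError:
            return np.inf

    ng = len(group_cols)
    starts = [np.full(ng, -6.0), np.full(ng, -1.0), np.full(ng, 1.0)]
    best = None
    for x0 in starts:
        r = minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 1000})
        if best is None or r.fun < best.fun:
            best = r
    theta = np.clip(best.x, _LOG_GAMMA_FLOOR, 30.0)
    nll, beta, sigma2, A = profile(theta)
    gammas = np.exp(theta)
    cov = sigma2 * np.linalg.inv(A)
    params, se, pv = _wald(beta, cov, terms)
    flags = []
    if (gammas < 1e-7).any():
        flags.append("variance_component_boundary")
    vc = {"residual": sigma2}
    for cname, g in zip(group_cols, gammas):
        vc[cname if cname != "anc_group" else "anc_group"] = g * sigma2
    k = len(terms) + spec.n_vc + 1
    return ModelFitResult(
        spec=spec, params=params, se=se, pvalues=pv, vc=vc,
        loglik=-nll, k=k, nobs=n, aicc=aicc(-nll, k, n),
        converged=bool(best.success), method="woodbury", flags=flags)


def fit_lmm_set(data: pd.DataFrame, condition: str) -> list:
    """Fit the null / sex / z / sex+z / full ladder on identical data."""
    return [fit_lmm(data, LmmSpec(condition=condition, fixed=f))
            for f in FIXED_STRUCTURES]


def select_models(fits: Sequence[ModelFitResult]) -> list:
    """Rank fits by AICc; attach delta AICc and Akaike weights.

    Models within delta AICc <= 2 of the best are conventionally treated
    as equally supported.
    """
    if not fits:
        raise ValueError("no fits to select among")
    nobs = {f.nobs for f in fits}
    if len(nobs) != 1:
        raise ValueError("model set must be fitted on identical data")
    ranked = sorted(fits, key=lambda f: f.aicc)
    best = ranked[0].aicc
    rel = np.array([np.exp(-0.5 * (f.aicc - best)) for f in ranked])
    weights = rel / rel.sum()
    for f, w in zip(ranked, weights):
        f.delta_aicc = f.aicc - best
        f.weight = float(w)
    return ranked


def selection_table(ranked: Sequence[ModelFitResult]) -> pd.DataFrame:
    """Model-selection table (model, intercept, delta_aicc, weight)."""
    return pd.DataFrame({
        "model": [f.model_label for f in ranked],
        "intercept": [f.params["intercept"] for f in ranked],
        "delta_aicc": [f.delta_aicc for f in ranked],
        "weight": [f.weight for f in ranked],
    })


def coefficient_table(fit: ModelFitResult) -> pd.DataFrame:
    """Coefficient table (term, estimate, se, p) of one fit."""
    terms = list(fit.params)
    return pd.DataFrame({
        "term": terms,
        "estimate": [fit.params[t] for t in terms],
        "se": [fit.se[t] for t in terms],
        "p": [fit.pvalues[t] for t in terms],
    })
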