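"""Expression variability (BCV) and its relation to dosage balance.

The biological coefficient of variation, sqrt of the negative-binomial
dispersion of expression counts, proxies the strength of purifying
selection on expression: tightly constrained genes vary less among
individuals.  Per-sex, per-transcript dispersions are estimated by
Cox-Reid adjusted profile likelihood with empirical-Bayes shrinkage
toward the common dispersion.  Because male and female variability are
correlated, a PCA splits them into a concordant-intensity axis (PC1) and
a sex-bias axis (PC2, larger = male expression more constrained), and an
ordinary linear model asks whether these axes predict the per-transcript
log2(F/M) expression ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import nbinom, poisson, wilcoxon

__all__ = [
    "estimate_bcv", "signed_rank_test", "SignedRankResult",
    "bcv_pca", "PcaResult", "selection_model", "SelectionModelFit",
]

_PHI_GRID = np.exp(np.linspace(np.log(1e-6), np.log(30.0), 140))


def _nb_loglik(y, mu, phi):
    """log NB(y; mean mu, dispersion phi), Poisson at tiny phi.

    Shapes broadcast; y, mu are (..., n_samples)."""
    if phi < 1e-8:
        return poisson.logpmf(y, mu).sum(axis=-1)
    r = 1.0 / phi
    p = r / (r + mu)
    return nbinom.logpmf(y, r, p).sum(axis=-1)


def estimate_bcv(counts: pd.DataFrame, lib_sizes: pd.Series,
                 sample_sex: pd.Series, sex: str,
                 prior_df: float = 10.0) -> pd.DataFrame:
    """Tagwise NB dispersion and BCV for one sex.

    Counts are modelled as NB(mean = s_j * lambda_g, phi_g) with relative
    size factors s_j from the library sizes.  For each transcript the
    Cox-Reid adjusted profile likelihood APL_g(phi) is evaluated on a
    dispersion grid (lambda profiled out by Newton steps); the common
    dispersion maximizes the summed APL, and tagwise estimates maximize
    APL_g + G0 * mean-APL with G0 = prior_df / (n - 1) transcripts' worth
    of shared information, shrinking noisy per-transcript estimates
    toward the common value.  Returns (transcript, sex, phi, bcv,
    log2_bcv, excluded).
    """
    cols = sample_sex.index[sample_sex == sex]
    if len(cols) < 2:
        raise ValueError(f"need >= 2 samples of sex {sex}")
    y = counts[cols].to_numpy(float)
    s = lib_sizes[cols].to_numpy(float)
    if (s <= 0).any():
        raise ValueError("library sizes must be positive")
    s = s / s.mean()  # relative size factors: estimates invariant to rescaling
    n = len(cols)

    nonzero = y.sum(axis=1) > 0
    yn = y[nonzero]
    G = len(yn)
    if G == 0:
        raise ValueError("no transcript with nonzero counts")

    # profile lambda_g at each grid phi: start at the moment estimate and
    # take Newton steps on the score sum_j (y - s*lam) / (1 + phi*s*lam)
    lam0 = yn.sum(axis=1) / s.sum()
    K = len(_PHI_GRID)
    lam = np.repeat(lam0[:, None], K, axis=1)        # G x K
    phi = _PHI_GRID[None, :, None]                    # 1 x K x 1
    sj = s[None, None, :]
    yj = yn[:, None, :]
    for _ in range(6):
        mu = lam[:, :, None] * sj
        denom = 1.0 + phi * mu
        score = ((yj - mu) / (lam[:, :, None] * denom + 1e-300)).sum(axis=2)
        # expected information for lambda: sum_j s_j / (lam * (1 + phi*s_j*lam))
        info = (sj / (lam[:, :, None] * denom + 1e-300)).sum(axis=2)
        lam = np.clip(lam + score / np.maximum(info, 1e-12), 1e-8, None)

    mu = lam[:, :, None] * sj                         # G x K x n
    apl = np.empty((G, K))
    for k in range(K):
        apl[:, k] = _nb_loglik(yn, mu[:, k, :], _PHI_GRID[k])
    # Cox-Reid adjustment: -0.5 log I(lambda_hat)
    fisher = (s[None, None, :] ** 2 /
              (mu * (1.0 + _PHI_GRID[None, :, None] * mu) + 1e-300)).sum(axis=2)
    apl -= 0.5 * np.log(np.maximum(fisher, 1e-300))

    common_idx = int(np.argmax(apl.sum(axis=0)))
    g0 = prior_df / max(n - 1, 1)
    weighted = apl + g0 * apl.mean(axis=0)[None, :]
    tag_idx = np.argmax(weighted, axis=1)
    phi_hat = _PHI_GRID[tag_idx]

    out = pd.DataFrame({
        "transcript": counts.index[nonzero],
        "sex": sex,
        "phi": phi_hat,
        "bcv": np.sqrt(phi_hat),
        "excluded": False,
    })
    out["log2_bcv"] = np.log2(out["bcv"])
    excluded = pd.DataFrame({
        "transcript": counts.index[~nonzero], "sex": sex,
        "phi": np.nan, "bcv": np.nan, "excluded": True, "log2_bcv": np.nan,
    })
    res = pd.concat([out, excluded], ignore_index=True)
    res.attrs["common_phi"] = float(_PHI_GRID[common_idx])
    return res


@dataclass
class SignedRankResult:
    v: float           # sum of ranks of positive (female - male) differences
    p: Optional[float]
    n_used: int
    n_zero_dropped: int
    method: str
    degenerate: bool = False


def signed_rank_test(female, male) -> SignedRankResult:
    """Wilcoxon signed-rank test on paired values (female minus male).

    Zero differences are dropped (standard convention); the p-value is
    exact for n <= 15 without tied magnitudes, otherwise a normal
    approximation with continuity correction.  V = 0 means every female
    value sits below its male pair.
    """
    f = np.asarray(female, dtype=float)
    m = np.asarray(male, dtype=float)
    if f.shape != m.shape:
        raise ValueError("paired arrays must have equal length")
    d = f - m
    nz = d != 0
    n_zero = int((~nz).sum())
    d = d[nz]
    if len(d) == 0:
        return SignedRankResult(v=np.nan, p=None, n_used=0,
                                n_zero_dropped=n_zero, method="degenerate",
                                degenerate=True)
    mags = np.abs(d)
    no_ties = len(np.unique(mags)) == len(mags)
    method = "exact" if (len(d) <= 15 and no_ties) else "approx"
    res = wilcoxon(d, zero_method="wilcox", correction=True,
                   alternative="two-sided", method=method)
    # scipy's statistic is the smaller rank sum; recover V = positive-rank sum
    from scipy.stats import rankdata
    ranks = rankdata(mags)
    v = float(ranks[d > 0].sum())
    return SignedRankResult(v=v, p=float(res.pvalue), n_used=len(d),
                            n_zero_dropped=n_zero, method=method)


@dataclass
class PcaResult:
    loadings: np.ndarray        # 2x2, columns = PCs
    scores: pd.DataFrame        # index transcript, columns PC1, PC2
    variance_explained: np.ndarray
    center: np.ndarray
    pc1_flipped: bool
    pc2_flipped: bool
    degenerate: bool = False


def bcv_pca(pairs: pd.DataFrame) -> PcaResult:
    """PCA of centered (log2 BCV female, log2 BCV male) pairs.

    Sign convention: PC1 loadings both non-negative (concordant
    variability intensity); PC2 oriented with a positive female and
    negative male loading, so larger PC2 scores mean relatively lower
    male variability — a male bias in expression constraint.
    """
    cols = list(pairs.columns)
    if len(cols) != 2:
        raise ValueError("expect exactly two columns (female, male log2 BCV)")
    X = pairs.to_numpy(float)
    if len(X) < 3:
        raise ValueError("need >= 3 transcripts with both-sex BCV")
    center = X.mean(axis=0)
    Xc = X - center
    degenerate = bool((Xc.std(axis=0) == 0).any())
    u, sv, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt.T  # columns are PCs
    var = sv ** 2 / (len(X) - 1)
    pc1_flipped = loadings[:, 0].sum() < 0
    if pc1_flipped:
        loadings[:, 0] *= -1
    pc2_flipped = loadings[0, 1] < 0  # want female loading positive
    if pc2_flipped:
        loadings[:, 1] *= -1
    scores = Xc @ loadings
    return PcaResult(
        loadings=loadings,
        scores=pd.DataFrame(scores, index=pairs.index, columns=["PC1", "PC2"]),
        variance_explained=var, center=center,
        pc1_flipped=pc1_flipped, pc2_flipped=pc2_flipped,
        degenerate=degenerate)


@dataclass
class SelectionModelFit:
    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    r_squared: float
    nobs: int
    residuals: np.ndarray
    design_columns: list


def selection_model(scores: pd.DataFrame, outcome: pd.Series) -> SelectionModelFit:
    """OLS of log2(F/M) expression on PC1 + PC2 + PC1:PC2."""
    common = scores.index.intersection(outcome.index)
    if len(common) < 5:
        raise ValueError("too few transcripts shared between scores and outcome")
    s = scores.loc[common]
    y = outcome.loc[common].to_numpy(float)
    X = pd.DataFrame({
        "intercept": 1.0,
        "PC1": s["PC1"],
        "PC2": s["PC2"],
        "PC1:PC2": s["PC1"] * s["PC2"],
    })
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending column via QR pivoting
        q, r = np.linalg.qr(X.to_numpy())
        bad = X.columns[np.abs(np.diag(r)).argmin()]
        raise ValueError(f"rank-deficient design: column {bad!r} is collinear")
    fit = sm.OLS(y, X.to_numpy()).fit()
    cols = list(X.columns)
    return SelectionModelFit(
        params=pd.Series(fit.params, index=cols),
        se=pd.Series(fit.bse, index=cols),
        pvalues=pd.Series(fit.pvalues, index=cols),
        r_squared=float(fit.rsquared), nobs=int(fit.nobs),
        residuals=np.asarray(fit.resid), design_columns=cols)
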