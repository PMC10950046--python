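"""Dosage balance and dosage compensation diagnosis.

*Dosage balance* asks whether Z-linked expression is equal between the
sexes; *dosage compensation* asks whether female Z expression has been
restored to the ancestral (proto-autosomal) level, proxied by outgroup
expression of orthologs.  Both are tested two ways, mirroring common
practice: nonparametric Mann-Whitney U tests (frequentist and Bayesian)
on per-transcript summaries, and crossed random-intercept linear mixed
models on normalized per-observation expression, compared by AICc.  The
two conditions combine into a dosage-type label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm

from .bayesfactor import bayes_factor_ranksum, BayesRankSumResult
from .lmm import INTERACTION, ModelFitResult
from .simulate import ExpressionMatrix

__all__ = [
    "filter_expressed", "FilterExpressedResult", "fm_expression_ratio",
    "mwu_test", "bonferroni", "TestResult", "support_tier_p", "support_tier_bf",
    "order_quantile_normalize", "OrderNormResult",
    "build_lmm_data", "DosageSummaries", "dosage_summaries",
    "classify_dosage", "DosageDiagnosis", "TYPE_LABELS",
]


# ---------------------------------------------------------------------------
# expression filtering and ratios
# ---------------------------------------------------------------------------

@dataclass
class FilterExpressedResult:
    expr: ExpressionMatrix
    n_in: int
    n_dropped_unexpressed: int
    n_dropped_par: int


def filter_expressed(expr: ExpressionMatrix, mode: str = "sex_mean",
                     drop_par: bool = True) -> FilterExpressedResult:
    """Keep transcripts expressed in both sexes; drop PAR transcripts.

    ``mode='sex_mean'`` (default) drops a transcript when its mean FPKM is
    zero in either sex; ``'per_sample'`` requires every sample positive.
    PAR transcripts are removed from the analysis set because they are
    diploid in both sexes and carry no dosage signal.
    """
    if mode not in ("sex_mean", "per_sample"):
        raise ValueError("mode must be 'sex_mean' or 'per_sample'")
    for sex in ("F", "M"):
        if (expr.samples["sex"] == sex).sum() == 0:
            raise ValueError(f"no samples of sex {sex}")
    n_in = len(expr.fpkm)
    if mode == "sex_mean":
        means = expr.sex_means()
        keep = (means["F"] > 0) & (means["M"] > 0)
    else:
        keep = (expr.fpkm > 0).all(axis=1)
    n_unexpr = int((~keep).sum())
    if drop_par:
        is_par = expr.transcripts["linkage"] == "PAR"
        n_par = int((keep & is_par).sum())
        keep = keep & ~is_par
    else:
        n_par = 0
    out = ExpressionMatrix(
        fpkm=expr.fpkm[keep],
        transcripts=expr.transcripts[keep],
        samples=expr.samples.copy(),
    )
    return FilterExpressedResult(expr=out, n_in=n_in,
                                 n_dropped_unexpressed=n_unexpr,
                                 n_dropped_par=n_par)


def fm_expression_ratio(expr: ExpressionMatrix) -> pd.Series:
    """Per-transcript log2(mean female FPKM / mean male FPKM)."""
    means = expr.sex_means()
    if ((means["F"] <= 0) | (means["M"] <= 0)).any():
        raise ValueError("zero sex-mean FPKM present; run filter_expressed first")
    return np.log2(means["F"] / means["M"]).rename("log2_fm")


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def support_tier_p(p: float) -> str:
    if p <= 0.001:
        return "strong"
    if p <= 0.01:
        return "moderate"
    if p <= 0.05:
        return "modest"
    return "none"


def support_tier_bf(bf10: float) -> str:
    if bf10 > 30:
        return "strong"
    if bf10 >= 10:
        return "moderate"
    if bf10 >= 1:
        return "modest"
    return "none"


@dataclass
class TestResult:
    label: str
    u: float
    p: float
    n1: int
    n2: int
    method: str
    p_adjusted: Optional[float] = None
    bf10: Optional[float] = None
    bf01: Optional[float] = None
    degenerate: bool = False

    @property
    def tier_p(self) -> str:
        return support_tier_p(self.p_adjusted if self.p_adjusted is not None else self.p)

    @property
    def tier_bf(self) -> Optional[str]:
        return None if self.bf10 is None else support_tier_bf(self.bf10)


def mwu_test(x, y, label: str = "") -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when n1+n2 <= 12 with no ties, otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(label=label, u=len(x) * len(y) / 2.0, p=1.0,
                          n1=len(x), n2=len(y), method="degenerate",
                          degenerate=True)
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= 12 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method,
                       use_continuity=True)
    return TestResult(label=label, u=float(res.statistic), p=float(res.pvalue),
                      n1=len(x), n2=len(y), method=method)


def bonferroni(pvals: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p) for a family of m tests."""
    p = np.asarray(pvals, dtype=float)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError(f"family size m={m} smaller than number of tests {len(p)}")
    return np.minimum(1.0, m * p)


def attach_bayes(result: TestResult, x, y, seed: int = 0,
                 draws: int = 2000, **kwargs) -> TestResult:
    """Add the latent-normal rank-sum Bayes factor to a frequentist result."""
    bf = bayes_factor_ranksum(x, y, draws=draws, seed=seed, **kwargs)
    result.bf10 = bf.bf10
    result.bf01 = bf.bf01
    return result


# ---------------------------------------------------------------------------
# ordered quantile normalization
# ---------------------------------------------------------------------------

@dataclass
class OrderNormResult:
    """Rank-based inverse-normal transform Phi^-1(rank / (n + 1)).

    Stores the fitted monotone mapping so unseen values can be
    transformed by linear interpolation.
    """
    values: np.ndarray
    degenerate: bool
    _x: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)

    def transform(self, new) -> np.ndarray:
        new = np.asarray(new, dtype=float)
        if self.degenerate:
            return np.zeros_like(new)
        return np.interp(new, self._x, self._y)


def order_quantile_normalize(values) -> OrderNormResult:
    """Ordered quantile (rank inverse-normal) normalization.

    Output_i = Phi^-1(rank_i / (n + 1)) with average ranks for ties:
    strictly rank-preserving and, for all-distinct input, exactly normal
    in shape regardless of the input distribution.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a 1-D array with n >= 2")
    if np.all(v == v[0]):
        return OrderNormResult(values=np.zeros_like(v), degenerate=True)
    from scipy.stats import rankdata
    out = norm.ppf(rankdata(v) / (len(v) + 1.0))
    ux, uidx = np.unique(v, return_index=True)
    uy = out[uidx]
    return OrderNormResult(values=out, degenerate=False, _x=ux, _y=uy)


# ---------------------------------------------------------------------------
# LMM data assembly
# ---------------------------------------------------------------------------

def build_lmm_data(expr: ExpressionMatrix,
                   ancestral: Optional[pd.DataFrame] = None,
                   normalize: str = "ordernorm",
                   pseudocount: float = 0.0) -> pd.DataFrame:
    """Long observation table for the mixed models.

    One row per transcript x sample with the normalized outcome ``y``,
    sex_male / z_linked indicators, transcript and individual ids and,
    when ``ancestral`` (index ortholog; columns anc_male, anc_female) is
    given, the anc_group factor (one level per distinct outgroup mean
    pair).  PAR transcripts must already be removed.
    """
    if (expr.transcripts["linkage"] == "PAR").any():
        raise ValueError("PAR transcripts present; run filter_expressed first")
    fpkm = expr.fpkm
    long = fpkm.stack().rename("fpkm").reset_index()
    long.columns = ["transcript", "individual", "fpkm"]
    meta = expr.transcripts
    long["z_linked"] = long["transcript"].map(meta["linkage"]).eq("Z").astype(int)
    long["sex_male"] = long["individual"].map(expr.samples["sex"]).eq("M").astype(int)

    if normalize == "ordernorm":
        long["y"] = order_quantile_normalize(long["fpkm"].to_numpy()).values
    elif normalize == "log2":
        vals = long["fpkm"].to_numpy() + pseudocount
        if (vals <= 0).any():
            raise ValueError("nonpositive FPKM under log2; set pseudocount > 0")
        long["y"] = np.log2(vals)
    elif normalize == "none":
        long["y"] = long["fpkm"]
    else:
        raise ValueError("normalize must be 'ordernorm', 'log2' or 'none'")

    if ancestral is not None:
        orth = long["transcript"].map(meta["ortholog"])
        missing = orth.isna() | ~orth.isin(ancestral.index)
        if missing.any():
            bad = long.loc[missing, "transcript"].unique()[:3]
            raise ValueError(
                f"transcripts without ancestral expression, e.g. {list(bad)}")
        pairs = ancestral.loc[orth, ["anc_male", "anc_female"]].to_numpy()
        codes, _ = pd.factorize(pd.Series(map(tuple, pairs)), sort=True)
        long["anc_group"] = codes
    return long


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

#: (balance, compensation) -> dosage type.  Type I: compensated and
#: balanced.  Type II: neither (female Z at half the ancestral level).
#: Type III: unbalanced with gene-by-gene (incomplete) compensation.
#: Type IV: complete compensation without balance (female at ancestral,
#: male above).  Balance without compensation has no canonical number.
TYPE_LABELS = {
    ("present", "complete"): "Type I",
    ("absent", "absent"): "Type II",
    ("absent", "incomplete"): "Type III",
    ("absent", "complete"): "Type IV",
    ("present", "incomplete"): "balanced-uncompensated",
    ("present", "absent"): "balanced-uncompensated",
}


@dataclass
class DosageSummaries:
    """Per-transcript medians feeding the effect-size gates."""
    median_z_log2_fm: float            # Z-linked log2(F/M)
    median_z_log2_f_vs_anc: float      # Z-linked log2(female mean / ancestral mean)
    median_a_log2_fm: Optional[float] = None


def dosage_summaries(expr: ExpressionMatrix,
                     ancestral: pd.DataFrame) -> DosageSummaries:
    """Compute the ratio summaries used by classify_dosage."""
    ratios = fm_expression_ratio(expr)
    on_z = expr.transcripts["linkage"] == "Z"
    on_a = expr.transcripts["linkage"] == "A"
    means = expr.sex_means()
    orth = expr.transcripts.loc[on_z, "ortholog"]
    anc_mean = ancestral.loc[orth, ["anc_male", "anc_female"]].mean(axis=1)
    anc_mean.index = orth.index
    f_vs_anc = np.log2(means.loc[on_z, "F"] / anc_mean)
    return DosageSummaries(
        median_z_log2_fm=float(ratios[on_z].median()),
        median_z_log2_f_vs_anc=float(f_vs_anc.median()),
        median_a_log2_fm=float(ratios[on_a].median()) if on_a.any() else None,
    )


@dataclass
class DosageDiagnosis:
    balance: str        # 'present' | 'absent'
    compensation: str   # 'complete' | 'incomplete' | 'absent'
    type_label: str
    conflict: bool
    notes: list
    summaries: DosageSummaries
    balance_best: Optional[str] = None
    compensation_best: Optional[str] = None


def _significant_positive_interaction(fit: ModelFitResult, alpha: float) -> bool:
    beta = fit.params.get(INTERACTION)
    p = fit.pvalues.get(INTERACTION)
    return beta is not None and p is not None and p < alpha and beta > 0


def classify_dosage(balance_ranked: Sequence[ModelFitResult],
                    compensation_ranked: Sequence[ModelFitResult],
                    summaries: DosageSummaries,
                    tests: Optional[Sequence[TestResult]] = None,
                    alpha: float = 0.05, margin: float = 0.25) -> DosageDiagnosis:
    """Combine model selection and ratio summaries into a dosage type.

    Balance is absent when the best balance model carries a significant
    male-positive sex x Z interaction *and* the median Z log2(F/M) is
    materially below parity (<= -margin); the effect-size gate keeps a
    spurious small interaction from flipping the call.  Compensation is
    complete unless either the ancestral-controlled model shows that same
    gated interaction, or median female Z expression sits below the
    ancestral level by more than the margin; incomplete vs absent is
    decided by whether the relevant median clears -1 + margin (an
    entirely uncompensated Z halves female expression, log2 = -1).
    """
    notes = []
    best_bal = balance_ranked[0]
    best_comp = compensation_ranked[0]
    bal_inter = _significant_positive_interaction(best_bal, alpha)
    comp_inter = _significant_positive_interaction(best_comp, alpha)
    m_fm = summaries.median_z_log2_fm
    m_fa = summaries.median_z_log2_f_vs_anc

    balance = "absent" if (bal_inter and m_fm <= -margin) else "present"
    if bal_inter and m_fm > -margin:
        notes.append("interaction significant but median log2(F/M) near parity; "
                     "balance kept 'present'")

    not_complete = (comp_inter and m_fm <= -margin) or (m_fa < -margin)
    if not not_complete:
        compensation = "complete"
    else:
        ref = m_fm if balance == "absent" else m_fa
        compensation = "incomplete" if ref > -1.0 + margin else "absent"

    label = TYPE_LABELS[(balance, compensation)]
    conflict = balance == "present" and compensation == "absent"
    if conflict:
        notes.append("balance present with absent compensation: check inputs")
    if label == "balanced-uncompensated":
        notes.append("balanced expression away from the ancestral level has "
                     "no canonical dosage type")
    if tests:
        for t in tests:
            if t.degenerate:
                notes.append(f"degenerate rank test: {t.label}")
    return DosageDiagnosis(
        balance=balance, compensation=compensation, type_label=label,
        conflict=conflict, notes=notes, summaries=summaries,
        balance_best=best_bal.model_label,
        compensation_best=best_comp.model_label)
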