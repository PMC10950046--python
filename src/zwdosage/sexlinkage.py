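"""Z-scaffold identification, PAR detection and Z/A diversity theory.

Candidate Z scaffolds in a ZZ/ZW system show female/male depth ratios
near 0.5 (one Z in females vs two in males) together with grossly
inflated apparent female heterozygosity caused by W-gametolog reads
mismapping onto Z scaffolds.  Pseudoautosomal regions retain diploid
coverage in both sexes and appear as terminal runs of balanced
log2(F/M) windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .loess import loess_smooth

__all__ = [
    "VariantFilterThresholds", "FilteredGenotypes", "apply_variant_filters",
    "scaffold_fm_depth_ratio", "HetRateSummary", "het_rate",
    "CandidateThresholds", "CandidateZReport", "call_candidate_z",
    "window_log2_fm", "ParScan", "detect_par",
    "za_ratio_theory", "za_ratio_max", "observed_za_diversity",
]


# ---------------------------------------------------------------------------
# variant hard filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantFilterThresholds:
    """Hard filters: MQ >= 30 and QD > 2 site-wide; DP >= 10 and GQ >= 30
    per genotype."""
    min_mq: float = 30.0
    min_qd: float = 2.0   # strict: site fails when QD <= min_qd
    min_dp: int = 10
    min_gq: int = 30


@dataclass
class FilteredGenotypes:
    table: pd.DataFrame
    n_sites_in: int
    n_sites_removed: int
    n_genotypes_masked: int


def apply_variant_filters(sites: pd.DataFrame,
                          thresholds: VariantFilterThresholds = VariantFilterThresholds(),
                          policy: str = "strict") -> FilteredGenotypes:
    """Remove failing sites and mask failing genotypes.

    ``sites`` is the long genotype table (scaffold, pos, mq, qd, sample,
    gt, dp, gq).  MQ/QD failures remove the site for every sample; DP/GQ
    failures set that one genotype to ``missing``.  Missing INFO values
    raise under ``policy='strict'`` and pass under ``'lenient'``.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError("policy must be 'strict' or 'lenient'")
    df = sites.copy()
    info_na = df["mq"].isna() | df["qd"].isna()
    if info_na.any():
        if policy == "strict":
            bad = df.loc[info_na, ["scaffold", "pos"]].iloc[0]
            raise ValueError(
                f"missing INFO annotation at {bad['scaffold']}:{bad['pos']} "
                "(use policy='lenient' to treat missing as passing)")
        df["mq"] = df["mq"].fillna(np.inf)
        df["qd"] = df["qd"].fillna(np.inf)

    n_sites_in = len(df[["scaffold", "pos"]].drop_duplicates())
    site_pass = (df["mq"] >= thresholds.min_mq) & (df["qd"] > thresholds.min_qd)
    kept = df[site_pass].copy()
    n_sites_kept = len(kept[["scaffold", "pos"]].drop_duplicates())

    geno_fail = (kept["dp"] < thresholds.min_dp) | (kept["gq"] < thresholds.min_gq)
    masked = int((geno_fail & (kept["gt"] != "missing")).sum())
    kept.loc[geno_fail, "gt"] = "missing"
    return FilteredGenotypes(table=kept, n_sites_in=n_sites_in,
                             n_sites_removed=n_sites_in - n_sites_kept,
                             n_genotypes_masked=masked)


# ---------------------------------------------------------------------------
# depth ratios
# ---------------------------------------------------------------------------

def scaffold_fm_depth_ratio(summary: pd.DataFrame) -> pd.DataFrame:
    """Mean female over mean male length-normalized read count per scaffold.

    ``summary`` columns: scaffold, length, sample, sex, count.  The per-sex
    mean of count/length approximates depth of coverage; the ratio is the
    primary Z-linkage screen (~0.5 for fully Z-linked scaffolds).
    """
    df = summary.copy()
    if not set(df["sex"]) <= {"F", "M"}:
        raise ValueError("sex labels must be 'F' or 'M'")
    df["norm"] = df["count"] / df["length"]
    per_sex = df.pivot_table(index="scaffold", columns="sex", values="norm",
                             aggfunc="mean")
    for sex in ("F", "M"):
        if sex not in per_sex:
            raise ValueError(f"need at least one sample of sex {sex}")
    out = pd.DataFrame({
        "female_mean": per_sex["F"],
        "male_mean": per_sex["M"],
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fm_ratio"] = out["female_mean"] / out["male_mean"]
    out["defined"] = out["male_mean"] > 0
    out.loc[~out["defined"], "fm_ratio"] = np.nan
    return out


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------

@dataclass
class HetRateSummary:
    """Two views of heterozygosity.

    ``per_sample``: het/non-ref fraction per (scaffold, sample) — the
    heterozygous *rate*.  ``per_sex``: mean het sites per bp per
    (scaffold, sex) — *heterozygosity*.  Missing genotypes count in
    neither numerator nor denominator.
    """
    per_sample: pd.DataFrame  # scaffold, sample, n_het, n_nonref, het_rate, defined
    per_sex: pd.DataFrame     # scaffold, sex, het_per_bp


def het_rate(sites: pd.DataFrame, lengths: Mapping[str, int],
             samples: Optional[pd.DataFrame] = None) -> HetRateSummary:
    """Per-sample het rates and per-sex heterozygosity from filtered calls."""
    df = sites[sites["gt"] != "missing"]
    grp = df.groupby(["scaffold", "sample"], observed=True)["gt"]
    n_het = grp.apply(lambda g: int((g == "het").sum()))
    n_nonref = grp.apply(lambda g: int(g.isin(["het", "hom_alt"]).sum()))
    per_sample = pd.DataFrame({"n_het": n_het, "n_nonref": n_nonref}).reset_index()
    per_sample["defined"] = per_sample["n_nonref"] > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        per_sample["het_rate"] = np.where(
            per_sample["defined"],
            per_sample["n_het"] / per_sample["n_nonref"].replace(0, np.nan),
            np.nan)

    if samples is not None:
        sex_of = samples.set_index("sample")["sex"]
    elif "sex" in sites.columns:
        sex_of = sites.drop_duplicates("sample").set_index("sample")["sex"]
    else:
        raise ValueError("sample sex labels required (samples= or a 'sex' column)")
    per_sample["sex"] = per_sample["sample"].map(sex_of)
    ln = pd.Series(lengths)
    per_sample["het_per_bp"] = per_sample["n_het"] / per_sample["scaffold"].map(ln)
    per_sex = (per_sample.groupby(["scaffold", "sex"], observed=True)["het_per_bp"]
               .mean().reset_index())
    return HetRateSummary(per_sample=per_sample.drop(columns="het_per_bp"),
                          per_sex=per_sex)


# ---------------------------------------------------------------------------
# candidate calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateThresholds:
    """Signal cuts separating copy-number 1 from 2 under realistic noise,
    plus the size filters (>500 kb, >10 transcripts)."""
    ratio_max: float = 0.8
    het_ratio_min: float = 5.0   # female/male het-per-bp ratio
    min_length: int = 500_000
    min_transcripts: int = 10


@dataclass
class CandidateZReport:
    table: pd.DataFrame
    candidates: list = field(default_factory=list)
    par_intervals: dict = field(default_factory=dict)  # scaffold -> [(start, end)]
    thresholds: CandidateThresholds = CandidateThresholds()


def call_candidate_z(depth_ratios: pd.DataFrame,
                     het: HetRateSummary,
                     lengths: Mapping[str, int],
                     n_transcripts: Mapping[str, int],
                     thresholds: CandidateThresholds = CandidateThresholds()
                     ) -> CandidateZReport:
    """Call candidate Z scaffolds from depth and heterozygosity signals.

    Candidate iff fm depth ratio <= ratio_max AND female/male
    heterozygosity (het sites per bp) ratio >= het_ratio_min AND length >=
    min_length AND n_transcripts > min_transcripts.  Scaffolds passing the
    signal cuts but failing a size cut are flagged, not dropped; scaffolds
    without het data are flagged indeterminate.
    """
    hs = het.per_sex.pivot_table(index="scaffold", columns="sex",
                                 values="het_per_bp")
    rate = het.per_sample.pivot_table(index="scaffold", columns="sex",
                                      values="het_rate", aggfunc="mean")
    rows = []
    for scaffold, drow in depth_ratios.iterrows():
        length = int(lengths[scaffold])
        ntr = int(n_transcripts.get(scaffold, 0))
        f_het = hs["F"].get(scaffold, np.nan) if "F" in hs else np.nan
        m_het = hs["M"].get(scaffold, np.nan) if "M" in hs else np.nan
        indeterminate = np.isnan(f_het) or np.isnan(m_het)
        het_ratio = np.nan if indeterminate or m_het == 0 else f_het / m_het
        signal = (not indeterminate
                  and drow["fm_ratio"] <= thresholds.ratio_max
                  and not np.isnan(het_ratio)
                  and het_ratio >= thresholds.het_ratio_min)
        short = length < thresholds.min_length
        few = ntr <= thresholds.min_transcripts
        rows.append({
            "scaffold": scaffold, "length": length, "n_transcripts": ntr,
            "fm_depth_ratio": drow["fm_ratio"],
            "female_het_per_bp": f_het, "male_het_per_bp": m_het,
            "het_fm_ratio": het_ratio,
            "female_het_rate": rate["F"].get(scaffold, np.nan) if "F" in rate else np.nan,
            "male_het_rate": rate["M"].get(scaffold, np.nan) if "M" in rate else np.nan,
            "candidate": bool(signal and not short and not few),
            "excluded_short": bool(signal and short),
            "excluded_few_transcripts": bool(signal and few),
            "indeterminate": bool(indeterminate),
        })
    table = pd.DataFrame(rows).set_index("scaffold")
    return CandidateZReport(table=table,
                            candidates=list(table.index[table["candidate"]]),
                            thresholds=thresholds)


# ---------------------------------------------------------------------------
# window ratios and PAR detection
# ---------------------------------------------------------------------------

def window_log2_fm(profile_windows: pd.DataFrame, samples: pd.DataFrame,
                   eps: float = 1e-6) -> pd.DataFrame:
    """Per-window log2((mean F depth + eps) / (mean M depth + eps)).

    eps guards zero-depth windows (flagged) so coordinates stay contiguous.
    """
    females = list(samples.loc[samples["sex"] == "F", "sample"])
    males = list(samples.loc[samples["sex"] == "M", "sample"])
    if not females or not males:
        raise ValueError("need at least one sample of each sex")
    out = profile_windows[["scaffold", "start", "end"]].copy()
    f = profile_windows[females].mean(axis=1)
    m = profile_windows[males].mean(axis=1)
    out["zero_depth"] = (f == 0) | (m == 0)
    out["log2_fm"] = np.log2((f + eps) / (m + eps))
    return out


@dataclass
class ParScan:
    """PAR intervals (bp, 0-based half-open) detected on one scaffold."""
    intervals: list                      # [(start, end)]
    boundaries: list                     # bp coordinate of each PAR edge interior to the scaffold
    warning: Optional[str] = None
    n_windows: int = 0


def _terminal_run(status: np.ndarray, from_start: bool) -> int:
    """Length of the terminal run of balanced (+1) windows."""
    arr = status if from_start else status[::-1]
    run = 0
    for v in arr:
        if v == 1:
            run += 1
        else:
            break
    return run


def _refine_changepoint(raw: np.ndarray, guess: int, halfwidth: int) -> int:
    """Least-squares two-level step fit for the balanced->linked boundary."""
    n = len(raw)
    lo = max(1, guess - halfwidth)
    hi = min(n - 1, guess + halfwidth)
    if lo >= hi:
        return guess
    seg_end = min(n, hi + halfwidth)
    seg = raw[:seg_end]
    cs = np.concatenate([[0.0], np.cumsum(seg)])
    cs2 = np.concatenate([[0.0], np.cumsum(seg ** 2)])
    best_k, best_cost = guess, np.inf
    for k in range(lo, hi + 1):
        left_n, right_n = k, seg_end - k
        left_ss = cs2[k] - cs[k] ** 2 / left_n
        right_ss = (cs2[seg_end] - cs2[k]) - (cs[seg_end] - cs[k]) ** 2 / right_n
        cost = left_ss + right_ss
        if cost < best_cost:
            best_cost, best_k = cost, k
    return best_k


def detect_par(windows: pd.DataFrame, smoothed: Sequence[float],
               balanced_cut: float = -0.25, linked_cut: float = -0.6,
               min_run: int = 20, raw: Optional[Sequence[float]] = None,
               refine_halfwidth: Optional[int] = None) -> ParScan:
    """Detect pseudoautosomal regions as terminal runs of balanced windows.

    ``windows`` holds one scaffold's sorted windows (start, end); ``smoothed``
    the LOESS-smoothed log2(F/M) depth ratios.  Windows are balanced above
    ``balanced_cut``, sex-linked below ``linked_cut``; intermediate windows
    take the label of the nearest decided window.  A terminal balanced run
    of >= ``min_run`` windows is a PAR; its interior edge is refined by a
    two-level step fit on the raw ratios when they are supplied, which
    undoes the boundary displacement smoothing introduces.
    """
    s = np.asarray(smoothed, dtype=float)
    n = len(s)
    if n == 0:
        return ParScan([], [], warning="no windows", n_windows=0)
    if len(windows) != n:
        raise ValueError("windows and smoothed values length mismatch")
    status = np.where(s > balanced_cut, 1, np.where(s < linked_cut, -1, 0))
    if (status == 0).any() and (status != 0).any():
        decided = np.flatnonzero(status != 0)
        for i in np.flatnonzero(status == 0):
            j = decided[np.argmin(np.abs(decided - i))]
            status[i] = status[j]
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()

    if (status == 1).all():
        return ParScan([(int(starts[0]), int(ends[-1]))], [],
                       warning="entire scaffold balanced; likely not sex-linked",
                       n_windows=n)
    if (status == -1).all():
        return ParScan([], [], n_windows=n)

    if refine_halfwidth is None:
        refine_halfwidth = max(min_run, n // 8)
    raw_arr = None if raw is None else np.asarray(raw, dtype=float)

    intervals, boundaries = [], []
    head = _terminal_run(status, from_start=True)
    if head >= min_run:
        k = head
        if raw_arr is not None:
            k = _refine_changepoint(raw_arr, head, refine_halfwidth)
        intervals.append((int(starts[0]), int(ends[k - 1])))
        boundaries.append(int(ends[k - 1]))
    tail = _terminal_run(status, from_start=False)
    if tail >= min_run and head < n:
        k = tail
        if raw_arr is not None:
            k = _refine_changepoint(raw_arr[::-1], tail, refine_halfwidth)
        intervals.append((int(starts[n - k]), int(ends[-1])))
        boundaries.append(int(starts[n - k]))
    return ParScan(intervals=intervals, boundaries=boundaries, n_windows=n)


# ---------------------------------------------------------------------------
# Z/A diversity theory and observation
# ---------------------------------------------------------------------------

def za_ratio_theory(nm: float, nf: float) -> float:
    """Theoretical Ne_Z / Ne_A for breeding sex ratio (Nm males, Nf females).

    Ne_A = 4*Nm*Nf/(Nm+Nf); Ne_Z = 9*Nm*Nf/(4*Nm+2*Nf).  Equal sex ratio
    gives 0.75; the female-biased limit approaches 9/8 = 1.125, so the
    ratio never reaches 1.2.
    """
    if nm <= 0 or nf <= 0:
        raise ValueError("breeding numbers must be positive")
    ne_a = 4.0 * nm * nf / (nm + nf)
    ne_z = 9.0 * nm * nf / (4.0 * nm + 2.0 * nf)
    return ne_z / ne_a


def za_ratio_max(lo: float = 1e-3, hi: float = 1e3, n_grid: int = 10_000) -> float:
    """Maximum theoretical Z/A ratio over sex ratios Nf/Nm in [lo, hi]."""
    r = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    vals = np.array([za_ratio_theory(1.0, ri) for ri in r])
    return float(vals.max())


def observed_za_diversity(het: HetRateSummary, z_scaffold: str,
                          a_scaffold: str, sex: str) -> float:
    """Z/A ratio of per-sex heterozygosity (het sites per bp).

    Returns NaN (with a warning) when the autosomal value is zero.
    """
    hs = het.per_sex.set_index(["scaffold", "sex"])["het_per_bp"]
    try:
        z = hs[(z_scaffold, sex)]
        a = hs[(a_scaffold, sex)]
    except KeyError as e:
        raise ValueError(f"heterozygosity undefined for {e.args[0]}") from e
    if a == 0:
        warnings.warn("autosomal heterozygosity is zero; Z/A ratio undefined")
        return float("nan")
    return float(z / a)
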