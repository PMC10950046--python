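"""End-to-end orchestration: simulate or load, then analyse and report.

Stage order mirrors the analysis chain: scaffold screening -> PAR scan ->
variant filtering and heterozygosity -> expression filtering and rank
tests -> mixed models and AICc selection -> dosage classification ->
BCV / selection modelling.  A single config (YAML-able) plus seed
determines every output; each report table carries the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import pickle
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as zio
from . import simulate as sim
from .dosage import (attach_bayes, bonferroni, build_lmm_data, classify_dosage,
                     dosage_summaries, filter_expressed, fm_expression_ratio,
                     mwu_test)
from .lmm import coefficient_table, fit_lmm_set, select_models, selection_table
from .loess import loess_smooth
from .selection import bcv_pca, estimate_bcv, selection_model, signed_rank_test
from .sexlinkage import (CandidateThresholds, apply_variant_filters,
                         call_candidate_z, detect_par, het_rate,
                         scaffold_fm_depth_ratio, window_log2_fm)

log = logging.getLogger("zwdosage")


@dataclass
class PipelineConfig:
    """Pipeline inputs, thresholds and stage toggles.

    Exactly one of ``simulate`` (a SimulationConfig) or ``inputs`` (paths
    to the on-disk tables) must be provided.
    """
    simulate: Optional[sim.SimulationConfig] = None
    inputs: Optional[dict] = None
    seed: int = 0
    outdir: str = "zwdosage_out"
    log_level: str = "INFO"
    # stage toggles
    run_sexlinkage: bool = True
    run_dosage: bool = True
    run_selection: bool = True
    # sexlinkage thresholds
    ratio_max: float = 0.8
    het_ratio_min: float = 5.0
    min_length: int = 500_000
    min_transcripts: int = 10
    loess_span: float = 0.25
    loess_degree: int = 2
    balanced_cut: float = -0.25
    linked_cut: float = -0.6
    min_run: int = 20
    # dosage settings
    normalize: str = "ordernorm"
    alpha: float = 0.05
    margin: float = 0.25
    bayes_draws: int = 2000
    compute_bayes: bool = True
    # selection settings
    prior_df: float = 10.0
    cache: bool = False

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("provide exactly one of simulate= or inputs=")
        if self.normalize not in ("ordernorm", "log2", "none"):
            raise ValueError("normalize must be 'ordernorm', 'log2' or 'none'")
        for name, lo, hi in (("ratio_max", 0, 2), ("loess_span", 0, 1),
                             ("alpha", 0, 1), ("margin", 0, 1)):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"] = sim.config_to_dict(self.simulate)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        for run_local in ("outdir", "log_level", "cache"):
            d.pop(run_local, None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = sim.config_from_dict(d["simulate"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class InputBundle:
    scaffold_summary: pd.DataFrame
    profile: sim.WindowDepthProfile
    genotypes: pd.DataFrame
    expr: sim.ExpressionMatrix
    ancestral: pd.DataFrame
    counts: sim.CountMatrix
    lengths: dict
    n_transcripts: dict
    truth: Optional[sim.TruthTable] = None


@dataclass
class ReportBundle:
    provenance: dict
    candidate_report: Optional[object] = None
    par_scans: dict = field(default_factory=dict)
    window_ratios: Optional[pd.DataFrame] = None
    test_table: Optional[pd.DataFrame] = None
    selection_tables: dict = field(default_factory=dict)   # condition -> model table
    coefficient_tables: dict = field(default_factory=dict)  # condition -> coef table
    diagnosis: Optional[object] = None
    bcv_table: Optional[pd.DataFrame] = None
    pca_scores: Optional[pd.DataFrame] = None
    selection_fit: Optional[object] = None
    signed_rank: Optional[object] = None
    filter_report: dict = field(default_factory=dict)


def load_inputs(config: PipelineConfig) -> InputBundle:
    """Load (or simulate) and validate every stage input."""
    if config.simulate is not None:
        scfg = dataclasses.replace(config.simulate, seed=config.seed)
        scfg.validate()
        layout = sim.simulate_genome_layout(scfg)
        profile = sim.simulate_depth_windows(layout, scfg)
        summary = sim.scaffold_read_counts(profile, layout)
        genotypes = sim.simulate_genotypes(layout, scfg)
        expr, anc, truth = sim.simulate_expression(layout, scfg)
        counts = sim.simulate_counts(expr, scfg)
        lengths = dict(zip(layout.scaffolds["scaffold"], layout.scaffolds["length"]))
        ntr = layout.transcripts.groupby("scaffold").size().to_dict()
        return InputBundle(scaffold_summary=summary, profile=profile,
                           genotypes=genotypes, expr=expr, ancestral=anc,
                           counts=counts, lengths=lengths, n_transcripts=ntr,
                           truth=truth)
    paths = config.inputs
    summary = zio.read_scaffold_summary(paths["scaffold_summary"])
    sample_sex = summary[["sample", "sex"]].drop_duplicates()
    profile = zio.read_window_depth(paths["window_depth"], sample_sex)
    genotypes = zio.read_vcf(paths["vcf"],
                             dict(zip(sample_sex["sample"], sample_sex["sex"])))
    expr = zio.read_expression(paths["fpkm"], paths["fpkm_meta"])
    anc = zio.read_ancestral(paths["ancestral"])
    counts = zio.read_counts(paths["counts"], expr.samples)
    lengths = summary.drop_duplicates("scaffold").set_index("scaffold")["length"].to_dict()
    ntr = expr.transcripts.groupby("scaffold").size().to_dict()
    return InputBundle(scaffold_summary=summary, profile=profile,
                       genotypes=genotypes, expr=expr, ancestral=anc,
                       counts=counts, lengths=lengths, n_transcripts=ntr)


def _stage_sexlinkage(config, bundle, report):
    ratios = scaffold_fm_depth_ratio(bundle.scaffold_summary)
    filtered = apply_variant_filters(bundle.genotypes)
    log.info("variant filters: %d sites removed, %d genotypes masked",
             filtered.n_sites_removed, filtered.n_genotypes_masked)
    het = het_rate(filtered.table, bundle.lengths)
    thresholds = CandidateThresholds(
        ratio_max=config.ratio_max, het_ratio_min=config.het_ratio_min,
        min_length=config.min_length, min_transcripts=config.min_transcripts)
    cz = call_candidate_z(ratios, het, bundle.lengths,
                          bundle.n_transcripts, thresholds)
    log.info("candidate Z scaffolds: %s", cz.candidates or "none")

    samples_df = bundle.profile.samples
    wr = window_log2_fm(bundle.profile.windows, samples_df)
    report.window_ratios = wr
    for scaffold in cz.candidates:
        w = wr[wr["scaffold"] == scaffold].reset_index(drop=True)
        mid = (w["start"] + w["end"]).to_numpy() / 2.0
        smooth = loess_smooth(mid, w["log2_fm"].to_numpy(),
                              span=config.loess_span, degree=config.loess_degree)
        scan = detect_par(w, smooth, balanced_cut=config.balanced_cut,
                          linked_cut=config.linked_cut, min_run=config.min_run,
                          raw=w["log2_fm"].to_numpy())
        report.par_scans[scaffold] = scan
        cz.par_intervals[scaffold] = scan.intervals
    report.candidate_report = cz
    report.filter_report["variant_sites_removed"] = filtered.n_sites_removed
    report.filter_report["genotypes_masked"] = filtered.n_genotypes_masked


def _stage_dosage(config, bundle, report):
    fr = filter_expressed(bundle.expr)
    log.info("expression filter: %d in, %d unexpressed dropped, %d PAR dropped, %d remain",
             fr.n_in, fr.n_dropped_unexpressed, fr.n_dropped_par, len(fr.expr.fpkm))
    report.filter_report.update({
        "transcripts_in": fr.n_in,
        "transcripts_unexpressed": fr.n_dropped_unexpressed,
        "transcripts_par": fr.n_dropped_par,
        "transcripts_retained": len(fr.expr.fpkm)})
    expr = fr.expr
    ratios = fm_expression_ratio(expr)
    on_z = expr.transcripts["linkage"] == "Z"
    on_a = expr.transcripts["linkage"] == "A"
    means = expr.sex_means()

    tests = [
        mwu_test(ratios[on_z], ratios[on_a], label="log2FM_Z_vs_A"),
        mwu_test(np.log2(means.loc[on_z, "M"]), np.log2(means.loc[on_a, "M"]),
                 label="male_Z_vs_A"),
        mwu_test(np.log2(means.loc[on_z, "F"]), np.log2(means.loc[on_a, "F"]),
                 label="female_Z_vs_A"),
    ]
    adj = bonferroni([t.p for t in tests])
    for t, pa in zip(tests, adj):
        t.p_adjusted = float(pa)
    if config.compute_bayes:
        pairs = [(ratios[on_z], ratios[on_a]),
                 (np.log2(means.loc[on_z, "M"]), np.log2(means.loc[on_a, "M"])),
                 (np.log2(means.loc[on_z, "F"]), np.log2(means.loc[on_a, "F"]))]
        for t, (x, y) in zip(tests, pairs):
            attach_bayes(t, np.asarray(x), np.asarray(y), seed=config.seed,
                         draws=config.bayes_draws)
    report.test_table = pd.DataFrame([{
        "comparison": t.label, "U": t.u, "p": t.p, "p_bonferroni": t.p_adjusted,
        "BF10": t.bf10, "BF01": t.bf01, "n1": t.n1, "n2": t.n2,
        "tier_p": t.tier_p, "tier_bf": t.tier_bf} for t in tests])

    bal_data = build_lmm_data(expr, normalize=config.normalize)
    bal_ranked = select_models(fit_lmm_set(bal_data, "balance"))
    comp_data = build_lmm_data(expr, ancestral=bundle.ancestral,
                               normalize=config.normalize)
    comp_ranked = select_models(fit_lmm_set(comp_data, "compensation"))
    for cond, ranked in (("balance", bal_ranked), ("compensation", comp_ranked)):
        report.selection_tables[cond] = selection_table(ranked)
        report.coefficient_tables[cond] = coefficient_table(ranked[0])
        log.info("%s best model: %s", cond, ranked[0].model_label)

    summ = dosage_summaries(expr, bundle.ancestral)
    report.diagnosis = classify_dosage(bal_ranked, comp_ranked, summ,
                                       tests=tests, alpha=config.alpha,
                                       margin=config.margin)
    log.info("dosage diagnosis: %s", report.diagnosis.type_label)
    report._expr_filtered = expr
    report._ratios = ratios


def _stage_selection(config, bundle, report):
    expr = getattr(report, "_expr_filtered", None)
    if expr is None:
        fr = filter_expressed(bundle.expr)
        expr = fr.expr
        report._ratios = fm_expression_ratio(expr)
    keep = expr.fpkm.index
    counts = sim.CountMatrix(
        counts=bundle.counts.counts.loc[bundle.counts.counts.index.intersection(keep)],
        lib_sizes=bundle.counts.lib_sizes, samples=bundle.counts.samples)
    sex_series = counts.samples["sex"]
    bcv_f = estimate_bcv(counts.counts, counts.lib_sizes, sex_series, "F",
                         prior_df=config.prior_df)
    bcv_m = estimate_bcv(counts.counts, counts.lib_sizes, sex_series, "M",
                         prior_df=config.prior_df)
    report.bcv_table = pd.concat([bcv_f, bcv_m], ignore_index=True)

    on_z = expr.transcripts["linkage"] == "Z"
    z_ids = expr.fpkm.index[on_z]
    f = bcv_f[~bcv_f["excluded"]].set_index("transcript")["log2_bcv"]
    m = bcv_m[~bcv_m["excluded"]].set_index("transcript")["log2_bcv"]
    common = z_ids.intersection(f.index).intersection(m.index)
    report.signed_rank = signed_rank_test(f[common], m[common])
    pairs = pd.DataFrame({"log2_bcv_f": f[common], "log2_bcv_m": m[common]})
    pca = bcv_pca(pairs)
    report.pca_scores = pca.scores
    outcome = report._ratios.loc[common]
    report.selection_fit = selection_model(pca.scores, outcome)
    log.info("selection model R^2 = %.3f", report.selection_fit.r_squared)


_STAGES = (("sexlinkage", _stage_sexlinkage),
           ("dosage", _stage_dosage),
           ("selection", _stage_selection))


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    chash = config.config_hash()
    cache_dir = os.path.join(config.outdir, ".cache")
    bundle = None
    if config.cache:
        os.makedirs(cache_dir, exist_ok=True)
        cpath = os.path.join(cache_dir, f"{chash}-inputs.pkl")
        if os.path.exists(cpath):
            with open(cpath, "rb") as fh:
                bundle = pickle.load(fh)
            log.info("loaded cached inputs (%s)", chash)
    if bundle is None:
        bundle = load_inputs(config)
        if config.cache:
            with open(os.path.join(cache_dir, f"{chash}-inputs.pkl"), "wb") as fh:
                pickle.dump(bundle, fh)

    report = ReportBundle(provenance={
        "config_hash": chash, "seed": config.seed,
        "package": "zwdosage 0.1.0",
        "regime": (config.simulate.regime if config.simulate else None),
    })
    toggles = {"sexlinkage": config.run_sexlinkage,
               "dosage": config.run_dosage,
               "selection": config.run_selection}
    for name, fn in _STAGES:
        if not toggles[name]:
            log.info("stage %s disabled", name)
            continue
        try:
            fn(config, bundle, report)
        except Exception as e:
            raise RuntimeError(f"stage {name!r} failed: {e}") from e
    return report


def write_report(report: ReportBundle, outdir: str) -> list:
    """Serialize every table of the bundle; returns written paths."""
    os.makedirs(outdir, exist_ok=True)
    written = []

    def _tsv(df, name, float_format=zio.FLOAT_FMT):
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", index=False, float_format=float_format)
        written.append(path)

    def _json(obj, name):
        path = os.path.join(outdir, name)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
            fh.write("\n")
        written.append(path)

    _json(report.provenance, "provenance.json")
    lines = [f"config {report.provenance['config_hash']} seed {report.provenance['seed']}"]
    if report.candidate_report is not None:
        cz = report.candidate_report
        _tsv(cz.table.reset_index(), "candidate_z.tsv")
        _json({"candidates": cz.candidates, "par_intervals": cz.par_intervals},
              "candidate_z.json")
        if cz.candidates:
            lines.append("candidate Z scaffolds: " + ", ".join(cz.candidates))
        else:
            lines.append("no sex-linked scaffolds detected")
        for scaffold, scan in report.par_scans.items():
            if scan.intervals:
                iv = "; ".join(f"[{a:,}, {b:,})" for a, b in scan.intervals)
                lines.append(f"PAR on {scaffold}: {iv}")
    if report.window_ratios is not None:
        path = os.path.join(outdir, "window_log2_fm.bedgraph")
        zio.write_bedgraph(report.window_ratios, "log2_fm", path)
        written.append(path)
    if report.test_table is not None:
        _tsv(report.test_table, "dosage_tests.tsv")
    for cond, table in report.selection_tables.items():
        _tsv(table, f"model_selection_{cond}.tsv")
    for cond, table in report.coefficient_tables.items():
        _tsv(table, f"coefficients_{cond}.tsv")
    if report.diagnosis is not None:
        d = report.diagnosis
        _json({"balance": d.balance, "compensation": d.compensation,
               "type": d.type_label, "conflict": d.conflict, "notes": d.notes,
               "median_z_log2_fm": d.summaries.median_z_log2_fm,
               "median_z_log2_f_vs_anc": d.summaries.median_z_log2_f_vs_anc,
               "balance_best_model": d.balance_best,
               "compensation_best_model": d.compensation_best},
              "diagnosis.json")
        lines.append(f"dosage balance {d.balance}, compensation {d.compensation} "
                     f"-> {d.type_label}")
    if report.bcv_table is not None:
        _tsv(report.bcv_table, "bcv.tsv")
    if report.pca_scores is not None:
        _tsv(report.pca_scores.reset_index(), "pca_scores.tsv")
    if report.selection_fit is not None:
        sf = report.selection_fit
        _json({"params": sf.params.to_dict(), "se": sf.se.to_dict(),
               "pvalues": sf.pvalues.to_dict(), "r_squared": sf.r_squared,
               "nobs": sf.nobs}, "selection_model.json")
    if report.signed_rank is not None:
        sr = report.signed_rank
        _json({"V": sr.v, "p": sr.p, "n_used": sr.n_used,
               "n_zero_dropped": sr.n_zero_dropped, "method": sr.method},
              "signed_rank.json")
    if report.filter_report:
        _json(report.filter_report, "filter_report.json")
    with open(os.path.join(outdir, "summary.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    written.append(os.path.join(outdir, "summary.txt"))
    return written


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)
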