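"""Readers and writers for the pipeline's tabular formats.

Text formats only: scaffold-summary TSV, window depth BED-like TSV,
minimal VCF 4.2 (read back through pysam), FPKM TSV with a YAML metadata
sidecar, ancestral-expression TSV, count TSV, and bedGraph ratio tracks.
Window coordinates are 0-based half-open (BED); VCF positions 1-based.
All floats are written at a fixed precision so re-serialization is
byte-identical.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd
import pysam
import yaml

from .simulate import ExpressionMatrix, CountMatrix, WindowDepthProfile

FLOAT_FMT = "%.6g"


class InputValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scaffold summary
# ---------------------------------------------------------------------------

def write_scaffold_summary(df: pd.DataFrame, path: str) -> None:
    df[["scaffold", "length", "sample", "sex", "count"]].to_csv(
        path, sep="\t", index=False)


def read_scaffold_summary(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"scaffold", "length", "sample", "sex", "count"}
    if not need <= set(df.columns):
        raise InputValidationError(f"{path}: missing columns {need - set(df.columns)}")
    if (df["count"] < 0).any() or (df["length"] <= 0).any():
        raise InputValidationError(f"{path}: negative counts or non-positive lengths")
    bad = ~df["sex"].isin(["M", "F"])
    if bad.any():
        raise InputValidationError(
            f"{path}: sample {df.loc[bad, 'sample'].iloc[0]!r} has no valid sex label")
    return df


# ---------------------------------------------------------------------------
# window depth
# ---------------------------------------------------------------------------

def write_window_depth(profile: WindowDepthProfile, path: str,
                       samples_path: Optional[str] = None) -> None:
    profile.windows.to_csv(path, sep="\t", index=False)
    if samples_path:
        profile.samples.to_csv(samples_path, sep="\t", index=False)


def read_window_depth(path: str, samples: pd.DataFrame) -> WindowDepthProfile:
    df = pd.read_csv(path, sep="\t")
    for col in ("scaffold", "start", "end"):
        if col not in df.columns:
            raise InputValidationError(f"{path}: missing column {col!r}")
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise InputValidationError(
            f"{path}: empty/inverted window {bad['scaffold']}:{bad['start']}-{bad['end']}")
    for scaffold, grp in df.groupby("scaffold"):
        g = grp.sort_values("start")
        overlap = g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]
        if overlap.any():
            i = int(np.flatnonzero(overlap)[0])
            raise InputValidationError(
                f"{path}: overlapping windows on {scaffold} at "
                f"{g['start'].iloc[i + 1]} < end {g['end'].iloc[i]}")
    missing = set(samples["sample"]) - set(df.columns)
    if missing:
        raise InputValidationError(f"{path}: no depth column for samples {sorted(missing)}")
    return WindowDepthProfile(windows=df, samples=samples.copy())


def write_bedgraph(df: pd.DataFrame, value_col: str, path: str,
                   track_name: str = "log2_fm") -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for _, r in df.iterrows():
            fh.write(f"{r['scaffold']}\t{int(r['start'])}\t{int(r['end'])}\t"
                     f"{FLOAT_FMT % r[value_col]}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_TO_VCF = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}
_VCF_TO_GT = {(0, 0): "hom_ref", (0, 1): "het", (1, 0): "het",
              (1, 1): "hom_alt", (None, None): "missing"}


def write_vcf(genotypes: pd.DataFrame, lengths, path: str) -> None:
    """Minimal VCF 4.2 with MQ/QD INFO and GT:DP:GQ FORMAT fields.

    ``genotypes`` is the long table (scaffold, pos, mq, qd, sample, gt,
    dp, gq); REF/ALT are placeholder A/T since only genotype classes and
    quality fields matter downstream.
    """
    samples = list(dict.fromkeys(genotypes["sample"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for scaffold, length in dict(lengths).items():
            fh.write(f"##contig=<ID={scaffold},length={int(length)}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        wide = genotypes.pivot_table(
            index=["scaffold", "pos", "mq", "qd"], columns="sample",
            values=["gt", "dp", "gq"], aggfunc="first", observed=True)
        wide = wide.sort_index()
        for (scaffold, pos, mq, qd), row in wide.iterrows():
            cells = []
            for s in samples:
                cells.append(f"{_GT_TO_VCF[row[('gt', s)]]}:"
                             f"{int(row[('dp', s)])}:{int(row[('gq', s)])}")
            fh.write(f"{scaffold}\t{int(pos)}\t.\tA\tT\t.\t.\t"
                     f"MQ={FLOAT_FMT % mq};QD={FLOAT_FMT % qd}\tGT:DP:GQ\t"
                     + "\t".join(cells) + "\n")


def read_vcf(path: str, sample_sex: Optional[dict] = None) -> pd.DataFrame:
    """Read a VCF into the long genotype table via pysam."""
    rows = []
    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as e:
        raise InputValidationError(f"{path}: malformed VCF ({e})") from e
    with vcf:
        for rec in vcf:
            mq = rec.info.get("MQ", np.nan)
            qd = rec.info.get("QD", np.nan)
            for sample, call in rec.samples.items():
                alleles = call.get("GT", (None, None))
                gt = _VCF_TO_GT.get(tuple(alleles) if alleles else (None, None),
                                    "missing")
                rows.append((rec.chrom, rec.pos, mq, qd, sample, gt,
                             call.get("DP", 0) or 0, call.get("GQ", 0) or 0))
    df = pd.DataFrame(rows, columns=["scaffold", "pos", "mq", "qd",
                                     "sample", "gt", "dp", "gq"])
    if sample_sex is not None:
        unlabeled = set(df["sample"].unique()) - set(sample_sex)
        if unlabeled:
            raise InputValidationError(
                f"{path}: sample {sorted(unlabeled)[0]!r} has no sex label")
        df["sex"] = df["sample"].map(sample_sex)
    return df


# ---------------------------------------------------------------------------
# expression / ancestral / counts
# ---------------------------------------------------------------------------

def write_expression(expr: ExpressionMatrix, tsv_path: str, meta_path: str) -> None:
    df = expr.fpkm.copy()
    df.insert(0, "transcript", df.index)
    df.to_csv(tsv_path, sep="\t", index=False, float_format=FLOAT_FMT)
    meta = {
        "samples": {s: str(row["sex"]) for s, row in expr.samples.iterrows()},
        "transcripts": {
            t: {"scaffold": str(r["scaffold"]), "linkage": str(r["linkage"]),
                "ortholog": (None if pd.isna(r["ortholog"]) else str(r["ortholog"]))}
            for t, r in expr.transcripts.iterrows()},
    }
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_expression(tsv_path: str, meta_path: str) -> ExpressionMatrix:
    df = pd.read_csv(tsv_path, sep="\t")
    if "transcript" not in df.columns:
        raise InputValidationError(f"{tsv_path}: missing 'transcript' column")
    if df["transcript"].duplicated().any():
        dup = df.loc[df["transcript"].duplicated(), "transcript"].iloc[0]
        raise InputValidationError(f"{tsv_path}: duplicate transcript id {dup!r}")
    df = df.set_index("transcript")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    unlabeled = [s for s in df.columns if s not in meta.get("samples", {})]
    if unlabeled:
        raise InputValidationError(
            f"{meta_path}: sample {unlabeled[0]!r} has no sex label")
    samples = pd.DataFrame(
        {"sex": {s: meta["samples"][s] for s in df.columns}})
    samples.index.name = "sample"
    tmeta_src = meta.get("transcripts", {})
    missing = [t for t in df.index if t not in tmeta_src]
    if missing:
        raise InputValidationError(
            f"{meta_path}: transcript {missing[0]!r} has no metadata")
    tmeta = (pd.DataFrame.from_dict(tmeta_src, orient="index")
             .loc[df.index, ["scaffold", "linkage", "ortholog"]])
    if (df.to_numpy() < 0).any():
        raise InputValidationError(f"{tsv_path}: negative FPKM values")
    return ExpressionMatrix(fpkm=df, transcripts=tmeta, samples=samples)


def write_ancestral(anc: pd.DataFrame, path: str) -> None:
    out = anc.copy()
    out.insert(0, "ortholog", out.index)
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_ancestral(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"ortholog", "anc_male", "anc_female"}
    if not need <= set(df.columns):
        raise InputValidationError(f"{path}: missing columns {need - set(df.columns)}")
    if df["ortholog"].duplicated().any():
        raise InputValidationError(f"{path}: duplicate ortholog ids")
    if (df[["anc_male", "anc_female"]].to_numpy() < 0).any():
        raise InputValidationError(f"{path}: negative ancestral means")
    return df.set_index("ortholog")


def write_counts(cm: CountMatrix, path: str) -> None:
    df = cm.counts.copy()
    df.insert(0, "transcript", df.index)
    df.to_csv(path, sep="\t", index=False)


def read_counts(path: str, samples: pd.DataFrame,
                lib_sizes: Optional[pd.Series] = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t").set_index("transcript")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer) or (arr < 0).any():
        raise InputValidationError(f"{path}: counts must be non-negative integers")
    if lib_sizes is None:
        lib_sizes = df.sum(axis=0)
    lib_sizes.name = "lib_size"
    return CountMatrix(counts=df, lib_sizes=lib_sizes, samples=samples)
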