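"""Synthetic data for a female-heterogametic (ZZ/ZW) genome analysis.

Everything downstream of read alignment is emulated here: per-scaffold and
per-window sequencing depth that tracks Z copy number (females carry a
single Z outside the pseudoautosomal region), variant genotypes including
the W-gametolog mismapping artifact that inflates apparent female
heterozygosity on Z scaffolds, FPKM expression matrices under configurable
dosage regimes with an outgroup proxy for ancestral expression, and
negative-binomial read counts for dispersion estimation.  Every generator
returns ground-truth labels so recovery can be asserted, and all
randomness derives from one seed via named sub-streams.
"""

from __future__ import annotations

import io as _io
import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

REGIMES = (
    "no_compensation",
    "complete_compensation",
    "incomplete_compensation",
    "complete_balance",
)

#: Dosage-type label each regime should be diagnosed as (recovery oracle).
#: no_compensation: male-level Z in males, halved in females -> neither
#: balance nor compensation (Type II).  complete_compensation restores the
#: ancestral level in both sexes (Type I).  incomplete_compensation is the
#: gene-by-gene mosaic (Type III).  complete_balance equalizes the sexes at
#: a non-ancestral level, a non-canonical state.
REGIME_EXPECTED_LABEL = {
    "no_compensation": "Type II",
    "complete_compensation": "Type I",
    "incomplete_compensation": "Type III",
    "complete_balance": "balanced-uncompensated",
}


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated ZW study.

    Defaults mirror a small squamate resequencing + RNA-seq design: three
    individuals per sex, ~30x diploid depth, 5 kb depth windows, a 1.75 Mb
    PAR at the start of the first (5 Mb) Z scaffold, lognormal FPKM
    baselines and modest per-individual and residual expression noise.
    """

    n_autosomes: int = 8
    n_z_scaffolds: int = 4
    scaffold_lengths: Optional[Sequence[int]] = None  # autosomes then Z
    autosome_length: int = 3_000_000
    z_length: int = 3_000_000
    par_host_length: int = 5_000_000
    par_length: int = 1_750_000
    par_offset: int = 0
    window_size: int = 5_000
    n_males: int = 3
    n_females: int = 3
    mean_depth: float = 30.0          # reads/bp at a diploid locus
    depth_dispersion: float = 0.05    # NB overdispersion of window depth
    transcripts_per_scaffold: int = 40
    transcript_length: int = 1_000
    baseline_fpkm: float = 20.0
    expression_mu_logsd: float = 1.0  # log-scale SD of per-transcript baseline
    individual_sd: float = 0.1        # log-scale SD of per-sample effect
    residual_sd: float = 0.25         # log-scale SD of per-observation noise
    anc_noise_sd: float = 0.1         # log-scale SD of outgroup means
    regime: str = "no_compensation"
    compensated_fraction: float = 0.5
    balance_level: float = 0.7        # F=M=balance_level*mu under complete_balance
    site_density: float = 1e-3            # true variant sites per bp
    artifact_site_density: float = 8e-3   # W-mismapping artifact sites per bp (non-PAR Z)
    mismap_het_rate: float = 0.8      # P(female called het at an artifact site)
    background_het: float = 0.35      # P(het) at a true variant site (diploid)
    background_hom_alt: float = 0.30
    qc_fail_frac: float = 0.02        # per-field probability of failing a hard filter
    bcv_true: float = 0.4
    library_size: float = 2e7
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_autosomes", "n_z_scaffolds", "n_males", "n_females",
                     "transcripts_per_scaffold"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be > 0")
        if not 0.0 <= self.compensated_fraction <= 1.0:
            raise ConfigurationError("compensated_fraction must be in [0, 1]")
        if self.regime not in REGIMES:
            raise ConfigurationError(f"unknown regime {self.regime!r}")
        lengths = self._lengths()
        if self.par_length > 0:
            host = lengths[self.n_autosomes]  # first Z scaffold hosts the PAR
            if self.par_offset + self.par_length >= host:
                raise ConfigurationError(
                    f"par interval [{self.par_offset}, "
                    f"{self.par_offset + self.par_length}) must lie strictly "
                    f"inside its host scaffold (length {host})")
        for L in lengths:
            if L // self.transcripts_per_scaffold <= self.transcript_length:
                raise ConfigurationError(
                    "transcripts_per_scaffold too dense for scaffold length")

    def _lengths(self) -> list[int]:
        if self.scaffold_lengths is not None:
            expected = self.n_autosomes + self.n_z_scaffolds
            if len(self.scaffold_lengths) != expected:
                raise ConfigurationError(
                    f"scaffold_lengths must have {expected} entries")
            return list(self.scaffold_lengths)
        z = [self.par_host_length] + [self.z_length] * (self.n_z_scaffolds - 1)
        return [self.autosome_length] * self.n_autosomes + z

    def rng(self, component: str) -> np.random.Generator:
        """Named deterministic sub-stream of the master seed."""
        key = zlib.crc32(component.encode())
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))

    def sample_table(self) -> pd.DataFrame:
        males = [f"M{i + 1}" for i in range(self.n_males)]
        females = [f"F{i + 1}" for i in range(self.n_females)]
        return pd.DataFrame({
            "sample": males + females,
            "sex": ["M"] * self.n_males + ["F"] * self.n_females,
        })


@dataclass
class GenomeLayout:
    """Scaffold classes, PAR interval and transcript coordinates."""

    scaffolds: pd.DataFrame   # scaffold, length, cls {autosome,Z}, par_start, par_end
    transcripts: pd.DataFrame  # transcript, scaffold, start, end, linkage {A,Z,PAR}

    def to_bytes(self) -> bytes:
        buf = _io.StringIO()
        self.scaffolds.to_csv(buf, sep="\t", index=False)
        self.transcripts.to_csv(buf, sep="\t", index=False)
        return buf.getvalue().encode()

    def scaffold_lengths(self) -> pd.Series:
        return self.scaffolds.set_index("scaffold")["length"]

    def par_interval(self, scaffold: str):
        row = self.scaffolds.set_index("scaffold").loc[scaffold]
        if pd.isna(row["par_start"]):
            return None
        return int(row["par_start"]), int(row["par_end"])


@dataclass
class WindowDepthProfile:
    """0-based half-open depth windows, one column per sample."""

    windows: pd.DataFrame  # scaffold, start, end, <sample columns>
    samples: pd.DataFrame  # sample, sex


@dataclass
class ExpressionMatrix:
    fpkm: pd.DataFrame         # index transcript, columns sample
    transcripts: pd.DataFrame  # index transcript: scaffold, linkage, ortholog
    samples: pd.DataFrame      # index sample: sex

    def sex_means(self) -> pd.DataFrame:
        """Per-transcript mean FPKM for each sex (columns F, M)."""
        out = {}
        for sex in ("F", "M"):
            cols = self.samples.index[self.samples["sex"] == sex]
            out[sex] = self.fpkm[cols].mean(axis=1)
        return pd.DataFrame(out)


@dataclass
class CountMatrix:
    counts: pd.DataFrame     # index transcript, columns sample (integers)
    lib_sizes: pd.Series     # per sample
    samples: pd.DataFrame    # index sample: sex


@dataclass
class TruthTable:
    """Ground truth for recovery tests.

    ``true_interaction_beta`` is the male-minus-female Z-vs-autosome
    difference-in-differences on the log2(FPKM) scale, which is exact under
    the lognormal generative model.
    """

    scaffold_class: dict
    par_boundaries: dict
    gene_compensated: dict
    true_interaction_beta: float
    regime: str


def simulate_genome_layout(config: SimulationConfig) -> GenomeLayout:
    """Lay out autosomal and Z scaffolds with non-overlapping transcripts.

    The PAR, when present, sits on the first Z scaffold; transcripts are
    evenly spaced and labelled PAR iff their interval intersects the PAR.
    """
    config.validate()
    lengths = config._lengths()
    names = ([f"A{i + 1}" for i in range(config.n_autosomes)]
             + [f"Z{i + 1}" for i in range(config.n_z_scaffolds)])
    classes = ["autosome"] * config.n_autosomes + ["Z"] * config.n_z_scaffolds
    par_start = [np.nan] * len(names)
    par_end = [np.nan] * len(names)
    if config.par_length > 0:
        par_start[config.n_autosomes] = config.par_offset
        par_end[config.n_autosomes] = config.par_offset + config.par_length
    scaffolds = pd.DataFrame({
        "scaffold": names, "length": lengths, "cls": classes,
        "par_start": par_start, "par_end": par_end,
    })

    rows = []
    for name, length, cls, ps, pe in zip(names, lengths, classes, par_start, par_end):
        spacing = length // config.transcripts_per_scaffold
        for i in range(config.transcripts_per_scaffold):
            start = i * spacing
            end = start + config.transcript_length
            if cls == "autosome":
                linkage = "A"
            elif not np.isnan(ps) and start < pe and end > ps:
                linkage = "PAR"
            else:
                linkage = "Z"
            rows.append((f"{name}_t{i + 1:03d}", name, start, end, linkage))
    transcripts = pd.DataFrame(
        rows, columns=["transcript", "scaffold", "start", "end", "linkage"])
    return GenomeLayout(scaffolds=scaffolds, transcripts=transcripts)


def _nb_draw(rng, mean, dispersion):
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_depth_windows(layout: GenomeLayout,
                           config: SimulationConfig) -> WindowDepthProfile:
    """Negative-binomial window depths tracking Z copy number.

    Window mean is ``mean_depth * copy_number / 2``; copy number is 2
    everywhere except non-PAR Z windows in females (1).  A window counts as
    PAR when its midpoint falls inside the PAR interval.
    """
    rng = config.rng("depth")
    samples = config.sample_table()
    frames = []
    for _, scaf in layout.scaffolds.iterrows():
        length = int(scaf["length"])
        starts = np.arange(0, length, config.window_size)
        ends = np.minimum(starts + config.window_size, length)
        mid = (starts + ends) / 2
        if scaf["cls"] == "Z":
            in_par = np.zeros(len(starts), dtype=bool)
            if not pd.isna(scaf["par_start"]):
                in_par = (mid >= scaf["par_start"]) & (mid < scaf["par_end"])
            female_cn = np.where(in_par, 2.0, 1.0)
        else:
            female_cn = np.full(len(starts), 2.0)
        block = {"scaffold": scaf["scaffold"], "start": starts, "end": ends}
        for _, s in samples.iterrows():
            cn = female_cn if s["sex"] == "F" else 2.0
            mean = config.mean_depth * cn / 2.0
            block[s["sample"]] = _nb_draw(rng, np.broadcast_to(
                np.asarray(mean, dtype=float), starts.shape), config.depth_dispersion)
        frames.append(pd.DataFrame(block))
    windows = pd.concat(frames, ignore_index=True)
    return WindowDepthProfile(windows=windows, samples=samples)


def scaffold_read_counts(profile: WindowDepthProfile,
                         layout: GenomeLayout) -> pd.DataFrame:
    """Aggregate window depths into a per-scaffold mapped-count summary.

    Returns the long table (scaffold, length, sample, sex, count) used for
    female/male depth-ratio screening.
    """
    lengths = layout.scaffold_lengths()
    sample_ids = list(profile.samples["sample"])
    sums = profile.windows.groupby("scaffold")[sample_ids].sum()
    rows = []
    sex_of = profile.samples.set_index("sample")["sex"]
    for scaffold, row in sums.iterrows():
        for sample in sample_ids:
            rows.append((scaffold, int(lengths[scaffold]), sample,
                         sex_of[sample], int(row[sample])))
    return pd.DataFrame(rows, columns=["scaffold", "length", "sample", "sex", "count"])


def _positions(rng, length: int, n: int, lo: int = 0) -> np.ndarray:
    """n distinct 1-based positions in (lo, length]."""
    if n <= 0:
        return np.array([], dtype=int)
    draw = rng.integers(lo + 1, length + 1, size=int(n * 1.2) + 8)
    pos = np.unique(draw)
    while len(pos) < n:
        extra = rng.integers(lo + 1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


# Values assigned to quality fields; "fail" values violate the default
# hard filters (MQ >= 30, QD > 2, DP >= 10, GQ >= 30).
_QC = {"mq": (60.0, 20.0), "qd": (25.0, 1.0), "dp": (30, 5), "gq": (99, 15)}


def simulate_genotypes(layout: GenomeLayout, config: SimulationConfig) -> pd.DataFrame:
    """Variant-site genotype calls with the female W-mismapping artifact.

    Two site populations: *true* variants (density ``site_density``) where
    diploid samples are het/hom-alt at background rates and hemizygous
    females on non-PAR Z are never het; and *artifact* sites (non-PAR Z
    only, density ``artifact_site_density``) where mismapped W reads make
    females appear heterozygous with probability ``mismap_het_rate``.
    Returns a long table (scaffold, pos, mq, qd, sample, sex, gt, dp, gq);
    positions are 1-based.
    """
    rng = config.rng("genotypes")
    samples = config.sample_table()
    out = []
    for _, scaf in layout.scaffolds.iterrows():
        name, length, cls = scaf["scaffold"], int(scaf["length"]), scaf["cls"]
        par = (None if pd.isna(scaf["par_start"])
               else (int(scaf["par_start"]), int(scaf["par_end"])))
        n_true = int(round(length * config.site_density))
        pos_true = _positions(rng, length, n_true)
        pos_art = np.array([], dtype=int)
        if cls == "Z":
            nonpar_len = length - (0 if par is None else par[1] - par[0])
            n_art = int(round(nonpar_len * config.artifact_site_density))
            # artifact sites live outside the PAR (assumes PAR at an end)
            if par is not None and par[0] == 0:
                pos_art = _positions(rng, length, n_art, lo=par[1])
            else:
                pos_art = _positions(rng, length, n_art)
        pos = np.concatenate([pos_true, pos_art])
        is_artifact = np.zeros(len(pos), dtype=bool)
        is_artifact[len(pos_true):] = True
        order = np.argsort(pos, kind="stable")
        pos, is_artifact = pos[order], is_artifact[order]
        in_par = np.zeros(len(pos), dtype=bool)
        if par is not None:
            in_par = (pos - 1 >= par[0]) & (pos - 1 < par[1])

        mq = np.where(rng.random(len(pos)) < config.qc_fail_frac, _QC["mq"][1], _QC["mq"][0])
        qd = np.where(rng.random(len(pos)) < config.qc_fail_frac, _QC["qd"][1], _QC["qd"][0])

        hemi = (cls == "Z") & ~in_par  # hemizygous region in females
        for _, s in samples.iterrows():
            u = rng.random(len(pos))
            gt = np.where(u < config.background_het, "het",
                          np.where(u < config.background_het + config.background_hom_alt,
                                   "hom_alt", "hom_ref"))
            if s["sex"] == "F":
                # single Z: true sites are hom; artifact sites het w.p. mismap rate
                u2 = rng.random(len(pos))
                female_true = np.where(u2 < 0.5, "hom_alt", "hom_ref")
                u3 = rng.random(len(pos))
                female_art = np.where(u3 < config.mismap_het_rate, "het", "hom_ref")
                gt = np.where(hemi & ~is_artifact, female_true, gt)
                gt = np.where(hemi & is_artifact, female_art, gt)
            else:
                gt = np.where(hemi & is_artifact, "hom_ref", gt)
            dp_base = np.where(hemi & (s["sex"] == "F"), _QC["dp"][0] // 2, _QC["dp"][0])
            dp = np.where(rng.random(len(pos)) < config.qc_fail_frac, _QC["dp"][1], dp_base)
            gq = np.where(rng.random(len(pos)) < config.qc_fail_frac, _QC["gq"][1], _QC["gq"][0])
            out.append(pd.DataFrame({
                "scaffold": name, "pos": pos, "mq": mq, "qd": qd,
                "sample": s["sample"], "sex": s["sex"],
                "gt": gt, "dp": dp.astype(int), "gq": gq.astype(int),
            }))
    table = pd.concat(out, ignore_index=True)
    return table.sort_values(["scaffold", "pos", "sample"], kind="stable",
                             ignore_index=True)


def _sex_factors(linkage: np.ndarray, config: SimulationConfig,
                 rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-transcript expected expression multipliers (female, male).

    Returns (female factor, male factor, compensated flag) on Z non-PAR
    transcripts; autosomal and PAR transcripts are unaffected by regime.
    """
    n = len(linkage)
    f = np.ones(n)
    m = np.ones(n)
    comp = np.zeros(n, dtype=bool)
    on_z = linkage == "Z"
    if config.regime == "no_compensation":
        f[on_z] = 0.5
    elif config.regime == "complete_compensation":
        comp[on_z] = True
    elif config.regime == "incomplete_compensation":
        comp_draw = rng.random(n) < config.compensated_fraction
        comp[on_z] = comp_draw[on_z]
        f[on_z & ~comp] = 0.5
    elif config.regime == "complete_balance":
        f[on_z] = config.balance_level
        m[on_z] = config.balance_level
    return f, m, comp


def simulate_expression(layout: GenomeLayout, config: SimulationConfig):
    """FPKM matrix, outgroup (ancestral) means and truth table.

    FPKM = mu_g * regime factor * individual effect * residual noise with
    all multiplicative terms lognormal.  Ancestral expression is mu_g with
    independent per-sex noise, so divergence from relative ancestral
    expression is exactly the regime's sex factor.
    """
    config.validate()
    rng = config.rng("expression")
    samples = config.sample_table().set_index("sample")
    tr = layout.transcripts
    n = len(tr)
    mu = config.baseline_fpkm * rng.lognormal(0.0, config.expression_mu_logsd, size=n)
    f_fac, m_fac, comp = _sex_factors(tr["linkage"].to_numpy(), config, rng)
    # FPKM is per-library normalized, which removes global per-sample scale
    # factors; emulate that by centering individual effects (geometric mean 1
    # within each sex) so sex-mean ratios stay unbiased at any sample size.
    indiv = rng.lognormal(0.0, config.individual_sd, size=len(samples))
    sexes = samples["sex"].to_numpy()
    for sex in ("F", "M"):
        grp = sexes == sex
        if grp.any():
            indiv[grp] /= np.exp(np.mean(np.log(indiv[grp])))

    cols = {}
    for j, (sample, row) in enumerate(samples.iterrows()):
        fac = f_fac if row["sex"] == "F" else m_fac
        noise = rng.lognormal(0.0, config.residual_sd, size=n)
        cols[sample] = mu * fac * indiv[j] * noise
    fpkm = pd.DataFrame(cols, index=tr["transcript"].to_numpy())
    fpkm.index.name = "transcript"

    orthologs = "og_" + tr["transcript"]
    tmeta = pd.DataFrame({
        "scaffold": tr["scaffold"].to_numpy(),
        "linkage": tr["linkage"].to_numpy(),
        "ortholog": orthologs.to_numpy(),
    }, index=fpkm.index)
    anc = pd.DataFrame({
        "anc_male": mu * rng.lognormal(0.0, config.anc_noise_sd, size=n),
        "anc_female": mu * rng.lognormal(0.0, config.anc_noise_sd, size=n),
    }, index=pd.Index(orthologs.to_numpy(), name="ortholog"))

    expr = ExpressionMatrix(fpkm=fpkm, transcripts=tmeta, samples=samples)

    on_z = tr["linkage"].to_numpy() == "Z"
    beta = {
        "no_compensation": 1.0,
        "complete_compensation": 0.0,
        "incomplete_compensation": 1.0 - config.compensated_fraction,
        "complete_balance": 0.0,
    }[config.regime]
    truth = TruthTable(
        scaffold_class=dict(zip(layout.scaffolds["scaffold"], layout.scaffolds["cls"])),
        par_boundaries={s: int(e) for s, e in
                        zip(layout.scaffolds["scaffold"], layout.scaffolds["par_end"])
                        if not np.isnan(e)},
        gene_compensated=dict(zip(tr["transcript"].to_numpy()[on_z], comp[on_z])),
        true_interaction_beta=beta,
        regime=config.regime,
    )
    return expr, anc, truth


def simulate_counts(expr: ExpressionMatrix, config: SimulationConfig,
                    transcript_lengths: Optional[pd.Series] = None) -> CountMatrix:
    """Integer read counts with biological CV ``bcv_true``.

    The expected count of transcript g in sample j is its sex-mean FPKM *
    transcript kb * library size / 1e6; counts are NB with dispersion
    bcv_true**2 (Poisson when bcv_true = 0).  Anchoring the mean at the
    sex-level expectation rather than the noisy per-sample FPKM makes
    bcv_true the *total* biological CV of the counts instead of stacking
    on top of the FPKM matrix's own residual noise.
    """
    if (expr.fpkm.to_numpy() < 0).any():
        raise ValueError("FPKM must be non-negative")
    rng = config.rng("counts")
    n_samples = expr.fpkm.shape[1]
    lib = config.library_size * rng.lognormal(0.0, 0.05, size=n_samples)
    lib_sizes = pd.Series(lib, index=expr.fpkm.columns, name="lib_size")
    if transcript_lengths is None:
        kb = config.transcript_length / 1000.0
        kb = pd.Series(kb, index=expr.fpkm.index)
    else:
        kb = transcript_lengths.reindex(expr.fpkm.index) / 1000.0
    sex_means = expr.sex_means()
    expected = pd.DataFrame(
        {s: sex_means[expr.samples.loc[s, "sex"]] for s in expr.fpkm.columns},
        index=expr.fpkm.index)
    mean = expected.mul(kb, axis=0).mul(lib_sizes / 1e6, axis=1)
    counts = pd.DataFrame(
        _nb_draw(rng, mean.to_numpy(), config.bcv_true ** 2),
        index=expr.fpkm.index, columns=expr.fpkm.columns)
    return CountMatrix(counts=counts, lib_sizes=lib_sizes, samples=expr.samples.copy())


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    if d.get("scaffold_lengths") is not None:
        d["scaffold_lengths"] = list(d["scaffold_lengths"])
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    cfg = SimulationConfig(**d)
    cfg.validate()
    return cfg
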