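"""Generator behaviour: determinism, copy-number signal, regime geometry."""

import numpy as np
import pandas as pd
import pytest

import zwdosage as z
from zwdosage.simulate import ConfigurationError

from conftest import expression_config


class TestLayout:
    def test_degenerate_no_par(self):
        cfg = z.SimulationConfig(n_autosomes=1, n_z_scaffolds=1, par_length=0)
        layout = z.simulate_genome_layout(cfg)
        assert len(layout.scaffolds) == 2
        assert layout.scaffolds["par_start"].isna().all()
        assert (layout.transcripts["linkage"] != "PAR").all()

    def test_par_interval_on_single_z(self):
        layout = z.simulate_genome_layout(z.SimulationConfig())
        hosts = layout.scaffolds.dropna(subset=["par_start"])
        assert list(hosts["scaffold"]) == ["Z1"]
        assert layout.par_interval("Z1") == (0, 1_750_000)

    def test_par_longer_than_host_rejected(self):
        cfg = z.SimulationConfig(par_host_length=1_000_000, par_length=1_000_000)
        with pytest.raises(ConfigurationError):
            z.simulate_genome_layout(cfg)

    def test_transcripts_within_bounds_and_disjoint(self):
        layout = z.simulate_genome_layout(z.SimulationConfig())
        lengths = layout.scaffold_lengths()
        tr = layout.transcripts
        assert (tr["start"] >= 0).all()
        assert (tr["end"] <= tr["scaffold"].map(lengths)).all()
        for _, grp in tr.groupby("scaffold"):
            g = grp.sort_values("start")
            assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()

    def test_seed_determinism_byte_identical(self):
        cfg = z.SimulationConfig(seed=42)
        a = z.simulate_genome_layout(cfg).to_bytes()
        b = z.simulate_genome_layout(cfg).to_bytes()
        assert a == b


class TestDepth:
    def test_poisson_limit_window_means(self):
        cfg = z.SimulationConfig(seed=0, n_autosomes=1, n_z_scaffolds=1,
                                 par_length=0, autosome_length=5_000_000,
                                 z_length=5_000_000, depth_dispersion=0.0)
        layout = z.simulate_genome_layout(cfg)
        prof = z.simulate_depth_windows(layout, cfg)
        w = prof.windows
        se = np.sqrt(cfg.mean_depth / 1000)
        auto = w[w["scaffold"] == "A1"]
        for s in prof.samples["sample"]:
            assert abs(auto[s].mean() - cfg.mean_depth) < 3 * se
        on_z = w[w["scaffold"] == "Z1"]
        for _, srow in prof.samples.iterrows():
            target = cfg.mean_depth / 2 if srow["sex"] == "F" else cfg.mean_depth
            assert abs(on_z[srow["sample"]].mean() - target) < 3 * se

    def test_z_depth_ratio_near_half(self, default_genome):
        _, _, _, summary, _ = default_genome
        ratios = z.scaffold_fm_depth_ratio(summary)
        for scaf in ("Z2", "Z3", "Z4"):  # fully Z-linked (no PAR)
            assert 0.45 <= ratios.loc[scaf, "fm_ratio"] <= 0.55

    def test_depth_determinism(self):
        cfg = z.SimulationConfig(seed=3, n_autosomes=1, n_z_scaffolds=1)
        layout = z.simulate_genome_layout(cfg)
        a = z.simulate_depth_windows(layout, cfg).windows
        b = z.simulate_depth_windows(layout, cfg).windows
        pd.testing.assert_frame_equal(a, b)


class TestGenotypes:
    def test_no_artifact_means_no_female_z_hets(self):
        cfg = z.SimulationConfig(seed=4, n_autosomes=1, n_z_scaffolds=1,
                                 par_length=0, mismap_het_rate=0.0)
        layout = z.simulate_genome_layout(cfg)
        gt = z.simulate_genotypes(layout, cfg)
        f_on_z = gt[(gt["scaffold"] == "Z1") & (gt["sex"] == "F")]
        assert (f_on_z["gt"] != "het").all()

    def test_female_het_excess_in_paper_band(self, genome_het):
        hs = genome_het.per_sex.set_index(["scaffold", "sex"])["het_per_bp"]
        for scaf in ("Z2", "Z3", "Z4"):
            ratio = hs[(scaf, "F")] / hs[(scaf, "M")]
            assert 13 <= ratio <= 35

    def test_autosomal_heterozygosity_sex_symmetric(self, genome_het):
        hs = genome_het.per_sex.set_index(["scaffold", "sex"])["het_per_bp"]
        for scaf in ("A1", "A2"):
            assert 0.8 <= hs[(scaf, "F")] / hs[(scaf, "M")] <= 1.2


class TestExpression:
    @pytest.mark.parametrize("regime,expected", [
        ("complete_compensation", 0.0),
        ("no_compensation", -1.0),
    ])
    def test_regime_median_log2_ratio(self, regime, expected):
        cfg = expression_config(seed=1, regime=regime)
        layout = z.simulate_genome_layout(cfg)
        expr, _, _ = z.simulate_expression(layout, cfg)
        means = expr.sex_means()
        on_z = expr.transcripts["linkage"] == "Z"
        med = float(np.log2(means.loc[on_z, "F"] / means.loc[on_z, "M"]).median())
        assert abs(med - expected) <= 0.05

    def test_incomplete_fraction_matches_truth(self):
        cfg = expression_config(seed=6, regime="incomplete_compensation")
        layout = z.simulate_genome_layout(cfg)
        expr, _, truth = z.simulate_expression(layout, cfg)
        means = expr.sex_means()
        on_z = expr.transcripts["linkage"] == "Z"
        ratios = np.log2(means.loc[on_z, "F"] / means.loc[on_z, "M"])
        frac = float((ratios > -0.25).mean())
        assert abs(frac - 0.5) <= 0.1
        # per-gene recount at the midpoint between the two clusters agrees
        # with the truth table for nearly every transcript
        labels = pd.Series(truth.gene_compensated)
        agree = ((ratios.loc[labels.index] > -0.5) == labels).mean()
        assert agree >= 0.85

    def test_truth_table_labels_only_nonpar_z(self):
        cfg = z.SimulationConfig(seed=2, transcripts_per_scaffold=30)
        layout = z.simulate_genome_layout(cfg)
        _, _, truth = z.simulate_expression(layout, cfg)
        on_z = set(layout.transcripts.loc[layout.transcripts["linkage"] == "Z",
                                          "transcript"])
        assert set(truth.gene_compensated) == on_z
        assert truth.par_boundaries == {"Z1": 1_750_000}

    def test_autosome_and_par_unaffected_by_regime(self):
        cfg = z.SimulationConfig(seed=9, regime="no_compensation",
                                 transcripts_per_scaffold=60)
        layout = z.simulate_genome_layout(cfg)
        expr, _, _ = z.simulate_expression(layout, cfg)
        means = expr.sex_means()
        for link in ("A", "PAR"):
            sel = expr.transcripts["linkage"] == link
            med = float(np.log2(means.loc[sel, "F"] / means.loc[sel, "M"]).median())
            assert abs(med) < 0.15

    def test_expression_determinism(self):
        cfg = expression_config(seed=8, regime="incomplete_compensation",
                                n_z_transcripts=50, n_a_transcripts=50)
        layout = z.simulate_genome_layout(cfg)
        a, anc_a, _ = z.simulate_expression(layout, cfg)
        b, anc_b, _ = z.simulate_expression(layout, cfg)
        pd.testing.assert_frame_equal(a.fpkm, b.fpkm)
        pd.testing.assert_frame_equal(anc_a, anc_b)


class TestCounts:
    def test_poisson_limit_variance_mean_ratio(self):
        cfg = expression_config(seed=3, regime="complete_compensation",
                                n_z_transcripts=500, n_a_transcripts=500,
                                bcv_true=0.0)
        layout = z.simulate_genome_layout(cfg)
        expr, _, _ = z.simulate_expression(layout, cfg)
        cm = z.simulate_counts(expr, cfg)
        males = [s for s in cm.counts.columns if cm.samples.loc[s, "sex"] == "M"]
        adj = cm.counts[males].div(cm.lib_sizes[males] / cm.lib_sizes[males].mean())
        high = adj[adj.mean(axis=1) > 50]
        vmr = (high.var(axis=1) / high.mean(axis=1)).mean()
        assert abs(vmr - 1.0) <= 0.1

    def test_count_cv_matches_bcv_true(self):
        cfg = expression_config(seed=2, regime="complete_compensation",
                                n_z_transcripts=500, n_a_transcripts=500,
                                bcv_true=0.4, n_males=40, n_females=40)
        layout = z.simulate_genome_layout(cfg)
        expr, _, _ = z.simulate_expression(layout, cfg)
        cm = z.simulate_counts(expr, cfg)
        males = [s for s in cm.counts.columns if cm.samples.loc[s, "sex"] == "M"]
        adj = cm.counts[males].div(cm.lib_sizes[males] / cm.lib_sizes[males].mean())
        high = adj[adj.mean(axis=1) > 200]
        cv = float((high.std(axis=1) / high.mean(axis=1)).median())
        assert abs(cv - 0.4) <= 0.05

    def test_zero_fpkm_gives_zero_counts(self):
        cfg = expression_config(seed=5, regime="complete_compensation",
                                n_z_transcripts=20, n_a_transcripts=20)
        layout = z.simulate_genome_layout(cfg)
        expr, _, _ = z.simulate_expression(layout, cfg)
        expr.fpkm.iloc[0, :] = 0.0
        cm = z.simulate_counts(expr, cfg)
        assert (cm.counts.iloc[0] == 0).all()
        assert np.issubdtype(cm.counts.to_numpy().dtype, np.integer)
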