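"""Variant filtering, depth/heterozygosity screens and Z/A theory."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import zwdosage as z
from zwdosage.sexlinkage import (CandidateThresholds, HetRateSummary,
                                 VariantFilterThresholds)


def geno_row(scaffold="S1", pos=100, mq=60.0, qd=25.0, sample="M1", sex="M",
             gt="het", dp=30, gq=99):
    return dict(scaffold=scaffold, pos=pos, mq=mq, qd=qd, sample=sample,
                sex=sex, gt=gt, dp=dp, gq=gq)


class TestVariantFilters:
    def test_low_mq_removes_whole_site(self):
        df = pd.DataFrame([geno_row(pos=1, mq=29.0),
                           geno_row(pos=1, mq=29.0, sample="F1", sex="F"),
                           geno_row(pos=2)])
        res = z.apply_variant_filters(df)
        assert res.n_sites_removed == 1
        assert set(res.table["pos"]) == {2}

    def test_low_dp_masks_single_genotype(self):
        df = pd.DataFrame([geno_row(pos=1, dp=9),
                           geno_row(pos=1, sample="F1", sex="F")])
        res = z.apply_variant_filters(df)
        assert res.n_genotypes_masked == 1
        by_sample = res.table.set_index("sample")["gt"]
        assert by_sample["M1"] == "missing" and by_sample["F1"] == "het"

    def test_boundary_values_pass(self):
        # MQ >= 30 inclusive, QD > 2 strict, DP >= 10, GQ >= 30
        df = pd.DataFrame([geno_row(pos=1, mq=30.0, qd=2.0),
                           geno_row(pos=2, mq=30.0, qd=2.01, dp=10, gq=30)])
        res = z.apply_variant_filters(df)
        assert set(res.table["pos"]) == {2}
        assert (res.table["gt"] == "het").all()

    def test_hand_enumerated_survivors(self):
        rows = []
        # sites 1-3 fail MQ, QD, both; 4-10 pass site filters;
        # site 4 has one DP failure, site 5 one GQ failure
        rows.append(geno_row(pos=1, mq=20.0))
        rows.append(geno_row(pos=2, qd=1.0))
        rows.append(geno_row(pos=3, mq=10.0, qd=0.5))
        for pos in range(4, 11):
            rows.append(geno_row(pos=pos, dp=9 if pos == 4 else 30,
                                 gq=15 if pos == 5 else 99))
        res = z.apply_variant_filters(pd.DataFrame(rows))
        assert res.n_sites_in == 10
        assert res.n_sites_removed == 3
        assert res.n_genotypes_masked == 2
        assert len(res.table) == 7

    def test_missing_info_policy(self):
        df = pd.DataFrame([geno_row(pos=1, mq=np.nan)])
        with pytest.raises(ValueError, match="missing INFO"):
            z.apply_variant_filters(df)
        res = z.apply_variant_filters(df, policy="lenient")
        assert len(res.table) == 1


class TestDepthRatio:
    def make_summary(self, f_count, m_count, length=1000):
        return pd.DataFrame([
            {"scaffold": "S1", "length": length, "sample": "F1", "sex": "F",
             "count": f_count},
            {"scaffold": "S1", "length": length, "sample": "M1", "sex": "M",
             "count": m_count}])

    def test_equal_counts_unit_ratio(self):
        r = z.scaffold_fm_depth_ratio(self.make_summary(500, 500))
        assert r.loc["S1", "fm_ratio"] == pytest.approx(1.0)

    def test_half_counts_half_ratio(self):
        r = z.scaffold_fm_depth_ratio(self.make_summary(250, 500))
        assert r.loc["S1", "fm_ratio"] == pytest.approx(0.5)

    def test_zero_male_mean_flagged(self):
        r = z.scaffold_fm_depth_ratio(self.make_summary(250, 0))
        assert not r.loc["S1", "defined"]
        assert np.isnan(r.loc["S1", "fm_ratio"])

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        base = self.make_summary(300, 600)
        scaled = base.assign(count=base["count"] * scale)
        r0 = z.scaffold_fm_depth_ratio(base).loc["S1", "fm_ratio"]
        r1 = z.scaffold_fm_depth_ratio(scaled).loc["S1", "fm_ratio"]
        assert r1 == pytest.approx(r0, rel=1e-12)


class TestHetRate:
    def table_of(self, gts, sample="M1", sex="M"):
        return pd.DataFrame([geno_row(pos=i + 1, gt=g, sample=sample, sex=sex)
                             for i, g in enumerate(gts)])

    def test_direct_count(self):
        df = self.table_of(["het"] * 3 + ["hom_alt"] * 2 + ["hom_ref"] * 4)
        res = z.het_rate(df, {"S1": 1000})
        row = res.per_sample.iloc[0]
        assert row["het_rate"] == pytest.approx(0.6)
        assert row["n_nonref"] == 5

    def test_all_hom_alt_rate_zero_and_all_het_rate_one(self):
        r0 = z.het_rate(self.table_of(["hom_alt"] * 4), {"S1": 1000})
        assert r0.per_sample.iloc[0]["het_rate"] == 0.0
        r1 = z.het_rate(self.table_of(["het"] * 4), {"S1": 1000})
        assert r1.per_sample.iloc[0]["het_rate"] == 1.0

    def test_no_nonref_sites_flagged_undefined(self):
        res = z.het_rate(self.table_of(["hom_ref"] * 5), {"S1": 1000})
        row = res.per_sample.iloc[0]
        assert not row["defined"] and np.isnan(row["het_rate"])

    def test_missing_genotypes_excluded(self):
        df = self.table_of(["het", "missing", "hom_alt", "missing"])
        row = z.het_rate(df, {"S1": 1000}).per_sample.iloc[0]
        assert row["n_nonref"] == 2 and row["het_rate"] == pytest.approx(0.5)


class TestCandidateZ:
    def _report(self, fm_ratio, f_het, m_het, length, ntr):
        ratios = pd.DataFrame({"female_mean": [1.0], "male_mean": [1.0],
                               "fm_ratio": [fm_ratio], "defined": [True]},
                              index=pd.Index(["S1"], name="scaffold"))
        het = HetRateSummary(
            per_sample=pd.DataFrame({"scaffold": ["S1", "S1"],
                                     "sample": ["F1", "M1"],
                                     "sex": ["F", "M"],
                                     "n_het": [1, 1], "n_nonref": [2, 2],
                                     "het_rate": [0.5, 0.5],
                                     "defined": [True, True]}),
            per_sex=pd.DataFrame({"scaffold": ["S1", "S1"], "sex": ["F", "M"],
                                  "het_per_bp": [f_het, m_het]}))
        return z.call_candidate_z(ratios, het, {"S1": length}, {"S1": ntr})

    def test_short_low_transcript_scaffold_flagged_not_called(self):
        rep = self._report(0.55, 2e-3, 1e-4, length=450_000, ntr=4)
        row = rep.table.loc["S1"]
        assert not row["candidate"]
        assert row["excluded_short"] and row["excluded_few_transcripts"]

    def test_autosome_like_scaffold_not_candidate(self):
        rep = self._report(1.0, 1e-4, 1e-4, length=2_000_000, ntr=50)
        assert rep.candidates == []
        row = rep.table.loc["S1"]
        assert not (row["excluded_short"] or row["excluded_few_transcripts"])

    def test_simulated_recovery_exact(self, default_genome, genome_het):
        cfg, layout, profile, summary, genotypes = default_genome
        ratios = z.scaffold_fm_depth_ratio(summary)
        ntr = layout.transcripts.groupby("scaffold").size().to_dict()
        rep = z.call_candidate_z(ratios, genome_het,
                                 layout.scaffold_lengths().to_dict(), ntr)
        assert sorted(rep.candidates) == ["Z1", "Z2", "Z3", "Z4"]

    def test_missing_het_data_indeterminate(self):
        ratios = pd.DataFrame({"female_mean": [1.0], "male_mean": [1.0],
                               "fm_ratio": [0.5], "defined": [True]},
                              index=pd.Index(["S9"], name="scaffold"))
        het = HetRateSummary(per_sample=pd.DataFrame(
            columns=["scaffold", "sample", "sex", "n_het", "n_nonref",
                     "het_rate", "defined"]),
            per_sex=pd.DataFrame(columns=["scaffold", "sex", "het_per_bp"]))
        rep = z.call_candidate_z(ratios, het, {"S9": 1_000_000}, {"S9": 20})
        assert rep.table.loc["S9", "indeterminate"]
        assert not rep.table.loc["S9", "candidate"]


class TestWindowRatios:
    def _profile(self, f, m):
        return pd.DataFrame({"scaffold": "S1",
                             "start": np.arange(len(f)) * 5000,
                             "end": (np.arange(len(f)) + 1) * 5000,
                             "F1": f, "M1": m})

    samples = pd.DataFrame({"sample": ["F1", "M1"], "sex": ["F", "M"]})

    def test_equal_and_halved_depth(self):
        out = z.window_log2_fm(self._profile([30, 15], [30, 30]), self.samples)
        assert out["log2_fm"].to_numpy() == pytest.approx([0.0, -1.0])

    def test_zero_depth_flagged_and_cancelled(self):
        out = z.window_log2_fm(self._profile([0], [0]), self.samples)
        assert out["log2_fm"].iloc[0] == pytest.approx(0.0)
        assert out["zero_depth"].iloc[0]

    def test_sex_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        f, m = rng.poisson(20, 50) + 1, rng.poisson(30, 50) + 1
        fwd = z.window_log2_fm(self._profile(f, m), self.samples)
        swapped = self.samples.assign(sex=["M", "F"])
        rev = z.window_log2_fm(self._profile(f, m), swapped)
        assert rev["log2_fm"].to_numpy() == pytest.approx(
            -fwd["log2_fm"].to_numpy(), abs=1e-9)


class TestZaTheory:
    def test_equal_sex_ratio(self):
        assert z.za_ratio_theory(10, 10) == pytest.approx(0.75)

    def test_female_biased_limit(self):
        assert z.za_ratio_theory(1, 1e9) == pytest.approx(1.125, abs=1e-6)

    def test_grid_max_below_paper_bound(self):
        assert z.za_ratio_max() < 1.2

    @given(c=st.floats(min_value=1e-3, max_value=1e3),
           nm=st.floats(min_value=0.1, max_value=100),
           nf=st.floats(min_value=0.1, max_value=100))
    def test_scale_invariance(self, c, nm, nf):
        assert z.za_ratio_theory(c * nm, c * nf) == pytest.approx(
            z.za_ratio_theory(nm, nf), rel=1e-9)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            z.za_ratio_theory(0, 5)


class TestObservedZa:
    def _het(self, z_val, a_val, sex="M"):
        return HetRateSummary(
            per_sample=pd.DataFrame(),
            per_sex=pd.DataFrame({"scaffold": ["Z1", "A1"], "sex": [sex, sex],
                                  "het_per_bp": [z_val, a_val]}))

    def test_equal_and_double(self):
        assert z.observed_za_diversity(self._het(1e-4, 1e-4), "Z1", "A1", "M") == 1.0
        assert z.observed_za_diversity(self._het(2e-4, 1e-4), "Z1", "A1", "M") == 2.0

    def test_zero_autosomal_undefined(self):
        with pytest.warns(UserWarning):
            out = z.observed_za_diversity(self._het(1e-4, 0.0), "Z1", "A1", "M")
        assert np.isnan(out)

    def test_artifact_fixture_female_excess(self, genome_het):
        male = z.observed_za_diversity(genome_het, "Z2", "A1", "M")
        female = z.observed_za_diversity(genome_het, "Z2", "A1", "F")
        assert 0.8 <= male <= 1.2
        assert female > 5 * male
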