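"""Mixed-model fitting: OLS reduction, symmetry, AICc, and an lme4 oracle."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import zwdosage as z
from zwdosage.dosage import build_lmm_data, filter_expressed
from zwdosage.lmm import (INTERACTION, LmmSpec, ModelFitResult, aicc,
                          fit_lmm, fit_lmm_set, select_models, selection_table,
                          _fit_balanced, _fit_general)

from conftest import expression_config


def balanced_frame(n_tr=20, n_ind=6, beta=(1.0, 0.3, -0.5, 0.8), noise=0.1,
                   tr_sd=0.0, ind_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    transcripts = [f"t{i}" for i in range(n_tr)]
    individuals = [f"M{i}" for i in range(n_ind // 2)] + \
                  [f"F{i}" for i in range(n_ind - n_ind // 2)]
    z_of = {t: int(i >= n_tr // 2) for i, t in enumerate(transcripts)}
    sex_of = {s: int(s.startswith("M")) for s in individuals}
    u_t = dict(zip(transcripts, rng.normal(0, tr_sd, n_tr)))
    u_i = dict(zip(individuals, rng.normal(0, ind_sd, n_ind)))
    rows = []
    for t in transcripts:
        for s in individuals:
            x = (1.0, sex_of[s], z_of[t], sex_of[s] * z_of[t])
            y = sum(b * v for b, v in zip(beta, x)) + u_t[t] + u_i[s] \
                + rng.normal(0, noise)
            rows.append({"y": y, "sex_male": sex_of[s], "z_linked": z_of[t],
                         "transcript": t, "individual": s})
    return pd.DataFrame(rows)


def diff_in_diff(data):
    cells = data.groupby(["sex_male", "z_linked"])["y"].mean()
    return cells[1, 1] - cells[1, 0] - cells[0, 1] + cells[0, 0]


class TestFitLmm:
    def test_zero_variance_reduces_to_cell_mean_contrast(self):
        data = balanced_frame()
        fit = fit_lmm(data, LmmSpec("balance", "full"))
        assert fit.params[INTERACTION] == pytest.approx(diff_in_diff(data),
                                                        abs=1e-6)
        assert fit.method == "balanced-eigen"

    def test_sex_label_swap_negates_interaction(self):
        data = balanced_frame(tr_sd=0.5, ind_sd=0.2, seed=3)
        fit = fit_lmm(data, LmmSpec("balance", "full"))
        swapped = data.assign(sex_male=1 - data["sex_male"])
        fit2 = fit_lmm(swapped, LmmSpec("balance", "full"))
        assert fit2.params[INTERACTION] == pytest.approx(
            -fit.params[INTERACTION], abs=1e-6)

    def test_variance_components_recovered(self):
        data = balanced_frame(n_tr=400, n_ind=40, tr_sd=1.0, ind_sd=0.5,
                              noise=0.3, seed=5)
        fit = fit_lmm(data, LmmSpec("balance", "full"))
        assert fit.vc["transcript"] == pytest.approx(1.0, abs=0.2)
        assert fit.vc["individual"] == pytest.approx(0.25, abs=0.15)
        assert fit.vc["residual"] == pytest.approx(0.09, abs=0.02)

    def test_general_route_agrees_with_eigen_route(self):
        data = balanced_frame(tr_sd=0.5, ind_sd=0.2, noise=0.2, seed=9)
        spec = LmmSpec("balance", "full")
        a = _fit_balanced(data, spec)
        b = _fit_general(data, spec)
        assert b.loglik == pytest.approx(a.loglik, abs=1e-4)
        for term in a.params:
            assert b.params[term] == pytest.approx(a.params[term], abs=1e-5)

    def test_unbalanced_data_uses_general_route(self):
        data = balanced_frame(tr_sd=0.4, seed=2).iloc[:-1]
        fit = fit_lmm(data, LmmSpec("balance", "full"))
        assert fit.method == "woodbury"
        assert np.isfinite(fit.loglik)

    def test_confounded_ancestral_grouping_flagged(self):
        data = balanced_frame(tr_sd=0.4, seed=4)
        data["anc_group"] = data["transcript"].astype("category").cat.codes
        fit = fit_lmm(data, LmmSpec("compensation", "full"))
        assert "anc_confounded_with_transcript" in fit.flags
        assert fit.vc["anc_group"] == 0.0
        assert fit.k == 4 + 3 + 1

    def test_missing_columns_rejected(self):
        data = balanced_frame().drop(columns="individual")
        with pytest.raises(ValueError, match="individual"):
            fit_lmm(data, LmmSpec("balance", "full"))


class TestAicc:
    def test_matches_formula_and_reduces_to_aic(self):
        ll, k = -1234.5, 7
        n = 100
        assert aicc(ll, k, n) == pytest.approx(
            -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1))
        aic = -2 * ll + 2 * k
        assert abs(aicc(ll, k, 100_000) - aic) < 0.01

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    def test_penalty_orders_equal_likelihood_models(self):
        def fake(k):
            return ModelFitResult(spec=LmmSpec("balance", "full"), params={},
                                  se={}, pvalues={}, vc={}, loglik=-100.0,
                                  k=k, nobs=500, aicc=aicc(-100.0, k, 500),
                                  converged=True, method="synthetic")
        ranked = select_models([fake(4), fake(3)])
        assert ranked[0].k == 3

    def test_weights_sum_to_one(self):
        data = balanced_frame(tr_sd=0.5, seed=1)
        ranked = select_models(fit_lmm_set(data, "balance"))
        assert sum(f.weight for f in ranked) == pytest.approx(1.0, abs=1e-12)
        assert ranked[0].delta_aicc == 0.0


@pytest.fixture(scope="module")
def nocomp_fits(nocomp_expression):
    _, expr, anc, truth = nocomp_expression
    data = build_lmm_data(filter_expressed(expr).expr, normalize="log2")
    return select_models(fit_lmm_set(data, "balance")), truth


class TestSimulatedRecovery:
    def test_full_model_wins_without_compensation(self, nocomp_fits):
        ranked, _ = nocomp_fits
        assert ranked[0].spec.fixed == "full"
        null = next(f for f in ranked if f.spec.fixed == "null")
        assert null.delta_aicc > 2

    def test_interaction_beta_covers_truth(self, nocomp_fits):
        ranked, truth = nocomp_fits
        best = ranked[0]
        beta, se = best.params[INTERACTION], best.se[INTERACTION]
        assert beta > 0
        assert abs(beta - truth.true_interaction_beta) <= 2 * se

    def test_compensated_regime_interaction_near_zero(self):
        cfg = expression_config(seed=4, regime="complete_compensation")
        layout = z.simulate_genome_layout(cfg)
        expr, _, truth = z.simulate_expression(layout, cfg)
        data = build_lmm_data(filter_expressed(expr).expr, normalize="log2")
        fit = fit_lmm(data, LmmSpec("balance", "full"))
        assert abs(fit.params[INTERACTION] - 0.0) <= 2 * fit.se[INTERACTION]

    def test_selection_table_columns(self, nocomp_fits):
        ranked, _ = nocomp_fits
        table = selection_table(ranked)
        assert list(table.columns) == ["model", "intercept", "delta_aicc", "weight"]
        assert table["delta_aicc"].iloc[0] == 0.0


class TestAgainstLme4:
    def test_ml_fit_matches_lme4(self, tmp_path):
        cfg = expression_config(seed=9, regime="no_compensation",
                                n_z_transcripts=30, n_a_transcripts=30)
        layout = z.simulate_genome_layout(cfg)
        expr, _, _ = z.simulate_expression(layout, cfg)
        data = build_lmm_data(filter_expressed(expr).expr, normalize="log2")
        fit = fit_lmm(data, LmmSpec("balance", "full"))

        csv = tmp_path / "fixture.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(y ~ sex_male * z_linked + (1|transcript) + (1|individual),
                      data = d, REML = FALSE)
            cat(fixef(m), as.numeric(logLik(m)), sep = "\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        vals = [float(v) for v in out.stdout.split()]
        r_beta, r_loglik = vals[:4], vals[4]
        terms = ["intercept", "sex_male", "z_linked", INTERACTION]
        for term, want in zip(terms, r_beta):
            assert fit.params[term] == pytest.approx(want, abs=1e-4)
        assert fit.loglik == pytest.approx(r_loglik, abs=1e-3)
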