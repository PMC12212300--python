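"""GLMM fit correctness, ICC, odds ratios, classification metrics."""

import json
import math
import subprocess

import numpy as np
import pytest
from scipy.special import expit

from ethnosae import (Codebook, MODELLED_INDICATORS, SeparationError,
                      classification_metrics, combined_or, design_matrix,
                      fit_glmm, fitted_probabilities, icc, icc_bootstrap_ci,
                      laplace_loglik, metrics_from_counts, odds_ratios,
                      published_model, simulate)
from ethnosae.core_data import domain_labels
from ethnosae.model_fit import _laplace_nll

from conftest import make_simple_truth, population_as_survey


class TestLaplaceObjective:
    def test_analytic_gradient_matches_finite_differences(self, small_sim):
        sv = small_sim.survey
        X, _ = design_matrix(sv)
        y = sv["y_use_any"].to_numpy().astype(float)
        keys, g = np.unique(domain_labels(sv).to_numpy(),
                            return_inverse=True)
        G = len(keys)
        w = np.ones(len(y))
        rng = np.random.default_rng(0)
        theta = np.concatenate([rng.normal(0, 0.3, X.shape[1]),
                                [np.log(0.4)]])
        _, grad = _laplace_nll(theta, X, y, g, G, w, np.zeros(G))
        for j in [0, 3, X.shape[1] - 1, X.shape[1]]:
            h = 1e-6 * max(1, abs(theta[j]))
            tp = theta.copy(); tp[j] += h
            tm = theta.copy(); tm[j] -= h
            fp, _ = _laplace_nll(tp, X, y, g, G, w, np.zeros(G))
            fm, _ = _laplace_nll(tm, X, y, g, G, w, np.zeros(G))
            assert abs((fp - fm) / (2 * h) - grad[j]) < 1e-4 * (1 + abs(grad[j]))


class TestFitGlmm:
    def test_null_truth_recovers_zero(self):
        params = make_simple_truth(n_states=6, rows_per_state=3400,
                                   sigma=0.0, seed=7)
        for ind in MODELLED_INDICATORS:
            params.beta[ind] = {k: 0.0 for k in params.beta[ind]}
        sim = simulate(params, fractions=1.0, seed=7)
        m = fit_glmm(population_as_survey(sim.population), "use_any",
                     params.codebook)
        assert m.converged
        assert np.all(np.abs(m.beta) < 3 * m.se)
        assert m.sigma_v < 0.05
        # with no between-domain variance, predicted intercepts shrink to ~0
        assert max(abs(v) for v in m.v_hat.values()) < 0.1

    def test_single_domain_matches_plain_logistic_irls(self, fixture_sim):
        import statsmodels.api as sm

        sv = fixture_sim.survey
        one = sv[(sv["ethnic_group"] == "nonethnic")
                 & (sv["state"] == 2)].reset_index(drop=True)
        cb = Codebook(("is_mother", "education", "working"))
        m = fit_glmm(one, "use_any", cb)
        X, _ = design_matrix(one, cb)
        oracle = sm.Logit(one["y_use_any"].to_numpy(), X).fit(disp=0)
        assert m.sigma_v < 1e-3
        assert np.allclose(m.beta, oracle.params, atol=1e-4)

    def test_loglik_at_optimum_beats_null_parameters(self, fitted_models,
                                                     fixture_sim):
        m = fitted_models["use_any"]
        p = len(m.beta)
        null_ll = laplace_loglik(m, fixture_sim.survey,
                                 beta=np.zeros(p), sigma_v=0.0)
        assert m.loglik >= null_ll

    def test_complete_separation_raises_naming_covariate(self, small_sim):
        sv = small_sim.survey.copy()
        sv["working"] = sv["y_use_any"]
        with pytest.raises(SeparationError, match="working"):
            fit_glmm(sv, "use_any")

    def test_model_json_roundtrip(self, fitted_models, tmp_path):
        from ethnosae import FittedModel
        m = fitted_models["unmet"]
        path = tmp_path / "m.json"
        m.to_json(path)
        back = FittedModel.from_json(path)
        assert back.names == m.names
        assert np.allclose(back.beta, m.beta)
        assert back.v_hat == m.v_hat
        assert back.sigma_v == m.sigma_v

    def test_glmer_agrees_on_small_fixture(self, tmp_path):
        """lme4::glmer maximizes the same Laplace objective; the two
        independent implementations must land on the same optimum."""
        params = make_simple_truth(n_states=4, rows_per_state=700,
                                   sigma=0.5, seed=13)
        sim = simulate(params, fractions=1.0, seed=13)
        sv = population_as_survey(sim.population)
        cb = params.codebook
        m = fit_glmm(sv, "use_any", cb)
        assert m.converged

        X, names = design_matrix(sv, cb)
        df_cols = {n: X[:, i] for i, n in enumerate(names) if n != "intercept"}
        import pandas as pd
        rdf = pd.DataFrame({"y": sv["y_use_any"].to_numpy(),
                            "domain": domain_labels(sv).to_numpy(), **df_cols})
        csv = tmp_path / "glmm.csv"
        rdf.to_csv(csv, index=False)
        rhs = " + ".join(df_cols)
        rscript = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(y ~ {rhs} + (1 | domain), data = d, family = binomial,
                   nAGQ = 1)
        out <- list(beta = as.numeric(fixef(m)),
                    sigma = as.numeric(attr(VarCorr(m)$domain, "stddev")))
        cat(sprintf('{{"beta": [%s], "sigma": %.10f}}',
            paste(sprintf("%.10f", out$beta), collapse=", "), out$sigma))
        """
        res = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        ref = json.loads(res.stdout.strip())
        assert np.allclose(m.beta, ref["beta"], atol=2e-3)
        assert abs(m.sigma_v - ref["sigma"]) < 1e-2


class TestIcc:
    def test_closed_forms(self):
        assert icc(0.0) == 0.0
        assert icc(math.sqrt(math.pi ** 2 / 3)) == pytest.approx(0.5)
        assert icc(0.3) == pytest.approx(0.09 / (0.09 + math.pi ** 2 / 3),
                                         abs=1e-12)
        assert icc(0.3) == pytest.approx(0.0266, abs=5e-4)

    def test_monotone_in_sigma(self):
        sigmas = np.linspace(0, 3, 40)
        vals = [icc(s) for s in sigmas]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(0 <= v < 1 for v in vals)

    def test_bootstrap_smoke_returns_ordered_triple(self, small_sim):
        boot = icc_bootstrap_ci(small_sim.survey, "use_any", B=2, seed=1,
                                tol=1e-6, compute_se=False)
        assert boot.lower <= boot.mean <= boot.upper

    def test_bootstrap_near_zero_truth_has_low_lower_bound(self):
        params = make_simple_truth(n_states=8, rows_per_state=400,
                                   sigma=0.0, seed=21)
        sim = simulate(params, fractions=1.0, seed=21)
        boot = icc_bootstrap_ci(population_as_survey(sim.population),
                                "use_any", params.codebook, B=30, seed=2,
                                tol=1e-6, compute_se=False)
        assert boot.lower < 0.05

    def test_bootstrap_percentile_interval_covers_known_icc(self):
        """Scaled-down coverage study for the domain-resampling bootstrap.

        Needs enough domains for the variance component to be well
        determined (75 here); with few, small clusters the percentile
        interval inherits the downward bias of sigma_hat and undercovers.
        """
        sigma = 0.5
        true_icc = icc(sigma)
        covered = 0
        n_outer = 20
        for r in range(n_outer):
            params = make_simple_truth(n_states=25, rows_per_state=240,
                                       sigma=sigma, seed=500 + r)
            sim = simulate(params, fractions=1.0, seed=500 + r)
            boot = icc_bootstrap_ci(population_as_survey(sim.population),
                                    "use_any", params.codebook, B=100,
                                    seed=r, tol=1e-5, compute_se=False)
            covered += boot.lower <= true_icc <= boot.upper
        assert covered / n_outer >= 0.85


class TestOddsRatios:
    def test_exp_log_identity(self, fitted_models):
        t = odds_ratios(fitted_models["use_any"])
        assert np.allclose(np.log(t["odds_ratio"]), t["coefficient"],
                           atol=1e-12)

    def test_zero_coefficient_gives_unit_or(self):
        m = published_model("use_any")
        m.beta = np.zeros_like(m.beta)
        assert np.all(odds_ratios(m)["odds_ratio"] == 1.0)

    def test_combined_or_unknown_name_errors(self):
        with pytest.raises(KeyError, match="nonexistent"):
            combined_or(published_model("use_any"), ["nonexistent"])


class TestClassificationMetrics:
    def test_printed_accuracy_formula_on_counts(self):
        m = metrics_from_counts(p11=2, p00=3, p01=1, p10=1)
        assert m["accuracy"] == pytest.approx(5 / 7)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["specificity"] == pytest.approx(3 / 4)

    def test_perfectly_separated_toy_gives_all_ones(self):
        m = metrics_from_counts(p11=5, p00=5, p01=0, p10=0)
        assert all(m[k] == 1.0 for k in
                   ("accuracy", "precision", "sensitivity", "specificity"))

    def test_empty_class_reported_as_none(self):
        m = metrics_from_counts(p11=0, p00=4, p01=0, p10=0)
        assert m["precision"] is None
        assert m["sensitivity"] is None
        assert m["accuracy"] == 1.0

    def test_threshold_validated(self, fitted_models, fixture_sim):
        with pytest.raises(ValueError, match="threshold"):
            classification_metrics(fitted_models["use_any"],
                                   fixture_sim.survey, threshold=1.5)

    def test_counts_match_sklearn_confusion_oracle(self, fitted_models,
                                                   fixture_sim):
        from sklearn.metrics import confusion_matrix

        sv = fixture_sim.survey.head(500)
        model = fitted_models["use_any"]
        got = classification_metrics(model, sv)["counts"]
        y = sv["y_use_any"].to_numpy()
        yhat = (fitted_probabilities(model, sv) >= 0.5).astype(int)
        tn, fp, fn, tp = confusion_matrix(y, yhat).ravel()
        assert got == {"P11": tp, "P00": tn, "P01": fp, "P10": fn}
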