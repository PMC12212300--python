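"""Direct estimates, adjustment ratios, raking calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from ethnosae import (LevelConstraint, benchmarked_domain_estimates,
                      build_constraints, calibrate_weights, default_levels,
                      direct_estimates, hajek_mean, level_mask, predict_all,
                      ratio_adjust)
from ethnosae.benchmarking import PREDICTION_COLUMN


class TestDirectEstimates:
    def test_equal_weights_give_arithmetic_mean(self, fixture_sim):
        sv = fixture_sim.survey.copy()
        sv["weight"] = 2.0
        D = direct_estimates(sv, "use_any", ["national"])
        assert D["national"] == pytest.approx(sv["y_use_any"].mean(),
                                              abs=1e-12)

    def test_doubling_one_weight_equals_duplicating_the_row(self,
                                                            fixture_sim):
        sv = fixture_sim.survey.head(50).copy()
        sv["weight"] = 1.0
        doubled = sv.copy()
        doubled.loc[0, "weight"] = 2.0
        dup = pd.concat([sv, sv.iloc[[0]]], ignore_index=True)
        Dd = direct_estimates(doubled, "unmet", ["national"])["national"]
        Du = direct_estimates(dup, "unmet", ["national"])["national"]
        assert Dd == pytest.approx(Du, abs=1e-12)

    def test_matches_weighted_mean_oracle_on_random_weights(self,
                                                            fixture_sim):
        sv = fixture_sim.survey.copy()
        rng = np.random.default_rng(8)
        sv["weight"] = rng.uniform(0.5, 4.0, len(sv))
        levels = default_levels(sorted(sv["state"].unique()))
        D = direct_estimates(sv, "use_modern", levels)
        for lev in levels:
            m = level_mask(sv, lev)
            w = sv.loc[m, "weight"].to_numpy()
            y = sv.loc[m, "y_use_modern"].to_numpy()
            assert D[lev] == pytest.approx(np.sum(w * y) / np.sum(w),
                                           abs=1e-12)

    def test_need_satisfied_direct_is_weighted_demand_ratio(self,
                                                            fixture_sim):
        sv = fixture_sim.survey
        D = direct_estimates(sv, "need_satisfied", ["national"])["national"]
        w = sv["weight"].to_numpy()
        expected = (np.sum(w * sv["y_use_modern"])
                    / np.sum(w * (sv["y_use_any"] + sv["y_unmet"])))
        assert D == pytest.approx(expected, abs=1e-12)

    def test_empty_level_reported_as_nan(self, fixture_sim):
        D = direct_estimates(fixture_sim.survey, "use_any", ["state:999"])
        assert np.isnan(D["state:999"])


class TestRatioAdjust:
    def test_identity_and_halving(self):
        assert ratio_adjust(0.3, 0.3) == pytest.approx(1.0)
        assert ratio_adjust(0.2, 0.4) == pytest.approx(0.5)

    def test_zero_census_mean_errors(self):
        with pytest.raises(ZeroDivisionError):
            ratio_adjust(0.2, 0.0)

    def test_random_pairs_match_division(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            d, y = rng.uniform(0.01, 1, 2)
            assert ratio_adjust(d, y) == d / y


def _national_constraint(p, D):
    return LevelConstraint(level="national", indicator="use_any", D=D,
                           Y=float(p.mean()), R=D / float(p.mean()),
                           mask=np.ones(len(p), dtype=bool))


class TestCalibrateWeights:
    def test_zero_constraints_identity(self):
        sol = calibrate_weights(np.linspace(0.1, 0.9, 10), [])
        assert sol.converged
        assert np.all(sol.weights == 1.0)
        assert sol.iterations == 0

    def test_already_satisfied_returns_unit_weights_in_one_sweep(self):
        p = np.array([0.2, 0.4, 0.6, 0.8])
        sol = calibrate_weights(p, [_national_constraint(p, float(p.mean()))])
        assert sol.converged
        assert sol.iterations == 1
        assert np.allclose(sol.weights, 1.0, atol=1e-12)

    def test_single_constraint_matches_lagrange_tilt_oracle(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.2, 0.9, 400)
        D = float(p.mean()) + 0.03
        sol = calibrate_weights(p, [_national_constraint(p, D)])
        assert sol.converged
        assert abs(hajek_mean(p, sol.weights) - D) < 1e-8
        # independent route: lambda minimizes the convex potential
        # sum_i exp(lambda (p_i - D)), whose stationarity condition is the
        # calibration constraint; the optimal weights are the tilts.
        c = p - D
        lam = minimize_scalar(lambda l: np.sum(np.exp(l * c)),
                              bounds=(-200, 200), method="bounded",
                              options={"xatol": 1e-12}).x
        w_oracle = np.exp(lam * c)
        assert np.allclose(sol.weights, w_oracle, rtol=1e-5)

    def test_full_system_converges_on_fixture(self, fixture_sim,
                                              fitted_models):
        pred = predict_all(fitted_models, fixture_sim.census)
        cons = build_constraints(fixture_sim.survey, pred,
                                 fixture_sim.census, "use_any")
        assert [c.level for c in cons][-1] == "national"
        sol = calibrate_weights(pred["p_use_any"].to_numpy(), cons)
        assert sol.converged
        assert sol.iterations < 1000
        assert max(sol.residuals.values()) < 1e-6
        assert np.all(sol.weights > 0)
        # self-consistency: recomputing every constraint reproduces D
        for c in cons:
            got = hajek_mean(pred.loc[c.mask, "p_use_any"].to_numpy(),
                             sol.weights[c.mask])
            assert got == pytest.approx(c.D, abs=1e-6)

    def test_infeasible_constraint_flagged_not_silent(self):
        p = np.full(10, 0.5)
        sol = calibrate_weights(p, [_national_constraint(p, 0.9)],
                                max_iter=5)
        assert not sol.converged
        assert "national" in sol.infeasible
        assert sol.residuals["national"] > 0.1

    def test_hajek_invariant_to_weight_rescaling(self):
        rng = np.random.default_rng(7)
        y = rng.uniform(0, 1, 100)
        w = rng.uniform(0.5, 3, 100)
        assert hajek_mean(y, w) == pytest.approx(hajek_mean(y, 17.3 * w),
                                                 abs=1e-12)


class TestBenchmarkedEstimates:
    def test_unit_weights_give_plain_domain_means(self, fixture_sim,
                                                  fitted_models):
        pred = predict_all(fitted_models, fixture_sim.census)
        est = benchmarked_domain_estimates(pred, np.ones(len(pred)),
                                           "use_any")
        oracle = pred.groupby(["ethnic_group", "state"],
                              observed=True)["p_use_any"].mean()
        for _, row in est.iterrows():
            assert row["estimate"] == pytest.approx(
                oracle[(row["ethnic_group"], row["state"])], abs=1e-12)

    def test_matches_bruteforce_weighted_mean(self, fixture_sim,
                                              fitted_models):
        pred = predict_all(fitted_models, fixture_sim.census)
        rng = np.random.default_rng(10)
        w = rng.uniform(0.3, 3.0, len(pred))
        est = benchmarked_domain_estimates(pred, w, "unmet")
        for _, row in est.iterrows():
            m = ((pred["ethnic_group"] == row["ethnic_group"])
                 & (pred["state"] == row["state"])).to_numpy()
            brute = (np.sum(w[m] * pred.loc[m, "p_unmet"])
                     / np.sum(w[m]))
            assert row["estimate"] == pytest.approx(brute, abs=1e-12)

    def test_national_aggregate_hits_direct_estimate(self, fixture_sim,
                                                     fitted_models):
        pred = predict_all(fitted_models, fixture_sim.census)
        cons = build_constraints(fixture_sim.survey, pred,
                                 fixture_sim.census, "use_modern")
        sol = calibrate_weights(pred["p_use_modern"].to_numpy(), cons)
        D_nat = direct_estimates(fixture_sim.survey, "use_modern",
                                 ["national"])["national"]
        got = hajek_mean(pred["p_use_modern"].to_numpy(), sol.weights)
        assert got == pytest.approx(D_nat, abs=1e-6)

    def test_state_additivity_under_common_weights(self, fixture_sim,
                                                   fitted_models):
        pred = predict_all(fitted_models, fixture_sim.census)
        cons = build_constraints(fixture_sim.survey, pred,
                                 fixture_sim.census, "use_any")
        sol = calibrate_weights(pred["p_use_any"].to_numpy(), cons)
        w = sol.weights
        p = pred["p_use_any"].to_numpy()
        national = hajek_mean(p, w)
        states = sorted(pred["state"].unique())
        combo = 0.0
        for s in states:
            m = (pred["state"] == s).to_numpy()
            combo += (w[m].sum() / w.sum()) * hajek_mean(p[m], w[m])
        assert combo == pytest.approx(national, abs=1e-12)

    def test_missing_requested_domain_reported_nan(self, fixture_sim,
                                                   fitted_models):
        pred = predict_all(fitted_models, fixture_sim.census)
        est = benchmarked_domain_estimates(pred, np.ones(len(pred)),
                                           "use_any",
                                           domains=[("afro", 999)])
        row = est[(est["ethnic_group"] == "afro") & (est["state"] == 999)]
        assert len(row) == 1 and np.isnan(row["estimate"].iloc[0])
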