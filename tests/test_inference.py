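"""Model fitting, AICc selection, separation handling and permutation tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from pairwinter.inference import (
    ModelSpec,
    _build_design,
    _irls_binomial,
    _response,
    aicc_from_aic,
    compare_aicc,
    detect_separation,
    fit_binomial,
    fit_preferred_models,
    permutation_pvalues,
    predict_curves,
)
from pairwinter.synthetic_data import make_fixture, simulate_daily_table

TWO_STATUS = {"faithful": 20, "divorcing": 20}


def wa_table(seed=0, **kwargs):
    kwargs.setdefault("n_pairs_per_status", dict(TWO_STATUS))
    return simulate_daily_table(seed, **kwargs)


class TestFitBinomial:
    def test_intercept_recovered_for_even_split(self):
        table = wa_table(seed=1)
        n = table[["x", "m", "f"]].sum(axis=1)
        table = table[n % 2 == 0].copy()  # k/n == 0.5 exactly on even totals
        total = table[["x", "m", "f"]].sum(axis=1)
        table["x"] = total // 2
        table["m"] = total - total // 2
        table["f"] = 0
        fit = fit_binomial(table, ModelSpec(response="wa", degree=0))
        assert fit.coef("intercept") == pytest.approx(0.0, abs=1e-6)

    def test_single_status_level_rejected(self):
        table = wa_table(seed=2)
        with pytest.raises(ValueError):
            fit_binomial(table[table.status == "faithful"], ModelSpec("wa", degree=0))

    def test_offset_recovery_within_three_se(self):
        """A -1.0 divorcing log-odds offset at 100 pairs x 26 days."""
        table = simulate_daily_table(
            seed=3,
            n_pairs_per_status={"faithful": 50, "divorcing": 50},
            offsets={"divorcing": -1.0},
        )
        fit = fit_binomial(table, ModelSpec("wa", degree=0))
        est, se = fit.coef("status[divorcing]"), fit.se("status[divorcing]")
        assert est < 0
        assert abs(est - (-1.0)) <= 3 * se

    def test_null_coefficients_cover_zero(self):
        """With no true effects, estimates stay within +-3 SE of 0."""
        hits = 0
        for rep in range(100):
            table = simulate_daily_table(
                seed=10_000 + rep,
                n_pairs_per_status={"faithful": 8, "divorcing": 8},
                mean_events_per_day=6.0,
            )
            fit = fit_binomial(table, ModelSpec("wa", degree=1))
            ok = all(
                abs(fit.coef(t)) <= 3 * fit.se(t)
                for t in fit.terms
                if t != "intercept"
            )
            hits += ok
        assert hits >= 94

    def test_slope_recovery_with_trend(self):
        table = simulate_daily_table(
            seed=4,
            n_pairs_per_status=dict(TWO_STATUS),
            slopes={"faithful": 0.24, "divorcing": -0.26},
        )
        fit = fit_binomial(table, ModelSpec("wa", degree=1))
        assert fit.coef("day") > 0
        assert fit.coef("day") + fit.coef("status[divorcing]:day") < 0

    def test_irls_matches_statsmodels(self):
        table = wa_table(seed=5, slopes={"divorcing": -0.2})
        spec = ModelSpec("wa", degree=2)
        k, n, sub = _response(table, spec)
        X, names = _build_design(
            sub, spec, sub.experimental_day.mean(), sub.experimental_day.std(ddof=0)
        )
        beta, cov, ll, ok = _irls_binomial(X, k, n)
        ref = sm.GLM(np.column_stack([k, n - k]), X, family=sm.families.Binomial()).fit()
        assert ok
        np.testing.assert_allclose(beta, ref.params, atol=1e-8)
        np.testing.assert_allclose(np.sqrt(np.diag(cov)), ref.bse, rtol=1e-6)

    def test_beta_binomial_preferred_on_overdispersed_data(self):
        rng = np.random.default_rng(6)
        rows = []
        for status in ("faithful", "divorcing"):
            for i in range(25):
                p_pair = rng.beta(2.0, 4.0)  # strong pair-level heterogeneity
                for day in range(1, 27):
                    n = 1 + rng.poisson(10)
                    x = rng.binomial(n, p_pair)
                    rows.append(
                        {"pair_id": f"{status}{i}", "status": status,
                         "experimental_day": day, "x": x,
                         "m": (n - x) // 2, "f": n - x - (n - x) // 2}
                    )
        table = pd.DataFrame(rows)
        plain = fit_binomial(table, ModelSpec("wa", degree=0))
        bb = fit_binomial(table, ModelSpec("wa", degree=0, overdispersion=True))
        assert bb.converged
        assert bb.aicc < plain.aicc
        assert bb.extra_params["rho"] > 0.01

    def test_zero_inflated_fit_recovers_extra_zero_mass(self):
        rng = np.random.default_rng(7)
        rows = []
        for status in ("faithful", "divorcing"):
            for i in range(25):
                for day in range(1, 27):
                    n = 1 + rng.poisson(10)
                    x = 0 if rng.random() < 0.3 else rng.binomial(n, 0.4)
                    rows.append(
                        {"pair_id": f"{status}{i}", "status": status,
                         "experimental_day": day, "x": x,
                         "m": (n - x) // 2, "f": n - x - (n - x) // 2}
                    )
        table = pd.DataFrame(rows)
        plain = fit_binomial(table, ModelSpec("wa", degree=0))
        zi = fit_binomial(table, ModelSpec("wa", degree=0, zero_inflation=True))
        assert zi.converged
        assert zi.aicc < plain.aicc
        assert zi.extra_params["zero_inflation_prob"] == pytest.approx(0.3, abs=0.05)


class TestAICc:
    def test_closed_form_and_large_n_limit(self):
        k = 5
        assert aicc_from_aic(100.0, k, 50) == pytest.approx(
            100.0 + 2 * k * (k + 1) / (50 - k - 1)
        )
        n = 10**6
        assert aicc_from_aic(100.0, k, n) - 100.0 == pytest.approx(
            2 * k * (k + 1) / (n - k - 1), abs=1e-6
        )

    def test_quadratic_day_effect_selected(self):
        chosen = 0
        for rep in range(50):
            table = simulate_daily_table(
                seed=20_000 + rep,
                n_pairs_per_status=dict(TWO_STATUS),
                quadratics={"faithful": -0.3, "divorcing": -0.3},
            )
            fits = [
                fit_binomial(table, ModelSpec("wa", degree=1)),
                fit_binomial(table, ModelSpec("wa", degree=2)),
            ]
            chosen += compare_aicc(fits).spec.degree == 2
        assert chosen >= 45

    def test_spurious_extra_terms_penalised(self):
        chosen = 0
        for rep in range(50):
            table = simulate_daily_table(
                seed=30_000 + rep,
                n_pairs_per_status={"faithful": 6, "divorcing": 6},
                mean_events_per_day=4.0,
            )
            fits = [
                fit_binomial(table, ModelSpec("wa", degree=1)),
                fit_binomial(table, ModelSpec("wa", degree=2)),
            ]
            chosen += compare_aicc(fits).spec.degree == 2
        assert chosen < 25

    def test_all_failed_candidates_error(self):
        fit = fit_binomial(wa_table(seed=8), ModelSpec("wa", degree=0))
        fit.converged = False
        with pytest.raises(ValueError):
            compare_aicc([fit])


class TestSeparation:
    def test_all_zero_level_flagged(self):
        table = make_fixture("separation_case")
        flags = detect_separation(table)
        assert flags["divorcing"].separated
        assert not flags["faithful"].separated

    def test_mixed_levels_unflagged(self):
        table = pd.DataFrame(
            {"status": ["faithful"] * 4 + ["new"] * 4,
             "is_breeding_partner": [0, 1, 1, 0, 1, 0, 0, 1]}
        )
        assert not any(f.separated for f in detect_separation(table).values())

    def test_empty_level_distinct_reason(self):
        table = pd.DataFrame(
            {"status": pd.Categorical(["faithful"] * 3,
                                      categories=["faithful", "divorcing"]),
             "is_breeding_partner": [0, 1, 0]}
        )
        flags = detect_separation(table)
        assert flags["divorcing"].separated
        assert flags["divorcing"].reason == "no observations"

    def test_aggregate_skipped_but_over_time_fits(self):
        table = make_fixture("separation_case")
        out = fit_preferred_models(table, B=49, seed=0)
        assert out["aggregate"] is None
        assert out["separation_flags"]["divorcing"].separated
        assert out["over_time"].converged
        assert out["over_time"].separation_flag


class TestPermutations:
    def test_balanced_data_gives_p_equal_one(self):
        """Identical series in every pair: every permuted |coef| ties the observed."""
        days = list(range(1, 9))
        rows = []
        for status in ("faithful", "divorcing"):
            for i in range(4):
                for d in days:
                    rows.append(
                        {"pair_id": f"{status}{i}", "status": status,
                         "experimental_day": d, "x": 3, "m": 2, "f": 2}
                    )
        p = permutation_pvalues(
            pd.DataFrame(rows), ModelSpec("wa", degree=0), B=99, seed=0
        )
        assert p["status[divorcing]"] == pytest.approx(1.0)

    def test_strong_effect_reaches_resolution_floor(self):
        table = simulate_daily_table(
            seed=9,
            n_pairs_per_status=dict(TWO_STATUS),
            offsets={"divorcing": -1.5},
        )
        p = permutation_pvalues(table, ModelSpec("wa", degree=0), B=99, seed=1)
        assert p["status[divorcing]"] == pytest.approx(1 / 100)

    def test_day_scheme_targets_temporal_terms(self):
        table = simulate_daily_table(
            seed=10,
            n_pairs_per_status=dict(TWO_STATUS),
            slopes={"faithful": 0.3, "divorcing": 0.3},
        )
        p = permutation_pvalues(
            table, ModelSpec("wa", degree=1), B=99, seed=2, scheme="day-within-pair"
        )
        assert set(p) == {"day"}
        assert p["day"] <= 0.05

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalues(wa_table(seed=11), ModelSpec("wa", degree=0),
                                B=9, seed=0, scheme="bogus")

    def test_null_pperm_uniform(self, null_pperm_sample):
        """Under H0 the permutation p-values are (super-)uniform (KS, alpha=0.01)."""
        stat, pval = stats.kstest(null_pperm_sample, "uniform")
        cdf_excess = np.max(
            np.arange(1, null_pperm_sample.size + 1) / null_pperm_sample.size
            - np.sort(null_pperm_sample)
        )
        super_uniform = cdf_excess <= stat + 1e-12
        assert pval > 0.01 or super_uniform

    def test_asymptotic_and_permutation_decisions_agree(self, null_asymptotic_decisions):
        asym, perm = null_asymptotic_decisions.T
        agree = np.mean((asym <= 0.05) == (perm <= 0.05))
        assert agree >= 0.9


class TestPredictCurves:
    def test_intercept_only_flat_at_mean(self):
        table = wa_table(seed=12)
        fit = fit_binomial(table, ModelSpec("wa", degree=0))
        curves = predict_curves(fit)
        faithful = curves[curves.status == "faithful"]
        assert faithful["prediction"].nunique() == 1
        observed = table.query("status == 'faithful'")
        rate = observed["x"].sum() / observed[["x", "m", "f"]].sum().sum()
        assert faithful["prediction"].iloc[0] == pytest.approx(rate, abs=0.01)
        assert ((curves.ci_lo <= curves.prediction) & (curves.prediction <= curves.ci_hi)).all()

    def test_trends_follow_generator_truth(self):
        table = simulate_daily_table(
            seed=13,
            n_pairs_per_status=dict(TWO_STATUS),
            slopes={"faithful": 0.4, "divorcing": -0.4},
        )
        fit = fit_binomial(table, ModelSpec("wa", degree=1))
        curves = predict_curves(fit)
        faithful = curves[curves.status == "faithful"].sort_values("experimental_day")
        divorcing = curves[curves.status == "divorcing"].sort_values("experimental_day")
        assert (np.diff(faithful["prediction"]) >= 0).all()
        assert divorcing["prediction"].iloc[-1] < divorcing["prediction"].iloc[0]
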