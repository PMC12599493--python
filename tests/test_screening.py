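"""Plackett-Burman design construction and effect estimation."""

import numpy as np
import pytest
from scipy.stats import t as student_t

from probioferm import fixtures as fx
from probioferm.screening import (
    SUPPORTED_BASE_RUNS,
    DesignError,
    FactorSpec,
    ScreeningFit,
    build_pb_design,
    critical_margin,
    effect_summary,
    evaluate_regression,
    fit_screening,
    hadamard_matrix,
)


def _random_factors(k, rng):
    return [
        FactorSpec(f"f{i}", chr(65 + i), 0.0, c / 2, c)
        for i, c in enumerate(rng.uniform(0.5, 20.0, k))
    ]


class TestDesignConstruction:
    @pytest.mark.parametrize("n_base", SUPPORTED_BASE_RUNS)
    def test_orthogonality_all_supported_sizes(self, n_base, rng):
        """X'X over coded non-center columns equals n_base * identity."""
        k = n_base - 1
        design = build_pb_design(_random_factors(k, rng), n_base, 2, seed=1)
        base = design.coded[~design.is_center]
        assert np.array_equal(base.T @ base, n_base * np.eye(k, dtype=int))
        assert (np.abs(base).sum(axis=0) == n_base).all()  # balanced +/-1

    @pytest.mark.parametrize(
        "k,n_base,n_center,n_rows",
        [(14, 36, 1, 37), (5, 12, 1, 13), (3, 8, 0, 8)],
    )
    def test_run_counts(self, k, n_base, n_center, n_rows, rng):
        design = build_pb_design(_random_factors(k, rng), n_base, n_center, seed=3)
        assert design.n_runs == n_rows
        assert design.is_center.sum() == n_center
        assert not design.coded[design.is_center].any()

    def test_three_factor_eight_run_balance(self, small_factors):
        design = build_pb_design(small_factors, 8, 0)
        base = design.coded
        assert ((base == -1).sum(axis=0) == 4).all()
        assert ((base == 1).sum(axis=0) == 4).all()
        gram = base.T @ base
        assert (gram[~np.eye(3, dtype=bool)] == 0).all()

    def test_unsupported_run_count_names_sizes(self, small_factors):
        with pytest.raises(DesignError, match=r"8, 12, 16, 20, 24, 36"):
            build_pb_design(small_factors, 10, 0)

    def test_capacity_error(self, rng):
        with pytest.raises(DesignError, match="at most 7"):
            build_pb_design(_random_factors(9, rng), 8, 0)

    def test_seeded_run_order_is_deterministic(self, small_factors):
        a = build_pb_design(small_factors, 12, 1, seed=42)
        b = build_pb_design(small_factors, 12, 1, seed=42)
        c = build_pb_design(small_factors, 12, 1, seed=43)
        assert np.array_equal(a.coded, b.coded)
        assert not np.array_equal(a.coded, c.coded)

    def test_hadamard_constructions_validate(self):
        for order in SUPPORTED_BASE_RUNS:
            H = hadamard_matrix(order)
            assert np.array_equal(H @ H.T, order * np.eye(order, dtype=int))

    def test_csv_round_trip(self, small_factors, tmp_path):
        from probioferm.screening import DesignMatrix

        design = build_pb_design(small_factors, 12, 2, seed=5)
        path = tmp_path / "design.csv"
        design.to_csv(path)
        back = DesignMatrix.from_csv(path, small_factors)
        assert np.array_equal(back.coded, design.coded)
        assert np.array_equal(back.is_center, design.is_center)

    def test_natural_levels_map_to_low_high(self, small_factors):
        design = build_pb_design(small_factors, 8, 1)
        nat = design.natural_levels()
        f = small_factors[0]
        col = nat[f.code].to_numpy()
        coded = design.coded[:, 0]
        assert np.allclose(col[coded == -1], f.low_level)
        assert np.allclose(col[coded == 1], f.high_level)
        assert np.allclose(col[design.is_center], f.center_level)


class TestFitScreening:
    def test_zero_noise_exact_recovery(self, small_factors):
        """Noise-free linear responses are interpolated exactly: r2 = 1."""
        design = build_pb_design(small_factors, 12, 2, seed=0)
        b = np.array([0.8, -1.3, 0.05])
        y = 2.0 + design.coded @ b + 0.3 * design.is_center
        fit = fit_screening(design, y)
        for code, truth in zip(design.codes, b):
            assert fit.coded_coefficients[code] == pytest.approx(truth, abs=1e-9)
        assert fit.coded_coefficients["intercept"] == pytest.approx(2.0, abs=1e-9)
        assert fit.coded_coefficients["center_point"] == pytest.approx(0.3, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        """OLS coefficients and SEs equal the direct (X'X)^-1 X'y solution."""
        for _ in range(120):
            n_base = int(rng.choice([8, 12, 16, 20, 24]))
            k = int(rng.integers(2, min(n_base - 3, 8)))
            n_center = int(rng.integers(0, 3))
            design = build_pb_design(
                _random_factors(k, rng), n_base, n_center, seed=int(rng.integers(1e6))
            )
            y = rng.normal(0.0, 1.0, design.n_runs)
            use_center = n_center > 0
            fit = fit_screening(design, y, fit_center_term=use_center)
            X = np.column_stack(
                [np.ones(design.n_runs), design.coded.astype(float)]
                + ([design.is_center.astype(float)] if use_center else [])
            )
            XtX_inv = np.linalg.inv(X.T @ X)
            beta = XtX_inv @ X.T @ y
            resid = y - X @ beta
            df = design.n_runs - X.shape[1]
            s2 = resid @ resid / df
            se = np.sqrt(s2 * np.diag(XtX_inv))
            names = ["intercept"] + design.codes + (
                ["center_point"] if use_center else []
            )
            for name, b_hat, se_hat in zip(names, beta, se):
                assert fit.coded_coefficients[name] == pytest.approx(b_hat, abs=1e-8)
                assert fit.standard_errors[name] == pytest.approx(se_hat, abs=1e-8)

    def test_residual_df_structure(self, biomass_design, eps_design, rng):
        y37 = rng.normal(size=37)
        fit = fit_screening(biomass_design, y37)
        assert fit.residual_df == 37 - (14 + 1 + 1)
        fit13 = fit_screening(eps_design, rng.normal(size=13))
        assert fit13.residual_df == 6

    def test_effect_symmetry(self, small_factors, rng):
        """Negating the responses negates coefficients, |t-ratios| unchanged."""
        design = build_pb_design(small_factors, 12, 1, seed=2)
        y = rng.normal(5.0, 1.0, design.n_runs)
        fit_pos = fit_screening(design, y)
        fit_neg = fit_screening(design, -y)
        for code in design.codes:
            assert fit_neg.coded_coefficients[code] == pytest.approx(
                -fit_pos.coded_coefficients[code], abs=1e-10
            )
            assert abs(fit_neg.standardized_effects[code]) == pytest.approx(
                abs(fit_pos.standardized_effects[code]), abs=1e-10
            )

    def test_saturated_model_error(self, rng):
        design = build_pb_design(_random_factors(7, rng), 8, 0)
        with pytest.raises(ValueError, match="saturated"):
            fit_screening(design, rng.normal(size=8), fit_center_term=False)

    def test_response_length_mismatch(self, small_factors):
        design = build_pb_design(small_factors, 8, 0)
        with pytest.raises(ValueError, match="responses"):
            fit_screening(design, np.zeros(5))

    def test_natural_units_recover_generating_model(self, small_factors):
        """Fitting zero-noise data generated from natural-unit coefficients
        returns those coefficients after the coded -> natural conversion."""
        from probioferm.synthetic import gen_screening_responses

        design = build_pb_design(small_factors, 12, 1, seed=9)
        truth = {
            "intercept": 1.5, "alpha": 0.2, "beta": -3.0, "gamma": 4.0,
            "center_point": 0.25,
        }
        y = gen_screening_responses(design, truth, 0.0, seed=0)
        fit = fit_screening(design, y)
        for key, val in truth.items():
            assert fit.coefficients[key] == pytest.approx(val, abs=1e-9)

    def test_coefficient_error_scales_with_noise(self, small_factors):
        """Mean absolute coefficient error doubles when sigma doubles."""
        design = build_pb_design(small_factors, 12, 0, seed=0)
        b = np.array([1.0, -0.5, 0.25])

        def mean_abs_err(sigma, n_rep=150):
            errs = []
            for rep in range(n_rep):
                rng = np.random.default_rng(1000 + rep)
                y = design.coded @ b + rng.normal(0.0, sigma, design.n_runs)
                fit = fit_screening(design, y, fit_center_term=False)
                errs.append(
                    np.mean([abs(fit.coded_coefficients[c] - t)
                             for c, t in zip(design.codes, b)])
                )
            return np.mean(errs)

        e1, e2 = mean_abs_err(0.1), mean_abs_err(0.2)
        assert e2 / e1 == pytest.approx(2.0, rel=0.2)
        # absolute scale sigma/sqrt(n): E|err| = sigma*sqrt(2/(pi*n))
        assert e1 == pytest.approx(0.1 * np.sqrt(2 / (np.pi * 12)), rel=0.2)


class TestCriticalMargin:
    @pytest.mark.parametrize(
        "alpha,df,expected,ndigits",
        [(0.05, 21, 2.08, 2), (0.05, 6, 2.4469, 4), (0.05, 10**6, 1.960, 3)],
    )
    def test_reference_quantiles(self, alpha, df, expected, ndigits):
        assert round(critical_margin(alpha, df), ndigits) == pytest.approx(expected)

    def test_monotonicity(self):
        margins = [critical_margin(0.05, df) for df in range(1, 60)]
        assert all(a > b for a, b in zip(margins, margins[1:]))
        alphas = [0.2, 0.1, 0.05, 0.01, 0.001]
        vals = [critical_margin(a, 10) for a in alphas]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("alpha,df", [(0.0, 5), (1.0, 5), (-0.1, 5), (0.05, 0)])
    def test_domain_errors(self, alpha, df):
        with pytest.raises(ValueError):
            critical_margin(alpha, df)


class TestEvaluateRegression:
    def test_eps_regression_at_center_levels(self):
        settings = {
            "soy peptone": 5, "yeast extract": 5, "Na2HPO4": 9.5,
            "MnSO4": 0.0025, "ascorbic acid": 0.25,
        }
        assert evaluate_regression(fx.EQ2_EPS_COEFFICIENTS, settings) == pytest.approx(
            389.405, abs=1e-9
        )

    def test_biomass_regression_intercept_only(self):
        settings = {k: 0.0 for k in fx.EQ1_BIOMASS_COEFFICIENTS if k != "intercept"}
        settings["center_point"] = 0.0
        assert evaluate_regression(fx.EQ1_BIOMASS_COEFFICIENTS, settings) == pytest.approx(
            -0.287
        )

    def test_null_model(self):
        coeffs = {"intercept": 0.0, "a": 0.0, "b": 0.0}
        assert evaluate_regression(coeffs, {"a": 123.0, "b": -4.0}) == 0.0

    def test_missing_factor_lists_absences(self):
        with pytest.raises(KeyError, match="yeast extract"):
            evaluate_regression(fx.EQ2_EPS_COEFFICIENTS, {"soy peptone": 5})


class TestEffectSummary:
    def _fit_with_effects(self, effects, margin):
        factors = [FactorSpec(c.lower(), c, 0, 1, 2) for c in effects]
        return ScreeningFit(
            factors=factors,
            coefficients={},
            coded_coefficients={c: e for c, e in effects.items()},
            standard_errors={c: 1.0 for c in effects},
            standardized_effects=dict(effects),
            residual_df=10, s=1.0, r_squared=0.9, r_squared_adjusted=0.88,
            alpha=0.05, critical_margin=margin,
        )

    def test_published_pareto_ranking(self):
        """Reported top effects 7.6 / 5.2 / 2.9 all clear the 2.08 margin."""
        fit = self._fit_with_effects({"A": 7.6, "B": 5.2, "C": 2.9, "D": 1.0}, 2.08)
        df = effect_summary(fit)
        assert list(df["code"]) == ["A", "B", "C", "D"]
        assert list(df["significant"]) == [True, True, True, False]

    def test_all_zero_ties_order_by_code(self):
        fit = self._fit_with_effects({"B": 0.0, "A": 0.0, "C": 0.0}, 2.0)
        df = effect_summary(fit)
        assert list(df["code"]) == ["A", "B", "C"]
        assert not df["significant"].any()

    def test_ranking_matches_sort_oracle(self, rng):
        effects = {chr(65 + i): float(e) for i, e in enumerate(rng.normal(0, 3, 10))}
        fit = self._fit_with_effects(effects, 2.0)
        df = effect_summary(fit)
        oracle = sorted(effects, key=lambda c: (-abs(effects[c]), c))
        assert list(df["code"]) == oracle
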