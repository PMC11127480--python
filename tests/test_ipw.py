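import numpy as np
import pandas as pd
import pytest

from screenpp import (WeightModelSpec, cumulative_censor_weights,
                      exposure_weights, fit_censoring_model,
                      fit_exposure_model, truncate_weights)
from screenpp.errors import FitDiagnosticError, ParameterError
from screenpp.ipw import build_design, fit_logit, infer_levels, segmented_cumprod
from screenpp.risk import STATUS_PROTOCOL


def test_weight_model_spec_invariants():
    with pytest.raises(ParameterError):
        WeightModelSpec(numerator_covariates=("sex",),
                        denominator_covariates=("comorb_cat",))
    with pytest.raises(ParameterError):
        WeightModelSpec(truncation_percentile=40)


class TestLogisticSolver:
    def test_agrees_with_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(0)
        n = 3000
        X = np.column_stack([np.ones(n), rng.random(n),
                             rng.integers(0, 2, n).astype(float)])
        beta_true = np.array([-1.0, 0.8, -0.5])
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
        beta = fit_logit(X, y)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(beta, ref.params, atol=1e-8)

    def test_recovers_known_coefficients_within_3_se(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(1)
        n = 50000
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float),
                             rng.integers(0, 2, n).astype(float)])
        beta_true = np.array([-2.0, 0.7, -0.4])
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
        beta = fit_logit(X, y)
        se = sm.GLM(y, X, family=sm.families.Binomial()).fit().bse
        assert (np.abs(beta - beta_true) < 3 * se).all()

    def test_perfect_separation_raises_with_column_name(self):
        X = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)]])
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(FitDiagnosticError, match="x1"):
            fit_logit(X, y, names=["intercept", "x1"])


def baseline_frame(n, rng, confounded=True):
    sex = rng.choice(["F", "M"], size=n)
    race = rng.choice(["white", "black", "hispanic", "other"], size=n)
    state = rng.choice(["A", "B", "C"], size=n)
    period = rng.choice(["p1", "p2", "p3"], size=n)
    logit = -2.0 + (0.9 * (sex == "M") + 0.8 * (race == "black")
                    if confounded else 0.0)
    exposed = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    return pd.DataFrame({"id": np.arange(n), "sex": sex, "race_ethnicity": race,
                         "state": state, "period": period, "exposed": exposed})


class TestExposureWeights:
    def test_null_generator_gives_unit_weights(self):
        rng = np.random.default_rng(3)
        base = baseline_frame(20000, rng, confounded=False)
        model = fit_exposure_model(base)
        w = exposure_weights(model, base)
        assert abs(w.mean() - 1) < 0.01
        assert np.percentile(np.abs(w - 1), 95) < 0.1

    def test_saturated_two_by_two_matches_cell_proportions(self):
        base = pd.DataFrame({
            "sex": ["F"] * 40 + ["M"] * 60,
            "exposed": [1] * 10 + [0] * 30 + [1] * 30 + [0] * 30,
        })
        model = fit_exposure_model(base, covariates=("sex",))
        p = model.predict_p_exposed(base)
        np.testing.assert_allclose(p[:40], 10 / 40, atol=1e-8)
        np.testing.assert_allclose(p[40:], 30 / 60, atol=1e-8)
        w = exposure_weights(model, base)
        # stabilized weights reproduce exact standardization to the margin
        marg = base["exposed"].mean()
        np.testing.assert_allclose(w[:10], marg / (10 / 40), atol=1e-8)

    def test_weighted_covariates_balance(self):
        rng = np.random.default_rng(4)
        base = baseline_frame(40000, rng, confounded=True)
        model = fit_exposure_model(base)
        w = exposure_weights(model, base)
        for group in (0, 1):
            sel = base["exposed"] == group
            weighted_male = np.average(base.loc[sel, "sex"] == "M",
                                       weights=w[sel])
            pooled_male = (base["sex"] == "M").mean()
            assert abs(weighted_male - pooled_male) < 0.02

    def test_single_group_raises(self):
        base = baseline_frame(100, np.random.default_rng(5))
        base["exposed"] = 0
        with pytest.raises(FitDiagnosticError):
            fit_exposure_model(base)


def intervals_frame(n_person, n_bins, rng, censor_logit=None):
    rows = []
    for pid in range(n_person):
        comorb = 0
        for t in range(n_bins):
            rows.append((pid, t, "F" if pid % 2 else "M", "white", "A", "p1",
                         min(comorb, 2), 0, pid % 2))
            if rng.random() < 0.05:
                comorb += 1
    df = pd.DataFrame(rows, columns=["id", "t", "sex", "race_ethnicity",
                                     "state", "period", "comorb_cat", "status",
                                     "exposed"])
    return df


class _StubModel:
    censor_type = "protocol"

    def __init__(self, p_num, p_den):
        self.p_num, self.p_den = p_num, p_den

    def predict_uncensored(self, df):
        return (np.full(len(df), self.p_num), np.full(len(df), self.p_den))


class TestCumulativeWeights:
    def test_hand_computed_two_interval_product(self):
        df = pd.DataFrame({"id": [1, 1], "t": [0, 1]})
        w = cumulative_censor_weights(_StubModel(0.9, 0.8), df)
        np.testing.assert_allclose(w, [1.125, 1.265625], atol=1e-12)

    def test_constant_equal_hazards_give_unit_weights(self):
        df = pd.DataFrame({"id": np.repeat([1, 2], 5), "t": np.tile(range(5), 2)})
        w = cumulative_censor_weights(_StubModel(0.93, 0.93), df)
        np.testing.assert_allclose(w, 1.0, atol=1e-12)

    def test_segmented_cumprod_respects_blocks(self):
        vals = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        starts = np.array([True, False, True, False, False])
        np.testing.assert_allclose(segmented_cumprod(vals, starts),
                                   [2.0, 6.0, 4.0, 20.0, 120.0])

    def test_saturated_time_model_matches_empirical_hazard(self):
        """With a categorical-time-only model the fitted per-interval censoring
        probability equals the empirical proportion censored among at-risk
        rows in each time stratum."""
        rng = np.random.default_rng(6)
        rows = []
        for pid in range(800):
            exit_t = int(rng.integers(1, 60))
            censored = rng.random() < 0.3 + 0.005 * exit_t
            for t in range(exit_t):
                status = STATUS_PROTOCOL if censored and t == exit_t - 1 else 0
                rows.append((pid, t, status, 0))
        df = pd.DataFrame(rows, columns=["id", "t", "status", "exposed"])
        spec = WeightModelSpec(denominator_covariates=(),
                               numerator_covariates=(), time_spec="bins",
                               fit_stratum="pooled")
        model = fit_censoring_model(df, "protocol", spec)
        _, p_den = model.predict_uncensored(df)
        emp = df.groupby(df["t"] // 10)["status"].apply(
            lambda s: (s == STATUS_PROTOCOL).mean())
        for tb, hazard in emp.items():
            got = 1.0 - p_den[(df["t"] // 10).to_numpy() == tb]
            np.testing.assert_allclose(got, hazard, atol=1e-6)

    def test_no_censoring_events_gives_constant_one(self):
        rng = np.random.default_rng(7)
        df = intervals_frame(50, 4, rng)
        spec = WeightModelSpec(fit_stratum="pooled")
        model = fit_censoring_model(df, "disenrollment", spec)
        w = cumulative_censor_weights(model, df)
        np.testing.assert_allclose(w, 1.0)


class TestTruncation:
    def test_percentile_100_is_identity(self):
        w = np.array([0.5, 1.0, 4.0])
        out, report = truncate_weights(w, 100.0)
        np.testing.assert_array_equal(out, w)
        assert report["n_truncated"] == 0

    def test_order_statistic_cut(self):
        w = np.array([1.0, 1.0, 1.0, 100.0])
        out, report = truncate_weights(w, 75.0)
        cut = np.percentile(w, 75)
        np.testing.assert_allclose(out, [1, 1, 1, cut])
        assert report["n_truncated"] == 1

    def test_continuity_toward_full_weights(self):
        rng = np.random.default_rng(8)
        w = rng.lognormal(0, 1, size=2000)
        means = [truncate_weights(w, p)[0].mean()
                 for p in (97.0, 99.0, 99.9, 100.0)]
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))
        assert abs(means[-2] - means[-1]) < abs(means[0] - means[-1]) + 1e-12


class TestWeightComponentsUnderNullGenerator:
    def test_all_components_converge_to_one(self):
        """With every covariate effect on exposure, screening uptake and
        disenrollment switched off, the three stabilized weight components
        are pointwise close to 1."""
        from screenpp import (GeneratorParams, ProtocolSpec, build_cohort,
                              build_person_intervals, compute_weights,
                              generate_population)
        params = GeneratorParams(n_beneficiaries=20000, seed=29).replace(
            hiv_model={"intercept": -2.2, "sex": {}, "race": {}, "state": {},
                       "period": {}},
            endoscopy_model={"per_comorb": 0.0, "hiv": 0.0},
            disenroll_hazard={"hiv_rr": 1.0, "male_rr": 1.0,
                              "per_comorb_rr": 1.0, "race_rr": {}})
        data = generate_population(params)
        cohort, _ = build_cohort(data.demographics, data.enrollment,
                                 data.claims)
        iv = build_person_intervals(cohort, data.claims,
                                    ProtocolSpec(cadence_years=10))
        weights, report = compute_weights(iv.sort_values(["id", "t"]),
                                          WeightModelSpec())
        assert abs(report["mean_exposure_weight"] - 1) < 0.02
        for col in ("exposure_weight", "adherence_weight",
                    "disenrollment_weight", "combined_weight"):
            w = weights[col].to_numpy()
            assert abs(w.mean() - 1) < 0.03, col
            assert np.percentile(np.abs(w - 1), 99) < 0.35, col
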