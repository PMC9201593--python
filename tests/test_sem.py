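"""Path-model specification and maximum-likelihood fitting.

Oracle: for recursive models with uncorrelated disturbances the ML solution
equals equation-by-equation OLS, so closed-form least squares checks the
optimizer.
"""

import numpy as np
import pytest

from pmconn.sem import (
    PathModelSpec,
    aic,
    build_mediation_spec,
    fit_ml,
    parse_path_spec,
    rmsea,
    scaling_invariance,
)
from pmconn.synthetic import generate_mediation_dataset

TWO_MEDIATOR_TRUTH = {
    ("input", "m1"): 0.8,
    ("input", "m2"): 0.75,
    ("m1", "output"): 0.5,
    ("m2", "output"): 0.3,
    ("input", "output"): 0.25,
}


class TestSpec:
    def test_one_mediator_three_paths(self):
        spec = build_mediation_spec("x", ["m"], "y")
        assert len(spec.paths) == 3

    def test_two_mediators_five_paths(self):
        spec = build_mediation_spec("tpdc", ["coh", "pow"], "su")
        assert len(spec.paths) == 5
        assert ("tpdc", "su") in spec.paths

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            build_mediation_spec("x", ["x"], "y")

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            PathModelSpec(("a", "b"), (("a", "b"), ("b", "a")))

    def test_dsl_round_trip(self):
        spec = parse_path_spec("tpdc -> coh; tpdc -> pow; coh -> su; pow -> su; tpdc -> su")
        assert spec.variables == ("tpdc", "coh", "pow", "su")
        assert len(spec.paths) == 5


class TestFit:
    def test_single_path_recovery(self):
        data = generate_mediation_dataset(
            10000, {("input", "m1"): 0.7, ("m1", "output"): 0.5}, seed=13
        )
        spec = build_mediation_spec("input", ["m1"], "output")
        fit = fit_ml(spec, data)
        assert fit.standardized[("input", "m1")] == pytest.approx(0.7, abs=0.02)

    def test_ml_equals_ols_for_recursive_model(self):
        data = generate_mediation_dataset(2000, TWO_MEDIATOR_TRUTH, seed=17)
        spec = build_mediation_spec("input", ["m1", "m2"], "output")
        fit = fit_ml(spec, data)
        x = data[["m1", "m2", "input"]].to_numpy()
        x = np.column_stack([x, np.ones(len(data))])
        beta, *_ = np.linalg.lstsq(x, data["output"].to_numpy(), rcond=None)
        assert fit.coefficients[("m1", "output")] == pytest.approx(beta[0], abs=1e-3)
        assert fit.coefficients[("m2", "output")] == pytest.approx(beta[1], abs=1e-3)
        assert fit.coefficients[("input", "output")] == pytest.approx(beta[2], abs=1e-3)

    def test_independent_columns_give_null_paths(self):
        n = 5000
        data = generate_mediation_dataset(n, {("input", "m1"): 0.0, ("m1", "output"): 0.0,
                                              ("input", "output"): 0.0}, seed=19)
        spec = build_mediation_spec("input", ["m1"], "output")
        fit = fit_ml(spec, data)
        assert all(abs(s) < 3 / np.sqrt(n) for s in fit.standardized.values())

    def test_saturated_model_chi2_zero(self):
        data = generate_mediation_dataset(500, {("input", "m1"): 0.6, ("m1", "output"): 0.5},
                                          seed=23)
        spec = build_mediation_spec("input", ["m1"], "output")
        fit = fit_ml(spec, data[["input", "m1", "output"]])
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)
        assert fit.rmsea == 0.0

    def test_standardization_invariance(self):
        data = generate_mediation_dataset(800, TWO_MEDIATOR_TRUTH, seed=29)
        spec = build_mediation_spec("input", ["m1", "m2"], "output")
        worst = scaling_invariance(spec, data, n_draws=2, seed=1)
        assert worst < 1e-6

    def test_missing_column_rejected(self):
        data = generate_mediation_dataset(100, {("input", "m1"): 0.5}, seed=1)
        spec = build_mediation_spec("input", ["m1"], "outcome_not_there")
        with pytest.raises(ValueError, match="lacks columns"):
            fit_ml(spec, data)

    def test_too_few_rows_rejected(self):
        data = generate_mediation_dataset(10, TWO_MEDIATOR_TRUTH, seed=1).head(8)
        spec = build_mediation_spec("input", ["m1", "m2"], "output")
        with pytest.raises(ValueError, match="free parameters"):
            fit_ml(spec, data)


class TestFitIndices:
    def test_rmsea_closed_form(self):
        assert rmsea(20.0, 10, 101) == pytest.approx(0.1)
        assert rmsea(10.0, 10, 101) == 0.0  # chi2 == df
        assert rmsea(0.0, 0, 100) == 0.0

    def test_aic_identical_models_identical(self):
        data = generate_mediation_dataset(500, TWO_MEDIATOR_TRUTH, seed=31)
        spec = build_mediation_spec("input", ["m1", "m2"], "output")
        assert aic(fit_ml(spec, data)) == aic(fit_ml(spec, data))

    def test_smaller_true_model_preferred_by_aic(self):
        # data generated WITHOUT the direct path; the smaller model should win
        truth = {("input", "m1"): 0.7, ("m1", "output"): 0.6}
        small = PathModelSpec(("input", "m1", "output"),
                              (("input", "m1"), ("m1", "output")))
        big = build_mediation_spec("input", ["m1"], "output")
        wins = 0
        deltas = []
        for seed in range(20):
            data = generate_mediation_dataset(400, truth, seed=900 + seed)
            cols = data[["input", "m1", "output"]]
            a_small = aic(fit_ml(small, cols))
            a_big = aic(fit_ml(big, cols))
            wins += a_small < a_big
            deltas.append(a_big - a_small)
        assert wins >= 16  # >= 80% of 20 seeds
        assert np.mean(deltas) > 0  # adding a zero-true path costs AIC on average
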