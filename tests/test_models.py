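"""Curve families, weighted fitting and the pure-error lack-of-fit test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rbefit as rf
from rbefit.exceptions import (
    DataValidationError,
    DegenerateDataError,
    DegenerateVarianceError,
    UnderdeterminedFitError,
)

# Frozen hand-computed oracles for the printed iron-ion group summaries
# (means 0, 0, 11.7, 49, 64 at 0, 0.2, 0.5, 1.0, 1.5 Gy; n = 12,11,7,7,6):
#   MS_pure = (6*8.1^2 + 6*9.2^2 + 5*6.3^2) / 38 = 28.946...
#   linear through-origin slope = sum(n x m)/sum(n x^2) = 959.95/22.69
PURE_ERROR_MS = 1099.95 / 38
LINEAR_SLOPE = 959.95 / 22.69


class TestEvaluate:
    def test_shifted_power_through_origin_is_zero_at_zero(self):
        m = rf.DoseResponseModel("shifted_power", {"a": 0.95, "p": 5, "b": -(0.95**5)})
        assert rf.evaluate(m, 0.0) == 0.0

    def test_printed_xray_curve_at_its_shift(self):
        # (0.9 - 0.9)^3 + 0.729 = 0.729
        assert rf.evaluate(rf.XRAY_CURVE, 0.9) == pytest.approx(0.729, abs=1e-12)

    def test_linear_proportionality(self):
        m = rf.DoseResponseModel("linear", {"c": 10.0})
        assert rf.evaluate(m, 1.5) == 15.0

    def test_negative_dose_rejected(self):
        with pytest.raises(DataValidationError):
            rf.evaluate(rf.IRON_CURVE, -0.1)

    def test_negative_coefficients_rejected(self):
        with pytest.raises(DataValidationError):
            rf.DoseResponseModel("linear", {"c": -1.0})
        with pytest.raises(DataValidationError):
            rf.DoseResponseModel("linear_quadratic", {"alpha": 1.0, "beta": -0.5})

    def test_even_exponent_rejected(self):
        with pytest.raises(DataValidationError):
            rf.DoseResponseModel("shifted_power", {"a": 1.0, "p": 4, "b": 0.0})


class TestOddRoot:
    @pytest.mark.parametrize(
        "value, p, expected",
        [(-8.0, 3, -2.0), (0.0, 7, 0.0), (15.774, 5, 15.774 ** 0.2)],
    )
    def test_known_roots(self, value, p, expected):
        assert rf.odd_root(value, p) == pytest.approx(expected, rel=1e-12)

    def test_even_p_rejected(self):
        with pytest.raises(DataValidationError):
            rf.odd_root(8.0, 2)

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
        st.sampled_from([1, 3, 5, 7, 9]),
    )
    def test_exact_inverse_of_odd_power(self, value, p):
        root = rf.odd_root(value, p)
        assert root ** p == pytest.approx(value, rel=1e-12, abs=1e-12)


def _noiseless_dataset(model, doses, n=5):
    groups = tuple(
        rf.DoseGroup.from_summary(d, max(0.0, float(rf.evaluate(model, d))), 1.0, n)
        for d in doses
    )
    return rf.DoseResponseDataset(label="noiseless", groups=groups)


class TestFitModel:
    def test_exact_recovery_of_generating_shifted_power(self):
        gen = rf.DoseResponseModel("shifted_power", {"a": 0.6, "p": 3, "b": -(0.6**3)})
        ds = _noiseless_dataset(gen, (0.0, 0.5, 1.0, 1.5, 2.0))
        fit = rf.fit_model(ds, "shifted_power", constrain_origin=True)
        assert fit.model.params["p"] == 3
        assert fit.model.params["a"] == pytest.approx(0.6, abs=1e-4)
        assert fit.sse < 1e-8
        assert fit.accepted

    def test_exact_recovery_of_generating_linear(self):
        gen = rf.DoseResponseModel("linear", {"c": 7.5})
        ds = _noiseless_dataset(gen, (0.0, 0.5, 1.0, 2.0))
        fit = rf.fit_model(ds, "linear")
        assert fit.model.params["c"] == pytest.approx(7.5, rel=1e-12)
        assert fit.sse < 1e-18

    def test_iron_linear_fit_matches_hand_oracle(self, iron):
        fit = rf.fit_model(iron, "linear")
        assert fit.model.params["c"] == pytest.approx(LINEAR_SLOPE, rel=1e-9)
        assert fit.lack_of_fit_F == pytest.approx(14.928, abs=0.01)
        assert fit.lack_of_fit_p < 0.001
        assert not fit.accepted

    def test_underdetermined(self):
        ds = _noiseless_dataset(rf.DoseResponseModel("linear", {"c": 2.0}), (0.0, 1.0))
        with pytest.raises(UnderdeterminedFitError):
            rf.fit_model(ds, "linear_quadratic")

    def test_all_zero_means_degenerate(self):
        groups = tuple(rf.DoseGroup.from_summary(d, 0.0, 1.0, 4) for d in (0.0, 1.0, 2.0))
        ds = rf.DoseResponseDataset(label="zero", groups=groups)
        with pytest.raises(DegenerateDataError):
            rf.fit_model(ds, "linear")


class TestLackOfFit:
    def test_zero_when_curve_interpolates_the_means(self, iron):
        # a curve through every group mean has F = 0, p = 1 regardless of family
        class _Interp:
            family = "linear"
            params = {"c": 0.0}

        # use the real mechanism: evaluate a fitted linear model on its own fit
        gen = rf.DoseResponseModel("linear", {"c": 4.0})
        groups = tuple(
            rf.DoseGroup.from_summary(d, 4.0 * d, 1.0, 4) for d in (0.0, 0.5, 1.0, 2.0)
        )
        ds = rf.DoseResponseDataset(label="exact", groups=groups)
        lof = rf.lack_of_fit(ds, gen)
        assert lof.F == 0.0 and lof.p == 1.0

    def test_iron_pure_error_ms(self, iron):
        gen = rf.DoseResponseModel("linear", {"c": LINEAR_SLOPE})
        lof = rf.lack_of_fit(iron, gen)
        assert lof.ms_pure == pytest.approx(PURE_ERROR_MS, rel=1e-12)
        assert lof.df_pure == 38
        assert lof.F == pytest.approx(14.928, abs=0.01)

    def test_zero_pure_error_raises(self):
        groups = tuple(rf.DoseGroup.from_summary(d, 2.0 * d, 0.0, 4) for d in (0.0, 1.0, 2.0))
        ds = rf.DoseResponseDataset(label="noiseless", groups=groups)
        with pytest.raises(DegenerateVarianceError):
            rf.lack_of_fit(ds, rf.DoseResponseModel("linear", {"c": 2.0}))


class TestSelectModel:
    def test_linear_generator_selects_linear(self):
        rng = np.random.default_rng(11)
        gen = rf.DoseResponseModel("linear", {"c": 12.0})
        cfg = rf.SimulationConfig(
            model=gen, doses=(0.0, 0.5, 1.0, 1.5, 2.0), n_per_dose=40, dispersion=10.0, seed=11
        )
        ds = rf.simulate_experiment(cfg)
        sel = rf.select_model(ds)
        assert sel.model.family == "linear"
        assert sel.accepted

    def test_single_candidate_returned(self, iron):
        sel = rf.select_model(iron, candidates=("quadratic",))
        assert sel.model.family == "quadratic"

    def test_no_survivor_returns_lowest_sse_with_warning(self, iron):
        sel = rf.select_model(iron)
        assert not sel.accepted
        assert sel.warning is not None and "lack-of-fit" in sel.warning
        fits = [rf.fit_model(iron, fam) for fam in rf.FAMILIES]
        assert sel.sse == min(f.sse for f in fits)

    def test_empty_candidates_rejected(self, iron):
        with pytest.raises(DataValidationError):
            rf.select_model(iron, candidates=())


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_fitted_curves_are_monotone_on_dose_grid(seed):
    """Every constrained fitted curve is non-decreasing on [0, 5] Gy."""
    rng = np.random.default_rng(seed)
    from conftest import random_raw_dataset

    ds = random_raw_dataset(rng)
    grid = np.linspace(0.0, 5.0, 201)
    for fam in rf.FAMILIES:
        try:
            fit = rf.fit_model(ds, fam)
        except (UnderdeterminedFitError, DegenerateDataError, DegenerateVarianceError):
            continue
        y = np.asarray(rf.evaluate(fit.model, grid))
        assert np.all(np.diff(y) >= -1e-9)
        if fit.constrain_origin:
            assert rf.evaluate(fit.model, 0.0) == 0.0
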