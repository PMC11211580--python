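import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pscea.curves import DigitizedCurve
from pscea.survival import (
    FAMILY_ORDER,
    InputError,
    ParameterError,
    ParametricFit,
    SelectionError,
    enforce_endpoint_coherence,
    fit_all,
    fit_curve,
    median_survival,
    select_by_aic,
    survival_value,
)
from pscea.synthetic import CurveRecipe, generate_km_points


def make_fit(family, **params):
    return ParametricFit(
        family=family, params=params, k=len(params), rss=0.0, aic=0.0, n=0
    )


# reference parameter sets, one per family
REFERENCE_PARAMS = {
    "exponential": {"rate": 0.1},
    "weibull": {"shape": 1.3, "scale": 7.0},
    "gamma": {"shape": 1.5, "scale": 4.0},
    "gengamma": {"a": 1.5, "c": 1.2, "scale": 4.0},
    "gompertz": {"shape": 0.08, "rate": 0.09},
    "lognormal": {"mu": np.log(5.6), "sigma": 0.9},
    "loglogistic": {"shape": 1.8, "scale": 5.0},
}


class TestSurvivalValue:
    def test_lognormal_median_is_exp_mu(self):
        fit = make_fit("lognormal", mu=np.log(5.6), sigma=0.8)
        assert survival_value(fit, 5.6) == pytest.approx(0.5)

    @pytest.mark.parametrize("family", FAMILY_ORDER)
    def test_survival_starts_at_one(self, family):
        assert survival_value(make_fit(family, **REFERENCE_PARAMS[family]), 0.0) == 1.0

    def test_lognormal_sigma_calibrated_to_landmark(self):
        # sigma chosen so that S(12) = 0.248 given a 5.6-month median
        mu = np.log(5.6)
        z = stats.norm.ppf(1 - 0.248)
        sigma = (np.log(12.0) - mu) / z
        fit = make_fit("lognormal", mu=mu, sigma=sigma)
        assert survival_value(fit, 12.0) == pytest.approx(0.248, abs=1e-12)

    def test_negative_time_is_domain_error(self):
        with pytest.raises(ValueError):
            survival_value(make_fit("exponential", rate=0.1), -1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            survival_value(make_fit("lognormal", mu=0.0, sigma=-1.0), 1.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        family=st.sampled_from(FAMILY_ORDER),
        raw=st.lists(st.floats(-1.5, 1.5), min_size=3, max_size=3),
    )
    def test_any_parameterization_yields_valid_survival(self, family, raw):
        """S(0)=1, bounded in [0,1], non-increasing — for every family and
        random (positive-through-exp) parameters."""
        names = {
            "exponential": ("rate",),
            "weibull": ("shape", "scale"),
            "gamma": ("shape", "scale"),
            "gengamma": ("a", "c", "scale"),
            "gompertz": ("shape", "rate"),
            "lognormal": ("mu", "sigma"),
            "loglogistic": ("shape", "scale"),
        }[family]
        params = {}
        for name, x in zip(names, raw):
            # shape of gompertz and mu of lognormal may be any real
            free = (family == "gompertz" and name == "shape") or (
                family == "lognormal" and name == "mu"
            )
            params[name] = x if free else float(np.exp(x))
        fit = make_fit(family, **params)
        t = np.linspace(0, 60, 121)
        s = survival_value(fit, t)
        assert s[0] == 1.0
        assert np.all((s >= 0) & (s <= 1))
        assert np.all(np.diff(s) <= 1e-12)


class TestFitCurve:
    def test_exponential_rate_recovered_from_noiseless_points(self):
        c = generate_km_points(
            CurveRecipe("exponential", {"rate": 0.1}, n_points=40, t_max=30, noise_sd=0)
        )
        fit = fit_curve(c, "exponential")
        assert fit.params["rate"] == pytest.approx(0.1, abs=1e-3)

    @pytest.mark.parametrize("family", FAMILY_ORDER)
    def test_noiseless_self_consistency_all_families(self, family):
        """Fitting noiseless data generated by family F recovers the
        generating parameters within 1e-3 relative error."""
        truth = REFERENCE_PARAMS[family]
        c = generate_km_points(
            CurveRecipe(family, truth, n_points=40, t_max=18, noise_sd=0)
        )
        fit = fit_curve(c, family)
        for name, value in truth.items():
            assert fit.params[name] == pytest.approx(value, rel=1e-3, abs=1e-6)

    def test_lognormal_mu_recovered(self):
        c = generate_km_points(
            CurveRecipe(
                "lognormal", {"mu": np.log(5.6), "sigma": 0.9}, 40, 18.0, 0.0, 0
            )
        )
        fit = fit_curve(c, "lognormal")
        assert fit.params["mu"] == pytest.approx(np.log(5.6), abs=1e-3)

    def test_underdetermined_curve_is_input_error(self):
        c = DigitizedCurve(arm="a", endpoint="PFS", times=[1.0, 2.0], survival=[0.9, 0.8])
        with pytest.raises(InputError):
            fit_curve(c, "gengamma")

    def test_unknown_family_rejected(self):
        c = generate_km_points(CurveRecipe("exponential", {"rate": 0.1}, 10, 10, 0))
        with pytest.raises(ValueError):
            fit_curve(c, "spline")


class TestSelection:
    def test_smallest_aic_wins(self):
        fits = [
            ParametricFit("exponential", {"rate": 0.1}, 1, 1.0, 10.0, 40),
            ParametricFit("lognormal", {"mu": 1.0, "sigma": 1.0}, 2, 0.5, 4.0, 40),
        ]
        assert select_by_aic(fits).best == "lognormal"

    def test_tie_broken_by_fewer_parameters_then_family_order(self):
        fits = [
            ParametricFit("gengamma", {"a": 1, "c": 1, "scale": 1}, 3, 1.0, 5.0, 40),
            ParametricFit("weibull", {"shape": 1, "scale": 1}, 2, 1.0, 5.0, 40),
            ParametricFit("gamma", {"shape": 1, "scale": 1}, 2, 1.0, 5.0, 40),
        ]
        assert select_by_aic(fits).best == "weibull"

    def test_single_fit_selected(self):
        only = ParametricFit("gamma", {"shape": 1, "scale": 1}, 2, 1.0, 5.0, 40)
        assert select_by_aic([only]).best == "gamma"

    def test_no_fits_is_selection_error(self):
        with pytest.raises(SelectionError):
            select_by_aic([])

    def test_low_noise_lognormal_data_selects_lognormal(self):
        c = generate_km_points(
            CurveRecipe(
                "lognormal", {"mu": np.log(5.6), "sigma": 1.1}, 40, 18.0, 0.005, 7
            )
        )
        sel = select_by_aic(*fit_all(c))
        assert sel.best == "lognormal"


class TestMedian:
    def test_lognormal_closed_form(self):
        assert median_survival(make_fit("lognormal", mu=np.log(5.6), sigma=0.4)) == (
            pytest.approx(5.6)
        )

    def test_exponential_closed_form(self):
        assert median_survival(make_fit("exponential", rate=0.2)) == pytest.approx(
            np.log(2) / 0.2
        )

    def test_gompertz_matches_dense_grid_inversion(self):
        fit = make_fit("gompertz", shape=0.08, rate=0.09)
        grid = np.arange(1e-4, 60, 1e-4)
        brute = grid[np.argmin(np.abs(survival_value(fit, grid) - 0.5))]
        assert median_survival(fit) == pytest.approx(brute, abs=1e-3)

    def test_plateau_above_half_has_no_median(self):
        # strongly negative Gompertz shape: survival plateaus above 0.5
        assert median_survival(make_fit("gompertz", shape=-1.0, rate=0.1)) is None

    @pytest.mark.parametrize("family", FAMILY_ORDER)
    def test_median_inverts_survival(self, family):
        fit = make_fit(family, **REFERENCE_PARAMS[family])
        med = median_survival(fit)
        assert med is not None
        assert abs(survival_value(fit, med) - 0.5) < 1e-6


class TestCoherence:
    def test_identical_fits_have_no_violations(self):
        fit = make_fit("lognormal", mu=np.log(8), sigma=1.0)
        rep = enforce_endpoint_coherence(fit, fit, np.linspace(0, 60, 121))
        assert rep.coherent
        assert rep.max_gap <= 1e-12

    def test_os_uniformly_above_pfs_is_coherent(self):
        pfs = make_fit("lognormal", mu=np.log(5.6), sigma=1.0)
        os_ = make_fit("lognormal", mu=np.log(11.0), sigma=1.0)
        rep = enforce_endpoint_coherence(os_, pfs, np.linspace(0, 120, 241))
        assert rep.coherent

    def test_crossing_curves_flagged_exactly_where_closed_forms_cross(self):
        # exponentials cross nowhere, so use different-sigma lognormals with
        # equal medians: S_os < S_pfs exactly for t > median
        pfs = make_fit("lognormal", mu=np.log(6.0), sigma=1.2)
        os_ = make_fit("lognormal", mu=np.log(6.0), sigma=0.6)
        grid = np.linspace(0.5, 24, 48)
        rep = enforce_endpoint_coherence(os_, pfs, grid)
        expected = grid[
            np.array([survival_value(os_, t) < survival_value(pfs, t) - 1e-12 for t in grid])
        ]
        np.testing.assert_array_equal(rep.violation_times, expected)
        assert rep.violation_times.size > 0
        assert rep.violation_times.min() > 6.0
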