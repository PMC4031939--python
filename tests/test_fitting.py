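"""Weighted least squares, model comparison, t-tests, sensitivity mechanics."""

import math

import numpy as np
import pytest

from retkin.fitting import (
    compare_models,
    FitResult,
    fit_model,
    group_coefficient_ttest,
    sensitivity_to_fixed,
    weighted_wss,
)
from retkin.model import TracerCurve
from retkin.solver import simulate_tracer


def _curve(times, values, fsd=0.05):
    return TracerCurve(
        times=np.asarray(times, float),
        values=np.asarray(values, float),
        weight_fsd=fsd,
    )


def _fake_fit(wss, n, k):
    return FitResult(
        estimates={},
        fsds={},
        covariance=np.zeros((0, 0)),
        param_names=[],
        wss=wss,
        n_obs=n,
        n_free=k,
        aic=n * math.log(wss / n) + 2 * k,
        success=True,
        message="",
    )


class TestWeightedWss:
    def test_perfect_prediction_is_zero(self):
        c = _curve([0.1, 0.2], [0.04, 0.03])
        assert weighted_wss(c, c) == 0.0

    def test_hand_computed_single_point(self):
        obs = _curve([0.1], [0.04])
        pred = _curve([0.1], [0.042])
        assert weighted_wss(obs, pred) == pytest.approx(1.0)

    def test_scale_invariance_of_relative_weighting(self):
        obs = _curve([0.1, 0.2, 0.4], [0.04, 0.03, 0.02])
        pred = _curve([0.1, 0.2, 0.4], [0.041, 0.029, 0.021])
        obs2 = _curve(obs.times, 2 * obs.values)
        pred2 = _curve(pred.times, 2 * pred.values)
        assert weighted_wss(obs, pred) == pytest.approx(weighted_wss(obs2, pred2))

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="time grid"):
            weighted_wss(_curve([0.1], [0.04]), _curve([0.2], [0.04]))


class TestCompareModels:
    def test_identical_fits_not_justified(self):
        small, big = _fake_fit(2.0, 14, 4), _fake_fit(2.0, 14, 5)
        cmp = compare_models(small, big)
        assert cmp.f_statistic == pytest.approx(0.0)
        assert cmp.delta_aic == pytest.approx(2.0)
        assert cmp.verdict == "not justified"

    def test_hand_computed_f_statistic(self):
        cmp = compare_models(_fake_fit(2.0, 14, 4), _fake_fit(1.0, 14, 5))
        assert cmp.f_statistic == pytest.approx(9.0)

    def test_tenfold_wss_drop_is_justified(self):
        small, big = _fake_fit(1.0, 14, 4), _fake_fit(0.1, 14, 5)
        cmp = compare_models(small, big)
        assert cmp.delta_aic == pytest.approx(14 * math.log(0.1) + 2, rel=1e-9)
        assert cmp.verdict == "justified"

    def test_swapped_roles_rejected_not_sign_flipped(self):
        small, big = _fake_fit(2.0, 14, 4), _fake_fit(1.0, 14, 5)
        with pytest.raises(ValueError, match="bigger nested model"):
            compare_models(big, small)

    def test_different_data_sizes_rejected(self):
        with pytest.raises(ValueError, match="same data"):
            compare_models(_fake_fit(2.0, 14, 4), _fake_fit(1.0, 12, 5))


class TestGroupTTest:
    def test_uptake_coefficient_clearly_different_between_groups(self):
        r = group_coefficient_ttest(169.4, 0.04, 60.3, 0.07)
        assert r.t_statistic == pytest.approx(
            109.1 / math.sqrt(6.776**2 + 4.221**2), rel=1e-3
        )
        assert r.significant

    def test_equal_values_not_significant(self):
        r = group_coefficient_ttest(5.0, 0.1, 5.0, 0.1)
        assert r.t_statistic == 0.0
        assert not r.significant

    def test_tissue_release_coefficient_not_different(self):
        r = group_coefficient_ttest(5.52, 0.07, 5.06, 0.14)
        assert abs(r.t_statistic) == pytest.approx(0.57, abs=0.03)
        assert not r.significant

    def test_zero_sems_with_different_values_rejected(self):
        with pytest.raises(ValueError, match="SEM"):
            group_coefficient_ttest(5.0, 0.0, 6.0, 0.0)


class TestFitModel:
    def test_zero_free_parameters_rejected(self, oil_model, schedule):
        curve = simulate_tracer(oil_model, 1.0, schedule)
        with pytest.raises(ValueError, match="at least one"):
            fit_model(oil_model, curve, [])

    def test_non_positive_start_rejected(self, vara_model, schedule):
        curve = simulate_tracer(vara_model, 1.0, schedule)
        # L(5,2) is 0 in this preset, so its default start is invalid
        with pytest.raises(ValueError, match="positive"):
            fit_model(vara_model, curve, ["L(5,2)"])

    def test_fit_is_deterministic_for_identical_starts(self, oil_model, schedule):
        curve = simulate_tracer(oil_model, 1.0, schedule)
        kw = dict(starts={"L(6,5)": 80.0}, max_nfev=8)
        r1 = fit_model(oil_model, curve, ["L(6,5)"], **kw)
        r2 = fit_model(oil_model, curve, ["L(6,5)"], **kw)
        assert r1.estimates == r2.estimates
        assert r1.wss == r2.wss

    def test_single_coefficient_recovered_from_perturbed_start(
        self, oil_model, schedule
    ):
        curve = simulate_tracer(oil_model, 1.0, schedule)
        res = fit_model(oil_model, curve, ["L(6,5)"], starts={"L(6,5)": 90.0})
        assert res.success
        assert res.estimates["L(6,5)"] == pytest.approx(60.3, rel=1e-3)
        assert res.fsds["L(6,5)"] < 0.01
        assert res.identifiable["L(6,5)"]

    def test_estimates_never_negative(self, oil_model, schedule):
        curve = simulate_tracer(oil_model, 1.0, schedule)
        res = fit_model(
            oil_model,
            curve,
            ["L(0,6):before"],
            starts={"L(0,6):before": 0.5},
        )
        assert res.estimates["L(0,6):before"] >= 0.0


class TestSensitivity:
    def test_zero_factor_changes_nothing(self, oil_model, schedule):
        curve = simulate_tracer(oil_model, 1.0, schedule)
        ref = _fake_fit(1.0, 14, 1)
        ref.estimates = {"L(6,5)": 60.3}
        ref.param_names = ["L(6,5)"]
        tab = sensitivity_to_fixed(
            oil_model, curve, ["L(2,1)"], ["L(6,5)"], factor=0.0, reference=ref
        )
        assert (tab.to_numpy() == 0.0).all()

    def test_disconnected_coefficient_has_no_influence(self, oil_model, schedule):
        # add an isolated pool with its own loss: nothing flows into it, so
        # scaling its loss cannot move any estimate
        d = oil_model.to_dict()
        d["compartments"].append(9)
        d["coefficients"].append(
            {"to": 0, "from": 9, "value": 1.0, "status": "fixed"}
        )
        from retkin.model import CompartmentalModel

        model = CompartmentalModel.from_dict(d)
        curve = simulate_tracer(model, 1.0, schedule)
        ref = fit_model(model, curve, ["L(6,5)"])
        tab = sensitivity_to_fixed(
            model, curve, ["L(0,9)"], ["L(6,5)"], factor=0.5, reference=ref
        )
        assert np.nanmax(np.abs(tab.to_numpy())) < 1e-6
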