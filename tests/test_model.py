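"""Model definition: rate matrix, validation, parameter addressing, round-trip."""

import numpy as np
import pytest

from retkin.model import (
    CompartmentalModel,
    DelayElement,
    TimeInterrupt,
    TracerCurve,
    TransferCoefficient,
    build_rate_matrix,
    parse_param_name,
)
from retkin import io as rio

from conftest import tc


class TestRateMatrix:
    def test_oil_pre_interrupt_entries(self, oil_model):
        mat = build_rate_matrix(oil_model, t=1.0)
        assert mat.loc[6, 5] == pytest.approx(60.3)
        assert mat.loc[5, 6] == pytest.approx(0.60)
        assert mat.loc[6, 6] == pytest.approx(-(0.60 + 0.004))

    def test_oil_post_interrupt_diagonal(self, oil_model):
        mat = build_rate_matrix(oil_model, t=10.0)
        assert mat.loc[6, 6] == pytest.approx(-(0.60 + 0.197))

    def test_single_pool_matrix(self):
        m = CompartmentalModel(
            compartments={1},
            coefficients=dict([tc(0, 1, 0.7)]),
            input_compartment=1,
            observation={1},
        )
        mat = build_rate_matrix(m)
        assert mat.shape == (1, 1)
        assert mat.loc[1, 1] == pytest.approx(-0.7)

    def test_delay_feed_counts_as_exit_not_transfer(self, oil_model):
        mat = build_rate_matrix(oil_model, t=0.0)
        # L(3,2) leaves 2 into the delay: on the diagonal, not as a (3,2) entry
        assert mat.loc[2, 2] == pytest.approx(-(0.43 + 0.44 + 18.6))
        assert 3 not in mat.index
        # the delay emergence into 10 is solver forcing, absent from the matrix
        assert mat.loc[10, 2] == 0.0


class TestValidation:
    def test_negative_coefficient_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            TransferCoefficient(6, 5, -1.0)

    def test_self_transfer_rejected(self):
        with pytest.raises(ValueError, match="self-transfer"):
            TransferCoefficient(5, 5, 1.0)

    def test_unknown_compartment_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            CompartmentalModel(
                compartments={1},
                coefficients=dict([tc(0, 9, 1.0)]),
                input_compartment=1,
                observation={1},
            )

    def test_delay_needs_single_feeder(self):
        with pytest.raises(ValueError, match="exactly one feeding"):
            CompartmentalModel(
                compartments={1, 2},
                coefficients=dict([tc(0, 1, 1.0)]),
                delays={3: DelayElement(3, 0.1, upstream=1, downstream=2)},
                input_compartment=1,
                observation={2},
            )

    def test_duplicate_interrupt_rejected(self, oil_model):
        d = oil_model.to_dict()
        d["interrupts"] = d["interrupts"] * 2
        with pytest.raises(ValueError, match="multiple interrupts"):
            CompartmentalModel.from_dict(d)

    def test_zero_delay_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            DelayElement(3, 0.0, upstream=1, downstream=2)


class TestParameterAddressing:
    def test_parse_names(self):
        assert parse_param_name("L(6,5)") == ("L", 6, 5, None)
        assert parse_param_name("L(0,6):after") == ("L", 0, 6, "after")
        assert parse_param_name("DT(3)") == ("DT", 3)
        with pytest.raises(ValueError):
            parse_param_name("X(1)")

    def test_interrupted_coefficient_requires_segment(self, oil_model):
        with pytest.raises(KeyError, match="before"):
            oil_model.parameter_value("L(0,6)")
        assert oil_model.parameter_value("L(0,6):before") == pytest.approx(0.004)
        assert oil_model.parameter_value("L(0,6):after") == pytest.approx(0.197)

    def test_with_values_both_segments(self, oil_model):
        m = oil_model.with_values(
            {"L(0,6):before": 0.01, "L(0,6):after": 0.3, "L(6,5)": 70.0}
        )
        assert m.coefficient_value(0, 6, 1.0) == pytest.approx(0.01)
        assert m.coefficient_value(0, 6, 9.0) == pytest.approx(0.3)
        assert m.coefficient_value(6, 5, 0.0) == pytest.approx(70.0)
        # original untouched
        assert oil_model.coefficient_value(0, 6, 1.0) == pytest.approx(0.004)

    def test_with_values_delay_duration(self, oil_model):
        m = oil_model.with_values({"DT(3)": 0.07})
        assert m.delays[3].duration == pytest.approx(0.07)

    def test_freeze_interrupts(self, oil_model):
        before = oil_model.freeze_interrupts("before")
        after = oil_model.freeze_interrupts("after")
        assert not before.interrupts and not after.interrupts
        assert before.coefficient_value(0, 6, 12.0) == pytest.approx(0.004)
        assert after.coefficient_value(0, 6, 0.0) == pytest.approx(0.197)


class TestSerialization:
    def test_yaml_round_trip_is_lossless(self, oil_model, tmp_path):
        p = tmp_path / "oil.yaml"
        rio.save_model(oil_model, p)
        again = rio.load_model(p)
        assert again.to_dict() == oil_model.to_dict()

    def test_observation_map_is_plasma_pair(self, oil_model, vara_model):
        assert oil_model.observation == frozenset({5, 10})
        assert vara_model.observation == frozenset({5, 10})


class TestTracerCurve:
    def test_rejects_non_increasing_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            TracerCurve(times=np.array([0.1, 0.1]), values=np.array([0.1, 0.2]))

    def test_rejects_out_of_range_fractions(self):
        with pytest.raises(ValueError, match="fraction"):
            TracerCurve(times=np.array([0.1]), values=np.array([1.5]))

    def test_frame_round_trip(self, tmp_path):
        c = TracerCurve(
            times=np.array([0.1, 0.2]),
            values=np.array([0.01, 0.02]),
            group="oil",
            weight_fsd=0.05,
        )
        p = tmp_path / "c.csv"
        rio.save_curve(c, p)
        back = rio.load_curve(p, group="oil")
        np.testing.assert_allclose(back.times, c.times)
        np.testing.assert_allclose(back.values, c.values)
        np.testing.assert_allclose(back.weight_fsd, c.weight_fsd)

    def test_load_curve_reports_offending_rows(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "group,time_days,fraction_of_dose\n"
            "oil,0.2,0.01\noil,0.1,0.02\noil,0.3,0.01\n"
        )
        with pytest.raises(ValueError, match="not strictly increasing"):
            rio.load_curve(p)
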