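import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluidloop.errors import (
    CapacityExceededError,
    InvalidArgumentError,
    InvalidConfigurationError,
)
from fluidloop.kinematics import (
    STANDARD_SYRINGES,
    DispenseErrorModel,
    PumpConfig,
    SyringeSpec,
    flow_rate_to_step_period,
    simulate_dispense,
    step_volume,
    steps_to_volume,
    volume_to_steps,
)


class TestSyringeSpec:
    def test_valid(self, half_ul_syringe):
        assert half_ul_syringe.cross_section_area == pytest.approx(100.0, rel=1e-4)

    @pytest.mark.parametrize("field,value", [
        ("inner_diameter", 0.0),
        ("inner_diameter", -1.0),
        ("capacity", 0.0),
        ("plunger_travel", -5.0),
    ])
    def test_nonpositive_geometry_rejected(self, field, value):
        kwargs = dict(inner_diameter=10.0, capacity=1000.0, plunger_travel=50.0)
        kwargs[field] = value
        with pytest.raises(InvalidConfigurationError):
            SyringeSpec(**kwargs)

    def test_capacity_swept_volume_consistency(self):
        # area ~78.5 mm^2 x 10 mm travel = 785 uL; 5000 uL capacity impossible
        with pytest.raises(InvalidConfigurationError):
            SyringeSpec(inner_diameter=10.0, capacity=5000.0, plunger_travel=10.0)

    def test_standard_syringes_consistent(self):
        for spec in STANDARD_SYRINGES.values():
            swept = spec.cross_section_area * spec.plunger_travel
            assert spec.capacity <= swept * 1.05


class TestPumpConfig:
    def test_address_range(self):
        PumpConfig(address=0)
        PumpConfig(address=127)
        with pytest.raises(InvalidConfigurationError):
            PumpConfig(address=128)
        with pytest.raises(InvalidConfigurationError):
            PumpConfig(address=-1)

    def test_bad_drivetrain(self):
        with pytest.raises(InvalidConfigurationError):
            PumpConfig(steps_per_revolution=0)
        with pytest.raises(InvalidConfigurationError):
            PumpConfig(gear_ratio=0.0)


class TestStepVolume:
    def test_hand_geometry_oracle(self, half_ul_syringe, default_pump):
        # area 100 mm^2, 1 mm lead / 200 steps -> 0.005 mm travel/step
        # -> 0.5 mm^3 = 0.5 uL per step
        assert step_volume(half_ul_syringe, default_pump) == pytest.approx(0.5, rel=1e-4)

    def test_monotone_decreasing_in_steps_per_rev(self, half_ul_syringe):
        sv = [
            step_volume(half_ul_syringe, PumpConfig(steps_per_revolution=n))
            for n in (100, 200, 400, 3200)
        ]
        assert all(a > b for a, b in zip(sv, sv[1:]))
        assert sv[-1] < 0.04  # -> 0 in the limit

    def test_gear_ratio_halves_step_volume(self, half_ul_syringe):
        sv1 = step_volume(half_ul_syringe, PumpConfig(gear_ratio=1.0))
        sv2 = step_volume(half_ul_syringe, PumpConfig(gear_ratio=2.0))
        assert sv2 == pytest.approx(sv1 / 2)

    def test_monotone_in_diameter_and_lead(self, default_pump):
        small = SyringeSpec(inner_diameter=5.0, capacity=500.0, plunger_travel=30.0)
        big = SyringeSpec(inner_diameter=10.0, capacity=2000.0, plunger_travel=30.0)
        assert step_volume(big, default_pump) > step_volume(small, default_pump)
        assert step_volume(small, PumpConfig(lead_pitch=2.0)) > step_volume(
            small, PumpConfig(lead_pitch=1.0)
        )


class TestVolumeSteps:
    def test_zero(self, half_ul_syringe, default_pump):
        assert volume_to_steps(0.0, half_ul_syringe, default_pump) == 0
        assert steps_to_volume(0, half_ul_syringe, default_pump) == 0.0

    def test_division_oracle(self, half_ul_syringe, default_pump):
        assert volume_to_steps(100.0, half_ul_syringe, default_pump) == 200

    def test_round_half_even(self, half_ul_syringe, default_pump):
        # 100.2 / 0.5 = 200.4 -> 200; exact halves round to the even step
        assert volume_to_steps(100.2, half_ul_syringe, default_pump) == 200
        sv = step_volume(half_ul_syringe, default_pump)
        assert volume_to_steps(sv * 200.5, half_ul_syringe, default_pump) == 200
        assert volume_to_steps(sv * 201.5, half_ul_syringe, default_pump) == 202

    def test_multiplication_oracle(self, half_ul_syringe, default_pump):
        assert steps_to_volume(200, half_ul_syringe, default_pump) == pytest.approx(100.0)

    def test_errors(self, half_ul_syringe, default_pump):
        with pytest.raises(InvalidArgumentError):
            volume_to_steps(-1.0, half_ul_syringe, default_pump)
        with pytest.raises(CapacityExceededError):
            volume_to_steps(half_ul_syringe.capacity + 1, half_ul_syringe, default_pump)
        with pytest.raises(InvalidArgumentError):
            steps_to_volume(-1, half_ul_syringe, default_pump)

    @given(volume=st.floats(min_value=0.0, max_value=5000.0,
                            allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_within_half_step(self, volume):
        syringe = SyringeSpec(
            inner_diameter=11.283791670955125, capacity=5000.0, plunger_travel=57.0
        )
        pump = PumpConfig()
        sv = step_volume(syringe, pump)
        back = steps_to_volume(volume_to_steps(volume, syringe, pump), syringe, pump)
        assert abs(back - volume) <= sv / 2 + 1e-9


class TestFlowRate:
    def test_arithmetic_oracle(self, half_ul_syringe, default_pump):
        # 0.5 uL/step at 300 uL/min -> 600 steps/min -> 100 ms/step
        assert flow_rate_to_step_period(300.0, half_ul_syringe, default_pump) == (
            pytest.approx(100.0)
        )

    def test_doubling_rate_halves_period(self, half_ul_syringe, default_pump):
        p1 = flow_rate_to_step_period(150.0, half_ul_syringe, default_pump)
        p2 = flow_rate_to_step_period(300.0, half_ul_syringe, default_pump)
        assert p1 == pytest.approx(2 * p2)

    @pytest.mark.parametrize("rate", [0.0, -5.0])
    def test_nonpositive_rate(self, rate, half_ul_syringe, default_pump):
        with pytest.raises(InvalidArgumentError):
            flow_rate_to_step_period(rate, half_ul_syringe, default_pump)


class TestSimulateDispense:
    def test_identity_model_exact(self, half_ul_syringe, default_pump):
        model = DispenseErrorModel(step_quantization=True, seed=0)
        measured = simulate_dispense(500.0, half_ul_syringe, default_pump, model)
        # exact up to float rounding of the 0.5 uL/step geometry
        assert measured == pytest.approx(500.0, abs=1e-9)

    def test_identity_no_quantization_is_identity(self, half_ul_syringe, default_pump):
        model = DispenseErrorModel(step_quantization=False, seed=0)
        assert simulate_dispense(123.456, half_ul_syringe, default_pump, model) == (
            pytest.approx(123.456)
        )

    @pytest.mark.parametrize("nominal", [0.1, 17.3, 100.25, 4999.9])
    def test_quantization_bound(self, nominal, half_ul_syringe, default_pump):
        model = DispenseErrorModel(step_quantization=True, seed=0)
        measured = simulate_dispense(nominal, half_ul_syringe, default_pump, model)
        sv = step_volume(half_ul_syringe, default_pump)
        assert abs(measured - nominal) <= sv / 2 + 1e-12

    def test_seed_determinism(self, half_ul_syringe, default_pump):
        kwargs = dict(per_step_jitter_sd=0.01, diameter_tolerance=0.02, seed=42)
        a = [
            simulate_dispense(250.0, half_ul_syringe, default_pump,
                              DispenseErrorModel(**kwargs))
            for _ in range(1)
        ]
        m1, m2 = DispenseErrorModel(**kwargs), DispenseErrorModel(**kwargs)
        seq1 = [simulate_dispense(250.0, half_ul_syringe, default_pump, m1) for _ in range(5)]
        seq2 = [simulate_dispense(250.0, half_ul_syringe, default_pump, m2) for _ in range(5)]
        assert seq1 == seq2
        assert seq1[0] == a[0]

    def test_reset_replays(self, half_ul_syringe, default_pump):
        model = DispenseErrorModel(per_step_jitter_sd=0.01, seed=3)
        first = simulate_dispense(250.0, half_ul_syringe, default_pump, model)
        model.reset()
        assert simulate_dispense(250.0, half_ul_syringe, default_pump, model) == first

    def test_jitter_parameter_recovery(self, half_ul_syringe, default_pump):
        # aggregate sd of an n-step dispense = jitter_sd * sqrt(n) * step_vol
        jitter_sd = 0.05
        nominal = 250.0  # 500 steps of 0.5 uL
        model = DispenseErrorModel(per_step_jitter_sd=jitter_sd, seed=11)
        draws = np.array([
            simulate_dispense(nominal, half_ul_syringe, default_pump, model)
            for _ in range(1000)
        ])
        expected_sd = jitter_sd * math.sqrt(500) * 0.5
        assert draws.std(ddof=1) == pytest.approx(expected_sd, rel=0.10)

    def test_backlash_on_direction_change(self, half_ul_syringe, default_pump):
        model = DispenseErrorModel(backlash_steps=4, seed=0)
        infuse1 = simulate_dispense(100.0, half_ul_syringe, default_pump, model, direction=1)
        infuse2 = simulate_dispense(100.0, half_ul_syringe, default_pump, model, direction=1)
        withdraw = simulate_dispense(100.0, half_ul_syringe, default_pump, model, direction=-1)
        assert infuse1 == pytest.approx(100.0)
        assert infuse2 == pytest.approx(100.0)
        assert withdraw == pytest.approx(100.0 - 4 * 0.5)

    def test_capacity_enforced(self, half_ul_syringe, default_pump):
        model = DispenseErrorModel(seed=0)
        with pytest.raises(CapacityExceededError):
            simulate_dispense(6000.0, half_ul_syringe, default_pump, model)
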