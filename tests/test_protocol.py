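import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluidloop.clock import SimulatedClock
from fluidloop.errors import InvalidArgumentError, ValidationError
from fluidloop.kinematics import STANDARD_SYRINGES, PumpConfig
from fluidloop.network import SimulatedBus
from fluidloop.protocol import (
    ChamberModel,
    EventSource,
    Hooks,
    Protocol,
    ProtocolStep,
    StepKind,
    execute,
    load_protocol,
    mitotic_fixation_protocol,
    overflow_dispense,
    protocol_from_dict,
    protocol_to_dict,
    save_protocol,
    total_duration,
    validate,
    wait_duration,
)


def make_bus(n_pumps=4, clock=None):
    bus = SimulatedBus(clock or SimulatedClock())
    for addr in range(n_pumps):
        bus.attach_pump(addr, STANDARD_SYRINGES["5mL"], PumpConfig(address=addr))
    return bus


class TestStepValidation:
    def test_motion_requires_fields(self):
        with pytest.raises(InvalidArgumentError):
            ProtocolStep(kind=StepKind.INFUSE, pump=0, volume=100.0)  # no rate
        with pytest.raises(InvalidArgumentError):
            ProtocolStep(kind=StepKind.WAIT, duration=0.0)
        with pytest.raises(InvalidArgumentError):
            ProtocolStep(kind=StepKind.WAIT, duration=5.0, repeat=0)

    def test_empty_protocol_rejected(self):
        with pytest.raises(InvalidArgumentError):
            Protocol(name="empty", steps=[])


class TestValidate:
    def test_published_sequence_clean(self):
        protocol = mitotic_fixation_protocol()
        assert validate(protocol, make_bus()) == []

    def test_capacity_finding(self):
        step = ProtocolStep(kind=StepKind.INFUSE, pump=0, volume=2000.0, rate=500.0)
        protocol = Protocol(
            name="p", steps=[step], chamber=ChamberModel(working_volume=5000.0)
        )
        bus = SimulatedBus(SimulatedClock())
        bus.attach_pump(0, STANDARD_SYRINGES["1mL"], PumpConfig())
        findings = validate(protocol, bus)
        assert any("capacity" in f for f in findings)

    def test_unknown_pump_finding(self):
        step = ProtocolStep(kind=StepKind.INFUSE, pump=9, volume=100.0, rate=500.0)
        findings = validate(Protocol(name="p", steps=[step]), make_bus())
        assert any("unknown pump 9" in f for f in findings)

    def test_overfill_finding(self):
        steps = [
            ProtocolStep(kind=StepKind.INFUSE, pump=0, volume=900.0, rate=500.0),
            ProtocolStep(kind=StepKind.INFUSE, pump=1, volume=900.0, rate=500.0),
        ]
        protocol = Protocol(
            name="p", steps=steps, chamber=ChamberModel(working_volume=1000.0)
        )
        findings = validate(protocol, make_bus())
        assert any("overfill" in f for f in findings)


class TestTotalDuration:
    def test_published_sequence_155_min(self):
        protocol = mitotic_fixation_protocol()
        validate(protocol, make_bus())
        # incubation (WAIT) times: 15 + 3x10 + 30 + 60 + 2x10 = 155 exactly
        assert wait_duration(protocol) == pytest.approx(155.0)
        # motion time at the default high flow rate is negligible
        assert total_duration(protocol) == pytest.approx(155.0, abs=1.0)

    def test_motion_only_arithmetic(self):
        step = ProtocolStep(kind=StepKind.INFUSE, pump=0, volume=500.0, rate=500.0)
        protocol = Protocol(name="p", steps=[step])
        validate(protocol, make_bus())
        assert total_duration(protocol) == pytest.approx(1.0)

    def test_repeat_contribution(self):
        step = ProtocolStep(kind=StepKind.WAIT, duration=10.0, repeat=3)
        protocol = Protocol(name="p", steps=[step])
        validate(protocol)
        assert total_duration(protocol) == pytest.approx(30.0)

    def test_await_event_contributes_zero(self):
        steps = [
            ProtocolStep(kind=StepKind.AWAIT_EVENT),
            ProtocolStep(kind=StepKind.WAIT, duration=5.0),
        ]
        protocol = Protocol(name="p", steps=steps)
        validate(protocol)
        assert total_duration(protocol) == pytest.approx(5.0)

    def test_unvalidated_protocol_rejected(self):
        protocol = Protocol(
            name="p", steps=[ProtocolStep(kind=StepKind.WAIT, duration=1.0)]
        )
        with pytest.raises(ValidationError):
            total_duration(protocol)


class TestOverflowDispense:
    def test_paper_loading_mode(self):
        chamber = ChamberModel()
        # 100 uL aliquot flushed by 500 uL carrier -> all 100 uL delivered
        assert overflow_dispense(100.0, 500.0, chamber) == pytest.approx(100.0)

    def test_conservation_bound(self):
        assert overflow_dispense(100.0, 60.0, ChamberModel()) == pytest.approx(60.0)

    def test_zero_flush(self):
        assert overflow_dispense(100.0, 0.0, ChamberModel()) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(InvalidArgumentError):
            overflow_dispense(-1.0, 10.0, ChamberModel())


class TestExecute:
    def test_wait_then_infuse_timing(self):
        clock = SimulatedClock()
        bus = make_bus(clock=clock)
        steps = [
            ProtocolStep(kind=StepKind.WAIT, duration=15.0),
            ProtocolStep(kind=StepKind.INFUSE, pump=0, reagent="pfa",
                         volume=500.0, rate=10_000.0),
        ]
        protocol = Protocol(name="p", steps=steps)
        log = execute(protocol, bus)
        starts = [e for e in log.entries if e.outcome == "start"]
        assert starts[1].timestamp - starts[0].timestamp == pytest.approx(15.0)

    def test_await_event_delay_timing(self):
        clock = SimulatedClock()
        bus = make_bus(clock=clock)
        source = EventSource()
        source.fire(20.0)
        steps = [
            ProtocolStep(kind=StepKind.AWAIT_EVENT, post_trigger_delay=15.0),
            ProtocolStep(kind=StepKind.WAIT, duration=1.0),
        ]
        protocol = Protocol(name="p", steps=steps)
        log = execute(protocol, bus, hooks=Hooks(event_source=source))
        wait_start = next(
            e for e in log.entries if e.action == "WAIT" and e.outcome == "start"
        )
        assert wait_start.timestamp == pytest.approx(35.0)

    def test_halt_contract_on_bus_error(self):
        clock = SimulatedClock()
        bus = make_bus(clock=clock)
        wash = ProtocolStep(kind=StepKind.INFUSE, pump=1, reagent="pbs",
                            volume=200.0, rate=10_000.0)
        protocol = Protocol(name="p", steps=[wash, wash, wash])
        validate(protocol, bus)
        # wash 1 succeeds (1 dispatch + 1 status); fail wash 2's dispatch
        bus.inject_fault(0)
        orig_dispatch = bus.dispatch
        calls = {"n": 0}

        def failing_dispatch(frame):
            calls["n"] += 1
            if calls["n"] == 3:  # wash 2's INFUSE
                bus.inject_fault(1)
            return orig_dispatch(frame)

        bus.dispatch = failing_dispatch
        log = execute(protocol, bus)
        outcomes = {}
        for e in log.entries:
            outcomes[e.step_index] = e.outcome
        assert outcomes[0] == "done"
        assert outcomes[1] == "failed"
        assert outcomes[2] == "skipped"
        assert log.failed
        assert any("FAILURE" in m for _, m in log.notifications)

    def test_notify_fires_once_per_step_in_order(self):
        bus = make_bus()
        received = []
        steps = [
            ProtocolStep(kind=StepKind.NOTIFY, message="one"),
            ProtocolStep(kind=StepKind.WAIT, duration=1.0),
            ProtocolStep(kind=StepKind.NOTIFY, message="two"),
        ]
        protocol = Protocol(name="p", steps=steps)
        hooks = Hooks(notify=lambda msg, t: received.append(msg))
        execute(protocol, bus, hooks=hooks)
        assert received == ["one", "two"]

    def test_hook_exception_does_not_halt(self):
        bus = make_bus()

        def bad_hook(msg, t):
            raise RuntimeError("smtp down")

        steps = [
            ProtocolStep(kind=StepKind.NOTIFY, message="x"),
            ProtocolStep(kind=StepKind.WAIT, duration=1.0),
        ]
        log = execute(Protocol(name="p", steps=steps), bus, hooks=Hooks(notify=bad_hook))
        assert not log.failed

    def test_conservation_per_reagent(self):
        clock = SimulatedClock()
        bus = make_bus(clock=clock)
        protocol = mitotic_fixation_protocol()
        chamber = protocol.chamber
        log = execute(protocol, bus)
        assert not log.failed
        for reagent, infused in chamber.infused.items():
            extracted = chamber.extracted.get(reagent, 0.0)
            net = chamber.contents.get(reagent, 0.0)
            assert infused - extracted == pytest.approx(net, abs=1e-9)

    def test_determinism_byte_identical_logs(self):
        def one_run():
            clock = SimulatedClock()
            bus = make_bus(clock=clock)
            return execute(mitotic_fixation_protocol(), bus)

        rows1, rows2 = one_run().to_rows(), one_run().to_rows()
        assert rows1 == rows2

    def test_planner_executor_oracle_equivalence(self):
        # without AWAIT_EVENT the last log timestamp equals total_duration
        clock = SimulatedClock()
        bus = make_bus(clock=clock)
        protocol = mitotic_fixation_protocol()
        validate(protocol, bus)
        planned = total_duration(protocol)
        log = execute(protocol, bus, clock)
        assert log.last_timestamp() == pytest.approx(planned)

    @given(
        volumes=st.lists(
            st.floats(min_value=1.0, max_value=400.0,
                      allow_nan=False, allow_infinity=False),
            min_size=1, max_size=6,
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_conservation_property_random_protocols(self, volumes):
        clock = SimulatedClock()
        bus = make_bus(clock=clock)
        chamber = ChamberModel(working_volume=5000.0)
        steps = []
        for i, v in enumerate(volumes):
            steps.append(
                ProtocolStep(kind=StepKind.INFUSE, pump=i % 4, reagent=f"r{i % 2}",
                             volume=v, rate=1000.0)
            )
            if i % 2:
                steps.append(ProtocolStep(kind=StepKind.EXTRACT, volume=v / 2))
        protocol = Protocol(name="p", steps=steps, chamber=chamber)
        log = execute(protocol, bus)
        assert not log.failed
        total_in = sum(chamber.infused.values())
        total_out = sum(chamber.extracted.values())
        assert total_in - total_out == pytest.approx(chamber.total_volume, abs=1e-9)


class TestYamlRoundTrip:
    def test_round_trip(self, tmp_path):
        protocol = mitotic_fixation_protocol()
        path = tmp_path / "protocol.yaml"
        save_protocol(protocol, path)
        loaded = load_protocol(path)
        assert protocol_to_dict(loaded) == protocol_to_dict(protocol)

    def test_version_checked(self):
        with pytest.raises(InvalidArgumentError):
            protocol_from_dict({"version": 99, "steps": []})
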