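"""Protocol compilation, lockstep execution, run control, and calibration."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadpure.control import HardwareController
from quadpure.errors import CompileError, RunStateError
from quadpure.fluidics import FlowSink, FlowSource
from quadpure.protocol import (
    Protocol,
    ProtocolEngine,
    ProtocolStep,
    RunState,
    StepKind,
    compile_protocol,
    get_protocol,
    shipped_protocols,
)


def small_protocol():
    """A scaled-down purification used for run-control tests."""
    return Protocol(name="mini", steps=[
        ProtocolStep(kind=StepKind.EQUILIBRATE, buffer_port=1, volume_cv=2),
        ProtocolStep(kind=StepKind.LOAD, volume_cv=3, collect_flowthrough=True),
        ProtocolStep(kind=StepKind.ELUTE, buffer_port=3, volume_cv=2,
                     fraction_size_cv=1.0),
    ])


class TestCompile:
    def test_wash_step_compiles_to_60_ml_at_1_ml_per_min(self, registry):
        plan = compile_protocol(get_protocol("histrap_1ml"),
                                registry.get("histrap_1ml"))
        wash = plan.steps[2]
        assert wash.kind is StepKind.WASH
        assert wash.volume_ml == {ch: 60.0 for ch in range(1, 5)}
        assert wash.rate_ml_min == {ch: 1.0 for ch in range(1, 5)}
        assert wash.sink is FlowSink.POST_COLUMN_WASTE

    def test_protein_a_elution_expands_into_five_prefilled_fractions(self, registry):
        plan = compile_protocol(get_protocol("protein_a_1ml"),
                                registry.get("protein_a_1ml"))
        elute = plan.steps[-1]
        assert len(elute.fractions) == 5
        for frac in elute.fractions:
            assert frac.volume_ml[1] == pytest.approx(0.85)
            assert frac.prefill_ml[1] == pytest.approx(0.15)
        assert [f.row for f in elute.fractions] == [1, 2, 3, 4, 5]

    def test_histrap_5ml_scales_volumes_by_column_volume(self, registry):
        plan = compile_protocol(get_protocol("histrap_5ml"),
                                registry.get("histrap_5ml"))
        assert plan.steps[0].volume_ml[1] == pytest.approx(50.0)   # 10 CV
        assert plan.steps[1].volume_ml[1] == pytest.approx(1000.0)  # 200 CV
        assert plan.steps[3].fractions[0].volume_ml[1] == pytest.approx(5.0)

    def test_too_many_fractions_for_the_plate(self, registry):
        proto = Protocol(name="overfull", steps=[
            ProtocolStep(kind=StepKind.ELUTE, buffer_port=1, volume_cv=12,
                         fraction_size_cv=1.0)])
        with pytest.raises(CompileError, match="small rows"):
            compile_protocol(proto, registry.get("histrap_1ml"))

    def test_undefined_buffer_port_rejected(self, registry):
        proto = Protocol(name="bad-port", steps=[
            ProtocolStep(kind=StepKind.WASH, buffer_port=7, volume_cv=1)])
        with pytest.raises(CompileError, match="port 7"):
            compile_protocol(proto, registry.get("histrap_1ml"))

    def test_rate_above_pump_ceiling_fails_at_compile_time(self, registry):
        proto = Protocol(name="fast", steps=[
            ProtocolStep(kind=StepKind.WASH, buffer_port=1, volume_cv=1,
                         rate_cv_per_min=5.0)])   # 25 mL/min on a 5 mL column
        with pytest.raises(CompileError, match="ceiling"):
            compile_protocol(proto, registry.get("histrap_5ml"))

    def test_plan_total_volume_is_sum_of_steps(self, registry):
        plan = compile_protocol(get_protocol("histrap_1ml"),
                                registry.get("histrap_1ml"))
        assert plan.total_volume_ml(1) == pytest.approx(10 + 50 + 60 + 8)

    @given(volume_cv=st.floats(0.2, 10), fraction_cv=st.floats(0.1, 2))
    @settings(max_examples=50, deadline=None)
    def test_fraction_count_is_ceil_of_volume_over_size(self, volume_cv,
                                                        fraction_cv):
        step = ProtocolStep(kind=StepKind.ELUTE, buffer_port=1,
                            volume_cv=volume_cv, fraction_size_cv=fraction_cv)
        assert step.n_fractions == math.ceil(volume_cv / fraction_cv - 1e-9)

    def test_step_validation(self):
        with pytest.raises(ValueError):
            ProtocolStep(kind=StepKind.WASH, volume_cv=1)       # missing port
        with pytest.raises(ValueError):
            ProtocolStep(kind=StepKind.LOAD, volume_cv=-5)      # negative CV
        with pytest.raises(ValueError):
            ProtocolStep(kind=StepKind.ELUTE, buffer_port=1, volume_cv=1)


class TestExecute:
    def test_histrap_ledger_matches_printed_protocol(self, histrap_engine):
        # per channel: 10 mL equilibration waste, 50 mL load flow-through,
        # 60 mL wash waste, eight 1.000 mL elution fractions
        eng = histrap_engine
        ledger = eng.execute(eng.compile(get_protocol("histrap_1ml")))
        assert eng.run.state is RunState.COMPLETE
        for ch in range(1, 5):
            waste = ledger.channel_waste_ml(ch, FlowSink.POST_COLUMN_WASTE)
            assert waste == pytest.approx(70.0, abs=1e-9)   # 10 equil + 60 wash
            flowthrough = [f for f in ledger.channel_fractions(ch)
                           if f.fraction_index == 0]
            assert len(flowthrough) == 1
            assert flowthrough[0].dispensed_ml == pytest.approx(50.0, abs=1e-9)
            assert flowthrough[0].row == 11                 # first 50 mL row
            fractions = ledger.channel_fractions(ch, elution_only=True)
            assert len(fractions) == 8
            for f in fractions:
                assert f.dispensed_ml == pytest.approx(1.0, abs=1e-9)
            assert ledger.conservation_residual_ml(ch) == pytest.approx(0, abs=1e-9)

    def test_fraction_composition_names_only_collector_sources(self, histrap_engine):
        eng = histrap_engine
        ledger = eng.execute(eng.compile(get_protocol("histrap_1ml")))
        for f in ledger.channel_fractions(1, elution_only=True):
            assert set(f.composition) == {"buffer:3"}       # elution buffer only
            assert sum(f.composition.values()) == pytest.approx(f.dispensed_ml)
        flowthrough = [f for f in ledger.channel_fractions(2)
                       if f.fraction_index == 0][0]
        assert set(flowthrough.composition) == {"load:ch2"}

    def test_empty_plan_completes_with_empty_ledger(self, histrap_engine):
        eng = histrap_engine
        ledger = eng.execute(eng.compile(Protocol(name="noop", steps=[])))
        assert eng.run.state is RunState.COMPLETE
        assert ledger.fractions == []
        assert ledger.pumped_ml == {}

    def test_channel_subset_and_load_override(self, histrap_engine):
        eng = histrap_engine
        ledger = eng.execute(eng.compile(small_protocol(), channels=[2],
                                         overrides={2: 1.5}))
        assert sorted({f.channel for f in ledger.fractions}) == [2]
        flowthrough = [f for f in ledger.channel_fractions(2)
                       if f.fraction_index == 0][0]
        assert flowthrough.dispensed_ml == pytest.approx(1.5)

    def test_abort_mid_wash_preserves_partial_conserving_ledger(self, histrap_engine):
        eng = histrap_engine
        plan = eng.compile(get_protocol("histrap_1ml"))
        ticks = {"n": 0}

        def control(run):
            if run.state is not RunState.RUNNING:
                return
            ticks["n"] += 1
            # abort partway through the wash (step 3)
            if run.current_step == 3 and run.step_delivered_ml.get(1, 0) >= 30:
                run.abort()

        ledger = eng.execute(plan, control=control)
        assert eng.run.state is RunState.ABORTED
        wash_waste = ledger.channel_waste_ml(1, FlowSink.POST_COLUMN_WASTE)
        assert 10 < wash_waste < 70            # partial wash only
        for ch in range(1, 5):
            assert ledger.conservation_residual_ml(ch) == pytest.approx(0, abs=1e-9)
        # no elution fractions were collected
        assert ledger.channel_fractions(1, elution_only=True) == []
        # safe state afterwards
        assert all(r is None for r in eng.controller.state.routes.values())

    def test_spill_flagged_when_a_tube_overfills(self, histrap_engine):
        eng = histrap_engine
        proto = Protocol(name="overfill", steps=[
            ProtocolStep(kind=StepKind.ELUTE, buffer_port=3, volume_cv=2,
                         fraction_size_cv=2.0)])   # 2 mL into a 1.5 mL tube
        ledger = eng.execute(eng.compile(proto))
        frac = ledger.channel_fractions(1, elution_only=True)[0]
        assert frac.spilled
        assert frac.spilled_ml == pytest.approx(0.5)
        assert frac.in_tube_ml == pytest.approx(1.5)
        assert ledger.conservation_residual_ml(1) == pytest.approx(0, abs=1e-9)

    def test_lockstep_rows_are_shared_across_channels(self, histrap_engine):
        eng = histrap_engine
        ledger = eng.execute(eng.compile(small_protocol()))
        for row in (1, 2):
            channels = sorted(f.channel for f in ledger.fractions
                              if f.row == row)
            assert channels == [1, 2, 3, 4]


class TestRunControl:
    def test_pause_then_resume_completes_remaining_volume_exactly(self, histrap_engine):
        eng = histrap_engine
        proto = Protocol(name="wash-only", steps=[
            ProtocolStep(kind=StepKind.WASH, buffer_port=2, volume_cv=60)])
        actions = {"paused": False}

        def control(run):
            if (run.state is RunState.RUNNING and not actions["paused"]
                    and run.step_delivered_ml.get(1, 0) >= 30):
                actions["paused"] = True
                run.pause()
            elif run.state is RunState.PAUSED:
                run.resume()

        ledger = eng.execute(eng.compile(proto), control=control)
        assert actions["paused"]
        assert ledger.channel_waste_ml(1, FlowSink.POST_COLUMN_WASTE) == \
            pytest.approx(60.0, abs=1e-9)

    def test_hold_completes_current_step_then_waits(self, histrap_engine):
        eng = histrap_engine
        states_seen = []

        def control(run):
            states_seen.append(run.state)
            if run.state is RunState.RUNNING and run.current_step == 2 \
                    and not any(s is RunState.HOLDING for s in states_seen):
                if run.step_delivered_ml.get(1, 0) == 0.5:  # early in the load
                    run.hold()
            elif run.state is RunState.HOLDING:
                run.resume()

        ledger = eng.execute(eng.compile(small_protocol()), control=control)
        assert RunState.HOLDING in states_seen
        # the load still ran to its full commanded volume before holding
        flowthrough = [f for f in ledger.channel_fractions(1)
                       if f.fraction_index == 0][0]
        assert flowthrough.dispensed_ml == pytest.approx(3.0)
        assert eng.run.state is RunState.COMPLETE

    def test_illegal_transitions_rejected(self, histrap_engine):
        eng = histrap_engine
        with pytest.raises(RunStateError):
            eng.run.resume()               # resume from IDLE
        eng.execute(eng.compile(Protocol(name="noop", steps=[])))
        with pytest.raises(RunStateError):
            eng.run.resume()               # resume from COMPLETE
        with pytest.raises(RunStateError):
            eng.run.pause()                # pause from COMPLETE
        with pytest.raises(RunStateError):
            eng.run.abort()                # abort from COMPLETE

    @given(pause_at=st.sets(st.integers(1, 25), max_size=6))
    @settings(max_examples=20, deadline=None)
    def test_pause_resume_interleavings_conserve_step_volumes(self, registry,
                                                              pause_at):
        # any interleaving of pause/resume leaves per-step delivered volume
        # unchanged (noiseless)
        ctl = HardwareController(registry)
        ctl.set_seed(0)
        ctl.load_configuration("histrap_1ml")
        eng = ProtocolEngine(ctl)
        counter = {"n": 0}

        def control(run):
            if run.state is RunState.RUNNING:
                counter["n"] += 1
                if counter["n"] in pause_at:
                    run.pause()
            elif run.state is RunState.PAUSED:
                run.resume()

        ledger = eng.execute(eng.compile(small_protocol()), control=control)
        assert eng.run.state is RunState.COMPLETE
        for ch in range(1, 5):
            assert ledger.pumped_ml[ch] == pytest.approx(7.0, abs=1e-9)
            assert ledger.conservation_residual_ml(ch) == pytest.approx(0, abs=1e-9)
        fracs = ledger.channel_fractions(1, elution_only=True)
        assert [f.dispensed_ml for f in fracs] == pytest.approx([1.0, 1.0])


class TestCalibration:
    def _route_all(self, ctl):
        for ch in range(1, ctl.n_channels + 1):
            ctl.set_flow_path(ch, FlowSource.buffer(1),
                              FlowSink.POST_COLUMN_WASTE)

    def test_well_calibrated_pump_is_a_fixed_point(self, histrap_engine):
        eng = histrap_engine
        self._route_all(eng.controller)
        before = eng.controller.pump_model(1).volume_per_step_ul
        model = eng.calibrate_flow(1)
        assert model.volume_per_step_ul == pytest.approx(before, rel=1e-12)

    def test_five_percent_mis_scale_recovered_in_one_pass(self, registry):
        from quadpure.experiments import calibration_recovery_experiment
        result = calibration_recovery_experiment(scale_error=1.05)
        assert abs(result["error_before_rel"]) == pytest.approx(0.05, abs=1e-6)
        assert abs(result["error_after_rel"]) < 0.005     # within 0.5% of 1 CV

    def test_repeated_calibration_converges(self, registry):
        from quadpure.experiments import calibration_recovery_experiment
        # one pass already lands within rounding of the step quantization;
        # a second pass must not drift away
        first = calibration_recovery_experiment(scale_error=0.9)
        assert abs(first["error_after_rel"]) < 0.005

    def test_zero_measured_volume_raises(self, histrap_engine):
        from quadpure.errors import CalibrationError
        eng = histrap_engine
        with pytest.raises(CalibrationError):
            eng.calibrate_flow(1, measurement_window_min=0.0)


class TestNoisyFractionConsistency:
    def test_monte_carlo_mirrors_bench_fraction_experiment(self):
        # 30 one-minute dispenses x 4 channels after a coarse parallel
        # calibration, synthetic aliquot noise sd 1%: the empirical mean
        # lands within 1% of 1 CV and the spread reflects the noise model
        from quadpure.experiments import (
            fraction_consistency_experiment,
            summarize_fractions,
        )
        df = fraction_consistency_experiment(seed=2026)
        assert len(df) == 30 * 4
        assert df["volume_cv"].mean() == pytest.approx(1.0, abs=0.01)
        assert 0.005 < df["volume_cv"].std() < 0.02
        summary = summarize_fractions(df)
        assert set(summary["channel"]) == {1, 2, 3, 4}


class TestShippedProtocols:
    def test_all_shipped_protocols_compile_on_their_paired_configs(self, registry):
        for name, proto in shipped_protocols().items():
            plan = compile_protocol(proto, registry.get(name))
            assert plan.steps
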