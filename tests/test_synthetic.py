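"""Generator behaviour: protocol structure, gait synthesis, kinetics, noise."""


import numpy as np
import pytest

from vo2lstm import synthetic
from vo2lstm.synthetic import (
    ExerciseProtocol,
    ProtocolSegment,
    SubjectProfile,
    ValidationError,
    generate_protocol,
    inject_sync_artifacts,
    simulate_physiology,
    simulate_steps,
    vo2_steady_state,
)


class TestProtocol:
    def test_default_structure(self, protocol):
        labels = [s.label for s in protocol.segments]
        assert labels == ["rest", "walk", "rest", "walk", "rest", "run", "rest", "run", "rest"]
        assert protocol.total_duration == pytest.approx(1320.0)

    def test_stage_and_rest_arithmetic(self):
        p = generate_protocol((1.3, 1.8), (2.5, 3.5), stage_duration=180, rest_duration=120)
        assert len(p.segments) == 9
        assert p.total_duration == pytest.approx(4 * 180 + 5 * 120)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"stage_duration": 0},
            {"walk_speeds": (1.0, 1.8)},  # below protocol range
            {"run_speeds": (2.5, 4.0)},  # above protocol range
            {"walk_speeds": (1.3, 2.6)},  # walking not slower than running
        ],
    )
    def test_invalid_protocols_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            generate_protocol(**kwargs)

    def test_rest_segment_speed_must_be_zero(self):
        with pytest.raises(ValidationError):
            ProtocolSegment("rest", 1.0, 60.0)

    def test_protocol_must_start_at_rest(self):
        with pytest.raises(ValidationError):
            ExerciseProtocol((ProtocolSegment("walk", 1.5, 60.0),))


class TestSubject:
    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            SubjectProfile(vo2_rest=60.0, vo2_peak=50.0)
        with pytest.raises(ValidationError):
            SubjectProfile(tau_vo2_on=-1.0)

    def test_sampler_mass_within_truncation(self):
        masses = [synthetic.sample_subject(i).body_mass for i in range(50)]
        assert all(45.0 <= m <= 120.0 for m in masses)
        assert np.std(masses) > 5.0  # actually varies


class TestSteadyState:
    def test_rest_fixed_point(self, subject):
        assert vo2_steady_state(0.0, "walk", subject) == subject.vo2_rest

    def test_linear_walk_and_run_mappings(self):
        s = SubjectProfile(vo2_rest=3.5)
        assert vo2_steady_state(1.5, "walk", s) == pytest.approx(12.5)
        assert vo2_steady_state(3.0, "run", s) == pytest.approx(39.5)

    def test_monotone_in_speed(self, subject):
        speeds = np.linspace(0.5, 3.5, 10)
        for gait in ("walk", "run"):
            vals = [vo2_steady_state(v, gait, subject) for v in speeds]
            assert np.all(np.diff(vals) > 0)

    def test_negative_speed_rejected(self, subject):
        with pytest.raises(ValidationError):
            vo2_steady_state(-0.1, "walk", subject)


class TestGaitSynthesis:
    def test_step_count_matches_cadence_model(self):
        # cadence fixed at 1/0.35 steps/s -> about 514 steps in 180 s
        subj = SubjectProfile(cadence_base=1.0 / 0.35, preferred_cadence_slope=0.0)
        proto = ExerciseProtocol(
            (ProtocolSegment("rest", 0.0, 10.0), ProtocolSegment("run", 3.0, 180.0))
        )
        _, steps = simulate_steps(proto, subj, seed=0)
        assert abs(steps.size - 514) <= 6

    def test_rest_emits_no_steps(self, protocol, motion_and_steps):
        _, steps = motion_and_steps
        for start, end, seg in protocol.segment_bounds():
            if seg.label == "rest":
                inside = (steps > start + 1e-9) & (steps < end - 1.0)
                assert not inside.any()

    def test_determinism_under_seed(self, protocol, subject):
        t1, s1 = simulate_steps(protocol, subject, seed=5)
        t2, s2 = simulate_steps(protocol, subject, seed=5)
        assert np.array_equal(t1.speed, t2.speed)
        assert np.array_equal(t1.vertical_position, t2.vertical_position)
        assert np.array_equal(s1, s2)
        t3, _ = simulate_steps(protocol, subject, seed=6)
        assert not np.array_equal(t1.speed, t3.speed)

    def test_step_count_scales_with_duration(self, subject):
        counts = {}
        for dur in (90.0, 180.0):
            proto = ExerciseProtocol(
                (ProtocolSegment("rest", 0.0, 10.0), ProtocolSegment("run", 3.0, dur))
            )
            _, steps = simulate_steps(proto, subject, seed=3)
            counts[dur] = steps.size
        assert counts[180.0] / counts[90.0] == pytest.approx(2.0, rel=0.02)


class TestKinetics:
    def test_matches_closed_form_on_constant_speed(self, subject):
        """Exact-discretization latent trace equals the analytic exponential."""
        proto = ExerciseProtocol(
            (ProtocolSegment("rest", 0.0, 60.0), ProtocolSegment("run", 3.0, 300.0))
        )
        sim = simulate_physiology(proto, subject, seed=0)
        t, v = sim.latent_vo2.time, sim.latent_vo2.values
        v0 = subject.vo2_rest
        vss = vo2_steady_state(3.0, "run", subject)
        onset = t >= 60.0
        analytic = vss + (v0 - vss) * np.exp(-(t[onset] - 60.0) / subject.tau_vo2_on)
        assert np.max(np.abs(v[onset] - analytic)) < 1e-6

    def test_transition_63_percent_at_tau(self, subject):
        proto = ExerciseProtocol(
            (ProtocolSegment("rest", 0.0, 60.0), ProtocolSegment("run", 3.0, 300.0))
        )
        sim = simulate_physiology(proto, subject, seed=0)
        t, v = sim.latent_vo2.time, sim.latent_vo2.values
        vss = vo2_steady_state(3.0, "run", subject)
        at_tau = np.interp(60.0 + subject.tau_vo2_on, t, v)
        frac = (at_tau - subject.vo2_rest) / (vss - subject.vo2_rest)
        assert frac == pytest.approx(0.6321, abs=1e-3)

    def test_long_rest_returns_to_baseline(self, subject):
        proto = ExerciseProtocol(
            (
                ProtocolSegment("rest", 0.0, 30.0),
                ProtocolSegment("run", 3.5, 180.0),
                ProtocolSegment("rest", 0.0, 600.0),
            )
        )
        sim = simulate_physiology(proto, subject, seed=0)
        assert sim.latent_vo2.values[-1] == pytest.approx(subject.vo2_rest, abs=0.01)
        assert sim.latent_hr.values[-1] == pytest.approx(subject.hr_rest, abs=0.2)

    def test_steady_state_reached_after_five_tau(self, subject):
        proto = ExerciseProtocol(
            (ProtocolSegment("rest", 0.0, 30.0),
             ProtocolSegment("run", 3.0, 6.0 * subject.tau_vo2_on))
        )
        sim = simulate_physiology(proto, subject, seed=0)
        vss = vo2_steady_state(3.0, "run", subject)
        at_5tau = np.interp(30.0 + 5 * subject.tau_vo2_on,
                            sim.latent_vo2.time, sim.latent_vo2.values)
        assert abs(at_5tau - vss) < 0.01 * (vss - subject.vo2_rest)

    def test_measurement_noise_magnitude(self, protocol, subject, physio):
        """Spirometer noise: 125 mL/min divided by body mass per sample."""
        lat = np.interp(physio.vo2.time, physio.latent_vo2.time, physio.latent_vo2.values)
        resid = physio.vo2.values - lat
        expected_sd = 125.0 / subject.body_mass
        assert np.std(resid) == pytest.approx(expected_sd, rel=0.2)

    def test_sampling_rates(self, physio, protocol):
        assert np.allclose(np.diff(physio.vo2.time), 5.0)
        assert np.allclose(np.diff(physio.hr.time), 1.0)
        assert physio.vo2.time[-1] <= protocol.total_duration


class TestSyncArtifacts:
    def test_offsets_applied_exactly(self, motion_and_steps, physio):
        motion, _ = motion_and_steps
        out = inject_sync_artifacts(
            motion, physio.vo2, physio.hr, (0.0, 2.0, -1.5), jump_time=10.0, seed=0
        )
        assert np.allclose(out.hr.time, physio.hr.time - 1.5)
        assert np.allclose(out.vo2.time, physio.vo2.time + 2.0)
        assert np.allclose(out.motion.time, motion.time)

    def test_spike_is_strict_global_maximum(self, motion_and_steps, physio):
        motion, _ = motion_and_steps
        out = inject_sync_artifacts(
            motion, physio.vo2, physio.hr, (1.0, 0.0, 0.0), jump_time=10.0, seed=0
        )
        acc = np.abs(out.motion.vertical_acceleration)
        peak = np.argmax(acc)
        assert acc[peak] > np.max(np.delete(acc, peak))
        assert out.motion.time[peak] == pytest.approx(10.0 + 1.0, abs=0.02)

    def test_invalid_arguments_rejected(self, motion_and_steps, physio):
        motion, _ = motion_and_steps
        with pytest.raises(ValidationError):
            inject_sync_artifacts(motion, physio.vo2, physio.hr, (31.0, 0, 0), 10.0)
        with pytest.raises(ValidationError):
            inject_sync_artifacts(motion, physio.vo2, physio.hr, (0, 0, 0), -5.0)


class TestWriters:
    def test_round_trip_csv(self, tmp_path, motion_and_steps, physio, protocol, subject):
        motion, steps = motion_and_steps
        files = synthetic.write_simulation(
            tmp_path, motion, physio, steps, subject, protocol, seeds={"s": 1}
        )
        assert set(files) == {
            "motion.csv", "vo2.csv", "hr.csv", "vo2_latent.csv",
            "steps_true.csv", "sidecar.json",
        }
        back = synthetic.read_motion_csv(tmp_path / "motion.csv")
        assert back.sample_rate == pytest.approx(motion.sample_rate, rel=1e-6)
        assert np.allclose(back.speed, motion.speed, atol=1e-6)
        vo2 = synthetic.read_physio_csv(tmp_path / "vo2.csv", "vo2", 0.2)
        assert np.allclose(vo2.values, physio.vo2.values, atol=1e-6)
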