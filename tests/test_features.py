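"""Step segmentation accuracy, per-step metrics, correlations, ablation."""

import numpy as np
import pandas as pd
import pytest

from vo2lstm import features as feat
from vo2lstm import model as mod
from vo2lstm.synthetic import MotionTrace, PhysioSeries, ValidationError


def _sine_trace(period=0.5, duration=60.0, rate=100.0, amplitude=0.04):
    t = np.arange(int(duration * rate)) / rate
    pos = amplitude * np.sin(2 * np.pi * t / period)
    return MotionTrace(rate, t, np.full(t.size, 2.0), pos, np.zeros(t.size))


def _steps_from_arrays(mean_speed, vo2=None, hr=None, duration=0.4):
    out = []
    for k, v in enumerate(mean_speed):
        out.append(
            feat.StepRecord(
                index=k,
                start_time=k * duration,
                duration=duration,
                mean_speed=float(v),
                speed_p2p=0.1,
                vertical_disp_p2p=0.05,
                hr=None if hr is None else float(hr[k]),
                vo2_target=None if vo2 is None else float(vo2[k]),
            )
        )
    return out


class TestSegmentation:
    def test_recovers_true_boundaries(self, motion_and_steps):
        motion, true_steps = motion_and_steps
        segs = feat.segment_steps(motion)
        det = np.array([s for s, _ in segs])
        dist = np.abs(true_steps[:, None] - det[None, :]).min(axis=1)
        assert (dist < 0.05).mean() >= 0.98

    def test_flat_trace_yields_no_steps(self):
        n = 3000
        trace = MotionTrace(100.0, np.arange(n) / 100.0, np.zeros(n), np.zeros(n), np.zeros(n))
        assert feat.segment_steps(trace) == []

    def test_pure_sinusoid_counts_cycles(self):
        segs = feat.segment_steps(_sine_trace(period=0.5, duration=60.0))
        assert len(segs) == 120

    def test_rest_periods_produce_no_steps(self, protocol, motion_and_steps):
        motion, _ = motion_and_steps
        segs = feat.segment_steps(motion)
        starts = np.array([s for s, _ in segs])
        for seg_start, seg_end, seg in protocol.segment_bounds():
            if seg.label == "rest":
                assert not ((starts > seg_start + 1.0) & (starts < seg_end - 1.5)).any()


class TestStepMetrics:
    def test_constant_speed_step(self):
        t = np.arange(100) / 100.0
        trace = MotionTrace(100.0, t, np.full(100, 3.0), np.zeros(100), np.zeros(100))
        recs = feat.compute_step_metrics(trace, [(0.1, 0.5)])
        assert recs[0].mean_speed == pytest.approx(3.0)
        assert recs[0].speed_p2p == 0.0
        assert recs[0].duration == pytest.approx(0.4)

    def test_sinusoid_amplitude_gives_peak_to_peak(self):
        trace = _sine_trace(period=0.5, amplitude=0.05, duration=2.0)
        recs = feat.compute_step_metrics(trace, [(0.0, 0.5)])
        assert recs[0].vertical_disp_p2p == pytest.approx(0.10, rel=0.01)

    def test_tiny_segments_dropped(self):
        t = np.arange(100) / 100.0
        trace = MotionTrace(100.0, t, np.full(100, 2.0), np.zeros(100), np.zeros(100))
        recs = feat.compute_step_metrics(trace, [(0.395, 0.4), (0.5, 0.9)])
        assert len(recs) == 1

    def test_overlapping_segments_rejected(self):
        t = np.arange(100) / 100.0
        trace = MotionTrace(100.0, t, np.full(100, 2.0), np.zeros(100), np.zeros(100))
        with pytest.raises(ValidationError):
            feat.compute_step_metrics(trace, [(0.0, 0.5), (0.3, 0.8)])

    def test_metrics_recover_generator_parameters(self, protocol, subject, motion_and_steps):
        """Mean step duration tracks the cadence model; displacement tracks
        twice the oscillation amplitude, per gait.  Uses each stage's last
        minute, where the gait-settling transient has decayed."""
        motion, _ = motion_and_steps
        segs = feat.segment_steps(motion)
        recs = feat.compute_step_metrics(motion, segs)
        starts = np.array([r.start_time for r in recs])
        for seg_start, seg_end, seg in protocol.segment_bounds():
            if seg.label == "rest":
                continue
            inside = (starts > seg_end - 62.0) & (starts < seg_end - 2.0)
            sel = [r for r, keep in zip(recs, inside) if keep]
            mean_dur = np.mean([r.duration for r in sel])
            expected = 1.0 / subject.step_frequency(seg.target_speed)
            assert mean_dur == pytest.approx(expected, rel=0.05)
            mean_disp = np.mean([r.vertical_disp_p2p for r in sel])
            expected_p2p = 0.05 if seg.label == "walk" else 0.09
            assert mean_disp == pytest.approx(expected_p2p, rel=0.05)


class TestAttachPhysiology:
    def test_targets_interpolated_at_step_end(self):
        steps = _steps_from_arrays([2.0, 2.0, 2.0])
        vo2 = PhysioSeries("vo2", np.array([0.0, 2.0]), np.array([10.0, 20.0]), 0.5)
        out = feat.attach_physiology(steps, vo2=vo2)
        # step ends at 0.4, 0.8, 1.2 -> linear interpolation of the ramp
        assert [s.vo2_target for s in out] == pytest.approx([12.0, 14.0, 16.0])

    def test_steps_outside_span_dropped(self):
        steps = _steps_from_arrays([2.0] * 10)
        vo2 = PhysioSeries("vo2", np.array([1.0, 2.0]), np.array([10.0, 20.0]), 1.0)
        out = feat.attach_physiology(steps, vo2=vo2)
        assert len(out) < 10
        assert all(s.vo2_target is not None for s in out)


class TestCorrelations:
    def test_linear_feature_has_unit_correlation(self, rng):
        speed = rng.uniform(1.0, 3.0, 50)
        steps = _steps_from_arrays(speed, vo2=3.0 * speed + 2.0)
        rep = feat.correlations(steps)
        assert rep.feature_target["mean_speed"] == pytest.approx(1.0)

    def test_matrix_symmetric_unit_diagonal(self, rng):
        speed = rng.uniform(1.0, 3.0, 80)
        steps = _steps_from_arrays(speed, vo2=rng.normal(size=80) + 10.0,
                                   hr=rng.uniform(80, 150, 80))
        rep = feat.correlations(steps)
        m = rep.feature_feature
        assert np.allclose(m.values, m.values.T, equal_nan=True)
        assert np.allclose(np.diag(m.values)[~np.isnan(np.diag(m.values))], 1.0)

    def test_four_point_table_matches_textbook_formula(self):
        speed = np.array([1.0, 2.0, 3.0, 4.0])
        vo2 = np.array([5.0, 9.0, 8.0, 14.0])
        steps = _steps_from_arrays(speed, vo2=vo2)
        rep = feat.correlations(steps)
        # independent direct evaluation of Pearson's formula
        sx, sy = speed - speed.mean(), vo2 - vo2.mean()
        expected = abs(np.sum(sx * sy) / np.sqrt(np.sum(sx**2) * np.sum(sy**2)))
        assert rep.feature_target["mean_speed"] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_feature_is_undefined_not_zero(self):
        steps = _steps_from_arrays(np.full(10, 2.0), vo2=np.arange(10.0) + 5.0)
        rep = feat.correlations(steps)
        assert np.isnan(rep.feature_target["mean_speed"])

    def test_requires_three_targets(self):
        steps = _steps_from_arrays([1.0, 2.0], vo2=[5.0, 6.0])
        with pytest.raises(ValidationError):
            feat.correlations(steps)


@pytest.fixture(scope="module")
def tiny_config():
    return mod.ModelConfig(
        window_length=5, hidden_units=6, epochs=40, batch_size=32, seed=11
    )


@pytest.fixture(scope="module")
def speed_driven_steps():
    rng = np.random.default_rng(42)
    speed = rng.uniform(1.3, 3.5, 400)
    steps = []
    for k in range(400):
        steps.append(
            feat.StepRecord(
                index=k, start_time=0.4 * k, duration=float(rng.uniform(0.3, 0.5)),
                mean_speed=float(speed[k]),
                speed_p2p=float(rng.uniform(0.0, 0.5)),
                vertical_disp_p2p=float(rng.uniform(0.02, 0.1)),
                hr=float(rng.uniform(80, 170)),
                vo2_target=float(3.5 + 10.0 * speed[k]),
            )
        )
    return steps


class TestAblation:
    def test_only_one_produces_one_row_per_feature(self, speed_driven_steps, tiny_config):
        table = feat.ablation_study(speed_driven_steps, "only_one", tiny_config)
        assert len(table) == 5
        assert set(table["features"]) == set(feat.FEATURE_NAMES)

    def test_speed_ranks_best_when_vo2_is_speed_driven(self, speed_driven_steps, tiny_config):
        table = feat.ablation_study(speed_driven_steps, "only_one", tiny_config)
        assert table.iloc[0]["features"] == "mean_speed"

    def test_leave_one_out_has_four_feature_subsets(self, speed_driven_steps, tiny_config):
        table = feat.ablation_study(speed_driven_steps, "leave_one_out", tiny_config)
        assert len(table) == 5
        assert all(len(f.split("+")) == 4 for f in table["features"])

    def test_study_is_reproducible_bit_for_bit(self, speed_driven_steps, tiny_config):
        a = feat.ablation_study(speed_driven_steps, "only_one", tiny_config)
        b = feat.ablation_study(speed_driven_steps, "only_one", tiny_config)
        pd.testing.assert_frame_equal(a, b)

    def test_subset_failure_does_not_abort_study(self, tiny_config):
        rng = np.random.default_rng(0)
        speed = rng.uniform(1.3, 3.5, 200)
        steps = _steps_from_arrays(speed, vo2=3.5 + 10 * speed)  # hr missing
        table = feat.ablation_study(steps, "only_one", tiny_config)
        hr_row = table[table["features"] == "hr"].iloc[0]
        assert hr_row["error"] != ""
        speed_row = table[table["features"] == "mean_speed"].iloc[0]
        assert speed_row["error"] == "" and np.isfinite(speed_row["loa95"])


class TestStepCsv:
    def test_round_trip(self, tmp_path, rng):
        speed = rng.uniform(1.0, 3.0, 20)
        steps = _steps_from_arrays(speed, vo2=rng.uniform(5, 40, 20), hr=rng.uniform(60, 180, 20))
        path = tmp_path / "steps.csv"
        feat.write_steps_csv(path, steps)
        back = feat.read_steps_csv(path)
        assert len(back) == len(steps)
        assert back[3].mean_speed == pytest.approx(steps[3].mean_speed, abs=1e-6)
        assert back[3].hr == pytest.approx(steps[3].hr, abs=1e-6)
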