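"""Step segmentation, per-step gait metrics, correlations, and ablation.

One step corresponds to one vertical oscillation of the torso.  Steps are
found by peak-picking the vertical-position signal; per step the pipeline
computes the metrics used as model inputs:

* mean speed over the step (m/s),
* within-step peak-to-peak speed difference (m/s),
* step duration (s),
* within-step peak-to-peak vertical displacement (m),
* optionally heart rate (bpm) interpolated at the step.

The V̇O2 target attached to a step is the smoothed oxygen-uptake series
interpolated at a configurable anchor within the step (end by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import preprocessing
from .synthetic import MotionTrace, PhysioSeries, ValidationError

__all__ = [
    "FEATURE_NAMES",
    "StepRecord",
    "CorrelationReport",
    "segment_steps",
    "compute_step_metrics",
    "attach_physiology",
    "correlations",
    "ablation_study",
    "steps_to_frame",
    "write_steps_csv",
    "read_steps_csv",
]

log = logging.getLogger(__name__)

#: canonical model-input feature order
FEATURE_NAMES = ("mean_speed", "speed_p2p", "duration", "vertical_disp_p2p", "hr")

#: physiologically plausible single-step duration range, s
STEP_DURATION_RANGE = (0.2, 1.5)


@dataclass(frozen=True)
class StepRecord:
    """One gait step and its motion metrics (the unit of the feature stream)."""

    index: int
    start_time: float  # s
    duration: float  # s
    mean_speed: float  # m/s
    speed_p2p: float  # m/s
    vertical_disp_p2p: float  # m
    hr: float | None = None  # bpm
    vo2_target: float | None = None  # mL/min/kg

    def __post_init__(self) -> None:
        lo, hi = STEP_DURATION_RANGE
        if not lo < self.duration < hi:
            raise ValidationError(
                f"step {self.index}: duration {self.duration:.3f} s outside ({lo}, {hi}) s"
            )
        if self.mean_speed < 0 or self.speed_p2p < 0 or self.vertical_disp_p2p < 0:
            raise ValidationError(f"step {self.index}: negative metric")

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def feature(self, name: str) -> float:
        val = getattr(self, "vertical_disp_p2p" if name == "vertical_disp_p2p" else name)
        if val is None:
            raise ValidationError(f"step {self.index}: feature {name!r} is missing")
        return float(val)


@dataclass
class CorrelationReport:
    """Absolute Pearson correlations among features and against the target.

    Zero-variance features produce NaN entries (undefined, not zero).
    """

    feature_feature: pd.DataFrame
    feature_target: pd.Series


def segment_steps(
    motion: MotionTrace,
    min_period: float = 0.2,
    min_prominence: float = 0.03,
) -> list[tuple[float, float]]:
    """Detect one (start, end) interval per vertical oscillation cycle.

    Peaks of the vertical position (one per step, mid-step) are found with
    a minimum separation of ``min_period`` seconds and a minimum prominence
    of ``min_prominence`` metres; each step spans the midpoints toward the
    neighbouring peaks, capped at 0.6 of the median inter-peak interval at
    recording edges and across locomotion pauses.  Cycles with durations
    outside the plausible single-step range are discarded, so rest periods
    yield no steps.  An empty list is returned when nothing oscillates.
    """
    dt = 1.0 / motion.sample_rate
    distance = max(int(round(min_period / dt)), 1)
    peaks, _ = find_peaks(
        motion.vertical_position, distance=distance, prominence=min_prominence
    )
    if peaks.size == 0:
        return []
    pt = motion.time[peaks]
    if peaks.size == 1:
        return []
    gaps = np.diff(pt)
    med = float(np.median(gaps))
    half_cap = 0.6 * med
    lo, hi = STEP_DURATION_RANGE

    segments: list[tuple[float, float]] = []
    for i, p in enumerate(pt):
        left = min(gaps[i - 1] / 2 if i > 0 else np.inf, half_cap)
        right = min(gaps[i] / 2 if i < gaps.size else np.inf, half_cap)
        start = max(p - left, motion.time[0])
        end = min(p + right, motion.time[-1])
        if lo < end - start < hi:
            segments.append((float(start), float(end)))
    return segments


def compute_step_metrics(
    motion: MotionTrace, segments: Sequence[tuple[float, float]]
) -> list[StepRecord]:
    """Per-step metrics from the raw motion samples inside each segment.

    Segments must be ordered and non-overlapping; any segment containing
    fewer than two samples is dropped and logged.
    """
    for (s0, e0), (s1, _) in zip(segments, segments[1:]):
        if s1 < e0 - 1e-9:
            raise ValidationError("segments must be ordered and non-overlapping")
    records: list[StepRecord] = []
    dropped = 0
    idx = 0
    for start, end in segments:
        j0 = int(np.searchsorted(motion.time, start, side="left"))
        j1 = int(np.searchsorted(motion.time, end, side="right"))
        if j1 - j0 < 2:
            dropped += 1
            continue
        sp = motion.speed[j0:j1]
        vp = motion.vertical_position[j0:j1]
        records.append(
            StepRecord(
                index=idx,
                start_time=float(start),
                duration=float(end - start),
                mean_speed=float(sp.mean()),
                speed_p2p=float(sp.max() - sp.min()),
                vertical_disp_p2p=float(vp.max() - vp.min()),
            )
        )
        idx += 1
    if dropped:
        log.info("compute_step_metrics: dropped %d segments with < 2 samples", dropped)
    return records


def attach_physiology(
    steps: Sequence[StepRecord],
    vo2: PhysioSeries | None = None,
    hr: PhysioSeries | None = None,
    anchor: Literal["start", "mid", "end"] = "end",
) -> list[StepRecord]:
    """Interpolate V̇O2 targets and/or HR at each step's anchor time.

    Steps whose anchor falls outside a series' span are dropped (the
    interpolation never extrapolates).
    """
    if anchor == "start":
        times = np.array([s.start_time for s in steps])
    elif anchor == "mid":
        times = np.array([s.start_time + s.duration / 2 for s in steps])
    else:
        times = np.array([s.end_time for s in steps])

    kept = np.ones(len(steps), dtype=bool)
    vo2_vals = hr_vals = None
    if vo2 is not None:
        vo2_vals, kept_v = preprocessing.resample_to_steps(vo2, times)
        kept &= kept_v
    if hr is not None:
        hr_vals, kept_h = preprocessing.resample_to_steps(hr, times)
        kept &= kept_h

    out: list[StepRecord] = []
    iv = ih = 0
    for i, s in enumerate(steps):
        take_v = vo2 is not None and (times[i] >= vo2.time[0]) and (times[i] <= vo2.time[-1])
        take_h = hr is not None and (times[i] >= hr.time[0]) and (times[i] <= hr.time[-1])
        v = float(vo2_vals[iv]) if take_v else None
        h = float(hr_vals[ih]) if take_h else None
        iv += int(take_v)
        ih += int(take_h)
        if kept[i]:
            out.append(dc_replace(s, index=len(out), vo2_target=v, hr=h))
    return out


def steps_to_frame(steps: Iterable[StepRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "index": [s.index for s in steps],
            "start_time_s": [s.start_time for s in steps],
            "duration_s": [s.duration for s in steps],
            "mean_speed_mps": [s.mean_speed for s in steps],
            "speed_p2p_mps": [s.speed_p2p for s in steps],
            "vert_disp_p2p_m": [s.vertical_disp_p2p for s in steps],
            "hr_bpm": [s.hr for s in steps],
            "vo2_target_mlkgmin": [s.vo2_target for s in steps],
        }
    )


def write_steps_csv(path, steps: Iterable[StepRecord]) -> None:
    steps_to_frame(steps).to_csv(path, index=False, float_format="%.6f")


def read_steps_csv(path) -> list[StepRecord]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(
            StepRecord(
                index=int(r["index"]),
                start_time=float(r["start_time_s"]),
                duration=float(r["duration_s"]),
                mean_speed=float(r["mean_speed_mps"]),
                speed_p2p=float(r["speed_p2p_mps"]),
                vertical_disp_p2p=float(r["vert_disp_p2p_m"]),
                hr=None if pd.isna(r["hr_bpm"]) else float(r["hr_bpm"]),
                vo2_target=(
                    None
                    if pd.isna(r["vo2_target_mlkgmin"])
                    else float(r["vo2_target_mlkgmin"])
                ),
            )
        )
    return out


def correlations(steps: Sequence[StepRecord]) -> CorrelationReport:
    """|Pearson r| between all feature pairs and each feature vs the target."""
    with_targets = [s for s in steps if s.vo2_target is not None]
    if len(with_targets) < 3:
        raise ValidationError("correlations need at least 3 steps with V̇O2 targets")
    cols = {
        "mean_speed": [s.mean_speed for s in with_targets],
        "speed_p2p": [s.speed_p2p for s in with_targets],
        "duration": [s.duration for s in with_targets],
        "vertical_disp_p2p": [s.vertical_disp_p2p for s in with_targets],
    }
    if all(s.hr is not None for s in with_targets):
        cols["hr"] = [s.hr for s in with_targets]
    df = pd.DataFrame(cols)
    target = pd.Series([s.vo2_target for s in with_targets], name="vo2")
    ff = df.corr().abs()
    ft = df.corrwith(target).abs()
    return CorrelationReport(feature_feature=ff, feature_target=ft)


def ablation_study(
    steps: Sequence[StepRecord] | Sequence[Sequence[StepRecord]],
    mode: Literal["only_one", "leave_one_out"],
    model_config,
    features: Sequence[str] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Train one model per feature subset and report test-set agreement.

    ``only_one`` trains a single-feature model for each feature;
    ``leave_one_out`` drops one feature at a time from the full set.  All
    runs share the configuration's seed and split, so rows differ only in
    their feature subset.  Per-subset training failures are recorded in the
    ``error`` column without aborting the remaining subsets.  Rows are
    sorted by the 95% limits of agreement.
    """
    from . import evaluation, model as model_mod

    if mode == "only_one":
        subsets = [(f,) for f in features]
    elif mode == "leave_one_out":
        subsets = [tuple(g for g in features if g != f) for f in features]
    else:
        raise ValidationError(f"unknown ablation mode {mode!r}")

    rows = []
    for subset in subsets:
        row: dict = {"features": "+".join(subset)}
        try:
            cfg = dc_replace(model_config, features=tuple(subset))
            dataset = model_mod.build_sequences(steps, cfg)
            train_ds, test_ds = model_mod.split_dataset(dataset, cfg)
            trained = model_mod.train(train_ds, cfg)
            pred = model_mod.predict(trained, test_ds)
            rep = evaluation.bland_altman(test_ds.targets, pred)
            row.update(
                n_train=len(train_ds),
                n_test=len(test_ds),
                bias=rep.bias,
                loa95=rep.loa95,
                rmse=rep.rmse,
                error="",
            )
        except Exception as exc:  # noqa: BLE001 - per-subset failures must not abort
            log.warning("ablation subset %s failed: %s", subset, exc)
            row.update(n_train=0, n_test=0, bias=np.nan, loa95=np.nan,
                       rmse=np.nan, error=str(exc))
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values("loa95", na_position="last").reset_index(drop=True)
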