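"""Stream synchronization, V̇O2 smoothing/outlier removal, and resampling.

The three device streams (motion, V̇O2, HR) run on independent clocks.  A
two-footed jump executed at the start of each recording leaves a sharp
vertical-acceleration spike in the motion trace and a bookmark marker in
the gas-exchange and HR devices; aligning those events gives offline
synchronization to within a fraction of a second, which is sufficient for
signals changing on the time scale of tens of seconds.

The breath-by-breath V̇O2 stream is noisy (spirometer SD on the order of
125 mL/min); it is de-spiked with a robust rolling-median rule and smoothed
with a repeated Savitzky-Golay filter before being interpolated onto the
per-step time grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .synthetic import MotionTrace, PhysioSeries, ValidationError

__all__ = [
    "PreprocessConfig",
    "BookmarkNotFoundError",
    "detect_jump_bookmark",
    "align_streams",
    "smooth_vo2",
    "remove_outliers",
    "resample_to_steps",
]

log = logging.getLogger(__name__)


class BookmarkNotFoundError(RuntimeError):
    """No synchronization spike/marker could be located in a stream."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings for synchronization, smoothing and outlier removal.

    The Savitzky-Golay defaults keep polynomial order 3 and three passes;
    the window (frame length) must be odd and larger than the order, and 11
    samples (55 s at the 0.2 Hz V̇O2 rate) is the smallest conventional
    choice that visibly smooths the spirometer noise.
    """

    sg_polyorder: int = 3
    sg_window: int = 11
    sg_passes: int = 3
    outlier_mad_threshold: float = 5.0
    outlier_window: int = 5
    interpolation: str = "linear"
    sync_tolerance: float = 0.2  # s
    bookmark_search_window: float = 60.0  # s from recording start
    bookmark_min_amplitude: float = 20.0  # m/s^2

    def __post_init__(self) -> None:
        if self.sg_window % 2 != 1 or self.sg_window <= self.sg_polyorder:
            raise ValidationError("sg_window must be odd and exceed sg_polyorder")
        if self.sg_passes < 1:
            raise ValidationError("sg_passes must be >= 1")
        if self.sync_tolerance <= 0:
            raise ValidationError("sync_tolerance must be positive")
        if self.interpolation != "linear":
            raise ValidationError("only linear interpolation is supported")


def detect_jump_bookmark(
    motion: MotionTrace,
    search_window: float = 60.0,
    min_amplitude: float = 20.0,
) -> float:
    """Time of the jump spike: global max of |vertical acceleration|.

    Searches the first ``search_window`` seconds of the recording.  Raises
    :class:`BookmarkNotFoundError` when no sample exceeds ``min_amplitude``.
    """
    if motion.time.size == 0:
        raise ValidationError("empty motion trace")
    mask = motion.time <= motion.time[0] + search_window
    acc = np.abs(motion.vertical_acceleration[mask])
    if acc.size == 0 or float(acc.max()) < min_amplitude:
        raise BookmarkNotFoundError(
            f"no bookmark found: no |vertical acceleration| above "
            f"{min_amplitude} m/s^2 in the first {search_window} s"
        )
    return float(motion.time[mask][int(np.argmax(acc))])


def align_streams(
    motion: MotionTrace,
    vo2: PhysioSeries,
    hr: PhysioSeries,
    motion_bookmark: float | None = None,
    vo2_bookmark: float | None = None,
    hr_bookmark: float | None = None,
    config: PreprocessConfig | None = None,
) -> tuple[MotionTrace, PhysioSeries, PhysioSeries, dict[str, float]]:
    """Shift every stream so its bookmark lands at t = 0.

    Bookmarks default to the motion spike found by
    :func:`detect_jump_bookmark` and to each physiological series'
    recorded ``bookmark_time``; a stream without one raises
    :class:`BookmarkNotFoundError` naming the stream.  Returns the aligned
    streams and the applied shifts (the negated bookmarks), which on
    synthetic data recover the injected offsets up to marker jitter.
    """
    config = config or PreprocessConfig()
    if motion_bookmark is None:
        motion_bookmark = detect_jump_bookmark(
            motion, config.bookmark_search_window, config.bookmark_min_amplitude
        )
    if vo2_bookmark is None:
        vo2_bookmark = vo2.bookmark_time
    if hr_bookmark is None:
        hr_bookmark = hr.bookmark_time
    for name, bm in (("vo2", vo2_bookmark), ("hr", hr_bookmark)):
        if bm is None:
            raise BookmarkNotFoundError(f"stream {name!r} has no bookmark")
    shifts = {
        "motion": -float(motion_bookmark),
        "vo2": -float(vo2_bookmark),
        "hr": -float(hr_bookmark),
    }
    return (
        motion.shifted(shifts["motion"]),
        vo2.shifted(shifts["vo2"]),
        hr.shifted(shifts["hr"]),
        shifts,
    )


def smooth_vo2(series: PhysioSeries, config: PreprocessConfig | None = None) -> PhysioSeries:
    """Repeated Savitzky-Golay smoothing; timestamps and length unchanged.

    Boundary samples are handled by refitting the polynomial on the
    truncated edge windows (``mode='interp'``), which preserves the
    polynomial-reproduction property in the interior.
    """
    config = config or PreprocessConfig()
    if series.values.size < config.sg_window:
        raise ValidationError(
            f"series of length {series.values.size} is shorter than the "
            f"smoothing window {config.sg_window}"
        )
    vals = series.values.astype(float)
    for _ in range(config.sg_passes):
        vals = savgol_filter(vals, config.sg_window, config.sg_polyorder, mode="interp")
    if series.quantity == "vo2":
        vals = np.clip(vals, 1e-9, None)
    return replace(series, values=vals)


def remove_outliers(
    series: PhysioSeries, config: PreprocessConfig | None = None
) -> PhysioSeries:
    """Replace samples far from a rolling median by linear interpolation.

    A sample is an outlier when it deviates from the rolling median by more
    than ``outlier_mad_threshold`` robust standard deviations
    (1.4826 x median absolute deviation of the residuals).  When the
    residual MAD is zero (e.g. a constant series), any nonzero deviation is
    treated as an outlier.  The number of replaced samples is logged.
    """
    from scipy.ndimage import median_filter

    config = config or PreprocessConfig()
    x = series.values.astype(float)
    if x.size < 5:
        raise ValidationError("outlier removal needs at least 5 samples")
    med = median_filter(x, size=config.outlier_window, mode="nearest")
    resid = x - med
    mad = float(np.median(np.abs(resid)))
    robust_sd = 1.4826 * mad
    if robust_sd == 0.0:
        mask = resid != 0.0
    else:
        mask = np.abs(resid) > config.outlier_mad_threshold * robust_sd
    n_out = int(mask.sum())
    if n_out:
        good = ~mask
        if good.sum() < 2:
            raise ValidationError("too few inliers to interpolate over")
        x = x.copy()
        x[mask] = np.interp(series.time[mask], series.time[good], x[good])
        log.info("remove_outliers: replaced %d of %d samples", n_out, x.size)
    return replace(series, values=x)


def resample_to_steps(
    series: PhysioSeries, step_times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate the series at per-step times; never extrapolate.

    Steps outside the series' time span are dropped (and logged).  Returns
    ``(values, kept_mask)`` where ``kept_mask`` marks the retained steps.
    Raises when no step falls inside the span.
    """
    step_times = np.asarray(step_times, dtype=float)
    kept = (step_times >= series.time[0]) & (step_times <= series.time[-1])
    if not kept.any():
        raise ValidationError("no step time falls inside the series' time span")
    dropped = int((~kept).sum())
    if dropped:
        log.info("resample_to_steps: dropped %d steps outside the series span", dropped)
    vals = np.interp(step_times[kept], series.time, series.values)
    return vals, kept
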