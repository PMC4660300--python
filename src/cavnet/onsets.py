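"""Fluorescence-trace processing: from ROI traces to cluster onset times.

A cluster activation shows up as a sharp fluorescence rise followed by a
slow indicator decay.  Onsets are detected where the (denoised) signal
amplitude above baseline and its derivative are *concurrently* high
relative to the trace's noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FluorescenceRecording", "OnsetTrain", "detect_onsets"]

#: Gaussian-consistency factor for the median absolute deviation
_MAD_TO_SD = 1.4826


@dataclass
class FluorescenceRecording:
    """Time x ROI fluorescence trace table."""

    traces: np.ndarray            # (T, n) trace units
    frame_dt: float               # s
    roi_ids: list = field(default_factory=list)
    condition: str | None = None     # "before" | "after"
    cavity_role: str | None = None   # "control" | "M" | "Abeta" | "M-Abeta"

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D time x ROI array")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")
        if not self.roi_ids:
            self.roi_ids = [f"c{i:03d}" for i in range(self.traces.shape[1])]
        if len(self.roi_ids) != self.traces.shape[1]:
            raise ValueError("roi_ids length must match the number of ROI columns")

    @property
    def n_frames(self) -> int:
        return self.traces.shape[0]

    @property
    def n_rois(self) -> int:
        return self.traces.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_dt


@dataclass
class OnsetTrain:
    """Sorted activation times of one cluster."""

    cluster_id: object
    onset_times: np.ndarray  # sorted seconds

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        if self.onset_times.size > 1 and np.any(np.diff(self.onset_times) <= 0):
            raise ValueError("onset times must be strictly increasing")

    def __len__(self) -> int:
        return self.onset_times.size

    def rate_per_min(self, duration_s: float) -> float:
        return 60.0 * self.onset_times.size / duration_s


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge-shrinking windows."""
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    out = np.convolve(x, kernel, mode="same")
    # correct shrunken edge windows
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    return out / norm


def _running_percentile(
    x: np.ndarray, window_frames: int, q: float, hop_frames: int
) -> np.ndarray:
    """Percentile of ``x`` in sliding windows, linearly interpolated to all frames."""
    n = x.size
    window_frames = min(window_frames, n)
    hop_frames = max(1, min(hop_frames, n))
    centers = np.arange(0, n, hop_frames)
    half = window_frames // 2
    starts = np.clip(centers - half, 0, max(0, n - window_frames))
    # windows all have the same length -> vectorized percentile
    idx = starts[:, None] + np.arange(window_frames)[None, :]
    vals = np.percentile(x[idx], q, axis=1)
    return np.interp(np.arange(n), centers, vals)


def detect_onsets(
    recording: FluorescenceRecording,
    amp_k: float = 3.0,
    deriv_k: float = 2.0,
    refractory: float = 0.5,
    *,
    baseline_window: float = 30.0,
    baseline_percentile: float = 10.0,
    smooth_frames: int = 3,
) -> list[OnsetTrain]:
    """Detect cluster activation onsets in every ROI trace.

    Per ROI: the trace is smoothed with a ``smooth_frames``-point moving
    average; the baseline is a running ``baseline_percentile``-th percentile
    over ``baseline_window`` seconds; the noise level is the MAD-based
    robust s.d. of the raw baseline-subtracted trace.  A frame qualifies
    when the smoothed amplitude above baseline exceeds ``amp_k`` times the
    noise s.d. AND the forward difference of the smoothed trace exceeds
    ``deriv_k`` times the raw derivative's robust s.d.  The onset is the
    first frame of each qualifying run; onsets closer than ``refractory``
    seconds merge into one.

    Thresholds are expressed in units of the *raw* trace noise but applied
    to the denoised signal, which suppresses false positives on transient-
    free traces while leaving genuine calcium transients (whose amplitude
    far exceeds the noise) untouched.
    """
    if amp_k <= 0 or deriv_k <= 0:
        raise ValueError("amp_k and deriv_k must be positive")
    if np.isnan(recording.traces).any():
        raise ValueError("recording contains NaN frames")

    dt = recording.frame_dt
    win = max(1, int(round(baseline_window / dt)))
    hop = max(1, win // 30)
    refractory_frames = int(round(refractory / dt))

    trains: list[OnsetTrain] = []
    for j in range(recording.n_rois):
        raw = recording.traces[:, j]
        if raw.size == 0:
            trains.append(OnsetTrain(recording.roi_ids[j], np.empty(0)))
            continue
        smoothed = _smooth(raw, smooth_frames)
        baseline = _running_percentile(raw, win, baseline_percentile, hop)
        resid = raw - baseline
        sd = _MAD_TO_SD * np.median(np.abs(resid - np.median(resid)))

        dsmooth = np.diff(smoothed, prepend=smoothed[0])
        draw = np.diff(raw, prepend=raw[0])
        sd_deriv = _MAD_TO_SD * np.median(np.abs(draw - np.median(draw)))

        if sd == 0.0 or sd_deriv == 0.0:
            # constant (or noiseless-flat) trace: nothing to detect
            trains.append(OnsetTrain(recording.roi_ids[j], np.empty(0)))
            continue

        hot = ((smoothed - baseline) > amp_k * sd) & (dsmooth > deriv_k * sd_deriv)
        frames = np.flatnonzero(hot)
        if frames.size == 0:
            trains.append(OnsetTrain(recording.roi_ids[j], np.empty(0)))
            continue
        # first frame of each qualifying run, then runs within the
        # refractory of the previous onset merged into it
        run_starts = frames[np.r_[True, np.diff(frames) > 1]]
        starts = [int(run_starts[0])]
        for f in run_starts[1:]:
            if f - starts[-1] > refractory_frames:
                starts.append(int(f))
        trains.append(OnsetTrain(recording.roi_ids[j], np.asarray(starts) * dt))
    return trains
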