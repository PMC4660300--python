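"""Homogeneous-culture analysis: network bursts and burst-rate ratios.

Homogeneous cultures (no clustering; ROIs are grid elements of ~5-10
neurons) show all-or-none collective events - network bursts - instead of
community-structured sequences.  A burst is a firing sequence whose
participating ROI fraction reaches ``min_fraction``; chemical damage is
quantified as the drift-corrected ratio of burst rates after/before.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .onsets import OnsetTrain
from .sequences import detect_sequences

__all__ = ["BurstTrain", "detect_network_bursts", "burst_rate_ratio"]

#: default ROI grid used for real recordings (30 x 30 per cavity)
GRID_SHAPE = (30, 30)


@dataclass
class BurstTrain:
    """Network-burst times and per-burst ROI participation."""

    burst_times: np.ndarray   # sorted seconds (first onset of each burst)
    participation: np.ndarray # fraction of ROIs active per burst, in [0, 1]
    duration: float           # recording length, s

    def __post_init__(self) -> None:
        self.burst_times = np.asarray(self.burst_times, dtype=float)
        self.participation = np.asarray(self.participation, dtype=float)

    @property
    def n_bursts(self) -> int:
        return self.burst_times.size

    @property
    def rate_per_min(self) -> float:
        return 60.0 * self.n_bursts / self.duration


def detect_network_bursts(
    onset_trains: list[OnsetTrain],
    duration: float,
    window: float = 0.2,
    min_fraction: float = 0.5,
) -> BurstTrain:
    """Detect network bursts on grid-ROI onset trains.

    Uses the sequence chaining rule; a chain qualifies as a burst when the
    fraction of distinct participating ROIs is >= ``min_fraction``.  The
    burst time is the first onset of the chain.
    """
    if not onset_trains:
        raise ValueError("need at least one ROI")
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    n_rois = len(onset_trains)
    sequences = detect_sequences(onset_trains, window=window)
    times, fracs = [], []
    for seq in sequences:
        frac = seq.size / n_rois
        if frac >= min_fraction:
            times.append(seq.start)
            fracs.append(frac)
    return BurstTrain(np.asarray(times), np.asarray(fracs), duration=duration)


def burst_rate_ratio(
    after: BurstTrain,
    before: BurstTrain,
    control_after: BurstTrain | None = None,
    control_before: BurstTrain | None = None,
) -> float:
    """After/before burst-rate ratio, drift-corrected by the control pair.

    With a control pair the perturbed ratio is divided by the control's
    after/before ratio, exactly as the firing-rate drift correction.
    """
    if before.n_bursts == 0:
        raise ValueError("no bursts before perturbation: ratio undefined")
    ratio = after.rate_per_min / before.rate_per_min
    if control_after is not None or control_before is not None:
        if control_after is None or control_before is None:
            raise ValueError("provide both control trains or neither")
        if control_before.n_bursts == 0 or control_after.n_bursts == 0:
            raise ValueError("control bursts missing: drift unmeasurable")
        ratio /= control_after.rate_per_min / control_before.rate_per_min
    return float(ratio)
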