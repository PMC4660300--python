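"""Activity statistics: firing rates, drift correction and difference summaries.

Two scalar measures summarize a cavity's spontaneous activity: the mean
clusters' firing rate Phi (mean over clusters of the per-cluster rate
phi_i, silent clusters included at zero) and the sequences' occurrence
rate Psi (number of detected firing sequences per minute).  Because the
whole well shares temperature/evaporation drifts between the first and the
second recording, perturbed-cavity quantities are divided by the control
cavity's second/first ratio before any comparison.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .onsets import OnsetTrain
from .sequences import FiringSequence

__all__ = [
    "ActivitySummary",
    "DriftModel",
    "DifferenceSummary",
    "summarize_activity",
    "drift_correct",
    "difference_summary",
    "compare_conditions",
    "significance_stars",
]


@dataclass(frozen=True)
class ActivitySummary:
    """Per-cavity activity rates, all in events per minute."""

    cluster_ids: tuple
    phi: np.ndarray        # (N,) per-cluster firing rate, /min
    Phi: float             # mean clusters' firing rate, /min
    Psi: float             # sequences' occurrence rate, /min
    duration: float        # s
    condition: str | None = None


@dataclass(frozen=True)
class DriftModel:
    """Control-cavity drift ratios (second recording / first recording)."""

    r_phi: float
    r_psi: float

    def __post_init__(self) -> None:
        if not self.r_phi > 0:
            raise ValueError("drift unmeasurable: control firing-rate ratio must be > 0")


@dataclass(frozen=True)
class DifferenceSummary:
    """Per-cluster changes between the (corrected) after and before summaries."""

    delta_phi: np.ndarray       # phi_after_corrected - phi_before, /min
    delta_phi_norm: np.ndarray  # bounded normalized difference in [-1, 1]
    mu: float                   # Gaussian-fit mean of the normalized differences
    sigma: float                # Gaussian-fit s.d.
    gamma: float                # Fisher sample skewness (bias corrected)


def summarize_activity(
    onset_trains: list[OnsetTrain],
    sequences: list[FiringSequence],
    duration: float,
    condition: str | None = None,
) -> ActivitySummary:
    """Compute phi_i, Phi and Psi for one recording of ``duration`` seconds."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    minutes = duration / 60.0
    phi = np.array([len(t) / minutes for t in onset_trains])
    return ActivitySummary(
        cluster_ids=tuple(t.cluster_id for t in onset_trains),
        phi=phi,
        Phi=float(phi.mean()) if phi.size else 0.0,
        Psi=len(sequences) / minutes,
        duration=duration,
        condition=condition,
    )


def drift_correct(
    perturbed_before: ActivitySummary,
    perturbed_after: ActivitySummary,
    control_before: ActivitySummary,
    control_after: ActivitySummary,
) -> tuple[ActivitySummary, DriftModel]:
    """Divide the perturbed after-summary by the control drift ratios.

    ``r_phi = Phi_control_after / Phi_control_before`` rescales phi and Phi;
    Psi is rescaled by the control's own sequence-rate ratio (falling back
    to ``r_phi`` when the control produced no sequences).
    """
    if control_before.Phi <= 0:
        raise ValueError("drift unmeasurable: control cavity is silent before perturbation")
    r_phi = control_after.Phi / control_before.Phi
    if control_before.Psi > 0 and control_after.Psi > 0:
        r_psi = control_after.Psi / control_before.Psi
    else:
        r_psi = r_phi
    model = DriftModel(r_phi=r_phi, r_psi=r_psi)
    corrected = dataclasses.replace(
        perturbed_after,
        phi=perturbed_after.phi / r_phi,
        Phi=perturbed_after.Phi / r_phi,
        Psi=perturbed_after.Psi / r_psi,
    )
    return corrected, model


def _gaussian(x: np.ndarray, a: float, mu: float, sigma: float) -> np.ndarray:
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _fit_gaussian(values: np.ndarray) -> tuple[float, float]:
    """Least-squares Gaussian fit to a Freedman-Diaconis histogram.

    Falls back to the sample mean/s.d. when the histogram is degenerate or
    the fit does not converge.
    """
    mean, sd = float(np.mean(values)), float(np.std(values))
    if sd == 0 or values.size < 4:
        return mean, sd
    counts, edges = np.histogram(values, bins="fd", density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if np.count_nonzero(counts) < 4:
        return mean, sd
    try:
        popt, _ = optimize.curve_fit(
            _gaussian, centers, counts,
            p0=(counts.max(), mean, sd), maxfev=5000,
        )
        return float(popt[1]), abs(float(popt[2]))
    except RuntimeError:
        return mean, sd


def difference_summary(
    before: ActivitySummary, after_corrected: ActivitySummary
) -> DifferenceSummary:
    """Per-cluster firing-rate differences between conditions.

    The normalized difference (phiP - phi0) / (phiP + phi0) is bounded in
    [-1, 1]: a cluster silenced by the perturbation scores -1, a newly
    activated one +1, and a cluster silent in both recordings scores 0.
    """
    if before.cluster_ids != after_corrected.cluster_ids:
        raise ValueError("summaries cover different cluster sets")
    phi0, phiP = before.phi, after_corrected.phi
    delta = phiP - phi0
    total = phiP + phi0
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(total > 0, delta / np.where(total > 0, total, 1.0), 0.0)
    gamma = float(stats.skew(norm, bias=False)) if norm.size >= 3 and np.std(norm) > 0 else 0.0
    mu, sigma = _fit_gaussian(norm)
    return DifferenceSummary(delta_phi=delta, delta_phi_norm=norm, mu=mu, sigma=sigma, gamma=gamma)


def compare_conditions(values_a, values_b, test: str = "t") -> float:
    """Two-sided p-value comparing two samples (Student t or KS)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if test == "t":
        if np.std(a) == 0 and np.std(b) == 0:
            if a.mean() == b.mean():
                return 1.0
            raise ValueError("degenerate constant samples with distinct means")
        p = stats.ttest_ind(a, b).pvalue
    elif test.lower() == "ks":
        p = stats.ks_2samp(a, b).pvalue
    else:
        raise ValueError("test must be 't' or 'KS'")
    return float(p)


def significance_stars(p: float) -> str:
    """Printing convention: * for p < 0.05, ** for p < 0.005."""
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return ""
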