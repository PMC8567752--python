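"""Enhancement-curve preprocessing: baseline, bolus arrival, normalization.

The raw lesion-mean signal S(t) is converted to relative enhancement on a
clock zeroed at bolus arrival:

* the baseline S0 is the mean of the first five frames (assumed pre-bolus);
* bolus arrival is the first frame whose raw intensity strictly exceeds
  1.05 * S0;
* frames before arrival are dropped, the arrival frame becomes t = 0 and
  enhancement is (S - S0)/S0.

A curve in which no frame crosses the threshold, or in which the threshold
is crossed inside the 5-frame baseline window, is unanalyzable and raises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    BaselineContaminationError,
    InsufficientDataError,
    NoArrivalError,
)

__all__ = [
    "RawCurve",
    "NormalizedCurve",
    "compute_baseline",
    "detect_bolus_arrival",
    "normalize_curve",
    "preprocess_curve",
    "BASELINE_FRAMES",
    "ARRIVAL_THRESHOLD",
]

BASELINE_FRAMES = 5
ARRIVAL_THRESHOLD = 1.05  # raw intensity must strictly exceed threshold * S0


@dataclass(frozen=True)
class RawCurve:
    """Timestamped raw signal intensities for one lesion, as acquired."""

    patient_id: str
    times: np.ndarray  # seconds, strictly increasing
    intensities: np.ndarray  # raw signal units, non-negative

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", s)
        if t.size != s.size:
            raise ValueError("times and intensities must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class NormalizedCurve:
    """Post-arrival relative-enhancement series on a zeroed clock."""

    patient_id: str
    times: np.ndarray  # seconds since bolus arrival, times[0] == 0
    enhancement: np.ndarray  # (S - S0)/S0
    baseline_intensity: float
    arrival_index: int


def compute_baseline(curve: RawCurve) -> float:
    """Mean raw intensity of the first five frames."""
    if curve.intensities.size < BASELINE_FRAMES:
        raise InsufficientDataError(
            f"baseline needs {BASELINE_FRAMES} frames, curve "
            f"{curve.patient_id!r} has {curve.intensities.size}"
        )
    return float(np.mean(curve.intensities[:BASELINE_FRAMES]))


def detect_bolus_arrival(curve: RawCurve, baseline: float) -> int:
    """Index of the first frame strictly exceeding 1.05 * baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    above = curve.intensities > ARRIVAL_THRESHOLD * baseline
    if not above.any():
        raise NoArrivalError(
            f"curve {curve.patient_id!r}: no frame exceeds "
            f"{ARRIVAL_THRESHOLD:.2f} x baseline"
        )
    return int(np.argmax(above))


def normalize_curve(curve: RawCurve, baseline: float, arrival: int) -> NormalizedCurve:
    """Drop pre-arrival frames, zero the clock and scale to enhancement."""
    if not 0 <= arrival < curve.times.size:
        raise ValueError(f"arrival index {arrival} out of range")
    t = curve.times[arrival:] - curve.times[arrival]
    e = (curve.intensities[arrival:] - baseline) / baseline
    return NormalizedCurve(
        patient_id=curve.patient_id,
        times=t,
        enhancement=e,
        baseline_intensity=baseline,
        arrival_index=arrival,
    )


def preprocess_curve(curve: RawCurve) -> NormalizedCurve:
    """Full preprocessing chain for one curve.

    Raises
    ------
    InsufficientDataError
        Fewer than five frames.
    NoArrivalError
        Threshold never crossed (curve unanalyzable).
    BaselineContaminationError
        Arrival inside the five-frame baseline window.
    """
    baseline = compute_baseline(curve)
    arrival = detect_bolus_arrival(curve, baseline)
    if arrival < BASELINE_FRAMES:
        raise BaselineContaminationError(
            f"curve {curve.patient_id!r}: bolus arrival at frame {arrival} "
            f"contaminates the {BASELINE_FRAMES}-frame baseline"
        )
    return normalize_curve(curve, baseline, arrival)
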