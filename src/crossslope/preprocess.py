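"""Signal conditioning for gait trials.

Four operations, applied before windowing: zero-phase low-pass Butterworth
filtering (6 Hz for kinematics, 20 Hz for force-plate channels), body-weight
normalization of forces and moments, referencing ankle angles to their
unloaded swing configuration, and numerical differentiation for angular
velocity/acceleration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .gait_data import ConfigurationError, EventError, TrialRecording

__all__ = [
    "FilterSpec",
    "SwingReference",
    "butterworth_lowpass",
    "butterworth_gain",
    "normalize_to_bodyweight",
    "normalize_ankle_to_swing",
    "differentiate",
    "preprocess_trial",
    "GRAVITY",
]

GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter parameters.

    ``zero_phase`` applies the filter forward and backward (filtfilt), which
    doubles the effective order of the magnitude response and removes phase
    lag — important here because feature windows are anchored to the
    heel-strike event.
    """

    order: int = 4
    cutoff: float = 6.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order <= 0 or self.order % 2:
            raise ConfigurationError("filter order must be a positive even integer")
        if self.cutoff <= 0:
            raise ConfigurationError("cutoff must be positive")

    def validate_for(self, sample_rate: float) -> None:
        if self.cutoff >= sample_rate / 2:
            raise ConfigurationError(
                f"cutoff {self.cutoff} Hz ≥ Nyquist ({sample_rate / 2} Hz)"
            )


KINEMATIC_FILTER = FilterSpec(order=4, cutoff=6.0)
GRF_FILTER = FilterSpec(order=4, cutoff=20.0)


def butterworth_lowpass(
    series, sample_rate: float, spec: FilterSpec = KINEMATIC_FILTER
) -> np.ndarray:
    """Low-pass Butterworth filter, zero-phase by default. Unit DC gain."""
    spec.validate_for(sample_rate)
    x = np.asarray(series, dtype=float)
    if len(x) <= 3 * spec.order:
        raise ValueError(
            f"series length {len(x)} too short for order-{spec.order} filter"
        )
    sos = sps.butter(spec.order, spec.cutoff, btype="low", fs=sample_rate, output="sos")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def butterworth_gain(freq_hz, sample_rate: float, spec: FilterSpec) -> np.ndarray:
    """Realized magnitude gain of the filter at ``freq_hz`` (squared when
    zero-phase, because the filter runs twice)."""
    sos = sps.butter(spec.order, spec.cutoff, btype="low", fs=sample_rate, output="sos")
    _, h = sps.sosfreqz(sos, worN=2 * np.pi * np.atleast_1d(freq_hz) / sample_rate)
    mag = np.abs(h)
    return mag**2 if spec.zero_phase else mag


def normalize_to_bodyweight(series, body_mass: float | None) -> np.ndarray:
    """Divide a force/moment series by body weight (mass × g)."""
    if body_mass is None or body_mass <= 0:
        raise ConfigurationError("body_mass must be a positive number of kilograms")
    return np.asarray(series, dtype=float) / (body_mass * GRAVITY)


@dataclass(frozen=True)
class SwingReference:
    """Swing interval used to zero ankle angles, seconds relative to heel
    strike (negative = before). Default [−400, −250] ms: late swing with the
    prosthesis unloaded, ending where mid-swing windows begin."""

    start_s: float = -0.400
    end_s: float = -0.250

    def __post_init__(self) -> None:
        if not (self.start_s < self.end_s <= 0.0):
            raise ConfigurationError(
                "swing reference must satisfy start < end ≤ 0 (relative to heel strike)"
            )


def normalize_ankle_to_swing(
    angle_series,
    sample_rate: float,
    heel_strike_time: float,
    ref: SwingReference = SwingReference(),
) -> np.ndarray:
    """Subtract the mean angle over the unloaded-swing reference interval."""
    x = np.asarray(angle_series, dtype=float)
    i0 = int(round((heel_strike_time + ref.start_s) * sample_rate))
    i1 = int(round((heel_strike_time + ref.end_s) * sample_rate))
    if i0 < 0 or i1 > len(x) or i1 <= i0:
        raise EventError(
            f"swing reference interval [{ref.start_s}, {ref.end_s}]s relative "
            f"to heel strike falls outside the recording"
        )
    return x - x[i0:i1].mean()


def differentiate(series, sample_rate: float, order: int = 1) -> np.ndarray:
    """First or second time derivative: central differences on the interior,
    second-order one-sided stencils at the ends (length preserved)."""
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    x = np.asarray(series, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    dt = 1.0 / sample_rate
    d = np.gradient(x, dt, edge_order=2)
    if order == 2:
        d = np.gradient(d, dt, edge_order=2)
    return d


_FORCE_PREFIXES = ("grf_",)
_MOMENT_SUFFIXES = ("_moment",)
_PLATE_PREFIXES = ("grf_", "cop_")
_ANGLE_NAMES = ("ankle_flexion_angle", "ankle_inversion_angle")


def preprocess_trial(
    trial: TrialRecording,
    kinematic_filter: FilterSpec = KINEMATIC_FILTER,
    grf_filter: FilterSpec = GRF_FILTER,
    swing_ref: SwingReference = SwingReference(),
    bodyweight_normalize: bool = True,
    recompute_ankle_derivatives: bool = False,
) -> TrialRecording:
    """Condition every signal of a trial.

    Force-plate channels (grf_*, cop_*) get the 20 Hz filter; everything
    else the 6 Hz filter. GRFs and ankle moments are divided by body weight
    when a body mass is recorded. Ankle angles are referenced to the
    unloaded-swing mean; optionally their first/second derivatives are
    recomputed from the conditioned angle.
    """
    out: dict[str, np.ndarray] = {}
    for name, x in trial.series.items():
        spec = grf_filter if name.startswith(_PLATE_PREFIXES) else kinematic_filter
        y = butterworth_lowpass(x, trial.sample_rate, spec)
        if bodyweight_normalize and trial.body_mass is not None and (
            name.startswith(_FORCE_PREFIXES) or name.endswith(_MOMENT_SUFFIXES)
        ):
            y = normalize_to_bodyweight(y, trial.body_mass)
        if name in _ANGLE_NAMES:
            y = normalize_ankle_to_swing(
                y, trial.sample_rate, trial.heel_strike_time, swing_ref
            )
        out[name] = y
    if recompute_ankle_derivatives:
        for plane in ("flexion", "inversion"):
            angle = out.get(f"ankle_{plane}_angle")
            if angle is None:
                continue
            if f"ankle_{plane}_angvel" in out:
                out[f"ankle_{plane}_angvel"] = differentiate(angle, trial.sample_rate, 1)
            if f"ankle_{plane}_angacc" in out:
                out[f"ankle_{plane}_angacc"] = differentiate(angle, trial.sample_rate, 2)
    return trial.with_series(out)
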