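"""Heel-strike-anchored sliding windows on the 120 Hz sample grid.

Analysis windows are 150 ms long and advance one sample (8.33 ms at
120 Hz). A window is *mid-swing* — the region used for classification —
when at least half of its data precede heel strike by enough margin and
less than half follow it. Two readings of that rule are provided:

* ``span_rule`` (default): mid-swing iff the window starts no more than
  250 ms before heel strike and ends no later than 75 ms after it, i.e.
  start ∈ [−250, −75] ms. This matches a classification region running
  from mid-swing up to 75 ms after heel strike (22 windows per stride).
* ``strict_rule``: start ∈ [−250, −192] ms and end ≤ +75 ms (7 windows).
"""

from __future__ import annotations

from dataclasses import dataclass

from .gait_data import ConfigurationError, TrialRecording

__all__ = [
    "WindowSpec",
    "Window",
    "classify_window_region",
    "enumerate_windows",
    "midswing_window_count",
]

#: Timing tolerance (ms) for boundary comparisons: start times computed as
#: sample_index · 1000/fs carry float rounding of order 1e-13 ms.
EPS_MS = 1e-6


@dataclass(frozen=True)
class WindowSpec:
    length_ms: float = 150.0
    step_ms: float = 1000.0 / 120.0  # exactly one sample at 120 Hz
    midswing_earliest_start_ms: float = 250.0  # before heel strike
    midswing_latest_start_ms: float = 192.0  # before heel strike
    latest_end_after_hs_ms: float = 75.0
    rule: str = "span_rule"

    def __post_init__(self) -> None:
        if self.length_ms <= 0 or self.step_ms <= 0:
            raise ConfigurationError("window length and step must be positive")
        if not (self.midswing_earliest_start_ms > self.midswing_latest_start_ms >= 0):
            raise ConfigurationError(
                "need earliest_start > latest_start ≥ 0 (both before heel strike)"
            )
        if self.latest_end_after_hs_ms < 0:
            raise ConfigurationError("latest_end_after_hs_ms must be ≥ 0")
        if self.rule not in ("span_rule", "strict_rule"):
            raise ConfigurationError(f"unknown window rule {self.rule!r}")

    def length_samples(self, sample_rate: float) -> int:
        n = int(round(self.length_ms * sample_rate / 1000.0))
        if n < 2:
            raise ConfigurationError("window shorter than 2 samples")
        return n

    def step_samples(self, sample_rate: float) -> int:
        return max(1, int(round(self.step_ms * sample_rate / 1000.0)))


@dataclass(frozen=True)
class Window:
    """Half-open sample range [start_sample, end_sample) within a trial."""

    trial_id: str
    start_sample: int
    end_sample: int
    start_time_rel_hs_ms: float
    region: str


def classify_window_region(start_time_rel_hs_ms: float, spec: WindowSpec) -> str:
    """Assign a window (by its start time relative to heel strike, ms) to
    ``mid_swing`` or ``other``. Pure function of (start, spec)."""
    s = start_time_rel_hs_ms
    end = s + spec.length_ms
    if spec.rule == "span_rule":
        ok = (
            s >= -spec.midswing_earliest_start_ms - EPS_MS
            and end <= spec.latest_end_after_hs_ms + EPS_MS
        )
    else:  # strict_rule
        ok = (
            s >= -spec.midswing_earliest_start_ms - EPS_MS
            and s <= -spec.midswing_latest_start_ms + EPS_MS
            and end <= spec.latest_end_after_hs_ms + EPS_MS
        )
    return "mid_swing" if ok else "other"


def enumerate_windows(trial: TrialRecording, spec: WindowSpec) -> list[Window]:
    """All windows on the sample grid, in time order, with regions assigned.

    Window starts step by ``step_samples`` from sample 0; start times are
    reported relative to the heel-strike sample (heel strike snapped to the
    nearest sample).
    """
    fs = trial.sample_rate
    length = spec.length_samples(fs)
    step = spec.step_samples(fs)
    n = trial.n_samples
    if n < length:
        raise ValueError(
            f"trial {trial.trial_id!r} has {n} samples, shorter than one "
            f"{length}-sample window"
        )
    hs = trial.heel_strike_sample
    windows = []
    for start in range(0, n - length + 1, step):
        rel_ms = (start - hs) * 1000.0 / fs
        windows.append(
            Window(
                trial_id=trial.trial_id,
                start_sample=start,
                end_sample=start + length,
                start_time_rel_hs_ms=rel_ms,
                region=classify_window_region(rel_ms, spec),
            )
        )
    return windows


def midswing_window_count(spec: WindowSpec, sample_rate: float) -> int:
    """Closed-form number of mid-swing windows per stride.

    Counts start samples s (relative to heel strike, on the step grid
    anchored at the heel-strike sample) whose start time classifies as
    mid-swing. Equals brute-force enumeration for any valid spec.
    """
    import math

    dt_ms = 1000.0 / sample_rate
    step = spec.step_samples(sample_rate)
    nudge = EPS_MS / dt_ms  # tolerance converted to samples

    lo_ms = -spec.midswing_earliest_start_ms
    if spec.rule == "span_rule":
        hi_ms = spec.latest_end_after_hs_ms - spec.length_ms
    else:
        hi_ms = min(
            -spec.midswing_latest_start_ms,
            spec.latest_end_after_hs_ms - spec.length_ms,
        )
    s_lo = math.ceil(lo_ms / dt_ms - nudge)
    s_hi = math.floor(hi_ms / dt_ms + nudge)
    if s_hi < s_lo:
        return 0
    # count multiples of `step` in [s_lo, s_hi]
    return math.floor(s_hi / step) - math.ceil(s_lo / step) + 1
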