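"""Synthetic stride generator with the statistical structure the analysis
assumes.

Each trial is one 1.2 s stride sampled at 120 Hz with heel strike at
0.8 s. Every signal is a smooth periodic baseline (up to three harmonics
of the stride frequency) plus a terrain effect that ramps in over late
swing and early stance, a per-subject offset, and additive noise:

    x_j(t) = baseline_j(t) + δ_{j,terrain} · w(t) + u_{s,j} + ε_j(t)

with ``w`` a smooth 0→1→0 bump supported on the effect window (default
−250 ms to +75 ms around heel strike — exactly where mid-swing windows
look), ``u_{s,j} ~ N(0, τ_j²)`` fixed per subject, and ε white or AR(1)
noise. Flush is the zero-effect reference class; the ±15° slopes carry
opposite-signed effects by default. Everything is deterministic given
(seed, subject, terrain, trial).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .gait_data import (
    ConfigurationError,
    Dataset,
    SignalId,
    SignalInventory,
    TerrainClass,
    TERRAIN_ORDER,
    TrialRecording,
)

__all__ = [
    "SyntheticConfig",
    "generate_trial",
    "generate_dataset",
    "preset_discriminative",
    "single_informative_config",
    "shifted_config",
    "study_cohort",
]

#: Harmonic amplitude falloff of the baseline waveform.
_HARMONICS = (1.0, 0.5, 0.25)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale defaults: 3 subjects, 5 trials per class per subject
    (the protocol collected 4–6 per block), 120 Hz sampling, one cross-slope
    step per trial."""

    n_subjects: int = 3
    trials_per_class: int = 5
    sample_rate: float = 120.0
    stride_duration: float = 1.2
    heel_strike_time: float = 0.8
    #: signal name → {terrain label: effect amplitude}; flush must be 0.
    class_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    effect_window: tuple[float, float] = (-0.250, 0.075)  # s relative to HS
    subject_sd: float = 0.3
    noise_sd: float = 1.0
    noise_model: str = "white"  # or "ar1"
    ar1_rho: float = 0.9
    baseline_amplitude: float = 1.0
    inventory_variant: str = "full_with_ips"
    signals: tuple[SignalId, ...] | None = None  # overrides the variant
    prosthesis: str = "prescribed"
    body_mass: float = 83.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_class < 1:
            raise ConfigurationError("need ≥1 subject and ≥1 trial per class")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.noise_model not in ("white", "ar1"):
            raise ConfigurationError(f"unknown noise model {self.noise_model!r}")
        a, b = self.effect_window
        if not (-self.heel_strike_time < a < b):
            raise ConfigurationError("effect window must start inside the stride")
        if self.heel_strike_time + b > self.stride_duration:
            raise ConfigurationError("effect window extends past the stride end")
        for sig, eff in self.class_effects.items():
            if eff.get("flush", 0.0) != 0.0:
                raise ConfigurationError(
                    f"flush is the reference class; δ must be 0 ({sig})"
                )

    def inventory(self) -> SignalInventory:
        if self.signals is not None:
            return SignalInventory(self.signals, variant="custom")
        return SignalInventory.from_variant(self.inventory_variant)

    @property
    def n_samples(self) -> int:
        return int(round(self.stride_duration * self.sample_rate))


def _effect_ramp(t_rel_hs: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Smooth 0→1→0 bump (sin²) supported on the effect window."""
    a, b = window
    w = np.zeros_like(t_rel_hs)
    inside = (t_rel_hs >= a) & (t_rel_hs <= b)
    w[inside] = np.sin(math.pi * (t_rel_hs[inside] - a) / (b - a)) ** 2
    return w


def _baseline(config: SyntheticConfig, signal_index: int, t: np.ndarray) -> np.ndarray:
    """Deterministic smooth waveform: ≤3 harmonics of the stride frequency
    with phases derived from the signal index (no randomness)."""
    f0 = 1.0 / config.stride_duration
    x = np.zeros_like(t)
    for h, amp in enumerate(_HARMONICS, start=1):
        phase = 2 * math.pi * ((signal_index * 0.37 + h * 0.61) % 1.0)
        x += config.baseline_amplitude * amp * np.sin(2 * math.pi * h * f0 * t + phase)
    return x


def _subject_offsets(config: SyntheticConfig, subject_index: int, n_signals: int) -> np.ndarray:
    rng = np.random.default_rng([config.seed % (2**31), 7919, subject_index])
    return rng.normal(0.0, config.subject_sd, size=n_signals)


def _noise(config: SyntheticConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if config.noise_model == "white":
        return rng.normal(0.0, config.noise_sd, size=n)
    rho = config.ar1_rho
    innov = rng.normal(0.0, config.noise_sd, size=n)
    x = np.empty(n)
    x[0] = innov[0]
    scale = math.sqrt(1.0 - rho**2)
    for i in range(1, n):  # AR(1) with stationary marginal sd = noise_sd
        x[i] = rho * x[i - 1] + scale * innov[i]
    return x


def generate_trial(
    config: SyntheticConfig,
    subject_index: int,
    terrain: TerrainClass,
    trial_index: int,
) -> TrialRecording:
    """One synthetic stride; bit-identical for identical arguments."""
    inventory = config.inventory()
    n = config.n_samples
    t = np.arange(n) / config.sample_rate
    t_rel = t - config.heel_strike_time
    ramp = _effect_ramp(t_rel, config.effect_window)
    offsets = _subject_offsets(config, subject_index, len(inventory))
    terrain_code = TERRAIN_ORDER.index(terrain)
    rng = np.random.default_rng(
        [config.seed % (2**31), subject_index, terrain_code, trial_index]
    )
    series: dict[str, np.ndarray] = {}
    for j, sig in enumerate(inventory.signals):
        delta = config.class_effects.get(sig.name, {}).get(terrain.label, 0.0)
        series[sig.name] = (
            _baseline(config, j, t)
            + delta * ramp
            + offsets[j]
            + _noise(config, rng, n)
        )
    return TrialRecording(
        subject_id=f"SYN{subject_index + 1:02d}",
        prosthesis=config.prosthesis,
        terrain=terrain,
        series=series,
        heel_strike_time=config.heel_strike_time,
        sample_rate=config.sample_rate,
        trial_id=f"SYN{subject_index + 1:02d}_{terrain.label}_{trial_index:02d}",
        body_mass=config.body_mass,
    )


def generate_dataset(config: SyntheticConfig, role: str = "synthetic") -> Dataset:
    """n_subjects × 3 terrain classes × trials_per_class trials."""
    trials = [
        generate_trial(config, s, terrain, k)
        for s in range(config.n_subjects)
        for terrain in TERRAIN_ORDER
        for k in range(config.trials_per_class)
    ]
    return Dataset(trials=trials, role=role)


def preset_discriminative(seed: int = 0, **overrides) -> SyntheticConfig:
    """The benchmark configuration for pipeline tests.

    Three signals carry the terrain: ankle inversion angular velocity and
    foot vertical velocity respond positively to the inverting (+15°) slope
    and negatively to the everting one; foot ML angular velocity responds
    with the opposite polarity. Effect amplitude is 3× the noise sd, so a
    single informative signal separates classes clearly while noise-only
    signals stay near chance. Noise is AR(1) (ρ=0.9): adjacent 8.33 ms
    windows of real kinematics are strongly correlated, and white noise
    would make window-level cross-validation look deceptively honest.
    """
    delta = 3.0  # × noise_sd
    effects = {
        "ankle_inversion_angvel": {"inversion": +delta, "eversion": -delta},
        "foot_vert_velocity": {"inversion": +delta, "eversion": -delta},
        "foot_ml_angvel": {"inversion": -delta, "eversion": +delta},
    }
    params = dict(
        class_effects=effects,
        noise_sd=1.0,
        subject_sd=0.3,
        noise_model="ar1",
        ar1_rho=0.9,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def single_informative_config(
    n_signals: int = 8,
    informative: str = "sig_00",
    delta: float = 3.0,
    seed: int = 0,
    **overrides,
) -> SyntheticConfig:
    """A reduced configuration for selection tests: ``n_signals`` generic
    four-stat signals of which exactly one carries class separation."""
    signals = tuple(SignalId(f"sig_{i:02d}") for i in range(n_signals))
    if informative not in {s.name for s in signals}:
        raise ConfigurationError(f"{informative!r} not among the generated signals")
    effects = {informative: {"inversion": +delta, "eversion": -delta}}
    params = dict(
        signals=signals,
        class_effects=effects,
        noise_model="ar1",
        ar1_rho=0.9,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def shifted_config(config: SyntheticConfig, offset_scale: float = 2.0, seed_shift: int = 104729) -> SyntheticConfig:
    """A distribution-shifted sibling of ``config`` (new subjects, larger
    subject offsets) for test-set analogues of the blinded/prototype
    conditions."""
    return replace(
        config,
        subject_sd=config.subject_sd * offset_scale,
        seed=(config.seed + seed_shift) % (2**31),
    )


def study_cohort(seed: int = 0) -> dict[str, SyntheticConfig]:
    """Synthetic analogues of the study's three data collections.

    ``training``: 3 subjects, prescribed prosthesis, visible slope.
    ``test1``: 1 new subject who cannot see the slope — emulated as a
    distribution shift (subject offsets doubled, anticipatory effect
    slightly weaker). ``test2``: 2 new subjects on the prototype
    prosthesis — emulated by attenuating every terrain effect by 20%
    (a slightly different stiffness profile), 4 trials per block.
    """
    training = preset_discriminative(seed=seed)
    test1 = replace(
        shifted_config(training, offset_scale=2.0, seed_shift=104729),
        n_subjects=1,
        class_effects={
            sig: {c: 0.9 * d for c, d in eff.items()}
            for sig, eff in training.class_effects.items()
        },
    )
    test2 = replace(
        shifted_config(training, offset_scale=1.5, seed_shift=1299709),
        n_subjects=2,
        trials_per_class=4,
        prosthesis="prototype",
        class_effects={
            sig: {c: 0.8 * d for c, d in eff.items()}
            for sig, eff in training.class_effects.items()
        },
    )
    return {"training": training, "test1": test1, "test2": test2}
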