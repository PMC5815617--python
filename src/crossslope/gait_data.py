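"""Domain types and plain-text I/O for cross-slope gait trials.

A *trial* is one step onto a cross-slope surface (everting −15°, flush 0°,
or inverting +15°), recorded as a set of uniformly sampled signals on a
shared 120 Hz time base together with the residual-limb heel-strike time.
Trials are serialized as tab-separated text with a ``#``-prefixed metadata
preamble, and collections of trials are described by a one-path-per-line
manifest.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TerrainClass",
    "TERRAIN_ORDER",
    "SignalSource",
    "StatPolicy",
    "SignalId",
    "SignalInventory",
    "TrialRecording",
    "Dataset",
    "TrialDialect",
    "read_trial",
    "write_trial",
    "load_dataset",
    "write_manifest",
    "GaitDataError",
    "FormatError",
    "SamplingError",
    "EventError",
    "SchemaError",
    "ConfigurationError",
    "DataError",
]


class GaitDataError(Exception):
    """Base class for domain errors."""


class FormatError(GaitDataError):
    """A file does not conform to the expected trial format."""


class SamplingError(GaitDataError):
    """Time stamps are not uniform at the declared rate."""


class EventError(GaitDataError):
    """Heel-strike event missing or outside the usable range."""


class SchemaError(GaitDataError):
    """Signals present do not match the expected inventory."""


class ConfigurationError(GaitDataError):
    """Invalid or missing configuration value."""


class DataError(GaitDataError):
    """Dataset content insufficient for the requested computation."""


class TerrainClass(enum.Enum):
    """The three cross-slope terrain classes.

    The enum value is the mediolateral slope in degrees: a +15° surface
    forces ankle inversion, −15° forces eversion, 0° is flush.
    """

    EVERSION = -15
    FLUSH = 0
    INVERSION = 15

    @property
    def label(self) -> str:
        return self.name.lower()

    @property
    def slope_deg(self) -> int:
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "TerrainClass":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ConfigurationError(f"unknown terrain label {label!r}") from None

    @classmethod
    def from_slope(cls, slope_deg: float) -> "TerrainClass":
        for t in cls:
            if t.value == int(round(slope_deg)):
                return t
        raise ConfigurationError(f"no terrain class with slope {slope_deg}°")


#: Fixed class order used everywhere (confusion matrices, tie-breaking).
TERRAIN_ORDER: tuple[TerrainClass, ...] = (
    TerrainClass.EVERSION,
    TerrainClass.FLUSH,
    TerrainClass.INVERSION,
)


class SignalSource(enum.Enum):
    MOTION_CAPTURE = "motion_capture"
    IN_PYLON = "in_pylon"


class StatPolicy(enum.Enum):
    """Which per-window statistics a signal contributes.

    Kinematic/kinetic signals contribute mean, sd, max and min; ground
    reaction force and center-of-pressure signals contribute mean and sd
    only.
    """

    FOUR_STATS = "four_stats"
    TWO_STATS = "two_stats"

    @property
    def n_stats(self) -> int:
        return 4 if self is StatPolicy.FOUR_STATS else 2


@dataclass(frozen=True)
class SignalId:
    name: str
    source: SignalSource = SignalSource.MOTION_CAPTURE
    stat_policy: StatPolicy = StatPolicy.FOUR_STATS


def _mc(name: str) -> SignalId:
    return SignalId(name, SignalSource.MOTION_CAPTURE, StatPolicy.FOUR_STATS)


def _ips(name: str) -> SignalId:
    return SignalId(name, SignalSource.IN_PYLON, StatPolicy.FOUR_STATS)


def _plate(name: str) -> SignalId:
    return SignalId(name, SignalSource.MOTION_CAPTURE, StatPolicy.TWO_STATS)


# Ankle kinematics/kinetics in the two anatomical planes (10 signals).
_ANKLE = [
    _mc("ankle_flexion_angle"),
    _mc("ankle_inversion_angle"),
    _mc("ankle_flexion_angvel"),
    _mc("ankle_inversion_angvel"),
    _mc("ankle_flexion_angacc"),
    _mc("ankle_inversion_angacc"),
    _mc("ankle_flexion_moment"),
    _mc("ankle_inversion_moment"),
    _mc("ankle_flexion_power"),
    _mc("ankle_inversion_power"),
]

# Foot segment kinematics in lab-frame AP/ML/Vert (9 signals).
_FOOT = [
    _mc("foot_ap_velocity"),
    _mc("foot_ml_velocity"),
    _mc("foot_vert_velocity"),
    _mc("foot_ap_acc"),
    _mc("foot_ml_acc"),
    _mc("foot_vert_acc"),
    _mc("foot_ap_angvel"),
    _mc("foot_ml_angvel"),
    _mc("foot_vert_angvel"),
]

# Shank segment linear velocity (3 signals).
_SHANK_VEL = [
    _mc("shank_ap_velocity"),
    _mc("shank_ml_velocity"),
    _mc("shank_vert_velocity"),
]

# In-pylon sensor package, shank-fixed frame (6 signals).
_IPS = [
    _ips("ips_ap_acc"),
    _ips("ips_infsup_acc"),
    _ips("ips_ml_acc"),
    _ips("ips_cor_angvel"),
    _ips("ips_sag_angvel"),
    _ips("ips_tran_angvel"),
]

# Motion-capture substitutes for the in-pylon channels (6 signals).
_SHANK_MC_SUB = [
    _mc("shank_ap_acc"),
    _mc("shank_ml_acc"),
    _mc("shank_vert_acc"),
    _mc("shank_ap_angvel"),
    _mc("shank_ml_angvel"),
    _mc("shank_vert_angvel"),
]

# Force plate signals, mean+sd only (6 signals).
_PLATE = [
    _plate("grf_ap"),
    _plate("grf_ml"),
    _plate("grf_vert"),
    _plate("cop_ap"),
    _plate("cop_ml"),
    _plate("cop_vert"),
]


@dataclass(frozen=True)
class SignalInventory:
    """Ordered registry of the signals a classifier may draw on.

    Variants: ``full_with_ips`` (28 four-stat + 6 two-stat signals → 124
    feature values), ``full_mc_only`` (the six in-pylon channels replaced by
    their motion-capture analogues, still 124), and ``ips_only`` (the six
    in-pylon channels → 24 values).
    """

    signals: tuple[SignalId, ...]
    variant: str = "custom"

    def __post_init__(self) -> None:
        names = [s.name for s in self.signals]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate signal names in inventory")
        if self.variant == "ips_only" and len(self.signals) != 6:
            raise SchemaError("ips_only inventory must have exactly 6 signals")
        if self.variant in ("full_with_ips", "full_mc_only"):
            n4 = sum(s.stat_policy is StatPolicy.FOUR_STATS for s in self.signals)
            n2 = sum(s.stat_policy is StatPolicy.TWO_STATS for s in self.signals)
            if (n4, n2) != (28, 6):
                raise SchemaError(
                    f"full inventory must have 28 four-stat + 6 two-stat "
                    f"signals, got {n4}+{n2}"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.signals)

    @property
    def feature_count(self) -> int:
        return sum(s.stat_policy.n_stats for s in self.signals)

    def __len__(self) -> int:
        return len(self.signals)

    def __getitem__(self, name: str) -> SignalId:
        for s in self.signals:
            if s.name == name:
                return s
        raise KeyError(name)

    def subset(self, names) -> "SignalInventory":
        names = list(names)
        known = set(self.names)
        unknown = [n for n in names if n not in known]
        if unknown:
            raise SchemaError(f"unknown signals: {unknown}")
        keep = set(names)
        return SignalInventory(
            tuple(s for s in self.signals if s.name in keep), variant="custom"
        )

    @classmethod
    def full_with_ips(cls) -> "SignalInventory":
        return cls(
            tuple(_ANKLE + _FOOT + _SHANK_VEL + _IPS + _PLATE),
            variant="full_with_ips",
        )

    @classmethod
    def full_mc_only(cls) -> "SignalInventory":
        return cls(
            tuple(_ANKLE + _FOOT + _SHANK_VEL + _SHANK_MC_SUB + _PLATE),
            variant="full_mc_only",
        )

    @classmethod
    def ips_only(cls) -> "SignalInventory":
        return cls(tuple(_IPS), variant="ips_only")

    @classmethod
    def from_variant(cls, variant: str) -> "SignalInventory":
        try:
            return {
                "full_with_ips": cls.full_with_ips,
                "full_mc_only": cls.full_mc_only,
                "ips_only": cls.ips_only,
            }[variant]()
        except KeyError:
            raise ConfigurationError(f"unknown inventory variant {variant!r}") from None


# Margins (s) around heel strike required for a classifiable trial: the
# earliest mid-swing window starts 250 ms before heel strike and the latest
# ends 75 ms after it.
MIN_BEFORE_HS_S = 0.250
MIN_AFTER_HS_S = 0.075


@dataclass
class TrialRecording:
    """One stride's multichannel time series with its heel-strike anchor."""

    subject_id: str
    terrain: TerrainClass
    series: dict[str, np.ndarray]
    heel_strike_time: float
    sample_rate: float = 120.0
    prosthesis: str = "prescribed"
    trial_id: str = ""
    body_mass: float | None = None
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        self.series = {k: np.asarray(v, dtype=float) for k, v in self.series.items()}
        lengths = {len(v) for v in self.series.values()}
        if len(lengths) > 1:
            raise SchemaError(f"series lengths differ: {sorted(lengths)}")
        if not self.trial_id:
            self.trial_id = f"{self.subject_id}_{self.terrain.label}"

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.series.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def heel_strike_sample(self) -> int:
        """Heel-strike time snapped to the nearest sample index."""
        return int(round(self.heel_strike_time * self.sample_rate))

    @property
    def signal_names(self) -> tuple[str, ...]:
        return tuple(self.series.keys())

    def validate(self) -> None:
        if not self.series:
            raise SchemaError("trial has no signals")
        if not (0.0 <= self.heel_strike_time <= self.duration):
            raise EventError(
                f"heel strike at {self.heel_strike_time:.3f}s outside the "
                f"recorded interval [0, {self.duration:.3f}]s"
            )
        if self.heel_strike_time < MIN_BEFORE_HS_S:
            raise EventError(
                f"only {self.heel_strike_time * 1e3:.0f} ms recorded before heel "
                f"strike; need ≥{MIN_BEFORE_HS_S * 1e3:.0f} ms"
            )
        after = self.duration - self.heel_strike_time
        if after < MIN_AFTER_HS_S:
            raise EventError(
                f"only {after * 1e3:.0f} ms recorded after heel strike; "
                f"need ≥{MIN_AFTER_HS_S * 1e3:.0f} ms"
            )

    def with_series(self, series: dict[str, np.ndarray]) -> "TrialRecording":
        return replace(self, series=series)


@dataclass
class Dataset:
    """A collection of trials sharing one signal set."""

    trials: list[TrialRecording]
    role: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.trials:
            raise DataError("dataset has no trials")
        ref = set(self.trials[0].signal_names)
        for t in self.trials[1:]:
            if set(t.signal_names) != ref:
                raise SchemaError(
                    f"trial {t.trial_id!r} signal set differs from "
                    f"{self.trials[0].trial_id!r}"
                )

    def __len__(self) -> int:
        return len(self.trials)

    def class_counts(self) -> dict[TerrainClass, int]:
        counts = {t: 0 for t in TERRAIN_ORDER}
        for trial in self.trials:
            counts[trial.terrain] += 1
        return counts

    @property
    def signal_names(self) -> tuple[str, ...]:
        return self.trials[0].signal_names


# ---------------------------------------------------------------------------
# Trial file I/O

_META_KEYS = (
    "subject_id",
    "prosthesis",
    "terrain",
    "heel_strike_time",
    "sample_rate",
    "body_mass",
    "trial_id",
)


@dataclass(frozen=True)
class TrialDialect:
    """Explicit description of a foreign tab-separated trial file.

    ``column_map`` maps file column names to canonical signal names; columns
    not mentioned are dropped. ``time_column`` names the time column (s); if
    ``None``, ``sample_rate`` must be given and rows are assumed uniform.
    ``required_signals`` triggers a schema check after mapping. The native
    dialect (all ``None``) reads files produced by :func:`write_trial`.
    """

    column_map: dict[str, str] | None = None
    time_column: str | None = "time"
    sample_rate: float | None = None
    required_signals: tuple[str, ...] | None = None
    metadata_defaults: dict[str, str] = field(default_factory=dict)


NATIVE_DIALECT = TrialDialect()

_TIME_TOL_REL = 1e-6


def write_trial(trial: TrialRecording, path: str | os.PathLike) -> None:
    """Serialize a trial to tab-separated text (deterministic byte output)."""
    trial.validate()
    names = list(trial.signal_names)
    lines: list[str] = []
    lines.append(f"# subject_id: {trial.subject_id}")
    lines.append(f"# prosthesis: {trial.prosthesis}")
    lines.append(f"# terrain: {trial.terrain.label}")
    lines.append(f"# heel_strike_time: {trial.heel_strike_time!r}")
    lines.append(f"# sample_rate: {trial.sample_rate!r}")
    if trial.body_mass is not None:
        lines.append(f"# body_mass: {trial.body_mass!r}")
    lines.append(f"# trial_id: {trial.trial_id}")
    for name in sorted(trial.units):
        lines.append(f"# unit.{name}: {trial.units[name]}")
    lines.append("\t".join(["time"] + names))
    t = np.arange(trial.n_samples) / trial.sample_rate
    cols = [t] + [trial.series[n] for n in names]
    for row in zip(*cols):
        lines.append("\t".join(repr(float(v)) for v in row))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_trial(
    path: str | os.PathLike, dialect: TrialDialect = NATIVE_DIALECT
) -> TrialRecording:
    """Read a trial file. Fails loudly rather than guessing the layout."""
    meta: dict[str, str] = dict(dialect.metadata_defaults)
    header: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                continue
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric data row: {line!r}") from exc
    if header is None or not rows:
        raise FormatError(f"{path}: no data table found")
    widths = {len(r) for r in rows}
    if widths != {len(header)}:
        raise FormatError(
            f"{path}: ragged rows (header has {len(header)} columns, "
            f"rows have {sorted(widths)})"
        )
    data = np.asarray(rows, dtype=float)
    columns = dict(zip(header, data.T))

    if dialect.column_map is not None:
        missing_cols = [c for c in dialect.column_map if c not in columns]
        if missing_cols:
            raise FormatError(f"{path}: missing columns {missing_cols}")
        series = {sig: columns[col] for col, sig in dialect.column_map.items()}
    else:
        series = {
            name: col for name, col in columns.items() if name != dialect.time_column
        }

    # Sampling: explicit time column wins; otherwise the declared rate.
    if dialect.time_column is not None and dialect.time_column in columns:
        t = columns[dialect.time_column]
        dt = np.diff(t)
        if len(dt) and (dt.min() <= 0 or np.ptp(dt) > _TIME_TOL_REL * max(dt.mean(), 1e-12)):
            raise SamplingError(f"{path}: non-uniform time steps")
        sample_rate = 1.0 / dt.mean() if len(dt) else float(meta.get("sample_rate", 120.0))
    elif dialect.sample_rate is not None:
        sample_rate = dialect.sample_rate
    elif "sample_rate" in meta:
        sample_rate = float(meta["sample_rate"])
    else:
        raise SamplingError(f"{path}: no time column and no sample rate declared")
    if "sample_rate" in meta:
        sample_rate = float(meta["sample_rate"])

    if dialect.required_signals is not None:
        missing = [s for s in dialect.required_signals if s not in series]
        if missing:
            raise FormatError(f"{path}: missing required signals {missing}")

    if "heel_strike_time" not in meta:
        raise EventError(f"{path}: no heel_strike_time in metadata")
    if "terrain" not in meta:
        raise FormatError(f"{path}: no terrain label in metadata")

    units = {
        k[len("unit.") :]: v for k, v in meta.items() if k.startswith("unit.")
    }
    trial = TrialRecording(
        subject_id=meta.get("subject_id", "unknown"),
        prosthesis=meta.get("prosthesis", "prescribed"),
        terrain=TerrainClass.from_label(meta["terrain"]),
        series=series,
        heel_strike_time=float(meta["heel_strike_time"]),
        sample_rate=float(sample_rate),
        trial_id=meta.get("trial_id", ""),
        body_mass=float(meta["body_mass"]) if "body_mass" in meta else None,
        units=units,
    )
    trial.validate()
    return trial


# ---------------------------------------------------------------------------
# Manifests

def write_manifest(paths, role: str, manifest_path: str | os.PathLike) -> None:
    """Write a dataset manifest: a role header and one trial path per line."""
    base = os.path.dirname(os.path.abspath(manifest_path))
    lines = [f"# role: {role}"]
    for p in paths:
        lines.append(os.path.relpath(os.path.abspath(p), base))
    with open(manifest_path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def load_dataset(
    manifest: str | os.PathLike, dialect: TrialDialect = NATIVE_DIALECT
) -> Dataset:
    """Load every trial listed in a manifest into a consistent Dataset."""
    base = os.path.dirname(os.path.abspath(manifest))
    role = "synthetic"
    paths: list[str] = []
    with open(manifest) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("role:"):
                    role = body.partition(":")[2].strip()
                continue
            paths.append(os.path.join(base, line))
    if not paths:
        raise FormatError(f"{manifest}: manifest lists no trials")
    trials = [read_trial(p, dialect) for p in paths]
    return Dataset(trials=trials, role=role)
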