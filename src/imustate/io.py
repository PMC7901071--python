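"""File formats, configuration and shared data containers.

All pipeline artifacts are plain text: comma-separated tables for sensor
series, window features, decoded states and budgets; JSON for calibration
and fitted model parameters; YAML for the run configuration.

The sensor file schema carries one individual per file: a small ``# key=value``
metadata block (individual id, sampling rate, covariate level, hemisphere)
followed by a CSV header ``t_s,acc_x,acc_y,acc_z,mag_x,mag_y,mag_z``.
Acceleration is in g, magnetometer in microtesla; the axes follow the tag
frame [forward (surge), right (sway), up (heave)].  Missing samples are
encoded as empty fields and surface as the validity mask.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SENSOR_MAGIC = "# imustate-sensor-v1"
ACC_COLS = ["acc_x", "acc_y", "acc_z"]
MAG_COLS = ["mag_x", "mag_y", "mag_z"]

FEATURE_COLUMNS = [
    "individual_id", "window_index", "t_start",
    "df", "hf", "ms", "ss", "p5", "iqr", "mo", "sh",
    "covariate", "missing",
]

STATE_LABELS = ("flap", "soar", "water")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SensorTimeSeries:
    """Regular-grid tri-axial accelerometer (+ optional magnetometer) record.

    Attributes
    ----------
    t : (n,) seconds since deployment start, strictly increasing, spacing 1/fs_hz
    acc : (n, 3) surge/sway/heave acceleration in g
    mag : (n, 3) magnetometer in microtesla, or None
    fs_hz : sampling rate
    valid : (n,) boolean per-sample validity mask
    """

    t: np.ndarray
    acc: np.ndarray
    mag: np.ndarray | None
    fs_hz: float
    valid: np.ndarray = None  # type: ignore[assignment]
    individual_id: str = "ind0"
    covariate_level: str = "A"
    hemisphere: str = "north"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float)
            if len(self.mag) != len(self.acc):
                raise ValueError("acc and mag must have equal length")
        if self.valid is None:
            self.valid = np.ones(len(self.t), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.t) != len(self.acc):
            raise ValueError("t and acc must have equal length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.fs_hz, atol=1e-9, rtol=0):
                raise ValueError("time grid spacing must equal 1/fs_hz within 1e-9")

    @property
    def n(self) -> int:
        return len(self.t)

    def copy(self) -> "SensorTimeSeries":
        return SensorTimeSeries(
            t=self.t.copy(),
            acc=self.acc.copy(),
            mag=None if self.mag is None else self.mag.copy(),
            fs_hz=self.fs_hz,
            valid=self.valid.copy(),
            individual_id=self.individual_id,
            covariate_level=self.covariate_level,
            hemisphere=self.hemisphere,
        )


@dataclass
class CalibrationModel:
    """Hard-iron offset and soft-iron correction for a magnetometer.

    ``corrected = soft_iron_correction @ (raw - hard_iron)`` maps raw
    samples onto a sphere of radius ``reference_norm`` (the mean centered
    sample norm, so corrected values stay on the raw microtesla scale).
    """

    hard_iron: np.ndarray
    soft_iron_correction: np.ndarray
    reference_norm: float

    def apply(self, mag: np.ndarray) -> np.ndarray:
        centered = np.asarray(mag, dtype=float) - self.hard_iron
        return centered @ self.soft_iron_correction.T

    def to_json(self) -> str:
        return json.dumps(
            {
                "hard_iron": list(map(float, self.hard_iron)),
                "soft_iron_correction": [
                    list(map(float, row)) for row in self.soft_iron_correction
                ],
                "reference_norm": float(self.reference_norm),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        return cls(
            hard_iron=np.asarray(d["hard_iron"], dtype=float),
            soft_iron_correction=np.asarray(d["soft_iron_correction"], dtype=float),
            reference_norm=float(d["reference_norm"]),
        )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Stage parameters for the whole pipeline with their documented defaults."""

    # grid
    fs_hz: float = 25.0
    window_s: float = 30.0
    # preprocessing
    trim_start_s: float = 7200.0
    trim_end_s: float = 0.0
    median_window: int = 5
    smooth_s: float = 2.0
    water_odba_g: float = 0.08
    min_cal_samples: int = 100
    attitude_lowpass_hz: float = 0.5
    hemisphere: str = "north"
    # features
    peak_fraction: float = 0.05
    sh_floor: float = 1e-6
    sh_cap: float = 4.0
    feature_floor: float = 1e-6
    corr_threshold: float = 0.7
    feature_set: tuple = ("hf", "p5", "sh")
    # model
    n_states: int = 3
    n_restarts: int = 25
    covariate: bool = True
    delta_mode: str = "estimate"  # or "stationary"
    missing_split_run: int = 10
    stability_tol: float = 1e-3
    # evaluation
    n_per_bird: int = 50
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.median_window % 2 != 1:
            raise ValueError("median_window must be odd")
        if self.delta_mode not in ("estimate", "stationary"):
            raise ValueError("delta_mode must be 'estimate' or 'stationary'")
        n = self.window_s * self.fs_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window_s * fs_hz must be an integer sample count")
        self.feature_set = tuple(self.feature_set)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["feature_set"] = list(self.feature_set)
        return d

    @property
    def hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# sensor file I/O
# ---------------------------------------------------------------------------

def write_sensor_file(series: SensorTimeSeries, path: str | Path) -> None:
    path = Path(path)
    buf = _io.StringIO()
    buf.write(SENSOR_MAGIC + "\n")
    buf.write(f"# individual_id={series.individual_id}\n")
    buf.write(f"# fs_hz={series.fs_hz!r}\n")
    buf.write(f"# covariate_level={series.covariate_level}\n")
    buf.write(f"# hemisphere={series.hemisphere}\n")
    cols = {"t_s": series.t}
    for j, c in enumerate(ACC_COLS):
        cols[c] = series.acc[:, j]
    if series.mag is not None:
        for j, c in enumerate(MAG_COLS):
            cols[c] = series.mag[:, j]
    df = pd.DataFrame(cols)
    # invalid samples serialize as empty data fields (timestamp retained)
    bad = ~series.valid
    if bad.any():
        df.loc[bad, [c for c in df.columns if c != "t_s"]] = np.nan
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def read_sensor_file(path: str | Path) -> SensorTimeSeries:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != SENSOR_MAGIC:
            raise ValueError(f"{path}: line 1: not an imustate sensor file")
        pos = fh.tell()
        lineno = 1
        while True:
            line = fh.readline()
            lineno += 1
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
        df = pd.read_csv(fh)
    missing = [c for c in ["t_s", *ACC_COLS] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: line {lineno + 1}: missing columns {missing}")
    acc = df[ACC_COLS].to_numpy(dtype=float)
    mag = df[MAG_COLS].to_numpy(dtype=float) if set(MAG_COLS) <= set(df.columns) else None
    data = acc if mag is None else np.hstack([acc, mag])
    valid = np.all(np.isfinite(data), axis=1)
    return SensorTimeSeries(
        t=df["t_s"].to_numpy(dtype=float),
        acc=acc,
        mag=mag,
        fs_hz=float(meta.get("fs_hz", "nan")),
        valid=valid,
        individual_id=meta.get("individual_id", path.stem),
        covariate_level=meta.get("covariate_level", "A"),
        hemisphere=meta.get("hemisphere", "north"),
    )


# ---------------------------------------------------------------------------
# tabular artifacts
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    """Write a delimited artifact, optionally stamped with the config hash."""
    path = Path(path)
    buf = _io.StringIO()
    if config_hash is not None:
        buf.write(f"# config_hash={config_hash}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def read_table(path: str | Path, expect_hash: str | None = None) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        found = None
        if line.startswith("# config_hash="):
            found = line.strip().split("=", 1)[1]
        else:
            fh.seek(pos)
        if expect_hash is not None and found is not None and found != expect_hash:
            raise ValueError(
                f"{path}: config hash mismatch ({found} != {expect_hash}); "
                "artifacts from different configurations refuse to combine"
            )
        return pd.read_csv(fh)
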