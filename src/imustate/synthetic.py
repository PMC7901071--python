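"""Seeded, ground-truth-labeled synthetic IMU deployments.

The generator is a stylized emulator of the three albatross movement modes,
not an aerodynamic model.  Hidden states follow a Markov chain at the 30-s
window scale (the model's time resolution) and each window is rendered at
25 Hz under its state's signal regime:

* **flap** — a heave sinusoid at a wingbeat frequency drawn near 2.6 Hz,
  with a weaker in-phase surge component, broadband dynamic noise, and a
  slowly drifting heading;
* **soar** — slow periodic heading arcs (tens of seconds); pitch and roll
  are rendered proportional to the heading-arc derivative (banked turns)
  and the specific-force magnitude rises in the banks, so tilt correction
  and the static-heave features are exercised non-trivially;
* **water** — heave near 1 g plus a slow swell oscillation, near-constant
  heading, and only small dynamic noise.

The magnetometer sees the ambient field rotated into the instantaneous tag
frame, then distorted by a soft-iron matrix, a hard-iron offset and white
noise; a tag-mount roll offset rotates both sensors.  Identical configs and
seeds give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import STATE_LABELS, SensorTimeSeries, write_table, write_sensor_file
from .preprocess import rot_x

# Generative window-scale transition matrices, anchored to published
# 3-state estimates for this system (rows renormalized to machine precision).
_M1 = np.array([[0.778, 0.204, 0.019],
                [0.083, 0.900, 0.017],
                [0.010, 0.016, 0.974]])
_M2 = np.array([[0.781, 0.194, 0.025],
                [0.080, 0.911, 0.009],
                [0.011, 0.008, 0.980]])
MODEL1_TPM = _M1 / _M1.sum(axis=1, keepdims=True)
MODEL2_TPM = _M2 / _M2.sum(axis=1, keepdims=True)


@dataclass
class StateRegimeParams:
    """Signal regime for one behavioral state.

    Amplitudes in g, frequencies in Hz, angles in degrees.
    """

    state_label: str
    flap_freq_mean_hz: float = 0.0
    flap_freq_sd_hz: float = 0.0
    heave_osc_amplitude_g: float = 0.0
    surge_osc_fraction: float = 0.3
    heading_arc_period_s: float = 0.0
    heading_arc_period_sd_s: float = 0.0
    heading_arc_amplitude_deg: float = 0.0
    bank_amplitude_deg: float = 0.0
    pitch_amplitude_deg: float = 0.0
    dyn_noise_sd_g: float = 0.0
    mean_heave_g: float = 1.0
    swell_freq_hz: float = 0.0
    swell_freq_sd_hz: float = 0.0
    swell_amplitude_g: float = 0.0
    heading_jitter_sd_deg: float = 0.0
    heading_drift_sd_deg_s: float = 0.0
    # slow pitch/roll variability independent of the heading arc: gust
    # wobble in flight, wave rocking on the water.  Keeps the rendered
    # orientations from collapsing onto a degenerate band of the sphere.
    att_wander_sd_deg: float = 0.0
    att_wander_tau_s: float = 8.0
    rock_amplitude_deg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("heave_osc_amplitude_g", "swell_amplitude_g",
                     "dyn_noise_sd_g", "flap_freq_sd_hz",
                     "heading_jitter_sd_deg", "heading_drift_sd_deg_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def default_regimes() -> dict:
    """Regime defaults emulating the study's three signal classes."""
    return {
        "flap": StateRegimeParams(
            state_label="flap", flap_freq_mean_hz=2.6, flap_freq_sd_hz=0.1,
            heave_osc_amplitude_g=0.9, surge_osc_fraction=0.3,
            dyn_noise_sd_g=0.05, heading_jitter_sd_deg=3.0,
            heading_drift_sd_deg_s=1.5),
        "soar": StateRegimeParams(
            state_label="soar", heading_arc_period_s=10.0,
            heading_arc_period_sd_s=1.0, heading_arc_amplitude_deg=80.0,
            bank_amplitude_deg=40.0, pitch_amplitude_deg=10.0,
            dyn_noise_sd_g=0.03, heading_jitter_sd_deg=2.0),
        "water": StateRegimeParams(
            state_label="water", mean_heave_g=1.0, swell_freq_hz=0.125,
            swell_freq_sd_hz=0.015, swell_amplitude_g=0.05,
            dyn_noise_sd_g=0.02, heading_jitter_sd_deg=2.0),
    }


def _default_tpms() -> dict:
    return {"A": MODEL1_TPM.copy(), "B": MODEL2_TPM.copy()}


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic multi-individual deployment."""

    n_individuals: int = 20
    windows_per_individual: int = 500
    window_s: float = 30.0
    fs_hz: float = 25.0
    covariate_levels: tuple = ("A", "B")
    true_tpm: dict = field(default_factory=_default_tpms)
    initial_dist: np.ndarray = None  # type: ignore[assignment]
    regimes: dict = field(default_factory=default_regimes)
    mag_field: np.ndarray = None  # type: ignore[assignment]
    hard_iron: np.ndarray = None  # type: ignore[assignment]
    soft_iron: np.ndarray = None  # type: ignore[assignment]
    mag_noise_sd: float = 0.3
    roll_offset_deg: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_dist is None:
            from .hmm import stationary_distribution
            self.initial_dist = stationary_distribution(
                np.asarray(self.true_tpm[self.covariate_levels[0]]))
        self.initial_dist = np.asarray(self.initial_dist, dtype=float)
        if abs(self.initial_dist.sum() - 1.0) > 1e-9:
            raise ValueError("initial_dist must sum to 1")
        if self.mag_field is None:
            # magnitude 45 uT, inclination 60 deg down (north/east/up frame)
            self.mag_field = 45.0 * np.array(
                [np.cos(np.deg2rad(60.0)), 0.0, -np.sin(np.deg2rad(60.0))])
        self.mag_field = np.asarray(self.mag_field, dtype=float)
        if self.hard_iron is None:
            self.hard_iron = np.array([12.0, -8.0, 5.0])
        self.hard_iron = np.asarray(self.hard_iron, dtype=float)
        if self.soft_iron is None:
            self.soft_iron = np.array([[1.10, 0.03, 0.00],
                                       [0.03, 0.96, 0.02],
                                       [0.00, 0.02, 0.88]])
        self.soft_iron = np.asarray(self.soft_iron, dtype=float)
        n = self.window_s * self.fs_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window_s * fs_hz must be an integer sample count")
        for level, tpm in self.true_tpm.items():
            _check_stochastic(np.asarray(tpm), where=f"true_tpm[{level!r}]")

    def level_of(self, individual: int) -> str:
        return self.covariate_levels[individual % len(self.covariate_levels)]


def _check_stochastic(tpm: np.ndarray, tol: float = 1e-9, where: str = "tpm") -> None:
    tpm = np.asarray(tpm, dtype=float)
    if tpm.ndim != 2 or tpm.shape[0] != tpm.shape[1]:
        raise ValueError(f"{where} must be a square matrix")
    if np.any(tpm < 0):
        raise ValueError(f"{where} has negative entries")
    sums = tpm.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > tol)
    if len(bad):
        raise ValueError(
            f"{where} row {bad[0]} sums to {sums[bad[0]]!r}, not 1")


# ---------------------------------------------------------------------------
# hidden-state chain
# ---------------------------------------------------------------------------

def simulate_state_sequence(tpm: np.ndarray, initial_dist: np.ndarray,
                            n_windows: int, seed=None,
                            labels: tuple = STATE_LABELS) -> np.ndarray:
    """Sample a Markov chain of state labels of length ``n_windows``."""
    tpm = np.asarray(tpm, dtype=float)
    _check_stochastic(tpm)
    initial_dist = np.asarray(initial_dist, dtype=float)
    if abs(initial_dist.sum() - 1.0) > 1e-9:
        raise ValueError("initial_dist must sum to 1")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = tpm.shape[0]
    cum0 = np.cumsum(initial_dist)
    cum = np.cumsum(tpm, axis=1)
    u = rng.random(n_windows)
    states = np.empty(n_windows, dtype=int)
    states[0] = np.searchsorted(cum0, u[0], side="right")
    for t in range(1, n_windows):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t], side="right")
    states = np.minimum(states, S - 1)
    return np.asarray(labels)[states]


# ---------------------------------------------------------------------------
# per-window signal rendering
# ---------------------------------------------------------------------------

def _ou_series(n: int, sd_deg: float, tau_s: float, fs_hz: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck attitude wander, in radians."""
    if sd_deg <= 0:
        return np.zeros(n)
    sd = np.deg2rad(sd_deg)
    a = np.exp(-1.0 / (tau_s * fs_hz))
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - a * a), size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = a * x[i - 1] + eps[i]
    return x


def _gravity_in_tag(pitch: np.ndarray, roll: np.ndarray) -> np.ndarray:
    """Unit specific-force direction in the tag frame for given attitude."""
    sp, cp = np.sin(pitch), np.cos(pitch)
    sr, cr = np.sin(roll), np.cos(roll)
    return np.stack([sp, sr * cp, cr * cp], axis=1)

def render_window(state: str, regime: StateRegimeParams, window_s: float,
                  fs_hz: float, seed=None, heading0: float | None = None) -> dict:
    """Render one window of tri-axial acceleration plus true attitude.

    Returns a dict with ``acc`` (total, g), its exact ``static``/``dynamic``
    decomposition (``static + dynamic == acc`` samplewise), and the true
    ``heading`` (deg), ``pitch``/``roll`` (rad) series.
    """
    if regime.state_label != state:
        raise ValueError(f"regime is for {regime.state_label!r}, not {state!r}")
    n = window_s * fs_hz
    if abs(n - round(n)) > 1e-9:
        raise ValueError("window_s * fs_hz must be integral")
    n = int(round(n))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(n) / fs_hz
    if heading0 is None:
        heading0 = rng.uniform(0.0, 360.0)
    pitch = np.zeros(n)
    roll = np.zeros(n)
    static = np.zeros((n, 3))
    dynamic = rng.normal(0.0, regime.dyn_noise_sd_g, size=(n, 3))

    if state == "flap":
        f = float(np.clip(rng.normal(regime.flap_freq_mean_hz,
                                     regime.flap_freq_sd_hz),
                          0.2, 0.45 * fs_hz))
        if regime.flap_freq_mean_hz >= 0.5 * fs_hz:
            raise ValueError("flap frequency must lie below the Nyquist rate")
        phase = rng.uniform(0.0, 2.0 * np.pi)
        osc = np.sin(2.0 * np.pi * f * t + phase)
        dynamic[:, 2] += regime.heave_osc_amplitude_g * osc
        dynamic[:, 0] += (regime.surge_osc_fraction
                          * regime.heave_osc_amplitude_g
                          * np.sin(2.0 * np.pi * f * t + phase + 1.0))
        pitch = _ou_series(n, regime.att_wander_sd_deg, regime.att_wander_tau_s,
                           fs_hz, rng)
        roll = _ou_series(n, regime.att_wander_sd_deg, regime.att_wander_tau_s,
                          fs_hz, rng)
        static = regime.mean_heave_g * _gravity_in_tag(pitch, roll)
        drift = rng.normal(0.0, regime.heading_drift_sd_deg_s)
        heading = heading0 + drift * t
    elif state == "soar":
        period = max(4.0, rng.normal(regime.heading_arc_period_s,
                                     regime.heading_arc_period_sd_s))
        phase = rng.uniform(0.0, 2.0 * np.pi)
        theta = 2.0 * np.pi * t / period + phase
        heading = heading0 + regime.heading_arc_amplitude_deg * np.sin(theta)
        # banked turns: roll (and a smaller pitch) follow the heading-arc
        # derivative; the load factor grows in the banks, which is what
        # lifts the static-heave features above the on-water level
        roll = np.deg2rad(regime.bank_amplitude_deg) * np.cos(theta)
        pitch = np.deg2rad(regime.pitch_amplitude_deg) * np.cos(theta)
        load = 1.0 / np.cos(roll) ** 2
        static = load[:, None] * _gravity_in_tag(pitch, roll)
    elif state == "water":
        fsw = regime.swell_freq_hz
        if regime.swell_freq_sd_hz > 0:
            fsw = max(0.02, rng.normal(fsw, regime.swell_freq_sd_hz))
        phase = rng.uniform(0.0, 2.0 * np.pi)
        heave = np.full(n, regime.mean_heave_g)
        if regime.swell_amplitude_g > 0:
            heave = heave + regime.swell_amplitude_g * np.sin(
                2.0 * np.pi * fsw * t + phase)
        if regime.rock_amplitude_deg > 0:  # wave rocking
            amp = np.deg2rad(regime.rock_amplitude_deg)
            ph_p, ph_r = rng.uniform(0.0, 2.0 * np.pi, size=2)
            pitch = 0.5 * amp * np.sin(2.0 * np.pi * fsw * t + ph_p)
            roll = amp * np.sin(2.0 * np.pi * fsw * t + ph_r)
        static = heave[:, None] * _gravity_in_tag(pitch, roll)
        heading = np.full(n, heading0)
    else:
        raise ValueError(f"unknown state {state!r}")

    if regime.heading_jitter_sd_deg > 0:
        # smooth yaw wander (~1 s correlation): a flying or floating bird
        # has rotational inertia, so heading jitter is not white at 25 Hz
        heading = heading + np.rad2deg(
            _ou_series(n, regime.heading_jitter_sd_deg, 1.0, fs_hz, rng))
    heading = np.asarray(heading, dtype=float) % 360.0
    return {
        "acc": static + dynamic,
        "static": static,
        "dynamic": dynamic,
        "heading": heading,
        "pitch": pitch,
        "roll": roll,
    }


# ---------------------------------------------------------------------------
# magnetometer rendering
# ---------------------------------------------------------------------------

def render_magnetometer(heading_deg: np.ndarray, pitch: np.ndarray,
                        roll: np.ndarray, mag_field: np.ndarray,
                        hard_iron: np.ndarray, soft_iron: np.ndarray,
                        noise_sd: float = 0.0, seed=None):
    """Ambient field in the instantaneous tag frame, then distorted.

    Returns ``(distorted, undistorted)``; ``distorted = soft_iron @ m +
    hard_iron + noise`` per sample.
    """
    heading_deg = np.asarray(heading_deg, dtype=float)
    pitch = np.asarray(pitch, dtype=float)
    roll = np.asarray(roll, dtype=float)
    if not (len(heading_deg) == len(pitch) == len(roll)):
        raise ValueError("heading and attitude series must have equal length")
    soft_iron = np.asarray(soft_iron, dtype=float)
    if abs(np.linalg.det(soft_iron)) < 1e-12:
        raise ValueError("soft_iron matrix is singular")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B = np.asarray(mag_field, dtype=float)
    psi = np.deg2rad(heading_deg)
    # m = Rx(-roll) Ry(pitch) Rz(-psi) B   (tag <- nav)
    c, s = np.cos(psi), np.sin(psi)
    v1 = np.stack([B[0] * c + B[1] * s, -B[0] * s + B[1] * c,
                   np.full_like(c, B[2])], axis=1)
    cp, sp = np.cos(pitch), np.sin(pitch)
    v2 = np.stack([cp * v1[:, 0] + sp * v1[:, 2], v1[:, 1],
                   -sp * v1[:, 0] + cp * v1[:, 2]], axis=1)
    cr, sr = np.cos(roll), np.sin(roll)
    m = np.stack([v2[:, 0], cr * v2[:, 1] + sr * v2[:, 2],
                  -sr * v2[:, 1] + cr * v2[:, 2]], axis=1)
    distorted = m @ soft_iron.T + np.asarray(hard_iron, dtype=float)
    if noise_sd > 0:
        distorted = distorted + rng.normal(0.0, noise_sd, size=m.shape)
    return distorted, m


# ---------------------------------------------------------------------------
# full deployments
# ---------------------------------------------------------------------------

def simulate_individual(config: GeneratorConfig, individual: int,
                        seed_seq: np.random.SeedSequence | None = None):
    """One individual's raw sensor record plus window-level truth.

    Returns ``(SensorTimeSeries, states, truth)`` where ``truth`` also
    carries the rendered per-sample heading/pitch/roll for oracle tests.
    """
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed).spawn(config.n_individuals)[individual]
    rng = np.random.default_rng(seed_seq)
    level = config.level_of(individual)
    states = simulate_state_sequence(np.asarray(config.true_tpm[level]),
                                     config.initial_dist,
                                     config.windows_per_individual, seed=rng)
    n_win = int(round(config.window_s * config.fs_hz))
    n = n_win * config.windows_per_individual
    acc = np.empty((n, 3))
    heading = np.empty(n)
    pitch = np.empty(n)
    roll = np.empty(n)
    heading0 = rng.uniform(0.0, 360.0)
    for w, state in enumerate(states):
        out = render_window(state, config.regimes[state], config.window_s,
                            config.fs_hz, seed=rng, heading0=heading0)
        sl = slice(w * n_win, (w + 1) * n_win)
        acc[sl] = out["acc"]
        heading[sl] = out["heading"]
        pitch[sl] = out["pitch"]
        roll[sl] = out["roll"]
        heading0 = float(out["heading"][-1])
    # true field in the bird frame, then the tag-mount roll offset rotates
    # both sensors (tag <- bird); soft/hard iron act in the tag frame
    _, mag_true_bird = render_magnetometer(
        heading, pitch, roll, config.mag_field, np.zeros(3), np.eye(3))
    Rm = rot_x(-np.deg2rad(config.roll_offset_deg))
    acc = acc @ Rm.T
    mag = (mag_true_bird @ Rm.T) @ config.soft_iron.T + config.hard_iron
    if config.mag_noise_sd > 0:
        mag = mag + rng.normal(0.0, config.mag_noise_sd, size=mag.shape)
    series = SensorTimeSeries(
        t=np.arange(n) / config.fs_hz, acc=acc, mag=mag, fs_hz=config.fs_hz,
        individual_id=f"ind{individual:02d}", covariate_level=level,
        hemisphere="north")
    truth = pd.DataFrame({
        "individual_id": series.individual_id,
        "window_index": np.arange(config.windows_per_individual),
        "true_state": states,
    })
    attitude_truth = {"heading": heading, "pitch": pitch, "roll": roll}
    return series, states, truth, attitude_truth


def simulate_deployment(config: GeneratorConfig, out_dir: str | Path | None = None):
    """Simulate every individual; optionally write sensor + truth files.

    Returns ``(list of SensorTimeSeries, truth table)``.  Output is
    byte-identical for identical configs and seeds.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_individuals)
    all_series = []
    truths = []
    for i in range(config.n_individuals):
        series, _, truth, _ = simulate_individual(config, i, seed_seq=seeds[i])
        all_series.append(series)
        truths.append(truth)
    truth = pd.concat(truths, ignore_index=True)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for series in all_series:
            write_sensor_file(series, out_dir / f"{series.individual_id}.csv")
        write_table(truth, out_dir / "truth.csv")
    return all_series, truth


# ---------------------------------------------------------------------------
# window-level feature sets (direct Weibull sampling)
# ---------------------------------------------------------------------------

def default_emission_params():
    """(shapes, scales) for (hf, p5, sh) per state, matching the default
    regimes' feature clouds; used for window-level simulation."""
    # rows: flap, soar, water; cols: hf, p5, sh
    shapes = np.array([[28.0, 30.0, 1.6],
                       [8.0, 14.0, 7.0],
                       [9.0, 60.0, 2.2]])
    scales = np.array([[2.65, 1.06, 0.30],
                       [0.21, 1.25, 1.10],
                       [0.14, 1.05, 0.040]])
    return shapes, scales


def simulate_feature_windows(shapes, scales, tpms: dict, initial_dist,
                             n_individuals: int, windows_per_individual: int,
                             seed: int = 0,
                             feature_names=("hf", "p5", "sh"),
                             covariate_levels=("A",)) -> tuple:
    """Window-level feature table drawn directly from Weibull emissions.

    Bypasses signal rendering: states follow the window-scale Markov chain
    and features are sampled from the state's Weibull distributions.
    Returns ``(feature table, truth table)``.
    """
    shapes = np.asarray(shapes, dtype=float)
    scales = np.asarray(scales, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    for i in range(n_individuals):
        level = covariate_levels[i % len(covariate_levels)]
        states = simulate_state_sequence(np.asarray(tpms[level]), initial_dist,
                                         windows_per_individual, seed=rng)
        idx = np.array([STATE_LABELS.index(s) for s in states])
        x = scales[idx] * rng.weibull(shapes[idx])
        for w in range(windows_per_individual):
            row = {"individual_id": f"ind{i:02d}", "window_index": w,
                   "t_start": w * 30.0, "covariate": level, "missing": False}
            row.update({f: x[w, j] for j, f in enumerate(feature_names)})
            rows.append(row)
            truth_rows.append({"individual_id": f"ind{i:02d}",
                               "window_index": w, "true_state": states[w]})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
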