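"""Raw sensor streams -> calibrated, frame-corrected, analysis-ready series.

Frame conventions (fixed for the whole package)
-----------------------------------------------
Tag/bird frame: x forward (surge), y right (sway), z up (heave).
Navigation frame: North, East, Up.  Attitude angles:

* heading ``psi``: degrees clockwise from magnetic north, in [0, 360)
* pitch ``p = atan2(a_x, hypot(a_y, a_z))``: nose-up positive, radians
* roll ``phi = atan2(a_y, a_z)``: right-side-down positive, radians

with ``a`` the static (gravity) specific force in g, heave near +1 at rest.
The tag-to-navigation rotation is ``R = Rz(psi) @ Ry(-p) @ Rx(phi)`` with the
usual right-handed elemental matrices, so a navigation-frame vector ``v``
is seen by the sensors as ``R.T @ v``.  Tilt correction de-rotates the
magnetometer by ``Ry(-p) @ Rx(phi)`` and heading is the four-quadrant
arctangent of the levelled horizontal components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, ndimage, signal

from .io import CalibrationModel, RunConfig, SensorTimeSeries


# ---------------------------------------------------------------------------
# elemental rotations
# ---------------------------------------------------------------------------

def rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def tag_to_nav(heading_deg: float, pitch: float, roll: float) -> np.ndarray:
    """Rotation matrix taking tag-frame vectors to the North/East/Up frame."""
    return rot_z(np.deg2rad(heading_deg)) @ rot_y(-pitch) @ rot_x(roll)


@dataclass
class AttitudeSeries:
    """Per-sample pitch/roll (radians) and heading (degrees in [0, 360))."""

    pitch: np.ndarray
    roll: np.ndarray
    heading: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)


# ---------------------------------------------------------------------------
# decimation
# ---------------------------------------------------------------------------

def decimate(series: SensorTimeSeries, target_fs: float) -> SensorTimeSeries:
    """Reduce the sampling rate by an integer factor.

    A zero-phase (forward-backward) 8th-order Butterworth low-pass with
    cutoff at 0.8x the target Nyquist precedes integer downsampling, so
    passband content survives and super-Nyquist content is strongly
    attenuated without shifting wingbeat onsets across window boundaries.
    """
    ratio = series.fs_hz / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"source rate {series.fs_hz} is not an integer multiple of {target_fs}"
        )
    q = int(round(ratio))
    if q == 1:
        return series.copy()
    cutoff = 0.8 * (target_fs / 2.0)
    sos = signal.butter(8, cutoff, btype="low", fs=series.fs_hz, output="sos")

    def _filt(x: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [signal.sosfiltfilt(sos, x[:, j])[::q] for j in range(x.shape[1])]
        )

    return SensorTimeSeries(
        t=series.t[::q],
        acc=_filt(series.acc),
        mag=None if series.mag is None else _filt(series.mag),
        fs_hz=target_fs,
        valid=series.valid[::q],
        individual_id=series.individual_id,
        covariate_level=series.covariate_level,
        hemisphere=series.hemisphere,
    )


# ---------------------------------------------------------------------------
# tag-mount roll offset
# ---------------------------------------------------------------------------

def detect_water_mask(series: SensorTimeSeries, odba_threshold_g: float = 0.08,
                      smooth_s: float = 2.0, win_s: float = 10.0) -> np.ndarray:
    """Heuristic resting-on-water mask: rolling mean ODBA below a threshold.

    Used only to pick calm samples for the roll-offset estimate; it does not
    feed the behavioral classification.
    """
    from .features import odba, static_dynamic_split

    _, dyn = static_dynamic_split(series.acc, series.fs_hz, smooth_s)
    o = odba(dyn)
    n = max(1, int(round(win_s * series.fs_hz)))
    rolled = ndimage.uniform_filter1d(o, size=n, mode="nearest")
    return (rolled < odba_threshold_g) & series.valid


def estimate_roll_offset(series: SensorTimeSeries, water_mask: np.ndarray) -> float:
    """Roll offset (degrees) of the tag mount, from resting-on-water samples.

    While a bird rests on the water the average specific force is ~1 g of
    heave with sway and surge near zero; any persistent mean sway therefore
    reflects a roll tilt of the tag relative to the bird.
    """
    water_mask = np.asarray(water_mask, dtype=bool)
    if water_mask.sum() < 2 * series.fs_hz:
        raise ValueError("water mask must select at least 2 s of samples")
    sway = series.acc[water_mask, 1].mean()
    heave = series.acc[water_mask, 2].mean()
    return float(np.rad2deg(np.arctan2(sway, heave)))


def correct_frame(series: SensorTimeSeries, roll_offset_deg: float) -> SensorTimeSeries:
    """Rotate acc and mag by the roll offset so the tag frame matches the bird."""
    if not np.isfinite(roll_offset_deg):
        raise ValueError("roll offset must be finite")
    R = rot_x(np.deg2rad(roll_offset_deg))
    out = series.copy()
    out.acc = series.acc @ R.T
    if series.mag is not None:
        out.mag = series.mag @ R.T
    return out


# ---------------------------------------------------------------------------
# magnetometer cleaning and calibration
# ---------------------------------------------------------------------------

def clean_magnetometer(series: SensorTimeSeries, trim_start_s: float = 7200.0,
                       trim_end_s: float = 0.0, median_window: int = 5) -> SensorTimeSeries:
    """Trim deployment edges and median-filter the magnetometer channels.

    Trimming marks samples invalid rather than deleting them, so every
    channel stays on the common grid.  The running median suppresses
    isolated interference spikes; acceleration is untouched.
    """
    if median_window % 2 != 1:
        raise ValueError("median_window must be odd")
    duration = series.t[-1] - series.t[0]
    if trim_start_s + trim_end_s >= duration:
        raise ValueError("trim exceeds record duration")
    out = series.copy()
    keep = (series.t >= series.t[0] + trim_start_s) & (series.t <= series.t[-1] - trim_end_s)
    out.valid = series.valid & keep
    if series.mag is not None and median_window > 1:
        out.mag = np.column_stack(
            [ndimage.median_filter(series.mag[:, j], size=median_window, mode="nearest")
             for j in range(3)]
        )
    return out


def fit_calibration(mag_samples: np.ndarray, min_samples: int = 100,
                    coverage_tol: float = 1e-4,
                    max_points: int = 20000) -> CalibrationModel:
    """Least-squares ellipsoid calibration of raw magnetometer samples.

    A linear sphere fit initializes the center; a Cholesky-parameterized
    least-squares refinement then fits a general ellipsoid (center + shape),
    which stays an ellipsoid by construction.  A weak quadratic prior pulls
    the solution toward the initial sphere: a real deployment samples only
    the band of orientations the animal actually visits, where the
    unpenalized problem has a near-flat direction (a huge osculating
    ellipsoid fits a shallow band arbitrarily well).  The prior is far too
    weak to bias well-covered directions but pins the flat one.  The
    hard-iron offset is the fitted center; the soft-iron correction is the
    symmetric square root of the shape matrix, scaled so corrected norms
    sit at ``reference_norm`` (the mean centered sample norm).

    Notes
    -----
    An ellipsoid fit determines the soft-iron distortion only up to an
    orthogonal factor; the returned correction is the symmetric
    representative, which is exact for symmetric distortion matrices.
    """
    from scipy.optimize import least_squares

    X = np.asarray(mag_samples, dtype=float)
    X = X[np.all(np.isfinite(X), axis=1)]
    if len(X) < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {len(X)}")
    C = np.cov((X - X.mean(axis=0)).T)
    w = np.linalg.eigvalsh(C)
    if w[0] / w[-1] < coverage_tol:
        raise ValueError(
            "degenerate orientation coverage: samples are near-coplanar "
            f"(covariance eigenvalue ratio {w[0] / w[-1]:.2e})"
        )
    if len(X) > max_points:
        X = X[:: int(np.ceil(len(X) / max_points))]
    # sphere fit (linear in center):  ||x||^2 = 2 c.x + (r^2 - ||c||^2)
    D = np.column_stack([2 * X, np.ones(len(X))])
    sol, *_ = np.linalg.lstsq(D, (X ** 2).sum(axis=1), rcond=None)
    c0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + c0 @ c0, 1e-12)))

    def unpack(p):
        c = p[:3]
        L = np.zeros((3, 3))
        L[0, 0], L[1, 1], L[2, 2] = np.exp(p[3:6])  # positive diagonal
        L[1, 0], L[2, 0], L[2, 1] = p[6:9]
        return c, L

    # weak sphere prior: each pseudo-residual acts like 0.01*sqrt(n) data
    # points at prior scales of 0.5 r0 (center), 0.3 (log axis), 0.1 (skew)
    w = 0.01 * np.sqrt(len(X))

    def resid(p):
        c, L = unpack(p)
        v = (X - c) @ L.T
        r = np.linalg.norm(v, axis=1) - 1.0
        prior = np.concatenate([
            w * (c - c0) / (0.5 * r0),
            w * (p[3:6] + np.log(r0)) / 0.3,
            w * (p[6:9] * r0) / 0.1,
        ])
        return np.concatenate([r, prior])

    p0 = np.concatenate([c0, np.full(3, -np.log(r0)), np.zeros(3)])
    fit = least_squares(resid, p0, method="lm", xtol=1e-12, ftol=1e-12)
    center, L = unpack(fit.x)
    E = L.T @ L  # shape matrix: (x-c)^T E (x-c) = 1
    lam, V = np.linalg.eigh(E)
    W = V @ np.diag(np.sqrt(lam)) @ V.T  # symmetric sqrt
    centered = X - center
    reference_norm = float(np.linalg.norm(centered, axis=1).mean())
    return CalibrationModel(hard_iron=center,
                            soft_iron_correction=reference_norm * W,
                            reference_norm=reference_norm)


def attitude_static(acc: np.ndarray, fs: float, cutoff_hz: float = 0.5) -> np.ndarray:
    """Gravity estimate for tilt correction: zero-phase low-pass of the
    acceleration.

    A 4th-order Butterworth at 0.5 Hz is maximally flat across banked-turn
    timescales (~0.1 Hz) while suppressing the wingbeat band (>= 2 Hz), so
    pitch/roll track dynamic-soaring banks without flapping leakage.  The
    feature pipeline's 2-s running-mean split is a separate definition and
    is not affected.
    """
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    return np.column_stack([signal.sosfiltfilt(sos, acc[:, j])
                            for j in range(acc.shape[1])])


def refine_calibration(mag_samples: np.ndarray, pitch: np.ndarray,
                       roll: np.ndarray, init: CalibrationModel,
                       max_points: int = 5000) -> CalibrationModel:
    """Attitude-aided refinement of a magnetometer calibration.

    A deployment that only visits a band of orientations leaves the
    ellipsoid fit with a nearly flat direction (typically the vertical
    center/axis trade-off).  The accelerometer attitude supplies the
    missing constraints: after tilt de-rotation the corrected field must
    have a constant vertical component and a constant horizontal magnitude,
    whatever the heading.  This refit minimizes the departure from those
    two invariants together with the unit-norm residual, starting from the
    ellipsoid solution.
    """
    from scipy.optimize import least_squares

    X = np.asarray(mag_samples, dtype=float)
    ok = np.all(np.isfinite(X), axis=1)
    X, pitch, roll = X[ok], np.asarray(pitch)[ok], np.asarray(roll)[ok]
    if len(X) > max_points:
        step = int(np.ceil(len(X) / max_points))
        X, pitch, roll = X[::step], pitch[::step], roll[::step]
    cp, sp = np.cos(pitch), np.sin(pitch)
    cr, sr = np.cos(roll), np.sin(roll)

    # symmetric correction (the package's gauge convention: no rotational
    # freedom, so the refinement cannot introduce a constant heading bias)
    W0 = init.soft_iron_correction / init.reference_norm

    def unpack(p):
        c = p[:3]
        W = np.array([[p[3], p[6], p[7]],
                      [p[6], p[4], p[8]],
                      [p[7], p[8], p[5]]])
        return c, W

    p0 = np.concatenate([init.hard_iron,
                         np.diag(W0), [W0[0, 1], W0[0, 2], W0[1, 2]]])

    def resid(p):
        c, W = unpack(p)
        v = (X - c) @ W  # symmetric, so W.T == W
        # m_level = Ry(-p) Rx(phi) v
        y1 = cr * v[:, 1] - sr * v[:, 2]
        z1 = sr * v[:, 1] + cr * v[:, 2]
        hx = cp * v[:, 0] - sp * z1
        vz = sp * v[:, 0] + cp * z1
        h = np.hypot(hx, y1)
        r_norm = np.linalg.norm(v, axis=1) - 1.0
        return np.concatenate([r_norm, vz - vz.mean(), h - h.mean()])

    fit = least_squares(resid, p0, method="lm", xtol=1e-12, ftol=1e-12)
    c, W = unpack(fit.x)
    reference_norm = float(np.linalg.norm(X - c, axis=1).mean())
    return CalibrationModel(hard_iron=c,
                            soft_iron_correction=reference_norm * W,
                            reference_norm=reference_norm)


# ---------------------------------------------------------------------------
# attitude and heading
# ---------------------------------------------------------------------------

def attitude_and_heading(static_acc: np.ndarray, calibrated_mag: np.ndarray,
                         valid: np.ndarray | None = None) -> AttitudeSeries:
    """Pitch/roll from static acceleration; tilt-compensated heading from mag.

    Samples whose static vector has zero norm are flagged invalid rather
    than given a fabricated attitude.
    """
    a = np.asarray(static_acc, dtype=float)
    m = np.asarray(calibrated_mag, dtype=float)
    if len(a) != len(m):
        raise ValueError("static acc and calibrated mag must have equal length")
    norm = np.linalg.norm(a, axis=1)
    ok = norm > 1e-12
    if valid is not None:
        ok = ok & np.asarray(valid, dtype=bool)
    pitch = np.zeros(len(a))
    roll = np.zeros(len(a))
    pitch[ok] = np.arctan2(a[ok, 0], np.hypot(a[ok, 1], a[ok, 2]))
    roll[ok] = np.arctan2(a[ok, 1], a[ok, 2])
    # de-rotate mag by roll then pitch:  m_level = Ry(-p) Rx(phi) m
    cp, sp = np.cos(pitch), np.sin(pitch)
    cr, sr = np.cos(roll), np.sin(roll)
    my1 = cr * m[:, 1] - sr * m[:, 2]
    mz1 = sr * m[:, 1] + cr * m[:, 2]
    mx_level = cp * m[:, 0] - sp * mz1
    my_level = my1
    heading = np.degrees(np.arctan2(-my_level, mx_level)) % 360.0
    heading[~ok] = np.nan
    return AttitudeSeries(pitch=pitch, roll=roll, heading=heading, valid=ok)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def preprocess_deployment(series: SensorTimeSeries, config: RunConfig | None = None):
    """Full preprocessing chain for one individual.

    decimate (if needed) -> roll-offset correction -> magnetometer trim +
    median filter -> ellipsoid calibration -> tilt-corrected heading.

    Returns ``(series, attitude, calibration, roll_offset_deg)`` where the
    returned series is frame-corrected and cleaned.
    """
    from .features import static_dynamic_split

    cfg = config or RunConfig()
    if series.fs_hz != cfg.fs_hz:
        series = decimate(series, cfg.fs_hz)
    water = detect_water_mask(series, cfg.water_odba_g, cfg.smooth_s)
    if water.sum() >= 2 * series.fs_hz:
        roll_offset = estimate_roll_offset(series, water)
    else:
        roll_offset = 0.0
    series = correct_frame(series, roll_offset)
    series = clean_magnetometer(series, cfg.trim_start_s, cfg.trim_end_s,
                                cfg.median_window)
    calibration = None
    attitude = None
    static = attitude_static(series.acc, series.fs_hz, cfg.attitude_lowpass_hz)
    if series.mag is not None:
        calibration = fit_calibration(series.mag[series.valid], cfg.min_cal_samples)
        # pitch/roll are mag-independent; use them to resolve the
        # calibration directions the orientation coverage leaves flat
        pre = attitude_and_heading(static, series.mag, series.valid)
        calibration = refine_calibration(series.mag[series.valid],
                                         pre.pitch[series.valid],
                                         pre.roll[series.valid], calibration)
        mag_cal = calibration.apply(series.mag)
        attitude = attitude_and_heading(static, mag_cal, series.valid)
    return series, attitude, calibration, roll_offset
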