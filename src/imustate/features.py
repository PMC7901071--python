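"""Windowed movement features from calibrated 25 Hz series.

Eight candidate per-window features are computed over fixed, non-overlapping
30-s windows anchored at the record start (incomplete trailing windows are
dropped):

* ``df``  dominant frequency (Hz) of total heave acceleration
* ``hf``  highest dominant frequency (Hz)
* ``ms``  mean static heave (g)
* ``ss``  SD of static heave (g)
* ``p5``  top-fifth-percentile boundary (95th percentile) of static heave (g)
* ``iqr`` inter-quartile range of dynamic heave (g)
* ``mo``  mean ODBA (g)
* ``sh``  circular standard deviation of heading (radians)

"Dominant frequencies" are local maxima of the mean-removed power spectrum
whose power reaches a configurable fraction (default 5%) of the spectral
maximum, DC excluded; ``df`` is the global maximum and ``hf`` the largest
qualifying frequency.  Aperiodic (flat-spectrum) windows report the 0 Hz
sentinel for both.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import FEATURE_COLUMNS, SensorTimeSeries
from .preprocess import AttitudeSeries

SH_FLOOR = 1e-6
SH_CAP = 4.0


def static_dynamic_split(acc: np.ndarray, fs: float, smooth_s: float = 2.0):
    """Split total acceleration into static (postural) and dynamic parts.

    Static acceleration is a centered running mean over ``smooth_s`` seconds;
    dynamic is the residual, so ``static + dynamic`` reconstructs the input
    exactly by construction.
    """
    acc = np.asarray(acc, dtype=float)
    n = max(1, int(round(smooth_s * fs)))
    if acc.ndim == 1:
        static = ndimage.uniform_filter1d(acc, size=n, mode="nearest")
    else:
        static = np.column_stack(
            [ndimage.uniform_filter1d(acc[:, j], size=n, mode="nearest")
             for j in range(acc.shape[1])]
        )
    return static, acc - static


def odba(dynamic: np.ndarray) -> np.ndarray:
    """Overall dynamic body acceleration: sum of |dynamic| over the 3 axes."""
    dynamic = np.asarray(dynamic, dtype=float)
    return np.abs(dynamic).sum(axis=1)


def dominant_frequencies(heave: np.ndarray, fs: float,
                         peak_fraction: float = 0.05) -> tuple[float, float]:
    """(df, hf): dominant and highest-dominant frequency of a heave window."""
    x = np.asarray(heave, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("window must span at least 2 s")
    x = x - x.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    power = power[1:]  # exclude DC
    freqs = freqs[1:]
    pmax = power.max()
    if pmax <= 1e-24:
        return 0.0, 0.0
    left = np.empty_like(power)
    right = np.empty_like(power)
    left[0], left[1:] = -np.inf, power[:-1]
    right[-1], right[:-1] = -np.inf, power[1:]
    is_peak = (power > left) & (power >= right) & (power >= peak_fraction * pmax)
    if not is_peak.any():
        return 0.0, 0.0
    df = float(freqs[np.argmax(power)])
    hf = float(freqs[is_peak].max())
    return df, hf


def circular_sd(heading_deg: np.ndarray, floor: float = SH_FLOOR,
                cap: float = SH_CAP) -> float:
    """Circular standard deviation sqrt(-2 ln Rbar) of headings, in radians.

    The result is floored/capped into (0, cap] so that a degenerate window
    (constant heading, or perfectly balanced headings with Rbar = 0) stays
    inside the support of a Weibull emission distribution.
    """
    theta = np.deg2rad(np.asarray(heading_deg, dtype=float))
    theta = theta[np.isfinite(theta)]
    if len(theta) < 2:
        return float("nan")
    rbar = float(np.abs(np.exp(1j * theta).mean()))
    if rbar <= 0:
        return float(cap)
    sh = np.sqrt(max(0.0, -2.0 * np.log(min(rbar, 1.0))))
    return float(np.clip(sh, floor, cap))


def window_features(series: SensorTimeSeries, attitude: AttitudeSeries | None,
                    window_s: float = 30.0, fs: float | None = None,
                    smooth_s: float = 2.0, peak_fraction: float = 0.05,
                    sh_floor: float = SH_FLOOR, sh_cap: float = SH_CAP,
                    max_invalid_fraction: float = 0.5) -> pd.DataFrame:
    """One row of the eight features per complete window.

    Windows with more than ``max_invalid_fraction`` invalid samples are
    emitted with ``missing = True`` and no feature values, preserving the
    regular window grid for the state chain.
    """
    fs = fs or series.fs_hz
    n_win = int(round(window_s * fs))
    if attitude is not None and len(attitude.heading) != series.n:
        raise ValueError("attitude and sensor series are misaligned")
    static, dynamic = static_dynamic_split(series.acc, fs, smooth_s)
    od = odba(dynamic)
    heave = series.acc[:, 2]
    n_windows = series.n // n_win
    rows = []
    for w in range(n_windows):
        sl = slice(w * n_win, (w + 1) * n_win)
        valid = series.valid[sl]
        if attitude is not None:
            valid = valid & attitude.valid[sl]
        row = {
            "individual_id": series.individual_id,
            "window_index": w,
            "t_start": float(series.t[sl.start]),
            "covariate": series.covariate_level,
            "missing": False,
        }
        if valid.mean() < 1.0 - max_invalid_fraction:
            row.update({f: np.nan for f in ["df", "hf", "ms", "ss", "p5", "iqr", "mo", "sh"]})
            row["missing"] = True
        else:
            df_, hf_ = dominant_frequencies(heave[sl], fs, peak_fraction)
            sh = np.nan
            if attitude is not None:
                sh = circular_sd(attitude.heading[sl][valid], sh_floor, sh_cap)
            row.update({
                "df": df_,
                "hf": hf_,
                "ms": float(static[sl, 2].mean()),
                "ss": float(static[sl, 2].std()),
                "p5": float(np.percentile(static[sl, 2], 95)),
                "iqr": float(np.subtract(*np.percentile(dynamic[sl, 2], [75, 25]))),
                "mo": float(od[sl].mean()),
                "sh": sh,
            })
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def feature_correlation_screen(table: pd.DataFrame, threshold: float = 0.7,
                               feature_names: tuple = ("df", "hf", "ms", "ss",
                                                       "p5", "iqr", "mo", "sh")):
    """Greedy correlation-based feature selection.

    Pearson correlations are computed over complete rows.  Constant columns
    (undefined correlation) are dropped first.  While any surviving pair
    exceeds ``|r| > threshold``, the member of the worst pair with the larger
    mean absolute correlation to all other survivors is dropped; exact ties
    drop the later column in declaration order.

    Returns (selected feature names, full correlation matrix DataFrame).
    """
    cols = [f for f in feature_names if f in table.columns]
    if len(cols) < 2:
        raise ValueError("need at least 2 features")
    data = table.loc[~table.get("missing", False).astype(bool), cols].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete rows")
    constant = [c for c in cols if data[c].nunique() <= 1]
    survivors = [c for c in cols if c not in constant]
    corr = data[cols].corr()
    while True:
        sub = corr.loc[survivors, survivors].abs()
        np.fill_diagonal(sub.values, 0.0)
        worst = sub.values.max()
        if worst <= threshold:
            break
        i, j = np.unravel_index(np.argmax(sub.values), sub.shape)
        a, b = survivors[i], survivors[j]
        mean_a = sub.loc[a].drop(a).mean()
        mean_b = sub.loc[b].drop(b).mean()
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:  # tie: drop the later column in declaration order
            drop = b if cols.index(b) > cols.index(a) else a
        survivors.remove(drop)
    return survivors, corr
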