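"""Classification accuracy, bouts and time-activity budgets.

Confusion matrices follow the convention: rows are HMM-assigned states,
columns are "true" (reference) states, cells report column percentages;
raw counts are retained.  Overall accuracy carries an exact
(Clopper-Pearson) 95% binomial confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import STATE_LABELS


@dataclass
class ConfusionMatrix:
    labels: tuple
    counts: np.ndarray  # (assigned, true)
    column_percent: np.ndarray
    accuracy: float
    ci95: tuple
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=[f"assigned_{l}" for l in self.labels],
                            columns=[f"true_{l}" for l in self.labels])

    def report(self) -> str:
        lines = [f"n = {self.n}",
                 f"overall accuracy: {100 * self.accuracy:.1f}% "
                 f"({100 * self.ci95[0]:.1f}, {100 * self.ci95[1]:.1f})",
                 "column % (rows = assigned, cols = true):"]
        pct = pd.DataFrame(self.column_percent, index=self.labels,
                           columns=self.labels)
        lines.append(pct.round(1).to_string())
        return "\n".join(lines)


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple:
    """Exact binomial confidence interval for a proportion."""
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def sample_validation_windows(feature_table: pd.DataFrame, birds,
                              n_per_bird: int = 50, seed: int = 0,
                              colony_mask: pd.Series | None = None):
    """Random validation windows, ``n_per_bird`` per listed bird.

    Sampling is without replacement and reproducible for a fixed seed.
    Windows flagged as colony periods are excluded *after* sampling (their
    count is reported), mirroring a validation pool whose colony
    observations are discarded rather than resampled.

    Returns ``(subset table, n_excluded)``.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for bird in birds:
        g = feature_table[feature_table["individual_id"] == bird]
        if len(g) < n_per_bird:
            raise ValueError(
                f"individual {bird!r} has only {len(g)} windows, "
                f"needs {n_per_bird}")
        take = rng.choice(len(g), size=n_per_bird, replace=False)
        parts.append(g.iloc[np.sort(take)])
    subset = pd.concat(parts, ignore_index=False)
    n_excluded = 0
    if colony_mask is not None:
        flagged = colony_mask.reindex(subset.index, fill_value=False).astype(bool)
        n_excluded = int(flagged.sum())
        subset = subset[~flagged]
    return subset.reset_index(drop=True), n_excluded


def confusion(true_labels, assigned_labels, labels=None) -> ConfusionMatrix:
    """Counts, column percentages, overall accuracy and exact 95% CI."""
    true_labels = np.asarray(true_labels)
    assigned_labels = np.asarray(assigned_labels)
    if len(true_labels) != len(assigned_labels):
        raise ValueError("label vectors must have equal length")
    if labels is None:
        labels = tuple(l for l in STATE_LABELS
                       if l in set(true_labels) | set(assigned_labels))
        extra = sorted((set(true_labels) | set(assigned_labels)) - set(labels))
        labels = labels + tuple(extra)
    alphabet = set(labels)
    stray = (set(true_labels) | set(assigned_labels)) - alphabet
    if stray:
        raise ValueError(f"labels outside alphabet: {sorted(stray)}")
    index = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, a in zip(true_labels, assigned_labels):
        counts[index[a], index[t]] += 1
    col_tot = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(col_tot > 0, 100.0 * counts / col_tot, np.nan)
    n = int(counts.sum())
    k = int(np.trace(counts))
    return ConfusionMatrix(labels=tuple(labels), counts=counts,
                           column_percent=pct, accuracy=k / n,
                           ci95=clopper_pearson(k, n), n=n)


def grouped_accuracy(validation: pd.DataFrame, true_col: str = "true_state",
                     assigned_col: str = "assigned_state",
                     group_col: str = "covariate", labels=None):
    """Per-group confusion matrices plus the pooled matrix.

    Empty groups are reported with ``None`` rather than silently dropped.
    """
    out = {}
    for group, g in validation.groupby(group_col, sort=True):
        out[group] = (confusion(g[true_col], g[assigned_col], labels)
                      if len(g) else None)
    pooled = confusion(validation[true_col], validation[assigned_col], labels)
    return out, pooled


def extract_bouts(state_sequence, window_s: float = 30.0,
                  individual_id: str = "ind0") -> pd.DataFrame:
    """Maximal runs of identical states with durations in minutes."""
    seq = np.asarray(state_sequence)
    if len(seq) == 0:
        return pd.DataFrame(columns=["individual_id", "state", "start_window",
                                     "end_window", "n_windows", "duration_min"])
    change = np.flatnonzero(seq[1:] != seq[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(seq)]])
    return pd.DataFrame({
        "individual_id": individual_id,
        "state": seq[starts],
        "start_window": starts,
        "end_window": ends - 1,
        "n_windows": ends - starts,
        "duration_min": (ends - starts) * window_s / 60.0,
    })


def activity_budget(state_sequence, at_sea_mask=None,
                    individual_id: str = "ind0",
                    labels=STATE_LABELS) -> pd.DataFrame:
    """Percent time per state over at-sea windows (sums to 100)."""
    seq = np.asarray(state_sequence)
    mask = (np.ones(len(seq), dtype=bool) if at_sea_mask is None
            else np.asarray(at_sea_mask, dtype=bool))
    if mask.sum() == 0:
        raise ValueError("at-sea mask selects no windows")
    sel = seq[mask]
    rows = [{"individual_id": individual_id, "state": l,
             "percent": 100.0 * float((sel == l).sum()) / len(sel)}
            for l in labels]
    return pd.DataFrame(rows)
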