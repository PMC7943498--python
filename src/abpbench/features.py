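"""Sliding-window feature matrices from blood pressure trend data.

Only the vital signs themselves (SBP, DBP, MAP, HR) feed the features, so
the same extraction applies to any retrospective database without extra
context. Nine feature types are derived per data point: the four raw
channels, pulse pressure, and four ratios (SBP/HR, DBP/HR, SBP/MAP,
MAP/DBP). For each type the current value plus its differences to the
five preceding and five following data points give 11 columns (9 × 11 =
99); for the four core signals a summary block adds the window median,
the difference to it and the relative difference (4 × 3 = 12), for 111
columns total in per-minute mode.

High-rate (1/5 Hz) mode uses the 15 preceding and 15 following neighbors
spaced 20 s apart (every 4th sample), i.e. 31 values per type (9 × 31 =
279) plus the same summary block over the 31-point window: 291 columns.

``extended`` mode additionally emits the mean-based summary triple per
signal (123 / 303 columns) for users who want the full literal set.

Rows whose window is incomplete (series edges, gaps) are masked rather
than filled. Zero-denominator ratios become NaN in otherwise valid rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregate import MINUTE_S
from .simulate import SAMPLE_PERIOD_S

CHANNEL_TYPES = ("sbp", "dbp", "map", "hr", "pp", "sbp_hr", "dbp_hr", "sbp_map", "map_dbp")
SUMMARY_SIGNALS = ("hr", "dbp", "sbp", "map")

assert 9 * 11 + 4 * 3 == 111
assert 9 * 31 + 4 * 3 == 291


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.asarray(num, dtype=float) / den
    return np.where(den == 0.0, np.nan, out)


def derive_channels(sbp, dbp, map_, hr) -> dict[str, np.ndarray]:
    """The nine per-point feature types.

    Accepts scalars or aligned arrays; a zero denominator yields NaN for
    the affected ratio rather than raising.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    map_ = np.asarray(map_, dtype=float)
    hr = np.asarray(hr, dtype=float)
    return {
        "sbp": sbp,
        "dbp": dbp,
        "map": map_,
        "hr": hr,
        "pp": sbp - dbp,
        "sbp_hr": _safe_ratio(sbp, hr),
        "dbp_hr": _safe_ratio(dbp, hr),
        "sbp_map": _safe_ratio(sbp, map_),
        "map_dbp": _safe_ratio(map_, dbp),
    }


@dataclass
class FeatureMatrix:
    """A design matrix plus the mask of rows with incomplete windows."""

    data: pd.DataFrame
    time_col: str
    feature_columns: list[str]
    valid: np.ndarray
    mode: str
    kind: str

    @property
    def n_features(self) -> int:
        return len(self.feature_columns)

    def usable(self) -> pd.DataFrame:
        """Rows with complete windows (ratio NaNs may remain; drop per need)."""
        return self.data.loc[self.valid].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.data.loc[self.valid].to_csv(path, index=False)


def _shift(v: np.ndarray, k: int) -> np.ndarray:
    """Value at position i + k, NaN outside the series."""
    out = np.full(v.shape, np.nan)
    if k == 0:
        return v.astype(float).copy()
    if k > 0:
        out[:-k] = v[k:]
    else:
        out[-k:] = v[:k]
    return out


def _build_matrix(t: np.ndarray, present: np.ndarray,
                  chans: dict[str, np.ndarray], offsets: list[int], stride: int,
                  time_col: str, mode: str, kind: str) -> FeatureMatrix:
    cols: dict[str, np.ndarray] = {time_col: t}
    for name in CHANNEL_TYPES:
        v = chans[name]
        cols[name] = v.astype(float)
        for k in offsets:
            cols[f"{name}_lag{k // stride:+d}"] = v - _shift(v, k)
    win_offsets = sorted(set(offsets) | {0})
    for sig in SUMMARY_SIGNALS:
        stack = np.vstack([_shift(chans[sig], k) for k in win_offsets])
        med = np.median(stack, axis=0)
        cols[f"{sig}_med"] = med
        cols[f"{sig}_dmed"] = chans[sig] - med
        cols[f"{sig}_rdmed"] = _safe_ratio(chans[sig] - med, med)
        if mode == "extended":
            mean = np.mean(stack, axis=0)
            cols[f"{sig}_mean"] = mean
            cols[f"{sig}_dmean"] = chans[sig] - mean
            cols[f"{sig}_rdmean"] = _safe_ratio(chans[sig] - mean, mean)
    pres_stack = np.vstack([_shift(present.astype(float), k) for k in win_offsets])
    valid = np.all(pres_stack == 1.0, axis=0)
    data = pd.DataFrame(cols)
    feat_cols = [c for c in data.columns if c != time_col]
    expected = 9 * len(win_offsets) + 4 * (6 if mode == "extended" else 3)
    if len(feat_cols) != expected:
        raise AssertionError(f"feature-count identity violated: {len(feat_cols)} != {expected}")
    return FeatureMatrix(data=data, time_col=time_col, feature_columns=feat_cols,
                         valid=valid, mode=mode, kind=kind)


def _regrid(frame: pd.DataFrame, time_col: str, step: int) -> pd.DataFrame:
    t = frame[time_col].to_numpy()
    grid = np.arange(t.min(), t.max() + step, step, dtype=np.int64)
    return frame.set_index(time_col).reindex(grid).rename_axis(time_col).reset_index()


def extract_minute_features(minutes: pd.DataFrame, mode: str = "paper") -> FeatureMatrix:
    """Per-minute design matrix: 111 columns in paper mode, 123 extended.

    ``minutes`` needs columns ``t_end_s, sbp, dbp, map, hr``; rows must be
    time-ordered. Missing minutes (absent rows) break windows; the ±5
    window must be fully present for a row to be valid.
    """
    if mode not in ("paper", "extended"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(minutes) < 11:
        warnings.warn("fewer than 11 minute records: every row is masked")
    if len(minutes) == 0:
        raise ValueError("empty minute series")
    g = _regrid(minutes, "t_end_s", MINUTE_S)
    present = g["sbp"].notna().to_numpy() & g["dbp"].notna().to_numpy() & \
        g["map"].notna().to_numpy() & g["hr"].notna().to_numpy()
    chans = derive_channels(g["sbp"], g["dbp"], g["map"], g["hr"])
    offsets = [k for k in range(-5, 6) if k != 0]
    fm = _build_matrix(g["t_end_s"].to_numpy(), present, chans, offsets, 1,
                       "t_end_s", mode, kind="minute")
    keep = np.isin(fm.data["t_end_s"].to_numpy(), minutes["t_end_s"].to_numpy())
    fm.data = fm.data.loc[keep].reset_index(drop=True)
    fm.valid = fm.valid[keep]
    return fm


def extract_highrate_features(vitals: pd.DataFrame, mode: str = "paper") -> FeatureMatrix:
    """High-rate design matrix: 291 columns in paper mode, 303 extended.

    Neighbors are taken 20 s apart (every 4th 1/5 Hz sample), 15 before
    and 15 after, so a valid row needs the full ±300 s strided window.
    """
    if mode not in ("paper", "extended"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(vitals) == 0:
        raise ValueError("empty series")
    if len(vitals) < 121:
        warnings.warn("fewer than 121 samples: every row is masked")
    g = _regrid(vitals, "t_s", SAMPLE_PERIOD_S)
    present = g["sbp"].notna().to_numpy() & g["dbp"].notna().to_numpy() & \
        g["map"].notna().to_numpy() & g["hr"].notna().to_numpy()
    chans = derive_channels(g["sbp"], g["dbp"], g["map"], g["hr"])
    offsets = [4 * k for k in range(-15, 16) if k != 0]
    fm = _build_matrix(g["t_s"].to_numpy(), present, chans, offsets, 4,
                       "t_s", mode, kind="highrate")
    keep = np.isin(fm.data["t_s"].to_numpy(), vitals["t_s"].to_numpy())
    fm.data = fm.data.loc[keep].reset_index(drop=True)
    fm.valid = fm.valid[keep]
    return fm
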