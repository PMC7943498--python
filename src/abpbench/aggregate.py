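"""AIMS-style per-minute storage and observer-clock synchronization.

The anesthesia information management system stores one data point per
measurement minute: the median of the previous minute's twelve 1/5 Hz
samples. Minute windows are half-open ``[t_end - 60, t_end)`` with
boundaries at multiples of 60 s from session start. Live observation logs
live on a laptop clock with an unknown offset; the non-pulsatile
high-pressure plateau of the line flush at session start serves as a
landmark to recover that offset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import SAMPLE_PERIOD_S, ObservationLog

MINUTE_S = 60
MINUTE_COLUMNS = ("t_end_s", "sbp", "dbp", "map", "hr", "n")


def aggregate_minutes(vitals: pd.DataFrame, min_contributing: int = 1) -> pd.DataFrame:
    """Collapse a 1/5 Hz series to per-minute medians.

    Parameters
    ----------
    vitals
        Time-ordered frame with columns ``t_s, sbp, dbp, map, hr``.
    min_contributing
        Minutes with fewer contributing samples get NaN medians but keep
        their count; default 1 stores whatever the minute had.

    Returns
    -------
    DataFrame with columns ``t_end_s, sbp, dbp, map, hr, n`` — one row per
    minute boundary whose window ``[t_end-60, t_end)`` contains data. The
    even-count median is the mean of the two central values.
    """
    if len(vitals) == 0:
        return pd.DataFrame(columns=list(MINUTE_COLUMNS))
    t = vitals["t_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError("vitals must be strictly increasing in t_s")
    minute = t // MINUTE_S
    rows = []
    for m, grp in vitals.groupby(minute):
        n = len(grp)
        if n >= min_contributing:
            med = [float(np.median(grp[c])) for c in ("sbp", "dbp", "map", "hr")]
        else:
            med = [np.nan] * 4
        rows.append([int((m + 1) * MINUTE_S), *med, n])
    out = pd.DataFrame(rows, columns=list(MINUTE_COLUMNS))
    out["t_end_s"] = out["t_end_s"].astype(np.int64)
    out["n"] = out["n"].astype(np.int64)
    return out


def detect_flush(vitals: pd.DataFrame, plateau_mmhg: float = 200.0,
                 min_run: int = 2) -> int:
    """Locate the landmark flush on the monitor clock.

    Returns the time of the first run of at least ``min_run`` consecutive
    samples with ``sbp > plateau_mmhg`` and pulse pressure below 10 mmHg
    (the flush plateau is non-pulsatile). Consecutive means 5 s apart;
    a gap breaks the run.

    Raises
    ------
    ValueError
        If no qualifying run exists ("flush not found").
    """
    if len(vitals) == 0:
        raise ValueError("flush not found: empty series")
    t = vitals["t_s"].to_numpy()
    hit = (vitals["sbp"].to_numpy() > plateau_mmhg) & (
        (vitals["sbp"].to_numpy() - vitals["dbp"].to_numpy()) < 10.0
    )
    run = 0
    for i in range(len(t)):
        contiguous = i > 0 and (t[i] - t[i - 1]) == SAMPLE_PERIOD_S
        run = (run if contiguous else 0) + 1 if hit[i] else 0
        if run >= min_run:
            return int(t[i - min_run + 1])
    raise ValueError("flush not found: no non-pulsatile run above "
                     f"{plateau_mmhg} mmHg of length >= {min_run}")


def sync_clocks(log: ObservationLog, flush_t_monitor: float) -> tuple[ObservationLog, float]:
    """Shift an observer-clock log onto the monitor clock.

    The offset is ``logged_flush_s − flush_t_monitor``; every episode time
    (and the logged flush itself) is shifted by its negative. Returns the
    synchronized log and the recovered offset.
    """
    offset = log.logged_flush_s - flush_t_monitor
    return log.shifted(-offset), offset
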