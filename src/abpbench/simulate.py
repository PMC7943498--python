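"""Synthetic invasive blood pressure sessions with artifact episodes.

Emulates the data-generating situation of an anesthesia monitoring session:
a patient monitor emits systolic/diastolic/mean arterial pressure and heart
rate at 1/5 Hz; the anesthesia information management system later stores
one median per minute. Artifact episodes of six cause categories disturb
the pressure channels with cause-specific signatures; a live observer logs
episode start/end on a laptop clock that is offset from the monitor clock
by an unknown amount, and the arterial line is flushed at the start of
every session so the two clocks can be reconciled afterwards. A second,
imperfect "retrospective annotator" re-labels stored minutes with
cause-dependent detection probabilities.

All times are integer seconds; the sample grid is 5 s. Every stochastic
choice flows through one :class:`numpy.random.Generator`, so a config with
a fixed seed reproduces a session bitwise.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: The six artifact cause categories distinguished by the live observer.
CAUSES = (
    "flush",
    "blood_sampling",
    "sensor_movement",
    "simultaneous_nibp",
    "sensor_height",
    "other",
)

SAMPLE_PERIOD_S = 5
VITALS_COLUMNS = ("t_s", "sbp", "dbp", "map", "hr")

_DEFAULT_RATES = {
    "flush": 0.2,
    "blood_sampling": 0.4,
    "sensor_movement": 0.6,
    "simultaneous_nibp": 0.5,
    "sensor_height": 0.1,
    "other": 0.3,
}

_DEFAULT_DURATIONS = {
    "flush": (5, 15),
    "blood_sampling": (20, 60),
    "sensor_movement": (5, 90),
    "simultaneous_nibp": (30, 60),
    "sensor_height": (60, 600),
    "other": (10, 60),
}

# Cause-dependent retrospective detection: sustained systematic errors
# (sensor height) are easy to spot in stored trend data, brief movement
# spikes are mostly invisible after the one-minute median.
_DEFAULT_DETECT = {
    "flush": 1.0,
    "blood_sampling": 0.22,
    "sensor_movement": 0.13,
    "simultaneous_nibp": 0.17,
    "sensor_height": 0.54,
    "other": 0.38,
}


@dataclass(frozen=True)
class ArtifactEpisode:
    """A contiguous disturbance of the pressure signal, half-open [start_s, end_s)."""

    start_s: float
    end_s: float
    cause: str

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(
                f"episode must have start < end, got [{self.start_s}, {self.end_s})"
            )
        if self.cause not in CAUSES:
            raise ValueError(f"unknown artifact cause {self.cause!r}")

    def shifted(self, offset_s: float) -> "ArtifactEpisode":
        return ArtifactEpisode(self.start_s + offset_s, self.end_s + offset_s, self.cause)


@dataclass
class ObservationLog:
    """Live-observed artifact episodes on the observer's (laptop) clock."""

    episodes: list[ArtifactEpisode]
    logged_flush_s: float

    def shifted(self, offset_s: float) -> "ObservationLog":
        return ObservationLog(
            [e.shifted(offset_s) for e in self.episodes],
            self.logged_flush_s + offset_s,
        )


@dataclass
class SimulationConfig:
    """Parameters of one simulated monitoring session.

    Rates are per hour, durations in seconds, pressures in mmHg, heart
    rate in bpm. ``trend_sd`` is the step standard deviation of the
    bounded random walk that moves the hemodynamic baseline between
    consecutive 5 s samples; ``noise_sd`` is additive observation noise.
    ``clock_offset_s`` is observer clock minus monitor clock.
    """

    duration_s: int = 3600
    baseline_sbp: float = 120.0
    baseline_dbp: float = 60.0
    baseline_hr: float = 70.0
    trend_sd: float = 0.5
    noise_sd: float = 1.5
    episode_rate_per_hour_by_cause: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RATES)
    )
    duration_range_by_cause: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_DURATIONS)
    )
    clock_offset_s: int = 30
    retro_detect_prob_by_cause: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DETECT)
    )
    retro_false_pos_rate: float = 0.015
    seed: int = 0
    # cause-signature parameters
    flush_plateau_mmhg: float = 280.0
    blood_sampling_range_mmhg: tuple[float, float] = (30.0, 60.0)
    movement_spike_sd_mmhg: float = 40.0
    nibp_pp_compression: float = 0.7
    height_offset_range_mmhg: tuple[float, float] = (10.0, 30.0)
    other_gain_range: tuple[float, float] = (0.85, 1.15)

    def validate(self) -> None:
        if self.duration_s < 600:
            raise ValueError("duration_s must be at least 600 s (session must host the landmark flush)")
        for cause, rate in self.episode_rate_per_hour_by_cause.items():
            if cause not in CAUSES:
                raise ValueError(f"unknown cause {cause!r} in episode rates")
            if rate < 0:
                raise ValueError(f"negative episode rate for {cause!r}")
        for cause, (lo, hi) in self.duration_range_by_cause.items():
            if cause not in CAUSES:
                raise ValueError(f"unknown cause {cause!r} in duration ranges")
            if not (0 < lo <= hi):
                raise ValueError(f"duration range for {cause!r} must be positive and ordered")
        for cause, p in self.retro_detect_prob_by_cause.items():
            if cause not in CAUSES:
                raise ValueError(f"unknown cause {cause!r} in detection probabilities")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"detection probability for {cause!r} outside [0, 1]")
        if not 0.0 <= self.retro_false_pos_rate <= 1.0:
            raise ValueError("retro_false_pos_rate outside [0, 1]")
        if self.trend_sd < 0 or self.noise_sd < 0:
            raise ValueError("trend_sd and noise_sd must be nonnegative")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass
class Session:
    """One simulated session: monitor-clock vitals, observer-clock log, truth.

    ``vitals`` has columns ``t_s, sbp, dbp, map, hr`` on a 5 s grid;
    ``truth`` is aligned with ``vitals`` and carries the per-sample ground
    truth ``artifact`` flag and ``cause`` (empty string on clean samples).
    ``clock_offset_s`` is the true offset, retained for testing clock
    synchronization only.
    """

    vitals: pd.DataFrame
    log: ObservationLog
    truth: pd.DataFrame
    clock_offset_s: int


def _bounded_walk(rng: np.random.Generator, n: int, start: float, sd: float,
                  lo: float, hi: float) -> np.ndarray:
    """Random walk reflected into [lo, hi]."""
    steps = rng.normal(0.0, sd, size=n)
    out = np.empty(n)
    x = start
    for i in range(n):
        x = x + steps[i]
        if x < lo:
            x = 2 * lo - x
        elif x > hi:
            x = 2 * hi - x
        out[i] = x
    return out


def _draw_episodes(rng: np.random.Generator, cfg: SimulationConfig) -> list[ArtifactEpisode]:
    episodes: list[ArtifactEpisode] = []
    # Landmark flush within the first 120 s; duration at least 10 s so the
    # plateau always covers two grid samples and stays detectable.
    lo, hi = cfg.duration_range_by_cause.get("flush", (5, 15))
    flush_dur = int(rng.integers(max(10, lo), max(10, lo, hi) + 1))
    flush_start = int(rng.integers(10, 120 - flush_dur + 1))
    episodes.append(ArtifactEpisode(flush_start, flush_start + flush_dur, "flush"))

    for cause in CAUSES:
        rate = cfg.episode_rate_per_hour_by_cause.get(cause, 0.0)
        n = rng.poisson(rate * cfg.duration_s / 3600.0)
        lo, hi = cfg.duration_range_by_cause.get(cause, (5, 60))
        for _ in range(n):
            dur = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, cfg.duration_s))
            end = min(start + dur, cfg.duration_s)
            if end > start:
                episodes.append(ArtifactEpisode(start, end, cause))
    episodes.sort(key=lambda e: (e.start_s, e.end_s, CAUSES.index(e.cause)))
    return episodes


def _apply_signature(rng: np.random.Generator, cfg: SimulationConfig,
                     vit: pd.DataFrame, idx: np.ndarray, cause: str) -> None:
    """Distort samples ``idx`` of ``vit`` in place with the cause's signature."""
    k = idx.sum()
    if k == 0:
        return
    if cause == "flush":
        # non-pulsatile high-pressure plateau from the pressurized flush bag
        v = cfg.flush_plateau_mmhg + rng.normal(0.0, 2.0, size=k)
        vit.loc[idx, "sbp"] = v + 1.0
        vit.loc[idx, "dbp"] = v - 1.0
        vit.loc[idx, "map"] = v
    elif cause == "blood_sampling":
        lo, hi = cfg.blood_sampling_range_mmhg
        v = rng.uniform(lo, hi) + rng.normal(0.0, 2.0, size=k)
        vit.loc[idx, "sbp"] = v + 2.0
        vit.loc[idx, "dbp"] = v - 2.0
        vit.loc[idx, "map"] = v
    elif cause == "sensor_movement":
        sd = cfg.movement_spike_sd_mmhg
        for col in ("sbp", "dbp", "map", "hr"):
            spikes = rng.standard_t(3, size=k) * (sd if col != "hr" else sd / 2.0)
            vit.loc[idx, col] = vit.loc[idx, col] + spikes
    elif cause == "simultaneous_nibp":
        keep = 1.0 - cfg.nibp_pp_compression
        m = vit.loc[idx, "map"]
        vit.loc[idx, "sbp"] = m + keep * (vit.loc[idx, "sbp"] - m)
        vit.loc[idx, "dbp"] = m + keep * (vit.loc[idx, "dbp"] - m)
    elif cause == "sensor_height":
        lo, hi = cfg.height_offset_range_mmhg
        off = rng.uniform(lo, hi) * (1 if rng.random() < 0.5 else -1)
        for col in ("sbp", "dbp", "map"):
            vit.loc[idx, col] = vit.loc[idx, col] + off
    elif cause == "other":
        lo, hi = cfg.other_gain_range
        gain = rng.uniform(lo, hi)
        for col in ("sbp", "dbp", "map"):
            vit.loc[idx, col] = vit.loc[idx, col] * gain


def simulate_session(config: SimulationConfig) -> Session:
    """Simulate one monitoring session.

    Returns a :class:`Session` whose vitals live on the monitor clock and
    whose observation log lives on the observer clock (shifted by
    ``config.clock_offset_s``). Baselines follow bounded random walks,
    MAP = DBP + (SBP − DBP)/3 on clean samples, episode onsets are a
    Poisson process per cause, and a landmark flush is always injected
    within the first 120 s and recorded in ``log.logged_flush_s``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.duration_s // SAMPLE_PERIOD_S
    t = np.arange(n, dtype=np.int64) * SAMPLE_PERIOD_S

    sbp = _bounded_walk(rng, n, config.baseline_sbp, config.trend_sd,
                        config.baseline_sbp - 30, config.baseline_sbp + 30)
    dbp = _bounded_walk(rng, n, config.baseline_dbp, config.trend_sd,
                        config.baseline_dbp - 20, config.baseline_dbp + 20)
    hr = _bounded_walk(rng, n, config.baseline_hr, config.trend_sd,
                       max(35.0, config.baseline_hr - 25), config.baseline_hr + 25)

    sbp = sbp + rng.normal(0.0, config.noise_sd, size=n)
    dbp = dbp + rng.normal(0.0, config.noise_sd, size=n)
    hr = hr + rng.normal(0.0, config.noise_sd, size=n)
    # keep the clean-sample ordering SBP >= MAP >= DBP > 0 exact
    dbp = np.clip(dbp, 20.0, None)
    sbp = np.maximum(sbp, dbp + 5.0)
    hr = np.clip(hr, 30.0, None)
    mean_ap = dbp + (sbp - dbp) / 3.0

    vitals = pd.DataFrame({"t_s": t, "sbp": sbp, "dbp": dbp, "map": mean_ap, "hr": hr})

    episodes = _draw_episodes(rng, config)
    artifact = np.zeros(n, dtype=bool)
    cause = np.full(n, "", dtype=object)
    for ep in episodes:
        inside = (t >= ep.start_s) & (t < ep.end_s)
        # first-starting episode claims the per-sample cause
        cause[inside & ~artifact] = ep.cause
        artifact |= inside
    # flush signatures last: the pressurized flush bag dominates the
    # transducer, so an overlapping disturbance cannot erase the plateau
    for ep in [e for e in episodes if e.cause != "flush"] + \
              [e for e in episodes if e.cause == "flush"]:
        inside = (t >= ep.start_s) & (t < ep.end_s)
        _apply_signature(rng, config, vitals, inside, ep.cause)

    truth = pd.DataFrame({"t_s": t, "artifact": artifact, "cause": cause})
    log = ObservationLog(
        episodes=[e.shifted(config.clock_offset_s) for e in episodes],
        logged_flush_s=episodes[0].start_s + config.clock_offset_s,
    )
    return Session(vitals=vitals, log=log, truth=truth,
                   clock_offset_s=config.clock_offset_s)


def simulate_retrospective_annotator(
    labels: np.ndarray | pd.Series,
    causes: np.ndarray | pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Emulate imperfect retrospective annotation of stored minutes.

    Each true artifact minute is detected with the cause's detection
    probability; each clean minute is falsely flagged with
    ``config.retro_false_pos_rate``. Returns a boolean array of the same
    length (a stand-in for retrospective annotation labels).
    """
    labels = np.asarray(labels, dtype=bool)
    causes = np.asarray(causes, dtype=object)
    if labels.shape != causes.shape:
        raise ValueError("labels and causes must be aligned")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    probs = np.empty(labels.shape, dtype=float)
    for i, (lab, c) in enumerate(zip(labels, causes)):
        if lab:
            if c not in config.retro_detect_prob_by_cause:
                raise ValueError(f"unknown artifact cause {c!r}")
            probs[i] = config.retro_detect_prob_by_cause[c]
        else:
            probs[i] = config.retro_false_pos_rate
    return rng.random(labels.shape) < probs


# ---------------------------------------------------------------------------
# session I/O: plain CSV + JSON sidecar


def _read_numeric_csv(path: Path, columns: tuple[str, ...]) -> pd.DataFrame:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if header != list(columns):
            raise ValueError(f"{path}: expected header {','.join(columns)}, got {','.join(header)}")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(columns):
                raise ValueError(f"{path}: line {lineno}: expected {len(columns)} fields, got {len(row)}")
            try:
                rows.append([float(x) for x in row])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-numeric value in {row!r}") from None
    return pd.DataFrame(rows, columns=list(columns))


def write_session(session: Session, out_dir: str | Path) -> None:
    """Write a session as vitals.csv, events.csv, truth.csv and session.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.vitals.to_csv(out / "vitals.csv", index=False)
    ev = pd.DataFrame(
        [(e.start_s, e.end_s, e.cause) for e in session.log.episodes],
        columns=["start_s", "end_s", "cause"],
    )
    ev.to_csv(out / "events.csv", index=False)
    session.truth.to_csv(out / "truth.csv", index=False)
    with open(out / "session.json", "w") as fh:
        json.dump(
            {
                "logged_flush_s": session.log.logged_flush_s,
                "clock_offset_s": session.clock_offset_s,
            },
            fh,
            indent=1,
        )


def read_session(in_dir: str | Path) -> Session:
    """Read a session written by :func:`write_session`.

    Malformed rows raise ``ValueError`` naming the file and line number.
    """
    d = Path(in_dir)
    vitals = _read_numeric_csv(d / "vitals.csv", VITALS_COLUMNS)
    vitals["t_s"] = vitals["t_s"].astype(np.int64)

    episodes: list[ArtifactEpisode] = []
    with open(d / "events.csv", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["start_s", "end_s", "cause"]:
            raise ValueError(f"{d / 'events.csv'}: expected header start_s,end_s,cause")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ValueError(f"{d / 'events.csv'}: line {lineno}: expected 3 fields")
            try:
                start, end = float(row[0]), float(row[1])
            except ValueError:
                raise ValueError(f"{d / 'events.csv'}: line {lineno}: non-numeric time") from None
            if row[2] not in CAUSES:
                raise ValueError(f"{d / 'events.csv'}: line {lineno}: unknown cause {row[2]!r}")
            episodes.append(ArtifactEpisode(start, end, row[2]))

    with open(d / "session.json") as fh:
        meta = json.load(fh)

    truth_path = d / "truth.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, keep_default_na=False,
                            dtype={"t_s": np.int64, "artifact": object, "cause": str})
        truth["artifact"] = truth["artifact"].astype(str).isin(("True", "1", "true"))
        truth["cause"] = truth["cause"].astype(object)
    else:
        truth = pd.DataFrame({"t_s": vitals["t_s"],
                              "artifact": np.zeros(len(vitals), dtype=bool),
                              "cause": [""] * len(vitals)})

    log = ObservationLog(episodes=episodes, logged_flush_s=float(meta["logged_flush_s"]))
    return Session(vitals=vitals, log=log, truth=truth,
                   clock_offset_s=int(meta["clock_offset_s"]))
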