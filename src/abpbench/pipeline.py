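"""End-to-end experiment: simulate → aggregate → label → features → stats → bench.

One :class:`ExperimentConfig` drives a reproducible experiment over many
simulated sessions. Every stage's intermediate table is written as CSV,
the agreement report and benchmark table as CSV/JSON, and a manifest
records the config, derived seeds and SHA-256 hashes of all outputs, so a
rerun with the same config produces an identical bundle.

All randomness funnels through the experiment seed: per-session and
per-model sub-seeds derive from it via a seed sequence, never from the
wall clock.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg
from . import bench, features, labeling
from .agreement import contingency, diagnostics, incidence, round_half_up
from .simulate import (
    CAUSES,
    Session,
    SimulationConfig,
    simulate_retrospective_annotator,
    simulate_session,
    write_session,
)

log = logging.getLogger("abpbench")

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


@dataclass
class ExperimentConfig:
    """Configuration of one experiment (YAML/JSON-loadable)."""

    n_sessions: int = 5
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    feature_mode: str = "minute"  # "minute" or "highrate"
    definitions: list[str] = field(default_factory=lambda: ["def1", "def2", "def3"])
    families: list[str] = field(default_factory=lambda: list(bench.FAMILIES))
    grid: str = "small"  # "small" or "default"
    seed: int = 0
    write_sessions: bool = False

    def validate(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if self.feature_mode not in ("minute", "highrate"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        valid_defs = {"def1", "def2", "def3", "def4"}
        for d in self.definitions:
            if d not in valid_defs:
                raise ValueError(f"unknown definition {d!r}")
        if "def4" in self.definitions and self.feature_mode != "highrate":
            raise ValueError("definition def4 requires feature_mode: highrate")
        for f in self.families:
            if f not in bench.FAMILIES:
                raise ValueError(f"unknown family {f!r}")
        if self.grid not in ("small", "default"):
            raise ValueError(f"unknown grid {self.grid!r}")
        self.simulation.validate()


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML/JSON experiment config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> ExperimentConfig:
    raw = dict(raw)
    sim_raw = raw.pop("simulation", {}) or {}
    known = {f.name for f in dataclasses.fields(ExperimentConfig)} - {"simulation"}
    for key in raw:
        if key not in known:
            raise ValueError(f"unknown config key {key!r}")
    for key in sim_raw:
        if key not in _SIM_FIELDS:
            raise ValueError(f"unknown simulation config key {key!r}")
    for dict_field in ("episode_rate_per_hour_by_cause", "duration_range_by_cause",
                       "retro_detect_prob_by_cause"):
        for cause in (sim_raw.get(dict_field) or {}):
            if cause not in CAUSES:
                raise ValueError(f"unknown cause {cause!r} in {dict_field}")
    # per-cause maps override the defaults entry-wise
    sim_defaults = SimulationConfig()
    for dict_field in ("episode_rate_per_hour_by_cause", "duration_range_by_cause",
                       "retro_detect_prob_by_cause"):
        if dict_field in sim_raw:
            merged = dict(getattr(sim_defaults, dict_field))
            merged.update({k: tuple(v) if isinstance(v, list) else v
                           for k, v in sim_raw[dict_field].items()})
            sim_raw[dict_field] = merged
    for tup_field in ("blood_sampling_range_mmhg", "height_offset_range_mmhg",
                      "other_gain_range"):
        if tup_field in sim_raw and isinstance(sim_raw[tup_field], list):
            sim_raw[tup_field] = tuple(sim_raw[tup_field])
    cfg = ExperimentConfig(simulation=SimulationConfig(**sim_raw), **raw)
    cfg.validate()
    return cfg


def config_to_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def build_session_tables(session: Session) -> pd.DataFrame:
    """Aggregate, synchronize and label one session's stored minutes."""
    minutes = agg.aggregate_minutes(session.vitals)
    flush_t = agg.detect_flush(session.vitals)
    synced, _offset = agg.sync_clocks(session.log, flush_t)
    labeled = labeling.label_minutes(minutes, synced.episodes)
    return labeled


def build_minute_dataset(sim_config: SimulationConfig, n_sessions: int, seed: int
                         ) -> tuple[pd.DataFrame, list, list]:
    """Simulate, synchronize and label ``n_sessions`` sessions' minutes.

    Returns (concatenated labeled minute table with a ``session`` column,
    per-session labeled tables, per-session feature matrices). Each
    session and its annotator draw sub-seeds from ``seed``.
    """
    labeled_parts, feat_parts = [], []
    for i in range(n_sessions):
        session = simulate_session(sim_config.with_seed(bench.derive_seed(seed, 0, i)))
        labeled = build_session_tables(session)
        annot_rng = np.random.default_rng(bench.derive_seed(seed, 1, i))
        def3 = simulate_retrospective_annotator(
            labeled["def2"], np.where(labeled["def2"], labeled["cause"], ""),
            sim_config, rng=annot_rng)
        labeled = labeling.attach_retrospective(labeled, def3)
        labeled.insert(0, "session", i)
        fm = features.extract_minute_features(labeled)
        labeled_parts.append(labeled)
        feat_parts.append(fm)
    return pd.concat(labeled_parts, ignore_index=True), labeled_parts, feat_parts


def assemble_design(labeled_parts: list, feat_parts: list, definition: str
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Stack per-session feature rows with labels, dropping masked or
    non-finite rows (incomplete windows, zero-denominator ratios)."""
    Xs, ys = [], []
    for lab, fm in zip(labeled_parts, feat_parts):
        X = fm.data.loc[fm.valid, fm.feature_columns]
        y = lab.loc[fm.valid, definition].to_numpy(dtype=bool)
        finite = np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
        Xs.append(X.loc[finite])
        ys.append(y[finite])
    return pd.concat(Xs, ignore_index=True), np.concatenate(ys)


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline and write the report bundle under ``out_dir``.

    Returns the report dictionary (incidences, agreement statistics and
    the benchmark table) that was also written to disk.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()

    labeled_parts, feat_parts = [], []
    for i in range(cfg.n_sessions):
        s_seed = bench.derive_seed(cfg.seed, 0, i)
        session = simulate_session(cfg.simulation.with_seed(s_seed))
        try:
            labeled = build_session_tables(session)
        except ValueError as exc:
            raise RuntimeError(f"stage 'label' failed for session {i}: {exc}") from exc
        annot_rng = np.random.default_rng(bench.derive_seed(cfg.seed, 1, i))
        def3 = simulate_retrospective_annotator(
            labeled["def2"], np.where(labeled["def2"], labeled["cause"], ""),
            cfg.simulation, rng=annot_rng)
        labeled = labeling.attach_retrospective(labeled, def3)
        labeled.insert(0, "session", i)

        if cfg.feature_mode == "minute":
            fm = features.extract_minute_features(labeled)
        else:
            fm = features.extract_highrate_features(session.vitals)
            flush_t = agg.detect_flush(session.vitals)
            synced, _ = agg.sync_clocks(session.log, flush_t)
            def4 = labeling.label_def4(session.vitals, synced.episodes)
            fm.data.insert(0, "session", i)
            fm.data["def4"] = def4[np.isin(session.vitals["t_s"].to_numpy(),
                                           fm.data["t_s"].to_numpy())]
        labeled_parts.append(labeled)
        feat_parts.append((i, fm))
        if cfg.write_sessions:
            write_session(session, out / f"session_{i:03d}")
        log.info("session %d simulated and labeled (%.1fs)", i, time.monotonic() - t0)

    labels_df = pd.concat(labeled_parts, ignore_index=True)
    labels_df.to_csv(out / "labels.csv", index=False)

    # agreement report (live definitions vs retrospective annotation)
    report: dict = {"incidence_pct": {}, "agreement": {}}
    for d in ("def1", "def2", "def3"):
        report["incidence_pct"][d] = round_half_up(
            100.0 * incidence(labels_df[d]), 1)
    for ref in ("def1", "def2"):
        table = contingency(labels_df[ref], labels_df["def3"])
        stats = diagnostics(table)
        report["agreement"][f"def3_vs_{ref}"] = {
            "table": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
            **stats.rounded(),
        }

    # benchmark
    datasets = {}
    for d in cfg.definitions:
        Xs, ys = [], []
        for i, fm in feat_parts:
            lab = labeled_parts[i]
            X = fm.data.loc[fm.valid, fm.feature_columns]
            if cfg.feature_mode == "minute":
                y = lab.loc[fm.valid, d].to_numpy(dtype=bool)
            else:
                y = fm.data.loc[fm.valid, "def4"].to_numpy(dtype=bool) if d == "def4" else None
                if y is None:
                    continue
            finite = np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
            Xs.append(X.loc[finite])
            ys.append(y[finite])
        if Xs:
            datasets[d] = (pd.concat(Xs, ignore_index=True), np.concatenate(ys))

    grids = {f: (bench.HyperGrid.small(f) if cfg.grid == "small"
                 else bench.HyperGrid.default(f)) for f in cfg.families}
    bench_df = bench.benchmark(datasets, families=cfg.families, grids=grids,
                               seed=bench.derive_seed(cfg.seed, 2))
    bench_df.to_csv(out / "benchmark.csv", index=False)
    report["benchmark"] = bench_df.to_dict(orient="records")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)

    manifest = {
        "config": config_to_dict(cfg),
        "package": "abpbench 0.1.0",
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.glob("*.csv")) + [out / "report.json"]
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    log.info("experiment complete in %.1fs", time.monotonic() - t0)
    return report


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
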