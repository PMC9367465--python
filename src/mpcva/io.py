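"""Table readers/writers, configuration, seeding and orchestration.

Delimited text (CSV) is the canonical interchange format for all
tables; ground-truth labels travel in a sidecar table keyed by event or
cell id so that analysis inputs never contain truth columns.  Every run
writes a provenance record (config echo + seed + package version) next
to its outputs, and a single global seed expands into per-stage child
seeds through a documented deterministic derivation, so any stage can
be re-run in isolation and every output file is reproducible
byte-for-byte from its provenance record.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cytometry import CytometryViabilityModel, GateConfig
from .dye import DyeModelParams
from .simulate import (
    ScenarioConfig,
    generate_cytometry_sample,
    generate_timelapse_cohort,
    tracks_to_frames,
)
from .timelapse import TimelapseViabilityModel

__all__ = [
    "EVENT_COLUMNS",
    "MEASUREMENT_COLUMNS",
    "read_event_table",
    "write_event_table",
    "read_track_tables",
    "write_track_tables",
    "load_config",
    "child_seed",
    "write_provenance",
    "run_pipeline",
]

#: Required columns of a cytometry event table.
EVENT_COLUMNS = (
    "event_id",
    "sample_id",
    "duplicate_index",
    "total_intensity",
    "dye_area",
    "cell_area",
    "dna_intensity",
    "dna_area",
)
#: Truth columns split into the sidecar table.
EVENT_TRUTH_COLUMNS = ("event_id", "cell_id", "true_state", "dividing")

MEASUREMENT_COLUMNS = ("cell_id", "time_h", "raw_intensity", "background_intensity")
TRACK_EVENT_COLUMNS = ("cell_id", "division_time", "lysis_time")

_NUMERIC_EVENT_COLUMNS = (
    "duplicate_index",
    "total_intensity",
    "dye_area",
    "cell_area",
    "dna_intensity",
    "dna_area",
)

#: Pipeline stages in their fixed execution (and seed-derivation) order.
STAGES = ("simulate", "label", "gate", "score", "benchmark")


class SchemaError(ValueError):
    """A table is missing required columns or violates its invariants."""


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _coerce_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header row, one for 1-based numbering
            lines = (df.index[bad] + 2).tolist()
            raise SchemaError(
                f"{path}: non-numeric value(s) in column {col!r} "
                f"at line(s) {lines[:10]}"
            )
        df[col] = coerced
    return df


def read_event_table(path) -> pd.DataFrame:
    """Read and validate a cytometry event table.

    Checks the column schema, coerces numeric columns (reporting the
    line number of any malformed cell), and enforces the event
    invariants: positive dye and cell areas, non-negative intensities,
    duplicate index in {1, 2}.  An empty file with a valid header
    yields an empty event set.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, EVENT_COLUMNS, path)
    if len(df) == 0:
        return df
    df = _coerce_numeric(df, _NUMERIC_EVENT_COLUMNS, path)

    def _reject(mask, message):
        if mask.any():
            lines = (df.index[mask] + 2).tolist()
            raise SchemaError(f"{path}: {message} at line(s) {lines[:10]}")

    _reject(df["dye_area"] <= 0, "dye_area must be positive")
    _reject(df["cell_area"] <= 0, "cell_area must be positive")
    _reject(df["total_intensity"] < 0, "total_intensity must be >= 0")
    _reject(~df["duplicate_index"].isin([1, 2]), "duplicate_index must be 1 or 2")
    df["duplicate_index"] = df["duplicate_index"].astype(int)
    return df


def write_event_table(events: pd.DataFrame, path, truth_path=None) -> None:
    """Write an event table, splitting truth columns into a sidecar.

    The main table carries exactly the documented measurement schema;
    ground-truth columns (``true_state`` etc.), when present, go to
    ``truth_path`` (default: ``<path stem>.truth.csv``).
    """
    path = Path(path)
    events[list(EVENT_COLUMNS)].to_csv(path, index=False)
    truth_cols = [c for c in EVENT_TRUTH_COLUMNS if c in events.columns]
    if len(truth_cols) > 1:
        if truth_path is None:
            truth_path = path.with_suffix(".truth.csv")
        events[truth_cols].to_csv(truth_path, index=False)


def write_track_tables(measurements, events, truth, prefix) -> dict:
    """Write the three time-lapse tables under a common path prefix."""
    prefix = Path(prefix)
    paths = {
        "measurements": prefix.with_name(prefix.name + "_measurements.csv"),
        "events": prefix.with_name(prefix.name + "_events.csv"),
        "truth": prefix.with_name(prefix.name + "_truth.csv"),
    }
    measurements.to_csv(paths["measurements"], index=False)
    events.to_csv(paths["events"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return paths


def read_track_tables(measurements_path, events_path):
    """Read and validate the time-lapse measurement and fate tables."""
    mpath, epath = Path(measurements_path), Path(events_path)
    measurements = pd.read_csv(mpath)
    _check_columns(measurements, MEASUREMENT_COLUMNS, mpath)
    measurements = _coerce_numeric(
        measurements, ("time_h", "raw_intensity", "background_intensity"), mpath
    )
    bad = measurements["background_intensity"] <= 0
    if bad.any():
        lines = (measurements.index[bad] + 2).tolist()
        raise SchemaError(
            f"{mpath}: background_intensity must be positive at line(s) {lines[:10]}"
        )
    events = pd.read_csv(epath)
    _check_columns(events, TRACK_EVENT_COLUMNS, epath)
    events = _coerce_numeric(events, ("division_time", "lysis_time"), epath)
    return measurements, events


# ---------------------------------------------------------------------------
# configuration and seeding


def load_config(path) -> dict:
    """Load a YAML run configuration; the seed key is mandatory."""
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if "seed" not in config:
        raise ValueError(f"{path}: config must set an explicit 'seed'")
    return config


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed.

    Derived as ``SeedSequence([seed, stage_index])`` with the stage's
    fixed position in :data:`STAGES`, truncated below 2**31 so stages
    can be re-run in isolation with plain integer seeds.
    """
    idx = STAGES.index(stage)
    state = np.random.SeedSequence([int(seed), idx]).generate_state(1)[0]
    return int(state % (2**31))


def write_provenance(out_dir, config: dict, seed: int, stage: str) -> Path:
    """Write the machine-readable provenance record next to the outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    record = {
        "package": "mpcva",
        "version": __version__,
        "seed": int(seed),
        "stage": stage,
        "config": config,
    }
    path = out_dir / f"provenance_{stage}.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")
    return path


def _scenario_from_config(config: dict, seed: int) -> ScenarioConfig:
    block = dict(config.get("scenario", {}))
    block.setdefault("seed", seed)
    if "duration_range" in block and block["duration_range"] is not None:
        block["duration_range"] = tuple(block["duration_range"])
    if "sample_times" in block:
        block["sample_times"] = tuple(block["sample_times"])
    return ScenarioConfig(**block)


def _gate_from_config(config: dict) -> GateConfig:
    return GateConfig(**config.get("gate", {}))


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the configured stages and return the artifact paths.

    Stages (``config['stages']``, default ``['simulate', 'label',
    'gate']``) run in fixed order: ``simulate`` writes time-lapse and
    cytometry tables for a control and a treated sample, ``label`` runs
    the time-lapse arm, ``gate`` the cytometry arm, ``benchmark`` the
    four-assay comparison.  Deterministic under a fixed seed; any stage
    error propagates as ``RuntimeError`` naming the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages = config.get("stages", ["simulate", "label", "gate"])
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; valid stages: {list(STAGES)}")
    # validate parameter blocks before any computation
    gate_cfg = _gate_from_config(config)
    label_block = config.get("label", {})
    if float(label_block.get("k", 2.0)) < 0:
        raise ValueError("label.k must be >= 0")
    params = DyeModelParams(**config.get("dye", {}))
    artifacts: dict[str, Path] = {}

    for stage in [s for s in STAGES if s in stages]:
        try:
            if stage == "simulate":
                scen = _scenario_from_config(config, child_seed(seed, stage))
                tracks = generate_timelapse_cohort(scen, params)
                frames = tracks_to_frames(tracks)
                artifacts.update(
                    write_track_tables(*frames, prefix=out_dir / "tracks")
                )
                control_scen = ScenarioConfig(
                    **{
                        **scen.__dict__,
                        "toxin_effect": 0.0,
                        "pathway_mix": dict(scen.pathway_mix),
                        "seed": child_seed(seed, stage) + 1,
                    }
                )
                measure_time = float(config.get("measure_time", 24.0))
                events = pd.concat(
                    [
                        generate_cytometry_sample(
                            control_scen, measure_time, params, sample_id="control"
                        ),
                        generate_cytometry_sample(
                            scen, measure_time, params, sample_id="treated"
                        ),
                    ],
                    ignore_index=True,
                )
                epath = out_dir / "events.csv"
                write_event_table(events, epath)
                artifacts["events"] = epath
            elif stage == "label":
                measurements, events = read_track_tables(
                    config.get("tracks_measurements", out_dir / "tracks_measurements.csv"),
                    config.get("tracks_events", out_dir / "tracks_events.csv"),
                )
                model = TimelapseViabilityModel(
                    measurements,
                    events,
                    k=float(label_block.get("k", 2.0)),
                    dead_window=float(label_block.get("dead_window", 48.0)),
                )
                res = model.fit()
                lpath = out_dir / "labeled_intensities.csv"
                res.classified.to_csv(lpath, index=False)
                (out_dir / "timelapse_summary.txt").write_text(res.summary() + "\n")
                artifacts["labeled"] = lpath
            elif stage in ("gate", "score"):
                events = read_event_table(config.get("events", out_dir / "events.csv"))
                controls = config.get("control_samples", ["control"])
                res = CytometryViabilityModel(events, controls, config=gate_cfg).fit()
                spath = out_dir / "sample_scores.csv"
                res.sample_table.to_csv(spath, index=False)
                rpath = out_dir / "viable_ranges.csv"
                pd.DataFrame(
                    [
                        {
                            "group": g,
                            "center": r.center,
                            "spread": r.spread,
                            "k": r.k,
                            "low": r.low,
                            "high": r.high,
                        }
                        for g, r in res.ranges.items()
                    ]
                ).to_csv(rpath, index=False)
                artifacts["scores"] = spath
                artifacts["ranges"] = rpath
            elif stage == "benchmark":
                from .comparators import benchmark

                block = dict(config.get("comparator", {}))
                block.setdefault("seed", child_seed(seed, stage))
                table = benchmark(params=params, gate=gate_cfg, **block)
                bpath = out_dir / "benchmark.csv"
                table.to_csv(bpath, index=False)
                artifacts["benchmark"] = bpath
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        write_provenance(out_dir, config, seed, stage)
    return artifacts
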