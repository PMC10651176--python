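"""End-to-end orchestration: simulate/load -> correct -> measure -> compare.

A run config (YAML or JSON) names one block per condition, each either a
simulation config or paths to existing track/protrusion tables, plus the
analysis parameters.  The run writes per-cell and per-embryo CSVs, rose
histogram JSONs, a pooled orientation table and a single ``summary.json``
whose provenance block records the package version, config hash and
seed.  All outputs are deterministic given the config and seed: rerunning
produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, protrusion_metrics, stats_engine, synthetic, track_io, track_metrics

log = logging.getLogger("cardiotrack")

_ANALYSIS_DEFAULTS = {
    "midline_x": 0.0,
    "window_min": 30.0,
    "rose_bins": 6,
    "protrusion_rose_bins": 12,
    "unit": "embryo",
}

_TRACK_CFG_FIELDS = set(synthetic.EmbryoSimConfig.__dataclass_fields__)
_PROT_CFG_FIELDS = set(synthetic.ProtrusionSimConfig.__dataclass_fields__)


def load_config(path: str | Path) -> dict:
    """Parse a YAML or JSON run config."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def validate_config(config: dict) -> list[str]:
    """Return a list of blocking issues (empty iff the config is runnable).

    Unknown keys produce log warnings, not issues.
    """
    issues: list[str] = []
    if not isinstance(config, dict):
        return ["config must be a mapping"]
    conditions = config.get("conditions")
    if not isinstance(conditions, dict) or not conditions:
        issues.append("config needs a non-empty 'conditions' mapping")
        conditions = {}
    for name, block in conditions.items():
        if not isinstance(block, dict):
            issues.append(f"condition {name!r} must be a mapping")
            continue
        has_sim = "tracks" in block or "protrusions" in block
        has_files = "tracks_csv" in block or "protrusions_csv" in block
        if not has_sim and not has_files:
            issues.append(f"condition {name!r} defines neither simulation nor input files")
        for key, fields in (("tracks", _TRACK_CFG_FIELDS), ("protrusions", _PROT_CFG_FIELDS)):
            sub = block.get(key)
            if sub is None:
                continue
            if not isinstance(sub, dict):
                issues.append(f"condition {name!r}: {key} must be a mapping")
                continue
            for k in sub:
                if k not in fields:
                    log.warning("condition %r: unknown %s key %r ignored", name, key, k)
            try:
                cfg_cls = synthetic.EmbryoSimConfig if key == "tracks" else synthetic.ProtrusionSimConfig
                cfg_cls(**{k: v for k, v in sub.items() if k in fields})
            except synthetic.ConfigError as exc:
                issues.append(f"condition {name!r}: {exc}")
        if "tracks_csv" in block and not Path(block["tracks_csv"]).exists():
            issues.append(f"condition {name!r}: tracks file not found: {block['tracks_csv']}")
        if "reference_csv" in block and not Path(block["reference_csv"]).exists():
            issues.append(f"condition {name!r}: reference file not found: {block['reference_csv']}")
        if "protrusions_csv" in block and not Path(block["protrusions_csv"]).exists():
            issues.append(f"condition {name!r}: protrusion file not found: {block['protrusions_csv']}")
    analysis = config.get("analysis", {})
    if "window_min" in analysis and analysis["window_min"] <= 0:
        issues.append("analysis: 'window_min' must be > 0")
    if "rose_bins" in analysis and analysis["rose_bins"] < 1:
        issues.append("analysis: 'rose_bins' must be >= 1")
    if "unit" in analysis and analysis["unit"] not in ("cell", "embryo"):
        issues.append("analysis: 'unit' must be 'cell' or 'embryo'")
    return issues


def _config_hash(config: dict) -> str:
    # output_dir is excluded: where a run is written must not change what
    # it computes, and byte-identical reruns may use different directories
    content = {k: v for k, v in config.items() if k != "output_dir"}
    return hashlib.sha256(
        json.dumps(content, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _condition_tracks(name: str, block: dict, seed: int, midline_x: float):
    """Load or simulate one condition's tracks; return (trackset, references)."""
    if "tracks_csv" in block:
        trackset = track_io.read_tracks(block["tracks_csv"])
        references = track_io.read_reference(block["reference_csv"]) if "reference_csv" in block else None
    else:
        overrides = {k: v for k, v in (block.get("tracks") or {}).items()
                     if k in _TRACK_CFG_FIELDS}
        overrides.setdefault("condition", name)
        if "drift_velocity" in overrides:
            overrides["drift_velocity"] = tuple(overrides["drift_velocity"])
        cfg = synthetic.EmbryoSimConfig(**overrides)
        trackset, references = synthetic.simulate_track_study(
            cfg, int(block.get("n_embryos", 5)), derive_seed_for(seed, name, "tracks")
        )
    if references is not None:
        trackset = track_io.correct_drift(trackset, references)
    return track_io.canonicalize_sides(trackset, midline_x=midline_x)


def derive_seed_for(seed: int, condition: str, stage: str) -> int:
    return synthetic.derive_seed(seed, f"{stage}:{condition}")


def _condition_protrusions(name: str, block: dict, seed: int):
    if "protrusions_csv" in block:
        return track_io.read_protrusions(block["protrusions_csv"]), block.get(
            "protrusion_movie_duration", 60.0), block.get("protrusion_frame_interval", 1.5)
    sub = {k: v for k, v in (block.get("protrusions") or {}).items() if k in _PROT_CFG_FIELDS}
    if not sub and "protrusions" not in block:
        return None, None, None
    sub.setdefault("condition", name)
    sub.setdefault("seed", derive_seed_for(seed, name, "protrusions"))
    cfg = synthetic.ProtrusionSimConfig(**sub)
    return synthetic.simulate_protrusions(cfg), cfg.movie_duration, cfg.frame_interval


def run_pipeline(config: dict, output_dir: str | Path | None = None) -> dict:
    """Run the full analysis described by ``config`` and return the summary.

    Writes per-condition tables under ``output_dir`` (default from the
    config) and ``summary.json`` at its root.  Raises on the first stage
    failure, naming the stage.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out = Path(output_dir or config.get("output_dir", "cardiotrack_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    analysis = {**_ANALYSIS_DEFAULTS, **(config.get("analysis") or {})}
    unit = analysis["unit"]

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("cardiotrack %s seed=%d config_hash=%s", __version__, seed, _config_hash(config))

    summary: dict = {
        "provenance": {
            "version": __version__,
            "seed": seed,
            "config_hash": _config_hash(config),
            "unit_of_analysis": unit,
        },
        "conditions": {},
        "comparisons": {},
    }
    per_embryo_by_condition: dict[str, pd.DataFrame] = {}
    cell_metrics_by_condition: dict[str, pd.DataFrame] = {}
    events_by_condition: dict[str, pd.DataFrame] = {}
    prot_summaries: dict[str, pd.DataFrame] = {}
    prot_duration = prot_interval = None

    try:
        for name, block in config["conditions"].items():
            stage = f"tracks:{name}"
            trackset = _condition_tracks(name, block, seed, analysis["midline_x"])
            metrics = track_metrics.compute_metrics_table(trackset)
            embryo = track_metrics.aggregate_per_embryo(metrics)
            rose = track_metrics.direction_rose(metrics, n_bins=int(analysis["rose_bins"]))
            metrics.to_csv(out / f"{name}_cell_metrics.csv", index=False, float_format="%.6f")
            embryo.to_csv(out / f"{name}_embryo_summary.csv", index=False, float_format="%.6f")
            _write_json(rose.to_dict(), out / f"{name}_direction_rose.json")
            cell_metrics_by_condition[name] = metrics
            per_embryo_by_condition[name] = embryo
            cond_summary = {
                "n_cells": int(len(metrics)),
                "n_embryos": int(len(embryo)),
                "mean_speed_um_min": float(embryo["speed_mean"].mean()),
                "mean_efficiency": float(embryo["efficiency_mean"].mean()),
                "mean_direction_deg": float(embryo["direction_mean"].mean()),
                "n_lateral_cells": int(embryo["n_lateral"].sum()),
            }

            stage = f"protrusions:{name}"
            events, duration, interval = _condition_protrusions(name, block, seed)
            if events is not None:
                prot_duration, prot_interval = duration, interval
                track_io.write_protrusions(events, out / f"{name}_protrusions.csv")
                cells = protrusion_metrics.summarize_cells(events, duration, interval)
                cells.to_csv(out / f"{name}_protrusion_cells.csv", index=False,
                             float_format="%.6f")
                prose = protrusion_metrics.protrusion_rose(
                    events, n_bins=int(analysis["protrusion_rose_bins"]),
                    frame_interval=interval)
                _write_json(prose.to_dict(), out / f"{name}_protrusion_rose.json")
                events_by_condition[name] = events
                prot_summaries[name] = cells
                cond_summary.update({
                    "n_protrusion_events": int(len(events)),
                    "protrusion_rate_per_hour": float(cells["frequency"].mean()),
                    "protrusion_persistence_min": float(cells["mean_persistence"].mean()),
                    "forward_fraction": float(cells["forward_fraction"].mean()),
                })
            summary["conditions"][name] = cond_summary

        stage = "comparisons"
        names = list(config["conditions"])
        if len(names) == 2 and all(n in per_embryo_by_condition for n in names):
            a, b = names
            for metric in ("speed", "efficiency", "direction"):
                if unit == "embryo":
                    x = per_embryo_by_condition[a][f"{metric}_mean"]
                    y = per_embryo_by_condition[b][f"{metric}_mean"]
                else:
                    x = cell_metrics_by_condition[a][metric].dropna()
                    y = cell_metrics_by_condition[b][metric].dropna()
                cmp_ = stats_engine.two_sample_t(x, y, unit=unit, groups=(a, b))
                summary["comparisons"][f"{metric}_t"] = cmp_.to_dict()
        if len(events_by_condition) == 2:
            prot = protrusion_metrics.compare_conditions(
                events_by_condition, prot_duration, prot_interval, unit="cell")
            table = prot["orientation_counts"]
            pd.DataFrame(table, index=["forward", "backward"]).T.to_csv(
                out / "orientation_counts.tsv", sep="\t")
            summary["comparisons"]["orientation_fisher"] = prot["orientation_fisher"].to_dict()
            summary["comparisons"]["protrusion_frequency_t"] = prot["frequency_t"].to_dict()
            summary["comparisons"]["protrusion_persistence_t"] = prot["mean_persistence_t"].to_dict()
            summary["comparisons"]["orientation_counts"] = table
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    # headline qualitative flags for a two-condition control-vs-treated run
    if len(per_embryo_by_condition) == 2:
        a, b = list(per_embryo_by_condition)
        ca, cb = summary["conditions"][a], summary["conditions"][b]
        summary["flags"] = {
            "lower_direction_angle_in": a if ca["mean_direction_deg"] < cb["mean_direction_deg"] else b,
            "higher_efficiency_in": a if ca["mean_efficiency"] > cb["mean_efficiency"] else b,
        }
        if "forward_fraction" in ca and "forward_fraction" in cb:
            summary["flags"]["higher_forward_fraction_in"] = (
                a if ca["forward_fraction"] > cb["forward_fraction"] else b
            )

    _write_json(summary, out / "summary.json")
    return summary
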