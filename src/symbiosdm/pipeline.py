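"""End-to-end orchestration of the interaction-approach comparison.

A single :class:`RunConfig` drives the full experiment: simulate a
virtual scenario (or load layers from disk), fit the host and dependent
ensembles, run the four approaches, evaluate, screen the reference-area
projection for non-analogue climate, tabulate range changes and binned
gain/loss surfaces, build the per-learner factorial outcome table, and
partition its variance.  Every artifact is written to the output
directory and listed, with a SHA-256 checksum, in ``manifest.json``;
re-running an identical config reproduces identical checksums.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import grid_io
from .change_metrics import binned_gain_loss, change_table
from .grid_io import write_layers
from .interactions import (
    APPROACHES,
    approach_explanatory,
    approach_overlap,
    approach_reference_area,
    model_no_interaction,
)
from .mess import mess_map
from .sdm_core import LearnerSpec, rank_variables, variable_importance
from .synthetic_data import VirtualScenarioConfig, default_config, generate_scenario

__all__ = ["RunConfig", "run_experiment", "run_approaches"]

log = logging.getLogger(__name__)

DEFAULT_LEARNERS = (LearnerSpec("glm_poly2"), LearnerSpec("sre"))


@dataclass
class RunConfig:
    """Validated configuration for :func:`run_experiment`."""

    output_dir: str
    scenario: VirtualScenarioConfig | None = None
    learner_specs: tuple = DEFAULT_LEARNERS
    split_fraction: float = 0.7
    seed: int = 0
    threshold_method: str = "prevalence"
    approaches: tuple = APPROACHES
    n_perm: int = 10
    n_bins: int = 20
    file_format: str = "csv"

    def __post_init__(self):
        if self.threshold_method not in ("prevalence", "mean_probability"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        unknown = set(self.approaches) - set(APPROACHES)
        if unknown:
            raise ValueError(f"unknown approaches: {sorted(unknown)}")
        if not 0 < self.split_fraction <= 1:
            raise ValueError("split_fraction must lie in (0, 1]")
        if self.n_perm < 1 or self.n_bins < 1:
            raise ValueError("n_perm and n_bins must be >= 1")
        if self.scenario is None:
            self.scenario = default_config(seed=self.seed)

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o).__name__)

        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)  # location metadata, not experiment config
        return json.dumps(payload, indent=1, default=enc, sort_keys=True)


def run_approaches(scenario, specs, seed: int, threshold_method: str = "prevalence"):
    """Fit host + dependent models and run the four schemes on a scenario.

    Returns ``(host_result, {approach: ApproachResult})``.  The host is
    always the climate-only ensemble; the dependent species' split is
    shared between the climate-only and explanatory schemes so that
    their comparison isolates the host predictor, while the
    reference-area scheme holds its own split within the calibration
    area.
    """
    host = model_no_interaction(
        scenario.host_occurrence,
        scenario.climate_current,
        scenario.climate_future,
        specs,
        seed=seed,
        threshold_method=threshold_method,
    )
    results = {}
    none = model_no_interaction(
        scenario.dependent_occurrence,
        scenario.climate_current,
        scenario.climate_future,
        specs,
        seed=seed + 1,
        threshold_method=threshold_method,
    )
    results["none"] = none
    results["overlap"] = approach_overlap(none, host, observed=scenario.dependent_occurrence)
    results["explanatory"] = approach_explanatory(
        scenario.dependent_occurrence,
        scenario.climate_current,
        scenario.climate_future,
        host.suitability["current"],
        host.suitability["future"],
        specs,
        split=none.split,
        threshold_method=threshold_method,
    )
    results["reference_area"] = approach_reference_area(
        scenario.dependent_occurrence,
        scenario.host_occurrence,
        scenario.climate_current,
        scenario.climate_future,
        host.suitability["current"],
        host.suitability["future"],
        specs,
        seed=seed + 2,
        threshold_method=threshold_method,
    )
    return host, results


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_experiment(config: RunConfig) -> dict:
    """Execute the full comparison experiment; return the artifact manifest.

    Any stage failure aborts with the stage name; partial outputs are
    retained next to a ``FAILED`` marker file.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = config.file_format
    ext = "csv" if fmt == "csv" else "tif"
    artifacts: list[Path] = []
    stage = "configure"

    def emit(obj, name: str):
        path = out / f"{name}.{ext}"
        write_layers(obj, path, fmt)
        artifacts.append(path)
        if fmt == "csv":
            artifacts.append(grid_io._sidecar(path))
        return path

    try:
        (out / "config.json").write_text(config.to_json())
        artifacts.append(out / "config.json")

        stage = "simulate"
        scenario = generate_scenario(config.scenario)
        emit(scenario.climate_current, "climate_current")
        emit(scenario.climate_future, "climate_future")
        emit(scenario.host_occurrence, "occurrence_host")
        emit(scenario.dependent_occurrence, "occurrence_dependent")

        stage = "fit"
        specs = tuple(config.learner_specs)
        host, results = run_approaches(
            scenario, specs, config.seed, config.threshold_method
        )
        results = {a: results[a] for a in config.approaches}
        emit(host.suitability["current"], "suitability_host_current")
        emit(host.suitability["future"], "suitability_host_future")
        for name, res in results.items():
            emit(res.suitability["current"], f"suitability_{name}_current")
            emit(res.suitability["future"], f"suitability_{name}_future")
            emit(res.binary["future"], f"range_{name}_future")

        stage = "evaluate"
        eval_rows = [{"approach": "host", **host.report.as_row()}] if host.report else []
        for name, res in results.items():
            if res.report is not None:
                eval_rows.append({"approach": name, **res.report.as_row()})
        eval_path = out / "evaluation.csv"
        pd.DataFrame(eval_rows).to_csv(eval_path, index=False)
        artifacts.append(eval_path)

        stage = "importance"
        baseline = results.get("none") or next(iter(results.values()))
        importances = variable_importance(
            baseline.model,
            scenario.climate_current,
            n_perm=config.n_perm,
            seed=config.seed + 100,
        )
        ranked = rank_variables(importances)
        imp_path = out / "importance.csv"
        pd.DataFrame(
            {
                "variable": list(importances),
                "importance": [importances[v] for v in importances],
                "rank": [ranked.index(v) + 1 for v in importances],
            }
        ).to_csv(imp_path, index=False)
        artifacts.append(imp_path)

        stage = "mess"
        mess_summary = None
        if "reference_area" in results:
            ref = results["reference_area"]
            mess = mess_map(
                scenario.climate_current,
                scenario.climate_future,
                calibration_cells=ref.split.training,
            )
            ref.non_analogue = mess.similarity < 0
            mess_path = out / "mess_similarity.csv"
            frame = pd.DataFrame(
                {
                    "cell_id": list(scenario.climate_future.grid.cell_ids),
                    "similarity": mess.similarity,
                    "most_dissimilar": mess.most_dissimilar,
                }
            )
            frame.to_csv(mess_path, index=False)
            artifacts.append(mess_path)
            mess_summary = {"fraction_negative": mess.fraction_negative()}

        stage = "change_metrics"
        table = change_table(results.values(), scenario.dependent_occurrence)
        change_path = out / "change_table.csv"
        table.to_csv(change_path, index=False)
        artifacts.append(change_path)
        v1, v2 = (ranked + ranked)[:2]
        for name, res in results.items():
            binned = binned_gain_loss(
                scenario.dependent_occurrence,
                res.binary["future"],
                scenario.climate_current,
                v1,
                v2,
                n_bins=config.n_bins,
            )
            path = out / f"binned_gain_loss_{name}.csv"
            binned.to_frame().to_csv(path, index=False)
            artifacts.append(path)

        stage = "uncertainty"
        partition_summary = None
        if len(specs) >= 2 and len(config.approaches) >= 2:
            from .uncertainty import build_outcome_table, hierarchical_partition

            per_member = {}
            for spec in specs:
                _, member_results = run_approaches(
                    scenario, (spec,), config.seed, config.threshold_method
                )
                for name in config.approaches:
                    per_member[(spec.name, name)] = member_results[name]
            outcome = build_outcome_table(per_member, scenario.dependent_occurrence)
            outcome_path = out / "outcome_table.csv"
            outcome.to_csv(outcome_path, index=False)
            artifacts.append(outcome_path)
            part = hierarchical_partition(outcome)
            partition_summary = {
                "r2_full": part.r2_full,
                "factors": {
                    f: {
                        "independent": part.independent[f],
                        "joint": part.joint[f],
                        "share_pct": part.share_pct[f],
                    }
                    for f in part.independent
                },
            }
            part_path = out / "partition.json"
            part_path.write_text(json.dumps(partition_summary, indent=1, sort_keys=True))
            artifacts.append(part_path)

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "learners": [s.name for s in specs],
            "threshold_method": config.threshold_method,
            "thresholds": {
                "host": host.thresholds,
                **{name: res.thresholds for name, res in results.items()},
            },
            "two_most_important_variables": [v1, v2],
            "mess": mess_summary,
            "partition": partition_summary,
            "files": {
                str(p.relative_to(out)): _sha256(p) for p in sorted(set(artifacts))
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        log.info(
            "experiment complete: %d artifacts, seed %s, learners %s",
            len(manifest["files"]),
            config.seed,
            manifest["learners"],
        )
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
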