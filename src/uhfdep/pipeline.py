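"""End-to-end scenario runs: calibrate → sample → measure → compare.

A scenario names a set of condition-target configs (printed crossover
summaries per culture condition or sorted subpopulation).  For each
condition the population generator is calibrated, a virtual population is
sampled with a per-condition seed fanned out from the master seed, the
sweep protocol quantizes every cell's crossovers, and the group
comparison report is produced.  Same config + seed → identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .measurement_protocol import (
    FX01_PROTOCOL,
    FX02_PROTOCOL,
    SweepProtocol,
    records_to_dataframe,
    run_protocol,
)
from .stats_compare import compare_conditions, report_to_markdown
from .synthetic_population import (
    bundled_population_configs,
    calibrate_from_config,
    load_population_config,
    sample_population,
    samples_to_dataframe,
)

__all__ = ["RunConfig", "SCENARIOS", "run_scenario", "scenario_config"]

#: Built-in scenarios: condition config names (bundled) and the group
#: comparisons evaluated on each frequency.
SCENARIOS: dict[str, dict] = {
    "culture": {
        "conditions": ["u87_nm", "u87_dm"],
        "comparisons": [["NM", "DM"]],
    },
    "kinetics": {
        "conditions": ["u87_kinetics_nm", "u87_kinetics_dm", "u87_kinetics_dmplus"],
        "comparisons": [["NM", "DM"], ["DM", "DM+"], ["NM", "DM", "DM+"]],
    },
    "patients": {
        "conditions": [
            f"patient{k}_cd133{s}" for k in (1, 2, 3, 4) for s in ("neg", "pos")
        ],
        "comparisons": [
            [f"P{k}-CD133neg", f"P{k}-CD133pos"] for k in (1, 2, 3, 4)
        ],
    },
}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    scenario: str
    condition_configs: tuple[dict, ...]
    comparisons: tuple[tuple[str, ...], ...]
    seed: int
    out_dir: Path | None = None
    fx01_protocol: SweepProtocol = FX01_PROTOCOL
    fx02_protocol: SweepProtocol = FX02_PROTOCOL

    def config_hash(self) -> str:
        payload = {
            "scenario": self.scenario,
            "conditions": list(self.condition_configs),
            "comparisons": [list(c) for c in self.comparisons],
            "seed": self.seed,
            "fx01_protocol": self.fx01_protocol.to_dict(),
            "fx02_protocol": self.fx02_protocol.to_dict(),
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def scenario_config(name: str, seed: int, out_dir=None) -> RunConfig:
    """Resolve a built-in scenario name into a :class:`RunConfig`."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    bundled = bundled_population_configs()
    spec = SCENARIOS[name]
    missing = [c for c in spec["conditions"] if c not in bundled]
    if missing:
        raise FileNotFoundError(f"bundled configs not found: {missing}")
    configs = tuple(load_population_config(bundled[c]) for c in spec["conditions"])
    return RunConfig(
        scenario=name,
        condition_configs=configs,
        comparisons=tuple(tuple(c) for c in spec["comparisons"]),
        seed=int(seed),
        out_dir=None if out_dir is None else Path(out_dir),
    )


def condition_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic per-condition seed: spawn child ``index`` of the master."""
    return np.random.SeedSequence(master_seed, spawn_key=(index,))


def run_scenario(config: RunConfig) -> dict:
    """Execute one scenario; return the in-memory result bundle.

    When ``config.out_dir`` is set, writes ``cells.csv`` (sampled cell
    parameters and exact crossovers), ``measurements.csv`` (quantized
    per-cell table), ``report.json`` / ``report.md`` (summaries, ANOVA
    verdicts) and ``provenance.json`` (config hash, seed, version).
    """
    all_samples = []
    all_records = []
    excluded: dict[str, int] = {}
    models = {}
    for i, cfg in enumerate(config.condition_configs):
        model = calibrate_from_config(cfg)
        models[model.label] = model
        samples = sample_population(model, condition_seed(config.seed, i))
        records, n_exc = run_protocol(
            samples, config.fx01_protocol, config.fx02_protocol,
        )
        all_samples.extend(samples)
        all_records.extend(records)
        excluded[model.label] = n_exc

    report = compare_conditions(all_records, [list(c) for c in config.comparisons])
    report["excluded_cells"] = excluded
    result = {
        "config": config,
        "models": models,
        "samples": all_samples,
        "records": all_records,
        "report": report,
        "provenance": {
            "scenario": config.scenario,
            "seed": config.seed,
            "config_sha256": config.config_hash(),
            "uhfdep_version": __version__,
        },
    }
    if config.out_dir is not None:
        _write_artifacts(result, config.out_dir)
    return result


def _write_artifacts(result: dict, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples_to_dataframe(result["samples"]).to_csv(out_dir / "cells.csv", index=False)
    records_to_dataframe(result["records"]).to_csv(
        out_dir / "measurements.csv", index=False
    )
    (out_dir / "report.json").write_text(json.dumps(result["report"], indent=2))
    (out_dir / "report.md").write_text(report_to_markdown(result["report"]))
    (out_dir / "provenance.json").write_text(json.dumps(result["provenance"], indent=2))
    models = {lab: m.to_dict() for lab, m in result["models"].items()}
    (out_dir / "calibrated_models.json").write_text(json.dumps(models, indent=2))
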