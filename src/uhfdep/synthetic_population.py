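"""Calibrated synthetic cell populations for the DEP pipeline.

No per-cell raw measurements are published for the glioblastoma
populations this package models; the study conditions are available only
as summary statistics (number of cells, median, SD) of the two crossover
frequencies per culture condition.  This module therefore generates
virtual cell populations whose forward-modelled crossovers reproduce
those summaries: per-cell heterogeneity is carried by

* outer radius r — truncated normal (median 11.5 µm, CV 10% by default),
* specific membrane capacitance C_area — log-normal (drives fx01),
* intracellular conductivity σ_int — log-normal (drives fx02),

with the interior permittivity, membrane thickness and membrane
conductivity fixed per condition.  ``calibrate_to_summary`` inverts the
closed-form crossover approximations for initial distribution medians,
sets log-SDs by the delta method, then corrects the medians against the
full single-shell model by secant iteration on simulated populations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from .dielectric_core import EPS0, DielectricMaterial, ShelledCell
from .crossover_solver import (
    find_crossovers_batch,
    invert_fx01_to_membrane_capacitance,
    invert_fx02_to_sigma_int,
)

__all__ = [
    "PopulationModel",
    "CellSample",
    "CalibrationError",
    "DEP_MEDIUM",
    "sample_population",
    "samples_to_dataframe",
    "calibrate_to_summary",
    "load_population_config",
    "bundled_population_configs",
]

#: Sucrose DEP suspension medium used on the bench: ε_r 78, 26 mS/m.
DEP_MEDIUM = DielectricMaterial(rel_permittivity=78.0, conductivity=0.026)

#: Physical (unscaled) plasma-membrane defaults: 7 nm shell, 1.43e-6 S/m.
DEFAULT_MEMBRANE_THICKNESS = 7e-9
DEFAULT_MEMBRANE_SIGMA = 1.43e-6

_CALIBRATION_SEED = 101
_CALIBRATION_N = 2000


class CalibrationError(RuntimeError):
    """Population calibration failed (non-convergence or excess resampling)."""


@dataclass(frozen=True)
class PopulationModel:
    """Per-condition distributions of single-shell cell parameters.

    Medians are in SI units (m, F/m², S/m); ``radius_cv`` is the
    coefficient of variation of the truncated-normal radius and the
    ``*_log_sd`` values are the log-space SDs of the log-normal
    membrane-capacitance and intracellular-conductivity distributions.
    """

    label: str
    radius_median: float
    radius_cv: float
    cmem_median: float
    cmem_log_sd: float
    sigma_int_median: float
    sigma_int_log_sd: float
    interior_eps_r: float = 50.0
    membrane_thickness: float = DEFAULT_MEMBRANE_THICKNESS
    membrane_sigma: float = DEFAULT_MEMBRANE_SIGMA
    medium: DielectricMaterial = DEP_MEDIUM
    n_cells: int = 100

    def __post_init__(self):
        for name in ("radius_median", "cmem_median", "sigma_int_median"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("radius_cv", "cmem_log_sd", "sigma_int_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "radius_median_um": self.radius_median * 1e6,
            "radius_cv": self.radius_cv,
            "cmem_median_F_per_m2": self.cmem_median,
            "cmem_log_sd": self.cmem_log_sd,
            "sigma_int_median_S_per_m": self.sigma_int_median,
            "sigma_int_log_sd": self.sigma_int_log_sd,
            "interior_eps_r": self.interior_eps_r,
            "membrane_thickness_nm": self.membrane_thickness * 1e9,
            "membrane_sigma_S_per_m": self.membrane_sigma,
            "medium": self.medium.to_dict(),
            "n_cells": self.n_cells,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        return cls(
            label=d["label"],
            radius_median=float(d["radius_median_um"]) * 1e-6,
            radius_cv=float(d["radius_cv"]),
            cmem_median=float(d["cmem_median_F_per_m2"]),
            cmem_log_sd=float(d["cmem_log_sd"]),
            sigma_int_median=float(d["sigma_int_median_S_per_m"]),
            sigma_int_log_sd=float(d["sigma_int_log_sd"]),
            interior_eps_r=float(d["interior_eps_r"]),
            membrane_thickness=float(d["membrane_thickness_nm"]) * 1e-9,
            membrane_sigma=float(d["membrane_sigma_S_per_m"]),
            medium=DielectricMaterial.from_dict(d["medium"]),
            n_cells=int(d["n_cells"]),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "PopulationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CellSample:
    """One virtual cell with its exact (pre-quantization) crossovers."""

    cell_id: str
    cell: ShelledCell
    true_fx01: float
    true_fx02: float
    condition: str = ""

    def __post_init__(self):
        if not (self.true_fx01 < self.true_fx02):
            raise ValueError("true_fx01 must be < true_fx02")


def _draw_parameters(model: PopulationModel, rng: np.random.Generator, n: int):
    sd = model.radius_cv * model.radius_median
    lower = 2.0 * model.membrane_thickness
    if sd == 0.0:
        r = np.full(n, model.radius_median)
    else:
        a = (lower - model.radius_median) / sd
        r = truncnorm.rvs(a, np.inf, loc=model.radius_median, scale=sd,
                          size=n, random_state=rng)
    cmem = rng.lognormal(np.log(model.cmem_median), model.cmem_log_sd, size=n)
    sigma_int = rng.lognormal(np.log(model.sigma_int_median),
                              model.sigma_int_log_sd, size=n)
    return r, cmem, sigma_int


def _batch_crossovers(model: PopulationModel, r, cmem, sigma_int,
                      f_min: float, f_max: float):
    th = model.membrane_thickness
    eps_cm_r = cmem * th / EPS0
    return find_crossovers_batch(
        r, th, eps_cm_r, model.membrane_sigma,
        model.interior_eps_r, sigma_int,
        medium=model.medium, f_min=f_min, f_max=f_max,
    )


def sample_population(
    model: PopulationModel,
    seed,
    f_min: float = 1e4,
    f_max: float = 1e9,
    max_resample_frac: float = 0.10,
) -> list[CellSample]:
    """Draw ``model.n_cells`` virtual cells and compute their crossovers.

    Each cell's (r, C_area, σ_int) triple is drawn independently; its
    exact fx01/fx02 are located with the full single-shell root finder on
    ``[f_min, f_max]``.  Cells lacking either crossover in range are
    redrawn; more than ``max_resample_frac`` redraws raises
    :class:`CalibrationError`.  Reproducible given ``seed`` (int,
    ``SeedSequence`` or ``Generator``).
    """
    rng = np.random.default_rng(seed)
    n = model.n_cells
    r, cmem, sig = _draw_parameters(model, rng, n)
    fx01, fx02, _ = _batch_crossovers(model, r, cmem, sig, f_min, f_max)

    n_resampled = 0
    missing = np.isnan(fx01) | np.isnan(fx02)
    while missing.any():
        n_resampled += int(missing.sum())
        if n_resampled > max_resample_frac * n:
            raise CalibrationError(
                f"{n_resampled}/{n} cells lacked crossovers in "
                f"[{f_min:g}, {f_max:g}] Hz (> {max_resample_frac:.0%} resampling)"
            )
        k = int(missing.sum())
        r2, c2, s2 = _draw_parameters(model, rng, k)
        f1, f2, _ = _batch_crossovers(model, r2, c2, s2, f_min, f_max)
        idx = np.where(missing)[0]
        r[idx], cmem[idx], sig[idx] = r2, c2, s2
        fx01[idx], fx02[idx] = f1, f2
        missing = np.isnan(fx01) | np.isnan(fx02)

    th = model.membrane_thickness
    samples = []
    for i in range(n):
        cell = ShelledCell(
            radius=float(r[i]),
            membrane_thickness=th,
            membrane=DielectricMaterial(float(cmem[i] * th / EPS0),
                                        model.membrane_sigma),
            interior=DielectricMaterial(model.interior_eps_r, float(sig[i])),
        )
        samples.append(
            CellSample(
                cell_id=f"{model.label}-{i:04d}", cell=cell,
                true_fx01=float(fx01[i]), true_fx02=float(fx02[i]),
                condition=model.label,
            )
        )
    return samples


def samples_to_dataframe(samples):
    import pandas as pd

    return pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in samples],
            "condition": [s.condition for s in samples],
            "radius_um": [s.cell.radius * 1e6 for s in samples],
            "cmem_F_per_m2": [s.cell.specific_membrane_capacitance for s in samples],
            "sigma_int_S_per_m": [s.cell.interior.conductivity for s in samples],
            "true_fx01_hz": [s.true_fx01 for s in samples],
            "true_fx02_hz": [s.true_fx02 for s in samples],
        }
    )


def _simulated_medians(model: PopulationModel, n: int, seed) -> tuple[float, float]:
    sim = replace(model, n_cells=n)
    samples = sample_population(sim, seed)
    fx01 = np.median([s.true_fx01 for s in samples])
    fx02 = np.median([s.true_fx02 for s in samples])
    return float(fx01), float(fx02)


def calibrate_to_summary(
    target_median_fx01: float,
    target_sd_fx01: float,
    target_median_fx02: float,
    target_sd_fx02: float,
    *,
    label: str = "condition",
    n_cells: int = 100,
    radius_median: float = 11.5e-6,
    radius_cv: float = 0.10,
    interior_eps_r: float = 50.0,
    membrane_thickness: float = DEFAULT_MEMBRANE_THICKNESS,
    membrane_sigma: float = DEFAULT_MEMBRANE_SIGMA,
    medium: DielectricMaterial = DEP_MEDIUM,
    tol: float = 0.01,
    max_iter: int = 20,
    calibration_n: int = _CALIBRATION_N,
    calibration_seed: int = _CALIBRATION_SEED,
) -> PopulationModel:
    """Build a :class:`PopulationModel` matching printed crossover summaries.

    Stage 1 (closed form): the membrane-capacitance median is initialized
    by inverting the fx01 approximation at the target median, the
    intracellular-conductivity median by inverting the fx02 approximation;
    log-SDs come from the delta method on the target SD/median ratios
    (the radius CV's contribution is subtracted from the fx01 spread).

    Stage 2 (full model): the two distribution medians are corrected by
    secant iteration in log space until the simulated median fx01 and
    fx02 (``calibration_n`` cells, fixed ``calibration_seed``, common
    random numbers across iterations) are within ``tol`` of the targets.
    Targets are the exact (pre-quantization) crossovers; the measurement
    grids (1 kHz / 1 MHz) perturb medians by well under the printed SDs.
    """
    for v in (target_median_fx01, target_sd_fx01, target_median_fx02, target_sd_fx02):
        if v <= 0:
            raise ValueError("calibration targets must be > 0")

    cmem0 = invert_fx01_to_membrane_capacitance(target_median_fx01, radius_median, medium)
    sigma0 = invert_fx02_to_sigma_int(target_median_fx02, interior_eps_r, medium)
    v1 = target_sd_fx01 / target_median_fx01
    v2 = target_sd_fx02 / target_median_fx02
    cmem_log_sd = np.sqrt(max(np.log1p(v1**2) - np.log1p(radius_cv**2), 0.0))
    sigma_log_sd = np.sqrt(np.log1p(v2**2))

    def build(log_c, log_s):
        return PopulationModel(
            label=label, n_cells=n_cells,
            radius_median=radius_median, radius_cv=radius_cv,
            cmem_median=float(np.exp(log_c)), cmem_log_sd=float(cmem_log_sd),
            sigma_int_median=float(np.exp(log_s)), sigma_int_log_sd=float(sigma_log_sd),
            interior_eps_r=interior_eps_r,
            membrane_thickness=membrane_thickness, membrane_sigma=membrane_sigma,
            medium=medium,
        )

    x = np.array([np.log(cmem0), np.log(sigma0)])
    prev_x = None
    prev_err = None
    trace = []
    for it in range(max_iter):
        model = build(*x)
        med1, med2 = _simulated_medians(model, calibration_n, calibration_seed)
        err = np.array([np.log(med1 / target_median_fx01),
                        np.log(med2 / target_median_fx02)])
        trace.append({"iter": it, "median_fx01": med1, "median_fx02": med2})
        if np.all(np.abs(np.expm1(err)) < tol):
            return model
        if prev_err is None:
            # fx01 ~ 1/C and fx02 ~ sigma_int: unit log-log sensitivity
            step = np.array([err[0], -err[1]])
        else:
            d_err = err - prev_err
            slope = np.where(np.abs(d_err) > 1e-12, (x - prev_x) / d_err,
                             np.array([1.0, -1.0]))
            step = -err * slope
            step = np.clip(step, -1.0, 1.0)
        prev_x, prev_err = x.copy(), err.copy()
        x = x + step
    raise CalibrationError(
        f"calibration for '{label}' did not converge in {max_iter} iterations; "
        f"trace: {trace}"
    )


def load_population_config(path) -> dict:
    """Read a condition-target config (printed medians/SDs) from JSON."""
    return json.loads(Path(path).read_text())


def bundled_population_configs() -> dict[str, Path]:
    """Name → path of the condition configs shipped with the package."""
    root = Path(__file__).parent / "data" / "populations"
    return {p.stem: p for p in sorted(root.glob("*.json"))}


def calibrate_from_config(config: dict, **overrides) -> PopulationModel:
    """Calibrate a population model from a condition-target config dict.

    The config carries the printed summary rows: fx01 median/SD in kHz,
    fx02 median/SD in MHz, the sample size and optionally the medium.
    """
    medium = (DielectricMaterial.from_dict(config["medium"])
              if "medium" in config else DEP_MEDIUM)
    kwargs = dict(
        label=config["label"],
        n_cells=int(config["n_cells"]),
        medium=medium,
    )
    kwargs.update(overrides)
    return calibrate_to_summary(
        target_median_fx01=float(config["fx01"]["median_khz"]) * 1e3,
        target_sd_fx01=float(config["fx01"]["sd_khz"]) * 1e3,
        target_median_fx02=float(config["fx02"]["median_mhz"]) * 1e6,
        target_sd_fx02=float(config["fx02"]["sd_mhz"]) * 1e6,
        **kwargs,
    )
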