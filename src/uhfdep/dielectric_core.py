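"""Complex-permittivity algebra for dielectrophoresis (DEP) modelling.

A biological cell in suspension is idealized as a single-shell particle: a
homogeneous conducting sphere (the cytoplasm and everything inside it)
wrapped in a thin, poorly conducting shell (the plasma membrane).  Each
phase — suspending medium, membrane, cell interior — is a homogeneous
dielectric described by a relative permittivity and a conductivity.  The
frequency-dependent polarizability contrast between the equivalent particle
and the medium is the Clausius–Mossotti (CM) factor; the sign of its real
part decides whether the DEP force pulls the cell toward strong-field
regions (pDEP, Re > 0) or repels it toward weak-field regions (nDEP,
Re < 0).

All frequencies are in Hz, lengths in m, conductivities in S/m.  The
complex permittivity follows the ε* = ε − jσ/ω time convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "EPS0",
    "DielectricMaterial",
    "ShelledCell",
    "Spectrum",
    "complex_permittivity",
    "equivalent_particle_permittivity",
    "clausius_mossotti",
    "cm_spectrum",
    "dep_force",
]

#: Vacuum permittivity, F/m.
EPS0 = 8.854e-12


def _require_positive_frequency(frequency) -> np.ndarray:
    f = np.asarray(frequency, dtype=float)
    if not np.all(np.isfinite(f)) or np.any(f <= 0.0):
        raise ValueError("frequency must be finite and > 0 Hz")
    return f


@dataclass(frozen=True)
class DielectricMaterial:
    """A homogeneous dielectric phase.

    Parameters
    ----------
    rel_permittivity : float
        Relative permittivity ε_r (dimensionless, > 0).
    conductivity : float
        Conductivity σ in S/m (≥ 0).
    """

    rel_permittivity: float
    conductivity: float

    def __post_init__(self):
        if not np.isfinite(self.rel_permittivity) or self.rel_permittivity <= 0:
            raise ValueError("rel_permittivity must be finite and > 0")
        if not np.isfinite(self.conductivity) or self.conductivity < 0:
            raise ValueError("conductivity must be finite and >= 0")

    @property
    def abs_permittivity(self) -> float:
        """Absolute (lossless) permittivity ε_r·ε_0, F/m."""
        return self.rel_permittivity * EPS0

    def to_dict(self) -> dict:
        return {
            "eps_r": self.rel_permittivity,
            "sigma_S_per_m": self.conductivity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DielectricMaterial":
        return cls(
            rel_permittivity=float(d["eps_r"]),
            conductivity=float(d["sigma_S_per_m"]),
        )

    @classmethod
    def from_json(cls, path) -> "DielectricMaterial":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ShelledCell:
    """Single-shell cell model: homogeneous interior + thin membrane shell.

    Parameters
    ----------
    radius : float
        Outer radius r in m (> 0).
    membrane_thickness : float
        Shell thickness in m (0 < thickness < radius).
    membrane, interior : DielectricMaterial
        Dielectric properties of the plasma membrane and of the cell
        content treated as one homogeneous phase.
    """

    radius: float
    membrane_thickness: float
    membrane: DielectricMaterial
    interior: DielectricMaterial

    def __post_init__(self):
        if not np.isfinite(self.radius) or self.radius <= 0:
            raise ValueError("radius must be finite and > 0")
        if not (0 < self.membrane_thickness < self.radius):
            raise ValueError("membrane_thickness must satisfy 0 < th < radius")

    @property
    def inner_radius(self) -> float:
        return self.radius - self.membrane_thickness

    @property
    def specific_membrane_capacitance(self) -> float:
        """Membrane capacitance per unit area, ε_cm/th, F/m²."""
        return self.membrane.abs_permittivity / self.membrane_thickness

    def to_dict(self) -> dict:
        return {
            "radius_um": self.radius * 1e6,
            "membrane_thickness_nm": self.membrane_thickness * 1e9,
            "membrane": self.membrane.to_dict(),
            "interior": self.interior.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShelledCell":
        return cls(
            radius=float(d["radius_um"]) * 1e-6,
            membrane_thickness=float(d["membrane_thickness_nm"]) * 1e-9,
            membrane=DielectricMaterial.from_dict(d["membrane"]),
            interior=DielectricMaterial.from_dict(d["interior"]),
        )

    @classmethod
    def from_json(cls, path) -> "ShelledCell":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class Spectrum:
    """Clausius–Mossotti factor sampled on a frequency grid."""

    frequencies: np.ndarray
    cm_values: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        v = np.asarray(self.cm_values, dtype=complex)
        if f.shape != v.shape:
            raise ValueError("frequencies and cm_values must have equal length")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing and > 0")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "cm_values", v)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frequency_hz": self.frequencies,
                "re_cm": self.cm_values.real,
                "im_cm": self.cm_values.imag,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def complex_permittivity(material: DielectricMaterial, frequency):
    """Complex permittivity ε* = ε_r·ε_0 − jσ/ω of a phase at ``frequency``.

    ``frequency`` may be a scalar or an array; the result broadcasts.
    """
    f = _require_positive_frequency(frequency)
    out = _complex_perm(material.rel_permittivity, material.conductivity, f)
    return complex(out) if np.isscalar(frequency) else out


def _complex_perm(eps_r, sigma, f):
    return np.asarray(eps_r) * EPS0 - 1j * np.asarray(sigma) / (2.0 * np.pi * f)


def _equivalent_perm(eps_cm, sig_cm, eps_int, sig_int, r, th, f):
    """Array core of the single-shell reduction (broadcasting on all args)."""
    ec = _complex_perm(eps_cm, sig_cm, f)
    ei = _complex_perm(eps_int, sig_int, f)
    gamma3 = (np.asarray(r) / (np.asarray(r) - np.asarray(th))) ** 3
    k = (ei - ec) / (ei + 2.0 * ec)
    return ec * (gamma3 + 2.0 * k) / (gamma3 - k)


def equivalent_particle_permittivity(cell: ShelledCell, frequency):
    """Complex permittivity of the homogeneous sphere equivalent to ``cell``.

    The shelled sphere is reduced to a single effective particle:

        ε_p* = ε_cm* (γ³ + 2K) / (γ³ − K),
        γ = r/(r − th),  K = (ε_int* − ε_cm*)/(ε_int* + 2ε_cm*).

    When the shell material equals the interior material, K collapses so
    that ε_p* = ε_int* exactly.
    """
    f = _require_positive_frequency(frequency)
    out = _equivalent_perm(
        cell.membrane.rel_permittivity,
        cell.membrane.conductivity,
        cell.interior.rel_permittivity,
        cell.interior.conductivity,
        cell.radius,
        cell.membrane_thickness,
        f,
    )
    return complex(out) if np.isscalar(frequency) else out


def _re_cm_arrays(f, r, th, eps_cm, sig_cm, eps_int, sig_int, eps_m, sig_m):
    """Re[f_CM] with full numpy broadcasting over cells and frequencies."""
    ep = _equivalent_perm(eps_cm, sig_cm, eps_int, sig_int, r, th, f)
    em = _complex_perm(eps_m, sig_m, f)
    return ((ep - em) / (ep + 2.0 * em)).real


def clausius_mossotti(cell: ShelledCell, medium: DielectricMaterial, frequency):
    """Clausius–Mossotti factor (ε_p* − ε_m*)/(ε_p* + 2ε_m*).

    For passive materials Re lies in [−0.5, 1].  ``frequency`` may be a
    scalar or an array.
    """
    f = _require_positive_frequency(frequency)
    ep = equivalent_particle_permittivity(cell, f)
    em = _complex_perm(medium.rel_permittivity, medium.conductivity, f)
    denom = ep + 2.0 * em
    if np.any(np.abs(denom) == 0.0):
        raise FloatingPointError(
            "degenerate CM denominator eps_p* + 2 eps_m* = 0 "
            "(not reachable with passive materials)"
        )
    out = (ep - em) / denom
    return complex(out) if np.isscalar(frequency) else out


def cm_spectrum(
    cell: ShelledCell,
    medium: DielectricMaterial,
    f_min: float,
    f_max: float,
    points_per_decade: int = 50,
) -> Spectrum:
    """CM factor on a log-spaced grid from ``f_min`` to ``f_max`` Hz."""
    if not (0 < f_min < f_max):
        raise ValueError("require 0 < f_min < f_max")
    if points_per_decade < 2:
        raise ValueError("points_per_decade must be >= 2")
    n_decades = np.log10(f_max / f_min)
    n = max(2, int(np.ceil(n_decades * points_per_decade)) + 1)
    freqs = np.logspace(np.log10(f_min), np.log10(f_max), n)
    return Spectrum(frequencies=freqs, cm_values=clausius_mossotti(cell, medium, freqs))


def dep_force(radius: float, medium: DielectricMaterial, re_cm: float, grad_e2: float) -> float:
    """Time-averaged DEP force F = 2π r³ ε_m Re[f_CM] ∇|E|², in N.

    ``grad_e2`` is the gradient of the squared field magnitude, V²/m³.
    The sign of the force follows the sign of Re[f_CM].
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    return 2.0 * np.pi * radius**3 * medium.abs_permittivity * re_cm * grad_e2
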