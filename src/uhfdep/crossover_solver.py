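"""Crossover frequencies of the DEP spectrum: root finding and closed forms.

A cell whose Re[f_CM] spectrum shows the canonical nDEP → pDEP → nDEP band
structure has two crossover frequencies: fx01 in the low-frequency range
(set by cell size and specific membrane capacitance) and fx02 in the
ultra-high-frequency range (set by the intracellular conductivity and the
permittivity contrast with the medium).  This module locates both as exact
roots of Re[f_CM](f) = 0 by log-grid bracketing plus bisection, provides
the standard closed-form approximations, and inverts those approximations
to estimate dielectric parameters from measured crossovers:

    fx01 ≈ σ_m th / (2π r ε_cm)                      (membrane regime)
    fx02 ≈ (σ_int/2π) · sqrt(1/(2ε_m² − ε_int ε_m − ε_int²))   (UHF regime)

with σ_m the medium conductivity and all permittivities absolute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dielectric_core import EPS0, DielectricMaterial, ShelledCell, _re_cm_arrays

__all__ = [
    "CrossoverResult",
    "find_crossovers",
    "find_crossovers_batch",
    "fx01_approx",
    "fx02_approx",
    "invert_fx01_to_membrane_capacitance",
    "invert_fx02_to_sigma_int",
]

#: Below this magnitude across the whole range, Re[f_CM] is treated as
#: identically zero: no crossings, rather than infinitely many.
_ZERO_CM = 1e-12


@dataclass(frozen=True)
class CrossoverResult:
    """Roots of Re[f_CM](f) = 0 located in ``search_range``.

    ``fx01`` is the lowest-frequency root, ``fx02`` the next one; either
    may be ``None`` when Re[f_CM] does not change sign.  A single sign
    change is classified by its direction: − → + with rising frequency is
    fx01, + → − is fx02 (the nDEP→pDEP→nDEP ordering of the single-shell
    spectrum).
    """

    fx01: float | None
    fx02: float | None
    search_range: tuple[float, float]
    n_sign_changes: int

    @property
    def both_present(self) -> bool:
        return self.fx01 is not None and self.fx02 is not None


def _cell_param_arrays(cell: ShelledCell):
    return (
        np.atleast_1d(cell.radius),
        np.atleast_1d(cell.membrane_thickness),
        np.atleast_1d(cell.membrane.rel_permittivity),
        np.atleast_1d(cell.membrane.conductivity),
        np.atleast_1d(cell.interior.rel_permittivity),
        np.atleast_1d(cell.interior.conductivity),
    )


def find_crossovers_batch(
    radius,
    membrane_thickness,
    membrane_eps_r,
    membrane_sigma,
    interior_eps_r,
    interior_sigma,
    medium: DielectricMaterial,
    f_min: float = 1e4,
    f_max: float = 1e9,
    points_per_decade: int = 50,
    rel_tol: float = 1e-6,
):
    """Vectorized crossover search for arrays of single-shell cells.

    All cell-parameter arguments broadcast to a common shape ``(n,)``.
    Returns ``(fx01, fx02, n_sign_changes)`` where the frequency arrays
    hold ``nan`` for absent roots.  Roots are refined by bisection in
    log-frequency to relative tolerance ``rel_tol``.
    """
    if not (0 < f_min < f_max):
        raise ValueError("require 0 < f_min < f_max")
    r, th, ecm, scm, ei, si = np.broadcast_arrays(
        *map(np.atleast_1d, (radius, membrane_thickness, membrane_eps_r,
                             membrane_sigma, interior_eps_r, interior_sigma))
    )
    n = r.shape[0]
    em, sm = medium.rel_permittivity, medium.conductivity

    n_decades = np.log10(f_max / f_min)
    m = max(2, int(np.ceil(n_decades * points_per_decade)) + 1)
    grid = np.logspace(np.log10(f_min), np.log10(f_max), m)

    re = _re_cm_arrays(grid[None, :], r[:, None], th[:, None], ecm[:, None],
                       scm[:, None], ei[:, None], si[:, None], em, sm)
    if not np.all(np.isfinite(re)):
        raise FloatingPointError("non-finite Re[f_CM] encountered during bracketing")

    near_zero = np.all(np.abs(re) < _ZERO_CM, axis=1)
    sgn = np.where(re >= 0.0, 1, -1)
    flips = sgn[:, :-1] * sgn[:, 1:] < 0  # (n, m-1)
    n_changes = flips.sum(axis=1)
    n_changes[near_zero] = 0

    # first two bracket indices per cell
    def _kth_bracket(k):
        csum = np.cumsum(flips, axis=1)
        hit = flips & (csum == k + 1)
        idx = np.argmax(hit, axis=1)
        ok = hit.any(axis=1) & ~near_zero
        return idx, ok

    fx = np.full((2, n), np.nan)
    rising = np.zeros((2, n), dtype=bool)
    for k in (0, 1):
        idx, ok = _kth_bracket(k)
        if not ok.any():
            continue
        lo = grid[idx[ok]]
        hi = grid[idx[ok] + 1]
        re_lo = re[ok, idx[ok]]
        rising[k, ok] = re_lo < 0
        sub = (r[ok], th[ok], ecm[ok], scm[ok], ei[ok], si[ok])
        fx[k, ok] = _bisect_log(sub, em, sm, lo, hi, re_lo, rel_tol)

    # classification: two roots -> (fx01, fx02) in order; one root -> by
    # direction of the sign change
    fx01 = np.full(n, np.nan)
    fx02 = np.full(n, np.nan)
    two = n_changes >= 2
    fx01[two] = fx[0, two]
    fx02[two] = fx[1, two]
    one = n_changes == 1
    fx01[one & rising[0]] = fx[0, one & rising[0]]
    fx02[one & ~rising[0]] = fx[0, one & ~rising[0]]
    return fx01, fx02, n_changes


def _bisect_log(cell_arrays, em, sm, lo, hi, re_lo, rel_tol, max_iter=80):
    """Vectorized bisection in log-frequency; sign at ``lo`` is ``re_lo``."""
    r, th, ecm, scm, ei, si = cell_arrays
    llo, lhi = np.log(lo), np.log(hi)
    s_lo = np.sign(re_lo)
    for _ in range(max_iter):
        mid = 0.5 * (llo + lhi)
        fmid = np.exp(mid)
        re_mid = _re_cm_arrays(fmid, r, th, ecm, scm, ei, si, em, sm)
        same = np.sign(re_mid) == s_lo
        llo = np.where(same, mid, llo)
        lhi = np.where(same, lhi, mid)
        if np.all(lhi - llo < np.log1p(rel_tol)):
            break
    return np.exp(0.5 * (llo + lhi))


def find_crossovers(
    cell: ShelledCell,
    medium: DielectricMaterial,
    f_min: float = 1e4,
    f_max: float = 1e9,
    points_per_decade: int = 50,
    rel_tol: float = 1e-6,
) -> CrossoverResult:
    """Locate fx01 and fx02 as roots of Re[f_CM](f) = 0 on ``[f_min, f_max]``.

    A log grid with at least ``points_per_decade`` points per decade is
    scanned for sign changes; each bracket is refined by bisection to
    relative frequency tolerance ``rel_tol``.  More than two sign changes
    is unexpected for a single-shell cell and raises a warning; the first
    two roots are still reported.
    """
    params = _cell_param_arrays(cell)
    fx01, fx02, n_changes = find_crossovers_batch(
        *params, medium=medium, f_min=f_min, f_max=f_max,
        points_per_decade=points_per_decade, rel_tol=rel_tol,
    )
    n = int(n_changes[0])
    if n > 2:
        import warnings

        warnings.warn(
            f"{n} sign changes of Re[f_CM] found in [{f_min:g}, {f_max:g}] Hz; "
            "only the first two are labelled fx01/fx02",
            stacklevel=2,
        )
    return CrossoverResult(
        fx01=None if np.isnan(fx01[0]) else float(fx01[0]),
        fx02=None if np.isnan(fx02[0]) else float(fx02[0]),
        search_range=(f_min, f_max),
        n_sign_changes=n,
    )


def fx01_approx(cell: ShelledCell, medium: DielectricMaterial) -> float:
    """Membrane-regime approximation fx01 ≈ σ_m th / (2π r ε_cm), Hz.

    σ_m is the *medium* conductivity; ε_cm the absolute membrane
    permittivity.  Equivalently fx01 ≈ σ_m / (2π r C_area) with C_area the
    specific membrane capacitance.
    """
    if cell.membrane.rel_permittivity <= 0:
        raise ValueError("membrane permittivity must be > 0")
    return (
        medium.conductivity
        * cell.membrane_thickness
        / (2.0 * np.pi * cell.radius * cell.membrane.abs_permittivity)
    )


def _fx02_radicand(interior_eps: float, medium_eps: float) -> float:
    return 2.0 * medium_eps**2 - interior_eps * medium_eps - interior_eps**2


def fx02_approx(interior: DielectricMaterial, medium: DielectricMaterial) -> float:
    """UHF approximation fx02 ≈ (σ_int/2π)·sqrt(1/(2ε_m² − ε_int ε_m − ε_int²)).

    Valid when the medium conductivity is well below the intracellular
    conductivity; by construction the result does not depend on σ_m.
    Raises for ε_int ≥ ε_m regimes where the radicand is non-positive.
    """
    rad = _fx02_radicand(interior.abs_permittivity, medium.abs_permittivity)
    if rad <= 0:
        raise ValueError(
            "approximation invalid for eps_int >= eps_m regime (non-positive radicand)"
        )
    return interior.conductivity / (2.0 * np.pi) * np.sqrt(1.0 / rad)


def invert_fx02_to_sigma_int(
    fx02: float, interior_eps_r: float, medium: DielectricMaterial
) -> float:
    """Intracellular conductivity (S/m) from a measured fx02, exact inverse
    of :func:`fx02_approx`: σ_int = 2π fx02 · sqrt(2ε_m² − ε_int ε_m − ε_int²)."""
    rad = _fx02_radicand(interior_eps_r * EPS0, medium.abs_permittivity)
    if rad <= 0:
        raise ValueError(
            "approximation invalid for eps_int >= eps_m regime (non-positive radicand)"
        )
    if fx02 <= 0:
        raise ValueError("fx02 must be > 0")
    return 2.0 * np.pi * fx02 * np.sqrt(rad)


def invert_fx01_to_membrane_capacitance(
    fx01: float, radius: float, medium: DielectricMaterial
) -> float:
    """Specific membrane capacitance (F/m²) from a measured fx01, exact
    inverse of :func:`fx01_approx`: C_area = σ_m / (2π r fx01)."""
    if fx01 <= 0 or radius <= 0 or medium.conductivity <= 0:
        raise ValueError("fx01, radius and medium conductivity must all be > 0")
    return medium.conductivity / (2.0 * np.pi * radius * fx01)
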