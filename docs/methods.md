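# Methods

## Dielectric model

Each phase (suspending medium, plasma membrane, cell interior) is a
homogeneous, non-dispersive dielectric with complex permittivity
`ε* = ε_r ε₀ − jσ/ω` (ε₀ = 8.854×10⁻¹² F/m; the `−jσ/ω` time convention is
fixed — no alternative sign convention is accepted). A cell is a single-shell
particle: a cytoplasm sphere of radius `r − th` wrapped in a membrane shell of
thickness `th`. The shelled sphere is reduced to an equivalent homogeneous
particle by the standard two-phase mixture formula

```
ε_p* = ε_cm* (γ³ + 2K)/(γ³ − K),   γ = r/(r − th),
K = (ε_int* − ε_cm*)/(ε_int* + 2ε_cm*),
```

and the Clausius–Mossotti factor is `f_CM = (ε_p* − ε_m*)/(ε_p* + 2ε_m*)`.
For passive materials Re[f_CM] ∈ [−0.5, 1]; when shell and interior materials
coincide the reduction collapses to the interior permittivity at machine
precision (K's numerator cancels exactly), which the tests assert.

Assumptions: no nucleus or multi-shell structure, no frequency dispersion of
the intrinsic permittivities, spherical cells, linear (low-field) response.

### The scaled vs. physical membrane

The bundled reference parameter set uses a ×100-scaled membrane (700 nm
thickness, ε_r 100, σ 1.43×10⁻⁴ S/m) — a common finite-element meshing
convenience that preserves the specific membrane capacitance
`C_area = ε_cm/th` and areal conductance, and hence the crossover physics at
moderate C_area. The population generator instead uses the physical pair
(7 nm, σ 1.43×10⁻⁶ S/m) by default. This is deliberate: at the measured
low-frequency crossovers (~82 kHz in a 26 mS/m medium) the implied
C_area ≈ 4–6×10⁻³ F/m² would require a scaled-shell ε_r of several hundred,
which pushes the high-frequency limit of the equivalent permittivity above the
medium's and destroys the UHF crossover altogether — an artifact of the thick
shell, not of the cell. In the thin-shell (physical) regime the high-frequency
limit tends to the interior permittivity regardless of C_area, and both
crossovers survive for every calibrated parameter set. Membrane thickness
remains a per-model field, so scaled configurations are still expressible.

## Crossover root finding

`find_crossovers` scans a log-spaced grid (default 50 points/decade over
10 kHz–1 GHz, the span of the drive electronics) for sign changes of
Re[f_CM], then refines each bracket by bisection in log-frequency to a
relative tolerance of 10⁻⁶ — far below the 1 kHz / 1 MHz instrument
resolutions. The lowest root is fx01, the next fx02; a single sign change is
classified by direction (− → + rising = fx01, + → − falling = fx02, matching
the nDEP→pDEP→nDEP ordering); |Re[f_CM]| < 10⁻¹² across the whole range is
reported as "no crossings" rather than infinitely many. More than two sign
changes triggers a warning. A vectorized batch variant evaluates the grid and
the bisection on whole populations at once; tests pin it pointwise to the
scalar path and both to an independent dense-grid + linear-interpolation
oracle on randomized parameter sets.

The closed forms `fx01 ≈ σ_m th/(2π r ε_cm)` (implemented exactly in this
form, without the √2 factor some literature variants carry; deviations from
the full model are reported, not corrected) and
`fx02 ≈ (σ_int/2π)·√(1/(2ε_m² − ε_int ε_m − ε_int²))` are exposed together
with their exact inverses, which map measured crossovers to specific membrane
capacitance and intracellular conductivity. On the reference parameters the
full model sits ~40% above the fx01 closed form and within ~9% of the fx02
closed form (both documented by tests as ratio bounds: factor 2 and 25%
respectively, in the regimes where the approximations apply).

## Synthetic populations and calibration

Per-cell heterogeneity uses the simplest positive-support families that can
reproduce a median/SD pair: truncated normal for radius (default median
11.5 µm, CV 10%, truncated at twice the membrane thickness) and log-normals
for C_area and σ_int. Parameters are drawn independently (no covariance
structure is available to calibrate against). The interior permittivity is
fixed at ε_r 50 for all conditions; condition differences are carried entirely
by σ_int (for fx02) and C_area (for fx01). Default medium: ε_r 78, 26 mS/m
(the bench DEP buffer); the reference reproduction uses 20 mS/m.

`calibrate_to_summary` matches a condition's printed medians/SDs in two
stages. Stage 1 inverts the closed forms at the target medians for the
distribution medians and sets log-SDs by the delta method
(`s = √(ln(1+(SD/median)²))`, with the radius CV's share subtracted from the
fx01 spread, since fx01 ∝ 1/(rC)). Stage 2 corrects the two medians against
the full model: simulate 2000 cells at a fixed calibration seed (common
random numbers across iterations), compare simulated exact-crossover medians
to the targets, and update by secant steps in log space (≤ 20 iterations,
1% convergence; in practice 2–4 iterations suffice). Calibration targets the
*pre-quantization* crossover distribution; quantization then shifts medians by
at most one fine step (≤ 1 MHz / 1 kHz, i.e. ≈ 0.5 step systematic bias, well
under the printed SDs).

Cells whose crossovers fall outside the search range are redrawn; more than
10% redraws aborts with a calibration error. Patient subpopulations, for which
only medians were printed, default to n = 50 cells and SD/median ratios
borrowed from the NM condition — these spreads are synthetic defaults, flagged
as such in the bundled configs.

What the generator does *not* emulate: cell-cycle structure (nucleocytoplasmic
ratio changes are noted in the source narrative but not modelled), parameter
correlations, multi-modal subpopulation mixtures within a condition, and any
measurement noise beyond grid quantization. Passing calibration round-trips
therefore shows that the model family + protocol can reproduce the printed
summaries, not that real populations are log-normal.

## Measurement protocol simulation

Each crossover is identified by a two-stage sweep: coarse steps from a
far-side start frequency (500 MHz descending at 10 MHz for fx02; 10 kHz
ascending at 10 kHz for fx01) until the DEP behaviour flips, one coarse step
back, then fine steps (1 MHz / 1 kHz); the reported value is the *first*
fine-grid frequency at which the flipped behaviour is observed. The flip test
is inclusive (a crossover exactly on a grid point reads out at that point), so
the absolute error is always in [0, fine_step) — verified exhaustively by
enumeration at 0.1-step increments. Detection is noiseless by default (the
duplicated characterization trivially confirms itself); an optional Gaussian
observation jitter averages the repeated fine scans and snaps back to the
grid. Cells whose true crossover lies outside a sweep span are excluded and
counted, as on the bench. All sweep arithmetic is exact in floating point
(grid frequencies are integer Hz).

## Statistics

Group summaries use the midpoint median, n−1 SD, and linearly interpolated
quartiles (the original analysis software's quartile convention is unknown;
linear interpolation is the documented choice here). Inference is classical
one-way fixed-effects ANOVA (scipy's implementation, cross-checked in tests
against an explicit sum-of-squares oracle and the two-group F = t² identity),
with stars * p<0.05, ** p<0.01, *** p<0.001 as the operative convention; the
stricter p<0.005 convention is noted in the report footer but not enforced.
Zero within-group variance with unequal means reports F = ∞, p = 0 with a
degeneracy flag. A Kruskal–Wallis alternative sits behind `method="rank"` for
robustness checks on the right-skewed data and is never used for verdicts.
Violin figures are rendered with a Gaussian KDE for visualization only.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit seed; pipeline- and script-level
master seeds fan out per condition via `SeedSequence(master, spawn_key=(i,))`
in the fixed condition order, so identical configs and seeds give
byte-identical CSV outputs. Simulation sizes follow the printed cohorts
(139/134 cells for the two culture conditions, 150 for the kinetics arms,
50 per patient subpopulation) with 2000-cell calibration runs; the
discrimination check repeats the two-condition experiment over 100 master
seeds. With the vectorized batch root finder each condition calibrates and
samples in about a second on one core.

A caveat that follows from the printed cohort sizes: the sample median of
~139 draws from a distribution with SD/median ≈ 0.32 has a standard error of
≈ 3.3% of the median. Fixed-seed medians therefore scatter by a few percent
around their calibration targets — the calibration itself converges to < 1%
at n = 2000 — and individual fixed-seed checks at a ±3% band can land just
outside it without indicating a model defect.

## Known limitations

- Single-shell only: no nuclear envelope, so fx02 inversion yields an
  *effective* cytoplasmic conductivity.
- The fx02 closed form is invalid when ε_int approaches ε_m (non-positive
  radicand); the package raises rather than extrapolating.
- Crossover-vs-medium-conductivity sweeps and temperature dependence are out
  of scope (no anchoring data).
- ANOVA is applied to skewed, quantized data exactly as in the original
  discrimination logic; it compares means although the headline summaries are
  medians.
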