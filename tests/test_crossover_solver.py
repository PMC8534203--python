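"""Crossover root finding, closed-form approximations and their inverses."""

import numpy as np
import pytest

from uhfdep import (
    EPS0,
    DielectricMaterial,
    ShelledCell,
    clausius_mossotti,
    find_crossovers,
    find_crossovers_batch,
    fx01_approx,
    fx02_approx,
    invert_fx01_to_membrane_capacitance,
    invert_fx02_to_sigma_int,
)


def dense_grid_oracle(cell, medium, f_min=1e4, f_max=1e9, n=200_000):
    """Independent root locator: dense log grid + linear interpolation of
    each sign change of Re[f_CM]."""
    f = np.logspace(np.log10(f_min), np.log10(f_max), n)
    re = np.array([clausius_mossotti(cell, medium, ff).real for ff in f]) \
        if n <= 2000 else clausius_mossotti(cell, medium, f).real
    sgn = np.sign(re)
    idx = np.where(sgn[:-1] * sgn[1:] < 0)[0]
    roots = []
    for i in idx:
        x0, x1, y0, y1 = f[i], f[i + 1], re[i], re[i + 1]
        roots.append(x0 + (x1 - x0) * (-y0) / (y1 - y0))
    step = f[1:] / f[:-1]
    return roots, float(step.max())


class TestFindCrossovers:
    def test_reference_cell_band_positions(self, reference_cell, reference_medium):
        res = find_crossovers(reference_cell, reference_medium)
        assert res.n_sign_changes == 2
        assert res.fx01 is not None and res.fx01 < 400e3
        assert res.fx02 is not None and 100e6 <= res.fx02 <= 150e6
        assert res.fx01 < res.fx02

    def test_roots_are_actual_zeros(self, reference_cell, reference_medium):
        res = find_crossovers(reference_cell, reference_medium)
        for root in (res.fx01, res.fx02):
            assert abs(clausius_mossotti(reference_cell, reference_medium, root).real) < 1e-4

    def test_matches_dense_grid_oracle(self, reference_cell, reference_medium):
        res = find_crossovers(reference_cell, reference_medium)
        roots, max_ratio = dense_grid_oracle(reference_cell, reference_medium)
        assert len(roots) == 2
        for found, expect in zip((res.fx01, res.fx02), roots):
            assert abs(found / expect - 1.0) < (max_ratio - 1.0)

    def test_matched_phases_report_no_crossing(self):
        mat = DielectricMaterial(78.0, 0.02)
        cell = ShelledCell(1e-5, 1e-6, mat, mat)
        res = find_crossovers(cell, mat)
        assert res.fx01 is None and res.fx02 is None
        assert res.n_sign_changes == 0

    def test_single_rising_crossing_is_fx01(self):
        # eps_p > eps_m, sigma_p < sigma_m: nDEP at low f, pDEP at high f
        mat = DielectricMaterial(120.0, 0.005)
        cell = ShelledCell(1e-5, 1e-6, mat, mat)
        medium = DielectricMaterial(78.0, 0.026)
        res = find_crossovers(cell, medium)
        assert res.n_sign_changes == 1
        assert res.fx01 is not None and res.fx02 is None

    def test_single_falling_crossing_is_fx02(self):
        # sigma_p > sigma_m, eps_p < eps_m: pDEP at low f, nDEP at high f
        mat = DielectricMaterial(40.0, 0.2)
        cell = ShelledCell(1e-5, 1e-6, mat, mat)
        medium = DielectricMaterial(78.0, 0.026)
        res = find_crossovers(cell, medium)
        assert res.n_sign_changes == 1
        assert res.fx02 is not None and res.fx01 is None

    def test_invalid_range_rejected(self, reference_cell, reference_medium):
        with pytest.raises(ValueError):
            find_crossovers(reference_cell, reference_medium, 1e9, 1e4)

    def test_randomized_cells_match_oracle(self):
        rng = np.random.default_rng(42)
        medium = DielectricMaterial(78.0, 0.026)
        for _ in range(30):
            cell = ShelledCell(
                radius=rng.uniform(3e-6, 15e-6),
                membrane_thickness=rng.uniform(4e-9, 10e-9),
                membrane=DielectricMaterial(rng.uniform(2, 20), 10 ** rng.uniform(-7, -4)),
                interior=DielectricMaterial(rng.uniform(30, 70), 10 ** rng.uniform(-1.5, 0.3)),
            )
            res = find_crossovers(cell, medium)
            roots, max_ratio = dense_grid_oracle(cell, medium, n=50_000)
            assert res.n_sign_changes == len(roots)
            found = [x for x in (res.fx01, res.fx02) if x is not None]
            for got, expect in zip(found, roots):
                assert abs(got / expect - 1.0) < (max_ratio - 1.0)

    def test_batch_agrees_with_scalar(self, reference_medium):
        rng = np.random.default_rng(7)
        n = 20
        r = rng.uniform(5e-6, 15e-6, n)
        th = np.full(n, 7e-9)
        ecm = rng.uniform(2, 10, n)
        scm = np.full(n, 1.43e-6)
        ei = np.full(n, 50.0)
        si = rng.uniform(0.2, 1.0, n)
        fx01, fx02, nsc = find_crossovers_batch(
            r, th, ecm, scm, ei, si, medium=reference_medium
        )
        for i in range(n):
            cell = ShelledCell(r[i], th[i], DielectricMaterial(ecm[i], scm[i]),
                               DielectricMaterial(ei[i], si[i]))
            res = find_crossovers(cell, reference_medium)
            assert nsc[i] == res.n_sign_changes
            if res.fx01 is not None:
                assert fx01[i] == pytest.approx(res.fx01, rel=1e-9)
            if res.fx02 is not None:
                assert fx02[i] == pytest.approx(res.fx02, rel=1e-9)


class TestClosedForms:
    def test_fx01_approx_reference_value(self, reference_cell, reference_medium):
        # 0.02 * 7e-7 / (2 pi * 1.15e-5 * 100 eps0) = 2.188e5 Hz
        assert fx01_approx(reference_cell, reference_medium) == pytest.approx(2.19e5, rel=2e-3)

    def test_fx01_approx_scalings(self, reference_cell, reference_medium):
        base = fx01_approx(reference_cell, reference_medium)
        double_sigma = DielectricMaterial(78.0, 0.04)
        assert fx01_approx(reference_cell, double_sigma) == pytest.approx(2 * base)
        bigger = ShelledCell(
            2 * reference_cell.radius, reference_cell.membrane_thickness,
            reference_cell.membrane, reference_cell.interior,
        )
        assert fx01_approx(bigger, reference_medium) == pytest.approx(base / 2)

    def test_fx02_approx_reference_value(self, reference_cell, reference_medium):
        # radicand (2*78^2 - 50*78 - 50^2) eps0^2 = 5768 eps0^2 -> 118 MHz
        got = fx02_approx(reference_cell.interior, reference_medium)
        assert got == pytest.approx(1.18e8, abs=0.5e6)  # 3 significant figures

    def test_fx02_approx_linear_in_sigma_int(self, reference_medium):
        a = fx02_approx(DielectricMaterial(50.0, 0.5), reference_medium)
        b = fx02_approx(DielectricMaterial(50.0, 0.25), reference_medium)
        assert b == pytest.approx(a / 2)

    def test_fx02_approx_ignores_medium_conductivity(self):
        lo = DielectricMaterial(78.0, 0.001)
        hi = DielectricMaterial(78.0, 0.1)
        interior = DielectricMaterial(50.0, 0.5)
        assert fx02_approx(interior, lo) == fx02_approx(interior, hi)

    def test_fx02_approx_invalid_regime(self):
        with pytest.raises(ValueError):
            fx02_approx(DielectricMaterial(100.0, 0.5), DielectricMaterial(78.0, 0.02))

    def test_fx01_approx_within_factor_two_of_full_model(
        self, reference_cell, reference_medium
    ):
        full = find_crossovers(reference_cell, reference_medium).fx01
        approx = fx01_approx(reference_cell, reference_medium)
        assert 0.5 < full / approx < 2.0

    def test_fx02_approx_within_25pct_of_full_model(self, reference_cell, reference_medium):
        # medium sigma (0.02) is well below sigma_int (0.5)
        full = find_crossovers(reference_cell, reference_medium).fx02
        approx = fx02_approx(reference_cell.interior, reference_medium)
        assert abs(full / approx - 1.0) < 0.25

    def test_full_model_fx02_monotone_in_sigma_int(self, reference_cell, reference_medium):
        prev = 0.0
        for sig in np.linspace(0.1, 1.0, 7):
            cell = ShelledCell(
                reference_cell.radius, reference_cell.membrane_thickness,
                reference_cell.membrane, DielectricMaterial(50.0, float(sig)),
            )
            fx02 = find_crossovers(cell, reference_medium).fx02
            assert fx02 is not None and fx02 > prev
            prev = fx02


class TestInversions:
    def test_sigma_int_roundtrip(self, reference_medium):
        fx = fx02_approx(DielectricMaterial(50.0, 0.5), reference_medium)
        back = invert_fx02_to_sigma_int(fx, 50.0, reference_medium)
        assert back == pytest.approx(0.5, rel=1e-12)

    @pytest.mark.parametrize(
        "fx02_hz,expected", [(88e6, 0.372), (109e6, 0.461)]
    )
    def test_sigma_int_from_measured_fx02(self, fx02_hz, expected, reference_medium):
        got = invert_fx02_to_sigma_int(fx02_hz, 50.0, reference_medium)
        assert got == pytest.approx(expected, rel=2e-3)

    def test_membrane_capacitance_roundtrip(self, reference_cell, reference_medium):
        fx = fx01_approx(reference_cell, reference_medium)
        c = invert_fx01_to_membrane_capacitance(fx, reference_cell.radius, reference_medium)
        assert c == pytest.approx(reference_cell.specific_membrane_capacitance, rel=1e-12)
        assert c == pytest.approx(100 * EPS0 / 700e-9, rel=1e-12)

    def test_membrane_capacitance_from_measured_fx01(self, dep_medium):
        # C = 0.026 / (2 pi * 1.15e-5 * 8.2e4) = 4.39e-3 F/m^2
        c = invert_fx01_to_membrane_capacitance(82e3, 11.5e-6, dep_medium)
        assert c == pytest.approx(4.388e-3, rel=2e-3)

    def test_membrane_capacitance_reciprocal_in_fx01(self, dep_medium):
        c1 = invert_fx01_to_membrane_capacitance(82e3, 11.5e-6, dep_medium)
        c2 = invert_fx01_to_membrane_capacitance(164e3, 11.5e-6, dep_medium)
        assert c2 == pytest.approx(c1 / 2)

    def test_zero_inputs_rejected(self, dep_medium):
        with pytest.raises(ValueError):
            invert_fx01_to_membrane_capacitance(0.0, 11.5e-6, dep_medium)
        with pytest.raises(ValueError):
            invert_fx02_to_sigma_int(-1.0, 50.0, dep_medium)
        with pytest.raises(ValueError):
            invert_fx02_to_sigma_int(88e6, 100.0, DielectricMaterial(78.0, 0.02))
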