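"""Coupled-dipole optics: lattice geometry, solver oracles, Mie limits."""

import numpy as np
import pytest
from scipy.optimize import brentq

from gnptherm import dda
from gnptherm.dda import (
    DipoleLattice,
    IncidentField,
    assign_polarizability,
    build_rod_lattice,
    build_sphere_lattice,
    compute_efficiencies,
    cross_sections,
    efficiencies,
    gold_refractive_index,
    mie_oracle,
    solve_dipole_system,
)


class TestLattices:
    def test_rod_volume_matches_equal_volume_sphere(self):
        lat = build_rod_lattice(20.0, 6.67, 1.0)
        target = 4.0 / 3.0 * np.pi * 20.0**3
        assert lat.lattice_volume == pytest.approx(target, rel=0.05)

    def test_rod_cylinder_radius_solves_volume_equation(self):
        # independent oracle: solve pi a^2 (2 a AR) = (4/3) pi r^3 numerically
        r_eff, ar = 20.0, 6.67
        vol = 4.0 / 3.0 * np.pi * r_eff**3
        a = brentq(lambda a: 2.0 * np.pi * a**3 * ar - vol, 1.0, r_eff)
        lat = build_rod_lattice(r_eff, ar, 1.5)
        assert lat.cylinder_radius == pytest.approx(a, rel=1e-9)
        assert a == pytest.approx(9.28, abs=0.01)

    def test_aspect_ratio_one_rod_matches_sphere_volume(self):
        rod = build_rod_lattice(10.0, 1.0, 0.5)
        sph = build_sphere_lattice(10.0, 0.5)
        assert rod.lattice_volume == pytest.approx(sph.lattice_volume, rel=0.05)

    def test_too_coarse_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing|dipoles"):
            build_rod_lattice(20.0, 6.67, 15.0)

    @pytest.mark.parametrize("bad", [dict(spacing=-1.0), dict(aspect_ratio=0.5)])
    def test_invalid_parameters_rejected(self, bad):
        kw = dict(r_eff=20.0, aspect_ratio=6.67, spacing=2.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            build_rod_lattice(**kw)


class TestPolarizability:
    def test_vacuum_contrast_gives_zero_optics(self):
        lat = build_sphere_lattice(5.0, 1.0)
        eff = compute_efficiencies(lat, 1.0 + 0j, 532.0)
        assert eff.q_abs == pytest.approx(0.0, abs=1e-12)
        assert eff.q_sca == pytest.approx(0.0, abs=1e-12)

    def test_cm_sum_matches_bulk_clausius_mossotti(self):
        m = 1.5 + 0.2j
        lat = build_sphere_lattice(6.0, 0.5)
        alphas = assign_polarizability(lat, m, 1064.0, prescription="cm")
        bulk = lat.lattice_volume * 3.0 / (4 * np.pi) * (m**2 - 1) / (m**2 + 2)
        assert np.sum(alphas) == pytest.approx(bulk, rel=0.01)

    def test_gold_polarizability_is_absorptive(self):
        m = gold_refractive_index(1064.0)
        assert m.imag > 0
        lat = build_sphere_lattice(5.0, 1.0)
        alphas = assign_polarizability(lat, m, 1064.0)
        # positive absorptive part: -Im(1/alpha) - (2/3) k^3 > 0
        k = 2 * np.pi / 1064.0
        assert -np.imag(1.0 / alphas[0]) - (2.0 / 3.0) * k**3 > 0

    def test_wrong_sign_convention_rejected(self):
        lat = build_sphere_lattice(5.0, 1.0)
        with pytest.raises(ValueError, match="imaginary"):
            assign_polarizability(lat, 0.3 - 6.0j, 1064.0)


def _manual_lattice(positions, spacing=1.0):
    return DipoleLattice(
        positions=np.asarray(positions, dtype=float),
        spacing=spacing,
        shape="points",
        r_eff=1.0,
    )


class TestSolver:
    def test_single_dipole_is_exact(self):
        lat = _manual_lattice([[0.0, 0.0, 0.0]])
        inc = IncidentField(wavelength=1064.0)
        alpha = np.array([2.0 + 0.5j])
        sol = solve_dipole_system(lat, alpha, inc)
        np.testing.assert_allclose(
            sol.polarizations[0], alpha[0] * inc.field_at(lat.positions)[0],
            rtol=1e-12,
        )

    def test_two_dipoles_match_hand_coded_6x6_solve(self):
        # brute-force oracle: assemble the 6x6 system from the tensor formula
        pos = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        lam, alpha_val = 700.0, 1.5 + 0.3j
        k = 2 * np.pi / lam
        inc = IncidentField(wavelength=lam)  # pol x, prop z

        rvec = pos[1] - pos[0]
        r = np.linalg.norm(rvec)
        rr = np.outer(rvec, rvec)
        A12 = (np.exp(1j * k * r) / r**3) * (
            k**2 * (rr - r**2 * np.eye(3))
            + (1 - 1j * k * r) / r**2 * (r**2 * np.eye(3) - 3 * rr)
        )
        M = np.zeros((6, 6), dtype=complex)
        M[:3, :3] = np.eye(3) / alpha_val
        M[3:, 3:] = np.eye(3) / alpha_val
        M[:3, 3:] = A12
        M[3:, :3] = A12  # symmetric in +/- rvec for this tensor
        b = inc.field_at(pos).ravel()
        expected = np.linalg.solve(M, b).reshape(2, 3)

        lat = _manual_lattice(pos)
        sol = solve_dipole_system(lat, np.full(2, alpha_val), inc)
        np.testing.assert_allclose(sol.polarizations, expected, rtol=1e-10)

    def test_converged_residual_below_tolerance(self):
        lat = build_sphere_lattice(8.0, 1.0)
        m = gold_refractive_index(532.0)
        eff_tol = 1e-6
        alphas = assign_polarizability(lat, m, 532.0)
        sol = solve_dipole_system(lat, alphas, IncidentField(wavelength=532.0),
                                  tolerance=eff_tol)
        assert sol.residual <= eff_tol

    def test_fft_and_dense_paths_agree(self):
        lat = build_sphere_lattice(6.0, 1.0)
        m = gold_refractive_index(650.0)
        e1 = compute_efficiencies(lat, m, 650.0, method="dense")
        e2 = compute_efficiencies(lat, m, 650.0, method="fft", tolerance=1e-8)
        assert e2.q_ext == pytest.approx(e1.q_ext, rel=1e-5)
        assert e2.q_abs == pytest.approx(e1.q_abs, rel=1e-5)

    def test_rotation_invariance(self):
        lat = build_sphere_lattice(4.0, 1.0)
        m = 1.8 + 0.4j
        lam = 600.0
        base = compute_efficiencies(lat, m, lam, method="dense")
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0.0],
             [np.sin(theta), np.cos(theta), 0.0],
             [0.0, 0.0, 1.0]]
        )
        rot = lat.rotated(R)
        rot_eff = compute_efficiencies(
            rot, m, lam,
            polarization=R @ np.array([1.0, 0.0, 0.0]),
            direction=R @ np.array([0.0, 0.0, 1.0]),
            method="dense",
        )
        assert rot_eff.q_ext == pytest.approx(base.q_ext, rel=1e-9)
        assert rot_eff.q_abs == pytest.approx(base.q_abs, rel=1e-9)


class TestCrossSections:
    def test_lossless_sphere_has_no_absorption(self):
        lat = build_sphere_lattice(20.0, 2.0)
        eff = compute_efficiencies(lat, 1.5 + 0j, 532.0)
        assert eff.q_abs == pytest.approx(0.0, abs=1e-10)
        assert eff.q_ext == pytest.approx(eff.q_sca, rel=1e-9)

    def test_extinction_is_absorption_plus_scattering(self):
        lat = build_sphere_lattice(10.0, 1.5)
        m = gold_refractive_index(532.0)
        eff = compute_efficiencies(lat, m, 532.0)
        assert eff.q_ext == pytest.approx(eff.q_abs + eff.q_sca, rel=1e-9)

    def test_efficiency_normalisation(self):
        r = 7.0
        eff = efficiencies(np.pi * r**2, 3 * np.pi * r**2, 2 * np.pi * r**2, r)
        assert eff.q_abs == pytest.approx(1.0)
        assert eff.q_ext == pytest.approx(3.0)
        with pytest.raises(ValueError):
            efficiencies(1.0, 1.0, 0.0, -1.0)


class TestMieOracle:
    def test_no_contrast_gives_zero(self):
        eff = mie_oracle(50.0, 1.0 + 0j, 532.0)
        assert abs(eff.q_ext) < 1e-12
        assert abs(eff.q_sca) < 1e-12

    def test_rayleigh_scattering_limit(self):
        m = 1.5 + 0j
        r, lam = 2.0, 1064.0
        x = 2 * np.pi * r / lam
        expected = (8.0 / 3.0) * x**4 * abs((m**2 - 1) / (m**2 + 2)) ** 2
        eff = mie_oracle(r, m, lam)
        assert eff.q_sca == pytest.approx(expected, rel=2e-3)

    def test_rayleigh_absorption_limit_for_gold(self):
        m = gold_refractive_index(532.0)
        r, lam = 4.0, 532.0
        x = 2 * np.pi * r / lam
        expected = 4 * x * np.imag((m**2 - 1) / (m**2 + 2))
        eff = mie_oracle(r, m, lam)
        assert eff.q_abs == pytest.approx(expected, rel=0.01)

    def test_size_parameter_guard(self):
        with pytest.raises(ValueError, match="size parameter"):
            mie_oracle(1e5, 1.5 + 0j, 532.0)


class TestGoldIndex:
    def test_interpolation_monotone_infrared_k(self):
        # extinction coefficient k grows toward the infrared
        k_values = [gold_refractive_index(w).imag for w in (600, 800, 1064, 1300)]
        assert np.all(np.diff(k_values) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gold_refractive_index(250.0)
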