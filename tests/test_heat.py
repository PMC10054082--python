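"""Heat solver: stability bound, conservation, analytic conduction oracles."""

import numpy as np
import pytest
from scipy.special import erfc

from gnptherm.heat import (
    BoundarySpec,
    ThermalStepConfig,
    run_simulation,
    stability_limit,
    step_temperature,
)
from gnptherm.tissue import build_mouse_domain
from conftest import make_uniform_grid


class TestStabilityLimit:
    def test_homogeneous_closed_form(self):
        grid = make_uniform_grid(shape=(6, 6, 6), spacing=0.5, k=0.4, rho=1100, cv=3200)
        d = 0.5e-3
        assert stability_limit(grid) == pytest.approx(1100 * 3200 * d**2 / (12 * 0.4))

    def test_mouse_parameters_plug_in(self):
        grid = make_uniform_grid(shape=(4, 4, 4), spacing=0.5, k=0.34, rho=1000, cv=3000)
        assert stability_limit(grid) == pytest.approx(0.18382, rel=1e-3)

    def test_halving_spacing_quarters_the_limit(self):
        a = make_uniform_grid(shape=(4, 4, 4), spacing=1.0)
        b = make_uniform_grid(shape=(4, 4, 4), spacing=0.5)
        assert stability_limit(a) == pytest.approx(4 * stability_limit(b))


class TestStepping:
    def test_equilibrium_is_preserved(self):
        grid = make_uniform_grid(shape=(5, 5, 5))
        T = np.full(grid.shape, 37.0)
        Tn = step_temperature(T, grid, np.zeros(grid.shape), 0.01,
                              BoundarySpec(top=("dirichlet", 37.0)))
        np.testing.assert_allclose(Tn, T, atol=1e-12)

    def test_uniform_conductivity_reduces_to_laplacian(self):
        rng = np.random.default_rng(0)
        grid = make_uniform_grid(shape=(6, 6, 6), spacing=1.0, k=0.5, rho=1000, cv=1000)
        T = 37.0 + rng.random(grid.shape)
        dt = 0.05
        Tn = step_temperature(T, grid, np.zeros(grid.shape), dt, BoundarySpec.insulated())
        d = 1e-3
        lap = np.zeros_like(T)
        for axis in range(3):
            upper = np.roll(T, -1, axis)
            lower = np.roll(T, 1, axis)
            # insulated: mirror at the ends
            sl_hi = [slice(None)] * 3
            sl_hi[axis] = -1
            upper[tuple(sl_hi)] = T[tuple(sl_hi)]
            sl_lo = [slice(None)] * 3
            sl_lo[axis] = 0
            lower[tuple(sl_lo)] = T[tuple(sl_lo)]
            lap += upper + lower - 2 * T
        expected = T + dt * 0.5 * lap / (1000 * 1000 * d**2)
        np.testing.assert_allclose(Tn, expected, rtol=1e-12)

    def test_unstable_step_rejected(self):
        grid = make_uniform_grid(shape=(4, 4, 4))
        T = np.full(grid.shape, 37.0)
        with pytest.raises(ValueError, match="stability"):
            step_temperature(T, grid, np.zeros(grid.shape), 1e3)


class TestConservationAndBounds:
    def test_energy_conserved_insulated_sourceless(self):
        rng = np.random.default_rng(1)
        grid = make_uniform_grid(shape=(7, 7, 7), spacing=0.5)
        # heterogeneous properties: conservation must hold in the flux form
        grid.k[:] = 0.2 + 0.6 * rng.random(grid.shape)
        grid.rho[:] = 900 + 300 * rng.random(grid.shape)
        grid.cv[:] = 2500 + 1500 * rng.random(grid.shape)
        T = 37.0 + 5.0 * rng.random(grid.shape)
        rhocv = grid.rho * grid.cv
        e0 = float((rhocv * T).sum())
        dt = stability_limit(grid)
        bc = BoundarySpec.insulated()
        for _ in range(100):
            T = step_temperature(T, grid, np.zeros(grid.shape), dt, bc)
        e1 = float((rhocv * T).sum())
        assert abs(e1 - e0) / abs(e0) < 1e-10

    def test_maximum_principle_no_new_extrema(self):
        rng = np.random.default_rng(2)
        grid = make_uniform_grid(shape=(6, 6, 6))
        T = 37.0 + 10.0 * rng.random(grid.shape)
        lo, hi = T.min(), T.max()
        dt = stability_limit(grid)
        for _ in range(50):
            T = step_temperature(T, grid, np.zeros(grid.shape), dt, BoundarySpec.insulated())
        assert T.min() >= lo - 1e-12 and T.max() <= hi + 1e-12

    def test_uniform_source_insulated_exact_rise(self):
        grid = make_uniform_grid(shape=(5, 5, 5), rho=1000, cv=4000)
        q = np.full(grid.shape, 5e5)  # W/m^3
        T = np.full(grid.shape, 37.0)
        dt = 0.02
        steps = 50
        bc = BoundarySpec.insulated()
        for _ in range(steps):
            T = step_temperature(T, grid, q, dt, bc)
        expected = 37.0 + 5e5 * dt * steps / (1000 * 4000)
        np.testing.assert_allclose(T, expected, rtol=1e-12)


class TestAnalyticConduction:
    def test_two_slab_steady_state_series_resistance(self):
        k1, k2 = 0.2, 0.8
        nz = 24
        d = 0.5
        grid = make_uniform_grid(shape=(3, 3, nz), spacing=d, rho=1000, cv=1000)
        grid.k[:, :, : nz // 2] = k1
        grid.k[:, :, nz // 2 :] = k2
        t_top, t_bot = 100.0, 0.0
        bc = BoundarySpec(
            top=("dirichlet", t_top), bottom=("dirichlet", t_bot),
            sides=("insulated",),
        )
        T = np.full(grid.shape, 50.0)
        dt = stability_limit(grid)
        for _ in range(6000):
            T = step_temperature(T, grid, np.zeros(grid.shape), dt, bc)
        profile = T[1, 1, :]
        # analytic: the Dirichlet values act at ghost centres one spacing
        # outside the outermost voxel centres, i.e. d/2 beyond each wall
        d_m = d * 1e-3
        L_half = (nz // 2) * d_m
        R1 = (L_half + d_m / 2) / k1
        R2 = (L_half + d_m / 2) / k2
        flux = (t_top - t_bot) / (R1 + R2)
        z = (np.arange(nz) + 0.5) * d_m
        expected = np.where(
            z < L_half,
            t_top - flux * (z + d_m / 2) / k1,
            t_top - flux * R1 - flux * (z - L_half) / k2,
        )
        assert np.max(np.abs(profile - expected) / (t_top - t_bot)) < 0.005

    def test_semi_infinite_constant_flux_erfc_solution(self):
        # constant surface flux modelled as a source in the first voxel layer
        k, rho, cv = 0.5, 1000.0, 3600.0
        d = 0.5
        nz = 60
        grid = make_uniform_grid(shape=(3, 3, nz), spacing=d, k=k, rho=rho, cv=cv)
        q0 = 5000.0  # W/m^2 surface flux
        d_m = d * 1e-3
        q = np.zeros(grid.shape)
        q[:, :, 0] = q0 / d_m
        bc = BoundarySpec(top=("insulated",), bottom=("dirichlet", 37.0),
                          sides=("insulated",))
        T = np.full(grid.shape, 37.0)
        dt = stability_limit(grid)
        t_end = 30.0
        steps = int(round(t_end / dt))
        dt = t_end / steps
        for _ in range(steps):
            T = step_temperature(T, grid, q, dt, bc)
        alpha = k / (rho * cv)
        s = np.sqrt(alpha * t_end)

        def analytic(z):
            x = z / (2 * s)
            ierfc = np.exp(-(x**2)) / np.sqrt(np.pi) - x * erfc(x)
            return 37.0 + 2 * q0 * s / k * ierfc

        for iz in [4, 6, 8, 10]:
            z = (iz + 0.5) * d_m
            rise = T[1, 1, iz] - 37.0
            expected = analytic(z) - 37.0
            assert rise == pytest.approx(expected, rel=0.02)


class TestRunSimulation:
    def test_power_linearity_of_temperature_rise(self):
        grid = build_mouse_domain(spacing=1.0)
        F = np.zeros(grid.shape)
        F[28:32, 28:32, :3] = 2.0  # synthetic fluence, 1/mm^2 per W
        cfg = ThermalStepConfig(duration=20.0, record_interval=10.0,
                                boundary=BoundarySpec.insulated())
        base = run_simulation(grid, F, 0.0, cfg, record_full=True)
        one = run_simulation(grid, F, 0.1, cfg, record_full=True)
        two = run_simulation(grid, F, 0.2, cfg, record_full=True)
        np.testing.assert_allclose(
            two.frames - base.frames, 2 * (one.frames - base.frames), rtol=1e-9, atol=1e-11
        )

    def test_frames_recorded_on_schedule(self):
        grid = make_uniform_grid(shape=(5, 5, 5))
        cfg = ThermalStepConfig(duration=30.0, record_interval=10.0)
        s = run_simulation(grid, np.zeros(grid.shape), 0.0, cfg)
        np.testing.assert_allclose(s.times, [10.0, 20.0, 30.0])
        assert s.frames.shape == (3, 5, 5, 5)

    def test_mismatched_interval_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            ThermalStepConfig(duration=25.0, record_interval=10.0)

    def test_masked_recording_matches_full(self):
        grid = make_uniform_grid(shape=(6, 6, 6), mu_abs=0.5)
        F = np.full(grid.shape, 1.0)
        mask = np.zeros(grid.shape, dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        cfg = ThermalStepConfig(duration=20.0, record_interval=10.0)
        s = run_simulation(grid, F, 0.05, cfg, record_full=True,
                           record_masks={"m": mask})
        np.testing.assert_array_equal(
            s.masked["m"], s.frames.reshape(2, -1)[:, mask.ravel()]
        )
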