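"""Explicit finite-difference heat diffusion with heterogeneous conductivity.

Forward-Euler update of the thermal diffusion equation on the voxel grid:

    dT_v = (dt / (rho_v c_v)) * [ q_v + sum_faces (T_nb - T_v) * k_face / d^2 ]

where ``k_face = 2 k_v k_nb / (k_v + k_nb)`` is the harmonic-mean interface
conductance (the symmetric, energy-conserving reading of the face terms) and
``q_v = mu_a * F * P_l`` is the volumetric laser heat source from the Monte
Carlo fluence map.  Properties are temperature independent; blood perfusion
and metabolic heat are deliberately absent from the model.

Default boundary conditions (the source never states any): lateral and bottom
faces and the inert voxels outside the tissue cylinder are a 37 degC
deep-tissue Dirichlet sink; the irradiated top surface is convective with
h = 10 W/m^2 K to a 25 degC ambient.  All faces are configurable, including
fully insulated (used by the conservation tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from numba import njit

__all__ = [
    "BoundarySpec",
    "ThermalStepConfig",
    "TemperatureSeries",
    "stability_limit",
    "step_temperature",
    "run_simulation",
    "mouse_validation_run",
]

BODY_TEMP_C = 37.0

_BC_INSULATED = 0
_BC_DIRICHLET = 1
_BC_CONVECTIVE = 2


@dataclass(frozen=True)
class BoundarySpec:
    """Per-face boundary conditions; faces are x-, x+, y-, y+, z- (top), z+.

    Each face is ``("insulated",)``, ``("dirichlet", T)`` or
    ``("convective", h, T_ambient)`` with h in W/m^2 K.
    """

    top: tuple = ("convective", 10.0, 25.0)
    bottom: tuple = ("dirichlet", BODY_TEMP_C)
    sides: tuple = ("dirichlet", BODY_TEMP_C)
    sink_temp: float = BODY_TEMP_C   # inert voxels are pinned here

    @classmethod
    def insulated(cls) -> "BoundarySpec":
        """All outer faces insulated; inert voxels (if any) stay pinned."""
        return cls(top=("insulated",), bottom=("insulated",), sides=("insulated",))

    def _encode(self):
        kinds = np.zeros(6, dtype=np.int64)
        vals = np.zeros(6)
        hs = np.zeros(6)
        spec = [self.sides, self.sides, self.sides, self.sides, self.top, self.bottom]
        for i, s in enumerate(spec):
            if s[0] == "insulated":
                kinds[i] = _BC_INSULATED
            elif s[0] == "dirichlet":
                kinds[i] = _BC_DIRICHLET
                vals[i] = s[1]
            elif s[0] == "convective":
                kinds[i] = _BC_CONVECTIVE
                hs[i] = s[1]
                vals[i] = s[2]
            else:
                raise ValueError(f"unknown boundary condition {s!r}")
        return kinds, vals, hs


@dataclass
class ThermalStepConfig:
    """Time stepping for the treatment simulation."""

    duration: float = 600.0           # s of continuous irradiation
    record_interval: float = 10.0     # s between stored frames
    dt: Optional[float] = None        # s; defaults to the stability limit
    safety: float = 1.0               # fraction of the stability limit used
    boundary: BoundarySpec = field(default_factory=BoundarySpec)

    def __post_init__(self):
        n = self.duration / self.record_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be a multiple of the recording interval")


@dataclass
class TemperatureSeries:
    """Recorded temperature frames (degC) over the simulation."""

    times: np.ndarray                           # (n_frames,) s
    frames: Optional[np.ndarray]                # (n_frames, nx, ny, nz) or None
    masked: Dict[str, np.ndarray]               # name -> (n_frames, n_mask)
    max_temperature: float
    max_index: tuple
    max_time: float
    dt: float


@njit(cache=True)
def _harm(a, b):
    return 2.0 * a * b / (a + b)


@njit(cache=True)
def _step(T, Tn, k, rhocv, q, inert, d, dt, bc_kind, bc_val, bc_h, sink):
    nx, ny, nz = T.shape
    inv_d2 = 1.0 / (d * d)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if inert[ix, iy, iz]:
                    Tn[ix, iy, iz] = sink
                    continue
                t0 = T[ix, iy, iz]
                kc = k[ix, iy, iz]
                acc = q[ix, iy, iz]
                for f in range(6):
                    if f == 0:
                        jx, jy, jz = ix - 1, iy, iz
                    elif f == 1:
                        jx, jy, jz = ix + 1, iy, iz
                    elif f == 2:
                        jx, jy, jz = ix, iy - 1, iz
                    elif f == 3:
                        jx, jy, jz = ix, iy + 1, iz
                    elif f == 4:
                        jx, jy, jz = ix, iy, iz - 1
                    else:
                        jx, jy, jz = ix, iy, iz + 1
                    if 0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz:
                        if inert[jx, jy, jz]:
                            acc += (sink - t0) * kc * inv_d2
                        else:
                            acc += (T[jx, jy, jz] - t0) * _harm(kc, k[jx, jy, jz]) * inv_d2
                    else:
                        kind = bc_kind[f]
                        if kind == _BC_DIRICHLET:
                            acc += (bc_val[f] - t0) * kc * inv_d2
                        elif kind == _BC_CONVECTIVE:
                            acc += bc_h[f] * (bc_val[f] - t0) / d
                        # insulated: no flux
                Tn[ix, iy, iz] = t0 + dt * acc / rhocv[ix, iy, iz]


@njit(cache=True)
def _stability(k, rhocv, inert, d):
    nx, ny, nz = k.shape
    best = 1e300
    inv_d2 = 1.0 / (d * d)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if inert[ix, iy, iz]:
                    continue
                kc = k[ix, iy, iz]
                s = 0.0
                for f in range(6):
                    if f == 0:
                        jx, jy, jz = ix - 1, iy, iz
                    elif f == 1:
                        jx, jy, jz = ix + 1, iy, iz
                    elif f == 2:
                        jx, jy, jz = ix, iy - 1, iz
                    elif f == 3:
                        jx, jy, jz = ix, iy + 1, iz
                    elif f == 4:
                        jx, jy, jz = ix, iy, iz - 1
                    else:
                        jx, jy, jz = ix, iy, iz + 1
                    if 0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz and not inert[jx, jy, jz]:
                        s += 2.0 * _harm(kc, k[jx, jy, jz]) * inv_d2
                    else:
                        s += 2.0 * kc * inv_d2
                dt = rhocv[ix, iy, iz] / s
                if dt < best:
                    best = dt
    return best


def stability_limit(grid) -> float:
    """Largest non-oscillatory explicit time step (s).

    ``dt_max = min_v rho c / sum_faces 2 k_face / d^2``; for a homogeneous
    medium on a cubic grid this is ``rho c d^2 / (12 k)``.
    """
    d_m = grid.spacing * 1e-3
    return float(
        _stability(grid.k, grid.rho * grid.cv, grid.inert_mask, d_m)
    )


def _source_w_m3(grid, fluence, power_w: float) -> np.ndarray:
    # mu_a (1/mm) * F (1/mm^2) * P (W) = W/mm^3 -> W/m^3
    return grid.mu_abs * fluence * power_w * 1e9


def step_temperature(
    T: np.ndarray,
    grid,
    source_w_m3: np.ndarray,
    dt: float,
    boundary: Optional[BoundarySpec] = None,
) -> np.ndarray:
    """Advance the temperature field by one explicit step (out of place)."""
    boundary = boundary or BoundarySpec()
    limit = stability_limit(grid)
    if dt > limit * (1 + 1e-9):
        raise ValueError(f"dt {dt} s exceeds the stability limit {limit:.4g} s")
    kinds, vals, hs = boundary._encode()
    Tn = np.empty_like(T)
    _step(
        T, Tn, grid.k, grid.rho * grid.cv, source_w_m3,
        grid.inert_mask, grid.spacing * 1e-3, dt,
        kinds, vals, hs, boundary.sink_temp,
    )
    if not np.isfinite(Tn).all():
        bad = np.unravel_index(np.argmax(~np.isfinite(Tn)), Tn.shape)
        raise FloatingPointError(f"non-finite temperature at voxel {bad}")
    return Tn


def run_simulation(
    grid,
    fluence,
    power_w: float,
    config: Optional[ThermalStepConfig] = None,
    initial_temp: float = BODY_TEMP_C,
    record_full: bool = True,
    record_masks: Optional[Dict[str, np.ndarray]] = None,
) -> TemperatureSeries:
    """Run the irradiation simulation and record temperature frames.

    ``fluence`` may be a FluenceMap or a bare per-unit-power array; the source
    is constant in time (continuous irradiation).  Frames are recorded at the
    end of every recording interval (the initial uniform state is not
    stored).  ``record_masks`` maps names to boolean voxel masks recorded as
    compact (n_frames, n_mask) arrays.
    """
    config = config or ThermalStepConfig()
    F = fluence.fluence if hasattr(fluence, "fluence") else np.asarray(fluence)
    if F.shape != grid.shape:
        raise ValueError("fluence and grid shapes differ")
    q = _source_w_m3(grid, F, power_w)
    limit = stability_limit(grid)
    dt = config.dt if config.dt is not None else limit * config.safety
    if dt > limit * (1 + 1e-9):
        raise ValueError(f"dt {dt} s exceeds the stability limit {limit:.4g} s")
    steps_per_frame = int(np.ceil(config.record_interval / dt))
    dt = config.record_interval / steps_per_frame
    n_frames = int(round(config.duration / config.record_interval))

    kinds, vals, hs = config.boundary._encode()
    sink = config.boundary.sink_temp
    d_m = grid.spacing * 1e-3
    rhocv = grid.rho * grid.cv
    inert = grid.inert_mask
    T = np.full(grid.shape, float(initial_temp))
    if inert.any():
        T[inert] = sink
    Tn = np.empty_like(T)

    times = np.empty(n_frames)
    frames = np.empty((n_frames,) + grid.shape) if record_full else None
    masked = {}
    mask_idx = {}
    if record_masks:
        for name, mask in record_masks.items():
            mask_idx[name] = np.nonzero(mask.ravel())[0]
            masked[name] = np.empty((n_frames, mask_idx[name].size))

    t_max = float(T.max())
    i_max = np.unravel_index(int(np.argmax(T)), T.shape)
    time_max = 0.0
    for fidx in range(n_frames):
        for _ in range(steps_per_frame):
            _step(T, Tn, grid.k, rhocv, q, inert, d_m, dt, kinds, vals, hs, sink)
            T, Tn = Tn, T
        if not np.isfinite(T).all():
            bad = np.unravel_index(np.argmax(~np.isfinite(T)), T.shape)
            raise FloatingPointError(f"instability: non-finite temperature at voxel {bad}")
        cur = float(T.max())
        if cur > t_max:
            t_max = cur
            i_max = np.unravel_index(int(np.argmax(T)), T.shape)
            time_max = (fidx + 1) * config.record_interval
        times[fidx] = (fidx + 1) * config.record_interval
        if record_full:
            frames[fidx] = T
        for name, idx in mask_idx.items():
            masked[name][fidx] = T.ravel()[idx]

    return TemperatureSeries(
        times=times,
        frames=frames,
        masked=masked,
        max_temperature=t_max,
        max_index=tuple(int(i) for i in i_max),
        max_time=time_max,
        dt=dt,
    )


def mouse_validation_run(
    f_v: float = 6.5e-4,
    power_w: float = 0.4,
    beam_radius_mm: float = 5.0,
    duration_s: float = 300.0,
    spacing: float = 0.5,
    n_photons: int = 100_000,
    seed: int = 1,
    boundary: Optional[BoundarySpec] = None,
):
    """Peak temperature for the homogeneous-mouse validation scenario.

    BALB/c tissue properties throughout, a single 2 mm-diameter nanoparticle
    depot at the surface centre, 1064 nm beam of the given 1/e^2 radius and
    power, irradiated for ``duration_s``.  Returns (peak_temp_C, series).
    """
    from .tissue import apply_injections, build_mouse_domain, place_injections
    from .transport import BeamSpec, run_transport

    grid = build_mouse_domain(spacing=spacing)
    if f_v > 0:
        plan = place_injections(1, f_v)
        grid = apply_injections(grid, plan, subsample=2)
    fl = run_transport(grid, BeamSpec(radius=beam_radius_mm), n_photons, seed)
    cfg = ThermalStepConfig(
        duration=duration_s,
        record_interval=10.0,
        boundary=boundary or BoundarySpec(),
    )
    series = run_simulation(grid, fl, power_w, cfg, record_full=False)
    return series.max_temperature, series
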