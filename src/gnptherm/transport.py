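"""Monte Carlo photon transport in the heterogeneous voxel grid.

Weighted-photon random walk in the MCML tradition, on a voxel grid instead of
layers: packets enter through a Gaussian beam profile travelling in +z, take
steps of optical depth ``-ln(xi)``, deposit ``w * mu_a / mu_t`` at each
interaction, scatter through Henyey-Greenstein angles with the local
anisotropy g, and die by Russian roulette or by leaving the domain.  Voxel
boundaries are crossed with exact ray stepping and the remaining optical path
carries over, so heterogeneous media incur no step-truncation bias.

Refractive-index interfaces are matched (no Fresnel reflection); lateral and
bottom boundaries, and the inert voxels outside the 15 mm cylinder, absorb
escaping packets into an escape tally.

The output :class:`FluenceMap` stores the fluence rate per unit incident
power, ``F_v = A_v / (mu_a,v * V_voxel)`` in 1/mm^2, so that
``mu_a * F * P_l`` is the volumetric heat source at laser power ``P_l``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "BeamSpec",
    "FluenceMap",
    "sample_beam_entries",
    "hg_sample_cos",
    "propagate_one",
    "run_transport",
]

_W_MIN = 1e-4        # Russian-roulette weight threshold
_P_SURVIVE = 0.1     # roulette survival probability


@dataclass(frozen=True)
class BeamSpec:
    """Gaussian beam normal to the surface, centred on the domain axis.

    ``radius`` is the 1/e^2 intensity radius in mm.  Power is not part of the
    transport (fluence is stored per unit power); it enters the heat source.
    """

    radius: float = 2.0
    wavelength: float = 1064.0

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("beam radius must be non-negative")


@dataclass
class FluenceMap:
    """Per-voxel fluence rate per unit incident power."""

    fluence: np.ndarray          # (nx, ny, nz) 1/mm^2
    absorbed: np.ndarray         # per-voxel absorbed fraction of launched weight
    absorbed_fraction: float
    escaped_fraction: float
    n_photons: int
    seed: int


def sample_beam_entries(beam: BeamSpec, n: int, seed: int, max_radius: float = np.inf):
    """(x, y) entry offsets from the beam axis (mm), truncated at max_radius.

    The intensity profile exp(-2 r^2 / w^2) corresponds to a 2-D normal
    distribution with sigma = w/2 per axis.
    """
    rng = np.random.default_rng(seed)
    if beam.radius == 0:
        return np.zeros((n, 2))
    sigma = beam.radius / 2.0
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        pts = rng.normal(0.0, sigma, size=(n - filled, 2))
        ok = pts[:, 0] ** 2 + pts[:, 1] ** 2 <= max_radius**2
        kept = pts[ok]
        out[filled : filled + len(kept)] = kept
        filled += len(kept)
    return out


@njit(cache=True)
def _hg_cos(g, u):
    if abs(g) < 1e-8:
        return 2.0 * u - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - t * t) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True)
def _hg_batch(g, n, seed):
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = _hg_cos(g, np.random.random())
    return out


def hg_sample_cos(g: float, n: int, seed: int) -> np.ndarray:
    """Sample n scattering-angle cosines from the Henyey-Greenstein function.

    The sample mean converges to g (the first moment of the phase function).
    """
    return _hg_batch(float(g), int(n), int(seed))


@njit(cache=True)
def _new_direction(ux, uy, uz, cost):
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    phi = 2.0 * np.pi * np.random.random()
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    if abs(uz) > 0.99999:
        nx = sint * cosp
        ny = sint * sinp
        nz = cost * (1.0 if uz >= 0 else -1.0)
    else:
        den = np.sqrt(1.0 - uz * uz)
        nx = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
        ny = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
        nz = -sint * cosp * den + uz * cost
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def _trace(mua, mus, g, inert, d, x0, y0, w0, A, record, rec_ix, rec_dep):
    """Trace one packet entering at (x0, y0, z=0); returns (escaped, n_rec).

    Deposits accumulate into A; when ``record`` the per-event voxel flat
    indices and deposits are stored in rec_ix / rec_dep.
    """
    nx, ny, nz = mua.shape
    x = x0
    y = y0
    z = 1e-12
    ux = 0.0
    uy = 0.0
    uz = 1.0
    w = w0
    ix = int(x / d)
    iy = int(y / d)
    iz = 0
    nrec = 0
    if ix < 0 or ix >= nx or iy < 0 or iy >= ny:
        return w, nrec
    if inert[ix, iy, iz]:
        return w, nrec
    tau = -np.log(np.random.random())
    escaped = 0.0
    while True:
        mu_a = mua[ix, iy, iz]
        mu_t = mu_a + mus[ix, iy, iz]
        # distance to the next voxel face along the current direction
        if ux > 0.0:
            tx = ((ix + 1) * d - x) / ux
        elif ux < 0.0:
            tx = (ix * d - x) / ux
        else:
            tx = 1e30
        if uy > 0.0:
            ty = ((iy + 1) * d - y) / uy
        elif uy < 0.0:
            ty = (iy * d - y) / uy
        else:
            ty = 1e30
        if uz > 0.0:
            tz = ((iz + 1) * d - z) / uz
        elif uz < 0.0:
            tz = (iz * d - z) / uz
        else:
            tz = 1e30
        tmin = tx
        axis = 0
        if ty < tmin:
            tmin = ty
            axis = 1
        if tz < tmin:
            tmin = tz
            axis = 2
        if tmin < 0.0:
            tmin = 0.0
        if mu_t > 0.0 and tau <= mu_t * tmin:
            # interaction inside this voxel
            s = tau / mu_t
            x += ux * s
            y += uy * s
            z += uz * s
            dep = w * mu_a / mu_t
            A[ix, iy, iz] += dep
            if record and nrec < rec_ix.shape[0]:
                rec_ix[nrec] = (ix * ny + iy) * nz + iz
                rec_dep[nrec] = dep
                nrec += 1
            w -= dep
            cost = _hg_cos(g[ix, iy, iz], np.random.random())
            ux, uy, uz = _new_direction(ux, uy, uz, cost)
            tau = -np.log(np.random.random())
            if w < _W_MIN:
                if np.random.random() < _P_SURVIVE:
                    w /= _P_SURVIVE
                else:
                    return escaped, nrec  # roulette kill (weight dropped)
            continue
        # advance to the face and carry the remaining optical path over
        if mu_t > 0.0:
            tau -= mu_t * tmin
        x += ux * tmin
        y += uy * tmin
        z += uz * tmin
        if axis == 0:
            ix += 1 if ux > 0 else -1
            x = ix * d if ux > 0 else (ix + 1) * d
        elif axis == 1:
            iy += 1 if uy > 0 else -1
            y = iy * d if uy > 0 else (iy + 1) * d
        else:
            iz += 1 if uz > 0 else -1
            z = iz * d if uz > 0 else (iz + 1) * d
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            return escaped + w, nrec
        if inert[ix, iy, iz]:
            return escaped + w, nrec


@njit(cache=True)
def _transport_batch(mua, mus, g, inert, d, entries, seed):
    np.random.seed(seed)
    nx, ny, nz = mua.shape
    A = np.zeros((nx, ny, nz))
    rec_ix = np.empty(0, dtype=np.int64)
    rec_dep = np.empty(0)
    escaped = 0.0
    cx = nx * d / 2.0
    cy = ny * d / 2.0
    for i in range(entries.shape[0]):
        e, _ = _trace(
            mua, mus, g, inert, d,
            cx + entries[i, 0], cy + entries[i, 1], 1.0,
            A, False, rec_ix, rec_dep,
        )
        escaped += e
    return A, escaped


@njit(cache=True)
def _trace_recorded(mua, mus, g, inert, d, x, y, seed, A, rec_ix, rec_dep):
    np.random.seed(seed)
    return _trace(mua, mus, g, inert, d, x, y, 1.0, A, True, rec_ix, rec_dep)


def propagate_one(grid, x_mm: float, y_mm: float, seed: int, max_events: int = 100000):
    """Trace a single packet; returns (list of (ix,iy,iz,deposit), escaped weight).

    Debug/inspection path sharing the production kernel.
    """
    rec_ix = np.empty(max_events, dtype=np.int64)
    rec_dep = np.empty(max_events)
    A = np.zeros(grid.shape)
    nx, ny, nz = grid.shape
    escaped, nrec = _trace_recorded(
        grid.mu_abs, grid.mu_sca, grid.g, grid.inert_mask, grid.spacing,
        nx * grid.spacing / 2.0 + x_mm, ny * grid.spacing / 2.0 + y_mm,
        seed, A, rec_ix, rec_dep,
    )
    events = []
    for i in range(nrec):
        flat = rec_ix[i]
        iz = flat % nz
        iy = (flat // nz) % ny
        ix = flat // (ny * nz)
        events.append(((int(ix), int(iy), int(iz)), float(rec_dep[i])))
    return events, float(escaped)


def run_transport(grid, beam: BeamSpec, n_photons: int, seed: int) -> FluenceMap:
    """Transport ``n_photons`` packets and return the normalised fluence map.

    ``fluence`` is zero wherever the local absorption coefficient is zero
    (the absorbed-fraction array is still populated there, which is always
    zero too for matched boundaries).
    """
    if n_photons < 1000:
        raise ValueError("need at least 1000 photons for a usable fluence map")
    nx, ny, nz = grid.shape
    half = nx * grid.spacing / 2.0
    entries = sample_beam_entries(beam, int(n_photons), seed, max_radius=half)
    A, escaped = _transport_batch(
        grid.mu_abs, grid.mu_sca, grid.g,
        grid.inert_mask, grid.spacing, entries, int(seed) & 0x7FFFFFFF,
    )
    A /= n_photons
    escaped /= n_photons
    vol = grid.voxel_volume_mm3
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(grid.mu_abs > 0, A / (grid.mu_abs * vol), 0.0)
    return FluenceMap(
        fluence=F,
        absorbed=A,
        absorbed_fraction=float(A.sum()),
        escaped_fraction=float(escaped),
        n_photons=int(n_photons),
        seed=int(seed),
    )
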