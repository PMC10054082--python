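"""Treatment scores from a temperature time series.

Three scalar metrics rank a photothermal treatment:

* theta_A* — apoptosis retention ratio: the time-averaged fraction of tumor
  volume inside the apoptosis temperature band (43-50 degC, bounds
  inclusive).  1 means the whole tumor sat in the band for the whole
  treatment.
* theta_H* — thermal hazard retention value: a temperature-weighted damage
  score averaged over time and over the normal-tissue shell that extends
  from the tumor surface out to 50% of the tumor diameter.  1 means the
  shell never warmed past the first hazard breakpoint.
* theta_eff* = theta_A* / theta_H* — the combined treatment-quality score,
  at most theta_A* and maximal (1) for full apoptosis coverage with no
  collateral heating.

The hazard weight table w(T) is not fixed by the source literature available
here; the default (1 below 43 degC, 2 in 43-50, 4 in 50-60, 8 above 60) is
non-decreasing and fully configurable, and is serialized with every sweep so
absolute theta_H* values are interpretable relative to it.  Comparisons
across scenarios under a fixed weighting are the meaningful output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "ApoptosisBand",
    "HazardWeighting",
    "MetricRecord",
    "shell_mask",
    "apoptosis_retention",
    "thermal_hazard",
    "effective_retention",
    "evaluate_metrics",
]


@dataclass(frozen=True)
class ApoptosisBand:
    """Temperature band (degC, inclusive) scored as apoptotic."""

    lower: float = 43.0
    upper: float = 50.0

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("band lower bound must be below the upper bound")


@dataclass(frozen=True)
class HazardWeighting:
    """Step-function damage weights: w = 1 below the first breakpoint."""

    breakpoints: Tuple[float, ...] = (43.0, 50.0, 60.0)
    weights: Tuple[float, ...] = (2.0, 4.0, 8.0)

    def __post_init__(self):
        if len(self.breakpoints) != len(self.weights):
            raise ValueError("breakpoints and weights must pair up")
        bp = np.asarray(self.breakpoints)
        w = np.asarray(self.weights)
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(w < 1) or np.any(np.diff(w) < 0):
            raise ValueError("weights must be >= 1 and non-decreasing")
        if bp[0] <= 37.0:
            raise ValueError("w(37 degC) must be 1: first breakpoint must exceed 37")

    def __call__(self, T: np.ndarray) -> np.ndarray:
        """Weight w(T) >= 1, elementwise."""
        table = np.concatenate([[1.0], np.asarray(self.weights)])
        return table[np.searchsorted(self.breakpoints, T, side="right")]

    def as_dict(self) -> dict:
        return {"breakpoints": list(self.breakpoints), "weights": list(self.weights)}


@dataclass
class MetricRecord:
    """Scores for one (laser power, volume fraction, injections) scenario."""

    theta_a: float
    theta_h: float
    theta_eff: float
    max_temp: float
    power_mw: float = np.nan
    f_v: float = np.nan
    n_injections: int = 0

    def __post_init__(self):
        if not (np.isfinite(self.theta_a) and np.isfinite(self.theta_h)):
            raise ValueError("metrics must be finite")


def shell_mask(grid, fraction: float = 0.5) -> np.ndarray:
    """Normal-tissue shell around the tumor for hazard scoring.

    Voxels outside the tumor whose distance from the tumor surface is at most
    ``fraction`` of the tumor diameter (2 mm for the default tumor).  The
    tumor diameter is taken from the lateral extent of the tumor mask.
    """
    tumor = grid.tumor_mask
    if not tumor.any():
        raise ValueError("grid has no tumor region")
    if tumor.all():
        raise ValueError("tumor mask covers the whole domain: empty shell")
    x, y, _ = grid.centers()
    X, Y = np.meshgrid(x, y, indexing="ij")
    r_xy = np.sqrt(X**2 + Y**2)[:, :, None] * np.ones_like(tumor, dtype=float)
    diameter = 2.0 * float(r_xy[tumor].max())
    dist = ndimage.distance_transform_edt(~tumor, sampling=grid.spacing)
    shell = (~tumor) & (~grid.inert_mask) & (dist <= fraction * diameter + 1e-9)
    if not shell.any():
        raise ValueError("empty normal-tissue shell (geometry bug)")
    return shell


def apoptosis_retention(
    frames: np.ndarray, band: ApoptosisBand = ApoptosisBand()
) -> float:
    """theta_A*: time-averaged in-band fraction of the tumor volume.

    ``frames`` is (n_frames, n_tumor_voxels) of temperatures (degC).
    """
    frames = np.atleast_2d(np.asarray(frames))
    if frames.shape[0] < 1 or frames.shape[1] < 1:
        raise ValueError("need at least one frame over a non-empty tumor")
    in_band = (frames >= band.lower) & (frames <= band.upper)
    return float(in_band.mean(axis=1).mean())


def thermal_hazard(
    frames: np.ndarray, weighting: HazardWeighting = HazardWeighting()
) -> float:
    """theta_H*: time- and shell-averaged hazard weight (>= 1)."""
    frames = np.atleast_2d(np.asarray(frames))
    if frames.shape[0] < 1 or frames.shape[1] < 1:
        raise ValueError("need at least one frame over a non-empty shell")
    return float(weighting(frames).mean(axis=1).mean())


def effective_retention(theta_a: float, theta_h: float) -> float:
    """theta_eff* = theta_A* / theta_H*."""
    if theta_h < 1.0 - 1e-12:
        raise ValueError("theta_H* below its minimum of 1")
    return float(theta_a / theta_h)


def evaluate_metrics(
    tumor_frames: np.ndarray,
    shell_frames: np.ndarray,
    band: ApoptosisBand = ApoptosisBand(),
    weighting: HazardWeighting = HazardWeighting(),
    **ids,
) -> MetricRecord:
    """Bundle the three scores (plus the peak temperature seen in the frames)."""
    a = apoptosis_retention(tumor_frames, band)
    h = thermal_hazard(shell_frames, weighting)
    return MetricRecord(
        theta_a=a,
        theta_h=h,
        theta_eff=effective_retention(a, h),
        max_temp=float(max(np.max(tumor_frames), np.max(shell_frames))),
        **ids,
    )
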