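"""Beam-profile reconstruction and top-hat metrics from pinhole scans.

A small pinhole is rastered across the beam at the sample position while a
diode behind it records the transmitted intensity; the readings, reshaped
onto the scan grid, give a 2-D beam-intensity map. For a top-hat beam the
useful descriptors are the FWHM along each axis (from half-maximum crossings
of the marginal, axis-summed profiles, with linear interpolation between
grid points), the plateau flatness (sd/mean over the region at or above 90%
of the maximum) and the 10%-90% edge width. A calibrated-diode total flux
can be spread over the map so that it integrates (trapezoidal, per um^2) to
the calibrated photons/s.

No pinhole deconvolution is applied: the pinhole (~5 um) is much smaller
than the beam, so the measured profile is taken as the beam profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PinholeScan",
    "BeamProfileMap",
    "BeamMetrics",
    "reconstruct_profile",
    "beam_metrics",
    "calibrate_flux",
]


@dataclass(frozen=True)
class PinholeScan:
    """Flat lists of scan positions (um) and diode intensities."""

    x_um: np.ndarray
    y_um: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x_um, dtype=float)
        y = np.asarray(self.y_um, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if not (x.shape == y.shape == i.shape) or x.ndim != 1:
            raise ValueError("x_um, y_um, intensity must be equal-length 1-D arrays")
        object.__setattr__(self, "x_um", x)
        object.__setattr__(self, "y_um", y)
        object.__setattr__(self, "intensity", i)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PinholeScan":
        df = pd.read_csv(path)
        if not {"x_um", "y_um", "intensity"}.issubset(df.columns):
            raise ValueError("scan CSV must have columns x_um,y_um,intensity")
        return cls(
            df["x_um"].to_numpy(float),
            df["y_um"].to_numpy(float),
            df["intensity"].to_numpy(float),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"x_um": self.x_um, "y_um": self.y_um, "intensity": self.intensity}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class BeamProfileMap:
    """Regular 2-D intensity grid; ``intensity[i, j]`` at (x_um[i], y_um[j])."""

    x_um: np.ndarray
    y_um: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x_um, dtype=float)
        y = np.asarray(self.y_um, dtype=float)
        z = np.asarray(self.intensity, dtype=float)
        if z.shape != (x.size, y.size):
            raise ValueError("intensity must have shape (len(x_um), len(y_um))")
        if not np.all(np.isfinite(z)) or np.any(z < 0):
            raise ValueError("intensity must be finite and non-negative")
        object.__setattr__(self, "x_um", x)
        object.__setattr__(self, "y_um", y)
        object.__setattr__(self, "intensity", z)

    def to_csv(self, path: str | Path) -> None:
        """Grid CSV: first column x_um, remaining columns headed by y_um."""
        df = pd.DataFrame(
            self.intensity, columns=[f"{y:g}" for y in self.y_um]
        )
        df.insert(0, "x_um", self.x_um)
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class BeamMetrics:
    """Top-hat descriptors of a beam-profile map."""

    fwhm_x_um: float
    fwhm_y_um: float
    plateau_flatness: float
    edge_width_x_um: float
    edge_width_y_um: float
    total_flux_ph_s: float | None = None

    def to_dict(self) -> dict:
        return {
            "fwhm_x_um": self.fwhm_x_um,
            "fwhm_y_um": self.fwhm_y_um,
            "plateau_flatness": self.plateau_flatness,
            "edge_width_x_um": self.edge_width_x_um,
            "edge_width_y_um": self.edge_width_y_um,
            "total_flux_ph_s": self.total_flux_ph_s,
        }


def reconstruct_profile(scan: PinholeScan, dark_level: float = 0.0) -> BeamProfileMap:
    """Dark-subtract, clip at zero and reshape a scan onto its rectangular grid."""
    xs = np.unique(scan.x_um)
    ys = np.unique(scan.y_um)
    if xs.size * ys.size != scan.x_um.size:
        raise ValueError(
            f"scan positions do not form a rectangular grid "
            f"({xs.size} x {ys.size} != {scan.x_um.size} points)"
        )
    grid = np.full((xs.size, ys.size), np.nan)
    ix = np.searchsorted(xs, scan.x_um)
    iy = np.searchsorted(ys, scan.y_um)
    grid[ix, iy] = scan.intensity
    if np.any(np.isnan(grid)):
        raise ValueError("scan does not cover every grid point exactly once")
    return BeamProfileMap(xs, ys, np.clip(grid - dark_level, 0.0, None))


def _crossing(axis: np.ndarray, profile: np.ndarray, level: float) -> tuple[float, float]:
    """Left and right positions where the profile crosses ``level`` (linear interp)."""
    above = profile >= level
    idx = np.flatnonzero(above)
    if idx.size == 0:
        raise ValueError("profile never reaches the requested level")
    i0, i1 = idx[0], idx[-1]
    if i0 == 0:
        left = axis[0]
    else:
        f = (level - profile[i0 - 1]) / (profile[i0] - profile[i0 - 1])
        left = axis[i0 - 1] + f * (axis[i0] - axis[i0 - 1])
    if i1 == profile.size - 1:
        right = axis[-1]
    else:
        f = (profile[i1] - level) / (profile[i1] - profile[i1 + 1])
        right = axis[i1] + f * (axis[i1 + 1] - axis[i1])
    return float(left), float(right)


def _marginal_metrics(axis: np.ndarray, profile: np.ndarray) -> tuple[float, float]:
    """(FWHM, mean 10-90% edge width) of one marginal profile."""
    peak = profile.max()
    l50, r50 = _crossing(axis, profile, 0.5 * peak)
    fwhm = r50 - l50
    l10, r10 = _crossing(axis, profile, 0.1 * peak)
    l90, r90 = _crossing(axis, profile, 0.9 * peak)
    edge = 0.5 * ((l90 - l10) + (r10 - r90))
    return fwhm, edge


def beam_metrics(profile: BeamProfileMap) -> BeamMetrics:
    """Top-hat metrics from marginal (axis-summed) profiles.

    Marginals are robust to pixel noise compared with single central slices
    and, for a separable top-hat, share the slice's FWHM. The plateau is the
    set of pixels at or above 90% of the 2-D maximum.
    """
    z = profile.intensity
    peak = z.max()
    if peak <= 0:
        raise ValueError("degenerate beam: all-zero profile")
    fwhm_x, edge_x = _marginal_metrics(profile.x_um, z.sum(axis=1))
    fwhm_y, edge_y = _marginal_metrics(profile.y_um, z.sum(axis=0))
    plateau = z[z >= 0.9 * peak]
    flatness = float(plateau.std() / plateau.mean()) if plateau.size else 0.0
    return BeamMetrics(
        fwhm_x_um=fwhm_x,
        fwhm_y_um=fwhm_y,
        plateau_flatness=flatness,
        edge_width_x_um=edge_x,
        edge_width_y_um=edge_y,
    )


def integrated_intensity(profile: BeamProfileMap) -> float:
    """Trapezoidal integral of the map over the scan area (units * um^2)."""
    inner = np.trapezoid(profile.intensity, profile.y_um, axis=1)
    return float(np.trapezoid(inner, profile.x_um))


def calibrate_flux(profile: BeamProfileMap, diode_total_ph_s: float) -> BeamProfileMap:
    """Rescale the map to photons/s/um^2 integrating to the calibrated total."""
    if diode_total_ph_s <= 0:
        raise ValueError("diode_total_ph_s must be > 0")
    integral = integrated_intensity(profile)
    if integral <= 0:
        raise ValueError("cannot calibrate a zero-integral map")
    return BeamProfileMap(
        profile.x_um, profile.y_um, profile.intensity * (diode_total_ph_s / integral)
    )
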