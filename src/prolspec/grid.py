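"""Wavelength grid of the emulated line-scan imaging spectrometer.

The instrument disperses 400-1000 nm onto a fixed detector axis whose band
centres grow slightly farther apart toward the red: the local sampling
interval is affine in wavelength, d(lambda) = alpha + beta * lambda, which
makes the band centre at detector index k

    lambda(k) = (lambda_0 + alpha/beta) * exp(beta * k) - alpha/beta .

The three dispersion constants below were calibrated against the printed
characteristic wavelengths of the reference instrument (e.g. 650.34,
662.97, 665.5 nm); every one of the 27 CARS-consensus wavelengths falls
within 0.04 nm of a band centre of the default 350-band grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WavelengthGrid", "make_wavelength_grid"]

# Dispersion calibration: centre of effective band 0 (nm), sampling interval
# extrapolated to lambda = 0 (nm), and relative interval growth per band.
_LAMBDA0 = 502.245133
_ALPHA = 1.12158278
_BETA = 2.13646742e-4

#: Full spectral range of the sensor (nm); grids must stay inside it.
SENSOR_RANGE = (400.0, 1000.0)


def _dispersion(k: np.ndarray | float) -> np.ndarray | float:
    """Band centre (nm) at detector index ``k`` (index 0 = first effective band)."""
    s = _ALPHA / _BETA
    return (_LAMBDA0 + s) * np.exp(_BETA * np.asarray(k, dtype=float)) - s


def _index_of(lam: float) -> float:
    """Fractional detector index whose centre lies at ``lam`` nm."""
    s = _ALPHA / _BETA
    return np.log((lam + s) / (_LAMBDA0 + s)) / _BETA


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band centres (nm) of a spectral axis."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", c)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("grid must be a non-empty 1-D array of band centres")
        if np.any(np.diff(c) <= 0):
            raise ValueError("band centres must be strictly increasing")
        lo, hi = SENSOR_RANGE
        if c[0] < lo or c[-1] > hi:
            raise ValueError(f"band centres must lie within [{lo}, {hi}] nm")

    def __len__(self) -> int:
        return int(self.centers.size)

    def nearest(self, wavelength_nm: float) -> int:
        """Index of the band centre closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.centers - wavelength_nm)))

    def window_indices(self, window: tuple[float, float]) -> np.ndarray:
        """Indices of bands whose centres fall in ``window`` (inclusive)."""
        lo, hi = window
        if hi < lo:
            raise ValueError("inverted wavelength window")
        return np.flatnonzero((self.centers >= lo) & (self.centers <= hi))

    def select(self, indices: np.ndarray) -> "WavelengthGrid":
        return WavelengthGrid(self.centers[np.asarray(indices)])

    @property
    def spacing(self) -> np.ndarray:
        return np.diff(self.centers)


def make_wavelength_grid(
    n_bands: int = 350, window: tuple[float, float] = (500.0, 950.0)
) -> WavelengthGrid:
    """Band centres of ``n_bands`` consecutive detector bands starting at ``window[0]``.

    The default (350 bands in 500-950 nm) is the effective-band selection used
    throughout the package: the noisy ends of the 400-1000 nm sensor range are
    discarded and 350 consecutive bands starting at the first centre >= 500 nm
    are kept.

    Raises
    ------
    ValueError
        If ``n_bands < 2``, the window is inverted or outside the sensor
        range, or ``n_bands`` consecutive bands do not fit inside the window.
    """
    if n_bands < 2:
        raise ValueError("n_bands must be at least 2")
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError("inverted wavelength window")
    if lo < SENSOR_RANGE[0] or hi > SENSOR_RANGE[1]:
        raise ValueError(f"window must lie within the sensor range {SENSOR_RANGE}")
    k0 = int(np.ceil(_index_of(lo) - 1e-9))
    ks = np.arange(k0, k0 + n_bands)
    centers = _dispersion(ks)
    if centers[-1] > hi + 1e-9:
        raise ValueError(
            f"{n_bands} consecutive bands starting at {centers[0]:.2f} nm "
            f"exceed the window upper edge {hi} nm"
        )
    return WavelengthGrid(centers)
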