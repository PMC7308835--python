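"""Leaf segmentation, mean-spectrum extraction and modelling-table assembly.

A leaf is separated from the dark background by thresholding a single NIR
band (default: the band nearest 800 nm, where healthy tissue reflects ~0.5
and the background ~0.05), keeping the largest connected component.  Each
sample's spectrum is the per-band mean over its four leaves' masked mean
spectra; the analysis window (500-950 nm, 350 bands) is applied inclusively
on both edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .cube_io import SpectralCube
from .grid import WavelengthGrid

__all__ = [
    "LeafMask",
    "SpectraTable",
    "NoLeafError",
    "segment_leaf",
    "mean_spectrum",
    "trim_bands",
    "assemble_samples",
]

MIN_LEAF_PIXELS = 50


class NoLeafError(ValueError):
    """Segmentation found no (or too small a) leaf region."""


@dataclass(frozen=True)
class LeafMask:
    """Boolean leaf-vs-background mask."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class SpectraTable:
    """n samples x p bands mean-reflectance matrix with FP references."""

    X: np.ndarray
    grid: WavelengthGrid
    y: np.ndarray
    labels: pd.DataFrame  # sample_id, day, cd_um

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.grid):
            raise ValueError("X must be (n, p) with p equal to the grid size")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match the number of rows")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("table contains missing or non-finite values")
        if self.labels["sample_id"].duplicated().any():
            raise ValueError("sample_id values must be unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: np.ndarray) -> "SpectraTable":
        rows = np.asarray(rows)
        return SpectraTable(
            self.X[rows], self.grid, self.y[rows],
            self.labels.iloc[rows].reset_index(drop=True),
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = self.labels.copy()
        df["fp_mg_g"] = self.y
        bands = pd.DataFrame(
            self.X, columns=[f"{w:.2f}" for w in self.grid.centers]
        )
        pd.concat([df, bands], axis=1).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraTable":
        df = pd.read_csv(path)
        meta = ["sample_id", "day", "cd_um", "fp_mg_g"]
        band_cols = [c for c in df.columns if c not in meta]
        grid = WavelengthGrid(np.array([float(c) for c in band_cols]))
        return cls(
            X=df[band_cols].to_numpy(float),
            grid=grid,
            y=df["fp_mg_g"].to_numpy(float),
            labels=df[["sample_id", "day", "cd_um"]].copy(),
        )


def segment_leaf(
    cube: SpectralCube,
    nir_nm: float = 800.0,
    threshold: float = 0.25,
    min_pixels: int = MIN_LEAF_PIXELS,
) -> LeafMask:
    """Threshold the NIR band nearest ``nir_nm`` and keep the largest blob.

    Raises :class:`NoLeafError` if no pixel exceeds the threshold or the
    largest component is smaller than ``min_pixels``.
    """
    band = cube.values[cube.grid.nearest(nir_nm)]
    above = band > threshold
    if not above.any():
        raise NoLeafError("no pixel exceeds the NIR reflectance threshold")
    labels, n = ndimage.label(above)
    sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    mask = labels == best
    if mask.sum() < min_pixels:
        raise NoLeafError(
            f"largest component has {int(mask.sum())} px < {min_pixels}"
        )
    return LeafMask(mask)


def mean_spectrum(cube: SpectralCube, mask: LeafMask | np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean of the in-mask pixel spectra."""
    m = mask.mask if isinstance(mask, LeafMask) else np.asarray(mask, bool)
    if not m.any():
        raise NoLeafError("empty mask")
    return cube.values[:, m].mean(axis=1)


def trim_bands(obj, window: tuple[float, float]):
    """Restrict a SpectraTable, SpectralCube or (spectrum, grid) to ``window``.

    Bands whose centres fall in ``[lo, hi]`` (inclusive) are retained; raises
    ValueError if none do.
    """
    if isinstance(obj, SpectraTable):
        idx = obj.grid.window_indices(window)
        if idx.size == 0:
            raise ValueError("window retains no bands")
        return SpectraTable(obj.X[:, idx], obj.grid.select(idx), obj.y, obj.labels)
    if isinstance(obj, SpectralCube):
        idx = obj.grid.window_indices(window)
        if idx.size == 0:
            raise ValueError("window retains no bands")
        return SpectralCube(obj.values[idx], obj.grid.select(idx), dict(obj.metadata))
    spectrum, grid = obj
    idx = grid.window_indices(window)
    if idx.size == 0:
        raise ValueError("window retains no bands")
    return np.asarray(spectrum)[..., idx], grid.select(idx)


def assemble_samples(
    leaf_spectra: dict[str, list[np.ndarray]],
    references: pd.DataFrame,
    grid: WavelengthGrid,
    leaves_per_sample: int = 4,
) -> SpectraTable:
    """Average each sample's leaf spectra and join its FP reference.

    ``leaf_spectra`` maps sample_id to exactly ``leaves_per_sample`` spectra;
    ``references`` must carry sample_id, day, cd_um, fp_mg_g.  Leaf order
    within a sample does not affect the result.
    """
    ref = references.set_index("sample_id")
    rows, ys, labels = [], [], []
    for sid in references["sample_id"]:
        if sid not in leaf_spectra:
            raise ValueError(f"missing leaf spectra for sample {sid!r}")
        spectra = leaf_spectra[sid]
        if len(spectra) != leaves_per_sample:
            raise ValueError(
                f"sample {sid!r} has {len(spectra)} leaves, expected {leaves_per_sample}"
            )
        rows.append(np.mean(np.asarray(spectra, dtype=float), axis=0))
        ys.append(float(ref.loc[sid, "fp_mg_g"]))
        labels.append((sid, ref.loc[sid, "day"], ref.loc[sid, "cd_um"]))
    extra = set(leaf_spectra) - set(references["sample_id"])
    if extra:
        raise ValueError(f"samples without FP reference: {sorted(extra)!r}")
    return SpectraTable(
        X=np.vstack(rows),
        grid=grid,
        y=np.array(ys),
        labels=pd.DataFrame(labels, columns=["sample_id", "day", "cd_um"]),
    )
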