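"""Pixel-wise FP prediction maps and pseudo-colour rendering.

Every in-mask pixel spectrum receives the same band subset and model as the
sample-level calibration; predictions outside the leaf mask are no-data
(NaN).  For the linear PLS engine the map mean over a leaf equals the
prediction of the leaf's mean spectrum exactly (affine map identity); kernel
and network engines agree on homogeneous leaves only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import Normalize

from .cube_io import SpectralCube
from .preprocess import LeafMask, NoLeafError
from .wavesel import SelectionResult

__all__ = ["PredictionMap", "predict_map", "render_pseudocolor", "shared_display_range"]


@dataclass
class PredictionMap:
    """Per-pixel FP estimates (mg/g) over a leaf mask; NaN = no data."""

    values: np.ndarray
    mask: np.ndarray
    display_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("map and mask shapes differ")
        if np.any(np.isnan(self.values[self.mask])):
            raise ValueError("in-mask estimates must be finite")
        if not np.all(np.isnan(self.values[~self.mask])):
            raise ValueError("estimates present outside the mask")
        if self.display_range is not None and not (
            self.display_range[0] < self.display_range[1]
        ):
            raise ValueError("display range must satisfy lo < hi")

    @property
    def in_mask(self) -> np.ndarray:
        return self.values[self.mask]


def predict_map(
    cube: SpectralCube,
    mask: LeafMask | np.ndarray,
    model,
    selection: SelectionResult | None = None,
) -> PredictionMap:
    """Apply a fitted model to every in-mask pixel of ``cube``.

    ``cube`` must already be trimmed to the band window the model was
    calibrated on; with ``selection`` given, its band indices (into that
    window) are applied per pixel, exactly as for the sample-level spectra.
    Negative estimates are preserved — clipping is a display concern.
    """
    m = mask.mask if isinstance(mask, LeafMask) else np.asarray(mask, bool)
    if m.shape != cube.values.shape[1:]:
        raise ValueError("mask shape does not match cube frame")
    if not m.any():
        raise NoLeafError("empty mask")
    X = cube.values[:, m].T  # (npix, p)
    if selection is not None:
        if selection.indices.max() >= X.shape[1]:
            raise ValueError("selection indices exceed cube band count")
        X = X[:, selection.indices]
    estimates = np.asarray(model.predict(X)).ravel()
    values = np.full(m.shape, np.nan)
    values[m] = estimates
    return PredictionMap(values=values, mask=m)


def shared_display_range(maps: list[PredictionMap], pct=(1.0, 99.0)) -> tuple[float, float]:
    """Common display range: 1st-99th percentile over all in-mask estimates."""
    pooled = np.concatenate([p.in_mask for p in maps])
    lo, hi = np.percentile(pooled, pct)
    if hi <= lo:
        hi = lo + 1e-6
    return float(lo), float(hi)


def map_to_rgba(
    values: np.ndarray, vmin: float, vmax: float, cmap: str = "jet"
) -> np.ndarray:
    """Colormap lookup used by the renderer; NaN maps to the 'bad' colour."""
    norm = Normalize(vmin=vmin, vmax=vmax, clip=True)
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad((1.0, 1.0, 1.0, 0.0))
    return cm(norm(np.ma.masked_invalid(values)))


def render_pseudocolor(
    pmap: PredictionMap,
    path: str | Path,
    cmap: str = "jet",
    vrange: tuple[float, float] | None = None,
    title: str | None = None,
) -> Path:
    """Write a pseudo-colour PNG of the map with a colourbar in mg/g.

    Negative estimates are clipped to 0 for display (FP is non-negative);
    the stored map is untouched.  A shared ``vrange`` across a panel of maps
    guarantees identical colours for identical FP values.
    """
    path = Path(path)
    if vrange is None:
        vrange = pmap.display_range or shared_display_range([pmap])
    lo, hi = vrange
    if not lo < hi:
        raise ValueError("display range must satisfy lo < hi")
    shown = np.where(pmap.mask, np.maximum(pmap.values, 0.0), np.nan)
    fig, ax = plt.subplots(figsize=(3.2, 3.0))
    im = ax.imshow(np.ma.masked_invalid(shown), cmap=cmap, vmin=lo, vmax=hi)
    im.cmap.set_bad("white")
    ax.set_axis_off()
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, label="FP (mg/g)", shrink=0.85)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def render_panel(
    maps: dict, path: str | Path, cmap: str = "jet",
    vrange: tuple[float, float] | None = None,
) -> Path:
    """Render a day x concentration panel of maps with one shared scale."""
    path = Path(path)
    days = sorted({d for d, _ in maps})
    concs = sorted({c for _, c in maps})
    if vrange is None:
        vrange = shared_display_range(list(maps.values()))
    fig, axes = plt.subplots(
        len(days), len(concs),
        figsize=(2.0 * len(concs), 1.9 * len(days)), squeeze=False,
    )
    im = None
    for i, d in enumerate(days):
        for j, c in enumerate(concs):
            ax = axes[i][j]
            ax.set_axis_off()
            pm = maps.get((d, c))
            if pm is None:
                continue
            shown = np.where(pm.mask, np.maximum(pm.values, 0.0), np.nan)
            im = ax.imshow(np.ma.masked_invalid(shown), cmap=cmap,
                           vmin=vrange[0], vmax=vrange[1])
            if i == 0:
                ax.set_title(f"{c:g} uM", fontsize=8)
            if j == 0:
                ax.text(-0.15, 0.5, f"{d} d", transform=ax.transAxes,
                        rotation=90, va="center", fontsize=8)
    if im is not None:
        fig.colorbar(im, ax=[a for row in axes for a in row],
                     label="FP (mg/g)", shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
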