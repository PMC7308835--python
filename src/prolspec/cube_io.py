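"""ENVI-style hypercube I/O and two-point reflectance calibration.

Cubes are stored as a plain-text ENVI header (``.hdr``) next to a raw
band-sequential (BSQ) binary.  Only the subset of the ENVI dialect needed
here is implemented: BSQ interleave, float32/float64 samples, little-endian,
wavelength list in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grid import WavelengthGrid

__all__ = [
    "SpectralCube",
    "CalibrationFrames",
    "read_cube",
    "write_cube",
    "reflectance_correct",
]

_DTYPES = {4: np.float32, 5: np.float64}
_DTYPE_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}

#: Ceiling applied after reflectance correction; guards specular pixels.
REFLECTANCE_CEILING = 1.5


@dataclass
class SpectralCube:
    """Reflectance (or raw-intensity) cube, ``(bands, rows, cols)``."""

    values: np.ndarray
    grid: WavelengthGrid
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("cube values must be (bands, rows, cols)")
        if self.values.shape[0] != len(self.grid):
            raise ValueError(
                f"band count {self.values.shape[0]} != grid count {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class CalibrationFrames:
    """White (~100 % reflectivity) and dark (blocked lens) raw frames."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark frames must share dimensions")


def _hdr_path(path: Path) -> Path:
    return path.with_suffix(".hdr")


def write_cube(cube: SpectralCube, path: str | Path, dtype=np.float32) -> Path:
    """Write ``cube`` as ENVI header + BSQ binary at ``path`` (``.raw``)."""
    path = Path(path)
    arr = np.ascontiguousarray(cube.values, dtype=dtype)
    bands, rows, cols = arr.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.grid.centers)
    hdr = (
        "ENVI\n"
        "description = {prolspec synthetic hypercube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np.dtype(dtype)]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    _hdr_path(path).write_text(hdr)
    arr.tofile(path)
    return path


def _parse_header(text: str) -> dict:
    """Parse ENVI ``key = value`` lines, honouring {...} multi-line blocks."""
    fields: dict[str, str] = {}
    buf = ""
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        buf = f"{buf} {line}" if buf else line
        if buf.count("{") > buf.count("}"):
            continue  # block still open
        if "=" in buf:
            key, val = buf.split("=", 1)
            fields[key.strip().lower()] = val.strip()
        buf = ""
    return fields


def read_cube(path: str | Path) -> SpectralCube:
    """Read an ENVI BSQ cube written by :func:`write_cube`.

    Raises
    ------
    ValueError
        On a missing wavelength list, unsupported interleave/data type, or a
        header/binary size mismatch.
    FileNotFoundError
        If the header or binary is absent.
    """
    path = Path(path)
    hdr = _parse_header(_hdr_path(path).read_text())
    for key in ("samples", "lines", "bands"):
        if key not in hdr:
            raise ValueError(f"ENVI header missing {key!r}")
    cols, rows, bands = (int(hdr[k]) for k in ("samples", "lines", "bands"))
    interleave = hdr.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise ValueError(f"unsupported interleave {interleave!r} (only BSQ)")
    code = int(hdr.get("data type", "4"))
    if code not in _DTYPES:
        raise ValueError(f"unsupported ENVI data type {code}")
    if "wavelength" not in hdr:
        raise ValueError("ENVI header missing wavelength list")
    wl = np.array(
        [float(t) for t in hdr["wavelength"].strip("{} ").split(",") if t.strip()]
    )
    if wl.size != bands:
        raise ValueError("wavelength list length disagrees with band count")
    data = np.fromfile(path, dtype=_DTYPES[code])
    if data.size != bands * rows * cols:
        raise ValueError(
            f"binary holds {data.size} values, header implies {bands * rows * cols}"
        )
    values = data.reshape(bands, rows, cols).astype(float)
    return SpectralCube(values, WavelengthGrid(wl), metadata={"path": str(path)})


def reflectance_correct(
    raw: SpectralCube | np.ndarray,
    frames: CalibrationFrames,
    average_rows: bool = True,
    clip: tuple[float, float] | None = (0.0, REFLECTANCE_CEILING),
) -> SpectralCube | np.ndarray:
    """Two-point radiometric calibration: ``(raw - dark) / (white - dark)``.

    With ``average_rows`` (default) the white/dark references are averaged
    over the row axis before use, suppressing reference noise; the corrected
    value is clipped to ``clip`` unless ``clip`` is None.

    Raises
    ------
    ValueError
        On dimension mismatch or wherever ``white - dark <= 0``.
    """
    values = raw.values if isinstance(raw, SpectralCube) else np.asarray(raw, float)
    white, dark = frames.white, frames.dark
    if values.shape != white.shape:
        raise ValueError(
            f"raw dims {values.shape} disagree with reference dims {white.shape}"
        )
    if average_rows:
        white = white.mean(axis=1, keepdims=True)
        dark = dark.mean(axis=1, keepdims=True)
    denom = white - dark
    if np.any(denom <= 0):
        raise ValueError("white - dark must be positive everywhere")
    corrected = (values - dark) / denom
    if clip is not None:
        corrected = np.clip(corrected, *clip)
    if isinstance(raw, SpectralCube):
        return SpectralCube(corrected, raw.grid, dict(raw.metadata))
    return corrected
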