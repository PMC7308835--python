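"""Synthetic Cd-stress study generator.

Emulates the full study design — 5 CdCl2 concentrations (0/5/25/50/100 uM)
x 4 stress durations (5/10/15/20 d) x 5 samples per group, each sample the
average of 4 leaves — producing leaf-shaped reflectance hypercubes, white and
dark calibration frames, and free-proline (FP) reference values with known
ground truth, so that every downstream stage (calibration, wavelength
selection, mapping) can be tested against planted signal.

The spectral forward model is deliberately phenomenological, not radiative
transfer: a green-leaf baseline curve plus stress-scaled pigment / dry-matter
/ water components, plus an FP-linked absorber that depresses reflectance at
six configured "informative" bands in proportion to FP content. The
informative band positions are recorded on the generator so that
selection-recovery tests can assert against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cube_io import CalibrationFrames, SpectralCube, write_cube
from .grid import WavelengthGrid, make_wavelength_grid

__all__ = [
    "StudyDesign",
    "FPTruth",
    "EndmemberSet",
    "DEFAULT_TREND",
    "make_wavelength_grid",
    "simulate_fp_truth",
    "render_leaf_cube",
    "simulate_spectra_table",
    "make_dataset",
]


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of the Cd-stress experiment."""

    concentrations: tuple[float, ...] = (0.0, 5.0, 25.0, 50.0, 100.0)  # uM Cd2+
    days: tuple[int, ...] = (5, 10, 15, 20)  # stress duration, d
    samples_per_group: int = 5
    leaves_per_sample: int = 4
    seed: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.concentrations) * len(self.days)

    @property
    def n_samples(self) -> int:
        return self.samples_per_group * self.n_groups

    @property
    def n_leaves(self) -> int:
        return self.n_samples * self.leaves_per_sample


# Per-(day, concentration) FP group means (mg/g fresh weight) and per-day
# within-group SD.  The five group means of each day average exactly to the
# day-level pooled mean (5 d: 0.1027, 10 d: 0.1335, 15 d: 0.1622,
# 20 d: 0.1880 mg/g) and the chosen between-group spread plus within-group SD
# reproduce the day-level pooled SDs (0.0172 / 0.0096 / 0.0138 / 0.0192).
# Ordinal structure: at 5 d mild stress (5 uM) raises FP while higher doses
# depress it below control; by 15-20 d FP rises monotonically with dose.
DEFAULT_TREND: dict[int, dict[str, object]] = {
    5: {"means": {0.0: 0.1050, 5.0: 0.1250, 25.0: 0.1000, 50.0: 0.0950, 100.0: 0.0885},
        "sd": 0.0119},
    10: {"means": {0.0: 0.1310, 5.0: 0.1400, 25.0: 0.1330, 50.0: 0.1320, 100.0: 0.1315},
         "sd": 0.0087},
    15: {"means": {0.0: 0.1440, 5.0: 0.1530, 25.0: 0.1620, 50.0: 0.1710, 100.0: 0.1810},
         "sd": 0.0040},
    20: {"means": {0.0: 0.1620, 5.0: 0.1750, 25.0: 0.1880, 50.0: 0.2010, 100.0: 0.2140},
         "sd": 0.0055},
}

#: Nominal centres (nm) of the FP-linked absorber bands.  These are the
#: wavelengths repeatedly flagged by independent selection methods on the
#: reference instrument; the generator snaps each to the nearest band centre.
INFORMATIVE_NM = (601.37, 625.18, 626.44, 650.34, 689.56, 943.52)
#: Relative absorber strength at each informative band (breaks exact ties).
#: The NIR O-H overtone band (943.52 nm) is strongest: it sits on the high
#: NIR plateau where the dip must compete with the water component's flank;
#: the visible-band strengths are bounded by the low (~0.07) visible baseline.
INFORMATIVE_AMP = (0.33, 0.30, 0.28, 0.33, 0.32, 1.0)
#: Reflectance depression per (mg/g) FP at a unit-strength informative band.
FP_ABSORPTIVITY = 0.45

#: Per-band Gaussian noise SD on a leaf mean spectrum (reflectance units).
#: Matches the band-to-band repeatability of a pushbroom imager after
#: averaging several hundred leaf pixels; also what keeps the six planted
#: bands mutually non-redundant (each contributes to the FP estimate).
LEAF_NOISE_SD = 0.004
#: Per-band, per-pixel Gaussian noise SD inside a hypercube.
PIXEL_NOISE_SD = 0.004
#: SD of per-leaf FP around the sample value (mg/g), recentred per sample.
LEAF_FP_SD = 0.005
#: Flat background reflectance outside the leaf.
BACKGROUND_REFLECTANCE = 0.05


@dataclass(frozen=True)
class FPTruth:
    """Ground-truth FP values of a simulated study."""

    samples: pd.DataFrame  # sample_id, day, cd_um, fp_mg_g
    leaves: pd.DataFrame   # sample_id, leaf, fp_mg_g

    def day_mean(self, day: int) -> float:
        sub = self.samples[self.samples["day"] == day]
        return float(sub["fp_mg_g"].mean())


@dataclass(frozen=True)
class EndmemberSet:
    """Component spectra of the forward model over a wavelength grid."""

    grid: WavelengthGrid
    baseline: np.ndarray
    pigment: np.ndarray
    dry_matter: np.ndarray
    water: np.ndarray
    fp_absorber: np.ndarray
    informative_indices: np.ndarray

    def __post_init__(self) -> None:
        for name in ("baseline", "pigment", "dry_matter", "water", "fp_absorber"):
            comp = getattr(self, name)
            if comp.min() < 0 or comp.max() > 1:
                raise ValueError(f"component {name!r} outside [0, 1]")


def _gauss(lam: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - mu) / sd) ** 2)


def make_endmembers(grid: WavelengthGrid) -> EndmemberSet:
    """Component spectra of the leaf forward model on ``grid``."""
    lam = grid.centers
    baseline = (
        0.06
        + 0.04 * _gauss(lam, 550.0, 25.0)          # green reflectance bump
        + 0.45 / (1.0 + np.exp(-(lam - 715.0) / 14.0))  # red edge to NIR plateau
        - 0.04 * _gauss(lam, 970.0, 45.0)          # water absorption shoulder
    )
    pigment = _gauss(lam, 675.0, 30.0) + 0.5 * _gauss(lam, 550.0, 40.0)
    pigment = pigment / pigment.max()
    dry = (lam - lam[0]) / (lam[-1] - lam[0])
    water = _gauss(lam, 950.0, 45.0)
    idx = np.array([grid.nearest(w) for w in INFORMATIVE_NM])
    fp = np.zeros_like(lam)
    for i, amp in zip(idx, INFORMATIVE_AMP):
        fp += amp * _gauss(lam, lam[i], 0.7)
    fp = np.clip(fp, 0.0, 1.0)
    return EndmemberSet(grid, baseline, pigment, dry, water, fp, idx)


def stress_index(day: float, cd_um: float) -> float:
    """Combined stress severity in [0, 1]: duration x log-dose."""
    return (day / 20.0) * (np.log1p(cd_um) / np.log1p(100.0))


def simulate_fp_truth(design: StudyDesign, trend: dict | None = None) -> FPTruth:
    """Draw per-sample and per-leaf FP reference values for a study design.

    Per-sample FP is Gaussian around its (day, concentration) group mean with
    the day's within-group SD; per-leaf FP scatters around the sample value
    with SD ``LEAF_FP_SD`` and is recentred so the 4-leaf mean equals the
    sample value exactly.  All values are clipped to stay positive.

    Raises
    ------
    KeyError
        If the trend table lacks a (day, concentration) cell.
    ValueError
        If any SD is negative.
    """
    trend = DEFAULT_TREND if trend is None else trend
    rng = np.random.default_rng([design.seed, 101])
    rows, leaf_rows = [], []
    sid = 0
    for day in design.days:
        try:
            cell = trend[day]
        except KeyError as exc:
            raise KeyError(f"trend table missing day {day}") from exc
        sd = float(cell["sd"])
        if sd < 0:
            raise ValueError("negative within-group SD")
        for cd in design.concentrations:
            try:
                mu = float(cell["means"][cd])
            except KeyError as exc:
                raise KeyError(f"trend table missing cell (day={day}, cd={cd})") from exc
            for _ in range(design.samples_per_group):
                fp = max(float(rng.normal(mu, sd)), 1e-3)
                name = f"s{sid:03d}"
                rows.append((name, day, cd, fp))
                dev = rng.normal(0.0, LEAF_FP_SD, design.leaves_per_sample)
                dev -= dev.mean()  # 4-leaf mean == sample value exactly
                for j, d in enumerate(dev):
                    leaf_rows.append((name, j, max(fp + d, 1e-4)))
                sid += 1
    samples = pd.DataFrame(rows, columns=["sample_id", "day", "cd_um", "fp_mg_g"])
    leaves = pd.DataFrame(leaf_rows, columns=["sample_id", "leaf", "fp_mg_g"])
    return FPTruth(samples, leaves)


def _draw_abundances(rng: np.random.Generator, s: float) -> dict[str, float]:
    """Per-leaf nuisance component abundances at stress severity ``s``."""
    return {
        "pigment": rng.normal(0.005 * s, 0.004),   # chlorosis brightens the visible
        "dry_matter": rng.normal(0.008 * s, 0.005),
        "water": rng.normal(0.008 * s, 0.004),     # drying lifts the NIR shoulder
    }


def _leaf_spectrum(
    em: EndmemberSet, fp: float, ab: dict[str, float]
) -> np.ndarray:
    """Noise-free reflectance of leaf tissue at FP content ``fp`` (mg/g)."""
    return (
        em.baseline
        + ab["pigment"] * em.pigment
        + ab["dry_matter"] * em.dry_matter
        + ab["water"] * em.water
        - FP_ABSORPTIVITY * fp * em.fp_absorber
    )


def _leaf_shape(rows: int, cols: int) -> tuple[np.ndarray, np.ndarray]:
    """Leaf-blade mask and along-axis position t in [0, 1] (petiole -> tip)."""
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    margin = max(2, cols // 12)
    t = (c - margin) / max(cols - 2 * margin - 1, 1)
    half_width = 0.35 * rows * np.sin(np.pi * np.clip(t, 0.0, 1.0)) ** 0.7
    mask = (t >= 0) & (t <= 1) & (np.abs(r - (rows - 1) / 2.0) <= half_width)
    tmap = np.broadcast_to(np.clip(t, 0.0, 1.0), (rows, cols))
    return mask, tmap


def render_leaf_cube(
    leaf_fp: float,
    grid: WavelengthGrid,
    shape: tuple[int, int] = (48, 40),
    gradient: tuple[float, float] = (0.9, 1.15),
    noise_sd: float = PIXEL_NOISE_SD,
    abundances: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[SpectralCube, np.ndarray, np.ndarray]:
    """Render one leaf as a reflectance hypercube with known per-pixel FP.

    Per-pixel FP is ``leaf_fp`` times a tip-to-petiole gradient factor, linear
    along the leaf main axis over ``gradient`` (tip end high) and normalised
    to mean 1 over the mask so the leaf-mean FP equals ``leaf_fp``.  Pixel
    spectra follow the shared forward model; background pixels carry a flat
    spectrum of ``BACKGROUND_REFLECTANCE``.

    Returns ``(cube, mask, fp_map)`` where ``fp_map`` is NaN off-leaf.
    """
    if leaf_fp <= 0:
        raise ValueError("leaf_fp must be positive")
    rows, cols = shape
    if rows < 32 or cols < 32:
        raise ValueError("image dims must be at least 32x32")
    mask, t = _leaf_shape(rows, cols)
    if not mask.any():
        raise ValueError("degenerate leaf shape: empty mask")
    rng = np.random.default_rng([seed, 202])
    lo, hi = gradient
    factor = lo + (hi - lo) * t
    factor = factor / factor[mask].mean()
    fp_map = np.where(mask, leaf_fp * factor, np.nan)

    em = make_endmembers(grid)
    ab = abundances if abundances is not None else _draw_abundances(rng, 0.5)
    p = len(grid)
    values = np.full((p, rows, cols), BACKGROUND_REFLECTANCE, dtype=float)
    fp_px = fp_map[mask]  # (npix,)
    base = _leaf_spectrum(em, 0.0, ab)  # fp term added per pixel below
    spectra = base[:, None] - FP_ABSORPTIVITY * em.fp_absorber[:, None] * fp_px[None, :]
    values[:, mask] = spectra
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, values.shape)
    cube = SpectralCube(values, grid, metadata={"leaf_fp": leaf_fp})
    return cube, mask, fp_map


def simulate_spectra_table(
    design: StudyDesign,
    trend: dict | None = None,
    grid: WavelengthGrid | None = None,
    noise_sd: float = LEAF_NOISE_SD,
):
    """Sample-level modelling table straight from the leaf forward model.

    For each sample, four leaf mean spectra are drawn (shared forward model,
    per-leaf abundances and FP, per-band noise ``noise_sd``) and averaged.
    Statistically this matches rendering full hypercubes and extracting
    masked mean spectra, at a small fraction of the cost.

    Returns a :class:`~prolspec.preprocess.SpectraTable`.
    """
    from .preprocess import SpectraTable

    grid = make_wavelength_grid() if grid is None else grid
    em = make_endmembers(grid)
    truth = simulate_fp_truth(design, trend)
    leaves = truth.leaves.set_index(["sample_id", "leaf"])["fp_mg_g"]
    X = np.empty((design.n_samples, len(grid)))
    for i, row in truth.samples.iterrows():
        rng = np.random.default_rng([design.seed, 303, i])
        s = stress_index(row["day"], row["cd_um"])
        spec = np.zeros(len(grid))
        for j in range(design.leaves_per_sample):
            ab = _draw_abundances(rng, s)
            fp = float(leaves.loc[(row["sample_id"], j)])
            spec += _leaf_spectrum(em, fp, ab) + rng.normal(0.0, noise_sd, len(grid))
        X[i] = spec / design.leaves_per_sample
    labels = truth.samples[["sample_id", "day", "cd_um"]].copy()
    return SpectraTable(
        X=X, grid=grid, y=truth.samples["fp_mg_g"].to_numpy(), labels=labels
    )


def _lamp_profile(lam: np.ndarray) -> np.ndarray:
    """Halogen-lamp raw white-reference intensity (arbitrary counts)."""
    return 3000.0 * (0.55 + 0.45 * _gauss(lam, 800.0, 200.0))


def make_calibration_frames(
    grid: WavelengthGrid,
    shape: tuple[int, int] = (48, 40),
    noise_sd: float = 0.5,
    seed: int = 0,
) -> CalibrationFrames:
    """White (lamp on whiteboard) and dark (blocked lens) raw frames."""
    rng = np.random.default_rng([seed, 404])
    rows, cols = shape
    lamp = _lamp_profile(grid.centers)[:, None, None]
    white = np.broadcast_to(lamp, (len(grid), rows, cols)).copy()
    dark = np.full((len(grid), rows, cols), 80.0)
    white += rng.normal(0.0, noise_sd, white.shape)
    dark += rng.normal(0.0, 0.2, dark.shape)
    return CalibrationFrames(white=white, dark=dark)


def make_dataset(
    design: StudyDesign,
    outdir: str | Path,
    trend: dict | None = None,
    shape: tuple[int, int] = (48, 40),
) -> dict:
    """Write the full synthetic study to ``outdir``.

    Emits one raw-intensity ENVI cube per leaf, one white and one dark
    calibration frame, a per-sample reference table ``references.csv``
    (sample_id, day, cd_um, fp_mg_g; one row per sample, not per leaf) and a
    per-leaf truth table ``leaves.csv``.  Raw counts are dark + reflectance x
    (white - dark), so two-point correction recovers the rendered reflectance.

    Returns a manifest with file paths and in-memory truth objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = make_wavelength_grid()
    truth = simulate_fp_truth(design, trend)
    frames = make_calibration_frames(grid, shape, seed=design.seed)
    lamp = _lamp_profile(grid.centers)[:, None, None]
    leaves = truth.leaves.set_index(["sample_id", "leaf"])["fp_mg_g"]

    write_cube(SpectralCube(frames.white, grid, {"frame": "white"}), outdir / "white.raw")
    write_cube(SpectralCube(frames.dark, grid, {"frame": "dark"}), outdir / "dark.raw")

    cube_paths: dict[tuple[str, int], Path] = {}
    masks: dict[tuple[str, int], np.ndarray] = {}
    fp_maps: dict[tuple[str, int], np.ndarray] = {}
    for i, row in truth.samples.iterrows():
        s = stress_index(row["day"], row["cd_um"])
        for j in range(design.leaves_per_sample):
            rng = np.random.default_rng([design.seed, 505, i, j])
            ab = _draw_abundances(rng, s)
            fp = float(leaves.loc[(row["sample_id"], j)])
            cube, mask, fp_map = render_leaf_cube(
                fp, grid, shape=shape, abundances=ab,
                seed=int(rng.integers(2**31)),
            )
            raw = 80.0 + cube.values * (lamp - 80.0)
            path = outdir / f"{row['sample_id']}_leaf{j}.raw"
            write_cube(
                SpectralCube(raw, grid, {"sample_id": row["sample_id"], "leaf": j}),
                path,
            )
            cube_paths[(row["sample_id"], j)] = path
            masks[(row["sample_id"], j)] = mask
            fp_maps[(row["sample_id"], j)] = fp_map
    truth.samples.to_csv(outdir / "references.csv", index=False)
    truth.leaves.to_csv(outdir / "leaves.csv", index=False)
    return {
        "outdir": outdir,
        "grid": grid,
        "truth": truth,
        "white": outdir / "white.raw",
        "dark": outdir / "dark.raw",
        "cubes": cube_paths,
        "masks": masks,
        "fp_maps": fp_maps,
        "references": outdir / "references.csv",
    }
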