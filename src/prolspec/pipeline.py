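"""End-to-end reproduction driver.

``run_pipeline`` chains simulate -> (trim) -> split -> select -> fit ->
evaluate -> map on one config: it emits a 12-cell report ({full, GA, CARS,
Bw} x {PLS, LS-SVM, ELM}) in the layout of the reference study's result
tables, plus a day x concentration pseudo-colour FP map panel rendered with
the best-performing cell's model.

By default the modelling table is drawn directly from the leaf-level forward
model and hypercubes are rendered only for the map panel (one leaf per
group); ``cube_rendering="full"`` instead writes every leaf cube and runs
the correction/segmentation/averaging path, which is what the tests exercise
on small designs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemometrics as chem
from . import evalstats, mapping, preprocess, synth, wavesel
from .cube_io import CalibrationFrames, read_cube, reflectance_correct
from .grid import make_wavelength_grid

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a run needs; fully JSON-serialisable."""

    outdir: str = "prolspec_run"
    seed: int = 0
    samples_per_group: int = 5
    concentrations: tuple[float, ...] = (0.0, 5.0, 25.0, 50.0, 100.0)
    days: tuple[int, ...] = (5, 10, 15, 20)
    leaves_per_sample: int = 4
    window: tuple[float, float] = (500.0, 950.0)
    n_bands: int = 350
    engines: tuple[str, ...] = ("pls", "lssvm", "elm")
    selectors: tuple[str, ...] = ("full", "ga", "cars", "bw")
    split_ratio: float = 0.25
    cars_iterations: int = 50
    ga_pop_size: int = 30
    ga_generations: int = 100
    ga_p_crossover: float = 0.6
    ga_p_mutation: float = 0.01
    selection_n_lv: int = 10
    max_lv: int = 15
    cube_rendering: str = "panel"  # "panel" | "full" | "none"
    cube_shape: tuple[int, int] = (48, 40)

    def design(self) -> synth.StudyDesign:
        return synth.StudyDesign(
            concentrations=tuple(self.concentrations),
            days=tuple(self.days),
            samples_per_group=self.samples_per_group,
            leaves_per_sample=self.leaves_per_sample,
            seed=self.seed,
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        for key in ("concentrations", "days", "window", "engines", "selectors",
                    "cube_shape"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _fit_engine(engine: str, X, y, cfg: RunConfig):
    """Fit one engine; returns (model, parameter-string)."""
    if engine == "pls":
        model, cv = chem.pls_fit(X, y, max_lv=min(cfg.max_lv, X.shape[0] - 1,
                                                  X.shape[1]))
        return model, str(model.n_lv)
    if engine == "lssvm":
        model, cv = chem.lssvm_fit(X, y)
        return model, f"{model.gam:,.2f}; {model.sig2:,.2f}"
    if engine == "elm":
        model, cv = chem.elm_fit(X, y, seed=cfg.seed)
        return model, str(model.n_nodes)
    raise ValueError(f"unknown engine {engine!r}")


def _make_table(cfg: RunConfig, outdir: Path) -> preprocess.SpectraTable:
    design = cfg.design()
    grid = make_wavelength_grid(cfg.n_bands, cfg.window)
    if cfg.cube_rendering == "full":
        data_dir = outdir / "cubes"
        manifest = synth.make_dataset(design, data_dir, shape=cfg.cube_shape)
        white = read_cube(manifest["white"])
        dark = read_cube(manifest["dark"])
        frames = CalibrationFrames(white=white.values, dark=dark.values)
        spectra: dict[str, list[np.ndarray]] = {}
        for (sid, leaf), path in manifest["cubes"].items():
            cube = reflectance_correct(read_cube(path), frames)
            mask = preprocess.segment_leaf(cube)
            spectra.setdefault(sid, []).append(preprocess.mean_spectrum(cube, mask))
        refs = pd.read_csv(manifest["references"])
        table = preprocess.assemble_samples(
            spectra, refs, manifest["grid"], design.leaves_per_sample
        )
        return preprocess.trim_bands(table, cfg.window)
    table = synth.simulate_spectra_table(design, grid=grid)
    return preprocess.trim_bands(table, cfg.window)


def _render_maps(cfg: RunConfig, model, selection, outdir: Path) -> Path:
    design = cfg.design()
    truth = synth.simulate_fp_truth(design)
    grid = make_wavelength_grid(cfg.n_bands, cfg.window)
    maps = {}
    for (day, cd), group in truth.samples.groupby(["day", "cd_um"]):
        fp = float(group["fp_mg_g"].iloc[0])
        s = synth.stress_index(day, cd)
        rng = np.random.default_rng([cfg.seed, 606, int(day), int(cd)])
        cube, mask, _ = synth.render_leaf_cube(
            fp, grid, shape=cfg.cube_shape,
            abundances=synth._draw_abundances(rng, s),
            seed=int(rng.integers(2**31)),
        )
        maps[(int(day), float(cd))] = mapping.predict_map(cube, mask, model, selection)
    path = mapping.render_panel(maps, outdir / "fp_map_panel.png")
    return path


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full study reproduction; returns report, selections and paths."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(cfg.to_json())

    # --- simulate / load (config-hash cache) ------------------------------
    stage = "simulate"
    try:
        table_path = outdir / "spectra.csv"
        hash_path = outdir / "spectra.hash"
        if table_path.exists() and hash_path.exists() and \
                hash_path.read_text() == cfg.config_hash:
            table = preprocess.SpectraTable.from_csv(table_path)
        else:
            table = _make_table(cfg, outdir)
            table.to_csv(table_path)
            hash_path.write_text(cfg.config_hash)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- split ------------------------------------------------------------
    stage = "split"
    try:
        cal_idx, pred_idx = evalstats.rank_split(table.y, cfg.split_ratio)
        cal, pred = table.subset(cal_idx), table.subset(pred_idx)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- select -----------------------------------------------------------
    stage = "select"
    selections: dict[str, wavesel.SelectionResult | None] = {}
    try:
        for sel in cfg.selectors:
            if sel == "full":
                selections["full"] = None
            elif sel == "cars":
                selections["cars"] = wavesel.cars_select(
                    cal.X, cal.y, cal.grid, n_iterations=cfg.cars_iterations,
                    n_lv=cfg.selection_n_lv, seed=cfg.seed,
                )
            elif sel == "ga":
                selections["ga"] = wavesel.ga_select(
                    cal.X, cal.y, cal.grid, pop_size=cfg.ga_pop_size,
                    n_generations=cfg.ga_generations,
                    p_crossover=cfg.ga_p_crossover,
                    p_mutation=cfg.ga_p_mutation,
                    n_lv=cfg.selection_n_lv, seed=cfg.seed,
                )
            elif sel == "bw":
                base, _ = chem.pls_fit(
                    cal.X, cal.y,
                    max_lv=min(cfg.max_lv, cal.n - 1, cal.p),
                )
                selections["bw"] = wavesel.bw_select(base, cal.grid)
            else:
                raise ValueError(f"unknown selector {sel!r}")
            result = selections[sel]
            if result is not None:
                result.to_frame().to_csv(outdir / f"selection_{sel}.csv", index=False)
                result.trace.to_csv(outdir / f"selection_{sel}_trace.csv", index=False)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- fit + evaluate ---------------------------------------------------
    stage = "fit/evaluate"
    rows = []
    fitted = {}
    try:
        for sel_name, sel in selections.items():
            idx = sel.indices if sel is not None else np.arange(cal.p)
            Xc, Xp = cal.X[:, idx], pred.X[:, idx]
            for engine in cfg.engines:
                model, param = _fit_engine(engine, Xc, cal.y, cfg)
                report = evalstats.evaluate(model, Xc, cal.y, Xp, pred.y)
                fitted[(sel_name, engine)] = model
                rows.append({
                    "selector": sel_name,
                    "n_vars": int(idx.size),
                    "engine": engine,
                    "parameter": param,
                    "Rc": report.Rc,
                    "RMSECV": report.RMSECV,
                    "Rp": report.Rp,
                    "RMSEP": report.RMSEP,
                })
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    report_df = pd.DataFrame(rows)
    report_df.to_csv(outdir / "report.csv", index=False)
    (outdir / "report.txt").write_text(_format_report(report_df))

    # --- map --------------------------------------------------------------
    stage = "map"
    panel_path = None
    if cfg.cube_rendering != "none":
        try:
            best = report_df.loc[report_df["Rp"].idxmax()]
            best_model = fitted[(best["selector"], best["engine"])]
            panel_path = _render_maps(
                cfg, best_model, selections[best["selector"]], outdir
            )
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    return {
        "outdir": outdir,
        "table": table,
        "split": (cal_idx, pred_idx),
        "selections": selections,
        "report": report_df,
        "models": fitted,
        "map_panel": panel_path,
    }


def _format_report(df: pd.DataFrame) -> str:
    lines = [
        f"{'Selector':<8} {'Vars':>5} {'Model':<7} {'Parameter':<24} "
        f"{'Rc':>7} {'RMSECV':>8} {'Rp':>7} {'RMSEP':>8}"
    ]
    names = {"pls": "PLS", "lssvm": "LS-SVM", "elm": "ELM"}
    for _, r in df.iterrows():
        lines.append(
            f"{r['selector']:<8} {r['n_vars']:>5} {names.get(r['engine'], r['engine']):<7} "
            f"{r['parameter']:<24} {r['Rc']:>7.4f} {r['RMSECV']:>8.4f} "
            f"{r['Rp']:>7.4f} {r['RMSEP']:>8.4f}"
        )
    return "\n".join(lines) + "\n"
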