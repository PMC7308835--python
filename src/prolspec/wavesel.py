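"""Wavelength selection: CARS, a binary GA, and Bw coefficient extrema.

All three operate on a calibration SpectraTable-style (X, y) pair and return
a :class:`SelectionResult` with sorted unique band indices, their wavelengths
and a diagnostic trace.

CARS (competitive adaptive reweighted sampling) alternates Monte-Carlo
subsampling of samples, PLS fitting, an exponentially decreasing forced
retention of the largest-|b| bands, and |b|-weighted resampling of the
survivors; the subset with minimal leave-one-out RMSECV over all iterations
is returned.

Bw reads characteristic wavelengths directly off the signed PLS regression
vector: strict interior local maxima (peaks) and minima (valleys).

The GA evolves binary chromosomes over bands with tournament selection,
single-point crossover, bit-flip mutation and 1-elitism; fitness is the
negative LOO-RMSECV of a PLS model on the encoded bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import PLSModel, _nipals, _pls_fit_fixed, _validate_xy
from .grid import WavelengthGrid

__all__ = ["SelectionResult", "cars_select", "ga_select", "bw_select"]


@dataclass
class SelectionResult:
    """Outcome of a wavelength-selection run."""

    method: str
    indices: np.ndarray
    wavelengths: np.ndarray
    trace: pd.DataFrame
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size < 1:
            raise ValueError("selection must keep at least one band")
        if np.unique(idx).size != idx.size:
            raise ValueError("selected indices must be unique")
        order = np.argsort(idx)
        self.indices = idx[order]
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)[order]

    @property
    def n_selected(self) -> int:
        return int(self.indices.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"index": self.indices, "wavelength_nm": self.wavelengths}
        )


def _loo_rmsecv_pls(X: np.ndarray, y: np.ndarray, n_lv: int) -> float:
    """LOO-RMSECV of a fixed-LV PLS model (per-fold NIPALS refits)."""
    n = X.shape[0]
    a = min(n_lv, n - 2, X.shape[1])
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        Xi, yi = X[keep], y[keep]
        xm = Xi.mean(axis=0)
        ym = yi.mean()
        B = _nipals(Xi - xm, yi - ym, a)
        preds[i] = (X[i] - xm) @ B[:, a - 1] + ym
    return float(np.sqrt(np.mean((preds - y) ** 2)))


def _pls_b(X: np.ndarray, y: np.ndarray, n_lv: int) -> np.ndarray:
    a = min(n_lv, X.shape[0] - 1, X.shape[1])
    xm = X.mean(axis=0)
    B = _nipals(X - xm, y - y.mean(), a)
    return B[:, a - 1]


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    grid: WavelengthGrid | None = None,
    n_iterations: int = 50,
    mc_ratio: float = 0.8,
    n_lv: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    The enforced retention ratio at iteration i follows the exponentially
    decreasing function r_i = a*exp(-k*i) with a, k fixed by r_1 = 1 and
    r_N = 2/p, so the run starts from the full spectrum and ends at two
    bands.  Retained-band counts are non-increasing across iterations.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    if n_iterations < 2:
        raise ValueError("need at least 2 iterations")
    if p < 2:
        raise ValueError("need at least 2 bands")
    if not 0 < mc_ratio <= 1:
        raise ValueError("mc_ratio must be in (0, 1]")
    rng = np.random.default_rng(seed)
    # EDF constants from r_1 = 1, r_N = 2/p
    a_edf = (p / 2.0) ** (1.0 / (n_iterations - 1))
    k_edf = np.log(p / 2.0) / (n_iterations - 1)
    n_mc = max(int(round(mc_ratio * n)), 3)

    current = np.arange(p)
    rows = []
    subsets: list[np.ndarray] = []
    for it in range(1, n_iterations + 1):
        sub = rng.choice(n, size=n_mc, replace=False)
        b = _pls_b(X[np.ix_(sub, current)], y[sub], n_lv)
        weights = np.abs(b)
        if weights.sum() <= 0:
            weights = np.ones_like(weights)
        ratio = a_edf * np.exp(-k_edf * it)
        n_keep = int(round(ratio * p))
        n_keep = max(2, min(n_keep, current.size))
        order = np.argsort(weights)[::-1]
        sel = np.sort(order[:n_keep])
        survivors = current[sel]
        w_surv = weights[sel]
        # adaptive reweighted sampling among survivors, proportional to |b|
        probs = w_surv / w_surv.sum()
        picks = rng.choice(survivors.size, size=n_keep, replace=True, p=probs)
        retained = np.unique(survivors[picks])
        if retained.size < 2:
            retained = survivors[np.argsort(w_surv)[::-1][:2]]
            retained = np.sort(retained)
        if retained.size == 0:
            raise RuntimeError(f"all bands eliminated at iteration {it}")
        current = retained
        score = _loo_rmsecv_pls(X[:, current], y, n_lv)
        rows.append((it, ratio, current.size, score))
        subsets.append(current.copy())
    trace = pd.DataFrame(rows, columns=["iteration", "edf_ratio", "n_retained", "rmsecv"])
    best = int(trace["rmsecv"].idxmin())
    chosen = subsets[best]
    wl = grid.centers[chosen] if grid is not None else chosen.astype(float)
    return SelectionResult(
        "CARS", chosen, wl, trace, seed,
        extras={"best_iteration": best + 1, "n_lv": n_lv},
    )


def bw_select(
    model: PLSModel,
    grid: WavelengthGrid | None = None,
    min_abs_quantile: float | None = None,
) -> SelectionResult:
    """Characteristic wavelengths at the peaks and valleys of the PLS b vector.

    Strict interior local maxima and minima of the signed coefficient profile
    (plateau points excluded); optionally keep only extrema whose |b| exceeds
    the given quantile of |b|.  Raises ValueError if b has no extrema.
    """
    b = np.asarray(model.coef, dtype=float)
    if b.size < 3:
        raise ValueError("need at least 3 bands to find interior extrema")
    interior = np.arange(1, b.size - 1)
    peaks = interior[(b[1:-1] > b[:-2]) & (b[1:-1] > b[2:])]
    valleys = interior[(b[1:-1] < b[:-2]) & (b[1:-1] < b[2:])]
    idx = np.sort(np.concatenate([peaks, valleys]))
    if min_abs_quantile is not None:
        cut = np.quantile(np.abs(b), min_abs_quantile)
        idx = idx[np.abs(b[idx]) >= cut]
    if idx.size == 0:
        raise ValueError("coefficient profile has no strict interior extrema")
    trace = pd.DataFrame({"index": np.arange(b.size), "b": b})
    wl = grid.centers[idx] if grid is not None else idx.astype(float)
    return SelectionResult("Bw", idx, wl, trace, None, extras={"n_lv": model.n_lv})


def ga_select(
    X: np.ndarray,
    y: np.ndarray,
    grid: WavelengthGrid | None = None,
    pop_size: int = 30,
    n_generations: int = 100,
    p_crossover: float = 0.6,
    p_mutation: float = 0.01,
    n_lv: int = 10,
    seed: int = 0,
    init_include_prob: float = 0.5,
    initial_population: np.ndarray | None = None,
) -> SelectionResult:
    """Binary-chromosome genetic algorithm over bands.

    Fitness is -(LOO-RMSECV of a fixed-LV PLS on the encoded bands); an
    all-zero chromosome receives -inf and can never be returned.  Tournament
    selection (size 2), single-point crossover, per-bit mutation, elitism of
    one.  Same seed, same arguments -> identical result.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    if pop_size < 4 or pop_size % 2:
        raise ValueError("pop_size must be even and at least 4")
    rng = np.random.default_rng(seed)
    if initial_population is not None:
        pop = np.asarray(initial_population, dtype=bool).copy()
        if pop.shape != (pop_size, p):
            raise ValueError("initial_population must be (pop_size, p)")
    else:
        pop = rng.random((pop_size, p)) < init_include_prob
        for chrom in pop:  # repair empty chromosomes
            if not chrom.any():
                chrom[rng.integers(p)] = True

    cache: dict[bytes, float] = {}

    def fitness(chrom: np.ndarray) -> float:
        if not chrom.any():
            return -np.inf
        key = np.packbits(chrom).tobytes()
        if key not in cache:
            cache[key] = -_loo_rmsecv_pls(X[:, chrom], y, n_lv)
        return cache[key]

    fits = np.array([fitness(c) for c in pop])
    best_hist = []
    for gen in range(n_generations):
        elite = pop[int(np.argmax(fits))].copy()
        children = [elite]
        while len(children) < pop_size:
            parents = []
            for _ in range(2):
                i, j = rng.integers(pop_size, size=2)
                parents.append(pop[i if fits[i] >= fits[j] else j].copy())
            if rng.random() < p_crossover and p > 1:
                cut = int(rng.integers(1, p))
                parents[0][cut:], parents[1][cut:] = (
                    parents[1][cut:].copy(), parents[0][cut:].copy()
                )
            for child in parents:
                flip = rng.random(p) < p_mutation
                child ^= flip
                children.append(child)
        pop = np.array(children[:pop_size])
        fits = np.array([fitness(c) for c in pop])
        best_hist.append((gen + 1, float(np.max(fits)), int(pop[np.argmax(fits)].sum())))
    best = pop[int(np.argmax(fits))]
    idx = np.flatnonzero(best)
    trace = pd.DataFrame(best_hist, columns=["generation", "best_fitness", "n_selected"])
    wl = grid.centers[idx] if grid is not None else idx.astype(float)
    return SelectionResult(
        "GA", idx, wl, trace, seed,
        extras={"n_lv": n_lv, "best_fitness": float(np.max(fits))},
    )
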