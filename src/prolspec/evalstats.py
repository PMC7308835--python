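"""Sample splitting, model evaluation, per-band ANOVA and letter displays.

The calibration/prediction split is rank-based: samples are ordered by their
FP reference value and, within each consecutive block of four, the third
goes to the prediction set — a deterministic 3:1 split that keeps the
prediction set interior to the calibration range (100 samples -> 75/25).

Rc/RMSECV are computed from leave-one-out refits on the calibration set with
the model's chosen hyperparameters held fixed; Rp/RMSEP come from the model
fitted on the full calibration set applied to the untouched prediction set.
R metrics are Pearson correlations between predicted and reference values.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import SpectraTable

__all__ = [
    "EvaluationReport",
    "AnovaProfile",
    "LetterDisplay",
    "rank_split",
    "evaluate",
    "wavelength_anova",
    "group_letters",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Calibration and prediction performance of one fitted model."""

    Rc: float
    RMSECV: float
    Rp: float
    RMSEP: float
    n_cal: int
    n_pred: int

    def __post_init__(self) -> None:
        if self.RMSECV < 0 or self.RMSEP < 0:
            raise ValueError("RMSEs must be non-negative")
        if abs(self.Rc) > 1 + 1e-12 or abs(self.Rp) > 1 + 1e-12:
            raise ValueError("|R| cannot exceed 1")


@dataclass(frozen=True)
class AnovaProfile:
    """Per-band one-way ANOVA p-values against a grouping factor."""

    pvalues: np.ndarray
    factor: str
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return self.pvalues < self.alpha

    @property
    def fraction_significant(self) -> float:
        return float(np.mean(self.significant))


@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter display over groups plus the pairwise p-value matrix."""

    letters: dict
    pvalues: pd.DataFrame
    alpha: float = 0.05


def rank_split(y: np.ndarray, ratio: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic rank-based calibration/prediction split.

    Samples are sorted by ``y`` ascending (ties broken by original index);
    within each full block of ``round(1/ratio)`` consecutive ranks the
    second-to-last goes to prediction, the rest to calibration; a trailing
    partial block goes entirely to calibration.  The default ratio 0.25
    reproduces the 1-in-4 rule (third of every four).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    block = int(round(1.0 / ratio))
    if block < 2:
        raise ValueError("ratio must give blocks of at least 2")
    if n < block:
        raise ValueError(f"need at least {block} samples")
    order = np.argsort(y, kind="stable")
    pick = block - 2  # third position in a block of four
    pred, cal = [], []
    for start in range(0, n, block):
        chunk = order[start:start + block]
        if chunk.size == block:
            for j, idx in enumerate(chunk):
                (pred if j == pick else cal).append(idx)
        else:  # trailing partial block
            cal.extend(chunk)
    return np.sort(np.array(cal, dtype=int)), np.sort(np.array(pred, dtype=int))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("correlation undefined for constant input; reporting 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def evaluate(
    model,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_pred: np.ndarray,
    y_pred: np.ndarray,
) -> EvaluationReport:
    """Score a fitted model: LOO on calibration, straight pass on prediction.

    ``model`` must expose ``predict`` and ``refit(X, y)`` (refit with fixed
    hyperparameters); it is assumed fitted on the full calibration set.
    """
    X_cal = np.asarray(X_cal, float)
    y_cal = np.asarray(y_cal, float).ravel()
    X_pred = np.asarray(X_pred, float)
    y_pred = np.asarray(y_pred, float).ravel()
    if y_pred.size == 0:
        raise ValueError("empty prediction set")
    n = y_cal.size
    loo_preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        sub = model.refit(X_cal[keep], y_cal[keep])
        loo_preds[i] = sub.predict(X_cal[i][None, :])[0]
    yhat_pred = np.asarray(model.predict(X_pred)).ravel()
    return EvaluationReport(
        Rc=_pearson(y_cal, loo_preds),
        RMSECV=float(np.sqrt(np.mean((loo_preds - y_cal) ** 2))),
        Rp=_pearson(y_pred, yhat_pred),
        RMSEP=float(np.sqrt(np.mean((yhat_pred - y_pred) ** 2))),
        n_cal=int(n),
        n_pred=int(y_pred.size),
    )


def wavelength_anova(
    table: SpectraTable, factor: str = "cd_um", day: int | None = None
) -> AnovaProfile:
    """One-way ANOVA of reflectance against ``factor``, per band.

    With ``day`` given, rows are first restricted to that stress day so the
    factor compares concentration groups within the day.  Every group needs
    at least 2 members.
    """
    X = table.X
    labels = table.labels
    if day is not None:
        keep = labels["day"].to_numpy() == day
        X = X[keep]
        labels = labels[keep]
    groups = labels[factor].to_numpy()
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("need at least 2 groups")
    arrays = [X[groups == g] for g in levels]
    if any(a.shape[0] < 2 for a in arrays):
        raise ValueError("every group needs at least 2 members")
    result = stats.f_oneway(*arrays, axis=0)
    name = factor if day is None else f"{factor} | day={day}"
    return AnovaProfile(pvalues=np.asarray(result.pvalue), factor=name)


def _letters_from_pairs(levels: list, nonsig: dict, means: dict) -> dict:
    """Insert-and-absorb compact letter display.

    Columns (letter groups) are split until no column joins a significantly
    different pair; groups sharing a letter are exactly the pairs whose
    comparison is not significant.
    """
    columns: list[set] = [set(levels)]
    for i, gi in enumerate(levels):
        for gj in levels[i + 1:]:
            if nonsig[(gi, gj)]:
                continue
            for col in [c for c in columns if gi in c and gj in c]:
                columns.remove(col)
                columns.extend([col - {gi}, col - {gj}])
            # absorb: drop columns contained in another
            columns = [
                c for c in columns
                if c and not any(c < d for d in columns if d is not c)
            ]
    # deduplicate while keeping order by group mean
    uniq: list[set] = []
    for c in columns:
        if c not in uniq:
            uniq.append(c)
    uniq.sort(key=lambda c: min(means[g] for g in c))
    letters = {g: "" for g in levels}
    for char, col in zip(string.ascii_lowercase, uniq):
        for g in sorted(col, key=lambda g: means[g]):
            letters[g] += char
    return letters


def group_letters(
    values: np.ndarray, groups: np.ndarray, alpha: float = 0.05
) -> LetterDisplay:
    """Tukey-HSD all-pairs comparison summarised as a compact letter display.

    Two groups share a letter iff their pairwise comparison is not
    significant at ``alpha``.  Letters are assigned in order of increasing
    group mean (``a`` = lowest).
    """
    values = np.asarray(values, dtype=float).ravel()
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [values[groups == g] for g in levels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 members")
    res = stats.tukey_hsd(*arrays)
    pmat = pd.DataFrame(res.pvalue, index=levels, columns=levels)
    means = {g: float(a.mean()) for g, a in zip(levels, arrays)}
    nonsig = {}
    for i, gi in enumerate(levels):
        for j, gj in enumerate(levels):
            nonsig[(gi, gj)] = res.pvalue[i, j] >= alpha
    letters = _letters_from_pairs(levels, nonsig, means)
    return LetterDisplay(letters=letters, pvalues=pmat, alpha=alpha)
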