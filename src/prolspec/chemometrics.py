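"""Calibration engines: NIPALS-PLS, LS-SVM (RBF) and ELM regression.

All three select their hyperparameter (latent-variable count, (gam, sig2)
pair, hidden-node count) at the minimum leave-one-out RMSECV, with ties
broken toward the simpler model.  Cross-validation is implemented as literal
per-fold refits — every left-out sample is predicted by a model fitted on
the remaining n-1 — so reported RMSECVs are exactly the quantity a naive
double loop computes.

X and y are mean-centred for PLS (no autoscaling: reflectance bands share a
common unit).  The PLS regression vector over bands, ``b``, is the weighted
regression coefficient profile that the Bw and CARS selectors consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "LSSVMModel",
    "ELMModel",
    "CVResult",
    "pls_fit",
    "pls_predict",
    "lssvm_fit",
    "elm_fit",
    "loocv_rmsecv",
]


@dataclass
class CVResult:
    """Cross-validation trace of a hyperparameter search."""

    candidates: list
    rmsecv: np.ndarray
    chosen: object

    def __post_init__(self) -> None:
        self.rmsecv = np.asarray(self.rmsecv, dtype=float)
        if len(self.candidates) != self.rmsecv.size:
            raise ValueError("one RMSECV per candidate required")


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


# ---------------------------------------------------------------------------
# PLS


def _nipals(Xc: np.ndarray, yc: np.ndarray, a_max: int) -> np.ndarray:
    """NIPALS decomposition of mean-centred data.

    Returns the (p, a_max) matrix whose column a-1 is the regression vector
    using the first a latent variables.  If the residual is exhausted before
    a_max components, later columns repeat the last valid one.
    """
    X = Xc.copy()
    y = yc.copy()
    p = X.shape[1]
    B = np.zeros((p, a_max))
    R_cols: list[np.ndarray] = []   # W (P'W)^{-1} built incrementally
    P_cols: list[np.ndarray] = []
    b = np.zeros(p)
    scale = max(float(np.abs(yc) @ np.abs(yc)), 1e-300)
    for a in range(a_max):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * np.sqrt(scale):
            B[:, a:] = b[:, None]
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= 1e-30:
            B[:, a:] = b[:, None]
            break
        pl = X.T @ t / tt
        q = float(y @ t / tt)
        X -= np.outer(t, pl)
        y = y - q * t
        # r_a = w_a - sum_j r_j (p_j . w_a): maps original X to score t_a
        r = w.copy()
        for rj, pj in zip(R_cols, P_cols):
            r -= rj * float(pj @ w)
        R_cols.append(r)
        P_cols.append(pl)
        b = b + q * r
        B[:, a] = b
    else:
        return B
    return B


@dataclass
class PLSModel:
    """Fitted PLS regression model."""

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray  # regression vector b over bands (the Bw profile)

    @property
    def b(self) -> np.ndarray:
        return self.coef

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.coef.size:
            raise ValueError(
                f"band count {X.shape[1]} != training band count {self.coef.size}"
            )
        return (X - self.x_mean) @ self.coef + self.y_mean

    def refit(self, X: np.ndarray, y: np.ndarray) -> "PLSModel":
        """Refit on new data with the same latent-variable count."""
        return _pls_fit_fixed(X, y, self.n_lv)


def _validate_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) with one y per row")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; nothing to regress")
    if np.all(np.ptp(X, axis=0) == 0):
        raise ValueError("X has zero variance everywhere")
    return X, y


def _pls_fit_fixed(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    X, y = _validate_xy(X, y)
    xm = X.mean(axis=0)
    ym = float(y.mean())
    B = _nipals(X - xm, y - ym, n_lv)
    return PLSModel(n_lv=n_lv, x_mean=xm, y_mean=ym, coef=B[:, n_lv - 1])


def pls_fit(
    X: np.ndarray, y: np.ndarray, max_lv: int | None = None
) -> tuple[PLSModel, CVResult]:
    """Fit PLS with the LV count chosen at minimum leave-one-out RMSECV.

    Candidates are 1..max_lv (default min(n-1, p, 15)); ties go to the
    smallest LV.  Returns the model refitted on all data at the chosen LV
    and the full RMSECV trace.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if max_lv is None:
        max_lv = min(n - 1, p, 15)
    if not 1 <= max_lv <= min(n - 1, p):
        raise ValueError(f"max_lv must be in [1, {min(n - 1, p)}]")
    preds = np.empty((n, max_lv))
    for i in range(n):
        keep = np.arange(n) != i
        Xi, yi = X[keep], y[keep]
        xm = Xi.mean(axis=0)
        ym = yi.mean()
        B = _nipals(Xi - xm, yi - ym, max_lv)
        preds[i] = (X[i] - xm) @ B + ym
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    chosen = int(np.argmin(rmsecv)) + 1  # argmin takes the first (smallest) LV
    model = _pls_fit_fixed(X, y, chosen)
    return model, CVResult(list(range(1, max_lv + 1)), rmsecv, chosen)


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


# ---------------------------------------------------------------------------
# LS-SVM


def _rbf_kernel(sq_dists: np.ndarray, sig2: float) -> np.ndarray:
    return np.exp(-sq_dists / sig2)


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    aa = np.sum(A * A, axis=1)[:, None]
    bb = np.sum(B * B, axis=1)[None, :]
    return np.maximum(aa + bb - 2.0 * A @ B.T, 0.0)


def _lssvm_solve(K: np.ndarray, y: np.ndarray, gam: float):
    """Solve the LS-SVM dual KKT system; returns (alpha, bias)."""
    n = K.shape[0]
    A = np.empty((n + 1, n + 1))
    A[0, 0] = 0.0
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gam
    rhs = np.concatenate(([0.0], y))
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular LS-SVM system (degenerate kernel)") from exc
    return sol[1:], float(sol[0])


@dataclass
class LSSVMModel:
    """LS-SVM regression with an RBF kernel."""

    alpha: np.ndarray
    bias: float
    gam: float
    sig2: float
    X_train: np.ndarray
    kkt_residual: float = 0.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.X_train.shape[1]:
            raise ValueError("band count mismatch")
        K = _rbf_kernel(_sq_dists(X, self.X_train), self.sig2)
        return K @ self.alpha + self.bias

    def refit(self, X: np.ndarray, y: np.ndarray) -> "LSSVMModel":
        """Refit on new data with the same (gam, sig2)."""
        return _lssvm_fit_fixed(np.asarray(X, float), np.asarray(y, float),
                                self.gam, self.sig2)


def _lssvm_fit_fixed(X, y, gam, sig2) -> LSSVMModel:
    K = _rbf_kernel(_sq_dists(X, X), sig2)
    alpha, bias = _lssvm_solve(K, y, gam)
    n = X.shape[0]
    resid = np.concatenate((
        [np.sum(alpha)],
        (K + np.eye(n) / gam) @ alpha + bias - y,
    ))
    kkt = float(np.max(np.abs(resid)))
    if kkt > 1e-8 * max(1.0, float(np.max(np.abs(y)))):
        raise ValueError(f"LS-SVM KKT residual {kkt:.2e} exceeds tolerance")
    return LSSVMModel(alpha, bias, float(gam), float(sig2), X, kkt)


def default_gam_grid() -> np.ndarray:
    return np.logspace(0, 7, 8)


def default_sig2_grid() -> np.ndarray:
    return np.logspace(0, 6, 7)


def _lssvm_loo(X, y, gam, sig2) -> float:
    n = X.shape[0]
    K = _rbf_kernel(_sq_dists(X, X), sig2)
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        alpha, bias = _lssvm_solve(K[np.ix_(keep, keep)], y[keep], gam)
        preds[i] = K[i, keep] @ alpha + bias
    return _rmse(preds, y)


def lssvm_fit(
    X: np.ndarray,
    y: np.ndarray,
    gam_grid: np.ndarray | None = None,
    sig2_grid: np.ndarray | None = None,
    refine: bool = True,
) -> tuple[LSSVMModel, CVResult]:
    """Grid-search (gam, sig2) by leave-one-out RMSECV and refit on all data.

    A coarse log-spaced grid (10^0..10^7 x 10^0..10^6 by default) is scanned
    first and, with ``refine``, a 5x5 half-decade grid around the optimum is
    scanned once more.  Ties prefer the smaller gam, then the smaller sig2.
    """
    X, y = _validate_xy(X, y)
    gam_grid = default_gam_grid() if gam_grid is None else np.asarray(gam_grid, float)
    sig2_grid = default_sig2_grid() if sig2_grid is None else np.asarray(sig2_grid, float)
    if gam_grid.size == 0 or sig2_grid.size == 0:
        raise ValueError("hyperparameter grids must be non-empty")
    if np.any(gam_grid <= 0) or np.any(sig2_grid <= 0):
        raise ValueError("gam and sig2 must be positive")

    def scan(ggrid, sgrid):
        cands, scores = [], []
        for g in sorted(ggrid):
            for s in sorted(sgrid):
                cands.append((float(g), float(s)))
                scores.append(_lssvm_loo(X, y, g, s))
        return cands, np.array(scores)

    cands, scores = scan(gam_grid, sig2_grid)
    best = cands[int(np.argmin(scores))]
    if refine:
        g0, s0 = best
        fine = np.array([10 ** e for e in (-0.5, -0.25, 0.0, 0.25, 0.5)])
        c2, s2 = scan(g0 * fine, s0 * fine)
        cands += c2
        scores = np.concatenate([scores, s2])
        best = cands[int(np.argmin(scores))]
    model = _lssvm_fit_fixed(X, y, *best)
    return model, CVResult(cands, scores, best)


# ---------------------------------------------------------------------------
# ELM


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class ELMModel:
    """Extreme learning machine: random sigmoid hidden layer + LS output."""

    n_nodes: int
    seed: int
    w_in: np.ndarray    # (p, n_nodes) random input weights
    b_in: np.ndarray    # (n_nodes,) random biases
    beta: np.ndarray    # (n_nodes,) least-squares output weights
    x_lo: float         # global input scaling: reflectance bands share one
    x_hi: float         # unit, so a single min-max pair maps X to [-1, 1]

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        span = self.x_hi - self.x_lo if self.x_hi > self.x_lo else 1.0
        Xs = 2.0 * (X - self.x_lo) / span - 1.0
        return _sigmoid(Xs @ self.w_in + self.b_in)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.w_in.shape[0]:
            raise ValueError("band count mismatch")
        return self._hidden(X) @ self.beta

    def refit(self, X: np.ndarray, y: np.ndarray) -> "ELMModel":
        """Refit output weights on new data; same seed, node count and scaling."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        H = self._hidden(X)
        beta, *_ = np.linalg.lstsq(H, np.asarray(y, float), rcond=None)
        return ELMModel(self.n_nodes, self.seed, self.w_in, self.b_in,
                        beta, self.x_lo, self.x_hi)


def _elm_draw(p: int, n_nodes: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    w = rng.uniform(-1.0, 1.0, size=(p, n_nodes))
    b = rng.uniform(-1.0, 1.0, size=n_nodes)
    return w, b


def elm_fit(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    node_range: range | None = None,
    selection: str = "loo",
    pred_set: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[ELMModel, CVResult]:
    """Fit an ELM, selecting the hidden-node count over ``node_range``.

    Input weights/biases are uniform(-1, 1) draws from ``seed`` for the
    largest candidate; a k-node model uses the first k of them.  Inputs are
    min-max scaled to [-1, 1] per band using the training data.  Selection:

    - ``"loo"`` (default): minimum leave-one-out RMSECV, ties to fewer nodes.
    - ``"rmsep"``: minimum RMSE on ``pred_set`` — the reference procedure of
      the emulated study; note it leaks the prediction set into model choice.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    if node_range is None:
        node_range = range(1, n + 1)
    nodes = [int(k) for k in node_range]
    if not nodes:
        raise ValueError("empty node range")
    if min(nodes) < 1 or max(nodes) > n:
        raise ValueError(f"node counts must lie in [1, {n}]")
    w_all, b_all = _elm_draw(p, max(nodes), seed)

    def fixed_model(k: int, Xf: np.ndarray, yf: np.ndarray) -> ELMModel:
        m = ELMModel(k, seed, w_all[:, :k], b_all[:k], np.zeros(k),
                     float(Xf.min()), float(Xf.max()))
        return m.refit(Xf, yf)

    scores = np.empty(len(nodes))
    if selection == "loo":
        for ki, k in enumerate(nodes):
            preds = np.empty(n)
            for i in range(n):
                keep = np.arange(n) != i
                m = fixed_model(k, X[keep], y[keep])
                preds[i] = m.predict(X[i][None, :])[0]
            scores[ki] = _rmse(preds, y)
    elif selection == "rmsep":
        if pred_set is None:
            raise ValueError("selection='rmsep' requires pred_set=(X_pred, y_pred)")
        Xp, yp = pred_set
        for ki, k in enumerate(nodes):
            m = fixed_model(k, X, y)
            scores[ki] = _rmse(m.predict(Xp), yp)
    else:
        raise ValueError(f"unknown selection {selection!r}")
    chosen = nodes[int(np.argmin(scores))]  # first minimum = fewest nodes
    model = fixed_model(chosen, X, y)
    return model, CVResult(nodes, scores, chosen)


# ---------------------------------------------------------------------------
# Generic leave-one-out cross-validation


def loocv_rmsecv(fit, X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Leave-one-out RMSECV of an arbitrary fitting procedure.

    ``fit(X_train, y_train)`` must return a predictor: either a callable or
    an object with ``.predict``.  Returns (rmsecv, per-fold predictions).
    A fit failure is re-raised annotated with the fold index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for LOO")
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            model = fit(X[keep], y[keep])
        except Exception as exc:
            raise RuntimeError(f"fit failed on LOO fold {i}: {exc}") from exc
        predict = model.predict if hasattr(model, "predict") else model
        preds[i] = np.asarray(predict(X[i][None, :])).ravel()[0]
    return _rmse(preds, y), preds
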