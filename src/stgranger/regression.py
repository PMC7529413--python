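"""Lagged linear models with ASO multi-task learning.

Granger-causality testing compares two nested lagged regressions of a
target pixel series Y:

* the *base* model uses an intercept plus lags 1..P of Y and of the
  conditional variable(s) X2;
* the *full* model additionally includes lags 1..P of the candidate
  cause X1.

There is no lag-0 predictor: a cause cannot act instantaneously.  With
P=10 and three system variables the base model has k = 1 + 2*10 = 21
coefficients and the full model k = 1 + 3*10 = 31.

Because the fields are spatially correlated, the per-pixel regressions
are fitted jointly by alternating structure optimization (ASO): each
pixel's weight vector is decomposed as ``w_l = u_l + v_l @ Theta`` with
a shared h-dimensional subspace ``Theta`` (orthonormal rows,
``Theta @ Theta.T = I``), and the objective

    sum_l [ ||X_l w_l - y_l||^2 + lam * ||u_l||^2 ]

is minimized by alternating an L-BFGS pass over (u, v) with Theta fixed
and a closed-form Theta update from the SVD of the stacked weights.
With lam = 0 the penalty vanishes and the fit reproduces independent
per-pixel least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import optimize

__all__ = [
    "LaggedDesign",
    "FitResult",
    "MTLWeights",
    "build_lagged_design",
    "build_design_stack",
    "fit_ols",
    "fit_aso_mtl",
    "predict",
]

logger = logging.getLogger(__name__)


@dataclass
class LaggedDesign:
    """Target vector and lagged predictor matrix for one pixel.

    ``X`` has shape (N, k) with N = T - P rows indexed t = P+1..T and a
    fixed column order: intercept, Y lags 1..P, conditional-variable
    lags 1..P (one block per conditional), then — for the full model —
    cause lags 1..P.
    """

    X: np.ndarray
    y: np.ndarray
    P: int
    model_kind: str
    columns: list[str]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_coeffs(self) -> int:
        return self.X.shape[1]


@dataclass
class FitResult:
    """Predictions and residuals; ``yhat + resid`` reconstructs ``y`` exactly."""

    yhat: np.ndarray
    resid: np.ndarray

    @property
    def sse(self) -> np.ndarray | float:
        return (self.resid**2).sum(axis=-1)


@dataclass
class MTLWeights:
    """Fitted per-pixel weights with shared low-rank structure.

    ``W[l] = U[l] + V[l] @ Theta`` for every pixel l; ``Theta`` is
    (h, k) with orthonormal rows.
    """

    W: np.ndarray
    U: np.ndarray
    V: np.ndarray
    Theta: np.ndarray
    lam: float
    h: int
    columns: list[str]
    converged: bool = True
    n_iter: int = 0
    objective_history: list[float] = dc_field(default_factory=list)


def _lag_matrix(series: np.ndarray, P: int) -> np.ndarray:
    """Columns [x_{t-1}, ..., x_{t-P}] for t = P+1..T (shape (T-P, P))."""
    T = series.shape[0]
    return np.column_stack([series[P - p : T - p] for p in range(1, P + 1)])


def build_lagged_design(
    y: np.ndarray,
    x_cond: np.ndarray | list[np.ndarray],
    x_cause: np.ndarray | None = None,
    P: int = 10,
    model_kind: str | None = None,
    cond_names: list[str] | None = None,
    cause_name: str = "x_cause",
) -> LaggedDesign:
    """Build the base or full lagged design for one pixel.

    ``model_kind`` defaults to "full" when ``x_cause`` is given, else
    "base".  All series must share length T with T > P (at least one
    regression row).  Identifiability (N = T - P > k) is enforced where
    models are actually fitted jointly (:func:`build_design_stack`);
    building a short design is allowed so its rows can be inspected.
    """
    y = np.asarray(y, dtype=float)
    conds = [np.asarray(x_cond, dtype=float)] if isinstance(x_cond, np.ndarray) else [
        np.asarray(x, dtype=float) for x in x_cond
    ]
    if model_kind is None:
        model_kind = "full" if x_cause is not None else "base"
    if model_kind not in ("base", "full"):
        raise ValueError(f"model_kind must be 'base' or 'full', got {model_kind!r}")
    if model_kind == "full" and x_cause is None:
        raise ValueError("full model requires the cause series")

    T = y.shape[0]
    n_blocks = 1 + len(conds) + (1 if model_kind == "full" else 0)
    k = 1 + n_blocks * P
    if T <= P:
        raise ValueError(f"series too short: T={T} leaves no rows at lag P={P}")
    for s in conds + ([np.asarray(x_cause, dtype=float)] if x_cause is not None else []):
        if s.shape[0] != T:
            raise ValueError("all series must share the same length")

    if cond_names is None:
        cond_names = [f"x_cond{i + 1}" for i in range(len(conds))]
    blocks = [np.ones((T - P, 1)), _lag_matrix(y, P)]
    columns = ["intercept"] + [f"y_lag{p}" for p in range(1, P + 1)]
    for name, s in zip(cond_names, conds):
        blocks.append(_lag_matrix(s, P))
        columns += [f"{name}_lag{p}" for p in range(1, P + 1)]
    if model_kind == "full":
        blocks.append(_lag_matrix(np.asarray(x_cause, dtype=float), P))
        columns += [f"{cause_name}_lag{p}" for p in range(1, P + 1)]
    X = np.hstack(blocks)
    return LaggedDesign(X=X, y=y[P:], P=P, model_kind=model_kind, columns=columns)


def build_design_stack(
    Y: np.ndarray,
    X_cond: np.ndarray | list[np.ndarray],
    X_cause: np.ndarray | None = None,
    P: int = 10,
    model_kind: str | None = None,
    cond_names: list[str] | None = None,
    cause_name: str = "x_cause",
) -> list[LaggedDesign]:
    """Per-pixel designs from co-registered (T, L) series arrays.

    Unlike the single-pixel builder, this requires identifiable designs
    (N = T - P > k) since its output feeds the joint model fits.
    """
    conds = [X_cond] if isinstance(X_cond, np.ndarray) and X_cond.ndim == 2 else list(X_cond)
    T = Y.shape[0]
    n_blocks = 1 + len(conds) + (0 if X_cause is None else 1)
    k = 1 + n_blocks * P
    if T - P <= k:
        raise ValueError(f"series too short: T={T} gives N={T - P} <= k={k}")
    L = Y.shape[1]
    out = []
    for l in range(L):
        out.append(
            build_lagged_design(
                Y[:, l],
                [c[:, l] for c in conds],
                None if X_cause is None else X_cause[:, l],
                P=P,
                model_kind=model_kind,
                cond_names=cond_names,
                cause_name=cause_name,
            )
        )
    return out


def fit_ols(design: LaggedDesign) -> tuple[np.ndarray, FitResult, bool]:
    """Ordinary least squares for one pixel.

    Returns ``(weights, fit, rank_deficient)``.  A rank-deficient design
    yields the minimum-norm solution with the flag set.
    """
    w, _, rank, _ = np.linalg.lstsq(design.X, design.y, rcond=None)
    rank_deficient = rank < design.X.shape[1]
    if rank_deficient:
        logger.warning("fit_ols: rank-deficient design (rank %d < k=%d); minimum-norm solution", rank, design.X.shape[1])
    yhat = design.X @ w
    return w, FitResult(yhat=yhat, resid=design.y - yhat), rank_deficient


def predict(weights: np.ndarray, design: LaggedDesign) -> FitResult:
    """Model prediction Yhat = X @ w and residuals for one pixel."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != design.X.shape[1]:
        raise ValueError(
            f"weight dimension {weights.shape[0]} does not match design k={design.X.shape[1]}"
        )
    yhat = design.X @ weights
    return FitResult(yhat=yhat, resid=design.y - yhat)


def _top_subspace(W: np.ndarray, h: int, seed: int | None) -> np.ndarray:
    """Orthonormal (h, k) basis spanning the top right-singular directions
    of ``W``; completed with an orthonormal complement when ``W`` has
    fewer than ``h`` singular vectors (e.g. fewer pixels than h)."""
    _, _, Vt = np.linalg.svd(W, full_matrices=False)
    Theta = Vt[: min(h, Vt.shape[0])]
    missing = h - Theta.shape[0]
    if missing > 0:
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((W.shape[1], missing))
        A -= Theta.T @ (Theta @ A)
        Q, _ = np.linalg.qr(A)
        Theta = np.vstack([Theta, Q.T])
    return Theta


def _check_shared_structure(designs: list[LaggedDesign]) -> tuple[int, int]:
    d0 = designs[0]
    for d in designs[1:]:
        if d.X.shape != d0.X.shape or d.P != d0.P or d.model_kind != d0.model_kind:
            raise ValueError("all pixels must share an identical design structure")
    return d0.X.shape


def _aso_objective(
    params: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    Theta: np.ndarray,
    lam: float,
    L: int,
    k: int,
    h: int,
) -> tuple[float, np.ndarray]:
    """Vectorized ASO loss and gradient over all pixels' (u, v)."""
    U = params[: L * k].reshape(L, k)
    V = params[L * k :].reshape(L, h)
    W = U + V @ Theta
    resid = np.einsum("lnk,lk->ln", X, W) - Y
    loss = float((resid**2).sum() + lam * (U**2).sum())
    g_w = 2.0 * np.einsum("lnk,ln->lk", X, resid)
    g_u = g_w + 2.0 * lam * U
    g_v = g_w @ Theta.T
    return loss, np.concatenate([g_u.ravel(), g_v.ravel()])


def fit_aso_mtl(
    designs: list[LaggedDesign],
    lam: float = 0.1,
    h: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 30,
    lbfgs_maxiter: int = 500,
    seed: int | None = None,
) -> tuple[MTLWeights, FitResult]:
    """Fit all pixels jointly by alternating structure optimization.

    Parameters
    ----------
    designs:
        One :class:`LaggedDesign` per pixel, all sharing the same
        structure (P, model kind, column order).
    lam:
        Regularization weight on the pixel-specific component ``u``.
        ``lam = 0`` reduces to independent per-pixel least squares.
    h:
        Shared-subspace dimension (default ``min(5, k)``).
    tol:
        Relative objective change between alternations at which the fit
        is declared converged.
    max_iter:
        Maximum number of (u,v)/Theta alternations.
    seed:
        Used only if the SVD warm start degenerates and a random
        orthonormal Theta is required.

    Returns the fitted :class:`MTLWeights` and a batched
    :class:`FitResult` with ``yhat``/``resid`` of shape (L, N).
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    L = len(designs)
    N, k = _check_shared_structure(designs)
    if h is None:
        h = min(5, k)
    if not 1 <= h <= k:
        raise ValueError(f"subspace dimension h must lie in [1, k={k}]")

    X = np.stack([d.X for d in designs])  # (L, N, k)
    Y = np.stack([d.y for d in designs])  # (L, N)

    # Warm start: per-pixel OLS weights, Theta from their top singular vectors.
    W0 = np.einsum("lkn,ln->lk", np.linalg.pinv(X), Y)
    finite = np.isfinite(W0)
    if not finite.all():  # pragma: no cover - defensive
        W0 = np.where(finite, W0, 0.0)
    try:
        Theta = _top_subspace(W0, h, seed)
    except np.linalg.LinAlgError:  # pragma: no cover - randomized fallback
        rng = np.random.default_rng(seed)
        Theta = np.linalg.qr(rng.standard_normal((k, h)))[0].T
    V = W0 @ Theta.T
    U = W0 - V @ Theta

    params = np.concatenate([U.ravel(), V.ravel()])
    history: list[float] = []
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        res = optimize.minimize(
            _aso_objective,
            params,
            args=(X, Y, Theta, lam, L, k, h),
            method="L-BFGS-B",
            jac=True,
            options={"maxiter": lbfgs_maxiter},
        )
        params = res.x
        U = params[: L * k].reshape(L, k)
        V = params[L * k :].reshape(L, h)
        W = U + V @ Theta

        # Theta step: with W fixed, the penalty sum_l ||w_l - v_l Theta||^2 is
        # minimized by the top-h right singular vectors of the stacked weights.
        Theta = _top_subspace(W, h, seed)
        V = W @ Theta.T
        U = W - V @ Theta
        params = np.concatenate([U.ravel(), V.ravel()])

        resid = np.einsum("lnk,lk->ln", X, W) - Y
        obj = float((resid**2).sum() + lam * (U**2).sum())
        history.append(obj)
        if it >= 2:
            prev = history[-2]
            if prev - obj <= tol * max(abs(prev), 1.0):
                converged = True
                break
        if lam == 0.0 and it >= 1:
            converged = True  # penalty absent: Theta step cannot change the fit
            break

    if not converged:
        logger.warning("fit_aso_mtl: not converged after %d alternations; returning best iterate", max_iter)

    yhat = np.einsum("lnk,lk->ln", X, W)
    weights = MTLWeights(
        W=W,
        U=U,
        V=V,
        Theta=Theta,
        lam=lam,
        h=h,
        columns=list(designs[0].columns),
        converged=converged,
        n_iter=n_iter,
        objective_history=history,
    )
    return weights, FitResult(yhat=yhat, resid=Y - yhat)
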