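"""Per-pixel Granger-causality decisions.

For every ordered variable pair (cause -> effect) the full and base
lagged models are fitted (jointly across pixels via ASO multi-task
learning), their in-sample fit is summarized by the adjusted R^2

    R2_adj = 1 - (1 - R2) * (N - 1) / (N - k - 1)

and their predictions are compared by a one-sided Diebold–Mariano test
on the squared-error loss differential.  A pixel is marked causal iff

1. the full model's adjusted R^2 is positive,
2. it exceeds the base model's adjusted R^2, and
3. the Diebold–Mariano test rejects at level alpha (full model better).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fields import FieldStack, stack_pixel_series
from .features import zscore
from .regression import (
    FitResult,
    MTLWeights,
    build_design_stack,
    build_lagged_design,
    fit_aso_mtl,
    fit_ols,
)

__all__ = [
    "ModelComparison",
    "CausalityMap",
    "InferenceConfig",
    "r_squared",
    "adjusted_r_squared",
    "diebold_mariano",
    "decision_rule",
    "test_pixel",
    "causality_maps",
]

logger = logging.getLogger(__name__)


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float | np.ndarray:
    """Coefficient of determination over the evaluated points.

    ``R2 = 1 - SSE/SST`` with the total sum of squares taken about the
    mean of ``y`` over the same points.  Accepts batched input with the
    time axis last; returns NaN where SST is zero (degenerate target).
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must share a shape")
    sse = ((y - yhat) ** 2).sum(axis=-1)
    sst = ((y - y.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 1.0 - sse / sst
    return np.where(sst > 0, out, np.nan) if np.ndim(out) else (float(out) if sst > 0 else float("nan"))


def adjusted_r_squared(r2: float | np.ndarray, N: int, k: int) -> float | np.ndarray:
    """Adjusted R^2 penalizing the k model coefficients (excluding none).

    Requires N > k + 1 samples.
    """
    if N <= k + 1:
        raise ValueError(f"insufficient samples: N={N} must exceed k+1={k + 1}")
    return 1.0 - (1.0 - np.asarray(r2, dtype=float)) * (N - 1) / (N - k - 1)


def _bartlett_hac_variance(d: np.ndarray, hac_lags: int) -> np.ndarray:
    """HAC (Newey–West/Bartlett) variance of the mean of ``d`` (time axis last)."""
    n = d.shape[-1]
    dc = d - d.mean(axis=-1, keepdims=True)
    gamma0 = (dc**2).mean(axis=-1)
    acc = gamma0.copy()
    for j in range(1, min(hac_lags, n - 1) + 1):
        gj = (dc[..., j:] * dc[..., :-j]).sum(axis=-1) / n
        acc = acc + 2.0 * (1.0 - j / (hac_lags + 1.0)) * gj
    # a negative HAC estimate can occur in small samples; fall back to gamma0
    acc = np.where(acc > 0, acc, gamma0)
    return acc / n


def diebold_mariano(
    resid_full: np.ndarray,
    resid_base: np.ndarray,
    hac_lags: int = 10,
    alternative: str = "greater",
    k_full: int = 0,
    k_base: int = 0,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Diebold–Mariano comparison of squared prediction errors.

    The loss differential is ``d_t = e_base_t^2 - e_full_t^2``; the
    statistic is mean(d) over the autocorrelation-robust (Bartlett
    window, ``hac_lags``) standard error of the mean, referred to the
    standard normal.  ``alternative="greater"`` tests the one-sided
    hypothesis that the full model predicts better.  Batched input is
    supported with the time axis last.  If every ``d_t`` is zero the
    statistic is 0 and p = 1 (non-causal by convention).

    When the residuals are *in-sample* residuals of nested fitted
    models, the larger model mechanically shrinks its training error,
    which would bias the test toward the full model.  Passing the
    coefficient counts ``k_full``/``k_base`` rescales each squared loss
    by its unbiased variance factor N/(N-k) — the same penalty logic as
    the adjusted R^2 — restoring a mean-zero loss differential under
    the null.  With the default ``k=0`` the classical test on genuine
    forecast errors is performed unchanged.
    """
    ef = np.asarray(resid_full, dtype=float)
    eb = np.asarray(resid_base, dtype=float)
    if ef.shape != eb.shape:
        raise ValueError("residual vectors must share a shape")
    if ef.shape[-1] < 10:
        raise ValueError("Diebold–Mariano test needs at least 10 residuals")
    n = ef.shape[-1]
    if k_full >= n or k_base >= n:
        raise ValueError("coefficient counts must be smaller than the sample size")
    d = eb**2 * (n / (n - k_base)) - ef**2 * (n / (n - k_full))
    var = _bartlett_hac_variance(d, hac_lags)
    mean = d.mean(axis=-1)
    degenerate = var <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(degenerate, 0.0, mean / np.sqrt(np.where(degenerate, 1.0, var)))
    if alternative == "greater":
        p = stats.norm.sf(stat)
    elif alternative == "two-sided":
        p = 2.0 * stats.norm.sf(np.abs(stat))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = np.where(degenerate, 1.0, p)
    if np.ndim(stat) == 0:
        return float(stat), float(p)
    return stat, p


@dataclass
class ModelComparison:
    """Per-pixel diagnostics for one directed pair (arrays over pixels)."""

    r2_base: np.ndarray
    r2_full: np.ndarray
    adjr2_base: np.ndarray
    adjr2_full: np.ndarray
    dm_stat: np.ndarray
    dm_p: np.ndarray
    N: int
    k_base: int
    k_full: int

    @property
    def delta_adjr2(self) -> np.ndarray:
        return self.adjr2_full - self.adjr2_base


@dataclass
class CausalityMap:
    """Directed causality decision map and diagnostics on the grid."""

    cause: str
    effect: str
    conditional: str
    decision: np.ndarray  # (rows, cols) bool
    mask: np.ndarray
    alpha: float
    comparison: ModelComparison
    # grid-shaped diagnostic maps (NaN outside mask)
    dm_p: np.ndarray | None = None
    delta_adjr2: np.ndarray | None = None

    @property
    def causal_fraction(self) -> float:
        """Percent of masked pixels marked causal."""
        return 100.0 * self.decision[self.mask].mean()


@dataclass
class InferenceConfig:
    """Tunables of the inference stage (defaults as used throughout)."""

    P: int = 10
    lam: float = 0.1
    h: int | None = None
    alpha: float = 0.05
    hac_lags: int | None = None  # None -> P
    tol: float = 1e-8
    max_iter: int = 30
    use_mtl: bool = True
    #: rescale in-sample squared losses by N/(N-k) before the DM test
    df_correct: bool = True
    seed: int | None = None

    @property
    def effective_hac_lags(self) -> int:
        return self.P if self.hac_lags is None else self.hac_lags


def decision_rule(adjr2_full, adjr2_base, dm_p, alpha: float = 0.05) -> np.ndarray | bool:
    """The three-condition causality rule (vectorized).

    A pixel is causal iff the full model's adjusted R^2 is positive AND
    exceeds the base model's AND the Diebold–Mariano p-value falls
    below ``alpha``.  Non-finite diagnostics (degenerate pixels) yield
    a non-causal decision.
    """
    adjr2_full = np.asarray(adjr2_full, dtype=float)
    adjr2_base = np.asarray(adjr2_base, dtype=float)
    dm_p = np.asarray(dm_p, dtype=float)
    ok = np.isfinite(adjr2_full) & np.isfinite(adjr2_base) & np.isfinite(dm_p)
    out = ok & (adjr2_full > 0) & (adjr2_full > adjr2_base) & (dm_p < alpha)
    return bool(out) if out.ndim == 0 else out


_decision = decision_rule


def test_pixel(
    y: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    P: int = 10,
    alpha: float = 0.05,
    hac_lags: int | None = None,
) -> tuple[bool, ModelComparison, str]:
    """Single-pixel Granger test of ``x1 -> y`` conditioned on ``x2``.

    Fits both models by per-pixel least squares (the single-task limit
    of the joint fit) and applies the three-condition rule.  Returns
    ``(decision, comparison, reason)`` where ``reason`` is non-empty
    when the pixel is non-causal for a structural reason (degenerate
    series) rather than by the statistical rule.
    """
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    nan_cmp = ModelComparison(*(np.nan,) * 6, N=len(y) - P, k_base=0, k_full=0)
    if np.std(y) == 0:
        return False, nan_cmp, "degenerate target"
    if np.std(x1) == 0:
        return False, nan_cmp, "degenerate predictor"
    base = build_lagged_design(y, x2, P=P, model_kind="base")
    full = build_lagged_design(y, x2, x1, P=P, model_kind="full")
    _, fit_b, _ = fit_ols(base)
    _, fit_f, _ = fit_ols(full)
    N = base.n_samples
    r2_b = r_squared(base.y, fit_b.yhat)
    r2_f = r_squared(full.y, fit_f.yhat)
    if not (np.isfinite(r2_b) and np.isfinite(r2_f)):
        return False, nan_cmp, "degenerate target"
    adj_b = adjusted_r_squared(r2_b, N, base.n_coeffs)
    adj_f = adjusted_r_squared(r2_f, N, full.n_coeffs)
    lags = P if hac_lags is None else hac_lags
    dm, p = diebold_mariano(
        fit_f.resid, fit_b.resid, hac_lags=lags, k_full=full.n_coeffs, k_base=base.n_coeffs
    )
    cmp_ = ModelComparison(
        r2_base=np.asarray(r2_b),
        r2_full=np.asarray(r2_f),
        adjr2_base=np.asarray(adj_b),
        adjr2_full=np.asarray(adj_f),
        dm_stat=np.asarray(dm),
        dm_p=np.asarray(p),
        N=N,
        k_base=base.n_coeffs,
        k_full=full.n_coeffs,
    )
    return bool(_decision(adj_f, adj_b, p, alpha)), cmp_, ""


def _fit_models(series, config, cause=None, target=None, conds=None):
    """Fit one (target, model_kind) joint run and return (weights, fit, k)."""
    Y = series[target]
    X_cond = [series[c] for c in conds]
    X_cause = series[cause] if cause is not None else None
    designs = build_design_stack(
        Y, X_cond, X_cause, P=config.P, cond_names=list(conds), cause_name=cause or "x_cause"
    )
    if config.use_mtl:
        weights, fit = fit_aso_mtl(
            designs,
            lam=config.lam,
            h=config.h,
            tol=config.tol,
            max_iter=config.max_iter,
            seed=config.seed,
        )
    else:
        W = np.empty((len(designs), designs[0].n_coeffs))
        yh = np.empty((len(designs), designs[0].n_samples))
        for i, d in enumerate(designs):
            w, f, _ = fit_ols(d)
            W[i] = w
            yh[i] = f.yhat
        Ymat = np.stack([d.y for d in designs])
        weights = MTLWeights(
            W=W, U=W, V=np.zeros((len(designs), 1)), Theta=np.zeros((1, designs[0].n_coeffs)),
            lam=0.0, h=1, columns=list(designs[0].columns),
        )
        fit = FitResult(yhat=yh, resid=Ymat - yh)
    return weights, fit, designs[0].n_coeffs


def causality_maps(
    stacks: dict[str, FieldStack],
    config: InferenceConfig | None = None,
    zscore_inputs: bool = True,
    return_weights: bool = False,
    pairs: list[tuple[str, str]] | None = None,
):
    """Directed causality maps for all ordered variable pairs.

    For each ordered pair (A -> B) among the stack variables the third
    variable is the conditional.  The full model of a given target is
    shared between the two directed pairs with that effect, so each
    target requires one full and two base joint fits.  Input stacks are
    z-scored per pixel unless ``zscore_inputs=False`` (pixels whose
    trace has zero variance are dropped from the shared mask).
    ``pairs`` restricts computation to the listed (cause, effect)
    combinations; by default all six are produced.

    Returns a dict ``{(cause, effect): CausalityMap}`` (and the fitted
    full-model weights per target when ``return_weights`` is set).
    """
    config = config or InferenceConfig()
    names = list(stacks)
    if len(names) < 3:
        raise ValueError("need at least three co-registered variables")
    if pairs is not None:
        for a, b in pairs:
            if a not in names or b not in names or a == b:
                raise ValueError(f"invalid pair {(a, b)}")
    if zscore_inputs:
        stacks = {n: zscore(s) for n, s in stacks.items()}
    series, mask = stack_pixel_series(stacks)
    if not mask.any():
        raise ValueError("empty mask after degeneracy screening")
    shape = next(iter(stacks.values())).grid_shape

    full_fits: dict[str, tuple[MTLWeights, FitResult, int]] = {}
    maps: dict[tuple[str, str], CausalityMap] = {}
    targets = names if pairs is None else sorted({b for _, b in pairs}, key=names.index)
    for target in targets:
        others = [n for n in names if n != target]
        # one full fit per target: conditionals in a fixed order, cause last
        weights_f, fit_f, k_full = _fit_models(
            series, config, cause=others[-1], target=target, conds=others[:-1]
        )
        full_fits[target] = (weights_f, fit_f, k_full)
        N = fit_f.yhat.shape[1]
        Ymat = fit_f.yhat + fit_f.resid
        r2_f = r_squared(Ymat, fit_f.yhat)
        adj_f = adjusted_r_squared(r2_f, N, k_full)
        causes = others if pairs is None else [a for a, b in pairs if b == target]
        for cause in causes:
            conditional = [n for n in others if n != cause][0]
            weights_b, fit_b, k_base = _fit_models(
                series, config, cause=None, target=target, conds=[conditional]
            )
            r2_b = r_squared(Ymat, fit_b.yhat)
            adj_b = adjusted_r_squared(r2_b, N, k_base)
            dm, p = diebold_mariano(
                fit_f.resid,
                fit_b.resid,
                hac_lags=config.effective_hac_lags,
                k_full=k_full if config.df_correct else 0,
                k_base=k_base if config.df_correct else 0,
            )
            dec_vec = _decision(adj_f, adj_b, p, config.alpha)
            decision = np.zeros(shape, dtype=bool)
            decision[mask] = dec_vec
            p_map = np.full(shape, np.nan)
            p_map[mask] = p
            delta_map = np.full(shape, np.nan)
            delta_map[mask] = adj_f - adj_b
            maps[(cause, target)] = CausalityMap(
                cause=cause,
                effect=target,
                conditional=conditional,
                decision=decision,
                mask=mask,
                alpha=config.alpha,
                comparison=ModelComparison(
                    r2_base=np.asarray(r2_b),
                    r2_full=np.asarray(r2_f),
                    adjr2_base=np.asarray(adj_b),
                    adjr2_full=np.asarray(adj_f),
                    dm_stat=np.asarray(dm),
                    dm_p=np.asarray(p),
                    N=N,
                    k_base=k_base,
                    k_full=k_full,
                ),
                dm_p=p_map,
                delta_adjr2=delta_map,
            )
    if return_weights:
        return maps, {t: full_fits[t][0] for t in full_fits}
    return maps
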