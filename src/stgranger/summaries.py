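"""Aggregate causality maps and parameter fields into summary statistics.

These operations reproduce, on any input, the standard read-outs of the
analysis: the percentage of the nucleus showing each directed causality,
its dependence on distance to the nuclear periphery, a causal loop
diagram over the three variables, parameter comparisons between causal
and non-causal regions (with subsampled rank-sum tests that blunt
trivial large-n significance), lagged cross-correlations, and temporal
weight profiles of the fitted models.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference import CausalityMap
from .regression import MTLWeights

__all__ = [
    "PeripheryProfile",
    "LoopDiagram",
    "RegionComparison",
    "causal_fraction",
    "fraction_vs_periphery",
    "loop_diagram",
    "region_comparison",
    "lagged_xcorr",
    "mean_abs_xcorr",
    "weight_profiles",
]

logger = logging.getLogger(__name__)


def causal_fraction(decision: np.ndarray | CausalityMap, mask: np.ndarray | None = None) -> float:
    """Percent of masked (non-degenerate) pixels marked causal."""
    if isinstance(decision, CausalityMap):
        mask = decision.mask if mask is None else mask
        decision = decision.decision
    if mask is None:
        raise ValueError("mask required when passing a raw decision array")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return 100.0 * float(np.asarray(decision, dtype=bool)[mask].mean())


@dataclass
class PeripheryProfile:
    """Causal fraction binned by distance to the nuclear periphery."""

    bin_edges: np.ndarray  # µm, length n_bins + 1
    fraction: np.ndarray  # percent per bin, NaN where a bin is empty
    counts: np.ndarray  # masked pixels per bin

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_um": self.bin_edges[:-1],
                "bin_hi_um": self.bin_edges[1:],
                "fraction_pct": self.fraction,
                "n_pixels": self.counts,
            }
        )


def fraction_vs_periphery(
    cmap: CausalityMap | np.ndarray,
    distance_um: np.ndarray,
    n_bins: int = 10,
    mask: np.ndarray | None = None,
) -> PeripheryProfile:
    """Per-distance-bin causal fraction (equal-width bins over [0, max])."""
    if isinstance(cmap, CausalityMap):
        mask = cmap.mask if mask is None else mask
        decision = cmap.decision
    else:
        decision = np.asarray(cmap, dtype=bool)
    if mask is None:
        raise ValueError("mask required when passing a raw decision array")
    mask = np.asarray(mask, dtype=bool)
    d = np.asarray(distance_um, dtype=float)[mask]
    dec = decision[mask]
    edges = np.linspace(0.0, d.max(), n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    frac = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            frac[b] = 100.0 * dec[sel].mean()
    return PeripheryProfile(bin_edges=edges, fraction=frac, counts=counts)


@dataclass
class LoopDiagram:
    """Directed-pair percentages with a display threshold.

    All six percentages are retained in ``percentages``; ``displayed``
    lists only the edges at or above ``threshold_pct`` (edges below the
    threshold are omitted from display, not from the data).
    """

    percentages: dict[tuple[str, str], float]
    threshold_pct: float = 2.0

    @property
    def displayed(self) -> list[tuple[str, str, float]]:
        return [
            (a, b, p)
            for (a, b), p in sorted(self.percentages.items())
            if p >= self.threshold_pct
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cause": a, "effect": b, "percent": p, "displayed": p >= self.threshold_pct}
            for (a, b), p in sorted(self.percentages.items())
        ]
        return pd.DataFrame(rows)


def loop_diagram(maps: dict[tuple[str, str], CausalityMap], threshold_pct: float = 2.0) -> LoopDiagram:
    """Causal loop diagram percentages for all directed pairs."""
    pct = {pair: causal_fraction(m) for pair, m in maps.items()}
    return LoopDiagram(percentages=pct, threshold_pct=threshold_pct)


@dataclass
class RegionComparison:
    """Inside- vs outside-causal-region comparison of one parameter."""

    parameter: str
    stats_causal: dict[str, float]
    stats_noncausal: dict[str, float]
    median_p: float
    n_tests: int
    subsample: int
    n_causal: int
    n_noncausal: int


def _group_stats(x: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "q25": float(np.percentile(x, 25)),
        "q75": float(np.percentile(x, 75)),
    }


def region_comparison(
    field_avg: np.ndarray,
    cmap: CausalityMap | np.ndarray,
    mask: np.ndarray | None = None,
    parameter: str = "",
    n_tests: int = 250,
    subsample: int = 100,
    seed: int | None = None,
) -> RegionComparison:
    """Compare a time-averaged parameter in causal vs non-causal pixels.

    The p-value is the median of ``n_tests`` two-sided Wilcoxon rank-sum
    tests on subsamples of ``subsample`` pixels per group, which avoids
    reporting significance driven purely by the large pixel count.  If a
    group is smaller than ``subsample`` the subsample shrinks to the
    smaller group size (logged).
    """
    if isinstance(cmap, CausalityMap):
        mask = cmap.mask if mask is None else mask
        decision = cmap.decision
    else:
        decision = np.asarray(cmap, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(field_avg, dtype=float)
    causal = vals[mask & decision]
    noncausal = vals[mask & ~decision]
    if causal.size == 0 or noncausal.size == 0:
        raise ValueError("both causal and non-causal groups must be non-empty")
    sub = min(subsample, causal.size, noncausal.size)
    if sub < subsample:
        logger.warning("region_comparison: shrinking subsample to %d (smallest group)", sub)
    rng = np.random.default_rng(seed)
    ps = np.empty(n_tests)
    for i in range(n_tests):
        a = rng.choice(causal, size=sub, replace=False)
        b = rng.choice(noncausal, size=sub, replace=False)
        if np.ptp(np.concatenate([a, b])) == 0:
            ps[i] = 1.0  # no ranks to separate
        else:
            ps[i] = stats.ranksums(a, b).pvalue
    return RegionComparison(
        parameter=parameter,
        stats_causal=_group_stats(causal),
        stats_noncausal=_group_stats(noncausal),
        median_p=float(np.median(ps)),
        n_tests=n_tests,
        subsample=sub,
        n_causal=causal.size,
        n_noncausal=noncausal.size,
    )


def lagged_xcorr(a: np.ndarray, b: np.ndarray, max_lag: int = 10) -> np.ndarray:
    """Pearson correlation of ``(a_t, b_{t-lag})`` for lags 0..max_lag.

    Each lag uses the valid overlap of length T - lag, with the overlap's
    own means and standard deviations (so every entry is a true Pearson
    coefficient, bounded by 1 in magnitude).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be equal-length 1-D arrays")
    out = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        x = a[lag:]
        y = b[: len(b) - lag] if lag else b
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            out[lag] = np.nan
            continue
        out[lag] = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return out


def mean_abs_xcorr(
    series_a: np.ndarray,
    series_b: np.ndarray,
    decision_vec: np.ndarray | None = None,
    max_lag: int = 10,
) -> dict[str, np.ndarray]:
    """Per-lag mean absolute cross-correlation, by causal regime.

    ``series_a``/``series_b`` are (T, L) pixel-series arrays;
    ``decision_vec`` is a length-L boolean vector (True = causal pixel).
    Returns a dict with keys ``"causal"`` and/or ``"noncausal"`` (a
    single ``"all"`` regime when no decision vector is given), each an
    array of length ``max_lag + 1``.
    """
    A = np.asarray(series_a, dtype=float)
    B = np.asarray(series_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("series arrays must be co-registered")
    L = A.shape[1]
    corrs = np.empty((L, max_lag + 1))
    for l in range(L):
        corrs[l] = np.abs(lagged_xcorr(A[:, l], B[:, l], max_lag=max_lag))
    if decision_vec is None:
        return {"all": np.nanmean(corrs, axis=0)}
    dec = np.asarray(decision_vec, dtype=bool)
    out: dict[str, np.ndarray] = {}
    if dec.any():
        out["causal"] = np.nanmean(corrs[dec], axis=0)
    if (~dec).any():
        out["noncausal"] = np.nanmean(corrs[~dec], axis=0)
    return out


def weight_profiles(
    weights: MTLWeights, decision_vec: np.ndarray | None = None
) -> pd.DataFrame:
    """Mean absolute regression coefficient per (variable, lag).

    Parses the design's column labels (``<variable>_lag<p>``) and
    averages |w| across pixels, optionally split by the causal decision.
    The temporal weight profile shows which past lags of each variable
    carry predictive relevance for the target.
    """
    cols = weights.columns
    pattern = re.compile(r"^(?P<var>.+)_lag(?P<lag>\d+)$")
    rows = []
    groups: dict[str, np.ndarray] = {"all": np.ones(weights.W.shape[0], dtype=bool)}
    if decision_vec is not None:
        dec = np.asarray(decision_vec, dtype=bool)
        groups = {"causal": dec, "noncausal": ~dec}
    for j, name in enumerate(cols):
        m = pattern.match(name)
        if not m:
            continue
        for regime, sel in groups.items():
            if not sel.any():
                continue
            rows.append(
                {
                    "variable": m.group("var"),
                    "lag": int(m.group("lag")),
                    "regime": regime,
                    "mean_abs_weight": float(np.abs(weights.W[sel, j]).mean()),
                }
            )
    return pd.DataFrame(rows).sort_values(["variable", "lag", "regime"]).reset_index(drop=True)
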