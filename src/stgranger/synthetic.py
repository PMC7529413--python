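"""Synthetic data with known causal structure.

Two generators make every stage of the causality pipeline verifiable
without real imaging data:

``generate_var_fields``
    Gridded multivariate AR time series (flow, NND, area) on a masked
    nucleus grid, with spatially correlated innovations and an optional
    directed lagged coupling injected in a designated region.  This is
    the default test surface for the regression/inference stages.

``generate_blob_movie``
    Image stacks of Gaussian "blobs" with prescribed drift and
    Poisson–Gaussian noise, plus exact ground-truth blob tables, to
    exercise segmentation, nearest-neighbor and optical-flow extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .fields import FieldStack

__all__ = [
    "SyntheticFieldSpec",
    "SyntheticMovieSpec",
    "GroundTruth",
    "VARIABLES",
    "ellipse_mask",
    "central_region",
    "generate_var_fields",
    "generate_blob_movie",
]

#: Canonical variable names, in fixed order.
VARIABLES = ("flow", "nnd", "area")


def ellipse_mask(grid_shape: tuple[int, int]) -> np.ndarray:
    """Axis-aligned ellipse inscribed in the grid (the synthetic 'nucleus')."""
    rows, cols = grid_shape
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    rr, cc = np.mgrid[0:rows, 0:cols]
    return ((rr - r0) / (rows / 2.0)) ** 2 + ((cc - c0) / (cols / 2.0)) ** 2 <= 1.0


def central_region(mask: np.ndarray, n_pixels: int, center: tuple[float, float] | None = None) -> np.ndarray:
    """Boolean region of the ``n_pixels`` masked pixels closest to ``center``.

    Defaults to the mask centroid, yielding a compact interior region in
    which couplings can be injected.
    """
    if n_pixels > mask.sum():
        raise ValueError(f"requested {n_pixels} pixels but mask has only {int(mask.sum())}")
    rr, cc = np.nonzero(mask)
    if center is None:
        center = (rr.mean(), cc.mean())
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    keep = np.argsort(d2, kind="stable")[:n_pixels]
    region = np.zeros_like(mask)
    region[rr[keep], cc[keep]] = True
    return region


@dataclass
class SyntheticFieldSpec:
    """Specification of a gridded VAR field simulation.

    The defaults reproduce the acquisition geometry of the live-cell
    super-resolution series the analysis targets: T=166 frames at
    0.36 s, one value per 67.5 nm pixel inside an elliptical nucleus
    mask.  A single directed coupling ``cause -> effect`` with lag
    ``coupling_lag`` frames and coefficient ``coupling_coeff`` can be
    injected inside ``causal_region``; everywhere else (and for all
    other variables) each series is an independent AR(1) process with
    spatially correlated Gaussian innovations.
    """

    grid_shape: tuple[int, int] = (32, 32)
    T: int = 166
    dt: float = 0.36
    mask_kind: str = "ellipse"
    causal_region: np.ndarray | None = None
    direction: tuple[str, str] = ("flow", "nnd")
    coupling_lag: int = 3
    coupling_coeff: float = 0.0
    ar_coeff: float | dict[str, float] = 0.5
    noise_sd: float = 1.0
    spatial_corr_len: float = 1.5
    region_mean_shift: dict[str, float] = dc_field(default_factory=dict)
    burn_in: int = 50
    pixel_size_nm: float = 67.5
    seed: int = 0
    #: maximum lag supported by the downstream regression
    max_supported_lag: int = 10

    def ar(self, var: str) -> float:
        if isinstance(self.ar_coeff, dict):
            return float(self.ar_coeff.get(var, 0.0))
        return float(self.ar_coeff)

    def mask(self) -> np.ndarray:
        if self.mask_kind == "ellipse":
            return ellipse_mask(self.grid_shape)
        if self.mask_kind == "full":
            return np.ones(self.grid_shape, dtype=bool)
        raise ValueError(f"unknown mask_kind {self.mask_kind!r}")

    def validate(self) -> None:
        for v in VARIABLES:
            if not abs(self.ar(v)) < 1:
                raise ValueError(f"ar_coeff for {v!r} must satisfy |a| < 1 (stationarity)")
        if not 1 <= self.coupling_lag <= self.max_supported_lag:
            raise ValueError(
                f"coupling_lag must lie in [1, {self.max_supported_lag}], got {self.coupling_lag}"
            )
        cause, effect = self.direction
        if cause not in VARIABLES or effect not in VARIABLES or cause == effect:
            raise ValueError(f"direction must be an ordered pair of distinct variables, got {self.direction}")
        if self.causal_region is not None:
            region = np.asarray(self.causal_region, dtype=bool)
            if region.shape != tuple(self.grid_shape):
                raise ValueError("causal_region shape does not match grid_shape")
            if np.any(region & ~self.mask()):
                raise ValueError("causal_region must be a subset of the nucleus mask")
        if self.T <= 0 or self.noise_sd <= 0:
            raise ValueError("T and noise_sd must be positive")


@dataclass
class GroundTruth:
    """What the generator actually injected, for scoring detections.

    ``causal_masks`` maps every ordered variable pair to a boolean grid;
    it is non-empty only for the injected direction (and only when the
    coupling coefficient is non-zero).
    """

    causal_masks: dict[tuple[str, str], np.ndarray]
    mask: np.ndarray
    coupling_lag: int | None = None
    coupling_coeff: float | None = None
    blob_tables: pd.DataFrame | None = None

    def causal_mask(self, cause: str, effect: str) -> np.ndarray:
        return self.causal_masks[(cause, effect)]


def _correlated_innovations(
    rng: np.random.Generator,
    n_frames: int,
    grid_shape: tuple[int, int],
    corr_len: float,
    sd: float,
) -> np.ndarray:
    """White-in-time Gaussian innovations, spatially smoothed to a
    Gaussian correlation structure and rescaled to marginal SD ``sd``.

    Smoothing uses wrap-around boundaries so the marginal variance is
    exactly uniform across the grid; the rescaling factor is the L2 norm
    of the effective smoothing kernel, computed from a delta impulse.
    """
    eps = rng.standard_normal((n_frames,) + tuple(grid_shape))
    if corr_len <= 0:
        return sd * eps
    delta = np.zeros(grid_shape)
    delta[grid_shape[0] // 2, grid_shape[1] // 2] = 1.0
    kernel = ndimage.gaussian_filter(delta, sigma=corr_len, mode="wrap")
    norm = np.sqrt((kernel**2).sum())
    smoothed = ndimage.gaussian_filter(eps, sigma=(0, corr_len, corr_len), mode="wrap")
    return sd * smoothed / norm


def generate_var_fields(
    spec: SyntheticFieldSpec,
) -> tuple[dict[str, FieldStack], GroundTruth]:
    """Simulate the three co-registered per-pixel series.

    Inside ``spec.causal_region`` the effect variable follows

    ``effect_t = a * effect_{t-1} + c * cause_{t-tau} + eps_t``

    while everywhere else every variable is an independent AR(1).
    Innovations are Gaussian random fields, white in time, with spatial
    correlation length ``spatial_corr_len`` pixels.  The first
    ``burn_in`` frames are discarded so the recorded T points are drawn
    from the stationary regime.  Identical spec + seed gives bit-identical
    output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mask = spec.mask()
    tau = spec.coupling_lag
    c = spec.coupling_coeff
    cause_name, effect_name = spec.direction
    n_total = spec.T + spec.burn_in

    region = np.zeros(spec.grid_shape, dtype=bool)
    if spec.causal_region is not None and c != 0.0:
        region = np.asarray(spec.causal_region, dtype=bool)

    series: dict[str, np.ndarray] = {}
    # innovations drawn in fixed variable order for reproducibility
    innovations = {
        v: _correlated_innovations(rng, n_total, spec.grid_shape, spec.spatial_corr_len, spec.noise_sd)
        for v in VARIABLES
    }

    def ar_series(var: str, extra: np.ndarray | None = None) -> np.ndarray:
        a = spec.ar(var)
        eps = innovations[var]
        x = np.empty_like(eps)
        # stationary AR(1) initialisation; burn-in removes any residual transient
        x[0] = eps[0] / math.sqrt(1.0 - a**2)
        for t in range(1, n_total):
            x[t] = a * x[t - 1] + eps[t]
            if extra is not None and t >= tau:
                x[t] += extra[t]
        return x

    cause_full = ar_series(cause_name)
    series[cause_name] = cause_full
    coupling_term = None
    if region.any():
        coupling_term = np.zeros_like(cause_full)
        coupling_term[tau:] = c * cause_full[:-tau] * region
    series[effect_name] = ar_series(effect_name, extra=coupling_term)
    (third_name,) = [v for v in VARIABLES if v not in spec.direction]
    series[third_name] = ar_series(third_name)

    stacks: dict[str, FieldStack] = {}
    for v in VARIABLES:
        vals = series[v][spec.burn_in :].copy()
        shift = spec.region_mean_shift.get(v, 0.0)
        if shift and spec.causal_region is not None:
            vals[:, np.asarray(spec.causal_region, dtype=bool)] += shift
        stacks[v] = FieldStack(
            name=v, values=vals, mask=mask, pixel_size_nm=spec.pixel_size_nm, dt_s=spec.dt
        )

    causal_masks = {}
    for a_name in VARIABLES:
        for b_name in VARIABLES:
            if a_name == b_name:
                continue
            if (a_name, b_name) == spec.direction and region.any():
                causal_masks[(a_name, b_name)] = region.copy()
            else:
                causal_masks[(a_name, b_name)] = np.zeros(spec.grid_shape, dtype=bool)
    gt = GroundTruth(
        causal_masks=causal_masks,
        mask=mask,
        coupling_lag=tau if region.any() else None,
        coupling_coeff=c if region.any() else None,
    )
    return stacks, gt


# ---------------------------------------------------------------------------
# Blob movies
# ---------------------------------------------------------------------------


@dataclass
class SyntheticMovieSpec:
    """Specification of a synthetic blob movie.

    Blobs are isotropic Gaussian spots of width ``blob_sigma_px`` on a
    uniform background, displaced between frames by ``drift_px`` and
    corrupted by Poisson shot noise plus Gaussian read noise.  At desk
    scale a few dozen blobs stand in for the ~10^4 blobs of a full
    nucleus; the statistics exercised (centroids, NND, flow) are the
    same.
    """

    frame_shape: tuple[int, int] = (128, 128)
    n_frames: int = 12
    n_blobs: int = 50
    #: Gaussian spot width; a scalar gives identical blobs, a (lo, hi)
    #: tuple samples one width per blob uniformly from the range
    blob_sigma_px: float | tuple[float, float] = 2.0
    #: displacement applied between consecutive frames; broadcastable to
    #: (n_frames, n_blobs, 2) with row 0 ignored (no motion before frame 0)
    drift_px: np.ndarray | tuple[float, float] | None = None
    peak_intensity: float = 100.0
    background: float = 10.0
    read_noise_sd: float = 2.0
    pixel_size_nm: float = 13.5
    dt_s: float = 0.36
    min_separation_px: float = 9.0
    margin_px: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_blobs < 2:
            raise ValueError("n_blobs must be >= 2 (NND undefined otherwise)")
        if self.max_sigma() <= 0 or self.n_frames < 1:
            raise ValueError("blob_sigma_px and n_frames must be positive")

    def max_sigma(self) -> float:
        if np.isscalar(self.blob_sigma_px):
            return float(self.blob_sigma_px)
        return float(max(self.blob_sigma_px))

    def blob_sigmas(self, rng: np.random.Generator) -> np.ndarray:
        if np.isscalar(self.blob_sigma_px):
            return np.full(self.n_blobs, float(self.blob_sigma_px))
        lo, hi = self.blob_sigma_px
        return rng.uniform(lo, hi, size=self.n_blobs)

    def drift_array(self) -> np.ndarray:
        drift = np.zeros((self.n_frames, self.n_blobs, 2))
        if self.drift_px is not None:
            drift[1:] = np.broadcast_to(np.asarray(self.drift_px, dtype=float), (self.n_frames - 1, self.n_blobs, 2))
        return drift


def _sample_positions(rng: np.random.Generator, spec: SyntheticMovieSpec) -> np.ndarray:
    """Rejection-sample blob centers with a minimum pairwise separation."""
    lo = spec.margin_px
    hi_r = spec.frame_shape[0] - 1 - spec.margin_px
    hi_c = spec.frame_shape[1] - 1 - spec.margin_px
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < spec.n_blobs:
        cand = np.array([rng.uniform(lo, hi_r), rng.uniform(lo, hi_c)])
        if all(np.hypot(*(cand - p)) >= spec.min_separation_px for p in pts):
            pts.append(cand)
        attempts += 1
        if attempts > 100000:
            raise ValueError("could not place blobs with requested minimum separation")
    return np.array(pts)


def _render_frame(
    shape: tuple[int, int], centers: np.ndarray, sigmas: np.ndarray, peak: float, bg: float
) -> np.ndarray:
    img = np.full(shape, bg, dtype=float)
    for (r0, c0), sigma in zip(centers, sigmas):
        half = int(math.ceil(4 * sigma))
        r_lo, r_hi = max(0, int(r0) - half), min(shape[0], int(r0) + half + 1)
        c_lo, c_hi = max(0, int(c0) - half), min(shape[1], int(c0) + half + 1)
        rr = np.arange(r_lo, r_hi)[:, None]
        cc = np.arange(c_lo, c_hi)[None, :]
        img[r_lo:r_hi, c_lo:c_hi] += peak * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)
        )
    return img


def generate_blob_movie(spec: SyntheticMovieSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a noisy blob movie and its exact ground-truth blob table.

    Returns ``(movie, ground_truth)`` where ``movie`` has shape
    ``(n_frames, rows, cols)`` and ``ground_truth.blob_tables`` is a
    DataFrame with one row per (frame, blob): true centroid, area proxy
    (the pi*sigma^2 Gaussian footprint), NND and per-frame displacement
    magnitude.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pos0 = _sample_positions(rng, spec)
    sigmas = spec.blob_sigmas(rng)
    drift = spec.drift_array()
    positions = pos0[None, :, :] + np.cumsum(drift, axis=0)

    half = 3 * spec.max_sigma()
    if (
        positions[..., 0].min() < half
        or positions[..., 1].min() < half
        or positions[..., 0].max() > spec.frame_shape[0] - 1 - half
        or positions[..., 1].max() > spec.frame_shape[1] - 1 - half
    ):
        raise ValueError("drift carries a blob outside the frame; reduce drift or n_frames")

    movie = np.empty((spec.n_frames,) + tuple(spec.frame_shape))
    records = []
    from .features import compute_nnd  # local import to avoid cycle at module load

    area_px2 = math.pi * sigmas**2  # Gaussian footprint proxy, per blob
    for f in range(spec.n_frames):
        clean = _render_frame(spec.frame_shape, positions[f], sigmas, spec.peak_intensity, spec.background)
        movie[f] = rng.poisson(clean) + rng.normal(0.0, spec.read_noise_sd, size=clean.shape)
        nnd_px = compute_nnd(positions[f], pitch_nm=1.0)
        # instantaneous displacement convention: frame f carries the motion
        # from f to f+1 (the last frame repeats the preceding interval)
        fwd = f + 1 if f + 1 < spec.n_frames else f
        disp = np.hypot(drift[fwd, :, 0], drift[fwd, :, 1])
        for b in range(spec.n_blobs):
            records.append(
                {
                    "frame": f,
                    "blob": b,
                    "row_px": positions[f, b, 0],
                    "col_px": positions[f, b, 1],
                    "area_px2": area_px2[b],
                    "area_nm2": area_px2[b] * spec.pixel_size_nm**2,
                    "nnd_px": nnd_px[b],
                    "nnd_nm": nnd_px[b] * spec.pixel_size_nm,
                    "disp_px": disp[b],
                    "flow_px": disp[b],
                    "flow_nm_s": disp[b] * spec.pixel_size_nm / spec.dt_s,
                }
            )
    table = pd.DataFrame.from_records(records)
    gt = GroundTruth(causal_masks={}, mask=np.ones(spec.frame_shape, dtype=bool), blob_tables=table)
    return movie, gt
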