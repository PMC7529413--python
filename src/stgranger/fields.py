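"""Gridded spatio-temporal field containers.

A :class:`FieldStack` holds one observable (chromatin flow magnitude,
blob nearest-neighbor distance, or blob area) sampled on a fixed pixel
grid across a nucleus at a constant frame interval.  All downstream
stages — z-scoring, lagged regression, causality mapping, spatial
summaries — operate on stacks that share the same grid geometry and
nucleus mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["FieldStack", "stack_pixel_series"]


@dataclass
class FieldStack:
    """One variable's values on a (time x rows x cols) grid.

    Parameters
    ----------
    name:
        Variable name, conventionally one of ``"flow"`` (optical-flow
        magnitude), ``"nnd"`` (nearest-neighbor distance) or ``"area"``
        (blob area).
    values:
        Array of shape ``(T, rows, cols)``.  Values outside the mask may
        be arbitrary (NaN allowed); values on masked pixels must be finite.
    mask:
        Boolean nucleus mask of shape ``(rows, cols)``; True marks pixels
        that belong to the nucleus and carry valid time series.
    pixel_size_nm:
        Grid pitch in nanometres (67.5 nm for the fivefold-downsampled
        super-resolution grid).
    dt_s:
        Frame interval in seconds (0.36 s).
    """

    name: str
    values: np.ndarray
    mask: np.ndarray
    pixel_size_nm: float = 67.5
    dt_s: float = 0.36

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError(f"values must be (T, rows, cols), got shape {self.values.shape}")
        if self.mask.shape != self.values.shape[1:]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match grid {self.values.shape[1:]}"
            )
        if not np.isfinite(self.values[:, self.mask]).all():
            raise ValueError(f"non-finite values on masked pixels in field {self.name!r}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    @property
    def n_pixels(self) -> int:
        """Number of masked pixels."""
        return int(self.mask.sum())

    def pixel_series(self) -> np.ndarray:
        """Return the masked time series as a ``(T, L)`` array.

        Pixels are ordered row-major over the mask, matching
        ``np.flatnonzero(mask.ravel())``.
        """
        return self.values[:, self.mask]

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "FieldStack":
        """Copy of this stack with new values (and optionally a new mask)."""
        return replace(self, values=values, mask=self.mask if mask is None else mask)

    def time_average(self) -> np.ndarray:
        """Per-pixel temporal mean, NaN outside the mask."""
        out = np.full(self.grid_shape, np.nan)
        out[self.mask] = self.values[:, self.mask].mean(axis=0)
        return out


def stack_pixel_series(stacks: dict[str, FieldStack]) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Extract co-registered per-pixel series from several stacks.

    All stacks must share grid geometry; the common mask is the
    intersection of the individual masks.  Returns ``({name: (T, L)}, mask)``.
    """
    items = list(stacks.values())
    shape = items[0].grid_shape
    T = items[0].n_frames
    mask = np.ones(shape, dtype=bool)
    for st in items:
        if st.grid_shape != shape or st.n_frames != T:
            raise ValueError("stacks are not co-registered")
        mask &= st.mask
    return {name: st.values[:, mask] for name, st in stacks.items()}, mask
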