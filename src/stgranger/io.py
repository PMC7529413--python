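"""HDF5 / TIFF / CSV serialization of pipeline artifacts."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .fields import FieldStack
from .inference import CausalityMap
from .regression import MTLWeights
from .synthetic import GroundTruth

__all__ = [
    "write_fields_h5",
    "read_fields_h5",
    "write_movie_tiff",
    "read_movie_tiff",
    "write_blob_table_csv",
    "write_causality_h5",
    "write_weights_h5",
]


def write_fields_h5(
    path: str | Path, stacks: dict[str, FieldStack], ground_truth: GroundTruth | None = None
) -> None:
    """Write co-registered field stacks (and optional ground truth) to HDF5.

    Layout: ``/fields/<name>`` datasets, ``/mask``, grid metadata as
    attributes, ``/ground_truth/causal_mask/<cause>__<effect>``.
    """
    with h5py.File(path, "w") as f:
        any_stack = next(iter(stacks.values()))
        f.create_dataset("mask", data=any_stack.mask)
        grp = f.create_group("fields")
        for name, st in stacks.items():
            ds = grp.create_dataset(name, data=st.values)
            ds.attrs["pixel_size_nm"] = st.pixel_size_nm
            ds.attrs["dt_s"] = st.dt_s
        if ground_truth is not None:
            g = f.create_group("ground_truth/causal_mask")
            for (a, b), m in ground_truth.causal_masks.items():
                g.create_dataset(f"{a}__{b}", data=m)


def read_fields_h5(path: str | Path) -> tuple[dict[str, FieldStack], dict[tuple[str, str], np.ndarray]]:
    """Read field stacks written by :func:`write_fields_h5`."""
    stacks: dict[str, FieldStack] = {}
    gt_masks: dict[tuple[str, str], np.ndarray] = {}
    with h5py.File(path, "r") as f:
        mask = f["mask"][...].astype(bool)
        for name, ds in f["fields"].items():
            stacks[name] = FieldStack(
                name=name,
                values=ds[...],
                mask=mask,
                pixel_size_nm=float(ds.attrs["pixel_size_nm"]),
                dt_s=float(ds.attrs["dt_s"]),
            )
        if "ground_truth/causal_mask" in f:
            for key, ds in f["ground_truth/causal_mask"].items():
                a, b = key.split("__")
                gt_masks[(a, b)] = ds[...].astype(bool)
    return stacks, gt_masks


def write_movie_tiff(path: str | Path, movie: np.ndarray) -> None:
    """Write an image stack as a multi-page TIFF (float32)."""
    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32))


def read_movie_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_blob_table_csv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def write_causality_h5(path: str | Path, maps: dict[tuple[str, str], CausalityMap]) -> None:
    """Write decision/diagnostic maps: ``/causality/<cause>_<effect>/...``."""
    with h5py.File(path, "w") as f:
        for (cause, effect), m in maps.items():
            g = f.create_group(f"causality/{cause}_{effect}")
            g.attrs["alpha"] = m.alpha
            g.attrs["conditional"] = m.conditional
            g.create_dataset("decision", data=m.decision)
            g.create_dataset("mask", data=m.mask)
            if m.dm_p is not None:
                g.create_dataset("p", data=m.dm_p)
            if m.delta_adjr2 is not None:
                g.create_dataset("delta_adjr2", data=m.delta_adjr2)
            c = m.comparison
            diag = g.create_group("pixelwise")
            for name in ("r2_base", "r2_full", "adjr2_base", "adjr2_full", "dm_stat", "dm_p"):
                diag.create_dataset(name, data=np.asarray(getattr(c, name)))
            diag.attrs["N"] = c.N
            diag.attrs["k_base"] = c.k_base
            diag.attrs["k_full"] = c.k_full


def write_weights_h5(path: str | Path, weights: dict[str, dict[str, MTLWeights]]) -> None:
    """Write fitted weights: ``/weights/<target>/<model_kind>/{w,u,v,theta}``."""
    with h5py.File(path, "w") as f:
        for target, kinds in weights.items():
            for kind, w in kinds.items():
                g = f.create_group(f"weights/{target}/{kind}")
                g.create_dataset("w", data=w.W)
                g.create_dataset("u", data=w.U)
                g.create_dataset("v", data=w.V)
                g.create_dataset("theta", data=w.Theta)
                g.attrs["lambda"] = w.lam
                g.attrs["h"] = w.h
                g.attrs["converged"] = w.converged
                g.attrs["columns"] = [c.encode() for c in w.columns]
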