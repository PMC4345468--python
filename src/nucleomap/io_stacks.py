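"""Reading and writing of image stacks, tables and voxel maps.

Conventions
-----------
* Voxel arrays are indexed ``(z, y, x, channel)``.
* Voxel index ``(k, j, i)`` maps to the physical point
  ``((i + 0.5)·sx, (j + 0.5)·sy, (k + 0.5)·sz)`` — voxel-centre convention
  with 0-based indices.  Physical coordinates are used for all geometry
  because confocal stacks are strongly anisotropic (few z-slices, many
  lateral pixels), which makes index-space geometry wrong.
* Tables are headered CSV; voxel maps are ``.npz`` containers carrying grid
  origin, voxel size and axis order so they reload losslessly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, DataError

log = logging.getLogger("nucleomap")

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "write_table",
    "read_table",
    "write_array",
    "read_array",
]


@dataclass
class ImageStack:
    """A multi-channel 3D image with physical voxel spacing.

    ``voxels`` is ``(z, y, x, channel)`` and non-negative; ``spacing`` is the
    physical voxel size along ``(z, y, x)``; ``channel_map`` assigns named
    roles (at least ``envelope`` and ``compartment``) to channel indices.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channel_map: Mapping[str, int]

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4 or 0 in self.voxels.shape:
            raise DataError(
                f"voxels must be a non-empty (z, y, x, channel) array, "
                f"got shape {self.voxels.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigurationError(f"spacing must be 3 positive lengths, got {self.spacing}")
        n_chan = self.voxels.shape[3]
        for role in ("envelope", "compartment"):
            if role not in self.channel_map:
                raise ConfigurationError(f"channel_map is missing required role {role!r}")
        for role, idx in self.channel_map.items():
            if not (0 <= int(idx) < n_chan):
                raise ConfigurationError(
                    f"channel_map[{role!r}] = {idx} out of range for {n_chan} channels"
                )

    def channel(self, role: str) -> np.ndarray:
        """Return the (z, y, x) array for a named channel role."""
        if role not in self.channel_map:
            raise ConfigurationError(f"unknown channel role {role!r}")
        return self.voxels[..., int(self.channel_map[role])]

    def voxel_centres(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Physical (x, y, z) coordinates of voxel centres, optionally masked."""
        sz, sy, sx = self.spacing
        if mask is None:
            kk, jj, ii = np.indices(self.voxels.shape[:3])
            kk, jj, ii = kk.ravel(), jj.ravel(), ii.ravel()
        else:
            kk, jj, ii = np.nonzero(mask)
        return np.column_stack(
            [(ii + 0.5) * sx, (jj + 0.5) * sy, (kk + 0.5) * sz]
        ).astype(float)


def read_stack(
    path,
    channel_map: Mapping[str, int],
    spacing: Optional[Sequence[float]] = None,
) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Pages are taken as z-slices; channels may be stored as per-page samples
    (``(z, y, x, c)``) or as a separate small leading/second axis.  Pixel
    values are preserved bit-exactly.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"stack file not found: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # malformed TIFF, ragged pages
        raise DataError(f"cannot read TIFF {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None, :, :, None]
    elif arr.ndim == 3:
        # single-channel z-stack
        arr = arr[..., None]
    elif arr.ndim == 4:
        # distinguish (z, c, y, x) from (z, y, x, c): channels are few.
        if arr.shape[3] > 16 and arr.shape[1] <= 16:
            arr = np.moveaxis(arr, 1, 3)
    else:
        raise DataError(f"unsupported TIFF dimensionality {arr.ndim} in {path}")
    if spacing is None:
        log.warning("no voxel spacing given for %s; assuming isotropic 1.0", path)
        spacing = (1.0, 1.0, 1.0)
    return ImageStack(voxels=arr, spacing=tuple(spacing), channel_map=dict(channel_map))


def write_stack(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as a multi-page TIFF, z as pages."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.voxels, photometric="minisblack")


def write_table(records: Sequence[Mapping], path, columns: Optional[Sequence[str]] = None) -> None:
    """Write keyed rows as headered CSV; ``columns`` fixes the schema when
    the record set is empty."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(list(records), columns=columns)
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_array(
    values: np.ndarray,
    path,
    origin: Sequence[float],
    voxel_size: float,
    axis_order: str = "zyx",
) -> None:
    """Persist a voxel map with its grid metadata (lossless round trip)."""
    values = np.asarray(values)
    if not np.all(np.isfinite(values)):
        raise DataError("voxel map contains non-finite values")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        values=values,
        origin=np.asarray(origin, dtype=float),
        voxel_size=float(voxel_size),
        axis_order=np.array(axis_order),
    )


def read_array(path) -> tuple[np.ndarray, dict]:
    with np.load(path, allow_pickle=False) as npz:
        values = npz["values"]
        meta = {
            "origin": npz["origin"],
            "voxel_size": float(npz["voxel_size"]),
            "axis_order": str(npz["axis_order"]),
        }
    return values, meta
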