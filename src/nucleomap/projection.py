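"""2D orthogonal projections and 3D exports of aggregate-map results.

The headline visualization projects the 3D significance map along the stack
axis: each pixel shows the proportion of interior voxels along its line of
projection that reject CSR (darkest colour = all voxels reject, lightest =
none).  Pixels whose projection ray meets no interior voxel are flagged as
outside-domain and rendered distinctly rather than as zero — near the edge
of a projected map the ray depth can be very small, so colouring such
pixels like "no rejection" would overstate the evidence there.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import trimesh

from .errors import ConfigurationError
from .inference import SignificanceMap
from .intensity import IntensityMap

__all__ = [
    "ProjectionImage",
    "project_proportion",
    "project_mean_intensity",
    "export_3d",
    "save_projection_png",
]

_AXES = {"z": 0, "y": 1, "x": 2}  # arrays are (z, y, x)


@dataclass
class ProjectionImage:
    """A 2D orthogonal projection of a voxel map.

    ``pixels`` holds proportions in [0, 1] (``proportion_reject``) or
    intensity units (``mean_intensity``); ``count_along_ray`` is the number
    of interior voxels per projection ray, and pixels with zero count are
    outside the projected domain (``pixels`` is NaN there, not zero).
    """

    pixels: np.ndarray
    count_along_ray: np.ndarray
    axis: str
    kind: str

    @property
    def outside_domain(self) -> np.ndarray:
        return self.count_along_ray == 0


def _axis_index(axis: str) -> int:
    if axis not in _AXES:
        raise ConfigurationError(f"projection axis must be one of {sorted(_AXES)}")
    return _AXES[axis]


def project_proportion(
    sig: SignificanceMap, direction: str = "aggregated", axis: str = "z"
) -> ProjectionImage:
    """Proportion of interior voxels along each ray that reject CSR."""
    ax = _axis_index(axis)
    reject = sig.reject(direction)
    interior = sig.grid.interior_mask
    count = interior.sum(axis=ax)
    hits = (reject & interior).sum(axis=ax)
    with np.errstate(invalid="ignore", divide="ignore"):
        pixels = np.where(count > 0, hits / np.maximum(count, 1), np.nan)
    return ProjectionImage(pixels=pixels, count_along_ray=count, axis=axis, kind="proportion_reject")


def project_mean_intensity(intensity: IntensityMap, axis: str = "z") -> ProjectionImage:
    """Mean intensity over the interior voxels along each projection ray."""
    ax = _axis_index(axis)
    interior = intensity.grid.interior_mask
    count = interior.sum(axis=ax)
    total = np.where(interior, intensity.values, 0.0).sum(axis=ax)
    with np.errstate(invalid="ignore", divide="ignore"):
        pixels = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return ProjectionImage(pixels=pixels, count_along_ray=count, axis=axis, kind="mean_intensity")


def export_3d(
    sig: SignificanceMap,
    direction: str = "aggregated",
    cutaway: Optional[tuple[int, int, int]] = None,
    path: Optional[str | Path] = None,
    hull=None,
) -> dict:
    """Export rejecting voxels as a point cloud, optionally with the hull.

    ``cutaway`` removes one octant, specified by signs ``(sx, sy, sz)`` in
    {-1, +1} relative to the grid centre, so the map centre is visible.
    When ``path`` is given, writes ``<path>_voxels.ply`` (and
    ``<path>_hull.ply`` when a mean-hull boundary is passed).  Returns
    voxel counts and the exported coordinates for bookkeeping.
    """
    reject = sig.reject(direction)
    coords = sig.grid.centres(reject)
    n_total = coords.shape[0]
    if cutaway is not None and n_total:
        centre = sig.grid.origin + 0.5 * sig.grid.voxel_size * np.array(sig.grid.dims)[::-1]
        sx, sy, sz = cutaway
        in_octant = (
            (np.sign(coords[:, 0] - centre[0]) == np.sign(sx))
            & (np.sign(coords[:, 1] - centre[1]) == np.sign(sy))
            & (np.sign(coords[:, 2] - centre[2]) == np.sign(sz))
        )
        coords = coords[~in_octant]
    n_kept = coords.shape[0]
    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        if n_kept:
            trimesh.PointCloud(coords).export(f"{path}_voxels.ply")
        if hull is not None:
            export_hull_mesh(hull, f"{path}_hull.ply")
    return {"n_rejecting": n_total, "n_exported": n_kept, "coords": coords}


def export_hull_mesh(boundary, path) -> None:
    """Write a convex boundary as a PLY mesh."""
    mesh = trimesh.Trimesh(
        vertices=np.asarray(boundary.vertices), faces=np.asarray(boundary.facets)
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    mesh.export(str(path))


def save_projection_png(
    img: ProjectionImage, path, title: str = "", cmap: str = "cividis"
) -> None:
    """Render a projection to PNG with a colour bar; outside-domain pixels
    are shown in a distinct neutral colour."""
    fig, ax = plt.subplots(figsize=(5, 4.2))
    cm = matplotlib.colormaps[cmap].copy()
    cm.set_bad("0.85")
    shown = np.ma.masked_invalid(img.pixels)
    vmax = 1.0 if img.kind == "proportion_reject" else None
    im = ax.imshow(shown, origin="lower", cmap=cm, vmin=0.0, vmax=vmax)
    label = (
        "proportion of voxels rejecting CSR"
        if img.kind == "proportion_reject"
        else "mean intensity along projection"
    )
    fig.colorbar(im, ax=ax, label=label)
    if title:
        ax.set_title(title)
    ax.set_xlabel("x (voxels)")
    ax.set_ylabel("y (voxels)" if img.axis == "z" else "z (voxels)")
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
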