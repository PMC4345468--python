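"""Segmentation: image stack -> convex nuclear boundary + compartment centres.

The nuclear envelope channel is thresholded (Otsu on the full 3D histogram by
default; fixed-value and quantile thresholds are available since the choice
of thresholder is not critical for convex-hull delineation), the convex hull
of the largest connected foreground component gives the boundary, and each
connected compartment component above a minimum size is reduced to the
unweighted centroid of its voxel centres.  Binary (rather than
intensity-weighted) centroids are used because they are stable under
threshold changes; intensity weighting is available as an option.
"""
from __future__ import annotations

import logging
import re
import warnings
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ConfigurationError, DataError
from .geometry import ConvexBoundary, PointPattern, clip_to_surface, convex_boundary_from_points
from .io_stacks import ImageStack

log = logging.getLogger("nucleomap")

__all__ = [
    "ConvexBoundary",
    "PointPattern",
    "threshold_channel",
    "boundary_hull",
    "compartment_centres",
    "segment_replicate",
]

#: Default connectivity for blob labelling: 26 (vertex-connected), the
#: standard choice for anisotropic confocal stacks.
DEFAULT_CONNECTIVITY = 26

#: Components smaller than this many voxels are rejected as noise.
DEFAULT_MIN_SIZE = 4

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def threshold_channel(stack: ImageStack, role: str, method: str = "otsu") -> np.ndarray:
    """Binary mask of one channel by a global threshold.

    ``method`` is ``"otsu"`` (full 3D histogram), ``"fixed:<value>"`` or
    ``"quantile:<q>"``.  An all-zero channel yields an empty mask with a
    warning rather than an error.
    """
    img = stack.channel(role)
    if not np.any(img):
        warnings.warn(f"channel {role!r} is entirely zero; returning empty mask")
        return np.zeros(img.shape, dtype=bool)
    if method == "otsu":
        if np.ptp(img) == 0:
            warnings.warn(f"channel {role!r} is constant; returning empty mask")
            return np.zeros(img.shape, dtype=bool)
        thr = threshold_otsu(img.ravel())
        return img > thr
    m = re.fullmatch(r"fixed:([-+0-9.eE]+)", method)
    if m:
        return img > float(m.group(1))
    m = re.fullmatch(r"quantile:([0-9.eE]+)", method)
    if m:
        q = float(m.group(1))
        if not (0 < q < 1):
            raise ConfigurationError(f"quantile must be in (0, 1), got {q}")
        return img > np.quantile(img, q)
    raise ConfigurationError(
        f"unknown threshold method {method!r}; use 'otsu', 'fixed:<v>' or 'quantile:<q>'"
    )


def _largest_component(mask: np.ndarray, connectivity: int) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n <= 1:
        return mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == sizes.argmax()


def boundary_hull(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    connectivity: int = DEFAULT_CONNECTIVITY,
    replicate_id: str = "",
) -> ConvexBoundary:
    """Convex hull (physical units) of the largest foreground component.

    Voxel centres of the largest 26-connected component are hulled; requires
    at least four non-coplanar foreground voxels.
    """
    if connectivity not in _STRUCTURES:
        raise ConfigurationError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    mask = _largest_component(np.asarray(mask, dtype=bool), connectivity)
    kk, jj, ii = np.nonzero(mask)
    if kk.size < 4:
        raise DataError(
            f"replicate {replicate_id!r}: fewer than 4 boundary voxels ({kk.size})"
        )
    sz, sy, sx = spacing
    pts = np.column_stack([(ii + 0.5) * sx, (jj + 0.5) * sy, (kk + 0.5) * sz])
    try:
        return convex_boundary_from_points(pts)
    except DataError as exc:
        raise DataError(f"replicate {replicate_id!r}: degenerate boundary mask ({exc})") from exc


def compartment_centres(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    boundary: ConvexBoundary,
    min_size: int = DEFAULT_MIN_SIZE,
    connectivity: int = DEFAULT_CONNECTIVITY,
    replicate_id: str = "",
    weights: Optional[np.ndarray] = None,
) -> PointPattern:
    """Reduce compartment components to their centres of gravity.

    Components (26-connectivity by default) with fewer than ``min_size``
    voxels are dropped; each survivor becomes the centroid of its voxel
    centres in physical units (intensity-weighted when ``weights`` is
    given).  Centroids falling outside the hull are clipped to the nearest
    hull surface point and flagged.  An empty pattern is legal.
    """
    if connectivity not in _STRUCTURES:
        raise ConfigurationError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return PointPattern(points=np.empty((0, 3)), replicate_id=replicate_id,
                            source_sizes=np.empty(0, dtype=int),
                            clipped=np.empty(0, dtype=bool))
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(sizes >= min_size) + 1
    if keep.size == 0:
        return PointPattern(points=np.empty((0, 3)), replicate_id=replicate_id,
                            source_sizes=np.empty(0, dtype=int),
                            clipped=np.empty(0, dtype=bool))
    w = weights if weights is not None else mask.astype(float)
    coms = np.array(ndimage.center_of_mass(w, labels, keep))  # (k, j, i) index space
    sz, sy, sx = spacing
    pts = np.column_stack(
        [(coms[:, 2] + 0.5) * sx, (coms[:, 1] + 0.5) * sy, (coms[:, 0] + 0.5) * sz]
    )
    pts, was_clipped = clip_to_surface(boundary, pts)
    if np.any(was_clipped):
        log.info(
            "replicate %s: clipped %d/%d compartment centres onto the hull",
            replicate_id, int(was_clipped.sum()), len(pts),
        )
    return PointPattern(
        points=pts,
        replicate_id=replicate_id,
        source_sizes=sizes[keep - 1],
        clipped=was_clipped,
    )


def segment_replicate(
    stack: ImageStack,
    threshold_method: str = "otsu",
    min_size: int = DEFAULT_MIN_SIZE,
    connectivity: int = DEFAULT_CONNECTIVITY,
    replicate_id: str = "",
) -> tuple[ConvexBoundary, PointPattern]:
    """Full segmentation of one replicate: boundary hull + compartment centres."""
    env_mask = threshold_channel(stack, "envelope", threshold_method)
    boundary = boundary_hull(env_mask, stack.spacing, connectivity, replicate_id)
    comp_mask = threshold_channel(stack, "compartment", threshold_method)
    pattern = compartment_centres(
        comp_mask, stack.spacing, boundary, min_size, connectivity, replicate_id
    )
    return boundary, pattern
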