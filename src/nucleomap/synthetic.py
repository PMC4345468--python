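"""Synthetic cohorts of nuclei with known spatial-preference ground truth.

Every pipeline stage is validated against data produced here: convex, ovoid,
variably shaped nuclear boundaries (emulating flat-lying fibroblast nuclei,
which are smooth and convex, elongated in-plane and thin along the optical
axis), compartment point patterns drawn from named spatial-preference models,
and optionally rendered two-channel image stacks (envelope shell + blurred,
noisy compartment blobs).

Spatial-preference models (all radial coordinates are the *fractional
radius*: centroid distance divided by the centroid-to-surface distance along
the same ray, so 1.0 is the boundary regardless of shape):

``csr``
    Complete spatial randomness — uniform in the hull; the null model.
``central``
    Uniform draws radially shrunk toward the centroid by a factor drawn from
    a half-normal of width ``sigma_r``; emulates a preference for the centre.
``annular``
    Points at fractional radius ~ Normal(``r0``, ``w``) along uniform
    directions; emulates an annular preference.
``shell_excluded``
    CSR restricted to fractional radius <= 1 - ``t``; emulates compartments
    excluded from the nuclear boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay

from .errors import ConfigurationError, DataError, GenerationError
from .geometry import (
    ConvexBoundary,
    PointPattern,
    convex_boundary_from_points,
    fractional_radius,
    ray_exit_distance,
    sample_uniform,
)
from .io_stacks import ImageStack, write_stack, write_table

__all__ = [
    "ShapeSpec",
    "PatternSpec",
    "ImagingSpec",
    "SyntheticNucleus",
    "generate_boundary",
    "sample_pattern",
    "render_stack",
    "generate_cohort",
    "write_cohort",
]

#: Default model parameters: chosen once as biologically plausible strengths
#: for the three alternatives (central width, annulus mid-radius/width,
#: excluded outer-shell thickness as fractions of the nuclear radius).
DEFAULT_MODEL_PARAMS = {
    "csr": {},
    "central": {"sigma_r": 0.3},
    "annular": {"r0": 0.65, "w": 0.1},
    "shell_excluded": {"t": 0.25},
}

_N_SURFACE_SAMPLES = 1000


@dataclass
class ShapeSpec:
    """Parameters of one synthetic nuclear boundary.

    ``semi_axes = (a, b, c)`` with ``a >= b >= c > 0`` (lengths);
    ``bump_amplitude`` perturbs the radius by a smooth random field (fraction
    of local radius, <= 0.15 to preserve convexity); ``tip_sharpening``
    elongates the +x half before the random in-plane rotation, creating a
    unique ovoid tip.
    """

    semi_axes: tuple[float, float, float] = (9.0, 6.5, 3.0)
    bump_amplitude: float = 0.05
    tip_sharpening: float = 0.25
    rng_seed: int = 0

    def __post_init__(self):
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ConfigurationError(f"semi_axes must satisfy a >= b >= c > 0, got {self.semi_axes}")
        if not (0 <= self.bump_amplitude <= 0.15):
            raise ConfigurationError("bump_amplitude must be in [0, 0.15]")
        if not (0 <= self.tip_sharpening <= 0.5):
            raise ConfigurationError("tip_sharpening must be in [0, 0.5]")


@dataclass
class PatternSpec:
    """Parameters of one compartment point pattern.

    ``n_points`` is either a fixed count or ``("poisson", mean)``.
    ``model_params`` defaults are taken from :data:`DEFAULT_MODEL_PARAMS`.
    """

    model: str = "csr"
    n_points: int | tuple = 8
    model_params: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self):
        if self.model not in DEFAULT_MODEL_PARAMS:
            raise ConfigurationError(
                f"unknown pattern model {self.model!r}; "
                f"choose from {sorted(DEFAULT_MODEL_PARAMS)}"
            )
        params = dict(DEFAULT_MODEL_PARAMS[self.model])
        params.update(self.model_params)
        self.model_params = params
        for key, val in params.items():
            if not (0 < float(val) < 1) and key in ("sigma_r", "r0", "w", "t"):
                raise ConfigurationError(f"model parameter {key}={val} must lie in (0, 1)")
        if isinstance(self.n_points, (int, np.integer)):
            if self.n_points < 0:
                raise ConfigurationError("n_points must be >= 0")
        else:
            kind, mean = self.n_points
            if kind != "poisson" or mean < 0:
                raise ConfigurationError(
                    "n_points must be an int or ('poisson', mean >= 0)"
                )

    def draw_count(self, rng: np.random.Generator) -> int:
        if isinstance(self.n_points, (int, np.integer)):
            return int(self.n_points)
        return int(rng.poisson(self.n_points[1]))


@dataclass
class ImagingSpec:
    """Rendering parameters for a two-channel synthetic confocal stack.

    Defaults emulate a confocal z-stack of a flat-lying fibroblast nucleus:
    anisotropic spacing (0.5 axially vs 0.15 laterally, in the same length
    unit as the shape semi-axes, i.e. micrometres for the defaults), a thin
    lamin-like envelope shell, sub-micron compartment blobs, modest optical
    blur and Poisson-like shot noise.
    """

    spacing: tuple[float, float, float] = (0.36, 0.15, 0.15)  # (z, y, x)
    shape: tuple[int, int, int] = (20, 192, 192)  # (nz, ny, nx)
    envelope_thickness: float = 0.45
    blob_radius: float = 0.4
    blur_sigma: float = 0.15
    noise: float = 0.05  # 0 disables; SNR at full scale ~ 1/noise
    rng_seed: int = 0


@dataclass
class SyntheticNucleus:
    """One cohort member: rendered stack (optional) plus ground truth."""

    stack: Optional[ImageStack]
    boundary: ConvexBoundary
    pattern: PointPattern
    info: dict


def _fibonacci_directions(n: int) -> np.ndarray:
    """Near-uniform unit directions on the sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0**0.5) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _bump_field(dirs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth random radial perturbation, normalized to max |f| = 1."""
    f = np.zeros(dirs.shape[0])
    for _ in range(3):
        g = rng.normal(size=3)
        g /= np.linalg.norm(g)
        f += rng.normal() * (dirs @ g) ** 2 + 0.5 * rng.normal() * (dirs @ g)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def generate_boundary(
    spec: ShapeSpec, return_info: bool = False
) -> ConvexBoundary | tuple[ConvexBoundary, dict]:
    """Generate a convex ovoid boundary with an optional sharpened tip.

    The surface is a perturbed ellipsoid: radius along each sampled
    direction is the ellipsoid radius times ``(1 + bump_amplitude * f)`` for
    a smooth random field ``f``; ``tip_sharpening s`` then stretches the +x
    half by ``(1 + s)``, which keeps the body convex (the two halves join
    with a continuous tangent plane at x = 0) and makes +x the most pointed
    end.  A random rotation about the z axis and a random in-plane
    translation are applied last, emulating nuclei lying flat at arbitrary
    orientations.  Raises :class:`GenerationError` if the sampled surface is
    not convex within tolerance.
    """
    rng = np.random.default_rng(spec.rng_seed)
    a, b, c = spec.semi_axes
    dirs = _fibonacci_directions(_N_SURFACE_SAMPLES)
    # Bumps perturb the *unit sphere* radius; the affine axis scaling below
    # preserves convexity, so small smooth perturbations stay convex even
    # for strongly flattened nuclei.
    radius = np.ones(dirs.shape[0])
    if spec.bump_amplitude > 0:
        radius += spec.bump_amplitude * _bump_field(dirs, rng)
    pts = dirs * radius[:, None] * np.array([a, b, c])
    if spec.tip_sharpening > 0:
        pts[:, 0] = np.where(pts[:, 0] > 0, pts[:, 0] * (1 + spec.tip_sharpening), pts[:, 0])

    boundary = convex_boundary_from_points(pts)
    # Post-hoc convexity check: every surface sample must be an extreme
    # point of its own sample set, i.e. a hull vertex; any absorbed sample
    # is tested for how deep inside the hull it fell.
    if boundary.vertices.shape[0] < pts.shape[0]:
        missing = np.ones(pts.shape[0], dtype=bool)
        # vertices are a subset of pts rows; match by nearest identity
        vert_set = {tuple(v) for v in np.round(boundary.vertices, 12)}
        for i, p in enumerate(np.round(pts, 12)):
            if tuple(p) in vert_set:
                missing[i] = False
        if np.any(missing):
            depth = -boundary.signed_distance(pts[missing]).max(axis=1)
            if depth.max() > 1e-6 * boundary.diameter:
                raise GenerationError(
                    f"generated surface is not convex: a sample lies "
                    f"{depth.max():.3g} inside its own hull "
                    f"(bump_amplitude too large?)"
                )

    angle = rng.uniform(0, 2 * np.pi)
    ca, sa = np.cos(angle), np.sin(angle)
    rot = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    shift = np.array([rng.uniform(-1.0, 1.0), rng.uniform(-1.0, 1.0), rng.uniform(-0.2, 0.2)])
    boundary = boundary.transformed(rot, shift)
    if not return_info:
        return boundary
    tip_dir = rot @ np.array([1.0, 0.0, 0.0])
    info = {"rotation": rot, "translation": shift, "tip_direction": tip_dir, "angle": angle}
    return boundary, info


def sample_pattern(
    boundary: ConvexBoundary, spec: PatternSpec, replicate_id: str = ""
) -> PointPattern:
    """Draw a compartment point pattern inside a boundary (see module docs)."""
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.draw_count(rng)
    if n == 0:
        return PointPattern(points=np.empty((0, 3)), replicate_id=replicate_id)
    if boundary.volume <= 0:
        raise DataError("cannot sample points in a degenerate (zero-volume) boundary")
    params = spec.model_params
    c = boundary.centroid

    if spec.model == "csr":
        pts = sample_uniform(boundary, n, rng)
    elif spec.model == "central":
        base = sample_uniform(boundary, n, rng)
        shrink = np.clip(np.abs(rng.normal(0.0, params["sigma_r"], size=n)), 0.0, 1.0)
        pts = c + (base - c) * shrink[:, None]
    elif spec.model == "annular":
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        frac = np.clip(rng.normal(params["r0"], params["w"], size=n), 1e-3, 1.0 - 1e-3)
        t = ray_exit_distance(boundary, c, dirs)
        pts = c + dirs * (frac * t)[:, None]
    elif spec.model == "shell_excluded":
        t_max = 1.0 - params["t"]
        pts = np.empty((n, 3))
        filled = 0
        while filled < n:
            cand = sample_uniform(boundary, 2 * (n - filled) + 8, rng)
            good = cand[fractional_radius(boundary, cand) <= t_max]
            take = min(n - filled, good.shape[0])
            pts[filled : filled + take] = good[:take]
            filled += take
    else:  # pragma: no cover - guarded by PatternSpec validation
        raise ConfigurationError(f"unknown model {spec.model!r}")
    return PointPattern(points=pts, replicate_id=replicate_id)


def render_stack(
    boundary: ConvexBoundary, pattern: PointPattern, imaging: ImagingSpec
) -> ImageStack:
    """Render a two-channel 8-bit stack: envelope shell + compartment blobs.

    Channel 0 (``envelope``) is a shell of the given thickness just inside
    the hull surface; channel 1 (``compartment``) is a sphere of
    ``blob_radius`` at each pattern point.  Both channels are Gaussian
    blurred and, for ``noise > 0``, corrupted with Poisson shot noise scaled
    so the full-scale signal-to-noise ratio is ``1/noise``.
    """
    nz, ny, nx = imaging.shape
    sz, sy, sx = imaging.spacing
    lo, hi = boundary.bounding_box()
    extent = np.array([nx * sx, ny * sy, nz * sz])  # (x, y, z)
    overflow = [
        ax
        for ax, (lo_v, hi_v, ext) in zip("xyz", zip(lo, hi, extent))
        if lo_v < 0 or hi_v > ext
    ]
    if overflow:
        raise DataError(
            f"boundary exceeds the stack extent along axes {overflow!r}; "
            "enlarge the stack shape or recentre the boundary"
        )

    kk, jj, ii = np.indices((nz, ny, nx))
    coords = np.column_stack(
        [((ii.ravel() + 0.5) * sx), ((jj.ravel() + 0.5) * sy), ((kk.ravel() + 0.5) * sz)]
    )
    # Interior test via Delaunay of hull vertices (fast C path).
    tri = Delaunay(boundary.vertices)
    inside = (tri.find_simplex(coords) >= 0).reshape(nz, ny, nx)

    # Envelope: a shell of the given thickness just inside the hull surface,
    # so the outer edge of the stained shell coincides with the ground-truth
    # boundary (the lamina lines the inner face of the envelope).
    d_in = ndimage.distance_transform_edt(inside, sampling=imaging.spacing)
    shell = (d_in > 0) & (d_in <= imaging.envelope_thickness)
    envelope = shell.astype(float) * 200.0

    compartment = np.zeros((nz, ny, nx))
    r = imaging.blob_radius
    for p in pattern.points:
        x, y, z = p
        k0 = max(int((z - r) / sz - 1), 0)
        k1 = min(int((z + r) / sz + 2), nz)
        j0 = max(int((y - r) / sy - 1), 0)
        j1 = min(int((y + r) / sy + 2), ny)
        i0 = max(int((x - r) / sx - 1), 0)
        i1 = min(int((x + r) / sx + 2), nx)
        kk_l, jj_l, ii_l = np.meshgrid(
            np.arange(k0, k1), np.arange(j0, j1), np.arange(i0, i1), indexing="ij"
        )
        d2 = (
            ((ii_l + 0.5) * sx - x) ** 2
            + ((jj_l + 0.5) * sy - y) ** 2
            + ((kk_l + 0.5) * sz - z) ** 2
        )
        compartment[k0:k1, j0:j1, i0:i1] = np.maximum(
            compartment[k0:k1, j0:j1, i0:i1], 255.0 * (d2 <= r * r)
        )

    if imaging.blur_sigma > 0:
        sig = [imaging.blur_sigma / s for s in imaging.spacing]
        envelope = ndimage.gaussian_filter(envelope, sig)
        compartment = ndimage.gaussian_filter(compartment, sig)

    img = np.stack([envelope, compartment], axis=-1)
    if imaging.noise > 0:
        rng = np.random.default_rng(imaging.rng_seed)
        photons = 1.0 / imaging.noise**2  # photons at full scale
        img = rng.poisson(img / 255.0 * photons) / photons * 255.0
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return ImageStack(
        voxels=img,
        spacing=imaging.spacing,
        channel_map={"envelope": 0, "compartment": 1},
    )


def _default_shape_drawer(rng: np.random.Generator) -> ShapeSpec:
    """Per-nucleus shape variability of a fibroblast-like cohort."""
    a = rng.uniform(8.0, 10.5)
    b = rng.uniform(5.5, 7.5)
    c = rng.uniform(2.5, 3.2)
    return ShapeSpec(
        semi_axes=(a, b, c),
        bump_amplitude=rng.uniform(0.02, 0.08),
        tip_sharpening=rng.uniform(0.2, 0.3),
        rng_seed=int(rng.integers(2**31 - 1)),
    )


def generate_cohort(
    n_nuclei: int,
    pattern_spec: PatternSpec,
    shape_spec_distribution: Optional[Callable[[np.random.Generator], ShapeSpec]] = None,
    imaging: Optional[ImagingSpec] = None,
    seed: int = 0,
    render: bool = True,
) -> list[SyntheticNucleus]:
    """Generate a cohort of nuclei with independent shapes and patterns.

    ``shape_spec_distribution`` maps an rng to a per-nucleus
    :class:`ShapeSpec` (default: fibroblast-like ranges).  With
    ``render=False`` (or ``imaging=None``) no image stacks are rendered and
    only the geometric ground truth is returned — appropriate for tests of
    the registration/intensity/inference stages that consume points and
    boundaries directly.
    """
    if n_nuclei < 1:
        raise ConfigurationError("n_nuclei must be >= 1")
    draw_shape = shape_spec_distribution or _default_shape_drawer
    master = np.random.default_rng(seed)
    members = []
    for idx in range(n_nuclei):
        rng = np.random.default_rng(master.integers(2**31 - 1))
        spec = draw_shape(rng)
        boundary, info = generate_boundary(spec, return_info=True)
        pspec = PatternSpec(
            model=pattern_spec.model,
            n_points=pattern_spec.n_points,
            model_params=dict(pattern_spec.model_params),
            rng_seed=int(rng.integers(2**31 - 1)),
        )
        rep_id = f"rep{idx:04d}"
        pattern = sample_pattern(boundary, pspec, replicate_id=rep_id)
        stack = None
        if render and imaging is not None:
            img = ImagingSpec(
                spacing=imaging.spacing,
                shape=imaging.shape,
                envelope_thickness=imaging.envelope_thickness,
                blob_radius=imaging.blob_radius,
                blur_sigma=imaging.blur_sigma,
                noise=imaging.noise,
                rng_seed=int(rng.integers(2**31 - 1)),
            )
            centre = np.array(
                [img.shape[2] * img.spacing[2], img.shape[1] * img.spacing[1], img.shape[0] * img.spacing[0]]
            ) / 2.0
            offset = centre - boundary.centroid
            boundary = boundary.transformed(np.eye(3), offset)
            pattern = PointPattern(
                points=pattern.points + offset, replicate_id=rep_id
            )
            stack = render_stack(boundary, pattern, img)
        info["shape_spec"] = spec
        info["pattern_spec"] = pspec
        members.append(
            SyntheticNucleus(stack=stack, boundary=boundary, pattern=pattern, info=info)
        )
    return members


def write_cohort(members: Sequence[SyntheticNucleus], out_dir) -> Path:
    """Write rendered stacks as TIFFs plus a cohort manifest CSV.

    Returns the manifest path.  Ground-truth centres are also written for
    end-to-end validation.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth_rows = []
    for idx, m in enumerate(members):
        rep_id = m.pattern.replicate_id or f"rep{idx:04d}"
        stack_path = ""
        if m.stack is not None:
            stack_path = f"stack_{idx:04d}.tif"
            write_stack(m.stack, out_dir / stack_path)
        spec = m.info.get("shape_spec")
        pspec = m.info.get("pattern_spec")
        rows.append(
            {
                "replicate_id": rep_id,
                "stack": stack_path,
                "model": pspec.model if pspec else "",
                "n_points": len(m.pattern),
                "semi_a": spec.semi_axes[0] if spec else np.nan,
                "semi_b": spec.semi_axes[1] if spec else np.nan,
                "semi_c": spec.semi_axes[2] if spec else np.nan,
                "shape_seed": spec.rng_seed if spec else -1,
                "pattern_seed": pspec.rng_seed if pspec else -1,
            }
        )
        for p in m.pattern.points:
            truth_rows.append(
                {"replicate_id": rep_id, "x": p[0], "y": p[1], "z": p[2]}
            )
    manifest = out_dir / "manifest.csv"
    write_table(rows, manifest)
    write_table(
        truth_rows, out_dir / "truth_centres.csv", columns=["replicate_id", "x", "y", "z"]
    )
    return manifest
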