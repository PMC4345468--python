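import numpy as np
import pytest

from nucleomap.geometry import ConvexBoundary, convex_boundary_from_points
from nucleomap.synthetic import PatternSpec, ShapeSpec, generate_boundary, generate_cohort


def fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@pytest.fixture(scope="session")
def unit_sphere_boundary() -> ConvexBoundary:
    return convex_boundary_from_points(fibonacci_sphere(800))


@pytest.fixture(scope="session")
def ellipsoid_boundary() -> ConvexBoundary:
    """Plain ellipsoid with semi-axes (10, 7, 3), no bumps, no tip, unrotated."""
    pts = fibonacci_sphere(1000) * np.array([10.0, 7.0, 3.0])
    return convex_boundary_from_points(pts)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight CSR nuclei without rendered stacks (geometry ground truth only)."""
    return generate_cohort(
        8, PatternSpec(model="csr", n_points=6, rng_seed=0), seed=11, render=False
    )
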