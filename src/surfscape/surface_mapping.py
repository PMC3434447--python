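"""Map grid scalars onto mesh vertices and derive material channels.

The potential at each mesh vertex is the trilinear interpolation of the
8 surrounding grid nodes. MLP values are then turned into a gray level:
the working range [-3, 1] maps onto [0, 1] with MLP 0 pinned at gray
0.5 — a two-segment piecewise-linear map (one linear map cannot satisfy
both constraints). Gray drives the material: hydrophobic (bright) areas
render shiny and smooth, hydrophilic (dark) areas dull and rough, so
``specular = gray`` and ``roughness = noise_amplitude = 1 - gray``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .core import ScalarGrid, TriangleMesh
from .errors import ContractError, OutOfBoundsError

__all__ = [
    "GrayMapParams",
    "sample_grid_at_vertices",
    "sample_grid_at_points",
    "mlp_to_gray",
    "gray_to_material_channels",
]


def sample_grid_at_points(grid: ScalarGrid, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of ``grid`` at arbitrary points (exact at
    grid nodes and for affine fields)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    inside = grid.contains(points)
    if not inside.all():
        bad = int(np.flatnonzero(~inside)[0])
        raise OutOfBoundsError(
            f"point {bad} at {points[bad]} lies outside the grid box "
            f"[{grid.origin}, {grid.upper_corner}]; increase grid padding"
        )
    interp = RegularGridInterpolator(
        tuple(grid.axis_coordinates(a) for a in range(3)),
        grid.values,
        method="linear",
        bounds_error=False,
        fill_value=None,
    )
    return interp(points)


def sample_grid_at_vertices(
    grid: ScalarGrid, mesh: TriangleMesh, channel_name: str
) -> TriangleMesh:
    """Add a per-vertex channel sampled from ``grid`` (in place; returns
    the mesh for chaining). Raises OutOfBoundsError naming the first
    offending vertex if any vertex escapes the grid box."""
    try:
        values = sample_grid_at_points(grid, mesh.vertices)
    except OutOfBoundsError as exc:
        raise OutOfBoundsError(f"vertex {exc}") from None
    mesh.set_channel(channel_name, values)
    return mesh


@dataclass
class GrayMapParams:
    """Knots and post-adjustments of the MLP-to-gray transfer curve.

    ``contrast`` scales about gray 0.5 and ``brightness`` shifts, both
    applied after the piecewise-linear knot map, then clamped to [0, 1]:
    ``out = clamp((g - 0.5) * contrast + 0.5 + brightness)``.
    """

    in_low: float = -3.0
    in_mid: float = 0.0
    in_high: float = 1.0
    out_low: float = 0.0
    out_mid: float = 0.5
    out_high: float = 1.0
    contrast: float = 1.0
    brightness: float = 0.0

    def __post_init__(self) -> None:
        if not (self.in_low < self.in_mid < self.in_high):
            raise ContractError("gray map knots must satisfy low < mid < high")
        if self.contrast < 0:
            raise ContractError("contrast must be non-negative")


def mlp_to_gray(
    mlp: np.ndarray, params: GrayMapParams | None = None
) -> np.ndarray:
    """Gray level in [0, 1] from MLP; monotone non-decreasing.

    Defaults: [-3, 0] -> [0, 0.5] and [0, 1] -> [0.5, 1], inputs outside
    [-3, 1] clamped to the endpoints.
    """
    if params is None:
        params = GrayMapParams()
    mlp = np.asarray(mlp, dtype=float)
    g = np.interp(
        mlp,
        [params.in_low, params.in_mid, params.in_high],
        [params.out_low, params.out_mid, params.out_high],
    )
    g = (g - 0.5) * params.contrast + 0.5 + params.brightness
    return np.clip(g, 0.0, 1.0)


def gray_to_material_channels(
    gray: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-vertex (specular, roughness, noise_amplitude) from gray.

    Bright/hydrophobic: reflective and smooth (no noise); dark/hydrophilic:
    dull with full-amplitude roughness noise.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.size and (gray.min() < 0.0 or gray.max() > 1.0):
        raise ContractError("gray channel must lie in [0, 1]")
    specular = gray.copy()
    roughness = 1.0 - gray
    noise_amplitude = 1.0 - gray
    return specular, roughness, noise_amplitude
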