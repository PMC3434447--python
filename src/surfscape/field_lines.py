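"""Electric field lines from an EP grid and a molecular surface.

The multi-step procedure mirrors the classic surface-electrostatics
visualization workflow:

1. EP is sampled onto the mesh vertices (trilinear interpolation).
2. The scalar EP grid is differentiated into a gradient vector grid.
3. Surface patches (faces) with high |EP| are selected by Monte Carlo
   sampling weighted by |EP| x area, subject to a minimum-potential
   threshold; the expected number of lines is proportional to the
   integrated surface potential (``line_density`` in lines per eV/Å²).
4. From each seed, a line is integrated in both directions along the
   gradient with fixed small steps, stopping when it (a) reaches the
   grid boundary, (b) intersects the mesh, or (c) enters a region where
   the field is too low. Lines are oriented positive -> negative.

The integrator is fixed-step Euler on the *normalized* gradient
(default step 0.5 x the minimum grid spacing); normalization keeps the
step length uniform even near charges where |grad EP| blows up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .core import (
    FieldLine,
    FieldLineFile,
    ScalarGrid,
    Termination,
    TriangleMesh,
    VectorGrid,
)
from .ep_field import kt_per_e_to_ev
from .errors import ContractError
from .geometry import MeshIntersector
from .surface_mapping import sample_grid_at_vertices

__all__ = [
    "SeedControls",
    "TracingParams",
    "Seed",
    "gradient_grid",
    "select_seeds",
    "trace_line",
    "compute_field_lines",
]

DEFAULT_LOW_FIELD_THRESHOLD = 1e-4  # field units / Å


def gradient_grid(ep: ScalarGrid) -> VectorGrid:
    """Finite-difference gradient of the EP grid, same lattice.

    Central differences over 2*spacing at interior nodes, one-sided at
    the boundary (exact for affine fields everywhere, for quadratics at
    interior nodes).
    """
    if any(c < 2 for c in ep.counts):
        raise ContractError("gradient needs at least 2 nodes per axis")
    gx, gy, gz = np.gradient(
        ep.values, ep.spacing[0], ep.spacing[1], ep.spacing[2]
    )
    return VectorGrid(
        origin=ep.origin,
        spacing=ep.spacing,
        vectors=np.stack([gx, gy, gz], axis=-1),
    )


@dataclass
class SeedControls:
    """User controls of the seed selection.

    minimum_potential: absolute EP (field units of the ep channel) a face
        must reach to emit lines.
    line_density: expected lines per eV/Å² of integrated surface |EP|;
        the total line count scales linearly with the molecule's global
        surface potential.
    rng_seed: seed of the Monte Carlo draw (fixed seed => fixed lines).
    ep_in_kt_per_e: whether the ep channel is in kT/e (converted to eV
        for the density bookkeeping); set False for as-labeled eV grids.
    """

    minimum_potential: float = 0.0
    line_density: float = 1.0
    rng_seed: int = 0
    ep_in_kt_per_e: bool = True
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.minimum_potential < 0:
            raise ContractError("minimum_potential is interpreted on |EP|; must be >= 0")
        if self.line_density < 0:
            raise ContractError("line_density must be >= 0")


@dataclass
class Seed:
    position: np.ndarray
    face_id: int
    ep_value: float


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def select_seeds(mesh: TriangleMesh, controls: SeedControls) -> list[Seed]:
    """EP-weighted Monte Carlo selection of line seed points on the mesh.

    Candidate faces have mean-vertex |EP| >= minimum_potential; faces are
    drawn with replacement with probability proportional to |EP| x area,
    and each seed is a uniform random point within its face. Returns an
    empty list (not an error) when nothing qualifies.
    """
    if "ep" not in mesh.channels:
        raise ContractError("mesh lacks an 'ep' channel; sample the EP grid first")
    ep_face = mesh.channels["ep"][mesh.triangles].mean(axis=1)
    areas = mesh.face_areas()
    candidates = np.flatnonzero(np.abs(ep_face) >= controls.minimum_potential)
    if candidates.size == 0 or controls.line_density == 0:
        return []
    weights = np.abs(ep_face[candidates]) * areas[candidates]
    total = weights.sum()
    if total <= 0:
        return []
    total_ev = (
        kt_per_e_to_ev(total, controls.temperature)
        if controls.ep_in_kt_per_e
        else total
    )
    n_seeds = _round_half_away(controls.line_density * float(total_ev))
    if n_seeds <= 0:
        return []
    rng = np.random.default_rng(controls.rng_seed)
    drawn = rng.choice(candidates, size=n_seeds, replace=True, p=weights / total)
    # uniform point in each triangle via the sqrt trick
    r1 = np.sqrt(rng.random(n_seeds))
    r2 = rng.random(n_seeds)
    tri = mesh.triangles[drawn]
    a = mesh.vertices[tri[:, 0]]
    b = mesh.vertices[tri[:, 1]]
    c = mesh.vertices[tri[:, 2]]
    pts = (
        (1 - r1)[:, None] * a
        + (r1 * (1 - r2))[:, None] * b
        + (r1 * r2)[:, None] * c
    )
    return [
        Seed(position=pts[i], face_id=int(drawn[i]), ep_value=float(ep_face[drawn[i]]))
        for i in range(n_seeds)
    ]


@dataclass
class TracingParams:
    """Numerical parameters of the line integrator."""

    step: float | None = None  # Å; default 0.5 x min grid spacing
    low_field_threshold: float = DEFAULT_LOW_FIELD_THRESHOLD
    max_points: int = 2000

    def resolve_step(self, grid_spacing: np.ndarray) -> float:
        if self.step is not None:
            if self.step <= 0:
                raise ContractError("step must be positive")
            return float(self.step)
        return 0.5 * float(np.min(grid_spacing))


def _grad_interpolator(grad: VectorGrid) -> RegularGridInterpolator:
    axes = tuple(
        grad.origin[a] + grad.spacing[a] * np.arange(grad.counts[a])
        for a in range(3)
    )
    return RegularGridInterpolator(
        axes, grad.vectors, method="linear", bounds_error=False, fill_value=None
    )


def _half_trace(
    start: np.ndarray,
    sign: float,
    grad_interp: RegularGridInterpolator,
    lo: np.ndarray,
    hi: np.ndarray,
    intersector: MeshIntersector | None,
    step: float,
    low_field_threshold: float,
    max_points: int,
) -> tuple[list[np.ndarray], Termination]:
    points: list[np.ndarray] = []
    p = np.asarray(start, dtype=float)
    for _ in range(max_points):
        g = sign * grad_interp(p[None, :])[0]
        norm = float(np.linalg.norm(g))
        if norm < low_field_threshold:
            return points, Termination.LOW_FIELD
        u = g / norm
        p_next = p + step * u
        if np.any(p_next < lo) or np.any(p_next > hi):
            return points, Termination.GRID_BOUNDARY
        if intersector is not None:
            t_hit = intersector.first_hit(p, u, step)
            if t_hit is not None:
                points.append(p + t_hit * u)
                return points, Termination.MESH_INTERSECTION
        points.append(p_next)
        p = p_next
    return points, Termination.LOW_FIELD


def trace_line(
    seed: Seed | np.ndarray,
    grad: VectorGrid,
    ep: ScalarGrid,
    mesh: TriangleMesh | None = None,
    step: float = 0.5,
    low_field_threshold: float = DEFAULT_LOW_FIELD_THRESHOLD,
    max_points: int = 2000,
    seed_index: int = 0,
) -> FieldLine:
    """Integrate one field line through ``seed`` in both directions.

    Fixed-step Euler along the trilinearly interpolated unit gradient;
    the two half-traces are concatenated and oriented from the positive
    (high-EP) end to the negative end. The recorded termination is that
    of the downstream (negative-going) half. Every returned point lies
    inside the grid box.
    """
    if isinstance(seed, Seed):
        start = np.asarray(seed.position, dtype=float)
        seed_ep = seed.ep_value
    else:
        start = np.asarray(seed, dtype=float)
        seed_ep = float("nan")
    if not ep.contains(start[None, :])[0]:
        raise ContractError(f"seed {start} lies outside the EP grid box")
    if step <= 0:
        raise ContractError("step must be positive")
    grad_interp = _grad_interpolator(grad)
    lo, hi = ep.origin, ep.upper_corner
    intersector = MeshIntersector(mesh) if mesh is not None and mesh.n_triangles else None
    up, _term_up = _half_trace(
        start, +1.0, grad_interp, lo, hi, intersector,
        step, low_field_threshold, max_points,
    )
    down, term_down = _half_trace(
        start, -1.0, grad_interp, lo, hi, intersector,
        step, low_field_threshold, max_points,
    )
    points = list(reversed(up)) + [start] + down
    return FieldLine(
        points=np.asarray(points),
        seed_index=seed_index,
        seed_ep=seed_ep,
        termination=term_down,
    )


def compute_field_lines(
    mesh: TriangleMesh,
    ep_grid: ScalarGrid,
    controls: SeedControls | None = None,
    tracing: TracingParams | None = None,
) -> FieldLineFile:
    """Full pipeline: EP on surface -> gradient grid -> weighted seeds ->
    bidirectional traces. Deterministic for a fixed ``rng_seed``."""
    if controls is None:
        controls = SeedControls()
    if tracing is None:
        tracing = TracingParams()
    sample_grid_at_vertices(ep_grid, mesh, "ep")
    grad = gradient_grid(ep_grid)
    seeds = select_seeds(mesh, controls)
    step = tracing.resolve_step(ep_grid.spacing)
    normals = mesh.face_normals()
    lines: list[FieldLine] = []
    for i, seed in enumerate(seeds):
        lifted = seed.position + 0.5 * step * normals[seed.face_id]
        if not ep_grid.contains(lifted[None, :])[0]:
            continue
        lines.append(
            trace_line(
                Seed(position=lifted, face_id=seed.face_id, ep_value=seed.ep_value),
                grad,
                ep_grid,
                mesh=mesh,
                step=step,
                low_field_threshold=tracing.low_field_threshold,
                max_points=tracing.max_points,
                seed_index=i,
            )
        )
    header = {
        "minimum_potential": controls.minimum_potential,
        "line_density": controls.line_density,
        "rng_seed": controls.rng_seed,
        "step": step,
        "low_field_threshold": tracing.low_field_threshold,
        "n_seeds": len(seeds),
    }
    return FieldLineFile(lines=lines, header=header)
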