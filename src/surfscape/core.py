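"""Core in-memory containers shared by every pipeline stage.

Units convention: all coordinates, spacings and radii are in Ångström;
partial charges in elementary charges; electrostatic potential in kT/e
unless a grid is explicitly labelled otherwise; the molecular lipophilic
potential (MLP) is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .errors import ContractError

__all__ = [
    "Atom",
    "Structure",
    "ScalarGrid",
    "VectorGrid",
    "TriangleMesh",
    "Termination",
    "FieldLine",
    "FieldLineFile",
]


@dataclass
class Atom:
    """One atom record: identity, position, and optional PQR charge/radius.

    ``charge`` and ``radius`` are ``None`` for plain PDB input so that
    charge-dependent stages fail loudly instead of computing a zero field.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    position: np.ndarray
    charge: Optional[float] = None
    radius: Optional[float] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ContractError(
                f"atom {self.serial}: position must be a finite 3-vector"
            )
        if self.radius is not None and not self.radius > 0:
            raise ContractError(f"atom {self.serial}: radius must be > 0")


@dataclass
class Structure:
    """An ordered set of atoms for one conformation (animation frame)."""

    atoms: list[Atom]
    frame_index: int = 0
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ContractError("a structure must contain at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ContractError("atom serials must be unique within a frame")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        """Per-atom charges (e); raises if any atom lacks one."""
        if any(a.charge is None for a in self.atoms):
            raise ContractError(
                "structure has atoms without charges; supply PQR input "
                "(occupancy/B-factor columns carry charge and radius)"
            )
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        if any(a.radius is None for a in self.atoms):
            raise ContractError("structure has atoms without radii")
        return np.array([a.radius for a in self.atoms], dtype=float)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        pos = self.positions
        return pos.min(axis=0), pos.max(axis=0)


@dataclass
class ScalarGrid:
    """Scalar values on a regular 3D lattice (the OpenDX payload).

    ``values`` is indexed ``[ix, iy, iz]``; the grid node ``(ix,iy,iz)``
    sits at ``origin + spacing * (ix,iy,iz)``.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    unit: str = "as-labeled"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ContractError("grid values must be a 3D array")
        if any(c < 2 for c in self.values.shape):
            raise ContractError("grid must have at least 2 nodes per axis")
        if not np.all(self.spacing > 0):
            raise ContractError("grid spacing must be positive on every axis")

    @property
    def counts(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def upper_corner(self) -> np.ndarray:
        return self.origin + self.spacing * (np.array(self.counts) - 1)

    def axis_coordinates(self, axis: int) -> np.ndarray:
        n = self.counts[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the grid's bounding box."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo, hi = self.origin, self.upper_corner
        return np.all((pts >= lo) & (pts <= hi), axis=1)


@dataclass
class VectorGrid:
    """A 3-vector per node on the same lattice as its source ScalarGrid."""

    origin: np.ndarray
    spacing: np.ndarray
    vectors: np.ndarray  # shape (nx, ny, nz, 3)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[3] != 3:
            raise ContractError("vector grid must have shape (nx, ny, nz, 3)")

    @property
    def counts(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    @property
    def upper_corner(self) -> np.ndarray:
        return self.origin + self.spacing * (np.array(self.counts) - 1)


@dataclass
class TriangleMesh:
    """Triangle surface mesh with named per-vertex scalar channels.

    Channels used by the pipeline: ``ep``, ``mlp``, ``gray``, ``specular``,
    ``roughness``, ``noise_amplitude``.
    """

    vertices: np.ndarray  # (V, 3) float
    triangles: np.ndarray  # (F, 3) int, 0-based
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=int).reshape(-1, 3)
        if len(self.triangles) and self.triangles.max() >= len(self.vertices):
            raise ContractError("triangle index exceeds vertex count")
        for name, ch in self.channels.items():
            ch = np.asarray(ch, dtype=float)
            if ch.shape != (len(self.vertices),):
                raise ContractError(
                    f"channel {name!r} length {ch.shape} does not match "
                    f"vertex count {len(self.vertices)}"
                )
            self.channels[name] = ch

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def set_channel(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_vertices,):
            raise ContractError(
                f"channel {name!r} must have one value per vertex"
            )
        self.channels[name] = values

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        norm = np.linalg.norm(cross, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return cross / norm

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )


class Termination(str, Enum):
    """Why a field-line half-trace stopped."""

    GRID_BOUNDARY = "grid_boundary"
    MESH_INTERSECTION = "mesh_intersection"
    LOW_FIELD = "low_field"


@dataclass
class FieldLine:
    """An electric field line, ordered from positive toward negative EP."""

    points: np.ndarray  # (K, 3)
    seed_index: int
    seed_ep: float
    termination: Termination

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 1:
            raise ContractError("a field line needs at least one point")
        self.termination = Termination(self.termination)


@dataclass
class FieldLineFile:
    """A set of field lines plus the controls that produced them."""

    lines: list[FieldLine]
    header: dict = field(default_factory=dict)
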