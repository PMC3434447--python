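"""Readers and writers for the pipeline's interchange formats.

Supported formats:

* **PDB** (via gemmi) — coordinates only; multi-model files map model *k*
  to animation frame *k*.
* **PQR** — PDB-like records where the occupancy and B-factor columns
  carry per-atom partial charge (e) and radius (Å). Parsed by whitespace
  tokens, not fixed width, because charge-assignment tools widen columns
  freely.
* **OpenDX** regular scalar grids (the ``.dx`` files exchanged with
  Poisson–Boltzmann solvers and MLP calculators). Only the
  "regular positions, regular connections" dialect is supported; values
  are stored with the last axis (z) fastest.
* **Wavefront OBJ** — the surface mesh, with the per-vertex MLP value
  stored in the V texture coordinate (``vt 0 <mlp>``), one ``vt`` per
  vertex.
* **Field-line text files** — one block per line: a declaration row with
  the point count, seed EP and termination code, then one ``x y z`` row
  per point. The header records the seed controls for reproducibility.
"""

from __future__ import annotations

import os
from pathlib import Path

import gemmi
import numpy as np

from .core import (
    Atom,
    FieldLine,
    FieldLineFile,
    ScalarGrid,
    Structure,
    Termination,
    TriangleMesh,
)
from .errors import ContractError, ParseError, UnsupportedDialectError

__all__ = [
    "read_structure",
    "read_dx",
    "write_dx",
    "write_obj_with_mlp",
    "read_obj",
    "write_field_lines",
    "read_field_lines",
]


# ---------------------------------------------------------------------------
# structures (PDB / PQR)
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    """Best-effort element symbol from a PDB-style atom name."""
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        return "X"
    two = stripped[:2].capitalize()
    if two in ("Cl", "Br", "Fe", "Zn", "Mg", "Na", "Ca", "Mn", "Cu", "Se"):
        return two
    return stripped[0].upper()


def _read_pqr(path: str, frame: int) -> Structure:
    models: list[list[Atom]] = [[]]
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw.split()
            if not rec:
                continue
            tag = rec[0]
            if tag == "ENDMDL":
                models.append([])
                continue
            if tag not in ("ATOM", "HETATM"):
                continue
            # PDB2PQR flavor: ATOM serial name resName [chain] resSeq
            # x y z charge radius  -> 10 or 11 tokens
            if len(rec) not in (10, 11):
                raise ParseError(
                    f"{path}:{lineno}: expected 10 or 11 whitespace-separated "
                    f"fields in PQR record, got {len(rec)}"
                )
            has_chain = len(rec) == 11
            try:
                chain = rec[4] if has_chain else ""
                off = 5 if has_chain else 4
                atom = Atom(
                    serial=int(rec[1]),
                    name=rec[2],
                    element=_element_from_name(rec[2]),
                    residue_name=rec[3],
                    residue_id=int(rec[off]),
                    chain=chain,
                    position=np.array(
                        [float(rec[off + 1]), float(rec[off + 2]), float(rec[off + 3])]
                    ),
                    charge=float(rec[off + 4]),
                    radius=float(rec[off + 5]),
                )
            except (ValueError, ContractError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed PQR record: {exc}") from exc
            models[-1].append(atom)
    models = [m for m in models if m]
    if not models:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    if frame >= len(models):
        raise IndexError(
            f"{path}: requested frame {frame} but file has {len(models)} model(s)"
        )
    return Structure(atoms=models[frame], frame_index=frame, source_path=str(path))


def _read_pdb(path: str, frame: int) -> Structure:
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    if frame >= len(st):
        raise IndexError(
            f"{path}: requested frame {frame} but file has {len(st)} model(s)"
        )
    model = st[frame]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            for at in residue:
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name,
                        residue_name=residue.name,
                        residue_id=residue.seqid.num,
                        chain=chain.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        charge=None,
                        radius=None,
                    )
                )
    if not atoms:
        raise ParseError(f"{path}: model {frame} contains no atoms")
    return Structure(atoms=atoms, frame_index=frame, source_path=str(path))


def read_structure(path: str | os.PathLike, frame: int = 0) -> Structure:
    """Read one conformation from a .pdb or .pqr file.

    ``frame`` selects the model in a multi-model file (0-based). Plain PDB
    atoms carry ``charge=None``/``radius=None`` so the electrostatics stage
    can demand PQR input explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext == ".pqr":
        return _read_pqr(str(path), frame)
    if ext in (".pdb", ".ent"):
        return _read_pdb(str(path), frame)
    raise ContractError(f"{path}: unrecognised structure extension {ext!r}")


# ---------------------------------------------------------------------------
# OpenDX scalar grids
# ---------------------------------------------------------------------------

def read_dx(path: str | os.PathLike) -> ScalarGrid:
    """Read an OpenDX regular scalar grid.

    Only "regular positions, regular connections" grids with diagonal
    deltas are accepted; anything else raises UnsupportedDialectError.
    """
    path = str(path)
    counts = None
    origin = None
    deltas: list[list[float]] = []
    n_items = None
    data: list[float] = []
    in_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if in_data:
                if line.startswith(("attribute", "component", "object", "end")):
                    in_data = False
                    continue
                try:
                    data.extend(float(tok) for tok in line.split())
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad data value: {exc}") from exc
                continue
            tokens = line.split()
            if tokens[0] == "object" and "gridpositions" in tokens:
                try:
                    counts = tuple(int(t) for t in tokens[-3:])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad counts: {exc}") from exc
            elif tokens[0] == "object" and "gridconnections" in tokens:
                pass
            elif tokens[0] == "origin":
                origin = [float(t) for t in tokens[1:4]]
            elif tokens[0] == "delta":
                deltas.append([float(t) for t in tokens[1:4]])
            elif tokens[0] == "object" and "array" in tokens:
                if "items" in tokens:
                    n_items = int(tokens[tokens.index("items") + 1])
                if tokens[-2:] == ["data", "follows"]:
                    in_data = True
    if counts is None or origin is None or len(deltas) != 3:
        raise UnsupportedDialectError(
            f"{path}: not a regular-positions OpenDX grid (missing "
            f"gridpositions/origin/3 deltas)"
        )
    delta = np.array(deltas, dtype=float)
    if not np.allclose(delta, np.diag(np.diag(delta))):
        raise UnsupportedDialectError(
            f"{path}: non-axis-aligned deltas are not supported"
        )
    spacing = np.diag(delta)
    expected = counts[0] * counts[1] * counts[2]
    if n_items is not None and n_items != expected:
        raise ParseError(
            f"{path}: item count {n_items} != product of grid counts {expected}"
        )
    if len(data) != expected:
        raise ParseError(
            f"{path}: read {len(data)} values, expected {expected}"
        )
    values = np.asarray(data, dtype=float).reshape(counts)  # z fastest
    return ScalarGrid(origin=np.asarray(origin), spacing=spacing, values=values)


def write_dx(grid: ScalarGrid, path: str | os.PathLike, comment: str = "") -> None:
    """Write a ScalarGrid as an OpenDX regular grid (z fastest, 3/row)."""
    nx, ny, nz = grid.counts
    flat = grid.values.reshape(-1)  # C order == z fastest
    with open(path, "w") as fh:
        if comment:
            for ln in comment.splitlines():
                fh.write(f"# {ln}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(
            "origin {:.12g} {:.12g} {:.12g}\n".format(*grid.origin)
        )
        fh.write(f"delta {grid.spacing[0]:.12g} 0 0\n")
        fh.write(f"delta 0 {grid.spacing[1]:.12g} 0\n")
        fh.write(f"delta 0 0 {grid.spacing[2]:.12g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {flat.size} "
            "data follows\n"
        )
        for i in range(0, flat.size, 3):
            chunk = flat[i : i + 3]
            fh.write(" ".join(format(v, ".17g") for v in chunk) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


# ---------------------------------------------------------------------------
# OBJ with MLP stored in the V texture coordinate
# ---------------------------------------------------------------------------

def write_obj_with_mlp(mesh: TriangleMesh, path: str | os.PathLike) -> None:
    """Write an OBJ whose ``vt`` V field carries the per-vertex MLP value.

    One ``vt 0 <mlp>`` record per vertex, faces as ``f i/i j/j k/k`` so the
    texture index always matches the vertex index.
    """
    if mesh.n_vertices == 0:
        raise ContractError("refusing to write an empty mesh")
    if "mlp" not in mesh.channels:
        raise ContractError(
            "mesh lacks an 'mlp' channel; run the MLP mapping stage first"
        )
    mlp = mesh.channels["mlp"]
    with open(path, "w") as fh:
        fh.write("# surfscape molecular surface; vt V field = MLP value\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for m in mlp:
            fh.write(f"vt 0.000000 {m:.6f}\n")
        for t in mesh.triangles:
            a, b, c = (int(i) + 1 for i in t)
            fh.write(f"f {a}/{a} {b}/{b} {c}/{c}\n")


def read_obj(path: str | os.PathLike) -> TriangleMesh:
    """Read v/vt/f records; recovers the MLP channel from the vt V field."""
    vertices: list[list[float]] = []
    vt_v: list[float] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            tokens = raw.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            tag = tokens[0]
            try:
                if tag == "v":
                    vertices.append([float(t) for t in tokens[1:4]])
                elif tag == "vt":
                    vt_v.append(float(tokens[2]))
                elif tag == "f":
                    idx = [int(t.split("/")[0]) - 1 for t in tokens[1:4]]
                    faces.append(idx)
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed OBJ record") from exc
    if not vertices:
        raise ParseError(f"{path}: no vertices found")
    channels = {}
    if vt_v:
        if len(vt_v) != len(vertices):
            raise ParseError(
                f"{path}: {len(vt_v)} vt records for {len(vertices)} vertices"
            )
        channels["mlp"] = np.asarray(vt_v)
    return TriangleMesh(
        vertices=np.asarray(vertices),
        triangles=np.asarray(faces, dtype=int).reshape(-1, 3),
        channels=channels,
    )


# ---------------------------------------------------------------------------
# field-line ASCII files
# ---------------------------------------------------------------------------

def write_field_lines(line_file: FieldLineFile, path: str | os.PathLike) -> None:
    """Write field lines as plain text (one block per line, 6 decimals)."""
    with open(path, "w") as fh:
        fh.write("# surfscape field lines\n")
        for key in sorted(line_file.header):
            fh.write(f"# {key} = {line_file.header[key]}\n")
        fh.write(f"nlines {len(line_file.lines)}\n")
        for i, line in enumerate(line_file.lines):
            fh.write(
                f"line {i} npoints {len(line.points)} "
                f"seed_ep {line.seed_ep:.6f} termination {line.termination.value}\n"
            )
            for p in line.points:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def read_field_lines(path: str | os.PathLike) -> FieldLineFile:
    """Read the field-line text format written by :func:`write_field_lines`."""
    header: dict = {}
    lines: list[FieldLine] = []
    with open(path) as fh:
        rows = fh.readlines()
    i = 0
    n_declared = None
    while i < len(rows):
        row = rows[i].strip()
        i += 1
        if not row:
            continue
        if row.startswith("#"):
            body = row.lstrip("# ").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                header[k.strip()] = v.strip()
            continue
        tokens = row.split()
        if tokens[0] == "nlines":
            n_declared = int(tokens[1])
            continue
        if tokens[0] != "line":
            raise ParseError(f"{path}: unexpected row {row!r}")
        try:
            block_idx = int(tokens[1])
            npoints = int(tokens[tokens.index("npoints") + 1])
            seed_ep = float(tokens[tokens.index("seed_ep") + 1])
            term = tokens[tokens.index("termination") + 1]
        except (ValueError, IndexError) as exc:
            raise ParseError(
                f"{path}: malformed line declaration in block {len(lines)}"
            ) from exc
        pts = []
        for j in range(npoints):
            if i >= len(rows):
                raise ParseError(
                    f"{path}: block {block_idx} truncated "
                    f"({j} of {npoints} points)"
                )
            tok = rows[i].split()
            if len(tok) != 3:
                raise ParseError(
                    f"{path}: block {block_idx}: bad coordinate row {rows[i]!r}"
                )
            pts.append([float(t) for t in tok])
            i += 1
        lines.append(
            FieldLine(
                points=np.asarray(pts),
                seed_index=block_idx,
                seed_ep=seed_ep,
                termination=Termination(term),
            )
        )
    if n_declared is not None and n_declared != len(lines):
        raise ParseError(
            f"{path}: header declares {n_declared} lines, found {len(lines)}"
        )
    return FieldLineFile(lines=lines, header=header)
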