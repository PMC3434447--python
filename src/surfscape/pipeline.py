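"""Per-frame pipeline orchestration for still and moving proteins.

For every conformation (frame) the pipeline rebuilds the surface mesh
from scratch — moving proteins change topology (parts merge and
separate), so mesh geometry cannot be reused across frames — then
computes the MLP and EP grids, maps them onto the mesh, derives the
material channels, traces field lines and writes a particle schedule.
Five artifacts are written per frame (OBJ surface with the MLP texture
channel plus a sidecar channel table, MLP .dx, EP .dx, field-line text,
particle schedule) together with the resolved configuration, which alone
suffices to reproduce the frame bit-identically.
"""

from __future__ import annotations

import logging
import re
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io_formats
from .core import Structure, TriangleMesh
from .ep_field import EpParameters, compute_ep_grid, load_ep_grid
from .errors import SurfscapeError
from .field_lines import SeedControls, TracingParams, compute_field_lines
from .mlp_field import LipophilicLibrary, compute_mlp_grid, load_default_library
from .particles import AnimationParams, write_schedule
from .surface_mapping import (
    GrayMapParams,
    gray_to_material_channels,
    mlp_to_gray,
    sample_grid_at_vertices,
)
from .surface_mesh import DEFAULT_PROBE, DEFAULT_VOXEL, build_surface

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "FrameOutputs", "run_frame", "run_sequence"]


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run; serialized next to the outputs."""

    # surface
    voxel: float = DEFAULT_VOXEL
    probe: float = DEFAULT_PROBE
    # MLP
    mlp_formula: str = "testa"
    mlp_spacing: float = 1.0
    library_path: str | None = None  # None = packaged table
    # EP
    ep: EpParameters = field(default_factory=EpParameters)
    ep_dx_path: str | None = None  # imported grid takes precedence
    # channels
    gray: GrayMapParams = field(default_factory=GrayMapParams)
    # field lines
    minimum_potential: float = 0.0
    line_density: float = 1.0
    rng_seed: int = 0
    tracing: TracingParams = field(default_factory=TracingParams)
    # animation
    animation: AnimationParams = field(default_factory=AnimationParams)
    schedule_frames: int = 50
    # padding applied to both grids beyond what the mesh needs
    grid_margin: float = 2.0

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class FrameOutputs:
    """Paths of the artifacts written for one frame."""

    frame_index: int
    obj_path: Path
    channels_path: Path
    mlp_dx_path: Path
    ep_dx_path: Path
    lines_path: Path
    schedule_path: Path
    config_path: Path

    def paths(self) -> list[Path]:
        return [
            self.obj_path,
            self.channels_path,
            self.mlp_dx_path,
            self.ep_dx_path,
            self.lines_path,
            self.schedule_path,
        ]


def _required_padding(structure: Structure, mesh: TriangleMesh, margin: float) -> float:
    """Grid padding so every mesh vertex lies strictly inside the grids."""
    lo, hi = structure.bounding_box()
    mlo = mesh.vertices.min(axis=0)
    mhi = mesh.vertices.max(axis=0)
    need = max(float((lo - mlo).max()), float((mhi - hi).max()), 0.0)
    return need + margin


def _write_channels(mesh: TriangleMesh, path: Path) -> None:
    names = [n for n in ("ep", "gray", "specular", "roughness", "noise_amplitude") if n in mesh.channels]
    with open(path, "w") as fh:
        fh.write("vertex\t" + "\t".join(names) + "\n")
        cols = [mesh.channels[n] for n in names]
        for i in range(mesh.n_vertices):
            fh.write(str(i) + "\t" + "\t".join(f"{c[i]:.6f}" for c in cols) + "\n")


def run_frame(
    structure: Structure,
    config: PipelineConfig,
    out_dir,
    library: LipophilicLibrary | None = None,
) -> FrameOutputs:
    """Run the whole pipeline on one conformation and write its artifacts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if library is None:
        library = (
            LipophilicLibrary.from_file(config.library_path)
            if config.library_path
            else load_default_library()
        )
    t0 = time.perf_counter()

    def _stage(name: str):
        log.info("frame %d: stage %s at %.2fs", structure.frame_index, name,
                 time.perf_counter() - t0)

    try:
        _stage("surface")
        mesh = build_surface(structure, voxel=config.voxel, probe=config.probe)
        pad = _required_padding(structure, mesh, config.grid_margin)

        _stage("mlp")
        mlp_grid = compute_mlp_grid(
            structure,
            library=library,
            formula=config.mlp_formula,
            spacing=config.mlp_spacing,
            padding=pad,
        )
        sample_grid_at_vertices(mlp_grid, mesh, "mlp")
        gray = mlp_to_gray(mesh.channels["mlp"], config.gray)
        mesh.set_channel("gray", gray)
        spec_ch, rough, noise = gray_to_material_channels(gray)
        mesh.set_channel("specular", spec_ch)
        mesh.set_channel("roughness", rough)
        mesh.set_channel("noise_amplitude", noise)

        _stage("ep")
        if config.ep_dx_path:
            ep_grid = load_ep_grid(config.ep_dx_path)
        else:
            ep = EpParameters(**{**asdict(config.ep), "padding": pad})
            ep_grid = compute_ep_grid(structure, ep)

        _stage("field_lines")
        controls = SeedControls(
            minimum_potential=config.minimum_potential,
            line_density=config.line_density,
            rng_seed=config.rng_seed + structure.frame_index,
            ep_in_kt_per_e=(ep_grid.unit == "kT/e"),
        )
        lines = compute_field_lines(mesh, ep_grid, controls, config.tracing)

        _stage("write")
        fo = FrameOutputs(
            frame_index=structure.frame_index,
            obj_path=out_dir / "surface.obj",
            channels_path=out_dir / "channels.tsv",
            mlp_dx_path=out_dir / "mlp.dx",
            ep_dx_path=out_dir / "ep.dx",
            lines_path=out_dir / "field_lines.txt",
            schedule_path=out_dir / "particles.txt",
            config_path=out_dir / "config.yaml",
        )
        io_formats.write_obj_with_mlp(mesh, fo.obj_path)
        _write_channels(mesh, fo.channels_path)
        io_formats.write_dx(mlp_grid, fo.mlp_dx_path, comment="surfscape MLP grid")
        io_formats.write_dx(ep_grid, fo.ep_dx_path, comment=f"surfscape EP grid ({ep_grid.unit})")
        io_formats.write_field_lines(lines, fo.lines_path)
        write_schedule(lines, config.animation, config.schedule_frames, fo.schedule_path)
        config.save(fo.config_path)
        return fo
    except SurfscapeError:
        raise
    except Exception as exc:  # annotate unexpected failures with the stage
        raise SurfscapeError(f"frame {structure.frame_index} failed: {exc}") from exc


def _frame_paths(source) -> list[tuple[int, Path, int]]:
    """(frame_index, file, model_in_file) triples for a sequence source."""
    source = Path(source)
    if source.is_dir():
        def natkey(p: Path):
            return [int(t) if t.isdigit() else t
                    for t in re.split(r"(\d+)", p.name)]
        files = sorted(
            [p for p in source.iterdir() if p.suffix.lower() in (".pdb", ".pqr")],
            key=natkey,
        )
        return [(i, p, 0) for i, p in enumerate(files)]
    # multi-model file: probe model count by reading until IndexError
    frames = []
    k = 0
    while True:
        try:
            io_formats.read_structure(source, frame=k)
        except IndexError:
            break
        except SurfscapeError:
            # unreadable model: record it so run_sequence can report failure
            frames.append((k, source, k))
            k += 1
            continue
        frames.append((k, source, k))
        k += 1
    return frames


def run_sequence(
    source,
    config: PipelineConfig,
    out_dir,
    fail_fast: bool = False,
) -> list[FrameOutputs | None]:
    """Process every frame of a multi-model file or a directory of
    numbered structure files; each frame is independent (fresh mesh and
    grids). Writes ``manifest.yaml`` listing per-frame status."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = _frame_paths(source)
    if not entries:
        raise SurfscapeError(f"{source}: no frames found")
    outputs: list[FrameOutputs | None] = []
    manifest = []
    for frame_index, path, model in entries:
        frame_dir = out_dir / f"frame_{frame_index:04d}"
        try:
            structure = io_formats.read_structure(path, frame=model)
            structure.frame_index = frame_index
            fo = run_frame(structure, config, frame_dir)
            outputs.append(fo)
            manifest.append({"frame": frame_index, "status": "ok",
                             "dir": frame_dir.name})
        except Exception as exc:
            if fail_fast:
                raise
            log.error("frame %d failed: %s", frame_index, exc)
            outputs.append(None)
            manifest.append({"frame": frame_index, "status": "failed",
                             "error": str(exc)})
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"source": str(source), "frames": manifest}, fh,
                       sort_keys=False)
    return outputs
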