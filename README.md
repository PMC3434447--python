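# surfscape

Data pipeline for physically informative protein-surface visualization.
Given a protein structure (PDB, or PQR with per-atom partial charges and
radii), surfscape computes the two scalar fields that dominate how a
molecule "feels" to its neighbours — the **molecular lipophilic
potential (MLP)** and the **electrostatic potential (EP)** — on regular
3D grids, maps them onto a molecular surface mesh, converts them into
renderer-agnostic material channels, traces electric field lines from
the most electrically active surface patches, and emits per-frame
particle schedules that animate charge flow along those lines. For a
moving protein (multi-model PDB/PQR), the whole pipeline is re-run per
conformation, because surface topology changes between frames.

The output is plain data (OBJ + .dx grids + text tables), so any
renderer or viewer can consume it; surfscape itself does no rendering.

## The quantities it computes

**MLP** is an atomic fragment sum with an exponential distance kernel:

    MLP(r) = Σᵢ fᵢ · exp(−|r − rᵢ| / 2)

where `fᵢ` is the Broto-scheme lipophilic fragment value of atom *i* at
position `rᵢ`. Positive MLP = hydrophobic, negative = hydrophilic;
surface values of soluble proteins typically fall in [−3, 1]. That
range maps to a gray level in [0, 1] with MLP 0 pinned at 0.5; gray then
drives the material channels (`specular = gray`,
`roughness = noise_amplitude = 1 − gray`): hydrophobic patches render
shiny and smooth, hydrophilic patches dull and rough. Alternative
kernels (`fauchere`, `dubost`, `brasseur`) are selectable.

**EP** comes either from an externally solved Poisson–Boltzmann grid
(OpenDX import — the faithful path) or from the built-in
uniform-dielectric screened-Coulomb (Debye–Hückel) approximation

    φ(r) [kT/e] = Σᵢ qᵢ · exp(−κ|r − rᵢ|) / (4πε₀ε_s |r − rᵢ|)

with defaults 0.150 mol/L NaCl, solvent dielectric 78.54, 298.15 K
(κ ≈ 0.127 Å⁻¹). Field-line seeds are drawn by Monte Carlo on the
surface, weighted by |EP| × area above a minimum-potential threshold;
lines are integrated in both directions along the EP gradient and
oriented positive → negative, stopping at the grid boundary, at a mesh
intersection, or where the field vanishes. Each line then acts as a
particle emitter: with the 25 fps defaults, one particle every 5 frames
(0.2 s) with a 20-frame (0.8 s) lifetime, reaching steady state at
0.6 s.

## Worked example

```bash
surfscape make-fixture dipole --out dipole.pqr
surfscape run dipole.pqr --line-density 4 --rng-seed 2 --out out/
```

writes seven files under `out/`:

```
surface.obj      # watertight surface mesh; MLP in the vt V field
channels.tsv     # per-vertex ep, gray, specular, roughness, noise_amplitude
mlp.dx           # MLP grid (OpenDX)
ep.dx            # EP grid in kT/e (OpenDX)
field_lines.txt  # polylines, positive→negative, with termination codes
particles.txt    # frame, line_id, curve parameter t, age
config.yaml      # resolved configuration (reproduces the run exactly)
```

For the ±1 e dipole fixture the EP grid spans ±21.0 kT/e and the run
traces 23 field lines (density 4 lines per eV/Å²), each terminating by
`mesh_intersection` on the opposite pole or `grid_boundary`:

```python
>>> from surfscape import read_field_lines
>>> lf = read_field_lines("out/field_lines.txt")
>>> len(lf.lines), lf.lines[0].termination.value
(23, 'grid_boundary')
```

Identical inputs and `--rng-seed` give byte-identical outputs. A
multi-model file (or a directory of numbered `.pqr` frames) with
`--sequence` produces one output set per conformation plus a
`manifest.yaml`.

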