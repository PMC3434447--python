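# Methods

## Scope and data flow

surfscape turns a protein conformation into renderer-agnostic
visualization data in five stages: surface meshing → MLP grid → EP grid
→ surface mapping (material channels) → field lines and particle
schedules. Each stage is a pure function of its inputs plus an explicit
RNG seed, so a resolved `config.yaml` reproduces a run bit-identically.
For trajectories every frame is processed independently — conformational
motion changes surface topology (lobes merge and separate), so mesh
geometry is rebuilt per frame rather than deformed.

## Surface model

The molecular surface is a Gaussian-density isosurface. Each atom
contributes `exp(−k·(d/(rᵢ+p))²)` to a density sampled on a cubic
lattice (voxel default 1.0 Å; probe p default 1.4 Å, water). With the
iso level fixed at `exp(−k)`, a lone atom's surface sits at `rᵢ + p`
exactly in the continuum limit; the sharpness `k = 2.3` controls how
aggressively nearby atoms blend. This is not the solvent-excluded
(Connolly) surface, but it shares the properties the pipeline needs:
closed, watertight, smooth, and topology-merging. Marching cubes
(scikit-image) polygonizes the density; trimesh merges duplicate
vertices and fixes winding so face normals point outward; five Taubin
smoothing passes remove lattice staircase artefacts with negligible
shrinkage. Measured on analytic spheres, surface area converges
monotonically as the voxel shrinks and is within ~0.3% of
`4π(r+p)²` at voxel 0.25 Å (about −7% at 1.0 Å, dominated by
discretization). Internal cavity surfaces are kept by default;
`drop_enclosed_components=True` removes closed components whose
vertices lie inside another component (ray-parity containment).
The mean edge length tracks the voxel size within a factor of two,
and triangle-area uniformity is reported as a coefficient of variation
by `mesh_statistics`.

A voxel larger than the smallest atomic radius is rejected as a
resolution error rather than producing a broken isosurface.

## MLP

`MLP(r) = Σᵢ fᵢ·kernel(|r−rᵢ|)` on a lattice covering the structure
plus padding. The default (*testa*) kernel is `exp(−d/2)`: Broto
fragment values with exponential distance decay. The kernel is a
pluggable object; `fauchere` (`exp(−d)`), `dubost` (`100/(1+d)`) and
`brasseur` (`exp(−d/2)`, historically tied to its own fragment set) are
shipped as labelled variants, not validated science. Contributions are
truncated at 12 Å, where the default kernel has fallen below
`e⁻⁶ ≈ 2.5·10⁻³`; the truncation error per atom is bounded by
`f·exp(−cutoff/2)`.

Fragment values are data, not code: a three-column text table
(residue, atom, value) with `*`-rows as element-level fallbacks, so
lookup is total over protein atoms (hydrogens and unusual residues
resolve through the fallback; nucleic-acid and sugar atoms currently
resolve the same way). **The packaged table is synthetic** — typed
per-atom-class stand-ins (aliphatic/aromatic carbons positive, N/O
negative, S mildly positive) chosen to produce the documented [−3, 1]
surface regime on the test fixtures; published Broto/Testa constants
are not redistributed here. Any table with the same layout can be
substituted via `LipophilicLibrary.from_file`. Tests that check grid
numerics use symbolic per-fixture values (±1, ±0.5) and are therefore
independent of the shipped table.

Default grid spacing is 1.0 Å, comparable to the mesh edge length —
finer grids sharpen the surface mapping but cost memory cubically.

## EP

The built-in solver is a **uniform-dielectric screened-Coulomb
(Debye–Hückel) approximation**, *not* a Poisson–Boltzmann solution: it
ignores the low-dielectric protein interior (the solute dielectric,
default 2, is accepted and logged but unused) and linearizes ion
screening. Defaults: 0.150 mol/L 1:1 salt, solvent dielectric 78.54,
298.15 K, giving κ ≈ 0.1273 Å⁻¹. Potentials are in kT/e; the
kT/e ↔ eV conversion (×0.02569 at 298.15 K) is applied only at the
seed-density interface. Grid nodes within 0.1 Å of an atom are clamped
to the value at 0.1 Å to avoid the 1/r singularity. Externally solved
grids imported from OpenDX pass through with units "as-labeled" and are
treated identically downstream; this is the accurate path for real
proteins, and the line-tracing machinery is agnostic to grid
provenance.

## Surface mapping and material channels

Vertex values are trilinear interpolations of the 8 enclosing grid
nodes (scipy `RegularGridInterpolator`); vertices outside the grid are
a loud error naming the vertex — grids are always padded to enclose the
mesh, so silent extrapolation would only hide a bug.

The MLP→gray transfer has knots (−3, 0, 1) → (0, 0.5, 1). The two
published constraints — a linear [−3,1]→[0,1] map and MLP 0 ↦ gray
0.5 — are mutually inconsistent for a single linear map, so the
two-segment piecewise-linear map satisfying both is used; out-of-range
MLP clamps to the endpoints. Contrast/brightness follow the standard
form `clamp((g−0.5)·contrast + 0.5 + brightness)`. Material channels
are deterministic functions of gray: `specular = gray`,
`roughness = noise_amplitude = 1 − gray`. The noise amplitude is
exported as a per-vertex scalar; realizing an actual noise texture is a
renderer concern and out of scope.

## Field lines

Gradient grids use central differences (one-sided at boundaries),
which are exact for affine fields and, at interior nodes, for
quadratics. Seeding works at face granularity (the finest consistent
choice): per-face EP is the mean of its three vertices, weights are
|EP|·area over faces at or above the minimum-potential threshold, and
the seed count is `round(line_density × Σ |EP_eV|·area)` with
round-half-away-from-zero, so the line count is proportional both to
the density control and to the molecule's global surface potential.
Faces are drawn with replacement from a seeded `numpy` Generator;
each seed is a uniform point in its triangle (square-root trick).

Tracing is fixed-step Euler on the normalized gradient, step default
0.5 × the minimum grid spacing; normalization prevents step blow-up
near charges, and an RK2 upgrade would be a drop-in replacement.
Seeds are lifted 0.5 step along the outward face normal so lines do
not immediately re-intersect their source face. Termination follows
three conditions: leaving the grid box (the last in-box point is kept),
segment–triangle intersection with the mesh (the line ends exactly at
the intersection point; vectorized Möller–Trumbore against all faces —
meshes here are small enough that a spatial index would cost more than
it saves), or |∇EP| below the user-settable low-field threshold
(default 10⁻⁴ field-units/Å). The two half-traces are concatenated and
oriented positive → negative (EP at the first point ≥ EP at the last);
when the halves end for different reasons the downstream
(negative-going) half's code is recorded, which is the end a particle
reaches. A `max_points` cap (default 2000) guards against cycling in
degenerate fields and records `low_field`.

Whether seeds belong strictly on the surface or in the volume above it
is a free choice; surface-with-offset is used and documented here.

## Particle schedules

Frames are 0-based with the first emission at frame 0. With defaults
(25 fps, emit every 5 frames, lifetime 20 frames) a particle's curve
parameter is `t = age / lifetime` — constant parametric speed along the
arc-length-normalized curve, since no speed law is otherwise specified.
One particle is emitted per event. Live count per line reaches its
steady maximum `lifetime / period = 4` at frame 15 (= 0.6 s), i.e. the
sixteenth frame counting from one, and is periodic thereafter;
`steady_state_time` finds this by brute-force simulation rather than a
closed form so the rule survives parameter changes. Loop mode (single
conformation) emits for 250 frames, after which the system drains over
one lifetime.

## Fixtures and what tests do (and do not) show

The fixture generator produces point-charge micro-molecules (monopole,
dipole, quadrupole, amphipathic rod, mini helix) with symbolic fragment
values and net charges fixed by construction, plus a closed-form
screened-Coulomb monopole grid evaluated directly from physical
constants as an independent oracle. These exercise every code path at
desk scale (≤ 20 atoms, grids ≤ ~30³, meshes ≤ ~3k faces; the full
suite runs in seconds) and validate numerics: grid sums against naive
loops to 1e−10, trilinear sampling against 8-corner sums to 1e−12,
sphere areas against `4πr²` to 5%, binomial statistics of weighted
seeding at n = 10⁴. They do not validate biochemical realism: real
proteins have thousands of atoms, true fragment constants,
Poisson–Boltzmann electrostatics with a dielectric boundary, and
surface detail the Gaussian model smooths over. Passing tests certify
the machinery, not the biophysics of any particular protein.

## Numerical choices, edge cases

- PQR is whitespace-tokenized (charge-assignment tools widen columns
  past fixed-width PDB); malformed records fail with the line number.
- Plain PDB atoms carry `charge=None`, so the EP stage demands PQR
  explicitly instead of silently computing a zero field.
- OpenDX values are stored z-fastest, three per row, full `%.17g`
  precision, so write∘read is exact; only diagonal-delta regular grids
  are accepted.
- OBJ export writes one `vt 0 <mlp>` per vertex with matched
  vertex/texture indices; an empty mesh or a missing MLP channel is an
  error, never an empty file.
- Degenerate inputs fail loudly: zero-density seeding and all-neutral
  structures return empty results (valid), while out-of-range frames,
  sub-threshold resolution, and missing charges raise typed errors.
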