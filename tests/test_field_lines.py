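"""Gradient grids, weighted seed sampling and line tracing."""

import numpy as np
import pytest

from surfscape import (
    EpParameters,
    FixtureSpec,
    ScalarGrid,
    SeedControls,
    TracingParams,
    TriangleMesh,
    build_surface,
    compute_ep_grid,
    compute_field_lines,
    gradient_grid,
    make_fixture,
    select_seeds,
    trace_line,
)
from surfscape.core import Termination
from surfscape.ep_field import kt_per_e_to_ev
from surfscape.errors import ContractError
from surfscape.surface_mapping import sample_grid_at_points


def _grid_from(f, counts=(7, 7, 7), origin=(0, 0, 0), spacing=(1, 1, 1)):
    origin = np.asarray(origin, float)
    spacing = np.asarray(spacing, float)
    ax = [origin[a] + spacing[a] * np.arange(counts[a]) for a in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    return ScalarGrid(origin=origin, spacing=spacing, values=f(X, Y, Z))


# ---------------------------------------------------------------------------
# gradient
# ---------------------------------------------------------------------------

def test_gradient_of_affine_field_is_exact():
    g = _grid_from(lambda x, y, z: 3 * x)
    grad = gradient_grid(g)
    np.testing.assert_allclose(grad.vectors[..., 0], 3.0, atol=1e-12)
    np.testing.assert_allclose(grad.vectors[..., 1:], 0.0, atol=1e-12)


def test_gradient_of_constant_is_zero():
    g = ScalarGrid(origin=[0, 0, 0], spacing=[1, 1, 1], values=np.full((4, 4, 4), 5.0))
    grad = gradient_grid(g)
    np.testing.assert_array_equal(grad.vectors, 0.0)


def test_central_difference_exact_for_quadratic():
    """d/dx of x^2 by central differences is exactly 2x at interior nodes."""
    g = _grid_from(lambda x, y, z: x**2, spacing=(0.5, 1, 1))
    grad = gradient_grid(g)
    x = g.axis_coordinates(0)
    interior = grad.vectors[1:-1, :, :, 0]
    np.testing.assert_allclose(
        interior, np.broadcast_to(2 * x[1:-1, None, None], interior.shape), atol=1e-12
    )


# ---------------------------------------------------------------------------
# seed selection
# ---------------------------------------------------------------------------

def _two_patch_mesh(ep_hi=3.0, ep_lo=1.0):
    """Two equal-area unit right triangles with face EPs ep_hi and ep_lo."""
    v = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 0, 0], [6, 0, 0], [5, 1, 0]],
        dtype=float,
    )
    t = np.array([[0, 1, 2], [3, 4, 5]])
    mesh = TriangleMesh(vertices=v, triangles=t)
    mesh.set_channel("ep", np.array([ep_hi] * 3 + [ep_lo] * 3))
    return mesh


def test_threshold_excludes_all_subthreshold_faces():
    mesh = _two_patch_mesh()
    controls = SeedControls(minimum_potential=10.0, line_density=5.0, rng_seed=0,
                            ep_in_kt_per_e=False)
    assert select_seeds(mesh, controls) == []


def test_zero_density_gives_zero_seeds():
    mesh = _two_patch_mesh()
    assert select_seeds(mesh, SeedControls(line_density=0.0, rng_seed=0)) == []


def test_weighted_sampling_ratio_three_to_one():
    """With |EP| weights 3:1 on equal areas, 10,000 draws split within
    3 binomial standard deviations of 3:1."""
    mesh = _two_patch_mesh(3.0, 1.0)
    total = 3.0 * 0.5 + 1.0 * 0.5  # sum |EP| x area in "eV"
    density = 10000 / total
    controls = SeedControls(
        line_density=density, rng_seed=42, ep_in_kt_per_e=False
    )
    seeds = select_seeds(mesh, controls)
    assert len(seeds) == 10000
    n_hi = sum(1 for s in seeds if s.face_id == 0)
    p = 0.75
    sigma = np.sqrt(10000 * p * (1 - p))
    assert abs(n_hi - 10000 * p) < 3 * sigma


def test_seed_count_linear_in_density_and_in_ev_units():
    mesh = _two_patch_mesh(3.0, 1.0)
    total_ev = float(kt_per_e_to_ev(2.0))  # weights interpreted in kT/e
    seeds = select_seeds(mesh, SeedControls(line_density=100.0, rng_seed=0))
    assert len(seeds) == round(100.0 * total_ev)
    twice = select_seeds(mesh, SeedControls(line_density=200.0, rng_seed=0))
    assert abs(len(twice) - 2 * len(seeds)) <= 1


def test_seeds_deterministic_and_inside_faces():
    mesh = _two_patch_mesh()
    c = SeedControls(line_density=50.0, rng_seed=7, ep_in_kt_per_e=False)
    a = select_seeds(mesh, c)
    b = select_seeds(mesh, c)
    assert len(a) == len(b) > 0
    for sa, sb in zip(a, b):
        np.testing.assert_array_equal(sa.position, sb.position)
        assert sa.position[2] == 0.0  # in the triangle plane


def test_negative_density_rejected():
    with pytest.raises(ContractError):
        SeedControls(line_density=-1.0)
    with pytest.raises(ContractError):
        SeedControls(minimum_potential=-0.5)


# ---------------------------------------------------------------------------
# tracing
# ---------------------------------------------------------------------------

def test_uniform_field_trace_is_straight_to_boundary():
    g = _grid_from(lambda x, y, z: 1.0 * x, counts=(9, 9, 9))
    grad = gradient_grid(g)
    line = trace_line(np.array([4.0, 4.0, 4.0]), grad, g, step=0.5)
    assert line.termination is Termination.GRID_BOUNDARY
    np.testing.assert_array_equal(line.points[:, 1], 4.0)
    np.testing.assert_array_equal(line.points[:, 2], 4.0)
    x = line.points[:, 0]
    assert np.all(np.diff(x) < 0)  # oriented positive -> negative
    assert x.max() == pytest.approx(8.0) and x.min() == pytest.approx(0.0)


def test_monopole_trace_is_radial_within_2_degrees():
    structure, _ = make_fixture(FixtureSpec(kind="monopole"))
    ep = compute_ep_grid(structure, EpParameters(spacing=1.0, padding=12.0))
    grad = gradient_grid(ep)
    line = trace_line(np.array([5.0, 0.0, 0.0]), grad, ep, step=0.25)
    pts = line.points[np.linalg.norm(line.points, axis=1) > 0.5]
    cos = np.abs(pts[:, 0]) / np.linalg.norm(pts, axis=1)
    angles = np.degrees(np.arccos(np.clip(cos, -1, 1)))
    assert angles.max() < 2.0


def test_zero_field_yields_single_point_low_field_line():
    g = ScalarGrid(origin=[0, 0, 0], spacing=[1, 1, 1], values=np.zeros((5, 5, 5)))
    line = trace_line(np.array([2.0, 2.0, 2.0]), gradient_grid(g), g, step=0.5)
    assert len(line.points) == 1
    assert line.termination is Termination.LOW_FIELD


def test_step_halving_first_order_consistency():
    """Halving the step moves the monopole trace endpoint by less than
    one step length (first-order integrator consistency)."""
    structure, _ = make_fixture(FixtureSpec(kind="monopole"))
    ep = compute_ep_grid(structure, EpParameters(spacing=1.0, padding=10.0))
    grad = gradient_grid(ep)
    seed = np.array([4.0, 0.0, 0.0])
    coarse = trace_line(seed, grad, ep, step=0.5)
    fine = trace_line(seed, grad, ep, step=0.25)
    # compare the outward (downstream) endpoints
    d = np.linalg.norm(coarse.points[-1] - fine.points[-1])
    assert d < 0.5


def test_seed_outside_grid_rejected():
    g = ScalarGrid(origin=[0, 0, 0], spacing=[1, 1, 1], values=np.zeros((3, 3, 3)))
    with pytest.raises(ContractError):
        trace_line(np.array([10.0, 0.0, 0.0]), gradient_grid(g), g)


# ---------------------------------------------------------------------------
# composed pipeline
# ---------------------------------------------------------------------------

def test_neutral_structure_yields_no_lines():
    structure, _ = make_fixture(FixtureSpec(kind="dipole"))
    for a in structure.atoms:
        a.charge = 0.0
    mesh = build_surface(structure)
    ep = compute_ep_grid(structure, EpParameters(spacing=1.0, padding=8.0))
    out = compute_field_lines(mesh, ep, SeedControls(line_density=5.0, rng_seed=0))
    assert out.lines == []


def test_dipole_lines_oriented_and_terminated(dipole):
    """Every line runs from higher to lower EP; >90% stop at the mesh or
    the grid boundary."""
    mesh = build_surface(dipole)
    ep = compute_ep_grid(dipole, EpParameters(spacing=1.0, padding=8.0))
    out = compute_field_lines(
        mesh, ep, SeedControls(line_density=5.0, rng_seed=11)
    )
    assert len(out.lines) > 5
    for line in out.lines:
        e0 = sample_grid_at_points(ep, line.points[:1])[0]
        e1 = sample_grid_at_points(ep, line.points[-1:])[0]
        assert e0 >= e1 - 1e-9
        assert np.all(ep.contains(line.points))
    hard_stop = sum(
        line.termination in (Termination.MESH_INTERSECTION, Termination.GRID_BOUNDARY)
        for line in out.lines
    )
    assert hard_stop / len(out.lines) > 0.9


def test_line_count_scales_linearly_with_density(dipole):
    mesh = build_surface(dipole)
    ep = compute_ep_grid(dipole, EpParameters(spacing=1.0, padding=8.0))
    n1 = len(compute_field_lines(mesh, ep, SeedControls(line_density=4.0, rng_seed=5)).lines)
    n2 = len(compute_field_lines(mesh, ep, SeedControls(line_density=8.0, rng_seed=5)).lines)
    assert abs(n2 - 2 * n1) <= 2  # rounding plus skipped out-of-grid seeds


def test_field_line_file_deterministic(dipole, tmp_path):
    from surfscape import write_field_lines

    mesh = build_surface(dipole)
    ep = compute_ep_grid(dipole, EpParameters(spacing=1.0, padding=8.0))
    controls = SeedControls(line_density=5.0, rng_seed=9)
    p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
    write_field_lines(compute_field_lines(mesh, ep, controls), p1)
    write_field_lines(compute_field_lines(mesh, ep, controls), p2)
    assert p1.read_bytes() == p2.read_bytes()
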