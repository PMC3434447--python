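"""MLP grid: kernel oracles, brute-force comparison, equivariance."""

import numpy as np
import pytest

from surfscape import (
    FORMULAS,
    FixtureSpec,
    LipophilicLibrary,
    compute_mlp_grid,
    default_spacing,
    load_default_library,
    make_fixture,
)
from surfscape.core import Atom, Structure
from surfscape.errors import ContractError, FragmentLookupError


def _structure_from_points(points, names=None):
    atoms = []
    for i, p in enumerate(points):
        atoms.append(
            Atom(
                serial=i + 1,
                name=(names[i] if names else "C"),
                element=(names[i][0] if names else "C"),
                residue_name="FIX",
                residue_id=i + 1,
                chain="A",
                position=np.asarray(p, dtype=float),
                charge=0.0,
                radius=1.5,
            )
        )
    return Structure(atoms=atoms)


def _unit_library(value=1.0):
    return LipophilicLibrary(by_element={"C": value, "X": value})


def test_kernel_identity_at_zero_distance():
    """MLP at the atom position equals f (kernel(0) = 1 for testa)."""
    s = _structure_from_points([[0.0, 0.0, 0.0]])
    grid = compute_mlp_grid(s, library=_unit_library(), spacing=1.0, padding=4.0)
    ix = np.argmin(np.abs(grid.axis_coordinates(0)))
    iy = np.argmin(np.abs(grid.axis_coordinates(1)))
    iz = np.argmin(np.abs(grid.axis_coordinates(2)))
    assert grid.values[ix, iy, iz] == pytest.approx(1.0, abs=1e-12)


def test_testa_kernel_value_at_2A():
    """exp(-d/2) at d = 2 Å is e^-1, evaluated independently of the grid."""
    s = _structure_from_points([[0.0, 0.0, 0.0]])
    grid = compute_mlp_grid(s, library=_unit_library(), spacing=1.0, padding=4.0)
    ix = np.argmin(np.abs(grid.axis_coordinates(0) - 2.0))
    iy = np.argmin(np.abs(grid.axis_coordinates(1)))
    iz = np.argmin(np.abs(grid.axis_coordinates(2)))
    assert grid.axis_coordinates(0)[ix] == pytest.approx(2.0)
    assert grid.values[ix, iy, iz] == pytest.approx(np.exp(-1.0), abs=1e-12)


@pytest.mark.parametrize("formula", sorted(FORMULAS))
def test_two_atom_grid_is_sum_of_single_atom_grids(formula):
    lib = _unit_library()
    pts = [[0.0, 0, 0], [2.5, 1.0, -0.5]]
    both = compute_mlp_grid(
        _structure_from_points(pts), library=lib, formula=formula,
        spacing=1.0, padding=3.0,
    )
    # evaluate each single-atom field on the same lattice by brute force
    kernel = FORMULAS[formula]
    axes = [both.axis_coordinates(a) for a in range(3)]
    expect = np.zeros(both.counts)
    for p in pts:
        d = np.sqrt(
            (axes[0][:, None, None] - p[0]) ** 2
            + (axes[1][None, :, None] - p[1]) ** 2
            + (axes[2][None, None, :] - p[2]) ** 2
        )
        expect += np.where(d <= 12.0, kernel(d), 0.0)
    np.testing.assert_allclose(both.values, expect, atol=1e-10)


def test_matches_naive_triple_loop_oracle(rng):
    """Grid evaluation equals an explicit python triple loop on a random
    <=10-atom structure (pre-cutoff geometry)."""
    n = 7
    pts = rng.uniform(-3, 3, (n, 3))
    f = rng.choice([-1.0, -0.5, 0.5, 1.0], n)
    # per-atom values via a custom library keyed by unique atom names
    names = [f"C{i}" for i in range(n)]
    s = _structure_from_points(pts, names=names)
    lib = LipophilicLibrary(
        by_residue_atom={("FIX", f"C{i}".upper()): float(f[i]) for i in range(n)},
    )
    grid = compute_mlp_grid(s, library=lib, spacing=1.5, padding=2.0)
    axes = [grid.axis_coordinates(a) for a in range(3)]
    expect = np.zeros(grid.counts)
    for ix, x in enumerate(axes[0]):
        for iy, y in enumerate(axes[1]):
            for iz, z in enumerate(axes[2]):
                total = 0.0
                for k in range(n):
                    d = np.sqrt(
                        (x - pts[k][0]) ** 2 + (y - pts[k][1]) ** 2 + (z - pts[k][2]) ** 2
                    )
                    if d <= 12.0:
                        total += f[k] * np.exp(-d / 2.0)
                expect[ix, iy, iz] = total
    np.testing.assert_allclose(grid.values, expect, atol=1e-10)


def test_translation_equivariance(rng):
    pts = rng.uniform(-2, 2, (4, 3))
    shift = np.array([5.0, -3.0, 2.0])
    lib = _unit_library()
    g0 = compute_mlp_grid(_structure_from_points(pts), library=lib, spacing=1.0, padding=3.0)
    g1 = compute_mlp_grid(
        _structure_from_points(pts + shift), library=lib, spacing=1.0, padding=3.0
    )
    np.testing.assert_allclose(g0.values, g1.values, atol=1e-10)
    np.testing.assert_allclose(g1.origin - g0.origin, shift, atol=1e-12)


def test_default_spacing_is_1A_and_override_honored():
    assert default_spacing() == 1.0
    s = _structure_from_points([[0.0, 0, 0]])
    g = compute_mlp_grid(s, library=_unit_library(), spacing=0.5, padding=2.0)
    np.testing.assert_allclose(g.spacing, [0.5, 0.5, 0.5])
    with pytest.raises(ContractError):
        compute_mlp_grid(s, library=_unit_library(), spacing=0.0)
    with pytest.raises(ContractError):
        compute_mlp_grid(s, library=_unit_library(), spacing=-1.0)


def test_unresolvable_atom_raises_named_lookup_error():
    s = _structure_from_points([[0.0, 0, 0]], names=["QQ"])
    s.atoms[0].element = "Q"
    lib = LipophilicLibrary(by_element={"C": 1.0})  # no X fallback
    with pytest.raises(FragmentLookupError, match="QQ"):
        compute_mlp_grid(s, library=lib)


def test_packaged_library_covers_standard_residues():
    lib = load_default_library()
    for res, atom in [("ALA", "CB"), ("TRP", "CH2"), ("GLY", "CA"), ("ARG", "NH1")]:
        assert isinstance(lib.lookup(res, atom, atom[0]), float)
    # hydrogens and unknown heavy atoms resolve through element fallback
    assert lib.lookup("ALA", "HB1", "H") == pytest.approx(0.1)


def test_fixture_surface_mlp_in_working_range():
    """Sanity: surface-level MLP magnitudes of the helix fixture stay
    predominantly inside the typical working range [-3, 1]."""
    structure, _ = make_fixture(FixtureSpec(kind="mini_helix", n_atoms=8))
    grid = compute_mlp_grid(structure, spacing=1.0, padding=4.0)
    frac = np.mean((grid.values >= -3.0) & (grid.values <= 1.0))
    assert frac > 0.9
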