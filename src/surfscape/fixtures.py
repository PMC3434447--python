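"""Synthetic micro-molecules and analytic reference fields.

Every pipeline stage is testable without downloading structures: these
generators build point-charge fixtures (monopole, dipole, quadrupole, an
amphipathic rod, a miniature helix) with symbolic lipophilic fragment
values (±1, ±0.5) so MLP tests do not depend on the shipped fragment
table, plus a closed-form screened-Coulomb grid used as the independent
oracle for the electrostatics solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from scipy import constants

from .core import Atom, ScalarGrid, Structure
from .ep_field import EpParameters
from .errors import ContractError

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "write_pqr",
    "analytic_monopole_grid",
    "FIXTURE_KINDS",
]

FIXTURE_KINDS = ("monopole", "dipole", "quadrupole", "amphipathic_rod", "mini_helix")

#: symbolic fragment values attached to fixture atoms (hydrophobic face
#: +1/+0.5, hydrophilic face -1/-0.5); tests read them from this map
FIXTURE_F_POSITIVE = 1.0
FIXTURE_F_NEGATIVE = -1.0


@dataclass
class FixtureSpec:
    """Recipe for a synthetic molecule."""

    kind: str = "dipole"
    n_atoms: int = 2
    separation: float = 6.0  # Å between charge centers
    radius: float = 1.5  # Å per atom
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ContractError(
                f"unknown fixture kind {self.kind!r}; choose from {FIXTURE_KINDS}"
            )


def _atom(serial, pos, charge, radius, name="C", resname="FIX", resid=1):
    return Atom(
        serial=serial,
        name=name,
        element=name[0],
        residue_name=resname,
        residue_id=resid,
        chain="A",
        position=np.asarray(pos, dtype=float),
        charge=charge,
        radius=radius,
    )


def make_fixture(spec: FixtureSpec) -> tuple[Structure, np.ndarray]:
    """Build a fixture Structure and its per-atom fragment values.

    Deterministic for a fixed ``rng_seed``. The dipole has net charge 0;
    the amphipathic rod has one face of positive-f atoms and one of
    negative-f atoms.
    """
    rng = np.random.default_rng(spec.rng_seed)
    s, r = spec.separation, spec.radius
    if spec.kind == "monopole":
        atoms = [_atom(1, (0, 0, 0), +1.0, r)]
        f = np.array([FIXTURE_F_POSITIVE])
    elif spec.kind == "dipole":
        atoms = [
            _atom(1, (-s / 2, 0, 0), +1.0, r, name="N"),
            _atom(2, (+s / 2, 0, 0), -1.0, r, name="O"),
        ]
        f = np.array([FIXTURE_F_POSITIVE, FIXTURE_F_NEGATIVE])
    elif spec.kind == "quadrupole":
        atoms = [
            _atom(1, (-s / 2, -s / 2, 0), +1.0, r, name="N"),
            _atom(2, (+s / 2, -s / 2, 0), -1.0, r, name="O"),
            _atom(3, (-s / 2, +s / 2, 0), -1.0, r, name="O"),
            _atom(4, (+s / 2, +s / 2, 0), +1.0, r, name="N"),
        ]
        f = np.array([1.0, -1.0, -1.0, 1.0])
    elif spec.kind == "amphipathic_rod":
        n = max(spec.n_atoms, 2)
        half = n // 2
        atoms = []
        fvals = []
        for i in range(n):
            along = (i % half) * 1.8
            face = +1 if i < half else -1
            pos = (along, face * 1.2, 0.2 * rng.standard_normal())
            q = 0.1 * face
            atoms.append(
                _atom(i + 1, pos, q, r, name="C" if face > 0 else "O")
            )
            fvals.append(FIXTURE_F_POSITIVE if face > 0 else FIXTURE_F_NEGATIVE)
        f = np.asarray(fvals)
    elif spec.kind == "mini_helix":
        n = max(spec.n_atoms, 4)
        atoms = []
        fvals = []
        for i in range(n):
            theta = i * 100.0 * np.pi / 180.0  # ~alpha-helical twist
            pos = (2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i)
            q = [0.25, -0.25, 0.0, 0.0][i % 4]
            fvals.append([0.5, -0.5, 1.0, -1.0][i % 4])
            atoms.append(
                _atom(i + 1, pos, q, r, name=["N", "O", "C", "C"][i % 4])
            )
        f = np.asarray(fvals)
    else:  # pragma: no cover - guarded by FixtureSpec
        raise ContractError(spec.kind)
    return Structure(atoms=atoms, source_path=f"fixture:{spec.kind}"), f


def write_pqr(structure: Structure, path) -> None:
    """Write a whitespace-separated PQR file (charge + radius columns)."""
    with open(path, "w") as fh:
        for a in structure.atoms:
            chain = a.chain or "A"
            fh.write(
                f"ATOM {a.serial} {a.name} {a.residue_name} {chain} "
                f"{a.residue_id} {a.position[0]:.3f} {a.position[1]:.3f} "
                f"{a.position[2]:.3f} {a.charge:.4f} {a.radius:.4f}\n"
            )
        fh.write("END\n")


def analytic_monopole_grid(
    q: float,
    params: EpParameters,
    origin: np.ndarray,
    spacing: np.ndarray,
    counts: tuple[int, int, int],
    center: np.ndarray = (0.0, 0.0, 0.0),
    clamp: float = 0.1,
) -> ScalarGrid:
    """Closed-form screened-Coulomb grid of a single point charge (kT/e).

    Independent oracle for the grid solver: evaluates
    ``pref * q * exp(-kappa d) / d`` directly at every node, deriving
    kappa and the Coulomb prefactor from physical constants here rather
    than reusing the solver's helpers.
    """
    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    center = np.asarray(center, dtype=float)
    kT = constants.k * params.temperature
    kappa_m = np.sqrt(
        2.0 * constants.N_A * constants.e**2 * (params.ionic_strength * 1e3)
        / (constants.epsilon_0 * params.solvent_dielectric * kT)
    )
    kappa = kappa_m * 1e-10
    pref = (
        constants.e**2
        / (4 * np.pi * constants.epsilon_0 * params.solvent_dielectric * kT)
    ) * 1e10
    axes = [origin[a] + spacing[a] * np.arange(counts[a]) for a in range(3)]
    d = np.sqrt(
        (axes[0][:, None, None] - center[0]) ** 2
        + (axes[1][None, :, None] - center[1]) ** 2
        + (axes[2][None, None, :] - center[2]) ** 2
    )
    d = np.maximum(d, clamp)
    values = pref * q * np.exp(-kappa * d) / d
    return ScalarGrid(origin=origin, spacing=spacing, values=values, unit="kT/e")
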