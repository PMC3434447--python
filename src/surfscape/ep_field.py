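"""Electrostatic potential (EP) grids.

Two routes produce an EP ScalarGrid:

* :func:`load_ep_grid` imports a grid solved externally by a
  Poisson–Boltzmann solver (OpenDX ``.dx``) — the faithful path; units
  pass through "as-labeled".
* :func:`compute_ep_grid` is a built-in **uniform-dielectric
  screened-Coulomb (Debye–Hückel) approximation**:

      phi(r) [kT/e] = sum_i q_i * exp(-kappa*|r - r_i|) / (4*pi*eps0*eps_s*|r - r_i|)

  with the inverse Debye length ``kappa`` computed from the ionic
  strength and temperature. It ignores the dielectric boundary (the
  solute dielectric is recorded but unused), so it is an approximation
  of the Poisson–Boltzmann potential suitable for development, testing
  and small fixtures; import a solved grid when accuracy matters.

Defaults follow common practice for protein electrostatics: 0.150 mol/L
NaCl, solute dielectric 2, solvent dielectric 78.54, 298.15 K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import constants

from .core import ScalarGrid, Structure
from .errors import ContractError
from .io_formats import read_dx

__all__ = [
    "EpParameters",
    "compute_ep_grid",
    "load_ep_grid",
    "net_charge",
    "inverse_debye_length",
    "kt_per_e_to_ev",
    "SINGULARITY_CLAMP",
]

log = logging.getLogger(__name__)

#: grid nodes closer than this (Å) to an atom are clamped to the value here
SINGULARITY_CLAMP = 0.1


@dataclass
class EpParameters:
    """Physical parameters of the electrostatics calculation."""

    ionic_strength: float = 0.150  # mol/L (1:1 salt)
    solute_dielectric: float = 2.0  # recorded, unused by the built-in solver
    solvent_dielectric: float = 78.54
    temperature: float = 298.15  # K
    spacing: float = 1.0  # Å
    padding: float = 6.0  # Å

    def __post_init__(self) -> None:
        for name in (
            "solute_dielectric",
            "solvent_dielectric",
            "temperature",
            "spacing",
            "padding",
        ):
            if not getattr(self, name) > 0:
                raise ContractError(f"{name} must be positive")
        if self.ionic_strength < 0:
            raise ContractError("ionic_strength must be >= 0")


def inverse_debye_length(params: EpParameters) -> float:
    """Inverse Debye screening length kappa in 1/Å.

    kappa^2 = 2 * N_A * e^2 * I / (eps0 * eps_s * kB * T), I in mol/m^3.
    About 0.127 1/Å for 0.150 mol/L at 298.15 K in water.
    """
    I_si = params.ionic_strength * 1000.0  # mol/m^3
    kappa_sq = (
        2.0
        * constants.N_A
        * constants.e**2
        * I_si
        / (
            constants.epsilon_0
            * params.solvent_dielectric
            * constants.k
            * params.temperature
        )
    )
    return float(np.sqrt(kappa_sq) * 1e-10)  # 1/m -> 1/Å


def _coulomb_prefactor(params: EpParameters) -> float:
    """e^2/(4*pi*eps0*eps_s*kB*T) in Å: phi[kT/e] = prefactor * q/d[Å]."""
    pref_m = constants.e**2 / (
        4.0
        * np.pi
        * constants.epsilon_0
        * params.solvent_dielectric
        * constants.k
        * params.temperature
    )
    return float(pref_m * 1e10)


def kt_per_e_to_ev(value_kt_e: float | np.ndarray, temperature: float = 298.15):
    """Convert a potential from kT/e to eV (multiply by kT in eV)."""
    return value_kt_e * (constants.k * temperature / constants.e)


def compute_ep_grid(
    structure: Structure,
    params: EpParameters | None = None,
) -> ScalarGrid:
    """Screened-Coulomb EP in kT/e on a lattice covering the structure.

    Every atom must carry a partial charge (PQR input). Nodes closer than
    ``SINGULARITY_CLAMP`` Å to an atom take the value at that distance.
    """
    if params is None:
        params = EpParameters()
    charges = structure.charges  # raises ContractError if any are missing
    if params.solute_dielectric != 1.0:
        log.info(
            "built-in EP solver is a uniform-dielectric approximation; "
            "solute_dielectric=%.3g is recorded but not used",
            params.solute_dielectric,
        )
    kappa = inverse_debye_length(params)
    pref = _coulomb_prefactor(params)
    lo, hi = structure.bounding_box()
    origin = lo - params.padding
    counts = np.maximum(
        np.ceil((hi + params.padding - origin) / params.spacing).astype(int) + 1, 2
    )
    axes = [
        origin[a] + params.spacing * np.arange(counts[a]) for a in range(3)
    ]
    values = np.zeros(tuple(counts))
    for pos, q in zip(structure.positions, charges):
        if q == 0.0:
            continue
        dx = axes[0] - pos[0]
        dy = axes[1] - pos[1]
        dz = axes[2] - pos[2]
        d = np.sqrt(
            dx[:, None, None] ** 2
            + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2
        )
        d = np.maximum(d, SINGULARITY_CLAMP)
        values += pref * q * np.exp(-kappa * d) / d
    return ScalarGrid(
        origin=origin,
        spacing=np.full(3, float(params.spacing)),
        values=values,
        unit="kT/e",
    )


def load_ep_grid(path) -> ScalarGrid:
    """Load an externally solved EP grid (.dx); units pass through."""
    grid = read_dx(path)
    grid.unit = "as-labeled"
    return grid


def net_charge(structure: Structure) -> float:
    """Total charge in e; diagnostic for the expected field-line count."""
    return float(structure.charges.sum())
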