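"""Molecular lipophilic potential (MLP) on a regular grid.

The MLP at a point ``r`` is the fragment sum

    MLP(r) = sum_i  f_i * kernel(|r - r_i|)

where ``f_i`` is the atomic lipophilic fragment value of atom *i* (the
Broto fragment scheme: each atom type carries an additive contribution to
the octanol/water partition behaviour) and ``kernel`` is a distance decay.
The default *testa* kernel is ``exp(-d/2)`` — Broto fragments with
exponential distance attenuation. Alternatives are provided as labelled
variants:

========  ==================  ==========================================
name      kernel(d)           note
========  ==================  ==========================================
testa     exp(-d/2)           default; exponential decay, e-fold 2 Å
fauchere  exp(-d)             steeper exponential
dubost    100 / (1 + d)       hyperbolic
brasseur  exp(-d/2)           historically tied to its own fragment set;
                              unified here onto one library
========  ==================  ==========================================

Positive MLP = hydrophobic environment, negative = hydrophilic; surface
values of soluble proteins typically fall in [-3, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable

import numpy as np

from .core import ScalarGrid, Structure
from .errors import ContractError, FragmentLookupError

__all__ = [
    "MlpFormula",
    "FORMULAS",
    "get_formula",
    "LipophilicLibrary",
    "load_default_library",
    "compute_mlp_grid",
    "default_spacing",
    "DEFAULT_CUTOFF",
]

#: beyond this distance (Å) kernel contributions are dropped; for the
#: default kernel exp(-d/2) the truncated tail is < e^-6 ≈ 2.5e-3 per atom
DEFAULT_CUTOFF = 12.0


@dataclass(frozen=True)
class MlpFormula:
    """A named MLP distance kernel; kernel(0) is finite, kernel(inf) -> 0."""

    name: str
    kernel: Callable[[np.ndarray], np.ndarray]

    def __call__(self, d: np.ndarray) -> np.ndarray:
        return self.kernel(np.asarray(d, dtype=float))


FORMULAS: dict[str, MlpFormula] = {
    "testa": MlpFormula("testa", lambda d: np.exp(-d / 2.0)),
    "fauchere": MlpFormula("fauchere", lambda d: np.exp(-d)),
    "dubost": MlpFormula("dubost", lambda d: 100.0 / (1.0 + d)),
    "brasseur": MlpFormula("brasseur", lambda d: np.exp(-d / 2.0)),
}


def get_formula(name: str) -> MlpFormula:
    try:
        return FORMULAS[name.lower()]
    except KeyError:
        raise ContractError(
            f"unknown MLP formula {name!r}; choose from {sorted(FORMULAS)}"
        ) from None


@dataclass
class LipophilicLibrary:
    """Atomic fragment values keyed by (residue, atom name), with an
    element-level fallback so lookup is total over protein atoms.

    The packaged default table is synthetic (see its header); pass any
    three-column text file (residue, atom, value; '*' residue = element
    fallback) to :meth:`from_file` to substitute real published values.
    """

    by_residue_atom: dict[tuple[str, str], float] = field(default_factory=dict)
    by_element: dict[str, float] = field(default_factory=dict)
    source: str = ""

    @classmethod
    def from_file(cls, path: str | Path) -> "LipophilicLibrary":
        by_ra: dict[tuple[str, str], float] = {}
        by_el: dict[str, float] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                tokens = line.split()
                if len(tokens) != 3:
                    raise ContractError(
                        f"{path}:{lineno}: expected 'residue atom value'"
                    )
                res, atom, val = tokens[0].upper(), tokens[1].upper(), float(tokens[2])
                if res == "*":
                    by_el[atom] = val
                else:
                    by_ra[(res, atom)] = val
        return cls(by_residue_atom=by_ra, by_element=by_el, source=str(path))

    def lookup(self, residue_name: str, atom_name: str, element: str) -> float:
        key = (residue_name.upper(), atom_name.upper())
        if key in self.by_residue_atom:
            return self.by_residue_atom[key]
        el = element.upper() if len(element) == 1 else element.capitalize()
        if el.upper() in self.by_element:
            return self.by_element[el.upper()]
        if "X" in self.by_element:
            return self.by_element["X"]
        raise FragmentLookupError(
            f"no fragment value for atom {atom_name!r} in residue "
            f"{residue_name!r} (element {element!r})"
        )

    def fragment_values(self, structure: Structure) -> np.ndarray:
        return np.array(
            [
                self.lookup(a.residue_name, a.name, a.element)
                for a in structure.atoms
            ],
            dtype=float,
        )


def load_default_library() -> LipophilicLibrary:
    """Load the packaged (synthetic, swappable) fragment table."""
    ref = resources.files("surfscape.data").joinpath(
        "lipophilicity_fragments_synthetic.txt"
    )
    with resources.as_file(ref) as path:
        return LipophilicLibrary.from_file(path)


def default_spacing() -> float:
    """Default MLP grid spacing in Å (comparable to the mesh edge size)."""
    return 1.0


def _grid_geometry(
    structure: Structure, spacing: float, padding: float
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = structure.bounding_box()
    origin = lo - padding
    counts = np.maximum(
        np.ceil((hi + padding - origin) / spacing).astype(int) + 1, 2
    )
    return origin, counts


def compute_mlp_grid(
    structure: Structure,
    library: LipophilicLibrary | None = None,
    formula: MlpFormula | str = "testa",
    spacing: float | None = None,
    padding: float = 6.0,
    cutoff: float = DEFAULT_CUTOFF,
) -> ScalarGrid:
    """Evaluate the fragment-sum MLP on a lattice covering the structure.

    Contributions beyond ``cutoff`` Å are dropped; with the default
    kernel the per-atom truncation error is below exp(-cutoff/2).
    """
    if spacing is None:
        spacing = default_spacing()
    if spacing <= 0:
        raise ContractError("grid spacing must be positive")
    if padding < 0:
        raise ContractError("padding must be non-negative")
    if isinstance(formula, str):
        formula = get_formula(formula)
    if library is None:
        library = load_default_library()
    f_values = library.fragment_values(structure)
    origin, counts = _grid_geometry(structure, spacing, padding)
    values = np.zeros(tuple(counts))
    axes = [origin[a] + spacing * np.arange(counts[a]) for a in range(3)]
    for pos, f in zip(structure.positions, f_values):
        i0 = np.maximum(np.floor((pos - cutoff - origin) / spacing).astype(int), 0)
        i1 = np.minimum(np.ceil((pos + cutoff - origin) / spacing).astype(int) + 1, counts)
        if np.any(i0 >= i1):
            continue
        dx = axes[0][i0[0]:i1[0]] - pos[0]
        dy = axes[1][i0[1]:i1[1]] - pos[1]
        dz = axes[2][i0[2]:i1[2]] - pos[2]
        d = np.sqrt(
            dx[:, None, None] ** 2
            + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2
        )
        contrib = f * formula(d)
        contrib[d > cutoff] = 0.0
        values[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] += contrib
    return ScalarGrid(
        origin=origin, spacing=np.full(3, float(spacing)), values=values,
        unit="dimensionless",
    )
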