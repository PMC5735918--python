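"""Core molecular data types, element data, physical constants, and XYZ I/O.

Internal unit conventions, used everywhere in the package:

* coordinates are Cartesian, in Angstrom;
* energies are in Hartree;
* conversions to kcal/mol (or anything else) happen only at I/O and
  reporting boundaries.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import MoleculeError

__all__ = [
    "ElementTable",
    "PhysicalConstants",
    "Molecule",
    "DEFAULT_ELEMENTS",
    "CONSTANTS",
    "vibrational_dof",
    "detect_linearity",
    "electron_count",
    "heavy_atom_count",
    "read_xyz",
    "write_xyz",
]


@dataclass(frozen=True)
class ElementTable:
    """Atomic numbers and standard atomic masses, keyed by element symbol.

    The shipped table (version 1) uses IUPAC standard atomic weights; this
    differs in the third decimal from the isotope masses some quantum
    chemistry codes default to, which matters only for frequencies, never
    for the sampling displacement law.
    """

    atomic_numbers: dict[str, int]
    masses: dict[str, float]
    version: str = "1"

    def __post_init__(self) -> None:
        if set(self.atomic_numbers) != set(self.masses):
            raise MoleculeError("atomic_numbers and masses must cover the same symbols")
        numbers = list(self.atomic_numbers.values())
        if len(set(numbers)) != len(numbers) or any(z <= 0 for z in numbers):
            raise MoleculeError("atomic numbers must be positive and unique per symbol")

    def atomic_number(self, symbol: str) -> int:
        try:
            return self.atomic_numbers[symbol]
        except KeyError:
            raise MoleculeError(f"unknown element symbol {symbol!r}") from None

    def mass(self, symbol: str) -> float:
        try:
            return self.masses[symbol]
        except KeyError:
            raise MoleculeError(f"unknown element symbol {symbol!r}") from None


DEFAULT_ELEMENTS = ElementTable(
    atomic_numbers={"H": 1, "C": 6, "N": 7, "O": 8, "F": 9},
    masses={"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998},
)


@dataclass(frozen=True)
class PhysicalConstants:
    """Boltzmann constant and Hartree/kcal conversion used by the sampler.

    k_b is in Hartree per Kelvin.
    """

    k_b: float = 3.166811563e-6
    hartree_to_kcalmol: float = 627.5094741

    def __post_init__(self) -> None:
        if self.k_b <= 0 or self.hartree_to_kcalmol <= 0:
            raise MoleculeError("physical constants must be strictly positive")


CONSTANTS = PhysicalConstants()


@dataclass
class Molecule:
    """A molecular composition plus one Cartesian geometry.

    species  -- ordered element symbols, one per atom
    coordinates -- (n_atoms, 3) array, Angstrom
    charge / multiplicity -- default neutral singlet, matching the systems
        the sampling pipeline targets
    """

    species: tuple[str, ...]
    coordinates: np.ndarray
    charge: int = 0
    multiplicity: int = 1
    name: str = ""
    elements: ElementTable = field(default=DEFAULT_ELEMENTS, repr=False)

    def __post_init__(self) -> None:
        self.species = tuple(str(s) for s in self.species)
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise MoleculeError(f"coordinates must be (n_atoms, 3); got {coords.shape}")
        if len(self.species) != coords.shape[0] or len(self.species) < 1:
            raise MoleculeError(
                f"species length {len(self.species)} does not match "
                f"{coords.shape[0]} coordinate rows (need >= 1 atom)"
            )
        for s in self.species:
            self.elements.atomic_number(s)  # raises on unknown symbol
        self.coordinates = coords

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    def masses(self) -> np.ndarray:
        return np.array([self.elements.mass(s) for s in self.species])

    def with_coordinates(self, coordinates: np.ndarray) -> "Molecule":
        return Molecule(
            species=self.species,
            coordinates=coordinates,
            charge=self.charge,
            multiplicity=self.multiplicity,
            name=self.name,
            elements=self.elements,
        )


def heavy_atom_count(molecule: Molecule) -> int:
    """Number of non-hydrogen atoms."""
    return sum(1 for s in molecule.species if s != "H")


def electron_count(molecule: Molecule) -> int:
    """Total electron count: sum of atomic numbers minus the molecular charge."""
    total = sum(molecule.elements.atomic_number(s) for s in molecule.species)
    n = total - molecule.charge
    if n <= 0:
        raise MoleculeError(f"non-positive electron count {n}")
    return n


def detect_linearity(molecule: Molecule, tolerance: float = 1e-8) -> bool:
    """True iff the geometry is linear.

    Decided from the principal moments of inertia: linear iff the smallest
    moment is below ``tolerance`` times the largest. Two-atom molecules are
    always linear; coincident atoms are rejected.
    """
    if molecule.n_atoms < 2:
        raise MoleculeError("linearity is undefined for a single atom")
    coords = molecule.coordinates
    diffs = coords[:, None, :] - coords[None, :, :]
    dists = np.linalg.norm(diffs, axis=-1)
    iu = np.triu_indices(molecule.n_atoms, k=1)
    if np.any(dists[iu] < 1e-10):
        raise MoleculeError("coincident atoms: zero interatomic distance")
    if molecule.n_atoms == 2:
        return True
    masses = molecule.masses()
    com = masses @ coords / masses.sum()
    r = coords - com
    inertia = np.einsum("a,ai,aj->ij", masses, r, r)
    tensor = np.eye(3) * np.trace(inertia) - inertia
    moments = np.sort(np.linalg.eigvalsh(tensor))
    return bool(moments[0] < tolerance * moments[2])


def vibrational_dof(molecule: Molecule, linear: bool | None = None) -> int:
    """Vibrational degrees of freedom: 3*N_a - 5 if linear, else 3*N_a - 6.

    ``linear`` overrides geometric detection when given explicitly.
    """
    if molecule.n_atoms < 2:
        raise MoleculeError("a single atom has no vibrational modes")
    if linear is None:
        linear = detect_linearity(molecule)
    return 3 * molecule.n_atoms - (5 if linear else 6)


# --- XYZ interchange -------------------------------------------------------

_ENERGY_TOKEN = re.compile(r"energy=(\S+)")


def read_xyz(path: str | Path, elements: ElementTable = DEFAULT_ELEMENTS) -> tuple[Molecule, float | None]:
    """Read a standard XYZ file.

    Returns the molecule and the energy in Hartree if the comment line
    carries an ``energy=<float>`` token, else None.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise MoleculeError(f"{path}: not an XYZ file (fewer than 2 lines)")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise MoleculeError(f"{path}: first line must hold the atom count") from None
    comment = lines[1]
    body = lines[2 : 2 + n]
    if len(body) != n:
        raise MoleculeError(f"{path}: expected {n} atom lines, found {len(body)}")
    species: list[str] = []
    coords = np.empty((n, 3))
    for i, line in enumerate(body):
        parts = line.split()
        if len(parts) < 4:
            raise MoleculeError(f"{path}: malformed atom line {i + 3}: {line!r}")
        species.append(parts[0])
        coords[i] = [float(x) for x in parts[1:4]]
    energy = None
    m = _ENERGY_TOKEN.search(comment)
    if m:
        energy = float(m.group(1))
    name = Path(path).stem
    return Molecule(tuple(species), coords, name=name, elements=elements), energy


def write_xyz(
    path: str | Path,
    molecule: Molecule,
    energy: float | None = None,
    comment: str = "",
) -> None:
    """Write a standard XYZ file; the energy (Ha) goes into the comment line."""
    lines = [str(molecule.n_atoms)]
    tokens = [comment] if comment else []
    if energy is not None:
        tokens.append(f"energy={energy!r}")
    lines.append(" ".join(tokens))
    for s, (x, y, z) in zip(molecule.species, molecule.coordinates):
        lines.append(f"{s} {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def iter_xyz_dir(path: str | Path, elements: ElementTable = DEFAULT_ELEMENTS) -> Iterator[tuple[Molecule, float | None]]:
    """Yield (molecule, energy) for every ``*.xyz`` file, sorted by name."""
    for p in sorted(Path(path).glob("*.xyz")):
        yield read_xyz(p, elements=elements)
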