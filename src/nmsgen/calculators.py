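"""Single-point-energy calculator contract and analytic toy potentials.

A calculator turns (species, coordinates) into a total energy in Hartree or
raises :class:`~nmsgen.errors.SinglePointFailure`, the typed stand-in for an
SCF that did not converge. Failed conformers are logged and excluded from
exported datasets; they never crash a sampling run.

Shipped backends:

* :class:`HarmonicCalculator` — an exactly quadratic surface built from a
  reference geometry, energy and Hessian; never fails. This is the surface
  on which the sampler's thermal-energy identity is exact.
* :class:`PairwiseMorseCalculator` — a sum of Morse terms over atom pairs;
  anharmonic, with an optional hard failure radius that emulates SCF
  breakdown for clashed geometries, so curated datasets grow a realistic
  high-energy tail.
* :class:`CommandCalculator` — delegates to an external executable (XYZ on
  stdin, one float on stdout; nonzero exit = failure).
"""
from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import CalculatorError, MoleculeError, SinglePointFailure
from .molecules import Molecule

__all__ = [
    "Calculator",
    "HarmonicCalculator",
    "PairwiseMorseCalculator",
    "CommandCalculator",
    "AtomicEnergyTable",
    "atomization_energy",
    "harmonic_calculator",
]


class Calculator:
    """Deterministic single-point energy backend."""

    name: str = "calculator"

    def supports(self, species: Sequence[str]) -> bool:
        raise NotImplementedError

    def evaluate(self, species: Sequence[str], coordinates: np.ndarray) -> float:
        """Total energy in Hartree; raises SinglePointFailure on non-convergence."""
        raise NotImplementedError


class HarmonicCalculator(Calculator):
    """E(x) = E_ref + (1/2) d^T H d with d the flattened Cartesian deviation."""

    def __init__(self, reference: Molecule, reference_energy: float, hessian: np.ndarray):
        hessian = np.asarray(hessian, dtype=float)
        dim = 3 * reference.n_atoms
        if hessian.shape != (dim, dim):
            raise CalculatorError(f"hessian must be {(dim, dim)}; got {hessian.shape}")
        self.reference = reference
        self.reference_energy = float(reference_energy)
        self.hessian = hessian
        self.name = f"harmonic[{reference.name or 'ref'}]"

    def supports(self, species: Sequence[str]) -> bool:
        return tuple(species) == self.reference.species

    def evaluate(self, species: Sequence[str], coordinates: np.ndarray) -> float:
        if not self.supports(species):
            raise CalculatorError(f"{self.name} only evaluates {self.reference.species}")
        d = (np.asarray(coordinates, dtype=float) - self.reference.coordinates).ravel()
        return self.reference_energy + 0.5 * float(d @ self.hessian @ d)


def harmonic_calculator(reference: Molecule, reference_energy: float, hessian: np.ndarray) -> HarmonicCalculator:
    """Functional alias for :class:`HarmonicCalculator`."""
    return HarmonicCalculator(reference, reference_energy, hessian)


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class MorseParams:
    """One pair interaction: well depth D (Ha), equilibrium distance r0 (A),
    steepness a (1/A)."""

    well_depth: float
    r0: float
    steepness: float


class PairwiseMorseCalculator(Calculator):
    """Sum over atom pairs of D * (1 - exp(-a (r - r0)))^2 (+ offset).

    Each pair term is zero at its equilibrium distance and tends to its well
    depth D at dissociation. If any interatomic distance falls below
    ``r_fail`` the evaluation raises SinglePointFailure, emulating SCF
    non-convergence for clashed geometries.
    """

    def __init__(
        self,
        params: Mapping[tuple[str, str], MorseParams],
        offset: float = 0.0,
        r_fail: float | None = None,
    ):
        self.params = {_pair_key(*k): v for k, v in params.items()}
        self.offset = float(offset)
        self.r_fail = r_fail
        self.name = "pairwise-morse"

    def supports(self, species: Sequence[str]) -> bool:
        species = tuple(species)
        return all(
            _pair_key(species[i], species[j]) in self.params
            for i in range(len(species))
            for j in range(i + 1, len(species))
        )

    def evaluate(self, species: Sequence[str], coordinates: np.ndarray) -> float:
        species = tuple(species)
        coords = np.asarray(coordinates, dtype=float)
        if not self.supports(species):
            raise CalculatorError(f"{self.name} lacks parameters for some pair in {species}")
        energy = self.offset
        for i in range(len(species)):
            for j in range(i + 1, len(species)):
                r = float(np.linalg.norm(coords[i] - coords[j]))
                if self.r_fail is not None and r < self.r_fail:
                    raise SinglePointFailure(
                        f"pair ({i},{j}) at r={r:.3f} A below failure radius {self.r_fail}"
                    )
                p = self.params[_pair_key(species[i], species[j])]
                energy += p.well_depth * (1.0 - np.exp(-p.steepness * (r - p.r0))) ** 2
        return float(energy)


class CommandCalculator(Calculator):
    """External executable backend.

    The child process receives the geometry as standard XYZ on stdin and
    must print a single float (Hartree) to stdout; a nonzero exit status is
    interpreted as an SCF-style failure.
    """

    def __init__(self, executable: str, supported_species: set[str] | None = None, timeout: float = 60.0):
        self.executable = executable
        self.supported_species = supported_species
        self.timeout = timeout
        self.name = f"command[{executable}]"

    def supports(self, species: Sequence[str]) -> bool:
        if self.supported_species is None:
            return True
        return set(species) <= self.supported_species

    def evaluate(self, species: Sequence[str], coordinates: np.ndarray) -> float:
        coords = np.asarray(coordinates, dtype=float)
        lines = [str(len(species)), ""]
        lines += [f"{s} {x:.12f} {y:.12f} {z:.12f}" for s, (x, y, z) in zip(species, coords)]
        try:
            out = subprocess.run(
                [self.executable],
                input="\n".join(lines) + "\n",
                capture_output=True,
                text=True,
                timeout=self.timeout,
            )
        except (OSError, subprocess.TimeoutExpired) as exc:
            raise CalculatorError(f"cannot run {self.executable}: {exc}") from exc
        if out.returncode != 0:
            raise SinglePointFailure(f"{self.executable} exited {out.returncode}")
        try:
            return float(out.stdout.split()[0])
        except (IndexError, ValueError):
            raise CalculatorError(f"{self.executable} printed no parseable energy") from None


@dataclass(frozen=True)
class AtomicEnergyTable:
    """Isolated-atom reference energies (Ha) for atomization-energy accounting."""

    energies: Mapping[str, float]

    @classmethod
    def from_file(cls, path: str | Path) -> "AtomicEnergyTable":
        """Two whitespace-delimited columns ``symbol energy_Ha``; ``#`` comments."""
        table: dict[str, float] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise MoleculeError(f"{path}: malformed line {raw!r}")
            table[parts[0]] = float(parts[1])
        return cls(dict(table))

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.energies

    def __getitem__(self, symbol: str) -> float:
        return self.energies[symbol]


def atomization_energy(
    total_energy: float,
    species: Sequence[str],
    table: AtomicEnergyTable,
) -> float:
    """Total energy minus the sum of isolated-atom energies; negative for
    bound molecules."""
    missing = sorted({s for s in species if s not in table})
    if missing:
        raise MoleculeError(f"atomic energy table missing symbols: {missing}")
    return float(total_energy) - sum(table[s] for s in species)
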