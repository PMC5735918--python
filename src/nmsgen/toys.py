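"""Toy molecules with analytic quadratic force fields.

These fixtures make the whole pipeline runnable at desk scale with exact
expectations: every Hessian here has an exact translational/rotational null
space, so the sampler's thermal-energy identity holds to floating-point
precision on the matching harmonic surface.

Two construction routes:

* ``spring_network_hessian`` — harmonic pair springs at their natural
  lengths (the Hessian of sum of (k/2)(|r_i - r_j| - d_ij)^2 evaluated at
  equilibrium). A triangulated spring network is rigid, so all 3N-6 modes
  have positive curvature.
* ``spectral_hessian`` — assemble H = M^(1/2) (sum_i lambda_i v_i v_i^T) M^(1/2)
  from chosen eigenvalues on the orthogonal complement of the mass-weighted
  translation/rotation space. Used for the linear triatomic, where pair
  springs alone cannot produce transverse bend curvature.

The shipped library: a homonuclear diatomic (1 mode, closed-form force
constant 2k), a bent water-like triatomic (3 modes), a linear symmetric
CO2-like triatomic (4 modes, exercising the 3N-5 count), and a tetrahedral
methane-like 5-atom molecule (9 modes). All reference energies and the
toy atomic-energy table are synthetic values chosen for testing, not
quantum-chemistry results.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calculators import (
    AtomicEnergyTable,
    Calculator,
    HarmonicCalculator,
    MorseParams,
    PairwiseMorseCalculator,
)
from .curation import CurationConfig, SubsetSummary, energy_window_split, summarize_dataset
from .h5format import AniMoleculeRecord, write_ani_h5
from .molecules import Molecule
from .normal_modes import NormalModeSet, normal_mode_analysis
from .sampling import ANI1_SCHEDULE, ConformerSet, SamplingSchedule, molecule_rng, sample_window

__all__ = [
    "ToyMolecule",
    "spring_network_hessian",
    "spectral_hessian",
    "make_toy_library",
    "toy_atomic_energies",
    "build_synthetic_dataset",
    "make_equilibrium_only_dataset",
]


@dataclass
class ToyMolecule:
    """A fixture molecule: geometry + analytic Hessian + reference energy.

    known_force_constants holds closed-form mode force constants where a
    hand derivation exists (diatomic, spectral constructions); None where
    the independent oracle is direct diagonalization.
    """

    molecule: Molecule
    hessian: np.ndarray
    reference_energy: float
    known_force_constants: np.ndarray | None = None
    smiles: str = ""

    @property
    def name(self) -> str:
        return self.molecule.name

    def harmonic_calculator(self) -> HarmonicCalculator:
        return HarmonicCalculator(self.molecule, self.reference_energy, self.hessian)

    def morse_calculator(self, well_depth: float = 0.4, steepness: float = 1.5,
                         r_fail: float | None = None) -> PairwiseMorseCalculator:
        """Anharmonic surrogate: Morse pairs with r0 set to the toy's actual
        pair distances, so the equilibrium geometry stays the minimum."""
        coords = self.molecule.coordinates
        species = self.molecule.species
        params = {}
        for i in range(len(species)):
            for j in range(i + 1, len(species)):
                key = tuple(sorted((species[i], species[j])))
                r = float(np.linalg.norm(coords[i] - coords[j]))
                # keep the first distance seen per element pair
                params.setdefault(key, MorseParams(well_depth, r, steepness))
        return PairwiseMorseCalculator(params, offset=self.reference_energy, r_fail=r_fail)

    def modes(self, **kwargs) -> NormalModeSet:
        return normal_mode_analysis(self.molecule, self.hessian, **kwargs)


def spring_network_hessian(
    coordinates: np.ndarray, springs: list[tuple[int, int, float]], n_atoms: int | None = None
) -> np.ndarray:
    """Cartesian Hessian of harmonic pair springs at their natural lengths.

    springs is a list of (i, j, k) with k in Ha/A^2. At equilibrium the
    Hessian block for a spring along unit vector u is k * u u^T, so the
    result has exact translational and rotational zero modes.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    n = n_atoms or coordinates.shape[0]
    h = np.zeros((3 * n, 3 * n))
    for i, j, k in springs:
        u = coordinates[i] - coordinates[j]
        u = u / np.linalg.norm(u)
        block = k * np.outer(u, u)
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        h[si, si] += block
        h[sj, sj] += block
        h[si, sj] -= block
        h[sj, si] -= block
    return h


def spectral_hessian(
    molecule: Molecule, eigenvalues: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Build a Hessian with prescribed mass-weighted vibrational eigenvalues.

    Returns (hessian, force_constants) where force_constants are the exact
    quadratic-form values along the Cartesian-normalized modes,
    K_i = lambda_i / |M^(-1/2) v_i|^2 — the closed-form oracle for this
    construction. The vibrational basis is the (deterministic) orthogonal
    complement of the mass-weighted translation/rotation space.
    """
    from .normal_modes import _tr_basis  # deliberate reuse: same frame convention

    eigenvalues = np.asarray(eigenvalues, dtype=float)
    masses = molecule.masses()
    m3 = np.repeat(masses, 3)
    d = _tr_basis(molecule, masses)
    nf = 3 * molecule.n_atoms - d.shape[1]
    if eigenvalues.shape != (nf,):
        raise ValueError(f"need {nf} eigenvalues, got {eigenvalues.shape}")
    # deterministic complement basis via SVD of the projector
    proj = np.eye(3 * molecule.n_atoms) - d @ d.T
    u, s, _ = np.linalg.svd(proj)
    v = u[:, :nf]  # singular value 1 subspace
    # fix signs for reproducibility
    for col in range(nf):
        pivot = np.argmax(np.abs(v[:, col]))
        if v[pivot, col] < 0:
            v[:, col] = -v[:, col]
    a = (v * eigenvalues) @ v.T
    sqm = np.sqrt(m3)
    hessian = a * np.outer(sqm, sqm)
    ks = eigenvalues / np.sum((v / sqm[:, None]) ** 2, axis=0)
    order = np.argsort(eigenvalues)
    return hessian, ks[order]


def make_toy_library() -> dict[str, ToyMolecule]:
    """The shipped fixture molecules, keyed by name."""
    lib: dict[str, ToyMolecule] = {}

    # Homonuclear diatomic (N2-like, 2 heavy atoms): one stretch mode.
    # Closed form: Cartesian stretch mode (u, -u)/sqrt(2) gives K = 2k.
    k_bond = 1.2
    d = 1.10
    n2 = Molecule(("N", "N"), np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]), name="n2")
    lib["n2"] = ToyMolecule(
        molecule=n2,
        hessian=spring_network_hessian(n2.coordinates, [(0, 1, k_bond)]),
        reference_energy=-109.0,
        known_force_constants=np.array([2.0 * k_bond]),
        smiles="N#N",
    )

    # Bent water-like triatomic (1 heavy atom): triangle of springs, 3 modes.
    theta = np.deg2rad(104.5)
    r_oh = 0.96
    water = Molecule(
        ("O", "H", "H"),
        np.array(
            [
                [0.0, 0.0, 0.0],
                [r_oh, 0.0, 0.0],
                [r_oh * np.cos(theta), r_oh * np.sin(theta), 0.0],
            ]
        ),
        name="water",
    )
    lib["water"] = ToyMolecule(
        molecule=water,
        hessian=spring_network_hessian(
            water.coordinates, [(0, 1, 0.9), (0, 2, 0.9), (1, 2, 0.25)]
        ),
        reference_energy=-76.4,
        smiles="O",
    )

    # Linear symmetric CO2-like triatomic (3 heavy atoms): 4 modes incl. a
    # degenerate bend pair, built spectrally.
    r_co = 1.16
    co2 = Molecule(
        ("O", "C", "O"),
        np.array([[-r_co, 0.0, 0.0], [0.0, 0.0, 0.0], [r_co, 0.0, 0.0]]),
        name="co2",
    )
    # amu-weighted eigenvalues, Ha/(A^2 amu); the bend pair is split slightly
    # so mode/force-constant identification stays unambiguous in oracles
    co2_evals = np.array([0.02, 0.022, 0.06, 0.10])
    co2_h, co2_ks = spectral_hessian(co2, co2_evals)
    lib["co2"] = ToyMolecule(
        molecule=co2,
        hessian=co2_h,
        reference_energy=-188.0,
        known_force_constants=co2_ks,
        smiles="O=C=O",
    )

    # Tetrahedral methane-like 5-atom molecule (1 heavy atom): full spring
    # triangulation over all 10 pairs -> 9 positive modes.
    r_ch = 1.09
    t = r_ch / np.sqrt(3.0)
    vertices = np.array([[t, t, t], [t, -t, -t], [-t, t, -t], [-t, -t, t]])
    coords = np.vstack([[0.0, 0.0, 0.0], vertices])
    methane = Molecule(("C", "H", "H", "H", "H"), coords, name="methane")
    springs = [(0, j, 0.7) for j in range(1, 5)]
    springs += [(i, j, 0.15) for i in range(1, 5) for j in range(i + 1, 5)]
    lib["methane"] = ToyMolecule(
        molecule=methane,
        hessian=spring_network_hessian(coords, springs),
        reference_energy=-40.0,
        smiles="C",
    )
    return lib


def toy_atomic_energies() -> AtomicEnergyTable:
    """Synthetic isolated-atom energies sized so toy molecules are bound
    (atomization energy < 0). Not quantum-chemistry values."""
    return AtomicEnergyTable({"H": -0.5, "C": -37.0, "N": -54.0, "O": -75.0})


def _curate_and_pack(
    conformer_sets: list[ConformerSet],
    config: CurationConfig,
    schedule: SamplingSchedule,
) -> tuple[list[AniMoleculeRecord], SubsetSummary]:
    groups: dict[int, list[tuple[ConformerSet, ConformerSet]]] = {}
    records = []
    for cs in conformer_sets:
        low, high = energy_window_split(cs, config)
        heavy = cs.provenance.get("heavy_atoms")
        if heavy is None:
            heavy = sum(1 for s in cs.species if s != "H")
        groups.setdefault(heavy, []).append((low, high))
        records.append(AniMoleculeRecord.from_conformer_sets(low, high, name=cs.molecule.name))
    return records, summarize_dataset(groups, schedule)


def build_synthetic_dataset(
    path: str | Path,
    seed: int,
    schedule: SamplingSchedule = ANI1_SCHEDULE,
    calculator: str = "harmonic",
    curation: CurationConfig = CurationConfig(),
    library: dict[str, ToyMolecule] | None = None,
) -> SubsetSummary:
    """Run the full pipeline — sampling, curation, HDF5 export — over the toy
    library, deterministically under ``seed``.

    calculator: "harmonic" (exact quadratic surfaces, never fails) or
    "morse" (anharmonic with a clash-failure radius, so both the failure
    path and the high-energy partition get exercised).
    """
    library = library if library is not None else make_toy_library()
    conformer_sets = []
    for name in sorted(library):
        toy = library[name]
        modes = toy.modes()
        if calculator == "harmonic":
            calc: Calculator = toy.harmonic_calculator()
        elif calculator == "morse":
            calc = toy.morse_calculator(r_fail=0.35)
        else:
            raise ValueError(f"unknown calculator choice {calculator!r}")
        rng = molecule_rng(seed, name)
        conformer_sets.append(
            sample_window(toy.molecule, modes, schedule, calc, rng, smiles=toy.smiles)
        )
    records, summary = _curate_and_pack(conformer_sets, curation, schedule)
    write_ani_h5(path, records)
    return summary


def make_equilibrium_only_dataset(
    path: str | Path,
    library: dict[str, ToyMolecule] | None = None,
) -> None:
    """Write a dataset holding exactly one conformer per molecule: the
    equilibrium geometry at its reference energy (the baseline the coverage
    statistics compare against)."""
    library = library if library is not None else make_toy_library()
    records = []
    for name in sorted(library):
        toy = library[name]
        records.append(
            AniMoleculeRecord(
                species=toy.molecule.species,
                coordinates=toy.molecule.coordinates[None, :, :],
                energies=np.array([toy.reference_energy]),
                coordinates_he=np.zeros((0, toy.molecule.n_atoms, 3)),
                energies_he=np.zeros((0,)),
                smiles=toy.smiles,
                name=name,
            )
        )
    write_ani_h5(path, records)
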