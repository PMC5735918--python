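"""Normal mode sampling: thermal off-equilibrium conformer generation.

For an equilibrium structure with N_f vibrational modes and force constants
K_i, one conformer is drawn as follows:

1. draw N_f nonnegative weights c_i with sum(c) in [0, 1];
2. set each mode's displacement magnitude by equating the harmonic energy
   (1/2) K_i R_i^2 to the c_i-scaled mean thermal energy of the N_a-particle
   system at temperature T:

       R_i = sqrt(3 * c_i * N_a * k_b * T / K_i)          [Angstrom]

3. give each R_i a fair random sign so both sides of the well are sampled;
4. displace the equilibrium geometry by the superposition sum_i s_i R_i q_i
   and evaluate a single-point energy there.

On an exactly quadratic surface the energy rise of one draw is
(3/2) * N_a * k_b * T * sum(c), which is bounded by (3/2) N_a k_b T because
sum(c) <= 1 by construction.

A sampling schedule maps the heavy-atom count of a molecule to the number
of draws per degree of freedom, S, and to the sampling temperature T_max.
The shipped default schedule is the one used to generate the ANI-1 release.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .calculators import Calculator
from .errors import CalculatorError, ImaginaryModeError, MoleculeError, ScheduleError
from .molecules import CONSTANTS, Molecule, PhysicalConstants, heavy_atom_count
from .normal_modes import NormalModeSet

__all__ = [
    "SamplingSchedule",
    "DisplacementDraw",
    "Conformer",
    "ConformerSet",
    "ANI1_SCHEDULE",
    "draw_mode_weights",
    "draw_signs",
    "displacement_magnitude",
    "generate_conformer",
    "conformer_count",
    "schedule_lookup",
    "sample_window",
    "molecule_rng",
]

TemperatureMode = Literal["fixed_at_max", "uniform_up_to_max"]
WeightMethod = Literal["simplex", "rejection"]


@dataclass(frozen=True)
class SamplingSchedule:
    """Per-heavy-atom-count sampling parameters.

    rows maps heavy-atom count -> (S, T_max) where S is the number of draws
    per vibrational degree of freedom and T_max the sampling temperature cap
    in Kelvin.
    """

    rows: dict[int, tuple[int, float]]
    temperature_mode: TemperatureMode = "fixed_at_max"

    def __post_init__(self) -> None:
        for size, (s, t_max) in self.rows.items():
            if s < 1:
                raise ScheduleError(f"S must be >= 1 (size {size}: S={s})")
            if t_max <= 0:
                raise ScheduleError(f"T_max must be > 0 (size {size}: T_max={t_max})")


#: The schedule used to build the ANI-1 release: heavy atoms -> (S, T_max K).
ANI1_SCHEDULE = SamplingSchedule(
    rows={
        1: (500, 2000.0),
        2: (450, 1500.0),
        3: (425, 1000.0),
        4: (400, 600.0),
        5: (200, 600.0),
        6: (30, 600.0),
        7: (20, 600.0),
        8: (5, 450.0),
    }
)


def schedule_lookup(schedule: SamplingSchedule, heavy_atoms: int) -> tuple[int, float]:
    """Exact row lookup: (S, T_max) for a heavy-atom count."""
    try:
        return schedule.rows[heavy_atoms]
    except KeyError:
        sizes = sorted(schedule.rows)
        raise ScheduleError(
            f"no schedule row for {heavy_atoms} heavy atoms (rows cover {sizes})"
        ) from None


def conformer_count(s_value: int, dof: int) -> int:
    """Number of conformers to draw: N = S x (vibrational degrees of freedom)."""
    if s_value < 1:
        raise ScheduleError(f"S must be >= 1, got {s_value}")
    if dof < 1:
        raise MoleculeError(f"degrees of freedom must be >= 1, got {dof}")
    return s_value * dof


def draw_mode_weights(
    n_modes: int,
    rng: np.random.Generator,
    method: WeightMethod = "simplex",
) -> np.ndarray:
    """Draw nonnegative mode weights c with sum(c) in [0, 1].

    ``simplex`` (default): normalize N_f i.i.d. uniforms to unit sum, then
    scale by one extra independent uniform — sum(c) is exactly Uniform[0,1]
    for any N_f and the weights are exchangeable.

    ``rejection``: redraw N_f uniforms until their sum is <= 1. Exactly
    uniform on the corner of the cube, but the acceptance probability is
    1/N_f!, so it is only practical for a handful of modes.
    """
    if n_modes < 1:
        raise MoleculeError("need at least one mode to draw weights")
    if method == "simplex":
        u = rng.uniform(size=n_modes)
        total = u.sum()
        if total == 0.0:  # probability zero, but keep the contract airtight
            u = np.full(n_modes, 1.0 / n_modes)
            total = 1.0
        return u / total * rng.uniform()
    if method == "rejection":
        while True:
            u = rng.uniform(size=n_modes)
            if u.sum() <= 1.0:
                return u
    raise ValueError(f"unknown weight method {method!r}")


def draw_signs(n_modes: int, rng: np.random.Generator) -> np.ndarray:
    """Fair i.i.d. +1/-1 signs, one per mode."""
    if n_modes < 1:
        raise MoleculeError("need at least one mode to draw signs")
    return np.where(rng.uniform(size=n_modes) < 0.5, -1.0, 1.0)


def displacement_magnitude(
    c_i: float | np.ndarray,
    n_atoms: int,
    temperature: float,
    force_constant: float | np.ndarray,
    constants: PhysicalConstants = CONSTANTS,
) -> float | np.ndarray:
    """Thermal displacement magnitude R_i = sqrt(3 c_i N_a k_b T / K_i), Angstrom."""
    if np.any(np.asarray(force_constant) <= 0):
        raise ImaginaryModeError("displacement undefined for non-positive force constant")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    c = np.asarray(c_i, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise ValueError("weights must lie in [0, 1]")
    r = np.sqrt(3.0 * c * n_atoms * constants.k_b * temperature / force_constant)
    return float(r) if np.isscalar(c_i) else r


@dataclass
class DisplacementDraw:
    """One realization of the sampling randomness for one conformer."""

    weights: np.ndarray      # c_i, sum in [0, 1]
    signs: np.ndarray        # +1 / -1
    magnitudes: np.ndarray   # R_i, Angstrom
    displacement: np.ndarray  # (n_atoms, 3), superposition of signed modes
    temperature: float       # K


def generate_conformer(
    modes: NormalModeSet,
    temperature: float,
    rng: np.random.Generator,
    constants: PhysicalConstants = CONSTANTS,
    weight_method: WeightMethod = "simplex",
) -> tuple[DisplacementDraw, Molecule]:
    """Draw one off-equilibrium conformer from an equilibrium mode set."""
    nf = modes.n_modes
    ref = modes.reference_geometry
    c = draw_mode_weights(nf, rng, method=weight_method)
    signs = draw_signs(nf, rng)
    r = displacement_magnitude(c, ref.n_atoms, temperature, modes.force_constants, constants)
    disp = np.tensordot(signs * r, modes.modes, axes=1)
    draw = DisplacementDraw(weights=c, signs=signs, magnitudes=np.asarray(r), displacement=disp, temperature=temperature)
    return draw, ref.with_coordinates(ref.coordinates + disp)


@dataclass
class Conformer:
    """One sampled geometry with its single-point result."""

    coordinates: np.ndarray
    energy: float | None
    status: Literal["ok", "energy_failed"]


@dataclass
class ConformerSet:
    """Equilibrium structure plus its sampled window of conformers."""

    molecule: Molecule
    equilibrium_energy: float | None
    conformers: list[Conformer] = field(default_factory=list)
    smiles: str = ""
    provenance: dict = field(default_factory=dict)

    @property
    def species(self) -> tuple[str, ...]:
        return self.molecule.species

    def ok_conformers(self) -> list[Conformer]:
        return [c for c in self.conformers if c.status == "ok"]

    def n_failed(self) -> int:
        return sum(1 for c in self.conformers if c.status != "ok")

    @classmethod
    def from_arrays(
        cls,
        molecule: Molecule,
        coordinates: np.ndarray,
        energies: np.ndarray,
        equilibrium_energy: float | None = None,
        smiles: str = "",
    ) -> "ConformerSet":
        coordinates = np.asarray(coordinates, dtype=float)
        energies = np.asarray(energies, dtype=float)
        if coordinates.shape[0] != energies.shape[0]:
            raise MoleculeError("coordinate and energy leading dimensions differ")
        confs = [Conformer(c, float(e), "ok") for c, e in zip(coordinates, energies)]
        return cls(molecule=molecule, equilibrium_energy=equilibrium_energy, conformers=confs, smiles=smiles)


def molecule_rng(global_seed: int, molecule_id: str) -> np.random.Generator:
    """Per-molecule generator: seed derived from (global seed, molecule id)
    so results do not depend on processing order."""
    return np.random.default_rng(
        np.random.SeedSequence([int(global_seed), zlib.crc32(molecule_id.encode())])
    )


def sample_window(
    molecule: Molecule,
    modes: NormalModeSet,
    schedule: SamplingSchedule,
    calculator: Calculator,
    rng: np.random.Generator,
    constants: PhysicalConstants = CONSTANTS,
    weight_method: WeightMethod = "simplex",
    smiles: str = "",
) -> ConformerSet:
    """Sample a window of the potential surface around one equilibrium structure.

    Draws N = S x N_f conformers at the scheduled temperature and evaluates
    each with ``calculator``. Conformers whose evaluation fails are recorded
    with status ``energy_failed`` and are excluded from exported arrays
    downstream; the equilibrium geometry is stored alongside but not counted
    within N.
    """
    from .errors import SinglePointFailure

    if not calculator.supports(molecule.species):
        raise CalculatorError(
            f"calculator {calculator.name!r} does not support species {molecule.species}"
        )
    heavy = heavy_atom_count(molecule)
    s_value, t_max = schedule_lookup(schedule, heavy)
    n_draws = conformer_count(s_value, modes.n_modes)

    try:
        eq_energy: float | None = calculator.evaluate(molecule.species, molecule.coordinates)
    except SinglePointFailure:
        eq_energy = None

    conformers: list[Conformer] = []
    for _ in range(n_draws):
        if schedule.temperature_mode == "uniform_up_to_max":
            t = rng.uniform(0.0, t_max)
            t = t if t > 0 else t_max  # open interval at zero
        else:
            t = t_max
        _, geom = generate_conformer(modes, t, rng, constants, weight_method)
        try:
            e = calculator.evaluate(geom.species, geom.coordinates)
            conformers.append(Conformer(geom.coordinates, float(e), "ok"))
        except SinglePointFailure:
            conformers.append(Conformer(geom.coordinates, None, "energy_failed"))

    return ConformerSet(
        molecule=molecule,
        equilibrium_energy=eq_energy,
        conformers=conformers,
        smiles=smiles,
        provenance={
            "heavy_atoms": heavy,
            "S": s_value,
            "T_max": t_max,
            "temperature_mode": schedule.temperature_mode,
            "n_draws": n_draws,
        },
    )
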