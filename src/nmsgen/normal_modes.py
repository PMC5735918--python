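"""Vibrational normal-mode analysis from a Cartesian Hessian.

The analysis follows the standard recipe: mass-weight the Hessian, project
out the three translations and the two (linear) or three infinitesimal
rotations in the Eckart frame, diagonalize, and keep the N_f vibrational
modes with the largest eigenvalues.

Normalization convention (important): each returned mode q_i is unit-
normalized in *plain Cartesian* space, and its force constant is defined as
the quadratic form along that unit direction,

    K_i = q_i^T H q_i     [Ha / Angstrom^2],

so that displacing the equilibrium geometry by x * q_i on a quadratic
surface raises the energy by exactly (1/2) K_i x^2. Because the Cartesian
modes are un-mass-weighted eigenvectors, they are mutually H-orthogonal and
the same identity holds for superpositions mode by mode. This makes the
thermal displacement law of the sampler dimensionally consistent
(K_i in Ha/A^2, displacements in Angstrom) with no reduced-mass bookkeeping.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import HessianError, ImaginaryModeError
from .molecules import DEFAULT_ELEMENTS, ElementTable, Molecule, detect_linearity, vibrational_dof

__all__ = ["NormalModeSet", "normal_mode_analysis", "read_hessian", "read_mode_files"]

# Hartree, amu, Angstrom -> wavenumber conversion for reporting frequencies.
_HARTREE_J = 4.3597447222071e-18
_AMU_KG = 1.66053906660e-27
_C_CM_S = 2.99792458e10
_EV_TO_CM1 = (_HARTREE_J / (_AMU_KG * 1e-20)) ** 0.5 / (2.0 * np.pi * _C_CM_S)


@dataclass
class NormalModeSet:
    """Vibrational modes and force constants of one equilibrium structure.

    modes            -- (N_f, n_atoms, 3), each unit-normalized in Cartesian space
    force_constants  -- (N_f,) strictly positive, Ha/A^2
    frequencies      -- (N_f,) harmonic wavenumbers in cm^-1, reporting only
    reference_geometry -- the equilibrium Molecule the modes belong to
    """

    modes: np.ndarray
    force_constants: np.ndarray
    frequencies: np.ndarray
    reference_geometry: Molecule

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=float)
        self.force_constants = np.asarray(self.force_constants, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        n_modes = self.modes.shape[0]
        if self.modes.ndim != 3 or self.modes.shape[1:] != (self.reference_geometry.n_atoms, 3):
            raise HessianError(f"modes must be (N_f, n_atoms, 3); got {self.modes.shape}")
        if self.force_constants.shape != (n_modes,) or self.frequencies.shape != (n_modes,):
            raise HessianError("force constant / frequency arrays must match mode count")
        if n_modes:
            norms = np.linalg.norm(self.modes.reshape(n_modes, -1), axis=1)
            if not np.allclose(norms, 1.0, atol=1e-10):
                raise HessianError("modes must be unit-normalized in Cartesian space")
        if np.any(self.force_constants <= 0):
            raise ImaginaryModeError("force constants must be strictly positive")

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]


def _tr_basis(molecule: Molecule, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation + rotation vectors, (3N, d)."""
    n = molecule.n_atoms
    sqm = np.sqrt(masses)
    com = masses @ molecule.coordinates / masses.sum()
    r = molecule.coordinates - com
    raw = []
    for axis in range(3):  # translations
        v = np.zeros((n, 3))
        v[:, axis] = sqm
        raw.append(v.ravel())
    for axis in range(3):  # infinitesimal rotations (about COM)
        e = np.zeros(3)
        e[axis] = 1.0
        v = sqm[:, None] * np.cross(np.broadcast_to(e, (n, 3)), r)
        raw.append(v.ravel())
    # Gram-Schmidt, dropping the degenerate rotation of a linear molecule.
    basis: list[np.ndarray] = []
    for v in raw:
        scale = np.linalg.norm(v)
        for b in basis:
            v = v - (b @ v) * b
        if np.linalg.norm(v) > 1e-8 * max(scale, 1.0):
            basis.append(v / np.linalg.norm(v))
    return np.column_stack(basis)


def normal_mode_analysis(
    molecule: Molecule,
    hessian: np.ndarray,
    element_table: ElementTable | None = None,
    linear: bool | None = None,
    allow_imaginary: bool = False,
    symmetry_rtol: float = 1e-8,
) -> NormalModeSet:
    """Diagonalize a Cartesian Hessian into vibrational modes + force constants.

    Parameters
    ----------
    molecule : equilibrium geometry (coordinates in Angstrom).
    hessian : (3N, 3N) symmetric second-derivative matrix, Ha/A^2.
    linear : force the linear/nonlinear mode count; autodetected if None.
    allow_imaginary : if True, modes with non-positive curvature are dropped
        with a warning instead of raising (a structure optimized onto a
        saddle point still yields usable real modes this way).
    """
    table = element_table or molecule.elements
    n = molecule.n_atoms
    hessian = np.asarray(hessian, dtype=float)
    if hessian.shape != (3 * n, 3 * n):
        raise HessianError(f"hessian must be {(3 * n, 3 * n)}; got {hessian.shape}")
    asym = np.abs(hessian - hessian.T).max()
    scale = max(np.abs(hessian).max(), 1e-300)
    if asym > symmetry_rtol * scale:
        raise HessianError(f"hessian is not symmetric (max asymmetry {asym:.3e})")

    if linear is None:
        linear = detect_linearity(molecule)
    nf = vibrational_dof(molecule, linear=linear)
    masses = np.array([table.mass(s) for s in molecule.species])
    m3 = np.repeat(masses, 3)
    h_mw = hessian / np.sqrt(np.outer(m3, m3))

    d = _tr_basis(molecule, masses)
    proj = np.eye(3 * n) - d @ d.T
    a = proj @ h_mw @ proj
    a = 0.5 * (a + a.T)
    evals, evecs = np.linalg.eigh(a)  # ascending

    vib_evals = evals[-nf:]
    vib_vecs = evecs[:, -nf:]
    max_ev = max(abs(evals[0]), abs(evals[-1]), 1e-300)
    bad = vib_evals <= 1e-10 * max_ev
    if np.any(bad):
        if not allow_imaginary:
            raise ImaginaryModeError(
                f"{int(bad.sum())} imaginary/zero vibrational mode(s); "
                "pass allow_imaginary=True to drop them"
            )
        warnings.warn(
            f"dropping {int(bad.sum())} imaginary/zero vibrational mode(s)",
            stacklevel=2,
        )
        vib_evals = vib_evals[~bad]
        vib_vecs = vib_vecs[:, ~bad]

    modes = []
    ks = []
    freqs = []
    for lam, v in zip(vib_evals, vib_vecs.T):
        w = v / np.sqrt(m3)  # un-mass-weight
        w = w / np.linalg.norm(w)
        # deterministic sign: first component of magnitude > 1e-8 made positive
        for comp in w:
            if abs(comp) > 1e-8:
                if comp < 0:
                    w = -w
                break
        modes.append(w.reshape(n, 3))
        ks.append(float(w @ hessian @ w))
        freqs.append(float(np.sqrt(max(lam, 0.0)) * _EV_TO_CM1))

    return NormalModeSet(
        modes=np.array(modes).reshape(len(modes), n, 3),
        force_constants=np.array(ks),
        frequencies=np.array(freqs),
        reference_geometry=molecule,
    )


def read_hessian(path: str | Path, n_atoms: int) -> np.ndarray:
    """Read a plain-text Hessian: 3N x 3N whitespace floats, full square or
    lower triangle row-wise. Triangle input is mirrored to a full matrix."""
    # token-wise parse: triangle files have ragged rows that loadtxt rejects
    values = np.array(Path(path).read_text().split(), dtype=float)
    dim = 3 * n_atoms
    n_full = dim * dim
    n_tri = dim * (dim + 1) // 2
    if values.size == n_full:
        h = values.reshape(dim, dim)
    elif values.size == n_tri:
        h = np.zeros((dim, dim))
        idx = np.tril_indices(dim)
        h[idx] = values
        h = h + h.T - np.diag(np.diag(h))
    else:
        raise HessianError(
            f"{path}: expected {n_full} (full {dim}x{dim}) or {n_tri} "
            f"(lower triangle) values, found {values.size}"
        )
    return h


def read_mode_files(
    modes_path: str | Path,
    constants_path: str | Path,
    molecule: Molecule,
) -> NormalModeSet:
    """Ingest externally computed modes + force constants.

    ``modes_path`` holds N_f blocks of n_atoms x 3 floats; ``constants_path``
    holds N_f floats (Ha/A^2). Modes are renormalized to Cartesian unit norm.
    """
    ks = np.loadtxt(constants_path).ravel()
    raw = np.loadtxt(modes_path).ravel()
    nf = ks.size
    n = molecule.n_atoms
    if raw.size != nf * n * 3:
        raise HessianError(
            f"{modes_path}: expected {nf} blocks of {n}x3 floats, found {raw.size} values"
        )
    modes = raw.reshape(nf, n, 3)
    norms = np.linalg.norm(modes.reshape(nf, -1), axis=1)
    if np.any(norms == 0):
        raise HessianError("zero-norm mode vector")
    modes = modes / norms[:, None, None]
    freqs = np.full(nf, np.nan)
    return NormalModeSet(modes=modes, force_constants=ks, frequencies=freqs, reference_geometry=molecule)
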