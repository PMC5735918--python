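"""Optional RDKit hook: SMILES -> pre-optimized 3-D geometry.

Everywhere else in the package SMILES strings are opaque metadata. This is
the one place they are interpreted: embed a SMILES, saturate with explicit
hydrogens (neutral singlet), and pre-optimize with MMFF94 to get a starting
geometry for an external optimizer. RDKit is imported lazily so the rest of
the package works without it.
"""
from __future__ import annotations

import numpy as np

from .errors import MoleculeError
from .molecules import Molecule


def embed_smiles(smiles: str, seed: int = 0, mmff_iterations: int = 500) -> Molecule:
    """Embed a SMILES string into 3-D and MMFF94-pre-optimize it."""
    try:
        from rdkit import Chem
        from rdkit.Chem import AllChem
    except ImportError as exc:  # pragma: no cover
        raise MoleculeError("the SMILES hook needs rdkit installed") from exc

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"RDKit cannot parse SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise MoleculeError(f"3-D embedding failed for {smiles!r}")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=mmff_iterations)
    conf = mol.GetConformer()
    species = tuple(atom.GetSymbol() for atom in mol.GetAtoms())
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    return Molecule(species, coords, name=smiles)
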