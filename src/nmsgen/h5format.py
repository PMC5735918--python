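"""Reader/writer for the ANI-style HDF5 molecule-record layout.

Each molecule is one HDF5 group holding six datasets:

* ``coordinates``   (n_conf, n_atoms, 3) float32, Angstrom
* ``energies``      (n_conf,) float64, Hartree
* ``species``       (n_atoms,) fixed-length bytes, element symbols
* ``coordinatesHE`` / ``energiesHE`` — same shapes for the high-energy
  partition (possibly empty)
* ``smiles``        scalar bytes, opaque metadata

Groups are nested ``gdb<heavy-atom count, zero-padded>/mol<0-based index>``
and the schema version is a root attribute. Coordinates default to 32-bit
storage (adequate for geometries); energies stay 64-bit because kcal/mol
windows on hundred-Hartree totals need the precision. Files are written
with HDF5 object timestamps disabled so identical inputs produce
byte-identical files.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import h5py
import numpy as np

from .errors import AniFormatError
from .molecules import DEFAULT_ELEMENTS, ElementTable, Molecule, write_xyz
from .sampling import ConformerSet

__all__ = [
    "AniMoleculeRecord",
    "write_ani_h5",
    "iter_ani_h5",
    "read_ani_h5",
    "export_xyz",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "nmsgen-ani-1"
logger = logging.getLogger(__name__)

_MANDATORY_KEYS = ("coordinates", "energies", "species", "coordinatesHE", "energiesHE", "smiles")


@dataclass
class AniMoleculeRecord:
    """In-memory form of one on-disk molecule record."""

    species: tuple[str, ...]
    coordinates: np.ndarray      # (n_low, n_atoms, 3)
    energies: np.ndarray         # (n_low,)
    coordinates_he: np.ndarray   # (n_high, n_atoms, 3), possibly empty
    energies_he: np.ndarray      # (n_high,)
    smiles: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.species = tuple(str(s) for s in self.species)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        self.coordinates_he = np.asarray(self.coordinates_he, dtype=float)
        self.energies_he = np.asarray(self.energies_he, dtype=float)
        self.validate()

    def validate(self) -> None:
        na = len(self.species)
        label = self.name or self.smiles or "<record>"
        for key, coords, energies in (
            ("coordinates", self.coordinates, self.energies),
            ("coordinatesHE", self.coordinates_he, self.energies_he),
        ):
            if coords.ndim != 3 or coords.shape[2] != 3:
                raise AniFormatError(f"{label}: {key} must be (n_conf, n_atoms, 3); got {coords.shape}")
            if coords.shape[1] != na:
                raise AniFormatError(
                    f"{label}: {key} atom dimension {coords.shape[1]} != species length {na}"
                )
            if coords.shape[0] != energies.shape[0]:
                raise AniFormatError(
                    f"{label}: {key} holds {coords.shape[0]} conformers but its "
                    f"energies array holds {energies.shape[0]}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def heavy_atoms(self) -> int:
        return sum(1 for s in self.species if s != "H")

    @classmethod
    def from_conformer_sets(
        cls,
        low: ConformerSet,
        high: ConformerSet | None = None,
        name: str = "",
    ) -> "AniMoleculeRecord":
        """Pack curated (low, high) conformer sets into one record."""
        na = low.molecule.n_atoms

        def _arrays(cs: ConformerSet | None) -> tuple[np.ndarray, np.ndarray]:
            ok = cs.ok_conformers() if cs is not None else []
            if not ok:
                return np.zeros((0, na, 3)), np.zeros((0,))
            return np.stack([c.coordinates for c in ok]), np.array([c.energy for c in ok])

        coords, energies = _arrays(low)
        coords_he, energies_he = _arrays(high)
        return cls(
            species=low.species,
            coordinates=coords,
            energies=energies,
            coordinates_he=coords_he,
            energies_he=energies_he,
            smiles=low.smiles,
            name=name or low.molecule.name,
        )


def write_ani_h5(
    path: str | Path,
    records: Iterable[AniMoleculeRecord],
    coordinate_dtype: str = "f4",
    energy_dtype: str = "f8",
) -> None:
    """Write records grouped as ``gdb<NN>/mol<i>`` (index per subset, input order)."""
    records = list(records)
    for r in records:
        r.validate()
    counters: dict[int, int] = {}
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        for rec in records:
            heavy = rec.heavy_atoms
            idx = counters.get(heavy, 0)
            counters[heavy] = idx + 1
            grp = f.require_group(f"gdb{heavy:02d}").create_group(f"mol{idx}", track_order=False)
            na = rec.n_atoms
            opts = dict(track_times=False)
            grp.create_dataset("coordinates", data=rec.coordinates, dtype=coordinate_dtype, **opts)
            grp.create_dataset("energies", data=rec.energies, dtype=energy_dtype, **opts)
            grp.create_dataset(
                "coordinatesHE",
                data=rec.coordinates_he,
                shape=(rec.coordinates_he.shape[0], na, 3),
                dtype=coordinate_dtype,
                **opts,
            )
            grp.create_dataset("energiesHE", data=rec.energies_he, dtype=energy_dtype, **opts)
            width = max((len(s) for s in rec.species), default=1)
            grp.create_dataset(
                "species", data=np.array([s.encode() for s in rec.species], dtype=f"S{width}"), **opts
            )
            grp.create_dataset("smiles", data=np.bytes_(rec.smiles.encode() or b""), **opts)


def _load_record(grp: h5py.Group, name: str) -> AniMoleculeRecord:
    missing = [k for k in _MANDATORY_KEYS if k not in grp]
    if missing:
        raise AniFormatError(f"group {name!r} missing mandatory key(s): {missing}")
    species = tuple(s.decode() for s in grp["species"][()])
    smiles_raw = grp["smiles"][()]
    if isinstance(smiles_raw, np.ndarray):  # tolerate 1-element array storage
        smiles_raw = smiles_raw.ravel()[0] if smiles_raw.size else b""
    smiles = smiles_raw.decode() if isinstance(smiles_raw, bytes) else str(smiles_raw)
    return AniMoleculeRecord(
        species=species,
        coordinates=grp["coordinates"][()],
        energies=grp["energies"][()],
        coordinates_he=grp["coordinatesHE"][()],
        energies_he=grp["energiesHE"][()],
        smiles=smiles,
        name=name,
    )


def iter_ani_h5(path: str | Path, strict: bool = True) -> Iterator[AniMoleculeRecord]:
    """Lazily yield records in deterministic lexicographic group order.

    strict=True raises on a malformed group; strict=False skips it with a
    logged warning (useful for foreign files whose layout only loosely
    matches this dialect).
    """
    with h5py.File(path, "r") as f:
        for subset in sorted(f.keys()):
            node = f[subset]
            if not isinstance(node, h5py.Group):
                continue
            # leaf = group whose children are datasets, not nested groups
            children = sorted(node.keys())
            leaf_groups = [c for c in children if isinstance(node[c], h5py.Group)]
            targets = (
                [(f"{subset}/{c}", node[c]) for c in leaf_groups]
                if leaf_groups
                else [(subset, node)]
            )
            for name, grp in targets:
                try:
                    yield _load_record(grp, name)
                except AniFormatError as exc:
                    if strict:
                        raise
                    logger.warning("skipping group %s: %s", name, exc)


def read_ani_h5(path: str | Path, strict: bool = True) -> list[AniMoleculeRecord]:
    """Eager list form of :func:`iter_ani_h5`."""
    return list(iter_ani_h5(path, strict=strict))


def export_xyz(
    record: AniMoleculeRecord,
    conformer_index: int,
    path: str | Path,
    high_energy: bool = False,
    elements: ElementTable = DEFAULT_ELEMENTS,
) -> None:
    """Write one conformer of a record as a standard XYZ file with an
    ``energy=<Ha>`` token in the comment line."""
    coords = record.coordinates_he if high_energy else record.coordinates
    energies = record.energies_he if high_energy else record.energies
    n = coords.shape[0]
    if not 0 <= conformer_index < n:
        raise AniFormatError(
            f"conformer index {conformer_index} out of range for {n} conformer(s)"
        )
    mol = Molecule(record.species, coords[conformer_index], name=record.name, elements=elements)
    write_xyz(path, mol, energy=float(energies[conformer_index]), comment=record.smiles)
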