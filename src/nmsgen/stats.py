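"""Conformational-coverage statistics over ANI-style datasets.

Implements the distributions used to validate that normal-mode-sampled
data covers conformational space beyond equilibrium geometries:

* pair-distance histograms on the r / r0 axis (r0 a reference single-bond
  equilibrium distance), with optional seeded Bernoulli subsampling;
* internal-angle histograms for element triples (all triples, or "bonded"
  triples selected by a distance cutoff of 1.6 x r0 per pair);
* energy-per-electron distributions per heavy-atom subset, normalized to
  unit area so subsets of very different size can be overlaid;
* atomization-energy distributions (total energy minus isolated-atom
  references), reporting the maximum so the <= 0 Ha property of curated
  low-energy sets can be asserted.

Zero-count bins are omitted from the log10 series rather than clamped to
-inf.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calculators import AtomicEnergyTable, atomization_energy
from .errors import StatsError
from .h5format import AniMoleculeRecord
from .molecules import DEFAULT_ELEMENTS, ElementTable

__all__ = [
    "DistanceHistogramConfig",
    "HistogramResult",
    "pair_distance_histogram",
    "angle_histogram",
    "energy_per_electron_distribution",
    "atomization_energy_distribution",
]


@dataclass
class HistogramResult:
    """Binned tallies plus the log10 of the normalized (unit-mass) series."""

    edges: np.ndarray
    counts: np.ndarray
    total: int
    max_value: float | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.edges.ndim != 1 or np.any(np.diff(self.edges) <= 0):
            raise StatsError("bin edges must be strictly increasing")
        if int(self.counts.sum()) != self.total:
            raise StatsError(
                f"counts sum {int(self.counts.sum())} != total tallied {self.total}"
            )

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def normalized(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.total

    def log10_series(self) -> tuple[np.ndarray, np.ndarray]:
        """(bin centers, log10 of normalized counts), empty bins omitted."""
        mask = self.counts > 0
        return self.centers[mask], np.log10(self.normalized[mask])

    def support(self) -> set[int]:
        """Indices of occupied bins."""
        return set(np.nonzero(self.counts)[0].tolist())


@dataclass
class DistanceHistogramConfig:
    """Settings for one pair-distance histogram.

    pair -- element pair, order-insensitive (("C","H") == ("H","C")).
    r0 -- reference single-bond equilibrium distance, Angstrom.
    edges -- bin edges on the r/r0 axis.
    subsample_rate -- Bernoulli keep-probability per (conformer, pair)
        distance; 1.0 tallies everything.
    seed -- subsampling seed.
    include_high_energy -- also tally the HE arrays.
    """

    pair: tuple[str, str]
    r0: float
    edges: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 4.0, 201))
    subsample_rate: float = 1.0
    seed: int = 0
    include_high_energy: bool = False

    def __post_init__(self) -> None:
        self.pair = tuple(sorted(self.pair))  # type: ignore[assignment]
        self.edges = np.asarray(self.edges, dtype=float)
        if self.r0 <= 0:
            raise StatsError("r0 must be positive")
        if not 0 < self.subsample_rate <= 1:
            raise StatsError("subsample_rate must be in (0, 1]")
        if np.any(np.diff(self.edges) <= 0):
            raise StatsError("bin edges must be strictly increasing")


def _pair_indices(species: Sequence[str], pair: tuple[str, str]) -> list[tuple[int, int]]:
    a, b = pair
    out = []
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            if tuple(sorted((species[i], species[j]))) == (a, b):
                out.append((i, j))
    return out


def _conformer_blocks(record: AniMoleculeRecord, include_he: bool) -> Iterable[np.ndarray]:
    if record.coordinates.shape[0]:
        yield record.coordinates
    if include_he and record.coordinates_he.shape[0]:
        yield record.coordinates_he


def pair_distance_histogram(
    records: Iterable[AniMoleculeRecord],
    config: DistanceHistogramConfig,
) -> HistogramResult:
    """Histogram of r/r0 over all matching unordered atom pairs and conformers."""
    rng = np.random.default_rng(config.seed)
    values: list[np.ndarray] = []
    matched_any = False
    for rec in records:
        idx = _pair_indices(rec.species, config.pair)
        if not idx:
            continue
        matched_any = True
        ii = np.array([i for i, _ in idx])
        jj = np.array([j for _, j in idx])
        for coords in _conformer_blocks(rec, config.include_high_energy):
            d = np.linalg.norm(coords[:, ii, :] - coords[:, jj, :], axis=-1).ravel()
            if config.subsample_rate < 1.0:
                keep = rng.uniform(size=d.size) < config.subsample_rate
                d = d[keep]
            if d.size:
                values.append(d / config.r0)
    if not matched_any:
        raise StatsError(f"no atom pair of type {config.pair} in the dataset")
    data = np.concatenate(values) if values else np.empty(0)
    counts, _ = np.histogram(data, bins=config.edges)
    return HistogramResult(edges=config.edges, counts=counts, total=int(counts.sum()),
                           max_value=float(data.max()) if data.size else None)


def _triple_indices(
    species: Sequence[str], triple: tuple[str, str, str]
) -> list[tuple[int, int, int]]:
    """(i, j, k) with j the central atom; (i, k) unordered."""
    a, b, c = triple
    out = []
    n = len(species)
    for j in range(n):
        if species[j] != b:
            continue
        for i in range(n):
            if i == j or species[i] != a:
                continue
            for k in range(n):
                if k == j or k == i or species[k] != c:
                    continue
                if a == c and k < i:  # unordered ends
                    continue
                out.append((i, j, k))
    return out


def angle_histogram(
    records: Iterable[AniMoleculeRecord],
    triple: tuple[str, str, str],
    edges: np.ndarray | None = None,
    mode: str = "bonded",
    r0_table: Mapping[tuple[str, str], float] | None = None,
    cutoff_factor: float = 1.6,
    include_high_energy: bool = False,
) -> HistogramResult:
    """Histogram of the internal angle (degrees, [0, 180]) at the central atom
    of every matching element triple.

    mode="bonded" keeps a triple only when both arms are within
    ``cutoff_factor * r0`` of the corresponding pair (requires ``r0_table``);
    mode="all" tallies every triple.
    """
    if edges is None:
        edges = np.linspace(0.0, 180.0, 181)
    if mode not in ("bonded", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "bonded" and r0_table is None:
        raise StatsError("bonded mode needs an r0 table for the distance cutoff")

    def _cutoff(x: str, y: str) -> float:
        key = tuple(sorted((x, y)))
        if key not in r0_table:  # type: ignore[operator]
            raise StatsError(f"r0 table missing pair {key}")
        return cutoff_factor * r0_table[key]  # type: ignore[index]

    values: list[np.ndarray] = []
    matched_any = False
    for rec in records:
        idx = _triple_indices(rec.species, triple)
        if not idx:
            continue
        matched_any = True
        ii = np.array([t[0] for t in idx])
        jj = np.array([t[1] for t in idx])
        kk = np.array([t[2] for t in idx])
        for coords in _conformer_blocks(rec, include_high_energy):
            v1 = coords[:, ii, :] - coords[:, jj, :]
            v2 = coords[:, kk, :] - coords[:, jj, :]
            n1 = np.linalg.norm(v1, axis=-1)
            n2 = np.linalg.norm(v2, axis=-1)
            cosang = np.clip(np.einsum("cij,cij->ci", v1, v2) / (n1 * n2), -1.0, 1.0)
            ang = np.degrees(np.arccos(cosang))
            if mode == "bonded":
                a, b, c = triple
                mask = (n1 <= _cutoff(a, b)) & (n2 <= _cutoff(c, b))
                ang = ang[mask]
            values.append(ang.ravel())
    if not matched_any:
        raise StatsError(f"no atom triple of type {triple} in the dataset")
    data = np.concatenate(values) if values else np.empty(0)
    if data.size == 0:
        raise StatsError(f"no triple of type {triple} passed the bonded cutoff")
    counts, _ = np.histogram(data, bins=edges)
    return HistogramResult(edges=edges, counts=counts, total=int(counts.sum()),
                           max_value=float(data.max()))


def energy_per_electron_distribution(
    records: Iterable[AniMoleculeRecord],
    element_table: ElementTable = DEFAULT_ELEMENTS,
    edges: np.ndarray | None = None,
    include_high_energy: bool = False,
) -> dict[int, HistogramResult]:
    """Per-heavy-atom-count histograms of total energy / electron count.

    Each subset's histogram is normalized to unit area (via
    ``HistogramResult.normalized``) so subsets of different size compare.
    """
    per_subset: dict[int, list[np.ndarray]] = {}
    for rec in records:
        electrons = sum(element_table.atomic_number(s) for s in rec.species)
        vals = [rec.energies / electrons]
        if include_high_energy and rec.energies_he.size:
            vals.append(rec.energies_he / electrons)
        per_subset.setdefault(rec.heavy_atoms, []).append(np.concatenate(vals))
    out: dict[int, HistogramResult] = {}
    for heavy, chunks in sorted(per_subset.items()):
        data = np.concatenate(chunks)
        if edges is None:
            lo, hi = float(data.min()), float(data.max())
            pad = max(1e-6, 0.05 * (hi - lo))
            sub_edges = np.linspace(lo - pad, hi + pad, 101)
        else:
            sub_edges = np.asarray(edges, dtype=float)
        counts, _ = np.histogram(data, bins=sub_edges)
        out[heavy] = HistogramResult(
            edges=sub_edges, counts=counts, total=int(counts.sum()), max_value=float(data.max())
        )
    return out


def atomization_energy_distribution(
    records: Iterable[AniMoleculeRecord],
    table: AtomicEnergyTable,
    edges: np.ndarray | None = None,
    include_high_energy: bool = False,
) -> HistogramResult:
    """Histogram of atomization energies over all conformers.

    ``max_value`` reports the largest atomization energy so the "never above
    0 Ha" property of curated low-energy sets can be checked directly.
    """
    values: list[np.ndarray] = []
    for rec in records:
        shift = atomization_energy(0.0, rec.species, table)
        values.append(rec.energies + shift)
        if include_high_energy and rec.energies_he.size:
            values.append(rec.energies_he + shift)
    if not values or not any(v.size for v in values):
        raise StatsError("no conformers to tally")
    data = np.concatenate(values)
    if edges is None:
        lo, hi = float(data.min()), float(data.max())
        pad = max(1e-6, 0.05 * (hi - lo))
        edges = np.linspace(lo - pad, hi + pad, 101)
    counts, _ = np.histogram(data, bins=edges)
    return HistogramResult(edges=edges, counts=counts, total=int(counts.sum()),
                           max_value=float(data.max()))
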