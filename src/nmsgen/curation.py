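"""Energy-window curation, failure exclusion, and dataset bookkeeping.

Curation splits each molecule's conformers into a low-energy set (within a
fixed window — 275 kcal/mol by default — of the lowest-energy conformer)
and a high-energy remainder that is kept separately rather than discarded.
The boundary is inclusive: a conformer sitting exactly at the threshold
stays in the low-energy set, because only energies strictly *greater* than
the window are moved out.

The module also ships the published per-subset bookkeeping of the ANI-1
release (molecule counts and low/high structure counts per heavy-atom
count) so summary tables and grand totals can be reproduced exactly.
"""
from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import CurationError
from .molecules import CONSTANTS
from .sampling import Conformer, ConformerSet

__all__ = [
    "CurationConfig",
    "SummaryRow",
    "SubsetSummary",
    "ExclusionReport",
    "ANI1_RELEASE_ROWS",
    "ANI1_STARTING_MOLECULES",
    "ANI1_OPTIMIZATION_FAILURES",
    "energy_window_split",
    "summarize_dataset",
    "exclusion_report",
    "format_percent",
]


@dataclass(frozen=True)
class CurationConfig:
    """Energy-window parameters.

    window_threshold_kcal -- window width above the per-molecule minimum,
        kcal/mol (converted to Hartree internally).
    inclusive_boundary -- if True (default), E - E_min == threshold stays low.
    include_equilibrium_reference -- if True (default), the equilibrium
        energy participates in the minimum; it is itself a conformer of the
        set.
    """

    window_threshold_kcal: float = 275.0
    inclusive_boundary: bool = True
    include_equilibrium_reference: bool = True

    def __post_init__(self) -> None:
        if self.window_threshold_kcal <= 0:
            raise CurationError("window threshold must be positive")

    @property
    def threshold_hartree(self) -> float:
        return self.window_threshold_kcal / CONSTANTS.hartree_to_kcalmol


def energy_window_split(
    conformer_set: ConformerSet,
    config: CurationConfig = CurationConfig(),
) -> tuple[ConformerSet, ConformerSet]:
    """Partition a conformer set into (low, high) relative to its own minimum.

    Only conformers with status ``ok`` participate; failed evaluations are
    dropped from both outputs (they were never valid data). The reference
    minimum is taken over the ok conformers and, by default, the equilibrium
    energy. |low| + |high| always equals the number of ok conformers.
    """
    ok = conformer_set.ok_conformers()
    energies = [c.energy for c in ok]
    if config.include_equilibrium_reference and conformer_set.equilibrium_energy is not None:
        energies = energies + [conformer_set.equilibrium_energy]
    if not energies:
        raise CurationError(
            "cannot curate: no ok conformer and no equilibrium energy present"
        )
    e_min = min(energies)
    thr = config.threshold_hartree

    low: list[Conformer] = []
    high: list[Conformer] = []
    for c in ok:
        rel = c.energy - e_min
        is_low = rel <= thr if config.inclusive_boundary else rel < thr
        (low if is_low else high).append(c)

    def _clone(conformers: list[Conformer], part: str) -> ConformerSet:
        prov = dict(conformer_set.provenance)
        prov.update(window_partition=part, window_threshold_kcal=config.window_threshold_kcal)
        return ConformerSet(
            molecule=conformer_set.molecule,
            equilibrium_energy=conformer_set.equilibrium_energy,
            conformers=conformers,
            smiles=conformer_set.smiles,
            provenance=prov,
        )

    return _clone(low, "low"), _clone(high, "high")


def format_percent(value: float, decimals: int = 2) -> float:
    """Round a percentage with banker's (half-even) rounding to ``decimals``."""
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_EVEN))


@dataclass(frozen=True)
class SummaryRow:
    """One heavy-atom-count row of the dataset bookkeeping table."""

    heavy_atoms: int
    n_molecules: int
    t_max: float | None
    s_value: int | None
    n_low: int
    n_high: int

    def __post_init__(self) -> None:
        if self.n_low < 0 or self.n_high < 0 or self.n_molecules < 0:
            raise CurationError("counts must be nonnegative")

    @property
    def n_total(self) -> int:
        return self.n_low + self.n_high


#: Published per-subset bookkeeping of the ANI-1 release:
#: (heavy atoms, molecules, T_max K, S, structures within / beyond the
#: 275 kcal/mol window).
ANI1_RELEASE_ROWS: tuple[SummaryRow, ...] = (
    SummaryRow(1, 3, 2000.0, 500, 10_800, 0),
    SummaryRow(2, 13, 1500.0, 450, 50_962, 398),
    SummaryRow(3, 20, 1000.0, 425, 151_200, 0),
    SummaryRow(4, 61, 600.0, 400, 651_936, 6_144),
    SummaryRow(5, 267, 600.0, 200, 1_813_151, 9_889),
    SummaryRow(6, 1_406, 600.0, 30, 1_682_245, 29_963),
    SummaryRow(7, 7_760, 600.0, 20, 6_460_162, 869_222),
    SummaryRow(8, 47_932, 450.0, 5, 11_236_918, 1_714_819),
)

#: Molecules entering / failing the geometry-optimization stage of ANI-1.
ANI1_STARTING_MOLECULES = 57_947
ANI1_OPTIMIZATION_FAILURES = 485


@dataclass
class SubsetSummary:
    """Bookkeeping table: one row per heavy-atom count plus grand totals."""

    rows: tuple[SummaryRow, ...]

    @property
    def total_molecules(self) -> int:
        return sum(r.n_molecules for r in self.rows)

    @property
    def total_low(self) -> int:
        return sum(r.n_low for r in self.rows)

    @property
    def total_high(self) -> int:
        return sum(r.n_high for r in self.rows)

    @property
    def total_structures(self) -> int:
        return sum(r.n_total for r in self.rows)

    def high_energy_percent(self, decimals: int = 1) -> float:
        """Share of structures beyond the window, percent of the grand total."""
        if self.total_structures == 0:
            return 0.0
        return format_percent(100.0 * self.total_high / self.total_structures, decimals)

    def format_table(self, fmt: str = "tsv") -> str:
        header = ["heavy_atoms", "molecules", "T_max", "S", "n_low", "n_high", "n_total"]

        def cells(r: SummaryRow) -> list[str]:
            return [
                str(r.heavy_atoms),
                str(r.n_molecules),
                "-" if r.t_max is None else f"{r.t_max:g}",
                "-" if r.s_value is None else str(r.s_value),
                str(r.n_low),
                str(r.n_high),
                str(r.n_total),
            ]

        total = [
            "total",
            str(self.total_molecules),
            "-",
            "-",
            str(self.total_low),
            str(self.total_high),
            str(self.total_structures),
        ]
        table = [header] + [cells(r) for r in self.rows] + [total]
        if fmt == "tsv":
            return "\n".join("\t".join(row) for row in table)
        if fmt == "md":
            lines = ["| " + " | ".join(table[0]) + " |"]
            lines.append("|" + "---|" * len(header))
            lines += ["| " + " | ".join(row) + " |" for row in table[1:]]
            return "\n".join(lines)
        raise ValueError(f"unknown table format {fmt!r}")

    @classmethod
    def from_counts(cls, rows: Iterable[SummaryRow]) -> "SubsetSummary":
        return cls(rows=tuple(sorted(rows, key=lambda r: r.heavy_atoms)))


def summarize_dataset(
    groups: Mapping[int, Sequence[tuple[ConformerSet, ConformerSet]]],
    schedule=None,
) -> SubsetSummary:
    """Tabulate curated (low, high) conformer-set pairs grouped by heavy-atom
    count into a bookkeeping table with a grand-total row.

    ``schedule`` (a :class:`~nmsgen.sampling.SamplingSchedule`) supplies the
    S / T_max columns when given.
    """
    rows = []
    for heavy in sorted(groups):
        pairs = groups[heavy]
        s_value = t_max = None
        if schedule is not None and heavy in schedule.rows:
            s_value, t_max = schedule.rows[heavy]
        rows.append(
            SummaryRow(
                heavy_atoms=heavy,
                n_molecules=len(pairs),
                t_max=t_max,
                s_value=s_value,
                n_low=sum(len(low.conformers) for low, _ in pairs),
                n_high=sum(len(high.conformers) for _, high in pairs),
            )
        )
    return SubsetSummary.from_counts(rows)


@dataclass(frozen=True)
class ExclusionReport:
    """Outcome of an exclusion stage (failed optimizations or single points)."""

    n_started: int
    n_failed: int

    def __post_init__(self) -> None:
        if self.n_failed < 0 or self.n_started < 0:
            raise CurationError("counts must be nonnegative")
        if self.n_failed > self.n_started:
            raise CurationError(
                f"{self.n_failed} failures exceed {self.n_started} started"
            )

    @property
    def n_retained(self) -> int:
        return self.n_started - self.n_failed

    @property
    def failure_rate_percent(self) -> float:
        if self.n_started == 0:
            return 0.0
        return format_percent(100.0 * self.n_failed / self.n_started, 2)


def exclusion_report(n_started: int, failures: int | Sequence) -> ExclusionReport:
    """Build an :class:`ExclusionReport` from a failure count or failure log."""
    n_failed = failures if isinstance(failures, int) else len(failures)
    return ExclusionReport(n_started=n_started, n_failed=n_failed)
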