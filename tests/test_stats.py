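"""Coverage statistics: distance, angle and energy distributions."""
import numpy as np
import pytest

from nmsgen.calculators import AtomicEnergyTable
from nmsgen.errors import StatsError
from nmsgen.h5format import AniMoleculeRecord, read_ani_h5
from nmsgen.stats import (
    DistanceHistogramConfig,
    HistogramResult,
    angle_histogram,
    atomization_energy_distribution,
    energy_per_electron_distribution,
    pair_distance_histogram,
)


def record_from_coords(species, coords, energies=None):
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[0]
    return AniMoleculeRecord(
        species=tuple(species),
        coordinates=coords,
        energies=np.zeros(n) if energies is None else np.asarray(energies, dtype=float),
        coordinates_he=np.zeros((0, len(species), 3)),
        energies_he=np.zeros(0),
    )


class TestHistogramResult:
    def test_mass_conservation_and_unit_norm(self):
        h = HistogramResult(edges=np.array([0.0, 1, 2, 3]), counts=np.array([2, 0, 3]), total=5)
        assert int(h.counts.sum()) == h.total
        assert h.normalized.sum() == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_total_rejected(self):
        with pytest.raises(StatsError):
            HistogramResult(edges=np.array([0.0, 1.0]), counts=np.array([2]), total=5)

    def test_log_series_omits_empty_bins(self):
        h = HistogramResult(edges=np.array([0.0, 1, 2, 3]), counts=np.array([2, 0, 2]), total=4)
        centers, logs = h.log10_series()
        assert centers.tolist() == [0.5, 2.5]
        np.testing.assert_allclose(logs, np.log10([0.5, 0.5]))


class TestPairDistances:
    def test_diatomic_at_r0_lands_in_unit_bin(self):
        rec = record_from_coords("NN", [[0, 0, 0], [1.1, 0, 0]])
        cfg = DistanceHistogramConfig(pair=("N", "N"), r0=1.1)
        hist = pair_distance_histogram([rec], cfg)
        assert hist.total == 1
        occupied = hist.support().pop()
        assert hist.edges[occupied] <= 1.0 <= hist.edges[occupied + 1]

    def test_homoelement_triatomic_tallies_three_pairs(self):
        rec = record_from_coords("HHH", [[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        cfg = DistanceHistogramConfig(pair=("H", "H"), r0=1.0)
        assert pair_distance_histogram([rec], cfg).total == 3

    def test_pair_order_insensitive(self):
        rec = record_from_coords("OH", [[0, 0, 0], [0.96, 0, 0]])
        a = pair_distance_histogram([rec], DistanceHistogramConfig(pair=("O", "H"), r0=0.96))
        b = pair_distance_histogram([rec], DistanceHistogramConfig(pair=("H", "O"), r0=0.96))
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_no_matching_pair_errors(self):
        rec = record_from_coords("HH", [[0, 0, 0], [1, 0, 0]])
        with pytest.raises(StatsError):
            pair_distance_histogram([rec], DistanceHistogramConfig(pair=("C", "O"), r0=1.0))

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(size=(5, 4, 3))
        rec = record_from_coords("CHHO", coords)
        # a random rotation + translation applied to every conformer
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = coords @ q.T + np.array([3.0, -2.0, 1.0])
        rec2 = record_from_coords("CHHO", moved)
        cfg = DistanceHistogramConfig(pair=("H", "H"), r0=1.0)
        np.testing.assert_array_equal(
            pair_distance_histogram([rec], cfg).counts,
            pair_distance_histogram([rec2], cfg).counts,
        )

    def test_subsampling_is_binomial(self):
        """With n pair observations kept at rate p, the tally is
        Binomial(n, p); the seeded draw must land within 4 sigma."""
        n, p = 100_000, 0.1
        coords = np.tile(np.array([[0.0, 0, 0], [1.0, 0, 0]]), (n, 1, 1))
        rec = record_from_coords("NN", coords)
        cfg = DistanceHistogramConfig(pair=("N", "N"), r0=1.0, subsample_rate=p, seed=123)
        hist = pair_distance_histogram([rec], cfg)
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(hist.total - n * p) < 4 * sigma

    def test_nms_support_strictly_contains_equilibrium_support(self, nms_dataset, equilibrium_dataset):
        """Off-equilibrium sampling visits distance space the equilibrium-only
        dataset never reaches, while still covering the equilibrium bins."""
        cfg = DistanceHistogramConfig(pair=("N", "N"), r0=1.1, edges=np.linspace(0.5, 1.5, 21))
        nms = pair_distance_histogram(read_ani_h5(nms_dataset[0]), cfg)
        eq = pair_distance_histogram(read_ani_h5(equilibrium_dataset), cfg)
        assert eq.support() <= nms.support()
        assert len(nms.support()) > len(eq.support())


class TestAngles:
    def test_equilateral_triangle_at_60_degrees(self):
        rec = record_from_coords("HHH", [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        hist = angle_histogram([rec], ("H", "H", "H"), mode="all")
        centers, _ = hist.log10_series()
        assert np.allclose(centers, 60.5) or np.allclose(centers, 59.5)
        assert hist.total == 3  # one internal angle per central atom

    def test_collinear_triple_in_last_bin(self):
        rec = record_from_coords("HHH", [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        hist = angle_histogram([rec], ("H", "H", "H"), mode="all")
        assert hist.counts[-1] >= 1

    def test_angles_bounded(self, rng):
        coords = rng.normal(size=(20, 4, 3))
        rec = record_from_coords("HHHH", coords)
        hist = angle_histogram([rec], ("H", "H", "H"), mode="all")
        assert hist.max_value <= 180.0
        assert hist.counts.sum() == hist.total

    def test_bonded_mode_filters_by_cutoff(self):
        # H-O-H with one arm stretched far beyond 1.6 * r0
        near = record_from_coords("OHH", [[0, 0, 0], [0.96, 0, 0], [0, 0.96, 0]])
        far = record_from_coords("OHH", [[0, 0, 0], [0.96, 0, 0], [0, 5.0, 0]])
        r0 = {("H", "O"): 0.96}
        both = angle_histogram([near], ("H", "O", "H"), mode="bonded", r0_table=r0)
        assert both.total == 1
        with pytest.raises(StatsError):
            angle_histogram([far], ("H", "O", "H"), mode="bonded", r0_table=r0)

    def test_no_matching_triple_errors(self):
        rec = record_from_coords("HH", [[0, 0, 0], [1, 0, 0]])
        with pytest.raises(StatsError):
            angle_histogram([rec], ("H", "H", "H"), mode="all")


class TestEnergyDistributions:
    def test_energy_per_electron_arithmetic(self):
        rec = record_from_coords(
            "HH", np.zeros((2, 2, 3)) + [[0, 0, 0], [1, 0, 0]], energies=[-1.0, -1.2]
        )
        dists = energy_per_electron_distribution([rec])
        hist = dists[0]  # H2 has zero heavy atoms
        assert hist.total == 2
        centers, _ = hist.log10_series()
        # values -0.5 and -0.6 Ha/electron fall inside the tallied range
        assert hist.edges[0] < -0.6 < -0.5 < hist.edges[-1]

    def test_each_subset_normalized_to_unit_mass(self, nms_dataset):
        dists = energy_per_electron_distribution(read_ani_h5(nms_dataset[0]))
        assert set(dists) == {1, 2, 3}
        for hist in dists.values():
            assert hist.normalized.sum() == pytest.approx(1.0, abs=1e-12)

    def test_constant_shift_translates_histogram(self):
        coords = np.zeros((3, 2, 3)) + [[0, 0, 0], [1, 0, 0]]
        edges = np.linspace(-1.0, 0.0, 11)
        rec = record_from_coords("HH", coords, energies=[-1.02, -1.24, -1.46])
        shifted = record_from_coords("HH", coords, energies=[-1.22, -1.44, -1.66])
        a = energy_per_electron_distribution([rec], edges=edges)[0]
        b = energy_per_electron_distribution([shifted], edges=edges + (-0.1))[0]
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_atomization_with_zero_table_is_raw_totals(self):
        rec = record_from_coords(
            "HH", np.zeros((2, 2, 3)) + [[0, 0, 0], [1, 0, 0]], energies=[-1.0, -1.2]
        )
        hist = atomization_energy_distribution([rec], AtomicEnergyTable({"H": 0.0}))
        assert hist.max_value == pytest.approx(-1.0)

    def test_bound_fixture_has_negative_max(self, nms_dataset):
        """Toy reference energies sit far below the sum of toy atomic
        energies, so every sampled conformer stays bound (max < 0 Ha)."""
        from nmsgen.toys import toy_atomic_energies

        hist = atomization_energy_distribution(
            read_ani_h5(nms_dataset[0]), toy_atomic_energies(), include_high_energy=True
        )
        assert hist.max_value < 0.0

    def test_single_conformer_occupies_one_bin(self):
        rec = record_from_coords("HH", [[0, 0, 0], [1, 0, 0]], energies=[-1.1])
        hist = atomization_energy_distribution([rec], AtomicEnergyTable({"H": -0.5}))
        assert hist.total == 1
        assert len(hist.support()) == 1
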