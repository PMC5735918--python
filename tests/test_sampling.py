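"""Thermal normal-mode displacement sampling: draws, magnitudes, windows."""
import decimal

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmsgen.calculators import Calculator
from nmsgen.errors import (
    CalculatorError,
    ImaginaryModeError,
    MoleculeError,
    ScheduleError,
    SinglePointFailure,
)
from nmsgen.molecules import CONSTANTS
from nmsgen.sampling import (
    ANI1_SCHEDULE,
    SamplingSchedule,
    conformer_count,
    displacement_magnitude,
    draw_mode_weights,
    draw_signs,
    generate_conformer,
    molecule_rng,
    sample_window,
    schedule_lookup,
)


class TestModeWeights:
    def test_single_mode_weight_in_unit_interval(self, rng):
        for _ in range(100):
            c = draw_mode_weights(1, rng)
            assert 0.0 <= c[0] <= 1.0

    @pytest.mark.parametrize("method", ["simplex", "rejection"])
    def test_sum_bounded_by_one(self, rng, method):
        for _ in range(200):
            c = draw_mode_weights(4, rng, method=method)
            assert np.all(c >= 0)
            assert c.sum() <= 1.0

    def test_zero_modes_rejected(self, rng):
        with pytest.raises(MoleculeError):
            draw_mode_weights(0, rng)

    def test_simplex_sum_mean_is_half(self):
        """Under the simplex scheme sum(c) is exactly Uniform[0,1]; the
        empirical mean over 1e5 draws must sit within 3 standard errors of
        1/2 (Monte-Carlo oracle)."""
        rng = np.random.default_rng(2024)
        n = 100_000
        sums = np.array([draw_mode_weights(5, rng).sum() for _ in range(n)])
        se = 1.0 / np.sqrt(12.0 * n)
        assert abs(sums.mean() - 0.5) < 3 * se


class TestSigns:
    def test_values_and_determinism(self):
        a = draw_signs(50, np.random.default_rng(7))
        b = draw_signs(50, np.random.default_rng(7))
        assert set(np.unique(a)) <= {-1.0, 1.0}
        np.testing.assert_array_equal(a, b)

    def test_fair_coin(self):
        """Fraction of +1 within 3 sigma of 1/2 over 1e5 draws (binomial)."""
        rng = np.random.default_rng(99)
        n = 100_000
        signs = draw_signs(n, rng)
        frac = np.mean(signs > 0)
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(n)


class TestDisplacementMagnitude:
    def test_zero_weight_gives_zero(self):
        assert displacement_magnitude(0.0, 3, 300.0, 0.5) == 0.0

    def test_scaling_laws(self):
        r = displacement_magnitude(0.2, 3, 300.0, 0.5)
        assert displacement_magnitude(0.2, 3, 600.0, 0.5) == pytest.approx(r * np.sqrt(2), rel=1e-12)
        assert displacement_magnitude(0.2, 3, 300.0, 2.0) == pytest.approx(r / 2, rel=1e-12)

    def test_closed_form_against_high_precision_arithmetic(self):
        """sqrt(3 * (1/3) * 3 * k_b * 300 / 0.5) evaluated with 50-digit
        decimal arithmetic as the independent oracle."""
        decimal.getcontext().prec = 50
        d = decimal.Decimal
        expected = (3 * (d(1) / 3) * 3 * d("3.166811563e-6") * 300 / d("0.5")).sqrt()
        got = displacement_magnitude(1.0 / 3.0, 3, 300.0, 0.5)
        assert got == pytest.approx(float(expected), rel=1e-12)

    def test_imaginary_force_constant_rejected(self):
        with pytest.raises(ImaginaryModeError):
            displacement_magnitude(0.5, 3, 300.0, -1.0)


class TestGenerateConformer:
    def test_energy_rise_matches_thermal_identity(self, library, rng):
        """On the matching quadratic surface, the energy above equilibrium of
        each draw is exactly (3/2) N_a k_b T sum(c) — the displacement law
        run backwards."""
        toy = library["water"]
        modes = toy.modes()
        calc = toy.harmonic_calculator()
        t = 500.0
        for _ in range(300):
            draw, geom = generate_conformer(modes, t, rng)
            e = calc.evaluate(geom.species, geom.coordinates)
            predicted = 1.5 * toy.molecule.n_atoms * CONSTANTS.k_b * t * draw.weights.sum()
            assert e - toy.reference_energy == pytest.approx(predicted, rel=1e-9)

    def test_displacement_is_signed_mode_superposition(self, library, rng):
        toy = library["co2"]
        modes = toy.modes()
        draw, geom = generate_conformer(modes, 300.0, rng)
        recon = sum(
            s * r * q for s, r, q in zip(draw.signs, draw.magnitudes, modes.modes)
        )
        np.testing.assert_allclose(draw.displacement, recon, atol=1e-12)
        np.testing.assert_allclose(
            geom.coordinates, toy.molecule.coordinates + draw.displacement, atol=1e-12
        )

    def test_sign_symmetry_of_mean_displacement(self, library):
        """Fair Bernoulli signs make the mean Cartesian displacement vanish
        componentwise (3 sigma band)."""
        toy = library["n2"]
        modes = toy.modes()
        rng = np.random.default_rng(5)
        n = 4000
        disps = np.array([generate_conformer(modes, 800.0, rng)[0].displacement for _ in range(n)])
        mean = disps.mean(axis=0)
        sigma = disps.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(mean) <= 3 * np.maximum(sigma, 1e-15))

    def test_higher_temperature_dominates_displacements(self, library):
        """Raising T scales each |R_i| by sqrt(T2/T1) draw-for-draw, so the
        magnitude distribution at higher T stochastically dominates."""
        toy = library["water"]
        modes = toy.modes()
        lo = [generate_conformer(modes, 300.0, np.random.default_rng(3))[0].magnitudes for _ in range(500)]
        hi = [generate_conformer(modes, 1200.0, np.random.default_rng(3))[0].magnitudes for _ in range(500)]
        np.testing.assert_allclose(np.array(hi), 2.0 * np.array(lo), rtol=1e-9)


class TestSchedule:
    @pytest.mark.parametrize("heavy,expected", [(8, (5, 450.0)), (1, (500, 2000.0)), (4, (400, 600.0))])
    def test_default_schedule_rows(self, heavy, expected):
        assert schedule_lookup(ANI1_SCHEDULE, heavy) == expected

    def test_missing_size_errors(self):
        with pytest.raises(ScheduleError):
            schedule_lookup(ANI1_SCHEDULE, 9)

    def test_invalid_rows_rejected(self):
        with pytest.raises(ScheduleError):
            SamplingSchedule(rows={1: (0, 300.0)})
        with pytest.raises(ScheduleError):
            SamplingSchedule(rows={1: (5, -1.0)})

    @pytest.mark.parametrize("s,dof,expected", [(5, 60, 300), (425, 3, 1275)])
    def test_conformer_count(self, s, dof, expected):
        assert conformer_count(s, dof) == expected

    def test_conformer_count_zero_dof_errors(self):
        with pytest.raises(MoleculeError):
            conformer_count(5, 0)


class _AlwaysFails(Calculator):
    name = "always-fails"

    def supports(self, species):
        return True

    def evaluate(self, species, coordinates):
        raise SinglePointFailure("synthetic SCF failure")


class _WrongSpecies(Calculator):
    name = "wrong-species"

    def supports(self, species):
        return False

    def evaluate(self, species, coordinates):  # pragma: no cover
        return 0.0


class TestSampleWindow:
    def test_harmonic_window_counts_and_nonnegative_rise(self, library, small_schedule):
        toy = library["water"]
        cs = sample_window(
            toy.molecule, toy.modes(), small_schedule, toy.harmonic_calculator(),
            molecule_rng(1, "water"),
        )
        assert len(cs.conformers) == 3 * 3  # S x dof
        assert cs.n_failed() == 0
        assert cs.equilibrium_energy == toy.reference_energy
        for c in cs.ok_conformers():
            assert c.energy >= toy.reference_energy  # quadratic form >= 0

    def test_always_failing_calculator_records_failures(self, library, small_schedule):
        toy = library["n2"]
        cs = sample_window(
            toy.molecule, toy.modes(), small_schedule, _AlwaysFails(), molecule_rng(1, "n2")
        )
        assert len(cs.ok_conformers()) == 0
        assert cs.n_failed() == 3 * 1
        assert cs.equilibrium_energy is None

    def test_unsupported_species_errors_before_sampling(self, library, small_schedule):
        toy = library["n2"]
        with pytest.raises(CalculatorError):
            sample_window(toy.molecule, toy.modes(), small_schedule, _WrongSpecies(),
                          molecule_rng(1, "n2"))

    def test_energy_bound_from_weight_construction(self, library, small_schedule):
        """sum(c) <= 1 caps any harmonic-surface conformer at
        E_eq + (3/2) N_a k_b T_max."""
        toy = library["methane"]
        cs = sample_window(
            toy.molecule, toy.modes(), small_schedule, toy.harmonic_calculator(),
            molecule_rng(2, "methane"),
        )
        _, t_max = schedule_lookup(small_schedule, 1)
        cap = toy.reference_energy + 1.5 * toy.molecule.n_atoms * CONSTANTS.k_b * t_max
        assert max(c.energy for c in cs.ok_conformers()) <= cap

    def test_seeded_determinism(self, library, small_schedule):
        toy = library["co2"]
        runs = []
        for _ in range(2):
            cs = sample_window(
                toy.molecule, toy.modes(), small_schedule, toy.harmonic_calculator(),
                molecule_rng(7, "co2"),
            )
            runs.append(cs)
        a, b = runs
        assert len(a.conformers) == len(b.conformers)
        for ca, cb in zip(a.conformers, b.conformers):
            np.testing.assert_array_equal(ca.coordinates, cb.coordinates)
            assert ca.energy == cb.energy

    def test_uniform_temperature_mode_is_seeded(self, library):
        toy = library["water"]
        schedule = SamplingSchedule(rows={1: (2, 400.0)}, temperature_mode="uniform_up_to_max")
        a = sample_window(toy.molecule, toy.modes(), schedule, toy.harmonic_calculator(),
                          molecule_rng(3, "w"))
        b = sample_window(toy.molecule, toy.modes(), schedule, toy.harmonic_calculator(),
                          molecule_rng(3, "w"))
        assert [c.energy for c in a.conformers] == [c.energy for c in b.conformers]
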