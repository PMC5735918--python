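# nmsgen

Tooling for building machine-learning-potential training data by **normal
mode sampling (NMS)**: generate thermally plausible off-equilibrium
conformers around optimized molecular geometries, curate them with an
energy window, store them in the ANI-style HDF5 record layout, and measure
how much conformational space the result actually covers.

It is aimed at people assembling reference datasets for neural-network
potentials who want the data-generation machinery — the sampler, the
bookkeeping, the file format, the coverage statistics — as reusable,
testable code with pluggable energy backends, rather than a pipeline welded
to one quantum-chemistry package. Analytic toy potentials (exact harmonic
surfaces and anharmonic Morse pair sums) make every stage runnable and
verifiable on a laptop; real electronic-structure energies plug in through
a small calculator contract (any executable that reads XYZ on stdin and
prints a Hartree energy).

## The method

For an energy-minimized molecule of `N_a` atoms, a vibrational analysis of
the Cartesian Hessian (mass-weighting, Eckart projection of the 3
translations and 2–3 rotations, diagonalization) yields `N_f = 3N_a − 6`
normal modes (`3N_a − 5` if linear), each stored here as a Cartesian
unit vector `q̂_i` with force constant `K_i = q̂_iᵀ H q̂_i` (Ha/Å²). One
conformer is drawn by:

1. drawing `N_f` nonnegative weights `c_i` with `Σ c_i ∈ [0, 1]`;
2. equating the harmonic energy of each mode to its share of the thermal
   energy of the system at temperature `T`, which gives the displacement

       R_i = ± sqrt(3 c_i N_a k_B T / K_i)

   with the sign drawn from a fair Bernoulli so both sides of each well are
   sampled;
3. displacing the equilibrium geometry by the superposition `Σ_i R_i q̂_i`
   and evaluating a single-point energy there.

`N = S × N_f` conformers are drawn per molecule, with `S` and the sampling
temperature taken from a per-molecule-size schedule (the schedule used for
the ANI-1 release ships as the default: `S` from 500 down to 5 and
temperatures from 2000 K down to 450 K as molecules grow from 1 to 8 heavy
atoms). Failed single-point evaluations are recorded and excluded.
Curation then splits each molecule's conformers at a fixed window —
275 kcal/mol above its lowest-energy conformer by default, boundary
inclusive — into the main (training) arrays and the high-energy
`…HE` arrays of the on-disk record.

On an exactly quadratic surface the energy rise of every draw equals
`(3/2) N_a k_B T Σc_i`, which the test suite verifies to ~1e-13 relative;
since `Σc_i ≤ 1`, no harmonic conformer can exceed
`E_eq + (3/2) N_a k_B T`.

## Worked example

```sh
nmsgen demo --seed 1 --out demo_out
```

builds the four-molecule toy library (N2-like diatomic, bent water-like,
linear CO2-like, tetrahedral methane-like — all with analytic Hessians),
samples each on an anharmonic Morse surface under the default schedule,
curates at 275 kcal/mol, and writes the dataset plus a bookkeeping table:

```
heavy_atoms  molecules  T_max  S    n_low  n_high  n_total
1            2          2000   500  5672   328     6000
2            1          1500   450  450    0       450
3            1          1000   425  1700   0       1700
total        4          -      -    7822   328     8150
```

Reading the table: the two 1-heavy-atom toys get `S = 500` draws per degree
of freedom at 2000 K (500×3 + 500×9 = 6000 conformers); at that temperature
the anharmonic surface pushes 328 of them beyond 275 kcal/mol of their
molecule's minimum, so they land in the high-energy (`coordinatesHE` /
`energiesHE`) arrays instead of the training arrays. The demo directory
also contains an equilibrium-only comparison dataset and TSV histograms
(O–H distances on the r/r0 axis, atomization energies) showing the NMS
data covering distance bins the equilibrium-only data never touches.

The same stages are available separately: `nmsgen sample` (XYZ + Hessian
directories → HDF5), `nmsgen curate`, `nmsgen summarize`, `nmsgen stats`,
`nmsgen convert`, or programmatically:

```python
from nmsgen import normal_mode_analysis, sample_window, ANI1_SCHEDULE
modes = normal_mode_analysis(molecule, hessian)       # Ha/Å² Hessian
window = sample_window(molecule, modes, ANI1_SCHEDULE, calculator, rng)
```

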