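# Methods

## Scope

`nmsgen` implements the data-generation and curation machinery around
normal-mode-sampled molecular datasets: vibrational analysis from a
Cartesian Hessian, thermal normal-mode displacement sampling, single-point
evaluation through a calculator contract, energy-window curation,
ANI-style HDF5 storage, bookkeeping summaries, and conformational-coverage
statistics. It deliberately does **not** perform geometry optimization or
any electronic-structure calculation: equilibrium geometries and Hessians
are inputs (plain-text files or the built-in analytic toys), and energies
come from whatever calculator is plugged in.

## Vibrational analysis and the force-constant convention

Given a symmetric Hessian `H` (Ha/Å²) at an equilibrium geometry, the
analysis mass-weights `H` with the shipped standard-atomic-weight table,
projects out the three translations and the two (linear) or three
infinitesimal rotations about the center of mass, diagonalizes the
projected matrix, and keeps the `N_f` largest-eigenvalue vibrational
modes, `N_f = 3N_a − 6` (`3N_a − 5` for linear geometries; linearity is
autodetected from the principal moments of inertia with a relative
tolerance of 1e-8, and can be forced).

The single most consequential convention in the package: each returned
mode `q̂_i` is unit-normalized in **plain Cartesian** space (not
mass-weighted), and its force constant is defined as the quadratic form
along that unit direction, `K_i = q̂_iᵀ H q̂_i`, in Ha/Å². Consequences:

* a displacement `x·q̂_i` on the quadratic surface costs exactly
  `½ K_i x²` — by construction, not approximation;
* because the `q̂_i` are un-mass-weighted eigenvectors of the mass-weighted
  Hessian, they are mutually `H`-orthogonal, so the identity extends to
  superpositions mode by mode;
* the displacement law `R_i = sqrt(3 c_i N_a k_B T / K_i)` is
  dimensionally closed with `R_i` in Å and no reduced-mass bookkeeping.

Other conventions exist (mass-reduced force constants over reduced masses,
as some quantum-chemistry codes print); externally computed modes and
constants in this package's convention can be ingested as a two-file pair.

Modes with non-positive curvature (saddle-point artifacts) abort the
analysis by default, since the displacement law is undefined for
`K_i ≤ 0`; `allow_imaginary=True` drops them with a warning and samples
the remaining real modes. Degenerate eigenvalue blocks are returned in a
deterministic order (ascending eigenvalue, first significant component of
each mode made positive) for reproducibility.

## The sampling draw

Mode weights: the constraint is `c_i ≥ 0`, `Σ c_i ∈ [0, 1]`. The default
scheme draws `N_f` i.i.d. uniforms, normalizes them to unit sum, and
scales by one extra independent uniform, making `Σc` exactly Uniform[0,1]
for any `N_f` and the weights exchangeable. An alternative
rejection scheme (redraw uniforms until the sum is ≤ 1, exactly uniform on
the corner of the cube) is provided, but its acceptance probability is
`1/N_f!`, so it is practical only for a handful of modes. The choice of
joint law matters only beyond the sum constraint and is a strategy switch.

Temperature: the per-size schedule stores a maximum temperature. The
default mode samples at exactly `T_max`; a `uniform_up_to_max` mode draws
a fresh `T ~ U(0, T_max]` per conformer. Both are seed-reproducible.

Randomness: one named generator per molecule, seeded from
(global seed, CRC-32 of the molecule id), so per-molecule output is
independent of processing order and byte-identical across runs.

The equilibrium geometry is stored alongside the sampled window but is not
counted within `N = S × N_f`. Note the published bookkeeping table this
package ships for reference has per-size totals that are *not* integer
multiples of `S × Σ N_f` under any obvious accounting; the package
reproduces the stated formula, not those historical counts.

## Calculators and failure semantics

A calculator maps (species, coordinates) → energy (Ha) deterministically
or raises a typed `SinglePointFailure`. Failures mirror SCF
non-convergence: the conformer is recorded with `energy_failed` status,
excluded from exported arrays, and never aborts the run (an unsupported
species, by contrast, errors before any sampling). The harmonic backend is
exact quadratic and never fails; the Morse pair-sum backend is anharmonic
— giving curated datasets a genuine high-energy tail — and optionally
fails below a clash radius (default 0.35 Å in the synthetic pipeline).
External programs attach via an XYZ-on-stdin / float-on-stdout contract
where a nonzero exit is a failure.

## Curation

The window is 275 kcal/mol above each molecule's lowest-energy conformer
(converted to Hartree internally; energies are Hartree everywhere between
I/O boundaries). The boundary is inclusive — exactly-at-threshold stays in
the low set — because only energies strictly greater than the window are
removed. The minimum is taken over the ok conformers and, by default, the
equilibrium energy (it is a conformer of the set); a switch excludes it.
Percentages are reported with half-even rounding, two decimals for failure
rates and one for the window share.

## Synthetic data: what the toys emulate and what they do not

The toy library ships four molecules with analytic Hessians: a homonuclear
N2-like diatomic (1 mode, closed-form `K = 2k` for a bond spring `k`), a
bent water-like triatomic (triangulated springs, 3 modes), a linear
CO2-like triatomic (4 modes, built spectrally on the exact complement of
the translation/rotation space because pair springs alone give no
transverse bend curvature), and a tetrahedral methane-like 5-atom molecule
(fully triangulated springs, 9 modes). Spring constants, geometries and
reference energies are chosen to be of realistic magnitude (bond force
constants ~0.7–1.2 Ha/Å², bond lengths ~1 Å, total energies ~−40 to −190
Ha) but are synthetic; so is the toy atomic-energy table. Their
heavy-atom counts (1, 2, 3) deliberately map onto rows of the default
sampling schedule.

What passing tests on these toys shows: the displacement law, its energy
identity and bound, the curation partition, the file format, and the
coverage statistics behave exactly as specified on surfaces where the
expected answers are known in closed form. What it does not show: anything
about real potential-energy surfaces — anharmonicity beyond a Morse pair
sum, mode coupling, reaction channels, or the chemistry of real
optimization failures.

## Numerical choices

* Frozen constants: `k_B = 3.166811563e-6` Ha/K,
  `1 Ha = 627.5094741` kcal/mol; element masses are IUPAC standard atomic
  weights (H 1.008, C 12.011, N 14.007, O 15.999, F 18.998), version-tagged.
* Hessian symmetry is enforced to 1e-8 relative; translation/rotation
  residual eigenvalues after projection are verified below 1e-6 of the
  largest vibrational eigenvalue on all shipped fixtures.
* The thermal-energy identity is asserted at 1e-9 relative on zero-offset
  harmonic surfaces. With a realistic ~1e2 Ha reference energy the
  subtraction `E − E_ref` carries ~1e-14 Ha of double-precision noise,
  which for draws with tiny `Σc` floors the measurable relative error near
  1e-8; removing the offset isolates the identity itself, which holds to
  ~1e-13.
* HDF5 storage: coordinates float32, energies float64 (kcal-scale windows
  on hundred-Hartree totals need 64-bit), species/SMILES fixed-length
  bytes, object timestamps disabled so equal inputs give byte-identical
  files. Group layout `gdb<heavy count, zero-padded>/mol<index>`; readers
  have a strict mode (error on malformed groups) and a lenient mode (skip
  and log) for foreign files.
* Histogram log series omit empty bins rather than clamping to −inf;
  distance histograms subsample with a seeded Bernoulli per observation.
* Bonded-angle selection uses a distance cutoff of 1.6 × r0 per arm;
  an all-triples mode exists. r0 values are user input (the package does
  not compute reference bond lengths).

## Problem sizes used in checks

Desk-scale by design: the identity check uses 10,000 draws across the four
toys, the energy bound 100,000 draws, the synthetic end-to-end pipeline
~8,000 conformers under the default schedule (or 510 under the reduced
30-draws-per-dof schedule the acceptance script uses for its Morse run).

## Known limitations

* The force-constant convention may differ per mode from datasets whose
  constants came from mass-reduced conventions; ingest such modes through
  the two-file path only after converting.
* The sampler assumes a trusted equilibrium: it never re-optimizes, and a
  poor input geometry simply shifts the whole window.
* Linearity detection is geometric; near-linear molecules close to the
  tolerance boundary should have the flag set explicitly.
* The lenient HDF5 reader is best-effort for foreign layouts; it expects
  the six-key record structure within one or two group levels.
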