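# Methods

## Lattice model of tetramer self-association (`thermo`)

The elementary unit is a 2:2 coiled-coil heterotetramer modelled as a square
building block; each of its four faces can bind a neighbour with contact
free energy ε (in kBT; negative = attractive). Mass action with a reference
concentration c0 links the two measured dissociation constants to (ε, c0):
k8 = c0·e^ε for the octamer (one contact) and k16 = c0³·e^{4ε} for the
hexadecamer (four contacts in a 2×2 square). The pair is unique in closed
form: c0 = k8⁴/k16, ε = ln(k8/c0). With the measured k8 = 370 μM and
k16 = 3.0×10⁻¹³ M³ this gives ε = −5.13 kBT and c0 = 62.5 mM (printed
elsewhere rounded to 63 mM; the difference is rounding of the inputs).

Species equilibria are solved from conservation in tetramer units,
c4 + 2c4²/k8 + 4c4⁴/k16 = total, which is strictly increasing in c4, so
bracketed bisection on [0, total] cannot fail; the relative tolerance is at
machine precision and conservation holds to better than 1e−10 relative.
The dodecamer (a linear trimer of tetramers, two contacts) follows as
c12 = c4³/k8². The saturation concentration balances the dilute chemical
potential ln(c4/c0) against the bulk value 2ε (each added tetramer
contributes two contacts): c_sat = c0·e^{2ε} = k16/k8², identically equal to
the stepwise octamer–octamer K_d.

Nucleation uses the free energy of square L×L assemblies,
G(L) = 2L(L−1)ε − L²·ln(c4/c0), evaluated at integer L only (the contact
count 2L(L−1) is a square-lattice identity; no continuous-L interpolation).
The concentration entering the entropy term is the **free** tetramer
concentration from the equilibrium solve, not the total loading: at 55 μM
total the free concentration (33 μM) reproduces the ≈10 kBT barrier, while
the total would give ≈8 kBT. Below saturation no finite barrier exists and
a flagged "not supersaturated" result is returned rather than an exception.

## Sedimentation-equilibrium simulator and global fitter (`sedeq`)

Each species adopts the exponential radial profile
c_i(r) = c_i(r0)·exp[σ_i(r²−r0²)/2] with σ_i = M_i(1−v̄ρ)ω²/(RT); the
reference radius r0 is the meniscus. Because oligomer masses are integer
multiples of the 51.8 kDa tetramer, mass-action links imposed at the
meniscus hold at every radius, so the full profile is determined by the free
tetramer meniscus concentration alone. That concentration is found by a
bracketed root solve of the sector-shaped conservation condition
⟨c_total⟩ = loading, where the sector average ∫c·r dr/∫r dr of each
exponential is available in closed form ((e^{σU}−1)/(σU), U = (b²−m²)/2);
numeric quadrature is used only as an independent oracle in the tests.
Default cell geometry: meniscus 6.9 cm, base 7.2 cm, 200 radial points;
12 mm pathlength below 50 μM loading, 3 mm above. Default conditions
v̄ = 0.73 mL/g, ρ = 1.02 g/mL, T = 277.15 K; extinction 30 000 M⁻¹cm⁻¹ per
tetramer at 280 nm, strictly proportional to stoichiometry (no
hypo-/hyperchromicity), with the 250 nm extinction expressed as a fitted
ratio.

The global fit minimizes summed squared absorbance residuals over the
model's log10 dissociation constants jointly across speeds, loadings and
wavelengths. Per-profile baselines and the 250 nm extinction ratio enter
the model linearly and are profiled out in closed form at every trial point
(variable projection), so the nonlinear search runs over one or two
parameters only; this is an exact reformulation of the full least-squares
problem, adopted for speed and robustness. Three starts spread ±2 log units
guard against local minima; box bounds of ±6 log units keep K positive and
finite. Reduced χ² uses n_obs − (n_K + n_baselines + 1) degrees of freedom.

F-statistic confidence limits follow the stepwise-scan procedure: the
chosen K is fixed on a 0.02-decade grid above and below the best fit, all
other parameters are refit at each step, and the interval bound is the
crossing of χ²_crit = χ²_min·(1 + F(level; 1, ν)/ν), refined by a bracketed
root solve once the grid brackets the crossing (linear interpolation on a
coarse grid badly underestimates the crossing of a locally quadratic
surface). The two sides are scanned independently, so asymmetric intervals
are preserved; a scan that reaches ±3 decades without crossing returns an
open-ended bound flagged as such. Model comparison fits each candidate
(discrete 1–2–n schemes, an isodesmic scheme with one stepwise K_d for
every addition truncated at 16-mers, or a single ideal species) and ranks
by reduced χ²; individual non-convergence is recorded, not fatal.

## MINFLUX localization pipeline (`minflux`)

Traces with fewer than 5 localizations are discarded (background
rejection; a trace of exactly 5 is kept). Each surviving trace is collapsed
to one molecule position by a photon-weighted mean per axis (weight =
localization photons / trace total photons); a zero-photon trace falls back
to the unweighted mean with a warning. One trace is treated as one molecule,
justified by the pore-complex control's 9 % overcount, which is surfaced
separately rather than merged spatially. Localization precision is the
median over traces of the per-trace per-axis sample standard deviations
averaged to one scalar (per-axis averaging, not 3D pooling, is the default
and a config option); single-localization traces are excluded.

The cylinder axis is the optical z-axis through the least-squares circle
fit of the molecule x–y coordinates (algebraic Kåsa seed, geometric
Gauss–Newton refinement). Outlier exclusion is a single pass: Tukey
whiskers (quartiles ± 1.5×IQR, linear-interpolation percentile convention)
on the radial distances and on z flag outliers, which are removed before
any summary statistic. Heights are measured from the median z of retained
molecules. The reported geometry uses the 5th–95th percentiles of the
retained distributions: diameter = 2 × mean radius, radial width =
r_p95 − r_p5, height = z_p95 − z_p5, shell volume = π(r_p95² − r_p5²) ×
height, and the in-shell molar concentration = count/(N_A·V). Note that on
a uniform wall the 5th–95th percentile span recovers 90 % of the true
width/height by construction. Fewer than 10 molecules sets a
low-confidence flag. Density rendering bins localizations into 0.5 nm
voxels and convolves with a normalized σ = 4 nm 3D Gaussian; the grid is
padded by the kernel support so total intensity is preserved. A full
384 nm cylinder at 0.5 nm voxels is memory-hungry (~10⁹ voxels); rendering
is intended for single structures or crops.

Labeling statistics for a two-site (dimer) reference structure: with
labeling fraction p = clusters/(sites), a fraction 1 − p² of clusters carry
one label, the expected trace count is clusters·(1 + p²), and the
overcount is the relative excess of observed traces.

## Synthetic data (`synthdata`)

`gen_cylinder_molecules` places molecules uniformly **in area** on the
annular shell (r² uniform between the wall radii — a physically uniform
shell), z uniform, angle uniform in WT mode. The defaults are the wild-type
architecture: 192 nm mid radius, 109 nm wall, 262 nm height, 500 molecules.
Note the mean radius of a uniform-in-area annulus, (2/3)(R_o³−R_i³)/
(R_o²−R_i²) ≈ 197 nm, sits slightly above the mid radius. "Clumped" mode
emulates the assembly-deficient mutant phenotype directionally — lower
density (0.5×), 1–2 von Mises angular lobes (κ = 8), and a broader
radial/axial spread (1.5×) — since no quantitative mutant geometry is
available; it is validated only by direction (lower in-shell concentration,
more outliers, angular concentration).

`gen_localization_traces` labels molecules with a configurable efficiency
(default 1.0; 0.21 mirrors the under-labeled control), gives each labeled
molecule 1 + Bernoulli(0.09) traces, draws 1 + Poisson(12) localizations
per trace (so real traces overwhelmingly pass the ≥5 filter), log-normal
photons (median 500), and isotropic 13 nm Gaussian position noise; the 50
default background traces are short by construction (1 + Poisson(1)) so
the length filter is the discriminator. `gen_sedeq_dataset` simulates the
usable experimental design — loadings 12.6/25/55 μM × speeds
7000/11000/20000 rpm × 280/250 nm — with i.i.d. Gaussian absorbance noise
(default 0.005 AU). `gen_mass_histogram` draws particles by species number
concentration with Gaussian mass error (default σ = 15 kDa); trimers of
tetramers are absent by construction of the three-species model. All
generators take an integer seed and are byte-deterministic.

## Problem sizes and numerical choices

Simulation studies in the tests use 80-point radial grids (the simulator
default is 200) and 20 seeds for parameter-recovery/coverage, and 100
seeded runs of 450-molecule cylinders for geometry recovery; these sizes
give stable aggregate statistics while keeping the suite quick. Bisection
and Brent solves run at relative tolerances near machine precision with
explicit tiny absolute tolerances (molar concentrations are ~1e−6, far
below default absolute tolerances). Degenerate inputs are handled
explicitly: zero loading returns zero concentrations; an all-identical
radius cloud collapses the whiskers and reports zero width and volume (and
zero concentration); a sub-saturation nucleation query returns a flagged
result.

## What the synthetic data does and does not show

The generators reproduce the statistical structure the estimators assume —
exponential equilibrium profiles with additive Gaussian noise, uniform
cylindrical shells with isotropic Gaussian localization error, short
background traces. They do not model instrument drift, fixation/linkage
error, dye photophysics beyond the two-level extra-trace model, optical
PSFs, aggregation at high loading (the fitter never models aggregates), or
hypo-/hyperchromic extinction effects. Passing recovery tests therefore
demonstrates correctness of the estimators under their stated assumptions,
not robustness of those assumptions on real data.
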