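# Methods

## System and model

The solute is dimethylphosphate (DMP), (CH₃O)₂PO₂⁻, in its
gauche-gauche conformer: the standard minimal model of the DNA backbone
phosphate. The geometry is rebuilt at load time from internal
coordinates (P–O(free) 1.48 Å with a 119.6° O–P–O angle, P–O(ester)
1.60 Å at 101°, O–CH₃ 1.42 Å at 118.5°, both C–O–P–O dihedrals +70°)
stored in `src/shellfield/data/dmp_gg.yaml`. The solute is perfectly
rigid and never moves.

**Stand-in charges.** The electrostatic-potential-derived DMP charges
used in the original field simulations are not published. The packaged
set (P +1.20, free O −0.85, ester O −0.50, united-atom CH₃ +0.25; net
−1 e enforced to 10⁻⁶ e) is a synthetic stand-in with generic
heavy-atom Lennard-Jones parameters, clearly marked in the parameter
file and replaceable by the user. Consequence: hydration structure and
absolute field magnitudes are qualitatively sensible (first-shell water
oxygens peak near 2.7 Å from the PO₂ oxygens; projected fields of tens
of MV/cm) but not quantitative.

Water is TIP5P: rigid 5-site, OH 0.9572 Å/104.52°, lone pairs 0.70 Å/
109.47°, q_H = +0.241 e, q_L = −0.241 e, LJ on oxygen only
(σ = 3.12 Å, ε = 0.66944 kJ/mol), from `data/tip5p.yaml`. A molecule is
stored as oxygen position + unit quaternion; all site positions derive
from the body-frame template, so rigidity is exact by construction.

## Configuration sampling

Equilibrium configurations come from single-molecule rigid-body
Metropolis Monte Carlo (the downstream analysis needs ensembles, not
dynamics — an MD integrator is deliberately out of scope). One "sweep"
is one attempted move: a uniform translation (default ±0.25 Å; the
shipped analysis configurations use ±0.3 Å) combined with a rotation
about a random axis (default ±0.35 rad), accepted with probability
min(1, e^(−ΔU/kT)). Energies are pairwise LJ + Coulomb over all charged
sites with Lorentz–Berthelot mixing for water–solute LJ. Two cell
types:

- **droplet** (default): hard wall on the oxygen position at radius R.
  No images, no cutoff. Default R = 14 Å with 250 waters (≥ 2 hydration
  layers); the test suite uses R = 7.6 Å with 60 waters (approximately
  bulk density).
- **cubic**: minimum-image convention applied per molecule pair (the
  image shift decided by the O–O displacement moves the whole partner
  molecule, keeping molecules intact) with a default 9 Å O–O cutoff
  (capped at half the edge). No Ewald summation; the truncation is a
  documented fidelity gap.

Seeds are mandatory (`MCParams.seed`); there is no hidden global random
state, and identical parameters give bit-identical trajectories. The
per-move energy runs through a numba-compiled kernel when numba is
importable, with a numerically equivalent numpy fallback; the
incremental energy bookkeeping is verified against full recomputation
to ~10⁻¹² kJ/mol.

The Metropolis driver itself is exposed (`sampler.metropolis`) and
verified on an isotropic harmonic well against the closed-form
Boltzmann statistics (per-axis variance kT/k within 5% at 10⁵ steps;
Kolmogorov–Smirnov distance to the exact Gaussian < 0.025 on thinned
samples).

**Equilibration at desk scale.** Liquid-water relaxation under
single-particle MC is slow: the first hydration shell of the anion
keeps filling for several thousand accepted moves per molecule at
298 K. The shipped analysis configurations therefore discard the first
50–60% of 6×10⁵–1.5×10⁶ moves and verify stationarity with a slope
test on ten block means of the total energy (slope consistent with
zero at 3 SE). These run lengths are the package's own desk-scale
choice, standing in for the production runs' 450 ps averaging window.

## Field evaluation

The probe is the midpoint of the free O1–O2 axis; the projection axis ê
runs from P through that midpoint into the solvent (the C2 axis of
PO₂⁻ for a symmetric geometry). Reported amplitudes are the signed
projection E∥ = **E**·ê in MV/cm; with this sign convention the shell
field at the anion is strongly negative. The conversion constant
(e/4πε₀)/Å² = 1439.96 MV/cm uses CODATA-2018 values and is pinned by an
independent hand-computed Coulomb oracle in the tests.

Sources are, by default, the TIP5P point charges of every water —
consistent with the sampler's energetics. Optional per-molecule point
dipoles and Buckingham traceless quadrupoles (body-frame, rotated with
each molecule, placed at the oxygen) can be loaded from a YAML file for
distributed-multipole-style evaluation; the fragment parameters of the
original study are not published, so none are shipped. No short-range
damping or polarization is applied (documented fidelity gap). The
solute's own charges never contribute. Kernels: q·R̂/r², (3(μ·R̂)R̂−μ)/r³,
and (5R̂(R̂·Θ·R̂)−2Θ·R̂)/r⁴ from the potential φ = (R·Θ·R)/r⁵; each is
tested against finite point-charge constructions, and frame evaluation
against a brute-force superposition loop at 10⁻⁹ MV/cm.

## Distributions and statistics

g(r) is the standard shell-volume-normalized pair histogram averaged
over frames, with the target density taken as the mean target count per
frame over the analysis volume; validated against a uniform ideal-gas
oracle (flat at 1 within 3σ Poisson bands). Field distributions are
normalized histograms of E∥ (default bin width 2 MV/cm — the published
figure does not state one) carrying bin-free mean and standard
deviation; occurrence differences require identical grids (no silent
rebinning), making the zero-sum invariant exact. The mean-field change
between temperatures carries a seeded bootstrap standard error (default
1000 resamples); block averaging utilities cover autocorrelation-aware
errors.

## Stark mapping

Δν = a·ΔE, exactly and with no hidden factors; a = 0.4 cm⁻¹/(MV/cm) is
shipped only for the symmetric PO₂ stretch (no reliable tuning rates
exist for the other backbone modes, and the CLI refuses to default
them). Band profiles default to Gaussian (the lineshapes are not
published); a pure shift yields the difference spectrum
ΔA(ν) = band(ν; ν₀+Δν) − band(ν; ν₀). The bleach/enhancement extrema
separation (parabolic refinement of grid extrema) approaches Δν only
for shifts large against the band width; for small shifts it saturates
at the width scale (2σ for a Gaussian) — the relation "separation ≈
shift" used when comparing to experiment is an approximation this
package exposes but does not assert.

## Kinetics

Model forms: A·e^(−t/τ) + C; A₁(1−e^(−t/τ₁)) + A₂(1−e^(−t/τ₂));
A₁e^(−t/τ₁) + A₂(1−e^(−t/τ₂)). Synthetic traces add i.i.d. Gaussian
noise (experimental floor 0.03 mOD) on 80 log-spaced delays 0.2–100 ps
(60 linear delays 0.2–8 ps for the direct-excitation decays). The fit
window starting at 0.2 ps sidesteps the coherent-artifact region;
analytic Gaussian-IRF convolution (FWHM 0.1 ps ≈ the instrument
response) is available but off by default, since the published fits are
plain exponentials. The amplitude ratio A₁/A₂ = 3 of the synthetic
biphasic traces is a declared choice (the underlying ratios are not
printed).

Fitting is scipy `least_squares` with bounds τ > 0; initial guesses
come from endpoint amplitudes and a log-linear tail regression,
overridable. Uncertainties are 1σ from the Jacobian-based covariance
scaled by residual variance; a Monte-Carlo calibration test holds the
reported 1σ within 30% of the empirical replicate scatter. For the
biphasic *rise* (exchangeable components) τ₁ < τ₂ is enforced by
post-hoc reordering; decay-plus-rise components are structurally
distinct and never swapped. Time constants within 10% of each other
flag the result ill-conditioned. Global fits share selected time
constants across traces with free per-trace amplitudes, stacking
residuals (delay grids need not match); pooling demonstrably reduces
the variance of the shared slow constant.

## Dosimetry

Photon energy hcν̃; the excited fraction divides photons by water
molecules in the flat-top cylinder (spot area × penetration depth).
Whether published excitation fractions count incident or absorbed
photons is rarely stated, so both conventions are implemented —
`absorbed_in_one_depth` multiplies incident photons by (1−1/e) and is
the default, reproducing ~3% for the solution sample. ΔT assumes one
OH-stretch quantum per excited molecule, fully thermalized in water
(C_p = 75.3 J mol⁻¹ K⁻¹ by default; no heat loss to solute or windows),
giving 21.9 K at a 4% fraction. Penetration depth 1/(ln10·ε·c); the two
published (depth, concentration) pairs invert to decadic absorptivities
agreeing within 1%, an internal-consistency check in the tests.

## What the synthetic generators do and do not emulate

The MC sampler emulates equilibrium hydration-shell configurations at
298–330 K; it does not emulate dynamics (no time correlation
functions), polarization, counterions (excluded by default, switchable
sources), or production-scale statistics. The kinetic trace generator
emulates the biphasic/mono-exponential signal structure and the
detector noise floor; it does not emulate coherent artifacts, spectral
overlap between bands, or correlated (1/f) noise. Passing tests
therefore demonstrate correct machinery and faithful arithmetic at the
published operating points — not that the stand-in charge set
reproduces the published absolute field scale (~90 MV/cm time-averaged
amplitudes, ~25 MV/cm differential extrema separation), which requires
the unpublished fragment parameters and full MD sampling.

At desk scale the two qualitative temperature trends (field
distribution broadening; first-layer depletion on heating) have effect
sizes at or below the run-to-run sampling noise; short runs are
additionally biased by the slower cold-shell equilibration, which can
transiently *reverse* the occupancy trend. The corresponding checks are
therefore one-sided significance tests on block statistics from paired
seeds (same initial configuration at both temperatures): the expected
direction must not be violated at 3σ. They document consistency with
the published direction, not an independent demonstration of it.

## Numerical choices

- Quaternions renormalized after every composed rotation; validated to
  10⁻⁹. Trajectory files store real atoms only (O, H1, H2 per water);
  lone pairs are rebuilt by Kabsch alignment on read.
- XYZ written at 10⁻⁶ Å (round-trips fields to 10⁻³ MV/cm); PDB at its
  format-fixed 10⁻³ Å (fields to ~10⁻² MV/cm).
- Coincident-site singularities raise typed errors rather than
  returning infinities; the MC move path converts them into move
  rejection.
- Degenerate inputs (empty frames, empty selections, mismatched
  histogram grids, monotone difference spectra, < 8-point traces) raise
  with specific messages; fit non-convergence is flagged on the result,
  never raised.
- All stochastic stages take explicit seeds; the pipeline derives stage
  seeds as global seed + fixed offsets and stamps every artifact with
  the config hash and seed.
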