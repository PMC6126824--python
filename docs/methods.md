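# Methods

This note records the statistical models behind each check, the defaults
and why they were chosen, what the synthetic fixtures do and do not
emulate, and the numerical choices that matter.

## Internal units

All quantities are converted to a single internal system at load time:
kJ/mol (energy), nm (length), nm³ (volume), bar (pressure), ps (time),
K (temperature), unified atomic mass units.  In these units
1 u·(nm/ps)² = 1 kJ/mol exactly, so kinetic energies carry no conversion
factor.  k_B = 0.008 314 462 618 kJ/mol/K; 1 bar·nm³ =
0.060 221 4076 kJ/mol (from the exact SI Avogadro constant).  Input unit
systems are multiplicative factors only; affine temperature scales
(Celsius, Fahrenheit) are out of scope.

## Decorrelation pipeline

Every statistical test assumes approximately independent frames.  The
shared pipeline is:

1. **Equilibration detection** — scan candidate truncation points over
   the first 90% of the series (≤100 candidates) and keep the start that
   maximizes the effective sample count n_eff = (n − start)/g of the
   retained tail.  This is the standard "maximize usable data" heuristic;
   no single canonical algorithm exists for this step, so ours is a
   documented choice.
2. **Statistical inefficiency** — g = 1 + 2·Σ_t (1 − t/n)·ρ̂(t), with the
   autocorrelation estimated by FFT and the sum truncated at the first
   non-positive ρ̂(t) (initial-positive-sequence style).  This truncation
   keeps the noisy large-lag tail out of the sum; g is clipped to ≥1 and
   is invariant under affine transforms of the series.
3. **Subsampling** — keep frames start, start+⌈g⌉, start+2⌈g⌉, …  The
   ceiling errs toward independence at the cost of a few frames.

Bootstrap standard errors use the simple iid bootstrap on the
decorrelated frames (200 resamples by default, the conventional count
for SE estimation).  A block bootstrap is unnecessary because
decorrelation happens first; this is the main assumption a caller must
respect when passing raw, correlated series with `--raw`.

## Kinetic-energy tests

With N kinetic degrees of freedom at temperature T, momentum components
are independent normals with variance m k_B T, so K ~ Gamma(N/2, k_B T).
As printed in many sources the moment relations drop a radical; the
dimensionally and distributionally consistent forms used here are

    μ = ½ N k_B T,      σ = √(N/2) k_B T,
    T(μ̂) = 2 μ̂/(N k_B),  T(σ̂) = √(2/N) σ̂/k_B.

Both follow directly from the gamma law and are verified by Monte Carlo
in the test suite.

*Strict test.*  One-sample Kolmogorov–Smirnov against the gamma CDF,
using the asymptotic Kolmogorov distribution for the p-value (series
lengths after decorrelation make small-sample corrections irrelevant).
The reference parameters come from the system (ndof) and the thermostat
target — never from the sample, which would invalidate the K-S null
distribution.

*Non-strict test.*  T(μ̂) and T(σ̂) with bootstrap SEs; the default
flagging tolerance is 3 SE (2–3 SE is the sensible range; 3 keeps the
false-positive rate per comparison near 0.3%).  The default ndof for a
periodic bulk system is 3N_atoms − 3, reflecting centre-of-mass motion
removal.

*Sensitivity.*  The strict test's power grows with sample count, with
the number of degrees of freedom, and with the relative temperature
offset.  `sensitivity_scan` maps mean p-values over a (sample size ×
generating temperature) grid so users can judge what deviation their
trajectory length can actually resolve.

## Equipartition decomposition

Per molecule, with positions unwrapped by minimum-image chaining along
the atom order (consecutive atoms are assumed bonded or at least closer
than half a box edge):

* K_trans = |Σ m_i v_i|²/(2M);
* K_rot = ½ ω·L, with L the angular momentum about the centre of mass
  and ω = I⁺L — the Moore–Penrose pseudo-inverse (singular values below
  10⁻¹⁰ of the largest treated as zero) handles monatomic and linear
  molecules without special cases;
* K_int = K_total − K_trans − K_rot (floored at −10⁻¹² relative for
  round-off).

This is the standard rigid-body construction.  Degree-of-freedom
accounting per molecule of n atoms with c constraints: 3 translational;
rotational 3 (2 if linear — smallest principal moment < 10⁻⁸ of the
largest on the first frame — and 0 if monatomic); internal
3n − trans − rot − c.  Constraints are subtracted from the internal
count only, because fixed bond lengths remove internal motion; a
constraint pattern that immobilizes rotational freedom instead is not
auto-detected and would need a hand-set ndof.  No centre-of-mass
reduction is applied to subsets: removing the global COM does not pin
the COM of a molecule group.

Groups may be the three components (default), explicit molecule sets, a
seeded random bipartition, or a spatial bipartition by first-frame COM
half-space.  The spatial split is static by design — per-frame
reassignment would make the group ndof a random variable.

## Ensemble checks

The log-ratio of configurational distributions between two state points
is linear in the observables with slopes a_E = β₂−β₁,
a_V = β₂P₂−β₁P₁, a_N = β₂μ₂−β₁μ₁ (energies in kJ/mol, volumes in nm³,
so a_V carries nm⁻³ with pressures converted from bar).  The fit is a
pooled logistic regression: which state point a sample came from is
logistic in the observables, with a free intercept absorbing the unknown
free-energy difference.  This is the standard unbinned realization of
the linear log-ratio; a binned log-ratio linear regression is kept in
the test suite as an independent cross-check and agrees to ~1% at large
n.

Numerics: features are centred and scaled internally; Newton iterations
with step halving on the exact log-likelihood; convergence at gradient
norm < 10⁻¹⁰, hard stop at 100 iterations; initialization at zero slope
and intercept log(n₂/n₁).  The analytic covariance is the inverse
Hessian at the optimum; bootstrap covariance resamples each side
independently (per-frame pairing of E and V within a side is kept
intact) and refits.  Samples must overlap: if less than 1% of either
sample lies inside the other's empirical range the fit aborts with a
pointer to the spacing heuristic, since a near-disjoint pair carries no
slope information.

Interval conversions: ΔT′ = a_E k_B T₁T₂ (≈ T₁−T₂),
ΔP′ = a_V k_B T for the single-temperature volume fit (exactly P₂−P₁ at
the true slope) and ΔP′ = a_V k_B (T₁+T₂)/2 for the two-parameter fit
(296.1 bar for 300/308 K and 1/301 bar — the mean-temperature
approximation, not exactly 300).  SEs propagate linearly.  The verdict
compares |estimate − truth|/SE against a 3σ default.

State-point spacing: the fit is most informative when the two
distributions sit roughly one combined standard deviation apart, giving
ΔT = 2 k_B T²/σ_E and ΔP = 2 k_B T/σ_V.  The widths can be measured
from one trajectory or taken from material properties via
σ_E² = 2 k_B T² C and σ_V² = 2 k_B T V κ_T.  These width formulas carry
a factor of 2 relative to the textbook fluctuation relations
(σ_E² = k_B T² C_V); both conventions appear in the literature, the
spacing rule is a heuristic either way, and `factor_two=False` selects
the no-2 convention rather than silently "correcting" either form.  The
grand-canonical mode is implemented for a single species; the printed
µVT relation is read symmetrically (µ₁ in the reference ensemble of the
denominator), the only reading that makes the ratio a function of both
chemical potentials.

Potential energy is the default observable rather than total energy:
the kinetic part is independent of the configurational observables (and
is tested more rigorously on its own), while using E can mask
compensating kinetic/potential errors.  The equivalence of the two
choices on well-behaved data is a tested invariant.

## Integrator convergence

RMSD of the total energy about its mean, compared across runs at
different timesteps saved at a common interval; adjacent-pair ratios are
judged against (Δt₁/Δt₂)² with a default relative tolerance of 0.3 —
wide enough for the noise of picosecond-scale runs, far tighter than the
order-of-magnitude violations that discontinuous cutoffs produce.  The
least-squares drift rate is always reported (fluctuations should exceed
total drift by orders of magnitude for the comparison to be meaningful);
detrending before the RMSD is off by default, appropriate for short
runs, and available as `remove-linear` for long ones.

## Toy MD engine and samplers

The LJ fluid defaults are argon-like (σ = 0.3345 nm,
ε = 1.045128 kJ/mol, m = 39.948 u) at reduced density 0.8 and reduced
temperature 1.0 (125.707 K), cutoff 1 nm with force-switching from
0.8 nm.  216 particles is the smallest cube number whose box
(2.162 nm at ρ* = 0.8) keeps the 1 nm cutoff under half the box edge for
the minimum-image convention; it also keeps a full convergence check
under ~15 s on one core.  Pair interactions are brute-force O(n²) —
adequate at this scale, and free of pairlist-buffer artifacts by
construction.

Cutoff schemes: `simple` truncates (discontinuous U and F), `shift`
zeroes the potential at r_c (force untouched, still discontinuous),
`switch` multiplies the force by the descending C¹ smoothstep
1 − 3x² + 2x³ on [r_switch, r_c] and integrates the switched force
analytically for the potential, so U and F both vanish continuously at
r_c.  Any C¹ force-switch with F(r_c) = 0 serves the purpose of the
convergence test; this polynomial is the simplest such choice.

Thermostats: `weak-coupling` is Berendsen velocity scaling
λ = √(1 + Δt/τ (T₀/T − 1)) — correct mean, suppressed fluctuations, the
canonical negative control; `velocity-rescale` is the exact stochastic
kinetic-energy rescaling whose stationary kinetic distribution is the
canonical gamma; `maxwell-resample` redraws all velocities from the
Maxwell distribution every τ (with COM removal), making recorded frames
at redraw steps *exactly* canonical — the trusted reference in tests.

The flexible-molecule gas builds harmonic-bond/angle chains with no
intermolecular forces (the regime where equipartition artifacts are
starkest, since nothing re-thermalizes decoupled degrees of freedom).
Its `rescale-kick` thermostat — a global COM velocity kick followed by
uniform rescaling to the exact target kinetic energy each step — is a
deliberately broken scheme constructed to reproduce the flying-ice-cube
signature.  Two competing effects act: the exact-rescale dynamics itself
redistributes energy among components during an initial transient, and
the kick steadily pumps translational energy.  The default kick speed
(0.01 nm/ps per step) makes the injection dominate within a few
thousand steps, after which translation runs hot and internal motion
cold, monotonically.  Fixture tests therefore compare early and late
time windows rather than assuming stationarity.

### What the fixtures do and do not emulate

The samplers are *exact*: gamma kinetic energies and Gaussian
density-of-states potential energies realize the tested distributions
and the linear log-ratio identically, so test passes on them verify the
statistics, not the physics of any real system.  The toy LJ fluid adds
real (if miniature) dynamics: anharmonic forces, kinetic–potential
exchange, genuine integrator error.  None of the fixtures include
electrostatics, constraints, barostats, or the system sizes and
correlation times of production simulations — a pass on these fixtures
validates the checks' logic and calibration, not the behavior of any
particular MD package.  NPT-style volume series for the pressure checks
come from the Gaussian sampler, not from a barostatted run.

## Problem sizes and reproducibility

Default analysis sizes (216 LJ particles, 1–4 ps convergence runs,
10⁴ samples per side for ensemble fits, 100-seed repeat studies,
200 bootstrap resamples) were chosen so that every statistical
conclusion is comfortably resolved — coverage studies at the 95% level,
type-I-rate checks at ±1.5% over 1000 repeats — while a full run of the
suite stays in the minutes range on a single core.  All stochastic
components take either an integer seed or a numpy Generator; fixed seeds
give bit-identical results, including the CLI's JSON reports.

## Known limitations

* Flat ASCII files are the only external format; binary trajectory
  formats of specific MD packages are out of scope.
* Isotropic pressure only; anisotropic barostats have no unambiguous
  published distribution to test against.
* The equipartition unwrap assumes consecutive atoms in a molecule are
  near-bonded; exotic atom orderings need pre-unwrapped input.
* Kinetic-energy estimators that correct for finite-timestep effects are
  not implemented; all checks are valid up to the numerical error of the
  plain ½mv² estimator.
* The grand-canonical mode handles one species; the multi-species
  generalization is a documented extension point in the fit's design
  (one slope per species).
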