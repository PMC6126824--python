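# simval

Physical-validity checks for molecular simulation trajectories.

A molecular dynamics (MD) or Monte Carlo run can be numerically flawless
and still sample the wrong ensemble: a thermostat that suppresses
fluctuations, a cutoff scheme that breaks energy conservation, a
velocity-scaling scheme that silently freezes internal motion ("flying
ice cube").  `simval` implements post-hoc statistical checks for these
failure modes, aimed at users of MD codes who want to validate their
setup, and at developers who want physical sanity checks in CI.

## What it checks

**Kinetic-energy ensemble.**  At temperature *T* with *N* kinetic degrees
of freedom, equilibrium statistical mechanics fixes the kinetic-energy
distribution exactly:

    K ~ Gamma(shape = N/2, scale = k_B T),
    ⟨K⟩ = ½ N k_B T,   σ(K) = √(N/2) k_B T.

The *strict* test is a one-sample Kolmogorov–Smirnov comparison against
this law (parameters taken from the system and thermostat target — never
fitted to the data).  The *non-strict* test maps the sample moments to
equivalent temperatures, T(μ̂) = 2μ̂/(N k_B) and T(σ̂) = √(2/N) σ̂/k_B,
with bootstrap standard errors; deviations beyond ~3 SE are flagged.
Both tests apply to any subset of degrees of freedom (equipartition), and
`simval` decomposes per-molecule kinetic energy into translational,
rotational and internal parts to catch inter-component energy leaks.

**Configurational ensemble.**  The distributions of potential energy *U*,
volume *V* or particle number are unknown, but their *ratio* between two
state points is not — the density of states cancels:

    log [P(U|β₂) / P(U|β₁)] = c − (β₂−β₁) U          (NVT)
    log [P(U,V|β₂,P₂) / P(U,V|β₁,P₁)]
        = c − (β₂−β₁) U − (β₂P₂−β₁P₁) V              (NPT)

`simval` estimates the slope(s) by a pooled logistic maximum-likelihood
fit and converts them to interval estimates ΔT′ = a_E k_B T₁T₂ and
ΔP′ = a_V k_B T (or a_V k_B (T₁+T₂)/2 for the two-parameter fit), judged
against the true interval in standard-error units.

**Integrator quality.**  A symplectic integrator conserves a shadow
Hamiltonian; the total energy fluctuates about its mean with amplitude
∝ Δt².  Comparing paired runs, σ(H(Δt₁))/σ(H(Δt₂)) must equal
(Δt₁/Δt₂)² — halving the timestep must quarter the RMSD.  Discontinuous
potentials or forces (e.g. plain cutoffs) break this scaling visibly.

**Fixtures with known truth.**  A toy Lennard-Jones engine (three cutoff
schemes, velocity-Verlet/leapfrog, Berendsen-style weak coupling,
stochastic velocity-rescale, Maxwell-resample thermostats) and exact
samplers (gamma kinetic energies, Gaussian density-of-states potential
energies) generate every input the checks need — no external simulation
software required.

## Worked example

Validate the kinetic-energy ensemble of a toy LJ run whose weak-coupling
thermostat (strong coupling, τ = 0.02 ps) suppresses fluctuations:

```python
from simval import (ToyMDConfig, run_md, decorrelate,
                    kinetic_reference, ks_test_kinetic, mean_std_test)

cfg = ToyMDConfig(thermostat="weak-coupling", tau_t=0.02, dt=0.004,
                  n_steps=4000, output_stride=5, seed=42,
                  record_phase_space=False)
obs, _ = run_md(cfg)
K, info = decorrelate(obs.kinetic_energy)
ref = kinetic_reference(ndof=3 * cfg.n_particles - 3,
                        temperature=cfg.temperature)
print(f"strict K-S p-value:  {ks_test_kinetic(K, ref):.3g}")
print(mean_std_test(K, ref, seed=0))
```

Output:

```
strict K-S p-value:  1.75e-23
T(mean)  =   125.690 +- 0.080 K (0.1 SE from target 125.7 K)
T(sigma) =    20.769 +- 0.995 K (105.4 SE from target)
verdict: FAIL (tolerance 3 SE)
```

The mean temperature is perfect — a thermometer would see nothing wrong —
but the distribution is far too narrow (width equivalent to ~21 K instead
of 125.7 K), so the run is not canonical.  The same checks are available
from the shell:

```bash
simval kinetic run.obs --ndof 645 --temperature 125.707 --strict
simval ensemble run1.obs run2.obs --t1 300 --t2 308
simval integrator run_dt4.obs run_dt2.obs --dt 0.004 --dt 0.002
simval equipartition --positions run.pos --velocities run.vel \
       --topology topo.yaml --temperature 300
simval toy-md config.yaml --out run
```

Exit code 0 means all checks passed, 1 a failed check, 2 a usage error.

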