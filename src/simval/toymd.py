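"""Toy molecular-dynamics engine and exact statistical samplers.

Everything the validation checks need as input can be generated here,
with known ground truth:

* a minimal Lennard-Jones NVE/NVT engine (velocity-Verlet or leapfrog,
  minimum-image periodic boundaries, brute-force pair loop) with three
  interaction-cutoff schemes — ``simple`` (plain truncation:
  discontinuous potential and force), ``shift`` (potential shifted to
  zero at the cutoff: continuous potential, discontinuous force) and
  ``switch`` (force smoothly switched to zero over a buffer region:
  both continuous) — the canonical way to exercise the integrator
  convergence test;
* thermostats with known kinetic-energy statistics: ``weak-coupling``
  (Berendsen scaling — correct mean, suppressed fluctuations, not
  canonical), ``velocity-rescale`` (stochastic kinetic-energy rescaling
  with the canonical gamma target) and ``maxwell-resample`` (periodic
  full velocity redraw — exactly canonical kinetic marginal, the trusted
  reference);
* exact samplers: iid gamma kinetic energies, and a Gaussian
  density-of-states potential-energy sampler whose two-temperature
  log-density ratio is linear in the energy *by construction* — the
  ground truth for the ensemble slope fit;
* a flexible-molecule ideal gas (harmonic bonds/angles, no
  intermolecular forces) for equipartition checks, including a
  deliberately broken scale-plus-kick thermostat that reproduces the
  flying-ice-cube artifact.

Default Lennard-Jones parameters are argon-like (sigma = 0.3345 nm,
epsilon = 1.045128 kJ/mol) at reduced density 0.8 and reduced
temperature 1.0; the default particle count (216) keeps the box edge
above twice the 1 nm cutoff while remaining cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB
from .data import ObservableTrajectory, PhaseSpaceTrajectory, SystemInfo

CUTOFF_SCHEMES = ("simple", "shift", "switch")
INTEGRATORS = ("velocity-verlet", "leapfrog")
THERMOSTATS = ("none", "weak-coupling", "velocity-rescale", "maxwell-resample")

ARGON_SIGMA = 0.3345  # nm
ARGON_EPSILON = 1.045128  # kJ/mol
ARGON_MASS = 39.948  # u
ARGON_T_STAR_1 = ARGON_EPSILON / KB  # 125.707 K at reduced temperature 1


# ---------------------------------------------------------------------------
# pair interaction
# ---------------------------------------------------------------------------


from functools import lru_cache


@lru_cache(maxsize=32)
def _switch_coefficients(r_switch: float, r_c: float) -> tuple[float, ...]:
    """Coefficients (in powers of r) of the descending C^1 smoothstep.

    s(r) = 1 - 3 x^2 + 2 x^3 with x = (r - r_switch)/(r_c - r_switch);
    s(r_switch) = 1, s(r_c) = 0, s' = 0 at both ends.
    """
    w = r_c - r_switch
    x = np.polynomial.Polynomial([-r_switch / w, 1.0 / w])
    s = 1.0 - 3.0 * x**2 + 2.0 * x**3
    return tuple(s.coef)  # length 4, powers 0..3


def lj_pair_interaction(
    r: np.ndarray | float,
    sigma: float,
    epsilon: float,
    scheme: str = "switch",
    r_c: float = 1.0,
    r_switch: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair potential (kJ/mol) and force magnitude (kJ/mol/nm) at distance r.

    The force magnitude is along -dU/dr (positive = repulsive).  Beyond
    ``r_c`` both are zero.  ``switch`` multiplies the force by a C^1
    polynomial on [r_switch, r_c] and obtains the potential by exact
    integration of the switched force, so the potential and force both
    reach zero continuously at the cutoff.
    """
    if scheme not in CUTOFF_SCHEMES:
        raise ValueError(f"unknown cutoff scheme {scheme!r}")
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")

    A = 48.0 * epsilon * sigma**12
    B = 24.0 * epsilon * sigma**6

    def u_lj(x):
        inv2 = (sigma / x) ** 2
        sr6 = inv2 * inv2 * inv2
        return 4.0 * epsilon * (sr6 * sr6 - sr6)

    def f_lj(x):
        # A/r^13 - B/r^7 via multiplication chains
        inv = 1.0 / x
        inv2 = inv * inv
        inv6 = inv2 * inv2 * inv2
        return inv * inv6 * (A * inv6 - B)

    inside = r < r_c
    u = np.zeros_like(r)
    f = np.zeros_like(r)

    if scheme == "simple":
        u[inside] = u_lj(r[inside])
        f[inside] = f_lj(r[inside])
    elif scheme == "shift":
        u[inside] = u_lj(r[inside]) - u_lj(np.asarray(r_c))
        f[inside] = f_lj(r[inside])
    else:  # switch
        if not (0 < r_switch < r_c):
            raise ValueError("need 0 < r_switch < r_c for the switch scheme")
        coef = _switch_coefficients(r_switch, r_c)

        def g(x):
            """Antiderivative of the switched force."""
            x = np.asarray(x, dtype=float)
            inv = 1.0 / x
            inv2 = inv * inv
            inv6 = inv2 * inv2 * inv2
            inv12 = inv6 * inv6
            total = np.zeros_like(x)
            rk = np.ones_like(x)  # x**k
            for k, c in enumerate(coef):
                total += c * (A * inv12 * rk / (k - 12) - B * inv6 * rk / (k - 6))
                rk = rk * x
            return total

        u_switch_at_r1 = float(g(r_c) - g(r_switch))
        core = r < r_switch
        buf = inside & ~core
        u[core] = u_lj(r[core]) - u_lj(np.asarray(r_switch)) + u_switch_at_r1
        f[core] = f_lj(r[core])
        if np.any(buf):
            rb = r[buf]
            s = sum(c * rb**k for k, c in enumerate(coef))
            f[buf] = f_lj(rb) * s
            u[buf] = g(r_c) - g(rb)
    return u, f


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ToyMDConfig:
    """Complete, reproducible specification of a toy LJ simulation."""

    n_particles: int = 216
    mass: float = ARGON_MASS
    sigma: float = ARGON_SIGMA
    epsilon: float = ARGON_EPSILON
    box: float | None = None  #: cubic box edge (nm); default from density
    reduced_density: float = 0.8
    cutoff_scheme: str = "switch"
    r_c: float = 1.0
    r_switch: float = 0.8
    integrator: str = "velocity-verlet"
    dt: float = 0.002  # ps
    thermostat: str = "none"
    temperature: float = ARGON_T_STAR_1  # K
    tau_t: float = 0.1  # ps
    n_steps: int = 1000
    output_stride: int = 2
    seed: int = 0
    record_phase_space: bool = True
    initial_positions: np.ndarray | None = None
    initial_velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.box is None:
            self.box = float(
                self.sigma * (self.n_particles / self.reduced_density) ** (1 / 3)
            )
        if not (0 < self.r_switch < self.r_c):
            raise ValueError("need 0 < r_switch < r_c")
        if self.r_c >= self.box / 2:
            raise ValueError(
                f"cutoff {self.r_c} nm exceeds half the box edge "
                f"({self.box / 2:.4g} nm); minimum image breaks down"
            )
        if self.dt <= 0:
            raise ValueError("timestep must be positive")
        if self.thermostat not in THERMOSTATS:
            raise ValueError(f"unknown thermostat {self.thermostat!r}")
        if self.integrator not in INTEGRATORS:
            raise ValueError(f"unknown integrator {self.integrator!r}")
        if self.thermostat != "none" and self.tau_t <= 0:
            raise ValueError("coupling time must be positive")


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def maxwell_velocities(
    masses: np.ndarray,
    temperature: float,
    seed: int | np.random.Generator | None = None,
    remove_com: bool = False,
) -> np.ndarray:
    """Maxwell-Boltzmann velocity draw: each component ~ N(0, kB T / m).

    With ``remove_com`` the total momentum is zeroed afterwards (the
    kinetic energy then has 3N-3 degrees of freedom).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    m = np.asarray(masses, dtype=float).reshape(-1)
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(len(m), 3)) * np.sqrt(KB * temperature / m)[:, None]
    if remove_com:
        v -= (m[:, None] * v).sum(axis=0) / m.sum()
    return v


def gamma_kinetic_sampler(
    ndof: float,
    temperature: float,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """iid kinetic energies from the exact Gamma(N/2, kB T) law."""
    if ndof < 1 or temperature <= 0 or n < 1:
        raise ValueError("need ndof >= 1, temperature > 0, n >= 1")
    rng = np.random.default_rng(seed)
    return rng.gamma(shape=ndof / 2.0, scale=KB * temperature, size=n)


def gaussian_dos_sampler(
    s: float,
    a: float,
    beta: float,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Canonical potential energies for a Gaussian density of states.

    With log Omega(U) = a U - U^2/(2 s^2) + const, the canonical
    distribution at inverse temperature beta is exactly
    N(mean = s^2 (a - beta), sd = s).  Two samples drawn at beta1 and
    beta2 therefore satisfy the linear log-ratio relation with slope
    -(beta2 - beta1) *exactly*, making this the ground-truth fixture for
    the ensemble slope fit.
    """
    if s <= 0:
        raise ValueError("energy width s must be positive")
    rng = np.random.default_rng(seed)
    return rng.normal(loc=s**2 * (a - beta), scale=s, size=n)


# ---------------------------------------------------------------------------
# LJ engine
# ---------------------------------------------------------------------------


def _lattice_positions(n: int, box: float) -> np.ndarray:
    """Simple cubic lattice filling the box."""
    per_edge = int(np.ceil(n ** (1 / 3) - 1e-9))
    grid = (np.arange(per_edge) + 0.5) * (box / per_edge)
    pts = np.array(np.meshgrid(grid, grid, grid, indexing="ij")).reshape(3, -1).T
    return pts[:n].copy()


class _LJForces:
    """Brute-force minimum-image pair forces for a cubic box."""

    def __init__(self, cfg: ToyMDConfig):
        self.cfg = cfg
        self.ii, self.jj = np.triu_indices(cfg.n_particles, 1)

    def __call__(self, pos: np.ndarray) -> tuple[np.ndarray, float]:
        cfg = self.cfg
        d = pos[self.ii] - pos[self.jj]
        d -= cfg.box * np.round(d / cfg.box)
        r = np.sqrt(np.sum(d * d, axis=1))
        u, fmag = lj_pair_interaction(
            r, cfg.sigma, cfg.epsilon, cfg.cutoff_scheme, cfg.r_c, cfg.r_switch
        )
        if not np.all(np.isfinite(fmag)):
            raise RuntimeError("non-finite force (particle overlap?)")
        fvec = (fmag / r)[:, None] * d
        n = len(pos)
        forces = np.stack(
            [
                np.bincount(self.ii, weights=fvec[:, k], minlength=n)
                - np.bincount(self.jj, weights=fvec[:, k], minlength=n)
                for k in range(3)
            ],
            axis=1,
        )
        return forces, float(u.sum())


def _bussi_rescale_factor(
    K: float, K_target: float, ndof: float, dt_over_tau: float,
    rng: np.random.Generator,
) -> float:
    """Stochastic velocity-rescale factor with the canonical K distribution.

    Exact propagation of the kinetic-energy Ornstein-Uhlenbeck-like
    process: relaxes <K> toward the target while injecting exactly the
    noise needed for the stationary distribution to be Gamma(N/2, kB T).
    """
    c = np.exp(-dt_over_tau)
    r1 = rng.normal()
    # sum of squares of the remaining ndof-1 standard normals
    s = 2.0 * rng.gamma(shape=(ndof - 1) / 2.0) if ndof > 1 else 0.0
    kt = K_target / ndof
    alpha2 = (
        c
        + (1.0 - c) * kt / K * (r1**2 + s)
        + 2.0 * r1 * np.sqrt(c * (1.0 - c) * kt / K)
    )
    return float(np.sqrt(max(alpha2, 0.0)))


def run_md(
    config: ToyMDConfig,
) -> tuple[ObservableTrajectory, PhaseSpaceTrajectory | None]:
    """Run the toy LJ simulation; deterministic under the config seed.

    Returns the observable trajectory (kinetic/potential/total energy and
    instantaneous temperature at the output stride) and, unless disabled,
    the phase-space trajectory at the same stride.  The final frame of
    the phase-space trajectory can seed a follow-up run (paired-timestep
    protocols restart both runs from one equilibrated state).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    m = np.full(cfg.n_particles, cfg.mass)
    ndof = 3 * cfg.n_particles - 3  # COM momentum removed

    if cfg.initial_positions is not None:
        pos = np.array(cfg.initial_positions, dtype=float)
    else:
        pos = _lattice_positions(cfg.n_particles, cfg.box)
    if cfg.initial_velocities is not None:
        vel = np.array(cfg.initial_velocities, dtype=float)
    else:
        vel = maxwell_velocities(m, cfg.temperature, rng, remove_com=True)

    forces_of = _LJForces(cfg)
    f, u = forces_of(pos)
    dt = cfg.dt
    inv_m = 1.0 / m[:, None]
    k_target = 0.5 * ndof * KB * cfg.temperature
    resample_every = max(1, int(round(cfg.tau_t / dt)))

    n_out = cfg.n_steps // cfg.output_stride
    obs = {
        "time": np.empty(n_out),
        "kin": np.empty(n_out),
        "pot": np.empty(n_out),
    }
    if cfg.record_phase_space:
        rec_pos = np.empty((n_out, cfg.n_particles, 3))
        rec_vel = np.empty((n_out, cfg.n_particles, 3))

    vel_half_prev = None
    if cfg.integrator == "leapfrog":
        # seed the half-step velocity with a backward half-kick
        vel_half_prev = vel - 0.5 * dt * f * inv_m

    out = 0
    for step in range(1, cfg.n_steps + 1):
        if cfg.integrator == "velocity-verlet":
            vel += 0.5 * dt * f * inv_m
            pos += dt * vel
            try:
                f, u = forces_of(pos)
            except RuntimeError as exc:
                raise RuntimeError(f"{exc} at step {step}") from exc
            vel += 0.5 * dt * f * inv_m
        else:  # leapfrog
            vel_half = vel_half_prev + dt * f * inv_m
            pos += dt * vel_half
            vel = 0.5 * (vel_half_prev + vel_half)  # on-step estimate
            try:
                f, u = forces_of(pos)
            except RuntimeError as exc:
                raise RuntimeError(f"{exc} at step {step}") from exc
            vel_half_prev = vel_half

        k = 0.5 * float(np.sum(m[:, None] * vel**2))

        if cfg.thermostat == "weak-coupling":
            t_inst = 2.0 * k / (ndof * KB)
            lam = np.sqrt(
                max(1.0 + dt / cfg.tau_t * (cfg.temperature / t_inst - 1.0), 0.0)
            )
            vel *= lam
        elif cfg.thermostat == "velocity-rescale":
            alpha = _bussi_rescale_factor(k, k_target, ndof, dt / cfg.tau_t, rng)
            vel *= alpha
        elif cfg.thermostat == "maxwell-resample" and step % resample_every == 0:
            vel = maxwell_velocities(m, cfg.temperature, rng, remove_com=True)
        if cfg.thermostat != "none":
            k = 0.5 * float(np.sum(m[:, None] * vel**2))
            if cfg.integrator == "leapfrog":
                # re-derive the half-step velocity after the velocity update
                vel_half_prev = vel + 0.5 * dt * f * inv_m

        if step % cfg.output_stride == 0:
            obs["time"][out] = step * dt
            obs["kin"][out] = k
            obs["pot"][out] = u
            if cfg.record_phase_space:
                rec_pos[out] = pos
                rec_vel[out] = vel
            out += 1

    traj = ObservableTrajectory(
        time=obs["time"],
        kinetic_energy=obs["kin"],
        potential_energy=obs["pot"],
        total_energy=obs["kin"] + obs["pot"],
        temperature=2.0 * obs["kin"] / (ndof * KB),
    )
    phase = None
    if cfg.record_phase_space:
        box = np.tile([cfg.box, cfg.box, cfg.box], (n_out, 1))
        phase = PhaseSpaceTrajectory(rec_pos, rec_vel, box)
    return traj, phase


# ---------------------------------------------------------------------------
# flexible-molecule ideal gas
# ---------------------------------------------------------------------------

GAS_THERMOSTATS = ("maxwell-resample", "rescale-kick", "none")


def _molecule_forces(
    pos: np.ndarray,
    bonds: np.ndarray,
    angles: np.ndarray,
    bond_k: float,
    bond_r0: float,
    angle_k: float,
    angle_theta0: float,
) -> tuple[np.ndarray, float]:
    """Harmonic bond + angle forces; no intermolecular terms."""
    forces = np.zeros_like(pos)
    u = 0.0
    if len(bonds):
        d = pos[bonds[:, 1]] - pos[bonds[:, 0]]
        r = np.linalg.norm(d, axis=1)
        u += 0.5 * bond_k * float(np.sum((r - bond_r0) ** 2))
        fmag = -bond_k * (r - bond_r0)
        fvec = (fmag / r)[:, None] * d
        np.add.at(forces, bonds[:, 1], fvec)
        np.add.at(forces, bonds[:, 0], -fvec)
    if len(angles):
        ri = pos[angles[:, 0]] - pos[angles[:, 1]]
        rk = pos[angles[:, 2]] - pos[angles[:, 1]]
        ni = np.linalg.norm(ri, axis=1)
        nk = np.linalg.norm(rk, axis=1)
        cos_t = np.clip(np.sum(ri * rk, axis=1) / (ni * nk), -1.0, 1.0)
        theta = np.arccos(cos_t)
        sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 1e-12, None))
        u += 0.5 * angle_k * float(np.sum((theta - angle_theta0) ** 2))
        du = angle_k * (theta - angle_theta0)
        ei = ri / ni[:, None]
        ek = rk / nk[:, None]
        dth_i = (cos_t[:, None] * ei - ek) / (ni * sin_t)[:, None]
        dth_k = (cos_t[:, None] * ek - ei) / (nk * sin_t)[:, None]
        fi = -du[:, None] * dth_i
        fk = -du[:, None] * dth_k
        np.add.at(forces, angles[:, 0], fi)
        np.add.at(forces, angles[:, 2], fk)
        np.add.at(forces, angles[:, 1], -(fi + fk))
    return forces, u


def build_flexible_molecule_gas(
    n_molecules: int = 50,
    atoms_per_molecule: int = 3,
    bond_k: float = 1e4,  # kJ/mol/nm^2
    angle_k: float = 100.0,  # kJ/mol/rad^2
    temperature: float = 300.0,
    thermostat: str = "maxwell-resample",
    n_steps: int = 2000,
    dt: float = 0.002,
    output_stride: int = 10,
    resample_interval: int = 10,  # steps between velocity redraws
    kick_speed: float = 0.01,  # nm/ps per step, rescale-kick only
    mass: float = 12.0,
    bond_r0: float = 0.15,
    angle_theta0: float = 1.9,
    seed: int = 0,
) -> tuple[ObservableTrajectory, PhaseSpaceTrajectory, SystemInfo]:
    """Ideal gas of flexible harmonic molecules for equipartition checks.

    Molecules do not interact with each other (the gas-phase regime in
    which equipartition artifacts are most visible, since nothing
    re-thermalizes the decoupled degrees of freedom).  Thermostats:

    * ``maxwell-resample`` — redraw all velocities from the Maxwell
      distribution every ``resample_interval`` steps; exactly canonical,
      every component temperature equals the target;
    * ``rescale-kick`` — each step, kick the global centre of mass and
      rescale *all* velocities uniformly back to the target kinetic
      energy: a deliberately broken scheme that reproduces the
      flying-ice-cube artifact (translation heats, internal motion
      freezes);
    * ``none`` — plain NVE from Maxwell initial velocities.

    With ``atoms_per_molecule=1`` this degenerates to an ideal atomic gas.
    """
    if atoms_per_molecule < 1:
        raise ValueError("need at least one atom per molecule")
    if thermostat not in GAS_THERMOSTATS:
        raise ValueError(f"unknown gas thermostat {thermostat!r}")
    rng = np.random.default_rng(seed)
    n_atoms = n_molecules * atoms_per_molecule
    masses = np.full(n_atoms, float(mass))
    mol_index = np.repeat(np.arange(n_molecules), atoms_per_molecule)

    # initial geometry: per-molecule zig-zag chains at random placements
    pos = np.zeros((n_atoms, 3))
    spacing = 5.0  # nm between molecule anchors; they never interact anyway
    for mol in range(n_molecules):
        base = mol * atoms_per_molecule
        anchor = rng.uniform(0, spacing, 3) + np.array(
            [spacing * (mol % 10), spacing * (mol // 10), 0.0]
        )
        pos[base] = anchor
        direction = np.array([1.0, 0.0, 0.0])
        for i in range(1, atoms_per_molecule):
            # alternate directions so the chain is bent (nonlinear)
            direction = np.array([1.0, 0.4 * (-1) ** i, 0.1]) / np.linalg.norm(
                [1.0, 0.4, 0.1]
            )
            pos[base + i] = pos[base + i - 1] + bond_r0 * direction

    bonds = np.array(
        [
            (mol * atoms_per_molecule + i, mol * atoms_per_molecule + i + 1)
            for mol in range(n_molecules)
            for i in range(atoms_per_molecule - 1)
        ],
        dtype=int,
    ).reshape(-1, 2)
    angles = np.array(
        [
            (
                mol * atoms_per_molecule + i,
                mol * atoms_per_molecule + i + 1,
                mol * atoms_per_molecule + i + 2,
            )
            for mol in range(n_molecules)
            for i in range(atoms_per_molecule - 2)
        ],
        dtype=int,
    ).reshape(-1, 3)

    vel = maxwell_velocities(masses, temperature, rng)
    inv_m = 1.0 / masses[:, None]
    ndof = 3 * n_atoms
    k_target = 0.5 * ndof * KB * temperature

    f, u = _molecule_forces(
        pos, bonds, angles, bond_k, bond_r0, angle_k, angle_theta0
    )
    n_out = n_steps // output_stride
    rec_pos = np.empty((n_out, n_atoms, 3))
    rec_vel = np.empty((n_out, n_atoms, 3))
    t_arr = np.empty(n_out)
    k_arr = np.empty(n_out)
    u_arr = np.empty(n_out)

    out = 0
    for step in range(1, n_steps + 1):
        vel += 0.5 * dt * f * inv_m
        pos += dt * vel
        f, u = _molecule_forces(
            pos, bonds, angles, bond_k, bond_r0, angle_k, angle_theta0
        )
        vel += 0.5 * dt * f * inv_m

        if thermostat == "maxwell-resample" and step % resample_interval == 0:
            vel = maxwell_velocities(masses, temperature, rng)
        elif thermostat == "rescale-kick":
            # inject purely translational energy, then rescale everything
            kick_dir = rng.normal(size=3)
            kick_dir /= np.linalg.norm(kick_dir)
            vel += kick_speed * kick_dir
            k_now = 0.5 * float(np.sum(masses[:, None] * vel**2))
            vel *= np.sqrt(k_target / k_now)

        if step % output_stride == 0:
            k = 0.5 * float(np.sum(masses[:, None] * vel**2))
            t_arr[out] = step * dt
            k_arr[out] = k
            u_arr[out] = u
            rec_pos[out] = pos
            rec_vel[out] = vel
            out += 1

    traj = ObservableTrajectory(
        time=t_arr,
        kinetic_energy=k_arr,
        potential_energy=u_arr,
        total_energy=k_arr + u_arr,
        temperature=2.0 * k_arr / (ndof * KB),
    )
    box = np.full((n_out, 3), 1e3)  # effectively unbounded; gas never wraps
    phase = PhaseSpaceTrajectory(rec_pos, rec_vel, box)
    system = SystemInfo(
        ndof_total=ndof,
        ndof_com_reduction=0,
        masses=masses,
        molecule_index=mol_index,
        constraints_per_molecule=np.zeros(n_molecules, dtype=int),
    )
    return traj, phase, system
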