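"""Translational/rotational/internal kinetic-energy decomposition.

Equipartition demands that *every* subset of kinetic degrees of freedom
follows the gamma law with the subset's own degree-of-freedom count.  A
particularly diagnostic split separates each molecule's kinetic energy
into

* translation — motion of the centre of mass,
  ``K_trans = |sum_i m_i v_i|^2 / (2 M)``;
* rotation — rigid-body rotation about the centre of mass,
  ``K_rot = 1/2 w . L`` with ``L`` the angular momentum and
  ``w = I^+ L`` (pseudo-inverse of the inertia tensor, so monatomic and
  linear molecules are handled without special-casing);
* internal — the remainder, ``K_int = K_total - K_trans - K_rot``.

Velocity-scaling thermostats that act uniformly on decoupled degrees of
freedom pump energy from fast (internal) into slow (translational,
rotational) motion — the "flying ice cube" artifact.  The total kinetic
energy can then look perfectly canonical while the components are badly
wrong, which is exactly what the per-component tests expose.

Degree-of-freedom accounting per molecule of n atoms with c constraints:
3 translational; 3 rotational (2 if linear, 0 if monatomic);
3n - trans - rot - c internal.  Constraints (fixed bond lengths) are
subtracted from the internal count.  No centre-of-mass reduction is
applied to molecule subsets: removing the global COM does not pin the COM
of a subsystem.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import PhaseSpaceTrajectory, SystemInfo
from .kinetic import KineticTestResult, kinetic_reference, ks_test_kinetic, mean_std_test
from .prep import decorrelate

COMPONENTS = ("trans", "rot", "int")

#: singular values of the inertia tensor below this fraction of the largest
#: are treated as exactly zero (monatomic/linear molecules)
_INERTIA_RCOND = 1e-10

#: a molecule is linear when its smallest principal moment is below this
#: fraction of the largest
_LINEAR_TOL = 1e-8


def decompose_molecule_kinetic(
    positions: np.ndarray,
    velocities: np.ndarray,
    masses: np.ndarray,
) -> tuple[float, float, float]:
    """Split one molecule's kinetic energy into (K_trans, K_rot, K_int).

    Positions must be unwrapped (the molecule contiguous in space, not
    split across periodic images).  Units: nm, nm/ps, u -> kJ/mol.
    """
    r = np.asarray(positions, dtype=float).reshape(-1, 3)
    v = np.asarray(velocities, dtype=float).reshape(-1, 3)
    m = np.asarray(masses, dtype=float).reshape(-1)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite positions or velocities")
    if len(r) == 0:
        raise ValueError("empty molecule")

    k_total = 0.5 * float(np.sum(m * np.sum(v * v, axis=1)))
    M = float(m.sum())
    p_com = m[:, None] * v
    v_com = p_com.sum(axis=0) / M
    k_trans = 0.5 * M * float(v_com @ v_com)

    if len(r) == 1:
        return k_trans, 0.0, 0.0

    com = (m[:, None] * r).sum(axis=0) / M
    dr = r - com
    dv = v - v_com
    # angular momentum about the COM
    L = np.sum(m[:, None] * np.cross(dr, dv), axis=0)
    # inertia tensor about the COM
    r2 = np.sum(dr * dr, axis=1)
    inertia = np.eye(3) * np.sum(m * r2) - np.einsum("i,ij,ik->jk", m, dr, dr)
    omega = np.linalg.pinv(inertia, rcond=_INERTIA_RCOND) @ L
    k_rot = 0.5 * float(omega @ L)
    k_int = k_total - k_trans - k_rot
    # clip tiny negative round-off
    if k_int < 0 and k_int > -1e-12 * max(k_total, 1.0):
        k_int = 0.0
    return k_trans, k_rot, k_int


def molecule_is_linear(positions: np.ndarray, masses: np.ndarray) -> bool:
    """True when the smallest principal moment of inertia vanishes."""
    r = np.asarray(positions, dtype=float).reshape(-1, 3)
    m = np.asarray(masses, dtype=float).reshape(-1)
    if len(r) < 3:
        return len(r) == 2
    com = (m[:, None] * r).sum(axis=0) / m.sum()
    dr = r - com
    inertia = np.eye(3) * np.sum(m * np.sum(dr * dr, axis=1)) - np.einsum(
        "i,ij,ik->jk", m, dr, dr
    )
    moments = np.linalg.eigvalsh(inertia)
    return bool(moments[0] < _LINEAR_TOL * max(moments[-1], 1e-300))


def molecule_ndof(
    n_atoms: int, n_constraints: int = 0, linear: bool = False
) -> dict[str, int]:
    """Per-molecule degree-of-freedom counts by component."""
    trans = 3
    rot = 0 if n_atoms == 1 else (2 if linear else 3)
    internal = 3 * n_atoms - trans - rot - n_constraints
    if internal < 0:
        raise ValueError(
            f"{n_constraints} constraints leave a negative internal dof count"
        )
    return {"trans": trans, "rot": rot, "int": internal, "total": 3 * n_atoms - n_constraints}


def unwrap_molecule(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Make a molecule spatially contiguous across periodic boundaries.

    Atoms are chained in index order: each atom is placed at its minimum
    image relative to the previous one.  Assumes consecutive atoms are
    bonded (or at least closer than half a box edge), the usual topology
    ordering.
    """
    r = np.array(positions, dtype=float)
    for i in range(1, len(r)):
        d = r[i] - r[i - 1]
        r[i] = r[i - 1] + d - box * np.round(d / box)
    return r


@dataclass(frozen=True)
class GroupSpec:
    """Definition of kinetic-energy groups for equipartition checks.

    ``kind``:

    * ``"component"`` — one group per trans/rot/int component, summed over
      the selected molecules (default: all);
    * ``"molecules"`` — one group of total kinetic energy per listed
      molecule set (``members`` = sequence of molecule-index sequences,
      with ``names`` optionally labelling them);
    * ``"random"`` — a random bipartition of all molecules (seeded);
    * ``"spatial"`` — bipartition by the first-frame COM position along
      ``axis`` at the box midpoint.
    """

    kind: str = "component"
    members: tuple = ()
    names: tuple[str, ...] = ()
    molecules: tuple[int, ...] | None = None  # selection for "component"
    seed: int = 0
    axis: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("component", "molecules", "random", "spatial"):
            raise ValueError(f"unknown group kind {self.kind!r}")


@dataclass
class GroupKineticSeries:
    """Per-group kinetic-energy series with their dof counts."""

    series: dict[str, np.ndarray]
    ndof: dict[str, float]


def _molecule_atom_lists(system: SystemInfo) -> list[np.ndarray]:
    if system.molecule_index is None:
        raise ValueError("system has no molecule information")
    idx = system.molecule_index
    return [np.nonzero(idx == mol)[0] for mol in range(int(idx.max()) + 1)]


def _per_molecule_components(
    traj: PhaseSpaceTrajectory, system: SystemInfo
) -> tuple[np.ndarray, list[dict[str, int]]]:
    """(n_frames, n_molecules, 3) component energies + per-molecule ndof."""
    if system.masses is None:
        raise ValueError("system has no masses")
    atoms = _molecule_atom_lists(system)
    constraints = (
        system.constraints_per_molecule
        if system.constraints_per_molecule is not None
        else np.zeros(len(atoms), dtype=int)
    )
    if len(constraints) != len(atoms):
        raise ValueError("constraints_per_molecule length != number of molecules")

    ndofs: list[dict[str, int]] = []
    first_box = traj.box[0]
    for mol, aidx in enumerate(atoms):
        r0 = unwrap_molecule(traj.positions[0, aidx], first_box)
        linear = molecule_is_linear(r0, system.masses[aidx])
        ndofs.append(molecule_ndof(len(aidx), int(constraints[mol]), linear))

    out = np.empty((traj.n_frames, len(atoms), 3))
    for f in range(traj.n_frames):
        box = traj.box[f]
        for mol, aidx in enumerate(atoms):
            r = unwrap_molecule(traj.positions[f, aidx], box)
            out[f, mol] = decompose_molecule_kinetic(
                r, traj.velocities[f, aidx], system.masses[aidx]
            )
    return out, ndofs


def group_kinetic_series(
    traj: PhaseSpaceTrajectory,
    system: SystemInfo,
    groups: GroupSpec | None = None,
) -> GroupKineticSeries:
    """Per-frame kinetic-energy series for each requested group."""
    groups = groups or GroupSpec()
    comps, ndofs = _per_molecule_components(traj, system)
    n_mol = comps.shape[1]

    if groups.kind == "component":
        sel = (
            np.asarray(groups.molecules, dtype=int)
            if groups.molecules is not None
            else np.arange(n_mol)
        )
        if sel.size and (sel.min() < 0 or sel.max() >= n_mol):
            raise ValueError("group references unknown molecules")
        series = {
            comp: comps[:, sel, i].sum(axis=1)
            for i, comp in enumerate(COMPONENTS)
        }
        ndof = {
            comp: float(sum(ndofs[m][comp] for m in sel)) for comp in COMPONENTS
        }
        return GroupKineticSeries(series=series, ndof=ndof)

    if groups.kind == "molecules":
        member_sets = [np.asarray(g, dtype=int) for g in groups.members]
        names = groups.names or tuple(f"group{i}" for i in range(len(member_sets)))
    elif groups.kind == "random":
        rng = np.random.default_rng(groups.seed)
        perm = rng.permutation(n_mol)
        member_sets = [perm[: n_mol // 2], perm[n_mol // 2 :]]
        names = ("random_a", "random_b")
    else:  # spatial
        box = traj.box[0]
        atoms = _molecule_atom_lists(system)
        masses = system.masses
        coms = np.array(
            [
                (
                    masses[a][:, None] * unwrap_molecule(traj.positions[0, a], box)
                ).sum(axis=0)
                / masses[a].sum()
                for a in atoms
            ]
        )
        wrapped = coms[:, groups.axis] % box[groups.axis]
        lower = wrapped < box[groups.axis] / 2
        member_sets = [np.nonzero(lower)[0], np.nonzero(~lower)[0]]
        names = ("lower_half", "upper_half")

    seen: set[int] = set()
    for g in member_sets:
        if g.size and (g.min() < 0 or g.max() >= n_mol):
            raise ValueError("group references unknown molecules")
        overlap = seen.intersection(g.tolist())
        if overlap:
            raise ValueError(f"groups are not disjoint (molecules {sorted(overlap)})")
        seen.update(g.tolist())

    totals = comps.sum(axis=2)  # (frames, molecules)
    series = {
        name: totals[:, g].sum(axis=1) for name, g in zip(names, member_sets)
    }
    ndof = {
        name: float(sum(ndofs[m]["total"] for m in g))
        for name, g in zip(names, member_sets)
    }
    return GroupKineticSeries(series=series, ndof=ndof)


def equipartition_test(
    traj: PhaseSpaceTrajectory,
    system: SystemInfo,
    temperature: float,
    groups: GroupSpec | None = None,
    strict: bool = False,
    n_resamples: int = 200,
    seed: int | np.random.Generator | None = None,
    tolerance: float = 3.0,
    decorrelate_series: bool = True,
) -> dict[str, KineticTestResult | float | None]:
    """Run the kinetic-energy test on each group with its own dof count.

    Returns a mapping from group name to a :class:`KineticTestResult`
    (non-strict) or a K-S p-value (``strict=True``).  Groups with zero
    degrees of freedom (e.g. the internal component of fully rigid
    molecules) are reported as ``None`` and skipped.
    """
    gk = group_kinetic_series(traj, system, groups)
    rng = np.random.default_rng(seed)
    results: dict[str, KineticTestResult | float | None] = {}
    for name, K in gk.series.items():
        ndof = gk.ndof[name]
        if ndof < 1:
            results[name] = None
            continue
        if decorrelate_series and len(K) >= 10:
            K, _ = decorrelate(K)
        ref = kinetic_reference(ndof, temperature)
        if strict:
            results[name] = ks_test_kinetic(K, ref)
        else:
            results[name] = mean_std_test(
                K, ref, n_resamples=n_resamples, seed=rng, tolerance=tolerance
            )
    return results
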