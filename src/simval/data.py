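"""Uniform data model for simulation results.

All validation checks in this package operate on a small set of containers:
a :class:`UnitSystem` describing how raw numbers map to internal units
(kJ/mol, nm, ps, bar, K), an :class:`EnsembleSpec` naming the sampled
ensemble and its parameters, a :class:`SystemInfo` with degree-of-freedom
bookkeeping and topology, an :class:`ObservableTrajectory` of per-frame
scalar observables, and an optional :class:`PhaseSpaceTrajectory` holding
full position/velocity data for equipartition analysis.  A
:class:`SimulationData` bundles them.

Flat ASCII files (whitespace- or comma-separated columns, ``#`` comments)
are the only external format; everything else is plain numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

from .constants import BAR_NM3_TO_KJ_PER_MOL, KB, KCAL_TO_KJ


class FlatFileError(ValueError):
    """Raised when a flat observable/trajectory file cannot be parsed."""


@dataclass(frozen=True)
class UnitSystem:
    """Multiplicative conversion factors from input units to internal units.

    Internal units are kJ/mol (energy), nm (length), nm^3 (volume),
    bar (pressure), ps (time) and K (temperature).  ``kb`` is the
    Boltzmann constant expressed in the *internal* energy unit per K.
    """

    energy: float = 1.0
    length: float = 1.0
    volume: float = 1.0
    pressure: float = 1.0
    time: float = 1.0
    temperature: float = 1.0
    kb: float = KB

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"unit factor {f.name!r} must be positive, got {v}")

    @classmethod
    def internal(cls) -> "UnitSystem":
        """GROMACS-style units: identity conversion."""
        return cls()

    @classmethod
    def kcal(cls) -> "UnitSystem":
        """AMBER/CHARMM-style energies in kcal/mol, otherwise internal units."""
        return cls(energy=KCAL_TO_KJ)


@dataclass(frozen=True)
class EnsembleSpec:
    """Declared thermodynamic ensemble and its external parameters.

    ``kind`` is one of ``"NVE"``, ``"NVT"``, ``"NPT"``, ``"muVT"``.
    Temperatures are in K, pressures in bar, chemical potentials in
    kJ/mol, volumes in nm^3.
    """

    kind: str
    temperature: float | None = None
    pressure: float | None = None
    chemical_potential: float | Sequence[float] | None = None
    volume: float | None = None
    n_particles: int | Sequence[int] | None = None

    _REQUIRED = {
        "NVE": (),
        "NVT": ("temperature",),
        "NPT": ("temperature", "pressure"),
        "muVT": ("temperature", "chemical_potential"),
    }

    def __post_init__(self) -> None:
        if self.kind not in self._REQUIRED:
            raise ValueError(f"unknown ensemble kind {self.kind!r}")
        for name in self._REQUIRED[self.kind]:
            if getattr(self, name) is None:
                raise ValueError(f"{self.kind} ensemble requires {name!r}")
        if self.temperature is not None and self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def beta(self) -> float:
        """Inverse temperature (kJ/mol)^-1."""
        if self.temperature is None:
            raise ValueError("ensemble has no temperature")
        return 1.0 / (KB * self.temperature)


@dataclass
class SystemInfo:
    """Degree-of-freedom accounting and minimal topology.

    ``ndof_total`` counts the kinetic degrees of freedom entering the
    gamma-distribution reference; ``ndof_com_reduction`` is the number of
    globally removed degrees of freedom (3 when centre-of-mass motion is
    removed, the usual case with periodic boundaries).  ``molecule_index``
    assigns every atom to a molecule; ``constraints_per_molecule`` counts
    holonomic constraints (fixed bond lengths) within each molecule.
    """

    ndof_total: int
    ndof_com_reduction: int = 3
    masses: np.ndarray | None = None
    molecule_index: np.ndarray | None = None
    constraints_per_molecule: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.ndof_total <= 0:
            raise ValueError("ndof_total must be positive")
        if self.masses is not None:
            self.masses = np.asarray(self.masses, dtype=float)
        if self.molecule_index is not None:
            self.molecule_index = np.asarray(self.molecule_index, dtype=int)
        if self.constraints_per_molecule is not None:
            self.constraints_per_molecule = np.asarray(
                self.constraints_per_molecule, dtype=int
            )

    @property
    def ndof_effective(self) -> int:
        """Degrees of freedom after global reductions."""
        return self.ndof_total - self.ndof_com_reduction

    @property
    def n_molecules(self) -> int:
        if self.molecule_index is None:
            raise ValueError("no molecule information available")
        return int(self.molecule_index.max()) + 1


#: canonical observable names accepted by the flat-file reader
OBSERVABLE_ALIASES = {
    "time": "time",
    "t": "time",
    "kinetic_energy": "kinetic_energy",
    "kinetic": "kinetic_energy",
    "kin": "kinetic_energy",
    "k": "kinetic_energy",
    "potential_energy": "potential_energy",
    "potential": "potential_energy",
    "pot": "potential_energy",
    "u": "potential_energy",
    "total_energy": "total_energy",
    "total": "total_energy",
    "e": "total_energy",
    "enthalpy": "enthalpy",
    "h": "enthalpy",
    "volume": "volume",
    "v": "volume",
    "pressure": "pressure",
    "p": "pressure",
    "temperature": "temperature",
    "temp": "temperature",
}

_UNIT_KIND = {
    "time": "time",
    "kinetic_energy": "energy",
    "potential_energy": "energy",
    "total_energy": "energy",
    "enthalpy": "energy",
    "volume": "volume",
    "pressure": "pressure",
    "temperature": "temperature",
}

_SERIES_NAMES = tuple(n for n in _UNIT_KIND)


@dataclass
class ObservableTrajectory:
    """Per-frame scalar observables on a common frame index (internal units)."""

    time: np.ndarray | None = None
    kinetic_energy: np.ndarray | None = None
    potential_energy: np.ndarray | None = None
    total_energy: np.ndarray | None = None
    enthalpy: np.ndarray | None = None
    volume: np.ndarray | None = None
    pressure: np.ndarray | None = None
    temperature: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in _SERIES_NAMES:
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    def series(self) -> dict[str, np.ndarray]:
        """All present series, by canonical name."""
        return {
            n: getattr(self, n) for n in _SERIES_NAMES if getattr(self, n) is not None
        }

    @property
    def n_frames(self) -> int:
        lengths = {len(v) for v in self.series().values()}
        if not lengths:
            return 0
        if len(lengths) > 1:
            raise ValueError(f"inconsistent series lengths: {sorted(lengths)}")
        return lengths.pop()


@dataclass
class PhaseSpaceTrajectory:
    """Full per-frame positions (nm), velocities (nm/ps) and box edges (nm)."""

    positions: np.ndarray  # (n_frames, n_atoms, 3)
    velocities: np.ndarray  # (n_frames, n_atoms, 3)
    box: np.ndarray  # (n_frames, 3) rectangular box edge lengths

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities shapes disagree")
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        if self.box.shape != (self.positions.shape[0], 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box edge lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]


@dataclass
class SimulationData:
    """Bundle of everything a validation check may need."""

    units: UnitSystem = field(default_factory=UnitSystem)
    ensemble: EnsembleSpec | None = None
    system: SystemInfo | None = None
    observables: ObservableTrajectory | None = None
    phase_space: PhaseSpaceTrajectory | None = None


# ---------------------------------------------------------------------------
# flat-file I/O
# ---------------------------------------------------------------------------


def _parse_table(path: str) -> tuple[list[str], np.ndarray]:
    """Read a whitespace/comma table; returns (header names, data array)."""
    header: list[str] = []
    rows: list[list[float]] = []
    ncol = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                tokens = line.lstrip("#").replace(",", " ").split()
                if tokens and not rows and not header:
                    header = tokens
                continue
            parts = line.replace(",", " ").split()
            try:
                row = [float(p) for p in parts]
            except ValueError as exc:
                raise FlatFileError(
                    f"{path}:{lineno}: non-numeric value in line {line!r}"
                ) from exc
            if ncol is None:
                ncol = len(row)
            elif len(row) != ncol:
                raise FlatFileError(
                    f"{path}:{lineno}: expected {ncol} columns, got {len(row)}"
                )
            rows.append(row)
    if not rows:
        raise FlatFileError(f"{path}: no data rows")
    return header, np.asarray(rows, dtype=float)


def load_flat_observables(
    path: str,
    column_map: dict[str, int | str] | None = None,
    units: UnitSystem | None = None,
    check: bool = True,
) -> ObservableTrajectory:
    """Load an observable trajectory from a flat ASCII file.

    Parameters
    ----------
    path:
        Whitespace- or comma-separated text file; lines starting with ``#``
        are comments.  The first comment line may name the columns.
    column_map:
        Maps canonical observable names (``kinetic_energy``/``kin``,
        ``potential_energy``/``pot``, ``total_energy``, ``enthalpy``,
        ``volume``, ``pressure``, ``temperature``, ``time``) to 0-based
        column indices or header names.  When omitted, the header comment
        line is used.
    units:
        Unit system of the file contents; defaults to internal units.
    check:
        Verify E = K + U where all three series are present.
    """
    units = units or UnitSystem.internal()
    header, data = _parse_table(path)

    columns: dict[str, int] = {}
    if column_map is not None:
        for name, col in column_map.items():
            canon = OBSERVABLE_ALIASES.get(name.lower())
            if canon is None:
                raise ValueError(f"unknown observable name {name!r}")
            if isinstance(col, str):
                if col not in header:
                    raise FlatFileError(f"{path}: column {col!r} not in header")
                col = header.index(col)
            columns[canon] = int(col)
    else:
        if not header:
            raise FlatFileError(
                f"{path}: no header comment line; pass column_map explicitly"
            )
        for i, name in enumerate(header):
            canon = OBSERVABLE_ALIASES.get(name.lower())
            if canon is not None:
                columns[canon] = i

    if not columns:
        raise FlatFileError(f"{path}: no recognizable observable columns")

    kwargs: dict[str, np.ndarray] = {}
    for canon, col in columns.items():
        if col >= data.shape[1]:
            raise FlatFileError(
                f"{path}: column index {col} out of range ({data.shape[1]} columns)"
            )
        factor = getattr(units, _UNIT_KIND[canon])
        kwargs[canon] = data[:, col] * factor
    traj = ObservableTrajectory(**kwargs)
    if check:
        diags = _check_energy_consistency(traj)
        if diags:
            raise ValueError("; ".join(d.message for d in diags))
    return traj


def write_flat_observables(path: str, traj: ObservableTrajectory) -> None:
    """Write a trajectory to a flat file (internal units, full precision)."""
    series = traj.series()
    names = list(series)
    data = np.column_stack([series[n] for n in names])
    with open(path, "w") as fh:
        fh.write("# " + " ".join(names) + "\n")
        for row in data:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def load_flat_phase_space(
    path_positions: str,
    path_velocities: str,
    n_atoms: int,
    box: Sequence[float],
    units: UnitSystem | None = None,
) -> PhaseSpaceTrajectory:
    """Load position/velocity flat files (one atom per row, x y z columns).

    Frames are stored as consecutive blocks of ``n_atoms`` rows.  ``box``
    is a fixed rectangular box (3 edge lengths, input length units).
    """
    units = units or UnitSystem.internal()

    def _read(path: str) -> np.ndarray:
        _, data = _parse_table(path)
        if data.shape[1] != 3:
            raise FlatFileError(f"{path}: expected 3 columns, got {data.shape[1]}")
        if data.shape[0] % n_atoms:
            raise FlatFileError(
                f"{path}: {data.shape[0]} rows is not a multiple of n_atoms={n_atoms}"
            )
        return data.reshape(-1, n_atoms, 3)

    pos = _read(path_positions) * units.length
    vel = _read(path_velocities) * (units.length / units.time)
    box_arr = np.tile(np.asarray(box, dtype=float) * units.length, (pos.shape[0], 1))
    return PhaseSpaceTrajectory(pos, vel, box_arr)


# ---------------------------------------------------------------------------
# derived observables
# ---------------------------------------------------------------------------


def derive_enthalpy(
    traj: ObservableTrajectory,
    ensemble: EnsembleSpec,
    use_potential: bool = False,
) -> ObservableTrajectory:
    """Return a copy of ``traj`` with the enthalpy series H = E + P V added.

    The target pressure of the ensemble (not an instantaneous pressure
    series) multiplies the instantaneous volume; the product is converted
    from bar*nm^3 to kJ/mol.  With ``use_potential`` the configurational
    enthalpy U + P V is formed instead, which is valid for ensemble
    checks because the kinetic contribution is independent of the
    configurational observables.
    """
    energy = traj.potential_energy if use_potential else traj.total_energy
    if energy is None:
        which = "potential" if use_potential else "total"
        raise ValueError(f"trajectory has no {which} energy series")
    if traj.volume is None:
        raise ValueError("enthalpy requires a volume series")
    if ensemble.pressure is None:
        raise ValueError("ensemble defines no target pressure")
    h = energy + ensemble.pressure * traj.volume * BAR_NM3_TO_KJ_PER_MOL
    return replace(traj, enthalpy=h)


# ---------------------------------------------------------------------------
# consistency diagnostics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Diagnostic:
    """One violated invariant; machine-readable."""

    field: str
    message: str


def _check_energy_consistency(traj: ObservableTrajectory) -> list[Diagnostic]:
    k, u, e = traj.kinetic_energy, traj.potential_energy, traj.total_energy
    if k is None or u is None or e is None:
        return []
    if not (len(k) == len(u) == len(e)):
        return []
    scale = np.maximum(np.abs(e), 1.0)
    bad = np.abs(k + u - e) > 1e-6 * scale
    if bad.any():
        i = int(np.argmax(bad))
        return [
            Diagnostic(
                "total_energy",
                f"E != K + U at frame {i} "
                f"(E={e[i]:.6g}, K+U={k[i] + u[i]:.6g})",
            )
        ]
    return []


def validate_simulation_data(sim: SimulationData) -> list[Diagnostic]:
    """Check all container invariants; returns diagnostics, never raises."""
    diags: list[Diagnostic] = []
    if sim.ensemble is not None:
        ens = sim.ensemble
        for name in EnsembleSpec._REQUIRED.get(ens.kind, ()):
            if getattr(ens, name) is None:
                diags.append(
                    Diagnostic(f"ensemble.{name}", f"{ens.kind} requires {name}")
                )
    if sim.observables is not None:
        lengths = {n: len(v) for n, v in sim.observables.series().items()}
        if len(set(lengths.values())) > 1:
            diags.append(
                Diagnostic(
                    "observables",
                    f"series length mismatch: {lengths}",
                )
            )
        else:
            diags.extend(_check_energy_consistency(sim.observables))
    if sim.system is not None:
        sysinfo = sim.system
        if sysinfo.ndof_effective <= 0:
            diags.append(
                Diagnostic("system.ndof_total", "no degrees of freedom remain")
            )
        if (
            sysinfo.masses is not None
            and sysinfo.molecule_index is not None
            and len(sysinfo.masses) != len(sysinfo.molecule_index)
        ):
            diags.append(
                Diagnostic(
                    "system.molecule_index",
                    "molecule_index length differs from masses length",
                )
            )
    if sim.phase_space is not None and sim.system is not None:
        if (
            sim.system.masses is not None
            and sim.phase_space.n_atoms != len(sim.system.masses)
        ):
            diags.append(
                Diagnostic(
                    "phase_space",
                    "atom count differs between phase-space trajectory and system",
                )
            )
    return diags
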