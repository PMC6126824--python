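"""Integrator convergence test via timestep scaling of energy fluctuations.

A symplectic second-order integrator (velocity-Verlet, leapfrog) does not
conserve the physical Hamiltonian H but a nearby shadow Hamiltonian; the
instantaneous total energy therefore fluctuates around its mean with an
amplitude of order dt^2.  Comparing two otherwise identical constant-energy
runs whose timesteps differ, the ratio of the RMSD of the total energy
about its mean must equal the squared timestep ratio:

    RMSD(dt1) / RMSD(dt2) = (dt1 / dt2)^2.

Halving the timestep must divide the fluctuations by four.  Deviations
expose discontinuities in the potential or forces (e.g. plain interaction
cutoffs), broken constraints, or integrator bugs — anything that makes the
dynamics non-symplectic at the measured scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


def constant_of_motion_stats(
    E_series: np.ndarray,
    dt: float,
    drift_handling: str = "none",
) -> tuple[float, float]:
    """RMSD about the mean and linear drift rate of a total-energy series.

    Parameters
    ----------
    E_series:
        Total energy per saved frame (kJ/mol).
    dt:
        Time between saved frames (ps) — the output interval, not the
        integration timestep.
    drift_handling:
        ``"none"`` computes the RMSD of the raw series about its mean;
        ``"remove-linear"`` removes a least-squares linear trend first
        (useful for long runs where slow drift would inflate the RMSD).

    Returns
    -------
    (rmsd, drift):
        RMSD in kJ/mol and least-squares drift rate in kJ/mol/ps (the
        drift is always reported, whether or not it is removed).
    """
    E = np.asarray(E_series, dtype=float)
    if len(E) < 10:
        raise ValueError("series too short (need >= 10 frames)")
    if drift_handling not in ("none", "remove-linear"):
        raise ValueError(f"unknown drift_handling {drift_handling!r}")
    t = np.arange(len(E)) * dt
    slope, intercept = np.polyfit(t, E, 1)
    if drift_handling == "remove-linear":
        resid = E - (slope * t + intercept)
    else:
        resid = E - E.mean()
    return float(np.sqrt(np.mean(resid**2))), float(slope)


@dataclass(frozen=True)
class ConvergenceEntry:
    """One timestep level and its comparison to the next-smaller one."""

    dt: float
    rmsd: float
    drift: float
    ratio: float | None = None  #: rmsd / rmsd(next smaller dt)
    expected: float | None = None  #: (dt / dt_smaller)^2
    deviation: float | None = None  #: |ratio / expected - 1|


@dataclass(frozen=True)
class ConvergenceReport:
    entries: tuple[ConvergenceEntry, ...]
    tolerance: float
    passed: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"{'dt/ps':>10} {'RMSD':>12} {'drift':>12} "
            f"{'ratio':>8} {'expect':>8} {'dev':>6}"
        ]
        for e in self.entries:
            r = f"{e.ratio:8.3f}" if e.ratio is not None else " " * 8
            x = f"{e.expected:8.3f}" if e.expected is not None else " " * 8
            d = f"{e.deviation:6.2f}" if e.deviation is not None else " " * 6
            lines.append(
                f"{e.dt:10.5g} {e.rmsd:12.5g} {e.drift:12.5g} {r} {x} {d}"
            )
        lines.append(f"verdict: {'pass' if self.passed else 'FAIL'}")
        return "\n".join(lines)


def convergence_test(
    entries: Sequence[tuple[float, np.ndarray]],
    tolerance: float = 0.3,
    output_interval: float | None = None,
    drift_handling: str = "none",
) -> ConvergenceReport:
    """Check the dt^2 scaling of energy fluctuations across timestep levels.

    Parameters
    ----------
    entries:
        ``(dt, E_series)`` pairs from otherwise identical runs; the energy
        series must be saved at a common output interval so that all RMSDs
        are comparable.
    tolerance:
        Maximum allowed relative deviation of each adjacent-pair RMSD
        ratio from its expected value ``(dt_large / dt_small)^2``.
    output_interval:
        Time between saved frames (ps); defaults to the largest dt.

    The report also carries the per-level drift rate — fluctuations should
    dominate the total drift by orders of magnitude for the test to be
    meaningful.
    """
    if len(entries) < 2:
        raise ValueError("need at least two timestep levels")
    dts = [dt for dt, _ in entries]
    if len(set(dts)) != len(dts):
        raise ValueError("duplicate timestep values")
    ordered = sorted(entries, key=lambda e: -e[0])  # decreasing dt
    interval = output_interval if output_interval is not None else ordered[0][0]

    stats_ = [
        constant_of_motion_stats(E, interval, drift_handling) for _, E in ordered
    ]
    out: list[ConvergenceEntry] = []
    ok = True
    for i, ((dt, _), (rmsd, drift)) in enumerate(zip(ordered, stats_)):
        if i + 1 < len(ordered):
            dt2 = ordered[i + 1][0]
            rmsd2 = stats_[i + 1][0]
            ratio = rmsd / rmsd2 if rmsd2 > 0 else np.inf
            expected = (dt / dt2) ** 2
            deviation = abs(ratio / expected - 1.0)
            ok = ok and deviation <= tolerance
            out.append(
                ConvergenceEntry(dt, rmsd, drift, float(ratio), expected, deviation)
            )
        else:
            out.append(ConvergenceEntry(dt, rmsd, drift))
    return ConvergenceReport(entries=tuple(out), tolerance=tolerance, passed=ok)
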