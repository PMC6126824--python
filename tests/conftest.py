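"""Shared fixtures: equilibrated toy-MD states reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from simval.toymd import ToyMDConfig, build_flexible_molecule_gas, run_md


@pytest.fixture(scope="session")
def lj_equilibrated():
    """Equilibrated positions/velocities of the default 216-particle LJ gas.

    NVE from a lattice start with Maxwell velocities; 2 ps with the smooth
    force-switch cutoff is ample for this small fluid.
    """
    cfg = ToyMDConfig(
        n_particles=216,
        cutoff_scheme="switch",
        dt=0.004,
        n_steps=500,
        output_stride=100,
        thermostat="none",
        seed=20260919,
    )
    _, phase = run_md(cfg)
    return phase.positions[-1], phase.velocities[-1]


@pytest.fixture(scope="session")
def canonical_gas():
    """Flexible-molecule ideal gas under the exactly canonical thermostat."""
    return build_flexible_molecule_gas(
        n_molecules=40,
        atoms_per_molecule=3,
        thermostat="maxwell-resample",
        n_steps=4000,
        output_stride=10,
        temperature=300.0,
        seed=11,
    )
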