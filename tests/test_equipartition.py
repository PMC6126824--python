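"""Translational/rotational/internal decomposition and per-group tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from simval.constants import KB
from simval.equipartition import (
    GroupSpec,
    decompose_molecule_kinetic,
    equipartition_test,
    group_kinetic_series,
    molecule_is_linear,
    molecule_ndof,
    unwrap_molecule,
)
from simval.toymd import build_flexible_molecule_gas


def random_molecule(rng, n_atoms):
    r = rng.normal(scale=0.2, size=(n_atoms, 3))
    v = rng.normal(size=(n_atoms, 3))
    m = rng.uniform(1.0, 20.0, n_atoms)
    return r, v, m


class TestDecomposition:
    def test_single_particle_all_translational(self):
        kt, kr, ki = decompose_molecule_kinetic(
            [[0.0, 0.0, 0.0]], [[1.0, 0.0, 0.0]], [1.0]
        )
        assert kt == pytest.approx(0.5)
        assert kr == 0.0 and ki == 0.0

    def test_rigid_dumbbell_rotation_is_rotational(self):
        r = np.array([[0.0, 0.0, 0.0], [0.2, 0.0, 0.0]])
        m = np.array([1.0, 3.0])
        com = (m[:, None] * r).sum(axis=0) / m.sum()
        omega = np.array([0.0, 0.0, 10.0])
        v = np.cross(omega, r - com)
        kt, kr, ki = decompose_molecule_kinetic(r, v, m)
        k_total = 0.5 * np.sum(m * np.sum(v * v, axis=1))
        assert kt == pytest.approx(0.0, abs=1e-12)
        assert abs(ki) <= 1e-10 * k_total
        assert kr == pytest.approx(k_total, rel=1e-10)

    def test_pure_translation_no_rotation(self):
        rng = np.random.default_rng(0)
        r, _, m = random_molecule(rng, 4)
        v = np.tile([1.0, -2.0, 0.5], (4, 1))
        kt, kr, ki = decompose_molecule_kinetic(r, v, m)
        assert kr == pytest.approx(0.0, abs=1e-12)
        assert ki == pytest.approx(0.0, abs=1e-10)
        assert kt == pytest.approx(0.5 * m.sum() * 5.25, rel=1e-12)

    @given(st.integers(2, 8), st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_components_sum_to_total(self, n_atoms, seed):
        rng = np.random.default_rng(seed)
        r, v, m = random_molecule(rng, n_atoms)
        kt, kr, ki = decompose_molecule_kinetic(r, v, m)
        k_total = 0.5 * np.sum(m * np.sum(v * v, axis=1))
        assert kt + kr + ki == pytest.approx(k_total, rel=1e-8)
        assert min(kt, kr) >= -1e-12

    def test_invariance_under_translation_and_rotation(self):
        rng = np.random.default_rng(1)
        r, v, m = random_molecule(rng, 5)
        ref = decompose_molecule_kinetic(r, v, m)
        # global translation of positions
        shifted = decompose_molecule_kinetic(r + [10.0, -3.0, 7.0], v, m)
        np.testing.assert_allclose(shifted, ref, rtol=1e-9)
        # rigid rotation of the whole frame (positions and velocities)
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        rotated = decompose_molecule_kinetic(r @ R.T, v @ R.T, m)
        np.testing.assert_allclose(rotated, ref, rtol=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            decompose_molecule_kinetic(
                [[0.0, 0.0, np.nan]], [[1.0, 0.0, 0.0]], [1.0]
            )


class TestNdofAccounting:
    def test_rigid_water_has_no_internal_dof(self):
        # 3 atoms, 3 constraints: 9 - 3 trans - 3 rot - 3 constraints = 0
        nd = molecule_ndof(3, n_constraints=3, linear=False)
        assert nd == {"trans": 3, "rot": 3, "int": 0, "total": 6}

    def test_linear_and_monatomic_rotational_count(self):
        assert molecule_ndof(1)["rot"] == 0
        assert molecule_ndof(2, linear=True)["rot"] == 2
        assert molecule_ndof(3, linear=False)["rot"] == 3

    def test_overconstrained_rejected(self):
        with pytest.raises(ValueError):
            molecule_ndof(2, n_constraints=5)

    def test_linearity_detection(self):
        line = np.array([[0.0, 0, 0], [0.1, 0, 0], [0.2, 0, 0]])
        bent = np.array([[0.0, 0, 0], [0.1, 0, 0], [0.1, 0.1, 0]])
        m = np.ones(3)
        assert molecule_is_linear(line, m)
        assert not molecule_is_linear(bent, m)


class TestUnwrap:
    def test_molecule_split_across_boundary_is_rejoined(self):
        box = np.array([2.0, 2.0, 2.0])
        # bonded pair wrapped to opposite faces
        r = np.array([[1.95, 1.0, 1.0], [0.05, 1.0, 1.0]])
        un = unwrap_molecule(r, box)
        assert np.linalg.norm(un[1] - un[0]) == pytest.approx(0.1)


class TestGroups:
    def test_whole_system_group_equals_total(self, canonical_gas):
        traj, phase, system = canonical_gas
        gk = group_kinetic_series(
            phase, system, GroupSpec("molecules", members=(tuple(range(40)),))
        )
        total = sum(
            0.5
            * np.sum(
                system.masses[None, :, None] * phase.velocities**2, axis=(1, 2)
            )
        )
        np.testing.assert_allclose(
            gk.series["group0"].sum(), total, rtol=1e-10
        )

    def test_random_bipartition_conserves_ndof(self, canonical_gas):
        _, phase, system = canonical_gas
        gk = group_kinetic_series(phase, system, GroupSpec("random", seed=3))
        assert sum(gk.ndof.values()) == system.ndof_total

    def test_component_ndof_sums(self, canonical_gas):
        _, phase, system = canonical_gas
        gk = group_kinetic_series(phase, system, GroupSpec("component"))
        assert sum(gk.ndof.values()) == system.ndof_total

    def test_unknown_molecule_rejected(self, canonical_gas):
        _, phase, system = canonical_gas
        with pytest.raises(ValueError, match="unknown"):
            group_kinetic_series(
                phase, system, GroupSpec("molecules", members=((0, 999),))
            )


class TestEquipartitionTest:
    def test_canonical_gas_passes_all_components(self, canonical_gas):
        _, phase, system = canonical_gas
        res = equipartition_test(
            phase, system, 300.0, GroupSpec("component"), seed=0
        )
        for comp in ("trans", "rot", "int"):
            assert res[comp].dev_mean <= 3, comp

    def test_flying_ice_cube_detected(self):
        # uniform rescaling plus a COM kick pumps energy into translation
        _, phase, system = build_flexible_molecule_gas(
            n_molecules=40,
            atoms_per_molecule=3,
            thermostat="rescale-kick",
            n_steps=12_000,
            output_stride=10,
            temperature=300.0,
            seed=12,
        )
        gk = group_kinetic_series(phase, system, GroupSpec("component"))
        n = phase.n_frames

        def t_window(comp, window):
            return 2 * gk.series[comp][window].mean() / (gk.ndof[comp] * KB)

        early, late = slice(0, n // 6), slice(-n // 6, None)
        # translation heats past the target while internal motion cools
        assert t_window("trans", late) > 320.0
        assert t_window("int", late) < 280.0
        assert t_window("trans", late) > t_window("trans", early)
        assert t_window("int", late) < t_window("int", early)

    def test_zero_ndof_group_skipped(self, canonical_gas):
        _, phase, system = canonical_gas
        system2 = type(system)(
            ndof_total=system.ndof_total,
            ndof_com_reduction=0,
            masses=system.masses,
            molecule_index=system.molecule_index,
            constraints_per_molecule=np.full(40, 3),  # rigid: no internal dof
        )
        res = equipartition_test(
            phase, system2, 300.0, GroupSpec("component"), seed=0
        )
        assert res["int"] is None
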