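"""Pulse controller: axis geometry, impulses, thermostat, full cycles, SMD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from puffmd.engine import BreakableBond, HarmonicBond, ParticleSystem
from puffmd.errors import DegenerateAxisError, InvalidArgumentError
from puffmd.fixtures import (
    PAIR_ANCHORS,
    make_breakable_pair,
    make_free_pair,
    make_trapped_pair,
    make_two_bead_system,
)
from puffmd.protocol import (
    AnchorSpec,
    PuffParams,
    apply_impulse,
    per_pulse_displacement,
    pulling_axis,
    relative_axis_velocity,
    rescale_to_temperature,
    run_puff,
    run_smd_baseline,
    theoretical_max_force,
)
from puffmd.units import kinetic_temperature, mass_to_force_units


def _random_system(rng, n=6):
    masses = rng.uniform(10.0, 150.0, size=n)
    positions = rng.normal(scale=5.0, size=(n, 3))
    velocities = rng.normal(scale=2.0, size=(n, 3))
    return ParticleSystem(masses=masses, positions=positions, velocities=velocities)


class TestAxisGeometry:
    def test_axis_along_x_with_known_separation(self):
        system = make_free_pair(separation=50.0)
        axis, sep = pulling_axis(system, PAIR_ANCHORS)
        assert np.allclose(axis, [1.0, 0.0, 0.0])
        assert sep == pytest.approx(50.0)

    def test_swapping_groups_negates_axis(self, rng):
        system = _random_system(rng)
        anchors = AnchorSpec(group1=(0, 1), group2=(4, 5))
        flipped = AnchorSpec(group1=(4, 5), group2=(0, 1))
        a1, s1 = pulling_axis(system, anchors)
        a2, s2 = pulling_axis(system, flipped)
        assert np.allclose(a1, -a2)
        assert s1 == pytest.approx(s2)

    def test_axis_is_unit_length(self, rng):
        for _ in range(10):
            system = _random_system(rng)
            axis, _ = pulling_axis(system, AnchorSpec((0, 2), (3, 5)))
            assert np.linalg.norm(axis) == pytest.approx(1.0, abs=1e-12)

    def test_coincident_coms_raise(self):
        system = make_free_pair(separation=5.0)
        system.positions[1] = system.positions[0]
        with pytest.raises(DegenerateAxisError):
            pulling_axis(system, PAIR_ANCHORS)


class TestRelativeAxisVelocity:
    def test_receding_groups_add_their_speeds(self):
        system = make_free_pair(separation=10.0)
        system.velocities[0, 0] = -0.5
        system.velocities[1, 0] = +0.5
        assert relative_axis_velocity(system, PAIR_ANCHORS) == pytest.approx(1.0)

    def test_common_translation_gives_zero(self, rng):
        system = _random_system(rng)
        system.velocities[:] = [1.3, -0.4, 2.2]
        anchors = AnchorSpec((0, 1, 2), (3, 4))
        assert relative_axis_velocity(system, anchors) == pytest.approx(0.0, abs=1e-12)

    def test_perpendicular_motion_projects_to_zero(self):
        system = make_free_pair(separation=10.0)  # axis = x
        system.velocities[1] = [0.0, 3.0, -2.0]
        assert relative_axis_velocity(system, PAIR_ANCHORS) == pytest.approx(0.0, abs=1e-12)


class TestImpulse:
    def test_worked_force_cap_example(self):
        # pre-pulse velocity -1, target +1: ΔV = 2, and with a pulling mass
        # given directly as 41 pN·ps²/Å the booked force is 82 pN
        assert theoretical_max_force(1.0, mass_pn=41.0) == pytest.approx(82.0)
        m_da = 41.0 / mass_to_force_units(1.0)  # Da equivalent of 41 pN·ps²/Å
        system = make_two_bead_system(m_da / 2, m_da / 2, None, 10.0)
        system.velocities[0, 0] = +0.5
        system.velocities[1, 0] = -0.5  # approaching at -1 Å/ps
        record = apply_impulse(system, PAIR_ANCHORS, v_target=1.0)
        assert record.pre_pulse_velocity == pytest.approx(-1.0)
        assert record.delta_v == pytest.approx(2.0)
        assert record.applied_force == pytest.approx(82.0, rel=1e-9)

    def test_already_at_target_is_a_fixed_point(self):
        system = make_free_pair(separation=10.0)
        system.velocities[1, 0] = 2.0
        before = system.velocities.copy()
        record = apply_impulse(system, PAIR_ANCHORS, v_target=2.0)
        assert record.delta_v == pytest.approx(0.0, abs=1e-12)
        assert record.applied_force == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(system.velocities, before)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 2**31 - 1), v_target=st.floats(0.0, 8.0))
    def test_reset_is_exact_on_arbitrary_systems(self, seed, v_target):
        rng = np.random.default_rng(seed)
        system = _random_system(rng)
        anchors = AnchorSpec((0, 3), (1, 4, 5))
        apply_impulse(system, anchors, v_target)
        assert relative_axis_velocity(system, anchors) == pytest.approx(
            v_target, abs=1e-9
        )

    def test_impulse_momentum_bookkeeping_per_group(self, rng):
        system = _random_system(rng)
        anchors = AnchorSpec((0, 1), (2, 3, 4))
        m1, m2 = anchors.group_masses(system)
        p_before = {
            g: system.masses[list(idx)] @ system.velocities[list(idx)]
            for g, idx in (("g1", anchors.group1), ("g2", anchors.group2))
        }
        record = apply_impulse(system, anchors, v_target=3.0)
        p_after = {
            g: system.masses[list(idx)] @ system.velocities[list(idx)]
            for g, idx in (("g1", anchors.group1), ("g2", anchors.group2))
        }
        assert np.allclose(
            p_after["g2"] - p_before["g2"], m2 * 0.5 * record.delta_v * record.axis
        )
        assert np.allclose(
            p_after["g1"] - p_before["g1"], -m1 * 0.5 * record.delta_v * record.axis
        )

    def test_com_drift_compensation_restores_total_momentum(self, rng):
        system = _random_system(rng)
        anchors = AnchorSpec((0,), (1, 2, 3, 4, 5))  # very unequal masses
        p0 = system.masses @ system.velocities
        apply_impulse(system, anchors, v_target=4.0, remove_com_drift=True)
        p1 = system.masses @ system.velocities
        assert np.allclose(p0, p1, atol=1e-9)


class TestRescale:
    def test_at_target_temperature_is_idempotent(self, rng):
        system = _random_system(rng)
        t0 = kinetic_temperature(system.velocities, system.masses)
        rescale_to_temperature(system, t0)  # removes COM first
        t_mid = kinetic_temperature(system.velocities, system.masses)
        factor = rescale_to_temperature(system, t_mid)
        assert factor == pytest.approx(1.0, abs=1e-9)

    def test_quarter_temperature_doubles_velocities(self):
        system = make_free_pair()
        system.velocities[0, 0] = -1.0
        system.velocities[1, 0] = 1.0
        t75 = kinetic_temperature(system.velocities, system.masses)
        rescale_to_temperature(system, 4 * t75)
        assert system.velocities[1, 0] == pytest.approx(2.0)

    def test_rescale_hits_requested_temperature(self, rng):
        system = _random_system(rng)
        rescale_to_temperature(system, 300.0)
        assert kinetic_temperature(system.velocities, system.masses) == pytest.approx(
            300.0, rel=1e-6
        )

    def test_zero_kinetic_energy_warns_and_noop(self):
        system = make_free_pair()
        with pytest.warns(UserWarning):
            rescale_to_temperature(system, 300.0)
        assert np.allclose(system.velocities, 0.0)


class TestRunPuff:
    def test_free_pair_is_unimpeded(self):
        system = make_free_pair(separation=10.0)
        params = PuffParams(v_target=2.0, n_pulses=20, rescale_temp=None)
        traj = run_puff(system, PAIR_ANCHORS, params)
        assert len(traj.pulses) == 20
        assert np.max(np.abs(traj.applied_forces[1:])) < 1e-6
        # separation grows by v_target · pulse between consecutive pulses
        gaps = np.diff(traj.separations)
        assert np.allclose(gaps, 2.0 * 0.1, atol=1e-9)
        # input system untouched
        assert system.time == 0.0

    def test_trapped_pair_shows_negative_pre_pulse_velocities(self):
        from puffmd.engine import EquilibrationParams, langevin_equilibrate

        system = make_trapped_pair()
        langevin_equilibrate(
            system, EquilibrationParams(temperature=300.0, duration=3.0, gamma=5.0, seed=5)
        )
        params = PuffParams(v_target=1.0, n_pulses=150)
        traj = run_puff(system, PAIR_ANCHORS, params)
        tail = traj.pre_pulse_velocities[15:]
        assert tail.mean() < -0.2
        # displacement damping: the pair never strays further than one
        # pulse's worth of travel beyond its rest separation
        assert traj.separations.max() < 3.0 + 1.0 * 0.1 + 0.2

    def test_weak_breakable_bond_ruptures_and_motion_frees(self):
        system = make_breakable_pair(total_mass=224.0, omega=8.0, r_break=0.3)
        params = PuffParams(v_target=4.0, n_pulses=60, rescale_temp=5.0)
        traj = run_puff(system, PAIR_ANCHORS, params)
        assert not traj.final_system.bonds[0].intact
        # after rupture the pair recedes unimpeded at the target rate
        late = np.diff(traj.separations[-10:])
        assert np.allclose(late, 4.0 * 0.1, rtol=0.01)

    def test_same_seed_gives_identical_pulse_records(self):
        def one():
            system = make_trapped_pair()
            from puffmd.engine import EquilibrationParams, langevin_equilibrate

            langevin_equilibrate(
                system,
                EquilibrationParams(temperature=300.0, duration=2.0, gamma=5.0, seed=3),
            )
            return run_puff(system, PAIR_ANCHORS, PuffParams(v_target=1.0, n_pulses=40))

        a, b = one(), one()
        assert np.array_equal(a.applied_forces, b.applied_forces)
        assert np.array_equal(a.separations, b.separations)

    def test_force_cap_respected_when_not_super_reflecting(self):
        system = make_free_pair()
        params = PuffParams(v_target=1.5, n_pulses=30, rescale_temp=None)
        traj = run_puff(system, PAIR_ANCHORS, params)
        cap = theoretical_max_force(1.5, mass_da=224.0)
        ok = traj.pre_pulse_velocities >= -1.5
        assert np.all(traj.applied_forces[ok] <= cap + 1e-6)


class TestScalars:
    @pytest.mark.parametrize(
        "mass_pn, v, expected",
        [(41.0, 1.0, 82.0), (44.0, 0.4, 35.2), (41.0, 0.0, 0.0)],
    )
    def test_force_cap_worked_values(self, mass_pn, v, expected):
        assert theoretical_max_force(v, mass_pn=mass_pn) == pytest.approx(expected)

    def test_force_cap_argument_validation(self):
        with pytest.raises(InvalidArgumentError):
            theoretical_max_force(1.0)
        with pytest.raises(InvalidArgumentError):
            theoretical_max_force(1.0, mass_da=10.0, mass_pn=10.0)

    def test_per_pulse_displacement_scale(self):
        assert per_pulse_displacement(1.0, 100.0) == pytest.approx(0.1)


class TestSmdBaseline:
    def test_static_cantilever_on_resting_system_is_force_free(self):
        system = make_trapped_pair()
        res = run_smd_baseline(
            system, PAIR_ANCHORS, spring_k=500.0, cantilever_velocity=0.0, duration_fs=500
        )
        assert res.peak_force == pytest.approx(0.0, abs=1e-9)

    def test_logged_force_matches_spring_extension(self):
        system = make_trapped_pair()
        res = run_smd_baseline(
            system, PAIR_ANCHORS, spring_k=800.0, cantilever_velocity=1.0, duration_fs=2000
        )
        assert np.allclose(res.forces, 800.0 * (res.targets - res.separations), rtol=1e-9)

    def test_stiff_spring_on_trapped_system_beats_constant_momentum_cap(self):
        system = make_trapped_pair()
        res = run_smd_baseline(
            system, PAIR_ANCHORS, spring_k=1000.0, cantilever_velocity=1.0, duration_fs=5000
        )
        cap = theoretical_max_force(1.0, mass_da=224.0)
        assert res.peak_force > cap
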