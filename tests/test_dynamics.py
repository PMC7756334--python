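"""Integrator, SHAKE, baths, pressure and the simulation driver."""

import numpy as np
import pytest

import cutoffmd as md
from cutoffmd.constants import ATM, KB
from cutoffmd.dynamics import Protocol, minimize, weak_coupling_P_scale
from cutoffmd.system import SOLUTE, SOLVENT, LJTable, System


def free_particles(n, box_edge, seed=0, mass=10.0):
    """Non-interacting point particles (no charges, no LJ)."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, box_edge, (n, 3))
    return System(
        names=np.array(["P"] * n, dtype=object),
        positions=pos,
        velocities=np.zeros_like(pos),
        masses=np.full(n, mass),
        charges=np.zeros(n),
        lj_type=np.zeros(n, dtype=np.int64),
        molecule_id=np.arange(n),
        charge_group_id=np.arange(n),
        subsystem=np.full(n, SOLVENT),
        constraint_pairs=np.empty((0, 2), dtype=np.int64),
        constraint_lengths=np.empty(0),
        box=np.full(3, float(box_edge)),
        lj_table=LJTable([[0.0]], [[0.0]]),
    )


class TestLeapfrog:
    def test_free_drift(self):
        s = free_particles(1, 5.0)
        s.velocities[0] = [1.0, 0.0, 0.0]
        start = s.positions[0].copy()
        md.leapfrog_step(s, np.zeros((1, 3)), 0.002)
        assert s.positions[0] == pytest.approx(start + [0.002, 0.0, 0.0])

    def test_constant_force_closed_form(self):
        # hand-iterated recurrence: after n steps from rest,
        # v_n = n a dt,  x_n = dt^2 a n(n+1)/2
        s = free_particles(1, 5.0)
        s.positions[0] = 0.0
        f = np.array([[5.0, 0.0, 0.0]])
        a = 5.0 / s.masses[0]
        dt = 0.002
        for _ in range(10):
            md.leapfrog_step(s, f, dt)
        assert s.velocities[0, 0] == pytest.approx(10 * a * dt, rel=1e-12)
        assert s.positions[0, 0] == pytest.approx(dt**2 * a * 55, rel=1e-12)

    def test_at_rest_stays_at_rest(self):
        s = free_particles(3, 5.0)
        before = s.positions.copy()
        md.leapfrog_step(s, np.zeros((3, 3)), 0.002)
        assert np.array_equal(s.positions, before)


class TestShake:
    def test_satisfied_constraints_are_fixed_point(self):
        pos = np.array([[0.0, 0, 0], [0.1, 0, 0]])
        out = md.shake(pos, pos, np.array([[0, 1]]), np.array([0.1]), 1e-8, np.array([1.0, 1.0]))
        assert np.array_equal(out, pos)

    def test_symmetric_stretch_equal_masses(self):
        ref = np.array([[0.0, 0, 0], [0.10, 0, 0]])
        stretched = np.array([[-0.01, 0, 0], [0.11, 0, 0]])
        out = md.shake(stretched, ref, np.array([[0, 1]]), np.array([0.1]), 1e-12,
                       np.array([2.0, 2.0]))
        # equal masses: each atom moves 0.01 inward
        assert out[0, 0] == pytest.approx(0.0, abs=1e-8)
        assert out[1, 0] == pytest.approx(0.10, abs=1e-8)

    def test_rigid_water_random_perturbations(self, water8):
        rng = np.random.default_rng(8)
        ref = water8.positions[:3]
        pairs = np.array([[0, 1], [0, 2], [1, 2]])
        lengths = water8.constraint_lengths[[0, 8, 16]]
        masses = water8.masses[:3]
        tol = 1e-4
        for _ in range(1000):
            perturbed = ref + rng.normal(scale=0.01, size=ref.shape)
            out = md.shake(perturbed, ref, pairs, lengths, tol, masses)
            d2 = ((out[pairs[:, 0]] - out[pairs[:, 1]]) ** 2).sum(axis=1)
            assert (np.abs(d2 - lengths**2) <= tol * lengths**2).all()


class TestBaths:
    def test_bath_temperature_definition(self):
        # one free particle with E_kin = (3/2) kB 300 must read 300 K
        assert md.bath_temperature(1.5 * KB * 300.0, 3) == pytest.approx(300.0, rel=1e-12)
        assert md.bath_temperature(0.0, 3) == 0.0
        t1 = md.bath_temperature(7.3, 12)
        assert md.bath_temperature(14.6, 12) == pytest.approx(2 * t1, rel=1e-12)

    def test_temperature_scale_identity(self):
        lam = md.weak_coupling_T_scale(298.15, 298.15, 0.002, 0.1)
        assert lam == 1.0

    def test_temperature_scale_relaxation_algebra(self):
        t, t_ref, dt, tau = 310.0, 300.0, 0.002, 0.1
        lam = md.weak_coupling_T_scale(t, t_ref, dt, tau)
        t_after = lam**2 * t
        assert t_after == pytest.approx(t + (dt / tau) * (t_ref - t), rel=1e-13)
        assert t_after == pytest.approx(309.8, abs=1e-10)

    def test_repeated_scaling_contracts_to_reference(self):
        t = 350.0
        for _ in range(2000):
            t = md.weak_coupling_T_scale(t, 300.0, 0.002, 0.1) ** 2 * t
        assert t == pytest.approx(300.0, abs=1e-6)

    def test_pressure_scale_identity_and_sign(self):
        assert weak_coupling_P_scale(ATM, ATM, 0.002, 0.5, 4.575e-4) == 1.0
        assert weak_coupling_P_scale(10 * ATM, ATM, 0.002, 0.5, 4.575e-4) > 1.0
        assert weak_coupling_P_scale(-10 * ATM, ATM, 0.002, 0.5, 4.575e-4) < 1.0

    def test_pressure_scale_linearization(self):
        kappa, dt, tau = 4.575e-4, 0.002, 0.5
        dp = 0.3
        mu = weak_coupling_P_scale(ATM + dp, ATM, dt, tau, kappa)
        assert mu**3 == pytest.approx(1.0 + kappa * (dt / tau) * dp, rel=1e-12)

    def test_pathological_pressure_clamped(self):
        with pytest.warns(UserWarning, match="clamp"):
            mu = weak_coupling_P_scale(1e7, ATM, 0.002, 0.5, 4.575e-4)
        assert mu == 1.1


class TestPressure:
    def test_static_system_has_zero_pressure(self):
        assert md.compute_pressure(0.0, 0.0, 10.0) == 0.0

    def test_kinetic_contribution_scales_quadratically(self):
        p1 = md.compute_pressure(5.0, 0.0, 10.0)
        p4 = md.compute_pressure(20.0, 0.0, 10.0)
        assert p4 == pytest.approx(4 * p1, rel=1e-12)

    def test_ideal_gas_equation_of_state(self):
        n, t_ref = 100, 300.0
        s = free_particles(n, 6.0, seed=3)
        s = md.assign_maxwell_velocities(s, t_ref, seed=4)
        scheme = md.scheme_at_tr(r_short=1.0, r_long=1.0, update_interval=1)
        proto = Protocol(n_steps=100, temperature_coupling=False,
                         log_interval=10, frame_interval=10**6)
        res = md.run_simulation(s, scheme, proto, params=md.RFParams(78.0, 1.0))
        df = res.log_frame()
        pv = (df["pressure"] * df["volume"]).mean()
        # a single Maxwell draw fixes E_kin, so PV/NkT fluctuates with
        # sampling SD sqrt(2/dof)
        assert pv == pytest.approx(n * KB * t_ref, rel=3 * np.sqrt(2.0 / (3 * n)))


class TestRunSimulation:
    def test_thermostat_relaxes_ideal_gas_to_reference(self):
        # free particles have no cutoff noise, so the weak-coupling bath must
        # bring a 50 K-off start within 3 K of the reference in 5 ps
        system = free_particles(100, 6.0, seed=6)
        system = md.assign_maxwell_velocities(system, 248.0, seed=7)
        proto = Protocol(n_steps=2500, t_ref_solute=298.15, t_ref_solvent=298.15,
                         log_interval=25, frame_interval=10**6)
        res = md.run_simulation(
            system, md.scheme_at_tr(r_short=1.0, r_long=1.0, update_interval=1),
            proto, params=md.RFParams(78.0, 1.0),
        )
        df = res.log_frame()
        late = df[df["time"] >= 4.0]["T_solvent"]
        assert abs(late.mean() - 298.15) < 3.0

    def test_thermostat_pulls_cold_water_box_toward_reference(self):
        # an interacting box carries cutoff-noise heating, so the bath holds
        # it near — but measurably above — the reference; from 50 K cold the
        # temperature must recover to the reference's neighborhood
        system = md.build_water_box(64, 1.7, seed=6)
        scheme = md.scheme_cg_ow(r_short=0.8, r_long=0.8, update_interval=1)
        params = md.RFParams(78.0, 0.8)
        system = minimize(system, scheme, params=params, n_steps=150)
        system = md.assign_maxwell_velocities(system, 248.0, seed=7)  # 50 K cold
        proto = Protocol(n_steps=2500, t_ref_solute=298.15, t_ref_solvent=298.15,
                         log_interval=25, frame_interval=10**6)
        res = md.run_simulation(system, scheme, proto, params=params)
        df = res.log_frame()
        late = df[df["time"] >= 4.0]["T_solvent"].mean()
        assert late > 280.0  # recovered from the cold start
        assert late - 298.15 < 60.0  # held near the reference by the bath

    def test_bath_isolation_solute_untouched_by_solvent_reference(self):
        water = md.build_water_box(27, 2.0, seed=9)
        solute = md.build_toy_solute(2, seed=9)
        system = md.solvate(solute, water, overlap_cutoff=0.28)
        system = md.assign_maxwell_velocities(system, 300.0, seed=10)
        scheme = md.scheme_sa_tr(r_short=0.9, r_long=0.9, update_interval=1)
        params = md.RFParams(78.0, 0.9)
        n_solute = int((system.subsystem == SOLUTE).sum())

        def one_step(t_ref_solvent):
            proto = Protocol(n_steps=1, t_ref_solute=300.0,
                             t_ref_solvent=t_ref_solvent,
                             log_interval=1, frame_interval=10**6)
            return md.run_simulation(system, scheme, proto, params=params)

        a = one_step(200.0).system
        b = one_step(400.0).system
        # after one step, only the solvent bath scaling differs; the solute
        # velocities must be bit-identical
        assert np.array_equal(a.velocities[:n_solute], b.velocities[:n_solute])
        assert not np.array_equal(a.velocities[n_solute:], b.velocities[n_solute:])

    def test_box_constant_without_barostat(self):
        system = md.build_water_box(27, 2.0, seed=12)
        system = md.assign_maxwell_velocities(system, 300.0, seed=12)
        scheme = md.scheme_cg_ow(r_short=0.9, r_long=0.9, update_interval=1)
        proto = Protocol(n_steps=50, log_interval=10, frame_interval=10**6)
        res = md.run_simulation(system, scheme, proto, params=md.RFParams(78.0, 0.9))
        assert np.array_equal(res.system.box, system.box)

    def test_barostat_changes_volume_and_respects_bound(self):
        system = md.build_water_box(27, 2.0, seed=13)
        scheme = md.scheme_cg_ow(r_short=0.9, r_long=0.9, update_interval=1)
        params = md.RFParams(78.0, 0.9)
        system = minimize(system, scheme, params=params, n_steps=100)
        system = md.assign_maxwell_velocities(system, 298.15, seed=13)
        proto = Protocol(n_steps=200, pressure_coupling=True,
                         isothermal_compressibility=7.51e-4,
                         log_interval=20, frame_interval=10**6)
        res = md.run_simulation(system, scheme, proto, params=params)
        assert not np.array_equal(res.system.box, system.box)
        assert (res.system.box >= 2 * 0.9).all()

    def test_reproducible_for_fixed_inputs(self):
        system = md.build_water_box(8, 1.6, seed=14)
        system = md.assign_maxwell_velocities(system, 300.0, seed=15)
        scheme = md.scheme_cg_ow(r_short=0.7, r_long=0.7, update_interval=1)
        proto = Protocol(n_steps=30, log_interval=10, frame_interval=10)
        r1 = md.run_simulation(system, scheme, proto, params=md.RFParams(78.0, 0.7))
        r2 = md.run_simulation(system, scheme, proto, params=md.RFParams(78.0, 0.7))
        assert np.array_equal(r1.system.positions, r2.system.positions)
        assert r1.log_frame().equals(r2.log_frame())

    def test_minimize_lowers_potential_energy(self):
        from cutoffmd.nonbonded import compute_single_range
        from cutoffmd.pairlist import make_entities

        system = md.build_water_box(27, 2.0, seed=21)
        scheme = md.scheme_at_tr(r_short=0.9, r_long=0.9, update_interval=1)
        params = md.RFParams(78.0, 0.9)
        before, _, _ = compute_single_range(
            system, make_entities(system, scheme), params, 0.9
        )
        relaxed = minimize(system, scheme, params=params, n_steps=150)
        after, _, _ = compute_single_range(
            relaxed, make_entities(relaxed, scheme), params, 0.9
        )
        assert after.total < before.total
        # constraints stay satisfied through the descent
        d = np.linalg.norm(
            relaxed.positions[relaxed.constraint_pairs[:, 0]]
            - relaxed.positions[relaxed.constraint_pairs[:, 1]],
            axis=1,
        )
        assert np.allclose(d, relaxed.constraint_lengths, rtol=1e-4)

    def test_dof_accounting(self, water8):
        # 24 atoms, 24 constraints: 72 - 24 = 48 solvent dof, no solute dof
        assert water8.dof(SOLVENT) == 48
        assert water8.dof(SOLUTE) == 0
        assert water8.dof() == 48
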