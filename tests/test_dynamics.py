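"""Integrator correctness: conservation, clamps, determinism, relaxation."""

import numpy as np
import pytest

import hexfrac as hf
from hexfrac import kernels
from hexfrac.dynamics import _advance
from hexfrac.errors import InstabilityError


def total_energy(system, table):
    k3, ro3, rc3 = table.as_arrays()
    box = system.box_x if system.box_x is not None else -1.0
    _, _, pe = kernels.compute_forces(
        system.positions, system.bonds, system.species, k3, ro3, rc3, box
    )
    ke = 0.5 * float((system.masses[:, None] * system.velocities**2).sum())
    return pe + ke


def test_relaxed_lattice_is_stationary(table):
    """Zero temperature, zero friction, zero net force: nothing moves."""
    system = hf.build_hexagonal_lattice(5, 5)
    before = system.positions.copy()
    config = hf.DynamicsConfig(temperature=0.0, friction=0.0)
    hf.step(system, table, config)
    assert np.abs(system.positions - before).max() < 1e-12


def test_two_body_oscillation_frequency(table):
    """Closed-form oracle: a bonded pair displaced by +0.1 nm oscillates at
    omega = sqrt(2 * (2 k_P) / m) about its centre of mass."""
    m = 1.0e6
    system = hf.build_hexagonal_lattice(2, 1, spacing=9.17, mass=m)
    system.positions[1, 0] += 0.1
    config = hf.DynamicsConfig(time_step_fs=50.0, temperature=0.0, friction=0.0)
    omega = np.sqrt(2.0 * (2.0 * hf.PRISTINE_DEFAULT.k) / m)
    n_steps = 160  # a bit over one full period at dt = 0.05 ps
    separations = []
    for s in range(1, n_steps + 1):
        hf.step(system, table, config)
        t = s * 0.05
        r = system.positions[1, 0] - system.positions[0, 0]
        assert r == pytest.approx(9.17 + 0.1 * np.cos(omega * t), abs=2e-4)
        separations.append(r)
    # half-period check: full swing to the compressed turning point at t = pi/omega
    half_period = np.pi / omega
    t_min = (1 + np.argmin(separations)) * 0.05
    assert min(separations) == pytest.approx(9.07, abs=1e-3)
    assert t_min == pytest.approx(half_period, abs=0.05)


def test_energy_conservation_athermal_undamped(table):
    """No thermostat, no friction, no switching: energy drift < 1e-4 over 1e4 steps."""
    system = hf.apply_affine_strain(
        hf.build_hexagonal_lattice(16, 16), hf.StrainProtocol(magnitude=0.02)
    )
    config = hf.DynamicsConfig(temperature=0.0, friction=0.0, series_every=0)
    e0 = total_energy(system, table)
    result = _advance(system, table, config, n_steps=10_000, seed=0)
    assert result.switch_log == []  # 2% strain: well below any rupture
    e1 = total_energy(system, table)
    assert abs(e1 - e0) / abs(e0) < 1e-4


def test_damage_count_monotone_along_trajectory(notched_run):
    _, series, switch_log, _ = notched_run
    assert np.all(np.diff(series.n_damaged) >= 0)
    assert np.all(np.diff(series.n_broken_bonds) >= 0)
    assert len(switch_log) > 0
    steps = [s for s, _ in switch_log]
    assert steps == sorted(steps)


def test_switching_log_deterministic_per_seed(table):
    def run():
        system = hf.insert_notch(hf.build_hexagonal_lattice(30, 30), 15, 4, 2)
        protocol = hf.StrainProtocol(magnitude=0.05, hold_steps=1500)
        config = hf.DynamicsConfig(random_seed=42, series_every=100)
        _, series, switch_log, _ = hf.run_constant_strain(system, table, protocol, config)
        return switch_log, series

    log1, series1 = run()
    log2, series2 = run()
    assert log1 == log2
    assert np.array_equal(series1.sigma_xx, series2.sigma_xx)  # bit-identical


def test_grip_columns_hold_the_strained_coordinate(notched_run):
    """Grips pin the loading-axis coordinate exactly (transverse dof is free)."""
    final, _, _, _ = notched_run
    clamped = final.clamped
    assert clamped.sum() > 0
    expected_x = (final.cols * 9.17 + 0.5 * 9.17 * (final.rows % 2)) * 1.05
    assert np.abs(final.positions[clamped, 0] - expected_x[clamped]).max() < 1e-12
    assert np.abs(final.velocities[clamped, 0]).max() == 0.0


def test_instability_signal_names_block(table):
    system = hf.build_hexagonal_lattice(3, 3)
    system.velocities[4] = [1e6, 0.0]  # absurd velocity: one step exceeds r_o
    config = hf.DynamicsConfig(temperature=0.0, friction=0.0)
    with pytest.raises(InstabilityError) as err:
        hf.step(system, table, config)
    assert err.value.block_id == 4


class TestRelax:
    def test_pristine_lattice_converges_immediately(self, table):
        system = hf.build_hexagonal_lattice(10, 10)
        system, result = hf.relax(system, table, force_tolerance=1e-6)
        assert result.converged
        assert result.stopped_by == "force_tolerance"
        assert result.n_iterations == 0  # already at equilibrium
        assert system.bond_lengths().mean() == pytest.approx(9.17, abs=1e-9)

    def test_all_damaged_lattice_relaxes_to_damaged_spacing(self, table):
        system = hf.build_hexagonal_lattice(12, 12, species=hf.Species.DAMAGED)
        system, result = hf.relax(system, table, force_tolerance=1e-6)
        assert result.converged
        interior = system.interior_bond_mask()
        assert system.bond_lengths()[interior].mean() == pytest.approx(9.35, abs=1e-3)

    def test_single_block(self, table):
        system = hf.build_hexagonal_lattice(1, 1)
        system, result = hf.relax(system, table)
        assert result.converged
        assert result.max_force == 0.0


class TestRunConstantStrain:
    def test_zero_strain_zero_temperature_is_quiescent(self, table):
        system = hf.build_hexagonal_lattice(10, 10)
        protocol = hf.StrainProtocol(magnitude=0.0, hold_steps=500)
        config = hf.DynamicsConfig(temperature=0.0, friction=0.0, series_every=50)
        _, series, switch_log, _ = hf.run_constant_strain(system, table, protocol, config)
        assert np.abs(series.sigma_xx).max() < 1e-8
        assert switch_log == []

    def test_defect_free_five_percent_never_ruptures(self, table):
        """9.17 * 1.05 = 9.6285 < 9.65: without a defect nothing breaks."""
        system = hf.build_hexagonal_lattice(20, 20)
        protocol = hf.StrainProtocol(magnitude=0.05, hold_steps=2000)
        config = hf.DynamicsConfig(temperature=0.0, friction=0.1, random_seed=0, series_every=500)
        final, series, switch_log, _ = hf.run_constant_strain(system, table, protocol, config)
        assert switch_log == []
        assert int((final.bond_broken_step >= 0).sum()) == 0

    def test_notched_lattice_initiates_at_notch(self, notched_run):
        final, _, switch_log, _ = notched_run
        assert len(switch_log) > 0
        notch_center = np.array([20 * 9.17 * 1.05, 39 * 9.17 * np.sqrt(3) / 2])
        first_blocks = [b for _, b in switch_log[:10]]
        d = np.linalg.norm(final.positions[first_blocks] - notch_center, axis=1)
        assert np.all(d < 6 * 9.17)  # initiation adjacent to the notch

    def test_snapshots_and_series_cadence(self, table):
        system = hf.insert_notch(hf.build_hexagonal_lattice(12, 12), 6, 4, 2)
        protocol = hf.StrainProtocol(magnitude=0.05, hold_steps=400)
        config = hf.DynamicsConfig(
            random_seed=1, series_every=100, snapshot_every=200, temperature=0.0
        )
        _, series, _, snapshots = hf.run_constant_strain(system, table, protocol, config)
        assert list(series.steps) == [0, 100, 200, 300, 400]
        assert [s.step for s in snapshots] == [200, 400]


def test_time_step_convergence_small_notched_benchmark(table):
    """Halving dt leaves the damage count unchanged and the stress within 1%."""

    def run(dt_fs, n_steps):
        system = hf.insert_notch(hf.build_hexagonal_lattice(10, 10), 5, 4, 2)
        protocol = hf.StrainProtocol(magnitude=0.05, hold_steps=n_steps)
        config = hf.DynamicsConfig(
            time_step_fs=dt_fs,
            temperature=0.0,
            friction=0.5,
            random_seed=0,
            series_every=n_steps,
        )
        final, series, _, _ = hf.run_constant_strain(system, table, protocol, config)
        return int((final.species == 1).sum()), float(series.sigma_xx[-1])

    damaged_full, stress_full = run(350.0, 20_000)
    damaged_half, stress_half = run(175.0, 40_000)
    assert damaged_half == damaged_full
    assert abs(stress_half - stress_full) / abs(stress_full) < 0.01
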