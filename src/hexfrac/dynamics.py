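"""Langevin dynamics, damped relaxation and the strain-and-hold driver.

The equations of motion are integrated with velocity Verlet plus an
exact Ornstein-Uhlenbeck velocity update (Langevin thermostat); with
zero friction this is plain velocity Verlet and conserves energy in the
athermal limit.  The irreversible pristine->damaged switching rule is
evaluated once per step, after the position update, so each force
evaluation sees one consistent species assignment.

`relax` prepares unstrained reference states: it runs FIRE (fast
inertial relaxation engine) — damped zero-temperature dynamics with an
adaptive time step — until the largest per-block force drops below a
tolerance.  `run_constant_strain` is the loading experiment used
throughout: apply an instantaneous affine strain, then hold the clamps
fixed while the lattice relaxes, recording stress, damage and rupture
events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kernels
from .errors import InstabilityError, InvalidArgumentError
from .lattice import LatticeSystem, StrainProtocol, apply_affine_strain
from .observables import StressSeries, flag_broken_bonds, virial_stress
from .potentials import PotentialTable, Species, update_species
from .units import FS_PER_PS, KB

__all__ = [
    "DynamicsConfig",
    "Snapshot",
    "RelaxResult",
    "step",
    "relax",
    "run_constant_strain",
]


@dataclass
class DynamicsConfig:
    """Integration settings.

    ``time_step_fs`` defaults to the model's stable 350 fs step (about a
    thirtieth of the bond vibration period at the default block mass).
    ``temperature`` (K) and ``friction`` (ps^-1) parameterise the
    Langevin thermostat; zero temperature with positive friction gives a
    pure damped-relaxation mode, zero friction the microcanonical limit.
    """

    time_step_fs: float = 350.0
    n_steps: int = 0
    temperature: float = 300.0
    friction: float = 0.1
    random_seed: int = 0
    snapshot_every: int = 0
    series_every: int = 100

    def __post_init__(self):
        if self.time_step_fs <= 0:
            raise InvalidArgumentError(f"time_step_fs must be > 0, got {self.time_step_fs}")
        if self.n_steps < 0:
            raise InvalidArgumentError(f"n_steps must be >= 0, got {self.n_steps}")
        if self.temperature < 0:
            raise InvalidArgumentError(f"temperature must be >= 0, got {self.temperature}")
        if self.friction < 0:
            raise InvalidArgumentError(f"friction must be >= 0, got {self.friction}")

    @property
    def dt_ps(self) -> float:
        return self.time_step_fs / FS_PER_PS


@dataclass
class Snapshot:
    """Positions and species captured at one recorded step."""

    step: int
    time_ps: float
    positions: np.ndarray
    species: np.ndarray


@dataclass
class RelaxResult:
    converged: bool
    n_iterations: int
    max_force: float
    stopped_by: str = ""  # "force_tolerance" | "max_steps"


@dataclass
class RunResult:
    system: LatticeSystem
    series: StressSeries
    switch_log: list = field(default_factory=list)  # (step, block_id) tuples
    snapshots: list = field(default_factory=list)

    def __iter__(self):  # allow tuple-unpacking per the documented signature
        return iter((self.system, self.series, self.switch_log, self.snapshots))


def _advance(
    system: LatticeSystem,
    table: PotentialTable,
    config: DynamicsConfig,
    n_steps: int,
    seed: int,
) -> RunResult:
    """Run ``n_steps`` on ``system`` in place and collect records."""
    if system.n_bonds == 0 and system.n_blocks == 0:
        raise InvalidArgumentError("cannot integrate an empty system")
    k3, ro3, rc3 = table.as_arrays()
    dt = config.dt_ps
    kbt = KB * config.temperature
    box_x = system.box_x if system.box_x is not None else -1.0

    series_every = int(config.series_every)
    snapshot_every = int(config.snapshot_every)
    step0 = int(system.step)
    n_series_max = n_steps // series_every + 1 if series_every > 0 else 1
    n_snap_max = n_steps // snapshot_every + 1 if snapshot_every > 0 else 1
    series_steps = np.zeros(n_series_max, dtype=np.int64)
    series_data = np.zeros((n_series_max, 6))
    snap_steps = np.zeros(n_snap_max, dtype=np.int64)
    snap_pos = np.zeros((n_snap_max, system.n_blocks, 2))
    snap_species = np.zeros((n_snap_max, system.n_blocks), dtype=np.int8)
    switch_steps = np.zeros(system.n_blocks, dtype=np.int64)
    switch_blocks = np.zeros(system.n_blocks, dtype=np.int64)
    counters = np.zeros(3, dtype=np.int64)

    status, bad_block = kernels.run_langevin(
        system.positions,
        system.velocities,
        system.species,
        system.masses,
        system.clamped,
        system.frozen_mask(),
        system.bonds,
        k3,
        ro3,
        rc3,
        table.pristine.r_c,
        box_x,
        dt,
        config.friction,
        kbt,
        n_steps,
        step0,
        seed % 2**31,
        table.pristine.r_o,  # divergence threshold: one block size per step
        series_every,
        series_steps,
        series_data,
        snapshot_every,
        snap_steps,
        snap_pos,
        snap_species,
        switch_steps,
        switch_blocks,
        system.bond_broken_step,
        system.bond_broken_length,
        counters,
    )
    n_series, n_snap, n_switch = (int(c) for c in counters)
    system.step = step0 + n_steps
    system.time = system.step * dt
    if status == kernels.STATUS_UNSTABLE:
        raise InstabilityError(block_id=bad_block, step=system.step)

    series = StressSeries(
        steps=series_steps[:n_series].copy(),
        times=series_steps[:n_series] * dt,
        sigma_xx=series_data[:n_series, 0].copy(),
        sigma_yy=series_data[:n_series, 1].copy(),
        sigma_xy=series_data[:n_series, 2].copy(),
        potential_energy=series_data[:n_series, 3].copy(),
        n_damaged=series_data[:n_series, 4].astype(np.int64),
        n_broken_bonds=series_data[:n_series, 5].astype(np.int64),
    )
    snapshots = [
        Snapshot(
            step=int(snap_steps[i]),
            time_ps=float(snap_steps[i] * dt),
            positions=snap_pos[i].copy(),
            species=snap_species[i].copy(),
        )
        for i in range(n_snap)
    ]
    switch_log = [
        (int(switch_steps[i]), int(switch_blocks[i])) for i in range(n_switch)
    ]
    return RunResult(system=system, series=series, switch_log=switch_log, snapshots=snapshots)


def step(
    system: LatticeSystem, table: PotentialTable, config: DynamicsConfig
) -> LatticeSystem:
    """Advance the system by a single integration step (in place).

    The thermal noise for step ``n`` is seeded from the configured seed
    and ``n``, so repeated calls are individually deterministic.
    """
    seed = (config.random_seed * 1_000_003 + system.step + 1) % 2**31
    _advance(system, table, config, n_steps=1, seed=seed)
    return system


def relax(
    system: LatticeSystem,
    table: PotentialTable,
    config: DynamicsConfig | None = None,
    force_tolerance: float = 1e-6,
) -> tuple[LatticeSystem, RelaxResult]:
    """Damped zero-temperature relaxation to a force tolerance (FIRE).

    Runs adaptive-time-step damped dynamics until the maximum per-block
    force magnitude (kJ mol^-1 nm^-1) falls below ``force_tolerance`` or
    ``config.n_steps`` iterations are exhausted (default 200000 when the
    config leaves n_steps at 0).  Damage switching stays active during
    relaxation; clamped blocks do not move.
    """
    if force_tolerance <= 0:
        raise InvalidArgumentError(f"force_tolerance must be > 0, got {force_tolerance}")
    config = config or DynamicsConfig(temperature=0.0)
    max_steps = config.n_steps if config.n_steps > 0 else 200_000
    k3, ro3, rc3 = table.as_arrays()
    box_x = system.box_x if system.box_x is not None else -1.0

    # FIRE parameters (standard values)
    dt0 = config.dt_ps
    dt_max = 10.0 * dt0
    f_inc, f_dec = 1.1, 0.5
    alpha0, f_alpha = 0.1, 0.99
    n_min = 5
    max_move = 0.1 * system.spacing  # displacement cap per iteration

    pos = system.positions
    vel = np.zeros_like(pos)
    mass = system.masses[:, None]
    free = ~system.frozen_mask()  # per-dof: grips freeze the loading axis only
    any_free = bool(free.any())
    dt, alpha, n_pos = dt0, alpha0, 0

    def max_force(f):
        # per-block force magnitude over unconstrained dofs only
        return float(np.linalg.norm(np.where(free, f, 0.0), axis=1).max()) if any_free else 0.0

    forces, lengths, _ = kernels.compute_forces(
        pos, system.bonds, system.species, k3, ro3, rc3, box_x
    )
    max_f = max_force(forces)
    iteration = 0
    while max_f >= force_tolerance and iteration < max_steps:
        power = float((forces[free] * vel[free]).sum())
        if power > 0:
            n_pos += 1
            if n_pos > n_min:
                dt = min(dt * f_inc, dt_max)
                alpha *= f_alpha
        else:
            n_pos = 0
            dt *= f_dec
            alpha = alpha0
            vel[:] = 0.0
        vel[free] += dt * (forces / mass)[free]
        v_norm = float(np.linalg.norm(vel[free]))
        f_norm = float(np.linalg.norm(forces[free]))
        if f_norm > 0:
            vel[free] = (1.0 - alpha) * vel[free] + alpha * v_norm * forces[free] / f_norm
        move = np.clip(dt * vel, -max_move, max_move)
        pos[free] += move[free]
        update_species(system, table)
        forces, lengths, _ = kernels.compute_forces(
            pos, system.bonds, system.species, k3, ro3, rc3, box_x
        )
        max_f = max_force(forces)
        iteration += 1

    system.velocities[:] = 0.0
    converged = max_f < force_tolerance
    return system, RelaxResult(
        converged=converged,
        n_iterations=iteration,
        max_force=max_f,
        stopped_by="force_tolerance" if converged else "max_steps",
    )


def run_constant_strain(
    system: LatticeSystem,
    table: PotentialTable,
    protocol: StrainProtocol,
    config: DynamicsConfig,
) -> RunResult:
    """Strain-and-hold experiment: instantaneous strain, then relaxation.

    Applies the affine strain once, clamping the grip columns, then runs
    ``protocol.hold_steps`` Langevin steps at constant clamp positions.
    Stress rows (including one at the moment of loading), snapshots and
    every switching event are recorded; the run is deterministic for a
    given ``config.random_seed``.
    """
    if protocol.mode != "instantaneous":
        raise InvalidArgumentError("only instantaneous strain application is supported")
    strained = apply_affine_strain(system, protocol)
    # register damage/ruptures caused by the loading itself before dynamics
    update_species(strained, table)
    flag_broken_bonds(strained, table)
    k3, ro3, rc3 = table.as_arrays()
    box_x = strained.box_x if strained.box_x is not None else -1.0
    _, _, pe0 = kernels.compute_forces(
        strained.positions, strained.bonds, strained.species, k3, ro3, rc3, box_x
    )
    sigma0 = virial_stress(strained, table)
    row0 = StressSeries(
        steps=np.array([strained.step], dtype=np.int64),
        times=np.array([strained.step * config.dt_ps]),
        sigma_xx=np.array([sigma0[0, 0]]),
        sigma_yy=np.array([sigma0[1, 1]]),
        sigma_xy=np.array([sigma0[0, 1]]),
        potential_energy=np.array([pe0]),
        n_damaged=np.array([int((strained.species == int(Species.DAMAGED)).sum())]),
        n_broken_bonds=np.array([int((strained.bond_broken_step >= 0).sum())]),
    )
    result = _advance(
        strained, table, config, n_steps=protocol.hold_steps, seed=config.random_seed
    )
    result.series = StressSeries.concatenate([row0, result.series])
    return result
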