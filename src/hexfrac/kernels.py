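"""Numba-compiled inner loops for force evaluation and Langevin dynamics.

All kernels work on plain arrays; the object-level API lives in
:mod:`hexfrac.dynamics`.  Species enter through the per-bond type index
``species[i] + species[j]`` (0 = P-P, 1 = P-D, 2 = D-D), matching
:meth:`hexfrac.potentials.PotentialTable.as_arrays`.

The integrator is velocity Verlet with an end-of-step Ornstein-Uhlenbeck
(Langevin) velocity update; at zero friction it reduces exactly to plain
velocity Verlet, so the athermal undamped limit conserves energy.  Damage
switching and rupture bookkeeping run once per step, after the position
update and before the new force evaluation, so every force evaluation
sees a single consistent species assignment.
"""

import numpy as np
from numba import njit

#: status codes returned by :func:`run_langevin`
STATUS_OK = 0
STATUS_UNSTABLE = 1


@njit(cache=False)
def bond_geometry(pos, bonds, box_x, dx_out, dy_out, r_out):
    """Minimum-image bond vectors x_i - x_j and lengths."""
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        if box_x > 0.0:
            dx -= box_x * np.round(dx / box_x)
        dx_out[b] = dx
        dy_out[b] = dy
        r_out[b] = np.sqrt(dx * dx + dy * dy)


@njit(cache=False)
def accumulate_forces(bonds, species, dx, dy, r, k3, ro3, rc3, forces):
    """Fill per-block forces from truncated-harmonic bonds; return potential energy."""
    forces[:] = 0.0
    pe = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        t = species[i] + species[j]
        k = k3[t]
        ro = ro3[t]
        rc = rc3[t]
        rb = r[b]
        if rb <= rc:
            d = rb - ro
            w = rc - ro
            pe += k * (d * d - w * w)
            fmag = -2.0 * k * d  # positive = repulsive
            fx = fmag * dx[b] / rb
            fy = fmag * dy[b] / rb
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[j, 0] -= fx
            forces[j, 1] -= fy
    return pe


@njit(cache=False)
def compute_forces(pos, bonds, species, k3, ro3, rc3, box_x):
    """Convenience one-shot force evaluation: (forces, lengths, potential energy)."""
    n_bonds = bonds.shape[0]
    dx = np.empty(n_bonds)
    dy = np.empty(n_bonds)
    r = np.empty(n_bonds)
    forces = np.zeros((pos.shape[0], 2))
    bond_geometry(pos, bonds, box_x, dx, dy, r)
    pe = accumulate_forces(bonds, species, dx, dy, r, k3, ro3, rc3, forces)
    return forces, r, pe


@njit(cache=False)
def _virial(bonds, species, dx, dy, r, k3, ro3, rc3, vel, masses, clamped):
    """2-D virial stress sums (not yet divided by area): (sxx, syy, sxy).

    Bond term: sum over bonds of r_a F_b with F the force on block i and
    r = x_i - x_j; kinetic term: sum of m v_a v_b over non-clamped blocks.
    """
    sxx = 0.0
    syy = 0.0
    sxy = 0.0
    for b in range(bonds.shape[0]):
        t = species[bonds[b, 0]] + species[bonds[b, 1]]
        rb = r[b]
        if rb <= rc3[t]:
            fmag = -2.0 * k3[t] * (rb - ro3[t])
            fx = fmag * dx[b] / rb
            fy = fmag * dy[b] / rb
            sxx += dx[b] * fx
            syy += dy[b] * fy
            sxy += dx[b] * fy
    for i in range(vel.shape[0]):
        if not clamped[i]:
            m = masses[i]
            sxx += m * vel[i, 0] * vel[i, 0]
            syy += m * vel[i, 1] * vel[i, 1]
            sxy += m * vel[i, 0] * vel[i, 1]
    return sxx, syy, sxy


@njit(cache=False)
def _sample_area(pos, box_x):
    xmin = pos[0, 0]
    xmax = pos[0, 0]
    ymin = pos[0, 1]
    ymax = pos[0, 1]
    for i in range(pos.shape[0]):
        if pos[i, 0] < xmin:
            xmin = pos[i, 0]
        if pos[i, 0] > xmax:
            xmax = pos[i, 0]
        if pos[i, 1] < ymin:
            ymin = pos[i, 1]
        if pos[i, 1] > ymax:
            ymax = pos[i, 1]
    width = box_x if box_x > 0.0 else xmax - xmin
    return width * (ymax - ymin)


@njit(cache=False)
def run_langevin(
    pos,
    vel,
    species,
    masses,
    clamped,
    frozen,
    bonds,
    k3,
    ro3,
    rc3,
    rc_switch,
    box_x,
    dt,
    friction,
    kbt,
    n_steps,
    step0,
    seed,
    max_disp,
    series_every,
    series_steps,
    series_data,
    snapshot_every,
    snap_steps,
    snap_pos,
    snap_species,
    switch_steps,
    switch_blocks,
    bond_broken_step,
    bond_broken_length,
    counters,
):
    """Advance ``n_steps`` of damped/thermostatted dynamics in place.

    Per step: half-kick, drift (with divergence check), damage switching
    on the new geometry, rupture bookkeeping, force evaluation, second
    half-kick, then the exact Ornstein-Uhlenbeck velocity update when the
    friction is positive.  ``frozen`` is an (N, 2) per-dof mask: grip
    (clamped) blocks have their loading-axis coordinate frozen while the
    transverse coordinate evolves freely; ``clamped`` marks whole grip
    blocks for the kinetic-virial exclusion.  Series rows (step, time,
    sxx, syy, sxy, pe, n_damaged,
    n_broken) are written every ``series_every`` steps, position/species
    snapshots every ``snapshot_every`` steps, and every switching event is
    appended to ``switch_steps``/``switch_blocks``.

    Returns (status, offending_block); counters[0:3] hold the number of
    series rows, snapshots and switch events written.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n_bonds = bonds.shape[0]
    dx = np.empty(n_bonds)
    dy = np.empty(n_bonds)
    r = np.empty(n_bonds)
    forces = np.zeros((n, 2))

    bond_geometry(pos, bonds, box_x, dx, dy, r)
    accumulate_forces(bonds, species, dx, dy, r, k3, ro3, rc3, forces)

    c1 = np.exp(-friction * dt) if friction > 0.0 else 1.0
    noise_var = kbt * (1.0 - c1 * c1)

    n_series = 0
    n_snap = 0
    n_switch = 0

    n_damaged = 0
    for i in range(n):
        n_damaged += species[i]
    n_broken = 0
    for b in range(n_bonds):
        if bond_broken_step[b] >= 0:
            n_broken += 1

    for s in range(n_steps):
        step = step0 + s + 1
        # B: first half-kick
        for i in range(n):
            inv_m = 1.0 / masses[i]
            if not frozen[i, 0]:
                vel[i, 0] += 0.5 * dt * forces[i, 0] * inv_m
            if not frozen[i, 1]:
                vel[i, 1] += 0.5 * dt * forces[i, 1] * inv_m
        # A: drift with divergence check
        for i in range(n):
            for d in range(2):
                if not frozen[i, d]:
                    dd = dt * vel[i, d]
                    if abs(dd) > max_disp:
                        counters[0] = n_series
                        counters[1] = n_snap
                        counters[2] = n_switch
                        return STATUS_UNSTABLE, i
                    pos[i, d] += dd
        # geometry on new positions; switching before the force evaluation
        bond_geometry(pos, bonds, box_x, dx, dy, r)
        for b in range(n_bonds):
            if r[b] >= rc_switch:
                for e in range(2):
                    blk = bonds[b, e]
                    if species[blk] == 0:
                        species[blk] = 1
                        switch_steps[n_switch] = step
                        switch_blocks[n_switch] = blk
                        n_switch += 1
                        n_damaged += 1
        # rupture bookkeeping with the updated species
        for b in range(n_bonds):
            if bond_broken_step[b] < 0:
                t = species[bonds[b, 0]] + species[bonds[b, 1]]
                if r[b] >= rc3[t]:
                    bond_broken_step[b] = step
                    bond_broken_length[b] = r[b]
                    n_broken += 1
        # force evaluation and second half-kick
        pe = accumulate_forces(bonds, species, dx, dy, r, k3, ro3, rc3, forces)
        for i in range(n):
            inv_m = 1.0 / masses[i]
            if not frozen[i, 0]:
                vel[i, 0] += 0.5 * dt * forces[i, 0] * inv_m
            if not frozen[i, 1]:
                vel[i, 1] += 0.5 * dt * forces[i, 1] * inv_m
        # O: Ornstein-Uhlenbeck velocity update
        if friction > 0.0:
            for i in range(n):
                sd = np.sqrt(noise_var / masses[i])
                if not frozen[i, 0]:
                    vel[i, 0] = c1 * vel[i, 0] + sd * np.random.normal()
                if not frozen[i, 1]:
                    vel[i, 1] = c1 * vel[i, 1] + sd * np.random.normal()
        # recording
        if series_every > 0 and step % series_every == 0:
            sxx, syy, sxy = _virial(
                bonds, species, dx, dy, r, k3, ro3, rc3, vel, masses, clamped
            )
            area = _sample_area(pos, box_x)
            if area <= 0.0:  # degenerate (e.g. single-row) geometry
                area = np.nan
            series_steps[n_series] = step
            series_data[n_series, 0] = sxx / area
            series_data[n_series, 1] = syy / area
            series_data[n_series, 2] = sxy / area
            series_data[n_series, 3] = pe
            series_data[n_series, 4] = n_damaged
            series_data[n_series, 5] = n_broken
            n_series += 1
        if snapshot_every > 0 and step % snapshot_every == 0:
            snap_steps[n_snap] = step
            for i in range(n):
                snap_pos[n_snap, i, 0] = pos[i, 0]
                snap_pos[n_snap, i, 1] = pos[i, 1]
                snap_species[n_snap, i] = species[i]
            n_snap += 1

    counters[0] = n_series
    counters[1] = n_snap
    counters[2] = n_switch
    return STATUS_OK, -1
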