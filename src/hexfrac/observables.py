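"""Stress, rupture detection, micro-crack clustering and decay fitting.

Stress is the 2-D virial stress (force-per-length units,
kJ mol^-1 nm^-2): bond term ``sum r_a F_b`` plus kinetic term
``sum m v_a v_b`` over non-clamped blocks, divided by the current sample
area.  With this sign convention tension appears as negative sigma_xx
(the attractive restoring forces of stretched bonds dominate); the
relaxation analyses below therefore work with magnitudes.

A micro-crack is a connected cluster of broken bonds: bonds are broken
once their length reaches the rupture cutoff of their resolved
potential, and two broken bonds belong to the same crack when they share
a block or their midpoints lie within one lattice spacing (which keeps a
bifurcated crack connected as one branched cluster).  A cluster whose
transverse extent covers the full free sample height percolates —
material failure under horizontal tension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .errors import FitFailureError, InvalidArgumentError, InvalidStateError
from .lattice import LatticeSystem
from .potentials import PotentialTable

__all__ = [
    "StressSeries",
    "BrokenBond",
    "CrackReport",
    "ExpDecayFit",
    "virial_stress",
    "detect_broken_bonds",
    "flag_broken_bonds",
    "cluster_cracks",
    "fit_exponential_decay",
]


@dataclass
class StressSeries:
    """Time-resolved virial stress record from a relaxation run."""

    steps: np.ndarray
    times: np.ndarray  # ps
    sigma_xx: np.ndarray
    sigma_yy: np.ndarray
    sigma_xy: np.ndarray
    potential_energy: np.ndarray | None = None
    n_damaged: np.ndarray | None = None
    n_broken_bonds: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.times)
        for name in ("steps", "sigma_xx", "sigma_yy", "sigma_xy"):
            if len(getattr(self, name)) != n:
                raise InvalidArgumentError(f"series field {name} has mismatched length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidArgumentError("series times must be strictly increasing")

    def __len__(self):
        return len(self.times)

    def component(self, label: str) -> np.ndarray:
        try:
            return getattr(self, label)
        except AttributeError:
            raise InvalidArgumentError(f"unknown stress component {label!r}") from None

    def to_frame(self):
        """The series as a pandas DataFrame (column names match the CSV schema)."""
        import pandas as pd

        data = {
            "step": self.steps,
            "time_ps": self.times,
            "sigma_xx": self.sigma_xx,
            "sigma_yy": self.sigma_yy,
            "sigma_xy": self.sigma_xy,
        }
        if self.potential_energy is not None:
            data["potential_energy"] = self.potential_energy
        if self.n_damaged is not None:
            data["n_damaged"] = self.n_damaged
        if self.n_broken_bonds is not None:
            data["n_broken_bonds"] = self.n_broken_bonds
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame) -> "StressSeries":
        def col(name):
            return frame[name].to_numpy() if name in frame else None

        return cls(
            steps=frame["step"].to_numpy(),
            times=frame["time_ps"].to_numpy(),
            sigma_xx=frame["sigma_xx"].to_numpy(),
            sigma_yy=frame["sigma_yy"].to_numpy(),
            sigma_xy=frame["sigma_xy"].to_numpy(),
            potential_energy=col("potential_energy"),
            n_damaged=col("n_damaged"),
            n_broken_bonds=col("n_broken_bonds"),
        )

    @classmethod
    def concatenate(cls, parts: list["StressSeries"]) -> "StressSeries":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls(*(np.empty(0) for _ in range(5)))

        def cat(name):
            vals = [getattr(p, name) for p in parts]
            return None if any(v is None for v in vals) else np.concatenate(vals)

        return cls(
            steps=np.concatenate([p.steps for p in parts]),
            times=np.concatenate([p.times for p in parts]),
            sigma_xx=np.concatenate([p.sigma_xx for p in parts]),
            sigma_yy=np.concatenate([p.sigma_yy for p in parts]),
            sigma_xy=np.concatenate([p.sigma_xy for p in parts]),
            potential_energy=cat("potential_energy"),
            n_damaged=cat("n_damaged"),
            n_broken_bonds=cat("n_broken_bonds"),
        )


@dataclass(frozen=True)
class BrokenBond:
    """One ruptured bond: topology index, block pair, length, first step seen."""

    bond_index: int
    pair: tuple[int, int]
    length: float
    first_step: int


@dataclass
class CrackReport:
    """Micro-crack clusters of broken bonds and their percolation status."""

    broken_bonds: list[BrokenBond]
    clusters: list[set]  # sets of bond indices into `broken_bonds`
    cluster_extents: list[tuple[float, float]]  # (x span, y span) nm
    spans_longitudinal: list[bool]  # covers clamped-edge-to-clamped-edge width
    spans_transverse: list[bool]  # covers free-surface-to-free-surface height
    percolates: bool
    sample_width: float = 0.0
    sample_height: float = 0.0

    @property
    def n_broken(self) -> int:
        return len(self.broken_bonds)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def to_dict(self) -> dict:
        return {
            "n_broken_bonds": self.n_broken,
            "n_clusters": self.n_clusters,
            "percolates": self.percolates,
            "sample_width_nm": self.sample_width,
            "sample_height_nm": self.sample_height,
            "clusters": [
                {
                    "bonds": sorted(int(b) for b in members),
                    "extent_x_nm": ext[0],
                    "extent_y_nm": ext[1],
                    "spans_longitudinal": bool(sl),
                    "spans_transverse": bool(st),
                }
                for members, ext, sl, st in zip(
                    self.clusters,
                    self.cluster_extents,
                    self.spans_longitudinal,
                    self.spans_transverse,
                )
            ],
            "broken_bonds": [
                {
                    "bond_index": bb.bond_index,
                    "i": bb.pair[0],
                    "j": bb.pair[1],
                    "length_nm": bb.length,
                    "first_step": bb.first_step,
                }
                for bb in self.broken_bonds
            ],
        }


def virial_stress(system: LatticeSystem, table: PotentialTable) -> np.ndarray:
    """Instantaneous 2-D virial stress tensor, kJ mol^-1 nm^-2.

    sigma_ab = (1/A) [ sum_bonds r_a F_b + sum_blocks m v_a v_b ], with the
    bond vector r = x_i - x_j, F the force on block i, the kinetic sum over
    non-clamped blocks and A the current bounding-box sample area.
    """
    width, height = system.extent()
    area = width * height
    if area <= 0:
        raise InvalidStateError("sample area is degenerate (zero extent)")
    k3, ro3, rc3 = table.as_arrays()
    sigma = np.zeros((2, 2))
    if system.n_bonds:
        d = system.bond_vectors()
        r = np.linalg.norm(d, axis=1)
        t = system.species[system.bonds[:, 0]].astype(np.int64) + system.species[
            system.bonds[:, 1]
        ].astype(np.int64)
        intact = r <= rc3[t]
        fmag = np.where(intact, -2.0 * k3[t] * (r - ro3[t]), 0.0)
        f = fmag[:, None] * d / r[:, None]
        sigma += np.einsum("ba,bc->ac", d, f)
    free = ~system.clamped
    v = system.velocities[free]
    m = system.masses[free]
    sigma += np.einsum("b,ba,bc->ac", m, v, v)
    sigma /= area
    return 0.5 * (sigma + sigma.T)  # symmetrise against roundoff


def flag_broken_bonds(system: LatticeSystem, table: PotentialTable) -> LatticeSystem:
    """Update the monotone first-rupture bookkeeping on ``system`` in place.

    A bond is broken iff its current length is at least the rupture
    cutoff of its resolved (current-species) potential; once flagged it
    stays flagged (no self-healing).
    """
    if system.n_bonds == 0:
        return system
    _, _, rc3 = table.as_arrays()
    r = system.bond_lengths()
    t = system.species[system.bonds[:, 0]].astype(np.int64) + system.species[
        system.bonds[:, 1]
    ].astype(np.int64)
    newly = (r >= rc3[t]) & (system.bond_broken_step < 0)
    system.bond_broken_step[newly] = system.step
    system.bond_broken_length[newly] = r[newly]
    return system


def detect_broken_bonds(
    system: LatticeSystem, table: PotentialTable
) -> list[BrokenBond]:
    """All bonds ever observed at or beyond their rupture cutoff.

    Merges the run's monotone bookkeeping with a fresh detection pass on
    the current geometry, so it works both on live trajectories and on a
    single static snapshot.
    """
    flag_broken_bonds(system, table)
    idx = np.flatnonzero(system.bond_broken_step >= 0)
    return [
        BrokenBond(
            bond_index=int(b),
            pair=(int(system.bonds[b, 0]), int(system.bonds[b, 1])),
            length=float(system.bond_broken_length[b]),
            first_step=int(system.bond_broken_step[b]),
        )
        for b in idx
    ]


class _UnionFind:
    """Union-find with path compression and union by size."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, a: int) -> int:
        root = a
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[a] != root:  # path compression
            self.parent[a], a = root, self.parent[a]
        return root

    def union(self, a: int, b: int):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def cluster_cracks(
    broken_bonds: list[BrokenBond], system: LatticeSystem
) -> CrackReport:
    """Group broken bonds into micro-crack clusters and test percolation.

    Two broken bonds are connected iff they share a block or their
    midpoints lie within one lattice spacing; connected components are
    found by union-find, so the result is independent of input order.  A
    cluster spans an axis when its bounding extent along that axis covers
    the sample extent minus one spacing (a crack path through bond
    midpoints cannot reach further than the outermost block centres).
    """
    width, height = system.extent() if system.n_blocks else (0.0, 0.0)
    if not broken_bonds:
        return CrackReport(
            broken_bonds=[],
            clusters=[],
            cluster_extents=[],
            spans_longitudinal=[],
            spans_transverse=[],
            percolates=False,
            sample_width=width,
            sample_height=height,
        )
    # canonical ordering so the report itself is order-independent
    broken = sorted(broken_bonds, key=lambda bb: bb.bond_index)
    n = len(broken)
    ends = np.array([bb.pair for bb in broken], dtype=np.int64)
    p_i = system.positions[ends[:, 0]]
    p_j = system.positions[ends[:, 1]]
    mid = 0.5 * (p_i + p_j)

    uf = _UnionFind(n)
    # shared-block adjacency
    by_block: dict[int, list[int]] = {}
    for a, (i, j) in enumerate(ends):
        by_block.setdefault(int(i), []).append(a)
        by_block.setdefault(int(j), []).append(a)
    for members in by_block.values():
        for other in members[1:]:
            uf.union(members[0], other)
    # midpoint proximity within one lattice spacing
    tree = cKDTree(mid)
    for a, b in tree.query_pairs(system.spacing * (1 + 1e-9)):
        uf.union(a, b)

    groups: dict[int, list[int]] = {}
    for a in range(n):
        groups.setdefault(uf.find(a), []).append(a)

    clusters, extents, spans_l, spans_t = [], [], [], []
    tol = system.spacing
    for members in groups.values():
        pts = np.vstack([p_i[members], p_j[members]])
        span = pts.max(axis=0) - pts.min(axis=0)
        clusters.append({broken[a].bond_index for a in members})
        extents.append((float(span[0]), float(span[1])))
        spans_l.append(bool(span[0] >= width - tol))
        spans_t.append(bool(span[1] >= height - tol))
    order = np.argsort([-len(c) for c in clusters], kind="stable")
    clusters = [clusters[i] for i in order]
    extents = [extents[i] for i in order]
    spans_l = [spans_l[i] for i in order]
    spans_t = [spans_t[i] for i in order]
    return CrackReport(
        broken_bonds=broken,
        clusters=clusters,
        cluster_extents=extents,
        spans_longitudinal=spans_l,
        spans_transverse=spans_t,
        percolates=bool(any(spans_t)),
        sample_width=width,
        sample_height=height,
    )


@dataclass
class ExpDecayFit:
    """Parameters of sigma(t) = offset + amplitude * exp(-t / tau)."""

    amplitude: float
    tau: float
    offset: float
    r_squared: float
    degenerate: bool = False
    residuals: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def fit_exponential_decay(
    series: StressSeries, component: str = "sigma_xx"
) -> ExpDecayFit:
    """Least-squares exponential-decay fit of one stress component.

    Fits ``offset + amplitude * exp(-t/tau)`` with ``tau > 0`` enforced by
    bounds; R^2 is computed on the raw (not log-transformed) series, so a
    near-zero offset poses no problem.  A constant series yields a
    degenerate fit flagged as such rather than an error; genuine solver
    non-convergence raises :class:`FitFailureError` with residuals.
    """
    y = np.asarray(series.component(component), dtype=float)
    t = np.asarray(series.times, dtype=float)
    if len(y) < 10:
        raise InvalidArgumentError(f"need >= 10 samples to fit, got {len(y)}")
    t0 = t - t[0]
    span = float(np.ptp(y))
    if span == 0 or span < 1e-12 * max(1.0, abs(y).max()):
        return ExpDecayFit(
            amplitude=0.0,
            tau=np.inf,
            offset=float(y.mean()),
            r_squared=0.0,
            degenerate=True,
            residuals=y - y.mean(),
        )

    def model(tt, amp, tau, off):
        return off + amp * np.exp(-tt / tau)

    t_span = float(t0[-1]) if t0[-1] > 0 else 1.0
    p0 = (float(y[0] - y[-1]), t_span / 5.0, float(y[-1]))
    try:
        popt, _ = curve_fit(
            model,
            t0,
            y,
            p0=p0,
            bounds=([-np.inf, 1e-12 * t_span, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20_000,
        )
    except RuntimeError as exc:
        resid = y - model(t0, *p0)
        raise FitFailureError(f"exponential fit did not converge: {exc}", residuals=resid)
    resid = y - model(t0, *popt)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return ExpDecayFit(
        amplitude=float(popt[0]),
        tau=float(popt[1]),
        offset=float(popt[2]),
        r_squared=r2,
        residuals=resid,
    )
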