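"""Hexagonally packed 2-D block arrays, notch defects and affine strain.

Blocks sit on a triangular (hexagonally packed) lattice in the xy plane:
row ``j`` is offset by half a spacing in x when ``j`` is odd and rows are
``spacing * sqrt(3)/2`` apart, so every interior block has six nearest
neighbours at exactly one spacing.  The origin is the lower-left block of
the unstrained lattice; x is the loading (horizontal) axis, y transverse.

Boundary conditions are displacement-controlled grips: the leftmost and
rightmost block columns are clamped at their strained positions while the
top and bottom surfaces stay free (a surface notch acts as crack
initiator there).  Periodic horizontal boundaries are available as a
configuration option for bulk-like runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError
from .potentials import Species

__all__ = [
    "BlockState",
    "NotchSpec",
    "LatticeSystem",
    "StrainProtocol",
    "build_hexagonal_lattice",
    "insert_notch",
    "apply_affine_strain",
]

ROW_PITCH_FACTOR = np.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class BlockState:
    """Read-only view of a single building block."""

    identifier: int
    position: np.ndarray
    velocity: np.ndarray
    species: Species
    mass: float


@dataclass(frozen=True)
class NotchSpec:
    center_col: int
    width_blocks: int
    depth_rows: int


@dataclass
class StrainProtocol:
    """Instantaneous affine deformation held for a fixed number of steps."""

    axis: str = "horizontal"
    magnitude: float = 0.05
    mode: str = "instantaneous"
    hold_steps: int = 0

    def __post_init__(self):
        if self.axis not in ("horizontal", "vertical"):
            raise InvalidArgumentError(f"axis must be horizontal|vertical, got {self.axis!r}")
        if self.mode != "instantaneous":
            raise InvalidArgumentError(f"only instantaneous mode is supported, got {self.mode!r}")
        if self.magnitude < 0:
            raise InvalidArgumentError(f"strain magnitude must be >= 0, got {self.magnitude}")
        if self.hold_steps < 0:
            raise InvalidArgumentError(f"hold_steps must be >= 0, got {self.hold_steps}")


@dataclass
class LatticeSystem:
    """State of a block lattice: positions, species, bonds and boundary.

    Arrays are the authoritative state (``positions`` (N,2) nm,
    ``velocities`` (N,2) nm/ps, ``species`` (N,) 0/1, ``masses`` (N,) u,
    ``bonds`` (M,2) block ids).  ``bond_broken_step`` / ``bond_broken_length``
    carry the monotone first-rupture bookkeeping (-1 / nan = never broken).
    ``box_x`` is the periodic x extent, or None for clamped grips.
    """

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    masses: np.ndarray
    bonds: np.ndarray
    clamped: np.ndarray
    cols: np.ndarray
    rows: np.ndarray
    n_cols: int
    n_rows: int
    spacing: float
    box_x: float | None = None
    applied_strain: float = 0.0
    strain_axis: str = "horizontal"
    time: float = 0.0
    step: int = 0
    notch: NotchSpec | None = None
    bond_broken_step: np.ndarray = field(default=None)  # type: ignore[assignment]
    bond_broken_length: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.bond_broken_step is None:
            self.bond_broken_step = np.full(len(self.bonds), -1, dtype=np.int64)
        if self.bond_broken_length is None:
            self.bond_broken_length = np.full(len(self.bonds), np.nan)

    # -- basic queries ---------------------------------------------------
    @property
    def n_blocks(self) -> int:
        return len(self.positions)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def block(self, i: int) -> BlockState:
        return BlockState(
            identifier=i,
            position=self.positions[i].copy(),
            velocity=self.velocities[i].copy(),
            species=Species(int(self.species[i])),
            mass=float(self.masses[i]),
        )

    def bond_vectors(self) -> np.ndarray:
        """Minimum-image bond vectors x_i - x_j, shape (M, 2)."""
        d = self.positions[self.bonds[:, 0]] - self.positions[self.bonds[:, 1]]
        if self.box_x is not None:
            d[:, 0] -= self.box_x * np.round(d[:, 0] / self.box_x)
        return d

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.bond_vectors(), axis=1)

    def coordination(self) -> np.ndarray:
        """Number of bonds per block."""
        counts = np.zeros(self.n_blocks, dtype=np.int64)
        if self.n_bonds:
            np.add.at(counts, self.bonds.ravel(), 1)
        return counts

    def interior_bond_mask(self) -> np.ndarray:
        """Bonds whose both endpoints are 6-coordinated (interior) blocks."""
        coord = self.coordination()
        return (coord[self.bonds[:, 0]] == 6) & (coord[self.bonds[:, 1]] == 6)

    def frozen_mask(self) -> np.ndarray:
        """(N, 2) per-dof constraint mask: grips freeze the strain-axis dof only."""
        frozen = np.zeros((self.n_blocks, 2), dtype=bool)
        axis = 0 if self.strain_axis == "horizontal" else 1
        frozen[self.clamped, axis] = True
        return frozen

    def extent(self) -> tuple[float, float]:
        """(width, height) of the block bounding box; width = box_x if periodic."""
        lo = self.positions.min(axis=0)
        hi = self.positions.max(axis=0)
        width = self.box_x if self.box_x is not None else hi[0] - lo[0]
        return float(width), float(hi[1] - lo[1])

    def copy(self) -> "LatticeSystem":
        return replace(
            self,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            masses=self.masses.copy(),
            bonds=self.bonds.copy(),
            clamped=self.clamped.copy(),
            cols=self.cols.copy(),
            rows=self.rows.copy(),
            bond_broken_step=self.bond_broken_step.copy(),
            bond_broken_length=self.bond_broken_length.copy(),
        )

    def validate(self):
        if self.n_bonds:
            if np.any(self.bonds[:, 0] == self.bonds[:, 1]):
                raise InvalidArgumentError("a bond pairs a block with itself")
            key = np.sort(self.bonds, axis=1)
            if len(np.unique(key, axis=0)) != self.n_bonds:
                raise InvalidArgumentError("duplicate bonds present")
            if self.bonds.min() < 0 or self.bonds.max() >= self.n_blocks:
                raise InvalidArgumentError("bond references a nonexistent block")
        if np.any(self.masses <= 0):
            raise InvalidArgumentError("block masses must be positive")
        return self


#: Default block mass: order-of-magnitude mass of 10x10x10 hydroxyapatite
#: unit cells plus one collagen triple-helix, in u.  With the pristine
#: spring constant this puts the bond vibration period near 10.6 ps, i.e.
#: about thirty 350 fs time steps.
DEFAULT_BLOCK_MASS = 1.0e6


def build_hexagonal_lattice(
    n_cols: int,
    n_rows: int,
    spacing: float = 9.17,
    species: Species = Species.PRISTINE,
    mass: float = DEFAULT_BLOCK_MASS,
    periodic_x: bool = False,
) -> LatticeSystem:
    """Construct an ``n_cols x n_rows`` hexagonally packed block lattice.

    Odd rows are offset by ``spacing/2``; the row pitch is
    ``spacing*sqrt(3)/2``.  All nearest-neighbour pairs at one spacing are
    bonded; velocities start at zero and no column is clamped until a
    strain protocol is applied.  With ``periodic_x`` the lattice wraps in
    x (requires even ``n_cols`` so the offset pattern closes).
    """
    if n_cols < 1 or n_rows < 1:
        raise InvalidArgumentError(f"lattice dimensions must be >= 1, got {n_cols}x{n_rows}")
    if spacing <= 0:
        raise InvalidArgumentError(f"spacing must be positive, got {spacing}")
    if mass <= 0:
        raise InvalidArgumentError(f"mass must be positive, got {mass}")
    if periodic_x and n_cols % 2:
        raise InvalidArgumentError("periodic_x requires an even number of columns")

    species = Species.from_label(species)
    jj, ii = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    cols = ii.ravel()
    rows = jj.ravel()
    x = cols * spacing + 0.5 * spacing * (rows % 2)
    y = rows * spacing * ROW_PITCH_FACTOR
    positions = np.column_stack([x, y]).astype(float)

    def bid(c, r):
        return r * n_cols + c

    bonds = []
    for r in range(n_rows):
        odd = r % 2
        for c in range(n_cols):
            i = bid(c, r)
            # right neighbour
            if c + 1 < n_cols:
                bonds.append((i, bid(c + 1, r)))
            elif periodic_x:
                bonds.append((i, bid(0, r)))
            # two upward neighbours, parity-dependent
            if r + 1 < n_rows:
                ups = (c, c + 1) if odd else (c - 1, c)
                for cu in ups:
                    if 0 <= cu < n_cols:
                        bonds.append((i, bid(cu, r + 1)))
                    elif periodic_x:
                        bonds.append((i, bid(cu % n_cols, r + 1)))
    bond_arr = (
        np.array(bonds, dtype=np.int64) if bonds else np.empty((0, 2), dtype=np.int64)
    )

    return LatticeSystem(
        positions=positions,
        velocities=np.zeros_like(positions),
        species=np.full(len(positions), int(species), dtype=np.int8),
        masses=np.full(len(positions), float(mass)),
        bonds=bond_arr,
        clamped=np.zeros(len(positions), dtype=bool),
        cols=cols.astype(np.int64),
        rows=rows.astype(np.int64),
        n_cols=n_cols,
        n_rows=n_rows,
        spacing=float(spacing),
        box_x=n_cols * spacing if periodic_x else None,
    ).validate()


def insert_notch(
    system: LatticeSystem,
    center_col: int,
    width_blocks: int = 4,
    depth_rows: int = 2,
) -> LatticeSystem:
    """Cut a rectangular notch into the top (free) surface.

    Removes ``width_blocks`` columns of blocks, centred on ``center_col``,
    from the top ``depth_rows`` rows, together with their bonds, and
    re-indexes the remaining blocks contiguously.  A zero-size notch is
    the identity.
    """
    if width_blocks < 0 or depth_rows < 0:
        raise InvalidArgumentError("notch width and depth must be >= 0")
    if width_blocks == 0 or depth_rows == 0:
        out = system.copy()
        out.notch = NotchSpec(center_col, width_blocks, depth_rows)
        return out
    c_lo = center_col - width_blocks // 2
    c_hi = c_lo + width_blocks  # exclusive
    if c_lo < 0 or c_hi > system.n_cols or depth_rows > system.n_rows:
        raise InvalidArgumentError(
            f"notch cols [{c_lo},{c_hi}) depth {depth_rows} exceeds "
            f"{system.n_cols}x{system.n_rows} lattice bounds"
        )
    r_lo = system.n_rows - depth_rows
    remove = (system.cols >= c_lo) & (system.cols < c_hi) & (system.rows >= r_lo)
    keep = ~remove
    new_index = np.cumsum(keep) - 1  # old id -> new id where kept

    bond_keep = keep[system.bonds[:, 0]] & keep[system.bonds[:, 1]]
    new_bonds = new_index[system.bonds[bond_keep]]

    return LatticeSystem(
        positions=system.positions[keep].copy(),
        velocities=system.velocities[keep].copy(),
        species=system.species[keep].copy(),
        masses=system.masses[keep].copy(),
        bonds=new_bonds.astype(np.int64),
        clamped=system.clamped[keep].copy(),
        cols=system.cols[keep].copy(),
        rows=system.rows[keep].copy(),
        n_cols=system.n_cols,
        n_rows=system.n_rows,
        spacing=system.spacing,
        box_x=system.box_x,
        applied_strain=system.applied_strain,
        strain_axis=system.strain_axis,
        time=system.time,
        step=system.step,
        notch=NotchSpec(center_col, width_blocks, depth_rows),
        bond_broken_step=system.bond_broken_step[bond_keep].copy(),
        bond_broken_length=system.bond_broken_length[bond_keep].copy(),
    ).validate()


def apply_affine_strain(system: LatticeSystem, protocol: StrainProtocol) -> LatticeSystem:
    """Scale every coordinate along the protocol axis by ``1 + strain``.

    The scaling is taken about the sample's minimum edge along that axis.
    With clamped boundaries the two extreme block columns (horizontal
    axis) or rows (vertical axis) become displacement-controlled grips:
    their loading-axis coordinate is held at the strained value while the
    transverse coordinate stays free (rigid two-axis grips would forbid
    Poisson contraction and nucleate spurious corner damage).  With
    periodic x the box length is scaled instead.  Strains above 20% are
    outside the model's intended range and raise a warning.
    """
    eps = protocol.magnitude
    if eps > 0.2:
        warnings.warn(
            f"strain {eps} exceeds the intended validity range (<= 0.2)", stacklevel=2
        )
    out = system.copy()
    ax = 0 if protocol.axis == "horizontal" else 1
    origin = out.positions[:, ax].min()
    out.positions[:, ax] = origin + (out.positions[:, ax] - origin) * (1.0 + eps)
    if protocol.axis == "horizontal" and out.box_x is not None:
        out.box_x = out.box_x * (1.0 + eps)
    else:
        idx = out.cols if protocol.axis == "horizontal" else out.rows
        out.clamped = (idx == idx.min()) | (idx == idx.max())
        # grips constrain the loading-axis dof only (transverse motion free,
        # so Poisson contraction is not blocked at the grip columns)
        out.velocities[out.clamped, ax] = 0.0
    out.applied_strain = (1.0 + out.applied_strain) * (1.0 + eps) - 1.0
    out.strain_axis = protocol.axis
    return out
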