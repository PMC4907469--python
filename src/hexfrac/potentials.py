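"""Building-block species and truncated-harmonic pair interactions.

The composite is coarse-grained into two species of building block, each
representing one collagen triple-helix embedded in 10x10x10 hydroxyapatite
unit cells:

* ``PRISTINE`` -- elastically intact composite,
* ``DAMAGED``  -- composite that has undergone plastic deformation, with a
  softer spring constant and a longer equilibrium distance.

Blocks interact through a truncated harmonic pair potential

    V(r) = k * [ (r - r_o)^2 - (r_c - r_o)^2 ]   for r <= r_c
    V(r) = 0                                     for r >  r_c

which is continuous at the rupture cutoff ``r_c`` (the parabola is shifted
so it crosses zero there).  Beyond ``r_c`` the bond transmits no force:
rupture is encoded directly in the force law.  Damage is irreversible: a
pristine block that sees any bonded neighbour separate beyond the pristine
cutoff switches to the damaged species and never reverts (self-healing is
far slower than damage accumulation and is neglected at this level of
coarse-graining).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import TYPE_CHECKING

import numpy as np

from .errors import InvalidArgumentError

if TYPE_CHECKING:  # pragma: no cover
    from .lattice import LatticeSystem

__all__ = [
    "Species",
    "PairPotential",
    "PotentialTable",
    "PRISTINE_DEFAULT",
    "DAMAGED_DEFAULT",
    "pair_energy",
    "pair_force",
    "resolve_potential",
    "update_species",
]


class Species(IntEnum):
    """The two building-block states; ordering PRISTINE < DAMAGED is fixed."""

    PRISTINE = 0
    DAMAGED = 1

    @classmethod
    def from_label(cls, label: "str | Species") -> "Species":
        if isinstance(label, Species):
            return label
        key = str(label).strip().upper()
        aliases = {"P": "PRISTINE", "D": "DAMAGED"}
        key = aliases.get(key, key)
        try:
            return cls[key]
        except KeyError:
            raise InvalidArgumentError(f"unknown species label {label!r}") from None


@dataclass(frozen=True)
class PairPotential:
    """Truncated-harmonic parameters for one species pair.

    Parameters
    ----------
    k : float
        Spring constant (prefactor of the squared displacement),
        kJ mol^-1 nm^-2.
    r_o : float
        Equilibrium centre-to-centre distance, nm.
    r_c : float
        Rupture cutoff, nm.  ``V(r_c) = 0`` exactly; the potential minimum
        ``V(r_o) = -k (r_c - r_o)^2`` is the bond (rupture) energy.
    """

    k: float
    r_o: float
    r_c: float

    def __post_init__(self):
        if not self.k > 0:
            raise InvalidArgumentError(f"spring constant must be positive, got {self.k}")
        if not 0 < self.r_o < self.r_c:
            raise InvalidArgumentError(
                f"need 0 < r_o < r_c, got r_o={self.r_o}, r_c={self.r_c}"
            )

    @property
    def well_depth(self) -> float:
        """Magnitude of the potential minimum, ``k (r_c - r_o)^2`` in kJ/mol."""
        return self.k * (self.r_c - self.r_o) ** 2

    def energy(self, r):
        return pair_energy(self, r)

    def force(self, r):
        return pair_force(self, r)

    def to_dict(self) -> dict:
        return {"k": self.k, "r_o": self.r_o, "r_c": self.r_c}

    @classmethod
    def from_dict(cls, d: dict) -> "PairPotential":
        return cls(k=float(d["k"]), r_o=float(d["r_o"]), r_c=float(d["r_c"]))


#: Pristine-pair parameters fitted to the elastic response of the intact
#: composite (energy-vs-stretch profile of the undamaged model).
PRISTINE_DEFAULT = PairPotential(k=1.77e5, r_o=9.17, r_c=9.65)

#: Damaged-pair parameters fitted to the relaxation of a plastically
#: deformed composite: softer spring, longer equilibrium distance.
DAMAGED_DEFAULT = PairPotential(k=1.10e5, r_o=9.35, r_c=9.82)


def _validate_r(r):
    arr = np.asarray(r, dtype=float)
    if np.any(arr <= 0):
        raise InvalidArgumentError(f"pair distance must be positive, got {r!r}")
    return arr


def pair_energy(pot: PairPotential, r):
    """Truncated-harmonic pair energy at separation ``r`` (nm), in kJ/mol.

    Zero at and beyond the rupture cutoff; accepts scalars or arrays.
    """
    arr = _validate_r(r)
    shifted = (arr - pot.r_o) ** 2 - (pot.r_c - pot.r_o) ** 2
    out = np.where(arr <= pot.r_c, pot.k * shifted, 0.0)
    return float(out) if np.isscalar(r) or np.ndim(r) == 0 else out


def pair_force(pot: PairPotential, r):
    """Signed force along the bond axis, ``-dV/dr`` (kJ mol^-1 nm^-1).

    Positive = repulsive.  Exactly zero beyond the cutoff; the force jumps
    by ``2 k (r_c - r_o)`` at ``r_c`` (brittle rupture).
    """
    arr = _validate_r(r)
    out = np.where(arr <= pot.r_c, -2.0 * pot.k * (arr - pot.r_o), 0.0)
    return float(out) if np.isscalar(r) or np.ndim(r) == 0 else out


class PotentialTable:
    """Complete mapping from unordered species pairs to pair potentials.

    The pristine potential applies only to P-P contacts; mixed P-D pairs
    default to the damaged potential (the softer law governs any contact
    touching damaged material), keeping the rule local, symmetric and a
    pure function of the two species involved.
    """

    def __init__(
        self,
        pristine: PairPotential = PRISTINE_DEFAULT,
        damaged: PairPotential = DAMAGED_DEFAULT,
        mixed: PairPotential | None = None,
    ):
        self.pristine = pristine
        self.damaged = damaged
        self.mixed = mixed if mixed is not None else damaged

    def resolve(self, a: Species, b: Species) -> PairPotential:
        a = Species.from_label(a)
        b = Species.from_label(b)
        if a == b:
            return self.pristine if a == Species.PRISTINE else self.damaged
        return self.mixed

    def as_arrays(self):
        """(k, r_o, r_c) length-3 arrays indexed by ``species_i + species_j``.

        Index 0 = P-P, 1 = P-D, 2 = D-D; used by the vectorised kernels.
        """
        pots = [self.pristine, self.mixed, self.damaged]
        k = np.array([p.k for p in pots])
        r_o = np.array([p.r_o for p in pots])
        r_c = np.array([p.r_c for p in pots])
        return k, r_o, r_c

    def to_dict(self) -> dict:
        return {
            "pristine_pristine": self.pristine.to_dict(),
            "damaged_damaged": self.damaged.to_dict(),
            "pristine_damaged": self.mixed.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PotentialTable":
        pristine = PairPotential.from_dict(d["pristine_pristine"])
        damaged = PairPotential.from_dict(d["damaged_damaged"])
        mixed = None
        if d.get("pristine_damaged") is not None:
            mixed = PairPotential.from_dict(d["pristine_damaged"])
        return cls(pristine, damaged, mixed)

    def __eq__(self, other):
        return (
            isinstance(other, PotentialTable)
            and self.pristine == other.pristine
            and self.damaged == other.damaged
            and self.mixed == other.mixed
        )

    def __repr__(self):
        return (
            f"PotentialTable(pristine={self.pristine!r}, damaged={self.damaged!r}, "
            f"mixed={self.mixed!r})"
        )


def resolve_potential(table: PotentialTable, a: Species, b: Species) -> PairPotential:
    """Potential governing a bond between species ``a`` and ``b`` (symmetric)."""
    return table.resolve(a, b)


def update_species(system: "LatticeSystem", table: PotentialTable):
    """Apply the irreversible pristine->damaged switching rule.

    A pristine block switches to damaged as soon as at least one of its
    bonded neighbours (of either species) is separated from it by at least
    the pristine rupture cutoff ``r_c^P``.  All blocks crossing the
    threshold in the same evaluation switch together, so the outcome does
    not depend on any block ordering.  Damaged blocks never revert.

    Returns
    -------
    (system, switched) : tuple
        The system (modified in place) and a sorted, duplicate-free list of
        the identifiers that switched in this call.
    """
    if system.n_bonds == 0:
        return system, []
    lengths = system.bond_lengths()
    over = lengths >= table.pristine.r_c
    if not over.any():
        return system, []
    touched = np.unique(system.bonds[over].ravel())
    switched = touched[system.species[touched] == int(Species.PRISTINE)]
    system.species[switched] = int(Species.DAMAGED)
    return system, [int(i) for i in switched]
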