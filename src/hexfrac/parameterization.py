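"""Fitting truncated-harmonic potentials to energy-distance profiles.

This is the model-reduction step: given a tabulated potential-energy
curve per building-block contact (in practice derived from stretching
simulations of the resolved composite), recover the three parameters of
the truncated harmonic law

    V(r) = k [ (r - r_o)^2 - (r_c - r_o)^2 ],  r <= r_c;   V = 0 beyond.

The rupture point makes the objective non-differentiable in ``r_c``, so
``r_c`` is selected by grid search; at each candidate cutoff the model is
linear in ``(k, k*r_o)`` and the constraint ``V(r_c) = 0`` is built into
the functional form, so ``k`` and ``r_o`` come from an exact linear
least-squares solve.  Points beyond the candidate cutoff contribute
their squared energies to the total residual (the model is identically
zero there), which is what lets the search locate the rupture distance.

A synthetic-profile generator provides test fixtures emulating such
energy curves, with optional Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, InvalidArgumentError
from .potentials import PairPotential, pair_energy

__all__ = [
    "EnergyProfile",
    "TruncatedHarmonicFit",
    "fit_truncated_harmonic",
    "generate_reference_profile",
    "read_profile",
    "write_profile",
]


@dataclass
class EnergyProfile:
    """Tabulated energy vs centre-to-centre distance for one contact.

    ``distances`` in nm (strictly increasing, at least 6 points),
    ``energies`` in kJ/mol per building-block contact.  ``provenance`` is
    a free-text label recording where the table came from.
    """

    distances: np.ndarray
    energies: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.distances.shape != self.energies.shape or self.distances.ndim != 1:
            raise InvalidArgumentError("distances and energies must be equal-length 1-D")
        if len(self.distances) < 6:
            raise InvalidArgumentError(
                f"profile needs at least 6 points, got {len(self.distances)}"
            )
        if not np.all(np.diff(self.distances) > 0):
            raise InvalidArgumentError("distances must be strictly increasing")

    def __len__(self):
        return len(self.distances)


@dataclass
class TruncatedHarmonicFit:
    """Best-fit potential plus per-candidate diagnostics."""

    potential: PairPotential
    residual: float  # total squared residual of the winning candidate
    r_c_grid: np.ndarray = field(repr=False)
    residuals_per_candidate: np.ndarray = field(repr=False)
    boundary_solution: bool = False  # r_c pinned at the grid's upper edge


def _solve_at_cutoff(r, e, r_c):
    """Exact least squares of V over points r <= r_c; returns (k, r_o, total residual).

    With a = k and b = k*r_o the model below the cutoff is linear:
    V = a (r^2 - r_c^2) + 2 b (r_c - r).  Points beyond the cutoff add
    their squared energies (model is zero there).
    """
    below = r <= r_c
    if below.sum() < 3:
        return None
    rb, eb = r[below], e[below]
    design = np.column_stack([rb**2 - r_c**2, 2.0 * (r_c - rb)])
    coef, *_ = np.linalg.lstsq(design, eb, rcond=None)
    a, b = coef
    if a <= 0:
        return None
    resid = float(((design @ coef - eb) ** 2).sum()) + float((e[~below] ** 2).sum())
    return float(a), float(b / a), resid


def fit_truncated_harmonic(
    profile: EnergyProfile, r_c_grid
) -> TruncatedHarmonicFit:
    """Grid search over rupture cutoffs with a linear solve at each one.

    Returns the candidate minimising the total squared residual.  If the
    winner sits at the top of the grid the profile shows no rupture
    signature within range (e.g. a pure parabola) and the result is
    flagged as a boundary solution.
    """
    grid = np.sort(np.asarray(r_c_grid, dtype=float).ravel())
    if grid.size == 0:
        raise InvalidArgumentError("r_c_grid must be non-empty")
    r, e = profile.distances, profile.energies
    results = [_solve_at_cutoff(r, e, rc) for rc in grid]
    residuals = np.array([np.inf if res is None else res[2] for res in results])
    if not np.isfinite(residuals).any():
        raise InsufficientDataError(
            "fewer than 3 profile points lie below every candidate cutoff"
        )
    best = int(np.argmin(residuals))
    k, r_o, resid = results[best]
    return TruncatedHarmonicFit(
        potential=PairPotential(k=k, r_o=r_o, r_c=float(grid[best])),
        residual=resid,
        r_c_grid=grid,
        residuals_per_candidate=residuals,
        boundary_solution=best == len(grid) - 1,
    )


def generate_reference_profile(
    pot: PairPotential,
    r_min: float,
    r_max: float,
    n: int = 40,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> EnergyProfile:
    """Synthetic energy profile sampled from a truncated harmonic law.

    Evaluates the pair energy at ``n`` equally spaced distances on
    ``[r_min, r_max]`` and adds Gaussian noise of standard deviation
    ``noise_sd`` (kJ/mol), deterministic per ``seed``.  Emulates the
    shape of stretch-energy curves from resolved composite models; the
    provenance string records every argument.
    """
    if not r_min < r_max:
        raise InvalidArgumentError(f"need r_min < r_max, got {r_min}, {r_max}")
    if n < 6:
        raise InvalidArgumentError(f"need n >= 6 points, got {n}")
    if noise_sd < 0:
        raise InvalidArgumentError(f"noise_sd must be >= 0, got {noise_sd}")
    r = np.linspace(r_min, r_max, n)
    e = pair_energy(pot, r)
    if noise_sd > 0:
        e = e + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return EnergyProfile(
        distances=r,
        energies=e,
        provenance=(
            f"synthetic truncated-harmonic profile: k={pot.k} r_o={pot.r_o} "
            f"r_c={pot.r_c} r_min={r_min} r_max={r_max} n={n} "
            f"noise_sd={noise_sd} seed={seed}"
        ),
    )


def write_profile(profile: EnergyProfile, path):
    """Two-column whitespace-delimited text with a mandatory units header."""
    header = [
        f"# {profile.provenance or 'energy profile'}",
        "# units: distance nm, energy kJ/mol per building-block contact",
        "# distance energy",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for r, e in zip(profile.distances, profile.energies):
            fh.write(f"{r:.10g} {e:.10g}\n")


def read_profile(path) -> EnergyProfile:
    lines = []
    provenance = ""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if not provenance:
                    provenance = line.lstrip("# ").strip()
                continue
            lines.append(line.split())
    if not lines:
        raise InvalidArgumentError(f"no data rows in profile file {path}")
    arr = np.array(lines, dtype=float)
    if arr.shape[1] != 2:
        raise InvalidArgumentError(
            f"profile file {path} must have exactly two columns, got {arr.shape[1]}"
        )
    return EnergyProfile(distances=arr[:, 0], energies=arr[:, 1], provenance=provenance)
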