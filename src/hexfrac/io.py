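"""File round-tripping: extended-XYZ snapshots, bond tables, series CSV.

Snapshots use the extended-XYZ convention (count line, key=value comment
line, then one row per block).  Species map to element tags for viewer
compatibility — pristine -> "C", damaged -> "O" — and the mapping is
recorded in the comment line.  Positions are 3-D with z = 0; lattice
bookkeeping (column/row indices, clamp flags) rides along as extra
per-block columns so a snapshot plus its bond table fully reconstructs a
:class:`~hexfrac.lattice.LatticeSystem`.
"""

from __future__ import annotations

import json
import shlex
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .lattice import LatticeSystem
from .observables import CrackReport, StressSeries

__all__ = [
    "SPECIES_TO_ELEMENT",
    "ELEMENT_TO_SPECIES",
    "write_snapshot",
    "read_snapshot",
    "write_bonds",
    "read_bonds",
    "write_series",
    "read_series",
    "write_switch_log",
    "write_crack_report",
]

SPECIES_TO_ELEMENT = {0: "C", 1: "O"}  # P -> C, D -> O
ELEMENT_TO_SPECIES = {v: k for k, v in SPECIES_TO_ELEMENT.items()}

_PROPERTIES = "species:S:1:pos:R:3:velo:R:3:mass:R:1:col:I:1:row:I:1:clamped:I:1"


def write_snapshot(system: LatticeSystem, path, format: str = "extended-xyz"):
    """Write one snapshot; only the extended-XYZ format is supported."""
    if format != "extended-xyz":
        raise InvalidArgumentError(f"unsupported snapshot format {format!r}")
    width, height = system.extent() if system.n_blocks else (0.0, 0.0)
    comment = (
        f'Properties={_PROPERTIES} Lattice="{width} 0 0 0 {height} 0 0 0 1" '
        f"time_ps={system.time} step={system.step} strain={system.applied_strain} "
        f"strain_axis={system.strain_axis} spacing={system.spacing} "
        f"n_cols={system.n_cols} n_rows={system.n_rows} "
        f"box_x={'none' if system.box_x is None else system.box_x} "
        f'species_map="P:C,D:O"'
    )
    lines = [str(system.n_blocks), comment]
    for i in range(system.n_blocks):
        x, y = system.positions[i]
        vx, vy = system.velocities[i]
        lines.append(
            f"{SPECIES_TO_ELEMENT[int(system.species[i])]} "
            f"{x:.12g} {y:.12g} 0 {vx:.12g} {vy:.12g} 0 "
            f"{system.masses[i]:.12g} {system.cols[i]} {system.rows[i]} "
            f"{int(system.clamped[i])}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_comment(comment: str) -> dict:
    out = {}
    for token in shlex.split(comment):
        if "=" in token:
            key, val = token.split("=", 1)
            out[key] = val
    return out


def read_snapshot(path) -> LatticeSystem:
    """Read an extended-XYZ snapshot back into a (bond-less) system.

    Bond topology lives in the sidecar table (:func:`read_bonds`); attach
    it by assigning to ``system.bonds`` or via the CLI's analyze step.
    """
    text = Path(path).read_text().splitlines()
    if not text:
        raise InvalidArgumentError(f"empty snapshot file {path}")
    n = int(text[0].strip())
    meta = _parse_comment(text[1]) if len(text) > 1 else {}
    rows = [line.split() for line in text[2 : 2 + n]]
    if len(rows) != n:
        raise InvalidArgumentError(f"snapshot {path} declares {n} blocks, has {len(rows)}")
    if n == 0:
        positions = np.empty((0, 2))
        velocities = np.empty((0, 2))
        species = np.empty(0, dtype=np.int8)
        masses = np.empty(0)
        cols = rows_idx = np.empty(0, dtype=np.int64)
        clamped = np.empty(0, dtype=bool)
    else:
        arr = np.array(rows, dtype=object)
        species = np.array(
            [ELEMENT_TO_SPECIES[e] for e in arr[:, 0]], dtype=np.int8
        )
        num = arr[:, 1:].astype(float)
        positions = num[:, [0, 1]].copy()
        velocities = num[:, [3, 4]].copy()
        masses = num[:, 6].copy()
        cols = num[:, 7].astype(np.int64)
        rows_idx = num[:, 8].astype(np.int64)
        clamped = num[:, 9].astype(bool)
    box_x = meta.get("box_x", "none")
    return LatticeSystem(
        positions=positions,
        velocities=velocities,
        species=species,
        masses=masses,
        bonds=np.empty((0, 2), dtype=np.int64),
        clamped=clamped,
        cols=cols,
        rows=rows_idx,
        n_cols=int(meta.get("n_cols", 0) or 0),
        n_rows=int(meta.get("n_rows", 0) or 0),
        spacing=float(meta.get("spacing", 0.0) or 0.0),
        box_x=None if box_x == "none" else float(box_x),
        applied_strain=float(meta.get("strain", 0.0) or 0.0),
        strain_axis=meta.get("strain_axis", "horizontal"),
        time=float(meta.get("time_ps", 0.0) or 0.0),
        step=int(meta.get("step", 0) or 0),
    )


def write_bonds(system: LatticeSystem, path):
    """Sidecar bond list: two integer columns (block i, block j)."""
    with open(path, "w") as fh:
        fh.write("# i j\n")
        for i, j in system.bonds:
            fh.write(f"{i} {j}\n")


def read_bonds(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                rows.append(line.split()[:2])
    if not rows:
        return np.empty((0, 2), dtype=np.int64)
    return np.array(rows, dtype=np.int64)


def write_series(series: StressSeries, path):
    series.to_frame().to_csv(path, index=False)


def read_series(path) -> StressSeries:
    return StressSeries.from_frame(pd.read_csv(path))


def write_switch_log(switch_log, path):
    """Switching events as CSV (step, block_id)."""
    pd.DataFrame(switch_log, columns=["step", "block_id"]).to_csv(path, index=False)


def write_crack_report(report: CrackReport, json_path, bonds_csv_path=None):
    """Crack report as JSON plus an optional per-bond CSV."""
    Path(json_path).write_text(json.dumps(report.to_dict(), indent=1) + "\n")
    if bonds_csv_path is not None:
        pd.DataFrame(
            [
                {
                    "bond_index": bb.bond_index,
                    "i": bb.pair[0],
                    "j": bb.pair[1],
                    "length_nm": bb.length,
                    "first_step": bb.first_step,
                }
                for bb in report.broken_bonds
            ],
            columns=["bond_index", "i", "j", "length_nm", "first_step"],
        ).to_csv(bonds_csv_path, index=False)
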