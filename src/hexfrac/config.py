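"""Run configuration: YAML schema, validation, defaults and round-trip.

One human-readable YAML file drives a whole experiment.  All physical
quantities carry fixed units — nm, fs, K, ps^-1, u, kJ/mol-derived — and
no unit inference is attempted.  Unknown keys are rejected (they are
almost always typos), every default filled in is logged, and a loaded
config serialises back to an equivalent file.

Defaults are the composite model's reference conditions: 9.17 nm block
spacing, the pristine/damaged truncated-harmonic parameters, 5% applied
strain and a 350 fs time step.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .dynamics import DynamicsConfig
from .errors import ConfigurationError, InvalidArgumentError
from .lattice import DEFAULT_BLOCK_MASS, StrainProtocol
from .potentials import PotentialTable

__all__ = ["LatticeConfig", "NotchConfig", "OutputConfig", "RunConfig", "load_config", "save_config"]

logger = logging.getLogger(__name__)


@dataclass
class NotchConfig:
    center_col: int | None = None  # None -> lattice midpoint
    width_blocks: int = 4
    depth_rows: int = 2


@dataclass
class LatticeConfig:
    n_cols: int = 100
    n_rows: int = 100
    spacing: float = 9.17
    species: str = "pristine"
    mass: float = DEFAULT_BLOCK_MASS
    boundary: str = "clamped"  # "clamped" | "periodic_x"
    notch: NotchConfig | None = None


@dataclass
class OutputConfig:
    directory: str = "out"


@dataclass
class RunConfig:
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    potentials: PotentialTable = field(default_factory=PotentialTable)
    protocol: StrainProtocol = field(default_factory=lambda: StrainProtocol(hold_steps=10_000))
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    def to_dict(self) -> dict:
        return {
            "lattice": {
                **{k: v for k, v in asdict(self.lattice).items() if k != "notch"},
                "notch": None if self.lattice.notch is None else asdict(self.lattice.notch),
            },
            "potentials": self.potentials.to_dict(),
            "protocol": {
                "axis": self.protocol.axis,
                "strain": self.protocol.magnitude,
                "mode": self.protocol.mode,
                "hold_steps": self.protocol.hold_steps,
            },
            "dynamics": asdict(self.dynamics),
            "output": asdict(self.output),
        }


def _take(section: dict, section_name: str, known: dict):
    """Pop known keys with defaults; reject anything left over."""
    out = {}
    for key, default in known.items():
        if key in section:
            out[key] = section.pop(key)
        else:
            out[key] = default
            if default is not None:
                logger.info("config: %s.%s not set, using default %r", section_name, key, default)
    if section:
        bad = next(iter(section))
        raise ConfigurationError(f"{section_name}.{bad}", "unknown key")
    return out


def _parse(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigurationError("<root>", "config must be a mapping")
    data = dict(data)
    sections = {
        name: dict(data.pop(name, None) or {})
        for name in ("lattice", "potentials", "protocol", "dynamics", "output")
    }
    if data:
        raise ConfigurationError(next(iter(data)), "unknown section")

    lat_raw = sections["lattice"]
    notch_raw = lat_raw.pop("notch", None)
    lat_kwargs = _take(
        lat_raw,
        "lattice",
        {
            "n_cols": 100,
            "n_rows": 100,
            "spacing": 9.17,
            "species": "pristine",
            "mass": DEFAULT_BLOCK_MASS,
            "boundary": "clamped",
        },
    )
    if lat_kwargs["boundary"] not in ("clamped", "periodic_x"):
        raise ConfigurationError("lattice.boundary", f"must be clamped|periodic_x, got {lat_kwargs['boundary']!r}")
    for key in ("n_cols", "n_rows"):
        if int(lat_kwargs[key]) < 1:
            raise ConfigurationError(f"lattice.{key}", f"must be >= 1, got {lat_kwargs[key]}")
    for key in ("spacing", "mass"):
        if float(lat_kwargs[key]) <= 0:
            raise ConfigurationError(f"lattice.{key}", f"must be > 0, got {lat_kwargs[key]}")
    notch = None
    if notch_raw is not None:
        nk = _take(dict(notch_raw), "lattice.notch", {"center_col": None, "width_blocks": 4, "depth_rows": 2})
        if nk["center_col"] is None:
            nk["center_col"] = int(lat_kwargs["n_cols"]) // 2
            logger.info("config: lattice.notch.center_col not set, using lattice midpoint %d", nk["center_col"])
        notch = NotchConfig(**{k: int(v) for k, v in nk.items()})
    lattice = LatticeConfig(
        n_cols=int(lat_kwargs["n_cols"]),
        n_rows=int(lat_kwargs["n_rows"]),
        spacing=float(lat_kwargs["spacing"]),
        species=str(lat_kwargs["species"]),
        mass=float(lat_kwargs["mass"]),
        boundary=str(lat_kwargs["boundary"]),
        notch=notch,
    )

    pot_raw = sections["potentials"]
    defaults = PotentialTable()
    pot_kwargs = _take(
        pot_raw,
        "potentials",
        {
            "pristine_pristine": defaults.pristine.to_dict(),
            "damaged_damaged": defaults.damaged.to_dict(),
            "pristine_damaged": None,
        },
    )
    try:
        potentials = PotentialTable.from_dict(pot_kwargs)
    except (KeyError, InvalidArgumentError, TypeError, ValueError) as exc:
        raise ConfigurationError("potentials", str(exc)) from exc

    proto_kwargs = _take(
        sections["protocol"],
        "protocol",
        {"axis": "horizontal", "strain": 0.05, "mode": "instantaneous", "hold_steps": 10_000},
    )
    try:
        protocol = StrainProtocol(
            axis=str(proto_kwargs["axis"]),
            magnitude=float(proto_kwargs["strain"]),
            mode=str(proto_kwargs["mode"]),
            hold_steps=int(proto_kwargs["hold_steps"]),
        )
    except InvalidArgumentError as exc:
        raise ConfigurationError("protocol", str(exc)) from exc

    dyn_defaults = DynamicsConfig()
    dyn_kwargs = _take(
        sections["dynamics"],
        "dynamics",
        {
            "time_step_fs": dyn_defaults.time_step_fs,
            "n_steps": dyn_defaults.n_steps,
            "temperature": dyn_defaults.temperature,
            "friction": dyn_defaults.friction,
            "random_seed": dyn_defaults.random_seed,
            "snapshot_every": dyn_defaults.snapshot_every,
            "series_every": dyn_defaults.series_every,
        },
    )
    try:
        dynamics = DynamicsConfig(
            time_step_fs=float(dyn_kwargs["time_step_fs"]),
            n_steps=int(dyn_kwargs["n_steps"]),
            temperature=float(dyn_kwargs["temperature"]),
            friction=float(dyn_kwargs["friction"]),
            random_seed=int(dyn_kwargs["random_seed"]),
            snapshot_every=int(dyn_kwargs["snapshot_every"]),
            series_every=int(dyn_kwargs["series_every"]),
        )
    except InvalidArgumentError as exc:
        raise ConfigurationError("dynamics", str(exc)) from exc

    out_kwargs = _take(sections["output"], "output", {"directory": "out"})
    return RunConfig(
        lattice=lattice,
        potentials=potentials,
        protocol=protocol,
        dynamics=dynamics,
        output=OutputConfig(directory=str(out_kwargs["directory"])),
    )


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run configuration.

    Fills documented defaults (logging each one), rejects unknown keys
    and out-of-range values with an error naming the offending key.
    """
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError("<file>", f"YAML parse error in {path}: {exc}") from exc
    return _parse(data or {})


def save_config(config: RunConfig, path):
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
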