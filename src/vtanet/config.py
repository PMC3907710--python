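"""Experiment configuration: YAML loading and validation.

An experiment file selects a schedule, a seed, output locations and any
network-level overrides (state-machine mode, pallidal gating polarity,
phasic-filter shapes, or a full replacement projection table).  A saved
configuration re-produces a run bit-for-bit under the same build.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .network import NetworkConfig, ProjectionRow, default_projection_rows

__all__ = ["ExperimentConfig", "load_config", "default_config"]

SCHEDULES = ("standard", "probes", "magnitude_sweep", "omission", "early")

#: keys accepted at the top level of an experiment file
_TOP_KEYS = {
    "schedule", "seed", "out_dir", "n_sensitization", "n_conditioning",
    "networks", "magnitudes", "assoc_id", "record", "network", "projections",
}
_NETWORK_KEYS = {f.name for f in dataclasses.fields(NetworkConfig)} - {"projections"}
_PROJ_KEYS = {f.name for f in dataclasses.fields(ProjectionRow)}


@dataclass
class ExperimentConfig:
    """Validated description of one experiment run."""

    schedule: str = "standard"
    seed: int = 0
    out_dir: str = "results"
    n_sensitization: int = 10
    n_conditioning: int = 15
    networks: int = 10                       # magnitude sweep replicates
    magnitudes: list[float] = field(
        default_factory=lambda: [round(0.1 * i, 1) for i in range(11)])
    assoc_id: int = 1                        # omission / early / sweep target
    record: list[str] = field(default_factory=lambda: ["VTA"])
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self) -> None:
        if self.schedule not in SCHEDULES:
            raise ValueError(
                f"unknown schedule {self.schedule!r}; expected one of {SCHEDULES}")
        if self.n_sensitization < 0 or self.n_conditioning < 1:
            raise ValueError("trial counts out of range")
        if self.assoc_id not in (1, 2, 3):
            raise ValueError("assoc_id must be 1, 2 or 3")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["network"].pop("projections", None)
        d["projections"] = [dataclasses.asdict(r)
                            for r in self.network.projections]
        return d

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def default_config() -> ExperimentConfig:
    return ExperimentConfig()


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


def load_config(path_or_mapping, **overrides) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML file or a mapping.

    Keyword overrides (e.g. a command-line seed) take precedence over the
    file.  Unknown keys are rejected with the offending name; a partial
    projection table is rejected naming the missing rows.
    """
    if isinstance(path_or_mapping, (str, Path)):
        raw = yaml.safe_load(Path(path_or_mapping).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    else:
        raw = dict(path_or_mapping or {})
    raw.update({k: v for k, v in overrides.items() if v is not None})
    _reject_unknown(raw, _TOP_KEYS, "experiment config")

    net_kwargs = dict(raw.pop("network", {}) or {})
    _reject_unknown(net_kwargs, _NETWORK_KEYS, "network section")
    rows_raw = raw.pop("projections", None)
    if rows_raw is not None:
        rows = []
        for i, row in enumerate(rows_raw):
            _reject_unknown(dict(row), _PROJ_KEYS, f"projection row {i}")
            rows.append(ProjectionRow(**row))
    else:
        rows = default_projection_rows()
    network = NetworkConfig(projections=rows, **net_kwargs)
    return ExperimentConfig(network=network, **raw)
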