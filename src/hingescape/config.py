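"""Run configuration: a flat, serializable record of every analysis parameter.

Defaults are the protocol's stated values: 120 landscape bins at 310 K,
4.0 Å GROMOS cutoff, 3.5 Å heavy-atom contact cutoff, 1.0 Å occupancy
grid spacing with a 0.44 isovalue, and an optional equilibration window
(e.g. discarding the first 50 ns).  A YAML config file and CLI flags
both map onto this record; flags win.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class RunConfig:
    # inputs / outputs
    input: str | None = None
    outdir: str = "results"
    seed: int = 0
    # collective variables
    cv_x: str = "phe63_asnrepeat_distance"
    cv_y: str = "interdomain_theta"
    # landscape
    bins: int = 120
    temperature: float = 310.0
    # clustering
    cluster_cutoff: float = 4.0
    cluster_selection: str = "backbone"
    # contacts
    contact_cutoff: float = 3.5
    group_a: str = "protein"
    group_b: str = "resname LIG"
    # occupancy
    grid_spacing: float = 1.0
    isovalue: float = 0.44
    water_selection: str = "water and name O"
    # modes
    enm_cutoff: float = 10.0
    fit_selection: str = "ca"
    # equilibration window (ps); None disables
    time_start: float | None = None
    time_end: float | None = None

    def __post_init__(self) -> None:
        positive = {
            "bins": self.bins, "temperature": self.temperature,
            "cluster_cutoff": self.cluster_cutoff,
            "contact_cutoff": self.contact_cutoff,
            "grid_spacing": self.grid_spacing, "enm_cutoff": self.enm_cutoff,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not (0.0 < self.isovalue <= 1.0):
            raise ValueError("isovalue must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
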