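"""Run configuration: cable constants, discretization, pipeline settings.

Defaults reproduce the passive parameters used throughout the study of VS
cells (R_m = 2,000 Ω·cm², R_i = 40 Ω·cm) and the package's own choices for
the quantities the experiments leave open (axonal measurement point,
filtering percentile, permutation count). Every pipeline run writes its
resolved configuration alongside its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cable import CableParams, Locus, default_axon_locus

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    rm_ohm_cm2: float = 2000.0
    ri_ohm_cm: float = 40.0
    resolution_um: float | None = None  # None -> min(2 μm, λ/50) per segment
    axon_locus: str = "auto"  # "auto" | "root" | "branchlet_id:fraction"
    delta: float = 0.0
    delta_grid: list[float] = field(default_factory=lambda: [float(d) for d in range(0, 100, 2)])
    n_shuffles: int = 1000
    seed: int = 0

    def cable_params(self) -> CableParams:
        return CableParams(rm_ohm_cm2=self.rm_ohm_cm2, ri_ohm_cm=self.ri_ohm_cm)

    def resolve_axon_locus(self, morphology) -> Locus:
        if self.axon_locus == "auto":
            return default_axon_locus(morphology)
        if self.axon_locus == "root":
            return Locus(0, 0.0)
        try:
            sec, frac = self.axon_locus.split(":")
            return Locus(int(sec), float(frac))
        except (ValueError, AttributeError):
            raise ValueError(
                "config key 'axon_locus' must be 'auto', 'root' or "
                f"'<branchlet_id>:<fraction>', got {self.axon_locus!r}"
            ) from None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
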