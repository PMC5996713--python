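"""Run configuration: a single serializable object reproducing a run.

Two scale presets exist.  ``paper`` encodes the printed full-scale
defaults (5,000 neurons/circuit, 1,000 examples per configuration, 6,000
timepoints, feature lag 10 for MAR and 3 for NN data).  ``desk`` is a
reduced recipe sized for a single CPU (500 neurons/circuit, 20 examples
per configuration by default) using the reduced-circuit efficacy preset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from effconn import lif, mar

__all__ = ["RunConfig", "load_config", "DEFAULT_FEATURE_LAG"]

DEFAULT_FEATURE_LAG = {"NN": 3, "MAR": 10}


@dataclass
class RunConfig:
    generator: str = "NN"  # "NN" | "MAR"
    scale: str = "desk"  # "paper" | "desk"
    n_per_config: int | None = None  # default from scale preset
    duration_ms: float | None = None  # NN: simulation length; MAR: N timepoints
    feature_lag: int | None = None  # default from generator
    folds: int = 5
    n_bootstrap: int = 1000
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generator not in ("NN", "MAR"):
            raise ValueError(f"unknown generator {self.generator!r}")
        if self.scale not in ("paper", "desk"):
            raise ValueError(f"unknown scale preset {self.scale!r}")

    @property
    def resolved_n_per_config(self) -> int:
        if self.n_per_config is not None:
            return self.n_per_config
        return 1000 if self.scale == "paper" else 20

    @property
    def resolved_duration(self) -> float:
        if self.duration_ms is not None:
            return self.duration_ms
        return 6000.0

    @property
    def resolved_feature_lag(self) -> int:
        if self.feature_lag is not None:
            return self.feature_lag
        return DEFAULT_FEATURE_LAG[self.generator]

    def lif_parameters(self):
        """(circuit, inter, ext, settings) for this configuration."""
        if self.scale == "paper":
            circuit = lif.CircuitParameters()
            inter = lif.InterCircuitParameters()
            ext = lif.ExternalInputParameters()
        else:
            circuit, inter, ext = lif.desk_dataset_preset()
        settings = lif.SimulationSettings(duration=self.resolved_duration, seed=self.seed)
        return circuit, inter, ext, settings

    def mar_parameters(self) -> mar.MarParameters:
        return mar.MarParameters()

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        obj = json.loads(text)
        if "c_grid" in obj and obj["c_grid"] is not None:
            obj["c_grid"] = tuple(obj["c_grid"])
        return cls(**obj)


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_json(Path(path).read_text())
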