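"""Run configuration shared by the CLI commands."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

from .forward import Scenario


@dataclass
class RunConfig:
    """Scenario plus analysis parameters for one pipeline run."""

    scenario: Scenario = field(default_factory=Scenario)
    forward_elements: int = 1600  # generator mesh (finer: avoids the inverse crime)
    inverse_elements: int = 400  # reconstruction mesh
    filter_order: int = 4
    cutoff_hz: float = 0.15
    lam: float = 0.1
    roi_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.forward_elements <= self.inverse_elements:
            raise ValueError("forward mesh must be finer than the inverse mesh")
        if self.filter_order < 1 or self.cutoff_hz <= 0:
            raise ValueError("filter parameters must be positive")
        if self.lam <= 0:
            raise ValueError("regularization parameter must be positive")
        if not 0 < self.roi_fraction < 1:
            raise ValueError("ROI fraction must be in (0, 1)")

    def to_json(self) -> str:
        doc = asdict(self)
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        doc = json.loads(text)

        def tuplify(v):
            return tuple(tuplify(x) for x in v) if isinstance(v, list) else v

        scenario = Scenario(**{
            k: tuplify(v) for k, v in doc.pop("scenario", {}).items()
        })
        known = {f.name for f in fields(cls)} - {"scenario"}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(scenario=scenario, **doc)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    def with_scenario(self, **kwargs) -> "RunConfig":
        return replace(self, scenario=replace(self.scenario, **kwargs))
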