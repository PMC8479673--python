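"""Run configuration shared by the CLI pipeline stages.

A single YAML/JSON-serializable record holds every tunable the pipeline
uses, and a snapshot is written next to every output so results carry
their provenance.  Defaults match the package-wide constants.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    #: confidence level of the thermodynamic ellipsoid
    alpha: float = 0.95
    #: strict-inequality margin for the second law (kJ/mol)
    epsilon: float = 0.1
    #: smallest flux magnitude counted as non-zero (mmol/gDW/h)
    v_min: float = 1e-6
    #: anomaly threshold in standard deviations
    theta: float = 1.0
    #: MCMC settings
    chains: int = 4
    steps: int = 5000
    burn_in: float = 0.2
    n_retain: int | None = None
    adapt: bool = False
    #: flux-mixture settings
    n_orthants: int = 100
    n_flux_samples: int = 10000
    #: root seed for every stochastic stage
    seed: int = 0
    #: diagnostics gates
    psrf_gate: float = 1.1
    ess_gate: float = 100.0
    #: LP/QP backend identifier (scipy HiGHS is the only built-in)
    solver: str = "highs"
    output_dir: str = "pta_out"

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("epsilon", "v_min", "theta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.chains < 2:
            raise ValueError("chains must be >= 2")
        if self.steps < 10:
            raise ValueError("steps must be >= 10")
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn_in must be in [0, 1)")

    @classmethod
    def load(cls, path: str | pathlib.Path) -> "RunConfig":
        path = pathlib.Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def save(self, path: str | pathlib.Path) -> None:
        path = pathlib.Path(path)
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            if path.suffix in {".yaml", ".yml"}:
                yaml.safe_dump(payload, fh, sort_keys=False)
            else:
                json.dump(payload, fh, indent=2)

    def with_overrides(self, **kwargs) -> "RunConfig":
        clean = {k: v for k, v in kwargs.items() if v is not None}
        cfg = dataclasses.replace(self, **clean)
        cfg.validate()
        return cfg
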