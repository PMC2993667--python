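"""Run configuration: one YAML file holding every numeric default."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .engine import SolverConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable defaults for CLI runs.

    Unspecified keys fall back to the documented defaults: solver tolerances
    (rtol 1e-6 / atol 1e-8), steady-state threshold 1e-6 per unit time with
    a 1e4 horizon, sensitivity perturbation -25% with qualitative threshold
    0.003 at baseline inputs NE=0.5/FSK=0.2/IBMX=0.2, and 10 seeded fit
    restarts.
    """

    solver: SolverConfig = field(default_factory=SolverConfig)
    dP_frac: float = -0.25
    qualitative_threshold: float = 0.003
    baseline_inputs: dict = field(
        default_factory=lambda: {"NE": 0.5, "FSK": 0.2, "IBMX": 0.2}
    )
    fit_restarts: int = 10
    fit_seed: int = 0
    verbosity: int = 1

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["solver"] = asdict(self.solver)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        solver = SolverConfig(**data.pop("solver", {}))
        return cls(solver=solver, **data)
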