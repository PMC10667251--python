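"""Run configuration shared by the CLI and the analysis drivers."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    restarts: int = 5
    solver_xtol: float = 1e-10
    solver_ftol: float = 1e-10
    fdr_method: str = "BH"
    conditions: tuple[str, str] = ("Ctrl", "sPD")
    injection_points: tuple[int, int, int, int, int] = (4, 3, 3, 3, 3)
    log_level: str = "INFO"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        cfg = cls()
        for k, v in data.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            setattr(cfg, k, tuple(v) if isinstance(getattr(cfg, k), tuple) else v)
        return cfg

    def ls_options(self) -> dict:
        return {"xtol": self.solver_xtol, "ftol": self.solver_ftol}

    def stamp(self, payload: dict) -> dict:
        """Record the seed in an output artifact."""
        return {"seed": self.seed, **payload}
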