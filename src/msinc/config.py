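"""Run configuration: one YAML-serializable record driving the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import Hyperparams

__all__ = ["RunConfig", "PAPER_T", "DEMO_T"]

#: iteration counts: the published experiments ran 400 SEM iterations;
#: the CLI demo profile uses 100, restorable with --paper-defaults.
PAPER_T = 400
DEMO_T = 100


@dataclass
class RunConfig:
    """Everything one scoring run needs, round-trippable through YAML."""

    input: str = ""
    input_format: str = "auto"      # tiff | dicom | png | auto
    window: int = 7
    output_dir: str = "msinc-out"
    seed: int = 0
    gamma: float = 1.2
    alpha: float = 1.0
    beta: float = 1.0
    r: float = 1.0
    l: int = 2
    T: int = DEMO_T
    burn_in: int = 0
    extras: dict = field(default_factory=dict)

    def hyperparams(self) -> Hyperparams:
        return Hyperparams(
            gamma=self.gamma, alpha=self.alpha, beta=self.beta,
            r=self.r, l=self.l, T=self.T, seed=self.seed,
            burn_in=self.burn_in,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        unknown = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extras.update(unknown)
        return cfg
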