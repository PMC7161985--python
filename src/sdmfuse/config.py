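"""Run configuration: nested dataclasses with YAML round-tripping."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fusion import FusionConfig
from .synthetic import SyntheticConfig


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``seed`` is the master seed: every stage derives its own RNG stream
    from it, so two runs with the same configuration are byte-identical.
    """

    outdir: str = "results/run"
    seed: int = 20200416
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    split_year: int = 2011           # train <= split_year, test after
    auc_threshold: float = 0.7       # inclusion filter, both seasons
    scenarios: tuple = ("p5", "mean", "p95")
    cap: float = 500.0               # reporting cap on percent increases
    criterion: str = "reml"          # smoothing-parameter selection
    n_species: int = 8               # uses the default panel when 8

    def __post_init__(self):
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig(**self.synthetic)
        if isinstance(self.fusion, dict):
            self.fusion = FusionConfig(**self.fusion)
        self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)
        if not (0.5 <= self.auc_threshold <= 1.0):
            raise ValueError("auc_threshold must lie in [0.5, 1]")
        if self.cap <= 0:
            raise ValueError("cap must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(_listify(d), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


def _listify(obj):
    """YAML-safe: tuples become lists recursively."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj
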