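"""Run configuration: one YAML file tying the pipeline together.

A :class:`RunConfig` bundles the training hyper-parameters, the tiling
parameters, the ordinal label space and the top-level seed, and every
run artifact embeds its resolved form so results are reproducible from
the file alone.  All randomness in a run flows from the single seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from . import __version__
from .mil import TrainConfig
from .ordinal import OrdinalLabelSpace, crc3

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class TilingConfig:
    size_px: int = 512
    stride_px: int | None = None
    threshold: float = 1.0
    mask_level: int | None = None


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)
    tiling: TilingConfig = field(default_factory=TilingConfig)
    class_names: tuple[str, ...] = ("non-neoplastic", "low-grade", "high-grade")
    class_values: tuple[float, ...] | None = None

    @property
    def space(self) -> OrdinalLabelSpace:
        if list(self.class_names) == list(crc3().names) and self.class_values is None:
            return crc3()
        return OrdinalLabelSpace(tuple(self.class_names), self.class_values)

    def resolved(self) -> "RunConfig":
        """Propagate the top-level seed into the training config."""
        return replace(self, train=replace(self.train, seed=self.seed))

    def to_dict(self) -> dict:
        return {"version": __version__, **asdict(self)}

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.pop("version", None)
        train = TrainConfig(**data.pop("train", {}))
        tiling = TilingConfig(**data.pop("tiling", {}))
        names = tuple(data.pop("class_names", cls.class_names))
        values = data.pop("class_values", None)
        values = tuple(values) if values is not None else None
        return cls(
            seed=int(data.pop("seed", 0)),
            train=train,
            tiling=tiling,
            class_names=names,
            class_values=values,
        )
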