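"""Model/Results interface over the MIL pipeline.

:class:`OrdinalMILModel` is built from a dataset of slide bags and a
training configuration; :meth:`~OrdinalMILModel.fit` runs the optional
supervised warm-start and the MIL epochs and returns a
:class:`MILResults` carrying the fitted backbone, the epoch history,
per-split metrics, and a ``summary()`` table.  Prediction, evaluation
and checkpoint persistence hang off the results object.

    >>> model = OrdinalMILModel.from_synthetic(seed=7, n_slides=80)
    >>> res = model.fit()
    >>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .backbone import Backbone, TextureBackbone
from .mil import (
    FeatureCache,
    MILDataset,
    TrainConfig,
    ConfigurationError,
    evaluate_bags,
    predict_slide,
    run_training,
)
from .ordinal import OrdinalLabelSpace

__all__ = ["OrdinalMILModel", "MILResults"]


def _space_hash(space: OrdinalLabelSpace) -> str:
    payload = json.dumps({"names": space.names, "values": space.values})
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class OrdinalMILModel:
    """Weakly-supervised ordinal MIL classifier for bags of tiles.

    Parameters
    ----------
    dataset
        Bags with train/val/test split tags, the ordinal label space,
        and any region annotations (used only when fitting with
        ``pretrain=True``).
    config
        Training configuration; defaults to :class:`TrainConfig`'s
        reference recipe.
    backbone
        Optional backbone instance; defaults to a freshly initialised
        :class:`~ordmil.backbone.TextureBackbone`.
    """

    def __init__(
        self,
        dataset: MILDataset,
        config: TrainConfig | None = None,
        backbone: Backbone | None = None,
    ):
        self.dataset = dataset
        self.config = config or TrainConfig()
        self.backbone = backbone
        self.cache = FeatureCache()

    @classmethod
    def from_synthetic(
        cls, seed: int, n_slides: int = 80, config: TrainConfig | None = None, **spec_kw
    ) -> "OrdinalMILModel":
        """Build the model on a freshly generated synthetic dataset."""
        from .experiments import desk_config, make_synthetic_dataset
        from .synthetic import SyntheticSpec

        spec = SyntheticSpec(seed=seed, n_slides=n_slides, **spec_kw)
        ds = make_synthetic_dataset(seed, n_slides, spec=spec)
        return cls(ds, config or desk_config(seed))

    @classmethod
    def from_dataframe(
        cls,
        manifest: pd.DataFrame,
        tile_loader,
        tiles_by_slide: dict,
        space: OrdinalLabelSpace,
        config: TrainConfig | None = None,
        annotations=None,
    ) -> "OrdinalMILModel":
        """Build from a slide manifest (slide_id, label, split, annotated).

        ``tiles_by_slide`` maps slide id to its :class:`TileRef` list
        and ``tile_loader`` maps a tile to its RGB array.
        """
        from .mil import SlideBag

        bags = []
        for row in manifest.itertuples():
            bags.append(
                SlideBag(
                    slide_id=str(row.slide_id),
                    tiles=tiles_by_slide[str(row.slide_id)],
                    label=int(row.label),
                    split=str(getattr(row, "split", "train")),
                    annotated=bool(getattr(row, "annotated", False)),
                    loader=tile_loader,
                )
            )
        return cls(
            MILDataset(bags=bags, space=space, annotations=list(annotations or [])), config
        )

    def fit(self, pretrain: bool = False) -> "MILResults":
        """Run the (optionally warm-started) MIL training; returns results."""
        trained = run_training(
            self.dataset, self.config, pretrain=pretrain,
            backbone=self.backbone, cache=self.cache,
        )
        return MILResults(self, trained.backbone, trained.history, trained.best_epoch, pretrain)


class MILResults:
    """Fitted MIL model: checkpointed backbone, history, diagnostics."""

    def __init__(self, model, backbone, history, best_epoch, pretrained):
        self.model = model
        self.backbone = backbone
        self.history: pd.DataFrame = history
        self.best_epoch = best_epoch
        self.pretrained = bool(pretrained)
        self._cache = model.cache

    # -- inference ---------------------------------------------------------

    def predict(self, bags=None) -> pd.DataFrame:
        """Slide-level predictions with the evidence tile per slide."""
        bags = bags if bags is not None else self.model.dataset.bags
        rows = []
        for bag in bags:
            cls, probs, tile = predict_slide(
                bag, self.backbone, self._cache, self.model.config.decode
            )
            rows.append(
                {
                    "slide_id": bag.slide_id,
                    "label": bag.label,
                    "prediction": cls,
                    "evidence_x": tile.x,
                    "evidence_y": tile.y,
                    **{f"p_{name}": p for name, p in zip(self.backbone.space.names, probs)},
                }
            )
        return pd.DataFrame(rows)

    def evaluate(self, split: str = "test") -> dict:
        """QWK, accuracy and lesion sensitivity on one split."""
        bags = self.model.dataset.split(split)
        if not bags:
            raise ConfigurationError(f"dataset has no {split!r} bags")
        return evaluate_bags(bags, self.backbone, self._cache, self.model.config.decode)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        space = self.backbone.space
        cfg = self.model.config
        lines = [
            "Ordinal MIL slide classifier",
            "=" * 60,
            f"classes:        {' < '.join(space.names)}",
            f"bags:           "
            + ", ".join(
                f"{tag}={len(self.model.dataset.split(tag))}" for tag in ("train", "val", "test")
            ),
            f"loss:           {cfg.loss} (ce_weight={cfg.ce_weight})",
            f"optimizer:      {cfg.optimizer}, lr={cfg.learning_rate}, batch={cfg.batch_size}",
            f"epochs:         {cfg.epochs} (best @ {self.best_epoch}), pretrained={self.pretrained}",
            f"seed:           {cfg.seed}",
            "-" * 60,
        ]
        for split in ("train", "test"):
            bags = self.model.dataset.split(split)
            if bags:
                m = self.evaluate(split)
                lines.append(
                    f"{split:<6} QWK={m['qwk']:+.3f}  accuracy={m['accuracy']:.3f}  "
                    f"lesion sensitivity={m['lesion_sensitivity']:.3f}  (n={m['n']})"
                )
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint: backbone parameters + config + seed + label-space hash."""
        path = Path(path)
        state = self.backbone.state_dict()
        meta = {
            "config": asdict(self.model.config),
            "space": {
                "names": list(self.backbone.space.names),
                "values": list(self.backbone.space.values),
            },
            "space_hash": _space_hash(self.backbone.space),
            "pretrained": self.pretrained,
            "best_epoch": self.best_epoch,
        }
        arrays = {f"param_{k}": v for k, v in state["params"].items()}
        np.savez(
            path,
            meta=json.dumps(meta),
            history=self.history.to_json(),
            state=json.dumps(
                {k: v for k, v in state.items() if k not in ("params", "adam")}, default=str
            ),
            **arrays,
        )

    @staticmethod
    def load_backbone(path: str | Path) -> tuple[Backbone, dict]:
        """Rebuild the checkpointed backbone; returns (backbone, metadata)."""
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            space = OrdinalLabelSpace(
                tuple(meta["space"]["names"]), tuple(meta["space"]["values"])
            )
            if _space_hash(space) != meta["space_hash"]:
                raise ConfigurationError("checkpoint label-space hash mismatch")
            cfg = meta["config"]
            backbone = TextureBackbone(space, hidden=cfg["hidden"], seed=cfg["seed"])
            for k in backbone.params:
                backbone.params[k] = data[f"param_{k}"]
        return backbone, meta
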