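"""The weakly-supervised MIL training and inference loop.

A slide is a *bag* of tiles carrying a single ordinal label.  The MIL
premise says the bag label bounds the tiles: no tile is more severe
than the slide, and at least one tile is exactly as severe.  Training
therefore alternates two passes per epoch:

1. *Ranking*: the backbone (at its epoch-start state, in evaluation
   mode) scores every tile of every training bag by the expected-value
   severity of its predicted class distribution.
2. *Learning*: the top-ranked tile of each bag, paired with the slide
   label, forms the epoch's supervised training set; the backbone is
   optimised over it in mini-batches with the batch-level QWK loss
   (or plain cross-entropy, pluggable via config).

Inference uses a single tile as well: the slide's predicted class is
the argmax (or, optionally, the rounded expected value) of the
top-ranked tile's probabilities, and that tile is returned as evidence.

An optional fully-supervised pre-training stage consumes region
annotations reduced to tile labels, mirroring the use of a small
annotated subset to warm-start the weakly-supervised stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .backbone import Backbone
from .ordinal import (
    ContractViolation,
    OrdinalLabelSpace,
    accuracy,
    confusion_matrix,
    crc3,
    expected_value_score,
    lesion_sensitivity,
    qwk,
)
from .regions import RegionAnnotation, tile_labels_from_regions
from .synthetic import GeneratedDataset, slide_grid_layout
from .tiling import TileRef

__all__ = [
    "SlideBag",
    "TrainConfig",
    "MILDataset",
    "score_all_tiles",
    "select_top_tile",
    "mil_train_epoch",
    "pretrain_on_annotations",
    "predict_slide",
    "run_training",
    "subset_experiment",
    "evaluate_bags",
    "bags_from_generated",
    "bag_probabilities",
    "epochs_to_reach",
    "stratified_holdout",
    "FeatureCache",
    "TrainedModel",
]


class ConfigurationError(ValueError):
    """The run configuration is inconsistent with the data."""


@dataclass
class SlideBag:
    """One slide as a MIL bag: its tiles, label, split tag.

    Tile images come either from the in-memory ``images`` list (aligned
    with ``tiles``) or from a ``loader`` callable mapping a
    :class:`TileRef` to an RGB array.
    """

    slide_id: str
    tiles: list[TileRef]
    label: int
    split: str = "train"
    annotated: bool = False
    images: list[np.ndarray] | None = None
    loader: Callable[[TileRef], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not self.tiles:
            raise ContractViolation(f"bag {self.slide_id!r} has no tiles")
        if self.label < 0:
            raise ContractViolation("slide label must be a class index")
        if self.images is not None and len(self.images) != len(self.tiles):
            raise ContractViolation("images must align with tiles")

    def image(self, i: int) -> np.ndarray:
        if self.images is not None:
            return self.images[i]
        if self.loader is None:
            raise ContractViolation(f"bag {self.slide_id!r} has no image source")
        return self.loader(self.tiles[i])

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters; every artifact records the seed.

    Defaults follow the reference training recipe (batches of 32, Adam
    at 1e-4, 512 px tiles, QWK loss, two pre-training epochs); small
    synthetic studies typically raise the learning rate and shrink the
    tile size, which the experiment helpers do explicitly.
    """

    batch_size: int = 32
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    epochs: int = 20
    pretrain_epochs: int = 2
    seed: int = 0
    tile_size: int = 512
    loss: str = "qwk"  # or "cross_entropy"
    ce_weight: float = 0.5  # cross-entropy stabiliser mixed into the QWK loss
    qwk_variant: str = "linear"  # or "log"
    decode: str = "argmax"  # or "expected"
    val_fraction: float = 0.15
    hidden: int = 16

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs + 1, self.pretrain_epochs + 1) <= 0:
            raise ConfigurationError("batch_size must be positive; epochs non-negative")
        if self.learning_rate < 0 or not 0 <= self.val_fraction < 1:
            raise ConfigurationError("learning_rate must be >= 0 and val_fraction in [0, 1)")
        if self.loss not in ("qwk", "cross_entropy"):
            raise ConfigurationError(f"unknown loss {self.loss!r}")
        if self.decode not in ("argmax", "expected"):
            raise ConfigurationError(f"unknown decode rule {self.decode!r}")


@dataclass
class MILDataset:
    """Bags plus label space and any region annotations."""

    bags: list[SlideBag]
    space: OrdinalLabelSpace = field(default_factory=crc3)
    annotations: list[RegionAnnotation] = field(default_factory=list)

    def split(self, tag: str) -> list[SlideBag]:
        return [b for b in self.bags if b.split == tag]

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "slide_id": b.slide_id,
                    "label": b.label,
                    "split": b.split,
                    "annotated": b.annotated,
                }
                for b in self.bags
            ],
            columns=["slide_id", "label", "split", "annotated"],
        )


class FeatureCache:
    """Per-tile feature memoisation; features are fixed given the extractor."""

    def __init__(self) -> None:
        self._store: dict[tuple[str, int, int], np.ndarray] = {}

    def features(self, bag: SlideBag, backbone: Backbone) -> np.ndarray:
        rows = []
        for i, t in enumerate(bag.tiles):
            key = (t.slide_id, t.x, t.y)
            if key not in self._store:
                self._store[key] = backbone.featurize(bag.image(i))
            rows.append(self._store[key])
        return np.stack(rows)


def bag_probabilities(
    bag: SlideBag, backbone: Backbone, cache: FeatureCache | None = None
) -> np.ndarray:
    """Class probabilities for every tile of a bag (evaluation mode)."""
    try:
        if cache is not None:
            feats = cache.features(bag, backbone)
        else:
            feats = np.stack([backbone.featurize(bag.image(i)) for i in range(bag.n_tiles)])
        return backbone.predict_proba_features(feats)
    except NotImplementedError:
        return backbone.predict_proba([bag.image(i) for i in range(bag.n_tiles)])


def score_all_tiles(
    bag: SlideBag, backbone: Backbone, cache: FeatureCache | None = None
) -> list[tuple[TileRef, np.ndarray, float]]:
    """Expected-value severity score per tile, in manifest order."""
    probs = bag_probabilities(bag, backbone, cache)
    space = backbone.space
    return [
        (t, p, expected_value_score(p, space)) for t, p in zip(bag.tiles, probs)
    ]


def select_top_tile(scored: Sequence[tuple[TileRef, np.ndarray, float]]) -> int:
    """Index of the maximal-score tile; ties go to the lowest manifest index."""
    if not scored:
        raise ContractViolation("cannot select a tile from an empty ranking")
    scores = np.array([s for _, _, s in scored])
    return int(np.argmax(scores))  # argmax returns the first maximum


@dataclass
class EpochLog:
    epoch: int
    loss: float
    train_qwk: float
    train_accuracy: float
    selections: dict[str, tuple[int, int, int]]  # slide_id -> (x, y, tile index)


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator) -> Iterable[np.ndarray]:
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _safe_qwk(truth: Sequence[int], pred: Sequence[int], k: int) -> float:
    try:
        return qwk(confusion_matrix(truth, pred, k))
    except ContractViolation:
        return float("nan")


def mil_train_epoch(
    bags: Sequence[SlideBag],
    backbone: Backbone,
    config: TrainConfig,
    cache: FeatureCache | None = None,
    rng: np.random.Generator | None = None,
    epoch: int = 0,
) -> EpochLog:
    """One MIL epoch: rank all tiles, then train on the top tile per bag.

    Ranking uses the epoch-start parameter state for every bag (the
    snapshot semantics make reruns reproducible); the selected tiles are
    then visited in seeded shuffled mini-batches.
    """
    if not bags:
        raise ConfigurationError("cannot train on an empty bag list")
    rng = rng or np.random.default_rng(config.seed)
    cache = cache if cache is not None else FeatureCache()
    k = backbone.space.n_classes

    feats, labels, selections, top_preds = [], [], {}, []
    for bag in bags:
        scored = score_all_tiles(bag, backbone, cache)
        idx = select_top_tile(scored)
        tile, probs, _ = scored[idx]
        selections[bag.slide_id] = (tile.x, tile.y, idx)
        feats.append(cache.features(bag, backbone)[idx])
        labels.append(bag.label)
        top_preds.append(int(np.argmax(probs)))
    feats = np.stack(feats)
    labels = np.asarray(labels)

    losses = []
    for batch in _iter_batches(len(bags), config.batch_size, rng):
        value = backbone.train_batch(
            feats[batch],
            labels[batch],
            loss=config.loss,
            lr=config.learning_rate,
            ce_weight=config.ce_weight,
            variant=config.qwk_variant,
        )
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        losses.append(value)

    return EpochLog(
        epoch=epoch,
        loss=float(np.mean(losses)),
        train_qwk=_safe_qwk(labels, top_preds, k),
        train_accuracy=accuracy(labels, top_preds),
        selections=selections,
    )


def predict_slide(
    bag: SlideBag, backbone: Backbone, cache: FeatureCache | None = None, decode: str = "argmax"
) -> tuple[int, np.ndarray, TileRef]:
    """Slide label from the top-ranked tile; returns the evidence tile.

    ``decode="argmax"`` takes the modal class of the top tile;
    ``decode="expected"`` rounds its expected-value score to the nearest
    class value instead.
    """
    scored = score_all_tiles(bag, backbone, cache)
    idx = select_top_tile(scored)
    tile, probs, score = scored[idx]
    if decode == "argmax":
        cls = int(np.argmax(probs))
    elif decode == "expected":
        values = np.asarray(backbone.space.values)
        cls = int(np.argmin(np.abs(values - score)))
    else:
        raise ContractViolation(f"unknown decode rule {decode!r}")
    return cls, probs, tile


def evaluate_bags(
    bags: Sequence[SlideBag],
    backbone: Backbone,
    cache: FeatureCache | None = None,
    decode: str = "argmax",
) -> dict:
    """Slide-level QWK, accuracy and lesion sensitivity over a split."""
    if not bags:
        raise ConfigurationError("cannot evaluate an empty bag list")
    truth = [b.label for b in bags]
    pred = [predict_slide(b, backbone, cache, decode)[0] for b in bags]
    k = backbone.space.n_classes
    try:
        sens = lesion_sensitivity(truth, pred)
    except ContractViolation:
        sens = float("nan")
    return {
        "qwk": _safe_qwk(truth, pred, k),
        "accuracy": accuracy(truth, pred),
        "lesion_sensitivity": sens,
        "n": len(bags),
    }


def pretrain_on_annotations(
    annotations: Sequence[RegionAnnotation],
    bags: Sequence[SlideBag],
    backbone: Backbone,
    config: TrainConfig,
    cache: FeatureCache | None = None,
) -> Backbone:
    """Fully-supervised warm-start from region annotations.

    Polygons are reduced to tile labels (majority-area rule, severity
    wins ties, non-diagnostic tags excluded); the backbone is trained
    ``config.pretrain_epochs`` epochs over the labelled tiles with the
    configured loss.  Raises :class:`ConfigurationError` when no tile
    receives a label.
    """
    cache = cache if cache is not None else FeatureCache()
    feats, labels = [], []
    for bag in bags:
        tile_labels = tile_labels_from_regions(bag.tiles, annotations, backbone.space)
        if not tile_labels:
            continue
        bag_feats = cache.features(bag, backbone)
        for i, lab in tile_labels.items():
            feats.append(bag_feats[i])
            labels.append(lab)
    if not feats:
        raise ConfigurationError("no tile received a diagnostic label from the annotations")
    feats = np.stack(feats)
    labels = np.asarray(labels)
    rng = np.random.default_rng([config.seed, 0xA]) if config.seed is not None else np.random.default_rng()
    for _ in range(config.pretrain_epochs):
        for batch in _iter_batches(len(labels), config.batch_size, rng):
            backbone.train_batch(
                feats[batch],
                labels[batch],
                loss=config.loss,
                lr=config.learning_rate,
                ce_weight=config.ce_weight,
                variant=config.qwk_variant,
            )
    return backbone


def stratified_holdout(
    bags: Sequence[SlideBag], fraction: float, seed: int
) -> tuple[list[SlideBag], list[SlideBag]]:
    """Split bags into (kept, held-out), stratified by label, seeded."""
    rng = np.random.default_rng([seed, 0x5])
    by_label: dict[int, list[int]] = {}
    for i, b in enumerate(bags):
        by_label.setdefault(b.label, []).append(i)
    held: set[int] = set()
    for label, idxs in sorted(by_label.items()):
        idxs = np.array(idxs)
        rng.shuffle(idxs)
        n_hold = int(round(fraction * len(idxs)))
        held.update(int(i) for i in idxs[:n_hold])
    kept = [b for i, b in enumerate(bags) if i not in held]
    out = [b for i, b in enumerate(bags) if i in held]
    return kept, out


@dataclass
class TrainedModel:
    """Backbone at the selected checkpoint plus the training history."""

    backbone: Backbone
    history: pd.DataFrame
    config: TrainConfig
    best_epoch: int | None


def run_training(
    dataset: MILDataset,
    config: TrainConfig,
    pretrain: bool = False,
    backbone: Backbone | None = None,
    cache: FeatureCache | None = None,
) -> TrainedModel:
    """Optional supervised pre-training, then the MIL epochs.

    Validation bags are taken from the dataset's ``val`` split if
    present, otherwise held out of the training split (stratified,
    seeded, ``config.val_fraction``).  The returned backbone carries the
    parameters of the epoch with maximal validation QWK; with no
    validation bags, the final state is kept.
    """
    from .backbone import TextureBackbone

    train_bags = dataset.split("train")
    if not train_bags:
        raise ConfigurationError("dataset has no training bags")
    val_bags = dataset.split("val")
    if not val_bags and config.val_fraction > 0:
        train_bags, val_bags = stratified_holdout(train_bags, config.val_fraction, config.seed)
        if not train_bags:
            raise ConfigurationError("validation hold-out consumed every training bag")

    backbone = backbone or TextureBackbone(
        dataset.space, hidden=config.hidden, seed=config.seed
    )
    cache = cache if cache is not None else FeatureCache()
    if pretrain:
        anns = [a for a in dataset.annotations]
        annotated_bags = [b for b in train_bags if b.annotated]
        backbone = pretrain_on_annotations(anns, annotated_bags, backbone, config, cache)

    rng = np.random.default_rng([config.seed, 0x7])
    rows = []
    best_state, best_qwk, best_epoch = None, -np.inf, None
    for epoch in range(config.epochs):
        log = mil_train_epoch(train_bags, backbone, config, cache, rng, epoch)
        row = {
            "epoch": epoch,
            "loss": log.loss,
            "train_qwk": log.train_qwk,
            "train_accuracy": log.train_accuracy,
        }
        if val_bags:
            val = evaluate_bags(val_bags, backbone, cache, config.decode)
            row["val_qwk"] = val["qwk"]
            row["val_accuracy"] = val["accuracy"]
            if np.isfinite(val["qwk"]) and val["qwk"] > best_qwk:
                best_state, best_qwk, best_epoch = backbone.state_dict(), val["qwk"], epoch
        rows.append(row)
    if best_state is not None:
        backbone.load_state_dict(best_state)
    history = pd.DataFrame(rows)
    return TrainedModel(backbone=backbone, history=history, config=config, best_epoch=best_epoch)


def subset_experiment(
    dataset: MILDataset,
    sizes: Sequence[int],
    config: TrainConfig,
    pretrain: bool = False,
) -> pd.DataFrame:
    """Train on nested training subsets and evaluate on the fixed test set.

    The training bags are shuffled once per seed; subsets are prefixes
    of that order, so smaller subsets are contained in larger ones.  All
    rows share the same test bags.
    """
    train_bags = dataset.split("train")
    test_bags = dataset.split("test")
    if not test_bags:
        raise ConfigurationError("subset experiment needs a test split")
    if max(sizes) > len(train_bags):
        raise ConfigurationError(
            f"subset size {max(sizes)} exceeds the {len(train_bags)} available training bags"
        )
    rng = np.random.default_rng([config.seed, 0x55])
    order = rng.permutation(len(train_bags))
    cache = FeatureCache()
    rows = []
    for size in sorted(sizes):
        subset = [train_bags[i] for i in order[:size]]
        sub_ds = MILDataset(
            bags=subset + test_bags, space=dataset.space, annotations=dataset.annotations
        )
        model = run_training(sub_ds, config, pretrain=pretrain, cache=cache)
        metrics = evaluate_bags(test_bags, model.backbone, cache, config.decode)
        rows.append(
            {
                "size": size,
                "qwk": metrics["qwk"],
                "accuracy": metrics["accuracy"],
                "lesion_sensitivity": metrics["lesion_sensitivity"],
                "best_epoch": model.best_epoch,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bridging synthetic datasets into MIL bags
# ---------------------------------------------------------------------------

def bags_from_generated(
    generated: GeneratedDataset,
    test_fraction: float = 0.25,
    seed: int | None = None,
) -> MILDataset:
    """Wrap generator output as a MIL dataset with a stratified test split.

    Tile coordinates follow the same near-square mosaic layout the
    pyramidal assembly uses, so manifests, annotations and in-memory
    bags all agree on geometry.
    """
    from .synthetic import ground_truth_annotations

    spec = generated.spec
    size = spec.tile_size
    bags = []
    for rec in generated.slides:
        cols, _ = slide_grid_layout(rec.n_tiles)
        tiles = []
        for i in range(rec.n_tiles):
            r, c = divmod(i, cols)
            tiles.append(TileRef(rec.slide_id, c * size, r * size, size))
        bags.append(
            SlideBag(
                slide_id=rec.slide_id,
                tiles=tiles,
                label=rec.label,
                annotated=rec.annotated,
                images=rec.images,
            )
        )
    seed = spec.seed if seed is None else seed
    if test_fraction > 0 and bags:
        _, test = stratified_holdout(bags, test_fraction, seed)
        test_ids = {b.slide_id for b in test}
        for b in bags:
            b.split = "test" if b.slide_id in test_ids else "train"
    annotations = []
    for rec in generated.slides:
        if rec.annotated:
            annotations.extend(ground_truth_annotations(rec, spec.space))
    return MILDataset(bags=bags, space=spec.space, annotations=annotations)


def epochs_to_reach(history: pd.DataFrame, threshold: float, column: str = "val_qwk") -> float:
    """1-based index of the first epoch whose ``column`` reaches ``threshold``
    (inf if never)."""
    if column not in history:
        return float("inf")
    hit = history.index[history[column] >= threshold]
    return float(hit[0] + 1) if len(hit) else float("inf")
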