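"""MIL engine: ranking, selection, training loop, prediction, experiments."""

import numpy as np
import pytest

from ordmil.backbone import StubBackbone, TextureBackbone
from ordmil.mil import (
    ConfigurationError,
    FeatureCache,
    MILDataset,
    SlideBag,
    TrainConfig,
    bags_from_generated,
    epochs_to_reach,
    evaluate_bags,
    mil_train_epoch,
    predict_slide,
    pretrain_on_annotations,
    run_training,
    score_all_tiles,
    select_top_tile,
    stratified_holdout,
    subset_experiment,
)
from ordmil.ordinal import ContractViolation, crc3
from ordmil.synthetic import SyntheticSpec, generate_dataset
from ordmil.tiling import TileRef

SPACE = crc3()


def make_bag(n_tiles=3, label=1, slide_id="s", seed=0):
    rng = np.random.default_rng(seed)
    tiles = [TileRef(slide_id, i * 32, 0, 32) for i in range(n_tiles)]
    images = [rng.integers(0, 255, size=(32, 32, 3), dtype=np.uint8) for _ in range(n_tiles)]
    return SlideBag(slide_id=slide_id, tiles=tiles, label=label, images=images)


class TestScoring:
    def test_single_tile_bag_yields_one_entry(self):
        bag = make_bag(1)
        scored = score_all_tiles(bag, StubBackbone(SPACE))
        assert len(scored) == 1

    def test_uniform_backbone_scores_midpoint(self):
        """Uniform probabilities give score (K-1)/2 for every tile."""
        bag = make_bag(4)
        scored = score_all_tiles(bag, StubBackbone(SPACE))
        assert all(s == pytest.approx(1.0) for _, _, s in scored)

    def test_marked_tile_scores_maximal(self):
        bag = make_bag(3)
        target = bag.images[1][0, 0].copy()

        def rule(img):
            return (0.0, 0.0, 1.0) if (img[0, 0] == target).all() else (1.0, 0.0, 0.0)

        scored = score_all_tiles(bag, StubBackbone(SPACE, rule))
        scores = [s for _, _, s in scored]
        assert scores[1] == 2.0 and np.argmax(scores) == 1

    def test_order_preserved_from_manifest(self):
        bag = make_bag(5)
        scored = score_all_tiles(bag, StubBackbone(SPACE))
        assert [t.x for t, _, _ in scored] == [t.x for t in bag.tiles]


class TestSelection:
    def _scored(self, scores):
        return [(TileRef("s", i, 0, 32), None, s) for i, s in enumerate(scores)]

    def test_argmax(self):
        assert select_top_tile(self._scored([0.1, 1.9, 0.5])) == 1

    def test_single_tile(self):
        assert select_top_tile(self._scored([0.7])) == 0

    def test_tie_breaks_to_lowest_index(self):
        assert select_top_tile(self._scored([1.0, 1.0])) == 0

    def test_empty_rejected(self):
        with pytest.raises(ContractViolation):
            select_top_tile([])


class TestTrainEpoch:
    def test_zero_learning_rate_keeps_parameters(self):
        ds = bags_from_generated(generate_dataset(SyntheticSpec(n_slides=8, seed=1)), 0.0)
        bb = TextureBackbone(SPACE, seed=1)
        cfg = TrainConfig(learning_rate=0.0, tile_size=128, seed=1)
        cache = FeatureCache()
        before = {k: v.copy() for k, v in bb.params.items()}
        log = mil_train_epoch(ds.bags, bb, cfg, cache)
        for k in before:
            np.testing.assert_array_equal(before[k], bb.params[k])
        assert np.isfinite(log.loss)

    def test_single_bag_trains_on_one_tile(self):
        bag = make_bag(4, label=2)
        bb = TextureBackbone(SPACE, seed=0)
        cfg = TrainConfig(learning_rate=0.01, tile_size=32, seed=0)
        log = mil_train_epoch([bag], bb, cfg)
        assert len(log.selections) == 1
        assert "s" in log.selections

    def test_selection_matches_epoch_start_ranking(self):
        """The trained tile is the argmax of the ranking pass at epoch start."""
        ds = bags_from_generated(generate_dataset(SyntheticSpec(n_slides=10, seed=2)), 0.0)
        bb = TextureBackbone(SPACE, seed=2)
        cache = FeatureCache()
        expected = {}
        for bag in ds.bags:
            scored = score_all_tiles(bag, bb, cache)
            idx = select_top_tile(scored)
            expected[bag.slide_id] = (scored[idx][0].x, scored[idx][0].y, idx)
        cfg = TrainConfig(learning_rate=0.02, tile_size=128, seed=2)
        log = mil_train_epoch(ds.bags, bb, cfg, cache)
        assert log.selections == expected

    def test_empty_bags_rejected(self):
        with pytest.raises(ConfigurationError):
            mil_train_epoch([], TextureBackbone(SPACE), TrainConfig())


class TestPredictSlide:
    def test_constant_benign_backbone_predicts_benign(self):
        bag = make_bag(3, label=2)
        rule = lambda img: (1.0, 0.0, 0.0)
        cls, probs, tile = predict_slide(bag, StubBackbone(SPACE, rule))
        assert cls == 0

    def test_prediction_follows_top_ranked_tile(self):
        """One tile at (0.1, 0.2, 0.7) among benign one-hots wins and decodes 2."""
        bag = make_bag(4)
        target = bag.images[2][0, 0].copy()

        def rule(img):
            return (0.1, 0.2, 0.7) if (img[0, 0] == target).all() else (1.0, 0.0, 0.0)

        cls, probs, tile = predict_slide(bag, StubBackbone(SPACE, rule))
        assert cls == 2 and tile.x == bag.tiles[2].x
        np.testing.assert_allclose(probs, (0.1, 0.2, 0.7))

    def test_expected_value_decoding(self):
        bag = make_bag(1)
        rule = lambda img: (0.0, 0.55, 0.45)  # expected value 1.45 -> class 1
        cls, _, _ = predict_slide(bag, StubBackbone(SPACE, rule), decode="expected")
        assert cls == 1

    def test_deterministic_across_calls(self):
        ds = bags_from_generated(generate_dataset(SyntheticSpec(n_slides=4, seed=3)), 0.0)
        bb = TextureBackbone(SPACE, seed=3)
        first = [predict_slide(b, bb)[0] for b in ds.bags]
        second = [predict_slide(b, bb)[0] for b in ds.bags]
        assert first == second


class TestPretraining:
    def _dataset(self, seed=4, n=20):
        return bags_from_generated(generate_dataset(SyntheticSpec(n_slides=n, seed=seed)), 0.0)

    def test_annotated_tiles_receive_generator_labels(self):
        """Region marks, reduced by the coverage rule, recover the ground truth."""
        ds = self._dataset()
        gen = generate_dataset(SyntheticSpec(n_slides=20, seed=4))
        from ordmil.regions import tile_labels_from_regions

        truth = {rec.slide_id: rec.tile_classes for rec in gen.slides if rec.annotated}
        for bag in ds.bags:
            if not bag.annotated:
                continue
            labels = tile_labels_from_regions(bag.tiles, ds.annotations, SPACE)
            assert [labels[i] for i in range(bag.n_tiles)] == truth[bag.slide_id]

    def test_no_labelled_tiles_is_configuration_error(self):
        ds = self._dataset()
        bb = TextureBackbone(SPACE, seed=0)
        with pytest.raises(ConfigurationError):
            pretrain_on_annotations([], ds.bags, bb, TrainConfig(seed=0))

    def test_pretraining_updates_parameters(self):
        ds = self._dataset()
        bb = TextureBackbone(SPACE, seed=0)
        before = {k: v.copy() for k, v in bb.params.items()}
        annotated = [b for b in ds.bags if b.annotated]
        pretrain_on_annotations(
            ds.annotations, annotated, bb, TrainConfig(seed=0, learning_rate=0.02)
        )
        assert any(not np.array_equal(before[k], bb.params[k]) for k in before)


class TestRunTraining:
    def _dataset(self, seed=5, n=30):
        return bags_from_generated(generate_dataset(SyntheticSpec(n_slides=n, seed=seed)), 0.25)

    def test_seeded_rerun_is_identical(self):
        ds = self._dataset()
        cfg = TrainConfig(learning_rate=0.02, epochs=4, tile_size=128, seed=5)
        h1 = run_training(ds, cfg).history
        h2 = run_training(ds, cfg).history
        assert h1.equals(h2)

    def test_zero_epochs_returns_initial_model(self):
        ds = self._dataset()
        cfg = TrainConfig(epochs=0, tile_size=128, seed=5)
        model = run_training(ds, cfg)
        assert model.history.empty and model.best_epoch is None
        fresh = TextureBackbone(SPACE, hidden=cfg.hidden, seed=5)
        for k in fresh.params:
            np.testing.assert_array_equal(fresh.params[k], model.backbone.params[k])

    def test_checkpoint_is_best_validation_epoch(self):
        ds = self._dataset(seed=6, n=40)
        cfg = TrainConfig(learning_rate=0.02, epochs=8, tile_size=128, seed=6)
        model = run_training(ds, cfg)
        hist = model.history
        assert model.best_epoch == int(hist.val_qwk.idxmax())

    def test_empty_train_split_rejected(self):
        ds = self._dataset()
        for b in ds.bags:
            b.split = "test"
        with pytest.raises(ConfigurationError):
            run_training(ds, TrainConfig(seed=0))

    def test_cross_entropy_loss_is_pluggable(self):
        """Swapping the ordinal loss for cross-entropy leaves the loop intact."""
        ds = self._dataset(seed=7)
        cfg = TrainConfig(learning_rate=0.02, epochs=6, tile_size=128, seed=7,
                          loss="cross_entropy")
        model = run_training(ds, cfg)
        metrics = evaluate_bags(ds.split("test"), model.backbone, FeatureCache())
        assert np.isfinite(metrics["qwk"]) and 0 <= metrics["accuracy"] <= 1


class TestSubsetExperiment:
    def test_nested_subsets_and_sorting(self):
        ds = bags_from_generated(generate_dataset(SyntheticSpec(n_slides=40, seed=8)), 0.25)
        cfg = TrainConfig(learning_rate=0.02, epochs=3, tile_size=128, seed=8)
        table = subset_experiment(ds, [20, 5, 10], cfg)
        assert list(table["size"]) == [5, 10, 20]

    def test_full_size_matches_run_training(self):
        ds = bags_from_generated(generate_dataset(SyntheticSpec(n_slides=30, seed=9)), 0.3)
        n_train = len(ds.split("train"))
        cfg = TrainConfig(learning_rate=0.02, epochs=4, tile_size=128, seed=9)
        table = subset_experiment(ds, [n_train], cfg)
        model = run_training(ds, cfg)
        metrics = evaluate_bags(ds.split("test"), model.backbone, FeatureCache())
        assert table.iloc[0]["qwk"] == pytest.approx(metrics["qwk"])

    def test_oversized_subset_rejected(self):
        ds = bags_from_generated(generate_dataset(SyntheticSpec(n_slides=10, seed=1)), 0.3)
        with pytest.raises(ConfigurationError):
            subset_experiment(ds, [999], TrainConfig(seed=1))

    def test_missing_test_split_rejected(self):
        ds = bags_from_generated(generate_dataset(SyntheticSpec(n_slides=10, seed=1)), 0.0)
        with pytest.raises(ConfigurationError):
            subset_experiment(ds, [5], TrainConfig(seed=1))


class TestSplitsAndHelpers:
    def test_stratified_holdout_fractions(self):
        ds = bags_from_generated(generate_dataset(SyntheticSpec(n_slides=60, seed=2)), 0.0)
        kept, held = stratified_holdout(ds.bags, 0.25, seed=0)
        assert len(kept) + len(held) == 60
        assert abs(len(held) - 15) <= 2  # per-class rounding
        # no overlap
        assert not {b.slide_id for b in kept} & {b.slide_id for b in held}

    def test_epochs_to_reach(self):
        import pandas as pd

        hist = pd.DataFrame({"val_qwk": [0.2, 0.5, 0.85, 0.9]})
        assert epochs_to_reach(hist, 0.8) == 3.0
        assert epochs_to_reach(hist, 0.95) == float("inf")

    def test_empty_bag_rejected(self):
        with pytest.raises(ContractViolation):
            SlideBag(slide_id="x", tiles=[], label=0)
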