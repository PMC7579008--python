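import numpy as np
import pandas as pd
import pytest

from ashazard.forest import (
    ForestSpec,
    fit_forest,
    load_forest,
    predict_prob_raster,
    predict_prob_table,
    save_forest,
    stratified_split,
    tune_mtry,
)
from ashazard.grids import GridSpec, RasterGrid
from ashazard.prep import ModelingTable


def make_table(n=100, n_pos=42, p=3, seed=0) -> ModelingTable:
    rng = np.random.default_rng(seed)
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    rng.shuffle(labels)
    frame = pd.DataFrame({f"x{k}": rng.normal(size=n) for k in range(p)})
    frame["label"] = labels
    frame["as_ugL"] = np.where(labels == 1, 20.0, 5.0)
    return ModelingTable(frame, [f"x{k}" for k in range(p)])


class TestStratifiedSplit:
    def test_stratification_arithmetic(self):
        table = make_table(n=100, n_pos=42)
        split = stratified_split(table, 0.8, seed=0)
        assert len(split.train) == 80
        assert len(split.test) == 20
        assert split.train.labels.sum() in (33, 34)
        assert split.train.labels.sum() + split.test.labels.sum() == 42

    def test_same_seed_gives_identical_partition(self):
        table = make_table()
        a = stratified_split(table, seed=5)
        b = stratified_split(table, seed=5)
        pd.testing.assert_frame_equal(a.train.frame, b.train.frame)
        pd.testing.assert_frame_equal(a.test.frame, b.test.frame)

    @pytest.mark.parametrize("seed", range(50))
    def test_union_and_disjointness(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 120))
        n_pos = int(rng.integers(5, n - 5))
        table = make_table(n=n, n_pos=n_pos, seed=seed)
        table.frame["uid"] = np.arange(n)
        split = stratified_split(table, 0.8, seed=seed)
        train_ids = set(split.train.frame["uid"])
        test_ids = set(split.test.frame["uid"])
        assert train_ids.isdisjoint(test_ids)
        assert train_ids | test_ids == set(range(n))

    def test_single_class_rejected(self):
        table = make_table(n=30, n_pos=0)
        with pytest.raises(ValueError):
            stratified_split(table)


class TestTuneMtry:
    def test_single_candidate_returns_it(self):
        table = make_table(n=80, p=1)
        best, trace = tune_mtry(table, n_trees_tuning=25, seed=0)
        assert best == 1
        assert list(trace["mtry"]) == [1]

    def test_returns_argmax_of_trace_with_parsimony_ties(self):
        table = make_table(n=200, p=6, seed=2)
        best, trace = tune_mtry(table, n_trees_tuning=51, seed=3)
        top = trace["oob_accuracy"].max()
        assert trace.loc[trace["mtry"] == best, "oob_accuracy"].iloc[0] == top
        # smallest among the tied maximizers
        assert best == int(trace.loc[trace["oob_accuracy"] == top, "mtry"].min())

    def test_out_of_range_candidates_rejected(self):
        table = make_table(p=3)
        with pytest.raises(ValueError):
            tune_mtry(table, candidates=[0, 2])


class TestFitForest:
    def test_label_copied_from_predictor_is_learnable(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 2, 500)
        frame = pd.DataFrame({"x0": x.astype(float), "label": x, "as_ugL": 0.0})
        table = ModelingTable(frame, ["x0"])
        model = fit_forest(table, ForestSpec(n_trees=101, mtry=1, seed=0))
        assert model.oob_accuracy > 0.95

    def test_permuted_labels_give_chance_oob(self):
        rng = np.random.default_rng(8)
        n = 2000
        labels = (rng.uniform(size=n) < 0.42).astype(int)
        frame = pd.DataFrame({f"x{k}": rng.normal(size=n) for k in range(5)})
        frame["label"] = labels
        frame["as_ugL"] = 0.0
        table = ModelingTable(frame, [f"x{k}" for k in range(5)])
        model = fit_forest(table, ForestSpec(n_trees=101, mtry=2, seed=1))
        majority = max(labels.mean(), 1 - labels.mean())
        assert abs(model.oob_accuracy - majority) < 0.05

    def test_seeded_determinism(self):
        table = make_table(n=200, seed=3)
        spec = ForestSpec(n_trees=51, mtry=2, seed=9)
        a = fit_forest(table, spec)
        b = fit_forest(table, spec)
        assert a.oob_accuracy == b.oob_accuracy
        np.testing.assert_array_equal(
            predict_prob_table(a, table), predict_prob_table(b, table)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_forest(make_table(n=30, n_pos=30), ForestSpec(n_trees=11))


class TestPredict:
    def test_probabilities_bounded(self, small_forest, small_table):
        p = predict_prob_table(small_forest, small_table)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_schema_mismatch_names_offending_columns(self, small_forest):
        bad = pd.DataFrame({"wrong": [1.0]})
        with pytest.raises(ValueError, match="field_00"):
            predict_prob_table(small_forest, bad)

    def test_raster_and_table_predictions_agree(self, small_forest, small_landscape):
        prob = predict_prob_raster(small_forest, small_landscape.predictors)
        rng = np.random.default_rng(10)
        rows = rng.integers(0, small_landscape.grid.nrows, 50)
        cols = rng.integers(0, small_landscape.grid.ncols, 50)
        frame = pd.DataFrame(
            {
                name: raster.data[rows, cols]
                for name, raster in small_landscape.predictors.items()
            }
        )
        table_p = predict_prob_table(small_forest, frame)
        np.testing.assert_allclose(prob.data[rows, cols], table_p)

    def test_nodata_cells_propagate(self, small_forest, small_landscape):
        predictors = dict(small_landscape.predictors)
        first = next(iter(predictors))
        data = predictors[first].data.copy()
        data[0, 0] = np.nan
        predictors[first] = RasterGrid(small_landscape.grid, data)
        prob = predict_prob_raster(small_forest, predictors)
        assert np.isnan(prob.data[0, 0])
        assert np.isfinite(prob.data[1:, :]).all()

    def test_misregistered_stack_rejected(self, small_forest, small_landscape):
        predictors = dict(small_landscape.predictors)
        first = next(iter(predictors))
        other = GridSpec(0.0, 0.0, 1.0, *small_landscape.grid.shape)
        predictors[first] = RasterGrid(other, predictors[first].data)
        with pytest.raises(ValueError, match="co-registered"):
            predict_prob_raster(small_forest, predictors)

    def test_save_load_round_trip(self, small_forest, small_table, tmp_path):
        path = tmp_path / "model.joblib"
        save_forest(small_forest, path)
        back = load_forest(path)
        np.testing.assert_array_equal(
            predict_prob_table(small_forest, small_table),
            predict_prob_table(back, small_table),
        )
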