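"""Feature pruning, classifier search, persistence, merging, eval."""

import numpy as np
import pandas as pd
import pytest

from rriclass.config import Config
from rriclass.features import FeatureTable
from rriclass.model import (
    RRISiteClassifier,
    TrainedModel,
    evaluate_sites,
    merge_feature_tables,
    prune_features,
    train_model,
)

import scipy.sparse as sp


def toy_data(rng, n=80, informative=True):
    X = rng.normal(size=(n, 6))
    y = (rng.random(n) < 0.5).astype(int)
    if informative:
        X[:, 2] = y + 0.05 * rng.normal(size=n)
    X[:, 4] = 1.0  # constant column
    return pd.DataFrame(X, columns=[f"f{k}" for k in range(6)]), y


class TestPruneFeatures:
    def test_constant_column_dropped(self, rng):
        X, y = toy_data(rng)
        kept, imp = prune_features(X, y, 1e-4, rng_seed=0)
        assert "f4" not in kept and imp[4] == 0.0

    def test_zero_cutoff_retains_everything(self, rng):
        X, y = toy_data(rng)
        kept, _ = prune_features(X, y, 0.0, rng_seed=0)
        assert kept == list(X.columns)

    def test_informative_column_survives(self, rng):
        X, y = toy_data(rng)
        kept, imp = prune_features(X, y, 1e-4, rng_seed=0)
        assert "f2" in kept and imp[2] == imp.max()

    def test_single_class_errors(self, rng):
        X, _ = toy_data(rng)
        with pytest.raises(ValueError):
            prune_features(X, np.zeros(len(X)), 1e-4, rng_seed=0)

    def test_cap_keeps_top_importances(self, rng):
        X, y = toy_data(rng, n=60)
        kept, imp = prune_features(X, y, 0.0, rng_seed=0, max_features_kept=2)
        assert len(kept) == 2 and "f2" in kept


class TestClassifier:
    def test_separable_data_perfect_cv_f1(self, rng):
        X, y = toy_data(rng)
        X["f2"] = y * 10.0  # fully separable
        clf = RRISiteClassifier(search_iters=4, random_state=0)
        clf.fit(X, y)
        assert clf.best_score_ == 1.0
        assert clf.best_family_ in ("hist_gb", "random_forest")
        assert (clf.predict(X) == y).all()

    def test_permuted_labels_score_near_chance(self, rng):
        scores = []
        for s in range(6):
            r = np.random.default_rng(s)
            X = pd.DataFrame(r.normal(size=(80, 5)),
                             columns=[f"f{k}" for k in range(5)])
            y = np.array([0, 1] * 40)
            y = r.permutation(y)
            clf = RRISiteClassifier(search_iters=3, random_state=s)
            clf.fit(X, y)
            scores.append(clf.best_score_)
        # F1 of a chance-level balanced classifier ~ 0.5; selection over
        # draws biases upward, so only assert it stays far from skill
        assert np.mean(scores) < 0.75

    def test_deterministic_cv_report(self, rng):
        X, y = toy_data(rng)
        reports = []
        for _ in range(2):
            clf = RRISiteClassifier(search_iters=5, random_state=7)
            clf.fit(X, y)
            reports.append(clf.cv_report_.to_csv())
        assert reports[0] == reports[1]

    def test_too_few_instances_names_minimum(self, rng):
        X, y = toy_data(rng, n=8)
        with pytest.raises(ValueError, match="at least 10"):
            RRISiteClassifier(random_state=0).fit(X, y)

    def test_single_class_errors(self, rng):
        X, _ = toy_data(rng)
        with pytest.raises(ValueError, match="single class"):
            RRISiteClassifier(random_state=0).fit(X, np.zeros(len(X)))

    def test_grouped_folds_keep_groups_intact(self, rng):
        X, y = toy_data(rng, n=60)
        groups = np.repeat(np.arange(30), 2)
        clf = RRISiteClassifier(search_iters=2, random_state=0)
        splits = list(clf._splitter(0, groups).split(X, y, groups))
        for tr, te in splits:
            assert not (set(groups[tr]) & set(groups[te]))

    def test_time_budget_stops_early_but_fits(self, rng):
        X, y = toy_data(rng)
        clf = RRISiteClassifier(search_iters=50, random_state=0, time_budget=0.01)
        clf.fit(X, y)
        assert hasattr(clf, "best_estimator_")


def small_table(rng, n_sites=20, fingerprint="fp", cols=None, hash_bits=None):
    cols = cols or ["a", "b", "c"]
    ids, labels = [], []
    for k in range(n_sites):
        ids += [f"s{k}::pos", f"s{k}::neg"]
        labels += [1.0, 0.0]
    dense = pd.DataFrame(
        rng.normal(size=(2 * n_sites, len(cols))), columns=cols
    )
    dense[cols[0]] += np.array(labels) * 3  # signal
    sparse = (
        sp.random(2 * n_sites, 1 << hash_bits, density=0.01,
                  random_state=1, format="csr")
        if hash_bits
        else None
    )
    return FeatureTable(
        ids=ids,
        dense=dense,
        labels=np.array(labels),
        sparse=sparse,
        fingerprint=fingerprint,
        hash_bits=hash_bits,
    )


class TestMergeTables:
    def test_identical_tables_double_rows(self, rng):
        t = small_table(rng)
        m = merge_feature_tables([t, t])
        assert len(m.ids) == 2 * len(t.ids)
        assert m.feature_names == t.feature_names
        assert m.provenance[:2] == ["source0", "source0"]

    def test_column_intersection(self, rng):
        t1 = small_table(rng, cols=["a", "b", "c"])
        t2 = small_table(rng, cols=["b", "c", "d"])
        m = merge_feature_tables([t1, t2])
        assert m.feature_names == sorted(
            set(["a", "b", "c"]) & set(["b", "c", "d"])
        )

    def test_empty_intersection_errors(self, rng):
        with pytest.raises(ValueError, match="share no"):
            merge_feature_tables(
                [small_table(rng, cols=["a"]), small_table(rng, cols=["b"])]
            )

    def test_hash_bits_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="hash_bits"):
            merge_feature_tables(
                [small_table(rng, hash_bits=10), small_table(rng, hash_bits=12)]
            )

    def test_merge_then_train(self, rng):
        cfg = Config(search_iters=3, rng_seed=0)
        t1 = small_table(rng, fingerprint="h")
        t2 = small_table(rng, fingerprint="m")
        model = train_model(merge_feature_tables([t1, t2]), cfg)
        assert model.classifier.best_score_ > 0.8


class TestPersistenceAndEval:
    def test_save_load_identical_predictions(self, rng, tmp_path):
        cfg = Config(search_iters=3, rng_seed=1)
        table = small_table(rng)
        model = train_model(table, cfg)
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = TrainedModel.load(path)
        a = evaluate_sites(model, table, force=True)
        b = evaluate_sites(loaded, table, force=True)
        pd.testing.assert_frame_equal(a, b)
        assert loaded.feature_names == model.feature_names

    def test_eval_reproduces_training_fit(self, rng):
        cfg = Config(search_iters=3, rng_seed=1)
        table = small_table(rng)
        model = train_model(table, cfg)
        out = evaluate_sites(model, table, force=True)
        fit_pred = model.classifier.predict(table.matrix())
        assert (out["predicted_label"].to_numpy() == fit_pred).all()

    def test_na_rows_for_sites_without_duplexes(self, rng):
        table = small_table(rng)
        table.na_ids.append("chr1:5-10:+;chr2:5-10:+::pos")
        model = train_model(table, Config(search_iters=2, rng_seed=0))
        out = evaluate_sites(model, table, force=True)
        na = out[out["predicted_label"] == "NA"]
        assert len(na) == 1 and na["site_id"].iloc[0] == "chr1:5-10:+;chr2:5-10:+"
        assert np.isnan(na["probability"]).all()

    def test_feature_mismatch_without_force_errors(self, rng):
        model = train_model(small_table(rng), Config(search_iters=2, rng_seed=0))
        other = small_table(rng, cols=["a", "b", "x"])
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_sites(model, other)

    def test_fingerprint_mismatch_without_force_errors(self, rng):
        model = train_model(small_table(rng), Config(search_iters=2, rng_seed=0))
        other = small_table(rng, fingerprint="other")
        with pytest.raises(ValueError, match="fingerprint"):
            evaluate_sites(model, other)
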