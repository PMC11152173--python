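"""Classifier selection, training, persistence and eval-mode labelling.

The central object is :class:`RRISiteClassifier`, a scikit-learn
compatible estimator that (1) drops near-zero-importance features via a
seeded random-forest importance screen, (2) runs a bounded randomized
hyperparameter search over the two classifier families that dominate on
this task — histogram-based gradient boosting and random forests —
selecting by mean cross-validated F1 on the positive class (stratified,
optionally site-grouped folds), and (3) refits the winner on all data.
An optional wall-clock budget bounds the search instead of the iteration
count. Class imbalance is handled by class weighting (on by default).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import (
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .config import Config
from .features import FeatureTable

FAMILIES = ("hist_gb", "random_forest")


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    if sp.issparse(X):
        return X.tocsr(), None
    return np.asarray(X, dtype=float), None


def _column_subset(X, idx):
    if sp.issparse(X):
        return X[:, idx]
    return X[:, idx]


def _densify(X):
    return X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)


def prune_features(
    X, y, importance_cutoff: float, rng_seed: int, max_features_kept: int = 256
):
    """Random-forest importance screen.

    Features below the importance cutoff are dropped; of the survivors at
    most ``max_features_kept`` (highest importance first, ties by column
    order) are retained, which bounds downstream search cost on wide
    hashed graph blocks. At least one feature is always kept (the
    importance argmax when all fall below the cutoff). Returns
    (retained, importances): retained feature names when X is a
    DataFrame, else retained column indices.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("pruning requires both classes in y")
    forest = RandomForestClassifier(
        n_estimators=200, random_state=rng_seed, n_jobs=1
    )
    forest.fit(Xm, y)
    imp = forest.feature_importances_
    keep = np.nonzero(imp >= importance_cutoff)[0]
    if keep.size == 0:
        keep = np.array([int(np.argmax(imp))])
    if keep.size > max_features_kept:
        order = np.lexsort((keep, -imp[keep]))
        keep = np.sort(keep[order[:max_features_kept]])
    if names is not None:
        return [names[i] for i in keep], imp
    return keep, imp


def _sample_params(family: str, rng: np.random.Generator) -> dict:
    if family == "hist_gb":
        return {
            "learning_rate": float(10 ** rng.uniform(-1.7, -0.3)),
            "max_iter": int(rng.integers(30, 121)),
            "max_leaf_nodes": int(rng.choice([7, 15, 31])),
            "min_samples_leaf": int(rng.integers(2, 31)),
            "l2_regularization": float(10 ** rng.uniform(-6, 1)),
        }
    if family == "random_forest":
        max_depth = rng.choice([0, 5, 10, 20, 40])
        return {
            "n_estimators": int(rng.integers(100, 301)),
            "max_depth": None if max_depth == 0 else int(max_depth),
            "max_features": rng.choice(["sqrt", "0.1", "0.2"]),
            "min_samples_leaf": int(rng.integers(1, 11)),
        }
    raise ValueError(f"unknown family {family!r}")


def _make_estimator(family, params, class_weight, seed):
    params = dict(params)
    if family == "hist_gb":
        # coarse bins + patience-based stopping: ample for a few hundred
        # training instances and much faster on wide graph-feature blocks
        return HistGradientBoostingClassifier(
            class_weight=class_weight,
            random_state=seed,
            max_bins=32,
            early_stopping=True,
            n_iter_no_change=10,
            validation_fraction=0.15,
            **params,
        )
    mf = params.pop("max_features")
    mf = float(mf) if mf not in ("sqrt", "log2") else mf
    return RandomForestClassifier(
        class_weight=class_weight,
        random_state=seed,
        n_jobs=1,
        max_features=mf,
        **params,
    )


class RRISiteClassifier(BaseEstimator, ClassifierMixin):
    """Binary classifier of interaction-site relevance.

    Parameters
    ----------
    families : tuple of str
        Classifier families searched ('hist_gb', 'random_forest').
    search_iters : int
        Number of randomized hyperparameter draws.
    cv_folds : int
        Stratified folds for the selection metric.
    importance_cutoff : float
        Random-forest importance below which features are dropped before
        the search.
    class_weight : 'balanced' or None
        Class weighting of both families.
    random_state : int or None
        Seed for pruning, sampling, folds and estimators.
    time_budget : float or None
        Optional wall-clock bound (seconds) on the search; at least one
        draw always runs.
    """

    def __init__(
        self,
        families=FAMILIES,
        search_iters: int = 50,
        cv_folds: int = 5,
        importance_cutoff: float = 1e-4,
        class_weight="balanced",
        random_state=None,
        time_budget=None,
    ):
        self.families = families
        self.search_iters = search_iters
        self.cv_folds = cv_folds
        self.importance_cutoff = importance_cutoff
        self.class_weight = class_weight
        self.random_state = random_state
        self.time_budget = time_budget

    def _splitter(self, seed, groups):
        if groups is not None:
            return StratifiedGroupKFold(
                n_splits=self.cv_folds, shuffle=True, random_state=seed
            )
        return StratifiedKFold(
            n_splits=self.cv_folds, shuffle=True, random_state=seed
        )

    def fit(self, X, y, groups=None):
        Xm, names = _as_matrix(X)
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training labels contain a single class")
        n = Xm.shape[0]
        n_min = 2 * self.cv_folds
        if n < n_min:
            raise ValueError(
                f"need at least {n_min} instances for {self.cv_folds}-fold "
                f"selection, got {n}"
            )
        seed = 0 if self.random_state is None else int(self.random_state)
        rng = np.random.default_rng(seed)
        groups = np.asarray(groups) if groups is not None else None

        keep, importances = prune_features(
            Xm, y, self.importance_cutoff, rng_seed=seed
        )
        keep = np.asarray(keep)
        # the retained set is small; dense fits are much faster than csr
        Xp = _densify(_column_subset(Xm, keep))

        splits = list(self._splitter(seed, groups).split(Xp, y, groups))
        t0 = time.monotonic()
        best = None
        for it in range(self.search_iters):
            family = str(rng.choice(list(self.families)))
            params = _sample_params(family, rng)
            fold_rows = []
            for fold_no, (tr, te) in enumerate(splits):
                est = _make_estimator(family, params, self.class_weight, seed)
                est.fit(Xp[tr], y[tr])
                pred = est.predict(Xp[te])
                fold_rows.append(
                    {
                        "fold": fold_no,
                        "f1": f1_score(y[te], pred, zero_division=0),
                        "precision": precision_score(y[te], pred, zero_division=0),
                        "recall": recall_score(y[te], pred, zero_division=0),
                    }
                )
            mean_f1 = float(np.mean([r["f1"] for r in fold_rows]))
            cand = (mean_f1, -it, family, params, fold_rows)
            if best is None or cand[:2] > best[:2]:
                best = cand
            if (
                self.time_budget is not None
                and time.monotonic() - t0 > self.time_budget
            ):
                break

        mean_f1, _, family, params, fold_rows = best
        # final CV pass over the winning configuration to collect the
        # probability-based metrics alongside F1/precision/recall
        for row, (tr, te) in zip(fold_rows, splits):
            est = _make_estimator(family, params, self.class_weight, seed)
            est.fit(Xp[tr], y[tr])
            row["auc_pr"] = average_precision_score(
                y[te], est.predict_proba(Xp[te])[:, 1]
            )
        final = _make_estimator(family, params, self.class_weight, seed)
        final.fit(Xp, y)

        self.classes_ = classes
        self.n_features_in_ = Xm.shape[1]
        self.feature_names_in_ = np.asarray(names) if names is not None else None
        self.retained_ = keep
        self.importances_ = importances
        self.best_family_ = family
        self.best_params_ = params
        self.best_score_ = mean_f1
        self.best_estimator_ = final
        self.cv_report_ = pd.DataFrame(fold_rows)
        return self

    def _prepare(self, X):
        check_is_fitted(self, "best_estimator_")
        Xm, names = _as_matrix(X)
        if Xm.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {Xm.shape[1]} features, expected {self.n_features_in_}"
            )
        return _densify(_column_subset(Xm, self.retained_))

    def predict(self, X):
        return self.best_estimator_.predict(self._prepare(X))

    def predict_proba(self, X):
        return self.best_estimator_.predict_proba(self._prepare(X))


# ---------------------------------------------------------------------------
# trained-model bundle


@dataclass
class TrainedModel:
    """Fitted classifier plus the metadata needed for safe evaluation."""

    classifier: RRISiteClassifier
    feature_names: list
    config_fingerprint: str
    hash_bits: int | None
    cv_report: pd.DataFrame
    training_set_id: str = ""
    pruning_record: dict = field(default_factory=dict)

    def save(self, path) -> None:
        """Persist as a single joblib archive (classifier + JSON-able
        metadata)."""
        meta = {
            "feature_names": list(self.feature_names),
            "config_fingerprint": self.config_fingerprint,
            "hash_bits": self.hash_bits,
            "cv_report": self.cv_report.to_dict(orient="list"),
            "training_set_id": self.training_set_id,
            "pruning_record": self.pruning_record,
        }
        joblib.dump({"classifier": self.classifier, "meta": json.dumps(meta)}, path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        blob = joblib.load(path)
        meta = json.loads(blob["meta"])
        return cls(
            classifier=blob["classifier"],
            feature_names=meta["feature_names"],
            config_fingerprint=meta["config_fingerprint"],
            hash_bits=meta["hash_bits"],
            cv_report=pd.DataFrame(meta["cv_report"]),
            training_set_id=meta["training_set_id"],
            pruning_record=meta["pruning_record"],
        )


def train_model(
    features: FeatureTable, config: Config | None = None, training_set_id: str = ""
) -> TrainedModel:
    """Fit an :class:`RRISiteClassifier` on a labelled feature table."""
    config = config or Config()
    table = features.labelled_subset()
    clf = RRISiteClassifier(
        search_iters=config.search_iters,
        cv_folds=config.cv_folds,
        importance_cutoff=config.importance_cutoff,
        random_state=config.rng_seed,
    )
    clf.fit(
        table.matrix(), table.labels.astype(int), groups=table.site_groups()
    )
    return TrainedModel(
        classifier=clf,
        feature_names=table.feature_names,
        config_fingerprint=table.fingerprint,
        hash_bits=table.hash_bits,
        cv_report=clf.cv_report_,
        training_set_id=training_set_id,
        pruning_record={
            "importance_cutoff": config.importance_cutoff,
            "n_features_in": int(clf.n_features_in_),
            "n_retained": int(len(clf.retained_)),
        },
    )


def merge_feature_tables(tables: list) -> FeatureTable:
    """Row-concatenate feature tables from different sources.

    Dense columns are intersected (canonical sorted order); sparse graph
    blocks must agree in hash width (all present or all absent); a
    provenance column records the source of each row.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables to merge")
    common = set(tables[0].feature_names)
    for t in tables[1:]:
        common &= set(t.feature_names)
    if not common:
        raise ValueError("merged tables share no dense feature columns")
    columns = sorted(common)
    bits = {t.hash_bits for t in tables}
    if len(bits) > 1:
        raise ValueError(f"incompatible graph blocks: hash_bits {sorted(map(str, bits))}")
    hash_bits = bits.pop()
    sparse = (
        sp.vstack([t.sparse for t in tables], format="csr")
        if hash_bits is not None
        else None
    )
    provenance = []
    for k, t in enumerate(tables):
        provenance.extend([f"source{k}"] * len(t.ids))
    return FeatureTable(
        ids=[i for t in tables for i in t.ids],
        dense=pd.concat(
            [t.dense[columns] for t in tables], ignore_index=True
        ),
        labels=np.concatenate([t.labels for t in tables]),
        sparse=sparse,
        na_ids=[i for t in tables for i in t.na_ids],
        fingerprint="+".join(dict.fromkeys(t.fingerprint for t in tables)),
        hash_bits=hash_bits,
        provenance=provenance,
    )


def evaluate_sites(
    model: TrainedModel, eval_table: FeatureTable, force: bool = False
) -> pd.DataFrame:
    """Label putative sites with a trained model.

    One row per input site: positions-based identifier, predicted label
    (0/1, or 'NA' for sites without any valid duplex) and class-1
    probability.
    """
    if not force:
        missing = [
            n for n in model.feature_names if n not in eval_table.feature_names
        ]
        extra = [
            n for n in eval_table.feature_names if n not in model.feature_names
        ]
        if missing or extra:
            raise ValueError(
                "feature mismatch between model and eval table "
                f"(missing: {missing}; extra: {extra}); pass force=True to override"
            )
        if (
            model.config_fingerprint != eval_table.fingerprint
            or model.hash_bits != eval_table.hash_bits
        ):
            raise ValueError(
                "config fingerprint mismatch between model and eval table; "
                "pass force=True to override"
            )
    rows = []
    if len(eval_table.ids) > 0:
        X = eval_table.matrix()
        labels = model.classifier.predict(X)
        proba = model.classifier.predict_proba(X)[:, 1]
        for iid, lab, p in zip(eval_table.ids, labels, proba):
            rows.append(
                {
                    "site_id": iid.rsplit("::", 1)[0],
                    "predicted_label": int(lab),
                    "probability": float(p),
                }
            )
    for iid in eval_table.na_ids:
        rows.append(
            {
                "site_id": iid.rsplit("::", 1)[0],
                "predicted_label": "NA",
                "probability": np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["site_id", "predicted_label", "probability"])
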