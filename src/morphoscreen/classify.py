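"""Drug-effect-category prediction from morphological profiles.

Per category, bootstrap training datasets are drawn from that category's
single-cell pool (50 datasets of 1000 cells by default), each reduced to a
12-feature profile.  A seeded random forest discriminates the categories;
performance is estimated by grouped cross-validation that holds out whole
bootstrap-source groups together, preventing leakage between folds.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import Field, model_validator
from sklearn.ensemble import RandomForestClassifier

from ._model import StrictModel, config_hash, derive_seed, rng_from
from .morphometry import CellTable
from .profiling import FEATURE_NAMES, PopulationProfile, ProfileMatrix, summarize_population

logger = logging.getLogger(__name__)

#: Default six drug-effect categories (cell line × drug × dose).
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "AR-24Q+DHT",
    "AR-97Q+DHT",
    "AR-97Q+DHT+PG-0.01uM",
    "AR-97Q+DHT+PG-0.1uM",
    "AR-97Q+DHT+NRT-1uM",
    "AR-97Q+DHT+NRT-10uM",
)


class ClassifierConfig(StrictModel):
    """Training-set construction and forest hyperparameters."""

    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    n_train_bootstrap: int = Field(default=50, ge=2)
    train_sample_size: int = Field(default=1000, ge=2)
    n_trees: int = Field(default=500, ge=1)
    max_depth: int | None = None
    n_cv_groups: int = Field(default=5, ge=2)
    cv_grouping: str = Field(
        default="category_replicate",
        pattern="^(category_replicate|well|experiment)$",
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ClassifierConfig":
        if len(self.categories) < 2:
            raise ValueError("need at least 2 categories")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("category labels must be unique")
        return self


def build_training_sets(
    pools: Mapping[str, CellTable], cfg: ClassifierConfig | None = None
) -> ProfileMatrix:
    """Bootstrap profile rows for every category.

    For each category, ``n_train_bootstrap`` samples of
    ``train_sample_size`` cells are drawn with replacement from that
    category's pool (seeded per category) and summarized into 12-feature
    profiles.  Rows are tagged with the category and a bootstrap-replicate
    group id ``0..n_cv_groups-1`` shared across categories, so grouped CV
    folds contain every class.
    """
    cfg = cfg or ClassifierConfig()
    profiles: list[PopulationProfile] = []
    for cat in cfg.categories:
        if cat not in pools:
            raise ValueError(f"no cell pool provided for category {cat!r}")
        pool = pools[cat]
        if len(pool) == 0:
            raise ValueError(f"empty cell pool for category {cat!r}")
        if len(pool) < cfg.train_sample_size // 2:
            logger.warning(
                "category %s pool has only %d cells (< %d); bootstrap "
                "samples will be highly correlated",
                cat,
                len(pool),
                cfg.train_sample_size // 2,
            )
        rng = rng_from(derive_seed(cfg.seed, f"train:{cat}"))
        for b in range(cfg.n_train_bootstrap):
            idx = rng.integers(0, len(pool), size=cfg.train_sample_size)
            group = b * cfg.n_cv_groups // cfg.n_train_bootstrap
            profiles.append(
                summarize_population(
                    pool.df.iloc[idx],
                    condition=cat,
                    sample_index=b,
                    seed=cfg.seed,
                    group=str(group),
                )
            )
    return ProfileMatrix.from_profiles(profiles)


@dataclass
class CategoryModel:
    """A trained drug-effect-category forest plus its provenance."""

    forest: RandomForestClassifier
    categories: tuple[str, ...]
    feature_names: tuple[str, ...]
    config_hash: str
    importances: np.ndarray

    def save(self, path: str | Path) -> None:
        """Persist as a pickle with a JSON sidecar describing it."""
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        sidecar = {
            "categories": list(self.categories),
            "feature_names": list(self.feature_names),
            "config_hash": self.config_hash,
            "importances": self.importances.tolist(),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @staticmethod
    def load(path: str | Path) -> "CategoryModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, CategoryModel):
            raise TypeError(f"{path} does not contain a CategoryModel")
        return model


def _new_forest(cfg: ClassifierConfig, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features="sqrt",
        max_depth=cfg.max_depth,
        oob_score=True,
        random_state=seed & 0x7FFFFFFF,
        n_jobs=1,
    )


def train_category_model(
    matrix: ProfileMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
    cfg: ClassifierConfig | None = None,
) -> CategoryModel:
    """Fit the seeded random forest on profile rows.

    Importances are impurity-based, renormalized to sum to exactly 1.
    Raises if only one class is present.
    """
    cfg = cfg or ClassifierConfig()
    X, y = _as_xy(matrix, labels)
    if len(set(y)) < 2:
        raise ValueError("training requires at least 2 classes")
    forest = _new_forest(cfg, derive_seed(cfg.seed, "forest"))
    forest.fit(X, y)
    imp = np.asarray(forest.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return CategoryModel(
        forest=forest,
        categories=tuple(forest.classes_),
        feature_names=FEATURE_NAMES,
        config_hash=config_hash(cfg),
        importances=imp,
    )


def _as_xy(
    matrix: ProfileMatrix | np.ndarray, labels: Sequence[str] | None
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(matrix, ProfileMatrix):
        X = matrix.values
        y = matrix.conditions if labels is None else np.asarray(labels)
    else:
        if labels is None:
            raise ValueError("labels are required with a bare feature array")
        X, y = np.asarray(matrix, dtype=float), np.asarray(labels)
    if X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected {len(FEATURE_NAMES)} features, got {X.shape[1]}")
    if len(X) != len(y):
        raise ValueError("feature/label length mismatch")
    return X, np.asarray([str(v) for v in y])


@dataclass
class CVResult:
    """Grouped cross-validation outcome."""

    confusion: pd.DataFrame       # rows = true class, normalized to sum 1
    accuracy: float
    fold_accuracies: list[float]
    categories: tuple[str, ...]


def cross_validate(
    matrix: ProfileMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
    cfg: ClassifierConfig | None = None,
) -> CVResult:
    """Leave-one-group-out CV over bootstrap-source groups.

    All rows sharing a group id are held out together.  Every class must
    appear in at least two groups; otherwise some fold would have to test a
    class its training data never saw (and the group structure could not
    prevent leakage anyway), so this raises.
    """
    cfg = cfg or ClassifierConfig()
    X, y = _as_xy(matrix, labels)
    if groups is None:
        if not isinstance(matrix, ProfileMatrix):
            raise ValueError("groups are required with a bare feature array")
        groups = matrix.groups
    g = np.asarray([str(v) for v in groups])
    classes = sorted(set(y))
    for c in classes:
        if len(set(g[y == c])) < 2:
            raise ValueError(
                f"class {c!r} appears in a single group; grouped CV would "
                "either leak it or never test it"
            )
    uniq_groups = sorted(set(g))
    cats = tuple(classes)
    counts = pd.DataFrame(0.0, index=list(cats), columns=list(cats))
    fold_acc: list[float] = []
    n_correct = 0
    for i, hold in enumerate(uniq_groups):
        test = g == hold
        forest = _new_forest(cfg, derive_seed(cfg.seed, f"cv:{i}"))
        forest.fit(X[~test], y[~test])
        pred = forest.predict(X[test])
        truth = y[test]
        for t, p in zip(truth, pred):
            counts.loc[t, p] += 1
        correct = int((pred == truth).sum())
        n_correct += correct
        fold_acc.append(correct / int(test.sum()))
    row_sums = counts.sum(axis=1).replace(0, 1.0)
    confusion = counts.div(row_sums, axis=0)
    return CVResult(
        confusion=confusion,
        accuracy=n_correct / len(y),
        fold_accuracies=fold_acc,
        categories=cats,
    )


def predict_category(
    model: CategoryModel,
    profiles: ProfileMatrix | pd.DataFrame,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Predict category labels and class probabilities for profile rows.

    The input's feature columns must match the model's feature names
    exactly (order included); mismatches raise with the differences listed.
    """
    if isinstance(profiles, ProfileMatrix):
        names = tuple(profiles.features.columns)
        X = profiles.values
    else:
        names = tuple(profiles.columns)
        X = profiles.to_numpy(dtype=float)
    if names != model.feature_names:
        missing = [n for n in model.feature_names if n not in names]
        extra = [n for n in names if n not in model.feature_names]
        raise ValueError(
            "feature mismatch with model: "
            f"missing={missing}, unexpected={extra}, "
            f"order_ok={sorted(names) == sorted(model.feature_names)}"
        )
    proba = model.forest.predict_proba(X)
    labels = model.forest.classes_[np.argmax(proba, axis=1)]
    proba_df = pd.DataFrame(proba, columns=list(model.forest.classes_))
    return np.asarray(labels), proba_df


def shuffle_labels_within_groups(
    labels: Sequence[str], groups: Sequence[str], seed: int = 0
) -> np.ndarray:
    """Permutation-null helper: shuffle labels independently inside each
    group, preserving the group structure used by the CV splitter."""
    y = np.asarray([str(v) for v in labels])
    g = np.asarray([str(v) for v in groups])
    rng = rng_from(seed)
    out = y.copy()
    for grp in sorted(set(g)):
        idx = np.flatnonzero(g == grp)
        out[idx] = y[idx][rng.permutation(len(idx))]
    return out
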