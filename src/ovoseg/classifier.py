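"""RBF-SVM long-bone classification with anatomical constraints.

Workflow: standardize the 23 features plus the day of incubation, fit a
one-vs-one soft-margin SVM with an RBF kernel (SMO-lineage solver) whose
pairwise outputs are calibrated to probabilities by logistic fits, and
classify unknown specimens under the constraint that an embryo carries
at most two long bones of each class — surplus assignments keep the two
highest-probability objects and the rest fall back to "not of interest".

The shipped defaults C = 1.25 and gamma = 0.1125 are the grid-search
optimum reported for the original annotated training corpus; they remain
configurable, and ``grid_search`` re-derives an optimum for any dataset.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .model import ANNOTATION_CLASSES, ANNOTATION_COLUMN, FEATURE_COLUMNS, NOI

__all__ = [
    "DEFAULT_C", "DEFAULT_GAMMA", "TrainingConfig", "ClassifierModel",
    "standardize", "grid_search", "train", "classify_specimen",
]

#: Published grid-search optimum for the reference training data.
DEFAULT_C = 1.25
DEFAULT_GAMMA = 0.1125


@dataclass
class TrainingConfig:
    """Grid-search and cross-validation settings."""

    C: float = DEFAULT_C
    gamma: float = DEFAULT_GAMMA
    c_grid: tuple[float, ...] = tuple(2.0 ** k for k in range(-5, 6))
    gamma_grid: tuple[float, ...] = tuple(2.0 ** k for k in range(-7, 4))
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be > 0")
        if self.cv_folds < 2:
            raise ValueError("cross-validation needs at least 2 folds")


def _numeric_matrix(table: pd.DataFrame) -> np.ndarray:
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    return table[list(FEATURE_COLUMNS)].to_numpy(dtype=np.float64)


def standardize(
    table: pd.DataFrame,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, tuple[np.ndarray, np.ndarray]]:
    """Transform every numeric feature to zero mean and unit SD.

    In train mode (``stats=None``) the statistics are computed from the
    table; in test mode the provided ``(mean, sd)`` are applied.  The day
    of incubation is standardized like any other numeric feature; the
    annotation column is untouched.  Zero-variance features standardize
    with SD 1 (and a warning) so they map to zeros rather than NaN.
    """
    x = _numeric_matrix(table)
    if stats is None:
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        zero = sd == 0
        if zero.any():
            names = [FEATURE_COLUMNS[i] for i in np.flatnonzero(zero)]
            warnings.warn(f"zero-variance features standardized with SD 1: {names}")
            sd = np.where(zero, 1.0, sd)
        stats = (mean, sd)
    mean, sd = stats
    out = table.copy()
    out[list(FEATURE_COLUMNS)] = (x - mean) / sd
    return out, stats


@dataclass
class ClassifierModel:
    """Standardization stats plus the fitted, calibrated SVM.

    ``svm`` is the raw one-vs-one RBF SVM (fast label prediction);
    ``calibrated`` carries the same SVM with pairwise logistic
    calibration fitted to its outputs, and is present unless the model
    was trained with ``calibrate=False``.
    """

    mean: np.ndarray
    sd: np.ndarray
    svm: SVC
    calibrated: SVC | None
    classes: tuple[str, ...]
    C: float
    gamma: float

    def predict(self, table: pd.DataFrame) -> pd.Series:
        x = (_numeric_matrix(table) - self.mean) / self.sd
        return pd.Series(self.svm.predict(x), index=table.index)

    def predict_proba(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.calibrated is None:
            raise ValueError("model was trained without probability calibration")
        x = (_numeric_matrix(table) - self.mean) / self.sd
        proba = self.calibrated.predict_proba(x)
        return pd.DataFrame(proba, columns=self.calibrated.classes_,
                            index=table.index)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        return path

    @staticmethod
    def load(path: str | Path) -> "ClassifierModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, ClassifierModel):
            raise ValueError(f"{path} does not contain a classifier model")
        return model


def _labels(table: pd.DataFrame) -> np.ndarray:
    if ANNOTATION_COLUMN not in table.columns:
        raise ValueError("training requires an annotation column")
    return table[ANNOTATION_COLUMN].to_numpy()


def grid_search(table: pd.DataFrame,
                config: TrainingConfig | None = None) -> tuple[float, float]:
    """Exhaustive (C, gamma) search by stratified k-fold CV accuracy.

    Ties break toward smaller C, then smaller gamma.
    """
    config = config or TrainingConfig()
    if not config.c_grid or not config.gamma_grid:
        raise ValueError("empty parameter grid")
    y = _labels(table)
    if len(np.unique(y)) < 2:
        raise ValueError("grid search needs at least two classes")
    if len(table) < config.cv_folds:
        raise ValueError("fewer rows than cross-validation folds")
    std, _ = standardize(table)
    x = _numeric_matrix(std)
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                         random_state=config.seed)
    best = None
    for c in sorted(config.c_grid):
        for g in sorted(config.gamma_grid):
            svm = SVC(kernel="rbf", C=c, gamma=g, random_state=config.seed)
            acc = cross_val_score(svm, x, y, cv=cv, scoring="accuracy").mean()
            if best is None or acc > best[0] + 1e-12:
                best = (acc, c, g)
    return best[1], best[2]


def train(table: pd.DataFrame, C: float = DEFAULT_C, gamma: float = DEFAULT_GAMMA,
          seed: int = 0, calibrate: bool = True,
          require_all_classes: bool = True) -> ClassifierModel:
    """Fit the one-vs-one RBF SVM, with logistic probability calibration.

    All eight classes (seven bones plus NOI) must be present unless
    ``require_all_classes`` is off.  Calibration fits logistic models to
    the SVM outputs via internal cross-validation; everything is seeded,
    so training twice with the same seed reproduces identical
    predictions.  ``calibrate=False`` skips the calibration (labels
    only — several times faster, used inside cross-validation).
    """
    y = _labels(table)
    present = set(np.unique(y))
    if require_all_classes:
        missing = [c for c in ANNOTATION_CLASSES if c not in present]
        if missing:
            raise ValueError(f"training data is missing classes: {missing}")
    elif len(present) < 2:
        raise ValueError("training needs at least two classes")
    std, (mean, sd) = standardize(table)
    x = _numeric_matrix(std)
    svm = SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed,
              decision_function_shape="ovo")
    svm.fit(x, y)
    calibrated = None
    if calibrate:
        # pairwise (one-vs-one) logistic calibration of the SVM outputs;
        # robust for the rare bone classes where a one-vs-rest logistic
        # fit would see only a handful of positives per internal fold
        calibrated = SVC(kernel="rbf", C=C, gamma=gamma, probability=True,
                         random_state=seed, decision_function_shape="ovo")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            calibrated.fit(x, y)
    return ClassifierModel(mean=mean, sd=sd, svm=svm, calibrated=calibrated,
                           classes=tuple(svm.classes_), C=C, gamma=gamma)


def classify_specimen(
    model: ClassifierModel,
    table: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame]:
    """Classify one specimen's objects under the two-per-class constraint.

    Returns ``(labels, probabilities)`` aligned to the table's index.
    For every bone class assigned to more than two objects, only the two
    with the highest probability of that class keep the label; the rest
    become NOI.  Probability ties break toward the lower object id (or
    row position when no ``object_id`` column exists).
    """
    proba = model.predict_proba(table)
    labels = proba.idxmax(axis=1)
    order_key = (table["object_id"] if "object_id" in table.columns
                 else pd.Series(range(len(table)), index=table.index))
    for cls in model.classes:
        if cls == NOI:
            continue
        idx = labels.index[labels == cls]
        if len(idx) <= 2:
            continue
        ranked = sorted(idx, key=lambda i: (-proba.loc[i, cls], order_key.loc[i]))
        for i in ranked[2:]:
            labels.loc[i] = NOI
    return labels, proba


def classify_table(model: ClassifierModel,
                   table: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Classify a multi-specimen table, constraining each specimen separately."""
    if "specimen_id" not in table.columns:
        return classify_specimen(model, table)
    labels_parts, proba_parts = [], []
    for _, sub in table.groupby("specimen_id", sort=False):
        lab, pr = classify_specimen(model, sub)
        labels_parts.append(lab)
        proba_parts.append(pr)
    labels = pd.concat(labels_parts).reindex(table.index)
    proba = pd.concat(proba_parts).reindex(table.index)
    return labels, proba
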