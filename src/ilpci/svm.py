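"""SVM staging of tumor ROIs from low-frequency wavelet texture.

Tumor-ROI texture features of the level-1 lowpass subband (LF1) are pooled
across stages, standardized and reduced by correlation-matrix PCA with the
80% contribution-rate rule; the retained component scores feed an RBF SVM
evaluated by stratified k-fold cross-validation over a small parameter
grid.  The report carries the maximum mean CV accuracy over the grid, the
pooled confusion matrix at the best grid point, and a label-permutation
chance baseline on the same folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .pca import FeatureMatrix, orient_by_loading, pca_fit, scores, select_components, standardize


@dataclass
class StageDataset:
    """Retained PC scores of tumor-ROI LF1 texture, one row per ROI."""

    features: np.ndarray
    stages: np.ndarray
    cr_retained: np.ndarray  # contribution rates of the retained components
    cr1: float

    def __post_init__(self) -> None:
        if len(np.unique(self.stages)) < 2:
            raise ValueError("stage dataset needs at least 2 distinct stages")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite feature values")


@dataclass
class ClassifierConfig:
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (0.01, 0.1, 1.0)
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need >= 2 folds")
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("parameter grids must be nonempty")


@dataclass
class ClassificationReport:
    accuracy: float                      # max mean CV accuracy over the grid
    fold_accuracies: np.ndarray          # per-fold accuracies at the best point
    best_params: dict
    confusion: np.ndarray                # pooled over folds at the best point
    class_order: np.ndarray
    permutation_accuracy: float          # same folds, shuffled labels
    grid_accuracies: dict = field(default_factory=dict)


def build_stage_features(
    roi_features: FeatureMatrix,
    cr_threshold: float = 0.80,
    orient_feature: str | None = "idm",
) -> StageDataset:
    """Pooled standardization + PCA over all tumor ROIs; keep components by
    the cumulative-CR rule; rows keep their stage labels.

    Components are sign-oriented on the ``orient_feature`` loading
    (homogeneity-positive by default, so the first score grows as tumor
    texture coarsens); pass ``None`` for the plain max-loading convention.
    """
    if roi_features.stages is None:
        raise ValueError("feature matrix carries no stage labels")
    stages, counts = np.unique(roi_features.stages, return_counts=True)
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    if counts.min() < 5:
        raise ValueError("need at least 5 ROIs per stage")
    X, params = standardize(roi_features)
    model = pca_fit(X, params, roi_features.feature_names)
    table = scores(model, X, stages=roi_features.stages)
    model, table = orient_by_loading(model, table, feature=orient_feature)
    selected = select_components(model, cr_threshold)
    return StageDataset(
        features=table.scores[:, selected],
        stages=np.asarray(roi_features.stages),
        cr_retained=model.contribution_rates[selected],
        cr1=float(model.contribution_rates[0]),
    )


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, folds, C: float, gamma: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-fold accuracy plus pooled (true, predicted) labels."""
    accs, y_true, y_pred = [], [], []
    for train, test in folds:
        clf = SVC(C=C, gamma=gamma, kernel="rbf", decision_function_shape="ovo")
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        accs.append(float(np.mean(pred == y[test])))
        y_true.extend(y[test])
        y_pred.extend(pred)
    return np.array(accs), np.array(y_true), np.array(y_pred)


def crossval_svm(dataset: StageDataset, config: ClassifierConfig | None = None) -> ClassificationReport:
    """Stratified k-fold CV over the (C, gamma) grid; the reported accuracy
    is the maximum mean CV accuracy (a parameter search is implied whenever
    a 'maximum classification accuracy' is quoted)."""
    config = config or ClassifierConfig()
    X = np.asarray(dataset.features, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    # PC scores have variance lambda_i; the kernel-width grid assumes
    # standardized inputs, so rescale columns to unit sd
    sd = X.std(axis=0, ddof=1)
    X = X / np.where(sd > 0, sd, 1.0)
    y = np.asarray(dataset.stages)
    _, class_counts = np.unique(y, return_counts=True)
    if class_counts.min() < config.n_folds:
        raise ValueError(
            f"a class has only {class_counts.min()} rows, fewer than "
            f"{config.n_folds} folds; use fewer folds"
        )
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X, y))

    grid_acc: dict[tuple[float, float], float] = {}
    best = None
    for C in config.c_grid:
        for gamma in config.gamma_grid:
            accs, yt, yp = _cv_accuracy(X, y, folds, C, gamma)
            grid_acc[(C, gamma)] = float(accs.mean())
            if best is None or accs.mean() > best[0]:
                best = (float(accs.mean()), accs, yt, yp, {"C": C, "gamma": gamma})

    acc, fold_accs, y_true, y_pred, best_params = best
    classes = np.unique(y)
    conf = confusion_matrix(y_true, y_pred, labels=classes)

    # chance baseline: same folds, labels permuted with the run seed
    rng = np.random.default_rng(config.seed)
    y_perm = rng.permutation(y)
    perm_folds = list(
        StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed
        ).split(X, y_perm)
    )
    perm_accs, _, _ = _cv_accuracy(
        X, y_perm, perm_folds, best_params["C"], best_params["gamma"]
    )

    return ClassificationReport(
        accuracy=acc,
        fold_accuracies=fold_accs,
        best_params=best_params,
        confusion=conf,
        class_order=classes,
        permutation_accuracy=float(perm_accs.mean()),
        grid_accuracies={f"C={c},gamma={g}": a for (c, g), a in grid_acc.items()},
    )
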