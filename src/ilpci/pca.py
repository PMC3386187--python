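"""Correlation-matrix PCA of ROI texture features and the F1-sign discriminant.

The feature matrix (one row per ROI, nine texture features) is standardized
column-wise; the eigendecomposition of its correlation matrix yields
eigenvalues lambda_i (descending) with contribution rates
CR_i = lambda_i / sum(lambda).  Per-ROI scores are F_i = x_std . e_i.
Because eigenvector signs are mathematically arbitrary, components are
oriented so the mean score of a reference group (normal parenchyma) is
non-negative; the discriminant then reads: F1 > 0 -> normal region,
F1 < 0 -> tumor region (F1 = 0 ties resolve to normal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .glcm import TEXTURE_FEATURE_NAMES

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """ROI-by-feature matrix with region/stage labels carried along."""

    values: np.ndarray
    feature_names: tuple[str, ...] = TEXTURE_FEATURE_NAMES
    region_labels: np.ndarray | None = None  # "normal"/"tumor" per row
    stages: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError("feature matrix needs >= 2 rows")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("column count does not match feature names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")


@dataclass
class Standardization:
    means: np.ndarray
    sds: np.ndarray
    kept: np.ndarray  # indices of non-constant columns
    dropped_names: tuple[str, ...]

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (values[:, self.kept] - self.means) / self.sds


@dataclass
class PCAModel:
    eigenvalues: np.ndarray            # descending, clipped at 0
    eigenvectors: np.ndarray           # columns e_i, unit length
    contribution_rates: np.ndarray     # lambda_i / sum lambda
    standardization: Standardization
    feature_names: tuple[str, ...]
    sign_flips: np.ndarray | None = None  # +-1 per component after orientation

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class ScoreTable:
    scores: np.ndarray  # rows align with the feature matrix
    region_labels: np.ndarray | None = None
    stages: np.ndarray | None = None


@dataclass
class DiscriminantReport:
    group_mean_sd: dict[str, tuple[float, float]]
    cr1: float
    predicted: np.ndarray
    agreement: float | None
    n_ties: int = 0


def standardize(features: FeatureMatrix) -> tuple[np.ndarray, Standardization]:
    """Column-wise zero-mean, unit-sd scaling (sample sd, n-1).

    Constant columns carry no correlation information and would divide by
    zero; they are dropped with a warning naming the feature.
    """
    X = features.values
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    kept = np.nonzero(sds > 0)[0]
    dropped = tuple(features.feature_names[i] for i in np.nonzero(sds == 0)[0])
    if dropped:
        logger.warning("dropping constant feature columns: %s", ", ".join(dropped))
    if len(kept) == 0:
        raise ValueError("all feature columns are constant; nothing to analyze")
    params = Standardization(means[kept], sds[kept], kept, dropped)
    return params.apply(X), params


def pca_fit(
    standardized: np.ndarray,
    params: Standardization,
    feature_names: tuple[str, ...] = TEXTURE_FEATURE_NAMES,
) -> PCAModel:
    """Eigendecomposition of the sample correlation matrix of the
    standardized features; eigenvalues sorted descending."""
    if not np.all(np.isfinite(standardized)):
        raise ValueError("standardized matrix contains non-finite values")
    n, p = standardized.shape
    if n < 2 or p < 1:
        raise ValueError("need >= 2 rows and >= 1 column")
    corr = standardized.T @ standardized / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    cr = eigvals / total if total > 0 else np.full_like(eigvals, np.nan)
    kept_names = tuple(feature_names[i] for i in params.kept)
    return PCAModel(
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        contribution_rates=cr,
        standardization=params,
        feature_names=kept_names,
    )


def scores(
    model: PCAModel,
    standardized: np.ndarray,
    region_labels: np.ndarray | None = None,
    stages: np.ndarray | None = None,
) -> ScoreTable:
    """Per-ROI principal-component scores F_i = x_std . e_i."""
    if standardized.shape[1] != model.eigenvectors.shape[0]:
        raise ValueError("column count does not match the fitted model")
    F = standardized @ model.eigenvectors
    if model.sign_flips is not None:
        F = F * model.sign_flips
    return ScoreTable(scores=F, region_labels=region_labels, stages=stages)


def orient_signs(
    model: PCAModel,
    table: ScoreTable,
    reference_label: str = "normal",
) -> tuple[PCAModel, ScoreTable]:
    """Flip components so the reference group's mean score is >= 0.

    Eigenvector signs are arbitrary; anchoring the normal group at
    non-negative mean makes the F1 > 0 <-> normal rule well-defined.
    Returns a new model (flips recorded) and re-signed scores; magnitudes
    and eigenvalues are unchanged.
    """
    if table.region_labels is None:
        raise ValueError("score table carries no region labels")
    ref = np.asarray(table.region_labels) == reference_label
    if not ref.any():
        raise ValueError(f"reference group {reference_label!r} absent from labels")
    means = table.scores[ref].mean(axis=0)
    flips = np.where(means < 0, -1.0, 1.0)
    prior = model.sign_flips if model.sign_flips is not None else 1.0
    oriented = PCAModel(
        eigenvalues=model.eigenvalues,
        eigenvectors=model.eigenvectors,
        contribution_rates=model.contribution_rates,
        standardization=model.standardization,
        feature_names=model.feature_names,
        sign_flips=prior * flips,
    )
    return oriented, ScoreTable(
        scores=table.scores * flips,
        region_labels=table.region_labels,
        stages=table.stages,
    )


def orient_by_loading(
    model: PCAModel, table: ScoreTable, feature: str | None = None
) -> tuple[PCAModel, ScoreTable]:
    """Label-free orientation of component signs.

    With ``feature=None``, flip each component so its largest-magnitude
    loading is positive (the usual deterministic SVD sign convention).
    With a feature name, flip so that feature's loading is non-negative —
    e.g. anchoring on the inverse difference moment makes the component a
    signed homogeneity axis, which is the direction along which tumor
    texture coarsens as necrotic lumps grow.
    """
    V = model.eigenvectors
    if feature is not None and feature in model.feature_names:
        lead = V[model.feature_names.index(feature), :]
    else:
        lead = V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])]
    flips = np.where(lead < 0, -1.0, 1.0)
    prior = model.sign_flips if model.sign_flips is not None else 1.0
    oriented = PCAModel(
        eigenvalues=model.eigenvalues,
        eigenvectors=model.eigenvectors * flips,
        contribution_rates=model.contribution_rates,
        standardization=model.standardization,
        feature_names=model.feature_names,
        sign_flips=prior * flips,
    )
    return oriented, ScoreTable(table.scores * flips, table.region_labels, table.stages)


def select_components(model: PCAModel, threshold: float = 0.80) -> list[int]:
    """Smallest leading component set whose cumulative contribution rate
    reaches the threshold (the 80% CR rule)."""
    cum = np.cumsum(model.contribution_rates)
    k = int(np.searchsorted(cum, threshold - 1e-15) + 1)
    return list(range(min(k, model.n_components)))


def sign_discriminate(table: ScoreTable, cr1: float | None = None) -> DiscriminantReport:
    """Classify each ROI by the sign of its oriented F1 score.

    F1 > 0 -> normal, F1 < 0 -> tumor; the measure-zero tie F1 = 0 resolves
    to normal (documented convention).  When true labels are present the
    report carries group mean +- sd and the agreement fraction.
    """
    f1 = table.scores[:, 0]
    predicted = np.where(f1 >= 0, "normal", "tumor")
    n_ties = int(np.count_nonzero(f1 == 0))
    group_stats: dict[str, tuple[float, float]] = {}
    agreement = None
    if table.region_labels is not None:
        labels = np.asarray(table.region_labels)
        for g in np.unique(labels):
            vals = f1[labels == g]
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            group_stats[str(g)] = (float(vals.mean()), sd)
        agreement = float(np.mean(predicted == labels))
    return DiscriminantReport(
        group_mean_sd=group_stats,
        cr1=float(cr1) if cr1 is not None else float("nan"),
        predicted=predicted,
        agreement=agreement,
        n_ties=n_ties,
    )


def fit_discriminant(
    features: FeatureMatrix, threshold: float = 0.80
) -> tuple[PCAModel, ScoreTable, DiscriminantReport, list[int]]:
    """Convenience: standardize, fit, orient on the normal group, select
    components by the CR rule and run the sign discriminant."""
    X, params = standardize(features)
    model = pca_fit(X, params, features.feature_names)
    table = scores(model, X, features.region_labels, features.stages)
    model, table = orient_signs(model, table)
    selected = select_components(model, threshold)
    report = sign_discriminate(table, cr1=model.contribution_rates[0])
    return model, table, report, selected


def stage_monotonicity(stage_means: dict[str, float] | list[float]) -> float:
    """Spearman rank correlation between stage order and per-stage means.

    rho = 1 iff the means are strictly increasing in stage.  Ties among
    means are handled by midranks (scipy convention) and logged.
    """
    if isinstance(stage_means, dict):
        means = [stage_means[k] for k in sorted(stage_means, key=lambda s: float(s.rstrip("d")))]
    else:
        means = list(stage_means)
    if len(means) < 3:
        raise ValueError("need at least 3 stages for a rank trend")
    if len(set(means)) < len(means):
        logger.info("stage_monotonicity: tied stage means, midranks used")
    rho, _ = sps.spearmanr(np.arange(len(means)), means)
    return float(rho)
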