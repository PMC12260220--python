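"""Individual-vs-social condition discrimination with linear classifiers.

Pipeline: standardize features (z-scores), winsorize outliers, prune one
member of every feature pair with |Pearson r| above a threshold, then run
stratified k-fold cross-validation with logistic regression or a linear
support-vector machine and report per-fold accuracies together with
coefficient-based feature importance from a fit on the full table.

The intent is inferential, not predictive: above-chance accuracy shows the
two growing conditions differ on a multivariate basis, and the signed
coefficients say which features carry the difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

logger = logging.getLogger("rootkin")

MODELS = ("logistic_regression", "linear_svm")

#: Class treated as the positive class: positive coefficients push toward
#: the social label.
POSITIVE_CLASS = "social"


@dataclass
class FeatureTable:
    """Numeric per-plant feature matrix plus binary condition labels."""

    features: pd.DataFrame
    labels: pd.Series
    #: Per-feature (mean, sd) captured by :func:`standardize`.
    scale_params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.features.index)
        if self.labels.isna().any():
            raise ValueError("every row needs a condition label")
        counts = self.labels.value_counts()
        if len(counts) != 2:
            raise ValueError("exactly two classes required")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_column: str = "condition",
        feature_names: list[str] | None = None,
    ) -> "FeatureTable":
        """Build from a features-plus-label DataFrame, collapsing any
        ``social_*`` condition values to ``social``."""
        labels = df[label_column].astype(str).str.replace(
            r"^social.*", "social", regex=True
        )
        feats = df.drop(columns=[label_column])
        if feature_names is not None:
            feats = feats[feature_names]
        feats = feats.select_dtypes(include=[np.number])
        return cls(feats, labels)


@dataclass
class ClassificationReport:
    """Cross-validation outcome of one linear model."""

    model: str
    fold_accuracies: np.ndarray
    coefficients: pd.Series
    retained_features: list[str]
    dropped_pairs: list[tuple[str, str, float]]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=0))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "retained_features": self.retained_features,
            "dropped_pairs": [
                {"feature_a": a, "feature_b": b, "r": float(r)}
                for a, b, r in self.dropped_pairs
            ],
        }


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def standardize(table: FeatureTable) -> FeatureTable:
    """Z-score every feature (population sd). Constant features are dropped
    with a warning; the (mean, sd) parameters are stored for reuse."""
    feats = table.features
    if len(feats) < 2:
        raise ValueError("standardization needs at least 2 rows")
    means = feats.mean()
    sds = feats.std(ddof=0)
    constant = sds[sds == 0].index.tolist()
    if constant:
        logger.warning("dropping constant feature(s): %s", constant)
    keep = [c for c in feats.columns if c not in constant]
    if not keep:
        raise ValueError("all features are constant")
    z = (feats[keep] - means[keep]) / sds[keep]
    params = {c: (float(means[c]), float(sds[c])) for c in keep}
    return FeatureTable(z, table.labels, scale_params=params)


def clip_outliers(table: FeatureTable, z_max: float = 3.0) -> FeatureTable:
    """Winsorize standardized values at ±z_max (idempotent); preserves the
    row count rather than deleting extreme plants."""
    clipped = table.features.clip(lower=-z_max, upper=z_max)
    n = int((table.features.abs() > z_max).to_numpy().sum())
    if n:
        logger.info("winsorized %d outlier value(s) at |z| > %g", n, z_max)
    return FeatureTable(clipped, table.labels, scale_params=table.scale_params)


def prune_correlated(
    table: FeatureTable,
    threshold: float = 0.7,
    force_retain: list[str] | None = None,
) -> tuple[FeatureTable, list[tuple[str, str, float]]]:
    """Iteratively drop one member of every feature pair with |r| above
    ``threshold``.

    The member with the larger mean absolute correlation to all remaining
    features is dropped; ties break by fixed column order. Features in
    ``force_retain`` are never dropped (useful to reproduce a published
    retained set). Returns the pruned table and the dropped-pair log.
    """
    feats = table.features.copy()
    if len(feats) < 3:
        raise ValueError("correlation pruning needs at least 3 rows")
    protected = set(force_retain or [])
    dropped: list[tuple[str, str, float]] = []

    while feats.shape[1] > 1:
        corr = feats.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        # Resolvable offending pairs: at least one member unprotected.
        pairs = [
            (x, y) for xi, x in enumerate(corr.columns)
            for y in corr.columns[xi + 1:]
            if corr.loc[x, y] > threshold and not (x in protected and y in protected)
        ]
        both_protected = int(
            (corr.values > threshold).sum() // 2 - len(pairs)
        )
        if not pairs:
            if both_protected:
                logger.warning(
                    "%d correlated pair(s) fully protected; kept", both_protected
                )
            break
        a, b = max(pairs, key=lambda p: corr.loc[p[0], p[1]])
        r = float(table.features[a].corr(table.features[b]))
        mean_r = corr.mean()
        if a in protected:
            victim = b
        elif b in protected:
            victim = a
        else:
            victim = a if (mean_r[a], a) >= (mean_r[b], b) else b
        dropped.append((a, b, r))
        feats = feats.drop(columns=[victim])

    pruned = FeatureTable(feats, table.labels, scale_params=table.scale_params)
    return pruned, dropped


# ---------------------------------------------------------------------------
# Cross-validated classification
# ---------------------------------------------------------------------------

def _make_model(model: str, C: float):
    if model == "logistic_regression":
        return LogisticRegression(C=C, max_iter=5000)
    if model == "linear_svm":
        return LinearSVC(C=C, max_iter=50000)
    raise ValueError(f"model must be one of {MODELS}")


def crossval_classify(
    table: FeatureTable,
    model: str = "logistic_regression",
    k: int = 5,
    seed: int = 0,
    C: float = 1.0,
    prune_threshold: float | None = 0.7,
    force_retain: list[str] | None = None,
) -> ClassificationReport:
    """Stratified k-fold cross-validation of a linear classifier.

    Standardization, winsorizing and correlation pruning are applied once,
    globally, before splitting. Per fold: fit on the training split, score
    accuracy on the test split. Final coefficients come from a fit on the
    full table; a positive coefficient pushes the prediction toward the
    social class.
    """
    prepared = clip_outliers(standardize(table))
    if prune_threshold is not None:
        prepared, dropped = prune_correlated(
            prepared, prune_threshold, force_retain=force_retain
        )
    else:
        dropped = []

    X = prepared.features.to_numpy()
    y = (prepared.labels == POSITIVE_CLASS).to_numpy().astype(int)
    if min(np.bincount(y, minlength=2)) < 1:
        raise ValueError("both classes must be present")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accuracies = []
    try:
        for train, test in skf.split(X, y):
            clf = _make_model(model, C)
            clf.fit(X[train], y[train])
            accuracies.append(float(clf.score(X[test], y[test])))
    except ValueError as exc:
        raise ValueError(
            f"a fold contained a single class; use a smaller k than {k}"
        ) from exc

    final = _make_model(model, C)
    final.fit(X, y)
    coefs = pd.Series(final.coef_.ravel(), index=prepared.features.columns)
    return ClassificationReport(
        model=model,
        fold_accuracies=np.asarray(accuracies),
        coefficients=coefs,
        retained_features=list(prepared.features.columns),
        dropped_pairs=dropped,
    )


def feature_importance(report: ClassificationReport) -> pd.Series:
    """Coefficients ranked by absolute magnitude, signs retained."""
    return report.coefficients.reindex(
        report.coefficients.abs().sort_values(ascending=False).index
    )


def permutation_null_accuracies(
    table: FeatureTable,
    model: str = "logistic_regression",
    n_permutations: int = 100,
    k: int = 5,
    seed: int = 0,
    **kwargs,
) -> np.ndarray:
    """Mean CV accuracy under random label permutation, one value per
    permutation — the chance-level reference distribution."""
    rng = np.random.default_rng(seed)
    # Preprocessing is label-independent, so prepare the table once.
    prepared = clip_outliers(standardize(table))
    prepared, _ = prune_correlated(
        prepared, kwargs.pop("prune_threshold", 0.7) or 1.1,
        force_retain=kwargs.pop("force_retain", None),
    )
    out = []
    for i in range(n_permutations):
        permuted = pd.Series(
            rng.permutation(table.labels.to_numpy()), index=table.labels.index
        )
        shuffled = FeatureTable(prepared.features, permuted)
        rep = crossval_classify(shuffled, model=model, k=k,
                                seed=int(rng.integers(2 ** 31)),
                                prune_threshold=None, **kwargs)
        out.append(rep.mean_accuracy)
    return np.asarray(out)
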