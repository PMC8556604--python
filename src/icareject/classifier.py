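"""Training, application and evaluation of the binary linear component
classifier, plus lossless removal of flagged components.

The decision rule is H = sign(w . z(x) + b) with z the training-set
standardisation; artifact = +1, neural = -1, and an exact zero maps to
neural — when in doubt, the component is retained. Training is regularised
linear discriminant analysis: shared within-class covariance shrunk toward a
scaled identity ("auto" = Ledoit-Wolf analytic shrinkage), with the bias
placing the boundary at equal Mahalanobis distance from the two class means.

Agreement between two labelings is reported as MSE: the fraction of
components on which they disagree (0.25 = 25% disagreement).
"""

from __future__ import annotations

import numpy as np

from .core import (
    ARTIFACT,
    NEURAL,
    ContinuousEEG,
    DataError,
    FEATURE_NAMES,
    FeatureVector,
    IcaDecomposition,
    LabelSet,
    LinearClassifier,
    features_to_matrix,
)


class StratificationError(DataError):
    """A cross-validation fold lost one of the classes."""


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        X = np.atleast_2d(np.asarray(features, float))
    else:
        X = features_to_matrix(list(features))
    if X.shape[1] != 6:
        raise DataError("feature matrix must have 6 columns")
    return X


def train(
    features,
    labels: LabelSet,
    reg: float | str = "auto",
    alpha_band: tuple[float, float] = (6.0, 9.0),
    min_per_class: int = 10,
) -> LinearClassifier:
    """Fit the regularised-LDA decision rule on labelled feature vectors.

    ``min_per_class`` guards against under-determined fits; cross-validation
    folds relax it (a fold's training split may dip below 10 per class).
    """
    X = _as_matrix(features)
    y = labels.labels
    if len(y) != len(X):
        raise DataError("features and labels differ in length")
    if np.isnan(X).any():
        raise DataError("training features contain NaN")
    for cls in (ARTIFACT, NEURAL):
        if (y == cls).sum() < max(min_per_class, 1):
            raise DataError(
                f"need at least {min_per_class} examples per class"
            )
    sds = X.std(axis=0, ddof=0)
    degenerate = np.nonzero(sds == 0)[0]
    if degenerate.size:
        names = ", ".join(FEATURE_NAMES[i] for i in degenerate)
        raise DataError(f"degenerate (constant) feature(s): {names}")
    means = X.mean(axis=0)
    Z = (X - means) / sds

    mu_a = Z[y == ARTIFACT].mean(axis=0)
    mu_n = Z[y == NEURAL].mean(axis=0)
    centred = np.vstack([Z[y == ARTIFACT] - mu_a, Z[y == NEURAL] - mu_n])
    if reg == "auto":
        from sklearn.covariance import LedoitWolf

        cov = LedoitWolf(assume_centered=True).fit(centred).covariance_
    else:
        gamma = float(reg)
        if not 0 <= gamma <= 1:
            raise DataError("shrinkage must lie in [0, 1] or be 'auto'")
        S = centred.T @ centred / len(centred)
        cov = (1 - gamma) * S + gamma * (np.trace(S) / S.shape[0]) * np.eye(
            S.shape[0]
        )
    w = np.linalg.solve(cov, mu_a - mu_n)
    b = -0.5 * float(w @ (mu_a + mu_n))
    return LinearClassifier(
        w=w, b=b, feature_means=means, feature_sds=sds, alpha_band=alpha_band
    )


def decision_values(clf: LinearClassifier, features) -> np.ndarray:
    """w . z(x) + b for each feature vector."""
    X = _as_matrix(features)
    if np.isnan(X).any():
        raise DataError("features contain NaN")
    return clf.standardise(X) @ clf.w + clf.b


def classify(clf: LinearClassifier, x) -> int | np.ndarray:
    """sign(w . z(x) + b); exact zero maps to -1 (retain the component)."""
    single = isinstance(x, FeatureVector) or (
        isinstance(x, np.ndarray) and x.ndim == 1
    )
    d = decision_values(clf, [x] if isinstance(x, FeatureVector) else x)
    labels = np.where(d > 0, ARTIFACT, NEURAL)
    return int(labels[0]) if single else labels


def classify_labelset(clf: LinearClassifier, features) -> LabelSet:
    return LabelSet(np.atleast_1d(classify(clf, _as_matrix(features))),
                    source="automatic")


def evaluate_mse(auto: LabelSet, manual: LabelSet) -> float:
    """Fraction of components on which the two labelings disagree."""
    if len(auto) != len(manual):
        raise DataError("label sets differ in length")
    if len(auto) == 0:
        raise DataError("label sets are empty")
    return float((auto.labels != manual.labels).mean())


def crossvalidate(
    features,
    labels: LabelSet,
    k_folds: int = 10,
    seed: int = 0,
    reg: float | str = "auto",
) -> dict:
    """Stratified k-fold cross-validation; k = n gives leave-one-out."""
    X = _as_matrix(features)
    y = labels.labels
    n = len(y)
    if k_folds < 2:
        raise DataError("need at least 2 folds")
    if k_folds == n:
        from sklearn.model_selection import LeaveOneOut

        splits = LeaveOneOut().split(X)
    else:
        from sklearn.model_selection import StratifiedKFold

        counts = min((y == ARTIFACT).sum(), (y == NEURAL).sum())
        if k_folds > counts:
            raise StratificationError(
                f"{k_folds} stratified folds impossible with a class of {counts}"
            )
        splits = StratifiedKFold(
            n_splits=k_folds, shuffle=True, random_state=seed
        ).split(X, y)
    fold_mse = []
    for train_idx, test_idx in splits:
        y_tr = y[train_idx]
        if (y_tr == ARTIFACT).sum() == 0 or (y_tr == NEURAL).sum() == 0:
            raise StratificationError("a training fold lost one class")
        clf = train(X[train_idx], LabelSet(y_tr, source=labels.source),
                    reg=reg, min_per_class=2)
        pred = LabelSet(np.atleast_1d(classify(clf, X[test_idx])))
        fold_mse.append(
            evaluate_mse(pred, LabelSet(y[test_idx], source=labels.source))
        )
    fold_mse = np.array(fold_mse)
    return {
        "fold_mse": fold_mse,
        "mean_mse": float(fold_mse.mean()),
        "sd_mse": float(fold_mse.std(ddof=1)) if len(fold_mse) > 1 else 0.0,
    }


def remove_components(
    ica: IcaDecomposition, artifact_labels: LabelSet
) -> ContinuousEEG:
    """Reconstruct the EEG with artifact-labelled columns zeroed (lossless)."""
    if len(artifact_labels) != ica.n_components:
        raise DataError("label count must equal component count")
    keep = np.nonzero(artifact_labels.labels == NEURAL)[0]
    data = ica.reconstruct(keep)
    return ContinuousEEG(
        data=data,
        srate=ica.srate,
        channel_names=list(ica.channel_names),
        montage_ref=ica.montage_ref,
    )
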