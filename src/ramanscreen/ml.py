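"""Model-evaluation harness: PCA / t-SNE visualization, SVM grid search,
five-fold and leave-one-out cross-validation, ROC/AUC, averaged linear
coefficients, and permutation importance.

Conventions:

* Features are standardized inside each training fold only (never using
  held-out samples), so the null calibration of the harness is exact.
* SVMs use ``gamma='scale'``, ``class_weight='balanced'`` and a one-vs-one
  decision shape; the regularization C and polynomial degree come from an
  exhaustive grid search.
* Reported accuracy SD is the *population* SD of per-fold accuracies.  For
  leave-one-out CV each fold's accuracy is 0 or 1, so the SD collapses to
  sqrt(p(1-p)) of the mean accuracy — the convention behind "95.6% +/- 20.5%"
  style summaries.
* Leave-one-out AUC is computed from the single pooled ROC over all held-out
  decision scores (a per-fold ROC is undefined for one sample).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, LeaveOneOut
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ParameterError
from .features import FeatureTable


@dataclass(frozen=True)
class ModelSpec:
    """SVM specification: kernel, regularization C, polynomial degree."""

    kernel: str = "linear"
    C: float = 1.0
    degree: int | None = None

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "poly", "rbf"):
            raise ParameterError(f"unknown kernel {self.kernel!r}")
        if self.C <= 0:
            raise ParameterError("C must be > 0")
        if (self.kernel == "poly") != (self.degree is not None):
            raise ParameterError("degree must be given iff kernel='poly'")
        if self.degree is not None and self.degree < 2:
            raise ParameterError("polynomial degree must be >= 2")


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation scheme: 'kfold5' or 'loo', optional shuffling."""

    mode: str = "kfold5"
    shuffle: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("kfold5", "loo"):
            raise ParameterError(f"unknown CV mode {self.mode!r}")

    def splitter(self):
        if self.mode == "loo":
            return LeaveOneOut()
        return KFold(
            n_splits=5, shuffle=self.shuffle,
            random_state=self.seed if self.shuffle else None,
        )


@dataclass
class CVReport:
    """Cross-validation outcome."""

    scheme: str
    model: ModelSpec
    fold_accuracies: np.ndarray
    accuracy_mean: float
    accuracy_sd: float  # population SD of per-fold accuracies
    fold_aucs: list[float] = field(default_factory=list)
    auc_mean: float = float("nan")
    auc_sd: float = float("nan")
    pooled_auc: float = float("nan")  # loo: AUC of the pooled held-out ROC
    roc_curves: list[dict] = field(default_factory=list)
    mean_coefficients: np.ndarray | None = None  # linear kernel only
    feature_names: list[str] = field(default_factory=list)
    importances_mean: np.ndarray | None = None
    importances_sd: np.ndarray | None = None

    def to_json(self) -> str:
        def enc(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, ModelSpec):
                return asdict(v)
            return v
        return json.dumps({k: enc(v) for k, v in self.__dict__.items()}, indent=2)


def summarize_fold_accuracies(fold_accuracies) -> tuple[float, float]:
    """Mean and population SD of per-fold accuracies.

    For leave-one-out folds (binary accuracies) this reduces exactly to
    mean = p and SD = sqrt(p(1-p))."""
    acc = np.asarray(fold_accuracies, dtype=float)
    if acc.size == 0 or np.any((acc < 0) | (acc > 1)):
        raise ParameterError("fold accuracies must be in [0, 1]")
    return float(acc.mean()), float(acc.std(ddof=0))


def _make_pipeline(model: ModelSpec) -> Pipeline:
    svc = SVC(
        kernel=model.kernel,
        C=model.C,
        degree=model.degree if model.degree is not None else 3,
        gamma="scale",
        class_weight="balanced",
        decision_function_shape="ovo",
    )
    return Pipeline([("scale", StandardScaler()), ("svm", svc)])


def _check_xy(X, y):
    if isinstance(X, FeatureTable):
        names = list(X.feature_names)
        y = X.labels if y is None else np.asarray(y, dtype=int)
        X = X.X
    else:
        X = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
        y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ParameterError("both classes must be present in the labels")
    return X, y, names


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC by threshold sweep and AUC by trapezoidal integration.

    Equals the Mann-Whitney concordance probability with ties counted 1/2.
    Returns (fpr, tpr, auc)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ParameterError("both classes must be present for a ROC")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def grid_search_svm(
    X, y=None, kernel: str = "linear",
    c_grid=(0.01, 0.1, 1.0, 10.0, 100.0),
    degree_grid=(2, 3, 4),
    scheme: CVScheme = CVScheme(),
) -> tuple[ModelSpec, dict]:
    """Exhaustive grid search by mean CV accuracy under ``scheme``.

    Duplicate grid values collapse to one evaluation; ties break to the
    smaller C, then the smaller degree.  Returns the winning spec and the
    full {spec: mean accuracy} map for auditability.
    """
    X, y, _ = _check_xy(X, y)
    cs = sorted(set(float(c) for c in c_grid))
    if not cs:
        raise ParameterError("empty C grid")
    if kernel == "poly":
        degs = sorted(set(int(d) for d in degree_grid))
        if not degs:
            raise ParameterError("empty degree grid")
        specs = [ModelSpec(kernel, c, d) for c in cs for d in degs]
    else:
        specs = [ModelSpec(kernel, c) for c in cs]
    scores: dict[ModelSpec, float] = {}
    for spec in specs:
        accs = _fold_accuracies(X, y, spec, scheme)
        scores[spec] = float(np.mean(accs))
    # max accuracy; ties -> smaller C then smaller degree (specs are sorted so)
    best = max(specs, key=lambda s: (scores[s], -s.C, -(s.degree or 0)))
    return best, scores


def _fold_accuracies(X, y, model: ModelSpec, scheme: CVScheme) -> list[float]:
    accs = []
    for train, test in scheme.splitter().split(X):
        if np.unique(y[train]).size < 2:
            raise ParameterError(
                "a training fold contains a single class; shuffle the scheme "
                "(CVScheme(shuffle=True, seed=...)) or reorder the samples"
            )
        pipe = _make_pipeline(model)
        pipe.fit(X[train], y[train])
        accs.append(float(np.mean(pipe.predict(X[test]) == y[test])))
    return accs


def cross_validate(
    X, y=None, model: ModelSpec = ModelSpec(), scheme: CVScheme = CVScheme()
) -> CVReport:
    """Train/evaluate per fold; standardization fitted on training folds only.

    kfold5 reports per-fold ROC/AUC (folds whose held-out part is
    single-class get no ROC, with a warning) and the AUC mean +/- SD; loo
    reports one pooled ROC/AUC over all held-out decision scores.
    """
    X, y, names = _check_xy(X, y)
    fold_accs: list[float] = []
    fold_aucs: list[float] = []
    rocs: list[dict] = []
    pooled_scores = np.empty(0)
    pooled_labels = np.empty(0, dtype=int)
    coefs: list[np.ndarray] = []
    for train, test in scheme.splitter().split(X):
        if np.unique(y[train]).size < 2:
            raise ParameterError(
                "a training fold contains a single class; shuffle the scheme "
                "(CVScheme(shuffle=True, seed=...)) or reorder the samples"
            )
        pipe = _make_pipeline(model)
        pipe.fit(X[train], y[train])
        pred = pipe.predict(X[test])
        fold_accs.append(float(np.mean(pred == y[test])))
        scores = pipe.decision_function(X[test])
        if scheme.mode == "loo":
            pooled_scores = np.append(pooled_scores, scores)
            pooled_labels = np.append(pooled_labels, y[test])
        else:
            if np.unique(y[test]).size < 2:
                warnings.warn(
                    "held-out fold is single-class; no per-fold ROC recorded",
                    stacklevel=2,
                )
            else:
                fpr, tpr, auc = roc_auc(scores, y[test])
                fold_aucs.append(auc)
                rocs.append({"fpr": fpr.tolist(), "tpr": tpr.tolist(), "auc": auc})
        if model.kernel == "linear":
            coefs.append(pipe.named_steps["svm"].coef_.ravel().copy())
    mean_acc, sd_acc = summarize_fold_accuracies(fold_accs)
    report = CVReport(
        scheme=scheme.mode,
        model=model,
        fold_accuracies=np.asarray(fold_accs),
        accuracy_mean=mean_acc,
        accuracy_sd=sd_acc,
        feature_names=names,
    )
    if scheme.mode == "loo":
        fpr, tpr, auc = roc_auc(pooled_scores, pooled_labels)
        report.pooled_auc = auc
        report.roc_curves = [{"fpr": fpr.tolist(), "tpr": tpr.tolist(), "auc": auc}]
    else:
        report.fold_aucs = fold_aucs
        report.roc_curves = rocs
        if fold_aucs:
            report.auc_mean = float(np.mean(fold_aucs))
            report.auc_sd = float(np.std(fold_aucs, ddof=0))
    if coefs:
        report.mean_coefficients = average_linear_coefficients(coefs)
    return report


def average_linear_coefficients(fold_coefficients) -> np.ndarray:
    """Element-wise mean of per-fold linear SVM weight vectors, in the
    original feature order.  Positive entries associate a feature with class
    1 (disease)."""
    coefs = [np.asarray(c, dtype=float).ravel() for c in fold_coefficients]
    if not coefs:
        raise ParameterError("no fold coefficients given")
    lengths = {c.size for c in coefs}
    if len(lengths) > 1:
        raise ParameterError("mixed kernels or feature counts across folds")
    return np.mean(coefs, axis=0)


def permutation_importance_cv(
    X, y=None, model: ModelSpec = ModelSpec(), scheme: CVScheme = CVScheme(),
    repeats: int = 30, seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation importance across CV folds.

    For each fold and feature, the held-out values of that feature are
    shuffled ``repeats`` times and the accuracy drop recorded; returns the
    per-feature mean and SD of the decrease over folds x repeats.
    """
    from sklearn.inspection import permutation_importance as _perm

    X, y, _ = _check_xy(X, y)
    rng = np.random.default_rng(seed)
    all_drops: list[np.ndarray] = []  # each (n_features, repeats)
    for train, test in scheme.splitter().split(X):
        if np.unique(y[train]).size < 2:
            raise ParameterError("a training fold contains a single class")
        pipe = _make_pipeline(model)
        pipe.fit(X[train], y[train])
        res = _perm(
            pipe, X[test], y[test], n_repeats=repeats,
            random_state=int(rng.integers(2**31 - 1)), scoring="accuracy",
        )
        all_drops.append(res.importances)
    stacked = np.concatenate(all_drops, axis=1)  # folds x repeats pooled
    return stacked.mean(axis=1), stacked.std(axis=1, ddof=0)


def pca_reduce(X, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Scores on the top covariance eigenvectors plus the explained-variance
    fractions (non-increasing, summing to <= 1).  Data are centered
    internally."""
    if isinstance(X, FeatureTable):
        X = X.X
    X = np.asarray(X, dtype=float)
    if n_components > min(X.shape):
        raise ParameterError(
            f"n_components={n_components} > min(n_samples, n_features)={min(X.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_


@dataclass
class EmbeddingResult:
    """2-D t-SNE embedding with the parameters that produced it."""

    coordinates: np.ndarray
    labels: np.ndarray | None
    perplexity: float
    exaggeration: float
    metric: str
    seed: int | None


def tsne_embed(
    scores,
    perplexity: float = 30.0,
    exaggeration: float = 3.0,
    metric: str = "chebyshev",
    seed: int | None = None,
    labels=None,
) -> EmbeddingResult:
    """Exact (non-approximate) t-SNE to 2-D with Chebyshev high-dimensional
    distances; deterministic given ``seed``."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ParameterError("non-finite input to t-SNE")
    n = scores.shape[0]
    if n <= 3 * perplexity:
        warnings.warn(
            f"n={n} <= 3 x perplexity ({perplexity}); embedding may be unstable",
            stacklevel=2,
        )
    eff_perp = min(perplexity, max(1.0, n - 2))  # sklearn needs perplexity < n
    tsne = TSNE(
        n_components=2,
        perplexity=eff_perp,
        early_exaggeration=exaggeration,
        metric=metric,
        method="exact",
        init="pca",
        random_state=seed,
    )
    coords = tsne.fit_transform(scores)
    return EmbeddingResult(
        coordinates=coords,
        labels=None if labels is None else np.asarray(labels),
        perplexity=perplexity,
        exaggeration=exaggeration,
        metric=metric,
        seed=seed,
    )
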