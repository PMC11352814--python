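"""Random-Forest aggregated conformal predictors for mortality and survival days.

The predictive machinery wraps Random Forests in an aggregated
conformal predictor (ACP): ten sub-models, each trained on a bootstrap
draw with the out-of-bag rows serving as its calibration set, whose
conformal p-values are combined by the median. The classifier
calibrates marginally by default; class-conditional (Mondrian)
calibration is available, but it only produces conclusive sets when
every class keeps enough calibration points that 1/(n_cal+1) stays
below 1 - confidence. The regressor normalizes its absolute-residual
nonconformity by the mean absolute training residual among the 15
nearest neighbors in selected-feature space. Upstream of the ACP sit
standard scaling, class rebalancing (Instance Hardness Threshold for
the categorical target, All-KNN for the continuous one) and univariate
K-best feature selection. Internal validation is a stratified 5-fold
cross-validation in which the whole pipeline is refit inside every
training fold, plus a permutation importance on the held-out folds.

Nonconformity choices (1 - predicted probability of the true class;
normalized absolute residual) are the standard ones and are isolated in
small functions so alternatives are one-line swaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.feature_selection import SelectKBest, f_classif, f_regression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

REBALANCE_IHT = "instance-hardness-threshold"
REBALANCE_ALLKNN = "all-knn"


@dataclass
class ModelConfig:
    """Knobs of the conformal Random-Forest pipeline.

    Defaults: 200 trees, confidence 0.8, 10 aggregated sub-models,
    15-neighbor residual normalization, seed 46, 10 K-best features,
    min 2 samples per split, max_features = floor(sqrt(#selected)).
    """

    n_trees: int = 200
    confidence: float = 0.8
    n_acp_models: int = 10
    knn_norm_k: int = 15
    seed: int = 46
    k_best: int | str = 10          # "auto" resolves to 10
    min_samples_split: int = 2
    rebalance: str | None = None    # filled per task when None
    aggregation: str = "median"
    # class-conditional calibration guards per-class validity but needs
    # calibration sets large enough that 1/(n_cal+1) < 1 - confidence;
    # pooled (marginal) calibration is the workable default at cohort scale
    mondrian: bool = False
    folds: int = 5
    n_permutations: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")
        if self.n_acp_models < 1:
            raise ValueError("n_acp_models must be >= 1")

    def resolved_k(self, n_features: int) -> int:
        k = 10 if self.k_best == "auto" else int(self.k_best)
        if k > n_features:
            raise ValueError(f"k_best={k} exceeds {n_features} features")
        return k

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class PredictionSet:
    """Conformal output for one patient."""

    p_values: dict | None = None        # classification: class -> aggregated p
    prediction_set: tuple = ()
    conclusive: bool = False
    point: object = None                # argmax class / point regression value
    interval: tuple | None = None       # regression: (lo, hi) in days

    def contains(self, y) -> bool:
        if self.interval is not None:
            return self.interval[0] <= y <= self.interval[1]
        return y in self.prediction_set


# ---------------------------------------------------------------------------
# Rebalancing
# ---------------------------------------------------------------------------

def _class_counts(y: np.ndarray) -> dict:
    vals, counts = np.unique(y, return_counts=True)
    return dict(zip(vals, counts))


def all_knn_indices(X: np.ndarray, y: np.ndarray, k_max: int = 3) -> np.ndarray:
    """All-KNN undersampling: for k = 1..k_max in turn, remove majority-class
    samples whose k nearest neighbors (within the current set) majority-vote
    against their own label. The minority class is never touched."""
    counts = _class_counts(y)
    if len(counts) < 2 or min(counts.values()) < 2:
        warnings.warn("all-knn skipped: need two classes with >= 2 samples")
        return np.arange(len(y))
    minority = min(counts, key=counts.get)
    keep = np.arange(len(y))
    for k in range(1, k_max + 1):
        Xc, yc = X[keep], y[keep]
        if (yc != minority).sum() <= (yc == minority).sum():
            break
        nn = NearestNeighbors(n_neighbors=min(k + 1, len(keep)))
        nn.fit(Xc)
        _, idx = nn.kneighbors(Xc)
        neigh = yc[idx[:, 1:]]                       # drop self
        votes_own = (neigh == yc[:, None]).sum(axis=1)
        # a tie (half the neighbors agreeing) counts as correctly kept
        misclassified = votes_own < (neigh.shape[1] / 2.0)
        drop = misclassified & (yc != minority)
        keep = keep[~drop]
    return keep


def instance_hardness_indices(X: np.ndarray, y: np.ndarray,
                              seed: int = 46) -> np.ndarray:
    """Instance Hardness Threshold undersampling: hardness of a sample is
    1 - cross-validated predicted probability of its own class; the hardest
    majority-class samples are dropped until the classes balance."""
    counts = _class_counts(y)
    if len(counts) < 2 or min(counts.values()) < 2:
        warnings.warn("instance-hardness-threshold skipped: need two classes "
                      "with >= 2 samples")
        return np.arange(len(y))
    minority = min(counts, key=counts.get)
    majority = max(counts, key=counts.get)
    n_min, n_maj = counts[minority], counts[majority]
    if n_maj == n_min:
        return np.arange(len(y))
    cv = min(5, n_min)
    est = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    proba = cross_val_predict(est, X, y, cv=skf, method="predict_proba")
    classes = np.unique(y)
    own = proba[np.arange(len(y)), np.searchsorted(classes, y)]
    hardness = 1.0 - own
    maj_idx = np.flatnonzero(y == majority)
    order = maj_idx[np.argsort(hardness[maj_idx])]   # easiest first
    kept_majority = order[: n_min]                   # keep the easiest n_min
    keep = np.sort(np.concatenate([np.flatnonzero(y != majority),
                                   kept_majority]))
    return keep


def rebalance(X: np.ndarray, y: np.ndarray, method: str | None,
              seed: int = 46) -> np.ndarray:
    """Return the row indices kept by the requested undersampling method."""
    if method is None:
        return np.arange(len(y))
    if method == REBALANCE_ALLKNN:
        return all_knn_indices(X, y)
    if method == REBALANCE_IHT:
        return instance_hardness_indices(X, y, seed=seed)
    raise ValueError(f"unknown rebalancing method {method!r}")


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

def select_k_best(X: np.ndarray, y: np.ndarray, k: int,
                  task: str = "classification") -> np.ndarray:
    """Indices of the top-k features by univariate F-score
    (ANOVA F for classification, F-regression for regression)."""
    score = f_classif if task == "classification" else f_regression
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # constant features yield 0/0 F
        sel = SelectKBest(score, k=k).fit(X, y)
    return np.sort(np.flatnonzero(sel.get_support()))


# ---------------------------------------------------------------------------
# ACP classifier
# ---------------------------------------------------------------------------

def _bootstrap_split(n: int, rng: np.random.Generator,
                     y: np.ndarray | None = None,
                     max_retries: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap draw (proper training) + out-of-bag rows (calibration),
    redrawn while either part misses a class."""
    for _ in range(max_retries):
        train = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), train)
        if len(oob) == 0:
            continue
        if y is not None:
            classes = np.unique(y)
            if (len(np.unique(y[train])) < len(classes)
                    or len(np.unique(y[oob])) < len(classes)):
                continue
        return train, oob
    raise RuntimeError("could not draw a bootstrap split containing every "
                       f"class in {max_retries} tries")


@dataclass
class ConformalClassifierBundle:
    """Ten bootstrap-calibrated RF conformal sub-models (Mondrian)."""

    config: ModelConfig
    classes: np.ndarray = field(default_factory=lambda: np.array([]))
    models: list = field(default_factory=list)           # fitted RFs
    calibration: list = field(default_factory=list)      # per model: {class: sorted scores}

    def p_values_per_model(self, X: np.ndarray) -> np.ndarray:
        """(n_models, n_samples, n_classes) conformal p-values."""
        out = np.empty((len(self.models), X.shape[0], len(self.classes)))
        for m, (rf, cal) in enumerate(zip(self.models, self.calibration)):
            proba = _proba_aligned(rf, X, self.classes)
            for c, cls in enumerate(self.classes):
                alpha = 1.0 - proba[:, c]
                scores = cal[cls] if self.config.mondrian else cal[None]
                n_cal = len(scores)
                ge = n_cal - np.searchsorted(scores, alpha, side="left")
                out[m, :, c] = (ge + 1.0) / (n_cal + 1.0)
        return out

    def aggregated_p(self, X: np.ndarray) -> np.ndarray:
        return np.median(self.p_values_per_model(X), axis=0)


def _proba_aligned(rf, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    proba = rf.predict_proba(X)
    aligned = np.zeros((X.shape[0], len(classes)))
    for j, cls in enumerate(rf.classes_):
        aligned[:, np.flatnonzero(classes == cls)[0]] = proba[:, j]
    return aligned


def _max_features(n_selected: int) -> int:
    return max(1, int(np.floor(np.sqrt(n_selected))))


def fit_acp_classifier(X: np.ndarray, y: np.ndarray,
                       cfg: ModelConfig) -> ConformalClassifierBundle:
    """Fit the aggregated conformal RF classifier on (already selected)
    features. Calibration nonconformity is 1 - p-hat(true class), kept
    class-conditionally (Mondrian)."""
    classes = np.unique(y)
    if len(classes) < 2 or min(_class_counts(y).values()) < 2:
        raise ValueError("need >= 2 samples per class to fit the ACP")
    master = np.random.default_rng(cfg.seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=cfg.n_acp_models)
    bundle = ConformalClassifierBundle(config=cfg, classes=classes)
    for s in sub_seeds:
        rng = np.random.default_rng(int(s))
        train, oob = _bootstrap_split(len(y), rng, y)
        rf = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            class_weight="balanced",
            max_features=_max_features(X.shape[1]),
            min_samples_split=cfg.min_samples_split,
            oob_score=True,
            random_state=int(s),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # small OOB folds
            rf.fit(X[train], y[train])
        proba = _proba_aligned(rf, X[oob], classes)
        cal: dict = {}
        true_col = np.searchsorted(classes, y[oob])
        # pooled scores (key None) and class-conditional scores both kept
        cal[None] = np.sort(1.0 - proba[np.arange(len(oob)), true_col])
        for c, cls in enumerate(classes):
            mask = y[oob] == cls
            cal[cls] = np.sort(1.0 - proba[mask, c])
        bundle.models.append(rf)
        bundle.calibration.append(cal)
    return bundle


def predict_set(bundle: ConformalClassifierBundle,
                X: np.ndarray) -> list[PredictionSet]:
    """Median-aggregated p-values -> prediction sets at the configured
    confidence; conclusive iff the set is a singleton."""
    X = np.atleast_2d(X)
    p = bundle.aggregated_p(X)
    eps = 1.0 - bundle.config.confidence
    out = []
    for i in range(X.shape[0]):
        pv = {cls: float(p[i, c]) for c, cls in enumerate(bundle.classes)}
        members = tuple(cls for cls, v in pv.items() if v > eps)
        out.append(PredictionSet(
            p_values=pv,
            prediction_set=members,
            conclusive=len(members) == 1,
            point=bundle.classes[int(np.argmax(p[i]))],
        ))
    return out


# ---------------------------------------------------------------------------
# ACP regressor (normalized nonconformity)
# ---------------------------------------------------------------------------

@dataclass
class ConformalRegressorBundle:
    config: ModelConfig
    models: list = field(default_factory=list)
    normalizers: list = field(default_factory=list)  # (NearestNeighbors, residuals, beta)
    quantiles: list = field(default_factory=list)    # per model conformal q


def calibration_quantile(scores: np.ndarray, confidence: float) -> float:
    """(n+1)-convention conformal quantile: the ceil(confidence*(n+1))-th
    smallest calibration score (the largest score when the rank overflows)."""
    scores = np.sort(np.asarray(scores, dtype=float))
    n_cal = len(scores)
    rank = int(np.ceil(confidence * (n_cal + 1)))
    return float(scores[min(rank, n_cal) - 1])


def _sigma_hat(normalizer, X: np.ndarray) -> np.ndarray:
    nn, residuals, beta = normalizer
    _, idx = nn.kneighbors(X)
    return residuals[idx].mean(axis=1) + beta


def fit_acp_regressor(X: np.ndarray, y: np.ndarray,
                      cfg: ModelConfig) -> ConformalRegressorBundle:
    """Aggregated conformal RF regressor with KNN-normalized residuals.

    sigma-hat(x) = mean absolute training residual among the 15 nearest
    training points (selected-feature space) plus a small floor
    beta = 0.01 * sd(y); per-model interval half-width is q * sigma-hat
    with q the (n+1)-convention calibration quantile at the configured
    confidence.
    """
    if len(y) < 3:
        raise ValueError("need at least 3 samples to fit the regressor")
    # degenerate constant outcome: keep sigma-hat strictly positive
    beta = 0.01 * float(np.std(y)) or 1e-9
    master = np.random.default_rng(cfg.seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=cfg.n_acp_models)
    bundle = ConformalRegressorBundle(config=cfg)
    for s in sub_seeds:
        rng = np.random.default_rng(int(s))
        train, oob = _bootstrap_split(len(y), rng)
        rf = RandomForestRegressor(
            n_estimators=cfg.n_trees,
            max_features=_max_features(X.shape[1]),
            min_samples_split=cfg.min_samples_split,
            oob_score=True,
            random_state=int(s),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(X[train], y[train])
        resid = np.abs(y[train] - rf.predict(X[train]))
        k = min(cfg.knn_norm_k, len(train))
        nn = NearestNeighbors(n_neighbors=k).fit(X[train])
        normalizer = (nn, resid, beta)
        sigma = _sigma_hat(normalizer, X[oob])
        scores = np.abs(y[oob] - rf.predict(X[oob])) / sigma
        q = calibration_quantile(scores, cfg.confidence)
        bundle.models.append(rf)
        bundle.normalizers.append(normalizer)
        bundle.quantiles.append(q)
    return bundle


def predict_interval(bundle: ConformalRegressorBundle,
                     X: np.ndarray) -> list[PredictionSet]:
    """Median of per-model interval bounds; regression sets are always
    conclusive."""
    X = np.atleast_2d(X)
    lows = np.empty((len(bundle.models), X.shape[0]))
    highs = np.empty_like(lows)
    points = np.empty_like(lows)
    for m, (rf, normalizer, q) in enumerate(
            zip(bundle.models, bundle.normalizers, bundle.quantiles)):
        yhat = rf.predict(X)
        sigma = _sigma_hat(normalizer, X)
        lows[m] = yhat - q * sigma
        highs[m] = yhat + q * sigma
        points[m] = yhat
    lo = np.median(lows, axis=0)
    hi = np.median(highs, axis=0)
    pt = np.median(points, axis=0)
    return [PredictionSet(interval=(float(lo[i]), float(hi[i])),
                          conclusive=True, point=float(pt[i]))
            for i in range(X.shape[0])]


# ---------------------------------------------------------------------------
# bundle persistence
# ---------------------------------------------------------------------------

_ARCHIVE_VERSION = 1


def save_bundle(bundle, path) -> None:
    """Serialize a fitted conformal bundle (or pipeline) to a versioned
    joblib archive."""
    import joblib

    joblib.dump({"format_version": _ARCHIVE_VERSION, "bundle": bundle}, path)


def load_bundle(path):
    import joblib

    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != _ARCHIVE_VERSION:
        raise ValueError(f"unsupported bundle archive version {version!r}")
    return payload["bundle"]


# ---------------------------------------------------------------------------
# Full pipeline + cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FittedPipeline:
    """Scaler + rebalanced fit + selected features + conformal bundle."""

    task: str
    scaler: StandardScaler
    selected: np.ndarray
    bundle: object
    kept_rows: np.ndarray

    def predict(self, X: np.ndarray) -> list[PredictionSet]:
        Xs = self.scaler.transform(np.atleast_2d(X))[:, self.selected]
        if self.task == "classification":
            return predict_set(self.bundle, Xs)
        return predict_interval(self.bundle, Xs)


def fit_pipeline(X: np.ndarray, y: np.ndarray, cfg: ModelConfig,
                 task: str = "classification",
                 rebalance_labels: np.ndarray | None = None) -> FittedPipeline:
    """scale -> rebalance -> K-best select -> fit the ACP.

    For the continuous target the resampling decision is made on
    ``rebalance_labels`` (event status), while the model is fit on the
    surviving rows' day counts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)

    method = cfg.rebalance
    if method is None:
        method = REBALANCE_IHT if task == "classification" else REBALANCE_ALLKNN
    elif method == "none":
        method = None
    labels = y if task == "classification" else rebalance_labels
    if labels is not None and method is not None:
        kept = rebalance(Xs, np.asarray(labels), method, seed=cfg.seed)
    else:
        kept = np.arange(len(y))
    Xr, yr = Xs[kept], y[kept]

    k = cfg.resolved_k(X.shape[1])
    selected = select_k_best(Xr, yr, k, task=task)
    Xsel = Xr[:, selected]
    if task == "classification":
        bundle = fit_acp_classifier(Xsel, yr, cfg)
    else:
        bundle = fit_acp_regressor(Xsel, yr.astype(float), cfg)
    return FittedPipeline(task=task, scaler=scaler, selected=selected,
                          bundle=bundle, kept_rows=kept)


@dataclass
class CVResult:
    prediction_sets: list
    y_true: np.ndarray
    fold_selected: list            # per fold: selected feature indices
    importances: pd.Series         # permutation importance per feature
    point_predictions: np.ndarray


def cross_validate(X, y, cfg: ModelConfig, task: str = "classification",
                   folds: int | None = None,
                   strata: np.ndarray | None = None,
                   feature_names: list[str] | None = None) -> CVResult:
    """Stratified K-fold internal validation of the whole pipeline.

    The complete pipeline (rebalance -> select -> fit) is re-run inside
    each training fold; out-of-fold prediction sets are pooled.
    Permutation importance is the mean degradation of held-out accuracy
    (classification) or R-squared on the held-out fold (regression)
    over ``cfg.n_permutations`` shuffles of one feature at a time,
    averaged across folds; features never selected score 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    folds = folds or cfg.folds
    if n < folds:
        raise ValueError(f"need n >= folds, got n={n}, folds={folds}")
    if strata is None:
        strata = y if task == "classification" else None
    if strata is None:
        raise ValueError("regression cross-validation needs strata "
                         "(e.g. event status)")
    strata = np.asarray(strata)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    preds: list = [None] * n
    points = np.empty(n, dtype=object)
    fold_selected = []
    importance_acc = np.zeros(p)
    importance_folds = np.zeros(p)

    for train_idx, test_idx in skf.split(X, strata):
        fp = fit_pipeline(X[train_idx], y[train_idx], cfg, task=task,
                          rebalance_labels=(strata[train_idx]
                                            if task != "classification" else None))
        fold_sets = fp.predict(X[test_idx])
        for i, ps in zip(test_idx, fold_sets):
            preds[i] = ps
            points[i] = ps.point
        fold_selected.append(fp.selected.copy())

        y_test = y[test_idx]
        n_test = len(test_idx)
        base = _metric_from_points(_points(fp, X[test_idx]), y_test, task)
        for f in fp.selected:
            # all permutations of one feature predicted in a single batch
            stack = np.tile(X[test_idx], (cfg.n_permutations, 1))
            for r in range(cfg.n_permutations):
                rows = slice(r * n_test, (r + 1) * n_test)
                stack[rows, f] = rng.permutation(X[test_idx][:, f])
            pts = _points(fp, stack)
            drops = np.empty(cfg.n_permutations)
            for r in range(cfg.n_permutations):
                rows = slice(r * n_test, (r + 1) * n_test)
                drops[r] = base - _metric_from_points(pts[rows], y_test, task)
            importance_acc[f] += drops.mean()
            importance_folds[f] += 1

    with np.errstate(invalid="ignore"):
        imp = np.where(importance_folds > 0,
                       importance_acc / np.maximum(importance_folds, 1), 0.0)
    names = feature_names if feature_names is not None else list(range(p))
    point_arr = (np.array([pt for pt in points])
                 if task == "classification"
                 else np.array([float(pt) for pt in points]))
    return CVResult(prediction_sets=preds, y_true=y,
                    fold_selected=fold_selected,
                    importances=pd.Series(imp, index=names),
                    point_predictions=point_arr)


def _points(fp: FittedPipeline, X: np.ndarray) -> np.ndarray:
    """Point predictions (argmax class / median regression value) without
    building PredictionSet objects, batched for speed."""
    Xs = fp.scaler.transform(np.atleast_2d(X))[:, fp.selected]
    if fp.task == "classification":
        p = fp.bundle.aggregated_p(Xs)
        return fp.bundle.classes[np.argmax(p, axis=1)]
    preds = np.stack([rf.predict(Xs) for rf in fp.bundle.models])
    return np.median(preds, axis=0)


def _metric_from_points(pts: np.ndarray, y: np.ndarray, task: str) -> float:
    if task == "classification":
        return float((pts == y).mean())
    y = y.astype(float)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    sse = float(((y - pts.astype(float)) ** 2).sum())
    return 1.0 - sse / tss
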