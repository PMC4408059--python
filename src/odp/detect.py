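"""Dicrotic-pulse detectors and their validation.

Three detector families operate on the 16 GLCM texture features:

- a univariate threshold rule on the phase-plane homogeneity (dicrotic iff
  homogeneity <= tau, default tau = 0.428);
- a conditional inference tree: recursive binary splitting where the split
  variable is chosen by permutation tests of association between each
  feature and the label, with Bonferroni multiplicity adjustment, and
  splitting stops when no adjusted p-value falls below alpha = 0.05;
- a random forest (entropy criterion), which also supplies the
  mean-decrease-in-entropy variable importance ranking used by backward
  sequential feature selection.

Generalisation accuracy is estimated by the bootstrap 632+ method: the
leave-one-out bootstrap error and the resubstitution error are blended
with a weight governed by the relative overfitting rate against the
no-information rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .signals import DICROTIC, NON_DICROTIC
from .texture import FEATURE_NAMES, FeatureVector

__all__ = [
    "Dataset",
    "DetectorModel",
    "homogeneity_rule",
    "fit_detector",
    "variable_importance",
    "backward_select",
    "bootstrap_632plus",
    "ValidationReport",
    "DEFAULT_THRESHOLD",
    "DETECTOR_KINDS",
]

DEFAULT_THRESHOLD = 0.428
DETECTOR_KINDS = ("homogeneity_threshold", "conditional_tree", "random_forest")

_PHASE_HOMOGENEITY = "phase_homogeneity"


@dataclass(frozen=True)
class Dataset:
    """Feature matrix with binary dicrotic / non-dicrotic labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError("feature matrix shape does not match feature names")
        if len(y) != X.shape[0]:
            raise ValueError("label count does not match feature rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains non-finite values")
        bad = set(y) - {DICROTIC, NON_DICROTIC}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
        ids = self.ids or tuple(str(i) for i in range(X.shape[0]))
        object.__setattr__(self, "ids", tuple(ids))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def y01(self) -> np.ndarray:
        return (self.y == DICROTIC).astype(int)

    def subset(self, features: Sequence[str]) -> "Dataset":
        idx = [self.feature_names.index(f) for f in features]
        return Dataset(self.X[:, idx], self.y, tuple(features), self.ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "id", list(self.ids))
        df["label"] = self.y
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Dataset":
        names = [c for c in df.columns if c not in ("id", "label")]
        ids = tuple(df["id"].astype(str)) if "id" in df else ()
        return cls(df[names].to_numpy(float), df["label"].to_numpy(), tuple(names), ids)


def _labels_from01(y01: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(y01).astype(bool), DICROTIC, NON_DICROTIC)


def homogeneity_rule(
    fv: FeatureVector | float, threshold: float = DEFAULT_THRESHOLD
) -> str:
    """Univariate rule: dicrotic iff phase-plane homogeneity <= threshold."""
    value = fv[_PHASE_HOMOGENEITY] if isinstance(fv, FeatureVector) else float(fv)
    return DICROTIC if value <= threshold else NON_DICROTIC


# -- detector implementations ------------------------------------------------


class ThresholdDetector:
    """Single-feature threshold rule (dicrotic iff value <= tau).

    With ``threshold`` given the rule is fixed and ``fit`` is a no-op;
    with ``threshold=None`` the cutpoint minimising training error is
    chosen among midpoints of consecutive sorted feature values.
    """

    def __init__(self, feature_index: int = 0, threshold: float | None = DEFAULT_THRESHOLD):
        self.feature_index = feature_index
        self.threshold = threshold

    def fit(self, X: np.ndarray, y01: np.ndarray) -> "ThresholdDetector":
        if self.threshold is not None:
            return self
        x = X[:, self.feature_index]
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], np.asarray(y01)[order]
        uniq = np.unique(xs)
        cuts = np.concatenate(
            ([uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0])
        )
        # errors of "dicrotic iff x <= cut" for every candidate cut
        errs = [np.mean((xs <= c).astype(int) != ys) for c in cuts]
        self.threshold = float(cuts[int(np.argmin(errs))])
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return (X[:, self.feature_index] <= self.threshold).astype(float)


class ConditionalInferenceTree:
    """Binary classification tree with test-based split selection.

    At each node, the association between every feature and the label is
    assessed by a permutation test of the absolute Pearson correlation
    (the same label permutations are shared across features); p-values are
    Bonferroni-adjusted over the features under test.  If no adjusted
    p-value is below ``alpha`` the node becomes a leaf, otherwise the
    feature with the smallest p-value is split at the cutpoint maximising
    the standardised two-sample statistic.  This test-then-split scheme
    gives unbiased variable selection and a statistically motivated
    stopping rule, without post-pruning.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        n_permutations: int = 499,
        min_samples_split: int = 8,
        min_leaf: int = 3,
        max_depth: int = 12,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.min_samples_split = min_samples_split
        self.min_leaf = min_leaf
        self.max_depth = max_depth
        self.random_state = random_state
        self.tree_: dict | None = None

    # tree nodes are plain dicts:
    #   leaf: {"prob": float, "n": int}
    #   split: {"feature": int, "cut": float, "left": node, "right": node}

    def fit(self, X: np.ndarray, y01: np.ndarray) -> "ConditionalInferenceTree":
        X = np.asarray(X, float)
        y = np.asarray(y01, float)
        rng = np.random.default_rng(self.random_state)
        self.tree_ = self._build(X, y, depth=0, rng=rng)
        return self

    def _association_pvalues(
        self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        n = len(y)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        sx = np.sqrt((Xc**2).sum(axis=0))
        sy = np.sqrt((yc**2).sum())
        valid = (sx > 0) & (sy > 0)
        stat = np.zeros(X.shape[1])
        pvals = np.ones(X.shape[1])
        if valid.any() and sy > 0:
            denom = np.where(valid, sx * sy, 1.0)
            stat = np.abs(Xc.T @ yc) / denom
            stat[~valid] = 0.0
            P = self.n_permutations
            perms = np.empty((P, n))
            for b in range(P):
                perms[b] = rng.permutation(yc)
            null = np.abs(Xc.T @ perms.T) / denom[:, None]  # (p, P)
            exceed = (null >= stat[:, None] - 1e-12).sum(axis=1)
            pvals = (1.0 + exceed) / (P + 1.0)
            pvals[~valid] = 1.0
        return stat, pvals

    def _best_cut(self, x: np.ndarray, y: np.ndarray) -> float | None:
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        n = len(ys)
        csum = np.cumsum(ys - ys.mean())
        n_left = np.arange(1, n)
        # candidate cut after position k only where the value actually changes
        changes = xs[:-1] < xs[1:]
        ok = (
            changes
            & (n_left >= self.min_leaf)
            & (n - n_left >= self.min_leaf)
        )
        if not ok.any():
            return None
        t = np.abs(csum[:-1]) / np.sqrt(n_left * (n - n_left))
        t[~ok] = -np.inf
        k = int(np.argmax(t))
        return float((xs[k] + xs[k + 1]) / 2.0)

    def _build(self, X, y, depth, rng) -> dict:
        leaf = {"prob": float(y.mean()), "n": int(len(y))}
        if (
            len(y) < self.min_samples_split
            or depth >= self.max_depth
            or y.min() == y.max()
        ):
            return leaf
        stat, pvals = self._association_pvalues(X, y, rng)
        m = X.shape[1]
        adj = np.minimum(1.0, pvals * m)
        if adj.min() > self.alpha:
            return leaf
        # smallest p-value wins; ties broken by the larger statistic then
        # by canonical feature order
        j = int(np.lexsort((np.arange(m), -stat, pvals))[0])
        cut = self._best_cut(X[:, j], y)
        if cut is None:
            return leaf
        mask = X[:, j] <= cut
        return {
            "feature": j,
            "cut": cut,
            "left": self._build(X[mask], y[mask], depth + 1, rng),
            "right": self._build(X[~mask], y[~mask], depth + 1, rng),
        }

    def _leaf_prob(self, node: dict, row: np.ndarray) -> float:
        while "feature" in node:
            node = node["left"] if row[node["feature"]] <= node["cut"] else node["right"]
        return node["prob"]

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        if self.tree_ is None:
            raise RuntimeError("tree has not been fitted")
        X = np.asarray(X, float)
        return np.array([self._leaf_prob(self.tree_, row) for row in X])

    def depth(self) -> int:
        def d(node):
            if "feature" not in node:
                return 0
            return 1 + max(d(node["left"]), d(node["right"]))

        return d(self.tree_) if self.tree_ else 0


class ForestDetector:
    """Random forest with the entropy (information-gain) split criterion."""

    def __init__(self, n_estimators: int = 100, random_state: int = 0):
        self.clf = RandomForestClassifier(
            n_estimators=n_estimators,
            criterion="entropy",
            random_state=random_state,
        )

    def fit(self, X, y01):
        self.clf.fit(X, np.asarray(y01).astype(int))
        return self

    def predict_score(self, X) -> np.ndarray:
        if len(self.clf.classes_) == 1:
            return np.full(len(X), float(self.clf.classes_[0]))
        return self.clf.predict_proba(X)[:, list(self.clf.classes_).index(1)]

    @property
    def importances(self) -> np.ndarray:
        return self.clf.feature_importances_


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _make_detector(
    kind, feature_names: Sequence[str], seed: int, **params
):
    if callable(kind):  # custom detector factory: kind(seed) -> detector
        return kind(seed)
    if kind == "homogeneity_threshold":
        name = params.pop("feature", _PHASE_HOMOGENEITY)
        idx = list(feature_names).index(name) if name in feature_names else 0
        return ThresholdDetector(feature_index=idx, **params)
    if kind == "conditional_tree":
        return ConditionalInferenceTree(random_state=seed, **params)
    if kind == "random_forest":
        return ForestDetector(random_state=seed, **params)
    raise ValueError(f"unknown detector kind {kind!r}; choose from {DETECTOR_KINDS}")


@dataclass
class DetectorModel:
    """A fitted detector restricted to ``selected_features``."""

    kind: str
    detector: object
    selected_features: tuple[str, ...]
    seed: int

    def score(self, data: Dataset) -> np.ndarray:
        """Dicrotic-class score in [0, 1] per signal."""
        X = data.subset(self.selected_features).X
        return self.detector.predict_score(X)

    def predict(self, data: Dataset) -> np.ndarray:
        """Predicted labels (score > 0.5 -> dicrotic)."""
        return _labels_from01(self.score(data) > 0.5)


def fit_detector(
    data: Dataset,
    kind: str = "random_forest",
    seed: int = 0,
    selected_features: Sequence[str] | None = None,
    **params,
) -> DetectorModel:
    """Fit a detector of the given kind; deterministic given ``seed``."""
    if len(np.unique(data.y)) < 2:
        raise ValueError("fitting requires both classes present")
    features = tuple(selected_features or data.feature_names)
    sub = data.subset(features)
    det = _make_detector(kind, features, seed, **params)
    det.fit(sub.X, sub.y01)
    return DetectorModel(kind=kind, detector=det, selected_features=features, seed=seed)


def variable_importance(
    data: Dataset, seed: int = 0, n_estimators: int = 200
) -> list[str]:
    """All features ranked by random-forest mean entropy decrease, descending.

    Ties are broken by canonical feature order.
    """
    det = ForestDetector(n_estimators=n_estimators, random_state=seed)
    det.fit(data.X, data.y01)
    imp = det.importances
    order = sorted(range(len(imp)), key=lambda k: (-imp[k], k))
    return [data.feature_names[k] for k in order]


@dataclass
class ValidationReport:
    """Bootstrap 632+ accuracy estimate with its ingredients.

    ``per_resample_accuracy`` holds each resample's out-of-bag accuracy
    (NaN when a resample had no out-of-bag sample); ``err_loo_per_sample``
    holds each sample's error averaged over the resamples excluding it.
    """

    accuracy_632plus: float
    sd: float
    n_bootstrap: int
    seed: int
    selected_features: tuple[str, ...]
    kind: str
    err_train: float
    err_loo_boot: float
    gamma: float
    overfitting_rate: float
    weight: float
    per_resample_accuracy: np.ndarray
    err_loo_per_sample: np.ndarray
    excluded_ids: tuple[str, ...] = ()


def bootstrap_632plus(
    data: Dataset,
    kind: str = "random_forest",
    B: int = 200,
    seed: int = 0,
    selected_features: Sequence[str] | None = None,
    **params,
) -> ValidationReport:
    """Estimate detector accuracy by the bootstrap 632+ method.

    ``err(1)`` is the leave-one-out bootstrap error (each sample's error
    averaged over the resamples that exclude it), ``err_train`` the
    resubstitution error, ``gamma`` the no-information rate from the label
    and prediction marginals, ``R = (err(1) - err_train)/(gamma -
    err_train)`` clipped to [0, 1] the relative overfitting rate, and the
    estimate is ``(1-w) err_train + w err(1)`` with ``w = .632/(1 - .368
    R)``.  Reported as an accuracy (1 - error) with the standard deviation
    of per-resample out-of-bag accuracies.
    """
    if B < 50:
        raise ValueError(f"B must be >= 50, got {B}")
    features = tuple(selected_features or data.feature_names)
    sub = data.subset(features)
    X, y01 = sub.X, sub.y01
    n = sub.n
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    err_matrix = np.full((B, n), np.nan)
    resample_acc = np.full(B, np.nan)
    for b in range(B):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(np.unique(y01[boot])) < 2 or oob.size == 0:
            continue
        det = _make_detector(kind, features, _seed_int(ss.spawn(1)[0]), **params)
        det.fit(X[boot], y01[boot])
        pred = (det.predict_score(X[oob]) > 0.5).astype(int)
        errs = (pred != y01[oob]).astype(float)
        err_matrix[b, oob] = errs
        resample_acc[b] = 1.0 - errs.mean()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        err_loo_per_sample = np.nanmean(err_matrix, axis=0)
    never_oob = np.isnan(err_loo_per_sample)
    excluded: tuple[str, ...] = ()
    if never_oob.any():
        excluded = tuple(np.array(sub.ids)[never_oob])
        warnings.warn(
            f"{never_oob.sum()} sample(s) never out-of-bag across {B} "
            "resamples; excluded from the leave-one-out bootstrap error",
            stacklevel=2,
        )
    err1 = float(np.mean(err_loo_per_sample[~never_oob]))

    full = _make_detector(kind, features, _seed_int(ss.spawn(1)[0]), **params)
    full.fit(X, y01)
    pred_full = (full.predict_score(X) > 0.5).astype(int)
    err_train = float(np.mean(pred_full != y01))

    # no-information rate from label (p) and prediction (q) marginals
    p1 = float(np.mean(y01))
    q1 = float(np.mean(pred_full))
    gamma = p1 * (1.0 - q1) + (1.0 - p1) * q1

    if err1 > err_train and gamma > err_train:
        R = float(np.clip((err1 - err_train) / (gamma - err_train), 0.0, 1.0))
    else:
        R = 0.0
    w = 0.632 / (1.0 - 0.368 * R)
    err632p = (1.0 - w) * err_train + w * err1

    acc = resample_acc[~np.isnan(resample_acc)]
    return ValidationReport(
        accuracy_632plus=1.0 - err632p,
        sd=float(np.std(acc, ddof=1)) if acc.size > 1 else 0.0,
        n_bootstrap=B,
        seed=seed,
        selected_features=features,
        kind=kind if isinstance(kind, str) else getattr(kind, "__name__", "custom"),
        err_train=err_train,
        err_loo_boot=err1,
        gamma=gamma,
        overfitting_rate=R,
        weight=w,
        per_resample_accuracy=resample_acc,
        err_loo_per_sample=err_loo_per_sample,
        excluded_ids=excluded,
    )


def backward_select(
    data: Dataset,
    kind: str = "random_forest",
    seed: int = 0,
    inner_B: int = 50,
    **params,
) -> tuple[str, ...]:
    """Backward sequential feature selection driven by forest importance.

    Starting from all features, the least-important feature (random-forest
    entropy-loss ranking) is dropped at each step; every candidate subset
    is scored by a bootstrap 632+ estimate with ``inner_B`` resamples, and
    the subset with the highest estimate is returned (ties favour the
    smaller subset).  Never returns the empty set.
    """
    if data.n < 16:
        raise ValueError("backward selection needs at least 16 samples")
    ss = np.random.SeedSequence(seed)
    current = list(data.feature_names)
    best_acc = -np.inf
    best: tuple[str, ...] = tuple(current)
    while True:
        rep = bootstrap_632plus(
            data, kind, B=inner_B, seed=_seed_int(ss.spawn(1)[0]),
            selected_features=current, **params,
        )
        if rep.accuracy_632plus >= best_acc:  # ties -> smaller subset
            best_acc = rep.accuracy_632plus
            best = tuple(current)
        if len(current) == 1:
            break
        ranking = variable_importance(
            data.subset(current), seed=_seed_int(ss.spawn(1)[0])
        )
        current.remove(ranking[-1])
    return best
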