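"""Predictive modeling of peripheral neuropathy from game features.

The pipeline mirrors a glmnet-style workflow: near-zero-variance and
intercorrelation filters, a stratified 3:7 hold-out split, univariate
screening on the training partition, model-based/ROC importance ranking,
a nested-prefix subset search over the top-20 features with a grid over
the elastic-net mixing (alpha) and penalty strength (lambda) scored by
repeated stratified 5-fold cross-validated AUC-ROC, and final held-out
evaluation (sensitivity, specificity, balanced accuracy, AUC).  The
multiclass phenotype model is evaluated by repeated CV only, with the
Hand-Till generalization of the AUC.

The penalized objective is the glmnet parameterization
``(1/n) NLL + lambda[(1-alpha)/2 ||b||^2 + alpha ||b||_1]`` (scikit-learn's
saga solver behind the scenes, ``C = 1/(n lambda)``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kruskal, rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold

from .errors import DegenerateInputError, NeuroplayError
from .stats import compare_groups

DEFAULT_ALPHAS = (0.1, 0.55, 1.0)
DEFAULT_LAMBDAS = tuple(np.logspace(-5, 1, 100))


@dataclass(frozen=True)
class ModelSpec:
    family: str = "elastic_net_logistic"
    alpha: float = 0.1
    lam: float = 1e-3
    standardize: bool = True

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise NeuroplayError("alpha must be in [0, 1]")
        if self.lam < 0:
            raise NeuroplayError("lambda must be >= 0")


@dataclass(frozen=True)
class CvScheme:
    folds: int = 5
    repeats: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise NeuroplayError("folds must be >= 2")

    def splitter(self) -> RepeatedStratifiedKFold:
        return RepeatedStratifiedKFold(n_splits=self.folds,
                                       n_repeats=self.repeats,
                                       random_state=self.seed)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class EvalReport:
    confusion: ConfusionMatrix
    sensitivity: float        # percent, 1 decimal
    specificity: float
    balanced_accuracy: float
    auc_roc: float | None = None
    per_class_auc: dict = field(default_factory=dict)

    @classmethod
    def from_confusion(cls, tp: int, fn: int, fp: int, tn: int,
                       auc: float | None = None) -> "EvalReport":
        sens = 100.0 * tp / (tp + fn)
        spec = 100.0 * tn / (tn + fp)
        bal = (sens + spec) / 2.0
        return cls(ConfusionMatrix(tp, fn, fp, tn),
                   round(sens, 1), round(spec, 1), round(bal, 1), auc)


# ---------------------------------------------------------------------------
# metrics

def binary_auc(scores, labels) -> float:
    """AUC-ROC by the rank statistic with tie correction (midranks)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise DegenerateInputError("AUC undefined for single-class labels")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def multiclass_auc(scores: pd.DataFrame, labels) -> float:
    """Hand-Till multiclass AUC: the average over unordered class pairs
    (i, j) of [A(i|j) + A(j|i)] / 2, where A(i|j) is the AUC of class i's
    score separating classes i and j."""
    labels = np.asarray(labels)
    classes = list(scores.columns)
    for c in classes:
        if not np.any(labels == c):
            raise DegenerateInputError(f"class {c!r} absent from labels")
    total, pairs = 0.0, 0
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            ci, cj = classes[a], classes[b]
            mask = (labels == ci) | (labels == cj)
            yi = (labels[mask] == ci).astype(int)
            a_ij = binary_auc(scores.loc[mask, ci].to_numpy(), yi)
            a_ji = binary_auc(scores.loc[mask, cj].to_numpy(), 1 - yi)
            total += (a_ij + a_ji) / 2.0
            pairs += 1
    return total / pairs


# ---------------------------------------------------------------------------
# feature filters

def variance_filter(table: pd.DataFrame, sd_floor: float = 1e-8,
                    min_unique: int = 3) -> pd.DataFrame:
    """Drop near-zero-variance features (sd below the floor or fewer than
    ``min_unique`` distinct values)."""
    sd = table.std(ddof=1)
    nun = table.nunique()
    keep = (sd.fillna(0.0) >= sd_floor) & (nun >= min_unique)
    return table.loc[:, keep]


def correlation_filter(table: pd.DataFrame,
                       threshold: float = 0.75) -> pd.DataFrame:
    """Greedy elimination of redundant features.

    While any pair has |r| strictly above the threshold, the member of the
    most-correlated pair with the larger mean absolute correlation to all
    other features is dropped (ties: the lexicographically later feature
    id goes).
    """
    cols = list(table.columns)
    if len(cols) < 2:
        return table
    c = np.abs(np.corrcoef(table.to_numpy(float), rowvar=False))
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 0.0)
    alive = np.ones(len(cols), bool)
    while True:
        sub = np.where(alive)[0]
        if len(sub) < 2:
            break
        block = c[np.ix_(sub, sub)]
        i, j = np.unravel_index(np.argmax(block), block.shape)
        if block[i, j] <= threshold:
            break
        gi, gj = sub[i], sub[j]
        mi = c[gi, alive].mean()
        mj = c[gj, alive].mean()
        if mi > mj:
            drop = gi
        elif mj > mi:
            drop = gj
        else:
            drop = max(gi, gj, key=lambda k: cols[k])
        alive[drop] = False
    return table.loc[:, [cols[k] for k in np.where(alive)[0]]]


def univariate_filter(table: pd.DataFrame, labels,
                      alpha: float = 0.05,
                      fallback_k: int = 20) -> pd.DataFrame:
    """Keep features with a significant univariate class difference (t or
    Mann-Whitney for binary labels, Kruskal-Wallis for multiclass); on an
    empty survivor set, keep the ``fallback_k`` smallest p-values."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise DegenerateInputError("labels are constant")
    pvals = {}
    for col in table.columns:
        v = table[col].to_numpy(float)
        try:
            if len(classes) == 2:
                p = compare_groups(v, labels, feature_id=col).p_raw
            else:
                groups = [v[labels == g] for g in classes]
                p = float(kruskal(*groups).pvalue)
        except (DegenerateInputError, ValueError):
            p = 1.0
        pvals[col] = p
    ps = pd.Series(pvals)
    keep = ps.index[ps < alpha]
    if len(keep) == 0:
        keep = ps.nsmallest(fallback_k).index
    return table.loc[:, keep]


def rank_importance(table: pd.DataFrame, labels,
                    family: str = "roc", cv: CvScheme | None = None) -> list[str]:
    """Feature ranking, most important first.

    For ``family='roc'`` each feature is scored by its univariate AUC
    distance from chance |AUC - 0.5| (direction-agnostic); for
    ``family='elastic_net_logistic'`` the intrinsic importance
    |standardized coefficient| of a lightly penalized fit is used.  Ties
    break by feature id order.
    """
    labels = np.asarray(labels)
    if family == "elastic_net_logistic":
        model = fit_elastic_net_logistic(table, (labels == np.max(labels))
                                         if labels.dtype != bool else labels,
                                         alpha=0.5, lam=1e-3)
        imp = pd.Series(np.abs(model.coef), index=table.columns)
    else:
        y = labels if labels.dtype == bool else labels == np.unique(labels)[-1]
        imp = pd.Series(
            {col: abs(binary_auc(table[col].to_numpy(float), y) - 0.5)
             for col in table.columns})
    order = sorted(table.columns, key=lambda c: (-imp[c], c))
    return order


# ---------------------------------------------------------------------------
# splitting

def stratified_split(table: pd.DataFrame | None, labels,
                     test_fraction: float = 0.3, seed: int = 0):
    """Stratified hold-out split conserving class proportions.

    The test size is floor(n * test_fraction); per-class counts are the
    floors corrected upward by largest fractional remainder until the
    total matches.  Returns (train_idx, test_idx) positions, or the
    sliced (train_table, test_table, train_labels, test_labels) when a
    table is given.
    """
    labels = np.asarray(labels)
    n = len(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        raise DegenerateInputError("every class needs >= 2 members to split")
    n_test = int(np.floor(n * test_fraction))
    raw = counts * test_fraction
    base = np.floor(raw).astype(int)
    base = np.maximum(base, 1)  # keep every class represented in test
    rem = raw - np.floor(raw)
    short = n_test - base.sum()
    if short > 0:
        for k in np.argsort(-rem, kind="stable")[:short]:
            base[k] += 1
    elif short < 0:
        for k in np.argsort(rem, kind="stable"):
            if -short == 0:
                break
            if base[k] > 1:
                base[k] -= 1
                short += 1
    test_idx = []
    for cls, k in zip(classes, base):
        members = np.flatnonzero(labels == cls)
        test_idx.extend(rng.choice(members, size=k, replace=False))
    test_idx = np.sort(np.asarray(test_idx))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    if table is None:
        return train_idx, test_idx
    return (table.iloc[train_idx], table.iloc[test_idx],
            labels[train_idx], labels[test_idx])


# ---------------------------------------------------------------------------
# elastic-net logistic regression

@dataclass
class FittedElasticNet:
    spec: ModelSpec
    features: list[str]
    coef: np.ndarray
    intercept: float
    mean: np.ndarray
    scale: np.ndarray

    def _design(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.features].to_numpy(float)
        return (x - self.mean) / self.scale

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        z = self._design(table) @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, table: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(table) >= threshold).astype(int)


def fit_elastic_net_logistic(table: pd.DataFrame, labels,
                             alpha: float, lam: float,
                             tol: float = 1e-7,
                             max_iter: int = 10_000) -> FittedElasticNet:
    """Penalized logistic fit on z-scored features (training statistics)."""
    spec = ModelSpec(alpha=alpha, lam=lam)
    x = table.to_numpy(float)
    y = np.asarray(labels).astype(int)
    if not np.all(np.isfinite(x)):
        raise DegenerateInputError("non-finite values in the feature table")
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    xs = (x - mean) / scale
    n = len(y)
    if lam == 0:
        clf = LogisticRegression(C=np.inf, solver="lbfgs",
                                 tol=tol, max_iter=max_iter)
    else:
        clf = LogisticRegression(solver="saga", l1_ratio=alpha,
                                 C=1.0 / (n * lam),
                                 tol=tol, max_iter=max_iter)
    clf.fit(xs, y)
    return FittedElasticNet(spec, list(table.columns),
                            clf.coef_.ravel().copy(),
                            float(clf.intercept_[0]), mean, scale)


def evaluate(model: FittedElasticNet, table: pd.DataFrame, labels,
             threshold: float = 0.5) -> EvalReport:
    """Held-out evaluation: confusion matrix at the 0.5 probability
    threshold, sensitivity/specificity/balanced accuracy (percent, one
    decimal) and tie-corrected AUC-ROC."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("AUC undefined for single-class test labels")
    proba = model.predict_proba(table)
    pred = (proba >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    return EvalReport.from_confusion(tp, fn, fp, tn,
                                     auc=binary_auc(proba, y))


# ---------------------------------------------------------------------------
# subset search

def _cv_mean_auc(x: np.ndarray, y: np.ndarray, cv: CvScheme,
                 alphas, lambdas, n_prefixes: int) -> np.ndarray:
    """Mean CV AUC over the grid; shape (n_prefixes, n_alphas, n_lambdas).
    Lambdas are traversed descending with warm starts within a fold."""
    lam_order = np.argsort(lambdas)[::-1]
    out = np.zeros((n_prefixes, len(alphas), len(lambdas)))
    cnt = np.zeros_like(out)
    for tr, va in cv.splitter().split(x, y):
        xtr, xva = x[tr], x[va]
        ytr, yva = y[tr], y[va]
        if len(np.unique(yva)) < 2 or len(np.unique(ytr)) < 2:
            continue
        mean = xtr.mean(axis=0)
        scale = xtr.std(axis=0)
        scale[scale == 0] = 1.0
        xtr = (xtr - mean) / scale
        xva = (xva - mean) / scale
        n = len(ytr)
        for pi in range(n_prefixes):
            k = pi + 1
            for ai, a in enumerate(alphas):
                clf = LogisticRegression(solver="saga", l1_ratio=a,
                                         warm_start=True,
                                         tol=1e-3, max_iter=300)
                for li in lam_order:
                    clf.C = 1.0 / (n * lambdas[li])
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", ConvergenceWarning)
                        clf.fit(xtr[:, :k], ytr)
                    z = xva[:, :k] @ clf.coef_.ravel() + clf.intercept_[0]
                    out[pi, ai, li] += binary_auc(z, yva)
                    cnt[pi, ai, li] += 1
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, out / np.maximum(cnt, 1), np.nan)


@dataclass
class SubsetSearchResult:
    features: list[str]
    spec: ModelSpec
    cv_auc: float
    model: FittedElasticNet


def subset_search(ranking: list[str], table: pd.DataFrame, labels,
                  cv: CvScheme,
                  alphas=DEFAULT_ALPHAS, lambdas=DEFAULT_LAMBDAS,
                  max_features: int = 20) -> SubsetSearchResult:
    """Evaluate nested prefixes of the importance ranking (top-1 ... top-k)
    under repeated CV with an (alpha, lambda) grid; the winner maximizes
    mean CV AUC (ties: smaller subset, then larger lambda)."""
    if len(ranking) < 1:
        raise DegenerateInputError("no candidate features to search over")
    ranking = ranking[:max_features]
    y = np.asarray(labels).astype(int)
    x = table[ranking].to_numpy(float)
    lambdas = np.asarray(lambdas, float)
    auc = _cv_mean_auc(x, y, cv, alphas, lambdas, len(ranking))
    # ties: smaller subset, then larger lambda, then smaller alpha
    best, best_key = None, None
    for pi in range(auc.shape[0]):
        for ai in range(auc.shape[1]):
            for li in range(auc.shape[2]):
                v = auc[pi, ai, li]
                if np.isnan(v):
                    continue
                key = (-round(float(v), 12), pi, -lambdas[li], alphas[ai])
                if best_key is None or key < best_key:
                    best_key = key
                    best = (pi, ai, li)
    pi, ai, li = best
    feats = ranking[:pi + 1]
    spec = ModelSpec(alpha=float(alphas[ai]), lam=float(lambdas[li]))
    model = fit_elastic_net_logistic(table[feats], y, spec.alpha, spec.lam)
    return SubsetSearchResult(feats, spec, float(auc[pi, ai, li]), model)


# ---------------------------------------------------------------------------
# the modeling front-ends

@dataclass(frozen=True)
class PipelineConfig:
    test_fraction: float = 0.3
    cv_folds: int = 5
    cv_repeats: int = 10
    alphas: tuple = DEFAULT_ALPHAS
    lambdas: tuple = DEFAULT_LAMBDAS
    max_features: int = 20
    corr_threshold: float = 0.75
    sd_floor: float = 1e-8

    @classmethod
    def fast(cls) -> "PipelineConfig":
        """Reduced grid for simulation studies (same pipeline stages)."""
        return cls(cv_repeats=2, alphas=(0.1, 1.0),
                   lambdas=tuple(np.logspace(-4, 0, 9)), max_features=10)

    @classmethod
    def screen(cls) -> "PipelineConfig":
        """Minimal grid for replicated Monte-Carlo property checks."""
        return cls(cv_repeats=1, alphas=(0.1, 1.0),
                   lambdas=tuple(np.logspace(-4, 0, 5)), max_features=5)


class PnpClassifier:
    """Binary per-foot PNP classifier (Model object).

    Parameters
    ----------
    features : DataFrame
        Rows = feet (or participants), columns = game features.
    labels : array-like of bool/int
        Clinically evident PNP per row.
    config : PipelineConfig, optional
    """

    def __init__(self, features: pd.DataFrame, labels,
                 config: PipelineConfig | None = None):
        self.features = features
        self.labels = np.asarray(labels).astype(int)
        if len(self.features) != len(self.labels):
            raise NeuroplayError("features and labels disagree in length")
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str,
                       config: PipelineConfig | None = None) -> "PnpClassifier":
        return cls(df.drop(columns=[label_col]), df[label_col], config)

    def fit(self, seed: int = 0, split=None) -> "PnpClassifierResults":
        """Run the full pipeline; ``split`` optionally fixes the hold-out
        partition as (train_idx, test_idx) positions."""
        cfg = self.config
        x = self.features.dropna(axis=1)
        x = variance_filter(x, sd_floor=cfg.sd_floor)
        x = correlation_filter(x, threshold=cfg.corr_threshold)
        if split is None:
            xtr, xte, ytr, yte = stratified_split(x, self.labels,
                                                  cfg.test_fraction, seed)
        else:
            tr, te = split
            xtr, xte = x.iloc[tr], x.iloc[te]
            ytr, yte = self.labels[tr], self.labels[te]
        xtr_f = univariate_filter(xtr, ytr)
        ranking = rank_importance(xtr_f, ytr)
        cv = CvScheme(cfg.cv_folds, cfg.cv_repeats, seed)
        search = subset_search(ranking, xtr_f, ytr, cv,
                               alphas=cfg.alphas, lambdas=cfg.lambdas,
                               max_features=cfg.max_features)
        report = evaluate(search.model, xte, yte)
        return PnpClassifierResults(self, seed, search, report,
                                    n_train=len(ytr), n_test=len(yte),
                                    n_candidates=x.shape[1])


@dataclass
class PnpClassifierResults:
    model: PnpClassifier
    seed: int
    search: SubsetSearchResult
    report: EvalReport
    n_train: int
    n_test: int
    n_candidates: int

    @property
    def selected_features(self) -> list[str]:
        return self.search.features

    @property
    def spec(self) -> ModelSpec:
        return self.search.spec

    def summary(self) -> str:
        r = self.report
        cm = r.confusion
        lines = [
            "PNP classification results (elastic-net logistic)",
            "=" * 52,
            f"train n = {self.n_train}   test n = {self.n_test}   "
            f"candidate features = {self.n_candidates}",
            f"selected features ({len(self.selected_features)}):",
        ]
        lines += [f"  {f}" for f in self.selected_features]
        lines += [
            f"alpha = {self.spec.alpha:g}   lambda = {self.spec.lam:.6g}",
            f"cross-validated AUC = {self.search.cv_auc:.3f}",
            "held-out confusion matrix [tp fn / fp tn] = "
            f"[{cm.tp} {cm.fn} / {cm.fp} {cm.tn}]",
            f"sensitivity = {r.sensitivity}%   specificity = {r.specificity}%",
            f"balanced accuracy = {r.balanced_accuracy}%   "
            f"AUC-ROC = {r.auc_roc:.3f}",
        ]
        return "\n".join(lines)

    def to_bundle(self) -> dict:
        m = self.search.model
        return {
            "selected_features": self.selected_features,
            "alpha": self.spec.alpha, "lambda": self.spec.lam,
            "coef": m.coef.tolist(), "intercept": m.intercept,
            "standardization": {"mean": m.mean.tolist(),
                                "scale": m.scale.tolist()},
            "seed": self.seed,
            "cv_auc": self.search.cv_auc,
            "report": {
                "sensitivity": self.report.sensitivity,
                "specificity": self.report.specificity,
                "balanced_accuracy": self.report.balanced_accuracy,
                "auc_roc": self.report.auc_roc,
                "confusion": [self.report.confusion.tp,
                              self.report.confusion.fn,
                              self.report.confusion.fp,
                              self.report.confusion.tn],
            },
        }


class PhenotypeClassifier:
    """Multiclass fiber-damage phenotype model (without/SFN/LFN/mixed),
    evaluated by repeated cross-validation on all data (no hold-out)."""

    def __init__(self, features: pd.DataFrame, labels,
                 config: PipelineConfig | None = None):
        self.features = features
        self.labels = np.asarray(labels)
        self.config = config or PipelineConfig.fast()

    def fit(self, seed: int = 0) -> "PhenotypeResults":
        cfg = self.config
        x = self.features.dropna(axis=1)
        x = variance_filter(x, sd_floor=cfg.sd_floor)
        x = correlation_filter(x, threshold=cfg.corr_threshold)
        x = univariate_filter(x, self.labels)
        # rank by multiclass separation (Kruskal-Wallis p)
        pvals = {}
        classes = np.unique(self.labels)
        for col in x.columns:
            v = x[col].to_numpy(float)
            try:
                pvals[col] = float(
                    kruskal(*[v[self.labels == c] for c in classes]).pvalue)
            except ValueError:
                pvals[col] = 1.0
        ranking = sorted(x.columns, key=lambda c: (pvals[c], c))
        feats = ranking[:cfg.max_features]
        xm = x[feats].to_numpy(float)
        y = self.labels
        cv = CvScheme(cfg.cv_folds, cfg.cv_repeats, seed)
        # grid on (alpha, lambda) with repeated-CV Hand-Till AUC
        best = None
        for a in cfg.alphas:
            for lam in np.asarray(cfg.lambdas)[::10] if len(cfg.lambdas) > 20 \
                    else cfg.lambdas:
                auc = self._cv_hand_till(xm, y, cv, a, float(lam), classes)
                key = (-round(auc, 12), -lam, a)
                if best is None or key < best[0]:
                    best = (key, a, float(lam), auc)
        _, alpha, lam, auc = best
        return PhenotypeResults(self, seed, feats,
                                ModelSpec(alpha=alpha, lam=lam), float(auc))

    @staticmethod
    def _cv_hand_till(x, y, cv: CvScheme, alpha, lam, classes) -> float:
        aucs = []
        le = {c: i for i, c in enumerate(classes)}
        yi = np.asarray([le[v] for v in y])
        proba = np.zeros((len(y), len(classes)))
        seen = np.zeros(len(y), bool)
        fold_i = 0
        per_repeat = cv.folds
        for tr, va in cv.splitter().split(x, yi):
            mean = x[tr].mean(axis=0)
            scale = x[tr].std(axis=0)
            scale[scale == 0] = 1.0
            n = len(tr)
            clf = LogisticRegression(solver="saga", l1_ratio=alpha,
                                     C=1.0 / (n * lam),
                                     tol=1e-3, max_iter=300)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit((x[tr] - mean) / scale, yi[tr])
            p = clf.predict_proba((x[va] - mean) / scale)
            full = np.zeros((len(va), len(classes)))
            for j, c in enumerate(clf.classes_):
                full[:, c] = p[:, j]
            proba[va] = full
            seen[va] = True
            fold_i += 1
            if fold_i % per_repeat == 0:  # one repeat pooled
                df = pd.DataFrame(proba[seen], columns=list(classes))
                aucs.append(multiclass_auc(df, y[seen]))
                proba[:] = 0.0
                seen[:] = False
        return float(np.mean(aucs))


@dataclass
class PhenotypeResults:
    model: PhenotypeClassifier
    seed: int
    selected_features: list[str]
    spec: ModelSpec
    cv_hand_till_auc: float

    def summary(self) -> str:
        lines = [
            "Phenotype classification (multiclass, repeated-CV evaluation)",
            "=" * 60,
            f"selected features ({len(self.selected_features)}):",
        ]
        lines += [f"  {f}" for f in self.selected_features]
        lines += [
            f"alpha = {self.spec.alpha:g}   lambda = {self.spec.lam:.6g}",
            f"cross-validated Hand-Till AUC = {self.cv_hand_till_auc:.3f}",
        ]
        return "\n".join(lines)
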