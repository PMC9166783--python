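"""Baseline prediction of the treatment-response subgroup.

Five classifier families (random forest as the oblique-forest stand-in,
PLS discriminant, sparse linear discriminant via L1-penalized optimal
scoring, a small weight-decayed neural network, and an RBF support vector
machine) are trained on discovery-set baseline features - cytokine panel
(optional block), CARS, SRS and ADOS scores, sex and age - after
minority-class oversampling and point-biserial feature selection, and
scored on the held-out validation set. Performance is summarized as the
mean AUC across the five families; pairs of models (with vs without
cytokines) are compared with a bootstrap percentile CI of the AUC
difference over test subjects.

Leak protocol: feature selection, oversampling, scaling and model fitting
all see discovery rows only; every fit is recorded in an audit trail that
can be checked against the test-set subject ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import Lasso
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import cohort as ch

__all__ = [
    "FAMILIES", "make_labels", "oversample", "feature_select",
    "baseline_features", "train_eval", "mean_auc", "bootstrap_auc_diff",
    "PredictionResult", "compare_feature_sets",
]

FAMILIES = ("ORF", "PLS-DA", "sLDA", "NN", "SVM")
DEMOGRAPHIC_COLS = ("sex", "age_months")
LABEL_MODES = ("best", "least", "cutoff2.5", "cutoff2")


@dataclass
class PredictionResult:
    labeling: str
    family: str
    include_cytokines: bool
    auc: float
    roc_points: pd.DataFrame
    scores: np.ndarray
    test_labels: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc outside [0, 1]")


def make_labels(cohort: pd.DataFrame, mode: str,
                cluster_labels: Optional[pd.Series] = None) -> pd.Series:
    """Binary responder labels per subject.

    Cluster modes ("best" / "least") take the named subgroup as positive;
    cutoff modes use the CARS total improvement with a strict inequality
    (a change of exactly 2.5 is a non-responder under "cutoff2.5").
    """
    if mode not in LABEL_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {LABEL_MODES}")
    if mode in ("best", "least"):
        if cluster_labels is None:
            raise ValueError("cluster modes need cluster_labels")
        return (pd.Series(cluster_labels) == mode).astype(int)
    cutoff = 2.5 if mode == "cutoff2.5" else 2.0
    delta = ch.cars_change(cohort, include_total=True)["CARS_total"]
    return (delta > cutoff).astype(int)


def oversample(X: pd.DataFrame, y: pd.Series,
               seed: Optional[int] = None) -> Tuple[pd.DataFrame, pd.Series]:
    """Duplicate minority-class rows (sampling with replacement) until the
    classes balance. Deterministic given seed; no-op when already balanced."""
    y = pd.Series(y).reset_index(drop=True)
    X = pd.DataFrame(X).reset_index(drop=True)
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("oversample needs both classes present")
    minority = counts.idxmin()
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return X, y
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero(y == minority)
    extra = rng.choice(pool, size=deficit, replace=True)
    idx = np.concatenate([np.arange(len(y)), extra])
    return X.iloc[idx].reset_index(drop=True), y.iloc[idx].reset_index(drop=True)


def feature_select(X: pd.DataFrame, y: pd.Series, m: int = 10) -> List[str]:
    """Top-m columns by absolute point-biserial correlation with the label,
    computed on training data only; demographic columns always retained."""
    if m < 1:
        raise ValueError("m must be >= 1")
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    candidates = [c for c in X.columns if c not in DEMOGRAPHIC_COLS]
    if m > len(candidates):
        m = len(candidates)
    scores = {}
    for c in candidates:
        col = X[c].to_numpy(dtype=float)
        if np.std(col) == 0 or np.std(y) == 0:
            scores[c] = 0.0
        else:
            scores[c] = abs(float(np.corrcoef(col, y)[0, 1]))
    top = sorted(candidates, key=lambda c: (-scores[c], c))[:m]
    keep = [c for c in X.columns if c in set(top) or c in DEMOGRAPHIC_COLS]
    return keep


class _SparseLDA(BaseEstimator):
    """Two-class sparse discriminant by L1-penalized optimal scoring.

    For two classes the LDA direction is proportional to the least-squares
    coefficient on the centered class indicator, so an L1 penalty on that
    regression yields a sparse discriminant axis.
    """

    def __init__(self, alpha: float = 0.02):
        self.alpha = alpha

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        target = y - y.mean()
        self.model_ = Lasso(alpha=self.alpha, max_iter=20000).fit(X, target)
        return self

    def decision_function(self, X):
        return self.model_.predict(X)


class _PLSDA(BaseEstimator):
    """PLS regression on the binary target; at most 3 latent components."""

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, X, y):
        ncomp = min(self.n_components, np.asarray(X).shape[1], len(y) - 1)
        self.model_ = PLSRegression(n_components=ncomp, scale=False)
        self.model_.fit(X, np.asarray(y, dtype=float))
        return self

    def decision_function(self, X):
        return self.model_.predict(X).ravel()


def _build_family(family: str, seed: Optional[int]):
    if family == "ORF":
        # axis-aligned random forest stands in for the oblique forest
        warnings.warn("ORF family uses an axis-aligned random forest as the "
                      "oblique-forest stand-in", RuntimeWarning, stacklevel=3)
        return RandomForestClassifier(n_estimators=200, min_samples_leaf=2,
                                      random_state=seed)
    if family == "PLS-DA":
        return _PLSDA()
    if family == "sLDA":
        return _SparseLDA()
    if family == "NN":
        return MLPClassifier(hidden_layer_sizes=(8,), alpha=1e-2,
                             solver="lbfgs", max_iter=2000, random_state=seed)
    if family == "SVM":
        return SVC(kernel="rbf", gamma="scale", C=1.0)
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


def _scores(model, X) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def baseline_features(cohort: pd.DataFrame, subjects: Sequence[str],
                      analytes: Sequence[str],
                      include_cytokines: bool = True) -> pd.DataFrame:
    """Baseline-only feature matrix (no follow-up-derived columns).

    Columns: optional cytokine block + CARS total and subscales + SRS
    total and subscales + ADOS subscales + sex (0/1) + age in months.
    """
    cols = (ch.CARS_SUBSCALES + ["CARS_total"] + ch.SRS_SUBSCALES
            + ["SRS_total"] + ch.ADOS_SUBSCALES)
    if include_cytokines:
        cols = list(analytes) + cols
    base = ch.baseline_matrix(cohort, cols).loc[list(subjects)]
    info = ch.subject_info(cohort).loc[list(subjects)]
    base["sex"] = (info["sex"] == "F").astype(float)
    base["age_months"] = info["age_months"].astype(float)
    return base


def train_eval(family: str, train_X: pd.DataFrame, train_y: pd.Series,
               test_X: pd.DataFrame, test_y: pd.Series,
               seed: Optional[int] = None, m_features: int = 10,
               labeling: str = "", include_cytokines: bool = True,
               audit: Optional[list] = None) -> PredictionResult:
    """Fit one family on oversampled, feature-selected training data and
    evaluate ROC/AUC on the held-out test subjects."""
    test_y = np.asarray(test_y, dtype=int)
    if len(np.unique(test_y)) < 2:
        raise ValueError("test set has a single class: AUC undefined")
    kept = feature_select(train_X, train_y, m=m_features)
    Xb, yb = oversample(train_X[kept], train_y, seed=seed)
    scaler = StandardScaler().fit(Xb)
    if audit is not None:
        audit.append({"stage": f"fit:{family}", "labeling": labeling,
                      "train_index": list(pd.DataFrame(train_X).index),
                      "features": kept})
    model = _build_family(family, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny-n convergence chatter
        model.fit(scaler.transform(Xb), np.asarray(yb, dtype=int))
    s = _scores(model, scaler.transform(test_X[kept]))
    fpr, tpr, thr = roc_curve(test_y, s)
    auc = float(roc_auc_score(test_y, s))
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return PredictionResult(labeling=labeling, family=family,
                            include_cytokines=include_cytokines, auc=auc,
                            roc_points=roc, scores=s, test_labels=test_y)


def mean_auc(results: Sequence[PredictionResult]) -> float:
    """Arithmetic mean AUC over exactly the five classifier families."""
    fams = sorted(r.family for r in results)
    if fams != sorted(FAMILIES):
        raise ValueError(f"expected one result per family {FAMILIES}, got {fams}")
    keys = {(r.labeling, r.include_cytokines) for r in results}
    if len(keys) != 1:
        raise ValueError("results mix labelings or feature sets")
    return float(np.mean([r.auc for r in results]))


def _safe_auc(y, s) -> Optional[float]:
    if len(np.unique(y)) < 2:
        return None
    return float(roc_auc_score(y, s))


def bootstrap_auc_diff(scores_a: np.ndarray, scores_b: np.ndarray,
                       labels: np.ndarray, n_boot: int = 100,
                       seed: Optional[int] = None,
                       ci: float = 0.95) -> Tuple[float, float]:
    """Percentile bootstrap CI of AUC(model a) - AUC(model b).

    Test subjects are resampled with replacement; replicates that draw a
    single class are redrawn. ``scores_a`` / ``scores_b`` may be 2-D
    (n_models x n_subjects), in which case the difference of mean AUCs
    across models is bootstrapped.
    """
    if n_boot < 20:
        raise ValueError("need at least 20 bootstrap replicates")
    a = np.atleast_2d(np.asarray(scores_a, dtype=float))
    b = np.atleast_2d(np.asarray(scores_b, dtype=float))
    y = np.asarray(labels, dtype=int)
    n = y.size
    if a.shape[1] != n or b.shape[1] != n:
        raise ValueError("scores must cover the same test subjects")
    rng = np.random.default_rng(seed)
    diffs = []
    guard = 0
    while len(diffs) < n_boot and guard < 100 * n_boot:
        guard += 1
        idx = rng.integers(0, n, size=n)
        ys = y[idx]
        aucs_a = [_safe_auc(ys, row[idx]) for row in a]
        aucs_b = [_safe_auc(ys, row[idx]) for row in b]
        if any(v is None for v in aucs_a + aucs_b):
            continue
        diffs.append(float(np.mean(aucs_a) - np.mean(aucs_b)))
    if len(diffs) < n_boot:
        raise RuntimeError("could not draw two-class bootstrap replicates")
    lo, hi = np.percentile(diffs, [50 * (1 - ci), 100 - 50 * (1 - ci)])
    return float(lo), float(hi)


def compare_feature_sets(cohort: pd.DataFrame, labels: pd.Series,
                         analytes: Sequence[str], train_ids: Sequence[str],
                         test_ids: Sequence[str], labeling: str,
                         seed: Optional[int] = None, m_features: int = 10,
                         n_boot: int = 100,
                         baseline_cytokines: Optional[pd.DataFrame] = None) -> dict:
    """Full with- vs without-cytokines contrast for one labeling.

    Trains all five families on the training subjects under both feature
    sets, reports each AUC, the two mean AUCs and the bootstrap CI of
    their difference, plus the leak-audit trail.
    ``baseline_cytokines`` optionally supplies preprocessed baseline
    concentrations (indexed by subject) to use instead of raw values.
    """
    labels = pd.Series(labels)
    audit: list = []
    out: Dict[str, object] = {"labeling": labeling, "results": {}, "audit": audit}
    scores = {}
    for include in (True, False):
        feats_tr = baseline_features(cohort, train_ids, analytes, include)
        feats_te = baseline_features(cohort, test_ids, analytes, include)
        if include and baseline_cytokines is not None:
            feats_tr[list(analytes)] = baseline_cytokines.loc[list(train_ids), analytes]
            feats_te[list(analytes)] = baseline_cytokines.loc[list(test_ids), analytes]
        res = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for fam in FAMILIES:
                res.append(train_eval(fam, feats_tr, labels.loc[list(train_ids)],
                                      feats_te, labels.loc[list(test_ids)],
                                      seed=seed, m_features=m_features,
                                      labeling=labeling, include_cytokines=include,
                                      audit=audit))
        out["results"][include] = res
        scores[include] = np.vstack([r.scores for r in res])
    out["mean_auc_with"] = mean_auc(out["results"][True])
    out["mean_auc_without"] = mean_auc(out["results"][False])
    y_test = out["results"][True][0].test_labels
    out["auc_diff_ci"] = bootstrap_auc_diff(scores[True], scores[False],
                                            y_test, n_boot=n_boot, seed=seed)
    out["test_index"] = list(test_ids)
    return out


def audit_no_leak(audit: Sequence[dict], test_ids: Sequence[str]) -> bool:
    """True when no fitting call saw any test subject."""
    test = set(test_ids)
    for entry in audit:
        if test & set(entry["train_index"]):
            return False
    return True
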