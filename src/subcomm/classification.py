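"""HC/AD classification from subcortical network features.

The framework nests a two-stage feature selection inside repeated stratified
k-fold cross-validation, so no selection step ever sees held-out data:

1. *Occurrence mask* — from the training fold's HC subjects only, the
   frequency e_ij with which each subcortical edge is nonzero is computed;
   edges occurring more often than chance (one-sided binomial test against
   p0 = 0.5, level alpha) are kept.  The same index mask is applied to
   whatever feature set is being classified (weights or communicability).
2. *SVM-RFE* — a linear maximum-margin classifier is fit on the training
   fold; the feature with the smallest squared weight is removed; repeat
   until none remain.  Rank is the reverse elimination order and the top
   ``rfe_keep`` features are retained.

A random forest (B trees, majority vote) is then trained on the selected
features and evaluated on the held-out fold.  AD is the positive class
(sensitivity = AD recall); AUC uses the forest's vote fractions as scores.
Metrics are averaged (mean +/- sd) over all repeat x fold evaluations, and
the whole procedure is reproducible from a single seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .connectome_io import Cohort, ConnectivityMatrix, extract_subnetwork, normalize_max
from .group_stats import PAIR_TAGS, pair_feature_ids, pair_vector, subject_pair_matrix


def binomial_threshold(n_hc: int, alpha: float) -> float:
    """Smallest occurrence frequency k/n that beats chance at level alpha.

    One-sided exact binomial test of k successes in ``n_hc`` trials against
    null success probability 0.5: returns k*/n_hc for the smallest k* with
    P(X >= k*) <= alpha.  Raises if even k* = n_hc is not significant.
    """
    if n_hc < 1:
        raise ValueError("n_hc must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    k = np.arange(n_hc + 1)
    tail = binom.sf(k - 1, n_hc, 0.5)  # P(X >= k)
    passing = np.flatnonzero(tail <= alpha)
    if passing.size == 0:
        raise ValueError(
            f"no occurrence count reaches significance for n_hc={n_hc}, alpha={alpha}"
        )
    return float(passing[0] / n_hc)


@dataclass
class OccurrenceMask:
    """Binary edge-selection mask from HC edge-occurrence frequencies."""

    frequency: np.ndarray  # e_ij in [0, 1], symmetric
    mask: np.ndarray  # boolean, frequency >= threshold
    threshold: float

    def feature_indices(self) -> np.ndarray:
        """Indices of masked-in features in the fixed pair (triu) order."""
        n = self.mask.shape[0]
        return np.flatnonzero(self.mask[np.triu_indices(n)])

    @property
    def n_selected(self) -> int:
        return int(self.feature_indices().size)


def build_mask(
    hc_weight_matrices: list[np.ndarray],
    alpha: float = 0.01,
    threshold: float | None = None,
) -> OccurrenceMask:
    """Occurrence mask from the training set's HC weight matrices.

    ``frequency[i, j]`` is the fraction of HC subjects with w_ij > 0.  The
    threshold defaults to the binomial-test value for the given HC count;
    pass ``threshold`` to override (e.g. to reproduce a previously reported
    study-specific cut).
    """
    if not hc_weight_matrices:
        raise ValueError("mask requires at least one HC training subject")
    stack = np.stack([np.asarray(m, dtype=float) for m in hc_weight_matrices])
    frequency = (stack > 0).mean(axis=0)
    if threshold is None:
        threshold = binomial_threshold(stack.shape[0], alpha)
    return OccurrenceMask(frequency, frequency >= threshold, float(threshold))


def apply_mask(feature_matrix: np.ndarray, mask: OccurrenceMask) -> np.ndarray:
    """Masked-in upper-triangle (diagonal included) entries, fixed order."""
    feature_matrix = np.asarray(feature_matrix, dtype=float)
    if feature_matrix.shape != mask.mask.shape:
        raise ValueError(
            f"feature matrix shape {feature_matrix.shape} does not match mask "
            f"{mask.mask.shape}"
        )
    return pair_vector(feature_matrix)[mask.feature_indices()]


def rfe_rank(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> list[int]:
    """SVM-based recursive feature elimination ranking (best feature first).

    Each iteration fits a linear SVM on the remaining features and removes
    the one with the smallest squared weight; near-ties (within relative
    1e-9) are broken by eliminating the lowest column index first.  The
    returned list is the reverse elimination order: position 0 is the last
    surviving (most important) feature.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with at least one feature")
    if np.unique(y).size < 2:
        raise ValueError("RFE requires both classes in the training data")
    remaining = list(range(X.shape[1]))
    eliminated: list[int] = []
    while len(remaining) > 1:
        svc = SVC(kernel="linear", C=C)
        svc.fit(X[:, remaining], y)
        w2 = np.ravel(np.asarray(svc.coef_)) ** 2
        lo = w2.min()
        ties = np.flatnonzero(w2 <= lo + 1e-9 * max(lo, 1e-30))
        drop = int(ties[0])
        eliminated.append(remaining.pop(drop))
    eliminated.extend(remaining)
    return eliminated[::-1]


@dataclass
class ClassifierConfig:
    """Knobs of the classification framework (defaults = study settings)."""

    n_trees: int = 500
    rfe_keep: int = 20
    cv_repeats: int = 50
    cv_folds: int = 10
    binomial_alpha: float = 0.01
    mask_threshold: float | None = None  # override the binomial-test threshold
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_trees", "rfe_keep", "cv_repeats", "cv_folds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None
) -> dict[str, float]:
    """Accuracy, sensitivity (AD recall), specificity (HC recall) and AUC.

    ``y_true``/``y_pred`` are boolean arrays with True = AD; ``scores`` are
    continuous AD scores for the ROC curve (trapezoidal AUC).
    """
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    tp = int(np.sum(y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    out = {
        "accuracy": (tp + tn) / max(tp + tn + fp + fn, 1),
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
    }
    if scores is not None:
        out["auc"] = float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))
    return out


def select_features(
    hc_train_weights: list[np.ndarray],
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: ClassifierConfig,
) -> tuple[OccurrenceMask, np.ndarray]:
    """Nested per-fold selection: occurrence mask, then SVM-RFE top-k.

    ``X_train`` holds the full 78-feature pair vectors of the *training*
    subjects only; returns the mask and the selected indices into the full
    pair-feature frame.  Depends on training data alone, so held-out
    subjects cannot influence it.
    """
    mask = build_mask(
        hc_train_weights, alpha=config.binomial_alpha, threshold=config.mask_threshold
    )
    cols = mask.feature_indices()
    if cols.size == 0:
        raise ValueError("occurrence mask selected no features")
    ranking = rfe_rank(X_train[:, cols], y_train, C=config.svm_c)
    keep = config.rfe_keep
    if keep > len(ranking):
        warnings.warn(
            f"rfe_keep={keep} exceeds {len(ranking)} masked features; clipping",
            stacklevel=2,
        )
        keep = len(ranking)
    return mask, cols[ranking[:keep]]


@dataclass
class CVReport:
    """Per-fold and aggregated cross-validation metrics for one feature set."""

    tag: str
    folds: pd.DataFrame  # repeat, fold, accuracy, auc, sensitivity, specificity, ...
    config: ClassifierConfig
    selected_features: list[list[str]] = field(default_factory=list)

    METRICS = ("accuracy", "auc", "sensitivity", "specificity")

    @property
    def aggregate(self) -> pd.DataFrame:
        return self.folds[list(self.METRICS)].agg(["mean", "std"])

    def summary(self) -> dict[str, float]:
        agg = self.aggregate
        out: dict[str, float] = {}
        for m in self.METRICS:
            out[f"{m}_mean"] = float(agg.loc["mean", m])
            out[f"{m}_sd"] = float(agg.loc["std", m])
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tag": self.tag,
            "config": asdict(self.config),
            "aggregate": self.summary(),
            "folds": self.folds.to_dict(orient="records"),
            "selected_features": self.selected_features,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _subcortical_weight_blocks(cohort: Cohort) -> list[np.ndarray]:
    """Normalized 12x12 weight blocks, the basis of every occurrence mask."""
    return [
        extract_subnetwork(normalize_max(s.matrix)).weights for s in cohort.subjects
    ]


def run_cv(cohort: Cohort, tag: str, config: ClassifierConfig) -> CVReport:
    """Repeated stratified k-fold CV of the full nested pipeline.

    Fold splits and all per-fold random states derive from ``config.seed``
    only (not from ``tag``), so reports for different feature sets share
    identical partitions and differences reflect the features alone.
    """
    if tag not in PAIR_TAGS:
        raise ValueError(f"classification operates on pair tags {PAIR_TAGS}")
    cohort.require_two_groups()
    y = cohort.labels == "AD"
    counts = {lab: int(np.sum(cohort.labels == lab)) for lab in ("HC", "AD")}
    if min(counts.values()) < config.cv_folds:
        raise ValueError(
            f"each class needs >= cv_folds={config.cv_folds} members, got {counts}"
        )
    weight_blocks = _subcortical_weight_blocks(cohort)
    X_full = np.stack(
        [pair_vector(subject_pair_matrix(s.matrix, tag)) for s in cohort.subjects]
    )
    feature_names = np.array(pair_feature_ids(cohort.atlas))

    ss = np.random.SeedSequence(config.seed)
    split_states = ss.generate_state(config.cv_repeats) % (2**31)
    rf_states = ss.generate_state(config.cv_repeats * config.cv_folds + 1)[1:] % (2**31)

    records = []
    selected: list[list[str]] = []
    for rep in range(config.cv_repeats):
        skf = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=int(split_states[rep])
        )
        for fold, (train, test) in enumerate(skf.split(X_full, y)):
            hc_train = [weight_blocks[i] for i in train if not y[i]]
            mask, kept = select_features(
                hc_train, X_full[train], y[train], config
            )
            rf = RandomForestClassifier(
                n_estimators=config.n_trees,
                random_state=int(rf_states[rep * config.cv_folds + fold]),
                n_jobs=1,
            )
            rf.fit(X_full[np.ix_(train, kept)], y[train])
            ad_col = int(np.flatnonzero(rf.classes_)[0])
            scores = rf.predict_proba(X_full[np.ix_(test, kept)])[:, ad_col]
            y_pred = rf.predict(X_full[np.ix_(test, kept)])
            metrics = compute_metrics(y[test], y_pred, scores)
            records.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    **metrics,
                    "n_masked": mask.n_selected,
                    "n_selected": int(kept.size),
                }
            )
            selected.append(feature_names[kept].tolist())
    folds = pd.DataFrame.from_records(records)
    return CVReport(tag=tag, folds=folds, config=config, selected_features=selected)


def compare_feature_sets(
    cohort: Cohort,
    config: ClassifierConfig,
    tags: tuple[str, ...] = PAIR_TAGS,
) -> dict[str, CVReport]:
    """CV reports for several feature sets on identical CV partitions."""
    return {tag: run_cv(cohort, tag, config) for tag in tags}


def comparison_table(reports: dict[str, CVReport]) -> pd.DataFrame:
    """Aggregate metric table (one row per feature set)."""
    rows = []
    for tag, report in reports.items():
        rows.append({"tag": tag, **report.summary()})
    return pd.DataFrame(rows)
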