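"""Response classifier: SMOTE-balanced random forest with wrapper selection.

The response-prediction problem is a small-cohort binary classification
(pathologic complete response vs residual tumor) over 15 candidate
predictors.  The classifier is a random forest ("parRF": the parallelised
forest is statistically identical to a serial one given fixed seeds), with

* SMOTE oversampling of the minority class, applied inside each training
  fold only so that no synthetic point ever reaches a test fold;
* sequential backward feature elimination wrapped around cross-validated AUC;
* repeated stratified k-fold cross-validation with pooled out-of-fold
  probabilities, a 0.5 probability cutoff, and Wilson confidence intervals
  on sensitivity/specificity computed over the pooled classification events.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.proportion import proportion_confint

from .errors import DcebrixError
from .stats import roc_auc

__all__ = [
    "PREDICTOR_COLUMNS",
    "CATEGORICAL_PREDICTORS",
    "ModelResult",
    "smote_oversample",
    "crossvalidate_parrf",
    "backward_select",
    "classify",
]

# the 15 candidate predictors: kinetic triple, derived perfusion features,
# conventional imaging features, HPV status and age
PREDICTOR_COLUMNS = [
    "A", "kep", "kel", "TTP", "PE", "AUC", "wash_in", "wash_out",
    "T1_raw", "T1_ratio", "STIR_raw", "STIR_ratio", "ADC", "hpv_p16", "age",
]
CATEGORICAL_PREDICTORS = {"hpv_p16"}

POSITIVE_LABEL = "pCR"  # "response" is the positive class throughout


@dataclass
class ModelResult:
    selected_features: list[str]
    probabilities: np.ndarray  # pooled out-of-fold P(response), one per event
    event_labels: np.ndarray  # true label per pooled event (bool, response)
    patient_probabilities: pd.Series  # mean out-of-fold probability per patient
    auc_roc: float
    auc_ci: tuple[float, float]
    sensitivity: float  # percent
    sensitivity_ci: tuple[float, float]
    specificity: float  # percent
    specificity_ci: tuple[float, float]
    cutoff: float = 0.5
    n_folds: int = 10
    n_repeats: int = 10
    trace: list = field(default_factory=list)


def smote_oversample(
    X: pd.DataFrame,
    y,
    seed: int,
    k_neighbors: int = 5,
    categorical=CATEGORICAL_PREDICTORS,
):
    """Balance classes by interpolating between minority-class neighbors.

    Each synthetic row lies on the segment between a minority seed row and
    one of its ``k`` nearest minority neighbors (Euclidean over continuous
    columns); categorical columns copy the seed row's value.  Original rows
    are preserved unchanged and come first in the returned table.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise DcebrixError("SMOTE needs two classes")
    minority = classes[np.argmin(counts)]
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return X.copy(), y.copy()

    minority_rows = X[y == minority].reset_index(drop=True)
    if len(minority_rows) < 2:
        raise DcebrixError("SMOTE needs at least 2 minority samples")
    k = min(k_neighbors, len(minority_rows) - 1)

    cont_cols = [c for c in X.columns if c not in categorical]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority_rows[cont_cols])
    _, idx = nn.kneighbors(minority_rows[cont_cols])

    rng = np.random.default_rng(seed)
    synth = []
    for _ in range(n_needed):
        i = int(rng.integers(len(minority_rows)))
        j = int(idx[i][1 + rng.integers(k)])  # skip self at position 0
        gap = rng.random()
        row = minority_rows.iloc[i].copy()
        base = minority_rows.iloc[i][cont_cols].to_numpy(dtype=float)
        neigh = minority_rows.iloc[j][cont_cols].to_numpy(dtype=float)
        row[cont_cols] = base + gap * (neigh - base)
        synth.append(row)

    X_out = pd.concat([X, pd.DataFrame(synth)], ignore_index=True)
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


def _make_forest(n_trees: int, mtry, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        random_state=seed,
        n_jobs=1,
    )


def _tune_mtry(X, y, candidates, n_trees, seed) -> int:
    """Pick max_features by inner 3-fold CV on AUC (the parRF tunable)."""
    candidates = [m for m in candidates if m <= X.shape[1]]
    if len(candidates) <= 1:
        return candidates[0] if candidates else X.shape[1]
    inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    best = None
    for m in candidates:
        probs = np.zeros(len(y))
        for tr, te in inner.split(X, y):
            clf = _make_forest(n_trees, m, seed)
            clf.fit(X.iloc[tr], y[tr])
            pos = list(clf.classes_).index(True)
            probs[te] = clf.predict_proba(X.iloc[te])[:, pos]
        auc, _ = roc_auc(probs, y)
        if best is None or auc > best[0]:
            best = (auc, m)
    return best[1]


def classify(probabilities, labels, cutoff: float = 0.5):
    """Dichotomize probabilities at ``cutoff`` and score the result.

    Predictions >= cutoff count as response.  Returns a dict with
    sensitivity and specificity in percent plus 95% Wilson intervals over
    the supplied classification events.
    """
    p = np.asarray(probabilities, dtype=float)
    truth = np.asarray(labels).astype(bool)
    pred = p >= cutoff
    tp = int(np.sum(pred & truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))

    def _rate(successes, total):
        if total == 0:
            return float("nan"), (float("nan"), float("nan"))
        lo, hi = proportion_confint(successes, total, method="wilson")
        return 100.0 * successes / total, (100.0 * lo, 100.0 * hi)

    sens, sens_ci = _rate(tp, tp + fn)
    spec, spec_ci = _rate(tn, tn + fp)
    return {
        "predictions": pred,
        "confusion": {"TP": tp, "FN": fn, "TN": tn, "FP": fp},
        "sensitivity": sens,
        "sensitivity_ci": sens_ci,
        "specificity": spec,
        "specificity_ci": spec_ci,
    }


def crossvalidate_parrf(
    table: pd.DataFrame,
    labels,
    features=None,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    mtry="tune",
    mtry_candidates=(2, 4, 8),
    cutoff: float = 0.5,
    smote_in_fold: bool = True,
    smote_k: int = 5,
) -> ModelResult:
    """Repeated stratified CV of the SMOTE-balanced forest.

    Out-of-fold probabilities are pooled over all repeats x folds
    (n_repeats * n_patients classification events); AUC with DeLong CI and
    sensitivity/specificity at the probability cutoff are computed on the
    pooled events.  ``smote_in_fold=False`` reproduces the optimistic
    ordering in which oversampling precedes the split (leaks information;
    for comparison only).
    """
    if features is None:
        features = [c for c in table.columns if c in PREDICTOR_COLUMNS]
    X_all = table[features].reset_index(drop=True)
    y_all = (np.asarray(labels) == POSITIVE_LABEL)

    if smote_in_fold:
        X_cv, y_cv = X_all, y_all
    else:
        X_cv, y_cv = smote_oversample(X_all, y_all, seed=seed, k_neighbors=smote_k)

    splitter = RepeatedStratifiedKFold(
        n_splits=n_folds, n_repeats=n_repeats, random_state=seed
    )
    with warnings.catch_warnings():
        # folds are deliberately stratified with a class smaller than n_folds
        warnings.filterwarnings("ignore", message="The least populated class")
        splits = list(splitter.split(X_cv, y_cv))
    probs, truths, patient_idx = [], [], []
    for fold_i, (tr, te) in enumerate(splits):
        X_tr, y_tr = X_cv.iloc[tr], y_cv[tr]
        if y_tr.all() or not y_tr.any():
            continue  # degenerate training fold (tiny cohorts); skip, logged upstream
        if smote_in_fold:
            X_tr, y_tr = smote_oversample(
                X_tr.reset_index(drop=True), y_tr, seed=seed + fold_i,
                k_neighbors=smote_k,
            )
        m = (
            _tune_mtry(X_tr, y_tr, mtry_candidates, n_trees, seed + fold_i)
            if mtry == "tune"
            else min(int(mtry), X_tr.shape[1])
        )
        clf = _make_forest(n_trees, m, seed + fold_i)
        clf.fit(X_tr, y_tr)
        pos = list(clf.classes_).index(True)
        probs.append(clf.predict_proba(X_cv.iloc[te])[:, pos])
        truths.append(y_cv[te])
        patient_idx.append(te)

    probs = np.concatenate(probs)
    truths = np.concatenate(truths)
    patient_idx = np.concatenate(patient_idx)

    auc, auc_ci = roc_auc(probs, truths)
    scored = classify(probs, truths, cutoff=cutoff)
    per_patient = (
        pd.Series(probs, index=patient_idx).groupby(level=0).mean()
    )
    return ModelResult(
        selected_features=list(features),
        probabilities=probs,
        event_labels=truths,
        patient_probabilities=per_patient,
        auc_roc=auc,
        auc_ci=auc_ci,
        sensitivity=scored["sensitivity"],
        sensitivity_ci=scored["sensitivity_ci"],
        specificity=scored["specificity"],
        specificity_ci=scored["specificity_ci"],
        cutoff=cutoff,
        n_folds=n_folds,
        n_repeats=n_repeats,
    )


def backward_select(
    table: pd.DataFrame,
    labels,
    features=None,
    seed: int = 0,
    min_features: int = 1,
    **cv_kwargs,
):
    """Sequential backward elimination maximizing cross-validated AUC.

    Starting from the full candidate set, repeatedly drop the single feature
    whose removal gives the largest pooled CV AUC; stop when no removal
    improves on the current set (or ``min_features`` is reached).  Returns
    (selected_features, trace) where the trace records every evaluated step.
    """
    if features is None:
        features = [c for c in table.columns if c in PREDICTOR_COLUMNS]
    if len(features) < 2:
        raise DcebrixError("backward selection needs at least 2 features")

    current = list(features)
    current_auc = crossvalidate_parrf(
        table, labels, features=current, seed=seed, **cv_kwargs
    ).auc_roc
    trace = [{"features": list(current), "auc": current_auc, "removed": None}]

    while len(current) > min_features:
        best_candidate = None
        for f in current:
            reduced = [c for c in current if c != f]
            auc = crossvalidate_parrf(
                table, labels, features=reduced, seed=seed, **cv_kwargs
            ).auc_roc
            if best_candidate is None or auc > best_candidate[0]:
                best_candidate = (auc, f, reduced)
        if best_candidate[0] > current_auc:
            current_auc, removed, current = best_candidate
            trace.append(
                {"features": list(current), "auc": current_auc, "removed": removed}
            )
        else:
            break
    return current, trace
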