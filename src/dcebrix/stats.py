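"""Group-comparison and prognostic-performance statistics.

Covers the cohort-level inference used in the analysis: two-sample rank tests
(Mann-Whitney U, exact for small tie-free samples; Kruskal-Wallis for >= 2
groups), ROC AUC with DeLong confidence intervals and the DeLong test for
correlated AUCs, and the two-way absolute-agreement single-measure intraclass
correlation with the Koo & Li interpretation bands.

ROC AUC is computed from the rank (Mann-Whitney) statistic with ties counted
one half, which equals the probability that a random positive scores above a
random negative.  The DeLong machinery is implemented from structural
components (placement values); no shipped dependency provides it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, UndefinedROCError

__all__ = [
    "rank_test",
    "kruskal_wallis",
    "roc_auc",
    "delong_compare",
    "icc_intrarater",
    "GroupComparison",
    "group_comparison_table",
]


def rank_test(values_a, values_b) -> float:
    """Two-sided Mann-Whitney U p-value for two independent samples.

    Uses the exact null distribution when both samples have <= 25
    observations and there are no ties; otherwise the normal approximation
    with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (no_ties and a.size <= 25 and b.size <= 25) else "asymptotic"
    return float(
        sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def kruskal_wallis(*groups) -> float:
    """Kruskal-Wallis p-value across two or more independent groups."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InsufficientDataError("need >= 2 groups with >= 2 observations")
    return float(sps.kruskal(*groups).pvalue)


def _placements(pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    # pairwise comparison with ties counted 1/2
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def roc_auc(scores, labels, alpha: float = 0.05):
    """AUC of the ROC curve with a DeLong (1 - alpha) confidence interval.

    ``labels`` are truthy for the positive class.  Returns (auc, (lo, hi)),
    the CI clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedROCError("both classes must be present")
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    var = 0.0
    if pos.size > 1:
        var += np.var(v10, ddof=1) / pos.size
    if neg.size > 1:
        var += np.var(v01, ddof=1) / neg.size
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var)
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def delong_compare(scores_1, scores_2, labels) -> float:
    """DeLong two-sided p-value for equality of two correlated AUCs.

    The two score vectors must be paired (same subjects, same labels).
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if s1.size != s2.size or s1.size != labels.size:
        raise ValueError("scores_1, scores_2 and labels must be paired")
    if labels.all() or not labels.any():
        raise UndefinedROCError("both classes must be present")

    m, n = int(labels.sum()), int((~labels).sum())
    V10 = np.empty((2, m))
    V01 = np.empty((2, n))
    aucs = np.empty(2)
    for k, s in enumerate((s1, s2)):
        v10, v01 = _placements(s[labels], s[~labels])
        V10[k], V01[k] = v10, v01
        aucs[k] = v10.mean()

    S10 = np.cov(V10) if m > 1 else np.zeros((2, 2))
    S01 = np.cov(V01) if n > 1 else np.zeros((2, 2))
    S = S10 / m + S01 / n
    var_diff = S[0, 0] + S[1, 1] - 2.0 * S[0, 1]
    if var_diff <= 0:
        return 1.0
    z = (aucs[0] - aucs[1]) / np.sqrt(var_diff)
    return float(2.0 * sps.norm.sf(abs(z)))


_ICC_BANDS = [(0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (np.inf, "excellent")]


def _icc_band(value: float) -> str:
    for upper, name in _ICC_BANDS:
        if value < upper:
            return name
    return "excellent"


def icc_intrarater(ratings):
    """Two-way absolute-agreement single-measure ICC for repeated ratings.

    ``ratings`` is an (n_subjects, 2) array-like: the original and the repeat
    measurement.  Returns (icc, (lo, hi), interpretation), where the
    interpretation is the range of Koo & Li bands the 95% CI spans
    (e.g. ``"moderate to excellent"``).
    """
    import pingouin as pg

    arr = np.asarray(ratings, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("ratings must be an (n, 2) table")
    if arr.shape[0] < 5:
        raise InsufficientDataError("need at least 5 subjects")
    if np.allclose(arr.mean(axis=1), arr.mean()):
        raise ValueError("zero between-subject variance: ICC degenerate")
    if np.allclose(arr[:, 0], arr[:, 1]):
        # perfect agreement: F statistics degenerate, ICC is exactly 1
        return 1.0, (1.0, 1.0), "excellent"

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(arr.shape[0]), 2),
            "rating": np.tile([0, 1], arr.shape[0]),
            "value": arr.ravel(),
        }
    )
    res = pg.intraclass_corr(
        data=long, targets="subject", raters="rating", ratings="value"
    ).set_index("Type")
    # McGraw-Wong ICC(A,1): single measure, absolute agreement
    key = "ICC(A,1)" if "ICC(A,1)" in res.index else "ICC2"
    row = res.loc[key]
    ci_col = "CI95" if "CI95" in res.columns else "CI95%"
    icc = float(row["ICC"])
    lo, hi = (float(x) for x in row[ci_col])
    low_band, high_band = _icc_band(lo), _icc_band(hi)
    interp = low_band if low_band == high_band else f"{low_band} to {high_band}"
    return icc, (lo, hi), interp


@dataclass
class GroupComparison:
    parameter_name: str
    median_per_group: tuple[float, float]  # (pCR, ReTu)
    iqr_per_group: tuple[tuple[float, float], tuple[float, float]]
    p_value: float
    auc_roc: float
    auc_ci: tuple[float, float]


def group_comparison_table(
    features: pd.DataFrame,
    labels,
    parameters=None,
    positive_label: str = "ReTu",
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-parameter medians/IQRs, rank-test p and ROC AUC, one row each.

    ``labels`` holds "pCR"/"ReTu" per row of ``features``.  Per-parameter
    AUC scores each feature directly against ``positive_label``; orientation
    is made >= 0.5-free by reporting the raw (unflipped) AUC, matching a
    published-table convention of one fixed direction per feature.
    ``adjust="holm"`` applies a Holm correction across the parameter family
    (off by default).
    """
    labels = np.asarray(labels)
    if parameters is None:
        parameters = [c for c in features.columns if c != "patient_id"]
    rows = []
    for name in parameters:
        x = features[name].to_numpy(dtype=float)
        a = x[labels == "pCR"]
        b = x[labels == "ReTu"]
        p = rank_test(a, b)
        auc, ci = roc_auc(x, labels == positive_label)
        if auc < 0.5:  # report the discriminative direction, as in ROC tables
            auc, ci = 1.0 - auc, (1.0 - ci[1], 1.0 - ci[0])
        rows.append(
            {
                "parameter": name,
                "median_pCR": float(np.median(a)),
                "q1_pCR": float(np.percentile(a, 25)),
                "q3_pCR": float(np.percentile(a, 75)),
                "median_ReTu": float(np.median(b)),
                "q1_ReTu": float(np.percentile(b, 25)),
                "q3_ReTu": float(np.percentile(b, 75)),
                "p_value": p,
                "auc_roc": auc,
                "auc_lo": ci[0],
                "auc_hi": ci[1],
            }
        )
    table = pd.DataFrame(rows)
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        table["p_adjusted"] = multipletests(table["p_value"], method="holm")[1]
    return table
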