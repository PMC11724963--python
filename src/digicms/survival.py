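"""Survival stratification and classifier evaluation of digital-CMS scores.

Covers the evaluation chain applied to patient-level scores: ROC/AUC,
Youden-cutoff selection on the discovery set, Kaplan-Meier curves with the
log-rank test on the validation set, multivariate Cox proportional-hazards
fits with clinical covariates, Harrell's concordance index, and DeLong's test
for comparing two classifications.

Orientation convention throughout: a higher digital-CMS score means more
C2-like, and predicted C2 is the high-risk group; patients whose score is at
or above the cutoff are assigned to the high-risk group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "ROCResult",
    "roc_auc",
    "youden_cutoff",
    "km_logrank",
    "fit_coxph",
    "harrell_cindex",
    "delong_test",
    "cindex_delong",
]


@dataclass
class ROCResult:
    """ROC curve of a score against binary labels (1 = positive = C2)."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    scores: np.ndarray
    labels: np.ndarray


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC (equals the Mann-Whitney probability; ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=float(roc_auc_score(labels, scores)),
        scores=scores,
        labels=labels,
    )


def youden_cutoff(roc: ROCResult) -> float:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints between adjacent distinct scores
    plus -inf/+inf; a score >= threshold predicts the positive (high-risk,
    C2) class.  Ties in J are broken toward the lowest threshold, which
    assigns more patients to the high-risk group only when forced.
    """
    scores, labels = roc.scores, roc.labels
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("all scores identical: no informative cutoff exists")
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best_thr, best_j = None, -np.inf
    for thr in candidates:
        pred = scores >= thr
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_thr = j, thr
    return float(best_thr)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank

@dataclass
class KMLogrankResult:
    curves: dict[str, pd.DataFrame]  # group -> columns (time, survival)
    statistic: float
    p_value: float
    df: int


def km_logrank(groups: dict[str, tuple[np.ndarray, np.ndarray]]) -> KMLogrankResult:
    """Kaplan-Meier estimate per group and the (k-1)-df log-rank test.

    ``groups`` maps a group name (e.g. "low-risk"/"high-risk") to
    ``(times, events)`` with right-censored 0/1 event indicators.
    """
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    curves: dict[str, pd.DataFrame] = {}
    all_t, all_e, all_g = [], [], []
    for name, (times, events) in groups.items():
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        if len(times) == 0:
            raise ValueError(f"group {name!r} has zero subjects")
        if (times < 0).any():
            raise ValueError(f"group {name!r} has negative times")
        kmf = KaplanMeierFitter()
        kmf.fit(times, events)
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame({
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        })
        all_t.append(times)
        all_e.append(events)
        all_g.extend([name] * len(times))
    res = multivariate_logrank_test(
        np.concatenate(all_t), np.asarray(all_g), np.concatenate(all_e)
    )
    return KMLogrankResult(
        curves=curves,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        df=len(groups) - 1,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards

#: Conventional reference levels for the categorical clinical covariates.
DEFAULT_REFERENCES = {"hpv_type": "HPV16", "stage": "I", "treatment": "surgery"}


def fit_coxph(
    records: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    references: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Multivariate Cox PH fit (Breslow tie handling, Wald inference).

    Categorical covariates are expanded to dummies against the declared
    reference level.  Returns one row per model term with hazard ratio, 95 %
    Wald CI and p-value.
    """
    import statsmodels.api as sm

    refs = {**DEFAULT_REFERENCES, **(references or {})}
    df = records[[duration_col, event_col, *covariates]].dropna().copy()
    if len(df) == 0:
        raise ValueError("no complete-case rows for the Cox fit")
    if df[event_col].sum() == 0:
        raise ValueError("Cox fit requires at least one observed event")

    cols = []
    for cov in covariates:
        if pd.api.types.is_numeric_dtype(df[cov]):
            cols.append(df[cov].astype(float))
        else:
            cats = sorted(df[cov].astype(str).unique())
            ref = refs.get(cov, cats[0])
            for level in cats:
                if level == ref:
                    continue
                cols.append((df[cov].astype(str) == level).astype(float).rename(f"{cov}[{level}]"))
    X = pd.concat(cols, axis=1)
    # collinearity / separation diagnostic
    rank = np.linalg.matrix_rank(np.c_[np.ones(len(X)), X.to_numpy()])
    if rank < X.shape[1] + 1:
        raise ValueError("covariates are perfectly collinear; drop or merge levels")

    model = sm.PHReg(df[duration_col].to_numpy(), X.to_numpy(),
                     status=df[event_col].to_numpy(), ties="breslow")
    fit = model.fit()
    coef = np.asarray(fit.params, dtype=float)
    se = np.asarray(fit.bse, dtype=float)
    z = coef / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "covariate": list(X.columns),
        "coef": coef,
        "hr": np.exp(coef),
        "hr_ci_low": np.exp(coef - 1.959963984540054 * se),
        "hr_ci_high": np.exp(coef + 1.959963984540054 * se),
        "p": p,
    })


# ---------------------------------------------------------------------------
# concordance and DeLong

def harrell_cindex(times, events, risk_scores) -> float:
    """Harrell's C for a risk score (higher score = higher risk = earlier event)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    risk = np.asarray(risk_scores, dtype=float)
    if events.sum() == 0:
        raise ValueError("concordance undefined: no comparable pairs (no events)")
    # lifelines' convention: higher prediction = longer survival, so negate
    return float(_lifelines_cindex(times, -risk, events))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """DeLong's two-sided test comparing the AUCs of two scores on one sample.

    Returns ``(auc_a, auc_b, p)``.  When the estimated variance of the AUC
    difference is zero (e.g. identical scores), p = 1 by convention.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("both score vectors must cover the same subjects")
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("DeLong requires both classes present")

    aucs = np.empty(2)
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    for idx, s in enumerate((scores_a, scores_b)):
        x, y = s[pos], s[~pos]
        tx = _midrank(x)
        ty = _midrank(y)
        tz = _midrank(np.concatenate([x, y]))
        auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        aucs[idx] = auc
        v10[idx] = (tz[:m] - tx) / n
        v01[idx] = 1.0 - (tz[m:] - ty) / m
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var_diff <= 0:
        return float(aucs[0]), float(aucs[1]), 1.0
    z = (aucs[0] - aucs[1]) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(aucs[0]), float(aucs[1]), float(p)


def cindex_delong(
    scores_a,
    scores_b,
    times,
    events,
    cms_labels,
) -> dict[str, float]:
    """Compare two classifications: Harrell's C per score plus DeLong's test.

    Harrell's C is computed against the survival endpoint (comparable pairs
    only); DeLong's test compares the two scores' AUCs against the binary
    molecular-subtype labels, two-sided.
    """
    c_a = harrell_cindex(times, events, scores_a)
    c_b = harrell_cindex(times, events, scores_b)
    auc_a, auc_b, p = delong_test(scores_a, scores_b, cms_labels)
    return {
        "c_index_a": c_a,
        "c_index_b": c_b,
        "auc_a": auc_a,
        "auc_b": auc_b,
        "delong_p": p,
    }
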