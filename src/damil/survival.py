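"""Evaluation: classification metrics, Cox risk stratification, KM tables.

Predicted risk groups come from thresholding slide probabilities and
aggregating to patients (most-suspicious-slide rule by default). The
univariate Cox model is fit by Newton iteration on the Breslow partial
likelihood; Kaplan-Meier tables use the product-limit estimator. Both
are cross-checked against an independent survival library in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from damil.bags import NRC, RC


@dataclass
class CoxResult:
    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n_events: int
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("CI must bracket the hazard ratio")


@dataclass
class MetricsEntry:
    auroc: float
    accuracy: float
    specificity: float
    sensitivity: float

    def as_dict(self) -> dict[str, float]:
        return self.__dict__.copy()


def classification_metrics(
    scores: np.ndarray, labels: list[str] | np.ndarray, threshold: float = 0.5
) -> MetricsEntry:
    """AUROC/accuracy/specificity/sensitivity on a 0-100 scale.

    RC is the positive class: sensitivity is recall on RC, specificity
    is recall on NRC. AUROC is the probability that a random RC score
    exceeds a random NRC score, ties counting one half.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray([1 if lab == RC else 0 for lab in np.asarray(labels)])
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC undefined: only one class present")
    pred = (scores >= threshold).astype(int)
    return MetricsEntry(
        auroc=100.0 * float(roc_auc_score(y, scores)),
        accuracy=100.0 * float((pred == y).mean()),
        specificity=100.0 * float((pred[y == 0] == 0).mean()),
        sensitivity=100.0 * float((pred[y == 1] == 1).mean()),
    )


def fold_metrics_report(
    predictions: pd.DataFrame, threshold: float = 0.5
) -> dict:
    """Fold-wise metrics plus mean +/- sd, from a crossval predictions table."""
    per_fold = {}
    for fold, grp in predictions.groupby("fold"):
        per_fold[int(fold)] = classification_metrics(
            grp["p_RC"].to_numpy(), grp["label"].tolist(), threshold
        ).as_dict()
    names = ["auroc", "accuracy", "specificity", "sensitivity"]
    summary = {}
    for name in names:
        vals = np.array([m[name] for m in per_fold.values()])
        summary[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
    return {"per_fold": per_fold, "summary": summary}


def aggregate_patient(
    predictions: pd.DataFrame, rule: str = "max", threshold: float = 0.5
) -> pd.DataFrame:
    """Patient score from slide scores (max by default, or mean) + group."""
    if rule not in ("max", "mean"):
        raise ValueError("rule must be 'max' or 'mean'")
    agg = (
        predictions.groupby("patient_id")["p_RC"]
        .agg(rule)
        .rename("score")
        .reset_index()
    )
    agg["group"] = np.where(agg["score"] >= threshold, "high", "low")
    return agg


def apply_admin_censoring(
    records: pd.DataFrame, horizon: float | None = 60.0
) -> pd.DataFrame:
    """Truncate times and censor events at the administrative horizon."""
    out = records.copy()
    if horizon is not None:
        over = out["time_months"] > horizon
        out.loc[over, "time_months"] = horizon
        out.loc[over, "event"] = 0
    return out


def cox_univariate(
    records: pd.DataFrame,
    covariate: str = "group",
    horizon: float | None = 60.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxResult:
    """Univariate Cox PH fit with Breslow tie handling by Newton iteration.

    ``records`` needs columns time_months, event and a binary covariate
    (``group`` coded high/low, or any 0/1 column). The Wald interval is
    exp(beta +/- 1.96 se). A monotone partial likelihood (one arm never
    ahead in risk) is flagged as non-converged rather than raised.
    """
    df = apply_admin_censoring(records, horizon)
    x = df[covariate]
    if x.dtype == object:
        x = x.map({"low": 0, "high": 1})
        if x.isna().any():
            raise ValueError("group column must be coded high/low")
    x = x.to_numpy(dtype=np.float64)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValueError("covariate must be binary 0/1")
    if len(np.unique(x)) < 2:
        raise ValueError("one predicted group has no subjects")
    time = df["time_months"].to_numpy(dtype=np.float64)
    event = df["event"].to_numpy(dtype=np.int64)
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events in the cohort")

    order = np.argsort(time, kind="stable")
    time, event, x = time[order], event[order], x[order]
    event_times = np.unique(time[event == 1])

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        score_val = 0.0
        info = 0.0
        ex = np.exp(beta * x)
        for t in event_times:
            at_risk = time >= t
            deaths = (time == t) & (event == 1)
            d = deaths.sum()
            s0 = ex[at_risk].sum()
            s1 = (ex[at_risk] * x[at_risk]).sum()
            s2 = (ex[at_risk] * x[at_risk] ** 2).sum()
            score_val += x[deaths].sum() - d * s1 / s0
            info += d * (s2 / s0 - (s1 / s0) ** 2)
        if info <= 0:
            break
        delta = score_val / info
        beta += delta
        if abs(delta) < tol:
            converged = True
            break
    if not np.isfinite(beta) or abs(beta) > 50:
        converged = False
        beta = float(np.clip(beta, -50, 50))
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    hr = float(np.exp(beta))
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    return CoxResult(
        beta=float(beta),
        se=se,
        hr=hr,
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        p=p,
        n_events=n_events,
        converged=converged,
    )


def km_table(records: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Product-limit survival table per group.

    One row per event time (plus a time-0 row at survival 1) with
    at-risk and event counts; the curve is non-increasing from 1.
    """
    rows = []
    for group, grp in records.groupby(group_col):
        if len(grp) == 0:
            raise ValueError(f"empty group {group!r}")
        time = grp["time_months"].to_numpy(dtype=np.float64)
        event = grp["event"].to_numpy(dtype=np.int64)
        surv = 1.0
        rows.append({"group": group, "time": 0.0, "n_risk": len(grp), "n_event": 0, "survival": 1.0})
        for t in np.unique(time[event == 1]):
            n_risk = int((time >= t).sum())
            d = int(((time == t) & (event == 1)).sum())
            surv *= 1.0 - d / n_risk
            rows.append(
                {"group": group, "time": float(t), "n_risk": n_risk, "n_event": d, "survival": surv}
            )
    if not rows:
        raise ValueError("no records")
    return pd.DataFrame(rows)


def chi_square_assoc(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on an r x 2 table.

    Returns (statistic, p) with (r - 1) degrees of freedom.
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("expected an r x 2 table")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def label_predicted_groups(
    cohort: pd.DataFrame,
    predictions: pd.DataFrame,
    rule: str = "max",
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Join patient-level predicted groups onto the cohort survival rows."""
    agg = aggregate_patient(predictions, rule=rule, threshold=threshold)
    per_patient = cohort.drop_duplicates("patient_id")[
        ["patient_id", "label", "time_months", "event"]
    ]
    merged = per_patient.merge(agg, on="patient_id", how="inner")
    return merged
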