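"""Coverage-aware performance metrics and prevalence re-adjustment.

Sensitivity, specificity and MCC are computed over *conclusive*
conformal predictions only; inconclusive (two-label or empty) sets
count solely against the coverage fraction. PPV, NPV and overall
accuracy are then re-expressed at an arbitrary event prevalence via
the Bayes identities

    ppv(pi) = se*pi / (se*pi + (1-sp)(1-pi))
    npv(pi) = sp(1-pi) / (sp(1-pi) + (1-se)pi)
    acc(pi) = se*pi + sp*(1-pi)

so that a cohort-internal confusion matrix can be read at either the
cohort's own 4-year mortality (32%) or an external literature rate
(47%). The positive class is death (non-survival).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conformal import PredictionSet
from .synthetic_cohort import NON_SURVIVOR

PREVALENCE_COHORT = 0.32
PREVALENCE_REPORTED = 0.47


@dataclass
class PerformanceSummary:
    se: float
    sp: float
    mcc: float
    coverage: float
    n_conclusive: int
    n_total: int
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    defined: bool = True
    prevalence_conclusive: float | None = None
    r2: float | None = None
    q2: float | None = None
    conformal_accuracy: float | None = None

    def at_prevalence(self, pi: float) -> tuple[float, float, float]:
        return adjust_prevalence(self.se, self.sp, pi)

    def row(self, label: str = "") -> dict:
        if (not self.defined or math.isnan(self.se) or math.isnan(self.sp)):
            # no conclusive prediction for one of the classes
            return {"model": label, "Se": self.se, "Sp": self.sp,
                    "MCC": self.mcc, "Cov": round(self.coverage, 2),
                    "PPV (rep|our)": "NA", "NPV (rep|our)": "NA",
                    "Acc (rep|our)": "NA"}
        ppv_r, npv_r, acc_r = self.at_prevalence(PREVALENCE_REPORTED)
        ppv_c, npv_c, acc_c = self.at_prevalence(PREVALENCE_COHORT)
        fmt = lambda a, b: f"{a:.2f}|{b:.2f}"
        return {
            "model": label,
            "Se": round(self.se, 2), "Sp": round(self.sp, 2),
            "MCC": round(self.mcc, 2), "Cov": round(self.coverage, 2),
            "PPV (rep|our)": fmt(ppv_r, ppv_c),
            "NPV (rep|our)": fmt(npv_r, npv_c),
            "Acc (rep|our)": fmt(acc_r, acc_c),
        }


def confusion_metrics(preds: list[PredictionSet], truth,
                      positive=NON_SURVIVOR) -> PerformanceSummary:
    """Confusion-matrix metrics over conclusive predictions.

    ``truth`` holds the real class labels; predictions whose set is not
    a singleton are excluded from Se/Sp/MCC and only lower coverage.
    """
    truth = np.asarray(truth)
    n_total = len(preds)
    if n_total != len(truth):
        raise ValueError("predictions and truth differ in length")
    tp = fp = tn = fn = 0
    n_conc = 0
    for ps, t in zip(preds, truth):
        if not ps.conclusive:
            continue
        n_conc += 1
        pred = ps.prediction_set[0]
        if t == positive:
            tp += pred == positive
            fn += pred != positive
        else:
            fp += pred == positive
            tn += pred != positive
    coverage = n_conc / n_total if n_total else 0.0
    if n_conc == 0:
        return PerformanceSummary(se=math.nan, sp=math.nan, mcc=math.nan,
                                  coverage=0.0, n_conclusive=0,
                                  n_total=n_total, defined=False)
    se = tp / (tp + fn) if (tp + fn) else math.nan
    sp = tn / (tn + fp) if (tn + fp) else math.nan
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return PerformanceSummary(
        se=se, sp=sp, mcc=mcc, coverage=coverage,
        n_conclusive=n_conc, n_total=n_total,
        tp=tp, fp=fp, tn=tn, fn=fn,
        prevalence_conclusive=(tp + fn) / n_conc,
    )


def adjust_prevalence(se: float, sp: float,
                      prevalence: float) -> tuple[float, float, float]:
    """Re-express PPV / NPV / accuracy at an external prevalence."""
    for name, v in (("se", se), ("sp", sp)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must lie in [0, 1], got {prevalence}")
    pi = prevalence
    pos = se * pi + (1.0 - sp) * (1.0 - pi)
    neg = sp * (1.0 - pi) + (1.0 - se) * pi
    ppv = se * pi / pos if pos > 0 else math.nan
    npv = sp * (1.0 - pi) / neg if neg > 0 else math.nan
    acc = se * pi + sp * (1.0 - pi)
    return ppv, npv, acc


def regression_metrics(y, yhat_fit=None, yhat_oof=None,
                       intervals: list[PredictionSet] | None = None
                       ) -> tuple[float | None, float | None, float | None]:
    """(R2 of the fit, Q2 from out-of-fold predictions, conformal accuracy).

    R2 = 1 - SSE_fit/TSS; Q2 = 1 - PRESS/TSS with PRESS the squared
    error of out-of-fold predictions; conformal accuracy = fraction of
    prediction intervals containing the truth.
    """
    y = np.asarray(y, dtype=float)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("constant outcome: R2/Q2 undefined (TSS = 0)")
    r2 = q2 = conf_acc = None
    if yhat_fit is not None:
        sse = float(((y - np.asarray(yhat_fit, dtype=float)) ** 2).sum())
        r2 = 1.0 - sse / tss
    if yhat_oof is not None:
        press = float(((y - np.asarray(yhat_oof, dtype=float)) ** 2).sum())
        q2 = 1.0 - press / tss
    if intervals is not None:
        conf_acc = float(np.mean([ps.contains(v)
                                  for ps, v in zip(intervals, y)]))
    return r2, q2, conf_acc


def cohort_rates(metadata: pd.DataFrame,
                 followup_days: int = 1460) -> dict:
    """Yearly cumulative mortality (integer %) and FE-stratified mortality.

    Patients with missing days of survival are excluded with a count in
    the output (mirrors subjects lost to follow-up). A patient counts as
    dead by year k when their status is non-survivor and days_survival
    <= 365*k.
    """
    meta = metadata
    missing = meta["days_survival"].isna()
    n_missing = int(missing.sum())
    meta = meta.loc[~missing]
    n = len(meta)
    if n == 0:
        raise ValueError("no patients with known survival")
    dead = meta["status"] == NON_SURVIVOR
    days = meta["days_survival"].astype(float)
    yearly = {}
    n_years = max(1, int(round(followup_days / 365)))
    for k in range(1, n_years + 1):
        yearly[k] = int(round(100.0 * float((dead & (days <= 365 * k)).mean())))
    fe = meta["frequent_exacerbator"].astype(bool)
    strat = {}
    for label, mask in (("FE", fe), ("non-FE", ~fe)):
        strat[label] = (int(round(100.0 * float(dead[mask].mean())))
                        if mask.any() else None)
    return {"yearly_mortality_pct": yearly,
            "fe_stratified_mortality_pct": strat,
            "n": n, "n_excluded_missing": n_missing}
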