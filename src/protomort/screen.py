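"""Differential-abundance screening: quantitative and presence/absence branches.

Quantitative branch: per protein, normality of each outcome group is
assessed with Shapiro-Wilk; an independent two-sample (pooled-variance)
t-test is used when both groups look normal, a two-sided Mann-Whitney U
otherwise. The effect is the log2 fold change (non-survivor mean minus
survivor mean of log2 abundances) with its percent-change counterpart
%d = (2**log2FC - 1) * 100.

Qualitative branch: proteins below the coverage threshold whose
detection pattern is "present in (almost) all of one group, absent in
the other" are tested with Barnard's unconditional exact test on the
2x2 detection table; the effect is the phi / Matthews correlation
coefficient signed so that positive means more present in non-survivors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ingest import ProcessedMatrix, QUANTITATIVE, QUALITATIVE_CANDIDATE, EXCLUDED
from .synthetic_cohort import SURVIVOR, NON_SURVIVOR

QUANT = "quantitative"
QUAL = "qualitative"


@dataclass
class DapRecord:
    protein: str
    branch: str                      # quantitative | qualitative
    statistic: float
    p_value: float
    log2fc: float | None = None      # quantitative branch
    pct_change: float | None = None
    mcc: float | None = None         # qualitative branch (phi)
    direction: str = ""              # "up-in-nonsurvivors" / "down-in-nonsurvivors"
    test_name: str = ""
    significant: bool = False
    functional_group: str | None = None
    fdr_q: float | None = None


def pct_change_from_log2fc(log2fc: float) -> float:
    return (2.0 ** log2fc - 1.0) * 100.0


def log2fc_from_pct_change(pct: float) -> float:
    return math.log2(pct / 100.0 + 1.0)


def quantitative_test(x_surv, x_nonsurv, alpha_normality: float = 0.05) -> DapRecord:
    """Two-group comparison of log2 abundances with a normality gate.

    Both samples must have >= 2 values. Shapiro-Wilk needs n >= 3; a
    group too small to assess is treated as non-normal (rank test).
    """
    x_surv = np.asarray(x_surv, dtype=float)
    x_nonsurv = np.asarray(x_nonsurv, dtype=float)
    if x_surv.size < 2 or x_nonsurv.size < 2:
        raise ValueError("each group needs at least 2 values")

    log2fc = float(x_nonsurv.mean() - x_surv.mean())

    def _normal(x: np.ndarray) -> bool:
        if x.size < 3 or np.ptp(x) == 0:
            return False
        return stats.shapiro(x).pvalue > alpha_normality

    both_const = np.ptp(x_surv) == 0 and np.ptp(x_nonsurv) == 0
    if both_const:
        # degenerate: no variation anywhere
        p = 1.0 if log2fc == 0 else 0.0
        stat, test = 0.0, "degenerate"
        if log2fc != 0:
            stat, test = math.inf, "degenerate"
    elif _normal(x_surv) and _normal(x_nonsurv):
        res = stats.ttest_ind(x_nonsurv, x_surv, equal_var=True)
        stat, p, test = float(res.statistic), float(res.pvalue), "t"
    else:
        res = stats.mannwhitneyu(x_nonsurv, x_surv, alternative="two-sided")
        stat, p, test = float(res.statistic), float(res.pvalue), "mannwhitney"

    return DapRecord(
        protein="", branch=QUANT, statistic=stat, p_value=p,
        log2fc=log2fc, pct_change=pct_change_from_log2fc(log2fc),
        direction="up-in-nonsurvivors" if log2fc >= 0 else "down-in-nonsurvivors",
        test_name=test,
    )


# ---------------------------------------------------------------------------
# Barnard unconditional exact test
# ---------------------------------------------------------------------------

_NUISANCE_GRID = np.arange(0.0005, 1.0, 0.001)   # dense, boundaries excluded


def _wald_pooled(x1: np.ndarray, n1: int, x2: np.ndarray, n2: int) -> np.ndarray:
    """Pooled Wald z-statistic for all 2x2 tables (x1 detections of n1 vs
    x2 of n2); tables with pooled rate 0 or 1 get statistic 0."""
    p1 = x1 / n1
    p2 = x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (p2 - p1) / np.sqrt(var)
    z[~np.isfinite(z)] = 0.0
    return z


def barnard_exact(present_a: int, n_a: int, present_b: int, n_b: int,
                  grid: np.ndarray | None = None) -> float:
    """Two-sided Barnard unconditional exact p-value.

    Orders tables by the pooled Wald statistic and maximizes the
    two-sided tail probability over the nuisance common detection
    probability on a dense grid (step 1e-3, boundaries excluded).
    Fully vectorized over the (n_a+1) x (n_b+1) table lattice.
    """
    if min(present_a, n_a, present_b, n_b) < 0:
        raise ValueError("counts must be non-negative")
    if present_a > n_a or present_b > n_b:
        raise ValueError("detections cannot exceed group size")
    total = present_a + present_b
    if total == 0 or total == n_a + n_b:
        return 1.0

    if grid is None:
        grid = _NUISANCE_GRID
    xa = np.arange(n_a + 1)
    xb = np.arange(n_b + 1)
    X1, X2 = np.meshgrid(xa, xb, indexing="ij")
    z = _wald_pooled(X1.astype(float), n_a, X2.astype(float), n_b)
    z_obs = _wald_pooled(np.array([float(present_a)]), n_a,
                         np.array([float(present_b)]), n_b)[0]
    in_tail = np.abs(z) >= abs(z_obs) - 1e-12

    pmf_a = stats.binom.pmf(xa[:, None], n_a, grid[None, :])   # (n_a+1, G)
    pmf_b = stats.binom.pmf(xb[:, None], n_b, grid[None, :])   # (n_b+1, G)
    # tail probability per nuisance value: sum over tables in the tail
    tail = np.einsum("ij,ig,jg->g", in_tail.astype(float), pmf_a, pmf_b)
    return float(min(1.0, tail.max()))


def phi_coefficient(present_surv: int, n_surv: int,
                    present_nonsurv: int, n_nonsurv: int) -> float:
    """Signed phi (Matthews) coefficient of the 2x2 detection table;
    positive = more present in non-survivors."""
    a = present_nonsurv
    b = n_nonsurv - present_nonsurv
    c = present_surv
    d = n_surv - present_surv
    denom = math.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    if denom == 0:
        return 0.0
    return (a * d - b * c) / denom


def qualitative_test(present_surv: int, n_surv: int,
                     present_nonsurv: int, n_nonsurv: int) -> DapRecord:
    """Barnard test + phi effect for a presence/absence protein."""
    if min(present_surv, present_nonsurv) < 0:
        raise ValueError("counts must be non-negative")
    if present_surv > n_surv or present_nonsurv > n_nonsurv:
        raise ValueError("detections cannot exceed group size")
    phi = phi_coefficient(present_surv, n_surv, present_nonsurv, n_nonsurv)
    total = present_surv + present_nonsurv
    if total == 0 or total == n_surv + n_nonsurv:
        p, stat = 1.0, 0.0
    else:
        p = barnard_exact(present_surv, n_surv, present_nonsurv, n_nonsurv)
        stat = _wald_pooled(np.array([float(present_surv)]), n_surv,
                            np.array([float(present_nonsurv)]), n_nonsurv)[0]
    return DapRecord(
        protein="", branch=QUAL, statistic=float(stat), p_value=p, mcc=phi,
        direction="up-in-nonsurvivors" if phi >= 0 else "down-in-nonsurvivors",
        test_name="barnard",
    )


# ---------------------------------------------------------------------------
# Whole-matrix screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    records: list[DapRecord]
    branch_counts: dict = field(default_factory=dict)

    @property
    def daps(self) -> list[DapRecord]:
        return [r for r in self.records if r.significant]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "protein": r.protein, "branch": r.branch, "test": r.test_name,
                "statistic": r.statistic, "p_value": r.p_value,
                "log2FC": r.log2fc, "pct_change": r.pct_change, "MCC": r.mcc,
                "direction": r.direction, "significant": r.significant,
                "fdr_q": r.fdr_q, "functional_group": r.functional_group,
            })
        return pd.DataFrame(rows)


def screen_all(pm: ProcessedMatrix, alpha: float = 0.05,
               alpha_normality: float = 0.05,
               qual_present_min: float = 0.80,
               qual_absent_max: float = 0.20) -> ScreenResult:
    """Run both screening branches over a routed, imputed matrix.

    Quantitative-branch proteins get the gated t / Mann-Whitney test on
    imputed log2 values. Qualitative candidates enter the Barnard branch
    only when detected in >= ``qual_present_min`` of one group and
    <= ``qual_absent_max`` of the other (the "present in almost all of
    one group, absent in the other" pattern); remaining candidates are
    marked excluded. Significance is two-sided unadjusted p < ``alpha``;
    a Benjamini-Hochberg q-value column is attached for reference only.
    """
    if not pm.imputed:
        raise ValueError("screen_all expects an imputed matrix "
                         "(run impute_min95 first)")
    surv = (pm.groups == SURVIVOR).to_numpy()
    dead = (pm.groups == NON_SURVIVOR).to_numpy()
    n_s, n_d = int(surv.sum()), int(dead.sum())

    records: list[DapRecord] = []
    n_excluded = 0
    for prot in pm.branch.index:
        if pm.branch[prot] == QUANTITATIVE:
            vals = pm.log2_values[prot].to_numpy()
            rec = quantitative_test(vals[surv], vals[dead],
                                    alpha_normality=alpha_normality)
            rec.protein = prot
            records.append(rec)
        else:
            det = pm.detected[prot].to_numpy()
            f_s = det[surv].mean()
            f_d = det[dead].mean()
            eligible = ((f_s >= qual_present_min and f_d <= qual_absent_max)
                        or (f_d >= qual_present_min and f_s <= qual_absent_max))
            if eligible:
                rec = qualitative_test(int(det[surv].sum()), n_s,
                                       int(det[dead].sum()), n_d)
                rec.protein = prot
                records.append(rec)
            else:
                n_excluded += 1
                pm.branch[prot] = EXCLUDED

    if records:
        pvals = np.array([r.p_value for r in records])
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for r, q in zip(records, qvals):
            r.fdr_q = float(q)
            r.significant = r.p_value < alpha

    counts = {
        QUANT: sum(r.branch == QUANT for r in records),
        QUAL: sum(r.branch == QUAL for r in records),
        EXCLUDED: n_excluded,
    }
    return ScreenResult(records=records, branch_counts=counts)
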