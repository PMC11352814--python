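"""Reading, merging, log2 transform, coverage routing and imputation.

The two platform tables (LC-MS label-free quantification and multiplex
immunoassay) are merged into one patient-by-protein matrix, values are
log2 transformed, per-group detection coverage is computed, and each
protein is routed to the quantitative branch (coverage >= 80% in each
outcome group), kept as a qualitative presence/absence candidate, or
excluded. Missing cells of quantitative-branch proteins receive a "95%
minimum" imputation: 95% of that protein's minimum observed linear-scale
value, guaranteeing the imputed value sits strictly below everything
observed (missing is presumed to mean "below the detection limit").
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synthetic_cohort import SURVIVOR, NON_SURVIVOR

QUANTITATIVE = "quantitative"
QUALITATIVE_CANDIDATE = "qualitative-candidate"
EXCLUDED = "excluded"


@dataclass
class AbundanceMatrix:
    """Linear-scale patients x proteins table with explicit missingness.

    ``values`` holds strictly positive reals where observed and NaN where
    missing; ``groups`` maps each patient to survivor / non-survivor.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate patient identifiers: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate protein identifiers: {dup}")
        observed = self.values.to_numpy()
        if np.any(observed[~np.isnan(observed)] <= 0):
            raise ValueError("observed abundances must be strictly positive "
                             "(log2 must be defined)")
        self.groups = self.groups.reindex(self.values.index)

    @property
    def patients(self) -> pd.Index:
        return self.values.index

    @property
    def proteins(self) -> pd.Index:
        return self.values.columns


@dataclass
class ProcessedMatrix:
    """Log2 matrix with per-group coverage and branch routing."""

    log2_values: pd.DataFrame
    groups: pd.Series
    coverage_survivor: pd.Series
    coverage_nonsurvivor: pd.Series
    branch: pd.Series            # per protein: quantitative / qualitative-candidate / excluded
    detected: pd.DataFrame       # boolean detection mask (pre-imputation)
    imputed: bool = False


def read_abundance_tsv(path, metadata_path=None, sep: str | None = None) -> AbundanceMatrix:
    """Read an abundance table written by the cohort generator (TSV or CSV).

    Patients are rows, proteins are columns (header carries the platform
    suffix ``:lcms`` / ``:mux``), empty cell = missing. Group labels come
    from the metadata table's ``status`` column when given.
    """
    df = pd.read_csv(path, sep=sep if sep else "\t", index_col=0)
    groups = pd.Series(index=df.index, dtype=object)
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep=sep if sep else "\t", index_col=0)
        groups = meta.loc[df.index, "status"]
    return AbundanceMatrix(values=df, groups=groups)


def merge_platforms(lcms: AbundanceMatrix, mux: AbundanceMatrix) -> AbundanceMatrix:
    """Column-wise merge of the two platform tables.

    Patient sets must match exactly; proteins named identically on both
    platforms stay as distinct tagged columns.
    """
    if mux.values.shape[1] == 0:
        return AbundanceMatrix(values=lcms.values.copy(), groups=lcms.groups.copy())
    left, right = set(lcms.patients), set(mux.patients)
    if left != right:
        only_l = sorted(left - right)
        only_r = sorted(right - left)
        raise ValueError(
            "patient sets differ between platforms: "
            f"only in lcms {only_l}; only in mux {only_r}"
        )
    mux_vals = mux.values.reindex(lcms.patients)
    merged = pd.concat([lcms.values, mux_vals], axis=1)
    return AbundanceMatrix(values=merged, groups=lcms.groups.copy())


def compute_coverage_and_route(m: AbundanceMatrix,
                               threshold: float = 0.80) -> ProcessedMatrix:
    """Log2 transform and route each protein by per-group detection coverage.

    quantitative  : observed fraction >= ``threshold`` in *each* group;
    everything else becomes a qualitative presence/absence candidate
    (final eligibility is decided by the screening stage).
    """
    surv = m.groups == SURVIVOR
    dead = m.groups == NON_SURVIVOR
    if surv.sum() == 0 or dead.sum() == 0:
        raise ValueError("both outcome groups must be non-empty for routing")
    detected = m.values.notna()
    cov_s = detected.loc[surv.values].mean(axis=0)
    cov_d = detected.loc[dead.values].mean(axis=0)
    quant = (cov_s >= threshold) & (cov_d >= threshold)
    branch = pd.Series(np.where(quant, QUANTITATIVE, QUALITATIVE_CANDIDATE),
                       index=m.proteins)
    return ProcessedMatrix(
        log2_values=np.log2(m.values),
        groups=m.groups.copy(),
        coverage_survivor=cov_s,
        coverage_nonsurvivor=cov_d,
        branch=branch,
        detected=detected,
    )


def impute_min95(pm: ProcessedMatrix, factor: float = 0.95) -> ProcessedMatrix:
    """Impute missing cells of quantitative-branch proteins.

    Each missing cell of protein j receives ``factor`` x (protein j's
    minimum observed linear-scale value); on the log2 scale this is
    min(log2) + log2(factor). Observed cells are untouched.
    """
    if not 0 < factor < 1:
        raise ValueError("imputation factor must lie in (0, 1) so the imputed "
                         "value falls below the observed minimum")
    log2 = pm.log2_values.copy()
    quant_cols = pm.branch.index[pm.branch == QUANTITATIVE]
    for col in quant_cols:
        colvals = log2[col]
        if colvals.isna().all():
            raise AssertionError(
                f"quantitative-branch protein {col!r} has no observed values; "
                "routing should have made this impossible"
            )
        if colvals.isna().any():
            log2.loc[colvals.isna(), col] = colvals.min() + np.log2(factor)
    return replace(pm, log2_values=log2, imputed=True)
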