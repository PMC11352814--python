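"""Synthetic two-platform plasma proteomics cohort with a linked survival outcome.

Generates patient-by-protein abundance tables that mimic a small COPD
mortality cohort profiled by label-free LC-MS and a bead-based multiplex
immunoassay: log-normal abundances, planted log2-scale group effects,
left-censored (missing-not-at-random) dropout plus a baseline
missing-at-random rate, a block of presence/absence proteins whose
detection probability depends on outcome group, and a 4-year survival
outcome (status + days of survival) driven by the planted markers.

Every downstream stage of the pipeline is testable against the planted
truth returned alongside the matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

LCMS = "lcms"
MUX = "mux"

SURVIVOR = "survivor"
NON_SURVIVOR = "non-survivor"


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the simulated cohort.

    Defaults mirror the study geometry this generator emulates: 23
    survivors vs 11 non-survivors, 300 LC-MS proteins plus 63 multiplex
    proteins (363 total), 15 planted quantitative effects and 16 planted
    presence/absence effects, a 4-year (1460-day) follow-up.
    """

    n_survivors: int = 23
    n_nonsurvivors: int = 11
    n_proteins_lcms: int = 300
    n_proteins_mux: int = 63
    n_quant_dap: int = 15
    n_qual_dap: int = 16
    effect_log2fc: float = 2.0
    detect_prob_present: float = 0.9
    detect_prob_absent: float = 0.1
    missing_rate: float = 0.03
    censor_quantile: float = 0.10
    followup_days: int = 1460
    seed: int = 46

    # log2-scale per-protein spread; baseline log2 means are drawn U(3, 10)
    log2_sd: float = 1.0

    def validate(self) -> None:
        counts = {
            "n_survivors": self.n_survivors,
            "n_nonsurvivors": self.n_nonsurvivors,
            "n_proteins_lcms": self.n_proteins_lcms,
            "followup_days": self.followup_days,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.n_proteins_mux < 0 or self.n_quant_dap < 0 or self.n_qual_dap < 0:
            raise ValueError("protein and effect counts must be non-negative")
        for name in ("detect_prob_present", "detect_prob_absent",
                     "missing_rate", "censor_quantile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        total = self.n_proteins_lcms + self.n_proteins_mux
        if self.n_quant_dap + self.n_qual_dap > total:
            raise ValueError(
                f"infeasible spec: {self.n_quant_dap} quantitative + "
                f"{self.n_qual_dap} qualitative planted effects exceed the "
                f"{total} proteins available"
            )

    @property
    def n_patients(self) -> int:
        return self.n_survivors + self.n_nonsurvivors

    @property
    def n_proteins(self) -> int:
        return self.n_proteins_lcms + self.n_proteins_mux


@dataclass
class SyntheticCohort:
    """Generated cohort: abundance table, patient metadata and planted truth."""

    abundance: pd.DataFrame      # patients x proteins, linear scale, NaN = missing
    metadata: pd.DataFrame       # status, days_survival, frequent_exacerbator
    truth: dict = field(default_factory=dict)
    spec: CohortSpec | None = None

    def write(self, outdir: str | Path) -> None:
        """Write abundance TSV, metadata TSV and truth JSON to ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.abundance.to_csv(outdir / "abundance.tsv", sep="\t",
                              index_label="patient", na_rep="")
        self.metadata.to_csv(outdir / "metadata.tsv", sep="\t",
                             index_label="patient")
        with open(outdir / "truth.json", "w") as fh:
            payload = dict(self.truth)
            if self.spec is not None:
                payload["spec"] = asdict(self.spec)
            json.dump(payload, fh, indent=2)


def _protein_names(spec: CohortSpec) -> list[str]:
    lcms = [f"P{i:04d}:{LCMS}" for i in range(spec.n_proteins_lcms)]
    mux = [f"M{i:03d}:{MUX}" for i in range(spec.n_proteins_mux)]
    return lcms + mux


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one synthetic cohort from ``spec``.

    Quantitative planted effects shift the non-survivor mean upward by
    ``effect_log2fc`` on the log2 scale. Presence/absence effects toggle
    the per-group detection probability, alternating which outcome group
    is the "present" one. Missingness is the union of left censoring at
    the protein's null-distribution ``censor_quantile`` (MNAR; the
    detection limit is a property of the assay, so it is computed from
    the baseline distribution, not the realized sample) and an
    independent ``missing_rate`` dropout (MCAR).

    Days of survival for non-survivors follow an exponential waiting
    time truncated to the follow-up window, with log-linear rate in a
    latent risk score built from the planted quantitative markers.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n, p = spec.n_patients, spec.n_proteins
    names = _protein_names(spec)
    patients = [f"PT{i:03d}" for i in range(n)]
    status = np.array([SURVIVOR] * spec.n_survivors
                      + [NON_SURVIVOR] * spec.n_nonsurvivors)
    is_dead = status == NON_SURVIVOR

    # planted effect positions: quantitative first, qualitative next
    dap_idx = rng.choice(p, size=spec.n_quant_dap + spec.n_qual_dap,
                         replace=False)
    quant_idx = np.sort(dap_idx[: spec.n_quant_dap])
    qual_idx = np.sort(dap_idx[spec.n_quant_dap:])

    base_mean = rng.uniform(3.0, 10.0, size=p)          # log2 units
    log2 = rng.normal(base_mean, spec.log2_sd, size=(n, p))
    log2[np.ix_(is_dead, quant_idx)] += spec.effect_log2fc

    # left censoring at the null-distribution quantile of each protein
    missing = np.zeros((n, p), dtype=bool)
    if spec.censor_quantile > 0:
        lod = base_mean + spec.log2_sd * stats.norm.ppf(spec.censor_quantile)
        missing |= log2 < lod[None, :]
    if spec.missing_rate > 0:
        missing |= rng.random((n, p)) < spec.missing_rate

    # presence/absence block: detection governed solely by group-dependent
    # Bernoulli draws; alternate which group carries the protein
    qual_dir = np.empty(spec.n_qual_dap, dtype=int)
    for k, j in enumerate(qual_idx):
        present_in_dead = k % 2 == 0
        qual_dir[k] = 1 if present_in_dead else -1
        p_det = np.where(is_dead == present_in_dead,
                         spec.detect_prob_present, spec.detect_prob_absent)
        missing[:, j] = rng.random(n) >= p_det

    values = np.power(2.0, log2)
    values[missing] = np.nan
    abundance = pd.DataFrame(values, index=patients, columns=names)

    # survival times: exponential with log-linear risk on planted markers,
    # administratively censored at followup_days
    risk = np.zeros(n)
    if spec.n_quant_dap > 0:
        z = (log2[:, quant_idx] - base_mean[quant_idx]) / spec.log2_sd
        risk = z.mean(axis=1)
    base_rate = 1.0 / 1500.0         # ~1500-day mean latent waiting time
    rate = base_rate * np.exp(0.3 * risk)
    days = np.full(n, spec.followup_days, dtype=int)
    u = rng.random(n)
    # inverse CDF of the exponential truncated to (0, followup_days)
    t_max = spec.followup_days
    trunc = -np.log1p(-u * (1.0 - np.exp(-rate * t_max))) / rate
    days[is_dead] = np.maximum(1, np.ceil(trunc[is_dead]).astype(int))
    days[is_dead] = np.minimum(days[is_dead], t_max - 1)

    # frequent-exacerbator flag with death-dependent probability (7/23 alive,
    # 7/11 dead in the emulated cohort)
    p_fe = np.where(is_dead, 7 / 11, 7 / 23)
    fe = rng.random(n) < p_fe

    metadata = pd.DataFrame(
        {
            "status": status,
            "days_survival": days,
            "frequent_exacerbator": fe.astype(int),
            "on_antihemostatics": (rng.random(n) < 0.3).astype(int),
        },
        index=patients,
    )

    quant_dir = np.ones(spec.n_quant_dap, dtype=int)  # planted upward in dead
    truth = {
        "quant_dap": {names[j]: int(d) for j, d in zip(quant_idx, quant_dir)},
        "qual_dap": {names[j]: int(d) for j, d in zip(qual_idx, qual_dir)},
    }
    return SyntheticCohort(abundance=abundance, metadata=metadata,
                           truth=truth, spec=spec)
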