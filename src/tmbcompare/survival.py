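"""Quartile stratification and survival analysis of TMB cohorts.

Samples are split into TMB quartiles — pan-cohort or within each tumor
type — and overall survival is compared across quartiles with Kaplan-Meier
curves and an unadjusted Cox proportional-hazards model (quartile as a
categorical covariate, hazard ratios vs a reference quartile).

Kaplan-Meier estimation uses lifelines; the Cox partial likelihood is fit
with statsmodels' PHReg (Efron tie handling by default, Breslow available).
Contrasts against any reference quartile are derived from a single fit by
linear transformation of the coefficient vector and its covariance, so
re-referencing is exact (HRs invert precisely, not merely to optimizer
tolerance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "ClinicalRecord",
    "QuartileAssignment",
    "CoxResult",
    "read_clinical",
    "assign_quartiles",
    "km_curve",
    "cox_quartile_hr",
    "survival_report",
]

logger = logging.getLogger(__name__)

QUARTILES = ("Q1", "Q2", "Q3", "Q4")
_Z95 = 1.959964


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    tumor_type: str
    os_days: float
    event: int

    def __post_init__(self) -> None:
        if self.os_days < 0:
            raise ValueError("os_days must be non-negative")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV: sample_id, tumor_type, os_days, event.

    Rows with missing follow-up time are dropped with a logged count;
    zero-time records are retained.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tumor_type": str})
    required = {"sample_id", "tumor_type", "os_days", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    n0 = len(df)
    df = df.dropna(subset=["os_days", "event"])
    if len(df) < n0:
        logger.warning("dropped %d clinical rows with missing follow-up", n0 - len(df))
    df = df.astype({"os_days": float, "event": int})
    if (df["os_days"] < 0).any() or not df["event"].isin([0, 1]).all():
        raise ValueError("invalid os_days or event values in clinical table")
    return df.reset_index(drop=True)


@dataclass
class QuartileAssignment:
    """Sample -> quartile labels with the cut points that produced them.

    ``cuts`` maps each stratum (``"ALL"`` in pan-cohort mode, tumor types in
    intra mode) to its (c25, c50, c75) percentile values.  Q4 is the highest
    25% of TMB; ties at a cut fall in the lower quartile (the <= rule).
    """

    mode: str
    cuts: dict[str, tuple[float, float, float]]
    groups: pd.Series  # index sample_id, values Q1..Q4
    quantile_method: str = "linear"
    skipped_strata: dict[str, str] = field(default_factory=dict)


def _quartile_labels(values: np.ndarray, cuts: tuple[float, float, float]) -> np.ndarray:
    c25, c50, c75 = cuts
    labels = np.full(len(values), "Q4", dtype=object)
    labels[values <= c75] = "Q3"
    labels[values <= c50] = "Q2"
    labels[values <= c25] = "Q1"
    return labels


def assign_quartiles(
    tmb_by_sample: Mapping[str, float] | pd.Series,
    clinical: pd.DataFrame,
    mode: str = "pan_cohort",
    min_stratum: int = 8,
) -> QuartileAssignment:
    """Split samples into TMB quartiles, pan-cohort or per tumor type.

    Cut points are the empirical 25/50/75 percentiles with linear
    interpolation between order statistics (the quantile definition is
    recorded on the result because membership near a cut depends on it).
    Strata with fewer than ``min_stratum`` samples are skipped with a
    warning; a stratum whose TMB values are all identical admits only a
    single group and raises in pan-cohort mode (it is recorded and skipped
    in intra mode).
    """
    if mode not in ("pan_cohort", "intra_tumor_type"):
        raise ValueError(f"unknown mode {mode!r}")
    tmb = pd.Series(dict(tmb_by_sample)) if not isinstance(tmb_by_sample, pd.Series) else tmb_by_sample
    merged = clinical[["sample_id", "tumor_type"]].copy()
    merged = merged[merged["sample_id"].isin(tmb.index)]
    merged["tmb"] = tmb.loc[merged["sample_id"]].to_numpy()
    merged["stratum"] = "ALL" if mode == "pan_cohort" else merged["tumor_type"]

    cuts: dict[str, tuple[float, float, float]] = {}
    skipped: dict[str, str] = {}
    labels = pd.Series(index=pd.Index([], name="sample_id"), dtype=object)
    for stratum, sub in merged.groupby("stratum", sort=True):
        vals = sub["tmb"].to_numpy()
        if len(vals) < min_stratum:
            skipped[str(stratum)] = f"fewer than {min_stratum} samples"
            logger.warning("stratum %s skipped: %d samples", stratum, len(vals))
            continue
        if np.ptp(vals) == 0:
            if mode == "pan_cohort":
                raise ValueError("all TMB values identical: only a single group exists")
            skipped[str(stratum)] = "constant TMB (single group)"
            logger.warning("stratum %s skipped: constant TMB", stratum)
            continue
        c = tuple(float(v) for v in np.percentile(vals, [25, 50, 75], method="linear"))
        cuts[str(stratum)] = c  # type: ignore[assignment]
        lab = _quartile_labels(vals, c)  # type: ignore[arg-type]
        labels = pd.concat([labels, pd.Series(lab, index=sub["sample_id"].to_numpy())])
    if not cuts:
        raise ValueError("no stratum could be quartiled")
    labels.index.name = "sample_id"
    return QuartileAssignment(mode=mode, cuts=cuts, groups=labels, skipped_strata=skipped)


def km_curve(clinical: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate of S(t) for one group.

    Returns a table (time, n_risk, n_event, n_censored, survival) with one
    row per distinct observed time; S(0) = 1 and steps occur only at event
    times.
    """
    if len(clinical) == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(clinical["os_days"], event_observed=clinical["event"])
    et = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": et.index.to_numpy(dtype=float),
            "n_risk": et["at_risk"].to_numpy(dtype=int),
            "n_event": et["observed"].to_numpy(dtype=int),
            "n_censored": et["censored"].to_numpy(dtype=int),
            "survival": surv.loc[et.index].to_numpy(dtype=float),
        }
    )
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class CoxResult:
    """One quartile contrast from the proportional-hazards fit."""

    contrast: str
    hr: float
    ci_low: float
    ci_high: float
    n_group: int
    n_events: int
    ties_method: str
    flagged: bool = False
    note: str = ""


def cox_quartile_hr(
    clinical: pd.DataFrame,
    qa: QuartileAssignment,
    reference: str = "Q1",
    ties: str = "efron",
) -> list[CoxResult]:
    """Hazard ratios of each TMB quartile against a reference quartile.

    Quartile enters the partial likelihood as a categorical covariate
    (three indicator contrasts).  Groups with no observed events produce a
    monotone likelihood; they are flagged (hr 0, upper bound infinite) and
    excluded from the fit rather than aborting the analysis.  The reference
    group must contain at least one event.
    """
    if reference not in QUARTILES:
        raise ValueError(f"reference must be one of {QUARTILES}")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    df = clinical.merge(
        qa.groups.rename("quartile"), left_on="sample_id", right_index=True, how="inner"
    )
    if df.empty:
        raise ValueError("no overlap between clinical table and quartile assignment")
    counts = df.groupby("quartile")["event"].agg(["size", "sum"])
    present = [q for q in QUARTILES if q in counts.index]
    if reference not in present:
        raise ValueError(f"reference group {reference} absent from data")
    if counts.loc[reference, "sum"] < 1:
        raise ValueError(f"reference group {reference} has no events")

    flagged = [q for q in present if q != reference and counts.loc[q, "sum"] == 0]
    fit_groups = [q for q in present if q not in flagged]
    results: list[CoxResult] = []
    for q in flagged:
        results.append(
            CoxResult(
                contrast=f"{q} vs {reference}",
                hr=0.0,
                ci_low=0.0,
                ci_high=np.inf,
                n_group=int(counts.loc[q, "size"]),
                n_events=0,
                ties_method=ties,
                flagged=True,
                note="no events in group: monotone likelihood",
            )
        )

    sub = df[df["quartile"].isin(fit_groups)]
    # Fit once against the lexicographically first group, then re-reference
    # by exact linear transformation of (beta, cov).
    base = sorted(fit_groups)[0]
    others = [q for q in sorted(fit_groups) if q != base]
    if not others:
        return results
    exog = np.column_stack([(sub["quartile"] == q).to_numpy(float) for q in others])
    model = PHReg(sub["os_days"].to_numpy(), exog, status=sub["event"].to_numpy(), ties=ties)
    fit = model.fit(disp=False)
    beta = {q: b for q, b in zip(others, fit.params)}
    beta[base] = 0.0
    cov = pd.DataFrame(fit.cov_params(), index=others, columns=others)
    cov[base] = 0.0
    cov.loc[base] = 0.0

    for q in sorted(fit_groups):
        if q == reference:
            continue
        b = beta[q] - beta[reference]
        var = cov.loc[q, q] + cov.loc[reference, reference] - 2 * cov.loc[q, reference]
        se = float(np.sqrt(var))
        results.append(
            CoxResult(
                contrast=f"{q} vs {reference}",
                hr=float(np.exp(b)),
                ci_low=float(np.exp(b - _Z95 * se)),
                ci_high=float(np.exp(b + _Z95 * se)),
                n_group=int(counts.loc[q, "size"]),
                n_events=int(counts.loc[q, "sum"]),
                ties_method=ties,
            )
        )
    results.sort(key=lambda r: r.contrast)
    return results


def survival_report(
    tmb: pd.DataFrame,
    clinical: pd.DataFrame,
    methods: list[str] | None = None,
    mode: str = "pan_cohort",
    reference: str = "Q1",
    ties: str = "efron",
    min_shared: int = 8,
) -> tuple[pd.DataFrame, dict[tuple[str, str, str], pd.DataFrame]]:
    """Quartile Cox HRs (and KM tables) for each TMB method.

    ``tmb`` is a samples x methods frame.  Samples are inner-joined with the
    clinical table on sample_id (mismatches logged).  Methods with constant
    TMB are skipped with a warning.  Returns the tidy HR table (method,
    stratum, contrast, hr, ci_low, ci_high, n, events, flagged) and a dict
    of KM tables keyed by (method, stratum, quartile).
    """
    methods = methods if methods is not None else list(tmb.columns)
    shared = set(tmb.index) & set(clinical["sample_id"])
    n_lost = len(set(tmb.index) ^ set(clinical["sample_id"]))
    if n_lost:
        logger.info("inner join: %d samples present in only one table", n_lost)
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} samples shared between TMB and clinical tables")
    clin = clinical[clinical["sample_id"].isin(shared)]

    rows = []
    km_tables: dict[tuple[str, str, str], pd.DataFrame] = {}
    for method in methods:
        col = tmb.loc[tmb.index.isin(shared), method]
        if np.ptp(col.to_numpy()) == 0:
            logger.warning("method %s skipped: constant TMB", method)
            continue
        try:
            qa = assign_quartiles(col, clin, mode=mode)
        except ValueError as exc:
            logger.warning("method %s skipped: %s", method, exc)
            continue
        strata = (
            {"ALL": clin}
            if mode == "pan_cohort"
            else {t: g for t, g in clin.groupby("tumor_type") if t in qa.cuts}
        )
        for stratum, sclin in strata.items():
            sclin = sclin.merge(
                qa.groups.rename("quartile"), left_on="sample_id", right_index=True
            )
            for q in QUARTILES:
                grp = sclin[sclin["quartile"] == q]
                if len(grp):
                    km_tables[(method, stratum, q)] = km_curve(grp)
            try:
                cox = cox_quartile_hr(sclin.drop(columns="quartile"), qa, reference, ties)
            except ValueError as exc:
                logger.warning("Cox fit skipped for %s/%s: %s", method, stratum, exc)
                continue
            for res in cox:
                rows.append(
                    {
                        "method": method,
                        "stratum": stratum,
                        "contrast": res.contrast,
                        "hr": res.hr,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "n": res.n_group,
                        "events": res.n_events,
                        "flagged": res.flagged,
                    }
                )
    if not rows:
        raise ValueError("no method yielded a survival fit")
    return pd.DataFrame(rows), km_tables
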