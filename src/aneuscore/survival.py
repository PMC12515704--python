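"""Time-to-event association of GWA status: KM, log-rank, Cox models.

Endpoints follow the treatment class: failure-free survival (FFS, start of
ARSI treatment to end of that treatment) for ARSI, time to next treatment
(TTNT, start of taxane to next line / best supportive care / death) for
taxanes.  Estimators are endpoint-agnostic: both are plain (time, event)
pairs and the endpoint semantics live in the labels.  Cox fits use the Efron
approximation for ties and report Wald 95% CIs and p-values, matching the
usual "HR (95% CI), P" table shape.  Patients contributing several treatment
lines are treated as independent records (a documented limitation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

TREATMENTS = ("ARSI", "taxane")
ENDPOINT_FOR_TREATMENT = {"ARSI": "FFS", "taxane": "TTNT"}
DYNAMICS_LABELS = ("GWAlow", "GWAswitch", "GWAhigh")


@dataclass(frozen=True)
class ClinicalRecord:
    """One treatment line of one patient: outcome plus GWA labels."""

    patient_id: str
    treatment: str
    time: float
    event: bool
    endpoint: str = ""
    status_bl: Optional[str] = None
    status_et: Optional[str] = None
    dynamics: Optional[str] = None

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")
        expected_ep = ENDPOINT_FOR_TREATMENT[self.treatment]
        if self.endpoint == "":
            object.__setattr__(self, "endpoint", expected_ep)
        elif self.endpoint != expected_ep:
            raise ValueError(
                f"endpoint {self.endpoint!r} inconsistent with treatment "
                f"{self.treatment!r} (expected {expected_ep})"
            )
        if not self.time > 0:
            raise ValueError("time must be positive")
        for s in (self.status_bl, self.status_et):
            if s is not None and s not in ("low", "high"):
                raise ValueError(f"GWA status must be 'low' or 'high', got {s!r}")
        if self.dynamics is not None:
            if self.dynamics not in DYNAMICS_LABELS:
                raise ValueError(f"dynamics must be one of {DYNAMICS_LABELS}")
            if self.status_bl is not None and self.status_et is not None:
                from .gwa import classify_dynamics

                if classify_dynamics(self.status_bl, self.status_et) != self.dynamics:
                    raise ValueError("dynamics label inconsistent with statuses")


@dataclass(frozen=True)
class SurvivalFit:
    """A fitted Cox model: per-term log-hazards, HRs, Wald CIs, p-values."""

    terms: tuple[str, ...]
    coef: tuple[float, ...]
    hazard_ratio: tuple[float, ...]
    ci_low: tuple[float, ...]
    ci_high: tuple[float, ...]
    p_value: tuple[float, ...]
    n: int
    n_events: int

    def __getitem__(self, term: str) -> dict[str, float]:
        i = self.terms.index(term)
        return {
            "coef": self.coef[i],
            "hazard_ratio": self.hazard_ratio[i],
            "ci_low": self.ci_low[i],
            "ci_high": self.ci_high[i],
            "p_value": self.p_value[i],
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "hazard_ratio": self.hazard_ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_value": self.p_value,
            }
        )


def records_to_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "treatment": [r.treatment for r in records],
            "endpoint": [r.endpoint for r in records],
            "time_days": [r.time for r in records],
            "event": [int(r.event) for r in records],
            "status_bl": [r.status_bl for r in records],
            "status_et": [r.status_et for r in records],
            "dynamics": [r.dynamics for r in records],
        }
    )


def records_from_frame(df: pd.DataFrame) -> list[ClinicalRecord]:
    """Build records from a clinical CSV frame (see ``records_to_frame``)."""

    def _opt(v):
        return None if pd.isna(v) else str(v)

    out = []
    for _, row in df.iterrows():
        dynamics = _opt(row.get("dynamics")) if "dynamics" in df.columns else None
        out.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                treatment=str(row["treatment"]),
                time=float(row["time_days"]),
                event=bool(int(row["event"])),
                status_bl=_opt(row.get("status_bl")),
                status_et=_opt(row.get("status_et")),
                dynamics=dynamics,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival curve and median survival time.

    ``median`` is the earliest time at which the estimated survival drops to
    0.5 or below; NaN when never reached.
    """

    table: pd.DataFrame = field(repr=False)
    median: float
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        past = self.table[self.table["time"] <= t]
        return 1.0 if past.empty else float(past["survival"].iloc[-1])


def km_estimate(records: Sequence[ClinicalRecord]) -> KMEstimate:
    """Kaplan-Meier estimate over one group of records."""
    if not records:
        raise ValueError("need at least one record")
    times = [r.time for r in records]
    events = [int(r.event) for r in records]
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    surv = kmf.survival_function_
    table = pd.DataFrame(
        {"time": surv.index.to_numpy(float), "survival": surv.iloc[:, 0].to_numpy(float)}
    )
    median = float(kmf.median_survival_time_)
    if np.isinf(median):
        median = float("nan")
    return KMEstimate(table=table, median=median, n=len(records), n_events=sum(events))


def logrank_test(groups: Sequence[Sequence[ClinicalRecord]]) -> tuple[float, float]:
    """Log-rank test across two or more groups (chi-square, df = groups - 1)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two nonempty groups")
    if not any(r.event for g in groups for r in g):
        raise ValueError("no events in any group")
    times, events, labels = [], [], []
    for i, g in enumerate(groups):
        for r in g:
            times.append(r.time)
            events.append(int(r.event))
            labels.append(i)
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox regression


def _indicator(record: ClinicalRecord, term: str, timepoint: str) -> float:
    status = record.status_bl if timepoint == "baseline" else record.status_et
    if term == "treatment":
        return float(record.treatment == "taxane")
    if term == "gwa":
        if status is None:
            raise ValueError(
                f"record {record.patient_id} lacks GWA status at {timepoint}"
            )
        return float(status == "high")
    if term == "interaction":
        return _indicator(record, "treatment", timepoint) * _indicator(
            record, "gwa", timepoint
        )
    if term == "dyn_switch":
        return float(record.dynamics == "GWAswitch")
    if term == "dyn_high":
        return float(record.dynamics == "GWAhigh")
    raise ValueError(f"unknown covariate term {term!r}")


def design_matrix(
    records: Sequence[ClinicalRecord],
    covariates: Sequence[str],
    timepoint: str = "baseline",
) -> pd.DataFrame:
    """(time, event, covariates) frame for Cox fitting.

    Supported terms: ``treatment`` (1 = taxane), ``gwa`` (1 = high at the
    chosen timepoint), ``interaction`` (their product), and the dynamics
    dummies ``dyn_switch`` / ``dyn_high`` (reference GWAlow).
    """
    if timepoint not in ("baseline", "early"):
        raise ValueError("timepoint must be 'baseline' or 'early'")
    data = {
        "time": [r.time for r in records],
        "event": [int(r.event) for r in records],
    }
    for term in covariates:
        data[term] = [_indicator(r, term, timepoint) for r in records]
    return pd.DataFrame(data)


def cox_fit(
    records: Sequence[ClinicalRecord],
    covariates: Sequence[str],
    timepoint: str = "baseline",
) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron ties, Wald 95% CIs).

    Raises
    ------
    ValueError
        On non-convergence (with lifelines' iteration diagnostics) or
        apparent complete separation, suggesting an exact or penalized fit.
    """
    df = design_matrix(records, covariates, timepoint)
    if df["event"].sum() == 0:
        raise ValueError("no events: Cox model cannot be fit")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise ValueError(f"Cox fit did not converge: {exc}") from exc
    summary = cph.summary
    if np.any(np.abs(summary["coef"].to_numpy()) > 15):
        raise ValueError(
            "apparent complete separation (|log-HR| > 15); consider an exact "
            "or penalized fit"
        )
    return SurvivalFit(
        terms=tuple(summary.index),
        coef=tuple(float(v) for v in summary["coef"]),
        hazard_ratio=tuple(float(v) for v in summary["exp(coef)"]),
        ci_low=tuple(float(v) for v in summary["exp(coef) lower 95%"]),
        ci_high=tuple(float(v) for v in summary["exp(coef) upper 95%"]),
        p_value=tuple(float(v) for v in summary["p"]),
        n=len(records),
        n_events=int(df["event"].sum()),
    )


def interaction_model(
    records: Sequence[ClinicalRecord], timepoint: str = "baseline"
) -> SurvivalFit:
    """Cox fit with treatment, GWA status, and treatment x GWA interaction.

    Reference levels are ARSI and GWA-low, so the three reported hazard
    ratios correspond to taxane vs ARSI, high vs low, and their product
    term.  Any empty treatment x status cell is an error naming the stratum.
    """
    for trt in TREATMENTS:
        for status in ("low", "high"):
            if not any(
                r.treatment == trt
                and _indicator(r, "gwa", timepoint) == float(status == "high")
                for r in records
            ):
                raise ValueError(f"empty stratum: {trt}/GWA-{status} at {timepoint}")
    return cox_fit(records, ["treatment", "gwa", "interaction"], timepoint)


def dynamics_analysis(records: Sequence[ClinicalRecord]) -> SurvivalFit:
    """Cox fit of GWAswitch and GWAhigh vs the GWAlow reference group."""
    labels = {r.dynamics for r in records}
    missing = set(DYNAMICS_LABELS) - labels
    if missing:
        raise ValueError(f"missing dynamics groups: {', '.join(sorted(missing))}")
    for lab in DYNAMICS_LABELS:
        if sum(r.dynamics == lab for r in records) < 2:
            warnings.warn(
                f"dynamics group {lab} has a single record; fit may be unstable",
                stacklevel=2,
            )
    return cox_fit(records, ["dyn_switch", "dyn_high"])
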