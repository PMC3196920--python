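"""Median-split survival analysis and clinical descriptive statistics.

Patients are labelled *high* or *low* by a gene's cohort-median log2
expression, and the two strata are compared with the Kaplan-Meier
product-limit estimator and the (unweighted) log-rank test.  Event
indicators are reconstructed from follow-up status: a death is an event
for overall survival (OVS); for event-free survival (EFS) an event is a
death or any earlier event revealed by EFS < OVS (e.g. a relapse
preceding last follow-up); patients alive with EFS equal to OVS are
censored for both endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalRecord, ExpressionMatrix, GeneList

ENDPOINTS = ("EFS", "OVS")


@dataclass
class SurvivalInput:
    sample_id: str
    time: float
    event: bool
    group: str  # "high" or "low"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"{self.sample_id}: negative survival time")


@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class ClinicalSummary:
    n: int
    mean_age: float
    mean_efs: float
    mean_ovs: float
    median_followup: float
    male_to_female: float | None
    n_primary: int
    n_recurrence: int
    n_metastasis: int


def median_split(expr_values: pd.Series) -> pd.Series:
    """Label samples high/low relative to the cohort median expression.

    The median of an even-length cohort is the midpoint of the two
    central order statistics.  Values strictly above the median are
    ``high``; ties at the median go to ``low``.
    """
    values = pd.Series(expr_values, dtype=float)
    if len(values) < 4:
        raise ValueError("median split needs at least 4 samples")
    if values.nunique() == 1:
        raise ValueError("all expression values identical; no median split possible")
    med = float(np.median(values.to_numpy()))
    return pd.Series(np.where(values.to_numpy() > med, "high", "low"), index=values.index)


def km_estimate(inputs: list[SurvivalInput]) -> KMCurve:
    """Kaplan-Meier product-limit estimator for one group.

    S(t) = prod over distinct event times t_i <= t of (1 - d_i / n_i)
    with d_i events among n_i subjects still at risk; censored subjects
    leave the risk set just after their censoring time.
    """
    if not inputs:
        raise ValueError("need at least one subject")
    times = np.array([s.time for s in inputs])
    events = np.array([s.event for s in inputs], dtype=bool)
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]

    event_times = np.unique(times[events])
    at_risk = np.empty(event_times.size, dtype=int)
    n_events = np.empty(event_times.size, dtype=int)
    surv = np.empty(event_times.size)
    s = 1.0
    for i, t in enumerate(event_times):
        n_i = int(np.sum(times >= t))
        d_i = int(np.sum(events & (times == t)))
        s *= 1.0 - d_i / n_i
        at_risk[i], n_events[i], surv[i] = n_i, d_i, s
    return KMCurve(event_times, surv, at_risk, n_events)


def logrank_test(
    group_high: list[SurvivalInput], group_low: list[SurvivalInput]
) -> tuple[float, float]:
    """Unweighted two-group log-rank test (1 df, two-sided).

    At each distinct event time the observed number of events in the
    first group is compared with its hypergeometric expectation given the
    risk sets; the variance uses the tie-corrected hypergeometric form.
    Returns (chi-square statistic, p-value).
    """
    if not group_high or not group_low:
        raise ValueError("both groups must be non-empty")
    t1 = np.array([s.time for s in group_high])
    e1 = np.array([s.event for s in group_high], dtype=bool)
    t2 = np.array([s.time for s in group_low])
    e2 = np.array([s.event for s in group_low], dtype=bool)
    if not (e1.any() or e2.any()):
        raise ValueError("log-rank test requires at least one event")

    event_times = np.unique(np.concatenate([t1[e1], t2[e2]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = np.sum(t1 >= t)
        n2 = np.sum(t2 >= t)
        n = n1 + n2
        d1 = np.sum(e1 & (t1 == t))
        d2 = np.sum(e2 & (t2 == t))
        d = d1 + d2
        if n < 2:
            continue
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def event_indicator(record: ClinicalRecord, endpoint: str) -> tuple[float, bool]:
    """(time, event) pair for a clinical record under a given endpoint.

    OVS: event iff the patient died; time is overall survival.  EFS:
    event iff the patient died or an earlier event occurred (EFS < OVS);
    time is event-free survival.  Alive patients with EFS = OVS are
    censored under both endpoints.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    if endpoint == "OVS":
        return record.ovs, record.status == "Dead"
    return record.efs, record.status == "Dead" or record.efs < record.ovs


def clinical_summary(records: list[ClinicalRecord]) -> ClinicalSummary:
    """Descriptive summary of a clinical table (means, follow-up, sex ratio)."""
    if not records:
        raise ValueError("no clinical records")
    ages = np.array([r.age for r in records], dtype=float)
    efs = np.array([r.efs for r in records], dtype=float)
    ovs = np.array([r.ovs for r in records], dtype=float)
    n_m = sum(r.sex == "M" for r in records)
    n_f = sum(r.sex == "F" for r in records)
    return ClinicalSummary(
        n=len(records),
        mean_age=float(ages.mean()),
        mean_efs=float(efs.mean()),
        mean_ovs=float(ovs.mean()),
        median_followup=float(np.median(ovs)),
        male_to_female=(n_m / n_f) if n_f else None,
        n_primary=sum(r.state == "Primary" for r in records),
        n_recurrence=sum(r.state == "Recurrence" for r in records),
        n_metastasis=sum(r.state == "Metastasis" for r in records),
    )


def survival_inputs_for_gene(
    expr_values: pd.Series,
    clinical: list[ClinicalRecord],
    endpoint: str,
) -> tuple[list[SurvivalInput], list[SurvivalInput]]:
    """Median-split one gene's expression and build the two survival strata."""
    by_code = {r.sample_code: r for r in clinical}
    orphans = sorted(set(expr_values.index) ^ set(by_code))
    if orphans:
        raise ValueError(f"sample ids mismatch between expression and clinical: {orphans}")
    labels = median_split(expr_values)
    high, low = [], []
    for sid, label in labels.items():
        time, event = event_indicator(by_code[sid], endpoint)
        (high if label == "high" else low).append(SurvivalInput(sid, time, event, label))
    return high, low


def survival_screen(
    expr: ExpressionMatrix,
    genes: GeneList,
    clinical: list[ClinicalRecord],
    endpoint: str = "EFS",
) -> pd.DataFrame:
    """Per-gene median-split log-rank screen, sorted by p-value.

    For each gene in the list (and present in the matrix) the patients
    are split at the median expression and the two strata compared with
    the log-rank test on the chosen endpoint.  Returns a table with
    columns gene, endpoint, n_high, n_low, chi2, p, plus the direction of
    benefit (sign of the high-group observed-minus-expected events).
    """
    found = [g for g in genes if g in expr.data.index]
    if not found:
        raise ValueError("no screen gene present in the expression matrix")
    rows = []
    for gene in found:
        high, low = survival_inputs_for_gene(expr.data.loc[gene], clinical, endpoint)
        chi2, p = logrank_test(high, low)
        high_curve = km_estimate(high) if any(s.event for s in high) else None
        low_curve = km_estimate(low) if any(s.event for s in low) else None
        # crude direction: compare stratum survival at the last shared time
        direction = ""
        if high_curve is not None and low_curve is not None:
            t_ref = min(high_curve.event_times[-1], low_curve.event_times[-1])
            diff = high_curve.survival_at(t_ref) - low_curve.survival_at(t_ref)
            direction = "protective" if diff > 0 else ("adverse" if diff < 0 else "")
        elif high_curve is None and low_curve is not None:
            direction = "protective"
        elif low_curve is None and high_curve is not None:
            direction = "adverse"
        rows.append(
            {
                "gene": gene,
                "endpoint": endpoint,
                "n_high": len(high),
                "n_low": len(low),
                "chi2": chi2,
                "p": p,
                "high_group_effect": direction,
            }
        )
    out = pd.DataFrame(rows).sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)
    return out
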