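"""Clinical-outcome summaries for a two-arm treatment cohort.

Covers best-response classification (ORR = CR+PR, DCR = CR+PR+SD under
RECIST v1.1), per-arm Fisher exact comparisons, landmark progression-free /
overall-survival rates, Kaplan-Meier curves with the log-rank test, and
patient-denominated adverse-event tables.

Landmark rates are patient-count proportions (``k (x.y%)`` arithmetic), not
Kaplan-Meier estimates: a patient is event-free at the horizon when their
observed time reaches the horizon. By default a patient censored before the
horizon counts as NOT event-free under this count convention; the number of
such patients is reported so the alternative reading (censored = still
event-free) can be checked via ``censored_event_free=True``. The KM
estimate at the horizon is reported alongside for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .errors import DataError, FormatError
from .stats import ContingencyTable2x2, GroupTestResult, fisher_exact_2x2

logger = logging.getLogger(__name__)

RESPONSES = ("CR", "PR", "SD", "PD")
ARMS = ("TP", "FP")
OUTCOME_FLAGS = {
    "ORR": ("CR", "PR"),
    "DCR": ("CR", "PR", "SD"),
    "CR": ("CR",),
    "PR": ("PR",),
    "SD": ("SD",),
    "PD": ("PD",),
}


@dataclass
class PatientRecord:
    """One patient: arm, best RECIST response, survival times, AEs."""

    patient_id: str
    regimen: str  # "TP" | "FP"
    best_response: str  # CR | PR | SD | PD
    pfs_months: float
    pfs_event: bool
    os_months: float
    os_event: bool
    ae_list: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.regimen not in ARMS:
            raise DataError(f"unknown regimen {self.regimen!r}")
        if self.best_response not in RESPONSES:
            raise DataError(f"unknown response code {self.best_response!r}")
        if self.pfs_months < 0 or self.os_months < 0:
            raise DataError("survival times must be non-negative")
        for term, grade in self.ae_list:
            if not 1 <= int(grade) <= 5:
                raise DataError(f"AE grade {grade} for {term!r} outside 1..5")

    @property
    def is_responder(self) -> bool:
        return self.best_response in OUTCOME_FLAGS["ORR"]


# ---------------------------------------------------------------------------
# Response classification


@dataclass
class CohortSummary:
    """Per-arm and total response counts and percentages."""

    counts: pd.DataFrame  # index = outcome rows, columns = total/TP/FP
    n_by_arm: dict[str, int]

    def percentage(self, outcome: str, arm: str = "total") -> float:
        n = sum(self.n_by_arm.values()) if arm == "total" else self.n_by_arm[arm]
        return round(100.0 * self.counts.loc[outcome, arm] / n, 1)


def classify_responses(patients: list[PatientRecord]) -> CohortSummary:
    if not patients:
        raise DataError("empty cohort")
    n_by_arm = {arm: sum(p.regimen == arm for p in patients) for arm in ARMS}
    rows = {}
    for outcome, members in OUTCOME_FLAGS.items():
        rows[outcome] = {
            "total": sum(p.best_response in members for p in patients),
            **{
                arm: sum(
                    p.best_response in members and p.regimen == arm for p in patients
                )
                for arm in ARMS
            },
        }
    counts = pd.DataFrame(rows).T[["total", *ARMS]]
    # reconciliation: CR+PR+SD+PD must account for every patient per arm
    for arm in ARMS:
        total = sum(counts.loc[r, arm] for r in RESPONSES)
        if total != n_by_arm[arm]:
            logger.warning(
                "arm %s: response categories sum to %d but arm has %d patients",
                arm, total, n_by_arm[arm],
            )
    return CohortSummary(counts=counts, n_by_arm=n_by_arm)


def arm_comparison(patients: list[PatientRecord], outcome: str) -> GroupTestResult:
    """Fisher exact test of one outcome flag across the two arms."""
    if outcome not in OUTCOME_FLAGS:
        raise DataError(f"unknown outcome flag {outcome!r}")
    arms_present = {p.regimen for p in patients}
    if len(arms_present) < 2:
        raise DataError("arm_comparison requires patients from both arms")
    members = OUTCOME_FLAGS[outcome]
    a = sum(p.regimen == "TP" and p.best_response in members for p in patients)
    b = sum(p.regimen == "TP" and p.best_response not in members for p in patients)
    c = sum(p.regimen == "FP" and p.best_response in members for p in patients)
    d = sum(p.regimen == "FP" and p.best_response not in members for p in patients)
    return fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))


# ---------------------------------------------------------------------------
# Landmark rates and Kaplan-Meier


@dataclass
class LandmarkResult:
    endpoint: str
    horizon: float
    counts: dict[str, int]  # arm -> event-free count
    n: dict[str, int]
    rates: dict[str, float]  # arm -> percent
    km_rates: dict[str, float]  # arm -> KM estimate at horizon (percent)
    censored_before: dict[str, int]
    fisher: GroupTestResult | None


def _times_events(patients, endpoint):
    if endpoint == "pfs":
        return [(p.pfs_months, p.pfs_event) for p in patients]
    if endpoint == "os":
        return [(p.os_months, p.os_event) for p in patients]
    raise DataError(f"unknown endpoint {endpoint!r} (expected 'pfs' or 'os')")


def landmark_rate(
    patients: list[PatientRecord],
    endpoint: str,
    horizon_months: float,
    censored_event_free: bool = False,
) -> LandmarkResult:
    """Patient-count landmark rate per arm with a Fisher exact comparison."""
    if horizon_months < 0:
        raise DataError("horizon must be non-negative")
    counts, n, rates, km_rates, censored = {}, {}, {}, {}, {}
    for arm in ARMS:
        arm_patients = [p for p in patients if p.regimen == arm]
        if not arm_patients:
            continue
        te = _times_events(arm_patients, endpoint)
        free = sum(
            t >= horizon_months or (censored_event_free and not e) for t, e in te
        )
        censored[arm] = sum(t < horizon_months and not e for t, e in te)
        counts[arm] = free
        n[arm] = len(arm_patients)
        rates[arm] = round(100.0 * free / len(arm_patients), 1)
        kmf = KaplanMeierFitter().fit(
            [t for t, _ in te], [e for _, e in te]
        )
        km_rates[arm] = round(
            100.0 * float(kmf.predict(horizon_months)), 1
        )
    fisher = None
    if len(counts) == 2:
        fisher = fisher_exact_2x2(
            ContingencyTable2x2(
                counts["TP"], n["TP"] - counts["TP"],
                counts["FP"], n["FP"] - counts["FP"],
            )
        )
    return LandmarkResult(
        endpoint=endpoint,
        horizon=horizon_months,
        counts=counts,
        n=n,
        rates=rates,
        km_rates=km_rates,
        censored_before=censored,
        fisher=fisher,
    )


@dataclass
class KMResult:
    endpoint: str
    curves: dict[str, pd.DataFrame]  # label -> (time, at_risk, survival)
    logrank_statistic: float | None
    logrank_p: float | None
    medians: dict[str, float]


def km_curve(
    patients: list[PatientRecord],
    endpoint: str,
    by: str = "regimen",
) -> KMResult:
    """Kaplan-Meier curves per group plus the two-group log-rank test.

    ``by`` is "regimen" (TP vs FP) or "response" (ORR vs non-ORR).

    Raises DataError if no events occurred at all (log-rank undefined); the
    fitted curves are attached to the exception as ``.curves``.
    """
    if by == "regimen":
        label = {p.patient_id: p.regimen for p in patients}
    elif by == "response":
        label = {
            p.patient_id: "ORR" if p.is_responder else "non_ORR" for p in patients
        }
    else:
        raise DataError(f"unknown grouping {by!r}")

    groups = sorted({label[p.patient_id] for p in patients})
    curves, medians, fitted = {}, {}, {}
    for g in groups:
        members = [p for p in patients if label[p.patient_id] == g]
        te = _times_events(members, endpoint)
        kmf = KaplanMeierFitter().fit(
            [t for t, _ in te], [e for _, e in te], label=g
        )
        fitted[g] = te
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {
                "time": sf.index.to_numpy(dtype=float),
                "at_risk": kmf.event_table["at_risk"].reindex(sf.index).to_numpy(),
                "survival": sf[g].to_numpy(),
            }
        )
        medians[g] = float(kmf.median_survival_time_)

    total_events = sum(e for p in patients for _, e in [_times_events([p], endpoint)[0]])
    if total_events == 0:
        err = DataError("log-rank test undefined: no events observed")
        err.curves = curves  # type: ignore[attr-defined]
        raise err
    stat = p = None
    if len(groups) == 2:
        a, b = (fitted[g] for g in groups)
        res = logrank_test(
            [t for t, _ in a], [t for t, _ in b],
            event_observed_A=[e for _, e in a],
            event_observed_B=[e for _, e in b],
        )
        stat, p = float(res.test_statistic), float(res.p_value)
    return KMResult(
        endpoint=endpoint,
        curves=curves,
        logrank_statistic=stat,
        logrank_p=p,
        medians=medians,
    )


# ---------------------------------------------------------------------------
# Adverse events


def ae_table(patients: list[PatientRecord]) -> pd.DataFrame:
    """Patient-denominated AE table: per-term counts plus rollups.

    A patient contributes once per term at their maximum grade for that
    term. Rollup rows: ``any_ae`` (>=1 AE of any grade), ``grade_ge3`` (max
    grade over all terms >= 3), ``grade_lt3`` (any AE but max grade < 3).
    """
    n_by_arm = {arm: sum(p.regimen == arm for p in patients) for arm in ARMS}
    n_total = len(patients)

    term_max: dict[str, dict[str, int]] = {}  # patient -> term -> max grade
    for p in patients:
        per = term_max.setdefault(p.patient_id, {})
        for term, grade in p.ae_list:
            grade = int(grade)
            if not 1 <= grade <= 5:
                raise DataError(f"AE grade {grade} outside 1..5")
            per[term] = max(per.get(term, 0), grade)

    arm_of = {p.patient_id: p.regimen for p in patients}
    terms = sorted({t for per in term_max.values() for t in per})

    def count(pred) -> dict[str, int]:
        out = {"total": 0, **{arm: 0 for arm in ARMS}}
        for pid, per in term_max.items():
            if per and pred(per):
                out["total"] += 1
                out[arm_of[pid]] += 1
        return out

    rows = {
        "any_ae": count(lambda per: True),
        "grade_ge3": count(lambda per: max(per.values()) >= 3),
        "grade_lt3": count(lambda per: max(per.values()) < 3),
    }
    for term in terms:
        rows[term] = count(lambda per, t=term: t in per)

    df = pd.DataFrame(rows).T
    for col, n in (("total", n_total), *((a, n_by_arm[a]) for a in ARMS)):
        df[f"{col}_pct"] = (100.0 * df[col] / n).round(1) if n else 0.0
    return df[["total", "total_pct", "TP", "TP_pct", "FP", "FP_pct"]]


# ---------------------------------------------------------------------------
# Cohort TSV I/O

_COHORT_COLUMNS = (
    "patient_id", "regimen", "best_response",
    "pfs_months", "pfs_event", "os_months", "os_event", "ae_list",
)


def _format_aes(ae_list: list[tuple[str, int]]) -> str:
    return ";".join(f"{term}:{grade}" for term, grade in ae_list)


def _parse_aes(s: str) -> list[tuple[str, int]]:
    if not s:
        return []
    out = []
    for item in s.split(";"):
        term, _, grade = item.rpartition(":")
        out.append((term, int(grade)))
    return out


def write_cohort_tsv(patients: list[PatientRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        (p.patient_id, p.regimen, p.best_response,
         f"{p.pfs_months:.6g}", int(p.pfs_event),
         f"{p.os_months:.6g}", int(p.os_event), _format_aes(p.ae_list))
        for p in patients
    ]
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_cohort_tsv(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    patients = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            patients.append(
                PatientRecord(
                    patient_id=row.patient_id,
                    regimen=row.regimen,
                    best_response=row.best_response,
                    pfs_months=float(row.pfs_months),
                    pfs_event=bool(int(row.pfs_event)),
                    os_months=float(row.os_months),
                    os_event=bool(int(row.os_event)),
                    ae_list=_parse_aes(row.ae_list),
                )
            )
        except (ValueError, DataError) as e:
            raise FormatError(f"{path}, line {i}: {e}") from None
    if not patients:
        raise DataError(f"{path}: empty cohort")
    return patients
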