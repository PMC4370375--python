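"""Person-year disaggregation for protracted exposures.

Poisson regression for cohort event-time data is equivalent to a piecewise
exponential survival model; each subject's follow-up is split into interval
records carrying person-time, an at-most-one event indicator, and the
cumulative (lagged) dose accrued per dosimetry realization.  The variance
correction then applies at the record level, with the record-level covariance
estimated across realizations -- records of one subject are automatically
correlated because their cumulative doses share annual terms.

Lag convention: a record covering ages [a, b) counts dose accrued strictly
before b - l for lag l, with uniform accrual within each exposure year.
Records ending within l years of first exposure therefore carry zero dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .realizations import DoseRealizations, DoseUncertaintyModel, empirical_covariance
from .risk_models import OutcomeData, RiskModelSpec, _mu_grad

__all__ = [
    "ExposureHistory",
    "PersonYearTable",
    "build_person_years",
    "build_person_year_table",
    "person_year_covariance",
    "piecewise_exponential_loglik",
    "load_histories",
]

Covariate = float | Callable[[float], float]


@dataclass
class ExposureHistory:
    """One subject's annual doses (per realization), follow-up, and covariates.

    ``annual_doses`` maps the integer age at which exposure was received (the
    year [age, age+1)) to a length-L vector of realized annual doses.
    ``background`` (A) and ``modifier`` (C) may be constants or functions of
    age evaluated at each record start.
    """

    subject_id: str
    annual_doses: Mapping[int, np.ndarray]
    entry_age: float
    exit_age: float
    event_age: float | None = None
    background: Covariate = 0.0
    modifier: Covariate = 0.0

    def __post_init__(self) -> None:
        if self.exit_age <= self.entry_age:
            raise ValueError("exit age must exceed entry age")
        if self.event_age is not None and not (
            self.entry_age < self.event_age <= self.exit_age
        ):
            raise ValueError(
                f"event age {self.event_age} outside ({self.entry_age}, {self.exit_age}]"
            )
        self.annual_doses = {
            int(a): np.atleast_1d(np.asarray(v, dtype=float))
            for a, v in self.annual_doses.items()
        }
        lengths = {v.shape[0] for v in self.annual_doses.values()}
        if len(lengths) > 1:
            raise ValueError("annual doses must have the same realization count")

    @property
    def n_realizations(self) -> int:
        return next(iter(self.annual_doses.values())).shape[0] if self.annual_doses else 1


@dataclass
class PersonYearTable:
    """Disaggregated person-year records plus cumulative lagged doses.

    ``records`` has one row per (subject, age interval); ``doses`` is
    records x L cumulative lagged dose, one column per realization.
    """

    records: pd.DataFrame
    doses: np.ndarray

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_realizations(self) -> int:
        return self.doses.shape[1]

    def to_outcome_data(self, realization: int | str = "mean") -> OutcomeData:
        """OutcomeData with events as counts, person-time as offset, and
        either the mean cumulative dose or one realization as the dose."""
        dose = (
            self.doses.mean(axis=1)
            if realization == "mean"
            else self.doses[:, int(realization)]
        )
        return OutcomeData(
            y=self.records["event"].to_numpy(dtype=float),
            dose=dose,
            offset=self.records["person_time"].to_numpy(dtype=float),
            background=self.records["A"].to_numpy(dtype=float),
            modifier=self.records["C"].to_numpy(dtype=float),
            subject_ids=self.records["record_id"].to_numpy(dtype=object),
        )


def _eval_cov(c: Covariate, age: float) -> float:
    return float(c(age)) if callable(c) else float(c)


def _lagged_cumulative(
    h: ExposureHistory, cutoff: float
) -> np.ndarray:
    """Dose accrued strictly before ``cutoff``, uniform within each year."""
    total = np.zeros(h.n_realizations)
    for age, dose in h.annual_doses.items():
        frac = np.clip(cutoff - age, 0.0, 1.0)
        if frac > 0:
            total += frac * dose
    return total


def build_person_years(
    h: ExposureHistory, interval: float = 1.0, lag: float = 0.0
) -> PersonYearTable:
    """Split one follow-up into half-open [a, a+interval) records.

    The final partial interval carries fractional person-time; the event is
    assigned to the record containing ``event_age`` (an event exactly at exit
    belongs to the last record); per-record dose is the cumulative annual dose
    accrued before record_end - lag.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    if lag < 0:
        raise ValueError("lag must be nonnegative")
    starts = []
    a = h.entry_age
    while a < h.exit_age - 1e-12:
        starts.append(a)
        a += interval
    # half-open records: the event at age e goes to the record with
    # start <= e < end (boundary events to the later interval); an event
    # exactly at exit belongs to the last record.
    event_idx = None
    if h.event_age is not None:
        if h.event_age == h.exit_age:
            event_idx = len(starts) - 1
        else:
            event_idx = int(
                np.searchsorted(np.asarray(starts), h.event_age, "right") - 1
            )
    rows = []
    dose_rows = []
    for i, start in enumerate(starts):
        end = min(start + interval, h.exit_age)
        rows.append(
            {
                "subject_id": h.subject_id,
                "record_id": f"{h.subject_id}:{i}",
                "age_start": start,
                "age_end": end,
                "person_time": end - start,
                "event": int(i == event_idx),
                "A": _eval_cov(h.background, start),
                "C": _eval_cov(h.modifier, start),
            }
        )
        dose_rows.append(_lagged_cumulative(h, end - lag))
    return PersonYearTable(records=pd.DataFrame(rows), doses=np.asarray(dose_rows))


def build_person_year_table(
    histories: Sequence[ExposureHistory], interval: float = 1.0, lag: float = 0.0
) -> PersonYearTable:
    """Concatenate per-subject disaggregations into one cohort table."""
    parts = [build_person_years(h, interval, lag) for h in histories]
    return PersonYearTable(
        records=pd.concat([p.records for p in parts], ignore_index=True),
        doses=np.vstack([p.doses for p in parts]),
    )


def person_year_covariance(table: PersonYearTable) -> DoseUncertaintyModel:
    """Record-level Var(X|W) from the cumulative doses across realizations."""
    if table.n_realizations < 2:
        raise ValueError("need at least 2 realizations for a covariance")
    r = DoseRealizations(
        table.records["record_id"].to_numpy(dtype=object), table.doses
    )
    return empirical_covariance(r)


def piecewise_exponential_loglik(
    table: PersonYearTable,
    spec: RiskModelSpec,
    theta: np.ndarray,
    realization: int | str = "mean",
) -> float:
    """Log likelihood of the piecewise-exponential hazard model on the grid.

    sum_records [ d log(lambda) - lambda * person_time ], with the hazard
    lambda given by the risk-model mean at offset 1.  Equals the Poisson log
    likelihood on the disaggregated table up to sum d log(person_time), a
    constant in theta, so the two fits and deviances coincide.
    """
    d = table.to_outcome_data(realization)
    unit = OutcomeData(
        y=d.y, dose=d.dose, offset=None, background=d.background, modifier=d.modifier
    )
    lam, _ = _mu_grad(spec, np.asarray(theta, float), unit)
    if np.any(lam <= 0):
        raise ValueError("nonpositive hazard")
    t = d.t
    return float(np.sum(d.y * np.log(lam) - lam * t))


def load_histories(
    history_path: str | Path,
    followup_path: str | Path,
    delimiter: str = ",",
) -> list[ExposureHistory]:
    """Read histories: ``id,year,annual_dose_r1,...`` plus follow-up
    ``id,entry_age,exit_age[,event_age]``."""
    hist = pd.read_csv(history_path, delimiter=delimiter, dtype={0: str})
    fu = pd.read_csv(followup_path, delimiter=delimiter, dtype={0: str})
    fu = fu.set_index(fu.columns[0])
    out = []
    for sid, grp in hist.groupby(hist.columns[0], sort=False):
        if sid not in fu.index:
            raise ValueError(f"subject {sid!r} missing from follow-up file")
        row = fu.loc[sid]
        doses = {
            int(r.iloc[1]): r.iloc[2:].to_numpy(dtype=float)
            for _, r in grp.iterrows()
        }
        event = None
        if "event_age" in fu.columns and not pd.isna(row.get("event_age", np.nan)):
            event = float(row["event_age"])
        out.append(
            ExposureHistory(
                subject_id=str(sid),
                annual_doses=doses,
                entry_age=float(row["entry_age"]),
                exit_age=float(row["exit_age"]),
                event_age=event,
            )
        )
    return out
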