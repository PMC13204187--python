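"""Synthetic positive-unlabeled longitudinal EHR cohorts.

The generator emulates the statistical structure a rare-disease screening
analysis assumes: a small set of labeled positive patients against a large
unlabeled pool containing a configurable fraction of latent (hidden) positives,
group-dependent CBC value distributions calibrated to published per-group
medians, Poisson visit processes at class-specific rates, ICD-10 code emission
with class-dependent odds, and missingness of optional laboratory parameters.

Labeled positives are selected completely at random from all positives (the
SCAR assumption), so the Elkan-Noto label-frequency estimator is consistent on
these cohorts by construction.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import (
    CBC_REFERENCE,
    DEFAULT_CODE_SPECS,
    STUDY_N_CENTERS,
)
from .records import ICD10_PATTERN, EVENT_COLUMNS, EventRecord

# Width of the log-scale range (in sigmas) implied by the published min/max of
# each CBC parameter: a sample of ~110k patient medians spans roughly +/- 4
# sigma. Used only to derive plausible per-parameter dispersions.
_CONTROL_RANGE_SIGMAS = 8.0


@dataclass(frozen=True)
class ParameterSpec:
    """Class-conditional log-normal model for one CBC parameter.

    The marginal per-measurement median equals ``control_median`` for latent
    negatives and ``case_median`` for (labeled or hidden) positives;
    ``dispersion`` is the log-scale sigma shared by both classes. Parameters
    flagged optional are dropped per visit with probability ``missing_rate``.
    """

    name: str
    unit: str
    control_median: float
    case_median: float
    dispersion: float
    optional_flag: bool = False
    missing_rate: float = 0.0
    percent_scale: bool = False  # values clipped to [0, 100]

    def __post_init__(self) -> None:
        if self.control_median <= 0 or self.case_median <= 0:
            raise ValueError(
                f"parameter {self.name!r}: medians must be positive for a "
                f"log-location family (got {self.control_median}, {self.case_median})"
            )
        if self.dispersion <= 0:
            raise ValueError(f"parameter {self.name!r}: dispersion must be > 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"parameter {self.name!r}: missing_rate must be in [0, 1]")


def default_parameter_specs(
    missing_rate_optional: float = 0.3,
) -> tuple[ParameterSpec, ...]:
    """The 22 CBC parameters with dispersions derived from published ranges."""
    specs = []
    for name, unit, c_med, (c_min, c_max), p_med, _p_range, optional in CBC_REFERENCE:
        if c_min > 0:
            sigma = (math.log(c_max) - math.log(c_min)) / _CONTROL_RANGE_SIGMAS
        else:  # zero-inflated lower bound: use the upper half-range only
            sigma = math.log(c_max / c_med) / (_CONTROL_RANGE_SIGMAS / 2)
        specs.append(
            ParameterSpec(
                name=name,
                unit=unit,
                control_median=c_med,
                case_median=p_med,
                dispersion=sigma,
                optional_flag=optional,
                missing_rate=missing_rate_optional if optional else 0.0,
                percent_scale=unit == "%",
            )
        )
    return tuple(specs)


def separable_parameter_specs(dispersion: float = 0.03) -> tuple[ParameterSpec, ...]:
    """Low-dispersion variant: classes are nearly separable on every parameter
    whose group medians differ. Used for limit-case and recovery experiments."""
    return tuple(
        dataclasses.replace(spec, dispersion=dispersion, missing_rate=0.0)
        for spec in default_parameter_specs()
    )


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters for one synthetic PU cohort.

    Defaults are the desk-scale analogue of the reference study (1/100 of the
    110,000-control pool; 5 labeled positives per each of 10 centers).
    ``hidden_positive_rate`` is the probability that an unlabeled patient is a
    latent positive.
    """

    n_unlabeled: int = 1100
    n_labeled_positive: int = 50
    hidden_positive_rate: float = 0.05
    n_centers: int = STUDY_N_CENTERS
    window_days: int = 730
    visit_rate_case: float = 2.5  # expected visits per year
    visit_rate_control: float = 1.5
    code_specs: tuple[tuple[str, float, float], ...] = DEFAULT_CODE_SPECS
    parameter_specs: tuple[ParameterSpec, ...] = field(
        default_factory=default_parameter_specs
    )
    drift_per_year: float = 0.0  # optional within-patient log-scale linear drift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_labeled_positive < 1:
            raise ValueError("n_labeled_positive must be >= 1")
        if self.n_unlabeled < 0:
            raise ValueError("n_unlabeled must be >= 0")
        if not 0.0 <= self.hidden_positive_rate < 1.0:
            raise ValueError("hidden_positive_rate must be in [0, 1)")
        if self.n_centers < 1:
            raise ValueError("n_centers must be >= 1")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if self.visit_rate_case < 0 or self.visit_rate_control < 0:
            raise ValueError("visit rates must be >= 0")
        for code, rate, mult in self.code_specs:
            if not ICD10_PATTERN.match(code):
                raise ValueError(f"code {code!r} is not ICD-10-like")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"code {code!r}: control_rate must be in [0, 1]")
            if mult < 0:
                raise ValueError(f"code {code!r}: case_odds_multiplier must be >= 0")


@dataclass
class SyntheticPatient:
    patient_id: str
    center_id: str
    birth_year: int
    gender: str
    anchor_date: dt.date
    events: list[EventRecord]
    y_true: int  # latent class: 1 positive, 0 negative
    s_observed: int  # observed PU label: 1 labeled positive, 0 unlabeled

    def __post_init__(self) -> None:
        if self.s_observed == 1 and self.y_true != 1:
            raise ValueError("labeled-positive patient must be a latent positive")


def sample_parameter_trajectory(
    spec: ParameterSpec,
    visit_dates: Sequence[dt.date],
    is_case: bool,
    rng: np.random.Generator,
    drift_per_year: float = 0.0,
) -> list[tuple[dt.date, float]]:
    """Draw one lab value per retained visit from the class-conditional
    log-normal, dropping optional parameters at ``missing_rate``.

    With a nonzero drift, the log-location shifts linearly with time toward
    the last visit (anchored so the final visit sits at the class median).
    """
    out: list[tuple[dt.date, float]] = []
    if not visit_dates:
        return out
    median = spec.case_median if is_case else spec.control_median
    last = max(visit_dates)
    for date in visit_dates:
        if spec.missing_rate > 0 and rng.random() < spec.missing_rate:
            continue
        years_before = (last - date).days / 365.25
        mu = math.log(median) - drift_per_year * years_before
        value = math.exp(mu + spec.dispersion * rng.standard_normal())
        if spec.percent_scale:
            value = min(value, 100.0)
        out.append((date, float(value)))
    return out


def code_emission_probability(control_rate: float, multiplier: float) -> float:
    """Case emission probability implied by a control rate and an odds
    multiplier: odds_case = multiplier * odds_control."""
    if control_rate in (0.0, 1.0):
        return control_rate
    odds = multiplier * control_rate / (1.0 - control_rate)
    return odds / (1.0 + odds)


def assign_codes(
    patient_id: str,
    code_specs: Sequence[tuple[str, float, float]],
    visit_dates: Sequence[dt.date],
    is_case: bool,
    rng: np.random.Generator,
) -> list[EventRecord]:
    """Emit each ICD-10 code at most once per window, Bernoulli with
    class-dependent probability; the code is stamped on a random visit date."""
    events: list[EventRecord] = []
    if not visit_dates:
        return events
    dates = list(visit_dates)
    for code, control_rate, multiplier in code_specs:
        if not ICD10_PATTERN.match(code):
            raise ValueError(f"code {code!r} is not ICD-10-like")
        p = code_emission_probability(control_rate, multiplier) if is_case else control_rate
        if rng.random() < p:
            date = dates[int(rng.integers(len(dates)))]
            events.append(EventRecord(date, patient_id, "icd10", code))
    return events


def _sample_visit_dates(
    anchor: dt.date, window_days: int, rate_per_year: float, rng: np.random.Generator
) -> list[dt.date]:
    """Homogeneous Poisson visit process over [anchor - window_days, anchor),
    with at least one visit (the cohort inclusion criterion: a usable record
    needs at least one pre-anchor encounter)."""
    expected = rate_per_year * window_days / 365.25
    n = max(1, int(rng.poisson(expected)))
    offsets = sorted(int(o) for o in rng.integers(1, window_days + 1, size=n))
    return [anchor - dt.timedelta(days=int(o)) for o in offsets]


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Generate ``n_unlabeled + n_labeled_positive`` synthetic patients.

    Deterministic: the same config (including seed) yields an identical cohort.
    Hidden positives draw labs and codes from the case distributions but carry
    ``s_observed = 0``.
    """
    rng = np.random.default_rng(config.seed)
    patients: list[SyntheticPatient] = []
    n_total = config.n_labeled_positive + config.n_unlabeled
    labeled = np.zeros(n_total, dtype=bool)
    labeled[: config.n_labeled_positive] = True
    y_true = labeled.copy()
    if config.n_unlabeled:
        y_true[config.n_labeled_positive :] = (
            rng.random(config.n_unlabeled) < config.hidden_positive_rate
        )
    for i in range(n_total):
        pid = f"P{i:06d}"
        center = f"C{i % config.n_centers:02d}"
        gender = "F" if rng.random() < 0.52 else "M"
        anchor = dt.date(2015, 1, 1) + dt.timedelta(days=int(rng.integers(0, 8 * 365)))
        age = float(np.clip(rng.normal(67.0, 10.0), 30.0, 90.0))
        is_case = bool(y_true[i])
        rate = config.visit_rate_case if is_case else config.visit_rate_control
        visits = _sample_visit_dates(anchor, config.window_days, rate, rng)
        events: list[EventRecord] = [
            EventRecord(d, pid, "visit", "visit") for d in visits
        ]
        for spec in config.parameter_specs:
            for date, value in sample_parameter_trajectory(
                spec, visits, is_case, rng, config.drift_per_year
            ):
                events.append(EventRecord(date, pid, "lab", spec.name, value, spec.unit))
        events.extend(assign_codes(pid, config.code_specs, visits, is_case, rng))
        events.sort()
        patients.append(
            SyntheticPatient(
                patient_id=pid,
                center_id=center,
                birth_year=anchor.year - int(round(age)),
                gender=gender,
                anchor_date=anchor,
                events=events,
                y_true=int(is_case),
                s_observed=int(labeled[i]),
            )
        )
    return patients


def true_labeling_frequency(patients: Sequence[SyntheticPatient]) -> float:
    """Realized label frequency c = P(labeled | latent positive)."""
    n_pos = sum(p.y_true for p in patients)
    if n_pos == 0:
        raise ValueError("cohort contains no latent positives")
    return sum(p.s_observed for p in patients) / n_pos


def events_frame(patients: Sequence[SyntheticPatient]) -> pd.DataFrame:
    """Flatten a cohort into the tidy event schema consumed by the pipeline."""
    rows = [
        (e.patient_id, e.date.isoformat(), e.kind, e.key, e.value, e.unit)
        for p in patients
        for e in p.events
    ]
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def patients_frame(patients: Sequence[SyntheticPatient]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "center_id": [p.center_id for p in patients],
            "birth_year": [p.birth_year for p in patients],
            "gender": [p.gender for p in patients],
            "anchor_date": [p.anchor_date.isoformat() for p in patients],
            "y_true": [p.y_true for p in patients],
            "s_observed": [p.s_observed for p in patients],
        }
    )


def write_cohort(patients: Sequence[SyntheticPatient], out_dir) -> dict[str, str]:
    """Write events.csv + patients.csv; returns the paths written."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": str(out / "events.csv"),
        "patients": str(out / "patients.csv"),
    }
    events_frame(patients).to_csv(paths["events"], index=False)
    patients_frame(patients).to_csv(paths["patients"], index=False)
    return paths
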