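"""Cohort construction: putative-case flagging, analysis-window extraction,
stratified control matching, and leakage-code exclusion.

All window intervals are half-open ``[window_start, anchor_date)``: events on
the anchor (diagnosis) day itself are excluded so that same-day diagnostic
labs cannot leak into the features.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import CASE_ICD_CODES, CASE_TEXT_PATTERN, LEAKAGE_ROOTS
from .records import EventRecord, icd10_root

_CASE_TEXT_RE = re.compile(CASE_TEXT_PATTERN)


@dataclass
class CohortWindow:
    """A patient's events restricted to a two-year window before an anchor date."""

    patient_id: str
    anchor_date: dt.date
    window_start: dt.date
    events: list[EventRecord]
    label: int  # 1 = labeled positive, 0 = unlabeled

    def __post_init__(self) -> None:
        if (self.anchor_date - self.window_start).days > 730:
            raise ValueError("window exceeds 730 days")
        for e in self.events:
            if not (self.window_start <= e.date < self.anchor_date):
                raise ValueError(f"event at {e.date} outside [{self.window_start}, {self.anchor_date})")


def _code_matches(code: str, listed: str) -> bool:
    # A bare 3-character root also matches every one of its subcodes.
    return code == listed or (len(listed) == 3 and icd10_root(code) == listed)


def flag_putative_positive(events: Iterable[EventRecord]) -> bool:
    """True iff any text event matches the word-boundary myelofibrosis stem,
    or any ICD-10 event matches one of the case-ascertainment codes."""
    for e in events:
        if e.kind == "text" and _CASE_TEXT_RE.search(str(e.value)):
            return True
        if e.kind == "icd10" and any(_code_matches(str(e.key), c) for c in CASE_ICD_CODES):
            return True
    return False


def sample_control_anchor(
    events: Sequence[EventRecord], rng: np.random.Generator
) -> dt.date:
    """Uniformly sample an anchor (window end) no later than the last visit.

    The anchor is drawn uniformly from calendar days in (first event, last
    visit], so the window always contains at least one event and may be
    shorter than two years when it extends before the record's start.
    """
    if not events:
        raise ValueError("cannot place a window for a patient with zero events")
    dates = sorted(e.date for e in events)
    visits = [e.date for e in events if e.kind == "visit"] or dates
    last = max(visits)
    first = dates[0]
    span = (last - first).days
    offset = int(rng.integers(1, span + 1)) if span > 0 else 0
    return first + dt.timedelta(days=offset)


def extract_window(
    events: Sequence[EventRecord],
    anchor_date: dt.date,
    window_days: int = 730,
    label: int = 0,
) -> CohortWindow:
    """Retain exactly the events with ``window_start <= date < anchor_date``.

    For positives the anchor is the diagnosis date; for controls use
    :func:`sample_control_anchor` first. The effective span may be shorter
    than ``window_days`` if the record starts later.
    """
    if not events:
        raise ValueError("cannot place a window for a patient with zero events")
    window_start = anchor_date - dt.timedelta(days=window_days)
    kept = [e for e in events if window_start <= e.date < anchor_date]
    pid = events[0].patient_id
    return CohortWindow(pid, anchor_date, window_start, sorted(kept), label)


def _stratum(age: int, gender: str) -> tuple[int, str]:
    return (int(age) // 10 * 10, gender)


def sample_matched_controls(
    candidates: pd.DataFrame,
    positives: pd.DataFrame,
    n_total: int,
    seed: int,
) -> list[str]:
    """Age-decade x gender stratified sampling of controls matched to the
    positive cohort's stratum shares.

    Both frames need columns ``patient_id``, ``age``, ``gender``. Quotas are
    proportional to positive stratum shares, apportioned by largest remainder;
    sampling is without replacement and reproducible by seed.
    """
    if n_total > len(candidates):
        raise ValueError(f"n_total={n_total} exceeds candidate pool of {len(candidates)}")
    overlap = set(candidates["patient_id"]) & set(positives["patient_id"])
    if overlap:
        raise ValueError(f"candidates overlap positives: {sorted(overlap)[:5]}")

    pos_strata = positives.apply(lambda r: _stratum(r["age"], r["gender"]), axis=1)
    shares = pos_strata.value_counts(normalize=True)
    cand = candidates.copy()
    cand["_stratum"] = cand.apply(lambda r: _stratum(r["age"], r["gender"]), axis=1)

    # largest-remainder apportionment of n_total over positive strata
    raw = shares * n_total
    quotas = raw.astype(int)
    remainder = int(n_total - quotas.sum())
    if remainder > 0:
        order = (raw - quotas).sort_values(ascending=False).index
        for s in order[:remainder]:
            quotas[s] += 1

    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for stratum, quota in quotas.items():
        if quota == 0:
            continue
        pool = cand.loc[cand["_stratum"] == stratum, "patient_id"].tolist()
        if len(pool) < quota:
            raise ValueError(
                f"stratum {stratum} has positive mass but only {len(pool)} candidates "
                f"for a quota of {quota}"
            )
        idx = rng.choice(len(pool), size=quota, replace=False)
        chosen.extend(pool[i] for i in sorted(idx))
    return chosen


def exclude_leakage_codes(code_keys: Iterable[str]) -> set[str]:
    """Drop every code whose 3-character root falls in the hematologic
    malignancy ranges (D45, D46, D47, D70-D77, C81-C96); all other codes pass
    through unchanged."""
    return {c for c in code_keys if icd10_root(c) not in LEAKAGE_ROOTS}


def windows_manifest(windows: Sequence[CohortWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [w.patient_id for w in windows],
            "label": [w.label for w in windows],
            "anchor_date": [w.anchor_date.isoformat() for w in windows],
            "window_start": [w.window_start.isoformat() for w in windows],
            "n_events": [len(w.events) for w in windows],
        }
    )


def windows_from_cohort(patients, window_days: int = 730) -> list[CohortWindow]:
    """Build one analysis window per synthetic patient at its anchor date."""
    return [
        extract_window(p.events, p.anchor_date, window_days, label=p.s_observed)
        for p in patients
    ]
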