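"""Atomic record types shared by the simulator and the cohort builder."""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass

ICD10_PATTERN = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")

EVENT_KINDS = ("visit", "lab", "icd10", "text")

EVENT_COLUMNS = ("patient_id", "date", "kind", "key", "value", "unit")


@dataclass(frozen=True, order=True)
class EventRecord:
    """One timestamped patient fact: a visit, lab value, ICD-10 code, or text flag."""

    date: dt.date
    patient_id: str
    kind: str
    key: str
    value: object = ""
    unit: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "lab" and not isinstance(self.value, (int, float)):
            raise ValueError(f"lab event {self.key!r} has non-numeric value {self.value!r}")
        if self.kind == "icd10" and not ICD10_PATTERN.match(str(self.key)):
            raise ValueError(f"key {self.key!r} is not ICD-10-like (root + optional subcode)")


def icd10_root(code: str) -> str:
    """3-character root of an ICD-10 code ("D47.1" -> "D47")."""
    return str(code)[:3]
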