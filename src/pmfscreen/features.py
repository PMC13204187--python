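"""Feature engineering: longitudinal aggregation, control-anchored decile
binning, presence indicators, prevalence filtering, phenotype mapping, and
Weight-of-Evidence encoding.

Conventions (frozen in :mod:`pmfscreen.constants`): percentiles use linear
interpolation, variance is the sample variance (``n-1``, zero for a single
measurement), monotonicity ties resolve to False, and a value equal to a bin
edge falls in the lower interval. Missing values stay missing — no imputation
anywhere in this module; learners receive the missing sentinel (NaN) natively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import CohortWindow, exclude_leakage_codes
from .constants import (
    AGGREGATE_NAMES,
    CBC_PARAMETER_NAMES,
    N_BINS,
    OPTIONAL_CBC_PARAMETERS,
    PREVALENCE_THRESHOLD,
)

MISSING = float("nan")
UNMAPPED = None


# --- aggregation -------------------------------------------------------------

def aggregate_series(values: Sequence[float]) -> dict[str, float]:
    """The eight per-parameter summary statistics of a time-ordered series.

    Empty input yields all-missing fields (not an error): a patient with no
    measurements of a parameter keeps a row of NaN aggregates.
    """
    if len(values) == 0:
        return {name: MISSING for name in AGGREGATE_NAMES}
    arr = np.asarray(values, dtype=float)
    p25, p50, p75 = np.percentile(arr, [25, 50, 75])
    return {
        "p25": float(p25),
        "p50": float(p50),
        "p75": float(p75),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "variance": float(arr.var(ddof=1)) if arr.size > 1 else 0.0,
        "first_last_absdiff": float(abs(arr[-1] - arr[0])),
        "monotonic_increase": float(arr[-1] > arr[0]),
    }


# --- decile binning ----------------------------------------------------------

def fit_bins(control_values: Sequence[float], n_bins: int = N_BINS) -> np.ndarray:
    """Interior bin edges at control percentiles 10, 20, ..., 90 (linear
    interpolation). Ties may produce duplicate edges, i.e. fewer effective
    intervals."""
    arr = np.asarray(control_values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < n_bins:
        raise ValueError(
            f"need at least {n_bins} non-missing control values to fit bins, got {arr.size}"
        )
    qs = np.arange(1, n_bins) * (100.0 / n_bins)
    return np.percentile(arr, qs)


def apply_bins(value: float, edges: np.ndarray) -> float:
    """Bin index = count of edges strictly below the value (0..n_bins-1);
    a value equal to an edge is assigned to the lower interval. NaN in, NaN out."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return MISSING
    return float(np.searchsorted(edges, value, side="left"))


class DecileBinner(TransformerMixin, BaseEstimator):
    """Percentile binning fitted on the control (unlabeled) group only.

    ``fit(X, y)`` uses the rows with ``y == 0`` — the vast and diverse control
    pool defines the physiological reference deciles. Columns not listed in
    ``columns`` pass through untouched; missing values stay missing.
    """

    def __init__(self, n_bins: int = N_BINS, columns: Sequence[str] | None = None):
        self.n_bins = n_bins
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None) -> "DecileBinner":
        X = pd.DataFrame(X)
        if y is None:
            control = X
        else:
            y = np.asarray(y)
            control = X.loc[y == 0]
        cols = list(self.columns) if self.columns is not None else list(X.columns)
        self.edges_: dict[str, np.ndarray] = {}
        bad: list[str] = []
        for col in cols:
            values = control[col].to_numpy(dtype=float)
            values = values[~np.isnan(values)]
            if values.size == 0:
                bad.append(col)
                continue
            self.edges_[col] = fit_bins(values, self.n_bins)
        if bad:
            raise ValueError(f"all-missing control features: {bad}")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X).copy()
        for col, edges in self.edges_.items():
            values = X[col].to_numpy(dtype=float)
            out = np.searchsorted(edges, values, side="left").astype(float)
            out[np.isnan(values)] = np.nan
            X[col] = out
        return X


# --- prevalence filter -------------------------------------------------------

def prevalence_filter(
    matrix: pd.DataFrame,
    labels: Sequence[int],
    schema: Mapping[str, str],
    threshold: float = PREVALENCE_THRESHOLD,
    optional_parameters: Iterable[str] = OPTIONAL_CBC_PARAMETERS,
) -> list[str]:
    """Columns retained after the joint-prevalence rule.

    Binary code/phenotype features and optional CBC parameters are kept only
    if present (value 1, resp. measured) in at least ``threshold`` of the
    positive AND of the control rows (inclusive). Mandatory CBC parameters
    and demographics are exempt.
    """
    labels = np.asarray(labels)
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValueError("prevalence filter needs both positive and control rows")
    optional = set(optional_parameters)

    def present_fraction(mask: np.ndarray, col: str) -> float:
        sub = matrix.loc[mask, col]
        if schema[col] == "binary":
            return float((sub == 1).mean())
        return float(sub.notna().mean())

    pos, neg = labels == 1, labels == 0
    dropped_params: set[str] = set()
    retained: list[str] = []
    for col in matrix.columns:
        kind = schema[col]
        param = col.split("__")[0]
        if kind == "demographic" or (kind == "aggregate" and param not in optional):
            retained.append(col)
            continue
        if kind == "aggregate":
            # optional parameter aggregates stand or fall with the parameter's
            # measured-presence column, judged below on the presence indicator
            probe = f"{param}__measured"
            probe = probe if probe in matrix.columns else col
        else:
            probe = col
        ok = (
            present_fraction(pos, probe) >= threshold
            and present_fraction(neg, probe) >= threshold
        )
        if ok:
            retained.append(col)
        elif kind == "aggregate" or col.endswith("__measured"):
            dropped_params.add(param)
    return [c for c in retained if c.split("__")[0] not in dropped_params]


# --- phenotype mapping -------------------------------------------------------

def load_phewas_mapping(table: pd.DataFrame | Iterable[tuple[str, str]]) -> dict[str, str]:
    """Validate a two-column code -> phenotype table into a lookup dict;
    conflicting duplicate rows are an error."""
    if isinstance(table, pd.DataFrame):
        pairs = list(table.iloc[:, :2].itertuples(index=False, name=None))
    else:
        pairs = list(table)
    mapping: dict[str, str] = {}
    for code, phenotype in pairs:
        code = str(code)
        if code in mapping and mapping[code] != phenotype:
            raise ValueError(
                f"conflicting mapping for {code!r}: {mapping[code]!r} vs {phenotype!r}"
            )
        mapping[code] = str(phenotype)
    return mapping


def map_phewas(code: str, mapping: Mapping[str, str]):
    """Exact-match phenotype lookup with 3-character-root fallback; returns
    the unmapped sentinel (None) when neither matches."""
    if code in mapping:
        return mapping[code]
    root = str(code)[:3]
    return mapping.get(root, UNMAPPED)


# --- Weight of Evidence ------------------------------------------------------

class WoEEncoder(TransformerMixin, BaseEstimator):
    """Per-category Weight-of-Evidence encoding with 0.5 pseudo-count
    smoothing, for categorical/binned columns.

    WoE(b) = ln( ((pos_b + 0.5) / (pos + 0.5 k)) / ((neg_b + 0.5) / (neg + 0.5 k)) )
    with k the number of categories of the column. Missing values form their
    own category; categories unseen at fit time encode to 0. Fit on training
    rows only (the fold-safety contract).
    """

    _MISSING_KEY = "__missing__"

    def fit(self, X: pd.DataFrame, y) -> "WoEEncoder":
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("WoE encoding requires both classes in the labels")
        n_pos = int((y == 1).sum())
        n_neg = int((y == 0).sum())
        self.encoding_: dict[str, dict[object, float]] = {}
        for col in X.columns:
            keys = X[col].where(X[col].notna(), self._MISSING_KEY)
            cats = keys.unique()
            k = len(cats)
            table: dict[object, float] = {}
            for cat in cats:
                in_cat = (keys == cat).to_numpy()
                pos_b = int((in_cat & (y == 1)).sum())
                neg_b = int((in_cat & (y == 0)).sum())
                table[cat] = math.log(
                    ((pos_b + 0.5) / (n_pos + 0.5 * k))
                    / ((neg_b + 0.5) / (n_neg + 0.5 * k))
                )
            self.encoding_[col] = table
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X).copy()
        for col, table in self.encoding_.items():
            keys = X[col].where(X[col].notna(), self._MISSING_KEY)
            X[col] = keys.map(lambda c: table.get(c, 0.0)).astype(float)
        return X


def woe_transform(
    matrix: pd.DataFrame, labels: Sequence[int]
) -> tuple[pd.DataFrame, dict[str, dict[object, float]]]:
    """Functional wrapper: encoded matrix plus the fitted encoding table."""
    enc = WoEEncoder().fit(matrix, np.asarray(labels))
    return enc.transform(matrix), enc.encoding_


# --- matrix assembly ---------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Patient x feature table with per-column metadata.

    ``schema`` maps each column to a kind: ``aggregate`` (continuous, to be
    decile-binned for modeling), ``binary`` (presence/code/phenotype
    indicators), or ``demographic``. Cells hold numerics with NaN as the
    missing sentinel; no imputation is ever applied.
    """

    frame: pd.DataFrame
    schema: dict[str, str]
    labels: pd.Series

    @property
    def aggregate_columns(self) -> list[str]:
        return [c for c, k in self.schema.items() if k == "aggregate"]


def build_feature_matrix(
    windows: Sequence[CohortWindow],
    demographics: pd.DataFrame | None = None,
    parameter_names: Sequence[str] = CBC_PARAMETER_NAMES,
    mapping: Mapping[str, str] | None = None,
    prevalence_threshold: float | None = PREVALENCE_THRESHOLD,
    optional_parameters: Iterable[str] = OPTIONAL_CBC_PARAMETERS,
) -> FeatureMatrix:
    """Assemble the modeling matrix: one row per analysis window.

    Per CBC parameter: a binary measured-presence indicator plus the eight
    aggregates. Per retained (non-leakage) ICD-10 code and mapped phenotype: a
    binary indicator. Demographics (age at anchor, gender) appended when a
    demographics frame (patient_id, birth_year, gender) is given. The joint
    5% prevalence filter is applied last (pass ``prevalence_threshold=None``
    to skip it, e.g. when filtering inside CV folds).
    """
    all_codes: set[str] = set()
    for w in windows:
        all_codes.update(str(e.key) for e in w.events if e.kind == "icd10")
    code_vocab = sorted(exclude_leakage_codes(all_codes))
    mapping = dict(mapping) if mapping else {}
    phenotype_vocab = sorted(
        {p for c in code_vocab if (p := map_phewas(c, mapping)) is not UNMAPPED}
    )

    rows = []
    for w in windows:
        row: dict[str, float] = {}
        labs: dict[str, list[tuple]] = {p: [] for p in parameter_names}
        codes_here: set[str] = set()
        for e in w.events:
            if e.kind == "lab" and e.key in labs:
                labs[e.key].append((e.date, float(e.value)))
            elif e.kind == "icd10":
                codes_here.add(str(e.key))
        for param in parameter_names:
            series = [v for _, v in sorted(labs[param], key=lambda t: t[0])]
            row[f"{param}__measured"] = float(bool(series))
            for name, value in aggregate_series(series).items():
                row[f"{param}__{name}"] = value
        for code in code_vocab:
            row[f"icd10__{code}"] = float(code in codes_here)
        for pheno in phenotype_vocab:
            row[f"phenotype__{pheno}"] = float(
                any(map_phewas(c, mapping) == pheno for c in codes_here)
            )
        rows.append(row)

    frame = pd.DataFrame(rows, index=[w.patient_id for w in windows])
    frame.index.name = "patient_id"
    labels = pd.Series([w.label for w in windows], index=frame.index, name="label")

    schema: dict[str, str] = {}
    for param in parameter_names:
        schema[f"{param}__measured"] = "binary"
        for name in AGGREGATE_NAMES:
            schema[f"{param}__{name}"] = "aggregate"
    for code in code_vocab:
        schema[f"icd10__{code}"] = "binary"
    for pheno in phenotype_vocab:
        schema[f"phenotype__{pheno}"] = "binary"

    if demographics is not None:
        demo = demographics.set_index("patient_id")
        anchor_years = pd.Series(
            [w.anchor_date.year for w in windows], index=frame.index
        )
        frame["age"] = anchor_years - demo.loc[frame.index, "birth_year"]
        frame["gender_female"] = (
            demo.loc[frame.index, "gender"].eq("F").astype(float)
        )
        schema["age"] = "demographic"
        schema["gender_female"] = "demographic"

    if prevalence_threshold is not None:
        retained = prevalence_filter(
            frame, labels, schema, prevalence_threshold, optional_parameters
        )
        frame = frame[retained]
        schema = {c: schema[c] for c in retained}
    return FeatureMatrix(frame=frame, schema=schema, labels=labels)
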