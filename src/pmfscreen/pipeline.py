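"""Run configuration, event I/O, end-to-end orchestration, and the clinical
review-table arithmetic.

A run is driven by a single :class:`RunConfig` (YAML or JSON on disk) and a
single top-level seed that fans out deterministically to every random draw:
cohort generation, fold shuffling, and PU holdout/spy sampling. Identical
config + seed reproduce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import pathlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortWindow, extract_window, windows_from_cohort, windows_manifest
from .constants import (
    DEFAULT_DECISION_THRESHOLD,
    DEFAULT_PHENOTYPE_MAPPING,
    PREVALENCE_THRESHOLD,
)
from .evaluation import make_repeated_stratified_folds, run_cv
from .features import build_feature_matrix, load_phewas_mapping
from .records import EVENT_COLUMNS, EventRecord
from .simulate import CohortConfig, generate_cohort, patients_frame, write_cohort
from .stats import univariate_table, volcano_table


# --- configuration -----------------------------------------------------------

@dataclass
class RunConfig:
    """Complete run description. With ``events_path`` unset, a synthetic
    cohort is generated from the ``cohort`` section; otherwise events and
    patient metadata (final labels included) are read from CSV."""

    seed: int = 0
    output_dir: str = "out"
    events_path: str | None = None
    patients_path: str | None = None
    mapping_path: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_bins: int = 10
    prevalence_threshold: float = PREVALENCE_THRESHOLD
    variant: str = "baseline"
    learner: str = "logistic_bins"
    holdout_frac: float = 0.1
    spy_frac: float = 0.1
    noise_tol: float = 0.2
    k: int = 10
    reps: int = 10
    threshold: float = DEFAULT_DECISION_THRESHOLD

    def __post_init__(self) -> None:
        for name in ("holdout_frac", "spy_frac", "noise_tol", "prevalence_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["parameter_specs"] = [
            dataclasses.asdict(s) if not isinstance(s, dict) else s
            for s in d["cohort"]["parameter_specs"]
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", None)
        if cohort is not None:
            from .simulate import ParameterSpec

            cohort = dict(cohort)
            specs = cohort.pop("parameter_specs", None)
            if specs is not None:
                cohort["parameter_specs"] = tuple(
                    s if isinstance(s, ParameterSpec) else ParameterSpec(**s)
                    for s in specs
                )
            if "code_specs" in cohort:
                cohort["code_specs"] = tuple(tuple(c) for c in cohort["code_specs"])
            d["cohort"] = CohortConfig(**cohort)
        return cls(**d)


def load_config(path) -> RunConfig:
    text = pathlib.Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    pathlib.Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


# --- event I/O ---------------------------------------------------------------

def load_events(path) -> tuple[list[EventRecord], pd.DataFrame]:
    """Read the tidy event CSV; malformed rows land in the error report (with
    1-based data line numbers) instead of aborting the load. A missing header
    column is fatal."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event file {path} is missing columns: {missing}")
    records: list[EventRecord] = []
    errors: list[dict] = []
    for line, row in enumerate(df.itertuples(index=False), start=1):
        try:
            date = dt.date.fromisoformat(row.date)
            value: object = row.value
            if row.kind == "lab":
                value = float(row.value)
            records.append(
                EventRecord(date, row.patient_id, row.kind, row.key, value, row.unit)
            )
        except (ValueError, TypeError) as exc:
            errors.append({"line": line, "error": str(exc)})
    return records, pd.DataFrame(errors, columns=["line", "error"])


# --- review-table fixtures ---------------------------------------------------

def load_review_tables() -> dict[str, pd.DataFrame]:
    """The clinical review count grids shipped with the package: risk level x
    diagnostic status for the consensus false-positive subset and for the
    remaining flagged patients of the best supervised model."""
    out = {}
    for name in ("review_consensus", "review_remaining"):
        with resources.files("pmfscreen.data").joinpath(f"{name}.csv").open() as fh:
            out[name] = pd.read_csv(fh)
    return out


def review_table_summaries(fixtures: Sequence[pd.DataFrame]) -> dict:
    """Exact integer sums over one or more review grids: grand total,
    per-diagnostic-status column sums, per-risk row sums, and the combined
    medium+high risk total."""
    col_sums: dict[str, int] = {}
    row_sums: dict[str, int] = {}
    total = 0
    medium_high = 0
    for table in fixtures:
        counts = table.set_index("risk")
        if (counts.to_numpy() < 0).any():
            raise ValueError("review counts must be non-negative")
        for status in counts.columns:
            col_sums[status] = col_sums.get(status, 0) + int(counts[status].sum())
        for risk, row in counts.iterrows():
            row_sums[risk] = row_sums.get(risk, 0) + int(row.sum())
        total += int(counts.to_numpy().sum())
        medium_high += int(counts.loc[counts.index.isin(["Medium", "High"])].to_numpy().sum())
    return {
        "total": total,
        "column_sums": col_sums,
        "row_sums": row_sums,
        "medium_high_total": medium_high,
    }


# --- orchestration -----------------------------------------------------------

@dataclass
class PipelineResult:
    matrix: "pd.DataFrame"
    schema: dict
    univariate: pd.DataFrame
    report: object
    manifest: dict
    output_dir: str


def _config_hash(config: RunConfig) -> str:
    # hash the scientific configuration only: where artifacts land does not
    # change what was computed
    d = config.to_dict()
    d.pop("output_dir", None)
    payload = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis: cohort -> windows -> features -> univariate
    statistics -> repeated-CV evaluation, writing all artifacts under
    ``config.output_dir``."""
    out = pathlib.Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_rng = np.random.default_rng(config.seed)
    gen_seed, cv_seed, plan_seed = (int(s) for s in seed_rng.integers(0, 2**31 - 1, 3))

    try:
        if config.events_path is None:
            cohort_cfg = dataclasses.replace(config.cohort, seed=gen_seed)
            patients = generate_cohort(cohort_cfg)
            write_cohort(patients, out / "cohort")
            windows = windows_from_cohort(patients, cohort_cfg.window_days)
            demographics = patients_frame(patients)[
                ["patient_id", "birth_year", "gender"]
            ]
        else:
            records, errors = load_events(config.events_path)
            if len(errors):
                errors.to_csv(out / "event_errors.csv", index=False)
            meta = pd.read_csv(config.patients_path)
            by_patient: dict[str, list[EventRecord]] = {}
            for r in records:
                by_patient.setdefault(r.patient_id, []).append(r)
            windows = [
                extract_window(
                    by_patient[row.patient_id],
                    dt.date.fromisoformat(row.anchor_date),
                    label=int(row.s_observed),
                )
                for row in meta.itertuples(index=False)
                if row.patient_id in by_patient
            ]
            demographics = meta[["patient_id", "birth_year", "gender"]]
    except Exception as exc:
        raise RuntimeError(f"cohort stage failed: {exc}") from exc

    if config.mapping_path:
        mapping = load_phewas_mapping(pd.read_csv(config.mapping_path))
    else:
        mapping = load_phewas_mapping(DEFAULT_PHENOTYPE_MAPPING)

    try:
        matrix = build_feature_matrix(
            windows,
            demographics=demographics,
            mapping=mapping,
            prevalence_threshold=config.prevalence_threshold,
        )
    except Exception as exc:
        raise RuntimeError(f"feature stage failed: {exc}") from exc

    try:
        univariate = univariate_table(matrix.frame, matrix.labels.to_numpy())
        volcano = volcano_table(univariate)
    except Exception as exc:
        raise RuntimeError(f"univariate stage failed: {exc}") from exc

    try:
        plan = make_repeated_stratified_folds(
            matrix.labels.to_numpy(), k=config.k, reps=config.reps, seed=plan_seed
        )
        from .pu import make_learner

        report = run_cv(
            matrix,
            plan,
            variant=config.variant,
            estimator=make_learner(config.learner, random_state=cv_seed),
            threshold=config.threshold,
            seed=cv_seed,
        )
    except Exception as exc:
        raise RuntimeError(f"evaluation stage failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stage_seeds": {"generator": gen_seed, "cv": cv_seed, "plan": plan_seed},
        "n_patients": int(len(matrix.frame)),
        "n_features": int(matrix.frame.shape[1]),
        "versions": _library_versions(),
    }

    windows_manifest(windows).to_csv(out / "windows.csv", index=False)
    matrix.frame.to_csv(out / "matrix.csv")
    (out / "schema.json").write_text(json.dumps(matrix.schema, indent=2))
    univariate.to_csv(out / "univariate.csv", index=False)
    volcano.to_csv(out / "volcano.csv", index=False)
    report.runs.to_csv(out / "runs.csv", index=False)
    report.predictions.to_csv(out / "predictions.csv", index=False)
    report.profile().to_csv(out / "profile.csv", index=False)
    report.consensus().to_csv(out / "consensus.csv", index=False)
    summary = {
        name: dataclasses.asdict(ms) for name, ms in report.summary().items()
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(
        matrix=matrix.frame,
        schema=matrix.schema,
        univariate=univariate,
        report=report,
        manifest=manifest,
        output_dir=str(out),
    )


def _library_versions() -> dict[str, str]:
    import sklearn
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
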