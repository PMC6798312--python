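"""Cohort file formats and run configuration.

Cohorts travel as long-format CSV (comma-separated, UTF-8, header required,
one row per eye/exam/location); ground truth as a sidecar JSON; SD curves,
fit tables and RMSE tables as tab-separated text.  An optional
``laterality`` column (OD/OS) mirrors left eyes into the right-eye frame at
ingestion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .grid import N_LOCATIONS, grid_24_2
from .series import MAX_DB, VFExam, VFSeries, mirror_left_eye
from .simulate import Cohort, CohortSpec, TruthTrajectory

COHORT_COLUMNS = (
    "eye_id", "exam_index", "time_years", "age", "location_index",
    "x_deg", "y_deg", "sensitivity_db", "fp_rate", "fn_rate",
)


def cohort_frame(cohort: Iterable[VFSeries]) -> pd.DataFrame:
    grid = grid_24_2()
    x = np.array([p.x_deg for p in grid])
    y = np.array([p.y_deg for p in grid])
    frames = []
    for s in cohort:
        for j, exam in enumerate(s.exams):
            frames.append(
                pd.DataFrame(
                    {
                        "eye_id": s.eye_id,
                        "exam_index": j,
                        "time_years": np.round(exam.time_years, 6),
                        "age": np.round(s.age_at(exam.time_years), 6),
                        "location_index": np.arange(N_LOCATIONS),
                        "x_deg": x,
                        "y_deg": y,
                        "sensitivity_db": exam.sensitivities.astype(int),
                        "fp_rate": np.round(exam.fp_rate, 6) if exam.fp_rate is not None else np.nan,
                        "fn_rate": np.round(exam.fn_rate, 6) if exam.fn_rate is not None else np.nan,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def write_cohort(cohort: Iterable[VFSeries], path) -> None:
    cohort_frame(cohort).to_csv(path, index=False)


class CohortFormatError(ValueError):
    pass


def read_cohort(path) -> list[VFSeries]:
    """Read and validate a long-format cohort CSV.

    Left eyes (``laterality == "OS"``) are mirrored into the right-eye
    frame.  Malformed rows raise :class:`CohortFormatError` naming the first
    offending CSV row (1-based, counting the header as row 1).
    """
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortFormatError(f"missing columns: {sorted(missing)}")
    rownum = df.index + 2  # 1-based file rows, after the header

    bad = ~df["location_index"].isin(range(N_LOCATIONS))
    if bad.any():
        raise CohortFormatError(
            f"row {rownum[bad][0]}: unknown location index "
            f"{df.loc[bad, 'location_index'].iloc[0]}"
        )
    out_of_range = (df["sensitivity_db"] < 0) | (df["sensitivity_db"] > MAX_DB)
    if out_of_range.any():
        raise CohortFormatError(
            f"row {rownum[out_of_range][0]}: sensitivity "
            f"{df.loc[out_of_range, 'sensitivity_db'].iloc[0]} outside [0, {MAX_DB}] dB"
        )
    dup = df.duplicated(["eye_id", "exam_index", "location_index"], keep=False)
    if dup.any():
        raise CohortFormatError(f"row {rownum[dup][0]}: duplicated (eye, exam, location)")

    series = []
    for eye_id, eye_df in df.groupby("eye_id", sort=True):
        mirror = False
        if "laterality" in eye_df.columns:
            lat = set(eye_df["laterality"].dropna().unique())
            if not lat <= {"OD", "OS"}:
                raise CohortFormatError(f"eye {eye_id!r}: bad laterality values {lat}")
            mirror = lat == {"OS"}
        exams = []
        baseline_age = None
        by_exam = eye_df.sort_values(["exam_index", "location_index"]).groupby("exam_index")
        prev_t = -np.inf
        for exam_idx, g in by_exam:
            if len(g) != N_LOCATIONS:
                raise CohortFormatError(
                    f"eye {eye_id!r} exam {exam_idx}: {len(g)} locations, expected {N_LOCATIONS}"
                )
            t = float(g["time_years"].iloc[0])
            if t <= prev_t:
                raise CohortFormatError(
                    f"row {rownum[g.index[0]]}: non-monotone exam times for eye {eye_id!r}"
                )
            prev_t = t
            sens = np.empty(N_LOCATIONS)
            sens[g["location_index"].to_numpy()] = g["sensitivity_db"].to_numpy(float)
            if mirror:
                sens = mirror_left_eye(sens)
            if baseline_age is None:
                baseline_age = float(g["age"].iloc[0]) - t
            fp = g["fp_rate"].iloc[0]
            fn = g["fn_rate"].iloc[0]
            exams.append(
                VFExam(
                    time_years=t, sensitivities=sens,
                    fp_rate=None if pd.isna(fp) else float(fp),
                    fn_rate=None if pd.isna(fn) else float(fn),
                )
            )
        series.append(VFSeries(eye_id=str(eye_id), baseline_age_years=baseline_age, exams=exams))
    return series


def write_truth(cohort: Cohort, path) -> None:
    with open(path, "w") as fh:
        json.dump(cohort.ground_truth_dict(), fh, indent=1)


def read_truth(path) -> dict:
    with open(path) as fh:
        d = json.load(fh)
    d["eyes"] = {
        k: {**v, "truth": TruthTrajectory.from_dict(v["truth"])}
        for k, v in d["eyes"].items()
    }
    d["spec"] = CohortSpec.from_dict(d["spec"])
    return d


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run; a copy is written next to
    every output so a run can be regenerated exactly."""

    seed: int = 0
    cohort_path: str | None = None
    cohort_spec: dict | None = None
    models: list[str] = dc_field(default_factory=lambda: ["linear", "weighted_linear", "exp"])
    noise: dict | None = None
    targets: list[int] = dc_field(default_factory=lambda: [10, 15, 20])
    knots: list[float] = dc_field(default_factory=lambda: [14.0, 32.0])
    apply_filters: bool = True
    outdir: str = "vfvar_out"

    def validate(self) -> "RunConfig":
        from .trend import MODEL_KINDS

        if self.cohort_path is None and self.cohort_spec is None:
            raise ValueError("config needs either cohort_path or cohort_spec")
        bad = set(self.models) - set(MODEL_KINDS)
        if bad:
            raise ValueError(f"unknown model kinds: {sorted(bad)}")
        if len(self.knots) != 2:
            raise ValueError("knots must be two sensitivities in dB")
        return self

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls(**data).validate()

    def to_file(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(data, fh, indent=1)
            else:
                yaml.safe_dump(data, fh, sort_keys=False)


def filter_report(cohort: Iterable[VFSeries]) -> dict:
    """Cohort accounting mirrored into the run log: exams rejected by the
    reliability filter and locations excluded by the modeling mask."""
    from .series import is_reliable, location_inclusion_mask

    n_eyes = n_exams = n_unreliable = n_excluded_locs = 0
    for s in cohort:
        n_eyes += 1
        for e in s.exams:
            n_exams += 1
            if not is_reliable(e, missing_policy="reject"):
                n_unreliable += 1
        if s.n_exams >= 3:
            n_excluded_locs += int((~location_inclusion_mask(s)).sum() - 2)
    return {
        "n_eyes": n_eyes,
        "n_exams": n_exams,
        "n_unreliable_exams": n_unreliable,
        "n_locations_excluded_by_mask": n_excluded_locs,
    }
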