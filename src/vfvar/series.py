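"""Longitudinal visual-field series: exams, reliability and inclusion filters.

An exam stores the 54 threshold sensitivities of the 24-2 grid (dB) together
with its reliability indices; a series is one eye's ordered exams.  The
reliability rule admits exams with at most 20% false positives and 25% false
negatives, with no restriction on fixation losses.  For trend modeling,
locations that started at the measurement floor (0 dB in two of the first
three exams) are excluded, as is the blind spot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field


import numpy as np

from .grid import BLIND_SPOT_INDICES, N_LOCATIONS, grid_24_2, subset_30_2_indices

MAX_DB = 50  # storage range for raw sensitivities; analyses use 0..35


@dataclass
class VFExam:
    """A single visual-field examination.

    ``sensitivities`` is indexed by the 24-2 grid (54 entries, integer dB in
    [0, 50]); ``fp_rate``/``fn_rate`` are fractions in [0, 1]; missing
    reliability indices are allowed but by default make the exam unreliable.
    """

    time_years: float
    sensitivities: np.ndarray
    fp_rate: float | None = None
    fn_rate: float | None = None
    fixation_losses: float | None = None

    def __post_init__(self) -> None:
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        if self.sensitivities.shape != (N_LOCATIONS,):
            raise ValueError(
                f"expected {N_LOCATIONS} sensitivities, got {self.sensitivities.shape}"
            )
        if self.time_years < 0:
            raise ValueError("time_years must be >= 0")
        if np.any(self.sensitivities < 0) or np.any(self.sensitivities > MAX_DB):
            raise ValueError(f"sensitivities must lie in [0, {MAX_DB}] dB")
        for name in ("fp_rate", "fn_rate", "fixation_losses"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0, 1]")


@dataclass
class VFSeries:
    """One eye's ordered visual-field examinations."""

    eye_id: str
    baseline_age_years: float
    exams: list[VFExam] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.exams) < 2:
            raise ValueError("a series needs at least 2 exams")
        times = self.times
        if np.any(np.diff(times) <= 0):
            raise ValueError("exam times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time_years for e in self.exams])

    @property
    def n_exams(self) -> int:
        return len(self.exams)

    @property
    def followup_years(self) -> float:
        return self.exams[-1].time_years - self.exams[0].time_years

    def sensitivity_matrix(self) -> np.ndarray:
        """(n_exams, 54) matrix of sensitivities."""
        return np.stack([e.sensitivities for e in self.exams])

    def age_at(self, time_years: float) -> float:
        return self.baseline_age_years + time_years


def subset_30_2(sensitivities_30_2: np.ndarray) -> np.ndarray:
    """Restrict a 76-point 30-2 sensitivity vector to the shared 24-2 locations.

    The result is ordered as :func:`vfvar.grid.grid_24_2`.  Input already on
    the 54-point grid is returned unchanged.
    """
    arr = np.asarray(sensitivities_30_2, dtype=float)
    if arr.shape == (N_LOCATIONS,):
        return arr
    if arr.shape != (76,):
        raise ValueError(f"expected a 76-point 30-2 exam, got shape {arr.shape}")
    return arr[list(subset_30_2_indices())]


FP_LIMIT = 0.20
FN_LIMIT = 0.25


def is_reliable(exam: VFExam, *, missing_policy: str = "reject") -> bool:
    """Reliability filter: fp <= 20% and fn <= 25%; fixation losses ignored.

    Missing fp/fn rates follow ``missing_policy``: ``"reject"`` (default,
    conservative, warns) or ``"accept"``.
    """
    if exam.fp_rate is None or exam.fn_rate is None:
        if missing_policy == "accept":
            return True
        if missing_policy == "reject":
            warnings.warn("exam with missing reliability indices treated as unreliable")
            return False
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    return exam.fp_rate <= FP_LIMIT and exam.fn_rate <= FN_LIMIT


def filter_reliable(series: VFSeries, *, missing_policy: str = "reject") -> VFSeries:
    """A copy of the series keeping only reliable exams."""
    kept = [e for e in series.exams if is_reliable(e, missing_policy=missing_policy)]
    if len(kept) < 2:
        raise ValueError(f"series {series.eye_id!r} has fewer than 2 reliable exams")
    return VFSeries(series.eye_id, series.baseline_age_years, kept)


def location_inclusion_mask(series: VFSeries) -> np.ndarray:
    """Per-location modeling inclusion flags.

    False for the blind spot and for locations at the floor early on (0 dB in
    at least two of the first three exams).  Used by the modeling/evaluation
    pipeline only; variability estimation excludes just the blind spot.
    """
    if series.n_exams < 3:
        raise ValueError("inclusion mask needs at least 3 exams")
    first3 = series.sensitivity_matrix()[:3]
    mask = (first3 == 0).sum(axis=0) < 2
    mask[list(BLIND_SPOT_INDICES)] = False
    return mask


def band_indices() -> dict[str, np.ndarray]:
    """Non-blind-spot location indices per eccentricity band."""
    out: dict[str, list[int]] = {}
    for loc in grid_24_2():
        if loc.is_blind_spot:
            continue
        out.setdefault(loc.band, []).append(loc.index)
    return {k: np.array(v) for k, v in out.items()}


def mirror_left_eye(sensitivities: np.ndarray) -> np.ndarray:
    """Map a left-eye exam from the screen frame onto the right-eye frame.

    On screen, the left eye's 24-2 chart is the mirror image of the right
    eye's (x -> -x), with indices running left-to-right within each row, so
    re-expressing a left eye in the canonical temporal-positive frame
    amounts to reversing each y-row.  The mirror is its own inverse and
    carries the left eye's screen blind spot at (-15, +/-3) onto the
    canonical (15, +/-3).
    """
    sens = np.asarray(sensitivities, dtype=float)
    out = np.empty_like(sens)
    rows: dict[float, list[int]] = {}
    for p in grid_24_2():
        rows.setdefault(p.y_deg, []).append(p.index)
    for idx in rows.values():  # indices are already x-ordered within a row
        out[idx] = sens[idx[::-1]]
    return out
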