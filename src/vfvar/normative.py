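"""Normative sensitivity surfaces and the censoring ceiling.

The improvement-model asymptote and the linear-prediction ceiling are the
age- and location-matched normal sensitivity plus two standard deviations.
Published normative tables are proprietary, so the default here is a
configurable parametric hill of vision — normal sensitivity declining
linearly with eccentricity and with age — that is a synthetic stand-in
calibrated only qualitatively, not a reproduction of any device's normative
database.  A per-location table can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import TestLocation, grid_24_2


class NormativeModel:
    """Interface: mean/SD of normal sensitivity and the derived ceiling."""

    age_support: tuple[float, float] = (18.0, 110.0)

    def _check_age(self, age: float) -> None:
        lo, hi = self.age_support
        if not (lo <= age <= hi):
            raise ValueError(f"age {age} outside normative support [{lo}, {hi}]")

    def normal_mean(self, location: TestLocation, age: float) -> float:
        raise NotImplementedError

    def normal_sd(self, location: TestLocation, age: float) -> float:
        raise NotImplementedError

    def ceiling(self, location: TestLocation, age: float) -> float:
        """Normal mean + 2 SD: the censoring/improvement-model ceiling."""
        return self.normal_mean(location, age) + 2.0 * self.normal_sd(location, age)

    def mean_field(self, age: float) -> np.ndarray:
        return np.array([self.normal_mean(p, age) for p in grid_24_2()])

    def ceiling_field(self, age: float) -> np.ndarray:
        return np.array([self.ceiling(p, age) for p in grid_24_2()])


@dataclass
class HillOfVision(NormativeModel):
    """Parametric normal surface: linear decay with eccentricity and age.

    ``peak_db`` is the normal sensitivity at fixation at ``age_ref``;
    sensitivity falls by ``ecc_slope`` dB per degree of eccentricity and by
    ``age_slope`` dB per year beyond ``age_ref``.  The normal SD grows
    slowly with eccentricity but at less than half the mean's rate, so the
    ceiling (mean + 2 SD) still decreases strictly with eccentricity.
    """

    peak_db: float = 33.5
    ecc_slope: float = 0.07  # dB per degree of eccentricity
    age_slope: float = 0.065  # dB per year after age_ref
    age_ref: float = 45.0
    sd0: float = 1.0
    sd_ecc_slope: float = 0.03

    def normal_mean(self, location: TestLocation, age: float) -> float:
        self._check_age(age)
        age_loss = self.age_slope * max(age - self.age_ref, 0.0)
        return self.peak_db - self.ecc_slope * location.eccentricity_deg - age_loss

    def normal_sd(self, location: TestLocation, age: float) -> float:
        self._check_age(age)
        return self.sd0 + self.sd_ecc_slope * location.eccentricity_deg


@dataclass
class TabularNormative(NormativeModel):
    """Per-location normal mean/SD at a reference age plus a linear age slope.

    ``mean_ref`` and ``sd_ref`` are length-54 arrays at ``age_ref``; user
    tables (e.g. exported from a device) can be loaded into this form.
    """

    mean_ref: np.ndarray
    sd_ref: np.ndarray
    age_ref: float = 45.0
    age_slope: float = 0.065

    def __post_init__(self) -> None:
        self.mean_ref = np.asarray(self.mean_ref, dtype=float)
        self.sd_ref = np.asarray(self.sd_ref, dtype=float)
        if self.mean_ref.shape != (54,) or self.sd_ref.shape != (54,):
            raise ValueError("mean_ref and sd_ref must have 54 entries")
        if np.any(self.sd_ref <= 0):
            raise ValueError("normal SD must be positive")

    def normal_mean(self, location: TestLocation, age: float) -> float:
        self._check_age(age)
        return float(
            self.mean_ref[location.index]
            - self.age_slope * max(age - self.age_ref, 0.0)
        )

    def normal_sd(self, location: TestLocation, age: float) -> float:
        self._check_age(age)
        return float(self.sd_ref[location.index])


def ceiling_value(normative: NormativeModel, location: TestLocation, age: float) -> float:
    """Ceiling Y = normal mean + 2 SD at a location and age."""
    return normative.ceiling(location, age)


DEFAULT_NORMATIVE = HillOfVision()
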