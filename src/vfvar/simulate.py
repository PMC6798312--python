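"""Synthetic longitudinal visual-field cohorts with known ground truth.

The clinical datasets behind the variability and modeling analyses are not
public, so this module generates stand-in cohorts that emulate their
reported statistical structure: exam counts and follow-up (median 9 exams
over ~9.5 years for the variability preset; median 20 exams over ~15 years
for the modeling preset), mildly depressed baseline fields (median mean
deviation around -3 dB) with focal and diffuse glaucomatous defects, slow
median progression, and heteroscedastic Gaussian measurement noise whose SD
follows a sensitivity-dependent noise model.  Noise is keyed to the TRUE
sensitivity (the generative analogue of binning residuals by observed
value); observations are rounded to integer dB and clamped to the analyzed
range [0, 35].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .grid import N_LOCATIONS, NON_BLIND_INDICES, grid_24_2
from .noise import NoiseModel, anchor_noise_model
from .normative import DEFAULT_NORMATIVE, NormativeModel
from .series import VFExam, VFSeries
from .trend import S_MAX, fit_linear

TRUTH_KINDS = ("stable", "linear", "exponential", "logistic")


@dataclass
class TruthTrajectory:
    """Noise-free per-location sensitivity trajectories for one eye.

    ``kinds`` selects the generating curve per location; ``baseline`` is the
    true sensitivity at t=0 (dB); ``rate`` is the kind's slope parameter
    (dB/year for linear, log-rate 1/year for exponential, the logistic slope
    for logistic); ``ceiling`` bounds every trajectory above.
    """

    kinds: np.ndarray
    baseline: np.ndarray
    rate: np.ndarray
    ceiling: np.ndarray
    zeta: np.ndarray | None = None  # logistic asymptote where kind == "logistic"

    def __post_init__(self) -> None:
        self.kinds = np.asarray(self.kinds, dtype=object)
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        self.ceiling = np.asarray(self.ceiling, dtype=float)
        for name in ("kinds", "baseline", "rate", "ceiling"):
            if getattr(self, name).shape != (N_LOCATIONS,):
                raise ValueError(f"{name} must have {N_LOCATIONS} entries")
        unknown = set(self.kinds) - set(TRUTH_KINDS)
        if unknown:
            raise ValueError(f"unknown truth kinds: {unknown}")
        if np.any(self.baseline < 0) or np.any(self.baseline > self.ceiling):
            raise ValueError("baseline truth must lie in [0, ceiling]")

    @classmethod
    def stable(cls, baseline, ceiling) -> "TruthTrajectory":
        baseline = np.asarray(baseline, dtype=float)
        return cls(
            kinds=np.full(N_LOCATIONS, "stable", dtype=object),
            baseline=baseline,
            rate=np.zeros(N_LOCATIONS),
            ceiling=np.asarray(ceiling, dtype=float),
        )

    def sensitivity(self, times) -> np.ndarray:
        """(n_times, 54) true sensitivities, clipped into [0, ceiling]."""
        t = np.atleast_1d(np.asarray(times, dtype=float))[:, None]
        s0, r = self.baseline[None, :], self.rate[None, :]
        out = np.empty((t.size, N_LOCATIONS))
        kinds = self.kinds
        stable = kinds == "stable"
        out[:, stable] = s0[:, stable]
        lin = kinds == "linear"
        out[:, lin] = s0[:, lin] + r[:, lin] * t
        expo = kinds == "exponential"
        out[:, expo] = s0[:, expo] * np.exp(r[:, expo] * t)
        logi = kinds == "logistic"
        if np.any(logi):
            zeta = self.zeta[None, logi]
            s0l = np.clip(s0[:, logi], 0.05, zeta - 0.05)
            a = np.log(zeta / s0l - 1.0)
            out[:, logi] = zeta / (1.0 + np.exp(a + r[:, logi] * t))
        return np.clip(out, 0.0, self.ceiling[None, :])

    def to_dict(self) -> dict:
        d = {
            "kinds": self.kinds.tolist(),
            "baseline": self.baseline.tolist(),
            "rate": self.rate.tolist(),
            "ceiling": self.ceiling.tolist(),
        }
        if self.zeta is not None:
            d["zeta"] = np.asarray(self.zeta).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthTrajectory":
        return cls(
            kinds=np.array(d["kinds"], dtype=object),
            baseline=np.array(d["baseline"]),
            rate=np.array(d["rate"]),
            ceiling=np.array(d["ceiling"]),
            zeta=np.array(d["zeta"]) if "zeta" in d else None,
        )


@dataclass
class CohortSpec:
    """Generation parameters for a synthetic cohort.

    Presets fix the exam-count and follow-up distributions: ``variability``
    guarantees >= 6 exams and >= 3 years; ``modeling`` guarantees >= 10
    exams and >= 6 years.  Exam gaps are drawn from a shifted gamma
    distribution; exam counts are ``min_exams`` plus a Poisson excess.
    """

    n_eyes: int
    preset: str = "variability"
    seed: int = 0
    # exam schedule
    min_exams: int = 6
    extra_exams_poisson: float = 3.2
    min_gap_years: float = 0.35
    gap_shape: float = 2.2
    gap_scale: float = 0.38
    min_followup_years: float = 3.0
    # truth structure
    truth: str = "glaucoma"  # glaucoma | uniform | fixed
    fixed_sensitivity: float | None = None
    fraction_progressing: float = 0.65
    diffuse_loss_scale: float = 2.0
    focal_depth_range: tuple[float, float] = (4.0, 25.0)
    decay_rate_mean: float = 0.12  # |log-rate| per year for progressing locations
    decay_rate_sd: float = 0.06
    # population
    age_mean: float = 66.0
    age_sd: float = 8.0
    # noise
    noise: NoiseModel = field(default_factory=anchor_noise_model)
    simulate_unreliable: bool = False

    @classmethod
    def variability_preset(cls, n_eyes: int, seed: int = 0, **overrides) -> "CohortSpec":
        return cls(n_eyes=n_eyes, seed=seed, preset="variability", **overrides)

    @classmethod
    def modeling_preset(cls, n_eyes: int, seed: int = 0, **overrides) -> "CohortSpec":
        spec = cls(
            n_eyes=n_eyes, seed=seed, preset="modeling",
            min_exams=10, extra_exams_poisson=10.0,
            min_gap_years=0.3, gap_shape=2.0, gap_scale=0.25,
            min_followup_years=6.0,
        )
        return replace(spec, **overrides) if overrides else spec

    def validate(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        if self.preset not in ("variability", "modeling"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.truth == "fixed" and self.fixed_sensitivity is None:
            raise ValueError("truth='fixed' requires fixed_sensitivity")
        # infeasible schedule: more exams than fit in attainable follow-up
        mean_gap = self.min_gap_years + self.gap_shape * self.gap_scale
        if (self.min_exams - 1) * mean_gap > 40:
            raise ValueError("infeasible exam schedule: expected follow-up exceeds 40 years")

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_eyes", "preset", "seed", "min_exams", "extra_exams_poisson",
                "min_gap_years", "gap_shape", "gap_scale", "min_followup_years",
                "truth", "fixed_sensitivity", "fraction_progressing",
                "diffuse_loss_scale", "decay_rate_mean", "decay_rate_sd",
                "age_mean", "age_sd", "simulate_unreliable",
            )
        }
        d["focal_depth_range"] = list(self.focal_depth_range)
        d["noise"] = self.noise.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "noise" in d:
            d["noise"] = NoiseModel.from_dict(d["noise"])
        if "focal_depth_range" in d:
            d["focal_depth_range"] = tuple(d["focal_depth_range"])
        return cls(**d)


def draw_exam_times(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    """Baseline at 0, then shifted-gamma gaps; resampled until the preset's
    minimum follow-up is met."""
    n = spec.min_exams + int(rng.poisson(spec.extra_exams_poisson))
    for _ in range(1000):
        gaps = spec.min_gap_years + rng.gamma(spec.gap_shape, spec.gap_scale, n - 1)
        if gaps.sum() >= spec.min_followup_years:
            return np.concatenate([[0.0], np.cumsum(gaps)])
    raise ValueError("infeasible spec: could not reach the minimum follow-up")


def _pairwise_distances() -> np.ndarray:
    xy = np.array([(p.x_deg, p.y_deg) for p in grid_24_2()])
    diff = xy[:, None, :] - xy[None, :, :]
    return np.hypot(diff[..., 0], diff[..., 1])


_GRID_DIST = None


def _grid_distances() -> np.ndarray:
    global _GRID_DIST
    if _GRID_DIST is None:
        _GRID_DIST = _pairwise_distances()
    return _GRID_DIST


def glaucoma_truth(
    rng: np.random.Generator,
    spec: CohortSpec,
    normative: NormativeModel,
    age: float,
    progressing: bool,
) -> TruthTrajectory:
    """Focal-plus-diffuse glaucomatous baseline field, optionally progressing.

    The baseline is the normative hill of vision minus a diffuse loss
    (exponentially distributed) and 1-2 focal defects with Gaussian spatial
    falloff.  In progressing eyes, defect-involved locations (plus a few
    random others) decay exponentially with per-location log-rates.
    """
    mean_field = normative.mean_field(age)
    ceiling = normative.ceiling_field(age)
    depression = np.full(N_LOCATIONS, rng.exponential(spec.diffuse_loss_scale))
    involved = np.zeros(N_LOCATIONS, dtype=bool)
    n_defects = 1 + int(rng.random() < 0.7)
    dist = _grid_distances()
    for _ in range(n_defects):
        center = int(rng.choice(NON_BLIND_INDICES))
        depth = rng.uniform(*spec.focal_depth_range)
        radius = rng.uniform(4.0, 8.0)
        bump = depth * np.exp(-((dist[center] / radius) ** 2))
        depression += bump
        involved |= bump > 1.0
    baseline = np.clip(mean_field - depression, 0.0, ceiling)
    kinds = np.full(N_LOCATIONS, "stable", dtype=object)
    rate = np.zeros(N_LOCATIONS)
    if progressing:
        extra = rng.random(N_LOCATIONS) < 0.05
        targets = (involved | extra) & (baseline > 0.5)
        rates = -np.abs(rng.normal(spec.decay_rate_mean, spec.decay_rate_sd, N_LOCATIONS))
        kinds[targets] = "exponential"
        rate[targets] = rates[targets]
    return TruthTrajectory(kinds=kinds, baseline=baseline, rate=rate, ceiling=ceiling)


def uniform_truth(
    rng: np.random.Generator, normative: NormativeModel, age: float
) -> TruthTrajectory:
    """Stable field with true sensitivities uniform over the analyzed range
    (capped by the normative ceiling) — the neutral density under which the
    binned-SD estimator is informative in every sensitivity bin."""
    ceiling = normative.ceiling_field(age)
    baseline = np.minimum(rng.uniform(0.0, S_MAX, N_LOCATIONS), ceiling)
    return TruthTrajectory.stable(baseline, ceiling)


def fixed_truth(spec: CohortSpec, normative: NormativeModel, age: float) -> TruthTrajectory:
    ceiling = normative.ceiling_field(age)
    baseline = np.minimum(np.full(N_LOCATIONS, float(spec.fixed_sensitivity)), ceiling)
    return TruthTrajectory.stable(baseline, ceiling)


def generate_eye(
    truth: TruthTrajectory,
    exam_times,
    noise: NoiseModel,
    normative: NormativeModel | None = None,
    seed=0,
    eye_id: str = "eye",
    baseline_age: float = 66.0,
    simulate_unreliable: bool = False,
) -> VFSeries:
    """Realize one eye: observed = round(clamp(truth + e, 0, 35)) with
    e ~ Normal(0, sigma(truth)); reliability indices drawn to pass the
    reliability filter (unless ``simulate_unreliable``)."""
    times = np.asarray(exam_times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("exam times must be strictly increasing")
    rng = np.random.default_rng(seed)
    s_true = truth.sensitivity(times)
    sigma = np.asarray(noise.sigma(s_true), dtype=float)
    obs = np.round(np.clip(s_true + rng.normal(0.0, sigma), 0.0, float(S_MAX)))
    exams = []
    for i, t in enumerate(times):
        if simulate_unreliable and rng.random() < 0.1:
            fp, fn = rng.uniform(0.21, 0.5), rng.uniform(0.0, 0.5)
        else:
            fp, fn = rng.uniform(0.0, 0.20), rng.uniform(0.0, 0.25)
        exams.append(
            VFExam(
                time_years=float(t),
                sensitivities=obs[i],
                fp_rate=float(fp),
                fn_rate=float(fn),
                fixation_losses=float(rng.uniform(0.0, 0.6)),
            )
        )
    return VFSeries(eye_id=eye_id, baseline_age_years=baseline_age, exams=exams)


@dataclass
class Cohort:
    """A generated cohort: series plus the per-eye generating record."""

    series: list[VFSeries]
    truths: dict[str, TruthTrajectory]
    spec: CohortSpec
    eye_seeds: dict[str, list[int]]

    def __iter__(self) -> Iterator[VFSeries]:
        return iter(self.series)

    def __len__(self) -> int:
        return len(self.series)

    def ground_truth_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "eyes": {
                s.eye_id: {
                    "baseline_age_years": s.baseline_age_years,
                    "exam_times": s.times.tolist(),
                    "noise_seed": self.eye_seeds[s.eye_id],
                    "truth": self.truths[s.eye_id].to_dict(),
                }
                for s in self.series
            },
        }

    def summary(self, normative: NormativeModel | None = None) -> dict:
        normative = normative or DEFAULT_NORMATIVE
        n_exams = [s.n_exams for s in self.series]
        fol = [s.followup_years for s in self.series]
        md0, md_slope = [], []
        for s in self.series:
            mds = np.array(
                [pseudo_md(e, normative, s.age_at(e.time_years)) for e in s.exams]
            )
            md0.append(mds[0])
            md_slope.append(fit_linear(s.times, mds).beta)
        return {
            "n_eyes": len(self.series),
            "median_exams": float(np.median(n_exams)),
            "iqr_exams": [float(np.percentile(n_exams, 25)), float(np.percentile(n_exams, 75))],
            "median_followup_years": float(np.median(fol)),
            "median_baseline_pseudo_md": float(np.median(md0)),
            "median_pseudo_md_slope": float(np.median(md_slope)),
        }


def generate_cohort(spec: CohortSpec, normative: NormativeModel | None = None) -> Cohort:
    """Generate a cohort of eyes with per-eye ground-truth records.

    All randomness descends from ``spec.seed``; eye ``i`` uses the seed
    sequences ``[seed, i, 0]`` (structure) and ``[seed, i, 1]`` (noise), so
    the ground-truth record plus the seed reproduces every observation.
    """
    spec.validate()
    normative = normative or DEFAULT_NORMATIVE
    series, truths, eye_seeds = [], {}, {}
    for i in range(spec.n_eyes):
        rng = np.random.default_rng([spec.seed, i, 0])
        age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 46.0, 84.0))
        if spec.truth == "glaucoma":
            progressing = rng.random() < spec.fraction_progressing
            truth = glaucoma_truth(rng, spec, normative, age, progressing)
        elif spec.truth == "uniform":
            truth = uniform_truth(rng, normative, age)
        elif spec.truth == "fixed":
            truth = fixed_truth(spec, normative, age)
        else:
            raise ValueError(f"unknown truth archetype {spec.truth!r}")
        times = draw_exam_times(rng, spec)
        eye_id = f"eye{i:04d}"
        noise_seed = [spec.seed, i, 1]
        s = generate_eye(
            truth, times, spec.noise, normative,
            seed=noise_seed, eye_id=eye_id, baseline_age=age,
            simulate_unreliable=spec.simulate_unreliable,
        )
        series.append(s)
        truths[eye_id] = truth
        eye_seeds[eye_id] = noise_seed
    return Cohort(series=series, truths=truths, spec=spec, eye_seeds=eye_seeds)


def pseudo_md(exam: VFExam, normative: NormativeModel, age: float) -> float:
    """Mean deviation stand-in: mean over non-blind-spot locations of
    observed minus the normative mean."""
    idx = list(NON_BLIND_INDICES)
    mean_field = normative.mean_field(age)
    return float(np.mean(exam.sensitivities[idx] - mean_field[idx]))
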