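"""Residual variability as a function of sensitivity and location.

The measurement noise of automated perimetry is heteroscedastic: its spread
depends on the underlying sensitivity.  Following the regression-residual
approach, each location's series is fitted with a pointwise trend model and
the residuals (observed - fitted, dB) are pooled over eyes and binned by the
observed sensitivity rounded to integer dB.  The sample SD per bin forms the
variability curve, which is then summarized by a log-linear model
ln(SD) = a + b*Sensitivity, or - because the relationship is not monotonic -
by a continuous piecewise-linear spline of ln(SD) with two knots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .grid import BANDS
from .series import VFSeries, band_indices, filter_reliable
from .trend import S_MAX, S_MIN, PointwiseTrend, PointwiseTrendResults

RESIDUAL_COLUMNS = (
    "eye_id", "location", "time_years", "observed", "fitted", "residual", "model_kind",
)

#: bins with fewer residuals than this are flagged unreliable
DEFAULT_MIN_COUNT = 25


def residual_records_from_results(results: PointwiseTrendResults) -> pd.DataFrame:
    """Long-format residual records for one fitted eye."""
    series = results.series
    fitted = results.fitted_values()
    obs = series.sensitivity_matrix()
    times = series.times
    locs = sorted(results.fits)
    rows = {
        "eye_id": np.repeat(series.eye_id, len(locs) * times.size),
        "location": np.tile(np.asarray(locs), times.size),
        "time_years": np.repeat(times, len(locs)),
        "observed": obs[:, locs].ravel(),
        "fitted": fitted[:, locs].ravel(),
    }
    df = pd.DataFrame(rows)
    df["residual"] = df["observed"] - df["fitted"]
    df["model_kind"] = results.model.kind
    return df


def pool_residuals(
    cohort: Iterable[VFSeries],
    model_kind: str = "exp",
    normative=None,
    *,
    min_exams: int = 6,
    min_followup_years: float = 3.0,
    enforce_criteria: bool = True,
    apply_reliability: bool = True,
    noise_model=None,
) -> pd.DataFrame:
    """Pointwise-fit every eligible series and pool the residuals.

    Eligibility mirrors the variability-dataset criteria (>= ``min_exams``
    reliable exams, >= ``min_followup_years`` of follow-up) unless
    ``enforce_criteria`` is off.  Only the blind spot is excluded (the
    early-floor modeling mask is not applied for variability estimation).
    """
    frames = []
    n_seen = n_used = 0
    for series in cohort:
        n_seen += 1
        if apply_reliability:
            try:
                series = filter_reliable(series)
            except ValueError:
                continue
        if enforce_criteria and (
            series.n_exams < min_exams or series.followup_years < min_followup_years
        ):
            continue
        res = PointwiseTrend(
            series, kind=model_kind, noise_model=noise_model,
            normative=normative, context="variability",
        ).fit()
        frames.append(residual_records_from_results(res))
        n_used += 1
    if n_seen == 0:
        raise ValueError("empty cohort")
    if not frames:
        raise ValueError("no series satisfied the variability criteria")
    return pd.concat(frames, ignore_index=True)


@dataclass
class SDCurve:
    """Sample SD of residuals per integer dB of observed sensitivity."""

    sensitivity: np.ndarray  # integer dB, S_MIN..S_MAX
    sd: np.ndarray           # sample SD (ddof=1), NaN where undefined
    n: np.ndarray            # residual count per bin
    min_count: int = DEFAULT_MIN_COUNT

    @property
    def reliable(self) -> np.ndarray:
        return (self.n >= self.min_count) & np.isfinite(self.sd)

    def sd_at(self, s: int) -> float:
        idx = np.searchsorted(self.sensitivity, s)
        if idx >= self.sensitivity.size or self.sensitivity[idx] != s:
            raise KeyError(f"no bin at {s} dB")
        return float(self.sd[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sensitivity_db": self.sensitivity, "sd_db": self.sd, "n": self.n}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, min_count: int = DEFAULT_MIN_COUNT) -> "SDCurve":
        df = pd.read_csv(path, sep="\t")
        return cls(
            sensitivity=df["sensitivity_db"].to_numpy(int),
            sd=df["sd_db"].to_numpy(float),
            n=df["n"].to_numpy(int),
            min_count=min_count,
        )

    @classmethod
    def from_sd_function(cls, fn, s=None, n: int = 10_000) -> "SDCurve":
        """Synthesize a curve by evaluating sigma(s) on integer bins (used by
        round-trip tests and for re-fitting printed formulas)."""
        s = np.arange(S_MIN, S_MAX + 1) if s is None else np.asarray(s, int)
        sd = np.asarray([float(fn(v)) for v in s])
        return cls(sensitivity=s, sd=sd, n=np.full(s.size, n))

    def plot(self, ax=None, log: bool = False, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ok = self.reliable
        y = np.log(self.sd[ok]) if log else self.sd[ok]
        ax.plot(self.sensitivity[ok], y, "o-", **kwargs)
        ax.set_xlabel("observed sensitivity (dB)")
        ax.set_ylabel("ln SD of residuals" if log else "SD of residuals (dB)")
        return ax


def sd_by_sensitivity(
    records: pd.DataFrame, *, min_count: int = DEFAULT_MIN_COUNT
) -> SDCurve:
    """Bin residuals by rounded observed sensitivity (0..35 dB) and take the
    sample SD (n-1 denominator) per bin."""
    if len(records) == 0:
        raise ValueError("no residual records")
    s = np.round(records["observed"].to_numpy(float)).astype(int)
    r = records["residual"].to_numpy(float)
    in_range = (s >= S_MIN) & (s <= S_MAX)
    s, r = s[in_range], r[in_range]
    bins = np.arange(S_MIN, S_MAX + 1)
    sd = np.full(bins.size, np.nan)
    n = np.zeros(bins.size, dtype=int)
    for i, b in enumerate(bins):
        vals = r[s == b]
        n[i] = vals.size
        if vals.size >= 2:
            sd[i] = vals.std(ddof=1)
    return SDCurve(sensitivity=bins, sd=sd, n=n, min_count=min_count)


def sd_by_location(
    records: pd.DataFrame, *, min_count: int = DEFAULT_MIN_COUNT
) -> dict[int, SDCurve]:
    """Per-location SD curves (blind spot never appears in the records)."""
    return {
        int(loc): sd_by_sensitivity(group, min_count=min_count)
        for loc, group in records.groupby("location")
    }


# ---------------------------------------------------------------------------
# summary-curve fits


@dataclass
class LogLinearSDFit:
    """ln(SD) = alpha + beta * Sensitivity over [s_min, s_max]."""

    alpha: float
    beta: float
    s_min: int
    s_max: int
    n_bins: int = 0

    def ln_sd(self, s):
        return self.alpha + self.beta * np.asarray(s, dtype=float)

    def sigma(self, s):
        return np.exp(self.ln_sd(s))


@dataclass
class SplineSDFit:
    """Continuous piecewise-linear model of ln(SD) on a truncated-power basis.

    ln(SD) = alpha + beta1*s + beta2*(s-k1)_+ + beta3*(s-k2)_+ ; continuity
    at the knots is built into the basis.
    """

    alpha: float
    betas: tuple[float, ...]
    knots: tuple[float, ...]
    continuous: bool = True
    n_bins: int = 0

    def ln_sd(self, s):
        s = np.asarray(s, dtype=float)
        out = self.alpha + self.betas[0] * s
        for k, b in zip(self.knots, self.betas[1:]):
            out = out + b * np.clip(s - k, 0.0, None)
        return out

    def sigma(self, s):
        return np.exp(self.ln_sd(s))


def _reliable_log_bins(curve: SDCurve, s_min: int, s_max: int):
    sel = (curve.sensitivity >= s_min) & (curve.sensitivity <= s_max) & curve.reliable
    zero = sel & (curve.sd == 0)
    if np.any(zero):
        warnings.warn(
            f"excluding {int(zero.sum())} zero-SD bin(s) from the log-scale fit"
        )
        sel &= curve.sd > 0
    return curve.sensitivity[sel].astype(float), np.log(curve.sd[sel])


def fit_loglinear_sd(curve: SDCurve, s_min: int = S_MIN, s_max: int = S_MAX) -> LogLinearSDFit:
    """OLS of ln(SD) on sensitivity over the reliable bins in [s_min, s_max].

    Each dB bin counts once (unweighted across bins).
    """
    s, ln_sd = _reliable_log_bins(curve, s_min, s_max)
    if s.size < 3:
        raise ValueError(f"need >= 3 reliable bins in [{s_min}, {s_max}], got {s.size}")
    X = np.column_stack([np.ones_like(s), s])
    coef, *_ = np.linalg.lstsq(X, ln_sd, rcond=None)
    return LogLinearSDFit(
        alpha=float(coef[0]), beta=float(coef[1]),
        s_min=s_min, s_max=s_max, n_bins=int(s.size),
    )


def fit_spline_sd(
    curve: SDCurve,
    knots: tuple[float, float] = (14.0, 32.0),
    s_min: int = S_MIN,
    s_max: int = S_MAX,
) -> SplineSDFit:
    """Continuous piecewise-linear OLS of ln(SD) on the truncated-power basis
    {1, s, (s-k1)_+, (s-k2)_+} with the given knots (defaults 14 and 32 dB).

    Knots outside the observed range collapse their basis column, degrading
    gracefully to the log-linear fit.
    """
    k1, k2 = sorted(float(k) for k in knots)
    s, ln_sd = _reliable_log_bins(curve, s_min, s_max)
    segments = {
        f"[{s_min}, {k1:g}]": s <= k1,
        f"({k1:g}, {k2:g}]": (s > k1) & (s <= k2),
        f"({k2:g}, {s_max}]": s > k2,
    }
    cols = [np.ones_like(s), s]
    active = []
    for (name, in_seg), k in zip(list(segments.items())[1:], (k1, k2)):
        if np.any(in_seg):
            cols.append(np.clip(s - k, 0.0, None))
            active.append(True)
        else:
            active.append(False)
    # each populated segment needs at least 2 reliable bins
    for name, in_seg in segments.items():
        count = int(in_seg.sum())
        if 0 < count < 2:
            raise ValueError(f"segment {name} has only {count} reliable bin(s)")
    if s.size < len(cols):
        raise ValueError("not enough reliable bins for the spline basis")
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, ln_sd, rcond=None)
    betas = [float(coef[1])]
    j = 2
    for flag in active:
        if flag:
            betas.append(float(coef[j]))
            j += 1
        else:
            betas.append(0.0)
    return SplineSDFit(
        alpha=float(coef[0]), betas=tuple(betas), knots=(k1, k2), n_bins=int(s.size),
    )


def evaluate_sd_model(model, s):
    """sigma(s) in dB from any SD model (curve, fitted summary, or callable).

    SDCurve evaluation linearly interpolates between reliable bins; inputs
    outside [0, 35] are clamped with a warning.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < S_MIN) or np.any(s > S_MAX):
        warnings.warn(f"sensitivity clamped into [{S_MIN}, {S_MAX}] dB")
        s = np.clip(s, S_MIN, S_MAX)
    if isinstance(model, SDCurve):
        ok = model.reliable & (model.sd > 0)
        if ok.sum() < 2:
            raise ValueError("SD curve has fewer than 2 reliable bins")
        out = np.interp(s, model.sensitivity[ok], model.sd[ok])
    elif isinstance(model, (LogLinearSDFit, SplineSDFit)):
        out = model.sigma(s)
    elif hasattr(model, "sigma"):
        out = np.asarray(model.sigma(s), dtype=float)
    elif callable(model):
        out = np.asarray(model(s), dtype=float)
    else:
        raise TypeError(f"cannot evaluate sigma from {type(model).__name__}")
    out = np.asarray(out, dtype=float)
    if np.any(out <= 0):
        raise ValueError("sigma(s) must be positive")
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# eccentricity-band comparison


@dataclass
class BandComparison:
    """Per-band SD curves and pairwise rank tests across matched dB bins."""

    curves: dict[str, SDCurve]
    table: pd.DataFrame  # band_a, band_b, n_bins, median_diff, higher, p, p_holm


def compare_bands(
    records: pd.DataFrame, *, min_count: int = DEFAULT_MIN_COUNT
) -> BandComparison:
    """Compare residual variability across eccentricity bands.

    SD curves are computed per band; for each band pair, SD values in the dB
    bins reliable in both bands are compared with a two-sided Wilcoxon
    signed-rank test, Holm-corrected over the three pairs.
    """
    bands = band_indices()
    loc_band = {}
    for band, idx in bands.items():
        for i in idx:
            loc_band[int(i)] = band
    tagged = records.assign(band=records["location"].map(loc_band))
    curves: dict[str, SDCurve] = {}
    for band in BANDS:
        sub = tagged[tagged["band"] == band]
        if len(sub) == 0:
            warnings.warn(f"band {band} has no residual records; excluded")
            continue
        curves[band] = sd_by_sensitivity(sub, min_count=min_count)
    if len(curves) < 2:
        raise ValueError("records must span at least 2 eccentricity bands")
    pairs = [
        (a, b)
        for i, a in enumerate(BANDS)
        for b in BANDS[i + 1:]
        if a in curves and b in curves
    ]
    rows = []
    for a, b in pairs:
        ca, cb = curves[a], curves[b]
        ok = ca.reliable & cb.reliable
        diff = ca.sd[ok] - cb.sd[ok]
        if diff.size < 3 or np.allclose(diff, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(diff, alternative="two-sided").pvalue)
        med = float(np.median(diff)) if diff.size else np.nan
        rows.append(
            {
                "band_a": a, "band_b": b, "n_bins": int(ok.sum()),
                "median_diff": med,
                "higher": a if med > 0 else (b if med < 0 else "tie"),
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        from statsmodels.stats.multitest import multipletests

        table["p_holm"] = multipletests(table["p"], method="holm")[1]
    return BandComparison(curves=curves, table=table)


# ---------------------------------------------------------------------------
# model-style wrapper


class VariabilityModel:
    """Cohort-level variability estimation in the Model/Results style.

    Runs pointwise regressions over a cohort, pools the residuals, and on
    :meth:`fit` returns a :class:`VariabilityResults` holding the SD curve,
    the log-linear and spline summaries, and the eccentricity-band
    comparison.
    """

    def __init__(
        self,
        cohort: Iterable[VFSeries],
        model_kind: str = "exp",
        normative=None,
        *,
        knots: tuple[float, float] = (14.0, 32.0),
        min_exams: int = 6,
        min_followup_years: float = 3.0,
        min_count: int = DEFAULT_MIN_COUNT,
    ) -> None:
        self.cohort = list(cohort)
        self.model_kind = model_kind
        self.normative = normative
        self.knots = knots
        self.min_exams = min_exams
        self.min_followup_years = min_followup_years
        self.min_count = min_count

    def fit(self) -> "VariabilityResults":
        records = pool_residuals(
            self.cohort, self.model_kind, self.normative,
            min_exams=self.min_exams, min_followup_years=self.min_followup_years,
        )
        curve = sd_by_sensitivity(records, min_count=self.min_count)
        loglinear = fit_loglinear_sd(curve)
        try:
            spline = fit_spline_sd(curve, knots=self.knots)
        except ValueError:
            spline = None
        try:
            bands = compare_bands(records, min_count=self.min_count)
        except ValueError:
            bands = None
        return VariabilityResults(
            model=self, records=records, curve=curve,
            loglinear=loglinear, spline=spline, bands=bands,
        )


@dataclass
class VariabilityResults:
    model: VariabilityModel
    records: pd.DataFrame
    curve: SDCurve
    loglinear: LogLinearSDFit
    spline: SplineSDFit | None = None
    bands: BandComparison | None = None

    def sigma(self, s):
        """sigma(s) from the spline if available, else the log-linear fit."""
        return evaluate_sd_model(self.spline or self.loglinear, s)

    def summary(self) -> str:
        import io

        buf = io.StringIO()
        buf.write("Visual-field variability estimate\n")
        buf.write("=================================\n")
        buf.write(f"model kind:      {self.model.model_kind}\n")
        buf.write(f"residuals:       {len(self.records)}\n")
        buf.write(f"reliable bins:   {int(self.curve.reliable.sum())}\n")
        buf.write(
            f"ln(SD) = {self.loglinear.beta:+.4f} * S + {self.loglinear.alpha:.4f}"
            f"  (bins {self.loglinear.s_min}-{self.loglinear.s_max})\n"
        )
        if self.spline is not None:
            b = self.spline.betas
            k = self.spline.knots
            buf.write(
                f"spline ln(SD) = {self.spline.alpha:.4f} {b[0]:+.4f}*S "
                f"{b[1]:+.4f}*(S-{k[0]:g})+ {b[2]:+.4f}*(S-{k[1]:g})+\n"
            )
        if self.bands is not None:
            buf.write("band comparison (Wilcoxon, Holm-adjusted):\n")
            for _, row in self.bands.table.iterrows():
                buf.write(
                    f"  {row.band_a} vs {row.band_b}: higher={row.higher}, "
                    f"p_holm={row.p_holm:.3g}\n"
                )
        return buf.getvalue()

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        self.curve.plot(ax=ax, log=True, label="binned SD")
        ok = self.curve.reliable
        s = self.curve.sensitivity[ok].astype(float)
        ax.plot(s, self.loglinear.ln_sd(s), label="log-linear")
        if self.spline is not None:
            ax.plot(s, self.spline.ln_sd(s), label="spline")
        ax.legend()
        return ax
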