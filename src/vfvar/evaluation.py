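"""Model-comparison harness: goodness of fit and rolling future-VF prediction.

Models are compared with the root-mean-square error (RMSE, dB) between
observed and fitted/predicted sensitivities.  For the data fit all exams are
regressed over the entire follow-up.  For prediction, regressions on the
first m exams predict the observed values of a later target exam under the
rolling schedules: target 10 uses training windows of the first 5..9 exams,
target 15 uses 5, 7, 9, 11, 13, and target 20 uses 5, 8, 11, 14, 17.  RMSE
is computed per eye (over included locations), then summarized across eyes
as median (IQR); models are compared pairwise per training window with
two-sided Wilcoxon signed-rank tests, Holm-adjusted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normative import NormativeModel
from .series import VFSeries, filter_reliable
from .trend import PointwiseTrend

logger = logging.getLogger(__name__)

SCHEDULES: dict[int, tuple[int, ...]] = {
    10: (5, 6, 7, 8, 9),
    15: (5, 7, 9, 11, 13),
    20: (5, 8, 11, 14, 17),
}

DEFAULT_MODELS = ("linear", "weighted_linear", "exp")


@dataclass(frozen=True)
class PredictionSchedule:
    """Training windows (each "the first m exams") for one target exam."""

    target: int  # 1-based exam number to predict
    windows: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(w >= self.target for w in self.windows):
            raise ValueError("every training window must end before the target exam")
        if any(b >= a for b, a in zip(self.windows, self.windows[1:])):
            raise ValueError("windows must be strictly increasing")


def schedule_for(target: int, windows: tuple[int, ...] | None = None) -> PredictionSchedule:
    """The rolling schedule for a target exam number (10, 15 or 20), or a
    custom one when ``windows`` is given."""
    if windows is not None:
        return PredictionSchedule(target=target, windows=tuple(windows))
    if target not in SCHEDULES:
        raise ValueError(
            f"no built-in schedule for target {target}; supply windows explicitly"
        )
    return PredictionSchedule(target=target, windows=SCHEDULES[target])


@dataclass
class RMSEResult:
    """Per-eye RMSE for one model in one context."""

    eye_id: str
    model_kind: str
    context: str  # "fit" or "prediction"
    rmse: float
    n_locations: int
    window: int | None = None
    target: int | None = None

    def as_row(self) -> dict:
        return {
            "eye_id": self.eye_id, "model_kind": self.model_kind,
            "context": self.context, "target": self.target,
            "window": self.window, "rmse": self.rmse,
            "n_locations": self.n_locations,
        }


def fit_rmse(
    series: VFSeries,
    model_kind: str,
    noise_model=None,
    normative: NormativeModel | None = None,
) -> RMSEResult:
    """Whole-follow-up goodness-of-fit RMSE over all included locations."""
    res = PointwiseTrend(
        series, kind=model_kind, noise_model=noise_model,
        normative=normative, context="modeling",
    ).fit()
    if not res.fits:
        raise ValueError(f"no included locations for eye {series.eye_id!r}")
    return RMSEResult(
        eye_id=series.eye_id, model_kind=model_kind, context="fit",
        rmse=res.rmse(), n_locations=len(res.fits),
    )


def predict_rmse(
    series: VFSeries,
    model_kind: str,
    window: int,
    target: int,
    noise_model=None,
    normative: NormativeModel | None = None,
    reference: np.ndarray | None = None,
) -> RMSEResult:
    """Train on the first ``window`` exams, predict at the target exam's
    time, and score against that exam's observed values (or ``reference``,
    e.g. the noise-free truth in simulation studies)."""
    if series.n_exams < target:
        raise ValueError(
            f"eye {series.eye_id!r} has {series.n_exams} exams, fewer than target {target}"
        )
    if window >= target:
        raise ValueError("training window must end before the target exam")
    train = VFSeries(series.eye_id, series.baseline_age_years, series.exams[:window])
    res = PointwiseTrend(
        train, kind=model_kind, noise_model=noise_model,
        normative=normative, context="modeling",
    ).fit()
    if not res.fits:
        raise ValueError(f"no included locations for eye {series.eye_id!r}")
    t_target = series.exams[target - 1].time_years
    pred = res.predict(t_target)
    obs = series.exams[target - 1].sensitivities if reference is None else np.asarray(reference)
    ok = np.isfinite(pred)
    err = obs[ok] - pred[ok]
    return RMSEResult(
        eye_id=series.eye_id, model_kind=model_kind, context="prediction",
        rmse=float(np.sqrt(np.mean(err**2))), n_locations=int(ok.sum()),
        window=window, target=target,
    )


@dataclass
class ComparisonTable:
    """Median (IQR) RMSE per model with pairwise paired rank tests."""

    summary: pd.DataFrame   # target, window, model_kind, n, median, q1, q3, best
    pairwise: pd.DataFrame  # target, window, model_a, model_b, n, p, p_holm


def _paired_p(a: np.ndarray, b: np.ndarray) -> float:
    diff = a - b
    if np.allclose(diff, 0.0):
        return 1.0
    return float(stats.wilcoxon(diff, alternative="two-sided").pvalue)


def compare_models(results: pd.DataFrame) -> ComparisonTable:
    """Compare models from a long-format RMSE table.

    Rows are paired by eye within each (context, target, window) cell; eyes
    missing a model in a cell are dropped from that cell with a warning.
    The model with the strictly smallest median is flagged ``best``.
    """
    from statsmodels.stats.multitest import multipletests

    df = results.copy()
    models = sorted(df["model_kind"].unique())
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    df["window"] = df["window"].astype(float).fillna(-1)
    df["target"] = df["target"].astype(float).fillna(-1)
    sum_rows, pair_rows = [], []
    for (context, target, window), cell in df.groupby(["context", "target", "window"]):
        wide = cell.pivot_table(index="eye_id", columns="model_kind", values="rmse")
        complete = wide.dropna()
        if len(complete) < len(wide):
            warnings.warn(
                f"dropping {len(wide) - len(complete)} unpaired eye(s) in "
                f"context={context} target={target:g} window={window:g}"
            )
        medians = complete.median()
        best = medians.idxmin() if (medians == medians.min()).sum() == 1 else None
        for m in complete.columns:
            sum_rows.append(
                {
                    "context": context, "target": target, "window": window,
                    "model_kind": m, "n": len(complete),
                    "median": float(medians[m]),
                    "q1": float(complete[m].quantile(0.25)),
                    "q3": float(complete[m].quantile(0.75)),
                    "best": m == best,
                }
            )
        cell_pairs = []
        for i, a in enumerate(complete.columns):
            for b in complete.columns[i + 1:]:
                cell_pairs.append(
                    {
                        "context": context, "target": target, "window": window,
                        "model_a": a, "model_b": b, "n": len(complete),
                        "p": _paired_p(complete[a].to_numpy(), complete[b].to_numpy()),
                    }
                )
        if cell_pairs:
            ps = [r["p"] for r in cell_pairs]
            adj = multipletests(ps, method="holm")[1]
            for r, q in zip(cell_pairs, adj):
                r["p_holm"] = float(q)
            pair_rows.extend(cell_pairs)
    summary = pd.DataFrame(sum_rows)
    pairwise = pd.DataFrame(pair_rows)
    for frame in (summary, pairwise):
        if len(frame):
            frame["target"] = frame["target"].replace(-1, np.nan)
            frame["window"] = frame["window"].replace(-1, np.nan)
    return ComparisonTable(summary=summary, pairwise=pairwise)


@dataclass
class BenchmarkResult:
    """Everything the model-comparison harness produces for one cohort."""

    results: pd.DataFrame  # long format, one row per eye/model/context/window
    comparison: ComparisonTable

    @property
    def fit_results(self) -> pd.DataFrame:
        return self.results[self.results["context"] == "fit"]

    @property
    def prediction_results(self) -> pd.DataFrame:
        return self.results[self.results["context"] == "prediction"]

    def summary(self) -> str:
        import io

        buf = io.StringIO()
        buf.write("Model comparison benchmark\n")
        buf.write("==========================\n")
        s = self.comparison.summary
        fit = s[s["context"] == "fit"]
        if len(fit):
            buf.write("data fit (median [IQR] RMSE, dB):\n")
            for _, r in fit.iterrows():
                star = " *" if r["best"] else ""
                buf.write(
                    f"  {r.model_kind:<16} {r['median']:.3f} [{r.q1:.3f}, {r.q3:.3f}]"
                    f" (n={r.n}){star}\n"
                )
        pred = s[s["context"] == "prediction"]
        for (target, window), cell in pred.groupby(["target", "window"]):
            buf.write(f"predict exam {target:g} from first {window:g}:\n")
            for _, r in cell.iterrows():
                star = " *" if r["best"] else ""
                buf.write(
                    f"  {r.model_kind:<16} {r['median']:.3f} [{r.q1:.3f}, {r.q3:.3f}]{star}\n"
                )
        return buf.getvalue()


def run_benchmark(
    cohort,
    models: tuple[str, ...] = DEFAULT_MODELS,
    targets: tuple[int, ...] = (10, 15, 20),
    noise_model=None,
    normative: NormativeModel | None = None,
    *,
    apply_reliability: bool = True,
    schedules: dict[int, tuple[int, ...]] | None = None,
) -> BenchmarkResult:
    """Fit RMSE plus every scheduled prediction for every model and eye.

    Deterministic given the cohort and configuration.  Per-eye failures are
    logged and excluded from pairing rather than aborting the run.
    """
    rows = []
    n_failures = 0
    for series in cohort:
        if apply_reliability:
            try:
                series = filter_reliable(series)
            except ValueError:
                n_failures += 1
                continue
        for model in models:
            try:
                rows.append(fit_rmse(series, model, noise_model, normative).as_row())
            except ValueError as exc:
                logger.warning("fit failed for %s/%s: %s", series.eye_id, model, exc)
                n_failures += 1
            for target in targets:
                if series.n_exams < target:
                    continue
                sched = schedule_for(target, (schedules or {}).get(target))
                for window in sched.windows:
                    try:
                        rows.append(
                            predict_rmse(
                                series, model, window, target, noise_model, normative
                            ).as_row()
                        )
                    except ValueError as exc:
                        logger.warning(
                            "prediction failed for %s/%s/%d/%d: %s",
                            series.eye_id, model, target, window, exc,
                        )
                        n_failures += 1
    results = pd.DataFrame(rows)
    if results.empty:
        raise ValueError("benchmark produced no results")
    comparison = compare_models(results)
    if n_failures:
        logger.info("benchmark completed with %d per-eye failures", n_failures)
    return BenchmarkResult(results=results, comparison=comparison)
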