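"""Pointwise regression models of threshold sensitivity over time.

Each test location's sensitivity series y(t) (dB) is modeled by one of:

* ``linear``            y = a + b t                      (ordinary least squares)
* ``weighted_linear``   y = a + b t, weights w_i = 1/v_i (variance-weighted LS)
* ``exp``               decay  ln(y) = a + b t, or, when the raw linear trend
                        is positive, improvement ln(Y - y) = a + b t where Y
                        is the normative ceiling (normal mean + 2 SD)
* ``logistic``          y = zeta / (1 + exp(a + b t))    (least squares via
                        Newton-Raphson on the sum-of-squares gradient)

Linear predictions are censored to [0, Y]; the exponential and logistic
curves approach floor/ceiling asymptotically and need no censoring.
Censoring applies to predictions only, never to the training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import BLIND_SPOT_INDICES, grid_24_2
from .normative import NormativeModel
from .series import VFSeries, location_inclusion_mask

#: floor applied to y (or Y - y) before taking logarithms: half the 1-dB
#: instrument step, so a measured 0 dB enters the log-space fit as 0.5 dB.
LOG_CLAMP_DB = 0.5

#: analyzed sensitivity range (dB)
S_MIN, S_MAX = 0, 35

MODEL_KINDS = ("linear", "weighted_linear", "exp", "logistic")


@dataclass
class TrendFit:
    """A fitted pointwise trend.

    ``kind`` is the resolved model (``exp`` becomes ``exp_decay`` or
    ``exp_improve``); ``alpha``/``beta`` are intercept and slope on the
    model's own scale (dB for linear kinds, log scale for exponential, the
    linear predictor for logistic); ``zeta`` is the logistic upper asymptote;
    ``ceiling_Y`` the censoring/improvement ceiling in dB.
    """

    kind: str
    alpha: float
    beta: float
    n_obs: int
    zeta: float | None = None
    ceiling_Y: float | None = None
    converged: bool = True


class FitError(ValueError):
    """Raised when a pointwise fit cannot be computed."""


def _validate_xy(times, sens, min_n=3):
    x = np.asarray(times, dtype=float)
    y = np.asarray(sens, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("times and sensitivities must be 1-D and the same length")
    if x.size < min_n:
        raise FitError(f"need at least {min_n} observations, got {x.size}")
    if np.ptp(x) == 0:
        raise FitError("degenerate design: all times equal")
    return x, y


def _ols(x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None) -> tuple[float, float]:
    """Closed-form (weighted) simple linear regression: returns (alpha, beta)."""
    if w is None:
        w = np.ones_like(x)
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    if sxx == 0:
        raise FitError("degenerate design: zero weighted time variance")
    beta = (w * (x - xbar) * (y - ybar)).sum() / sxx
    return ybar - beta * xbar, beta


def fit_linear(times, sens) -> TrendFit:
    """Unweighted pointwise linear regression (OLS)."""
    x, y = _validate_xy(times, sens)
    alpha, beta = _ols(x, y)
    return TrendFit(kind="linear", alpha=alpha, beta=beta, n_obs=x.size)


@dataclass
class WeightSpec:
    """Per-observation variances v_i (dB^2) and weights w_i = 1/v_i."""

    variances: np.ndarray

    def __post_init__(self) -> None:
        self.variances = np.asarray(self.variances, dtype=float)
        if np.any(self.variances <= 0) or not np.all(np.isfinite(self.variances)):
            raise ValueError("variances must be positive and finite")

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / self.variances


def _sigma_of(noise_model, s):
    """Evaluate a noise model sigma(s); accepts NoiseModel-likes or callables."""
    if hasattr(noise_model, "sigma"):
        return np.asarray(noise_model.sigma(s), dtype=float)
    return np.asarray(noise_model(s), dtype=float)


def weights_from_noise_model(observed_sens, noise_model) -> WeightSpec:
    """v_i = sigma(y_i)^2 with sigma evaluated at the observed sensitivity
    rounded to integer dB (the variance table is indexed by observed dB)."""
    s = np.clip(np.round(np.asarray(observed_sens, dtype=float)), S_MIN, S_MAX)
    sigma = _sigma_of(noise_model, s)
    if np.any(sigma <= 0):
        raise ValueError("noise model returned non-positive sigma")
    return WeightSpec(variances=sigma**2)


def fit_weighted_linear(times, sens, weights) -> TrendFit:
    """Variance-weighted pointwise linear regression.

    ``weights`` may be a :class:`WeightSpec` or an array of raw weights w_i.
    """
    x, y = _validate_xy(times, sens)
    if isinstance(weights, WeightSpec):
        w = weights.weights
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be positive and finite")
    if w.shape != x.shape:
        raise ValueError("weights must match the observations in length")
    alpha, beta = _ols(x, y, w)
    return TrendFit(kind="weighted_linear", alpha=alpha, beta=beta, n_obs=x.size)


def fit_exponential(times, sens, ceiling_Y) -> TrendFit:
    """Pointwise exponential regression.

    The direction of the raw linear trend selects the branch: a negative (or
    zero) slope fits the decay model ln(y) = a + b t; a positive slope fits
    the improvement model ln(Y - y) = a + b t toward the normative ceiling
    Y.  Values below ``LOG_CLAMP_DB`` are clamped before the logarithm.
    ``ceiling_Y`` may be a scalar or a per-observation array (age-matched).
    """
    x, y = _validate_xy(times, sens)
    Y = np.broadcast_to(np.asarray(ceiling_Y, dtype=float), x.shape)
    _, slope = _ols(x, y)
    if slope <= 0:  # ties route to the decay branch
        ly = np.log(np.clip(y, LOG_CLAMP_DB, None))
        alpha, beta = _ols(x, ly)
        return TrendFit(
            kind="exp_decay", alpha=alpha, beta=beta, n_obs=x.size,
            ceiling_Y=float(Y[-1]),
        )
    lz = np.log(np.clip(Y - y, LOG_CLAMP_DB, None))
    alpha, beta = _ols(x, lz)
    return TrendFit(
        kind="exp_improve", alpha=alpha, beta=beta, n_obs=x.size,
        ceiling_Y=float(Y[-1]),
    )


# ---------------------------------------------------------------------------
# logistic fit


def _logistic_curve(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    zeta, alpha, beta = theta
    u = alpha + beta * x
    return zeta / (1.0 + np.exp(np.clip(u, -500, 500)))


def _logistic_jacobian(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    zeta, alpha, beta = theta
    u = np.clip(alpha + beta * x, -500, 500)
    p = 1.0 / (1.0 + np.exp(u))
    dp = -p * (1.0 - p)
    return np.column_stack([p, zeta * dp, zeta * dp * x])


ZETA_MAX = 50.0  # upper asymptote bounded by the instrument range


def fit_logistic(
    times,
    sens,
    *,
    tol: float = 1e-8,
    max_iter: int = 200,
    n_restarts: int = 5,
    rng_seed: int = 19,
) -> TrendFit:
    """Least-squares logistic fit y = zeta / (1 + exp(a + b t)).

    Newton-Raphson iterations on the sum-of-squares gradient (Gauss-Newton
    normal equations) with step halving.  Initialization: zeta at max(y)+1,
    slope/intercept from an OLS fit of the logit transform, the intercept
    then shifted to match the first observation.  Up to ``n_restarts``
    seeded random restarts before giving up; a run that exhausts its
    iterations returns the best iterate with ``converged=False``.
    """
    x, y = _validate_xy(times, sens, min_n=4)
    rng = np.random.default_rng(rng_seed)

    def initial() -> np.ndarray:
        zeta0 = min(max(y.max() + 1.0, 1.0), ZETA_MAX)
        ratio = np.clip(zeta0 / np.clip(y, LOG_CLAMP_DB, None) - 1.0, 1e-6, None)
        _, beta0 = _ols(x, np.log(ratio))
        alpha0 = np.log(max(zeta0 / max(y[0], LOG_CLAMP_DB) - 1.0, 1e-6)) - beta0 * x[0]
        return np.array([zeta0, alpha0, beta0])

    def sse(theta: np.ndarray) -> float:
        r = y - _logistic_curve(theta, x)
        return float(r @ r)

    best_theta, best_sse, best_converged = None, np.inf, False
    theta0 = initial()
    for attempt in range(n_restarts + 1):
        if attempt > 0:
            theta = theta0 + rng.normal(0, [2.0, 1.0, 0.5])
            theta[0] = np.clip(theta[0], 1.0, ZETA_MAX)
        else:
            theta = theta0.copy()
        current = sse(theta)
        converged = False
        singular = False
        for _ in range(max_iter):
            r = y - _logistic_curve(theta, x)
            J = _logistic_jacobian(theta, x)
            H = J.T @ J
            g = J.T @ r
            try:
                step = np.linalg.solve(H + 1e-12 * np.eye(3), g)
            except np.linalg.LinAlgError:
                singular = True
                break
            if not np.all(np.isfinite(step)):
                singular = True
                break
            # step halving line search
            scale = 1.0
            for _ in range(40):
                cand = theta + scale * step
                cand[0] = np.clip(cand[0], 1e-3, ZETA_MAX)
                new = sse(cand)
                if new <= current + 1e-15:
                    break
                scale *= 0.5
            else:
                converged = True  # no further descent possible
                break
            moved = np.max(np.abs(cand - theta))
            theta, current = cand, new
            if moved < tol:
                converged = True
                break
        if current < best_sse:
            best_theta, best_sse, best_converged = theta, current, converged
        if converged and not singular:
            best_theta, best_sse, best_converged = (
                (theta, current, True) if current <= best_sse else (best_theta, best_sse, best_converged)
            )
            break
    if best_theta is None:
        raise FitError("logistic fit failed: singular Hessian in every attempt")
    zeta, alpha, beta = best_theta
    return TrendFit(
        kind="logistic", alpha=float(alpha), beta=float(beta),
        zeta=float(zeta), n_obs=x.size, converged=bool(best_converged),
    )


# ---------------------------------------------------------------------------
# prediction


def predict(fit: TrendFit, t, ceiling_Y: float | np.ndarray | None = None):
    """Predicted sensitivity (dB) at time(s) ``t``.

    Linear kinds are censored into [0, Y]; exponential decay is e^(a+bt);
    improvement is Y - e^(a+bt) floored at 0; logistic is zeta/(1+e^(a+bt)).
    """
    t = np.asarray(t, dtype=float)
    Y = fit.ceiling_Y if ceiling_Y is None else ceiling_Y
    if fit.kind in ("linear", "weighted_linear"):
        raw = fit.alpha + fit.beta * t
        hi = np.inf if Y is None else Y
        return np.clip(raw, 0.0, hi)
    if fit.kind == "exp_decay":
        return np.exp(fit.alpha + fit.beta * t)
    if fit.kind == "exp_improve":
        if Y is None:
            raise ValueError("exp_improve prediction needs a ceiling")
        return np.clip(Y - np.exp(fit.alpha + fit.beta * t), 0.0, None)
    if fit.kind == "logistic":
        return _logistic_curve(np.array([fit.zeta, fit.alpha, fit.beta]), t)
    raise ValueError(f"unknown fit kind {fit.kind!r}")


# ---------------------------------------------------------------------------
# whole-eye fitting


def _ceilings_for(series: VFSeries, normative: NormativeModel | None, times) -> np.ndarray:
    """(n_times, 54) age-matched ceilings; a flat fallback when no normative."""
    times = np.asarray(times, dtype=float)
    if normative is None:
        return np.full((times.size, 54), float(S_MAX))
    return np.stack(
        [normative.ceiling_field(series.age_at(t)) for t in times]
    )


def fit_all_locations(
    series: VFSeries,
    model_kind: str = "exp",
    noise_model=None,
    normative: NormativeModel | None = None,
    *,
    context: str = "variability",
) -> tuple[dict[int, TrendFit], dict[int, str]]:
    """Fit every included location; returns (fits, failures) keyed by location.

    ``context="variability"`` excludes only the blind spot;
    ``context="modeling"`` additionally applies the early-floor inclusion
    mask.  Per-location failures are recorded, not raised.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}; choose from {MODEL_KINDS}")
    if context == "modeling":
        included = np.flatnonzero(location_inclusion_mask(series))
    elif context == "variability":
        mask = np.ones(54, dtype=bool)
        mask[list(BLIND_SPOT_INDICES)] = False
        included = np.flatnonzero(mask)
    else:
        raise ValueError(f"unknown context {context!r}")
    times = series.times
    Y = _ceilings_for(series, normative, times)
    sens = series.sensitivity_matrix()
    fits: dict[int, TrendFit] = {}
    failures: dict[int, str] = {}
    for loc in included:
        y = sens[:, loc]
        try:
            if model_kind == "linear":
                fit = fit_linear(times, y)
                fit.ceiling_Y = float(Y[-1, loc])
            elif model_kind == "weighted_linear":
                if noise_model is None:
                    raise FitError("weighted_linear requires a noise model")
                fit = fit_weighted_linear(times, y, weights_from_noise_model(y, noise_model))
                fit.ceiling_Y = float(Y[-1, loc])
            elif model_kind == "exp":
                fit = fit_exponential(times, y, Y[:, loc])
            else:
                fit = fit_logistic(times, y)
        except (FitError, ValueError) as exc:
            failures[int(loc)] = str(exc)
            continue
        fits[int(loc)] = fit
    return fits, failures


class PointwiseTrend:
    """Pointwise trend model for one eye's visual-field series.

    A thin model object in the statsmodels style: construct from data, call
    :meth:`fit` to obtain a :class:`PointwiseTrendResults`.

    Parameters
    ----------
    series
        The eye's :class:`~vfvar.series.VFSeries` (assumed reliability-filtered;
        use :func:`vfvar.series.filter_reliable` upstream).
    kind
        One of ``linear``, ``weighted_linear``, ``exp``, ``logistic``.
    noise_model
        sigma(s) model supplying WLS variances (required for weighted_linear).
    normative
        Normative surface for the ceiling Y; defaults to a flat 35 dB ceiling
        when omitted.
    context
        ``"modeling"`` (early-floor locations excluded) or ``"variability"``.
    """

    def __init__(
        self,
        series: VFSeries,
        kind: str = "exp",
        noise_model=None,
        normative: NormativeModel | None = None,
        context: str = "modeling",
    ) -> None:
        self.series = series
        self.kind = kind
        self.noise_model = noise_model
        self.normative = normative
        self.context = context

    def fit(self) -> "PointwiseTrendResults":
        fits, failures = fit_all_locations(
            self.series, self.kind, self.noise_model, self.normative,
            context=self.context,
        )
        return PointwiseTrendResults(self, fits, failures)


@dataclass
class PointwiseTrendResults:
    """Fitted pointwise trends for one eye, with prediction and diagnostics."""

    model: PointwiseTrend
    fits: dict[int, TrendFit]
    failures: dict[int, str] = field(default_factory=dict)

    @property
    def series(self) -> VFSeries:
        return self.model.series

    def predict(self, t: float) -> np.ndarray:
        """Per-location predictions at time ``t`` (NaN where not fitted)."""
        Y = _ceilings_for(self.series, self.model.normative, [t])[0]
        out = np.full(54, np.nan)
        for loc, fit in self.fits.items():
            out[loc] = predict(fit, t, ceiling_Y=Y[loc])
        return out

    def fitted_values(self) -> np.ndarray:
        """(n_exams, 54) in-sample fitted values (NaN where not fitted)."""
        times = self.series.times
        Y = _ceilings_for(self.series, self.model.normative, times)
        out = np.full((times.size, 54), np.nan)
        for loc, fit in self.fits.items():
            out[:, loc] = predict(fit, times, ceiling_Y=Y[:, loc])
        return out

    def residuals(self) -> np.ndarray:
        """(n_exams, 54) observed - fitted (NaN where not fitted)."""
        return self.series.sensitivity_matrix() - self.fitted_values()

    def residual_records(self):
        """Long-format residual records (one row per location-exam pair)."""
        from .variability import residual_records_from_results

        return residual_records_from_results(self)

    def rmse(self) -> float:
        r = self.residuals()
        r = r[np.isfinite(r)]
        if r.size == 0:
            raise ValueError("no fitted locations")
        return float(np.sqrt(np.mean(r**2)))

    def to_frame(self):
        """Serializable fit table (eye, location, kind, parameters)."""
        import pandas as pd

        rows = [
            {
                "eye_id": self.series.eye_id,
                "location": loc,
                "kind": f.kind,
                "alpha": f.alpha,
                "beta": f.beta,
                "zeta": f.zeta,
                "ceiling_Y": f.ceiling_Y,
                "n_obs": f.n_obs,
                "converged": f.converged,
            }
            for loc, f in sorted(self.fits.items())
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        import io

        betas = np.array([f.beta for f in self.fits.values()])
        buf = io.StringIO()
        buf.write("Pointwise trend fit\n")
        buf.write("===================\n")
        buf.write(f"eye:            {self.series.eye_id}\n")
        buf.write(f"model kind:     {self.model.kind} ({self.model.context} context)\n")
        buf.write(f"exams:          {self.series.n_exams} over {self.series.followup_years:.1f} y\n")
        buf.write(f"locations fit:  {len(self.fits)} (failures: {len(self.failures)})\n")
        buf.write(f"RMSE (dB):      {self.rmse():.3f}\n")
        buf.write(
            f"slope (median [IQR]): {np.median(betas):.4f} "
            f"[{np.percentile(betas, 25):.4f}, {np.percentile(betas, 75):.4f}]\n"
        )
        return buf.getvalue()

    def plot_location(self, location: int, ax=None):
        """Observed points and the fitted curve for one location."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        times = self.series.times
        ax.plot(times, self.series.sensitivity_matrix()[:, location], "o", label="observed")
        tt = np.linspace(times[0], times[-1], 100)
        fit = self.fits[location]
        Y = _ceilings_for(self.series, self.model.normative, tt)[:, location]
        ax.plot(tt, predict(fit, tt, ceiling_Y=Y), "-", label=fit.kind)
        p = grid_24_2()[location]
        ax.set_xlabel("time (years)")
        ax.set_ylabel("sensitivity (dB)")
        ax.set_title(f"{self.series.eye_id} location {location} ({p.x_deg:g}, {p.y_deg:g})")
        ax.legend()
        return ax
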