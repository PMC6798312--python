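"""Noise models: sigma as a function of threshold sensitivity.

A :class:`NoiseModel` supplies the residual SD sigma(s) (dB) on the analyzed
range [0, 35] dB.  The same object drives both simulation (Gaussian noise
with sensitivity-dependent SD) and variance weighting in weighted linear
regression.  The default ``anchor`` model interpolates linearly through the
three measured SD anchors - 3.4 dB at 0 dB, a 5.5 dB peak at 11 dB, and a
2.0 dB minimum at 33 dB - with flat extrapolation above 33 dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .variability import (
    LogLinearSDFit,
    SDCurve,
    SplineSDFit,
    evaluate_sd_model,
)

#: measured SD-of-residuals anchors: (sensitivity dB, SD dB)
SD_ANCHORS = ((0.0, 3.4), (11.0, 5.5), (33.0, 2.0))

NOISE_KINDS = ("anchor_interp", "loglinear", "spline", "table", "constant")


@dataclass
class NoiseModel:
    """sigma(s) on [0, 35] dB, in one of several parameterizations."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_anchors(cls, anchors=SD_ANCHORS) -> "NoiseModel":
        pts = sorted((float(s), float(sd)) for s, sd in anchors)
        if any(sd <= 0 for _, sd in pts):
            raise ValueError("anchor SDs must be positive")
        return cls("anchor_interp", {"anchors": tuple(pts)})

    @classmethod
    def from_loglinear(cls, alpha: float, beta: float) -> "NoiseModel":
        return cls("loglinear", {"fit": LogLinearSDFit(alpha=alpha, beta=beta, s_min=0, s_max=35)})

    @classmethod
    def from_fit(cls, fit: LogLinearSDFit | SplineSDFit) -> "NoiseModel":
        kind = "loglinear" if isinstance(fit, LogLinearSDFit) else "spline"
        return cls(kind, {"fit": fit})

    @classmethod
    def from_curve(cls, curve: SDCurve) -> "NoiseModel":
        return cls("table", {"curve": curve})

    @classmethod
    def from_table(cls, sensitivity, sd, n: int = 10_000) -> "NoiseModel":
        curve = SDCurve(
            sensitivity=np.asarray(sensitivity, int),
            sd=np.asarray(sd, float),
            n=np.full(len(sd), n),
        )
        return cls("table", {"curve": curve})

    @classmethod
    def constant(cls, sigma: float) -> "NoiseModel":
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        return cls("constant", {"sigma": float(sigma)})

    # -- evaluation ---------------------------------------------------------

    def sigma(self, s):
        s_arr = np.clip(np.asarray(s, dtype=float), 0.0, 35.0)
        if self.kind == "anchor_interp":
            xs, ys = zip(*self.params["anchors"])
            # flat extrapolation beyond the outermost anchors
            out = np.interp(np.clip(s_arr, xs[0], xs[-1]), xs, ys)
        elif self.kind in ("loglinear", "spline"):
            out = self.params["fit"].sigma(s_arr)
        elif self.kind == "table":
            out = evaluate_sd_model(self.params["curve"], s_arr)
        else:
            out = np.full_like(s_arr, self.params["sigma"])
        out = np.asarray(out, dtype=float)
        return out if out.shape else float(out)

    def __call__(self, s):
        return self.sigma(s)

    # -- (de)serialization for configs -------------------------------------

    def to_dict(self) -> dict:
        if self.kind == "anchor_interp":
            return {"kind": self.kind, "anchors": [list(a) for a in self.params["anchors"]]}
        if self.kind == "loglinear":
            f = self.params["fit"]
            return {"kind": self.kind, "alpha": f.alpha, "beta": f.beta}
        if self.kind == "spline":
            f = self.params["fit"]
            return {
                "kind": self.kind, "alpha": f.alpha,
                "betas": list(f.betas), "knots": list(f.knots),
            }
        if self.kind == "table":
            c = self.params["curve"]
            return {
                "kind": self.kind,
                "sensitivity": c.sensitivity.tolist(),
                "sd": c.sd.tolist(),
            }
        return {"kind": self.kind, "sigma": self.params["sigma"]}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseModel":
        kind = d["kind"]
        if kind == "anchor_interp":
            return cls.from_anchors(tuple(tuple(a) for a in d["anchors"]))
        if kind == "loglinear":
            return cls.from_loglinear(d["alpha"], d["beta"])
        if kind == "spline":
            return cls.from_fit(
                SplineSDFit(alpha=d["alpha"], betas=tuple(d["betas"]), knots=tuple(d["knots"]))
            )
        if kind == "table":
            return cls.from_table(d["sensitivity"], d["sd"])
        return cls.constant(d["sigma"])


def anchor_noise_model() -> NoiseModel:
    """The default noise model through the measured SD anchors."""
    return NoiseModel.from_anchors()
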