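"""Growth-corrected single-exponential decay fits for protein stability.

Translation-shutoff time courses quantify a protein's immunoblot signal,
normalized to culture OD, at increasing times after adding a translation
inhibitor.  Because cells keep growing, a perfectly stable protein appears
to decay through dilution; multiplying the per-biomass signal by the
biomass ratio OD(t)/OD(0) recovers total abundance.  The corrected series
is fitted to A * exp(-k t); the half-life is ln 2 / k.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats as sps

from .io import ValidationError

logger = logging.getLogger("regulonflow")

__all__ = [
    "DecayDataset",
    "DecayFit",
    "correct_for_dilution",
    "fit_half_life",
    "percent_remaining",
]

#: decay rates below this (per minute) are reported as an infinite half-life
RATE_TOLERANCE = 1e-12


@dataclass(frozen=True)
class DecayDataset:
    """One decay series: minutes, positive signals, optional growth factors."""

    timepoints: tuple[float, ...]
    signals: tuple[float, ...]
    growth_factor: tuple[float, ...] | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        t = np.asarray(self.timepoints, float)
        s = np.asarray(self.signals, float)
        if len(t) != len(s):
            raise ValidationError("timepoints and signals differ in length")
        if len(t) == 0 or t[0] != 0:
            raise ValidationError("first timepoint must be 0")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("timepoints must be strictly increasing")
        if np.any(s <= 0):
            raise ValidationError("signals must be positive")
        if self.growth_factor is not None:
            g = np.asarray(self.growth_factor, float)
            if len(g) != len(t):
                raise ValidationError("growth_factor length mismatch")
            if g[0] != 1 or np.any(g < 1):
                raise ValidationError("growth_factor must be >= 1 with g(0) = 1")


@dataclass(frozen=True)
class DecayFit:
    """Fitted single-exponential: rate k (1/min), half-life (min), amplitude."""

    rate: float
    half_life: float
    amplitude: float
    rss: float
    method: str = "log-linear"


def correct_for_dilution(data: DecayDataset) -> DecayDataset:
    """Convert per-biomass signal to total abundance: signal(t) * growth(t).

    The growth factor is cleared on output so the correction cannot be
    applied twice.
    """
    if data.growth_factor is None:
        raise ValidationError(
            "no growth data present; to fit uncorrected signals, skip the "
            "correction explicitly rather than calling it without growth factors")
    corrected = tuple(s * g for s, g in zip(data.signals, data.growth_factor))
    return replace(data, signals=corrected, growth_factor=None)


def fit_half_life(data: DecayDataset, method: str = "log-linear") -> DecayFit:
    """Least-squares fit of A * exp(-k t).

    ``log-linear`` (default) regresses ln(signal) on t — the standard
    procedure for single-exponential blot quantification.  ``nonlinear``
    fits the exponential directly (use it when signals may hit zero noise
    floors).  A negative fitted rate (signal increase) is clamped to k = 0
    with a warning and reported as an infinite half-life.
    """
    t = np.asarray(data.timepoints, float)
    s = np.asarray(data.signals, float)
    if len(t) < 3:
        raise ValidationError("need at least 3 timepoints for a decay fit")
    if method == "log-linear":
        res = sps.linregress(t, np.log(s))
        k = -res.slope
        amplitude = math.exp(res.intercept)
    elif method == "nonlinear":
        def model(t, a, k):
            return a * np.exp(-k * t)
        p0 = (s[0], 1e-3)
        popt, _ = optimize.curve_fit(model, t, s, p0=p0, maxfev=10000)
        amplitude, k = float(popt[0]), float(popt[1])
    else:
        raise ValidationError(f"unknown fit method {method!r}")
    if k < 0:
        logger.warning("fitted rate %.3g < 0 (signal increases); clamping to 0", k)
        k = 0.0
    half_life = math.inf if k < RATE_TOLERANCE else math.log(2) / k
    rss = float(np.sum((s - amplitude * np.exp(-k * t)) ** 2))
    return DecayFit(rate=k, half_life=half_life, amplitude=amplitude,
                    rss=rss, method=method)


def percent_remaining(data: DecayDataset, t: float,
                      interpolate: bool = False) -> float:
    """Signal at time t as a percentage of the t = 0 signal.

    ``t`` must be one of the measured timepoints unless ``interpolate`` is
    set, in which case the signal is interpolated linearly between the
    bracketing measurements.
    """
    times = np.asarray(data.timepoints, float)
    signals = np.asarray(data.signals, float)
    if t < times[0]:
        raise ValidationError(f"t = {t} precedes the first timepoint")
    exact = np.flatnonzero(np.isclose(times, t))
    if len(exact):
        value = signals[exact[0]]
    elif interpolate:
        if t > times[-1]:
            raise ValidationError(f"t = {t} beyond the last timepoint")
        value = float(np.interp(t, times, signals))
    else:
        raise ValidationError(
            f"t = {t} is not a measured timepoint (pass interpolate=True)")
    return 100.0 * value / signals[0]
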