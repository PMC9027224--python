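"""Mono-exponential plasma clearance fitting and cohort half-life summary.

Plasma series are decay-corrected relative activity concentrations, so the
fitted half-life is the biologic clearance half-time.  The cohort value is
the arithmetic mean of per-patient half-lives (not ln2 over the mean rate,
and not a pooled fit — the two differ for heterogeneous cohorts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .kinetics import LN2

__all__ = ["PlasmaSeries", "PlasmaFit", "fit_monoexp", "cohort_half_life"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlasmaSeries:
    """Decay-corrected relative plasma activity concentration over time."""

    patient_id: str
    times_min: np.ndarray
    rel_conc: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        c = np.asarray(self.rel_conc, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if t.size < 3:
            raise ValueError("need at least 3 plasma samples to fit a half-life")
        if np.any(np.diff(t) <= 0):
            raise ValueError("plasma sample times must be strictly increasing")
        if np.any(c <= 0):
            raise ValueError("plasma concentrations must be positive")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "rel_conc", c)


@dataclass(frozen=True)
class PlasmaFit:
    """Mono-exponential fit result; ``decaying`` is False for flat/rising data."""

    patient_id: str
    half_life_min: float
    amplitude: float
    rss: float
    n: int
    decaying: bool = True

    def __post_init__(self) -> None:
        if self.decaying and not self.half_life_min > 0:
            raise ValueError("half_life_min must be > 0 for a decaying fit")


def _monoexp(t, c0, k):
    return c0 * np.exp(-k * t)


def fit_monoexp(series: PlasmaSeries) -> PlasmaFit:
    """Nonlinear least-squares fit of C(t) = C₀·e^(−k·t); half-life = ln2/k.

    A log-linear regression provides the start values.  Data whose fitted
    rate is non-positive (non-decaying) are flagged rather than rejected, so
    the cohort summary can exclude them with a warning.
    """
    t, c = series.times_min, series.rel_conc
    slope, intercept = np.polyfit(t, np.log(c), 1)
    k0, c00 = -slope, float(np.exp(intercept))
    if k0 <= 0:
        log.warning("plasma series %s is non-decaying (k0=%.3g)", series.patient_id, k0)
        return PlasmaFit(
            patient_id=series.patient_id,
            half_life_min=np.inf,
            amplitude=c00,
            rss=float(np.sum((c - c00) ** 2)),
            n=int(t.size),
            decaying=False,
        )
    popt, _ = curve_fit(_monoexp, t, c, p0=(c00, k0), maxfev=10000)
    c0_fit, k_fit = float(popt[0]), float(popt[1])
    resid = c - _monoexp(t, c0_fit, k_fit)
    if k_fit <= 0:
        log.warning("fitted plasma rate for %s is non-positive", series.patient_id)
        return PlasmaFit(
            patient_id=series.patient_id,
            half_life_min=np.inf,
            amplitude=c0_fit,
            rss=float(resid @ resid),
            n=int(t.size),
            decaying=False,
        )
    return PlasmaFit(
        patient_id=series.patient_id,
        half_life_min=LN2 / k_fit,
        amplitude=c0_fit,
        rss=float(resid @ resid),
        n=int(t.size),
    )


def cohort_half_life(fits: list[PlasmaFit]) -> tuple[float, tuple[float, float]]:
    """Arithmetic mean and (min, max) range of per-patient plasma half-lives.

    Non-decaying fits are excluded with a warning; at least one valid fit is
    required.
    """
    excluded = [f.patient_id for f in fits if not f.decaying]
    if excluded:
        log.warning("excluding non-decaying plasma fits from cohort mean: %s", excluded)
    valid = [f.half_life_min for f in fits if f.decaying]
    if not valid:
        raise ValueError("no valid (decaying) plasma fits to summarize")
    return float(np.mean(valid)), (float(min(valid)), float(max(valid)))
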