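"""Urinary excretion fit and the voiding-bladder TIAC.

Cumulative decay-corrected urine activity (fraction of injected) is fitted to
a one-phase exponential association

    U(t) = F · (1 − e^(−k·t)),

where F is the plateau (fraction of injected activity ultimately excreted)
and ln2/k the biologic excretion half-time.  Under a periodic voiding model
with interval T_v, the bladder contents at time t within the cycle starting
at the last void t_v are the activity that has entered since t_v, physically
decayed:

    B(t) = e^(−λt) · [U(t) − U(t_v)],

and the bladder-contents TIAC is the sum over cycles of ∫ B(t) dt, summed
until the next cycle would change the total by less than 0.01 %.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import curve_fit

from .kinetics import GA68, LN2, Nuclide

__all__ = [
    "UrineSeries",
    "ExcretionFit",
    "fit_cumulative_excretion",
    "bladder_tiac",
    "excreted_decays_h",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class UrineSeries:
    """Cumulative decay-corrected urinary excretion for one patient.

    ``cum_activity_frac`` is the cumulated fraction of injected activity
    (absolute MBq inputs are divided by A₀ at load time).
    """

    patient_id: str
    void_times_min: np.ndarray
    cum_activity_frac: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.void_times_min, dtype=float)
        u = np.asarray(self.cum_activity_frac, dtype=float)
        if t.ndim != 1 or u.ndim != 1 or t.size != u.size or t.size == 0:
            raise ValueError("void times and cumulative activity must match, nonempty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("void times must be strictly increasing")
        if np.any(np.diff(u) < 0):
            raise ValueError("cumulative excreted activity must be nondecreasing")
        if np.any((u < 0) | (u > 1)):
            raise ValueError("cumulative fractions must lie in [0, 1]")
        object.__setattr__(self, "void_times_min", t)
        object.__setattr__(self, "cum_activity_frac", u)


@dataclass(frozen=True)
class ExcretionFit:
    """One-phase exponential association parameters with fit diagnostics."""

    limit_frac: float
    rate_per_min: float
    rss: float = 0.0
    n_points: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.limit_frac <= 1.0):
            raise ValueError(f"limit_frac must lie in [0, 1], got {self.limit_frac}")
        if not self.rate_per_min > 0:
            raise ValueError(f"rate_per_min must be > 0, got {self.rate_per_min}")

    @property
    def biologic_half_life_min(self) -> float:
        return LN2 / self.rate_per_min

    def cumulative(self, t_min):
        """U(t) = F·(1 − e^(−k·t)); handles k = ∞ (instant excretion)."""
        t = np.asarray(t_min, dtype=float)
        if math.isinf(self.rate_per_min):
            out = np.where(t > 0, self.limit_frac, 0.0)
        else:
            out = self.limit_frac * (1.0 - np.exp(-self.rate_per_min * t))
        return out if out.ndim else float(out)


def _assoc(t, limit, rate):
    return limit * (1.0 - np.exp(-rate * t))


def fit_cumulative_excretion(
    series: list[UrineSeries] | UrineSeries, pooled: bool = True
) -> ExcretionFit | list[ExcretionFit]:
    """Least-squares one-phase association fit of cumulative urine data.

    By default all patients' points are pooled into one cloud and a single
    (F, k) is fitted, matching a cohort-level excretion model; ``pooled=False``
    returns one fit per patient for diagnostics.

    Initialization: F₀ = max observed cumulative fraction, k₀ = ln2/60 /min;
    bounds F ∈ [0, 1], k ∈ (0, 1].  An all-zero series is degenerate and
    returns F = 0 with a warning rather than failing.
    """
    if isinstance(series, UrineSeries):
        series = [series]
    if not series:
        raise ValueError("no urine series supplied")
    if not pooled:
        return [fit_cumulative_excretion([s], pooled=True) for s in series]

    t = np.concatenate([s.void_times_min for s in series])
    u = np.concatenate([s.cum_activity_frac for s in series])
    if np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct void times to fit (F, k)")
    if np.all(u == 0):
        log.warning("all urine activity is zero; degenerate excretion fit F=0")
        return ExcretionFit(
            limit_frac=0.0,
            rate_per_min=LN2 / 60.0,
            rss=0.0,
            n_points=int(t.size),
            degenerate=True,
        )

    p0 = (min(float(u.max()), 1.0), LN2 / 60.0)
    try:
        popt, _ = curve_fit(
            _assoc, t, u, p0=p0, bounds=([0.0, 1e-8], [1.0, 1.0]), maxfev=10000
        )
    except RuntimeError as err:  # pragma: no cover - pathological inputs
        raise RuntimeError(
            f"excretion fit did not converge from start values {p0}: {err}"
        ) from err
    resid = u - _assoc(t, *popt)
    return ExcretionFit(
        limit_frac=float(popt[0]),
        rate_per_min=float(popt[1]),
        rss=float(resid @ resid),
        n_points=int(t.size),
    )


def bladder_tiac(
    fit: ExcretionFit,
    nuclide: Nuclide = GA68,
    voiding_interval_min: float = 60.0,
    rel_tol: float = 1e-4,
) -> float:
    """Urinary-bladder-contents TIAC (hours) under periodic complete voiding.

    The bladder is emptied instantaneously every ``voiding_interval_min``
    minutes, first void at t = T_v.  Cycles are integrated numerically and
    accumulated until an additional cycle changes the total by less than
    ``rel_tol`` (default 0.01 %).
    """
    if not voiding_interval_min > 0:
        raise ValueError("voiding_interval_min must be > 0")
    if fit.limit_frac == 0.0:
        return 0.0
    lam = nuclide.decay_constant_per_min

    def contents(t, t_void):
        return math.exp(-lam * t) * float(fit.cumulative(t) - fit.cumulative(t_void))

    total_min = 0.0
    for cycle in range(100_000):
        t0 = cycle * voiding_interval_min
        seg, _ = quad(contents, t0, t0 + voiding_interval_min, args=(t0,), limit=200)
        total_min += seg
        # remaining activity still to be excreted, decayed to cycle end,
        # bounds every future cycle's contribution
        t_end = t0 + voiding_interval_min
        bound = (
            (fit.limit_frac - float(fit.cumulative(t_end)))
            * math.exp(-lam * t_end)
            * voiding_interval_min
        )
        if total_min > 0 and bound < rel_tol * total_min:
            break
        if seg == 0.0 and cycle > 0:
            break
    return total_min / 60.0


def excreted_decays_h(fit: ExcretionFit, nuclide: Nuclide = GA68) -> float:
    """Total decays (hours per unit injected) of all material ever excreted.

    A parcel excreted at time s (decay-corrected rate U′(s)) decays
    e^(−λs)/λ times after excretion, so the total is

        ∫₀^∞ U′(s) e^(−λs) / λ ds = F·k / (λ·(k + λ))

    for the one-phase association.  Splitting off the bladder-contents TIAC
    leaves the decays occurring in voided urine outside the body.
    """
    lam = nuclide.decay_constant_per_min
    if lam == 0.0:
        return math.inf if fit.limit_frac > 0 else 0.0
    k = fit.rate_per_min
    if math.isinf(k):
        return fit.limit_frac / lam / 60.0
    return fit.limit_frac * k / (lam * (k + lam)) / 60.0
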