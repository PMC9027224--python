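"""Radioactive decay arithmetic, SUV computation and time–activity curves.

Everything downstream (TIAC integration, the bladder voiding model, the dose
engine) works in a single time base: minutes post-injection, with injection at
t = 0.  Activity concentrations are kBq/mL; tissue density is taken as 1 g/mL
so SUV is dimensionally g/mL.

The radionuclide is a parameter everywhere decay enters, defaulting to Ga-68
(half-life 68 min).  A half-life of ``math.inf`` is permitted and yields a
decay constant of zero — useful for limiting-case checks of the integrators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Nuclide",
    "GA68",
    "STABLE",
    "PatientMeta",
    "TimeActivityCurve",
    "decay_factor",
    "decay_correct",
    "decay_uncorrect",
    "suv",
    "build_tac",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class Nuclide:
    """A radionuclide identified by name and physical half-life in minutes."""

    name: str
    half_life_min: float

    def __post_init__(self) -> None:
        if not self.half_life_min > 0:
            raise ValueError(f"half_life_min must be > 0, got {self.half_life_min}")

    @property
    def decay_constant_per_min(self) -> float:
        """Physical decay constant λ = ln2 / T½ in 1/min (0 for T½ = ∞)."""
        if math.isinf(self.half_life_min):
            return 0.0
        return LN2 / self.half_life_min


#: Gallium-68, the positron emitter used throughout.
GA68 = Nuclide("Ga-68", 68.0)

#: Non-decaying test nuclide (λ = 0) for limiting-case checks.
STABLE = Nuclide("stable", math.inf)


@dataclass(frozen=True)
class PatientMeta:
    """Per-patient administration metadata.

    ``injection_time_min`` is the reference origin of the study time base and
    is 0 by construction for all shipped workflows; it is carried so that data
    recorded on a clock time base can be re-referenced on load.
    """

    patient_id: str
    weight_kg: float
    injected_activity_MBq: float
    injection_time_min: float = 0.0

    def __post_init__(self) -> None:
        if not (20.0 < self.weight_kg < 300.0):
            raise ValueError(
                f"weight_kg must lie in (20, 300), got {self.weight_kg} "
                f"for patient {self.patient_id!r}"
            )
        if not self.injected_activity_MBq > 0:
            raise ValueError(
                f"injected_activity_MBq must be > 0, got {self.injected_activity_MBq}"
            )


@dataclass(frozen=True)
class TimeActivityCurve:
    """Sampled activity over time for one region.

    ``values`` holds activity concentration in kBq/mL for image-derived
    curves, or a dimensionless fraction of injected activity once converted by
    the TIAC stage; ``unit`` records which.  ``decay_corrected`` is an
    explicit flag so the integrator can refuse curves on the wrong convention.
    """

    region: str
    times_min: np.ndarray
    values: np.ndarray
    decay_corrected: bool
    unit: str = "kBq_per_mL"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times_min and values must be 1-D and equal length")
        if t.size < 1:
            raise ValueError("a time-activity curve needs at least one sample")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"times must be strictly increasing, got {t}")
        if np.any(t < 0):
            raise ValueError("negative sample times are not allowed")
        if np.any(v < 0):
            raise ValueError(f"negative activity values in region {self.region!r}")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "values", v)

    @property
    def conc_kBq_per_mL(self) -> np.ndarray:
        return self.values

    def __len__(self) -> int:
        return int(self.times_min.size)


def decay_factor(nuclide: Nuclide, dt_min: float) -> float:
    """Fraction of activity remaining after ``dt_min`` minutes: exp(−λ·dt).

    Multiplicative in dt (f(a+b) = f(a)·f(b)); 1.0 at dt = 0.  Negative dt is
    rejected rather than silently back-extrapolated.
    """
    if dt_min < 0:
        raise ValueError(f"dt_min must be >= 0, got {dt_min}")
    return math.exp(-nuclide.decay_constant_per_min * dt_min)


def decay_correct(conc, t_min: float, nuclide: Nuclide = GA68):
    """Rescale a measured value at ``t_min`` to its value at injection time."""
    return conc / decay_factor(nuclide, t_min)


def decay_uncorrect(conc, t_min: float, nuclide: Nuclide = GA68):
    """Inverse of :func:`decay_correct`: apply physical decay over ``t_min``."""
    return conc * decay_factor(nuclide, t_min)


def suv(conc_decaycorr: float, patient: PatientMeta) -> float:
    """Standardized uptake value from a decay-corrected concentration.

    SUV = C[kBq/mL] · W[kg] / A₀[MBq].  The kBq/MBq factor of 10⁻³ cancels the
    kg/g factor of 10³ at unit tissue density, so the result is g/mL.
    """
    if conc_decaycorr < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_decaycorr}")
    return conc_decaycorr * patient.weight_kg / patient.injected_activity_MBq


def build_tac(
    region: str,
    samples: list[tuple[float, float]],
    decay_corrected: bool,
    unit: str = "kBq_per_mL",
) -> TimeActivityCurve:
    """Build a validated, time-sorted curve from (time_min, value) pairs.

    Duplicate sample times are rejected — two acquisitions cannot share a
    nominal time in this dialect, and averaging them silently would hide an
    upstream bookkeeping error.
    """
    if not samples:
        raise ValueError("sample list is empty")
    ordered = sorted(samples, key=lambda s: s[0])
    times = [s[0] for s in ordered]
    if len(set(times)) != len(times):
        dupes = sorted({t for t in times if times.count(t) > 1})
        raise ValueError(f"duplicate sample times {dupes} in region {region!r}")
    return TimeActivityCurve(
        region=region,
        times_min=np.array(times, dtype=float),
        values=np.array([s[1] for s in ordered], dtype=float),
        decay_corrected=decay_corrected,
        unit=unit,
    )
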