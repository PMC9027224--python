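"""Organ time-integrated activity coefficients from sparse serial PET.

The pipeline here mirrors standard image-based internal dosimetry practice:
VOI concentrations (kBq/mL, decay-uncorrected) are converted to fractions of
the injected activity using reference-phantom organ masses scaled by the
patient/phantom total-mass ratio, and each organ's fraction-of-injected curve
is integrated over [0, ∞) to a time-integrated activity coefficient (TIAC,
hours) — the expected number of decays in the region per unit administered
activity.

Integration scheme for a curve sampled at t₁ < … < tₙ:

* leading segment [0, t₁]: linear rise from 0 at injection to the first
  measured value (conservative standard when first imaging is ~10 min p.i.);
* [t₁, tₙ]: trapezoidal rule on the samples;
* tail [tₙ, ∞): analytic, A(tₙ)/λ, i.e. physical decay only — no biologic
  clearance is extrapolated beyond the last measurement.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kinetics import GA68, Nuclide, PatientMeta, TimeActivityCurve

__all__ = [
    "Phantom",
    "TIACSet",
    "total_decays_h",
    "organ_activity_fraction",
    "activity_fraction_curve",
    "tiac",
    "average_tiacs",
    "remainder_tiac",
]

log = logging.getLogger(__name__)

REMAINDER = "remainder"
BLADDER_CONTENTS = "urinary_bladder_contents"


@dataclass(frozen=True)
class Phantom:
    """Reference anthropomorphic phantom: total mass and organ masses in grams."""

    name: str
    sex: str
    total_mass_kg: float
    organ_masses_g: dict[str, float]

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.total_mass_kg > 0:
            raise ValueError("total_mass_kg must be > 0")
        for region, m in self.organ_masses_g.items():
            if not m > 0:
                raise ValueError(f"organ mass for {region!r} must be > 0, got {m}")
        if sum(self.organ_masses_g.values()) >= self.total_mass_kg * 1000.0:
            raise ValueError("sum of organ masses must be below the total body mass")

    @classmethod
    def from_json(cls, path: str | Path) -> "Phantom":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls(
            name=raw["name"],
            sex=raw["sex"],
            total_mass_kg=float(raw["total_mass_kg"]),
            organ_masses_g={k: float(v) for k, v in raw["organ_masses_g"].items()},
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "sex": self.sex,
            "total_mass_kg": self.total_mass_kg,
            "organ_masses_g": dict(sorted(self.organ_masses_g.items())),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


@dataclass(frozen=True)
class TIACSet:
    """Per-patient (or cohort-average) TIACs in hours, keyed by source region.

    May include the synthetic bookkeeping regions ``remainder`` and
    ``urinary_bladder_contents``.  ``n_patients`` records, for cohort
    averages, how many patients contributed to each region.
    """

    patient_id: str
    tiac_h: dict[str, float]
    n_patients: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for region, v in self.tiac_h.items():
            if v < 0:
                raise ValueError(f"TIAC for {region!r} must be >= 0, got {v}")

    def total_h(self) -> float:
        return float(sum(self.tiac_h.values()))


def total_decays_h(nuclide: Nuclide = GA68) -> float:
    """Total decays per unit injected activity, in hours: 1/λ = T½/(60·ln2).

    For Ga-68 this is 68/(60·ln2) ≈ 1.6350 h — the hard upper bound on the sum
    of all source-region TIACs.
    """
    lam = nuclide.decay_constant_per_min
    if lam == 0.0:
        return math.inf
    return 1.0 / lam / 60.0


def organ_activity_fraction(
    conc_uncorr_kBq_per_mL: float,
    region: str,
    phantom: Phantom,
    patient: PatientMeta,
) -> float:
    """Fraction of injected activity in an organ at one time point.

    The organ volume is the phantom organ mass (1 g = 1 mL) scaled by the
    patient/phantom total-mass ratio:

        fraction = C[kBq/mL] · m_organ[g] · (W_patient / W_phantom) / (A₀[MBq] · 1000)
    """
    if region not in phantom.organ_masses_g:
        raise KeyError(f"region {region!r} not present in phantom {phantom.name!r}")
    if conc_uncorr_kBq_per_mL < 0:
        raise ValueError("concentration must be >= 0")
    volume_mL = phantom.organ_masses_g[region] * (
        patient.weight_kg / phantom.total_mass_kg
    )
    return conc_uncorr_kBq_per_mL * volume_mL / (patient.injected_activity_MBq * 1000.0)


def activity_fraction_curve(
    tac: TimeActivityCurve, phantom: Phantom, patient: PatientMeta
) -> TimeActivityCurve:
    """Convert a decay-uncorrected concentration curve to fractions of injected."""
    if tac.decay_corrected:
        raise ValueError(
            f"curve for {tac.region!r} is decay-corrected; the fraction curve "
            "feeding the TIAC integral must carry physical decay"
        )
    fracs = [
        organ_activity_fraction(c, tac.region, phantom, patient) for c in tac.values
    ]
    return TimeActivityCurve(
        region=tac.region,
        times_min=tac.times_min.copy(),
        values=np.array(fracs),
        decay_corrected=False,
        unit="fraction_of_injected",
    )


def tiac(curve: TimeActivityCurve, nuclide: Nuclide = GA68) -> float:
    """TIAC in hours for a decay-uncorrected fraction-of-injected curve.

    Trapezoid over the samples, a linear-from-zero leading segment on
    [0, t₁], and an analytic tail A(tₙ)/λ assuming only physical decay.
    """
    if curve.decay_corrected:
        raise ValueError(
            f"curve for {curve.region!r} is flagged decay-corrected; "
            "tiac() integrates physical (decay-uncorrected) activity"
        )
    lam = nuclide.decay_constant_per_min
    if lam == 0.0:
        raise ValueError("tail extrapolation is undefined for a stable nuclide")
    t = curve.times_min
    a = curve.values
    area_min = 0.5 * t[0] * a[0]  # linear rise from (0, 0)
    if len(curve) > 1:
        area_min += float(np.trapezoid(a, t))
    area_min += a[-1] / lam  # physical-decay tail
    return area_min / 60.0


def average_tiacs(per_patient: list[TIACSet]) -> TIACSet:
    """Arithmetic mean TIAC per region over the patients reporting that region.

    The union of regions is taken; a region missing in a patient is treated as
    absent (not zero), the per-region n is recorded, and a warning is logged
    when coverage is partial.
    """
    if not per_patient:
        raise ValueError("cannot average an empty list of TIAC sets")
    regions = sorted({r for ts in per_patient for r in ts.tiac_h})
    mean: dict[str, float] = {}
    counts: dict[str, int] = {}
    for region in regions:
        vals = [ts.tiac_h[region] for ts in per_patient if region in ts.tiac_h]
        mean[region] = float(np.mean(vals))
        counts[region] = len(vals)
        if len(vals) < len(per_patient):
            log.warning(
                "region %r present in %d/%d patients; averaged over those only",
                region,
                len(vals),
                len(per_patient),
            )
    return TIACSet(patient_id="cohort_mean", tiac_h=mean, n_patients=counts)


def remainder_tiac(
    organ_tiacs: dict[str, float],
    bladder_tiac_h: float,
    voided_urine_decays_h: float,
    nuclide: Nuclide = GA68,
) -> float:
    """Remainder-of-body TIAC by whole-body balance, floored at zero.

    Every decay happens somewhere: 1/λ hours split between explicit organs,
    bladder contents, voided urine (outside the body) and the remainder.
    ``voided_urine_decays_h`` is the decays occurring in urine after voiding
    (see :func:`mirdkit.bladder.excreted_decays_h`).
    """
    whole_body = total_decays_h(nuclide) - voided_urine_decays_h
    rem = whole_body - sum(organ_tiacs.values()) - bladder_tiac_h
    if rem < 0:
        log.warning(
            "remainder TIAC balance came out negative (%.4g h); flooring at 0", rem
        )
    return max(rem, 0.0)
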