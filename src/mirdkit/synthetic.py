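"""Synthetic study cohort with analytically known ground truth.

The generator emulates the structure of a first-in-human Ga-68 tracer study:
two disease groups (neuroendocrine neoplasm, breast cancer) of 5 patients,
three whole-body PET time points at ~10 min / 1 h / 2 h post-injection,
renal-dominant excretion with a declining blood pool and near-zero
brain/lung/bone/muscle uptake, cumulative urine rising to a plateau, and
mono-exponential plasma clearance with per-patient half-lives on 3.9–14 min.

Every organ's decay-uncorrected fraction-of-injected activity follows the
uptake–washout model

    A_r(t) = f_r · k_u/(k_u − k_w) · (e^(−k_w t) − e^(−k_u t)) · e^(−λt),

whose integral over [0, ∞) is available in closed form, so pipeline TIACs
can be checked against analytic truth.  The blood pool is a declining
mono-exponential.  A single pseudo-random stream keyed by the seed drives
all draws in a fixed (patient, region, time) order, so identical
(config, seed) pairs yield byte-identical datasets.

This module also builds the synthetic S-value matrix shipped with the
package: a physically motivated toy (local β⁺ self-absorption, a uniform
annihilation-photon bath, and a bladder contents→wall surface term), not a
reproduction of any proprietary phantom S-matrix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .dose import SMatrix
from .kinetics import GA68, Nuclide, PatientMeta
from .tiac import Phantom, REMAINDER, BLADDER_CONTENTS

__all__ = [
    "OrganKinetics",
    "CohortConfig",
    "GroundTruth",
    "CohortData",
    "gen_cohort",
    "gen_urine",
    "gen_plasma",
    "organ_fraction",
    "analytic_organ_tiac_h",
    "load_default_phantom",
    "make_synthetic_smatrix",
]


# ---------------------------------------------------------------------------
# packaged static data


def load_default_phantom(sex: str = "male") -> Phantom:
    """The packaged synthetic reference phantom for the given sex."""
    fname = f"phantom_adult_{sex}_synthetic.json"
    with resources.as_file(resources.files("mirdkit.data").joinpath(fname)) as p:
        return Phantom.from_json(p)


# toy dose physics for the synthetic S-matrix (Ga-68): mean β⁺ energy ×
# positron yield deposited locally; annihilation photons treated as a uniform
# whole-body bath with a bulk absorbed fraction.
_E_BETA_MEV = 0.836 * 0.89
_E_PHOTON_MEV = 1.022 * 0.89
_PHI_BATH = 0.33
_MU_511_PER_CM = 0.096
_MGY_KG_PER_MEV_MBQ_H = 1.602e-13 * 3.6e9 * 1000.0

#: source regions the synthetic S-matrix declares (generator organs, blood
#: pool, bladder contents, remainder)
SMATRIX_SOURCES = (
    "brain",
    "heart_contents",
    "kidneys",
    "liver",
    "lungs",
    "muscle",
    "red_marrow",
    "small_intestine",
    "spleen",
    REMAINDER,
    BLADDER_CONTENTS,
)


def _phi_self(mass_g: float) -> float:
    radius_cm = (3.0 * mass_g / 1.05 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return 1.0 - math.exp(-_MU_511_PER_CM * radius_cm)


def make_synthetic_smatrix(phantom: Phantom) -> SMatrix:
    """Toy S-matrix for a phantom: complete over targets × declared sources.

    S(t←s) = photon bath + [t = s] local β⁺ + bladder contents→wall surface
    term.  Self-dose dominates cross-dose to the same target by construction.
    """
    remainder_g = phantom.total_mass_kg * 1000.0 - sum(
        phantom.organ_masses_g.values()
    )
    masses = dict(phantom.organ_masses_g)
    masses[REMAINDER] = remainder_g
    bath = (
        _E_PHOTON_MEV * _PHI_BATH * _MGY_KG_PER_MEV_MBQ_H / (phantom.total_mass_kg)
    )
    entries: dict[tuple[str, str], float] = {}
    for target, m_t in masses.items():
        m_t_kg = m_t / 1000.0
        for source in SMATRIX_SOURCES:
            s = bath
            if target == source:
                s += (
                    _E_BETA_MEV + _E_PHOTON_MEV * _phi_self(m_t)
                ) * _MGY_KG_PER_MEV_MBQ_H / m_t_kg
            if target == "urinary_bladder_wall" and source == BLADDER_CONTENTS:
                s += (
                    0.5
                    * _E_BETA_MEV
                    * _MGY_KG_PER_MEV_MBQ_H
                    / (masses[BLADDER_CONTENTS] / 1000.0)
                )
            entries[(target, source)] = s
    return SMatrix(phantom_name=phantom.name, entries=entries)


# ---------------------------------------------------------------------------
# cohort configuration


@dataclass(frozen=True)
class OrganKinetics:
    """Uptake–washout parameters: peak-fraction scale f, rates in 1/min."""

    f: float
    k_u: float
    k_w: float

    def __post_init__(self) -> None:
        if not (self.f >= 0 and self.k_u > 0 and self.k_w > 0):
            raise ValueError("f must be >= 0 and both rates > 0")
        if self.k_u == self.k_w:
            raise ValueError("k_u must differ from k_w (removable singularity)")


#: Default organ kinetics: renal-dominant clearance with kidney retention,
#: moderate liver/spleen/intestine uptake, fast-clearing lung, near-zero
#: brain uptake and low muscle concentration (the muscle *fraction* is
#: sizeable only because its mass is ~29 kg; its SUV stays well below 1).
DEFAULT_ORGAN_KINETICS: dict[str, OrganKinetics] = {
    "brain": OrganKinetics(0.002, 0.05, 0.010),
    "kidneys": OrganKinetics(0.050, 0.15, 0.005),
    "liver": OrganKinetics(0.080, 0.08, 0.004),
    "lungs": OrganKinetics(0.008, 0.20, 0.020),
    "muscle": OrganKinetics(0.200, 0.30, 0.005),
    "red_marrow": OrganKinetics(0.015, 0.08, 0.005),
    "small_intestine": OrganKinetics(0.025, 0.05, 0.003),
    "spleen": OrganKinetics(0.005, 0.10, 0.004),
}

#: the blood pool is measured in a heart-contents VOI; its fraction below is
#: the share of injected activity inside that VOI (~10 % of blood volume),
#: not the whole circulating pool
BLOOD_REGION = "heart_contents"


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the emulated study's conditions: 5 patients per group (10
    total) with urine and plasma sampling in a 7-patient subset, whole-body
    imaging at 10/60/120 min p.i., excretion plateau F = 0.45 at rate
    k = 0.02 /min carried ≥ 80 % by the renal route, a heart-contents blood
    pool fraction of 0.02 clearing at 0.012 /min, plasma half-lives uniform on
    [3.9, 14.0] min, and 5 % multiplicative log-normal measurement noise.
    """

    n_per_group: int = 5
    n_pk_subset: int = 7
    scan_times_min: tuple[float, ...] = (10.0, 60.0, 120.0)
    void_times_min: tuple[float, ...] = (15.0, 70.0, 130.0, 180.0)
    plasma_times_min: tuple[float, ...] = (2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0)
    organ_kinetics: dict[str, OrganKinetics] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_KINETICS)
    )
    blood_fraction: float = 0.02
    blood_rate_per_min: float = 0.012
    excretion_limit_frac: float = 0.45
    excretion_rate_per_min: float = 0.02
    renal_fraction: float = 0.90
    plasma_half_life_range_min: tuple[float, float] = (3.9, 14.0)
    lesion_suvmax_lognorm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "NEN": (math.log(6.8), 0.30),
            "BC": (math.log(4.8), 0.30),
        }
    )
    lesion_time_multipliers: tuple[float, float, float] = (1.0, 1.30, 1.35)
    noise_cv: float = 0.05
    organ_jitter_cv: float = 0.08
    weight_mean_kg: float = 75.0
    weight_sd_kg: float = 12.0
    activity_mean_MBq: float = 184.4
    activity_sd_MBq: float = 38.4
    activity_range_MBq: tuple[float, float] = (97.3, 220.0)
    nuclide: Nuclide = GA68

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.noise_cv < 0 or self.organ_jitter_cv < 0:
            raise ValueError("noise CVs must be >= 0")
        if not (0.0 <= self.excretion_limit_frac <= 1.0):
            raise ValueError("excretion_limit_frac must lie in [0, 1]")
        budget = (
            sum(k.f for k in self.organ_kinetics.values())
            + self.blood_fraction
            + self.excretion_limit_frac
        )
        if budget > 1.0:
            raise ValueError(
                f"infeasible mass balance: organ fractions + blood + excreted "
                f"= {budget:.3f} > 1"
            )


# ---------------------------------------------------------------------------
# generating model and its analytic integrals


def organ_fraction(
    t_min, kin: OrganKinetics, nuclide: Nuclide = GA68
) -> np.ndarray:
    """Decay-uncorrected fraction-of-injected activity of the organ model."""
    t = np.asarray(t_min, dtype=float)
    lam = nuclide.decay_constant_per_min
    shape = kin.k_u / (kin.k_u - kin.k_w)
    return (
        kin.f
        * shape
        * (np.exp(-kin.k_w * t) - np.exp(-kin.k_u * t))
        * np.exp(-lam * t)
    )


def analytic_organ_tiac_h(kin: OrganKinetics, nuclide: Nuclide = GA68) -> float:
    """Closed-form TIAC (hours) of the uptake–washout organ model."""
    lam = nuclide.decay_constant_per_min
    shape = kin.k_u / (kin.k_u - kin.k_w)
    integral_min = kin.f * shape * (
        1.0 / (kin.k_w + lam) - 1.0 / (kin.k_u + lam)
    )
    return integral_min / 60.0


def blood_fraction_curve(t_min, config: CohortConfig) -> np.ndarray:
    t = np.asarray(t_min, dtype=float)
    lam = config.nuclide.decay_constant_per_min
    return config.blood_fraction * np.exp(-(config.blood_rate_per_min + lam) * t)


def analytic_blood_tiac_h(config: CohortConfig, f_b: float | None = None) -> float:
    lam = config.nuclide.decay_constant_per_min
    f = config.blood_fraction if f_b is None else f_b
    return f / (config.blood_rate_per_min + lam) / 60.0


# ---------------------------------------------------------------------------
# ground truth and generated data containers


@dataclass(frozen=True)
class GroundTruth:
    """Per-patient generating parameters and their analytic consequences."""

    organ_kinetics: dict[str, dict[str, OrganKinetics]]
    blood_fraction: dict[str, float]
    tiac_h: dict[str, dict[str, float]]
    plasma_half_life_min: dict[str, float]
    excretion_limit_frac: float
    excretion_rate_per_min: float
    renal_fraction: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "organ_kinetics": {
                pid: {r: asdict(k) for r, k in sorted(regs.items())}
                for pid, regs in sorted(self.organ_kinetics.items())
            },
            "blood_fraction": dict(sorted(self.blood_fraction.items())),
            "tiac_h": {
                pid: dict(sorted(t.items())) for pid, t in sorted(self.tiac_h.items())
            },
            "plasma_half_life_min": dict(sorted(self.plasma_half_life_min.items())),
            "excretion_limit_frac": self.excretion_limit_frac,
            "excretion_rate_per_min": self.excretion_rate_per_min,
            "renal_fraction": self.renal_fraction,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class CohortData:
    """Generated study tables in the pipeline's CSV dialects."""

    patients: pd.DataFrame
    tacs: pd.DataFrame
    urine: pd.DataFrame
    plasma: pd.DataFrame
    lesions: pd.DataFrame
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> None:
        """Write all tables with fixed ordering/formatting (byte-stable)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "patients.csv": self.patients,
            "tacs.csv": self.tacs,
            "urine.csv": self.urine,
            "plasma.csv": self.plasma,
            "lesions.csv": self.lesions,
        }
        for fname, df in tables.items():
            df.to_csv(out / fname, index=False, float_format="%.6g")
        self.truth.to_json(out / "ground_truth.json")

    def patient_meta(self) -> dict[str, PatientMeta]:
        return {
            row.patient_id: PatientMeta(
                patient_id=row.patient_id,
                weight_kg=row.weight_kg,
                injected_activity_MBq=row.injected_activity_MBq,
            )
            for row in self.patients.itertuples()
        }


# ---------------------------------------------------------------------------
# generators


def _jittered_kinetics(
    config: CohortConfig, rng: np.random.Generator
) -> dict[str, OrganKinetics]:
    """Per-patient organ kinetics with log-normal jitter on the fractions.

    If the jitter pushes the patient over the mass-balance budget the organ
    fractions are rescaled proportionally to restore feasibility.
    """
    kins = {}
    for region in sorted(config.organ_kinetics):
        base = config.organ_kinetics[region]
        mult = float(np.exp(rng.normal(0.0, config.organ_jitter_cv)))
        kins[region] = OrganKinetics(base.f * mult, base.k_u, base.k_w)
    budget = 1.0 - config.excretion_limit_frac - config.blood_fraction
    total = sum(k.f for k in kins.values())
    if total > budget:
        scale = budget / total
        kins = {r: OrganKinetics(k.f * scale, k.k_u, k.k_w) for r, k in kins.items()}
    return kins


def _lognoise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0.0:
        return np.ones(size)
    return np.exp(rng.normal(0.0, cv, size=size))


def gen_urine(
    config: CohortConfig, rng: np.random.Generator, patient_id: str
) -> pd.DataFrame:
    """Cumulative decay-corrected urine fractions at the void schedule."""
    t = np.asarray(config.void_times_min)
    u = config.excretion_limit_frac * (
        1.0 - np.exp(-config.excretion_rate_per_min * t)
    )
    u = u * _lognoise(rng, config.noise_cv, t.size)
    u = np.minimum(np.maximum.accumulate(u), 1.0)  # keep cumulative and physical
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "void_time_min": t,
            "cum_activity_frac": u,
        }
    )


def gen_plasma(
    config: CohortConfig,
    rng: np.random.Generator,
    patient_id: str,
    half_life_min: float,
) -> pd.DataFrame:
    """Decay-corrected relative plasma concentrations, C(0) = 100."""
    t = np.asarray(config.plasma_times_min)
    c = 100.0 * np.exp(-math.log(2.0) / half_life_min * t)
    c = c * _lognoise(rng, config.noise_cv, t.size)
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "time_min": t,
            "rel_conc": c,
            "decay_corrected": True,
        }
    )


def gen_cohort(
    config: CohortConfig = CohortConfig(), seed: int = 0
) -> CohortData:
    """Generate a complete synthetic study dataset with ground truth.

    Identical (config, seed) pairs produce identical tables; all random
    draws come from one stream in a fixed (patient, region, time) order.
    """
    rng = np.random.default_rng(seed)
    phantom = load_default_phantom("male")
    lam_tuple = config.plasma_half_life_range_min

    groups = ["NEN"] * config.n_per_group + ["BC"] * config.n_per_group
    patient_ids = [f"P{i + 1:02d}" for i in range(len(groups))]

    pat_rows, tac_rows, urine_frames, plasma_frames, lesion_rows = [], [], [], [], []
    truth_kin: dict[str, dict[str, OrganKinetics]] = {}
    truth_blood: dict[str, float] = {}
    truth_tiac: dict[str, dict[str, float]] = {}
    truth_thalf: dict[str, float] = {}

    for idx, (pid, group) in enumerate(zip(patient_ids, groups)):
        weight = float(
            np.clip(
                rng.normal(config.weight_mean_kg, config.weight_sd_kg), 50.0, 110.0
            )
        )
        activity = float(
            np.clip(
                rng.normal(config.activity_mean_MBq, config.activity_sd_MBq),
                *config.activity_range_MBq,
            )
        )
        pat_rows.append(
            {
                "patient_id": pid,
                "group": group,
                "weight_kg": weight,
                "injected_activity_MBq": activity,
            }
        )
        patient = PatientMeta(pid, weight, activity)

        kins = _jittered_kinetics(config, rng)
        truth_kin[pid] = kins
        truth_blood[pid] = config.blood_fraction
        tiacs = {
            region: analytic_organ_tiac_h(k, config.nuclide)
            for region, k in kins.items()
        }
        tiacs[BLOOD_REGION] = analytic_blood_tiac_h(config)
        truth_tiac[pid] = tiacs

        t_scan = np.asarray(config.scan_times_min)
        for region in sorted(kins):
            frac = organ_fraction(t_scan, kins[region], config.nuclide)
            conc = _frac_to_conc(frac, region, phantom, patient)
            conc = conc * _lognoise(rng, config.noise_cv, t_scan.size)
            tac_rows.extend(_tac_records(pid, region, t_scan, conc))
        blood = blood_fraction_curve(t_scan, config)
        conc = _frac_to_conc(blood, BLOOD_REGION, phantom, patient)
        conc = conc * _lognoise(rng, config.noise_cv, t_scan.size)
        tac_rows.extend(_tac_records(pid, BLOOD_REGION, t_scan, conc))

        in_pk_subset = idx < config.n_pk_subset
        if in_pk_subset:
            urine_frames.append(gen_urine(config, rng, pid))
            thalf = float(rng.uniform(*lam_tuple))
            truth_thalf[pid] = thalf
            plasma_frames.append(gen_plasma(config, rng, pid, thalf))

        mu, sigma = config.lesion_suvmax_lognorm[group]
        level = float(rng.lognormal(mu, sigma))
        size_cm = float(
            rng.lognormal(math.log(5.0), 0.35)
            if group == "NEN"
            else rng.lognormal(math.log(1.5), 0.35)
        )
        for tp, mult in zip(("PET_10", "PET_1h", "PET_2h"), config.lesion_time_multipliers):
            suv_max = level * mult * float(np.exp(rng.normal(0.0, 0.08)))
            suv_mean = suv_max * float(rng.uniform(0.45, 0.65))
            lesion_rows.append(
                {
                    "patient_id": pid,
                    "group": group,
                    "timepoint": tp,
                    "suv_max": suv_max,
                    "suv_mean": suv_mean,
                    "tumor_size_cm": size_cm,
                    "uptake_pattern": "heterogeneous"
                    if group == "NEN"
                    else "homogeneous",
                    "metastasis_site": False,
                }
            )

    truth = GroundTruth(
        organ_kinetics=truth_kin,
        blood_fraction=truth_blood,
        tiac_h=truth_tiac,
        plasma_half_life_min=truth_thalf,
        excretion_limit_frac=config.excretion_limit_frac,
        excretion_rate_per_min=config.excretion_rate_per_min,
        renal_fraction=config.renal_fraction,
    )
    return CohortData(
        patients=pd.DataFrame(pat_rows),
        tacs=pd.DataFrame(tac_rows),
        urine=pd.concat(urine_frames, ignore_index=True)
        if urine_frames
        else pd.DataFrame(
            columns=["patient_id", "void_time_min", "cum_activity_frac"]
        ),
        plasma=pd.concat(plasma_frames, ignore_index=True)
        if plasma_frames
        else pd.DataFrame(
            columns=["patient_id", "time_min", "rel_conc", "decay_corrected"]
        ),
        lesions=pd.DataFrame(lesion_rows),
        truth=truth,
    )


def _frac_to_conc(
    frac: np.ndarray, region: str, phantom: Phantom, patient: PatientMeta
) -> np.ndarray:
    """Invert the fraction↔concentration mapping used by the TIAC stage."""
    volume_mL = phantom.organ_masses_g[region] * (
        patient.weight_kg / phantom.total_mass_kg
    )
    return frac * patient.injected_activity_MBq * 1000.0 / volume_mL


def _tac_records(pid, region, times, conc):
    return [
        {
            "patient_id": pid,
            "region": region,
            "time_min": float(t),
            "conc_kBq_per_mL": float(c),
            "decay_corrected": False,
        }
        for t, c in zip(times, conc)
    ]
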