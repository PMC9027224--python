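"""End-to-end study analysis: TACs → TIACs → doses → effective dose, plus
plasma PK and lesion uptake statistics.

This is the chain the ``report`` CLI subcommand and the analysis drivers run:

1. organ concentration curves → fraction-of-injected curves (phantom masses,
   patient-weight scaling) → per-patient TIACs → cohort-average TIACs;
2. pooled urine → one-phase association fit → voiding-bladder TIAC and the
   whole-body remainder by decay balance;
3. cohort TIACs × S-matrix per sex → absorbed dose coefficients → ICRP-103
   effective dose → total dose at the administered activity;
4. per-patient mono-exponential plasma fits → cohort mean half-life;
5. lesion SUV group statistics and tumor-to-organ ratios.

All outputs are plain CSV/JSON written deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as mio
from .bladder import (
    ExcretionFit,
    bladder_tiac,
    excreted_decays_h,
    fit_cumulative_excretion,
)
from .dose import (
    ICRP103_WEIGHTS,
    SMatrix,
    absorbed_doses,
    effective_dose,
    scale_to_administration,
)
from .kinetics import GA68, Nuclide, PatientMeta, TimeActivityCurve, decay_correct, suv
from .lesions import (
    RATIO_ORGANS,
    TIMEPOINTS,
    group_ratio_summary,
    summarize_suv,
    tumor_to_organ,
)
from .pk import cohort_half_life, fit_monoexp
from .synthetic import load_default_phantom, make_synthetic_smatrix
from .tiac import (
    BLADDER_CONTENTS,
    REMAINDER,
    Phantom,
    TIACSet,
    activity_fraction_curve,
    average_tiacs,
    remainder_tiac,
    tiac,
)

__all__ = ["StudyReport", "run_study", "patient_tiacs", "organ_suv_table"]

#: organ SUVmean backgrounds used for tumor-to-organ ratios, mapped to the
#: TAC regions that measure them
RATIO_REGION_MAP = {
    "blood": "heart_contents",
    "liver": "liver",
    "kidney": "kidneys",
    "muscle": "muscle",
}

#: nominal acquisition time (min p.i.) for each reporting time point
TIMEPOINT_MINUTES = {"PET_10": 10.0, "PET_1h": 60.0, "PET_2h": 120.0}


@dataclass
class StudyReport:
    """All cohort-level results of one end-to-end run."""

    per_patient_tiacs: list[TIACSet]
    cohort_tiacs: TIACSet
    excretion_fit: ExcretionFit | None
    bladder_tiac_h: float
    doses_by_sex: dict[str, dict[str, float]]
    effective_mSv_per_MBq: float
    administration_MBq: float
    total_mSv: float
    plasma_half_life_mean_min: float | None
    plasma_half_life_range_min: tuple[float, float] | None
    pk_fits: pd.DataFrame
    suv_stats: pd.DataFrame
    ratio_stats: pd.DataFrame
    voiding_interval_min: float = 60.0

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = [
            {"patient_id": ts.patient_id, "region": r, "tiac_h": v}
            for ts in self.per_patient_tiacs
            for r, v in sorted(ts.tiac_h.items())
        ]
        mio.write_table(pd.DataFrame(rows), out / "tiacs_per_patient.csv")
        mio.write_table(
            pd.DataFrame(
                {
                    "region": sorted(self.cohort_tiacs.tiac_h),
                    "tiac_h": [
                        self.cohort_tiacs.tiac_h[r]
                        for r in sorted(self.cohort_tiacs.tiac_h)
                    ],
                    "n_patients": [
                        self.cohort_tiacs.n_patients.get(r, 0)
                        for r in sorted(self.cohort_tiacs.tiac_h)
                    ],
                }
            ),
            out / "tiacs_cohort.csv",
        )
        for sex, doses in sorted(self.doses_by_sex.items()):
            df = pd.DataFrame(
                {
                    "organ": sorted(doses),
                    "absorbed_mGy_per_MBq": [doses[t] for t in sorted(doses)],
                }
            )
            mio.write_table(df, out / f"dose_coefficients_{sex}.csv")
        if not self.pk_fits.empty:
            mio.write_table(self.pk_fits, out / "plasma_fits.csv")
        if not self.suv_stats.empty:
            mio.write_table(self.suv_stats, out / "suv_statistics.csv")
        if not self.ratio_stats.empty:
            mio.write_table(self.ratio_stats, out / "tumor_to_organ.csv")
        summary = {
            "effective_mSv_per_MBq": round(self.effective_mSv_per_MBq, 6),
            "administration_MBq": self.administration_MBq,
            "total_mSv": round(self.total_mSv, 6),
            "bladder_tiac_h": round(self.bladder_tiac_h, 6),
            "voiding_interval_min": self.voiding_interval_min,
            "excretion_limit_frac": None
            if self.excretion_fit is None
            else round(self.excretion_fit.limit_frac, 6),
            "excretion_rate_per_min": None
            if self.excretion_fit is None
            else round(self.excretion_fit.rate_per_min, 6),
            "plasma_half_life_mean_min": None
            if self.plasma_half_life_mean_min is None
            else round(self.plasma_half_life_mean_min, 4),
            "plasma_half_life_range_min": None
            if self.plasma_half_life_range_min is None
            else [round(v, 4) for v in self.plasma_half_life_range_min],
        }
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")


def patient_tiacs(
    curves: dict[str, TimeActivityCurve],
    phantom: Phantom,
    patient: PatientMeta,
    nuclide: Nuclide = GA68,
) -> TIACSet:
    """Per-patient TIACs from decay-uncorrected concentration curves."""
    out = {}
    for region in sorted(curves):
        frac = activity_fraction_curve(curves[region], phantom, patient)
        out[region] = tiac(frac, nuclide)
    return TIACSet(patient_id=patient.patient_id, tiac_h=out)


def organ_suv_table(
    tacs: dict[str, dict[str, TimeActivityCurve]],
    patients: dict[str, PatientMeta],
    nuclide: Nuclide = GA68,
) -> pd.DataFrame:
    """Decay-corrected organ SUVmean per patient × region × time point."""
    rows = []
    for pid in sorted(tacs):
        for region in sorted(tacs[pid]):
            curve = tacs[pid][region]
            for t, c in zip(curve.times_min, curve.values):
                c_corr = c if curve.decay_corrected else decay_correct(c, t, nuclide)
                rows.append(
                    {
                        "patient_id": pid,
                        "region": region,
                        "time_min": float(t),
                        "suv_mean": suv(c_corr, patients[pid]),
                    }
                )
    return pd.DataFrame(rows)


def _ratio_table(
    lesions: pd.DataFrame, organ_suv: pd.DataFrame
) -> pd.DataFrame:
    """Group mean (SEM) tumor-to-organ ratios per organ and time point."""
    rows = []
    for organ in RATIO_ORGANS:
        region = RATIO_REGION_MAP[organ]
        for tp in TIMEPOINTS:
            t_nom = TIMEPOINT_MINUTES[tp]
            ratios_by_group: dict[str, list[float]] = {}
            for row in lesions.itertuples():
                if row.timepoint != tp:
                    continue
                pid = str(row.patient_id)
                sub = organ_suv[
                    (organ_suv.patient_id == pid) & (organ_suv.region == region)
                ]
                if sub.empty:
                    continue
                nearest = sub.iloc[(sub.time_min - t_nom).abs().argsort().iloc[0]]
                r = tumor_to_organ(row.suv_max, nearest.suv_mean)
                ratios_by_group.setdefault(row.group, []).append(r)
            all_ratios = [r for rs in ratios_by_group.values() for r in rs]
            for label, vals in [*sorted(ratios_by_group.items()), ("All", all_ratios)]:
                if not vals:
                    continue
                mean, sem = group_ratio_summary(vals)
                rows.append(
                    {
                        "organ": organ,
                        "timepoint": tp,
                        "group": label,
                        "n": len(vals),
                        "ratio_mean": mean,
                        "ratio_sem": sem,
                    }
                )
    return pd.DataFrame(rows)


def run_study(
    config: mio.RunConfig,
    phantoms: dict[str, Phantom] | None = None,
    smatrices: dict[str, SMatrix] | None = None,
    nuclide: Nuclide = GA68,
) -> StudyReport:
    """Run the full analysis chain on a dataset in the pipeline dialects.

    By default both packaged synthetic phantoms and their toy S-matrices are
    used and the effective dose is the male/female mean per ICRP 103.
    """
    if phantoms is None:
        phantoms = {s: load_default_phantom(s) for s in ("male", "female")}
    if smatrices is None:
        smatrices = {s: make_synthetic_smatrix(p) for s, p in phantoms.items()}

    patients = mio.read_patients(config.patients)
    tacs = mio.read_tacs(config.tacs)
    unknown = sorted(set(tacs) - set(patients))
    if unknown:
        raise KeyError(f"TACs reference unknown patients: {unknown}")

    # per-patient organ TIACs on the male phantom's mass set (the masses
    # define VOI volumes; the per-sex S-matrices handle dose differences)
    ref_phantom = phantoms.get("male") or next(iter(phantoms.values()))
    per_patient = [
        patient_tiacs(tacs[pid], ref_phantom, patients[pid], nuclide)
        for pid in sorted(tacs)
    ]
    cohort = average_tiacs(per_patient)

    fit = None
    bladder_h = 0.0
    voided_decays_h = 0.0
    if config.urine is not None:
        urine = mio.read_urine(config.urine, patients)
        fit = fit_cumulative_excretion(urine, pooled=True)
        bladder_h = bladder_tiac(
            fit, nuclide, voiding_interval_min=config.voiding_interval_min
        )
        voided_decays_h = max(excreted_decays_h(fit, nuclide) - bladder_h, 0.0)

    organ_tiacs = dict(cohort.tiac_h)
    rem = remainder_tiac(organ_tiacs, bladder_h, voided_decays_h, nuclide)
    source_tiacs = {**organ_tiacs, BLADDER_CONTENTS: bladder_h, REMAINDER: rem}

    doses_by_sex = {
        sex: absorbed_doses(source_tiacs, sm) for sex, sm in sorted(smatrices.items())
    }
    ed = effective_dose(doses_by_sex, ICRP103_WEIGHTS)
    total = scale_to_administration(ed, config.administration_MBq)

    pk_rows = []
    mean_thalf = thalf_range = None
    if config.plasma is not None:
        fits = [fit_monoexp(s) for s in mio.read_plasma(config.plasma)]
        pk_rows = [
            {
                "patient_id": f.patient_id,
                "half_life_min": f.half_life_min,
                "amplitude": f.amplitude,
                "rss": f.rss,
                "n": f.n,
                "decaying": f.decaying,
            }
            for f in fits
        ]
        mean_thalf, thalf_range = cohort_half_life(fits)

    suv_stats = pd.DataFrame()
    ratio_stats = pd.DataFrame()
    if config.lesions is not None:
        lesions = mio.read_lesions(config.lesions)
        suv_stats = pd.concat(
            [summarize_suv(lesions, "suv_max"), summarize_suv(lesions, "suv_mean")],
            ignore_index=True,
        )
        organ_suv = organ_suv_table(tacs, patients, nuclide)
        if not organ_suv.empty:
            ratio_stats = _ratio_table(lesions, organ_suv)

    report = StudyReport(
        per_patient_tiacs=per_patient,
        cohort_tiacs=TIACSet(
            patient_id="cohort_mean",
            tiac_h=source_tiacs,
            n_patients=cohort.n_patients,
        ),
        excretion_fit=fit,
        bladder_tiac_h=bladder_h,
        doses_by_sex=doses_by_sex,
        effective_mSv_per_MBq=ed,
        administration_MBq=config.administration_MBq,
        total_mSv=total,
        plasma_half_life_mean_min=mean_thalf,
        plasma_half_life_range_min=thalf_range,
        pk_fits=pd.DataFrame(pk_rows),
        suv_stats=suv_stats,
        ratio_stats=ratio_stats,
        voiding_interval_min=config.voiding_interval_min,
    )
    report.write(config.out_dir)
    return report
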