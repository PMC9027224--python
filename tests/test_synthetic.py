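"""Synthetic cohort generator: determinism, mass balance, ground-truth
recovery through the pipeline."""

import filecmp
import math

import numpy as np
import pandas as pd
import pytest

from mirdkit import (
    GA68,
    CohortConfig,
    fit_cumulative_excretion,
    fit_monoexp,
    gen_cohort,
    total_decays_h,
)
from mirdkit import io as mio
from mirdkit.pipeline import patient_tiacs
from mirdkit.pk import cohort_half_life
from mirdkit.synthetic import (
    DEFAULT_ORGAN_KINETICS,
    OrganKinetics,
    analytic_organ_tiac_h,
    load_default_phantom,
    organ_fraction,
)


class TestDeterminism:
    def test_same_seed_identical_files(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        gen_cohort(CohortConfig(), seed=11).write(a)
        gen_cohort(CohortConfig(), seed=11).write(b)
        names = sorted(p.name for p in a.iterdir())
        assert names
        match, mismatch, errors = filecmp.cmpfiles(a, b, names, shallow=False)
        assert mismatch == [] and errors == []

    def test_different_seed_differs(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        gen_cohort(CohortConfig(), seed=11).write(a)
        gen_cohort(CohortConfig(), seed=12).write(b)
        assert (a / "tacs.csv").read_bytes() != (b / "tacs.csv").read_bytes()


class TestStudyStructure:
    def test_cohort_composition(self, default_cohort):
        pats = default_cohort.patients
        assert len(pats) == 10
        assert (pats.group == "NEN").sum() == 5
        assert (pats.group == "BC").sum() == 5
        # urine and plasma only in the 7-patient subset
        assert default_cohort.urine.patient_id.nunique() == 7
        assert default_cohort.plasma.patient_id.nunique() == 7

    def test_activity_within_administered_range(self, default_cohort):
        a = default_cohort.patients.injected_activity_MBq
        assert a.between(97.3, 220.0).all()

    def test_scan_schedule(self, default_cohort):
        times = sorted(default_cohort.tacs.time_min.unique())
        assert times == [10.0, 60.0, 120.0]

    def test_lesion_suvmax_brackets_observed_range(self, default_cohort):
        nen = default_cohort.lesions.query("group == 'NEN'").suv_max
        assert ((nen > 2.0) & (nen < 20.0)).all()
        assert default_cohort.lesions.suv_max.min() > 0

    def test_near_zero_background_regions(self, default_cohort, toy_phantom):
        """Brain and lung concentrations stay far below kidney concentrations."""
        tacs = default_cohort.tacs
        mean_conc = tacs.groupby("region").conc_kBq_per_mL.mean()
        assert mean_conc["brain"] < 0.05 * mean_conc["kidneys"]
        assert mean_conc["lungs"] < 0.15 * mean_conc["kidneys"]
        assert mean_conc["muscle"] < 0.05 * mean_conc["kidneys"]

    def test_blood_pool_declines(self, default_cohort):
        blood = default_cohort.tacs.query("region == 'heart_contents'")
        for _, sub in blood.groupby("patient_id"):
            vals = sub.sort_values("time_min").conc_kBq_per_mL.to_numpy()
            assert vals[0] > vals[-1]

    def test_infeasible_mass_balance_rejected(self):
        kins = dict(DEFAULT_ORGAN_KINETICS)
        kins["liver"] = OrganKinetics(0.9, 0.08, 0.004)
        with pytest.raises(ValueError, match="mass balance"):
            CohortConfig(organ_kinetics=kins)


class TestMassBalance:
    def test_decay_corrected_fractions_plus_urine_below_one(self, default_cohort):
        """At every sampled time: organ + blood + urine fractions <= 1."""
        lam = GA68.decay_constant_per_min
        phantom = load_default_phantom("male")
        patients = default_cohort.patient_meta()
        tacs = default_cohort.tacs
        urine = default_cohort.urine
        cfg = CohortConfig()
        for pid, sub in tacs.groupby("patient_id"):
            meta = patients[pid]
            for t in sorted(sub.time_min.unique()):
                rows = sub[sub.time_min == t]
                frac = 0.0
                for row in rows.itertuples():
                    vol = phantom.organ_masses_g[row.region] * (
                        meta.weight_kg / phantom.total_mass_kg
                    )
                    frac += (
                        row.conc_kBq_per_mL
                        * vol
                        / (meta.injected_activity_MBq * 1000.0)
                        / math.exp(-lam * t)
                    )
                u = 0.0
                pu = urine[urine.patient_id == pid]
                if not pu.empty:
                    before = pu[pu.void_time_min <= t]
                    if not before.empty:
                        u = float(before.cum_activity_frac.max())
                assert frac + u <= 1.0 + 1e-9


class TestGroundTruthRecovery:
    def test_dense_schedule_zero_noise_tiacs_within_3_percent(self):
        """Integrator recovers analytic TIACs at zero noise on dense sampling."""
        cfg = CohortConfig(
            n_per_group=1,
            n_pk_subset=0,
            noise_cv=0.0,
            organ_jitter_cv=0.0,
            scan_times_min=tuple(np.arange(2.0, 362.0, 2.0)),
        )
        data = gen_cohort(cfg, seed=3)
        phantom = load_default_phantom("male")
        patients = data.patient_meta()
        tacs_by_pid = {}
        for (pid, region), sub in data.tacs.groupby(["patient_id", "region"]):
            from mirdkit import build_tac

            tacs_by_pid.setdefault(pid, {})[region] = build_tac(
                region, list(zip(sub.time_min, sub.conc_kBq_per_mL)), False
            )
        for pid, curves in tacs_by_pid.items():
            est = patient_tiacs(curves, phantom, patients[pid]).tiac_h
            for region, truth in data.truth.tiac_h[pid].items():
                assert est[region] == pytest.approx(truth, rel=0.03), region

    def test_clinical_schedule_bias_positive_and_bounded(self, noiseless_cohort):
        """On the 3-point schedule the trapezoid overestimates by <12%."""
        phantom = load_default_phantom("male")
        patients = noiseless_cohort.patient_meta()
        from mirdkit import build_tac

        for (pid, region), sub in noiseless_cohort.tacs.groupby(
            ["patient_id", "region"]
        ):
            curve = build_tac(region, list(zip(sub.time_min, sub.conc_kBq_per_mL)), False)
            est = patient_tiacs({region: curve}, phantom, patients[pid]).tiac_h[region]
            truth = noiseless_cohort.truth.tiac_h[pid][region]
            assert truth <= est <= 1.12 * truth, region

    def test_analytic_tiac_matches_quadrature(self):
        kin = DEFAULT_ORGAN_KINETICS["kidneys"]
        t = np.arange(0.0, 3000.0, 0.01)
        brute = organ_fraction(t, kin, GA68).sum() * 0.01 / 60.0
        assert analytic_organ_tiac_h(kin, GA68) == pytest.approx(brute, rel=1e-4)

    def test_truth_respects_whole_body_bound(self, default_cohort):
        bound = total_decays_h(GA68)
        for pid, tiacs in default_cohort.truth.tiac_h.items():
            assert sum(tiacs.values()) <= bound

    def test_excretion_parameters_recovered_from_noisy_urine(self, default_cohort):
        fit = fit_cumulative_excretion(
            mio_read_urine_frames(default_cohort.urine), pooled=True
        )
        assert fit.limit_frac == pytest.approx(
            default_cohort.truth.excretion_limit_frac, rel=0.10
        )
        assert fit.rate_per_min == pytest.approx(
            default_cohort.truth.excretion_rate_per_min, rel=0.15
        )

    def test_plasma_half_lives_recovered(self, default_cohort):
        series = mio_read_plasma_frames(default_cohort.plasma)
        fits = [fit_monoexp(s) for s in series]
        mean, _ = cohort_half_life(fits)
        truths = default_cohort.truth.plasma_half_life_min
        for f in fits:
            assert f.half_life_min == pytest.approx(truths[f.patient_id], rel=0.20)
        assert mean == pytest.approx(np.mean(list(truths.values())), rel=0.05)


def mio_read_urine_frames(df: pd.DataFrame):
    from mirdkit import UrineSeries

    return [
        UrineSeries(
            patient_id=str(pid),
            void_times_min=sub.void_time_min.to_numpy(dtype=float),
            cum_activity_frac=sub.cum_activity_frac.to_numpy(dtype=float),
        )
        for pid, sub in df.groupby("patient_id")
    ]


def mio_read_plasma_frames(df: pd.DataFrame):
    from mirdkit import PlasmaSeries

    return [
        PlasmaSeries(
            patient_id=str(pid),
            times_min=sub.time_min.to_numpy(dtype=float),
            rel_conc=sub.rel_conc.to_numpy(dtype=float),
        )
        for pid, sub in df.groupby("patient_id")
    ]
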