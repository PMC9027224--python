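"""TIAC integration against closed-form oracles, and organ-activity scaling."""

import math

import numpy as np
import pytest

from mirdkit import (
    GA68,
    PatientMeta,
    TIACSet,
    average_tiacs,
    build_tac,
    organ_activity_fraction,
    tiac,
    total_decays_h,
)
GA68_TOTAL_H = 68.0 / (60.0 * math.log(2.0))  # 1.6350 h


def fraction_curve(times, values):
    return build_tac(
        "organ", list(zip(times, values)), decay_corrected=False,
        unit="fraction_of_injected",
    )


class TestOrganActivityFraction:
    def test_unit_arithmetic(self, toy_phantom):
        p = PatientMeta("p", weight_kg=70.0, injected_activity_MBq=200.0)
        assert organ_activity_fraction(10.0, "liver", toy_phantom, p) == pytest.approx(
            0.05
        )

    def test_zero_concentration(self, toy_phantom, patient):
        assert organ_activity_fraction(0.0, "liver", toy_phantom, patient) == 0.0

    def test_weight_scaling_is_linear(self, toy_phantom):
        heavier = PatientMeta("p", weight_kg=77.0, injected_activity_MBq=200.0)
        assert organ_activity_fraction(
            10.0, "liver", toy_phantom, heavier
        ) == pytest.approx(0.055)

    def test_unknown_region_rejected(self, toy_phantom, patient):
        with pytest.raises(KeyError):
            organ_activity_fraction(1.0, "pancreas", toy_phantom, patient)


class TestTiacIntegration:
    def test_single_point_at_zero_is_total_decays(self):
        curve = fraction_curve([0.0], [1.0])
        assert tiac(curve, GA68) == pytest.approx(GA68_TOTAL_H, rel=1e-12)
        assert total_decays_h(GA68) == pytest.approx(GA68_TOTAL_H, rel=1e-12)

    def test_three_point_physical_decay_curve(self):
        """Sparse samples of 0.2·e^(−λt): trapezoid+tail within 2% over
        [t₁, ∞); the linear-from-zero lead-in underestimates a curve that is
        already maximal at t = 0, bounding the full integral within 4%."""
        lam = GA68.decay_constant_per_min
        t = np.array([10.0, 60.0, 120.0])
        vals = 0.2 * np.exp(-lam * t)
        curve = fraction_curve(t, vals)
        truth_full = 0.2 * GA68_TOTAL_H

        tail_truth_min = 0.2 * math.exp(-lam * 10.0) / lam  # exact over [10, inf)
        est_tail_min = np.trapezoid(vals, t) + vals[-1] / lam
        assert est_tail_min == pytest.approx(tail_truth_min, rel=0.02)
        assert est_tail_min >= tail_truth_min  # trapezoid overestimates convex decay

        result = tiac(curve, GA68)
        assert result == pytest.approx(truth_full, rel=0.04)
        assert result <= truth_full  # lead-in triangle undershoots here

    def test_all_zero_curve(self):
        assert tiac(fraction_curve([10.0, 60.0], [0.0, 0.0]), GA68) == 0.0

    def test_decay_corrected_curve_rejected(self):
        curve = build_tac("organ", [(10.0, 1.0)], decay_corrected=True)
        with pytest.raises(ValueError):
            tiac(curve, GA68)

    @pytest.mark.parametrize(
        "amps,rates_per_min",
        [
            ((0.3,), (0.01,)),  # mono-exponential
            ((0.25, 0.15), (0.004, 0.08)),  # bi-exponential
            ((0.5, -0.5), (0.003, 0.2)),  # uptake-washout difference form
        ],
    )
    def test_dense_grid_matches_analytic_integral(self, amps, rates_per_min):
        """On a <=0.1-min grid the trapezoid+tail matches the closed form to 0.1%."""
        lam = GA68.decay_constant_per_min
        t = np.arange(0.0, 600.0, 0.1)
        vals = np.zeros_like(t)
        analytic_min = 0.0
        for a, k in zip(amps, rates_per_min):
            vals += a * np.exp(-(k + lam) * t)
            # integral over [0, inf) of a*exp(-(k+lam)t), but the sampled tail
            # beyond 600 min is extrapolated with physical decay only:
            analytic_min += a * (1.0 - math.exp(-(k + lam) * 600.0)) / (k + lam)
            analytic_min += a * math.exp(-(k + lam) * 600.0) / lam
        assert not np.any(vals < 0)
        curve = fraction_curve(t, vals)
        assert tiac(curve, GA68) == pytest.approx(analytic_min / 60.0, rel=1e-3)

    def test_monotone_in_sampled_values(self):
        t = [10.0, 60.0, 120.0]
        base = fraction_curve(t, [0.1, 0.05, 0.02])
        bumped = fraction_curve(t, [0.1, 0.06, 0.02])
        assert tiac(bumped, GA68) > tiac(base, GA68)


class TestAverageTiacs:
    def test_two_patient_mean(self):
        a = TIACSet("a", {"liver": 1.0})
        b = TIACSet("b", {"liver": 3.0})
        assert average_tiacs([a, b]).tiac_h == {"liver": 2.0}

    def test_single_patient_identity(self):
        a = TIACSet("a", {"liver": 1.2, "kidneys": 0.3})
        assert average_tiacs([a]).tiac_h == a.tiac_h

    def test_partial_region_coverage_averages_available(self, caplog):
        sets = [TIACSet(str(i), {"liver": 1.0}) for i in range(5)]
        sets += [TIACSet(str(i + 5), {"liver": 1.0, "spleen": 0.2}) for i in range(2)]
        with caplog.at_level("WARNING"):
            cohort = average_tiacs(sets)
        assert cohort.tiac_h["spleen"] == pytest.approx(0.2)
        assert cohort.n_patients == {"liver": 7, "spleen": 2}
        assert "2/7" in caplog.text

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_tiacs([])

    def test_negative_tiac_rejected(self):
        with pytest.raises(ValueError):
            TIACSet("a", {"liver": -0.1})
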