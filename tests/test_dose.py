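"""MIRD dose engine: hand-computable cases, linearity, effective dose."""

import pytest

from mirdkit import (
    ICRP103_WEIGHTS,
    SMatrix,
    TissueWeights,
    absorbed_doses,
    effective_dose,
    scale_to_administration,
)


def toy_smatrix(entries):
    return SMatrix(phantom_name="toy", entries=entries)


class TestAbsorbedDoses:
    def test_single_self_dose(self):
        s = toy_smatrix({("A", "A"): 0.01})
        assert absorbed_doses({"A": 1.0}, s)["A"] == pytest.approx(0.01)

    def test_two_source_hand_sum(self):
        s = toy_smatrix(
            {("A", "A"): 0.02, ("A", "B"): 0.004, ("B", "A"): 0.004, ("B", "B"): 0.05}
        )
        d = absorbed_doses({"A": 1.5, "B": 0.5}, s)
        assert d["A"] == pytest.approx(1.5 * 0.02 + 0.5 * 0.004)  # 0.032
        assert d["A"] == pytest.approx(0.032)

    def test_linearity_in_tiacs(self):
        s = toy_smatrix(
            {("A", "A"): 0.02, ("A", "B"): 0.004, ("B", "A"): 0.004, ("B", "B"): 0.05}
        )
        tiacs = {"A": 1.5, "B": 0.5}
        base = absorbed_doses(tiacs, s)
        doubled = absorbed_doses({k: 2 * v for k, v in tiacs.items()}, s)
        assert all(doubled[t] == pytest.approx(2 * base[t]) for t in base)

    def test_source_order_invariance(self):
        s = toy_smatrix(
            {("A", "A"): 0.02, ("A", "B"): 0.004, ("B", "A"): 0.004, ("B", "B"): 0.05}
        )
        d1 = absorbed_doses({"A": 1.5, "B": 0.5}, s)
        d2 = absorbed_doses({"B": 0.5, "A": 1.5}, s)
        assert d1 == d2

    def test_alias_resolution(self):
        s = toy_smatrix({("A", "A"): 0.02})
        d = absorbed_doses({"organ_a": 2.0}, s, aliases={"organ_a": "A"})
        assert d["A"] == pytest.approx(0.04)

    def test_unresolved_source_listed_in_error(self):
        s = toy_smatrix({("A", "A"): 0.02})
        with pytest.raises(KeyError, match="mystery"):
            absorbed_doses({"A": 1.0, "mystery": 0.5}, s)

    def test_negative_tiac_rejected(self):
        s = toy_smatrix({("A", "A"): 0.02})
        with pytest.raises(ValueError):
            absorbed_doses({"A": -1.0}, s)


class TestEffectiveDose:
    def test_equal_organ_doses_yield_that_dose(self):
        doses = {t: 0.0123 for t in ICRP103_WEIGHTS.w_T}
        assert effective_dose({"male": doses}) == pytest.approx(0.0123)

    def test_two_tissue_weighted_mean(self):
        w = TissueWeights({"A": 0.5, "B": 0.5})
        assert effective_dose({"male": {"A": 0.02, "B": 0.04}}, w) == pytest.approx(
            0.03
        )

    def test_single_sex_identity(self):
        w = TissueWeights({"A": 0.7, "B": 0.3})
        doses = {"A": 0.02, "B": 0.04}
        both = effective_dose({"male": doses, "female": doses}, w)
        assert effective_dose({"male": doses}, w) == pytest.approx(both)

    def test_sex_averaging(self):
        w = TissueWeights({"A": 1.0})
        ed = effective_dose({"male": {"A": 0.02}, "female": {"A": 0.04}}, w)
        assert ed == pytest.approx(0.03)

    def test_zero_weight_tissue_is_ignored(self):
        w = TissueWeights({"A": 1.0, "C": 0.0})
        assert effective_dose({"male": {"A": 0.02}}, w) == pytest.approx(0.02)

    def test_missing_weighted_tissue_listed(self):
        w = TissueWeights({"A": 0.5, "B": 0.5})
        with pytest.raises(KeyError, match="B"):
            effective_dose({"male": {"A": 0.02}}, w)

    def test_icrp103_weights_normalized(self):
        assert sum(ICRP103_WEIGHTS.w_T.values()) == pytest.approx(1.0, abs=1e-12)

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValueError):
            TissueWeights({"A": 0.5, "B": 0.6})

    def test_effective_dose_below_max_organ_dose(self):
        w = TissueWeights({"A": 0.4, "B": 0.6})
        doses = {"A": 0.1, "B": 0.02}
        assert effective_dose({"male": doses}, w) <= max(doses.values())


class TestScaleToAdministration:
    @pytest.mark.parametrize(
        "coeff,activity,expected",
        [(0.022, 200.0, 4.4), (0.05, 0.0, 0.0), (0.0218, 200.0, 4.36)],
    )
    def test_product(self, coeff, activity, expected):
        assert scale_to_administration(coeff, activity) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            scale_to_administration(-0.01, 100.0)


class TestToyPipelineHandCalculation:
    def test_three_region_spreadsheet_check(self):
        """TIAC -> dose -> ED on a 3-region toy matches explicit arithmetic."""
        tiacs = {"A": 0.8, "B": 0.3, "C": 0.1}
        s = toy_smatrix(
            {
                ("A", "A"): 0.030, ("A", "B"): 0.002, ("A", "C"): 0.001,
                ("B", "A"): 0.002, ("B", "B"): 0.040, ("B", "C"): 0.003,
                ("C", "A"): 0.001, ("C", "B"): 0.003, ("C", "C"): 0.050,
            }
        )
        d = absorbed_doses(tiacs, s)
        expected = {
            "A": 0.8 * 0.030 + 0.3 * 0.002 + 0.1 * 0.001,
            "B": 0.8 * 0.002 + 0.3 * 0.040 + 0.1 * 0.003,
            "C": 0.8 * 0.001 + 0.3 * 0.003 + 0.1 * 0.050,
        }
        for t in expected:
            assert d[t] == pytest.approx(expected[t], abs=1e-9)
        w = TissueWeights({"A": 0.2, "B": 0.3, "C": 0.5})
        ed = effective_dose({"male": d}, w)
        assert ed == pytest.approx(
            0.2 * expected["A"] + 0.3 * expected["B"] + 0.5 * expected["C"], abs=1e-9
        )
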