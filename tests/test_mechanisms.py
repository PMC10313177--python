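import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import fsolve

from tnbcqsp.mechanisms import (carrying_capacity_rate, checkpoint_occupancy,
                                cytotoxic_killing_rate, diameter_to_cells,
                                gompertz_growth_rate, myeloid_fluxes,
                                pmhc_level, synapse_cd28_occupancy,
                                tcell_activation_flux, tumor_diameter)
from tnbcqsp.params import KineticParameters


class TestGompertz:
    def test_empty_clone_is_zero(self):
        assert gompertz_growth_rate(0.0, 5e8, 1e9, 0.01) == 0.0

    def test_zero_at_carrying_capacity(self):
        assert gompertz_growth_rate(1e6, 1e9, 1e9, 0.01) == 0.0

    def test_closed_form_value(self):
        # k * n * ln(K/N) = 0.01 * 1e6 * ln(1e3)
        got = gompertz_growth_rate(1e6, 1e6, 1e9, 0.01)
        assert got == pytest.approx(0.01 * 1e6 * math.log(1e3), rel=1e-12)
        assert got == pytest.approx(6.9078e4, rel=1e-4)

    def test_overload_is_capped_net_death(self):
        # burden above capacity: negative, magnitude capped at k*n*ln_cap
        got = gompertz_growth_rate(1e6, 1e30, 1e9, 0.01, ln_cap=10.0)
        assert got == pytest.approx(-0.01 * 1e6 * 10.0)

    def test_non_finite_input_raises(self):
        with pytest.raises(ValueError):
            gompertz_growth_rate(float("nan"), 1.0, 1e9, 0.01)

    @given(n=st.floats(1.0, 1e12), K=st.floats(1.0, 1e12),
           k=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_sign_matches_burden_vs_capacity(self, n, K, k):
        rate = gompertz_growth_rate(n, n, K, k)
        if K > max(n, 1.0):
            assert rate >= 0.0
        elif K < max(n, 1.0):
            assert rate <= 0.0


class TestCarryingCapacity:
    def test_no_angio_no_decay_is_static(self):
        assert carrying_capacity_rate(1e9, 0.0, 0.1, 0.0, 1.0) == 0.0

    def test_saturation_limit(self):
        got = carrying_capacity_rate(1e9, 1e12, 0.1, 0.05, 1.0)
        assert got == pytest.approx((0.1 - 0.05) * 1e9, rel=1e-6)

    def test_half_saturation_balance(self):
        # growth at half max exactly offsets decay
        assert carrying_capacity_rate(1e9, 1.0, 0.1, 0.05, 1.0) == \
            pytest.approx(0.0, abs=1e-6)

    def test_negative_when_no_angiogenic_factor(self):
        assert carrying_capacity_rate(1e9, 0.0, 0.1, 0.05, 1.0) < 0.0


class TestCheckpoint:
    KDS = {"PDL1": 5.0, "PDL2": 8.0, "drug": 0.03}

    def test_no_drug_means_no_drug_binding(self):
        occ = checkpoint_occupancy(3000.0, {"PDL1": 5000.0, "PDL2": 500.0},
                                   0.0, self.KDS)
        assert occ["bound_drug_fraction"] == 0.0
        assert 0.0 < occ["bound_ligand_fraction"] < 1.0

    def test_drug_excess_saturates(self):
        occ = checkpoint_occupancy(3000.0, {"PDL1": 0.0, "PDL2": 0.0},
                                   1e6, self.KDS)
        assert occ["bound_drug_fraction"] == pytest.approx(1.0, abs=1e-6)

    def test_fractions_decrease_with_drug(self):
        drugs = [0.0, 0.1, 1.0, 10.0, 100.0]
        bound = [checkpoint_occupancy(3000.0, {"PDL1": 5000.0, "PDL2": 500.0},
                                      d, self.KDS)["bound_ligand_fraction"]
                 for d in drugs]
        assert all(b1 > b2 for b1, b2 in zip(bound, bound[1:]))

    def test_negative_totals_raise(self):
        with pytest.raises(ValueError):
            checkpoint_occupancy(-1.0, {"PDL1": 0.0, "PDL2": 0.0}, 0.0,
                                 self.KDS)

    def test_against_mass_balance_oracle(self, rng):
        """Brute-force oracle: solve the full conservation system (free
        receptor, two free ligands) with a generic multidimensional root
        finder and compare occupancies to <1e-8 relative error."""
        conv = 1.67e-3
        for _ in range(100):
            R_tot = rng.uniform(100.0, 1e4)
            L1, L2 = rng.uniform(0.0, 2e4, 2)
            drug = rng.uniform(0.0, 500.0)
            kd1, kd2, kdd = rng.uniform(0.01, 50.0, 3)
            kds = {"PDL1": kd1, "PDL2": kd2, "drug": kdd}
            occ = checkpoint_occupancy(R_tot, {"PDL1": L1, "PDL2": L2},
                                       drug, kds, conv)

            Rn, L1n, L2n = R_tot * conv, L1 * conv, L2 * conv

            def balance(x):
                r, l1, l2 = np.abs(x)
                b1, b2 = r * l1 / kd1, r * l2 / kd2
                bd = r * drug / kdd
                return [r + b1 + b2 + bd - Rn, l1 + b1 - L1n, l2 + b2 - L2n]

            r0 = Rn / (1.0 + drug / kdd + L1n / kd1 + L2n / kd2)
            x0 = [r0, L1n / (1.0 + r0 / kd1), L2n / (1.0 + r0 / kd2)]
            r, l1, l2 = np.abs(fsolve(balance, x0, xtol=1e-13))
            want_lig = (r * l1 / kd1 + r * l2 / kd2) / Rn
            want_drug = r * drug / kdd / Rn
            assert occ["bound_ligand_fraction"] == pytest.approx(
                want_lig, rel=1e-8, abs=1e-10)
            assert occ["bound_drug_fraction"] == pytest.approx(
                want_drug, rel=1e-8, abs=1e-10)

    def test_fraction_budget(self, rng):
        for _ in range(20):
            occ = checkpoint_occupancy(
                rng.uniform(10, 1e4),
                {"PDL1": rng.uniform(0, 1e4), "PDL2": rng.uniform(0, 1e3)},
                rng.uniform(0, 100), self.KDS)
            assert 0.0 <= occ["bound_ligand_fraction"] <= 1.0
            assert 0.0 <= occ["bound_drug_fraction"] <= 1.0
            assert occ["bound_ligand_fraction"] + occ["bound_drug_fraction"] \
                <= 1.0 + 1e-12


class TestKilling:
    def test_no_effectors_no_killing(self):
        assert cytotoxic_killing_rate(1e6, 0.0, 0.0, {}, 1.0, 0.3) == 0.0

    def test_full_checkpoint_suppression(self):
        assert cytotoxic_killing_rate(1e6, 1e6, 1.0, {}, 1.0, 0.3) == 0.0

    def test_half_max_ratio(self):
        # R = KD_ratio_half -> half of k_kill * C
        got = cytotoxic_killing_rate(1e6, 0.3 * 1e6, 0.0, {}, 1.0, 0.3)
        assert got == pytest.approx(5e5, rel=1e-9)

    def test_suppressors_reduce_killing(self):
        free = cytotoxic_killing_rate(1e6, 1e6, 0.0, {}, 1.0, 0.3)
        sup = cytotoxic_killing_rate(1e6, 1e6, 0.0,
                                     {"TGFb": 1.0, "ArgI": 20.0, "NO": 10.0},
                                     1.0, 0.3)
        assert sup == pytest.approx(free / 8.0, rel=1e-9)


class TestActivation:
    def test_no_presentation_no_activation(self):
        out = tcell_activation_flux(1e7, 1e5, 0.0, 0.1, 1e5, 0.3, 2.0,
                                    4.0, 2.0, 2.0, 0.5, 0.5)
        assert out["activation"] == 0.0

    def test_zero_division_signals(self):
        out = tcell_activation_flux(1e7, 1e5, 0.0, 0.1, 1e5, 0.3, 2.0,
                                    4.0, 2.0, 2.0, 0.0, 0.0)
        assert out["n_divisions"] == 0.0
        assert out["output"] == out["activation"]  # 2**0 == 1

    def test_linear_sum_of_divisions(self):
        # choose pMHC so the TCR Hill term is exactly one half
        out = tcell_activation_flux(1e7, 1e10, 0.3, 0.1, 1e5, 0.3, 2.0,
                                    2.0, 1.0, 1.0, 0.5, 0.5)
        assert out["n_divisions"] == pytest.approx(2.0)
        assert out["output"] == pytest.approx(out["activation"] * 4.0)


class TestMyeloid:
    def _state(self, **kw):
        base = dict(m1=1e6, m2=1e6, ccl2=0.0, il10=0.0, il12=0.0, ifng=0.0,
                    tgfb=0.0, cancer_total=1e8, f_vasc=1.0,
                    pd1_inhibition_m=0.0)
        base.update(kw)
        return base

    def test_no_ccl2_no_recruitment(self):
        out = myeloid_fluxes(self._state(), KineticParameters())
        assert out["M1_recruit"] == 0.0 and out["MDSC_recruit"] == 0.0

    def test_baseline_polarization_without_cytokines(self):
        p = KineticParameters()
        out = myeloid_fluxes(self._state(), p)
        assert out["M1toM2"] == pytest.approx(p.k_pol_M1toM2 * 1e6)
        assert out["M2toM1"] == pytest.approx(p.k_pol_M2toM1 * 1e6)

    def test_all_modulators_at_ec50(self):
        p = KineticParameters()
        st = self._state(ccl2=p.EC50_CCL2, il10=p.EC50_IL10_pol,
                         tgfb=p.EC50_TGFb_pol, il12=p.EC50_IL12_pol,
                         ifng=p.EC50_IFNg_pol, f_vasc=0.5)
        out = myeloid_fluxes(st, p)
        assert out["M1_recruit"] == pytest.approx(p.k_rec_M1 * 0.5 * 0.5)
        assert out["M1toM2"] == pytest.approx(
            (p.k_pol_M1toM2 + p.k_pol_ind_12 * 0.5) * 1e6)
        assert out["M2toM1"] == pytest.approx(
            (p.k_pol_M2toM1 + p.k_pol_ind_21 * 0.5) * 1e6)
        # phagocytosis with IL-10 at the phagocytosis EC50 wants its own term
        st2 = self._state(il10=p.EC50_IL10_phag, cancer_total=p.EC50_C_phag)
        out2 = myeloid_fluxes(st2, p)
        assert out2["phagocytosis"] == pytest.approx(
            p.k_phag * 1e6 * 0.5 * (1 - p.h_SIRPa) * 0.5)


class TestDiameter:
    def test_zero_cells_zero_diameter(self):
        assert tumor_diameter(0.0, 1e-9) == 0.0

    def test_closed_form(self):
        assert tumor_diameter(1e9, 1e-9) == pytest.approx(
            (6.0 / math.pi) ** (1 / 3), rel=1e-9)
        assert tumor_diameter(1e9, 1e-9) == pytest.approx(1.2407, abs=1e-4)

    def test_cube_root_scaling(self):
        d1 = tumor_diameter(1e8, 1e-9)
        d2 = tumor_diameter(2e8, 1e-9)
        assert d2 / d1 == pytest.approx(2 ** (1 / 3), rel=1e-12)

    @given(n=st.floats(1.0, 1e12))
    @settings(max_examples=30, deadline=None)
    def test_inverse_round_trip(self, n):
        assert diameter_to_cells(tumor_diameter(n, 1e-9), 1e-9) == \
            pytest.approx(n, rel=1e-10)


def test_synapse_occupancy_bounds_and_competition():
    # CTLA-4 competition reduces CD28 engagement
    f_free = synapse_cd28_occupancy(3000.0, 0.0, 5000.0, 10.0, 0.2)
    f_comp = synapse_cd28_occupancy(3000.0, 5000.0, 5000.0, 10.0, 0.2)
    assert 0.0 < f_comp < f_free < 1.0
    assert synapse_cd28_occupancy(3000.0, 1000.0, 0.0, 10.0, 0.2) == 0.0


def test_pmhc_level_saturates_and_tracks_affinity():
    assert pmhc_level(0.0, 100.0) == 0.0
    assert pmhc_level(2.0, 100.0, alpha=0.02) == pytest.approx(0.5)
    # weaker peptide-MHC binding (larger Kd) lowers presentation
    assert pmhc_level(2.0, 1000.0) < pmhc_level(2.0, 100.0)
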