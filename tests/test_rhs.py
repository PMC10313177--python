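"""The assembled right-hand side against the mechanism layer and closed forms."""

import math

import numpy as np
import pytest

from tnbcqsp import rhs as R
from tnbcqsp.mechanisms import (carrying_capacity_rate,
                                cytotoxic_killing_rate, gompertz_growth_rate,
                                hill, tumor_diameter)
from tnbcqsp.params import PatientParameters
from tnbcqsp.pkpd import Regimen, administer_dose, pd1_inhibition_relief
from tnbcqsp.simulate import (initial_state, integrate, seed_tumor,
                              target_diameter_event)
from tnbcqsp.state import (N_CLONES, N_STATE, N_TUMORS,
                           T_ANGIO, T_ARGI, T_CANCER, T_DRUG, T_IFNG, T_IL10,
                           T_IL12, T_K, T_M1, T_M2, T_NO, T_PDL1, T_TCYT,
                           T_TGFB, TUMOR0, TUMOR_BLOCK,
                           ModelState)


def _packed(patient):
    ps, pt = patient.pack()
    return ps, pt


def test_empty_system_is_a_fixed_point(default_patient):
    """All-zero cell state (carrying capacity at its floor) is stationary."""
    ps, pt = _packed(default_patient)
    y = np.zeros(N_STATE)
    for j in range(N_TUMORS):
        y[TUMOR0 + j * TUMOR_BLOCK + T_K] = default_patient.kinetics.K_min
    dy = R.rhs(0.0, y, ps, pt)
    assert np.all(dy == 0.0)


def test_compiled_and_python_kernels_agree(default_patient, rng):
    ps, pt = _packed(default_patient)
    for _ in range(5):
        y = rng.uniform(0.0, 1.0, N_STATE) * np.logspace(
            0, 8, N_STATE)[rng.permutation(N_STATE)]
        np.testing.assert_allclose(R.rhs(0.0, y, ps, pt),
                                   R.rhs_python(0.0, y, ps, pt),
                                   rtol=1e-12, atol=0)


def test_kernel_matches_mechanism_layer(default_patient, rng):
    """Spot-check assembled derivatives against the reference kinetic laws."""
    kin = default_patient.kinetics
    ps, pt = _packed(default_patient)
    y = np.abs(rng.normal(0.0, 1.0, N_STATE)) * 1e5
    j = 1
    off = TUMOR0 + j * TUMOR_BLOCK
    y[off + T_K] = 5e9
    y[off + T_PDL1] = 4000.0
    y[off + T_DRUG] = 2.0
    dy = R.rhs(0.0, y, ps, pt)

    # carrying capacity entry
    assert dy[off + T_K] == pytest.approx(
        carrying_capacity_rate(y[off + T_K], y[off + T_ANGIO],
                               kin.k_K_growth, kin.k_K_decay,
                               kin.EC50_angio), rel=1e-9)

    # cancer-clone entry: Gompertz minus apoptosis minus apportioned killing
    # and phagocytosis, with the checkpoint computed by the reference solver
    C = y[off + T_CANCER: off + T_CANCER + N_CLONES].sum()
    Ttot = y[off + T_TCYT: off + T_TCYT + 8].sum()
    h_t = pd1_inhibition_relief(y[off + T_DRUG], y[off + T_PDL1], kin)
    kill = cytotoxic_killing_rate(
        C, Ttot, h_t,
        {"TGFb": y[off + T_TGFB], "ArgI": y[off + T_ARGI],
         "NO": y[off + T_NO]},
        kin.k_kill, kin.KD_ratio_half, kin.EC50_TGFb_kill,
        kin.EC50_ArgI_kill, kin.EC50_NO_kill)
    bound = _bound_pd1(kin, y[off + T_PDL1], y[off + T_DRUG])
    h_m = hill(bound, kin.EC50_PD1_M, kin.n_PD1)
    phag = (kin.k_phag * y[off + T_M1] * C / (C + kin.EC50_C_phag)
            * (1 - h_m) * (1 - kin.h_SIRPa)
            * kin.EC50_IL10_phag / (kin.EC50_IL10_phag + y[off + T_IL10]))
    c0 = y[off + T_CANCER]
    want = (gompertz_growth_rate(c0, C, y[off + T_K],
                                 default_patient.clone_growth[j, 0])
            - kin.k_death_cancer * c0 - (kill + phag) * c0 / C)
    assert dy[off + T_CANCER] == pytest.approx(want, rel=1e-6)

    # myeloid polarization balance
    pol12 = (kin.k_pol_M1toM2 + kin.k_pol_ind_12 * 0.5
             * (hill(y[off + T_IL10], kin.EC50_IL10_pol)
                + hill(y[off + T_TGFB], kin.EC50_TGFb_pol))) * y[off + T_M1]
    pol21 = (kin.k_pol_M2toM1 + kin.k_pol_ind_21 * 0.5
             * (hill(y[off + T_IL12], kin.EC50_IL12_pol)
                + hill(y[off + T_IFNG], kin.EC50_IFNg_pol))) * y[off + T_M2]
    want_m2 = pol12 - pol21 - kin.k_death_M * y[off + T_M2]
    assert dy[off + T_M2] == pytest.approx(want_m2, rel=1e-9)


def _bound_pd1(kin, pdl1, drug):
    from tnbcqsp.mechanisms import checkpoint_occupancy
    occ = checkpoint_occupancy(
        kin.pd1_total, {"PDL1": pdl1, "PDL2": kin.pdl2_ratio * pdl1}, drug,
        {"PDL1": kin.Kd_PD1_PDL1, "PDL2": kin.Kd_PD1_PDL2,
         "drug": kin.Kd_PD1_drug}, kin.conv_surf)
    return occ["bound_ligand_fraction"] * kin.pd1_total


def _immune_free_patient(k_growth, K0, n0):
    p = PatientParameters()
    import dataclasses
    p = PatientParameters(kinetics=dataclasses.replace(
        p.kinetics, k_death_cancer=0.0, k_K_growth=0.0, k_K_decay=0.0,
        K_init=K0, k_rec_M1=0.0, k_rec_MDSC=0.0, k_rec_APC=0.0,
        k_act=0.0, k_act_Th=0.0, k_act_Treg=0.0, k_phag=0.0))
    p.clone_growth[:] = k_growth
    p.clone_fractions[:] = 0.0
    p.clone_fractions[:, 0] = 1.0
    p.n_seed_cells = n0
    return p


def test_immune_free_tumor_matches_gompertz_closed_form():
    """Single clone, no immunity, static capacity: the integrated lesion
    follows N(t) = K exp(ln(N0/K) e^{-kt}) to <1e-4 relative error."""
    k, K0, n0 = 0.02, 1e9, 1e5
    p = _immune_free_patient(k, K0, n0)
    s = initial_state(p)
    seed_tumor(s, p, 1)
    t_eval = np.arange(0.0, 301.0, 20.0)
    traj = integrate(p, s.vec, 0.0, 300.0, t_eval=t_eval)
    for i, t in enumerate(traj.times[1:], start=1):
        got = ModelState(traj.states[i]).cancer_total(1)
        want = K0 * math.exp(math.log(n0 / K0) * math.exp(-k * t))
        assert got == pytest.approx(want, rel=1e-4)


def test_trajectories_stay_essentially_nonnegative(default_patient):
    p = default_patient
    s = initial_state(p)
    seed_tumor(s, p, 1)
    traj = integrate(p, s.vec, 0.0, 400.0,
                     t_eval=np.arange(0.0, 401.0, 5.0))
    assert traj.states.min() >= 0.0  # post-hoc clip contract


def test_dose_zero_equals_untreated_bitwise(small_cohort):
    """A zero-dose regimen reproduces the untreated continuation exactly."""
    from tnbcqsp.trial import simulate_treatment
    vp = small_cohort.patients[0]
    res0 = simulate_treatment(vp, Regimen(dose_mg=0.0), duration_days=126)
    res1 = simulate_treatment(vp, Regimen(dose_mg=0.0), duration_days=126)
    np.testing.assert_array_equal(res0.states, res1.states)
    # and dosing zero truly adds nothing to the state
    dosed = administer_dose(vp.baseline_state, 0.0, vp.parameters.pk)
    np.testing.assert_array_equal(dosed.vec, vp.baseline_state.vec)


def test_more_killing_never_more_tumor(small_cohort):
    """Raising k_kill (all else fixed) does not increase final burden."""
    from tnbcqsp.trial import simulate_treatment
    vp = small_cohort.patients[0]
    finals = []
    for k_kill in (0.5, 1.5, 4.0):
        vp2 = type(vp)(vp.patient_id,
                       vp.parameters.with_updates(k_kill=k_kill),
                       vp.seeding_times, accepted=True,
                       baseline_state=vp.baseline_state,
                       baseline_time=vp.baseline_time,
                       baseline_diameters=vp.baseline_diameters)
        res = simulate_treatment(vp2, Regimen(), duration_days=189)
        burden = sum(ModelState(res.states[-1]).cancer_total(j)
                     for j in range(N_TUMORS))
        finals.append(burden)
    assert finals[0] >= finals[1] >= finals[2]


def test_burnin_stops_at_target_diameter(default_patient):
    p = default_patient
    s = initial_state(p)
    seed_tumor(s, p, 1)
    traj = integrate(p, s.vec, 0.0, 2000.0, events=target_diameter_event(p))
    assert traj.stop_time is not None
    d = tumor_diameter(traj.final().cancer_total(1), p.kinetics.v_cell_ml)
    assert d == pytest.approx(p.target_diameter_cm, rel=1e-3)
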