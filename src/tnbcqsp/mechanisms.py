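"""Kinetic laws of the tumor–immune system.

Each public function is one mechanism class used by the assembled ODE
right-hand side: modified Gompertzian clonal growth against a dynamic
carrying capacity, competitive quasi-equilibrium checkpoint binding,
ratio-dependent T-cell cytotoxicity with soluble-mediator suppression,
Hill-type T-cell activation with a linear sum of division signals, CCL2-driven
myeloid recruitment with reversible M1/M2 polarization, and the spherical
diameter map used for response assessment.

These functions are the reference implementations; the compiled right-hand
side in :mod:`tnbcqsp.rhs` mirrors them and is cross-checked against them in
the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq


def hill(x: float, ec50: float, n: float = 1.0) -> float:
    """Saturating Hill term x^n / (x^n + ec50^n), safe at x = 0."""
    if x <= 0.0:
        return 0.0
    xn = x ** n
    return xn / (xn + ec50 ** n)


def gompertz_growth_rate(n_clone: float, n_total: float, K: float,
                         k_growth: float, ln_cap: float = 10.0) -> float:
    """Modified Gompertzian growth rate of one cancer clone (cells/day).

    rate = k_growth * n_clone * ln(K / max(n_total, 1)); when the total burden
    exceeds the carrying capacity the logarithm is negative (net cell loss)
    and its magnitude is capped at ``ln_cap`` to bound stiffness.
    """
    for v in (n_clone, n_total, K, k_growth):
        if not math.isfinite(v):
            raise ValueError("non-finite input to gompertz_growth_rate "
                             "(corrupted state)")
    if n_clone < 0 or n_total < 0 or K <= 0 or k_growth < 0:
        raise ValueError("gompertz_growth_rate requires n >= 0, K > 0")
    if n_clone == 0.0:
        return 0.0
    log_term = math.log(K / max(n_total, 1.0))
    if log_term < -ln_cap:
        log_term = -ln_cap
    return k_growth * n_clone * log_term


def carrying_capacity_rate(K: float, angiogenic_factor: float,
                           k_K_growth: float, k_K_decay: float,
                           EC50_angio: float) -> float:
    """dK/dt: angiogenic-factor-driven vasculature growth minus regression."""
    for v in (K, angiogenic_factor, k_K_growth, k_K_decay, EC50_angio):
        if not math.isfinite(v):
            raise ValueError("non-finite input to carrying_capacity_rate")
    if K <= 0:
        raise ValueError("carrying capacity must be > 0")
    A = max(angiogenic_factor, 0.0)
    return k_K_growth * K * A / (A + EC50_angio) - k_K_decay * K


def free_receptor_concentration(R_tot: float, ligand_tots: tuple,
                                ligand_kds: tuple, drug: float,
                                Kd_drug: float, tol: float = 1e-14) -> float:
    """Free-receptor concentration of the competitive binding equilibrium.

    Receptor R binds each surface ligand i (totals ``ligand_tots``, subject to
    depletion) and the drug (reservoir, no depletion).  The free concentration
    r solves the monotone conservation equation

        r * (1 + drug/Kd_drug) + sum_i L_i * r / (Kd_i + r) = R_tot.

    All quantities in nM.
    """
    if R_tot == 0.0:
        return 0.0
    a = 1.0 + drug / Kd_drug

    def f(r: float) -> float:
        s = r * a - R_tot
        for L, kd in zip(ligand_tots, ligand_kds):
            s += L * r / (kd + r)
        return s

    hi = R_tot / a
    if f(hi) <= 0.0:
        return hi
    return brentq(f, 0.0, hi, xtol=tol * max(R_tot, 1.0), rtol=8.9e-16)


def checkpoint_occupancy(receptor_total: float, ligands: dict, drug: float,
                         kds: dict, conv_surf: float = 1.67e-3) -> dict:
    """Quasi-equilibrium PD-1 occupancy by its ligands and the blocking drug.

    Parameters
    ----------
    receptor_total : molecules/cell of PD-1.
    ligands : {"PDL1": molecules/cell, "PDL2": molecules/cell}.
    drug : free antibody concentration, nM (treated as an unlimited reservoir).
    kds : {"PDL1": nM, "PDL2": nM, "drug": nM}.
    conv_surf : nM per molecule/cell (synapse-volume conversion).

    Returns
    -------
    dict with ``bound_ligand_fraction`` and ``bound_drug_fraction`` of total
    PD-1; the two sum to at most 1.
    """
    if receptor_total < 0 or drug < 0 or any(v < 0 for v in ligands.values()):
        raise ValueError("negative totals in checkpoint_occupancy")
    for v in kds.values():
        if v <= 0:
            raise ValueError("dissociation constants must be > 0")
    R = receptor_total * conv_surf
    L = (ligands.get("PDL1", 0.0) * conv_surf,
         ligands.get("PDL2", 0.0) * conv_surf)
    kd = (kds["PDL1"], kds["PDL2"])
    if R == 0.0:
        denom = 1.0 + drug / kds["drug"] + sum(l / k for l, k in zip(L, kd))
        return {
            "bound_ligand_fraction": sum(l / k for l, k in zip(L, kd)) / denom,
            "bound_drug_fraction": (drug / kds["drug"]) / denom,
        }
    r = free_receptor_concentration(R, L, kd, drug, kds["drug"])
    bound_lig = sum(l * r / (k + r) for l, k in zip(L, kd))
    bound_drug = r * drug / kds["drug"]
    return {
        "bound_ligand_fraction": bound_lig / R,
        "bound_drug_fraction": bound_drug / R,
    }


def cytotoxic_killing_rate(C_total: float, Tcyt: float, pd1_inhibition: float,
                           suppression: dict, k_kill: float,
                           KD_ratio_half: float,
                           EC50_TGFb: float = 1.0, EC50_ArgI: float = 20.0,
                           EC50_NO: float = 10.0) -> float:
    """Total cancer-cell kill rate by cytotoxic T cells (cells/day).

    The rate saturates in the effector:target ratio R = Tcyt/C and is reduced
    by ligand-bound PD-1 (``pd1_inhibition`` in [0, 1]) and by TGF-b,
    arginase-I and NO, each as an independent inhibitory factor
    EC50 / (EC50 + s).
    """
    if C_total <= 0 or Tcyt <= 0:
        return 0.0
    R = Tcyt / max(C_total, 1.0)
    rate = k_kill * C_total * R / (R + KD_ratio_half) * (1.0 - pd1_inhibition)
    for key, ec50 in (("TGFb", EC50_TGFb), ("ArgI", EC50_ArgI), ("NO", EC50_NO)):
        s = max(suppression.get(key, 0.0), 0.0)
        rate *= ec50 / (ec50 + s)
    return rate


def synapse_cd28_occupancy(cd28_total: float, ctla4_total: float,
                           b7_total: float, Kd_CD28: float, Kd_CTLA4: float,
                           conv_surf: float = 1.67e-3) -> float:
    """Fraction of CD28 engaged by CD80/CD86 under CTLA-4 competition.

    CD28 and CTLA-4 compete for a shared CD80/CD86 pool in the immunological
    synapse; the free-ligand concentration solves a monotone conservation
    equation.  All totals in molecules/cell; CTLA-4 level is fixed
    (CTLA-4-directed therapy is out of scope).
    """
    L = b7_total * conv_surf
    R1 = cd28_total * conv_surf
    R2 = ctla4_total * conv_surf
    if L == 0.0 or cd28_total == 0.0:
        return 0.0

    def f(l: float) -> float:
        return l + R1 * l / (Kd_CD28 + l) + R2 * l / (Kd_CTLA4 + l) - L

    l_free = brentq(f, 0.0, L, rtol=8.9e-16)
    return l_free / (Kd_CD28 + l_free)


def tcell_activation_flux(naive: float, mAPC: float, pMHC_level: float,
                          k_act: float, EC50_APC: float, EC50_TCR: float,
                          n_TCR: float, d_TCR: float, d_CD28: float,
                          d_IL2: float, f_CD28: float, f_IL2: float) -> dict:
    """Naive T-cell activation in a lymph node.

    Activation is a Hill function of TCR ligation by peptide-MHC on mature
    APCs; the number of divisions of the activated cells is a linear sum of
    TCR, CD28 and IL-2 contributions, so the output flux of effector cells is
    ``activation * 2**n_divisions``.
    """
    h_tcr = hill(pMHC_level, EC50_TCR, n_TCR)
    activation = k_act * max(naive, 0.0) * hill(mAPC, EC50_APC) * h_tcr
    n_div = d_TCR * h_tcr + d_CD28 * f_CD28 + d_IL2 * f_IL2
    return {"activation": activation, "n_divisions": n_div,
            "output": activation * 2.0 ** n_div}


def myeloid_fluxes(state_tumor: dict, params) -> dict:
    """Myeloid fluxes in one tumor compartment (cells/day).

    ``state_tumor`` holds the local species: m1, m2, mdsc (unused), ccl2,
    il10, il12, ifng, tgfb, cancer_total, f_vasc (vascular-capacity factor in
    [0, 1]) and pd1_inhibition_m (ligand-bound PD-1 Hill term on macrophages).
    Recruitment of M1 macrophages and MDSCs is driven by tumor-derived CCL2;
    IL-10 and TGF-b polarize M1 to M2 while IL-12 and IFN-g polarize M2 to M1;
    phagocytosis by M1 is inhibited by IL-10 and by PD-1/SIRPa ligation.
    """
    p = params
    h_ccl2 = hill(state_tumor["ccl2"], p.EC50_CCL2)
    f_vasc = state_tumor["f_vasc"]
    m1, m2 = state_tumor["m1"], state_tumor["m2"]
    pol12 = (state_tumor.get("k_pol_M1toM2", p.k_pol_M1toM2)
             + p.k_pol_ind_12 * 0.5 * (hill(state_tumor["il10"], p.EC50_IL10_pol)
                                       + hill(state_tumor["tgfb"], p.EC50_TGFb_pol))) * m1
    pol21 = (p.k_pol_M2toM1
             + p.k_pol_ind_21 * 0.5 * (hill(state_tumor["il12"], p.EC50_IL12_pol)
                                       + hill(state_tumor["ifng"], p.EC50_IFNg_pol))) * m2
    C = state_tumor["cancer_total"]
    phag = (p.k_phag * m1 * hill(C, p.EC50_C_phag)
            * (1.0 - state_tumor["pd1_inhibition_m"]) * (1.0 - p.h_SIRPa)
            * p.EC50_IL10_phag / (p.EC50_IL10_phag + state_tumor["il10"]))
    return {
        "M1_recruit": state_tumor.get("k_rec_M1", p.k_rec_M1) * h_ccl2 * f_vasc,
        "MDSC_recruit": state_tumor.get("k_rec_MDSC", p.k_rec_MDSC) * h_ccl2 * f_vasc,
        "M1toM2": pol12,
        "M2toM1": pol21,
        "phagocytosis": phag,
    }


def pmhc_level(antigen_pool: float, Kd_pMHC: float, alpha: float = 0.02) -> float:
    """Quasi-steady-state peptide-MHC presentation level in [0, 1).

    The antigen processing chain is collapsed to a saturating function of the
    tumor antigen pool (nmol) with half-max at ``alpha * Kd_pMHC``, retaining
    the dependence on the peptide-MHC dissociation constant.
    """
    ag = max(antigen_pool, 0.0)
    return ag / (ag + alpha * Kd_pMHC)


def tumor_diameter(cancer_cells_total: float, cell_volume_ml: float) -> float:
    """Spherical lesion diameter in cm from the cancer-cell count.

    The lesion is treated as a sphere whose volume is the summed cancer-cell
    volume (immune/stromal volume is ignored): d = (6 N v / pi)^(1/3) with v
    in mL (= cm^3).
    """
    if cancer_cells_total < 0 or cell_volume_ml < 0:
        raise ValueError("inputs must be >= 0")
    if cancer_cells_total == 0.0:
        return 0.0
    return (6.0 * cancer_cells_total * cell_volume_ml / math.pi) ** (1.0 / 3.0)


def diameter_to_cells(diameter_cm: float, cell_volume_ml: float) -> float:
    """Inverse of :func:`tumor_diameter`."""
    return math.pi * diameter_cm ** 3 / (6.0 * cell_volume_ml)
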