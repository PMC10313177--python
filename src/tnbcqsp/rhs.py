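"""Assembled ODE right-hand side for the nine-compartment model.

The kernel combines every kinetic law of :mod:`tnbcqsp.mechanisms` into one
derivative evaluation over the flat state vector of :mod:`tnbcqsp.state`:
clonal Gompertzian growth against an angiogenesis-driven carrying capacity,
first-order apoptosis releasing antigens, APC uptake/maturation and migration
to the draining lymph node, quasi-steady-state peptide-MHC presentation,
Hill-type T-cell activation with division programming, trafficking of
effectors through blood into tumors, ratio-dependent killing with
checkpoint/suppressor inhibition, PD-1-and-IL-10-driven exhaustion, Th->Treg
trans-differentiation, CCL2-driven myeloid recruitment with reversible
polarization, cytokine bookkeeping, IFN-g-induced PD-L1, and the linear
antibody pharmacokinetics.

It is written in an njit-compatible subset of Python and compiled with numba
when available; the uncompiled function is the fallback and the reference for
the mechanism-layer cross-checks in the test suite.
"""

from __future__ import annotations

import numpy as np

from .params import (KINETIC_NAMES, N_KINETIC, PK_NAMES, TP_EXPR, TP_GROWTH,
                     TP_PDL1B, TP_POL12, TP_REC_APC, TP_REC_M1, TP_REC_MDSC)
from .state import (C_DRUG, C_NCD4, C_NCD8, C_TCYT, C_TH, C_TREG, CENTRAL0,
                    L_APC_MAT, L_DRUG, L_IL2, L_NCD4, L_NCD8, L_TCYT, L_TH,
                    L_TREG, LN0, LN_BLOCK, N_ANTIGENS, N_CLONES, N_EPITOPES,
                    N_LN, N_STATE, N_TUMORS, PER_DRUG, PER_NCD4, PER_NCD8,
                    PERIPHERAL0, T_AG, T_ANGIO, T_APC_IMM, T_APC_MAT, T_ARGI,
                    T_CANCER, T_CCL2, T_DEAD, T_DRUG, T_IFNG, T_IL10, T_IL12,
                    T_K, T_M1, T_M2, T_MDSC, T_NO, T_PDL1, T_TCYT, T_TEXH,
                    T_TGFB, T_TH, T_TREG, TUMOR0, TUMOR_BLOCK)

# scalar-parameter index constants (P_<NAME> for kinetics, PK_<NAME> for PK)
for _i, _n in enumerate(KINETIC_NAMES):
    globals()["P_" + _n.upper()] = _i
for _i, _n in enumerate(PK_NAMES):
    globals()["PK_" + _n.upper()] = N_KINETIC + _i

#: lymph node index draining each tumor (primary->0, lung1/2->1, other->2)
LN_OF_TUMOR = np.array([0, 1, 1, 2], dtype=np.int64)


def _free_receptor(R: float, L1: float, kd1: float, L2: float, kd2: float,
                   a: float) -> float:
    """Free-receptor concentration for two depleting ligands plus a reservoir
    competitor with relative occupancy ``a - 1`` (safeguarded Newton)."""
    if R <= 0.0:
        return 0.0
    lo = R / (a + L1 / kd1 + L2 / kd2)   # f(lo) <= 0
    hi = R / a                            # f(hi) >= 0
    r = lo
    for _ in range(100):
        f = r * a - R + L1 * r / (kd1 + r) + L2 * r / (kd2 + r)
        fp = a + L1 * kd1 / (kd1 + r) ** 2 + L2 * kd2 / (kd2 + r) ** 2
        if f > 0.0:
            hi = r
        else:
            lo = r
        rn = r - f / fp
        if rn <= lo or rn >= hi:
            rn = 0.5 * (lo + hi)
        if abs(rn - r) <= 1e-13 * (r + 1e-30):
            r = rn
            break
        r = rn
    return r


def _rhs(t: float, y: np.ndarray, p: np.ndarray, tp: np.ndarray) -> np.ndarray:
    dy = np.zeros(N_STATE)

    conv = p[P_CONV_SURF]
    kd1 = p[P_KD_PD1_PDL1]
    kd2 = p[P_KD_PD1_PDL2]
    kdd = p[P_KD_PD1_DRUG]
    n_pd1 = p[P_N_PD1]
    K_min = p[P_K_MIN]
    v_cell = p[P_V_CELL_ML]
    q_infil = p[P_Q_INFIL]

    # CD28/CTLA-4 synapse competition (parameters only -> constant in state)
    Lb7 = p[P_B7_TOTAL] * conv
    r_b7 = _free_receptor(Lb7, p[P_CD28_TOTAL] * conv, p[P_KD_CD28_B7],
                          p[P_CTLA4_TOTAL] * conv, p[P_KD_CTLA4_B7], 1.0)
    f_cd28 = r_b7 / (p[P_KD_CD28_B7] + r_b7)

    f_infil = np.zeros(N_TUMORS)
    ag_ln = np.zeros((N_LN, N_ANTIGENS))

    # ---------------- tumor compartments ----------------
    for j in range(N_TUMORS):
        off = TUMOR0 + j * TUMOR_BLOCK
        Ctot = 0.0
        for c in range(N_CLONES):
            v = y[off + T_CANCER + c]
            if v > 0.0:
                Ctot += v
        dead = max(y[off + T_DEAD], 0.0)
        K_raw = y[off + T_K]
        K = K_raw if K_raw > K_min else K_min
        Ttot = 0.0
        for e in range(N_EPITOPES):
            v = y[off + T_TCYT + e]
            if v > 0.0:
                Ttot += v
        texh = max(y[off + T_TEXH], 0.0)
        th = max(y[off + T_TH], 0.0)
        treg = max(y[off + T_TREG], 0.0)
        m1 = max(y[off + T_M1], 0.0)
        m2 = max(y[off + T_M2], 0.0)
        mdsc = max(y[off + T_MDSC], 0.0)
        apci = max(y[off + T_APC_IMM], 0.0)
        apcm = max(y[off + T_APC_MAT], 0.0)
        il10 = max(y[off + T_IL10], 0.0)
        il12 = max(y[off + T_IL12], 0.0)
        ifng = max(y[off + T_IFNG], 0.0)
        tgfb = max(y[off + T_TGFB], 0.0)
        ccl2 = max(y[off + T_CCL2], 0.0)
        angio = max(y[off + T_ANGIO], 0.0)
        argi = max(y[off + T_ARGI], 0.0)
        no = max(y[off + T_NO], 0.0)
        pdl1 = max(y[off + T_PDL1], 0.0)
        drug = max(y[off + T_DRUG], 0.0)

        vol_ml = (Ctot + dead) * v_cell
        f_vasc = K / (K + p[P_K_VASC_HALF])
        f_infil[j] = vol_ml / (vol_ml + p[P_V_HALF_INFIL]) * f_vasc

        # PD-1 competitive quasi-equilibrium
        R_pd1 = p[P_PD1_TOTAL] * conv
        L1 = pdl1 * conv
        L2 = p[P_PDL2_RATIO] * pdl1 * conv
        a = 1.0 + drug / kdd
        r = _free_receptor(R_pd1, L1, kd1, L2, kd2, a)
        bound_lig = (L1 * r / (kd1 + r) + L2 * r / (kd2 + r)) / conv
        bn = bound_lig ** n_pd1
        h_pd1_t = bn / (bn + p[P_EC50_PD1_T] ** n_pd1)
        h_pd1_m = bn / (bn + p[P_EC50_PD1_M] ** n_pd1)

        # killing by cytotoxic T cells, ratio-dependent and suppressible
        kill = 0.0
        if Ctot > 0.0 and Ttot > 0.0:
            ratio = Ttot / max(Ctot, 1.0)
            kill = (p[P_K_KILL] * Ctot * ratio / (ratio + p[P_KD_RATIO_HALF])
                    * (1.0 - h_pd1_t)
                    * p[P_EC50_TGFB_KILL] / (p[P_EC50_TGFB_KILL] + tgfb)
                    * p[P_EC50_ARGI_KILL] / (p[P_EC50_ARGI_KILL] + argi)
                    * p[P_EC50_NO_KILL] / (p[P_EC50_NO_KILL] + no))

        # phagocytosis by M1 macrophages
        phag = (p[P_K_PHAG] * m1 * Ctot / (Ctot + p[P_EC50_C_PHAG])
                * (1.0 - h_pd1_m) * (1.0 - p[P_H_SIRPA])
                * p[P_EC50_IL10_PHAG] / (p[P_EC50_IL10_PHAG] + il10))

        # clone dynamics: Gompertz growth minus apoptosis and apportioned loss
        Csafe = max(Ctot, 1e-12)
        log_term = np.log(K / max(Ctot, 1.0))
        if log_term < -p[P_LN_CAP]:
            log_term = -p[P_LN_CAP]
        dying_tot = 0.0
        rel = np.zeros(N_EPITOPES)
        for c in range(N_CLONES):
            Cc = max(y[off + T_CANCER + c], 0.0)
            growth = tp[j, TP_GROWTH + c] * Cc * log_term
            loss = (kill + phag) * Cc / Csafe
            death = p[P_K_DEATH_CANCER] * Cc
            dy[off + T_CANCER + c] = growth - death - loss
            dying = death + loss
            dying_tot += dying
            for e in range(N_EPITOPES):
                rel[e] += tp[j, TP_EXPR + c * N_EPITOPES + e] * dying
        dy[off + T_DEAD] = dying_tot - p[P_K_CLEAR_DEAD] * dead

        # carrying capacity (floored at K_min)
        dK = (p[P_K_K_GROWTH] * K * angio / (angio + p[P_EC50_ANGIO])
              - p[P_K_K_DECAY] * K)
        if K_raw <= K_min and dK < 0.0:
            dK = 0.0
        dy[off + T_K] = dK
        dy[off + T_ANGIO] = (p[P_K_ANGIO_C] * Ctot + p[P_K_ANGIO_M2] * m2
                             - p[P_K_DEG_ANGIO] * angio)

        # antigen pools; lymph-node presentation sees the draining tumors
        l_idx = LN_OF_TUMOR[j]
        ag_tot = 0.0
        for e in range(N_EPITOPES):
            ag = max(y[off + T_AG + e], 0.0)
            dy[off + T_AG + e] = p[P_K_AG_REL] * rel[e] - p[P_K_DEG_AG] * ag
            ag_ln[l_idx, e] += ag
            ag_tot += ag
        ag_s = max(y[off + T_AG + N_EPITOPES], 0.0)
        dy[off + T_AG + N_EPITOPES] = (p[P_K_AG_REL] * p[P_SELF_AG_SCALE]
                                       * dying_tot - p[P_K_DEG_AG] * ag_s)
        ag_ln[l_idx, N_EPITOPES] += ag_s
        ag_tot += ag_s

        # APCs: CCL2-recruited, antigen-matured (IL-12 up, IL-10 down)
        h_ccl2 = ccl2 / (ccl2 + p[P_EC50_CCL2])
        mat = (p[P_K_APC_MAT] * apci * ag_tot / (ag_tot + p[P_EC50_AG_MAT])
               * (1.0 + p[P_A_IL12_APC] * il12 / (il12 + p[P_EC50_IL12_APC]))
               * p[P_EC50_IL10_APC] / (p[P_EC50_IL10_APC] + il10))
        dy[off + T_APC_IMM] = (tp[j, TP_REC_APC] * h_ccl2 * f_vasc - mat
                               - p[P_K_APC_DEATH] * apci)
        mig = p[P_K_APC_MIG] * apcm
        dy[off + T_APC_MAT] = mat - mig - p[P_K_APC_DEATH] * apcm
        dy[LN0 + l_idx * LN_BLOCK + L_APC_MAT] += mig

        # T-cell trafficking, exhaustion, trans-differentiation
        k_exh = (p[P_K_EXHAUST_PD1] * h_pd1_t
                 + p[P_K_EXHAUST_IL10] * il10 / (il10 + p[P_EC50_IL10_EXH]))
        exh_flux = 0.0
        for e in range(N_EPITOPES):
            tc = max(y[CENTRAL0 + C_TCYT + e], 0.0)
            infl = q_infil * f_infil[j] * tc
            te = max(y[off + T_TCYT + e], 0.0)
            dy[off + T_TCYT + e] = infl - (k_exh + p[P_K_DEATH_T_TUMOR]) * te
            dy[CENTRAL0 + C_TCYT + e] -= infl
            exh_flux += k_exh * te
        dy[off + T_TEXH] = exh_flux - p[P_K_DEATH_TEXH] * texh

        th_c = max(y[CENTRAL0 + C_TH], 0.0)
        treg_c = max(y[CENTRAL0 + C_TREG], 0.0)
        infl_th = q_infil * f_infil[j] * th_c
        infl_treg = q_infil * f_infil[j] * treg_c
        dy[CENTRAL0 + C_TH] -= infl_th
        dy[CENTRAL0 + C_TREG] -= infl_treg
        td = (p[P_K_TD] * 0.5
              * (tgfb / (tgfb + p[P_EC50_TGFB_TD])
                 + argi / (argi + p[P_EC50_ARGI_TD])) * th)
        dy[off + T_TH] = infl_th - (k_exh + p[P_K_DEATH_T_TUMOR]) * th - td
        dy[off + T_TREG] = infl_treg + td - p[P_K_DEATH_TREG] * treg

        # myeloid compartment
        rec_m1 = tp[j, TP_REC_M1] * h_ccl2 * f_vasc
        rec_mdsc = tp[j, TP_REC_MDSC] * h_ccl2 * f_vasc
        pol12 = (tp[j, TP_POL12]
                 + p[P_K_POL_IND_12] * 0.5
                 * (il10 / (il10 + p[P_EC50_IL10_POL])
                    + tgfb / (tgfb + p[P_EC50_TGFB_POL]))) * m1
        pol21 = (p[P_K_POL_M2TOM1]
                 + p[P_K_POL_IND_21] * 0.5
                 * (il12 / (il12 + p[P_EC50_IL12_POL])
                    + ifng / (ifng + p[P_EC50_IFNG_POL]))) * m2
        dy[off + T_M1] = rec_m1 - pol12 + pol21 - p[P_K_DEATH_M] * m1
        dy[off + T_M2] = pol12 - pol21 - p[P_K_DEATH_M] * m2
        dy[off + T_MDSC] = rec_mdsc - p[P_K_DEATH_MDSC] * mdsc

        # cytokines and suppressive mediators
        dy[off + T_IL10] = (p[P_K_IL10_M2] * m2 + p[P_K_IL10_TREG] * treg
                            - p[P_K_DEG_IL10] * il10)
        dy[off + T_IL12] = p[P_K_IL12_M1] * m1 - p[P_K_DEG_IL12] * il12
        dy[off + T_IFNG] = (p[P_K_IFNG_T] * (Ttot + 0.5 * th)
                            - p[P_K_DEG_IFNG] * ifng)
        dy[off + T_TGFB] = p[P_K_TGFB_M2] * m2 - p[P_K_DEG_TGFB] * tgfb
        dy[off + T_CCL2] = p[P_K_CCL2_C] * Ctot - p[P_K_DEG_CCL2] * ccl2
        dy[off + T_ARGI] = p[P_K_ARGI_MDSC] * mdsc - p[P_K_DEG_ARGI] * argi
        dy[off + T_NO] = p[P_K_NO_MDSC] * mdsc - p[P_K_DEG_NO] * no

        # PD-L1: relaxation toward baseline + IFN-g induction, gated on
        # cancer-cell presence so the empty system stays a fixed point
        gate = Ctot / (Ctot + p[P_C_GATE_PDL1])
        target = tp[j, TP_PDL1B] * (1.0 + p[P_PDL1_IND_MAX]
                                    * ifng / (ifng + p[P_EC50_IFNG_PDL1]))
        dy[off + T_PDL1] = p[P_K_PDL1_RELAX] * (target - pdl1) * gate

    # ---------------- lymph-node compartments ----------------
    alpha_kd = p[P_ALPHA_PMHC] * p[P_KD_PMHC]
    n_tcr = p[P_N_TCR]
    ec_tcr_n = p[P_EC50_TCR] ** n_tcr
    clono = p[P_N_CLONOTYPES] / p[P_N_CLONOTYPES_REF]
    n8_c = max(y[CENTRAL0 + C_NCD8], 0.0)
    n4_c = max(y[CENTRAL0 + C_NCD4], 0.0)
    for l in range(N_LN):
        off = LN0 + l * LN_BLOCK
        n4 = max(y[off + L_NCD4], 0.0)
        n8 = max(y[off + L_NCD8], 0.0)
        apcm = max(y[off + L_APC_MAT], 0.0)
        il2 = max(y[off + L_IL2], 0.0)
        th_l = max(y[off + L_TH], 0.0)
        treg_l = max(y[off + L_TREG], 0.0)

        dy[off + L_APC_MAT] -= p[P_K_APC_DEATH_LN] * apcm
        f_apc = apcm / (apcm + p[P_EC50_APC_ACT])
        f_il2 = il2 / (il2 + p[P_EC50_IL2_DIV])

        act8_sum = 0.0
        pm_mean = 0.0
        for e in range(N_EPITOPES):
            ag = ag_ln[l, e]
            pm = ag / (ag + alpha_kd)
            pm_mean += pm / N_EPITOPES
            pmn = pm ** n_tcr
            h = pmn / (pmn + ec_tcr_n)
            act = p[P_K_ACT] * clono * n8 * f_apc * h
            act8_sum += act
            ndiv = p[P_D_TCR] * h + p[P_D_CD28] * f_cd28 + p[P_D_IL2] * f_il2
            t_le = max(y[off + L_TCYT + e], 0.0)
            out = p[P_Q_LN_OUT] * t_le
            dy[off + L_TCYT + e] = act * 2.0 ** ndiv - out
            dy[CENTRAL0 + C_TCYT + e] += out

        # helper T cells respond to the pooled neo-epitope presentation,
        # Tregs to self-antigen presentation
        pmn = pm_mean ** n_tcr
        h_th = pmn / (pmn + ec_tcr_n)
        ag_s = ag_ln[l, N_EPITOPES]
        pm_s = ag_s / (ag_s + alpha_kd)
        pmn = pm_s ** n_tcr
        h_s = pmn / (pmn + ec_tcr_n)
        act_th = p[P_K_ACT_TH] * n4 * f_apc * h_th
        act_tr = p[P_K_ACT_TREG] * n4 * f_apc * h_s
        ndiv_th = p[P_D_TCR] * h_th + p[P_D_CD28] * f_cd28 + p[P_D_IL2] * f_il2
        ndiv_s = p[P_D_TCR] * h_s + p[P_D_CD28] * f_cd28 + p[P_D_IL2] * f_il2
        out_th = p[P_Q_LN_OUT] * th_l
        out_tr = p[P_Q_LN_OUT] * treg_l
        dy[off + L_TH] = act_th * 2.0 ** ndiv_th - out_th
        dy[off + L_TREG] = act_tr * 2.0 ** ndiv_s - out_tr
        dy[CENTRAL0 + C_TH] += out_th
        dy[CENTRAL0 + C_TREG] += out_tr
        dy[off + L_IL2] = p[P_K_IL2_TH] * th_l - p[P_K_DEG_IL2] * il2

        # naive trafficking central <-> LN
        dy[off + L_NCD8] = p[P_Q_CL] * n8_c - p[P_Q_LC] * n8 - act8_sum
        dy[off + L_NCD4] = p[P_Q_CL] * n4_c - p[P_Q_LC] * n4 - act_th - act_tr
        dy[CENTRAL0 + C_NCD8] += p[P_Q_LC] * n8 - p[P_Q_CL] * n8_c
        dy[CENTRAL0 + C_NCD4] += p[P_Q_LC] * n4 - p[P_Q_CL] * n4_c

    # ---------------- central / peripheral ----------------
    n8_p = max(y[PERIPHERAL0 + PER_NCD8], 0.0)
    n4_p = max(y[PERIPHERAL0 + PER_NCD4], 0.0)
    dy[CENTRAL0 + C_NCD8] += (p[P_Q_PC] * n8_p - p[P_Q_CP] * n8_c
                              - p[P_K_DEATH_NAIVE] * n8_c)
    dy[CENTRAL0 + C_NCD4] += (p[P_Q_PC] * n4_p - p[P_Q_CP] * n4_c
                              - p[P_K_DEATH_NAIVE] * n4_c)
    dy[PERIPHERAL0 + PER_NCD8] = (p[P_Q_CP] * n8_c - p[P_Q_PC] * n8_p
                                  + p[P_K_NPROLIF] * n8_p
                                  * (1.0 - n8_p / p[P_N8_P_MAX]))
    dy[PERIPHERAL0 + PER_NCD4] = (p[P_Q_CP] * n4_c - p[P_Q_PC] * n4_p
                                  + p[P_K_NPROLIF] * n4_p
                                  * (1.0 - n4_p / p[P_N4_P_MAX]))
    for e in range(N_EPITOPES):
        dy[CENTRAL0 + C_TCYT + e] -= (p[P_K_DEATH_T_C]
                                      * max(y[CENTRAL0 + C_TCYT + e], 0.0))
    dy[CENTRAL0 + C_TH] -= p[P_K_DEATH_T_C] * max(y[CENTRAL0 + C_TH], 0.0)
    dy[CENTRAL0 + C_TREG] -= p[P_K_DEATH_T_C] * max(y[CENTRAL0 + C_TREG], 0.0)

    # ---------------- pharmacokinetics (amounts basis) ----------------
    vc = p[PK_V_CENTRAL]
    vp = p[PK_V_PERIPHERAL]
    vt = p[PK_V_TUMOR]
    vl = p[PK_V_LN]
    ac = max(y[CENTRAL0 + C_DRUG], 0.0) * vc
    ap = max(y[PERIPHERAL0 + PER_DRUG], 0.0) * vp
    dac = -(p[PK_K_CLEAR] + p[PK_K_CP] + N_TUMORS * p[PK_K_CT]) * ac \
        + p[PK_K_PC] * ap
    dy[PERIPHERAL0 + PER_DRUG] = (p[PK_K_CP] * ac - p[PK_K_PC] * ap) / vp
    aln_in = np.zeros(N_LN)
    for j in range(N_TUMORS):
        off = TUMOR0 + j * TUMOR_BLOCK
        at = max(y[off + T_DRUG], 0.0) * vt
        dat = p[PK_K_CT] * ac - (p[PK_K_TC] + p[PK_K_TLN]) * at
        dy[off + T_DRUG] = dat / vt
        dac += p[PK_K_TC] * at
        aln_in[LN_OF_TUMOR[j]] += p[PK_K_TLN] * at
    for l in range(N_LN):
        al = max(y[LN0 + l * LN_BLOCK + L_DRUG], 0.0) * vl
        dy[LN0 + l * LN_BLOCK + L_DRUG] = (aln_in[l] - p[PK_K_LN_C] * al) / vl
        dac += p[PK_K_LN_C] * al
    dy[CENTRAL0 + C_DRUG] = dac / vc

    return dy


# compile when numba is available; the pure-Python function is the fallback
try:  # pragma: no cover - exercised implicitly
    import numba

    rhs = numba.njit(cache=True, fastmath=False)(_rhs)
    _free_receptor = numba.njit(cache=True)(_free_receptor)  # noqa: F811
    rhs_python = _rhs
except ImportError:  # pragma: no cover
    rhs = _rhs
    rhs_python = _rhs


_SPARSITY_CACHE: dict = {}


def rhs_sparsity(pscal: np.ndarray, ptum: np.ndarray,
                 seed: int = 0) -> np.ndarray:
    """Structural Jacobian sparsity pattern, found by perturbation.

    The pattern depends only on the wiring, not parameter values; it is probed
    at a few random strictly positive states and cached.
    """
    key = "pattern"
    if key in _SPARSITY_CACHE:
        return _SPARSITY_CACHE[key]
    rng = np.random.default_rng(seed)
    pattern = np.zeros((N_STATE, N_STATE), dtype=bool)
    for _ in range(3):
        y = rng.uniform(0.5, 2.0, N_STATE) * 1e4
        f0 = rhs(0.0, y, pscal, ptum)
        for i in range(N_STATE):
            y2 = y.copy()
            y2[i] *= 1.0 + 1e-6
            y2[i] += 1e-6
            df = rhs(0.0, y2, pscal, ptum) - f0
            pattern[:, i] |= df != 0.0
    pattern |= np.eye(N_STATE, dtype=bool)
    _SPARSITY_CACHE[key] = pattern
    return pattern
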