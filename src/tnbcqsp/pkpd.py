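"""Pembrolizumab pharmacokinetics and checkpoint pharmacodynamics.

A linear mammillary system: intravenous bolus into the central compartment,
first-order clearance from central, bidirectional exchange with the
peripheral compartment and with each tumor, and unidirectional lymphatic
transport from each tumor to its draining lymph node and back to central.
The pharmacodynamic coupling is the reduction of ligand-bound PD-1 computed
by the competitive checkpoint equilibrium.

Drug-vector order for the standalone PK operations:
``[central, peripheral, tumor x4, lymph node x3]`` (concentrations, nM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mechanisms import checkpoint_occupancy, hill
from .params import PkParameters
from .state import (C_DRUG, CENTRAL0, DRAINING_LN, L_DRUG, LN0, LN_BLOCK,
                    LN_COMPARTMENTS, N_LN, N_TUMORS, PER_DRUG, PERIPHERAL0,
                    T_DRUG, TUMOR0, TUMOR_BLOCK, TUMOR_COMPARTMENTS,
                    ModelState)

N_PK = 2 + N_TUMORS + N_LN


@dataclass
class Regimen:
    """A fixed-interval intravenous dosing schedule."""

    dose_mg: float = 200.0
    interval_days: float = 21.0
    n_doses: int | None = None
    start_day: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise ValueError("dose_mg must be >= 0")
        if self.interval_days <= 0:
            raise ValueError("interval_days must be > 0")

    def dose_times(self, duration_days: float) -> np.ndarray:
        """Dose times within [start_day, start_day + duration_days)."""
        times = []
        t = self.start_day
        k = 0
        while t < self.start_day + duration_days:
            if self.n_doses is not None and k >= self.n_doses:
                break
            times.append(t)
            t += self.interval_days
            k += 1
        return np.asarray(times)


def dose_concentration_nM(dose_mg: float, pk: PkParameters) -> float:
    """Concentration increment in central from one bolus dose."""
    return dose_mg * 1e-3 / (pk.molecular_weight * pk.V_central) * 1e9


def administer_dose(state: ModelState, dose_mg: float,
                    pk: PkParameters) -> ModelState:
    """Bolus dose into the central compartment; all other species unchanged."""
    if dose_mg < 0:
        raise ValueError("dose must be >= 0")
    out = state.copy()
    out.vec[CENTRAL0 + C_DRUG] += dose_concentration_nM(dose_mg, pk)
    return out


def pk_volumes(pk: PkParameters) -> np.ndarray:
    return np.array([pk.V_central, pk.V_peripheral]
                    + [pk.V_tumor] * N_TUMORS + [pk.V_ln] * N_LN)


def pk_matrix(pk: PkParameters) -> np.ndarray:
    """First-order transfer matrix on drug *amounts*, da/dt = M a.

    Every column sums to zero except central, whose column sums to
    ``-k_clear``: mass is conserved up to the clearance integral.
    """
    M = np.zeros((N_PK, N_PK))
    c, p = 0, 1
    M[c, c] = -(pk.k_clear + pk.k_cp + N_TUMORS * pk.k_ct)
    M[c, p] = pk.k_pc
    M[p, c] = pk.k_cp
    M[p, p] = -pk.k_pc
    for j, comp in enumerate(TUMOR_COMPARTMENTS):
        tj = 2 + j
        ln = 2 + N_TUMORS + LN_COMPARTMENTS.index(DRAINING_LN[comp])
        M[tj, c] = pk.k_ct
        M[tj, tj] = -(pk.k_tc + pk.k_tln)
        M[c, tj] = pk.k_tc
        M[ln, tj] = pk.k_tln
    for l in range(N_LN):
        ll = 2 + N_TUMORS + l
        M[ll, ll] = -pk.k_ln_c
        M[c, ll] = pk.k_ln_c
    return M


def pk_rhs(drug_state: np.ndarray, pk: PkParameters) -> np.ndarray:
    """Concentration derivatives (nM/day) of the linear mammillary system."""
    conc = np.asarray(drug_state, dtype=float)
    if np.any(conc < 0):
        raise ValueError("drug concentrations must be >= 0")
    V = pk_volumes(pk)
    return pk_matrix(pk) @ (conc * V) / V


def drug_vector_from_state(state: ModelState) -> np.ndarray:
    """Extract the 9-entry drug-concentration vector from a full state."""
    v = state.vec
    out = np.empty(N_PK)
    out[0] = v[CENTRAL0 + C_DRUG]
    out[1] = v[PERIPHERAL0 + PER_DRUG]
    for j in range(N_TUMORS):
        out[2 + j] = v[TUMOR0 + j * TUMOR_BLOCK + T_DRUG]
    for l in range(N_LN):
        out[2 + N_TUMORS + l] = v[LN0 + l * LN_BLOCK + L_DRUG]
    return out


def pd1_inhibition_relief(drug_tumor_nM: float, pdl1_level: float, kin) -> float:
    """Hill term of ligand-bound PD-1 in [0, 1]; decreasing in drug.

    ``kin`` supplies the receptor total, PD-L2:PD-L1 ratio, dissociation
    constants and the Hill parameters.
    """
    occ = checkpoint_occupancy(
        kin.pd1_total,
        {"PDL1": pdl1_level, "PDL2": kin.pdl2_ratio * pdl1_level},
        drug_tumor_nM,
        {"PDL1": kin.Kd_PD1_PDL1, "PDL2": kin.Kd_PD1_PDL2,
         "drug": kin.Kd_PD1_drug},
        conv_surf=kin.conv_surf,
    )
    bound = occ["bound_ligand_fraction"] * kin.pd1_total
    return hill(bound, kin.EC50_PD1_T, kin.n_PD1)
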