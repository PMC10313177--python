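"""Model parameters: kinetic constants, pharmacokinetics, per-patient sets.

The kinetic parameter table below is the reduced-order system's equivalent of
a full supplementary parameter deposit: every rate constant, dissociation
constant and half-max concentration used by the right-hand side, in the
package's canonical units (day, cells, nM, molecules/cell, cm, L).  Defaults
are representative values chosen to place the simulated tumor–immune system in
a clinically plausible regime (metastases growing from ~100 cells to the
centimeter scale over roughly a year, partial immune control, checkpoint-
dependent exhaustion); they are documented in docs/methods.md and are fully
overridable from YAML parameter files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import yaml

from .state import N_CLONES, N_EPITOPES, N_TUMORS

# ---------------------------------------------------------------------------
# (name, default) tables.  Units in trailing comments.

KINETIC_FIELDS: list[tuple[str, float]] = [
    # -- cancer growth / death ------------------------------------------------
    ("k_growth_base", 0.016),      # 1/day, Gompertz rate scale per clone
    ("k_death_cancer", 1e-3),       # 1/day, first-order apoptosis
    ("ln_cap", 10.0),               # cap on |ln(K/N)| when N > K (overflow guard)
    ("K_min", 1e3),                 # cells, carrying-capacity floor
    ("K_init", 1e8),                # cells, carrying capacity of a naive site
    ("k_K_growth", 0.015),          # 1/day, vasculature growth rate
    ("k_K_decay", 0.001),           # 1/day, vasculature regression
    ("EC50_angio", 10.0),            # nM, angiogenic-factor half-max on K growth
    ("k_angio_C", 2e-8),            # nM/cell/day, secretion by cancer cells
    ("k_angio_M2", 4e-8),           # nM/cell/day, secretion by M2 macrophages
    ("k_deg_angio", 0.1),           # 1/day
    ("v_cell_ml", 1e-9),            # mL, volume of one cancer cell
    ("k_clear_dead", 0.1),          # 1/day, dead-cell clearance
    # -- T-cell killing -------------------------------------------------------
    ("k_kill", 0.8),                # 1/day, max killing rate
    ("KD_ratio_half", 1.5),         # dimensionless, T:C ratio at half-max killing
    ("EC50_TGFb_kill", 1.0),        # nM, TGF-b inhibition of cytotoxicity
    ("EC50_ArgI_kill", 20.0),       # nM, arginase-I inhibition
    ("EC50_NO_kill", 10.0),         # nM, nitric-oxide inhibition
    ("k_phag", 0.2),                # 1/day, M1 phagocytosis rate
    ("EC50_C_phag", 1e8),           # cells, cancer-cell half-max for phagocytosis
    ("h_SIRPa", 0.8),               # dimensionless, SIRPa "don't-eat-me" inhibition
    ("EC50_IL10_phag", 0.5),        # nM, IL-10 inhibition of phagocytosis
    # -- PD-1 checkpoint ------------------------------------------------------
    ("pd1_total", 3000.0),          # molecules/cell on T cells and macrophages
    ("pdl1_base", 5000.0),          # molecules/cell, baseline tumor PD-L1
    ("pdl2_ratio", 0.1),            # PD-L2 level as a fraction of PD-L1
    ("conv_surf", 1.67e-3),         # nM per molecule/cell (synapse-volume conversion)
    ("Kd_PD1_PDL1", 5.0),           # nM, synapse-effective
    ("Kd_PD1_PDL2", 8.0),           # nM
    ("Kd_PD1_drug", 0.03),          # nM, pembrolizumab
    ("n_PD1", 2.0),                 # Hill coefficient on bound PD-1
    ("EC50_PD1_T", 500.0),          # molecules/cell, bound PD-1 half-max on T cells
    ("EC50_PD1_M", 500.0),          # molecules/cell, on macrophages
    ("k_pdl1_relax", 0.5),          # 1/day, PD-L1 relaxation rate
    ("pdl1_ind_max", 4.0),          # max fold induction of PD-L1 by IFN-g
    ("EC50_IFNg_pdl1", 0.2),        # nM
    ("C_gate_pdl1", 1e3),           # cells, gates PD-L1 dynamics on cancer presence
    # -- CD28 / CTLA-4 synapse ------------------------------------------------
    ("cd28_total", 3000.0),         # molecules/cell
    ("ctla4_total", 1000.0),        # molecules/cell (fixed; CTLA-4 therapy out of scope)
    ("b7_total", 5000.0),           # molecules/cell, CD80/CD86 pool on APCs
    ("Kd_CD28_B7", 10.0),           # nM (synapse-effective)
    ("Kd_CTLA4_B7", 0.2),           # nM
    # -- antigen / APC --------------------------------------------------------
    ("k_ag_rel", 1e-6),             # nmol per dying cell, neo-antigen release
    ("self_ag_scale", 2.0),         # self-antigen release relative to neo-antigen
    ("k_deg_ag", 1.0),              # 1/day, antigen turnover (incl. uptake)
    ("alpha_pmhc", 0.02),           # nmol/nM, antigen scale in the pMHC saturation
    ("Kd_pMHC", 100.0),             # nM, peptide-MHC dissociation constant
    ("EC50_Ag_mat", 5.0),           # nmol, antigen half-max for APC maturation
    ("k_apc_mat", 1.0),             # 1/day, APC maturation rate
    ("a_IL12_apc", 1.0),            # max IL-12 enhancement of maturation
    ("EC50_IL12_apc", 0.1),         # nM
    ("EC50_IL10_apc", 0.5),         # nM, IL-10 inhibition of maturation
    ("k_rec_APC", 2e5),             # cells/day, immature-APC recruitment (per tumor)
    ("k_apc_death", 0.2),           # 1/day, APC turnover in tumor
    ("k_apc_mig", 0.5),             # 1/day, mature-APC migration to draining LN
    ("k_apc_death_LN", 0.3),        # 1/day, mature-APC turnover in LN
    # -- T-cell activation in lymph nodes ------------------------------------
    ("k_act", 0.03),                # 1/day, naive CD8 activation rate
    ("k_act_Th", 0.03),             # 1/day, naive CD4 -> Th
    ("k_act_Treg", 0.005),           # 1/day, naive CD4 -> Treg (self-antigen driven)
    ("EC50_APC_act", 1e5),          # cells, mature-APC half-max
    ("n_TCR", 2.0),                 # Hill coefficient on pMHC level
    ("EC50_TCR", 0.45),              # dimensionless pMHC level at half-max
    ("n_clonotypes", 10.0),         # T-cell clonotypes per neo-epitope specificity
    ("n_clonotypes_ref", 10.0),     # reference clonotype number (precursor scaling)
    ("d_TCR", 3.0),                 # divisions from TCR ligation
    ("d_CD28", 2.0),                # divisions from CD28 engagement
    ("d_IL2", 2.0),                 # divisions from IL-2
    ("EC50_IL2_div", 0.5),          # nM
    ("k_IL2_Th", 1e-7),             # nM/cell/day, IL-2 secretion by Th in LN
    ("k_deg_IL2", 5.0),             # 1/day
    # -- naive T-cell homeostasis / trafficking -------------------------------
    ("q_CL", 0.01),                 # 1/day, central -> each LN (naive)
    ("q_LC", 0.5),                  # 1/day, LN -> central (naive)
    ("q_CP", 0.05),                 # 1/day, central -> peripheral (naive)
    ("q_PC", 0.05),                 # 1/day, peripheral -> central (naive)
    ("k_death_naive", 1e-3),        # 1/day
    ("k_nprolif", 0.02),            # 1/day, logistic naive proliferation (peripheral)
    ("N8_P_max", 1e9),              # cells, peripheral naive CD8 capacity
    ("N4_P_max", 2e9),              # cells, peripheral naive CD4 capacity
    # -- effector trafficking and fate ----------------------------------------
    ("q_LN_out", 1.0),              # 1/day, activated-T egress LN -> central
    ("k_death_T_C", 0.1),           # 1/day, activated-T death in blood
    ("q_infil", 0.5),               # 1/day, max infiltration rate into a tumor
    ("V_half_infil", 0.5),          # mL, tumor-volume half-max for infiltration
    ("K_vasc_half", 1e8),           # cells, carrying capacity at half vascularity
    ("k_death_T_tumor", 0.08),      # 1/day, effector death in tumor
    ("k_death_Texh", 0.2),          # 1/day, exhausted-T death
    ("k_death_Treg", 0.1),          # 1/day
    ("k_exhaust_PD1", 0.3),         # 1/day, PD-1-driven exhaustion (max)
    ("k_exhaust_IL10", 0.1),        # 1/day, IL-10-driven exhaustion (max)
    ("EC50_IL10_exh", 0.5),         # nM
    ("k_td", 0.02),                 # 1/day, Th -> Treg trans-differentiation (max)
    ("EC50_TGFb_td", 1.0),          # nM
    ("EC50_ArgI_td", 20.0),         # nM
    # -- myeloid cells ---------------------------------------------------------
    ("k_rec_M1", 2e5),              # cells/day, M1 recruitment (per tumor)
    ("k_rec_MDSC", 2e5),            # cells/day, MDSC recruitment (per tumor)
    ("EC50_CCL2", 0.5),             # nM, CCL2 half-max for recruitment
    ("k_death_M", 0.02),            # 1/day, macrophage turnover
    ("k_death_MDSC", 0.05),         # 1/day
    ("k_pol_M1toM2", 0.05),         # 1/day, baseline M1 -> M2 polarization (per tumor)
    ("k_pol_M2toM1", 0.02),         # 1/day, baseline M2 -> M1
    ("k_pol_ind_12", 0.3),          # 1/day, cytokine-induced M1 -> M2 (max)
    ("k_pol_ind_21", 0.3),          # 1/day, cytokine-induced M2 -> M1 (max)
    ("EC50_IL10_pol", 0.3),         # nM
    ("EC50_TGFb_pol", 0.5),         # nM
    ("EC50_IL12_pol", 0.1),         # nM
    ("EC50_IFNg_pol", 0.2),         # nM
    # -- cytokines / soluble mediators ----------------------------------------
    ("k_IL10_M2", 2e-7),            # nM/cell/day
    ("k_IL10_Treg", 1e-8),          # nM/cell/day
    ("k_deg_IL10", 2.0),            # 1/day
    ("k_IL12_M1", 2e-7),            # nM/cell/day
    ("k_deg_IL12", 2.0),            # 1/day
    ("k_IFNg_T", 2e-8),             # nM/cell/day (active Tcyt; Th at half weight)
    ("k_deg_IFNg", 5.0),            # 1/day
    ("k_TGFb_M2", 2e-7),            # nM/cell/day
    ("k_deg_TGFb", 1.0),            # 1/day
    ("k_CCL2_C", 1e-9),             # nM/cell/day, secretion by cancer cells
    ("k_deg_CCL2", 2.0),            # 1/day
    ("k_ArgI_MDSC", 2e-6),          # nM/cell/day
    ("k_deg_ArgI", 1.0),            # 1/day
    ("k_NO_MDSC", 1e-6),            # nM/cell/day
    ("k_deg_NO", 1.0),              # 1/day
    # -- initial immune pools --------------------------------------------------
    ("N8_C0", 5e8),                 # cells, initial central naive CD8
    ("N4_C0", 1e9),                 # cells, initial central naive CD4
]

PK_FIELDS: list[tuple[str, float]] = [
    ("V_central", 3.5),             # L
    ("V_peripheral", 2.6),          # L
    ("V_tumor", 0.02),              # L, per tumor compartment (fixed)
    ("V_ln", 0.01),                 # L, per LN compartment
    ("k_clear", 0.063),             # 1/day, clearance from central
    ("k_cp", 0.23),                 # 1/day, central -> peripheral
    ("k_pc", 0.31),                 # 1/day, peripheral -> central
    ("k_ct", 5e-4),                 # 1/day, central -> each tumor
    ("k_tc", 0.2),                  # 1/day, tumor -> central
    ("k_tln", 0.05),                # 1/day, tumor -> draining LN
    ("k_ln_c", 1.0),                # 1/day, LN -> central
    ("molecular_weight", 1.49e5),   # g/mol, pembrolizumab
]

KINETIC_NAMES = [n for n, _ in KINETIC_FIELDS]
PK_NAMES = [n for n, _ in PK_FIELDS]
N_KINETIC = len(KINETIC_FIELDS)
N_PK = len(PK_FIELDS)

KineticParameters = dataclasses.make_dataclass(
    "KineticParameters",
    [(n, float, dataclasses.field(default=d)) for n, d in KINETIC_FIELDS],
)
KineticParameters.__doc__ = "Kinetic constants of the tumor–immune system (see module docstring)."

PkParameters = dataclasses.make_dataclass(
    "PkParameters",
    [(n, float, dataclasses.field(default=d)) for n, d in PK_FIELDS],
)
PkParameters.__doc__ = "Linear mammillary pharmacokinetic constants for pembrolizumab."


def _validate_positive(obj, names: Iterable[str]) -> None:
    for n in names:
        v = getattr(obj, n)
        if not np.isfinite(v):
            raise ValueError(f"parameter {n} is not finite")
        if v < 0:
            raise ValueError(f"parameter {n} must be >= 0 (got {v})")


# per-tumor parameter block layout (rows of the (4, TP_WIDTH) array)
TP_GROWTH = 0                        # .. +N_CLONES clone growth rates (1/day)
TP_EXPR = TP_GROWTH + N_CLONES       # .. +N_CLONES*N_EPITOPES expression matrix
TP_REC_M1 = TP_EXPR + N_CLONES * N_EPITOPES
TP_REC_MDSC = TP_REC_M1 + 1
TP_REC_APC = TP_REC_MDSC + 1
TP_POL12 = TP_REC_APC + 1
TP_PDL1B = TP_POL12 + 1
TP_WIDTH = TP_PDL1B + 1


@dataclass
class PatientParameters:
    """Fixed plus sampled parameters that define one virtual patient.

    ``clone_growth`` (tumors x clones, 1/day) and ``epitope_expr``
    (tumors x clones x epitopes, 0/1) carry the tumor-to-tumor heterogeneity;
    ``seeding_times`` are days relative to the first metastatic seeding event.
    """

    kinetics: "KineticParameters" = field(default_factory=KineticParameters)
    pk: "PkParameters" = field(default_factory=PkParameters)
    clone_growth: np.ndarray = None
    clone_fractions: np.ndarray = None
    epitope_expr: np.ndarray = None
    site_overrides: dict = field(default_factory=dict)
    seeding_times: dict = field(default_factory=dict)
    target_diameter_cm: float = 1.65
    n_seed_cells: float = 100.0
    primary_tumor_intact: bool = False
    patient_id: int = 0

    def __post_init__(self) -> None:
        kin = self.kinetics
        if self.clone_growth is None:
            self.clone_growth = np.full((N_TUMORS, N_CLONES), kin.k_growth_base)
        if self.clone_fractions is None:
            self.clone_fractions = np.full((N_TUMORS, N_CLONES), 1.0 / N_CLONES)
        if self.epitope_expr is None:
            self.epitope_expr = np.ones((N_TUMORS, N_CLONES, N_EPITOPES))
        self.clone_growth = np.asarray(self.clone_growth, dtype=float)
        self.clone_fractions = np.asarray(self.clone_fractions, dtype=float)
        self.epitope_expr = np.asarray(self.epitope_expr, dtype=float)
        _validate_positive(kin, KINETIC_NAMES)
        _validate_positive(self.pk, PK_NAMES)
        for kd in ("Kd_PD1_PDL1", "Kd_PD1_PDL2", "Kd_PD1_drug", "Kd_CD28_B7",
                   "Kd_CTLA4_B7", "Kd_pMHC"):
            if getattr(kin, kd) <= 0:
                raise ValueError(f"{kd} must be > 0")
        if kin.n_PD1 < 1 or kin.n_TCR < 1:
            raise ValueError("Hill coefficients must be >= 1")

    # -- packing for the ODE kernel ---------------------------------------
    def pack(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten into (scalar vector, per-tumor array) for the RHS kernel."""
        pscal = np.empty(N_KINETIC + N_PK)
        for i, n in enumerate(KINETIC_NAMES):
            pscal[i] = getattr(self.kinetics, n)
        for i, n in enumerate(PK_NAMES):
            pscal[N_KINETIC + i] = getattr(self.pk, n)
        ptum = np.empty((N_TUMORS, TP_WIDTH))
        ptum[:, TP_GROWTH:TP_GROWTH + N_CLONES] = self.clone_growth
        ptum[:, TP_EXPR:TP_EXPR + N_CLONES * N_EPITOPES] = (
            self.epitope_expr.reshape(N_TUMORS, -1))
        kin = self.kinetics
        for col, name in ((TP_REC_M1, "k_rec_M1"), (TP_REC_MDSC, "k_rec_MDSC"),
                          (TP_REC_APC, "k_rec_APC"), (TP_POL12, "k_pol_M1toM2"),
                          (TP_PDL1B, "pdl1_base")):
            ptum[:, col] = self.site_overrides.get(name, getattr(kin, name))
        return pscal, ptum

    def with_updates(self, **kinetic_updates) -> "PatientParameters":
        """Copy with selected kinetic parameters replaced (used by sensitivity)."""
        kin = dataclasses.replace(self.kinetics, **kinetic_updates)
        return PatientParameters(
            kinetics=kin, pk=dataclasses.replace(self.pk),
            clone_growth=self.clone_growth.copy(),
            clone_fractions=self.clone_fractions.copy(),
            epitope_expr=self.epitope_expr.copy(),
            site_overrides=dict(self.site_overrides),
            seeding_times=dict(self.seeding_times),
            target_diameter_cm=self.target_diameter_cm,
            n_seed_cells=self.n_seed_cells,
            primary_tumor_intact=self.primary_tumor_intact,
            patient_id=self.patient_id,
        )


# ---------------------------------------------------------------------------
# YAML round-trip for flat parameter files

def save_parameters(path, kinetics=None, pk=None) -> None:
    """Write a flat key -> value parameter file (YAML)."""
    out = {}
    if kinetics is not None:
        out.update({n: float(getattr(kinetics, n)) for n in KINETIC_NAMES})
    if pk is not None:
        out.update({n: float(getattr(pk, n)) for n in PK_NAMES})
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def load_parameters(path) -> tuple["KineticParameters", "PkParameters"]:
    """Read a flat parameter file; unknown keys raise."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kin_kwargs, pk_kwargs = {}, {}
    for key, val in raw.items():
        if key in KINETIC_NAMES:
            kin_kwargs[key] = float(val)
        elif key in PK_NAMES:
            pk_kwargs[key] = float(val)
        else:
            raise KeyError(f"unknown parameter {key!r}")
    return KineticParameters(**kin_kwargs), PkParameters(**pk_kwargs)
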