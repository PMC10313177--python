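"""State layout for the nine-compartment tumor–immune model.

The model tracks four tumor compartments (primary, two lung metastases, one
"other" metastasis), three tumor-draining lymph-node compartments (each lymph
node drains the tumors at its site), and central (blood) and peripheral
compartments.  Each tumor carries five cancer clones, cytotoxic T cells of
eight neo-epitope specificities, the myeloid/regulatory populations, a pool of
eight neo-antigens plus one self-antigen, and the soluble factors that couple
them.  The full state is a flat float vector; this module owns the indexing.

Units: cells for cell counts, nM for soluble species, molecules/cell for
surface species, day for time, cm for diameters.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

N_CLONES = 5
N_EPITOPES = 8
N_ANTIGENS = N_EPITOPES + 1  # eight neo-antigens plus one self-antigen


class CompartmentKind(enum.Enum):
    BLOOD = "blood"
    TISSUE = "tissue"
    TUMOR = "tumor"
    LYMPH_NODE = "lymph_node"


class CompartmentId(enum.Enum):
    CENTRAL = "central"
    PERIPHERAL = "peripheral"
    TUMOR_PRIMARY = "tumor_primary"
    TUMOR_LUNG1 = "tumor_lung1"
    TUMOR_LUNG2 = "tumor_lung2"
    TUMOR_OTHER = "tumor_other"
    LN_PRIMARY = "ln_primary"
    LN_LUNG = "ln_lung"
    LN_OTHER = "ln_other"

    @property
    def kind(self) -> CompartmentKind:
        if self in (CompartmentId.CENTRAL,):
            return CompartmentKind.BLOOD
        if self in (CompartmentId.PERIPHERAL,):
            return CompartmentKind.TISSUE
        if self.value.startswith("tumor"):
            return CompartmentKind.TUMOR
        return CompartmentKind.LYMPH_NODE


TUMOR_COMPARTMENTS = (
    CompartmentId.TUMOR_PRIMARY,
    CompartmentId.TUMOR_LUNG1,
    CompartmentId.TUMOR_LUNG2,
    CompartmentId.TUMOR_OTHER,
)
LN_COMPARTMENTS = (
    CompartmentId.LN_PRIMARY,
    CompartmentId.LN_LUNG,
    CompartmentId.LN_OTHER,
)

#: every tumor drains into exactly one lymph node
DRAINING_LN = {
    CompartmentId.TUMOR_PRIMARY: CompartmentId.LN_PRIMARY,
    CompartmentId.TUMOR_LUNG1: CompartmentId.LN_LUNG,
    CompartmentId.TUMOR_LUNG2: CompartmentId.LN_LUNG,
    CompartmentId.TUMOR_OTHER: CompartmentId.LN_OTHER,
}

#: tumor indices (0..3) draining into each LN index (0..2)
LN_DRAINAGE = ((0,), (1, 2), (3,))

N_TUMORS = len(TUMOR_COMPARTMENTS)
N_LN = len(LN_COMPARTMENTS)

# ---------------------------------------------------------------------------
# per-block species offsets

# tumor block (width 42)
T_CANCER = 0           # .. +N_CLONES
T_DEAD = 5
T_K = 6                # carrying capacity
T_TCYT = 7             # .. +N_EPITOPES
T_TEXH = 15
T_TH = 16
T_TREG = 17
T_M1 = 18
T_M2 = 19
T_MDSC = 20
T_APC_IMM = 21
T_APC_MAT = 22
T_AG = 23              # .. +N_ANTIGENS (last entry = self-antigen)
T_IL10 = 32
T_IL12 = 33
T_IFNG = 34
T_TGFB = 35
T_CCL2 = 36
T_ANGIO = 37
T_ARGI = 38
T_NO = 39
T_PDL1 = 40
T_DRUG = 41
TUMOR_BLOCK = 42

# lymph-node block (width 15)
L_NCD4 = 0
L_NCD8 = 1
L_APC_MAT = 2
L_TCYT = 3             # .. +N_EPITOPES
L_TH = 11
L_TREG = 12
L_IL2 = 13
L_DRUG = 14
LN_BLOCK = 15

# central block (width 13)
C_NCD4 = 0
C_NCD8 = 1
C_TCYT = 2             # .. +N_EPITOPES
C_TH = 10
C_TREG = 11
C_DRUG = 12
CENTRAL_BLOCK = 13

# peripheral block (width 3)
PER_NCD4 = 0
PER_NCD8 = 1
PER_DRUG = 2
PERIPHERAL_BLOCK = 3

TUMOR0 = 0
LN0 = N_TUMORS * TUMOR_BLOCK                      # 168
CENTRAL0 = LN0 + N_LN * LN_BLOCK                  # 213
PERIPHERAL0 = CENTRAL0 + CENTRAL_BLOCK            # 226
N_STATE = PERIPHERAL0 + PERIPHERAL_BLOCK          # 229


def tumor_offset(j: int) -> int:
    return TUMOR0 + j * TUMOR_BLOCK


def ln_offset(l: int) -> int:
    return LN0 + l * LN_BLOCK


def _tumor_species_names() -> list[str]:
    names = [f"cancer_clone_{c}" for c in range(N_CLONES)]
    names += ["dead_cells", "carrying_capacity"]
    names += [f"tcyt_active_{e}" for e in range(N_EPITOPES)]
    names += ["tcyt_exhausted", "th", "treg", "m1", "m2", "mdsc",
              "apc_immature", "apc_mature"]
    names += [f"antigen_{e}" for e in range(N_EPITOPES)] + ["antigen_self"]
    names += ["il10", "il12", "ifng", "tgfb", "ccl2",
              "angiogenic_factor", "argi", "no", "pdl1_level", "drug"]
    return names


def _ln_species_names() -> list[str]:
    names = ["naive_cd4", "naive_cd8", "apc_mature"]
    names += [f"tcyt_activated_{e}" for e in range(N_EPITOPES)]
    names += ["th_activated", "treg_activated", "il2", "drug"]
    return names


def species_table() -> list[tuple[CompartmentId, str]]:
    """(compartment, species name) for every entry of the state vector."""
    rows: list[tuple[CompartmentId, str]] = []
    for comp in TUMOR_COMPARTMENTS:
        rows.extend((comp, s) for s in _tumor_species_names())
    for comp in LN_COMPARTMENTS:
        rows.extend((comp, s) for s in _ln_species_names())
    rows.extend(
        (CompartmentId.CENTRAL, s)
        for s in (["naive_cd4", "naive_cd8"]
                  + [f"tcyt_{e}" for e in range(N_EPITOPES)]
                  + ["th", "treg", "drug"])
    )
    rows.extend((CompartmentId.PERIPHERAL, s)
                for s in ["naive_cd4", "naive_cd8", "drug"])
    assert len(rows) == N_STATE
    return rows


_SPECIES_TABLE = species_table()
_INDEX = {key: i for i, key in enumerate(_SPECIES_TABLE)}


def state_index(compartment: CompartmentId, species: str) -> int:
    return _INDEX[(compartment, species)]


def default_atol() -> np.ndarray:
    """Per-species absolute solver tolerance: 1e-3 cells, 1e-9 nM."""
    atol = np.empty(N_STATE)
    cellish = ("cancer", "dead", "carrying", "tcyt", "th", "treg", "m1", "m2",
               "mdsc", "apc", "naive")
    for i, (_, name) in enumerate(_SPECIES_TABLE):
        atol[i] = 1e-3 if name.startswith(cellish) else 1e-9
    return atol


@dataclass
class ModelState:
    """A full state vector at one time point, with named access."""

    vec: np.ndarray

    def __post_init__(self) -> None:
        self.vec = np.asarray(self.vec, dtype=float)
        if self.vec.shape != (N_STATE,):
            raise ValueError(f"state vector must have length {N_STATE}")

    @classmethod
    def zeros(cls) -> "ModelState":
        return cls(np.zeros(N_STATE))

    def copy(self) -> "ModelState":
        return ModelState(self.vec.copy())

    def get(self, compartment: CompartmentId, species: str) -> float:
        return float(self.vec[state_index(compartment, species)])

    def set(self, compartment: CompartmentId, species: str, value: float) -> None:
        self.vec[state_index(compartment, species)] = value

    # -- tumor-level aggregates -------------------------------------------
    def cancer_cells(self, j: int) -> np.ndarray:
        off = tumor_offset(j)
        return self.vec[off + T_CANCER: off + T_CANCER + N_CLONES]

    def cancer_total(self, j: int) -> float:
        return float(np.clip(self.cancer_cells(j), 0.0, None).sum())

    def tcyt_active(self, j: int) -> np.ndarray:
        off = tumor_offset(j)
        return self.vec[off + T_TCYT: off + T_TCYT + N_EPITOPES]

    def to_frame(self, time_day: float = 0.0) -> pd.DataFrame:
        """Long-form snapshot with columns (time_day, compartment, species, value)."""
        return pd.DataFrame({
            "time_day": time_day,
            "compartment": [c.value for c, _ in _SPECIES_TABLE],
            "species": [s for _, s in _SPECIES_TABLE],
            "value": self.vec,
        })


def trajectory_frame(times: np.ndarray, states: np.ndarray) -> pd.DataFrame:
    """Long-form trajectory (times: (T,), states: (T, N_STATE))."""
    frames = [ModelState(states[i]).to_frame(float(times[i]))
              for i in range(len(times))]
    return pd.concat(frames, ignore_index=True)
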