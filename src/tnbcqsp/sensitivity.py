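"""Parameter-influence analyses.

Two complementary views of how model parameters shape response:

* ``parameter_subgroup_ranking`` treats each *varied* parameter's per-patient
  value as a biomarker candidate and reuses the subgroup machinery (15
  cutoffs by default, subgroups under 20 patients discarded) to rank
  parameters by the best response probability attained in any
  threshold-defined patient subgroup.

* ``perturb_fixed_parameter`` re-simulates the identical cohort under a
  multiplicative perturbation (50% decrease to 50% increase) of one *fixed*
  parameter, applied during treatment from the unchanged baseline states, and
  reports the overall response rate and the PD/SD/PR-CR status-transition
  matrix against the unperturbed run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .params import KINETIC_NAMES
from .pkpd import Regimen
from .simulate import SolverError
from .trial import (DEFAULT_DURATION_DAYS, TrialResult, classify_recist,
                    simulate_treatment, sum_of_diameters)

STATUS_GROUPS = ("PD", "SD", "PR/CR")


def _status_group(status: str) -> str:
    return "PR/CR" if status in ("PR", "CR") else status


def cohort_parameter_table(cohort: Cohort, names: list | None = None
                           ) -> pd.DataFrame:
    """Per-patient values of the varied parameters (per-tumor parameters are
    averaged over the patient's tumors)."""
    rows = []
    for vp in cohort.patients:
        p = vp.parameters
        row = {"patient_id": vp.patient_id,
               "target_diameter_cm": p.target_diameter_cm,
               "growth_scale": float(p.clone_growth.mean()
                                     / p.kinetics.k_growth_base)}
        for name in KINETIC_NAMES:
            if name in p.site_overrides:
                row[name] = float(np.mean(p.site_overrides[name]))
            else:
                row[name] = float(getattr(p.kinetics, name))
        rows.append(row)
    df = pd.DataFrame(rows).set_index("patient_id")
    if names is not None:
        df = df[names]
    return df


def parameter_subgroup_ranking(cohort: Cohort, trial: TrialResult,
                               n_cutoffs: int = 15, min_size: int = 20,
                               n_boot: int = 200, seed: int = 0) -> list:
    """Rank varied parameters by maximum subgroup response probability.

    Parameters constant across the cohort produce no valid subgroup and are
    excluded.  Returns :class:`tnbcqsp.biomarker.SubgroupScore` objects.
    """
    from .biomarker import rank_candidates

    table = cohort_parameter_table(cohort)
    # drop parameters that do not vary
    varying = [c for c in table.columns
               if table[c].nunique(dropna=True) > 1]
    table = table[varying].copy()
    responder = pd.Series(
        {r.patient_id: r.responder for r in trial.records}, name="responder")
    table = table.loc[table.index.intersection(responder.index)]
    table["responder"] = responder.loc[table.index]
    return rank_candidates(table, metric="rp", n_thresholds=n_cutoffs,
                           min_size=min_size, n_boot=n_boot, seed=seed)


@dataclass
class PerturbationResult:
    parameter: str
    factor: float
    orr: float
    transition: pd.DataFrame        # rows: baseline group, cols: perturbed
    records: list = field(default_factory=list)


def _classify_cohort(cohort: Cohort, regimen: Regimen, duration: float,
                     updates_fn) -> dict:
    """Status per patient id under kinetics transformed by ``updates_fn``."""
    out = {}
    for vp in cohort.patients:
        patient = updates_fn(vp.parameters)
        vp2 = type(vp)(vp.patient_id, patient, vp.seeding_times,
                       accepted=True, baseline_state=vp.baseline_state,
                       baseline_time=vp.baseline_time,
                       baseline_diameters=vp.baseline_diameters)
        try:
            res = simulate_treatment(vp2, regimen, duration)
        except SolverError:
            continue
        assess = res.lesions[0].times
        sums = np.array([sum_of_diameters(res.lesions, t) for t in assess])
        out[vp.patient_id] = classify_recist(assess, sums,
                                             patient_id=vp.patient_id)
    return out


def perturb_fixed_parameter(cohort: Cohort, name: str, factors,
                            regimen: Regimen | None = None,
                            duration_days: float = DEFAULT_DURATION_DAYS,
                            baseline_records: dict | None = None) -> list:
    """ORR and response-status shifts under multiplicative perturbation.

    ``name`` must be a kinetic parameter; each factor in ``factors`` (within
    [0.5, 1.5]) rescales it for the whole cohort during treatment, keeping
    the baseline states of the unperturbed burn-in.  The transition matrix
    counts patients by (baseline status group x perturbed status group); at
    factor 1 it is diagonal.
    """
    if name not in KINETIC_NAMES:
        raise KeyError(f"unknown parameter {name!r}")
    regimen = regimen if regimen is not None else Regimen()
    for f in factors:
        if not 0.5 <= f <= 1.5:
            raise ValueError("factors must lie in [0.5, 1.5]")

    if baseline_records is None:
        baseline_records = _classify_cohort(cohort, regimen, duration_days,
                                            lambda p: p)
    base_group = {pid: _status_group(r.status)
                  for pid, r in baseline_records.items()}

    results = []
    for f in factors:
        if f == 1.0:
            recs = baseline_records
        else:
            def updates(p, f=f):
                val = getattr(p.kinetics, name) * f
                return p.with_updates(**{name: val})
            recs = _classify_cohort(cohort, regimen, duration_days, updates)
        mat = pd.DataFrame(0, index=list(STATUS_GROUPS),
                           columns=list(STATUS_GROUPS))
        statuses = []
        for pid, rec in recs.items():
            if pid not in base_group:
                continue
            mat.loc[base_group[pid], _status_group(rec.status)] += 1
            statuses.append(rec.status)
        orr = float(np.mean([s in ("CR", "PR") for s in statuses]))
        results.append(PerturbationResult(
            parameter=name, factor=float(f), orr=orr, transition=mat,
            records=list(recs.values())))
    return results


#: fixed parameters perturbed by default: the mediators named in the
#: sensitivity discussion (CCL2 axis, dead-cell clearance, self-antigen,
#: suppressive mediators, activation/exhaustion machinery)
DEFAULT_PERTURBED = [
    "EC50_CCL2", "k_deg_CCL2", "k_clear_dead", "self_ag_scale",
    "k_IL10_M2", "k_TGFb_M2", "k_ArgI_MDSC", "k_NO_MDSC",
    "k_kill", "k_exhaust_PD1", "k_act", "k_apc_mat", "k_rec_APC",
    "k_pol_M2toM1", "q_infil", "k_death_Treg", "Kd_pMHC", "k_K_growth",
]

DEFAULT_FACTORS = (0.5, 0.75, 1.0, 1.25, 1.5)


def perturbation_frame(results: list) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"parameter": r.parameter, "factor": r.factor, "orr": r.orr}
        for b in STATUS_GROUPS:
            for a in STATUS_GROUPS:
                row[f"n_{b.replace('/', '')}_to_{a.replace('/', '')}"] = (
                    int(r.transition.loc[b, a]))
        rows.append(row)
    return pd.DataFrame(rows)
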