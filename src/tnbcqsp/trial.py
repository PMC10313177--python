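"""Virtual clinical trial: treatment simulation and RECIST v1.1 scoring.

Pembrolizumab is given as repeated intravenous boluses (default 200 mg every
3 weeks); lesion diameters are assessed every 9 weeks and the per-patient
best overall response is categorized by RECIST v1.1: complete response (CR)
when all target lesions fall below the disappearance threshold, partial
response (PR) at a >= 30% drop of the diameter sum from baseline,
progressive disease (PD) at a >= 20% and >= 5 mm rise from the nadir, and
stable disease (SD) otherwise when maintained for a minimum duration
(default 24 weeks from treatment start).  No response confirmation scan is
required.  Only target lesions present at baseline are evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MET_SITES, Cohort, VirtualPatient
from .mechanisms import tumor_diameter
from .pkpd import Regimen, administer_dose
from .simulate import SolverError, integrate
from .state import ModelState

logger = logging.getLogger(__name__)

ASSESSMENT_INTERVAL_DAYS = 63.0      # 9 weeks
SD_MIN_DAYS = 168.0                  # 24 weeks
CR_THRESHOLD_MM = 2.0                # lesion "disappearance"
PR_FRACTION = 0.70                   # sum <= 70% of baseline
PD_FRACTION = 1.20                   # sum >= 120% of nadir ...
PD_ABS_MM = 5.0                      # ... and >= 5 mm above nadir
DEFAULT_DURATION_DAYS = 730.0


@dataclass
class LesionTrajectory:
    lesion_id: str
    compartment: str
    times: np.ndarray       # day, assessment grid starting at treatment start
    diameters_mm: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.diameters_mm = np.asarray(self.diameters_mm, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("assessment times must be strictly increasing")
        if np.any(self.diameters_mm < 0):
            raise ValueError("diameters must be >= 0")


@dataclass
class ResponseRecord:
    patient_id: int
    status: str                      # CR | PR | SD | PD
    time_to_response: float | None = None
    duration_of_response: float | None = None
    progressed_by_end: bool = False

    def __post_init__(self) -> None:
        if self.status in ("CR", "PR"):
            if self.time_to_response is None:
                raise ValueError("CR/PR requires a time to response")
        elif self.time_to_response is not None:
            raise ValueError("TTR only defined for CR/PR")

    @property
    def responder(self) -> bool:
        """Responder in the biomarker sense: CR, PR or SD."""
        return self.status in ("CR", "PR", "SD")


@dataclass
class TreatmentResult:
    patient: VirtualPatient
    lesions: list                    # LesionTrajectory per target lesion
    state_times: np.ndarray          # daily grid
    states: np.ndarray               # (T, N_STATE)
    evaluable: bool = True


def simulate_treatment(vp: VirtualPatient, regimen: Regimen,
                       duration_days: float = DEFAULT_DURATION_DAYS,
                       assessment_interval: float = ASSESSMENT_INTERVAL_DAYS,
                       ) -> TreatmentResult:
    """Integrate the treated model from the patient's baseline state.

    Doses are applied as boluses at the regimen times; the full state is
    recorded on a 1-day grid and lesion diameters on the assessment grid.
    Target lesions are the metastatic lesions established at baseline (plus
    the primary tumor when intact).
    """
    if duration_days < assessment_interval:
        raise ValueError("duration must cover at least one assessment")
    patient = vp.parameters
    dose_times = regimen.dose_times(duration_days)
    breakpoints = np.unique(np.concatenate([[0.0], dose_times,
                                            [duration_days]]))
    state = vp.baseline_state.copy()
    times = [0.0]
    states = [state.vec.copy()]
    dose_set = set(np.round(dose_times, 9))
    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        if round(t0, 9) in dose_set:
            state = administer_dose(state, regimen.dose_mg, patient.pk)
        grid = np.arange(np.floor(t0) + 1, t1 + 0.5)
        grid = grid[(grid > t0) & (grid < t1)]
        t_eval = np.unique(np.concatenate([[t0], grid, [t1]]))
        traj = integrate(patient, state.vec, t0, t1, t_eval=t_eval)
        state = traj.final()
        times.extend(traj.times[1:].tolist())
        states.extend(list(traj.states[1:]))
    state_times = np.asarray(times)
    state_arr = np.asarray(states)

    assess = np.arange(0.0, duration_days + 0.5, assessment_interval)
    idx = np.searchsorted(state_times, assess)
    idx = np.clip(idx, 0, len(state_times) - 1)
    v_cell = patient.kinetics.v_cell_ml
    lesions = []
    targets = [(s, j) for s, j in MET_SITES.items()
               if s in vp.baseline_diameters]
    if patient.primary_tumor_intact:
        targets.insert(0, ("primary", 0))
    for site, j in targets:
        diam = np.array([tumor_diameter(ModelState(state_arr[i]).cancer_total(j),
                                        v_cell) * 10.0 for i in idx])
        lesions.append(LesionTrajectory(
            lesion_id=site, compartment=f"tumor_{site}",
            times=assess, diameters_mm=diam))
    return TreatmentResult(patient=vp, lesions=lesions,
                           state_times=state_times, states=state_arr)


def sum_of_diameters(lesions: list, t: float,
                     cr_threshold_mm: float = CR_THRESHOLD_MM) -> float:
    """Sum of target-lesion diameters (mm) at an assessment time.

    Lesions below the disappearance threshold contribute zero.
    """
    total = 0.0
    for les in lesions:
        i = np.flatnonzero(np.isclose(les.times, t))
        if len(i) == 0:
            raise ValueError(f"{t} is not on the assessment grid")
        d = les.diameters_mm[i[0]]
        total += d if d >= cr_threshold_mm else 0.0
    return total


def classify_recist(times: np.ndarray, sums_mm: np.ndarray,
                    patient_id: int = 0,
                    sd_min_days: float = SD_MIN_DAYS) -> ResponseRecord:
    """Best overall response from the diameter-sum series.

    ``times[0]`` must be the treatment start and ``sums_mm[0]`` the baseline
    (pre-treatment) sum.  A sum of zero means every lesion is below the
    disappearance threshold (CR).  PD is judged against the nadir (smallest
    sum observed so far, baseline included); SD requires a non-PD assessment
    at or after ``sd_min_days`` with no earlier PD.
    """
    times = np.asarray(times, dtype=float)
    sums = np.asarray(sums_mm, dtype=float)
    if len(times) == 0 or len(sums) != len(times):
        raise ValueError("empty or mismatched response series")
    if len(times) < 2:
        raise ValueError("need at least one post-baseline assessment")
    baseline = sums[0]
    nadir = baseline
    categories: list[tuple[float, str]] = []
    for t, s in zip(times[1:], sums[1:]):
        if s >= PD_FRACTION * nadir and s - nadir >= PD_ABS_MM:
            cat = "PD"
        elif s == 0.0:
            cat = "CR"
        elif s <= PR_FRACTION * baseline:
            cat = "PR"
        else:
            cat = "NN"  # non-CR/non-PR, SD candidate
        categories.append((float(t), cat))
        nadir = min(nadir, s)

    pd_times = [t for t, c in categories if c == "PD"]
    first_pd = pd_times[0] if pd_times else None
    pre_pd = [(t, c) for t, c in categories
              if first_pd is None or t < first_pd]

    status = None
    ttr = None
    for want in ("CR", "PR"):
        hits = [t for t, c in pre_pd if c == want]
        if hits:
            status = want
            ttr = hits[0]
            break
    if status is None:
        sd_ok = [t for t, c in pre_pd if t >= sd_min_days]
        status = "SD" if sd_ok else "PD"

    dor = None
    if status in ("CR", "PR"):
        end = first_pd if first_pd is not None else float(times[-1])
        dor = end - ttr
    return ResponseRecord(patient_id=patient_id, status=status,
                          time_to_response=ttr, duration_of_response=dor,
                          progressed_by_end=first_pd is not None)


@dataclass
class TrialResult:
    records: list                    # ResponseRecord, evaluable patients
    results: list                    # TreatmentResult, evaluable patients
    n_nonevaluable: int = 0
    summary: dict = field(default_factory=dict)

    def record_for(self, patient_id: int) -> ResponseRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)


def run_trial(cohort: Cohort, regimen: Regimen | None = None,
              duration_days: float = DEFAULT_DURATION_DAYS,
              n_boot: int = 1000, seed: int = 0) -> TrialResult:
    """Simulate treatment for every accepted patient and score responses."""
    regimen = regimen if regimen is not None else Regimen()
    records, results = [], []
    n_bad = 0
    for vp in cohort.patients:
        try:
            res = simulate_treatment(vp, regimen, duration_days)
        except SolverError as err:
            logger.warning("patient %d nonevaluable (%s)", vp.patient_id, err)
            n_bad += 1
            continue
        assess = res.lesions[0].times
        sums = np.array([sum_of_diameters(res.lesions, t) for t in assess])
        records.append(classify_recist(assess, sums,
                                       patient_id=vp.patient_id))
        results.append(res)
    lung = [cohort.patients[i].has_lung_met
            for i in range(len(cohort.patients))]
    summary = trial_summary(records, n_boot=n_boot, seed=seed,
                            lung_met_flags=lung)
    return TrialResult(records=records, results=results,
                       n_nonevaluable=n_bad, summary=summary)


def _percentile_ci(samples: np.ndarray) -> tuple[float, float]:
    return (float(np.percentile(samples, 2.5)),
            float(np.percentile(samples, 97.5)))


def trial_summary(records: list, n_boot: int = 1000, seed: int = 0,
                  lung_met_flags: list | None = None) -> dict:
    """Trial-level endpoints with percentile-bootstrap 95% CIs.

    ORR is the CR/PR fraction over all evaluable patients; median duration of
    response and time to response are computed over CR/PR patients only (a
    patient who never progresses contributes response-to-end-of-simulation).
    """
    if not records:
        raise ValueError("no response records")
    rng = np.random.default_rng(seed)
    is_resp = np.array([r.status in ("CR", "PR") for r in records])
    orr = float(is_resp.mean())
    dor = np.array([r.duration_of_response for r in records
                    if r.status in ("CR", "PR")], dtype=float)
    ttr = np.array([r.time_to_response for r in records
                    if r.status in ("CR", "PR")], dtype=float)

    n = len(records)
    boot_orr = np.empty(n_boot)
    boot_dor = np.full(n_boot, np.nan)
    boot_ttr = np.full(n_boot, np.nan)
    for b in range(n_boot):
        pick = rng.integers(0, n, n)
        sel = is_resp[pick]
        boot_orr[b] = sel.mean()
        if sel.any():
            chosen = [records[i] for i in pick if records[i].status in ("CR", "PR")]
            boot_dor[b] = np.median([r.duration_of_response for r in chosen])
            boot_ttr[b] = np.median([r.time_to_response for r in chosen])

    out = {
        "n": n,
        "orr": orr,
        "orr_ci": _percentile_ci(boot_orr),
        "n_cr_pr": int(is_resp.sum()),
        "responder_fraction_crprsd": float(np.mean([r.responder
                                                    for r in records])),
    }
    if len(dor):
        ok = ~np.isnan(boot_dor)
        out["median_dor_days"] = float(np.median(dor))
        out["median_ttr_days"] = float(np.median(ttr))
        out["median_dor_ci"] = _percentile_ci(boot_dor[ok])
        out["median_ttr_ci"] = _percentile_ci(boot_ttr[ok])
    else:
        out["median_dor_days"] = None
        out["median_ttr_days"] = None
    if lung_met_flags is not None:
        out["lung_met_fraction"] = float(np.mean(lung_met_flags))
    return out


# ---------------------------------------------------------------------------
# tabular exports

def waterfall_table(trial: TrialResult) -> pd.DataFrame:
    """Best percent change in diameter sum per patient, sorted descending."""
    rows = []
    for rec, res in zip(trial.records, trial.results):
        assess = res.lesions[0].times
        sums = np.array([sum_of_diameters(res.lesions, t) for t in assess])
        base = sums[0]
        pct = 100.0 * (sums[1:] - base) / base
        row = {"patient_id": rec.patient_id, "status": rec.status,
               "best_pct_change_sum": float(pct.min()),
               "final_pct_change_sum": float(pct[-1])}
        for les in res.lesions:
            b = les.diameters_mm[0]
            row[f"best_pct_change_{les.lesion_id}"] = (
                float(100.0 * (les.diameters_mm[1:] - b).min() / b)
                if b > 0 else np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("best_pct_change_sum",
                          ascending=False).reset_index(drop=True)


def spider_table(trial: TrialResult) -> pd.DataFrame:
    """Long-format percent change in the diameter sum over time."""
    rows = []
    for rec, res in zip(trial.records, trial.results):
        assess = res.lesions[0].times
        sums = np.array([sum_of_diameters(res.lesions, t) for t in assess])
        base = sums[0]
        for t, s in zip(assess, sums):
            rows.append({"patient_id": rec.patient_id, "day": float(t),
                         "pct_change": float(100.0 * (s - base) / base)})
    return pd.DataFrame(rows)


def response_table(trial: TrialResult) -> pd.DataFrame:
    return pd.DataFrame([{
        "patient_id": r.patient_id, "status": r.status,
        "responder": r.responder,
        "time_to_response_day": r.time_to_response,
        "duration_of_response_day": r.duration_of_response,
        "progressed": r.progressed_by_end,
    } for r in trial.records])
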