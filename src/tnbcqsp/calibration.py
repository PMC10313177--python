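"""Calibration of metastatic immune content and trial-level handles.

Two fitting problems:

* ``fit_metastasis_params`` adjusts metastasis-compartment immune parameters
  (recruitment rates of macrophages/MDSCs/APCs, M1->M2 polarization) so that
  the simulated relative abundance of immune cell types in a metastatic
  lesion, with respect to the matched primary tumor of the same reference
  patient, matches a target table of ratios such as those derived externally
  by transcriptome deconvolution.  Cell fractions are counts divided by all
  cells in the lesion (cancer plus immune); lesions are compared at a matched
  diameter (default 1 cm) rather than a matched time.  The loss is the mean
  squared log-ratio error, minimized by bounded Nelder-Mead in log-parameter
  space.

* ``calibrate_trial_handles`` tunes the two population-level handles of the
  virtual trial: the median metastatic seeding time (against the lung-
  metastasis prevalence among accepted patients, target 65%) and the median
  of the target-diameter distribution (against the cohort median baseline
  lesion diameter, target 1.65 cm), each by one-dimensional search on
  repeated scaled-down cohort generations.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cohort import Cohort, PopulationSpec, generate_cohort
from .mechanisms import tumor_diameter
from .params import PatientParameters
from .simulate import initial_state, integrate, seed_tumor
from .state import TUMOR_COMPARTMENTS, ModelState

logger = logging.getLogger(__name__)

CELL_TYPES = ("tcyt", "th", "treg", "m1", "m2", "mdsc", "apc")

#: site -> tumor compartment indices carrying that site's overrides
SITE_TUMORS = {"lung": (1, 2), "other": (3,)}

FITTABLE = ("k_rec_M1", "k_rec_MDSC", "k_rec_APC", "k_pol_M1toM2")


@dataclass
class AbundanceTargets:
    """Target relative abundances (metastasis : matched primary).

    Table columns: cell_type, site (lung | other), estimator, ratio,
    tolerance (half-width of the acceptable band on the log-ratio, optional).
    MDSC rows are monocyte-proxied estimates by convention of the upstream
    deconvolution tools.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cell_type", "site", "ratio"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"targets table needs columns {sorted(required)}")
        if (self.table["ratio"] <= 0).any():
            raise ValueError("target ratios must be > 0")

    @classmethod
    def from_csv(cls, path) -> "AbundanceTargets":
        return cls(pd.read_csv(path, comment="#"))

    @classmethod
    def synthetic_default(cls) -> "AbundanceTargets":
        """Synthetic stand-in table encoding the qualitative pattern of
        reduced lymphocyte content in metastases, with wide tolerances."""
        path = Path(__file__).parent / "data" / "abundance_targets_synthetic.csv"
        return cls.from_csv(path)


def _cell_counts(state: ModelState, j: int) -> dict:
    comp = TUMOR_COMPARTMENTS[j]
    g = lambda s: state.get(comp, s)  # noqa: E731
    tcyt = float(np.clip(state.tcyt_active(j), 0.0, None).sum())
    return {
        "tcyt": tcyt + g("tcyt_exhausted"),
        "th": g("th"),
        "treg": g("treg"),
        "m1": g("m1"),
        "m2": g("m2"),
        "mdsc": g("mdsc"),
        "apc": g("apc_immature") + g("apc_mature"),
        "cancer": state.cancer_total(j),
    }


def cell_fractions(state: ModelState, j: int) -> dict:
    """Cell-type fractions of all cells (cancer + immune) in tumor ``j``."""
    counts = _cell_counts(state, j)
    total = sum(counts.values())
    if total <= 0:
        return {t: np.nan for t in CELL_TYPES}
    return {t: counts[t] / total for t in CELL_TYPES}


def simulated_relative_abundance(met_state: ModelState, met_j: int,
                                 primary_state: ModelState,
                                 primary_j: int = 0) -> dict:
    """Per-cell-type ratio of metastatic to matched-primary cell fractions.

    Ratios with a zero primary fraction are absent from the result.
    """
    met = cell_fractions(met_state, met_j)
    pri = cell_fractions(primary_state, primary_j)
    out = {}
    for t in CELL_TYPES:
        if pri[t] and np.isfinite(pri[t]) and pri[t] > 0:
            out[t] = met[t] / pri[t]
    return out


def abundance_loss(sim_ratios: dict, targets: AbundanceTargets,
                   site: str | None = None) -> float:
    """Mean squared log-ratio error between simulated and target ratios.

    ``sim_ratios`` maps cell_type -> ratio (optionally nested by site:
    {site: {cell_type: ratio}}).  Zero iff every matched entry agrees.
    """
    table = targets.table
    if site is not None:
        table = table[table["site"] == site]
    errs = []
    for _, row in table.iterrows():
        pool = sim_ratios.get(row["site"], sim_ratios) if site is None \
            else sim_ratios
        if isinstance(pool, dict) and row["cell_type"] in pool:
            sim = pool[row["cell_type"]]
            if np.isfinite(sim) and sim > 0:
                errs.append(np.log(sim / row["ratio"]) ** 2)
    if not errs:
        raise ValueError("no overlapping cell types between simulation and "
                         "targets")
    return float(np.mean(errs))


def reference_states(patient: PatientParameters,
                     met_j: int = 1,
                     match_diameter_cm: float = 1.0,
                     horizon_days: float = 2000.0
                     ) -> tuple[ModelState, ModelState]:
    """Grow the primary tumor and one metastasis of a reference patient and
    snapshot each lesion when it reaches the matching diameter."""
    patient = copy.deepcopy(patient)
    patient.primary_tumor_intact = True
    state = initial_state(patient)
    seed_tumor(state, patient, 0)
    seed_tumor(state, patient, met_j)
    t_eval = np.arange(0.0, horizon_days + 0.5, 5.0)
    traj = integrate(patient, state.vec, 0.0, horizon_days, t_eval=t_eval)
    v_cell = patient.kinetics.v_cell_ml
    snap = {}
    for j in (0, met_j):
        for i, t in enumerate(traj.times):
            d = tumor_diameter(ModelState(traj.states[i]).cancer_total(j),
                               v_cell)
            if d >= match_diameter_cm:
                snap[j] = ModelState(traj.states[i].copy())
                break
        if j not in snap:
            raise RuntimeError(
                f"lesion {j} never reached {match_diameter_cm} cm within "
                f"{horizon_days} days; calibration reference unusable")
    return snap[0], snap[met_j]


@dataclass
class FitResult:
    fitted: dict                     # name -> fitted met-compartment value
    loss_initial: float
    loss_final: float
    trace: list = field(default_factory=list)
    converged: bool = True
    message: str = ""


def fit_metastasis_params(patient: PatientParameters, free_names: list,
                          targets: AbundanceTargets, site: str = "lung",
                          bounds_log10: float = 1.0, budget: int = 200,
                          match_diameter_cm: float = 1.0) -> FitResult:
    """Fit metastasis-site immune parameters to the abundance targets.

    ``free_names`` are per-tumor-capable parameters (see ``FITTABLE``); each
    is varied multiplicatively within ``10**±bounds_log10`` of its current
    value for the tumors of ``site`` only, on a single reference patient.
    Bounded Nelder-Mead in log10 space; the best-seen point is returned even
    if the evaluation budget is exhausted first.
    """
    for n in free_names:
        if n not in FITTABLE:
            raise KeyError(f"{n} is not a fittable metastasis parameter")
    if not free_names:
        return FitResult(fitted={}, loss_initial=np.nan, loss_final=np.nan,
                         message="no free parameters; input returned")
    met_j = SITE_TUMORS[site][0]
    def _base(n):
        if n in patient.site_overrides:
            return float(np.mean(patient.site_overrides[n]))
        return float(getattr(patient.kinetics, n))

    base_vals = np.array([_base(n) for n in free_names])
    trace = []

    def run(log_mult: np.ndarray) -> float:
        trial_patient = copy.deepcopy(patient)
        for name, b, lm in zip(free_names, base_vals, log_mult):
            arr = np.full(len(TUMOR_COMPARTMENTS),
                          patient.site_overrides.get(
                              name, getattr(patient.kinetics, name)),
                          dtype=float)
            for j in SITE_TUMORS[site]:
                arr[j] = b * 10.0 ** lm
            trial_patient.site_overrides[name] = arr
        try:
            pri, met = reference_states(trial_patient, met_j,
                                        match_diameter_cm)
        except RuntimeError:
            return 1e6
        ratios = simulated_relative_abundance(met, met_j, pri)
        loss = abundance_loss(ratios, targets, site=site)
        trace.append({"log10_multipliers": log_mult.tolist(), "loss": loss})
        return loss

    x0 = np.zeros(len(free_names))
    loss0 = run(x0)
    res = minimize(run, x0, method="Nelder-Mead",
                   bounds=[(-bounds_log10, bounds_log10)] * len(free_names),
                   options={"maxfev": budget, "xatol": 1e-3, "fatol": 1e-4})
    best = min(trace, key=lambda t: t["loss"])
    fitted = {n: float(b * 10.0 ** lm)
              for n, b, lm in zip(free_names, base_vals,
                                  best["log10_multipliers"])}
    if best["loss"] > loss0:
        logger.warning("calibration budget exhausted without improvement")
    return FitResult(fitted=fitted, loss_initial=loss0,
                     loss_final=best["loss"], trace=trace,
                     converged=bool(res.success),
                     message=str(res.message))


# ---------------------------------------------------------------------------
# trial-level handles

@dataclass
class HandleReport:
    handle: str
    target: float
    achieved: float
    value: float                     # calibrated handle value (median)
    n_evaluations: int
    within_tolerance: bool


def _measure(spec: PopulationSpec) -> Cohort:
    return generate_cohort(spec)


def calibrate_trial_handles(spec: PopulationSpec,
                            lung_prevalence_target: float = 0.65,
                            median_diameter_target_cm: float = 1.65,
                            prevalence_tol: float = 0.05,
                            diameter_tol_cm: float = 0.1,
                            n_cohort: int = 200,
                            max_iter: int = 8,
                            calibration_seeds: int = 2) -> tuple[PopulationSpec, list]:
    """Calibrate seeding-time and diameter medians on scaled-down cohorts.

    Returns the updated :class:`PopulationSpec` and a list of
    :class:`HandleReport`.  The diameter handle passes through the acceptance
    filter almost unchanged, so a proportional update converges in a couple
    of iterations; the seeding-time handle is solved by bisection on the log
    median (prevalence decreases monotonically as lung lesions seed later).
    Each seeding-handle evaluation averages the prevalence over
    ``calibration_seeds`` cohort replicates, and the bisection stops only
    well inside ``prevalence_tol``, so a freshly seeded cohort still lands
    within the tolerance.  A warning is emitted for any handle that misses
    its tolerance.
    """
    spec = copy.deepcopy(spec)
    spec.n_patients = n_cohort
    reports = []

    # --- handle 1: median of the target-diameter distribution -------------
    n_eval = 0
    median = spec.get_varied("target_diameter_cm").args[0]
    achieved = np.nan
    for _ in range(max_iter):
        spec.set_median("target_diameter_cm", median)
        achieved = _measure(spec).median_baseline_diameter
        n_eval += 1
        if abs(achieved - median_diameter_target_cm) <= diameter_tol_cm:
            break
        median *= median_diameter_target_cm / achieved
    ok = abs(achieved - median_diameter_target_cm) <= diameter_tol_cm
    if not ok:
        logger.warning("diameter handle missed tolerance: achieved %.3f cm",
                       achieved)
    reports.append(HandleReport("target_diameter_cm",
                                median_diameter_target_cm, achieved,
                                median, n_eval, ok))

    # --- handle 2: median lung seeding time (bisection on log median) -----
    n_eval = 0
    lo, hi = np.log(30.0), np.log(3000.0)
    achieved = np.nan
    value = spec.get_varied("seed_time_lung1").args[0]

    inner_tol = 0.4 * prevalence_tol
    base_seed = spec.seed

    def prevalence_at(log_m):
        spec.set_median("seed_time_lung", float(np.exp(log_m)))
        prevs = []
        for r in range(calibration_seeds):
            spec.seed = base_seed + r
            prevs.append(_measure(spec).lung_met_fraction)
        spec.seed = base_seed
        return float(np.mean(prevs))

    p_lo, p_hi = prevalence_at(lo), prevalence_at(hi)
    n_eval += 2
    if p_lo < lung_prevalence_target - prevalence_tol:
        achieved, value = p_lo, float(np.exp(lo))
    elif p_hi > lung_prevalence_target + prevalence_tol:
        achieved, value = p_hi, float(np.exp(hi))
    else:
        mid = np.log(value)
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            p_mid = prevalence_at(mid)
            n_eval += 1
            achieved, value = p_mid, float(np.exp(mid))
            if abs(p_mid - lung_prevalence_target) <= inner_tol:
                break
            if p_mid > lung_prevalence_target:
                lo = mid
            else:
                hi = mid
    spec.set_median("seed_time_lung", value)
    ok = abs(achieved - lung_prevalence_target) <= prevalence_tol
    if not ok:
        logger.warning("seeding handle missed tolerance: achieved %.3f "
                       "lung prevalence", achieved)
    reports.append(HandleReport("seed_time_lung_median_day",
                                lung_prevalence_target, achieved, value,
                                n_eval, ok))
    return spec, reports
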