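"""Virtual-patient generation.

Patients are produced by Latin hypercube sampling of the varied parameters
(interindividual variability plus per-tumor, i.e. intraindividual,
heterogeneity), stochastic seeding of up to two lung and one "other"
metastatic lesion at log-normally distributed times, an untreated burn-in
until a metastatic lesion reaches the patient's target diameter, and an
acceptance filter that discards patients who never attain the target within
the burn-in horizon.  The baseline state at the moment the target is reached
becomes the initial condition for treatment simulation.

The primary tumor is resected by default (its cancer-cell count is zero);
``primary_tumor_intact`` seeds it at time zero instead.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .mechanisms import tumor_diameter
from .params import (KINETIC_NAMES, KineticParameters, PatientParameters,
                     PkParameters)
from .simulate import (SolverError, initial_state, integrate, seed_tumor,
                       target_diameter_event)
from .state import N_CLONES, N_EPITOPES, N_TUMORS, ModelState

logger = logging.getLogger(__name__)

#: metastatic tumor slots and their compartment indices
MET_SITES = {"lung1": 1, "lung2": 2, "other": 3}

#: kinetic parameters that may vary tumor-to-tumor within a patient
PER_TUMOR_KINETICS = ("pdl1_base", "k_rec_M1", "k_rec_MDSC", "k_rec_APC",
                      "k_pol_M1toM2")


@dataclass
class VariedParam:
    """One sampled dimension of the virtual population.

    ``dist`` is one of lognormal (args: median, sigma_log), uniform
    (args: lo, hi) or normal (args: mu, sigma).  ``scope`` is "patient" (one
    draw shared by all tumors) or "tumor" (an independent draw per tumor, for
    the kinetic parameters in :data:`PER_TUMOR_KINETICS`).
    """

    name: str
    dist: str = "lognormal"
    args: tuple = (1.0, 0.5)
    scope: str = "patient"

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.dist == "lognormal":
            median, sigma = self.args
            return median * np.exp(stats.norm.ppf(u) * sigma)
        if self.dist == "uniform":
            lo, hi = self.args
            return lo + (hi - lo) * u
        if self.dist == "normal":
            mu, sigma = self.args
            return stats.norm.ppf(u, loc=mu, scale=sigma)
        raise ValueError(f"unknown distribution family {self.dist!r}")


def default_varied(seed_median_lung: float = 300.0,
                   seed_median_other: float = 180.0,
                   diameter_median_cm: float = 1.65,
                   kinetics: KineticParameters | None = None) -> list[VariedParam]:
    """Default varied-parameter list: the high-impact parameters named in the
    model description (seeding times, target diameter, growth and killing
    rates, PD-L1 level, clonotype number, exhaustion, recruitment, peptide-MHC
    affinity), log-normal with medians at the kinetic defaults."""
    kin = kinetics if kinetics is not None else KineticParameters()
    g = lambda name: getattr(kin, name)  # noqa: E731
    v = [
        VariedParam("seed_time_lung1", "lognormal", (seed_median_lung, 0.8)),
        VariedParam("seed_time_lung2", "lognormal", (seed_median_lung, 0.8)),
        VariedParam("seed_time_other", "lognormal", (seed_median_other, 0.8)),
        VariedParam("target_diameter_cm", "lognormal", (diameter_median_cm, 0.25)),
        VariedParam("growth_scale", "lognormal", (1.0, 0.35)),
        VariedParam("k_kill", "lognormal", (g("k_kill"), 0.6)),
        VariedParam("k_act", "lognormal", (g("k_act"), 0.8)),
        VariedParam("n_clonotypes", "lognormal", (g("n_clonotypes"), 0.8)),
        VariedParam("k_exhaust_PD1", "lognormal", (g("k_exhaust_PD1"), 0.6)),
        VariedParam("Kd_pMHC", "lognormal", (g("Kd_pMHC"), 0.6)),
        VariedParam("q_infil", "lognormal", (g("q_infil"), 0.5)),
        VariedParam("k_td", "lognormal", (g("k_td"), 0.5)),
        VariedParam("k_ArgI_MDSC", "lognormal", (g("k_ArgI_MDSC"), 0.5)),
        VariedParam("pdl1_base", "lognormal", (g("pdl1_base"), 0.8), scope="tumor"),
        VariedParam("k_rec_M1", "lognormal", (g("k_rec_M1"), 0.5), scope="tumor"),
        VariedParam("k_rec_MDSC", "lognormal", (g("k_rec_MDSC"), 0.5), scope="tumor"),
        VariedParam("k_rec_APC", "lognormal", (g("k_rec_APC"), 0.5), scope="tumor"),
    ]
    return v


@dataclass
class PopulationSpec:
    """Configuration of a virtual population."""

    n_patients: int = 100
    varied: list = field(default_factory=default_varied)
    kinetics: KineticParameters = field(default_factory=KineticParameters)
    pk: PkParameters = field(default_factory=PkParameters)
    seed: int = 0
    max_burnin_days: float = 1500.0
    primary_tumor_intact: bool = False
    n_seed_cells: float = 100.0
    p_seed_lung: float = 1.0
    p_seed_other: float = 1.0
    p_epitope: float = 0.5
    clone_growth_sigma: float = 0.3
    dirichlet_alpha: float = 1.0

    def get_varied(self, name: str) -> VariedParam:
        for v in self.varied:
            if v.name == name:
                return v
        raise KeyError(name)

    def set_median(self, name_prefix: str, median: float) -> None:
        """Rescale the median of every varied entry whose name starts with
        ``name_prefix`` (calibration handle for seeding times / diameter)."""
        found = False
        for v in self.varied:
            if v.name.startswith(name_prefix):
                if v.dist != "lognormal":
                    raise ValueError("median handle requires lognormal")
                v.args = (median, v.args[1])
                found = True
        if not found:
            raise KeyError(name_prefix)


@dataclass
class VirtualPatient:
    patient_id: int
    parameters: PatientParameters
    seeding_times: dict
    accepted: bool = False
    failed: bool = False
    baseline_state: ModelState | None = None
    baseline_time: float | None = None
    baseline_diameters: dict = field(default_factory=dict)

    @property
    def has_lung_met(self) -> bool:
        return any(s in self.baseline_diameters and self.baseline_diameters[s] > 0
                   for s in ("lung1", "lung2"))

    @property
    def max_baseline_diameter(self) -> float:
        vals = [d for d in self.baseline_diameters.values() if d > 0]
        return max(vals) if vals else 0.0


def sample_parameters(spec: PopulationSpec) -> list[PatientParameters]:
    """Latin hypercube draw of the varied parameters for ``spec.n_patients``.

    Each scalar dimension is stratified into one stratum per patient;
    per-tumor-scope parameters occupy one dimension per metastatic-capable
    tumor so that every tumor's draw is independently stratified.  Clone
    composition (symmetric Dirichlet), per-clone growth multipliers and the
    binary clone-epitope expression matrix are drawn from the companion
    generator, all deterministically under ``spec.seed``.
    """
    if spec.n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    dims: list[tuple[VariedParam, int | None]] = []
    for v in spec.varied:
        known = (v.name in KINETIC_NAMES
                 or v.name in ("target_diameter_cm", "growth_scale")
                 or v.name.startswith("seed_time_"))
        if not known:
            raise KeyError(f"varied parameter {v.name!r} does not resolve to "
                           "a model parameter")
        if v.scope == "tumor":
            if v.name not in PER_TUMOR_KINETICS:
                raise ValueError(f"{v.name} cannot vary per tumor")
            for j in range(N_TUMORS):
                dims.append((v, j))
        else:
            dims.append((v, None))

    sampler = qmc.LatinHypercube(d=len(dims), seed=spec.seed)
    U = sampler.random(n=spec.n_patients)
    rng = np.random.default_rng(spec.seed + 1)

    patients = []
    for i in range(spec.n_patients):
        kin_kwargs: dict = {}
        site_overrides: dict = {}
        seeding: dict = {}
        target_d = 1.65
        growth_scale = 1.0
        for d, (v, j) in enumerate(dims):
            val = float(v.ppf(np.array([U[i, d]]))[0])
            if v.scope == "tumor":
                site_overrides.setdefault(
                    v.name, np.full(N_TUMORS, getattr(spec.kinetics, v.name)))
                site_overrides[v.name][j] = val
            elif v.name.startswith("seed_time_"):
                seeding[v.name.removeprefix("seed_time_")] = val
            elif v.name == "target_diameter_cm":
                target_d = val
            elif v.name == "growth_scale":
                growth_scale = val
            else:
                kin_kwargs[v.name] = val

        # stochastic lesion presence and per-tumor clonal structure
        for site, p_site in (("lung1", spec.p_seed_lung),
                             ("lung2", spec.p_seed_lung),
                             ("other", spec.p_seed_other)):
            if site in seeding and rng.random() >= p_site:
                del seeding[site]
        kin = dataclasses.replace(spec.kinetics, **kin_kwargs)
        clone_growth = (kin.k_growth_base * growth_scale
                       * rng.lognormal(0.0, spec.clone_growth_sigma,
                                       (N_TUMORS, N_CLONES)))
        fractions = rng.dirichlet(np.full(N_CLONES, spec.dirichlet_alpha),
                                  N_TUMORS)
        expr = (rng.random((N_TUMORS, N_CLONES, N_EPITOPES))
                < spec.p_epitope).astype(float)

        patients.append(PatientParameters(
            kinetics=kin, pk=dataclasses.replace(spec.pk),
            clone_growth=clone_growth, clone_fractions=fractions,
            epitope_expr=expr, site_overrides=site_overrides,
            seeding_times=seeding, target_diameter_cm=target_d,
            n_seed_cells=spec.n_seed_cells,
            primary_tumor_intact=spec.primary_tumor_intact, patient_id=i))
    return patients


def seed_metastases(patient: PatientParameters) -> dict:
    """Seeding schedule of one patient, re-based so the earliest event is day
    zero.  Returns {site: day}; the primary tumor (if intact) seeds at the
    start of the burn-in."""
    times = dict(patient.seeding_times)
    if not times and not patient.primary_tumor_intact:
        return {}
    offset = min(times.values()) if times else 0.0
    if patient.primary_tumor_intact:
        offset = min(offset, 0.0)
    return {s: t - offset for s, t in times.items()}


def burn_in(patient: PatientParameters,
            max_burnin_days: float = 1500.0) -> VirtualPatient:
    """Untreated growth from first seeding until the target diameter.

    The model is integrated from the earliest seeding event, introducing each
    lesion's inoculum at its seeding time; the burn-in stops when any
    metastatic lesion (any lesion at all, if the primary is intact) reaches
    the patient's target diameter.  Patients that never reach it within
    ``max_burnin_days`` are rejected; solver failures are flagged separately.
    """
    vp = VirtualPatient(patient.patient_id, patient,
                        seed_metastases(patient))
    schedule = sorted(vp.seeding_times.items(), key=lambda kv: kv[1])
    if not schedule and not patient.primary_tumor_intact:
        return vp

    state = initial_state(patient)
    if patient.primary_tumor_intact:
        seed_tumor(state, patient, 0)
    event = target_diameter_event(
        patient, metastatic_only=not patient.primary_tumor_intact)
    t = 0.0
    reached = False
    try:
        for site, t_seed in schedule:
            if t_seed >= max_burnin_days:
                break  # this lesion never seeds within the burn-in horizon
            if t_seed > t:
                traj = integrate(patient, state.vec, t, t_seed, events=event)
                state = traj.final()
                if traj.stop_time is not None:
                    t = traj.stop_time
                    reached = True
                    break
                t = t_seed
            seed_tumor(state, patient, MET_SITES[site])
        if not reached and t < max_burnin_days:
            traj = integrate(patient, state.vec, t, max_burnin_days,
                             events=event)
            state = traj.final()
            reached = traj.stop_time is not None
            t = traj.stop_time if reached else max_burnin_days
    except SolverError as err:
        logger.warning("patient %d: solver failure during burn-in (%s)",
                       patient.patient_id, err)
        vp.failed = True
        return vp
    vp.baseline_time = t
    if reached:
        vp.accepted = True
        vp.baseline_state = state
        v_cell = patient.kinetics.v_cell_ml
        for site, j in MET_SITES.items():
            if site in vp.seeding_times and vp.seeding_times[site] <= t:
                vp.baseline_diameters[site] = tumor_diameter(
                    state.cancer_total(j), v_cell)
        if patient.primary_tumor_intact:
            vp.baseline_diameters["primary"] = tumor_diameter(
                state.cancer_total(0), v_cell)
    return vp


@dataclass
class Cohort:
    patients: list          # accepted VirtualPatient only
    audit: dict
    manifest: pd.DataFrame

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def lung_met_fraction(self) -> float:
        if not self.patients:
            return float("nan")
        return float(np.mean([p.has_lung_met for p in self.patients]))

    @property
    def median_baseline_diameter(self) -> float:
        return float(np.median([p.max_baseline_diameter
                                for p in self.patients]))


def generate_cohort(spec: PopulationSpec) -> Cohort:
    """Sample, seed, burn in and filter a cohort; accepted patients only."""
    if spec.n_patients < 1:
        raise ValueError("empty cohort requested (n_patients < 1)")
    params = sample_parameters(spec)
    rows = []
    accepted = []
    n_failed = 0
    for patient in params:
        vp = burn_in(patient, spec.max_burnin_days)
        if vp.failed:
            n_failed += 1
        elif vp.accepted:
            accepted.append(vp)
        rows.append({
            "patient_id": patient.patient_id,
            "accepted": vp.accepted, "failed": vp.failed,
            "baseline_time_day": vp.baseline_time,
            **{f"seed_time_{s}": vp.seeding_times.get(s, np.nan)
               for s in MET_SITES},
            **{f"baseline_diameter_{s}_cm": vp.baseline_diameters.get(s, np.nan)
               for s in MET_SITES},
        })
    if not accepted:
        raise RuntimeError(
            "no virtual patient reached the target diameter; rescale the "
            "seeding-time / growth-rate distributions or raise "
            "max_burnin_days")
    audit = {"seed": spec.seed, "n_sampled": spec.n_patients,
             "n_accepted": len(accepted), "n_failed": n_failed}
    logger.info("cohort: %d/%d accepted (%d solver failures)",
                len(accepted), spec.n_patients, n_failed)
    return Cohort(patients=accepted, audit=audit,
                  manifest=pd.DataFrame(rows))
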