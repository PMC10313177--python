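"""Small, fast test cohorts with planted biomarker structure.

``make_fixture_cohort`` builds a scaled-down population (small target
diameters, early seeding, short burn-in) that generates end-to-end in well
under a minute, and plants a known ground truth for the biomarker ranking
machinery: responder labels are a noisy threshold function of one designated
baseline candidate, so that candidate must rank first (statistically) in
:func:`tnbcqsp.biomarker.rank_candidates`.  The labels are synthetic by
construction; they are not produced by treatment simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biomarker import extract_candidates
from .cohort import Cohort, PopulationSpec, default_varied, generate_cohort
from .trial import ResponseRecord

PLANTED_CANDIDATE = "ln_density_apc"


@dataclass
class FixtureCohort:
    cohort: Cohort
    table: pd.DataFrame            # biomarker table with planted labels
    records: list                  # planted ResponseRecords
    planted_candidate: str = PLANTED_CANDIDATE


def fixture_population_spec(n: int = 50, seed: int = 0) -> PopulationSpec:
    """A fast population: ~0.7 cm lesions, early seeding, short burn-in."""
    if n < 1:
        raise ValueError("fixture cohort must have n >= 1")
    varied = default_varied(seed_median_lung=120.0, seed_median_other=80.0,
                            diameter_median_cm=0.7)
    return PopulationSpec(n_patients=n, varied=varied, seed=seed,
                          max_burnin_days=900.0)


def plant_labels(table: pd.DataFrame, candidate: str = PLANTED_CANDIDATE,
                 flip_probability: float = 0.1,
                 seed: int = 0) -> pd.Series:
    """Responder labels as a noisy above-median threshold on ``candidate``."""
    rng = np.random.default_rng(seed)
    vals = table[candidate]
    labels = vals > vals.median()
    flip = rng.random(len(labels)) < flip_probability
    return (labels ^ flip).astype(bool)


def make_fixture_cohort(n: int = 50, seed: int = 0,
                        candidate: str = PLANTED_CANDIDATE,
                        flip_probability: float = 0.1) -> FixtureCohort:
    """Generate the fixture cohort and its planted biomarker table."""
    spec = fixture_population_spec(n, seed)
    cohort = generate_cohort(spec)
    # provisional all-responder records so extraction has labels to join on
    provisional = [ResponseRecord(vp.patient_id, "SD")
                   for vp in cohort.patients]
    table = extract_candidates(cohort.patients, provisional)
    labels = plant_labels(table, candidate, flip_probability, seed)
    table["responder"] = labels
    records = [ResponseRecord(pid, "SD" if resp else "PD")
               for pid, resp in labels.items()]
    return FixtureCohort(cohort=cohort, table=table, records=records,
                         planted_candidate=candidate)


def synthetic_biomarker_table(n: int = 200, n_noise: int = 4,
                              flip_probability: float = 0.1,
                              seed: int = 0) -> tuple[pd.DataFrame, str]:
    """A pure-synthetic biomarker table (no ODE model involved).

    One informative candidate ``signal`` drives responder status through a
    noisy threshold; the remaining candidates are uninformative log-normal
    noise.  Used for ranking-recovery and brute-force-oracle checks.
    """
    rng = np.random.default_rng(seed)
    data = {"signal": rng.lognormal(0.0, 1.0, n)}
    for i in range(n_noise):
        data[f"noise_{i}"] = rng.lognormal(0.0, 1.0, n)
    df = pd.DataFrame(data)
    df.index.name = "patient_id"
    labels = df["signal"] > np.median(df["signal"])
    flip = rng.random(n) < flip_probability
    df["responder"] = (labels ^ flip).astype(bool)
    return df, "signal"
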