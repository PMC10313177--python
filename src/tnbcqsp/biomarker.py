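"""Biomarker discovery on baseline virtual-patient states.

Candidate biomarkers are baseline quantities: cell densities and cytokine
concentrations per compartment class, derived ratios (M2:M1,
suppressive:activating, Treg:Tcyt, T-cell subset fractions, fraction of
tumor-infiltrating lymphocytes, fraction of exhausted cytotoxic T cells),
tumor PD-L1, the number of neo-antigen-specific T-cell clones, the initial
tumor diameter, and diversity indices (richness S, Shannon index
H = -sum p_k ln p_k, evenness J = H/ln S) of cancer clones and of cytotoxic
T-cell specificities.  Tumor and lymph-node candidates are averaged over the
patient's established metastatic lesions / their draining lymph nodes.

Patients are stratified into overlapping subgroups by uniformly spaced
thresholds over each candidate's range (above/below, default 8 cutoffs,
subgroups smaller than 20 patients discarded) and the subgroups are scored
by two metrics: response probability (fraction of responders inside the
subgroup, responders = CR/PR/SD) and the responder inclusion score

    RIS = (responders in subgroup / cohort responders)
        - (nonresponders in subgroup / cohort nonresponders),

which rewards capturing many responders while excluding nonresponders.
Candidates (and candidate pairs, via conjunctions of two thresholded
conditions) are ranked by the best subgroup score, with percentile-bootstrap
confidence intervals over patient resampling at fixed thresholds.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MET_SITES, VirtualPatient
from .state import (DRAINING_LN, N_EPITOPES, TUMOR_COMPARTMENTS,
                    CompartmentId, ModelState)

logger = logging.getLogger(__name__)

EXTINCTION_THRESHOLD = 1.0   # cells; below this a clone/specificity is absent


@dataclass
class DiversityProfile:
    richness: int
    shannon: float              # nats
    evenness: float | None      # H / ln S; undefined for S <= 1


def diversity(counts, extinction_threshold: float = EXTINCTION_THRESHOLD
              ) -> DiversityProfile:
    """Richness, Shannon index and evenness of a class-abundance vector.

    Classes with fewer than ``extinction_threshold`` members are extinct
    (continuous ODE abundances never reach exactly zero).  Proportions are
    taken over surviving classes only.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be >= 0")
    alive = c[c >= extinction_threshold]
    S = int(len(alive))
    if S == 0:
        return DiversityProfile(0, 0.0, None)
    p = alive / alive.sum()
    H = float(-(p * np.log(p)).sum())
    J = float(H / math.log(S)) if S >= 2 else None
    return DiversityProfile(S, H, J)


# ---------------------------------------------------------------------------
# candidate extraction

def _tumor_candidates(state: ModelState, vp: VirtualPatient, j: int) -> dict:
    comp = TUMOR_COMPARTMENTS[j]
    g = lambda s: state.get(comp, s)  # noqa: E731
    cancer = state.cancer_total(j)
    tcyt = float(np.clip(state.tcyt_active(j), 0.0, None).sum())
    texh = g("tcyt_exhausted")
    th, treg = g("th"), g("treg")
    m1, m2, mdsc = g("m1"), g("m2"), g("mdsc")
    apc = g("apc_immature") + g("apc_mature")
    t_all = tcyt + texh + th + treg
    immune = t_all + m1 + m2 + mdsc + apc
    total = cancer + immune
    kin = vp.parameters.kinetics

    def ratio(a, b):
        return a / b if b > 0 else np.nan

    clone_div = diversity(state.cancer_cells(j))
    tdiv = diversity(state.tcyt_active(j))
    out = {
        "tumor_density_tcyt": tcyt,
        "tumor_density_tcyt_exhausted": texh,
        "tumor_density_th": th,
        "tumor_density_treg": treg,
        "tumor_density_m1": m1,
        "tumor_density_m2": m2,
        "tumor_density_mdsc": mdsc,
        "tumor_density_apc": apc,
        "tumor_pdl1": g("pdl1_level"),
        "tumor_il10": g("il10"),
        "tumor_il12": g("il12"),
        "tumor_ifng": g("ifng"),
        "tumor_tgfb": g("tgfb"),
        "tumor_ccl2": g("ccl2"),
        "tumor_argi": g("argi"),
        "tumor_no": g("no"),
        "tumor_angiogenic_factor": g("angiogenic_factor"),
        "tumor_ratio_m2_m1": ratio(m2, m1),
        "tumor_ratio_treg_tcyt": ratio(treg, tcyt),
        "tumor_ratio_supp_act": ratio(treg + m2 + mdsc, tcyt + th + m1),
        "tumor_frac_tcyt_of_t": ratio(tcyt, t_all),
        "tumor_frac_treg_of_t": ratio(treg, t_all),
        "tumor_frac_exhausted_tcyt": ratio(texh, tcyt + texh),
        "tumor_frac_til": ratio(t_all, total),
        "tumor_frac_immune": ratio(immune, total),
        "tumor_clone_richness": clone_div.richness,
        "tumor_clone_shannon": clone_div.shannon,
        "tumor_clone_evenness": (clone_div.evenness
                                 if clone_div.evenness is not None else np.nan),
        "tumor_tcyt_richness_clonotypes": tdiv.richness * kin.n_clonotypes,
        "tumor_tcyt_shannon": tdiv.shannon,
        "tumor_tcyt_evenness": (tdiv.evenness
                                if tdiv.evenness is not None else np.nan),
    }
    return out


def _ln_candidates(state: ModelState, ln: CompartmentId, kin) -> dict:
    g = lambda s: state.get(ln, s)  # noqa: E731
    tcyt_spec = np.array([g(f"tcyt_activated_{e}") for e in range(N_EPITOPES)])
    tcyt = float(np.clip(tcyt_spec, 0.0, None).sum())
    th, treg = g("th_activated"), g("treg_activated")
    t_all = tcyt + th + treg
    tdiv = diversity(tcyt_spec)
    return {
        "ln_density_apc": g("apc_mature"),
        "ln_density_tcyt": tcyt,
        "ln_density_th": th,
        "ln_density_treg": treg,
        "ln_il2": g("il2"),
        "ln_frac_tcyt_of_t": tcyt / t_all if t_all > 0 else np.nan,
        "ln_tcyt_richness_clonotypes": tdiv.richness * kin.n_clonotypes,
        "ln_tcyt_shannon": tdiv.shannon,
        "ln_tcyt_evenness": (tdiv.evenness
                             if tdiv.evenness is not None else np.nan),
    }


def extract_candidates(patients: list, records: list) -> pd.DataFrame:
    """Per-patient baseline biomarker table with responder labels.

    ``patients`` are accepted :class:`VirtualPatient`s with baseline states;
    ``records`` the matching ResponseRecords (CR/PR/SD = responder).  Tumor
    and lymph-node candidates are averaged over the patient's established
    metastatic lesions and their draining lymph nodes.
    """
    rec_by_id = {r.patient_id: r for r in records}
    rows = []
    for vp in patients:
        if vp.patient_id not in rec_by_id:
            continue
        state = vp.baseline_state
        kin = vp.parameters.kinetics
        lesion_js = [j for s, j in MET_SITES.items()
                     if s in vp.baseline_diameters]
        if vp.parameters.primary_tumor_intact:
            lesion_js.insert(0, 0)
        tumor_parts = [_tumor_candidates(state, vp, j) for j in lesion_js]
        lns = sorted({DRAINING_LN[TUMOR_COMPARTMENTS[j]] for j in lesion_js},
                     key=lambda c: c.value)
        ln_parts = [_ln_candidates(state, ln, kin) for ln in lns]

        def _nanmean(vals):
            ok = [v for v in vals if not np.isnan(v)]
            return float(np.mean(ok)) if ok else np.nan

        row: dict = {"patient_id": vp.patient_id}
        for key in tumor_parts[0]:
            row[key] = _nanmean([p[key] for p in tumor_parts])
        for key in ln_parts[0]:
            row[key] = _nanmean([p[key] for p in ln_parts])

        tc_central = np.array([state.get(CompartmentId.CENTRAL, f"tcyt_{e}")
                               for e in range(N_EPITOPES)])
        tc = float(np.clip(tc_central, 0.0, None).sum())
        th = state.get(CompartmentId.CENTRAL, "th")
        treg = state.get(CompartmentId.CENTRAL, "treg")
        t_all = tc + th + treg
        row.update({
            "central_density_tcyt": tc,
            "central_density_th": th,
            "central_density_treg": treg,
            "central_frac_tcyt_of_t": tc / t_all if t_all > 0 else np.nan,
            "n_neoantigen_tcell_clones": (
                diversity(tc_central).richness * kin.n_clonotypes),
            "initial_tumor_diameter_cm": vp.max_baseline_diameter,
            "responder": rec_by_id[vp.patient_id].responder,
        })
        rows.append(row)
    df = pd.DataFrame(rows).set_index("patient_id")
    if df["responder"].isna().any():
        raise ValueError("missing responder labels")
    return df


def candidate_columns(table: pd.DataFrame) -> list:
    return [c for c in table.columns if c != "responder"]


# ---------------------------------------------------------------------------
# subgroups and metrics

@dataclass
class Subgroup:
    direction: str          # "above" (value >= threshold) or "below" (<)
    threshold: float
    member_ids: np.ndarray


@dataclass
class SubgroupScore:
    candidates: tuple       # one name, or a pair
    directions: tuple
    thresholds: tuple
    n_patients: int
    response_probability: float
    ris: float
    metric: str
    value: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    pct_change_vs_best_single: float | None = None


def make_subgroups(values: pd.Series | np.ndarray, n_thresholds: int = 8,
                   min_size: int = 20) -> list:
    """Threshold-defined overlapping subgroups of one candidate.

    ``n_thresholds`` uniformly spaced cutoffs span the candidate's observed
    range (interior grid points; the extremes themselves define empty or
    singleton subgroups); each cutoff defines an "above" (>= cutoff) and a
    "below" (<) subgroup; subgroups with fewer than ``min_size`` members are
    discarded.
    Patients with absent (NaN) values are excluded pairwise.
    """
    s = pd.Series(values)
    s = s.dropna()
    if len(s) < min_size:
        return []
    vals = s.to_numpy(dtype=float)
    ids = s.index.to_numpy()
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        logger.info("constant candidate skipped (range is empty)")
        return []
    out = []
    for t in np.linspace(lo, hi, n_thresholds + 2)[1:-1]:
        for direction in ("above", "below"):
            mask = vals >= t if direction == "above" else vals < t
            if mask.sum() >= min_size:
                out.append(Subgroup(direction, float(t), ids[mask]))
    return out


def response_probability(member_ids, responder: pd.Series) -> float:
    """Fraction of responders among the subgroup members."""
    members = np.asarray(member_ids)
    if len(members) == 0:
        raise ValueError("empty subgroup")
    return float(responder.loc[members].mean())


def ris(member_ids, responder: pd.Series) -> float:
    """Responder inclusion score of a subgroup against the whole cohort."""
    n_resp = int(responder.sum())
    n_nonresp = int((~responder.astype(bool)).sum())
    if n_resp == 0 or n_nonresp == 0:
        raise ValueError("RIS undefined: cohort needs responders and "
                         "nonresponders")
    members = np.asarray(member_ids)
    flags = responder.loc[members].astype(bool)
    return float(flags.sum() / n_resp - (~flags).sum() / n_nonresp)


def _score(members, responder) -> tuple[float, float]:
    return response_probability(members, responder), ris(members, responder)


def _bootstrap_ci(masks: list, responder: np.ndarray,
                  metric: str, n_boot: int, rng) -> tuple[float, float]:
    """Percentile CI by patient resampling; thresholds held fixed."""
    n = len(responder)
    stats = np.full(n_boot, np.nan)
    mask = masks[0] if len(masks) == 1 else masks[0] & masks[1]
    for b in range(n_boot):
        pick = rng.integers(0, n, n)
        m = mask[pick]
        r = responder[pick]
        if metric == "rp":
            if m.sum() == 0:
                continue
            stats[b] = r[m].mean()
        else:
            nr, nn = r.sum(), (~r).sum()
            if nr == 0 or nn == 0:
                continue
            stats[b] = (r & m).sum() / nr - (~r & m).sum() / nn
    ok = stats[~np.isnan(stats)]
    if len(ok) == 0:
        return (np.nan, np.nan)
    return float(np.percentile(ok, 2.5)), float(np.percentile(ok, 97.5))


def _threshold_masks(vals: np.ndarray, n_thresholds: int) -> list:
    """All (direction, threshold, mask) triples over the value range."""
    finite = vals[~np.isnan(vals)]
    if len(finite) == 0:
        return []
    lo, hi = float(finite.min()), float(finite.max())
    if hi <= lo:
        return []
    out = []
    for t in np.linspace(lo, hi, n_thresholds + 2)[1:-1]:
        with np.errstate(invalid="ignore"):
            out.append(("above", t, vals >= t))
            out.append(("below", t, vals < t))
    return out


def rank_candidates(table: pd.DataFrame, metric: str = "rp",
                    n_thresholds: int = 8, min_size: int = 20,
                    n_boot: int = 1000, seed: int = 0) -> list:
    """Best subgroup per candidate, ranked by the chosen metric.

    Ties are broken by larger subgroup size, then candidate name.  Returns a
    list of :class:`SubgroupScore` in rank order.
    """
    if metric not in ("rp", "ris"):
        raise ValueError("metric must be 'rp' or 'ris'")
    responder = table["responder"].astype(bool)
    resp_arr = responder.to_numpy()
    rng = np.random.default_rng(seed)
    scores = []
    for name in candidate_columns(table):
        vals = table[name].to_numpy(dtype=float)
        best = None
        for direction, t, mask in _threshold_masks(vals, n_thresholds):
            mask = mask & ~np.isnan(vals)
            n_m = int(mask.sum())
            if n_m < min_size:
                continue
            rp_v = resp_arr[mask].mean()
            ris_v = ((resp_arr & mask).sum() / resp_arr.sum()
                     - (~resp_arr & mask).sum() / (~resp_arr).sum())
            val = rp_v if metric == "rp" else ris_v
            key = (val, n_m)
            if best is None or key > best[0]:
                best = (key, direction, t, mask, n_m, rp_v, ris_v)
        if best is None:
            logger.info("candidate %s produced no valid subgroup", name)
            continue
        _, direction, t, mask, n_m, rp_v, ris_v = best
        lo, hi = _bootstrap_ci([mask], resp_arr, metric, n_boot, rng)
        scores.append(SubgroupScore(
            candidates=(name,), directions=(direction,), thresholds=(t,),
            n_patients=n_m, response_probability=float(rp_v),
            ris=float(ris_v), metric=metric,
            value=float(rp_v if metric == "rp" else ris_v),
            ci_low=lo, ci_high=hi))
    scores.sort(key=lambda s: (-s.value, -s.n_patients, s.candidates))
    return scores


def rank_pairs(table: pd.DataFrame, metric: str = "rp",
               n_thresholds: int = 8, min_size: int = 20,
               n_boot: int = 200, seed: int = 0) -> list:
    """Best conjunction subgroup per candidate pair, ranked by the metric.

    A pair subgroup is the intersection of one thresholded condition per
    candidate (both directions, ``n_thresholds`` cutoffs each).  Each score
    also reports the percent change of the pair's best value against the
    better of its two constituent single-candidate best values.
    """
    singles = {s.candidates[0]: s.value
               for s in rank_candidates(table, metric, n_thresholds,
                                        min_size, n_boot=1, seed=seed)}
    responder = table["responder"].astype(bool).to_numpy()
    rng = np.random.default_rng(seed)
    names = candidate_columns(table)
    masks = {}
    for name in names:
        vals = table[name].to_numpy(dtype=float)
        trip = _threshold_masks(vals, n_thresholds)
        masks[name] = [(d, t, m & ~np.isnan(vals)) for d, t, m in trip]

    scores = []
    n_resp = responder.sum()
    n_non = (~responder).sum()
    for a, b in itertools.combinations(names, 2):
        best = None
        for da, ta, ma in masks[a]:
            for db, tb, mb in masks[b]:
                m = ma & mb
                n_m = int(m.sum())
                if n_m < min_size:
                    continue
                rp_v = responder[m].mean()
                ris_v = ((responder & m).sum() / n_resp
                         - (~responder & m).sum() / n_non)
                val = rp_v if metric == "rp" else ris_v
                key = (val, n_m)
                if best is None or key > best[0]:
                    best = (key, (da, db), (ta, tb), (ma, mb), n_m, rp_v, ris_v)
        if best is None:
            continue
        _, dirs, ths, mm, n_m, rp_v, ris_v = best
        val = float(rp_v if metric == "rp" else ris_v)
        lo, hi = _bootstrap_ci(list(mm), responder, metric, n_boot, rng)
        best_single = max(singles.get(a, -np.inf), singles.get(b, -np.inf))
        pct = (100.0 * (val - best_single) / abs(best_single)
               if np.isfinite(best_single) and best_single != 0 else np.nan)
        scores.append(SubgroupScore(
            candidates=(a, b), directions=dirs, thresholds=ths,
            n_patients=n_m, response_probability=float(rp_v),
            ris=float(ris_v), metric=metric, value=val,
            ci_low=lo, ci_high=hi, pct_change_vs_best_single=pct))
    scores.sort(key=lambda s: (-s.value, -s.n_patients, s.candidates))
    return scores


def scores_to_frame(scores: list) -> pd.DataFrame:
    """Ranking output as a CSV-ready table."""
    rows = []
    for s in scores:
        rows.append({
            "candidate": " & ".join(s.candidates),
            "direction": " & ".join(s.directions),
            "threshold": " & ".join(f"{t:.6g}" for t in s.thresholds),
            "n": s.n_patients,
            "rp": s.response_probability,
            "ris": s.ris,
            "metric": s.metric,
            "value": s.value,
            "ci_low": s.ci_low,
            "ci_high": s.ci_high,
            "pct_change_vs_best_single": s.pct_change_vs_best_single,
        })
    return pd.DataFrame(rows)
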