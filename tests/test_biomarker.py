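import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tnbcqsp.biomarker import (DiversityProfile, Subgroup, diversity,
                               extract_candidates, make_subgroups,
                               rank_candidates, rank_pairs,
                               response_probability, ris, scores_to_frame)
from tnbcqsp.fixtures import synthetic_biomarker_table
from tnbcqsp.state import TUMOR_COMPARTMENTS


class TestDiversity:
    def test_single_clone(self):
        d = diversity([1000.0, 0.0, 0.0, 0.0, 0.0])
        assert d.richness == 1 and d.shannon == 0.0 and d.evenness is None

    def test_five_equal_clones_maximal_evenness(self):
        d = diversity([100.0] * 5)
        assert d.shannon == pytest.approx(math.log(5), rel=1e-12)
        assert d.shannon == pytest.approx(1.6094, abs=1e-4)
        assert d.evenness == pytest.approx(1.0)

    def test_direct_summation(self):
        # p = (1/2, 1/4, 1/4) -> H = 1.5 ln 2
        d = diversity([200.0, 100.0, 100.0])
        assert d.shannon == pytest.approx(1.5 * math.log(2), rel=1e-12)
        assert d.shannon == pytest.approx(1.0397, abs=1e-4)

    def test_all_extinct(self):
        d = diversity([0.5, 0.0, 0.9])
        assert d == DiversityProfile(0, 0.0, None)

    def test_extinction_threshold_counts_richness(self):
        assert diversity([0.5, 10.0, 10.0]).richness == 2

    def test_invariants_on_random_counts(self, rng):
        for _ in range(50):
            c = rng.lognormal(2.0, 2.0, rng.integers(1, 9))
            d = diversity(c)
            assert d.shannon >= 0.0
            if d.richness >= 1:
                assert d.shannon <= math.log(max(d.richness, 1)) + 1e-12
            if d.richness >= 2:
                assert 0.0 <= d.evenness <= 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            diversity([-1.0, 2.0])


class TestExtraction:
    def test_one_row_per_patient(self, small_cohort, small_trial):
        table = extract_candidates(small_cohort.patients, small_trial.records)
        assert len(table) == len(small_trial.records)
        assert table["responder"].dtype == bool

    def test_til_fraction_recomputed_independently(self, small_cohort,
                                                   small_trial):
        """The TIL-fraction column equals an independent tally of T cells
        over all cells from the raw baseline state."""
        table = extract_candidates(small_cohort.patients, small_trial.records)
        vp = small_cohort.patients[0]
        state = vp.baseline_state
        fracs = []
        from tnbcqsp.cohort import MET_SITES
        for site, j in MET_SITES.items():
            if site not in vp.baseline_diameters:
                continue
            comp = TUMOR_COMPARTMENTS[j]
            tc = sum(max(state.get(comp, f"tcyt_active_{e}"), 0.0)
                     for e in range(8))
            t_all = (tc + state.get(comp, "tcyt_exhausted")
                     + state.get(comp, "th") + state.get(comp, "treg"))
            allcells = (state.cancer_total(j) + t_all
                        + state.get(comp, "m1") + state.get(comp, "m2")
                        + state.get(comp, "mdsc")
                        + state.get(comp, "apc_immature")
                        + state.get(comp, "apc_mature"))
            fracs.append(t_all / allcells)
        assert table.loc[vp.patient_id, "tumor_frac_til"] == pytest.approx(
            np.mean(fracs), rel=1e-9)

    def test_degenerate_ratio_is_absent_not_zero(self):
        # a patient with an absent ratio is excluded pairwise, not counted
        df = pd.DataFrame({"x": [np.nan, 1.0, 2.0, 3.0, 4.0],
                           "responder": [True, False, True, False, True]})
        subs = make_subgroups(df["x"], min_size=2)
        assert subs
        assert all(0 not in s.member_ids for s in subs)


class TestSubgroups:
    def test_uniform_values_all_16_subgroups_survive(self, rng):
        vals = pd.Series(rng.uniform(0.0, 1.0, 1000))
        subs = make_subgroups(vals, n_thresholds=8, min_size=20)
        assert len(subs) == 16

    def test_min_size_larger_than_n_gives_empty(self, rng):
        assert make_subgroups(pd.Series(rng.uniform(0, 1, 10)),
                              min_size=20) == []

    def test_thresholds_uniformly_spaced(self, rng):
        vals = pd.Series(rng.uniform(0.0, 1.0, 500))
        subs = make_subgroups(vals, n_thresholds=8, min_size=1)
        ts = sorted({s.threshold for s in subs})
        gaps = np.diff(ts)
        assert np.allclose(gaps, gaps[0])
        lo, hi = vals.min(), vals.max()
        step = (hi - lo) / 9
        assert ts[0] == pytest.approx(lo + step)
        assert ts[-1] == pytest.approx(hi - step)

    def test_direction_convention(self, rng):
        vals = pd.Series(np.arange(100, dtype=float))
        subs = make_subgroups(vals, n_thresholds=8, min_size=1)
        for s in subs:
            got = set(s.member_ids)
            if s.direction == "above":
                want = set(vals[vals >= s.threshold].index)
            else:
                want = set(vals[vals < s.threshold].index)
            assert got == want

    def test_constant_candidate_skipped(self):
        assert make_subgroups(pd.Series([3.0] * 50), min_size=5) == []


class TestMetrics:
    def _responder(self, flags):
        return pd.Series(flags, dtype=bool)

    def test_rp_extremes_and_ratio(self):
        r = self._responder([True] * 43 + [False] * 7)
        assert response_probability(r.index[:43], r) == 1.0
        assert response_probability(r.index[43:], r) == 0.0
        assert response_probability(r.index[:50], r) == pytest.approx(0.86)

    def test_rp_empty_errors(self):
        with pytest.raises(ValueError):
            response_probability([], self._responder([True, False]))

    def test_ris_whole_cohort_is_zero(self):
        r = self._responder([True] * 30 + [False] * 70)
        assert ris(r.index, r) == pytest.approx(0.0)

    def test_ris_pure_responder_subgroup_is_one(self):
        r = self._responder([True] * 30 + [False] * 70)
        assert ris(r.index[:30], r) == pytest.approx(1.0)

    def test_ris_72_29_gives_0_43(self):
        """A subgroup holding 72% of responders and 29% of nonresponders
        scores RIS = 0.43."""
        r = self._responder([True] * 100 + [False] * 100)
        members = list(r.index[:72]) + list(r.index[100:129])
        assert ris(members, r) == pytest.approx(0.43)

    def test_ris_undefined_without_both_classes(self):
        with pytest.raises(ValueError):
            ris([0], self._responder([True, True]))


# ---------------------------------------------------------------------------
# brute-force oracle for the ranking machinery

def _oracle_best(table, name, metric, n_thresholds, min_size):
    vals = table[name].dropna()
    resp = table["responder"].astype(bool)
    n_resp = resp.sum()
    n_non = (~resp).sum()
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        return None
    best = None
    for t in np.linspace(lo, hi, n_thresholds + 2)[1:-1]:
        for direction in ("above", "below"):
            ids = vals[vals >= t].index if direction == "above" \
                else vals[vals < t].index
            if len(ids) < min_size:
                continue
            flags = resp.loc[ids]
            rp_v = flags.mean()
            ris_v = flags.sum() / n_resp - (~flags).sum() / n_non
            val = rp_v if metric == "rp" else ris_v
            key = (val, len(ids))
            if best is None or key > best[0]:
                best = (key, direction, t)
    return best


class TestRankingOracle:
    @pytest.mark.parametrize("metric", ["rp", "ris"])
    def test_single_candidate_ranking_matches_brute_force(self, metric):
        table, _ = synthetic_biomarker_table(n=60, n_noise=2, seed=5)
        scores = rank_candidates(table, metric, n_thresholds=8, min_size=10,
                                 n_boot=10, seed=0)
        oracle = {}
        for name in ("signal", "noise_0", "noise_1"):
            best = _oracle_best(table, name, metric, 8, 10)
            oracle[name] = best
        # per-candidate best values and thresholds agree exactly
        for s in scores:
            key, direction, t = oracle[s.candidates[0]]
            assert s.value == pytest.approx(key[0], rel=1e-12)
            assert s.n_patients == key[1]
            assert s.directions[0] == direction
            assert s.thresholds[0] == pytest.approx(t, rel=1e-12)
        # ranking order agrees with sorting the oracle values
        want_order = sorted(oracle, key=lambda n: (-oracle[n][0][0],
                                                   -oracle[n][0][1], n))
        assert [s.candidates[0] for s in scores] == want_order

    @pytest.mark.parametrize("metric", ["rp", "ris"])
    def test_pair_ranking_matches_brute_force(self, metric):
        table, _ = synthetic_biomarker_table(n=60, n_noise=2, seed=9)
        pairs = rank_pairs(table, metric, n_thresholds=8, min_size=10,
                           n_boot=5, seed=0)
        names = ["signal", "noise_0", "noise_1"]
        resp = table["responder"].astype(bool)
        n_resp, n_non = resp.sum(), (~resp).sum()
        for a, b in itertools.combinations(names, 2):
            best = None
            for ta in np.linspace(table[a].min(), table[a].max(), 10)[1:-1]:
                for tb in np.linspace(table[b].min(), table[b].max(), 10)[1:-1]:
                    for da in ("above", "below"):
                        for db in ("above", "below"):
                            ma = table[a] >= ta if da == "above" \
                                else table[a] < ta
                            mb = table[b] >= tb if db == "above" \
                                else table[b] < tb
                            ids = table.index[ma & mb]
                            if len(ids) < 10:
                                continue
                            flags = resp.loc[ids]
                            rp_v = flags.mean()
                            ris_v = (flags.sum() / n_resp
                                     - (~flags).sum() / n_non)
                            val = rp_v if metric == "rp" else ris_v
                            if best is None or (val, len(ids)) > best:
                                best = (val, len(ids))
            got = [s for s in pairs if set(s.candidates) == {a, b}][0]
            assert got.value == pytest.approx(best[0], rel=1e-12)
            assert got.n_patients == best[1]

    def test_identical_pair_equals_best_single(self):
        table, _ = synthetic_biomarker_table(n=80, n_noise=0, seed=3)
        table["signal_copy"] = table["signal"]
        singles = rank_candidates(table, "rp", min_size=10, n_boot=5, seed=0)
        pairs = rank_pairs(table, "rp", min_size=10, n_boot=5, seed=0)
        best_single = max(s.value for s in singles)
        pair = [p for p in pairs
                if set(p.candidates) == {"signal", "signal_copy"}][0]
        assert pair.value == pytest.approx(best_single, rel=1e-12)
        assert pair.pct_change_vs_best_single == pytest.approx(0.0, abs=1e-9)


class TestRankingProperties:
    def test_affine_transform_leaves_scores_unchanged(self):
        """Thresholds are quantile-spaced over the range, so any affine map
        of a candidate reproduces identical memberships and scores."""
        table, _ = synthetic_biomarker_table(n=100, n_noise=1, seed=2)
        t2 = table.copy()
        t2["signal"] = 3.5 * t2["signal"] + 11.0
        s1 = rank_candidates(table, "rp", min_size=10, n_boot=5, seed=0)
        s2 = rank_candidates(t2, "rp", min_size=10, n_boot=5, seed=0)
        for a, b in zip(s1, s2):
            assert a.candidates == b.candidates
            assert a.value == pytest.approx(b.value, rel=1e-12)
            assert a.n_patients == b.n_patients

    def test_patient_order_permutation_invariance(self, rng):
        table, _ = synthetic_biomarker_table(n=100, n_noise=2, seed=4)
        perm = table.iloc[rng.permutation(len(table))]
        s1 = rank_candidates(table, "ris", min_size=10, n_boot=5, seed=0)
        s2 = rank_candidates(perm, "ris", min_size=10, n_boot=5, seed=0)
        assert [(s.candidates, s.value) for s in s1] == \
            [(s.candidates, s.value) for s in s2]

    def test_bootstrap_ci_deterministic_and_brackets_value(self):
        table, _ = synthetic_biomarker_table(n=150, n_noise=1, seed=6)
        s1 = rank_candidates(table, "rp", min_size=20, n_boot=300, seed=42)
        s2 = rank_candidates(table, "rp", min_size=20, n_boot=300, seed=42)
        assert [(s.ci_low, s.ci_high) for s in s1] == \
            [(s.ci_low, s.ci_high) for s in s2]
        top = s1[0]
        assert top.ci_low <= top.value + 0.05
        assert top.ci_high >= top.value - 0.05

    def test_planted_candidate_recovered_over_20_seeds(self):
        """With responder status a noisy threshold function of one candidate,
        that candidate ranks first in >95% of seeded replicates."""
        wins = 0
        for seed in range(20):
            table, planted = synthetic_biomarker_table(
                n=200, n_noise=4, flip_probability=0.1, seed=seed)
            scores = rank_candidates(table, "rp", min_size=20, n_boot=1,
                                     seed=seed)
            wins += scores[0].candidates[0] == planted
        assert wins >= 19

    def test_scores_frame_columns(self):
        table, _ = synthetic_biomarker_table(n=60, n_noise=1, seed=0)
        df = scores_to_frame(rank_candidates(table, "rp", min_size=10,
                                             n_boot=5, seed=0))
        assert {"candidate", "direction", "threshold", "n", "rp", "ris",
                "ci_low", "ci_high"} <= set(df.columns)
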