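"""Inverse-MDS engine: trial scaling, aggregation, adaptive subsets,
simulated arrangers, reliability and agreement statistics."""

import numpy as np
import pytest

from actionrsa.arrangement import (Arena, ArrangementSession, ArrangementTrial,
                                   EvidenceMatrix, aggregate_session,
                                   cosine_agreement, loso_reliability,
                                   select_consistent_items, select_next_subset,
                                   simulate_arranger, trial_distances)
from actionrsa.rdm import RDM, euclidean_rdm, rdm_correlation
from actionrsa import make_ground_truth


def session_of(trials, items, subject="s1"):
    return ArrangementSession(subject, "semantic", items, trials,
                              Arena(radius=300.0))


class TestTrialDistances:
    def test_max_pair_scales_to_one(self):
        t = ArrangementTrial(("a", "b"), [[0, 0], [0, 100]])
        assert trial_distances(t).values[0, 1] == 1.0

    def test_equilateral_triangle_all_ones(self):
        pts = [[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]]
        t = ArrangementTrial(("a", "b", "c"), pts)
        assert np.allclose(trial_distances(t).vector(), 1.0)

    def test_matches_brute_force_scaled(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        t = ArrangementTrial(tuple("abcdef"), pts)
        d = np.array([[np.linalg.norm(pts[i] - pts[j]) for j in range(6)]
                      for i in range(6)])
        assert np.allclose(trial_distances(t).values, d / d.max(), atol=1e-12)

    def test_single_item_trial_rejected(self):
        with pytest.raises(ValueError):
            trial_distances(ArrangementTrial(("a",), [[0, 0]]))


class TestAggregation:
    def test_single_trial_session_is_normalized_trial(self):
        pts = np.random.default_rng(1).normal(size=(5, 2))
        items = tuple("abcde")
        sess = session_of([ArrangementTrial(items, pts)], items)
        agg = aggregate_session(sess)
        td = trial_distances(ArrangementTrial(items, pts))
        assert np.allclose(agg.values, td.values / td.vector().max())

    def test_duplicate_trials_change_nothing(self):
        pts = np.random.default_rng(2).normal(size=(4, 2))
        items = tuple("abcd")
        one = session_of([ArrangementTrial(items, pts)], items)
        two = session_of([ArrangementTrial(items, pts)] * 2, items)
        assert np.allclose(aggregate_session(one).values,
                           aggregate_session(two).values)

    def test_invariant_to_global_rescaling(self):
        rng = np.random.default_rng(3)
        items = tuple("abcdef")
        t1 = rng.normal(size=(6, 2))
        t2 = rng.normal(size=(6, 2))
        base = session_of([ArrangementTrial(items, t1),
                           ArrangementTrial(items, t2)], items)
        scaled = session_of([ArrangementTrial(items, 7.3 * t1),
                             ArrangementTrial(items, 0.2 * t2)], items)
        assert np.allclose(aggregate_session(base).values,
                           aggregate_session(scaled).values, atol=1e-12)

    def test_trial1_must_cover_all_items(self):
        with pytest.raises(ValueError, match="every item"):
            session_of([ArrangementTrial(("a", "b"), [[0, 0], [1, 1]])],
                       ("a", "b", "c"))

    def test_evidence_weighted_mode_close_to_mean_mode(self, gt28):
        sess = simulate_arranger(gt28.true_rdm, noise_sd=0.05,
                                 time_budget_trials=8, seed=1)
        a = aggregate_session(sess, mode="mean")
        b = aggregate_session(sess, mode="evidence_weighted")
        assert rdm_correlation(a, b) > 0.98


class TestAdaptiveSubsets:
    def test_uniform_evidence_returns_first_min_items(self):
        ev = EvidenceMatrix(tuple("abcdef"))
        ev.values[:] = 1.0
        np.fill_diagonal(ev.values, 0)
        assert select_next_subset(ev, min_items=3) == ("a", "b", "c")

    def test_weakest_pair_always_included(self):
        ev = EvidenceMatrix(tuple("abcdef"))
        ev.values[:] = 5.0
        ev.values[2, 4] = ev.values[4, 2] = 0.0
        np.fill_diagonal(ev.values, 0)
        subset = select_next_subset(ev, min_items=3)
        assert "c" in subset and "e" in subset

    def test_min_pair_evidence_grows_over_adaptive_session(self, gt28):
        ev = EvidenceMatrix(gt28.items)
        n = len(gt28.items)
        mins = []
        subset = gt28.items
        idx = {it: i for i, it in enumerate(gt28.items)}
        for _ in range(15):
            ix = np.array([idx[i] for i in subset])
            ev.add_trial(ix, weight=n / len(subset))
            mins.append(ev.min_pair_evidence())
            subset = select_next_subset(ev)
        assert all(b >= a for a, b in zip(mins, mins[1:]))
        assert mins[-1] > mins[0]

    def test_adaptive_beats_random_subsets_on_min_evidence(self, gt28):
        rng = np.random.default_rng(0)
        n = len(gt28.items)
        idx = {it: i for i, it in enumerate(gt28.items)}

        def run(select):
            ev = EvidenceMatrix(gt28.items)
            subset = gt28.items
            for t in range(20):
                ix = np.array([idx[i] for i in subset])
                ev.add_trial(ix, weight=n / len(subset))
                subset = select(ev)
            return ev.min_pair_evidence()

        adaptive = run(lambda ev: select_next_subset(ev))
        k = 8
        random_min = run(lambda ev: tuple(
            gt28.items[i] for i in sorted(rng.choice(n, size=k, replace=False))))
        assert adaptive >= random_min


class TestSimulatedArranger:
    def test_noiseless_2d_truth_recovered(self, gt28):
        sess = simulate_arranger(gt28.true_rdm, noise_sd=0.0,
                                 time_budget_trials=10, seed=0)
        agg = aggregate_session(sess)
        assert rdm_correlation(agg, gt28.true_rdm) >= 0.99

    def test_recovery_degrades_monotonically_with_noise(self, gt28):
        grid = [0.0, 0.05, 0.2, 0.8, 3.0]
        rs = []
        for noise in grid:
            vals = []
            for seed in range(5):
                sess = simulate_arranger(gt28.true_rdm, noise_sd=noise,
                                         time_budget_trials=8, seed=seed)
                vals.append(rdm_correlation(aggregate_session(sess),
                                            gt28.true_rdm))
            rs.append(np.mean(vals))
        # Monte-Carlo tolerance: allow tiny inversions, demand overall decay
        assert all(b <= a + 0.05 for a, b in zip(rs, rs[1:]))
        assert rs[-1] < 0.5 < rs[0]

    def test_sessions_reproducible_per_seed(self, gt28):
        a = simulate_arranger(gt28.true_rdm, 0.1, seed=4)
        b = simulate_arranger(gt28.true_rdm, 0.1, seed=4)
        assert all(np.allclose(x.coords, y.coords)
                   for x, y in zip(a.trials, b.trials))

    def test_json_round_trip(self, tmp_path, gt28):
        sess = simulate_arranger(gt28.true_rdm, 0.1, time_budget_trials=4,
                                 seed=2)
        sess.to_json(tmp_path / "s.json")
        back = ArrangementSession.from_json(tmp_path / "s.json")
        assert back.items == sess.items
        assert np.allclose(back.trials[-1].coords, sess.trials[-1].coords)


class TestReliability:
    def test_identical_subjects_all_r_one(self, gt28):
        rdms = [gt28.true_rdm.copy(subject=f"s{i}") for i in range(4)]
        df = loso_reliability(rdms, n_perm=200, seed=0)
        assert np.allclose(df["r"], 1.0)
        assert df["significant"].all()

    def test_independent_random_rdms_not_reliable(self):
        rng = np.random.default_rng(5)
        items = tuple(f"i{k}" for k in range(12))
        rdms = [euclidean_rdm(rng.normal(size=(12, 6)), items)
                for _ in range(8)]
        df = loso_reliability(rdms, n_perm=500, seed=1)
        assert abs(df["r"].mean()) < 0.25
        assert df["significant"].mean() <= 0.25

    def test_mismatching_items_rejected(self, gt28):
        other = euclidean_rdm(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError):
            loso_reliability([gt28.true_rdm, gt28.true_rdm, other])


class TestAgreement:
    def test_identical_rows_give_zero(self, gt28):
        scores = cosine_agreement([gt28.true_rdm, gt28.true_rdm])
        assert np.allclose(scores, 0.0, atol=1e-12)

    def test_orthogonal_rows_give_one(self):
        items = ("a", "b", "c")
        m1 = RDM(items, np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]]))
        m2 = RDM(items, np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0.0]]))
        scores = cosine_agreement([m1, m2])
        # item a's profile is (0,1,0) vs (0,0,1): orthogonal
        assert scores["a"] == pytest.approx(1.0)

    def test_matches_pairwise_loop_oracle(self):
        rng = np.random.default_rng(6)
        items = tuple(f"i{k}" for k in range(7))
        rdms = [euclidean_rdm(rng.normal(size=(7, 3)), items)
                for _ in range(4)]
        got = cosine_agreement(rdms)
        for i, item in enumerate(items):
            vals = []
            for a in range(4):
                for b in range(a + 1, 4):
                    u, v = rdms[a].values[i], rdms[b].values[i]
                    vals.append(1 - u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
            assert got[item] == pytest.approx(np.mean(vals), abs=1e-12)


class TestItemSelection:
    def test_all_equal_scores_all_kept(self):
        import pandas as pd
        s = pd.Series(0.3, index=list("abcde"))
        out = select_consistent_items({"t1": s, "t2": s})
        assert out["keep"].all()

    def test_inflated_item_discarded(self):
        import pandas as pd
        base = pd.Series(0.2, index=list("abcde"))
        bad = base.copy()
        bad["c"] = 2.0  # far beyond mean + 1 sd even with the outlier included
        out = select_consistent_items({"t1": base, "t2": bad})
        assert not out.loc["c", "keep"]
        assert out.drop("c")["keep"].all()
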