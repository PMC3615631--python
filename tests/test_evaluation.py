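"""Leave-one-out protocol, ROC/AUC and the restart sweep."""

import numpy as np
import pytest

from omimwalk import (
    AssociationSet,
    RWRConfig,
    SimilarityMatrix,
    TrialResult,
    generate,
    loocv,
    normalize,
    null_config,
    parameter_sweep,
    roc_from_trials,
    rwr_closed_form,
    SyntheticConfig,
)
from scipy.stats import rankdata


def brute_force_auc(trials):
    """P(positive outranks negative) by explicit pair counting."""
    wins = total = 0.0
    for t in trials:
        # the positive occupies rank mass at t.rank; negatives fill the rest
        for k in np.delete(np.arange(1, t.n_candidates + 1),
                           int(round(t.rank)) - 1):
            total += 1
            if t.rank < k:
                wins += 1
            elif t.rank == k:
                wins += 0.5
    return wins / total


class TestLoocv:
    def test_two_disease_universe_forced_rank_one(self):
        sim = SimilarityMatrix(("1", "2"), np.array([[1.0, 0.4], [0.4, 1.0]]))
        assoc = AssociationSet(frozenset({("m1", "1"), ("m1", "2")}))
        trials = loocv(assoc, normalize(sim))
        assert len(trials) == 2
        for t in trials:
            assert t.rank == 1 and t.n_candidates == 1

    def test_ranks_match_per_trial_score_vectors(self):
        # brute-force: recompute every trial's rank from the closed form
        cfg = SyntheticConfig(n_diseases=12, n_mirnas=6, n_clusters=2,
                              associations_per_mirna=3, rng_seed=5)
        sim, assoc, _ = generate(cfg)
        W = normalize(sim)
        trials = loocv(assoc, W)
        by_key = {(t.mirna_id, t.left_out_disease): t for t in trials}
        idx = {d: i for i, d in enumerate(W.disease_ids)}
        for mirna in assoc.mirna_ids:
            diseases = sorted(assoc.diseases_of(mirna))
            for left_out in diseases:
                seeds = [d for d in diseases if d != left_out]
                p0 = np.zeros(W.n)
                if seeds:
                    p0[[idx[s] for s in seeds]] = 1 / len(seeds)
                else:
                    p0[:] = 1 / W.n
                p = rwr_closed_form(W, p0, 0.8)
                cand = [d for d in W.disease_ids if d not in seeds]
                scores = np.array([p[idx[d]] for d in cand])
                ranks = rankdata(-scores)
                expected = float(ranks[cand.index(left_out)])
                t = by_key[(mirna, left_out)]
                assert t.rank == pytest.approx(expected)
                assert t.n_candidates == len(cand)

    def test_signal_data_ranks_left_out_early(self):
        cfg = SyntheticConfig(rng_seed=11)  # default signal configuration
        sim, assoc, _ = generate(cfg)
        trials = loocv(assoc, normalize(sim))
        mean_pct = np.mean([t.rank_percentile for t in trials])
        assert mean_pct < 0.35

    def test_empty_seed_policy_contract(self):
        sim = SimilarityMatrix(
            ("1", "2", "3"),
            np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]]),
        )
        assoc = AssociationSet(frozenset({("m1", "1")}))  # degree-1 miRNA
        skipped = loocv(assoc, normalize(sim), empty_seed_policy="skip")
        assert skipped == []
        uniform = loocv(assoc, normalize(sim), empty_seed_policy="uniform")
        assert len(uniform) == 1
        assert uniform[0].n_candidates == 3  # all diseases are candidates

    def test_unmapped_diseases_dropped_with_warning(self, caplog):
        sim = SimilarityMatrix(("1", "2"), np.array([[1.0, 0.4], [0.4, 1.0]]))
        assoc = AssociationSet(
            frozenset({("m1", "1"), ("m1", "2"), ("m1", "999")})
        )
        with caplog.at_level("WARNING"):
            trials = loocv(assoc, normalize(sim))
        assert len(trials) == 2
        assert any("dropped 1" in r.message for r in caplog.records)

    def test_empty_association_set_rejected(self):
        sim = SimilarityMatrix(("1",), np.array([[1.0]]))
        with pytest.raises(ValueError, match="empty"):
            loocv(AssociationSet(frozenset()), normalize(sim))


class TestRoc:
    def test_worked_example_two_thirds(self):
        trials = [
            TrialResult("m", "a", rank=1, n_candidates=4),
            TrialResult("m", "b", rank=3, n_candidates=4),
        ]
        curve = roc_from_trials(trials)
        assert curve.auc == pytest.approx(2 / 3)
        assert brute_force_auc(trials) == pytest.approx(2 / 3)

    def test_perfect_ranking_auc_approaches_one(self):
        trials = [
            TrialResult("m", str(i), rank=1, n_candidates=100)
            for i in range(20)
        ]
        assert roc_from_trials(trials).auc == pytest.approx(1.0)

    def test_uniform_ranks_give_half(self):
        rng = np.random.default_rng(99)
        n_cand = 50
        trials = [
            TrialResult("m", str(i), rank=int(rng.integers(1, n_cand + 1)),
                        n_candidates=n_cand)
            for i in range(10_000)
        ]
        assert roc_from_trials(trials).auc == pytest.approx(0.5, abs=0.01)

    def test_rank_identity_matches_trapezoid(self):
        rng = np.random.default_rng(3)
        n_cand = 40  # equal candidate sets: pooled and per-trial agree
        trials = [
            TrialResult("m", str(i),
                        rank=int(rng.integers(1, n_cand // 2)),
                        n_candidates=n_cand)
            for i in range(500)
        ]
        curve = roc_from_trials(trials, n_thresholds=1000)
        assert curve.auc == pytest.approx(curve.auc_trapezoid, abs=1 / 1000 + 1e-3)

    def test_auc_matches_sklearn_on_pooled_percentiles(self):
        # independent cross-check of the rank identity (equal-size trials)
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        n_cand = 30
        trials = [
            TrialResult("m", str(i), rank=int(r), n_candidates=n_cand)
            for i, r in enumerate(rng.integers(1, n_cand + 1, size=400))
        ]
        y, s = [], []
        for t in trials:
            pct = (np.arange(1, n_cand + 1) - 0.5) / n_cand
            pos = int(t.rank) - 1
            for k, p in enumerate(pct):
                y.append(1 if k == pos else 0)
                s.append(-p)  # lower percentile = better score
        assert roc_from_trials(trials).auc == pytest.approx(
            roc_auc_score(y, s), abs=1e-9
        )

    def test_sensitivity_non_decreasing(self):
        trials = [
            TrialResult("m", str(i), rank=i + 1, n_candidates=10)
            for i in range(10)
        ]
        sens = [p[1] for p in roc_from_trials(trials, n_thresholds=100).points]
        assert all(b >= a for a, b in zip(sens, sens[1:]))

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            roc_from_trials([])


class TestAucInvariance:
    @pytest.mark.parametrize(
        "transform", [np.log, np.sqrt, lambda s: 10 * s + 3, np.expm1]
    )
    def test_midranks_invariant_under_monotone_score_transform(self, transform):
        # AUC depends on scores only through midranks, which any strictly
        # increasing transform preserves (including across ties)
        rng = np.random.default_rng(21)
        scores = rng.choice(np.linspace(0.1, 1.0, 12), size=40)
        raw = rankdata(-scores)
        transformed = rankdata(-transform(scores))
        np.testing.assert_array_equal(raw, transformed)


class TestSweep:
    def test_degenerate_all_zero_similarity_constant_auc(self):
        sim = SimilarityMatrix(("1", "2", "3"), np.eye(3))
        assoc = AssociationSet(
            frozenset({("m1", "1"), ("m1", "2"), ("m2", "2"), ("m2", "3")})
        )
        rows = parameter_sweep(assoc, sim, [0.2, 0.5, 0.8])
        aucs = {round(a, 12) for _, a in rows}
        assert len(aucs) == 1

    def test_signal_data_robust_to_restart_probability(self):
        sim, assoc, _ = generate(SyntheticConfig(rng_seed=17))
        rows = parameter_sweep(assoc, sim, [0.1, 0.3, 0.5, 0.7, 0.9])
        aucs = [a for _, a in rows]
        assert max(aucs) - min(aucs) < 0.1
        assert min(aucs) > 0.7

    def test_rows_follow_input_order(self):
        sim, assoc, _ = generate(SyntheticConfig(
            n_diseases=10, n_mirnas=5, n_clusters=2, rng_seed=2))
        rows = parameter_sweep(assoc, sim, [0.9, 0.1, 0.5])
        assert [r for r, _ in rows] == [0.9, 0.1, 0.5]


class TestSignalDestruction:
    def test_label_permutation_destroys_signal(self):
        cfg = SyntheticConfig(rng_seed=23)
        sim, assoc, _ = generate(cfg)
        auc_signal = roc_from_trials(loocv(assoc, normalize(sim))).auc
        rng = np.random.default_rng(23)
        perm = rng.permutation(sim.n)
        shuffled = SimilarityMatrix(
            tuple(sim.disease_ids[i] for i in perm), sim.values
        )
        auc_null = roc_from_trials(loocv(assoc, normalize(shuffled))).auc
        assert auc_signal > auc_null + 0.1
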