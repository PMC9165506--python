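import numpy as np
import pandas as pd
import pytest

import synpolar as sp

from conftest import random_signed_network


def ranked_from(pairs_scores_signs, method="test"):
    df = pd.DataFrame(pairs_scores_signs,
                      columns=["pre", "post", "score", "predicted_sign"])
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return sp.RankedPredictions(df, method=method)


class TestPrecisionCurve:
    def reference(self):
        #  truth: a->b +, a->c -, b->c -
        signs = np.zeros((3, 3), dtype=int)
        signs[0, 1], signs[0, 2], signs[1, 2] = 1, -1, -1
        return sp.SignedConnectome(("a", "b", "c"), signs)

    def test_hand_counted_hits(self):
        ranked = ranked_from([("a", "b", 3.0, 1), ("a", "c", 2.0, 1),
                              ("b", "c", -1.0, -1)])
        curve = sp.precision_curve(ranked, self.reference())
        np.testing.assert_allclose(curve.precision, [1.0, 0.5, 2 / 3])
        np.testing.assert_array_equal(curve.hits, [1, 0, 1])

    def test_perfect_agreement_is_flat_one(self):
        ranked = ranked_from([("a", "b", 3.0, 1), ("b", "c", -1.0, -1)])
        curve = sp.precision_curve(ranked, self.reference())
        np.testing.assert_array_equal(curve.precision, [1.0, 1.0])

    def test_pairs_without_reference_are_dropped_before_ranking(self):
        ranked = ranked_from([("a", "b", 3.0, 1), ("c", "a", 2.0, 1),
                              ("b", "c", -1.0, -1)])
        curve = sp.precision_curve(ranked, self.reference())
        assert len(curve) == 2
        np.testing.assert_array_equal(curve.score_at_rank, [3.0, 1.0])

    def test_empty_intersection_rejected(self):
        ranked = ranked_from([("c", "a", 1.0, 1)])
        with pytest.raises(sp.ValidationError, match="reference"):
            sp.precision_curve(ranked, self.reference())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_prefix_recount(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        ids = tuple(f"n{i}" for i in range(6))
        ref = random_signed_network(seed, n=6, density=0.9)
        pairs = [(ids[i], ids[j]) for i, j in zip(*np.nonzero(ref.signs))]
        scores = -np.sort(-rng.random(len(pairs)))
        predicted = rng.choice([-1, 1], size=len(pairs))
        ranked = ranked_from([(p, q, s * t, t) for (p, q), s, t in
                              zip(pairs, scores, predicted)])
        curve = sp.precision_curve(ranked, ref)
        idx = {lab: i for i, lab in enumerate(ids)}
        for r in range(1, len(curve) + 1):
            hits = sum(1 for (p, q), t in list(zip(pairs, predicted))[:r]
                       if ref.signs[idx[p], idx[q]] == t)
            assert curve.precision[r - 1] == pytest.approx(hits / r)


class TestThreshold:
    def curve(self, precisions, scores=None):
        p = np.asarray(precisions, dtype=float)
        r = np.arange(1, len(p) + 1)
        hits = np.r_[p[0], np.diff(p * r)]
        s = np.asarray(scores) if scores is not None else np.linspace(1, 0.1, len(p))
        return sp.PrecisionCurve(r, hits, p, s)

    def test_largest_qualifying_rank_and_cutoff(self):
        curve = self.curve([1.0, 0.5, 2 / 3], scores=[0.9, 0.5, 0.3])
        rank, cutoff = sp.threshold_for_precision(curve, 0.6)
        assert rank == 3
        assert cutoff == pytest.approx(0.3)

    def test_perfect_curve_returns_last_rank(self):
        curve = self.curve([1.0, 1.0, 1.0])
        assert sp.threshold_for_precision(curve, 1.0)[0] == 3

    def test_unreachable_target_warns_and_returns_none(self):
        curve = self.curve([0.0])
        with pytest.warns(UserWarning, match="no rank"):
            assert sp.threshold_for_precision(curve, 0.5) is None

    def test_target_must_be_in_unit_interval(self):
        with pytest.raises(sp.ValidationError):
            sp.threshold_for_precision(self.curve([1.0]), 0.0)


class TestRandomBaseline:
    @pytest.mark.parametrize("p, expect", [
        (0.64, 0.5392), (0.5, 0.5), (1.0, 1.0), (0.0, 1.0)])
    def test_analytic_values(self, p, expect):
        assert sp.random_baseline(p) == pytest.approx(expect)

    def test_out_of_range_rejected(self):
        with pytest.raises(sp.ValidationError):
            sp.random_baseline(1.2)

    def test_matches_monte_carlo_expectation(self):
        """Bernoulli truths vs independent Bernoulli predictions, 1e5 draws."""
        rng = np.random.default_rng(42)
        p = 0.64
        n = 100_000
        truth = np.where(rng.random(n) < p, 1, -1)
        pred = np.where(rng.random(n) < p, 1, -1)
        assert abs((truth == pred).mean() - sp.random_baseline(p)) < 0.005


class TestFolds:
    def pairs(self, n=20):
        return [(f"a{i}", f"b{i}") for i in range(n)]

    def test_folds_partition_pairs_near_equally(self):
        plan = sp.make_folds(self.pairs(), k=3, seed=0)
        sizes = [len(plan.fold_pairs(f)) for f in range(3)]
        assert sum(sizes) == 20
        assert max(sizes) - min(sizes) <= 1

    def test_same_seed_same_plan(self):
        p1 = sp.make_folds(self.pairs(), 4, seed=9)
        p2 = sp.make_folds(self.pairs(), 4, seed=9)
        assert p1.assignments == p2.assignments

    def test_bad_fold_counts_rejected(self):
        with pytest.raises(sp.ValidationError):
            sp.make_folds(self.pairs(), 1, seed=0)
        with pytest.raises(sp.ValidationError):
            sp.make_folds(self.pairs(3), 5, seed=0)


class TestKfoldCV:
    def test_two_fold_sl3_curves_recomputable_by_hand(self):
        """k=2 on a dense 4-node toy network: verify the mean curve by enumeration."""
        ids = ("a", "b", "c", "d")
        signs = np.ones((4, 4), dtype=int)
        signs[1, 0] = signs[2, 0] = -1
        np.fill_diagonal(signs, 0)
        A = sp.SignedConnectome(ids, signs)
        pairs = [(ids[i], ids[j]) for i, j in zip(*np.nonzero(signs))]
        plan = sp.make_folds(pairs, 2, seed=1)
        curve = sp.kfold_cv("sl3", A, plan)
        # oracle: recompute each fold from scratch with the same machinery
        per_fold = []
        for f in range(2):
            test = plan.fold_pairs(f)
            idx = {lab: i for i, lab in enumerate(A.neuron_ids)}
            s = A.signs.copy()
            for p, q in test:
                s[idx[p], idx[q]] = 0
            P = s @ s.T @ s
            scored = sorted(
                ((p, q, P[idx[p], idx[q]]) for p, q in test
                 if P[idx[p], idx[q]] != 0),
                key=lambda t: (-abs(t[2]), t[0], t[1]))
            hits = [1 if np.sign(t[2]) == A.signs[idx[t[0]], idx[t[1]]] else 0
                    for t in scored]
            per_fold.append(np.cumsum(hits) / np.arange(1, len(hits) + 1))
        r = min(map(len, per_fold))
        if r:
            expect = np.mean([p[:r] for p in per_fold], axis=0)
            np.testing.assert_allclose(curve.precision[:r], expect)

    def test_deterministic_under_fixed_seed(self, planted_half_hidden):
        ds = planted_half_hidden
        ii, jj = np.nonzero(ds.A_known.signs)
        pairs = [(ds.A_known.neuron_ids[i], ds.A_known.neuron_ids[j])
                 for i, j in zip(ii, jj)]
        plan = sp.make_folds(pairs, 5, seed=3)
        c1 = sp.kfold_cv("spa", ds.A_known, plan)
        c2 = sp.kfold_cv("spa", ds.A_known, plan)
        np.testing.assert_array_equal(c1.precision, c2.precision)

    def test_scm_near_perfect_on_noiseless_planted_data(self, planted_half_hidden):
        """Cross-validated learned rules reproduce noiseless planted labels."""
        ds = planted_half_hidden
        ii, jj = np.nonzero(ds.A_known.signs)
        pairs = [(ds.A_known.neuron_ids[i], ds.A_known.neuron_ids[j])
                 for i, j in zip(ii, jj)]
        plan = sp.make_folds(pairs, 5, seed=2)
        curve = sp.kfold_cv("scm", ds.A_known, plan, X=ds.X, Y=ds.Y,
                            cfg=sp.RidgeConfig(alpha=1.0))
        assert curve.precision.mean() > 0.98

    def test_scm_requires_expression(self, planted_half_hidden):
        ds = planted_half_hidden
        plan = sp.make_folds(list(ds.hidden_pairs), 2, seed=0)
        with pytest.raises(sp.ValidationError, match="expression"):
            sp.kfold_cv("scm", ds.A_full, plan)


class TestSubsampling:
    def test_fraction_one_reproduces_full_input_curve(self, planted_half_hidden):
        ds = planted_half_hidden
        hidden = list(ds.hidden_pairs)
        table = sp.subsample_experiment(
            ds.X, ds.Y, ds.A_known, ds.A_full, hidden,
            fraction_grid=[1.0], seed=0, reps=2, cfg=sp.RidgeConfig(alpha=1.0))
        ii, jj = np.nonzero(ds.A_known.signs)
        pairs = [(ds.A_known.neuron_ids[i], ds.A_known.neuron_ids[j])
                 for i, j in zip(ii, jj)]
        O_t = sp.fit_scm(ds.X, ds.Y, ds.A_known, pairs, sp.RidgeConfig(alpha=1.0))
        full = sp.precision_curve(
            sp.rank_and_threshold(sp.scm_scores(ds.X, O_t, ds.Y), hidden),
            ds.A_full)
        rank, _ = sp.threshold_for_precision(full, 0.95)
        assert (table["rank_at_target"] == rank).all()

    def test_invalid_fraction_rejected(self, planted_half_hidden):
        ds = planted_half_hidden
        with pytest.raises(sp.ValidationError, match="fraction"):
            sp.subsample_experiment(ds.X, ds.Y, ds.A_known, ds.A_full,
                                    list(ds.hidden_pairs), [0.0], seed=0)


class TestUnionReport:
    def nets(self):
        ids = ("a", "b", "c")
        known = sp.SignedConnectome(ids, [[0, 1, 0], [0, 0, -1], [0, 0, 0]])
        cm = sp.SignedConnectome(ids, [[0, 0, 1], [0, 0, 0], [0, 0, 0]])
        scm = sp.SignedConnectome(ids, [[0, 0, 0], [0, 0, 0], [-1, 0, 0]])
        return known, cm, scm

    def test_counts_and_ratios(self):
        known, cm, scm = self.nets()
        rep = sp.union_report(known, cm, scm)
        assert rep["total_resolved"] == 4
        assert rep["added_excitatory"] == 1
        assert rep["added_inhibitory"] == 1
        assert rep["ei_ratio_before"] == pytest.approx(1.0)
        assert rep["ei_ratio_after"] == pytest.approx(1.0)

    def test_empty_additions_reproduce_known_tallies(self):
        known, _, _ = self.nets()
        zero = sp.SignedConnectome(known.neuron_ids, np.zeros((3, 3), dtype=int))
        rep = sp.union_report(known, zero, zero)
        assert rep["total_resolved"] == 2
        assert rep["total_excitatory"] == rep["known_excitatory"] == 1

    def test_overlap_is_an_error_listing_conflicts(self):
        known, cm, _ = self.nets()
        clash = sp.SignedConnectome(known.neuron_ids,
                                    [[0, -1, 0], [0, 0, 0], [0, 0, 0]])
        with pytest.raises(sp.ValidationError, match="overlapping"):
            sp.union_report(known, cm, clash)
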