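"""AUC family (per-protein, wAUC, mAUC, tAUC), funnel, count estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from rbscore.evaluate import (
    CountEstimator,
    UndefinedAUCError,
    auc_single,
    evaluate_dataset,
    fit_count_estimator,
    funnel_correlation,
    mauc,
    six_type_fraction,
    tauc,
    wauc,
)
from rbscore.synthetic import make_planted_funnel


def brute_force_auc(scores, labels):
    """Exhaustive Mann-Whitney count over all positive x negative pairs."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAucSingle:
    def test_perfect_ranking(self):
        scores = np.array([5.0, 4.0, 1.0, 0.0])
        labels = np.array([True, True, False, False])
        assert auc_single(scores, labels) == 1.0

    def test_all_ties_give_half(self):
        assert auc_single(np.ones(10), np.arange(10) < 3) == 0.5

    def test_matches_brute_force_and_sklearn(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            scores = rng.normal(size=20).round(1)  # rounding forces ties
            labels = np.zeros(20, dtype=bool)
            labels[rng.choice(20, 6, replace=False)] = True
            got = auc_single(scores, labels)
            assert got == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
            assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedAUCError):
            auc_single(np.arange(4.0), np.ones(4, dtype=bool))

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.3
        if labels.sum() in (0, 30):
            labels[:3] = True
        base = auc_single(scores, labels)
        for transform in (lambda s: 3 * s + 7, np.exp, lambda s: s ** 3):
            assert auc_single(transform(scores), labels) == pytest.approx(base)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(14)
        scores = rng.permutation(25).astype(float)  # tie-free
        labels = rng.random(25) < 0.4
        labels[0], labels[1] = True, False
        assert auc_single(scores, labels) == pytest.approx(1 - auc_single(scores, ~labels))


class TestAggregates:
    def test_weighted_and_plain_means(self):
        assert wauc([1.0, 0.5], [10, 30]) == pytest.approx(0.625)
        assert mauc([1.0, 0.5]) == pytest.approx(0.75)

    def test_single_protein_degenerate(self):
        assert wauc([0.83], [57]) == pytest.approx(0.83)
        assert mauc([0.83]) == pytest.approx(0.83)

    def test_equal_lengths_collapse_to_mauc(self):
        aucs = [0.9, 0.6, 0.7, 0.85]
        assert wauc(aucs, [50] * 4) == pytest.approx(mauc(aucs))

    def test_bounded_by_extremes(self):
        rng = np.random.default_rng(15)
        aucs = rng.uniform(0.4, 1.0, 8)
        lengths = rng.integers(20, 300, 8)
        w = wauc(aucs, lengths)
        assert aucs.min() <= w <= aucs.max()
        assert aucs.min() <= mauc(aucs) <= aucs.max()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wauc([], [])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.floats(0.0, 1.0), st.integers(1, 500)),
                    min_size=1, max_size=12))
    def test_wauc_mauc_are_convex_combinations(self, pairs):
        aucs = [a for a, _ in pairs]
        lengths = [n for _, n in pairs]
        assert min(aucs) - 1e-12 <= wauc(aucs, lengths) <= max(aucs) + 1e-12
        assert min(aucs) - 1e-12 <= mauc(aucs) <= max(aucs) + 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_auc_invariant_to_affine_rescaling(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = rng.random(20) < 0.4
        labels[0], labels[1] = True, False
        assert auc_single(scale * scores + shift, labels) == pytest.approx(
            auc_single(scores, labels), abs=1e-12)


class TestTauc:
    def test_single_protein_equals_auc(self):
        scores = np.array([3.0, 2.0, 1.0, 0.0])
        labels = np.array([True, False, True, False])
        assert tauc([scores], [labels]) == pytest.approx(auc_single(scores, labels))

    def test_pooling_breaks_perfect_per_protein_ranking(self):
        # each protein ranks perfectly, but their score ranges don't overlap:
        # protein B's negatives outscore protein A's positives
        s_a = np.array([2.0, 1.0, 0.0])
        l_a = np.array([True, False, False])
        s_b = np.array([12.0, 11.0, 10.0])
        l_b = np.array([True, False, False])
        w = wauc([auc_single(s_a, l_a), auc_single(s_b, l_b)], [3, 3])
        t = tauc([s_a, s_b], [l_a, l_b])
        assert w == 1.0
        assert t == pytest.approx(brute_force_auc(np.concatenate([s_a, s_b]),
                                                  np.concatenate([l_a, l_b])))
        assert t < 1.0

    def test_matches_brute_force_on_pooled_random_case(self):
        rng = np.random.default_rng(16)
        score_lists = [rng.normal(size=n).round(1) for n in (10, 15, 8)]
        label_lists = [rng.random(n) < 0.4 for n in (10, 15, 8)]
        label_lists[0][0] = True
        label_lists[0][1] = False
        pooled_s = np.concatenate(score_lists)
        pooled_l = np.concatenate(label_lists)
        assert tauc(score_lists, label_lists) == pytest.approx(
            brute_force_auc(pooled_s, pooled_l), abs=1e-12)


class TestEvaluateDataset:
    def test_skips_single_class_proteins(self):
        rng = np.random.default_rng(17)
        good = ("good", rng.normal(size=30), rng.random(30) < 0.3)
        degenerate = ("allneg", rng.normal(size=25), np.zeros(25, dtype=bool))
        good[2][:3] = True
        report = evaluate_dataset([good, degenerate], cutoff=3.5)
        assert report.names == ["good"]
        assert report.skipped[0][0] == "allneg"
        assert report.wauc == report.mauc  # one protein left

    def test_cutoff_ladder_never_crashes(self, toy_fixture):
        from rbscore.structure import compute_delta_asa, label_binding_residues
        cx, _, _ = toy_fixture
        rng = np.random.default_rng(18)
        scores = rng.normal(size=len(cx.protein_chains["A"]))
        dasa = compute_delta_asa(cx, "A", density=240)
        reports = []
        for cutoff in np.arange(3.5, 6.01, 0.5):
            labels = label_binding_residues(cx, "A", cutoff=float(cutoff), delta_asa=dasa)
            reports.append(evaluate_dataset([("toy", scores, labels.labels)],
                                            cutoff=float(cutoff)))
        assert len(reports) == 6


class TestFunnel:
    def test_perfect_antimonotone(self):
        d = np.linspace(1, 15, 40)
        prof = funnel_correlation(d, -d)
        assert prof.pearson_r == pytest.approx(-1.0)

    def test_constant_scores_undefined(self):
        with pytest.raises(ValueError):
            funnel_correlation(np.linspace(1, 15, 10), np.ones(10))

    def test_region_limit_masks_far_residues(self):
        d = np.array([1.0, 5.0, 10.0, 30.0, 40.0])
        s = np.array([4.8, 4.0, 3.0, 100.0, -50.0])  # 5 - 0.2 d inside the region
        prof = funnel_correlation(d, s, region_limit=20.0)
        assert prof.mask.sum() == 3
        assert prof.pearson_r == pytest.approx(-1.0)

    def test_planted_funnel_recovered(self):
        d, s = make_planted_funnel(n=200, slope=-1.0, noise_sigma=0.1, seed=20)
        prof = funnel_correlation(d, s)
        assert abs(prof.pearson_r) >= 0.8

    def test_too_few_residues_in_region(self):
        with pytest.raises(ValueError):
            funnel_correlation(np.array([30.0, 40.0, 1.0]), np.array([1.0, 2.0, 3.0]))


class TestCountEstimator:
    def test_recovers_noiseless_linear_relation(self):
        rng = np.random.default_rng(21)
        seqs, counts = [], []
        for _ in range(20):
            n = int(rng.integers(50, 200))
            six = rng.integers(5, n // 2)
            seq = "R" * six + "L" * (n - six)
            seqs.append(seq)
            counts.append(0.5 * six_type_fraction(seq) * n)
        est = fit_count_estimator(seqs, counts)
        assert est.slope == pytest.approx(0.5, abs=1e-6)
        assert est.intercept == pytest.approx(0.0, abs=1e-6)
        assert est.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_zero_composition_boundary(self):
        est = CountEstimator(slope=0.5, intercept=0.02, pearson_r=0.8)
        assert est.estimate_binding_count("LLLLLLLLLL") == round(0.02 * 10)
        negative = CountEstimator(slope=0.5, intercept=-0.5, pearson_r=0.8)
        assert negative.estimate_binding_count("LLLL") == 0

    def test_noisy_fit_near_population_r(self):
        rng = np.random.default_rng(22)
        slope, n = 0.5, 100
        x = rng.uniform(0.1, 0.4, n)
        noise_sd = slope * x.std() * np.sqrt(1 / 0.8 ** 2 - 1)  # population r = 0.8
        y = np.clip(slope * x + rng.normal(0, noise_sd, n), 0.0, 1.0)
        lengths = rng.integers(60, 300, n)
        seqs = []
        for xi, L in zip(x, lengths):
            k = int(round(xi * L))
            seqs.append("K" * k + "A" * (int(L) - k))
        counts = [yi * len(s) for yi, s in zip(y, seqs)]
        est = fit_count_estimator(seqs, counts)
        assert est.pearson_r == pytest.approx(0.8, abs=0.1)
        assert est.slope == pytest.approx(slope, rel=0.3)

    def test_degenerate_composition_rejected(self):
        with pytest.raises(ValueError):
            fit_count_estimator(["KKAA", "KKAA", "KKAA"], [1, 2, 3])

    def test_six_types(self):
        assert six_type_fraction("RDGHKT") == 1.0
        assert six_type_fraction("LLLL") == 0.0
        assert six_type_fraction("RL") == 0.5
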