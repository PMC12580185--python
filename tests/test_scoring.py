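"""Filter scorers, fusion, knee detection and dual-task construction.

Every scorer is checked against an independent direct-formula or brute-force
oracle written as a plain transcription of its definition.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swarmfs import (
    ScoringConfig,
    compute_fisher_score,
    compute_pcc_score,
    compute_relief_f,
    compute_variance_score,
    detect_knee,
    fuse_scores,
    generate_tasks,
    informative_recall,
    make_synthetic_dataset,
    normalize_scores,
)
from swarmfs.datasets import SyntheticSpec

# ---------------------------------------------------------------- oracles


def fisher_oracle(X, y):
    """Direct transcription: between-class over within-class scatter."""
    d = X.shape[1]
    out = np.zeros(d)
    mu = X.mean(axis=0)
    for j in range(d):
        num = den = 0.0
        for c in np.unique(y):
            col = X[y == c, j]
            num += len(col) * (col.mean() - mu[j]) ** 2
            den += len(col) * col.var()
        out[j] = num / (den + 1e-12)
    return out


def pcc_oracle(X, y):
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if col.std() == 0 or np.std(y) == 0:
            out[j] = 0.0
        else:
            out[j] = abs(np.corrcoef(col, y)[0, 1])
    return out


def relief_oracle(X, y, k):
    """Brute-force Relief-F: exhaustive distance sort per sampled instance."""
    n, d = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    Z = (X - lo) / span
    classes = np.unique(y)
    prior = {c: np.sum(y == c) / n for c in classes}
    w = np.zeros(d)
    for i in range(n):
        dists = np.abs(Z - Z[i]).sum(axis=1)
        same = [j for j in range(n) if y[j] == y[i] and j != i]
        same.sort(key=lambda j: (dists[j], j))
        hits = same[: min(k, len(same))]
        if hits:
            w -= np.mean([np.abs(Z[i] - Z[h]) for h in hits], axis=0)
        for c in classes:
            if c == y[i]:
                continue
            other = [j for j in range(n) if y[j] == c]
            other.sort(key=lambda j: (dists[j], j))
            miss = other[: min(k, len(other))]
            w += (prior[c] / (1 - prior[y[i]])) * np.mean(
                [np.abs(Z[i] - Z[m]) for m in miss], axis=0
            )
    return w / n


def knee_oracle(s):
    """Exhaustive max perpendicular distance to the endpoint chord."""
    d = len(s)
    x0, y0, x1, y1 = 0.0, s[0], float(d - 1), s[-1]
    hyp = np.hypot(x1 - x0, y1 - y0)
    dists = [
        abs((y1 - y0) * i - (x1 - x0) * (s[i] - y0)) / hyp for i in range(d)
    ]
    if max(dists) <= 1e-12 * max(1.0, abs(y1 - y0)) / hyp:
        return int(np.ceil(d / 2)) - 1
    return int(np.argmax(dists))


# ---------------------------------------------------------------- Fisher


class TestFisherScore:
    def test_hand_worked_two_class_example(self):
        # class A = {0, 1}, class B = {2, 3}: numerator 4, denominator 1
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        assert compute_fisher_score(X, y)[0] == pytest.approx(4.0, rel=1e-9)

    def test_constant_feature_scores_zero(self, toy_xy):
        X, y = toy_xy
        assert compute_fisher_score(X, y)[1] == 0.0

    def test_sample_order_invariance(self, rng, small_dataset):
        ds = small_dataset
        perm = rng.permutation(ds.n_samples)
        a = compute_fisher_score(ds.X, ds.y)
        b = compute_fisher_score(ds.X[perm], ds.y[perm])
        np.testing.assert_allclose(a, b, rtol=1e-10, atol=1e-12)

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(10):
            n, d = int(rng.integers(6, 50)), int(rng.integers(2, 10))
            X = rng.normal(size=(n, d))
            y = rng.integers(0, 3, size=n)
            if np.unique(y).size < 2:
                continue
            np.testing.assert_allclose(
                compute_fisher_score(X, y), fisher_oracle(X, y), atol=1e-10
            )

    @pytest.mark.parametrize(
        "X, y, msg",
        [
            (np.zeros((4, 2)), np.zeros(4, dtype=int), "classes"),
            (np.full((4, 2), np.nan), np.array([0, 0, 1, 1]), "finite"),
        ],
    )
    def test_invalid_inputs_rejected(self, X, y, msg):
        with pytest.raises(ValueError, match=msg):
            compute_fisher_score(X, y)


# ---------------------------------------------------------------- Relief-F


class TestReliefF:
    def test_constant_feature_weight_exactly_zero(self, toy_xy):
        X, y = toy_xy
        w = compute_relief_f(X, y, ScoringConfig(relief_neighbors=1))
        assert w[1] == 0.0

    def test_separating_feature_is_strict_maximum(self):
        rng = np.random.default_rng(5)
        n = 30
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 8))
        X[:, 3] = y * 6.0 + rng.normal(scale=0.1, size=n)  # clean separator
        w = compute_relief_f(X, y, ScoringConfig(relief_neighbors=5))
        assert np.argmax(w) == 3
        assert w[3] > np.max(np.delete(w, 3))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(8):
            n, d = int(rng.integers(8, 50)), int(rng.integers(2, 10))
            y = rng.integers(0, 3, size=n)
            if np.unique(y).size < 2:
                continue
            X = rng.normal(size=(n, d))
            k = int(rng.integers(1, 6))
            got = compute_relief_f(X, y, ScoringConfig(relief_neighbors=k))
            np.testing.assert_allclose(got, relief_oracle(X, y, k), atol=1e-10)

    def test_deterministic_with_all_samples(self, small_dataset):
        ds = small_dataset
        cfg = ScoringConfig()
        a = compute_relief_f(ds.X, ds.y, cfg, np.random.default_rng(1))
        b = compute_relief_f(ds.X, ds.y, cfg, np.random.default_rng(99))
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            compute_relief_f(np.eye(3), np.zeros(3, dtype=int))


# ------------------------------------------------------- PCC and variance


class TestAblationScorers:
    def test_label_copy_feature_has_unit_pcc(self):
        y = np.array([0, 1, 0, 1, 1])
        X = np.column_stack([y.astype(float), np.ones(5)])
        s = compute_pcc_score(X, y)
        assert s[0] == pytest.approx(1.0)
        assert s[1] == 0.0  # zero-variance feature defined as 0

    def test_pcc_matches_direct_formula(self, rng):
        X = rng.normal(size=(25, 8))
        y = rng.integers(0, 3, size=25)
        np.testing.assert_allclose(
            compute_pcc_score(X, y), pcc_oracle(X, y), atol=1e-12
        )

    def test_variance_of_constant_feature_is_zero(self, toy_xy):
        X, _ = toy_xy
        assert compute_variance_score(X)[1] == 0.0


# ------------------------------------------------- normalization / fusion


class TestNormalizeAndFuse:
    def test_minmax_example(self):
        np.testing.assert_allclose(
            normalize_scores([2.0, 4.0, 6.0]), [0.0, 0.5, 1.0]
        )

    def test_degenerate_range_maps_to_zeros(self):
        np.testing.assert_array_equal(
            normalize_scores([5.0, 5.0, 5.0]), np.zeros(3)
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=20),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_affine_invariance(self, vals, a, b):
        s = np.asarray(vals)
        np.testing.assert_allclose(
            normalize_scores(a * s + b), normalize_scores(s), atol=1e-9
        )

    @pytest.mark.parametrize(
        "alpha, beta, rf, fs, expected",
        [
            (1.0, 0.0, [0.3, 0.9], [0.5, 0.1], [0.3, 0.9]),
            (0.5, 0.5, [1.0, 0.0], [0.0, 1.0], [0.5, 0.5]),
            (0.5, 0.5, [0.8, 0.2], [0.4, 0.6], [0.6, 0.4]),
        ],
    )
    def test_fusion_examples(self, alpha, beta, rf, fs, expected):
        cfg = ScoringConfig(alpha=alpha, beta=beta)
        np.testing.assert_allclose(fuse_scores(rf, fs, cfg), expected)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0, 5), st.integers(1, 10))
    def test_fusion_is_linear(self, scale, d):
        rng = np.random.default_rng(d)
        u, v = rng.random(d), rng.random(d)
        cfg = ScoringConfig(alpha=0.3, beta=0.7)
        np.testing.assert_allclose(
            fuse_scores(scale * u, scale * v, cfg),
            scale * fuse_scores(u, v, cfg),
            atol=1e-10,
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            fuse_scores(np.ones(3), np.ones(4))


# ---------------------------------------------------------------- knee


class TestKneeDetection:
    def test_hand_worked_curve(self):
        res = detect_knee([1.0, 0.9, 0.2, 0.15, 0.1])
        assert res.knee_index == 2
        assert res.selected_count == 3
        assert res.threshold_score == 0.2

    def test_collinear_curve_falls_back_to_top_half(self):
        res = detect_knee([4.0, 3.0, 2.0, 1.0])
        assert res.selected_count == 2
        assert res.knee_index == 1

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(3, 60), st.floats(-10, 10))
    def test_translation_invariance(self, d, shift):
        rng = np.random.default_rng(d)
        s = np.sort(rng.random(d))[::-1]
        assert detect_knee(s + shift).knee_index == detect_knee(s).knee_index

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            d = int(rng.integers(2, 300))
            s = np.sort(rng.random(d))[::-1]
            assert detect_knee(s).knee_index == knee_oracle(s)

    @pytest.mark.parametrize("bad", [[1.0], [0.1, 0.5, 0.2]])
    def test_invalid_curves_rejected(self, bad):
        with pytest.raises(ValueError):
            detect_knee(bad)


# ---------------------------------------------------------- task pairing


class TestGenerateTasks:
    def test_mask_bounds_and_subset_relation(self, small_dataset):
        ds = small_dataset
        tasks = generate_tasks(ds.X, ds.y, rng=np.random.default_rng(0))
        aux = tasks.auxiliary_mask
        assert tasks.primary_mask.all()
        assert 1 <= aux.sum() < ds.n_features
        assert np.all(~aux | tasks.primary_mask)  # aux subset of primary

    def test_recovers_planted_features_on_benchmark(self):
        ds = make_synthetic_dataset(SyntheticSpec(seed=1))
        tasks = generate_tasks(ds.X, ds.y, rng=np.random.default_rng(1))
        recall = informative_recall(tasks.auxiliary_mask, ds.informative)
        assert recall >= 0.8

    def test_deterministic_given_seed(self, small_dataset):
        ds = small_dataset
        a = generate_tasks(ds.X, ds.y, rng=np.random.default_rng(7))
        b = generate_tasks(ds.X, ds.y, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a.auxiliary_mask, b.auxiliary_mask)
        np.testing.assert_array_equal(a.ranking, b.ranking)
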