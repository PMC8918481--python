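"""Sample weights, triplets, the weighted large-margin loss and its fit."""

import numpy as np
import pytest
from conftest import (
    brute_sample_weight,
    brute_weighted_loss,
    mean_anchor_margin,
    random_instance,
)

from imfuse import (
    DensityParams,
    ImlmnnConfig,
    LabeledDataset,
    LinearTransform,
    SyntheticSpec,
    apply_transform,
    build_triplets,
    class_center,
    fit_imlmnn,
    generate_synthetic,
    imlmnn_gradient,
    imlmnn_loss,
    lmnn_loss,
    sample_density,
    sample_weights,
)
from imfuse.exceptions import InsufficientSamplesError
from imfuse.imlmnn import load_transform, save_transform


class TestClassCenter:
    def test_midpoint(self):
        ds = LabeledDataset(np.array([[0., 0], [2, 2], [9, 9]]),
                            np.array([0, 0, 1]))
        assert np.allclose(class_center(ds, 0), [1, 1])
        assert np.allclose(class_center(ds, 1), [9, 9])

    def test_matches_column_loop(self, rng):
        X = rng.standard_normal((25, 5))
        y = np.array([0] * 20 + [1] * 5)
        ds = LabeledDataset(X, y)
        manual = np.array([sum(X[i][j] for i in range(20)) / 20
                           for j in range(5)])
        assert np.allclose(class_center(ds, 0), manual, atol=1e-12)

    def test_empty_class(self):
        ds = LabeledDataset(np.zeros((3, 1)) + [[1], [2], [3]],
                            np.array([0, 0, 0]))
        with pytest.raises(InsufficientSamplesError):
            class_center(ds, 1)


class TestSampleDensity:
    def test_unit_distances(self):
        ds = LabeledDataset(np.array([[0.], [1.], [2.]]), np.array([0, 0, 1]))
        dn, dp, d = sample_density(1, ds, DensityParams(k=1, h=1))
        assert (dn, dp, d) == (1.0, 1.0, 2.0)

    def test_duplicate_clamped_to_epsilon(self):
        ds = LabeledDataset(np.array([[0.], [0.], [5.], [9.]]),
                            np.array([0, 0, 1, 1]))
        dn, dp, d = sample_density(0, ds, DensityParams(k=1, h=1))
        assert dn == 1.0 / 1e-12 and np.isfinite(d)

    def test_matches_full_sort_oracle(self, rng):
        ds = random_instance(rng, n_max=30, d_max=2)
        params = DensityParams(k=3, h=3)
        for i in range(ds.n):
            dists = np.linalg.norm(ds.features - ds.features[i], axis=1)
            maj = sorted(dists[j] for j in range(ds.n)
                         if ds.labels[j] == 0 and j != i)
            mino = sorted(dists[j] for j in range(ds.n)
                          if ds.labels[j] == 1 and j != i)
            dn, dp, _ = sample_density(i, ds, params)
            assert dn == pytest.approx(1 / (sum(maj[:3]) / 3), abs=1e-12)
            assert dp == pytest.approx(1 / (sum(mino[:3]) / 3), abs=1e-12)

    def test_insufficient_neighbors(self):
        ds = LabeledDataset(np.arange(4.)[:, None], np.array([0, 0, 1, 1]))
        with pytest.raises(InsufficientSamplesError):
            sample_density(0, ds, DensityParams(k=2, h=1))


def mirrored_fixture():
    """Minority pair and a majority quad with identical within-class
    nearest distances (2), identical cross-class nearest distances (5)
    and identical distance to the own class center (1), so the weight
    ratio reduces to the class-size ratio exactly."""
    H = 5.0
    minority = np.array([[-1.0, 0.0], [1.0, 0.0]])
    majority = np.array([[-3.0, H], [-1.0, H], [1.0, H], [3.0, H]])
    X = np.vstack([majority, minority])
    y = np.array([0, 0, 0, 0, 1, 1])
    return LabeledDataset(X, y)


class TestSampleWeights:
    def test_mirrored_fixture_ratio_is_class_size_ratio(self):
        ds = mirrored_fixture()
        w = sample_weights(ds, DensityParams(k=1, h=1))
        w_maj = w[2]   # (1, H): distance 1 from majority center (0, H)
        w_min = w[5]   # (1, 0): distance 1 from minority center (0, 0)
        assert w_min / w_maj == 2.0  # |N_majority| / |N_minority| = 4/2

    def test_sample_at_center_stays_finite(self):
        X = np.array([[0., 0], [-1, 0], [1, 0], [8, 0], [9, 0]])
        y = np.array([0, 0, 0, 1, 1])
        w = sample_weights(LabeledDataset(X, y), DensityParams(k=1, h=1))
        assert np.isfinite(w).all() and (w > 0).all()

    def test_matches_straight_line_oracle(self, rng):
        ds = random_instance(rng, n_max=40, d_max=4)
        k = h = 2
        w = sample_weights(ds, DensityParams(k=k, h=h))
        for i in range(ds.n):
            expected = brute_sample_weight(ds.features, ds.labels, i, k, h)
            assert w[i] == pytest.approx(expected, rel=1e-12)


class TestBuildTriplets:
    def test_counts(self):
        ds = LabeledDataset(np.arange(12.).reshape(6, 2),
                            np.array([0, 0, 0, 1, 1, 1]))
        t = build_triplets(ds, 1)
        assert len(t.pull_pairs) == 6
        assert len(t.push_triplets) == 18

    def test_exhaustive_neighbors_cover_all_same_class_pairs(self):
        ds = LabeledDataset(np.arange(12.).reshape(6, 2),
                            np.array([0, 0, 0, 1, 1, 1]))
        t = build_triplets(ds, 2)  # class size - 1
        pairs = {tuple(p) for p in t.pull_pairs}
        expected = {(i, j) for i in range(6) for j in range(6)
                    if i != j and ds.labels[i] == ds.labels[j]}
        assert pairs == expected

    def test_pull_pairs_match_distance_sort_oracle(self, rng):
        ds = random_instance(rng, n_max=25, d_max=3)
        k = 2
        t = build_triplets(ds, k)
        for i in range(ds.n):
            dists = np.linalg.norm(ds.features - ds.features[i], axis=1)
            cands = [j for j in range(ds.n)
                     if j != i and ds.labels[j] == ds.labels[i]]
            cands.sort(key=lambda j: (dists[j], j))  # ties by lower index
            got = [j for a, j in t.pull_pairs if a == i]
            assert sorted(got) == sorted(cands[:k])

    def test_class_too_small(self):
        ds = LabeledDataset(np.arange(8.)[:, None], np.array([0, 0, 0, 0, 0, 0, 1, 1]))
        with pytest.raises(InsufficientSamplesError):
            build_triplets(ds, 2)


class TestLoss:
    def test_zero_map_gives_margin_times_weight_sum(self, rng):
        ds = random_instance(rng)
        t = build_triplets(ds, 1)
        w = rng.uniform(0.5, 2.0, ds.n)
        margin = 0.7
        expected = margin * w[t.push_triplets[:, 0]].sum()
        L = np.zeros((ds.d, ds.d))
        assert imlmnn_loss(L, ds, w, t, margin) == pytest.approx(expected, rel=1e-12)

    def test_separated_classes_leave_pull_term_only(self):
        # classes 100 apart: every impostor hinge is inactive under identity
        X = np.vstack([np.random.default_rng(0).standard_normal((5, 2)),
                       np.random.default_rng(1).standard_normal((5, 2)) + 100])
        ds = LabeledDataset(X, np.array([0] * 5 + [1] * 5))
        t = build_triplets(ds, 2)
        w = np.ones(ds.n)
        L = np.eye(2)
        pull_only = sum(w[i] * np.sum((X[i] - X[j]) ** 2)
                        for i, j in t.pull_pairs)
        assert imlmnn_loss(L, ds, w, t, 1.0) == pytest.approx(pull_only, rel=1e-12)

    def test_matches_brute_force(self, rng):
        ds = random_instance(rng, n_max=12, d_max=3)
        t = build_triplets(ds, 1)
        w = rng.uniform(0.1, 3.0, ds.n)
        L = rng.standard_normal((2, ds.d))
        expected = brute_weighted_loss(L, ds.features, w, t.pull_pairs,
                                       t.push_triplets, 1.0)
        assert imlmnn_loss(L, ds, w, t, 1.0) == pytest.approx(expected, abs=1e-10)

    def test_lmnn_is_unit_weight_reduction(self, rng):
        ds = random_instance(rng, n_max=15, d_max=3)
        t = build_triplets(ds, 1)
        L = rng.standard_normal((ds.d, ds.d))
        assert lmnn_loss(L, ds, t, 1.0) == pytest.approx(
            imlmnn_loss(L, ds, np.ones(ds.n), t, 1.0), abs=1e-12)

    def test_dimension_mismatch(self, rng):
        ds = random_instance(rng, n_max=12, d_max=3)
        t = build_triplets(ds, 1)
        with pytest.raises(ValueError):
            imlmnn_loss(np.zeros((2, ds.d + 1)), ds, np.ones(ds.n), t)


class TestGradient:
    def _instance(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_instance(rng, n_max=10, d_max=3)
        t = build_triplets(ds, 1)
        w = rng.uniform(0.1, 2.0, ds.n)
        return rng, ds, t, w

    def test_central_difference(self):
        rng, ds, t, w = self._instance(3)
        # pick an L where no hinge argument sits near the kink
        from imfuse.imlmnn import _LossContext
        ctx = _LossContext(ds.features, w, t, 1.0)
        L = None
        for _ in range(50):
            cand = rng.standard_normal((2, ds.d))
            if np.abs(ctx._hinge(cand)).min() > 1e-3:
                L = cand
                break
        assert L is not None
        g = imlmnn_gradient(L, ds, w, t, 1.0)
        num = np.zeros_like(g)
        h = 1e-6
        for a in range(g.shape[0]):
            for b in range(g.shape[1]):
                Lp, Lm = L.copy(), L.copy()
                Lp[a, b] += h
                Lm[a, b] -= h
                num[a, b] = (imlmnn_loss(Lp, ds, w, t, 1.0)
                             - imlmnn_loss(Lm, ds, w, t, 1.0)) / (2 * h)
        rel = np.abs(g - num) / max(1.0, np.abs(num).max())
        assert rel.max() < 1e-5

    def test_zero_map_has_zero_gradient(self):
        _, ds, t, w = self._instance(5)
        g = imlmnn_gradient(np.zeros((ds.d, ds.d)), ds, w, t, 1.0)
        assert np.all(g == 0.0)

    def test_linear_in_weights(self):
        rng, ds, t, w = self._instance(7)
        L = rng.standard_normal((ds.d, ds.d))
        g1 = imlmnn_gradient(L, ds, w, t, 1.0)
        g2 = imlmnn_gradient(L, ds, 2 * w, t, 1.0)
        assert np.allclose(g2, 2 * g1, rtol=1e-12)


class TestFit:
    def test_zero_iterations_returns_truncated_identity(self, small_dataset):
        tr = fit_imlmnn(small_dataset,
                        ImlmnnConfig(max_iters=0, output_dim=3))
        assert np.array_equal(tr.matrix, np.eye(3, small_dataset.d))

    def test_loss_decreases_and_history_monotone(self, small_dataset):
        cfg = ImlmnnConfig(max_iters=40)
        tr = fit_imlmnn(small_dataset, cfg)
        hist = np.array(tr.loss_history)
        assert len(hist) > 1
        assert (np.diff(hist) < 0).all()
        # recompute the endpoint losses from the definitions
        Z = (small_dataset.features - tr.mean) / tr.scale
        zd = small_dataset.with_features(Z)
        w = sample_weights(zd, cfg.density)
        t = build_triplets(zd, cfg.k_targets)
        assert imlmnn_loss(tr.matrix, zd, w, t, cfg.margin) == pytest.approx(
            hist[-1], rel=1e-9)
        assert imlmnn_loss(np.eye(zd.d), zd, w, t, cfg.margin) == pytest.approx(
            hist[0], rel=1e-9)

    def test_margin_improves_on_transformable_data(self):
        ds = generate_synthetic(SyntheticSpec(80, 20, 2, 4, 4.0, seed=2))
        tr = fit_imlmnn(ds, ImlmnnConfig(max_iters=100, learning_rate=1e-2))
        Z = (ds.features - tr.mean) / tr.scale
        before = mean_anchor_margin(Z, ds.labels)
        after = mean_anchor_margin(Z @ tr.matrix.T, ds.labels)
        assert after > before

    def test_determinism(self, small_dataset):
        cfg = ImlmnnConfig(max_iters=30)
        a = fit_imlmnn(small_dataset, cfg)
        b = fit_imlmnn(small_dataset, cfg)
        assert np.array_equal(a.matrix, b.matrix)


class TestApplyTransform:
    def test_identity_without_standardization(self, small_dataset):
        tr = LinearTransform(np.eye(small_dataset.d))
        out = apply_transform(tr, small_dataset)
        assert np.array_equal(out.features, small_dataset.features)
        assert np.array_equal(out.labels, small_dataset.labels)

    def test_scaling_scales_pairwise_distances(self, rng, small_dataset):
        L = rng.standard_normal((3, small_dataset.d))
        a = apply_transform(LinearTransform(L), small_dataset).features
        b = apply_transform(LinearTransform(2.5 * L), small_dataset).features
        da = np.linalg.norm(a[0] - a[1])
        db = np.linalg.norm(b[0] - b[1])
        assert db == pytest.approx(2.5 * da, rel=1e-12)

    def test_rows_equal_direct_product(self, rng, small_dataset):
        L = rng.standard_normal((2, small_dataset.d))
        out = apply_transform(LinearTransform(L), small_dataset)
        for i in range(0, small_dataset.n, 7):
            assert np.allclose(out.features[i], L @ small_dataset.features[i],
                               atol=1e-12)


def test_transform_serialization_round_trip(tmp_path, small_dataset):
    tr = fit_imlmnn(small_dataset, ImlmnnConfig(max_iters=10))
    p = tmp_path / "transform.txt"
    save_transform(tr, p)
    back = load_transform(p)
    assert np.array_equal(back.matrix, tr.matrix)
    assert np.array_equal(back.mean, tr.mean)
    assert np.array_equal(back.scale, tr.scale)
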