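import numpy as np
import pytest

from gashap import SurrogateClassifier, Volume
from gashap.attribution import (
    FeatureGrouping,
    Heatmap,
    check_consistency,
    compute_heatmap,
    exact_shapley,
    sampled_shapley,
)

SHAPE = (4, 4, 4)


def grouping_of(m, seed=0):
    """Random M-group partition of the toy grid with all groups nonempty."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, m, size=SHAPE)
    for i in range(m):  # guarantee every group appears
        labels.flat[i] = i
    return FeatureGrouping(labels.astype(np.int64) + 1)


def group_means(batch, g):
    return np.stack(
        [batch[:, g.labels == i + 1].mean(axis=1) for i in range(g.M)], axis=1
    )


class TestFeatureGrouping:
    def test_blocks_partition_grid(self):
        g = FeatureGrouping.from_blocks((8, 8, 8), block=4)
        assert g.M == 8
        assert (g.labels >= 1).all()
        assert g.group_sizes().sum() == 512

    def test_ragged_edge_blocks(self):
        g = FeatureGrouping.from_blocks((6, 6, 6), block=4)
        assert g.group_sizes().sum() == 216
        assert g.M == 8  # 2x2x2 blocks, edge ones smaller

    def test_spread_conserves_total(self, rng):
        g = grouping_of(5)
        phi = rng.normal(size=5)
        voxels = g.spread_to_voxels(phi)
        assert voxels.sum() == pytest.approx(phi.sum())


class TestExactShapley:
    def test_additive_model_gives_weighted_means(self, rng):
        g = grouping_of(6)
        w = rng.normal(size=6)
        x = rng.normal(size=SHAPE)
        res = exact_shapley(lambda b: group_means(b, g) @ w, x, np.zeros(SHAPE), g)
        expected = w * group_means(x[None], g)[0]
        np.testing.assert_allclose(res.phi, expected, atol=1e-12)

    def test_and_game_splits_credit_equally(self):
        g = grouping_of(2)
        sizes = g.group_sizes()

        def model(batch):  # 1 iff both groups present (nonzero mean)
            means = group_means(batch, g)
            return ((np.abs(means) > 1e-9).sum(axis=1) == 2).astype(float)

        x = np.ones(SHAPE)
        res = exact_shapley(model, x, np.zeros(SHAPE), g)
        np.testing.assert_allclose(res.phi, [0.5, 0.5], atol=1e-12)
        assert sizes.sum() == np.prod(SHAPE)

    def test_ignored_group_gets_zero(self, rng):
        g = grouping_of(4)
        w = np.array([1.0, 0.0, -2.0, 0.5])  # group 2 ignored

        def model(batch):
            m = group_means(batch, g)
            return m[:, 0] * w[0] + m[:, 2] * w[2] + m[:, 3] * w[3]

        res = exact_shapley(model, rng.normal(size=SHAPE), np.zeros(SHAPE), g)
        assert res.phi[1] == 0.0

    def test_efficiency_on_random_games(self, rng):
        g = grouping_of(5)
        for trial in range(5):
            w = rng.normal(size=5)
            W2 = rng.normal(size=(5, 5)) * 0.5

            def model(batch):
                m = group_means(batch, g)
                return m @ w + np.einsum("ni,ij,nj->n", m, W2, m)

            x = rng.normal(size=SHAPE)
            res = exact_shapley(model, x, np.zeros(SHAPE), g)
            full = model(x[None])[0]
            assert abs(res.phi0 + res.phi.sum() - full) < 1e-6

    def test_symmetry_of_identical_groups(self):
        g = grouping_of(3)

        def model(batch):  # symmetric in groups 0 and 1
            m = (np.abs(group_means(batch, g)) > 1e-9).astype(float)
            return m[:, 0] + m[:, 1] + 3.0 * m[:, 0] * m[:, 1]

        res = exact_shapley(model, np.ones(SHAPE), np.zeros(SHAPE), g)
        assert res.phi[0] == pytest.approx(res.phi[1], abs=1e-12)

    def test_refuses_large_m(self):
        labels = np.arange(1, 28).reshape(3, 3, 3)
        with pytest.raises(ValueError, match="sampled_shapley"):
            exact_shapley(lambda b: b.sum(axis=(1, 2, 3)), np.ones((3, 3, 3)),
                          np.zeros((3, 3, 3)), FeatureGrouping(labels))


class TestSampledShapley:
    def _model(self, g, seed=1):
        rng = np.random.default_rng(seed)
        w = rng.normal(size=g.M)
        W2 = rng.normal(size=(g.M, g.M)) * 0.4

        def model(batch):
            m = group_means(batch, g)
            return m @ w + np.einsum("ni,ij,nj->n", m, W2, m)

        return model

    def test_matches_exact_oracle(self, rng):
        g = grouping_of(6)
        model = self._model(g)
        x = rng.normal(size=SHAPE)
        exact = exact_shapley(model, x, np.zeros(SHAPE), g)
        sampled = sampled_shapley(model, x, np.zeros(SHAPE), g, n_permutations=4000, seed=9)
        tol = 0.02 * (np.abs(exact.phi).max() + 1)
        assert np.abs(sampled.phi - exact.phi).max() < tol

    def test_deterministic_for_seed(self, rng):
        g = grouping_of(4)
        model = self._model(g)
        x = rng.normal(size=SHAPE)
        a = sampled_shapley(model, x, np.zeros(SHAPE), g, 50, seed=3)
        b = sampled_shapley(model, x, np.zeros(SHAPE), g, 50, seed=3)
        np.testing.assert_array_equal(a.phi, b.phi)

    def test_zero_permutations_rejected(self):
        g = grouping_of(3)
        with pytest.raises(ValueError, match="n_permutations"):
            sampled_shapley(lambda b: b.sum(axis=(1, 2, 3)), np.ones(SHAPE),
                            np.zeros(SHAPE), g, 0)

    def test_error_shrinks_as_inverse_sqrt(self):
        """RMSE over replicates follows the 1/sqrt(n) Monte-Carlo rate."""
        g = grouping_of(5)
        model = self._model(g, seed=4)
        x = np.random.default_rng(5).normal(size=SHAPE)
        exact = exact_shapley(model, x, np.zeros(SHAPE), g)
        budgets = [8, 80, 800]
        rmse = []
        for n in budgets:
            errs = [
                np.abs(
                    sampled_shapley(model, x, np.zeros(SHAPE), g, n, seed=100 + r).phi
                    - exact.phi
                ).max()
                for r in range(12)
            ]
            rmse.append(np.sqrt(np.mean(np.square(errs))))
        slope = np.polyfit(np.log10(budgets), np.log10(rmse), 1)[0]
        assert -0.75 < slope < -0.3


class TestConsistency:
    def _setup(self, rng):
        g = grouping_of(3)
        w = rng.normal(size=3)

        def f(batch):
            return group_means(batch, g) @ w

        return g, f

    def test_constant_shift_preserves_phi(self, rng):
        g, f = self._setup(rng)
        x = rng.normal(size=SHAPE)
        assert check_consistency(f, lambda b: f(b) + 5.0, x, np.zeros(SHAPE), g, 0)

    def test_positive_bump_increases_phi(self, rng):
        g, f = self._setup(rng)

        def fprime(batch):  # extra reward whenever group 0 is present
            present = np.abs(group_means(batch, g)[:, 0]) > 1e-9
            return f(batch) + 2.0 * present

        x = rng.normal(size=SHAPE)
        x[g.labels == 1] += 3.0  # make group 0 clearly present
        assert check_consistency(f, fprime, x, np.zeros(SHAPE), g, 0)

    def test_identity_is_reflexive(self, rng):
        g, f = self._setup(rng)
        assert check_consistency(f, f, rng.normal(size=SHAPE), np.zeros(SHAPE), g, 1)

    def test_violated_premise_raises(self, rng):
        g, f = self._setup(rng)

        def fprime(batch):  # penalize group 0's presence: premise fails
            present = np.abs(group_means(batch, g)[:, 0]) > 1e-9
            return f(batch) - 10.0 * present

        x = rng.normal(size=SHAPE)
        x[g.labels == 1] += 3.0
        with pytest.raises(ValueError, match="premise"):
            check_consistency(f, fprime, x, np.zeros(SHAPE), g, 0)


class TestComputeHeatmap:
    @pytest.fixture()
    def surrogate(self, small_atlas):
        support = small_atlas.labels <= 3  # arbitrary fixed voxel set
        return SurrogateClassifier(voxel_set=support, threshold=0.0)

    def test_grad_input_closed_form(self, surrogate, small_atlas, rng):
        """For the linear surrogate, grad x input = weight * input voxelwise."""
        v = Volume(rng.normal(size=small_atlas.shape).astype(np.float32))
        h = compute_heatmap(surrogate, v, backend="grad_input", target=1)
        w = surrogate.input_gradient(v.data[None], 1)[0]
        np.testing.assert_allclose(h.values, w * v.data, atol=1e-10)

    def test_region_shapley_efficiency(self, surrogate, small_atlas, rng):
        """Exact region attribution sums to the model output minus base."""
        v = Volume(rng.normal(size=small_atlas.shape).astype(np.float32))
        h = compute_heatmap(
            surrogate, v, backend="region_shapley", atlas=small_atlas,
            mode="exact", target=1,
        )
        out = surrogate.predict_proba(v.data[None])[0, 1]
        assert abs(h.values.sum() + h.base_value - out) < 1e-6

    def test_block_shapley_is_seed_deterministic(self, surrogate, small_atlas, rng):
        v = Volume(rng.normal(size=small_atlas.shape).astype(np.float32))
        kw = dict(backend="block_shapley", block=8, n_permutations=8, seed=2, target=1)
        a = compute_heatmap(surrogate, v, **kw)
        b = compute_heatmap(surrogate, v, **kw)
        np.testing.assert_array_equal(a.values, b.values)

    def test_external_adapter(self, surrogate, small_atlas, rng):
        v = Volume(rng.normal(size=small_atlas.shape).astype(np.float32))
        ref = rng.normal(size=small_atlas.shape)
        h = compute_heatmap(surrogate, v, backend="external", explain_fn=lambda d: d - ref)
        np.testing.assert_allclose(h.values, v.data - ref, atol=1e-6)

    def test_unknown_backend_rejected(self, surrogate, small_atlas):
        v = Volume(np.zeros(small_atlas.shape, dtype=np.float32) + 1.0)
        v.data[0, 0, 0] = 2.0  # non-constant
        with pytest.raises(ValueError, match="backend"):
            compute_heatmap(surrogate, v, backend="lrp")


def test_heatmap_rejects_non_finite():
    bad = np.zeros((3, 3, 3))
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        Heatmap(values=bad, target_class=1)
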