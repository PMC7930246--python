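"""Metric layer: oracle values, closed forms, and invariance properties."""

import numpy as np
import pytest

from predrep.metrics import (
    canonical_correlations,
    dimensionality_gain,
    intrinsic_dimension,
    lag_decoding,
    manifold_cell_maps,
    participation_ratio,
    pca_scores,
    place_maps,
    predictive_error_curve,
    signal_transfer,
    symmetry_axis,
)


def _orthonormal_centered(rng, T, N):
    z = rng.normal(size=(T, N))
    z -= z.mean(0)
    q, _ = np.linalg.qr(z)
    return q[:, :N]


class TestPredictiveErrorCurve:
    def test_perfect_predictor_zero_at_plus_one(self, rng):
        obs = rng.random((200, 3))
        curve = predictive_error_curve(np.vstack([obs[1:], obs[-1:]]), obs)
        assert curve.values[curve.lags.tolist().index(1)] == pytest.approx(0.0)

    def test_identity_output_zero_at_lag_zero(self, rng):
        obs = rng.random((200, 3))
        curve = predictive_error_curve(obs, obs)
        assert curve.values[curve.lags.tolist().index(0)] == 0.0
        assert np.array_equal(curve.values, curve.baseline)

    def test_constant_stream_all_zero(self):
        obs = np.ones((100, 4))
        curve = predictive_error_curve(obs, obs)
        assert np.all(curve.values == 0)

    def test_lag_minimum_for_shifted_predictors(self, rng):
        obs = np.cumsum(rng.normal(size=(500, 2)), axis=0)
        for k in (-1, 0, 1):
            y = np.roll(obs, -k, axis=0)
            curve = predictive_error_curve(y[2:-2], obs[2:-2])
            assert curve.lags[np.nanargmin(curve.values)] == k


class TestSymmetryAxis:
    def test_exact_parabola(self):
        lags = np.arange(-5, 6)
        axis, flag = symmetry_axis((lags, (lags - 1.0) ** 2))
        assert axis == pytest.approx(1.0, abs=1e-9)
        assert not flag

    def test_even_curve_is_zero(self):
        lags = np.arange(-5, 6)
        axis, _ = symmetry_axis((lags, lags**2.0))
        assert axis == pytest.approx(0.0, abs=1e-9)

    def test_flat_curve_degenerate(self):
        axis, flag = symmetry_axis((np.arange(-5, 6), np.ones(11)))
        assert axis == 0.0 and flag

    def test_noisy_offcenter_parabola(self, rng):
        lags = np.arange(-5, 6)
        vals = (lags - 0.7) ** 2 + rng.normal(0, 0.05, len(lags))
        axis, _ = symmetry_axis((lags, vals))
        assert axis == pytest.approx(0.7, abs=0.1)

    def test_matches_bruteforce_oracle_on_random_curves(self, rng):
        # independent brute-force: evaluate every candidate axis directly
        lags = np.arange(-5, 6).astype(float)
        for _ in range(100):
            vals = rng.random(11)
            best, best_cost = None, np.inf
            for c in np.arange(-5.0, 5.0001, 0.05):
                refl = 2 * c - lags
                ok = (refl >= -5) & (refl <= 5)
                if ok.sum() < 3:
                    continue
                cost = np.mean((vals[ok] - np.interp(refl[ok], lags, vals)) ** 2)
                if cost < best_cost - 1e-15 or (
                    abs(cost - best_cost) <= 1e-15 and abs(c) < abs(best)
                ):
                    best, best_cost = c, cost
            axis, _ = symmetry_axis((lags, vals))
            assert axis == pytest.approx(best, abs=1e-9)


class TestLagDecoding:
    def test_identity_decoding(self, rng):
        z = rng.normal(size=(400, 2))
        out = lag_decoding(z, z, lags=[0])
        assert out[0][0] < 0.05 and out[1][0] < 0.05

    def test_independent_representation_hits_mean_baseline(self, rng):
        rep = rng.normal(size=(2000, 10))
        z = rng.normal(0, 2.0, size=(2000, 1))
        out = lag_decoding(rep, z, lags=[0])
        assert out[0][0] == pytest.approx(2.0, rel=0.1)

    def test_shifted_representation_minimizes_at_plus_one(self, rng):
        z = np.cumsum(rng.normal(size=(1000, 1)), axis=0)
        rep = np.roll(z, -1, axis=0)[:-2]
        out = lag_decoding(rep, z[:-2], lags=range(-3, 4))
        assert np.nanargmin(out[0]) == list(range(-3, 4)).index(1)

    def test_circular_variable_decoded_on_circle(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 1000)
        rep = np.column_stack([np.cos(theta), np.sin(theta), rng.normal(size=1000)])
        out = lag_decoding(rep, theta[:, None], lags=[0], circular=(0,))
        assert out[0][0] < 0.1


class TestSignalTransfer:
    def test_invertible_map_gives_unit_correlation(self, rng):
        z = rng.normal(size=(500, 2))
        rep = z @ rng.normal(size=(2, 2))
        assert signal_transfer(rep, z, n_pcs=2) == pytest.approx(1.0, abs=1e-3)

    def test_independent_blocks_below_permutation_null(self, rng):
        rep = rng.normal(size=(10_000, 20))
        z = rng.normal(size=(10_000, 2))
        observed = signal_transfer(rep, z, n_pcs=3)
        null = []
        for _ in range(20):
            null.append(signal_transfer(rep, z[rng.permutation(len(z))], n_pcs=3))
        assert observed < np.quantile(null, 0.95) + 0.02

    def test_invariance_to_variable_block_transform(self, rng):
        rep = rng.normal(size=(300, 10))
        z = rng.normal(size=(300, 3))
        m = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        a = signal_transfer(rep, z, n_pcs=4)
        b = signal_transfer(rep, z @ m, n_pcs=4)
        assert a == pytest.approx(b, abs=1e-6)

    def test_monotone_in_n_pcs_for_noiseless_linear(self, rng):
        z = rng.normal(size=(500, 3))
        rep = z @ rng.normal(size=(3, 10))
        vals = [signal_transfer(rep, z, n_pcs=k) for k in (1, 2, 3)]
        assert vals[0] <= vals[1] + 1e-5 <= vals[2] + 2e-5

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            canonical_correlations(rng.normal(size=(5, 10)), rng.normal(size=(5, 2)))


class TestParticipationRatio:
    def test_equal_eigenvalues_give_dimension(self, rng):
        x = _orthonormal_centered(rng, 50, 5)
        assert participation_ratio(x) == pytest.approx(5.0, abs=1e-9)

    def test_rank_one_gives_one(self, rng):
        x = np.outer(rng.normal(size=40), rng.normal(size=6))
        assert participation_ratio(x) == pytest.approx(1.0, abs=1e-9)

    def test_known_spectrum(self, rng):
        x = _orthonormal_centered(rng, 60, 3) @ np.diag(np.sqrt([2.0, 1.0, 1.0]))
        assert participation_ratio(x) == pytest.approx(16 / 6, abs=1e-9)

    def test_bounds(self, rng):
        for _ in range(10):
            x = rng.normal(size=(30, 8)) @ rng.normal(size=(8, 8))
            pr = participation_ratio(x)
            assert 1.0 - 1e-12 <= pr <= min(8, 29) + 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            participation_ratio(np.ones((10, 3)))


@pytest.fixture(scope="module")
def embeddings():
    rng = np.random.default_rng(7)
    q, _ = np.linalg.qr(rng.normal(size=(10, 10)))
    t = rng.uniform(0, 2 * np.pi, 1500)
    circle = np.column_stack([np.cos(t), np.sin(t)]) @ q[:2]
    square = rng.uniform(0, 1, (1500, 2)) @ q[:2]
    gauss = rng.normal(size=(1500, 5))
    return {"circle": circle, "square": square, "gauss": gauss}


class TestIntrinsicDimension:

    @pytest.mark.parametrize("method", ["mle_k_nn", "correlation_dimension"])
    @pytest.mark.parametrize(
        "name,lo,hi", [("circle", 0.8, 1.2), ("square", 1.7, 2.3), ("gauss", 4.2, 5.8)]
    )
    def test_known_manifold_brackets(self, embeddings, method, name, lo, hi):
        est = intrinsic_dimension(embeddings[name], method, seed=0)
        assert lo <= est.estimate <= hi, (method, name, est.estimate)

    @pytest.mark.parametrize("name", ["circle", "square", "gauss"])
    def test_estimators_agree_within_25_percent(self, embeddings, name):
        a = intrinsic_dimension(embeddings[name], "mle_k_nn", seed=0).estimate
        b = intrinsic_dimension(embeddings[name], "correlation_dimension", seed=0).estimate
        assert abs(a - b) / min(a, b) < 0.25

    def test_subsampling_is_seeded(self, rng):
        x = rng.normal(size=(12_000, 4))
        a = intrinsic_dimension(x, "mle_k_nn", seed=3)
        b = intrinsic_dimension(x, "mle_k_nn", seed=3)
        assert a.estimate == b.estimate
        assert a.n_samples <= 10_000

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            intrinsic_dimension(rng.normal(size=(200, 3)), "danco")

    def test_duplicates_pruned_with_warning(self, rng):
        x = np.repeat(rng.normal(size=(150, 3)), 2, axis=0)
        with pytest.warns(UserWarning, match="duplicate"):
            intrinsic_dimension(x, "mle_k_nn", seed=0)


class TestDimensionalityGain:
    def test_arithmetic(self):
        assert dimensionality_gain(7.0, 2.0) == 3.5
        assert dimensionality_gain(4.0, 4.0) == 1.0

    def test_isotropic_gaussian_near_one(self, rng):
        x = rng.normal(size=(3000, 5))
        pr = participation_ratio(x)
        ids = [
            intrinsic_dimension(x, m, seed=0).estimate
            for m in ("mle_k_nn", "correlation_dimension")
        ]
        assert dimensionality_gain(pr, np.mean(ids)) == pytest.approx(1.0, abs=0.3)

    def test_invalid_id_rejected(self):
        with pytest.raises(ValueError):
            dimensionality_gain(5.0, 0.0)


class TestMaps:
    def test_pc1_tuned_neuron_constant_along_pc2(self, rng):
        z = rng.normal(size=(5000, 2)) @ np.diag([5.0, 1.0])
        rep = np.column_stack([z, np.tanh(z[:, 0])])
        maps = manifold_cell_maps(rep, bins=8, min_occupancy=2)
        m = maps[2]  # the tanh(PC1) unit
        row_var = np.nanvar(np.nanmean(m, axis=1))
        col_var = np.nanvar(np.nanmean(m, axis=0))
        assert row_var > 5 * col_var

    def test_constant_neuron_constant_map(self, rng):
        rep = np.column_stack([rng.normal(size=(500, 2)), np.ones(500)])
        maps = manifold_cell_maps(rep, bins=5, min_occupancy=1)
        vals = maps[2][np.isfinite(maps[2])]
        assert np.allclose(vals, 1.0)

    def test_synthetic_bump_recovery_on_manifold(self, rng):
        # population tuned to Gaussian bumps on a 2-D latent that maps
        # linearly (hence PC-aligned) into activity space
        z = rng.uniform(-1, 1, (8000, 2))
        centers = rng.uniform(-0.8, 0.8, (20, 2))
        act = np.exp(-np.sum((z[:, None] - centers[None]) ** 2, -1) / 0.05)
        # unequal latent gains pin PC1 to z0 and PC2 to z1 (up to sign)
        rep = np.column_stack([20 * z[:, 0], 10 * z[:, 1], act])
        maps = manifold_cell_maps(rep, bins=10, min_occupancy=3)
        scores = pca_scores(rep, 2)
        s0 = np.sign(np.corrcoef(scores[:, 0], z[:, 0])[0, 1])
        s1 = np.sign(np.corrcoef(scores[:, 1], z[:, 1])[0, 1])
        # binned_statistic_2d uses uniform edges over the observed range
        def bin_of(val, col):
            edges = np.linspace(scores[:, col].min(), scores[:, col].max(), 11)
            return int(np.clip(np.searchsorted(edges, val, side="right") - 1, 0, 9))

        hits = 0
        for i, c in enumerate(centers):
            m = maps[2 + i]
            peak = np.unravel_index(np.nanargmax(m), m.shape)
            bx = bin_of(20 * c[0] * s0, 0)
            by = bin_of(10 * c[1] * s1, 1)
            if abs(peak[0] - bx) <= 1 and abs(peak[1] - by) <= 1:
                hits += 1
        assert hits >= 15

    def test_place_map_step_neuron(self, rng):
        xy = rng.uniform(0, 10, (4000, 2))
        rep = (xy[:, 0] > 5).astype(float)[:, None]
        maps = place_maps(rep, xy, bins=8, min_occupancy=2)
        m = maps[0]
        assert np.nanmean(m[:4]) < 0.05
        assert np.nanmean(m[4:]) > 0.95

    def test_unvisited_bins_are_nan(self, rng):
        xy = rng.uniform(0, 1, (500, 2))
        xy[:, 0] *= 0.4  # never visit the right side
        rep = rng.normal(size=(500, 3))
        full_range = np.vstack([xy, [[1.0, 1.0]]])
        maps = place_maps(np.vstack([rep, rep[:1]]), full_range, bins=8, min_occupancy=2)
        assert np.isnan(maps[0, 6, :]).all()
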