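"""The synthetic world: latents, toy images, feature pyramid, responses."""

import numpy as np
import pytest

from latentcoding.encoding import fit_kernel_ridge, predict, score_encoders
from latentcoding.responses import average_repetitions, average_window
from latentcoding.synthetic import (
    SyntheticConfig,
    extract_toy_features,
    gen_latents,
    latent_to_blob_params,
    make_ground_truth,
    make_mixing,
    map_z_to_w,
    render_toy_images,
    simulate_responses,
    temporal_profile,
)


class TestGenLatents:
    def test_shape_and_determinism(self):
        a = gen_latents(50, 16, 0.7, seed=4)
        b = gen_latents(50, 16, 0.7, seed=4)
        assert a.values.shape == (50, 16)
        np.testing.assert_array_equal(a.values, b.values)

    def test_full_truncation_collapses_to_center(self):
        out = gen_latents(10, 4, 0.0, seed=0)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_truncation_contracts_variance_by_psi_squared(self):
        psi = 0.7
        full = gen_latents(4000, 8, 1.0, seed=9).values
        trunc = gen_latents(4000, 8, psi, seed=9).values
        ratio = trunc.var() / full.var()
        assert ratio == pytest.approx(psi**2, rel=1e-12)

    @pytest.mark.parametrize("n,d,psi", [(0, 4, 0.7), (4, 0, 0.7), (4, 4, 1.5)])
    def test_invalid_arguments(self, n, d, psi):
        with pytest.raises(ValueError):
            gen_latents(n, d, psi, seed=0)


class TestMapZtoW:
    def test_identity_mixing(self):
        z = gen_latents(20, 6, 0.7, seed=1)
        w = map_z_to_w(z, np.eye(6))
        np.testing.assert_array_equal(w.values, z.values)
        assert w.kind == "w"

    def test_orthogonal_mixing_preserves_row_norms(self):
        z = gen_latents(20, 8, 0.7, seed=2)
        w = map_z_to_w(z, make_mixing(8, seed=3))
        np.testing.assert_allclose(
            np.linalg.norm(w.values, axis=1),
            np.linalg.norm(z.values, axis=1),
            atol=1e-10,
        )

    def test_invertible_mixing_round_trip(self, rng):
        """Applying the inverse mixing recovers z to machine precision."""
        mixing = rng.standard_normal((8, 8)) + 4 * np.eye(8)
        z = gen_latents(15, 8, 0.7, seed=5)
        w = map_z_to_w(z, mixing)
        back = map_z_to_w(w, np.linalg.inv(mixing))
        np.testing.assert_allclose(back.values, z.values, atol=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            map_z_to_w(gen_latents(5, 4, 0.7, 0), np.eye(5))


class TestRenderToyImages:
    def test_equal_latents_give_identical_images(self, rng):
        w = rng.standard_normal(12)
        imgs = render_toy_images(np.stack([w, w]), size=32)
        np.testing.assert_array_equal(imgs[0], imgs[1])

    def test_zero_latent_renders_the_blank_baseline(self):
        img = render_toy_images(np.zeros((1, 8)), size=32)
        np.testing.assert_array_equal(img, 0.0)

    def test_each_latent_dim_controls_one_blob_parameter(self, rng):
        w = rng.standard_normal(8)
        base = latent_to_blob_params(w, 32)
        for dim in range(8):
            bumped = w.copy()
            bumped[dim] += 0.5
            altered = latent_to_blob_params(bumped, 32)
            changed = np.nonzero(~np.isclose(altered, base))
            assert changed[0].tolist() == [dim // 4]
            assert changed[1].tolist() == [dim % 4]

    def test_perturbing_one_dim_changes_only_its_blob_region(self):
        # two well-separated blobs; nudging blob 2's amplitude leaves
        # blob 1's neighbourhood untouched
        w = np.array([-2.0, -2.0, 0.0, 1.0, 2.0, 2.0, 0.0, 1.0])
        bumped = w.copy()
        bumped[7] += 1.0
        a = render_toy_images(w[None], size=64)[0]
        b = render_toy_images(bumped[None], size=64)[0]
        diff = np.abs(b - a)
        params = latent_to_blob_params(w, 64)
        x1, y1 = params[0, 0], params[0, 1]
        x2, y2 = params[1, 0], params[1, 1]
        assert diff[int(y2), int(x2)] > 1e-3
        assert diff[int(y1), int(x1)] < 1e-6 * diff.max()

    def test_too_small_canvas(self):
        with pytest.raises(ValueError):
            render_toy_images(np.zeros((1, 4)), size=4)


class TestExtractToyFeatures:
    def test_constant_image_gives_the_baseline_vector_at_every_level(self):
        const = np.full((1, 64, 64), 3.0)
        for level in range(1, 6):
            f = extract_toy_features(const, level)
            again = extract_toy_features(const, level)
            np.testing.assert_array_equal(f.values, again.values)
            assert np.all(np.isfinite(f.values))

    def test_feature_dim_strictly_decreases_with_level(self):
        imgs = np.zeros((2, 64, 64))
        dims = [extract_toy_features(imgs, lvl).dim for lvl in range(1, 6)]
        assert dims == sorted(dims, reverse=True)
        assert len(set(dims)) == 5

    def test_single_pixel_change_visible_at_fine_level_only(self):
        # structured image so coarse features are far from zero
        a = render_toy_images(np.array([[0.0, 0.0, 0.5, 2.0]]), size=64)[0]
        b = a.copy()
        b[10, 10] += 1.0
        f1a = extract_toy_features(a, 1).values
        f1b = extract_toy_features(b, 1).values
        f5a = extract_toy_features(a, 5).values
        f5b = extract_toy_features(b, 5).values
        rel_fine = np.abs(f1b - f1a).max() / np.abs(f1a).max()
        rel_coarse = np.abs(f5b - f5a).max() / np.abs(f5a).max()
        assert rel_fine > 0
        assert rel_coarse < rel_fine / 10

    def test_pooling_scale_errors(self):
        with pytest.raises(ValueError):
            extract_toy_features(np.zeros((1, 16, 16)), 5)
        with pytest.raises(ValueError):
            extract_toy_features(np.zeros((1, 64, 64)), 0)


def _tiny_cfg(noise=0.0, seed=0):
    return SyntheticConfig(
        n_train=40,
        n_test=15,
        latent_dim=8,
        regions=(("V1", 1, 6), ("V4", 1, 6), ("IT", 1, 6)),
        noise_sigma=noise,
        seed=seed,
    )


def _latent_drivers(cfg, seed=0):
    lat = gen_latents(cfg.n_train + cfg.n_test, cfg.latent_dim, 0.7, seed)
    train = lat.values[: cfg.n_train]
    test = lat.values[cfg.n_train :]
    regions = [name for name, *_ in cfg.regions]
    return (
        {r: train for r in regions},
        {r: test for r in regions},
        train,
        test,
    )


class TestSimulateResponses:
    def test_noiseless_windowed_response_is_the_linear_map(self):
        cfg = _tiny_cfg(noise=0.0)
        drivers, _, train, _ = _latent_drivers(cfg)
        rmap = cfg.region_map()
        gt = make_ground_truth(drivers, rmap, cfg)
        rec = simulate_responses(drivers, gt, cfg, n_reps=1, seed=1)
        windowed = average_repetitions(average_window(rec, rmap))
        for region in rmap.region_names:
            chans = rmap.channels(region)
            lo, hi = rmap.windows[region]
            prof = gt.profiles[region]
            gain = prof[int(cfg.onset_ms + lo) : int(cfg.onset_ms + hi)].mean()
            expected = (train @ gt.weights[region]) * gain + gt.bias[chans]
            np.testing.assert_allclose(windowed[:, chans], expected, atol=1e-12)

    def test_test_split_has_twenty_repetitions(self):
        cfg = _tiny_cfg(noise=0.3)
        drivers, _, *_ = _latent_drivers(cfg)
        gt = make_ground_truth(drivers, cfg.region_map(), cfg)
        rec = simulate_responses(drivers, gt, cfg, n_reps=cfg.n_reps_test, seed=2)
        assert rec.n_reps == 20
        assert rec.values.shape == (40, 20, 18, 300)

    def test_seeded_reproducibility(self):
        cfg = _tiny_cfg(noise=0.5)
        drivers, _, *_ = _latent_drivers(cfg)
        gt = make_ground_truth(drivers, cfg.region_map(), cfg)
        a = simulate_responses(drivers, gt, cfg, n_reps=2, seed=7)
        b = simulate_responses(drivers, gt, cfg, n_reps=2, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_doubling_noise_lowers_mean_encoding_r(self):
        """More channel noise means worse held-out encoding, averaged
        over seeds with shared structure."""
        mean_r = {}
        for sigma in (0.5, 2.0):
            scores = []
            for seed in range(3):
                cfg = _tiny_cfg(noise=sigma, seed=seed)
                drv_tr, drv_te, train, test = _latent_drivers(cfg, seed=seed)
                rmap = cfg.region_map()
                gt = make_ground_truth(drv_tr, rmap, cfg)
                rec_tr = simulate_responses(drv_tr, gt, cfg, 1, seed=100 + seed)
                rec_te = simulate_responses(drv_te, gt, cfg, 20, seed=200 + seed)
                ytr = average_repetitions(average_window(rec_tr, rmap))
                yte = average_repetitions(average_window(rec_te, rmap))
                model = fit_kernel_ridge(train, ytr, lam=1.0)
                r = score_encoders(predict(model, test), yte)
                scores.append(np.nanmean(r))
            mean_r[sigma] = np.mean(scores)
        assert mean_r[2.0] < mean_r[0.5]

    def test_dimension_mismatch_and_bad_reps(self):
        cfg = _tiny_cfg()
        drivers, _, *_ = _latent_drivers(cfg)
        gt = make_ground_truth(drivers, cfg.region_map(), cfg)
        bad = {r: v[:, :4] for r, v in drivers.items()}
        with pytest.raises(ValueError):
            simulate_responses(bad, gt, cfg, n_reps=1, seed=0)
        with pytest.raises(ValueError):
            simulate_responses(drivers, gt, cfg, n_reps=0, seed=0)


def test_temporal_profile_is_onset_locked_unit_peak():
    prof = temporal_profile(300, 100, 75.0)
    assert prof.shape == (300,)
    assert prof.max() == pytest.approx(1.0)
    assert prof.argmax() == 175
    np.testing.assert_array_equal(prof[:100], 0.0)
    assert np.all(prof >= 0)
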