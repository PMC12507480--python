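"""OCT pipeline: crop arithmetic, feature conventions (including a
hand-computed co-occurrence oracle), classifier behaviour, boundary
tracing, and perpendicular thickness against a dense geometric oracle."""

import math

import numpy as np
import pytest

from afshear import oct as om
from afshear.synthetic import generate_lamellae_image
from afshear.types import LamellaeParams

PX = 10.23
FAST_DPAD = (10, 30)  # reduced iteration counts for unit-scale checks


def clean_params(**kw):
    defaults = dict(
        mean_thickness_um=30 * PX,
        sd_thickness_um=0.0,
        undulation_amplitude_um=0.0,
        bright_dark_contrast=1.0,
        speckle_shape=math.inf,
        image_size_px=440,
    )
    defaults.update(kw)
    return LamellaeParams(**defaults)


class TestCrop:
    def test_1024_center(self):
        img = om.OCTImage(np.zeros((1024, 1024)), PX)
        cropped = om.crop_central(img)
        assert cropped.meta["crop"] == (312, 312, 400)
        assert cropped.data.shape == (400, 400)

    def test_exact_identity(self):
        img = om.OCTImage(np.arange(160000, dtype=float).reshape(400, 400), PX)
        assert np.array_equal(om.crop_central(img).data, img.data)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            om.crop_central(om.OCTImage(np.zeros((399, 500)), PX))

    def test_odd_margin_resolves_top_left(self):
        img = om.OCTImage(np.zeros((401, 402)), PX)
        assert om.crop_central(img).meta["crop"] == (0, 1, 400)

    def test_tiff_and_boundary_json_round_trip(self, tmp_path):
        synth = generate_lamellae_image(clean_params(), seed=7)
        img = om.OCTImage(synth.image, PX)
        om.write_oct_image(img, tmp_path / "img.tiff")
        back = om.read_oct_image(tmp_path / "img.tiff", PX)
        assert back.data.shape == img.data.shape
        # intensity is rescaled to the 16-bit range; structure is preserved
        assert np.corrcoef(back.data.ravel(), img.data.ravel())[0, 1] > 0.999
        om.write_boundaries_json(synth.boundaries, tmp_path / "gt.json")
        loaded = om.read_boundaries_json(tmp_path / "gt.json")
        for a, b in zip(loaded, synth.boundaries):
            assert np.allclose(a, b)


class TestFeatures:
    def test_constant_image_conventions(self):
        img = om.OCTImage(np.full((64, 64), 3.0), PX)
        asm = om.haralick_planes(img.data, (7, 7), 1)
        assert np.allclose(asm["asm"], 1.0)  # single grey pair
        assert np.allclose(asm["entropy"], 0.0)
        assert np.allclose(om.speckle_index(img.data, (5, 5)), 0.0)
        stack = om.compute_features(img, dpad_iterations=FAST_DPAD)
        for name, plane in zip(stack.names, stack.planes):
            if name.endswith("_z"):
                assert np.allclose(plane, 0.0), name  # z-score of constant = 0

    def test_two_valued_stripes_match_hand_computed_glcm(self):
        # rows alternate 0,1: vertical offset-1 pairs are always (0,1) or
        # (1,0), each with probability 1/2 in any window of even height,
        # so ASM = 2 * (1/2)^2 = 0.5 and entropy = 1 bit
        img = np.tile(np.array([[0.0], [1.0]]), (32, 64)).reshape(64, 64)
        planes = om.haralick_planes(img, (8, 8), 1, levels=32)
        center = np.s_[16:48, 16:48]
        assert np.allclose(planes["asm"][center], 0.5, atol=1e-6)
        assert np.allclose(planes["entropy"][center], 1.0, atol=1e-6)
        # marginal variance of a fair 0/31 quantized coin = (31/2)^2
        assert np.allclose(planes["ssq"][center], (31 / 2) ** 2, atol=1e-3)

    def test_median_plane_robust_to_salt_and_pepper(self, rng):
        img = np.full((64, 64), 0.5, dtype=np.float32)
        idx = rng.choice(64 * 64, size=200, replace=False)
        img.ravel()[idx[:100]] = 0.0
        img.ravel()[idx[100:]] = 1.0
        from scipy import ndimage

        med = ndimage.median_filter(img, size=(5, 5))
        assert np.mean(med == 0.5) > 0.99

    def test_determinism(self):
        synth = generate_lamellae_image(LamellaeParams(image_size_px=440), seed=5)
        img = om.OCTImage(synth.image[:120, :120], PX)
        a = om.compute_features(img, dpad_iterations=FAST_DPAD)
        b = om.compute_features(img, dpad_iterations=FAST_DPAD)
        assert a.names == b.names
        assert np.array_equal(a.planes, b.planes)

    def test_dpad_reduces_speckle_preserving_edges(self, rng):
        synth = generate_lamellae_image(LamellaeParams(image_size_px=440), rng)
        img = synth.image[:160, :160]
        mask = synth.bright_mask[:160, :160]
        out = om.dpad(img, iterations=(200,))[0]
        # within-class variance drops, class separation survives
        assert np.var(out[mask]) < 0.5 * np.var(img[mask])
        assert abs(np.mean(out[mask]) - np.mean(out[~mask])) > 0.2


class TestClassifier:
    def _stack_and_mask(self, synth):
        img = om.OCTImage(synth.image, synth.pixel_size_um)
        return om.compute_features(img, dpad_iterations=FAST_DPAD), synth.bright_mask

    def test_separable_data_self_consistency(self, tmp_path):
        synth = generate_lamellae_image(clean_params(), seed=1)
        stack, mask = self._stack_and_mask(synth)
        clf = om.train_classifier([stack], [mask], seed=0)
        pred = clf.predict_proba_image(stack) > 0.5
        assert np.mean(pred == mask) > 0.99
        # persisted model reproduces the same probabilities
        om.save_classifier(clf, tmp_path / "rf.joblib")
        back = om.load_classifier(tmp_path / "rf.joblib")
        assert np.array_equal(back.predict_proba_image(stack), clf.predict_proba_image(stack))

    def test_speckled_held_out_accuracy(self):
        train = [
            generate_lamellae_image(LamellaeParams(image_size_px=440), seed=s)
            for s in (1, 2)
        ]
        test = generate_lamellae_image(LamellaeParams(image_size_px=440), seed=9)
        stacks, masks = zip(*(self._stack_and_mask(s) for s in train))
        clf = om.train_classifier(list(stacks), list(masks), seed=0)
        stack, mask = self._stack_and_mask(test)
        pred = clf.predict_proba_image(stack) > 0.5
        assert np.mean(pred == mask) > 0.90

    def test_permuted_labels_chance_accuracy(self, rng):
        synth = generate_lamellae_image(LamellaeParams(image_size_px=440), seed=4)
        stack, mask = self._stack_and_mask(synth)
        permuted = rng.permutation(mask.ravel()).reshape(mask.shape)
        clf = om.train_classifier([stack], [permuted], seed=0)
        held = generate_lamellae_image(LamellaeParams(image_size_px=440), seed=11)
        stack_h, mask_h = self._stack_and_mask(held)
        acc = np.mean((clf.predict_proba_image(stack_h) > 0.5) == mask_h)
        assert 0.35 < acc < 0.65

    def test_single_class_rejected(self):
        synth = generate_lamellae_image(clean_params(), seed=1)
        stack, mask = self._stack_and_mask(synth)
        with pytest.raises(ValueError, match="single class"):
            om.train_classifier([stack], [np.ones_like(mask)], seed=0)


class TestTracing:
    def _proba_from_truth(self, synth, blur=0.0):
        p = synth.bright_mask.astype(np.float32)
        if blur:
            from scipy import ndimage

            p = ndimage.gaussian_filter(p, blur)
        return p

    def test_exact_seeds_on_clean_bands(self):
        synth = generate_lamellae_image(clean_params(), seed=2)
        p = self._proba_from_truth(synth, blur=1.0)
        seeds = [om.seeds_from_truth(b, jitter_px=0.0) for b in synth.boundaries]
        traced = om.trace_boundaries(p, seeds)
        for t, b in zip(traced, synth.boundaries):
            assert np.max(np.abs(t - b)) < 1.0

    def test_offset_seeds_snap_back(self):
        synth = generate_lamellae_image(clean_params(), seed=2)
        p = self._proba_from_truth(synth, blur=1.0)
        seeds = [
            om.seeds_from_truth(b, jitter_px=0.0) + np.array([0.0, 3.0])
            for b in synth.boundaries
        ]
        traced = om.trace_boundaries(p, seeds)
        for t, b in zip(traced, synth.boundaries):
            assert np.max(np.abs(t - b)) < 1.0

    def test_seeds_in_uniform_region_rejected(self):
        p = np.full((100, 100), 0.9, dtype=np.float32)
        seeds = [np.column_stack([np.linspace(0, 99, 10), np.full(10, 50.0)])]
        with pytest.raises(om.BoundaryRejected):
            om.trace_boundaries(p, seeds)


class TestThickness:
    def test_flat_parallel_boundaries(self):
        w = 200
        up = np.full(w, 50.0)
        lo = np.full(w, 80.0)
        res = om.measure_thickness([up, lo], PX)
        assert res.mean_um == pytest.approx(30 * PX)  # 306.9 um
        assert res.layer_count == 1
        assert res.coverage == 1.0

    def test_tilted_boundaries_cosine_factor(self):
        w = 400
        x = np.arange(w, dtype=float)
        s = math.tan(math.radians(10.0))
        up = 50.0 + s * x
        lo = up + 30.0
        res = om.measure_thickness([up, lo], PX, node_step=2)
        expected = 30.0 * math.cos(math.radians(10.0)) * PX
        assert res.mean_um == pytest.approx(expected, rel=0.01)

    def test_undulating_bands_match_dense_oracle(self):
        w = 400
        x = np.arange(w, dtype=float)
        up = 100.0 + 12.0 * np.sin(2 * math.pi * x / 160.0)
        lo = up + 35.0
        res = om.measure_thickness([up, lo], PX, node_step=1)
        # dense oracle: minimum distance from each upper point to a
        # 100x-oversampled lower polyline (perpendicular = nearest for
        # smooth near-parallel curves)
        xf = np.linspace(0, w - 1, w * 100)
        lof = np.interp(xf, x, lo)
        d = [
            np.min(np.hypot(xf - xi, lof - ui))
            for xi, ui in zip(x[::4], up[::4])
        ]
        oracle = float(np.mean(d)) * PX
        assert abs(res.mean_um - oracle) < 1.0 * PX

    def test_missing_border_excludes_its_layers_only(self):
        w = 100
        b0, b1, b2, b3 = (np.full(w, r) for r in (20.0, 45.0, 80.0, 95.0))
        # a failed middle border must not merge its two layers into one
        with pytest.raises(ValueError, match="both borders"):
            om.measure_layers([b0, None, b2], PX)
        # layers away from the failed border are still measured
        res = om.measure_layers([b0, b1, None, b3], PX)
        assert res.layer_count == 1
        assert res.mean_um == pytest.approx(25.0 * PX)

    def test_crossing_boundaries_rejected(self):
        w = 100
        up = np.full(w, 50.0)
        lo = np.linspace(40.0, 70.0, w)
        with pytest.raises(ValueError, match="cross"):
            om.measure_thickness([up, lo], PX)

    def test_layer_count_bounded_by_window(self):
        synth = generate_lamellae_image(LamellaeParams(image_size_px=440), seed=6).crop(400)
        n = len(synth.layer_thickness_um)
        mean_px = np.mean(synth.layer_thickness_um) / PX
        assert n * mean_px <= 400 * 1.1


class TestEndToEnd:
    def test_noise_free_recovery_within_one_pixel(self):
        synth = generate_lamellae_image(
            clean_params(mean_thickness_um=32 * PX), seed=3
        ).crop(400)
        img = om.OCTImage(synth.image, synth.pixel_size_um)
        stack = om.compute_features(img, dpad_iterations=FAST_DPAD)
        clf = om.train_classifier([stack], [synth.bright_mask], seed=0)
        proba = clf.predict_proba_image(stack)
        seeds = [om.seeds_from_truth(b, jitter_px=2.0, rng=1) for b in synth.boundaries]
        traced = om.trace_boundaries(proba, seeds)
        res = om.measure_thickness(traced, synth.pixel_size_um)
        assert abs(res.mean_um - synth.true_mean_thickness_um) < 1.0 * PX

    def test_rotation_consistency_of_tilted_bands(self):
        from scipy import ndimage

        params = clean_params(mean_thickness_um=300.0, tilt_deg=8.0)
        synth = generate_lamellae_image(params, seed=8)
        # measure on the tilted truth boundaries directly
        res_tilted = om.measure_thickness(synth.boundaries, PX, node_step=2)
        # rotate the mask to remove tilt and measure flat spacing
        rot = ndimage.rotate(
            synth.bright_mask.astype(float), -8.0, reshape=False, order=1
        )
        center = rot[150:290, 150:290] > 0.5
        cols = [np.flatnonzero(np.diff(center[:, j])) for j in range(0, 140, 20)]
        spacings = np.concatenate([np.diff(c) for c in cols if len(c) > 1])
        flat_um = float(np.mean(spacings)) * PX
        assert res_tilted.mean_um == pytest.approx(flat_um, abs=1.5 * PX)
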