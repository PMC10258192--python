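"""Phase-splitting contracts: exact rank selection, per-phase ratios, profiles."""

import numpy as np
import pytest

from crowdscope.errors import DegenerateSegmentationError, InsufficientPixelsError
from crowdscope.phase_split import (
    PhaseMasks, derive_cell_mask, extract_line_profiles, measure_phase_ratios,
    segment_phases,
)
from crowdscope.ratiometric import RatioImage, compute_ratio_image
from crowdscope.synthetic_scenes import (
    AGGREGATION, CONSOLIDATION, NoiseModel, SensorModel, make_scene,
    render_fret_images,
)


def _uniform_ratio(shape, value=1.0):
    return RatioImage(ratio_map=np.full(shape, value), valid_mask=np.ones(shape, bool),
                      background_donor=0.0, background_acceptor=0.0,
                      intensity_threshold=0.0)


def _disc_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


class TestSegmentPhases:
    def test_two_level_image_recovered_exactly(self):
        shape = (64, 64)
        cell = np.ones(shape, bool)
        disc = _disc_mask(shape, (32, 32), 10)
        img = np.where(disc, 1000.0, 100.0)
        frac = disc.sum() / cell.sum()
        masks = segment_phases(img, cell, dense_quantile=frac, dilute_quantile=0.3)
        inter = (masks.dense_mask & disc).sum()
        union = (masks.dense_mask | disc).sum()
        assert inter / union == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_masks_disjoint_and_inside_cell(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 100, (40, 40))
        cell = _disc_mask((40, 40), (20, 20), 15)
        masks = segment_phases(img, cell, 0.1, 0.3)
        assert not (masks.dense_mask & masks.dilute_mask).any()
        assert not (masks.dense_mask & ~cell).any()
        assert not (masks.dilute_mask & ~cell).any()
        assert img[masks.dense_mask].mean() >= img[masks.dilute_mask].mean()

    def test_uniform_image_degenerate(self):
        with pytest.raises(DegenerateSegmentationError):
            segment_phases(np.ones((10, 10)), np.ones((10, 10), bool), 0.1, 0.3)

    def test_quantile_monotone_inclusion(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 100, (40, 40))
        cell = np.ones((40, 40), bool)
        prev = None
        for q in (0.05, 0.10, 0.25, 0.50):
            dense = segment_phases(img, cell, q, 0.1).dense_mask
            if prev is not None:
                assert not (prev & ~dense).any()  # previous mask is a subset
            prev = dense

    def test_validity_mask_limits_pool(self):
        img = np.arange(100.0).reshape(10, 10)
        cell = np.ones((10, 10), bool)
        valid = img >= 50
        masks = segment_phases(img, cell, 0.2, 0.2, validity_mask=valid)
        assert not (masks.dilute_mask & ~valid).any()

    def test_bad_quantiles_rejected(self):
        img = np.arange(16.0).reshape(4, 4)
        cell = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            segment_phases(img, cell, 0.0, 0.3)
        with pytest.raises(ValueError):
            segment_phases(img, cell, 0.6, 0.6)


class TestMeasurePhaseRatios:
    def test_constant_regions(self):
        shape = (20, 20)
        dense = np.zeros(shape, bool); dense[:5] = True
        dilute = np.zeros(shape, bool); dilute[10:] = True
        ratio_map = np.where(dense, 1.3, 1.0)
        ratio = RatioImage(ratio_map=ratio_map, valid_mask=np.ones(shape, bool),
                           background_donor=0.0, background_acceptor=0.0,
                           intensity_threshold=0.0)
        masks = PhaseMasks(dense, dilute, np.ones(shape, bool), 0.25, 0.5)
        intensity = np.where(dense, 500.0, 50.0)
        m = measure_phase_ratios(ratio, masks, intensity)
        assert m.dense_mean_ratio == pytest.approx(1.3)
        assert m.dilute_mean_ratio == pytest.approx(1.0)
        assert m.dense_mean_intensity > m.dilute_mean_intensity

    def test_insufficient_pixels_raises(self):
        shape = (10, 10)
        dense = np.zeros(shape, bool); dense[0, :5] = True
        dilute = np.zeros(shape, bool); dilute[5:] = True
        masks = PhaseMasks(dense, dilute, np.ones(shape, bool), 0.05, 0.5)
        with pytest.raises(InsufficientPixelsError):
            measure_phase_ratios(_uniform_ratio(shape), masks, np.ones(shape),
                                 min_pixels=20)

    def _measure_clean_scene(self, mode, dense_c, dilute_c, seed=0):
        sensor = SensorModel()
        scene = make_scene(mode_label=mode, crowding_dense=dense_c,
                           crowding_dilute=dilute_c, seed=seed, width=96,
                           height=96, n_condensates=5)
        channels = render_fret_images(scene, sensor, noise=None)
        ratio = compute_ratio_image(channels, background=0.0, intensity_threshold=0.0)
        frac = scene.condensate_mask.sum() / scene.cell_mask.sum()
        masks = segment_phases(channels.acceptor, scene.cell_mask,
                               dense_quantile=frac, dilute_quantile=0.3,
                               validity_mask=ratio.valid_mask)
        m = measure_phase_ratios(ratio, masks, channels.acceptor)
        return m, sensor

    def test_aggregation_dense_more_crowded(self):
        m, sensor = self._measure_clean_scene(AGGREGATION, 0.45, 0.30)
        assert m.dense_mean_ratio > m.dilute_mean_ratio
        assert m.dense_mean_ratio == pytest.approx(sensor.expected_ratio(0.45), abs=1e-9)
        assert m.dilute_mean_ratio == pytest.approx(sensor.expected_ratio(0.30), abs=1e-9)

    def test_consolidation_equal_crowding_equal_ratio(self):
        m, _ = self._measure_clean_scene(CONSOLIDATION, 0.30, 0.30)
        assert m.dense_mean_ratio == pytest.approx(m.dilute_mean_ratio, abs=1e-9)

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        shape = (30, 30)
        ratio_map = rng.uniform(0.5, 2.0, shape)
        intensity = rng.uniform(10, 100, shape)
        dense = np.zeros(shape, bool); dense[5:10, 5:10] = True
        dilute = np.zeros(shape, bool); dilute[15:25, 15:25] = True

        def measure(shift):
            r = RatioImage(np.roll(ratio_map, shift, (0, 1)),
                           np.ones(shape, bool), 0.0, 0.0, 0.0)
            masks = PhaseMasks(np.roll(dense, shift, (0, 1)),
                               np.roll(dilute, shift, (0, 1)),
                               np.ones(shape, bool), 0.1, 0.3)
            return measure_phase_ratios(r, masks, np.roll(intensity, shift, (0, 1)))

        a, b = measure(0), measure(3)
        assert a.dense_mean_ratio == pytest.approx(b.dense_mean_ratio, rel=1e-12)
        assert a.dilute_mean_ratio == pytest.approx(b.dilute_mean_ratio, rel=1e-12)

    def test_weighted_mean_equals_ratio_of_sums(self):
        rng = np.random.default_rng(5)
        shape = (20, 20)
        donor = rng.uniform(20, 100, shape)
        acceptor = rng.uniform(20, 100, shape)
        ratio = RatioImage(acceptor / donor, np.ones(shape, bool), 0.0, 0.0, 0.0)
        dense = np.zeros(shape, bool); dense[:8] = True
        dilute = np.zeros(shape, bool); dilute[12:] = True
        masks = PhaseMasks(dense, dilute, np.ones(shape, bool), 0.4, 0.4)
        m = measure_phase_ratios(ratio, masks, acceptor, weights=donor)
        assert m.dense_mean_ratio == pytest.approx(
            acceptor[dense].sum() / donor[dense].sum(), rel=1e-12)


class TestGroundTruthAgreement:
    def test_dense_mask_matches_condensates_on_noisy_scenes(self):
        """Mean Jaccard >= 0.8 against ground truth over 50 seeded scenes."""
        sensor = SensorModel()
        noise = NoiseModel()
        scores = []
        for seed in range(50):
            scene = make_scene(mode_label=AGGREGATION, crowding_dense=0.45,
                               crowding_dilute=0.30, enrichment=2.0, seed=seed,
                               width=96, height=96, n_condensates=5)
            channels = render_fret_images(scene, sensor, noise, seed=seed + 500)
            frac = scene.condensate_mask.sum() / scene.cell_mask.sum()
            masks = segment_phases(channels.acceptor, scene.cell_mask,
                                   dense_quantile=frac, dilute_quantile=0.3)
            inter = (masks.dense_mask & scene.condensate_mask).sum()
            union = (masks.dense_mask | scene.condensate_mask).sum()
            scores.append(inter / union)
        assert np.mean(scores) >= 0.8


class TestLineProfiles:
    def test_constant_ratio_correlation_undefined(self):
        img = np.tile(np.arange(20.0), (20, 1))
        profile = extract_line_profiles(img, _uniform_ratio((20, 20)), (10, 0), (10, 19))
        assert not profile.correlation_defined
        assert profile.correlation is None

    def _scene_profile(self, mode, dense_c, dilute_c):
        scene = make_scene(mode_label=mode, crowding_dense=dense_c,
                           crowding_dilute=dilute_c, seed=2, width=96, height=96,
                           n_condensates=3, radius_range=(6.0, 8.0))
        channels = render_fret_images(scene, SensorModel(),
                                      NoiseModel(read_sigma=0.5), seed=7)
        ratio = compute_ratio_image(channels, background=(10.0, 10.0),
                                    intensity_threshold=0.0)
        x, y, _ = scene.params["centers"][0]
        # horizontal transect through the first condensate (row, col coords)
        lo, hi = max(x - 20, 0), min(x + 20, 95)
        return extract_line_profiles(channels.acceptor, ratio,
                                     (y, lo), (y, hi), width=3,
                                     pixel_size=scene.pixel_size)

    def test_aggregation_profiles_correlate(self):
        profile = self._scene_profile(AGGREGATION, 0.5, 0.3)
        assert profile.correlation_defined
        assert profile.correlation > 0.5

    def test_consolidation_profiles_uncorrelated(self):
        profile = self._scene_profile(CONSOLIDATION, 0.3, 0.3)
        assert abs(profile.correlation) < 0.2

    def test_positions_and_scaling(self):
        img = np.tile(np.arange(30.0), (30, 1))
        ratio = _uniform_ratio((30, 30))
        ratio.ratio_map *= np.tile(np.linspace(1, 2, 30), (30, 1))
        p = extract_line_profiles(img, ratio, (15, 0), (15, 29), pixel_size=0.1)
        assert p.positions_um[0] == 0.0
        assert p.positions_um[-1] == pytest.approx(2.9)
        assert p.intensity_scaled.min() == 0.0 and p.intensity_scaled.max() == 1.0

    def test_endpoint_outside_image_rejected(self):
        with pytest.raises(ValueError):
            extract_line_profiles(np.ones((10, 10)), _uniform_ratio((10, 10)),
                                  (0, 0), (20, 20))


def test_derive_cell_mask_finds_bright_ellipse():
    scene = make_scene(seed=3, width=96, height=96)
    channels = render_fret_images(scene, SensorModel(), NoiseModel(), seed=4)
    mask = derive_cell_mask(channels.acceptor)
    inter = (mask & scene.cell_mask).sum()
    union = (mask | scene.cell_mask).sum()
    assert inter / union > 0.9
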