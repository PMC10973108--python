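import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from gazesim.core import Zone
from gazesim.saliency import (
    AOILayout,
    AOISaliencyStream,
    FormatError,
    aggregate_aoi,
    bottom_up_distribution,
    bottom_up_table,
    dynamic_saliency,
    static_saliency,
    stream_from_frames,
)


@pytest.fixture
def layout():
    return AOILayout(
        image_size=(40, 30),
        face=(8, 4, 32, 26),
        eyes=(12, 8, 28, 12),
        mouth=(14, 18, 26, 22),
    )


class TestAOILayout:
    def test_rectangles_validated(self):
        with pytest.raises(FormatError):
            AOILayout(image_size=(40, 30), face=(0, 0, 50, 20),
                      eyes=(1, 1, 5, 5), mouth=(10, 10, 20, 20))
        with pytest.raises(FormatError):  # eyes/mouth overlap
            AOILayout(image_size=(40, 30), face=(0, 0, 40, 30),
                      eyes=(5, 5, 20, 20), mouth=(15, 15, 30, 25))

    def test_zone_mask_partitions_image(self, layout):
        mask = layout.zone_mask()
        assert mask.shape == (30, 40)
        assert set(np.unique(mask)) == {0, 1, 2, 3}
        # eyes rect fully labelled Eyes
        assert (mask[8:12, 12:28] == 0).all()
        assert (mask[18:22, 14:26] == 1).all()

    def test_point_mapping_and_half_open_boundaries(self, layout):
        assert layout.zone_of_point(12, 8) is Zone.EYES  # inclusive corner
        assert layout.zone_of_point(28, 8) is Zone.ROF   # exclusive edge
        assert layout.zone_of_point(20, 20) is Zone.MOUTH
        assert layout.zone_of_point(9, 5) is Zone.ROF
        assert layout.zone_of_point(1, 1) is Zone.OTHER
        assert layout.zone_of_point(-1, 5) is None
        assert layout.zone_of_point(40, 5) is None

    def test_json_round_trip(self, layout, tmp_path):
        path = tmp_path / "layout.json"
        layout.to_json(path)
        assert AOILayout.from_json(path) == layout


class TestStaticSaliency:
    def test_constant_image_has_zero_saliency(self):
        assert static_saliency(np.full((20, 20), 0.7)).max() == pytest.approx(0.0)

    def test_single_bright_pixel_peaks_at_pixel(self):
        img = np.zeros((31, 31))
        img[15, 15] = 1.0
        sal = static_saliency(img)
        assert np.unravel_index(np.argmax(sal), sal.shape) == (15, 15)

    def test_step_edge_matches_single_scale_convolution_oracle(self):
        img = np.zeros((24, 24))
        img[:, 12:] = 1.0
        sal = static_saliency(img, scales=((1.0, 4.0),), normalize_scales=False)
        oracle = np.abs(
            gaussian_filter(img, 1.0, mode="nearest")
            - gaussian_filter(img, 4.0, mode="nearest")
        )
        np.testing.assert_allclose(sal, oracle, atol=1e-12)
        # ridge of high saliency along the step
        assert sal[:, 10:14].mean() > 5 * sal[:, :6].mean()

    def test_invariant_to_constant_offset(self, rng):
        img = rng.random((20, 20)) * 0.5
        np.testing.assert_allclose(
            static_saliency(img), static_saliency(img + 0.3), atol=1e-9
        )

    def test_rejects_non_2d(self):
        with pytest.raises(FormatError):
            static_saliency(np.zeros((3, 3, 3)))
        with pytest.raises(FormatError):
            static_saliency(np.zeros((0, 5)))


class TestDynamicSaliency:
    def test_identical_frames_are_zero(self, rng):
        img = rng.random((10, 10))
        assert dynamic_saliency(img, img).max() == 0.0

    def test_squared_intensity_difference(self):
        a = np.zeros((5, 5))
        b = np.zeros((5, 5))
        a[2, 2] = 1.0
        assert dynamic_saliency(a, b)[2, 2] == pytest.approx(1.0)
        a[2, 2], b[2, 2] = 0.3, 0.5
        # |0.09 - 0.25|
        assert dynamic_saliency(a, b)[2, 2] == pytest.approx(0.16)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(FormatError):
            dynamic_saliency(np.zeros((4, 4)), np.zeros((5, 5)))


class TestAggregateAOI:
    def test_uniform_map(self, layout):
        means = aggregate_aoi(np.full(layout.shape, 0.7), layout)
        np.testing.assert_allclose(means, 0.7, atol=1e-12)

    def test_indicator_map_concentrates_on_eyes(self, layout):
        amap = np.zeros(layout.shape)
        amap[8:12, 12:28] = 1.0
        means = aggregate_aoi(amap, layout)
        assert means[0] == pytest.approx(1.0)
        assert means[1] == 0.0 and means[2] == 0.0 and means[3] == 0.0

    def test_checkerboard_average(self):
        layout = AOILayout(image_size=(8, 8), face=(0, 0, 8, 8),
                           eyes=(2, 2, 4, 4), mouth=(5, 5, 7, 7))
        amap = np.indices((8, 8)).sum(axis=0) % 2
        means = aggregate_aoi(amap.astype(float), layout)
        assert means[0] == pytest.approx(0.5)

    def test_mismatched_map_rejected(self, layout):
        with pytest.raises(FormatError):
            aggregate_aoi(np.zeros((5, 5)), layout)


class TestBottomUpDistribution:
    def test_theta_endpoints_select_components(self):
        static = (0.7, 0.1, 0.1, 0.1)
        dynamic = (0.1, 0.7, 0.1, 0.1)
        np.testing.assert_allclose(
            bottom_up_distribution(static, dynamic, 1.0).probs, static, atol=1e-12
        )
        np.testing.assert_allclose(
            bottom_up_distribution(static, dynamic, 0.0).probs, dynamic, atol=1e-12
        )

    def test_hand_mixture(self):
        dist = bottom_up_distribution(
            (0.7, 0.1, 0.1, 0.1), (0.1, 0.7, 0.1, 0.1), 0.5
        )
        np.testing.assert_allclose(dist.probs, (0.4, 0.4, 0.1, 0.1), atol=1e-12)

    @pytest.mark.parametrize("theta", [0.25, 0.5, 0.75])
    def test_linear_in_theta(self, theta, rng):
        static = rng.dirichlet(np.ones(4))
        dynamic = rng.dirichlet(np.ones(4))
        ends = (
            bottom_up_distribution(static, dynamic, 0.0).probs,
            bottom_up_distribution(static, dynamic, 1.0).probs,
        )
        mixed = bottom_up_distribution(static, dynamic, theta).probs
        np.testing.assert_allclose(
            mixed, (1 - theta) * ends[0] + theta * ends[1], atol=1e-12
        )

    def test_all_zero_streams_fall_back_to_uniform(self):
        with pytest.warns(UserWarning):
            dist = bottom_up_distribution((0, 0, 0, 0), (0, 0, 0, 0), 0.5)
        np.testing.assert_allclose(dist.probs, 0.25, atol=1e-12)

    def test_table_matches_pointwise(self, rng):
        static = rng.random((30, 4))
        dynamic = rng.random((30, 4))
        dynamic[0] = 0.0
        stream = AOISaliencyStream(static, dynamic)
        table = bottom_up_table(stream, 0.3)
        import warnings

        for t in [0, 7, 29]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                expected = bottom_up_distribution(static[t], dynamic[t], 0.3)
            np.testing.assert_allclose(table[t], expected.probs, atol=1e-12)


class TestStreamFromFrames:
    def test_stream_length_and_zero_first_dynamic(self, layout, rng):
        frames = [rng.random(layout.shape) for _ in range(5)]
        stream = stream_from_frames(frames, layout)
        assert len(stream) == 5
        np.testing.assert_allclose(stream.dynamic[0], 0.0, atol=1e-12)

    def test_identical_frames_have_zero_dynamic(self, layout, rng):
        img = rng.random(layout.shape)
        stream = stream_from_frames([img, img], layout)
        np.testing.assert_allclose(stream.dynamic, 0.0, atol=1e-12)

    def test_motion_in_mouth_dominates_dynamic(self, layout):
        base = np.full(layout.shape, 0.5)
        moved = base.copy()
        moved[18:22, 14:26] = 0.9  # inside mouth rect
        stream = stream_from_frames([base, moved], layout)
        assert stream.dynamic[1, 1] > stream.dynamic[1, [0, 2, 3]].max()

    def test_inconsistent_shapes_rejected(self, layout):
        with pytest.raises(FormatError):
            stream_from_frames([np.zeros((30, 40)), np.zeros((31, 40))], layout)
        with pytest.raises(FormatError):
            stream_from_frames([np.zeros((30, 40))], layout)

    def test_tsv_round_trip(self, layout, rng, tmp_path):
        frames = [rng.random(layout.shape) for _ in range(4)]
        stream = stream_from_frames(frames, layout)
        path = tmp_path / "stream.tsv"
        stream.to_tsv(path)
        loaded = AOISaliencyStream.from_tsv(path)
        np.testing.assert_allclose(loaded.static, stream.static, atol=1e-9)
        np.testing.assert_allclose(loaded.dynamic, stream.dynamic, atol=1e-9)
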