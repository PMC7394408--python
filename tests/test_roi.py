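"""ROI primitives: thresholding, components, scaling, set algebra, boundaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import inclusiontools as it
from inclusiontools.errors import EmptyROIError, GeometryError, ThresholdError
from oracle_utils import brute_boundary, raster_disk


def roi_from_coords(coords, shape=(16, 16)):
    return it.PixelROI(frozenset(coords), shape)


# -- auto_threshold ---------------------------------------------------------


def test_threshold_recovers_noiseless_disk_exactly():
    mask = raster_disk((100, 100), (50, 50), 18)
    channel = np.where(mask, 100.0, 0.0)
    roi = it.auto_threshold(channel)
    assert roi.to_mask().tolist() == mask.tolist()
    assert roi.metadata["method"] == "otsu"
    assert 0 < roi.metadata["threshold"] < 100


def test_threshold_constant_image_raises():
    with pytest.raises(ThresholdError):
        it.auto_threshold(np.full((32, 32), 7.0))


def test_threshold_with_noise_high_jaccard_against_ground_truth():
    """Jaccard vs the generator's true disk >= 0.95 at 10%-of-contrast noise."""
    worst = 1.0
    for seed in range(20):
        spec = it.maturity_scene_spec(0.3, cerulean_level=100.0,
                                      noise_sigma=10.0, seed=seed)
        image, truth = it.render_scene(spec)
        roi = it.largest_component(it.auto_threshold(image["cerulean"]))
        inter = len(roi.coordinates & truth.inclusion_roi.coordinates)
        union = len(roi.coordinates | truth.inclusion_roi.coordinates)
        worst = min(worst, inter / union)
    assert worst >= 0.95


# -- largest_component ------------------------------------------------------


def test_largest_component_picks_bigger_disk():
    mask = raster_disk((100, 100), (30, 30), 10) | raster_disk((100, 100), (70, 70), 5)
    roi = it.largest_component(it.PixelROI.from_mask(mask))
    assert roi.to_mask().tolist() == raster_disk((100, 100), (30, 30), 10).tolist()


def test_largest_component_identity_for_single_component(disk_roi):
    assert it.largest_component(disk_roi) == disk_roi


def test_largest_component_tie_broken_lexicographically():
    # two 2x2 squares of equal area; the one containing (1,1) must win
    coords_a = {(1, 1), (1, 2), (2, 1), (2, 2)}
    coords_b = {(10, 10), (10, 11), (11, 10), (11, 11)}
    roi = it.largest_component(roi_from_coords(coords_a | coords_b))
    assert roi.coordinates == frozenset(coords_a)


def test_largest_component_empty_raises():
    with pytest.raises(EmptyROIError):
        it.largest_component(it.PixelROI(frozenset(), (8, 8)))


# -- scale_roi --------------------------------------------------------------


def test_scale_identity(disk_roi):
    assert it.scale_roi(disk_roi, 1.0).coordinates == disk_roi.coordinates


def test_scale_110_percent_matches_rasterized_radius_22(disk_roi):
    scaled = it.scale_roi(disk_roi, 1.10)
    oracle = raster_disk((200, 200), (100, 100), 22)
    assert abs(scaled.area - np.pi * 22 ** 2) / (np.pi * 22 ** 2) < 0.05
    inter = len(scaled.coordinates & it.PixelROI.from_mask(oracle).coordinates)
    union = len(scaled.coordinates | it.PixelROI.from_mask(oracle).coordinates)
    assert inter / union > 0.9


def test_scale_half_area_ratio(disk_roi):
    scaled = it.scale_roi(disk_roi, 0.5)
    assert abs(scaled.area / disk_roi.area - 0.25) < 0.025


@pytest.mark.parametrize("factor", [0.8, 0.9, 1.1, 1.25])
@pytest.mark.parametrize("radius", [10, 20, 35])
def test_scale_round_trip_jaccard(factor, radius):
    roi = it.PixelROI.from_mask(raster_disk((120, 120), (60, 60), radius))
    back = it.scale_roi(it.scale_roi(roi, factor), 1.0 / factor)
    inter = len(back.coordinates & roi.coordinates)
    union = len(back.coordinates | roi.coordinates)
    assert inter / union >= 0.9


def test_scale_invalid_factor(disk_roi):
    with pytest.raises(ValueError):
        it.scale_roi(disk_roi, 0.0)


# -- subtract / set algebra -------------------------------------------------


def test_subtract_disjoint_returns_a(disk_roi):
    b = it.PixelROI.from_mask(raster_disk((200, 200), (20, 20), 5))
    assert it.subtract(disk_roi, b).coordinates == disk_roi.coordinates


def test_subtract_self_is_empty(disk_roi):
    assert it.subtract(disk_roi, disk_roi).is_empty


def test_subtract_half_plane_leaves_half_disk():
    # disk centred between columns so the diameter splits it exactly
    disk = it.PixelROI.from_mask(raster_disk((200, 200), (100, 99.5), 20))
    mask = np.zeros((200, 200), dtype=bool)
    mask[:, 100:] = True
    half = it.subtract(disk, it.PixelROI.from_mask(mask))
    assert abs(half.area - disk.area / 2) / (disk.area / 2) < 0.02


def test_subtract_shape_mismatch_raises(disk_roi):
    with pytest.raises(GeometryError):
        it.subtract(disk_roi, it.PixelROI(frozenset({(0, 0)}), (10, 10)))


coords_strategy = st.sets(
    st.tuples(st.integers(0, 15), st.integers(0, 15)), min_size=0, max_size=60
)


@settings(deadline=None, derandomize=True)
@given(a=coords_strategy, b=coords_strategy)
def test_subtract_conserves_pixels(a, b):
    """subtract(a, b) | (a & b) == a for arbitrary pixel sets."""
    ra, rb = roi_from_coords(a), roi_from_coords(b)
    diff = it.subtract(ra, rb)
    assert diff.coordinates | (ra.coordinates & rb.coordinates) == ra.coordinates


# -- mean_intensity ---------------------------------------------------------


def test_mean_intensity_constant_and_two_pixel():
    img = np.full((8, 8), 7.0)
    assert it.mean_intensity(img, roi_from_coords({(1, 1), (2, 2)}, (8, 8))) == 7.0
    img[1, 1], img[2, 2] = 10.0, 20.0
    assert it.mean_intensity(img, roi_from_coords({(1, 1), (2, 2)}, (8, 8))) == 15.0


def test_mean_intensity_uniform_disk_exact(disk_roi):
    channel = np.where(disk_roi.to_mask(), 42.0, 0.0)
    assert it.mean_intensity(channel, disk_roi) == 42.0


def test_mean_intensity_empty_raises():
    with pytest.raises(EmptyROIError):
        it.mean_intensity(np.zeros((4, 4)), it.PixelROI(frozenset(), (4, 4)))


# -- circular_roi -----------------------------------------------------------


def test_circular_roi_area_close_to_analytic():
    roi = it.circular_roi((100, 100), 25, (200, 200))
    assert abs(roi.area - np.pi * 25 ** 2) / (np.pi * 25 ** 2) < 0.02


def test_circular_roi_radius_one_contains_cross():
    roi = it.circular_roi((5, 5), 1, (11, 11))
    assert {(5, 5), (4, 5), (6, 5), (5, 4), (5, 6)} <= roi.coordinates


def test_circular_roi_corner_quarter_disk():
    full = it.circular_roi((100, 100), 25, (200, 200))
    corner = it.circular_roi((0, 0), 25, (200, 200))
    assert abs(corner.area - full.area / 4) / (full.area / 4) < 0.06


def test_circular_roi_outside_image_raises():
    with pytest.raises(GeometryError):
        it.circular_roi((-100, -100), 5, (20, 20))


# -- boundary / centroid ----------------------------------------------------


@settings(deadline=None, derandomize=True, max_examples=40)
@given(coords=coords_strategy.filter(lambda s: len(s) > 0))
def test_boundary_matches_brute_force_neighbor_scan(coords):
    roi = roi_from_coords(coords)
    assert roi.boundary().to_mask().tolist() == brute_boundary(roi.to_mask()).tolist()


def test_boundary_of_disk_matches_brute_force(disk_roi):
    assert (disk_roi.boundary().to_mask().tolist()
            == brute_boundary(disk_roi.to_mask()).tolist())


def test_centroid_inside_bounding_box(disk_roi):
    c = disk_roi.centroid()
    arr = disk_roi.coord_array
    assert arr[:, 0].min() <= c.row <= arr[:, 0].max()
    assert arr[:, 1].min() <= c.col <= arr[:, 1].max()
    assert abs(c.row - 100) < 0.5 and abs(c.col - 100) < 0.5


# -- serialization ----------------------------------------------------------


def test_rle_round_trip(tmp_path, disk_roi):
    path = tmp_path / "roi.json"
    disk_roi.to_json(path)
    assert it.PixelROI.from_json(path) == disk_roi


def test_label_tiff_import(tmp_path, disk_roi):
    import tifffile

    path = tmp_path / "labels.tif"
    tifffile.imwrite(path, disk_roi.to_mask().astype(np.uint8))
    assert it.PixelROI.from_label_tiff(path).coordinates == disk_roi.coordinates
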