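"""Tile iteration, the skip rule, standardization and HF-map accumulation."""
import numpy as np
import pytest

from hfmap import (
    CTSlice,
    MapParams,
    ProfileParams,
    StandardizationSpec,
    compute_hf_map,
    compute_hf_map_pair,
    iter_tiles,
    slice_feature,
    standardize,
    tile_skip,
)

STEP100 = ProfileParams(threshold_step=100.0)


def uniform_slice(value=-500.0, n=12, spacing=(1.0, 1.0)) -> CTSlice:
    return CTSlice(np.full((n, n), value), spacing)


def test_iter_tiles_counts_and_order():
    origins = iter_tiles((512, 512), 32, 8)
    assert len(origins) == 61 * 61 == 3721
    assert origins[0] == (0, 0) and origins[1] == (0, 8)  # row-major
    assert iter_tiles((32, 32), 32, 8) == [(0, 0)]
    non_overlap = iter_tiles((64, 64), 32, 32)
    assert non_overlap == [(0, 0), (0, 32), (32, 0), (32, 32)]
    with pytest.raises(ValueError):
        iter_tiles((16, 16), 32, 8)


def test_skip_rule_is_strict():
    tile = np.zeros((20, 20), dtype=bool)
    assert tile_skip(tile, 0.95)                      # fully outside -> skip
    assert not tile_skip(~tile, 0.95)                 # fully inside -> keep
    tile.flat[:20] = True                             # 380/400 = exactly 0.95 outside
    assert not tile_skip(tile, 0.95)                  # "over 95%" is strict: keep
    tile.flat[19] = False                             # 381/400 > 0.95 outside
    assert tile_skip(tile, 0.95)


def test_standardization_modes():
    area = StandardizationSpec("pixel_area", (0.5, 0.5))
    assert standardize(10.0, area) == 40.0
    assert standardize(10.0, StandardizationSpec("none")) == 10.0
    assert standardize(12.0, StandardizationSpec("tile_pixels"), 1024) == 12.0 / 1024
    assert standardize(10.0, StandardizationSpec("pixel_spacing", (0.5, 0.7))) == 20.0
    with pytest.raises(ValueError):
        standardize(1.0, StandardizationSpec("tile_pixels"), 0)


def test_analytic_uniform_slice_map():
    """Uniform -500 HU, full mask, tile 4 / shift 2, no standardization:
    every tile's max-b0 is 1, so pixel values equal tile coverage."""
    ct = uniform_slice()
    params = MapParams(tile_size=4, shift=2, standardization="none", profile=STEP100)
    hf = compute_hf_map(ct, np.ones(ct.shape, dtype=bool), params)
    assert hf.values[6, 6] == 4.0      # interior pixel covered by 4 tiles
    assert hf.values[0, 0] == 1.0      # corner covered by 1 tile
    assert slice_feature(hf) == 4.0
    assert hf.n_skipped == 0


def test_empty_mask_gives_zero_map():
    ct = uniform_slice()
    params = MapParams(tile_size=4, shift=2, profile=STEP100)
    hf = compute_hf_map(ct, np.zeros(ct.shape, dtype=bool), params)
    assert not hf.values.any()
    assert slice_feature(hf) == 0.0


def test_shift_equal_tile_gives_single_coverage():
    ct = uniform_slice()
    params = MapParams(tile_size=4, shift=4, standardization="none", profile=STEP100)
    hf = compute_hf_map(ct, np.ones(ct.shape, dtype=bool), params)
    assert (hf.values == 1.0).all()


def test_pixel_area_standardization_scales_with_spacing():
    rng = np.random.default_rng(2)
    hu = rng.uniform(-800.0, -300.0, size=(16, 16))
    mask = np.ones((16, 16), dtype=bool)
    params = MapParams(tile_size=8, shift=4, profile=STEP100)
    a = compute_hf_map(CTSlice(hu, (0.7, 0.7)), mask, params)
    b = compute_hf_map(CTSlice(hu, (1.4, 1.4)), mask, params)
    np.testing.assert_allclose(b.values, a.values / 4.0)


def test_removing_skip_rule_never_decreases_values():
    rng = np.random.default_rng(3)
    hu = rng.uniform(-800.0, -300.0, size=(24, 24))
    mask = np.zeros((24, 24), dtype=bool)
    mask[4:12, 4:20] = True
    kwargs = dict(tile_size=8, shift=4, standardization="none", profile=STEP100)
    with_skip = compute_hf_map(CTSlice(hu), mask, MapParams(skip_fraction=0.5, **kwargs))
    no_skip = compute_hf_map(CTSlice(hu), mask, MapParams(skip_fraction=1.0, **kwargs))
    assert (no_skip.values >= with_skip.values).all()
    assert no_skip.n_skipped == 0 and with_skip.n_skipped > 0


def test_coverage_bound():
    rng = np.random.default_rng(4)
    hu = rng.uniform(-800.0, -300.0, size=(16, 16))
    mask = np.ones((16, 16), dtype=bool)
    params = MapParams(tile_size=8, shift=2, standardization="none", profile=STEP100)
    m0, _ = compute_hf_map_pair(CTSlice(hu), mask, params)
    coverage = (params.tile_size // params.shift) ** 2
    per_tile_max = max(
        m0.values[r : r + 8, c : c + 8].max() for r, c in iter_tiles((16, 16), 8, 2)
    )
    assert m0.values.max() <= coverage * per_tile_max


def test_determinism_identical_bytes():
    rng = np.random.default_rng(9)
    hu = rng.uniform(-900.0, -200.0, size=(20, 20))
    mask = rng.random((20, 20)) < 0.8
    params = MapParams(tile_size=8, shift=4, profile=STEP100)
    a = compute_hf_map(CTSlice(hu, (0.7, 0.7)), mask, params)
    b = compute_hf_map(CTSlice(hu, (0.7, 0.7)), mask, params)
    assert a.values.tobytes() == b.values.tobytes()


def test_argmax_mode_accumulates_thresholds():
    ct = uniform_slice()
    params = MapParams(
        tile_size=4, shift=4, standardization="none", profile=STEP100, mode="argmax"
    )
    hf = compute_hf_map(ct, np.ones(ct.shape, dtype=bool), params)
    # per-tile b0 profile is (1,1,1,0); first maximizer is the lowest threshold
    assert (hf.values == -700.0).all()


def test_param_validation():
    with pytest.raises(ValueError):
        MapParams(shift=0)
    with pytest.raises(ValueError):
        MapParams(shift=33)
    with pytest.raises(ValueError):
        MapParams(skip_fraction=0.0)
    with pytest.raises(ValueError):
        MapParams(standardization="per_tile")
    with pytest.raises(ValueError):
        MapParams(index="b2")
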