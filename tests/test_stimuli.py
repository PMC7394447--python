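"""Stimulus generation: geometry, labels, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uncrowd import stimuli as sti
from uncrowd.stimuli import (EXP1_CLASSES, EXP1_SHAPES, AugmentationConfig,
                             Exp2ShapeSpec, StimulusConfig, TestCondition,
                             augment, build_test_battery, build_training_set,
                             compose_test_stimulus, cuboid_patch,
                             render_exp2_stimulus, render_shape_group,
                             render_vernier, scrambled_cuboid_patch,
                             shape_patch, vernier_patch)


# ------------------------------------------------------------ render_vernier
def test_vernier_mirror_symmetry(stim_cfg):
    left = render_vernier("left", stim_cfg)
    right = render_vernier("right", stim_cfg)
    assert np.array_equal(left.image[:, ::-1], right.image)


def test_vernier_pixel_count(stim_cfg):
    frame = render_vernier("left", stim_cfg)
    expected = 2 * stim_cfg.bar_length * stim_cfg.bar_width
    assert (frame.image > 0).sum() == expected


def test_vernier_labels(stim_cfg):
    frame = render_vernier("right", stim_cfg)
    assert frame.shape_class == "vernier"
    assert frame.vernier_offset == "right"


def test_vernier_label_space_is_three():
    from uncrowd.heads_losses import VERNIER_LABELS
    assert VERNIER_LABELS == ("left", "right", "none")


def test_vernier_bad_direction(stim_cfg):
    with pytest.raises(ValueError):
        render_vernier("up", stim_cfg)


def test_vernier_geometry_exceeding_canvas():
    cfg = StimulusConfig(height=6, width=9, bar_length=10)
    with pytest.raises(ValueError, match="exceeds canvas"):
        render_vernier("left", cfg)


# -------------------------------------------------------- render_shape_group
def test_single_shape_centered(stim_cfg):
    frame = render_shape_group("square", 1, cfg=stim_cfg)
    x, y = frame.target_location
    assert abs(x - stim_cfg.width // 2) <= 1
    assert abs(y - stim_cfg.height // 2) <= 1


@pytest.mark.parametrize("shape", EXP1_SHAPES)
def test_group_pixel_count_scales_exactly(shape, stim_cfg):
    one = (render_shape_group(shape, 1, cfg=stim_cfg).image > 0).sum()
    five = (render_shape_group(shape, 5, cfg=stim_cfg).image > 0).sum()
    assert five == 5 * one


def test_bounding_box_width_increases_with_n(stim_cfg):
    widths = []
    for n in (1, 3, 5):
        img = render_shape_group("circle", n, cfg=stim_cfg).image
        cols = np.nonzero(img)[1]
        widths.append(cols.max() - cols.min())
    assert widths[0] < widths[1] < widths[2]


def test_invalid_repetition_count(stim_cfg):
    with pytest.raises(ValueError):
        render_shape_group("square", 2, cfg=stim_cfg)


def test_group_wider_than_canvas():
    cfg = StimulusConfig(height=44, width=41, shape_size=14)
    with pytest.raises(ValueError):
        render_shape_group("square", 5, cfg=cfg)


# -------------------------------------------------------- experiment-2 shapes
def test_cuboid_and_scramble_pixel_counts_match(small_stim_cfg, rng):
    spec_c = Exp2ShapeSpec("cuboid_pair", pair_spacing=3)
    spec_s = Exp2ShapeSpec("scrambled_cuboid_pair", pair_spacing=3)
    n_cub = (render_exp2_stimulus(spec_c, small_stim_cfg, rng).image > 0).sum()
    n_scr = (render_exp2_stimulus(spec_s, small_stim_cfg, rng).image > 0).sum()
    assert n_cub == n_scr


def test_cuboid_segments_are_pixel_disjoint(small_stim_cfg):
    """The scramble-preserving property rests on disjoint segments."""
    from uncrowd.stimuli import _bresenham, _cuboid_segments
    L, wc, d = (small_stim_cfg.flanker_line_length, small_stim_cfg.cuboid_width,
                small_stim_cfg.cuboid_depth)
    shape = (L + d, wc + d + 1)
    total = np.zeros(shape, dtype=int)
    for r0, c0, r1, c1 in _cuboid_segments(small_stim_cfg):
        m = np.zeros(shape, dtype=bool)
        _bresenham(m, r0, c0, r1, c1)
        total += m
    assert total.max() == 1


def test_cuboid_inner_edge_matches_line_condition(small_stim_cfg):
    """The centermost cuboid edge sits exactly where the flanking line is."""
    cfg = small_stim_cfg
    battery = {c.name: c for c in build_test_battery(2)}
    vern = render_vernier("left", cfg)
    rng = np.random.default_rng(0)
    lines = compose_test_stimulus(vern, battery["lines_pair"], cfg, rng).image
    cubs = compose_test_stimulus(vern, battery["cuboids_pair"], cfg, rng).image
    # columns of the flanking lines (exclude the vernier's own columns)
    vcols = set(np.nonzero(vern.image)[1])
    line_cols = sorted(set(np.nonzero(lines)[1]) - vcols)
    cc = cfg.width // 2
    expected = [cc - cfg.flanker_distance, cc + cfg.flanker_distance]
    assert line_cols == expected
    # those columns must carry a full-length vertical edge in the cuboids too
    for col in expected:
        assert cubs[:, col].sum() >= cfg.flanker_line_length


def test_pair_spacing_range_checked():
    with pytest.raises(ValueError):
        Exp2ShapeSpec("cuboid_pair", pair_spacing=0)
    with pytest.raises(ValueError):
        Exp2ShapeSpec("cuboid_pair", pair_spacing=7)


def test_invalid_exp2_kind():
    with pytest.raises(ValueError):
        Exp2ShapeSpec("triangle_pair")


def test_line_group_evenly_spaced(small_stim_cfg, rng):
    spec = Exp2ShapeSpec("line_group", line_count=4, pair_spacing=2)
    img = render_exp2_stimulus(spec, small_stim_cfg, rng).image
    cols = np.unique(np.nonzero(img)[1])
    assert len(cols) == 4
    assert len(set(np.diff(cols))) == 1  # constant pitch


# ------------------------------------------------------- compose_test_stimulus
def test_alone_condition_is_identity(stim_cfg):
    vern = render_vernier("left", stim_cfg)
    cond = TestCondition("vernier_alone", (), "alone")
    out = compose_test_stimulus(vern, cond, stim_cfg)
    assert np.array_equal(out.image, vern.image)


def test_inside_composition_centers_vernier_on_flanker(stim_cfg):
    vern = render_vernier("left", stim_cfg)
    cond = TestCondition("square_1", ("square",), "inside")
    out = compose_test_stimulus(vern, cond, stim_cfg)
    sq = render_shape_group("square", 1, cfg=stim_cfg)
    # centroid of the vernier-only pixels equals the square's centroid
    vmask = (out.image > 0) & ~(sq.image > 0)
    rows, cols = np.nonzero(vmask)
    assert abs(cols.mean() - sq.target_location[0]) <= 1.0
    assert abs(rows.mean() - sq.target_location[1]) <= 1.0


def test_outside_composition_clear_of_flankers(stim_cfg):
    vern = render_vernier("right", stim_cfg)
    cond = TestCondition("square_5_outside", ("square",) * 5, "outside")
    out = compose_test_stimulus(vern, cond, stim_cfg)
    assert out.vernier_offset == "right"
    # vernier pixels (center) and flanker bbox must not share rows
    h, w = stim_cfg.vernier_patch_shape
    r0 = stim_cfg.height // 2 - h // 2
    flanker_rows = np.nonzero(out.image[:r0 - 1, :])[0]
    assert flanker_rows.max() < r0


def test_composition_keeps_offset_label(stim_cfg):
    vern = render_vernier("left", stim_cfg)
    cond = TestCondition("circle_5", ("circle",) * 5, "inside")
    out = compose_test_stimulus(vern, cond, stim_cfg)
    assert out.vernier_offset == "left"
    assert out.image.max() <= 1.0


# ----------------------------------------------------------------- augment
def test_augment_identity(stim_cfg, rng):
    frame = render_vernier("left", stim_cfg)
    out = augment(frame, AugmentationConfig.identity(), rng)
    np.testing.assert_array_equal(out.image, frame.image)


def test_augment_clips_to_unit_interval(stim_cfg, rng):
    frame = render_vernier("left", stim_cfg)
    cfg = AugmentationConfig(noise_sd_range=(0.5, 1.0),
                             brightness_shift_range=(-0.5, 0.5),
                             contrast_factor_range=(0.1, 3.0))
    for _ in range(5):
        out = augment(frame, cfg, rng)
        assert out.image.min() >= 0.0 and out.image.max() <= 1.0


def test_augment_deterministic_under_seed(stim_cfg):
    frame = render_vernier("left", stim_cfg)
    cfg = AugmentationConfig()
    a = augment(frame, cfg, np.random.default_rng(99)).image
    b = augment(frame, cfg, np.random.default_rng(99)).image
    np.testing.assert_array_equal(a, b)


def test_augment_preserves_labels(stim_cfg, rng):
    frame = render_vernier("right", stim_cfg)
    out = augment(frame, AugmentationConfig(), rng)
    assert out.vernier_offset == "right"
    assert out.shape_class == "vernier"


def test_augmentation_config_rejects_negative_bounds():
    with pytest.raises(ValueError):
        AugmentationConfig(noise_sd_range=(-0.1, 0.1))
    with pytest.raises(ValueError):
        AugmentationConfig(contrast_factor_range=(-1.0, 1.0))


# ----------------------------------------------------------- training frames
def test_training_set_never_mixes_vernier_and_flankers(small_stim_cfg, rng):
    frames = build_training_set(1, 200, rng, small_stim_cfg)
    for f in frames:
        if f.vernier_offset != "none":
            assert f.shape_class == "vernier"
        else:
            assert f.shape_class != "vernier"


def test_training_set_class_spaces(small_stim_cfg, rng):
    frames1 = build_training_set(1, 300, rng, small_stim_cfg)
    assert set(f.shape_class for f in frames1) == set(EXP1_CLASSES)
    assert len(EXP1_CLASSES) == 7
    frames2 = build_training_set(2, 300, rng, small_stim_cfg)
    assert set(f.shape_class for f in frames2) == {
        "vernier", "lines", "cuboids", "scrambled_cuboids"}


def test_training_set_images_in_unit_interval(small_stim_cfg, rng):
    for f in build_training_set(1, 50, rng, small_stim_cfg):
        assert f.image.min() >= 0 and f.image.max() <= 1


def test_training_set_deterministic(small_stim_cfg):
    a = build_training_set(1, 20, np.random.default_rng(3), small_stim_cfg)
    b = build_training_set(1, 20, np.random.default_rng(3), small_stim_cfg)
    for fa, fb in zip(a, b):
        np.testing.assert_array_equal(fa.image, fb.image)
        assert fa.shape_class == fb.shape_class


def test_training_set_requires_frames(small_stim_cfg, rng):
    with pytest.raises(ValueError):
        build_training_set(1, 0, rng, small_stim_cfg)


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=10, deadline=None)
def test_training_frames_label_consistency(seed):
    cfg = StimulusConfig.small()
    frames = build_training_set(1, 10, np.random.default_rng(seed), cfg)
    for f in frames:
        f.validate()
        assert (f.vernier_offset == "none") == (f.shape_class != "vernier")


# ------------------------------------------------------------- test battery
def test_battery_exp1_contents():
    battery = build_test_battery(1)
    names = {c.name for c in battery}
    assert "vernier_alone" in names
    for s in EXP1_SHAPES:
        assert {f"{s}_1", f"{s}_5", f"{s}_1_outside", f"{s}_5_outside"} <= names
    # all ordered alternating pairs
    alternating = [c for c in battery if c.name.endswith("_alt")]
    assert len(alternating) == 6 * 5
    for c in alternating:
        assert len(c.flanker_layout) == 5
        assert c.flanker_layout[0] == c.flanker_layout[2] == c.flanker_layout[4]
        assert c.flanker_layout[1] == c.flanker_layout[3]
        assert c.flanker_layout[0] != c.flanker_layout[1]


def test_battery_baselines_exist():
    battery = build_test_battery(1)
    names = {c.name for c in battery}
    for c in battery:
        if c.baseline_name is not None:
            assert c.baseline_name in names


def test_battery_exp2_contents():
    names = {c.name for c in build_test_battery(2)}
    assert {"vernier_alone", "lines_pair", "cuboids_pair"} <= names


def test_battery_alone_has_no_flankers():
    for exp in (1, 2):
        for c in build_test_battery(exp):
            if c.vernier_placement == "alone":
                assert c.flanker_layout == ()


# ------------------------------------------------------------------ export
def test_write_stimulus_set(tmp_path, small_stim_cfg, rng):
    frames = build_training_set(1, 5, rng, small_stim_cfg)
    csv_path = sti.write_stimulus_set(frames, tmp_path / "out")
    import csv as csvmod
    with open(csv_path) as fh:
        rows = list(csvmod.DictReader(fh))
    assert len(rows) == 5
    assert set(rows[0]) == {"frame_id", "shape_class", "n_repetitions",
                            "vernier_offset", "x", "y", "condition_name"}
    assert (tmp_path / "out" / rows[0]["frame_id"]).exists()
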