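"""Discretization, texture matrices vs brute-force oracles, and features."""

import numpy as np
import pytest

from conftest import make_disc
from oracles import bf_glcm, bf_gldzm, bf_glrlm, bf_glszm, bf_ngldm, bf_ngtdm
from petfuse.radiomics import (
    DIRECTIONS_13,
    RadiomicsConfig,
    discretize,
    extract_all,
    first_order_features,
    glcm_matrix,
    gldzm_matrix,
    glrlm_matrix,
    glszm_matrix,
    ngldm_matrix,
    ngtdm_matrix,
    texture_features,
)
from petfuse.radiomics.texture import glcm_features, ngldm_features
from petfuse.volume import Volume


# ---------------------------------------------------------------------------
# discretization


def test_constant_roi_maps_to_level_one():
    v = Volume(np.full((3, 3, 3), 7.0))
    d = discretize(v, np.ones((3, 3, 3), bool), 32)
    assert (d.in_mask_levels() == 1).all()


def test_unit_width_bins_are_identity_plus_one():
    data = np.arange(32.0).reshape(2, 4, 4)
    d = discretize(Volume(data), np.ones((2, 4, 4), bool), 32)
    assert np.array_equal(d.levels, data.astype(int) + 1)


def test_bin_edge_goes_to_upper_bin():
    data = np.array([0.0, 5.0, 10.0]).reshape(3, 1, 1)
    d = discretize(Volume(data), np.ones((3, 1, 1), bool), 2)
    assert list(d.levels[:, 0, 0]) == [1, 2, 2]


def test_histogram_sums_to_mask_count(rng):
    data = rng.random((6, 6, 6))
    mask = rng.random((6, 6, 6)) > 0.4
    d = discretize(Volume(data), mask, 8)
    assert np.bincount(d.in_mask_levels())[1:].sum() == mask.sum()
    assert d.in_mask_levels().min() >= 1 and d.in_mask_levels().max() <= 8


# ---------------------------------------------------------------------------
# matrices vs oracles (hand examples; the 50-array sweep is in acceptance)


def test_ngldm_isolated_voxel():
    disc = make_disc(np.array([[[3]]]))
    m = ngldm_matrix(disc).matrix
    assert m[2, 0] == 1 and m.sum() == 1


def test_ngldm_uniform_cube_neighbor_census():
    """3x3x3 uniform ROI, alpha=0: corner/edge/face/center dependents."""
    disc = make_disc(np.ones((3, 3, 3), dtype=int))
    m = ngldm_matrix(disc, alpha=0).matrix
    assert m[0, 7] == 8  # corners
    assert m[0, 11] == 12  # edges
    assert m[0, 17] == 6  # faces
    assert m[0, 26] == 1  # center
    assert m.sum() == 27


def test_dependence_count_nonuniformity_on_uniform_cube():
    disc = make_disc(np.ones((3, 3, 3), dtype=int))
    feats = ngldm_features(ngldm_matrix(disc).matrix)
    expected = (8**2 + 12**2 + 6**2 + 1**2) / 27
    assert feats["dependence_count_nonuniformity"] == pytest.approx(expected)


def test_sdlgle_decreases_when_levels_shift_up():
    rng = np.random.default_rng(0)
    lev = rng.integers(1, 4, (4, 4, 4))
    base = ngldm_features(ngldm_matrix(make_disc(lev)).matrix)
    shifted = ngldm_features(ngldm_matrix(make_disc(lev + 2)).matrix)
    key = "low_dependence_low_grey_level_emphasis"
    assert shifted[key] < base[key]


def test_glcm_checkerboard_hand_count():
    lev = np.array([[[1], [2]], [[2], [1]]])  # 2x2x1 checkerboard
    disc = make_disc(lev)
    m = glcm_matrix(disc, (1, 0, 0)).matrix
    assert m[0, 1] == 2 and m[1, 0] == 2
    assert m[0, 0] == 0 and m[1, 1] == 0


@pytest.mark.parametrize("direction", [(1, 0, 0), (0, 1, 0), (1, 1, 0), (1, -1, 1)])
def test_glcm_and_glrlm_match_oracle_per_direction(rng, direction):
    lev = rng.integers(0, 4, (4, 4, 4))
    disc = make_disc(lev)
    assert np.array_equal(glcm_matrix(disc, direction).matrix, bf_glcm(lev, direction))
    ours = glrlm_matrix(disc, direction).matrix
    theirs = bf_glrlm(lev, direction)
    assert np.array_equal(ours[:, : theirs.shape[1]], theirs)
    assert ours[:, theirs.shape[1] :].sum() == 0


def test_zone_and_dependence_matrices_match_oracle(rng):
    lev = rng.integers(0, 4, (4, 4, 4))
    disc = make_disc(lev)
    assert np.array_equal(glszm_matrix(disc).matrix, bf_glszm(lev))
    assert np.array_equal(gldzm_matrix(disc).matrix, bf_gldzm(lev))
    assert np.array_equal(ngldm_matrix(disc, alpha=1).matrix, bf_ngldm(lev, alpha=1))
    assert np.allclose(ngtdm_matrix(disc).matrix, bf_ngtdm(lev))


def test_matrix_conservation_laws(rng):
    lev = rng.integers(0, 5, (5, 5, 5))
    lev[2, 2, 2] = 1  # ensure non-empty
    disc = make_disc(lev)
    n_vox = disc.n_voxels
    assert ngldm_matrix(disc).matrix.sum() == n_vox
    for d in DIRECTIONS_13:
        m = glrlm_matrix(disc, d).matrix
        lengths = np.arange(1, m.shape[1] + 1)
        assert (m * lengths).sum() == n_vox  # run-length-weighted sum
        c = glcm_matrix(disc, d).matrix
        if c.sum():
            assert (c / c.sum()).sum() == pytest.approx(1.0)


def test_invalid_direction_rejected(rng):
    disc = make_disc(rng.integers(1, 3, (3, 3, 3)))
    with pytest.raises(ValueError):
        glcm_matrix(disc, (2, 0, 0))
    with pytest.raises(ValueError):
        glrlm_matrix(disc, (0, 0, 0))


# ---------------------------------------------------------------------------
# features


def test_uniform_roi_glcm_degenerate_conventions():
    disc = make_disc(np.ones((3, 3, 3), dtype=int))
    f = glcm_features(glcm_matrix(disc, (1, 0, 0)).matrix)
    assert f["angular_second_moment"] == 1.0
    assert f["joint_entropy"] == 0.0
    assert f["correlation"] == 0.0


def test_first_order_maximum_and_iqr():
    data = np.array([1.0, 2.0, 3.0, 4.0, 100.0]).reshape(5, 1, 1)
    v = Volume(data)
    mask = np.ones((5, 1, 1), bool)
    f, _ = first_order_features(v, mask, discretize(v, mask, 4))
    assert f["stat_maximum"] == 100.0
    data4 = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
    v4 = Volume(data4)
    mask4 = np.ones((4, 1, 1), bool)
    f4, _ = first_order_features(v4, mask4, discretize(v4, mask4, 4))
    # linear-interpolation percentiles: p75 - p25 = 3.25 - 1.75
    assert f4["stat_interquartile_range"] == pytest.approx(1.5)


def test_single_voxel_roi_is_finite_and_degenerate():
    v = Volume(np.full((1, 1, 1), 4.2))
    mask = np.ones((1, 1, 1), bool)
    f, prov = first_order_features(v, mask, discretize(v, mask, 4))
    assert f["stat_mean"] == f["stat_minimum"] == f["stat_maximum"] == 4.2
    assert f["stat_variance"] == 0.0
    assert f["stat_skewness"] == 0.0 and f["stat_kurtosis"] == 0.0
    assert all(np.isfinite(list(f.values())))


def test_feature_counts_and_required_names(small_control):
    fv = extract_all(small_control)
    assert fv.feature_count == 215
    names = set(fv.values)
    assert {
        "stat_maximum",
        "stat_interquartile_range",
        "ngldm_dependence_count_nonuniformity",
        "ngldm_low_dependence_low_grey_level_emphasis",
    } <= names
    first_order = [n for n in fv.values if n.split("_")[0] in ("morph", "li", "stat", "ih", "ivh")]
    texture = [n for n in fv.values if n.split("_")[0] in ("glcm", "glrlm", "glszm", "gldzm", "ngtdm", "ngldm")]
    assert len(first_order) == 79
    assert len(texture) == 136


def test_extraction_deterministic(small_control):
    a = extract_all(small_control).values
    b = extract_all(small_control.copy()).values
    assert a == b


def test_intensity_scaling_leaves_texture_unchanged(small_control):
    fv = extract_all(small_control)
    scaled = small_control.copy(data=small_control.data * 3.0)
    scaled.brain_mask = small_control.brain_mask
    fv2 = extract_all(scaled, mask=small_control.brain_mask)
    for name, val in fv.values.items():
        fam = name.split("_")[0]
        if fam in ("glcm", "glrlm", "glszm", "gldzm", "ngtdm", "ngldm", "ih"):
            assert fv2.values[name] == pytest.approx(val, rel=1e-9), name
    assert fv2.values["stat_mean"] == pytest.approx(3.0 * fv.values["stat_mean"])
    assert fv2.values["stat_maximum"] == pytest.approx(3.0 * fv.values["stat_maximum"])


def test_rotation_invariance_of_aggregated_texture(rng):
    lev = rng.integers(0, 5, (6, 6, 6))
    lev[3, 3, 3] = 2
    base = texture_features(make_disc(lev))
    rot = texture_features(make_disc(np.rot90(lev, k=1, axes=(0, 1))))
    for name, val in base.items():
        assert rot[name] == pytest.approx(val, rel=1e-9, abs=1e-12), name


@pytest.mark.parametrize(
    "shape,fill",
    [((1, 1, 1), 1), ((2, 1, 1), 1), ((3, 3, 3), 1)],
)
def test_pathological_rois_all_finite(shape, fill):
    data = np.full(shape, float(fill))
    fv = extract_all(Volume(data), mask=np.ones(shape, bool))
    assert fv.feature_count == 215
    assert all(np.isfinite(v) for v in fv.values.values())


def test_two_distinct_voxels_finite(rng):
    data = np.array([1.0, 2.0]).reshape(2, 1, 1)
    fv = extract_all(Volume(data), mask=np.ones((2, 1, 1), bool))
    assert all(np.isfinite(v) for v in fv.values.values())


def test_empty_mask_rejected(small_control):
    with pytest.raises(ValueError):
        extract_all(small_control, mask=np.zeros(small_control.shape, bool))
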