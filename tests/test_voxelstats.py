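"""Single-subject GLM t-maps and cluster extent thresholding."""

import numpy as np
import pytest
from scipy import ndimage

from oracles import glm_t_group
from petfuse.phantom import PhantomConfig, generate_control_volume, generate_demented_volume
from petfuse.volume import Volume
from petfuse.voxelstats import TMap, single_subject_tmap, threshold_and_cluster


def _vols(arrays, spacing=(2, 2, 2)):
    return [Volume(np.asarray(a, dtype=float), spacing_mm=spacing) for a in arrays]


def test_identical_scans_give_zero_t_everywhere():
    data = np.random.default_rng(0).random((5, 5, 5))
    controls = _vols([data] * 5)
    tmap = single_subject_tmap(Volume(data.copy()), controls, 70, [60, 65, 70, 75, 80])
    assert np.allclose(tmap.t, 0.0)


def test_scalar_example_matches_normal_equations_oracle():
    """Single-voxel scans, equal ages: GLM t equals the closed-form value."""
    vals = [10.0, 11.0, 9.0, 10.0, 10.0]
    controls = _vols([np.full((1, 1, 1), v) for v in vals])
    subject = Volume(np.full((1, 1, 1), 6.0))
    tmap = single_subject_tmap(subject, controls, 70, [70] * 5)
    y = np.array(vals + [6.0])
    group = np.array([0, 0, 0, 0, 0, 1.0])
    t_expected, df_expected = glm_t_group(y, group, age=None)
    assert tmap.covariates_used == []  # zero-variance age dropped
    assert tmap.df == df_expected == 4
    assert tmap.t[0, 0, 0] == pytest.approx(t_expected, abs=1e-10)


def test_age_covariate_absorbs_linear_age_trend():
    """A subject on the controls' age-uptake line is null only with age in."""
    ages = [50.0, 60.0, 70.0, 80.0, 90.0]
    rng = np.random.default_rng(1)
    base = rng.random((3, 3, 3))
    controls = _vols([base + 0.1 * a for a in ages])
    subject_age = 30.0  # extrapolated but exactly on the trend
    subject = Volume(base + 0.1 * subject_age)
    with_age = single_subject_tmap(subject, controls, subject_age, ages)
    assert np.abs(with_age.t).max() < 1e-6

    y = np.array([0.1 * a for a in ages] + [0.1 * subject_age]) + base[0, 0, 0]
    group = np.array([0] * 5 + [1.0])
    t_no_age, _ = glm_t_group(y, group, age=None)
    assert abs(t_no_age) > 2.0  # confound visible without the covariate


def test_scalar_example_with_age_matches_oracle():
    rng = np.random.default_rng(3)
    vals = rng.normal(10, 1, 7)
    ages = rng.uniform(50, 90, 7)
    controls = _vols([np.full((1, 1, 1), v) for v in vals])
    tmap = single_subject_tmap(Volume(np.full((1, 1, 1), 7.5)), controls, 66.0, list(ages))
    y = np.append(vals, 7.5)
    group = np.append(np.zeros(7), 1.0)
    t_exp, df_exp = glm_t_group(y, group, np.append(ages, 66.0))
    assert tmap.df == df_exp
    assert tmap.t[0, 0, 0] == pytest.approx(t_exp, abs=1e-10)


def test_grid_mismatch_and_too_few_controls_raise():
    with pytest.raises(ValueError):
        single_subject_tmap(Volume(np.ones((2, 2, 2))), _vols([np.ones((3, 3, 3))] * 4), 70, [70] * 4)
    with pytest.raises(ValueError):
        single_subject_tmap(Volume(np.ones((2, 2, 2))), _vols([np.ones((2, 2, 2))] * 2), 70, [70] * 2)


def test_all_zero_tmap_gives_empty_clusterset():
    tmap = TMap(t=np.zeros((6, 6, 6)), df=10, n_controls=11)
    cs = threshold_and_cluster(tmap, 0.01, 0)
    assert cs.clusters == []
    assert not cs.label_map.any()


def test_cluster_extent_rule_is_strictly_more_than():
    """A 100-voxel blob at min_size=100 is discarded (needs > 100)."""
    t = np.zeros((10, 10, 10))
    blob = np.zeros_like(t, dtype=bool)
    blob.ravel()[:0] = False
    blob[:4, :5, :5] = True  # 100 voxels, one 18-connected component
    t[blob] = -10.0
    tmap = TMap(t=t, df=20, n_controls=21)
    assert int(blob.sum()) == 100
    cs = threshold_and_cluster(tmap, 0.01, min_size=100)
    assert cs.clusters == []
    cs99 = threshold_and_cluster(tmap, 0.01, min_size=99)
    assert [c["size_voxels"] for c in cs99.clusters] == [100]


def test_two_blob_map_keeps_only_large_component():
    t = np.zeros((12, 12, 12))
    t[:6, :5, :5] = -8.0  # 150 voxels
    t[8:, 8:, 6:] = -8.0  # 4*4*6 = 96 -> trimmed to 40 below
    t[8:, 8:, 6:] = 0.0
    t[8:10, 8:12, 7:12] = -8.0  # 2*4*5 = 40 voxels
    tmap = TMap(t=t, df=20, n_controls=21)
    cs = threshold_and_cluster(tmap, 0.01, min_size=100)
    assert len(cs.clusters) == 1
    assert cs.clusters[0]["size_voxels"] == 150
    # labels in the map are exactly the listed ids
    assert set(np.unique(cs.label_map)) == {0, 1}


def test_type_one_error_rate_at_nominal_level():
    """Null simulations: supra-threshold voxel fraction ~ p at p=0.01."""
    rng = np.random.default_rng(2024)
    shape = (10, 10, 10)
    n_controls, n_sims, p = 12, 200, 0.01
    hits = 0
    total = 0
    for _ in range(n_sims):
        controls = [Volume(rng.normal(0, 1, shape)) for _ in range(n_controls)]
        subject = Volume(rng.normal(0, 1, shape))
        tmap = single_subject_tmap(subject, controls, 70, [70.0] * n_controls)
        t_crit = threshold_and_cluster(tmap, p, 0).t_critical
        hits += int((tmap.t < -t_crit).sum())
        total += int(np.prod(shape))
    rate = hits / total
    se = np.sqrt(p * (1 - p) / total)
    assert abs(rate - p) < 5 * se


def test_implanted_lesion_recovered_with_dice_above_half():
    grid = (24, 26, 22)
    cfg = PhantomConfig(
        grid_shape=grid, noise_sd=1.5, smoothness_mm=3.0, hypometabolism_factor=0.7
    )
    controls = [generate_control_volume(cfg, seed=100 + i) for i in range(12)]
    subject = generate_demented_volume(cfg, ["frontal"], seed=999)
    tmap = single_subject_tmap(subject, controls, 70, [60 + i for i in range(12)])
    cs = threshold_and_cluster(tmap, 0.01, min_size=10)
    assert cs.clusters, "no cluster recovered"
    region = cfg.region("frontal").mask(grid) & (controls[0].data > 0)
    detected = cs.label_map > 0
    dice = 2 * (detected & region).sum() / (detected.sum() + region.sum())
    assert dice > 0.5


def test_hypo_clusters_monotone_under_global_subject_scaling():
    grid = (16, 16, 16)
    cfg = PhantomConfig(grid_shape=grid, noise_sd=2.0, smoothness_mm=3.0)
    controls = [generate_control_volume(cfg, seed=i) for i in range(8)]
    subject = generate_control_volume(cfg, seed=50)
    ages = [65.0] * 8
    counts = []
    for scale in (1.0, 0.9, 0.7):
        scaled = subject.copy(data=subject.data * scale)
        tmap = single_subject_tmap(scaled, controls, 70.0, ages)
        cs = threshold_and_cluster(tmap, 0.01, 0)
        counts.append(int((cs.label_map > 0).sum()))
    assert counts[0] <= counts[1] <= counts[2]
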