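import numpy as np
import pytest
from scipy import stats

from zfmorph.atlas import make_atlas
from zfmorph.voxelstats import (
    VoxelwiseModel,
    filter_significance,
    voxelwise_two_group,
    voxelwise_two_way_anova,
)


@pytest.fixture(scope="module")
def random_stack(rng=np.random.default_rng(42)):
    """12 subjects x 8^3 random maps with unbalanced genotype/batch labels."""
    y = rng.normal(size=(12, 8, 8, 8))
    genotype = np.array(["ctl"] * 7 + ["mut"] * 5)
    batch = np.array(["b1", "b1", "b2", "b2", "b2", "b1", "b2",
                      "b1", "b1", "b2", "b2", "b2"])
    return y, genotype, batch


def test_t_matches_scalar_oracle_at_sampled_voxels(random_stack):
    y, genotype, _ = random_stack
    res = voxelwise_two_group(y, genotype)
    rng = np.random.default_rng(0)
    flat = y.reshape(12, -1)
    for v in rng.choice(flat.shape[1], 50, replace=False):
        ref = stats.ttest_ind(flat[genotype == "ctl", v], flat[genotype == "mut", v])
        idx = np.unravel_index(v, (8, 8, 8))
        assert res.statistic[idx] == pytest.approx(ref.statistic, abs=1e-10)
        assert res.pvalue[idx] == pytest.approx(ref.pvalue, abs=1e-10)


def test_welch_matches_scipy(random_stack):
    y, genotype, _ = random_stack
    res = voxelwise_two_group(y, genotype, equal_var=False)
    flat = y.reshape(12, -1)
    for v in (0, 100, 500):
        ref = stats.ttest_ind(
            flat[genotype == "ctl", v], flat[genotype == "mut", v], equal_var=False
        )
        idx = np.unravel_index(v, (8, 8, 8))
        assert res.statistic[idx] == pytest.approx(ref.statistic, abs=1e-10)
        assert res.pvalue[idx] == pytest.approx(ref.pvalue, abs=1e-10)


def test_anova_matches_statsmodels_glm_oracle(random_stack):
    """Per-voxel F/p equal an independent Type II two-way OLS ANOVA fit."""
    import pandas as pd
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    y, genotype, batch = random_stack
    res = voxelwise_two_way_anova(y, genotype, batch)
    flat = y.reshape(12, -1)
    rng = np.random.default_rng(1)
    for v in rng.choice(flat.shape[1], 20, replace=False):
        df = pd.DataFrame({"y": flat[:, v], "g": genotype, "b": batch})
        fit = smf.ols("y ~ C(g) + C(b)", data=df).fit()
        table = anova_lm(fit, typ=2)
        idx = np.unravel_index(v, (8, 8, 8))
        assert res.statistic[idx] == pytest.approx(table.loc["C(g)", "F"], abs=1e-8)
        assert res.pvalue[idx] == pytest.approx(table.loc["C(g)", "PR(>F)"], abs=1e-8)
    assert res.df == (1, 12 - 3)


def test_anova_single_batch_equals_one_way(random_stack):
    y, genotype, _ = random_stack
    res = voxelwise_two_way_anova(y, genotype, np.repeat("b1", 12))
    flat = y.reshape(12, -1)
    for v in (3, 77, 311):
        ref = stats.f_oneway(flat[genotype == "ctl", v], flat[genotype == "mut", v])
        idx = np.unravel_index(v, (8, 8, 8))
        assert res.statistic[idx] == pytest.approx(ref.statistic, rel=1e-10)
        assert res.pvalue[idx] == pytest.approx(ref.pvalue, rel=1e-10)


def test_identical_groups_give_null_stats():
    base = np.random.default_rng(2).normal(size=(3, 6, 6, 6))
    y = np.concatenate([base, base])
    groups = np.array(["a"] * 3 + ["b"] * 3)
    res = voxelwise_two_group(y, groups)
    assert np.all(res.statistic == 0.0)
    assert np.all(res.pvalue == 1.0)


def test_constant_data_gives_f_zero_p_one():
    y = np.ones((8, 5, 5, 5))
    res = voxelwise_two_way_anova(
        y, np.array(["a"] * 4 + ["b"] * 4), np.array(["x", "y"] * 4)
    )
    assert np.all(res.statistic == 0.0)
    assert np.all(res.pvalue == 1.0)
    assert res.n_degenerate == 125


def test_zero_variance_voxels_flagged_not_nan(random_stack):
    y, genotype, _ = random_stack
    y = y.copy()
    y[:, 0, 0, 0] = 5.0  # both groups constant at one voxel
    res = voxelwise_two_group(y, genotype)
    assert res.pvalue[0, 0, 0] == 1.0 and res.statistic[0, 0, 0] == 0.0
    assert res.n_degenerate == 1
    assert np.all(np.isfinite(res.pvalue))


def test_empty_design_cell_raises(random_stack):
    y, genotype, _ = random_stack
    batch = np.where(genotype == "ctl", "b1", "b2")  # mut never in b1
    with pytest.raises(ValueError, match="empty design cell"):
        voxelwise_two_way_anova(y, genotype, batch)


def test_out_of_brain_voxels_forced_to_p_one(random_stack):
    y, genotype, _ = random_stack
    brain = np.zeros((8, 8, 8), dtype=bool)
    brain[2:6, 2:6, 2:6] = True
    res = voxelwise_two_group(y, genotype, brain_mask=brain)
    assert np.all(res.pvalue[~brain] == 1.0)
    assert np.any(res.pvalue[brain] < 1.0)


# ------------------------------------------------------------------ filtering
def test_filter_p_equal_one_gives_empty_mask(atlas32):
    roi = filter_significance(np.ones(atlas32.shape), atlas=atlas32,
                              brain_mask=atlas32.brain_mask())
    assert roi.n_voxels == 0


def test_filter_keeps_symmetric_cluster_drops_asymmetric(atlas32):
    """Constructed map: a mirror-symmetric cluster pair survives; an
    asymmetric cluster of the same size does not."""
    p = np.ones(atlas32.shape)
    plane = atlas32.mirror_plane  # 15.5 on the 32-grid
    # symmetric pair, 4x4x4 each, mirrored about the midsagittal plane
    p[4:8, 14:18, 14:18] = 0.001
    p[int(2 * plane) - 7 : int(2 * plane) - 3, 14:18, 14:18] = 0.001
    # asymmetric cluster, same size, no mirror partner
    p[20:24, 4:8, 4:8] = 0.001
    roi = filter_significance(
        p, alpha=0.01, min_cluster=32, symmetric=True, atlas=atlas32
    )
    assert roi.n_voxels == 2 * 64
    assert roi.mask[5, 15, 15] and not roi.mask[21, 5, 5]
    # the surviving mask is itself mirror-symmetric
    assert np.array_equal(roi.mask, atlas32.mirror(roi.mask))


def test_filter_cluster_size_threshold(atlas32):
    p = np.ones(atlas32.shape)
    p[10:12, 10:12, 10:12] = 0.001  # 8 voxels
    roi_keep = filter_significance(p, min_cluster=8, symmetric=False)
    roi_drop = filter_significance(p, min_cluster=9, symmetric=False)
    assert roi_keep.n_voxels == 8 and roi_drop.n_voxels == 0


def test_filter_direction_constraint():
    p = np.full((6, 6, 6), 0.001)
    sign = np.ones((6, 6, 6))
    sign[:3] = -1.0
    roi = filter_significance(p, min_cluster=1, symmetric=False,
                              sign=sign, direction="negative")
    assert roi.n_voxels == 3 * 36
    assert roi.provenance["direction"] == "negative"


def test_filter_provenance_recorded(atlas32):
    roi = filter_significance(
        np.ones(atlas32.shape), alpha=0.01, min_cluster=50, symmetric=True, atlas=atlas32
    )
    assert roi.provenance["alpha"] == 0.01
    assert roi.provenance["min_cluster"] == 50
    assert roi.provenance["symmetric"] is True
    assert roi.provenance["connectivity"] == 26


def test_group_difference_sign(atlas32, small_effect_cohort):
    model = VoxelwiseModel.from_cohort(small_effect_cohort, atlas32)
    diff = model.group_difference("ctl")
    core = atlas32.mask("lcep")
    assert diff[core].mean() < -0.2  # crispants locally smaller on LJD maps


def test_permutation_fwer_conservative_and_detects_strong_effect():
    """Max-statistic permutation p-values are valid (>= parametric raw p up
    to resolution) and still flag a large planted effect."""
    rng = np.random.default_rng(9)
    y = rng.normal(size=(12, 6, 6, 6))
    groups = np.array(["a"] * 6 + ["b"] * 6)
    # effect large enough that permuted (mixed-label) splits cannot reach the
    # observed |t|: mixed splits asymptote to a finite t as the shift grows
    y[6:, 2, 2, 2] += 25.0
    model = VoxelwiseModel(y, groups)
    raw = model.fit("t")
    fwer = model.fit_permutation_fwer(n_perm=200, seed=1)
    assert np.all(fwer.pvalue >= raw.pvalue - 1e-12)
    assert fwer.pvalue[2, 2, 2] < 0.05
    # corrected map is deterministic given the seed
    again = model.fit_permutation_fwer(n_perm=200, seed=1)
    assert np.array_equal(fwer.pvalue, again.pvalue)
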