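import numpy as np
import pytest

from zfmorph.fields import DisplacementField, jacobian_determinant, log_jacobian
from zfmorph.simulate import (
    CohortDesign,
    GroupSpec,
    _contraction_displacement,
    effect_mask,
    make_cohort,
    make_gene_tables,
    make_qpcr,
    make_subject,
    make_trace,
)


# ----------------------------------------------------------- imaging subjects
def test_identity_subject(atlas32):
    design = CohortDesign(
        groups=[GroupSpec("ctl", "b1", 2)], shape=(32, 32, 32), amplitude=0.0
    )
    s = make_subject(atlas32, "ctl", 1.0, design, seed=0)
    assert np.all(s.field.u == 0.0)
    voxvol = atlas32.voxel_volume
    for name, vol in s.truth.division_volumes.items():
        assert vol == pytest.approx(atlas32.mask(name).sum() * voxvol, rel=1e-9)


def test_contraction_only_closed_form(atlas32):
    """Pure contraction: the labeled LCeP's true volume ratio is exactly s^3."""
    design = CohortDesign(
        groups=[GroupSpec("x", "b1", 2, 0.9)], shape=(32, 32, 32), amplitude=0.0
    )
    s = make_subject(atlas32, "xrcc", 0.9, design, seed=0)
    voxvol = atlas32.voxel_volume
    for side in ("lcep_left", "lcep_right"):
        atlas_vol = atlas32.mask(side).sum() * voxvol
        assert s.truth.division_volumes[side] / atlas_vol == pytest.approx(
            0.9**3, rel=0.01
        )
    # and the measured (LJD-route) core value matches the closed form too
    core = atlas32.mask("lcep")
    assert log_jacobian(s.field).values[core].mean() == pytest.approx(
        3 * np.log(0.9), abs=1e-9
    )


def test_fields_are_orientation_preserving(atlas32):
    design = CohortDesign(
        groups=[GroupSpec("x", "b1", 2, 0.9)], shape=(32, 32, 32), truth_volumes=False
    )
    for seed in range(3):
        s = make_subject(atlas32, "xrcc", 0.9, design, seed=seed)
        assert jacobian_determinant(s.field).min() > 0


def test_subject_determinism(atlas32):
    design = CohortDesign(
        groups=[GroupSpec("x", "b1", 2, 0.9)], shape=(32, 32, 32), truth_volumes=False
    )
    a = make_subject(atlas32, "xrcc", 0.9, design, seed=5)
    b = make_subject(atlas32, "xrcc", 0.9, design, seed=5)
    assert np.array_equal(a.field.u, b.field.u)
    c = make_subject(atlas32, "xrcc", 0.9, design, seed=6)
    assert not np.array_equal(a.field.u, c.field.u)


def test_cohort_determinism_and_structure(atlas32):
    design = CohortDesign(
        groups=[GroupSpec("ctl", "b1", 2), GroupSpec("xrcc", "b1", 3, 0.9)],
        shape=(32, 32, 32),
        truth_volumes=False,
        seed=9,
    )
    a = make_cohort(design, atlas32)
    b = make_cohort(design, atlas32)
    assert len(a) == 5
    assert list(a.genotypes) == ["ctl", "ctl", "xrcc", "xrcc", "xrcc"]
    for sa, sb in zip(a, b):
        assert np.array_equal(sa.field.u, sb.field.u)
    # null subjects carry an empty effect region; affected ones the LCeP region
    assert not a.subjects[0].truth.effect_region.any()
    assert np.array_equal(a.subjects[-1].truth.effect_region, effect_mask(atlas32))


def test_effect_region_invariants(atlas32):
    eff = effect_mask(atlas32)
    assert eff.any()
    assert np.all(atlas32.brain_mask()[eff])
    assert np.array_equal(eff, atlas32.mirror(eff))


def test_channels_have_programmed_means(atlas32):
    design = CohortDesign(
        groups=[GroupSpec("ctl", "b1", 2)],
        shape=(32, 32, 32),
        channels={"gfp": {"brain": 50.0, "lcep": 200.0}},
        channel_noise=0.01,
        truth_volumes=False,
    )
    s = make_subject(atlas32, "ctl", 1.0, design, seed=1)
    assert s.channels["gfp"][atlas32.mask("lcep")].mean() == pytest.approx(200.0, rel=0.05)


def test_invalid_design_rejected():
    with pytest.raises(ValueError):
        CohortDesign(groups=[GroupSpec("ctl", "b1", 1)])
    with pytest.raises(ValueError):
        CohortDesign(groups=[GroupSpec("ctl", "b1", 2, contraction=0.0)])


# ------------------------------------------------------------------- traces
def test_trace_single_peak_when_pure_wildtype():
    trace = make_trace(wt_fraction=1.0, wt_size_bp=250.0, noise=0.0)
    assert trace.truth["fractions"] == [1.0]
    assert trace.size_bp[np.argmax(trace.rfu)] == pytest.approx(250.0, abs=0.2)


def test_trace_truth_normalized():
    trace = make_trace(wt_fraction=0.3, areas=(0.5, 0.2), noise=0.0, seed=1)
    assert sum(trace.truth["fractions"]) == pytest.approx(1.0)
    assert trace.truth["wt_fraction"] == pytest.approx(0.3)


def test_trace_area_matches_trapezoid_oracle():
    """Noise-free trace: integrating each peak window recovers its stated area."""
    trace = make_trace(
        wt_fraction=0.6, indel_sizes=(-12.0,), areas=(0.4,), noise=0.0, total_area=1000.0
    )
    for size, frac in zip(trace.truth["peak_sizes_bp"], trace.truth["fractions"]):
        window = np.abs(trace.size_bp - size) <= 5.0
        area = np.trapezoid(trace.rfu[window], trace.size_bp[window])
        assert area == pytest.approx(frac * 1000.0, rel=0.01)


def test_trace_crowded_flag():
    near = make_trace(wt_fraction=0.5, indel_sizes=(1.0,), areas=(0.5,), noise=0.0)
    far = make_trace(wt_fraction=0.5, indel_sizes=(-15.0,), areas=(0.5,), noise=0.0)
    assert near.truth["crowded"] and not far.truth["crowded"]


# --------------------------------------------------------------- gene tables
def test_gene_tables_determinism_and_truth_bookkeeping():
    a1, b1, t1 = make_gene_tables(n_genes=2000, n_true_shared=10,
                                  n_true_private_per_expt=(20, 40), seed=3)
    a2, _, _ = make_gene_tables(n_genes=2000, n_true_shared=10,
                                n_true_private_per_expt=(20, 40), seed=3)
    assert a1.equals(a2)
    assert t1["shared"].sum() == 10
    assert t1["true_in_a"].sum() == 30 and t1["true_in_b"].sum() == 50
    # shared true genes have concordant fold-change sign in both experiments
    shared = t1.loc[t1["shared"], "gene_id"]
    sa = a1.set_index("gene_id").loc[shared, "log2FoldChange"]
    sb = b1.set_index("gene_id").loc[shared, "log2FoldChange"]
    assert np.all(np.sign(sa.to_numpy()) == np.sign(sb.to_numpy()))


def test_gene_tables_null_pvalues_uniform():
    a, b, truth = make_gene_tables(
        n_genes=5000, n_true_shared=0, n_true_private_per_expt=(0, 0), seed=7
    )
    frac = (a["pvalue"] < 0.05).mean()
    # binomial 3-sigma band around 0.05 at n = 5000
    assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 5000)


def test_gene_tables_too_many_true_genes():
    with pytest.raises(ValueError):
        make_gene_tables(n_genes=10, n_true_shared=8, n_true_private_per_expt=(2, 2))


# --------------------------------------------------------------------- qPCR
def test_qpcr_noise_free_closed_forms():
    plate = make_qpcr([("ctl", 3)], {"ctl": 1.0}, sd=0.0, seed=0)
    wide = plate.pivot(index="sample", columns="gene", values="Cp")
    assert np.allclose(wide["tp53"], wide["eef1a1l1"])

    plate2 = make_qpcr([("x", 3)], {"x": 2.0}, sd=0.0, seed=0)
    wide2 = plate2.pivot(index="sample", columns="gene", values="Cp")
    assert np.allclose(wide2["eef1a1l1"] - wide2["tp53"], 1.0)


def test_qpcr_fold_recovery_within_sampling_error():
    n, sd, fold = 5, 0.2, 1.5
    plate = make_qpcr([("x", n)], {"x": fold}, sd=sd, seed=21)
    wide = plate.pivot(index="sample", columns="gene", values="Cp")
    dcp = (wide["eef1a1l1"] - wide["tp53"]).to_numpy()
    # dCp ~ N(log2 fold, 2 sd^2); mean within 3 SE of truth
    se = sd * np.sqrt(2.0 / n)
    assert abs(dcp.mean() - np.log2(fold)) < 3 * se
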