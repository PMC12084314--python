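"""End-to-end in-silico reproduction of the morphometry study design.

Stages mirror the experimental logic:

1. *discovery* — simulate a control-vs-crispant cohort (batch 1), compute
   LJD maps, run the voxelwise two-group t-test, and build the ROI by
   p < alpha thresholding with bilateral-symmetry and cluster filtering;
2. *replication* — measure that ROI's volume in an independent batch-2
   cohort and t-test controls vs crispants;
3. *combined map* — pool both batches and run the per-voxel additive
   two-way ANOVA (genotype + batch), filtered the same way;
4. *rescue* — three-group cohort (control / crispant / double crispant),
   one-way ANOVA on ROI volume percent with post hoc t-tests;
5. *expression* and *qPCR* — the DE-overlap and 2^dCp sub-analyses.

Every stage is deterministic given the config seed; each report embeds the
config hash and all thresholds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import simulate
from .atlas import LabelAtlas, make_atlas
from .expression import GeneOverlapModel, QpcrModel
from .fragment import classify_efficiency, detect_peaks, wildtype_fraction
from .simulate import Cohort, CohortDesign, GroupSpec
from .voxelstats import RoiMask, VoxelwiseModel, VoxelwiseResults

__all__ = [
    "RunConfig",
    "run_discovery",
    "run_replication",
    "run_rescue",
    "run_combined_map",
    "run_expression",
    "run_qpcr",
    "run_crispr_qc",
    "run_all",
]


@dataclass
class RunConfig:
    """All knobs of the in-silico study, JSON-serializable.

    Thresholds default to the analysis constants: voxelwise alpha 0.01,
    expression filter baseMean >= 100, FDR 0.1, wildtype-peak inclusion
    threshold 0.5.
    """

    seed: int = 0
    # imaging geometry / noise
    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    smoothness: float = 6.0
    amplitude: float = 0.5
    contraction: float = 0.9
    # group sizes (discovery, replication, rescue)
    n_discovery: tuple[int, int] = (14, 14)
    n_replication: tuple[int, int] = (14, 17)
    n_rescue: tuple[int, int, int] = (16, 14, 12)
    # voxelwise filtering
    alpha: float = 0.01
    min_cluster: int = 50
    symmetric: bool = True
    symmetry_tol: int = 0
    # the symmetry check is self-confirming within ~1 correlation length of
    # the midplane, so that band is excluded from symmetry-filtered masks
    symmetry_midline_exclusion: int = 3
    # the "affected region" mask keeps only voxels reduced in crispants
    roi_direction: str = "negative"
    reference_genotype: str = "ctl"
    # expression / crispr / qpcr
    min_base_mean: float = 100.0
    fdr_alpha: float = 0.1
    wt_threshold: float = 0.5
    qpcr_folds: dict = field(
        default_factory=lambda: {"ctl": 1.0, "xrcc": 2.5, "dbl": 1.6}
    )
    qpcr_n: int = 5
    qpcr_sd: float = 0.2

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        for key in ("shape", "spacing", "n_discovery", "n_replication", "n_rescue"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    # ------------------------------------------------------------------
    def _design(self, groups, seed_offset: int, truth: bool = False) -> CohortDesign:
        return CohortDesign(
            groups=groups,
            shape=self.shape,
            spacing=self.spacing,
            smoothness=self.smoothness,
            amplitude=self.amplitude,
            truth_volumes=truth,
            seed=self.seed + seed_offset,
        )

    def discovery_design(self) -> CohortDesign:
        n1, n2 = self.n_discovery
        return self._design(
            [GroupSpec("ctl", "b1", n1, 1.0), GroupSpec("xrcc", "b1", n2, self.contraction)],
            seed_offset=1,
        )

    def replication_design(self) -> CohortDesign:
        n1, n2 = self.n_replication
        return self._design(
            [GroupSpec("ctl", "b2", n1, 1.0), GroupSpec("xrcc", "b2", n2, self.contraction)],
            seed_offset=2,
        )

    def rescue_design(self) -> CohortDesign:
        n1, n2, n3 = self.n_rescue
        return self._design(
            [
                GroupSpec("ctl", "b3", n1, 1.0),
                GroupSpec("xrcc", "b3", n2, self.contraction),
                GroupSpec("dbl", "b3", n3, 1.0),
            ],
            seed_offset=3,
        )


def _base_report(config: RunConfig, stage: str) -> dict:
    return {
        "stage": stage,
        "config_hash": config.hash(),
        "seed": config.seed,
        "thresholds": {
            "alpha": config.alpha,
            "min_cluster": config.min_cluster,
            "symmetric": config.symmetric,
            "symmetry_tol": config.symmetry_tol,
            "min_base_mean": config.min_base_mean,
            "fdr_alpha": config.fdr_alpha,
            "wt_threshold": config.wt_threshold,
        },
    }


def run_discovery(
    config: RunConfig, atlas: LabelAtlas | None = None, cohort: Cohort | None = None
) -> tuple[RoiMask, dict]:
    """Batch-1 voxelwise discovery: t-test on LJD maps, then ROI filtering."""
    if atlas is None:
        atlas = make_atlas(config.shape, config.spacing)
    if cohort is None:
        cohort = simulate.make_cohort(config.discovery_design(), atlas)
    results = VoxelwiseModel.from_cohort(cohort, atlas).fit("t")
    roi = results.significance_mask(
        atlas,
        alpha=config.alpha,
        min_cluster=config.min_cluster,
        symmetric=config.symmetric,
        tol=config.symmetry_tol,
        direction=config.roi_direction,
        reference=config.reference_genotype,
        midline_exclusion=config.symmetry_midline_exclusion,
    )
    report = _base_report(config, "discovery")
    report.update(
        {
            "n_subjects": len(cohort),
            "roi_voxels": roi.n_voxels,
            "roi_provenance": roi.provenance,
            "min_p": float(results.pvalue.min()),
            "n_p_below_alpha": int(
                ((results.pvalue < config.alpha) & atlas.brain_mask()).sum()
            ),
        }
    )
    return roi, report


def run_replication(
    config: RunConfig,
    roi: RoiMask,
    atlas: LabelAtlas | None = None,
    cohort: Cohort | None = None,
) -> dict:
    """Measure the discovered ROI in an independent cohort; two-group t-test."""
    from .roistats import roi_replication_test

    if atlas is None:
        atlas = make_atlas(config.shape, config.spacing)
    if cohort is None:
        cohort = simulate.make_cohort(config.replication_design(), atlas)
    res = roi_replication_test(cohort, roi, atlas)
    report = _base_report(config, "replication")
    report.update(
        {
            "groups": res.groups,
            "t": res.t,
            "pvalue": res.pvalue,
            "df": res.df,
            "group_means_pct": res.table.groupby("genotype")["roi_volume_pct"].mean().to_dict(),
        }
    )
    return report


def run_rescue(
    config: RunConfig,
    roi: RoiMask,
    atlas: LabelAtlas | None = None,
    cohort: Cohort | None = None,
) -> dict:
    """Three-group ROI ANOVA (ctl / xrcc / dbl) with post hoc t-tests."""
    from .roistats import three_group_roi_anova

    if atlas is None:
        atlas = make_atlas(config.shape, config.spacing)
    if cohort is None:
        cohort = simulate.make_cohort(config.rescue_design(), atlas)
    res = three_group_roi_anova(cohort, roi, atlas)
    report = _base_report(config, "rescue")
    report.update(
        {
            "F": res.f,
            "df": list(res.df),
            "pvalue": res.pvalue,
            "group_means_pct": res.group_stats["mean"].to_dict(),
            "posthoc": res.posthoc.to_dict(orient="records"),
        }
    )
    return report


def run_combined_map(
    config: RunConfig,
    atlas: LabelAtlas | None = None,
    cohorts: tuple[Cohort, Cohort] | None = None,
) -> tuple[VoxelwiseResults, RoiMask, dict]:
    """Two-batch pooled per-voxel ANOVA (genotype + batch), then ROI filtering."""
    if atlas is None:
        atlas = make_atlas(config.shape, config.spacing)
    if cohorts is None:
        cohorts = (
            simulate.make_cohort(config.discovery_design(), atlas),
            simulate.make_cohort(config.replication_design(), atlas),
        )
    maps = np.concatenate([c.ljd_stack() for c in cohorts])
    genotype = np.concatenate([c.genotypes for c in cohorts])
    batch = np.concatenate([c.batches for c in cohorts])
    results = VoxelwiseModel(
        maps, genotype, batch=batch, brain_mask=atlas.brain_mask()
    ).fit("anova")
    roi = results.significance_mask(
        atlas,
        alpha=config.alpha,
        min_cluster=config.min_cluster,
        symmetric=config.symmetric,
        tol=config.symmetry_tol,
        direction=config.roi_direction,
        reference=config.reference_genotype,
        midline_exclusion=config.symmetry_midline_exclusion,
    )
    report = _base_report(config, "combined_map")
    report.update(
        {
            "df": list(results.df),
            "roi_voxels": roi.n_voxels,
            "min_p": float(results.pvalue.min()),
        }
    )
    return results, roi, report


def run_expression(config: RunConfig) -> dict:
    """Simulated two-experiment DE tables -> filter, FDR, overlap test."""
    table_a, table_b, truth = simulate.make_gene_tables(seed=config.seed + 4)
    fitted = GeneOverlapModel(table_a, table_b).fit(
        min_base_mean=config.min_base_mean, fdr_alpha=config.fdr_alpha
    )
    r = fitted.result
    report = _base_report(config, "expression")
    report.update(
        {
            "n_universe": r.n_universe,
            "n_sig_a": r.n_a,
            "n_sig_b": r.n_b,
            "n_overlap": r.n_overlap,
            "n_same_direction": r.n_same_direction,
            "expected_overlap": r.expected_overlap,
            "fisher_p": r.fisher_p,
            "odds_ratio": r.odds_ratio,
            "n_true_shared": int(truth["shared"].sum()),
        }
    )
    return report


def run_qpcr(config: RunConfig) -> dict:
    """Simulated Cp plate -> 2^dCp quantification and group t-tests."""
    groups = [(g, config.qpcr_n) for g in config.qpcr_folds]
    plate = simulate.make_qpcr(
        groups, config.qpcr_folds, sd=config.qpcr_sd, seed=config.seed + 5
    )
    res = QpcrModel(plate, "tp53").fit(control_group="ctl")
    report = _base_report(config, "qpcr")
    report.update(
        {
            "group_folds_norm": res.group_folds(normalized=True).to_dict(),
            "group_folds_raw": res.group_folds(normalized=False).to_dict(),
            "tests": res.tests.to_dict(orient="records"),
            "true_folds": config.qpcr_folds,
        }
    )
    return report


def run_crispr_qc(config: RunConfig, wt_fractions=(0.3, 0.8), n_larvae: int = 4) -> dict:
    """Simulated traces -> wildtype fractions and inclusion flags."""
    rows = []
    rng = np.random.default_rng(config.seed + 6)
    for larva in range(n_larvae):
        for g, wt in enumerate(wt_fractions):
            trace = simulate.make_trace(
                wt_fraction=wt, seed=int(rng.integers(2**31))
            )
            peaks = detect_peaks(trace)
            frac = wildtype_fraction(peaks, trace.wt_size_bp)
            rows.append({"larva": f"l{larva}", "guide": f"g{g+1}", "wt_fraction": frac, "true_wt": wt})
    import pandas as pd

    flags = classify_efficiency(pd.DataFrame(rows), threshold=config.wt_threshold)
    report = _base_report(config, "crispr_qc")
    report.update(
        {
            "n_larvae": n_larvae,
            "included": int(flags.groupby("larva")["included"].first().sum()),
            "max_abs_error": float((flags["wt_fraction"] - flags["true_wt"]).abs().max()),
        }
    )
    return report


def run_all(config: RunConfig, atlas: LabelAtlas | None = None) -> dict:
    """Run every stage; returns {stage: report} plus the ROI voxel count."""
    if atlas is None:
        atlas = make_atlas(config.shape, config.spacing)
    roi, rep_disc = run_discovery(config, atlas)
    reports = {"discovery": rep_disc}
    if roi.n_voxels:
        reports["replication"] = run_replication(config, roi, atlas)
        reports["rescue"] = run_rescue(config, roi, atlas)
    _, _, rep_comb = run_combined_map(config, atlas)
    reports["combined_map"] = rep_comb
    reports["expression"] = run_expression(config)
    reports["qpcr"] = run_qpcr(config)
    reports["crispr_qc"] = run_crispr_qc(config)
    return reports
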