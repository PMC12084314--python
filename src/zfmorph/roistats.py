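"""Region-of-interest volumetry and group comparisons.

Division and ROI volumes are obtained per subject by integrating exp(LJD)
over the region (change of variables through the registration), expressed
both in um^3 and as percent of that subject's total brain volume.  Group
comparisons follow the study design: a two-group t-test for replicating a
discovered ROI in an independent experiment, and a one-way ANOVA with
pairwise post hoc t-tests for the three-group rescue comparison
(control / crispant / double crispant).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import LabelAtlas
from .fields import region_volume
from .voxelstats import RoiMask

__all__ = [
    "division_stats",
    "roi_volume_table",
    "roi_replication_test",
    "three_group_roi_anova",
    "RoiVolumeAnova",
    "RoiAnovaResults",
    "ReplicationResult",
]


def division_stats(cohort, atlas: LabelAtlas) -> pd.DataFrame:
    """Per-subject, per-division volume and mean channel intensity table.

    One row per (subject, division) with absolute volume (um^3), volume as
    percent of total brain volume, and the mean of each fluorescence channel
    over the division mask.  Channels absent for a subject simply yield no
    column.
    """
    rows = []
    masks = {name: atlas.mask(name) for name in atlas.division_names()}
    brain = atlas.brain_mask()
    for s in cohort:
        ljd = s.ljd()
        expj = np.exp(ljd.values)
        total = float(expj[brain].sum() * ljd.voxel_volume)
        for name, mask in masks.items():
            vol = float(expj[mask].sum() * ljd.voxel_volume)
            row = {
                "subject_id": s.subject_id,
                "genotype": s.genotype,
                "batch": s.batch,
                "division": name,
                "volume_um3": vol,
                "volume_pct": 100.0 * vol / total,
            }
            for ch, img in s.channels.items():
                row[f"mean_{ch}"] = float(img[mask].mean())
            rows.append(row)
    return pd.DataFrame(rows)


def roi_volume_table(cohort, roi: RoiMask | np.ndarray, atlas: LabelAtlas) -> pd.DataFrame:
    """Per-subject ROI volume (um^3 and % of total brain volume)."""
    mask = roi.mask if isinstance(roi, RoiMask) else np.asarray(roi, dtype=bool)
    if not mask.any():
        raise ValueError("ROI is empty")
    brain = atlas.brain_mask()
    rows = []
    for s in cohort:
        vol, pct = region_volume(s.ljd(), mask, brain_mask=brain)
        rows.append(
            {
                "subject_id": s.subject_id,
                "genotype": s.genotype,
                "batch": s.batch,
                "roi_volume_um3": vol,
                "roi_volume_pct": pct,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ReplicationResult:
    """Two-group ROI replication test: per-subject volumes plus a t-test."""

    table: pd.DataFrame
    groups: tuple[str, str]
    t: float
    pvalue: float
    df: int

    def summary(self) -> str:
        means = self.table.groupby("genotype")["roi_volume_pct"].agg(["mean", "std", "count"])
        lines = [
            "ROI replication test (two-sided t-test on ROI volume %)",
            means.to_string(),
            f"  t({self.df}) = {self.t:.3f}, p = {self.pvalue:.4g}",
        ]
        return "\n".join(lines)


def roi_replication_test(
    cohort, roi: RoiMask | np.ndarray, atlas: LabelAtlas, value: str = "roi_volume_pct"
) -> ReplicationResult:
    """Measure a previously discovered ROI in an independent cohort.

    The ROI mask (from the discovery experiment) is measured in every subject
    of ``cohort`` and the two genotype groups are compared with a two-sided
    pooled-variance t-test on ROI volume percent.
    """
    table = roi_volume_table(cohort, roi, atlas)
    levels = np.unique(table["genotype"])
    if len(levels) != 2:
        raise ValueError(f"replication test needs exactly 2 groups, got {list(levels)}")
    a = table.loc[table["genotype"] == levels[0], value].to_numpy()
    b = table.loc[table["genotype"] == levels[1], value].to_numpy()
    if min(len(a), len(b)) < 2:
        raise ValueError("need >= 2 subjects per group")
    res = stats.ttest_ind(a, b)
    return ReplicationResult(
        table=table,
        groups=(str(levels[0]), str(levels[1])),
        t=float(res.statistic),
        pvalue=float(res.pvalue),
        df=len(a) + len(b) - 2,
    )


@dataclass
class RoiAnovaResults:
    """One-way ANOVA on ROI volume with pairwise post hoc t-tests."""

    f: float
    df: tuple[int, int]
    pvalue: float
    posthoc: pd.DataFrame
    group_stats: pd.DataFrame
    table: pd.DataFrame

    def posthoc_p(self, a: str, b: str, adjusted: bool = False) -> float:
        """Post hoc p-value for an unordered group pair."""
        col = "p_holm" if adjusted else "pvalue"
        ph = self.posthoc
        row = ph[((ph.group_a == a) & (ph.group_b == b)) | ((ph.group_a == b) & (ph.group_b == a))]
        if row.empty:
            raise KeyError(f"no post hoc comparison {a} vs {b}")
        return float(row.iloc[0][col])

    def summary(self) -> str:
        lines = [
            "One-way ANOVA on ROI volume (% of total brain volume)",
            self.group_stats.to_string(),
            f"  F({self.df[0]},{self.df[1]}) = {self.f:.3f}, p = {self.pvalue:.4g}",
            "Post hoc pairwise t-tests (unadjusted; Holm column alongside):",
            self.posthoc.to_string(index=False),
        ]
        return "\n".join(lines)


class RoiVolumeAnova:
    """One-way ANOVA model for per-subject ROI volumes across >= 3 groups.

    ``data`` needs one row per subject with a group column and a value column
    (default: ``genotype`` and ``roi_volume_pct``).
    """

    def __init__(self, data: pd.DataFrame, group_col: str = "genotype", value_col: str = "roi_volume_pct"):
        self.data = data
        self.group_col = group_col
        self.value_col = value_col

    def fit(self) -> RoiAnovaResults:
        from statsmodels.stats.multitest import multipletests

        levels = list(pd.unique(self.data[self.group_col]))
        if len(levels) < 3:
            raise ValueError("need >= 3 groups for the rescue ANOVA")
        samples = []
        for lev in levels:
            vals = self.data.loc[self.data[self.group_col] == lev, self.value_col].to_numpy()
            if len(vals) < 2:
                raise ValueError(f"group {lev!r} has < 2 subjects")
            samples.append(vals)
        n_total = sum(len(s) for s in samples)
        k = len(samples)
        f, p = stats.f_oneway(*samples)
        rows = []
        for (ia, a), (ib, b) in combinations(enumerate(levels), 2):
            res = stats.ttest_ind(samples[ia], samples[ib])
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_a": samples[ia].mean(),
                    "mean_b": samples[ib].mean(),
                    "t": float(res.statistic),
                    "pvalue": float(res.pvalue),
                    "df": len(samples[ia]) + len(samples[ib]) - 2,
                }
            )
        posthoc = pd.DataFrame(rows)
        posthoc["p_holm"] = multipletests(posthoc["pvalue"], method="holm")[1]
        group_stats = (
            self.data.groupby(self.group_col)[self.value_col]
            .agg(["mean", "std", "count"])
            .loc[levels]
        )
        return RoiAnovaResults(
            f=float(f),
            df=(k - 1, n_total - k),
            pvalue=float(p),
            posthoc=posthoc,
            group_stats=group_stats,
            table=self.data,
        )


def three_group_roi_anova(
    cohort, roi: RoiMask | np.ndarray, atlas: LabelAtlas
) -> RoiAnovaResults:
    """Rescue-style comparison: ANOVA on ROI volume % across >= 3 groups.

    Error degrees of freedom are ``N - k`` (e.g. 39 for groups of 16/14/12).
    Post hoc pairwise t-tests are reported unadjusted, with a Holm-adjusted
    column alongside.
    """
    table = roi_volume_table(cohort, roi, atlas)
    return RoiVolumeAnova(table).fit()
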