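"""Differential-expression overlap statistics and qPCR relative quantification.

Two crispant experiments (non-overlapping guide sets against the same gene)
each yield a per-gene statistics table from the upstream count model
(gene id, baseMean, log2FoldChange, pvalue).  This module implements the
post-processing: drop genes with baseMean < 100 in either experiment,
Benjamini-Hochberg FDR over the surviving genes, call significance at
FDR < 0.1, and test whether the two experiments' significant sets overlap
more than chance with a one-sided Fisher exact (hypergeometric) test,
reporting how many overlapping genes change in the same direction.

qPCR quantification uses the 2^dCp method against a reference gene:
fold expression = 2^(Cp_reference - Cp_target); a target amplifying one
cycle earlier than the reference means two-fold more transcript.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_genes",
    "bh_fdr",
    "significant_genes",
    "overlap_analysis",
    "OverlapResult",
    "GeneOverlapModel",
    "OverlapResults",
    "qpcr_relative",
    "QpcrModel",
    "QpcrResults",
]


# ----------------------------------------------------------------------
def filter_genes(
    table_a: pd.DataFrame, table_b: pd.DataFrame, min_base_mean: float = 100.0
) -> pd.DataFrame:
    """Join two per-gene tables and keep genes well-expressed in BOTH.

    A gene survives iff ``baseMean >= min_base_mean`` in each experiment
    ("less than 100 in either" is removed; exactly 100 is kept).  Returns the
    inner join with ``_a`` / ``_b`` suffixes.
    """
    joined = table_a.merge(table_b, on="gene_id", suffixes=("_a", "_b"))
    if joined.empty:
        raise ValueError("no shared gene ids between the two tables")
    keep = (joined["baseMean_a"] >= min_base_mean) & (joined["baseMean_b"] >= min_base_mean)
    return joined.loc[keep].reset_index(drop=True)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, set q_(i) = p_(i) * m / i, enforce monotonicity from the
    largest rank down, cap at 1, restore the original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def significant_genes(
    table: pd.DataFrame,
    fdr_alpha: float = 0.1,
    pvalue_col: str = "pvalue",
    lfc_col: str = "log2FoldChange",
) -> pd.DataFrame:
    """Call significance at FDR-adjusted p strictly below ``fdr_alpha``.

    Adds a ``padj`` column if absent and returns the significant rows with a
    ``direction`` column (sign of log2FC; exactly zero fold change gets
    direction ``"none"``).
    """
    df = table.copy()
    if "padj" not in df.columns:
        df["padj"] = bh_fdr(df[pvalue_col].to_numpy())
    sig = df.loc[df["padj"] < fdr_alpha].copy()
    sig["direction"] = np.sign(sig[lfc_col]).map({1.0: "up", -1.0: "down", 0.0: "none"})
    return sig


@dataclass
class OverlapResult:
    """Two-list overlap with a one-sided enrichment Fisher exact test.

    The 2x2 table is built on the post-filter universe from membership in
    the A-significant and B-significant sets:
    ``[[overlap, A-only], [B-only, neither]]``; ``fisher_p`` is the
    one-sided (greater) hypergeometric tail P(overlap >= observed).
    Direction agreement is reported separately and does not enter the test.
    """

    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    n_same_direction: int
    fisher_p: float
    odds_ratio: float
    expected_overlap: float

    def __post_init__(self) -> None:
        ok = (
            self.n_same_direction <= self.n_overlap <= min(self.n_a, self.n_b) <= self.n_universe
        )
        if not ok:
            raise ValueError("inconsistent overlap counts")

    @property
    def contingency(self) -> np.ndarray:
        return np.array(
            [
                [self.n_overlap, self.n_a - self.n_overlap],
                [self.n_b - self.n_overlap, self.n_universe - self.n_a - self.n_b + self.n_overlap],
            ]
        )

    def summary(self) -> str:
        return (
            f"Gene-list overlap: {self.n_overlap} shared of {self.n_a} (A) and "
            f"{self.n_b} (B) over a universe of {self.n_universe} "
            f"({self.n_same_direction} same direction; expected "
            f"{self.expected_overlap:.2f} by chance)\n"
            f"  one-sided Fisher exact p = {self.fisher_p:.3g}, "
            f"odds ratio = {self.odds_ratio:.3g}"
        )


def overlap_analysis(
    set_a,
    set_b,
    universe_size: int,
    directions_a: dict | None = None,
    directions_b: dict | None = None,
) -> OverlapResult:
    """Test whether two gene sets drawn from a common universe converge.

    ``fisher_p`` is the exact one-sided enrichment tail
    ``P(|A & B| >= observed)`` under random draws of B (hypergeometric);
    this equals Fisher's exact test with alternative="greater" on the 2x2
    membership table.
    """
    a, b = set(set_a), set(set_b)
    if len(a | b) > universe_size:
        raise ValueError("universe smaller than the union of the two sets")
    overlap = a & b
    k, na, nb = len(overlap), len(a), len(b)
    same = 0
    if directions_a is not None and directions_b is not None:
        same = sum(
            1
            for g in overlap
            if directions_a.get(g) == directions_b.get(g) and directions_a.get(g) != "none"
        )
    # P(X >= k), X ~ Hypergeom(universe, na, nb)
    fisher_p = float(stats.hypergeom.sf(k - 1, universe_size, na, nb))
    table = [[k, na - k], [nb - k, universe_size - na - nb + k]]
    odds = stats.contingency.odds_ratio(table, kind="sample").statistic if k else 0.0
    return OverlapResult(
        n_universe=universe_size,
        n_a=na,
        n_b=nb,
        n_overlap=k,
        n_same_direction=same,
        fisher_p=fisher_p,
        odds_ratio=float(odds) if np.isfinite(odds) else float("inf"),
        expected_overlap=na * nb / universe_size if universe_size else 0.0,
    )


@dataclass
class OverlapResults:
    """Fitted two-experiment convergence analysis."""

    result: OverlapResult
    filtered: pd.DataFrame
    sig_a: pd.DataFrame
    sig_b: pd.DataFrame
    params: dict

    def summary(self) -> str:
        return (
            f"Two-experiment DE convergence (baseMean >= "
            f"{self.params['min_base_mean']:g} in both, BH FDR < "
            f"{self.params['fdr_alpha']:g})\n" + self.result.summary()
        )


class GeneOverlapModel:
    """Convergence model for two differential-expression experiments.

    Built from the two raw per-gene tables; ``fit`` applies the expression
    filter, BH FDR within each experiment over the filtered universe, calls
    significant sets, and runs the one-sided overlap test.
    """

    def __init__(self, table_a: pd.DataFrame, table_b: pd.DataFrame):
        self.table_a = table_a
        self.table_b = table_b

    def fit(self, min_base_mean: float = 100.0, fdr_alpha: float = 0.1) -> OverlapResults:
        joined = filter_genes(self.table_a, self.table_b, min_base_mean)
        frames = {}
        for side in ("a", "b"):
            sub = joined[["gene_id", f"baseMean_{side}", f"log2FoldChange_{side}", f"pvalue_{side}"]]
            sub = sub.rename(
                columns={
                    f"baseMean_{side}": "baseMean",
                    f"log2FoldChange_{side}": "log2FoldChange",
                    f"pvalue_{side}": "pvalue",
                }
            )
            frames[side] = significant_genes(sub, fdr_alpha=fdr_alpha)
        dir_a = dict(zip(frames["a"]["gene_id"], frames["a"]["direction"]))
        dir_b = dict(zip(frames["b"]["gene_id"], frames["b"]["direction"]))
        result = overlap_analysis(
            frames["a"]["gene_id"],
            frames["b"]["gene_id"],
            universe_size=len(joined),
            directions_a=dir_a,
            directions_b=dir_b,
        )
        return OverlapResults(
            result=result,
            filtered=joined,
            sig_a=frames["a"],
            sig_b=frames["b"],
            params={"min_base_mean": min_base_mean, "fdr_alpha": fdr_alpha},
        )


# ----------------------------------------------------------------------
@dataclass
class QpcrResults:
    """Per-sample relative expression and between-group t-tests."""

    per_sample: pd.DataFrame
    tests: pd.DataFrame
    target: str
    reference: str
    n_dropped: int

    def group_folds(self, normalized: bool = True) -> pd.Series:
        col = "rel_expr_norm" if normalized else "rel_expr"
        return self.per_sample.groupby("group")[col].mean()

    def summary(self) -> str:
        lines = [
            f"qPCR relative expression of {self.target} vs {self.reference} (2^dCp)",
            self.per_sample.groupby("group")[["rel_expr", "rel_expr_norm"]]
            .mean()
            .to_string(),
            "Between-group two-sided t-tests on relative expression:",
            self.tests.to_string(index=False),
        ]
        if self.n_dropped:
            lines.append(f"  samples dropped for missing reference Cp: {self.n_dropped}")
        return "\n".join(lines)


def qpcr_relative(
    plate: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_group: str | None = None,
    pairs: list[tuple[str, str]] | None = None,
) -> QpcrResults:
    """2^dCp relative quantification with between-group t-tests.

    ``dCp = Cp_reference - Cp_target`` per sample; relative expression is
    ``2^dCp`` (one cycle earlier = two-fold more transcript).
    ``rel_expr_norm`` additionally divides by the control-group mean (the
    first group encountered if ``control_group`` is None).  Samples missing
    the reference gene are dropped and counted.
    """
    required = {"sample", "group", "gene", "Cp"}
    if not required.issubset(plate.columns):
        raise ValueError(f"plate needs columns {sorted(required)}")
    wide = plate.pivot_table(index=["sample", "group"], columns="gene", values="Cp", aggfunc="mean")
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} not on the plate")
    n_before = len(wide)
    wide = wide.dropna(subset=[reference_gene, target_gene])
    n_dropped = n_before - len(wide)
    out = wide.reset_index()[["sample", "group"]].copy()
    dcp = wide[reference_gene].to_numpy() - wide[target_gene].to_numpy()
    out["delta_cp"] = dcp
    out["rel_expr"] = 2.0**dcp

    groups = list(pd.unique(out["group"]))
    if control_group is None:
        control_group = groups[0]
    ctrl_mean = out.loc[out["group"] == control_group, "rel_expr"].mean()
    out["rel_expr_norm"] = out["rel_expr"] / ctrl_mean

    if pairs is None:
        pairs = list(combinations(groups, 2))
    rows = []
    for a, b in pairs:
        va = out.loc[out["group"] == a, "rel_expr"].to_numpy()
        vb = out.loc[out["group"] == b, "rel_expr"].to_numpy()
        res = stats.ttest_ind(va, vb)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_a": va.mean(),
                "mean_b": vb.mean(),
                "t": float(res.statistic),
                "pvalue": float(res.pvalue),
                "df": len(va) + len(vb) - 2,
            }
        )
    return QpcrResults(
        per_sample=out,
        tests=pd.DataFrame(rows),
        target=target_gene,
        reference=reference_gene,
        n_dropped=n_dropped,
    )


class QpcrModel:
    """2^dCp quantification model over a long-format Cp plate."""

    def __init__(self, plate: pd.DataFrame, target_gene: str, reference_gene: str = "eef1a1l1"):
        self.plate = plate
        self.target_gene = target_gene
        self.reference_gene = reference_gene

    def fit(self, control_group: str | None = None, pairs=None) -> QpcrResults:
        return qpcr_relative(
            self.plate, self.target_gene, self.reference_gene, control_group, pairs
        )
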