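from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfmorph.expression import (
    GeneOverlapModel,
    bh_fdr,
    filter_genes,
    overlap_analysis,
    qpcr_relative,
    significant_genes,
)
from zfmorph.simulate import make_gene_tables, make_qpcr


def _table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "baseMean", "log2FoldChange", "pvalue"])


# ----------------------------------------------------------------- filtering
def test_filter_drops_gene_low_in_either_experiment():
    a = _table([("g1", 99.0, 1.0, 0.01), ("g2", 100.0, 1.0, 0.01), ("g3", 500.0, 1.0, 0.5)])
    b = _table([("g1", 500.0, 1.0, 0.01), ("g2", 100.0, -1.0, 0.2), ("g3", 150.0, 1.0, 0.5)])
    out = filter_genes(a, b)
    assert set(out["gene_id"]) == {"g2", "g3"}  # 99 removed; exactly 100 kept


def test_filter_matches_bruteforce_oracle():
    rng = np.random.default_rng(5)
    ids = [f"g{i}" for i in range(300)]
    a = _table([(g, rng.lognormal(4.5, 1.0), 0.0, 0.5) for g in ids])
    b = _table([(g, rng.lognormal(4.5, 1.0), 0.0, 0.5) for g in ids])
    out = filter_genes(a, b, 100.0)
    expected = {
        g
        for g in ids
        if a.set_index("gene_id").loc[g, "baseMean"] >= 100
        and b.set_index("gene_id").loc[g, "baseMean"] >= 100
    }
    assert set(out["gene_id"]) == expected


def test_filter_empty_intersection_raises():
    a = _table([("g1", 200.0, 1.0, 0.1)])
    b = _table([("h1", 200.0, 1.0, 0.1)])
    with pytest.raises(ValueError, match="no shared gene ids"):
        filter_genes(a, b)


# ----------------------------------------------------------------------- BH
def test_bh_hand_computed_example():
    assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])


def test_bh_single_p_unchanged():
    assert bh_fdr([0.037])[0] == pytest.approx(0.037)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(11)
    p = rng.uniform(size=200)
    assert np.allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_properties(pvals):
    adj = bh_fdr(pvals)
    assert np.all(adj >= np.asarray(pvals) - 1e-12)  # adjusted >= raw
    assert np.all((adj >= 0) & (adj <= 1))
    # order-equivariant: permuting inputs permutes outputs
    perm = np.argsort(np.asarray(pvals), kind="stable")[::-1]
    assert np.allclose(bh_fdr(np.asarray(pvals)[perm]), adj[perm])


def test_significant_genes_strict_threshold():
    table = _table(
        [("g1", 200, 1.0, 0.001), ("g2", 200, -2.0, 0.002), ("g3", 200, 0.5, 0.9)]
    )
    table["padj"] = [0.05, 0.1, 0.9]  # g2 exactly at alpha -> excluded
    sig = significant_genes(table, fdr_alpha=0.1)
    assert list(sig["gene_id"]) == ["g1"]
    assert list(sig["direction"]) == ["up"]


# -------------------------------------------------------------------- Fisher
from functools import lru_cache


@lru_cache(maxsize=None)
def _overlap_distribution(m, n_a, n_b):
    a = set(range(n_a))
    counts: dict[int, int] = {}
    for b in combinations(range(m), n_b):
        k = len(a & set(b))
        counts[k] = counts.get(k, 0) + 1
    return tuple(sorted(counts.items()))


def enumerate_overlap_tail(m, n_a, n_b, k):
    """Exhaustive oracle: P(|A & B| >= k) over all C(m, n_b) choices of B."""
    hits = sum(c for kk, c in _overlap_distribution(m, n_a, n_b) if kk >= k)
    return hits / comb(m, n_b)


def test_fisher_equals_exhaustive_enumeration_small_universes():
    for m in (5, 8, 10, 12):
        for n_a in range(m + 1):
            for n_b in range(m + 1):
                max_k = min(n_a, n_b)
                for k in range(max(0, n_a + n_b - m), max_k + 1):
                    res = overlap_analysis(
                        set(range(n_a)),
                        set(range(n_a - k, n_a - k + n_b)) if k else set(range(n_a, n_a + n_b)),
                        m,
                    )
                    assert res.n_overlap == k
                    assert res.fisher_p == pytest.approx(
                        enumerate_overlap_tail(m, n_a, n_b, k), abs=1e-12
                    )


def test_fisher_worked_example_universe_10():
    # universe 10, |A| = 4, |B| = 5, overlap 4 -> 6/252
    res = overlap_analysis({0, 1, 2, 3}, {0, 1, 2, 3, 4}, 10)
    assert res.fisher_p == pytest.approx(6 / 252)


def test_overlap_empty_sets():
    res = overlap_analysis(set(), set(), 100)
    assert res.n_overlap == 0 and res.fisher_p == 1.0


def test_overlap_counts_match_bruteforce_random_sets(rng):
    for _ in range(20):
        m = int(rng.integers(20, 200))
        a = set(rng.choice(m, rng.integers(0, m // 2), replace=False).tolist())
        b = set(rng.choice(m, rng.integers(0, m // 2), replace=False).tolist())
        res = overlap_analysis(a, b, m)
        assert res.n_overlap == len(a & b)
        assert res.n_a == len(a) and res.n_b == len(b)
        assert res.n_same_direction <= res.n_overlap <= min(res.n_a, res.n_b) <= m


def test_overlap_universe_too_small_raises():
    with pytest.raises(ValueError, match="universe"):
        overlap_analysis({1, 2}, {3, 4}, 3)


def test_direction_agreement_counted():
    res = overlap_analysis(
        {"a", "b", "c"},
        {"a", "b", "d"},
        50,
        directions_a={"a": "up", "b": "down", "c": "up"},
        directions_b={"a": "up", "b": "up", "d": "down"},
    )
    assert res.n_overlap == 2 and res.n_same_direction == 1


# ----------------------------------------------------- end-to-end convergence
def test_planted_shared_genes_recovered_and_fisher_monotone():
    """More planted shared true genes -> larger same-direction overlap and
    (median over seeds) smaller Fisher p."""
    med_p, med_overlap = [], []
    for n_shared in (0, 10, 30):
        ps, ovs = [], []
        for seed in range(3):
            a, b, _ = make_gene_tables(
                n_genes=4000,
                n_true_shared=n_shared,
                n_true_private_per_expt=(40, 120),
                seed=seed,
            )
            fitted = GeneOverlapModel(a, b).fit()
            ps.append(fitted.result.fisher_p)
            ovs.append(fitted.result.n_same_direction)
        med_p.append(np.median(ps))
        med_overlap.append(np.median(ovs))
    assert med_overlap[0] < med_overlap[1] < med_overlap[2]
    assert med_p[0] > med_p[1] > med_p[2]


def test_null_overlap_close_to_hypergeometric_expectation():
    """With no shared true genes the observed overlap of significant sets
    matches the chance expectation n_A * n_B / universe over seeds."""
    tot_obs, tot_exp = 0.0, 0.0
    for seed in range(12):
        a, b, _ = make_gene_tables(
            n_genes=4000, n_true_shared=0, n_true_private_per_expt=(60, 200), seed=seed
        )
        r = GeneOverlapModel(a, b).fit().result
        tot_obs += r.n_overlap
        tot_exp += r.expected_overlap
    assert abs(tot_obs - tot_exp) < 4 * np.sqrt(tot_exp) + 2


# --------------------------------------------------------------------- qPCR
def test_qpcr_closed_forms():
    plate = pd.DataFrame(
        {
            "sample": ["s1", "s1", "s2", "s2"],
            "group": ["ctl", "ctl", "mut", "mut"],
            "gene": ["eef1a1l1", "tp53", "eef1a1l1", "tp53"],
            "Cp": [18.0, 18.0, 18.0, 17.0],
        }
    )
    res = qpcr_relative(plate, "tp53", "eef1a1l1")
    by = res.per_sample.set_index("sample")
    assert by.loc["s1", "rel_expr"] == pytest.approx(1.0)  # Cp_t = Cp_ref
    assert by.loc["s2", "rel_expr"] == pytest.approx(2.0)  # one cycle earlier


def test_qpcr_missing_reference_drops_sample():
    plate = pd.DataFrame(
        {
            "sample": ["s1", "s1", "s2"],
            "group": ["ctl", "ctl", "ctl"],
            "gene": ["eef1a1l1", "tp53", "tp53"],
            "Cp": [18.0, 18.0, 17.0],
        }
    )
    res = qpcr_relative(plate, "tp53", "eef1a1l1")
    assert res.n_dropped == 1 and len(res.per_sample) == 1


def test_qpcr_group_fold_recovery():
    plate = make_qpcr(
        [("ctl", 5), ("xrcc", 5)], {"ctl": 1.0, "xrcc": 1.5}, sd=0.2, seed=13
    )
    res = qpcr_relative(plate, "tp53", "eef1a1l1", control_group="ctl")
    folds = res.group_folds(normalized=True)
    se = 0.2 * np.sqrt(2.0 / 5) * 2  # two groups on log2 scale
    assert abs(np.log2(folds["xrcc"]) - np.log2(1.5)) < 3 * se
    assert len(res.tests) == 1 and res.tests.iloc[0]["df"] == 8
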