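"""Differential-methylation tests: coverage filter, logistic LRT with grid
oracle, BH, delta, regions (union-find oracle), annotation, ranking, gene
classes, and power."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from methylrescue.core import MethylationMatrix
from methylrescue.dmr import (
    Contrast,
    annotate_site,
    bh_adjust,
    classify_gene_direction,
    compute_delta,
    contrast_from_cells,
    filter_coverage,
    fit_logistic_table,
    fit_per_cpg_logistic,
    group_regions,
    planned_contrasts,
    power_simulation,
    rank_and_filter,
    run_contrast,
)
from methylrescue.simulate import GeneModel

from _helpers import grid_search_logistic, bh_by_formula


def _matrix(meth_rows, unmeth_rows, units):
    idx = pd.MultiIndex.from_tuples(
        [("c", 10 * i) for i in range(len(meth_rows))], names=["contig", "pos"]
    )
    meth = pd.DataFrame(meth_rows, index=idx, columns=units, dtype=float)
    unmeth = pd.DataFrame(unmeth_rows, index=idx, columns=units, dtype=float)
    return MethylationMatrix(meth, unmeth)


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def test_contrast_validation():
    with pytest.raises(ValueError):
        Contrast("x", ("a", "b"), ("b", "c"))  # overlap
    with pytest.raises(ValueError):
        Contrast("x", ("a",), ("b", "c"))  # too few


def test_planned_contrasts_from_design(units):
    cs = planned_contrasts(units)
    assert [c.name for c in cs] == [
        "n-6-SAL vs n-6-POL", "n-3-POL vs n-6-POL", "n-3-SAL vs n-6-SAL"
    ]
    for c in cs:
        assert len(c.group_a) == 6 and len(c.group_b) == 6
    mia = cs[0]
    assert all(u.startswith("SAL-n6") for u in mia.group_a)
    assert all(u.startswith("POL-n6") for u in mia.group_b)


def test_contrast_flip_swaps_groups():
    c = Contrast("x", ("a", "b"), ("c", "d"))
    f = c.flipped()
    assert f.group_a == ("c", "d") and f.group_b == ("a", "b")


# ---------------------------------------------------------------------------
# coverage filter
# ---------------------------------------------------------------------------

def test_filter_excludes_depth_9():
    m = _matrix([[5, 10, 10, 10], [10, 10, 10, 10]],
                [[4, 5, 5, 5], [5, 5, 5, 5]],
                ["a1", "a2", "b1", "b2"])
    c = Contrast("x", ("a1", "a2"), ("b1", "b2"))
    kept = filter_coverage(m, c, min_depth=10)
    assert list(kept) == [("c", 10)]  # first site has one unit at depth 9


def test_filter_min_depth_zero_keeps_all_covered():
    m = _matrix([[1, 1, 1, 1]], [[0, 0, 0, 0]], ["a1", "a2", "b1", "b2"])
    c = Contrast("x", ("a1", "a2"), ("b1", "b2"))
    assert len(filter_coverage(m, c, min_depth=0)) == 1


def test_filter_matches_brute_force_500_sites():
    rng = np.random.default_rng(0)
    units = ["a1", "a2", "a3", "b1", "b2", "b3"]
    meth = rng.integers(0, 20, (500, 6))
    unmeth = rng.integers(0, 20, (500, 6))
    m = _matrix(meth.tolist(), unmeth.tolist(), units)
    c = Contrast("x", ("a1", "a2", "a3"), ("b1", "b2", "b3"))
    kept = set(filter_coverage(m, c, min_depth=10))
    depth = meth + unmeth
    expect = {("c", 10 * i) for i in range(500) if (depth[i] >= 10).all()}
    assert kept == expect


# ---------------------------------------------------------------------------
# logistic LRT
# ---------------------------------------------------------------------------

def test_logistic_null_fixed_point():
    fit = fit_per_cpg_logistic([5, 5], [10, 10], [5, 5], [10, 10])
    assert fit.beta1 == pytest.approx(0.0, abs=1e-12)
    assert fit.p_value == pytest.approx(1.0)


def test_logistic_complete_separation_stabilised():
    fit = fit_per_cpg_logistic([0, 0], [10, 10], [10, 10], [10, 10])
    assert fit.corrected
    assert fit.beta1 > 0
    assert fit.p_value < 1e-6


def test_logistic_matches_grid_search_oracle():
    # 2-unit-per-group toy: A 3/10 + 4/10, B 8/10 + 7/10
    fit = fit_per_cpg_logistic([3, 4], [10, 10], [8, 7], [10, 10])
    b0, b1, _ = grid_search_logistic(7, 20, 15, 20)
    assert fit.beta1 == pytest.approx(b1, abs=1e-4)
    assert fit.beta0 == pytest.approx(b0, abs=1e-4)


def test_logistic_random_instances_match_grid_oracle():
    rng = np.random.default_rng(1)
    for _ in range(10):
        na, nb = int(rng.integers(10, 60)), int(rng.integers(10, 60))
        ma, mb = int(rng.integers(1, na)), int(rng.integers(1, nb))
        fit = fit_per_cpg_logistic([ma], [na], [mb], [nb])
        b0, b1, _ = grid_search_logistic(ma, na, mb, nb)
        assert fit.beta1 == pytest.approx(b1, abs=1e-4)


def test_logistic_sign_flip_antisymmetry():
    fwd = fit_per_cpg_logistic([3], [10], [8], [10])
    rev = fit_per_cpg_logistic([8], [10], [3], [10])
    assert fwd.beta1 == pytest.approx(-rev.beta1, abs=1e-12)
    assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)


def test_logistic_zero_depth_raises():
    with pytest.raises(ValueError):
        fit_logistic_table([0], [0], [5], [10])


def test_logistic_vectorised_equals_scalar():
    rng = np.random.default_rng(2)
    na = rng.integers(10, 50, 50)
    nb = rng.integers(10, 50, 50)
    ma = rng.binomial(na, 0.4)
    mb = rng.binomial(nb, 0.6)
    table = fit_logistic_table(ma, na, mb, nb)
    for i in range(0, 50, 7):
        fit = fit_per_cpg_logistic([ma[i]], [na[i]], [mb[i]], [nb[i]])
        assert table["p_value"].iloc[i] == pytest.approx(fit.p_value, rel=1e-12)


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

def test_bh_single_p():
    assert bh_adjust([0.03]) == pytest.approx([0.03])


def test_bh_worked_example():
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_all_equal():
    assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)


def test_bh_matches_formula_and_statsmodels():
    rng = np.random.default_rng(3)
    p = rng.uniform(0, 1, 200) ** 2
    q = bh_adjust(p)
    assert q == pytest.approx(bh_by_formula(p), rel=1e-12)
    assert q == pytest.approx(multipletests(p, method="fdr_bh")[1], rel=1e-12)


def test_bh_invalid_p_raises():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])
    with pytest.raises(ValueError):
        bh_adjust([np.nan])


# ---------------------------------------------------------------------------
# delta
# ---------------------------------------------------------------------------

def test_delta_identical_groups_zero():
    m = _matrix([[5, 5, 5, 5]], [[5, 5, 5, 5]], ["a1", "a2", "b1", "b2"])
    c = Contrast("x", ("a1", "a2"), ("b1", "b2"))
    assert compute_delta(m, c).iloc[0] == 0.0


def test_delta_worked_example():
    m = _matrix([[60, 62, 40, 42]], [[40, 38, 60, 58]],
                ["a1", "a2", "b1", "b2"])
    c = Contrast("x", ("a1", "a2"), ("b1", "b2"))
    assert compute_delta(m, c).iloc[0] == pytest.approx(-20.0)


def test_delta_matches_brute_force_100_sites():
    rng = np.random.default_rng(4)
    units = ["a1", "a2", "a3", "b1", "b2", "b3"]
    meth = rng.integers(0, 30, (100, 6))
    unmeth = rng.integers(1, 30, (100, 6))
    m = _matrix(meth.tolist(), unmeth.tolist(), units)
    c = Contrast("x", ("a1", "a2", "a3"), ("b1", "b2", "b3"))
    delta = compute_delta(m, c).to_numpy()
    pct = 100.0 * meth / (meth + unmeth)
    expect = pct[:, 3:].mean(axis=1) - pct[:, :3].mean(axis=1)
    assert delta == pytest.approx(expect)


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

def test_regions_worked_example():
    r = group_regions([("c", 100), ("c", 300), ("c", 900)], gap=250)
    assert r[("c", 100)] == r[("c", 300)] == "c:100-300"
    assert r[("c", 900)] == "c:900-900"


def test_regions_singleton():
    r = group_regions([("c", 5)])
    assert r[("c", 5)] == "c:5-5"


def test_regions_contig_boundary_not_chained():
    r = group_regions([("c1", 100), ("c2", 150)], gap=250)
    assert r[("c1", 100)] != r[("c2", 150)]


def test_regions_match_union_find_oracle():
    rng = np.random.default_rng(5)
    sites = [("c", int(p)) for p in np.unique(rng.integers(0, 50_000, 1000))]
    got = group_regions(sites, gap=250)

    parent = {s: s for s in sites}

    def find(s):
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    for a in sites:
        for b in sites:
            if a[0] == b[0] and abs(a[1] - b[1]) <= 250:
                parent[find(a)] = find(b)
    oracle_groups = {}
    for s in sites:
        oracle_groups.setdefault(find(s), set()).add(s)
    got_groups = {}
    for s, rid in got.items():
        got_groups.setdefault(rid, set()).add(s)
    assert set(map(frozenset, oracle_groups.values())) == set(
        map(frozenset, got_groups.values())
    )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_GENES = [
    GeneModel("c", 1000, 3000, "+", "gA", ((1000, 1400), (2000, 3000))),
    GeneModel("c", 6000, 8000, "-", "gB", ((6000, 7000), (7500, 8000))),
]
_ISLANDS = [("c", 500, 900)]


def test_annotate_exon_plus_strand():
    ann = annotate_site(("c", 1050), _GENES, _ISLANDS)
    assert ann["nearest_gene"] == "gA"
    assert ann["signed_tss_distance"] == 50
    # within 500 bp downstream of the TSS -> promoter takes precedence
    assert ann["feature_class"] == "promoter"


def test_annotate_exon_beyond_promoter_window():
    ann = annotate_site(("c", 2500), _GENES, _ISLANDS)
    assert ann["feature_class"] == "exon"
    assert ann["signed_tss_distance"] == 1500


def test_annotate_intron():
    ann = annotate_site(("c", 1700), _GENES, _ISLANDS)
    assert ann["feature_class"] == "intron"


def test_annotate_minus_strand_tss():
    # gB TSS is at 7999; position 7800 is 199 bp downstream in gene
    # orientation -> promoter
    ann = annotate_site(("c", 7800), _GENES, _ISLANDS)
    assert ann["nearest_gene"] == "gB"
    assert ann["signed_tss_distance"] == 199
    assert ann["feature_class"] == "promoter"


def test_annotate_island_classes():
    assert annotate_site(("c", 2400), _GENES, _ISLANDS)["island_class"] == "shore"
    assert annotate_site(("c", 600), _GENES, _ISLANDS)["island_class"] == "island"
    assert annotate_site(("c", 4000), _GENES, _ISLANDS)["island_class"] == "open_sea"


def test_annotate_nearest_gene_matches_exhaustive_minimiser():
    rng = np.random.default_rng(6)
    genes = []
    for i in range(50):
        s = int(rng.integers(0, 200_000))
        e = s + int(rng.integers(500, 3000))
        genes.append(GeneModel("c", s, e, "+", f"g{i:02d}", ((s, e),)))
    for _ in range(100):
        pos = int(rng.integers(0, 205_000))
        ann = annotate_site(("c", pos), genes, [])

        def dist(g):
            if g.start <= pos < g.end:
                return 0
            return g.start - pos if pos < g.start else pos - (g.end - 1)

        best = min(dist(g) for g in genes)
        # implementation breaks distance ties by gene name
        candidates = sorted(g.name for g in genes if dist(g) == best)
        assert ann["nearest_gene"] == candidates[0]


# ---------------------------------------------------------------------------
# ranking and gene classes
# ---------------------------------------------------------------------------

def _records(rows):
    idx = pd.MultiIndex.from_tuples(
        [("c", 10 * i) for i in range(len(rows))], names=["contig", "pos"]
    )
    return pd.DataFrame(rows, index=idx)


def test_rank_boundary_q_excluded():
    rec = _records([
        {"q_value": 0.01, "delta_pct": -30.0, "nearest_gene": "g1"},
        {"q_value": 0.005, "delta_pct": 5.0, "nearest_gene": "g2"},
    ])
    kept, _ = rank_and_filter(rec, q_cut=0.01)
    assert len(kept) == 1
    assert kept["nearest_gene"].iloc[0] == "g2"


def test_rank_by_abs_delta():
    rec = _records([
        {"q_value": 1e-4, "delta_pct": -30.0, "nearest_gene": "g1"},
        {"q_value": 1e-4, "delta_pct": 12.0, "nearest_gene": "g2"},
        {"q_value": 1e-4, "delta_pct": -4.0, "nearest_gene": "g3"},
    ])
    kept, _ = rank_and_filter(rec)
    assert list(kept["delta_pct"]) == [-30.0, 12.0, -4.0]


def test_pathway_list_matches_hand_filter():
    rng = np.random.default_rng(7)
    rows = [
        {"q_value": float(rng.uniform(0, 0.02)),
         "delta_pct": float(rng.uniform(-10, 10)),
         "nearest_gene": f"g{i % 8}"}
        for i in range(20)
    ]
    rec = _records(rows)
    _, genes = rank_and_filter(rec, q_cut=0.01, delta_cut_pathway=3.0)
    expect = sorted({
        r["nearest_gene"] for r in rows
        if r["q_value"] < 0.01 and abs(r["delta_pct"]) > 3.0
    })
    assert genes == expect


def test_gene_direction_classes():
    rec = _records([
        {"delta_pct": -10.0, "nearest_gene": "g1"},
        {"delta_pct": -5.0, "nearest_gene": "g1"},
        {"delta_pct": -10.0, "nearest_gene": "g2"},
        {"delta_pct": 5.0, "nearest_gene": "g2"},
        {"delta_pct": 4.0, "nearest_gene": "g3"},
    ])
    classes, counts = classify_gene_direction(rec)
    assert classes["g1"] == "hypo"
    assert classes["g2"] == "both"
    assert classes["g3"] == "hyper"
    assert counts == {"hypo": 1, "hyper": 1, "both": 1}


def test_gene_class_counts_sum_to_total():
    # the three class counts always partition the gene set (as in the
    # printed 164 + 33 + 7 = 204 arithmetic)
    rng = np.random.default_rng(8)
    rec = _records([
        {"delta_pct": float(rng.normal()), "nearest_gene": f"g{i % 11}"}
        for i in range(60)
    ])
    classes, counts = classify_gene_direction(rec)
    assert counts["hypo"] + counts["hyper"] + counts["both"] == len(classes) == 11


# ---------------------------------------------------------------------------
# run_contrast integration on count-level data
# ---------------------------------------------------------------------------

def test_run_contrast_recovers_planted_direction(units):
    from methylrescue.simulate import simulate_count_study
    meth, unmeth, dmr_sites, _, _ = simulate_count_study(
        800, depth=30, seed=99, baseline=75, mia_shift=-5,
        n_dmr=60, dmr_delta=-20, rescue_fraction=0.0, units=units,
    )
    idx = pd.MultiIndex.from_tuples(
        [("c", int(i)) for i in meth.index], names=["contig", "pos"]
    )
    m = MethylationMatrix(meth.set_axis(idx), unmeth.set_axis(idx))
    contrast = contrast_from_cells(
        "n-6-SAL vs n-6-POL", units,
        {"group": "SAL", "diet": "n6"}, {"group": "POL", "diet": "n6"},
    )
    res = run_contrast(m, contrast, min_depth=10, q_cut=0.01)
    sig = res.significant
    planted = {("c", i) for i in dmr_sites}
    hits = set(map(tuple, sig.index)) & planted
    assert len(hits) >= 0.8 * len(planted)
    assert (sig["delta_pct"] < 0).mean() > 0.9
    assert (res.table["q_value"] >= res.table["p_value"] - 1e-12).all()


# ---------------------------------------------------------------------------
# power simulation
# ---------------------------------------------------------------------------

def test_power_null_matches_level():
    out = power_simulation(6, 30, 50.0, 0.0, alpha=0.05, n_reps=2000, seed=1)
    se = np.sqrt(0.05 * 0.95 / 2000)
    assert abs(out["power"] - 0.05) < 2.576 * se + 0.01


def test_power_monotone_in_n():
    p10 = power_simulation(10, 20, 50.0, 8.0, n_reps=1000, seed=2)["power"]
    p20 = power_simulation(20, 20, 50.0, 8.0, n_reps=1000, seed=2)["power"]
    assert p20 >= p10


def test_power_extreme_effect():
    out = power_simulation(10, 50, 25.0, 50.0, n_reps=500, seed=3)
    assert out["power"] > 0.99


def test_power_validation():
    with pytest.raises(ValueError):
        power_simulation(6, 30, 90.0, 20.0)  # pushes past 100
    with pytest.raises(ValueError):
        power_simulation(6, 30, 50.0, 5.0, n_reps=10)
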