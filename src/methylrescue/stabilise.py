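"""Dietary-stabilisation statistics: pair delta-methylation across the MIA
contrast (n-6-SAL vs n-6-POL) and the diet contrast (n-3-POL vs n-6-POL),
classify genes as stabilised / MIA-only / diet-only, compute the rescue
fraction, and run the two-sample Kolmogorov-Smirnov and paired Wilcoxon
signed-rank tests on the paired gene-level deltas.

Both contrasts measure n-6-POL minus its comparator, so a site whose MIA
change is reversed by the n-3 diet has sign-concordant deltas in the two
columns. The default stabilisation rule for a site is: sign concordance AND
nominal diet p < 0.05 AND |delta_diet| >= ratio * |delta_mia|; a gene is
stabilised when at least half of its MIA-significant sites are. A strict
q < 0.01 variant is available via ``p_column='q_value'`` and
``p_threshold=0.01``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)


def pair_contrasts(
    mia_significant: pd.DataFrame, diet_full: pd.DataFrame
) -> pd.DataFrame:
    """Join every MIA-significant site with its diet-contrast delta and p
    (whether or not diet-significant). Sites missing from the diet results
    (coverage loss) are logged and excluded.

    Inputs are contrast tables indexed by (contig, pos) with columns
    delta_pct, p_value, q_value and (for the MIA table) nearest_gene.
    """
    common = mia_significant.index.intersection(diet_full.index)
    lost = len(mia_significant) - len(common)
    if lost:
        logger.warning("pair_contrasts: %d MIA sites missing from diet results", lost)
    mia = mia_significant.loc[common]
    diet = diet_full.loc[common]
    out = pd.DataFrame(index=common)
    out["gene"] = mia["nearest_gene"] if "nearest_gene" in mia else None
    out["delta_mia"] = mia["delta_pct"]
    out["delta_diet"] = diet["delta_pct"]
    out["p_diet"] = diet["p_value"]
    out["q_diet"] = diet["q_value"]
    return out


@dataclass
class StabilisationReport:
    gene_classes: pd.Series  # gene -> {stabilised, mia_only, diet_only}
    n_stabilised: int
    n_mia_genes: int
    n_diet_only: int
    rescue_fraction: float | None  # percent
    ks_D: float | None
    ks_p: float | None
    wilcoxon_V: float | None
    wilcoxon_p: float | None
    site_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    gene_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def rescue_fraction_from_counts(n_stabilised: int, n_mia_genes: int) -> float:
    """Percent of MIA-altered genes rescued by the diet."""
    if n_mia_genes < 1:
        raise ValueError("no MIA genes")
    return 100.0 * n_stabilised / n_mia_genes


def classify_stabilisation(
    pairs: pd.DataFrame,
    p_threshold: float = 0.05,
    magnitude_ratio: float = 0.5,
    p_column: str = "p_diet",
    diet_only_genes=(),
) -> StabilisationReport:
    """Site- then gene-level stabilisation classes and the rescue fraction.

    ``diet_only_genes``: genes significant in the diet contrast but absent
    from the MIA gene set (reported in the diet_only class).
    """
    if pairs.empty:
        logger.warning("classify_stabilisation: empty pair table")
        return StabilisationReport(
            gene_classes=pd.Series(dtype=object),
            n_stabilised=0, n_mia_genes=0, n_diet_only=len(set(diet_only_genes)),
            rescue_fraction=None, ks_D=None, ks_p=None,
            wilcoxon_V=None, wilcoxon_p=None,
        )
    pairs = pairs.copy()
    concordant = pairs["delta_mia"] * pairs["delta_diet"] > 0
    pairs["stabilised"] = (
        concordant
        & (pairs[p_column] < p_threshold)
        & (pairs["delta_diet"].abs() >= magnitude_ratio * pairs["delta_mia"].abs())
    )
    gene_table = pairs.groupby("gene").agg(
        n_sites=("stabilised", "size"),
        n_stab_sites=("stabilised", "sum"),
        delta_mia=("delta_mia", "mean"),
        delta_diet=("delta_diet", "mean"),
    )
    gene_table["stabilised"] = gene_table["n_stab_sites"] >= 0.5 * gene_table["n_sites"]
    classes = pd.Series(
        np.where(gene_table["stabilised"], "stabilised", "mia_only"),
        index=gene_table.index, dtype=object,
    )
    for g in set(diet_only_genes) - set(classes.index):
        classes.loc[g] = "diet_only"
    n_mia = len(gene_table)
    n_stab = int(gene_table["stabilised"].sum())
    stab = gene_table[gene_table["stabilised"]]
    if len(stab) >= 2:
        ks_D, ks_p = ks_two_sample(stab["delta_mia"].to_numpy(), stab["delta_diet"].to_numpy())
    else:
        ks_D = ks_p = None
    try:
        w_V, w_p = wilcoxon_signed_rank(
            gene_table["delta_mia"].to_numpy(), gene_table["delta_diet"].to_numpy()
        )
    except ValueError:
        w_V = w_p = None
    return StabilisationReport(
        gene_classes=classes,
        n_stabilised=n_stab,
        n_mia_genes=n_mia,
        n_diet_only=int((classes == "diet_only").sum()),
        rescue_fraction=rescue_fraction_from_counts(n_stab, n_mia) if n_mia else None,
        ks_D=ks_D, ks_p=ks_p, wilcoxon_V=w_V, wilcoxon_p=w_p,
        site_table=pairs, gene_table=gene_table,
    )


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov: D = sup |ECDF_x - ECDF_y|, asymptotic p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = scipy.stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def _exact_wilcoxon_p(ranks: np.ndarray, v: float) -> float:
    """Exact two-sided p by dynamic programming over sign assignments.

    Midranks are multiples of 0.5, so doubling makes the support integral and
    the null distribution of 2V is a convolution of {0, 2r_i} point masses.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    v2 = int(round(2 * v))
    lower = dist[: v2 + 1].sum()
    upper = dist[v2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(
    x, y=None, continuity: bool = True, exact_limit: int = 25
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test on x - y (or on x if y is None).

    V = sum of midranks of positive differences, zero differences dropped.
    p is exact (full sign enumeration via DP) when n <= exact_limit, else a
    normal approximation with tie correction and continuity correction.
    """
    d = np.asarray(x, float) - (0.0 if y is None else np.asarray(y, float))
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = scipy.stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    if n <= exact_limit:
        return v, _exact_wilcoxon_p(ranks, v)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    z = v - mean
    if continuity:
        z -= 0.5 * np.sign(z)
    z /= np.sqrt(var)
    return v, float(2.0 * scipy.stats.norm.sf(abs(z)))
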