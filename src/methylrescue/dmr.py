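"""Per-CpG differential methylation between two groups of experimental units.

The model is a binomial logistic regression of per-unit methylated counts on
a binary treatment indicator,

    log(pi / (1 - pi)) = beta0 + beta1 * treatment_i,

tested with a 1-df likelihood-ratio chi-square against the intercept-only
model. With a single binary covariate the MLE pools counts within each group
(group proportions are sufficient), so the fit is closed-form and the whole
site table is vectorised. Complete separation (a pooled group at 0% or 100%)
is stabilised by adding 0.5 to each of the four pooled cells
(Haldane-Anscombe) and flagged.

Downstream: BH correction, delta-methylation (unweighted unit means, second
group minus first), 250-bp single-linkage region grouping, genomic
annotation, significance ranking, per-gene direction classes, and a design
power simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .core import MethylationMatrix
from .simulate import ExperimentalUnit, GeneModel


@dataclass(frozen=True)
class Contrast:
    """Delta is defined as mean percent over group_b minus group_a, so for
    'n-6-SAL vs n-6-POL' (a=SAL, b=POL) MIA-hypomethylated sites get a
    negative delta."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self):
        a, b = set(self.group_a), set(self.group_b)
        if a & b:
            raise ValueError(f"contrast {self.name}: groups overlap")
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"contrast {self.name}: each group needs >= 2 units")

    def flipped(self) -> "Contrast":
        return Contrast(self.name + " (flipped)", self.group_b, self.group_a)


def contrast_from_cells(
    name: str, units: list[ExperimentalUnit], a: dict, b: dict
) -> Contrast:
    """Build a contrast from factor-level selectors, e.g. a={'group': 'SAL',
    'diet': 'n6'}, b={'group': 'POL', 'diet': 'n6'}."""

    def match(u, sel):
        return all(getattr(u, k) == v for k, v in sel.items())

    ga = tuple(u.unit_id for u in units if match(u, a))
    gb = tuple(u.unit_id for u in units if match(u, b))
    return Contrast(name, ga, gb)


PLANNED_CONTRASTS = (
    ("n-6-SAL vs n-6-POL", {"group": "SAL", "diet": "n6"}, {"group": "POL", "diet": "n6"}),
    ("n-3-POL vs n-6-POL", {"group": "POL", "diet": "n3"}, {"group": "POL", "diet": "n6"}),
    ("n-3-SAL vs n-6-SAL", {"group": "SAL", "diet": "n3"}, {"group": "SAL", "diet": "n6"}),
)


def planned_contrasts(units: list[ExperimentalUnit]) -> list[Contrast]:
    return [contrast_from_cells(n, units, a, b) for n, a, b in PLANNED_CONTRASTS]


@dataclass(frozen=True)
class LogisticFit:
    beta0: float
    beta1: float
    p_value: float
    corrected: bool = False  # Haldane-Anscombe stabilisation applied


def filter_coverage(
    matrix: MethylationMatrix, contrast: Contrast, min_depth: int = 10
) -> pd.Index:
    """Sites with depth >= min_depth in every unit of both groups."""
    units = list(contrast.group_a) + list(contrast.group_b)
    depth = matrix.depth[units]
    ok = depth.notna().all(axis=1) & (depth >= min_depth).all(axis=1)
    return matrix.meth.index[ok]


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _binom_ll(m, u, p):
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(m > 0, m * np.log(p), 0.0)
        term2 = np.where(u > 0, u * np.log1p(-p), 0.0)
    return term1 + term2


def fit_logistic_table(
    meth_a: np.ndarray, depth_a: np.ndarray, meth_b: np.ndarray, depth_b: np.ndarray
) -> pd.DataFrame:
    """Vectorised per-site logistic LRT from group-pooled counts.

    Returns columns beta0, beta1, lr, p_value, corrected.
    """
    ma = np.asarray(meth_a, float)
    ua = np.asarray(depth_a, float) - ma
    mb = np.asarray(meth_b, float)
    ub = np.asarray(depth_b, float) - mb
    if np.any((ma + ua) <= 0) or np.any((mb + ub) <= 0):
        raise ValueError("zero-depth group encountered; filter sites first")
    corrected = (ma == 0) | (ua == 0) | (mb == 0) | (ub == 0)
    ma = ma + 0.5 * corrected
    ua = ua + 0.5 * corrected
    mb = mb + 0.5 * corrected
    ub = ub + 0.5 * corrected
    pa = ma / (ma + ua)
    pb = mb / (mb + ub)
    pp = (ma + mb) / (ma + ua + mb + ub)
    ll_full = _binom_ll(ma, ua, pa) + _binom_ll(mb, ub, pb)
    ll_null = _binom_ll(ma, ua, pp) + _binom_ll(mb, ub, pp)
    lr = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = scipy.stats.chi2.sf(lr, df=1)
    return pd.DataFrame(
        {
            "beta0": _logit(pa),
            "beta1": _logit(pb) - _logit(pa),
            "lr": lr,
            "p_value": p,
            "corrected": corrected,
        }
    )


def fit_per_cpg_logistic(
    meth_a, depth_a, meth_b, depth_b
) -> LogisticFit:
    """Single-site fit from per-unit counts (arrays over units)."""
    row = fit_logistic_table(
        np.array([np.sum(meth_a)]),
        np.array([np.sum(depth_a)]),
        np.array([np.sum(meth_b)]),
        np.array([np.sum(depth_b)]),
    ).iloc[0]
    return LogisticFit(
        beta0=float(row.beta0), beta1=float(row.beta1),
        p_value=float(row.p_value), corrected=bool(row.corrected),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def compute_delta(
    matrix: MethylationMatrix, contrast: Contrast, sites: pd.Index | None = None
) -> pd.Series:
    """Unweighted mean of unit-level percents, group_b minus group_a."""
    pct = matrix.percent
    if sites is not None:
        pct = pct.loc[sites]
    return pct[list(contrast.group_b)].mean(axis=1) - pct[list(contrast.group_a)].mean(axis=1)


def group_regions(sites: list[tuple[str, int]], gap: int = 250) -> pd.Series:
    """Single-linkage chaining of sites within ``gap`` bp on one contig.

    Returns a Series site -> region_id (region ids are 'contig:start-end'
    over member sites).
    """
    ordered = sorted(sites)
    labels = {}
    members: list[tuple[str, int]] = []

    def flush():
        if members:
            contig = members[0][0]
            rid = f"{contig}:{members[0][1]}-{members[-1][1]}"
            for s in members:
                labels[s] = rid

    for site in ordered:
        if members and site[0] == members[-1][0] and site[1] - members[-1][1] <= gap:
            members.append(site)
        else:
            flush()
            members = [site]
    flush()
    out = pd.Series(labels, name="region_id")
    if len(out):
        out.index.names = ["contig", "pos"]
    return out


def annotate_site(
    site: tuple[str, int],
    genes: list[GeneModel],
    islands: list[tuple[str, int, int]],
    promoter_window: tuple[int, int] = (2000, 500),
    shore_width: int = 2000,
) -> dict:
    """Nearest gene (distance to gene body, 0 inside), signed TSS distance in
    the gene's orientation (negative upstream), feature class with
    promoter > exon > intron > intergenic precedence, and island class
    (island / shore within ``shore_width`` / open sea)."""
    contig, pos = site
    best = None
    best_dist = None
    for g in genes:
        if g.contig != contig:
            continue
        if g.start <= pos < g.end:
            d = 0
        elif pos < g.start:
            d = g.start - pos
        else:
            d = pos - (g.end - 1)
        if best_dist is None or d < best_dist or (d == best_dist and g.name < best.name):
            best, best_dist = g, d
    if best is None:
        return {
            "nearest_gene": None, "signed_tss_distance": None,
            "feature_class": "intergenic", "island_class": _island_class(site, islands, shore_width),
        }
    tss_dist = (pos - best.tss) if best.strand == "+" else (best.tss - pos)
    up, down = promoter_window
    if -up <= tss_dist <= down:
        feature = "promoter"
    elif best.start <= pos < best.end:
        feature = "exon" if any(s <= pos < e for s, e in best.exons) else "intron"
    else:
        feature = "intergenic"
    return {
        "nearest_gene": best.name,
        "signed_tss_distance": int(tss_dist),
        "feature_class": feature,
        "island_class": _island_class(site, islands, shore_width),
    }


def _island_class(site, islands, shore_width):
    contig, pos = site
    for c, s, e in islands:
        if c != contig:
            continue
        if s <= pos < e:
            return "island"
    for c, s, e in islands:
        if c == contig and s - shore_width <= pos < e + shore_width:
            return "shore"
    return "open_sea"


@dataclass
class ContrastResult:
    contrast: Contrast
    table: pd.DataFrame  # all eligible sites: delta_pct, p_value, q_value, ...
    min_depth: int
    q_cut: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["q_value"] < self.q_cut]


def run_contrast(
    matrix: MethylationMatrix,
    contrast: Contrast,
    genes: list[GeneModel] | None = None,
    islands: list[tuple[str, int, int]] | None = None,
    min_depth: int = 10,
    q_cut: float = 0.01,
    region_gap: int = 250,
    promoter_window: tuple[int, int] = (2000, 500),
    shore_width: int = 2000,
) -> ContrastResult:
    """Full per-contrast analysis over eligible sites."""
    sites = filter_coverage(matrix, contrast, min_depth)
    a, b = list(contrast.group_a), list(contrast.group_b)
    fits = fit_logistic_table(
        matrix.meth.loc[sites, a].sum(axis=1).to_numpy(),
        matrix.depth.loc[sites, a].sum(axis=1).to_numpy(),
        matrix.meth.loc[sites, b].sum(axis=1).to_numpy(),
        matrix.depth.loc[sites, b].sum(axis=1).to_numpy(),
    )
    table = pd.DataFrame(index=sites)
    table["contrast"] = contrast.name
    table["delta_pct"] = compute_delta(matrix, contrast, sites).to_numpy()
    table["beta1"] = fits["beta1"].to_numpy()
    table["p_value"] = fits["p_value"].to_numpy()
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table["corrected"] = fits["corrected"].to_numpy()
    table["direction"] = np.where(table["delta_pct"] < 0, "hypo", "hyper")

    sig_sites = [tuple(s) for s in table.index[table["q_value"] < q_cut]]
    regions = group_regions(sig_sites, gap=region_gap)
    table["region_id"] = regions.reindex(table.index) if len(regions) else None
    if genes is not None:
        ann = [
            annotate_site(tuple(s), genes, islands or [], promoter_window, shore_width)
            for s in sig_sites
        ]
        ann = pd.DataFrame(ann, index=pd.MultiIndex.from_tuples(sig_sites, names=["contig", "pos"]) if sig_sites else table.index[:0])
        for col in ("nearest_gene", "signed_tss_distance", "feature_class", "island_class"):
            table[col] = ann[col].reindex(table.index) if len(ann) else None
    return ContrastResult(contrast, table, min_depth, q_cut)


def rank_and_filter(
    records: pd.DataFrame, q_cut: float = 0.01, delta_cut_pathway: float = 3.0
) -> tuple[pd.DataFrame, list[str]]:
    """Rank q<q_cut records by |delta| (ties: smaller q, then coordinate);
    pathway gene list = unique nearest genes with |delta| > cutoff."""
    kept = records[records["q_value"] < q_cut].copy()
    kept["_absd"] = kept["delta_pct"].abs()
    kept = kept.sort_values(
        by=["_absd", "q_value"], ascending=[False, True], kind="stable"
    ).drop(columns="_absd")
    if "nearest_gene" in kept:
        big = kept[kept["delta_pct"].abs() > delta_cut_pathway]
        genes = sorted(set(big["nearest_gene"].dropna()))
    else:
        genes = []
    return kept, genes


def classify_gene_direction(significant: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Per-gene class from the signs of member site deltas: hypo if all
    negative, hyper if all positive, both otherwise."""
    if "nearest_gene" not in significant or significant["nearest_gene"].isna().all():
        return pd.Series(dtype=object), {"hypo": 0, "hyper": 0, "both": 0}

    def _cls(deltas):
        if (deltas < 0).all():
            return "hypo"
        if (deltas > 0).all():
            return "hyper"
        return "both"

    classes = (
        significant.dropna(subset=["nearest_gene"])
        .groupby("nearest_gene")["delta_pct"]
        .apply(_cls)
    )
    counts = classes.value_counts().to_dict()
    for k in ("hypo", "hyper", "both"):
        counts.setdefault(k, 0)
    return classes, counts


def power_simulation(
    n_units_per_group: int,
    depth: int,
    baseline_pct: float,
    delta_pct: float,
    alpha: float = 0.05,
    n_reps: int = 1000,
    seed: int = 0,
) -> dict:
    """Monte-Carlo power of the per-CpG logistic LRT for one site.

    Simulates binomial counts at the stated baseline/delta per unit, fits the
    test per replicate, and reports the rejection fraction with a 95% Wilson
    interval.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    for v in (baseline_pct, baseline_pct + delta_pct):
        if not 0 <= v <= 100:
            raise ValueError("baseline/delta push probability outside [0, 100]")
    rng = np.random.default_rng(seed)
    pa = baseline_pct / 100.0
    pb = (baseline_pct + delta_pct) / 100.0
    ma = rng.binomial(depth, pa, size=(n_reps, n_units_per_group)).sum(axis=1)
    mb = rng.binomial(depth, pb, size=(n_reps, n_units_per_group)).sum(axis=1)
    tot = float(depth * n_units_per_group)
    fits = fit_logistic_table(ma, np.full(n_reps, tot), mb, np.full(n_reps, tot))
    reject = fits["p_value"].to_numpy() < alpha
    power = float(reject.mean())
    lo, hi = scipy.stats.binomtest(int(reject.sum()), n_reps).proportion_ci(0.95, "wilson")
    return {"power": power, "ci_low": float(lo), "ci_high": float(hi), "n_reps": n_reps}
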