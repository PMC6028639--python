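"""Per-site methylation scoring, cross-unit depth quantile normalisation, and
the read-start global CCGG methylation estimator.

The global estimator exploits the MspI chemistry of a directional RRBS
library: every fragment begins at a C^CGG cut, so after bisulfite conversion
a read starts CGG when the first CpG of the fragment was methylated and TGG
when it was not. The C/(C+T) ratio over read starts therefore measures global
CCGG methylation without any alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


def methylation_score(n_meth, n_unmeth):
    """Percent methylation = 100 * C / (C + T); scalar or array.

    Scalar zero depth raises; array zero-depth entries become NaN.
    """
    if np.isscalar(n_meth) and np.isscalar(n_unmeth):
        depth = n_meth + n_unmeth
        if depth < 1:
            raise ValueError("methylation score undefined at zero depth")
        return 100.0 * n_meth / depth
    n_meth = np.asarray(n_meth, dtype=float)
    depth = n_meth + np.asarray(n_unmeth, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(depth > 0, 100.0 * n_meth / depth, np.nan)


class MethylationMatrix:
    """Sites x units counts; NaN marks a site not covered in a unit."""

    def __init__(self, meth: pd.DataFrame, unmeth: pd.DataFrame):
        if not meth.index.equals(unmeth.index) or not meth.columns.equals(unmeth.columns):
            raise ValueError("meth/unmeth must share index and columns")
        self.meth = meth.astype(float)
        self.unmeth = unmeth.astype(float)

    @classmethod
    def from_unit_counts(cls, unit_counts: dict[str, pd.DataFrame]) -> "MethylationMatrix":
        """unit_counts: unit_id -> DataFrame(contig, pos, n_meth, n_unmeth)."""
        meth_cols, unmeth_cols = {}, {}
        for unit_id, df in unit_counts.items():
            idx = pd.MultiIndex.from_frame(df[["contig", "pos"]])
            meth_cols[unit_id] = pd.Series(df["n_meth"].to_numpy(), index=idx)
            unmeth_cols[unit_id] = pd.Series(df["n_unmeth"].to_numpy(), index=idx)
        meth = pd.DataFrame(meth_cols).sort_index()
        unmeth = pd.DataFrame(unmeth_cols).sort_index()
        return cls(meth, unmeth)

    @property
    def depth(self) -> pd.DataFrame:
        return self.meth + self.unmeth

    @property
    def percent(self) -> pd.DataFrame:
        depth = self.depth
        return 100.0 * self.meth / depth.where(depth > 0)

    @property
    def units(self) -> list[str]:
        return list(self.meth.columns)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def quantile_normalize_depth(matrix: MethylationMatrix) -> MethylationMatrix:
    """Force per-unit depth distributions to the cross-unit mean order
    statistics, preserving each site's methylation percent.

    Operates on sites covered in every unit (the complete-case block); other
    sites keep their raw counts. Ties within a unit receive the average of
    the reference order statistics spanned by the tied ranks. New counts are
    recomputed from the preserved percent with half-away-from-zero rounding
    of n_meth and n_unmeth taken by subtraction so depth stays exact.
    """
    depth = matrix.depth
    complete = depth.notna().all(axis=1) & (depth > 0).all(axis=1)
    n = int(complete.sum())
    if matrix.meth.shape[1] < 2 or n < 2:
        logger.warning("quantile normalisation skipped: fewer than 2 shared sites")
        return MethylationMatrix(matrix.meth.copy(), matrix.unmeth.copy())
    block = depth.loc[complete]
    ref = np.sort(block.to_numpy(), axis=0).mean(axis=1)

    pct = matrix.percent
    new_meth = matrix.meth.copy()
    new_unmeth = matrix.unmeth.copy()
    for unit in matrix.units:
        d = block[unit].to_numpy()
        order = np.argsort(d, kind="stable")
        new_d = np.empty(n)
        new_d[order] = ref
        # average reference order statistics over tied depth values
        sorted_d = d[order]
        i = 0
        while i < n:
            j = i
            while j + 1 < n and sorted_d[j + 1] == sorted_d[i]:
                j += 1
            if j > i:
                new_d[order[i : j + 1]] = ref[i : j + 1].mean()
            i = j + 1
        new_d = _round_half_away(new_d)
        p = pct.loc[complete, unit].to_numpy() / 100.0
        m = _round_half_away(p * new_d)
        new_meth.loc[complete, unit] = m
        new_unmeth.loc[complete, unit] = new_d - m
    return MethylationMatrix(new_meth, new_unmeth)


@dataclass(frozen=True)
class GlobalMethylationEstimate:
    unit_id: str
    n_cgg: int
    n_tgg: int
    n_other: int

    @property
    def percent(self) -> float:
        return 100.0 * self.n_cgg / (self.n_cgg + self.n_tgg)

    @property
    def total_reads(self) -> int:
        return self.n_cgg + self.n_tgg + self.n_other


def global_ccgg_methylation(reads, unit_id: str = "") -> GlobalMethylationEstimate:
    """Classify each read by its first trinucleotide (CGG = methylated MspI
    cytosine, TGG = unmethylated, anything else excluded and logged)."""
    n_cgg = n_tgg = n_other = 0
    for item in reads:
        bases = item[1] if isinstance(item, tuple) else item
        start = bases[:3]
        if start == "CGG":
            n_cgg += 1
        elif start == "TGG":
            n_tgg += 1
        else:
            n_other += 1
    if n_cgg + n_tgg == 0:
        raise ValueError(f"no CGG/TGG-start reads for unit {unit_id!r}")
    total = n_cgg + n_tgg + n_other
    logger.info(
        "global estimator %s: %d/%d reads unclassifiable (%.2f%%)",
        unit_id, n_other, total, 100.0 * n_other / total,
    )
    return GlobalMethylationEstimate(unit_id, n_cgg, n_tgg, n_other)


@dataclass
class GlobalGLMResult:
    params: pd.Series
    pvalues: pd.Series
    anova: pd.DataFrame
    r_squared: float
    f_statistic: float
    f_pvalue: float
    t_tests: pd.DataFrame  # name, stratum, t, p, delta


def glm_global_methylation(data: pd.DataFrame) -> GlobalGLMResult:
    """OLS of unit-level global methylation percent on group, diet, sex and
    their two-way interactions, with stratified post-hoc Welch-free t-tests.

    ``data`` needs columns unit_id, group, diet, sex, percent with all eight
    design cells present.
    """
    cells = set(map(tuple, data[["group", "diet", "sex"]].drop_duplicates().to_numpy()))
    expected = {(g, d, s) for g in ("SAL", "POL") for d in ("n6", "n3") for s in ("M", "F")}
    missing = expected - cells
    if missing:
        raise ValueError(f"design cells missing: {sorted(missing)}")
    model = smf.ols(
        "percent ~ C(group) + C(diet) + C(sex)"
        " + C(group):C(diet) + C(group):C(sex) + C(diet):C(sex)",
        data=data,
    ).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    def _ttest(name, stratum, a, b):
        t, p = scipy.stats.ttest_ind(a, b)
        return {
            "name": name, "stratum": stratum, "t": float(t), "p": float(p),
            "delta": float(np.mean(b) - np.mean(a)),
        }

    tests = []
    strata = [("all", data)] + [(s, data[data["sex"] == s]) for s in ("M", "F")]
    for label, sub in strata:
        s = lambda **kw: sub.loc[
            np.logical_and.reduce([sub[k] == v for k, v in kw.items()]), "percent"
        ]
        tests.append(_ttest("n-6-SAL vs n-6-POL", label, s(group="SAL", diet="n6"), s(group="POL", diet="n6")))
        tests.append(_ttest("n-3-POL vs n-6-POL", label, s(group="POL", diet="n3"), s(group="POL", diet="n6")))
        tests.append(_ttest("n-3-SAL vs n-6-SAL", label, s(group="SAL", diet="n3"), s(group="SAL", diet="n6")))
    # with zero response variance R^2 is 0/0; report 0 (no variance explained)
    r_squared = float(model.rsquared)
    if not np.isfinite(r_squared):
        r_squared = 0.0
    return GlobalGLMResult(
        params=model.params,
        pvalues=model.pvalues,
        anova=anova,
        r_squared=r_squared,
        f_statistic=float(model.fvalue),
        f_pvalue=float(model.f_pvalue),
        t_tests=pd.DataFrame(tests),
    )
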