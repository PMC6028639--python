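"""Overlay of DMRs with regulatory tag tracks (DNase hypersensitivity and
MECP2 ChIP): per-site tag density in a window, per-million normalisation, a
density cutoff (DHS default > 5), three-way set overlap, and a hypergeometric
over-representation test against the contrast-eligible background."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)

DEFAULT_CUTOFFS = {"DHS": 5.0, "MECP2": 0.0}


def auto_cutoff(densities, factor: float = 3.0, anchor_quantile: float = 0.25) -> float:
    """Density cutoff scaled to the track at hand: ``factor`` times a low
    quantile of the per-million window densities over the eligible sites.

    A fixed cutoff like the DHS default of 5 is meaningful on a full-size
    genome, where it sits several-fold above the typical window density; on
    a miniature genome the typical density itself is huge, so the cutoff is
    anchored to the observed background level instead. The anchor is a low
    quantile (default 25th percentile) because enriched sites and their
    neighbours can make up a sizeable minority of a miniature background.
    """
    return factor * float(np.quantile(np.asarray(densities, dtype=float), anchor_quantile))


class TagTrack:
    """Sorted single-position tags per contig."""

    def __init__(self, tags: pd.DataFrame, name: str = "track"):
        self.name = name
        self.positions = {
            contig: np.sort(sub["pos"].to_numpy())
            for contig, sub in tags.groupby("contig")
        }
        self.total = int(sum(len(v) for v in self.positions.values()))

    def count_window(self, contig: str, pos: int, window: int) -> int:
        p = self.positions.get(contig)
        if p is None:
            return 0
        return int(
            np.searchsorted(p, pos + window, side="right")
            - np.searchsorted(p, pos - window, side="left")
        )


def tag_density(
    sites, track: TagTrack, window: int = 1000, cutoff: float = 5.0
) -> pd.DataFrame:
    """Tags within +-window of each site, scaled per million track tags.

    ``sites`` is an iterable of (contig, pos). passes iff density > cutoff.
    """
    sites = list(sites)
    if track.total == 0:
        logger.warning("empty tag track %s: all densities 0", track.name)
        raw = np.zeros(len(sites), dtype=int)
        density = raw.astype(float)
    else:
        raw = np.array(
            [track.count_window(c, p, window) for c, p in sites], dtype=int
        )
        density = raw * 1e6 / track.total
    idx = pd.MultiIndex.from_tuples(sites, names=["contig", "pos"]) if sites else None
    return pd.DataFrame(
        {"raw_tags": raw, "density": density, "passes": density > cutoff}, index=idx
    )


def overlap_sets(dmr_sites, dhs_sites, mecp2_sites) -> dict:
    """Venn-region counts of the DMR set against the two regulatory sets."""
    dmr, dhs, mecp2 = set(dmr_sites), set(dhs_sites), set(mecp2_sites)
    return {
        "n_dmr": len(dmr),
        "dmr_only": len(dmr - dhs - mecp2),
        "dmr_dhs_only": len((dmr & dhs) - mecp2),
        "dmr_mecp2_only": len((dmr & mecp2) - dhs),
        "dmr_dhs_mecp2": len(dmr & dhs & mecp2),
        "dmr_dhs": len(dmr & dhs),
        "dmr_mecp2": len(dmr & mecp2),
    }


@dataclass(frozen=True)
class OverlapResult:
    n_background: int
    n_background_hit: int
    n_dmr: int
    n_dmr_hit: int

    def __post_init__(self):
        ok = (
            0 <= self.n_dmr_hit <= min(self.n_dmr, self.n_background_hit)
            and self.n_dmr <= self.n_background
            and self.n_background_hit <= self.n_background
        )
        if not ok:
            raise ValueError(f"inconsistent overlap counts: {self}")


def overrepresentation_test(overlap: OverlapResult) -> float:
    """Upper-tail hypergeometric P(X >= n_dmr_hit) when drawing n_dmr sites
    from a background containing n_background_hit track-positive sites."""
    return float(
        scipy.stats.hypergeom.sf(
            overlap.n_dmr_hit - 1,
            overlap.n_background,
            overlap.n_background_hit,
            overlap.n_dmr,
        )
    )


def integrate(
    eligible_sites,
    dmr_sites,
    dhs_track: TagTrack,
    mecp2_track: TagTrack,
    window: int = 1000,
    dhs_cutoff: float | str = 5.0,
    mecp2_cutoff: float | str = 0.0,
) -> dict:
    """Full integration step over the contrast-eligible background: densities,
    Venn counts over the DMR set, and the two over-representation tests.

    A cutoff of ``"auto"`` resolves to :func:`auto_cutoff` over the eligible
    background densities of that track.
    """
    eligible = [tuple(s) for s in eligible_sites]
    dmr = [tuple(s) for s in dmr_sites]
    missing = set(dmr) - set(eligible)
    if missing:
        raise ValueError(f"{len(missing)} DMR sites outside the eligible background")
    dhs = tag_density(eligible, dhs_track, window, 0.0)
    mecp2 = tag_density(eligible, mecp2_track, window, 0.0)
    if dhs_cutoff == "auto":
        dhs_cutoff = auto_cutoff(dhs["density"])
    if mecp2_cutoff == "auto":
        mecp2_cutoff = auto_cutoff(mecp2["density"])
    dhs["passes"] = dhs["density"] > dhs_cutoff
    mecp2["passes"] = mecp2["density"] > mecp2_cutoff
    dhs_pass = set(dhs.index[dhs["passes"]])
    mecp2_pass = set(mecp2.index[mecp2["passes"]])
    venn = overlap_sets(dmr, dhs_pass, mecp2_pass)
    results = {}
    for label, passes in (("DHS", dhs_pass), ("MECP2", mecp2_pass)):
        ov = OverlapResult(
            n_background=len(eligible),
            n_background_hit=len(passes),
            n_dmr=len(dmr),
            n_dmr_hit=len(set(dmr) & passes),
        )
        results[label] = {"overlap": ov, "p_value": overrepresentation_test(ov)}
    return {
        "dhs_density": dhs,
        "mecp2_density": mecp2,
        "venn": venn,
        "tests": results,
    }
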