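"""Synthetic RRBS study generator.

Builds a fully specified miniature methylome study: a small reference genome
with MspI (CCGG) sites and CpG islands, a balanced 2x2x2 experimental design
(prenatal group SAL/POL x postnatal diet n6/n3 x sex M/F), per-site per-unit
methylation ground truth with a global MIA hypomethylation shift plus planted
site-specific DMRs partially reversed by the n-3 diet, directional single-end
bisulfite reads, and regulatory tag tracks enriched at a subset of DMR sites.

Everything is deterministic under the configured seed; the generator is the
test bed for every downstream stage of the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("SAL", "POL")
DIETS = ("n6", "n3")
SEXES = ("M", "F")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Percent-scale parameters are in [0, 100]; ``mia_global_shift`` and
    ``dmr_delta`` are percentage-point offsets (negative = hypomethylation).
    ``unit_dispersion`` is the precision of the beta distribution from which
    unit-level methylation probabilities are drawn around the cell mean
    (``None`` disables unit-level scatter entirely).
    """

    seed: int
    n_contigs: int = 2
    contig_length: int = 50_000
    ccgg_rate: float = 5.0  # expected CCGG sites per kb
    n_islands: int = 8
    island_length: int = 1_000
    n_genes: int = 30
    baseline_meth: float = 75.0
    island_meth: float = 20.0
    mia_global_shift: float = -5.0
    n_dmr_sites: int = 100
    dmr_delta: float = -20.0
    rescue_fraction: float = 0.8
    unit_dispersion: float | None = 200.0
    coverage: float = 20.0
    read_length: int = 51
    conversion_rate: float = 0.995
    size_range: tuple[int, int] = (40, 220)
    error_rate: float = 0.0
    # regulatory-track simulation
    tag_background_rate: float = 0.02  # tags per bp
    tag_enrichment_fold: float = 10.0
    tag_window: int = 50  # enrichment half-width; small so that planted
    # peaks stay sparse relative to the miniature genome
    dhs_dmr_fraction: float = 0.6
    mecp2_dmr_fraction: float = 0.6

    def __post_init__(self) -> None:
        for name in ("baseline_meth", "island_meth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if not 0.0 <= self.rescue_fraction <= 1.0:
            raise ValueError("rescue_fraction outside [0, 1]")
        lo, hi = self.size_range
        if lo > hi or lo < 20:
            raise ValueError(f"size_range {self.size_range} invalid (min >= 20 bp)")
        if self.conversion_rate < 0 or self.conversion_rate > 1:
            raise ValueError("conversion_rate outside [0, 1]")
        if self.unit_dispersion is not None and self.unit_dispersion <= 0:
            raise ValueError("unit_dispersion must be positive or None")
        if self.read_length < 1 or self.coverage < 0:
            raise ValueError("read_length/coverage invalid")


@dataclass(frozen=True)
class ExperimentalUnit:
    """One same-sex, same-litter cage pool: the unit of replication."""

    unit_id: str
    group: str
    diet: str
    sex: str
    n_animals: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS or self.diet not in DIETS or self.sex not in SEXES:
            raise ValueError(f"bad factor levels in unit {self.unit_id}")
        if not 2 <= self.n_animals <= 6:
            raise ValueError(f"n_animals={self.n_animals} outside [2, 6]")

    @property
    def cell(self) -> tuple[str, str]:
        return (self.group, self.diet)


@dataclass(frozen=True)
class GeneModel:
    contig: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    name: str
    exons: tuple[tuple[int, int], ...]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class Fragment:
    contig: str
    start: int  # 0-based
    end: int  # half-open
    seq: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Reference:
    contigs: dict[str, str]
    islands: list[tuple[str, int, int]]
    genes: list[GeneModel]

    def cpg_positions(self, contig: str) -> np.ndarray:
        """0-based positions of the C of every top-strand CpG."""
        seq = np.frombuffer(self.contigs[contig].encode(), dtype=np.uint8)
        return np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))

    def is_cpg(self, contig: str) -> np.ndarray:
        seq = self.contigs[contig]
        mask = np.zeros(len(seq), dtype=bool)
        mask[self.cpg_positions(contig)] = True
        return mask


@dataclass
class MethylationGroundTruth:
    """True per-site per-unit methylation probabilities (scale [0, 1])."""

    probs: pd.DataFrame  # index (contig, pos), columns unit_id
    cell_means: pd.DataFrame  # index (contig, pos), columns "GROUP-diet", percent
    dmr_site_ids: frozenset
    rescued_site_ids: frozenset

    def __post_init__(self) -> None:
        if not self.rescued_site_ids <= self.dmr_site_ids:
            raise ValueError("rescued sites must be a subset of DMR sites")


def make_design(seed: int | np.random.Generator = 0) -> list[ExperimentalUnit]:
    """The full 24-unit design: 3 units per group x diet x sex cell."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    units = []
    for group in GROUPS:
        for diet in DIETS:
            for sex in SEXES:
                for i in range(1, 4):
                    units.append(
                        ExperimentalUnit(
                            unit_id=f"{group}-{diet}-{sex}{i}",
                            group=group,
                            diet=diet,
                            sex=sex,
                            n_animals=int(rng.integers(2, 7)),
                        )
                    )
    return units


def design_frame(units: list[ExperimentalUnit]) -> pd.DataFrame:
    return pd.DataFrame([asdict(u) for u in units]).set_index("unit_id")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    """Background sequence as uint8 codes, mildly AT-rich like mouse."""
    probs = np.array([0.29, 0.21, 0.21, 0.29])
    return _BASES[rng.choice(4, size=length, p=probs)]


def _island_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    """CpG-dense sequence built from CG dinucleotides and filler bases."""
    out = np.empty(length + 1, dtype=np.uint8)
    i = 0
    while i < length:
        if rng.random() < 0.30 and i + 1 < length:
            out[i] = ord("C")
            out[i + 1] = ord("G")
            i += 2
        else:
            out[i] = _BASES[rng.choice(4, p=[0.25, 0.3, 0.2, 0.25])]
            i += 1
    return out[:length]


def _scrub_accidental_ccgg(seq: bytearray, planted: set[int]) -> None:
    """Break every CCGG occurrence that was not deliberately planted.

    The second C is mutated to A, which can never create a new CCGG; repeat
    until only planted occurrences remain so the total CCGG count is exactly
    the planted Poisson draw.
    """
    while True:
        dirty = False
        start = 0
        data = bytes(seq)
        while True:
            hit = data.find(b"CCGG", start)
            if hit < 0:
                break
            if hit not in planted:
                seq[hit + 1] = ord("A")
                dirty = True
            start = hit + 1
        if not dirty:
            return


def generate_reference(config: SimulationConfig) -> Reference:
    """Generate the reference genome with islands, genes and CCGG sites.

    CCGG occurrences are planted as a Poisson process at ``ccgg_rate`` per kb;
    accidental occurrences arising from the background composition are
    scrubbed so the realised count follows the configured rate exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    contigs: dict[str, str] = {}
    islands: list[tuple[str, int, int]] = []
    genes: list[GeneModel] = []
    total_ccgg = 0
    per_contig_islands = max(1, config.n_islands // config.n_contigs)
    per_contig_genes = max(1, config.n_genes // config.n_contigs)

    for c in range(config.n_contigs):
        name = f"chr{c + 1}"
        L = config.contig_length
        seq = bytearray(_random_sequence(rng, L).tobytes())

        # non-overlapping islands on a regular grid with random jitter
        slot = L // per_contig_islands
        for j in range(per_contig_islands):
            lo = j * slot
            hi = max(lo + 1, (j + 1) * slot - config.island_length - 1)
            s = int(rng.integers(lo, hi))
            e = min(s + config.island_length, L)
            seq[s:e] = _island_sequence(rng, e - s).tobytes()
            islands.append((name, s, e))

        # plant CCGG sites
        n_sites = rng.poisson(config.ccgg_rate * L / 1000.0)
        positions = np.sort(rng.choice(L - 4, size=min(n_sites, L // 8), replace=False))
        planted: set[int] = []
        last = -10
        planted = set()
        for p in positions:
            if p - last >= 4:
                seq[p : p + 4] = b"CCGG"
                planted.add(int(p))
                last = p
        _scrub_accidental_ccgg(seq, planted)
        total_ccgg += len(planted)

        # gene models: random non-overlapping bodies with 2-4 exons
        gslot = L // per_contig_genes
        for g in range(per_contig_genes):
            max_len = min(6_000, gslot - 100)
            min_len = min(2_000, max(200, max_len // 2))
            body_len = int(rng.integers(min_len, max(min_len + 1, max_len)))
            lo = g * gslot
            s = int(rng.integers(lo, lo + gslot - body_len))
            e = s + body_len
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 5))
            bounds = np.sort(rng.choice(body_len - 2, size=2 * n_ex - 2, replace=False) + 1)
            edges = np.concatenate([[0], bounds, [body_len]])
            exons = tuple(
                (s + int(edges[2 * k]), s + int(edges[2 * k + 1])) for k in range(n_ex)
            )
            genes.append(
                GeneModel(name, s, e, strand, f"gene_{name}_{g + 1:03d}", exons)
            )
        contigs[name] = seq.decode()

    if total_ccgg < config.n_dmr_sites:
        raise ValueError(
            f"genome has {total_ccgg} CCGG sites but n_dmr_sites={config.n_dmr_sites}"
        )
    return Reference(contigs=contigs, islands=islands, genes=genes)


def digest_mspi(contigs: dict[str, str]) -> list[Fragment]:
    """In-silico MspI digestion: cut every C^CGG, keeping all fragments.

    Concatenating the returned fragments of one contig reconstructs it.
    """
    fragments: list[Fragment] = []
    for name, seq in contigs.items():
        cuts = [0]
        start = 0
        while True:
            hit = seq.find("CCGG", start)
            if hit < 0:
                break
            cuts.append(hit + 1)  # between the first C and CGG
            start = hit + 1
        cuts.append(len(seq))
        for a, b in zip(cuts[:-1], cuts[1:]):
            if b > a:
                fragments.append(Fragment(name, a, b, seq[a:b]))
    return fragments


def size_select(fragments: list[Fragment], size_range: tuple[int, int]) -> list[Fragment]:
    lo, hi = size_range
    return [f for f in fragments if lo <= len(f) <= hi]


def assign_methylation(
    reference: Reference,
    units: list[ExperimentalUnit],
    config: SimulationConfig,
) -> MethylationGroundTruth:
    """Draw the per-site per-unit methylation ground truth.

    Cell mean (percent) = base + mia_global_shift*[group=POL]
    + dmr_delta*[site in DMR, group=POL]*(1 - [site rescued, diet=n3]),
    where base is island_meth inside islands and baseline_meth elsewhere.
    Unit probabilities are beta-distributed around the cell mean.
    """
    cells = {(g, d) for u in units for (g, d) in [u.cell]}
    if cells != {(g, d) for g in GROUPS for d in DIETS}:
        raise ValueError("units must cover all four group x diet cells")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    sites: list[tuple[str, int]] = []
    base: list[float] = []
    for contig in reference.contigs:
        pos = reference.cpg_positions(contig)
        in_island = np.zeros(pos.size, dtype=bool)
        for c, s, e in reference.islands:
            if c == contig:
                in_island |= (pos >= s) & (pos < e)
        sites.extend((contig, int(p)) for p in pos)
        base.extend(np.where(in_island, config.island_meth, config.baseline_meth))
    index = pd.MultiIndex.from_tuples(sites, names=["contig", "pos"])
    base = np.asarray(base)

    # DMR sites are drawn from fragment-start CpGs of size-selected fragments,
    # which guarantees read coverage downstream.
    kept = size_select(digest_mspi(reference.contigs), config.size_range)
    site_set = set(index)
    candidates = [
        (f.contig, f.start)
        for f in kept
        if f.seq.startswith("CG") and (f.contig, f.start) in site_set
    ]
    if len(candidates) < config.n_dmr_sites:
        raise ValueError(
            f"only {len(candidates)} covered CCGG-start CpGs available "
            f"for n_dmr_sites={config.n_dmr_sites}"
        )
    order = rng.permutation(len(candidates))
    dmr_sites = [candidates[i] for i in order[: config.n_dmr_sites]]
    n_rescued = int(round(config.rescue_fraction * len(dmr_sites)))
    rescued = frozenset(dmr_sites[:n_rescued])
    dmr_sites = frozenset(dmr_sites)

    is_dmr = np.fromiter((s in dmr_sites for s in index), bool, len(index))
    is_rescued = np.fromiter((s in rescued for s in index), bool, len(index))

    cell_means = {}
    for g in GROUPS:
        for d in DIETS:
            mean = base.copy()
            if g == "POL":
                mean = mean + config.mia_global_shift
                effect = np.where(is_rescued & (d == "n3"), 0.0, config.dmr_delta)
                mean = mean + np.where(is_dmr, effect, 0.0)
            clipped = np.clip(mean, 0.0, 100.0)
            if np.any(clipped != mean):
                logger.warning(
                    "clamped %d cell means to [0, 100] in cell %s-%s",
                    int(np.sum(clipped != mean)), g, d,
                )
            cell_means[f"{g}-{d}"] = clipped
    cell_means = pd.DataFrame(cell_means, index=index)

    probs = {}
    for u in units:
        mean = cell_means[f"{u.group}-{u.diet}"].to_numpy() / 100.0
        if config.unit_dispersion is None:
            p = mean
        else:
            kappa = config.unit_dispersion
            a = np.clip(mean * kappa, 1e-9, None)
            b = np.clip((1.0 - mean) * kappa, 1e-9, None)
            p = rng.beta(a, b)
            p = np.where((mean <= 0.0) | (mean >= 1.0), mean, p)
        probs[u.unit_id] = p
    probs = pd.DataFrame(probs, index=index)

    return MethylationGroundTruth(
        probs=probs,
        cell_means=cell_means,
        dmr_site_ids=dmr_sites,
        rescued_site_ids=rescued,
    )


def simulate_reads(
    fragments: list[Fragment],
    truth: MethylationGroundTruth,
    unit: ExperimentalUnit,
    config: SimulationConfig,
    reference: Reference,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str, str]]:
    """Simulate directional bisulfite reads for one unit.

    Each read is the 5' prefix (length <= read_length) of the original top
    strand of a size-selected fragment after in-silico bisulfite treatment:
    CpG cytosines survive as C with the site's unit probability, non-CpG
    cytosines convert to T with ``conversion_rate``. Read count per fragment
    is Poisson(coverage). Returns (read_id, bases, quals) tuples.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    if not fragments:
        logger.warning("simulate_reads: empty fragment list for %s", unit.unit_id)
        return []
    unit_probs = truth.probs[unit.unit_id]
    is_cpg = {c: reference.is_cpg(c) for c in reference.contigs}
    qual_char = "I"  # Phred 40
    reads: list[tuple[str, str, str]] = []
    C, T = ord("C"), ord("T")
    for fi, frag in enumerate(fragments):
        L = min(config.read_length, len(frag))
        template = np.frombuffer(frag.seq[:L].encode(), dtype=np.uint8).copy()
        mask = is_cpg[frag.contig][frag.start : frag.start + L]
        c_pos = np.flatnonzero(template == C)
        cpg_c = c_pos[mask[c_pos]]
        other_c = c_pos[~mask[c_pos]]
        site_p = np.array(
            [unit_probs.loc[(frag.contig, frag.start + int(j))] for j in cpg_c]
        )
        qual = qual_char * L
        n_reads = rng.poisson(config.coverage)
        for r in range(n_reads):
            out = template.copy()
            if cpg_c.size:
                out[cpg_c] = np.where(rng.random(cpg_c.size) < site_p, C, T)
            if other_c.size:
                out[other_c] = np.where(
                    rng.random(other_c.size) < config.conversion_rate, T, C
                )
            if config.error_rate > 0.0:
                err = rng.random(L) < config.error_rate
                if err.any():
                    out[err] = _BASES[rng.integers(0, 4, int(err.sum()))]
            rid = f"{unit.unit_id}|{frag.contig}|{frag.start}|{fi}:{r}"
            reads.append((rid, out.tobytes().decode(), qual))
    return reads


def simulate_tag_track(
    contig_lengths: dict[str, int],
    enriched_sites: list[tuple[str, int]],
    background_rate: float,
    enrichment_fold: float,
    rng: np.random.Generator,
    window: int = 500,
) -> pd.DataFrame:
    """Single-position tag track: Poisson background plus fold-enrichment
    within +-window of the enriched sites. Returns columns contig, pos."""
    if enrichment_fold < 1:
        raise ValueError("enrichment_fold must be >= 1")
    rows: list[tuple[str, int]] = []
    for contig, L in contig_lengths.items():
        n_bg = rng.poisson(background_rate * L)
        rows.extend((contig, int(p)) for p in np.sort(rng.integers(0, L, n_bg)))
    extra_rate = background_rate * (enrichment_fold - 1.0)
    for contig, pos in enriched_sites:
        L = contig_lengths[contig]
        lo, hi = max(0, pos - window), min(L, pos + window + 1)
        n = rng.poisson(extra_rate * (hi - lo))
        rows.extend((contig, int(p)) for p in rng.integers(lo, hi, n))
    df = pd.DataFrame(rows, columns=["contig", "pos"])
    return df.sort_values(["contig", "pos"], kind="stable").reset_index(drop=True)


def simulate_count_study(
    n_sites: int,
    depth: int,
    seed: int,
    baseline: float = 75.0,
    mia_shift: float = 0.0,
    n_dmr: int = 0,
    dmr_delta: float = 0.0,
    rescue_fraction: float = 0.0,
    dmr_baseline: float | None = None,
    dispersion: float | None = None,
    units: list[ExperimentalUnit] | None = None,
):
    """Count-level study simulator (no reads): binomial methylated counts at
    fixed depth for every site x unit, under the same cell-mean structure as
    :func:`assign_methylation`. Site ids are integers; DMR site i is mapped
    to synthetic gene ``gene_i``.

    Returns (meth, unmeth, dmr_sites, rescued_sites, site_gene) where meth and
    unmeth are DataFrames (site x unit).
    """
    rng = np.random.default_rng(seed)
    if units is None:
        units = make_design(rng)
    base = np.full(n_sites, baseline)
    dmr_idx = np.arange(n_dmr)
    if dmr_baseline is not None:
        base[dmr_idx] = dmr_baseline
    n_rescued = int(round(rescue_fraction * n_dmr))
    rescued_idx = dmr_idx[:n_rescued]
    is_dmr = np.zeros(n_sites, bool)
    is_dmr[dmr_idx] = True
    is_rescued = np.zeros(n_sites, bool)
    is_rescued[rescued_idx] = True

    meth = {}
    for u in units:
        mean = base.copy()
        if u.group == "POL":
            mean = mean + mia_shift
            effect = np.where(is_rescued & (u.diet == "n3"), 0.0, dmr_delta)
            mean = mean + np.where(is_dmr, effect, 0.0)
        p = np.clip(mean / 100.0, 0.0, 1.0)
        if dispersion is not None:
            a = np.clip(p * dispersion, 1e-9, None)
            b = np.clip((1 - p) * dispersion, 1e-9, None)
            drawn = rng.beta(a, b)
            p = np.where((p <= 0) | (p >= 1), p, drawn)
        meth[u.unit_id] = rng.binomial(depth, p)
    meth = pd.DataFrame(meth, index=pd.RangeIndex(n_sites, name="site"))
    unmeth = depth - meth
    site_gene = pd.Series(
        [f"gene_{i}" if is_dmr[i] else f"bg_{i}" for i in range(n_sites)],
        index=meth.index,
        name="gene",
    )
    return meth, unmeth, set(dmr_idx.tolist()), set(rescued_idx.tolist()), site_gene
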