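"""FASTQ to per-CpG counts: adapter trimming, mean-Phred quality screening,
C->T-collapsed bisulfite alignment against the top strand, and methylation
calling.

The aligner is a pigeonhole seed-and-verify unique matcher over the
C->T-collapsed reference: a read with at most ``max_mismatches`` collapsed
mismatches must match one of three disjoint segments exactly, so candidate
loci come from exact seed hits and are verified by Hamming distance. Ties in
the best score are rejected as ambiguous rather than broken arbitrarily,
making results invariant to reference order. Only the top strand is indexed
(directional library); there is no indel handling.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import Reference

DEFAULT_ADAPTER = "AGATCGGAAGAGC"  # standard sequencing adapter stem
_COLLAPSE = str.maketrans("C", "T")


@dataclass(frozen=True)
class Read:
    id: str
    bases: str
    quals: str  # Phred+33

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.id}: bases/quals length mismatch")

    def __len__(self):
        return len(self.bases)


@dataclass(frozen=True)
class Alignment:
    read_id: str
    contig: str
    start: int  # 0-based
    length: int
    n_mismatches: int
    unique: bool = True


def _hamming(a: str, b: str, limit: int) -> int:
    """Mismatch count with early abort above ``limit``."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def trim_adapter(
    read: Read,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 12,
    max_mismatches: int = 2,
    min_keep: int = 22,
) -> Read | None:
    """Trim the leftmost 3'-end adapter match; None = discard.

    A match is a start position i where the overlap between the adapter
    prefix and the read suffix is at least ``min_overlap`` bases with at most
    ``max_mismatches`` mismatches. Reads shorter than ``min_keep`` after
    trimming are discarded.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    L = len(read)
    for i in range(0, L - min_overlap + 1):
        overlap = min(len(adapter), L - i)
        if overlap < min_overlap:
            break
        if _hamming(read.bases[i : i + overlap], adapter[:overlap], max_mismatches) <= max_mismatches:
            if i < min_keep:
                return None
            return Read(read.id, read.bases[:i], read.quals[:i])
    return read


def quality_screen(read: Read, cutoff: float = 20.0) -> bool:
    """Keep iff mean Phred >= cutoff (boundary inclusive); empty reads drop."""
    if len(read) == 0:
        return False
    mean_q = np.frombuffer(read.quals.encode(), dtype=np.uint8).mean() - 33.0
    return bool(mean_q >= cutoff)


class BisulfiteIndex:
    """Exact k-mer index over the C->T-collapsed top strand."""

    def __init__(self, reference: Reference, k: int = 12):
        if not reference.contigs:
            raise ValueError("empty reference")
        self.k = k
        self.reference = reference
        self.collapsed = {
            name: seq.translate(_COLLAPSE) for name, seq in reference.contigs.items()
        }
        self._kmers: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, cseq in self.collapsed.items():
            for i in range(len(cseq) - k + 1):
                self._kmers[cseq[i : i + k]].append((name, i))

    def seed_hits(self, seed: str) -> list[tuple[str, int]]:
        """Loci of all exact occurrences of ``seed`` (len >= 1)."""
        if len(seed) >= self.k:
            hits = []
            for contig, pos in self._kmers.get(seed[: self.k], ()):
                if self.collapsed[contig][pos : pos + len(seed)] == seed:
                    hits.append((contig, pos))
            return hits
        hits = []
        for contig, cseq in self.collapsed.items():
            start = 0
            while True:
                p = cseq.find(seed, start)
                if p < 0:
                    break
                hits.append((contig, p))
                start = p + 1
        return hits


def build_index(reference: Reference, k: int = 12) -> BisulfiteIndex:
    return BisulfiteIndex(reference, k=k)


def align_read(
    read: Read, index: BisulfiteIndex, max_mismatches: int = 2
) -> Alignment | str:
    """Align the collapsed read; returns an Alignment or a rejection reason
    in {"unmapped", "ambiguous"}."""
    cread = read.bases.translate(_COLLAPSE)
    L = len(cread)
    if L == 0:
        return "unmapped"
    s = max(1, L // 3)
    offsets = (0, s, 2 * s)
    candidates: set[tuple[str, int]] = set()
    for off in offsets:
        seed = cread[off : off + s]
        if not seed:
            continue
        for contig, hit in index.seed_hits(seed):
            pos = hit - off
            if 0 <= pos <= len(index.collapsed[contig]) - L:
                candidates.add((contig, pos))
    best = max_mismatches + 1
    best_loci: list[tuple[str, int]] = []
    for contig, pos in sorted(candidates):
        d = _hamming(cread, index.collapsed[contig][pos : pos + L], best)
        if d < best:
            best, best_loci = d, [(contig, pos)]
        elif d == best:
            best_loci.append((contig, pos))
    if best > max_mismatches or not best_loci:
        return "unmapped"
    if len(best_loci) > 1:
        return "ambiguous"
    contig, pos = best_loci[0]
    return Alignment(read.id, contig, pos, L, best)


def call_methylation(
    alignments: list[Alignment],
    reads: dict[str, Read],
    reference: Reference,
    unit_id: str,
) -> pd.DataFrame:
    """Pileup over reference top-strand CpGs: C -> methylated, T ->
    unmethylated, anything else ignored. Returns columns contig, pos,
    n_meth, n_unmeth for covered sites only."""
    is_cpg = {c: reference.is_cpg(c) for c in reference.contigs}
    counts: dict[tuple[str, int], list[int]] = defaultdict(lambda: [0, 0])
    for aln in alignments:
        seq_len = len(reference.contigs[aln.contig])
        if aln.start < 0 or aln.start + aln.length > seq_len:
            raise ValueError(f"alignment of {aln.read_id} beyond contig bounds")
        bases = reads[aln.read_id].bases
        mask = is_cpg[aln.contig][aln.start : aln.start + aln.length]
        for off in np.flatnonzero(mask):
            b = bases[off]
            if b == "C":
                counts[(aln.contig, aln.start + int(off))][0] += 1
            elif b == "T":
                counts[(aln.contig, aln.start + int(off))][1] += 1
    rows = [
        (contig, pos, m, u) for (contig, pos), (m, u) in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["contig", "pos", "n_meth", "n_unmeth"])


def process_unit(
    reads,
    index: BisulfiteIndex,
    unit_id: str,
    adapter: str = DEFAULT_ADAPTER,
    quality_cutoff: float = 20.0,
    max_mismatches: int = 2,
    min_overlap: int = 12,
    trim_max_mismatches: int = 2,
    min_keep: int = 22,
) -> tuple[pd.DataFrame, dict]:
    """Full per-unit pipeline: trim -> screen -> align -> call.

    ``reads`` is an iterable of (id, bases, quals). Returns the CpG count
    table plus a summary whose categories partition the input reads
    (reads_in = kept_aligned + trim_discarded + quality_dropped + unmapped +
    ambiguous).
    """
    summary = {
        "unit_id": unit_id,
        "reads_in": 0,
        "trim_discarded": 0,
        "quality_dropped": 0,
        "unmapped": 0,
        "ambiguous": 0,
        "kept_aligned": 0,
    }
    alignments: list[Alignment] = []
    kept_reads: dict[str, Read] = {}
    for rid, bases, quals in reads:
        summary["reads_in"] += 1
        read = trim_adapter(
            Read(rid, bases, quals), adapter, min_overlap, trim_max_mismatches, min_keep
        )
        if read is None:
            summary["trim_discarded"] += 1
            continue
        if not quality_screen(read, quality_cutoff):
            summary["quality_dropped"] += 1
            continue
        result = align_read(read, index, max_mismatches)
        if isinstance(result, str):
            summary[result] += 1
            continue
        summary["kept_aligned"] += 1
        alignments.append(result)
        kept_reads[read.id] = read
    assert summary["reads_in"] == (
        summary["kept_aligned"] + summary["trim_discarded"]
        + summary["quality_dropped"] + summary["unmapped"] + summary["ambiguous"]
    )
    counts = call_methylation(alignments, kept_reads, index.reference, unit_id)
    return counts, summary
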