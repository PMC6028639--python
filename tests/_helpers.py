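"""Shared test utilities: independent oracles and a count-level contrast
runner used by several test modules.

Oracles here deliberately re-derive results from first principles (grid
search, exhaustive enumeration, naive scans) so that agreement with the
package is a two-route check, not a tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from methylrescue.dmr import bh_adjust, fit_logistic_table


def run_count_contrast(meth, unmeth, units_a, units_b):
    """Per-site pooled logistic contrast on count-level matrices.

    Returns a DataFrame with delta_pct, p_value, q_value indexed like meth.
    """
    ma = meth[units_a].sum(axis=1).to_numpy()
    da = (meth[units_a] + unmeth[units_a]).sum(axis=1).to_numpy()
    mb = meth[units_b].sum(axis=1).to_numpy()
    db = (meth[units_b] + unmeth[units_b]).sum(axis=1).to_numpy()
    fits = fit_logistic_table(ma, da, mb, db)
    pct = 100.0 * meth / (meth + unmeth)
    delta = pct[units_b].mean(axis=1) - pct[units_a].mean(axis=1)
    out = pd.DataFrame(index=meth.index)
    out["delta_pct"] = delta.to_numpy()
    out["p_value"] = fits["p_value"].to_numpy()
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def units_in_cell(units, **levels):
    return [
        u.unit_id
        for u in units
        if all(getattr(u, k) == v for k, v in levels.items())
    ]


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def grid_search_logistic(ma, da, mb, db, span=8.0, rounds=4, n_grid=81):
    """Maximise the two-group binomial log-likelihood over (beta0, beta1) by
    iterative grid refinement; returns (beta0, beta1, max loglik)."""

    def loglik(b0, b1):
        pa = 1.0 / (1.0 + math.exp(-b0))
        pb = 1.0 / (1.0 + math.exp(-(b0 + b1)))
        ll = 0.0
        for m, d, p in ((ma, da, pa), (mb, db, pb)):
            p = min(max(p, 1e-12), 1 - 1e-12)
            ll += m * math.log(p) + (d - m) * math.log(1 - p)
        return ll

    c0, c1, width = 0.0, 0.0, span
    best = (c0, c1, loglik(c0, c1))
    for _ in range(rounds):
        for b0 in np.linspace(c0 - width, c0 + width, n_grid):
            for b1 in np.linspace(c1 - width, c1 + width, n_grid):
                ll = loglik(b0, b1)
                if ll > best[2]:
                    best = (b0, b1, ll)
        c0, c1 = best[0], best[1]
        width = width * 2.0 / (n_grid - 1) * 2.0
    return best


def bh_by_formula(p):
    """Direct step-up definition: q_i = min_{j: p_j >= p_i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_idx in range(m):
        i = order[rank_idx]
        q[i] = min(
            p[order[j]] * m / (j + 1) for j in range(rank_idx, m)
        )
        q[i] = min(q[i], 1.0)
    return q


def hypergeom_sf_enumeration(k, N, K, n):
    """P(X >= k) for hypergeometric(N, K, n) by direct summation of the pmf
    written with binomial coefficients."""
    total = 0.0
    denom = math.comb(N, n)
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / denom
    return total


def wilcoxon_enumeration(diffs):
    """Exhaustive 2^n sign enumeration of the Wilcoxon signed-rank null.

    Returns (V, two-sided exact p) with midranks of |d| and zero diffs
    dropped, matching the doubled two-sided convention (capped at 1).
    """
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    absd = np.abs(d)
    # midranks
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    v_obs = ranks[d > 0].sum()
    vs = []
    for signs in itertools.product((0, 1), repeat=n):
        vs.append(sum(r for s, r in zip(signs, ranks) if s))
    vs = np.asarray(vs)
    eps = 1e-9
    lower = np.mean(vs <= v_obs + eps)
    upper = np.mean(vs >= v_obs - eps)
    return float(v_obs), float(min(1.0, 2.0 * min(lower, upper)))


def ks_statistic_enumeration(x, y):
    """D = sup_t |ECDF_x(t) - ECDF_y(t)| evaluated over all data points."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        best = max(best, abs(fx - fy))
    return best


def naive_pileup(alignments, reads, reference):
    """Dictionary-based per-position pileup over reference CpGs."""
    counts = {}
    for aln in alignments:
        seq = reference.contigs[aln.contig]
        bases = reads[aln.read_id].bases
        for off in range(aln.length):
            pos = aln.start + off
            if seq[pos] == "C" and pos + 1 < len(seq) and seq[pos + 1] == "G":
                b = bases[off]
                if b in "CT":
                    key = (aln.contig, pos)
                    m, u = counts.get(key, (0, 0))
                    counts[key] = (m + 1, u) if b == "C" else (m, u + 1)
    return counts


def brute_force_align(cread, collapsed_contigs, max_mismatches=2):
    """All-loci scan: best Hamming alignment of a collapsed read; returns
    ('unmapped'|'ambiguous'|(contig, pos, mismatches))."""
    L = len(cread)
    best = max_mismatches + 1
    loci = []
    for contig, cseq in collapsed_contigs.items():
        for pos in range(len(cseq) - L + 1):
            d = sum(a != b for a, b in zip(cread, cseq[pos : pos + L]))
            if d < best:
                best, loci = d, [(contig, pos)]
            elif d == best:
                loci.append((contig, pos))
    if best > max_mismatches or not loci:
        return "unmapped"
    if len(loci) > 1:
        return "ambiguous"
    return (loci[0][0], loci[0][1], best)


def brute_force_trim(bases, adapter, min_overlap=12, max_mismatches=2,
                     min_keep=22):
    """Independent restatement of the adapter rule: leftmost i with >=
    min_overlap bases of adapter prefix matching within max_mismatches.
    Returns kept length, or None for discard, or len(bases) if untouched."""
    L = len(bases)
    for i in range(L):
        overlap = min(len(adapter), L - i)
        if overlap < min_overlap:
            break
        mism = sum(a != b for a, b in zip(bases[i : i + overlap], adapter[:overlap]))
        if mism <= max_mismatches:
            return None if i < min_keep else i
    return L
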