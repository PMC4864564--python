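"""Independent brute-force oracles used to validate the fast paths.

Everything here works per nucleotide, with its own independent coding of
the binning rule, and never calls the interval-tree / cumulative-offset
implementations it is used to check.
"""

from __future__ import annotations

import math
from fractions import Fraction


def mature_order(tx) -> list[int]:
    """Genomic positions of the mature transcript in 5'->3' order,
    enumerated exon by exon."""
    pos = []
    for e in tx.exons:
        pos.extend(range(e.start, e.end))
    if tx.strand == "-":
        pos.reverse()
    return pos


def component_of_index(tx) -> list[str]:
    """Component label of every mature index, from the CDS genomic span."""
    order = mature_order(tx)
    if tx.cds_span is None:
        return ["whole"] * len(order)
    gs, ge = tx.cds_span
    cds_idx = [i for i, g in enumerate(order) if gs <= g < ge]
    first, last = cds_idx[0], cds_idx[-1]
    return [
        "utr5" if i < first else ("cds" if i <= last else "utr3")
        for i in range(len(order))
    ]


def bin_of_index(j: int, L: int, B: int) -> int:
    """Bin of mature index j within a component of length L cut into B
    near-equal bins, the first L % B bins one nt wider."""
    base, rem = divmod(L, B)
    if j < rem * (base + 1):
        return j // (base + 1)
    return rem + (j - rem * (base + 1)) // base


def per_nt_bin_map(tx, B: int) -> dict[int, tuple[str, int]]:
    """genomic position -> (component, bin_index) for one transcript."""
    order = mature_order(tx)
    comps = component_of_index(tx)
    # component lengths and the offset of each component's first index
    lengths: dict[str, int] = {}
    starts: dict[str, int] = {}
    for i, c in enumerate(comps):
        if c not in starts:
            starts[c] = i
        lengths[c] = lengths.get(c, 0) + 1
    mapping = {}
    for i, (g, c) in enumerate(zip(order, comps)):
        mapping[g] = (c, bin_of_index(i - starts[c], lengths[c], B))
    return mapping


def strands_compatible(f_strand: str, t_strand: str, same_strand: bool) -> bool:
    return not same_strand or f_strand == "." or f_strand == t_strand


def oracle_assign(features, transcripts, B: int, same_strand: bool = True):
    """Reference assignment: set of (feature_id, tx_id, component,
    bin_index, weight) tuples computed nucleotide by nucleotide."""
    maps = {t.tx_id: per_nt_bin_map(t, B) for t in transcripts}
    out = set()
    for f in features:
        iv = f.interval
        nts = range(iv.start, iv.end)
        overlapping = [
            t for t in transcripts
            if t.chrom == iv.chrom
            and strands_compatible(iv.strand, t.strand, same_strand)
            and any(g in maps[t.tx_id] for g in nts)
        ]
        n = len(overlapping)
        if n == 0:
            continue
        for t in overlapping:
            hit = {maps[t.tx_id][g] for g in nts if g in maps[t.tx_id]}
            for comp, idx in hit:
                out.add((f.id, t.tx_id, comp, idx, 1.0 / n))
    return out


def binom_upper_tail(m: int, n: int, p: Fraction) -> Fraction:
    """P(X >= m) by exact PMF summation."""
    return sum(
        (Fraction(math.comb(n, k)) * p**k * (1 - p) ** (n - k)
         for k in range(m, n + 1)),
        Fraction(0),
    )


def binom_lower_tail(m: int, n: int, p: Fraction) -> Fraction:
    """P(X <= m) by exact PMF summation."""
    return sum(
        (Fraction(math.comb(n, k)) * p**k * (1 - p) ** (n - k)
         for k in range(0, m + 1)),
        Fraction(0),
    )


def oracle_classify(m: int, n: int, p: Fraction, alpha: Fraction) -> str:
    if binom_upper_tail(m, n, p) < alpha:
        return "high"
    if binom_lower_tail(m, n, p) < alpha:
        return "low"
    return "undetermined"
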