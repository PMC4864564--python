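"""Overlap features with guitar bins and allocate isoform-ambiguity weights.

A genomic feature that overlaps ``n`` retained transcripts is associated
with each of them with weight 1/n; a feature fully specific to one
transcript carries weight 1. Within a transcript, every bin whose genomic
footprint shares at least one nucleotide with the feature records a hit
(an indicator, not fractional coverage): because bins within a component
have equal width, the number of bins hit is proportional to the feature's
extent in each component, so a feature lying 70% on the 5'UTR and 30% on
the CDS splits its hits 70/30 between the two components' bins.

When flanking DNA bins are present they take part exactly like transcript
bins; ``n`` is then the number of retained transcripts with at least one
bin (flank or mature) hit, which coincides with exonic-footprint counting
whenever flanks are disabled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation import GenomicInterval, Transcript, TranscriptomeAnnotation
from .coordinates import GuitarCoordinateSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Feature:
    """A genomic feature (modification site, peak) with an optional group
    label used to stratify profiles."""

    id: str
    interval: GenomicInterval
    group: Optional[str] = None


@dataclass(frozen=True)
class OverlapRecord:
    feature_id: str
    tx_id: str
    component: str
    bin_index: int
    weight: float


def read_bed(path: str, group: Optional[str] = None) -> list[Feature]:
    """Read features from BED3/BED6 (0-based half-open; strand from column
    6 when present, else '.')."""
    feats = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i + 1}: BED line has <3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] else f"feat{i}"
            strand = parts[5] if len(parts) > 5 else "."
            feats.append(
                Feature(name, GenomicInterval(chrom, start, end, strand), group)
            )
    return feats


def _strand_match(feature_strand: str, tx_strand: str, same_strand: bool) -> bool:
    if not same_strand or feature_strand == ".":
        return True
    return feature_strand == tx_strand


def overlapping_transcripts(
    feature: Feature,
    annotation: TranscriptomeAnnotation,
    same_strand: bool = True,
) -> set[str]:
    """Retained transcripts sharing >= 1 exonic nt with the feature."""
    iv = feature.interval
    hits = set()
    for tx in annotation:
        if tx.chrom != iv.chrom:
            continue
        if not _strand_match(iv.strand, tx.strand, same_strand):
            continue
        if any(e.start < iv.end and iv.start < e.end for e in tx.exons):
            hits.add(tx.tx_id)
    return hits


def _bin_tree(guitar_set: GuitarCoordinateSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, b in enumerate(guitar_set.bins):
        for iv in b.genomic_footprint:
            trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, (idx, iv.strand)
            )
    return trees


def assign(
    features: Sequence[Feature],
    guitar_set: GuitarCoordinateSet,
    annotation: TranscriptomeAnnotation,
    same_strand: bool = True,
) -> list[OverlapRecord]:
    """Produce one :class:`OverlapRecord` per (feature, transcript, bin) hit
    with weight 1/n, n = number of retained transcripts the feature is
    associated with. Features associated with no transcript yield nothing.
    """
    trees = _bin_tree(guitar_set)
    records: list[OverlapRecord] = []
    bins = guitar_set.bins
    for f in features:
        iv = f.interval
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hit_bins: set[int] = set()
        for hit in tree.overlap(iv.start, iv.end):
            idx, strand = hit.data
            if _strand_match(iv.strand, strand, same_strand):
                hit_bins.add(idx)
        if not hit_bins:
            continue
        n = len({bins[i].tx_id for i in hit_bins})
        w = 1.0 / n
        for i in sorted(hit_bins):
            b = bins[i]
            records.append(
                OverlapRecord(f.id, b.tx_id, b.component, b.bin_index, w)
            )
    logger.info(
        "assignment: %d features -> %d overlap records", len(features),
        len(records),
    )
    return records


def bin_weight_vector(
    records: Sequence[OverlapRecord],
    guitar_set: GuitarCoordinateSet,
    feature_groups: Optional[dict[str, Optional[str]]] = None,
) -> dict[tuple[str, Optional[str]], pd.Series]:
    """Sum record weights onto the shared standardized-axis grid.

    Returns a mapping (biotype, group) -> Series indexed by
    (component, bin_index). mRNA and lncRNA are always separate groups; no
    cross-biotype normalization is meaningful downstream.
    """
    feature_groups = feature_groups or {}
    out: dict[tuple[str, Optional[str]], dict] = {}
    for r in records:
        biotype = guitar_set.biotype_of[r.tx_id]
        group = feature_groups.get(r.feature_id)
        cells = out.setdefault((biotype, group), {})
        key = (r.component, r.bin_index)
        cells[key] = cells.get(key, 0.0) + r.weight
    result = {}
    for gkey, cells in out.items():
        biotype = gkey[0]
        grid = guitar_set.axis_cells(biotype)
        idx = pd.MultiIndex.from_frame(grid[["component", "bin_index"]])
        s = pd.Series(0.0, index=idx)
        for key, w in cells.items():
            s.loc[key] = w
        result[gkey] = s
    return result


def records_to_tsv(records: Sequence[OverlapRecord], path: str) -> None:
    """Export raw overlap records (the intermediate-result hook for custom
    downstream graphics)."""
    pd.DataFrame(
        [
            (r.feature_id, r.tx_id, r.component, r.bin_index, r.weight)
            for r in records
        ],
        columns=["feature_id", "tx_id", "component", "bin_index", "weight"],
    ).to_csv(path, sep="\t", index=False)
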