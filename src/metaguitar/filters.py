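"""Transcript and feature filters applied before coordinate building.

Three filters, run as a fixed pipeline:

1. length filter -- every non-empty mRNA component (or the whole lncRNA)
   must be at least a user threshold long, and at least ``B`` nt so that
   ``B`` bins are feasible;
2. isoform-ambiguity filter -- transcripts whose exonic footprint overlaps
   more than ``max_tx_overlap`` other transcripts are discarded (overlap
   counts are computed once, before any removal, so the outcome does not
   depend on removal order);
3. feature-ambiguity filter -- optional removal of features overlapping
   more than ``max_feature_tx`` retained transcripts.

By default transcripts only count as overlapping when on the same strand
(antisense transcripts are distinct RNAs); set ``same_strand=False`` to
count across strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation import MRNA, TranscriptomeAnnotation, derive_components

if TYPE_CHECKING:  # pragma: no cover
    from .assignment import Feature

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    min_component_length: int = 100
    min_lncrna_length: int = 300
    max_tx_overlap: int = 3
    max_feature_tx: int = 5
    same_strand: bool = True

    def __post_init__(self):
        for name in ("min_component_length", "min_lncrna_length",
                     "max_tx_overlap", "max_feature_tx"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _exon_trees(
    annotation: TranscriptomeAnnotation, same_strand: bool
) -> dict:
    """IntervalTree of exons per chromosome (or per chromosome+strand)."""
    trees: dict = {}
    for tx in annotation:
        key = (tx.chrom, tx.strand) if same_strand else tx.chrom
        tree = trees.setdefault(key, IntervalTree())
        for e in tx.exons:
            tree.addi(e.start, e.end, tx.tx_id)
    return trees


def length_filter(
    annotation: TranscriptomeAnnotation,
    cfg: FilterConfig,
    B: int = 100,
) -> TranscriptomeAnnotation:
    """Retain transcripts whose components are long enough to profile."""
    keep = []
    for tx in annotation:
        cm = derive_components(tx)
        if cm.biotype == MRNA:
            floor = max(cfg.min_component_length, B)
        else:
            floor = max(cfg.min_lncrna_length, B)
        if all(cm.component_length(c) >= floor for c in cm.components):
            keep.append(tx.tx_id)
    return annotation.subset(keep)


def count_exonic_overlaps(
    annotation: TranscriptomeAnnotation, same_strand: bool = True
) -> dict[str, int]:
    """Number of *other* transcripts sharing >= 1 exonic nt with each
    transcript. Symmetric by construction."""
    trees = _exon_trees(annotation, same_strand)
    partners: dict[str, set[str]] = {tx.tx_id: set() for tx in annotation}
    for tx in annotation:
        key = (tx.chrom, tx.strand) if same_strand else tx.chrom
        tree = trees[key]
        for e in tx.exons:
            for hit in tree.overlap(e.start, e.end):
                if hit.data != tx.tx_id:
                    partners[tx.tx_id].add(hit.data)
    return {tid: len(p) for tid, p in partners.items()}


def ambiguity_filter(
    annotation: TranscriptomeAnnotation,
    cfg: FilterConfig,
    counts: dict[str, int] | None = None,
) -> TranscriptomeAnnotation:
    """Drop transcripts overlapping more than ``max_tx_overlap`` others.

    ``counts`` may be supplied (e.g. computed before the length filter);
    otherwise they are computed on ``annotation`` as given.
    """
    if counts is None:
        counts = count_exonic_overlaps(annotation, cfg.same_strand)
    keep = [t.tx_id for t in annotation
            if counts.get(t.tx_id, 0) <= cfg.max_tx_overlap]
    return annotation.subset(keep)


def feature_ambiguity_filter(
    features: Sequence["Feature"],
    annotation: TranscriptomeAnnotation,
    cfg: FilterConfig,
) -> list["Feature"]:
    """Drop features overlapping the exonic footprint of more than
    ``max_feature_tx`` retained transcripts. Features touching no transcript
    are kept (they simply contribute nothing downstream)."""
    trees = _exon_trees(annotation, cfg.same_strand)
    kept = []
    for f in features:
        iv = f.interval
        if cfg.same_strand and iv.strand in ("+", "-"):
            keys = [(iv.chrom, iv.strand)]
        elif cfg.same_strand:
            keys = [(iv.chrom, "+"), (iv.chrom, "-")]
        else:
            keys = [iv.chrom]
        tx_hit: set[str] = set()
        for key in keys:
            if key in trees:
                tx_hit |= {h.data for h in trees[key].overlap(iv.start, iv.end)}
        if len(tx_hit) <= cfg.max_feature_tx:
            kept.append(f)
    return kept


def apply_filters(
    annotation: TranscriptomeAnnotation,
    cfg: FilterConfig,
    B: int = 100,
    count_before_length_filter: bool = False,
) -> tuple[TranscriptomeAnnotation, pd.DataFrame]:
    """Run length then ambiguity filter and assemble a per-transcript
    report (mature length, component lengths, overlap count, retained flag,
    removal reason)."""
    counts_input = (
        count_exonic_overlaps(annotation, cfg.same_strand)
        if count_before_length_filter else None
    )
    after_len = length_filter(annotation, cfg, B)
    counts = counts_input or count_exonic_overlaps(after_len, cfg.same_strand)
    retained = ambiguity_filter(after_len, cfg, counts)

    rows = []
    for tx in annotation:
        cm = derive_components(tx)
        in_len = tx.tx_id in after_len
        in_final = tx.tx_id in retained
        reason = ""
        if not in_len:
            reason = "length"
        elif not in_final:
            reason = "ambiguity"
        rows.append(
            {
                "tx_id": tx.tx_id,
                "biotype": cm.biotype,
                "mature_length": tx.mature_length,
                "utr5": cm.component_length("utr5"),
                "cds": cm.component_length("cds"),
                "utr3": cm.component_length("utr3"),
                "overlap_count": counts.get(tx.tx_id, pd.NA),
                "retained": in_final,
                "removal_reason": reason,
            }
        )
    report = pd.DataFrame(rows)
    logger.info(
        "filters: %d transcripts in, %d after length filter, %d retained",
        len(annotation), len(after_len), len(retained),
    )
    return retained, report
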