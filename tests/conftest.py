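from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metaguitar.annotation import (
    GenomicInterval,
    Transcript,
    TranscriptomeAnnotation,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_transcript(
    rng: np.random.Generator,
    tx_id: str = "t0",
    chrom: str = "chr1",
    strand: str | None = None,
    min_component: int = 10,
    coding: bool | None = None,
) -> Transcript:
    """A random multi-exon transcript whose non-empty components are all at
    least ``min_component`` nt, suitable for binning with B <= that."""
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    if coding is None:
        coding = rng.random() < 0.7
    if coding:
        comp_lens = [int(rng.integers(min_component, 4 * min_component))
                     for _ in range(3)]
        mature = sum(comp_lens)
    else:
        mature = int(rng.integers(min_component, 12 * min_component))
    n_introns = int(rng.integers(0, 4))
    n_introns = min(n_introns, mature - 1)
    cuts = sorted(
        int(c)
        for c in rng.choice(np.arange(1, mature), n_introns, replace=False)
    ) if n_introns else []
    bounds = [0] + cuts + [mature]
    start = int(rng.integers(100, 2000))
    exons, pos = [], start
    for a, b in zip(bounds, bounds[1:]):
        exons.append(GenomicInterval(chrom, pos, pos + (b - a), strand))
        pos += (b - a) + int(rng.integers(20, 200))
    cds_span = None
    if coding:
        tmp = Transcript(tx_id, "g", tuple(exons))
        pieces = tmp.transcript_to_genomic(
            comp_lens[0], comp_lens[0] + comp_lens[1]
        )
        cds_span = (pieces[0].start, pieces[-1].end)
    return Transcript(tx_id, "g", tuple(exons), cds_span)


def mirror_transcript(tx: Transcript, M: int = 10**7) -> Transcript:
    """Reflect a transcript through genomic coordinate M and flip strand;
    transcript-coordinate quantities must be unchanged."""
    exons = tuple(
        sorted(
            (GenomicInterval(e.chrom, M - e.end, M - e.start,
                             "-" if e.strand == "+" else "+")
             for e in tx.exons),
            key=lambda iv: iv.start,
        )
    )
    cds = None
    if tx.cds_span is not None:
        cs, ce = tx.cds_span
        cds = (M - ce, M - cs)
    return Transcript(tx.tx_id, tx.gene_id, exons, cds)


@pytest.fixture
def two_exon_plus() -> Transcript:
    """Exons [100,200)+[300,400) on +, CDS genomic [150,350): the standard
    worked example (mature 200 nt, components 50/100/50)."""
    return Transcript(
        "tx1", "g1",
        (GenomicInterval("chr1", 100, 200, "+"),
         GenomicInterval("chr1", 300, 400, "+")),
        (150, 350),
    )


@pytest.fixture
def equal_component_mrna() -> Transcript:
    """Single-exon mRNA with 5'UTR = CDS = 3'UTR = 300 nt starting at
    genomic 1000 on +."""
    return Transcript(
        "eq", "geq", (GenomicInterval("chr1", 1000, 1900, "+"),),
        (1300, 1600),
    )


def single_annotation(tx: Transcript) -> TranscriptomeAnnotation:
    return TranscriptomeAnnotation([tx])
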