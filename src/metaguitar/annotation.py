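"""Transcript models and genomic <-> transcript coordinate arithmetic.

A transcript is an ordered set of exons on one chromosome and strand,
optionally with a CDS span. All coordinates are held internally as 0-based
half-open intervals; GTF input (1-based closed) is converted on read.
Positions on the *mature* (spliced) transcript count nucleotides from the
transcription start site in 5'->3' reading order, so on the minus strand
transcript position 0 is the genomically rightmost exonic nucleotide.

An mRNA decomposes into three components -- 5'UTR, CDS, 3'UTR -- delimited
by the start and stop codons; a transcript without annotated CDS is treated
as lncRNA, a single-component transcript. The CDS span is taken exactly as
annotated (no stop-codon adjustment); users whose annotation excludes the
stop codon from the CDS should pre-adjust if that distinction matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterator, Optional

from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

MRNA = "mRNA"
LNCRNA = "lncRNA"

#: component labels in 5'->3' transcript order
MRNA_COMPONENTS = ("utr5", "cds", "utr3")
LNCRNA_COMPONENTS = ("whole",)


class AnnotationError(ValueError):
    """Invalid transcript structure (e.g. CDS not covered by exons)."""


class ParseError(AnnotationError):
    """Malformed annotation file; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Strand-aware half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Transcript:
    """One isoform: ordered exons plus an optional genomic CDS span.

    ``cds_span`` is the 0-based half-open genomic interval from the first to
    the last CDS nucleotide (strand-independent ordering). Biotype is
    derived: mRNA iff a CDS is present.
    """

    tx_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    cds_span: Optional[tuple[int, int]] = None

    def __post_init__(self):
        if not self.exons:
            raise AnnotationError(f"{self.tx_id}: transcript has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"{self.tx_id}: exons on multiple chromosomes/strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise AnnotationError(
                    f"{self.tx_id}: exons overlap or are unsorted"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def biotype(self) -> str:
        return MRNA if self.cds_span is not None else LNCRNA

    @cached_property
    def mature_length(self) -> int:
        return sum(e.width for e in self.exons)

    @cached_property
    def _exons_5to3(self) -> tuple[GenomicInterval, ...]:
        """Exons in transcript (5'->3') order."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    @cached_property
    def _offsets_5to3(self) -> tuple[int, ...]:
        """Cumulative mature offset at the start of each 5'->3' exon."""
        offs, acc = [], 0
        for e in self._exons_5to3:
            offs.append(acc)
            acc += e.width
        return tuple(offs)

    @property
    def tss(self) -> int:
        """Genomic position of the transcription start (first mature nt)."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end - 1

    @property
    def tes(self) -> int:
        """Genomic position of the transcription end (last mature nt)."""
        return self.exons[-1].end - 1 if self.strand == "+" else self.exons[0].start

    # -- coordinate conversion -------------------------------------------

    def genomic_to_transcript(self, g: int) -> Optional[int]:
        """Mature-transcript offset of genomic position ``g``, or None.

        Intronic and intergenic positions map to None; they are absent from
        the mature RNA.
        """
        for off, e in zip(self._offsets_5to3, self._exons_5to3):
            if e.start <= g < e.end:
                if self.strand == "+":
                    return off + (g - e.start)
                return off + (e.end - 1 - g)
        return None

    def transcript_to_genomic(self, a: int, b: int) -> list[GenomicInterval]:
        """Genomic footprint of the mature span [a, b).

        Returns a minimal list of intervals in genomic order whose total
        width is ``b - a``; more than one interval exactly when the span
        crosses an intron.
        """
        if not (0 <= a < b <= self.mature_length):
            raise AnnotationError(
                f"{self.tx_id}: span [{a},{b}) outside mature "
                f"[0,{self.mature_length})"
            )
        pieces = []
        for off, e in zip(self._offsets_5to3, self._exons_5to3):
            lo, hi = max(a, off), min(b, off + e.width)
            if lo >= hi:
                continue
            if self.strand == "+":
                pieces.append(
                    GenomicInterval(self.chrom, e.start + (lo - off),
                                    e.start + (hi - off), self.strand)
                )
            else:
                pieces.append(
                    GenomicInterval(self.chrom, e.end - (hi - off),
                                    e.end - (lo - off), self.strand)
                )
        pieces.sort(key=lambda iv: iv.start)
        return pieces


@dataclass(frozen=True)
class ComponentMap:
    """Mature-coordinate spans and genomic footprints of a transcript's
    components (utr5/cds/utr3 for mRNA, whole for lncRNA).

    ``spans`` maps component label -> half-open mature span (a, b); empty
    components (e.g. an mRNA with no 5'UTR) are absent. The spans present
    partition [0, mature_length) in 5'->3' order.
    """

    tx_id: str
    biotype: str
    spans: dict[str, tuple[int, int]]
    footprints: dict[str, tuple[GenomicInterval, ...]] = field(default_factory=dict)

    def component_length(self, comp: str) -> int:
        if comp not in self.spans:
            return 0
        a, b = self.spans[comp]
        return b - a

    @property
    def components(self) -> tuple[str, ...]:
        order = MRNA_COMPONENTS if self.biotype == MRNA else LNCRNA_COMPONENTS
        return tuple(c for c in order if c in self.spans)


def derive_components(tx: Transcript) -> ComponentMap:
    """Split a transcript into its mature components.

    For mRNA the 5'UTR is everything strictly 5' of the first CDS
    nucleotide and the 3'UTR everything strictly 3' of the last; either may
    be empty. A lncRNA is one component covering the whole mature length.
    """
    L = tx.mature_length
    if tx.cds_span is None:
        spans = {"whole": (0, L)}
    else:
        gs, ge = tx.cds_span
        first_nt = gs if tx.strand == "+" else ge - 1
        last_nt = ge - 1 if tx.strand == "+" else gs
        t_first = tx.genomic_to_transcript(first_nt)
        t_last = tx.genomic_to_transcript(last_nt)
        if t_first is None or t_last is None:
            raise AnnotationError(
                f"{tx.tx_id}: CDS span not covered by exons"
            )
        spans = {}
        if t_first > 0:
            spans["utr5"] = (0, t_first)
        spans["cds"] = (t_first, t_last + 1)
        if t_last + 1 < L:
            spans["utr3"] = (t_last + 1, L)
    footprints = {
        c: tuple(tx.transcript_to_genomic(a, b)) for c, (a, b) in spans.items()
    }
    return ComponentMap(tx.tx_id, tx.biotype, spans, footprints)


class TranscriptomeAnnotation:
    """An ordered collection of transcripts keyed by tx_id."""

    def __init__(self, transcripts: list[Transcript] | dict[str, Transcript]):
        if isinstance(transcripts, dict):
            self._tx = dict(transcripts)
        else:
            self._tx = {t.tx_id: t for t in transcripts}

    def __len__(self) -> int:
        return len(self._tx)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self._tx.values())

    def __contains__(self, tx_id: str) -> bool:
        return tx_id in self._tx

    def __getitem__(self, tx_id: str) -> Transcript:
        return self._tx[tx_id]

    @property
    def tx_ids(self) -> list[str]:
        return list(self._tx)

    def subset(self, tx_ids) -> "TranscriptomeAnnotation":
        keep = set(tx_ids)
        return TranscriptomeAnnotation(
            {k: v for k, v in self._tx.items() if k in keep}
        )

    def component_maps(self) -> dict[str, ComponentMap]:
        return {t.tx_id: derive_components(t) for t in self}


def _merge_book_ended(
    intervals: list[GenomicInterval],
) -> tuple[GenomicInterval, ...]:
    """Sort and merge intervals that touch or overlap."""
    ivs = sorted(intervals, key=lambda iv: iv.start)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and iv.start <= merged[-1].end:
            last = merged[-1]
            merged[-1] = GenomicInterval(
                last.chrom, last.start, max(last.end, iv.end), last.strand
            )
        else:
            merged.append(iv)
    return tuple(merged)


def parse_annotation(path: str) -> TranscriptomeAnnotation:
    """Read a GTF file into a :class:`TranscriptomeAnnotation`.

    Exon records are required per transcript; CDS records are optional and
    determine the biotype. 1-based closed GTF coordinates are converted to
    the internal 0-based half-open convention. Transcripts whose exons fall
    on multiple chromosomes or strands, or with undefined strand ".", are
    skipped with a warning.

    Raises :class:`ParseError` (carrying the line number) for malformed
    lines.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # noqa: BLE001 - rewrap with location
                raise ParseError(f"cannot parse GTF record ({exc})", lineno) from exc
            if feat.featuretype not in ("exon", "CDS"):
                continue
            if feat.start > feat.end:
                raise ParseError(
                    f"start {feat.start} > end {feat.end}", lineno
                )
            try:
                tx_id = feat.attributes["transcript_id"][0]
                gene_id = feat.attributes["gene_id"][0]
            except (KeyError, IndexError) as exc:
                raise ParseError(
                    "missing transcript_id/gene_id attribute", lineno
                ) from exc
            iv = GenomicInterval(
                feat.seqid, feat.start - 1, feat.end, feat.strand
            )
            gene_of[tx_id] = gene_id
            (exons if feat.featuretype == "exon" else cds).setdefault(
                tx_id, []
            ).append(iv)

    transcripts: dict[str, Transcript] = {}
    for tx_id, exon_list in exons.items():
        chroms = {e.chrom for e in exon_list}
        strands = {e.strand for e in exon_list}
        if len(chroms) > 1 or len(strands) > 1:
            logger.warning(
                "skipping %s: exons on multiple chromosomes/strands", tx_id
            )
            continue
        if exon_list[0].strand == ".":
            logger.warning("skipping %s: strand undefined", tx_id)
            continue
        merged = _merge_book_ended(exon_list)
        cds_span = None
        if tx_id in cds:
            cds_span = (
                min(c.start for c in cds[tx_id]),
                max(c.end for c in cds[tx_id]),
            )
        transcripts[tx_id] = Transcript(
            tx_id=tx_id,
            gene_id=gene_of[tx_id],
            exons=merged,
            cds_span=cds_span,
        )
    for tx_id in cds:
        if tx_id not in exons:
            logger.warning("%s has CDS records but no exons; skipped", tx_id)
    return TranscriptomeAnnotation(transcripts)


# module-level functional aliases mirroring the operation names
def genomic_to_transcript(tx: Transcript, g: int) -> Optional[int]:
    return tx.genomic_to_transcript(g)


def transcript_to_genomic(tx: Transcript, a: int, b: int) -> list[GenomicInterval]:
    return tx.transcript_to_genomic(a, b)
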