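"""Guitar coordinates: standardized transcript bins projected to the genome.

Every non-empty component of a retained transcript is cut into ``B`` bins of
(near-)equal mature width, and each bin's genomic footprint is obtained by
inverting the splicing map -- a bin that crosses an intron owns several
genomic intervals. Overlaying the bins of all transcripts of a biotype on a
common standardized axis (each mRNA component a fixed sub-interval; the
whole lncRNA the unit interval) is what makes features on transcripts of
very different lengths comparable.

Flanking DNA (promoter upstream of the TSS, the complementary tail
downstream of the TES) can be added as extra bins on axis extensions; those
are plain genomic windows with no intron logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .annotation import (
    LNCRNA,
    MRNA,
    MRNA_COMPONENTS,
    ComponentMap,
    GenomicInterval,
    Transcript,
    TranscriptomeAnnotation,
    derive_components,
)

logger = logging.getLogger(__name__)

DEFAULT_BINS = 100
DEFAULT_FLANK_WIDTH = 1000
#: axis width of each flank relative to the [0, 1] transcript axis
DEFAULT_FLANK_AXIS_WIDTH = 1.0 / 3.0

FLANK_COMPONENTS = ("promoter", "tail")


@dataclass(frozen=True)
class GuitarBin:
    """One standardized-coordinate bin and its genomic footprint."""

    tx_id: str
    component: str  # promoter | utr5 | cds | utr3 | whole | tail
    bin_index: int
    std_pos: float
    mature_span: Optional[tuple[int, int]]  # None for flank bins
    genomic_footprint: tuple[GenomicInterval, ...]

    @property
    def genomic_width(self) -> int:
        return sum(iv.width for iv in self.genomic_footprint)


def axis_layout(
    mode: str = "equal",
    mean_lengths: Optional[dict[str, float]] = None,
) -> dict[str, tuple[float, float]]:
    """Per-component (offset, width) on the [0, 1] mRNA axis.

    ``equal`` gives each of 5'UTR/CDS/3'UTR one third of the axis;
    ``true_width`` sizes them proportionally to their mean mature lengths
    over the retained transcripts, so the plot reflects real geometry at the
    cost of squeezing short components.
    """
    if mode == "equal":
        return {
            c: (i / 3.0, 1.0 / 3.0) for i, c in enumerate(MRNA_COMPONENTS)
        }
    if mode != "true_width":
        raise ValueError(f"unknown layout mode {mode!r}")
    if mean_lengths is None:
        raise ValueError("true_width layout requires mean component lengths")
    total = sum(mean_lengths.get(c, 0.0) for c in MRNA_COMPONENTS)
    if total <= 0:
        raise ValueError("true_width layout: all mean lengths are zero")
    layout, offset = {}, 0.0
    for c in MRNA_COMPONENTS:
        w = mean_lengths.get(c, 0.0) / total
        layout[c] = (offset, w)
        offset += w
    return layout


LNCRNA_LAYOUT: dict[str, tuple[float, float]] = {"whole": (0.0, 1.0)}


def _bin_edges(length: int, nbins: int) -> list[int]:
    """Edges of ``nbins`` near-equal bins tiling [0, length); the remainder
    nucleotides are front-loaded so the first ``length % nbins`` bins are one
    nt wider."""
    base, rem = divmod(length, nbins)
    edges, pos = [0], 0
    for i in range(nbins):
        pos += base + (1 if i < rem else 0)
        edges.append(pos)
    return edges


def build_bins(
    tx: Transcript,
    cmap: ComponentMap,
    B: int = DEFAULT_BINS,
    layout: Optional[dict[str, tuple[float, float]]] = None,
) -> list[GuitarBin]:
    """Cut every non-empty component of ``tx`` into ``B`` bins.

    Bin widths within a component differ by at most one nucleotide and the
    bins tile the component's mature span exactly. ``std_pos`` is the bin
    center on the standardized axis under ``layout``.
    """
    if layout is None:
        layout = axis_layout("equal") if cmap.biotype == MRNA else LNCRNA_LAYOUT
    bins: list[GuitarBin] = []
    for comp in cmap.components:
        a, b = cmap.spans[comp]
        L = b - a
        if L < B:
            raise ValueError(
                f"{tx.tx_id}/{comp}: component length {L} < {B} bins; "
                "apply the length filter before building coordinates"
            )
        offset, width = layout[comp]
        edges = _bin_edges(L, B)
        for i in range(B):
            lo, hi = a + edges[i], a + edges[i + 1]
            bins.append(
                GuitarBin(
                    tx_id=tx.tx_id,
                    component=comp,
                    bin_index=i,
                    std_pos=offset + (i + 0.5) / B * width,
                    mature_span=(lo, hi),
                    genomic_footprint=tuple(tx.transcript_to_genomic(lo, hi)),
                )
            )
    return bins


def add_flanks(
    tx: Transcript,
    F: int = DEFAULT_FLANK_WIDTH,
    Bf: int = DEFAULT_BINS,
    flank_axis_width: float = DEFAULT_FLANK_AXIS_WIDTH,
    axis_max: float = 1.0,
) -> list[GuitarBin]:
    """Promoter and tail bins covering the ``F`` genomic nt flanking the
    transcript, strand-aware (the promoter is 5' of the TSS in reading
    direction). Flanks extending below genomic position 0 are truncated with
    a warning; bins left empty by truncation are dropped.
    """
    if F <= 0 or Bf < 1:
        raise ValueError("flank width must be > 0 and flank bin count >= 1")
    first = tx.exons[0].start
    last = tx.exons[-1].end
    if tx.strand == "+":
        promoter = (first - F, first)
        tail = (last, last + F)
    else:
        promoter = (last, last + F)
        tail = (first - F, first)

    bins: list[GuitarBin] = []
    for comp, (lo, hi) in (("promoter", promoter), ("tail", tail)):
        if lo < 0:
            logger.warning(
                "%s: %s flank truncated at chromosome start", tx.tx_id, comp
            )
            lo = 0
        span = hi - lo
        if span <= 0:
            continue
        edges = _bin_edges(span, Bf)
        # axis: promoter on [-w, 0), tail on (axis_max, axis_max + w]
        for i in range(Bf):
            if edges[i] == edges[i + 1]:
                continue
            # genomic order of bins follows reading direction
            if tx.strand == "+":
                g_lo, g_hi = lo + edges[i], lo + edges[i + 1]
            else:
                g_lo, g_hi = hi - edges[i + 1], hi - edges[i]
            center = (i + 0.5) / Bf * flank_axis_width
            std = (-flank_axis_width + center if comp == "promoter"
                   else axis_max + center)
            bins.append(
                GuitarBin(
                    tx_id=tx.tx_id,
                    component=comp,
                    bin_index=i,
                    std_pos=std,
                    mature_span=None,
                    genomic_footprint=(
                        GenomicInterval(tx.chrom, g_lo, g_hi, tx.strand),
                    ),
                )
            )
    return bins


@dataclass
class GuitarCoordinateSet:
    """All guitar bins of the retained transcripts plus the axis geometry."""

    bins: list[GuitarBin]
    B: int
    flank: int
    flank_bins: int
    layout_mode: str
    mrna_layout: dict[str, tuple[float, float]]
    flank_axis_width: float = DEFAULT_FLANK_AXIS_WIDTH
    component_lengths: pd.DataFrame = field(default_factory=pd.DataFrame)
    biotype_of: dict[str, str] = field(default_factory=dict)

    def bins_of(self, tx_id: str) -> list[GuitarBin]:
        return [b for b in self.bins if b.tx_id == tx_id]

    def layout_for(self, biotype: str) -> dict[str, tuple[float, float]]:
        return self.mrna_layout if biotype == MRNA else dict(LNCRNA_LAYOUT)

    def axis_cells(self, biotype: str) -> pd.DataFrame:
        """The shared standardized-axis grid for one biotype: one row per
        (component, bin_index) with the cell center and width."""
        layout = self.layout_for(biotype)
        rows = []
        if self.flank > 0:
            w = self.flank_axis_width
            for i in range(self.flank_bins):
                rows.append(
                    ("promoter", i, -w + (i + 0.5) / self.flank_bins * w,
                     w / self.flank_bins)
                )
        comps = MRNA_COMPONENTS if biotype == MRNA else ("whole",)
        for comp in comps:
            offset, width = layout[comp]
            for i in range(self.B):
                rows.append(
                    (comp, i, offset + (i + 0.5) / self.B * width,
                     width / self.B)
                )
        if self.flank > 0:
            w = self.flank_axis_width
            for i in range(self.flank_bins):
                rows.append(
                    ("tail", i, 1.0 + (i + 0.5) / self.flank_bins * w,
                     w / self.flank_bins)
                )
        return pd.DataFrame(
            rows, columns=["component", "bin_index", "std_pos", "width"]
        )

    def landmarks(self, biotype: str) -> dict[str, float]:
        if biotype == LNCRNA:
            return {"TSS": 0.0, "TES": 1.0}
        layout = self.mrna_layout
        cds_off, cds_w = layout["cds"]
        return {
            "TSS": 0.0,
            "start codon": cds_off,
            "stop codon": cds_off + cds_w,
            "TES": 1.0,
        }

    def to_tsv(self, path: str) -> None:
        """Export bin footprints as a BED-like TSV (one row per genomic
        piece) for inspection or external use."""
        rows = []
        for b in self.bins:
            for iv in b.genomic_footprint:
                rows.append(
                    (iv.chrom, iv.start, iv.end,
                     f"{b.tx_id}|{b.component}|{b.bin_index}",
                     round(b.std_pos, 6), iv.strand)
                )
        pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        ).to_csv(path, sep="\t", index=False, header=False)


def build_guitar_coordinates(
    annotation: TranscriptomeAnnotation,
    B: int = DEFAULT_BINS,
    flank: int = 0,
    flank_bins: Optional[int] = None,
    layout_mode: str = "equal",
    component_maps: Optional[dict[str, ComponentMap]] = None,
) -> GuitarCoordinateSet:
    """Build the full guitar coordinate set for an (already filtered)
    annotation. ``flank=0`` disables flanking DNA bins."""
    if flank_bins is None:
        flank_bins = B
    cmaps = component_maps or {
        t.tx_id: derive_components(t) for t in annotation
    }
    lengths = pd.DataFrame(
        [
            {
                "tx_id": tid,
                "biotype": cm.biotype,
                **{c: cm.component_length(c) for c in cm.spans},
            }
            for tid, cm in cmaps.items()
        ]
    )
    if layout_mode == "true_width":
        mrna = lengths[lengths["biotype"] == MRNA]
        means = {
            c: float(mrna[c].fillna(0).mean()) if c in mrna else 0.0
            for c in MRNA_COMPONENTS
        }
        mrna_layout = axis_layout("true_width", means)
    else:
        mrna_layout = axis_layout("equal")

    all_bins: list[GuitarBin] = []
    biotype_of = {}
    for tx in annotation:
        cm = cmaps[tx.tx_id]
        biotype_of[tx.tx_id] = cm.biotype
        layout = mrna_layout if cm.biotype == MRNA else LNCRNA_LAYOUT
        all_bins.extend(build_bins(tx, cm, B, layout))
        if flank > 0:
            all_bins.extend(
                add_flanks(tx, flank, flank_bins, DEFAULT_FLANK_AXIS_WIDTH)
            )
    return GuitarCoordinateSet(
        bins=all_bins,
        B=B,
        flank=flank,
        flank_bins=flank_bins,
        layout_mode=layout_mode,
        mrna_layout=mrna_layout,
        component_lengths=lengths,
        biotype_of=biotype_of,
    )
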