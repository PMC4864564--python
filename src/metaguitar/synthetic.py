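"""Seeded synthetic genomes, annotations, feature sets and cytosine tables.

Everything downstream of annotation parsing can be exercised without real
data: the generator emits multi-isoform loci (to trip the ambiguity
filter), intron-containing transcripts (so bins span introns), mRNAs with
and without UTRs, lncRNAs, feature sets drawn from a known placement law on
the standardized axis, and cytosine call tables drawn from a known rate
mixture. The generator's own bookkeeping (component lengths, per-nucleotide
overlap counts, true placement parameters, true site classes) serves as an
independent oracle in tests.

Coordinates are integer-only and the RNG is numpy's default PCG64 seeded
explicitly, so output files are byte-identical across runs and platforms
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    GenomicInterval,
    Transcript,
    TranscriptomeAnnotation,
    derive_components,
)
from .assignment import Feature


@dataclass
class SyntheticSpec:
    """Parameters of the toy transcriptome.

    Defaults sketch a compact mammalian-like mix: mostly single-isoform
    genes with a tail of multi-isoform loci, a quarter lncRNA, component
    lengths in the few-hundred-nt range and introns of 50-500 nt.
    """

    seed: int = 0
    n_genes: int = 30
    isoform_probs: tuple[float, ...] = (0.60, 0.20, 0.10, 0.05, 0.05)
    lncrna_fraction: float = 0.25
    utr5_range: tuple[int, int] = (100, 300)
    cds_range: tuple[int, int] = (300, 1500)
    utr3_range: tuple[int, int] = (150, 600)
    lncrna_range: tuple[int, int] = (300, 2000)
    n_introns_range: tuple[int, int] = (0, 4)
    intron_range: tuple[int, int] = (50, 500)
    no_utr5_prob: float = 0.08
    no_utr3_prob: float = 0.05
    chroms: tuple[str, ...] = ("chr1", "chr2")
    gene_gap: tuple[int, int] = (500, 2000)


def _split_into_exons(
    rng: np.random.Generator,
    gene_start: int,
    mature_length: int,
    spec: SyntheticSpec,
    strand: str,
    chrom: str,
) -> tuple[GenomicInterval, ...]:
    """Lay ``mature_length`` nt onto the genome from ``gene_start`` with a
    random number of introns inserted at random mature positions."""
    lo, hi = spec.n_introns_range
    k = int(rng.integers(lo, hi + 1))
    k = min(k, mature_length - 1)
    if k > 0:
        cuts = sorted(
            int(c) for c in rng.choice(
                np.arange(1, mature_length), size=k, replace=False
            )
        )
    else:
        cuts = []
    bounds = [0] + cuts + [mature_length]
    exon_lens = [b - a for a, b in zip(bounds, bounds[1:])]
    intron_lens = [
        int(rng.integers(spec.intron_range[0], spec.intron_range[1] + 1))
        for _ in range(k)
    ]
    exons, pos = [], gene_start
    for i, el in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + el, strand))
        pos += el
        if i < k:
            pos += intron_lens[i]
    return tuple(exons)


def _make_transcript(
    rng: np.random.Generator,
    tx_id: str,
    gene_id: str,
    chrom: str,
    strand: str,
    gene_start: int,
    is_lnc: bool,
    spec: SyntheticSpec,
) -> tuple[Transcript, dict]:
    if is_lnc:
        length = int(rng.integers(*spec.lncrna_range))
        u5 = cds = u3 = 0
        mature = length
    else:
        u5 = (0 if rng.random() < spec.no_utr5_prob
              else int(rng.integers(*spec.utr5_range)))
        cds = int(rng.integers(*spec.cds_range))
        u3 = (0 if rng.random() < spec.no_utr3_prob
              else int(rng.integers(*spec.utr3_range)))
        mature = u5 + cds + u3
    exons = _split_into_exons(rng, gene_start, mature, spec, strand, chrom)
    cds_span = None
    if not is_lnc:
        # mature 5'->3' span of the CDS mapped to the genome; on the minus
        # strand mature position 0 sits at the genomic right
        tmp = Transcript(tx_id, gene_id, exons)
        pieces = tmp.transcript_to_genomic(u5, u5 + cds)
        cds_span = (pieces[0].start, pieces[-1].end)
    tx = Transcript(tx_id, gene_id, exons, cds_span)
    truth = {
        "tx_id": tx_id,
        "gene_id": gene_id,
        "biotype": "lncRNA" if is_lnc else "mRNA",
        "utr5": u5,
        "cds": cds,
        "utr3": u3,
        "whole": mature if is_lnc else 0,
        "mature_length": mature,
    }
    return tx, truth


def brute_force_overlap_counts(
    transcripts: Sequence[Transcript], same_strand: bool = True
) -> dict[str, int]:
    """Per-nucleotide oracle for exonic transcript-overlap counts."""
    nt_sets = {}
    for tx in transcripts:
        key = (tx.chrom, tx.strand) if same_strand else tx.chrom
        nts = set()
        for e in tx.exons:
            nts.update(range(e.start, e.end))
        nt_sets[tx.tx_id] = (key, nts)
    counts = {}
    for tid, (key, nts) in nt_sets.items():
        counts[tid] = sum(
            1 for other, (k2, n2) in nt_sets.items()
            if other != tid and k2 == key and nts & n2
        )
    return counts


def write_gtf(annotation: TranscriptomeAnnotation, path: str) -> None:
    """Write exon and CDS records (1-based closed coordinates) in a fixed
    deterministic order."""
    with open(path, "w") as fh:
        for tx in annotation:
            for e in tx.exons:
                fh.write(
                    f"{e.chrom}\tsynthetic\texon\t{e.start + 1}\t{e.end}\t."
                    f"\t{e.strand}\t.\tgene_id \"{tx.gene_id}\"; "
                    f"transcript_id \"{tx.tx_id}\";\n"
                )
            if tx.cds_span is not None:
                cs, ce = tx.cds_span
                for e in tx.exons:
                    lo, hi = max(e.start, cs), min(e.end, ce)
                    if lo < hi:
                        fh.write(
                            f"{e.chrom}\tsynthetic\tCDS\t{lo + 1}\t{hi}\t."
                            f"\t{e.strand}\t.\tgene_id \"{tx.gene_id}\"; "
                            f"transcript_id \"{tx.tx_id}\";\n"
                        )


def make_annotation(
    spec: SyntheticSpec,
    gtf_path: Optional[str] = None,
) -> tuple[TranscriptomeAnnotation, pd.DataFrame]:
    """Generate the toy annotation and its ground-truth table.

    The truth table records the component lengths each transcript was built
    with and its per-nucleotide exonic overlap count -- both independent of
    the parsing/derivation code they are used to check.
    """
    rng = np.random.default_rng(spec.seed)
    cursors = {c: 1000 for c in spec.chroms}
    transcripts: list[Transcript] = []
    truths: list[dict] = []
    iso_probs = np.asarray(spec.isoform_probs, dtype=float)
    iso_probs = iso_probs / iso_probs.sum()
    for g in range(spec.n_genes):
        chrom = spec.chroms[int(rng.integers(len(spec.chroms)))]
        strand = "+" if rng.random() < 0.5 else "-"
        gap = int(rng.integers(*spec.gene_gap))
        gene_start = cursors[chrom] + gap
        is_lnc = rng.random() < spec.lncrna_fraction
        n_iso = 1 + int(rng.choice(len(iso_probs), p=iso_probs))
        gene_id = f"G{g:04d}"
        max_end = gene_start
        for i in range(n_iso):
            tx, truth = _make_transcript(
                rng, f"{gene_id}.T{i}", gene_id, chrom, strand,
                gene_start, is_lnc, spec,
            )
            transcripts.append(tx)
            truths.append(truth)
            max_end = max(max_end, tx.exons[-1].end)
        cursors[chrom] = max_end
    annotation = TranscriptomeAnnotation(transcripts)
    truth_df = pd.DataFrame(truths)
    counts = brute_force_overlap_counts(transcripts)
    truth_df["overlap_count"] = truth_df["tx_id"].map(counts)
    if gtf_path is not None:
        write_gtf(annotation, gtf_path)
    return annotation, truth_df


@dataclass
class PlacementLaw:
    """Distribution of feature positions on the standardized [0, 1] axis.

    ``uniform``: flat. ``triangular``: mixture of a symmetric triangular
    peak (center, half_width) with mixture weight ``peak_weight`` and a
    uniform background -- a simple integrable stand-in for landmark
    enrichment such as the stop-codon peak of m6A.
    """

    kind: str = "uniform"
    center: float = 2.0 / 3.0
    half_width: float = 0.05
    peak_weight: float = 0.8

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "uniform":
            return rng.random(n)
        if self.kind != "triangular":
            raise ValueError(f"unknown placement law {self.kind!r}")
        u = rng.random(n)
        peak = rng.triangular(
            self.center - self.half_width, self.center,
            self.center + self.half_width, n,
        )
        out = np.where(u < self.peak_weight, peak, rng.random(n))
        return np.clip(out, 0.0, np.nextafter(1.0, 0.0))


def _axis_to_mature(u: float, cmap, mature_length: int) -> Optional[int]:
    """Map a standardized axis position (equal layout) to a mature nt."""
    if cmap.biotype == "lncRNA":
        a, b = cmap.spans["whole"]
        return a + min(int(u * (b - a)), b - a - 1)
    comp_idx = min(int(u * 3), 2)
    comp = ("utr5", "cds", "utr3")[comp_idx]
    if comp not in cmap.spans:
        return None
    rel = u * 3 - comp_idx
    a, b = cmap.spans[comp]
    return a + min(int(rel * (b - a)), b - a - 1)


def make_features(
    annotation: TranscriptomeAnnotation,
    law: PlacementLaw,
    n: int,
    seed: int,
    width: int = 1,
    bed_path: Optional[str] = None,
    group: Optional[str] = None,
) -> tuple[list[Feature], pd.DataFrame]:
    """Draw ``n`` features from ``law`` on the standardized axis of the
    given (retained) transcripts and emit BED6 plus a truth table with each
    feature's transcript and drawn axis position."""
    rng = np.random.default_rng(seed)
    txs = list(annotation)
    cmaps = {t.tx_id: derive_components(t) for t in txs}
    feats: list[Feature] = []
    rows = []
    made = 0
    while made < n:
        tx = txs[int(rng.integers(len(txs)))]
        u = float(law.sample(rng, 1)[0])
        pos = _axis_to_mature(u, cmaps[tx.tx_id], tx.mature_length)
        if pos is None:  # empty component on this isoform; redraw
            continue
        w = min(width, tx.mature_length - pos)
        pieces = tx.transcript_to_genomic(pos, pos + w)
        # a genomic feature is a single interval spanning any introns
        iv = GenomicInterval(
            tx.chrom, pieces[0].start, pieces[-1].end, tx.strand
        )
        fid = f"f{made:06d}"
        feats.append(Feature(fid, iv, group))
        rows.append(
            {"feature_id": fid, "tx_id": tx.tx_id, "axis_pos": u,
             "mature_pos": pos}
        )
        made += 1
    truth = pd.DataFrame(
        rows, columns=["feature_id", "tx_id", "axis_pos", "mature_pos"]
    )
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for f in feats:
                iv = f.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{f.id}\t0\t"
                    f"{iv.strand}\n"
                )
    return feats, truth


def make_cytosine_table(
    n: int,
    seed: int,
    rate_mixture: Optional[dict[str, tuple[float, float]]] = None,
    coverage_law: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
    path: Optional[str] = None,
    chrom: str = "chrS",
) -> pd.DataFrame:
    """Simulate a per-cytosine bisulfite call table.

    ``rate_mixture`` maps class label -> (fraction, methylation rate);
    fractions must sum to 1. Default: 90% background at the 1.65%
    transcriptome-average rate and 10% highly methylated at 50%. Coverage
    defaults to Poisson(mean 30) truncated to >= 1. Returns a DataFrame
    with 1-based positions, counts, and the true class of every site;
    ``path`` writes the 5-column TSV the methylation module reads.
    """
    if rate_mixture is None:
        rate_mixture = {"background": (0.9, 0.0165), "high": (0.1, 0.5)}
    fracs = np.array([f for f, _ in rate_mixture.values()])
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("mixture fractions must sum to 1")
    rng = np.random.default_rng(seed)
    labels = list(rate_mixture)
    which = rng.choice(len(labels), size=n, p=fracs)
    if coverage_law is None:
        cov = np.maximum(rng.poisson(30, size=n), 1)
    else:
        cov = np.asarray(coverage_law(rng, n), dtype=int)
    rates = np.array([rate_mixture[labels[w]][1] for w in which])
    m = rng.binomial(cov, rates)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "position": np.arange(1, n + 1) * 10,  # 1-based, spaced
            "strand": "+",
            "m": m,
            "u": cov - m,
            "true_class": [labels[w] for w in which],
        }
    )
    if path is not None:
        df[["chrom", "position", "strand", "m", "u"]].to_csv(
            path, sep="\t", index=False, header=False
        )
    return df
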