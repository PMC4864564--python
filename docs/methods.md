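# Methods

## The problem

RNA-related features — m⁶A and m⁵C modification sites, MeRIP-Seq peaks —
are reported in genome coordinates, but their biology is organized around
transcript landmarks: TSS, start codon, stop codon, TES. Transcripts vary
enormously in length, genes have many isoforms, and mature RNAs are
spliced, so "distance to the stop codon in bp" is not comparable across
genes. This package summarizes where features sit on a *standardized*
transcript axis, aggregated over a whole transcriptome.

## Guitar coordinates

Each retained transcript is decomposed into components: 5′UTR, CDS and
3′UTR for mRNA (delimited by the annotated CDS span; either UTR may be
empty), or the whole transcript for lncRNA. Every non-empty component of
mature length *L* is cut into *B* bins of width ⌊L/B⌋ or ⌈L/B⌉ (the
remainder *L* mod *B* is front-loaded onto the first bins — deterministic
and order-preserving). Each bin's genomic footprint is obtained by
inverting the splicing map, so a bin may own several genomic intervals when
it crosses introns. Bin *i* of a component occupying axis interval
`[offset, offset+width)` sits at standardized position
`offset + (i + ½)/B · width`.

**Axis layout.** In `equal` mode each mRNA component occupies one third of
the [0, 1] axis, so the start codon is at 1/3 and the stop codon at 2/3
regardless of true component sizes. In `true_width` mode component axis
widths are proportional to the mean component lengths over retained mRNAs.
lncRNAs always use the single-component [0, 1] axis; mRNA and lncRNA are
never mixed on one axis.

**Defaults.** *B* = 100 bins per component, giving ≈1 % resolution per
component on the standardized axis. Flanking DNA is off by default; when
enabled, the promoter covers the *F* = 1000 nt upstream of the TSS and the
tail the 1000 nt downstream of the TES (strand-aware, pure genomic windows,
truncated with a warning at chromosome start), each rendered on an axis
extension of width 1/3 with *B* bins.

## Filters

1. **Length filter** — every non-empty mRNA component (and each lncRNA)
   must be at least `min_component_length` (default 100 nt; lncRNA default
   300 nt) *and* at least *B* nt so that *B* bins are feasible. The
   per-component application is a deliberate strengthening of a plain
   transcript-length cutoff: bins cannot be built on a component shorter
   than *B*. For single-base-resolution data a user can lower the cutoff
   (with a smaller *B*); for peak-resolution data 100 nt is appropriate.
2. **Isoform-ambiguity filter** — transcripts whose exonic footprint
   shares ≥1 nt with more than `max_tx_overlap` = 3 other transcripts are
   discarded. Counts are computed **once**, on the post-length-filter set
   (switchable to pre-filter counting), and never recomputed after
   removals; iterative recounting would make the result depend on removal
   order.
3. **Feature-ambiguity filter** — optional removal of features overlapping
   more than `max_feature_tx` = 5 retained transcripts.

**Strand policy.** Transcripts overlap only when on the same strand
(antisense RNAs are biologically distinct); `same_strand=False` disables
this. Features with strand "." match both strands.

## Weight allocation

A feature associated with *n* retained transcripts is allocated weight
1/*n* per transcript; *n* = 1 means full weight 1. Within a transcript,
every bin whose genomic footprint intersects the feature by ≥1 nt records a
hit — an indicator, not fractional coverage. Because bins within a
component have (near-)equal width, the number of bins hit per component is
proportional to the feature's extent there: a feature 70 % on the 5′UTR and
30 % on the CDS of an equal-component mRNA yields exactly 70 % of its hits
from 5′UTR bins. A feature spanning two components of one transcript
contributes in both. With half-open bins a single-nucleotide site on a bin
boundary hits exactly one bin.

When flanks are enabled, flank bins participate identically and *n* is the
number of retained transcripts with at least one bin hit (flank or mature);
with flanks disabled this is provably identical to counting transcripts by
exonic-footprint overlap, since the mature bins tile the exons exactly.

Features are not length-normalized: a long peak hits many bins and
contributes to many cells. Likewise all transcripts carry equal weight, so
read-level input (where abundant genes dominate) is out of scope.

## Density, smoothing, plotting

Per (biotype, group), cell weights *wᵢ* on the standardized grid are
normalized to a density `dᵢ = (wᵢ/Σw)/widthᵢ`, which integrates to exactly
1 over the displayed axis (flanks included in the domain when present).
Normalization is per group, so curves compare *shape*, not abundance, and
scaling one group leaves the others unchanged. An all-zero weight vector
produces an all-zero density with a warning.

Optional presentation smoothing convolves the cell masses with a Gaussian
kernel (default bandwidth 0.02 axis units) evaluated at cell centers, with
the source mass reflected at both axis ends and each source row
renormalized over the cells — mass, hence the unit integral, is conserved
exactly, and a uniform profile is a fixed point to ≪1e−9. Exported TSVs
carry the raw weights alongside the (possibly smoothed) density.

## Bisulfite cytosine grouping

Cytosine calls (methylated count *m*, unmethylated *u*) are first filtered
to coverage ≥ 5 reads. The average methylation probability is estimated by
pooling reads, Σm/Σ(m+u) — "the average over the transcriptome" read as a
read-level average; an unweighted per-site mean is available via
`pooled=False`. Each site is then tested with two one-sided exact binomial
tests at α = 0.05 using inclusive tails: **high** if P(X ≥ m) < α, **low**
if P(X ≤ m) < α, else **undetermined**. Inclusive tails are conservative
and the two tails cannot both fire for α ≤ ½, so the three labels
partition the sites. No multiple-testing correction is applied — each site
is tested at raw α, matching common practice for this screen; users wanting
FDR control can post-process the exported groups. The three groups export
as BED6 and feed straight back into the metagene pipeline.

## Synthetic data

The generator emits a coordinate-only toy genome (no sequence is needed
anywhere in the method): 30 genes by default, isoform counts 1–5 with
probabilities 0.60/0.20/0.10/0.05/0.05, 25 % lncRNA, component lengths
5′UTR 100–300, CDS 300–1500, 3′UTR 150–600, lncRNA 300–2000 nt, 0–4
introns of 50–500 nt per transcript, and small probabilities (0.08/0.05)
of missing UTRs — a compact mammalian-like mixture chosen to exercise
multi-isoform ambiguity, intron-spanning bins and degenerate components.
Feature placement laws on the standardized axis are uniform or a
uniform+triangular mixture (location, half-width, mixture weight), the
latter a simple integrable stand-in for landmark enrichment such as the
m⁶A stop-codon peak. Cytosine tables draw coverage from Poisson(30)
truncated at ≥1 and methylated counts from a labelled rate mixture
(default 90 % background at 1.65 %, 10 % high at 50 %).

All generation uses numpy's seeded PCG64 with integer-only coordinates, so
outputs are byte-identical per seed. The generator's bookkeeping (component
lengths, per-nucleotide overlap counts, true placement positions, true site
classes) serves as an independent oracle for the annotation, filter and
assignment modules.

What the generator does **not** emulate: real splice-site sequence
structure, expression levels (all transcripts equally weighted), overlapping
genes on opposite strands beyond chance placement, read-level noise, or
mapping artifacts. Passing tests therefore demonstrate correctness of the
coordinate/weighting machinery and statistical calibration of the
classifier under the stated models — not robustness to annotation errors or
alignment biases in real data.

## Numerical choices and edge cases

- Coordinates: 0-based half-open internally; GTF converted on read, BED
  taken as-is, cytosine TSV positions are 1-based in files.
- CDS span taken verbatim from annotation (no ±3 nt stop-codon
  adjustment).
- Transcripts with strand "." are skipped (5′→3′ direction undefined);
  transcripts with exons on several chromosomes/strands are skipped with a
  warning.
- Book-ended or overlapping exon records of one transcript are merged.
- Empty components contribute no bins; a transcript missing a UTR is still
  profiled on its remaining components.
- Profile integral tolerance 1e−9; smoothing bandwidth 0 disables
  smoothing exactly.
- Test problem sizes (100 random oracle instances ≤10 kb / ≤5 transcripts /
  ≤50 features; 1000 round-trip transcripts; 10⁴ features for peak
  recovery; 10⁴ simulated null sites) were chosen as the smallest scales at
  which the checked statistics are stable.

## Known limitations

- No expression weighting: highly expressed genes and long ambiguous
  features can dominate profiles.
- No cross-normalization between mRNA and lncRNA panels.
- Peak calling, read trimming/alignment and methylation calling are
  upstream of this package; it consumes their interval/count outputs.
- Per-nucleotide coordinate sets (B = mature length) work but are not
  optimized for whole mammalian transcriptomes.
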