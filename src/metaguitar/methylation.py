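"""Bisulfite cytosine post-processing: coverage filtering, the
transcriptome-average methylation rate, and exact binomial grouping.

Each called cytosine carries methylated (``m``) and unmethylated (``u``)
read counts. After discarding low-coverage calls, sites are classified
against the pooled average methylation probability ``p`` with two one-sided
exact binomial tests at level ``alpha``:

* **high** if the inclusive upper tail ``P(X >= m | n, p)`` is below alpha,
* **low** if the inclusive lower tail ``P(X <= m | n, p)`` is below alpha,
* **undetermined** otherwise.

Inclusive tails make the test conservative, and for alpha <= 0.5 the two
tails can never both fire (their sum is 1 + P(X = m) >= 1). No
multiple-testing correction is applied: each site is tested at raw alpha.
The three groups can be exported as BED6 files and profiled on the
standardized axis like any other feature set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from scipy.stats import binom

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 5
DEFAULT_ALPHA = 0.05

LABELS = ("high", "low", "undetermined")


@dataclass(frozen=True)
class CytosineRecord:
    chrom: str
    position: int  # 0-based
    strand: str
    m: int  # methylated read count
    u: int  # unmethylated read count

    def __post_init__(self):
        if self.m < 0 or self.u < 0:
            raise ValueError("read counts must be >= 0")

    @property
    def coverage(self) -> int:
        return self.m + self.u


def read_cytosine_table(path: str) -> list[CytosineRecord]:
    """Read a cytosine call TSV with columns chrom, position (1-based),
    strand, methylated count, unmethylated count. A header line is detected
    and skipped; positions are converted to 0-based."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "position", "strand", "m", "u"], dtype=str,
    )
    if len(df) and not df.iloc[0]["position"].lstrip("-").isdigit():
        df = df.iloc[1:]
    return [
        CytosineRecord(
            r.chrom, int(r.position) - 1, r.strand, int(r.m), int(r.u)
        )
        for r in df.itertuples(index=False)
    ]


def coverage_filter(
    records: Sequence[CytosineRecord], min_reads: int = DEFAULT_MIN_READS
) -> list[CytosineRecord]:
    """Keep cytosines called with at least ``min_reads`` aligned reads."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return [r for r in records if r.coverage >= min_reads]


def global_rate(
    records: Sequence[CytosineRecord], pooled: bool = True
) -> float:
    """Average methylation probability over all sites.

    Pooled estimator (default): total methylated reads / total reads, i.e.
    the probability a random aligned read over the whole set is methylated.
    ``pooled=False`` gives the unweighted mean of per-site fractions.
    """
    if not records:
        raise ValueError("no records to estimate a rate from")
    if pooled:
        m = sum(r.m for r in records)
        cov = sum(r.coverage for r in records)
        return m / cov
    fracs = [r.m / r.coverage for r in records if r.coverage > 0]
    return sum(fracs) / len(fracs)


def classify(
    record: CytosineRecord,
    p_global: float,
    alpha: float = DEFAULT_ALPHA,
) -> str:
    """Label a cytosine high/low/undetermined by exact binomial tails."""
    if not 0.0 < p_global < 1.0:
        raise ValueError(
            f"degenerate methylation model: p_global={p_global}"
        )
    n = record.coverage
    if n < 1:
        raise ValueError("cannot classify a site with zero coverage")
    upper = float(binom.sf(record.m - 1, n, p_global))  # P(X >= m)
    lower = float(binom.cdf(record.m, n, p_global))     # P(X <= m)
    hi, lo = upper < alpha, lower < alpha
    if hi and lo:  # impossible for alpha <= 0.5; guards misuse
        raise ValueError("both tails significant; alpha too large")
    if hi:
        return "high"
    if lo:
        return "low"
    return "undetermined"


def group_records(
    records: Sequence[CytosineRecord],
    p_global: Optional[float] = None,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[list[str], dict[str, int]]:
    """Classify every record; returns labels (aligned to input order) and
    per-label counts. ``p_global`` defaults to the pooled rate of the
    records themselves."""
    if p_global is None:
        p_global = global_rate(records)
    labels = [classify(r, p_global, alpha) for r in records]
    counts = {lab: labels.count(lab) for lab in LABELS}
    return labels, counts


def group_and_export(
    records: Sequence[CytosineRecord],
    outdir: str,
    p_global: Optional[float] = None,
    alpha: float = DEFAULT_ALPHA,
    prefix: str = "cytosines",
) -> dict:
    """Classify records and write one BED6 per group (single-nt intervals,
    label in the name field) plus a JSON summary. The BED files feed
    directly into the metagene profiling pipeline as grouped feature sets.
    """
    if p_global is None:
        p_global = global_rate(records)
    labels, counts = group_records(records, p_global, alpha)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for lab in LABELS:
        rows = [
            (r.chrom, r.position, r.position + 1,
             f"{lab}_{i}", f"{r.m}/{r.coverage}", r.strand)
            for i, (r, l) in enumerate(zip(records, labels)) if l == lab
        ]
        path = out / f"{prefix}.{lab}.bed"
        pd.DataFrame(rows).to_csv(
            path, sep="\t", index=False, header=False
        )
        paths[lab] = str(path)
    summary = {
        "n_records": len(records),
        "p_global": p_global,
        "alpha": alpha,
        "counts": counts,
        "bed": paths,
    }
    with open(out / f"{prefix}.summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info(
        "cytosine grouping: %s (p=%.4g, alpha=%g)", counts, p_global, alpha
    )
    return summary
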