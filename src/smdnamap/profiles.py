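"""Genome-scale coverage statistics: *ter* targeting, strand ratios, plasmid bias.

The headline questions these statistics answer: what fraction of the guide
library comes from each replication-termination window and from which
strand (fork-trapping at Tus-bound *ter* sites produces a 3'-terminated
strand that is over-represented); how ciprofloxacin redistributes guides
between the leading and lagging strands genome-wide; and how strongly the
expression plasmid is over-represented once replicon length and copy
number are accounted for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import ReferenceBundle, TerSite
from .reads import ReadProcessingError, StrandCounts


@dataclass
class TerFractionReport:
    """Percent of chromosome-mapped reads with a 5' end in each ter window."""

    table: pd.DataFrame  # ter, strand, reads, percent
    total_reads: int

    def percent(self, ter: str, strand: str) -> float:
        sel = self.table[(self.table["ter"] == ter) & (self.table["strand"] == strand)]
        return float(sel["percent"].iloc[0])


def ter_fraction(
    counts: StrandCounts,
    ter_sites: list[TerSite],
    replicon: str | None = None,
) -> TerFractionReport:
    """Per-ter-window, per-strand read counts as a percent of the library.

    The denominator is the total number of reads mapped to both strands of
    the chromosome (the replicon carrying the ter windows).
    """
    if replicon is None:
        # ter windows live on the largest replicon by convention
        replicon = max(counts.counts, key=lambda r: len(counts.counts[r]["+"]))
    total = counts.replicon_total(replicon)
    if total == 0:
        raise ReadProcessingError("empty library: no reads on the chromosome")
    rows = []
    for t in ter_sites:
        for strand in ("+", "-"):
            n = int(counts.counts[replicon][strand][t.start: t.end].sum())
            rows.append((t.name, strand, n, 100.0 * n / total))
    return TerFractionReport(
        table=pd.DataFrame(rows, columns=["ter", "strand", "reads", "percent"]),
        total_reads=total,
    )


def ter_strand_asymmetry(report: TerFractionReport, ter: TerSite) -> float:
    """Ratio of blocked-strand (3'-terminated) to complementary-strand reads."""
    blocked = report.percent(ter.name, ter.blocked_strand)
    other = report.percent(ter.name, "+" if ter.blocked_strand == "-" else "-")
    if other == 0:
        return float("inf")
    return blocked / other


@dataclass
class RatioProfile:
    """Rolling-window plus/minus ratio profile (or a ratio of such ratios)."""

    step: int
    window: int
    starts: np.ndarray  # window start coordinate per step
    values: np.ndarray
    defined: np.ndarray  # False where a window had no reads beyond pseudocount
    pseudocount: float


def _rolling_window_sums(arr: np.ndarray, window: int, step: int, circular: bool) -> np.ndarray:
    L = len(arr)
    starts = np.arange(0, L, step, dtype=np.int64)
    csum = np.concatenate([[0], np.cumsum(arr, dtype=np.float64)])
    ends = starts + window
    if circular:
        whole = ends // L
        out = whole * csum[L] + csum[ends % L] - csum[starts]
    else:
        out = csum[np.minimum(ends, L)] - csum[starts]
    return out


def strand_ratio_profile(
    counts_cfx: StrandCounts,
    counts_ctrl: StrandCounts,
    replicon: str | None = None,
    window: int = 50_000,
    step: int = 10_000,
    pseudocount: float = 1.0,
    circular: bool = True,
) -> RatioProfile:
    """(+Cfx plus/minus ratio) divided by (control plus/minus ratio).

    Each library's plus/minus coverage ratio is computed in rolling windows
    (``window`` bp wide, every ``step`` bp, wrapping around circular
    replicons), with ``pseudocount`` reads added per window and strand, and
    the +Cfx profile is divided by the control profile step-wise.
    """
    if window < step:
        raise ValueError("window must be >= step")
    if replicon is None:
        replicon = max(counts_cfx.counts, key=lambda r: len(counts_cfx.counts[r]["+"]))
    if set(counts_cfx.counts) != set(counts_ctrl.counts):
        raise ValueError("libraries aligned to different references")

    def lib_ratio(counts: StrandCounts) -> tuple[np.ndarray, np.ndarray]:
        p = _rolling_window_sums(counts.counts[replicon]["+"], window, step, circular)
        m = _rolling_window_sums(counts.counts[replicon]["-"], window, step, circular)
        defined = (p + m) > 0
        return (p + pseudocount) / (m + pseudocount), defined

    r_cfx, d1 = lib_ratio(counts_cfx)
    r_ctrl, d2 = lib_ratio(counts_ctrl)
    L = len(counts_cfx.counts[replicon]["+"])
    return RatioProfile(
        step=step,
        window=window,
        starts=np.arange(0, L, step, dtype=np.int64),
        values=r_cfx / r_ctrl,
        defined=d1 & d2,
        pseudocount=pseudocount,
    )


@dataclass
class PlasmidEnrichment:
    """Plasmid over-representation after length and copy-number correction."""

    fold: float
    plasmid_reads: int
    chromosome_reads: int
    plasmid_length: int
    chromosome_length: int
    copy_number: int


def plasmid_enrichment(counts: StrandCounts, bundle: ReferenceBundle) -> PlasmidEnrichment:
    """fold = (reads_p / (L_p * c)) / (reads_ch / L_ch).

    A fold of 1 means plasmid reads are exactly proportional to plasmid DNA
    content (length x copy number); the pAgo's plasmid preference is the
    excess over 1.
    """
    plasmid = bundle.plasmid
    if plasmid is None:
        raise ValueError("bundle has no plasmid replicon")
    chrom = bundle.chromosome
    reads_p = counts.replicon_total(plasmid.name)
    reads_ch = counts.replicon_total(chrom.name)
    if reads_ch == 0:
        raise ReadProcessingError("zero chromosome reads")
    fold = (reads_p / (plasmid.length * plasmid.copy_number)) / (reads_ch / chrom.length)
    return PlasmidEnrichment(
        fold=fold,
        plasmid_reads=reads_p,
        chromosome_reads=reads_ch,
        plasmid_length=plasmid.length,
        chromosome_length=chrom.length,
        copy_number=plasmid.copy_number,
    )
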