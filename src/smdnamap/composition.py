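"""Descriptive statistics of guide sequences: lengths, logos, GC content.

These summaries characterise what the pAgo is loaded with rather than
where the guides map: the length spectrum of the 14-19 nt guides, the
positional base composition from the guide 5' end (a mild G preference at
position 1 is the only bias reported for SeAgo), and GC content of the
guides and their flanking genomic context relative to the genome mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reads import ReadSet
from .reference import ReferenceBundle, gc_content

_BASE_ORDER = "ACGT"


@dataclass
class LengthHistogram:
    counts: dict[int, int]
    modal_length: int | None
    fraction_in_range: float  # within [14, 19]


def length_histogram(reads: ReadSet) -> LengthHistogram:
    lengths = np.array([len(s) for s in reads.seqs], dtype=np.int64)
    if len(lengths) == 0:
        return LengthHistogram(counts={}, modal_length=None, fraction_in_range=float("nan"))
    uniq, cts = np.unique(lengths, return_counts=True)
    counts = {int(l): int(c) for l, c in zip(uniq, cts)}
    modal = int(uniq[np.argmax(cts)])
    in_range = float(((lengths >= 14) & (lengths <= 19)).mean())
    return LengthHistogram(counts=counts, modal_length=modal, fraction_in_range=in_range)


@dataclass
class LogoMatrix:
    """Per-position base frequencies over positions 1..17 from the 5' end.

    Only reads longer than 16 nt qualify; reads longer than 17 nt are
    truncated to 17 nt from the 3' end.
    """

    frequencies: pd.DataFrame  # index 1..17, columns A/C/G/T
    n_reads: int


def logo_matrix(reads: ReadSet, min_length: int = 17, width: int = 17) -> LogoMatrix:
    qualifying = [s[:width] for s in reads.seqs if len(s) >= min_length]
    if not qualifying:
        raise ValueError("no reads qualify for the logo (need length > 16)")
    mat = np.frombuffer("".join(qualifying).encode(), dtype=np.uint8).reshape(len(qualifying), width)
    freqs = np.zeros((width, 4))
    for bi, base in enumerate(_BASE_ORDER.encode()):
        freqs[:, bi] = (mat == base).mean(axis=0)
    df = pd.DataFrame(freqs, columns=list(_BASE_ORDER), index=pd.RangeIndex(1, width + 1, name="position"))
    return LogoMatrix(frequencies=df, n_reads=len(qualifying))


def write_pwm(logo: LogoMatrix, path) -> None:
    """Position-weight-matrix text export (rows = positions, columns = A/C/G/T)."""
    logo.frequencies.to_csv(path, sep="\t", float_format="%.6f")


@dataclass
class GCProfile:
    """GC fraction per position across the guide and flanking genomic context.

    Positions are guide-relative: 0 is the guide 5' base, negative offsets
    are genomic flank 5' of the guide (in guide orientation), positions
    beyond each read's 3' end continue into its 3' genomic flank.
    """

    positions: np.ndarray
    gc_fraction: np.ndarray
    n_reads: np.ndarray  # contributing reads per position
    flank_width: int
    genome_mean_gc: float


def gc_profile(
    alignments: pd.DataFrame,
    bundle: ReferenceBundle,
    flank: int = 20,
) -> GCProfile:
    """Positional GC of aligned guides plus flanking genome, guide-oriented.

    For a plus-strand guide the window is read left-to-right from the
    reference; for a minus-strand guide the window is the reverse
    complement, so positional effects stay guide-relative.  Each read
    contributes to offsets ``-flank .. length + flank - 1``.
    """
    max_len = int(alignments["length"].max())
    span = flank + max_len + flank
    gc_sum = np.zeros(span)
    gc_n = np.zeros(span, dtype=np.int64)

    seqs = {name: rep.sequence.upper() for name, rep in bundle.replicons.items()}
    is_gc = {name: np.frombuffer(s.encode(), dtype=np.uint8) for name, s in seqs.items()}
    for name, arr in is_gc.items():
        is_gc[name] = (arr == ord("G")) | (arr == ord("C"))

    for r in alignments.itertuples(index=False):
        g = is_gc[r.replicon]
        L = len(g)
        n = int(r.length) + 2 * flank
        if r.strand == "+":
            idx = (np.arange(r.match_start - flank, r.match_start - flank + n)) % L
            window = g[idx]
        else:
            end = r.match_start + int(r.length)  # exclusive, plus-strand coords
            idx = (np.arange(end + flank - 1, end + flank - 1 - n, -1)) % L
            window = g[idx]  # complementation preserves G+C
        gc_sum[:n] += window
        gc_n[:n] += 1

    with np.errstate(invalid="ignore"):
        frac = np.where(gc_n > 0, gc_sum / np.maximum(gc_n, 1), np.nan)
    return GCProfile(
        positions=np.arange(-flank, max_len + flank),
        gc_fraction=frac,
        n_reads=gc_n,
        flank_width=flank,
        genome_mean_gc=gc_content(bundle.chromosome.sequence),
    )
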