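"""Read preprocessing, exact alignment, and strand-specific coverage.

smDNA guides are 14-19 nt, so alignment is exact string matching: a read is
reported wherever it equals the reference (strand ``+``) or its reverse
complement (strand ``-``), with no mismatches, across all replicons and
across circular origin junctions.  Each aligned read contributes one count
at the plus-strand coordinate of its 5' base; every downstream statistic is
built from these per-strand 5'-end count arrays.

The index is a per-length table of 2-bit-encoded k-mer codes of the
reference, sorted for binary search; it is built lazily for the read
lengths actually present in a library.  Memory is bounded by a few machine
words per reference base per distinct length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import ReferenceBundle

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


class ReadProcessingError(ValueError):
    pass


@dataclass
class ReadSet:
    """Preprocessed reads plus a processing log."""

    ids: list[str]
    seqs: list[str]
    provenance: str = ""
    n_input: int = 0
    n_trimmed: int = 0
    n_discarded_short: int = 0

    def __len__(self) -> int:
        return len(self.seqs)

    @property
    def log(self) -> dict:
        return {
            "input_reads": self.n_input,
            "adapter_trimmed": self.n_trimmed,
            "discarded_short": self.n_discarded_short,
            "kept": len(self.seqs),
        }


def preprocess_reads(
    fastq_path: str | Path,
    adapter: str = "",
    min_length: int = 14,
) -> ReadSet:
    """Trim the 3' adapter (leftmost exact occurrence) and drop short reads.

    Everything from the first exact occurrence of ``adapter`` onward is
    removed; reads shorter than ``min_length`` after trimming are discarded.
    """
    adapter = adapter.upper()
    ids: list[str] = []
    seqs: list[str] = []
    n_input = n_trimmed = n_short = 0
    try:
        with open(fastq_path) as fh:
            for title, seq, _qual in FastqGeneralIterator(fh):
                n_input += 1
                seq = seq.upper()
                if adapter:
                    cut = seq.find(adapter)
                    if cut != -1:
                        seq = seq[:cut]
                        n_trimmed += 1
                if len(seq) < min_length:
                    n_short += 1
                    continue
                ids.append(title.split()[0])
                seqs.append(seq)
    except ValueError as exc:
        raise ReadProcessingError(f"malformed FASTQ near record {n_input + 1}: {exc}") from exc
    return ReadSet(
        ids=ids,
        seqs=seqs,
        provenance=str(fastq_path),
        n_input=n_input,
        n_trimmed=n_trimmed,
        n_discarded_short=n_short,
    )


@dataclass
class StrandCounts:
    """Per-replicon, per-strand counts of aligned-read 5' ends."""

    counts: dict[str, dict[str, np.ndarray]]  # replicon -> strand -> int array
    total_aligned: int
    total_input: int

    def replicon_total(self, replicon: str) -> int:
        return int(sum(a.sum() for a in self.counts[replicon].values()))

    def copy(self) -> "StrandCounts":
        return StrandCounts(
            {r: {s: a.copy() for s, a in d.items()} for r, d in self.counts.items()},
            self.total_aligned,
            self.total_input,
        )


class _LengthIndex:
    """Sorted k-mer code table of one replicon for one read length."""

    def __init__(self, codes: np.ndarray, k: int, circular: bool):
        L = len(codes)
        self.k = k
        self.length = L
        if circular:
            ext = np.concatenate([codes, codes[: k - 1]])
            n = L
        else:
            ext = codes
            n = L - k + 1
        if n <= 0:
            self.uniq = np.empty(0, dtype=np.int64)
            self.minpos = self.count = np.empty(0, dtype=np.int64)
            return
        valid = np.ones(n, dtype=bool)
        kmer = np.zeros(n, dtype=np.int64)
        for j in range(k):
            c = ext[j: j + n].astype(np.int64)
            valid &= c != 255
            kmer = kmer * 4 + np.where(c == 255, 0, c)
        pos = np.flatnonzero(valid).astype(np.int64)
        kmer = kmer[valid]
        order = np.argsort(kmer, kind="stable")
        skmer, spos = kmer[order], pos[order]
        uniq, start = np.unique(skmer, return_index=True)
        self.uniq = uniq
        self.minpos = np.minimum.reduceat(spos, start) if len(spos) else np.empty(0, dtype=np.int64)
        self.count = np.diff(np.append(start, len(skmer)))

    def lookup(self, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (min match position or -1, match count) per query code."""
        if len(self.uniq) == 0:
            return (np.full(len(queries), -1, dtype=np.int64), np.zeros(len(queries), dtype=np.int64))
        i = np.searchsorted(self.uniq, queries)
        i_clip = np.minimum(i, len(self.uniq) - 1)
        hit = self.uniq[i_clip] == queries
        minpos = np.where(hit, self.minpos[i_clip], -1)
        count = np.where(hit, self.count[i_clip], 0)
        return minpos, count


@dataclass
class AlignmentResult:
    counts: StrandCounts
    records: pd.DataFrame  # read_id, replicon, strand, five_prime, match_start, length, n_hits
    n_unaligned: int
    n_multimapped: int


def align_exact(
    reads: ReadSet,
    bundle: ReferenceBundle,
    discard_multimappers: bool = False,
) -> AlignmentResult:
    """Align reads by exact match on both strands of every replicon.

    A read matching k > 1 locations is assigned to the single hit with the
    smallest (replicon index, plus-strand match start, strand) — strand ``+``
    ordering before ``-`` — unless ``discard_multimappers`` is set, in which
    case such reads are dropped.  Reads containing non-ACGT characters are
    unalignable.  The 5'-end coordinate is the match start for plus-strand
    hits and ``match_start + length - 1`` (mod length on circular replicons)
    for minus-strand hits.
    """
    rep_names = list(bundle.replicons)
    rep_codes = {n: _CODE[np.frombuffer(bundle.replicons[n].sequence.upper().encode(), dtype=np.uint8)] for n in rep_names}

    n_reads = len(reads.seqs)
    lengths = np.array([len(s) for s in reads.seqs], dtype=np.int64)
    assign_rep = np.full(n_reads, -1, dtype=np.int64)
    assign_start = np.full(n_reads, -1, dtype=np.int64)
    assign_strand = np.full(n_reads, -1, dtype=np.int64)  # 0 = '+', 1 = '-'
    hit_counts = np.zeros(n_reads, dtype=np.int64)

    indexes: dict[tuple[str, int], _LengthIndex] = {}
    for k in sorted(set(lengths.tolist())):
        sel = np.flatnonzero(lengths == k)
        if k == 0:
            continue
        # encode all reads of this length into a (n, k) code matrix
        blob = "".join(reads.seqs[i] for i in sel)
        mat = _CODE[np.frombuffer(blob.encode(), dtype=np.uint8)].reshape(len(sel), k)
        ok = (mat != 255).all(axis=1)
        pw = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        fwd = (np.where(mat == 255, 0, mat).astype(np.int64) @ pw)
        rcm = (3 - mat)[:, ::-1]
        rev = (np.where(mat == 255, 0, rcm).astype(np.int64) @ pw)

        # candidate hits per replicon and orientation; pick lexicographic min
        best_rep = np.full(len(sel), np.iinfo(np.int64).max, dtype=np.int64)
        best_start = np.full(len(sel), np.iinfo(np.int64).max, dtype=np.int64)
        best_strand = np.full(len(sel), 2, dtype=np.int64)
        tot = np.zeros(len(sel), dtype=np.int64)
        for ri, name in enumerate(rep_names):
            rep = bundle.replicons[name]
            key = (name, k)
            if key not in indexes:
                indexes[key] = _LengthIndex(rep_codes[name], k, rep.circular)
            idx = indexes[key]
            for strand_i, q in ((0, fwd), (1, rev)):
                mp, ct = idx.lookup(q)
                ct = np.where(ok, ct, 0)
                tot += ct
                better = (ct > 0) & (
                    (ri < best_rep)
                    | ((ri == best_rep) & (mp < best_start))
                    | ((ri == best_rep) & (mp == best_start) & (strand_i < best_strand))
                )
                best_rep[better] = ri
                best_start[better] = mp[better]
                best_strand[better] = strand_i

        aligned = tot > 0
        assign_rep[sel[aligned]] = best_rep[aligned]
        assign_start[sel[aligned]] = best_start[aligned]
        assign_strand[sel[aligned]] = best_strand[aligned]
        hit_counts[sel] = tot

    if discard_multimappers:
        drop = hit_counts > 1
        assign_rep[drop] = -1

    aligned_mask = assign_rep >= 0
    n_aligned = int(aligned_mask.sum())
    n_multi = int((hit_counts > 1).sum())

    counts = {
        name: {
            "+": np.zeros(bundle.replicons[name].length, dtype=np.int64),
            "-": np.zeros(bundle.replicons[name].length, dtype=np.int64),
        }
        for name in rep_names
    }
    five_prime = np.full(n_reads, -1, dtype=np.int64)
    for ri, name in enumerate(rep_names):
        Lr = bundle.replicons[name].length
        for strand_i, strand in ((0, "+"), (1, "-")):
            sel = np.flatnonzero(aligned_mask & (assign_rep == ri) & (assign_strand == strand_i))
            if len(sel) == 0:
                continue
            if strand_i == 0:
                fp = assign_start[sel]
            else:
                fp = (assign_start[sel] + lengths[sel] - 1) % Lr
            five_prime[sel] = fp
            np.add.at(counts[name][strand], fp, 1)

    rec_sel = np.flatnonzero(aligned_mask)
    records = pd.DataFrame(
        {
            "read_id": [reads.ids[i] for i in rec_sel],
            "replicon": [rep_names[assign_rep[i]] for i in rec_sel],
            "strand": np.where(assign_strand[rec_sel] == 0, "+", "-"),
            "five_prime": five_prime[rec_sel],
            "match_start": assign_start[rec_sel],
            "length": lengths[rec_sel],
            "n_hits": hit_counts[rec_sel],
        }
    )
    sc = StrandCounts(counts=counts, total_aligned=n_aligned, total_input=reads.n_input or n_reads)
    return AlignmentResult(
        counts=sc,
        records=records,
        n_unaligned=n_reads - n_aligned,
        n_multimapped=n_multi,
    )


@dataclass
class WindowedCoverage:
    """Per-window RPKM per strand.  RPKM = count * 1e9 / (window_bp * total_aligned)."""

    window_size: int
    values: dict[str, dict[str, np.ndarray]]
    window_starts: dict[str, np.ndarray]


def rpkm_windows(counts: StrandCounts, window_size: int = 1000) -> WindowedCoverage:
    """Windowed strand-specific coverage, normalized to RPKM.

    The final partial window of each replicon is normalized by its true
    length.
    """
    if counts.total_aligned <= 0:
        raise ReadProcessingError("empty library: no aligned reads")
    values: dict[str, dict[str, np.ndarray]] = {}
    starts: dict[str, np.ndarray] = {}
    for rep, strands in counts.counts.items():
        L = len(strands["+"])
        edges = np.arange(0, L, window_size, dtype=np.int64)
        widths = np.minimum(edges + window_size, L) - edges
        starts[rep] = edges
        values[rep] = {}
        for strand, arr in strands.items():
            c = np.add.reduceat(arr, edges).astype(np.float64)
            values[rep][strand] = c * 1e9 / (widths * counts.total_aligned)
    return WindowedCoverage(window_size=window_size, values=values, window_starts=starts)


# ---------------------------------------------------------------------------
# Text-format export


def write_bed6(records: pd.DataFrame, path: str | Path) -> None:
    """One BED6 line per assigned read (score 0, name = read id)."""
    with open(path, "w") as fh:
        for r in records.itertuples(index=False):
            end = r.match_start + r.length
            fh.write(f"{r.replicon}\t{r.match_start}\t{end}\t{r.read_id}\t0\t{r.strand}\n")


def write_bedgraph(counts: StrandCounts, replicon: str, strand: str, path: str | Path) -> None:
    """Sparse bedGraph of 5'-end counts for one replicon/strand."""
    arr = counts.counts[replicon][strand]
    nz = np.flatnonzero(arr)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{replicon}_{strand}"\n')
        for p in nz:
            fh.write(f"{replicon}\t{p}\t{p + 1}\t{arr[p]}\n")
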