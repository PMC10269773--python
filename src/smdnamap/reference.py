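"""Reference replicons, annotations, masks, and oriented site sets.

The analysis operates on a small set of replicons (one circular bacterial
chromosome plus, optionally, an expression plasmid) together with interval
annotations: gene borders, masked regions that are excluded from statistics
(the replication-termination region and other over-represented loci such as
rRNA operons), replication-termination (*ter*) windows, and two kinds of
oriented point sites — Chi motifs (5'-GCTGGTGG-3' in E. coli), which halt
RecBCD resection of the 3'-terminated strand, and gyrase cleavage sites
(GCSs) stabilised by ciprofloxacin.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open.  I/O converts: GFF3 and
"paper-style" coordinates are 1-based inclusive; BED is 0-based half-open.
A Chi site's ``position`` is always the 0-based start of the 8-mer on the
plus strand, whatever the strand label; "the 3'-side of Chi" means
increasing coordinates for ``+`` sites and decreasing coordinates for ``-``
sites.  On circular replicons interval arithmetic wraps modulo the length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

CHI_MOTIF = "GCTGGTGG"

_DNA = set("ACGT")
_IUPAC = set("ACGTRYSWKMBDHVN")


class ReferenceError(ValueError):
    """Raised for malformed or inconsistent reference inputs."""


@dataclass(frozen=True)
class Replicon:
    """A single reference sequence (chromosome or plasmid)."""

    name: str
    sequence: str
    topology: str = "circular"  # "circular" | "linear"
    copy_number: int = 1
    role: str = "chromosome"  # "chromosome" | "plasmid"

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ReferenceError(f"replicon {self.name!r}: empty sequence")
        if self.topology not in ("circular", "linear"):
            raise ReferenceError(f"replicon {self.name!r}: bad topology {self.topology!r}")
        if self.copy_number < 1:
            raise ReferenceError(f"replicon {self.name!r}: copy_number must be >= 1")
        bad = set(self.sequence.upper()) - _IUPAC
        if bad:
            raise ReferenceError(f"replicon {self.name!r}: non-IUPAC characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def circular(self) -> bool:
        return self.topology == "circular"


@dataclass(frozen=True, order=True)
class OrientedSite:
    """A strand-oriented point feature (Chi motif occurrence, GCS, ...).

    ``position`` is the 0-based offset of the motif start on the plus strand.
    """

    replicon: str
    position: int
    strand: str = "+"  # "+" | "-" ("+" by convention for unstranded sites, e.g. GCSs)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ReferenceError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class TerSite:
    """A replication-termination window.

    ``blocked_strand`` is the strand whose 3' end points toward the site,
    i.e. the strand from which RecBCD-resected smDNAs are over-produced.
    """

    name: str
    start: int
    end: int
    blocked_strand: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ReferenceError(f"ter site {self.name!r}: start must be < end")
        if self.blocked_strand not in ("+", "-"):
            raise ReferenceError(f"ter site {self.name!r}: bad strand")


class MaskSet:
    """Normalized (sorted, merged, non-overlapping) masked intervals per replicon."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        raw: dict[str, list[tuple[int, int]]] = {}
        for rep, start, end in intervals:
            if end <= start:
                raise ReferenceError(f"mask interval ({start}, {end}) is empty or inverted")
            raw.setdefault(rep, []).append((int(start), int(end)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for rep, ivals in raw.items():
            merged: list[list[int]] = []
            for s, e in sorted(ivals):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[rep] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[rep] = np.array([m[1] for m in merged], dtype=np.int64)

    def intervals(self, replicon: Optional[str] = None) -> list[tuple[str, int, int]]:
        out = []
        for rep in sorted(self._starts):
            if replicon is not None and rep != replicon:
                continue
            out.extend((rep, int(s), int(e)) for s, e in zip(self._starts[rep], self._ends[rep]))
        return out

    def overlaps(self, replicon: str, start: int, end: int) -> bool:
        """True if [start, end) intersects any mask interval on ``replicon``."""
        if replicon not in self._starts:
            return False
        starts, ends = self._starts[replicon], self._ends[replicon]
        i = np.searchsorted(starts, end, side="left")
        return bool(i > 0 and ends[i - 1] > start)

    def overlaps_many(self, replicon: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorised ``overlaps`` for parallel arrays of half-open intervals."""
        if replicon not in self._starts:
            return np.zeros(len(starts), dtype=bool)
        ms, me = self._starts[replicon], self._ends[replicon]
        i = np.searchsorted(ms, ends, side="left")
        hit = i > 0
        hit[hit] = me[i[hit] - 1] > starts[hit]
        return hit

    def position_mask(self, replicon: str, length: int) -> np.ndarray:
        """Boolean array of shape (length,), True at masked positions."""
        m = np.zeros(length, dtype=bool)
        if replicon in self._starts:
            for s, e in zip(self._starts[replicon], self._ends[replicon]):
                m[max(0, s):min(length, e)] = True
        return m

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())


@dataclass
class GeneAnnotation:
    """Gene borders: (id, replicon, start, end, strand), 0-based half-open."""

    genes: pd.DataFrame  # columns: id, replicon, start, end, strand

    def __post_init__(self):
        req = {"id", "replicon", "start", "end", "strand"}
        missing = req - set(self.genes.columns)
        if missing:
            raise ReferenceError(f"annotation missing columns: {sorted(missing)}")
        if self.genes["id"].duplicated().any():
            raise ReferenceError("duplicate gene ids in annotation")
        if (self.genes["start"] >= self.genes["end"]).any():
            raise ReferenceError("gene with start >= end")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ReferenceBundle:
    """Everything downstream statistics need to know about the reference."""

    replicons: dict[str, Replicon]
    annotation: Optional[GeneAnnotation] = None
    masks: MaskSet = field(default_factory=MaskSet)
    ter_sites: list[TerSite] = field(default_factory=list)
    chi_sites: list[OrientedSite] = field(default_factory=list)
    gcs_sites: list[OrientedSite] = field(default_factory=list)
    ori_position: Optional[int] = None

    @property
    def chromosome(self) -> Replicon:
        for rep in self.replicons.values():
            if rep.role == "chromosome":
                return rep
        raise ReferenceError("bundle has no chromosome replicon")

    @property
    def plasmid(self) -> Optional[Replicon]:
        plasmids = [r for r in self.replicons.values() if r.role == "plasmid"]
        if len(plasmids) > 1:
            raise ReferenceError("bundle has more than one plasmid replicon")
        return plasmids[0] if plasmids else None


# ---------------------------------------------------------------------------
# I/O


def read_gff_genes(path: str | Path, known_replicons: Optional[set[str]] = None) -> GeneAnnotation:
    """Read gene records from a GFF3 file into a GeneAnnotation.

    Keeps rows of type ``gene``; coordinates converted from 1-based inclusive
    to 0-based half-open.  Gene ids come from the ``ID=`` (or ``locus_tag=``)
    attribute, falling back to a positional name.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ReferenceError(f"{path}: line {ln}: expected 9 GFF columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("ID") or attr.get("locus_tag") or f"gene_{ln}"
            rows.append((gid, seqid, int(start) - 1, int(end), strand))
    df = pd.DataFrame(rows, columns=["id", "replicon", "start", "end", "strand"])
    if known_replicons is not None:
        unknown = set(df["replicon"]) - known_replicons
        if unknown:
            raise ReferenceError(f"annotation refers to unknown replicons: {sorted(unknown)}")
    return GeneAnnotation(df.sort_values(["replicon", "start"], kind="stable").reset_index(drop=True))


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read (replicon, start, end) triples from a BED file (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def read_reference(
    fasta_path: str | Path,
    annotation_path: Optional[str | Path] = None,
    config: Optional[dict] = None,
) -> ReferenceBundle:
    """Load replicons from FASTA plus per-replicon roles/topology from config.

    ``config`` follows the pipeline YAML schema::

        replicons:
          <fasta record name>:
            role: chromosome | plasmid
            topology: circular | linear
            copy_number: 12
        ori: 0                      # chromosome origin, 0-based
        ter_sites:                  # 0-based half-open windows
          - {name: terA, start: 1327999, end: 1350000, blocked_strand: "-"}
        masks_bed: path/to/masks.bed
        gcs_bed: path/to/gcs.bed    # BED6; strand column used if present
    """
    config = config or {}
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ReferenceError(f"empty reference: {fasta_path}")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        raise ReferenceError("duplicate record names in reference FASTA")

    rep_cfg = config.get("replicons", {})
    replicons: dict[str, Replicon] = {}
    for i, rec in enumerate(records):
        cfg = rep_cfg.get(rec.id, {})
        role = cfg.get("role", "chromosome" if i == 0 else "plasmid")
        replicons[rec.id] = Replicon(
            name=rec.id,
            sequence=str(rec.seq).upper(),
            topology=cfg.get("topology", "circular"),
            copy_number=int(cfg.get("copy_number", 1)),
            role=role,
        )

    annotation = None
    if annotation_path is not None:
        annotation = read_gff_genes(annotation_path, known_replicons=set(replicons))

    masks = MaskSet()
    if config.get("masks_bed"):
        masks = MaskSet(read_bed_intervals(config["masks_bed"]))
    elif config.get("masks"):
        masks = MaskSet((m["replicon"], m["start"], m["end"]) for m in config["masks"])

    ter_sites = [
        TerSite(t["name"], int(t["start"]), int(t["end"]), t["blocked_strand"])
        for t in config.get("ter_sites", [])
    ]

    gcs_sites: list[OrientedSite] = []
    if config.get("gcs_bed"):
        chrom = next(n for n, r in replicons.items() if r.role == "chromosome")
        with open(config["gcs_bed"]) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                strand = parts[5] if len(parts) > 5 else "+"
                gcs_sites.append(OrientedSite(parts[0] if parts[0] else chrom, int(parts[1]), strand))

    return ReferenceBundle(
        replicons=replicons,
        annotation=annotation,
        masks=masks,
        ter_sites=ter_sites,
        gcs_sites=gcs_sites,
        ori_position=config.get("ori"),
    )


# ---------------------------------------------------------------------------
# Motif scanning


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def scan_motif(
    bundle_or_replicon: ReferenceBundle | Replicon,
    motif: str = CHI_MOTIF,
    masks: Optional[MaskSet] = None,
) -> list[OrientedSite]:
    """Find all occurrences of ``motif`` on both strands, outside masks.

    Plus-strand hits are occurrences of the motif itself; minus-strand hits
    are occurrences of its reverse complement, reported at the 0-based start
    of the matched 8-mer on the plus strand.  Circular replicons are also
    scanned across the origin junction (positions reduced modulo length).
    A site is masked if any base of its motif overlaps a mask interval.
    """
    motif = motif.upper()
    if len(motif) < 4:
        raise ReferenceError("motif too short (need >= 4 bases)")
    if set(motif) - _DNA:
        raise ReferenceError(f"motif contains non-DNA characters: {motif!r}")
    rc = reverse_complement(motif)
    k = len(motif)

    if isinstance(bundle_or_replicon, Replicon):
        replicons: Sequence[Replicon] = [bundle_or_replicon]
    else:
        replicons = list(bundle_or_replicon.replicons.values())
        if masks is None:
            masks = bundle_or_replicon.masks

    sites: list[OrientedSite] = []
    for rep in replicons:
        seq = rep.sequence.upper()
        search = seq + seq[: k - 1] if rep.circular else seq
        hits: set[tuple[int, str]] = set()
        for pos in _find_all(search, motif):
            hits.add((pos % rep.length, "+"))
        if rc != motif:
            for pos in _find_all(search, rc):
                hits.add((pos % rep.length, "-"))
        for pos, strand in hits:
            if masks is not None and masks.overlaps(rep.name, pos, pos + k):
                # circular wrap: a motif crossing the junction overlaps [pos, L) and [0, ...)
                continue
            if masks is not None and rep.circular and pos + k > rep.length:
                if masks.overlaps(rep.name, 0, (pos + k) % rep.length):
                    continue
            sites.append(OrientedSite(rep.name, pos, strand))
    sites.sort(key=lambda s: (s.replicon, s.position, s.strand))
    return sites


def gc_content(sequence: str) -> float:
    """Fraction of G+C among A/C/G/T bases (ambiguous bases ignored)."""
    seq = sequence.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


# ---------------------------------------------------------------------------
# Replichores and intergenic classes


def assign_replichore(
    bundle: ReferenceBundle,
    ori_position: int,
    ter_midpoint: int,
) -> pd.DataFrame:
    """Label chromosome genes by replichore and co-orientation with replication.

    The circular chromosome is split at ``ori_position`` and ``ter_midpoint``
    into the rightward arc (ori -> ter in increasing coordinates, where the
    fork moves 5'->3' along the plus strand) and the leftward arc.  A gene is
    assigned by its midpoint; a gene co-directed with its fork's direction of
    travel is labeled ``codirected``, otherwise ``opposite``.  Midpoints that
    coincide exactly with ori or the ter midpoint go to the rightward arc.
    """
    chrom = bundle.chromosome
    L = chrom.length
    if bundle.annotation is None:
        raise ReferenceError("bundle has no annotation")
    genes = bundle.annotation.genes
    genes = genes[genes["replicon"] == chrom.name]

    ori = ori_position % L
    ter = ter_midpoint % L

    def on_right_arc(mid: float) -> bool:
        # rightward arc = half-open arc [ori, ter) walking in increasing coords
        a = (mid - ori) % L
        span = (ter - ori) % L
        return a < span or mid % L == ter  # tie at ter -> rightward

    rows = []
    for _, g in genes.iterrows():
        mid = (g["start"] + g["end"]) / 2 % L
        right = on_right_arc(mid)
        replichore = "rightward" if right else "leftward"
        fork_strand = "+" if right else "-"  # leading-strand template direction
        orientation = "codirected" if g["strand"] == fork_strand else "opposite"
        rows.append((g["id"], replichore, orientation))
    return pd.DataFrame(rows, columns=["id", "replichore", "orientation"])


_INTERGENIC_CLASSES = {
    ("+", "+"): "co_forward",
    ("-", "-"): "co_reverse",
    ("+", "-"): "convergent",
    ("-", "+"): "divergent",
}


def classify_intergenic(
    annotation: GeneAnnotation,
    max_gap: int = 500,
    pad: int = 100,
) -> pd.DataFrame:
    """Classify short intergenic gaps by the orientation of flanking genes.

    For each pair of adjacent genes on the same replicon with a gap shorter
    than ``max_gap``, the gap is extended by ``pad`` nt into each flanking
    gene and labeled divergent (<- ->), convergent (-> <-), co_forward
    (-> ->) or co_reverse (<- <-).  Overlapping adjacent genes are skipped.
    """
    rows = []
    for rep, sub in annotation.genes.groupby("replicon"):
        sub = sub.sort_values("start", kind="stable").reset_index(drop=True)
        for i in range(len(sub) - 1):
            a, b = sub.iloc[i], sub.iloc[i + 1]
            gap = b["start"] - a["end"]
            if gap < 0:
                continue  # overlapping genes: interval skipped
            if gap >= max_gap:
                continue
            cls = _INTERGENIC_CLASSES[(a["strand"], b["strand"])]
            rows.append(
                (rep, max(0, a["end"] - pad), b["start"] + pad, cls, a["id"], b["id"])
            )
    return pd.DataFrame(
        rows, columns=["replicon", "start", "end", "class", "left_gene", "right_gene"]
    )
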