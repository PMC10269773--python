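"""Reverse-complement remapping of references, sites, and counts.

Flipping the genome is a pure relabeling: position p becomes L - 1 - p,
strands swap, an 8-mer starting at p starts at L - p - 8, and per-strand
count arrays swap and reverse.  Every orientation-aware statistic in this
package is invariant under this transformation; the helpers here build the
flipped objects so that invariance can be asserted exactly.
"""

from __future__ import annotations

from Bio.Seq import reverse_complement

from .reads import StrandCounts
from .reference import (
    GeneAnnotation,
    MaskSet,
    OrientedSite,
    ReferenceBundle,
    Replicon,
    TerSite,
)


def flip_site(site: OrientedSite, length: int, motif_length: int = 8) -> OrientedSite:
    return OrientedSite(
        replicon=site.replicon,
        position=length - site.position - motif_length,
        strand="-" if site.strand == "+" else "+",
    )


def flip_ter(t: TerSite, length: int) -> TerSite:
    return TerSite(
        name=t.name,
        start=length - t.end,
        end=length - t.start,
        blocked_strand="-" if t.blocked_strand == "+" else "+",
    )


def flip_bundle(bundle: ReferenceBundle, motif_length: int = 8) -> ReferenceBundle:
    reps = {
        name: Replicon(
            name=rep.name,
            sequence=reverse_complement(rep.sequence),
            topology=rep.topology,
            copy_number=rep.copy_number,
            role=rep.role,
        )
        for name, rep in bundle.replicons.items()
    }
    L = bundle.chromosome.length
    masks = MaskSet(
        (rep, reps[rep].length - e, reps[rep].length - s) for rep, s, e in bundle.masks.intervals()
    )
    annotation = None
    if bundle.annotation is not None:
        genes = bundle.annotation.genes.copy()
        lengths = genes["replicon"].map(lambda r: reps[r].length)
        s, e = genes["start"].copy(), genes["end"].copy()
        genes["start"] = lengths - e
        genes["end"] = lengths - s
        genes["strand"] = genes["strand"].map({"+": "-", "-": "+"})
        annotation = GeneAnnotation(genes.sort_values(["replicon", "start"]).reset_index(drop=True))
    return ReferenceBundle(
        replicons=reps,
        annotation=annotation,
        masks=masks,
        ter_sites=[flip_ter(t, L) for t in bundle.ter_sites],
        chi_sites=sorted(flip_site(s_, L, motif_length) for s_ in bundle.chi_sites),
        gcs_sites=[
            OrientedSite(s_.replicon, L - s_.position - 1, s_.strand) for s_ in bundle.gcs_sites
        ],
        ori_position=None if bundle.ori_position is None else (L - bundle.ori_position) % L,
    )


def flip_counts(counts: StrandCounts) -> StrandCounts:
    flipped = {
        rep: {"+": d["-"][::-1].copy(), "-": d["+"][::-1].copy()}
        for rep, d in counts.counts.items()
    }
    return StrandCounts(flipped, counts.total_aligned, counts.total_input)
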