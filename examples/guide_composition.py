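"""Describe what the pAgo is loaded with: lengths, logo, GC content.

Prints the guide length spectrum, the positional nucleotide frequencies
(reads > 16 nt, truncated to 17 nt), and the GC profile of the guides and
their genomic flanks relative to the genome mean.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

import numpy as np

import smdnamap as m
from smdnamap.simulate import GenerativeConfig, build_intensity, build_reference, sample_reads

cfg = GenerativeConfig(seed=4, n_reads=60_000, genome_length=150_000, chi_count=20,
                       gcs_count=4, ter_sites=[], cfx_ter_fraction_fold=None)

with TemporaryDirectory() as td:
    bundle, truth = build_reference(cfg)
    lam = build_intensity(bundle, truth, cfg, cfx=False)
    fq = Path(td) / "reads.fastq"
    sample_reads(bundle, lam, cfg, fq)
    reads = m.preprocess_reads(fq, adapter=cfg.adapter)
    records = m.align_exact(reads, bundle).records

    hist = m.length_histogram(reads)
    print("guide length histogram:", hist.counts)
    print(f"modal length {hist.modal_length} nt; "
          f"{hist.fraction_in_range * 100:.1f}% within 14-19 nt")

    logo = m.logo_matrix(reads)
    print(f"\nnucleotide frequencies over positions 1-17 ({logo.n_reads} reads):")
    print(logo.frequencies.round(3).head(5).to_string())

    gp = m.gc_profile(records, bundle, flank=20)
    print(f"\ngenome mean GC: {gp.genome_mean_gc * 100:.1f}%")
    inside = (gp.positions >= 0) & (gp.positions < 14)
    print(f"mean guide GC (positions 1-14): {np.nanmean(gp.gc_fraction[inside]) * 100:.1f}%")
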