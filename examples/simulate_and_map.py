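"""Simulate a small smDNA library and map it back to its reference.

Builds a 120-kb chromosome with planted ter windows and Chi sites, draws a
40k-read guide library from the biogenesis model, trims and aligns it, and
prints the library accounting plus the ter-targeting summary.  The strand
asymmetry printed for each ter site is the excess of the 3'-terminated
(fork-blocked) strand over its complement — the RecBCD-processing signature.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

import smdnamap as m
from smdnamap.simulate import GenerativeConfig, build_intensity, build_reference, sample_reads

cfg = GenerativeConfig(
    seed=1,
    n_reads=40_000,
    genome_length=120_000,
    chi_count=24,
    gcs_count=6,
    ter_sites=[m.TerSite("terA", 34_000, 35_500, "-"), m.TerSite("terC", 41_000, 42_500, "+")],
    ter_chi_distance=1_000,
    ter_peak_height=4.0,
    cfx_ter_fraction_fold=None,
)

with TemporaryDirectory() as td:
    bundle, truth = build_reference(cfg)
    lam = build_intensity(bundle, truth, cfg, cfx=False)
    fastq = Path(td) / "reads.fastq"
    sample_reads(bundle, lam, cfg, fastq)

    reads = m.preprocess_reads(fastq, adapter=cfg.adapter)
    print("preprocessing:", reads.log)

    result = m.align_exact(reads, bundle)
    print(f"aligned {result.counts.total_aligned} reads "
          f"({result.n_unaligned} unaligned, {result.n_multimapped} multi-mapped)")

    report = m.ter_fraction(result.counts, bundle.ter_sites, bundle.chromosome.name)
    print("\nter window targeting (percent of chromosome-mapped reads):")
    print(report.table.to_string(index=False))
    for t in bundle.ter_sites:
        asym = m.ter_strand_asymmetry(report, t)
        print(f"{t.name}: blocked-strand asymmetry = {asym:.2f} (planted a = {cfg.strand_asymmetry})")
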