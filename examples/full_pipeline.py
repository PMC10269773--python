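"""Run the whole pipeline from one config and read back the summary JSON.

Equivalent to `smdnamap run-all --config demo.yaml --outdir demo_run` on
the command line; every stage output (TSV/BED/bedGraph/JSON) plus a
checksummed run manifest lands in the output directory.
"""

import json
from pathlib import Path
from tempfile import TemporaryDirectory

import smdnamap as m

config = {
    "seed": 5,
    "simulate": {
        "n_reads": 20_000,
        "genome_length": 120_000,
        "chi_count": 24,
        "gcs_count": 6,
        "ter_sites": [
            {"name": "terA", "start": 34_000, "end": 35_500, "blocked_strand": "-"},
            {"name": "terC", "start": 41_000, "end": 42_500, "blocked_strand": "+"},
        ],
        "ter_chi_distance": 1_000,
        "ter_peak_height": 4.0,
        "cfx_ter_fraction_fold": 2.0,
        "chi_drop_extent": 3_000,
        "plasmid_length": 3_000,
    },
    "analysis": {
        "metaplot": {"half_width": 20_000, "flank": [12_000, 20_000]},
        "strand_ratio": {"window": 20_000, "step": 5_000},
        "enrichment": {"n_permutations": 1_000},
    },
}

with TemporaryDirectory() as td:
    outdir = Path(td) / "demo_run"
    manifest = m.run_pipeline(config, outdir=outdir)
    print("\nstages completed:", ", ".join(sorted(manifest.stages)))

    summary = json.loads((outdir / "summary.json").read_text())
    print("\nchi drop percent:", {k: round(v, 1) for k, v in summary["chi_drop_percent"].items()})
    print("plasmid enrichment fold:",
          {k: round(v, 1) for k, v in summary["plasmid_enrichment_fold"].items()})
    print("enrichment test:", summary["chi_gcs_enrichment"]["t_statistic"],
          summary["chi_gcs_enrichment"]["p_value"])
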