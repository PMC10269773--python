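"""Shared fixtures: a small simulated ±Cfx study used across test modules.

The small study uses a 120-kb circular chromosome with ter windows, Chi
sites, GCSs and a plasmid, scaled so a full simulate-align round trip runs
in a few seconds.  Session scope: the same libraries back many read-only
assertions.
"""

from __future__ import annotations

import numpy as np
import pytest

import smdnamap as m
from smdnamap.simulate import GenerativeConfig, build_intensity, build_reference, sample_reads


def small_config(**overrides) -> GenerativeConfig:
    base = dict(
        seed=9,
        n_reads=40_000,
        genome_length=120_000,
        gc_fraction=0.51,
        chi_count=24,
        gcs_count=6,
        gcs_min_distance=800,
        gcs_max_distance=2_000,
        ter_sites=[
            m.TerSite("terA", 34_000, 35_500, "-"),
            m.TerSite("terC", 41_000, 42_500, "+"),
        ],
        ter_chi_distance=1_000,
        ter_peak_height=4.0,
        cfx_ter_fraction_fold=2.0,
        chi_drop_extent=3_000,
        plasmid_length=3_000,
    )
    base.update(overrides)
    return GenerativeConfig(**base)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """Bundle, ground truth, and aligned ±Cfx counts for the small study."""
    tmp = tmp_path_factory.mktemp("small_study")
    cfg = small_config()
    bundle, truth = build_reference(cfg)
    counts = {}
    records = {}
    for cond in ("ctrl", "cfx"):
        cfx = cond == "cfx"
        lam = build_intensity(bundle, truth, cfg, cfx=cfx)
        fastq = tmp / f"{cond}.fastq"
        sample_reads(bundle, lam, cfg, fastq, truth=truth, cfx=cfx)
        rs = m.preprocess_reads(fastq, adapter=cfg.adapter)
        res = m.align_exact(rs, bundle)
        counts[cond] = res.counts
        records[cond] = res.records
    return {
        "config": cfg,
        "bundle": bundle,
        "truth": truth,
        "counts": counts,
        "records": records,
        "tmp": tmp,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_counts(arrays: dict[str, dict[str, np.ndarray]], total_input=None) -> m.StrandCounts:
    """Build a StrandCounts from raw arrays (unit-test scaffolding)."""
    total = int(sum(a.sum() for d in arrays.values() for a in d.values()))
    return m.StrandCounts(
        {r: {s: np.asarray(a, dtype=np.int64) for s, a in d.items()} for r, d in arrays.items()},
        total_aligned=total,
        total_input=total if total_input is None else total_input,
    )
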