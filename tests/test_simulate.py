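"""Generative model: planted references, intensity closed forms, sampling."""

import numpy as np
import pytest

import smdnamap as m
from smdnamap.simulate import (
    GenerativeConfig,
    build_intensity,
    build_reference,
    sample_reads,
)
from conftest import small_config


class TestBuildReference:
    def test_zero_chi_means_zero_motifs(self):
        cfg = GenerativeConfig(
            seed=3, n_reads=0, genome_length=50_000, chi_count=0, gcs_count=0, ter_sites=[]
        )
        bundle, truth = build_reference(cfg)
        assert truth.chi_sites == []
        assert m.scan_motif(bundle.chromosome) == []

    def test_scan_recovers_exactly_the_planted_sites(self):
        cfg = small_config(chi_count=20, seed=21)
        bundle, truth = build_reference(cfg)
        got = {(s.position, s.strand) for s in m.scan_motif(bundle.chromosome)}
        assert got == {(s.position, s.strand) for s in truth.chi_sites}
        assert len(got) == 20

    def test_realized_gc_matches_request(self):
        cfg = GenerativeConfig(
            seed=5, n_reads=0, genome_length=300_000, gc_fraction=0.51,
            chi_count=0, gcs_count=0, ter_sites=[],
        )
        bundle, _ = build_reference(cfg)
        assert abs(m.gc_content(bundle.chromosome.sequence) - 0.51) < 0.01

    def test_plasmid_carries_copy_number(self):
        bundle, _ = build_reference(small_config())
        assert bundle.plasmid.copy_number == 12
        assert bundle.plasmid.length == 3_000

    def test_gcs_sites_have_an_upstream_chi_within_the_planted_range(self):
        cfg = small_config(seed=33)
        bundle, truth = build_reference(cfg)
        L = cfg.genome_length
        for g in truth.gcs_sites:
            near = [
                s for s in truth.chi_sites
                if (s.strand == "+" and 0 < (g.position - s.position - 8) % L <= cfg.gcs_max_distance)
                or (s.strand == "-" and 0 < (s.position - g.position) % L <= cfg.gcs_max_distance)
            ]
            assert near, f"GCS at {g.position} lacks a planted nearby Chi"


class TestIntensityModel:
    def test_all_modifiers_unity_gives_flat_intensity(self):
        cfg = small_config(
            ter_peak_height=1.0, strand_asymmetry=1.0, chi_drop=0.0, chi_drop_cfx=None,
            gcs_enrichment=1.0, cfx_ter_fraction_fold=None,
        )
        bundle, truth = build_reference(cfg)
        lam = build_intensity(bundle, truth, cfg, cfx=True)
        for strand in ("+", "-"):
            assert np.allclose(lam[bundle.chromosome.name][strand], cfg.background_rate)

    def test_chi_ramp_closed_form(self):
        w, delta, beta = 1_000, 0.5, 1.0
        cfg = GenerativeConfig(
            seed=7, n_reads=0, genome_length=30_000, chi_count=1, gcs_count=0,
            ter_sites=[], chi_drop=delta, chi_drop_cfx=None, chi_drop_extent=w,
            background_rate=beta, cfx_ter_fraction_fold=None,
        )
        bundle, truth = build_reference(cfg)
        (site,) = truth.chi_sites
        lam = build_intensity(bundle, truth, cfg, cfx=False)[bundle.chromosome.name]
        L = cfg.genome_length
        if site.strand == "+":
            co, c = lam["+"], site.position
            assert co[(c - 1) % L] == pytest.approx((1 - delta) * beta)
            assert co[(c - w - 1) % L] == pytest.approx(beta)
            assert co[(c - w // 2 - 1) % L] == pytest.approx((1 - delta / 2) * beta, rel=1e-2)
        else:
            co, c3 = lam["-"], site.position + 8  # 5' side of a minus site is rightward
            assert co[c3 % L] == pytest.approx((1 - delta) * beta)
            assert co[(c3 + w) % L] == pytest.approx(beta)

    def test_matches_brute_force_recomputation(self):
        """Independent per-position loop over all sites reproduces the arrays."""
        cfg = small_config(seed=17, n_reads=0, cfx_ter_fraction_fold=None)
        bundle, truth = build_reference(cfg)
        for cfx in (False, True):
            lam = build_intensity(bundle, truth, cfg, cfx=cfx)[bundle.chromosome.name]
            oracle = _intensity_oracle(bundle, truth, cfg, cfx)
            for strand in ("+", "-"):
                assert np.allclose(lam[strand], oracle[strand], rtol=1e-12)

    def test_cfx_ter_fraction_fold_is_planted_exactly_in_expectation(self):
        cfg = small_config(seed=17)
        bundle, truth = build_reference(cfg)
        lam0 = build_intensity(bundle, truth, cfg, cfx=False)[bundle.chromosome.name]
        lam1 = build_intensity(bundle, truth, cfg, cfx=True)[bundle.chromosome.name]
        t0 = sum(a.sum() for a in lam0.values())
        t1 = sum(a.sum() for a in lam1.values())
        for t in cfg.ter_sites:
            w0 = lam0[t.blocked_strand][t.start: t.end].sum() / t0
            w1 = lam1[t.blocked_strand][t.start: t.end].sum() / t1
            assert w1 / w0 == pytest.approx(cfg.cfx_ter_fraction_fold, rel=1e-9)


def _intensity_oracle(bundle, truth, cfg, cfx):
    """Straightforward loop-based reimplementation of the intensity model."""
    L = bundle.chromosome.length
    k = 8
    delta = cfg.delta(cfx)
    lam = {s: np.full(L, cfg.background_rate) for s in ("+", "-")}
    chi = {"+": sorted(s.position for s in truth.chi_sites if s.strand == "+"),
           "-": sorted(s.position for s in truth.chi_sites if s.strand == "-")}
    # chi ramps
    for c in chi["+"]:
        for j in range(cfg.chi_drop_extent):
            p = (c - 1 - j) % L
            lam["+"][p] *= 1 - delta + delta * j / cfg.chi_drop_extent
    for c in chi["-"]:
        for j in range(cfg.chi_drop_extent):
            p = (c + k + j) % L
            lam["-"][p] *= 1 - delta + delta * j / cfg.chi_drop_extent
    # gcs intervals (+Cfx only)
    if cfx and cfg.gcs_enrichment != 1.0:
        for g in (s.position for s in truth.gcs_sites):
            ups = [c for c in chi["+"]]
            if ups:
                c = min(ups, key=lambda c: (g - k - c) % L)
                span = (g - (c + k)) % L
                for j in range(span):
                    lam["+"][(c + k + j) % L] *= cfg.gcs_enrichment
            downs = [c for c in chi["-"]]
            if downs:
                c = min(downs, key=lambda c: (c - g - 1) % L)
                span = (c - g) % L
                for j in range(span):
                    lam["-"][(g + j) % L] *= cfg.gcs_enrichment
    # ter peaks (fixed height; the fold-solving branch is checked separately)
    for t in truth.ter_sites:
        if t.blocked_strand == "-":
            cands = [c for c in chi["-"]]
            c = min(cands, key=lambda c: (c - t.end) % L)
            span = ((c + k) - t.start) % L
            start = t.start
        else:
            cands = [c for c in chi["+"]]
            c = min(cands, key=lambda c: (t.start - k - c) % L)
            span = (t.end - c) % L
            start = c
        other = "+" if t.blocked_strand == "-" else "-"
        for j in range(span):
            lam[t.blocked_strand][(start + j) % L] *= cfg.ter_peak_height
            lam[other][(start + j) % L] *= cfg.ter_peak_height / cfg.strand_asymmetry
    return lam


class TestSampling:
    def test_zero_reads_gives_empty_fastq(self, tmp_path):
        cfg = small_config(n_reads=0)
        bundle, truth = build_reference(cfg)
        lam = build_intensity(bundle, truth, cfg, cfx=False)
        out = tmp_path / "empty.fastq"
        rec = sample_reads(bundle, lam, cfg, out)
        assert len(rec) == 0 and out.read_text() == ""

    def test_uniform_intensity_bin_counts_within_poisson_bound(self, tmp_path):
        cfg = GenerativeConfig(
            seed=6, n_reads=100_000, genome_length=100_000, chi_count=0, gcs_count=0,
            ter_sites=[], chi_drop=0.0, chi_drop_cfx=None, gcs_enrichment=1.0,
            ter_peak_height=1.0, strand_asymmetry=1.0, cfx_ter_fraction_fold=None,
            plasmid_length=1_000, plasmid_copy_number=1, plasmid_preference=1.0,
        )
        bundle, truth = build_reference(cfg)
        lam = build_intensity(bundle, truth, cfg, cfx=False)
        rec = sample_reads(bundle, lam, cfg, tmp_path / "u.fastq")
        chrom_reads = rec[rec["replicon"] == 0]
        bins = np.bincount(chrom_reads["position"] // 10_000, minlength=10)
        expected = len(chrom_reads) / 10 / 2  # per strand per bin
        for s in (0, 1):
            b = np.bincount(
                chrom_reads["position"][chrom_reads["strand"] == s] // 10_000, minlength=10
            )
            assert np.all(np.abs(b - expected) < 4 * np.sqrt(expected))
        assert bins.sum() == len(chrom_reads)

    def test_reads_match_reference_at_recorded_positions(self, tmp_path):
        from Bio.Seq import reverse_complement

        cfg = small_config(n_reads=500, adapter="")
        bundle, truth = build_reference(cfg)
        lam = build_intensity(bundle, truth, cfg, cfx=False)
        fq = tmp_path / "r.fastq"
        rec = sample_reads(bundle, lam, cfg, fq)
        seqs = [l.strip() for i, l in enumerate(fq.read_text().splitlines()) if i % 4 == 1]
        reps = list(lam.keys())
        for row, seq in zip(rec, seqs):
            ref = bundle.replicons[reps[row["replicon"]]].sequence
            Lr, p, n = len(ref), int(row["position"]), int(row["length"])
            if row["strand"] == 0:
                expect = "".join(ref[(p + j) % Lr] for j in range(n))
            else:
                expect = reverse_complement("".join(ref[(p - n + 1 + j) % Lr] for j in range(n)))
            assert seq == expect

    def test_fastq_is_byte_identical_for_same_seed(self, tmp_path):
        cfg = small_config(n_reads=2_000)
        bundle, truth = build_reference(cfg)
        lam = build_intensity(bundle, truth, cfg, cfx=False)
        a, b = tmp_path / "a.fastq", tmp_path / "b.fastq"
        sample_reads(bundle, lam, cfg, a)
        sample_reads(bundle, lam, cfg, b)
        assert a.read_bytes() == b.read_bytes()

    def test_length_distribution_recovered(self, small_study):
        rec = small_study["truth"].read_records[False]
        cfg = small_study["config"]
        n = len(rec)
        for length, p in cfg.length_distribution.items():
            got = np.mean(rec["length"] == length)
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(got - p) < 4 * sd

    def test_ground_truth_records_sum_to_n_reads(self, small_study):
        for cfx in (False, True):
            assert len(small_study["truth"].read_records[cfx]) == small_study["config"].n_reads
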