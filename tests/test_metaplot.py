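"""Anchor metaplots, background/drop, Chi-GCS classes, enrichment test."""

import numpy as np
import pandas as pd
import pytest

import smdnamap as m
from smdnamap.metaplot import (
    MetaplotError,
    anchored_profile,
    classify_chi_gcs,
    normalize_and_drop,
    relative_density_enrichment,
)
from smdnamap.reference import MaskSet, OrientedSite
from conftest import make_counts


def chrom_counts(plus, minus):
    return make_counts({"chrom": {"+": np.asarray(plus), "-": np.asarray(minus)}})


def site(pos, strand="+"):
    return OrientedSite("chrom", pos, strand)


class TestAnchoredProfile:
    def test_uniform_counts_flat_profile_with_F_equal_R(self):
        counts = chrom_counts(np.full(20_000, 4), np.full(20_000, 4))
        prof = anchored_profile(counts, [site(5_000), site(12_000, "-")], 2_000, smoothing=1)
        scale = 4 * 1e9 / counts.total_aligned
        assert np.allclose(prof.mean_density_F, scale)
        assert np.allclose(prof.mean_density_R, scale)

    def test_plus_anchor_peak_lands_at_positive_offset(self):
        plus = np.zeros(20_000, dtype=np.int64)
        plus[5_010] = 7
        counts = chrom_counts(plus, np.zeros(20_000, dtype=np.int64))
        counts.total_aligned = 1_000
        prof = anchored_profile(counts, [site(5_000, "+")], 100, smoothing=1)
        peak = prof.offsets[np.nanargmax(prof.mean_density_F)]
        assert peak == 10
        assert np.nanmax(prof.mean_density_R) == 0

    def test_minus_anchor_is_flip_symmetric_to_plus(self):
        """Counts 10 bp 3' of a minus anchor give the identical F profile."""
        plus = np.zeros(20_000, dtype=np.int64)
        plus[5_010] = 7
        cp = chrom_counts(plus, np.zeros(20_000, dtype=np.int64))
        minus = np.zeros(20_000, dtype=np.int64)
        minus[5_000 + 7 - 10] = 7  # anchor frame of a minus site starts at position+7
        cm = chrom_counts(np.zeros(20_000, dtype=np.int64), minus)
        p1 = anchored_profile(cp, [site(5_000, "+")], 100, smoothing=1)
        p2 = anchored_profile(cm, [site(5_000, "-")], 100, smoothing=1)
        assert np.array_equal(p1.mean_density_F, p2.mean_density_F, equal_nan=True)

    def test_matches_loop_based_oracle(self, rng):
        """Vectorised extraction equals a per-anchor per-offset python loop."""
        L, hw = 6_000, 300
        plus = rng.integers(0, 5, L)
        minus = rng.integers(0, 5, L)
        counts = chrom_counts(plus, minus)
        anchors = [site(int(rng.integers(0, L)), "+" if rng.random() < 0.5 else "-")
                   for _ in range(50)]
        mask = MaskSet([("chrom", 1_000, 1_200), ("chrom", 4_700, 4_750)])
        prof = anchored_profile(counts, anchors, hw, smoothing=1, masks=mask)

        scale = 1e9 / counts.total_aligned
        maskarr = mask.position_mask("chrom", L)
        offsets = np.arange(-hw, hw + 1)
        for oi in [0, 17, len(offsets) - 1, hw, hw - 93]:
            o = offsets[oi]
            f_vals, r_vals = [], []
            for a in anchors:
                if a.strand == "+":
                    p = (a.position + o) % L
                    f_arr, r_arr = plus, minus
                else:
                    p = (a.position + 7 - o) % L
                    f_arr, r_arr = minus, plus
                if maskarr[p]:
                    continue
                f_vals.append(f_arr[p] * scale)
                r_vals.append(r_arr[p] * scale)
            assert prof.mean_density_F[oi] == pytest.approx(np.mean(f_vals))
            assert prof.mean_density_R[oi] == pytest.approx(np.mean(r_vals))
            assert prof.n_valid_F[oi] == len(f_vals)

    def test_masked_anchors_are_dropped_and_all_masked_errors(self):
        counts = chrom_counts(np.ones(2_000, dtype=np.int64), np.ones(2_000, dtype=np.int64))
        mask = MaskSet([("chrom", 0, 2_000)])
        with pytest.raises(MetaplotError, match="masked"):
            anchored_profile(counts, [site(500)], 100, smoothing=1, masks=mask)


class TestNormalizeAndDrop:
    @staticmethod
    def _flat_profile(value=2.0, hw=50_000):
        counts = chrom_counts(np.full(120_000, 1), np.full(120_000, 1))
        prof = anchored_profile(counts, [site(60_000)], hw, smoothing=1)
        prof.mean_density_F = np.full_like(prof.mean_density_F, value)
        prof.mean_density_R = np.full_like(prof.mean_density_R, value)
        return prof

    def test_flat_profile_background_equals_value_and_zero_drop(self):
        prof = self._flat_profile(2.0)
        norm, drop = normalize_and_drop(prof)
        assert norm.background == pytest.approx(2.0)
        assert np.allclose(norm.normalized_F, 1.0)
        assert drop.drop_percent == pytest.approx(0.0)

    def test_minimum_of_0p6_gives_40_percent_drop(self):
        prof = self._flat_profile(1.0)
        center = len(prof.offsets) // 2
        prof.mean_density_F[center - 50] = 0.60
        _, drop = normalize_and_drop(prof)
        assert drop.drop_percent == pytest.approx(40.0)
        assert drop.minimum_offset == -50

    def test_minimum_outside_window_ignored(self):
        prof = self._flat_profile(1.0)
        center = len(prof.offsets) // 2
        prof.mean_density_F[center - 10_000] = 0.1  # far from the anchor
        _, drop = normalize_and_drop(prof, drop_window=2_000)
        assert drop.drop_percent == pytest.approx(0.0)

    def test_flank_wider_than_profile_errors(self):
        prof = self._flat_profile(1.0, hw=10_000)
        with pytest.raises(MetaplotError, match="half-width"):
            normalize_and_drop(prof, flank=(35_000, 50_000))

    def test_drop_recovery_is_monotone_in_planted_delta(self, tmp_path):
        """Recovered drops preserve the ordering of planted depths."""
        from conftest import small_config
        from smdnamap.simulate import build_intensity, build_reference, sample_reads

        drops = []
        for delta in (0.1, 0.2, 0.3, 0.4):
            cfg = small_config(
                seed=101, n_reads=150_000, chi_drop=delta, chi_drop_cfx=None,
                gcs_enrichment=1.0, cfx_ter_fraction_fold=None,
            )
            bundle, truth = build_reference(cfg)
            lam = build_intensity(bundle, truth, cfg, cfx=False)
            fq = tmp_path / f"d{delta}.fastq"
            sample_reads(bundle, lam, cfg, fq)
            rs = m.preprocess_reads(fq, adapter=cfg.adapter)
            counts = m.align_exact(rs, bundle).counts
            prof = anchored_profile(counts, bundle.chi_sites, 20_000, 400, bundle.masks)
            _, drop = normalize_and_drop(prof, flank=(12_000, 20_000))
            drops.append(drop.drop_percent)
        assert drops == sorted(drops)
        assert drops[0] > 5 and drops[-1] < 60


class TestClassifyChiGcs:
    def test_simple_downstream_adjacency(self):
        out = classify_chi_gcs([site(10_000, "+")], [site(12_000)], 100_000)
        assert out.iloc[0]["class"] == "downstream_gcs"
        assert out.iloc[0]["gcs_distance"] == 2_000

    def test_intervening_co_oriented_chi_blocks_adjacency(self):
        out = classify_chi_gcs(
            [site(10_000, "+"), site(11_000, "+")], [site(12_000)], 100_000
        ).set_index("position")
        assert out.loc[10_000, "class"] == "other"
        assert out.loc[11_000, "class"] == "downstream_gcs"

    def test_minus_strand_downstream_is_decreasing_coordinates(self):
        out = classify_chi_gcs([site(10_000, "-")], [site(8_000)], 100_000)
        assert out.iloc[0]["class"] == "downstream_gcs"
        # on a linear replicon a GCS 3' of nothing stays upstream-only
        out2 = classify_chi_gcs([site(10_000, "-")], [site(12_000)], 100_000, circular=False)
        assert out2.iloc[0]["class"] == "other"
        assert bool(out2.iloc[0]["upstream_gcs"])

    def test_classes_partition_the_chi_set(self, small_study):
        bundle = small_study["bundle"]
        out = classify_chi_gcs(bundle.chi_sites, bundle.gcs_sites, bundle.chromosome.length)
        assert len(out) == len(bundle.chi_sites)
        assert set(out["class"]) <= {"downstream_gcs", "other"}

    def test_matches_brute_force_pairwise_check(self, rng):
        L = 50_000
        for _ in range(20):
            chi = [site(int(p), "+" if rng.random() < 0.5 else "-")
                   for p in rng.choice(L, size=12, replace=False)]
            gcs = [site(int(p)) for p in rng.choice(L, size=5, replace=False)]
            out = classify_chi_gcs(chi, gcs, L).set_index(["position", "strand"])
            for c in chi:
                expected = "other"
                for g in gcs:
                    d = (g.position - c.position) % L if c.strand == "+" else (c.position - g.position) % L
                    if d == 0:
                        continue
                    blocked = any(
                        q.strand == c.strand and q.position != c.position
                        and 0 < ((q.position - c.position) % L if c.strand == "+" else (c.position - q.position) % L) < d
                        for q in chi
                    )
                    if not blocked:
                        expected = "downstream_gcs"
                        break
                assert out.loc[(c.position, c.strand), "class"] == expected


class TestEnrichment:
    @staticmethod
    def _classes(chi):
        return pd.DataFrame(
            [(s.position, s.strand, cls) for s, cls in chi],
            columns=["position", "strand", "class"],
        )

    def test_identical_libraries_give_unity_t_zero_p_one(self, rng):
        arr_p, arr_m = rng.integers(0, 9, 40_000), rng.integers(0, 9, 40_000)
        counts = chrom_counts(arr_p, arr_m)
        classes = self._classes(
            [(site(5_000), "downstream_gcs"), (site(9_000), "downstream_gcs"),
             (site(15_000), "other"), (site(22_000), "other"), (site(30_000, "-"), "other")]
        )
        res = relative_density_enrichment(counts, counts, classes, "chrom", seed=0,
                                          n_permutations=200)
        assert np.allclose(res.per_site["enrichment"], 1.0)
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_planted_boost_separates_groups(self, rng):
        """Doubling +Cfx counts 3' of downstream_gcs sites yields p < 0.05."""
        L = 200_000
        base_p = rng.integers(2, 10, L)
        base_m = rng.integers(2, 10, L)
        ds_sites = [site(int(p), "+") for p in range(5_000, 105_000, 5_000)]  # 20 sites
        other_sites = [site(int(p), "+") for p in range(110_000, 190_000, 4_000)]
        cfx_p = base_p.copy()
        for s in ds_sites:
            cfx_p[s.position: s.position + 4_000] *= 2  # gamma = 2 over the Chi->GCS span
        ctrl = chrom_counts(base_p, base_m)
        cfx = chrom_counts(cfx_p, base_m)
        classes = self._classes([(s, "downstream_gcs") for s in ds_sites]
                                + [(s, "other") for s in other_sites])
        res = relative_density_enrichment(cfx, ctrl, classes, "chrom", seed=0,
                                          n_permutations=2_000)
        gs = res.group_stats.set_index("class")
        assert gs.loc["downstream_gcs", "mean"] > gs.loc["other", "mean"]
        assert res.p_value < 0.05
        assert res.p_permutation < 0.05

    def test_small_group_skips_test_with_warning(self, rng):
        counts = chrom_counts(rng.integers(0, 9, 30_000), rng.integers(0, 9, 30_000))
        classes = self._classes([(site(5_000), "downstream_gcs"), (site(9_000), "other"),
                                 (site(15_000), "other")])
        res = relative_density_enrichment(counts, counts, classes, "chrom", seed=0,
                                          n_permutations=100)
        assert res.warning is not None
        assert np.isnan(res.t_statistic)

    def test_welch_t_matches_closed_form(self):
        """Package Welch statistic equals the hand-computed formula."""
        a = np.array([1.2, 1.5, 1.1, 1.7, 1.4])
        b = np.array([1.0, 0.9, 1.1, 1.05, 0.95])
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        from scipy import stats

        t_pkg, _ = stats.ttest_ind(a, b, equal_var=False)
        assert t_pkg == pytest.approx(t_hand, rel=1e-12)


class TestGcsNullProfile:
    def test_no_planted_gcs_effect_gives_flat_relative_profile(self, rng):
        """Both-strand relative density around GCSs is ~1 without enrichment."""
        n = 60_000
        ctrl = chrom_counts(rng.poisson(5, n), rng.poisson(5, n))
        cfx = chrom_counts(rng.poisson(5, n), rng.poisson(5, n))
        gcs = [site(int(p)) for p in rng.choice(n, size=12, replace=False)]
        offsets, rel = m.gcs_relative_profile(cfx, ctrl, gcs, half_width=5_000, smoothing=2_000)
        assert np.nanmax(np.abs(rel - 1.0)) < 0.1
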