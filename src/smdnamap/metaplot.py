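"""Anchor-site metaplots and Chi/GCS statistics.

A metaplot averages strand-specific smDNA density around a set of oriented
anchor sites after flipping every anchor into a common frame: positive
offsets are always the anchor's 3' side.  For a plus-strand anchor the
co-oriented (F) strand is the plus strand and offsets run with the genome
coordinate; for a minus-strand anchor the F strand is the minus strand and
offsets run against it.  The anchor point of a minus-strand site is the
last plus-strand base of its motif, so that reverse-complementing the
genome and relabeling strands leaves every profile exactly invariant.

Derived statistics:

* background normalization against remote flanks (default 35-50 kb on both
  sides) and the *drop* statistic — the percent decrease of the normalized
  density at its minimum near the anchor, the signature of RecBCD halting
  3'-strand degradation at Chi;
* Chi-GCS adjacency classes — a Chi site is ``downstream_gcs`` when a
  gyrase cleavage site lies on its 3' side with no co-oriented Chi in
  between;
* per-Chi-site +Cfx/-Cfx relative density over the first 5 kb of the
  3' side, compared between adjacency classes with a two-sided Welch t
  test (a seeded permutation p value is reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .reference import MaskSet, OrientedSite
from .reads import StrandCounts

MOTIF_LENGTH = 8  # Chi 8-mer; anchor frame for minus-strand sites


class MetaplotError(ValueError):
    pass


def _smooth_nan(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average ignoring NaNs (window in array steps)."""
    if window <= 1:
        return values.copy()
    kernel = np.ones(window)
    valid = np.isfinite(values)
    num = np.convolve(np.where(valid, values, 0.0), kernel, mode="same")
    den = np.convolve(valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


@dataclass
class MetaplotProfile:
    """Orientation-flipped mean density around anchors.

    ``mean_density_F``/``mean_density_R`` are smoothed per-offset means (in
    RPKM per base) over anchors for the co-oriented and opposite strands;
    raw (unsmoothed) means and per-offset contributing-anchor counts are
    kept for downstream estimators.
    """

    offsets: np.ndarray
    mean_density_F: np.ndarray
    mean_density_R: np.ndarray
    raw_F: np.ndarray
    raw_R: np.ndarray
    n_valid_F: np.ndarray
    n_valid_R: np.ndarray
    n_anchors: int
    smoothing_window: int


def anchored_profile(
    counts: StrandCounts,
    anchors: list[OrientedSite],
    half_width: int = 50_000,
    smoothing: int = 400,
    masks: Optional[MaskSet] = None,
    motif_length: int = MOTIF_LENGTH,
    chunk: int = 64,
) -> MetaplotProfile:
    """Position-wise mean density around anchors, flipped to anchor frame.

    Anchors whose motif overlaps a mask are excluded; for the remaining
    anchors, offsets that land on masked genome positions are excluded from
    that anchor's contribution (per-offset anchor counts are tracked so the
    mean stays unbiased near masked regions).
    """
    if not anchors:
        raise MetaplotError("no anchors")
    rep = anchors[0].replicon
    if any(a.replicon != rep for a in anchors):
        raise MetaplotError("anchors span multiple replicons")
    if masks is not None:
        anchors = [
            a for a in anchors if not masks.overlaps(rep, a.position, a.position + motif_length)
        ]
        if not anchors:
            raise MetaplotError("all anchors masked")

    plus = counts.counts[rep]["+"].astype(np.float64) * 1e9 / counts.total_aligned
    minus = counts.counts[rep]["-"].astype(np.float64) * 1e9 / counts.total_aligned
    L = len(plus)
    maskarr = masks.position_mask(rep, L) if masks is not None else np.zeros(L, dtype=bool)

    offsets = np.arange(-half_width, half_width + 1, dtype=np.int64)
    n_off = len(offsets)
    sum_F = np.zeros(n_off)
    sum_R = np.zeros(n_off)
    n_F = np.zeros(n_off, dtype=np.int64)
    n_R = np.zeros(n_off, dtype=np.int64)

    plus_anchor = np.array([a.position for a in anchors if a.strand == "+"], dtype=np.int64)
    minus_anchor = np.array(
        [a.position + motif_length - 1 for a in anchors if a.strand == "-"], dtype=np.int64
    )

    for points, sign, f_arr, r_arr in (
        (plus_anchor, 1, plus, minus),
        (minus_anchor, -1, minus, plus),
    ):
        for i in range(0, len(points), chunk):
            pts = points[i: i + chunk]
            pos = (pts[:, None] + sign * offsets[None, :]) % L
            ok = ~maskarr[pos]
            sum_F += np.where(ok, f_arr[pos], 0.0).sum(axis=0)
            sum_R += np.where(ok, r_arr[pos], 0.0).sum(axis=0)
            nv = ok.sum(axis=0)
            n_F += nv
            n_R += nv

    with np.errstate(invalid="ignore"):
        raw_F = np.where(n_F > 0, sum_F / np.maximum(n_F, 1), np.nan)
        raw_R = np.where(n_R > 0, sum_R / np.maximum(n_R, 1), np.nan)
    return MetaplotProfile(
        offsets=offsets,
        mean_density_F=_smooth_nan(raw_F, smoothing),
        mean_density_R=_smooth_nan(raw_R, smoothing),
        raw_F=raw_F,
        raw_R=raw_R,
        n_valid_F=n_F,
        n_valid_R=n_R,
        n_anchors=len(plus_anchor) + len(minus_anchor),
        smoothing_window=smoothing,
    )


@dataclass
class NormalizedProfile:
    profile: MetaplotProfile
    background: float
    normalized_F: np.ndarray
    normalized_R: np.ndarray


@dataclass
class DropStatistic:
    """Percent decrease of normalized F density at its minimum near the anchor."""

    drop_percent: float
    minimum: float
    minimum_offset: int
    window: int


def normalize_and_drop(
    profile: MetaplotProfile,
    flank: tuple[int, int] = (35_000, 50_000),
    drop_window: int = 2_000,
) -> tuple[NormalizedProfile, DropStatistic]:
    """Divide the smoothed F profile by its remote-flank background.

    Background is the mean smoothed co-oriented density over the two remote
    flanks (``-flank[1]..-flank[0]`` and ``+flank[0]..+flank[1]``); the drop
    statistic is ``(1 - min normalized density within +-drop_window) * 100``.
    """
    off = profile.offsets
    lo, hi = flank
    if hi > off.max():
        raise MetaplotError("profile half-width smaller than the background flank")
    sel = ((off >= lo) & (off <= hi)) | ((off <= -lo) & (off >= -hi))
    background = float(np.nanmean(profile.mean_density_F[sel]))
    if not np.isfinite(background) or background <= 0:
        raise MetaplotError("background density is zero or undefined")
    norm_F = profile.mean_density_F / background
    norm_R = profile.mean_density_R / background
    near = np.abs(off) <= drop_window
    vals = norm_F[near]
    idx = int(np.nanargmin(vals))
    minimum = float(vals[idx])
    return (
        NormalizedProfile(profile, background, norm_F, norm_R),
        DropStatistic(
            drop_percent=(1.0 - minimum) * 100.0,
            minimum=minimum,
            minimum_offset=int(off[near][idx]),
            window=drop_window,
        ),
    )


# ---------------------------------------------------------------------------
# Chi-GCS adjacency


def classify_chi_gcs(
    chi: list[OrientedSite],
    gcs: list[OrientedSite],
    genome_length: int,
    circular: bool = True,
) -> pd.DataFrame:
    """Partition Chi sites by the presence of an adjacent 3'-side GCS.

    A Chi site is ``downstream_gcs`` iff some GCS lies on its 3' side with
    no co-oriented Chi site strictly between them; all remaining sites are
    ``other``.  The complementary flag ``upstream_gcs`` (a GCS on the
    5' side before the previous co-oriented Chi) is emitted as well.  GCSs
    are treated as unstranded cleavage points.
    """
    gcs_pos = np.array(sorted(s.position for s in gcs), dtype=np.int64)
    out = []
    for strand in ("+", "-"):
        positions = np.array(sorted(s.position for s in chi if s.strand == strand), dtype=np.int64)
        n = len(positions)
        for i, c in enumerate(positions):
            # arc to the neighbouring co-oriented Chi in each direction of
            # the genome; "next" means the 3' direction of this strand
            if n == 1:
                arc_incr = arc_decr = genome_length
            elif circular:
                arc_incr = (positions[(i + 1) % n] - c) % genome_length
                arc_decr = (c - positions[(i - 1) % n]) % genome_length
            else:
                arc_incr = positions[i + 1] - c if i + 1 < n else genome_length - c
                arc_decr = c - positions[i - 1] if i > 0 else c
            arc_next = arc_incr if strand == "+" else arc_decr
            arc_prev = arc_decr if strand == "+" else arc_incr

            if strand == "+":
                d_down = (gcs_pos - c) % genome_length if circular else gcs_pos - c
                d_up = (c - gcs_pos) % genome_length if circular else c - gcs_pos
            else:
                d_down = (c - gcs_pos) % genome_length if circular else c - gcs_pos
                d_up = (gcs_pos - c) % genome_length if circular else gcs_pos - c
            d_down = d_down[d_down > 0] if len(d_down) else d_down
            d_up = d_up[d_up > 0] if len(d_up) else d_up
            down_dist = int(d_down.min()) if len(d_down) else None
            up_dist = int(d_up.min()) if len(d_up) else None
            has_down = down_dist is not None and down_dist < arc_next
            has_up = up_dist is not None and up_dist < arc_prev
            out.append(
                (
                    c,
                    strand,
                    "downstream_gcs" if has_down else "other",
                    down_dist if has_down else np.nan,
                    bool(has_up),
                )
            )
    return pd.DataFrame(
        out, columns=["position", "strand", "class", "gcs_distance", "upstream_gcs"]
    ).sort_values(["position", "strand"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# +-Cfx relative enrichment


def _circular_cumsum(arr: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(arr, dtype=np.float64)])


def _window_sums(csum: np.ndarray, starts: np.ndarray, ends: np.ndarray, L: int) -> np.ndarray:
    """Sum of the underlying array over circular [start, end) intervals."""
    total = csum[L]

    def f(x):
        return (x // L) * total + csum[x % L]

    return f(ends) - f(starts)


@dataclass
class EnrichmentResult:
    per_site: pd.DataFrame  # position, strand, class, enrichment
    group_stats: pd.DataFrame  # class, n, mean, sd
    t_statistic: float
    p_value: float
    p_permutation: float
    span: int
    smoothing: int
    warning: Optional[str] = None


def relative_density_enrichment(
    counts_cfx: StrandCounts,
    counts_ctrl: StrandCounts,
    classes: pd.DataFrame,
    replicon: Optional[str] = None,
    smoothing: int = 1_000,
    span: int = 5_000,
    pseudocount: float = 1.0,
    n_permutations: int = 10_000,
    seed: int = 0,
    motif_length: int = MOTIF_LENGTH,
) -> EnrichmentResult:
    """Per-Chi-site +Cfx/-Cfx density ratio over the first ``span`` bp 3' of Chi.

    For each Chi site, co-oriented-strand densities in the two libraries are
    normalized to RPKM, smoothed with a centered ``smoothing``-bp sliding
    window (``pseudocount`` reads added per window and library), divided
    (+Cfx over control), and averaged over offsets ``0..span``.  Group
    means +- SD for ``downstream_gcs`` vs ``other`` sites are compared with
    a two-sided Welch t test; a label-permutation p value (seeded) is
    reported alongside.
    """
    if replicon is None:
        replicon = max(counts_cfx.counts, key=lambda r: len(counts_cfx.counts[r]["+"]))
    L = len(counts_cfx.counts[replicon]["+"])
    half = smoothing // 2

    csums = {
        ("cfx", s): _circular_cumsum(counts_cfx.counts[replicon][s])
        for s in ("+", "-")
    } | {
        ("ctrl", s): _circular_cumsum(counts_ctrl.counts[replicon][s])
        for s in ("+", "-")
    }
    totals = {"cfx": counts_cfx.total_aligned, "ctrl": counts_ctrl.total_aligned}

    offs = np.arange(0, span + 1, dtype=np.int64)
    enrich = np.empty(len(classes))
    for i, row in enumerate(classes.itertuples(index=False)):
        if row.strand == "+":
            centers = row.position + offs
            starts, ends = centers - half, centers + half + 1
        else:
            anchor = row.position + motif_length - 1
            centers = anchor - offs
            starts, ends = centers - half, centers + half + 1
        rates = {}
        for lib in ("cfx", "ctrl"):
            s = _window_sums(csums[(lib, row.strand)], starts + L, ends + L, L)
            rates[lib] = (s + pseudocount) * 1e9 / ((ends - starts) * totals[lib])
        enrich[i] = np.mean(rates["cfx"] / rates["ctrl"])

    per_site = classes[["position", "strand", "class"]].copy()
    per_site["enrichment"] = enrich

    groups = {
        name: per_site.loc[per_site["class"] == name, "enrichment"].to_numpy()
        for name in ("downstream_gcs", "other")
    }
    gs = pd.DataFrame(
        [
            (name, len(v), float(np.mean(v)) if len(v) else np.nan, float(np.std(v, ddof=1)) if len(v) > 1 else np.nan)
            for name, v in groups.items()
        ],
        columns=["class", "n", "mean", "sd"],
    )

    warning = None
    if min(len(v) for v in groups.values()) < 2:
        return EnrichmentResult(per_site, gs, np.nan, np.nan, np.nan, span, smoothing,
                                warning="a group has fewer than 2 sites; test skipped")

    pooled_sd = float(np.std(np.concatenate(list(groups.values()))))
    if pooled_sd == 0.0:
        # degenerate case (e.g. identical libraries): no variation, no effect
        return EnrichmentResult(per_site, gs, 0.0, 1.0, 1.0, span, smoothing)

    t_stat, p_val = stats.ttest_ind(groups["downstream_gcs"], groups["other"], equal_var=False)

    rng = np.random.default_rng(seed)
    a, b = groups["downstream_gcs"], groups["other"]
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    n_a = len(a)
    perm = np.tile(pooled, (n_permutations, 1))
    perm = rng.permuted(perm, axis=1)
    diffs = np.abs(perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1))
    p_perm = (1 + np.sum(diffs >= obs - 1e-12)) / (n_permutations + 1)

    return EnrichmentResult(
        per_site=per_site,
        group_stats=gs,
        t_statistic=float(t_stat),
        p_value=float(p_val),
        p_permutation=float(p_perm),
        span=span,
        smoothing=smoothing,
        warning=warning,
    )


def gcs_relative_profile(
    counts_cfx: StrandCounts,
    counts_ctrl: StrandCounts,
    gcs: list[OrientedSite],
    half_width: int = 15_000,
    smoothing: int = 2_000,
    masks: Optional[MaskSet] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """+Cfx over -Cfx mean density around GCS anchors (both strands pooled).

    Returns (offsets, smoothed relative density).  With no planted GCS
    effect this profile is flat at 1 — the null check for cleavage-site
    enrichment per se.
    """
    prof_cfx = anchored_profile(counts_cfx, gcs, half_width, smoothing=1, masks=masks)
    prof_ctrl = anchored_profile(counts_ctrl, gcs, half_width, smoothing=1, masks=masks)
    dens_cfx = prof_cfx.raw_F + prof_cfx.raw_R
    dens_ctrl = prof_ctrl.raw_F + prof_ctrl.raw_R
    rel = _smooth_nan(dens_cfx, smoothing) / _smooth_nan(dens_ctrl, smoothing)
    return prof_cfx.offsets, rel
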