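# Methods

## Overview

`smdnamap` analyses libraries of 14–19 nt single-stranded guide DNAs
(smDNAs) bound by a prokaryotic Argonaute expressed in *E. coli*. The
analysis half of the package is a deterministic function of a FASTQ
library and a reference replicon set; the generative half draws such
libraries from an explicit intensity model with recorded ground truth.
This note documents both models, the parameters that matter, the
numerical choices, and what the tests do and do not establish.

## Coordinates and orientation conventions

All internal coordinates are 0-based half-open; GFF3 input (1-based
inclusive) and BED input (0-based half-open) are converted at the
boundary. Circular replicons wrap modulo their length everywhere,
including motif scanning across the origin junction and rolling windows.

A Chi site's `position` is the 0-based start of the 8-mer on the plus
strand regardless of strand label. "3′ side of Chi" means increasing
coordinates for a `+` site and decreasing coordinates for a `−` site.
In metaplots, the anchor point of a minus-strand site is the **last**
plus-strand base of its motif (`position + 7`): with this convention
reverse-complementing the genome and relabeling strands is an exact
symmetry of every profile (asserted to 10⁻¹⁰ in the test suite), rather
than a symmetry up to a 7-bp shift.

## Read processing and alignment

Preprocessing removes everything from the leftmost exact occurrence of
the 3′ adapter and discards reads shorter than 14 nt. Alignment is exact
string matching — guides this short make mismatch tolerance meaningless —
against both strands of every replicon: a per-length table of 2-bit
k-mer codes of the reference, sorted for binary search, built lazily for
the read lengths present. Memory is a few words per reference base per
distinct length; the aligner is checked against exhaustive string search
on hundreds of randomized instances.

Each aligned read contributes one count at the plus-strand coordinate of
its 5′ base (match start on `+`; match end − 1 on `−`). 5′-end
attribution, rather than full-length coverage, is the density definition
throughout: the statistics are strand-polar and the paper-scale guides
are shorter than every window used downstream. A read matching k > 1
locations is assigned to the smallest (replicon index, match start,
strand) triple, `+` ordering before `−` — a deterministic rule that keeps
runs reproducible; `discard_multimappers` drops such reads instead.
Masked regions are **not** excluded from alignment; masks are applied at
statistic level (anchors and windows), matching the semantics of
"removed from the analysis".

RPKM is `count · 10⁹ / (window_bp · total_aligned)`; the final partial
window of a replicon is normalized by its true width.

## Genome-scale statistics

* **ter fractions** — per *ter* window and strand, 5′-end counts divided
  by all chromosome-mapped reads, ×100. The strand asymmetry of a window
  is blocked-strand over complementary-strand percent, where the blocked
  strand is the one whose 3′ end points toward the site.
* **Strand-ratio profile** — plus/minus coverage ratio in rolling windows
  (default 50 kb every 10 kb, wrapping on circular replicons) computed
  per library with a pseudocount of 1 read per window and strand, then
  the +Cfx profile divided by the control profile. The pseudocount
  avoids empty-window divisions and is recorded in the output.
* **Plasmid enrichment** — `(reads_p/(L_p·c)) / (reads_ch/L_ch)`: the
  excess of plasmid reads over the plasmid's share of cellular DNA
  content. Note that chromosome-side intensity structure (ter peaks, Chi
  drops) shifts the chromosomal mean density, so the recovered fold on
  structured simulations sits a few percent below the planted preference.

## Chi metaplots and the drop statistic

For each anchor the co-oriented (F) and opposite (R) strand densities
over ±half_width (default 50 kb) are extracted in anchor orientation,
averaged position-wise over anchors, and smoothed with a centered moving
average (default 400 bp; the estimator is centered rather than trailing
— ties broken toward symmetry). Anchors whose motif overlaps a mask are
excluded; for remaining anchors, masked offsets are excluded from that
anchor's contribution with per-offset anchor counts tracked, so means
near masked regions stay unbiased.

Background is the mean smoothed F density over the remote flanks
(−50…−35 kb and +35…+50 kb). The background uses the F strand only; a
both-strand variant is available. The **drop** is
`(1 − min normalized density within ±2 kb of the anchor) × 100`; the
±2-kb search window is a package choice (exposed in config) — the
minimum sits immediately 5′ of the motif, and the window merely bounds
the search against remote noise.

## Chi–GCS adjacency and the enrichment test

A Chi site is `downstream_gcs` iff some GCS lies on its 3′ side with no
co-oriented Chi strictly between (GCSs are unstranded cleavage points;
distances wrap on circular replicons). The complementary `upstream_gcs`
flag is emitted for the inactive-orientation comparison.

Per Chi site, co-oriented-strand densities in the two libraries are
RPKM-normalized, smoothed with a 1-kb sliding window (pseudocount 1 read
per window per library), divided (+Cfx/−Cfx), and averaged over offsets
0…+5 kb. Group means ± SD for `downstream_gcs` vs `other` are compared
with a **two-sided unequal-variance (Welch) t test** — the variance of
the small downstream group is visibly larger, so the pooled-variance
form would be wrong — and a label-permutation p value (10 000 seeded
shuffles) is reported alongside as a distribution-free check.

## The generative model

Intensities compose multiplicatively, `λ(p,s) = β·m_ter·m_chi·m_gcs`,
so planted effects survive as ratios in every downstream statistic:

* `m_chi`: on the strand co-oriented with each Chi, density is `1 − δ`
  immediately 5′ of the motif, recovering **linearly** to 1 over `w` bp
  (default 10 kb). The recovery is gradual in real profiles but has no
  known functional form; linear is the simplest one-parameter choice and
  is surfaced in config.
* `m_gcs` (+Cfx only): factor γ between each GCS and its closest
  upstream co-oriented Chi, on that Chi's strand — both directions from
  the cleavage point, matching RecBCD entry from either side of a break.
* `m_ter`: factor `h` from each *ter* window to its bounding co-oriented
  Chi on the blocked strand and `h/a` on the complement. Under +Cfx the
  per-site height is instead **solved in closed form** from the −Cfx
  intensity masses so that the blocked-strand window *fraction* folds by
  the configured factor (default 2.6): a fraction is a ratio of library
  percentages, and the boosted regions inflate the +Cfx total, so a raw
  height multiplier would under-shoot the intended fold.
* Plasmid positions get `β · copy_number · preference` on both strands.

Reference construction plants `chi_count` motifs at random positions and
strands, removes spurious occurrences by re-randomizing the offending
8-mers (bounded retries), places one bounding Chi at a fixed distance
(default 3 kb) beyond each *ter* window — mirroring the observed
peak-bounding geometry — and plants each GCS a short distance (default
1.5–4.5 kb) 3′ of a randomly chosen Chi, so every GCS carries a
Chi-adjacent signal inside the 5-kb quantification window. Reads are
drawn from the normalized intensity; lengths from a categorical
distribution over 14–19 nt; sequences are read off the reference strand
5′→3′ with the adapter appended; a fixed seed reproduces the FASTQ
byte-for-byte.

### Reference study conditions (defaults)

| parameter | default | meaning |
|---|---|---|
| genome_length | 1 Mb | stand-in for the 4.6-Mb chromosome; ter geometry scaled by position |
| n_reads | 5×10⁵ | per library |
| gc_fraction | 0.51 | genome GC |
| chi_count / gcs_count | 100 / 15 | ≈ 23 % of Chi sites get a downstream GCS, as in the real census ratio |
| β | 1 | background intensity (arbitrary units; cancels in ratios) |
| h, a | 10, 3 | ter peak height and strand asymmetry |
| δ (−Cfx / +Cfx) | 0.23 / 0.40 | Chi drop depth per condition |
| w | 10 kb | drop recovery extent |
| γ | 2 | cleavage-linked enrichment (+Cfx) |
| cfx_ter_fraction_fold | 2.6 | planted +Cfx fold of the ter window fraction |
| plasmid | 5 kb, copy 12, preference 12 | pBAD-like replicon |

The 1-Mb/5×10⁵ problem size keeps a full ±Cfx study under a minute per
pair on one CPU while leaving per-offset sampling error at the
sub-percent level after smoothing; recovery accuracy at this size is ±1–3
percentage points on the drop and a few percent on ratio statistics.

### What the simulator does and does not emulate

It emulates the *structure* the analysis assumes: length spectrum,
GC-matched composition, Chi-bounded ter peaks with strand asymmetry, the
Chi drop with gradual recovery, Cfx-dependent cleavage-linked enrichment,
and copy-number-weighted plasmid reads. It does **not** emulate
sequencing error, PCR duplication, RNA contamination, adapter dimers,
non-uniform fragment ends, replication-associated copy-number gradients,
or biological site-to-site variability. Passing recovery tests therefore
establishes estimator correctness under the assumed model, not
robustness to artifacts absent from it.

One model interaction is worth knowing: with γ > 1 the +Cfx metaplot
background includes cleavage-linked enrichment spread over the flanks, so
the measured +Cfx drop on the *full* study exceeds the planted δ by
several points (≈ 47 % for δ = 0.40 at the defaults). Isolated
recoveries (γ = 1) land on the planted value; both numbers are reported
by `scripts/acceptance.py`.

## Numerical choices and degenerate inputs

* Smoothing near profile edges uses the valid-sample count of the
  truncated kernel (no zero-padding bias); NaN offsets (all anchors
  masked) propagate rather than silently filling.
* Identical ±Cfx libraries give zero-variance enrichment groups; the
  Welch statistic is then reported as t = 0, p = 1 instead of NaN.
* A group with fewer than two sites skips the test with a warning.
* Ties in replichore assignment (gene midpoint exactly at ori/ter) go to
  the rightward replichore; equidistant adjacency ties resolve toward
  the nearer coordinate. Palindromic scan motifs are reported once, on
  the plus strand.
* Empty libraries, empty references, duplicate record names, annotation
  referencing unknown replicons, and malformed FASTQ records raise
  typed errors naming the offending input.

## Pipeline reproducibility

`run_pipeline` executes simulate → align → profile → chi → compose →
report from one YAML config, records every parameter and the SHA-256 of
every output in `manifest.json`, and on re-run skips stages whose
outputs still match their recorded checksums under the same config hash;
any config change invalidates the manifest. All randomness flows from
the single config seed; two runs from the same config are byte-identical.

## Known limitations

* Chi census on a real genome depends on the full masked-region list;
  with only the termination-region mask the count is reproducible but
  mask-list-sensitive.
* The null-calibration flatness check is evaluated on disjoint 10-kb
  offset bins: a pointwise band over ~10⁵ boxcar-smoothed offsets makes
  ~2–3 spurious 3σ excursions per dataset (Rice upcrossing rate) under
  any correct null, so per-offset assertion at full resolution is not a
  meaningful test.
* The exact aligner assumes ACGT references; ambiguity codes make the
  containing k-mers unmatchable (conservative for masked/padded bases).
* GCS calling itself (Topo-Seq) is out of scope; GCS coordinates are
  consumed as input.
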