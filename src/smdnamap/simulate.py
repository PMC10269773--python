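"""Generative model for pAgo-associated smDNA libraries.

The simulator emulates the structure that the downstream analysis assumes
about smDNA biogenesis in E. coli:

* reads are 14-19 nt guide DNAs, GC-matched to the genome;
* large smDNA peaks sit between each *ter* site and the nearest co-oriented
  Chi site, with the 3'-terminated (fork-blocked) strand over-represented
  2-3 fold relative to its complement;
* on the strand co-oriented with each Chi motif, smDNA density drops
  abruptly at the Chi sequence (RecBCD loads RecA 3' of Chi and shields
  that strand) and recovers gradually on the 5' side;
* under ciprofloxacin (+Cfx), density is additionally enriched between each
  gyrase cleavage site (GCS) and its closest upstream co-oriented Chi, the
  Chi drop deepens, and the *ter* peaks grow;
* plasmid reads are weighted by copy number (and by the pAgo's intrinsic
  plasmid preference).

Densities compose multiplicatively:  lambda(p, s) = beta * m_ter * m_chi *
m_gcs, so planted effects survive as ratios in the downstream statistics.
All randomness flows from a single integer seed; a given (seed, config)
pair reproduces the FASTQ byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .reference import (
    CHI_MOTIF,
    MaskSet,
    OrientedSite,
    ReferenceBundle,
    Replicon,
    TerSite,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


class SimulationError(RuntimeError):
    pass


@dataclass
class GenerativeConfig:
    """Parameters of the smDNA intensity model and library sampling.

    Defaults are the package's reference study conditions: a 1-Mb circular
    chromosome standing in for the 4.6-Mb E. coli genome (coordinates of the
    termination region scaled accordingly), SeAgo-like library parameters.
    """

    seed: int = 1
    n_reads: int = 500_000
    genome_length: int = 1_000_000
    gc_fraction: float = 0.51
    chi_count: int = 100
    gcs_count: int = 15
    gcs_min_distance: int = 1_500  # GCS planted this far 3' of a Chi site
    gcs_max_distance: int = 4_500
    ter_sites: list[TerSite] = field(
        default_factory=lambda: [
            TerSite("terA", 291_000, 296_000, "-"),
            TerSite("terC", 334_000, 341_000, "+"),
            TerSite("terB", 356_000, 357_000, "+"),
        ]
    )
    ter_chi_distance: int = 3_000  # planted Chi bounding each ter peak
    ori_position: int = 0
    background_rate: float = 1.0  # beta
    ter_peak_height: float = 10.0  # h
    strand_asymmetry: float = 3.0  # a: blocked (3'-terminated) vs other strand
    chi_drop: float = 0.23  # delta in the -Cfx condition
    chi_drop_cfx: Optional[float] = 0.40  # delta under +Cfx (None -> same)
    chi_drop_extent: int = 10_000  # w: linear recovery ramp, bp
    gcs_enrichment: float = 2.0  # gamma, applied only when cfx
    cfx_ter_fraction_fold: Optional[float] = 2.6  # target terA-fraction fold under +Cfx
    plasmid_length: int = 5_000
    plasmid_copy_number: int = 12
    plasmid_preference: float = 12.0  # pAgo bias beyond copy number
    length_distribution: dict[int, float] = field(
        default_factory=lambda: {14: 0.04, 15: 0.12, 16: 0.28, 17: 0.30, 18: 0.18, 19: 0.08}
    )
    adapter: str = "AGATCGGAAGAGC"
    chromosome_name: str = "sim_chrom"
    plasmid_name: str = "sim_plasmid"

    def __post_init__(self):
        if self.n_reads < 0:
            raise SimulationError("n_reads must be >= 0")
        if not 0.0 < self.gc_fraction < 1.0:
            raise SimulationError("gc_fraction must be in (0, 1)")
        if not 0.0 <= self.chi_drop < 1.0:
            raise SimulationError("chi_drop must be in [0, 1)")
        if self.background_rate <= 0 or self.ter_peak_height < 1 or self.strand_asymmetry < 1:
            raise SimulationError("rates/factors must be positive (h, a >= 1)")
        if self.gcs_enrichment < 1:
            raise SimulationError("gcs_enrichment must be >= 1")
        tot = sum(self.length_distribution.values())
        if abs(tot - 1.0) > 1e-9:
            raise SimulationError("length_distribution must sum to 1")
        if not set(self.length_distribution) <= set(range(14, 20)):
            raise SimulationError("read lengths must lie in [14, 19]")
        for t in self.ter_sites:
            if t.end > self.genome_length:
                raise SimulationError(f"ter window {t.name} outside genome")

    def delta(self, cfx: bool) -> float:
        if cfx and self.chi_drop_cfx is not None:
            return self.chi_drop_cfx
        return self.chi_drop

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ter_sites"] = [dataclasses.asdict(t) for t in self.ter_sites]
        d["length_distribution"] = {str(k): v for k, v in self.length_distribution.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeConfig":
        d = dict(d)
        if "ter_sites" in d:
            d["ter_sites"] = [TerSite(**t) for t in d["ter_sites"]]
        if "length_distribution" in d:
            d["length_distribution"] = {int(k): float(v) for k, v in d["length_distribution"].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted values and per-read provenance for recovery tests."""

    config: GenerativeConfig
    chi_sites: list[OrientedSite]
    gcs_sites: list[OrientedSite]
    ter_sites: list[TerSite]
    intensity: dict[bool, dict[str, dict[str, np.ndarray]]] = field(default_factory=dict)
    read_records: dict[bool, "np.ndarray | None"] = field(default_factory=dict)
    # read_records[cfx]: structured array (replicon_idx, position, strand_idx, length)

    def save_json(self, path: str | Path) -> None:
        doc = {
            "config": self.config.to_dict(),
            "chi_sites": [dataclasses.asdict(s) for s in self.chi_sites],
            "gcs_sites": [dataclasses.asdict(s) for s in self.gcs_sites],
            "ter_sites": [dataclasses.asdict(t) for t in self.ter_sites],
        }
        Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# Reference construction


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def seq_to_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_MOTIF_CODES = seq_to_codes(CHI_MOTIF)
_MOTIF_RC_CODES = (3 - _MOTIF_CODES)[::-1]


def _occurrences(codes: np.ndarray, motif: np.ndarray) -> np.ndarray:
    """Start positions of exact occurrences of ``motif`` in ``codes`` (linear)."""
    k = len(motif)
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    hit = codes[: len(codes) - k + 1] == motif[0]
    for j in range(1, k):
        hit &= codes[j: len(codes) - k + 1 + j] == motif[j]
    return np.flatnonzero(hit).astype(np.int64)


def build_reference(config: GenerativeConfig) -> tuple[ReferenceBundle, GroundTruth]:
    """Build a random circular chromosome with planted Chi/GCS/ter features.

    Chi motifs are planted at random positions and strands; spurious motif
    occurrences elsewhere are removed by re-randomising the offending 8-mers
    (bounded retries), so ``scan_motif`` on the output recovers exactly the
    planted set.  One co-oriented Chi is planted near each *ter* window to
    bound its smDNA peak, as observed for the real termination region.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    k = len(CHI_MOTIF)

    # exclusion zones around ter windows: random sites stay out so the
    # planted bounding Chi is the nearest co-oriented one
    zones = []
    for t in config.ter_sites:
        zones.append((t.start - config.ter_chi_distance - 3 * k, t.end + config.ter_chi_distance + 3 * k))

    def in_zone(pos: int) -> bool:
        return any(z0 <= pos < z1 for z0, z1 in zones)

    # planted Chi bounding each ter peak
    planted: list[tuple[int, str]] = []
    for t in config.ter_sites:
        if t.blocked_strand == "-":
            planted.append((t.end + config.ter_chi_distance, "-"))
        else:
            planted.append((t.start - config.ter_chi_distance - k, "+"))

    n_random = config.chi_count - len(planted)
    if n_random < 0:
        raise SimulationError("chi_count smaller than the number of ter-bounding Chi sites")
    occupied = sorted(p for p, _ in planted)
    tries = 0
    while len(planted) < config.chi_count:
        pos = int(rng.integers(0, L - k))
        if in_zone(pos) or any(abs(pos - q) < 2 * k for q in occupied):
            tries += 1
            if tries > 100 * config.chi_count:
                raise SimulationError("cannot place requested Chi motifs")
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        planted.append((pos, strand))
        occupied.append(pos)
        occupied.sort()

    # GCS positions: unstranded double-strand cleavage points, planted a
    # short distance 3' of randomly chosen Chi sites so that each carries a
    # Chi-adjacent cleavage signal inside the quantification window
    gcs_positions: list[int] = []
    if config.gcs_count > 0:
        candidates = [pc for pc in planted if not in_zone(pc[0])]
        rng.shuffle(candidates)
        tries = 0
        while len(gcs_positions) < config.gcs_count:
            tries += 1
            if tries > 1000 * config.gcs_count or not candidates:
                raise SimulationError("cannot place requested GCSs")
            cpos, cstrand = candidates[(tries - 1) % len(candidates)]
            d = int(rng.integers(config.gcs_min_distance, config.gcs_max_distance + 1))
            pos = (cpos + k + d) % L if cstrand == "+" else (cpos - d) % L
            # no co-oriented Chi may fall between the Chi and its GCS
            clash = any(
                qs == cstrand
                and 0 < ((qp - cpos) % L if cstrand == "+" else (cpos - qp) % L) <= d + k
                for qp, qs in planted
                if (qp, qs) != (cpos, cstrand)
            )
            if clash or in_zone(pos) or any(abs(pos - q) < 500 for q in gcs_positions):
                continue
            gcs_positions.append(pos)
            candidates = [pc for pc in candidates if pc != (cpos, cstrand)]
    gcs_positions.sort()

    for attempt in range(20):
        codes = _random_codes(rng, L, config.gc_fraction)
        for pos, strand in planted:
            m = _MOTIF_CODES if strand == "+" else _MOTIF_RC_CODES
            codes[pos: pos + k] = m
        planted_pos = {p for p, _ in planted}
        ok = False
        for _scrub in range(60):
            ext = np.concatenate([codes, codes[: k - 1]])  # circular junction
            spurious = [
                int(p) % L
                for m in (_MOTIF_CODES, _MOTIF_RC_CODES)
                for p in _occurrences(ext, m)
                if int(p) % L not in planted_pos
            ]
            spurious = [
                p for p in spurious
                if not any(q < p + k and p < q + k for q in planted_pos)
            ]
            if not spurious:
                ok = True
                break
            for p in spurious:
                repl = _random_codes(rng, k, config.gc_fraction)
                idx = (p + np.arange(k)) % L
                codes[idx] = repl
        if ok:
            break
    else:
        raise SimulationError("cannot scrub spurious Chi motifs")

    chrom = Replicon(
        name=config.chromosome_name,
        sequence=codes_to_seq(codes),
        topology="circular",
        copy_number=1,
        role="chromosome",
    )
    plasmid = Replicon(
        name=config.plasmid_name,
        sequence=codes_to_seq(_random_codes(rng, config.plasmid_length, config.gc_fraction)),
        topology="circular",
        copy_number=config.plasmid_copy_number,
        role="plasmid",
    )

    chi_sites = sorted(
        OrientedSite(chrom.name, pos, strand) for pos, strand in planted
    )
    gcs_sites = [OrientedSite(chrom.name, pos, "+") for pos in gcs_positions]

    # analysis mask: the scaled termination region, as the real analysis
    # excludes 1.2-1.7 Mb of the 4.6-Mb chromosome
    if config.ter_sites:
        lo = min(t.start for t in config.ter_sites) - 20_000
        hi = max(t.end for t in config.ter_sites) + 20_000
        masks = MaskSet([(chrom.name, max(0, lo), min(L, hi))])
    else:
        masks = MaskSet()

    bundle = ReferenceBundle(
        replicons={chrom.name: chrom, plasmid.name: plasmid},
        masks=masks,
        ter_sites=list(config.ter_sites),
        chi_sites=chi_sites,
        gcs_sites=gcs_sites,
        ori_position=config.ori_position,
    )
    truth = GroundTruth(
        config=config,
        chi_sites=chi_sites,
        gcs_sites=gcs_sites,
        ter_sites=list(config.ter_sites),
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# Intensity model


def _nearest_chi_after(chi_pos: np.ndarray, pos: int, L: int) -> int:
    """Nearest element of ``chi_pos`` at or after ``pos`` on a circle of size L."""
    if len(chi_pos) == 0:
        return -1
    i = np.searchsorted(chi_pos, pos, side="left")
    return int(chi_pos[i % len(chi_pos)])


def _nearest_chi_before(chi_pos: np.ndarray, pos: int, L: int) -> int:
    if len(chi_pos) == 0:
        return -1
    i = np.searchsorted(chi_pos, pos, side="right") - 1
    return int(chi_pos[i])  # i == -1 wraps to the last element


def _mul_circular(arr: np.ndarray, start: int, end: int, factor) -> None:
    """Multiply arr over the circular half-open interval [start, end).

    ``end <= start`` (after reduction mod L) wraps through the origin.
    """
    L = len(arr)
    if (end - start) % L == 0:
        return
    s, e = start % L, end % L
    if e > s:
        arr[s:e] *= factor
    else:
        arr[s:] *= factor
        arr[:e] *= factor


def build_intensity(
    bundle: ReferenceBundle,
    truth: GroundTruth,
    config: GenerativeConfig,
    cfx: bool,
    _store: bool = True,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-replicon, per-strand expected read-5'-end intensity arrays.

    lambda(p, s) = beta * m_ter(p, s) * m_chi(p, s) * m_gcs(p, s); plasmid
    positions get beta scaled by copy number and plasmid preference.  When a
    target +Cfx *ter*-fraction fold is configured, the +Cfx *ter* peak height
    is solved from the -Cfx intensity masses so that the observed fraction
    fold (a ratio of library percentages, which compresses the raw boost)
    lands on the configured value.
    """
    chrom = bundle.chromosome
    L = chrom.length
    k = len(CHI_MOTIF)
    beta = config.background_rate
    delta = config.delta(cfx)
    w = config.chi_drop_extent

    chi_plus = np.array(sorted(s.position for s in truth.chi_sites if s.strand == "+"), dtype=np.int64)
    chi_minus = np.array(sorted(s.position for s in truth.chi_sites if s.strand == "-"), dtype=np.int64)

    lam = {
        "+": np.full(L, beta, dtype=np.float64),
        "-": np.full(L, beta, dtype=np.float64),
    }

    # --- m_chi: drop (1 - delta) just 5' of each co-oriented Chi, linear
    # recovery to 1 over w bp
    ramp = 1.0 - delta + delta * np.arange(w - 1, -1, -1) / w  # index 0 -> farthest
    # plus-strand Chi at c: positions [c-w, c-1], factor 1-delta at c-1
    for c in chi_plus:
        idx = (np.arange(c - w, c)) % L
        lam["+"][idx] *= ramp
    # minus-strand Chi at c (motif occupies [c, c+k)): 5' side is increasing
    # coordinates beyond the motif end
    for c in chi_minus:
        idx = (np.arange(c + k, c + k + w)) % L
        lam["-"][idx] *= ramp[::-1]

    # --- m_gcs: gamma between each GCS and the closest upstream co-oriented
    # Chi, on that Chi's strand, +Cfx only
    if cfx and config.gcs_enrichment != 1.0:
        gamma = config.gcs_enrichment
        for site in truth.gcs_sites:
            g = site.position
            cp = _nearest_chi_before(chi_plus, g - k, L)
            if cp >= 0:
                _mul_circular(lam["+"], cp + k, g, gamma)
            cm = _nearest_chi_after(chi_minus, g + 1, L)
            if cm >= 0:
                _mul_circular(lam["-"], g, cm, gamma)

    # --- m_ter: h over [ter, bounding co-oriented Chi] on the blocked
    # (3'-terminated) strand, h/a on the complement
    def ter_regions() -> list[tuple[TerSite, int, int]]:
        out = []
        for t in truth.ter_sites:
            if t.blocked_strand == "-":
                c = _nearest_chi_after(chi_minus, t.end, L)
                if c < 0:
                    continue
                out.append((t, t.start, c + k))
            else:
                c = _nearest_chi_before(chi_plus, t.start - k, L)
                if c < 0:
                    continue
                out.append((t, c, t.end))
        return out

    def apply_ter(heights: dict[str, float]) -> None:
        for t, start, end in ter_regions():
            h_t = heights[t.name]
            _mul_circular(lam[t.blocked_strand], start, end, h_t)
            other = "+" if t.blocked_strand == "-" else "-"
            _mul_circular(lam[other], start, end, h_t / config.strand_asymmetry)

    if cfx and config.cfx_ter_fraction_fold is not None and truth.ter_sites:
        # Solve a per-ter-site peak height so that the blocked-strand window
        # fraction (percent of the chromosome library) folds by the
        # configured factor relative to the -Cfx condition.  A ratio of
        # library percentages compresses the raw height boost (the boosted
        # regions inflate the +Cfx total) and local Chi/GCS modifiers skew
        # it per site, so the heights are obtained in closed form from the
        # pre-boost intensity masses.  Assumes disjoint ter regions.
        lam_ctrl = build_intensity(bundle, truth, config, cfx=False, _store=False)[chrom.name]
        t_ctrl = sum(a.sum() for a in lam_ctrl.values())
        t_pre = sum(a.sum() for a in lam.values())
        fold = config.cfx_ter_fraction_fold
        a_sum = 0.0
        m_sum = 0.0
        per_site = []
        for t, start, end in ter_regions():
            ridx = np.arange(start, end) % L
            widx = np.arange(t.start, t.end) % L
            other = "+" if t.blocked_strand == "-" else "-"
            mb = lam[t.blocked_strand][ridx].sum()
            mc = lam[other][ridx].sum()
            wb = lam[t.blocked_strand][widx].sum()
            wb_ctrl = lam_ctrl[t.blocked_strand][widx].sum()
            a_sum += (wb_ctrl / wb) * (mb + mc / config.strand_asymmetry)
            m_sum += mb + mc
            per_site.append((t.name, wb_ctrl / wb))
        denom = t_ctrl - fold * a_sum
        if denom <= 0:
            raise SimulationError("cfx_ter_fraction_fold target is unattainable")
        k_fold = fold * (t_pre - m_sum) / denom
        apply_ter({name: k_fold * ratio for name, ratio in per_site})
    else:
        apply_ter({t.name: config.ter_peak_height for t in truth.ter_sites})

    plasmid = bundle.plasmid
    out = {chrom.name: lam}
    if plasmid is not None:
        level = beta * plasmid.copy_number * config.plasmid_preference
        out[plasmid.name] = {
            "+": np.full(plasmid.length, level, dtype=np.float64),
            "-": np.full(plasmid.length, level, dtype=np.float64),
        }
    if _store:
        truth.intensity[cfx] = out
    return out


# ---------------------------------------------------------------------------
# Read sampling


def sample_reads(
    bundle: ReferenceBundle,
    intensity: dict[str, dict[str, np.ndarray]],
    config: GenerativeConfig,
    fastq_path: str | Path,
    truth: Optional[GroundTruth] = None,
    cfx: Optional[bool] = None,
    seed_offset: int = 0,
) -> np.ndarray:
    """Draw reads 5'-end positions from the intensity model and write FASTQ.

    Read sequence is the reference strand sequence 5'->3' from the sampled
    position (reverse complement of the plus strand for minus-strand reads);
    the configured adapter is appended; qualities are constant.  Returns the
    per-read ground-truth records as a structured array.
    """
    rng = np.random.default_rng(config.seed + 7_919 * (seed_offset + (2 if cfx else 1)))
    rep_names = list(intensity.keys())
    code_arrays = {name: seq_to_codes(bundle.replicons[name].sequence) for name in rep_names}

    blocks = []  # (rep_idx, strand_idx, length of replicon, lam array)
    probs = []
    for ri, name in enumerate(rep_names):
        for si, strand in enumerate(("+", "-")):
            lam = intensity[name][strand]
            blocks.append((ri, si, len(lam)))
            probs.append(lam)
    flat = np.concatenate(probs)
    flat = flat / flat.sum()
    n = config.n_reads

    rec = np.zeros(
        n,
        dtype=[("replicon", np.int32), ("position", np.int64), ("strand", np.int8), ("length", np.int16)],
    )
    if n > 0:
        draws = rng.choice(len(flat), size=n, p=flat)
        lengths_support = np.array(sorted(config.length_distribution), dtype=np.int16)
        lengths_p = np.array([config.length_distribution[int(l)] for l in lengths_support])
        lens = rng.choice(lengths_support, size=n, p=lengths_p)
        offsets = np.cumsum([0] + [b[2] for b in blocks])
        block_idx = np.searchsorted(offsets, draws, side="right") - 1
        block_rep = np.array([b[0] for b in blocks], dtype=np.int32)
        block_strand = np.array([b[1] for b in blocks], dtype=np.int8)
        rec["replicon"] = block_rep[block_idx]
        rec["strand"] = block_strand[block_idx]
        rec["position"] = draws - offsets[block_idx]
        rec["length"] = lens

    # assemble sequences grouped by (replicon, strand, length) for speed
    seqs = np.empty(n, dtype=object)
    for ri, name in enumerate(rep_names):
        codes = code_arrays[name]
        Lr = len(codes)
        for si in (0, 1):
            for Lread in sorted(config.length_distribution):
                sel = np.flatnonzero(
                    (rec["replicon"] == ri) & (rec["strand"] == si) & (rec["length"] == Lread)
                )
                if len(sel) == 0:
                    continue
                pos = rec["position"][sel]
                if si == 0:
                    idx = (pos[:, None] + np.arange(Lread)[None, :]) % Lr
                    mat = codes[idx]
                else:
                    idx = (pos[:, None] - np.arange(Lread)[None, :]) % Lr
                    mat = 3 - codes[idx]
                chars = _BASES[mat]
                for row, j in enumerate(sel):
                    seqs[j] = chars[row].tobytes().decode("ascii")

    adapter = config.adapter or ""
    with open(fastq_path, "w") as fh:
        for i in range(n):
            s = seqs[i] + adapter
            fh.write(f"@sim_{i}\n{s}\n+\n{'I' * len(s)}\n")

    if truth is not None and cfx is not None:
        truth.read_records[cfx] = rec
    return rec


def simulate_library(
    config: GenerativeConfig,
    out_prefix: str | Path,
    cfx: bool,
    bundle: Optional[ReferenceBundle] = None,
    truth: Optional[GroundTruth] = None,
) -> tuple[ReferenceBundle, GroundTruth, Path]:
    """Convenience wrapper: reference + intensity + FASTQ for one condition."""
    if bundle is None or truth is None:
        bundle, truth = build_reference(config)
    lam = build_intensity(bundle, truth, config, cfx=cfx)
    fastq = Path(f"{out_prefix}{'_cfx' if cfx else '_ctrl'}.fastq")
    sample_reads(bundle, lam, config, fastq, truth=truth, cfx=cfx)
    return bundle, truth, fastq
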