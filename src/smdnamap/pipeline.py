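"""End-to-end orchestration: simulate -> align -> profile -> chi -> compose -> report.

A single YAML config drives every stage; all tunable parameters (windows,
smoothing, pseudocounts, seeds, masks) are recorded in a run manifest
together with SHA-256 checksums of every stage output, so a finished run
is reproducible and a partially finished run can resume: a stage is
skipped when its outputs exist and their checksums match the manifest
entry written under the same config hash.

Stage outputs are plain text (TSV with headers, BED/bedGraph, JSON, FASTQ,
FASTA) except the per-strand count arrays, which are cached as ``.npz``
for exact, fast reload by downstream stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import length_histogram, logo_matrix, write_pwm
from .metaplot import (
    anchored_profile,
    classify_chi_gcs,
    normalize_and_drop,
    relative_density_enrichment,
)
from .profiles import plasmid_enrichment, strand_ratio_profile, ter_fraction
from .reads import StrandCounts, align_exact, preprocess_reads, rpkm_windows, write_bed6
from .reference import (
    MaskSet,
    OrientedSite,
    ReferenceBundle,
    Replicon,
    TerSite,
)
from .simulate import GenerativeConfig, build_intensity, build_reference, sample_reads

STAGES = ("simulate", "align", "profile", "chi", "compose", "report")
_CONDITIONS = ("ctrl", "cfx")


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)  # stage -> {outputs: {path: {sha256, rows}}}

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        d = json.loads(path.read_text())
        return cls(config_hash=d["config_hash"], seed=d["seed"], version=d.get("version", "?"),
                   stages=d.get("stages", {}))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# Reference/counts persistence


def save_bundle(bundle: ReferenceBundle, outdir: Path) -> list[Path]:
    fasta = outdir / "reference.fasta"
    with open(fasta, "w") as fh:
        for rep in bundle.replicons.values():
            fh.write(f">{rep.name}\n")
            for i in range(0, rep.length, 80):
                fh.write(rep.sequence[i: i + 80] + "\n")
    meta = outdir / "reference.json"
    doc = {
        "replicons": {
            r.name: {"topology": r.topology, "copy_number": r.copy_number, "role": r.role}
            for r in bundle.replicons.values()
        },
        "masks": bundle.masks.intervals(),
        "ter_sites": [dataclasses.asdict(t) for t in bundle.ter_sites],
        "chi_sites": [dataclasses.asdict(s) for s in bundle.chi_sites],
        "gcs_sites": [dataclasses.asdict(s) for s in bundle.gcs_sites],
        "ori_position": bundle.ori_position,
    }
    meta.write_text(json.dumps(doc, indent=1))
    return [fasta, meta]


def load_bundle(outdir: Path) -> ReferenceBundle:
    from Bio import SeqIO

    meta = json.loads((outdir / "reference.json").read_text())
    replicons = {}
    for rec in SeqIO.parse(str(outdir / "reference.fasta"), "fasta"):
        m = meta["replicons"][rec.id]
        replicons[rec.id] = Replicon(rec.id, str(rec.seq), m["topology"], m["copy_number"], m["role"])
    return ReferenceBundle(
        replicons=replicons,
        masks=MaskSet(tuple(i) for i in meta["masks"]),
        ter_sites=[TerSite(**t) for t in meta["ter_sites"]],
        chi_sites=[OrientedSite(**s) for s in meta["chi_sites"]],
        gcs_sites=[OrientedSite(**s) for s in meta["gcs_sites"]],
        ori_position=meta["ori_position"],
    )


def save_counts(counts: StrandCounts, path: Path) -> None:
    arrays = {f"{rep}|{strand}": arr for rep, d in counts.counts.items() for strand, arr in d.items()}
    np.savez_compressed(path, total_aligned=counts.total_aligned, total_input=counts.total_input, **arrays)


def load_counts(path: Path) -> StrandCounts:
    z = np.load(path)
    counts: dict[str, dict[str, np.ndarray]] = {}
    for key in z.files:
        if "|" not in key:
            continue
        rep, strand = key.rsplit("|", 1)
        counts.setdefault(rep, {})[strand] = z[key]
    return StrandCounts(counts, int(z["total_aligned"]), int(z["total_input"]))


# ---------------------------------------------------------------------------
# Stages


def _stage_done(manifest: RunManifest, stage: str, outdir: Path) -> bool:
    entry = manifest.stages.get(stage)
    if not entry:
        return False
    for rel, info in entry["outputs"].items():
        p = outdir / rel
        if not p.exists() or _sha256(p) != info["sha256"]:
            return False
    return True


def _record(manifest: RunManifest, stage: str, outdir: Path, outputs: list[Path], params: dict) -> None:
    entry = {"outputs": {}, "params": params}
    for p in outputs:
        rows = None
        if p.suffix in (".tsv", ".bed", ".bedgraph", ".fastq"):
            with open(p) as fh:
                rows = sum(1 for _ in fh)
        entry["outputs"][str(p.relative_to(outdir))] = {"sha256": _sha256(p), "rows": rows}
    manifest.stages[stage] = entry


def run_pipeline(
    config: dict | str | Path,
    stages: Optional[list[str]] = None,
    outdir: Optional[str | Path] = None,
) -> RunManifest:
    """Execute the requested stages in dependency order.

    ``config`` is a dict or path to YAML with keys ``seed``, ``outdir``,
    ``simulate`` (GenerativeConfig fields) and ``analysis`` (windows,
    smoothing, pseudocounts).  Raises PipelineError when a requested stage's
    inputs are missing.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir or config.get("outdir", "smdnamap_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]

    seed = int(config.get("seed", 1))
    sim_cfg = GenerativeConfig.from_dict({"seed": seed, **config.get("simulate", {})})
    ana = config.get("analysis", {})
    chash = _config_hash({**config, "seed": seed})

    mpath = outdir / "manifest.json"
    if mpath.exists():
        manifest = RunManifest.load(mpath)
        if manifest.config_hash != chash:
            manifest = RunManifest(config_hash=chash, seed=seed)  # stale: recompute all
    else:
        manifest = RunManifest(config_hash=chash, seed=seed)

    log: list[str] = []

    def fastq_path(cond: str) -> Path:
        return outdir / f"reads_{cond}.fastq"

    def counts_path(cond: str) -> Path:
        return outdir / f"counts_{cond}.npz"

    # --- simulate
    if "simulate" in stages and not _stage_done(manifest, "simulate", outdir):
        bundle, truth = build_reference(sim_cfg)
        outputs = save_bundle(bundle, outdir)
        for cond in _CONDITIONS:
            cfx = cond == "cfx"
            lam = build_intensity(bundle, truth, sim_cfg, cfx=cfx)
            sample_reads(bundle, lam, sim_cfg, fastq_path(cond), truth=truth, cfx=cfx)
            outputs.append(fastq_path(cond))
        gt = outdir / "ground_truth.json"
        truth.save_json(gt)
        outputs.append(gt)
        _record(manifest, "simulate", outdir, outputs, sim_cfg.to_dict())
        manifest.save(mpath)
        log.append(f"simulate: {sim_cfg.n_reads} reads x {len(_CONDITIONS)} conditions")

    # --- align
    if "align" in stages:
        for cond in _CONDITIONS:
            if not fastq_path(cond).exists():
                raise PipelineError(f"align: missing input {fastq_path(cond)} (run simulate first)")
        if not _stage_done(manifest, "align", outdir):
            bundle = load_bundle(outdir)
            outputs = []
            stats = {}
            for cond in _CONDITIONS:
                rs = preprocess_reads(
                    fastq_path(cond),
                    adapter=str(config.get("adapter", sim_cfg.adapter)),
                    min_length=int(ana.get("min_length", 14)),
                )
                res = align_exact(rs, bundle, discard_multimappers=bool(ana.get("discard_multimappers", False)))
                save_counts(res.counts, counts_path(cond))
                bed = outdir / f"alignments_{cond}.bed"
                write_bed6(res.records, bed)
                outputs += [counts_path(cond), bed]
                stats[cond] = {
                    **rs.log,
                    "aligned": res.counts.total_aligned,
                    "unaligned": res.n_unaligned,
                    "multimapped": res.n_multimapped,
                }
                log.append(
                    f"align[{cond}]: in={rs.log['input_reads']} trimmed={rs.log['adapter_trimmed']} "
                    f"kept={rs.log['kept']} aligned={res.counts.total_aligned} unaligned={res.n_unaligned}"
                )
            _record(manifest, "align", outdir, outputs, {"stats": stats})
            manifest.save(mpath)

    def _need_counts(stage: str) -> dict[str, StrandCounts]:
        for cond in _CONDITIONS:
            if not counts_path(cond).exists():
                raise PipelineError(f"{stage}: missing alignment counts (run align first)")
        return {cond: load_counts(counts_path(cond)) for cond in _CONDITIONS}

    # --- profile
    if "profile" in stages and not _stage_done(manifest, "profile", outdir):
        bundle = load_bundle(outdir)
        counts = _need_counts("profile")
        outputs = []
        rows = []
        for cond in _CONDITIONS:
            rep_report = ter_fraction(counts[cond], bundle.ter_sites, bundle.chromosome.name)
            for r in rep_report.table.itertuples(index=False):
                rows.append((cond, r.ter, r.strand, r.reads, r.percent))
        ter_tsv = outdir / "ter_fractions.tsv"
        pd.DataFrame(rows, columns=["condition", "ter", "strand", "reads", "percent"]).to_csv(
            ter_tsv, sep="\t", index=False
        )
        outputs.append(ter_tsv)

        sr = ana.get("strand_ratio", {})
        prof = strand_ratio_profile(
            counts["cfx"], counts["ctrl"], bundle.chromosome.name,
            window=int(sr.get("window", 50_000)), step=int(sr.get("step", 10_000)),
            pseudocount=float(sr.get("pseudocount", 1.0)),
        )
        sr_tsv = outdir / "strand_ratio.tsv"
        pd.DataFrame(
            {"start": prof.starts, "ratio_of_ratios": prof.values, "defined": prof.defined}
        ).to_csv(sr_tsv, sep="\t", index=False)
        outputs.append(sr_tsv)

        pe_rows = []
        if bundle.plasmid is not None:
            for cond in _CONDITIONS:
                pe = plasmid_enrichment(counts[cond], bundle)
                pe_rows.append((cond, pe.fold, pe.plasmid_reads, pe.chromosome_reads))
        pe_tsv = outdir / "plasmid_enrichment.tsv"
        pd.DataFrame(pe_rows, columns=["condition", "fold", "plasmid_reads", "chromosome_reads"]).to_csv(
            pe_tsv, sep="\t", index=False
        )
        outputs.append(pe_tsv)

        wsize = int(ana.get("window_size", 1000))
        for cond in _CONDITIONS:
            wc = rpkm_windows(counts[cond], wsize)
            for strand, tag in (("+", "plus"), ("-", "minus")):
                bg = outdir / f"coverage_{cond}_{tag}.bedgraph"
                with open(bg, "w") as fh:
                    fh.write(f'track type=bedGraph name="RPKM_{cond}_{tag}"\n')
                    for rep in wc.values:
                        starts = wc.window_starts[rep]
                        vals = wc.values[rep][strand]
                        Lr = len(counts[cond].counts[rep]["+"])
                        for s0, v in zip(starts, vals):
                            fh.write(f"{rep}\t{s0}\t{min(s0 + wsize, Lr)}\t{v:.6g}\n")
                outputs.append(bg)
        _record(manifest, "profile", outdir, outputs, {"window_size": wsize, **sr})
        manifest.save(mpath)
        log.append("profile: ter fractions, strand ratio, plasmid enrichment, RPKM tracks")

    # --- chi
    if "chi" in stages and not _stage_done(manifest, "chi", outdir):
        bundle = load_bundle(outdir)
        counts = _need_counts("chi")
        mp = ana.get("metaplot", {})
        half_width = int(mp.get("half_width", 50_000))
        smoothing = int(mp.get("smoothing", 400))
        chrom = bundle.chromosome.name
        chi_unmasked = [
            s for s in bundle.chi_sites
            if not bundle.masks.overlaps(chrom, s.position, s.position + 8)
        ]
        outputs = []
        drop_rows = []
        for cond in _CONDITIONS:
            prof = anchored_profile(
                counts[cond], bundle.chi_sites, half_width, smoothing, bundle.masks
            )
            norm, drop = normalize_and_drop(
                prof,
                flank=tuple(mp.get("flank", (35_000, 50_000))),
                drop_window=int(mp.get("drop_window", 2_000)),
            )
            tsv = outdir / f"chi_metaplot_{cond}.tsv"
            pd.DataFrame(
                {
                    "offset": prof.offsets,
                    "F": prof.mean_density_F,
                    "R": prof.mean_density_R,
                    "F_normalized": norm.normalized_F,
                    "n_anchors_F": prof.n_valid_F,
                }
            ).to_csv(tsv, sep="\t", index=False, float_format="%.6g")
            outputs.append(tsv)
            drop_rows.append((cond, prof.n_anchors, norm.background, drop.drop_percent, drop.minimum_offset))
        drop_tsv = outdir / "chi_drop.tsv"
        pd.DataFrame(
            drop_rows, columns=["condition", "n_anchors", "background_rpkm", "drop_percent", "min_offset"]
        ).to_csv(drop_tsv, sep="\t", index=False)
        outputs.append(drop_tsv)

        L = bundle.chromosome.length
        classes = classify_chi_gcs(chi_unmasked, bundle.gcs_sites, L)
        en = ana.get("enrichment", {})
        result = relative_density_enrichment(
            counts["cfx"], counts["ctrl"], classes, chrom,
            smoothing=int(en.get("smoothing", 1_000)),
            span=int(en.get("span", 5_000)),
            n_permutations=int(en.get("n_permutations", 10_000)),
            seed=seed,
        )
        cls_bed = outdir / "chi_classes.bed"
        with open(cls_bed, "w") as fh:
            for r in classes.rename(columns={"class": "cls"}).itertuples(index=False):
                fh.write(f"{chrom}\t{r.position}\t{r.position + 8}\t{r.cls}\t0\t{r.strand}\n")
        site_tsv = outdir / "chi_enrichment.tsv"
        result.per_site.to_csv(site_tsv, sep="\t", index=False, float_format="%.6g")
        group_tsv = outdir / "chi_enrichment_groups.tsv"
        summary = result.group_stats.copy()
        summary["t_statistic"] = result.t_statistic
        summary["p_value"] = result.p_value
        summary["p_permutation"] = result.p_permutation
        summary.to_csv(group_tsv, sep="\t", index=False, float_format="%.6g")
        outputs += [cls_bed, site_tsv, group_tsv]
        _record(
            manifest, "chi", outdir, outputs,
            {"half_width": half_width, "smoothing": smoothing, **en},
        )
        manifest.save(mpath)
        log.append(f"chi: {len(chi_unmasked)} unmasked anchors; drop + enrichment computed")

    # --- compose
    if "compose" in stages and not _stage_done(manifest, "compose", outdir):
        bundle = load_bundle(outdir)
        outputs = []
        for cond in _CONDITIONS:
            if not fastq_path(cond).exists():
                raise PipelineError("compose: missing FASTQ (run simulate first)")
            rs = preprocess_reads(fastq_path(cond), adapter=str(config.get("adapter", sim_cfg.adapter)))
            hist = length_histogram(rs)
            h_tsv = outdir / f"length_hist_{cond}.tsv"
            pd.DataFrame(
                sorted(hist.counts.items()), columns=["length", "count"]
            ).to_csv(h_tsv, sep="\t", index=False)
            outputs.append(h_tsv)
            logo = logo_matrix(rs)
            pwm = outdir / f"logo_{cond}.tsv"
            write_pwm(logo, pwm)
            outputs.append(pwm)
        _record(manifest, "compose", outdir, outputs, {})
        manifest.save(mpath)
        log.append("compose: length histograms and logos")

    # --- report
    if "report" in stages:
        for stage in ("profile", "chi"):
            if stage not in manifest.stages:
                raise PipelineError(f"report: missing upstream stage {stage!r}")
        summary = write_summary(outdir)
        _record(manifest, "report", outdir, [outdir / "summary.json"], {})
        manifest.save(mpath)
        log.append(f"report: {len(summary)} top-level keys")

    for line in log:
        print(line)
    return manifest


def write_summary(outdir: Path) -> dict:
    """Collect the key statistics of a finished run into one JSON document."""
    outdir = Path(outdir)
    summary: dict = {}

    ter = pd.read_csv(outdir / "ter_fractions.tsv", sep="\t")
    summary["ter_fractions"] = {
        cond: {
            f"{r.ter}:{r.strand}": r.percent
            for r in ter[ter["condition"] == cond].itertuples(index=False)
        }
        for cond in ter["condition"].unique()
    }

    pe = pd.read_csv(outdir / "plasmid_enrichment.tsv", sep="\t")
    summary["plasmid_enrichment_fold"] = {
        r.condition: r.fold for r in pe.itertuples(index=False)
    }

    drop = pd.read_csv(outdir / "chi_drop.tsv", sep="\t")
    summary["chi_drop_percent"] = {r.condition: r.drop_percent for r in drop.itertuples(index=False)}
    summary["chi_background_rpkm"] = {r.condition: r.background_rpkm for r in drop.itertuples(index=False)}

    groups = pd.read_csv(outdir / "chi_enrichment_groups.tsv", sep="\t")
    summary["chi_gcs_enrichment"] = {
        "groups": {
            r.cls: {"n": int(r.n), "mean": r.mean, "sd": r.sd}
            for r in groups.rename(columns={"class": "cls"}).itertuples(index=False)
        },
        "t_statistic": float(groups["t_statistic"].iloc[0]),
        "p_value": float(groups["p_value"].iloc[0]),
        "p_permutation": float(groups["p_permutation"].iloc[0]),
    }

    for cond_file in sorted(outdir.glob("length_hist_*.tsv")):
        cond = cond_file.stem.replace("length_hist_", "")
        h = pd.read_csv(cond_file, sep="\t")
        summary.setdefault("length_histogram", {})[cond] = dict(zip(h["length"], h["count"]))

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
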