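"""End-to-end orchestration: simulate → scan (two passes) → anchor → call →
boundaries, as one reproducible, manifest-producing run.

The synthetic pipeline mirrors the real study design: window statistics
are computed on a *fragmented* scanning assembly (first against its
reference, then against the majority-allele consensus — the pass whose
statistics are reported), lifted onto the contiguous truth chromosomes
through anchor alignments, segmented into sex-linked regions, and finally
re-examined on a second, more contiguous assembly to locate PAR
boundaries and fusion ends and assemble the neo-Z model.

Real-mode inputs (BAM/VCF/PAF against a real study assembly) enter
through the stage functions and CLI subcommands; ``run_all`` automates
the synthetic mode, where the second-pass "realignment" is an analytic
mismatch recount (in real mode the user's aligner provides it).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anchoring import anchors_from_paf_table, assign_anchors, lift_windows, write_paf
from .boundaries import build_neo_model, classify_scaffolds, scaffold_sexlink_profile
from .caller import call_regions, classify_regions, flag_windows, select_diagnostic_loci, summarize_chromosomes
from .consensus import majority_substitutions
from .simulate import (
    Assembly,
    GenomeSpec,
    ReadSet,
    SimulatedGenome,
    ValidationError,
    default_spec,
    fragment_assembly,
    place_reads,
    reads_to_scaffolds,
    simulate_genome,
    truth_to_scaffolds,
)
from .windows import make_window_stats, normalize_coverage, tile_windows, window_depth, window_heterozygosity

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_all", "report", "scan_direct", "window_stats_tables"]


@dataclass
class RunConfig:
    """All knobs of a synthetic end-to-end run (thresholds documented on the
    stage functions they feed)."""

    spec: GenomeSpec = field(default_factory=default_spec)
    outdir: str | Path = "neozscan_run"
    window: int = 100_000
    mismatch_filter: int | None = 2
    min_depth: int = 3
    min_sites: int = 20
    scan_n50: int = 24_000          # scanning-assembly contiguity (study-assembly analogue)
    boundary_n50: int = 1_500_000   # contiguous-assembly analogue for boundary inference
    min_scaffold: int = 2_000
    boundary_min_scaffold: int = 300_000
    boundary_max_scaffold: int = 2_000_000
    boundary_margin: int = 250_000  # keep random cuts away from recombination boundaries
    rc_fraction: float = 0.3
    anchor_min_len: int = 1_000
    anchor_min_identity: float = 0.0
    min_run: int = 10
    max_gap: int = 2
    min_windows: int = 10
    cov_drastic: float = -0.3
    t_full: float = 0.9
    t_none: float = 0.1
    seed: int | None = None         # overrides spec.seed when set
    write_bams: bool = False
    write_sequences: bool = False
    write_vcf: bool = True

    def validate(self) -> None:
        if self.window <= 0:
            raise ValidationError("window size must be > 0")
        if self.min_run < 1 or self.max_gap < 0 or self.min_windows < 1:
            raise ValidationError("min_run/min_windows must be >= 1 and max_gap >= 0")
        if not 0 <= self.t_none < self.t_full <= 1:
            raise ValidationError("need 0 <= t_none < t_full <= 1")
        if not 0 <= self.rc_fraction <= 1:
            raise ValidationError("rc_fraction must be in [0, 1]")
        self.spec.validate()

    def resolved_spec(self) -> GenomeSpec:
        spec = dataclasses.replace(self.spec)
        if self.seed is not None:
            spec.seed = int(self.seed)
        return spec

    def to_dict(self, include_outdir: bool = True) -> dict:
        d = dataclasses.asdict(self)
        d["spec"] = yaml.safe_load(self.spec.to_yaml())
        if not include_outdir:
            d.pop("outdir")
        else:
            d["outdir"] = str(self.outdir)
        return d

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(include_outdir=False), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        spec_doc = doc.pop("spec", None)
        cfg = cls(**doc)
        if spec_doc is not None:
            cfg.spec = GenomeSpec.from_yaml(yaml.safe_dump(spec_doc))
        cfg.validate()
        return cfg


@dataclass
class RunResult:
    manifest: dict
    tables: dict[str, pd.DataFrame]
    model: object | None
    sim: SimulatedGenome
    outdir: Path


def truth_genotype_codes(truth: pd.DataFrame) -> pd.DataFrame:
    """Genotype-code table (no materialized alleles) from a truth frame."""
    return truth[["chrom", "pos", "gt_f", "gt_m", "dp_f", "dp_m", "ins_len"]].copy()


def window_stats_tables(reads_f: ReadSet, reads_m: ReadSet, genotypes: pd.DataFrame,
                        windows: pd.DataFrame, *, mismatch_filter: int | None = 2,
                        min_depth: int = 3, min_sites: int = 20) -> pd.DataFrame:
    """Window-stat table for one pass: per-sex normalized depth and percent
    heterozygosity plus their female-minus-male differences."""
    het = window_heterozygosity(genotypes, windows, min_depth=min_depth, min_sites=min_sites)
    profiles = {}
    for tag, reads, het_col in (("f", reads_f, "het_f"), ("m", reads_m, "het_m")):
        depth, bases = window_depth(reads, windows, mismatch_filter)
        profiles[tag] = pd.DataFrame({
            "seq": windows["seq"], "start": windows["start"], "end": windows["end"],
            "cov": depth, "cov_norm": normalize_coverage(depth),
            "het": het[het_col], "n_sites": het["n_sites"], "aligned_bases": bases,
        })
    return make_window_stats(profiles["f"], profiles["m"])


def scan_direct(sim: SimulatedGenome, *, window: int = 100_000,
                mismatch_filter: int | None = 2, min_depth: int = 3,
                min_sites: int = 20, reads: tuple[ReadSet, ReadSet] | None = None
                ) -> pd.DataFrame:
    """Single-pass scan in chromosome coordinates (no assembly fragmentation):
    the minimal route from a simulation to a WindowStat table."""
    reads_f, reads_m = reads if reads is not None else (
        place_reads(sim, "female"), place_reads(sim, "male"))
    windows = tile_windows(sim.lengths, window)
    gts = truth_genotype_codes(sim.truth)
    return window_stats_tables(reads_f, reads_m, gts, windows,
                               mismatch_filter=mismatch_filter,
                               min_depth=min_depth, min_sites=min_sites)


def _fusion_breaks(spec: GenomeSpec) -> dict[str, list[int]]:
    breaks: dict[str, list[int]] = {}
    for seg in spec.segments:
        if seg.role == "SEXLINKED" and seg.fusion_side is not None:
            pos = seg.start if seg.fusion_side == "left" else seg.end
            breaks.setdefault(seg.chrom, []).append(pos)
    return breaks


def _recombination_boundaries(spec: GenomeSpec) -> dict[str, list[int]]:
    """Sex-linkage edges that are recombination boundaries, not fusion
    junctions — contiguous sequence in the study species, which the
    boundary assembly should span rather than break at."""
    out: dict[str, list[int]] = {}
    fusion = _fusion_breaks(spec)
    for seg in spec.segments:
        if seg.role != "SEXLINKED":
            continue
        for edge in (seg.start, seg.end):
            if edge in fusion.get(seg.chrom, ()):
                continue
            out.setdefault(seg.chrom, []).append(edge)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> RunResult:
    """Execute the full synthetic two-pass pipeline and write every stage
    output plus a manifest under ``config.outdir``.

    Any stage failure aborts with the stage name; outputs of completed
    stages are preserved on disk.
    """
    config.validate()
    spec = config.resolved_spec()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    stage = "init"
    try:
        stage = "simulate"
        sim = simulate_genome(spec)
        reads_f = place_reads(sim, "female")
        reads_m = place_reads(sim, "male")

        stage = "fragment"
        scan_asm = fragment_assembly(sim, config.scan_n50, seed=spec.seed,
                                     rc_fraction=config.rc_fraction,
                                     min_scaffold=config.min_scaffold)

        stage = "stats_pass1"
        truth_sc = truth_to_scaffolds(sim, scan_asm)
        gts_sc = truth_genotype_codes(truth_sc)
        windows_sc = tile_windows(scan_asm.scaffold_lengths, config.window)
        sc_f = reads_to_scaffolds(reads_f, scan_asm, sim)
        sc_m = reads_to_scaffolds(reads_m, scan_asm, sim)
        tables["windows_pass1"] = window_stats_tables(
            sc_f, sc_m, gts_sc, windows_sc, mismatch_filter=config.mismatch_filter,
            min_depth=config.min_depth, min_sites=config.min_sites)

        stage = "consensus"
        substituted, consensus_report = majority_substitutions(gts_sc)

        stage = "stats_pass2"
        sc2_f = reads_to_scaffolds(reads_f, scan_asm, sim, substituted=substituted)
        sc2_m = reads_to_scaffolds(reads_m, scan_asm, sim, substituted=substituted)
        tables["windows_pass2"] = window_stats_tables(
            sc2_f, sc2_m, gts_sc, windows_sc, mismatch_filter=config.mismatch_filter,
            min_depth=config.min_depth, min_sites=config.min_sites)

        stage = "anchor"
        anchors = assign_anchors(anchors_from_paf_table(scan_asm.to_paf()),
                                 min_len=config.anchor_min_len,
                                 min_identity=config.anchor_min_identity)
        lifted, n_dropped = lift_windows(tables["windows_pass2"], anchors,
                                         config.window, spec.lengths)

        stage = "call"
        flagged, thresholds = flag_windows(lifted)
        tables["windows_lifted"] = flagged
        tables["chromosome_summary"] = summarize_chromosomes(flagged, config.min_windows)
        regions = classify_regions(
            call_regions(flagged, min_run=config.min_run, max_gap=config.max_gap),
            cov_drastic=config.cov_drastic)
        tables["regions"] = regions

        stage = "diagnostic_loci"
        scaffold_regions = []
        for reg in regions.itertuples():
            for scaf, a, b in scan_asm.invert_interval(reg.chrom, reg.start, reg.end):
                scaffold_regions.append({"chrom": scaf, "start": a, "end": b})
        tables["diagnostic_loci"] = select_diagnostic_loci(
            gts_sc, pd.DataFrame(scaffold_regions, columns=["chrom", "start", "end"]))

        stage = "boundaries"
        b_asm = fragment_assembly(sim, config.boundary_n50,
                                  seed=(spec.seed + 1) % (2**31),
                                  rc_fraction=config.rc_fraction,
                                  min_scaffold=config.boundary_min_scaffold,
                                  max_scaffold=config.boundary_max_scaffold,
                                  forced_breaks=_fusion_breaks(spec),
                                  avoid_breaks=_recombination_boundaries(spec),
                                  avoid_margin=config.boundary_margin)
        b_f = reads_to_scaffolds(reads_f, b_asm, sim)
        b_m = reads_to_scaffolds(reads_m, b_asm, sim)
        gts_b = truth_genotype_codes(truth_to_scaffolds(sim, b_asm))
        windows_b = tile_windows(b_asm.scaffold_lengths, config.window)
        stats_b = window_stats_tables(b_f, b_m, gts_b, windows_b,
                                      mismatch_filter=config.mismatch_filter,
                                      min_depth=config.min_depth, min_sites=config.min_sites)
        flagged_b, _ = flag_windows(stats_b)
        anchors_b = assign_anchors(anchors_from_paf_table(b_asm.to_paf()),
                                   min_len=config.anchor_min_len,
                                   min_identity=config.anchor_min_identity)
        profile = scaffold_sexlink_profile(flagged_b, anchors_b, min_len=config.anchor_min_len)
        calls = classify_scaffolds(profile, anchors_b, regions,
                                   t_full=config.t_full, t_none=config.t_none,
                                   window=config.window)
        tables["scaffold_profile"] = profile
        tables["boundary_calls"] = calls
        tables["boundary_anchors"] = b_asm.anchors
        tables["scan_anchors"] = scan_asm.anchors

        stage = "model"
        model = None
        if spec.ancestral_z is not None and spec.ancestral_z in set(regions["chrom"]):
            model = build_neo_model(regions, calls, spec.ancestral_z,
                                    spec.lengths, window=config.window)

        stage = "write"
        written: dict[str, Path] = {}

        def _tsv(name: str, df: pd.DataFrame, json_cols: tuple[str, ...] = ()) -> None:
            out = df.copy()
            for col in json_cols:
                out[col] = out[col].map(lambda v: json.dumps(v, sort_keys=True))
            path = outdir / f"{name}.tsv"
            out.to_csv(path, sep="\t", index=False, float_format="%.6g")
            written[name] = path

        _tsv("windows_pass1", tables["windows_pass1"])
        _tsv("windows_pass2", tables["windows_pass2"])
        _tsv("windows_lifted", tables["windows_lifted"])
        _tsv("chromosome_summary", tables["chromosome_summary"])
        _tsv("boundary_calls", tables["boundary_calls"], json_cols=("evidence",))
        _tsv("scaffold_profile", tables["scaffold_profile"], json_cols=("per_chrom",))

        regions_bed = regions.copy()
        regions_bed["name"] = regions_bed["klass"].where(~regions_bed["weak"],
                                                         regions_bed["klass"] + "_weak")
        regions_bed["score"] = (1000 * regions_bed[["support_cov", "support_het"]]
                                .max(axis=1)).round().astype(int)
        from .io import write_bed
        written["regions"] = outdir / "regions.bed"
        write_bed(regions_bed[["chrom", "start", "end", "name", "score"]],
                  written["regions"])
        written["diagnostic_loci"] = outdir / "diagnostic_loci.bed"
        loci = tables["diagnostic_loci"]
        write_bed(loci.rename(columns={"pos": "start"})[["chrom", "start", "end", "ins_len", "rank"]],
                  written["diagnostic_loci"])

        written["consensus_report"] = outdir / "consensus_report.json"
        consensus_report.to_json(written["consensus_report"])

        if model is not None:
            written["neo_model"] = outdir / "neo_model.txt"
            written["neo_model"].write_text(model.render() + "\n")
            written["neo_model_json"] = outdir / "neo_model.json"
            written["neo_model_json"].write_text(json.dumps(
                {"segments": [dataclasses.asdict(s) for s in model.segments],
                 "render": model.render()}, ensure_ascii=False, sort_keys=True, indent=2))

        if config.write_sequences or config.write_bams or config.write_vcf:
            from .io import emit_standard_files, genotype_table, write_vcf as _write_vcf
            if config.write_sequences or config.write_bams:
                emitted = emit_standard_files(
                    sim, outdir, sc2_f if config.write_bams else None,
                    sc2_m if config.write_bams else None, assembly=scan_asm,
                    write_bams=config.write_bams)
                written.update({f"emit_{k}": v for k, v in emitted.items()})
            elif config.write_vcf:
                written["vcf"] = outdir / "joint.vcf"
                _write_vcf(genotype_table(sim, scan_asm), scan_asm.scaffold_lengths,
                           written["vcf"])
            written.setdefault("anchors_paf", outdir / "anchors.paf")
            write_paf(scan_asm.to_paf(), written["anchors_paf"])

        config_path = outdir / "config.yaml"
        config_path.write_text(yaml.safe_dump(config.to_dict(include_outdir=False),
                                              sort_keys=True))
        written["config"] = config_path

        manifest = {
            "package": {"name": "neozscan", "version": __version__},
            "versions": {m.__name__: m.__version__ for m in (np, pd)},
            "seed": int(spec.seed),
            "config_hash": config.config_hash(),
            "thresholds": thresholds,
            "counts": {
                "reads_female": reads_f.n_records,
                "reads_male": reads_m.n_records,
                "variants": int(len(sim.truth)),
                "scan_scaffolds": int(len(scan_asm.anchors)),
                "boundary_scaffolds": int(len(b_asm.anchors)),
                "windows_dropped_in_lift": int(n_dropped),
                "regions": int(len(regions)),
            },
            "files": {},
        }
        for name, path in sorted(written.items()):
            manifest["files"][str(Path(path).name)] = _sha256(Path(path))
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

        return RunResult(manifest=manifest, tables=tables, model=model,
                         sim=sim, outdir=outdir)
    except ValidationError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def report(outdir) -> dict:
    """Load a completed run's manifest, verify every referenced file exists
    (naming the missing one), and return the plot-ready summary tables."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {outdir} (stage 'write' incomplete?)")
    manifest = json.loads(manifest_path.read_text())
    for name in manifest["files"]:
        if not (outdir / name).exists():
            raise FileNotFoundError(f"output file {name!r} referenced by the manifest is missing")
    out = {"manifest": manifest}
    for key in ("chromosome_summary", "windows_lifted", "boundary_calls"):
        path = outdir / f"{key}.tsv"
        if path.exists():
            out[key] = pd.read_csv(path, sep="\t")
    return out
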