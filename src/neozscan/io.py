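"""Standard-format emission and loading (FASTA, BAM, VCF, PAF, BED).

The simulator's in-memory objects round-trip through the same formats a
real study would provide, so file-based and in-memory code paths can be
checked against each other exactly.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .simulate import Assembly, ReadSet, SimulatedGenome, truth_to_scaffolds

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_bam",
    "genotype_table",
    "write_vcf",
    "load_genotypes",
    "write_bed",
    "emit_standard_files",
]

_B2I = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _B2I[_b] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_TAB = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")
_STR_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _as_bytes(seq) -> bytes:
    if isinstance(seq, np.ndarray):
        return seq.tobytes()
    if isinstance(seq, str):
        return seq.encode()
    return bytes(seq)


def write_fasta(seqs: dict, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            raw = _as_bytes(seq)
            for i in range(0, len(raw), width):
                fh.write(raw[i:i + width].decode())
                fh.write("\n")


def read_fasta(path) -> dict[str, np.ndarray]:
    import pyfaidx

    fa = pyfaidx.Fasta(os.fspath(path), rebuild=True)
    return {name: np.frombuffer(str(fa[name][:]).upper().encode(), dtype=np.uint8)
            for name in fa.keys()}


def write_bam(reads: ReadSet, lengths: dict[str, int], path) -> None:
    """Write placed records as a coordinate-sorted, indexed BAM.

    Records carry no base sequence (placement is analytic); CIGAR is a
    single match run and the mismatch count goes into the NM tag.  Pieces
    of junction-spanning reads are written as independent primary records.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": seq, "LN": int(ln)} for seq, ln in lengths.items()],
    }
    path = os.fspath(path)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for tid, seq in enumerate(lengths):
            rec = reads.records.get(seq)
            if rec is None:
                continue
            starts, ends, nms = rec["start"], rec["end"], rec["nm"]
            for i in range(len(starts)):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"{seq}.{i}"
                a.flag = 0
                a.reference_id = tid
                a.reference_start = int(starts[i])
                a.mapping_quality = 60
                a.cigartuples = [(0, int(ends[i] - starts[i]))]
                a.set_tag("NM", int(nms[i]))
                bam.write(a)
    pysam.index(path)


# ---------------------------------------------------------------------------
# genotypes

def _alt_codes(ref_codes: np.ndarray, alt_offset: np.ndarray) -> np.ndarray:
    return _BASES[(_B2I[ref_codes].astype(np.int16) + alt_offset) % 4]


def _ins_seq(seed: int, chrom: str, pos: int, length: int) -> str:
    import zlib

    tag = zlib.crc32(chrom.encode()) & 0x7FFFFFFF  # stable across processes
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13, tag, int(pos)]))
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def genotype_table(sim: SimulatedGenome, assembly: Assembly | None = None) -> pd.DataFrame:
    """Truth variants with materialized alleles, in chromosome coordinates or
    (with ``assembly``) in study-assembly coordinates.

    On reverse-complemented scaffolds SNV alleles are complemented;
    insertion alleles are anchored at the complemented base with the
    reverse-complemented inserted sequence.
    """
    t = truth_to_scaffolds(sim, assembly) if assembly is not None else sim.truth.copy()
    if assembly is None:
        t = t.rename(columns={})
        t["chrom_src"] = t["chrom"]
        t["pos_src"] = t["pos"]
        t["strand"] = np.int8(1)

    ref_codes = np.empty(len(t), dtype=np.uint8)
    for chrom, grp in t.groupby("chrom_src", sort=False):
        ref_codes[grp.index.to_numpy()] = sim.reference[chrom][grp["pos_src"].to_numpy()]
    alt_codes = _alt_codes(ref_codes, t["alt_offset"].to_numpy())

    rev = t["strand"].to_numpy() == -1
    ref_b = np.frombuffer(ref_codes.tobytes().translate(_COMP_TAB), dtype=np.uint8)
    alt_b = np.frombuffer(alt_codes.tobytes().translate(_COMP_TAB), dtype=np.uint8)
    ref_out = np.where(rev, ref_b, ref_codes)
    alt_out = np.where(rev, alt_b, alt_codes)

    ref_str = [chr(c) for c in ref_out]
    alt_str = [chr(c) for c in alt_out]
    ins = t["ins_len"].to_numpy()
    for j in np.flatnonzero(ins > 0):
        row = t.iloc[j]
        s = _ins_seq(sim.spec.seed, row["chrom_src"], int(row["pos_src"]), int(ins[j]))
        if rev[j]:
            s = s.translate(_STR_COMP)[::-1]
        alt_str[j] = ref_str[j] + s

    out = pd.DataFrame({
        "chrom": t["chrom"].to_numpy(),
        "pos": t["pos"].to_numpy(),
        "ref": ref_str,
        "alt": alt_str,
        "gt_f": t["gt_f"].to_numpy(),
        "gt_m": t["gt_m"].to_numpy(),
        "dp_f": t["dp_f"].to_numpy(),
        "dp_m": t["dp_m"].to_numpy(),
        "ins_len": ins,
    })
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


_GT_TUPLE = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_vcf(genotypes: pd.DataFrame, lengths: dict[str, int], path,
              samples: tuple[str, str] = ("female", "male")) -> None:
    """Write joint genotypes as VCF 4.2 (one record per truth variant, GT and
    DP per sample).  An empty table yields a valid header-only VCF."""
    header = pysam.VariantHeader()
    for seq, ln in lengths.items():
        header.add_line(f"##contig=<ID={seq},length={int(ln)}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for s in samples:
        header.add_sample(s)
    order = {seq: i for i, seq in enumerate(lengths)}
    g = genotypes.sort_values(["chrom", "pos"], kind="stable",
                              key=lambda col: col.map(order) if col.name == "chrom" else col)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as vcf:
        for row in g.itertuples():
            rec = vcf.new_record(contig=row.chrom, start=int(row.pos),
                                 alleles=(row.ref, row.alt))
            rec.samples[samples[0]]["GT"] = _GT_TUPLE[int(row.gt_f)]
            rec.samples[samples[0]]["DP"] = int(row.dp_f)
            rec.samples[samples[1]]["GT"] = _GT_TUPLE[int(row.gt_m)]
            rec.samples[samples[1]]["DP"] = int(row.dp_m)
            vcf.write(rec)


def load_genotypes(path, samples: tuple[str, str] | None = None) -> pd.DataFrame:
    """Load a two-sample VCF into the internal genotype table (codes: 0 hom-ref,
    1 het, 2 hom-alt, −1 missing).  Malformed records are skipped with a
    warning."""
    import logging

    log = logging.getLogger(__name__)
    rows = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        file_samples = list(vcf.header.samples)
        if samples is None:
            if len(file_samples) != 2:
                raise ValueError(f"expected 2 samples, found {len(file_samples)}")
            samples = (file_samples[0], file_samples[1])
        n_bad = 0
        for rec in vcf:
            try:
                alts = rec.alts or ()
                alt = ",".join(alts) if alts else "."
                codes = []
                dps = []
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None or any(a is None for a in gt):
                        codes.append(-1)
                    else:
                        codes.append(int(sum(1 for a in gt if a != 0)))
                    dp = rec.samples[s].get("DP")
                    dps.append(int(dp) if dp is not None else 0)
                ins_len = (len(alts[0]) - len(rec.ref)) if len(alts) == 1 else 0
                rows.append((rec.contig, rec.start, rec.ref, alt,
                             codes[0], codes[1], dps[0], dps[1], max(ins_len, 0)))
            except (KeyError, TypeError, ValueError):
                n_bad += 1
        if n_bad:
            log.warning("skipped %d malformed VCF records", n_bad)
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "gt_f", "gt_m", "dp_f", "dp_m", "ins_len"])


def write_bed(df: pd.DataFrame, path, columns=("chrom", "start", "end")) -> None:
    extra = [c for c in df.columns if c not in columns]
    df[list(columns) + extra].to_csv(path, sep="\t", header=False, index=False)


def emit_standard_files(sim: SimulatedGenome, outdir, reads_f: ReadSet | None = None,
                        reads_m: ReadSet | None = None, assembly: Assembly | None = None,
                        write_bams: bool = True) -> dict[str, Path]:
    """Write the simulation as standard files: reference (and scaffold) FASTA,
    coordinate-sorted indexed BAMs, joint VCF, truth-anchor PAF and truth
    segment BED.  Reads must already be in the coordinate system implied by
    ``assembly`` (scaffolds) or its absence (chromosomes)."""
    from .anchoring import write_paf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["reference"] = outdir / "reference.fa"
    write_fasta({c: sim.reference[c] for c in sim.chrom_names}, paths["reference"])

    lengths = sim.lengths
    if assembly is not None:
        lengths = assembly.scaffold_lengths
        paths["scaffolds"] = outdir / "scaffolds.fa"
        write_fasta(assembly.scaffold_sequences(sim.reference), paths["scaffolds"])
        paths["anchors"] = outdir / "anchors.paf"
        write_paf(assembly.to_paf(), paths["anchors"])

    if write_bams:
        for name, reads in (("female", reads_f), ("male", reads_m)):
            if reads is None:
                continue
            paths[f"{name}_bam"] = outdir / f"{name}.bam"
            write_bam(reads, lengths, paths[f"{name}_bam"])

    paths["vcf"] = outdir / "joint.vcf"
    write_vcf(genotype_table(sim, assembly), lengths, paths["vcf"])

    paths["segments"] = outdir / "segments.bed"
    write_bed(sim.truth_segments().fillna("."), paths["segments"])
    return paths
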