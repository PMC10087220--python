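"""Synthetic ZW genome, read-placement and assembly-fragmentation simulator.

The simulator plants a known sex-chromosome architecture into a diploid
female (Z + W) and male (Z + Z) individual and emits everything the
downstream scan consumes: a reference genome, pre-placed read alignments
with analytic mismatch counts, joint truth genotypes, a fragmented
"study" assembly with ground-truth anchors, and BED truth segments.

W-chromosome degeneration is modelled as two separable signals:

* **coverage loss** — within a SEXLINKED segment the W haplotype is
  deleted over a fraction ``1 - w_retention`` of its length (in blocks of
  ``block_size`` bp), so the expected female:male depth ratio over the
  segment is ``(1 + w) / 2``;
* **heterozygosity gain** — retained W sequence carries fixed Z–W
  differences at ``zw_divergence`` per bp, heterozygous in every female
  and absent in males.

Reads are *placed*, not aligned: each record carries the number of
variant positions at which its source haplotype differs from the
reference it is recorded against, so mapping stringency filters can be
emulated without an external aligner.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PlantedSegment",
    "GenomeSpec",
    "SimulatedGenome",
    "ReadSet",
    "Assembly",
    "default_spec",
    "autosomal_spec",
    "simulate_genome",
    "fragment_assembly",
    "place_reads",
    "n50",
]

ROLES = ("AUTOSOME", "PAR", "SEXLINKED")

# haplotype codes used throughout: female carries Z_F and W, male Z_M1/Z_M2.
HAP_ZF, HAP_W, HAP_ZM1, HAP_ZM2 = 0, 1, 2, 3
HAP_ALL = -1  # variant present on every haplotype (reference/assembly error)
FEMALE_HAPS = (HAP_ZF, HAP_W)
MALE_HAPS = (HAP_ZM1, HAP_ZM2)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = dict(zip("ACGT", "TGCA"))


class ValidationError(ValueError):
    """Raised when a genome spec or configuration violates its invariants."""


@dataclass(frozen=True)
class PlantedSegment:
    """One planted interval of the simulated architecture (0-based, half-open).

    ``fusion_side`` marks, for SEXLINKED segments that are part of a
    neo-sex chromosome, which edge of the segment abuts the ancestral Z
    ('left' = the ``start`` edge, 'right' = the ``end`` edge).  It drives
    forced assembly breaks and the ground-truth neo-Z layout; it carries
    no signal of its own.
    """

    chrom: str
    start: int
    end: int
    role: str
    w_retention: float = 1.0
    zw_divergence: float = 0.0
    fusion_side: str | None = None

    def validate(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown segment role {self.role!r}")
        if not 0 <= self.start < self.end:
            raise ValidationError(f"bad interval {self.start}-{self.end} on {self.chrom}")
        if not 0.0 <= self.w_retention <= 1.0:
            raise ValidationError("w_retention must be in [0, 1]")
        if self.zw_divergence < 0:
            raise ValidationError("zw_divergence must be >= 0")
        if self.role in ("AUTOSOME", "PAR") and (
            self.w_retention != 1.0 or self.zw_divergence != 0.0
        ):
            raise ValidationError(f"{self.role} segments must have w_retention=1, zw_divergence=0")
        if self.fusion_side not in (None, "left", "right"):
            raise ValidationError("fusion_side must be 'left', 'right' or None")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeSpec:
    """Declarative description of a simulated ZW genome.

    Rates are per bp; ``mean_depth`` is per-haplotype fold coverage, so an
    autosome is sequenced to ``2 * mean_depth`` in both sexes.
    """

    chromosomes: list[tuple[str, int]]
    segments: list[PlantedSegment] = field(default_factory=list)
    snp_rate: float = 1e-3
    ref_error_rate: float = 1e-4
    zw_insertion_rate: float = 1e-5
    read_length: int = 150
    mean_depth: float = 5.0
    block_size: int = 1000
    error_rate: float = 0.0
    ancestral_z: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.chromosomes:
            raise ValidationError("no chromosomes")
        lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"zero-length chromosome {name!r}")
            if self.read_length > length:
                raise ValidationError(f"read_length exceeds length of {name!r}")
        if not 0.0 <= self.snp_rate < 1.0:
            raise ValidationError("snp_rate must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ValidationError("mean_depth must be > 0")
        if self.block_size <= 0 or self.read_length <= 0:
            raise ValidationError("block_size and read_length must be > 0")
        by_chrom: dict[str, list[PlantedSegment]] = {}
        for seg in self.segments:
            seg.validate()
            if seg.chrom not in lengths:
                raise ValidationError(f"segment on unknown chromosome {seg.chrom!r}")
            if seg.end > lengths[seg.chrom]:
                raise ValidationError(f"segment {seg.chrom}:{seg.start}-{seg.end} out of bounds")
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise ValidationError(f"overlapping segments on {chrom}")
        if self.ancestral_z is not None and self.ancestral_z not in lengths:
            raise ValidationError(f"ancestral_z {self.ancestral_z!r} is not a chromosome")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    # -- YAML round-trip ------------------------------------------------
    def to_yaml(self, path=None) -> str:
        doc = dataclasses.asdict(self)
        doc["chromosomes"] = [list(c) for c in self.chromosomes]
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "GenomeSpec":
        """Load a spec from YAML text, a file object, or a path."""
        if hasattr(source, "read"):
            doc = yaml.safe_load(source.read())
        elif isinstance(source, str) and "\n" in source:
            doc = yaml.safe_load(source)
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        doc["chromosomes"] = [(str(n), int(l)) for n, l in doc["chromosomes"]]
        doc["segments"] = [PlantedSegment(**s) for s in doc.get("segments", [])]
        spec = cls(**doc)
        spec.validate()
        return spec


def default_spec(seed: int = 1) -> GenomeSpec:
    """Scaled-down mirror of the *S. brachyura* architecture.

    * ``chrZ`` — 5 Mb ancestral Z, fully degenerate W (halved female depth,
      no excess female heterozygosity);
    * ``chr4A`` — 3 Mb translocated-chromosome analogue: 1.5 Mb still
      recombining (PAR-like), 1.5 Mb moderately degenerate, fused to Z at
      its high-coordinate end;
    * ``chr8`` — 4 Mb: 1 Mb autosomal remainder, a 2 Mb interior
      moderately degenerate segment fused to Z at its low-coordinate edge,
      and a 1 Mb PAR;
    * ``chrA`` — 8 Mb autosome, giving the per-individual median window
      depth (the normalization constant) an unambiguous autosomal majority.
    """
    return GenomeSpec(
        chromosomes=[("chrZ", 5_000_000), ("chr4A", 3_000_000), ("chr8", 4_000_000), ("chrA", 8_000_000)],
        segments=[
            PlantedSegment("chrZ", 0, 5_000_000, "SEXLINKED", w_retention=0.0, zw_divergence=2e-3),
            PlantedSegment("chr4A", 0, 1_500_000, "PAR"),
            PlantedSegment(
                "chr4A", 1_500_000, 3_000_000, "SEXLINKED",
                w_retention=0.5, zw_divergence=2e-3, fusion_side="right",
            ),
            PlantedSegment("chr8", 0, 1_000_000, "AUTOSOME"),
            PlantedSegment(
                "chr8", 1_000_000, 3_000_000, "SEXLINKED",
                w_retention=0.5, zw_divergence=2e-3, fusion_side="left",
            ),
            PlantedSegment("chr8", 3_000_000, 4_000_000, "PAR"),
        ],
        ancestral_z="chrZ",
        seed=seed,
    )


def autosomal_spec(n_chromosomes: int = 20, chrom_length: int = 2_000_000, seed: int = 1,
                   **kwargs) -> GenomeSpec:
    """An all-autosome genome (specificity null model): no planted signal."""
    return GenomeSpec(
        chromosomes=[(f"chr{i + 1}", chrom_length) for i in range(n_chromosomes)],
        segments=[], seed=seed, **kwargs,
    )


# ---------------------------------------------------------------------------
# interval helpers (all intervals are 0-based half-open numpy arrays)

def _interval_lengths(ivs: np.ndarray) -> np.ndarray:
    return ivs[:, 1] - ivs[:, 0]


def _complement(ivs: np.ndarray, length: int) -> np.ndarray:
    """Complement of a sorted, disjoint interval set within [0, length)."""
    out = []
    prev = 0
    for a, b in ivs:
        if a > prev:
            out.append((prev, a))
        prev = max(prev, b)
    if prev < length:
        out.append((prev, length))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def _merge(ivs: Iterable[tuple[int, int]]) -> np.ndarray:
    ivs = sorted(ivs)
    out: list[list[int]] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def _sample_positions(ivs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` positions uniformly over an interval set."""
    if n == 0 or len(ivs) == 0:
        return np.empty(0, dtype=np.int64)
    lens = _interval_lengths(ivs)
    cum = np.concatenate([[0], np.cumsum(lens)])
    u = rng.integers(0, cum[-1], size=n)
    k = np.searchsorted(cum, u, side="right") - 1
    return ivs[k, 0] + (u - cum[k])


# ---------------------------------------------------------------------------

@dataclass
class Haplotype:
    """A sequence-producing haplotype: name plus producing intervals per chromosome."""

    name: str
    code: int
    producing: dict[str, np.ndarray]  # chrom -> (n, 2) intervals that emit reads


class SimulatedGenome:
    """Output of :func:`simulate_genome`.

    Attributes
    ----------
    spec : GenomeSpec
    truth : pandas.DataFrame
        One row per planted variant: ``chrom, pos, kind, hap, alt_offset,
        ins_len, gt_f, gt_m, dp_f, dp_m``.  Genotypes are coded
        0 = hom-ref, 1 = het, 2 = hom-alt.  ``hap`` names the carrier
        haplotype (−1 = all four, for reference-error sites).
    female, male : tuple[Haplotype, Haplotype]
    """

    def __init__(self, spec: GenomeSpec, truth: pd.DataFrame,
                 w_retained: dict[str, np.ndarray]):
        self.spec = spec
        self.truth = truth
        self.w_retained = w_retained
        full = {c: np.array([[0, l]], dtype=np.int64) for c, l in spec.chromosomes}
        self.female = (
            Haplotype("Z_F", HAP_ZF, full),
            Haplotype("W", HAP_W, w_retained),
        )
        self.male = (
            Haplotype("Z_M1", HAP_ZM1, full),
            Haplotype("Z_M2", HAP_ZM2, full),
        )
        self._reference: dict[str, np.ndarray] | None = None

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.spec.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return self.spec.lengths

    def haplotypes(self, individual: str) -> tuple[Haplotype, Haplotype]:
        if individual == "female":
            return self.female
        if individual == "male":
            return self.male
        raise ValueError(f"unknown individual {individual!r}")

    # -- reference sequence (lazy; not needed for in-memory statistics) --
    @property
    def reference(self) -> dict[str, np.ndarray]:
        """Reference sequence per chromosome as uint8 arrays of ACGT codes."""
        if self._reference is None:
            self._reference = {}
            for i, (name, length) in enumerate(self.spec.chromosomes):
                rng = np.random.default_rng(
                    np.random.SeedSequence([self.spec.seed, 101, i])
                )
                self._reference[name] = _BASES[rng.integers(0, 4, size=length)]
        return self._reference

    def reference_str(self, chrom: str) -> str:
        return self.reference[chrom].tobytes().decode()

    def w_copy_present(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean: does the W haplotype produce sequence at these positions?"""
        ivs = self.w_retained[chrom]
        if len(ivs) == 0:
            return np.zeros(len(positions), dtype=bool)
        starts, ends = ivs[:, 0], ivs[:, 1]
        k = np.searchsorted(starts, positions, side="right") - 1
        k_ok = k >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[k_ok] = positions[k_ok] < ends[k[k_ok]]
        return out

    def mismatch_positions(self, hap_code: int, substituted: pd.Series | None = None
                           ) -> dict[str, np.ndarray]:
        """Sorted per-chromosome positions where a haplotype differs from the
        reference (``substituted=None``) or from a consensus in which the rows
        flagged by ``substituted`` (boolean, aligned to ``self.truth.index``)
        carry the alternate allele.  Insertions are excluded (they do not
        contribute to per-read mismatch counts)."""
        t = self.truth
        carries = (t["hap"].to_numpy() == hap_code) | (t["hap"].to_numpy() == HAP_ALL)
        snv = t["ins_len"].to_numpy() == 0
        if substituted is None:
            mism = carries & snv
        else:
            mism = snv & (carries ^ substituted.to_numpy())
        sub = t.loc[mism, ["chrom", "pos"]]
        return {c: np.sort(g["pos"].to_numpy()) for c, g in sub.groupby("chrom", sort=False)}

    def truth_segments(self) -> pd.DataFrame:
        """Planted segments as a BED-like table (chrom, start, end, role, ...)."""
        rows = [dataclasses.asdict(s) for s in self.spec.segments]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "role",
                                           "w_retention", "zw_divergence", "fusion_side"])


def simulate_genome(spec: GenomeSpec) -> SimulatedGenome:
    """Plant variants and W-deletion structure according to ``spec``.

    Returns a :class:`SimulatedGenome`; the reference sequence is generated
    lazily so purely statistical experiments never materialize it.
    """
    spec.validate()
    root = np.random.SeedSequence([int(spec.seed), 7])
    ss_blocks, ss_var, ss_dp = root.spawn(3)
    rng_blocks = np.random.default_rng(ss_blocks)
    rng = np.random.default_rng(ss_var)

    lengths = spec.lengths
    segs_by_chrom: dict[str, list[PlantedSegment]] = {c: [] for c in lengths}
    for seg in spec.segments:
        segs_by_chrom[seg.chrom].append(seg)

    # W retention structure: delete blocks within SEXLINKED segments.
    w_retained: dict[str, np.ndarray] = {}
    zw_eligible: dict[str, np.ndarray] = {}  # retained W within SEXLINKED segments
    for chrom, length in spec.chromosomes:
        deleted: list[tuple[int, int]] = []
        eligible: list[tuple[int, int]] = []
        for seg in segs_by_chrom[chrom]:
            if seg.role != "SEXLINKED":
                continue
            bounds = np.arange(seg.start, seg.end, spec.block_size)
            ends = np.minimum(bounds + spec.block_size, seg.end)
            keep = rng_blocks.random(len(bounds)) < seg.w_retention
            deleted.extend(zip(bounds[~keep], ends[~keep]))
            eligible.extend(zip(bounds[keep], ends[keep]))
        deleted_ivs = _merge(deleted) if deleted else np.empty((0, 2), dtype=np.int64)
        w_retained[chrom] = _complement(deleted_ivs, length)
        zw_eligible[chrom] = _merge(eligible) if eligible else np.empty((0, 2), dtype=np.int64)

    records: list[pd.DataFrame] = []
    for chrom, length in spec.chromosomes:
        whole = np.array([[0, length]], dtype=np.int64)
        parts = []

        def _add(positions, kind, hap, gt_f, gt_m, ins_len=None):
            n = len(positions)
            if n == 0:
                return
            parts.append(pd.DataFrame({
                "pos": positions,
                "kind": kind,
                "hap": np.full(n, hap, dtype=np.int8),
                "alt_offset": rng.integers(1, 4, size=n).astype(np.int8),
                "ins_len": np.zeros(n, dtype=np.int32) if ins_len is None else ins_len,
                "gt_f": np.full(n, gt_f, dtype=np.int8),
                "gt_m": np.full(n, gt_m, dtype=np.int8),
            }))

        # individual heterozygous SNPs, one carrier haplotype each
        for individual, haps in (("f", FEMALE_HAPS), ("m", MALE_HAPS)):
            n = rng.poisson(spec.snp_rate * length)
            pos = _sample_positions(whole, n, rng)
            hap_pick = rng.integers(0, 2, size=n)
            for j, hap in enumerate(haps):
                _add(pos[hap_pick == j], f"snp_{individual}", hap,
                     gt_f=1 if individual == "f" else 0,
                     gt_m=1 if individual == "m" else 0)

        # reference/assembly error sites: both individuals hom-alt
        n = rng.poisson(spec.ref_error_rate * length)
        _add(_sample_positions(whole, n, rng), "ref_err", HAP_ALL, gt_f=2, gt_m=2)

        # fixed Z-W differences on retained W sequence
        elig = zw_eligible[chrom]
        if len(elig):
            by_seg = {s: s.zw_divergence for s in segs_by_chrom[chrom] if s.role == "SEXLINKED"}
            for seg, div in by_seg.items():
                sub = elig[(elig[:, 0] >= seg.start) & (elig[:, 1] <= seg.end)]
                total = int(_interval_lengths(sub).sum()) if len(sub) else 0
                n = rng.poisson(div * total)
                _add(_sample_positions(sub, n, rng), "zw", HAP_W, gt_f=1, gt_m=0)
                # W-linked insertions (diagnostic-locus candidates)
                n_ins = rng.poisson(spec.zw_insertion_rate * total)
                ins_len = rng.integers(5, 51, size=n_ins).astype(np.int32)
                _add(_sample_positions(sub, n_ins, rng), "zw_ins", HAP_W,
                     gt_f=1, gt_m=0, ins_len=ins_len)

        if not parts:
            continue
        df = pd.concat(parts, ignore_index=True)
        df.insert(0, "chrom", chrom)
        df = df.sort_values("pos", kind="stable").drop_duplicates("pos", keep="first")
        records.append(df)

    if records:
        truth = pd.concat(records, ignore_index=True)
    else:
        truth = pd.DataFrame(columns=["chrom", "pos", "kind", "hap", "alt_offset",
                                      "ins_len", "gt_f", "gt_m"])
    truth["chrom"] = truth["chrom"].astype(str)

    sim = SimulatedGenome(spec, truth, w_retained)

    # per-site sampled sequencing depth (used for genotype-call DP fields)
    rng_dp = np.random.default_rng(ss_dp)
    if len(truth):
        copies_f = np.ones(len(truth), dtype=np.int8)
        for chrom, grp in truth.groupby("chrom", sort=False):
            present = sim.w_copy_present(chrom, grp["pos"].to_numpy())
            copies_f[grp.index.to_numpy()] += present.astype(np.int8)
        truth["dp_f"] = rng_dp.poisson(spec.mean_depth * copies_f).astype(np.int32)
        truth["dp_m"] = rng_dp.poisson(spec.mean_depth * 2.0, size=len(truth)).astype(np.int32)
    else:
        truth["dp_f"] = np.array([], dtype=np.int32)
        truth["dp_m"] = np.array([], dtype=np.int32)
    return sim


# ---------------------------------------------------------------------------
# read placement

class ReadSet:
    """Placed alignment records for one individual.

    Records are stored per sequence as parallel arrays ``start, end, nm,
    hap`` (coordinate-sorted).  Reads crossing a deletion or scaffold
    junction are stored as separate records (each a primary alignment of
    its own length), so depth counting treats files and memory alike.
    """

    def __init__(self, individual: str, records: dict[str, dict[str, np.ndarray]],
                 read_length: int):
        self.individual = individual
        self.records = records
        self.read_length = read_length

    @property
    def n_records(self) -> int:
        return sum(len(r["start"]) for r in self.records.values())

    def sequences(self) -> list[str]:
        return list(self.records)

    def mean_mismatches(self) -> float:
        tot = sum(r["nm"].sum() for r in self.records.values())
        return float(tot / max(self.n_records, 1))

    def with_mismatches(self, mismatch_pos: dict[str, dict[int, np.ndarray]]) -> "ReadSet":
        """Recount NM against a different target genome.

        ``mismatch_pos[seq][hap_code]`` is the sorted array of positions at
        which that haplotype differs from the new target.
        """
        out: dict[str, dict[str, np.ndarray]] = {}
        for seq, rec in self.records.items():
            nm = np.zeros(len(rec["start"]), dtype=np.int32)
            per_hap = mismatch_pos.get(seq, {})
            for hap, mpos in per_hap.items():
                sel = rec["hap"] == hap
                if not sel.any() or len(mpos) == 0:
                    continue
                nm[sel] = (
                    np.searchsorted(mpos, rec["end"][sel])
                    - np.searchsorted(mpos, rec["start"][sel])
                ).astype(np.int32)
            out[seq] = {"start": rec["start"], "end": rec["end"], "nm": nm, "hap": rec["hap"]}
        return ReadSet(self.individual, out, self.read_length)


def _map_through_intervals(ivs: np.ndarray, cum: np.ndarray, s: np.ndarray,
                           rl: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map reads placed on the concatenated producing space back to reference
    coordinates, splitting reads that span producing-interval junctions.

    Returns (piece_start, piece_end, read_index)."""
    starts_out, ends_out, idx_out = [], [], []
    k = np.searchsorted(cum, s, side="right") - 1
    off = s - cum[k]
    remaining = np.full(len(s), rl, dtype=np.int64)
    read_idx = np.arange(len(s))
    while len(k):
        seg_start = ivs[k, 0] + off
        room = ivs[k, 1] - seg_start
        take = np.minimum(room, remaining)
        starts_out.append(seg_start)
        ends_out.append(seg_start + take)
        idx_out.append(read_idx)
        remaining = remaining - take
        more = remaining > 0
        k, off, remaining, read_idx = k[more] + 1, np.zeros(more.sum(), dtype=np.int64), remaining[more], read_idx[more]
    return (np.concatenate(starts_out), np.concatenate(ends_out), np.concatenate(idx_out))


def place_reads(sim: SimulatedGenome, individual: str, *,
                substituted: pd.Series | None = None,
                seed: int | None = None) -> ReadSet:
    """Place single-end reads uniformly on each sequence-producing haplotype.

    Each record's mismatch count is the number of SNV positions it overlaps
    at which its source haplotype differs from the reference (or from the
    consensus whose substituted truth rows are flagged by ``substituted``).
    With ``error_rate > 0`` an additional Poisson term emulates sequencing
    errors.  Identical seeds give identical placements, so a consensus-pass
    recount changes only the NM values.
    """
    spec = sim.spec
    rl = spec.read_length
    base_seed = spec.seed if seed is None else seed
    idx = {"female": 0, "male": 1}[individual]
    rng = np.random.default_rng(np.random.SeedSequence([int(base_seed), 11, idx]))

    mismatch = {
        hap.code: sim.mismatch_positions(hap.code, substituted)
        for hap in sim.haplotypes(individual)
    }

    per_seq: dict[str, dict[str, list[np.ndarray]]] = {
        c: {"start": [], "end": [], "nm": [], "hap": []} for c in sim.chrom_names
    }
    for hap in sim.haplotypes(individual):
        for chrom in sim.chrom_names:
            ivs = hap.producing.get(chrom)
            if ivs is None or len(ivs) == 0:
                continue
            lens = _interval_lengths(ivs)
            total = int(lens.sum())
            if total < rl:
                continue
            cum = np.concatenate([[0], np.cumsum(lens)])
            n = rng.poisson(spec.mean_depth * total / rl)
            if n == 0:
                continue
            s = rng.integers(0, total - rl + 1, size=n)
            ps, pe, ridx = _map_through_intervals(ivs, cum, s, rl)
            mpos = mismatch[hap.code].get(chrom, np.empty(0, dtype=np.int64))
            nm = (np.searchsorted(mpos, pe) - np.searchsorted(mpos, ps)).astype(np.int32)
            if spec.error_rate > 0:
                nm = nm + rng.poisson(spec.error_rate * (pe - ps)).astype(np.int32)
            del ridx
            d = per_seq[chrom]
            d["start"].append(ps)
            d["end"].append(pe)
            d["nm"].append(nm)
            d["hap"].append(np.full(len(ps), hap.code, dtype=np.int8))

    records: dict[str, dict[str, np.ndarray]] = {}
    for chrom, d in per_seq.items():
        if not d["start"]:
            continue
        start = np.concatenate(d["start"])
        order = np.argsort(start, kind="stable")
        records[chrom] = {
            "start": start[order],
            "end": np.concatenate(d["end"])[order],
            "nm": np.concatenate(d["nm"])[order],
            "hap": np.concatenate(d["hap"])[order],
        }
    return ReadSet(individual, records, rl)


# ---------------------------------------------------------------------------
# assembly fragmentation

def n50(lengths: Sequence[int]) -> int:
    """Standard N50: largest L such that pieces >= L cover half the total."""
    arr = np.sort(np.asarray(lengths))[::-1]
    if arr.size == 0:
        return 0
    half = arr.sum() / 2
    return int(arr[np.searchsorted(np.cumsum(arr), half)])


class Assembly:
    """A fragmented study assembly plus ground-truth anchors.

    ``anchors`` has one row per scaffold: ``scaffold, s_len, chrom,
    c_start, c_end, strand``; scaffolds partition every chromosome.
    Scaffold coordinates: position ``p`` on the chromosome maps to
    ``p - c_start`` (+) or ``c_end - 1 - p`` (−).
    """

    def __init__(self, anchors: pd.DataFrame):
        self.anchors = anchors.reset_index(drop=True)
        self._by_chrom = {
            c: g.sort_values("c_start").reset_index(drop=True)
            for c, g in self.anchors.groupby("chrom", sort=False)
        }

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return dict(zip(self.anchors["scaffold"], self.anchors["s_len"]))

    def realized_n50(self) -> int:
        return n50(self.anchors["s_len"].to_numpy())

    def chrom_partition(self, chrom: str) -> pd.DataFrame:
        return self._by_chrom[chrom]

    # -- coordinate transforms -----------------------------------------
    def map_positions(self, chrom: str, pos: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map chromosome positions to (anchor_row_index, scaffold_pos, strand=+1/−1)."""
        part = self._by_chrom[chrom]
        starts = part["c_start"].to_numpy()
        k = np.searchsorted(starts, pos, side="right") - 1
        c_start = part["c_start"].to_numpy()[k]
        c_end = part["c_end"].to_numpy()[k]
        fwd = (part["strand"].to_numpy() == "+")[k]
        spos = np.where(fwd, pos - c_start, c_end - 1 - pos)
        return k, spos, np.where(fwd, 1, -1)

    def map_intervals(self, chrom: str, starts: np.ndarray, ends: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Split chromosome intervals at scaffold junctions and express them in
        scaffold coordinates (strand-aware).

        Returns flat arrays ``(anchor_row, s_start, s_end, source_index)``
        where ``anchor_row`` indexes this chromosome's partition table and
        ``source_index`` indexes the input intervals."""
        part = self._by_chrom[chrom]
        p_start = part["c_start"].to_numpy()
        p_end = part["c_end"].to_numpy()
        fwd = part["strand"].to_numpy() == "+"
        rows_out, sa_out, sb_out, idx_out = [], [], [], []
        a = np.asarray(starts, dtype=np.int64).copy()
        b = np.asarray(ends, dtype=np.int64).copy()
        idx = np.arange(len(a))
        while len(a):
            k = np.searchsorted(p_start, a, side="right") - 1
            stop = np.minimum(b, p_end[k])
            sa = np.where(fwd[k], a - p_start[k], p_end[k] - stop)
            sb = np.where(fwd[k], stop - p_start[k], p_end[k] - a)
            rows_out.append(k)
            sa_out.append(sa)
            sb_out.append(sb)
            idx_out.append(idx)
            more = stop < b
            a, b, idx = stop[more], b[more], idx[more]
        if not rows_out:
            z = np.empty(0, dtype=np.int64)
            return z, z, z, z
        return (np.concatenate(rows_out), np.concatenate(sa_out),
                np.concatenate(sb_out), np.concatenate(idx_out))

    def invert_interval(self, chrom: str, start: int, end: int
                        ) -> list[tuple[str, int, int]]:
        """Scaffold intervals corresponding to a chromosome interval."""
        part = self._by_chrom[chrom]
        names = part["scaffold"].to_numpy()
        rows, sa, sb, _ = self.map_intervals(
            chrom, np.array([start], dtype=np.int64), np.array([end], dtype=np.int64)
        )
        return [(names[r], int(x), int(y)) for r, x, y in zip(rows, sa, sb)]

    def scaffold_sequences(self, reference: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        seqs = {}
        comp = np.zeros(256, dtype=np.uint8)
        for x, y in zip(b"ACGT", b"TGCA"):
            comp[x] = y
        for row in self.anchors.itertuples():
            chunk = reference[row.chrom][row.c_start:row.c_end]
            seqs[row.scaffold] = chunk if row.strand == "+" else comp[chunk[::-1]]
        return seqs

    def to_paf(self) -> pd.DataFrame:
        """Truth anchors as PAF rows (scaffold = query, chromosome = target)."""
        a = self.anchors
        ln = a["s_len"]
        tlen = a["chrom"].map(a.groupby("chrom")["c_end"].max())
        return pd.DataFrame({
            "qname": a["scaffold"], "qlen": ln, "qstart": 0, "qend": ln,
            "strand": a["strand"], "tname": a["chrom"],
            "tlen": tlen.astype(int),
            "tstart": a["c_start"], "tend": a["c_end"],
            "nmatch": ln, "alnlen": ln, "mapq": 60,
        })


def fragment_assembly(sim_or_lengths, target_n50: int, seed: int = 0, *,
                      rc_fraction: float = 0.3, min_scaffold: int = 2000,
                      max_scaffold: int | None = None,
                      forced_breaks: dict[str, Sequence[int]] | None = None,
                      avoid_breaks: dict[str, Sequence[int]] | None = None,
                      avoid_margin: int = 0) -> Assembly:
    """Cut each chromosome into scaffolds whose realized N50 approximates
    ``target_n50``; a ``rc_fraction`` of scaffolds is reverse-complemented
    (strand recorded in the truth anchors).

    ``forced_breaks`` forces scaffold ends at given chromosome coordinates,
    emulating assembly breaks at fusion junctions; ``avoid_breaks`` (with
    ``avoid_margin``) suppresses random cuts near given coordinates, so
    that e.g. recombination boundaries — which are not sequence breaks in
    the study species — end up *inside* scaffolds with informative flanks
    on both sides.  Scaffolds partition the reference: concatenating
    anchors in truth order reconstructs every chromosome exactly.
    """
    lengths = sim_or_lengths.lengths if hasattr(sim_or_lengths, "lengths") else dict(sim_or_lengths)
    if not lengths:
        raise ValidationError("empty reference")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    forced_breaks = forced_breaks or {}
    avoid_breaks = avoid_breaks or {}

    if target_n50 > max(lengths.values()):
        warnings.warn("target_n50 exceeds the longest chromosome; "
                      "emitting one scaffold per chromosome", stacklevel=2)

    # exponential piece lengths; length-weighted median of Exp(m) pieces ~ 1.678 m
    mean_piece = max(float(min_scaffold), target_n50 / 1.678)
    rows = []
    for chrom, length in lengths.items():
        avoided = np.asarray(sorted(avoid_breaks.get(chrom, ())), dtype=np.int64)
        cuts = {0, length}
        pos = 0
        while True:
            step = max(min_scaffold, int(rng.exponential(mean_piece)))
            if max_scaffold is not None:
                step = min(step, max_scaffold)
            pos += step
            if pos >= length - min_scaffold:
                break
            if len(avoided) and np.min(np.abs(avoided - pos)) < avoid_margin:
                continue
            cuts.add(pos)
        for b in forced_breaks.get(chrom, ()):
            if 0 < b < length:
                cuts.add(int(b))
        bounds = sorted(cuts)
        for a, b in zip(bounds, bounds[1:]):
            strand = "-" if rng.random() < rc_fraction else "+"
            rows.append((chrom, a, b, strand))

    order = rng.permutation(len(rows))
    anchors = pd.DataFrame(
        [rows[i] for i in order], columns=["chrom", "c_start", "c_end", "strand"]
    )
    anchors.insert(0, "scaffold", [f"scaffold_{i + 1}" for i in range(len(anchors))])
    anchors.insert(1, "s_len", anchors["c_end"] - anchors["c_start"])
    return Assembly(anchors)


# ---------------------------------------------------------------------------
# coordinate transforms of reads and truth genotypes onto an assembly

def reads_to_scaffolds(reads: ReadSet, assembly: Assembly, sim: SimulatedGenome,
                       substituted: pd.Series | None = None) -> ReadSet:
    """Re-express placed records in study-assembly coordinates, splitting
    records that span scaffold junctions, and recount each piece's mismatches
    in scaffold space (against the scaffold reference, or against a consensus
    when ``substituted`` flags the majority-substituted truth rows)."""
    truth_sc = truth_to_scaffolds(sim, assembly)
    hap_codes = [h.code for h in (*sim.female, *sim.male)]
    mismatch = {h: scaffold_mismatch_positions(truth_sc, h, substituted) for h in hap_codes}

    per_seq: dict[str, dict[str, list[np.ndarray]]] = {}
    for chrom, rec in reads.records.items():
        part = assembly.chrom_partition(chrom)
        names = part["scaffold"].to_numpy()
        rows, sa, sb, src = assembly.map_intervals(chrom, rec["start"], rec["end"])
        hap = rec["hap"][src]
        order = np.argsort(rows, kind="stable")
        rows, sa, sb, hap = rows[order], sa[order], sb[order], hap[order]
        bounds = np.searchsorted(rows, np.arange(len(part) + 1))
        for r in range(len(part)):
            lo, hi = bounds[r], bounds[r + 1]
            if lo == hi:
                continue
            d = per_seq.setdefault(names[r], {"start": [], "end": [], "hap": []})
            d["start"].append(sa[lo:hi])
            d["end"].append(sb[lo:hi])
            d["hap"].append(hap[lo:hi])

    records = {}
    for scaf, d in per_seq.items():
        start = np.concatenate(d["start"])
        order = np.argsort(start, kind="stable")
        start = start[order]
        end = np.concatenate(d["end"])[order]
        hap = np.concatenate(d["hap"])[order]
        nm = np.zeros(len(start), dtype=np.int32)
        for h in hap_codes:
            mpos = mismatch[h].get(scaf)
            if mpos is None or len(mpos) == 0:
                continue
            sel = hap == h
            nm[sel] = (np.searchsorted(mpos, end[sel])
                       - np.searchsorted(mpos, start[sel])).astype(np.int32)
        records[scaf] = {"start": start, "end": end, "nm": nm, "hap": hap}
    return ReadSet(reads.individual, records, reads.read_length)


def truth_to_scaffolds(sim: SimulatedGenome, assembly: Assembly) -> pd.DataFrame:
    """Truth variant table re-expressed in scaffold coordinates.

    Adds ``chrom_src``/``pos_src`` (original coordinates) and ``strand``.
    """
    t = sim.truth
    out = t.copy()
    new_seq = np.empty(len(t), dtype=object)
    new_pos = np.empty(len(t), dtype=np.int64)
    strand = np.empty(len(t), dtype=np.int8)
    for chrom, grp in t.groupby("chrom", sort=False):
        part = assembly.chrom_partition(chrom)
        k, spos, sgn = assembly.map_positions(chrom, grp["pos"].to_numpy())
        new_seq[grp.index.to_numpy()] = part["scaffold"].to_numpy()[k]
        new_pos[grp.index.to_numpy()] = spos
        strand[grp.index.to_numpy()] = sgn
    out = out.rename(columns={"chrom": "chrom_src", "pos": "pos_src"})
    out.insert(0, "chrom", new_seq)
    out.insert(1, "pos", new_pos)
    out["strand"] = strand
    return out


def scaffold_mismatch_positions(truth_sc: pd.DataFrame, hap_code: int,
                                substituted: pd.Series | None = None
                                ) -> dict[str, np.ndarray]:
    """Per-scaffold sorted mismatch positions for one haplotype (scaffold space)."""
    carries = (truth_sc["hap"].to_numpy() == hap_code) | (truth_sc["hap"].to_numpy() == HAP_ALL)
    snv = truth_sc["ins_len"].to_numpy() == 0
    if substituted is None:
        mism = carries & snv
    else:
        mism = snv & (carries ^ substituted.to_numpy())
    sub = truth_sc.loc[mism, ["chrom", "pos"]]
    return {c: np.sort(g["pos"].to_numpy()) for c, g in sub.groupby("chrom", sort=False)}
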