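"""Synteny anchoring: lifting scaffold-space window statistics onto the
chromosomes of a contiguous reference genome.

A fragmented study assembly has no chromosome coordinates; pairwise
alignments (PAF) against a chromosome-level genome of a related species
provide them.  Anchors are filtered to a best-hit set (overlaps on the
same scaffold query interval are resolved by alignment length, then
identity, then target name), and each scaffold window is lifted through
the anchor covering its midpoint with a strand-aware affine transform,
then re-binned into target-coordinate windows by weighted mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import tile_windows

log = logging.getLogger(__name__)

__all__ = [
    "ScaffoldAnchor",
    "read_paf",
    "write_paf",
    "assign_anchors",
    "lift_windows",
]

PAF_COLUMNS = ["qname", "qlen", "qstart", "qend", "strand", "tname", "tlen",
               "tstart", "tend", "nmatch", "alnlen", "mapq"]


@dataclass(frozen=True)
class ScaffoldAnchor:
    """One scaffold-to-chromosome alignment (0-based half-open intervals)."""

    scaffold: str
    q_start: int
    q_end: int
    chrom: str
    t_start: int
    t_end: int
    strand: str
    aln_len: int
    identity: float

    def validate(self) -> None:
        if self.q_end <= self.q_start or self.t_end <= self.t_start:
            raise ValueError("anchor intervals must be non-empty and ordered")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")


def _frame(anchors: list[ScaffoldAnchor]) -> pd.DataFrame:
    return pd.DataFrame([a.__dict__ for a in anchors],
                        columns=list(ScaffoldAnchor.__dataclass_fields__))


def read_paf(path) -> pd.DataFrame:
    """Read PAF alignments into an anchor table (scaffold = query,
    chromosome = target).  Malformed lines are rejected with a logged
    warning carrying their line numbers; an empty file (or one with no
    valid line) is an error."""
    anchors: list[ScaffoldAnchor] = []
    rejected: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 12:
                    raise ValueError("fewer than 12 columns")
                qname, qlen, qs, qe, strand, tname, tlen, ts, te, nmatch, alnlen, _mapq = fields[:12]
                anchor = ScaffoldAnchor(
                    scaffold=qname, q_start=int(qs), q_end=int(qe),
                    chrom=tname, t_start=int(ts), t_end=int(te),
                    strand=strand, aln_len=int(alnlen),
                    identity=int(nmatch) / max(int(alnlen), 1),
                )
                anchor.validate()
                if anchor.q_end > int(qlen) or anchor.t_end > int(tlen):
                    raise ValueError("interval exceeds sequence length")
            except (ValueError, ZeroDivisionError):
                rejected.append(lineno)
                continue
            anchors.append(anchor)
    if rejected:
        log.warning("rejected %d malformed PAF lines: %s", len(rejected), rejected)
    if not anchors:
        raise ValueError(f"no valid PAF alignments in {path}")
    df = _frame(anchors)
    df.attrs["rejected_lines"] = rejected
    return df


def write_paf(paf: pd.DataFrame, path) -> None:
    """Write a PAF table (with the 12 standard columns) as tab-separated text."""
    missing = [c for c in PAF_COLUMNS if c not in paf.columns]
    if missing:
        raise ValueError(f"PAF table lacks columns {missing}")
    paf[PAF_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def anchors_to_paf(anchors: pd.DataFrame, qlen: dict[str, int], tlen: dict[str, int]
                   ) -> pd.DataFrame:
    """Anchor table back to PAF columns (identity → nmatch, rounded)."""
    return pd.DataFrame({
        "qname": anchors["scaffold"],
        "qlen": anchors["scaffold"].map(qlen),
        "qstart": anchors["q_start"], "qend": anchors["q_end"],
        "strand": anchors["strand"], "tname": anchors["chrom"],
        "tlen": anchors["chrom"].map(tlen),
        "tstart": anchors["t_start"], "tend": anchors["t_end"],
        "nmatch": (anchors["identity"] * anchors["aln_len"]).round().astype(int),
        "alnlen": anchors["aln_len"], "mapq": 60,
    })


def anchors_from_paf_table(paf: pd.DataFrame) -> pd.DataFrame:
    """Convert a 12-column PAF table into the internal anchor table."""
    return pd.DataFrame({
        "scaffold": paf["qname"].astype(str),
        "q_start": paf["qstart"].astype(int),
        "q_end": paf["qend"].astype(int),
        "chrom": paf["tname"].astype(str),
        "t_start": paf["tstart"].astype(int),
        "t_end": paf["tend"].astype(int),
        "strand": paf["strand"].astype(str),
        "aln_len": paf["alnlen"].astype(int),
        "identity": (paf["nmatch"] / paf["alnlen"].clip(lower=1)).astype(float),
    })


def _trim(row: pd.Series, a: int, b: int) -> dict:
    """Restrict an anchor to query sub-interval [a, b), affine-adjusting the
    target interval (strand-aware)."""
    scale = (row.t_end - row.t_start) / (row.q_end - row.q_start)
    if row.strand == "+":
        ta = row.t_start + round((a - row.q_start) * scale)
        tb = row.t_start + round((b - row.q_start) * scale)
    else:
        ta = row.t_end - round((b - row.q_start) * scale)
        tb = row.t_end - round((a - row.q_start) * scale)
    out = row._asdict() if hasattr(row, "_asdict") else dict(row)
    out.pop("Index", None)
    out.update(q_start=a, q_end=b, t_start=int(ta), t_end=int(tb),
               aln_len=int(round(row.aln_len * (b - a) / (row.q_end - row.q_start))))
    return out


def assign_anchors(anchors: pd.DataFrame, min_len: int = 1000,
                   min_identity: float = 0.0) -> pd.DataFrame:
    """Filter anchors to a per-base best-hit set.

    Anchors shorter than ``min_len`` or below ``min_identity`` are dropped.
    Where two retained anchors overlap on the same scaffold query interval,
    the one with greater ``aln_len`` (ties: greater identity, then
    lexicographically smaller target name) masks the overlap of the other;
    the loser keeps its non-overlapped portions, affine-trimmed.
    """
    kept = anchors[(anchors["aln_len"] >= min_len)
                   & (anchors["identity"] >= min_identity)].copy()
    out_rows: list[dict] = []
    for scaffold, grp in kept.groupby("scaffold", sort=False):
        grp = grp.sort_values(["aln_len", "identity", "chrom"],
                              ascending=[False, False, True], kind="stable")
        claimed: list[tuple[int, int]] = []  # disjoint sorted q-intervals
        for row in grp.itertuples():
            pieces = [(row.q_start, row.q_end)]
            for ca, cb in claimed:
                nxt = []
                for a, b in pieces:
                    if b <= ca or a >= cb:
                        nxt.append((a, b))
                    else:
                        if a < ca:
                            nxt.append((a, ca))
                        if b > cb:
                            nxt.append((cb, b))
                pieces = nxt
            for a, b in pieces:
                if b - a <= 0:
                    continue
                out_rows.append(_trim(row, a, b))
                claimed.append((a, b))
            claimed.sort()
    result = pd.DataFrame(out_rows, columns=list(anchors.columns))
    return result.sort_values(["scaffold", "q_start"], kind="stable").reset_index(drop=True)


def _covering_anchor(anchors_sorted: pd.DataFrame, mids: np.ndarray) -> np.ndarray:
    """Index (into anchors_sorted) of the anchor covering each midpoint, or −1."""
    qs = anchors_sorted["q_start"].to_numpy()
    qe = anchors_sorted["q_end"].to_numpy()
    k = np.searchsorted(qs, mids, side="right") - 1
    ok = (k >= 0) & (mids < qe[np.clip(k, 0, None)])
    return np.where(ok, k, -1)


def lift_windows(stats: pd.DataFrame, anchors: pd.DataFrame, target_window: int,
                 target_lengths: dict[str, int],
                 value_columns: tuple[str, ...] = ("cov_f_norm", "cov_m_norm", "cov_diff",
                                                   "het_f", "het_m", "het_diff"),
                 ) -> tuple[pd.DataFrame, int]:
    """Lift scaffold-space window statistics into target chromosome windows.

    Each source window's midpoint is mapped through its covering (assigned)
    anchor; windows without a covering anchor are dropped and counted.
    Lifted values are re-binned into the target tiling by weighted mean:
    coverage columns are weighted by source-window extent (bases) and
    heterozygosity columns by genotyped sites, so a lifted value is the
    pooled per-base / per-site statistic of its sources rather than an
    equal-weight mean over scaffolds of very different sizes (weights are
    tracked separately per column, since heterozygosity may be missing
    where coverage is not).

    Returns ``(lifted stats on the full target tiling, n_dropped)``.
    """
    target = tile_windows(target_lengths, target_window)
    by_scaffold = {s: g.reset_index(drop=True) for s, g in anchors.groupby("scaffold", sort=False)}

    seqs = stats["seq"].to_numpy()
    mids = ((stats["start"].to_numpy() + stats["end"].to_numpy()) // 2).astype(np.int64)
    t_chrom = np.full(len(stats), "", dtype=object)
    t_pos = np.full(len(stats), -1, dtype=np.int64)
    for scaffold, grp_anchors in by_scaffold.items():
        sel = np.flatnonzero(seqs == scaffold)
        if len(sel) == 0:
            continue
        k = _covering_anchor(grp_anchors, mids[sel])
        hit = k >= 0
        rows = grp_anchors.iloc[k[hit]]
        q0 = rows["q_start"].to_numpy()
        scale = (rows["t_end"].to_numpy() - rows["t_start"].to_numpy()) / (
            rows["q_end"].to_numpy() - rows["q_start"].to_numpy())
        off = ((mids[sel][hit] - q0) * scale).astype(np.int64)
        fwd = rows["strand"].to_numpy() == "+"
        pos = np.where(fwd, rows["t_start"].to_numpy() + off,
                       rows["t_end"].to_numpy() - 1 - off)
        chroms = rows["chrom"].to_numpy()
        lens = np.array([target_lengths.get(c, -1) for c in chroms])
        if np.any((pos < 0) | (pos >= lens)):
            raise ValueError("anchor arithmetic maps outside target bounds "
                             "(inconsistent PAF?)")
        t_chrom[sel[hit]] = chroms
        t_pos[sel[hit]] = pos
    n_dropped = int((t_pos < 0).sum())

    # target bin per source window
    tgt_blocks = {c: np.flatnonzero((target["seq"] == c).to_numpy()) for c in target_lengths}
    bin_idx = np.full(len(stats), -1, dtype=np.int64)
    hit = t_pos >= 0
    for chrom in target_lengths:
        m = hit & (t_chrom == chrom)
        if not m.any():
            continue
        bin_idx[m] = tgt_blocks[chrom][0] + t_pos[m] // target_window

    out = target.copy()
    counts_any = np.zeros(len(target), dtype=np.int64)
    np.add.at(counts_any, bin_idx[hit], 1)
    out["n_source"] = counts_any
    cov_w = (stats["end"].to_numpy() - stats["start"].to_numpy()).astype(float)
    het_w = (stats["n_sites_genotyped"].to_numpy(dtype=float)
             if "n_sites_genotyped" in stats else np.ones(len(stats)))
    for col in value_columns:
        if col not in stats:
            continue
        weights = het_w if col.startswith("het") else cov_w
        vals = stats[col].to_numpy(dtype=float)
        good = hit & np.isfinite(vals) & (weights > 0)
        tot = np.zeros(len(target))
        cnt = np.zeros(len(target))
        np.add.at(tot, bin_idx[good], vals[good] * weights[good])
        np.add.at(cnt, bin_idx[good], weights[good])
        with np.errstate(invalid="ignore"):
            out[col] = np.where(cnt > 0, tot / np.maximum(cnt, 1e-300), np.nan)
    for col in ("n_sites_genotyped", "n_bases_covered"):
        if col in stats:
            vals = stats[col].to_numpy(dtype=float)
            good = hit & np.isfinite(vals)
            tot = np.zeros(len(target))
            np.add.at(tot, bin_idx[good], vals[good])
            out[col] = tot.astype(np.int64)
    return out, n_dropped
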