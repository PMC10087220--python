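"""Per-window coverage and heterozygosity statistics.

The scan's two metrics, computed in fixed windows along each sequence:

* normalized genome coverage per sex — mean per-base read depth per
  window, divided by the genome-wide *median* of that individual's window
  depths (robust against the sex-linked minority of windows);
* percent heterozygous sites per sex — among sites with a passing
  genotype call in *both* samples, the percentage called heterozygous for
  that sample.

The female-minus-male differences of these two metrics (``cov_diff``,
``het_diff``) are the signal everything downstream consumes: W
degeneration halves female depth over hemizygous sequence
(``cov_diff → −0.5``) while fixed Z–W differences on retained W sequence
inflate female heterozygosity (``het_diff > 0``).
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .simulate import ReadSet

log = logging.getLogger(__name__)

__all__ = [
    "tile_windows",
    "window_depth",
    "normalize_coverage",
    "window_heterozygosity",
    "make_window_stats",
]


def tile_windows(lengths: dict[str, int], window: int) -> pd.DataFrame:
    """Tile every sequence with half-open windows of ``window`` bp; the final
    window of a sequence is truncated."""
    if window <= 0:
        raise ValueError("window size must be > 0")
    rows = []
    for seq, length in lengths.items():
        starts = np.arange(0, length, window, dtype=np.int64)
        ends = np.minimum(starts + window, length)
        rows.append(pd.DataFrame({"seq": seq, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def _seq_blocks(windows: pd.DataFrame) -> dict[str, tuple[int, np.ndarray, np.ndarray]]:
    blocks = {}
    for seq, grp in windows.groupby("seq", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if not (np.all(np.diff(starts) > 0) and np.all(starts[1:] == ends[:-1])):
            raise ValueError(f"windows for {seq!r} are not a sorted contiguous tiling")
        blocks[seq] = (int(grp.index[0]), starts, ends)
    return blocks


def _add_intervals(acc: np.ndarray, offset: int, wstarts: np.ndarray, wends: np.ndarray,
                   a: np.ndarray, b: np.ndarray) -> None:
    """Accumulate interval base counts into window bins (handles intervals
    spanning several windows)."""
    limit = wends[-1]
    a = np.clip(a, wstarts[0], limit)
    b = np.clip(b, wstarts[0], limit)
    keep = b > a
    a, b = a[keep], b[keep]
    while len(a):
        i = np.searchsorted(wstarts, a, side="right") - 1
        stop = np.minimum(b, wends[i])
        np.add.at(acc, offset + i, stop - a)
        more = stop < b
        a, b = stop[more], b[more]


def _bam_records(path) -> ReadSet:
    import pysam

    per_seq: dict[str, dict[str, list]] = {}
    with pysam.AlignmentFile(os.fspath(path), "rb") as bam:
        if not bam.has_index():
            raise FileNotFoundError(f"BAM index missing for {path}")
        for read in bam.fetch():
            if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            d = per_seq.setdefault(read.reference_name, {"start": [], "end": [], "nm": []})
            d["start"].append(read.reference_start)
            d["end"].append(read.reference_end)
            d["nm"].append(read.get_tag("NM") if read.has_tag("NM") else 0)
    records = {
        seq: {
            "start": np.asarray(d["start"], dtype=np.int64),
            "end": np.asarray(d["end"], dtype=np.int64),
            "nm": np.asarray(d["nm"], dtype=np.int32),
            "hap": np.zeros(len(d["start"]), dtype=np.int8),
        }
        for seq, d in per_seq.items()
    }
    return ReadSet("unknown", records, 0)


def window_depth(alignments, windows: pd.DataFrame, mismatch_filter: int | None = 2
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-base depth per window for one individual.

    ``alignments`` is a :class:`~neozscan.simulate.ReadSet` or a path to a
    coordinate-sorted indexed BAM.  Records with mismatch count above
    ``mismatch_filter`` are ignored (``None`` disables the filter — the
    lenient "unfiltered" setting); unmapped/secondary/duplicate records are
    always excluded.

    Returns ``(mean_depth, aligned_bases)`` arrays aligned with ``windows``.
    """
    if isinstance(mismatch_filter, str):
        mismatch_filter = None if mismatch_filter.lower() in ("none", "unfiltered") else int(mismatch_filter)
    reads = alignments if isinstance(alignments, ReadSet) else _bam_records(alignments)
    blocks = _seq_blocks(windows)
    bases = np.zeros(len(windows), dtype=np.int64)
    for seq, rec in reads.records.items():
        if seq not in blocks:
            continue
        offset, wstarts, wends = blocks[seq]
        a, b = rec["start"], rec["end"]
        if mismatch_filter is not None:
            keep = rec["nm"] <= mismatch_filter
            a, b = a[keep], b[keep]
        _add_intervals(bases, offset, wstarts, wends, a, b)
    sizes = (windows["end"] - windows["start"]).to_numpy()
    return bases / sizes, bases


def normalize_coverage(depths: np.ndarray, trim_factor: float = 0.8) -> np.ndarray:
    """Divide window depths by a refined genome-wide median (per individual).

    The constant is the median of the windows lying within a factor
    ``trim_factor`` of an initial plain median.  For profiles where
    depth-shifted (sex-linked) windows are a small minority the refinement
    changes nothing; when they approach half the genome it re-centres the
    constant on the unshifted (autosomal) depth peak, where the plain
    median order statistic would sit in the lower tail of the autosomal
    block and bias every normalized value upward.  Normalizing an already
    normalized profile is the identity.
    """
    depths = np.asarray(depths, dtype=float)
    med0 = np.nanmedian(depths)
    if not np.isfinite(med0) or med0 == 0:
        raise ValueError("no coverage: cannot normalize an all-zero depth profile")
    band = (depths > trim_factor * med0) & (depths < med0 / trim_factor)
    med = np.nanmedian(depths[band]) if band.sum() >= 3 else med0
    return depths / med


def window_heterozygosity(genotypes: pd.DataFrame, windows: pd.DataFrame, *,
                          min_depth: int = 3, min_sites: int = 20
                          ) -> pd.DataFrame:
    """Percent heterozygous sites per window for both samples.

    ``genotypes`` needs columns ``chrom, pos, gt_f, gt_m, dp_f, dp_m`` with
    genotypes coded 0 = hom-ref, 1 = het, 2 = hom-alt, −1 = missing.  A site
    enters the denominator when both samples have a call with depth ≥
    ``min_depth`` (joint denominator, which makes the sample-swap symmetry
    of the female-minus-male difference exact).  Windows with fewer than
    ``min_sites`` passing sites get missing (NaN) heterozygosity, not 0.
    """
    blocks = _seq_blocks(windows)
    n_sites = np.zeros(len(windows), dtype=np.int64)
    het_f_n = np.zeros(len(windows), dtype=np.int64)
    het_m_n = np.zeros(len(windows), dtype=np.int64)

    ok = (
        (genotypes["dp_f"].to_numpy() >= min_depth)
        & (genotypes["dp_m"].to_numpy() >= min_depth)
        & (genotypes["gt_f"].to_numpy() >= 0)
        & (genotypes["gt_m"].to_numpy() >= 0)
    )
    gts = genotypes.loc[ok]
    for seq, grp in gts.groupby("chrom", sort=False):
        if seq not in blocks:
            continue
        offset, wstarts, wends = blocks[seq]
        pos = grp["pos"].to_numpy()
        inside = (pos >= wstarts[0]) & (pos < wends[-1])
        pos = pos[inside]
        i = offset + np.searchsorted(wstarts, pos, side="right") - 1
        np.add.at(n_sites, i, 1)
        np.add.at(het_f_n, i, (grp["gt_f"].to_numpy()[inside] == 1).astype(np.int64))
        np.add.at(het_m_n, i, (grp["gt_m"].to_numpy()[inside] == 1).astype(np.int64))

    with np.errstate(invalid="ignore", divide="ignore"):
        het_f = np.where(n_sites >= min_sites, 100.0 * het_f_n / n_sites, np.nan)
        het_m = np.where(n_sites >= min_sites, 100.0 * het_m_n / n_sites, np.nan)
    return pd.DataFrame({"n_sites": n_sites, "het_f": het_f, "het_m": het_m},
                        index=windows.index)


def make_window_stats(profile_f: pd.DataFrame, profile_m: pd.DataFrame) -> pd.DataFrame:
    """Join the two per-sex window profiles into the WindowStat table.

    Each profile needs columns ``seq, start, end, cov_norm, het, n_sites,
    aligned_bases`` on an identical window tiling.  ``cov_diff`` and
    ``het_diff`` are female minus male; a metric missing in either sex is
    missing in the difference, independently of the other metric.
    """
    key = ["seq", "start", "end"]
    if len(profile_f) != len(profile_m) or not (
        profile_f[key].reset_index(drop=True).equals(profile_m[key].reset_index(drop=True))
    ):
        raise ValueError("female and male profiles use different window tilings")
    f = profile_f.reset_index(drop=True)
    m = profile_m.reset_index(drop=True)
    out = f[key].copy()
    out["cov_f_norm"] = f["cov_norm"].to_numpy()
    out["cov_m_norm"] = m["cov_norm"].to_numpy()
    out["cov_diff"] = out["cov_f_norm"] - out["cov_m_norm"]
    out["het_f"] = f["het"].to_numpy()
    out["het_m"] = m["het"].to_numpy()
    out["het_diff"] = out["het_f"] - out["het_m"]
    out["n_sites_genotyped"] = np.minimum(f["n_sites"].to_numpy(), m["n_sites"].to_numpy())
    out["n_bases_covered"] = f["aligned_bases"].to_numpy() + m["aligned_bases"].to_numpy()
    return out
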