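"""Sex-linked region calling and classification.

Chromosome summaries (mean ± SD of the two female-minus-male metrics),
one-sided 1-SD window outlier flags, run-based segmentation of flagged
windows into contiguous candidate regions, degeneration-class labels, and
selection of PCR-validatable diagnostic indel loci.

Classification follows the two canonical ZW signatures: drastically
reduced female coverage with no heterozygosity excess marks a region with
a heavily degenerated W (``HIGH_DEGENERATION``); moderately reduced
coverage with clearly elevated female heterozygosity marks a younger,
less degenerated stratum (``LOW_DEGENERATION``).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "summarize_chromosomes",
    "flag_windows",
    "call_regions",
    "classify_region",
    "classify_regions",
    "select_diagnostic_loci",
]

HIGH, LOW = "HIGH_DEGENERATION", "LOW_DEGENERATION"


def summarize_chromosomes(stats: pd.DataFrame, min_windows: int = 10) -> pd.DataFrame:
    """Per-chromosome mean and SD (population SD) of ``cov_diff`` and
    ``het_diff`` over non-missing windows, with a reliability flag.

    Chromosomes with too few windows (``n_windows < min_windows``) get
    ``reliable=False``: their chromosome-level means are reported but must
    never by themselves promote a chromosome to candidate sex-linked
    status — deviating means on small chromosomes are typically sampling
    noise.  Chromosomes with zero non-missing windows are omitted with a
    warning.
    """
    rows = []
    for chrom, grp in stats.groupby("seq", sort=False):
        cov = grp["cov_diff"].to_numpy(dtype=float)
        het = grp["het_diff"].to_numpy(dtype=float)
        cov = cov[np.isfinite(cov)]
        het = het[np.isfinite(het)]
        if len(cov) == 0 and len(het) == 0:
            log.warning("chromosome %s has no usable windows; omitted", chrom)
            continue
        n = int(max(len(cov), len(het)))
        rows.append({
            "chrom": chrom,
            "n_windows": n,
            "mean_cov_diff": float(np.mean(cov)) if len(cov) else np.nan,
            "sd_cov_diff": float(np.std(cov)) if len(cov) else np.nan,
            "mean_het_diff": float(np.mean(het)) if len(het) else np.nan,
            "sd_het_diff": float(np.std(het)) if len(het) else np.nan,
            "reliable": n >= min_windows,
        })
    return pd.DataFrame(rows, columns=["chrom", "n_windows", "mean_cov_diff", "sd_cov_diff",
                                       "mean_het_diff", "sd_het_diff", "reliable"])


def flag_windows(stats: pd.DataFrame, exclude: pd.DataFrame | None = None
                 ) -> tuple[pd.DataFrame, dict]:
    """Flag windows beyond one standard deviation of the genome-wide mean,
    one-sided in the sex-linked direction: ``cov_low`` when
    ``cov_diff < mean − SD``, ``het_high`` when ``het_diff > mean + SD``.

    Means/SDs are computed over all non-missing windows (the genome-wide
    spread deliberately includes sex-linked windows); passing previously
    called regions as ``exclude`` recomputes them once without those
    windows.  If an SD is zero no windows are flagged on that metric.
    """
    out = stats.copy()
    mask = np.ones(len(stats), dtype=bool)
    if exclude is not None and len(exclude):
        for reg in exclude.itertuples():
            mask &= ~((stats["seq"].to_numpy() == reg.chrom)
                      & (stats["start"].to_numpy() < reg.end)
                      & (stats["end"].to_numpy() > reg.start))
    thresholds = {}
    for metric, flag, side in (("cov_diff", "cov_low", -1), ("het_diff", "het_high", +1)):
        vals = stats[metric].to_numpy(dtype=float)
        base = vals[mask & np.isfinite(vals)]
        mean = float(np.mean(base)) if len(base) else np.nan
        sd = float(np.std(base)) if len(base) else np.nan
        thresholds[metric] = {"mean": mean, "sd": sd, "cut": mean + side * sd}
        if not np.isfinite(sd) or sd == 0:
            log.warning("SD of %s is zero or undefined; no windows flagged", metric)
            out[flag] = False
            continue
        with np.errstate(invalid="ignore"):
            out[flag] = (vals < mean - sd) if side < 0 else (vals > mean + sd)
        out[flag] = out[flag].fillna(False) if hasattr(out[flag], "fillna") else out[flag]
    return out, thresholds


def call_regions(flagged: pd.DataFrame, min_run: int = 10, max_gap: int = 2) -> pd.DataFrame:
    """Segment flagged windows into contiguous candidate regions.

    A region is a maximal run of windows flagged on either metric,
    tolerating up to ``max_gap`` consecutive unflagged windows, and is
    retained when at least ``min_run`` of its windows are flagged on a
    *single* metric (a run supported only by an incoherent mixture of weak
    coverage and heterozygosity flags is noise).  Region bounds are the
    outer bounds of the run's flagged windows.
    """
    regions = []
    for chrom, grp in flagged.groupby("seq", sort=False):
        grp = grp.sort_values("start").reset_index(drop=True)
        either = (grp["cov_low"] | grp["het_high"]).to_numpy()
        idx = np.flatnonzero(either)
        if len(idx) == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) - 1 > max_gap)
        for chunk in np.split(idx, breaks + 1):
            span = grp.iloc[chunk[0]: chunk[-1] + 1]
            n_cov = int(span["cov_low"].sum())
            n_het = int(span["het_high"].sum())
            if max(n_cov, n_het) < min_run:
                continue
            regions.append({
                "chrom": chrom,
                "start": int(span["start"].iloc[0]),
                "end": int(span["end"].iloc[-1]),
                "n_windows": len(span),
                "n_flagged": int((span["cov_low"] | span["het_high"]).sum()),
                "support_cov": n_cov / len(span),
                "support_het": n_het / len(span),
                "mean_cov_diff": float(np.nanmean(span["cov_diff"].to_numpy(dtype=float))),
                "mean_het_diff": float(np.nanmean(span["het_diff"].to_numpy(dtype=float)))
                if np.isfinite(span["het_diff"].to_numpy(dtype=float)).any() else np.nan,
            })
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "n_windows", "n_flagged",
                                          "support_cov", "support_het",
                                          "mean_cov_diff", "mean_het_diff"])


def classify_region(region, cov_drastic: float = -0.3) -> tuple[str, bool]:
    """Degeneration class of one called region.

    ``HIGH_DEGENERATION``: drastically reduced female coverage
    (``mean_cov_diff ≤ cov_drastic``) without majority heterozygosity
    support.  ``LOW_DEGENERATION``: elevated female heterozygosity
    (``mean_het_diff > 0`` with ``support_het ≥ 0.5``) and only moderately
    reduced coverage.  A region matching neither canonical signature is
    labelled LOW_DEGENERATION with ``weak=True``.
    """
    if region.mean_cov_diff <= cov_drastic and region.support_het < 0.5:
        return HIGH, False
    if (region.support_het >= 0.5 and region.mean_cov_diff > cov_drastic
            and np.isfinite(region.mean_het_diff) and region.mean_het_diff > 0):
        return LOW, False
    return LOW, True


def classify_regions(regions: pd.DataFrame, cov_drastic: float = -0.3) -> pd.DataFrame:
    out = regions.copy()
    klass, weak = [], []
    for row in regions.itertuples():
        k, w = classify_region(row, cov_drastic=cov_drastic)
        klass.append(k)
        weak.append(w)
    out["klass"] = klass
    out["weak"] = weak
    return out


def select_diagnostic_loci(genotypes: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Candidate PCR validation loci: insertion polymorphisms inside called
    regions where the female is heterozygous for the insertion and the male
    is homozygous reference (so additional females show two bands on a gel
    and males one), ranked by insertion length descending.

    ``genotypes`` needs ``chrom, pos, gt_f, gt_m`` and either ``ins_len`` or
    ``ref``/``alt`` allele strings.  An empty result is not an error.
    """
    g = genotypes
    if "ins_len" in g:
        ins_len = g["ins_len"].to_numpy()
    else:
        ins_len = (g["alt"].astype(str).str.len() - g["ref"].astype(str).str.len()).to_numpy()
    cand = (ins_len > 0) & (g["gt_f"].to_numpy() == 1) & (g["gt_m"].to_numpy() == 0)
    inside = np.zeros(len(g), dtype=bool)
    for reg in regions.itertuples():
        inside |= ((g["chrom"].to_numpy() == reg.chrom)
                   & (g["pos"].to_numpy() >= reg.start)
                   & (g["pos"].to_numpy() < reg.end))
    sel = g.loc[cand & inside, ["chrom", "pos"]].copy()
    sel["end"] = sel["pos"] + 1
    sel["ins_len"] = ins_len[cand & inside]
    sel = sel.sort_values(["ins_len", "chrom", "pos"],
                          ascending=[False, True, True]).reset_index(drop=True)
    sel.insert(0, "rank", np.arange(1, len(sel) + 1))
    return sel[["rank", "chrom", "pos", "end", "ins_len"]]
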