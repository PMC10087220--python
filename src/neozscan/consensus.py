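"""Consensus-reference construction (mapping-bias correction).

The first scan pass aligns both sexes against a reference derived from the
male sample, so female reads systematically carry more mismatches and map
less well.  The consensus pass substitutes, at every biallelic SNV, the
allele that is in the majority across the two samples' genotypes (each
diploid genotype contributes two alleles); ties keep the reference base,
and indels / multiallelic sites are skipped so coordinates never shift.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["ConsensusReport", "majority_substitutions", "build_consensus"]

_ACGT = frozenset(b"ACGT")


@dataclass
class ConsensusReport:
    n_sites_considered: int = 0
    n_substituted: int = 0
    n_ties_kept_ref: int = 0
    n_skipped_indel: int = 0
    n_skipped_multiallelic: int = 0
    n_skipped_nonacgt_ref: int = 0
    substitution_density: dict = field(default_factory=dict)  # per-seq subs per bp

    def __post_init__(self):
        if self.n_substituted + self.n_ties_kept_ref > self.n_sites_considered:
            raise ValueError("inconsistent consensus counts")

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def majority_substitutions(genotypes: pd.DataFrame) -> tuple[pd.Series, ConsensusReport]:
    """Decide, per site, whether the alternate allele is the majority.

    ``genotypes`` needs ``chrom, pos, gt_f, gt_m`` (0/1/2 coded alt-allele
    counts, −1 missing) and, when available, ``ins_len`` (or ``ref``/``alt``
    strings) to recognize indels and multiallelic records.

    Returns a boolean Series aligned with ``genotypes.index`` (True =
    substitute the alternate) and a :class:`ConsensusReport` without the
    per-sequence densities (those are filled in by :func:`build_consensus`).
    """
    gt_f = genotypes["gt_f"].to_numpy()
    gt_m = genotypes["gt_m"].to_numpy()

    if "ins_len" in genotypes:
        is_indel = genotypes["ins_len"].to_numpy() != 0
        is_multi = np.zeros(len(genotypes), dtype=bool)
    elif {"ref", "alt"} <= set(genotypes.columns):
        ref = genotypes["ref"].astype(str)
        alt = genotypes["alt"].astype(str)
        is_multi = alt.str.contains(",").to_numpy()
        is_indel = ((ref.str.len() != 1) | (alt.str.len() != 1)) & ~is_multi
    else:
        is_indel = np.zeros(len(genotypes), dtype=bool)
        is_multi = np.zeros(len(genotypes), dtype=bool)

    called_f = gt_f >= 0
    called_m = gt_m >= 0
    usable = ~is_indel & ~is_multi & (called_f | called_m)
    alt_n = np.where(called_f, gt_f, 0) + np.where(called_m, gt_m, 0)
    ref_n = 2 * (called_f.astype(int) + called_m.astype(int)) - alt_n

    substitute = usable & (alt_n > ref_n)
    tie = usable & (alt_n == ref_n) & (alt_n > 0)
    report = ConsensusReport(
        n_sites_considered=int(usable.sum()),
        n_substituted=int(substitute.sum()),
        n_ties_kept_ref=int(tie.sum()),
        n_skipped_indel=int(is_indel.sum()),
        n_skipped_multiallelic=int(is_multi.sum()),
    )
    return pd.Series(substitute, index=genotypes.index), report


def build_consensus(reference: dict[str, np.ndarray], genotypes: pd.DataFrame
                    ) -> tuple[dict[str, np.ndarray], ConsensusReport]:
    """Apply majority-allele substitutions to the reference sequences.

    ``reference`` maps sequence name to a uint8 ACGT array (as produced by
    the simulator or loaded from FASTA); ``genotypes`` additionally needs
    an ``alt`` column (single-base alternate) for substituted sites.
    Output sequence lengths equal input lengths; a VCF contig absent from
    the reference is an error, a non-ACGT reference base at a substituted
    site is skipped with a warning.
    """
    substitute, report = majority_substitutions(genotypes)
    missing = set(genotypes["chrom"].unique()) - set(reference)
    if missing:
        raise ValueError(f"VCF contigs absent from reference: {sorted(missing)}")

    consensus = {seq: arr.copy() for seq, arr in reference.items()}
    sub = genotypes.loc[substitute.to_numpy()]
    n_bad = 0
    for seq, grp in sub.groupby("chrom", sort=False):
        arr = consensus[seq]
        pos = grp["pos"].to_numpy()
        alt = grp["alt"].astype(str).str.upper().to_numpy()
        ok = np.array([arr[p] in _ACGT for p in pos])
        n_bad += int((~ok).sum())
        arr[pos[ok]] = np.frombuffer("".join(alt[ok]).encode(), dtype=np.uint8)
        report.substitution_density[seq] = round(float(ok.sum()) / len(arr), 10)
    if n_bad:
        log.warning("skipped %d substitutions at non-ACGT reference bases", n_bad)
        report.n_skipped_nonacgt_ref = n_bad
        report.n_substituted -= n_bad
    for seq, arr in reference.items():
        report.substitution_density.setdefault(seq, 0.0)
        assert len(consensus[seq]) == len(arr)
    return consensus, report
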