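"""PAR-boundary / fusion-point inference and the neo-sex chromosome model.

Scaffolds of a contiguous assembly, anchored to a chromosome-level
synteny genome, are classified by how sex-linkage flags distribute along
their length:

* sex differences over only part of a scaffold, with a single internal
  transition → ``PAR_BOUNDARY`` (the recombination boundary lies inside
  the scaffold);
* sex differences across the whole scaffold with synteny to two
  different sex-linked chromosomes → ``FUSION_POINT``;
* sex differences across the whole scaffold, positioned at the outer
  range of a sex-linked region → ``PUTATIVE_FUSION_END`` (scaffolds end
  where the non-recombining region ends).

From classified regions and boundary calls the hypothesized neo-Z
chromosome is assembled as an ordered, oriented segment list rendered in
a canonical string grammar, e.g. ``8_28.0–7.3(−)_–Z_0.0–72.9(+)_–4A_9.6–0.0(−)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import GenomeSpec

__all__ = [
    "BoundaryCall",
    "NeoSegment",
    "NeoSexModel",
    "scaffold_sexlink_profile",
    "classify_scaffold",
    "classify_scaffolds",
    "build_neo_model",
    "truth_neo_model",
]

EN_DASH = "–"   # joins coordinates and segments
MINUS = "−"     # reverse-orientation sign

PAR_BOUNDARY = "PAR_BOUNDARY"
FUSION_POINT = "FUSION_POINT"
PUTATIVE_FUSION_END = "PUTATIVE_FUSION_END"
NONE = "NONE"


@dataclass
class BoundaryCall:
    scaffold: str
    call: str
    target_chroms: tuple[str, ...] = ()
    boundary_chrom: str | None = None
    boundary_position: int | None = None
    frac_flagged: float = float("nan")
    evidence: dict = field(default_factory=dict)  # per-chrom flagged fraction
    annotation: str = ""


# ---------------------------------------------------------------------------
# per-scaffold evidence

def _smooth_flags(flags: np.ndarray) -> np.ndarray:
    """Width-3 majority filter: a single window flipped against both of its
    neighbours is treated as noise, so one stray flag (or miss) inside an
    otherwise homogeneous scaffold does not spawn spurious transitions."""
    if len(flags) < 3:
        return flags
    s = flags.astype(np.int8)
    c = s.copy()
    c[1:-1] = s[:-2] + s[1:-1] + s[2:]
    out = flags.copy()
    out[1:-1] = c[1:-1] >= 2
    return out


def _runs(flags: np.ndarray) -> tuple[int, int, int, int | None]:
    """(longest flagged run, longest unflagged run, n transitions,
    index of first window after the single transition or None)."""
    if len(flags) == 0:
        return 0, 0, 0, None
    change = np.flatnonzero(np.diff(flags.astype(np.int8)) != 0)
    bounds = np.concatenate([[-1], change, [len(flags) - 1]])
    run_lens = np.diff(bounds)
    states = flags[bounds[1:]]
    longest_f = int(run_lens[states].max()) if states.any() else 0
    longest_u = int(run_lens[~states].max()) if (~states).any() else 0
    transition = int(change[0]) + 1 if len(change) == 1 else None
    return longest_f, longest_u, len(change), transition


def scaffold_sexlink_profile(flagged: pd.DataFrame, anchors: pd.DataFrame,
                             min_len: int = 1000) -> pd.DataFrame:
    """Per-scaffold sex-linkage evidence table.

    ``flagged`` is a scaffold-space window-stat table with ``cov_low`` /
    ``het_high`` columns; ``anchors`` an assigned anchor table.  For each
    scaffold: fraction of windows flagged (either metric), longest flagged
    and unflagged runs, number of internal flag transitions, and, per
    target chromosome with anchored extent ≥ ``min_len``: the flagged
    fraction of its windows and the lifted extent of their midpoints.
    """
    by_scaffold = {s: g.reset_index(drop=True) for s, g in anchors.groupby("scaffold", sort=False)}
    rows = []
    for scaffold, grp in flagged.groupby("seq", sort=False):
        grp = grp.sort_values("start").reset_index(drop=True)
        wlen = (grp["end"] - grp["start"]).to_numpy()
        grp = grp.loc[wlen >= 0.5 * wlen.max()].reset_index(drop=True)  # drop tiny truncated stubs
        flags = _smooth_flags((grp["cov_low"] | grp["het_high"]).to_numpy(dtype=bool))
        longest_f, longest_u, n_trans, trans_idx = _runs(flags)
        anc = by_scaffold.get(scaffold)
        per_chrom: dict[str, dict] = {}
        if anc is not None:
            extents = anc.groupby("chrom")["aln_len"].sum()
            mids = ((grp["start"] + grp["end"]) // 2).to_numpy()
            qs, qe = anc["q_start"].to_numpy(), anc["q_end"].to_numpy()
            k = np.searchsorted(qs, mids, side="right") - 1
            ok = (k >= 0) & (mids < qe[np.clip(k, 0, None)])
            for chrom, extent in extents.items():
                if extent < min_len:
                    continue
                rows_k = ok & (anc["chrom"].to_numpy()[np.clip(k, 0, None)] == chrom)
                if not rows_k.any():
                    per_chrom[chrom] = {"n": 0, "frac": np.nan, "tmin": None, "tmax": None}
                    continue
                sub = anc.iloc[k[rows_k]]
                scale = (sub["t_end"].to_numpy() - sub["t_start"].to_numpy()) / (
                    sub["q_end"].to_numpy() - sub["q_start"].to_numpy())
                off = ((mids[rows_k] - sub["q_start"].to_numpy()) * scale).astype(np.int64)
                tpos = np.where(sub["strand"].to_numpy() == "+",
                                sub["t_start"].to_numpy() + off,
                                sub["t_end"].to_numpy() - 1 - off)
                per_chrom[chrom] = {
                    "n": int(rows_k.sum()),
                    "frac": float(flags[rows_k].mean()),
                    "tmin": int(tpos.min()),
                    "tmax": int(tpos.max()),
                }
        rows.append({
            "scaffold": scaffold,
            "n_windows": len(grp),
            "frac_flagged": float(flags.mean()) if len(flags) else np.nan,
            "longest_flagged_run": longest_f,
            "longest_unflagged_run": longest_u,
            "n_transitions": n_trans,
            "transition_pos": int(grp["start"].iloc[trans_idx]) if trans_idx is not None else None,
            "per_chrom": per_chrom,
        })
    return pd.DataFrame(rows)


def _lift_point(anchors_sorted: pd.DataFrame, pos: int) -> tuple[str, int] | None:
    qs = anchors_sorted["q_start"].to_numpy()
    qe = anchors_sorted["q_end"].to_numpy()
    k = int(np.searchsorted(qs, pos, side="right")) - 1
    if k < 0 or pos >= qe[k]:
        return None
    row = anchors_sorted.iloc[k]
    scale = (row.t_end - row.t_start) / (row.q_end - row.q_start)
    off = int((pos - row.q_start) * scale)
    t = row.t_start + off if row.strand == "+" else row.t_end - 1 - off
    return str(row.chrom), int(t)


def classify_scaffold(profile_row, anchors: pd.DataFrame, regions: pd.DataFrame,
                      t_full: float = 0.9, t_none: float = 0.1,
                      window: int = 100_000) -> BoundaryCall:
    """Apply the boundary/fusion decision rules to one scaffold's evidence."""
    per_chrom = profile_row.per_chrom
    target_chroms = tuple(sorted(per_chrom))
    frac = profile_row.frac_flagged
    call = BoundaryCall(scaffold=profile_row.scaffold, call=NONE,
                        target_chroms=target_chroms, frac_flagged=frac,
                        evidence={c: d["frac"] for c, d in per_chrom.items()})

    full_chroms = [c for c, d in per_chrom.items()
                   if d["n"] > 0 and np.isfinite(d["frac"]) and d["frac"] >= t_full]
    if len(full_chroms) >= 2:
        call.call = FUSION_POINT
        call.target_chroms = tuple(sorted(full_chroms))
        return call

    if t_none < frac < t_full:
        if profile_row.n_transitions == 1 and profile_row.transition_pos is not None:
            anc = anchors[anchors["scaffold"] == profile_row.scaffold].sort_values("q_start")
            lifted = _lift_point(anc, int(profile_row.transition_pos)) if len(anc) else None
            call.call = PAR_BOUNDARY
            if lifted is not None:
                call.boundary_chrom, call.boundary_position = lifted
            return call
        if profile_row.n_transitions > 1:
            call.annotation = "complex"
            return call
        return call

    if frac >= t_full and len(full_chroms) == 1:
        chrom = full_chroms[0]
        d = per_chrom[chrom]
        for reg in regions.itertuples():
            if reg.chrom != chrom or d["tmin"] is None:
                continue
            for edge in (reg.start, reg.end):
                if d["tmin"] - window <= edge <= d["tmax"] + window:
                    call.call = PUTATIVE_FUSION_END
                    call.boundary_chrom = chrom
                    call.boundary_position = int(edge)
                    return call
    return call


def classify_scaffolds(profile: pd.DataFrame, anchors: pd.DataFrame,
                       regions: pd.DataFrame, t_full: float = 0.9,
                       t_none: float = 0.1, window: int = 100_000) -> pd.DataFrame:
    """Classify every profiled scaffold; order-independent by construction."""
    calls = [classify_scaffold(row, anchors, regions, t_full, t_none, window)
             for row in profile.itertuples()]
    return pd.DataFrame([c.__dict__ for c in calls])


# ---------------------------------------------------------------------------
# neo-sex chromosome model

_SEG_RE = re.compile(
    r"^(?P<chrom>.+)_(?P<a>\d+(?:\.\d+)?)[–‐-](?P<b>\d+(?:\.\d+)?)"
    r"\((?P<s>[+\-−?])\)$"
)


@dataclass(frozen=True)
class NeoSegment:
    """One oriented building block of the fused chromosome, in Mb."""

    chrom: str
    a: float  # rendered first
    b: float
    strand: str  # '+', '-', or '?' when orientation is unresolvable

    def __post_init__(self):
        if self.strand not in "+-?":
            raise ValueError(f"bad strand {self.strand!r}")

    def render(self) -> str:
        sign = {"+": "+", "-": MINUS, "?": "?"}[self.strand]
        return f"{self.chrom}_{self.a:.1f}{EN_DASH}{self.b:.1f}({sign})"


@dataclass
class NeoSexModel:
    """Ordered, oriented segment list of the hypothesized neo-Z chromosome.

    Adjacent segments are joined end-to-start; ``render`` produces the
    canonical dash-joined string and round-trips through ``parse``.
    """

    segments: list[NeoSegment]

    def __post_init__(self):
        if not self.segments:
            raise ValueError("a neo-sex model needs at least one segment")

    def render(self) -> str:
        return (f"_{EN_DASH}").join(s.render() for s in self.segments)

    @classmethod
    def parse(cls, text: str) -> "NeoSexModel":
        text = text.strip().rstrip("_")
        parts = text.split(f"_{EN_DASH}")
        segments = []
        for part in parts:
            m = _SEG_RE.match(part)
            if not m:
                raise ValueError(f"cannot parse model segment {part!r}")
            strand = m.group("s").replace(MINUS, "-")
            segments.append(NeoSegment(m.group("chrom"), float(m.group("a")),
                                       float(m.group("b")), strand))
        return cls(segments)

    def __eq__(self, other):
        if not isinstance(other, NeoSexModel):
            return NotImplemented
        return self.render() == other.render()


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok
            for tok in re.split(r"(\d+)", name)]


def _mb(x: float) -> float:
    return round(x / 1e6, 1)


def _partner_segment(chrom: str, lo: int, hi: int, fused: int | None, side: str
                     ) -> NeoSegment:
    """Render a translocated partner so its fused end abuts the Z.

    ``side`` is 'left' (precedes Z: fused coordinate rendered last) or
    'right' (follows Z: fused coordinate rendered first)."""
    if fused is None:
        return NeoSegment(chrom, _mb(lo), _mb(hi), "?")
    far = hi if fused == lo else lo
    first, last = (fused, far) if side == "right" else (far, fused)
    return NeoSegment(chrom, _mb(first), _mb(last), "+" if first < last else "-")


def _assemble(z_chrom: str, z_len: int,
              partners: list[tuple[str, int, int, int | None]]) -> NeoSexModel:
    """Attach translocated partners to the ancestral Z.

    By convention (the fusion sides of the Z itself are not identifiable
    from coverage/heterozygosity data alone) partners are name-sorted and
    attached alternately to the high-coordinate end of Z first, then the
    low end — which reproduces the published Sylvioidea layout.
    """
    ordered = sorted(partners, key=lambda p: _natural_key(p[0]))
    right: list[NeoSegment] = []
    left: list[NeoSegment] = []
    for i, (chrom, lo, hi, fused) in enumerate(ordered):
        side = "right" if i % 2 == 0 else "left"
        seg = _partner_segment(chrom, lo, hi, fused, side)
        (right if side == "right" else left).append(seg)
    z = NeoSegment(z_chrom, 0.0, _mb(z_len), "+")
    return NeoSexModel(list(reversed(left)) + [z] + right)


def build_neo_model(regions: pd.DataFrame, calls: pd.DataFrame, ancestral_z: str,
                    chrom_lengths: dict[str, int], window: int = 100_000) -> NeoSexModel:
    """Assemble the hypothesized neo-Z from called regions and boundary calls.

    The ancestral Z spans its whole chromosome.  Each other region-bearing
    chromosome contributes its region extended through the contiguous PAR
    (located by a ``PAR_BOUNDARY`` call near one region edge) to the
    chromosome end on that side; the opposite edge is the fused end.  A
    region with no usable boundary evidence is attached with orientation
    '?' over its called extent.
    """
    if ancestral_z not in set(regions["chrom"]):
        raise ValueError(f"ancestral Z {ancestral_z!r} is not among the called regions")
    partners: list[tuple[str, int, int, int | None]] = []
    for chrom, grp in regions.groupby("chrom", sort=False):
        if chrom == ancestral_z:
            continue
        r_start = int(grp["start"].min())
        r_end = int(grp["end"].max())
        sides = set()
        if len(calls):
            pb = calls[(calls["call"] == PAR_BOUNDARY) & (calls["boundary_chrom"] == chrom)]
            for pos in pb["boundary_position"]:
                if pos is None:
                    continue
                if abs(int(pos) - r_end) <= window:
                    sides.add("par_right")
                elif abs(int(pos) - r_start) <= window:
                    sides.add("par_left")
        if sides == {"par_right"}:
            partners.append((chrom, r_start, int(chrom_lengths[chrom]), r_start))
        elif sides == {"par_left"}:
            partners.append((chrom, 0, r_end, r_end))
        else:
            partners.append((chrom, r_start, r_end, None))
    return _assemble(ancestral_z, int(chrom_lengths[ancestral_z]), partners)


def truth_neo_model(spec: GenomeSpec) -> NeoSexModel:
    """Ground-truth neo-Z layout implied by a genome spec's planted segments."""
    if spec.ancestral_z is None:
        raise ValueError("spec declares no ancestral Z")
    lengths = spec.lengths
    segs = sorted(spec.segments, key=lambda s: (s.chrom, s.start))
    partners = []
    for seg in segs:
        if seg.role != "SEXLINKED" or seg.chrom == spec.ancestral_z or seg.fusion_side is None:
            continue
        chrom_segs = [s for s in segs if s.chrom == seg.chrom]
        if seg.fusion_side == "left":
            hi = seg.end
            for s in chrom_segs:
                if s.role == "PAR" and s.start == hi:
                    hi = s.end
            if hi == max(s.end for s in chrom_segs):
                hi = lengths[seg.chrom]
            partners.append((seg.chrom, seg.start, hi, seg.start))
        else:
            lo = seg.start
            for s in reversed(chrom_segs):
                if s.role == "PAR" and s.end == lo:
                    lo = s.start
            partners.append((seg.chrom, lo, seg.end, seg.end))
    return _assemble(spec.ancestral_z, lengths[spec.ancestral_z], partners)
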