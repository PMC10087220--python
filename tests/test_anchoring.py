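"""Anchor handling: PAF round-trips, best-hit assignment against a per-base
oracle, strand-aware lifting and re-binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neozscan import fragment_assembly
from neozscan.anchoring import (
    ScaffoldAnchor,
    anchors_from_paf_table,
    assign_anchors,
    lift_windows,
    read_paf,
    write_paf,
)
from neozscan.pipeline import scan_direct
from neozscan.windows import tile_windows


def _anchor_row(**kw):
    base = dict(scaffold="s1", q_start=0, q_end=1000, chrom="chr1",
                t_start=0, t_end=1000, strand="+", aln_len=1000, identity=1.0)
    base.update(kw)
    return base


class TestPaf:
    def test_single_line(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text("s1\t1000\t0\t1000\t+\tchr1\t5000\t2000\t3000\t990\t1000\t60\n")
        anchors = read_paf(p)
        a = anchors.iloc[0]
        assert (a.scaffold, a.q_start, a.q_end, a.chrom, a.t_start, a.t_end,
                a.strand) == ("s1", 0, 1000, "chr1", 2000, 3000, "+")
        assert a.identity == pytest.approx(0.99)

    def test_malformed_lines_rejected_with_numbers(self, tmp_path, caplog):
        p = tmp_path / "a.paf"
        p.write_text(
            "s1\t1000\t0\t1000\t+\tchr1\t5000\t2000\t3000\t990\t1000\t60\n"
            "s2\t1000\t0\t1000\t+\tchr1\t5000\t3000\t2000\t990\t1000\t60\n"  # t_end < t_start
            "garbage line\n"
        )
        with caplog.at_level("WARNING"):
            anchors = read_paf(p)
        assert len(anchors) == 1
        assert anchors.attrs["rejected_lines"] == [2, 3]

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text("")
        with pytest.raises(ValueError, match="no valid"):
            read_paf(p)

    def test_roundtrip(self, small_sim, tmp_path):
        paf = fragment_assembly(small_sim, 50_000, seed=3).to_paf()
        p1, p2 = tmp_path / "a.paf", tmp_path / "b.paf"
        write_paf(paf, p1)
        anchors = read_paf(p1)
        # rebuild PAF columns from the anchor table and compare text
        qlen = dict(zip(paf["qname"], paf["qlen"]))
        tlen = dict(zip(paf["tname"], paf["tlen"]))
        from neozscan.anchoring import anchors_to_paf
        write_paf(anchors_to_paf(anchors, qlen, tlen), p2)
        assert p1.read_text() == p2.read_text()

    def test_interval_lengths_equal_per_line(self, small_sim):
        paf = fragment_assembly(small_sim, 50_000, seed=3).to_paf()
        assert ((paf["qend"] - paf["qstart"]) == (paf["tend"] - paf["tstart"])).all()


class TestAssignAnchors:
    def test_single_anchor_unchanged(self):
        anchors = pd.DataFrame([_anchor_row()])
        out = assign_anchors(anchors)
        pd.testing.assert_frame_equal(out, anchors)

    def test_longer_alignment_wins_overlap(self):
        anchors = pd.DataFrame([
            _anchor_row(aln_len=500, q_end=500, t_end=500, chrom="chrA"),
            _anchor_row(aln_len=800, q_end=800, t_end=800, chrom="chrB"),
        ])
        out = assign_anchors(anchors, min_len=1)
        assert set(out.loc[out["q_start"] == 0, "chrom"]) == {"chrB"}

    def test_threshold_filters(self):
        anchors = pd.DataFrame([_anchor_row(aln_len=500, identity=0.5)])
        assert len(assign_anchors(anchors, min_len=1000)) == 0
        assert len(assign_anchors(anchors, min_len=1, min_identity=0.9)) == 0

    def test_random_overlaps_match_per_base_oracle(self):
        """Best-hit assignment of 30 random overlapping anchors equals an
        exhaustive per-base winner scan."""
        rng = np.random.default_rng(7)
        rows = []
        for i in range(30):
            q0 = int(rng.integers(0, 9000))
            ln = int(rng.integers(200, 2000))
            rows.append(_anchor_row(
                q_start=q0, q_end=q0 + ln, t_start=q0, t_end=q0 + ln, aln_len=ln,
                identity=float(rng.choice([0.8, 0.9, 1.0])),
                chrom=str(rng.choice(["chrA", "chrB"])), src=i))
        anchors = pd.DataFrame(rows)
        out = assign_anchors(anchors, min_len=1)

        winner = np.full(12000, -1)
        order = sorted(range(30), key=lambda i: (-rows[i]["aln_len"], -rows[i]["identity"],
                                                 rows[i]["chrom"]))
        for i in reversed(order):  # lowest priority painted first
            winner[rows[i]["q_start"]:rows[i]["q_end"]] = i
        got = np.full(12000, -1)
        for r in out.itertuples():
            got[r.q_start:r.q_end] = r.src
        assert np.array_equal(winner, got)


class TestLiftWindows:
    def _stats(self, windows, cov, het=None, n_sites=50):
        s = windows.copy()
        s["cov_f_norm"] = cov
        s["cov_m_norm"] = 1.0
        s["cov_diff"] = s["cov_f_norm"] - 1.0
        s["het_f"] = het if het is not None else 0.0
        s["het_m"] = 0.0
        s["het_diff"] = s["het_f"]
        s["n_sites_genotyped"] = n_sites
        return s

    def test_identity_anchor_is_identity(self):
        w = tile_windows({"s1": 1000}, 100)
        stats = self._stats(w, np.linspace(0.5, 1.5, 10))
        anchors = pd.DataFrame([_anchor_row(chrom="chr1")])
        lifted, dropped = lift_windows(stats, anchors, 100, {"chr1": 1000})
        assert dropped == 0
        assert np.allclose(lifted["cov_f_norm"], stats["cov_f_norm"])

    def test_negative_strand_reflection(self):
        """A minus-strand anchor [0,1000) -> [5000,6000) sends scaffold
        position 100 to target base 5899 (base-level reflection)."""
        w = pd.DataFrame({"seq": ["s1"], "start": [50], "end": [150]})  # midpoint 100
        w = tile_windows({"s1": 1000}, 200)  # midpoints 100, 300, ...
        stats = self._stats(w, np.arange(5, dtype=float))
        anchors = pd.DataFrame([_anchor_row(strand="-", t_start=5000, t_end=6000)])
        lifted, _ = lift_windows(stats, anchors, 100, {"chr1": 10_000})
        # midpoint 100 -> 5899 -> target window [5800, 5900)
        row = lifted[(lifted["seq"] == "chr1") & (lifted["start"] == 5800)]
        assert row["cov_f_norm"].iloc[0] == pytest.approx(0.0)

    def test_windows_without_anchor_dropped_and_counted(self):
        w = tile_windows({"s1": 1000}, 100)
        stats = self._stats(w, np.ones(10))
        anchors = pd.DataFrame([_anchor_row(q_end=500, t_end=500, aln_len=500)])
        lifted, dropped = lift_windows(stats, anchors, 100, {"chr1": 1000})
        assert dropped == 5
        assert lifted["n_source"].sum() == 5

    def test_out_of_bounds_anchor_is_error(self):
        w = tile_windows({"s1": 1000}, 100)
        stats = self._stats(w, np.ones(10))
        anchors = pd.DataFrame([_anchor_row(t_start=9500, t_end=10_500)])
        with pytest.raises(ValueError, match="target bounds"):
            lift_windows(stats, anchors, 100, {"chr1": 10_000})

    @given(st.integers(0, 999))
    def test_strand_involution(self, pos):
        """Reflecting a coordinate twice through a minus-strand anchor returns
        the source coordinate."""
        t_end, q_start = 6000, 0
        forward = t_end - 1 - (pos - q_start)           # q -> t through the anchor
        back = q_start + (t_end - 1 - forward)          # t -> q through the same anchor
        assert back == pos

    def test_lift_matches_direct_computation(self, small_sim):
        """Window stats computed on window-aligned scaffolds and lifted back
        equal the direct chromosome-space profile, window for window."""
        from neozscan.pipeline import truth_genotype_codes, window_stats_tables
        from neozscan.simulate import Assembly, place_reads, reads_to_scaffolds, truth_to_scaffolds

        window = 50_000
        anchors = pd.DataFrame([
            {"scaffold": "sc1", "s_len": 300_000, "chrom": "c1", "c_start": 0,
             "c_end": 300_000, "strand": "+"},
            {"scaffold": "sc2", "s_len": 200_000, "chrom": "c1", "c_start": 300_000,
             "c_end": 500_000, "strand": "-"},
            {"scaffold": "sc3", "s_len": 400_000, "chrom": "c2", "c_start": 0,
             "c_end": 400_000, "strand": "-"},
        ])
        asm = Assembly(anchors)
        reads = {ind: place_reads(small_sim, ind) for ind in ("female", "male")}
        sc = {ind: reads_to_scaffolds(reads[ind], asm, small_sim) for ind in reads}
        gts_sc = truth_genotype_codes(truth_to_scaffolds(small_sim, asm))
        stats_sc = window_stats_tables(sc["female"], sc["male"], gts_sc,
                                       tile_windows(asm.scaffold_lengths, window),
                                       min_sites=1)
        lifted, dropped = lift_windows(stats_sc, anchors_from_paf_table(asm.to_paf()),
                                       window, small_sim.lengths)
        direct = scan_direct(small_sim, window=window, min_sites=1,
                             reads=(reads["female"], reads["male"]))
        assert dropped == 0
        for col in ("cov_diff", "het_f", "het_m", "het_diff"):
            assert np.allclose(lifted[col], direct[col], rtol=1e-9, equal_nan=True)
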