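"""Boundary inference: scaffold evidence profiles, PAR/fusion classification
rules, the neo-Z model grammar and its assembly from calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neozscan import default_spec
from neozscan.boundaries import (
    FUSION_POINT,
    NONE,
    PAR_BOUNDARY,
    PUTATIVE_FUSION_END,
    NeoSegment,
    NeoSexModel,
    build_neo_model,
    classify_scaffolds,
    scaffold_sexlink_profile,
    truth_neo_model,
)
from neozscan.windows import tile_windows

PUBLISHED = "8_28.0–7.3(−)_–Z_0.0–72.9(+)_–4A_9.6–0.0(−)"


def _flagged(scaffold, flags, window=100_000):
    n = len(flags)
    w = tile_windows({scaffold: n * window}, window)
    w["cov_diff"] = np.where(flags, -0.5, 0.0)
    w["het_diff"] = 0.0
    w["cov_low"] = np.asarray(flags, dtype=bool)
    w["het_high"] = False
    return w


def _anchor(scaffold, chrom, length, t_start, strand="+"):
    return {"scaffold": scaffold, "q_start": 0, "q_end": length, "chrom": chrom,
            "t_start": t_start, "t_end": t_start + length, "strand": strand,
            "aln_len": length, "identity": 1.0}


class TestProfiles:
    def test_fully_flagged_scaffold(self):
        stats = _flagged("s1", np.ones(10, bool))
        anchors = pd.DataFrame([_anchor("s1", "chr1", 1_000_000, 0)])
        prof = scaffold_sexlink_profile(stats, anchors)
        row = prof.iloc[0]
        assert row["frac_flagged"] == 1.0 and row["n_transitions"] == 0
        assert row["per_chrom"]["chr1"]["frac"] == 1.0

    def test_half_flagged_transition_position(self):
        flags = np.zeros(20, bool)
        flags[:10] = True
        prof = scaffold_sexlink_profile(
            _flagged("s1", flags), pd.DataFrame([_anchor("s1", "chr1", 2_000_000, 0)]))
        row = prof.iloc[0]
        assert row["frac_flagged"] == 0.5
        assert row["n_transitions"] == 1
        assert row["transition_pos"] == 10 * 100_000

    def test_hand_computed_mixed_scaffolds(self):
        stats = pd.concat([
            _flagged("a", [True] * 4),
            _flagged("b", [True, True, False, False]),
            _flagged("c", [False] * 4),
            _flagged("d", [True, False, True, False]),
        ], ignore_index=True)
        anchors = pd.DataFrame([_anchor(s, "chr1", 400_000, i * 400_000)
                                for i, s in enumerate("abcd")])
        prof = scaffold_sexlink_profile(stats, anchors).set_index("scaffold")
        assert prof.loc["a", "frac_flagged"] == 1.0
        assert prof.loc["b", "frac_flagged"] == 0.5
        assert prof.loc["c", "frac_flagged"] == 0.0
        assert prof.loc["b", "longest_flagged_run"] == 2
        # alternating flags are majority-smoothed into one clean transition
        assert prof.loc["d", "n_transitions"] == 1
        assert prof.loc["d", "frac_flagged"] == 0.5

    def test_single_noise_window_smoothed_away(self):
        flags = np.ones(12, bool)
        flags[5] = False
        prof = scaffold_sexlink_profile(
            _flagged("s1", flags), pd.DataFrame([_anchor("s1", "chr1", 1_200_000, 0)]))
        assert prof.iloc[0]["n_transitions"] == 0
        assert prof.iloc[0]["frac_flagged"] == 1.0


class TestClassification:
    def _classify(self, stats, anchors, regions=None):
        regions = regions if regions is not None else pd.DataFrame(
            columns=["chrom", "start", "end"])
        prof = scaffold_sexlink_profile(stats, anchors)
        return classify_scaffolds(prof, anchors, regions).set_index("scaffold")

    def test_two_chromosome_scaffold_is_fusion_point(self):
        stats = _flagged("s1", np.ones(10, bool))
        anchors = pd.DataFrame([
            _anchor("s1", "chrZ", 500_000, 4_500_000),
            {**_anchor("s1", "chr4A", 500_000, 0), "q_start": 500_000, "q_end": 1_000_000},
        ])
        calls = self._classify(stats, anchors)
        assert calls.loc["s1", "call"] == FUSION_POINT
        assert set(calls.loc["s1", "target_chroms"]) == {"chrZ", "chr4A"}

    def test_partial_flags_single_transition_is_par_boundary(self):
        flags = np.zeros(20, bool)
        flags[:10] = True
        anchors = pd.DataFrame([_anchor("s1", "chr8", 2_000_000, 1_000_000)])
        calls = self._classify(_flagged("s1", flags), anchors)
        assert calls.loc["s1", "call"] == PAR_BOUNDARY
        assert calls.loc["s1", "boundary_chrom"] == "chr8"
        assert abs(calls.loc["s1", "boundary_position"] - 2_000_000) <= 100_000

    def test_unflagged_scaffold_is_none(self):
        calls = self._classify(_flagged("s1", np.zeros(10, bool)),
                               pd.DataFrame([_anchor("s1", "chr1", 1_000_000, 0)]))
        assert calls.loc["s1", "call"] == NONE

    def test_fully_flagged_at_region_edge_is_putative_fusion_end(self):
        regions = pd.DataFrame([{"chrom": "chrZ", "start": 0, "end": 5_000_000}])
        anchors = pd.DataFrame([_anchor("s1", "chrZ", 1_000_000, 4_000_000)])
        calls = self._classify(_flagged("s1", np.ones(10, bool)), anchors, regions)
        assert calls.loc["s1", "call"] == PUTATIVE_FUSION_END
        assert calls.loc["s1", "boundary_position"] == 5_000_000

    def test_fully_flagged_interior_scaffold_is_none(self):
        regions = pd.DataFrame([{"chrom": "chrZ", "start": 0, "end": 5_000_000}])
        anchors = pd.DataFrame([_anchor("s1", "chrZ", 1_000_000, 1_500_000)])
        calls = self._classify(_flagged("s1", np.ones(10, bool)), anchors, regions)
        assert calls.loc["s1", "call"] == NONE

    def test_multiple_transitions_marked_complex(self):
        flags = np.array([True] * 5 + [False] * 5 + [True] * 5 + [False] * 5)
        calls = self._classify(_flagged("s1", flags),
                               pd.DataFrame([_anchor("s1", "chr1", 2_000_000, 0)]))
        assert calls.loc["s1", "call"] == NONE
        assert calls.loc["s1", "annotation"] == "complex"

    def test_input_order_invariance(self):
        stats = pd.concat([_flagged("s1", np.ones(10, bool)),
                           _flagged("s2", np.zeros(10, bool))], ignore_index=True)
        anchors = pd.DataFrame([_anchor("s1", "chr1", 1_000_000, 0),
                                _anchor("s2", "chr1", 1_000_000, 1_000_000)])
        fwd = self._classify(stats, anchors)
        rev = self._classify(stats.iloc[::-1].reset_index(drop=True), anchors)
        pd.testing.assert_series_equal(fwd["call"].sort_index(), rev["call"].sort_index())


class TestModelGrammar:
    def test_published_sylvioidea_string_roundtrips(self):
        model = NeoSexModel.parse(PUBLISHED)
        assert [s.chrom for s in model.segments] == ["8", "Z", "4A"]
        assert model.render() == PUBLISHED

    def test_parse_tolerates_trailing_underscore_and_ascii(self):
        model = NeoSexModel.parse("Z_0.0-72.9(+)_")
        assert model.segments[0] == NeoSegment("Z", 0.0, 72.9, "+")

    def test_bad_segment_rejected(self):
        with pytest.raises(ValueError, match="cannot parse"):
            NeoSexModel.parse("Z_banana(+)")

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            NeoSexModel([])

    @given(st.lists(
        st.tuples(
            st.sampled_from(["Z", "4A", "8", "chr5", "25"]),
            st.integers(0, 800).map(lambda v: v / 10),
            st.integers(0, 800).map(lambda v: v / 10),
            st.sampled_from(["+", "-", "?"]),
        ), min_size=1, max_size=5))
    def test_random_models_roundtrip(self, parts):
        model = NeoSexModel([NeoSegment(*p) for p in parts])
        assert NeoSexModel.parse(model.render()) == model


class TestBuildModel:
    def test_z_only(self):
        regions = pd.DataFrame([{"chrom": "chrZ", "start": 0, "end": 5_000_000}])
        calls = pd.DataFrame(columns=["call", "boundary_chrom", "boundary_position"])
        model = build_neo_model(regions, calls, "chrZ", {"chrZ": 5_000_000})
        assert model.render() == "chrZ_0.0–5.0(+)"

    def test_missing_ancestral_z_is_error(self):
        regions = pd.DataFrame([{"chrom": "chr8", "start": 0, "end": 1_000_000}])
        with pytest.raises(ValueError, match="ancestral"):
            build_neo_model(regions, pd.DataFrame(), "chrZ", {"chrZ": 5_000_000})

    def test_partner_without_boundary_evidence_gets_unknown_orientation(self):
        regions = pd.DataFrame([
            {"chrom": "chrZ", "start": 0, "end": 5_000_000},
            {"chrom": "chr8", "start": 1_000_000, "end": 3_000_000},
        ])
        calls = pd.DataFrame(columns=["call", "boundary_chrom", "boundary_position"])
        model = build_neo_model(regions, calls, "chrZ",
                                {"chrZ": 5_000_000, "chr8": 4_000_000})
        assert any(s.strand == "?" for s in model.segments)

    def test_par_boundary_extends_partner_through_par(self):
        regions = pd.DataFrame([
            {"chrom": "chrZ", "start": 0, "end": 5_000_000},
            {"chrom": "chr8", "start": 1_000_000, "end": 3_000_000},
        ])
        calls = pd.DataFrame([{"call": PAR_BOUNDARY, "boundary_chrom": "chr8",
                               "boundary_position": 3_000_000}])
        model = build_neo_model(regions, calls, "chrZ",
                                {"chrZ": 5_000_000, "chr8": 4_000_000})
        # PAR boundary at the region's high edge: the segment runs from the
        # fused edge (1.0) through the PAR to the chromosome end (4.0); a
        # single partner attaches after the Z by convention.
        assert model.render() == "chrZ_0.0–5.0(+)_–chr8_1.0–4.0(+)"

    def test_truth_model_of_default_toy_genome(self):
        assert truth_neo_model(default_spec()).render() == \
            "chr8_4.0–1.0(−)_–chrZ_0.0–5.0(+)_–chr4A_3.0–0.0(−)"
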