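"""Region calling: chromosome summaries, 1-SD outlier flags, run-based
segmentation against an exhaustive enumeration oracle, classification and
diagnostic-locus selection."""

import numpy as np
import pandas as pd
import pytest

from neozscan.caller import (
    HIGH,
    LOW,
    call_regions,
    classify_region,
    classify_regions,
    flag_windows,
    select_diagnostic_loci,
    summarize_chromosomes,
)
from neozscan.windows import tile_windows


def _stats(cov, het, chrom="c1", window=1000):
    n = len(cov)
    w = tile_windows({chrom: n * window}, window)
    w["cov_diff"] = np.asarray(cov, dtype=float)
    w["het_diff"] = np.asarray(het, dtype=float)
    return w


class TestSummaries:
    def test_single_window_chromosome_unreliable_sd_zero(self):
        s = summarize_chromosomes(_stats([0.2], [1.0]), min_windows=10)
        assert s["sd_cov_diff"].iloc[0] == 0.0
        assert not s["reliable"].iloc[0]

    def test_manual_five_window_arithmetic(self):
        cov = [0.1, -0.1, 0.0, 0.2, -0.2]
        het = [1.0, 2.0, 3.0, 4.0, 5.0]
        s = summarize_chromosomes(_stats(cov, het), min_windows=5)
        assert s["mean_cov_diff"].iloc[0] == pytest.approx(np.mean(cov))
        assert s["sd_cov_diff"].iloc[0] == pytest.approx(np.std(cov))
        assert s["mean_het_diff"].iloc[0] == pytest.approx(3.0)
        assert s["reliable"].iloc[0]

    def test_all_missing_chromosome_omitted(self, caplog):
        s = _stats([np.nan, np.nan], [np.nan, np.nan])
        with caplog.at_level("WARNING"):
            out = summarize_chromosomes(s)
        assert len(out) == 0

    def test_toy_autosome_is_inconspicuous(self, toy_stats):
        """On the toy genome the autosome's chromosome mean stays well inside
        one SD of the genome-wide window spread for both metrics."""
        summ = summarize_chromosomes(toy_stats).set_index("chrom")
        for metric in ("cov_diff", "het_diff"):
            vals = toy_stats[metric].to_numpy(dtype=float)
            spread = np.nanstd(vals)
            assert abs(summ.loc["chrA", f"mean_{metric}"] - np.nanmean(vals)) < spread


class TestFlags:
    def test_uniform_profile_no_flags(self, caplog):
        with caplog.at_level("WARNING"):
            flagged, _ = flag_windows(_stats([0.0] * 5, [0.0] * 5))
        assert not flagged["cov_low"].any() and not flagged["het_high"].any()

    def test_forced_outlier_flagged(self):
        rng = np.random.default_rng(0)
        cov = rng.normal(0, 0.05, 100)
        cov[50] = -0.5
        flagged, _ = flag_windows(_stats(cov, np.zeros(100)))
        assert flagged["cov_low"][50]

    def test_one_sided_direction(self):
        cov = np.concatenate([np.zeros(50), [-1.0, 1.0]])
        flagged, _ = flag_windows(_stats(cov, np.zeros(52)))
        assert flagged["cov_low"][50] and not flagged["cov_low"][51]

    def test_gaussian_noise_tail_fraction(self):
        """One-sided 1-SD flags catch ~15.9% of pure-noise windows."""
        rng = np.random.default_rng(1)
        n = 20_000
        flagged, _ = flag_windows(_stats(rng.normal(0, 1, n), np.zeros(n)))
        p = flagged["cov_low"].mean()
        assert abs(p - 0.1587) < 3 * np.sqrt(0.1587 * (1 - 0.1587) / n)

    def test_exclude_regions_recomputes_baseline(self):
        cov = np.concatenate([np.full(50, -0.5), np.zeros(150)])
        stats = _stats(cov, np.zeros(200))
        regions = pd.DataFrame([{"chrom": "c1", "start": 0, "end": 50_000}])
        _, thr_all = flag_windows(stats)
        _, thr_excl = flag_windows(stats, exclude=regions)
        assert thr_excl["cov_diff"]["sd"] < thr_all["cov_diff"]["sd"]


def _flag_frame(flags_cov, flags_het=None, chrom="c1"):
    n = len(flags_cov)
    w = tile_windows({chrom: n * 1000}, 1000)
    w["cov_diff"] = np.where(flags_cov, -0.5, 0.0)
    w["het_diff"] = np.where(flags_het if flags_het is not None else np.zeros(n, bool), 30.0, 0.0)
    w["cov_low"] = np.asarray(flags_cov, dtype=bool)
    w["het_high"] = (np.asarray(flags_het, dtype=bool) if flags_het is not None
                     else np.zeros(n, dtype=bool))
    return w


def _enumerate_regions(flags, min_run, max_gap):
    """Independent oracle: exhaustive scan for maximal qualifying runs of a
    single metric's flag vector (cov-only input)."""
    idx = [i for i, f in enumerate(flags) if f]
    runs, current = [], []
    for i in idx:
        if current and i - current[-1] - 1 > max_gap:
            runs.append(current)
            current = []
        current.append(i)
    if current:
        runs.append(current)
    return [(r[0], r[-1]) for r in runs if len(r) >= min_run]


class TestCallRegions:
    def test_no_flags_no_regions(self):
        assert len(call_regions(_flag_frame(np.zeros(20, bool)))) == 0

    def test_single_run_with_gaps(self):
        flags = np.zeros(20, bool)
        flags[3:11] = True
        flags[6] = False  # tolerated gap
        out = call_regions(_flag_frame(flags), min_run=3, max_gap=2)
        assert len(out) == 1
        assert (out["start"].iloc[0], out["end"].iloc[0]) == (3000, 11_000)

    @pytest.mark.parametrize("trial", range(50))
    def test_random_vectors_match_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        flags = rng.random(200) < 0.25
        min_run, max_gap = int(rng.integers(1, 6)), int(rng.integers(0, 4))
        got = call_regions(_flag_frame(flags), min_run=min_run, max_gap=max_gap)
        expected = _enumerate_regions(flags, min_run, max_gap)
        assert len(got) == len(expected)
        for row, (a, b) in zip(got.itertuples(), expected):
            assert (row.start, row.end) == (a * 1000, (b + 1) * 1000)

    def test_single_metric_support_required(self):
        """A run of alternating weak cov/het flags with no coherent metric is
        not retained."""
        cov = np.zeros(14, bool)
        het = np.zeros(14, bool)
        cov[::2] = True   # 7 coverage flags
        het[1::2] = True  # 7 heterozygosity flags
        out = call_regions(_flag_frame(cov, het), min_run=10, max_gap=2)
        assert len(out) == 0
        # the same 14-flag run coherent on one metric is retained
        out2 = call_regions(_flag_frame(cov | het), min_run=10, max_gap=2)
        assert len(out2) == 1


class TestClassification:
    def _region(self, **kw):
        base = dict(chrom="c", start=0, end=10, n_windows=10, n_flagged=10,
                    support_cov=1.0, support_het=0.0, mean_cov_diff=0.0,
                    mean_het_diff=0.0)
        base.update(kw)
        return pd.DataFrame([base]).itertuples().__next__()

    def test_drastic_coverage_loss_is_high_degeneration(self):
        klass, weak = classify_region(self._region(mean_cov_diff=-0.5, support_het=0.1))
        assert klass == HIGH and not weak

    def test_elevated_heterozygosity_is_low_degeneration(self):
        klass, weak = classify_region(self._region(
            mean_cov_diff=-0.1, support_het=0.8, mean_het_diff=1.2))
        assert klass == LOW and not weak

    def test_neither_signature_is_weak(self):
        klass, weak = classify_region(self._region(
            mean_cov_diff=-0.1, support_het=0.2, mean_het_diff=0.5))
        assert klass == LOW and weak

    def test_classify_regions_adds_columns(self):
        regions = pd.DataFrame([
            dict(chrom="c", start=0, end=10, n_windows=10, n_flagged=10,
                 support_cov=1.0, support_het=0.0, mean_cov_diff=-0.5, mean_het_diff=0.0),
        ])
        out = classify_regions(regions)
        assert list(out["klass"]) == [HIGH]


class TestDiagnosticLoci:
    def _gts(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "gt_f", "gt_m", "ins_len"])

    def test_selection_rule(self):
        regions = pd.DataFrame([{"chrom": "c1", "start": 0, "end": 1000}])
        g = self._gts([
            ("c1", 10, 1, 0, 12),   # female het insertion, male hom-ref: selected
            ("c1", 20, 1, 0, 0),    # SNV: excluded
            ("c1", 30, 1, 1, 12),   # male not hom-ref: excluded
            ("c1", 40, 2, 0, 12),   # female hom: excluded
            ("c2", 10, 1, 0, 12),   # outside regions: excluded
        ])
        out = select_diagnostic_loci(g, regions)
        assert list(out["pos"]) == [10]

    def test_ranked_by_insertion_length_and_matches_hand_filter(self):
        rng = np.random.default_rng(3)
        rows = [("c1", int(p), int(rng.integers(0, 3)), int(rng.integers(0, 3)),
                 int(rng.choice([0, 0, 8, 15, 30]))) for p in range(50)]
        regions = pd.DataFrame([{"chrom": "c1", "start": 10, "end": 40}])
        out = select_diagnostic_loci(self._gts(rows), regions)
        expected = sorted(
            [r for r in rows if r[4] > 0 and r[2] == 1 and r[3] == 0 and 10 <= r[1] < 40],
            key=lambda r: (-r[4], r[1]))
        assert [(r.pos, r.ins_len) for r in out.itertuples()] == [(r[1], r[4]) for r in expected]
        assert list(out["rank"]) == list(range(1, len(expected) + 1))

    def test_empty_result_is_not_an_error(self):
        out = select_diagnostic_loci(self._gts([]), pd.DataFrame(columns=["chrom", "start", "end"]))
        assert len(out) == 0


class TestSmallChromosomeGuard:
    def test_unreliable_chromosomes_not_promoted_by_means(self):
        """A deviant chromosome-level mean on a chromosome with too few
        windows is marked unreliable and yields no region on its own."""
        frames = []
        rng = np.random.default_rng(5)
        for i in range(5):
            frames.append(_stats(rng.normal(0, 0.05, 100), rng.normal(0, 2, 100),
                                 chrom=f"big{i}"))
        frames.append(_stats([-0.4, -0.35, -0.45], [0.0, 0.0, 0.0], chrom="tiny"))
        stats = pd.concat(frames, ignore_index=True)
        flagged, _ = flag_windows(stats)
        summ = summarize_chromosomes(flagged, min_windows=10).set_index("chrom")
        assert not summ.loc["tiny", "reliable"]
        regions = call_regions(flagged, min_run=10, max_gap=2)
        assert "tiny" not in set(regions["chrom"])
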