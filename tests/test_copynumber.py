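"""Coverage log-ratio tracks, median decimation, arm calls and focal deletions."""

import numpy as np
import pytest

from gliomics.copynumber import (
    ArmCall,
    CoverageTrack,
    LogRatioTrack,
    arm_summary,
    detect_codeletion,
    focal_deletions,
    log_ratio,
    median_decimate,
)
from gliomics.genome import GeneModel
from gliomics.simulate import SimulationConfig, simulate_paired_cohort


def _track(counts, sample_id="t", w=1000):
    return CoverageTrack(sample_id, w, {c: np.asarray(v, dtype=float) for c, v in counts.items()})


class TestLogRatio:
    def test_identity(self):
        t = _track({"chr1": [10, 20, 30], "chr2": [5, 5]})
        lr = log_ratio(t, t)
        for vals in lr.ratios.values():
            assert np.allclose(vals, 0.0)

    def test_scaling_invariance(self):
        t = _track({"chr1": [10, 20, 30, 40]})
        n = _track({"chr1": [12, 18, 33, 37]}, "n")
        t2 = _track({"chr1": [30, 60, 90, 120]})
        np.testing.assert_allclose(log_ratio(t, n).ratios["chr1"], log_ratio(t2, n).ratios["chr1"])

    def test_halved_arm_reads_minus_one_after_normalization(self):
        # chr1 halved, chr2 unchanged: after total normalization chr1 ~ -1 + shift
        n = _track({"chr1": [100] * 10, "chr2": [100] * 30}, "n")
        t = _track({"chr1": [50] * 10, "chr2": [100] * 30})
        lr = log_ratio(t, n)
        shift = np.log2(4000 / 3500)  # library-size renormalization
        np.testing.assert_allclose(lr.ratios["chr1"], -1 + shift, atol=1e-12)
        np.testing.assert_allclose(lr.ratios["chr2"], shift, atol=1e-12)

    def test_zero_windows_masked_not_infinite(self):
        n = _track({"chr1": [100, 0, 100]}, "n")
        t = _track({"chr1": [0, 50, 100]})
        lr = log_ratio(t, n)
        assert np.isnan(lr.ratios["chr1"][0]) and np.isnan(lr.ratios["chr1"][1])
        assert np.isfinite(lr.ratios["chr1"][2])

    def test_windowing_mismatch_rejected(self):
        with pytest.raises(ValueError, match="windowing"):
            log_ratio(_track({"chr1": [1, 2]}), _track({"chr1": [1, 2, 3]}, "n"))


class TestMedianDecimate:
    def _lr(self, vals, w=1000):
        return LogRatioTrack("s", w, {"chr1": np.asarray(vals, dtype=float)})

    def test_factor_one_is_identity(self):
        t = self._lr([1.0, 2.0, np.nan])
        out = median_decimate(t, 1)
        np.testing.assert_array_equal(out.ratios["chr1"], t.ratios["chr1"])

    def test_median_of_consecutive_integers(self):
        out = median_decimate(self._lr(np.arange(1, 201)), 200)
        assert out.ratios["chr1"] == pytest.approx([100.5])
        assert out.window_size == 200_000 and out.decimation == 200

    def test_constant_track_with_masked_windows_stays_constant(self):
        vals = np.full(100, 2.5)
        vals[::10] = np.nan  # 10% masked
        out = median_decimate(self._lr(vals), 20)
        np.testing.assert_allclose(out.ratios["chr1"], 2.5)

    def test_output_length_is_ceil_and_terminal_block_used(self):
        out = median_decimate(self._lr(np.arange(10.0)), 4)
        assert len(out.ratios["chr1"]) == 3  # ceil(10/4)
        assert out.ratios["chr1"][-1] == pytest.approx(8.5)  # median of [8, 9]

    def test_fully_masked_block_stays_masked(self):
        vals = np.array([np.nan, np.nan, 1.0, 1.0])
        out = median_decimate(self._lr(vals), 2)
        assert np.isnan(out.ratios["chr1"][0]) and out.ratios["chr1"][1] == 1.0

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            median_decimate(self._lr([1.0]), 0)


class TestArmCalls:
    def test_flat_track_all_neutral(self, genome):
        n_win = {c: len(genome.chroms[c]) // 1000 for c in genome.chroms}
        track = LogRatioTrack("s", 1000, {c: np.zeros(n) for c, n in n_win.items()})
        calls = arm_summary(track, genome.arms)
        assert all(c.call == "neutral" for c in calls)

    def test_simulated_arm_events_called(self, bundle):
        expected = {"1p": "loss", "19q": "loss", "7p": "gain", "7q": "gain"}
        for sid, cov in bundle.coverage.items():
            lr = log_ratio(cov, bundle.normal)
            calls = arm_summary(median_decimate(lr, 200), bundle.genome.arms)
            by_arm = {c.arm: c.call for c in calls}
            for arm, want in expected.items():
                assert by_arm[arm] == want, (sid, arm)
            assert by_arm["10p"] == "neutral" and by_arm["9q"] == "neutral"

    def test_empty_arm_reported_missing(self, genome):
        track = LogRatioTrack("s", 1000, {"chr1": np.full(1200, np.nan)})
        calls = arm_summary(track, genome.arms)
        by_arm = {c.arm: c.call for c in calls}
        assert by_arm["1p"] == "missing" and by_arm["7q"] == "missing"


class TestCodeletion:
    @pytest.mark.parametrize(
        "c1p,c19q,expected",
        [("loss", "loss", True), ("loss", "neutral", False), ("gain", "loss", False), ("neutral", "neutral", False)],
    )
    def test_truth_table(self, c1p, c19q, expected):
        calls = [ArmCall("1p", -1.0, c1p), ArmCall("19q", -1.0, c19q), ArmCall("7p", 0.0, "neutral")]
        assert detect_codeletion(calls) is expected

    def test_missing_arm_is_an_error(self):
        with pytest.raises(ValueError, match="19q"):
            detect_codeletion([ArmCall("1p", -1.0, "loss")])


class TestFocalDeletions:
    def _gene(self, start=10_000, end=60_000, strand="+"):
        return GeneModel("G1", "chr1", strand, start, end,
                        exons=((start, start + 100), (end - 100, end)), coding_lengths=(100, 100))

    def test_planted_tss_deletion_recovered(self):
        vals = np.zeros(200)
        vals[5:55] = -2.0  # 50 kb deletion over windows 5..54
        track = LogRatioTrack("s", 1000, {"chr1": vals})
        events = focal_deletions(track, [self._gene()])
        assert len(events) == 1
        ev = events[0]
        assert ev.gene_id == "G1" and ev.start == 5000 and ev.end == 55_000 and ev.tss_overlap

    def test_flat_track_yields_nothing(self):
        track = LogRatioTrack("s", 1000, {"chr1": np.zeros(100)})
        assert focal_deletions(track, [self._gene()]) == []

    def test_arm_wide_loss_excluded_by_span(self):
        vals = np.full(12_000, -1.0)  # 12 Mb of single-copy loss
        track = LogRatioTrack("s", 1000, {"chr1": vals})
        gene = GeneModel("G1", "chr1", "+", 1_000_000, 1_050_000,
                         exons=((1_000_000, 1_000_100),), coding_lengths=(100,))
        assert focal_deletions(track, [gene], del_thr=-1.0, max_span=10_000_000) == []

    def test_tss_overlap_false_when_run_misses_tss(self):
        vals = np.zeros(200)
        vals[30:40] = -2.0  # inside the gene body, away from the + strand TSS at 10 kb
        track = LogRatioTrack("s", 1000, {"chr1": vals})
        (ev,) = focal_deletions(track, [self._gene()])
        assert not ev.tss_overlap

    def test_min_windows_suppresses_single_window_dips(self):
        vals = np.zeros(200)
        vals[20] = -3.0
        track = LogRatioTrack("s", 1000, {"chr1": vals})
        assert focal_deletions(track, [self._gene()], min_windows=2) == []
        assert len(focal_deletions(track, [self._gene()], min_windows=1)) == 1

    def test_simulated_ptprd_tss_deletion_in_relapse_only(self, bundle):
        for sid, cov in bundle.coverage.items():
            lr = log_ratio(cov, bundle.normal)
            events = focal_deletions(median_decimate(lr, 10), bundle.genome.genes,
                                     del_thr=-1.5, min_windows=2)
            if sid.endswith("relapse"):
                assert any(e.gene_id == "PTPRD" and e.tss_overlap for e in events), sid
            else:
                assert events == [], sid


def test_planted_arm_recovery_across_seeds():
    """Arm loss at copy ratio 0.5 and gain at 1.5 are always called at 60x depth."""
    for seed in range(10):
        b = simulate_paired_cohort(
            SimulationConfig(seed=seed, n_patients=1, n_true_somatic=5, n_artifacts=0,
                             n_germline=0, hypermutator_patient=None)
        )
        lr = log_ratio(b.coverage["case1-relapse"], b.normal)
        calls = arm_summary(median_decimate(lr, 200), b.genome.arms)
        by_arm = {c.arm: c.call for c in calls}
        assert by_arm["1p"] == "loss" and by_arm["19q"] == "loss"
        assert by_arm["7p"] == "gain" and by_arm["7q"] == "gain"
        assert detect_codeletion(calls)
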