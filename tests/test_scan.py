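"""Sliding-window scan: tiling, counting, merging, refinement, background."""

import numpy as np
import pandas as pd
import pytest

from iris import synth
from iris.scan import (
    call_significant_windows,
    count_window,
    make_windows,
    merge_windows,
    refine_bounds,
    rescore_loci,
    scan_windows,
    select_background_loci,
)


class TestMakeWindows:
    @pytest.mark.parametrize(
        "length, expected",
        [
            (1000, [(0, 500), (250, 750), (500, 1000)]),
            (400, [(0, 400)]),  # shorter than width -> one full-length window
            (1100, [(0, 500), (250, 750), (500, 1000), (750, 1100)]),
            (500, [(0, 500)]),
        ],
    )
    def test_tiling(self, length, expected):
        assert make_windows(length) == expected

    def test_short_tail_dropped(self):
        # width 500, step 400: terminal window of 150 < step is dropped
        assert make_windows(950, width=500, step=400) == [(0, 500), (400, 900)]

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_windows(0)
        with pytest.raises(ValueError):
            make_windows(1000, width=500, step=600)


class TestCountWindow:
    def test_no_reads(self, reads_factory):
        counts = count_window(reads_factory([]), (0, 500))
        assert counts.as_tuple() == (0, 0, 0, 0)

    def test_sense_read_counted_by_start(self, reads_factory):
        reads = reads_factory([("T1", 100, 150, "sense")])
        assert count_window(reads, (0, 500)).as_tuple() == (0, 0, 1, 0)

    def test_antisense_read_counted_by_biological_five_prime(self, reads_factory):
        # antisense read spanning [490,540): 5' end at 539 -> rest
        reads = reads_factory([("T1", 490, 540, "antisense")])
        assert count_window(reads, (0, 500)).as_tuple() == (0, 1, 0, 0)

    def test_every_read_on_exactly_one_side(self, reads_factory):
        rng = np.random.default_rng(0)
        rows = [
            ("T1", int(s), int(s) + 50, strand)
            for s, strand in zip(
                rng.integers(0, 1950, 200),
                rng.choice(["sense", "antisense"], 200),
            )
        ]
        reads = reads_factory(rows)
        counts = count_window(reads, (250, 750))
        assert sum(counts.as_tuple()) == 200

    def test_mixed_transcripts_rejected(self, reads_factory):
        reads = reads_factory([("T1", 0, 50, "sense"), ("T2", 0, 50, "sense")])
        with pytest.raises(ValueError):
            count_window(reads, (0, 500))


class TestSignificanceAndMerging:
    def test_strict_thresholds(self):
        frame = pd.DataFrame(
            {
                "transcript_id": ["T"] * 3,
                "start": [0, 250, 500],
                "end": [500, 750, 1000],
                "log_asr": [0.6, 0.5, 2.0],
                "q": [0.005, 0.001, 0.02],
            }
        )
        kept = call_significant_windows(frame)
        assert list(kept["start"]) == [0]  # logASR == 0.5 and q == 0.02 both dropped

    def test_merge_overlapping(self):
        frame = pd.DataFrame(
            {"transcript_id": ["T", "T"], "start": [0, 250], "end": [500, 750]}
        )
        assert merge_windows(frame).iloc[0].tolist() == ["T", 0, 750]

    def test_gap_not_merged(self):
        frame = pd.DataFrame(
            {"transcript_id": ["T", "T"], "start": [0, 750], "end": [500, 1250]}
        )
        assert len(merge_windows(frame)) == 2

    def test_transcripts_never_merged(self):
        frame = pd.DataFrame(
            {"transcript_id": ["T1", "T2"], "start": [0, 0], "end": [500, 500]}
        )
        assert len(merge_windows(frame)) == 2

    def test_book_ended_merged(self):
        frame = pd.DataFrame(
            {"transcript_id": ["T", "T"], "start": [0, 500], "end": [500, 1000]}
        )
        assert merge_windows(frame).iloc[0].tolist() == ["T", 0, 1000]


class TestRefinement:
    def test_refined_to_read_span(self):
        starts = np.array([300, 400, 650])
        ends = np.array([350, 450, 720])
        assert refine_bounds((250, 750), starts, ends, 2000) == (300, 720)

    def test_extension_beyond_merged_bounds(self):
        starts = np.array([200, 700])
        ends = np.array([320, 800])
        assert refine_bounds((250, 750), starts, ends, 2000) == (200, 800)

    def test_no_overlapping_reads_discards(self):
        assert refine_bounds((250, 750), np.array([900]), np.array([950]), 2000) is None

    def test_clipped_to_transcript(self):
        assert refine_bounds((0, 100), np.array([0]), np.array([600]), 500) == (0, 500)


class TestRescore:
    def _reads(self, reads_factory):
        rows = [("T", 100 + 3 * i, 150 + 3 * i, "sense") for i in range(100)]
        rows += [("T", 260 + 2 * i, 310 + 2 * i, "antisense") for i in range(40)]
        return reads_factory(rows)

    def test_single_locus_q_equals_p(self, reads_factory):
        reads = self._reads(reads_factory)
        merged = pd.DataFrame({"transcript_id": ["T"], "start": [250], "end": [750]})
        refined = rescore_loci(merged, reads, {"T": 1000})
        assert len(refined) == 1
        assert refined.loc[0, "q"] == pytest.approx(refined.loc[0, "p"])

    def test_survivor_flagged(self, reads_factory):
        reads = self._reads(reads_factory)
        merged = pd.DataFrame({"transcript_id": ["T"], "start": [250], "end": [750]})
        refined = rescore_loci(merged, reads, {"T": 1000})
        assert bool(refined.loc[0, "groseq_pass"])
        # refined bounds = antisense read span
        assert refined.loc[0, "start"] == 260
        assert refined.loc[0, "end"] == 310 + 2 * 39

    def test_diluted_locus_dropped(self, reads_factory):
        # antisense reads spread uniformly: refined interval keeps logASR ~ 0
        rows = [("T", 10 * i, 10 * i + 50, "sense") for i in range(95)]
        rows += [("T", 190 * i, 190 * i + 50, "antisense") for i in range(5)]
        reads = reads_factory(rows)
        merged = pd.DataFrame({"transcript_id": ["T"], "start": [0], "end": [1000]})
        refined = rescore_loci(merged, reads, {"T": 1000})
        assert not refined["groseq_pass"].any()

    def test_no_antisense_reads_discarded(self, reads_factory):
        reads = reads_factory([("T", 0, 50, "sense")])
        merged = pd.DataFrame({"transcript_id": ["T"], "start": [250], "end": [750]})
        assert len(rescore_loci(merged, reads, {"T": 1000})) == 0


class TestBackgroundSelection:
    def _windows(self):
        return pd.DataFrame(
            {
                "transcript_id": ["T"] * 4,
                "start": [0, 250, 500, 750],
                "end": [500, 750, 1000, 1250],
                "log_asr": [-0.1, 0.4, 0.0, -0.5],
                "q": [0.8, 0.9, 0.4, 0.95],
            }
        )

    def test_eligibility(self):
        # logASR <= 0 AND q > 0.5: rows 0 and 3 (row 1 has logASR 0.4,
        # row 2 has q 0.4)
        bg = select_background_loci(self._windows())
        assert bg[["start", "end"]].to_numpy().tolist() == [[0, 500], [750, 1250]]

    def test_seeded_sampling_reproducible(self):
        win = pd.concat([self._windows()] * 1, ignore_index=True)
        win["transcript_id"] = ["T1", "T1", "T2", "T2"]
        win.loc[:, "log_asr"] = -0.2
        win.loc[:, "q"] = 0.9
        a = select_background_loci(win, n=2, seed=11)
        b = select_background_loci(win, n=2, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_fewer_than_requested_returns_all(self):
        bg = select_background_loci(self._windows(), n=10)
        assert len(bg) == 2


class TestScanRecovery:
    def test_null_scan_calibration_small(self):
        """Uniform bleed-through, no units: p < 0.05 fraction near nominal
        (the full 2000-window check runs in the acceptance suite)."""
        cfg = synth.SimConfig(n_genes=40, n_units=0, seed=3)
        models = synth.simulate_transcriptome(cfg)
        reads = synth.simulate_stranded_reads(models, cfg, "groseq")
        windows = scan_windows(reads, models)
        frac = float((windows["p"] < 0.05).mean())
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(windows))

    def test_declared_units_recovered(self):
        """Units at log2 enrichment 2.0 with ample antisense reads are
        called by the scan with accurate refined bounds."""
        cfg = synth.SimConfig(n_genes=60, n_units=10, unit_log2_enrichment=2.0, seed=5)
        models = synth.simulate_transcriptome(cfg)
        units = synth.place_antisense_units(models, cfg)
        reads = synth.simulate_stranded_reads(models, cfg, "groseq", units)
        windows = scan_windows(reads, models)
        sig = call_significant_windows(windows)
        merged = merge_windows(sig)
        refined = rescore_loci(merged, reads, models)
        kept = refined.loc[refined["groseq_pass"]]
        recovered = 0
        errors = []
        for tid, us, ue, _ in units:
            hits = kept.loc[
                (kept["transcript_id"] == tid) & (kept["start"] < ue) & (kept["end"] > us)
            ]
            if len(hits):
                recovered += 1
                row = hits.iloc[0]
                errors.append(max(abs(row["start"] - us), abs(row["end"] - ue)))
        assert recovered >= 0.9 * len(units)
        assert np.mean(errors) <= 250
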