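"""Scoring, percentile labeling, normalization, windows and sample assembly."""

import numpy as np
import pytest

from epig4nn.features import (LabeledPQS, assemble_samples, build_window,
                              coverage_filter, label_by_percentile,
                              load_dataset, normalize_track, one_hot,
                              save_dataset, score_pqs, window_span)
from epig4nn.genomio import Genome, GenomicInterval, SignalTrack, revcomp
from epig4nn.pqs import PQSMotif


def _motif(chrom="c1", start=0, end=10, strand="+", seq=None):
    seq = seq or "G" * (end - start)
    return PQSMotif(GenomicInterval(chrom, start, end, strand), seq, "canonical",
                    seq.count("G"))


class TestScorePQS:
    def test_full_cover_constant_run(self):
        t = SignalTrack({"c1": [(0, 10, 4.0)]})
        (s,) = score_pqs([_motif()], t)
        assert s.g4_score == pytest.approx(4.0)

    def test_partial_cover_counts_uncovered_as_zero(self):
        t = SignalTrack({"c1": [(0, 5, 2.0)]})
        (s,) = score_pqs([_motif()], t)
        assert s.g4_score == pytest.approx(1.0)

    def test_absent_chromosome_scores_zero(self):
        (s,) = score_pqs([_motif()], SignalTrack({"c9": [(0, 5, 3.0)]}))
        assert s.g4_score == 0.0

    def test_matches_dense_expansion(self, rng):
        runs, pos = [], 0
        for _ in range(30):
            pos += int(rng.integers(0, 15)) + 1
            end = pos + int(rng.integers(1, 30))
            runs.append((pos, end, float(rng.uniform(0, 3))))
            pos = end
        t = SignalTrack({"c1": runs})
        dense = np.zeros(pos + 50)
        for s, e, v in runs:
            dense[s:e] = v
        for _ in range(30):
            a = int(rng.integers(0, len(dense) - 40))
            b = a + int(rng.integers(5, 40))
            (scored,) = score_pqs([_motif(start=a, end=b)], t)
            assert scored.g4_score == pytest.approx(dense[a:b].mean())


class TestLabelByPercentile:
    def test_top_five_of_hundred(self):
        scored = [LabeledPQS(_motif(start=i, end=i + 5), 0.0) for i in range(95)]
        scored += [
            LabeledPQS(_motif(start=1000 + 10 * k, end=1005 + 10 * k), float(k))
            for k in range(1, 6)
        ]
        labeled = label_by_percentile(scored, 5)
        assert sum(l.label for l in labeled) == 5
        assert all(l.label == int(l.g4_score > 0.05) for l in labeled)

    def test_all_equal_scores_all_negative(self):
        scored = [LabeledPQS(_motif(start=i, end=i + 5), 1.0) for i in range(20)]
        assert all(l.label == 0 for l in label_by_percentile(scored, 5))

    def test_median_threshold(self):
        scored = [
            LabeledPQS(_motif(start=10 * i, end=10 * i + 5), float(i + 1))
            for i in range(10)
        ]
        labeled = label_by_percentile(scored, 50)
        assert [l.label for l in labeled] == [0] * 5 + [1] * 5

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            label_by_percentile([], 5)

    def test_monotone_in_scores(self, rng):
        """Raising one score never flips a positive to negative."""
        scores = rng.uniform(0, 1, size=50)
        scored = [
            LabeledPQS(_motif(start=10 * i, end=10 * i + 5), float(s))
            for i, s in enumerate(scores)
        ]
        base = label_by_percentile(scored, 10)
        k = int(np.argmax([l.label for l in base]))
        bumped = [
            LabeledPQS(l.motif, l.g4_score + (0.5 if i == k else 0.0))
            for i, l in enumerate(base)
        ]
        assert label_by_percentile(bumped, 10)[k].label == 1

    def test_positive_fraction_bounded(self, rng):
        scores = rng.exponential(1.0, size=400)
        scored = [
            LabeledPQS(_motif(start=10 * i, end=10 * i + 5), float(s))
            for i, s in enumerate(scores)
        ]
        for pct in (2, 5, 25):
            labeled = label_by_percentile(scored, pct)
            frac = np.mean([l.label for l in labeled])
            assert frac <= pct / 100 + 1 / len(scored)


class TestNormalizeTrack:
    def test_min_max(self):
        t = SignalTrack({"c1": [(0, 5, 0.0), (5, 10, 2.0), (10, 15, 4.0)]})
        n = normalize_track(t)
        assert [v for _, _, v in n.runs("c1")] == [0.0, 0.5, 1.0]
        assert n.normalized

    def test_all_zero_stays_zero(self):
        t = SignalTrack({"c1": [(0, 10, 0.0)]})
        n = normalize_track(t)
        assert [v for _, _, v in n.runs("c1")] == [0.0]

    def test_constant_full_cover_normalizes_to_zero(self):
        g = Genome({"c1": "ACGT" * 5})
        t = SignalTrack({"c1": [(0, 20, 3.0)]})
        n = normalize_track(t, genome=g)
        assert [v for _, _, v in n.runs("c1")] == [0.0]

    def test_clip_percentile_tames_outlier(self):
        runs = [(i, i + 1, 1.0) for i in range(999)] + [(999, 1000, 1000.0)]
        t = SignalTrack({"c1": runs})
        n = normalize_track(t, clip_percentile=99.9)
        values = [v for _, _, v in n.runs("c1")]
        assert values[-1] == 1.0
        assert values[0] == 1.0  # ordinary values no longer crushed to ~0


class TestWindows:
    def test_one_hot_order_and_n(self):
        m = one_hot("ATCGN")
        assert m.tolist() == [
            [1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1], [0, 0, 0, 0],
        ]

    def test_one_hot_empty_and_counts(self):
        assert one_hot("").shape == (0, 4)
        s = "ACGTTTGGA"
        sums = one_hot(s).sum(axis=0)
        assert sums.tolist() == [s.count("A"), s.count("T"), s.count("C"),
                                 s.count("G")]

    def test_one_hot_rejects_bad_base(self):
        with pytest.raises(ValueError):
            one_hot("ACGU")

    def test_centering_with_edge_padding(self):
        g = Genome({"c1": "A" * 1000})
        m = _motif(start=10, end=20)
        seq, window = build_window(m, g, width=100)
        assert len(seq) == 100
        assert seq[:35] == "N" * 35          # clipped left flank padded
        assert (window.start, window.end) == (0, 65)
        assert window_span(m, 100) == (-35, 65)

    def test_motif_exactly_window_wide(self):
        g = Genome({"c1": "A" * 50 + "G" * 20 + "A" * 50})
        m = _motif(start=50, end=70)
        seq, window = build_window(m, g, width=20)
        assert seq == "G" * 20
        assert (window.start, window.end) == (50, 70)

    def test_minus_strand_window_is_revcomp_of_forward(self):
        core = "ACGTACGTACGTACGTACGT"
        g = Genome({"c1": "T" * 40 + core + "A" * 40})
        m = _motif(start=45, end=55, strand="-", seq=revcomp(core[5:15]))
        seq, _ = build_window(m, g, width=20)
        ws, we = window_span(m, 20)
        assert seq == revcomp(g.fetch("c1", ws, we))

    def test_oversized_motif_is_error(self):
        with pytest.raises(ValueError):
            window_span(_motif(start=0, end=30), 20)


class TestCoverageFilter:
    def test_gap_in_one_track_drops_motif(self):
        m = _motif(start=100, end=110)
        full = SignalTrack({"c1": [(0, 1000, 1.0)]})
        gappy = SignalTrack({"c1": [(0, 104, 1.0), (106, 1000, 1.0)]})
        assert coverage_filter([m], [full], 50) == [m]
        assert coverage_filter([m], [full, gappy], 50) == []

    def test_no_tracks_is_identity(self):
        ms = [_motif(start=0, end=10)]
        assert coverage_filter(ms, [], 100) == ms

    def test_window_off_chromosome_start_dropped(self):
        m = _motif(start=2, end=12)
        full = SignalTrack({"c1": [(0, 1000, 1.0)]})
        assert coverage_filter([m], [full], 100) == []


class TestAssembleSamples:
    def test_sequence_only_has_four_channels(self, small_fixture):
        labeled = [
            LabeledPQS(m, 0.0, label=0) for m in small_fixture.motifs[:5]
        ]
        samples = assemble_samples(labeled, small_fixture.genome, None, width=250)
        assert all(s.matrix.shape == (250, 4) for s in samples)

    def test_unnormalized_track_rejected(self, small_fixture):
        t = SignalTrack({"chr1": [(0, 100, 2.0)]})
        labeled = [LabeledPQS(small_fixture.motifs[0], 0.0, label=0)]
        with pytest.raises(ValueError):
            assemble_samples(labeled, small_fixture.genome, t, width=250)

    def test_constant_track_gives_all_ones_channel(self, small_fixture):
        g = small_fixture.genome
        t = SignalTrack(
            {c: [(0, g.length(c), 1.0)] for c in g.chroms()}, normalized=True
        )
        labeled = [LabeledPQS(m, 0.0, label=1) for m in small_fixture.motifs[:4]]
        for s in assemble_samples(labeled, g, t, width=250):
            assert np.all(s.matrix[:, 4] == 1.0)

    def test_planted_peak_appears_at_window_center(self, small_fixture):
        fx = small_fixture
        pos_idx = [i for i, l in enumerate(fx.labels) if l == 1][:5]
        labeled = [LabeledPQS(fx.motifs[i], 1.0, label=1) for i in pos_idx]
        for s in assemble_samples(labeled, fx.genome, fx.epi_track, width=250):
            center = np.argmax(s.matrix[:, 4])
            assert abs(int(center) - 125) < 20

    def test_strand_consistency_on_mirrored_genome(self):
        """A motif and its reverse-complement twin encode identically."""
        motif_seq = "GGGAGGGTGGGAGGG"
        left, right = "ATCTTACG" * 5, "TTGACATA" * 5
        fwd = left + motif_seq + right
        g = Genome({"p": fwd, "m": revcomp(fwd)})
        m_plus = PQSMotif(
            GenomicInterval("p", 40, 55, "+"), motif_seq, "canonical", 12
        )
        m_minus = PQSMotif(
            GenomicInterval("m", len(fwd) - 55, len(fwd) - 40, "-"),
            motif_seq, "canonical", 12,
        )
        track = SignalTrack(
            {
                "p": [(i, i + 1, (i % 7) / 7) for i in range(len(fwd))],
                "m": [(i, i + 1, (len(fwd) - 1 - i) % 7 / 7)
                      for i in range(len(fwd))],
            },
            normalized=True,
        )
        sp, sm = assemble_samples(
            [LabeledPQS(m_plus, 1.0, 1), LabeledPQS(m_minus, 1.0, 1)],
            g, track, width=80,
        )
        assert np.array_equal(sp.matrix, sm.matrix)

    def test_dataset_round_trip(self, tmp_path, small_fixture):
        fx = small_fixture
        labeled = [
            LabeledPQS(m, 0.0, label=int(l))
            for m, l in zip(fx.motifs[:10], fx.labels[:10])
        ]
        samples = assemble_samples(labeled, fx.genome, fx.epi_track, width=250)
        save_dataset(samples, str(tmp_path / "ds"), meta={"upper_pct": 5})
        loaded = load_dataset(str(tmp_path / "ds"))
        assert len(loaded) == len(samples)
        for a, b in zip(samples, loaded):
            assert np.array_equal(a.matrix, b.matrix)
            assert (a.label, a.window, a.motif_id) == (b.label, b.window, b.motif_id)
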