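"""Fixture generator contracts: exact ground truth, recoverable labels."""

import numpy as np
import pytest

from epig4nn.features import (assemble_samples, label_by_percentile, score_pqs,
                              LabeledPQS)
from epig4nn.genomio import read_bed, read_bedgraph, read_fasta
from epig4nn.pqs import PATTERNS, scan_genome
from epig4nn.profiles import mean_profile
from epig4nn.synthetic import (FixtureSpec, assign_labels, make_fixture,
                               make_genome, write_fixture)


class TestMakeGenome:
    def test_zero_planted_genome_is_motif_free(self):
        spec = FixtureSpec(n_chroms=2, chrom_length=5000, n_canonical=0,
                           n_bulged=0, n_irregular=0, seed=7)
        genome, motifs, pairs = make_genome(spec)
        assert motifs == [] and pairs == []
        assert scan_genome(genome) == []

    def test_scanner_recovers_planted_exactly(self, small_fixture):
        fx = small_fixture
        found = scan_genome(fx.genome)
        key = lambda m: (m.interval.chrom, m.interval.start, m.interval.end,
                         m.interval.strand, m.motif_class)
        assert sorted(map(key, found)) == sorted(map(key, fx.motifs))

    def test_planted_class_mix_and_strands(self, small_fixture):
        fx = small_fixture
        classes = {c: 0 for c in ("canonical", "bulged", "irregular")}
        strands = {"+": 0, "-": 0}
        for m in fx.motifs:
            classes[m.motif_class] += 1
            strands[m.interval.strand] += 1
            assert PATTERNS[m.motif_class].fullmatch(m.sequence)
            assert m.g_count >= 12
        assert classes == {"canonical": 14, "bulged": 13, "irregular": 13}
        assert strands["+"] > 0 and strands["-"] > 0

    def test_same_seed_same_genome(self):
        spec = FixtureSpec(n_chroms=2, chrom_length=8000, n_canonical=5,
                           n_bulged=5, n_irregular=5, seed=42)
        g1, m1, _ = make_genome(spec)
        g2, m2, _ = make_genome(spec)
        assert all(g1[c] == g2[c] for c in g1.chroms())
        assert m1 == m2

    def test_infeasible_density_raises(self):
        spec = FixtureSpec(n_chroms=1, chrom_length=600, n_canonical=30,
                           n_bulged=0, n_irregular=0, seed=0)
        with pytest.raises(ValueError):
            make_genome(spec)

    def test_motifs_pairwise_separated(self, small_fixture):
        by_chrom = {}
        for m in small_fixture.motifs:
            by_chrom.setdefault(m.interval.chrom, []).append(m.interval)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                assert b.start >= a.end + 1


class TestLabelsAndSignal:
    def test_pair_labels_discordant(self, small_fixture):
        fx = small_fixture
        assert len(fx.pairs) == 4
        for a, b in fx.pairs:
            assert fx.labels[a] + fx.labels[b] == 1
            assert fx.motifs[a].sequence == fx.motifs[b].sequence
            assert fx.motifs[a].motif_class == fx.motifs[b].motif_class

    def test_positive_fraction_hit(self, small_fixture):
        fx = small_fixture
        target = round(fx.spec.positive_fraction * len(fx.motifs))
        assert int(fx.labels.sum()) == target

    def test_noise_free_signal_recovers_labels_exactly(self):
        spec = FixtureSpec(n_chroms=3, chrom_length=12000, n_canonical=10,
                           n_bulged=10, n_irregular=10, g4_noise_floor=0.0,
                           positive_fraction=0.2, seed=9)
        fx = make_fixture(spec)
        labeled = label_by_percentile(
            score_pqs(fx.motifs, fx.g4_track), 100 * spec.positive_fraction
        )
        assert np.array_equal([l.label for l in labeled], fx.labels)

    def test_all_negative_scores_at_floor(self):
        spec = FixtureSpec(n_chroms=2, chrom_length=10000, n_canonical=8,
                           n_bulged=8, n_irregular=8, positive_fraction=0.2,
                           seed=3)
        fx = make_fixture(spec)
        scored = score_pqs(fx.motifs, fx.g4_track)
        for s, label in zip(scored, fx.labels):
            if label:
                assert s.g4_score >= 0.6
            else:
                assert s.g4_score <= fx.spec.g4_noise_floor

    def test_stricter_percentile_selects_top_scores(self, small_fixture):
        fx = small_fixture
        scored = score_pqs(fx.motifs, fx.g4_track)
        labeled = label_by_percentile(scored, 10)  # half the planted 20%
        chosen = {i for i, l in enumerate(labeled) if l.label}
        ranked = np.argsort([-s.g4_score for s in scored], kind="stable")
        assert chosen <= set(ranked[:len(chosen) + 1].tolist())
        assert all(fx.labels[i] == 1 for i in chosen)


class TestEpiTrack:
    def test_noise_free_peak_height_at_positive_anchors(self):
        spec = FixtureSpec(n_chroms=2, chrom_length=10000, n_canonical=8,
                           n_bulged=8, n_irregular=8, epi_noise_sd=0.0,
                           epi_height=1.0, positive_fraction=0.25, seed=13)
        fx = make_fixture(spec)
        anchors = [m.interval for m, l in zip(fx.motifs, fx.labels) if l == 1]
        profile, _ = mean_profile(fx.epi_track, anchors, 125)
        assert profile[125] == pytest.approx(1.0, abs=1e-9)

    def test_uninformative_track_when_height_zero(self):
        spec = FixtureSpec(n_chroms=2, chrom_length=10000, n_canonical=8,
                           n_bulged=8, n_irregular=8, epi_height=0.0,
                           epi_noise_sd=0.0, positive_fraction=0.25, seed=13)
        fx = make_fixture(spec)
        assert fx.epi_track.background_mean() == 0.0

    def test_track_fully_covers_genome(self, small_fixture):
        fx = small_fixture
        for c in fx.genome.chroms():
            assert fx.epi_track.covers(c, 0, fx.genome.length(c))

    def test_pair_matrices_identical_in_sequence_channels_only(self, small_fixture):
        fx = small_fixture
        labeled = [LabeledPQS(m, 0.0, int(l))
                   for m, l in zip(fx.motifs, fx.labels)]
        samples = assemble_samples(labeled, fx.genome, fx.epi_track, width=250)
        for a, b in fx.pairs:
            assert np.array_equal(samples[a].matrix[:, :4],
                                  samples[b].matrix[:, :4])
            assert not np.array_equal(samples[a].matrix[:, 4],
                                      samples[b].matrix[:, 4])


class TestRoundTrip:
    def test_fixture_files_round_trip_through_io(self, tmp_path, small_fixture):
        fx = small_fixture
        write_fixture(fx, str(tmp_path))
        genome = read_fasta(str(tmp_path / "genome.fa"))
        assert all(genome[c] == fx.genome[c] for c in fx.genome.chroms())
        ivs = read_bed(str(tmp_path / "pqs_truth.bed"))
        assert ivs == [m.interval for m in fx.motifs]
        g4 = read_bedgraph(str(tmp_path / "g4.bedgraph"))
        epi = read_bedgraph(str(tmp_path / "epi.bedgraph"))
        for c in fx.g4_track.chroms():
            assert g4.runs(c) == fx.g4_track.runs(c)
        for c in fx.epi_track.chroms():
            assert epi.runs(c) == fx.epi_track.runs(c)

    def test_end_to_end_determinism(self):
        spec = FixtureSpec(n_chroms=2, chrom_length=9000, n_canonical=6,
                           n_bulged=6, n_irregular=6, paired_identical=2,
                           positive_fraction=0.2, seed=21)
        f1, f2 = make_fixture(spec), make_fixture(spec)
        assert f1.motifs == f2.motifs
        assert np.array_equal(f1.labels, f2.labels)
        assert f1.g4_track.runs("chr1") == f2.g4_track.runs("chr1")
        assert f1.epi_track.runs("chr2") == f2.epi_track.runs("chr2")


def test_assign_labels_respects_pairs_and_budget(rng):
    labels = assign_labels(50, [(0, 1), (2, 3)], 0.2, rng)
    assert labels.sum() == 10
    assert labels[0] + labels[1] == 1
    assert labels[2] + labels[3] == 1
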