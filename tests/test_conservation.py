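"""Splice-site windows, strength scoring, conservation means and the
randomized GT/AG-matched null."""

import math

import numpy as np
import pytest

from junctionflux.conservation import (
    PositionWeightModel,
    ScoreTableModel,
    build_random_null,
    conserved_cassette_exons,
    exon_conservation,
    filter_conserved_sites,
    is_consensus_window,
    mean_conservation,
    profile_site,
    site_window,
    window_coords,
    ExonConservation,
    SpliceSiteProfile,
    NullModel,
)
from junctionflux.events import CassetteExon
from junctionflux.genome import Genome, reverse_complement
from junctionflux.tracks import ConservationTrack, write_bedgraph


@pytest.fixture(scope="module")
def genome(tmp_path_factory):
    rng = np.random.default_rng(21)
    seq = list("".join(rng.choice(list("ACGT"), 6000)))
    # consensus donor window around a '+' boundary at 1000
    seq[997:1006] = "CAGGTAAGT"
    path = tmp_path_factory.mktemp("cons") / "g.fa"
    path.write_text(">chr1\n" + "".join(seq) + "\n")
    return Genome(path), "".join(seq)


class TestSiteWindows:
    def test_plus_strand_donor_window(self, genome):
        g, seq = genome
        w = site_window("5'", "chr1", 1000, "+", g)
        assert w == seq[997:1006] == "CAGGTAAGT"
        assert is_consensus_window("5'", w)
        assert w[3:5] == "GT"  # 1-based positions 4-5

    def test_minus_strand_donor_window(self, genome):
        g, seq = genome
        w = site_window("5'", "chr1", 2000, "-", g)
        assert w == reverse_complement(seq[1994:2003])
        assert len(w) == 9

    def test_acceptor_window_lengths_and_offsets(self, genome):
        g, seq = genome
        w = site_window("3'", "chr1", 3000, "+", g)
        assert w == seq[2980:3003] and len(w) == 23
        wm = site_window("3'", "chr1", 3000, "-", g)
        assert wm == reverse_complement(seq[2997:3020])

    def test_off_contig_raises(self, genome):
        g, _ = genome
        with pytest.raises(ValueError):
            site_window("3'", "chr1", 5, "+", g)


class TestStrengthModels:
    def test_consensus_window_scores_maximal(self):
        rng = np.random.default_rng(3)
        windows = ["CAGGTAAGT"] * 60 + [
            "".join(rng.choice(list("ACGT"), 9)) for _ in range(20)
        ]
        model = PositionWeightModel.train(windows)
        consensus = model.consensus()
        best = model.score(consensus)
        for _ in range(200):
            w = "".join(rng.choice(list("ACGT"), 9))
            assert model.score(w) <= best + 1e-9

    def test_uniform_training_scores_near_zero(self):
        rng = np.random.default_rng(5)
        windows = ["".join(rng.choice(list("ACGT"), 9)) for _ in range(4000)]
        model = PositionWeightModel.train(windows)
        scores = [model.score("".join(rng.choice(list("ACGT"), 9))) for _ in range(300)]
        assert abs(np.mean(scores)) < 0.5

    def test_score_equals_brute_force_log_odds_sum(self):
        rng = np.random.default_rng(6)
        windows = ["".join(rng.choice(list("ACGT"), 9)) for _ in range(50)]
        model = PositionWeightModel.train(windows, pseudocount=0.5)
        counts = np.full((9, 4), 0.5)
        for w in windows:
            for i, b in enumerate(w):
                counts[i, "ACGT".index(b)] += 1
        probs = counts / counts.sum(axis=1, keepdims=True)
        for w in windows[:10]:
            expected = sum(
                math.log2(probs[i, "ACGT".index(b)] / 0.25) for i, b in enumerate(w)
            )
            assert model.score(w) == pytest.approx(expected)

    def test_score_table_backend(self, tmp_path):
        import pandas as pd

        table = pd.DataFrame(
            np.arange(36).reshape(9, 4), columns=list("ACGT")
        )
        path = tmp_path / "scores.tsv"
        table.to_csv(path, sep="\t", index=False)
        model = ScoreTableModel.from_tsv(path)
        w = "ACGTACGTA"
        assert model.score(w) == pytest.approx(
            sum(table.iloc[i][b] for i, b in enumerate(w))
        )

    def test_length_mismatch_rejected(self):
        model = PositionWeightModel.train(["ACGTACGTA"])
        with pytest.raises(ValueError):
            model.score("ACGT")


class TestMeanConservation:
    def make_track(self, tmp_path, rows):
        path = tmp_path / "t.bedgraph"
        write_bedgraph(path, rows)
        return ConservationTrack.open(str(path))

    def test_constant_track(self, tmp_path):
        track = self.make_track(tmp_path, [("chr1", 0, 100, 2.0)])
        mean, frac = mean_conservation("chr1", 10, 20, track)
        assert mean == pytest.approx(2.0) and frac == 1.0

    def test_half_and_half(self, tmp_path):
        track = self.make_track(tmp_path, [("chr1", 0, 5, 0.0), ("chr1", 5, 10, 1.0)])
        mean, _ = mean_conservation("chr1", 0, 10, track)
        assert mean == pytest.approx(0.5)

    def test_matches_per_base_oracle(self, tmp_path):
        rng = np.random.default_rng(11)
        vals = rng.normal(0, 1, 200)
        rows = [("chr1", i, i + 1, float(v)) for i, v in enumerate(vals)]
        track = self.make_track(tmp_path, rows)
        got = track.values("chr1", 37, 113)
        # bedGraph text round-trips at %g precision
        assert np.allclose(got, vals[37:113], atol=1e-5)
        mean, _ = mean_conservation("chr1", 37, 113, track)
        assert mean == pytest.approx(got.mean())

    def test_low_coverage_is_nan(self, tmp_path):
        track = self.make_track(tmp_path, [("chr1", 0, 4, 1.0)])
        mean, frac = mean_conservation("chr1", 0, 10, track)
        assert math.isnan(mean) and frac == pytest.approx(0.4)


@pytest.fixture(scope="module")
def genome_and_track(tmp_path_factory, genome):
    g, _ = genome
    path = tmp_path_factory.mktemp("null") / "c.bedgraph"
    write_bedgraph(path, [("chr1", 0, 6000, 0.7)])
    return g, ConservationTrack.open(str(path))


class TestRandomNull:
    def build(self, genome_and_track, n=300, seed=0):
        genome, track = genome_and_track
        spans = [("chr1", "+", 100, 5900)]
        return build_random_null(spans, genome, track, n=n, seed=seed)

    def test_constant_track_gives_degenerate_cutoff(self, genome_and_track):
        null = self.build(genome_and_track)
        assert null.cutoff_5 == pytest.approx(0.7)
        assert null.cutoff_3 == pytest.approx(0.7)

    def test_same_seed_identical(self, genome_and_track):
        a = self.build(genome_and_track, seed=5)
        b = self.build(genome_and_track, seed=5)
        assert a.cutoff_5 == b.cutoff_5 and a.cutoff_3 == b.cutoff_3
        assert a.draws_5.equals(b.draws_5)

    def test_draws_are_consensus_matched(self, genome_and_track, genome):
        g, seq = genome
        null = self.build(genome_and_track)
        for row in null.draws_5.itertuples():
            lo, hi = window_coords("5'", row.pos, row.strand)
            assert is_consensus_window("5'", g.fetch("chr1", lo, hi, row.strand))

    def test_cutoff_matches_sort_based_quantile_oracle(self, genome, tmp_path):
        g, _ = genome
        rng = np.random.default_rng(13)
        rows = [("chr1", i * 10, (i + 1) * 10, float(v))
                for i, v in enumerate(rng.normal(0, 1, 600))]
        path = tmp_path / "mix.bedgraph"
        write_bedgraph(path, rows)
        track = ConservationTrack.open(str(path))
        null = build_random_null([("chr1", "+", 100, 5900)], g, track, n=400, seed=3)
        oracle = float(np.percentile(null.draws_3["conservation"], 95.0))
        assert null.cutoff_3 == pytest.approx(oracle)

    def test_tiny_n_rejected(self, genome_and_track):
        with pytest.raises(ValueError):
            self.build(genome_and_track, n=10)


class TestConservedPartition:
    def null(self):
        return NullModel(n_draws=100, seed=0, cutoff_5=1.04, cutoff_3=0.63)

    def prof(self, side, cons):
        p = SpliceSiteProfile(side, "chr1", 0, "+", "")
        p.mean_conservation = cons
        return p

    def test_cutoff_comparisons(self):
        part = filter_conserved_sites(
            [self.prof("5'", 1.2), self.prof("3'", 0.5), self.prof("5'", 1.04)],
            self.null(),
        )
        assert [p.mean_conservation for p in part["conserved"]] == [1.2, 1.04]
        assert [p.mean_conservation for p in part["noise"]] == [0.5]

    def test_partition_exhaustive(self):
        rng = np.random.default_rng(1)
        profs = [
            self.prof("5'" if rng.random() < 0.5 else "3'", float(rng.normal()))
            for _ in range(100)
        ]
        part = filter_conserved_sites(profs, self.null())
        assert len(part["conserved"]) + len(part["noise"]) == 100


class TestConservedCassetteExons:
    def ec(self, ss5, ss3, body):
        exon = CassetteExon("chr1", "+", 0, 90, (None, None), "g", None)
        return ExonConservation(exon, body, ss5, ss3)

    def test_three_way_threshold(self):
        kept = conserved_cassette_exons(
            [self.ec(1.5, 1.2, 1.1), self.ec(1.5, 0.4, 2.0), self.ec(0.2, 1.2, 1.5)]
        )
        assert len(kept) == 1 and kept[0].ss5_conservation == 1.5

    def test_matches_brute_force_filter_oracle(self):
        rng = np.random.default_rng(17)
        ecs = [
            self.ec(float(a), float(b), float(c))
            for a, b, c in rng.normal(1, 0.5, (60, 3))
        ]
        kept = conserved_cassette_exons(ecs, 1.04, 0.63, 1.0)
        oracle = [
            e
            for e in ecs
            if e.ss5_conservation >= 1.04
            and e.ss3_conservation >= 0.63
            and e.mean_exon_conservation >= 1.0
        ]
        assert kept == oracle
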