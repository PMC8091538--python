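"""Junction extraction from CIGAR gaps and the junction filter cascade."""

import numpy as np
import pytest

from junctionflux.annotations import Intron, TranscriptModel, merge_references
from junctionflux.discovery import (
    FilterConfig,
    JunctionObservation,
    LibraryProfile,
    aggregate_junctions,
    call_junctions,
    observations_from_read,
    overhang_and_identity_filter,
    parse_gapped_reads,
    resolve_strand,
)
from junctionflux.genome import Genome, splice_dinucleotides


class TestCigarParsing:
    def test_single_gap(self, make_read):
        read = make_read(1000, "20M100N20M", md="40")
        obs = observations_from_read(read, FilterConfig())
        assert len(obs) == 1
        o = obs[0]
        assert (o.start, o.end) == (1020, 1120)
        assert (o.left_overhang, o.right_overhang) == (20, 20)
        assert (o.left_matches, o.right_matches) == (15, 15)

    def test_two_gaps(self, make_read):
        read = make_read(0, "30M50N40M60N30M", md="100")
        obs = observations_from_read(read, FilterConfig())
        assert [(o.start, o.end) for o in obs] == [(30, 80), (120, 180)]
        # middle segment bounds both overhangs
        assert (obs[0].right_overhang, obs[1].left_overhang) == (40, 40)

    def test_no_gap_no_observation(self, make_read):
        assert observations_from_read(make_read(0, "50M", md="50"), FilterConfig()) == []

    def test_soft_clips_do_not_count_toward_overhang(self, make_read):
        read = make_read(100, "5S20M100N20M5S", md="40")
        (o,) = observations_from_read(read, FilterConfig())
        assert (o.left_overhang, o.right_overhang) == (20, 20)

    def test_deletion_counts_as_reference_but_not_match(self, make_read):
        # 10M 2D 8M gap 20M: left overhang = 20 ref nt, window has 2 deleted
        read = make_read(0, "10M2D8M100N20M", md="10^AA28")
        (o,) = observations_from_read(read, FilterConfig())
        assert o.left_overhang == 20
        assert o.left_matches == 13  # 15-nt window contains the 2 deleted bases


class TestReadLevelFilters:
    def test_low_mapq_duplicates_unmapped_dropped(self, make_read):
        reads = [
            make_read(0, "20M100N20M", md="40", mapq=0, name="lowq"),
            make_read(0, "20M100N20M", md="40", flag=1024, name="dup"),
            make_read(0, "20M100N20M", md="40", flag=4, name="unmapped"),
            make_read(0, "20M100N20M", md="40", name="keep"),
        ]
        obs = list(parse_gapped_reads(iter(reads), FilterConfig()))
        assert [o.read_id for o in obs] == ["keep"]


class TestAnchorFilter:
    def cfg(self):
        return FilterConfig()

    def obs(self, left_oh, right_oh, left_m=15, right_m=15):
        return JunctionObservation(
            "chrT", 100, 200, left_oh, right_oh, left_m, right_m, "r", "lib", "rep"
        )

    def test_minimum_overhang_boundary(self):
        assert overhang_and_identity_filter(self.obs(15, 50), self.cfg())
        assert not overhang_and_identity_filter(self.obs(14, 50), self.cfg())

    def test_identity_threshold_within_window(self):
        # 14/15 = 93.3% passes the 90% bar; 13/15 = 86.7% fails
        assert overhang_and_identity_filter(self.obs(20, 20, left_m=14), self.cfg())
        assert not overhang_and_identity_filter(self.obs(20, 20, left_m=13), self.cfg())

    def test_mismatches_from_md_tag(self, make_read):
        cfg = FilterConfig()
        clean = make_read(0, "20M100N20M", md="40")
        one_mm = make_read(0, "20M100N20M", md="10A29")  # inside left window
        two_mm = make_read(0, "20M100N20M", md="10A2A26")
        assert overhang_and_identity_filter(
            observations_from_read(clean, cfg)[0], cfg
        )
        assert overhang_and_identity_filter(
            observations_from_read(one_mm, cfg)[0], cfg
        )
        assert not overhang_and_identity_filter(
            observations_from_read(two_mm, cfg)[0], cfg
        )

    def test_mismatch_outside_window_ignored(self, make_read):
        # mismatch at read pos 2: outside the 15-nt window next to the gap
        read = make_read(0, "20M100N20M", md="2A37")
        cfg = FilterConfig()
        assert overhang_and_identity_filter(observations_from_read(read, cfg)[0], cfg)


@pytest.fixture(scope="module")
def mini_genome(tmp_path_factory):
    """Tiny contig with a GT-AG intron at (1020, 1120) on '+', an AT-AC
    intron at (2020, 2120), and CT..AC (minus-strand GT-AG) at (3020, 3120)."""
    rng = np.random.default_rng(5)
    seq = list("".join(rng.choice(list("ACGT"), 5000)))
    seq[1020:1022] = "GT"
    seq[1118:1120] = "AG"
    seq[2020:2022] = "AT"
    seq[2118:2120] = "AC"
    seq[3020:3022] = "CT"
    seq[3118:3120] = "AC"
    path = tmp_path_factory.mktemp("genome") / "mini.fa"
    path.write_text(">chrT\n" + "".join(seq) + "\n")
    return Genome(path)


class TestSpliceDinucleotides:
    def test_plus_strand_gt_ag(self, mini_genome):
        assert splice_dinucleotides(
            Intron("chrT", 1020, 1120, "+"), "+", mini_genome
        ) == ("GT", "AG")

    def test_minus_strand_reads_reverse_complement(self, mini_genome):
        assert splice_dinucleotides(
            Intron("chrT", 3020, 3120, "-"), "-", mini_genome
        ) == ("GT", "AG")

    def test_minor_spliceosome_at_ac(self, mini_genome):
        assert splice_dinucleotides(
            Intron("chrT", 2020, 2120, "+"), "+", mini_genome
        ) == ("AT", "AC")


def _ref_with_gene(strand="+", gene="g1", lo=500, hi=4500):
    transcripts = [
        TranscriptModel(
            "t1", gene, "A", "chrT", strand, [(lo, lo + 100), (hi - 100, hi)]
        )
    ]
    return merge_references({"A": transcripts})


def _mk_obs(start, end, lib, rep, n):
    return [
        JunctionObservation("chrT", start, end, 30, 30, 15, 15, f"r{i}", lib, rep)
        for i in range(n)
    ]


LIBS = [LibraryProfile("EJC", ["r1", "r2", "r3"], {"r1": 10**6, "r2": 10**6, "r3": 10**6})]


class TestCallJunctions:
    def call(self, per_rep_counts, start=1020, end=1120, cfg=None):
        obs = []
        for rep, n in zip(["r1", "r2", "r3"], per_rep_counts):
            obs += _mk_obs(start, end, "EJC", rep, n)
        genome = self._genome
        return call_junctions(obs, self._ref, genome, LIBS, cfg or FilterConfig())

    @pytest.fixture(autouse=True)
    def _setup(self, mini_genome):
        self._genome = mini_genome
        self._ref = _ref_with_gene()

    def test_all_filters_met_retained(self):
        calls = self.call([2, 2, 2])
        assert len(calls) == 1 and calls[0].status == "unannotated"
        assert calls[0].dinucleotides == ("GT", "AG")

    def test_missing_replicate_rejected(self):
        assert self.call([5, 5, 0]) == []

    def test_mean_count_below_threshold_rejected(self):
        assert self.call([2, 2, 1]) == []  # mean 1.67 < 2

    def test_non_consensus_dinucleotide_rejected(self):
        # junction at (1500, 1600) has random (non-GT-AG) ends
        assert self.call([5, 5, 5], start=1500, end=1600) == []

    def test_minor_spliceosome_retained(self):
        calls = self.call([5, 5, 5], start=2020, end=2120)
        assert len(calls) == 1 and calls[0].dinucleotides == ("AT", "AC")

    def test_outside_gene_span_rejected(self):
        ref = _ref_with_gene(lo=500, hi=900)  # gene ends before the junction
        obs = _mk_obs(1020, 1120, "EJC", "r1", 5) + _mk_obs(
            1020, 1120, "EJC", "r2", 5
        ) + _mk_obs(1020, 1120, "EJC", "r3", 5)
        assert call_junctions(obs, ref, self._genome, LIBS, FilterConfig()) == []

    def test_annotated_exempt_from_dinucleotide_filter(self):
        # annotate the random-ended intron (1500, 1600)
        transcripts = [
            TranscriptModel("t1", "g1", "A", "chrT", "+", [(1400, 1500), (1600, 1700)])
        ]
        ref = merge_references({"A": transcripts})
        obs = []
        for rep in ["r1", "r2", "r3"]:
            obs += _mk_obs(1500, 1600, "EJC", rep, 3)
        calls = call_junctions(obs, ref, self._genome, LIBS, FilterConfig())
        assert len(calls) == 1 and calls[0].status == "annotated"

    def test_count_conservation(self):
        """Pre-filter aggregated counts equal the number of passing observations."""
        obs = (
            _mk_obs(1020, 1120, "EJC", "r1", 4)
            + _mk_obs(2020, 2120, "EJC", "r2", 3)
            + [JunctionObservation("chrT", 99, 199, 5, 30, 5, 15, "x", "EJC", "r1")]
        )
        agg = aggregate_junctions(obs, FilterConfig())
        assert sum(n for counts in agg.values() for n in counts.values()) == 7


class TestResolveStrand:
    def test_unique_gene_strand_wins(self, mini_genome):
        ref = _ref_with_gene(strand="-")
        strand, ambiguous = resolve_strand(
            "chrT", 1500, 1600, ref, mini_genome, FilterConfig()
        )
        assert (strand, ambiguous) == ("-", False)

    def test_dinucleotide_breaks_gene_conflict(self, mini_genome):
        transcripts = [
            TranscriptModel("t1", "g1", "A", "chrT", "+", [(500, 600), (4400, 4500)]),
            TranscriptModel("t2", "g2", "A", "chrT", "-", [(500, 600), (4400, 4500)]),
        ]
        ref = merge_references({"A": transcripts})
        # (3020, 3120) is GT-AG on '-' only
        strand, ambiguous = resolve_strand(
            "chrT", 3020, 3120, ref, mini_genome, FilterConfig()
        )
        assert (strand, ambiguous) == ("-", False)


class TestMonotonicity:
    def test_raising_thresholds_never_adds_calls(self, mini_genome):
        rng = np.random.default_rng(3)
        obs = []
        for start, end in [(1020, 1120), (2020, 2120)]:
            for rep in ["r1", "r2", "r3"]:
                n = int(rng.integers(0, 6))
                for i in range(n):
                    obs.append(
                        JunctionObservation(
                            "chrT", start, end,
                            int(rng.integers(10, 40)), int(rng.integers(10, 40)),
                            int(rng.integers(12, 16)), int(rng.integers(12, 16)),
                            f"r{i}", "EJC", rep,
                        )
                    )
        ref = _ref_with_gene()
        base = FilterConfig()
        n_base = len(
            [c for c in call_junctions(obs, ref, mini_genome, LIBS, base)
             if c.status == "unannotated"]
        )
        for stricter in [
            FilterConfig(min_overhang=20),
            FilterConfig(min_mean_count=4),
            FilterConfig(min_match_fraction=1.0),
        ]:
            n = len(
                [c for c in call_junctions(obs, ref, mini_genome, LIBS, stricter)
                 if c.status == "unannotated"]
            )
            assert n <= n_base
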