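"""Intron extraction, multi-source merging and intersection accounting."""

from itertools import combinations

import numpy as np
import pytest

from junctionflux.annotations import (
    AnnotationIndex,
    Intron,
    MalformedAnnotationError,
    TranscriptModel,
    extract_introns,
    intersection_counts,
    merge_references,
    per_source_totals,
    read_transcripts,
)


def tx(exons, strand="+", tid="t1", gene="g1", source="A", biotype="protein_coding"):
    return TranscriptModel(tid, gene, source, "chr1", strand, list(exons), biotype)


class TestExtractIntrons:
    @pytest.mark.parametrize(
        "exons,expected",
        [
            ([(100, 200), (300, 400)], [(200, 300)]),
            ([(0, 50)], []),
            ([(10, 20), (30, 40), (55, 60)], [(20, 30), (40, 55)]),
        ],
    )
    def test_gap_arithmetic(self, exons, expected):
        introns = extract_introns(tx(exons))
        assert [(i.start, i.end) for i in introns] == expected

    def test_overlapping_exons_rejected(self):
        with pytest.raises(MalformedAnnotationError):
            extract_introns(tx([(10, 50), (40, 90)]))

    def test_unsorted_exons_rejected(self):
        with pytest.raises(MalformedAnnotationError):
            extract_introns(tx([(300, 400), (100, 200)]))

    def test_roundtrip_through_exon_reconstruction(self):
        """Rebuilding exons from introns plus flanks and re-extracting is the
        identity on intron lists."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(2, 8))
            bounds = np.sort(rng.choice(np.arange(10_000), size=2 * n, replace=False))
            exons = [(int(bounds[i]), int(bounds[i + 1])) for i in range(0, 2 * n, 2)]
            introns = extract_introns(tx(exons))
            rebuilt = [(exons[0][0], introns[0].start)]
            rebuilt += [
                (introns[i].end, introns[i + 1].start) for i in range(len(introns) - 1)
            ]
            rebuilt.append((introns[-1].end, exons[-1][1]))
            assert extract_introns(tx(rebuilt)) == introns


def make_source(introns, source, gene="g1", strand="+"):
    """One transcript per intron, exons flanking it."""
    out = []
    for i, (s, e) in enumerate(introns):
        out.append(
            tx(
                [(s - 50, s), (e, e + 50)],
                strand=strand,
                tid=f"{source}.t{i}",
                gene=gene,
                source=source,
            )
        )
    return out


class TestMergeReferences:
    def test_set_union_and_membership(self):
        i1, i2, i3 = (100, 200), (300, 400), (500, 600)
        ref = merge_references(
            {"A": make_source([i1, i2], "A"), "B": make_source([i2, i3], "B")}
        )
        assert len(ref) == 3
        assert ref.entries[Intron("chr1", 300, 400, "+")] == {"A", "B"}
        assert ref.entries[Intron("chr1", 100, 200, "+")] == {"A"}

    def test_single_source(self):
        ref = merge_references({"A": make_source([(100, 200)], "A")})
        assert all(m == {"A"} for m in ref.entries.values())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_references({})

    def test_opposite_strands_distinct(self):
        ref = merge_references(
            {
                "A": make_source([(100, 200)], "A", strand="+"),
                "B": make_source([(100, 200)], "B", strand="-"),
            }
        )
        assert len(ref) == 2

    def test_deterministic_ordering(self):
        src = {"A": make_source([(500, 600), (100, 200)], "A")}
        ref = merge_references(src)
        keys = list(ref.entries)
        assert keys == sorted(keys, key=lambda i: (i.chrom, i.start, i.end, i.strand))


class TestIntersectionCounts:
    def test_shared_and_exclusive(self):
        ref = merge_references(
            {"A": make_source([(100, 200)], "A"), "B": make_source([(100, 200)], "B")}
        )
        counts = intersection_counts(ref)
        assert counts == {frozenset({"A", "B"}): 1}

    def test_disjoint(self):
        ref = merge_references(
            {
                "A": make_source([(100, 200), (300, 400)], "A"),
                "B": make_source([(500, 600), (700, 800), (900, 1000)], "B"),
            }
        )
        counts = intersection_counts(ref)
        assert counts[frozenset({"A"})] == 2
        assert counts[frozenset({"B"})] == 3
        assert frozenset({"A", "B"}) not in counts

    def test_matches_set_algebra_oracle_on_random_four_sources(self):
        """Exclusive-subset counts equal brute-force set algebra over four
        random intron lists (1000 candidate introns)."""
        rng = np.random.default_rng(7)
        universe = [(int(s), int(s) + 50) for s in rng.choice(10**6, 1000, replace=False)]
        sources = {}
        member_sets = {}
        for label in "ABCD":
            mask = rng.random(len(universe)) < 0.4
            chosen = [iv for iv, m in zip(universe, mask) if m]
            sources[label] = make_source(chosen, label)
            member_sets[label] = set(chosen)
        ref = merge_references(sources)
        counts = intersection_counts(ref)
        # oracle: enumerate every non-empty subset directly
        labels = "ABCD"
        for r in range(1, 5):
            for subset in combinations(labels, r):
                inside = set.intersection(*(member_sets[l] for l in subset))
                outside = set.union(
                    set(), *(member_sets[l] for l in labels if l not in subset)
                )
                expected = len(inside - outside)
                assert counts.get(frozenset(subset), 0) == expected
        # conservation of mass + per-source totals
        assert sum(counts.values()) == len(ref)
        totals = per_source_totals(ref)
        for label in labels:
            assert totals[label] == len(member_sets[label])


class TestGtfRoundTrip:
    def test_simulated_gtf_reproduces_structures(self, default_sim):
        study, paths = default_sim
        source = study.config.sources[0]
        txs = read_transcripts(paths.gtfs[source], source)
        by_id = {t.transcript_id: t for t in txs}
        for gene in study.genes:
            for sim_tx in gene.transcripts:
                if source not in sim_tx.sources:
                    continue
                got = by_id[sim_tx.transcript_id]
                assert got.exons == [tuple(b) for b in sim_tx.blocks]
                assert got.strand == gene.strand
                assert got.biotype == sim_tx.biotype
                assert got.cds == [tuple(b) for b in sim_tx.cds]

    def test_gene_spans_cover_all_transcripts(self, default_sim):
        study, _ = default_sim
        from junctionflux.annotations import merge_references

        sets = {}
        for source in study.config.sources:
            sets[source] = [
                TranscriptModel(
                    t.transcript_id, g.gene_id, source, study.chrom, g.strand,
                    [tuple(b) for b in t.blocks], t.biotype,
                )
                for g in study.genes
                for t in g.transcripts
                if source in t.sources
            ]
        ref = merge_references(sets)
        for gene in study.genes:
            lo, hi = gene.span
            genes_at = ref.genes_overlapping(study.chrom, lo, hi)
            assert (gene.gene_id, gene.strand) in genes_at


class TestCdsPhase:
    def test_phase_accumulates_coding_length(self):
        t = tx([(0, 100), (200, 300), (400, 500)])
        t.cds = [(30, 100), (200, 300), (400, 470)]
        index = AnnotationIndex([t])
        introns = extract_introns(t)
        assert index.phase_before_intron("g1", introns[0]) == 70 % 3
        assert index.phase_before_intron("g1", introns[1]) == 170 % 3

    def test_minus_strand_counts_from_transcription_start(self):
        t = tx([(0, 100), (200, 300), (400, 500)], strand="-")
        t.cds = [(30, 100), (200, 300), (400, 470)]
        index = AnnotationIndex([t])
        introns = extract_introns(t)
        # upstream of intron (300,400) in transcription = blocks right of 400
        assert index.phase_before_intron("g1", introns[1]) == 70 % 3
        assert index.phase_before_intron("g1", introns[0]) == 170 % 3

    def test_no_cds_returns_none(self):
        t = tx([(0, 100), (200, 300)], biotype="processed_transcript")
        index = AnnotationIndex([t])
        assert index.phase_before_intron("g1", extract_introns(t)[0]) is None
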