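"""Multi-source transcriptome annotations and the merged intron reference.

Transcript models are read from GTF/GFF3 (one file per annotation source,
e.g. RefSeq / Ensembl / GENCODE / CHESS-style sets), introns are extracted
per transcript, and the union of introns over all sources becomes a
:class:`MergedIntronReference` that records, for every intron, which sources
annotate it.  That reference is what junction discovery uses to decide
whether an observed alignment gap is an annotated intron or a previously
unannotated splicing event.

Coordinates are 0-based half-open over intronic bases throughout; GTF/GFF3
input (1-based inclusive exon records) is converted on read.  Intron
identity is the full tuple (chrom, strand, start, end): the same coordinates
on opposite strands are distinct introns because splice-site dinucleotides
are strand-dependent.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree


class MalformedAnnotationError(ValueError):
    """Raised for transcripts whose exon structure is inconsistent."""


@dataclass(frozen=True, order=True)
class Intron:
    """A spliced-out interval: ``start`` is the first intronic base, ``end``
    one past the last (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"intron end {self.end} <= start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def donor_pos(self) -> int:
        """Genomic boundary of the 5' splice site (exon|intron)."""
        return self.start if self.strand == "+" else self.end

    def acceptor_pos(self) -> int:
        """Genomic boundary of the 3' splice site (intron|exon)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    source: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "protein_coding"
    cds: list[tuple[int, int]] = field(default_factory=list)

    def validate(self) -> None:
        if not self.exons:
            raise MalformedAnnotationError(f"{self.transcript_id}: no exons")
        prev_end = None
        for start, end in self.exons:
            if end - start < 1:
                raise MalformedAnnotationError(
                    f"{self.transcript_id}: empty exon ({start},{end})"
                )
            if prev_end is not None and start < prev_end:
                raise MalformedAnnotationError(
                    f"{self.transcript_id}: exons overlap or are unsorted at {start}"
                )
            prev_end = end


def extract_introns(transcript: TranscriptModel) -> list[Intron]:
    """Introns between consecutive exons; empty for single-exon transcripts."""
    transcript.validate()
    return [
        Intron(transcript.chrom, left[1], right[0], transcript.strand)
        for left, right in zip(transcript.exons, transcript.exons[1:])
    ]


class MergedIntronReference:
    """Union of introns over annotation sources with per-source membership.

    ``entries`` maps each :class:`Intron` to the frozenset of source labels
    annotating it; ``gene_index`` holds one interval tree of gene spans per
    chromosome (a gene span is the min-start/max-end over all its transcripts,
    unioned across sources).
    """

    def __init__(
        self,
        entries: Mapping[Intron, frozenset[str]],
        gene_spans: Mapping[str, tuple[str, str, int, int]],
        sources: Iterable[str],
    ):
        self.entries: dict[Intron, frozenset[str]] = dict(
            sorted(entries.items(), key=lambda kv: (kv[0].chrom, kv[0].start, kv[0].end, kv[0].strand))
        )
        self.sources = tuple(sources)
        # gene_spans: gene_id -> (chrom, strand, start, end)
        self.gene_spans = dict(gene_spans)
        self.gene_index: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for gene_id, (chrom, strand, start, end) in sorted(self.gene_spans.items()):
            self.gene_index[chrom].addi(start, end, (gene_id, strand))
        # coordinate lookup ignoring strand, for resolving stranded status of
        # strand-unknown alignment gaps
        self._by_coords: dict[tuple[str, int, int], list[str]] = defaultdict(list)
        for intron in self.entries:
            self._by_coords[(intron.chrom, intron.start, intron.end)].append(intron.strand)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, intron: Intron) -> bool:
        return intron in self.entries

    def strands_at(self, chrom: str, start: int, end: int) -> list[str]:
        """Strands on which (chrom, start, end) is an annotated intron."""
        return self._by_coords.get((chrom, start, end), [])

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[tuple[str, str]]:
        """(gene_id, strand) of gene spans overlapping [start, end)."""
        tree = self.gene_index.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end))

    def in_gene_span(self, chrom: str, start: int, end: int) -> bool:
        return bool(self.genes_overlapping(chrom, start, end))

    def to_frame(self) -> pd.DataFrame:
        """BED-like table: chrom, start, end, strand, one 0/1 flag per source."""
        rows = []
        for intron, members in self.entries.items():
            row = {
                "chrom": intron.chrom,
                "start": intron.start,
                "end": intron.end,
                "strand": intron.strand,
            }
            for src in self.sources:
                row[src] = int(src in members)
            rows.append(row)
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", *self.sources])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def merge_references(
    annotation_sets: Mapping[str, list[TranscriptModel]],
) -> MergedIntronReference:
    """Build the merged cross-source intron reference.

    ``annotation_sets`` maps a source label to that source's transcripts.
    Raises on duplicate source labels (a mapping cannot express them, so this
    guards list-of-pairs callers) and on empty input.
    """
    if not annotation_sets:
        raise ValueError("at least one annotation source required")
    labels = list(annotation_sets)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate annotation source labels")

    entries: dict[Intron, set[str]] = defaultdict(set)
    span: dict[str, list] = {}
    for source, transcripts in annotation_sets.items():
        for tx in transcripts:
            for intron in extract_introns(tx):
                entries[intron].add(source)
            lo, hi = tx.exons[0][0], tx.exons[-1][1]
            rec = span.setdefault(tx.gene_id, [tx.chrom, tx.strand, lo, hi])
            rec[2] = min(rec[2], lo)
            rec[3] = max(rec[3], hi)
    frozen = {intron: frozenset(members) for intron, members in entries.items()}
    gene_spans = {g: tuple(v) for g, v in span.items()}
    return MergedIntronReference(frozen, gene_spans, labels)


def intersection_counts(ref: MergedIntronReference) -> dict[frozenset[str], int]:
    """Exclusive source-subset counts (UpSet-style).

    Each intron is counted once, under exactly the subset of sources that
    annotate it, so the counts sum to ``len(ref)``.  Per-source totals are the
    sums over subsets containing that source (:func:`per_source_totals`).
    """
    if len(ref) == 0:
        raise ValueError("empty reference")
    counts: dict[frozenset[str], int] = defaultdict(int)
    for members in ref.entries.values():
        counts[members] += 1
    return dict(counts)


def per_source_totals(ref: MergedIntronReference) -> dict[str, int]:
    totals = {src: 0 for src in ref.sources}
    for members in ref.entries.values():
        for src in members:
            totals[src] += 1
    return totals


# ---------------------------------------------------------------------------
# GTF / GFF3 input

_BIOTYPE_KEYS = ("transcript_biotype", "transcript_type", "biotype")


def read_transcripts(path, source: str, fmt: str | None = None) -> list[TranscriptModel]:
    """Read transcript models from a GTF or GFF3 file.

    Format is inferred from the file extension unless ``fmt`` is given.
    Attribute keys ``transcript_biotype``/``transcript_type``/``biotype`` are
    accepted as synonyms; coordinates are converted to 0-based half-open.
    """
    import pyranges as pr

    p = str(path)
    if fmt is None:
        fmt = "gff3" if p.endswith((".gff", ".gff3")) else "gtf"
    gr = pr.read_gff3(p) if fmt == "gff3" else pr.read_gtf(p)
    df = gr.df
    if df.empty:
        return []
    feat = df["Feature"].astype(str)
    keep = df[feat.isin(["exon", "CDS"])].copy()
    biotype_col = next((k for k in _BIOTYPE_KEYS if k in keep.columns), None)

    transcripts: dict[str, TranscriptModel] = {}
    for row in keep.itertuples(index=False):
        tid = getattr(row, "transcript_id", None)
        if tid is None or (isinstance(tid, float) and pd.isna(tid)):
            continue
        tx = transcripts.get(tid)
        if tx is None:
            biotype = getattr(row, biotype_col) if biotype_col else "protein_coding"
            if pd.isna(biotype):
                biotype = "protein_coding"
            tx = TranscriptModel(
                transcript_id=tid,
                gene_id=str(getattr(row, "gene_id", tid)),
                source=source,
                chrom=str(row.Chromosome),
                strand=str(row.Strand),
                exons=[],
                biotype=str(biotype),
            )
            transcripts[tid] = tx
        interval = (int(row.Start), int(row.End))
        if row.Feature == "exon":
            tx.exons.append(interval)
        else:
            tx.cds.append(interval)
    out = []
    for tx in transcripts.values():
        tx.exons.sort()
        tx.cds.sort()
        tx.validate()
        out.append(tx)
    out.sort(key=lambda t: (t.chrom, t.exons[0][0], t.transcript_id))
    return out


# ---------------------------------------------------------------------------
# Per-gene splice-site / exon index used by event classification

class AnnotationIndex:
    """Per-gene annotated splice sites, introns, exons and CDS phase.

    Built from the union of transcripts over all sources.  Donor/acceptor
    positions are genomic boundary coordinates (donor = intron start on '+',
    intron end on '-').
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.donors: dict[str, set[int]] = defaultdict(set)
        self.acceptors: dict[str, set[int]] = defaultdict(set)
        self.introns: dict[str, set[Intron]] = defaultdict(set)
        self.internal_exons: dict[str, set[tuple[int, int]]] = defaultdict(set)
        self.gene_strand: dict[str, str] = {}
        self.gene_chrom: dict[str, str] = {}
        self._tx_by_gene: dict[str, list[TranscriptModel]] = defaultdict(list)
        for tx in transcripts:
            g = tx.gene_id
            self.gene_strand[g] = tx.strand
            self.gene_chrom[g] = tx.chrom
            self._tx_by_gene[g].append(tx)
            for intron in extract_introns(tx):
                self.introns[g].add(intron)
                self.donors[g].add(intron.donor_pos())
                self.acceptors[g].add(intron.acceptor_pos())
            for exon in tx.exons[1:-1]:
                self.internal_exons[g].add(exon)

    def spans_internal_exon(self, gene_id: str, start: int, end: int) -> bool:
        """True if [start, end) fully contains an annotated internal exon."""
        return any(
            start <= es and ee <= end for es, ee in self.internal_exons.get(gene_id, ())
        )

    def phase_before_intron(self, gene_id: str, intron: Intron) -> int | None:
        """CDS phase entering an intron: coding nt upstream of the donor, mod 3.

        Uses the longest (by summed exon length) protein-coding transcript of
        the gene that contains this intron and has CDS records; ``None`` when
        no such transcript exists, in which case stop-codon scanning falls
        back to all three frames.
        """
        best = None
        for tx in self._tx_by_gene.get(gene_id, ()):
            if tx.biotype != "protein_coding" or not tx.cds:
                continue
            if intron not in set(extract_introns(tx)):
                continue
            size = sum(e - s for s, e in tx.exons)
            if best is None or size > best[0]:
                best = (size, tx)
        if best is None:
            return None
        tx = best[1]
        if tx.strand == "+":
            upstream = sum(
                min(e, intron.start) - s for s, e in tx.cds if s < intron.start
            )
        else:
            upstream = sum(
                e - max(s, intron.end) for s, e in tx.cds if e > intron.end
            )
        return upstream % 3
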