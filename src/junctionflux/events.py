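"""Classification of unannotated junctions into splicing event classes.

Every retained unannotated junction is assigned exactly one of five classes:

* ``skipped_exon``  — both splice sites annotated, novel pairing spanning at
  least one annotated internal exon;
* ``alt_3ss`` / ``alt_5ss`` — one annotated site combined with a novel
  acceptor / donor;
* ``new_cassette_exon`` — a pair of novel junctions inside one annotated
  intron that together define a new exon (two junctions, one event);
* ``new_intron``    — both sites novel.

Cassette exons then get a reading-frame consequence: a length not divisible
by 3 frameshifts the downstream CDS, and in-frame exons are scanned for stop
codons in the phase dictated by the upstream CDS.  Either consequence marks
the exon as a candidate poison exon (inclusion targets the transcript to
nonsense-mediated decay).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotations import AnnotationIndex, Intron
from .discovery import JunctionCall
from .genome import Genome

STOP_CODONS = ("TAA", "TAG", "TGA")

EVENT_CLASSES = (
    "skipped_exon",
    "alt_5ss",
    "alt_3ss",
    "new_intron",
    "new_cassette_exon",
)


@dataclass
class SpliceEvent:
    event_class: str
    junctions: list[JunctionCall]
    host_gene: str
    novel_sites: list[tuple[str, int]]  # (side "5'"|"3'", genomic boundary)


@dataclass
class CassetteExon:
    chrom: str
    strand: str
    start: int
    end: int
    flanking_junctions: tuple[JunctionCall, JunctionCall]  # (upstream, downstream)
    host_gene: str
    host_intron: Intron
    frame_status: str | None = None
    inframe_stops: list[int] = field(default_factory=list)
    poison: bool | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def classify_event(call: JunctionCall, index: AnnotationIndex) -> SpliceEvent:
    """Assign a single unannotated junction to its event class.

    Classification is relative to the annotated splice sites of the host
    gene(s): rules are applied in order (novel pairing of annotated sites →
    skipped exon; annotated donor + novel acceptor → alt 3'SS; novel donor +
    annotated acceptor → alt 5'SS; both novel → new intron).  Promotion of
    alt-SS junctions into cassette-exon halves happens separately in
    :func:`pair_cassette_exons`.
    """
    if call.status != "unannotated":
        raise ValueError("only unannotated junctions are classified")
    strand = call.strand
    if strand not in "+-":
        raise ValueError("strand must be resolved before classification")
    donor = call.intron.donor_pos()
    acceptor = call.intron.acceptor_pos()
    genes = [g for g in call.gene_ids if index.gene_strand.get(g) == strand]
    if not genes:
        genes = list(call.gene_ids)
    host = genes[0]
    donor_ann = any(donor in index.donors.get(g, ()) for g in genes)
    acceptor_ann = any(acceptor in index.acceptors.get(g, ()) for g in genes)
    if donor_ann and acceptor_ann:
        # novel pairing of two known sites; requires a fully spanned internal
        # exon, which holds for any genuine skip — kept as the class either way
        return SpliceEvent("skipped_exon", [call], host, [])
    if donor_ann:
        return SpliceEvent("alt_3ss", [call], host, [("3'", acceptor)])
    if acceptor_ann:
        return SpliceEvent("alt_5ss", [call], host, [("5'", donor)])
    return SpliceEvent("new_intron", [call], host, [("5'", donor), ("3'", acceptor)])


def _host_introns(call: JunctionCall, index: AnnotationIndex) -> list[tuple[Intron, str]]:
    """Annotated introns of the call's gene(s) for which this junction is a
    cassette-exon half: shares exactly one boundary and is interior otherwise.
    Returns (host intron, role) with role 'start' (shares host start) or
    'end' (shares host end)."""
    out = []
    for g in call.gene_ids:
        for intron in index.introns.get(g, ()):
            if intron.strand != call.strand or intron.chrom != call.chrom:
                continue
            if call.intron.start == intron.start and call.intron.end < intron.end:
                out.append((intron, "start"))
            elif call.intron.end == intron.end and call.intron.start > intron.start:
                out.append((intron, "end"))
    return out


def pair_cassette_exons(
    events: list[SpliceEvent], index: AnnotationIndex
) -> tuple[list[CassetteExon], list[SpliceEvent]]:
    """Promote pairable alt-SS junctions into new cassette exons.

    Within one annotated (host) intron, a junction re-using the host's 5'
    site with a novel 3' site at ``a`` pairs with a junction using a novel 5'
    site at ``b`` and the host's 3' site, provided ``a < b`` genomically; the
    new exon is [a, b).  Each junction joins at most one exon; ambiguity is
    resolved by shortest exon first, ties by higher summed read count
    (shortest-first is also maximum-cardinality under this interval order).
    Returns the exons plus the events list with paired junctions replaced by
    one ``new_cassette_exon`` event per exon.
    """
    candidates = [
        ev for ev in events if ev.event_class in ("alt_3ss", "alt_5ss")
    ]
    # feasible pairs per host intron
    feasible = []
    by_role: dict[tuple[Intron, str], list[SpliceEvent]] = {}
    for ev in candidates:
        for intron, role in _host_introns(ev.junctions[0], index):
            by_role.setdefault((intron, role), []).append(ev)
    for (intron, role), evs in sorted(
        by_role.items(), key=lambda kv: (kv[0][0], kv[0][1])
    ):
        if role != "start":
            continue
        partners = by_role.get((intron, "end"), [])
        for e1 in evs:
            a = e1.junctions[0].intron.end
            for e2 in partners:
                b = e2.junctions[0].intron.start
                if a < b:
                    count = e1.junctions[0].total_count() + e2.junctions[0].total_count()
                    feasible.append((b - a, -count, a, b, intron, e1, e2))
    feasible.sort(key=lambda t: t[:4])
    used: set[int] = set()
    exons: list[CassetteExon] = []
    promoted: dict[int, CassetteExon] = {}
    for length, _negcount, a, b, host_intron, e1, e2 in feasible:
        if id(e1) in used or id(e2) in used:
            continue
        used.update((id(e1), id(e2)))
        j_start, j_end = e1.junctions[0], e2.junctions[0]
        strand = host_intron.strand
        upstream, downstream = (j_start, j_end) if strand == "+" else (j_end, j_start)
        exon = CassetteExon(
            chrom=host_intron.chrom,
            strand=strand,
            start=a,
            end=b,
            flanking_junctions=(upstream, downstream),
            host_gene=e1.host_gene,
            host_intron=host_intron,
        )
        exons.append(exon)
        promoted[id(e1)] = exon
        promoted[id(e2)] = exon
    out_events: list[SpliceEvent] = []
    emitted: set[int] = set()
    for ev in events:
        exon = promoted.get(id(ev))
        if exon is None:
            out_events.append(ev)
        elif id(exon) not in emitted:
            emitted.add(id(exon))
            novel = [
                ("3'" if exon.strand == "+" else "5'", exon.start),
                ("5'" if exon.strand == "+" else "3'", exon.end),
            ]
            out_events.append(
                SpliceEvent(
                    "new_cassette_exon",
                    list(exon.flanking_junctions),
                    exon.host_gene,
                    novel,
                )
            )
    return exons, out_events


def frame_status(length: int) -> str:
    """'frameshifting' unless the exon length is a multiple of 3."""
    if length < 1:
        raise ValueError("exon length must be >= 1")
    return "in_frame" if length % 3 == 0 else "frameshifting"


def find_inframe_stops(seq: str, upstream_cds_phase: int) -> list[int]:
    """Stop-codon offsets in an exon sequence given the upstream CDS phase.

    ``upstream_cds_phase`` is the number of nucleotides of the current codon
    already consumed upstream, so codon reading starts at offset
    ``(3 - phase) % 3`` within the exon (transcription orientation).
    """
    if upstream_cds_phase not in (0, 1, 2):
        raise ValueError("phase must be 0, 1 or 2")
    seq = seq.upper()
    offset = (3 - upstream_cds_phase) % 3
    return [
        i for i in range(offset, len(seq) - 2, 3) if seq[i : i + 3] in STOP_CODONS
    ]


def scan_all_frames(seq: str) -> dict[int, list[int]]:
    """Stop positions per phase, for exons without an annotated upstream CDS."""
    return {phase: find_inframe_stops(seq, phase) for phase in (0, 1, 2)}


def poison_candidate(exon: CassetteExon) -> bool:
    """Poison-exon flag: frameshifting, or in-frame with >= 1 in-frame stop."""
    if exon.frame_status is None:
        raise ValueError("frame status not yet computed")
    return exon.frame_status == "frameshifting" or bool(exon.inframe_stops)


def annotate_cassette_exons(
    exons: list[CassetteExon], index: AnnotationIndex, genome: Genome
) -> None:
    """Fill frame status, in-frame stops and the poison flag in place.

    The scanning phase comes from the annotated CDS of the longest
    protein-coding transcript containing the host intron; without one, all
    three frames are scanned and an exon counts as stop-containing only if
    every frame contains a stop (conservative for the poison call).
    """
    for exon in exons:
        exon.frame_status = frame_status(exon.length)
        seq = genome.fetch(exon.chrom, exon.start, exon.end, exon.strand)
        phase = index.phase_before_intron(exon.host_gene, exon.host_intron)
        if phase is not None:
            exon.inframe_stops = find_inframe_stops(seq, phase)
        else:
            per_frame = scan_all_frames(seq)
            exon.inframe_stops = (
                per_frame[0] if all(per_frame.values()) else []
            )
        exon.poison = poison_candidate(exon)


def classify_all(
    calls: list[JunctionCall],
    index: AnnotationIndex,
    genome: Genome | None = None,
) -> tuple[list[SpliceEvent], list[CassetteExon]]:
    """Classify all retained unannotated calls and pair cassette exons."""
    events = [
        classify_event(c, index) for c in calls if c.status == "unannotated"
    ]
    exons, events = pair_cassette_exons(events, index)
    if genome is not None:
        annotate_cassette_exons(exons, index, genome)
    return events, exons


def events_to_frame(events: list[SpliceEvent], exons: list[CassetteExon]):
    """One row per event: class, coordinates, per-library counts, frame/poison."""
    import pandas as pd

    exon_by_junction = {}
    for exon in exons:
        for j in exon.flanking_junctions:
            exon_by_junction[id(j)] = exon
    rows = []
    for ev in events:
        j0 = ev.junctions[0]
        row = {
            "event_class": ev.event_class,
            "chrom": j0.chrom,
            "strand": j0.strand,
            "host_gene": ev.host_gene,
            "junction_starts": ",".join(str(j.intron.start) for j in ev.junctions),
            "junction_ends": ",".join(str(j.intron.end) for j in ev.junctions),
            "total_count": sum(j.total_count() for j in ev.junctions),
        }
        exon = exon_by_junction.get(id(j0))
        if ev.event_class == "new_cassette_exon" and exon is not None:
            row.update(
                exon_start=exon.start,
                exon_end=exon.end,
                exon_length=exon.length,
                frame_status=exon.frame_status,
                n_inframe_stops=len(exon.inframe_stops),
                poison=exon.poison,
            )
        rows.append(row)
    return pd.DataFrame(rows)
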