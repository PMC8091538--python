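"""Exon-junction discovery from gapped read alignments.

Junction candidates are the N (skipped-region) operations of SAM/BAM CIGAR
strings.  Read-level filters (mapping quality, duplicate flag, anchoring
overhang length and exact-match identity next to the gap) produce
:class:`JunctionObservation` records; these are aggregated per intron and
per (library, replicate) and passed through the junction-level cascade —
gene overlap, detectability in all replicates of a library type, mean read
count, and splice-site dinucleotide consensus — to yield annotated and
unannotated :class:`JunctionCall` objects.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam

from .annotations import Intron, MergedIntronReference
from .genome import Genome, splice_dinucleotides

_REF_CONSUMING = {0, 2, 3, 7, 8}  # M D N = X
_ALIGNED_OPS = {0, 7, 8}  # M = X


class ConfigurationError(RuntimeError):
    pass


@dataclass
class FilterConfig:
    """Thresholds of the junction filter cascade.

    ``max_mismatches_per_read`` is advisory: the upstream aligner is expected
    to have enforced it, but reads exceeding it are dropped here as well when
    mismatch counts are computable.
    """

    min_overhang: int = 15
    min_match_fraction: float = 0.90
    min_mapq: int = 5
    min_mean_count: float = 2.0
    require_all_replicates: bool = True
    allowed_dinucleotides: frozenset = frozenset({("GT", "AG"), ("AT", "AC")})
    max_mismatches_per_read: int = 3

    def __post_init__(self):
        if self.min_overhang < 0 or self.min_mapq < 0 or self.min_mean_count < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0.0 <= self.min_match_fraction <= 1.0:
            raise ValueError("min_match_fraction must be in [0, 1]")


@dataclass
class JunctionObservation:
    """One CIGAR N gap in one read."""

    chrom: str
    start: int  # first intronic base
    end: int  # one past last intronic base
    left_overhang: int
    right_overhang: int
    left_matches: int  # exact matches in the window adjacent to the gap
    right_matches: int
    read_id: str
    library: str
    replicate: str


@dataclass
class JunctionCall:
    intron: Intron
    status: str  # "annotated" | "unannotated"
    counts: dict[tuple[str, str], int]
    dinucleotides: tuple[str, str]
    gene_ids: tuple[str, ...]
    detected_libraries: tuple[str, ...]

    @property
    def chrom(self) -> str:
        return self.intron.chrom

    @property
    def strand(self) -> str:
        return self.intron.strand

    def count_in(self, library: str, replicate: str) -> int:
        return self.counts.get((library, replicate), 0)

    def total_count(self, library: str | None = None) -> int:
        return sum(
            n for (lib, _), n in self.counts.items() if library is None or lib == library
        )


@dataclass
class LibraryProfile:
    """Replicate set of one library type with post-filter mapped-read totals."""

    library_type: str
    replicates: list[str]
    total_mapped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for rep, total in self.total_mapped.items():
            if total <= 0:
                raise ValueError(f"total_mapped must be > 0 ({self.library_type}/{rep})")


@dataclass
class ParseStats:
    reads_seen: int = 0
    reads_kept: int = 0
    reads_skipped_flags: int = 0  # unmapped / duplicate / low MAPQ
    reads_skipped_mismatches: int = 0
    parse_failures: int = 0


def _mismatch_positions(read: pysam.AlignedSegment, genome: Genome | None) -> set[int]:
    """Reference positions of substitution mismatches in an aligned read.

    Prefers the MD tag (via pysam's aligned-pairs machinery); falls back to
    comparing read sequence against the genome.  Deletions are handled
    separately from the CIGAR.
    """
    if read.has_tag("MD"):
        mism = set()
        for qpos, rpos, base in read.get_aligned_pairs(matches_only=True, with_seq=True):
            if base.islower():
                mism.add(rpos)
        return mism
    if genome is None:
        raise ConfigurationError(
            "MD tag absent and no genome supplied; cannot evaluate sequence identity"
        )
    mism = set()
    seq = read.query_sequence
    rpos = read.reference_start
    qpos = 0
    for op, ln in read.cigartuples:
        if op in _ALIGNED_OPS:
            ref_seq = genome.fetch(read.reference_name, rpos, rpos + ln)
            for i in range(ln):
                if seq[qpos + i].upper() != ref_seq[i]:
                    mism.add(rpos + i)
            rpos += ln
            qpos += ln
        elif op == 1 or op == 4:  # I, S
            qpos += ln
        elif op in (2, 3):  # D, N
            rpos += ln
    return mism


def observations_from_read(
    read: pysam.AlignedSegment,
    config: FilterConfig,
    genome: Genome | None = None,
    library: str = "lib",
    replicate: str = "rep",
) -> list[JunctionObservation]:
    """All junction observations (one per CIGAR N operation) in one read.

    Overhangs are the reference-consuming aligned lengths flanking the gap,
    bounded by adjacent N operations; soft-clipped bases never count.  Match
    counts are evaluated over the ``min_overhang``-nt reference window
    adjacent to the gap: a position matches unless it is deleted in the read
    or a substitution mismatch.
    """
    cig = read.cigartuples
    if cig is None or not any(op == 3 for op, _ in cig):
        return []
    # segments of reference intervals between N gaps
    segments: list[list[tuple[int, int, int]]] = [[]]  # (op, ref_start, ref_len)
    gaps: list[tuple[int, int]] = []
    rpos = read.reference_start
    deleted: set[int] = set()
    for op, ln in cig:
        if op == 3:
            gaps.append((rpos, rpos + ln))
            segments.append([])
            rpos += ln
        elif op in _REF_CONSUMING:
            segments[-1].append((op, rpos, ln))
            if op == 2:
                deleted.update(range(rpos, rpos + ln))
            rpos += ln
    mism = _mismatch_positions(read, genome)

    def window_matches(ref_positions: Iterable[int]) -> int:
        return sum(1 for p in ref_positions if p not in deleted and p not in mism)

    w = config.min_overhang
    out = []
    for i, (gs, ge) in enumerate(gaps):
        left, right = segments[i], segments[i + 1]
        left_oh = sum(ln for op, _, ln in left)
        right_oh = sum(ln for op, _, ln in right)
        left_lo = left[0][1] if left else gs
        right_hi = right[-1][1] + right[-1][2] if right else ge
        lwin = range(max(left_lo, gs - w), gs)
        rwin = range(ge, min(right_hi, ge + w))
        out.append(
            JunctionObservation(
                chrom=read.reference_name,
                start=gs,
                end=ge,
                left_overhang=left_oh,
                right_overhang=right_oh,
                left_matches=window_matches(lwin),
                right_matches=window_matches(rwin),
                read_id=read.query_name,
                library=library,
                replicate=replicate,
            )
        )
    return out


def parse_gapped_reads(
    alignments: Iterable[pysam.AlignedSegment],
    config: FilterConfig,
    genome: Genome | None = None,
    library: str = "lib",
    replicate: str = "rep",
    stats: ParseStats | None = None,
) -> Iterator[JunctionObservation]:
    """Stream junction observations from alignments, applying read-level filters.

    Unmapped, duplicate-flagged (0x400) and low-MAPQ records are discarded
    before CIGAR parsing; reads whose total substitution count exceeds
    ``max_mismatches_per_read`` are dropped when mismatches are computable.
    """
    for read in alignments:
        if stats:
            stats.reads_seen += 1
        if read.is_unmapped or read.is_duplicate or read.mapping_quality < config.min_mapq:
            if stats:
                stats.reads_skipped_flags += 1
            continue
        if read.reference_name is None:
            if stats:
                stats.parse_failures += 1
            continue
        try:
            obs = observations_from_read(read, config, genome, library, replicate)
        except ConfigurationError:
            raise
        except Exception as exc:  # malformed CIGAR/MD
            warnings.warn(f"skipping read {read.query_name}: {exc}")
            if stats:
                stats.parse_failures += 1
            continue
        if stats:
            stats.reads_kept += 1
        yield from obs


def overhang_and_identity_filter(obs: JunctionObservation, config: FilterConfig) -> bool:
    """Anchor filter: >= min_overhang nt on both sides of the gap, with
    >= min_match_fraction exact matches inside each flanking window."""
    w = config.min_overhang
    if obs.left_overhang < w or obs.right_overhang < w:
        return False
    if w == 0:
        return True
    return (
        obs.left_matches / w >= config.min_match_fraction
        and obs.right_matches / w >= config.min_match_fraction
    )


def aggregate_junctions(
    observations: Iterable[JunctionObservation], config: FilterConfig
) -> dict[tuple[str, int, int], dict[tuple[str, str], int]]:
    """Per-intron, per-(library, replicate) read counts over observations
    passing the anchor filter."""
    agg: dict[tuple[str, int, int], dict[tuple[str, str], int]] = defaultdict(
        lambda: defaultdict(int)
    )
    for obs in observations:
        if overhang_and_identity_filter(obs, config):
            agg[(obs.chrom, obs.start, obs.end)][(obs.library, obs.replicate)] += 1
    return {k: dict(v) for k, v in agg.items()}


def _detected_libraries(
    counts: dict[tuple[str, str], int],
    libraries: list[LibraryProfile],
    config: FilterConfig,
) -> tuple[str, ...]:
    """Library types in which the junction passes the detectability filters:
    >= 1 read in every replicate (when required) and mean count >= threshold."""
    detected = []
    for lib in libraries:
        per_rep = [counts.get((lib.library_type, rep), 0) for rep in lib.replicates]
        if config.require_all_replicates and any(c < 1 for c in per_rep):
            continue
        if sum(per_rep) / len(per_rep) >= config.min_mean_count:
            detected.append(lib.library_type)
    return tuple(detected)


def resolve_strand(
    chrom: str,
    start: int,
    end: int,
    ref: MergedIntronReference,
    genome: Genome,
    config: FilterConfig,
) -> tuple[str | None, bool]:
    """Strand of a strand-unknown junction: unique overlapping gene wins,
    else the strand whose dinucleotides hit an allowed pair; (None, True)
    when ambiguous (both strands consensus under conflicting gene context)."""
    genes = ref.genes_overlapping(chrom, start, end)
    strands = sorted({s for _, s in genes})
    if len(strands) == 1:
        return strands[0], False
    matches = []
    for strand in "+-":
        dinuc = splice_dinucleotides(Intron(chrom, start, end, strand), strand, genome)
        if dinuc in config.allowed_dinucleotides:
            matches.append(strand)
    if len(matches) == 1:
        return matches[0], False
    return None, True


def call_junctions(
    observations: Iterable[JunctionObservation],
    ref: MergedIntronReference,
    genome: Genome,
    libraries: list[LibraryProfile],
    config: FilterConfig,
) -> list[JunctionCall]:
    """Apply the full junction-level cascade and emit retained calls.

    Annotated junctions (exact coordinate match against the merged intron
    reference) pass through the detectability and mean-count filters only;
    unannotated candidates must additionally fall inside an annotated gene
    span, resolve to a unique strand, and carry GT-AG/AT-AC (or configured)
    splice-site dinucleotides.
    """
    if not libraries or any(not lib.replicates for lib in libraries):
        raise ValueError("at least one library with at least one replicate required")
    agg = aggregate_junctions(observations, config)
    calls: list[JunctionCall] = []
    for (chrom, start, end) in sorted(agg):
        counts = agg[(chrom, start, end)]
        detected = _detected_libraries(counts, libraries, config)
        if not detected:
            continue
        ann_strands = ref.strands_at(chrom, start, end)
        genes = ref.genes_overlapping(chrom, start, end)
        if ann_strands:
            if len(ann_strands) == 1:
                strand = ann_strands[0]
            else:
                gene_strands = sorted({s for _, s in genes})
                strand = gene_strands[0] if len(gene_strands) == 1 else "+"
            intron = Intron(chrom, start, end, strand)
            dinuc = splice_dinucleotides(intron, strand, genome) if end - start >= 4 else ("", "")
            calls.append(
                JunctionCall(
                    intron=intron,
                    status="annotated",
                    counts=counts,
                    dinucleotides=dinuc,
                    gene_ids=tuple(g for g, _ in genes),
                    detected_libraries=detected,
                )
            )
            continue
        if not genes:
            continue
        strand, ambiguous = resolve_strand(chrom, start, end, ref, genome, config)
        if ambiguous or strand is None:
            continue
        intron = Intron(chrom, start, end, strand)
        dinuc = splice_dinucleotides(intron, strand, genome)
        if dinuc not in config.allowed_dinucleotides:
            continue
        gene_ids = tuple(g for g, s in genes if s == strand) or tuple(g for g, _ in genes)
        calls.append(
            JunctionCall(
                intron=intron,
                status="unannotated",
                counts=counts,
                dinucleotides=dinuc,
                gene_ids=gene_ids,
                detected_libraries=detected,
            )
        )
    return calls


def read_alignment_file(
    path,
    config: FilterConfig,
    genome: Genome | None = None,
    library: str = "lib",
    replicate: str = "rep",
    stats: ParseStats | None = None,
) -> list[JunctionObservation]:
    """Parse a SAM/BAM file into junction observations."""
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        return list(parse_gapped_reads(fh, config, genome, library, replicate, stats))


def calls_to_frame(calls: list[JunctionCall], libraries: list[LibraryProfile]):
    """Junction table: one row per call, one count column per (library, replicate)."""
    import pandas as pd

    rows = []
    for call in calls:
        row = {
            "chrom": call.chrom,
            "start": call.intron.start,
            "end": call.intron.end,
            "strand": call.strand,
            "status": call.status,
            "donor_dinuc": call.dinucleotides[0],
            "acceptor_dinuc": call.dinucleotides[1],
            "gene_ids": ",".join(call.gene_ids),
            "detected_in": ",".join(call.detected_libraries),
        }
        for lib in libraries:
            for rep in lib.replicates:
                row[f"count_{lib.library_type}_{rep}"] = call.count_in(lib.library_type, rep)
        rows.append(row)
    return pd.DataFrame(rows)
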