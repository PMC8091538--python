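"""Self-contained synthetic study generator.

Builds, from a single seed, everything the pipeline consumes: a genome with
consensus-flavored GT-AG splice sites, multi-source transcript annotations
with controlled membership differences, a basewise conservation track in
which planted regulatory elements score high and noise sites low, and
aligned single-end reads (SAM, with CIGAR M/N blocks and MD tags) for two
library types — an "EJC" type enriched for NMD/poison-exon junctions and an
"RNASEQ" type depleted of them — with three replicates each.

Planted ground truth covers all five unannotated event classes (alternative
5'/3' splice site, exon skipping, new intron, new cassette exon), an
annotated NMD isoform, and a set of deliberate filter probes: a
non-consensus (GC-AG) junction, a junction below the mean-count threshold,
a junction missing from one replicate, and a junction supported only by
short-overhang reads.  Same seed, byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conservation import window_coords
from .genome import reverse_complement

STOP = "TAA"


@dataclass(frozen=True)
class LibrarySpec:
    """One library type: replicate count, per-replicate depth and the
    probability that a read from an event-carrying gene samples the
    alternative (NMD/novel) isoform."""

    name: str
    replicates: int = 3
    depth: int = 50_000
    alt_inclusion: float = 0.5


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 7)
    exon_length: tuple[int, int] = (120, 240)
    intron_length: tuple[int, int] = (300, 800)
    intergenic: tuple[int, int] = (400, 800)
    read_length: int = 100
    error_rate: float = 0.001
    chrom: str = "chrS"
    sources: tuple[str, ...] = (
        "refseq_like",
        "ensembl_like",
        "gencode_like",
        "chess_like",
    )
    libraries: tuple[LibrarySpec, ...] = (
        LibrarySpec("EJC", 3, 50_000, 0.5),
        LibrarySpec("RNASEQ", 3, 50_000, 0.05),
    )
    conserved_value: float = 2.0
    annotated_site_value: float = 1.5
    background_sd: float = 0.15
    track_chunk: int = 10
    low_mapq_fraction: float = 0.02
    duplicate_fraction: float = 0.01

    def __post_init__(self):
        if self.n_genes < 16 + len(self.sources):
            raise ValueError(
                "n_genes too small for the planted event and source-membership layout"
            )
        if any(lib.depth < 0 for lib in self.libraries):
            raise ValueError("depth must be >= 0")


@dataclass
class SimTranscript:
    transcript_id: str
    gene_id: str
    biotype: str
    blocks: list[tuple[int, int]]  # genomic ascending
    sources: tuple[str, ...]  # empty => unannotated isoform
    cds: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SimGene:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    transcripts: list[SimTranscript] = field(default_factory=list)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])
        ]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class PlantedTruth:
    """Ground-truth record for one planted junction."""

    chrom: str
    start: int
    end: int
    strand: str
    gene: str
    category: str  # annotated | planted | probe
    event_class: str
    conserved: bool
    expect_called: bool
    filter_reason: str = ""
    inclusion: dict[str, float] = field(default_factory=dict)


@dataclass
class TruthExon:
    gene: str
    chrom: str
    strand: str
    start: int
    end: int
    frame_status: str
    n_stops: int
    poison: bool
    conserved: bool
    annotated: bool


class SyntheticStudy:
    """In-memory synthetic study; see :func:`make_genome_and_annotation`."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.genes: list[SimGene] = []
        self.truth: list[PlantedTruth] = []
        self.truth_exons: list[TruthExon] = []
        self.seq: np.ndarray | None = None  # dtype U1
        # per-gene alternative isoform (blocks) driven by library alt_inclusion
        self.alt_isoform: dict[str, SimTranscript] = {}
        # probe junctions emitted as fixed extra reads: (u, v, counts, overhangs)
        self.probes: list[dict] = []
        self.conserved_windows: list[tuple[int, int]] = []
        self.annotated_site_windows: list[tuple[int, int]] = []

    # -- convenience -------------------------------------------------------
    @property
    def chrom(self) -> str:
        return self.config.chrom

    def genome_string(self) -> str:
        return "".join(self.seq)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            row = {
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "strand": t.strand,
                "gene": t.gene,
                "category": t.category,
                "event_class": t.event_class,
                "conserved": t.conserved,
                "expect_called": t.expect_called,
                "filter_reason": t.filter_reason,
            }
            for lib in self.config.libraries:
                row[f"inclusion_{lib.name}"] = t.inclusion.get(lib.name, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)

    def truth_exon_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.truth_exons])


# ---------------------------------------------------------------------------
# Sequence planting helpers


def _write_oriented(seq: np.ndarray, lo: int, motif: str, strand: str) -> None:
    s = motif if strand == "+" else reverse_complement(motif)
    seq[lo : lo + len(s)] = list(s)


def _plant_donor_window(seq, boundary, strand, rng) -> None:
    """Consensus-biased 9-mer: 3 exonic + GT + 4 intronic."""
    exonic = "".join(rng.choice(list("CA"), 2)) + "G"
    tail = "".join(
        rng.choice(list(opts), p=probs)
        for opts, probs in (("AG", (0.7, 0.3)), ("A", (1.0,)), ("GA", (0.8, 0.2)), ("TC", (0.9, 0.1)))
    )
    lo, _ = window_coords("5'", boundary, strand)
    _write_oriented(seq, lo, exonic + "GT" + tail, strand)


def _plant_acceptor_window(seq, boundary, strand, rng) -> None:
    """Consensus-biased 23-mer: 18 polypyrimidine + AG + 3 exonic."""
    polyy = "".join(rng.choice(list("TC"), 18, p=[0.7, 0.3]))
    exonic = "G" + "".join(rng.choice(list("ACGT"), 2))
    lo, _ = window_coords("3'", boundary, strand)
    _write_oriented(seq, lo, polyy + "AG" + exonic, strand)


def _plant_donor_dinuc(seq, boundary, strand, dinuc="GT") -> None:
    lo = boundary if strand == "+" else boundary - 2
    _write_oriented(seq, lo, dinuc, strand)


def _plant_acceptor_dinuc(seq, boundary, strand, dinuc="AG") -> None:
    lo = boundary - 2 if strand == "+" else boundary
    _write_oriented(seq, lo, dinuc, strand)


def _transcription_offset_to_genomic(start: int, end: int, strand: str, offset: int, n: int) -> int:
    """Genomic start of an n-mer at transcription offset within [start, end)."""
    if strand == "+":
        return start + offset
    return end - offset - n


def _cds_phase_before(tx: SimTranscript, intron: tuple[int, int], strand: str) -> int:
    if strand == "+":
        return sum(min(e, intron[0]) - s for s, e in tx.cds if s < intron[0]) % 3
    return sum(e - max(s, intron[1]) for s, e in tx.cds if e > intron[1]) % 3


# ---------------------------------------------------------------------------
# Genome + annotation construction


def make_genome_and_annotation(config: SimulationConfig) -> SyntheticStudy:
    """Build the synthetic genome, the per-source transcript sets and the
    planted ground truth (no reads, no track yet)."""
    rng = np.random.default_rng([config.seed, 1])
    study = SyntheticStudy(config)
    seq_parts: list[np.ndarray] = []
    cursor = 60  # leading pad so windows never run off the contig start
    gene_layouts: list[SimGene] = []
    for gi in range(config.n_genes):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "+" if gi % 2 == 0 else "-"
        exons = []
        pos = cursor
        for ei in range(n_ex):
            elen = int(rng.integers(*config.exon_length))
            exons.append((pos, pos + elen))
            pos += elen
            if ei < n_ex - 1:
                pos += int(rng.integers(*config.intron_length))
        gene_layouts.append(SimGene(f"gene{gi:03d}", config.chrom, strand, exons))
        cursor = pos + int(rng.integers(*config.intergenic))
    total_len = cursor + 60
    seq = rng.choice(list("ACGT"), size=total_len)
    study.seq = seq
    study.genes = gene_layouts

    # annotated transcripts: canonical protein-coding in all sources, CDS
    # trimmed 30 nt from each transcript end
    for gene in study.genes:
        tx = SimTranscript(
            f"{gene.gene_id}.t1",
            gene.gene_id,
            "protein_coding",
            list(gene.exons),
            tuple(config.sources),
        )
        tx.cds = _trim_blocks(gene.exons, 30, 30, gene.strand)
        gene.transcripts.append(tx)
        for intron in gene.introns:
            donor = intron[0] if gene.strand == "+" else intron[1]
            acceptor = intron[1] if gene.strand == "+" else intron[0]
            _plant_donor_window(seq, donor, gene.strand, rng)
            _plant_acceptor_window(seq, acceptor, gene.strand, rng)
            study.annotated_site_windows.append(window_coords("5'", donor, gene.strand))
            study.annotated_site_windows.append(window_coords("3'", acceptor, gene.strand))
            study.truth.append(
                PlantedTruth(
                    config.chrom, intron[0], intron[1], gene.strand, gene.gene_id,
                    "annotated", "annotated", False, True,
                    inclusion={lib.name: 1.0 for lib in config.libraries},
                )
            )

    _plant_events(study, rng)
    _plant_probes(study, rng)
    _plant_source_membership(study, rng)
    return study


def _trim_blocks(blocks, trim5: int, trim3: int, strand: str):
    """Trim nt from the transcription 5'/3' ends of a block chain."""
    lo, hi = (trim5, trim3) if strand == "+" else (trim3, trim5)
    out = []
    skip = lo
    for s, e in blocks:
        s2 = s + min(skip, e - s)
        skip -= s2 - s
        if s2 < e:
            out.append([s2, e])
    drop = hi
    for i in range(len(out) - 1, -1, -1):
        s, e = out[i]
        cut = min(drop, e - s)
        out[i][1] = e - cut
        drop -= cut
        if out[i][1] <= out[i][0]:
            out.pop(i)
    return [tuple(b) for b in out]


def _alt_isoform(study: SyntheticStudy, gene: SimGene, blocks, event_class: str):
    tx = SimTranscript(
        f"{gene.gene_id}.alt", gene.gene_id, f"unannotated_{event_class}", blocks, ()
    )
    study.alt_isoform[gene.gene_id] = tx
    gene.transcripts.append(tx)
    return tx


def _inclusion_map(config: SimulationConfig) -> dict[str, float]:
    return {lib.name: lib.alt_inclusion for lib in config.libraries}


def _plant_events(study: SyntheticStudy, rng) -> None:
    """Plant one event per class (plus extra NAGNAG positions and an
    annotated NMD isoform) on dedicated genes."""
    cfg = study.config
    seq = study.seq
    genes = study.genes
    chrom = cfg.chrom
    incl = _inclusion_map(cfg)

    def record(gene, start, end, event_class, conserved, windows=()):
        study.truth.append(
            PlantedTruth(
                chrom, start, end, gene.strand, gene.gene_id, "planted",
                event_class, conserved, True, inclusion=dict(incl),
            )
        )
        for w in windows:
            study.conserved_windows.append(w) if conserved else None

    # gene 0: exon skipping -----------------------------------------------
    g = genes[0]
    k = len(g.introns) // 2
    start, end = g.introns[k][0], g.introns[k + 1][1]
    blocks = [e for i, e in enumerate(g.exons) if i != k + 1]
    _alt_isoform(study, g, blocks, "skipped_exon")
    record(g, start, end, "skipped_exon", False)

    # gene 1: alternative 5'SS at +5 (conserved) ---------------------------
    g = genes[1]
    k = len(g.introns) // 2
    intron = g.introns[k]
    if g.strand == "+":
        novel = (intron[0] + 5, intron[1])
        donor_boundary = novel[0]
        blocks = _replace_intron(g.exons, k, novel)
    else:
        novel = (intron[0], intron[1] - 5)
        donor_boundary = novel[1]
        blocks = _replace_intron(g.exons, k, novel)
    _plant_donor_dinuc(seq, donor_boundary, g.strand)
    _alt_isoform(study, g, blocks, "alt_5ss")
    record(
        g, novel[0], novel[1], "alt_5ss", True,
        windows=[window_coords("5'", donor_boundary, g.strand)],
    )

    # genes 2-4: alternative 3'SS at +3 / +4 / +5; their acceptor windows
    # overlap the annotated acceptor's conserved footprint, so all three
    # score as conserved (exonic new intron + probe junctions supply the
    # background-level noise sites)
    for gi, (dist, conserved) in zip((2, 3, 4), ((3, True), (4, True), (5, True))):
        g = genes[gi]
        k = len(g.introns) // 2
        intron = g.introns[k]
        if g.strand == "+":
            novel = (intron[0], intron[1] + dist)
            acceptor_boundary = novel[1]
        else:
            novel = (intron[0] - dist, intron[1])
            acceptor_boundary = novel[0]
        _plant_acceptor_dinuc(seq, acceptor_boundary, g.strand)
        blocks = _replace_intron(g.exons, k, novel)
        _alt_isoform(study, g, blocks, "alt_3ss")
        record(
            g, novel[0], novel[1], "alt_3ss", conserved,
            windows=[window_coords("3'", acceptor_boundary, g.strand)],
        )

    # gene 5: new intron inside an exon (noise-like, not conserved) --------
    g = genes[5]
    m = len(g.exons) // 2
    es, _ee = g.exons[m]
    u, v = es + 40, es + 40 + 60
    donor_b = u if g.strand == "+" else v
    accept_b = v if g.strand == "+" else u
    _plant_donor_window(seq, donor_b, g.strand, rng)
    _plant_acceptor_window(seq, accept_b, g.strand, rng)
    blocks = _split_exon(g.exons, m, u, v)
    _alt_isoform(study, g, blocks, "new_intron")
    record(g, u, v, "new_intron", False)

    # genes 6-8: new cassette exons ----------------------------------------
    cassette_plan = [
        (6, 94, "stops_na", True),   # frameshifting
        (7, 69, "with_stops", True), # in-frame, 3 planted stops
        (8, 72, "no_stops", True),   # in-frame, scrubbed of stops
    ]
    for gi, length, stop_mode, conserved in cassette_plan:
        _plant_cassette(study, genes[gi], length, stop_mode, conserved, rng, annotated=False)

    # gene 9: annotated NMD isoform with an annotated poison exon ----------
    _plant_cassette(study, genes[9], 81, "with_stops", True, rng, annotated=True)


def _replace_intron(exons, k, novel):
    """Exon chain with intron k replaced by the interval ``novel``."""
    blocks = [list(e) for e in exons]
    blocks[k][1] = novel[0]
    blocks[k + 1][0] = novel[1]
    return [tuple(b) for b in blocks]


def _split_exon(exons, m, u, v):
    blocks = []
    for i, (s, e) in enumerate(exons):
        if i == m:
            blocks.extend([(s, u), (v, e)])
        else:
            blocks.append((s, e))
    return blocks


def _plant_cassette(study, gene: SimGene, length: int, stop_mode: str,
                    conserved: bool, rng, annotated: bool) -> None:
    cfg = study.config
    seq = study.seq
    k = len(gene.introns) // 2
    intron = gene.introns[k]
    x = intron[0] + 100
    y = x + length
    # splice windows at the new exon edges (roles swap with strand)
    accept_b = x if gene.strand == "+" else y
    donor_b = y if gene.strand == "+" else x
    _plant_acceptor_window(seq, accept_b, gene.strand, rng)
    _plant_donor_window(seq, donor_b, gene.strand, rng)
    blocks = [e for e in gene.exons]
    blocks = blocks[: k + 1] + [(x, y)] + blocks[k + 1 :]

    canonical = gene.transcripts[0]
    phase = _cds_phase_before(canonical, intron, gene.strand)
    offset = (3 - phase) % 3
    n_stops = 0
    if stop_mode == "with_stops":
        for j in (10, 12, 14):
            o = offset + 3 * j
            lo = _transcription_offset_to_genomic(x, y, gene.strand, o, 3)
            _write_oriented(seq, lo, STOP, gene.strand)
            n_stops += 1
    elif stop_mode == "no_stops":
        exon_seq = "".join(seq[x:y])
        if gene.strand == "-":
            exon_seq = reverse_complement(exon_seq)
        exon_seq = list(exon_seq)
        for o in range(offset, length - 2, 3):
            if "".join(exon_seq[o : o + 3]) in ("TAA", "TAG", "TGA"):
                exon_seq[o + 1] = "C"
        fixed = "".join(exon_seq)
        _write_oriented(seq, x, fixed, gene.strand)

    # record the stop count of the final sequence (background sequence can
    # contribute chance stops beyond the planted ones)
    from .events import find_inframe_stops

    exon_seq = "".join(seq[x:y])
    if gene.strand == "-":
        exon_seq = reverse_complement(exon_seq)
    n_stops = len(find_inframe_stops(exon_seq, phase))
    frame = "in_frame" if length % 3 == 0 else "frameshifting"
    poison = frame == "frameshifting" or n_stops > 0
    incl = _inclusion_map(cfg)
    if annotated:
        tx = SimTranscript(
            f"{gene.gene_id}.nmd", gene.gene_id, "nonsense_mediated_decay",
            blocks, tuple(cfg.sources),
        )
        gene.transcripts.append(tx)
        study.alt_isoform[gene.gene_id] = tx
        category, event_class = "annotated", "annotated_nmd_exon"
    else:
        _alt_isoform(study, gene, blocks, "new_cassette_exon")
        category, event_class = "planted", "new_cassette_exon"
    for (s, e) in ((intron[0], x), (y, intron[1])):
        study.truth.append(
            PlantedTruth(
                cfg.chrom, s, e, gene.strand, gene.gene_id, category,
                event_class, conserved, True, inclusion=incl,
            )
        )
    study.truth_exons.append(
        TruthExon(
            gene.gene_id, cfg.chrom, gene.strand, x, y, frame, n_stops,
            poison, conserved, annotated,
        )
    )
    if conserved:
        study.conserved_windows.append((x, y))
        study.conserved_windows.append(window_coords("3'", accept_b, gene.strand))
        study.conserved_windows.append(window_coords("5'", donor_b, gene.strand))


def _plant_probes(study: SyntheticStudy, rng) -> None:
    """Filter probes: junctions emitted as fixed extra reads in the first
    library type only, each designed to trip exactly one filter (or none)."""
    cfg = study.config
    seq = study.seq
    lib = cfg.libraries[0].name
    reps = cfg.libraries[0].replicates
    plans = [
        # gene index, dinucs, per-replicate counts, overhang, expectation, reason
        (10, ("GT", "AG"), [6] * reps, 50, True, ""),
        (11, ("GC", "AG"), [6] * reps, 50, False, "non_consensus_dinucleotide"),
        (12, ("GT", "AG"), [2, 2, 1][:reps], 50, False, "mean_count_below_threshold"),
        (13, ("GT", "AG"), [5, 5, 0][:reps], 50, False, "missing_replicate"),
        (14, ("GT", "AG"), [5] * reps, 8, False, "short_overhang"),
    ]
    for gi, (d5, d3), counts, overhang, expect, reason in plans:
        g = study.genes[gi]
        m = len(g.exons) // 2
        es, _ = g.exons[m]
        u, v = es + 55, es + 55 + 48
        donor_b = u if g.strand == "+" else v
        accept_b = v if g.strand == "+" else u
        _plant_donor_dinuc(seq, donor_b, g.strand, d5)
        _plant_acceptor_dinuc(seq, accept_b, g.strand, d3)
        study.probes.append(
            dict(gene=g.gene_id, u=u, v=v, counts=counts, overhang=overhang,
                 library=lib)
        )
        study.truth.append(
            PlantedTruth(
                cfg.chrom, u, v, g.strand, g.gene_id, "probe",
                "new_intron", False, expect, reason,
            )
        )


def _plant_source_membership(study: SyntheticStudy, rng) -> None:
    """Source-exclusive annotated transcripts for intersection accounting:
    each non-first source gets one private alt-acceptor transcript on a tail
    gene, and the first two sources share one more."""
    cfg = study.config
    seq = study.seq
    subsets = [(s,) for s in cfg.sources[1:]] + [tuple(cfg.sources[:2])]
    for i, subset in enumerate(subsets):
        g = study.genes[cfg.n_genes - 1 - i]
        intron = g.introns[0]
        if g.strand == "+":
            novel = (intron[0], intron[1] + 21)
            accept_b = novel[1]
        else:
            novel = (intron[0] - 21, intron[1])
            accept_b = novel[0]
        _plant_acceptor_dinuc(seq, accept_b, g.strand)
        tx = SimTranscript(
            f"{g.gene_id}.v{i}", g.gene_id, "protein_coding",
            _replace_intron(g.exons, 0, novel), tuple(subset),
        )
        g.transcripts.append(tx)
        study.truth.append(
            PlantedTruth(
                cfg.chrom, novel[0], novel[1], g.strand, g.gene_id,
                "annotated", "annotated", False, False, "not_sampled",
            )
        )


# ---------------------------------------------------------------------------
# Conservation track


def make_conservation_track(study: SyntheticStudy) -> list[tuple[str, int, int, float]]:
    """Basewise track: near-zero noisy background (piecewise constant in
    ``track_chunk``-bp chunks), annotated splice-site windows at the
    annotated level, planted conserved elements at the conserved level."""
    cfg = study.config
    rng = np.random.default_rng([cfg.seed, 3])
    n = len(study.seq)
    chunk = cfg.track_chunk
    n_chunks = math.ceil(n / chunk)
    values = np.repeat(
        np.round(rng.normal(0.0, cfg.background_sd, n_chunks), 3), chunk
    )[:n]
    for lo, hi in study.annotated_site_windows:
        values[lo:hi] = cfg.annotated_site_value
    for lo, hi in study.conserved_windows:
        values[lo:hi] = cfg.conserved_value
    # run-length encode
    intervals = []
    start = 0
    for i in range(1, n + 1):
        if i == n or values[i] != values[start]:
            intervals.append((cfg.chrom, start, i, float(values[start])))
            start = i
    return intervals


# ---------------------------------------------------------------------------
# Read simulation


def _blocks_cigar_and_span(blocks, tstart: int, read_len: int):
    """Aligned segments, CIGAR and genomic start for a read beginning at
    transcript-chain offset ``tstart`` (genome-order concatenation)."""
    segs = []
    remaining = read_len
    offset = tstart
    for s, e in blocks:
        blen = e - s
        if offset >= blen:
            offset -= blen
            continue
        take = min(blen - offset, remaining)
        segs.append((s + offset, s + offset + take))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    if remaining:
        raise ValueError("read runs off transcript end")
    parts = []
    for i, (s, e) in enumerate(segs):
        if i:
            parts.append(f"{s - segs[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return segs, "".join(parts), segs[0][0]


def _md_and_nm(ref: str, read: str) -> tuple[str, int]:
    md = []
    run = 0
    nm = 0
    for r, q in zip(ref, read):
        if r == q:
            run += 1
        else:
            md.append(str(run))
            md.append(r)
            run = 0
            nm += 1
    md.append(str(run))
    return "".join(md), nm


_QUAL_CACHE: dict[int, str] = {}


def _qual(n: int) -> str:
    if n not in _QUAL_CACHE:
        _QUAL_CACHE[n] = "I" * n
    return _QUAL_CACHE[n]


def simulate_alignments(study: SyntheticStudy, out_dir) -> pd.DataFrame:
    """Write one SAM per (library, replicate) plus the totals table.

    Reads are sampled uniformly from the canonical or alternative isoform of
    a uniformly chosen gene (isoform choice Bernoulli with the library's
    ``alt_inclusion`` for event genes); junction-spanning reads carry M/N
    CIGARs and MD/NM tags.  A small fraction of reads are low-MAPQ or
    duplicate-flagged decoys that the pipeline's read filters must drop.
    Probe junction reads are appended with their fixed per-replicate counts.
    Returns the totals table (mapped and post-filter read counts).
    """
    cfg = study.config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = study.genome_string()
    chrom_len = len(genome)
    rl = cfg.read_length

    # per-gene isoform block chains and lengths
    gene_iso: list[tuple[list, int, list | None, int]] = []
    for gene in study.genes:
        canon = gene.transcripts[0].blocks
        alt = study.alt_isoform.get(gene.gene_id)
        alt_blocks = alt.blocks if alt is not None else None
        gene_iso.append(
            (
                canon,
                sum(e - s for s, e in canon),
                alt_blocks,
                sum(e - s for s, e in alt_blocks) if alt_blocks else 0,
            )
        )

    totals_rows = []
    bases = np.array(list("ACGT"))
    for li, lib in enumerate(cfg.libraries):
        for ri in range(lib.replicates):
            rep = f"rep{ri + 1}"
            rng = np.random.default_rng([cfg.seed, 2, li, ri])
            path = out_dir / f"{lib.name}_{rep}.sam"
            mapped = 0
            post_filter = 0
            with open(path, "w") as fh:
                fh.write("@HD\tVN:1.6\tSO:unsorted\n")
                fh.write(f"@SQ\tSN:{cfg.chrom}\tLN:{chrom_len}\n")
                gene_idx = rng.integers(0, cfg.n_genes, size=lib.depth)
                iso_draw = rng.random(lib.depth)
                decoy_draw = rng.random(lib.depth)
                for i in range(lib.depth):
                    canon, clen, altb, alen = gene_iso[gene_idx[i]]
                    use_alt = altb is not None and iso_draw[i] < lib.alt_inclusion
                    blocks, tlen = (altb, alen) if use_alt else (canon, clen)
                    tstart = int(rng.integers(0, tlen - rl + 1))
                    segs, cigar, pos = _blocks_cigar_and_span(blocks, tstart, rl)
                    ref = "".join(genome[s:e] for s, e in segs)
                    read = ref
                    nerr = rng.binomial(rl, cfg.error_rate)
                    if nerr:
                        read = list(read)
                        for p in rng.integers(0, rl, size=nerr):
                            cur = read[p]
                            read[p] = str(rng.choice(bases[bases != cur]))
                        read = "".join(read)
                        md, nm = _md_and_nm(ref, read)
                    else:
                        md, nm = str(rl), 0
                    flag, mapq = 0, 60
                    d = decoy_draw[i]
                    if d < cfg.low_mapq_fraction:
                        mapq = 0
                    elif d < cfg.low_mapq_fraction + cfg.duplicate_fraction:
                        flag = 1024
                    mapped += 1
                    if mapq >= 5 and not flag & 1024:
                        post_filter += 1
                    fh.write(
                        f"r{li}_{ri}_{i}\t{flag}\t{cfg.chrom}\t{pos + 1}\t{mapq}\t"
                        f"{cigar}\t*\t0\t0\t{read}\t{_qual(rl)}\tMD:Z:{md}\tNM:i:{nm}\n"
                    )
                # probe reads (first library type only, fixed counts)
                for pi, probe in enumerate(study.probes):
                    if probe["library"] != lib.name:
                        continue
                    count = probe["counts"][ri]
                    oh = probe["overhang"]
                    u, v = probe["u"], probe["v"]
                    for j in range(count):
                        left = oh
                        right = rl - oh
                        pos = u - left
                        cigar = f"{left}M{v - u}N{right}M"
                        ref = genome[pos:u] + genome[v : v + right]
                        md, nm = str(len(ref)), 0
                        mapped += 1
                        post_filter += 1
                        fh.write(
                            f"p{li}_{ri}_{pi}_{j}\t0\t{cfg.chrom}\t{pos + 1}\t60\t"
                            f"{cigar}\t*\t0\t0\t{ref}\t{_qual(rl)}\tMD:Z:{md}\tNM:i:{nm}\n"
                        )
            totals_rows.append(
                {
                    "library": lib.name,
                    "replicate": rep,
                    "mapped": mapped,
                    "mapped_postfilter": post_filter,
                    "path": str(path),
                }
            )
    return pd.DataFrame(totals_rows)


# ---------------------------------------------------------------------------
# Output writing


def write_fasta(study: SyntheticStudy, path) -> None:
    seqstr = study.genome_string()
    with open(path, "w") as fh:
        fh.write(f">{study.chrom}\n")
        for i in range(0, len(seqstr), 80):
            fh.write(seqstr[i : i + 80] + "\n")


def write_gtfs(study: SyntheticStudy, out_dir) -> dict[str, str]:
    """One GTF per annotation source (1-based inclusive coordinates)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for source in study.config.sources:
        path = out_dir / f"{source}.gtf"
        with open(path, "w") as fh:
            for gene in study.genes:
                for tx in gene.transcripts:
                    if source not in tx.sources:
                        continue
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                        f'transcript_biotype "{tx.biotype}";'
                    )
                    lo = min(s for s, _ in tx.blocks)
                    hi = max(e for _, e in tx.blocks)
                    fh.write(
                        f"{study.chrom}\tsim\ttranscript\t{lo + 1}\t{hi}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )
                    for s, e in tx.blocks:
                        fh.write(
                            f"{study.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t"
                            f"{gene.strand}\t.\t{attrs}\n"
                        )
                    for s, e in tx.cds:
                        fh.write(
                            f"{study.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t"
                            f"{gene.strand}\t0\t{attrs}\n"
                        )
        paths[source] = str(path)
    return paths


@dataclass
class SimPaths:
    out_dir: str
    fasta: str
    gtfs: dict[str, str]
    track: str
    totals: str
    truth: str
    truth_exons: str
    sam_by_library: dict[tuple[str, str], str]


def simulate(config: SimulationConfig, out_dir) -> tuple[SyntheticStudy, SimPaths]:
    """Generate the full study into ``out_dir`` and return study + paths."""
    from .tracks import write_bedgraph

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study = make_genome_and_annotation(config)
    fasta = out_dir / "genome.fa"
    write_fasta(study, fasta)
    gtfs = write_gtfs(study, out_dir / "annotations")
    track_path = out_dir / "conservation.bedgraph"
    write_bedgraph(track_path, make_conservation_track(study))
    totals = simulate_alignments(study, out_dir / "alignments")
    totals_path = out_dir / "totals.tsv"
    totals.to_csv(totals_path, sep="\t", index=False)
    truth_path = out_dir / "ground_truth.tsv"
    study.truth_frame().to_csv(truth_path, sep="\t", index=False)
    exons_path = out_dir / "ground_truth_exons.tsv"
    study.truth_exon_frame().to_csv(exons_path, sep="\t", index=False)
    sams = {
        (row.library, row.replicate): row.path for row in totals.itertuples()
    }
    return study, SimPaths(
        out_dir=str(out_dir),
        fasta=str(fasta),
        gtfs=gtfs,
        track=str(track_path),
        totals=str(totals_path),
        truth=str(truth_path),
        truth_exons=str(exons_path),
        sam_by_library=sams,
    )


# ---------------------------------------------------------------------------
# Frame-blindness null: acceptors planted uniformly over available AGs


def simulate_frame_blind_acceptors(
    study: SyntheticStudy,
    genome,
    n_events: int = 2000,
    seed: int = 0,
    window: int = 30,
):
    """Plant novel 3' acceptors uniformly over the available AG positions
    around every annotated acceptor.

    If the splicing machinery has no ability to read frame, per-position
    novel-acceptor usage should be proportional to AG availability alone.
    Sampling candidates uniformly (with replacement) realizes exactly that
    null.  Returns (novel calls, annotated calls, expected counts per signed
    distance) ready for the nearest-site pairing analysis.
    """
    from .annotations import Intron
    from .discovery import JunctionCall
    from .proximity import _dinucleotide_at

    rng = np.random.default_rng([seed, 5])
    lib = study.config.libraries[0]
    base_counts = {(lib.name, f"rep{r + 1}"): 10 for r in range(lib.replicates)}
    annotated_calls = []
    candidates = []  # (distance, intron start, intron end, strand)
    for gene in study.genes:
        for intron in gene.introns:
            strand = gene.strand
            acceptor = intron[1] if strand == "+" else intron[0]
            annotated_calls.append(
                JunctionCall(
                    Intron(study.chrom, intron[0], intron[1], strand),
                    "annotated", dict(base_counts), ("GT", "AG"),
                    (gene.gene_id,), (lib.name,),
                )
            )
            for d in range(-window, window + 1):
                if d == 0:
                    continue
                if not _dinucleotide_at("3'", study.chrom, strand, acceptor, d, genome):
                    continue
                if strand == "+":
                    coords = (intron[0], acceptor + d)
                else:
                    coords = (acceptor - d, intron[1])
                if coords[1] - coords[0] < 4:
                    continue
                candidates.append((d, coords[0], coords[1], strand))
    draws = rng.integers(0, len(candidates), size=n_events)
    novel_calls = []
    for idx in draws:
        d, s, e, strand = candidates[int(idx)]
        novel_calls.append(
            JunctionCall(
                Intron(study.chrom, int(s), int(e), strand),
                "unannotated", dict(base_counts), ("GT", "AG"),
                (), (lib.name,),
            )
        )
    avail: dict[int, int] = {}
    for d, *_ in candidates:
        avail[d] = avail.get(d, 0) + 1
    total = sum(avail.values())
    expected = {d: n_events * n / total for d, n in sorted(avail.items())}
    return novel_calls, annotated_calls, expected


# ---------------------------------------------------------------------------
# Small statistical samplers used by recovery analyses


def sample_cassette_junction_counts(p: float, depth: float, rng) -> tuple[int, int, int]:
    """Poisson junction-read counts for a cassette event with true inclusion
    fraction p: (upstream inclusion, downstream inclusion, skipping)."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    return (
        int(rng.poisson(depth * p)),
        int(rng.poisson(depth * p)),
        int(rng.poisson(depth * (1 - p))),
    )


def sample_retention_counts(r: float, depth: float, rng) -> tuple[int, int, int]:
    """Poisson boundary/junction counts for an intron with true retention r:
    (5' boundary, 3' boundary, spliced junction)."""
    if not 0 <= r <= 1:
        raise ValueError("r must be in [0, 1]")
    return (
        int(rng.poisson(depth * r)),
        int(rng.poisson(depth * r)),
        int(rng.poisson(depth * (1 - r))),
    )
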