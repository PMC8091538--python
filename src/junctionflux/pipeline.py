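"""End-to-end orchestration: annotations + alignments -> classified events.

This is the programmatic equivalent of running the numbered analysis
scripts in order; each step delegates to the corresponding module so the
pieces stay independently usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotations import (
    AnnotationIndex,
    MergedIntronReference,
    merge_references,
    read_transcripts,
)
from .conservation import (
    NullModel,
    PositionWeightModel,
    SpliceSiteProfile,
    build_random_null,
    conserved_cassette_exons,
    exon_conservation,
    filter_conserved_sites,
    profile_site,
    site_window,
)
from .discovery import (
    FilterConfig,
    JunctionCall,
    LibraryProfile,
    call_junctions,
    read_alignment_file,
)
from .events import CassetteExon, SpliceEvent, classify_all
from .genome import Genome
from .quantify import event_psi_table
from .tracks import ConservationTrack


@dataclass
class PipelineResult:
    ref: MergedIntronReference
    index: AnnotationIndex
    libraries: list[LibraryProfile]
    calls: list[JunctionCall]
    events: list[SpliceEvent]
    exons: list[CassetteExon]
    null: NullModel | None = None
    site_partition: dict[str, list[SpliceSiteProfile]] = field(default_factory=dict)
    exon_conservations: list = field(default_factory=list)
    conserved_exons: list = field(default_factory=list)
    psi: pd.DataFrame | None = None
    models: tuple | None = None

    @property
    def annotated_calls(self) -> list[JunctionCall]:
        return [c for c in self.calls if c.status == "annotated"]

    @property
    def unannotated_calls(self) -> list[JunctionCall]:
        return [c for c in self.calls if c.status == "unannotated"]


def load_reference(gtfs: dict[str, str]) -> tuple[MergedIntronReference, AnnotationIndex]:
    """Read each source's GTF/GFF3, merge introns and index gene structure."""
    sets = {src: read_transcripts(path, src) for src, path in gtfs.items()}
    ref = merge_references(sets)
    all_tx = [tx for txs in sets.values() for tx in txs]
    return ref, AnnotationIndex(all_tx)


def library_profiles_from_totals(totals: pd.DataFrame) -> list[LibraryProfile]:
    libs = []
    for name, sub in totals.groupby("library", sort=False):
        libs.append(
            LibraryProfile(
                library_type=name,
                replicates=list(sub["replicate"]),
                total_mapped=dict(zip(sub["replicate"], sub["mapped_postfilter"])),
            )
        )
    return libs


def annotated_site_windows(
    ref: MergedIntronReference, genome: Genome
) -> tuple[list[str], list[str]]:
    """Training windows for the strength models, one per annotated splice site."""
    w5: list[str] = []
    w3: list[str] = []
    seen5: set = set()
    seen3: set = set()
    for intron in ref.entries:
        d, a = intron.donor_pos(), intron.acceptor_pos()
        try:
            key = (intron.chrom, intron.strand, d)
            if key not in seen5:
                seen5.add(key)
                w5.append(site_window("5'", intron.chrom, d, intron.strand, genome))
            key = (intron.chrom, intron.strand, a)
            if key not in seen3:
                seen3.add(key)
                w3.append(site_window("3'", intron.chrom, a, intron.strand, genome))
        except ValueError:
            continue  # window off contig end
    return w5, w3


def novel_site_profiles(
    events: list[SpliceEvent],
    genome: Genome,
    track: ConservationTrack,
    model_5: PositionWeightModel | None,
    model_3: PositionWeightModel | None,
) -> list[SpliceSiteProfile]:
    """One profile per distinct novel splice site across classified events."""
    seen: set = set()
    profiles: list[SpliceSiteProfile] = []
    for ev in events:
        strand = ev.junctions[0].strand
        chrom = ev.junctions[0].chrom
        for side, pos in ev.novel_sites:
            key = (side, chrom, strand, pos)
            if key in seen:
                continue
            seen.add(key)
            try:
                profiles.append(
                    profile_site(
                        side, chrom, pos, strand, genome, track,
                        model_5 if side == "5'" else model_3,
                    )
                )
            except ValueError:
                continue
    return profiles


def run_pipeline(
    gtfs: dict[str, str],
    fasta: str,
    sams: dict[tuple[str, str], str],
    totals: pd.DataFrame,
    track_path: str | None = None,
    filter_config: FilterConfig | None = None,
    null_n: int = 2000,
    null_seed: int = 17,
) -> PipelineResult:
    """Run discovery, classification, quantification and conservation.

    ``sams`` maps (library, replicate) to a SAM/BAM path; ``totals`` must
    carry library / replicate / mapped_postfilter columns.
    """
    config = filter_config or FilterConfig()
    ref, index = load_reference(gtfs)
    genome = Genome(fasta)
    libraries = library_profiles_from_totals(totals)

    observations = []
    for (lib, rep), path in sorted(sams.items()):
        observations.extend(
            read_alignment_file(path, config, genome, library=lib, replicate=rep)
        )
    calls = call_junctions(observations, ref, genome, libraries, config)
    events, exons = classify_all(
        [c for c in calls if c.status == "unannotated"], index, genome
    )
    result = PipelineResult(ref, index, libraries, calls, events, exons)
    result.psi = event_psi_table(events, exons, libraries, result.annotated_calls)

    if track_path is not None:
        track = ConservationTrack.open(track_path)
        w5, w3 = annotated_site_windows(ref, genome)
        model_5 = PositionWeightModel.train(w5) if w5 else None
        model_3 = PositionWeightModel.train(w3) if w3 else None
        result.models = (model_5, model_3)
        result.null = build_random_null(
            ref.gene_spans, genome, track, n=null_n, seed=null_seed,
            model_5=model_5, model_3=model_3,
        )
        profiles = novel_site_profiles(result.events, genome, track, model_5, model_3)
        result.site_partition = filter_conserved_sites(profiles, result.null)
        result.exon_conservations = [exon_conservation(e, track) for e in exons]
        result.conserved_exons = conserved_cassette_exons(result.exon_conservations)
    return result


def run_simulated(sim_paths, **kwargs) -> PipelineResult:
    """Run the pipeline on a :class:`~junctionflux.simulate.SimPaths` layout."""
    totals = pd.read_csv(sim_paths.totals, sep="\t")
    return run_pipeline(
        gtfs=sim_paths.gtfs,
        fasta=sim_paths.fasta,
        sams=sim_paths.sam_by_library,
        totals=totals,
        track_path=sim_paths.track,
        **kwargs,
    )


def load_sim_dir(out_dir) -> "object":
    """Reconstruct a SimPaths from a directory written by simulate()."""
    from .simulate import SimPaths

    out = Path(out_dir)
    totals = pd.read_csv(out / "totals.tsv", sep="\t")
    gtfs = {
        p.stem: str(p) for p in sorted((out / "annotations").glob("*.gtf"))
    }
    sams = {
        (row.library, row.replicate): row.path for row in totals.itertuples()
    }
    return SimPaths(
        out_dir=str(out),
        fasta=str(out / "genome.fa"),
        gtfs=gtfs,
        track=str(out / "conservation.bedgraph"),
        totals=str(out / "totals.tsv"),
        truth=str(out / "ground_truth.tsv"),
        truth_exons=str(out / "ground_truth_exons.tsv"),
        sam_by_library=sams,
    )
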