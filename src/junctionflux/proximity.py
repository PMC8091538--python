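"""Nearest annotated splice-site analysis.

Each unannotated splice site is paired with its nearest annotated
counterpart among annotated junctions sharing the opposite-side site (an
unannotated donor pairs through the acceptor both events use, and vice
versa).  Distances are signed in transcription orientation:

* 5' (donor) sites:  +d places the novel donor d nt further into the intron;
* 3' (acceptor) sites: +d places the novel acceptor d nt into the
  downstream exon (extending the intron past the annotated acceptor —
  the NAGNAG +3/+4/+5 configuration).

The per-position profile of novel-site usage is compared against the
availability of GT / AG dinucleotides around the same annotated sites: if
the splicing machinery cannot read frame, usage tracks availability with no
preference for positions that preserve the reading frame (d divisible by 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discovery import JunctionCall, LibraryProfile
from .genome import Genome
from .quantify import fractional_usage, rpm


@dataclass
class SitePair:
    side: str  # "5'" (donor) or "3'" (acceptor)
    novel: JunctionCall
    annotated: JunctionCall
    novel_pos: int
    annotated_pos: int
    distance: int  # signed, transcription orientation
    shared_partner: int  # genomic boundary of the common opposite-side site


def _signed_distance(side: str, strand: str, novel_pos: int, annotated_pos: int) -> int:
    if side == "5'":
        return novel_pos - annotated_pos if strand == "+" else annotated_pos - novel_pos
    return novel_pos - annotated_pos if strand == "+" else annotated_pos - novel_pos


def pair_nearest_site(
    novel_junctions: list[JunctionCall],
    annotated_junctions: list[JunctionCall],
) -> list[SitePair]:
    """Pair each novel splice site with the nearest annotated like site that
    shares the opposite-side splice site; nearest by |distance|, ties broken
    toward the downstream (+) site.  Sites with no same-partner annotated
    junction stay unpaired."""
    by_acceptor: dict[tuple[str, str, int], list[JunctionCall]] = {}
    by_donor: dict[tuple[str, str, int], list[JunctionCall]] = {}
    donors: set[tuple[str, str, int]] = set()
    acceptors: set[tuple[str, str, int]] = set()
    for call in annotated_junctions:
        dkey = (call.chrom, call.strand, call.intron.donor_pos())
        akey = (call.chrom, call.strand, call.intron.acceptor_pos())
        by_donor.setdefault(dkey, []).append(call)
        by_acceptor.setdefault(akey, []).append(call)
        donors.add(dkey)
        acceptors.add(akey)

    pairs: list[SitePair] = []
    for call in novel_junctions:
        chrom, strand = call.chrom, call.strand
        dpos, apos = call.intron.donor_pos(), call.intron.acceptor_pos()
        donor_novel = (chrom, strand, dpos) not in donors
        acceptor_novel = (chrom, strand, apos) not in acceptors
        if donor_novel:
            best = _nearest(
                "5'", strand, dpos,
                [c for c in by_acceptor.get((chrom, strand, apos), [])],
                lambda c: c.intron.donor_pos(),
            )
            if best is not None:
                ann, d = best
                pairs.append(
                    SitePair("5'", call, ann, dpos, ann.intron.donor_pos(), d, apos)
                )
        if acceptor_novel:
            best = _nearest(
                "3'", strand, apos,
                [c for c in by_donor.get((chrom, strand, dpos), [])],
                lambda c: c.intron.acceptor_pos(),
            )
            if best is not None:
                ann, d = best
                pairs.append(
                    SitePair("3'", call, ann, apos, ann.intron.acceptor_pos(), d, dpos)
                )
    return pairs


def _nearest(side, strand, novel_pos, candidates, pos_of):
    best = None
    for cand in candidates:
        d = _signed_distance(side, strand, novel_pos, pos_of(cand))
        if d == 0:
            continue
        if best is None or (abs(d), -d) < (abs(best[1]), -best[1]):
            best = (cand, d)
    return best


def distance_profile(
    pairs: list[SitePair],
    libraries: list[LibraryProfile],
    window: int = 30,
) -> pd.DataFrame:
    """Per-position novel-site usage histogram within +/- window nt.

    One row per (side, library type, distance) holding the number of novel
    sites whose junction was detected in that library and their summed mean
    RPM.  Distance 0 never occurs (that is the annotated site itself);
    distances beyond the window are excluded.
    """
    rows: dict[tuple[str, str, int], list[float]] = {}
    for pair in pairs:
        if abs(pair.distance) > window or pair.distance == 0:
            continue
        for lib in libraries:
            if lib.library_type not in pair.novel.detected_libraries:
                continue
            mean_rpm = float(
                np.mean(
                    [
                        rpm(pair.novel.count_in(lib.library_type, rep), lib.total_mapped[rep])
                        for rep in lib.replicates
                    ]
                )
            )
            key = (pair.side, lib.library_type, pair.distance)
            rec = rows.setdefault(key, [0, 0.0])
            rec[0] += 1
            rec[1] += mean_rpm
    return pd.DataFrame(
        [
            {"side": s, "library": l, "distance": d, "n_sites": n, "rpm_sum": r}
            for (s, l, d), (n, r) in sorted(rows.items())
        ],
        columns=["side", "library", "distance", "n_sites", "rpm_sum"],
    )


def within_subtotals(pairs: list[SitePair], limit: int = 15) -> dict[str, int]:
    """Number of paired novel sites within +/- limit nt, per side."""
    out = {"5'": 0, "3'": 0}
    for pair in pairs:
        if abs(pair.distance) <= limit:
            out[pair.side] += 1
    return out


def dinucleotide_availability(
    pairs: list[SitePair],
    genome: Genome,
    window: int = 30,
) -> pd.DataFrame:
    """Counts of available GT (5' analysis) / AG (3' analysis) dinucleotides
    at each signed distance around the paired annotated sites.

    A dinucleotide is available at distance d when using it as the novel
    donor/acceptor would place that site at signed distance d from the
    annotated site; the annotated site's own GT/AG appears only at d = 0.
    Positions with d divisible by 3 are flagged in-frame.
    """
    sites: dict[str, set[tuple[str, str, int]]] = {"5'": set(), "3'": set()}
    for pair in pairs:
        ann = pair.annotated
        sites[pair.side].add((ann.chrom, ann.strand, pair.annotated_pos))
    rows = []
    for side in ("5'", "3'"):
        counts = {d: 0 for d in range(-window, window + 1)}
        for chrom, strand, pos in sorted(sites[side]):
            for d in range(-window, window + 1):
                if _dinucleotide_at(side, chrom, strand, pos, d, genome):
                    counts[d] += 1
        for d in range(-window, window + 1):
            rows.append(
                {
                    "side": side,
                    "distance": d,
                    "count": counts[d],
                    "in_frame": d % 3 == 0,
                }
            )
    return pd.DataFrame(rows)


def _dinucleotide_at(side, chrom, strand, annotated_pos, d, genome: Genome) -> bool:
    """Is the consensus dinucleotide present for a hypothetical novel site at
    signed distance d from the annotated boundary?"""
    want = "GT" if side == "5'" else "AG"
    if side == "5'":
        # donor boundary: first two intronic bases
        p = annotated_pos + d if strand == "+" else annotated_pos - d
        lo, hi = (p, p + 2) if strand == "+" else (p - 2, p)
    else:
        # acceptor boundary: last two intronic bases
        p = annotated_pos + d if strand == "+" else annotated_pos - d
        lo, hi = (p - 2, p) if strand == "+" else (p, p + 2)
    if lo < 0 or hi > genome.contig_length(chrom):
        return False
    return genome.fetch(chrom, lo, hi, strand) == want


def nagnag_usage(
    pairs: list[SitePair],
    libraries: list[LibraryProfile],
    positions: tuple[int, ...] = (3, 4, 5),
    reference_library: str | None = None,
    top_fraction: float = 0.15,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Fractional usage of novel 3' splice sites at the +3/+4/+5 positions.

    For each qualifying pair and library type, usage is
    RPM_novel / (RPM_novel + RPM_annotated) over replicate-mean RPMs.
    Returns (per-pair table, per-(position, library) medians, and the
    top-``top_fraction`` subset ranked by novel RPM in ``reference_library``
    traced across all library types).
    """
    rows = []
    for pair in pairs:
        if pair.side != "3'" or pair.distance not in positions:
            continue
        row = {
            "chrom": pair.novel.chrom,
            "strand": pair.novel.strand,
            "novel_pos": pair.novel_pos,
            "position": pair.distance,
        }
        for lib in libraries:
            novel_rpm = float(
                np.mean(
                    [
                        rpm(pair.novel.count_in(lib.library_type, r), lib.total_mapped[r])
                        for r in lib.replicates
                    ]
                )
            )
            ann_rpm = float(
                np.mean(
                    [
                        rpm(pair.annotated.count_in(lib.library_type, r), lib.total_mapped[r])
                        for r in lib.replicates
                    ]
                )
            )
            row[f"rpm_novel_{lib.library_type}"] = novel_rpm
            row[f"usage_{lib.library_type}"] = fractional_usage(novel_rpm, ann_rpm)
        rows.append(row)
    table = pd.DataFrame(rows)
    med_rows = []
    for pos in positions:
        for lib in libraries:
            col = f"usage_{lib.library_type}"
            sub = table[table["position"] == pos][col] if not table.empty else pd.Series(dtype=float)
            med_rows.append(
                {
                    "position": pos,
                    "library": lib.library_type,
                    "median_usage": float(sub.median()) if len(sub.dropna()) else math.nan,
                    "n": int(len(sub)),
                }
            )
    medians = pd.DataFrame(med_rows)
    if table.empty or reference_library is None:
        top = table.iloc[0:0]
    else:
        k = max(1, int(math.ceil(top_fraction * len(table))))
        top = table.nlargest(k, f"rpm_novel_{reference_library}")
    return table, medians, top
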