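"""Splice-site usage statistics: RPM, PSI, PIR, PSO, fractional usage.

All formulas live here so alternative definitions are one-line changes.
PSI follows the replicate-mean convention: computed per replicate from
junction RPMs, then averaged across replicates.  PIR compares reads spanning
the two exon-intron boundaries (no alignment gap) with gapped reads spanning
the intron; PSO is its complement.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


def rpm(count: float, total_mapped: float) -> float:
    """Reads per million post-filter mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count * 1_000_000 / total_mapped


def psi(inclusion_rpms: Sequence[float], exclusion_rpm: float) -> float:
    """Percent spliced in: 100 * Ī / (Ī + E).

    ``inclusion_rpms`` holds one value for alt-SS / new-intron events or two
    (upstream + downstream inclusion junctions) for cassette exons; Ī is
    their mean.  NaN when no reads support either path.
    """
    if exclusion_rpm < 0 or any(v < 0 for v in inclusion_rpms):
        raise ValueError("RPM inputs must be >= 0")
    if not 1 <= len(inclusion_rpms) <= 2:
        raise ValueError("expected 1 or 2 inclusion junctions")
    inc = sum(inclusion_rpms) / len(inclusion_rpms)
    denom = inc + exclusion_rpm
    if denom == 0:
        return math.nan
    return min(100.0, max(0.0, 100.0 * inc / denom))


def psi_per_replicate(
    inclusion_by_rep: Sequence[Sequence[float]], exclusion_by_rep: Sequence[float]
) -> float:
    """Replicate-mean PSI: PSI per replicate, averaged over defined replicates."""
    vals = [
        psi(inc, exc) for inc, exc in zip(inclusion_by_rep, exclusion_by_rep)
    ]
    defined = [v for v in vals if not math.isnan(v)]
    return float(np.mean(defined)) if defined else math.nan


def pir(boundary_rpm_5: float, boundary_rpm_3: float, junction_rpm: float) -> float:
    """Percent intron retention: 100 * B̄ / (B̄ + J) with B̄ the mean of the
    two exon-intron boundary RPMs and J the spliced-junction RPM."""
    if min(boundary_rpm_5, boundary_rpm_3, junction_rpm) < 0:
        raise ValueError("RPM inputs must be >= 0")
    boundary = (boundary_rpm_5 + boundary_rpm_3) / 2.0
    denom = boundary + junction_rpm
    if denom == 0:
        return math.nan
    return min(100.0, max(0.0, 100.0 * boundary / denom))


def pso(pir_value: float) -> float:
    """Percent spliced out: the complement of intron retention."""
    if math.isnan(pir_value):
        return math.nan
    return 100.0 - pir_value


def fractional_usage(rpm_unannotated: float, rpm_annotated: float) -> float:
    """Novel-site usage ratio RPM_unanno / (RPM_unanno + RPM_anno); NaN when
    neither path has reads."""
    if rpm_unannotated < 0 or rpm_annotated < 0:
        raise ValueError("RPM inputs must be >= 0")
    denom = rpm_unannotated + rpm_annotated
    if denom == 0:
        return math.nan
    return rpm_unannotated / denom


# ---------------------------------------------------------------------------
# Library-type enrichment at transcript-unique junctions


def unique_junctions(transcripts) -> dict[tuple[str, int, int, str], str]:
    """Junctions present in exactly one annotated transcript, mapped to that
    transcript's biotype."""
    from .annotations import extract_introns

    seen: dict[tuple[str, int, int, str], list[str]] = {}
    for tx in transcripts:
        for intron in extract_introns(tx):
            key = (intron.chrom, intron.start, intron.end, intron.strand)
            seen.setdefault(key, []).append(tx.biotype)
    return {key: biotypes[0] for key, biotypes in seen.items() if len(biotypes) == 1}


def unique_junction_enrichment(
    calls,
    transcripts,
    libraries,
    numerator: str,
    denominator: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-biotype read-count enrichment at transcript-unique junctions.

    For every junction occurring in exactly one annotated transcript, the
    mean RPM per library type is computed from the call counts; the ratio
    ``numerator``-library / ``denominator``-library is reported per junction
    (junctions with zero denominator RPM are excluded from ratios but kept
    in the table), and the per-biotype median ratio summarizes enrichment.
    Returns (per-junction table, per-biotype summary).
    """
    uniq = unique_junctions(transcripts)
    lib_by_name = {lib.library_type: lib for lib in libraries}
    rows = []
    for call in calls:
        key = (call.chrom, call.intron.start, call.intron.end, call.strand)
        biotype = uniq.get(key)
        if biotype is None:
            continue
        row = {
            "chrom": call.chrom,
            "start": call.intron.start,
            "end": call.intron.end,
            "strand": call.strand,
            "biotype": biotype,
        }
        for name, lib in lib_by_name.items():
            reps = lib.replicates
            vals = [
                rpm(call.count_in(name, rep), lib.total_mapped[rep]) for rep in reps
            ]
            row[f"rpm_{name}"] = float(np.mean(vals))
        denom = row[f"rpm_{denominator}"]
        row["ratio"] = row[f"rpm_{numerator}"] / denom if denom > 0 else math.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return table, pd.DataFrame(columns=["biotype", "n", "n_ratio", "median_ratio"])
    summary = (
        table.groupby("biotype")
        .agg(
            n=("ratio", "size"),
            n_ratio=("ratio", lambda s: int(s.notna().sum())),
            median_ratio=("ratio", "median"),
        )
        .reset_index()
    )
    return table, summary


def event_psi_table(events, exons, libraries, annotated_calls) -> pd.DataFrame:
    """Replicate-mean PSI per cassette exon and library type.

    Inclusion junctions are the exon's two flanking junctions; the exclusion
    path is the host intron's own (annotated) junction when observed.
    """
    ann_by_intron = {
        (c.chrom, c.intron.start, c.intron.end, c.strand): c for c in annotated_calls
    }
    rows = []
    for exon in exons:
        host = exon.host_intron
        skip = ann_by_intron.get((host.chrom, host.start, host.end, host.strand))
        row = {
            "chrom": exon.chrom,
            "exon_start": exon.start,
            "exon_end": exon.end,
            "strand": exon.strand,
            "host_gene": exon.host_gene,
        }
        up, down = exon.flanking_junctions
        for lib in libraries:
            inc_by_rep, exc_by_rep = [], []
            for rep in lib.replicates:
                total = lib.total_mapped[rep]
                inc_by_rep.append(
                    [
                        rpm(up.count_in(lib.library_type, rep), total),
                        rpm(down.count_in(lib.library_type, rep), total),
                    ]
                )
                exc = skip.count_in(lib.library_type, rep) if skip else 0
                exc_by_rep.append(rpm(exc, total))
            row[f"psi_{lib.library_type}"] = psi_per_replicate(inc_by_rep, exc_by_rep)
        rows.append(row)
    return pd.DataFrame(rows)
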