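"""Splice-site strength scoring and conservation-based noise filtering.

A splice site is summarized by a fixed window in transcription orientation —
9 nt for donors (3 exonic + 6 intronic, GT at window positions 4-5) and
23 nt for acceptors (20 intronic + 3 exonic, AG at positions 19-20).  Each
window gets a strength score (default: position weight matrix log2-odds
trained on annotated-site windows; a precomputed score-table backend gives
bit-compatible parity with external maximum-entropy scorers) and a mean
basewise conservation over its genomic footprint.

The splicing-noise filter derives empirical cutoffs from a randomized null:
windows sampled uniformly inside annotated gene spans, kept only when they
carry the consensus GT/AG at the fixed offsets, scored the same way.  The
95th percentile of the null conservation distribution separates conserved
sites from noise; these cutoffs are re-derived per dataset and track rather
than treated as constants of the method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome
from .tracks import ConservationTrack

DONOR_EXONIC, DONOR_INTRONIC = 3, 6
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 20, 3
DONOR_LEN = DONOR_EXONIC + DONOR_INTRONIC  # 9
ACCEPTOR_LEN = ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC  # 23
# consensus dinucleotide offsets within the window (0-based)
DONOR_GT_OFFSET = DONOR_EXONIC  # GT at 1-based positions 4-5
ACCEPTOR_AG_OFFSET = ACCEPTOR_INTRONIC - 2  # AG at 1-based positions 19-20

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def window_coords(side: str, boundary_pos: int, strand: str) -> tuple[int, int]:
    """Genomic [start, end) of a splice-site window.

    ``boundary_pos`` is the exon|intron boundary: intron start for a donor on
    '+', intron end for a donor on '-', and vice versa for acceptors.
    """
    if side == "5'":
        if strand == "+":
            return boundary_pos - DONOR_EXONIC, boundary_pos + DONOR_INTRONIC
        return boundary_pos - DONOR_INTRONIC, boundary_pos + DONOR_EXONIC
    if side == "3'":
        if strand == "+":
            return boundary_pos - ACCEPTOR_INTRONIC, boundary_pos + ACCEPTOR_EXONIC
        return boundary_pos - ACCEPTOR_EXONIC, boundary_pos + ACCEPTOR_INTRONIC
    raise ValueError(f"side must be 5' or 3', got {side!r}")


def site_window(side: str, chrom: str, boundary_pos: int, strand: str, genome: Genome) -> str:
    """Window sequence in transcription orientation (9-mer or 23-mer)."""
    lo, hi = window_coords(side, boundary_pos, strand)
    if lo < 0 or hi > genome.contig_length(chrom):
        raise ValueError(f"window [{lo},{hi}) off end of contig {chrom}")
    return genome.fetch(chrom, lo, hi, strand)


def is_consensus_window(side: str, window: str) -> bool:
    """GT at donor positions 4-5 / AG at acceptor positions 19-20 (1-based)."""
    if side == "5'":
        return len(window) == DONOR_LEN and window[DONOR_GT_OFFSET : DONOR_GT_OFFSET + 2] == "GT"
    return (
        len(window) == ACCEPTOR_LEN
        and window[ACCEPTOR_AG_OFFSET : ACCEPTOR_AG_OFFSET + 2] == "AG"
    )


# ---------------------------------------------------------------------------
# Strength models


class PositionWeightModel:
    """0th-order position weight matrix scored as summed log2 odds vs a
    background; trained on annotated-site windows."""

    def __init__(self, log_odds: np.ndarray):
        self.log_odds = np.asarray(log_odds, dtype=float)
        self.length = self.log_odds.shape[0]

    @classmethod
    def train(
        cls,
        windows: list[str],
        pseudocount: float = 0.5,
        background: np.ndarray | None = None,
    ) -> "PositionWeightModel":
        if not windows:
            raise ValueError("no training windows")
        length = len(windows[0])
        if any(len(w) != length for w in windows):
            raise ValueError("training windows have unequal lengths")
        counts = np.full((length, 4), pseudocount)
        for w in windows:
            for i, base in enumerate(w.upper()):
                j = _BASE_INDEX.get(base)
                if j is not None:
                    counts[i, j] += 1
        probs = counts / counts.sum(axis=1, keepdims=True)
        q = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(np.log2(probs / q))

    def score(self, window: str) -> float:
        if len(window) != self.length:
            raise ValueError(
                f"window length {len(window)} != model length {self.length}"
            )
        total = 0.0
        for i, base in enumerate(window.upper()):
            j = _BASE_INDEX.get(base)
            if j is not None:  # ambiguous bases contribute 0
                total += self.log_odds[i, j]
        return total

    def consensus(self) -> str:
        return "".join(_BASES[j] for j in self.log_odds.argmax(axis=1))


class ScoreTableModel:
    """Strength scoring from an externally supplied per-position, per-base
    additive score table (e.g. exported maximum-entropy scores)."""

    def __init__(self, table: np.ndarray):
        self.table = np.asarray(table, dtype=float)
        self.length = self.table.shape[0]

    @classmethod
    def from_tsv(cls, path) -> "ScoreTableModel":
        df = pd.read_csv(path, sep="\t")
        return cls(df[list(_BASES)].to_numpy())

    def score(self, window: str) -> float:
        if len(window) != self.length:
            raise ValueError("window length mismatch with score table")
        return float(
            sum(
                self.table[i, _BASE_INDEX[b]]
                for i, b in enumerate(window.upper())
                if b in _BASE_INDEX
            )
        )


def train_site_models(
    annotated_windows_5: list[str], annotated_windows_3: list[str]
) -> tuple[PositionWeightModel, PositionWeightModel]:
    return (
        PositionWeightModel.train(annotated_windows_5),
        PositionWeightModel.train(annotated_windows_3),
    )


# ---------------------------------------------------------------------------
# Conservation


def mean_conservation(
    chrom: str,
    start: int,
    end: int,
    track: ConservationTrack,
    min_covered_fraction: float = 0.5,
) -> tuple[float, float]:
    """Mean basewise score over a genomic footprint (orientation-independent)
    with the covered fraction; NaN mean when coverage < the threshold."""
    return track.mean(chrom, start, end, min_covered_fraction)


@dataclass
class SpliceSiteProfile:
    side: str  # "5'" | "3'"
    chrom: str
    boundary_pos: int
    strand: str
    window_seq: str
    strength: float = math.nan
    mean_conservation: float = math.nan
    covered_fraction: float = 0.0
    conserved: bool | None = None


def profile_site(
    side: str,
    chrom: str,
    boundary_pos: int,
    strand: str,
    genome: Genome,
    track: ConservationTrack | None = None,
    model=None,
) -> SpliceSiteProfile:
    window = site_window(side, chrom, boundary_pos, strand, genome)
    prof = SpliceSiteProfile(side, chrom, boundary_pos, strand, window)
    if model is not None:
        prof.strength = model.score(window)
    if track is not None:
        lo, hi = window_coords(side, boundary_pos, strand)
        prof.mean_conservation, prof.covered_fraction = mean_conservation(
            chrom, lo, hi, track
        )
    return prof


# ---------------------------------------------------------------------------
# Randomized GT/AG-matched null


@dataclass
class NullModel:
    n_draws: int
    seed: int
    cutoff_5: float
    cutoff_3: float
    draws_5: pd.DataFrame = field(repr=False, default=None)
    draws_3: pd.DataFrame = field(repr=False, default=None)

    def cutoff(self, side: str) -> float:
        return self.cutoff_5 if side == "5'" else self.cutoff_3


def build_random_null(
    gene_spans,
    genome: Genome,
    track: ConservationTrack,
    n: int = 10_000,
    seed: int = 0,
    model_5=None,
    model_3=None,
    quantile: float = 95.0,
    max_attempts_per_accept: int = 10_000,
) -> NullModel:
    """Rejection-sample random gene-internal windows matched for GT/AG.

    ``gene_spans`` is an iterable of (chrom, strand, start, end) spans (the
    strand entry is ignored: draws sample both strands with equal
    probability).  Windows must lie inside the sampled span, carry GT at
    donor positions 4-5 (5' draws) or AG at acceptor positions 19-20
    (3' draws) and have computable conservation.  Cutoffs are the empirical
    ``quantile`` percentile of each side's conservation draws.
    """
    if n < 100:
        raise ValueError("n must be >= 100 for a stable quantile")
    spans = [(c, s, e) for c, _strand, s, e in _normalize_spans(gene_spans)]
    if not spans:
        raise ValueError("no gene spans supplied")
    lengths = np.array([e - s for _, s, e in spans], dtype=float)
    weights = lengths / lengths.sum()
    rng = np.random.default_rng(seed)

    draws: dict[str, list] = {"5'": [], "3'": []}
    models = {"5'": model_5, "3'": model_3}
    for side in ("5'", "3'"):
        attempts = 0
        while len(draws[side]) < n:
            attempts += 1
            if attempts > max_attempts_per_accept * max(1, len(draws[side]) + 1):
                raise RuntimeError(
                    "rejection sampling rate too low; degenerate genome/track"
                )
            i = int(rng.choice(len(spans), p=weights))
            chrom, s, e = spans[i]
            strand = "+" if rng.random() < 0.5 else "-"
            pos = int(rng.integers(s, e))
            lo, hi = window_coords(side, pos, strand)
            if lo < s or hi > e or lo < 0 or hi > genome.contig_length(chrom):
                continue
            window = genome.fetch(chrom, lo, hi, strand)
            if not is_consensus_window(side, window):
                continue
            cons, frac = mean_conservation(chrom, lo, hi, track)
            if math.isnan(cons):
                continue
            model = models[side]
            strength = model.score(window) if model is not None else math.nan
            draws[side].append((chrom, pos, strand, strength, cons, frac))
    frames = {
        side: pd.DataFrame(
            rows,
            columns=["chrom", "pos", "strand", "strength", "conservation", "covered"],
        )
        for side, rows in draws.items()
    }
    return NullModel(
        n_draws=n,
        seed=seed,
        cutoff_5=float(np.percentile(frames["5'"]["conservation"], quantile)),
        cutoff_3=float(np.percentile(frames["3'"]["conservation"], quantile)),
        draws_5=frames["5'"],
        draws_3=frames["3'"],
    )


def _normalize_spans(gene_spans):
    if isinstance(gene_spans, dict):
        return sorted(gene_spans.values())
    return list(gene_spans)


def filter_conserved_sites(
    profiles: list[SpliceSiteProfile], null: NullModel
) -> dict[str, list[SpliceSiteProfile]]:
    """Exhaustive, exclusive partition into conserved (mean conservation >=
    the side's null cutoff) and noise sites; sites with NaN conservation are
    treated as noise."""
    out: dict[str, list[SpliceSiteProfile]] = {"conserved": [], "noise": []}
    for prof in profiles:
        cons = prof.mean_conservation
        keep = (not math.isnan(cons)) and cons >= null.cutoff(prof.side)
        prof.conserved = keep
        out["conserved" if keep else "noise"].append(prof)
    return out


# ---------------------------------------------------------------------------
# Cassette-exon conservation


@dataclass
class ExonConservation:
    exon: object  # CassetteExon
    mean_exon_conservation: float
    ss5_conservation: float
    ss3_conservation: float


def exon_conservation(exon, track: ConservationTrack) -> ExonConservation:
    """Internal + splice-site conservation of a new cassette exon.

    The exon's 3' splice site sits at its transcription-upstream edge and its
    5' splice site at the downstream edge.
    """
    if exon.strand == "+":
        ss3_pos, ss5_pos = exon.start, exon.end
    else:
        ss3_pos, ss5_pos = exon.end, exon.start
    lo5, hi5 = window_coords("5'", ss5_pos, exon.strand)
    lo3, hi3 = window_coords("3'", ss3_pos, exon.strand)
    internal, _ = mean_conservation(exon.chrom, exon.start, exon.end, track)
    ss5, _ = mean_conservation(exon.chrom, lo5, hi5, track)
    ss3, _ = mean_conservation(exon.chrom, lo3, hi3, track)
    return ExonConservation(exon, internal, ss5, ss3)


def conserved_cassette_exons(
    exon_conservations: list[ExonConservation],
    ss5_threshold: float = 1.0,
    ss3_threshold: float = 1.0,
    exon_threshold: float = 1.0,
) -> list[ExonConservation]:
    """Exons passing the three-way conservation filter (both splice sites and
    the exon body at or above their thresholds; NaN fails)."""
    out = []
    for ec in exon_conservations:
        vals = (ec.ss5_conservation, ec.ss3_conservation, ec.mean_exon_conservation)
        if any(math.isnan(v) for v in vals):
            continue
        if (
            ec.ss5_conservation >= ss5_threshold
            and ec.ss3_conservation >= ss3_threshold
            and ec.mean_exon_conservation >= exon_threshold
        ):
            out.append(ec)
    return out
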