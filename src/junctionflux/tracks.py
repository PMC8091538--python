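"""Basewise conservation track access (bedGraph or bigWig).

Values are per-base scores (e.g. phyloP); positions not covered by the track
are NaN.  Means over windows are computed on the genomic footprint,
orientation-independent, with a covered-fraction guard for gappy tracks.
"""

from __future__ import annotations

import numpy as np


class ConservationTrack:
    """Random access to a basewise score track.

    Use :meth:`open` to auto-detect bedGraph vs bigWig by extension/magic.
    """

    def __init__(self, backend):
        self._backend = backend

    @classmethod
    def open(cls, path) -> "ConservationTrack":
        p = str(path)
        if p.endswith((".bw", ".bigwig", ".bigWig")):
            return cls.from_bigwig(p)
        return cls.from_bedgraph(p)

    @classmethod
    def from_bedgraph(cls, path) -> "ConservationTrack":
        return cls(_BedGraphBackend(str(path)))

    @classmethod
    def from_bigwig(cls, path) -> "ConservationTrack":
        return cls(_BigWigBackend(str(path)))

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base scores over [start, end); NaN where uncovered."""
        if end <= start:
            raise ValueError("empty window")
        return self._backend.values(chrom, start, end)

    def mean(
        self, chrom: str, start: int, end: int, min_covered_fraction: float = 0.5
    ) -> tuple[float, float]:
        """(mean over covered bases, covered fraction); mean is NaN when
        coverage falls below ``min_covered_fraction``."""
        vals = self.values(chrom, start, end)
        covered = ~np.isnan(vals)
        frac = float(covered.mean())
        if frac < min_covered_fraction or not covered.any():
            return float("nan"), frac
        return float(vals[covered].mean()), frac


class _BedGraphBackend:
    def __init__(self, path: str):
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        vals: dict[str, list[float]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#", "browser")):
                    continue
                chrom, s, e, v = line.split()[:4]
                starts.setdefault(chrom, []).append(int(s))
                ends.setdefault(chrom, []).append(int(e))
                vals.setdefault(chrom, []).append(float(v))
        self._data = {}
        for chrom in starts:
            order = np.argsort(starts[chrom], kind="stable")
            self._data[chrom] = (
                np.asarray(starts[chrom])[order],
                np.asarray(ends[chrom])[order],
                np.asarray(vals[chrom])[order],
            )

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        out = np.full(end - start, np.nan)
        data = self._data.get(chrom)
        if data is None:
            return out
        starts, ends, vals = data
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(starts[i], start) - start
            b = min(ends[i], end) - start
            if b > a:
                out[a:b] = vals[i]
        return out


class _BigWigBackend:
    def __init__(self, path: str):
        import pyBigWig

        self._bw = pyBigWig.open(path)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        if chrom not in self._bw.chroms():
            return np.full(end - start, np.nan)
        clen = self._bw.chroms(chrom)
        lo, hi = max(0, start), min(end, clen)
        out = np.full(end - start, np.nan)
        if hi > lo:
            out[lo - start : hi - start] = np.array(
                self._bw.values(chrom, lo, hi), dtype=float
            )
        return out


def write_bedgraph(path, intervals) -> None:
    """Write sorted, non-overlapping (chrom, start, end, value) records."""
    with open(path, "w") as fh:
        for chrom, start, end, value in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
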