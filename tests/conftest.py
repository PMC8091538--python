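"""Shared fixtures: one default synthetic study + pipeline run per session."""

from __future__ import annotations

import pysam
import pytest

from junctionflux.pipeline import run_simulated
from junctionflux.simulate import SimulationConfig, simulate

DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """Default-scale synthetic study (20 genes, 3 replicates x 2 library
    types x 50k reads) used by integration-level tests."""
    out = tmp_path_factory.mktemp("default_sim")
    study, paths = simulate(SimulationConfig(seed=DEFAULT_SEED), out)
    return study, paths


@pytest.fixture(scope="session")
def default_result(default_sim):
    _, paths = default_sim
    return run_simulated(paths, null_n=2000, null_seed=17)


@pytest.fixture()
def make_read():
    """Factory for in-memory alignments with arbitrary CIGAR/MD."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chrT", "LN": 1_000_000}]}
    )

    def _make(
        pos: int,
        cigar: str,
        seq: str | None = None,
        md: str | None = None,
        mapq: int = 60,
        flag: int = 0,
        name: str = "read1",
    ) -> pysam.AlignedSegment:
        read = pysam.AlignedSegment(header)
        read.query_name = name
        read.flag = flag
        read.reference_id = 0
        read.reference_start = pos
        read.mapping_quality = mapq
        read.cigarstring = cigar
        if seq is None:
            qlen = read.infer_query_length()
            seq = "A" * qlen
        read.query_sequence = seq
        read.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        if md is not None:
            read.set_tag("MD", md)
        return read

    return _make
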