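"""Nearest annotated splice-site analysis: distance profiles, GT/AG
availability and NAGNAG (+3/+4/+5) fractional usage per library type.

If splice-site choice cannot read frame, novel-acceptor usage should track
AG availability rather than favoring frame-preserving positions.
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py"
)
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from junctionflux.genome import Genome  # noqa: E402
from junctionflux.pipeline import run_simulated  # noqa: E402
from junctionflux.proximity import (  # noqa: E402
    dinucleotide_availability,
    distance_profile,
    nagnag_usage,
    pair_nearest_site,
    within_subtotals,
)


def main():
    paths = common.load_paths()
    tables = common.ensure_tables()
    result = run_simulated(paths)
    pairs = pair_nearest_site(result.unannotated_calls, result.annotated_calls)
    prof = distance_profile(pairs, result.libraries, window=30)
    prof.to_csv(tables / "distance_profile.tsv", sep="\t", index=False)
    genome = Genome(paths.fasta)
    avail = dinucleotide_availability(pairs, genome, window=30)
    avail.to_csv(tables / "dinucleotide_availability.tsv", sep="\t", index=False)
    usage, medians, top = nagnag_usage(pairs, result.libraries, reference_library="EJC")
    usage.to_csv(tables / "nagnag_usage.tsv", sep="\t", index=False)
    medians.to_csv(tables / "nagnag_medians.tsv", sep="\t", index=False)
    print(f"{len(pairs)} novel/annotated site pairs; within 15 nt: {within_subtotals(pairs)}")
    print("per-position usage:")
    print(prof.to_string(index=False))
    print("\nNAGNAG (+3/+4/+5) median fractional usage per library:")
    print(medians.to_string(index=False))


if __name__ == "__main__":
    main()
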