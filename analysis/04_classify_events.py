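"""Classify the retained unannotated junctions into the five event classes
and derive frame / stop-codon consequences for new cassette exons.

Junction pairs inside one annotated intron are promoted to new cassette
exons; each exon is then checked for frameshifting length or in-frame stop
codons — either marks it as a candidate poison exon.
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py"
)
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from collections import Counter  # noqa: E402

from junctionflux.events import events_to_frame  # noqa: E402
from junctionflux.pipeline import run_simulated  # noqa: E402


def main():
    paths = common.load_paths()
    tables = common.ensure_tables()
    result = run_simulated(paths)
    df = events_to_frame(result.events, result.exons)
    df.to_csv(tables / "events.tsv", sep="\t", index=False)
    print(Counter(ev.event_class for ev in result.events))
    for exon in result.exons:
        print(
            f"new cassette exon {exon.host_gene}:{exon.start}-{exon.end} "
            f"({exon.length} nt, {exon.frame_status}, "
            f"{len(exon.inframe_stops)} in-frame stops, poison={exon.poison})"
        )


if __name__ == "__main__":
    main()
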