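"""Merge the four annotation sources into the cross-source intron reference
and report the UpSet-style intersection counts.

Sources largely agree on canonical introns; each source also carries a few
private transcripts, so the exclusive-subset counts expose exactly which
introns each source contributes.
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py"
)
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

import pandas as pd  # noqa: E402

from junctionflux.annotations import (  # noqa: E402
    intersection_counts,
    merge_references,
    per_source_totals,
    read_transcripts,
)


def main():
    paths = common.load_paths()
    tables = common.ensure_tables()
    sets = {src: read_transcripts(p, src) for src, p in paths.gtfs.items()}
    ref = merge_references(sets)
    ref.write_tsv(tables / "merged_intron_reference.tsv")
    counts = intersection_counts(ref)
    rows = [
        {"sources": "+".join(sorted(subset)), "n_introns": n}
        for subset, n in sorted(counts.items(), key=lambda kv: -kv[1])
    ]
    df = pd.DataFrame(rows)
    df.to_csv(tables / "intersection_counts.tsv", sep="\t", index=False)
    print(f"{len(ref)} distinct introns across {len(sets)} sources")
    print(df.to_string(index=False))
    print("per-source totals:", per_source_totals(ref))


if __name__ == "__main__":
    main()
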