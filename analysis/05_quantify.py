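"""Quantify splicing usage: PSI of new cassette exons per library type and
EJC vs RNA-Seq enrichment at transcript-unique junctions per biotype.

The EJC-like library should report much higher poison-exon PSI than the
RNA-Seq-like library, and NMD-transcript-unique junctions should show an
EJC enrichment near the simulated inclusion fold change.
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py"
)
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from junctionflux.pipeline import run_simulated  # noqa: E402
from junctionflux.quantify import unique_junction_enrichment  # noqa: E402
from junctionflux.annotations import read_transcripts  # noqa: E402


def main():
    paths = common.load_paths()
    tables = common.ensure_tables()
    result = run_simulated(paths)
    result.psi.to_csv(tables / "cassette_psi.tsv", sep="\t", index=False)
    print("cassette-exon PSI per library type:")
    print(result.psi.to_string(index=False))

    src, gtf = next(iter(paths.gtfs.items()))
    transcripts = read_transcripts(gtf, src)
    table, summary = unique_junction_enrichment(
        result.annotated_calls, transcripts, result.libraries,
        numerator="EJC", denominator="RNASEQ",
    )
    table.to_csv(tables / "unique_junction_rpm.tsv", sep="\t", index=False)
    summary.to_csv(tables / "unique_junction_enrichment.tsv", sep="\t", index=False)
    print("\nunique-junction EJC/RNASEQ enrichment by biotype:")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
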