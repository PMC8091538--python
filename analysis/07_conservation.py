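"""Score novel splice sites for strength and conservation, derive the
randomized GT/AG-matched null cutoffs, and separate conserved events from
splicing noise; intersect with cassette-exon conservation to call the final
conserved poison-exon set.
"""

import importlib.util
import json
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py"
)
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

import pandas as pd  # noqa: E402

from junctionflux.pipeline import run_simulated  # noqa: E402


def main():
    paths = common.load_paths()
    tables = common.ensure_tables()
    result = run_simulated(paths, null_n=10_000, null_seed=17)
    null = result.null
    summary = {
        "n_draws": null.n_draws,
        "seed": null.seed,
        "cutoff_5": null.cutoff_5,
        "cutoff_3": null.cutoff_3,
    }
    (tables / "null_model.json").write_text(json.dumps(summary, indent=2))
    rows = []
    for label, profs in result.site_partition.items():
        for p in profs:
            rows.append(
                {
                    "side": p.side, "chrom": p.chrom, "pos": p.boundary_pos,
                    "strand": p.strand, "strength": p.strength,
                    "conservation": p.mean_conservation,
                    "covered": p.covered_fraction, "partition": label,
                }
            )
    pd.DataFrame(rows).to_csv(tables / "site_conservation.tsv", sep="\t", index=False)
    print(
        f"null cutoffs (n={null.n_draws}): 5'={null.cutoff_5:.3f}, "
        f"3'={null.cutoff_3:.3f}"
    )
    print(
        f"{len(result.site_partition['conserved'])} conserved vs "
        f"{len(result.site_partition['noise'])} noise novel splice sites"
    )
    kept = result.conserved_exons
    print(f"{len(kept)} / {len(result.exons)} new cassette exons pass the "
          "three-way conservation filter:")
    for ec in kept:
        e = ec.exon
        print(
            f"  {e.host_gene}:{e.start}-{e.end} exon={ec.mean_exon_conservation:.2f} "
            f"ss5={ec.ss5_conservation:.2f} ss3={ec.ss3_conservation:.2f} "
            f"poison={e.poison}"
        )


if __name__ == "__main__":
    main()
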