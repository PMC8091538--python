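"""Generate the default synthetic study: genome, four annotation sources,
conservation track and 3 replicates x 2 library types of aligned reads.

The EJC-like library samples NMD/poison-exon isoforms at 50% inclusion,
the RNA-Seq-like library at 5%, emulating the enrichment of
pre-translational mRNPs for translation-dependent decay targets.
"""

import argparse
import importlib.util
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py"
)
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from junctionflux.simulate import SimulationConfig, simulate  # noqa: E402


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=11)
    args = parser.parse_args()
    study, paths = simulate(SimulationConfig(seed=args.seed), common.SIM_DIR)
    truth = study.truth_frame()
    print(f"genome: {len(study.seq):,} bp, {len(study.genes)} genes -> {paths.out_dir}")
    print(truth.groupby(["category", "event_class"]).size().to_string())
    print(f"planted cassette exons:\n{study.truth_exon_frame().to_string(index=False)}")


if __name__ == "__main__":
    main()
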