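"""Shared paths and loaders for the numbered analysis scripts."""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SIM_DIR = RESULTS / "sim"
TABLES = RESULTS / "tables"


def load_paths():
    from junctionflux.pipeline import load_sim_dir

    if not SIM_DIR.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    return load_sim_dir(SIM_DIR)


def ensure_tables():
    TABLES.mkdir(parents=True, exist_ok=True)
    return TABLES
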