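"""Shared configuration for the numbered analysis scripts.

The simulated survey mirrors the study conditions end to end: a 20 x 48 Mb
genome carrying ~1,250 genes per chromosome, eight inversions per
chromosome (160 total), full gene duplication with 5% syntenic-copy loss,
a 73,728-clone library with 150 kb mean inserts, and a 17% per-end hit
rate.  All scripts derive their randomness from ANALYSIS_SEED so the whole
chain is reproducible.
"""
from pathlib import Path

from besmap.sim import SimConfig

ANALYSIS_SEED = 2010

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "analysis"


def survey_config() -> SimConfig:
    return SimConfig(seed=ANALYSIS_SEED)


def ensure_dirs() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
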