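"""Shared setup for the analysis drivers.

Each numbered script regenerates the default synthetic cohort
deterministically from MASTER_SEED (a few seconds) rather than passing
large intermediates between scripts; every number printed is recomputed
by the library at run time. Outputs land under results/.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

RESULTS = ROOT / "results"
MASTER_SEED = 1


def cohort():
    from tricross import pipeline, sim

    return sim.simulate_cohort(seed=pipeline.derive_seed(MASTER_SEED, "simulate"))


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
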