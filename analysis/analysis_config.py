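"""Shared settings for the numbered analysis drivers.

One master seed and one generator configuration, so every driver works on
the same deterministic synthetic compendium: 39 datasets (~9.2k samples)
emulating a multi-study breast-cancer expression compendium with an older
(>= 70y) stratum, planted risk groups and subtypes, and right-censored
recurrence outcomes.
"""

from pathlib import Path

from sigbench.simulate import SimulationConfig

ANALYSIS_SEED = 17
CONFIG = SimulationConfig()

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
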