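"""Shared study conditions for the numbered analysis scripts.

One seed, one simulation configuration (the generator defaults: 10
datasets x 100 samples, 2000 genes, 20 modules, planted gene-module
associations, coupled module pairs, cis/trans eQTLs, a TF network with a
planted driver, and cell-type marker sets). Every script regenerates the
same compendium deterministically from this seed, so the whole analysis
is reproducible end to end with no intermediate binary state.
"""

from pathlib import Path

from modnet.synthetic import SimulationConfig

SEED = 17
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_config() -> SimulationConfig:
    return SimulationConfig(seed=SEED)
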