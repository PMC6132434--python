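"""Shared settings for the numbered analysis drivers.

A scaled-down cohort (13 studies x 48 persons, 3 recorded days each) keeps
the scripts interactive while preserving the pooled sample's structure; the
seed fixes every stage.
"""

from pathlib import Path

from isosub import simulate

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 2018


def sim_config() -> simulate.SimulationConfig:
    return simulate.SimulationConfig(
        n_studies=13, persons_per_study=48, n_days=3, seed=SEED)
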