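"""Shared argument handling for the numbered analysis drivers.

Every driver operates on one study directory (default ``results/study``)
holding the plain-file handoff between pipeline stages, and derives all
randomness from a single seed.
"""

import argparse

from pcskit.synthetic_data import SimulationConfig


def study_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", default="results/study")
    return parser.parse_args()


def study_config(seed: int) -> SimulationConfig:
    """The default study scenario: 407 baseline twins, 298 at follow-up."""
    return SimulationConfig(seed=seed)
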