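"""Shared configuration for the numbered analysis scripts.

One synthetic body-wide circadian study, used by every stage: a main
atlas with planted global/organ cyclers, coupled pairs and modules; a
second atlas with night-amplified organ-factor coupling for the
day/night topology and comparison stages; and an interactome with a
planted disease module and a planted proximal set pair.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from chronet.simulate import ModuleSpec, SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "study"


def main_atlas_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_genes=800,
        n_organs=20,
        n_coupled_pairs=60,
        seed=seed,
    )


def module_atlas_config(seed: int) -> SimulationConfig:
    """Module scenario: two rhythmic modules (noon / midnight peaks) and a
    flat one, on enough organs for eigengene rhythm tests to have power
    against the organ-level module latent."""
    return SimulationConfig(
        n_genes=500,
        n_organs=25,
        module_plan=(
            ModuleSpec(40, 0.9, rhythmic=True, phase=6.0),
            ModuleSpec(40, 0.9, rhythmic=True, phase=18.0),
            ModuleSpec(40, 0.9, rhythmic=False),
        ),
        seed=seed + 3,
    )


def dimorphic_atlas_config(seed: int) -> SimulationConfig:
    """Night-amplified body-wide coupling plus phase-modulated cycler
    coupling: the scenario for day/night topology and ZT06-vs-ZT18
    network comparison."""
    return SimulationConfig(
        n_genes=300,
        n_organs=20,
        shared_factor_strength=1.0,
        night_amplification=0.5,
        cycler_factor_coupling=1.2,
        seed=seed + 1,
    )


def comparison_atlas_config(seed: int) -> SimulationConfig:
    """ZT06-vs-ZT18 comparison scenario: cyclers rewire through
    phase-modulated coupling to the organ factor; no body-wide loading, so
    arrhythmic genes keep their neighbourhoods."""
    return SimulationConfig(
        n_genes=300,
        n_organs=25,
        cycler_factor_coupling=1.2,
        seed=seed + 4,
    )


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=RESULTS)
    return parser.parse_args()
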