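"""Reference study designs for validating the calibration workflow.

These configurations pin down the simulated campaigns used throughout the
package's validation: a 26-sample / 21-cultivation mixing-series campaign at
the standard design levels {0, 25, 50, 75, 100}% w/w with 1 % proportional
ΔC noise, its noiseless counterpart for exact parameter recovery, and a
15-sample paired-volume study with a true container factor of 1.33 and 2 %
pairing noise. The generator truths are the legacy viable-cell-analyzer
constants β₁ = 1.67 pF/cm per g/kg and β₂ = 9.49 pF/cm.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .sample_data import Dataset
from .synthetic_fermentation import (
    LEGACY_ANALYZER,
    GroundTruth,
    SimulationConfig,
    UniformLaw,
    simulate_campaign,
    simulate_paired_volumes,
)

__all__ = [
    "reference_campaign_config",
    "noiseless_recovery_config",
    "paired_volume_study",
    "VOLUME_FACTOR_TRUE",
]

# container conversion factor used as truth in the paired-volume study
VOLUME_FACTOR_TRUE = 1.33


def reference_campaign_config(seed: int = 42) -> SimulationConfig:
    """Full-size calibration campaign: 26 samples, 21 cultivations, 1 % noise.

    Viable fractions are drawn Uniform(0.4, 1) with one sample forced fully
    viable; CDW spans 5–50 g/kg; no precipitate, so the drawn α is the viable
    fraction of total dry weight.
    """
    return SimulationConfig(
        n_samples=26,
        n_cultivations=21,
        alpha_law=UniformLaw(0.4, 1.0),
        cdw_range=(5.0, 50.0),
        precipitate_law=None,
        force_full_viability=True,
        instrument=LEGACY_ANALYZER,  # noise_cv 0.01
        seed=seed,
    )


def noiseless_recovery_config(seed: int = 3) -> SimulationConfig:
    """10-sample noiseless campaign for exact recovery of the instrument truth.

    α spread over [0.3, 1] with one sample at 1, no measurement or weighing
    noise: the fit must return the generator's β₁ and β₂ exactly.
    """
    return SimulationConfig(
        n_samples=10,
        n_cultivations=10,
        alpha_law=UniformLaw(0.3, 1.0),
        cdw_range=(5.0, 50.0),
        precipitate_law=None,
        force_full_viability=True,
        weighing_sd=0.0,
        instrument=replace(LEGACY_ANALYZER, noise_cv=0.0),
        seed=seed,
    )


def paired_volume_study(seed: int = 7) -> pd.DataFrame:
    """15 fresh samples read at both container volumes, k_true 1.33, 2 % noise."""
    cfg = replace(
        reference_campaign_config(seed=seed), n_samples=15, n_cultivations=15
    )
    dataset, _ = simulate_campaign(cfg)
    return simulate_paired_volumes(
        dataset, k_true=VOLUME_FACTOR_TRUE, noise_cv=0.02, seed=seed
    )
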