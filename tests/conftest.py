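from dataclasses import replace

import pytest

from viacal import (
    Dataset,
    FreshSample,
    LEGACY_ANALYZER,
    Phase,
    SampleMix,
    SimulationConfig,
    UniformLaw,
    simulate_campaign,
)

# instruments with the noise switched off, for exact-recovery fixtures
NOISELESS_LEGACY = replace(LEGACY_ANALYZER, noise_cv=0.0)


@pytest.fixture
def example_a() -> tuple[Dataset, dict]:
    """Three noiseless mixing series with known truth.

    alpha = (1, 0.5, 0.8), cdw = (10, 20, 15), beta1 = 2, beta2 = 5,
    mix levels {0, 0.5, 1}; every ΔC lies exactly on the model line.
    """
    truth = {"beta1": 2.0, "beta2": 5.0, "alpha": {"S0": 1.0, "S1": 0.5, "S2": 0.8}}
    cdws = {"S0": 10.0, "S1": 20.0, "S2": 15.0}
    samples = [
        FreshSample(sid, "C1", Phase.EARLY, "inst", 2.0, cdw) for sid, cdw in cdws.items()
    ]
    mixes = [
        SampleMix.from_fraction(
            sid, m, truth["beta1"] * truth["alpha"][sid] * m * cdws[sid] + truth["beta2"]
        )
        for sid in cdws
        for m in (0.0, 0.5, 1.0)
    ]
    return Dataset(samples=samples, mixes=mixes), truth


def noiseless_campaign_config(n_samples: int = 10, seed: int = 3) -> SimulationConfig:
    """Noiseless campaign from the legacy-analyzer truth, one sample fully viable."""
    return SimulationConfig(
        n_samples=n_samples,
        n_cultivations=max(1, n_samples - 2),
        alpha_law=UniformLaw(0.3, 1.0),
        precipitate_law=None,
        force_full_viability=True,
        weighing_sd=0.0,
        instrument=NOISELESS_LEGACY,
        seed=seed,
    )


@pytest.fixture
def noiseless_campaign():
    return simulate_campaign(noiseless_campaign_config())
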