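"""Synthetic calibration campaigns with the structure of a viability-control study.

The generator replaces the industrial dataset such a calibration study would
use (raw plant data are typically confidential) with campaigns that carry the
same statistical structure:

* ``n_samples`` fresh broth samples spread over ``n_cultivations`` production
  cultivations and three fermentation phases (early / middle / decline);
* each sample mixed gravimetrically with its own heat-killed portion at the
  design fractions (default 0, 25, 50, 75, 100 % w/w), the achieved fraction
  perturbed by weighing error and recorded exactly via the weighed masses;
* a latent viable fraction ``alpha`` per sample, drawn from a phase-dependent
  law; late (decline) phase samples can additionally carry insoluble
  precipitate that inflates CDW without contributing any permittivity —
  the mechanism that breaks naive CDW-vs-ΔC calibration;
* permittivity increments following the linear membrane-capacitance model
  ``ΔC = β₁ · α · m · CDW + β₂`` with heteroscedastic Gaussian noise whose
  standard deviation is ``noise_cv`` times the noiseless ΔC.

Killing removes no solids, so the CDW of every mixture equals the fresh
sample's CDW, and the m = 0 (fully killed) point reads the background β₂.

Determinism: one global seed; per-sample sub-streams are spawned from it so
that adding samples does not shift the draws of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .sample_data import Dataset, FreshSample, Phase, SampleMix

__all__ = [
    "InstrumentProfile",
    "UniformLaw",
    "SimulationConfig",
    "GroundTruth",
    "simulate_campaign",
    "simulate_paired_volumes",
    "LEGACY_ANALYZER",
    "PROBE_2ML",
    "PROBE_100ML",
    "INSTRUMENT_PROFILES",
]


@dataclass(frozen=True)
class InstrumentProfile:
    """A named instrument/container configuration used as generator truth.

    ``beta1_true`` (pF/cm per g/kg) and ``beta2_true`` (pF/cm) are the true
    slope and heat-kill background of the linear ΔC model; ``noise_cv`` is the
    relative standard deviation of the measurement noise.
    """

    instrument_id: str
    container_volume_ml: float
    beta1_true: float
    beta2_true: float
    noise_cv: float = 0.01
    frequency_info: str = ""

    def __post_init__(self) -> None:
        if self.beta1_true <= 0:
            raise ValueError("beta1_true must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.container_volume_ml <= 0:
            raise ValueError("container_volume_ml must be > 0")


# Default instrument truths: slope/intercept pairs typical of a legacy 2 mL
# at-line viable-cell analyzer and a dual-frequency annular probe read in
# 2 mL and 100 mL presentations of the same broth.
LEGACY_ANALYZER = InstrumentProfile(
    "viable_cell_analyzer", 2.0, 1.67, 9.49, frequency_info="cell-free background subtraction"
)
PROBE_2ML = InstrumentProfile(
    "annular_probe_2ml", 2.0, 0.89, 11.91, frequency_info="dual frequency 580/15650 kHz"
)
PROBE_100ML = InstrumentProfile(
    "annular_probe_100ml", 100.0, 1.18, 15.84, frequency_info="dual frequency 580/15650 kHz"
)
INSTRUMENT_PROFILES: Mapping[str, InstrumentProfile] = {
    p.instrument_id: p for p in (LEGACY_ANALYZER, PROBE_2ML, PROBE_100ML)
}


@dataclass(frozen=True)
class UniformLaw:
    """Uniform(low, high) distribution spec used for alpha and precipitate draws."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if self.high < self.low:
            raise ValueError(f"UniformLaw requires low <= high, got ({self.low}, {self.high})")

    def sample(self, rng: np.random.Generator, size=None):
        return rng.uniform(self.low, self.high, size=size)


AlphaLaw = Union[UniformLaw, Mapping[Phase, UniformLaw]]

# Phase-dependent default viability: high early, degrading toward decline.
DEFAULT_ALPHA_LAW: Mapping[Phase, UniformLaw] = {
    Phase.EARLY: UniformLaw(0.85, 1.0),
    Phase.MIDDLE: UniformLaw(0.6, 0.95),
    Phase.DECLINE: UniformLaw(0.3, 0.8),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Design of a synthetic calibration campaign.

    Defaults mirror a production-scale study design: 26 samples over 21
    cultivations, mixing levels {0, 0.25, 0.5, 0.75, 1} w/w, 0.05 g weighing
    error per portion, 1 % proportional ΔC noise, and decline-phase
    precipitate reaching up to half of the biological dry weight.
    """

    n_samples: int = 26
    n_cultivations: int = 21
    phase_mix: Mapping[Phase, float] = field(
        default_factory=lambda: {Phase.EARLY: 0.35, Phase.MIDDLE: 0.40, Phase.DECLINE: 0.25}
    )
    cdw_range: tuple[float, float] = (5.0, 50.0)
    alpha_law: AlphaLaw = field(default_factory=lambda: dict(DEFAULT_ALPHA_LAW))
    force_full_viability: bool = True
    precipitate_law: Optional[UniformLaw] = UniformLaw(0.1, 0.5)
    mix_levels: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0)
    weighing_sd: float = 0.05
    mix_total_mass: float = 100.0
    instrument: InstrumentProfile = LEGACY_ANALYZER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_cultivations < 1:
            raise ValueError("n_samples and n_cultivations must be >= 1")
        if not self.mix_levels:
            raise ValueError("mix_levels must be non-empty")
        levels = sorted(self.mix_levels)
        if any(m < 0 or m > 1 for m in levels):
            raise ValueError(f"mix_levels must lie in [0, 1], got {list(self.mix_levels)}")
        if levels[0] != 0.0 or levels[-1] != 1.0:
            raise ValueError("mix_levels must include 0 (fully killed) and 1 (fresh)")
        total = sum(self.phase_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phase_mix must sum to 1, got {total}")
        lo, hi = self.cdw_range
        if not (0 < lo <= hi):
            raise ValueError(f"cdw_range must satisfy 0 < low <= high, got {self.cdw_range}")
        if self.weighing_sd < 0:
            raise ValueError("weighing_sd must be >= 0")
        if self.mix_total_mass <= 0:
            raise ValueError("mix_total_mass must be > 0")

    def alpha_law_for(self, phase: Phase) -> UniformLaw:
        if isinstance(self.alpha_law, UniformLaw):
            return self.alpha_law
        return self.alpha_law[phase]


@dataclass
class GroundTruth:
    """Per-sample latent truth plus the global instrument constants.

    For every sample ``cdw = cdw_viable + cdw_dead + precipitate`` and
    ``alpha = cdw_viable / cdw`` (the viable fraction of *total* dry weight,
    precipitate included).
    """

    alpha_true: dict[str, float]
    cdw_viable_true: dict[str, float]
    cdw_dead_true: dict[str, float]
    precipitate_true: dict[str, float]
    beta1_true: float
    beta2_true: float

    def frame(self) -> pd.DataFrame:
        ids = list(self.alpha_true)
        return pd.DataFrame(
            {
                "sample_id": ids,
                "alpha_true": [self.alpha_true[i] for i in ids],
                "cdw_viable_true": [self.cdw_viable_true[i] for i in ids],
                "cdw_dead_true": [self.cdw_dead_true[i] for i in ids],
                "precipitate_true": [self.precipitate_true[i] for i in ids],
            }
        )


def _assign_phases(config: SimulationConfig, rng: np.random.Generator) -> list[Phase]:
    """Deterministic phase counts from the proportions, order shuffled by rng."""
    phases = [Phase.EARLY, Phase.MIDDLE, Phase.DECLINE]
    weights = np.array([config.phase_mix.get(p, 0.0) for p in phases], dtype=float)
    counts = np.floor(weights * config.n_samples).astype(int)
    # distribute the remainder to the largest fractional parts
    frac = weights * config.n_samples - counts
    for i in np.argsort(-frac)[: config.n_samples - counts.sum()]:
        counts[i] += 1
    assigned = [p for p, c in zip(phases, counts) for _ in range(c)]
    rng.shuffle(assigned)
    return assigned


def simulate_campaign(config: SimulationConfig) -> tuple[Dataset, GroundTruth]:
    """Simulate one mixing-series calibration campaign.

    Returns the observable :class:`Dataset` (samples + mixing-series ΔC
    readings) and the latent :class:`GroundTruth`. Deterministic for a given
    ``config.seed``; per-sample randomness comes from spawned sub-streams so
    the draws for sample *i* do not depend on ``n_samples``.
    """
    root_ss = np.random.SeedSequence(config.seed)
    # one child for campaign-level draws, then one per sample
    campaign_ss, *sample_ss = root_ss.spawn(config.n_samples + 1)
    campaign_rng = np.random.default_rng(campaign_ss)

    phases = _assign_phases(config, campaign_rng)
    prof = config.instrument

    samples: list[FreshSample] = []
    mixes: list[SampleMix] = []
    alpha_true: dict[str, float] = {}
    viable: dict[str, float] = {}
    dead: dict[str, float] = {}
    precip: dict[str, float] = {}

    force_idx = 0 if config.force_full_viability else -1

    for i, (phase, ss) in enumerate(zip(phases, sample_ss)):
        rng = np.random.default_rng(ss)
        sid = f"S{i + 1:02d}"
        cult = f"C{(i % config.n_cultivations) + 1:02d}"

        cdw_bio = float(rng.uniform(*config.cdw_range))
        a_bio = float(config.alpha_law_for(phase).sample(rng))
        p_frac = 0.0
        if config.precipitate_law is not None and phase is Phase.DECLINE:
            p_frac = float(config.precipitate_law.sample(rng))
        if i == force_idx:
            # guarantee one fully viable sample so the max-alpha normalization
            # of the downstream fit coincides with the generator truth
            a_bio, p_frac = 1.0, 0.0

        precipitate = p_frac * cdw_bio
        cdw_total = cdw_bio + precipitate
        cdw_viable = a_bio * cdw_bio
        alpha = cdw_viable / cdw_total

        samples.append(
            FreshSample(
                sample_id=sid,
                cultivation_id=cult,
                phase=phase,
                instrument_id=prof.instrument_id,
                container_volume_ml=prof.container_volume_ml,
                cdw=cdw_total,
            )
        )
        alpha_true[sid] = alpha
        viable[sid] = cdw_viable
        dead[sid] = cdw_bio - cdw_viable
        precip[sid] = precipitate

        for m_target in config.mix_levels:
            mf = m_target * config.mix_total_mass
            mk = (1.0 - m_target) * config.mix_total_mass
            if config.weighing_sd > 0:
                # only portions actually dispensed carry weighing error
                if mf > 0:
                    mf = max(0.0, mf + rng.normal(0.0, config.weighing_sd))
                if mk > 0:
                    mk = max(0.0, mk + rng.normal(0.0, config.weighing_sd))
            m_actual = mf / (mf + mk)
            mu = prof.beta1_true * alpha * m_actual * cdw_total + prof.beta2_true
            dc = mu
            if prof.noise_cv > 0:
                dc = mu + rng.normal(0.0, prof.noise_cv * abs(mu))
            mixes.append(
                SampleMix(
                    sample_id=sid,
                    mass_fresh=mf,
                    mass_killed=mk,
                    m_frac=m_actual,
                    delta_c=float(dc),
                )
            )

    truth = GroundTruth(
        alpha_true=alpha_true,
        cdw_viable_true=viable,
        cdw_dead_true=dead,
        precipitate_true=precip,
        beta1_true=prof.beta1_true,
        beta2_true=prof.beta2_true,
    )
    return Dataset(samples=samples, mixes=mixes), truth


def simulate_paired_volumes(
    dataset: Dataset,
    k_true: float,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pair each fresh-sample ΔC with a simulated large-container reading.

    The large-container value is ``k_true * delta_c_small * (1 + ε)`` with
    ``ε ~ Normal(0, noise_cv²)`` — the pure-scalar container-wall model.

    Returns a DataFrame with columns ``sample_id, delta_c_small_pf_per_cm,
    delta_c_large_pf_per_cm``. Deterministic for a given seed.
    """
    if k_true <= 0:
        raise ValueError(f"k_true must be > 0, got {k_true}")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    fresh = dataset.fresh_points()
    if fresh.empty:
        raise ValueError("dataset has no fresh (m_frac = 1) points to pair")
    rng = np.random.default_rng(seed)
    small = fresh["delta_c"].to_numpy(dtype=float)
    eps = rng.normal(0.0, noise_cv, size=small.size) if noise_cv > 0 else np.zeros(small.size)
    large = k_true * small * (1.0 + eps)
    return pd.DataFrame(
        {
            "sample_id": fresh["sample_id"].to_numpy(),
            "delta_c_small_pf_per_cm": small,
            "delta_c_large_pf_per_cm": large,
        }
    )
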