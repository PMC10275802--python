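"""Domain types and CSV I/O for fresh/heat-killed mixing-series datasets.

A calibration campaign consists of *fresh samples* — broth samples drawn from
fermentation cultivations, each with a measured cell dry weight (CDW, g dry
solids per kg broth) — and *mixing series*: gravimetric mixtures of each fresh
sample with a heat-killed portion of itself. Because heat-killed material
retains its solids but loses the membrane-dependent permittivity signal, the
mixing series imposes a known relative gradient of viable biomass at constant
CDW, which is what makes the latent viable fraction identifiable downstream.

Two CSV tables describe a dataset:

``samples.csv``
    ``sample_id, cultivation_id, phase, instrument_id, container_volume_ml,
    cdw_g_per_kg``

``mixes.csv``
    ``sample_id, mass_fresh_g, mass_killed_g, m_frac (optional),
    delta_c_pf_per_cm, replicate``

Units are fixed: CDW in g/kg, permittivity increment ΔC in pF/cm, masses in
grams. The fresh mass fraction ``m_frac`` is derived from the weighed masses
whenever both mass columns are present; an explicit ``m_frac`` column is used
only when masses are absent (nominal design levels).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Phase",
    "FreshSample",
    "SampleMix",
    "Dataset",
    "DatasetFormatError",
    "read_dataset",
    "write_dataset",
    "SAMPLE_COLUMNS",
    "MIX_COLUMNS",
]

SAMPLE_COLUMNS = [
    "sample_id",
    "cultivation_id",
    "phase",
    "instrument_id",
    "container_volume_ml",
    "cdw_g_per_kg",
]
MIX_COLUMNS = [
    "sample_id",
    "mass_fresh_g",
    "mass_killed_g",
    "m_frac",
    "delta_c_pf_per_cm",
    "replicate",
]
_MIX_REQUIRED = ["sample_id", "delta_c_pf_per_cm"]

# m_frac recomputed from masses must agree with the stored value this tightly
M_FRAC_TOL = 1e-12


class DatasetFormatError(ValueError):
    """Raised when a CSV file does not conform to the documented schema."""


class Phase(str, Enum):
    """Fermentation phase of a fresh sample."""

    EARLY = "early"
    MIDDLE = "middle"
    DECLINE = "decline"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class FreshSample:
    """A fresh broth sample with its total cell dry weight.

    Parameters
    ----------
    sample_id
        Unique identifier within a dataset.
    cultivation_id
        The cultivation (fermentation run) the sample was drawn from; several
        samples may share one cultivation.
    phase
        Fermentation phase at sampling time.
    instrument_id
        Dielectric instrument used for all ΔC readings of this sample's series.
    container_volume_ml
        Sample presentation volume in mL (e.g. 2 or 100).
    cdw
        Cell dry weight of the fresh sample, g dry solids / kg broth. Includes
        dead cells and any insoluble non-biological solids.
    """

    sample_id: str
    cultivation_id: str
    phase: Phase
    instrument_id: str
    container_volume_ml: float
    cdw: float

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be a non-empty string")
        if not math.isfinite(self.cdw) or self.cdw < 0:
            raise ValueError(
                f"sample {self.sample_id!r}: cdw must be finite and >= 0, got {self.cdw}"
            )
        if not math.isfinite(self.container_volume_ml) or self.container_volume_ml <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: container_volume_ml must be > 0, "
                f"got {self.container_volume_ml}"
            )
        if not isinstance(self.phase, Phase):
            object.__setattr__(self, "phase", Phase(self.phase))


@dataclass(frozen=True)
class SampleMix:
    """One measured point of a mixing series.

    ``m_frac`` is the mass fraction of the fresh portion,
    ``mass_fresh / (mass_fresh + mass_killed)``; it is recomputed from the
    weighed masses when both are given and must then agree to within 1e-12.
    """

    sample_id: str
    mass_fresh: float
    mass_killed: float
    m_frac: float
    delta_c: float
    replicate: int = 0

    def __post_init__(self) -> None:
        total = self.mass_fresh + self.mass_killed
        if self.mass_fresh < 0 or self.mass_killed < 0:
            raise ValueError(f"mix for {self.sample_id!r}: masses must be >= 0")
        if total <= 0:
            raise ValueError(
                f"mix for {self.sample_id!r}: mass_fresh + mass_killed must be > 0"
            )
        if not (0.0 <= self.m_frac <= 1.0):
            raise ValueError(
                f"mix for {self.sample_id!r}: m_frac must lie in [0, 1], got {self.m_frac}"
            )
        if abs(self.m_frac - self.mass_fresh / total) > M_FRAC_TOL:
            raise ValueError(
                f"mix for {self.sample_id!r}: m_frac={self.m_frac} inconsistent with "
                f"masses ({self.mass_fresh} g fresh / {self.mass_killed} g killed)"
            )
        if not math.isfinite(self.delta_c):
            raise ValueError(f"mix for {self.sample_id!r}: delta_c must be finite")

    @classmethod
    def from_masses(
        cls,
        sample_id: str,
        mass_fresh: float,
        mass_killed: float,
        delta_c: float,
        replicate: int = 0,
    ) -> "SampleMix":
        total = mass_fresh + mass_killed
        if total <= 0:
            raise ValueError(
                f"mix for {sample_id!r}: mass_fresh + mass_killed must be > 0"
            )
        return cls(
            sample_id=sample_id,
            mass_fresh=mass_fresh,
            mass_killed=mass_killed,
            m_frac=mass_fresh / total,
            delta_c=delta_c,
            replicate=replicate,
        )

    @classmethod
    def from_fraction(
        cls,
        sample_id: str,
        m_frac: float,
        delta_c: float,
        total_mass: float = 1.0,
        replicate: int = 0,
    ) -> "SampleMix":
        """Build a mix from a nominal fraction, synthesizing consistent masses."""
        return cls(
            sample_id=sample_id,
            mass_fresh=m_frac * total_mass,
            mass_killed=(1.0 - m_frac) * total_mass,
            m_frac=m_frac,
            delta_c=delta_c,
            replicate=replicate,
        )


@dataclass
class Dataset:
    """A collection of fresh samples and their mixing-series measurements."""

    samples: list[FreshSample] = field(default_factory=list)
    mixes: list[SampleMix] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id(s): {dupes}")
        known = set(ids)
        orphans = sorted({m.sample_id for m in self.mixes} - known)
        if orphans:
            raise ValueError(f"mixes reference unknown sample_id(s): {orphans}")

    def sample(self, sample_id: str) -> FreshSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def mixes_for(self, sample_id: str) -> list[SampleMix]:
        return [m for m in self.mixes if m.sample_id == sample_id]

    def calibratable_ids(self) -> list[str]:
        """Sample ids with >= 2 distinct mixing fractions (fit precondition)."""
        out = []
        for s in self.samples:
            fracs = {m.m_frac for m in self.mixes_for(s.sample_id)}
            if len(fracs) >= 2:
                out.append(s.sample_id)
        return out

    def fresh_points(self) -> pd.DataFrame:
        """ΔC of the undiluted (m_frac == 1) points, one row per reading."""
        rows = [
            {
                "sample_id": m.sample_id,
                "delta_c": m.delta_c,
                "cdw": self.sample(m.sample_id).cdw,
                "phase": self.sample(m.sample_id).phase.value,
            }
            for m in self.mixes
            if m.m_frac == 1.0
        ]
        return pd.DataFrame(rows, columns=["sample_id", "delta_c", "cdw", "phase"])

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "cultivation_id": s.cultivation_id,
                    "phase": s.phase.value,
                    "instrument_id": s.instrument_id,
                    "container_volume_ml": s.container_volume_ml,
                    "cdw_g_per_kg": s.cdw,
                }
                for s in self.samples
            ],
            columns=SAMPLE_COLUMNS,
        )

    def mixes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": m.sample_id,
                    "mass_fresh_g": m.mass_fresh,
                    "mass_killed_g": m.mass_killed,
                    "m_frac": m.m_frac,
                    "delta_c_pf_per_cm": m.delta_c,
                    "replicate": m.replicate,
                }
                for m in self.mixes
            ],
            columns=MIX_COLUMNS,
        )

    def __len__(self) -> int:
        return len(self.samples)


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{what}: missing required column(s) {missing}")


def read_dataset(
    samples_path: Union[str, Path],
    mixes_path: Union[str, Path],
    strict: bool = True,
) -> Dataset:
    """Read and validate a dataset from its two CSV tables.

    Parameters
    ----------
    samples_path, mixes_path
        Paths to the samples and mixes CSV files (UTF-8, comma-separated,
        '.' decimal, header row mandatory).
    strict
        If True (default), any invalid row raises with a message naming the
        row. If False, invalid rows are dropped with a logged warning.

    Returns
    -------
    Dataset
        Validated dataset; ``m_frac`` is computed from the mass columns when
        both are present, otherwise taken from an explicit ``m_frac`` column.
    """
    # round_trip parsing so written float64 values are recovered bit-exactly
    samples_df = pd.read_csv(samples_path, float_precision="round_trip")
    mixes_df = pd.read_csv(mixes_path, float_precision="round_trip")
    _require_columns(samples_df, [c for c in SAMPLE_COLUMNS], "samples CSV")
    _require_columns(mixes_df, _MIX_REQUIRED, "mixes CSV")
    has_masses = {"mass_fresh_g", "mass_killed_g"} <= set(mixes_df.columns)
    if not has_masses and "m_frac" not in mixes_df.columns:
        raise DatasetFormatError(
            "mixes CSV: need either mass_fresh_g + mass_killed_g or m_frac"
        )

    samples: list[FreshSample] = []
    for idx, row in samples_df.iterrows():
        try:
            samples.append(
                FreshSample(
                    sample_id=str(row["sample_id"]),
                    cultivation_id=str(row["cultivation_id"]),
                    phase=Phase(str(row["phase"])),
                    instrument_id=str(row["instrument_id"]),
                    container_volume_ml=float(row["container_volume_ml"]),
                    cdw=float(row["cdw_g_per_kg"]),
                )
            )
        except (ValueError, KeyError) as exc:
            if strict:
                raise DatasetFormatError(f"samples CSV row {idx}: {exc}") from exc
            logger.warning("dropping samples CSV row %d: %s", idx, exc)

    mixes: list[SampleMix] = []
    for idx, row in mixes_df.iterrows():
        try:
            replicate = int(row["replicate"]) if "replicate" in mixes_df.columns else 0
            if has_masses:
                mix = SampleMix.from_masses(
                    sample_id=str(row["sample_id"]),
                    mass_fresh=float(row["mass_fresh_g"]),
                    mass_killed=float(row["mass_killed_g"]),
                    delta_c=float(row["delta_c_pf_per_cm"]),
                    replicate=replicate,
                )
            else:
                mix = SampleMix.from_fraction(
                    sample_id=str(row["sample_id"]),
                    m_frac=float(row["m_frac"]),
                    delta_c=float(row["delta_c_pf_per_cm"]),
                    replicate=replicate,
                )
            mixes.append(mix)
        except ValueError as exc:
            if strict:
                raise DatasetFormatError(f"mixes CSV row {idx}: {exc}") from exc
            logger.warning("dropping mixes CSV row %d: %s", idx, exc)

    known = {s.sample_id for s in samples}
    orphans = [m for m in mixes if m.sample_id not in known]
    if orphans:
        orphan_ids = sorted({m.sample_id for m in orphans})
        if strict:
            raise DatasetFormatError(
                f"mixes CSV references unknown sample_id(s): {orphan_ids}"
            )
        logger.warning("dropping mixes with unknown sample_id(s): %s", orphan_ids)
        mixes = [m for m in mixes if m.sample_id in known]

    return Dataset(samples=samples, mixes=mixes)


def write_dataset(
    dataset: Dataset,
    samples_path: Union[str, Path],
    mixes_path: Union[str, Path],
) -> None:
    """Write a dataset to its two CSV tables; round-trips with read_dataset."""
    dataset.validate()
    # %.17g guarantees exact float64 round-trip through the text format
    dataset.samples_frame().to_csv(samples_path, index=False, float_format="%.17g")
    dataset.mixes_frame().to_csv(mixes_path, index=False, float_format="%.17g")
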