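"""Scalar conversion between ΔC read at different sample-presentation volumes.

A capacitance probe reads a lower permittivity increment in a small (2 mL)
tube than in a large (100 mL) container of the same broth, because container
walls close to the electrode attenuate the field. Empirically the two
readings are proportional, so a single dimensionless factor k converts
small-volume readings to the large-volume scale:

    ΔC_large ≈ k · ΔC_small .

Two estimators are provided. The default, through-origin least squares on
paired readings of the same fresh samples, honours the proportional model
exactly (k = Σxy / Σx²). The alternative takes the ratio of the β₁ slopes of
two independent calibrations performed at each volume — under the pure-scalar
model both estimators target the same k, which is a useful cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .viability_calibration import CalibrationResult

__all__ = [
    "VolumeTransferResult",
    "estimate_volume_factor",
    "slope_ratio_factor",
    "apply_volume_factor",
]


@dataclass
class VolumeTransferResult:
    """Estimated container-volume conversion factor.

    ``k`` is dimensionless (large-volume ΔC per unit small-volume ΔC);
    ``se_k`` is its standard error from the through-origin residuals and
    ``r_squared`` the coefficient of determination of the fit (computed about
    the mean of the large-volume readings).
    """

    k: float
    se_k: float
    r_squared: float
    n_pairs: int
    method: str = "origin_ls"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if self.method == "origin_ls" and self.n_pairs < 2:
            raise ValueError("origin_ls requires n_pairs >= 2")

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "se_k": self.se_k,
            "r_squared": self.r_squared,
            "n_pairs": self.n_pairs,
            "method": self.method,
        }


def _extract_pairs(pairs: Union[pd.DataFrame, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, pd.DataFrame):
        x = pairs["delta_c_small_pf_per_cm"].to_numpy(dtype=float)
        y = pairs["delta_c_large_pf_per_cm"].to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("paired ΔC values must all be finite")
    return x, y


def estimate_volume_factor(pairs: Union[pd.DataFrame, np.ndarray]) -> VolumeTransferResult:
    """Through-origin least squares of large-volume on small-volume ΔC.

    Parameters
    ----------
    pairs
        DataFrame with columns ``delta_c_small_pf_per_cm`` and
        ``delta_c_large_pf_per_cm``, or an (n, 2) array of (small, large)
        pairs. At least two pairs are required.

    Returns
    -------
    VolumeTransferResult
        with ``k = Σxy / Σx²``, its residual-based standard error, and the R²
        of the proportional fit.
    """
    x, y = _extract_pairs(pairs)
    if x.size < 2:
        raise ValueError(f"need >= 2 pairs, got {x.size}")
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("degenerate pairs: all small-volume ΔC are zero")
    k = float(np.sum(x * y) / sxx)
    resid = y - k * x
    sse = float(resid @ resid)
    # residual variance with one fitted parameter
    sigma2 = sse / (x.size - 1)
    se_k = float(np.sqrt(sigma2 / sxx))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0.0 and sse == 0.0 else 1.0 - sse / sst
    return VolumeTransferResult(k=k, se_k=se_k, r_squared=r2, n_pairs=int(x.size))


def slope_ratio_factor(
    calib_small: CalibrationResult,
    calib_large: CalibrationResult,
) -> tuple[float, float]:
    """Conversion factor implied by two independent volume-specific calibrations.

    Returns ``(beta1_large / beta1_small, beta2_large / beta2_small)``. Under
    the pure-scalar container model both ratios estimate the same k, so their
    agreement cross-checks that model.
    """
    if calib_small.beta1 <= 0 or calib_large.beta1 <= 0:
        raise ValueError("both calibrations must have beta1 > 0")
    k_slope = calib_large.beta1 / calib_small.beta1
    k_intercept = (
        calib_large.beta2 / calib_small.beta2 if calib_small.beta2 != 0 else float("nan")
    )
    return k_slope, k_intercept


def apply_volume_factor(
    delta_c_small: Union[float, np.ndarray],
    result: VolumeTransferResult,
) -> Union[float, np.ndarray]:
    """Convert small-volume ΔC reading(s) to the large-volume scale (k·ΔC)."""
    if result.k <= 0:
        raise ValueError("result.k must be > 0")
    scaled = result.k * np.asarray(delta_c_small, dtype=float)
    return float(scaled) if np.isscalar(delta_c_small) else scaled
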