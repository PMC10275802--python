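"""Viable-biomass calibration of dielectric permittivity increments.

The measurement model is a straight line between the permittivity increment
ΔC (pF/cm) and the viable biomass concentration X_viable (g/kg),

    ΔC = β₁ · X_viable + β₂ ,

with the heat-kill background β₂ as intercept. X_viable of a mixing-series
point is not observed directly, but for a mixture containing a mass fraction
``m`` of the fresh sample it is

    X_viable = α_s · m · CDW_s ,

where α_s ∈ [0, 1] is the latent viable fraction of the fresh sample's cell
dry weight. Fitting pools *all* points — fresh, mixed and fully killed — and
chooses β₁, β₂ and the α vector to maximize the pooled R² (equivalently,
minimize the pooled SSE).

Two solvers are provided and cross-check each other:

``closed_form_fit``
    The exact solution. With ``x_si = m_si · CDW_s`` the model is linear in
    the per-sample slopes ``a_s = β₁ α_s`` and the common intercept ``b``, so
    ordinary least squares on that design gives the global SSE minimum;
    bounded least squares handles the α ≥ 0 boundary when a fitted slope is
    negative. The α vector is identifiable only up to a common scalar
    (scaling α by c and β₁ by 1/c leaves every prediction unchanged), so the
    reported solution is normalized to max(α) = 1 — the convention that at
    least one sample is fully viable.

``optimize_alpha``
    A bounded numerical search over α ∈ [0, 1]^S with β₁, β₂ profiled out by
    inner OLS, mirroring how the problem is posed as a constrained R²
    maximization. Multistart restarts plus one start at the closed-form
    oracle; used to demonstrate that generic constrained solvers reach the
    same optimum.

Also here: per-sample linearity checks of ΔC against the mixing fraction, the
naive CDW-vs-ΔC correlation diagnostics (whose breakdown in late phases is
the motivation for viability correction), cluster-bootstrap uncertainty, and
inverse prediction of viable biomass from ΔC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sample_data import Dataset
from .synthetic_fermentation import GroundTruth

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationResult",
    "LinearityReport",
    "CalibrationError",
    "per_sample_linearity",
    "pooled_r_squared",
    "closed_form_fit",
    "optimize_alpha",
    "bootstrap_uncertainty",
    "BootstrapResult",
    "predict_viable",
    "cdw_correlation_diagnostics",
]


class CalibrationError(RuntimeError):
    """Raised when a calibration cannot be computed (no viable signal, rank...)."""


@dataclass
class CalibrationResult:
    """Fitted calibration: instrument constants plus per-sample viable fractions.

    ``beta1`` is in pF/cm per g/kg, ``beta2`` in pF/cm. ``alpha`` maps
    sample_id to the viable fraction in [0, 1]. Under the default
    ``max_alpha_one`` normalization the largest α is exactly 1.
    """

    beta1: float
    beta2: float
    alpha: dict[str, float]
    r_squared: float
    sse: float
    n_points: int
    normalization: str = "max_alpha_one"
    method: str = "closed_form"
    se_beta1: float = 0.0
    se_beta2: float = 0.0
    alpha_raw: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s: a for s, a in self.alpha.items() if not (-1e-12 <= a <= 1 + 1e-12)}
        if bad:
            raise ValueError(f"alpha values outside [0, 1]: {bad}")
        self.alpha = {s: float(min(1.0, max(0.0, a))) for s, a in self.alpha.items()}

    def to_dict(self) -> dict:
        return {
            "beta1": self.beta1,
            "beta2": self.beta2,
            "se_beta1": self.se_beta1,
            "se_beta2": self.se_beta2,
            "r_squared": self.r_squared,
            "sse": self.sse,
            "n_points": self.n_points,
            "normalization": self.normalization,
            "method": self.method,
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        return cls(
            beta1=d["beta1"],
            beta2=d["beta2"],
            alpha=dict(d["alpha"]),
            r_squared=d["r_squared"],
            sse=d.get("sse", float("nan")),
            n_points=d.get("n_points", 0),
            normalization=d.get("normalization", "max_alpha_one"),
            method=d.get("method", "closed_form"),
            se_beta1=d.get("se_beta1", 0.0),
            se_beta2=d.get("se_beta2", 0.0),
        )


@dataclass
class LinearityReport:
    """Per-sample OLS of ΔC on the fresh mass fraction m."""

    table: pd.DataFrame  # sample_id, slope, intercept, r_squared, n_points
    excluded: list[str]  # samples with < 2 distinct m_frac

    def __iter__(self):
        return iter(self.table.itertuples(index=False))


def _design_arrays(dataset: Dataset, sample_ids: list[str]):
    """Stack mixing points as (sample index, m·CDW, m, ΔC) arrays."""
    idx_of = {s: i for i, s in enumerate(sample_ids)}
    rows = [m for m in dataset.mixes if m.sample_id in idx_of]
    s_idx = np.array([idx_of[m.sample_id] for m in rows], dtype=int)
    m = np.array([m.m_frac for m in rows], dtype=float)
    cdw = np.array([dataset.sample(r.sample_id).cdw for r in rows], dtype=float)
    y = np.array([m_.delta_c for m_ in rows], dtype=float)
    return s_idx, m * cdw, m, y


def per_sample_linearity(dataset: Dataset) -> LinearityReport:
    """Ordinary least squares of ΔC on m_frac, one line per mixing series.

    Each fresh sample's series should be affine in the mixing fraction with
    intercept near the heat-kill background; a low per-sample R² flags a
    series where mixing or measurement went wrong. Samples with fewer than
    two distinct mixing fractions are excluded and listed. A series with zero
    ΔC variance (e.g. a fully dead sample) reports slope 0 and R² = 0.
    """
    if not dataset.samples:
        raise ValueError("empty dataset")
    records = []
    excluded = []
    for s in dataset.samples:
        mixes = dataset.mixes_for(s.sample_id)
        fracs = np.array([m.m_frac for m in mixes], dtype=float)
        dcs = np.array([m.delta_c for m in mixes], dtype=float)
        if np.unique(fracs).size < 2:
            excluded.append(s.sample_id)
            continue
        if np.allclose(dcs, dcs[0]):
            records.append((s.sample_id, 0.0, float(dcs[0]), 0.0, len(mixes)))
            continue
        res = stats.linregress(fracs, dcs)
        records.append(
            (s.sample_id, float(res.slope), float(res.intercept), float(res.rvalue**2), len(mixes))
        )
    table = pd.DataFrame(
        records, columns=["sample_id", "slope", "intercept", "r_squared", "n_points"]
    )
    return LinearityReport(table=table, excluded=excluded)


def pooled_r_squared(
    dataset: Dataset,
    beta1: float,
    beta2: float,
    alpha: Mapping[str, float],
) -> tuple[float, float]:
    """Pooled R² and SSE of the calibration over all mixing points.

    Predictions are ``β₁ · α_s · m · CDW_s + β₂`` for every point — fresh,
    mixed and fully killed alike — and R² = 1 − SSE/SST with SST taken about
    the grand mean of the observed ΔC.
    """
    sample_ids = [s.sample_id for s in dataset.samples if dataset.mixes_for(s.sample_id)]
    missing = [s for s in sample_ids if s not in alpha]
    if missing:
        raise ValueError(f"alpha does not cover sample(s): {missing}")
    s_idx, x_mc, _, y = _design_arrays(dataset, sample_ids)
    a = np.array([alpha[s] for s in sample_ids], dtype=float)
    pred = beta1 * a[s_idx] * x_mc + beta2
    sse = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise CalibrationError("all observed ΔC identical: R² undefined (zero SST)")
    return 1.0 - sse / sst, sse


def _normalize(beta2, rho, sample_ids, sse, sst, n, method) -> CalibrationResult:
    """Turn raw per-sample ratios rho_s = β₁α_s into a max(α)=1 result."""
    rho = np.asarray(rho, dtype=float)
    # bounded least squares can leave numerically-zero residue on the boundary
    rho = np.where(rho < 1e-12, 0.0, rho)
    rho_max = rho.max()
    if rho_max <= 0:
        raise CalibrationError("no viable signal: all fitted slopes are <= 0")
    alpha = rho / rho_max
    return CalibrationResult(
        beta1=float(rho_max),
        beta2=float(beta2),
        alpha={s: float(a) for s, a in zip(sample_ids, alpha)},
        r_squared=1.0 - sse / sst,
        sse=float(sse),
        n_points=int(n),
        normalization="max_alpha_one",
        method=method,
        alpha_raw={s: float(r) for s, r in zip(sample_ids, rho)},
    )


def closed_form_fit(dataset: Dataset) -> CalibrationResult:
    """Exact maximizer of the pooled R² over (β₁, β₂, α ≥ 0).

    Reparameterize with per-sample coefficients ``ρ_s = β₁ α_s`` against the
    regressor ``x = m · CDW_s`` plus a common intercept: the model is then
    linear, so least squares gives the global optimum. If any fitted ρ_s is
    negative, the constrained optimum lies on the α = 0 boundary and is
    recovered exactly by bounded least squares (ρ ≥ 0, intercept free).
    Because the α vector is only identified up to scale, the result is
    normalized as β₁ = max_s ρ_s and α_s = ρ_s / β₁ (max-alpha-one).
    """
    sample_ids = [
        s
        for s in dataset.calibratable_ids()
        if dataset.sample(s).cdw > 0
    ]
    if not sample_ids:
        raise CalibrationError(
            "no calibratable sample (need >= 2 distinct m_frac and CDW > 0)"
        )
    s_idx, x_mc, _, y = _design_arrays(dataset, sample_ids)
    n_s = len(sample_ids)
    n = y.size

    # design: one column of m·CDW per sample (coefficient β₁α_s), plus intercept
    X = np.zeros((n, n_s + 1))
    X[np.arange(n), s_idx] = x_mc
    X[:, -1] = 1.0

    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < n_s + 1:
        raise CalibrationError(
            "singular design: some mixing series has effectively one level"
        )
    rho, beta2 = coef[:-1], coef[-1]
    if np.any(rho < 0):
        lb = np.r_[np.zeros(n_s), -np.inf]
        ub = np.full(n_s + 1, np.inf)
        sol = optimize.lsq_linear(X, y, bounds=(lb, ub))
        rho, beta2 = sol.x[:-1], sol.x[-1]

    sse = float(np.sum((y - X @ np.r_[rho, beta2]) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise CalibrationError("all observed ΔC identical: R² undefined (zero SST)")
    return _normalize(beta2, rho, sample_ids, sse, sst, n, "closed_form")


def _profile_sse(alpha: np.ndarray, s_idx, x_mc, y):
    """SSE with β₁, β₂ profiled out by OLS of ΔC on α_s·m·CDW."""
    x = alpha[s_idx] * x_mc
    X = np.column_stack([x, np.ones_like(x)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), float(coef[0]), float(coef[1])


def optimize_alpha(
    dataset: Dataset,
    init: Union[Mapping[str, float], str] = "oracle",
    tol: float = 1e-10,
    multistart: int = 8,
    seed: int = 0,
) -> CalibrationResult:
    """Numerical R² maximization over α ∈ [0, 1]^S (β profiled by inner OLS).

    The outer search is bounded L-BFGS-B, started once from the closed-form
    oracle (or a user-supplied ``init`` map) plus ``multistart`` seeded random
    restarts. The best solution is renormalized to max(α) = 1 and must reach
    the closed-form R² to within ``tol`` (the optimum is attainable, so a
    shortfall beyond tolerance is reported as non-convergence).
    """
    oracle = closed_form_fit(dataset)
    sample_ids = list(oracle.alpha)
    s_idx, x_mc, _, y = _design_arrays(dataset, sample_ids)
    sst = float(np.sum((y - y.mean()) ** 2))
    n_s = len(sample_ids)

    def objective(a):
        sse, _, _ = _profile_sse(a, s_idx, x_mc, y)
        return sse

    starts = []
    if isinstance(init, str):
        if init != "oracle":
            raise ValueError(f"init must be a mapping or 'oracle', got {init!r}")
        starts.append(np.array([oracle.alpha[s] for s in sample_ids]))
    else:
        starts.append(np.clip([init[s] for s in sample_ids], 0.0, 1.0))
        starts.append(np.array([oracle.alpha[s] for s in sample_ids]))
    rng = np.random.default_rng(seed)
    starts.extend(rng.uniform(0.05, 1.0, size=(multistart, n_s)))

    best = None
    traces = []
    for a0 in starts:
        res = optimize.minimize(
            objective,
            np.asarray(a0, dtype=float),
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * n_s,
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 2000},
        )
        traces.append(f"start SSE={objective(np.asarray(a0)):.6g} -> {res.fun:.6g} ({res.message})")
        # only solutions with a positive profiled slope describe a calibration;
        # the oracle start always provides one
        _, b1_cand, _ = _profile_sse(res.x, s_idx, x_mc, y)
        if b1_cand <= 0:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise CalibrationError(
            "optimizer found no solution with positive slope; trace:\n" + "\n".join(traces)
        )

    sse, b1, b2 = _profile_sse(best.x, s_idx, x_mc, y)
    r2 = 1.0 - sse / sst
    if r2 < oracle.r_squared - max(tol, 1e-8):
        raise CalibrationError(
            "optimizer failed to reach the closed-form optimum "
            f"(R² {r2:.10f} < {oracle.r_squared:.10f}); trace:\n" + "\n".join(traces)
        )
    rho = b1 * best.x  # β₁α_s on the raw scale of this solution
    result = _normalize(b2, rho, sample_ids, sse, sst, y.size, "optimizer")
    result.alpha_raw = {s: float(a) for s, a in zip(sample_ids, best.x)}
    return result


@dataclass
class BootstrapResult:
    se_beta1: float
    se_beta2: float
    alpha_intervals: pd.DataFrame  # sample_id, lo, hi, n_reps
    n_boot: int
    n_skipped: int


def bootstrap_uncertainty(
    dataset: Dataset,
    n_boot: int = 200,
    seed: int = 0,
    ci: float = 0.95,
) -> BootstrapResult:
    """Cluster-bootstrap standard errors for β₁, β₂ and α intervals.

    Whole mixing series are resampled with replacement (points within a
    series share the latent α, so the series is the exchangeable unit), the
    closed-form fit is recomputed, and standard deviations over replicates
    are reported. Replicates whose resample cannot be fitted (e.g. no viable
    sample drawn) are skipped and counted. Deterministic given ``seed``.

    Because β₁ and the α vector are only jointly identified up to scale, each
    replicate is aligned to the full-data normalization before aggregating:
    the replicate's α vector is rescaled by the least-squares scalar matching
    it to the full-data α over the drawn series, and β₁ is rescaled inversely
    (which leaves every prediction unchanged). Without this alignment the
    max-α convention alone would inject variance whenever a resample misses
    the most-viable sample, even on noise-free data.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50")
    base_ids = dataset.calibratable_ids()
    if not base_ids:
        raise CalibrationError("no calibratable sample")
    reference = closed_form_fit(dataset)
    rng = np.random.default_rng(seed)
    b1s, b2s = [], []
    alpha_draws: dict[str, list[float]] = {s: [] for s in base_ids}
    skipped = 0
    for _ in range(n_boot):
        picked = rng.choice(base_ids, size=len(base_ids), replace=True)
        samples, mixes = [], []
        for j, sid in enumerate(picked):
            clone = f"{sid}__b{j}"
            s = dataset.sample(sid)
            samples.append(
                type(s)(
                    sample_id=clone,
                    cultivation_id=s.cultivation_id,
                    phase=s.phase,
                    instrument_id=s.instrument_id,
                    container_volume_ml=s.container_volume_ml,
                    cdw=s.cdw,
                )
            )
            for m in dataset.mixes_for(sid):
                mixes.append(
                    type(m)(
                        sample_id=clone,
                        mass_fresh=m.mass_fresh,
                        mass_killed=m.mass_killed,
                        m_frac=m.m_frac,
                        delta_c=m.delta_c,
                        replicate=m.replicate,
                    )
                )
        try:
            fit = closed_form_fit(Dataset(samples=samples, mixes=mixes))
        except CalibrationError:
            skipped += 1
            continue
        a_rep = np.array(list(fit.alpha.values()))
        a_ref = np.array([reference.alpha[c.split("__b")[0]] for c in fit.alpha])
        denom = float(a_rep @ a_rep)
        if denom == 0.0:
            skipped += 1
            continue
        c_align = float(a_rep @ a_ref) / denom
        if c_align <= 0:
            skipped += 1
            continue
        b1s.append(fit.beta1 / c_align)
        b2s.append(fit.beta2)
        for clone, a in fit.alpha.items():
            alpha_draws[clone.split("__b")[0]].append(min(1.0, c_align * a))

    if not b1s:
        raise CalibrationError("every bootstrap replicate failed to fit")
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    intervals = pd.DataFrame(
        [
            {
                "sample_id": s,
                "lo": float(np.quantile(v, lo_q)) if v else np.nan,
                "hi": float(np.quantile(v, hi_q)) if v else np.nan,
                "n_reps": len(v),
            }
            for s, v in alpha_draws.items()
        ]
    )
    return BootstrapResult(
        se_beta1=float(np.std(b1s, ddof=1)),
        se_beta2=float(np.std(b2s, ddof=1)),
        alpha_intervals=intervals,
        n_boot=n_boot,
        n_skipped=skipped,
    )


def predict_viable(
    delta_c: Union[float, np.ndarray],
    calib: CalibrationResult,
    clip: bool = True,
) -> Union[float, np.ndarray]:
    """Invert the calibration line: X_viable = (ΔC − β₂) / β₁ in g/kg.

    Readings below the heat-kill background β₂ would imply negative biomass;
    they are clipped to 0 (with a logged warning) unless ``clip=False``.
    """
    if calib.beta1 <= 0:
        raise CalibrationError(f"beta1 must be > 0 to invert, got {calib.beta1}")
    scalar = np.isscalar(delta_c)
    x = (np.asarray(delta_c, dtype=float) - calib.beta2) / calib.beta1
    if clip:
        n_neg = int(np.sum(x < 0))
        if n_neg:
            logger.warning(
                "%d ΔC reading(s) below background β₂=%.4g clipped to 0 g/kg",
                n_neg,
                calib.beta2,
            )
        x = np.maximum(x, 0.0)
    return float(x) if scalar else x


def cdw_correlation_diagnostics(
    dataset: Dataset,
    truth: Optional[GroundTruth] = None,
    min_points: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of fresh-sample ΔC against total CDW, by phase.

    Total CDW is a good biomass proxy only while everything filterable is
    alive; once dead cells or insoluble precipitate accumulate (late phases)
    the ΔC-vs-CDW correlation degrades, which these per-phase correlations
    quantify. Groups with fewer than ``min_points`` fresh points are omitted
    with a warning. When ground truth is supplied, the correlation of ΔC with
    the true viable CDW is added as a reference column.
    """
    fresh = dataset.fresh_points()
    if fresh.empty:
        raise ValueError("dataset has no fresh (m_frac = 1) points")
    groups = [("overall", fresh)] + [
        (phase, sub) for phase, sub in fresh.groupby("phase", sort=True)
    ]
    rows = []
    for name, sub in groups:
        if len(sub) < min_points:
            warnings.warn(
                f"phase group {name!r} has only {len(sub)} fresh point(s); omitted",
                UserWarning,
                stacklevel=2,
            )
            continue
        r, _ = stats.pearsonr(sub["cdw"], sub["delta_c"])
        row = {"group": name, "n": len(sub), "r_cdw": float(r)}
        if truth is not None:
            viable = sub["sample_id"].map(truth.cdw_viable_true)
            r_v, _ = stats.pearsonr(viable, sub["delta_c"])
            row["r_viable_true"] = float(r_v)
        rows.append(row)
    return pd.DataFrame(rows)
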