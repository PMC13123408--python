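"""PRE titration analysis: rate tables, bulk averages and Γ slopes.

The paramagnetic relaxation enhancement of a dopant is quantified as the
slope Γ of the relaxation rate against dopant concentration:
R(c) = R(0) + c·Γ, fitted by ordinary least squares with a free intercept
(the diamagnetic rate).

Bulk averaging is over RATES: the bulk rate at one concentration is the
unweighted mean of the per-residue R values, and any bulk time constant is
reported as 1/mean(R).  This matters — mean(T) ≠ 1/mean(R) whenever the
per-residue values spread, so a bulk T assembled from the same data by
averaging time constants will differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .relaxation import RateFit

__all__ = [
    "TitrationSeries",
    "PREResult",
    "BulkRate",
    "bulk_rate",
    "fit_pre",
    "pre_pattern",
]


@dataclass
class BulkRate:
    """Unweighted mean of per-residue rates at one concentration."""

    rate: float
    rate_err: float
    n_residues: int

    @property
    def time_constant(self) -> float:
        return 1.0 / self.rate


@dataclass
class TitrationSeries:
    """Per-residue and bulk rates across a dopant concentration series.

    ``rates`` maps residue label -> {concentration (mM) -> RateFit}; a
    residue may be missing at concentrations where line broadening removed
    it (the per-residue grid need not match the bulk grid).  ``bulk_rates``
    maps concentration -> BulkRate and may cover concentrations with no
    per-residue data (merged-envelope measurements).
    """

    dopant: str
    quantity: str                                  # "R1" | "R2"
    rates: dict[str, dict[float, RateFit]] = field(default_factory=dict)
    bulk_rates: dict[float, BulkRate] = field(default_factory=dict)
    nucleus: str = "19F"

    def __post_init__(self) -> None:
        concs = set(self.bulk_rates)
        for per_res in self.rates.values():
            concs |= set(per_res)
        if concs and 0.0 not in concs:
            raise ValueError("titration must include the 0 mM diamagnetic reference")

    def add_rate(self, label: str, concentration: float, fit: RateFit) -> None:
        self.rates.setdefault(label, {})[float(concentration)] = fit

    def compute_bulk(self) -> None:
        """Fill ``bulk_rates`` from the per-residue table (rate averaging)."""
        concs = sorted({c for m in self.rates.values() for c in m})
        for c in concs:
            fits = [m[c] for m in self.rates.values() if c in m and m[c].success]
            if fits:
                self.bulk_rates[c] = bulk_rate(fits)


def bulk_rate(rates: Sequence[RateFit]) -> BulkRate:
    """Unweighted mean rate with the propagated standard error.

    The error combines the individual fit uncertainties in quadrature,
    σ_bulk = sqrt(Σ σᵢ²)/n; residues with unknown errors contribute zero.
    """
    if not rates:
        raise ValueError("need at least one per-residue rate")
    vals = np.array([f.rate for f in rates])
    errs = np.array([f.rate_err if math.isfinite(f.rate_err) else 0.0 for f in rates])
    n = vals.size
    return BulkRate(
        rate=float(np.mean(vals)),
        rate_err=float(np.sqrt(np.sum(errs**2)) / n),
        n_residues=int(n),
    )


@dataclass
class PREResult:
    """Fitted PRE: Γ = slope of R vs concentration, intercept = R(0)."""

    gamma: float            # s^-1 mM^-1
    intercept: float        # s^-1
    gamma_err: float        # Monte-Carlo, s^-1 mM^-1
    intercept_err: float
    gamma_err_ols: float    # analytic OLS standard error
    scope: str              # residue label or "bulk"
    dopant: str
    quantity: str
    n_points: int
    negative_slope_flag: bool = False


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept and their analytic standard errors."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    if n > 2:
        resid = y - (intercept + slope * x)
        s2 = float(np.sum(resid**2) / (n - 2))
        se_slope = math.sqrt(s2 / sxx)
        se_int = math.sqrt(s2 * (1.0 / n + xm**2 / sxx))
    else:
        se_slope = float("nan")
        se_int = float("nan")
    return slope, intercept, se_slope, se_int


def fit_pre(
    series: TitrationSeries,
    scope: str,
    n_mc: int = 500,
    seed: int | np.random.Generator | None = None,
    weighted: bool = False,
) -> PREResult:
    """Fit Γ for one residue (``scope`` = label) or the bulk (``scope`` = "bulk").

    Ordinary least squares with free intercept by default; an optional
    1/σ² weighting uses the rate errors.  The Γ uncertainty is obtained by
    Monte-Carlo resampling of the input rates within their errors (the
    analytic OLS error is reported alongside).  A negative fitted slope is
    allowed but flagged.
    """
    if scope == "bulk":
        items = sorted(series.bulk_rates.items())
        concs = np.array([c for c, _ in items])
        vals = np.array([b.rate for _, b in items])
        errs = np.array([b.rate_err for _, b in items])
    else:
        if scope not in series.rates:
            raise KeyError(f"residue {scope!r} not in titration")
        items = sorted(
            (c, f) for c, f in series.rates[scope].items() if f.success
        )
        concs = np.array([c for c, _ in items])
        vals = np.array([f.rate for _, f in items])
        errs = np.array(
            [f.rate_err if math.isfinite(f.rate_err) else 0.0 for _, f in items]
        )
    if concs.size < 2:
        raise ValueError(f"need at least 2 concentration points, got {concs.size}")

    if weighted and np.all(errs > 0):
        w = 1.0 / errs**2
        W = np.sum(w)
        xm = np.sum(w * concs) / W
        ym = np.sum(w * vals) / W
        sxx = np.sum(w * (concs - xm) ** 2)
        slope = float(np.sum(w * (concs - xm) * (vals - ym)) / sxx)
        intercept = float(ym - slope * xm)
        se_slope = math.sqrt(1.0 / sxx)
        se_int = math.sqrt(1.0 / W + xm**2 / sxx)
    else:
        slope, intercept, se_slope, se_int = _ols_line(concs, vals)

    # MC: resample each rate within its error, refit the line
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_mc > 0 and np.any(errs > 0):
        slopes = np.empty(n_mc)
        intercepts = np.empty(n_mc)
        for i in range(n_mc):
            y = vals + rng.normal(0.0, errs)
            s, b, _, _ = _ols_line(concs, y)
            slopes[i] = s
            intercepts[i] = b
        gamma_err = float(np.std(slopes))
        intercept_err = float(np.std(intercepts))
    else:
        gamma_err = 0.0
        intercept_err = 0.0

    return PREResult(
        gamma=slope,
        intercept=intercept,
        gamma_err=gamma_err,
        intercept_err=intercept_err,
        gamma_err_ols=se_slope,
        scope=scope,
        dopant=series.dopant,
        quantity=series.quantity,
        n_points=int(concs.size),
        negative_slope_flag=slope < 0,
    )


def pre_pattern(results: Mapping[str, PREResult], bulk: PREResult) -> dict[str, float]:
    """Per-residue Γ normalised by the bulk Γ.

    The resulting dimensionless pattern lets PREs be compared across
    conditions (Γ₁ vs Γ₂, nuclei, dopants) where absolute magnitudes differ
    by orders of magnitude.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 residues for a pattern")
    if bulk.gamma <= 0:
        raise ValueError(f"bulk gamma must be positive, got {bulk.gamma}")
    return {label: r.gamma / bulk.gamma for label, r in results.items()}
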