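"""Mono-exponential relaxation fits with Monte-Carlo error propagation.

Saturation-recovery series follow M(τ) = M∞ (1 − exp(−τ R₁)); echo decays
follow M(τ) = M₀ exp(−τ R₂).  The default saturation-recovery model has no
offset at τ = 0: a long presaturation train leaves no residual longitudinal
magnetisation, so the ideal-saturation two-parameter form is appropriate.
A three-parameter variant with a free offset is available behind a flag.

Uncertainties are propagated parametrically: synthetic series are drawn
around the best-fit curve with the measured spectral-noise σ, refitted, and
the standard deviation of the refitted rates reported (500 iterations by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .spectra import IntensitySeries

__all__ = [
    "RelaxationSeries",
    "RateFit",
    "fit_saturation_recovery",
    "fit_decay",
    "monte_carlo_errors",
    "simulate_series",
]


@dataclass
class RelaxationSeries:
    """One residue's intensity-vs-delay series, ready to fit."""

    label: str
    delays: np.ndarray       # s
    intensities: np.ndarray  # arbitrary units
    sigma: float             # noise standard deviation, same units
    experiment: str          # "satrec_T1" | "echo_T2"

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays.size < 4:
            raise ValueError("need at least 4 delay points")
        if np.unique(self.delays).size != self.delays.size:
            raise ValueError("delays must be distinct")
        if self.experiment not in ("satrec_T1", "echo_T2"):
            raise ValueError(f"unknown experiment {self.experiment!r}")

    @classmethod
    def from_intensity_series(cls, s: IntensitySeries) -> "RelaxationSeries":
        return cls(
            label=s.label,
            delays=s.delays,
            intensities=s.intensities,
            sigma=s.sigma,
            experiment=s.experiment,
        )


@dataclass
class RateFit:
    """Fitted relaxation rate with its Monte-Carlo uncertainty."""

    rate: float               # R, s^-1
    amplitude: float          # M_inf or M_0
    rate_err: float = float("nan")
    offset: float = 0.0
    n_mc: int = 0
    residual_rms: float = float("nan")
    success: bool = True
    message: str = ""
    label: str = ""
    experiment: str = ""

    @property
    def time_constant(self) -> float:
        """T = 1/R, exactly."""
        return 1.0 / self.rate


def _satrec(tau: np.ndarray, m_inf: float, r1: float) -> np.ndarray:
    return m_inf * (1.0 - np.exp(-tau * r1))


def _satrec_offset(tau: np.ndarray, m_inf: float, r1: float, off: float) -> np.ndarray:
    return off + (m_inf - off) * (1.0 - np.exp(-tau * r1))


def _decay(tau: np.ndarray, m0: float, r2: float) -> np.ndarray:
    return m0 * np.exp(-tau * r2)


def _failed(series: RelaxationSeries, message: str) -> RateFit:
    return RateFit(
        rate=float("nan"), amplitude=float("nan"), success=False,
        message=message, label=series.label, experiment=series.experiment,
    )


def fit_saturation_recovery(
    series: RelaxationSeries, with_offset: bool = False
) -> RateFit:
    """Fit M(τ) = M∞ (1 − e^{−τR₁}); returns R₁ (and T₁ = 1/R₁)."""
    if series.experiment != "satrec_T1":
        raise ValueError(f"expected satrec_T1 series, got {series.experiment!r}")
    tau, y = series.delays, series.intensities
    ymax = float(np.max(np.abs(y)))
    if ymax == 0.0:
        return _failed(series, "all-zero intensities")
    # crude R1 guess from the delay where recovery reaches ~63 %
    m_guess = float(np.max(y))
    above = tau[y >= 0.632 * m_guess]
    r_guess = 1.0 / float(above[0]) if above.size and above[0] > 0 else 1.0 / np.median(tau)
    try:
        if with_offset:
            popt, _ = curve_fit(
                _satrec_offset, tau, y, p0=[m_guess, r_guess, 0.0], maxfev=10000
            )
            m_inf, r1, off = popt
        else:
            popt, _ = curve_fit(_satrec, tau, y, p0=[m_guess, r_guess], maxfev=10000)
            m_inf, r1 = popt
            off = 0.0
    except RuntimeError as exc:
        return _failed(series, f"non-convergence: {exc}")
    if r1 <= 0 or not np.isfinite(r1):
        return _failed(series, f"non-physical fitted R1 = {r1}")
    model = _satrec_offset(tau, m_inf, r1, off)
    return RateFit(
        rate=float(r1), amplitude=float(m_inf), offset=float(off),
        residual_rms=float(np.sqrt(np.mean((y - model) ** 2))),
        label=series.label, experiment=series.experiment,
    )


def fit_decay(series: RelaxationSeries) -> RateFit:
    """Fit M(τ) = M₀ e^{−τR₂}; returns R₂ (and T₂ = 1/R₂)."""
    if series.experiment != "echo_T2":
        raise ValueError(f"expected echo_T2 series, got {series.experiment!r}")
    tau, y = series.delays, series.intensities
    if float(np.max(np.abs(y))) == 0.0:
        return _failed(series, "all-zero intensities")
    m_guess = float(y[np.argmin(tau)])
    if m_guess <= 0:
        m_guess = float(np.max(np.abs(y)))
    # log-linear guess on the positive points
    pos = y > 0
    if pos.sum() >= 2:
        slope = np.polyfit(tau[pos], np.log(y[pos]), 1)[0]
        r_guess = max(-float(slope), 1.0 / float(np.max(tau)))
    else:
        r_guess = 1.0 / float(np.median(tau))
    try:
        popt, _ = curve_fit(_decay, tau, y, p0=[m_guess, r_guess], maxfev=10000)
    except RuntimeError as exc:
        return _failed(series, f"non-convergence: {exc}")
    m0, r2 = popt
    if r2 <= 0 or not np.isfinite(r2):
        return _failed(series, f"non-physical fitted R2 = {r2}")
    model = _decay(tau, m0, r2)
    return RateFit(
        rate=float(r2), amplitude=float(m0),
        residual_rms=float(np.sqrt(np.mean((y - model) ** 2))),
        label=series.label, experiment=series.experiment,
    )


def _refit(series: RelaxationSeries, fit: RateFit) -> RateFit:
    if series.experiment == "satrec_T1":
        return fit_saturation_recovery(series, with_offset=fit.offset != 0.0)
    return fit_decay(series)


def best_fit_curve(series: RelaxationSeries, fit: RateFit) -> np.ndarray:
    """Model intensities at the series' delays for a successful fit."""
    if series.experiment == "satrec_T1":
        return _satrec_offset(series.delays, fit.amplitude, fit.rate, fit.offset)
    return _decay(series.delays, fit.amplitude, fit.rate)


def monte_carlo_errors(
    series: RelaxationSeries,
    fit: RateFit,
    n_iter: int = 500,
    seed: int | np.random.Generator | None = None,
) -> RateFit:
    """Parametric Monte-Carlo rate uncertainty.

    Draws ``n_iter`` synthetic series (best-fit curve + Gaussian noise of
    the measured σ), refits each, and attaches the standard deviation of
    the refitted rates as ``rate_err``.  More than 10 % failed refits
    flags the result.
    """
    if not fit.success:
        raise ValueError("cannot propagate errors for a failed fit")
    if series.sigma <= 0:
        return replace(fit, rate_err=0.0, n_mc=n_iter)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    curve = best_fit_curve(series, fit)
    rates = []
    failures = 0
    for _ in range(n_iter):
        noisy = curve + rng.normal(0.0, series.sigma, size=curve.shape)
        synthetic = replace(series, intensities=noisy)
        f = _refit(synthetic, fit)
        if f.success:
            rates.append(f.rate)
        else:
            failures += 1
    result = replace(
        fit, rate_err=float(np.std(rates)) if rates else float("nan"), n_mc=n_iter
    )
    if failures > 0.1 * n_iter:
        result.success = False
        result.message = f"{failures}/{n_iter} Monte-Carlo refits failed"
    return result


def simulate_series(
    label: str,
    experiment: str,
    rate: float,
    delays: np.ndarray,
    amplitude: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> RelaxationSeries:
    """Ground-truth mono-exponential series with optional Gaussian noise."""
    delays = np.asarray(delays, dtype=float)
    if experiment == "satrec_T1":
        y = _satrec(delays, amplitude, rate)
    elif experiment == "echo_T2":
        y = _decay(delays, amplitude, rate)
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    if noise_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, size=y.shape)
    return RelaxationSeries(
        label=label, delays=delays, intensities=y,
        sigma=max(noise_sigma, 1e-12), experiment=experiment,
    )
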