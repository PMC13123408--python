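"""Lorentzian peak models, synthetic 1D spectra and pseudo-2D intensity extraction.

A relaxation measurement on a rotating solid yields a pseudo-2D data set:
one frequency dimension (chemical shift, ppm) and one pseudo dimension in
which a relaxation delay τ is incremented.  Each slice is modelled as a sum
of Lorentzian peaks — the lineshape of an exponentially decaying signal —
plus white Gaussian noise.  Peak heights extracted slice-by-slice form the
intensity series that the relaxation-fitting stage consumes.

The Lorentzian is parameterised in height-normalised form

    L(ν) = A (w/2)² / ((ν − ν₀)² + (w/2)²)

with ν in Hz (ppm × spectrometer frequency in MHz), so the full width at
half maximum w links directly to the transverse rate via w = R₂/π.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import lmfit
import numpy as np

__all__ = [
    "AxisSpec",
    "Spectrum1D",
    "PeakModel",
    "PseudoTwoD",
    "PeakFitResult",
    "simulate_spectrum",
    "estimate_noise",
    "fit_peaks",
    "extract_intensity_series",
    "write_p2d",
    "read_p2d",
]


@dataclass(frozen=True)
class AxisSpec:
    """Chemical-shift axis: ppm runs from ``ppm_max`` down to ``ppm_min``."""

    ppm_max: float = -120.0
    ppm_min: float = -128.0
    n_points: int = 1024
    sfrq_MHz: float = 564.6   # 19F at 14.09 T
    nucleus: str = "19F"

    def __post_init__(self) -> None:
        if self.n_points < 64:
            raise ValueError("axis needs at least 64 points")
        if self.ppm_max <= self.ppm_min:
            raise ValueError("ppm_max must exceed ppm_min")

    def ppm(self) -> np.ndarray:
        return np.linspace(self.ppm_max, self.ppm_min, self.n_points)

    @property
    def hz_per_ppm(self) -> float:
        return self.sfrq_MHz

    @property
    def step_hz(self) -> float:
        return abs(self.ppm_max - self.ppm_min) / (self.n_points - 1) * self.sfrq_MHz


@dataclass
class Spectrum1D:
    """One 1D spectrum: ppm axis (descending, uniform) and intensities."""

    axis: np.ndarray
    intensity: np.ndarray
    nucleus: str = "19F"
    sfrq_MHz: float = 564.6
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.size < 64:
            raise ValueError("axis needs at least 64 points")
        d = np.diff(self.axis)
        if not (np.all(d < 0) or np.all(d > 0)):
            raise ValueError("axis must be strictly monotone")
        if self.axis.shape != self.intensity.shape:
            raise ValueError("axis and intensity lengths differ")


@dataclass(frozen=True)
class PeakModel:
    """One Lorentzian peak: position (ppm), width (Hz), height (a.u.)."""

    label: str
    position: float     # ppm
    fwhm: float         # Hz
    amplitude: float    # peak height, arbitrary units

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be positive, got {self.fwhm}")


@dataclass
class PseudoTwoD:
    """Ordered stack of 1D slices, one per relaxation delay."""

    delays: np.ndarray                  # s, strictly increasing
    slices: list[Spectrum1D]
    experiment: str                     # "satrec_T1" | "echo_T2"
    dopant: str = "none"
    concentration: float = 0.0          # mM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        if self.delays.size < 4:
            raise ValueError("need at least 4 relaxation delays")
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if np.any(self.delays < 0):
            raise ValueError("delays must be non-negative")
        if len(self.slices) != self.delays.size:
            raise ValueError("one slice per delay required")
        if self.experiment not in ("satrec_T1", "echo_T2"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        ax0 = self.slices[0].axis
        for s in self.slices[1:]:
            if not np.array_equal(s.axis, ax0):
                raise ValueError("all slices must share one axis")


def _lorentzian_hz(nu: np.ndarray, amplitude: float, nu0: float, fwhm: float) -> np.ndarray:
    hw = 0.5 * fwhm
    return amplitude * hw * hw / ((nu - nu0) ** 2 + hw * hw)


def simulate_spectrum(
    peaks: Sequence[PeakModel],
    axis: AxisSpec | None = None,
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> Spectrum1D:
    """Sum of Lorentzians on the given axis plus i.i.d. Gaussian noise.

    Peaks narrower than two axis steps are under-sampled; the spectrum is
    still produced but carries a ``narrow_peaks`` warning in its metadata.
    """
    if not peaks:
        raise ValueError("peak list must not be empty")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    labels = [p.label for p in peaks]
    if len(set(labels)) != len(labels):
        raise ValueError("peak labels must be unique")
    axis = axis or AxisSpec()
    ppm = axis.ppm()
    nu = ppm * axis.sfrq_MHz  # Hz
    y = np.zeros_like(nu)
    narrow = []
    for p in peaks:
        if p.fwhm < 2.0 * axis.step_hz:
            narrow.append(p.label)
        y += _lorentzian_hz(nu, p.amplitude, p.position * axis.sfrq_MHz, p.fwhm)
    if noise_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, size=y.shape)
    meta: dict = {}
    if narrow:
        meta["narrow_peaks"] = narrow
    return Spectrum1D(ppm, y, nucleus=axis.nucleus, sfrq_MHz=axis.sfrq_MHz, meta=meta)


def estimate_noise(spectrum: Spectrum1D, signal_free_region: tuple[float, float]) -> float:
    """Standard deviation of the intensity inside a signal-free ppm interval."""
    lo, hi = sorted(signal_free_region)
    amin, amax = spectrum.axis.min(), spectrum.axis.max()
    if hi < amin or lo > amax:
        raise ValueError(
            f"region ({lo}, {hi}) ppm lies outside the axis ({amin}, {amax}) ppm"
        )
    mask = (spectrum.axis >= lo) & (spectrum.axis <= hi)
    if mask.sum() < 32:
        raise ValueError(f"signal-free region contains only {int(mask.sum())} points (< 32)")
    return float(np.std(spectrum.intensity[mask]))


@dataclass
class PeakFitResult:
    """Refined peaks plus per-peak height, resolvability and diagnostics."""

    peaks: list[PeakModel]
    intensities: dict[str, float]
    resolvable: dict[str, bool]
    success: bool
    message: str = ""
    redchi: float = float("nan")


def fit_peaks(
    spectrum: Spectrum1D,
    initial: Sequence[PeakModel],
    lock_positions: bool = False,
    lock_fwhm: bool = False,
) -> PeakFitResult:
    """Nonlinear least-squares refinement of a multi-Lorentzian model.

    A peak is flagged unresolvable when its fitted linewidth (Hz) exceeds
    the distance to its nearest neighbour (Hz): at that point the two
    envelopes have merged past the point where independent heights mean
    anything.  Non-convergence is reported through ``success``/``message``,
    never silently.
    """
    if not initial:
        raise ValueError("need at least one initial peak")
    amin, amax = spectrum.axis.min(), spectrum.axis.max()
    for p in initial:
        if not (amin <= p.position <= amax):
            raise ValueError(f"initial peak {p.label!r} at {p.position} ppm is off-axis")
    sf = spectrum.sfrq_MHz
    nu = spectrum.axis * sf

    params = lmfit.Parameters()
    for i, p in enumerate(initial):
        params.add(f"a{i}", value=p.amplitude, min=0.0)
        params.add(f"p{i}", value=p.position * sf, vary=not lock_positions)
        params.add(f"w{i}", value=p.fwhm, min=1e-6, vary=not lock_fwhm)

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        model = np.zeros_like(nu)
        for i in range(len(initial)):
            model += _lorentzian_hz(nu, pars[f"a{i}"].value, pars[f"p{i}"].value, pars[f"w{i}"].value)
        return model - spectrum.intensity

    out = lmfit.minimize(residual, params, method="leastsq")
    fitted: list[PeakModel] = []
    for i, p in enumerate(initial):
        fitted.append(
            PeakModel(
                label=p.label,
                # locked parameters are returned verbatim, untouched by unit
                # round-trips, so reference positions/widths propagate exactly
                position=p.position if lock_positions else out.params[f"p{i}"].value / sf,
                fwhm=p.fwhm if lock_fwhm else out.params[f"w{i}"].value,
                amplitude=out.params[f"a{i}"].value,
            )
        )
    resolvable: dict[str, bool] = {}
    for p in fitted:
        if len(fitted) == 1:
            resolvable[p.label] = True
            continue
        nearest = min(
            abs(p.position - q.position) * sf for q in fitted if q.label != p.label
        )
        resolvable[p.label] = p.fwhm <= nearest
    return PeakFitResult(
        peaks=fitted,
        intensities={p.label: p.amplitude for p in fitted},
        resolvable=resolvable,
        success=bool(out.success),
        message="" if out.success else str(out.message),
        redchi=float(out.redchi) if out.redchi is not None else float("nan"),
    )


def extract_intensity_series(
    p2d: PseudoTwoD,
    reference_peaks: Sequence[PeakModel],
    noise_region: tuple[float, float] | None = None,
) -> dict[str, "IntensitySeries"]:
    """Per-peak intensity vs delay from a pseudo-2D stack.

    The reference slice (largest total signal) is fitted with free
    positions and widths; those are then locked and only heights are
    refitted on every slice, which keeps low-signal slices stable and the
    series well defined.  Noise σ comes from ``estimate_noise`` on each
    slice when a region is given, otherwise from the residual scatter of
    the reference fit.
    """
    totals = [float(np.sum(np.abs(s.intensity))) for s in p2d.slices]
    iref = int(np.argmax(totals))
    ref_fit = fit_peaks(p2d.slices[iref], reference_peaks)
    if not ref_fit.success:
        raise RuntimeError(f"reference-slice fit failed: {ref_fit.message}")
    locked = ref_fit.peaks

    n = p2d.delays.size
    out: dict[str, IntensitySeries] = {}
    values = {p.label: np.empty(n) for p in locked}
    sigmas = np.empty(n)
    flags: list[str] = []
    for j, sl in enumerate(p2d.slices):
        fr = fit_peaks(sl, locked, lock_positions=True, lock_fwhm=True)
        if not fr.success:
            flags.append(f"slice {j}: {fr.message}")
        for lbl, v in fr.intensities.items():
            values[lbl][j] = v
        if noise_region is not None:
            sigmas[j] = estimate_noise(sl, noise_region)
        else:
            model = np.zeros_like(sl.intensity)
            nu = sl.axis * sl.sfrq_MHz
            for p in fr.peaks:
                model += _lorentzian_hz(nu, p.amplitude, p.position * sl.sfrq_MHz, p.fwhm)
            sigmas[j] = float(np.std(sl.intensity - model))
    sigma = float(np.mean(sigmas))
    for p in locked:
        out[p.label] = IntensitySeries(
            label=p.label,
            delays=p2d.delays.copy(),
            intensities=values[p.label],
            sigma=sigma,
            experiment=p2d.experiment,
            resolvable=ref_fit.resolvable[p.label],
            flags=list(flags),
        )
    return out


@dataclass
class IntensitySeries:
    """Extracted heights of one peak across the delay dimension."""

    label: str
    delays: np.ndarray
    intensities: np.ndarray
    sigma: float
    experiment: str
    resolvable: bool = True
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# P2D-CSV interchange: JSON manifest + CSV matrix (rows = delays)
# ---------------------------------------------------------------------------

def write_p2d(p2d: PseudoTwoD, directory: str | Path, name: str) -> tuple[Path, Path]:
    """Write one pseudo-2D set as ``<name>.json`` + ``<name>.csv``.

    The matrix is written at 17 significant digits so float64 values
    round-trip bit-exactly; the axis is stored as its generating
    parameters and rebuilt identically on read.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    s0 = p2d.slices[0]
    manifest = {
        "format": "P2D-CSV",
        "experiment": p2d.experiment,
        "dopant": p2d.dopant,
        "concentration_mM": p2d.concentration,
        "delays_s": [float(d) for d in p2d.delays],
        "axis": {
            "ppm_max": float(s0.axis[0]),
            "ppm_min": float(s0.axis[-1]),
            "n_points": int(s0.axis.size),
            "sfrq_MHz": s0.sfrq_MHz,
            "nucleus": s0.nucleus,
        },
        "meta": p2d.meta,
    }
    jpath = directory / f"{name}.json"
    cpath = directory / f"{name}.csv"
    jpath.write_text(json.dumps(manifest, indent=1))
    matrix = np.vstack([s.intensity for s in p2d.slices])
    np.savetxt(cpath, matrix, delimiter=",", fmt="%.17g")
    return jpath, cpath


def read_p2d(manifest_path: str | Path) -> PseudoTwoD:
    """Read a P2D-CSV bundle written by :func:`write_p2d`."""
    jpath = Path(manifest_path)
    manifest = json.loads(jpath.read_text())
    if manifest.get("format") != "P2D-CSV":
        raise ValueError(f"{jpath} is not a P2D-CSV manifest")
    ax = manifest["axis"]
    axis = np.linspace(ax["ppm_max"], ax["ppm_min"], ax["n_points"])
    matrix = np.loadtxt(jpath.with_suffix(".csv"), delimiter=",", ndmin=2)
    slices = [
        Spectrum1D(axis, row, nucleus=ax["nucleus"], sfrq_MHz=ax["sfrq_MHz"])
        for row in matrix
    ]
    return PseudoTwoD(
        delays=np.asarray(manifest["delays_s"]),
        slices=slices,
        experiment=manifest["experiment"],
        dopant=manifest["dopant"],
        concentration=manifest["concentration_mM"],
        meta=manifest.get("meta", {}),
    )
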