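# Methods

## Physical model

The paramagnetic relaxation enhancement (PRE) of a nucleus at distance r
from an unpaired electron is modelled with the Solomon–Bloembergen
dipolar terms only:

    Γ₁ = (2/15)(μ₀/4π)² γ_I² g_e² μ_B² S(S+1) r⁻⁶ [3J(ω_I) + 7J(ω_e)]
    Γ₂ = (1/15)(μ₀/4π)² γ_I² g_e² μ_B² S(S+1) r⁻⁶ [4τ_c + 3J(ω_I) + 13J(ω_e)]

with the Lorentzian spectral density J(ω) = τ_c/(1+ω²τ_c²).  Since
J(ω) ≤ τ_c, the adiabatic 4τ_c term guarantees Γ₂ ≥ Γ₁ for every
parameter set, with equality in the extreme-narrowing limit ω_e τ_c ≪ 1;
the test suite asserts both.  Curie-spin, contact-shift and
cross-correlated contributions are out of scope, as is inner-sphere
water-exchange modelling: for dissolved Gd³⁺ chelates acting on protein
nuclei the dipolar outer-sphere term is the dominant, interpretable part.

Constants are CODATA: μ₀ = 4π×10⁻⁷ T·m/A, μ_B = 9.2740100783×10⁻²⁴ J/T,
ħ = 1.054571817×10⁻³⁴ J·s, g_e = 2.00232, γ(¹H) = 2.6752218744×10⁸,
γ(¹⁹F) = 2.51815×10⁸, γ(¹³C) = 6.728284×10⁷ rad·s⁻¹·T⁻¹.  The electron
Larmor frequency is derived as ω_e = g_e μ_B B₀/ħ (the standard relation;
nothing else in the model needs ħ except the dipolar coupling constant).
Electron spin defaults to S = 7/2 (Gd³⁺).  τ_c is a free parameter: it is
chelate- and environment-specific and rarely known; the documented default
of 100 ps is a plausible order of magnitude for a small Gd³⁺ complex and
must be overridden for quantitative predictions.  All internal units are
SI; the public surfaces use Å, s and mM.

## Spectra and intensity extraction

1D slices are sums of height-normalised Lorentzians
A·(w/2)²/((ν−ν₀)²+(w/2)²) with ν in Hz (ppm × spectrometer MHz).  A pure
Lorentzian is used because it is the lineshape of an exponential decay
and keeps the linewidth–rate link exact: fwhm = R₂/π.  Noise is additive
i.i.d. Gaussian per point, seed-controlled.

Peak refinement is nonlinear least squares (lmfit/Levenberg–Marquardt)
on the multi-Lorentzian model.  For a pseudo-2D stack the reference slice
(largest total signal) is fitted with free positions and widths; those
are then locked and only amplitudes are refitted per slice.  Locking
stabilises low-signal slices and makes the per-peak intensity series well
defined; "intensity" is the fitted height, which under locked widths is
proportional to the integral anyway.  A peak is flagged unresolvable when
its fitted width (Hz) exceeds the distance to its nearest neighbour; this
reproduces the loss of per-residue information at high concentrations of
the stronger chelate (8 mM × 556.2 s⁻¹mM⁻¹ ≈ 1.4 kHz of extra width
against ~620 Hz peak spacings).

The default synthetic ¹⁹F axis spans −120 to −128 ppm with 1024 points at
564.6 MHz (¹⁹F at 14.09 T); the four tryptophan peaks sit at −122.3,
−123.4, −124.6 and −125.9 ppm (W276/W136/W106/W164).  These shift values
are invented plumbing — the real spectrum shows four resolved peaks but
their shifts are not tabulated — and are configurable; they are flagged in
`StudyDesign.non_measured_defaults`.

Interchange is the P2D-CSV pair: a JSON manifest (experiment, dopant,
concentration, delays, axis parameters) plus a CSV matrix (rows = delays)
written at 17 significant digits, giving a bit-exact float64 round trip.

## Relaxation fitting and errors

Saturation recovery is fitted as M(τ) = M∞(1−e^(−τR₁)) with no offset:
a repeated presaturation train justifies ideal saturation at τ = 0, and
the two-parameter model is better conditioned than the three-parameter
variant (available behind `with_offset=True`).  Echo decays are
M(τ) = M₀e^(−τR₂).  Initial guesses come from the 63 %-recovery delay /
log-linear slope; failures (non-convergence, non-positive rate, all-zero
input) are returned as flagged results, never silently.

Uncertainties are parametric Monte Carlo: 500 synthetic series per fit
(best-fit curve + Gaussian noise at the measured spectral σ), each refit;
the rate error is the standard deviation of the refitted rates.  The
resampling is around the best-fit curve rather than a residual bootstrap,
matching the noise-based error philosophy of the fitting chain.  More
than 10 % failed refits flags the result.  Calibration is tested: over
200 simulated series (T₁ ∈ [0.5, 8] s, σ = 2 %), the median T₁ bias is
below 1 % and ~68 % of true rates fall within ±1 reported error.

## Titration analysis

Γ is the ordinary-least-squares slope of R versus concentration with a
free intercept (the diamagnetic rate).  OLS is unweighted by default
(a 1/σ² option exists); the Γ error is obtained by Monte-Carlo resampling
of the input rates within their individual errors (500 draws, seeded),
with the analytic OLS standard error reported alongside.

**Bulk averaging is over rates**: the bulk at one concentration is the
unweighted mean of per-residue R values and bulk T = 1/mean(R).  This is
stated prominently because mean(T) ≠ 1/mean(R): for diamagnetic T₁ values
of {2.6, 6.0, 1.67, 2.5} s, rate averaging gives a bulk T₁ of 2.58 s
while time-constant averaging gives 3.19 s.  Quoted "bulk T₁" values for
such samples conventionally follow the time-constant average, so the
end-to-end sensitivity report prints both conventions side by side.

Missing data are simply omitted: a residue broadened beyond resolution at
some concentration drops out of that residue's fit, while the bulk fit
uses the merged-envelope rate (fitted as a single peak) at that point.
On complete data the bulk slope equals the mean of per-residue slopes
exactly (linearity of OLS); with missing per-residue points the two
diverge, and the divergence is surfaced rather than hidden.

## Sensitivity

Signal per transient after recycle delay τ is 1−e^(−τ/T₁) (90° pulses,
direct excitation), so SNR per unit time goes as f(x) = (1−e^(−x))/√x
with x = τ/T₁.  The maximizer x* ≈ 1.2564 is computed numerically
(`optimal_factor`); reported recycle delays use the conventional rounded
factor τ_opt = 1.26·T₁ so that the arithmetic matches how such numbers
are quoted, while the exact maximizer is always available.  Because
f(x*) is T₁-independent, the equal-SNR measurement-time ratio between
two samples is simply T₁(ref)/T₁(doped).

## Structure descriptors

d_rss for a tryptophan is √(Σⱼ d(F,Hⱼ)²) with the dipolar coupling
constant d = (μ₀/4π)γ_F γ_H ħ/(2π r³) in Hz.  The ¹⁹F position is
approximated by the CZ3 atom (the 5-position of the indole ring, the
labelled site); the ~1.3 Å C–F bond offset is below the descriptor's
interpretive precision.  The proton set spans the full assembly (all
chains) by default, since the dodecamer is the biological unit; a
monomer mode exists by passing a single-chain model.

Back-exchangeable protons are the backbone amide H plus hydrogens on
side-chain N/O/S — the set reprotonated when a perdeuterated protein is
exchanged into H₂O.  With explicit hydrogens the selection is geometric
(nearest heavy atom within 1.3 Å is N/O/S).  Without hydrogens, amide H
is constructed 1.01 Å from N along the C(i−1)→O(i−1) direction reversed
(trans to the preceding carbonyl, the classic peptide-plane placement;
prolines and chain starts are skipped), and side-chain exchangeables are
placed 1.0 Å from their heavy atom directed away from the residue
centroid, one placed proton per expected hydrogen (protons of NH₂/NH₃
groups share the idealized position — a documented simplification that
slightly overweights those sites).

SASA uses a sphere-point (Shrake–Rupley-style) algorithm via biotite with
a 1.4 Å probe, 960 points per atom and van-der-Waals radii H 1.2, C 1.7,
N 1.55, O 1.52, S 1.8 Å; per-residue SASA is the sum over the residue's
atoms computed in the context of the full assembly.  The test suite
checks the implementation against the analytic isolated-sphere area and
an independent dense-point numerical integration for a two-atom overlap.

Descriptor–PRE association uses the Pearson coefficient with a two-sided
permutation p-value; for n ≤ 7 residues all n! permutations are
enumerated (24 for four tryptophans), so the null is exact.

## Synthetic study generator

The generator emulates the measured study conditions: four ¹⁹F
tryptophan peaks; Gd(DTPA-BMA) at {0, 2, 4, 6, 8, 16} mM and Gd(DTPA) at
{0, 2, 8} mM; diamagnetic T₁ = {2.6, 6.0, 1.67, 2.5} s for
W106/W136/W164/W276 (the W136/W164 values are the measured extremes;
W106/W276 are invented); diamagnetic T₂ = 5 ms for all residues
(invented; typical for a rigid solid-state ¹⁹F line of ~64 Hz); bulk
Γ₁ = 0.101 / 0.743 and Γ₂ = 38.2 / 556.2 s⁻¹mM⁻¹ for Gd(DTPA-BMA) /
Gd(DTPA).  Per-residue slopes are only known graphically for the real
system, so the generator draws multiplicative perturbations of ±30 %
around the bulk with the mean constrained to the bulk exactly, and
records the result as ground truth.  Rates follow R(c) = R(0) + c·Γ
exactly; linewidths follow fwhm = R₂/π; amplitudes follow the
mono-exponential laws; noise is 2 % of the maximum clean signal.

Delay grids are 12 log-spaced points over 0.01–20 s (T₁) and 10 over
0.1–50 ms (T₂), chosen to bracket every time constant occurring in the
design.  ¹³C variants can be generated with Γ scaled by (γ_C/γ_F)²,
consistent with the γ² dependence of the forward model; this default is
likewise flagged as non-measured.  All randomness fans out
deterministically from one root seed (`numpy.random.SeedSequence`), so a
fixed seed reproduces every spectrum bit-for-bit.

What the generator does **not** emulate: static baseline/phase artefacts,
MAS sidebands, cross-polarisation transfer efficiency, temperature
effects, dopant–protein binding (the linear PRE model is exact by
construction), or non-Lorentzian lineshapes.  Passing closed-loop tests
therefore demonstrates the correctness and calibration of the analysis
chain under its own model assumptions, not robustness to every artefact
of real spectra.

## Problem sizes and numerical choices

Stochastic validations use 100 seeded repeats (T₁ recovery, PRE slope
recovery) and 100–500 Monte-Carlo iterations per fit; the closed-loop
end-to-end test uses a reduced 60 Monte-Carlo iterations per rate, which
is enough to make the ±3σ recovery criterion meaningful while keeping
the suite quick.  Curve fits use scipy's Levenberg–Marquardt with
data-driven initial guesses; peak fits bound amplitudes and widths below
by 0 (widths by 10⁻⁶ Hz).  Degenerate inputs (all-zero series, empty peak
lists, sub-2-point titrations, regions off the axis) raise or flag
rather than returning silent numbers.

## Known limitations

* The fluorine proxy at CZ3 ignores the C–F bond vector; d_rss values
  carry a corresponding systematic offset.
* Constructed exchangeable protons use idealized geometry; for
  hydrogen-less crystal structures the d_rss of residues near many
  side-chain amines is approximate.
* The envelope fit at resolution-lost concentrations treats the merged
  band as one Lorentzian; its "bulk" rate is an effective quantity and
  agrees with the mean of the underlying rates only approximately.
* The sensitivity model assumes 90° direct excitation; Ernst-angle
  optimization for small flip angles is out of scope.
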