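# predope

Paramagnetic-doping analysis for ¹⁹F/¹³C magic-angle-spinning (MAS) NMR of
proteins.

¹⁹F-excited MAS NMR of fluorine-labelled proteins (e.g. a
5-fluorotryptophan-labelled dodecameric aminopeptidase) is often limited by
long longitudinal relaxation: with T₁ of several seconds, the optimal
recycle delay τ_opt = 1.26·T₁ dominates the experiment time.  Doping the
buffer with a Gd³⁺ chelate such as Gd(DTPA-BMA) or Gd(DTPA) accelerates
relaxation by a concentration-proportional paramagnetic relaxation
enhancement (PRE), buying sensitivity — as long as the transverse rate R₂,
and with it the linewidth R₂/π, is not degraded past the point where peaks
merge.

`predope` is a library + CLI for everyone running or planning such
experiments.  It covers the full analysis chain:

* **Forward model** — Solomon–Bloembergen PREs for an electron spin S
  (7/2 for Gd³⁺) at distance r from the nucleus:

  Γ₁ = (2/15)(μ₀/4π)² γ_I² g_e² μ_B² S(S+1) r⁻⁶ [3J(ω_I) + 7J(ω_e)]
  Γ₂ = (1/15)(μ₀/4π)² γ_I² g_e² μ_B² S(S+1) r⁻⁶ [4τ_c + 3J(ω_I) + 13J(ω_e)]

  with J(ω) = τ_c/(1 + ω²τ_c²).
* **Spectra** — Lorentzian peak models, pseudo-2D relaxation series
  (frequency × incremented delay), nonlinear least-squares peak fitting
  with locked positions/widths, noise estimation, a plain-text P2D-CSV
  interchange format.
* **Relaxation fitting** — mono-exponential saturation-recovery (T₁) and
  echo-decay (T₂) fits with parametric Monte-Carlo errors (500 iterations).
* **PRE titration** — per-residue and bulk Γ₁/Γ₂ as ordinary
  least-squares slopes of R vs dopant concentration (mM).
* **Sensitivity** — recycle-delay optimization (the 1.26 factor is
  re-derived by maximizing SNR per unit time, (1−e⁻ˣ)/√x), time gains,
  linewidth budgets.
* **Structure descriptors** — per-tryptophan root-sum-square ¹⁹F–¹H
  dipolar coupling (d_rss) to back-exchangeable protons and
  solvent-accessible surface area (SASA) from a PDB model, with
  permutation-test correlation against measured PREs.
* **Synthetic studies** — a seeded generator producing a complete
  in-silico titration with known ground truth, used by the test suite for
  closed-loop validation.

## Worked example

Predict PREs for a ¹⁹F nucleus 10 Å from a Gd³⁺ centre (τ_c = 100 ps,
14.09 T):

```
$ predope sbm --tau-c 1e-10 --r 10
gamma1_s-1 = 122.357
gamma2_s-1 = 153.017
```

Γ₂ ≥ Γ₁ always; here both are ~10² s⁻¹ because r⁻⁶ makes 10 Å a strong
coupling distance.

Quantify what doping buys: bulk T₁ drops from 3.2 s (undoped) to 0.92 s
(8 mM Gd(DTPA-BMA), R₂ ≈ 505.6 s⁻¹):

```
$ predope sensitivity --t1-ref 3.2 --t1-doped 0.92 --r2-doped 505.6
{
 "tau_opt_ref_s": 4.032,
 "tau_opt_doped_s": 1.1592,
 "recycle_delay_fold_change": 3.4782608695652173,
 "exact_optimal_factor": 1.2564311711525813,
 "linewidth_doped_Hz": 160.93747845452458
}
```

The recycle delay shrinks from ~4.0 s to ~1.2 s — a more than 3-fold
speed-up — while the linewidth stays near 161 Hz, well below the ~620 Hz
peak spacing of the four tryptophan signals.

Closed-loop validation on a synthetic study (generate noisy spectra →
extract peak intensities → fit rates → fit PRE slopes):

```python
from predope import default_design, end_to_end

report = end_to_end(default_design(seed=7), n_mc=60)
g = report.pre_results[("Gd(DTPA-BMA)", "R2")]["bulk"]
print(f"bulk Gamma2 = {g.gamma:.1f} +/- {g.gamma_err:.1f} /s/mM")
# bulk Gamma2(Gd(DTPA-BMA)) = 37.8 +/- 1.3 /s/mM (6 points)
# max |z| of recovered PREs vs ground truth: 0.30
```

The generator's ground truth for this slope is 38.2 s⁻¹mM⁻¹; the full
pipeline recovers it within one reported error.

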