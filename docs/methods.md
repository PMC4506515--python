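# Methods

This note documents the models behind each `confex` module, the defaults of
the synthetic-data generators, and the numerical and design choices that
were genuinely open.

## Two-state exchange model

Every NMR observable derives from one structure: a spin exchanging between
environments 1 and 2 with equilibrium populations p₁ + p₂ = 1, resonance
offsets δ₁, δ₂ (Hz), transverse relaxation R₂,₁, R₂,₂ (s⁻¹) and total
exchange rate k_ex = k₁₂ + k₂₁. Detailed balance fixes the microscopic
rates, k₁₂ = p₂k_ex and k₂₁ = p₁k_ex. All temperatures are Kelvin
internally; interfaces accept °C with a 273.15 offset. Physical constants
are CODATA 2018 values.

### Line shapes

Transverse magnetization evolves as dM/dt = AM with
A = i·diag(2πδ₁, 2πδ₂) − diag(R₂,₁, R₂,₂) + K, K the exchange matrix. The
absorption spectrum is the resolvent S(ω) = Re[1ᵀ(iωI − A)⁻¹p], evaluated
in closed form for the 2×2 case. Its integrated area is independent of
k_ex; in the uncoupled limit it is two Lorentzians of FWHM R₂/π Hz with
areas p₁:p₂; for equal populations the doublet coalesces at
k_ex = √2·π·Δν (each jump rate then equals the classical threshold
πΔν/√2). A test verifies the resolvent against a numerically
Fourier-transformed time-domain propagation of the same matrix.

Peak regression uses an additive offset plus two Lorentzians parameterized
by center, height and FWHM; populations are taken as area fractions A·w.
A fit whose centers collapse within a quarter linewidth, or whose minor
amplitude vanishes, is flagged degenerate (single-peak/fast-exchange
input).

k_ex estimation per temperature holds the populations fixed from the
Lorentzian regression and optimizes k_ex, a shared R₂, the two centers and
an intensity scale/offset. Two numerical points matter:

* **Local center refinement.** Exchange pulls the apparent maxima toward
  each other; clamping the centers at the regressed (pulled-in) positions
  biases k_ex low by tens of percent even in deep slow exchange, because
  the fit trades a smaller k_ex against the irreducible center mismatch.
  The centers therefore seed the fit but float locally.
* **Degeneracy-aware initialization.** Exchange and relaxation broadening
  are nearly collinear (slow-exchange FWHM ≈ (R₂ + k_out)/π), so the
  coarse scan over a log-spaced k_ex grid pairs each candidate rate with
  the de-broadened R₂ implied by the observed width before the local
  least-squares refinement. A shared R₂ between states is the default (a
  split-R₂ variant was considered and rejected: the generator and typical
  data cannot distinguish it).

### ZZ-exchange

Longitudinal two-state kinetics with uniform R₁ give auto/cross peak
intensities via the matrix exponential of the rate-plus-relaxation matrix
(the oracle, `propagate_two_state`). The relaxation-compensated ratio

Ξ(t) = (I_AB·I_BA)/(I_AA·I_BB − I_AB·I_BA) = p_A·p_B·(1 − e^{−kt})²/e^{−kt}

cancels both uniform R₁ and the overall intensity scale; the closed form
follows from the eigendecomposition of the exchange matrix (eigenvalues 0
and −k_conf) and is validated against the oracle to 1e−10. The estimator
fits Ξ(t) per residue and pools residues by inverse variance. The
four-curve ("Farrow-style") alternative fits all auto/cross build-ups
jointly for (k_conf, shared R₁, scale); the two estimators agree within
10% at 2% multiplicative noise. Uniform R₁ across states is assumed
throughout — state-specific differences are largely absorbed by Ξ's ratio
construction, and the data modeled here cannot constrain them.

### Diffusion

Stejskal–Tanner attenuation I(G) = I₀·exp(−D·γ²δ²G²·(Δ − δ/3)) with γ the
¹H gyromagnetic ratio; the bipolar-pulse timing correction is omitted from
the default exponent (an optional `correction` field subtracts from the
effective diffusion time). Gradients may be absolute (T/m) or fractions of
a stated maximum. Replicated gradient points, when present, provide an
empirical noise SD that is propagated into the fitted SEs. Mixture
decomposition fits I(G) = I₀[w·e^{−D_open·b} + (1−w)·e^{−D_closed·b}] with
the two reference coefficients fixed from pure open (apo) and closed
(inhibitor-bound) samples and a single shared I₀ — populations do not
float per experiment. References closer than 5% are rejected as
unidentifiable. Stokes–Einstein converts D to hydrodynamic radius.

## Thermokinetics

Eyring–Polanyi regression is performed in the linear form
ln(k/T) = ln(k_B/h) + ΔS‡/R − (ΔH‡/R)(1/T), optionally weighted by the
rate SEs mapped to the log scale; the parameter covariance is retained.
Barrier SEs from `gibbs_activation` default to full covariance
propagation, var(ΔG‡) = var_H + T²var_S − 2T·cov(H,S).

For the *convergence verdict between independent experiments*, the
pipeline instead propagates marginally (dropping the covariance term).
Rationale: covariance-aware SE of an interpolated ΔG‡ inside the measured
temperature range is on the order of RT·σ_lnk/√n (~0.1 kJ/mol here), a
scale at which reproducible between-method offsets of ~1 kJ/mol — present
even between the two dynamics determinations — would always be flagged.
Parameter-level (marginal) uncertainty is the scale at which "the same
barrier measured two ways" is a meaningful statement, and it is the scale
on which such comparisons are conventionally quoted. The dynamics barrier
is the mean of the stopped-flow and line-shape determinations, with an SE
combining their fit SEs in quadrature with half their spread. Agreement is
declared when |ΔΔG‡| ≤ 2 pooled SE.

Michaelis–Menten (v = V_max·c/(K_M + c)) and the six-parameter two-state
van't Hoff melt (linear folded/unfolded baselines,
K_u = exp(−(ΔH_vH/R)(1/T − 1/T_m))) are ordinary nonlinear least squares;
the melt fit refuses flat signals (excursion below five times the noise
estimated from second differences) and midpoints outside the measured
range. Binding free energy is reported as the stabilization magnitude
RT·ln(1 M/K_D).

## Binding observables

* **Stopped flow**: I(t) = I_∞ + ΔI·e^{−k_app·t} after replicate averaging
  and dead-time truncation (default 2 ms in the generator — the initial
  bimolecular encounter is complete within the dead time, so the observed
  phase is the concentration-independent conformational step). Warnings:
  trace shorter than 3/k_app; non-exponential residual structure
  (sign-runs test).
* **ITC**: single-site Wiseman model. Working (detected) cell volume
  200 μl — the instrument-standard value, distinct from the 380 μl fill;
  Origin-style displaced-volume corrections for both concentrations and
  the differential heat, q_i = Q_i − Q_{i−1} + (dV_i/V₀)(Q_i + Q_{i−1})/2.
  Bound fraction from the quadratic mass-balance root. The first (0.3 μl
  discard) injection is excluded; stoichiometry n floats by default (the
  data determine it well at c ≈ 360). Warnings for c = n[P]/K_D outside
  [1, 10⁴] and for flat isotherms.
* **CSP**: Δδ = √(Δ¹H² + (αΔ¹⁵N)²), α = 0.2 by default (the common amide
  ¹⁵N weighting), exposed as a parameter.
* **MEXICO**: water→amide transfer build-up
  I(t) = A·k_hx(e^{−R₁w·t} − e^{−(R₁a+k_hx)t})/(R₁a + k_hx − R₁w), with the
  two relaxation rates supplied; a degenerate rate separation triggers an
  initial-slope fallback, flagged on the result.

## Synthetic-data generators

Each generator is a pure function of its `ScenarioConfig` (seed included);
per-modality substreams are spawned from the seed so modalities are
independent but reproducible. The bundled scenario encodes the study
conditions: k_conf = 25 s⁻¹ at 15 °C with mixing times 20/30/40/100 ms;
line-shape slices at 10–50 °C with k_ex = 10 and 20 s⁻¹ at 10 and 20 °C
and the line-shape activation law (ΔH‡ = 68.6 kJ/mol, ΔS‡ = 15.3 J/mol/K)
above; ¹⁵N slices at 86.2 MHz (850 MHz ¹H) with peaks at 105.0/106.2 ppm
and R₂ = 40 s⁻¹; a 21-gradient diffusion schedule (δ = 6 ms, Δ = 100 ms,
~90% maximal attenuation, repeats at 1/10/40/70%) with
D_open = 1.00×10⁻¹⁰ < D_closed = 1.15×10⁻¹⁰ m²/s mixed at equal weights;
a 17 °C stopped-flow trace with k_app = 24 s⁻¹ (the measured value) plus a
rate–temperature table from the stopped-flow activation law
(ΔH‡ = 62.1 kJ/mol, ΔS‡ = −4.7 J/mol/K; these give 22.7 s⁻¹ at 17 °C, so
the tabulated law and the headline trace are kept as separate truths);
enzyme velocities at 15–45 °C from the catalytic activation law
(ΔH‡ = 26.6 kJ/mol, ΔS‡ = −120 J/mol/K, K_M = 50 μM); an ITC titration
(90 μM cell / 541 μM syringe, 0.3 + 44×1.5 μl, K_D = 250 nM,
ΔH = −40 kJ/mol, n = 1); a CD melt (T_m = 325 K, ΔH_vH = 300 kJ/mol); and
MEXICO build-ups at the 10–250 ms delay schedule with per-residue k_hx
including a three-fold open/closed contrast at one site.

Noise defaults are instrument-typical: 2% multiplicative (ZZ, diffusion),
additive 2% of maximum (spectra), 1% (stopped-flow traces), 5% lognormal
(tabulated rates and assay velocities), 0.2 μcal absolute per ITC
injection. The ΔH of binding and K_M are representative choices where no
value is published.

What the generators deliberately do **not** emulate: baseline roll and
phase errors in spectra, temperature-dependent R₂/R₁, heats of dilution,
convection in diffusion data, photobleaching, or correlated noise. Passing
tests therefore demonstrate estimator correctness under the stated
measurement model, not robustness to every instrumental artifact.

## Pipeline

`run_pipeline` validates the config (required keys, unit sanity such as a
Celsius field holding a Kelvin-sized number, file existence), runs each
modality, records per-stage failures without aborting the run, and writes
the JSON report atomically; identical config + seed yields byte-identical
output. Problem sizes in the test-suite Monte-Carlo checks (tens to
hundreds of replicates) are chosen so the whole suite runs in well under a
minute of statistics per property while keeping standard errors a factor
of a few below the tolerances being asserted.

## Known limitations

* Two-state exchange only; no three-site models, CPMG/R1ρ relaxation
  dispersion, or 2D spectral processing (1D slices and peak intensities
  are the input contract).
* The Eyring analysis assumes temperature-independent ΔH‡, ΔS‡ (no ΔCp‡),
  matching the linear analysis performed on the data.
* The ZZ estimators assume uniform R₁; strongly state-specific R₁ would
  bias the four-curve fit (though barely the Ξ ratio).
* Induced-fit vs conformational-selection flux partitioning is outside
  scope: stopped-flow traces are treated as single-exponential
  phenomenology.
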