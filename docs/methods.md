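# Methods

## Forward model

The recovery model is the standard series solution for photobleaching of a
uniform 2-D fluorophore distribution with a Gaussian beam used for both
bleaching and monitoring:

    f(t) = Σₙ₌₀^∞ [(−K)ⁿ/n!] · [1 + n(1 + 2t/τ_D)]⁻¹

* `w` is the e⁻² radius of the Gaussian intensity profile; all formulas use
  τ_D = w²/(4D). This is the dominant convention for Gaussian-spot FRAP.
* Bleach and monitor beams share the same profile (one focused beam used at
  two intensities); monitoring-induced bleaching is neglected (the monitor
  power is ~5000× below the bleach pulse).
* The bleach parameter `K` sets the post-bleach fractional fluorescence
  f(0) = (1 − e⁻ᴷ)/K. K = 3 (≈68% depth) is the package-wide default,
  inside the 60–75% operating range of the emulated acquisition.
* Series truncation: terms are accumulated until the next term is below
  10⁻⁹ everywhere (the factorial bound |term_n| ≤ Kⁿ/(n!·(1+n)) makes the
  stopping rule safe once n > K), with a hard cap of 200 terms; hitting the
  cap raises, a partial sum is never returned.
* An immobile subpopulation enters as
  F(t) = F_pre[(1 − R_f)f(0) + R_f f(t)]; the normalized recovery then
  equals R_f identically, which is what makes the patch/FRAP complex
  fraction well defined.
* Units are fixed to µm, s, µm²/s internally; the display unit
  10⁻² µm²/s appears only in printed output.

Correctness is checked against an independent Crank–Nicolson
finite-difference solution of ∂c/∂t = D∇²c on a radial grid, started from
the post-bleach profile exp[−K·exp(−2r²/w²)] and read out through the
monitoring Gaussian; the series and the PDE agree to < 5×10⁻³ (max-abs,
t ∈ [0, 20 τ_D], K ∈ {1, 3, 6}; observed ≈ 5×10⁻⁵).

## Synthetic curves and cohorts

`generate_curve` adds measurement noise to the closed-form curve.  The
default noise is signal-scaled Gaussian, SD = σ₀√F with σ₀ = 0.02 — the
Gaussian limit of photon shot noise; the emulated instrument's detector is
not otherwise characterized, and a `constant`-SD scheme is available.
Bleach depths ≥ 95% are rejected (outside the linearity assumed of the
detector).

`generate_cohort` adds between-cell variability: lognormal jitter on D
(mean-preserving) and logit-normal jitter on R_f (delta-method calibrated),
both with a default coefficient of variation of 15%, roughly the spread
seen between cells in published per-cell FRAP measurements; the exact
magnitude is a free default. Cell seeds derive from the cohort seed plus
the running cell index, so cohorts are bit-reproducible and any single cell
can be regenerated.

What the generator does *not* emulate: detector offset and drift,
photobleaching of the monitoring signal, cell-shape and membrane-topography
effects, spatial heterogeneity of receptor density. Passing tests therefore
certify the estimator and inference chain under idealized acquisition, not
robustness to those instrumental effects.

## Binding Monte Carlo (patch/FRAP physics)

`simulate_binding_frap` propagates point receptors in a periodic square
membrane patch. A receptor is either free (2-D Brownian motion, D_free) or
bound to an immobile trap (zero mobility — the model of an IgG-crosslinked
receptor patch), switching with first-order rates k_on (pseudo-first-order
binding) and k_off. The bleach pulse marks each particle bleached with
probability 1 − exp[−K·exp(−2r²/w²)] at its instantaneous position, and the
recorded signal is the Gaussian-weighted (e⁻² radius w) count of unbleached
particles at each monitoring time.

Implementation notes:

* State flips are drawn per sojourn (geometric waiting times in units of
  the kinetic step dt) and the free-time displacement within each
  monitoring frame is drawn as a single Gaussian with variance
  2·D_free·dt·n_free per axis. This is distribution-exact at the sample
  times and identical to per-step Bernoulli/Brownian updating, at a small
  fraction of the cost. The stability requirements (k_on + k_off)·dt < 0.1
  and 4·D_free·dt < (box/100)² are enforced before simulation.
* The recorded signal is normalized by the no-bleach signal computed from
  the same particle configuration (a control variate). This cancels the
  occupation-number fluctuations of the monitoring spot, which otherwise
  dominate the Monte Carlo error of the curve; the expectation of the
  output is unchanged.
* Particles start uniformly distributed with states drawn from the
  stationary bound fraction k_on/(k_on + k_off), then equilibrate for
  5/(k_on + k_off) before the pre-bleach recording, capped (with a warning)
  at 10⁴ steps — benign because the initialization is already stationary.
* Box size must be ≥ 10·w; the simulation studies below use 20·w so that
  periodic images cannot refill the spot within the recording window
  (refill time (L/2)²/(4D) ≈ 490 s against ≤ 60 s recordings) and total
  depletion by the bleach stays below 1%.

Simulation study conditions (regime dichotomy): spot w = 0.77 µm, K = 3,
D_free = 0.03 µm²/s (τ_D ≈ 4.9 s), bound fraction 0.4, box 15.4 µm,
80 000 particles (≈340 µm⁻², a plausible density for an overexpressed
receptor), recording 48 s ≈ 10 τ_D at 2.4 s intervals, 6 cells per arm with
15% between-cell CV on D_free. The 10 τ_D window is deliberate: it pins the
recovery plateau well enough to separate R_f from D, yet stays short
against the slow-exchange complex lifetime (1/k_off ≈ 100 τ_D at the
stable-regime boundary k_off·τ_D = 10⁻²), whose partial unbinding during an
over-long recording otherwise leaks into a downward-biased D estimate.
At the fast-exchange boundary k_off·τ_D = 10² the fitted D approaches the
effective-diffusion limit D_free·k_off/(k_on + k_off). How many exchange
cycles separate the regimes is not hard-coded anywhere; k_off·τ_D is the
exposed dimensionless control.

## Curve fitting

1. The curve is normalized by its mean pre-bleach level (idempotent).
2. K is recovered per curve from the observed bleach depth by inverting the
   monotone relation (1 − e⁻ᴷ)/K = F(0)/F_pre with bisection (`fix_k=True`
   uses the acquisition K instead). Estimating K from the depth reduces the
   regression to the two parameters of interest; the chosen source of K is
   recorded in the output (`K_source`).
3. Initialization from the half-recovery time: the dimensionless time
   x_half at which the fully mobile series crosses half of its span is
   solved numerically for the curve's K, and D₀ = w²·x_half/(4·t_half).
4. Bounded least squares (scipy, trust-region reflective) over R_f ∈ [0, 1]
   and log D, unweighted on the normalized data. On failure the fit is
   restarted from three perturbed initializations; persistent failure is
   reported as `converged=False` with no fabricated estimate.
5. Standard errors come from the Gauss–Newton curvature at the optimum,
   plus the gain uncertainty of the pre-bleach normalization propagated by
   the delta method. They are conditional on the K used; reported as NaN
   when the curvature matrix is singular.

QC conventions: `recovery_pct` uses the mean of the last 5% of post-bleach
samples as the endpoint (robust to terminal noise; the endpoint is
otherwise a free choice). Curves with recovery < 20% keep their R_f
estimate but set `d_reliable=False`, and group statistics drop them from
the D comparison — which is why per-condition n is smaller for D than for
R_f. An estimate pinned at R_f = 0 is accepted only for genuinely flat
curves (recovery < 5%); otherwise the fit is flagged non-converged. A fit
pinned at R_f = 1 is accepted as a fully mobile population.

## Inference

* Complex fraction C = 100·(R_f,free − R_f,CL)/R_f,free on group means, as
  the published inline arithmetic does; cells differ between arms, so no
  pairing is possible. A percentile bootstrap over cohort means provides a
  CI. R_f,CL > R_f,free leaves no reduction to attribute and is an error
  from the statistic (the classifier then reports the D-based call with
  complex fraction 0).
* Two groups are compared with Student's t test (pooled variance); more
  than two with one-way ANOVA followed by all-pairs pooled-variance t tests
  and Bonferroni adjustment (statsmodels). Degenerate zero-variance groups
  give p = 1 when means coincide and p = 0 otherwise.
* Decision table for a free vs crosslinked pair: R_f significantly lower
  and D not — stable; D significantly lower and R_f not — transient; both —
  mixed (the published analyses never hit this case, so no binary rule is
  forced); neither — none. "Significantly lower" is adjusted p < α together
  with a mean decrease; "no effect" is operationalized as adjusted p ≥ α
  (an equivalence test is out of scope). Significance stars follow the
  0.05 / 0.01 / 10⁻³ / 10⁻⁴ tiers.
* If either arm has fewer than two reliable D estimates, the D contrast is
  reported as NaN and treated as "no effect", with a note.
* `frap infer` additionally accepts degenerate single-value groups (e.g.,
  published group means entered as one row each); it then reports the
  complex fraction from the means and marks the classification
  undetermined, since no test is possible.

## Problem sizes in the test suite

Stochastic checks run at sizes chosen to make their statistical assertions
sharp while remaining desk-scale: 200 curves for parameter recovery, 1000
replicate samples for type-I/power calibration, 10 replicate mini-cohorts
(6 cells per arm) for the regime dichotomy, and 30 cells per group for the
end-to-end pipeline, mirroring the ~30 cells per condition of the emulated
study. All randomness is seeded; reruns are bit-identical.

## Known limitations

* Single-component diffusion only: no anomalous diffusion, flow, 3-D
  exchange with a cytoplasmic pool, or two mobile populations.
* The bleach is single-step; blinking and reversible dark states are not
  modeled.
* Traps are point-like, immobile and unsaturable.
* The K-from-depth convention ties the fitted model's f(0) to a single
  noisy sample; its uncertainty is not propagated into the per-curve
  standard errors (they are conditional on K).
* The complex fraction inherits the assumption that crosslinking is
  complete and that the immobilized partner's complexes survive the
  measurement; partial patching reads as a smaller fraction.
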