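# Methods

## Scope

`bcellqsp` implements a quantitative systems pharmacology (QSP) model of the
T cell-dependent B cell response in mouse: homeostatic B-cell trafficking
across bone marrow, blood, spleen and lymph nodes; antigen-driven generation
of antibody-secreting cells (ASC) behind a transit-compartment delay;
saturable entry of ASC into the bone-marrow survival niche; and circulating
antigen-specific IgG. Around the model sit the analysis stages used to build
and interrogate it: analytic steady-state closure of the homeostatic rates,
maximum-likelihood calibration with identifiability diagnostics, uncertainty
propagation, local and variance-based global sensitivity analysis, and a
synthetic-study generator for validating the calibration machinery end to
end.

## Model structure

Twenty ODE states:

* **Homeostatic compartments (7).** Immature B cells in bone marrow mature
  into transitional T1 cells, which migrate via blood to the spleen and
  mature into naive B cells; naive cells recirculate between spleen, blood
  and lymph nodes, with elimination in spleen and lymph nodes. All
  homeostatic fluxes are first-order.
* **Antigen block (7).** An empirical exposure pulse `Antigen0` feeds a chain
  of six identical first-order transit stages (rate `ktr = n/mtt = 6/18` per
  day). The terminal stage is the delayed activation signal; a chain of `n`
  stages has a gamma-distributed residence time with mean `n/ktr = 18` days,
  matching the observed lag between peak exposure and peak ASC counts.
* **ASC compartments (5).** ASC are generated in spleen and lymph nodes at
  rate `kmat_3 · (naive pool · precursor frequency) · Antigen(t)` with a
  precursor frequency of 1 in 10⁶. They traffic through blood, enter
  non-lymphoid peripheral organs, and enter the bone-marrow survival niche
  through a saturable Michaelis–Menten influx `Vmax·B/(Khalf+B)` where `B` is
  blood ASC. There is no explicit ASC death; lifespan control is implicit in
  the niche capacity.
* **IgG (1).** Produced proportionally to the spleen + lymph-node + blood +
  bone-marrow ASC pool (peripheral ASC excluded) and cleared first-order.

Because `Khalf` (0.1 cells) is tiny relative to blood ASC counts, the niche
influx runs essentially saturated at `Vmax` during the response, giving the
analytic late limit `ASCBone → Vmax/k12` (≈ 24,530 cells at reference
values) — a useful closed-form oracle for the integrator.

## Parameters and steady-state closure

Thirty-one constants are carried: seven steady-state cell counts, the
trafficking rates `k1…k14`, maturation/elimination rates, IgG rates, and the
niche parameters. Seven homeostatic rates are not measured directly; they
are **derived analytically** by zeroing each compartment balance at the
observed counts (`derive_rates`). The solves are sequential along the
lineage; the naive blood/spleen pair closes jointly.

Two closure conventions:

* `paper` — the published reference table verbatim. The lymph-node return
  rate `k7 = 62.62`/day balances the LN pool against the *spleen* naive
  count, so the LN naive balance itself is left open (net flux ≈ −9.6×10⁷
  cells/day at the nominal counts). This mode reproduces the reference
  table exactly and is used for the closure targets.
* `self_consistent` — `k7` is solved from the LN balance itself
  (≈ 11.92/day) and the downstream rates follow, so every homeostatic
  compartment is exactly stationary. This is the default for forward
  simulation and calibration, where an artificial homeostatic drift would
  contaminate the response.

## Antigen forcing

Antigen exposure is represented by a Bateman (difference-of-exponentials)
pulse `A0(t) = amplitude·(e^(−decay·t) − e^(−rise·t))` with defaults
amplitude 10 (signal units), rise 1.5/day, decay 0.35/day, onset day 0. The
pulse's absolute scale is arbitrary: only the product amplitude × activation
rate × precursor pool is observable, so absolute ASC peak magnitudes under
this forcing are order-of-magnitude quantities, while peak *timing* (set by
the transit chain) and the bone-marrow plateau (set by `Vmax/k12`) are
amplitude-independent. This is reflected in the validation suite: timing and
plateau are checked tightly, peak magnitudes only to order of magnitude.

## Numerics

* **Integration.** `scipy.integrate.solve_ivp` with LSODA: rate constants
  span 0.02–6111/day, so stiffness switching is required. Defaults
  `rtol 1e-8 / atol 1e-6`; fitting and sensitivity loops use analysis-grade
  `rtol 1e-6 / atol 1e-3`, which changes the objective well below its
  statistical resolution while cutting the cost per evaluation by an order
  of magnitude. Right-hand sides are `numba`-compiled.
* **Activation-only fast path.** Under self-consistent closure the
  homeostatic block is constant and the antigen chain is autonomous
  (independent of every fitted parameter). `simulate_activation` therefore
  integrates only the six driven states (5 ASC + IgG) against a cached
  fine-grid antigen signal (0.05-day grid, `rtol 1e-10`), ~20× cheaper than
  the full system and agreeing with it to solver tolerance (tested).
  Parameter sets whose homeostatic block is not balanced fall back to the
  full integrator automatically.

## Likelihood and calibration

Five activation parameters are fitted: `k9, k12, k13, kmat_3, Vmax`. The
objective is −2 log-likelihood with the residual variance of each observed
variable profiled out analytically:

    −2LL = Σ_points r²/σ_v² + log(2πσ_v²),   σ_v² = SSR_v / n_v.

Cell-count residuals are computed on the `log10(value+1)` scale (counts span
five orders of magnitude across tissues; a multiplicative error model is the
only one consistent with weighted residuals confined to ±2); normalized IgG
residuals are linear. For constant residuals `r` the objective collapses to
`n·(1 + log(2πr²))`, which the test suite checks to machine precision.

Optimization is Nelder–Mead on log-transformed parameters, with an optional
simplex restart from the incumbent. The covariance of the log-estimates is
the inverse of one-half the central finite-difference Hessian of −2LL;
relative standard errors follow as `RSE% = 100·SE_log` (the SE of a
log-parameter is the CV of the natural-scale estimate).

Identifiability and stability tooling:

* **Profile likelihood** (`profile_likelihood`): re-optimized −2LL on a log
  grid; 95% CI where the profile crosses minimum + 3.84.
* **Profile-CI bisection** (`profile_ci`): per-side bracketing from a
  Wald-scaled initial step, then log-scale bisection; every nuisance
  re-optimization restarts from the global estimates, which keeps the
  profiled objective smooth when the bisection jumps between distant points.
* **Multistart** (`multistart`): Latin-hypercube starts within ±50% of the
  reference; dispersion of the optimized values measures practical
  identifiability.
* **Uncertainty bands** (`uncertainty_bands`): multivariate-normal draws on
  the log scale from the fitted covariance, propagated through the model to
  percentile envelopes. These quantify estimation uncertainty only.
* **Per-study Vmax refits** (`fit_vmax_per_study`): the bone-marrow niche
  capacity is the single study-level parameter carrying between-study
  heterogeneity.

## Sensitivity analysis

* **Local**: trajectory sweeps (±20%, `local_sweep`) and one-at-a-time
  tornado contrasts (`tornado`) on Cmax and the day-200 level of the four
  ASC tissues.
* **Global**: an in-package eFAST implementation (`efast`) — search curves
  `x_j(s) = 1/2 + (1/π)·arcsin(sin(ω_j s + φ_j))`, interference factor
  M = 4, driving frequency `ω_max = (NS−1)/(2M)`, complementary frequencies
  ≤ `ω_max/(2M)`, indices from the one-sided Fourier power spectrum.
  First-order indices read the M harmonics of the driving frequency;
  total-order indices are `1 − V_complementary/V`. The implementation is
  validated against the analytic variance shares of an additive linear
  function (agreement well within the 5% acceptance tolerance).

A structural note confirmed by the analysis: because ASC generation is
*linear* in `kmat_3` (generation = `kmat_3 · pool · signal` with an
effectively constant naive pool), the elasticity of spleen/LN ASC metrics
with respect to `kmat_3` is ≈ 1 — a −20% perturbation reduces those metrics
by ≈ 20–23%, not ≈ 50%. Bone-marrow day-200 ASC is insensitive to `kmat_3`
(< 0.1%) because the niche influx is saturated; `Vmax` dominates it with
first-order ≈ total-order indices, and `kmat_3` shows total-order >
first-order in the transient tissues. See `test_acceptance.py` for exactly
which clauses of the qualitative-sensitivity criterion hold.

## Synthetic studies (generator scope)

Digitized literature time courses are not redistributable, so calibration,
profiling and heterogeneity machinery are validated on synthetic studies
that emulate the *structure* of the real calibration sources: sparse
sampling days (defaults 7, 14, 21, 28, 42, 60, 100, 200), four observed ASC
tissues, a small number of replicate animals per point summarized as
mean ± SE, mean-one lognormal measurement noise (default CV 0.3), and
between-study heterogeneity carried by `Vmax`. Ground truth is serialized
alongside each dataset. The generator does **not** emulate digitization
error, per-study schedule differences, or systematic assay biases.

Recovery behavior at this design (20 replicates): median absolute bias below
10% for all five parameters, profile-CI coverage consistent with the nominal
95%, multistart dispersion within a few percent — see the acceptance suite.

## Observables

Experimental ASC counts are reported per tissue sample; whole-animal scaling
uses two-femur marrow = 12.7% of total (×7.9) and 22 lymph nodes per mouse
(×22). IgG time courses are compared after per-curve max-normalization.
Goodness of fit is summarized by RMSE, weighted residuals (residual / the
same σ profiled in the likelihood), and the fraction of |WRES| ≤ 2.

## Limitations

* The antigen pulse is empirical and its amplitude arbitrary; absolute ASC
  peak magnitudes are only meaningful relative to the configured amplitude.
* No ASC death terms: long-term persistence is governed entirely by niche
  capacity and efflux, so the model cannot represent niche-independent
  plasma-cell loss.
* The `paper` closure is intentionally non-stationary in the LN naive
  balance; forward simulation in that mode superimposes a homeostatic drift
  on the response and is supported only for auditing the published table.
* Calibration assumes independent residuals within each variable;
  within-animal correlation across days is not modeled.
* The reported parameter covariance is a local (Hessian-based)
  approximation; strongly curved profiles are better summarized by
  `profile_likelihood` / `profile_ci`.
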