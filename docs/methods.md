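# Methods

## The model

`proclean` implements a coarse-grained dynamical model of a two-strain
*E. coli* community grown in a stirred bioreactor: a **producer** that grows
mainly on glucose, diverts a fixed fraction of biomass synthesis into a
heterologous protein, and secretes acetate by overflow metabolism; and a
**cleaner** engineered (ptsG deletion, Acs overexpression) to scavenge that
acetate. The state is x = (G, A, B_P, H, B_C): glucose and acetate
concentrations [g L⁻¹], producer catalytic biomass, heterologous protein and
cleaner biomass [gDW L⁻¹]. Units are fixed package-wide (h, g L⁻¹,
g gDW⁻¹ h⁻¹); there is no unit-conversion layer.

Specific rates per strain (producer shown; the cleaner replaces k_g by the
residual uptake rate k_ΔPTS and adds an Acs term k_Acs·A/(A+K_Acs) to its
acetate uptake):

- glucose uptake r_g = k_g · G/(G+K_g) · Θ_aⁿ/(Aⁿ+Θ_aⁿ) — Monod kinetics
  damped by acetate growth inhibition;
- acetate uptake r_a = k_a · A/(A+K_a) · Θ_gᵐ/(r_gᵐ+Θ_gᵐ) — Monod kinetics
  repressed by carbon catabolite repression (CCR), driven by the glucose
  uptake rate itself;
- acetate overflow r_o = k_over · max(0, r_g − l) — zero below the uptake
  threshold l, proportional to the excess above it.

Mass balances couple the strains through G and A; the producer splits its
specific biomass-production rate r = Y_g r_g + Y_a (r_a − r_o) into
catalytic biomass (fraction 1−Y_h) and product (fraction Y_h); all biomass
decays at the maintenance-related rate k_deg = C_m·Y_g. Population growth
rates are defined through the total biomasses,
d(B_P+H)/dt = (μ_P − D)(B_P+H), so that μ_P = r·B_P/(B_P+H) − k_deg.

Reactor modes: **batch** (D = 0), **chemostat** (constant D, inflow glucose
G_in), **fed-batch** (no outflow; the glucose balance is removed
structurally, dG/dt = 0, emulating a feed that holds G at a set level — no
feedback controller is synthesized). The implied feed rate, the total
volumetric glucose uptake r_gP·B_P + r_gC·B_C, is recorded along fed-batch
trajectories because the fed-batch yield divides dH/dt by it.

Key structural identities used throughout the tests: at any chemostat
equilibrium with the respective biomass present, μ_P* = μ_C* = D and
H*/(B_P*+H*) = Y_h; on the producer-only branch below overflow,
r_g* = (k_deg + D)/((1−Y_h) Y_g); the chemostat process yield obeys
(D H*)/(D G_in) = Y_h (B_P*+H*)/G_in; in fed-batch the system settles into
exponential growth in which H/(B_P+H) again equals Y_h.

## Parameters

The packaged default set (`proclean/data/default_params.toml`) is the calibrated
wild-type-derived parameterisation: k_g = 1.53, K_g = 0.09, Θ_a = 0.52
(low-pH-adjusted acetate inhibition), n = 1, k_over = 0.17, l = 0.7,
k_a = 0.97, K_a = 0.5, Θ_g = 0.25, m = 1, Y_g = 0.44, Y_a = 0.298,
k_deg = 0.0044, with cleaner constants k_ΔPTS = 0.38 (4-fold PTS reduction),
k_Acs = 1.46 (1.5·k_a, mild Acs overexpression) and K_Acs = 0.012. The
product yield defaults to Y_h = 0.2 ("20% of protein synthesis diverted");
Y_h = 0 is the wild type. Exponents n and m are real-valued parameters with
guarded derivatives at zero concentrations; the calibrated values happen to
be 1.

## Numerics

- **Integration.** Stiff BDF with rtol 1e−8 / atol 1e−10 and the analytic
  Jacobian; the overflow kink is kept exact (no smoothing) because the
  piecewise-linear overflow law is itself a modeled mechanism and the
  steady-state analysis partitions the state space by it. Componentwise
  undershoot in (−1e−8, 0) — about 100× the absolute solver tolerance — is
  clipped to zero after each solve; larger negatives abort. Rates at exactly
  zero concentrations are defined by continuous extension (value 0).
- **Steady states by integration.** From x0 = (0, 0, 0.01, 0, 0.01) (both
  biomasses must be inoculated: the zero-biomass set is invariant), in
  geometrically growing time chunks up to a 1e6 h horizon, declaring
  convergence at ‖f(x)‖∞ < 1e−9. Each chunk endpoint is polished by a
  Newton solve restricted to the active components (biomasses above 1e−7);
  a polish is accepted only if it stays in the nonnegative orthant, meets
  the residual tolerance and is strictly stable, which shortcuts the slow
  exponential tail without changing the attractor. Non-convergence returns
  a flagged result.
- **Steady states by root finding.** The exhaustive enumeration of the
  piecewise-rational equilibrium conditions is replaced by a numerically
  equivalent family-wise search: the closed-form washout root; reduced
  3-dimensional producer-only and cleaner-only problems; and the interior
  coexistence problem in (G, A, B_P, B_C) with H tied to B_P by
  H = Y_h/(1−Y_h)·B_P. Each family is solved per overflow branch (the four
  subsets X1–X4 on which the overflow terms are identically zero or linear)
  with Powell's damped-Newton hybrid method from ≥ 32 Latin-hypercube
  starts in log-scaled state space, candidates violating their branch's
  defining inequality or nonnegativity are discarded, survivors are
  deduplicated at 1e−6 relative distance, and stability is decided by the
  eigenvalues of the analytic Jacobian (strictly stable ⇔ all real parts
  negative). On the kink itself the one-sided derivative of the state's own
  partition is used, with a warning.
- **Regimes and boundaries.** A population counts as present above
  1e−6 gDW L⁻¹, giving the labels coexistence / producer_only /
  cleaner_only / washout. Phase diagrams use ΔD = 0.005 h⁻¹ on [0, 0.7] and
  ΔG_in = 0.5 g L⁻¹ on [0, 20] by default; regime boundaries along D are
  refined by bisection to 1e−3 h⁻¹. Uniqueness of the stable steady state
  (a consequence of the monotone rate laws) is probed on request by
  re-solving each cell from random positive inocula; disagreement beyond
  1e−5 relative is flagged loudly.
- **Performance maxima.** Productivity D·H* and process yield H*/G_in are
  maximized over the D grid and then refined by golden-section search to
  1e−3 h⁻¹; the consortium's relative productivity gain is
  (max_consortium − max_producer)/max_producer in percent.
- **Fed-batch exponential window.** On a uniform time grid, the largest
  terminal run where the second differences of both log(B_P+H) and log H
  stay below 1e−6 per step, required to span ≥ 5 h; slopes by least squares
  on the window, the yield as the mean of (dH/dt)/feed with dH/dt evaluated
  exactly from the model. The default problem sizes (60 h horizon, 3001
  points) leave a ≈ 45 h window after an ≈ 12 h transient.

## Calibration

Step 1 solves the exponential-growth balances analytically on the
single-substrate conditions: from acetate-only records (G = 0 ⇒ no uptake
competition, CCR factor 1, no overflow) k_a = r_a⁺(A+K_a)/A and
Y_a = (μ⁺+k_deg)/r_a⁺; from glucose-only records (A ≈ 0 ⇒ no inhibition, no
acetate uptake; overflow present) k_g = r_g⁺(G+K_g)/G,
k_over = −net⁺/(r_g⁺−l) and Y_g = (μ⁺+k_deg−Y_a·net⁺)/r_g⁺, averaging
per-record inversions. K_g, K_a, l and k_deg are fixed literature constants.
These closed forms are not printed in any single reference and are the
package's own inversion of the balance equations; they are exact on
noise-free data by construction.

Step 2 estimates the regulatory constants (Θ_a, n, Θ_g, m) on the mixed
glucose+acetate records by minimizing the *unweighted* pooled sum of squared
errors of the three observables (they share a numeric scale of ≈ 0.1–1.5, so
no per-observable weighting is applied) with multi-start (8 starts)
bound-constrained Nelder–Mead, bounds Θ_a ∈ (0, 10], n ∈ [0.5, 4],
Θ_g ∈ (0, 5], m ∈ [0.5, 4]. Estimates pinned at a bound, non-convergence,
and structurally unidentifiable designs (no acetate in the mixed records)
are flagged rather than silently returned.

Identifiability uses a case-resampling bootstrap stratified by condition
class: records are resampled with replacement within each class and the
*full* two-step pipeline is rerun per replicate — the closed-form step-1
inversion on the resampled single-substrate records, then step 2 initialized
at the point estimate — so step-1 estimation error propagates into the
percentile 95% intervals. (Refitting step 2 alone against frozen step-1
values roughly halves the apparent spread of Θ_a and makes the resampling of
the single-substrate classes inert.) The procedure is deterministic under a
fixed seed, and replicate failure rates above 20% raise.

## The synthetic-data generator

The external dataset behind the original calibration is not redistributable,
so `synthetic` emulates its statistical structure: per condition the
noise-free observables are computed from the rate laws and multiplied by
independent mean-one lognormal factors with a chosen coefficient of
variation (σ² = ln(1+CV²)), applied to the magnitude so a net secretion
stays a secretion. The default design mirrors the visible structure of the
source experiments — one saturating glucose-only condition (2.7 g L⁻¹, so
overflow is active), an acetate-only gradient {0.5, 1, 2, 4} g L⁻¹, and a
mixed gradient A ∈ {0, 0.25, 0.5, 1, 2, 4} g L⁻¹ at 2.7 g L⁻¹ glucose, 3
replicates, CV 5%. The 5% CV is a modelling choice typical of physiological
rate measurements, not a reported value. The generator reproduces
*independent multiplicative* error only: it does not emulate
within-experiment autocorrelation, shared-batch effects or
instrument-specific error models, so recovery and coverage results on
synthetic data bound what can be expected from real data only under those
idealisations.

## Design choices on genuinely open points

- The integration route's published description starts "from x₀ = 0", which
  cannot be literal (zero biomass is invariant); we inoculate both strains
  at 0.01 gDW L⁻¹, consistent with the assumption that both biomasses are
  initially present.
- Two distinct onset quantities exist near the low-D edge of coexistence:
  the closed-form overflow onset D = (1−Y_h)Y_g·l − k_deg (0.3036 h⁻¹ at
  Y_h = 0; 0.242 at Y_h = 0.2) and the slightly larger cleaner-invasion
  threshold where overflow first suffices to sustain the cleaner at rate D.
  Both are computed and reported (`overflow_onset` vs `coexistence_lo`)
  rather than conflated.
- Whether n and m were integer-constrained during the original estimation
  is unknown; they are treated as real-valued with real-valued bounds, and
  the noiseless round trip recovers 1.0 for both.
- The bootstrap flavor is fixed to stratified case resampling with
  percentile intervals; aggregation of replicate measurements in step 1 is
  by averaging per-record inversions.

## Known limitations

- The washout boundary at G_in = 20, Y_h = 0.2 computes to
  D = (1−Y_h)(Y_g r_g(G_in,0) − Y_a r_o(G_in,0)) − k_deg ≈ 0.498 h⁻¹ with
  the shipped constants — the exact model value, slightly below the ≈ 0.52
  sometimes quoted from coarse-grid scans of the same system.
- Batch diauxie from G(0) = 2.7, B(0) = 0.1 depletes glucose at ≈ 4.7 h;
  accumulated acetate inhibition stretches the tail of the glucose phase
  beyond the ≈ 4 h back-of-envelope from the uninhibited growth rate.
- Non-monotone acetate growth laws (which can produce bistability in
  related models) are out of scope; with the monotone laws used here all
  probed cells have a unique stable steady state.
- The root-finding route is a multi-start heuristic, not a certified global
  enumeration; it is cross-checked against the integration route on test
  grids.
- Percentile case-resampling bootstrap intervals undercover at the default
  synthetic design: with only three replicates in the glucose-only stratum
  the bootstrap variance of that stratum's mean is deflated by (n−1)/n, and
  the nested simulation study in the test suite measures ≈ 75–95% coverage
  per parameter (mean ≈ 84%) at a nominal 95%. The intervals are reported
  as prescribed; treat them as slightly optimistic on designs this small.
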