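# Methods

## Model and assumptions

All inference is on the incremental net benefit (INB) scale,
b(λ) = λ·ΔE − ΔC, which linearizes the ICER: instead of a ratio with a
possibly unbounded standard error (ΔE near zero), the INB is a linear
combination of two approximately normal mean differences, indexed by the
willingness-to-pay λ. The package's hypothesis test is the one-sided
z-test of H0: b(λ) ≤ 0 against cost-effectiveness, with the mirrored
one-sided and a two-sided variant also exposed.

The exact two-arm variance (`variance_general`) combines per-arm second
moments:

σ²_b = Σ_j (1/n_j)(λ²σ²_{E,j} + σ²_{C,j} − 2λρ_j σ_{E,j}σ_{C,j}),  j = 0, 1.

Design-stage work uses the pooled simplification (`variance_simplified`):
balanced arms (n/2 each), common σ_E, σ_C and ρ, giving
σ²_b = (4/n)(λ²σ_E² + σ_C² − 2λρσ_Eσ_C). The two agree to machine
precision when the assumptions hold (property-tested). Because the cross
term is −2λρσ_Eσ_C, variance is strictly decreasing in ρ for λ > 0 and is
affine in ρ; `variance_as_linear_in_rho` exposes the intercept/slope
decomposition, whose ratio is the relative variance swing at ρ = ±1.
Variances are computed in CAD² and additionally reported as
`display_value` = value/1000 (thousands of CAD²), the conventional
reporting scale for these quantities.

## Sample size and power

The generic sample-size relation n = (z_{1−α}+z_{1−β})²·σ²_b / b_δ² is
circular as written, since σ²_b depends on n. It is implemented
non-circularly through the n-free unit variance V₁ ≡ n·σ²_b
(`sample_size_from_unit_variance`), which is exactly what the pooled
formula (`sample_size`) states:

n = 4z·(λ²πσ_E² + σ_C² − 2λρ√π·σ_Eσ_C) / (λΔE − ΔC)²,  z = (z_{1−α}+z_{1−β})².

π = n_e/d_e ≥ 1 is the efficacy design's event ratio; it multiplies the
effectiveness variance term (and √π the cross term) to account for
censoring, and is taken verbatim from the design — no other censoring model
is applied. The denominator is identically (λΔE − ΔC)², the squared
smallest important difference in its "observed" definition. n is reported
both as the continuous solution and rounded up to the next even integer
(balanced arms). Power (`analytic_power`) is
Φ(b_δ/σ_b − z_{1−α}) for direction "greater", the sign-flipped analogue for
"less", and Φ(|b_δ|/σ_b − z_{1−α/2}) for the two-sided variant — the
standard normal-approximation form that neglects the vanishing wrong-tail
probability. Power at the continuous solved n round-trips to the target to
1e−9 when π = 1; with π > 1 the solved n is deliberately larger than the
variance-only requirement, so the round trip is an inequality.

The smallest important difference b_δ supports three definitions:
observed (λΔE − ΔC; errors when exactly zero, since n diverges),
frequentist (the minimum detectable difference (z_{1−α}+z_{1−β})·σ_b at a
given n — it fixes power by construction, so it cannot be solved for n),
and explicit (a user-supplied CAD value).

## Confidence-interval curves and Fieller limits

`inb_interval_curve` evaluates b(λ) ± z_{(1+level)/2}·σ_b(λ) over a λ grid
(default $0–$250,000 in $1,000 steps; level defaults to 0.95 two-sided,
a documented package choice). The Fieller limits of the ICER are located
as the zero crossings of the two bound curves: each grid cell with a sign
change is refined by Brent's method (xtol 1e−9 in λ). A bound that never
changes sign on the grid hull yields `None` on that side — the unbounded
Fieller interval that arises when ΔE is not significantly different from
zero. Tests verify the root-found limits against the classical closed-form
Fieller quadratic computed from the same moments (independent oracle,
1e−6 relative agreement).

## Efficacy-design conversion

`effectiveness_inputs_from_design` maps an exponential-survival efficacy
design (control-arm survival at a landmark time, hazard ratio, planned
patients/events) to CEA inputs: θ₀ = −ln S₀(t*)/t*, θ₁ = HR·θ₀,
ΔE = 1/θ₁ − 1/θ₀, π = n_e/d_e. Collapsing the two exponential arm SDs
(1/θ₀, 1/θ₁) into the single pooled σ_E is genuinely underdetermined; the
default is root-mean-square pooling (preserves the average variance), with
the control-arm SD exposed as an alternative. This module is a
reconstruction of common design practice and its outputs are checked only
against closed-form exponential moments, not against any published figure.

## Monte-Carlo simulator

`generate_ipd` draws per-arm (effectiveness, cost) pairs from a Gaussian
copula with normal or exponential effectiveness and normal or lognormal
cost marginals. For normal marginals the copula correlation equals the
target Pearson ρ exactly; otherwise the latent correlation is calibrated by
inverting the induced Pearson correlation, computed with 48-point 2-D
Gauss–Hermite quadrature, via Brent's method. Targets outside the
attainable (Fréchet-type) range for the chosen marginals raise an error
that reports the range. The exponential effectiveness marginal is
one-parameter (SD = mean; the requested SD is ignored); the lognormal cost
marginal matches both requested moments.

`empirical_power` replays the full pipeline per replicate — simulate,
estimate per-arm moments (n−1 SDs, Pearson ρ), plug them into the two-arm
variance, apply the z-test — and returns the rejection fraction with its
binomial SE. One master seed is split into per-replicate streams with
`numpy.random.SeedSequence.spawn`, so any replicate is reproducible in
isolation and results are bit-identical across runs for a given seed.

The simulator emulates the *moment structure* of trial CEA data (means,
SDs, within-arm correlation, mild skew via the lognormal option). It does
not model censoring, cost-accumulation over time, zero-inflation, or
heavy-tailed cost outliers, so a passing calibration shows the analytic
formulas are correct for their own assumptions — not that those assumptions
hold in any particular trial.

## Problem sizes and defaults

Defaults follow standard design practice: α = 0.05 one-sided, target power
0.80, λ = $100,000 per effect unit, π = 1. The calibration study in the
test suite runs 5,000 replicates per cell over ρ ∈ {−0.5, 0, 0.44, 0.9} ×
λ ∈ {$50k, $100k, $200k} at n = 500 (250/arm) with CO.17-like moments
(σ_E = 0.309, σ_C = $16,130) and illustrative increments ΔE = 0.1,
ΔC = $3,000, chosen so the analytic power is interior (≈0.26–0.99) on the
whole grid; agreement is asserted within three binomial SEs, and the
type-I error is checked at the null boundary (λΔE = ΔC) at n = 200/arm.

## Known limitations

- The bundled parameter sets carry no ΔE/ΔC (those are user inputs), so
  power/sample-size numbers for the bundled trials depend on the increments
  the user supplies.
- The recorded reference line for CO.17 contains ρ-coefficients (3,516 and
  7,032 in thousands) that are internally inconsistent — half the values
  implied by the σ inputs, the recorded variances and the recorded
  percentage swings — along with one variance (21,746) inconsistent with
  its own recorded 21.5% decrease. The package computes the consistent
  values; `inbpower reproduce` flags the discrepancies rather than
  reproducing them.
- All power statements rest on the normal approximation for mean cost and
  effectiveness differences; very skewed costs at small n will be
  anticonservative, which the simulator's lognormal option can probe.
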