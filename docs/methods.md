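# Methods

## Model

For gene i in study j ∈ {1, 2}, let θⱼᵢ ∈ {0, 1} be the hidden significance
indicator. Conditional on θⱼᵢ the p-value follows a two-group model

    pⱼᵢ | θⱼᵢ ~ (1 − θⱼᵢ) f₀ + θⱼᵢ fⱼ,

with f₀ the Uniform(0,1) density (hard-coded; the package accepts no
user-supplied null density) and fⱼ the study-specific non-null density,
required to satisfy the monotone likelihood ratio condition: fⱼ/f₀
non-increasing on [0, 1]. The joint state τᵢ = (θ₁ᵢ, θ₂ᵢ) has prior
P(τᵢ = (k, l)) = ξₖₗ. The replicability null is the composite event
τᵢ ∈ {(0,0), (0,1), (1,0)}, and its posterior probability given the pair of
p-values is the local false discovery rate (Lfdr). Under the monotone
likelihood ratio condition the Lfdr is componentwise non-decreasing in
(p₁, p₂), which is what licenses isotonic density estimation and makes
Lfdr thresholding a sensible rejection region.

Modelling f₁ and f₂ separately (rather than forcing a shared alternative)
is what accommodates heterogeneity between studies — different platforms,
sample sizes, and signal strengths. The p-value sequences are assumed
conditionally independent given the hidden states, and genes are treated
as independent draws.

## Estimation

The marginal log-likelihood is Σᵢ log f(p₁ᵢ, p₂ᵢ) with
f = ξ₀₀ + ξ₀₁f₂(p₂ᵢ) + ξ₁₀f₁(p₁ᵢ) + ξ₁₁f₁(p₁ᵢ)f₂(p₂ᵢ). EM treats τᵢ as
latent:

* **E-step** — responsibilities γᵢ(k, l) ∝ ξₖₗ · (f₁(p₁ᵢ) or 1) · (f₂(p₂ᵢ)
  or 1).
* **M-step** — ξ̂ₖₗ = meanᵢ γᵢ(k, l); f̂₁ is the Grenander estimator of the
  p₁-sample weighted by w₁ᵢ = γᵢ(1,0) + γᵢ(1,1), and symmetrically f̂₂.

The weighted Grenander estimator — the non-increasing density maximizing
the weighted log-likelihood — is the left derivative of the least concave
majorant (LCM) of the weighted empirical CDF. It is computed by
non-increasing PAVA on the CDF chord slopes with the interval widths as
PAVA weights; exact ties among p-values are pooled at their shared knot,
and the density is 0 beyond the largest observation (tail knot at 1).
Both M-step blocks maximize their part of the expected complete-data
log-likelihood exactly, so the marginal log-likelihood is non-decreasing
across iterations; the trace is recorded and asserted in tests.

Step densities are evaluated left-continuously: each interval is
(knotₖ, knotₖ₊₁], with 0 belonging to the first interval. This is not a
cosmetic choice. The Grenander estimator is a *left* derivative, and only
with left-continuous evaluation does the fitted density evaluated at the
observations attain the maximized likelihood — with the right-continuous
convention an observation sitting exactly on a knot reads the next
(smaller) height, and the EM ascent property genuinely fails. Between
observed p-values the step-function convention is this package's choice;
the model itself does not pin down interpolation.

Numerical details, all exposed on `EMConfig`:

* Initialization: ξ⁰ = (0.85, 0.05, 0.05, 0.05); f₁⁰, f₂⁰ are one-study
  Grenander fits weighted by 1{p < median(p)}, a valid interior starting
  point that breaks the null/non-null symmetry. No randomness is used
  anywhere in the fit.
* Convergence: relative change |Δℓ|/(|ℓ| + 1) < 1e-6, at most 200
  iterations; non-convergence warns and returns the current fit. Note the
  stopping rule is effectively part of the estimator: the nonparametric
  density component lets the likelihood creep almost indefinitely
  (the Grenander piece slowly sharpens near 0), so "run to machine
  convergence" is not obviously better and can drift past sensible
  estimates. The defaults are ordinary EM practice; tighten `tol` to trade
  bias near heavy between-study inconsistency against that drift.
* Floors: density values are floored at 1e-10 inside ratios and logs
  (Lfdr divides by the mixture density); mixture weights are floored at
  1e-8 and renormalized, and a collapsed component's density update is
  skipped, keeping the previous estimate. p-values of exactly 0 or 1 are
  clipped to [1e-15, 1 − 1e-15] at ingestion, which changes no ordering.

## Inference

FDR*(λ) = Σ Lfdrᵢ 1{Lfdrᵢ ≤ λ} / Σ 1{Lfdrᵢ ≤ λ} estimates the FDR of the
region {Lfdr ≤ λ}, since the Lfdr is itself the posterior probability of a
false rejection. The procedure thresholds at
λ̂ₘ = sup{λ : FDR*(λ) ≤ α}; because FDR* jumps only at observed Lfdr
values, the supremum is taken over those values (plus 0). For tie-free
data this is exactly the running-mean step-up rule on the ordered Lfdr
values. Ties are resolved by the value-threshold reading: a block of equal
Lfdr values enters or leaves the rejection set as a whole, which keeps
FDR*(λ̂ₘ) ≤ α in all cases (the "extend k through the ties" reading can
violate it). Rejection sets are nested in α by construction.

The enrichment-oriented gene ranking orders genes by Lfdr and scores the
rank-i gene with the running mean (1/i) Σⱼ≤ᵢ Lfdr₍ⱼ₎ — the estimated FDR
of the top-i list — a non-decreasing score sequence that differs from
p-value-based rankings because the Lfdr borrows strength across studies
and across genes.

## Baselines

`adhoc_bh` runs plain (non-adaptive, no π₀ estimation) Benjamini–Hochberg
within each study at level α and intersects; `maxp` runs BH on
max(p₁ᵢ, p₂ᵢ). Neither is recommended: the intersection does not control
the composite-null FDR once the studies disagree often (ξ₀₁ = ξ₁₀ large),
and MaxP is valid but severely conservative. They exist for the
operating-characteristic comparisons.

## Simulation harness

`simulate_pair` draws τᵢ multinomially from ξ, then Xⱼᵢ ~ N(θⱼᵢ μⱼ, σⱼ²),
Zⱼᵢ = Xⱼᵢ/σⱼ, pⱼᵢ = 1 − Φ(Zⱼᵢ). Defaults are the reference study
conditions: m = 10,000 genes, ξ = (0.85, 0.05, 0.05, 0.05), μ₁ = μ₂ = 2,
σ₁ = σ₂ = 1, 100 replicates, nominal FDR 0.05. Replicate r uses the
substream `SeedSequence(seed, spawn_key=(r,))`, so any replicate is
reproducible in isolation and experiments parallelize deterministically.
Empirical FDR is reported as the mean false discovery proportion across
replicates with its Monte-Carlo standard error (the reference design
reports no standard errors; the ±2·MCSE bands used in tests are this
package's convention); power is the mean true positive proportion among
truly replicable genes, reported as 0 when no replicable genes exist.

What the generator does and does not emulate: it produces exactly
calibrated, independent uniform null p-values and a common parametric
alternative per study. Real SVG screens have correlated genes, discrete
and heteroskedastic expression, and imperfectly calibrated upstream tests,
none of which is represented here. Passing the simulation checks
demonstrates correctness of the procedure under its own assumptions, not
robustness to violations of them.

The replicated acceptance checks use 25 replicates per setting (the
headline script uses 100); both sizes give Monte-Carlo standard errors
well below the effects being asserted.

## Known limitations

* Exactly two studies; the mixture would extend to more by adding joint
  states, at cost exponential in the number of studies.
* The EM estimate of ξ carries a small finite-sample bias toward the null
  component when signals are weak and between-study inconsistency is
  heavy (ξ₀₁ = ξ₁₀ = 0.2 with μ = 2): mass on the boundary between "weak
  non-null" and "null" is genuinely hard to assign, and the averaged ξ̂₀₀
  error reaches ≈ 0.03 at m = 10,000. FDR control of the resulting
  procedure is unaffected in our checks.
* The raw power of the invalid intersection baseline can exceed this
  procedure's power exactly where that baseline has given up FDR control;
  power comparisons are meaningful only among procedures holding the same
  error rate.
* Lfdr values depend on the fitted mixture; with very small m (below a
  few hundred genes) the nonparametric density estimates are noisy and
  the step-up threshold unstable.
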