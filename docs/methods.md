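# Methods

## The model

`enf3d` models the nerve trees observed in epidermal skin-biopsy boxes as a
marked 3D point pattern: base points (where a nerve trunk enters the
epidermis), first branching points, and end points (terminations).  The
pattern is treated as a realization of a simple, locally finite, stationary
point process observed in a box `W × [0, Zmax]`, with the planar window
fixed by the imaging protocol (320 × 432 μm) and the depth `Zmax` following
the local epidermal thickness (50–200 μm).  All coordinates and lengths are
in μm; the window origin sits at `(0, 0, 0)` and membership is closed-box,
so traced points on a slide boundary are never dropped.

The model factorises into two conditional stages.

**Planar stage (two-step cluster model).**  Conditioned on the base points,
each tree receives one branching point at distance `L1 ~ Gamma(α1, β1)`
and direction `Φ1 ~ vonMises(m, κ)`, where the known mean direction `m`
points toward open space — the azimuth away from the nearest other base
point (ties broken by lowest index).  Around each branching point, `S` end
points are placed with radial distances `L2 ~ Gamma(α2, β2)` and isotropic
angles `Φ2 ~ Uniform(0, 2π)`; `S − 1 ~ NB(s, p)` so every tree terminates
at least once, with mean cluster size `1 + ps/(1−p)`.  All components are
treated as independent, so each is estimated from its own empirical sample:
Gamma and negative-binomial parameters by maximum likelihood (the NB fit
profiles out `p` through the MLE mean-matching identity and optimises only
`s`), and `κ` by the approximate MLE `κ̂ = R̄(2−R̄²)/(1−R̄²)` based on the
mean resultant length `R̄` of the angles centred at their known means.  A
full numerical MLE of `κ` (solving `I1(κ)/I0(κ) = R̄`) is provided as a
cross-check; the closed form agrees with it to a few percent over the κ
range seen here.

**Depth stage (pairwise-interaction Markov field).**  Given the planar
locations, the vector of end-point depths has Gibbs density proportional to
`γ^{s_B} · 1{hardcore}`, where `s_B` counts unordered pairs whose
displacement falls in a cylinder of radius `w` and half-height `t` aligned
with z, and the hardcore indicator requires every pair to be strictly more
than `h` apart in 3D.  `γ = 1` is no interaction; `γ > 1` attraction.  The
full conditional of one depth is `f(z_i | rest) = γ^{s_i} 1{hardcore}/c_i`
with `c_i` a 1D integral over `[0, Zmax]`.  Because the planar locations
are fixed, the integrand is piecewise constant — neighbour relations
toggle at `z_j ± t`, the hardcore at `z_j ± sqrt(h² − d_xy²)` — so `c_i` is
evaluated exactly by summing over its at most `2n + 1` constant segments
(midpoint evaluation inside a segment is exact).  Riemann quadrature is
retained only as a test oracle.

## Estimation

The hardcore is estimated first as `ĥ = (n−1) d_min / n`, with `d_min` the
minimum 3D distance among the end points (the mark the interaction model
applies to).  The remaining parameters combine pseudo-likelihood and grid
search: for every cell of a `(w, t)` grid, `Σ_i log f(z_i | rest)` is
maximised over `log γ` by bounded scalar optimisation on `[−5, 5]`
(positivity and scale invariance motivate the log parameterisation), and
the cell with the highest optimum supplies `(ŵ, t̂, γ̂)`.  Minus sampling
restricts the pseudo-likelihood sum to points of an eroded window — margins
`max(max w-grid, ĥ)` in xy and `max(max t-grid, ĥ)` in z, so every
candidate cell scores the same interior points and cell values are
comparable — while neighbour counts and `c_i` use all observed points.
Points at exactly distance `h` violate the hardcore (strict inequality).

Subjectwise fits pool a subject's samples: planar component samples are
concatenated; Markov fits sum the per-sample pseudo-likelihood terms at
shared `(γ, w, t)` with the subject-level hardcore
`(N−1)/N · min_samples d_min` (`N` = total end points).  Whether ĥ should
be per-sample or per-subject is genuinely open; per-subject is the default
and the `h` argument overrides it.

A finite-sample caveat worth knowing: when the generating depths carry no
interaction and no hardcore, the plug-in `ĥ` — which by construction sits
just below the realized `d_min` — "explains away" the chance absence of
very close pairs and pushes `γ̂` slightly above 1 (order +0.1 at n ≈ 150
clustered points in a 100 μm deep box, vanishing as n grows).  This is a
property of the plug-in procedure itself, not of the optimiser.

## Simulation

Depths are sampled by a fixed-n single-site Metropolis–Hastings sweep:
depths initialise uniformly (placed sequentially, each redrawn until
hardcore-compatible with the points already placed, since a joint uniform
draw may be infeasible), and each sweep visits every point once in a fresh
random permutation, proposing `z' ~ Uniform(0, Zmax)` and accepting with
probability `min(1, γ^{Δs} · 1{hardcore})` — the ratio of full
conditionals, in which `c_i` cancels.  Defaults are 5000 burn-in plus 5000
retained sweeps.  On a 3-point system with a discretised depth window, the
sampler's stationary distribution of `s_B` matches exhaustive
`γ^{s_B}`-weighted enumeration to total variation < 0.05.

## Summary statistics

Second-order diagnostics use translation-corrected estimators: Ripley's K
(`1/(λ̂n) Σ' 1{‖x1−x2‖≤r}/|W ∩ W_{x2−x1}|`, `λ̂ = n/|W|`) and the
cylindrical K in an axis direction `u`, normalised by
`λ̂2 = n(n−1)/|W|²`.  The cylindrical structuring set is the finite
cylinder of radius `w` and half-height `r` along `u`; with this choice
`K_cyl^u(r) = 2πw²r` under complete spatial randomness, so the centred
variant `L_cyl^u(r) − r = K_cyl^u(r)/(2πw²) − r` vanishes identically under
CSR, exactly as `L(r) − r = (K(r)/b_d)^{1/d} − r` does for the isotropic
statistic.  Anisotropy is read from the disagreement of the x-, y- and
z-direction curves.  The default r grid is 0–30 μm in 0.5 μm steps (the
scale of the end-point clusters); the goodness-of-fit half-width defaults
to `w = 7` μm, chosen smaller than the cluster radius, and is always an
explicit parameter.  Grid points that any contributing pair reaches with a
zero translation-overlap volume are flagged undefined (NaN) rather than
silently dropped.

Replicated patterns pool in two stages — samples into a subjectwise curve,
subjects into a groupwise curve — as pointwise weighted means.  Weights
default to the number of points behind each estimate and accumulate through
the stages, so two-stage pooling reproduces the one-stage pooled estimate
exactly.  `n²`-proportional weighting can be had by passing explicit
weights.

**Envelopes.**  Global envelopes use the extreme-rank-length (ERL)
ordering: pointwise two-sided ranks among all curves (observed +
simulated), each curve's rank vector sorted increasingly and compared
lexicographically.  At level `1−α` the `⌊α(n_sim+1)⌋` most extreme curves
are set aside; the band is the pointwise min/max of the rest, and the
verdict is the rank test itself — the observed curve is "outside" when it
is among the set-aside curves — which has exact nominal coverage under
exchangeability (a kept observed curve lies within the band everywhere by
construction).  Pointwise bootstrap envelopes resample subjects with
replacement, recompute the pooled curve per resample, and read off
pointwise quantile bands.

## Synthetic studies

The generator chains the three stages into group/subject/sample
hierarchies with per-sample windows (`Zmax ~ Uniform(50, 200)` μm) and
per-sample seeds derived deterministically from the master seed and the
(group, subject, sample) indices.  Base points follow a hardcore-thinned
planar Poisson process (Matérn-II-style, arrival order randomised); the
default intensity `1.5e-4 /μm²` and base hardcore 10 μm give roughly 20
trees per 320 × 432 μm sample, the visual scale of real biopsies.  Base
and branching points are placed at depth 0 — only the end points carry
modelled depths.  Offspring falling outside the planar window are redrawn
(length and angle together, preserving the radial law conditionally on
containment) up to 100 times before erroring.

Two built-in parameter sets encode the qualitative group contrasts reported
for real patterns — the healthy-like group has longer branches (mean L1
20 vs 14 μm), less concentrated branching directions (κ 0.5 vs 2), larger
clusters (mean S 5.5 vs 3, mean L2 12 vs 8 μm), and stronger, wider,
longer-ranged depth attraction (γ 3 vs 2, h 1.5 vs 1, w 10 vs 6, t 4 vs 3
μm) than the mild-neuropathy-like group.  The generator emulates the
hierarchy, geometry and interaction structure of real samples; it does not
emulate epidermal heterogeneity (dermal papillae), covariate effects, or
tracing noise, so passing tests demonstrate internal consistency of the
estimators under the model, not fidelity of the model to any particular
tissue.

## Numerical choices and problem sizes

Tolerances and scales used by the test-suite experiments, chosen as the
package's own desk-scale defaults: CSR properties use 100 replicates of
~200-point patterns; no-interaction γ recovery uses 50 replicates of
~150-point patterns; envelope coverage uses 200 trials of 199-simulation
envelopes at the 95% level; the end-to-end study uses 2 groups × 10
subjects × 2 samples with the MCMC defaults.  The γ optimiser converges
from either end of its bracket to within 1e−4 in log γ on unimodal
profiles; a completely flat profile (no interaction information in the
pattern) returns γ = 1 by convention.

## Known limitations

- One branching point per base point; trees without a branching point are
  skipped (with a warning) during component extraction.
- The base-point process itself is never modelled, only conditioned on;
  the synthetic generator's base process is deliberately simple.
- No joint 3D interaction between base, branching and end points, no
  non-cylindrical interaction regions, and no within-pattern variation
  of γ.
- Envelope verdicts are the only significance machinery; no test
  statistics for group differences are provided.
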