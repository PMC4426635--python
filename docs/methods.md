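# Methods

## Model and conventions

The reference process is the linear birth–death (BD) process: one founder at
forward time t = 0, per-capita birth rate λ > 0, death rate μ ∈ [0, λ),
stopped at the origin time T.  r = λ − μ is the net growth rate,
R₀ = λ/μ the basic reproductive number, and ρ = 1/(2λ) the generation time
that links the coalescent rate to the BD rates.  Forward time is t, backward
time τ = T − t; all coalescent-time distributions are in τ.  Only the
supercritical case μ < λ is supported (parameter validation enforces it);
the near-critical regime is reached as μ → λ with r > 0.

## Closed forms (module `bd_analytic`)

Everything follows from Kendall's solution for the process started at one
individual.  With E = e^{−rt}:

- p₀(t) = μ(1 − E)/(λ − μE), p₁(t) = r²E/(λ − μE)²;
- survivor count given survival is geometric with failure probability
  β(t) = λ(1 − E)/(λ − μE), so E[N(t)] = e^{rt} and, conditioning on
  survival to T (probability 1 − p₀(T)),

  E[N(t) | survival to T] =
  (e^{rt} − p₁(t)·a/(1 − β(t)a)²) / (1 − p₀(T)),  a = p₀(T − t),

  the "push of the past" curve: it exceeds e^{rt} whenever μ > 0, t > 0, and
  equals (λe^{rT} − μ)/r at t = T.  That endpoint value inverts in closed
  form, giving the origin time for a target conditioned size N:
  T = ln(((λ−μ)N + μ)/λ)/(λ−μ).  A bracketed Brent solver on
  [ln N/λ, ln N/r] is kept as an alternative `method="brent"` and as a test
  oracle; the two agree to ~1e−12 relative.

Writing all expressions through e^{−rt} rather than e^{rt} serves two
purposes: nothing overflows for large rT, and the μ = 0 (Yule) case needs no
separate branch — β(t) = 1 − e^{−λt} is exact there, whereas the ratio
p₀(τ)/p₀(T) would be 0/0.

### Pairwise coalescent time under BD

The genealogy of the individuals extant at T, for the process conditioned on
survival, is a coalescent point process: tip count geometric with failure
probability b = β(T), node depths i.i.d. with CDF u(τ) = β(τ)/β(T), and the
MRCA depth of tips i < j equal to the maximum of the j − i depths between
them.  Sampling two tips uniformly (which requires conditioning on at least
two survivors, the same conditioning used by the tree oracle) and summing
the geometric mixture in closed form yields

F_BD(τ) = 2u(1−b)/(b²(1−u)²) · [(1−bu)·ln((1−bu)/(1−b)) − b(1−u)],

with density f_BD = dF_BD/du · u′(τ), u′(τ) = λp₁(τ)/β(T).  The bracket
vanishes to third order as u → 1, so for a(1−u) < 1e−3 (a = b/(1−b)) both
F_BD and f_BD switch to their series in 1 − u; the two branches agree to
~1e−7 where they meet, and a numerical-derivative test pins the joint.  When
b rounds to exactly 1 in double precision (λT ≳ 37 with μ = 0, i.e.
populations ≳ 1e16) the distribution is returned as a point mass at T, its
analytic limit.  These forms were not taken on faith: the implementation was
accepted only after Kolmogorov–Smirnov agreement with 10⁵ brute-force
full-tree simulations (acceptance threshold KS < 0.01) and, during
development, with the Yule special case.

## Deterministic coalescents (module `coalescent_deterministic`)

CD uses hazard 1/(N(τ)ρ) with N(τ) = N₀e^{−rτ}: cumulative hazard
(e^{rτ}−1)/(rN₀ρ), hence closed-form density and CDF with support (0, ∞).
The within-[0, T] mass at T = ln N₀/r is 1 − exp(−(N₀−1)/(rN₀ρ)); its
N₀ → ∞ complement exp(−1/(rρ)) = exp(−2λ/(λ−μ)) is the ancestral-mass
limit: e⁻² at μ = 0, monotone decreasing in μ, → 0 as μ → λ.  As r → 0 at
fixed Θ = N₀ρ the CDF converges to the constant-size pair CDF 1 − e^{−τ/Θ}
(verified at r = 1e−8).

CDN replaces N(τ) by the push-of-the-past curve evaluated backward.  Its
cumulative hazard has no elementary antiderivative and is computed by
adaptive quadrature (absolute tolerance 1e−12, relative 1e−10), accumulated
incrementally over a sorted τ grid so a full 513-point curve costs one pass.
Tests require 1e−6 agreement with an independent composite Gauss–Legendre
integration (400 panels × 8 nodes).  The no-coalescence deficit
1 − F_CDN(T) is exposed as an explicit atom, never folded into the CDF.

The N−1 rate convention (hazard 1/((N(τ)−1)ρ)) is available for CD, CDN and
CS.  It is reconstructed from its uses — the comparison's dashed variants —
as "replace N by N − 1 in the pair rate"; for CD it has the closed form
F = 1 − ((N₀−e^{rτ})/(N₀−1))^{1/(rρ)}.  The hazard diverges where the size
function reaches 1 (τ → T), a logarithmic divergence of the cumulative
hazard, so F(T) = 1 and the atom is exactly 0; the quadrature never
integrates across that endpoint — the value there is set to its exact limit.

An optional `normalized_at_T()` view rescales any curve to reach 1 at T, for
comparisons of shape rather than mass.

## Simulation (modules `bd_simulator`, `cs_sampler`)

The Gillespie simulator is exact: with n alive the waiting time is
exponential with rate n(λ+μ) and the event is a birth w.p. λ/(λ+μ).  The
run extends to the first event time beyond T; no event occurs at T itself.
Conditioning — `survival` (N(T) ≥ 1, the conditioning of the mean-size
formula) or `at_least_two_at_T` (N(T) ≥ 2, required whenever a pair is
sampled, and therefore the default for trees and for CS) — is by rejection,
which is exact; the acceptance probability for survival is 1 − p₀(T)
(roughly r/λ for long horizons, ≈ 4.8% in the hardest comparison cell
R₀ = 1.05).  A guard aborts after 1e7 rejections.  Trajectories store only
event times and ±1 increments; trees store segment arrays (parent, creation
time, end time) and serialize to Newick with extant tips labelled t1..tn.

The CS sampler walks a trajectory backward from τ = 0, inverting a standard
exponential through the piecewise-linear cumulative hazard — exact, with no
time grid.  A draw exceeding the total hazard at τ = T is the sentinel
`NO_COALESCENCE`, a first-class outcome, never a number.  Under the N−1
variant a segment at size 1 has infinite hazard and coalesces the pair at
that segment's most recent endpoint, so no-coalescence cannot occur.  The
ensemble estimator draws one coalescence time per independent conditioned
trajectory: draws within one trajectory are dependent through it, and one
draw per trajectory keeps every grid-point standard error binomial
(≤ 0.5/√n_traj).  An optional `draws_per_traj > 1` exists for
variance-reduction experiments, with the caveat that its error accounting
requires trajectory-level resampling.

Randomness: one integer seed per call; replicate k of an ensemble uses
base_seed + k, so every artefact is bit-for-bit reproducible under a fixed
seed (asserted by tests on the CSV bytes).

## The comparison grid (module `experiments`)

λ = 0.5 fixes the time unit and makes ρ = 1.  Cells scan
R₀ ∈ {1.05, 1.3, 1.6, 2, 4, 10, 20} × N₀ ∈ {10, 100, 1000, 10000}, setting
μ = λ/R₀ and T so the survival-conditioned mean at T equals N₀ (exact by
the closed-form inversion).  Each cell emits the BD curve plus CD/CDN/CS
under both rate variants on a 512-point τ grid plus the exact point T, as
CSV and as an overlay plot (solid per-N, dotted per-(N−1), an end marker at
T for the coalesced-by-T fraction, ±2 SE bands on Monte-Carlo curves).
The default of 10⁴ CS trajectories per cell makes the full grid a
long-running batch job (the R₀ = 1.05, N₀ = 10⁴ cell alone needs ~4e5
events per accepted trajectory); the test suite therefore exercises
scaled-down cells — 10³ trajectories at (R₀ = 1.05, N₀ = 10³), where the
CS–BD sup-distance bound of 0.05 comfortably exceeds the ~0.016 Monte-Carlo
noise floor, and analytic-only checks at (R₀ = 20, N₀ = 10⁴).  Curves are
deliberately chosen so that every plotted line exists as CSV data.

## What the synthetic data do and do not show

All validation data are generated by the package's own exact simulators, so
agreement demonstrates internal correctness of the closed forms and
samplers under the stated model — constant rates, complete sampling at one
time point, a pair of lineages.  It does not probe serial sampling,
incomplete or non-uniform sampling, rate variation over time, n > 2
genealogies, or inference from sequence data; none of these are in scope.

## Known limitations

- The critical case μ = λ is excluded by construction (r > 0 is assumed
  throughout); behaviour near criticality is exercised only down to
  r = 0.001λ.
- CDN evaluation cost is one adaptive quadrature per curve, so very fine
  grids (≫ 10⁴ points) are slower than the closed-form models.
- The Gillespie simulator is event-driven pure Python; ensembles beyond
  ~1e8 events (e.g. the full default grid) are batch-scale rather than
  interactive.
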