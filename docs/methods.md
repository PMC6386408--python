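# Methods

## The reduced deme-level model

The simulator works at the level of demes, not individuals.  Each site of a
periodic `d`-dimensional integer lattice (`d ∈ {1, 2}`, linear size `L`)
holds one allelic identity: 0 for wildtype, `k ≥ 1` for the `k`-th
beneficial mutation to arise.  This reduction assumes strong selection and
weak mutation/migration at the deme scale: within-deme fixation of the
first arriving beneficial allele is fast compared to the arrival of the
next mutant or migrant, so a deme is effectively monomorphic and the first
allele to establish excludes all later ones (allelic exclusion).  Under
that reduction, the individual-level parameters (selection coefficient,
deme size, per-capita mutation and migration rates) collapse into a single
rate: the rescaled mutation rate `ũ = u/m`, the expected number of
deme-level mutation events per dispersal attempt.  The model is then fully
specified by `(L, d, μ, ũ)` plus a seed.

Event dynamics: each deme carries weight `ũ` if wildtype and 1 if mutant.
A step picks mutation with probability `ũ·n_wt / (ũ·n_wt + n_mut)` and
otherwise a migration from a uniformly chosen mutant deme.  The jump length
is `r = u^{-1/μ}` for uniform `u ∈ (0, 1]` (inverse CDF of
`J(r) = μ r^-(1+μ)` on `r ≥ 1`); the direction is a fair sign in 1D or a
uniform angle in 2D; each real component is rounded to the nearest integer
and the target is wrapped periodically.  Occupied targets leave the lattice
unchanged but still consume a time increment — this matters for correct
time accounting near sweep completion.  Time is measured in units of the
expected interval between dispersal events per deme and advances by
exponential increments of mean `1/R`, `R = n_mut + ũ·n_wt` (a deterministic
`1/R` mode exists for variance-reduced growth curves).  The all-mutant
state is absorbing, so termination is guaranteed; a configurable event
ceiling guards against runaway parameter choices.

Numerical detail: sampled jump distances are clamped at `10^15` demes
before rounding.  Distances beyond `~2^53` are not resolvable to unit
lattice spacing in double precision anyway, and after periodic wrapping the
clamp is statistically inconsequential for any representable range; it only
prevents int64 overflow for very heavy tails (`μ < 0.5`).

The inner loop is compiled with numba.  Category membership (wildtype vs
mutant demes) is kept in swap-and-pop index lists, making every event O(1);
sustained throughput is ~5×10^6 events/s on one CPU, which puts complete
sweeps at `L = 10^5` in seconds.  Randomness flows from one recorded seed
per replicate; ensembles derive distinct 31-bit seeds from a master seed
via `numpy.random.SeedSequence` and refuse duplicates.

## Solitary-clone growth and the core-growth function

`run_solitary` reuses the event loop with `ũ = 0` and one seeded mutant,
recording `(t, M)` at every colonization.  The core-growth function is
defined as `ℓ(t) = E[(M(t)/ω_d)^{1/d}]` with `ω_1 = 2`, `ω_2 = π`
(mass-equivalent radius), estimated by step-interpolating each trace on a
common grid and averaging.  The *canonical* `ℓ(t)` used by the scaling
solver is this tabulated curve with a monotone PCHIP interpolant in log-log
coordinates (noise is removed with a running maximum); fitted closed forms
are cross-checks and extrapolation devices, because the exact finite-time
growth laws near `μ = d` are not expressible in elementary closed form.
Regime-appropriate asymptotics, each with free length/time prefactors
`A, B`:

| regime | asymptotic `ℓ(t)` |
| --- | --- |
| `μ < d` | `exp(B_μ t^η)`, `η = log(2d/(d+μ))/log 2`, `B_μ ≈ 2d·log2/(μ−d)²` |
| `μ = d` | `exp(c·log² t)` (`c` fitted, qualitative only) |
| `d < μ < d+1` | `t^{1/(μ−d)}` |
| `μ = d+1` | `t log t` (1D) |
| `μ > d+1` | `t` (constant-speed front) |

Note `η ∈ (0, 1)`: it tends to 1 as `μ → 0` (exponential growth, the
well-mixed limit) and to 0 at `μ = d` (the marginal `log²` form).  Fits are
least squares on `log ℓ`; in the linear and power regimes `B` is degenerate
with `A` and is reported as 1.  A `t_min` window excludes the single-deme
transient.  Solitary runs set a finite-size flag once the clone passes
`(0.4 L)^d` demes, where wrap-around contaminates growth.

## Characteristic scales

`t*` solves `ũ · t · ω_d · ℓ^d(t) = 1` — the time by which one new
mutation is expected inside the space-time region swept by a growing core.
The left side is strictly increasing, so the root is unique; it is found by
bracket expansion plus Brent's method at ~1e-12 relative tolerance.  On a
tabulated curve too short to bracket the root, the solver raises an
out-of-domain error instructing the caller to simulate longer — silent
extrapolation is deliberately not performed; extrapolation is available
only through an explicitly fitted asymptotic form.

Derived scales: core extent `χ = ℓ(t*)`; satellite extent `ψ = ℓ(2t*)`
(key jumps that merge with a core at time `t` were launched near `t/2` over
distances `~ℓ(t)`, so a core grown for `t*` has seeded satellites out to
`~ℓ(2t*)`); rare-jump limit `ζ = ũ^{-1/μ}` (the clone makes `~1/ũ` jumps
during `t*`, of which a fraction `l^{-μ}` exceed `l`).  The expected number
of mutational origins in a range is `L^d/(ω_d χ^d)`.

Closed forms `χ_as` (unit prefactors), each obtained by solving the balance
equation analytically with the asymptotic `ℓ(t)` and cross-validated
against the numerical solver to <0.1%:

* `d < μ < d+1`: `χ_as = (ũ ω_d)^{-1/μ}`
* `μ > d+1`: `χ_as = (ũ ω_d)^{-1/(d+1)}`
* `μ < d`: `χ_as = [ξ/W(ξ)]^{1/(η d)}` with
  `ξ = η d B_μ (ũ ω_d)^{-η}` (principal Lambert branch `W_0`; all
  arguments are positive)
* `μ = d`: `log t*` is the positive root of
  `d c y² + y + log(ũ ω_d) = 0`, `χ = exp(c y²)` (requires the fitted `c`)
* `μ = d+1`, 1D: `χ_as = ½ √(W(1/ũ)/ũ)`

The halo/core ratio of a clone with core extent `l` is
`l' = ℓ(2 ℓ^{-1}(l))`: constant `2^{1/(μ−d)}` in the power regime,
size-dependent `l^{2^η − 1}` in the stretched regime.

## Clone geometry

Distances are periodic (minimal image) and measured from the recorded
originating deme of each clone.  `r_eq = (X/ω_d)^{1/d}`.  The 1D extent is
`r_max = (L − g)/2` with `g` the largest circular gap between members —
half the arc spanned by the clone, capped at `L/2` (the largest measurable
extent under periodic boundaries).  The 2D extent is the eighth root of the
mean eighth power of member distances from the periodic (circular-mean)
centroid; the high moment weights the farthest satellites, and the specific
convention matters only for 2D summaries, which are preliminary.

Occupancy profiles: `ρ(r)` is the occupied fraction of the lattice shell at
integer distance `r` from the clone's origin (in 1D the two demes
`origin ± r`; the antipodal shell on an even ring holds one deme, giving
the exact identity `Σ_r ρ(r)·|shell(r)| + 1 = X`).  Profiles are binned in
`r/r_eq` (default width 0.1, support to 50), averaged over clones with
`X > 100` within a simulation and then across simulations.  Core occupancy
is the trapezoidal fraction of the ensemble profile inside `r/r_eq ≤ 2`,
the maximal scaled distance a contiguous 1D clone can reach.  2D shells use
Euclidean distances rounded to integer radii, with shell sizes counted once
per lattice size.

## Spectra and sampling

The allele frequency spectrum is estimated on 50 logarithmic bins spanning
`[1/L^d, 1]`; counts are divided by bin width and averaged over
simulations, preserving `∫x f(x) dx = 1` to within binning error.  Two
finite-size artifacts are documented rather than corrected: the lowest-bin
uptick (hard frequency cutoff at one deme meeting log-width bins) and an
integer-mass "comb" below ~10 demes (frequency quantization finer than the
bins).  Statistics that depend on spectrum *shape* therefore mask bins
below 10 demes and bins holding fewer than ~10 clones.

The `(p, x_c)` summary follows the hard-cutoff power-law ansatz
`f ∝ x^p` for `x < x_c`.  The cutoff is the first scaled frequency where
the discrete log-log curvature (3-point second difference) drops below −4;
to keep that rule stable on finite ensembles the per-bin Poisson error is
propagated through the stencil and a crossing must clear the threshold by
3σ.  The exponent is the least-squares slope between the 5th percentile of
the log support and `x_c/3`, clipped to the theoretical range `[−1, 1]`
(the panmictic and wavelike limits).  For an exact ansatz population the
normalization ties cutoff and exponent: `L^d x_c / X_ave = (p+2)/(p+1)`,
and `P_hard(j) = (p+2)/(p+j+1) · x_c^{j−1}` by direct integration; both
serve as round-trip oracles.  On simulated sweep spectra, whose cutoffs are
soft shoulders rather than cliffs, the operational `x_c` is systematically
on the early side of the terminal falloff — fits there are summaries, not
parameter estimates.

Sampling is with replacement throughout: `P_hard(j)` is the ensemble mean
of `Σ_i x_i^j`, equal to `∫x^j f dx` up to binning.  The panmictic
reference is Ewens' monoallelic-sample probability `∏_{i<j} i/(θ+i)`, with
`θ` an explicit user parameter (its mapping onto `ũ L^d` is outside the
scope of this package).  Local protocols place `n_windows` contiguous
windows of linear size `L_s` uniformly at random (window placement takes
its own seed); reported are the window homoallelicity `Σ_a (n_a/L_s)²` and
the distinct-allele count, averaged over windows and simulations.  The
equal-clone null `P_hard,s(2) = 1 − x/3` (`x < 1`) or `1/x − 1/(3x²)`
(`x ≥ 1`), `x = L_s/X_ave`, is exact for the deterministic tessellation
fixture up to `O(1/X)` discreteness.

## Synthetic-data generators

Two generators make every analysis stage testable without long sweeps.
The tessellation fixture tiles the ring with equal contiguous clones
(origins at segment centers) — the geometry assumed by the equal-clone null
model.  The spectrum fixture draws clone masses from a prescribed density
(the ansatz by default), renormalizes to sum exactly `L^d` by
largest-remainder rounding, and drops zero-mass clones; drawing more clones
than `1/E[x]` per simulation sharpens the realized cutoff (the
renormalization rescales it) and is used where cutoff statistics matter.
What these fixtures deliberately lack: spatial correlations, halo
structure, and the clone-size correlations a real sweep induces — so tests
against them validate the *estimators*, while tests against simulated
ensembles validate the *science*.

## Problem sizes and test design

The packaged checks run 1D ensembles at `L = 3×10^4 – 10^5` with 12–100
replicates per condition and solitary-growth ensembles stopped at masses of
`4×10^3 – 1.5×10^5` — sizes at which every scaling property tested here is
already well developed, while a full suite completes in minutes.  Mean
clone masses are range-independent once `L ≫ χ`, so these stand in for the
much larger ranges used in production-scale studies; statistics that need
the halo far field (occupancy tails, extent ratios at `μ < d`) use the
larger `L` values.  2D code paths are implemented and unit-tested, but all
quantitative claims are exercised in 1D.

## Known limitations

* No within-deme dynamics: drift, selection coefficients and deme sizes
  enter only through the reduction to `ũ`; times are in dispersal units and
  are not converted to generations.
* No back mutation, no fitness differences among mutant alleles, no
  post-sweep mixing of neutral-relative alleles.
* The marginal forms (`μ = d`, `μ = d+1`) carry free coefficients and are
  qualitative; near those points the asymptotic closed forms are poor and
  the tabulated `ℓ(t)` should be used.
* Jumps longer than `L/2` alias under periodic wrapping (no kernel
  truncation is applied); extents are capped at `L/2` accordingly.
* The operational cutoff `x_c` on soft-shouldered simulated spectra is an
  underestimate of the terminal falloff; comparisons across kernels are
  meaningful, absolute values less so.
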