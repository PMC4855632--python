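# Methods

This note documents the statistical machinery behind `devplan`: the design
engines, the composition of the six development plans, the numerical
choices, and the points where the design of the package itself was open.

## Single-arm engine

A Simon two-stage design `(r1, n1, r, n)` stops for futility after `n1`
patients when responses are at most `r1`, and otherwise continues to `n`
patients, rejecting `H0S: pE <= p0` when total responses exceed `r`. The
optional efficacy boundary `e1` stops the trial with an immediate go when
stage-one responses exceed `e1`. All three boundaries are *strict*
("reject if more than"), matching the conventional `r1/n1 r/n` tabulated
notation; this is worth stating because an off-by-one reading of `e1`
changes the type-I error of the worked example's efficacy-stopping design
from 0.049 to 0.056 and breaks its published operating characteristics.

Rejection probabilities, early-termination probabilities and
`E(N) = n1 + (1 - PET)(n - n1)` are exact binomial sums (scipy's binomial
pmf/sf); no normal approximation is used in the single-arm stage. The
optimal-design search enumerates `n` ascending, then `n1`, `r1`, `e1` and
`r`, with the inner two dimensions vectorised: for each `(n1, r1, n2)` the
rejection probabilities for *all* `(e1, r)` pairs come from one cumulative
sum over the continuation outcomes. Feasibility is `P(reject | p0) <=
alpha_s` and `P(reject | p1) >= 1 - beta_s`; among feasible designs the
expected size under `p0` is minimised (the classical H0-optimal criterion,
also applied to the efficacy-stopping family), with ties kept at the first
design encountered, i.e. the smallest `n`. Branches are pruned when
`n1 >= best E(N)` (the expected size can never fall below `n1`) and when
the stage-one futility stop alone already exceeds `beta_s`. The default
search bound `n <= 100` covers the worked example comfortably; the bound is
configurable, and exceeding it raises an explicit infeasibility error
naming the bound.

## Two-arm engine

The fixed design uses the normal approximation to the difference of two
binomial proportions with unpooled variance:
`n/arm = ceil((z_alpha + z_beta)^2 (p0 q0 + p1 q1) / (p1 - p0)^2)`.

Group-sequential designs are parameterised by the canonical joint
distribution: at look `k` with information fraction `t_k` the standardised
statistic satisfies `Z_k ~ N(drift * sqrt(t_k), 1)`,
`Cov(Z_j, Z_k) = sqrt(t_j / t_k)`, where
`drift = (pE - pC) sqrt(n_max/arm / (pC qC + pE qE))`. The same unpooled
true-rate variance is used at design time (where it reduces to the design
variance at `(p0, p1)`) and for operating characteristics at arbitrary
rates; this keeps the whole surface internally consistent with the fixed
design's sizing formula. Exact-binomial evaluation of the group-sequential
designs is deliberately out of scope.

Boundaries follow Lan–DeMets error spending with the rho-family function
`err * t^rho` (default `rho = 1`): type-I error is spent at looks where a
go decision is permitted, type-II error at every look, and futility
boundaries are binding — the type-I recursion conditions on earlier
futility stops, which is what makes the realised null go probability equal
`alpha` exactly. At each look the efficacy bound solves the cumulative
type-I increment under drift 0 and the futility bound solves the type-II
increment under the design alternative; both recursions share continuation
regions and are advanced in lockstep, so no inner iteration is needed. The
maximum information is found by Brent root search (tolerance 1e-8) on the
requirement that the final efficacy and futility bounds coincide; candidate
sizes where the interim boundaries cross are treated as oversized rather
than errors.

First-passage probabilities use the classical recursive numerical
integration of the continuation subdensity on a Simpson grid, 129 points
per look by default, spanning the continuation region truncated at eight
standard deviations beyond the current mean. Crossing probabilities at the
next look are closed-form normal integrals against the stored subdensity,
so only the density propagation itself is discretised. Halving the grid
step changes reported probabilities by ~1e-10 (tested at 1e-5), and the
per-look probabilities are cross-checked against direct Monte Carlo
simulation of the joint normal sequence in the test suite. Infinite drift
(degenerate-variance corners of the rate square) returns the deterministic
limit; on the diagonal the drift-zero limit is used, which is the correct
continuous limit along `pE = pC`.

### Rounding solved sizes to whole patients

The continuous solution is converted to patients with equal arms (even
totals), and the information fractions are then recomputed from the rounded
sizes and the boundaries re-derived before the final futility bound is set
equal to the final efficacy bound (so `alpha` is preserved exactly and the
design becomes slightly overpowered — visible as go probabilities a little
above `1 - beta` at the alternative). Two rounding conventions coexist:

* schedules given as information *fractions* (DP4) round up to the smallest
  total for which every cumulative size is an even integer, preserving the
  prescribed spacing exactly (equally spaced thirds round to a multiple of
  6: solved 354.1 becomes 120/240/360);
* schedules with looks pinned at *fixed patient counts* (DP5, DP6) keep the
  pinned looks and round each remaining cumulative size up to the nearest
  even integer (DP6: solved 344.3 with midpoint 200.1 becomes 56/202/346 —
  note the unequal increments 146/144 that cumulative rounding produces).

A single convention cannot reproduce both behaviours; the split mirrors how
the two kinds of schedule are specified in practice.

## Plan composition

DP1/DP2 pair the Simon designs (without/with efficacy stopping) at stage
errors `(sqrt(alpha), 1 - sqrt(1-beta))` with one fixed two-arm design at
the same stage errors. The plan's go probability is the product of the two
stages' rejection probabilities — the single-arm stage depends on `pE`
only — and its expected size is the Simon expected size plus the
randomised total weighted by the single-arm rejection probability (a no-go
ends the plan; the single-arm data are otherwise disregarded). DP5's
futility looks sit at the Simon stage sizes rounded up to even totals
(19 -> 20, 55 -> 56); DP6's single futility look sits at the Simon total.

The lattice evaluator computes power, expected size and power per patient
on a `(pC, pE)` grid (default step 0.01, matching the visual resolution of
the published performance maps). DP1–DP3 are closed-form and vectorised;
DP4–DP6 run one grid recursion per lattice point (~40 s for all six plans
at the default resolution on one core).

## Optimality and reference priors

The four criteria are applied pointwise with ties broken by the lowest
plan index (recorded in the map metadata); the power floor for OC2/OC4 is
the strict inequality `P > 1 - beta`. Under OC2/OC4 a point may have no
feasible plan, reported as `none`.

The reference priors are beta densities fitted to two constraints by
bracketed root search in `log(a - 1)` (constraints reproduce to 1e-9):
the stance's *centre* is the **mode** (`(a-1)/(a+b-2)`), and the opposing
tail holds 10% mass. Mode-centring is a deliberate choice over the mean:
with the plan metrics fixed, mean-centred fits shift the enthusiast prior
too far left to reproduce the published usage probabilities (errors up to
0.13), while mode-centred fits — sceptic `Beta(3.71, 16.36)`, enthusiast
`Beta(2.81, 5.21)` — land every published cell within 0.01. A unimodal
interior mode requires both shapes above 1, which holds for any
`0 < p0 < p1 < 1` here.

Usage probabilities integrate the prior along the line `pC = p0`: each
lattice point owns the cell between the midpoints to its neighbours, and
the prior mass per cell is the difference of the beta distribution function
across the cell edges, so the three class probabilities partition unity
exactly for the given winner assignment. Refining the lattice from step
0.01 to 0.005 moves each probability by well under 0.005. If `p0` is not a
lattice value the nearest line is used with an explicit warning reporting
the offset.

## What the tests do and do not show

The package needs no synthetic data: its inputs are scenario parameters,
and the worked example (`p0 = 0.15`, `p1 = 0.30`, `alpha = 0.0025`,
`beta = 0.36`, observed rates `(0.15, 0.41)`) exercises every code path.
Independent oracles back the two numerical engines — exhaustive
path-by-path enumeration of every binary response sequence for Simon
designs with `n <= 12` (agreement to 1e-12), and seeded Monte Carlo
simulation of the group-sequential statistic sequence (agreement to 4e-3
at 400k replicates). Passing tests therefore validate the *calculations
under the stated models*; they say nothing about model adequacy on real
trials — in particular the normal approximation for two-arm designs at
extreme rates or tiny arms, response-rate drift between stages, or the
selection bias a non-randomised stage can introduce, none of which the
operating characteristics capture.

## Known limitations

* Two-arm operating characteristics are normal-approximate throughout; at
  rate pairs near 0 or 1 with small arms the binomial skew is not captured.
* Only 1:1 allocation and one-sided tests are supported; there is no
  re-estimation, unequal spacing optimisation, or optimal error split
  between the two trials of DP1–DP2.
* The strong-control variant of DP1–DP2 (running the randomised stage at
  the full `alpha`) is not implemented.
* Priors are placed on `pE` only; `pC` is treated as known.
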