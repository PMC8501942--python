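# Methods

## The model

`planktonmap` analyses a planar discrete-time model of a phytoplankton
population `p` grazed by zooplankton `z`.  The continuous parent system is

    dp/dt = r p (1 - p/k) - alpha p z/(a+p) - m1 p^3 - q1 E p
    dz/dt = beta p z/(a+p) - delta z - rho p z/(a+p) - m2 z^2 - q2 E z

logistic phytoplankton growth (rate `r`, capacity `k`), Holling type-II
grazing with half-saturation `a` and maximal rate `alpha`, conversion of
grazed biomass at rate `beta`, zooplankton mortality `delta`, toxin release
by phytoplankton at rate `rho` (acting through the same saturating kernel),
self-toxicity terms `m1 p^3` and `m2 z^2`, and proportional harvesting of
both populations with catchabilities `q1`, `q2` under a common effort `E`.
The discrete map is a Mickens-type nonstandard finite-difference (NSFD)
discretisation with step size `h` in which every loss term is evaluated at
the forward time level.  Each update is then a ratio of positive
quantities, so the scheme preserves positivity for *every* `h` and its
fixed points are exactly the ODE equilibria (both properties are tested).

`beta > rho` is enforced as a hard requirement for all analysis
operations: without it the net benefit of grazing is negative and the
trapping region and interior equilibrium theory collapse.  Plain orbit
iteration remains available in that regime because the map itself is still
well defined.  The softer modelling assumptions (`a > k`, `beta < alpha`,
`0 < m2 < m1`) are surfaced as warnings only — the shipped bloom benchmark
itself violates `beta < alpha`, harmlessly.

## Equilibria and the trapping region

Orbits started in `[0, k] x [0, k(beta-rho)/(m2(k+a))]` never leave it.
The interior (coexistence) point is computed by eliminating `z` through
the zooplankton nullcline `z = f(p)` and root-finding the scalar residual
`F(p)` on `(0, k]`: a uniform 512-node scan locates every sign change,
each bracket is polished by Brent's method (default relative tolerance
1e-12), and candidates are accepted only if `|F|` is genuinely small —
this rejects spurious sign changes across the pole of `F`, which occurs
when the denominator `(beta-rho) - (delta + m2 f(p) + q2 E)` crosses zero
inside the scan range.  Multiple accepted roots flag non-uniqueness
instead of failing.  The uniqueness theory (margin inequalities at the
ends of `[0, k]` and the derivative condition making `F` strictly
decreasing) is evaluated on a 101-node grid; the grid sizes are the
package's own choices — the conditions are inequalities over an interval
and any moderately fine grid serves.

A separate `worked_bounds_report` evaluates the closed-form bound
quantities with a *frozen* upper-bound variant
`f_upper = -(a+k)(m1 r^2 + q1 E)/alpha` (note `r^2` where the exact
nullcline carries `p^2`).  The analysis path never uses this variant; it
exists so a set of reference digits that depend on it remain reproducible
side by side with the exact theory.

## Linear stability

The Jacobian is the closed-form quotient-rule derivative of the two
rational map components, derived here from the map itself rather than
transcribed, and is validated against Richardson-extrapolated central
differences (agreement ~1e-8 relative at random states).  Classification
uses the Jury conditions on `M(xi) = xi^2 - Tr xi + Dt`.  The four-case
lemma carries the standing hypothesis `M(1) > 0`; when `M(1) < 0` the real
roots straddle +1 and the verdict is still fully determined (`saddle` if
`M(-1) > 0`, `source` if `M(-1) < 0`), so the classifier returns that
verdict and records the hypothesis violation in `lemma_case` instead of
refusing — the extinction point of the bloom benchmark lands exactly in
this case and is correctly reported as a saddle.  Ties within 1e-10 of a
boundary are reported as `marginal` rather than forced into a case.

Because the fixed point is `h`-independent while its Jacobian is not, `h`
is the bifurcation parameter.  The Neimark-Sacker point `h*` solves
`Dt(h) = 1` (complex pair leaving the unit circle) and is located by a
256-node scan plus Brent refinement to ~1e-12, with three certificates:
the residual `|Dt(h*) - 1|`, the transversality `d sqrt(Dt)/dh > 0`
(central difference, step 1e-6), and the low-order non-resonance
`Tr(h*) not in {-2, 0, 1, 2}` within 1e-8.  A tabulated closed-form
expression for the critical step exists in the literature on this model;
it is implicit in `h` and inherits typos, so the package evaluates it only
as a cross-reference and records its discrepancy from the computed
crossing.

## Normal form and the first Lyapunov quantity

The cubic Taylor table of the shifted map at the fixed point is computed
by symbolic differentiation (sympy, lambdified once and cached);
an independent finite-difference route (central differences of tensor
order up to 3 with one Richardson level, steps 1e-4/5e-3 scaled by
coordinate magnitude) must agree to ~1e-5 relative, and the gap between
the two routes is reported as the numerical uncertainty on the final
coefficient.  The similarity transform `P = v12 X`,
`Z = (l - v11) X - w Y` (`l = Tr/2`, `w = sqrt(4 Dt - Tr^2)/2`) brings the
linear part to rotation form; since the transform is linear and the
nonlinearity polynomial, the transformed partials are obtained by exact
polynomial expansion, not further differentiation.  The complex
coefficients theta_20, theta_11, theta_02, theta_21 and the first
Lyapunov quantity Omega follow the standard planar normal-form formulas
with `xi1 = l + i w` (upper half plane).  `Omega < 0` is *supercritical*.
The verdict is validated dynamically: just past `h*` the mean orbit
radius around the fixed point must grow like `sqrt(h - h*)` (measured
log-log slope in [0.35, 0.65] over offsets {0.01, 0.02, 0.04}), and below
`h*` it must collapse to the fixed point.  On the bloom benchmark Omega
is approximately -1.5e-4 with a two-route gap of ~5e-11; the package
treats the sign and the radius law as the meaningful, checkable content
of the computation.

## Bifurcation control

Both control schemes blend one map iterate with the identity,
`x' = c g(x) + (1-c) x`, with effective gain `c = S1` (hybrid) or
`c = L^3` (modified hybrid).  Fixed points are untouched and the
controlled Jacobian is exactly `J_c = c J + (1-c) I`, so each eigenvalue
moves along the straight segment `mu = 1 + c (xi - 1)`.  For an unstable
complex pair the largest stabilising effective gain is the closed form
`c* = 2 (1 - Re xi)/|xi - 1|^2`; the modified method's bound on `L` is its
cube root, which is why the modified gain interval is always the longer
one.  The package computes intervals from this exact identity (the
printed controlled-Jacobian matrices in the source literature inherit the
same typos as the uncontrolled one and are not used).  The stability
intervals reproduce the published six-row comparison table to about seven
significant digits; the table's remaining printed digits are not
reproducible from the exact map and are not targeted.

## Orbits, sweeps, Lyapunov exponent

The maximum Lyapunov exponent uses a single tangent vector propagated by
the analytic Jacobian with per-step renormalisation — sufficient for the
*maximum* exponent; no QR pair is needed.  Defaults (10^5 iterations,
10^4 transient) resolve the sqrt-law radius scaling; the test suite uses
smaller windows (4-6 x 10^4) chosen from the measured convergence rates.
Bifurcation sweeps start from the fixed point perturbed by +1e-4 in `p`
(fixed, not randomised — all orbit computations are bit-deterministic)
and classify each post-transient sample cloud by its radius spread:
max radius below 1e-6 is a fixed point, a thin annulus
(min > 0.2 max) a circle, anything broader irregular.  Near the crossing
the focus decay rate scales like the distance to criticality, so
localising the transition to one grid cell requires the transient to
out-run critical slowing down; the shipped tests use grid step 0.02 with
a 10^4 transient, sized from the measured transversality (~0.096 per unit
h).

## Benchmark fixtures and what they do and do not show

`ns_bloom` is the strongly grazed, strongly toxic benchmark regime behind
every numeric reference value in the tests: interior point
(0.1053484433, 6.88842511), Neimark-Sacker crossing at h* ≈ 0.4334,
supercritical.  `consistency_stable` / `consistency_unstable` are a
mild-toxicity pair (differing only in `m1`: 0.06 vs 0.025) used for
discrete-vs-continuous consistency checks; their source listing contains
a constant `c = 0.14` matching no model symbol (read here as the effort
`E`) and reported equilibria that do not satisfy the fixed-point
equations, so they ship with caveat notes and carry no numeric reference
values.  All fixtures are single parameter points of a deterministic map:
passing tests certify the dynamical-systems machinery on these regimes,
not any statistical property of real plankton data — there is no noise,
no seasonality, no spatial structure, and no time lag in toxin release.

## Numerical choices and limitations

Double precision throughout; the exact-rational oracles used to freeze
reference values in the tests were computed with `fractions.Fraction`.
Degenerate inputs are handled explicitly: `m1 = 0` switches the axial
point to the linear branch; `beta = rho` makes the trapping box and
existence theory degenerate and is a hard error for analysis; poles of
`F` raise rather than return numbers.  Known limitations: the generalized
k-iterate control scheme is not implemented (iterate count fixed at 1);
no center-manifold machinery beyond what the planar normal form needs; no
codimension-2 analysis; basins of attraction are out of scope.
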