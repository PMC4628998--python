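# Methods

## Panel data and the duplicate-target convention

A selectivity panel reports, per kinase, the residual activity at one
inhibitor concentration as a percent of the uninhibited control.
Residual activities above 100 % (apparent activation) are legitimate
readouts and are preserved verbatim by the I/O layer; they are floored
only when converted to percent inhibition (below).

The packaged quinalizarin table lists 141 rows but represents 140
kinases: the CK2 holoenzyme (α₂β₂) and the isolated catalytic subunit
(α) are two assay forms of the same kinase. Panel-wide statistics count
each biological target once, so `collapse_panel` merges rows sharing a
`group_key`. The default policy keeps a named representative per group —
for CK2, the holoenzyme row (10 % residual activity) — with
`keep-first` and `keep-min-activity` available as alternatives and a
`keep-first` fallback for groups without a named representative. The
holoenzyme convention is this package's inference from the panel's
printed denominators (140 kinases overall, 139 "other" kinases), not an
explicitly documented protocol of the source data; it is configurable
precisely for that reason.

## Selectivity statistics

Percent inhibition is `x = max(0, 100 − activity)` with the number of
clipped (activation) entries recorded. Clipping is the default because
activation carries no selectivity signal; disabling it on data
containing activations is an error rather than a silent sign flip.

The Gini coefficient uses the uncorrected discrete sample form

    G = (2 Σᵢ i·x₍ᵢ₎)/(n Σ x) − (n+1)/n,   x₍ᵢ₎ ascending, i = 1..n,

which is algebraically identical to the pairwise mean-difference form
`Σᵢⱼ|xᵢ−xⱼ| / (2 n² x̄)` and to twice the trapezoidal area between the
diagonal and the Lorenz polygon. The test suite asserts all three agree
to 1e−12 on random vectors; no small-sample (n/(n−1)) correction is
applied. An all-zero inhibition vector (a compound with no measurable
inhibition) raises `GiniUndefinedError` rather than returning 0, since
"no data" and "perfectly unselective" are different statements.

Inequalities are strict throughout: a *hit* is inhibition strictly
greater than the threshold (default 50 %), a census counts residual
activity strictly below the cutoff. On the packaged panel this puts a
kinase sitting exactly at 80 % residual activity in the "≥ 80 %" bin,
which is what makes the 7-versus-132 split of the off-target census
exact. Reported values are rounded half-away-from-zero to 3 decimals in
the `reported` block of JSON output, with full machine precision kept
alongside (6 significant digits in serialized JSON).

Multi-inhibitor comparison scores each panel on its own membership; no
cross-panel kinase alignment is attempted, so Gini values from panels of
different composition are panel-relative and should be compared with
that caveat in mind.

## Kinetic inference

The model is Michaelis–Menten with a purely ATP-competitive inhibitor,
`v = Vmax·S/(Km(1+I/Ki)+S)`; no mixed or uncompetitive alternatives are
fitted (mechanism discrimination is out of scope — the competitive
assumption is an input).

**Primary fits.** Replicate velocities are averaged per ([S], [I]) cell
*before* the reciprocal transform, which limits the variance distortion
the 1/v transform introduces. The default estimator is unweighted OLS of
1/v̄ on 1/S, i.e. the classical graphical Lineweaver–Burk method; Km =
slope/intercept, Vmax = 1/intercept. A direct nonlinear least-squares
fit of the hyperbola is available behind the same interface
(`method="direct"`); the two agree exactly on noiseless data and their
divergence under noise is visible to the caller, not hidden. A
nonpositive fitted slope or intercept raises a "non-hyperbolic data"
error.

**Ki.** The secondary replot regresses the primary slopes Km,app/Vmax on
[I]; under the competitive model slope(I) = (Km/Vmax)(1 + I/Ki), so Ki
is the intercept/slope ratio of the replot line. The slopes entering the
replot are the fitted double-reciprocal slopes themselves (identical to
the ratio of separately fitted Km and Vmax in exact arithmetic, not
under noise; the slope reading is adopted). A replot slope that is zero
(to a relative tolerance of 1e−10 against the intercept) means the
inhibitor has no measurable effect and raises "no inhibition detected";
a negative implied Ki raises a mechanism-violation error.

**IC50.** Dose–response data are fitted by
`a(I) = bottom + (top−bottom)/(1+(I/IC50)^h)` with top = 100, bottom = 0
and h = 1 fixed by default — exactly the fixed-substrate competitive MM
residual-activity curve, for which IC50 = Ki(1+S/Km) (Cheng–Prusoff).
Any of the three constants can be freed for empirical fits. At least 4
concentrations are required, and a transition-free table raises an
unidentifiability error instead of returning a boundary value.

Units: concentrations in µM throughout; velocities are unit-agnostic
because only ratios enter Km, Ki and IC50.

## Synthetic data: what it emulates and what it does not

**Panels** are drawn as a normal background (default 100 ± 12 %,
truncated below 0 by rejection, deliberately *not* truncated above
100 %, matching the visible activation tail of real panels) with planted
hits at exact activities. This reproduces the features the selectivity
statistics are sensitive to — a near-100 % mass, a graded tail, isolated
strong hits — but not kinase-family correlation structure, assay-to-assay
batch effects, or concentration–response consistency across related
kinases. Passing tests on synthetic panels therefore validate the
statistics, not any claim about real panel noise.

**Kinetic data** are the competitive MM surface times (1 + ε) with
ε ~ N(0, cv²) independent per observation and nonpositive draws
rejected — multiplicative noise with a constant coefficient of variation
being the standard description of radiometric assay error. Enzyme
depletion, substrate depletion, product inhibition and time-course
effects are not simulated (velocities are assumed to be true initial
rates).

Default kinetic parameters describe the CK2-holoenzyme/quinalizarin
system: Ki = 0.058 µM, Vmax = 1 (arbitrary), ATP Km = 13 µM — a typical
CK2 ATP Km, consistent with the measured pair IC50 ≈ 0.15 µM at
S = 20 µM ATP via 0.058·(1+20/13) ≈ 0.148 — with substrate grid
{5, 10, 20, 40, 80} µM bracketing the 20 µM assay concentration,
inhibitor grid {0, 0.05, 0.1, 0.2} µM (0–3.5 × Ki), 3 replicates and
cv = 5 %. Under exactly this design, 200 seeded simulations recover Ki
with a median relative error of about 7 % and Km about 5 % (the test
suite asserts < 15 % and < 10 % respectively); these recovery figures
are properties of the simulation design, not re-measurements of the
experimental values, whose raw velocities are not public.

All generators are deterministic given their integer seed
(`numpy.random.default_rng`).

## Alignment conservation

Reference positions are 1-based over the ungapped reference sequence;
the mapping to alignment columns is strictly monotone and invertible on
non-gap positions. Residue matching is case-insensitive; `X` never
matches; gap characters (`-`, `.`) count in the denominator but can
never match a query — a sequence lacking the position does not "have"
the residue. Frequencies computed on one alignment are relative to that
alignment's membership and are not comparable across alignments with
different denominators.

## Numerical and design choices

- OLS lines via `scipy.stats.linregress`; nonlinear fits via
  `scipy.optimize.curve_fit` seeded from the reciprocal-plot estimate
  (MM direct fit) or the midpoint crossing (IC50), with nonnegativity
  bounds on IC50.
- Ties in the potency ranking break alphabetically; tied inhibition
  values contribute identically to the Gini regardless of rank order
  (the rank formula is invariant under permutations within ties).
- Rounding for reported values is half-away-from-zero to 3 decimals;
  1/140 = 0.00714… reports as 0.007.
- CSV dialects are comma-separated UTF-8 with headers; panel column
  names are remappable because vendor exports vary.

## Known limitations

- Selectivity scores are single-concentration snapshots; they say
  nothing about potency (a weak but uniform binder and an inert compound
  both score low) and are panel-composition dependent.
- The Lineweaver–Burk estimator, kept as the faithful default, is
  statistically inefficient under noise relative to the direct fit;
  users quantifying small effects should compare both.
- The conservation utility consumes alignments; it does not build them,
  and its output depends entirely on the membership of the supplied
  alignment.
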