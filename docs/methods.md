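# Methods

This note documents the models, conventions, numerical choices and known
limitations of `regpes`, in the order the pipeline applies them.

## Data model

A **term table** is long-format delimited text with columns
`point_index, s, kind, atom_a, atom_b, energy`; `kind` is one of
`total | intra | cl | xc`. Pair terms are symmetric: `V(a,b)` and
`V(b,a)` canonicalize to the same identity (atoms stored lowercase in
lexicographic order), and a file listing both orders for the same point
is rejected as a duplicate rather than averaged. Missing (label, point)
combinations are errors, never implicit zeros — silent zero-filling would
corrupt the Σ REG = 1 diagnostic downstream. Every label must be present
at all M ≥ 2 points and the control coordinate must be strictly
increasing.

Energies carry a unit tag: kJ/mol by default, hartree accepted with the
conversion 2625.4996394799 kJ/mol per hartree. Floats are written with
17 significant digits and parsed through `str → float64` so read/write
round trips are bit-exact (the fast float parser in pandas is not
correctly rounded and loses the last ulp).

Geometries use standard XYZ; default atom labels are the lowercase
element symbol plus the 1-based file position (`o1, h2, ...`). The
parser is deliberately minimal and keeps float64 coordinate fidelity.

## Recovery error

`residual_j = Σ_i E_i(s_j) − E_tot(s_j)`, aggregated as an RMSE, a
maximum absolute value, and a percentage of the mean absolute total
energy. A constant residual is a systematic shift: it measures
numerical-integration quality but leaves all energy gradients — and hence
every REG value — untouched.

## Segmentation

Stationary points are detected on the discrete total-energy series only;
no spline or interpolation is used, because the analysis only ever
selects among geometries that were actually computed. Exact plateaus are
run-compressed so zero finite differences inherit the surrounding trend
(plateaus do not spawn segments) and a tied extremum reports its first
index. Segments are classified rising/falling by endpoint comparison; an
exactly flat profile (unreachable for real data) classifies as rising and
is rejected later as zero-variance anyway. Segmentation is invariant
under any strictly monotone reparameterization of `s` and under constant
energy shifts.

## REG per segment

`m_i = cov(E_i, E_tot)/var(E_tot)` over the segment's points after
mean-translation, computed directly in covariance form rather than
through a generic least-squares solver: after translation the intercept
is identically zero and the ratio is numerically transparent. The
Pearson correlation `R_i` accompanies every slope; both require at least
3 points (2-point segments always give |R| = 1, which carries no
information) and nonzero total-energy variance, otherwise a
`DegenerateSegmentError` is raised. In batch analysis a degenerate
segment becomes an error entry and the other segments proceed.

The |R| threshold defaults to 0.7 and is configurable from 0 (keep
everything) up to but excluding 1; low-|R| terms are flagged
`discarded` but retained in the output, and both sum diagnostics are
reported (`sum_of_reg` over all terms, `sum_of_reg_retained` over
survivors) so either reporting convention can be reproduced. A constant
term inside a batch is reported with slope 0, correlation 0 and the
discarded flag rather than aborting the segment; calling `pearson()` on
it directly still raises. Ranking sorts by REG descending with ties
broken by canonical label order, for deterministic tables.

## RDP geometry selection

The simplifier is the classic recursive algorithm: keep the point
farthest from the current chord when its perpendicular distance is
*strictly* greater than ε, ties broken toward the lowest index,
endpoints always kept. Because ε lives in mixed (coordinate, energy)
units, selection goes through an ε scan: ε = 0, step, 2·step, …, ε_max
(the largest deviation from the first–last chord, so the scan always
ends on the 2-endpoint simplification). Each row's retained set is
converted to an RMSE by piecewise-linear interpolation back onto every
original abscissa; the RMSE averages over **all** points (retained ones
contribute zero). An eliminated-points-only average is available and
differs only by a constant factor per retained set; the convention used
is recorded in the machine-readable output.

By default the abscissa is rescaled to [0, 1] before distances are
measured (`normalize_x`, configurable off) so behaviour does not depend
on the units of the control coordinate. The scan step defaults to 0.01
in these scan units; profiles whose selection looks too coarse at that
granularity can pass a smaller step at negligible cost. Note that the
perpendicular distance is homogeneous only under a *uniform* scaling of
both axes; scaling the energies alone scales the interpolated RMSE (a
vertical deviation) but not ε_max.

Selection picks the smallest retained set with RMSE ≤ tolerance and at
least 3 points, resolving size ties toward smaller ε. If only the
2-endpoint set qualifies, the farthest interior point is added back and
the `min3_override` flag is set — a straight line between reactant and
product is never a chemically meaningful profile. In the pipeline the
selection runs per segment by default so stationary points can never be
eliminated; a global mode exists behind a flag.

## Lite systems and truncation metrics

Sphere selection uses the closed ball (distance ≤ r): inclusion at the
boundary must be fixed one way or the other, and the closed convention
is deterministic under exact arithmetic. Term filtering keeps exactly
the terms whose atoms all belong to the subset, while the full-system
totals and coordinate are kept — matching the biased protocol in which
lite-system terms still come from the full wave-function. Filtering a
proper subset breaks the Σ REG = 1 rule by exactly the summed REG of the
excluded terms.

A truncation candidate is judged by three unity-convergence metrics on
identical grids: the slope *m* of the mean-translated lite-vs-full
regression (shape similarity per point), the coefficient of
determination *R*² (goodness of fit, more discriminating than *R*
against systematic changes), and ΔE_lite/ΔE_full with ΔE the endpoint
difference of the assessed segment (the activation-energy ratio when the
segment runs reactant → transition state; endpoint difference
generalizes it to any segment). Candidates are ranked by the largest
deviation of the triple from unity (L∞): this is this package's
aggregation of what is otherwise a visual three-panel inspection, and it
guarantees that a profile matching in shape but compressed in gradient
(m ≈ 1, R² ≈ 1, ΔE ratio ≈ 0.8) never ranks best. Hydrogen capping of
truncated structures is a wave-function-generation concern and is out of
scope here; the module consumes the resulting lite profiles only.

## Synthetic generators

The generators exist so that every operation above is testable without
quantum-chemistry software; they reproduce the statistical structure REG
assumes (additivity, near-linear term/total relations), not realistic
enzyme energetics.

* **Lennard-Jones 12-6**: repulsive A/r¹² and attractive −B/r⁶ terms
  whose sum is the total by construction (minimum at r = (2A/B)^{1/6}).
  The two terms are labelled with distinct pseudo-pairs `xc(a1,a2)` /
  `xc(b1,b2)` purely so they flow through the term bookkeeping — a
  fixture convention, not a physical statement.
* **Weighted decomposition**: term i is `w_i · E_base(s) + η_i` with η
  i.i.d. Normal(0, σ²) from a seeded stream, modelling unstructured
  numerical-integration error. With `exact_total` (weights must sum
  to 1) the last term absorbs the summed noise so the decomposition is
  exact at every point; without it the noise appears as recovery error.
  Identical spec + seed gives bit-identical output; the seeded streams
  are part of the public contract.
* **Base curves**: a sigmoid (one segment; default height 66, the kJ/mol
  scale of a typical activation barrier; steepness 10/range) and a
  symmetric quartic double well (default minima at 1/4 and 3/4 of the
  grid, barrier 66, optional linear tilt). A grid starting at the left
  minimum yields the canonical three-segment profile; a grid spanning
  both outer quartic walls adds a fourth (falling) segment and much
  larger wall energies — tests and demonstrations therefore use grids
  anchored at the left minimum.

Default study conditions used in tests and the acceptance script:
11-point grids on [0, 1] (mirroring a typical coarse IRC), weights
(0.7, 0.3), noise σ = 0.66 (1 % of the 66-unit curve range), 200
replicates for recovery statistics, 100 random datasets (M ≤ 20, ≤ 50
terms) for the dual-route regression check, and 50-point noisy sigmoids
for the RDP oracle comparison. These sizes keep the full battery in the
low seconds while leaving the statistical assertions well-powered.

## Pipeline

`regpes run --config run.yaml` executes load/simulate → optional subset
filter → recovery → segmentation → per-segment RDP selection → REG on
the selected geometries, writing delimited tables at 6 significant
digits plus full-precision JSON, and a run log with the package version,
seed, configuration echo and every decision taken (selected counts,
min-3 overrides, discarded-term counts). Unknown configuration keys are
rejected; any stage failure removes partial outputs and raises an error
naming the stage. Reruns with the same configuration are byte-identical.
Because each segment's endpoints are always retained and the total
energy is monotone within a segment, re-segmenting the selected subset
reproduces the original stationary points exactly.

## Known limitations

* No parser for native atomic-integration program outputs; the term
  table above is this package's own interchange convention and a
  converter is a future adapter.
* The analysis is strictly 1-D in the control coordinate; no
  multidimensional saddle detection.
* Exchange–correlation terms are never split into exchange and
  correlation parts, and no chemical-interpretation layer is provided.
* The synthetic noise model is i.i.d. Gaussian per term per point; real
  integration errors can be structured (size- and element-dependent),
  so passing tests demonstrate correctness of the arithmetic and
  bookkeeping, not robustness to every real-data pathology.
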