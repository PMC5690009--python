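# Methods

## Dose model

The engine evaluates the TG-43 line-source approximation

    D(r, θ) = Sk · Λ · [G_L(r,θ) / G_L(r₀,θ₀)] · g_L(r) · F(r,θ)

with all distances in cm, angles in degrees at the interface (radians
internally), dose rate in cGy/h and Sk in U.  The geometry function is

    G_L(r,θ) = β / (L · r · sinθ),      θ away from the poles
    G_L(r,θ) = 1 / (r² − L²/4),          θ at a pole (and by the
                                         θ ↔ 180°−θ symmetry at 180°)

where β is the angle subtended by the active core, computed from the two
arccos terms of the standard formulation.  Within a configurable ε of a
pole (default 10⁻⁴ degrees) the pole branch is used; the two branches
agree to better than 10⁻⁴ relative at θ = 10⁻³ degrees.  Points on the
active-core segment raise a domain error.  Unit tests check the arccos
form against an independent two-arctangent construction of the endpoint
angles; the arccos form loses roughly two digits near the poles, which is
why that cross-check is asserted at 10⁻¹⁰ relative rather than machine
precision.

**Angle conventions.** Internally the engine measures θ from the source
tip (the AAPM frame).  Published and vendor tables may place 0° on the
cable end instead; `AnisotropyTable.theta_zero` records the table's own
convention and lookups flip θ → 180° − θ as needed.  Keeping the flag on
the table (not the query) means a mixed set of tables can serve one
engine without silent convention errors.

**Radial dose function.** Either a polynomial in ascending powers of r
(the form vendors ship) or a table with linear or log-linear
interpolation; log-linear means ln g linear in ln r, so a query at the
geometric mean of two radii returns the geometric mean of their g values.
This is the recommended choice close to the source where g varies
fastest.  Models must satisfy g(r₀) = 1 within 10⁻⁶; the factory methods
can renormalise, the constructor rejects.  Out-of-range queries follow a
configurable policy, reject by default, clamp-with-warning optionally.

**Anisotropy lookup.** Bilinear interpolation on the (r, θ) grid, exact at
nodes.  Radii outside the tabulated range clamp to the nearest tabulated
radius (common TPS behaviour; the alternative is unstated in the
literature for the system studied).  Angles beyond the tabulated range
follow a first-order rule: a straight line through the two tabulated
angles nearest the pole, evaluated toward the pole and floored at 10⁻³ to
preserve positivity.  The lookup implements this by augmenting the grid
with extrapolated pole columns, so off-grid angles short of the pole ride
the same line.  If a table has fewer than two angles on one side of 90°,
extrapolation is impossible and the edge value is clamped instead.

## Table comparison and ODIN detection

Tables are compared after bilinear resampling onto a common grid
(provenance strings record the direction, `int-<src>2<dst>`).  Percent
differences are signed, 100·(b − a)/denominator with the denominator
configurable (reference by default); absolute values are a display
choice.  Cells whose |difference| exceeds the 2% investigation level are
flagged and classified against the 5% intervention level — the action
levels recommended for TPS commissioning.  For polar maps the report
lists contiguous flagged angular bands and the fraction of the [0°, 180°]
polar domain they cover; the two 15° pole cones give 30/180 ≈ 17%.  A
solid-angle coverage fraction is reported as a secondary output but not
used for flagging, since the polar-domain definition is the one that
matches the headline coverage number.

**Anisotropy extraction.** Given an along–away table D(y,z)/Sk, the
anisotropy at each grid point is

    F = [D(r,θ)/Sk] · G_L(r,θ₀) / ( [D(r,θ₀)/Sk] · G_L(r,θ) )

with the transverse-axis denominator computed analytically as
Λ·G_L(r,θ₀)/G_L(r₀,θ₀)·g_L(r) so no interpolation enters the denominator.
Points within L/2 + 0.05 cm of the source centre (configurable) are
skipped as a singular zone.  Because the synthetic along–away tables come
from a known engine, extraction is validated as an exact round trip
(≤ 10⁻⁶ relative; in practice machine precision).

## Clinical setups

Dwells are specified as in-plane positions with per-dwell axis vectors
(cable→tip) and positive weights; dose planes superpose single-dwell dose
rates after transforming each plane point into each dwell's local polar
frame.  Spacing between dwells is uniform including endpoints
(step = span/(n−1)).  Defaults: one dwell at the origin; 6 dwells over
3.5 cm (step 0.7 cm); 19 dwells over 9 cm (step 0.5 cm); a 6 cm tandem
(0.5 cm step) plus two 2 cm-diameter ovoids, one centre dwell each, axes
parallel to the tandem; five parallel 5 cm applicators at 1 cm pitch.
Dwell weights default to uniform — the setups probe the dose engine, not
an optimiser — and a weight vector is accepted.  Applicator capsules and
a per-dwell singular zone mask plane points as NaN.

The Fletcher ABS-style reporting points are configuration values (the
standard description names the points but gives no coordinates): point
A/H at (±2, 2) cm from the cervical os, a tandem-tip point 1.8 cm beyond
the tip on the axis, ovoid-surface and ovoid+0.5 cm points lateral to the
ovoids, and rectal/bladder surrogates placed near-perpendicular to the
applicator axes, as their anatomical positions are relative to the
ovoids.  Evaluation interpolates the percent-difference plane bilinearly;
masked cells are tolerated only with zero interpolation weight.

The default evaluation plane is a square of half-width 6 cm at 0.05 cm
spacing centred on the active-core centroid.  The bundled analysis
scripts and several tests use 0.1 cm spacing on 4–5 cm half-widths — the
localisation and ordering results are insensitive to this, and it keeps
the default suite fast.

## Gamma index

For each reference point, γ is the minimum over evaluated-plane positions
within 3×DTA of √[(Δr/DTA)² + (ΔD/(d%·D_ref))²], with the evaluated plane
interpolated bilinearly and the dose difference normalised locally by the
reference point's dose.  The search is an exhaustive scan at 0.1×DTA
steps — deterministic and directly checkable against a brute-force
minimiser — implemented as one shifted-slice accumulation per offset
(every reference point is a node of the shared uniform grid, so an offset
shifts the whole plane by the same fractional cell).  No low-dose cutoff
is applied by default and reference points whose search disc leaves the
plane are evaluated over the in-bounds portion.

Two numerical consequences are worth knowing.  First, the default sweep
{1,2,3}% × {1,2,3} mm shares one absolute search step (0.1× the finest
DTA): with per-criterion steps a coarser search at a larger DTA can miss
minima a tighter criterion's finer grid found, producing spurious
non-monotone pass rates; with nested candidate sets monotonicity is
structural.  Second, on planes whose dose-difference field crosses zero,
the γ minimum sits in a valley narrower than the search step and a
0.1×DTA scan can overshoot a 0.02×DTA brute force by a few 10⁻³.  The
oracle-equivalence test therefore uses a gentle-gradient plane pair on
which sub-step valleys are shallower than the 10⁻³ assertion; on steep
clinical planes the module's γ is an upper bound within the same search
radius (its candidates are a subset of the oracle's).

## Synthetic study conditions

The generator emulates the structure of Monte Carlo anisotropy data for a
cabled HDR source with an exponential pole-depression model,

    F(r,θ) ∝ 1 − A_cable·exp(−θ_c/w_cable) − A_tip·exp(−θ_t/w_tip),

renormalised so F(r, 90°) = 1 exactly (θ_c, θ_t are angular distances to
the poles; amplitudes may depend on r).  The functional form is an
emulation target chosen because it is smooth, monotone toward the poles
and reproduces the chord-below-the-curve mechanism that makes linear
interpolation underestimate F in sparse near-pole gaps; it is not a
physical source model.  Frozen defaults: A_cable = 0.55, w_cable = 6°,
A_tip = 0.45, w_tip = 10° (the cable side steeper, as the drive cable's
perturbation of the medium implies), 9 reference radii from 0.5 to 15 cm,
a 3° dense angle grid from 1.5° to 178.5° (published reference tables
typically omit the exact poles), and zero noise so round-trip oracles are
exact; optional multiplicative noise is seeded and re-pins the transverse
column.

The vendor subsample takes 17 angles × 10 radii: fine 1.5° sampling on
the cable side, mandatory 0° and 180° entries filled by the same
first-order pole rule (vendor pole entries have been observed to match
exactly that construction), and empty gaps at (1.5°, 25.5°) and
(155.5°, 178.5°).  Under these conditions the resampled vendor table
underestimates the reference by up to ≈ 19.7% inside the widest gap,
every cell beyond the 2% level falls inside the two gap bands, the
one-dwell plane extreme sits within 15° of a pole, the multi-applicator
array is strictly milder than the single dwell, and the half-star QA
pattern flags intervention-level findings that the legacy ray patterns
miss entirely.

The default along–away grid is 14 away-values × 26 along-values whose two
singular-zone points leave exactly 362 valid entries, matching the size
of the published reference point array; the actual published coordinates
are not reproduced, only the point count and general layout.

**What passing tests do and do not show.**  The generator produces
smooth, noiseless, exactly normalised tables; real Monte Carlo tables
carry statistical noise, phantom-size effects at large r, and
source-specific structure.  Passing the round-trip and localisation
suites shows the pipeline's algebra and flagging logic are correct, not
that any particular commercial data set is defective; conversely the
mechanism demonstrated — steep pole gradients plus sparse vendor angles ⇒
action-level interpolation errors invisible to legacy QA — transfers
directly to real tables.

## Limitations

- 2D planar geometry throughout: dwells coplanar with (or trivially
  projectable onto) the evaluation plane; no 3D grids or DVH metrics.
- No Monte Carlo transport, scatter/phantom-size corrections, applicator
  shielding or dwell-time optimisation.
- The gamma search is exhaustive by design; very fine sub-sampling on
  large planes costs proportionally.
- Legacy QA pattern coordinates are schematic defaults (the source
  documents publish figures, not numbers) and should be overridden with
  institutional values where available.
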