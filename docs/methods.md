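# Methods

This note records the mathematical conventions, algorithmic choices and
deliberate deviations-from-the-obvious in `cranialink`, in enough detail
to reimplement the package from scratch.

## Coordinates and geometry

Right-handed frame: +x anterior, +y dorsal, +z toward the animal's right;
midsagittal plane z = 0; units mm and radians. A geometry is the set of
11 joint positions; the 15 link lengths (14 sided + 1 midline) are always
derived from coordinates, so moving a joint is the only way to change a
length. Bilateral symmetry means left/right partners share x and y and
carry opposite-sign z, and midline joints (`NV`, `HYM`, `SYM`) sit at
z = 0; `validate_symmetry` reports per-pair and per-midline-joint
deviations against a tolerance (default 1e-9 mm).

Geometry files are CSV (`joint,side,x_mm,y_mm,z_mm`) or the equivalent
JSON. Writing uses `repr`-level precision and reading uses round-trip
float parsing, so write→read is bit-exact.

## Pose solution (one degree of freedom per input)

The non-actuated input is pinned at zero; the two inputs are analysed
separately. A pose at cumulative input value v is solved in three exact
stages:

1. **Actuated body.** Epaxial: rotate the rigid body {`NV`,`NS_L`,`NS_R`}
   by θ = v about the +z axis through `NV` (Rodrigues rotation; positive θ
   moves points anterior to `NV` dorsally). Hypaxial: translate
   {`CH_L`,`HYM`,`CH_R`} by t = v along −x.
2. **Suspensorium closure.** Each suspensorium is the rigid triangle
   {`NS`,`HS`,`JQ`}, hinged about an axis through `NS` that is fixed in
   the neurocranium frame (rest direction +x, co-rotated by θ). Splitting
   the `NS→HS` vector into axial and radial parts, the constraint
   |HS − CH| = L_hyoid becomes A·cosφ + B·sinφ = C with
   A = 2 d·u, B = 2 d·(axis×u), C = L² − |d|² − |u|² (d the circle centre
   minus CH, u the radial part) — solved by φ = atan2(B,A) ± acos(C/√(A²+B²)).
   |C|/√(A²+B²) may exceed 1 by at most 1e-12 (clamped) before the pose is
   declared infeasible.
3. **Symphysis trilateration.** `SYM` is the intersection of spheres
   around `JQ_L`, `JQ_R` (lower-jaw lengths) and `HYM` (protractor-
   hyoideus length), via the standard two-sphere-frame reduction. A
   negative discriminant beyond −1e-9·max(1, r²) mm² is infeasible.

Branch selection: each stage keeps the root closest to the previous
step's solution (φ compared after wrapping to the nearest turn); exactly
equidistant roots abort with `LinkageInfeasible` rather than guess. At
step 0 the trajectory is seeded with the stored geometry itself (φ = 0,
`SYM` as stored), so the branch through the rest pose is taken. A
simulation is n_steps + 1 poses at evenly spaced cumulative inputs
0 … magnitude (defaults 0.2 rad / 50 steps epaxial, 3 mm / 50 steps
hypaxial → increments 0.004 rad and 0.06 mm).

`check_link_constancy` recomputes every link length at every pose and
fails a trajectory whose worst deviation exceeds 1e-9 mm (observed
deviations are ~1e-14, i.e. pure rounding).

### Independent cross-check

`cranialink.projection.project_pose` re-solves a pose with none of the
closed-form algebra: the 15 coordinates of {`HS_L/R`,`JQ_L/R`,`SYM`} are
unknowns of a Levenberg–Marquardt least-squares system with 15 residuals
(per side: axial coordinate and radius of `HS` and `JQ` about the
suspensorium axis, the `HS–JQ` triangle edge, the hyoid length; plus the
three symphysis spheres), warm-started from the previous pose. Agreement
with the closed-form solver is ~1e-13 mm; the acceptance suite requires
< 1e-6 mm on 20 random geometries.

## KT metrics

Output link directions: suspensorium `NS→HS`, hyoid `HS→CH`, lower jaw
`JQ→SYM`; the right side is canonical (identical to the left for
symmetric geometries — asserted in tests). The rotation between
successive poses is the unsigned 3D angle
atan2(|u×v|, u·v) ∈ [0, π]. Instantaneous KT at step k is that angle
divided by the per-step input increment (dimensionless for epaxial,
rad/mm for hypaxial — never mix units across input types); KT̄ is the
arithmetic mean of the 50 per-step values.

## Sensitivity experiments

An experiment is (reference link, moved joint(s), axis, input type).
Moved joints are an endpoint of the reference link: a symmetric pair
(moved mirror-symmetrically: equal x/y shifts, opposite-sign z), a
midline joint, or the coordinated set {`NV`,`NS_L`,`NS_R`} (moved
identically; changes the NS-anchored suspensorium links while preserving
the neurocranium length).

For each percentage p in 75…125 (step 1), the moved joint is displaced
s along the axis so the right-side reference length equals p% of its
original value: with e the axis unit vector, |p₀ + s·e − q| = target is a
quadratic s² + 2bs + c = 0; the root closest to the previous percentage's
displacement is taken (tracked outward from 100% in both directions, so
the branch passes through s = 0 at 100%), with exact ties broken toward
the positive root. Unreachable targets, solver failures and
constancy-check failures drop that percentage with a recorded reason
(`infeasible-perturbation` / `solver-failure` / `non-constant-length`) —
the sweep's range-reduction behaviour. A sweep needs ≥ 3 retained
geometries with strictly monotone lengths.

Estimators, with L the reference length and a the retained count:

* instantaneous (at the default geometry):
  dKT = (KT̄₍₁₀₁₎ − KT̄₍₉₉₎) / (L₍₁₀₁₎ − L₍₉₉₎), signed; undefined (NaN)
  when 99% or 101% was dropped;
* averaged: dKT_avg = Σᵢ |central difference at interior sample i| / a.
  The denominator is deliberately the *geometry count* a although only
  a − 2 interior central differences exist (the endpoints contribute no
  term); `delta_kt_average(..., denominator="terms")` provides the a − 2
  variant. Central differences are exact on quadratics, giving the
  hand-checkable oracles used in the acceptance suite.

### Isolation and ranking

An output is *null* in an experiment when both |dKT| statistics are
≤ `zero_threshold` (default 1e-10 — far above the ~1e-15 rounding floor
of the structural zeros, far below the smallest genuine sensitivities,
~1e-3; NaN statistics from one-sided sweeps are ignored). Experiments
with exactly one active output isolate that output's KT. Two families of
zeros are exact by construction and proven in the test suite:

* moving `JQ` or `SYM` leaves the suspensorium and hyoid KT series
  bit-identical — those outputs are solved strictly upstream of the jaw;
* shifting the `NS` pair along the suspensorium rotation axis (+x)
  cancels exactly in the closure algebra (the shift is parallel to the
  axis, so circle centre and radius are unchanged and the rotation maps
  the shift onto itself): hyoid and jaw KT are unchanged to rounding,
  isolating the suspensorium.

`rank_sensitivity` orders experiments per (reference link, output) by
|dKT| with stable mergesort and label tie-breaks, so rankings are
independent of insertion order. The full roster enumerates every
(link, endpoint, axis) triple plus the coordinated `NV+NS` set (x and y)
for the two NS-anchored suspensorium links — 52 experiments.
`kt_surface` evaluates KT̄ on the Cartesian product of two displacement
grids on one link, with NaN for infeasible cells.

## Default geometry and generator

The packaged default (`cranialink/_data/salmon_default_synthetic.csv`) is
a *synthetic* salmon-like reconstruction at ~60 mm head length: it
reproduces the qualitative anatomical arrangement and the structural
behaviour of the mechanism (full 51-geometry flagship sweep, monotone
suspensorium/hyoid KT series with an interior extremum only in the
lower-jaw series, the isolation pattern above), but it is not specimen
landmark data, so published point values for any particular fish are not
expected to match. `generate_geometry(SynthesisParams(seed))` jitters the
right-side/midline template coordinates (midline z pinned), mirrors the
left side, and rejection-samples until both full-range inputs simulate
with link constancy — every emitted geometry is usable by every later
stage, and generation is deterministic in the seed.

## Reproducibility

CLI runs write a `manifest.json` (package version, resolved parameters,
SHA-256 of the geometry coordinates); identical configurations produce
byte-identical outputs. `scripts/acceptance.py --seed N --out f.json`
recomputes every headline quantity; its geometry seeds are derived from
`--seed` via `numpy.random.default_rng(seed).integers(0, 2**31)`.
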