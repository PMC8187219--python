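# Methods

## The optical model

The pseudophakic eye is reduced to a coaxial chain of thin elements, per
principal meridian:

```
spectacle plane --(12 mm, air)--> cornea K --(ELP, n=1.336)--> tIOL --(AL-ELP, n=1.336)--> retina
```

A vergence `V` [D] transfers across an axial gap `d` [m] in index `n` as
`V' = V / (1 − (d/n)·V)` and gains the element power at each thin lens.
Corneal power comes from the measured front radius through a keratometer
index, `K = (n_k − 1)/r`, which folds the back surface into one fictitious
refracting surface. The eye's focal plane is taken to sit exactly one
axial length behind the corneal apex, and the refraction lane fixes the
object vergence at the spectacle plane at `−1/d_meas`.

Assumptions, and what they buy:

* **Thin cornea and thin IOL** — only labelled powers enter; no lens
  geometry or internal index is needed, which matches what routine clinical
  records contain.
* **Aligned meridians** — the toric IOL's steep axis is placed on the flat
  corneal meridian, so the two principal meridians decouple and the
  spherocylindrical problem reduces to two independent spherical chains. No
  crossed-cylinder (4×4 matrix) algebra is implemented; off-axis placement
  and rotation error are out of scope.
* **One ELP for both meridians** — a single implant has one axial
  position; computing meridian-specific lens positions would be physically
  meaningless.
* **One medium index** for aqueous and vitreous, `n_media = 1.336`
  (standard schematic-eye value; configurable on `OpticalConstants`).

## Fixed parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `n_keratometer` | 1.332 | – | radius-to-corneal-power conversion |
| `n_media` | 1.336 | – | aqueous/vitreous index |
| `vertex_distance` | 0.012 | m | spectacle plane to corneal apex |
| `measurement_distance` | 6.0 | m | refraction lane |

Refractions recorded at a different lane are re-referenced before use:
`sphere − 1/d` (the vergence leaving the spectacle lens) is the
lane-invariant property of a corrected eye, so
`sphere_6m = sphere_d + 1/6 − 1/d`. Between 4 m and 6 m lanes this is the
familiar 1/12 D offset.

## ELP back-solve

For each case the effective lens position is derived from data rather than
predicted by a formula: the forward model maps (K_eq, AL, implanted IOL
power, ELP) to a spherical-equivalent refraction, and the ELP is the root
of `predicted SE − measured SE` on the physiologic bracket [0.5, 8.0] mm
(Brent's method, absolute tolerance 1e−9 mm; the bracket's upper edge is
additionally capped at AL − 0.5 mm). The forward SE is strictly monotone
in ELP over this range — verified by grid scan in the tests — so the root
is unique when it exists. Cases whose measured refraction is unreachable
for any ELP in the bracket are flagged `elp_out_of_range`, excluded from
all statistics, and counted in the exclusion log; under the default
generator noise this affects roughly 10 of 16,744 eyes.

## The translation ratio

At the back-solved ELP, the emmetropizing IOL power is computed separately
for the flat and steep corneal meridians; their mean is the equivalent
power `P_eq`, their difference the torus `T`, and

```
ratio = T / (K_steep − K_flat)
```

The ratio exceeds 1 because the correction acts behind the cornea: a
dioptre of corneal astigmatism needs about 1.2–1.6 D of torus at the
capsular-bag plane, growing with lens distance from the cornea. Exchanging
the meridian labels flips torus and astigmatism together, leaving the
ratio invariant (tested). Zero corneal astigmatism leaves the ratio
undefined; such cases are flagged `zero_astigmatism` and excluded.

## Synthetic cohort

No clinical cohort ships with the package. The generator draws, per eye:

| quantity | distribution | default |
|---|---|---|
| axial length AL | Normal, truncated [20, 30] mm | mean 23.5, SD 1.96 mm |
| mean corneal radius | Normal | mean 7.7, SD 0.26 mm (K̄_eq ≈ 43.1 D) |
| corneal astigmatism | min + Gamma(shape, scale) | 0.25 + Gamma(2, 0.5) D |
| true ELP | 1.1772 + 0.1513·AL + Normal(0, 0.45), truncated [2.5, 7] mm | mean ≈ 4.73 mm |
| phakic ACD | Normal, truncated [1.5, 5] mm (carried, optically unused) | mean 3.2, SD 0.35 mm |

Flat/steep radii are reconstructed from mean power ± astigmatism/2 through
the keratometer relation. An optional `al_k_corr` couples axial length to
corneal power (default 0: the near-identity of the simple and partial
corneal-power slopes in the sensitivity panel suggests weak coupling).
Surgery implants the emmetropizing equivalent power rounded to the 0.5 D
manufacturing grid; the observed refraction adds Normal(0, 0.25 D) noise
and 0.25 D chart quantization. Truncations use rejection resampling. Each
record consumes its own seeded substream (`SeedSequence(seed,
spawn_key=(i,))`), so growing a cohort never reshuffles earlier eyes.

Calibration rationale: the AL spread and ELP residual SD were chosen so
the cohort reproduces the magnitude of ratio dispersion and the
ELP-vs-AL explained variance a large cataract registry shows; the mean
corneal radius is the standard schematic value. These are population
stand-ins, not fits to any proprietary data.

What the generator does **not** emulate: multi-center and device-specific
measurement error, toric-surgery case mix (its astigmatism distribution is
population-typical rather than shifted toward high astigmats), ACD-based
ELP physiology, axial-length-dependent refraction targets (all eyes aim
for emmetropia), and real IOL labelling constraints beyond the power grid.
Passing tests therefore demonstrate the optics and the analysis machinery,
not the demographics of any particular clinic.

## Sensitivity analysis

Per-case results feed a fixed panel of OLS regressions (simple models of
the ratio on corneal equivalent power, corneal astigmatism, ELP and axial
length; ELP on axial length; equivalent IOL power on axial length, ELP and
corneal power; and the multiple model `P_eq ~ ELP + AL`). The ratio
regressions deliberately use the **back-solved** ELP, not the generator's
latent one — estimated lens position is what any real workflow has.
Each fit reports coefficients, standard errors, adjusted R², the overall
p-value (slope t-test for simple models, F-test for multiple ones),
`|R| = sqrt(max(adj R², 0))` and its Cohen class (negligible ≤ 0.1 <
small ≤ 0.3 < moderate ≤ 0.5 < large, upper edges inclusive). p-values are
descriptive only; no multiple-testing correction is applied. Plain OLS
standard errors are used throughout. Models that cannot be fitted (constant
predictor, too few cases) are itemized as unfittable without failing the
run.

The fixed-factor misestimation bounds convert a ratio range
[ρ_low, ρ_high] and a standard factor f into worst-case percent under- and
overcorrection of the refractive cylinder, `100·(ρ_high − f)/ρ_high` and
`100·(f − ρ_low)/ρ_low`.

## Numerical choices and degenerate inputs

* Vergence propagation raises a dedicated error when a focus falls inside
  a gap (denominator < 1e−12); per-case analysis converts such failures to
  flagged, excluded rows rather than exceptions.
* Summary SD uses the n−1 denominator; medians use midpoint interpolation
  for even n; a single-case summary reports SD as NaN.
* Biometric plausibility gates at load time (5 < r < 11 mm,
  15 < AL < 40 mm, r_steep ≤ r_flat); rejected rows are counted and
  itemized, and the CLI aborts when more than 10 % of rows reject.
* Cohort CSV uses comma separators, period decimals, UTF-8 and a mandatory
  header; floats are written with 10 significant digits so repeated runs
  are byte-identical.

## Problem sizes

The default cohort is 16,744 eyes, the size a full analysis is reported
at; it fits in about two seconds. Unit and property tests use smaller
cohorts (hundreds to a few thousand eyes) chosen so each statistical
tolerance still has several standard errors of headroom.

## Known limitations

Paraxial thin-lens optics only — no thick-lens model, no full-aperture
raytracing, no chromatic effects. Capsular-bag lenses only; sulcus,
add-on and phakic lenses sit closer to the cornea and have systematically
lower translation ratios. The multiple-regression ELP partial on the
default cohort (≈ 1.73 D/mm) sits somewhat below the pure optical partial
(≈ 1.89 D/mm at average biometry): the ELP estimation error is larger in
long eyes, where the partial is small, which attenuates the fitted
coefficient — a genuine feature of any workflow that regresses on
estimated lens positions under refraction noise.
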