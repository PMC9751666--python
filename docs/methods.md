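# Methods

This note records the models implemented in `osteorad`, their assumptions,
the defaults and why, and the numerical choices a maintainer would want to
know. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Internal dosimetry

**Model.** A bone-seeking β emitter injected at ages `t_i` produces a dose
rate that is a sum of decaying exponentials,
`r(t) = Σ_i r0_i · 2^(−(t−t_i)/T½)`, and a cumulative dose with the closed
form `D(t) = Σ_i r0_i · τ · (1 − 2^(−(t−t_i)/T½))`, `τ = T½/ln 2`.
Decay uses the *physical* half-life (163 d for Ca-45): calcium fixed in
mineralized bone has a biological half-life of decades, so biological
elimination is negligible on a mouse lifespan. `retention_consistency`
makes that assumption checkable: it predicts later whole-body retention
from an earlier time point under pure physical decay and flags "use
physical half-life" when every prediction lies within one SD of the
measured mean.

**Calibration modes.** Converting an injection schedule into initial dose
rates `r0_i` requires source-region mass and skeletal-uptake assumptions
that published dose envelopes rarely state. Two modes are provided:

* `physical_mass` — first principles:
  `r0 = A · f_ret · Δ · φ / (m_src · DDREF)`, with A the injected activity
  (Bq), f_ret the retained fraction (default 0.879, the ~88% whole-body
  retention measured ten days after injection), Δ the equilibrium dose
  constant (`n̄·Ē·1.602×10⁻¹³` Gy·kg/Bq·s, derived from the nuclide unless
  overridden), φ the absorbed fraction, and m_src the source-region mass.
* `pinned_peak_rate` (default) — per-injection rates are equal (both
  injections used the same activity concentration) and scaled so the
  summed rate immediately after the **last** injection equals a stated
  peak. Pinning at the last injection, not the first, is what reproduces
  all three published cumulative-dose ranges simultaneously; pinning the
  first would push the 34.3-week dose above the published upper bound.

**Absorbed fraction.** φ is a configured parameter (0.9 for Ca-45 in mouse
bone, 0.4 for Sr-89), not computed from point-kernel transport: the kernel
computation's geometric inputs are not available, and transport is out of
scope. `absorbed_fraction_slab_estimate` (φ = thickness/range, clipped) is
shipped as an explicitly labeled qualitative surrogate only — it preserves
the right monotonicities and the Ca-45 > Sr-89 ordering, nothing more.

**Range–energy relation.** Katz–Penfold,
`R[g/cm²] = 0.412·E^(1.265−0.0954 ln E)`, valid 0.01–2.5 MeV. At the
Ca-45 endpoint (0.257 MeV) it gives 0.0619 cm ≈ 0.062 cm at two
significant figures. At the Sr-89 endpoint (1.495 MeV) it gives 0.67 cm;
published Sr-89 figures around 0.84 cm presumably use a different endpoint
or relation, so Sr-89 range values are used only directionally (via φ).

**DDREF** is an explicit no-op scalar (default 1): dose- and dose-rate
effectiveness corrections are a reporting choice, kept visible but not
applied by default.

**Numerics.** Closed-form doses are exact; `cumulative_dose_trapezoid`
integrates the rate curve piecewise between injections (default step
0.1 d) and agrees with the closed form to <0.1%, which the tests and the
acceptance script both verify. Time is handled in days internally, weeks
at interfaces; doses in mGy/day and Gy.

## Morphometry

**Preprocessing.** 5×5×5 median filter (reflective boundaries), then an
inclusive threshold at a calibrated density of 334 mg/cm³. The boundary
convention (≥) is stated because only a "minimum threshold" is given.
Density calibration is a linear least-squares map from ≥2 phantom pairs.

**VOI rules.** Trabecular: a 1.0 mm slab starting 0.5 mm from the
growth-plate slice toward the diaphysis. (Published VOI figures of
"0.5 μm / 1.0 μm" are physically implausible — below one voxel — and are
read as mm.) Cortical: 50 midshaft slices (0.5 mm at 10 μm voxels). The
growth-plate slice is a configuration input; automatic detection is not
attempted. VOI overruns raise errors naming the offending bounds.

**Local thickness (Tb.Th, Tb.Sp, Ct.Th).** Hildebrand–Rüegsegger sphere
fitting on the Euclidean distance transform. Conventions: a sphere
centered on a voxel has diameter `2·dt − 1` (center-to-center distances
overshoot the phase boundary by half a voxel per side; a single voxel is
one voxel thick, odd slab widths are exact). Even slab widths put the
continuum sphere center between two equal-dt voxels straddling a crest of
the distance field; detected crest pairs get one extra voxel of diameter,
making even widths exact too. The max-over-covering-spheres is evaluated
by descending level sets (one EDT per quarter-voxel level, early exit once
every voxel is assigned) with a half-voxel-generous reach, which avoids
the coverage holes a sparse ridge-painting approximation produces on
curved structures. Verified accuracy: exact on slabs 4–20 voxels, within
one voxel on balls, rods and the annular shaft, with error decreasing
across 20/10/5 μm voxels. Ct.Th extends the mask along the shaft axis by
edge replication before fitting (a midshaft VOI is a crop of a continuing
shaft); trabecular VOIs are evaluated as-is.

**SMI.** `6·V·S′/S²` with S from marching cubes and S′ a central finite
difference displacing vertices half a voxel along outward normals. The
binary mask is Gaussian-smoothed (σ = 1.5 voxels) before surface
extraction; on a raw staircase surface S is inflated ~20% and SMI biased
low (a ball reads ~3.4 instead of 4). Plate/rod/ball phantoms come out
within 0.5 of 0/3/4; negative values for concave structures are reported
as-is. Finite plates have edge contributions of order `24·t/L`, so plate
phantoms for SMI need aspect ratios ≳ 50.

**Connectivity density.** `Conn.D = (1 − χ)/TV` with χ the 3D Euler
characteristic under 26-connected foreground / 6-connected background
(scikit-image's octant-pattern method) and TV the full VOI volume. For a
single connected, cavity-free structure this is the handle count (first
Betti number) per mm³; the tests verify χ against a brute-force
cubical-complex count (V−E+F−C) and Conn.D against a union-find Betti
oracle on random grids.

**Cortical areas.** Per slice, Tt.Ar is the hole-filled region inside the
periosteal contour (marrow included) and Ct.Ar the thresholded bone area
(intracortical pores excluded from Ct.Ar but inside Tt.Ar), averaged over
the VOI slices.

**Tb.N** is `1/(Tb.Th + Tb.Sp)` (parallel-plate model). A direct mid-axis
count would be an alternative; the plate model is used because the source
protocol does not state the method.

## Cohort statistics

Every test is two-sided; p < 0.05 is significant, p < 0.075 a trend; stars
map as * < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001.

**Normality gate.** Each group is screened with a one-sample KS test
against a normal with its own mean/SD; if either group rejects at 0.05
(or has zero variance, or n < 3) the comparison uses Mann–Whitney U,
otherwise Welch's t. Estimating the parameters from the sample makes the
KS gate anti-conservative in the Lilliefors sense — it under-detects mild
non-normality — which is accepted as the stated decision rule. The gated
procedure's type-I error is verified at 0.05 ± 0.01 by null simulation
(n = 10 per group, 10,000 replicates, fixed seed).

**Mann–Whitney** uses exact enumeration for combined n ≤ 12 without ties
(verified against a brute-force assignment enumeration), a tie-corrected
normal approximation otherwise. **ANOVA/Tukey** delegate to
scipy's `f_oneway`/`tukey_hsd` (studentized range).

**Survival.** Kaplan–Meier via lifelines. The Gehan–Breslow–Wilcoxon test
is implemented directly as the weighted log-rank with weight = number at
risk at each event time, variance from the hypergeometric law, statistic
`U²/Var` against χ²(1); it matches lifelines' `weightings="wilcoxon"`
log-rank exactly, which serves as an independent cross-check. Because
study arms are small, a label-permutation p (vectorized, add-one
estimator, seeded) is available; at arm sizes like the acute-exposure
groups (~18–20) the asymptotic p agrees with a 10,000-permutation p
within 3 Monte-Carlo SEs, while at n ≲ 13 the discreteness of the
permutation law can exceed that bound for any asymptotic version.

**Fold change.** Per group and marker, the ratio of late-window to
early-window means, with a direction arrow using a ±5% dead band and a
within-group gated test of late vs early.

## Synthetic data

**Phantoms** are deterministic voxelizations with closed-form truth
records; every feature must span ≥ 4 voxels so discretization error stays
inside the morphometry tolerances. The femur-like composite (annular
shaft + growth-plate disk + plate-stack metaphysis) exercises the full
filter → threshold → VOI → metrics pipeline with known truth. Grayscale
phantoms map density linearly to gray values with additive Gaussian noise
and return the matching calibration, so zero noise recovers the mask
exactly.

**Cohorts.** Group sizes and sex splits reproduce the study structure
(acute pair: control 18 = 10M/8F, exposed 20 = 9M/11F; chronic pair:
control 8 = 4M/4F, exposed 9 = 5M/4F). Lifespans are Gompertz
(shape 0.06/week, control median 110 weeks — standard rodent mortality);
exposure acts as a proportional hazard multiplier, default 4.0, chosen to
match the strong survival separation the study design reports and giving
the weighted log-rank >80% power at 20 per arm (verified by simulation).
White-blood-cell counts dip ~60% two weeks after acute exposure and
recover by week 10, versus a sustained ~25% deficit through week 29 in the
chronic arm. Serum markers are lognormal (concentrations are positive and
right-skewed, σ_log = 0.15) around per-group early/late means encoding the
qualitative trends: P1NP up everywhere; OPG down after acute, up under
chronic exposure; CTX-I up everywhere except the chronic arm; CCL2/CXCL1
flat after acute, up under chronic exposure. Effect sizes are qualitative
choices — the source figures print no axis values.

**Excretion.** The same three mice are whole-body counted on each
measurement day: each carries a persistent uptake offset (SD 1.4%) plus
per-count noise (SD 0.25%), around a residual curve
`R(d) = 90.8% · 2^(−d/163)`. This keeps day-3/day-10 means and SDs in the
measured envelopes and makes the physical-half-life decision reproduce in
>95% of seeds, because the persistent offsets cancel in the decay
prediction.

**What passing tests do and do not show.** Phantom recovery bounds
discretization and implementation error on ideal geometries; real
trabecular bone adds partial-volume effects, beam hardening and
segmentation ambiguity that no phantom here emulates. Cohort simulations
validate the statistical machinery and the direction of the encoded
trends; they cannot validate the biology, and the marker effect sizes are
not estimates of real concentrations.

## Problem sizes

Defaults keep the full suite at desk scale: phantoms up to ~170³ voxels
(10 μm annulus), resolution-convergence checks on shortened 6-slice
shafts at 20/10/5 μm, 10,000-replicate null calibrations, 50 × 10,000
permutation comparisons, and 300-replicate power runs.

## Known limitations

* No Monte-Carlo transport, voxel S-values or marrow/bone-surface dose
  partition; φ is an input.
* Local thickness is quarter-voxel quantized by the level-set evaluation.
* SMI is surface-mesh based and inherits marching-cubes behavior for
  structures a few voxels thick.
* The cohort simulator draws marker values independently across time
  points (no within-animal correlation).
* NRRD volumes are not read; use multi-page TIFF (explicit voxel size) or
  NIfTI.
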