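# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of `bronchmech`. Formula-level definitions
are in the README and module docstrings; here the focus is on *why* the
pieces look the way they do and what the tests do and do not demonstrate.

## 1. Densitometry and regional expansion

Gas fraction is linear in attenuation between the blood (65 HU) and air
(−1000 HU) references; expansion `E = F_gas/(1 − F_gas)` is the
gas-to-tissue volume ratio, a dimensionless analogue of specific gas
volume. Inside the parenchymal window of −950…−400 HU, `E` is confined to
[0.775, 20.300]; both window bounds are treated as **inclusive** (the
natural reading of a closed threshold range; the choice moves single
boundary voxels only). Out-of-window voxels inside the lung are simply
excluded by the mask — no imputation. `gas_fraction` clamps out-of-range
values by default and can be asked to raise; `expansion` raises on any
voxel with `F_gas ≥ 1`, which cannot occur inside a −950-bounded mask.

Units are mm/mm²/mL internally; subject-level volumes are litres.

## 2. Peribronchial ROI

The sampling region is a sphere of diameter four times the equivalent
outer diameter of the airway, centred on the airway centre point, and
intersected with the parenchyma mask. Membership is by **voxel centre**
(no partial-volume weighting): reproducible and checkable against a
brute-force distance scan, which the tests do.

At P and T the diameter is adjusted by bisection until the ROI
*parenchymal tissue volume* (the masked region's tissue, the only tissue
the pipeline can see) is within 5% of the baseline value, searching
diameters in [1×, 8×] the equivalent diameter with at most 60 iterations;
tissue volume is monotone in diameter, so bisection is sufficient, and an
unreachable reference raises with the achieved mismatch. The sampled
fraction `F_s` is ROI volume over the theoretical volume (sphere minus an
intersecting cylinder of cross-section `A_o`).

## 3. Vertical gradients and the conversion factor

`ΔE = E_SL − E_pb` is regressed on the normalised height offset `Δh` per
subject and condition by unweighted OLS (airways are not size-weighted; no
robust/mixed-effects variants). `ΔE_mean` is defined as the regression
**intercept** — ΔE adjusted to Δh = 0 — which makes the intercept and
ΔE_mean columns of the summary identical by construction. A constant
response is reported with `r² = 1` (the fit is exact); a degenerate design
(all Δh equal, or fewer than three airways) is an error.

The conversion factor `k̄` is computed per subject from that subject's own
P and T values; group-level regressions of ΔE_mean on E_Lung are reporting
surfaces only. `k̄` is used as a **multiplier** when converting the
critical-expansion gap into a closure volume and as a **divisor** when
mapping residual volume to expansion at RV — the two printed conventions,
adopted as-is even though they are not mutually consistent with the
identity that defines `k̄`. One consequence: with `k̄ > 1` an airway just
past the closing threshold can produce a negative per-airway excess in the
trapping sum; negative excesses are clamped to zero (they never
accumulate), and ties at the threshold do not close.

## 4. Per-airway mechanics

All area ratios are normalised by `A_o,T` at a single site (functions
accept raw mm²). Critical-expansion arguments outside [0, 1] are never
silently clamped: `x > 1` returns 1 with a `clamped_above` flag, `x < 0`
returns no closure with a `no_closure` flag, `RD ≤ 0` returns
`rd_nonpositive`. Airways with `RD ≤ 0` (outer area larger at breathing
volume than at TLC — plausibly measurement error, retained for
transparency) are kept in RD summaries but **excluded from closure and
trapping predictions**; the breathing-volume variant uses `A_w,P`, the
forced-exhalation variant `A_w,T`, never a blend. When a subject's least
stable airway carries a `no_closure` flag its critical expansion is taken
as 0 (closure only at full deflation), the most conservative value.

The subject-level minimum of `A_i*/A_o,T` is reported both as the plain
minimum and as mean − 2·(sample SD); the two track each other closely.

## 5. Subject-level predictions

`ΔV_C/TLC` uses the airway with the minimal iso-volume lumen among
positive-RD airways, with that airway's own baseline expansion ratio.
`RV_P = TLC − FVC_P` with the supine post-challenge FVC, as stated. The
trapping sum is emitted in both modes: `literal` reproduces the printed
formula, in which each closing airway contributes a whole-lung-scale
volume; `weighted` (the default for the per-subject prediction column)
multiplies each term by the segment's fractional lung volume at TLC,
restoring dimensional consistency. Both columns appear side by side in
every report, and the cohort-level FVC association is computed on the
literal values, since that is the scale the observed FVC responses live
on.

## 6. The tabular cohort generator

The generator emulates the study conditions: 7 "AS" + 9 "NA" subjects,
19 segmental airways, three conditions. Key defaults (chosen once, as the
emulated conditions): `RD ~ N(0.75, 0.5)` clipped to [−1, 3]; wall
fractions `A_w,P/A_o,T ~ U(0.3, 0.6)` with `A_w,T = 1.1·A_w,P`;
`MLV_B/TLC ~ 0.54 ± 0.08`; vertical gradient 3.0 ΔE per unit Δh with
between-subject SD 0.6; `E_Lung ~ 3.88 ± 0.70` at B and `8.66 ± 1.05` at
T, interpolated in volume fraction at P; `ΔE_mean = β·E_Lung + α` with
`β ~ 0.30 ± 0.05`, `α ~ −0.95 ± 0.15`; TLC `5.4 ± 0.9` L; baseline FVC
`0.70 ± 0.06` of TLC; outer areas log-uniform on [15, 80] mm².

Design choices that matter:

* **Shared peribronchial level.** Per subject, `E_pb` at each condition is
  the level `L_c = E_Lung,c − ΔE_mean,c`, so the identity
  `k̄·E_Lung,P/E_Lung,T = E_pb,P/E_pb,T` holds exactly and every recovery
  test has a sharp truth value. Per-airway heterogeneity enters as a
  log-normal **exponent** on the normalised expansion
  (`e_airway = e_subject^q`, `ln q ~ N(0, 0.35)`, clipped to ±0.59): local
  under- or over-expansion that preserves ordering across conditions.
  Without it, the subject-uniform expansion would make high-RD airways
  unmeasurable (their post-challenge lumen would close), collapsing the RD
  range; with it, measurable airways span RD ≈ −0.7…2.5 as in real lungs,
  where briskly dilating airways are the locally well-expanded ones.
* **Measurable set.** Airways are rejection-sampled until the lumen is
  ≥ 4.2 mm² in *all three* conditions — the validated measurement floor —
  evaluated at the lowest post-challenge volume the subject can end up at.
  This mirrors the selection operating on real segmental-airway data and
  is why the generated RD mean (~0.65–0.68) sits slightly below the
  nominal 0.75 of the sampling distribution.
* **Relaxed baseline.** The baseline state is off the constricted P–T
  line, on its own expansion curve: `a_B` centred at
  `0.82 + rd_relax·(e_B^{2/3} − 0.68)` with `rd_relax ~ 0.75 ± 0.25` and
  residual SD 0.04, clipped to keep the baseline lumen measurable. Giving
  the relaxed curve a slope comparable to the constricted one makes
  between-subject *level* differences in expansion cancel out of the B→P
  narrowing, leaving the volume rise as its physiological driver.
* **Volume defense.** The post-challenge volume rise is
  `max(rise + 0.6·max(ΔV_C/TLC, −0.08), 1.15·ΔV_C/TLC + 0.005, 0.02)`
  with resting rise `~ N(0.12, 0.05)`: an active-control response in which
  the chosen breathing volume tracks the closure threat of the least
  stable airway, floored at 15% above first closure. The coupling is the
  hypothesis under study made generative; with `volume_defense=False` the
  post-challenge volume is sampled directly from `0.67 ± 0.11`. A rare
  subject whose defense would require `MLV_P/TLC > 0.97` is redrawn.
* **FVC response.** The fractional FVC drop follows a per-group linear
  response to the predicted (literal-mode) trapped gas — slope/intercept
  1.74/0.15 (AS) and 0.97/0.07 (NA) plus 1% noise — solved to a fixed
  point by bisection, because trapped gas itself shrinks as the FVC drop
  raises RV_P (the feedback gain can exceed 1, so plain iteration would
  oscillate).
* An `airway_corr` knob exposes a shared smooth-muscle component of RD
  across a subject's airways (default 0); no fidelity claim is attached.

With zero noise the full pipeline recovers RD, ΔE_mean, `k̄`, ΔV_C/TLC
and both trapping sums to ≤ 1e−10 (truth for derived quantities is the
forward model evaluated on the true parameters). Across 60 of 62 tested
seeds the cohorts reproduce the sign structure of all four headline
associations, at magnitudes close to the emulated study; the two
exceptions flip only the weakest association (volume rise vs mean
narrowing), which at n = 16 subjects carries sampling noise of roughly
±0.25 on the correlation.

## 7. The voxel phantom

The phantom trades anatomy for analytic truth: the lung is a box, the 19
segments are dorso-ventral slabs (gravity along the last grid axis,
ventral = increasing index, recorded in the metadata), and expansion is a
single field linear in height, so each slab's mean is the field at its
parenchymal centroid and a z-symmetric sphere averages to the field at its
centre. Airways are full-width cylinders (air-HU lumen in a soft-tissue
wall at 40 HU) at voxel-centre heights, staggered over four lanes; one
vessel cylinder accompanies each airway at the same height, so all
exclusions from a sphere are z-symmetric. The grid refuses airways
narrower than 3 voxels across. The phantom does **not** deform between
conditions — only the density field changes — so no registration is
involved anywhere.

Default grid: 84×84×96 voxels at 1.25 mm (a scaled-down ~1.15 L lung),
small enough that the whole three-condition render plus morphometry runs
in ~1 s on one core; the ROI membership oracle runs on ≤ 64³ grids.
Residual imperfections: slab-mean recovery is exact to machine precision,
but sphere means for airways near the dorso-ventral boundary are biased by
up to ~1% where the sphere is clipped asymmetrically by the lung edge.

The noise-robustness experiment builds a subject whose airway areas are
exactly consistent with the phantom's own expansion field (RD clipped to
[0.1, 1.5] and outer areas 30–60 mm² so every rendered state stays
resolvable), renders P and T with Gaussian HU noise of SD 20, re-measures
`E_pb` through the full spherical-ROI procedure and re-estimates RD.
Noise-free recovery is exact to ~4e−4; at 20 HU the median absolute RD
error is ≈ 0.026, the calibrated value the regression test guards.

## 8. What passing tests do and do not show

The synthetic tier demonstrates *internal* consistency: the estimators
invert the forward model exactly, the closure algebra matches brute-force
scans, the ROI geometry matches its oracle, and the cohort-level
associations follow from the generative mechanism. It does not
demonstrate that real lungs satisfy the linearity of the constricted
airway law, the constancy of wall area from B to P, the log-exponent form
of local expansion heterogeneity, or the active-control coupling — those
are modelling assumptions of the emulated study and of this generator.
Real-data idiosyncrasies not emulated include segmentation error,
partial-volume effects at airway walls, cardiac/respiratory motion, blood
volume shifts within parenchyma, and non-spherical peribronchial
neighbourhoods.

Statistical conventions throughout: two-sided paired/unpaired t-tests and
Pearson correlations, significance at P < 0.05, no multiple-testing
correction (flagged in the report footer).
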