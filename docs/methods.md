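# Methods

## Projection geometry

All geometry lives in the vertical plane spanned by the bundle's
mechanosensitivity axis *x* and the apical-surface normal *z*. A
stereocilium with insertion tilt α (shared by the whole bundle) has axis
unit vector **u** = (sin α, cos α); the electron beam at angle of view τ is
**b** = (sin(α+τ), cos(α+τ)). Row *i* inserts at (−(i−1)·d, 0) with *d* the
center-to-center inter-row base spacing (assumed center-to-center; the
alternative edge-to-edge reading only shifts *d* by one shaft diameter and
is absorbed by the input value). The image records the component of any
vector perpendicular to the beam, P(**v**) = **v** − (**v**·**b**)**b**;
the projected length of a full stereocilium is h·|sin τ| and tip-to-tip
step distances are measured along the projected axis P(**u**)/|P(**u**)|,
oriented tip-ward.

**Stage-tilt convention.** Stage tilt θ is defined so the beam angle from
the surface normal equals θ; then the parallel angle θ₀ equals α for every
view of a bundle and τ = θ − θ₀. Medial ("front") views have τ > 0;
lateral ("back") and top views have τ < 0. The published descriptions of
such measurements give no sign convention, so this one was fixed once and
every closed-form inverse is validated against the numeric vector forward
model in the tests (both signs of τ).

Signed step projections: the forward model yields
p = (h₁−h_row)·sin τ − sign(τ)·(row−1)·d·cos(α+τ) on the oriented
projected axis. The measurement tables store this signed value for step
kinds (a shallow staircase viewed at a steep angle can legitimately put
the shorter row's tip *above* the taller row's tip in the image);
full-length projections are non-negative by construction. This is what
makes the noise-free round trip exact rather than exact-up-to-a-branch.

## Inverse solvers and numerical choices

- **Two-view** (lateral pair, θ₀ unknown): exact closed form; the solution
  must have α in the open interval (0°, 90°), otherwise the inputs are
  declared inconsistent. p₁ = 0 is rejected (it means the first view was
  already parallel, which is the reference-angle method's regime). A
  bracketed Brent root-find (tolerance 1e−10) is available behind
  `noisy=True` for inputs with independent errors; the default stays
  closed-form for determinism.
- **Reference angle**: `find_parallel_angle` fits h·|sin(θ−θ₀)| by
  Levenberg–Marquardt least squares with (h, θ₀) free rather than taking
  the sampled minimum, because tilt grids are coarse (5–10° steps); the
  fit localises θ₀ to well under 0.1° on noise-free series. A strictly
  monotone series means the minimum is outside the sampled range and the
  function refuses to extrapolate.
- **Degenerate views**: |τ| < 1° is rejected everywhere — the height error
  amplifies like 1/sin τ, so a sub-degree view multiplies measurement noise
  by ≥ 57. |τ| = 90° (perpendicular) is valid and gives p = h exactly.
- **Reconstruction cascade** (`reconstruct_bundle`): row-1 heights from
  full-length projections at views with known θ₀ (averaged over views),
  else from a two-view pair, which also yields α; the bundle's α is the
  parallel angle when known, else the mean two-view α; rows 2–3 from
  front-view steps against the bundle's row-1 mean (the per-bundle
  reference that lets per-stereocilium steps be pooled across cells), with
  a fallback to their own full-length projections. Each height records the
  solver that produced it; stereocilia with insufficient views are kept
  and flagged `unresolved`, never dropped. An implied non-positive height
  (possible when a deeply retracted stereocilium meets measurement noise)
  is likewise flagged rather than clamped.

## Morphometry

Heights are tip-apex heights ("highest point"), deliberately ignoring
tip-shape changes. Tip shape itself is modelled by a one-parameter
power-law taper, diameter(s) = shaft·min(1, (s/L)^γ): γ ≈ 0.5 is a blunt
rounded tip, γ ≈ 1 a conical wedge, γ > 1 an abnormally thin pointed tip.
The family is a package choice — real tip contours are only described
qualitatively — picked because one parameter spans all three regimes and
every derived statistic stays closed-form: the wedge-tip height (axial
extent of the taper up to a threshold fraction of the shaft diameter,
default 0.95, i.e. where the taper effectively meets the shaft) is
L·threshold^{1/γ}. Note this is increasing in γ: a more pointed tip's
taper hugs the shaft later. Default diameter positions are
{0.025, 0.05, 0.1, 0.2} µm from the apex plus a mid-shaft sentinel.

A tip link is a link leaving the *top cap* of a lower-row stereocilium,
pointing upward and toward the taller rows along the mechanosensitivity
axis; links leaving elsewhere on the tip hemisphere, shaft links, lateral
links and downward links are excluded. Tip-link prevalence is summarised
per cell first (percentage of rows-2/3 stereocilia with a link), then as
mean ± SE across cells. Supernumerary stereocilia are rank ≥ 4 or
unranked.

## Synthetic data: what it emulates and what it does not

`generate_bundle` draws per-row heights from independent normals truncated
at > 0, a Poisson number of supernumerary stereocilia, and Bernoulli tip
links (plus occasional lateral shaft links so the classifier's exclusion
rules are exercised). The default OHC geometry — row means 2.4/1.4/0.7 µm,
SDs 0.12/0.10/0.08 µm, d = 0.4 µm, α = 10°, 10.9 supernumerary per cell —
is a fixture resembling a mid-cochlear early-postnatal outer-hair-cell
bundle; IHC defaults are taller/thicker with ~25 supernumerary. Nothing
downstream treats these numbers as truth: all recovery scoring is against
the generated ground truth.

The treatment model scales every effect by
f = blocked_fraction(dose, IC50) · duration_scale with
blocked_fraction = dose/(dose+IC50) (Hill coefficient 1; only two
calibration points exist per drug, so a free slope is unidentifiable).
Default IC50s are back-solved from the expected ~75 % block at 100 µM
amiloride and ~90 % at 30 µM benzamil: 33.33 µM and 3.333 µM. Shortening
of rows 2–3 is a two-component mixture — graded loss
N(shorten_mean_max·f, (shorten_sd_max·variance_inflation·f)²) truncated at
non-negative loss, or (with probability retract_prob_max·f) deep
retraction to a uniform fraction of the original height — because
observed treated distributions show both a modest mean shift and outlier
near-total retractions. Amiloride's preset differs from benzamil's only
by variance_inflation = 2 (broader treated distribution at a weaker
block); IHC presets halve the effect magnitudes. Treated tips thin by an
additive γ shift; supernumerary stereocilia are binomially pruned with
probability supernumerary_prune_max·f. Row 1 is carried over bit-identical
— the invariance is exact by construction, not statistical — and tip-link
presence never changes under treatment. A height floor of 0.05 µm keeps
deeply retracted stereocilia physically meaningful.

Measurement noise is multiplicative Gaussian on projections (default
CV 5 %, an examiner's tracing error scaling with the measured length) and
additive on diameters (default SD 0.01 µm). Structure seeds and noise
seeds are separate streams, so noise can be re-rolled over fixed anatomy.
Washout/recovery conditions are modelled by moving duration_scale back
toward 0; no kinetics are modelled. The generator does **not** emulate:
image-level artefacts (occlusion, charging, fixation damage), correlated
within-cell height effects, tip-link tension mechanics, or any Ca²⁺/actin
biophysics — so passing tests demonstrate the *measurement pipeline's*
correctness under the stated statistical structure, not biological
realism of the effect sizes, which are placeholders tuned only to give
the comparisons reasonable power.

## Statistics

Per-stereocilium metrics: mean ± SD, Welch's unequal-variance t test with
Welch–Satterthwaite df. Per-cell percentages and counts: mean ± SE,
Student's pooled t test. All tests two-sided; stars at
p < 0.05/0.01/0.001/0.0001; no multiple-testing correction (panels report
per-contrast uncorrected stars — a deliberate, documented convention).
Stereocilia are pooled across cells, ignoring cell-level clustering; this
matches the field's reporting practice and is a known limitation — a
mixed-effects layer is out of scope. Note the pooled null comparison of
the untouched first row is an exact-size test: across replicate
simulations its nominal 5 % false-positive rate fluctuates binomially, as
the seeded replicate tests show.

## Problem sizes used in the test suite

Round-trip and recovery checks use ~1,000 randomly parameterised
stereocilia (334 three-row bundles with h ∈ [0.3, 3] µm, α ∈ [0°, 30°],
τ ∈ [5°, 85°]); the noisy-recovery check uses 34 default bundles
(~1,350 stereocilia) at 5 % projection CV; the cohort-pattern check runs
100 seeded replicates of 10-bundle groups (~100 stereocilia per row per
group, the scale of a typical single SEM series); the t-test size check
uses 10,000 null simulations at n = 20 per group with a 1:3 SD ratio.
These sizes were chosen as the smallest that make the statistical
assertions stable.
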