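# Methods

`daptsim` simulates complete courses of daily online-adaptive
intensity-modulated proton therapy (IMPT) for synthetic head-and-neck
geometries and quantifies the dosimetric cost of *treatment execution
uncertainty* — the residual patient-positioning error introduced after
daily imaging and plan adaptation but before delivery. This is the
uncertainty that distinguishes an in-room CT-on-rails workflow (the
patient is moved between imaging and treatment) from a CBCT workflow
(imaged at treatment position, taken here as offset-free).

## Uncertainty model

The total execution uncertainty combines the isocenter-matching term
σ_i and the couch-motion term σ_m in quadrature,

    σ = sqrt(σ_i² + σ_m²),

with σ_i = 1 mm held fixed and σ_m ∈ {1, 2, 3} mm, giving the three
scenarios σ₁ = 1.41 mm, σ₂ = 2.24 mm, σ₃ = 3.16 mm. For each fraction a
post-adaptation offset Δx is drawn per axis from N(0, σ) — equal
uncertainty in the left–right, posterior–anterior and inferior–superior
directions — and applied to the patient *after* the daily
re-optimization, so the adapted beamlet weights are structurally
independent of the offset (asserted by a dedicated test). Paired
scenario arms share one standard-normal triple per fraction scaled by
each scenario's σ (common random numbers), which sharpens the
between-scenario comparison without coupling the geometry streams.

## Synthetic cohort

No public dataset of daily in-room images exists for this problem, so
the cohort is synthetic with analytically known geometry and transforms.
The phantom is an elliptic-cylinder neck (water-equivalent, relative
stopping power 1.0; semi-axes 55 × 48 mm, length 104 mm) containing a
vertebral surrogate (RSP 1.6) around the spinal cord, two nested CTVs
(low-risk: r = 20 mm cylinder; high-risk boost: r = 15 mm, ≈ 30 cc),
parotid glands, pharyngeal constrictors, larynx and brainstem, with air
outside. The stopping-power map is anti-aliased (2×2×2 supersampling),
so surface voxels carry partial-volume values and water-equivalent
depths respond smoothly to sub-voxel rigid shifts; structure masks are
voxel-center inclusive.

Each of the (default ten) patients draws, from a fixed master seed:

| parameter | distribution | default | role |
|---|---|---|---|
| fractions | uniform {31…35} | — | course length |
| systematic setup error | N(0, 2 mm) per axis, once | 2 mm | interfraction reproducibility |
| random setup error | N(0, 2 mm) per axis, per fraction | 2 mm | daily setup noise |
| external shrinkage | max U(0, 4) mm, linear over course | — | weight-loss surrogate |
| air-cavity toggle | Bernoulli(0.2) per fraction | — | sinus-filling surrogate |
| target drift | max U(0, 5) mm, random direction, linear | — | tumor displacement vs. setup reference |

The sampled setup error is the daily displacement visible in the daily
image: online adaptation re-plans on that day's geometry and thereby
corrects it, while the unadapted base plan — delivered at its original
absolute isocenter — suffers it in full, together with the anatomy
changes (the shrinking contour changes water-equivalent depths, the
cavity perturbs one field's range, and the target drift moves the CTVs
relative to the reference anatomy). All randomness is keyed by
(master seed, patient, fraction, purpose) through `SeedSequence` spawn
keys; adding arms or scenarios never perturbs the geometry draws.

What the generator does *not* emulate: deformable (non-affine) anatomy,
CBCT image artifacts, registration error (structure identity is exact),
dental artifacts and tissue heterogeneity beyond the vertebral
surrogate, or intrafraction motion. Passing tests therefore demonstrate
the dosimetric mechanics of offset-after-adaptation workflows, not
clinical performance on real patients.

## Dose engine

An analytic spot-scanning pencil-beam model provides the same contract
as a Monte Carlo engine (dose-influence matrix; forward dose):

* range–energy: R = 0.0022 · E^1.77 (cm water, E in MeV);
* Bragg curve: the pristine (R − z)^(1/p − 1) stopping-power shape,
  capped near its integrable divergence, Gaussian-smeared with
  σ_R = sqrt[(0.012 R^0.935)² + (p R σ_E/E)²] where σ_E/E = 1.2% is the
  machine energy spread; re-centered so the maximum sits exactly at R,
  peak-normalized, hard-zeroed beyond R + 4σ_R. Without the machine
  term the peak (≈1 mm) would be far narrower than the energy-layer
  spacing and no weight schedule could produce a flat target dose;
* lateral: a single Gaussian with σ²(d) = σ_air²(E) + σ_med²(d), where
  σ_air interpolates linearly from 6.4 mm at 65 MeV to 2.5 mm at
  225 MeV and σ_med = 3 mm · (d/15 cm)² grows quadratically with
  water-equivalent depth;
* water-equivalent depth (WED): line integral of relative stopping
  power plus a 40 mm-WET range shifter. The whole-grid evaluation
  rotates the RSP volume so the beam runs along a grid axis, takes a
  midpoint cumulative sum and rotates back (validated against the
  per-point sub-voxel ray tracer to about one voxel); for a rigidly
  shifted phantom under a fixed beam it uses the identity
  wed'(r) = wed(r − δ), so offset arms translate cached WED grids.

Three coplanar fields (gantry 60°, 180°, 300°) target the low-risk CTV.
Energy layers step the peak WED at the lateral spot pitch (5 mm at the
default 2 mm grid; 6 mm at the coarse 3 mm grid), spots cover each
layer's beam's-eye-view footprint dilated by one spot. Influence
entries below 10⁻⁴ of their column maximum are dropped (verified to
move CTV doses by < 0.5%); the lateral kernel is truncated at 2.5 σ.
Only relative dosimetry matters for the scenario comparison; absolute
units are fixed by a calibration factor that scales the optimized base
plan's high-risk-CTV median to the prescription (RBE 1.1 is folded into
this calibration).

## Planning and adaptation

Plans are marginless (no PTV, no range margin — deliberately the
worst case for post-adaptation offsets) with simultaneous prescriptions
of 70/57 Gy(RBE) to the high-/low-risk CTV over the course. The
objective is a quadratic penalty: per-voxel squared relative deviation
from the target dose inside the CTVs — weighted by each voxel's
partial-volume target occupancy, so the optimizer sees the continuum
target rather than its rasterization — plus one-sided penalties for
mean-dose organs (parotids 26 Gy, constrictors 42 Gy, larynx 40 Gy) and
per-voxel max-dose organs (cord 45 Gy, brainstem 54 Gy; serial organs
are optimized with 5% headroom below the hard limit because the
quadratic penalty is soft), all scaled to the fraction dose. CTV underdose is weighted 1000 versus 100 for
overdose: coverage must survive sub-voxel re-rasterization and dose
warping while the hot-spot goal (D2 ≤ 107%) has ample headroom. A 3 mm
gradient ring around the boost is excluded from the low-dose target
term (the boost falloff has to live somewhere). A constraint is dropped
when > 5% of an organ's voxels lie within 5 mm of the low-risk CTV
(with the default geometry this disables the constrictors, which abut
the target — mirroring clinical practice for organs overlapping the
CTV).

Weights are optimized with L-BFGS-B under nonnegativity bounds
(analytic gradient; stop at relative objective decrease < 10⁻⁵ or the
iteration cap: 400 cold, 100 for warm-started daily adaptation). Daily
adaptation re-optimizes the *weights* of the base beamlet set on the
daily influence matrix, warm-started from the base weights; at the
capped budget the warm start reaches an objective equivalent to a cold
start (it does not reduce iterations-to-tolerance for a quasi-Newton
method, but it never meaningfully hurts and removes the dependence on
the heuristic initialization). The unadapted
base-plan arm recomputes the base weights' dose on the daily geometry at
the original absolute isocenter: the daily-image-visible displacement is
precisely what adaptation corrects and the unadapted plan suffers.

## Scoring

D_q uses the voxel-rank convention (value at rank ⌈q/100·n⌉ of the
descending-sorted structure doses; no interpolation); D1cc is the rank
⌈1000 mm³ / voxel volume⌉ value; the healthy-tissue integral dose D·V
(Gy·L) is summed over the external contour minus the CTVs. Fraction
doses are warped back to the planning frame by the exact inverse of
their composed rigid transform (setup + offset, trilinear) and summed.
When the target has drifted, CTV metrics are read from the accumulation
warped additionally through the drift — the exact-transform analog of
registering contours back to the planning CT — while OAR and healthy-
tissue metrics use the rigid warp. CTV D98/D2 are reported in % of the
structure's own prescription; per-fraction values are normalized to the
per-fraction prescription so fraction- and course-level coverage are
comparable.

Cohort distributions (n = patients) are compared arm-by-arm against the
no-offset adaptation reference with a two-sided Mann–Whitney U test —
exact when min(n₁,n₂) ≤ 8 and tie-free, tie-corrected normal
approximation with continuity correction otherwise; significance at
p ≤ .05 inclusive, no multiple-testing correction (raw per-cell
p-values are reported).

## Problem sizes and profiles

The `default` profile uses a 2 mm isotropic 120×120×80 grid with 5 mm
spot/layer pitch. Cohort-scale studies (including the reproduction
script) run the `coarse` profile — 3 mm isotropic 56×56×40 grid, 6 mm
spot/layer pitch, ~2000 beamlets, ~10⁴ influence-matrix builds per
10-patient 4-arm study — which keeps a full study within tens of
minutes on one core. A `tiny` 4 mm profile serves the unit tests. The
phantom geometry, variation distributions and scenario table are
identical across profiles.

## Numerical choices and degenerate inputs

Masks translate by round-half-to-even lattice shifts (exactly
invertible for any offset); dose and RSP translate trilinearly. Bragg
curves are cached per energy and evaluated by linear interpolation on a
σ_R/6 grid. Argmax ties resolve to the lowest index. A structure
smaller than 1 cc triggers a warning and D1cc falls back to the minimum
dose. An empty optimization target or structure mask raises; a target
deeper than the 225 MeV range raises a planning error. σ = 0 scenarios
reduce exactly to the no-offset arm.

## Known limitations

The anatomy-change model is affine-per-region rather than deformable;
real interfraction change is richer and interacts with range
uncertainty in ways a rigid model cannot show. The pencil-beam model
has no nuclear halo, so large-field low-dose envelopes are understated.
D98 on a ~30 cc boost volume at 3 mm resolution carries ~0.3 pp of
rasterization noise; results are reported at the cohort level for this
reason. The cohort shares one planning phantom — between-patient
variation enters through fractionation, setup statistics and anatomy
dynamics only.
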