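# Methods

## Optical model

The tear film is modelled as a single homogeneous lipid slab between air
(`n_air = 1.000`) and the aqueous layer (`n_tear = 1.337`), with meibum
at `n_m = 1.48` — standard literature values; all three are
configurable. Illumination is unpolarized broadband light at incidence
angle θ₁ (default 0, i.e. normal incidence; the slit-lamp geometry is
close to normal and the cosine correction is second order).

Reflected ray `m` makes `m` round trips inside the slab. Its intensity
follows from the per-interface Fresnel energy coefficients
(`I_0 = R₁₂·I_i`, `I_1 = T₁₂·R₂₃·T₂₁·I_i`, `I_m = R₂₁·R₂₃·I_{m−1}`),
its phase is `θ_m = m·Δ` with `Δ = 2π·OPD/λ` and
`OPD = 2·n_m·d·cos β`. The rays are summed coherently as
`Σ √I_m·e^{iθ_m}`; s- and p-polarized intensities are computed
separately and averaged, the physically standard treatment of an
unpolarized LED. The series is truncated when `I_m/I_i < 1e-9` or at 50
orders; for this stack the bounce ratio `R₂₁·R₂₃ ≈ 1e-4`, so three to
four orders already carry all the energy and the m=2 truncation error is
bounded by the analytic geometric tail (~2·|A|·√I₂/(1−√ρ) ≈ 2×10⁻⁴ in
intensity).

**Sign convention.** The magnitude-only sum above treats `√I_m` as
positive, which makes `d = 0` the in-phase *maximum* — a vanishing film
would look bright. Physically, `r₁₂ < 0` and `r₂₃ > 0` (the lipid index
exceeds both neighbours' on the entry side and the aqueous index on the
exit side), so the two leading rays interfere destructively at `d = 0`
and a vanishing film is dark, which is also what tear-film
interferograms show. Both conventions are implemented:
`interfere(..., signed_amplitudes=False)` is the literal
magnitude-plus-phase model (the default for the scalar API, and the one
all internal-consistency tests address), while the colour table is built
with `signed_amplitudes=True` so that its `d = 0` entry is the darkest —
the behaviour the inversion needs, since eyelash shadows and other dark
pixels must map to near-zero thickness.

## Colorimetry

The spectrum at each thickness is integrated over 360–830 nm (1 nm grid)
against an illuminant and the CIE 1964 10° standard observer:
`channel(d) = Σ_λ I(λ,d)·S(λ)·c̄(λ)`. The x̄ȳz̄ colour-matching
functions are evaluated from the published single-lobe Gaussian analytic
approximations (Wyman, Sloan & Shirley, JCGT 2013), which track the
tabulated observer to a few percent — ample here, because the same table
is used for rendering and inversion and only colour *differences* drive
the assignment. Tabulated CMFs can be injected via
`ObserverCMF.from_table`. XYZ weights are mapped to RGB with the fixed
linear sRGB matrix; channel sums are clipped at zero (RGB matching
weights have negative lobes that only matter for near-monochromatic
spectra). The default illuminant is a 6500 K Planck blackbody, matching
a nominal 6500 K white LED; equal-energy and user-supplied spectra are
available.

**Table normalization.** The linear RGB curve over the 0–240 nm grid
(1 nm steps, 241 entries) is scaled by a single global gain so its
maximum channel equals 255, then passed through the sRGB transfer curve
(camera output is gamma-encoded 8-bit; a linear mode exists). In memory
the colours keep full floating precision on the 0–255 scale — rounding
to integers merges neighbouring 1-nm entries (241 → 235 unique triples)
and would break exact nearest-colour inversion; the CSV export quantizes
to integer channels as an interchange format.

## Video pipeline

Brightness of a pixel is `(R+G+B)/3` throughout (a Rec. 601 luma option
exists). The analysis window is 2.5 s = 75 frames at 30 fps.

**Phase 1 — blink rejection.** `B_opened` is the mode of the per-frame
mean-brightness series (brightness rounded to the nearest integer, most
frequent value, ties to the smaller), `B_closed` its maximum; frames
above `B_opened + c·(B_closed − B_opened)`, `c = 0.33`, are dropped.
A mode-to-maximum gap ≤ 5 units is treated as *no blink evidence* and
every frame is kept: without this guard the formula would discard
ordinary frames of blink-free videos and selection would not be
idempotent. Frames whose geometry later fails (occluded pupil, no iris
boundary, empty ROI) are dropped downstream with a recorded reason.

**Phase 2 — pupil and eye centre.** The darkest 21×21 window (exact
integer window sums; ties toward top-left) seeds an 8-connected flood
fill with tolerance 5/256 measured against the starting pixel. Two
robustness details: the fill starts from the window's *median-brightness*
pixel (a start whose own value is a noise outlier strands the fill on a
fragment), and the refine step — paint the coarse region white, Gaussian
blur (σ = 5 px), re-flood with tolerance 3 — starts from the coarse
mask's incenter, because a start near the boundary would trace a thin
level-set ring instead of the core. The eye centre is the refined
centroid unless it lies farther than 0.4·expected_radius from the
darkest seed (the bound must exceed a plausible pupil radius, since the
darkest window can sit anywhere in the pupil), in which case the seed is
used.

**Phase 2 — iris radius.** A second flood fill (tolerance 20/256 —
the pupil's 5/256 is too tight for iris texture; configurable) is seeded
half an expected radius left of the centre and a quarter radius above it
(horizontally adjacent to the pupil, above the interference band). Canny
edges of that region are kept where the gradient is within 15° of
horizontal (edge tangent near vertical — eyelids corrupt the top and
bottom arcs, the left/right arcs survive) and where the distance to the
centre lies in [0.8, 1.2]×expected_radius (default 240 px, the
acquisition zoom; configurable). The radius is the mean distance of the
surviving edge pixels.

**Phase 3 — ROI.** Pixels within 0.8·iris_radius of the centre,
strictly below the centre row, laterally within 0.8 of that inner
circle, at or above the region's mean brightness, and outside the pupil
mask.

**Phases 4–5 — colour compensation.** The iris colour is the mean RGB
inside the inner circle but outside the *geometric* inferior band
(with a 5 px margin — pixels that merely failed the ROI brightness
filter are still interference, not iris) and outside the pupil dilated
by 20 px (the refined mask hugs the pupil interior by ≈ 2.2·blur σ).
It is subtracted channel-wise, clamped at zero; a row-resolved variant
is available behind `per_pixel_iris`. The sclera then serves as an
in-scene white reference: the brightest 1 % of unsaturated pixels
outside the iris circle — selected on a σ = 8 smoothed brightness image,
because a top quantile of raw noisy brightness picks only the noise
upper tail of a homogeneous sclera and biases the reference — gives
per-channel gains `255/sclera_c`, applied multiplicatively
(von-Kries-style; an additive mode exists for sensitivity analysis).
Gains are estimated once per video on the first valid frame by default
(`gains_per_frame` re-estimates each frame). Subtraction strictly
precedes the gain, matching the phase order.

**Phase 6 — assignment and statistics.** Each corrected ROI pixel takes
the grid thickness whose table colour is nearest in Euclidean RGB
distance; exact ties go to the smaller thickness (conservative and
deterministic). Pixels with corrected brightness below 10/255 are
excluded as eyelash shadow before any statistics. Per frame: mean,
population SD, and a relative-frequency histogram over 0–240 nm in
10 nm bins. Per video: the pooled mean and population SD over all
assigned pixels of all frames (not the SD of frame means; recorded in
the output metadata). Visualization products: the ROI bounding box
resampled to a 50×50 grid by nearest-pixel sampling, and (RGB,
thickness) pairs pooled from three consecutive frames, every third
pixel in scan order.

## Synthetic data

The generator composites frames directly from a scene description and
never calls pipeline code, so tests against its labels are not
self-confirming. Defaults mirror the acquisition: 640×800 frames,
iris radius 240 px (480 px diameter), pupil radius 80 px, 30 fps,
75-frame windows. The stored colour of a band pixel is
`gains ⊙ (iris_color + table(d))`, the sclera is pure white before the
tint, iris texture is a seeded Gaussian brightness field anchored to the
eye (so it translates with it), blink frames are globally brightened by
+150, and per-channel sensor noise (σ = 2 by default, σ = 3 for the
"patient" presets) is added before 8-bit quantization. Illumination
gains default to (0.75, 0.73, 0.70), strictly below one so the white
sclera never saturates. Presets: `patient1/2/3` (uniform 45/70/95 nm —
the thin/intermediate/thick ordering of hyposecretory MGD, dry eye
without MGD, hypersecretory MGD), `blinky` (five 3-frame blink bursts),
`moving` (random-walk translation ≤ 10 px/frame with eyelid occluders
and eyelash streaks), `gradient` (40→110 nm toward the lower lid).

What it does **not** emulate: real iris crypts and vasculature, specular
highlights, motion blur, tear break-up dynamics, light irises, or
partial lid closures that darken rather than brighten the frame.
Passing tests therefore demonstrate the algorithm's correctness under
its stated model — segmentation robustness on clinical video has to be
judged on clinical video.

## Numerical and testing choices

- Window sums for the darkest-region search use integer prefix sums, so
  tie-breaking is exact. Flood fill is a thresholded mask plus one
  connected-component extraction (identical semantics to breadth-first
  search, against which it is tested).
- The end-to-end suites run at the full 640×800 / 75-frame scale; the
  whole test suite takes a few minutes on one CPU. Geometry unit tests
  use a quarter-scale scene (iris 60 px) for speed.
- Noise tolerance of the colour inversion depends on the local speed of
  the colour curve: ≈ 2.6 RGB units/nm near 45 nm but ≈ 1.3 near 70 nm,
  so σ = 2 channel noise keeps ≥ 95 % of pixels within ±2 nm at 45 nm
  and within ±3 nm at 70 nm (oracle-derived bounds frozen in the tests).
- The gradient-surface trend is asserted on 5-row block means of the
  50×50 grid: individual rows hold few noisy pixels and jitter ±1 nm on
  a 1.4 nm/row gradient, while the claim under test is the spatial
  trend.
- Degenerate inputs: constant-brightness videos keep all frames; an eye
  centre on the bottom image row yields an empty ROI and the frame is
  rejected; an all-dark ROI (every pixel below the shadow floor) is an
  error rather than a zero-thickness reading.

## Known limitations

- The brightness-threshold blink rule cannot detect partial occlusions
  that do not brighten the frame; those frames are only caught if the
  geometry fails.
- The iris-colour subtraction uses one mean colour (or a row-resolved
  variant); strong iris texture leaks into the thickness map as noise.
- Absolute brightness calibration between the theoretical table and
  camera counts relies on the sclera-as-white assumption; a tinted or
  vascularized sclera biases all thicknesses together.
- Thickness is reported on the 0–240 nm grid only; films outside this
  range alias back into it via the periodicity of interference colours.
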