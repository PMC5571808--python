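# Methods

This note records the models, conventions, numerical choices and known
limitations behind `scatterheal`, at the level a maintainer or a careful
user needs. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Geometry and remeshing

Detector arrays are indexed `[row, col]` with rows increasing downward; the
beam center is given as `(x, y) = (col, row)`, 0-based and fractional, and
may lie outside the frame. The azimuth χ is measured counter-clockwise from
the +x axis as seen from the sample, so χ = 90° points toward decreasing
row index ("physics up"). These conventions must be fixed somewhere for
point-symmetry copying to be deterministic; they are this package's choice.

Uncalibrated, the radial coordinate is the pixel distance r from the beam
center (q is proportional to r in the small-angle limit, which is all the
workflow needs — any monotone radial coordinate works). With a calibration
(sample–detector distance, pixel size, wavelength λ in Å),
q = (4π/λ)·sin(θ/2) with θ = atan(r·pix/dist), in Å⁻¹.

**Forward remesh** (detector → polar) is mask-exact bin averaging with
pixel splitting: each valid pixel is sampled at 2×2 sub-pixel positions and
each sample's intensity share is distributed bilinearly over the four polar
cells surrounding its (q, χ). Weights per pixel sum to 1, so summed
intensity is conserved exactly and masked pixels are excluded exactly.
Plain nearest-bin assignment was rejected: on steep ring slopes the sub-bin
radial positions of the pixels alias into several-percent cell ripple, and
— because the square pixel lattice is invariant under 90° rotations about
its symmetry points — that ripple can carry an exactly fourfold signature
that poisons symmetry analysis. The 2×2 footprint sampling additionally
removes a residual bias on the lattice diagonals.

**Inverse remesh** (polar → detector) interpolates linearly in χ (wrapped
across 360°→0°) and with a Catmull–Rom cubic in q, clamped to constant
continuation past the first/last bin center. A bilinear inverse would stack
a second triangle kernel on the forward low-pass and visibly blunt ring
slopes. With these choices the cartesian→polar→cartesian roundtrip error on
a smooth Gaussian ring (radial σ = 6 px, 1° χ bins) is ≈ 1.1% at maximum
(≈ 2% at σ = 4 px); the acceptance script measures it.

Defaults: `n_chi = 360` (1° bins — fine enough for sharp peaks at the edge
of typical frames; the method is sensitive to this resolution, so it is
configurable) and `n_q = ceil(max valid radius)` (≈ 1 px bins).

## Anisotropy statistic and classification

Per q row, `ratio = mean(local std in 7.5° windows) / global std`, with all
standard deviations population (÷N) over covered bins only. Two numerical
points matter:

* **Small-sample bias.** A 7.5° window holds at most 7–8 covered bins, and
  sparsely covered rows far fewer. The raw standard deviation of n iid
  normal samples underestimates σ by the factor
  √(2/n)·Γ(n/2)/Γ((n−1)/2) (≈ 0.72 at n = 3), so without correction the
  ratio of an unstructured row sits at 0.6–0.9 and isotropic images sprout
  spurious anisotropic ranges. Every window std (and the global std) is
  divided by its expected bias factor, which re-centers the iid ratio on 1.
* **Degenerate rows.** If the global std is below 10⁻⁹ of the row mean the
  row is constant and the ratio is defined as 1.

Rows with ratio < 0.8 are anisotropic; maximal runs of ≥ 2 such rows form
the anisotropic q ranges. Three eligibility guards apply to flagging (not
to the pooled histograms): a row needs ≥ 0.75 pixel of weight per covered
χ bin (below ~1 pixel per bin, pixel splitting makes neighboring cells
share pixels, the curve becomes artificially smooth and isotropic rows read
anisotropic), ≥ 25% χ coverage (the statistic is meaningless on near-empty
rows), and an azimuthal coefficient of variation ≥ 2%. The last guard
exists because the ratio is scale-invariant: on noise-free synthetic images
the percent-level regridding ripple on ring slopes is otherwise
indistinguishable from structure; 2% matches the regridding fidelity
itself, and variation below the remesh error scale cannot be healed
meaningfully anyway. All three are configurable.

The pooled histograms (30 bins spanning min→max) of the ratio and of
σ_glob are fitted by unweighted least squares on normalized frequencies to
λᵏe^(−λ)/k! over bin indices k (λ continuous via the Γ function). The SSE
landscape is multimodal — for bottom-heavy histograms there is a plateau at
large λ where the pmf underflows over all 30 bins — so the fit is a coarse
grid search followed by bounded local refinement. A degenerate histogram
(max = min) is a single spike: λ = 0, `rel_center` defined as 0.5.

Classification tree (all thresholds configurable):

* `λ_ratio ≥ 0.8` → background isotropic. Then `rel_center(σ) < 0.08` →
  **iso background + peaks** (sharp peaks stretch the σ span by orders of
  magnitude, collapsing the bulk into the lowest bins), else **isotropic**
  (with photon noise the σ values cluster around the noise floor and the
  fitted center rides mid-span).
* `λ_ratio < 0.8` → background anisotropic. Then `rel_center(σ) ≥ 0.7` →
  **diffuse** (smooth halos spread σ broadly up to their own maximum and
  the fit rides the top of the span), else **complex** (sharp features
  stretch the span, compressing the diffuse bulk to mid-range).

The 0.8 per-row threshold is the one well-established value; the histogram
thresholds 0.08 and 0.7 were calibrated once on the synthetic archetype
battery (measured separations: isotropic 0.11–1.0 vs peaks ≤ 0.035;
diffuse 1.0 vs complex 0.40–0.51, stable across seeds) and there is no
claim they are universal — real-beamline use should expect to tune them.
Note the diffuse/complex comparison direction follows the measured behavior
of this statistic on the generator battery.

## Symmetry estimation

Candidates are even folds (point symmetry of the small-angle cut makes odd
folds unphysical), by default {2, 4, 6, 8, 10, 12}; `n_chi` must be
divisible by every candidate so copy shifts are whole bins.

A band's 1D χ profile is the q-average of its rows, each row first
normalized by its own circular average and the result rescaled to the band
mean. The normalization is essential under masking: a χ bin whose covered
rows happen to sample the radial peak center reads systematically higher
than one sampling the tails, and that coverage-subset jitter — which is not
point-symmetric — can reach a large fraction of the band variance.

Scoring a fold n: reshape the profile into n copies of the 360/n period.
`overlap` = fraction of period cells where ≥ 2 copies carry data (the
relative amount of measured data actually averaged when building the
model); `residual` = leave-one-copy-out mean squared error, each measured
sample compared against the mean of the *other* covered copies at its
period cell. The leave-one-out form matters under noise: a model containing
the sample itself retains the sample's own noise and systematically favors
low folds, whereas cross-validation rewards the fold that averages the most
consistent data. Then δ(n) = residual/(N_data·overlap^α), infinite at zero
overlap. α defaults to 0.5 (a mild bias toward high-overlap folds;
configurable — noisy data may need a stronger bias).

Selection: fold 2 is structurally exact for every even-fold pattern, so its
residual is a data-driven estimate of the measurement-error floor (noise
plus regridding ripple). All candidates whose residual is within 3× that
floor are indistinguishable from the data's own error and count as tied;
the tie goes to the largest such fold — the highest symmetry consistent
with the data. When no candidate reaches the floor, smallest δ wins.
Residuals below 10⁻¹² of the band's mean square are snapped to zero so that
exact ties (noise-free divisor folds) resolve deterministically. Bands with
< 25% χ coverage raise an error (the caller falls back to point-symmetry +
circular-average filling); if no candidate has any overlap, fold 2 is
returned as the point-symmetry minimum.

The fill model (as opposed to the scoring model) averages **all** covered
copies, with no smoothing, and is exactly n-fold periodic by construction.
For ordered patterns the fold is estimated from the *original* coverage,
before the point-symmetry copy: the 180° copies are duplicated data and
would hand fold 2 an artificial zero-residual tie.

## Healing branches

* **Isotropic:** every gap takes the circular average of its row; rows with
  no coverage at all (e.g. fully behind the beamstop) take the linear
  interpolation of the profile across q, clamped at the ends.
* **Ordered:** point-symmetry copy first (measured data are never averaged
  or overwritten — a gap at (q, χ) takes I(q, χ+180°) only if it is
  measured); then per flagged band, remaining gaps take the n-fold model;
  circular average for whatever is left.
* **Diffuse:** per band, the n-fold model is built as a (rows × period)
  grid; its remaining holes are closed by an iterative local-mean filter
  (undefined cells adjacent to defined ones become the mean of their
  defined 8-neighbors, χ-wrapped across the period boundary, iterated to
  completion with a cap of 2×max(grid dims); one final 3×3 local-mean
  smoothing pass then runs over the whole model — the filter both extends
  and smooths, but only the *model*; measured cells in the output are
  untouched). The filled model is tiled over χ into the gaps.
* **Complex:** the image is separated into components. Gaps are pre-filled
  with the circular average solely to complete the matrix; each q row is
  then median-filtered along χ (60° window, wrapped) and the rank-2 SVD
  reconstruction of that matrix is the background estimate. The median
  prefilter exists because a peak set along a ring is a nearly separable
  radial × azimuthal product — close to rank one — so a strong peak ring
  can capture a leading singular component and disappear from the
  variation map; suppressing localized spikes first keeps the low-rank
  estimate a true background. The variation map is original/background
  (division rather than subtraction, since shot noise scales with
  intensity), with the background floored at 10⁻⁶ of the image maximum;
  the peak mask thresholds it per q row at median + 3×MAD (MAD floored at
  10⁻³ of the row median so constant rows stay empty), dilated by one cell
  with χ wrap. The background (coverage minus peak cells) is healed with
  the diffuse branch, the peak component (original − healed background,
  floored at 0) with the ordered branch, and the two are summed into the
  gaps.

Every branch restores measured cells bit-identically, the final healed
frame is clipped at 0, and per-pixel provenance labels record the
inference: measured / symmetry_filled / interpolated / circavg_filled /
model_extended. A masked pixel that happens to fall in a polar cell
containing other measured pixels is labelled `interpolated` (its value is
the interpolation of measured cells), never `measured`.

## Extension

Tails of the circular average are fitted on the innermost/outermost 15% of
valid points (minimum 10) with two forms, by least squares in log
intensity: power law + constant a·q^(−p) + b (p ∈ [0, 12], a, b ≥ 0; the
Guinier form is a closed-form linear regression of log I on q²). The form
with the smaller mean squared log-residual wins; above 0.05 the side is
marked unreliable and extension clamps to constant continuation. The tail
forms are this package's choice of the canonical small-angle limits;
additional forms can be plugged in.

Extended q rows take the tail prediction; if a flagged anisotropic band
reaches the measured boundary (within 3 rows), the mean χ profile of its
last 5 rows, normalized to unit mean, multiplies the prediction so angular
structure follows the fitted decay. Everything beyond the measured span or
outside the original frame is labelled `model_extended`, and the report
carries an explicit warning: extended regions are model-dependent and must
not be used for quantitative fitting.

## Synthetic scenes and what the tests do (and do not) show

The generator sums separable contributions — Gaussian rings, cosine-
modulated diffuse halos, n-fold periodic Gaussian peak sets, constant +
power-law background — with optional Poisson noise (an exposure scale
multiplies the clean image before sampling; unit exposure makes intensities
counts). Masks compose a beamstop disc + arm, inter-module gap bands,
seeded random bad pixels, streaks and hold-out rectangles. Everything is
bit-reproducible from the spec + seed, and per-feature component images
are returned for oracle comparisons.

Study conditions used throughout validation: 512×512 frames, 1° χ bins,
background ~40–90 counts, peak amplitudes 110–450 counts (the
symmetry-recovery grid's noisy arm uses amplitude 110 on background 40,
i.e. peak SNR = A/√(A+bg) ≈ 10), standard beamstop/gap/bad-pixel mask, and
a beam center a few pixels off the frame center. The off-grid center is
deliberate: a beam center exactly on the pixel-lattice symmetry point — a
measure-zero condition in the laboratory — makes the remesh ripple exactly
fourfold symmetric and would bias fold selection. The archetype battery
(≥ 5 parameter variants per category) uses Poisson noise at unit exposure;
the noise floor is in fact load-bearing for classification, since the
"balanced" σ histogram of an isotropic image is a noise-floor phenomenon.

What passing these tests does **not** show: real detector frames have
non-separable peak shapes, polarization and solid-angle intensity
variation, structured backgrounds from windows and air scatter, detector
point-spread and flat-field structure, and wide-angle patterns that break
point symmetry through Ewald-sphere curvature. None of these are simulated;
the classifier thresholds in particular should be re-tuned on real data.
Grazing-incidence distortions and non-centrosymmetric WAXS are explicitly
out of scope.

## Limitations

* The χ resolution is a real sensitivity: too coarse blurs sharp edge
  peaks, too fine wastes time and starves rows of pixels. The defaults suit
  ~0.5–4 megapixel frames.
* Fold candidates stop at 12 by default; genuinely higher symmetries are
  reported as a divisor (or as 12).
* Bands are scored as q-averaged 1D profiles; features whose symmetry
  *changes within* a flagged band get a single fold. Merged adjacent bands
  (two peak rings bridged by low-ratio rows) can likewise receive a
  compromise fold — gap filling remains protected by the point-symmetry
  step, which is exact for any even-fold pattern.
* Extension is visualization-grade by design.
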