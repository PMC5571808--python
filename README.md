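# scatterheal

Physics-aware healing ("inpainting") and extension of 2D X-ray scattering
detector images.

Area-detector frames from SAXS/WAXS beamlines always contain gaps: the
beamstop and its arm, inter-module gaps of tiled photon-counting detectors,
bad pixels, parasitic streaks and geometry shadows. These regions are
masked, but many downstream tools — correlation analysis, convolutions,
machine-learning pipelines — are not mask-aware, and naive inpainting
ignores the structure of scattering data (rings arc around the beam center;
a peak bisected by a gap is not recovered by interpolating its shoulders).
`scatterheal` fills gaps in a way that respects scattering physics:
centro-symmetry of the small-angle pattern, azimuthal *n*-fold symmetry of
ordered features, and radial continuity. It is a library for beamline
scientists and scattering-data pipeline authors, with a thin `scatterheal`
command-line tool on top.

## Method

All healing happens on a regular polar grid $I(q, \chi)$, where $q$ is the
scattering-vector magnitude (or simply the radial pixel distance when no
geometry calibration is given) and $\chi$ the azimuth.

1. **Structural identification.** For every $q$ row the azimuthal curve
   $I(\chi)$ is summarized by $r_q = \overline{\sigma_{\rm loc}} /
   \sigma_{\rm glob}$, the mean of local standard deviations (7.5°
   windows) over the global standard deviation. Smooth angular structure
   pulls $r_q$ well below 1; $r_q < 0.8$ flags the row as anisotropic.
   Histograms of $r_q$ and $\sigma_{\rm glob}$ pooled over $q$ are fitted
   with a Poisson mass function $f(k) = \lambda^k e^{-\lambda}/k!$ (the
   $\lambda$ center is robust to the heavy skew of these distributions),
   and a two-level decision tree classifies the image as *isotropic*,
   *isotropic background + peaks*, *diffuse anisotropic* or *complex*.
2. **Symmetry estimation.** For each anisotropic $q$ band, candidate even
   folds $n \in \{2,4,\dots,12\}$ are scored by building the $n$-fold model
   (average of the $n$ shifted copies of the measured curve) and
   cross-validating every sample against the other copies:
   $\delta(n) = \mathrm{residual}(n) / (N_{\rm data}\cdot
   \mathrm{overlap}^{\alpha})$, where *overlap* is the fraction of the
   period where at least two copies were averaged. The highest fold whose
   residual sits at the measurement-error floor is selected — any 6-fold
   pattern is also 2-fold, but the highest consistent symmetry is the
   informative one.
3. **Healing branches.** Isotropic gaps take the circular average $I(q)$;
   ordered patterns are filled by point-symmetry copy then the $n$-fold
   model; diffuse patterns additionally close model gaps with an iterative
   local-mean filter before tiling the model over $\chi$; complex patterns
   are first separated into a diffuse background (rank-2 SVD estimate, with
   sharp cells excluded via a variation-map peak mask) and a peak component,
   healed independently and summed.
4. **Extension.** Beyond the measured $q$ span the circular average's tails
   are fitted with canonical small-angle forms — $I(q) = a q^{-p} + b$ or
   Guinier-like $I(q) = I_0 \exp(-q^2 R_g^2/3)$ — and the better model
   continues the pattern outward (scaled by the boundary band's angular
   profile where the edge is anisotropic).

Measured pixels are never modified, and every output pixel carries a
provenance label (`measured`, `symmetry_filled`, `interpolated`,
`circavg_filled`, `model_extended`), so healed frames can always be
distinguished from data.

## Worked example

Heal a synthetic "complex" frame (twofold diffuse halo + two orders of a
fourfold peak array, Poisson noise, beamstop/gap/bad-pixel mask, plus
hold-out rectangles deliberately masking whole peaks):

```bash
python examples/heal_image.py
```

```
category: complex
  band q-bins [17, 285] (background): fold 2
  ...
fill fractions by provenance:
  measured          0.888
  symmetry_filled   0.075
  interpolated      0.032
  circavg_filled    0.006
held-out region (17519 px): Pearson r = 0.9995, median relative error = 1.28%
```

The classifier routed the image to the complex branch, the background's
twofold orientation was detected, 11% of the frame was filled in, and the
deliberately masked peaks were reconstructed from their symmetry mates to
about one percent (r ≈ 1 against the noise-free ground truth).

Symmetry detection alone (`python examples/detect_symmetry.py`), on a noisy
sixfold peak ring:

```
  n= 2  residual=     8.066  overlap=0.994  delta=0.02253
  n= 4  residual=     693.9  overlap=1.000  delta=1.933
  n= 6  residual=     6.514  overlap=1.000  delta=0.01815
  ...
selected fold: 6
```

Folds 2 and 6 both fit (a sixfold pattern is twofold), the mismatched folds
are two orders of magnitude worse, and the selection takes the highest
consistent fold. The other examples cover scene simulation, structural
classification and image extension.

The same pipeline runs from a shell:

```bash
scatterheal heal --image frame.tif --mask mask.tif --center 250.3,261.7 \
    --out healed
scatterheal synth --archetype complex_0 --out demo
```

writing the healed float32 TIFF, the 8-bit provenance map and a JSON report
(category, per-band symmetry tables, fill fractions, effective config).

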