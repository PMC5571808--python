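"""Gap filling ("healing") of masked polar cells, branch per image category.

Measured data are sacred: every branch only writes into uncovered cells, and
the final detector-space composite restores the original pixel values
bit-exactly wherever the input mask was valid. Each filled cell carries a
provenance label recording how its value was inferred:

====================  =====================================================
label                 meaning
====================  =====================================================
MEASURED (0)          valid pixel of the input image
SYMMETRY_FILLED (1)   copied/averaged from symmetry mates (180 deg or n-fold)
INTERPOLATED (2)      iterative local-mean interpolation inside a fold model
CIRCAVG_FILLED (3)    per-q circular average (the 1D scattering curve)
MODEL_EXTENDED (4)    outside the measured q-span; from a fitted tail model
====================  =====================================================

Branches:

* isotropic        - every gap becomes the circular average at its q;
* ordered          - point-symmetry copy, then per anisotropic q-band an
                     n-fold model fill, circular average for the rest;
* diffuse          - per-band n-fold model, remaining model gaps closed by an
                     iterative local-mean filter, model tiled over chi;
* complex          - rank-2 SVD background + variation-map peak mask separate
                     the image into diffuse and sharp components, healed with
                     the diffuse and ordered branches respectively and summed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from . import metrics as _metrics
from .config import RunConfig
from .geometry import (
    DetectorImage,
    PolarImage,
    polar_bin_indices,
    remesh_to_cartesian,
    remesh_to_polar,
)
from .metrics import ImageCategory, StructureSignature
from .symmetry import (
    FoldModel,
    InsufficientCoverageError,
    build_fold_model,
    estimate_symmetry,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MEASURED",
    "SYMMETRY_FILLED",
    "INTERPOLATED",
    "CIRCAVG_FILLED",
    "MODEL_EXTENDED",
    "PROVENANCE_LABELS",
    "HealedResult",
    "circular_average",
    "fill_isotropic",
    "point_symmetry_fill",
    "heal_ordered",
    "iterative_local_mean_fill",
    "heal_diffuse",
    "lowrank_background",
    "variation_map",
    "make_peak_mask",
    "heal_complex",
    "heal",
]

MEASURED = 0
SYMMETRY_FILLED = 1
INTERPOLATED = 2
CIRCAVG_FILLED = 3
MODEL_EXTENDED = 4

PROVENANCE_LABELS = {
    MEASURED: "measured",
    SYMMETRY_FILLED: "symmetry_filled",
    INTERPOLATED: "interpolated",
    CIRCAVG_FILLED: "circavg_filled",
    MODEL_EXTENDED: "model_extended",
}

#: sentinel for polar cells whose provenance is not yet assigned
_UNSET = 255


@dataclass
class HealedResult:
    """Healed detector image plus everything computed along the way."""

    healed: np.ndarray
    provenance: np.ndarray  # uint8 labels, detector space
    category: ImageCategory
    signature: StructureSignature
    polar: PolarImage  # input polar image (with gaps)
    polar_healed: PolarImage  # fully filled polar image
    polar_provenance: np.ndarray
    config: RunConfig
    image: DetectorImage
    band_folds: List[dict] = field(default_factory=list)

    def fill_fractions(self) -> dict:
        """Fraction of detector pixels per provenance label."""
        total = self.provenance.size
        return {
            name: float((self.provenance == code).sum()) / total
            for code, name in PROVENANCE_LABELS.items()
        }


# ---------------------------------------------------------------------------
# isotropic branch


def circular_average(pol: PolarImage) -> np.ndarray:
    """I(q): mean over covered chi cells per q row; NaN flags empty rows."""
    cnt = pol.coverage.sum(axis=1)
    s = np.where(pol.coverage, pol.values, 0.0).sum(axis=1)
    prof = np.full(pol.n_q, np.nan)
    ok = cnt > 0
    prof[ok] = s[ok] / cnt[ok]
    return prof


def _complete_profile(profile: np.ndarray, q_centers: np.ndarray) -> np.ndarray:
    """Interpolate NaN rows of an I(q) profile linearly in q (clamped ends)."""
    ok = np.isfinite(profile)
    if not ok.any():
        raise ValueError("no q row has any coverage")
    if ok.all():
        return profile
    return np.interp(q_centers, q_centers[ok], profile[ok])


def fill_isotropic(
    pol: PolarImage,
    values: Optional[np.ndarray] = None,
    coverage: Optional[np.ndarray] = None,
) -> Tuple[PolarImage, np.ndarray]:
    """Fill every uncovered cell with the circular average at its q.

    Rows without any coverage (e.g. fully behind the beamstop) take the
    linear interpolation of the profile across q. Covered cells untouched.
    """
    out = pol.copy()
    if values is not None:
        out.values = values.copy()
    if coverage is not None:
        out.coverage = coverage.copy()
    prov = np.full(out.values.shape, _UNSET, dtype=np.uint8)
    prov[out.coverage] = MEASURED

    prof = circular_average(out)
    prof = _complete_profile(prof, out.q_centers)
    gaps = ~out.coverage
    out.values[gaps] = np.broadcast_to(prof[:, None], out.values.shape)[gaps]
    prov[gaps] = CIRCAVG_FILLED
    out.coverage[:] = True
    return out, prov


# ---------------------------------------------------------------------------
# ordered branch


def point_symmetry_fill(pol: PolarImage) -> Tuple[PolarImage, np.ndarray]:
    """Copy I(q, chi+180) into gaps at (q, chi).

    Cells where both mates are covered are untouched (measured data are never
    averaged away); cells where neither is covered stay uncovered.
    """
    if pol.n_chi % 2 != 0:
        raise ValueError("point-symmetry fill needs an even chi bin count")
    out = pol.copy()
    prov = np.full(out.values.shape, _UNSET, dtype=np.uint8)
    prov[out.coverage] = MEASURED

    half = out.n_chi // 2
    mate_v = np.roll(out.values, half, axis=1)
    mate_c = np.roll(out.coverage, half, axis=1)
    fillable = ~out.coverage & mate_c
    out.values[fillable] = mate_v[fillable]
    out.coverage |= fillable
    prov[fillable] = SYMMETRY_FILLED
    return out, prov


def _band_profile(
    values: np.ndarray, coverage: np.ndarray, lo: int, hi: int
) -> Tuple[np.ndarray, np.ndarray]:
    """q-averaged chi profile of rows lo..hi (inclusive).

    Each row is normalized by its own circular average before averaging
    across q, then the profile is rescaled to the band's mean intensity.
    Without this, a chi bin whose covered rows happen to sit near the radial
    peak center reads systematically higher than one sampling the radial
    tails, and that coverage-subset jitter (which need not be symmetric)
    drowns the azimuthal structure the profile is meant to expose.
    """
    v = values[lo : hi + 1]
    c = coverage[lo : hi + 1]
    row_mean = np.array([r[m].mean() if m.any() else 0.0 for r, m in zip(v, c)])
    usable = row_mean > 0
    v = v[usable]
    c = c[usable]
    row_mean = row_mean[usable]
    cnt = c.sum(axis=0)
    cov = cnt > 0
    prof = np.zeros(values.shape[1])
    if usable.any():
        vn = np.where(c, v, 0.0) / row_mean[:, None]
        prof[cov] = vn.sum(axis=0)[cov] / cnt[cov] * float(row_mean.mean())
    return prof, cov


def heal_ordered(
    pol: PolarImage,
    ranges: Sequence[Tuple[int, int]],
    alpha: float = 0.5,
    candidates: Sequence[int] = (2, 4, 6, 8, 10, 12),
) -> Tuple[PolarImage, np.ndarray, List[dict]]:
    """Heal an image with sharp anisotropic features on an isotropic background.

    Pipeline: point-symmetry copy; then for each flagged anisotropic q-band,
    estimate the fold on the band's q-averaged chi profile and fill remaining
    band gaps row by row from the n-fold model; finally circular-average fill
    for anything left. Bands with too little coverage fall back to the
    point-symmetry + circular-average route.
    """
    out, prov = point_symmetry_fill(pol)
    tables: List[dict] = []

    for lo, hi in ranges:
        # estimate the fold from the ORIGINAL coverage: the point-symmetry
        # copies are duplicated data and would hand n=2 an artificial
        # zero-residual tie against every true higher symmetry
        prof, cov = _band_profile(pol.values, pol.coverage, lo, hi)
        try:
            n, scores = estimate_symmetry(prof, cov, candidates=candidates, alpha=alpha)
        except InsufficientCoverageError as exc:
            logger.info("band q-bins %d-%d: %s; falling back to circular average", lo, hi, exc)
            tables.append({"q_range": [lo, hi], "fold": None, "scores": [], "error": str(exc)})
            continue
        tables.append(
            {"q_range": [int(lo), int(hi)], "fold": int(n), "scores": [s.to_dict() for s in scores]}
        )
        for i in range(lo, hi + 1):
            row_cov = out.coverage[i]
            if row_cov.all() or not row_cov.any():
                continue
            fm = build_fold_model(out.values[i], row_cov, n)
            model = fm.full_values
            fillable = ~row_cov & fm.full_coverage
            out.values[i, fillable] = model[fillable]
            out.coverage[i] |= fillable
            prov[i, fillable] = SYMMETRY_FILLED

    filled, prov_iso = fill_isotropic(out)
    prov[prov == _UNSET] = prov_iso[prov == _UNSET]
    return filled, prov, tables


# ---------------------------------------------------------------------------
# diffuse branch


def _box_sums(vals: np.ndarray, defined: np.ndarray, wrap_chi: bool) -> Tuple[np.ndarray, np.ndarray]:
    """3x3 sums of defined values and of the defined indicator.

    The chi axis (axis 1) wraps; the q axis does not (missing neighbors simply
    do not contribute).
    """
    v = np.where(defined, vals, 0.0)
    d = defined.astype(float)
    mode = "wrap" if wrap_chi else "constant"
    vp = np.pad(np.pad(v, ((1, 1), (0, 0))), ((0, 0), (1, 1)), mode=mode)
    dp = np.pad(np.pad(d, ((1, 1), (0, 0))), ((0, 0), (1, 1)), mode=mode)
    sv = np.zeros_like(v)
    sd = np.zeros_like(d)
    for di in range(3):
        for dj in range(3):
            sv += vp[di : di + v.shape[0], dj : dj + v.shape[1]]
            sd += dp[di : di + v.shape[0], dj : dj + v.shape[1]]
    return sv, sd


def iterative_local_mean_fill(
    values: np.ndarray,
    defined: np.ndarray,
    max_iter: Optional[int] = None,
    wrap_chi: bool = True,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grow defined regions into gaps with an iterative local-mean filter.

    At each iteration every undefined cell that touches (8-neighborhood,
    chi-wrapped) at least one defined cell becomes the mean of its defined
    neighbors. Once no undefined cells remain (or ``max_iter`` is hit) a
    single local-mean smoothing pass runs over the whole grid - the filter
    both extends the data into gaps and smooths the model it operates on.
    Cells still undefined afterwards are reported for circular-average
    fallback.

    Returns ``(filled_values, defined_after, was_gap)`` where ``was_gap``
    marks the cells that were filled (or remain undefined).
    """
    vals = np.asarray(values, dtype=float).copy()
    d = np.asarray(defined, dtype=bool).copy()
    was_gap = ~d
    if not d.any():
        raise ValueError("need at least one defined cell")
    if max_iter is None:
        max_iter = 2 * max(vals.shape)

    for _ in range(max_iter):
        if d.all():
            break
        sv, sd = _box_sums(vals, d, wrap_chi)
        grow = ~d & (sd > 0)
        if not grow.any():
            break
        vals[grow] = sv[grow] / sd[grow]
        d |= grow

    # final smoothing pass over the (model) grid
    sv, sd = _box_sums(vals, d, wrap_chi)
    smooth = d & (sd > 0)
    vals[smooth] = sv[smooth] / sd[smooth]
    return vals, d, was_gap


def heal_diffuse(
    pol: PolarImage,
    ranges: Sequence[Tuple[int, int]],
    alpha: float = 0.5,
    candidates: Sequence[int] = (2, 4, 6, 8, 10, 12),
    max_iter: Optional[int] = None,
) -> Tuple[PolarImage, np.ndarray, List[dict]]:
    """Heal anisotropic diffuse scattering via n-fold models plus interpolation.

    For each anisotropic q-band: estimate the fold, average the band's data
    into a (q x period) model, close the model's remaining gaps with the
    iterative local-mean filter (wrapping across the period boundary, since
    the model tiles), then tile the model over chi to fill uncovered band
    cells. Isotropic rows and leftovers get the circular average.
    """
    out = pol.copy()
    prov = np.full(out.values.shape, _UNSET, dtype=np.uint8)
    prov[out.coverage] = MEASURED
    tables: List[dict] = []

    for lo, hi in ranges:
        prof, cov = _band_profile(out.values, out.coverage, lo, hi)
        try:
            n, scores = estimate_symmetry(prof, cov, candidates=candidates, alpha=alpha)
        except InsufficientCoverageError as exc:
            logger.info("band q-bins %d-%d: %s; falling back", lo, hi, exc)
            tables.append({"q_range": [lo, hi], "fold": None, "scores": [], "error": str(exc)})
            continue
        tables.append(
            {"q_range": [int(lo), int(hi)], "fold": int(n), "scores": [s.to_dict() for s in scores]}
        )

        rows = range(lo, hi + 1)
        p = out.n_chi // n
        model = np.full((len(rows), p), np.nan)
        mcov = np.zeros((len(rows), p), dtype=bool)
        for k, i in enumerate(rows):
            if not out.coverage[i].any():
                continue
            fm = build_fold_model(out.values[i], out.coverage[i], n)
            model[k] = fm.period_values
            mcov[k] = fm.period_coverage

        if mcov.any():
            filled_model, mdef, gap_cells = iterative_local_mean_fill(
                model, mcov, max_iter=max_iter, wrap_chi=True
            )
            full_model = np.tile(filled_model, (1, n))
            full_def = np.tile(mdef, (1, n))
            full_gap = np.tile(gap_cells, (1, n))
            for k, i in enumerate(rows):
                fillable = ~out.coverage[i] & full_def[k]
                out.values[i, fillable] = full_model[k, fillable]
                out.coverage[i] |= fillable
                lab = np.where(full_gap[k], INTERPOLATED, SYMMETRY_FILLED).astype(np.uint8)
                prov[i, fillable] = lab[fillable]

    filled, prov_iso = fill_isotropic(out)
    prov[prov == _UNSET] = prov_iso[prov == _UNSET]
    return filled, prov, tables


# ---------------------------------------------------------------------------
# complex branch


def lowrank_background(values: np.ndarray, rank: int = 2) -> np.ndarray:
    """Rank-``rank`` SVD reconstruction of a complete (q x chi) matrix.

    The input must contain no undefined sentinels; gaps are pre-filled with
    the per-q circular average by the caller (the pre-fill is used for the
    decomposition only and never written to output). By the Eckart-Young
    theorem the reconstruction is the best rank-``rank`` approximation in the
    Frobenius norm; its error equals the root sum of squares of the discarded
    singular values.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("lowrank_background requires a fully defined matrix")
    if rank > min(values.shape):
        raise ValueError("rank exceeds matrix dimensions")
    u, s, vt = np.linalg.svd(values, full_matrices=False)
    return (u[:, :rank] * s[:rank]) @ vt[:rank]


def variation_map(
    pol: PolarImage,
    background: np.ndarray,
    floor_rel: float = 1e-6,
) -> np.ndarray:
    """Original / low-rank background, on covered cells; NaN elsewhere.

    Dividing (rather than subtracting) highlights sharp local deviations
    uniformly across intensity scales, since shot noise grows with intensity.
    The background is floored at ``floor_rel`` times the image maximum to
    keep the division finite.
    """
    floor = floor_rel * float(np.nanmax(np.abs(pol.values))) if pol.coverage.any() else floor_rel
    bg = np.maximum(background, max(floor, 1e-300))
    out = np.full(pol.values.shape, np.nan)
    out[pol.coverage] = pol.values[pol.coverage] / bg[pol.coverage]
    return out


def make_peak_mask(
    vmap: np.ndarray,
    k_mad: float = 3.0,
    dilate: int = 1,
) -> np.ndarray:
    """Threshold the variation map per q row at median + k_mad * MAD.

    The MAD is floored at 1e-3 times the row median so that constant rows
    (variation identically 1) produce an empty mask. The binary mask is
    dilated by ``dilate`` cells with chi wrap-around. Uncovered cells are 0.
    """
    vmap = np.asarray(vmap, dtype=float)
    mask = np.zeros(vmap.shape, dtype=bool)
    for i in range(vmap.shape[0]):
        row = vmap[i]
        ok = np.isfinite(row)
        if ok.sum() < 3:
            continue
        med = float(np.median(row[ok]))
        mad = float(np.median(np.abs(row[ok] - med)))
        mad = max(mad, 1e-3 * abs(med))
        if mad <= 0:
            continue
        mask[i, ok] = row[ok] > med + k_mad * mad
    if dilate > 0 and mask.any():
        padded = np.pad(mask, ((0, 0), (dilate, dilate)), mode="wrap")
        padded = ndimage.binary_dilation(padded, iterations=dilate)
        mask = padded[:, dilate:-dilate]
    return mask


def heal_complex(
    pol: PolarImage,
    alpha: float = 0.5,
    candidates: Sequence[int] = (2, 4, 6, 8, 10, 12),
    svd_rank: int = 2,
    k_mad: float = 3.0,
    dilate: int = 1,
    window_deg: float = 7.5,
    ratio_threshold: float = 0.8,
    min_run: int = 2,
    max_iter: Optional[int] = None,
    peak_filter_deg: float = 60.0,
) -> Tuple[PolarImage, np.ndarray, List[dict]]:
    """Heal a pattern with both structured background and sharp features.

    The image is split into a diffuse background (rank-2 SVD estimate,
    localized sharp cells excluded via the variation-map peak mask) and a
    sharp peak component (original minus healed background, floored at 0).
    The background is healed with the diffuse branch, the peak component with
    the ordered branch, and the two healed components are summed into the
    gaps. Measured cells are restored bit-identically.

    Before the SVD, each q row is median-filtered along chi over
    ``peak_filter_deg`` (wrapped). A set of sharp peaks along a ring is a
    nearly separable (radial x azimuthal) product, i.e. close to rank one,
    so a strong peak ring can capture a leading singular component and
    vanish from the variation map; the median prefilter suppresses localized
    spikes while preserving smooth azimuthal modulation, keeping the
    low-rank estimate a true background.
    """
    # (1) background estimate and peak mask
    prefilled, _ = fill_isotropic(pol)
    win = max(int(round(peak_filter_deg / (360.0 / pol.n_chi))) | 1, 3)
    smoothed = ndimage.median_filter(prefilled.values, size=(1, win), mode="wrap")
    bg_lowrank = lowrank_background(smoothed, rank=svd_rank)
    vmap = variation_map(pol, bg_lowrank)
    peak_mask = make_peak_mask(vmap, k_mad=k_mad, dilate=dilate)

    # (2) heal the background, excluding peak cells from its coverage
    cov_bg = pol.coverage & ~peak_mask
    bg_pol = PolarImage(
        np.where(cov_bg, pol.values, np.nan), cov_bg, pol.q_edges, pol.chi_edges
    )
    stats_bg = _metrics.azimuthal_stats(bg_pol, window_deg=window_deg)
    ranges_bg = (
        _metrics.flag_anisotropic_ranges(stats_bg, threshold=ratio_threshold, min_run=min_run)
        if stats_bg
        else []
    )
    bg_healed, bg_prov, bg_tables = heal_diffuse(
        bg_pol, ranges_bg, alpha=alpha, candidates=candidates, max_iter=max_iter
    )

    # (3) peak component on covered cells, floored at zero
    peak_vals = np.where(pol.coverage, pol.values - bg_healed.values, np.nan)
    peak_vals = np.where(pol.coverage, np.maximum(peak_vals, 0.0), np.nan)
    pk_pol = PolarImage(peak_vals, pol.coverage.copy(), pol.q_edges, pol.chi_edges)

    # (4) heal the peak component with the ordered branch
    stats_pk = _metrics.azimuthal_stats(pk_pol, window_deg=window_deg)
    ranges_pk = (
        _metrics.flag_anisotropic_ranges(stats_pk, threshold=ratio_threshold, min_run=min_run)
        if stats_pk
        else []
    )
    pk_healed, pk_prov, pk_tables = heal_ordered(
        pk_pol, ranges_pk, alpha=alpha, candidates=candidates
    )

    # (5) combine into the gaps; measured cells restored exactly
    out = pol.copy()
    gaps = ~pol.coverage
    combined = bg_healed.values + pk_healed.values
    out.values[gaps] = np.maximum(combined[gaps], 0.0)
    out.coverage[:] = True

    prov = np.full(out.values.shape, _UNSET, dtype=np.uint8)
    prov[pol.coverage] = MEASURED
    # a gap cell's label is the "strongest" inference used by either component
    for label in (SYMMETRY_FILLED, INTERPOLATED, CIRCAVG_FILLED):
        sel = gaps & (prov == _UNSET) & ((bg_prov == label) | (pk_prov == label))
        prov[sel] = label
    prov[gaps & (prov == _UNSET)] = CIRCAVG_FILLED

    tables = [dict(t, component="background") for t in bg_tables] + [
        dict(t, component="peaks") for t in pk_tables
    ]
    return out, prov, tables


# ---------------------------------------------------------------------------
# orchestrator


_BRANCH_BY_MODE = ("auto", "isotropic", "ordered", "diffuse", "complex")


def heal(img: DetectorImage, config: Optional[RunConfig] = None) -> HealedResult:
    """Full healing workflow: remesh, classify, dispatch, remesh back.

    The branch is chosen from the image category (``config.mode`` overrides);
    the detector-space output keeps original values wherever the input mask
    is valid and takes the remeshed healed polar image elsewhere, with a
    per-pixel provenance label.
    """
    cfg = config or RunConfig()
    cfg.validate()

    pol = remesh_to_polar(img, n_chi=cfg.n_chi, n_q=cfg.n_q)
    thresholds = _metrics.ClassifierThresholds(cfg.t_iso, cfg.t_peak, cfg.t_diffuse)
    sig = _metrics.analyze(
        pol,
        window_deg=cfg.window_deg,
        ratio_threshold=cfg.ratio_threshold,
        min_run=cfg.min_run,
        bins=cfg.histogram_bins,
        thresholds=thresholds,
    )
    category = sig.category
    branch = cfg.mode if cfg.mode != "auto" else {
        ImageCategory.ISOTROPIC: "isotropic",
        ImageCategory.ISO_BG_PLUS_PEAKS: "ordered",
        ImageCategory.DIFFUSE_ANISO: "diffuse",
        ImageCategory.COMPLEX: "complex",
    }[category]

    tables: List[dict] = []
    if branch == "isotropic":
        filled, prov_polar = fill_isotropic(pol)
    elif branch == "ordered":
        filled, prov_polar, tables = heal_ordered(
            pol, sig.anisotropic_ranges, alpha=cfg.alpha, candidates=cfg.candidates
        )
    elif branch == "diffuse":
        filled, prov_polar, tables = heal_diffuse(
            pol,
            sig.anisotropic_ranges,
            alpha=cfg.alpha,
            candidates=cfg.candidates,
            max_iter=cfg.max_iter,
        )
    elif branch == "complex":
        filled, prov_polar, tables = heal_complex(
            pol,
            alpha=cfg.alpha,
            candidates=cfg.candidates,
            svd_rank=cfg.svd_rank,
            k_mad=cfg.k_mad,
            dilate=cfg.dilate,
            window_deg=cfg.window_deg,
            ratio_threshold=cfg.ratio_threshold,
            min_run=cfg.min_run,
            max_iter=cfg.max_iter,
            peak_filter_deg=cfg.peak_filter_deg,
        )
    else:  # pragma: no cover - config.validate() rejects unknown modes
        raise ValueError(f"unknown mode {branch!r}")
    sig.symmetry_tables = tables

    cart = remesh_to_cartesian(filled, img.shape, img.center, img.calib)
    healed = np.where(img.mask, img.intensity, np.maximum(cart, 0.0))

    qi, ci = polar_bin_indices(filled, img.shape, img.center, img.calib)
    prov = prov_polar[qi, ci].astype(np.uint8)
    # a masked pixel landing in a measured polar cell was still inferred:
    # its value is the interpolation of surrounding measured cells
    prov[~img.mask & (prov == MEASURED)] = INTERPOLATED
    prov[img.mask] = MEASURED

    return HealedResult(
        healed=healed,
        provenance=prov,
        category=category,
        signature=sig,
        polar=pol,
        polar_healed=filled,
        polar_provenance=prov_polar,
        config=cfg,
        image=img,
        band_folds=tables,
    )
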