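"""Self-validation harness: quantitative checks of the whole workflow.

Every function here regenerates its inputs from the synthetic-scene
generator (or from closed-form constructions), runs the relevant part of
the pipeline and returns a measured number. The test suite asserts on these
measurements; the acceptance script reports them.
"""

from __future__ import annotations

import hashlib
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import RunConfig
from .extension import fit_tails
from .geometry import DetectorImage, _pixel_coords, remesh_to_cartesian, remesh_to_polar
from .healing import MEASURED, _band_profile, fill_isotropic, heal, lowrank_background
from .metrics import analyze, fit_poisson_histogram
from .symmetry import estimate_symmetry
from .synthgen import (
    DiffuseHalo,
    MaskSpec,
    PeakSet,
    archetype_suite,
    holdout_peak_rects,
    render_mask,
    render_scene,
    symmetry_grid_cases,
)

__all__ = [
    "classification_results",
    "anisotropic_range_localization",
    "symmetry_grid_accuracy",
    "holdout_metrics",
    "preservation_exact",
    "branch_equivalence_max_dev",
    "roundtrip_max_rel_error",
    "eckart_young_gap",
    "poisson_recovery_rel_error",
    "tail_fit_errors",
    "determinism_identical",
]


def classification_results(seed: int, shape: Tuple[int, int] = (512, 512)) -> Dict:
    """Fraction of archetype battery cases classified into their category."""
    cases = archetype_suite(seed=seed, shape=shape)
    correct = 0
    detail = []
    for c in cases:
        sig = analyze(remesh_to_polar(c.detector_image()))
        ok = sig.category.value == c.expected_category
        correct += ok
        detail.append({"name": c.name, "expected": c.expected_category,
                       "got": sig.category.value, "ok": bool(ok)})
    return {"accuracy": correct / len(cases), "n": len(cases), "detail": detail}


def _true_band_rows(case, delta_q: float, n_q: int, pad_sigmas: float) -> set:
    rows: set = set()
    for f in case.scene.features:
        width = f.width_r if isinstance(f, PeakSet) else getattr(f, "width", None)
        if width is None or not isinstance(f, (PeakSet, DiffuseHalo)):
            continue
        lo = max(int((f.q0 - pad_sigmas * width) / delta_q), 0)
        hi = min(int((f.q0 + pad_sigmas * width) / delta_q), n_q - 1)
        rows.update(range(lo, hi + 1))
    return rows


def anisotropic_range_localization(seed: int, shape: Tuple[int, int] = (512, 512)) -> Dict:
    """Check that the per-q ratio drops below threshold exactly at true bands.

    For every battery case: each flagged q row with adequate chi coverage
    (>= 25%, where the statistic is meaningful) must lie inside a true
    structured band (within 3.5 radial widths), and the core (+/- 1 width)
    of every structured band must intersect the flagged set.
    """
    cases = archetype_suite(seed=seed, shape=shape)
    ok_cases = 0
    for c in cases:
        pol = remesh_to_polar(c.detector_image())
        sig = analyze(pol)
        flagged = set()
        min_cov = pol.n_chi // 4
        ncov = pol.coverage.sum(axis=1)
        for lo, hi in sig.anisotropic_ranges:
            flagged.update(i for i in range(lo, hi + 1) if ncov[i] >= min_cov)
        allowed = _true_band_rows(c, pol.delta_q, pol.n_q, pad_sigmas=3.5)
        precision_ok = flagged <= allowed
        recall_ok = True
        for f in c.scene.features:
            if isinstance(f, (PeakSet, DiffuseHalo)):
                width = f.width_r if isinstance(f, PeakSet) else f.width
                core = set(
                    range(int((f.q0 - width) / pol.delta_q), int((f.q0 + width) / pol.delta_q) + 1)
                )
                if not core & flagged:
                    recall_ok = False
        if c.expected_category == "isotropic":
            precision_ok = not flagged
            recall_ok = True
        ok_cases += precision_ok and recall_ok
    return {"fraction_ok": ok_cases / len(cases), "n": len(cases)}


def symmetry_grid_accuracy(
    noise: Optional[str],
    seeds: Sequence[int] = (11, 22, 33),
    shape: Tuple[int, int] = (512, 512),
) -> Dict:
    """Selection accuracy over the fold x peak-width x seed grid."""
    cases = symmetry_grid_cases(seeds=seeds, noise=noise, shape=shape)
    correct = 0
    fails: List = []
    for case in cases:
        scene = case["scene"]
        rend = render_scene(scene)
        mask = render_mask(case["mask_spec"], scene.shape)
        pol = remesh_to_polar(DetectorImage(rend.image, mask, scene.center))
        lo = int(case["q_band"][0] / pol.delta_q)
        hi = int(case["q_band"][1] / pol.delta_q)
        prof, cov = _band_profile(pol.values, pol.coverage, lo, hi)
        sel, _ = estimate_symmetry(prof, cov)
        if sel == case["fold"]:
            correct += 1
        else:
            fails.append((case["fold"], case["width_chi"], case["seed"], sel))
    return {"accuracy": correct / len(cases), "n": len(cases), "fails": fails}


def holdout_metrics(
    name: str, noise: Optional[str], seed: int, shape: Tuple[int, int] = (512, 512)
) -> Dict:
    """Heal with extra hold-out rectangles over whole peaks; compare to truth."""
    case = {c.name: c for c in archetype_suite(seed=seed, shape=shape, noise=noise)}[name]
    rects = holdout_peak_rects(case.scene)
    mask = render_mask(
        MaskSpec(
            elements=list(case.mask_spec.elements) + rects,
            seed=case.mask_spec.seed,
            center=case.scene.center,
        ),
        case.image.shape,
    )
    held = case.mask & ~mask
    res = heal(DetectorImage(case.image, mask, case.scene.center))
    h, t = res.healed[held], case.truth[held]
    return {
        "pearson_r": float(np.corrcoef(h, t)[0, 1]),
        "median_rel_error": float(np.median(np.abs(h - t) / np.maximum(t, 1e-9))),
        "n_heldout": int(held.sum()),
        "category": res.category.value,
    }


def preservation_exact(seed: int, shape: Tuple[int, int] = (512, 512)) -> Dict:
    """Healed output bit-identical to input on every valid pixel, all cases."""
    cases = archetype_suite(seed=seed, shape=shape)
    all_exact = True
    for c in cases:
        img = c.detector_image()
        res = heal(img)
        if not np.array_equal(res.healed[img.mask], img.intensity[img.mask]):
            all_exact = False
        if not np.array_equal(res.provenance == MEASURED, img.mask):
            all_exact = False
        if not np.isfinite(res.healed).all() or (res.healed < 0).any():
            all_exact = False
    return {"all_exact": bool(all_exact), "n": len(cases)}


def branch_equivalence_max_dev(shape: Tuple[int, int] = (256, 256)) -> Dict:
    """Max relative deviation of each branch's gap fill from the circular average."""
    from .synthgen import Background, Beamstop, GapBand, IsotropicRing, SceneSpec, _generic_center

    scene = SceneSpec(
        shape=shape,
        center=_generic_center(shape),
        features=[IsotropicRing(q0=shape[0] * 0.23, width=shape[0] / 32.0, amplitude=120.0)],
        background=Background(constant=50.0),
        noise=None,
        seed=0,
    )
    rend = render_scene(scene)
    mask = render_mask(
        MaskSpec(
            elements=[
                Beamstop(radius=10.0, arm_width=5.0, arm_angle=270.0),
                GapBand(0, int(shape[0] * 0.35), 7),
            ],
            center=scene.center,
        ),
        shape,
    )
    img = DetectorImage(rend.image, mask, scene.center)
    pol = remesh_to_polar(img)
    iso_fill, _ = fill_isotropic(pol)
    out = {}
    for mode in ("isotropic", "ordered", "diffuse", "complex"):
        res = heal(img, RunConfig(mode=mode))
        gaps = ~res.polar.coverage
        ref = iso_fill.values[gaps]
        dev = np.abs(res.polar_healed.values[gaps] - ref) / np.maximum(ref, 1e-9)
        out[mode] = float(dev.max())
    return out


def roundtrip_max_rel_error(shape: Tuple[int, int] = (256, 256)) -> float:
    """Cartesian -> polar -> cartesian max relative error on a smooth ring."""
    from .synthgen import _generic_center

    center = _generic_center(shape)
    r, _ = _pixel_coords(shape, center)
    ring_r = shape[0] * 0.23
    intensity = 10.0 + 100.0 * np.exp(-((r - ring_r) ** 2) / (2.0 * 6.0**2))
    img = DetectorImage(intensity, np.ones(shape, bool), center)
    pol = remesh_to_polar(img, n_chi=360)
    filled, _ = fill_isotropic(pol)
    cart = remesh_to_cartesian(filled, shape, center)
    inscribed = min(center[0], center[1], shape[1] - 1 - center[0], shape[0] - 1 - center[1])
    sel = (r > 5) & (r < inscribed - 2)
    return float((np.abs(cart - intensity) / intensity)[sel].max())


def eckart_young_gap(seed: int = 0) -> float:
    """|rank-2 Frobenius error - discarded singular value| on a constructed matrix."""
    rng = np.random.default_rng(seed)
    qm, _ = np.linalg.qr(rng.normal(size=(30, 3)))
    qn, _ = np.linalg.qr(rng.normal(size=(40, 3)))
    m = (qm * np.array([10.0, 5.0, 1.0])) @ qn.T
    err = np.linalg.norm(m - lowrank_background(m, rank=2))
    return float(abs(err - 1.0))


def poisson_recovery_rel_error(lam: float = 4.0) -> float:
    """Relative error of the fitted lambda on an exact Poisson pmf histogram."""
    from scipy.special import gammaln

    k = np.arange(30)
    pmf = np.exp(k * np.log(lam) - lam - gammaln(k + 1.0))
    counts = np.round(pmf * 10000).astype(int)
    values = np.repeat(k + 0.5, counts) / 30.0
    values[0], values[-1] = 0.0, 1.0
    sig = fit_poisson_histogram(values)
    return float(abs(sig.lambda_fit - lam) / lam)


def tail_fit_errors() -> Dict[str, float]:
    """Relative parameter errors on synthetic power-law and Guinier profiles."""
    q = np.linspace(0.01, 0.5, 200)
    _, high = fit_tails(q, 100.0 * q**-4.0 + 2.0)
    low, _ = fit_tails(q, 7.0 * np.exp(-(q**2) * 50.0**2 / 3.0))
    return {
        "power_exponent_rel_error": float(abs(high.params["p"] - 4.0) / 4.0),
        "power_constant_rel_error": float(abs(high.params["b"] - 2.0) / 2.0),
        "guinier_rg_rel_error": float(abs(low.params["rg"] - 50.0) / 50.0),
    }


def determinism_identical(seed: int, shape: Tuple[int, int] = (256, 256)) -> bool:
    """Two identical runs produce byte-identical healed output and report."""
    case = archetype_suite(seed=seed, shape=shape)[7]  # a peaks image
    img = case.detector_image()
    digests = []
    for _ in range(2):
        res = heal(img)
        h = hashlib.sha256()
        h.update(res.healed.tobytes())
        h.update(res.provenance.tobytes())
        h.update(res.signature.to_json().encode())
        digests.append(h.hexdigest())
    return digests[0] == digests[1]
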