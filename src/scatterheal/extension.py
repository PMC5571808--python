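"""Extension of a healed image beyond the measured q-span.

The healed polar image already covers the full 360 deg azimuth, so extending
the image amounts to (a) appending q rows beyond the measured maximum, filled
from a radial tail model fitted to the circular average, and (b) remeshing
onto an arbitrary (typically larger) detector frame. Two canonical
small-angle tail forms are fitted per side and the better one kept:

* power law plus constant, I(q) = a q^-p + b (Porod-like decay at high q);
* Guinier-like, I(q) = I0 exp(-q^2 R^2 / 3) (low-q of a finite-size object).

If the terminal q rows sit inside an anisotropic band, the extension
continues that band's chi profile, scaled by the ratio of the tail-model
prediction to the boundary circular average, so angular structure follows
the fitted radial decay instead of being blurred to a ring.

Extended regions are provenance-labelled MODEL_EXTENDED and are inherently
model-dependent: they are for visualization and for algorithms that cannot
tolerate masks, not for quantitative fitting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from lmfit import Parameters, minimize

from .geometry import PolarImage, _pixel_coords, remesh_to_cartesian
from .healing import MEASURED, MODEL_EXTENDED, HealedResult, circular_average

logger = logging.getLogger(__name__)

__all__ = ["TailModel", "fit_tails", "extend_image", "extend_result"]

#: mean squared log-residual above which a tail fit is considered unreliable
GOODNESS_THRESHOLD = 0.05


@dataclass
class TailModel:
    """A fitted radial tail: functional form, parameters, fit range, quality."""

    side: str  # "low_q" | "high_q"
    form: str  # "power_law_plus_constant" | "guinier_like"
    params: dict
    q_range: Tuple[float, float]
    goodness: float  # mean squared log-residual over the fit window
    ok: bool = True

    def predict(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if self.form == "power_law_plus_constant":
            a, p, b = self.params["a"], self.params["p"], self.params["b"]
            with np.errstate(divide="ignore"):
                out = a * np.power(np.maximum(q, 1e-300), -p) + b
        elif self.form == "guinier_like":
            i0, rg = self.params["i0"], self.params["rg"]
            out = i0 * np.exp(-(q**2) * rg**2 / 3.0)
        elif self.form == "constant":
            out = np.full_like(q, self.params["c"])
        else:  # pragma: no cover
            raise ValueError(f"unknown tail form {self.form!r}")
        return np.maximum(out, 0.0)

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "form": self.form,
            "params": {k: float(v) for k, v in self.params.items()},
            "q_range": [float(self.q_range[0]), float(self.q_range[1])],
            "goodness": float(self.goodness),
            "ok": bool(self.ok),
        }


def _log_goodness(pred: np.ndarray, intensity: np.ndarray) -> float:
    pred = np.maximum(pred, 1e-300)
    obs = np.maximum(intensity, 1e-300)
    return float(np.mean((np.log(pred) - np.log(obs)) ** 2))


def _fit_power_law(q: np.ndarray, intensity: np.ndarray) -> Tuple[dict, float]:
    pos = intensity > 0
    lo = float(intensity.min())
    # slope between window endpoints in log-log as the exponent seed
    i_hi, i_lo = float(intensity[0]), float(intensity[-1])
    q_hi, q_lo = float(q[0]), float(q[-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = math.log(max(i_hi, 1e-12) / max(i_lo, 1e-12)) / math.log(max(q_lo, 1e-12) / max(q_hi, 1e-12))
    p0 = min(max(p0, 0.0), 8.0)
    a0 = max((i_hi - 0.5 * lo) * q_hi**p0, 1e-12)

    params = Parameters()
    params.add("loga", value=math.log(a0))
    params.add("p", value=max(p0, 0.1), min=0.0, max=12.0)
    params.add("b", value=0.5 * lo, min=0.0)

    def resid(pars):
        a = math.exp(pars["loga"].value)
        model = a * np.power(q, -pars["p"].value) + pars["b"].value
        return np.log(np.maximum(model, 1e-300)) - np.log(np.maximum(intensity, 1e-300))

    try:
        res = minimize(resid, params, method="leastsq")
        a = math.exp(res.params["loga"].value)
        fitted = {"a": a, "p": float(res.params["p"].value), "b": float(res.params["b"].value)}
    except Exception:  # pragma: no cover - leastsq failure on degenerate data
        fitted = {"a": 0.0, "p": 0.0, "b": float(np.mean(intensity))}
    model = fitted["a"] * np.power(q, -fitted["p"]) + fitted["b"]
    return fitted, _log_goodness(model, intensity)


def _fit_guinier(q: np.ndarray, intensity: np.ndarray) -> Tuple[dict, float]:
    # log I = log I0 - q^2 R^2/3 is linear in q^2: closed-form regression
    y = np.log(np.maximum(intensity, 1e-300))
    x = q**2
    slope, icept = np.polyfit(x, y, 1)
    rg2 = max(-3.0 * slope, 0.0)
    fitted = {"i0": float(np.exp(icept)), "rg": float(np.sqrt(rg2))}
    model = fitted["i0"] * np.exp(-x * rg2 / 3.0)
    return fitted, _log_goodness(model, intensity)


def _fit_side(q: np.ndarray, intensity: np.ndarray, side: str) -> TailModel:
    pw, g_pw = _fit_power_law(q, intensity)
    gu, g_gu = _fit_guinier(q, intensity)
    q_range = (float(q.min()), float(q.max()))
    if g_pw <= g_gu:
        return TailModel(side, "power_law_plus_constant", pw, q_range, g_pw, g_pw < GOODNESS_THRESHOLD)
    return TailModel(side, "guinier_like", gu, q_range, g_gu, g_gu < GOODNESS_THRESHOLD)


def fit_tails(
    q: np.ndarray,
    intensity: np.ndarray,
    fit_fraction: float = 0.15,
) -> Tuple[TailModel, TailModel]:
    """Fit low-q and high-q tail models to a circular-average profile.

    Each side uses the innermost/outermost ``fit_fraction`` of the valid
    points (at least 10); both candidate forms are fitted by least squares in
    log intensity and the better one kept. A side with too few points is
    marked not-ok; extension then clamps to the nearest measured value.
    """
    q = np.asarray(q, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    ok = np.isfinite(intensity) & np.isfinite(q) & (q > 0)
    qv, iv = q[ok], intensity[ok]

    n_win = max(10, int(math.ceil(fit_fraction * qv.size)))
    if qv.size < n_win or n_win < 10:
        c = float(np.mean(iv)) if iv.size else 0.0
        bad_lo = TailModel("low_q", "constant", {"c": c}, (0.0, 0.0), np.inf, False)
        bad_hi = TailModel("high_q", "constant", {"c": c}, (0.0, 0.0), np.inf, False)
        return bad_lo, bad_hi

    low = _fit_side(qv[:n_win], iv[:n_win], "low_q")
    high = _fit_side(qv[-n_win:], iv[-n_win:], "high_q")
    return low, high


def extend_image(
    pol: PolarImage,
    out_q_max: float,
    out_shape: Tuple[int, int],
    center: Tuple[float, float],
    calib=None,
    tail: Optional[TailModel] = None,
    aniso_ranges: Sequence[Tuple[int, int]] = (),
    fit_fraction: float = 0.15,
    base_provenance: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, dict]:
    """Extend a fully healed polar image to ``out_q_max`` and remesh it.

    q rows beyond the measured span are filled from the high-q tail model
    (fitted here if not supplied). If an anisotropic band reaches the
    measured boundary, its normalized chi profile is continued, scaled by the
    tail prediction. Returns the extended cartesian image, a provenance map
    (MODEL_EXTENDED beyond the measured q-span, otherwise the polar label of
    the underlying cell), and a report dict with the tail fits.

    The extension is model-dependent by construction; the report carries an
    explicit warning flag when the tail fit quality is poor.
    """
    if not pol.coverage.all():
        raise ValueError("extend_image requires a fully healed polar image")
    dq = pol.delta_q
    q_meas_max = float(pol.q_edges[-1])
    n_extra = max(int(math.ceil((out_q_max - q_meas_max) / dq)), 0)

    prof = circular_average(pol)
    low_tail, high_tail = fit_tails(pol.q_centers, prof, fit_fraction)
    if tail is not None:
        high_tail = tail

    n_q_ext = pol.n_q + n_extra
    q_edges_ext = np.linspace(0.0, pol.q_edges[-1] + n_extra * dq, n_q_ext + 1)
    values_ext = np.vstack([pol.values, np.zeros((n_extra, pol.n_chi))])

    clamped = False
    if n_extra:
        q_new = 0.5 * (q_edges_ext[pol.n_q : -1] + q_edges_ext[pol.n_q + 1 :])
        if high_tail.ok:
            radial = high_tail.predict(q_new)
        else:
            clamped = True
            radial = np.full(n_extra, max(float(prof[-1]), 0.0))
            logger.warning("high-q tail unreliable; extending with constant continuation")

        # does an anisotropic band touch the measured boundary?
        shape_chi = np.ones(pol.n_chi)
        for lo, hi in aniso_ranges:
            if hi >= pol.n_q - 3:
                rows = pol.values[max(lo, hi - 4) : hi + 1]
                band_prof = rows.mean(axis=0)
                m = float(band_prof.mean())
                if m > 0:
                    shape_chi = band_prof / m
                break
        values_ext[pol.n_q :] = radial[:, None] * shape_chi[None, :]

    pol_ext = PolarImage(
        values_ext, np.ones_like(values_ext, dtype=bool), q_edges_ext, pol.chi_edges
    )
    cart = np.maximum(remesh_to_cartesian(pol_ext, out_shape, center, calib), 0.0)

    r, _ = _pixel_coords(out_shape, center)
    qmap = calib.q_of_radius(r) if calib is not None else r
    beyond = qmap > q_meas_max
    # inside the measured q span the values are remeshed from the healed
    # polar image; without a pixel-level base provenance they are inferred
    # (interpolated), not model-extended
    from .healing import INTERPOLATED

    prov = np.where(beyond, MODEL_EXTENDED, INTERPOLATED).astype(np.uint8)
    if base_provenance is not None:
        inside = ~beyond
        h = min(out_shape[0], base_provenance.shape[0])
        w = min(out_shape[1], base_provenance.shape[1])
        # only meaningful when the extended frame shares the original origin
        prov[:h, :w][inside[:h, :w]] = base_provenance[:h, :w][inside[:h, :w]]

    report = {
        "low_tail": low_tail.to_dict(),
        "high_tail": high_tail.to_dict(),
        "clamped": clamped,
        "warning": "extended regions are model-dependent; do not fit physical parameters to them",
    }
    return cart, prov, report


def extend_result(
    result: HealedResult,
    factor: float = 1.5,
    out_shape: Optional[Tuple[int, int]] = None,
) -> Tuple[np.ndarray, np.ndarray, dict]:
    """Convenience wrapper: extend a HealedResult's q-span by ``factor``.

    The output frame defaults to the input frame scaled by ``factor`` about
    the beam center (so the new q-range fits), keeping the same pixel size.
    """
    pol = result.polar_healed
    img = result.image
    q_max = float(pol.q_edges[-1]) * factor
    if out_shape is None:
        out_shape = (
            int(round(img.shape[0] * factor)),
            int(round(img.shape[1] * factor)),
        )
    cx, cy = img.center
    center = (
        cx + (out_shape[1] - img.shape[1]) / 2.0,
        cy + (out_shape[0] - img.shape[0]) / 2.0,
    )
    base_prov = result.provenance if out_shape == img.shape and center == img.center else None
    return extend_image(
        pol,
        q_max,
        out_shape,
        center,
        calib=img.calib,
        aniso_ranges=result.signature.anisotropic_ranges,
        fit_fraction=result.config.tail_fit_fraction,
        base_provenance=base_prov,
    )
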