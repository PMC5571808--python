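"""Synthetic scattering images with known ground truth.

Scenes are sums of computed contributions of the feature types typically
seen on an area detector: isotropic rings, diffuse halos with an optional
cosine chi modulation, n-fold peak sets along a ring and a smooth background
(constant plus a power-law term). Every feature is separable: a Gaussian
radial profile times an azimuthal profile (constant, 1 + d cos(m(chi-chi0)),
or periodic Gaussian peaks at chi0 + j*360/n). Poisson counting noise is
applied last, parameterized by an exposure scale multiplying the clean image
before sampling.

Masks are composed from the standard culprits: a beamstop disc with an arm,
detector inter-module gap bands, random bad pixels, streaks and hold-out
rectangles (valid regions deliberately masked so the healed values can be
compared against the known truth).

Everything is reproducible bit-for-bit from the spec plus its seed, and the
per-feature component images are returned so tests can use them as oracles.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import DetectorImage, _pixel_coords

__all__ = [
    "IsotropicRing",
    "DiffuseHalo",
    "PeakSet",
    "Background",
    "SceneSpec",
    "Beamstop",
    "GapBand",
    "BadPixels",
    "Streak",
    "HoldoutRect",
    "MaskSpec",
    "SceneRender",
    "render_scene",
    "render_mask",
    "archetype_suite",
    "ArchetypeCase",
    "standard_mask_spec",
    "symmetry_grid_cases",
    "holdout_peak_rects",
]


# --------------------------------------------------------------------------
# scene features


@dataclass(frozen=True)
class IsotropicRing:
    """Gaussian ring: amplitude * exp(-(r - q0)^2 / (2 width^2))."""

    q0: float
    width: float
    amplitude: float


@dataclass(frozen=True)
class DiffuseHalo:
    """Broad ring with a cosine chi modulation 1 + depth*cos(fold*(chi-phase))."""

    q0: float
    width: float
    amplitude: float
    fold: int = 2
    depth: float = 0.5
    phase: float = 0.0


@dataclass(frozen=True)
class PeakSet:
    """n equally spaced Gaussian peaks along a ring.

    ``width_chi`` is the azimuthal Gaussian sigma in degrees; peak centers
    sit at phase + j*360/fold, so the rendered set is exactly fold-periodic.
    """

    q0: float
    width_r: float
    width_chi: float
    fold: int
    amplitude: float
    phase: float = 0.0


@dataclass(frozen=True)
class Background:
    """constant + power_amp * max(r, r_floor)^-power_exp."""

    constant: float = 0.0
    power_amp: float = 0.0
    power_exp: float = 2.0
    r_floor: float = 1.0


_FEATURE_TYPES = {
    "isotropic_ring": IsotropicRing,
    "diffuse_halo": DiffuseHalo,
    "peak_set": PeakSet,
}


@dataclass
class SceneSpec:
    shape: Tuple[int, int] = (512, 512)
    center: Tuple[float, float] = (255.5, 255.5)
    features: List = field(default_factory=list)
    background: Background = field(default_factory=Background)
    noise: Optional[str] = None  # None | "poisson"
    exposure: float = 1.0
    seed: int = 0

    def to_json(self, **kw) -> str:
        def tag(f):
            for name, cls in _FEATURE_TYPES.items():
                if isinstance(f, cls):
                    return {"type": name, **asdict(f)}
            raise TypeError(f"unknown feature {f!r}")

        return json.dumps(
            {
                "shape": list(self.shape),
                "center": list(self.center),
                "features": [tag(f) for f in self.features],
                "background": asdict(self.background),
                "noise": self.noise,
                "exposure": self.exposure,
                "seed": self.seed,
            },
            **kw,
        )

    @classmethod
    def from_json(cls, text: str) -> "SceneSpec":
        d = json.loads(text)
        feats = []
        for f in d.get("features", []):
            f = dict(f)
            typ = f.pop("type")
            feats.append(_FEATURE_TYPES[typ](**f))
        return cls(
            shape=tuple(d["shape"]),
            center=tuple(d["center"]),
            features=feats,
            background=Background(**d.get("background", {})),
            noise=d.get("noise"),
            exposure=d.get("exposure", 1.0),
            seed=d.get("seed", 0),
        )


@dataclass
class SceneRender:
    image: np.ndarray  # noisy if the spec asks for noise, else == truth
    truth: np.ndarray  # noise-free sum of all components
    components: Dict[str, np.ndarray]


def _angdist(chi: np.ndarray, center_deg: float) -> np.ndarray:
    """Smallest angular distance in degrees."""
    d = (chi - center_deg) % 360.0
    return np.minimum(d, 360.0 - d)


def _render_feature(f, r: np.ndarray, chi: np.ndarray) -> np.ndarray:
    if isinstance(f, IsotropicRing):
        if f.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        return f.amplitude * np.exp(-((r - f.q0) ** 2) / (2.0 * f.width**2))
    if isinstance(f, DiffuseHalo):
        if f.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if f.fold < 2 or f.fold % 2:
            raise ValueError("fold must be even and >= 2")
        radial = f.amplitude * np.exp(-((r - f.q0) ** 2) / (2.0 * f.width**2))
        azim = 1.0 + f.depth * np.cos(np.radians(f.fold * (chi - f.phase)))
        return radial * np.maximum(azim, 0.0)
    if isinstance(f, PeakSet):
        if f.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if f.fold < 2 or f.fold % 2:
            raise ValueError("fold must be even and >= 2")
        radial = np.exp(-((r - f.q0) ** 2) / (2.0 * f.width_r**2))
        azim = np.zeros_like(chi)
        for j in range(f.fold):
            d = _angdist(chi, f.phase + j * 360.0 / f.fold)
            azim += np.exp(-(d**2) / (2.0 * f.width_chi**2))
        return f.amplitude * radial * azim
    raise TypeError(f"unknown feature type {type(f).__name__}")


def render_scene(spec: SceneSpec) -> SceneRender:
    """Render a scene spec into (possibly noisy) image, truth and components."""
    r, chi = _pixel_coords(spec.shape, spec.center)
    components: Dict[str, np.ndarray] = {}
    for idx, f in enumerate(spec.features):
        components[f"{type(f).__name__.lower()}_{idx}"] = _render_feature(f, r, chi)
    bg = spec.background
    components["background"] = bg.constant + bg.power_amp * np.maximum(r, bg.r_floor) ** (
        -bg.power_exp
    )
    truth = np.zeros(spec.shape)
    for comp in components.values():
        truth = truth + comp

    if spec.noise is None:
        image = truth.copy()
    elif spec.noise == "poisson":
        if spec.exposure <= 0:
            raise ValueError("exposure must be positive for poisson noise")
        rng = np.random.default_rng(spec.seed)
        image = rng.poisson(truth * spec.exposure).astype(float) / spec.exposure
    else:
        raise ValueError(f"unknown noise model {spec.noise!r}")
    return SceneRender(image=image, truth=truth, components=components)


# --------------------------------------------------------------------------
# masks


@dataclass(frozen=True)
class Beamstop:
    radius: float = 20.0
    arm_width: float = 8.0
    arm_angle: float = 270.0  # direction of the arm from the center, degrees


@dataclass(frozen=True)
class GapBand:
    """Dead rows (axis=0) or columns (axis=1) of an inter-module gap."""

    axis: int
    start: int
    width: int


@dataclass(frozen=True)
class BadPixels:
    count: int = 100


@dataclass(frozen=True)
class Streak:
    row0: float
    col0: float
    row1: float
    col1: float
    width: float = 2.0


@dataclass(frozen=True)
class HoldoutRect:
    row0: int
    col0: int
    height: int
    width: int


@dataclass
class MaskSpec:
    elements: List = field(default_factory=list)
    seed: int = 0
    center: Optional[Tuple[float, float]] = None  # for the beamstop; defaults to frame center


def _dist_to_segment(
    rows: np.ndarray, cols: np.ndarray, r0: float, c0: float, r1: float, c1: float
) -> np.ndarray:
    dr, dc = r1 - r0, c1 - c0
    den = dr * dr + dc * dc
    if den == 0:
        return np.hypot(rows - r0, cols - c0)
    t = np.clip(((rows - r0) * dr + (cols - c0) * dc) / den, 0.0, 1.0)
    return np.hypot(rows - (r0 + t * dr), cols - (c0 + t * dc))


def render_mask(spec: MaskSpec, shape: Tuple[int, int]) -> np.ndarray:
    """Render a mask spec into a boolean validity mask (True = valid pixel)."""
    valid = np.ones(shape, dtype=bool)
    rows = np.arange(shape[0], dtype=float)[:, None] * np.ones((1, shape[1]))
    cols = np.ones((shape[0], 1)) * np.arange(shape[1], dtype=float)[None, :]
    center = spec.center or ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)
    cx, cy = center

    rng = np.random.default_rng(spec.seed)
    for el in spec.elements:
        if isinstance(el, Beamstop):
            rr = np.hypot(cols - cx, rows - cy)
            valid &= rr > el.radius
            # arm: a ray from the center toward arm_angle
            ang = math.radians(el.arm_angle)
            ex = cx + 4 * max(shape) * math.cos(ang)
            ey = cy - 4 * max(shape) * math.sin(ang)
            d = _dist_to_segment(rows, cols, cy, cx, ey, ex)
            valid &= d > el.arm_width / 2.0
        elif isinstance(el, GapBand):
            sl = slice(el.start, el.start + el.width)
            if el.axis == 0:
                valid[sl, :] = False
            else:
                valid[:, sl] = False
        elif isinstance(el, BadPixels):
            idx = rng.choice(shape[0] * shape[1], size=el.count, replace=False)
            flat = valid.reshape(-1)
            flat[idx] = False
        elif isinstance(el, Streak):
            d = _dist_to_segment(rows, cols, el.row0, el.col0, el.row1, el.col1)
            valid &= d > el.width / 2.0
        elif isinstance(el, HoldoutRect):
            valid[el.row0 : el.row0 + el.height, el.col0 : el.col0 + el.width] = False
        else:
            raise TypeError(f"unknown mask element {type(el).__name__}")
    if not valid.any():
        raise ValueError("mask covers the whole frame")
    return valid


# --------------------------------------------------------------------------
# archetype battery


@dataclass
class ArchetypeCase:
    name: str
    expected_category: str
    expected_folds: List[int]
    scene: SceneSpec
    mask_spec: MaskSpec
    image: np.ndarray
    mask: np.ndarray
    truth: np.ndarray
    peak_ranges: List[Tuple[float, float]] = field(default_factory=list)  # (q0, width_r)

    def detector_image(self) -> DetectorImage:
        return DetectorImage(self.image, self.mask, self.scene.center)


def holdout_peak_rects(
    scene: SceneSpec,
    pad_r: float = 3.0,
    pad_chi: float = 2.5,
    margin: int = 8,
) -> List[HoldoutRect]:
    """Square hold-out rectangles covering one whole peak of each peak set.

    Each rectangle is centered on the peak at ``chi = phase`` of a PeakSet
    and sized to cover +/- ``pad_r`` radial widths and +/- ``pad_chi``
    azimuthal widths of the peak, so the healed values there can be compared
    against the known truth.
    """
    rects: List[HoldoutRect] = []
    cx, cy = scene.center
    h, w = scene.shape
    for f in scene.features:
        if not isinstance(f, PeakSet):
            continue
        ang = math.radians(f.phase)
        x = cx + f.q0 * math.cos(ang)
        y = cy - f.q0 * math.sin(ang)
        half_r = pad_r * f.width_r + margin
        half_arc = math.radians(pad_chi * f.width_chi) * f.q0 / 2.0 + margin
        half = int(math.ceil(max(half_r, half_arc)))
        r0 = max(int(y) - half, 0)
        c0 = max(int(x) - half, 0)
        r1 = min(int(y) + half, h)
        c1 = min(int(x) + half, w)
        if r1 > r0 and c1 > c0:
            rects.append(HoldoutRect(row0=r0, col0=c0, height=r1 - r0, width=c1 - c0))
    return rects


def standard_mask_spec(seed: int = 0) -> MaskSpec:
    """Beamstop with arm, two inter-module gaps and scattered bad pixels."""
    return MaskSpec(
        elements=[
            Beamstop(radius=18.0, arm_width=7.0, arm_angle=270.0),
            GapBand(axis=0, start=170, width=9),
            GapBand(axis=1, start=330, width=9),
            BadPixels(count=200),
        ],
        seed=seed,
    )


#: exposure used by the (Poisson-noisy) battery; background counts ~ O(100)
DEFAULT_EXPOSURE = 1.0


def _generic_center(shape: Tuple[int, int]) -> Tuple[float, float]:
    """A realistic off-grid beam center near (but not on) the frame center.

    An exactly lattice-symmetric center (a measure-zero condition in the
    lab) makes the remesh ripple exactly 4-fold symmetric, which would bias
    symmetry analysis; the fixtures avoid it on purpose.
    """
    scale = shape[0] / 512.0
    return ((shape[1] - 1) / 2.0 - 5.2 * scale, (shape[0] - 1) / 2.0 + 6.2 * scale)


def symmetry_grid_cases(
    seeds: Sequence[int] = (11, 22, 33),
    folds: Sequence[int] = (2, 4, 6, 8, 10, 12),
    widths_chi: Sequence[float] = (5.0, 15.0),
    noise: Optional[str] = None,
    shape: Tuple[int, int] = (512, 512),
) -> List[dict]:
    """The symmetry-recovery grid: fold x peak width x seed.

    Noise-free peaks use amplitude 200 on a constant background of 40;
    Poisson runs use amplitude 110, which puts the peak signal-to-noise at
    ~10 (A / sqrt(A + background) with unit exposure). Each entry carries the
    scene, mask and the q-band (in radial pixels) where the peak ring lives.
    """
    amplitude = 110.0 if noise else 200.0
    q0, width_r = 120.0 * shape[0] / 512.0, 6.0 * shape[0] / 512.0
    out: List[dict] = []
    for n in folds:
        for w in widths_chi:
            for seed in seeds:
                scene = SceneSpec(
                    shape=shape,
                    center=_generic_center(shape),
                    features=[
                        PeakSet(q0=q0, width_r=width_r, width_chi=w, fold=n,
                                amplitude=amplitude, phase=13.0)
                    ],
                    background=Background(constant=40.0),
                    noise=noise,
                    seed=seed,
                )
                mspec = standard_mask_spec(seed)
                mspec.center = scene.center
                out.append(
                    {
                        "fold": n,
                        "width_chi": w,
                        "seed": seed,
                        "scene": scene,
                        "mask_spec": mspec,
                        "q_band": (q0 - 2 * width_r, q0 + 2 * width_r),
                    }
                )
    return out


def _battery_specs(seed: int) -> List[dict]:
    """Parameter variants for the four categories (>= 5 per category)."""
    iso = [
        dict(name=f"isotropic_{i}", category="isotropic", folds=[], features=[
            IsotropicRing(q0=q0, width=w, amplitude=a)
        ], bg=Background(constant=c, power_amp=0.0))
        for i, (q0, w, a, c) in enumerate(
            [(70, 8, 120, 60), (100, 12, 90, 80), (130, 10, 150, 50), (60, 6, 200, 70), (160, 14, 80, 90)]
        )
    ]
    peaks = [
        dict(name=f"iso_peaks_{n}", category="iso_bg_plus_peaks", folds=[n], features=[
            PeakSet(q0=q0, width_r=6.0, width_chi=wc, fold=n, amplitude=250.0, phase=ph)
        ], bg=Background(constant=80.0, power_amp=0.0))
        for n, q0, wc, ph in [(2, 90, 10, 15), (4, 110, 8, 0), (6, 100, 8, 10), (8, 120, 6, 5), (10, 100, 6, 0), (12, 130, 5, 7)]
    ]
    diffuse = [
        dict(name=f"diffuse_{i}", category="diffuse_aniso", folds=[m], features=[
            DiffuseHalo(q0=q0, width=w, amplitude=a, fold=m, depth=d, phase=ph)
        ], bg=Background(constant=40.0, power_amp=0.0))
        for i, (q0, w, a, m, d, ph) in enumerate(
            [
                (120, 70, 200, 2, 0.6, 0),
                (125, 75, 220, 2, 0.5, 30),
                (140, 80, 180, 2, 0.7, 60),
                (130, 75, 200, 2, 0.6, 100),
                (130, 70, 210, 4, 0.5, 20),
            ]
        )
    ]
    cmplx = [
        dict(name=f"complex_{i}", category="complex", folds=[2, 4, 4], features=[
            DiffuseHalo(q0=hq, width=hw, amplitude=ha, fold=2, depth=hd, phase=hph),
            # two orders of a fold-4 peak array (lattice-like), 45 deg apart
            PeakSet(q0=pq, width_r=8.0, width_chi=8.0, fold=4, amplitude=pa, phase=pph),
            PeakSet(q0=1.42 * pq, width_r=8.0, width_chi=8.0, fold=4, amplitude=0.6 * pa,
                    phase=pph + 45.0),
        ], bg=Background(constant=40.0, power_amp=0.0))
        for i, (hq, hw, ha, hd, hph, pq, pa, pph) in enumerate(
            [
                (110, 70, 200, 0.6, 0, 180, 400, 10),
                (120, 60, 220, 0.5, 45, 190, 450, 0),
                (100, 80, 180, 0.7, 90, 180, 420, 20),
                (130, 65, 200, 0.6, 20, 200, 400, 5),
                (115, 70, 200, 0.5, 70, 185, 430, 15),
            ]
        )
    ]
    return iso + peaks + diffuse + cmplx


def archetype_suite(
    seed: int = 0,
    shape: Tuple[int, int] = (512, 512),
    noise: Optional[str] = "poisson",
    exposure: float = DEFAULT_EXPOSURE,
) -> List[ArchetypeCase]:
    """The fixed validation battery: >= 5 parameter variants per category.

    Deterministic for a given seed. Each entry carries its expected category,
    the expected fold of every anisotropic feature, the ground-truth image
    and a standard mask (beamstop + module gaps + bad pixels).
    """
    scale = shape[0] / 512.0
    cases: List[ArchetypeCase] = []
    for i, spec_d in enumerate(_battery_specs(seed)):
        feats = []
        peak_ranges = []
        for f in spec_d["features"]:
            if isinstance(f, IsotropicRing):
                feats.append(IsotropicRing(f.q0 * scale, f.width * scale, f.amplitude))
            elif isinstance(f, DiffuseHalo):
                feats.append(
                    DiffuseHalo(f.q0 * scale, f.width * scale, f.amplitude, f.fold, f.depth, f.phase)
                )
                peak_ranges.append((f.q0 * scale, f.width * scale))
            elif isinstance(f, PeakSet):
                feats.append(
                    PeakSet(f.q0 * scale, f.width_r * scale, f.width_chi, f.fold, f.amplitude, f.phase)
                )
                peak_ranges.append((f.q0 * scale, f.width_r * scale))
        scene = SceneSpec(
            shape=shape,
            center=_generic_center(shape),
            features=feats,
            background=spec_d["bg"],
            noise=noise,
            exposure=exposure,
            seed=(seed * 1009 + i * 13) % (2**31 - 1),
        )
        mspec = MaskSpec(
            elements=[
                Beamstop(radius=18.0 * scale, arm_width=max(7.0 * scale, 3.0), arm_angle=270.0),
                GapBand(axis=0, start=int(170 * scale), width=max(int(9 * scale), 3)),
                GapBand(axis=1, start=int(330 * scale), width=max(int(9 * scale), 3)),
                BadPixels(count=int(200 * scale * scale)),
            ],
            seed=(seed * 733 + i * 7) % (2**31 - 1),
            center=scene.center,  # the beamstop covers the beam
        )
        render = render_scene(scene)
        mask = render_mask(mspec, shape)
        cases.append(
            ArchetypeCase(
                name=spec_d["name"],
                expected_category=spec_d["category"],
                expected_folds=spec_d["folds"],
                scene=scene,
                mask_spec=mspec,
                image=render.image,
                mask=mask,
                truth=render.truth,
                peak_ranges=peak_ranges,
            )
        )
    return cases
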