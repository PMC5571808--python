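"""Run configuration: every tunable of the workflow, with validated defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

__all__ = ["RunConfig"]

_MODES = ("auto", "isotropic", "ordered", "diffuse", "complex")


@dataclass
class RunConfig:
    """All workflow tunables.

    Defaults: 1 deg chi bins (fine enough for sharp peaks at the detector
    edge at typical frame sizes), auto q binning (one bin per pixel of
    radius), 7.5 deg local windows, per-q anisotropy threshold 0.8, 30-bin
    histograms, even fold candidates up to 12, overlap-bias exponent 0.5,
    rank-2 background, median + 3 MAD peak thresholding.
    """

    n_chi: int = 360
    n_q: Optional[int] = None
    window_deg: float = 7.5
    ratio_threshold: float = 0.8
    min_run: int = 2
    histogram_bins: int = 30
    t_iso: float = 0.8
    t_peak: float = 0.08
    t_diffuse: float = 0.7
    alpha: float = 0.5
    candidates: Tuple[int, ...] = (2, 4, 6, 8, 10, 12)
    svd_rank: int = 2
    k_mad: float = 3.0
    dilate: int = 1
    peak_filter_deg: float = 60.0
    max_iter: Optional[int] = None
    tail_fit_fraction: float = 0.15
    seed: int = 0
    mode: str = "auto"

    def validate(self) -> "RunConfig":
        if self.n_chi < 8:
            raise ValueError("n_chi must be >= 8")
        if self.n_q is not None and self.n_q < 2:
            raise ValueError("n_q must be >= 2")
        if not 0 < self.window_deg <= 360:
            raise ValueError("window_deg must be in (0, 360]")
        if not 0 < self.ratio_threshold <= 2:
            raise ValueError("ratio_threshold must be in (0, 2]")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        for n in self.candidates:
            if n < 2 or n % 2:
                raise ValueError("candidates must be even and >= 2")
            if self.n_chi % n:
                raise ValueError(f"n_chi={self.n_chi} not divisible by candidate fold {n}")
        if self.svd_rank < 1:
            raise ValueError("svd_rank must be >= 1")
        if self.dilate < 0:
            raise ValueError("dilate must be >= 0")
        if not 0 < self.tail_fit_fraction <= 0.5:
            raise ValueError("tail_fit_fraction must be in (0, 0.5]")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["candidates"] = list(self.candidates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "candidates" in d:
            d["candidates"] = tuple(int(n) for n in d["candidates"])
        return cls(**d).validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a YAML or TOML config file (chosen by extension)."""
        path = Path(path)
        if path.suffix in (".toml", ".tml"):
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            import yaml

            data = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(data)
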