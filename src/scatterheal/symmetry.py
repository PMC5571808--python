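"""Even n-fold azimuthal symmetry estimation by brute-force model comparison.

A candidate fold n splits the chi axis into n spans of 360/n degrees. The
n-fold model of a curve is the average of its n shifted copies wherever at
least one copy has data; an exactly n-fold curve is reproduced identically.
Candidates are ranked by

    delta(n) = residual(n) / (n_data * overlap(n)**alpha)

where ``residual`` is a leave-one-copy-out mean squared error (each measured
sample is compared against the mean of the *other* measured copies at the
same period cell), ``n_data`` is the number of measured chi samples in the
band and ``overlap`` is the fraction of the period where at least two copies
carry data, i.e. where model building actually averaged different parts of
the curve. The overlap term biases the selection toward higher symmetries,
which is desired: any 6-fold curve is also 2-fold, but the highest symmetry
consistent with the data is the informative one. Ties in delta are broken
toward the largest fold for the same reason.

The leave-one-out residual matters under noise: comparing a sample against a
model that contains the sample itself systematically favors low folds (the
model retains the sample's own noise), whereas cross-validating against the
other copies rewards the fold that averages the most consistent data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SymmetryScore",
    "FoldModel",
    "build_fold_model",
    "score_symmetry",
    "estimate_symmetry",
    "InsufficientCoverageError",
]

DEFAULT_CANDIDATES: Tuple[int, ...] = (2, 4, 6, 8, 10, 12)

#: residuals below this fraction of the band's mean square are numerical zero
_RESIDUAL_ZERO_REL = 1e-12
#: relative tolerance within which two deltas count as tied
_TIE_REL = 1e-9


class InsufficientCoverageError(ValueError):
    """Raised when a band has too little chi coverage for symmetry analysis."""


@dataclass
class SymmetryScore:
    n: int
    residual: float
    n_data: int
    overlap: float
    alpha: float
    delta: float

    def to_dict(self) -> dict:
        return {
            "n": int(self.n),
            "residual": float(self.residual),
            "n_data": int(self.n_data),
            "overlap": float(self.overlap),
            "alpha": float(self.alpha),
            "delta": float(self.delta),
        }


@dataclass
class FoldModel:
    """An n-fold periodic chi profile built by shifting and averaging."""

    n: int
    period_values: np.ndarray  # length n_chi // n, NaN where undefined
    period_coverage: np.ndarray

    @property
    def period(self) -> int:
        return self.period_values.size

    @property
    def full_values(self) -> np.ndarray:
        """The model tiled over the full chi axis (exactly n-fold periodic)."""
        return np.tile(self.period_values, self.n)

    @property
    def full_coverage(self) -> np.ndarray:
        return np.tile(self.period_coverage, self.n)


def _check_fold(n_chi: int, n: int) -> int:
    if n < 2 or n % 2 != 0:
        raise ValueError(f"fold must be even and >= 2, got {n}")
    if n_chi % n != 0:
        raise ValueError(f"n_chi={n_chi} not divisible by fold {n}")
    return n_chi // n


def build_fold_model(values: np.ndarray, coverage: np.ndarray, n: int) -> FoldModel:
    """Average the n shifted copies of a chi curve wherever any copy has data.

    ``values`` and ``coverage`` cover the full chi axis (length n_chi, with
    n_chi divisible by n). The model is the plain average of the available
    copies - no smoothing - and is exactly n-fold periodic by construction.
    """
    values = np.asarray(values, dtype=float)
    coverage = np.asarray(coverage, dtype=bool)
    p = _check_fold(values.size, n)
    V = np.where(coverage, values, 0.0).reshape(n, p)
    C = coverage.reshape(n, p)
    cnt = C.sum(axis=0)
    covered = cnt > 0
    period = np.full(p, np.nan)
    period[covered] = V.sum(axis=0)[covered] / cnt[covered]
    return FoldModel(n, period, covered)


def score_symmetry(
    values: np.ndarray,
    coverage: np.ndarray,
    n: int,
    alpha: float = 0.5,
) -> SymmetryScore:
    """Score a candidate fold for a chi band.

    overlap = fraction of period cells where >= 2 copies carry data (the
    relative amount of experimental data that was actually averaged when
    building the model). residual = leave-one-copy-out mean squared error
    over all such (copy, cell) samples. delta = residual / (n_data *
    overlap**alpha); infinite when overlap = 0, so candidates that involve no
    cross-checking are never selected over candidates that do.
    """
    values = np.asarray(values, dtype=float)
    coverage = np.asarray(coverage, dtype=bool)
    p = _check_fold(values.size, n)
    V = np.where(coverage, values, 0.0).reshape(n, p)
    C = coverage.reshape(n, p)
    cnt = C.sum(axis=0)
    n_data = int(coverage.sum())

    multi = cnt >= 2
    overlap = float(multi.sum()) / p

    if not multi.any():
        return SymmetryScore(n, np.nan, n_data, 0.0, alpha, np.inf)

    s = V.sum(axis=0)
    # leave-one-out prediction for every covered sample in a multi-covered cell
    with np.errstate(invalid="ignore", divide="ignore"):
        pred = (s[None, :] - V) / (cnt[None, :] - 1)
    sel = C & multi[None, :]
    err = (V[sel] - pred[sel]) ** 2
    residual = float(err.mean())

    msq = float(np.mean(values[coverage] ** 2)) if n_data else 0.0
    if residual <= _RESIDUAL_ZERO_REL * max(msq, 1e-300):
        residual = 0.0

    if overlap <= 0.0 or n_data == 0:
        delta = np.inf
    else:
        delta = residual / (n_data * overlap**alpha)
    return SymmetryScore(n, residual, n_data, overlap, alpha, delta)


def estimate_symmetry(
    values: np.ndarray,
    coverage: np.ndarray,
    candidates: Sequence[int] = DEFAULT_CANDIDATES,
    alpha: float = 0.5,
    min_coverage: float = 0.25,
    consistency_factor: float = 3.0,
) -> Tuple[int, List[SymmetryScore]]:
    """Select the highest fold consistent with the data; rank by delta otherwise.

    Point symmetry (n = 2) holds structurally for every even-fold pattern, so
    its residual is a data-driven estimate of the measurement-error floor
    (noise plus the remesh pixelation ripple). Candidates whose residual is
    within ``consistency_factor`` times that floor cannot be distinguished
    from the data's own error and count as ties; the tie-break goes to the
    largest such fold - the highest symmetry consistent with the data. When
    no candidate sits at the floor, the smallest delta wins (ties within
    1e-9 relative broken toward the largest fold). If every candidate has
    infinite delta (no copy overlap anywhere), fold 2 - the point-symmetry
    minimum - is returned, since nothing higher can be cross-checked.
    """
    coverage = np.asarray(coverage, dtype=bool)
    frac = float(coverage.mean())
    if frac < min_coverage:
        raise InsufficientCoverageError(
            f"insufficient coverage for symmetry analysis ({frac:.1%} < {min_coverage:.0%})"
        )
    scores = [score_symmetry(values, coverage, n, alpha=alpha) for n in candidates]
    finite = [s for s in scores if np.isfinite(s.delta)]
    if not finite:
        return 2, scores

    by_n = {s.n: s for s in finite}
    base = by_n[2].residual if 2 in by_n else min(s.residual for s in finite)
    floor = consistency_factor * base
    consistent = [s.n for s in finite if s.residual <= floor]
    if consistent:
        return max(consistent), scores

    dmin = min(s.delta for s in finite)
    tied = [s.n for s in finite if s.delta <= dmin * (1.0 + _TIE_REL)]
    return max(tied), scores
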