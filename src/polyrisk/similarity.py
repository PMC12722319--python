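"""Weighted cross-correlation (de Gelder-type) powder-pattern similarity.

Two diffractograms are compared through

    S(p, q) = Σ_r w(r)·c_pq(r) / √(Σ_r w(r)·c_pp(r) · Σ_r w(r)·c_qq(r))

where c_pq(r) is the discrete cross-correlation of the two intensity curves
at 2θ offset r and w is a triangular weight w(r) = max(0, 1 − |r|/l) of
half-width l.  The triangular window makes the score tolerant to small peak
displacements (zero-point error, modest cell-parameter error between a
predicted and a measured structure), which plain point-by-point correlation
is not.  S is symmetric, invariant to positive rescaling of either curve,
and equals 1 only for proportional curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .errors import UndefinedSimilarityError
from .xrpd import PowderPattern, simulate_pattern

__all__ = [
    "SimilarityParams",
    "MatchResult",
    "preprocess",
    "cross_correlation_similarity",
    "rank_candidates",
]


@dataclass(frozen=True)
class SimilarityParams:
    """Knobs of the pattern-matching stage.

    weight_width_l: triangular-weight half-width in degrees 2θ.  1.5° is the
        conventional choice and absorbs small peak shifts.
    background_degree: degree of the polynomial baseline removed before
        scoring (0 = constant).
    grid_step: common resampling step in degrees 2θ.
    """

    weight_width_l: float = 1.5
    background_degree: int = 0
    grid_step: float = 0.02

    def __post_init__(self):
        if self.weight_width_l <= 0 or self.grid_step <= 0:
            raise ValueError("weight_width_l and grid_step must be positive")
        if self.background_degree < 0:
            raise ValueError("background_degree must be >= 0")


@dataclass(frozen=True)
class MatchResult:
    candidate_id: str
    score: float
    rank: int


def _baseline(grid: np.ndarray, y: np.ndarray, degree: int, n_iter: int = 100) -> np.ndarray:
    """Iteratively clamped least-squares polynomial baseline.

    Fit a polynomial, then refit using only points at or below the current
    fit; peaks are progressively excluded so the polynomial settles on the
    smooth background rather than the mean of the whole curve.
    """
    mask = np.ones_like(y, dtype=bool)
    fit = np.zeros_like(y)
    for _ in range(n_iter):
        coeffs = np.polynomial.polynomial.polyfit(grid[mask], y[mask], degree)
        fit = np.polynomial.polynomial.polyval(grid, coeffs)
        new_mask = y <= fit + 1e-12
        if new_mask.sum() <= degree + 1 or np.array_equal(new_mask, mask):
            break
        mask = new_mask
    return fit


def preprocess(
    pattern: PowderPattern,
    params: SimilarityParams = SimilarityParams(),
    grid: Optional[np.ndarray] = None,
) -> PowderPattern:
    """Resample onto a common grid, strip the baseline, clip, scale to unit area."""
    if len(pattern.two_theta) < 10:
        raise ValueError("pattern needs at least 10 grid points")
    if grid is None:
        lo, hi = pattern.two_theta[0], pattern.two_theta[-1]
        grid = np.arange(lo, hi + params.grid_step / 2.0, params.grid_step)
    lo_ov = max(grid[0], pattern.two_theta[0])
    hi_ov = min(grid[-1], pattern.two_theta[-1])
    if hi_ov <= lo_ov:
        raise ValueError(
            f"no overlap between pattern range ({pattern.two_theta[0]:.2f}–"
            f"{pattern.two_theta[-1]:.2f}°) and target grid"
        )
    y = np.interp(grid, pattern.two_theta, pattern.intensity, left=0.0, right=0.0)
    y = y - _baseline(grid, y, params.background_degree)
    y = np.clip(y, 0.0, None)
    area = np.trapezoid(y, grid)
    if area > 0:
        y = y / area
    return PowderPattern(grid, y, pattern.wavelength)


def cross_correlation_similarity(
    p: PowderPattern, q: PowderPattern, params: SimilarityParams = SimilarityParams()
) -> float:
    """Triangular-weighted cross-correlation similarity of two patterns.

    Both patterns must be sampled on the same uniform grid (use
    :func:`preprocess`).  Returns a score in [−1, 1]; for non-negative
    intensity curves the effective range is [0, 1] with 1 for proportional
    curves.
    """
    if len(p.two_theta) != len(q.two_theta) or not np.allclose(
        p.two_theta, q.two_theta, atol=1e-9
    ):
        raise ValueError("patterns must share the same 2theta grid; preprocess first")
    step = float(np.mean(np.diff(p.two_theta)))
    a, b = p.intensity, q.intensity
    if not a.any() or not b.any():
        raise UndefinedSimilarityError("similarity undefined for an all-zero pattern")
    m = int(params.weight_width_l / step)

    def weighted(u: np.ndarray, v: np.ndarray) -> float:
        total = float(u @ v)  # offset 0, weight 1
        for r in range(1, m + 1):
            w = 1.0 - r * step / params.weight_width_l
            if w <= 0:
                break
            total += w * (float(u[:-r] @ v[r:]) + float(u[r:] @ v[:-r]))
        return total

    num = weighted(a, b)
    den = weighted(a, a) * weighted(b, b)
    return num / np.sqrt(den)


def rank_candidates(
    experimental: PowderPattern,
    candidates: Mapping[str, "object"],
    sim_params: SimilarityParams = SimilarityParams(),
    **pattern_kwargs,
) -> list:
    """Rank candidate crystal structures against an experimental pattern.

    Each candidate is simulated at the experimental wavelength over the
    experimental 2θ range, both sides are preprocessed identically, and the
    weighted cross-correlation score is computed.  Results are sorted by
    descending score with ties broken by candidate id; candidates whose
    simulation fails are recorded with score NaN and ranked last.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    tt = experimental.two_theta
    grid = np.arange(tt[0], tt[-1] + sim_params.grid_step / 2.0, sim_params.grid_step)
    exp_p = preprocess(experimental, sim_params, grid=grid)
    pattern_kwargs.setdefault("wavelength", experimental.wavelength)
    pattern_kwargs.setdefault("two_theta_range", (float(tt[0]), float(tt[-1])))

    scored = []
    for cid, structure in candidates.items():
        try:
            sim = simulate_pattern(structure, **pattern_kwargs)
            cand_p = preprocess(sim, sim_params, grid=grid)
            score = cross_correlation_similarity(exp_p, cand_p, sim_params)
        except Exception as exc:  # noqa: BLE001 - isolate per-candidate failures
            warnings.warn(f"candidate {cid!r} failed: {exc}", stacklevel=2)
            score = float("nan")
        scored.append((cid, score))

    def sort_key(item):
        cid, score = item
        return (np.isnan(score), -score if not np.isnan(score) else 0.0, cid)

    scored.sort(key=sort_key)
    return [
        MatchResult(candidate_id=cid, score=score, rank=i + 1)
        for i, (cid, score) in enumerate(scored)
    ]
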