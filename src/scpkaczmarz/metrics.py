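"""Quantitative metrics comparing a reconstruction x_r to a ground truth x_t."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError, UndefinedMetricError

__all__ = [
    "EvaluationReport",
    "relative_deviation",
    "dice_coefficient",
    "support_dice",
    "localization_error",
    "evaluate",
]


def _pair(x_r, x_t) -> tuple[np.ndarray, np.ndarray]:
    x_r = np.asarray(x_r, dtype=float).ravel()
    x_t = np.asarray(x_t, dtype=float).ravel()
    if x_r.shape != x_t.shape:
        raise ShapeError(f"length mismatch: {x_r.size} vs {x_t.size}")
    return x_r, x_t


def relative_deviation(x_r, x_t) -> float:
    """delta = ||x_r - x_t||_2 / ||x_t||_2 (the primary accuracy metric)."""
    x_r, x_t = _pair(x_r, x_t)
    denom = np.linalg.norm(x_t)
    if denom == 0.0:
        raise UndefinedMetricError("relative deviation undefined for zero ground truth")
    return float(np.linalg.norm(x_r - x_t) / denom)


def dice_coefficient(x_r, x_t) -> float:
    """D = 2 ||x_r o x_t||_2 / (||x_r||_2^2 ||x_t||_2^2), with o the Hadamard product.

    This is the intensity-weighted overlap score as conventionally reported for
    this reconstruction problem.  Note that it is not bounded by 1 (two
    coincident unit impulses give D = 2) and scales inversely with the
    amplitude of either argument; for a bounded support-overlap score use
    :func:`support_dice`.
    """
    x_r, x_t = _pair(x_r, x_t)
    nr, nt = np.linalg.norm(x_r), np.linalg.norm(x_t)
    if nr == 0.0 or nt == 0.0:
        raise UndefinedMetricError("Dice coefficient undefined for a zero vector")
    return float(2.0 * np.linalg.norm(x_r * x_t) / (nr**2 * nt**2))


def support_dice(x_r, x_t, rel_threshold: float = 0.5) -> float:
    """Conventional support-overlap Dice 2|S_r ∩ S_t| / (|S_r| + |S_t|) in [0, 1].

    The support of a vector is the set of entries strictly above
    rel_threshold * max(vector).  The default of 0.5 is the full-width-at-
    half-maximum convention for delineating a reconstructed target; for a
    binary phantom it reduces to the set of nonzero nodes.  Pass 0 to count
    every strictly positive entry instead.
    """
    x_r, x_t = _pair(x_r, x_t)

    def support(v: np.ndarray) -> np.ndarray:
        mx = np.max(v)
        if mx <= 0:
            raise UndefinedMetricError("support undefined: no positive entry")
        return v > rel_threshold * mx

    s_r, s_t = support(x_r), support(x_t)
    return float(2.0 * np.sum(s_r & s_t) / (np.sum(s_r) + np.sum(s_t)))


def localization_error(x_r, x_t, grid) -> float:
    """Distance (mm) between the intensity-weighted centres of mass of x_r and x_t.

    Negative entries carry no weight; both vectors must have a positive entry.
    """
    x_r, x_t = _pair(x_r, x_t)
    coords = grid.node_coordinates()
    if coords.shape[0] != x_r.size:
        raise ShapeError(
            f"grid has {coords.shape[0]} nodes but vectors have {x_r.size} entries"
        )

    def com(v: np.ndarray) -> np.ndarray:
        w = np.clip(v, 0.0, None)
        total = w.sum()
        if total <= 0:
            raise UndefinedMetricError("centre of mass undefined: no positive entry")
        return (w[:, None] * coords).sum(axis=0) / total

    return float(np.linalg.norm(com(x_r) - com(x_t)))


@dataclass(frozen=True)
class EvaluationReport:
    """Bundle of reconstruction-quality metrics for one (x_r, x_t) pair."""

    relative_deviation: float
    dice: float
    support_dice: float
    sparsity: float
    localization_error: float | None = None


def evaluate(x_r, x_t, grid=None) -> EvaluationReport:
    """Compute all metrics at once; localisation error only when a grid is given."""
    from .solve import hoyer_sparsity  # local import to avoid a cycle

    return EvaluationReport(
        relative_deviation=relative_deviation(x_r, x_t),
        dice=dice_coefficient(x_r, x_t),
        support_dice=support_dice(x_r, x_t),
        sparsity=hoyer_sparsity(x_r),
        localization_error=None if grid is None else localization_error(x_r, x_t, grid),
    )
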