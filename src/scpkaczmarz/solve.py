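"""Kaczmarz solvers and the sparsity-constrained preconditioned driver.

The classical Kaczmarz method (ART) cyclically projects the iterate onto the
hyperplane of each equation in sequential row order,

    x <- x + B_i^T (y_i - B_i x) / (B_i B_i^T),   i = 1 .. M,

one full sweep over all rows counting as one iteration.  The SCP-Kaczmarz
driver preconditions the system so the rows are (near-)orthogonal — after
which a single sweep solves a consistent full-rank system exactly — and after
every sweep thresholds the iterate so its Hoyer sparsity matches a preset
wanted value psi, which also enforces nonnegativity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidParameterError, ShapeError
from .forward import SensitivityMatrix
from .metrics import dice_coefficient, relative_deviation, support_dice
from .precondition import apply_preconditioner, compute_preconditioner

__all__ = [
    "SolverConfig",
    "IterationTrace",
    "kaczmarz_sweep",
    "hoyer_sparsity",
    "sparsity_threshold",
    "find_beta",
    "scp_kaczmarz",
    "classical_kaczmarz",
    "wanted_sparsity_from_fraction",
]

#: Rows whose norm falls below this fraction of the largest row norm are skipped.
_ROW_SKIP_REL = 1e-14


@dataclass
class SolverConfig:
    """Solver parameters.

    wanted_sparsity : psi in (0, 1], the Hoyer sparsity enforced on each iterate.
    max_iterations  : K_iter, cap on the number of full sweeps.
    tolerance       : epsilon for the update-norm stop rule ||x^k - x^(k-1)|| < eps.
    initial_x       : starting iterate (defaults to zeros).
    apply_sparsity_constraint : off = plain Kaczmarz iteration (no thresholding).
    record_iterates : keep a copy of every post-threshold iterate in the trace.
    """

    wanted_sparsity: float = 0.9
    max_iterations: int = 100
    tolerance: float = 1e-6
    access_order: str = "sequential"
    initial_x: np.ndarray | None = None
    apply_sparsity_constraint: bool = True
    record_iterates: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.wanted_sparsity <= 1.0:
            raise InvalidParameterError(
                f"wanted_sparsity must be in (0, 1], got {self.wanted_sparsity}"
            )
        if self.max_iterations < 1:
            raise InvalidParameterError(
                f"max_iterations must be >= 1, got {self.max_iterations}"
            )
        if self.tolerance < 0:
            raise InvalidParameterError(f"tolerance must be >= 0, got {self.tolerance}")
        if self.access_order != "sequential":
            raise InvalidParameterError(
                f"only sequential access order is supported, got {self.access_order!r}"
            )


@dataclass
class IterationTrace:
    """Per-sweep diagnostics: the quantities the convergence claims are judged on."""

    iteration: list[int] = field(default_factory=list)
    delta: list[float] = field(default_factory=list)
    dice: list[float] = field(default_factory=list)
    sparsity: list[float] = field(default_factory=list)
    update_norm: list[float] = field(default_factory=list)
    beta: list[float] = field(default_factory=list)
    support_dice: list[float] = field(default_factory=list)
    iterates: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.iteration)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.iteration,
                "delta": self.delta,
                "dice": self.dice,
                "sparsity": self.sparsity,
                "update_norm": self.update_norm,
                "beta": self.beta,
            }
        )

    def first_iteration_below(self, delta_star: float) -> int | None:
        """Earliest sweep index with relative deviation <= delta_star, or None."""
        for k, d in zip(self.iteration, self.delta):
            if not math.isnan(d) and d <= delta_star:
                return k
        return None


def kaczmarz_sweep(B: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """One full sequential Kaczmarz sweep over all rows of B x = y.

    Rows with norm below 1e-14 times the largest row norm are skipped.
    Returns a new vector; the input iterate is not modified.
    """
    B = np.asarray(B, dtype=float)
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if B.shape[0] != y.shape[0] or B.shape[1] != x.shape[0]:
        raise ShapeError(
            f"incompatible shapes: B {B.shape}, y {y.shape}, x {x.shape}"
        )
    sq_norms = np.einsum("ij,ij->i", B, B)
    max_sq = sq_norms.max() if sq_norms.size else 0.0
    if max_sq == 0.0:
        raise DegenerateInputError("all rows of B are zero")
    skip = sq_norms < (_ROW_SKIP_REL**2) * max_sq
    x = x.copy()
    for i in range(B.shape[0]):
        if skip[i]:
            continue
        r = y[i] - B[i] @ x
        x += (r / sq_norms[i]) * B[i]
    return x


def hoyer_sparsity(x: np.ndarray) -> float:
    """Hoyer sparseness measure (sqrt(N) - ||x||_1 / ||x||_2) / (sqrt(N) - 1).

    Ranges from 0 (all entries equal in magnitude) to 1 (a single nonzero).
    Undefined for the all-zero vector or for fewer than two entries.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise InvalidParameterError(f"need at least 2 entries, got {x.size}")
    l2 = np.linalg.norm(x)
    if l2 == 0.0:
        raise DegenerateInputError("sparsity is undefined for the all-zero vector")
    sqrt_n = math.sqrt(x.size)
    return float((sqrt_n - np.abs(x).sum() / l2) / (sqrt_n - 1.0))


def sparsity_threshold(x: np.ndarray, beta: float) -> np.ndarray:
    """Hard threshold: keep x_n where x_n >= beta * max(x), zero the rest.

    The comparison is on signed values, so with max(x) > 0 and beta > 0 every
    negative entry is zeroed — the step doubles as a nonnegativity projection.
    At beta = 0 the threshold is 0 whatever max(x) is, so negative entries are
    zeroed there too.
    """
    if not 0.0 <= beta <= 1.0:
        raise InvalidParameterError(f"beta must be in [0, 1], got {beta}")
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InvalidParameterError("x must be nonempty")
    return np.where(x >= beta * np.max(x), x, 0.0)


def _threshold_candidates(x: np.ndarray):
    """Sorted positive entries and the achievable top-m support sizes.

    A support cutting through a group of tied values cannot be realised by any
    single threshold, so only tie-group boundaries are candidates.
    """
    pos = np.sort(x[x > 0])[::-1]
    if pos.size == 0:
        return pos, None, None, None
    achievable = np.empty(pos.size, dtype=bool)
    achievable[:-1] = pos[:-1] > pos[1:]
    achievable[-1] = True
    l1 = np.cumsum(pos)
    l2 = np.sqrt(np.cumsum(pos**2))
    return pos, achievable, l1, l2


def find_beta(x: np.ndarray, psi: float) -> tuple[float, np.ndarray]:
    """Threshold level beta whose result best matches the wanted sparsity psi.

    Minimises |sparsity(threshold(x, beta)) - psi| over the discrete candidate
    set induced by the sorted positive entries of x (support = top-m positive
    entries, evaluated via cumulative-norm identities).  Ties break toward the
    sparser result (larger beta).  The thresholded vector is computed with the
    exact cutoff value, so tied boundary entries are retained regardless of
    floating-point rounding in beta itself.

    With no positive entry the threshold is degenerate: a warning is emitted
    and (1.0, zero vector) returned.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InvalidParameterError(f"need at least 2 entries, got {x.size}")
    if not 0.0 < psi <= 1.0:
        raise InvalidParameterError(f"psi must be in (0, 1], got {psi}")
    if not np.any(x):
        raise DegenerateInputError("cannot threshold the all-zero vector")

    pos, achievable, l1, l2 = _threshold_candidates(x)
    if pos.size == 0:
        warnings.warn(
            "no positive entry to retain; returning the zero vector", RuntimeWarning
        )
        return 1.0, np.zeros_like(x)

    sqrt_n = math.sqrt(x.size)
    sparsities = (sqrt_n - l1 / l2) / (sqrt_n - 1.0)
    objective = np.abs(sparsities - psi)
    objective[~achievable] = np.inf
    m_best = int(np.argmin(objective))  # first minimum = largest beta
    cutoff = pos[m_best]
    beta = float(cutoff / pos[0])
    return beta, np.where(x >= cutoff, x, 0.0)


def wanted_sparsity_from_fraction(fraction: float, N: int) -> float:
    """Wanted sparsity psi from an estimated target-to-domain volume fraction.

    Assumes the fluorescent target is uniformly distributed over
    round(fraction * N) nodes (at least 1):
    psi = (sqrt(N) - sqrt(round(fraction * N))) / (sqrt(N) - 1).
    """
    if not 0.0 < fraction <= 1.0:
        raise InvalidParameterError(f"fraction must be in (0, 1], got {fraction}")
    if N < 2:
        raise InvalidParameterError(f"N must be >= 2, got {N}")
    k = min(max(int(round(fraction * N)), 1), N)
    sqrt_n = math.sqrt(N)
    return float((sqrt_n - math.sqrt(k)) / (sqrt_n - 1.0))


def _as_matrix(A) -> np.ndarray:
    if isinstance(A, SensitivityMatrix):
        return A.entries
    return np.asarray(A, dtype=float)


def _iterate(
    B: np.ndarray,
    y: np.ndarray,
    config: SolverConfig,
    constrain: bool,
    x_true: np.ndarray | None,
) -> tuple[np.ndarray, IterationTrace]:
    """Shared sweep/threshold loop with per-iteration diagnostics."""
    N = B.shape[1]
    x = np.zeros(N) if config.initial_x is None else np.asarray(config.initial_x, float).copy()
    if x.shape != (N,):
        raise ShapeError(f"initial_x has shape {x.shape}, expected ({N},)")
    trace = IterationTrace()
    for k in range(1, config.max_iterations + 1):
        x_new = kaczmarz_sweep(B, y, x)
        beta = math.nan
        if constrain:
            beta, x_new = find_beta(x_new, config.wanted_sparsity)
        upd = float(np.linalg.norm(x_new - x))
        trace.iteration.append(k)
        trace.update_norm.append(upd)
        trace.beta.append(beta)
        trace.sparsity.append(hoyer_sparsity(x_new) if np.any(x_new) else math.nan)
        if x_true is not None:
            trace.delta.append(relative_deviation(x_new, x_true))
            trace.dice.append(
                dice_coefficient(x_new, x_true) if np.any(x_new) else math.nan
            )
            trace.support_dice.append(
                support_dice(x_new, x_true) if np.any(x_new) else math.nan
            )
        else:
            trace.delta.append(math.nan)
            trace.dice.append(math.nan)
            trace.support_dice.append(math.nan)
        if config.record_iterates:
            trace.iterates.append(x_new.copy())
        x = x_new
        if upd < config.tolerance:
            break
    return x, trace


def scp_kaczmarz(
    A,
    phi_m: np.ndarray,
    config: SolverConfig | None = None,
    loading: float | str = 0.0,
    x_true: np.ndarray | None = None,
    precondition: bool = True,
    rank_tol: float | None = None,
) -> tuple[np.ndarray, IterationTrace]:
    """Sparsity-constrained preconditioned Kaczmarz reconstruction.

    Computes W and B = W A from the SVD of A, preconditions the measurements
    (y = W phi_m), then alternates one full Kaczmarz sweep with a
    sparsity-matched thresholding to the wanted sparsity psi until the sweep
    cap K_iter is reached or the update norm drops below the tolerance.

    ``rank_tol`` passes a relative spectral-truncation level to the
    preconditioner; for noisy measurements use
    :func:`scpkaczmarz.precondition.noise_adapted_rank_tol`.

    With ``precondition=False`` (W = I) and the sparsity constraint switched
    off in ``config``, the driver reduces exactly to the classical Kaczmarz
    baseline.
    """
    config = config or SolverConfig()
    mat = _as_matrix(A)
    phi_m = np.asarray(phi_m, dtype=float)
    if phi_m.shape != (mat.shape[0],):
        raise ShapeError(
            f"phi_m has shape {phi_m.shape}, expected ({mat.shape[0]},) to match A"
        )
    if precondition:
        system = apply_preconditioner(
            compute_preconditioner(mat, loading, rank_tol=rank_tol), phi_m
        )
        B, y = system.B, system.y
    else:
        B, y = mat, phi_m
    return _iterate(B, y, config, config.apply_sparsity_constraint, x_true)


def classical_kaczmarz(
    A,
    phi_m: np.ndarray,
    config: SolverConfig | None = None,
    x_true: np.ndarray | None = None,
) -> tuple[np.ndarray, IterationTrace]:
    """Classical sequential Kaczmarz baseline: no preconditioning, no thresholding.

    Shares the stopping rules and trace of the SCP driver.  From x0 = 0 on a
    consistent system it converges to the minimum-norm solution.
    """
    config = config or SolverConfig()
    mat = _as_matrix(A)
    phi_m = np.asarray(phi_m, dtype=float)
    if phi_m.shape != (mat.shape[0],):
        raise ShapeError(
            f"phi_m has shape {phi_m.shape}, expected ({mat.shape[0]},) to match A"
        )
    return _iterate(mat, phi_m, config, constrain=False, x_true=x_true)
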