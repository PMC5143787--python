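"""Row-orthogonalising SVD preconditioner for the forward matrix.

Given A = U S V^T, the preconditioner W = (S S^T + lambda I)^(-1/2) U^T makes
the rows of B = W A mutually orthogonal when lambda = 0 and A has full row
rank: B B^T = I_M.  With a rank-deficient A the zero singular directions are
handled with the pseudo-inverse convention, and B B^T is the orthogonal
projection onto the row space.  Diagonal loading (lambda > 0) damps the
amplification of near-null measurement directions, at the price of only
approximate row orthogonality.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidParameterError, ShapeError

__all__ = [
    "PreconditionedSystem",
    "compute_preconditioner",
    "apply_preconditioner",
    "row_coherence",
]


@dataclass(frozen=True)
class PreconditionedSystem:
    """The preconditioned linear system B x = y with B = W A, y = W phi_m."""

    W: np.ndarray
    B: np.ndarray
    loading: float
    row_norms: np.ndarray
    y: np.ndarray | None = None

    @property
    def n_rows(self) -> int:
        return self.B.shape[0]


def compute_preconditioner(
    A: np.ndarray, loading: float | str = 0.0, rank_tol: float | None = None
) -> PreconditionedSystem:
    """Compute W = (S S^T + lambda I_M)^(-1/2) U^T and B = W A from the SVD of A.

    Parameters
    ----------
    A : (M, N) array
        Forward matrix; must not be all zero.
    loading : float or "auto"
        Diagonal-loading constant lambda >= 0.  ``"auto"`` selects
        lambda = 1e-6 * sigma_max^2.  Note that a Kaczmarz projection is
        invariant to the row scaling loading induces, so for a row-action
        solver loading acts only through the rows it (together with
        ``rank_tol``) effectively removes.
    rank_tol : float, optional
        Relative spectral truncation: singular values below
        rank_tol * sigma_max are treated as exactly zero and their reciprocal
        square roots set to zero (truncated-SVD / pseudo-inverse convention),
        giving zero rows in B that the sweep skips.  Defaults to the
        numerical-rank rule max(M, N) * eps, which only removes numerically
        zero directions; noisy data calls for a coarser truncation (see
        :func:`noise_adapted_rank_tol`).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ShapeError(f"A must be 2-D, got shape {A.shape}")
    if not np.any(A):
        raise DegenerateInputError("A is all zero; no preconditioner exists")

    M, N = A.shape
    U, s, _ = np.linalg.svd(A, full_matrices=True)
    smax = s[0]
    if loading == "auto":
        loading = 1e-6 * smax**2
    if not isinstance(loading, (int, float)) or loading < 0:
        raise InvalidParameterError(f"loading must be >= 0 or 'auto', got {loading!r}")
    if rank_tol is None:
        rank_tol = max(M, N) * np.finfo(float).eps
    if rank_tol < 0:
        raise InvalidParameterError(f"rank_tol must be >= 0, got {rank_tol}")

    # Squared singular values on the diagonal of S S^T (length M, zero-padded).
    s2 = np.zeros(M)
    s2[: s.size] = s**2
    keep = np.sqrt(s2) > rank_tol * smax
    if loading == 0.0:
        d = np.where(keep, 1.0 / np.sqrt(np.where(s2 > 0, s2, 1.0)), 0.0)
    else:
        d = np.where(keep, 1.0 / np.sqrt(s2 + loading), 0.0)

    W = d[:, None] * U.T
    B = W @ A
    row_norms = np.linalg.norm(B, axis=1)
    return PreconditionedSystem(W=W, B=B, loading=float(loading), row_norms=row_norms)


def noise_adapted_rank_tol(
    A: np.ndarray, phi_m: np.ndarray, noise_sigma: float, safety: float = 1.0
) -> float:
    """Relative truncation level chosen by the discrepancy principle.

    Keeps the smallest number of singular directions r such that the truncated
    reconstruction fits the data to within the noise:
    ||phi_m - A x_r||_2 <= safety * sqrt(M) * noise_sigma.  Returns a
    ``rank_tol`` for :func:`compute_preconditioner` that retains exactly those
    r directions.  Directions beyond r carry spectral coefficients at or below
    the noise floor; projecting onto their hyperplanes amplifies noise by
    1/sigma_i without adding information.
    """
    A = np.asarray(A, dtype=float)
    phi_m = np.asarray(phi_m, dtype=float)
    if phi_m.shape != (A.shape[0],):
        raise ShapeError(f"phi_m has shape {phi_m.shape}, expected ({A.shape[0]},)")
    if noise_sigma <= 0:
        raise InvalidParameterError(f"noise_sigma must be > 0, got {noise_sigma}")
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    proj = U.T @ phi_m
    # Residual of the rank-r truncated solution is the discarded tail energy.
    tail = np.sqrt(np.concatenate([np.cumsum(proj[::-1] ** 2)[::-1], [0.0]]))
    target = safety * np.sqrt(A.shape[0]) * noise_sigma
    r = int(np.argmax(tail <= target))
    r = max(min(r, s.size - 1), 1)
    # Midpoint between the last kept and first dropped singular value.
    return float(0.5 * (s[r - 1] + s[r]) / s[0])


def apply_preconditioner(
    system: PreconditionedSystem, phi_m: np.ndarray
) -> PreconditionedSystem:
    """Attach the preconditioned measurement vector y = W phi_m to the system."""
    phi_m = np.asarray(phi_m, dtype=float)
    if phi_m.shape != (system.W.shape[1],):
        raise ShapeError(
            f"phi_m has shape {phi_m.shape}, expected ({system.W.shape[1]},)"
        )
    return dataclasses.replace(system, y=system.W @ phi_m)


def row_coherence(Mtx: np.ndarray) -> float:
    """Maximum absolute cosine similarity between distinct nonzero rows, in [0, 1].

    Rows with zero norm are skipped; fewer than two nonzero rows is degenerate.
    """
    Mtx = np.asarray(Mtx, dtype=float)
    norms = np.linalg.norm(Mtx, axis=1)
    keep = norms > 0
    if np.count_nonzero(keep) < 2:
        raise DegenerateInputError("row_coherence needs at least two nonzero rows")
    R = Mtx[keep] / norms[keep, None]
    Gram = R @ R.T
    np.fill_diagonal(Gram, 0.0)
    return float(np.min([np.max(np.abs(Gram)), 1.0]))
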