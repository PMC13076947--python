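"""Tensor algebra: mode-n products, unfoldings, and Tucker factorization.

The interaction tensor of a cell line (drugs x drugs x interaction-types) is
factorized as ``A ~ G x1 U x2 V x3 J`` with a small core ``G`` and
column-orthonormal factor matrices.  The mode-1 factor ``U`` — the left
singular vectors of the mode-1 unfolding — is the *global* drug embedding:
each drug's row summarizes its interaction profile across partners and
interaction types.

Factors are computed by higher-order SVD (HOSVD), i.e. a truncated SVD per
mode unfolding, with an optional HOOI (alternating least squares) refinement.
A fixed sign convention (largest-magnitude entry of each singular vector made
positive) keeps results deterministic across platforms.

Unfolding layout: mode-n unfolding maps element ``(i_1, ..., i_N)`` to row
``i_n`` and the column indexed by the remaining indices in increasing-mode
order with the earliest mode varying fastest (Fortran order).  For the mode-1
unfolding of an (n, n, 3) tensor this sends ``A[i, j, k]`` to row ``i``,
column ``j + n*k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` unfolding (rows index ``mode``; columns in Fortran order)."""
    return np.reshape(np.moveaxis(tensor, mode, 0), (tensor.shape[mode], -1), order="F")


def fold(matrix: np.ndarray, mode: int, shape: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of final shape ``shape``."""
    moved = [shape[mode]] + [s for k, s in enumerate(shape) if k != mode]
    return np.moveaxis(np.reshape(matrix, moved, order="F"), 0, mode)


def mode_n_product(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Multiply ``tensor`` by ``matrix`` along ``mode``.

    ``matrix`` must have as many columns as the tensor's extent along
    ``mode``; the result's extent along ``mode`` is the matrix row count.
    """
    tensor = np.asarray(tensor, dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError(f"mode-{mode} product needs a matrix, got shape {matrix.shape}")
    if matrix.shape[1] != tensor.shape[mode]:
        raise ValueError(
            f"mode-{mode} product mismatch: matrix {matrix.shape} vs "
            f"tensor {tensor.shape}"
        )
    new_shape = list(tensor.shape)
    new_shape[mode] = matrix.shape[0]
    return fold(matrix @ unfold(tensor, mode), mode, tuple(new_shape))


def _sign_fix(u: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    u = u.copy()
    for c in range(u.shape[1]):
        col = u[:, c]
        k = int(np.argmax(np.abs(col)))
        if col[k] < 0:
            u[:, c] = -col
    return u


def _mode_factor(tensor: np.ndarray, mode: int, rank: int) -> np.ndarray:
    """Top-``rank`` left singular vectors of the mode unfolding, sign-fixed.

    A zero unfolding has no preferred directions; canonical identity columns
    are returned so the result is still deterministic and orthonormal.
    """
    m = unfold(tensor, mode)
    if not np.any(m):
        return np.eye(m.shape[0], rank)
    u, _, _ = scipy.linalg.svd(m, full_matrices=False, lapack_driver="gesvd")
    return _sign_fix(u[:, :rank])


@dataclass
class TuckerFactors:
    """Core tensor and the three mode factor matrices of a Tucker model."""

    core: np.ndarray  # (R1, R2, R3)
    U: np.ndarray     # (n, R1) — global drug feature
    V: np.ndarray     # (n, R2)
    J: np.ndarray     # (3, R3)
    ranks: tuple[int, int, int]

    def reconstruct(self) -> np.ndarray:
        out = mode_n_product(self.core, self.U, 0)
        out = mode_n_product(out, self.V, 1)
        return mode_n_product(out, self.J, 2)

    def relative_error(self, tensor: np.ndarray) -> float:
        denom = np.linalg.norm(tensor)
        if denom == 0:
            return 0.0
        return float(np.linalg.norm(tensor - self.reconstruct()) / denom)


def _validate(tensor: np.ndarray, ranks) -> tuple[int, ...]:
    tensor = np.asarray(tensor, dtype=float)
    if not np.isfinite(tensor).all():
        raise ValueError("tensor has non-finite entries")
    ranks = tuple(int(r) for r in ranks)
    if len(ranks) != tensor.ndim:
        raise ValueError(f"need {tensor.ndim} ranks, got {len(ranks)}")
    for mode, (r, s) in enumerate(zip(ranks, tensor.shape)):
        if not 1 <= r <= s:
            raise ValueError(f"rank {r} invalid for mode {mode} of extent {s}")
    return ranks


def tucker_decompose(tensor: np.ndarray, ranks, hooi_iters: int = 0) -> TuckerFactors:
    """HOSVD Tucker factorization with optional HOOI refinement.

    At full ranks the reconstruction is exact (up to numerical error); at
    reduced ranks HOSVD is quasi-optimal — the squared reconstruction error
    is bounded by the sum over modes of discarded singular-value energies.
    Deterministic under the column sign convention.
    """
    tensor = np.asarray(tensor, dtype=float)
    ranks = _validate(tensor, ranks)
    factors = [_mode_factor(tensor, mode, r) for mode, r in enumerate(ranks)]
    for _ in range(hooi_iters):
        for mode in range(tensor.ndim):
            partial = tensor
            for other in range(tensor.ndim):
                if other != mode:
                    partial = mode_n_product(partial, factors[other].T, other)
            factors[mode] = _mode_factor(partial, mode, ranks[mode])
    core = tensor
    for mode in range(tensor.ndim):
        core = mode_n_product(core, factors[mode].T, mode)
    return TuckerFactors(core, factors[0], factors[1], factors[2], ranks)


def global_features(tensor: np.ndarray, r1: int,
                    algorithm: str = "truncated_svd") -> np.ndarray:
    """Global drug embedding: mode-1 factor of the interaction tensor.

    ``truncated_svd`` (default) computes only the mode-1 factor from the
    mode-1 unfolding; ``hosvd``/``hooi`` run the full factorization and
    return its mode-1 factor.
    """
    tensor = np.asarray(tensor, dtype=float)
    n = tensor.shape[0]
    if not 1 <= r1 <= n:
        raise ValueError(f"R1={r1} must lie in [1, {n}]")
    if not np.isfinite(tensor).all():
        raise ValueError("tensor has non-finite entries")
    if algorithm == "truncated_svd":
        return _mode_factor(tensor, 0, r1)
    if algorithm in ("hosvd", "hooi"):
        ranks = (r1, min(r1, tensor.shape[1]), min(3, tensor.shape[2]))
        iters = 5 if algorithm == "hooi" else 0
        return tucker_decompose(tensor, ranks, hooi_iters=iters).U
    raise ValueError(f"unknown algorithm {algorithm!r}")


def save_factors(path, factors: TuckerFactors) -> None:
    np.savez(path, core=factors.core, U=factors.U, V=factors.V, J=factors.J,
             ranks=np.asarray(factors.ranks))


def load_factors(path) -> TuckerFactors:
    with np.load(path) as z:
        return TuckerFactors(z["core"], z["U"], z["V"], z["J"],
                             tuple(int(r) for r in z["ranks"]))
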