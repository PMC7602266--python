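"""Bilinear user x motion factorization of stacked multi-channel EMG features.

A single feature value observed on channel ``c`` when user ``u`` performs
repetition ``n`` of motion ``m`` is modelled as a bilinear form

    y_{c,n}^{u,m} = z_u^T W_c x_n^m,

where ``z_u`` (length I) captures everything user-specific (electrode
placement, skin impedance, muscle geometry), ``x_n^m`` (length J) captures the
motion content, and the per-channel interaction matrices ``W_c`` (I x J) couple
the two. Fitting separates "style" (user) from "content" (motion) so that a
classifier trained on motion factors transfers across users; a new user is
folded in with a closed-form pseudo-inverse chain from a single calibration
motion.

All data live in a stacked two-dimensional layout: ``Y`` has one vertical block
per channel (block ``c`` is the U x MN slice of channel ``c``) and one column
per (motion, repetition) pair, motion-major. The stacked transpose operator
transposes each block independently, which is what makes the two equivalent
compositions ``Y = [W^ST Z]^ST X`` and ``Y^ST = [W X]^ST Z`` hold exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "StackedMatrix",
    "BilinearModel",
    "AdaptationResult",
    "stack_layout",
    "stacked_transpose",
    "compose",
    "objective",
    "fit",
    "adapt_new_user",
    "project_motions",
    "grid_search_ij",
]


@dataclass(frozen=True)
class StackedMatrix:
    """A real matrix partitioned into ``block_count`` equal vertical blocks."""

    data: np.ndarray
    block_count: int

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"stacked matrix must be 2-D, got ndim={data.ndim}")
        if self.block_count < 1:
            raise ValueError("block_count must be >= 1")
        if data.shape[0] % self.block_count != 0:
            raise ValueError(
                f"row count {data.shape[0]} not divisible by block_count {self.block_count}"
            )
        if not np.isfinite(data).all():
            raise ValueError("stacked matrix entries must be finite")
        object.__setattr__(self, "data", data)

    @property
    def block_rows(self) -> int:
        return self.data.shape[0] // self.block_count

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def blocks(self) -> np.ndarray:
        """View as a (C, block_rows, n_cols) array."""
        c = self.block_count
        return self.data.reshape(c, self.block_rows, self.data.shape[1])

    @classmethod
    def from_blocks(cls, blocks: Sequence[np.ndarray]) -> "StackedMatrix":
        arr = [np.atleast_2d(np.asarray(b, dtype=float)) for b in blocks]
        shapes = {a.shape for a in arr}
        if len(shapes) != 1:
            raise ValueError(f"all blocks must share one shape, got {sorted(shapes)}")
        return cls(np.vstack(arr), len(arr))


def stacked_transpose(a: StackedMatrix) -> StackedMatrix:
    """Blockwise transpose: each of the C blocks is transposed independently.

    For a stacked (C*M x N) matrix the result is (C*N x M); with C=1 this is
    the ordinary transpose, and the operator is an involution.
    """
    blocks = a.blocks()  # (C, M, N)
    return StackedMatrix(
        np.transpose(blocks, (0, 2, 1)).reshape(-1, blocks.shape[1]), a.block_count
    )


def _st(data: np.ndarray, block_count: int) -> np.ndarray:
    """Stacked transpose on a raw array (internal fast path)."""
    c = block_count
    m = data.shape[0] // c
    return np.transpose(data.reshape(c, m, data.shape[1]), (0, 2, 1)).reshape(-1, m)


def stack_layout(
    c: int, u: int, m: int, n: int, dims: tuple[int, int, int, int]
) -> tuple[int, int]:
    """Map an observation index (channel, user, motion, repetition) to (row, col).

    This single function owns the stacked layout: rows are channel-major and
    user-minor (block ``c`` holds all users of channel ``c``), columns are
    motion-major and repetition-minor. ``dims`` is (C, U, M, N).
    """
    C, U, M, N = dims
    if not (0 <= c < C and 0 <= u < U and 0 <= m < M and 0 <= n < N):
        raise IndexError(f"index ({c}, {u}, {m}, {n}) out of bounds for dims {dims}")
    return c * U + u, m * N + n


@dataclass
class BilinearModel:
    """Fitted factors of the stacked bilinear model.

    Z is (I x U) with user factors as columns, W is a stacked (I*C x J) matrix
    whose block c is the interaction matrix W_c, and X is (J x M*N) with motion
    factors as columns in motion-major order. Z and X are only identifiable up
    to an invertible transform absorbed by W, so consumers should compare
    reconstructions and subspaces rather than raw factor entries.
    """

    Z: np.ndarray
    W: StackedMatrix
    X: np.ndarray
    dims: dict[str, int]
    objective_history: list[float] = field(default_factory=list)
    converged: bool = False
    n_iterations: int = 0
    config: dict = field(default_factory=dict)

    @property
    def I(self) -> int:  # noqa: E743 - domain name for the user-factor size
        return self.dims["I"]

    @property
    def J(self) -> int:
        return self.dims["J"]

    def motion_columns(self, m: int) -> np.ndarray:
        """The (J x N) slice of X holding motion m's repetition factors."""
        N = self.dims["N"]
        if not 0 <= m < self.dims["M"]:
            raise IndexError(f"motion index {m} out of range")
        return self.X[:, m * N : (m + 1) * N]


@dataclass
class AdaptationResult:
    """Closed-form new-user factors extracted from one calibration motion.

    ``W_train`` keeps a reference to the parent model's interaction matrix:
    the adapted ``W_new`` has rank at most the number of calibration columns
    (it is a product through the calibration data), so unlabeled-data
    projection defaults to the full-rank training interaction matrix instead
    (see :func:`project_motions`).
    """

    z_new: np.ndarray
    W_new: StackedMatrix
    X_new_m: np.ndarray
    motion_index: int
    residual_relative: float
    condition_numbers: dict[str, float]
    ill_conditioned: bool
    W_train: StackedMatrix | None = None


def compose(Z: np.ndarray, W: StackedMatrix, X: np.ndarray) -> StackedMatrix:
    """Reconstruct the stacked data matrix, Y = [W^ST Z]^ST X.

    Entrywise this equals y_{c,n}^{u,m} = z_u^T W_c x_n^m in the layout of
    :func:`stack_layout`.
    """
    Z = np.asarray(Z, dtype=float)
    X = np.asarray(X, dtype=float)
    I, U = Z.shape
    if W.block_rows != I:
        raise ValueError(f"W block rows {W.block_rows} != I {I}")
    if W.data.shape[1] != X.shape[0]:
        raise ValueError(f"W columns {W.data.shape[1]} != J {X.shape[0]}")
    wst_z = _st(W.data, W.block_count) @ Z  # (J*C x U)
    a = _st(wst_z, W.block_count)  # (U*C... -> C blocks of U x J)
    return StackedMatrix(a @ X, W.block_count)


def objective(Y: StackedMatrix, model: BilinearModel) -> float:
    """Sum of squared residuals between Y and the model reconstruction."""
    recon = compose(model.Z, model.W, model.X)
    if recon.shape != Y.shape:
        raise ValueError(f"shape mismatch: Y {Y.shape} vs reconstruction {recon.shape}")
    return float(np.sum((Y.data - recon.data) ** 2))


def _canonical_rows(vt: np.ndarray) -> np.ndarray:
    """Fix each row's sign so its largest-magnitude entry is positive."""
    vt = vt.copy()
    idx = np.argmax(np.abs(vt), axis=1)
    signs = np.sign(vt[np.arange(vt.shape[0]), idx])
    signs[signs == 0] = 1.0
    return vt * signs[:, None]


def _top_right_rows(a: np.ndarray, k: int) -> np.ndarray:
    """First k rows of V^T from the SVD of ``a``, sign-canonicalized.

    When k exceeds the economic rank the remaining rows come from the full
    orthonormal completion of the SVD, which is deterministic for a given
    input.
    """
    full = k > min(a.shape)
    _, _, vt = np.linalg.svd(a, full_matrices=full)
    if k > vt.shape[0]:
        raise ValueError(f"cannot take {k} rows of V^T with only {vt.shape[0]} available")
    return _canonical_rows(vt[:k])


def _solve_w(Y: StackedMatrix, Z: np.ndarray, X: np.ndarray) -> StackedMatrix:
    """Least-squares interaction matrices given orthonormal-row Z and X.

    With Z Z^T = I and X X^T = I the per-channel optimum of the objective is
    W_c = Z Y_c X^T.
    """
    blocks = Y.blocks()  # (C, U, MN)
    w_blocks = np.einsum("iu,cuk,jk->cij", Z, blocks, X)
    return StackedMatrix(w_blocks.reshape(-1, X.shape[0]), Y.block_count)


def fit(
    Y: StackedMatrix,
    dims: tuple[int, int, int, int, int, int],
    tol: float = 1e-6,
    max_iter: int = 50,
) -> BilinearModel:
    """Fit (Z, W, X) by the alternating SVD procedure.

    X is initialized as the first J rows of V^T from the SVD of Y. Each full
    iteration then updates Z as the first I rows of V^T of [Y X^T]^ST and X as
    the first J rows of V^T of [Y^ST Z^T]^ST, recovers the least-squares W,
    and records the objective. Iteration stops when the relative change in the
    objective drops below ``tol`` (or the fit is numerically exact), typically
    within a handful of iterations on data that the model class contains.

    Parameters
    ----------
    Y : stacked (C*U x M*N) data matrix
    dims : (I, J, C, U, M, N)
    tol : relative objective-change stopping threshold
    max_iter : hard cap on full iterations
    """
    I, J, C, U, M, N = dims
    if Y.block_count != C or Y.block_rows != U or Y.shape[1] != M * N:
        raise ValueError(
            f"Y shape {Y.shape} with {Y.block_count} blocks does not match dims "
            f"(C={C}, U={U}, M*N={M * N})"
        )
    if not 1 <= I <= U:
        raise ValueError(f"need 1 <= I <= U, got I={I}, U={U}")
    if not 1 <= J <= M * N:
        raise ValueError(f"need 1 <= J <= M*N, got J={J}, M*N={M * N}")
    y_norm2 = float(np.sum(Y.data**2))
    if y_norm2 == 0.0:
        raise ValueError("cannot fit an all-zero data matrix")

    X = _top_right_rows(Y.data, J)
    history: list[float] = []
    converged = False
    Z = np.empty((I, U))
    for _ in range(max_iter):
        # Z-update: best I-dim user subspace given the current motion subspace.
        b = _st(Y.data @ X.T, C)  # (J*C x U)
        Z = _top_right_rows(b, I)
        # X-update: best J-dim motion subspace given the user subspace.
        d = _st(_st(Y.data, C) @ Z.T, C)  # (I*C x M*N)
        X = _top_right_rows(d, J)
        W = _solve_w(Y, Z, X)
        e = float(np.sum((Y.data - compose(Z, W, X).data) ** 2))
        history.append(e)
        if len(history) >= 2:
            prev = history[-2]
            rel = abs(prev - e) / prev if prev > 0 else 0.0
            if rel < tol:
                converged = True
                break
        if e <= 1e-28 * y_norm2:  # numerically exact fit
            converged = True
            break
    W = _solve_w(Y, Z, X)
    return BilinearModel(
        Z=Z,
        W=W,
        X=X,
        dims={"I": I, "J": J, "C": C, "U": U, "M": M, "N": N},
        objective_history=history,
        converged=converged,
        n_iterations=len(history),
        config={"tol": tol, "max_iter": max_iter},
    )


_PINV_RCOND = 1e-10
_COND_THRESHOLD = 1e8


def _pinv(a: np.ndarray) -> tuple[np.ndarray, float]:
    """Pseudo-inverse with a relative singular-value cutoff and its condition number."""
    s = np.linalg.svd(a, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        cond = np.inf
    else:
        kept = s[s > _PINV_RCOND * s[0]]
        cond = float(s[0] / kept[-1]) if kept.size else np.inf
    return np.linalg.pinv(a, rcond=_PINV_RCOND), cond


def adapt_new_user(
    model: BilinearModel, Y_new_m: StackedMatrix, m: int
) -> AdaptationResult:
    """Extract a new user's factors from one calibration motion, closed form.

    Three pseudo-inverse steps: first the user factor z_new is the
    least-squares solution of Y_new^ST = [W X_m]^ST z; then the adapted
    interaction matrix W_new = [Y_new^ST {z_new}+]^ST {X_m}+; finally the
    calibration motion factors X_new_m = {[W_new^ST z_new]^ST}+ Y_new. All
    pseudo-inverses apply to the whole stacked matrix and use a relative
    singular-value cutoff; condition numbers are surfaced so a rank-hungry
    adaptation (small repetition count) is visible rather than silent.

    Parameters
    ----------
    model : fitted bilinear model
    Y_new_m : stacked (C x N_new) calibration data, one row per channel block
    m : motion index of the calibration motion
    """
    C = model.dims["C"]
    N = model.dims["N"]
    if Y_new_m.block_count != C:
        raise ValueError(
            f"calibration data has {Y_new_m.block_count} channel blocks, model has {C}"
        )
    if Y_new_m.block_rows != 1:
        raise ValueError("calibration data must have one row (one new user) per block")
    n_new = Y_new_m.shape[1]
    X_m = model.motion_columns(m)
    if n_new > N:
        raise ValueError(f"calibration repetitions {n_new} exceed model N={N}")
    X_cal = X_m[:, :n_new]

    conds: dict[str, float] = {}
    y_st = _st(Y_new_m.data, C)  # (N_new*C x 1)

    # Step 1: z_new from Y^ST = [W X_cal]^ST z.
    a = _st(model.W.data @ X_cal, C)  # (N_new*C x I)
    a_pinv, conds["z_step"] = _pinv(a)
    z_new = (a_pinv @ y_st).ravel()  # (I,)

    # Step 2: adapted interaction matrix.
    z_pinv, conds["w_step_z"] = _pinv(z_new[:, None])  # (1 x I)
    x_pinv, conds["w_step_x"] = _pinv(X_cal)  # (N_new x J)
    W_new_data = _st(y_st @ z_pinv, C) @ x_pinv  # (I*C x J)
    W_new = StackedMatrix(W_new_data, C)

    # Step 3: calibration motion factors under the adapted model.
    proj = _st(W_new_data, C) @ z_new[:, None]  # (J*C x 1)
    A = _st(proj, C)  # (C x J)
    a2_pinv, conds["x_step"] = _pinv(A)
    X_new_m = a2_pinv @ Y_new_m.data  # (J x N_new)

    recon = A @ X_new_m
    denom = float(np.linalg.norm(Y_new_m.data))
    resid = float(np.linalg.norm(Y_new_m.data - recon)) / denom if denom > 0 else 0.0
    return AdaptationResult(
        z_new=z_new,
        W_new=W_new,
        X_new_m=X_new_m,
        motion_index=m,
        residual_relative=resid,
        condition_numbers=conds,
        ill_conditioned=any(c > _COND_THRESHOLD for c in conds.values()),
        W_train=model.W,
    )


def project_motions(
    adapted: AdaptationResult, Y_new: StackedMatrix, use_adapted_w: bool = False
) -> np.ndarray:
    """Motion factors for unlabeled new-user data under the adapted model.

    Each column of ``Y_new`` (one per window/trial, C channel blocks of one
    row) is mapped through the pseudo-inverse of the user's composite channel
    response A = [W^ST z_new]^ST; the map is linear in the signal.

    By default the training interaction matrix is used for W. The fully
    adapted ``W_new`` (``use_adapted_w=True``, the same operator as the
    calibration step, so projecting the calibration data reproduces
    ``X_new_m``) has rank at most the number of calibration columns, which
    collapses the projected factors into a low-dimensional slice of the motion
    space; the training W keeps the projector full rank, and on exactly
    bilinear data it recovers the model's own motion factors.
    """
    W = adapted.W_new if use_adapted_w or adapted.W_train is None else adapted.W_train
    C = W.block_count
    if Y_new.block_count != C:
        raise ValueError(
            f"data has {Y_new.block_count} channel blocks, adapted model has {C}"
        )
    if Y_new.block_rows != 1:
        raise ValueError("new-user data must have one row per channel block")
    proj = _st(W.data, C) @ adapted.z_new[:, None]
    A = _st(proj, C)  # (C x J)
    a_pinv, _ = _pinv(A)
    return a_pinv @ Y_new.data  # (J x n_columns)


def grid_search_ij(
    I_candidates: Sequence[int],
    J_candidates: Sequence[int],
    evaluate: Callable[[int, int], float],
) -> tuple[list[tuple[int, int, float]], tuple[int, int]]:
    """Exhaustive accuracy surface over latent-dimension candidates.

    ``evaluate(I, J)`` must return a scalar accuracy. Returns the full surface
    as (I, J, accuracy) rows plus the argmax, with ties broken toward the
    smaller (I, J) lexicographically.
    """
    if not I_candidates or not J_candidates:
        raise ValueError("candidate lists must be non-empty")
    surface: list[tuple[int, int, float]] = []
    for i, j in itertools.product(sorted(I_candidates), sorted(J_candidates)):
        try:
            acc = float(evaluate(i, j))
        except Exception as exc:
            raise RuntimeError(f"evaluation failed at (I={i}, J={j}): {exc}") from exc
        surface.append((i, j, acc))
    best = max(surface, key=lambda r: (r[2], -r[0], -r[1]))
    return surface, (best[0], best[1])
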