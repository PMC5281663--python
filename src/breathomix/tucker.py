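"""Tucker3 decomposition and feature compression of 3-way measurement tensors.

A Tucker3 model factorizes a 64 x 36 x 3 array X as

    X ~ G x1 A x2 B x3 C

with orthonormal factor matrices A (64 x r1), B (36 x r2), C (3 x r3) and a
small core G (r1 x r2 x r3).  Fitting uses higher-order SVD (HOSVD) for
initialization and higher-order orthogonal iteration (HOOI) for refinement.
A compressor fitted on a set of training tensors projects any conforming
tensor onto the shared factors, giving a length r1*r2*r3 feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TuckerModel",
    "unfold",
    "refold",
    "hosvd",
    "hooi",
    "fit_compressor",
    "compress",
]


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding: mode ``mode`` becomes the rows, the remaining modes
    (in their original cyclic order) the columns."""
    tensor = np.asarray(tensor)
    if mode not in range(tensor.ndim):
        raise ValueError(f"mode {mode} out of range for ndim {tensor.ndim}")
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def refold(matrix: np.ndarray, mode: int, shape: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given shape."""
    shape = tuple(shape)
    if mode not in range(len(shape)):
        raise ValueError(f"mode {mode} out of range for shape {shape}")
    moved = (shape[mode],) + tuple(s for i, s in enumerate(shape) if i != mode)
    matrix = np.asarray(matrix)
    if matrix.shape != (moved[0], int(np.prod(moved[1:], dtype=int))):
        raise ValueError(f"matrix shape {matrix.shape} incompatible with {shape} mode {mode}")
    return np.moveaxis(matrix.reshape(moved), 0, mode)


def _mode_product(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n product: contract ``matrix`` (J x I_mode) with mode ``mode``."""
    return np.moveaxis(np.tensordot(matrix, tensor, axes=(1, mode)), 0, mode)


def _fix_signs(factor: np.ndarray) -> np.ndarray:
    """Flip columns so each column's largest-magnitude entry is positive,
    making factors reproducible across SVD backends."""
    idx = np.argmax(np.abs(factor), axis=0)
    signs = np.sign(factor[idx, np.arange(factor.shape[1])])
    signs[signs == 0] = 1.0
    return factor * signs


@dataclass
class TuckerModel:
    """Orthonormal factors plus core; ``factors[n]`` has shape (I_n, r_n)."""

    factors: list[np.ndarray]
    core: np.ndarray
    ranks: tuple[int, ...]
    rel_error: float
    n_iter: int = 0
    converged: bool = True

    def reconstruct(self) -> np.ndarray:
        out = self.core
        for n, f in enumerate(self.factors):
            out = _mode_product(out, f, n)
        return out

    def project(self, tensor: np.ndarray) -> np.ndarray:
        """Project a conforming tensor onto the factors, returning the
        (r1 x ... x rN) coefficient core."""
        tensor = np.asarray(tensor, dtype=float)
        expected = tuple(f.shape[0] for f in self.factors)
        if tensor.shape != expected:
            raise ValueError(f"tensor shape {tensor.shape} != model shape {expected}")
        out = tensor
        for n, f in enumerate(self.factors):
            out = _mode_product(out, f.T, n)
        return out


def _validate_ranks(shape: tuple[int, ...], ranks: tuple[int, ...]) -> tuple[int, ...]:
    ranks = tuple(int(r) for r in ranks)
    if len(ranks) != len(shape):
        raise ValueError(f"{len(shape)} ranks required, got {len(ranks)}")
    for r, d in zip(ranks, shape):
        if not 1 <= r <= d:
            raise ValueError(f"rank {r} outside [1, {d}]")
    return ranks


def _rel_error(tensor: np.ndarray, factors: list[np.ndarray], core: np.ndarray) -> float:
    # Explicit residual: the ||X||^2 - ||G||^2 shortcut loses half the digits
    # to cancellation when the fit is near-exact.
    norm = float(np.linalg.norm(tensor))
    if norm == 0:
        return 0.0
    recon = core
    for n, f in enumerate(factors):
        recon = _mode_product(recon, f, n)
    return float(np.linalg.norm(tensor - recon) / norm)


def hosvd(tensor: np.ndarray, ranks: tuple[int, ...]) -> TuckerModel:
    """Truncated higher-order SVD: factors are the leading left singular
    vectors of each mode unfolding; the core is the projection of the tensor."""
    tensor = np.asarray(tensor, dtype=float)
    ranks = _validate_ranks(tensor.shape, ranks)
    factors = []
    for mode, r in enumerate(ranks):
        u, _, _ = np.linalg.svd(unfold(tensor, mode), full_matrices=False)
        factors.append(_fix_signs(u[:, :r]))
    core = tensor
    for n, f in enumerate(factors):
        core = _mode_product(core, f.T, n)
    return TuckerModel(
        factors=factors,
        core=core,
        ranks=ranks,
        rel_error=_rel_error(tensor, factors, core),
        n_iter=0,
    )


def hooi(
    tensor: np.ndarray,
    ranks: tuple[int, ...],
    tol: float = 1e-7,
    max_iter: int = 200,
) -> TuckerModel:
    """Higher-order orthogonal iteration, initialized from HOSVD.

    Alternates: for each mode, project the tensor onto the other modes'
    factors and take the leading left singular vectors.  The fit (core norm)
    is non-decreasing, so the reconstruction error never exceeds HOSVD's.
    Stops when the relative fit improvement drops below ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    tensor = np.asarray(tensor, dtype=float)
    ranks = _validate_ranks(tensor.shape, ranks)
    model = hosvd(tensor, ranks)
    factors = model.factors
    norm = float(np.linalg.norm(tensor))
    if norm == 0:
        return model
    prev_fit = np.sqrt(np.sum(model.core**2)) / norm
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for mode in range(tensor.ndim):
            partial = tensor
            for n, f in enumerate(factors):
                if n != mode:
                    partial = _mode_product(partial, f.T, n)
            u, _, _ = np.linalg.svd(unfold(partial, mode), full_matrices=False)
            factors[mode] = _fix_signs(u[:, : ranks[mode]])
        core = tensor
        for n, f in enumerate(factors):
            core = _mode_product(core, f.T, n)
        fit = np.sqrt(np.sum(core**2)) / norm
        if fit - prev_fit < tol * max(prev_fit, 1e-300):
            converged = True
            prev_fit = fit
            break
        prev_fit = fit
    return TuckerModel(
        factors=factors,
        core=core,
        ranks=ranks,
        rel_error=_rel_error(tensor, factors, core),
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Group compression: one Tucker basis per training fold
# ---------------------------------------------------------------------------

def fit_compressor(
    training_tensors: list[np.ndarray] | np.ndarray,
    ranks: tuple[int, int, int],
    tol: float = 1e-7,
    max_iter: int = 200,
) -> TuckerModel:
    """Fit shared Tucker factors on a stack of training tensors.

    The training set is stacked along an augmented sample mode (giving a
    4-way array with an identity factor on the sample mode); HOOI then runs
    on the three measurement modes only.  Held-out tensors never enter the
    factor estimation.
    """
    stack = np.stack([np.asarray(t, dtype=float) for t in training_tensors])
    if stack.ndim != 4:
        raise ValueError("training tensors must be 3-way arrays of equal shape")
    n = stack.shape[0]
    shape3 = stack.shape[1:]
    ranks = _validate_ranks(shape3, ranks)

    # HOSVD init on the stacked array (sample mode untouched).
    factors: list[np.ndarray] = []
    for mode in range(3):
        unf = np.moveaxis(stack, mode + 1, 0).reshape(stack.shape[mode + 1], -1)
        u, _, _ = np.linalg.svd(unf, full_matrices=False)
        factors.append(_fix_signs(u[:, : ranks[mode]]))

    norm = float(np.linalg.norm(stack))
    if norm == 0:
        core = np.zeros((n,) + ranks)
        return TuckerModel(factors=factors, core=core, ranks=ranks, rel_error=0.0)

    def _project_all(fs: list[np.ndarray]) -> np.ndarray:
        out = stack
        for m, f in enumerate(fs):
            out = _mode_product(out, f.T, m + 1)
        return out

    prev_fit = np.sqrt(np.sum(_project_all(factors) ** 2)) / norm
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for mode in range(3):
            partial = stack
            for m, f in enumerate(factors):
                if m != mode:
                    partial = _mode_product(partial, f.T, m + 1)
            unf = np.moveaxis(partial, mode + 1, 0).reshape(partial.shape[mode + 1], -1)
            u, _, _ = np.linalg.svd(unf, full_matrices=False)
            factors[mode] = _fix_signs(u[:, : ranks[mode]])
        fit = np.sqrt(np.sum(_project_all(factors) ** 2)) / norm
        if fit - prev_fit < tol * max(prev_fit, 1e-300):
            converged = True
            prev_fit = fit
            break
        prev_fit = fit

    core = _project_all(factors)  # (n, r1, r2, r3): per-sample coefficient cores
    recon = core
    for m, f in enumerate(factors):
        recon = _mode_product(recon, f, m + 1)
    rel = float(np.linalg.norm(stack - recon) / norm)
    return TuckerModel(
        factors=factors, core=core, ranks=ranks, rel_error=rel, n_iter=it, converged=converged
    )


def compress(model: TuckerModel, tensor: np.ndarray) -> np.ndarray:
    """Project a 3-way tensor onto the fitted factors and vectorize the
    coefficient core, giving a feature vector of length r1*r2*r3."""
    tensor = np.asarray(tensor, dtype=float)
    expected = tuple(f.shape[0] for f in model.factors)
    if tensor.shape != expected:
        raise ValueError(f"tensor shape {tensor.shape} != compressor shape {expected}")
    out = tensor
    for n, f in enumerate(model.factors):
        out = _mode_product(out, f.T, n)
    return out.ravel()
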