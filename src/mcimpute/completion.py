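"""Low-rank matrix completion solvers for dropout imputation.

The observed (preprocessed, log-scale) expression matrix ``Y`` is modelled as
a subsampled view of a complete low-rank matrix ``X``::

    Y = A(X)

where ``A`` is a binary sampling operator: 1 where an entry was observed,
0 where it was not. Imputation is the recovery of ``X`` from ``Y`` and ``A``.
Two solvers are provided, both wrapped in the same majorization-minimization
(MM) outer loop. At each outer iteration the data-fit term is majorized at
the current iterate, which decouples the mask from the penalty and leaves a
plain proximal / factorization subproblem on

    B_{k+1} = X_k + (1/a) * A^T( Y - A(X_k) )

with ``a`` a scalar >= the squared spectral norm of ``A`` (for an elementwise
binary mask, a = 1 suffices).

**Nuclear-norm minimization (NNM)** solves the Lagrangian

    min_X  || Y - A(X) ||_F^2  +  lam * ||X||_*

by soft-thresholding the singular values of ``B`` at lam/2 each iteration
(the exact proximal operator of the nuclear norm), then projecting onto the
non-negative orthant — expression cannot be negative.

**Matrix factorization (MF)** fixes a target rank ``r``, writes ``X = U V``
with ``U`` m x r and ``V`` r x n, and fits

    min_{U,V}  || Y - A(UV) ||_F^2

by one alternating-least-squares sweep (U then V) against ``B`` per outer
iteration, again followed by non-negative projection of the reconstruction.
``V`` is initialized from the top ``r`` right singular vectors of ``Y``,
making the whole solve deterministic.

Both solvers record the objective at every iteration; MM guarantees the
trace is non-increasing, which the test suite asserts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .matrix import ExpressionMatrix, ValidationError
from .preprocess import (
    NormalizationRecord,
    PreprocessConfig,
    denormalize,
    inverse_log_transform,
    preprocess,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingMask",
    "CompletionConfig",
    "ImputationResult",
    "MFFactors",
    "McImputeOutput",
    "ConfigurationError",
    "build_mask",
    "soft_threshold",
    "svt_prox",
    "nnm_impute",
    "mf_impute",
    "objective_nnm",
    "choose_rank",
    "mcimpute",
]


class ConfigurationError(ValueError):
    """Solver configuration is inconsistent with the requested method."""


@dataclass
class SamplingMask:
    """Binary mask over matrix entries: 1 = observed, 0 = unobserved."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=float)
        if self.mask.ndim != 2:
            raise ValidationError(f"mask must be 2-D, got shape {self.mask.shape}")
        if not np.isin(self.mask, (0.0, 1.0)).all():
            raise ValidationError("mask entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    def complement(self) -> "SamplingMask":
        return SamplingMask(1.0 - self.mask)

    def check_solvable(self) -> bool:
        """Warn (don't fail) if some row or column has no observed entry."""
        empty_rows = int((self.mask.sum(axis=1) == 0).sum())
        empty_cols = int((self.mask.sum(axis=0) == 0).sum())
        if empty_rows or empty_cols:
            warnings.warn(
                f"{empty_rows} rows and {empty_cols} columns have no observed "
                "entries; their values are determined only by the low-rank "
                "structure",
                stacklevel=2,
            )
            return False
        return True


@dataclass
class CompletionConfig:
    """Hyperparameters shared by both solvers.

    Parameters
    ----------
    lam
        Lagrange multiplier on the nuclear norm (NNM), expressed as a
        fraction of the leading singular value of the observed matrix (the
        effective multiplier is ``lam * s1(Y)``, fixed once per solve). This
        makes the default meaningful regardless of matrix scale; the solver
        is robust to the value as long as it stays small (< 0.01).
        Default 0.005.
    step_a
        MM step scalar ``a``; 1 suffices because the binary mask operator has
        spectral norm <= 1.
    rank_r
        MF target rank. ``None`` means the caller must supply it or let the
        pipeline pick the smallest rank holding 99% of squared singular-value
        energy of the observed matrix.
    tol
        Stop when the relative change of the objective falls below this.
    max_iter
        Iteration cap.
    nonneg
        Project each iterate onto the non-negative orthant (default on).
    """

    lam: float = 0.005
    step_a: float = 1.0
    rank_r: int | None = None
    tol: float = 1e-4
    max_iter: int = 500
    nonneg: bool = True

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ConfigurationError(f"lam must be > 0, got {self.lam}")
        if self.step_a < 1:
            raise ConfigurationError(f"step_a must be >= 1, got {self.step_a}")
        if self.rank_r is not None and self.rank_r < 1:
            raise ConfigurationError(f"rank_r must be >= 1, got {self.rank_r}")
        if self.tol <= 0:
            raise ConfigurationError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1:
            raise ConfigurationError(f"max_iter must be >= 1, got {self.max_iter}")


@dataclass
class ImputationResult:
    """A recovered matrix plus the solver's convergence record."""

    X: ExpressionMatrix
    objective_trace: list[float]
    iterations: int
    converged: bool
    method: Literal["nnm", "mf"]
    factors: "MFFactors | None" = None
    lam_effective: float | None = None


@dataclass
class MFFactors:
    """The rank-r factor pair of the MF solver, X ~= U @ V."""

    U: np.ndarray  # m x r
    V: np.ndarray  # r x n


@dataclass
class McImputeOutput:
    """Imputed matrices on all three scales, mutually consistent."""

    log: ExpressionMatrix
    normalized: ExpressionMatrix
    counts: ExpressionMatrix
    result: ImputationResult
    record: NormalizationRecord


def build_mask(Y: ExpressionMatrix | np.ndarray) -> SamplingMask:
    """Derive the sampling operator from the data: nonzero => observed.

    Zeros are treated as unobserved — they are the candidate dropouts the
    completion fills in. (For masking experiments the mask is instead supplied
    externally by the evaluator.)
    """
    values = Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y)
    mask = SamplingMask((values > 0).astype(float))
    mask.check_solvable()
    return mask


def soft_threshold(s: np.ndarray | float, tau: float) -> np.ndarray:
    """Elementwise soft thresholding: sign(s) * max(0, |s| - tau)."""
    if tau < 0:
        raise ValidationError(f"threshold must be >= 0, got {tau}")
    s = np.asarray(s, dtype=float)
    return np.sign(s) * np.maximum(0.0, np.abs(s) - tau)


def _sign_fixed_svd(B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD with the sign ambiguity resolved for reproducibility.

    The largest-magnitude element of each left singular vector is forced
    positive (the corresponding right vector is flipped to compensate).
    """
    try:
        U, s, Vt = np.linalg.svd(B, full_matrices=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - LAPACK failure
        raise np.linalg.LinAlgError(
            f"SVD failed on a {B.shape[0]}x{B.shape[1]} matrix: {exc}"
        ) from exc
    pivot = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[pivot, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, s, Vt * signs[:, None]


def svt_prox(B: np.ndarray, tau: float) -> np.ndarray:
    """Singular-value soft thresholding: the proximal operator of the
    nuclear norm.

    Returns the exact minimizer of ``||B - X||_F^2 + 2*tau*||X||_*``:
    soft-threshold the singular values of ``B`` at ``tau`` and reconstruct.
    """
    U, s, Vt = _sign_fixed_svd(np.asarray(B, dtype=float))
    return (U * soft_threshold(s, tau)) @ Vt


def objective_nnm(
    X: np.ndarray, Y: np.ndarray, A: SamplingMask, lam: float
) -> float:
    """Lagrangian objective ||Y - A(X)||_F^2 + lam * ||X||_*."""
    resid = A.mask * (Y - X)
    nuclear = float(np.linalg.svd(X, compute_uv=False).sum())
    return float(np.sum(resid * resid)) + lam * nuclear


def _data_fit(X: np.ndarray, Y: np.ndarray, A: SamplingMask) -> float:
    resid = A.mask * (Y - X)
    return float(np.sum(resid * resid))


def _as_values(Y: ExpressionMatrix | np.ndarray) -> np.ndarray:
    return Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, dtype=float)


def _wrap_result(
    Y: ExpressionMatrix | np.ndarray, X: np.ndarray
) -> ExpressionMatrix | np.ndarray:
    if isinstance(Y, ExpressionMatrix):
        return Y.with_values(X)
    return X


def _check_finite(X: np.ndarray, k: int, method: str) -> None:
    if not np.all(np.isfinite(X)):
        raise FloatingPointError(
            f"{method} produced non-finite values at iteration {k}"
        )


def _mm_step(X: np.ndarray, Y: np.ndarray, A: SamplingMask, a: float) -> np.ndarray:
    # B_{k+1} = X_k + (1/a) A^T (Y - A(X_k)); for an elementwise mask the
    # adjoint is the mask itself.
    return X + (1.0 / a) * A.mask * (Y - X)


def nnm_impute(
    Y: ExpressionMatrix | np.ndarray,
    A: SamplingMask,
    cfg: CompletionConfig | None = None,
) -> ImputationResult:
    """Complete ``Y`` by iterative singular-value soft thresholding.

    Each outer iteration takes the MM step ``B = X + (1/a) A^T(Y - A(X))``,
    applies the nuclear-norm prox (threshold lam/2), and clips negatives.
    Stops when the relative change of the Lagrangian objective drops below
    ``cfg.tol``. Deterministic for fixed inputs.
    """
    cfg = cfg or CompletionConfig()
    Yv = _as_values(Y)
    if A.shape != Yv.shape:
        raise ValidationError(f"mask shape {A.shape} != matrix shape {Yv.shape}")
    # lam is relative to the data scale; fix the effective multiplier once
    s1 = float(np.linalg.svd(Yv, compute_uv=False)[0]) if Yv.any() else 1.0
    lam_eff = cfg.lam * max(s1, 1e-300)
    X = np.zeros_like(Yv)
    trace: list[float] = [objective_nnm(X, Yv, A, lam_eff)]
    converged = False
    k = 0
    for k in range(1, cfg.max_iter + 1):
        B = _mm_step(X, Yv, A, cfg.step_a)
        X = svt_prox(B, lam_eff / 2.0)
        if cfg.nonneg:
            np.clip(X, 0.0, None, out=X)
        _check_finite(X, k, "nnm")
        obj = objective_nnm(X, Yv, A, lam_eff)
        prev = trace[-1]
        trace.append(obj)
        if abs(prev - obj) <= cfg.tol * max(abs(prev), 1e-300):
            converged = True
            break
    return ImputationResult(
        X=_wrap_result(Y, X),
        objective_trace=trace,
        iterations=k,
        converged=converged,
        method="nnm",
        lam_effective=lam_eff,
    )


def mf_impute(
    Y: ExpressionMatrix | np.ndarray,
    A: SamplingMask,
    cfg: CompletionConfig,
) -> ImputationResult:
    """Complete ``Y`` by rank-``cfg.rank_r`` matrix factorization.

    The MM outer loop is the same as in :func:`nnm_impute`; the subproblem
    ``min ||B - UV||_F^2`` is attacked with one alternating-least-squares
    sweep per outer iteration (U given V, then V given U). Rank-deficient
    systems fall back to the least-norm (pseudoinverse) solution. ``V`` is
    initialized from the top right singular vectors of ``Y``, so the solve
    has no random element.
    """
    if cfg.rank_r is None:
        raise ConfigurationError(
            "mf_impute needs rank_r; set it explicitly or use the mcimpute() "
            "pipeline, which defaults it from the singular spectrum"
        )
    Yv = _as_values(Y)
    if A.shape != Yv.shape:
        raise ValidationError(f"mask shape {A.shape} != matrix shape {Yv.shape}")
    m, n = Yv.shape
    r = cfg.rank_r
    if r > min(m, n):
        raise ConfigurationError(f"rank_r={r} exceeds min(m, n)={min(m, n)}")

    _, _, Vt = _sign_fixed_svd(Yv)
    V = Vt[:r, :]
    X = np.zeros_like(Yv)
    trace: list[float] = [_data_fit(X, Yv, A)]
    scale = max(trace[0], 1e-300)
    converged = False
    rank_warned = False
    k = 0
    for k in range(1, cfg.max_iter + 1):
        B = _mm_step(X, Yv, A, cfg.step_a)
        # U <- argmin ||B - U V||_F^2, then V <- argmin ||B - U V||_F^2
        Ut, res_u, rank_u, _ = np.linalg.lstsq(V.T, B.T, rcond=None)
        U = Ut.T
        V, res_v, rank_v, _ = np.linalg.lstsq(U, B, rcond=None)
        if min(rank_u, rank_v) < r and not rank_warned:
            logger.info(
                "rank-deficient least-squares system at iteration %d "
                "(effective rank %d < %d); least-norm solution used",
                k, min(rank_u, rank_v), r,
            )
            rank_warned = True
        X = U @ V
        if cfg.nonneg:
            np.clip(X, 0.0, None, out=X)
        _check_finite(X, k, "mf")
        obj = _data_fit(X, Yv, A)
        prev = trace[-1]
        trace.append(obj)
        # stop on relative stagnation, or outright when the fit is exact
        if abs(prev - obj) <= cfg.tol * max(abs(prev), 1e-300) or obj <= 1e-20 * scale:
            converged = True
            break
    return ImputationResult(
        X=_wrap_result(Y, X),
        objective_trace=trace,
        iterations=k,
        converged=converged,
        method="mf",
        factors=MFFactors(U=U, V=V),
    )


def choose_rank(values: np.ndarray, energy: float = 0.99) -> int:
    """Smallest rank capturing ``energy`` of the squared singular-value mass."""
    s = np.linalg.svd(np.asarray(values, dtype=float), compute_uv=False)
    power = s**2
    total = power.sum()
    if total == 0:
        return 1
    cum = np.cumsum(power) / total
    return int(np.searchsorted(cum, energy) + 1)


def mcimpute(
    E_raw: ExpressionMatrix,
    method: Literal["nnm", "mf"] = "nnm",
    cfg: CompletionConfig | None = None,
    preprocess_cfg: PreprocessConfig | None = None,
) -> McImputeOutput:
    """End-to-end imputation: preprocess, complete, and undo the transforms.

    Runs filter -> library-size normalize -> log2(x+1), builds the sampling
    mask from the zeros of the log matrix, solves with the chosen method, and
    returns the imputed matrix on the log, normalized and (fractional) count
    scales, all consistent under the inverse maps.
    """
    if method not in ("nnm", "mf"):
        raise ConfigurationError(f"unknown method {method!r}")
    if E_raw.layer != "counts":
        raise ValidationError(f"mcimpute expects raw counts, got {E_raw.layer!r}")
    cfg = cfg or CompletionConfig()
    preprocess_cfg = preprocess_cfg or PreprocessConfig()

    logged, record = preprocess(E_raw, preprocess_cfg)
    mask = build_mask(logged)
    if method == "nnm":
        result = nnm_impute(logged, mask, cfg)
    else:
        if cfg.rank_r is None:
            auto_r = choose_rank(logged.values)
            logger.info("rank_r not set; using 99%%-energy rank %d", auto_r)
            cfg = CompletionConfig(
                lam=cfg.lam, step_a=cfg.step_a, rank_r=auto_r,
                tol=cfg.tol, max_iter=cfg.max_iter, nonneg=cfg.nonneg,
            )
        result = mf_impute(logged, mask, cfg)

    assert isinstance(result.X, ExpressionMatrix)
    imputed_log = result.X.with_values(result.X.values, layer="log")
    imputed_norm = inverse_log_transform(imputed_log, preprocess_cfg.pseudocount)
    imputed_counts = denormalize(imputed_norm, record)
    return McImputeOutput(
        log=imputed_log,
        normalized=imputed_norm,
        counts=imputed_counts,
        result=result,
        record=record,
    )
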