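"""Low-rank numerics: soft singular-value thresholding, the closed-form
rank-restricted SVT oracle, the iterative rank-restricted soft SVD
(alternating ridge regression on the bilinear factors), masked completion
by iterative fill-in (softImpute), Sylvester solves and the factor-based
convergence statistic.

Convention used throughout: the data term is ½‖·‖_F² and the nuclear-norm
weight λ shrinks singular values by exactly λ, i.e. the problem solved on a
fully observed Y is

    min_{rank(Z) ≤ r}  ½‖Y − Z‖_F² + λ‖Z‖_*

whose closed-form solution is U_r S_λ(D_r) V_rᵀ (truncated SVD followed by
soft thresholding).  The equivalent bilinear form replaces λ‖Z‖_* with
(λ/2)(‖A‖_F² + ‖B‖_F²) under Z = ABᵀ, using the variational identity
‖Z‖_* = min_{AB^T=Z} ½(‖A‖² + ‖B‖²).  Formulations written with a data
term ‖·‖² and threshold λ/2 map onto this convention by λ → 2λ.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import scipy.linalg

__all__ = [
    "LowRankFactors",
    "SolverConfig",
    "ConvergenceTrace",
    "soft_threshold_singular_values",
    "svt_oracle",
    "rank_restricted_soft_svd",
    "soft_impute_masked",
    "solve_sylvester",
    "relative_frobenius_change",
]


@dataclasses.dataclass
class LowRankFactors:
    """An SVD-form low-rank solution Z = U diag(d) Vᵀ with rank cap r.

    The bilinear factors of the variational identity are the balanced
    split A = U diag(d)^½, B = V diag(d)^½ (so Z = ABᵀ and
    ½(‖A‖² + ‖B‖²) = Σ d_i = ‖Z‖_* at any exact SVD form).
    """

    U: np.ndarray
    d: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        r = self.d.shape[0]
        if self.U.shape[1] != r or self.V.shape[1] != r:
            raise ValueError("factor shapes inconsistent with d")
        if (self.d < -1e-12).any():
            raise ValueError("singular values must be nonnegative")

    @property
    def rank_cap(self) -> int:
        return self.d.shape[0]

    @property
    def A(self) -> np.ndarray:
        return self.U * np.sqrt(self.d)

    @property
    def B(self) -> np.ndarray:
        return self.V * np.sqrt(self.d)

    def reconstruct(self) -> np.ndarray:
        return (self.U * self.d) @ self.V.T

    def nuclear_norm(self) -> float:
        return float(self.d.sum())


@dataclasses.dataclass
class SolverConfig:
    """Hyperparameters of the rank-restricted soft-SVD solvers.

    lam ≥ 0 is the nuclear-norm weight λ; r the rank cap; tol the threshold
    on the relative Frobenius change between successive iterates; seed
    drives the random orthonormal initialization.
    """

    lam: float = 0.1
    r: int = 4
    tol: float = 1e-5
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.r < 1:
            raise ValueError("rank cap must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclasses.dataclass
class ConvergenceTrace:
    """Per-iteration (iteration, relative Frobenius change, objective)."""

    iterations: list[int] = dataclasses.field(default_factory=list)
    delta: list[float] = dataclasses.field(default_factory=list)
    objective: list[float] = dataclasses.field(default_factory=list)
    converged: bool = False

    def append(self, it: int, delta: float, objective: float) -> None:
        self.iterations.append(it)
        self.delta.append(delta)
        self.objective.append(objective)

    def to_rows(self) -> list[tuple[int, float, float]]:
        return list(zip(self.iterations, self.delta, self.objective))


def soft_threshold_singular_values(sigma: np.ndarray,
                                   threshold: float) -> np.ndarray:
    """Elementwise max(σ_i − threshold, 0), order preserved."""
    sigma = np.asarray(sigma, dtype=float)
    if (sigma < 0).any():
        raise ValueError("singular values must be nonnegative")
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    return np.maximum(sigma - threshold, 0.0)


def svt_oracle(Y: np.ndarray, lam: float, r: int) -> LowRankFactors:
    """Closed-form solution of the rank-capped nuclear-norm proximal problem.

    Computes the full SVD of the fully observed Y, truncates to the top r
    triplets and soft-thresholds the singular values by λ.  This is the
    brute-force reference against which the iterative solver is validated.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-D")
    if not np.isfinite(Y).all():
        raise ValueError("Y must be finite")
    r = min(r, min(Y.shape))
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    d = soft_threshold_singular_values(s[:r], lam)
    return LowRankFactors(U[:, :r], d, Vt[:r].T)


def _init_factors(m: int, n: int, r: int, seed: int) -> LowRankFactors:
    rng = np.random.default_rng(seed)
    U, _ = np.linalg.qr(rng.standard_normal((m, r)))
    V, _ = np.linalg.qr(rng.standard_normal((n, r)))
    return LowRankFactors(U, np.ones(r), V)


def _refactor(A: np.ndarray, B: np.ndarray) -> LowRankFactors:
    """Restore SVD form (U, d, V) of the product ABᵀ via two thin QRs and
    an r×r SVD."""
    Qa, Ra = np.linalg.qr(A)
    Qb, Rb = np.linalg.qr(B)
    u, d, vt = np.linalg.svd(Ra @ Rb.T)
    return LowRankFactors(Qa @ u, d, Qb @ vt.T)


def rank_restricted_soft_svd(
    Y: np.ndarray,
    cfg: SolverConfig,
    warm: Optional[LowRankFactors] = None,
) -> tuple[LowRankFactors, ConvergenceTrace]:
    """Iterative solver for min ½‖Y − ABᵀ‖² + (λ/2)(‖A‖² + ‖B‖²), rank ≤ r.

    Alternates exact ridge-regression updates of the two factors
    (softImpute-style warm-started alternation) with re-orthogonalization
    after each sweep, until the relative Frobenius change between sweeps
    drops below cfg.tol.  At the fixed point the reconstruction equals the
    closed-form :func:`svt_oracle` solution.
    """
    Y = np.asarray(Y, dtype=float)
    m, n = Y.shape
    r = min(cfg.r, min(m, n))
    fac = warm if warm is not None else _init_factors(m, n, r, cfg.seed)
    if fac.rank_cap != r:
        raise ValueError("warm-start rank differs from cfg rank")
    trace = ConvergenceTrace()
    lam = cfg.lam
    prev_delta = np.inf
    for it in range(1, cfg.max_iter + 1):
        A = fac.A
        # ridge update of B given A, then of A given the new B
        B = Y.T @ A @ np.linalg.inv(A.T @ A + lam * np.eye(r))
        A = Y @ B @ np.linalg.inv(B.T @ B + lam * np.eye(r))
        new = _refactor(A, B)
        delta = relative_frobenius_change(fac, new)
        obj = _soft_svd_objective(Y, new, lam)
        trace.append(it, delta, obj)
        fac = new
        if delta <= cfg.tol:
            # the per-sweep change underestimates the distance to the
            # fixed point by ~rho/(1-rho) for a linear rate rho; stop only
            # once the estimated remaining (squared) distance is below tol
            rho = np.sqrt(delta / prev_delta) if prev_delta > 0 else 0.0
            rho = min(rho, 0.999)
            if delta * (rho / (1.0 - rho)) ** 2 <= cfg.tol:
                trace.converged = True
                break
        prev_delta = delta
    return fac, trace


def _soft_svd_objective(Y: np.ndarray, fac: LowRankFactors,
                        lam: float) -> float:
    Z = fac.reconstruct()
    return float(0.5 * np.linalg.norm(Y - Z) ** 2 + lam * fac.d.sum())


def soft_impute_masked(
    Y: np.ndarray,
    mask: np.ndarray,
    cfg: SolverConfig,
    warm: Optional[LowRankFactors] = None,
) -> tuple[LowRankFactors, ConvergenceTrace]:
    """Masked nuclear-norm completion by iterative fill-in.

    Each iteration forms Y* = P(Y) + P⊥(ABᵀ) — observed entries from the
    data, unobserved entries from the current reconstruction — and applies
    one warm-started alternating sweep of the rank-restricted soft SVD on
    Y*.  This is a majorize-minimize scheme: the recorded objective
    ½‖P(Y) − P(Z)‖² + λ‖Z‖_* is nonincreasing across iterations.

    When no warm start is given, iteration begins from the thresholded SVD
    of the zero-filled matrix P(Y).  This initialization is deterministic
    and permutation-equivariant: relabeling drugs or targets permutes the
    returned scores identically.
    """
    Y = np.asarray(Y, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if mask.shape != Y.shape:
        raise ValueError("mask shape differs from Y shape")
    if mask.sum() == 0:
        raise ValueError("mask has no observed entries")
    m, n = Y.shape
    r = min(cfg.r, min(m, n))
    obs = mask > 0
    fac = warm if warm is not None else svt_oracle(np.where(obs, Y, 0.0),
                                                   cfg.lam, r)
    trace = ConvergenceTrace()
    lam = cfg.lam
    sweep_cfg = dataclasses.replace(cfg, max_iter=1, r=r)
    prev_delta = np.inf
    for it in range(1, cfg.max_iter + 1):
        Z = fac.reconstruct()
        Ystar = np.where(obs, Y, Z)
        new, _ = rank_restricted_soft_svd(Ystar, sweep_cfg, warm=fac)
        delta = relative_frobenius_change(fac, new)
        obj = _masked_objective(Y, obs, new, lam)
        trace.append(it, delta, obj)
        fac = new
        if delta <= cfg.tol:
            rho = np.sqrt(delta / prev_delta) if prev_delta > 0 else 0.0
            rho = min(rho, 0.999)
            if delta * (rho / (1.0 - rho)) ** 2 <= cfg.tol:
                trace.converged = True
                break
        prev_delta = delta
    return fac, trace


def _masked_objective(Y: np.ndarray, obs: np.ndarray, fac: LowRankFactors,
                      lam: float) -> float:
    Z = fac.reconstruct()
    resid = np.where(obs, Y - Z, 0.0)
    return float(0.5 * np.linalg.norm(resid) ** 2 + lam * fac.d.sum())


def solve_sylvester(Aq: np.ndarray, Bq: np.ndarray,
                    C: np.ndarray) -> np.ndarray:
    """Solve Aq·X + X·Bq = C (Bartels–Stewart).

    The callers build Aq and Bq from positive-semidefinite Laplacian terms
    plus strictly positive multiples of the identity, so the pencil is
    nonsingular there; a singular pencil raises.
    """
    Aq = np.asarray(Aq, dtype=float)
    Bq = np.asarray(Bq, dtype=float)
    C = np.asarray(C, dtype=float)
    X = scipy.linalg.solve_sylvester(Aq, Bq, C)
    normC = np.linalg.norm(C)
    resid = np.linalg.norm(Aq @ X + X @ Bq - C)
    if not np.isfinite(X).all() or (normC > 0 and resid > 1e-6 * normC):
        raise np.linalg.LinAlgError("Sylvester solve failed (singular pencil?)")
    return X


def relative_frobenius_change(old: LowRankFactors,
                              new: LowRankFactors) -> float:
    """Relative squared Frobenius change ‖Z_old − Z_new‖² / ‖Z_old‖² between
    two SVD-form iterates, computed from the factors alone.

    With D² ≡ diag(d) (the singular values of the reconstruction), the
    trace identity

        [tr(D⁴) + tr(D̃⁴) − 2 tr(D² Uᵀ Ũ D̃² Ṽᵀ V)] / tr(D⁴)

    avoids forming either dense reconstruction.  A zero old iterate gives
    +inf unless the new iterate is also zero (then 0).
    """
    trd4_old = float(np.sum(old.d ** 2))
    trd4_new = float(np.sum(new.d ** 2))
    if trd4_old == 0.0:
        return 0.0 if trd4_new == 0.0 else np.inf
    cross = np.trace(
        (old.d[:, None] * (old.U.T @ new.U) * new.d[None, :]) @ (new.V.T @ old.V)
    )
    val = (trd4_old + trd4_new - 2.0 * float(cross)) / trd4_old
    return max(val, 0.0)
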