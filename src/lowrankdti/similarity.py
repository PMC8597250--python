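"""Interaction-profile similarities, p-nearest-neighbor sparsification and
graph Laplacians.

Besides an externally provided similarity (chemical structure for drugs,
sequence similarity for targets), four similarities are computed from the
binary interaction matrix itself, comparing interaction profiles (rows for
drugs, columns for targets): cosine, Pearson correlation, Hamming agreement
and Jaccard.  The five matrices are summed into a combined similarity whose
Laplacian regularizes the completion — by linearity of L = D − S, the
Laplacian of the sum equals the sum of the per-matrix Laplacians.

Degenerate profiles are resolved conservatively: an all-zero profile has
cosine/Jaccard similarity 0 with everything (no evidence), and a constant
profile has correlation 0.  Negative correlations are clipped to 0 because
graph regularization assumes nonnegative edge weights.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "SimilaritySet",
    "GraphLaplacian",
    "profile_similarity",
    "combine_similarities",
    "pnn_sparsify",
    "graph_laplacian",
    "PROFILE_KINDS",
]

Side = Literal["drug", "target"]
Kind = Literal["cos", "cor", "ham", "jac"]

PROFILE_KINDS: tuple[str, ...] = ("cos", "cor", "ham", "jac")


@dataclasses.dataclass
class SimilaritySet:
    """The similarity matrices for one side (drug or target).

    ``matrices`` is the ordered list [provided, cos, cor, ham, jac] (the
    provided slot is a zero matrix when no external similarity exists);
    ``combined`` is their elementwise sum, the S^com entering the combined
    Laplacian.
    """

    matrices: list[np.ndarray]
    kinds: list[str]
    combined: np.ndarray = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ValueError("empty similarity set")
        shape = self.matrices[0].shape
        for S in self.matrices:
            if S.shape != shape or S.ndim != 2 or S.shape[0] != S.shape[1]:
                raise ValueError("similarity matrices must be square, same size")
            if np.abs(S - S.T).max() > 1e-10:
                raise ValueError("similarity matrix not symmetric")
        if len(self.kinds) != len(self.matrices):
            raise ValueError("kinds/matrices length mismatch")
        self.combined = np.sum(self.matrices, axis=0)

    @property
    def n_sim(self) -> int:
        return len(self.matrices)

    @property
    def size(self) -> int:
        return self.matrices[0].shape[0]


@dataclasses.dataclass
class GraphLaplacian:
    """L = D − S with degree matrix D_ii = Σ_j S_ij."""

    laplacian: np.ndarray
    degree: np.ndarray


def _cosine(P: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(P, axis=1)
    G = P @ P.T
    denom = np.outer(norms, norms)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denom > 0, G / np.where(denom > 0, denom, 1.0), 0.0)
    return S


def _correlation(P: np.ndarray) -> np.ndarray:
    C = P - P.mean(axis=1, keepdims=True)
    sd = np.linalg.norm(C, axis=1)
    G = C @ C.T
    denom = np.outer(sd, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denom > 0, G / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(S, np.where(sd > 0, 1.0, 0.0))
    return np.clip(S, 0.0, 1.0)


def _hamming(P: np.ndarray) -> np.ndarray:
    # fraction of agreeing positions = 1 - Hamming distance / length
    n = P.shape[1]
    ones = P @ P.T
    zeros = (1.0 - P) @ (1.0 - P).T
    return (ones + zeros) / n


def _jaccard(P: np.ndarray) -> np.ndarray:
    inter = P @ P.T
    sizes = P.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return S


_KERNELS = {"cos": _cosine, "cor": _correlation, "ham": _hamming, "jac": _jaccard}


def profile_similarity(Y: np.ndarray, side: Side, kind: Kind) -> np.ndarray:
    """Similarity between interaction profiles of one side of Y.

    ``side="drug"`` compares rows of the binary matrix Y, ``side="target"``
    compares columns.  Outputs lie in [0, 1] and are exactly symmetric.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.size == 0:
        raise ValueError("Y must be a nonempty 2-D matrix")
    if not np.isin(Y, (0.0, 1.0)).all():
        raise ValueError("Y must be binary")
    if side == "drug":
        P = Y
    elif side == "target":
        P = Y.T
    else:
        raise ValueError(f"unknown side {side!r}")
    try:
        S = _KERNELS[kind](P)
    except KeyError:
        raise ValueError(f"unknown similarity kind {kind!r}") from None
    S = (S + S.T) / 2.0
    return np.clip(S, 0.0, 1.0)


def pnn_sparsify(S: np.ndarray, p: int) -> np.ndarray:
    """Keep only p-nearest-neighbor edges of a similarity matrix.

    An off-diagonal entry (i, j) survives when j is among the p most
    similar neighbors of i *or* i is among the p most similar neighbors of
    j (symmetric OR rule), so the result stays symmetric.  Entries tied
    with the p-th largest are all kept — ties are common with binary
    interaction profiles, and including them keeps the operation
    deterministic and equivariant under relabeling.  The diagonal is
    preserved.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not 1 <= p < n:
        raise ValueError(f"p={p} out of range for size-{n} matrix")
    off = S.astype(float).copy()
    np.fill_diagonal(off, -np.inf)
    # per-row threshold: the p-th largest off-diagonal value; the small
    # slack absorbs float noise among mathematically tied entries
    thr = np.partition(off, n - p, axis=1)[:, n - p]
    keep = off >= thr[:, None] - 1e-9
    keep |= keep.T
    out = np.where(keep, S, 0.0)
    np.fill_diagonal(out, np.diag(S))
    return out


def combine_similarities(
    provided: Optional[np.ndarray],
    Y: np.ndarray,
    side: Side,
    p_nn: Optional[int] = None,
) -> SimilaritySet:
    """Build the five-matrix similarity set for one side.

    The list is [provided-or-zero, cos, cor, ham, jac]; ``combined`` is
    their sum.  With ``p_nn`` set, each matrix is sparsified to its p
    nearest neighbors *before* summation.
    """
    Y = np.asarray(Y, dtype=float)
    size = Y.shape[0] if side == "drug" else Y.shape[1]
    if provided is None:
        provided = np.zeros((size, size))
    else:
        provided = np.asarray(provided, dtype=float)
        if provided.shape != (size, size):
            raise ValueError(
                f"provided similarity shape {provided.shape} does not match "
                f"{side} dimension {size}"
            )
        provided = (provided + provided.T) / 2.0
    mats = [provided] + [profile_similarity(Y, side, k) for k in PROFILE_KINDS]
    if p_nn is not None:
        mats = [pnn_sparsify(S, p_nn) for S in mats]
    return SimilaritySet(mats, ["provided", *PROFILE_KINDS])


def graph_laplacian(S: np.ndarray) -> GraphLaplacian:
    """Unnormalized graph Laplacian L = D − S of a nonnegative symmetric S."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if np.abs(S - S.T).max() > 1e-10:
        raise ValueError("S must be symmetric")
    if S.min() < 0:
        raise ValueError("S must be nonnegative (clip negative weights upstream)")
    D = np.diag(S.sum(axis=1))
    return GraphLaplacian(laplacian=D - S, degree=D)
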