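r"""PCA for p >> n via the n x n similarity (inner-product) matrix.

The sample covariance matrix :math:`C = X^T X / (n-1)` of a methylome matrix
is p x p with p in the millions, so it can be neither stored nor decomposed
directly.  The same principal components are available from the much smaller
n x n matrix :math:`M = X X^T / (n-1)` (principal *coordinate* analysis):
writing :math:`\alpha_i, u_i` for the positive eigenvalues and orthonormal
eigenvectors of :math:`M`, and :math:`\lambda_i, v_i` for those of
:math:`C`,

.. math::

    \lambda_i = \alpha_i, \qquad
    PC_i = X v_i = u_i \sqrt{(n-1)\,\alpha_i}, \qquad
    v_i = \frac{X^T u_i}{\sqrt{(n-1)\,\alpha_i}} .

Assembling :math:`X X^T` is the expensive step; it is computed in
subject-chunk pairs, each an independent job, so memory stays bounded and
jobs can run in parallel or be distributed — the result is identical for any
chunk size.  Column means (and standard deviations in correlation mode) are
computed once over the full sample before chunking, never per chunk.

Measured covariates (batch, input DNA amount, ...) can be regressed out of
every site prior to the PCA so the components capture only the remaining —
typically unmeasured — sources of variation.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .containers import CovariateTable, MethylationMatrix

RANK_RTOL = 1e-9  # relative eigenvalue cutoff for the numerical rank


def residualize(
    data: MethylationMatrix, covs: CovariateTable, which: Sequence[str]
) -> MethylationMatrix:
    """Replace each site by its OLS residual on intercept + named covariates.

    Residual columns are orthogonal to every covariate column by
    construction; residualizing twice with the same covariates is a no-op.
    """
    Z = covs.aligned_to(data.subject_ids, which)
    n = data.n_subjects
    D = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("rank-deficient covariate design (collinear covariates?)")
    beta, *_ = np.linalg.lstsq(D, data.values, rcond=None)
    resid = data.values - D @ beta
    return MethylationMatrix(
        subject_ids=list(data.subject_ids),
        chromosomes=data.chromosomes.copy(),
        positions=data.positions.copy(),
        values=resid,
    )


@dataclass
class PreparedMatrix:
    """Column-centered (and, in correlation mode, unit-variance) data.

    ``dropped`` logs the column indices (into the source matrix) removed in
    correlation mode because they had zero variance; in covariance mode such
    columns are retained as all-zero columns after centering.
    """

    X: np.ndarray
    mode: str  # "covariance" | "correlation"
    subject_ids: list[str]
    chromosomes: np.ndarray
    positions: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray | None
    dropped: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def prepare(data: MethylationMatrix, mode: str = "covariance") -> PreparedMatrix:
    """Center (and scale) columns; the PCA input contract."""
    if mode not in ("covariance", "correlation"):
        raise ValueError(f"mode must be 'covariance' or 'correlation', got {mode!r}")
    means = data.values.mean(axis=0)
    X = data.values - means
    chroms, positions = data.chromosomes, data.positions
    sds = None
    dropped = np.array([], dtype=np.int64)
    if mode == "correlation":
        sds_all = data.values.std(axis=0, ddof=1)
        keep = sds_all > 0.0
        dropped = np.flatnonzero(~keep)
        if not keep.any():
            raise ValueError("all columns have zero variance; correlation-mode PCA undefined")
        if dropped.size:
            warnings.warn(
                f"correlation mode: dropping {dropped.size} zero-variance column(s)",
                stacklevel=2,
            )
        X = X[:, keep] / sds_all[keep]
        means = means[keep]
        sds = sds_all[keep]
        chroms, positions = chroms[keep], positions[keep]
    return PreparedMatrix(
        X=X,
        mode=mode,
        subject_ids=list(data.subject_ids),
        chromosomes=chroms.copy(),
        positions=positions.copy(),
        col_means=means,
        col_sds=sds,
        dropped=dropped,
    )


@dataclass
class SimilarityMatrix:
    """M = X X^T / (n-1) plus a record of how it was assembled."""

    M: np.ndarray
    chunk_size: int
    n_chunk_pairs: int

    def __post_init__(self) -> None:
        M = self.M
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("similarity matrix must be square")
        scale = np.abs(M).max()
        if scale > 0 and np.abs(M - M.T).max() > 1e-10 * scale:
            raise ValueError("similarity matrix is not symmetric")


def chunk_bounds(n: int, chunk_size: int) -> list[tuple[int, int]]:
    if chunk_size < 1:
        raise ValueError(f"chunk_size must be >= 1, got {chunk_size}")
    return [(s, min(s + chunk_size, n)) for s in range(0, n, chunk_size)]


def chunk_pairs(n: int, chunk_size: int) -> list[tuple[int, int]]:
    """Independent (row-chunk, col-chunk) jobs covering the upper triangle."""
    k = len(chunk_bounds(n, chunk_size))
    return [(i, j) for i in range(k) for j in range(i, k)]


def compute_chunk_pair(prep: PreparedMatrix, chunk_size: int, i: int, j: int) -> np.ndarray:
    """One independent job: the (i, j) subject-chunk product of X X^T."""
    bounds = chunk_bounds(prep.n, chunk_size)
    (r0, r1), (c0, c1) = bounds[i], bounds[j]
    return prep.X[r0:r1] @ prep.X[c0:c1].T


def similarity_chunked(
    prep: PreparedMatrix, chunk_size: int, scratch_dir: str | os.PathLike | None = None
) -> SimilarityMatrix:
    """Assemble M = X X^T / (n-1) from independent chunk-pair products.

    With ``scratch_dir`` set, each product is persisted to a binary scratch
    file keyed by (row-chunk, col-chunk) and the assembly reads them back —
    the same contract as running the chunk jobs as separate processes.  The
    assembled M is independent of ``chunk_size`` and of job order.
    """
    n = prep.n
    pairs = chunk_pairs(n, chunk_size)
    if scratch_dir is not None:
        os.makedirs(scratch_dir, exist_ok=True)
        for i, j in pairs:
            np.save(chunk_path(scratch_dir, i, j), compute_chunk_pair(prep, chunk_size, i, j))
        return assemble_similarity(n, chunk_size, scratch_dir)
    M = np.empty((n, n))
    bounds = chunk_bounds(n, chunk_size)
    for i, j in pairs:
        P = compute_chunk_pair(prep, chunk_size, i, j)
        (r0, r1), (c0, c1) = bounds[i], bounds[j]
        M[r0:r1, c0:c1] = P
        if i != j:
            M[c0:c1, r0:r1] = P.T
    M /= n - 1
    return SimilarityMatrix(M=M, chunk_size=chunk_size, n_chunk_pairs=len(pairs))


def chunk_path(scratch_dir: str | os.PathLike, i: int, j: int) -> str:
    return os.path.join(scratch_dir, f"xxt_chunk_{i:04d}_{j:04d}.npy")


def assemble_similarity(
    n: int, chunk_size: int, scratch_dir: str | os.PathLike
) -> SimilarityMatrix:
    """Assemble M from previously persisted chunk-pair products."""
    bounds = chunk_bounds(n, chunk_size)
    pairs = chunk_pairs(n, chunk_size)
    M = np.empty((n, n))
    for i, j in pairs:
        path = chunk_path(scratch_dir, i, j)
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing chunk product {path}")
        P = np.load(path)
        (r0, r1), (c0, c1) = bounds[i], bounds[j]
        M[r0:r1, c0:c1] = P
        if i != j:
            M[c0:c1, r0:r1] = P.T
    M /= n - 1
    return SimilarityMatrix(M=M, chunk_size=chunk_size, n_chunk_pairs=len(pairs))


@dataclass
class PCAResult:
    """Eigenvalues, PC scores and (optionally) top-component loadings.

    ``eigenvalues`` holds every component above the rank cutoff, so a scree
    over the top 10 is available even when fewer scores were requested.
    Scores satisfy var(PC_i) = eigenvalue_i; loadings are unit-norm site-space
    eigenvectors of the covariance (or correlation) matrix.
    """

    eigenvalues: np.ndarray  # (r,) all retained components, descending
    eigenvectors: np.ndarray  # (n, r) orthonormal u_i
    scores: np.ndarray  # (n, n_components)
    loadings: np.ndarray  # (p, n_loadings)
    subject_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def scores_table(self) -> CovariateTable:
        names = [f"PC{i + 1}" for i in range(self.n_components)]
        return CovariateTable(list(self.subject_ids), names, self.scores)


def decompose(
    M: SimilarityMatrix,
    n_components: int,
    n_loadings: int,
    prep: PreparedMatrix,
) -> PCAResult:
    """Eigen-decompose M and map to PC scores and loadings.

    Components with eigenvalue <= RANK_RTOL x the largest are discarded as
    numerically null.  Eigenvector signs are fixed by forcing the entry of
    largest magnitude in each u_i to be positive, so output is deterministic
    across BLAS backends.  ``n_loadings = 0`` computes scores only.
    """
    n = prep.n
    if not 1 <= n_components <= n:
        raise ValueError(f"n_components must be in [1, {n}]")
    if not 0 <= n_loadings <= n_components:
        raise ValueError("n_loadings must be in [0, n_components]")
    w, U = scipy.linalg.eigh(M.M)
    w, U = w[::-1], U[:, ::-1]
    rank = int(np.sum(w > RANK_RTOL * max(w[0], 0.0)))
    if rank == 0:
        raise ValueError("similarity matrix is numerically zero")
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but numerical rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
        n_loadings = min(n_loadings, rank)
    w, U = w[:rank].copy(), U[:, :rank].copy()
    # deterministic sign: largest-|.| entry of each eigenvector made positive
    flip = U[np.abs(U).argmax(axis=0), np.arange(rank)] < 0
    U[:, flip] *= -1.0
    scale = np.sqrt((n - 1) * w)
    scores = U[:, :n_components] * scale[:n_components]
    if n_loadings > 0:
        loadings = (prep.X.T @ U[:, :n_loadings]) / scale[:n_loadings]
    else:
        loadings = np.empty((prep.p, 0))
    return PCAResult(
        eigenvalues=w,
        eigenvectors=U,
        scores=scores,
        loadings=loadings,
        subject_ids=list(prep.subject_ids),
    )


def scree(result: PCAResult, top: int) -> np.ndarray:
    """The ``top`` largest eigenvalues, for the scree (elbow) inspection."""
    if top < 1 or top > result.eigenvalues.size:
        raise ValueError(f"top must be in [1, {result.eigenvalues.size}]")
    return result.eigenvalues[:top].copy()


def dominant_components(eigenvalues: np.ndarray, top: int = 10) -> int:
    """Number of components before the largest relative eigenvalue drop.

    The scree criterion: among consecutive ratios alpha_i / alpha_{i+1} for
    i = 1..top-1, the largest marks the elbow; everything at or before it is
    treated as signal.
    """
    ev = np.asarray(eigenvalues, dtype=float)[:top]
    if ev.size < 2:
        raise ValueError("need at least 2 eigenvalues to locate a gap")
    ratios = ev[:-1] / ev[1:]
    return int(np.argmax(ratios)) + 1


def scree_plot(result: PCAResult, top: int, path: str | os.PathLike) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ev = scree(result, min(top, result.eigenvalues.size))
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(np.arange(1, ev.size + 1), ev, "o-")
    ax.set_xlabel("component")
    ax.set_ylabel("eigenvalue")
    ax.set_title("Scree plot")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pca(
    data: MethylationMatrix,
    mode: str = "covariance",
    chunk_size: int | None = None,
    n_components: int = 10,
    n_loadings: int = 0,
    covariates: CovariateTable | None = None,
    regress_out: Sequence[str] = (),
    scratch_dir: str | os.PathLike | None = None,
) -> PCAResult:
    """Convenience front-end: residualize -> prepare -> similarity -> decompose."""
    if regress_out:
        if covariates is None:
            raise ValueError("regress_out given but no covariate table supplied")
        data = residualize(data, covariates, regress_out)
    prep = prepare(data, mode)
    if chunk_size is None:
        chunk_size = prep.n
    M = similarity_chunked(prep, chunk_size, scratch_dir=scratch_dir)
    n_components = min(n_components, prep.n)
    return decompose(M, n_components, n_loadings, prep)
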