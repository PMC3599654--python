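"""Adaptive merging of neighboring, inter-correlated sites into blocks.

Correlation between nearby CpG sites arises both from assay mechanics (in
enrichment sequencing, neighboring sites are covered by the same DNA
fragments) and from regional biology (co-methylated domains).  Instead of a
fixed-width sliding window, blocks are grown adaptively from the observed
inter-correlations, and the analysis then proceeds on per-block means, which
reduces dimension and improves signal-to-noise.  Sites uncorrelated with
their neighbors survive as singleton blocks, so no site is ever dropped.

Three parameters control growth of a block:

``t1``
    minimum mean pairwise Pearson correlation over all site pairs inside the
    block;
``t2``
    minimum mean correlation of a newly considered site with the sites
    already in the block;
``nt``
    how many *consecutive* additions below ``t2`` are tolerated before the
    block is closed.

The scan is greedy and strictly left-to-right within each chromosome: open a
block at the leftmost unassigned site, keep appending the next site in
coordinate order, and stop when the block mean drops below ``t1`` or when
``nt`` consecutive below-``t2`` additions have accumulated.  On stopping, the
trailing below-``t2`` run (and the site that broke ``t1``, if any) is removed
from the block, the block is closed, and the scan restarts at the first
removed site.  Blocks never span chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Block, BlockMap, MethylationMatrix


@dataclass(frozen=True)
class BlockParams:
    """Thresholds of the adaptive merge; see module docstring."""

    t1: float
    t2: float
    nt: int = 2

    def __post_init__(self) -> None:
        for name, v in (("t1", self.t1), ("t2", self.t2)):
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {v}")
        if self.nt < 1:
            raise ValueError(f"nt must be >= 1, got {self.nt}")


def _safe_corr(xc: np.ndarray, xn: float, yc: np.ndarray, yn: float) -> float:
    """Pearson r from pre-centered vectors and norms; 0 if either is constant.

    A zero-variance column has no defined correlation; treating it as 0 keeps
    it below any positive threshold, so constant sites become singletons
    instead of propagating NaN through the merge decisions.
    """
    if xn == 0.0 or yn == 0.0:
        return 0.0
    return float(xc @ yc / (xn * yn))


def pairwise_correlation(x: np.ndarray, ys: list[np.ndarray] | np.ndarray) -> float:
    """Mean Pearson correlation of ``x`` against each column in ``ys``."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("x must be a vector of length >= 2")
    xc = x - x.mean()
    xn = float(np.linalg.norm(xc))
    total = 0.0
    count = 0
    for y in np.atleast_2d(np.asarray(ys, dtype=np.float64)):
        if y.shape != x.shape:
            raise ValueError("all vectors must share the same length")
        yc = y - y.mean()
        total += _safe_corr(xc, xn, yc, float(np.linalg.norm(yc)))
        count += 1
    if count == 0:
        raise ValueError("ys must contain at least one vector")
    return total / count


def _mean_pairwise(centered: np.ndarray, norms: np.ndarray, members: list[int]) -> float | None:
    """Mean correlation over all unordered member pairs (None for singletons)."""
    m = len(members)
    if m < 2:
        return None
    total = 0.0
    for a in range(m):
        ia = members[a]
        for b in range(a + 1, m):
            ib = members[b]
            total += _safe_corr(centered[:, ia], norms[ia], centered[:, ib], norms[ib])
    return total / (m * (m - 1) / 2)


def build_blocks(
    data: MethylationMatrix, params: BlockParams
) -> tuple[BlockMap, MethylationMatrix]:
    """Run the greedy merge and return the block map plus block-mean matrix.

    The returned matrix has one column per block holding the arithmetic mean
    of the member sites for each subject; its per-block position is the start
    position of the block, which keeps the karyotype ordering valid.
    """
    X = data.values
    n = data.n_subjects
    if n < 2:
        raise ValueError("correlation is undefined with fewer than 2 subjects")
    centered = X - X.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)

    blocks: list[Block] = []
    for chrom, sl in data.chromosome_slices().items():
        lo, hi = sl.start, sl.stop
        start = lo
        while start < hi:
            members = [start]
            pair_sum = 0.0  # running sum of pairwise correlations in the block
            tail: list[int] = []  # trailing run of members admitted with c < t2
            j = start + 1
            removed_at: int | None = None
            while j < hi:
                corrs = [
                    _safe_corr(centered[:, j], norms[j], centered[:, i], norms[i])
                    for i in members
                ]
                c = float(np.mean(corrs))
                m = len(members) + 1
                new_pair_sum = pair_sum + float(np.sum(corrs))
                mean_pair = new_pair_sum / (m * (m - 1) / 2)
                if c < params.t2:
                    tail.append(j)
                else:
                    tail = []
                broke_t1 = mean_pair < params.t1
                if broke_t1 or len(tail) >= params.nt:
                    removal = set(tail)
                    if broke_t1:
                        removal.add(j)
                    members = [i for i in members if i not in removal]
                    removed_at = min(removal)
                    break
                members.append(j)
                pair_sum = new_pair_sum
                j += 1
            blocks.append(
                Block(
                    chromosome=str(chrom),
                    start=int(data.positions[members[0]]),
                    end=int(data.positions[members[-1]]),
                    n_sites=len(members),
                    mean_corr=_mean_pairwise(centered, norms, members),
                    sites=tuple(members),
                )
            )
            start = removed_at if removed_at is not None else j

    block_map = BlockMap(blocks)
    means = np.column_stack([X[:, list(b.sites)].mean(axis=1) for b in blocks])
    block_matrix = MethylationMatrix(
        subject_ids=list(data.subject_ids),
        chromosomes=np.array([b.chromosome for b in blocks], dtype=object),
        positions=np.array([b.start for b in blocks], dtype=np.int64),
        values=means,
    )
    return block_map, block_matrix


def two_stage_blocks(
    data: MethylationMatrix, stage1: BlockParams, stage2: BlockParams
) -> tuple[BlockMap, BlockMap, MethylationMatrix]:
    """Cascade two merges: fragment-scale first, broader correlation second.

    Stage 2 runs the same greedy merge on the stage-1 block-mean matrix.  The
    returned composite map resolves each level-2 block back to original site
    coordinates: span = first member's start to last member's end, ``n_sites``
    counts original sites, ``sites`` holds original column indices.  A level-2
    block containing a single level-1 block inherits that block's mean
    correlation (its own level-2 mean is undefined).
    """
    map1, mat1 = build_blocks(data, stage1)
    map2, mat2 = build_blocks(mat1, stage2)

    composite: list[Block] = []
    level1 = map1.blocks
    for b2 in map2:
        members1 = [level1[i] for i in b2.sites]
        site_indices: tuple[int, ...] = tuple(i for b in members1 for i in b.sites)
        n_sites = sum(b.n_sites for b in members1)
        if len(members1) == 1:
            corr = members1[0].mean_corr
        else:
            corr = b2.mean_corr
        composite.append(
            Block(
                chromosome=b2.chromosome,
                start=members1[0].start,
                end=members1[-1].end,
                n_sites=n_sites,
                mean_corr=corr if n_sites > 1 else None,
                sites=site_indices,
            )
        )
    return map1, BlockMap(composite), mat2
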