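"""In-memory containers shared across the toolkit.

The central object is :class:`MethylationMatrix`: an ``n x p`` matrix of
quantitative methylation values (n subjects, p sites) with per-site genomic
coordinates.  Sites are kept in karyotype order: each chromosome occupies one
contiguous run of columns, and positions increase strictly within a
chromosome.  Because p is typically orders of magnitude larger than n, the
matrix is stored sites-last (subjects are rows) and all per-site operations
are vectorised over columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np


class SiteCoord(NamedTuple):
    """Genomic coordinate of a single methylation site (1-based position)."""

    chromosome: str
    position: int


@dataclass(frozen=True)
class SiteFilter:
    """Include- or exclude-list of site coordinates applied at load time."""

    mode: str  # "include" | "exclude"
    coords: frozenset[SiteCoord]

    def __post_init__(self) -> None:
        if self.mode not in ("include", "exclude"):
            raise ValueError(f"filter mode must be 'include' or 'exclude', got {self.mode!r}")
        object.__setattr__(self, "coords", frozenset(SiteCoord(c, int(p)) for c, p in self.coords))

    def keeps(self, coord: SiteCoord) -> bool:
        member = coord in self.coords
        return member if self.mode == "include" else not member


@dataclass
class MethylationMatrix:
    """Subjects x sites quantitative methylation values with coordinates.

    Parameters
    ----------
    subject_ids
        Unique subject labels, one per row.
    chromosomes
        Chromosome label per site (length p).  Each chromosome must form one
        contiguous run; the run order defines chromosome order.
    positions
        1-based base-pair position per site, strictly increasing within a
        chromosome.
    values
        ``n x p`` float array, all entries finite.
    """

    subject_ids: list[str]
    chromosomes: np.ndarray
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        n, p = self.values.shape
        if n < 2:
            raise ValueError("a methylation matrix needs at least 2 subjects")
        if p < 1:
            raise ValueError("a methylation matrix needs at least 1 site")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match value rows")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ID")
        if self.chromosomes.shape != (p,) or self.positions.shape != (p,):
            raise ValueError("site annotation length does not match value columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite methylation value")
        if np.any(self.positions < 1):
            raise ValueError("positions are 1-based and must be >= 1")
        seen: set[str] = set()
        prev_chrom: str | None = None
        prev_pos = 0
        for chrom, pos in zip(self.chromosomes, self.positions):
            if chrom != prev_chrom:
                if chrom in seen:
                    raise ValueError(f"unsorted sites: chromosome {chrom!r} occurs in two runs")
                seen.add(chrom)
                prev_chrom = chrom
                prev_pos = 0
            if pos <= prev_pos:
                raise ValueError(
                    f"unsorted sites: position {pos} after {prev_pos} on chromosome {chrom!r}"
                )
            prev_pos = pos

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    @property
    def sites(self) -> list[SiteCoord]:
        return [SiteCoord(c, int(p)) for c, p in zip(self.chromosomes, self.positions)]

    def chromosome_order(self) -> list[str]:
        """Chromosome labels in their order of appearance."""
        order: list[str] = []
        for c in self.chromosomes:
            if not order or order[-1] != c:
                order.append(c)
        return order

    def chromosome_slices(self) -> dict[str, slice]:
        """Column slice of each chromosome's contiguous run."""
        out: dict[str, slice] = {}
        start = 0
        chroms = self.chromosomes
        for j in range(1, len(chroms) + 1):
            if j == len(chroms) or chroms[j] != chroms[start]:
                out[str(chroms[start])] = slice(start, j)
                start = j
        return out

    def select_sites(self, mask: np.ndarray) -> "MethylationMatrix":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty matrix after filtering")
        return MethylationMatrix(
            subject_ids=list(self.subject_ids),
            chromosomes=self.chromosomes[mask],
            positions=self.positions[mask],
            values=self.values[:, mask],
        )

    def equals(self, other: "MethylationMatrix", rtol: float = 0.0, atol: float = 0.0) -> bool:
        return (
            self.subject_ids == other.subject_ids
            and list(self.chromosomes) == list(other.chromosomes)
            and np.array_equal(self.positions, other.positions)
            and np.allclose(self.values, other.values, rtol=rtol, atol=atol)
        )


@dataclass
class CovariateTable:
    """Subject-per-row covariate values (age, sex, batch, PC scores, ...)."""

    subject_ids: list[str]
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.names = [str(c) for c in self.names]
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape != (len(self.subject_ids), len(self.names)):
            raise ValueError("covariate value shape does not match labels")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ID in covariate table")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite covariate value")

    def aligned_to(self, subject_ids: Sequence[str], names: Iterable[str] | None = None) -> np.ndarray:
        """Rows reordered to ``subject_ids``, columns restricted to ``names``.

        The table must cover every requested subject.  Constant columns after
        alignment are rejected: they are collinear with the intercept.
        """
        index = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in index]
        if missing:
            raise ValueError(f"covariate table is missing subjects: {missing[:5]}")
        rows = [index[s] for s in subject_ids]
        use = list(self.names) if names is None else list(names)
        unknown = [c for c in use if c not in self.names]
        if unknown:
            raise KeyError(f"unknown covariate(s): {unknown}")
        cols = [self.names.index(c) for c in use]
        out = self.values[np.ix_(rows, cols)]
        for k, name in enumerate(use):
            if np.ptp(out[:, k]) == 0.0:
                raise ValueError(f"covariate {name!r} is constant over the analysis subjects")
        return out


@dataclass
class Block:
    """One block: a contiguous run of sites on a single chromosome.

    ``start`` / ``end`` are 1-based inclusive positions of the first and last
    member sites.  ``mean_corr`` is the mean Pearson correlation over all
    unordered member pairs; it is undefined (None) for singleton blocks.
    ``sites`` optionally records member column indices into the source matrix
    and is not part of the on-disk record, hence excluded from equality.
    """

    chromosome: str
    start: int
    end: int
    n_sites: int
    mean_corr: float | None
    sites: tuple[int, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("a block needs at least one site")
        if self.end < self.start:
            raise ValueError("block end before start")
        if self.n_sites == 1 and self.mean_corr is not None:
            raise ValueError("singleton block cannot carry a mean correlation")
        if self.n_sites > 1 and self.mean_corr is None:
            raise ValueError("multi-site block needs a mean correlation")


@dataclass
class BlockMap:
    """Ordered block definitions partitioning the retained sites."""

    blocks: list[Block]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev_end: dict[str, int] = {}
        seen: list[str] = []
        for b in self.blocks:
            if not seen or seen[-1] != b.chromosome:
                if b.chromosome in seen:
                    raise ValueError(f"chromosome {b.chromosome!r} occurs in two runs")
                seen.append(b.chromosome)
            if b.chromosome in prev_end and b.start <= prev_end[b.chromosome]:
                raise ValueError(
                    f"overlapping blocks on chromosome {b.chromosome!r} at {b.start}"
                )
            prev_end[b.chromosome] = b.end

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BlockMap) and self.blocks == other.blocks
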