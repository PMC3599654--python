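"""Readers and writers for every on-disk artifact.

All formats are plain tab-separated text:

* methylation matrix — one row per site, columns ``chrom``, ``pos`` (1-based),
  then one column per subject ID (header row mandatory);
* site filters — two columns ``chrom``, ``pos``;
* covariate / phenotype tables — first column ``subject_id``;
* block maps — BED-like, ``chrom  start  end  block_id  n_sites  mean_corr``
  with 0-based half-open spans (converted from the 1-based inclusive
  in-memory representation) and ``.`` for the undefined mean correlation of
  singleton blocks;
* PCA outputs — eigenvalue, PC-score and loading tables.

Missing values (literal ``NA``) in the matrix are rejected at load: silent
imputation would change PCA results invisibly, so incomplete data must be
handled upstream.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    Block,
    BlockMap,
    CovariateTable,
    MethylationMatrix,
    SiteCoord,
    SiteFilter,
)

MISSING_SENTINELS = ("NA", "NaN", "nan", "")


def read_methylation(path: str | os.PathLike, site_filter: SiteFilter | None = None) -> MethylationMatrix:
    """Load a site-per-row matrix TSV, optionally applying a site filter.

    Raises on duplicate subject IDs, unsorted sites, non-numeric cells and an
    empty matrix after filtering; these are data errors, never warnings.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[:2] != ["chrom", "pos"]:
        raise ValueError(f"{path}: first two columns must be 'chrom' and 'pos'")
    subject_ids = header[2:]
    if len(subject_ids) != len(set(subject_ids)):
        raise ValueError(f"{path}: duplicate subject ID in header")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, header=0, names=header)
    if len(subject_ids) < 2:
        raise ValueError(f"{path}: need at least 2 subject columns")
    chroms = df["chrom"].to_numpy(dtype=object)
    try:
        positions = df["pos"].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer position: {exc}") from None
    cells = df.iloc[:, 2:]
    bad = cells.isin(MISSING_SENTINELS)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(f"{path}: missing value at site row {r}, subject {subject_ids[c]}")
    try:
        values = cells.astype(np.float64).to_numpy().T  # subjects x sites
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell: {exc}") from None
    if site_filter is not None:
        keep = np.fromiter(
            (site_filter.keeps(SiteCoord(c, int(p))) for c, p in zip(chroms, positions)),
            dtype=bool,
            count=len(chroms),
        )
        if not keep.any():
            raise ValueError(f"{path}: empty matrix after filtering")
        chroms, positions, values = chroms[keep], positions[keep], values[:, keep]
    return MethylationMatrix(subject_ids, chroms, positions, values)


def write_methylation(data: MethylationMatrix, path: str | os.PathLike, float_format: str = "%.10g") -> None:
    df = pd.concat(
        [
            pd.DataFrame({"chrom": data.chromosomes, "pos": data.positions}),
            pd.DataFrame(data.values.T, columns=data.subject_ids),
        ],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_site_filter(path: str | os.PathLike, mode: str) -> SiteFilter:
    """Two-column (chrom, pos) list of coordinates to include or exclude."""
    coords = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'chrom<TAB>pos'")
            coords.add(SiteCoord(parts[0], int(parts[1])))
    return SiteFilter(mode=mode, coords=frozenset(coords))


def read_covariates(path: str | os.PathLike) -> CovariateTable:
    """Subject-per-row TSV; first column is the subject ID."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a subject-ID column plus at least one value column")
    subject_ids = df.iloc[:, 0].astype(str).tolist()
    names = [str(c) for c in df.columns[1:]]
    values = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    return CovariateTable(subject_ids, names, values)


def write_covariates(table: CovariateTable, path: str | os.PathLike, id_header: str = "subject_id") -> None:
    df = pd.DataFrame(table.values, columns=table.names)
    df.insert(0, id_header, table.subject_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotype(path: str | os.PathLike, column: str | None = None) -> tuple[list[str], np.ndarray]:
    """Phenotype vector keyed by subject ID (first column of the TSV)."""
    table = read_covariates(path)
    name = column if column is not None else table.names[0]
    if name not in table.names:
        raise KeyError(f"{path}: no phenotype column {name!r}")
    return list(table.subject_ids), table.values[:, table.names.index(name)].copy()


_BLOCK_COLUMNS = ("chrom", "start", "end", "block_id", "n_sites", "mean_corr")


def write_block_map(blocks: BlockMap, path: str | os.PathLike) -> None:
    """Serialise a block map as BED-like TSV (0-based half-open spans).

    Refuses invalid maps (overlaps are caught by BlockMap validation).  The
    undefined mean correlation of singleton blocks is written as ``.``.
    """
    blocks.validate()
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_BLOCK_COLUMNS) + "\n")
        for i, b in enumerate(blocks):
            corr = "." if b.mean_corr is None else format(float(b.mean_corr), ".17g")
            fh.write(f"{b.chromosome}\t{b.start - 1}\t{b.end}\t{i}\t{b.n_sites}\t{corr}\n")


def read_block_map(path: str | os.PathLike) -> BlockMap:
    out: list[Block] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{ln}: malformed block record ({len(parts)} fields)")
            chrom, start, end, _block_id, n_sites, corr = parts
            out.append(
                Block(
                    chromosome=chrom,
                    start=int(start) + 1,
                    end=int(end),
                    n_sites=int(n_sites),
                    mean_corr=None if corr == "." else float(corr),
                )
            )
    return BlockMap(out)  # validation catches overlapping spans


def write_eigenvalues(eigenvalues: Sequence[float], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"component": np.arange(1, len(eigenvalues) + 1), "eigenvalue": np.asarray(eigenvalues)}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_eigenvalues(path: str | os.PathLike) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["eigenvalue"].to_numpy()


def write_scores(subject_ids: Sequence[str], scores: np.ndarray, path: str | os.PathLike) -> None:
    """PC scores as a covariate-style table (columns PC1, PC2, ...)."""
    names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    write_covariates(CovariateTable(list(subject_ids), names, scores), path)


def read_scores(path: str | os.PathLike) -> CovariateTable:
    return read_covariates(path)


def write_loadings(
    data_sites: Iterable[SiteCoord], loadings: np.ndarray, path: str | os.PathLike
) -> None:
    sites = list(data_sites)
    df = pd.DataFrame(
        {"chrom": [s.chromosome for s in sites], "pos": [s.position for s in sites]}
    )
    for i in range(loadings.shape[1]):
        df[f"PC{i + 1}"] = loadings[:, i]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_association(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_association(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
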