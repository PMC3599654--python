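"""Per-site association testing with genomic control.

Each methylation site (or block) is tested by multiple linear regression of
the phenotype on the site value plus chosen covariates — measured ones (age,
sex, batch) and/or top PC scores capturing unmeasured confounders.  Linear
regression is used even for 0/1 case status.  The reported statistic is the
t statistic of the methylation coefficient with its two-sided Student-t
p-value.

Inflation of the whole test-statistic distribution is summarised by the
genomic-control factor lambda: each two-sided p-value is mapped to the
chi-square(1) upper quantile it corresponds to and the median of those
values is divided by the chi-square(1) median (~0.4549).  Lambda is close to
1 when no site is associated; values well above 1 indicate confounding.

The per-site sweep is vectorised through the Frisch-Waugh-Lovell identity:
residualize the phenotype and every site on the shared covariate design
once, then each site's coefficient, standard error and t statistic follow
from scalar products of the residual vectors — algebraically identical to
fitting the full regression site by site.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import BlockMap, CovariateTable, MethylationMatrix

#: median of the chi-square distribution with 1 degree of freedom
CHI2_1_MEDIAN = float(scipy.stats.chi2.ppf(0.5, df=1))  # 0.45493642...

ASSOC_COLUMNS = ("chrom", "start", "end", "beta", "se", "stat", "p")


def test_site(
    y: np.ndarray, x: np.ndarray, Z: np.ndarray | None = None
) -> tuple[float, float, float, float]:
    """OLS of ``y`` on [intercept, x, Z]; returns (beta, se, t, p) for x.

    A rank-deficient design (constant site, collinear covariates) flags the
    site: NaN is returned for all four values.
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    n = y.size
    cols = [np.ones(n), x]
    if Z is not None and np.asarray(Z).size:
        cols.append(np.atleast_2d(np.asarray(Z, dtype=np.float64)).reshape(n, -1))
    D = np.column_stack(cols)
    q = D.shape[1] - 2  # number of covariates beyond intercept + site
    if n <= q + 2 or np.linalg.matrix_rank(D) < D.shape[1]:
        return (np.nan, np.nan, np.nan, np.nan)
    DtD = D.T @ D
    beta_hat = np.linalg.solve(DtD, D.T @ y)
    resid = y - D @ beta_hat
    df = n - q - 2
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 * np.linalg.inv(DtD)[1, 1]))
    beta = float(beta_hat[1])
    t = beta / se
    p = float(2.0 * scipy.stats.t.sf(abs(t), df))
    return (beta, se, t, p)


def _covariate_design(
    subject_ids: Sequence[str],
    covariates: CovariateTable | None,
    use_covariates: Sequence[str],
    pcs: CovariateTable | None,
    n_pcs: int,
) -> np.ndarray:
    parts: list[np.ndarray] = []
    if use_covariates:
        if covariates is None:
            raise ValueError("covariate names given but no covariate table supplied")
        parts.append(covariates.aligned_to(subject_ids, use_covariates))
    if n_pcs > 0:
        if pcs is None:
            raise ValueError("n_pcs > 0 but no PC score table supplied")
        if n_pcs > len(pcs.names):
            raise ValueError(f"requested {n_pcs} PCs but only {len(pcs.names)} available")
        parts.append(pcs.aligned_to(subject_ids, pcs.names[:n_pcs]))
    if not parts:
        return np.empty((len(subject_ids), 0))
    return np.column_stack(parts)


def run_mwas(
    data: MethylationMatrix,
    pheno_ids: Sequence[str],
    phenotype: np.ndarray,
    covariates: CovariateTable | None = None,
    use_covariates: Sequence[str] = (),
    pcs: CovariateTable | None = None,
    n_pcs: int = 0,
    block_map: BlockMap | None = None,
) -> pd.DataFrame:
    """Test every site (or block) against the phenotype; one row per column.

    Chromosomes are processed independently, so execution order over
    chromosomes cannot change the table.  ``block_map``, when given, supplies
    genomic spans for the output (the matrix columns are then block means);
    otherwise each site spans a single base.
    """
    if data.n_sites == 0:
        raise ValueError("no sites to test")
    index = {s: i for i, s in enumerate(pheno_ids)}
    missing = [s for s in data.subject_ids if s not in index]
    if missing:
        raise ValueError(f"phenotype is missing subjects: {missing[:5]}")
    y = np.asarray(phenotype, dtype=np.float64)[[index[s] for s in data.subject_ids]]
    Z = _covariate_design(data.subject_ids, covariates, use_covariates, pcs, n_pcs)

    n = data.n_subjects
    q = Z.shape[1]
    df = n - q - 2
    if df < 1:
        raise ValueError("not enough subjects for the requested design")

    # Frisch-Waugh-Lovell: project out [1, Z] from y and all sites at once
    D = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta_all = np.empty(data.n_sites)
    se_all = np.empty(data.n_sites)
    stat_all = np.empty(data.n_sites)
    p_all = np.empty(data.n_sites)
    DtD_inv = np.linalg.inv(D.T @ D)
    y_res = y - D @ (DtD_inv @ (D.T @ y))
    for chrom, sl in data.chromosome_slices().items():
        X = data.values[:, sl]
        X_res = X - D @ (DtD_inv @ (D.T @ X))
        sxx = np.einsum("ij,ij->j", X_res, X_res)
        sxy = X_res.T @ y_res
        ok = sxx > np.finfo(float).eps * n * np.maximum(1.0, (X * X).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = sxy / sxx
            sse = float(y_res @ y_res) - beta * sxy
            se = np.sqrt(np.maximum(sse, 0.0) / df / sxx)
            t = beta / se
        beta[~ok] = np.nan
        se[~ok] = np.nan
        t[~ok] = np.nan
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
        beta_all[sl], se_all[sl], stat_all[sl], p_all[sl] = beta, se, t, p

    if block_map is not None:
        if len(block_map) != data.n_sites:
            raise ValueError("block map length does not match matrix columns")
        chroms = [b.chromosome for b in block_map]
        starts = [b.start for b in block_map]
        ends = [b.end for b in block_map]
    else:
        chroms = list(data.chromosomes)
        starts = data.positions.tolist()
        ends = data.positions.tolist()
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "beta": beta_all,
            "se": se_all,
            "stat": stat_all,
            "p": p_all,
        }
    )


@dataclass(frozen=True)
class GCSummary:
    """Genomic-control inflation summary."""

    lam: float
    n_tests: int
    reference_median: float = CHI2_1_MEDIAN


def genomic_lambda(table: pd.DataFrame) -> GCSummary:
    """Median chi-square(1)-equivalent statistic over the chi-square(1) median."""
    p = table["p"].to_numpy(dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no valid p-values: lambda undefined")
    chi2 = scipy.stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    return GCSummary(lam=lam, n_tests=int(p.size))


def qq_data(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, float]:
    """(expected, observed) -log10 p for ranked p-values, plus lambda.

    Expected quantiles are i/(m+1) for the i-th smallest of m observed
    p-values, the standard uniform-order-statistics reference.
    """
    p = table["p"].to_numpy(dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no valid p-values")
    observed = np.sort(p)
    m = observed.size
    expected = np.arange(1, m + 1) / (m + 1.0)
    lam = genomic_lambda(table).lam
    with np.errstate(divide="ignore"):
        return -np.log10(expected), -np.log10(observed), lam


def qq_plot(table: pd.DataFrame, path: str | os.PathLike) -> float:
    """Render the QQ plot with the lambda annotation; returns lambda."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    exp_q, obs_q, lam = qq_data(table)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(exp_q, obs_q, ".", ms=3)
    lim = max(exp_q.max(), np.nanmax(obs_q[np.isfinite(obs_q)]))
    ax.plot([0, lim], [0, lim], "r-", lw=1)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    ax.set_title(f"QQ plot (lambda = {lam:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return lam


def multiple_testing(
    table: pd.DataFrame, method: str = "bh-fdr", level: float = 0.05
) -> pd.DataFrame:
    """Add significance flags: Bonferroni or Benjamini-Hochberg step-up.

    Adds a ``significant`` boolean column and, for BH, a ``q`` column of
    adjusted p-values.  Sites with missing p are never flagged.
    """
    if method not in ("bonferroni", "bh-fdr"):
        raise ValueError(f"method must be 'bonferroni' or 'bh-fdr', got {method!r}")
    out = table.copy()
    p = out["p"].to_numpy(dtype=float)
    valid = np.isfinite(p)
    flags = np.zeros(p.size, dtype=bool)
    if method == "bonferroni":
        m = int(valid.sum())
        if m:
            flags[valid] = p[valid] <= level / m
    else:
        q = np.full(p.size, np.nan)
        if valid.any():
            rej, qvals, *_ = multipletests(p[valid], alpha=level, method="fdr_bh")
            flags[valid] = rej
            q[valid] = qvals
        out["q"] = q
    out["significant"] = flags
    return out
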