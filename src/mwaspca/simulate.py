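"""Synthetic case-control methylation data with planted confounders.

The generator produces the study conditions used throughout the test suite:
a balanced case-control cohort whose methylome carries K latent confounding
factors, each correlated with case status and each influencing a contiguous
band of chromosomes.  Because no site has a direct phenotype effect, every
association found on the raw data is spurious — the design isolates exactly
the inflation that PC adjustment is meant to remove.

Generative model, for subject i with case status y_i (fixed counts of cases
and controls) and site j:

* a continuous factor:  F_ik = b_k * y_i + m_ik,  m_ik ~ Normal(0, sigma^2);
* a dichotomous factor: F_ik ~ Bernoulli(p1) for cases, Bernoulli(p2) for
  controls;
* methylation:  x_ij = a_j + sum_k w_k * F_ik * l_kj + e_ij, with base level
  a_j ~ Uniform(a_range), noise e_ij ~ Normal(0, delta^2) and l_kj in {0,1}
  the influence indicator.  Factor k influences every site of chromosomes
  (k-1)*2+1 .. (k-1)*2+3, so each factor covers 3 chromosomes and adjacent
  factors share exactly one.
* all values are shifted by the global minimum so methylation is
  non-negative, as coverage-derived scores are.

The per-site effect weight w_k is 1 for continuous factors.  For dichotomous
factors it is ``dichotomous_effect`` (default 20), calibrated so that a
dichotomous confounder carries the same covariance with case status through
the sites as a continuous one at the default settings (20 x 0.25 x (p1-p2)
= b x 0.25 = 1): a raw 0/1 factor against noise of SD 40 would be invisible,
and the two confounder types are meant to induce comparable inflation.

Site counts per chromosome are Poisson; positions are consecutive integers
spaced 100 bp apart (spacing only matters for block-builder toys).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import MethylationMatrix


@dataclass(frozen=True)
class SimConfig:
    """All generative parameters; defaults are the standard study setting."""

    n_cases: int = 500
    n_controls: int = 500
    factor_types: tuple[str, ...] = ("continuous",) * 3 + ("dichotomous",) * 2
    b: float = 4.0  # case-status effect on a continuous factor
    sigma: float = 10.0  # SD of continuous-factor noise
    p1: float = 0.6  # Pr(F = 1 | case) for dichotomous factors
    p2: float = 0.4  # Pr(F = 1 | control)
    dichotomous_effect: float = 20.0  # per-site weight of a dichotomous factor
    a_range: tuple[float, float] = (0.0, 100.0)  # uniform base-level range
    delta: float = 40.0  # SD of per-site methylation noise
    n_chromosomes: int = 22
    sites_per_chrom_mean: float = 4000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        for t in self.factor_types:
            if t not in ("continuous", "dichotomous"):
                raise ValueError(f"unknown factor type {t!r}")
        if not 0.0 <= self.p2 <= self.p1 <= 1.0:
            raise ValueError("need 0 <= p2 <= p1 <= 1")
        if self.sigma <= 0 or self.delta <= 0:
            raise ValueError("sigma and delta must be positive")
        if self.a_range[1] < self.a_range[0]:
            raise ValueError("empty base-level range")
        K = len(self.factor_types)
        if K and (K - 1) * 2 + 3 > self.n_chromosomes:
            raise ValueError(
                f"{K} factors need at least {(K - 1) * 2 + 3} chromosomes "
                f"(have {self.n_chromosomes})"
            )
        if self.sites_per_chrom_mean <= 0:
            raise ValueError("sites_per_chrom_mean must be positive")

    @property
    def n_factors(self) -> int:
        return len(self.factor_types)

    @property
    def n_subjects(self) -> int:
        return self.n_cases + self.n_controls

    def influenced_chromosomes(self, k: int) -> range:
        """1-based chromosome numbers influenced by factor k (0-based k)."""
        return range(k * 2 + 1, k * 2 + 4)


@dataclass
class SimOutput:
    """A simulated dataset plus the ground truth that generated it."""

    data: MethylationMatrix
    phenotype: np.ndarray  # (n,) 0/1 case status
    factors: np.ndarray  # (n, K) true confounder values
    influence: np.ndarray  # (K, p) boolean l_kj indicator
    config: SimConfig = field(repr=False)


def simulate(config: SimConfig) -> SimOutput:
    """Draw one dataset; bit-identical for a fixed config (seed included)."""
    rng = np.random.default_rng(config.seed)
    n, K = config.n_subjects, config.n_factors

    y = np.concatenate([np.ones(config.n_cases), np.zeros(config.n_controls)])

    F = np.empty((n, K))
    w = np.empty(K)
    for k, ftype in enumerate(config.factor_types):
        if ftype == "continuous":
            F[:, k] = config.b * y + rng.normal(0.0, config.sigma, size=n)
            w[k] = 1.0
        else:
            prob = np.where(y == 1, config.p1, config.p2)
            F[:, k] = rng.random(n) < prob
            w[k] = config.dichotomous_effect

    counts = rng.poisson(config.sites_per_chrom_mean, size=config.n_chromosomes)
    counts = np.maximum(counts, 1)  # a chromosome with zero sites is unrepresentable
    p = int(counts.sum())
    chroms = np.concatenate(
        [np.full(c, str(i + 1), dtype=object) for i, c in enumerate(counts)]
    )
    positions = np.concatenate([100 * np.arange(1, c + 1) for c in counts])

    influence = np.zeros((K, p), dtype=bool)
    chrom_of_site = np.repeat(np.arange(1, config.n_chromosomes + 1), counts)
    for k in range(K):
        for c in config.influenced_chromosomes(k):
            influence[k] |= chrom_of_site == c

    a = rng.uniform(config.a_range[0], config.a_range[1], size=p)
    X = a + (F * w) @ influence + rng.normal(0.0, config.delta, size=(n, p))
    X -= X.min()  # enforce non-negative methylation levels

    data = MethylationMatrix(
        subject_ids=[f"S{i + 1:05d}" for i in range(n)],
        chromosomes=chroms,
        positions=positions,
        values=X,
    )
    return SimOutput(data=data, phenotype=y, factors=F, influence=influence, config=config)


def factor_phenotype_correlation(config: SimConfig, factor_type: str) -> float:
    """Analytic Pearson correlation between a factor and case status.

    Assumes equal numbers of cases and controls.  For a continuous factor
    F = b*y + m the point-biserial correlation is b/2 / sqrt(b^2/4 + sigma^2);
    for a dichotomous factor it is (p1-p2)/2 / sqrt(pbar*(1-pbar)) with
    pbar = (p1+p2)/2.
    """
    if factor_type == "continuous":
        return 0.5 * config.b / np.sqrt(0.25 * config.b**2 + config.sigma**2)
    if factor_type == "dichotomous":
        pbar = 0.5 * (config.p1 + config.p2)
        if pbar in (0.0, 1.0):
            return 0.0
        return 0.5 * (config.p1 - config.p2) / np.sqrt(pbar * (1.0 - pbar))
    raise ValueError(f"unknown factor type {factor_type!r}")


def _mix(n_continuous: int, n_dichotomous: int) -> tuple[str, ...]:
    return ("continuous",) * n_continuous + ("dichotomous",) * n_dichotomous


#: The six standard confounder mixes (5 factors split continuous/dichotomous).
PRESETS: dict[str, SimConfig] = {
    f"{c}c{5 - c}d": SimConfig(factor_types=_mix(c, 5 - c)) for c in range(6)
}
PRESETS["null"] = SimConfig(factor_types=())


def preset(
    name: str, seed: int = 0, sites_per_chrom_mean: float | None = None
) -> SimConfig:
    """A named preset, optionally re-seeded or scaled in site count."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = replace(PRESETS[name], seed=seed)
    if sites_per_chrom_mean is not None:
        cfg = replace(cfg, sites_per_chrom_mean=sites_per_chrom_mean)
    return cfg
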