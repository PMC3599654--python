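import numpy as np
import pytest

from mwaspca import MethylationMatrix


@pytest.fixture
def tiny_matrix() -> MethylationMatrix:
    """3 subjects x 4 sites on two chromosomes; values are hand-picked."""
    return MethylationMatrix(
        subject_ids=["a", "b", "c"],
        chromosomes=np.array(["1", "1", "1", "2"], dtype=object),
        positions=np.array([100, 200, 350, 50]),
        values=np.array(
            [
                [1.0, 2.0, 0.5, 3.0],
                [2.0, 4.0, 1.5, 1.0],
                [3.0, 6.5, 2.0, 2.0],
            ]
        ),
    )


def random_matrix(
    rng: np.random.Generator, n: int, p: int, n_chroms: int = 2
) -> MethylationMatrix:
    """Random valid methylation matrix with sites split over chromosomes."""
    cuts = np.sort(rng.choice(np.arange(1, p), size=n_chroms - 1, replace=False)) if n_chroms > 1 else []
    sizes = np.diff([0, *cuts, p])
    chroms = np.concatenate(
        [np.full(s, str(i + 1), dtype=object) for i, s in enumerate(sizes)]
    )
    positions = np.concatenate([np.arange(1, s + 1) * 10 for s in sizes])
    values = rng.gamma(shape=2.0, scale=10.0, size=(n, p))
    return MethylationMatrix(
        subject_ids=[f"s{i}" for i in range(n)],
        chromosomes=chroms,
        positions=positions,
        values=values,
    )


def factor_matrix(
    rng: np.random.Generator,
    n: int,
    group_sizes: list[int],
    within_r: float,
    cross_r: float = 0.0,
) -> np.ndarray:
    """Columns in groups sharing a latent factor -> known correlation blocks.

    Each column is sqrt(w)*g + sqrt(c)*h + sqrt(1-w-c)*noise with g a
    group-level factor and h a global factor, giving expected within-group
    correlation w + c and cross-group correlation c.
    """
    w = within_r - cross_r
    assert 0 <= w and w + cross_r <= 1
    h = rng.standard_normal(n)
    cols = []
    for size in group_sizes:
        g = rng.standard_normal(n)
        for _ in range(size):
            e = rng.standard_normal(n)
            cols.append(
                np.sqrt(w) * g + np.sqrt(cross_r) * h + np.sqrt(1 - w - cross_r) * e
            )
    return np.column_stack(cols)


def as_methylation(values: np.ndarray, chrom: str = "1") -> MethylationMatrix:
    n, p = values.shape
    return MethylationMatrix(
        subject_ids=[f"s{i}" for i in range(n)],
        chromosomes=np.full(p, chrom, dtype=object),
        positions=np.arange(1, p + 1) * 100,
        values=values,
    )
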