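import numpy as np
import pytest

from aimpanel import GenotypeSet


def make_random_gset(
    rng: np.random.Generator,
    n_per_pop=(6, 8),
    n_loci: int = 4,
    missing_rate: float = 0.0,
) -> GenotypeSet:
    """A random multi-population genotype set with allele codes {1, 2, 3}."""
    ids, pops, blocks = [], [], []
    for k, n in enumerate(n_per_pop):
        blocks.append(rng.integers(1, 4, size=(n, n_loci, 2)))
        pops += [f"pop{k}"] * n
        ids += [f"p{k}_i{j}" for j in range(n)]
    calls = np.concatenate(blocks, axis=0)
    if missing_rate > 0:
        miss = rng.random(size=calls.shape[:2]) < missing_rate
        calls[miss] = -9
    return GenotypeSet(ids, pops, [f"L{j}" for j in range(n_loci)], calls)


def make_diagnostic_gset(n_per_pop: int = 8, n_loci: int = 3, n_pops: int = 2) -> GenotypeSet:
    """Perfectly diagnostic markers: each population fixed for a private allele."""
    ids, pops, blocks = [], [], []
    for k in range(n_pops):
        blocks.append(np.full((n_per_pop, n_loci, 2), k + 1, dtype=np.int64))
        pops += [f"pop{k}"] * n_per_pop
        ids += [f"p{k}_i{j}" for j in range(n_per_pop)]
    return GenotypeSet(
        ids, pops, [f"L{j}" for j in range(n_loci)], np.concatenate(blocks, axis=0)
    )


def make_null_gset(rng: np.random.Generator, n_per_pop: int = 20, n_loci: int = 1,
                   freq: float = 0.5) -> GenotypeSet:
    """Two equal-sized populations with identical allele frequencies (no signal)."""
    n = 2 * n_per_pop
    calls = np.where(rng.random(size=(n, n_loci, 2)) < freq, 2, 1)
    pops = ["popA"] * n_per_pop + ["popB"] * n_per_pop
    ids = [f"i{j}" for j in range(n)]
    return GenotypeSet(ids, pops, [f"L{j}" for j in range(n_loci)], calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def diagnostic_gset():
    return make_diagnostic_gset()
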