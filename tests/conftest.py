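import numpy as np
import pytest

from oryzagen.datatypes import GenotypeMatrix
from oryzagen.simulate import SimConfig, simulate_dataset


def make_matrix(genotypes, pos=None, chrom="chr1", phased=True, sample_ids=None):
    """Small GenotypeMatrix from an (n, 2, m) or haplotype (2n, m) array."""
    g = np.asarray(genotypes, dtype=np.int8)
    if g.ndim == 2:  # haplotype rows, pair them up
        assert g.shape[0] % 2 == 0
        g = g.reshape(g.shape[0] // 2, 2, g.shape[1])
    n, _, m = g.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.full(m, chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(m, "A", dtype=object),
        alt=np.full(m, "T", dtype=object),
        genotypes=g,
        phased=phased,
    )


def random_matrix(rng, n_samples, n_sites, missing_rate=0.0, phased=True, pos_scale=100):
    g = rng.integers(0, 2, size=(n_samples, 2, n_sites)).astype(np.int8)
    if missing_rate:
        mask = rng.random(g.shape) < missing_rate
        g[mask] = -1
    pos = np.sort(rng.choice(np.arange(1, n_sites * pos_scale * 3), n_sites, replace=False))
    return make_matrix(g, pos=pos, phased=phased)


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic dataset (seed 7), shared across tests."""
    cfg = SimConfig(rng_seed=7)
    matrix, samples, truth = simulate_dataset(cfg)
    return {"cfg": cfg, "matrix": matrix, "samples": samples, "truth": truth}
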