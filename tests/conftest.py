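import numpy as np
import pytest

from hapgp import MarkerSet, PhasedGenotypes, SimulationConfig, simulate_dataset


def genotypes_from_haplotypes(haps: np.ndarray, chrom: str = "chr1",
                              positions: np.ndarray | None = None) -> PhasedGenotypes:
    """Wrap an (n, m, 2) indicator array as PhasedGenotypes without
    reorientation, so tests control the coding exactly."""
    n, m, _ = haps.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    markers = MarkerSet(
        np.array([f"m{j}" for j in range(m)]),
        np.full(m, chrom),
        np.asarray(positions, dtype=np.int64),
        np.full(m, "A"), np.full(m, "C"),
        haps.mean(axis=(0, 2)),
    )
    return PhasedGenotypes([f"i{i}" for i in range(n)], markers, haps.astype(np.int8))


def random_genotypes(rng: np.random.Generator, n: int, m: int) -> PhasedGenotypes:
    """Random polymorphic phased genotypes (every marker segregating)."""
    while True:
        haps = rng.integers(0, 2, size=(n, m, 2))
        freq = haps.mean(axis=(0, 2))
        if np.all((freq > 0) & (freq < 1)):
            return genotypes_from_haplotypes(haps)


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_individuals=150, n_chromosomes=2, markers_per_chrom=120,
        chrom_length=600_000, n_genes=16, architecture="snp_additive",
        n_qtl=15, seed=11,
    )
    return simulate_dataset(cfg)
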