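"""Relatedness kernels against hand computations and nested-loop oracles."""

import numpy as np
import pytest

import hapgp as hp

from _oracles import (
    epistasis_loops,
    grm_haplotype_loops,
    grm_vanraden_loops,
    ibs_loops,
)
from conftest import genotypes_from_haplotypes, random_genotypes


def from_dosage(dosage: np.ndarray) -> hp.PhasedGenotypes:
    """Phased genotypes realizing a given 0/1/2 dosage matrix."""
    n, m = dosage.shape
    haps = np.zeros((n, m, 2), dtype=np.int8)
    haps[:, :, 0] = dosage >= 1
    haps[:, :, 1] = dosage == 2
    return genotypes_from_haplotypes(haps)


# -------------------------------------------------------------- VanRaden G

def test_grm_hand_computed_three_by_two():
    """Dosages ((0,2),(1,1),(2,0)): p = (0.5, 0.5), denominator 1,
    centered rows (-1,1),(0,0),(1,-1)."""
    g = from_dosage(np.array([[0, 2], [1, 1], [2, 0]]))
    K = hp.grm_vanraden(g).matrix
    expected = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
    np.testing.assert_allclose(K, expected, atol=1e-12)


def test_grm_identical_rows_and_centering():
    g = from_dosage(np.array([[0, 1, 2], [0, 1, 2], [2, 1, 0], [1, 2, 0]]))
    k = hp.grm_vanraden(g)
    assert k.matrix[0, 0] == pytest.approx(k.matrix[0, 1])
    assert k.matrix[0, 1] == pytest.approx(k.matrix[1, 1])
    # p from the same sample centers columns, so row sums vanish
    np.testing.assert_allclose(k.matrix.sum(axis=0), 0.0, atol=1e-10)


def test_grm_monomorphic_error():
    g = from_dosage(np.ones((3, 2), dtype=int) * 2)
    with pytest.raises(ValueError, match="monomorphic"):
        hp.grm_vanraden(g)


# ------------------------------------------------------------ haplotype G_H

def test_gh_table2_dot_product():
    """Two individuals both AB|Ab in one block: off-diagonal 1*1 + 1*1 = 2."""
    mh = hp.PseudoMarkerMatrix(np.array([[1, 1, 0, 0], [1, 1, 0, 0]], dtype=np.int8),
                               [(0, 4)])
    k = hp.grm_haplotype(mh, q=1)
    assert k.matrix[0, 1] == pytest.approx(2.0)
    assert k.matrix[0, 0] == pytest.approx(2.0)  # fully heterozygous diagonal


def test_gh_diagonal_range_and_single_snp_outer_product():
    rng = np.random.default_rng(2)
    g = random_genotypes(rng, n=10, m=6)
    hs = hp.build_haploblocks(g, np.arange(6), max_alleles=8)
    mh = hp.dosage_encode(hs)
    k = hp.grm_haplotype(mh, hs.q)
    multi_only = all(not b.is_single_snp for b in hs.blocks)
    if multi_only:
        diag = np.diag(k.matrix) * hs.q
        assert np.all((diag >= 2 * hs.q / hs.q - 1e-12))  # per-block in [2, 4]
    # single-SNP pass-through: one column equals the genotype outer product
    d = g.dosage[:, 0].astype(float)
    single = hp.HaploblockSet([hp.build_haploblocks(g, np.array([0])).blocks[0]])
    k1 = hp.grm_haplotype(hp.dosage_encode(single), 1)
    np.testing.assert_allclose(k1.matrix, np.outer(d, d), atol=1e-12)


# ---------------------------------------------------------------- S and E

def test_ibs_hand_case_and_permutation_invariance():
    states = np.array([[0, 1, 2], [0, 2, 2], [1, 1, 1]])
    k = hp.ibs_categorical(states, 3, "S")
    assert k.matrix[0, 1] == pytest.approx(2 / 3)
    assert np.all(np.diag(k.matrix) == 1.0)
    perm = states[:, [2, 0, 1]]
    np.testing.assert_allclose(hp.ibs_categorical(perm, 3, "S").matrix, k.matrix)


def test_epistasis_closed_form_and_pair_counting():
    """S_ij = 2/3 at m = 3 gives E_ij = 1/3, the brute-force count of
    unordered shared-state locus pairs (self-pairs included) over m^2."""
    states = np.array([[0, 1, 2], [0, 2, 2]])
    s = hp.ibs_categorical(states, 3, "S")
    e = hp.epistasis_categorical(s)
    assert e.matrix[0, 1] == pytest.approx(1 / 3)
    np.testing.assert_allclose(e.matrix, epistasis_loops(states, 3), atol=1e-12)
    # diagonal identity (m+1)/(2m); zero-overlap entries stay zero
    assert e.matrix[0, 0] == pytest.approx((3 + 1) / (2 * 3))
    s0 = hp.Kernel(np.array([[1.0, 0.0], [0.0, 1.0]]), "S", 3.0)
    assert hp.epistasis_categorical(s0).matrix[0, 1] == 0.0


def test_epistasis_count_mismatch_rejected():
    s = hp.ibs_categorical(np.array([[0, 1], [1, 1]]), 2, "S")
    with pytest.raises(ValueError, match="denominator"):
        hp.epistasis_categorical(s, count=5)
    with pytest.raises(ValueError, match="S-family"):
        hp.epistasis_categorical(hp.Kernel(np.eye(2), "G", 1.0))


def test_all_kernels_match_nested_loop_oracles():
    """Random small instances: every kernel equals its brute-force twin."""
    rng = np.random.default_rng(99)
    for _ in range(25):
        n = int(rng.integers(3, 7))
        m = int(rng.integers(4, 13))
        g = random_genotypes(rng, n, m)
        d = g.dosage
        np.testing.assert_allclose(hp.grm_vanraden(g).matrix,
                                   grm_vanraden_loops(d), atol=1e-10)
        np.testing.assert_allclose(hp.ibs_categorical(d, m, "S").matrix,
                                   ibs_loops(d, m), atol=1e-10)
        s = hp.ibs_categorical(d, m, "S")
        np.testing.assert_allclose(hp.epistasis_categorical(s).matrix,
                                   epistasis_loops(d, m), atol=1e-10)
        hs = hp.build_haploblocks(g, np.arange(m), max_alleles=6)
        mh, cm = hp.dosage_encode(hs), hp.categorical_encode(hs)
        np.testing.assert_allclose(hp.grm_haplotype(mh, hs.q).matrix,
                                   grm_haplotype_loops(mh.matrix, hs.q), atol=1e-10)
        np.testing.assert_allclose(hp.ibs_categorical(cm, hs.q, "S_H").matrix,
                                   ibs_loops(cm.codes, hs.q), atol=1e-10)


def test_reduction_law_single_snp_blocks():
    """When every block holds one SNP, S_H == S and E_H == E."""
    rng = np.random.default_rng(7)
    for _ in range(10):
        g = random_genotypes(rng, n=8, m=10)
        blocks = hp.HaploblockSet([])
        for j in range(10):
            blocks.extend(hp.build_haploblocks(g, np.array([j])))
        cm = hp.categorical_encode(blocks)
        s_h = hp.ibs_categorical(cm, blocks.q, "S_H")
        s = hp.ibs_categorical(g.dosage, g.n_markers, "S")
        np.testing.assert_allclose(s_h.matrix, s.matrix, atol=1e-12)
        np.testing.assert_allclose(hp.epistasis_categorical(s_h).matrix,
                                   hp.epistasis_categorical(s).matrix, atol=1e-12)


def test_kernels_positive_semidefinite(small_dataset):
    g, _ = hp.apply_qc(small_dataset.genotypes)
    hs = hp.build_blocks_genomewide(g)
    kernels = [
        hp.grm_vanraden(g),
        hp.grm_haplotype(hp.dosage_encode(hs), hs.q),
        hp.ibs_categorical(g.dosage, g.n_markers, "S"),
        hp.ibs_categorical(hp.categorical_encode(hs), hs.q, "S_H"),
    ]
    kernels.append(hp.epistasis_categorical(kernels[2]))
    kernels.append(hp.epistasis_categorical(kernels[3]))
    for k in kernels:
        w = np.linalg.eigvalsh(k.matrix)
        assert w[0] >= -1e-8, k.model


def test_ibs_monotonicity_under_added_locus():
    rng = np.random.default_rng(12)
    states = rng.integers(0, 3, size=(6, 9))
    base = hp.ibs_categorical(states, 9, "S").matrix * 9
    shared = np.hstack([states, np.ones((6, 1), dtype=int)])
    grown = hp.ibs_categorical(shared, 10, "S").matrix * 10
    assert np.all(grown >= base - 1e-12)


# ----------------------------------------------------------------- export

def test_kernel_tsv_and_gcta_round_trip(tmp_path, small_dataset):
    g, _ = hp.apply_qc(small_dataset.genotypes)
    k = hp.grm_vanraden(g)
    tsv = tmp_path / "k.tsv"
    hp.kernels.write_kernel_tsv(k, str(tsv), g.individuals)
    k2, ids2 = hp.kernels.read_kernel_tsv(str(tsv), "G", k.denominator)
    assert ids2 == g.individuals
    np.testing.assert_allclose(k2.matrix, k.matrix, atol=1e-9)

    prefix = str(tmp_path / "grm")
    hp.write_grm_gcta(k, prefix, g.individuals)
    k3, ids3 = hp.read_grm_gcta(prefix)
    assert ids3 == g.individuals
    np.testing.assert_allclose(k3.matrix, k.matrix, atol=1e-6)  # float32 storage
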