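"""Haploblock construction and pseudo-marker encoding.

Within each SNP set (or whole chromosome), consecutive phased SNPs are
grouped greedily in physical order into haploblocks: the current block is
extended marker by marker until the number of distinct haplotype alleles
observed in the population would exceed a cap (10 by default), at which
point the block is closed and a new one starts.  A haploblock is then a
multi-allelic locus whose alleles are the distinct SNP strings; SNP sets of
a single marker (and trailing singletons) keep their 0/1/2 genotype.

Two encodings of a block are produced:

* numerical dosage — one pseudo-marker column per catalog allele holding
  the number of copies (0/1/2) carried, assuming intra-locus additivity;
* categorical — one code per unordered pair of alleles (the genotype
  configuration), with no additivity assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import ClassPartition, SnpSet
from .io_qc import PhasedGenotypes

DEFAULT_MAX_ALLELES = 10


@dataclass
class Haploblock:
    """One multi-allelic locus: a run of consecutive markers.

    ``alleles`` holds the per-individual pair of catalog indices, sorted
    within each row so the pair is unordered.  A single-SNP block has an
    implicit catalog {absent, present}: its alleles are the 0/1 haplotype
    indicators themselves.
    """

    marker_indices: np.ndarray     # ordered positions into the MarkerSet
    catalog: list[str]             # distinct haplotype strings, lexicographic
    alleles: np.ndarray            # (n, 2) catalog indices, row-sorted

    @property
    def n_snps(self) -> int:
        return len(self.marker_indices)

    @property
    def n_alleles(self) -> int:
        return len(self.catalog)

    @property
    def is_single_snp(self) -> bool:
        return self.n_snps == 1


@dataclass
class HaploblockSet:
    """Ordered blocks covering one or more SNP sets; Q counts all of them."""

    blocks: list[Haploblock]

    @property
    def q(self) -> int:
        return len(self.blocks)

    @property
    def n_individuals(self) -> int:
        return self.blocks[0].alleles.shape[0] if self.blocks else 0

    def extend(self, other: "HaploblockSet") -> None:
        self.blocks.extend(other.blocks)


@dataclass
class PseudoMarkerMatrix:
    """n x P dosage matrix M_H: copies of each haplotype allele per block."""

    matrix: np.ndarray             # (n, P) int8 entries in {0, 1, 2}
    block_offsets: list[tuple[int, int]]  # [start, stop) column range per block

    @property
    def n_blocks(self) -> int:
        return len(self.block_offsets)


@dataclass
class CategoricalGenotypeMatrix:
    """n x Q genotype-configuration codes; equality means identical state."""

    codes: np.ndarray              # (n, Q) int32
    n_states: np.ndarray           # number of possible codes per block


def _factorize_columns(strings: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Map rows of a 0/1 matrix to ids of their lexicographically sorted
    distinct strings."""
    # rows of `strings` are haplotype vectors over the block's markers
    as_str = np.array(["".join(map(str, row)) for row in strings])
    catalog, ids = np.unique(as_str, return_inverse=True)
    return ids, list(catalog)


def build_haploblocks(
    g: PhasedGenotypes,
    marker_indices: np.ndarray,
    max_alleles: int = DEFAULT_MAX_ALLELES,
) -> HaploblockSet:
    """Greedy left-to-right haploblock scan over one SNP set.

    The block boundary rule is population-wide: the count of distinct
    haplotype strings over all 2n phased haplotypes may not exceed
    ``max_alleles``.  A one-marker SNP set, or a singleton left at the end
    of the scan, is retained as a single-SNP 0/1/2 column.
    """
    g.require_complete()
    marker_indices = np.asarray(marker_indices, dtype=np.int64)
    if max_alleles < 2:
        raise ValueError("max_alleles must be at least 2")
    n = g.n_individuals
    # (2n, k) haplotype matrix: individual-major, two rows per individual
    haps = g.haplotypes[:, marker_indices, :].transpose(0, 2, 1).reshape(2 * n, -1)

    blocks: list[Haploblock] = []
    start = 0
    k = len(marker_indices)
    # group ids of the 2n haplotypes over the current open block [start, j)
    group = haps[:, 0].astype(np.int64)
    for j in range(1, k + 1):
        if j < k:
            cand = group * 2 + haps[:, j]
            uniq, cand_ids = np.unique(cand, return_inverse=True)
            if len(uniq) <= max_alleles:
                group = cand_ids
                continue
        blocks.append(_close_block(g, marker_indices[start:j], haps[:, start:j], n))
        if j < k:
            start = j
            group = haps[:, j].astype(np.int64)
    return HaploblockSet(blocks)


def _close_block(g: PhasedGenotypes, idx: np.ndarray, haps: np.ndarray,
                 n: int) -> Haploblock:
    if len(idx) == 1:
        # single-SNP retention: catalog-free, alleles are the indicators
        pairs = np.sort(haps.reshape(n, 2), axis=1).astype(np.int32)
        return Haploblock(idx, [], pairs)
    ids, catalog = _factorize_columns(haps)
    pairs = np.sort(ids.reshape(n, 2), axis=1).astype(np.int32)
    return Haploblock(idx, catalog, pairs)


def build_blocks_for_partition(
    g: PhasedGenotypes,
    partition: ClassPartition,
    max_alleles: int = DEFAULT_MAX_ALLELES,
) -> HaploblockSet:
    """Haploblocks for every SNP set of a genomic class; Q here is Q_H^GA."""
    out = HaploblockSet([])
    for snp_set in partition.snp_sets:
        out.extend(build_haploblocks(g, snp_set.marker_indices, max_alleles))
    return out


def build_blocks_genomewide(
    g: PhasedGenotypes,
    max_alleles: int = DEFAULT_MAX_ALLELES,
) -> HaploblockSet:
    """Whole-genome haploblocks: one scan per chromosome in physical order,
    ignoring annotation; Q here is Q_H."""
    out = HaploblockSet([])
    for chrom in dict.fromkeys(g.markers.chromosome):
        idx = np.where(g.markers.chromosome == chrom)[0]
        out.extend(build_haploblocks(g, idx, max_alleles))
    return out


def dosage_encode(h: HaploblockSet) -> PseudoMarkerMatrix:
    """Numerical coding: per catalog allele, the 0/1/2 copy count.

    Single-SNP blocks pass their minor-allele dosage through as one column.
    Each multi-SNP block's columns sum to 2 on every row (diploid copies).
    """
    n = h.n_individuals
    cols: list[np.ndarray] = []
    offsets: list[tuple[int, int]] = []
    p = 0
    for b in h.blocks:
        if b.is_single_snp:
            dose = b.alleles.sum(axis=1, dtype=np.int8)[:, None]
        else:
            dose = np.zeros((n, b.n_alleles), dtype=np.int8)
            rows = np.arange(n)
            np.add.at(dose, (rows, b.alleles[:, 0]), 1)
            np.add.at(dose, (rows, b.alleles[:, 1]), 1)
        cols.append(dose)
        offsets.append((p, p + dose.shape[1]))
        p += dose.shape[1]
    matrix = (np.concatenate(cols, axis=1) if cols
              else np.zeros((n, 0), dtype=np.int8))
    return PseudoMarkerMatrix(matrix, offsets)


def categorical_encode(h: HaploblockSet) -> CategoricalGenotypeMatrix:
    """Categorical coding: a stable code per unordered allele pair.

    For a block with catalog size c the codes range over the c(c+1)/2
    unordered pairs; a single-SNP block uses its 0/1/2 genotype directly.
    """
    n = h.n_individuals
    codes = np.zeros((n, h.q), dtype=np.int32)
    n_states = np.zeros(h.q, dtype=np.int64)
    for q, b in enumerate(h.blocks):
        a, bb = b.alleles[:, 0].astype(np.int64), b.alleles[:, 1].astype(np.int64)
        if b.is_single_snp:
            codes[:, q] = (a + bb).astype(np.int32)
            n_states[q] = 3
        else:
            c = b.n_alleles
            # unordered pair (a <= bb) -> index in upper-triangle enumeration
            codes[:, q] = (a * (2 * c - a - 1) // 2 + bb).astype(np.int32)
            n_states[q] = c * (c + 1) // 2
    return CategoricalGenotypeMatrix(codes, n_states)


def block_table(h: HaploblockSet, g: PhasedGenotypes) -> "np.ndarray":
    """Per-block summary rows (block_id, chrom, first, last, n_snps, n_alleles)."""
    import pandas as pd

    rows = []
    for i, b in enumerate(h.blocks):
        first, last = b.marker_indices[0], b.marker_indices[-1]
        rows.append({
            "block_id": i,
            "chrom": g.markers.chromosome[first],
            "first_marker": g.markers.marker_id[first],
            "last_marker": g.markers.marker_id[last],
            "n_snps": b.n_snps,
            "n_alleles": b.n_alleles if not b.is_single_snp else 2,
        })
    return pd.DataFrame(rows)
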