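"""Relatedness kernels for the nine prediction models.

Numerical-dosage family
    G        centered SNP relationship matrix (VanRaden),
             (M - P)(M - P)' / 2 sum p_i (1 - p_i)
    G_H      haplotype dosage cross-product M_H M_H' / Q_H (uncentered)
    G_H|GA   same, restricted to one genomic class (denominator Q_H^GA)

Categorical family (identity-by-state of configurations)
    S        proportion of markers with identical genotype
    S_H, S~  proportion of haploblocks with identical configuration
             (whole genome / one genomic class)

Categorical-epistasis family (first-order interactions)
    E, E_H, E~   0.5 * (cS) # (cS + 1) / c^2  with # the Hadamard product
                 and c the locus/block count of the underlying S kernel;
                 the entry counts unordered locus pairs (self-pairs
                 included) in identical state, divided by c^2.

All kernels are n x n symmetric.  G_H is deliberately uncentered (its
definition has no allele-frequency subtraction); the scale difference is
absorbed by the REML variance component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .haploblocks import CategoricalGenotypeMatrix, PseudoMarkerMatrix
from .io_qc import PhasedGenotypes

MODEL_TAGS = ("G", "G_H", "G_H|GA", "S", "S_H", "S~", "E", "E_H", "E~")


@dataclass
class Kernel:
    matrix: np.ndarray        # (n, n) symmetric
    model: str                # one of MODEL_TAGS
    denominator: float        # scaling count: 2*sum p(1-p), m, Q_H or Q_H^GA
    class_tag: str = "all"    # genomic class, or "all"

    def __post_init__(self) -> None:
        if self.model not in MODEL_TAGS:
            raise ValueError(f"unknown model tag {self.model!r}")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("kernel matrix not symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def grm_vanraden(g: PhasedGenotypes) -> Kernel:
    """Centered SNP relationship matrix G = (M-P)(M-P)' / 2 sum p(1-p).

    M is the minor-allele dosage matrix and P has columns 2 p_i with p_i
    the minor-allele frequency computed from the sample itself.
    """
    g.require_complete()
    M = g.dosage.astype(np.float64)
    p = M.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero VanRaden denominator")
    Z = M - 2.0 * p
    K = (Z @ Z.T) / denom
    return Kernel(_symmetrize(K), "G", denom)


def grm_haplotype(mh: PseudoMarkerMatrix, q: int,
                  class_tag: str = "all") -> Kernel:
    """Haplotype dosage kernel G_H = M_H M_H' / Q (uncentered).

    ``q`` is Q_H for whole-genome blocks or Q_H^GA for a genomic class;
    single-SNP columns ride along unchanged and count toward Q.
    """
    if q < 1:
        raise ValueError("block count q must be >= 1")
    M = mh.matrix.astype(np.float64)
    K = (M @ M.T) / float(q)
    model = "G_H" if class_tag == "all" else "G_H|GA"
    return Kernel(_symmetrize(K), model, float(q), class_tag)


def ibs_matrix(states: np.ndarray) -> np.ndarray:
    """Pairwise count of columns in identical state, via a sparse one-hot
    indicator product (avoids the n x n x L intermediate)."""
    states = np.asarray(states)
    n, m = states.shape
    # give every (column, state) combination a globally unique id
    offsets = np.zeros(m, dtype=np.int64)
    ids = np.empty_like(states, dtype=np.int64)
    total = 0
    for j in range(m):
        uniq, inv = np.unique(states[:, j], return_inverse=True)
        offsets[j] = total
        ids[:, j] = inv + total
        total += len(uniq)
    indptr = np.arange(0, n * m + 1, m)
    data = np.ones(n * m, dtype=np.float64)
    B = sp.csr_matrix((data, ids.ravel(), indptr), shape=(n, total))
    return np.asarray((B @ B.T).todense())


def ibs_categorical(states: np.ndarray | CategoricalGenotypeMatrix,
                    count: int | None = None,
                    model: str = "S",
                    class_tag: str = "all") -> Kernel:
    """Categorical (IBS) kernel: proportion of loci/blocks in identical state.

    ``states`` is either the n x m SNP genotype matrix (model S, count m)
    or a categorical block encoding (models S_H / S~, count Q_H / Q_H^GA).
    """
    if isinstance(states, CategoricalGenotypeMatrix):
        states = states.codes
    states = np.asarray(states)
    if count is None:
        count = states.shape[1]
    if count < 1:
        raise ValueError("state count must be >= 1")
    if model not in ("S", "S_H", "S~"):
        raise ValueError(f"{model!r} is not a categorical-model tag")
    K = ibs_matrix(states) / float(count)
    return Kernel(_symmetrize(K), model, float(count), class_tag)


_EPISTASIS_OF = {"S": "E", "S_H": "E_H", "S~": "E~"}


def epistasis_categorical(s: Kernel, count: int | None = None) -> Kernel:
    """Categorical-epistasis kernel E = 0.5 * (cS) # (cS + 1) / c^2.

    c is the locus/block count behind ``s``; the result counts unordered
    pairs of loci (self-pairs included) that are simultaneously in
    identical state, so the diagonal is exactly (c+1)/(2c).
    """
    if s.model not in _EPISTASIS_OF:
        raise ValueError(f"epistasis kernel requires an S-family input, got {s.model!r}")
    c = float(s.denominator) if count is None else float(count)
    if c != s.denominator:
        raise ValueError(
            f"count {c} does not match the S kernel's denominator {s.denominator}"
        )
    cS = c * s.matrix
    E = 0.5 * cS * (cS + 1.0) / (c * c)
    return Kernel(_symmetrize(E), _EPISTASIS_OF[s.model], c, s.class_tag)


def _symmetrize(K: np.ndarray) -> np.ndarray:
    return (K + K.T) / 2.0


def write_kernel_tsv(k: Kernel, path: str, individuals: list[str]) -> None:
    """Plain TSV: header row of individual ids, then the dense matrix."""
    import pandas as pd

    pd.DataFrame(k.matrix, columns=individuals).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_kernel_tsv(path: str, model: str = "G",
                    denominator: float = 1.0) -> tuple[Kernel, list[str]]:
    import pandas as pd

    frame = pd.read_csv(path, sep="\t")
    return Kernel(frame.to_numpy(dtype=np.float64), model, denominator), list(frame.columns)


def write_grm_gcta(k: Kernel, prefix: str, individuals: list[str]) -> None:
    """GCTA binary GRM triplet: <prefix>.grm.bin (float32 lower triangle,
    row-major), <prefix>.grm.N.bin, <prefix>.grm.id."""
    n = k.n
    tri = k.matrix[np.tril_indices(n)].astype("<f4")
    tri.tofile(f"{prefix}.grm.bin")
    np.full(tri.shape, k.denominator, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for ind in individuals:
            fh.write(f"{ind}\t{ind}\n")


def read_grm_gcta(prefix: str, model: str = "G") -> tuple[Kernel, list[str]]:
    with open(f"{prefix}.grm.id") as fh:
        individuals = [line.split("\t")[1].strip() for line in fh if line.strip()]
    n = len(individuals)
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4").astype(np.float64)
    if len(tri) != n * (n + 1) // 2:
        raise ValueError(f"{prefix}.grm.bin holds {len(tri)} values; expected n(n+1)/2")
    K = np.zeros((n, n))
    K[np.tril_indices(n)] = tri
    K = K + np.tril(K, -1).T
    denom = float(np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4", count=1)[0])
    return Kernel(K, model, denom), individuals
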