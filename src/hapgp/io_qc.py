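"""Input/output, quality control and phenotype pre-adjustment.

Reads phased biallelic VCF genotypes into minor-allele-oriented haplotype
indicators, applies the standard marker/individual quality-control filters
(call rate, minor-allele frequency, Hardy-Weinberg exact test), and
pre-adjusts trait values for environmental fixed effects by ordinary least
squares so that downstream variance-component models carry an intercept
only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln

MISSING = -1  # sentinel for a missing haplotype indicator / dosage

FIXED_EFFECT_FACTORS = ("sex", "year")
FIXED_EFFECT_COVARIATES = ("entry_weight", "fattening_days")


@dataclass
class MarkerSet:
    """Per-marker metadata; positions strictly increasing within chromosome."""

    marker_id: np.ndarray  # str
    chromosome: np.ndarray  # str
    position: np.ndarray  # int, 1-based
    ref: np.ndarray  # str
    alt: np.ndarray  # str
    maf: np.ndarray  # float in (0, 0.5]

    def __post_init__(self) -> None:
        for chrom in pd.unique(self.chromosome):
            pos = self.position[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.position)

    def subset(self, idx: np.ndarray) -> "MarkerSet":
        return MarkerSet(
            *(getattr(self, f.name)[idx] for f in dataclasses.fields(self))
        )


@dataclass
class PhasedGenotypes:
    """Phased genotypes as n x m x 2 minor-allele indicators.

    ``haplotypes[i, j, k]`` is 1 if haplotype ``k`` of individual ``i``
    carries the minor allele of marker ``j`` (``MISSING`` for an unknown
    call, only permitted transiently before QC).  The 0/1/2 dosage view is
    the sum over the last axis.
    """

    individuals: list[str]
    markers: MarkerSet
    haplotypes: np.ndarray  # (n, m, 2) int8

    def __post_init__(self) -> None:
        n, m, two = self.haplotypes.shape
        if two != 2 or n != len(self.individuals) or m != self.markers.n_markers:
            raise ValueError("haplotype array shape inconsistent with metadata")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return self.markers.n_markers

    @property
    def dosage(self) -> np.ndarray:
        """n x m minor-allele dosage; MISSING where either call is missing."""
        d = self.haplotypes.sum(axis=2, dtype=np.int8)
        d[(self.haplotypes == MISSING).any(axis=2)] = MISSING
        return d

    def require_complete(self) -> None:
        if (self.haplotypes == MISSING).any():
            raise ValueError("genotypes contain missing calls; complete phased input required")

    def subset(self, ind_idx: np.ndarray | None = None,
               marker_idx: np.ndarray | None = None) -> "PhasedGenotypes":
        h = self.haplotypes
        inds = self.individuals
        markers = self.markers
        if ind_idx is not None:
            ind_idx = np.atleast_1d(ind_idx)
            if ind_idx.dtype == bool:
                ind_idx = np.where(ind_idx)[0]
            h = h[ind_idx]
            inds = [self.individuals[i] for i in ind_idx]
        if marker_idx is not None:
            h = h[:, marker_idx]
            markers = markers.subset(marker_idx)
        g = PhasedGenotypes(inds, markers, h.copy())
        return _reorient_minor(g)


@dataclass
class QCReport:
    n_markers_in: int
    n_individuals_in: int
    removed_call_rate: int
    removed_maf: int
    removed_hwe: int
    removed_individuals: int
    n_markers_out: int
    n_individuals_out: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"filter": ["marker_call_rate", "marker_maf", "marker_hwe",
                        "individual_call_rate"],
             "removed": [self.removed_call_rate, self.removed_maf,
                         self.removed_hwe, self.removed_individuals]}
        )


@dataclass
class PhenotypeTable:
    """One row per individual: trait value plus fixed-effect columns."""

    frame: pd.DataFrame  # columns: individual, trait, sex, year, entry_weight, fattening_days

    def __post_init__(self) -> None:
        required = {"individual", "trait", *FIXED_EFFECT_FACTORS, *FIXED_EFFECT_COVARIATES}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        if self.frame["individual"].duplicated().any():
            raise ValueError("duplicate individual ids in phenotype table")


@dataclass
class AdjustedPhenotypes:
    individuals: list[str]
    y_adj: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"individual": self.individuals, "y_adj": self.y_adj})


def _allele_freq(haplotypes: np.ndarray) -> np.ndarray:
    """Frequency of the currently-counted allele, ignoring missing calls."""
    obs = haplotypes != MISSING
    cnt = np.where(obs, haplotypes, 0).sum(axis=(0, 2))
    tot = obs.sum(axis=(0, 2))
    with np.errstate(invalid="ignore"):
        return np.where(tot > 0, cnt / np.maximum(tot, 1), 0.0)


def _reorient_minor(g: PhasedGenotypes) -> PhasedGenotypes:
    """Flip indicator orientation wherever the counted allele is major."""
    freq = _allele_freq(g.haplotypes)
    flip = freq > 0.5
    if flip.any():
        h = g.haplotypes.copy()
        block = h[:, flip, :]
        miss = block == MISSING
        block = (1 - block).astype(np.int8)
        block[miss] = MISSING
        h[:, flip, :] = block
        ref = g.markers.ref.copy()
        alt = g.markers.alt.copy()
        ref[flip], alt[flip] = alt[flip].copy(), ref[flip].copy()
        g = PhasedGenotypes(
            g.individuals,
            MarkerSet(g.markers.marker_id, g.markers.chromosome,
                      g.markers.position, ref, alt,
                      np.minimum(freq, 1 - freq)),
            h,
        )
    else:
        g.markers.maf = np.minimum(freq, 1 - freq)
    return g


def read_phased_vcf(path: str) -> PhasedGenotypes:
    """Read a phased, biallelic, complete VCF into ``PhasedGenotypes``.

    The minor allele of every marker is determined from the sample allele
    frequencies and the indicators are oriented to it.  Unphased, missing
    or multiallelic records violate the contract and raise ``ValueError``.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    individuals = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {rec.CHROM}:{rec.POS}; biallelic input required"
            )
        # genotypes: [a0, a1, phased] per sample
        gts = np.asarray(rec.genotypes, dtype=np.int64)
        if gts.shape[1] < 3 or not np.all(gts[:, 2]):
            bad = int(np.argmin(gts[:, 2])) if gts.shape[1] >= 3 else 0
            raise ValueError(
                f"unphased genotype for sample {individuals[bad]} at "
                f"{rec.CHROM}:{rec.POS}; phased input ('|') required"
            )
        if np.any(gts[:, :2] < 0):
            raise ValueError(
                f"missing genotype at {rec.CHROM}:{rec.POS}; complete input required"
            )
        ids.append(rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(gts[:, :2].astype(np.int8))
    if not rows:
        raise ValueError(f"no records in {path}")
    h = np.stack(rows, axis=1)  # (n, m, 2) counting ALT
    markers = MarkerSet(
        np.asarray(ids), np.asarray(chroms), np.asarray(poss, dtype=np.int64),
        np.asarray(refs), np.asarray(alts), np.zeros(len(ids)),
    )
    return _reorient_minor(PhasedGenotypes(individuals, markers, h))


def write_phased_vcf(g: PhasedGenotypes, path: str) -> None:
    """Emit uncompressed VCFv4.2 with phased GT fields.

    The counted (minor) allele is written as ALT so a round trip through
    :func:`read_phased_vcf` reproduces the indicator matrix.
    """
    m = g.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(m.chromosome):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.individuals) + "\n")
        h = g.haplotypes
        for j in range(g.n_markers):
            gts = "\t".join(f"{h[i, j, 0]}|{h[i, j, 1]}" for i in range(g.n_individuals))
            fh.write(f"{m.chromosome[j]}\t{m.position[j]}\t{m.marker_id[j]}\t"
                     f"{m.ref[j]}\t{m.alt[j]}\t.\t.\t.\tGT\t{gts}\n")


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value for a biallelic marker.

    Conditional-on-allele-counts exact test (no mid-p correction): the
    p-value sums the probabilities of all heterozygote counts at least as
    improbable as the one observed.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = n_het + 2 * min(n_hom1, n_hom2)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    # P(het = h | allele counts) via log-factorials
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1) - gammaln(rare_hom + 1) - gammaln(common_hom + 1)
        + hets * np.log(2)
        + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1) - gammaln(2 * n + 1)
    )
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs + 1e-12].sum()))


def apply_qc(
    g: PhasedGenotypes,
    snp_call_rate: float = 0.90,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
    ind_call_rate: float = 0.90,
) -> tuple[PhasedGenotypes, QCReport]:
    """Apply marker filters (call rate, MAF, HWE), then individual call rate.

    Marker criteria are evaluated on the input matrix; individuals are then
    filtered on the surviving markers.  MAF and orientation are recomputed
    from the surviving matrix, so the returned genotypes satisfy
    0 < maf <= 0.5.
    """
    d = g.dosage
    obs = d != MISSING
    n, m = d.shape

    call_rate = obs.mean(axis=0)
    keep_cr = call_rate > snp_call_rate

    freq = _allele_freq(g.haplotypes)
    maf = np.minimum(freq, 1 - freq)
    keep_maf = maf > maf_min

    keep_hwe = np.ones(m, dtype=bool)
    for j in range(m):
        dj = d[obs[:, j], j]
        n_het = int((dj == 1).sum())
        n_hom1 = int((dj == 0).sum())
        n_hom2 = int((dj == 2).sum())
        keep_hwe[j] = hwe_exact_pvalue(n_het, n_hom1, n_hom2) > hwe_p_min

    removed_cr = int((~keep_cr).sum())
    removed_maf = int((keep_cr & ~keep_maf).sum())
    removed_hwe = int((keep_cr & keep_maf & ~keep_hwe).sum())
    keep_m = keep_cr & keep_maf & keep_hwe
    if not keep_m.any():
        raise ValueError("QC removed all markers")

    ind_cr = obs[:, keep_m].mean(axis=1)
    keep_i = ind_cr > ind_call_rate
    removed_ind = int((~keep_i).sum())
    if not keep_i.any():
        raise ValueError("QC removed all individuals")

    out = g.subset(np.where(keep_i)[0], np.where(keep_m)[0])
    report = QCReport(
        n_markers_in=m, n_individuals_in=n,
        removed_call_rate=removed_cr, removed_maf=removed_maf,
        removed_hwe=removed_hwe, removed_individuals=removed_ind,
        n_markers_out=out.n_markers, n_individuals_out=out.n_individuals,
    )
    return out, report


def read_phenotypes(path: str) -> PhenotypeTable:
    frame = pd.read_csv(path, sep="\t", dtype={"individual": str, "sex": str, "year": str})
    return PhenotypeTable(frame)


def write_phenotypes(p: PhenotypeTable, path: str) -> None:
    p.frame.to_csv(path, sep="\t", index=False)


def adjust_phenotypes(p: PhenotypeTable) -> AdjustedPhenotypes:
    """OLS residuals of the trait on sex + year + entry weight + fattening days.

    Raises on a singular design, naming the aliased columns, so confounded
    factor codings fail loudly instead of silently absorbing genetic signal.
    """
    frame = p.frame
    parts = [pd.Series(1.0, index=frame.index, name="intercept")]
    for f in FIXED_EFFECT_FACTORS:
        dummies = pd.get_dummies(frame[f].astype(str), prefix=f, drop_first=True, dtype=float)
        parts.append(dummies)
    for c in FIXED_EFFECT_COVARIATES:
        parts.append(frame[c].astype(float))
    X = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _find_aliased(X.to_numpy(), list(X.columns))
        raise ValueError(f"singular fixed-effect design; aliased columns: {aliased}")
    fit = sm.OLS(frame["trait"].astype(float).to_numpy(), X.to_numpy()).fit()
    return AdjustedPhenotypes(list(frame["individual"]), np.asarray(fit.resid))


def _find_aliased(X: np.ndarray, names: list[str]) -> list[str]:
    kept: list[int] = []
    aliased: list[str] = []
    for j in range(X.shape[1]):
        cols = kept + [j]
        if np.linalg.matrix_rank(X[:, cols]) == len(cols):
            kept.append(j)
        else:
            aliased.append(names[j])
    return aliased
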