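"""Synthetic cohorts: phased genotypes with LD, toy annotation, phenotypes.

The generator emulates the structure of a beef-cattle genomic-prediction
cohort at desk scale: ~1331 individuals carrying phased biallelic markers
whose linkage disequilibrium decays over tens of kilobases, a genome
annotation of partially nested gene/exon/CDS/UTR features, and phenotypes
composed of environmental fixed effects, a genetic value under a chosen
architecture, and Gaussian residuals at a target heritability of 0.4.

Haplotypes are mosaics of a small founder pool: each sampled haplotype
copies one founder and switches to a (weighted) random founder between
consecutive markers with probability 1 - exp(-ld_decay * distance).  The
switch rate is the single LD knob: nearby markers tend to be copied from
the same founder and are therefore correlated, and the correlation decays
with distance.  Founder sampling weights are Dirichlet-distributed so
marker allele frequencies spread over (0, 0.5] instead of clumping at
multiples of 1/n_founders.

Genetic architectures
    snp_additive    additive effects on individual SNP dosages
    haplotype_qtl   effects attached to the distinct haplotype alleles of
                    multi-SNP QTL windows (not expressible as a sum of
                    per-SNP dosage effects)
    epistatic       effects attached to unordered state pairs of
                    haploblock pairs, the configuration the categorical
                    epistasis kernel measures
    mixed           half snp_additive, half haplotype_qtl
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomeFeature, merge_intervals
from .haploblocks import build_blocks_genomewide, categorical_encode
from .io_qc import MarkerSet, PhasedGenotypes, PhenotypeTable, _reorient_minor

ARCHITECTURES = ("snp_additive", "haplotype_qtl", "epistatic", "mixed")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the cohort the generator emulates where a value is
    dictated by it (cohort size 1331, target h2 0.4, QC-compatible MAF
    spectrum); marker density is scaled to desk size at a similar per-bp
    spacing order (5 kb vs the chip's ~3.4 kb).
    """

    n_individuals: int = 1331
    n_chromosomes: int = 5
    markers_per_chrom: int = 400
    chrom_length: int = 2_000_000
    ld_decay: float = 1e-5        # per-bp founder-switch rate
    n_founders: int = 4
    n_genes: int = 150            # total across chromosomes
    gene_length: tuple[int, int] = (10_000, 30_000)
    exons_per_gene: tuple[int, int] = (1, 3)
    architecture: str = "snp_additive"
    n_qtl: int = 50
    qtl_block_size: int = 4       # markers per haplotype-QTL window
    qtl_class_bias: float = 0.0   # fraction of QTL forced inside genes
    h2_target: float = 0.4
    fixed_var_fraction: float = 0.2  # share of phenotypic variance from fixed effects
    sex_levels: int = 2
    year_levels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.h2_target < 1:
            raise ValueError("h2_target must lie in (0, 1)")
        if not 0 <= self.qtl_class_bias <= 1:
            raise ValueError("qtl_class_bias must lie in [0, 1]")
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.markers_per_chrom >= self.chrom_length:
            raise ValueError("markers do not fit within chrom_length")


@dataclass
class SimTruth:
    genetic_values: np.ndarray     # per individual, centered
    fixed_part: np.ndarray         # per individual fixed-effect contribution
    residuals: np.ndarray
    sigma2_e: float
    realized_h2: float             # var(genetic) / var(genetic + residual)
    qtl: pd.DataFrame              # one row per QTL locus/window/pair


@dataclass
class SimulatedDataset:
    genotypes: PhasedGenotypes
    features: list[GenomeFeature]
    chrom_lengths: dict[str, int]
    phenotypes: PhenotypeTable
    truth: SimTruth


def simulate_haplotypes(cfg: SimulationConfig,
                        rng: np.random.Generator) -> PhasedGenotypes:
    """Founder-mosaic phased genotypes with distance-decaying LD.

    Markers that come out monomorphic are dropped, so the returned marker
    count can fall slightly short of the configured one.
    """
    n = cfg.n_individuals
    all_h, ids, chroms, poss = [], [], [], []
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        m = cfg.markers_per_chrom
        spacing = cfg.chrom_length // (m + 1)
        jitter = rng.integers(-spacing // 3, spacing // 3 + 1, size=m)
        pos = (np.arange(1, m + 1) * spacing + jitter).astype(np.int64)

        freq = rng.uniform(0.05, 0.5, size=m)
        founders = (rng.random((cfg.n_founders, m)) < freq).astype(np.int8)
        # keep the founder pool polymorphic everywhere: flip one founder
        # where all agree, so no marker is lost to monomorphism
        mono = founders.min(axis=0) == founders.max(axis=0)
        flip_who = rng.integers(0, cfg.n_founders, size=m)
        founders[flip_who[mono], np.where(mono)[0]] ^= 1
        weights = rng.dirichlet(np.ones(cfg.n_founders))

        gaps = np.diff(pos)
        p_switch = 1.0 - np.exp(-cfg.ld_decay * gaps)
        switch = np.empty((2 * n, m), dtype=bool)
        switch[:, 0] = True
        switch[:, 1:] = rng.random((2 * n, m - 1)) < p_switch
        choice = rng.choice(cfg.n_founders, size=(2 * n, m), p=weights)
        # founder id at each marker = choice made at the last switch point
        last_switch = np.maximum.accumulate(
            np.where(switch, np.arange(m), 0), axis=1)
        founder_path = np.take_along_axis(choice, last_switch, axis=1)
        haps = founders[founder_path, np.arange(m)]

        keep = (haps.mean(axis=0) > 0) & (haps.mean(axis=0) < 1)
        haps, pos = haps[:, keep], pos[keep]
        all_h.append(haps)
        chroms.extend([chrom] * len(pos))
        poss.extend(pos.tolist())
        ids.extend(f"{chrom}_m{j + 1}" for j in range(len(pos)))

    h = np.concatenate(all_h, axis=1)  # (2n, m_total)
    h = h.reshape(n, 2, -1).transpose(0, 1, 2)
    h = np.stack([h[:, 0, :], h[:, 1, :]], axis=2)  # (n, m, 2)
    m_total = h.shape[1]
    markers = MarkerSet(
        np.asarray(ids), np.asarray(chroms),
        np.asarray(poss, dtype=np.int64),
        np.full(m_total, "A"), np.full(m_total, "C"),
        np.zeros(m_total),
    )
    individuals = [f"ind{i + 1}" for i in range(n)]
    return _reorient_minor(PhasedGenotypes(individuals, markers, h.astype(np.int8)))


def simulate_annotation(cfg: SimulationConfig,
                        rng: np.random.Generator) -> list[GenomeFeature]:
    """Non-overlapping genes with nested exons; CDS and UTR partition exons.

    Genes are placed one per slot of an even chromosome tiling, which
    guarantees non-overlap; an infeasible packing raises.
    """
    features: list[GenomeFeature] = []
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_genes // cfg.n_chromosomes)
    per_chrom[: cfg.n_genes % cfg.n_chromosomes] += 1
    gid = 0
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        n_g = int(per_chrom[c])
        if n_g == 0:
            continue
        slot = cfg.chrom_length // n_g
        if cfg.gene_length[0] + 2 > slot:
            raise ValueError(
                f"cannot pack {n_g} genes of length >= {cfg.gene_length[0]} "
                f"into chromosome of length {cfg.chrom_length}"
            )
        for s in range(n_g):
            gid += 1
            glen = int(rng.integers(cfg.gene_length[0],
                                    min(cfg.gene_length[1], slot - 2) + 1))
            gstart = int(s * slot + rng.integers(1, slot - glen)) + 1
            gend = gstart + glen - 1
            gene_id = f"gene{gid}"
            features.append(GenomeFeature(gene_id, "gene", chrom, gstart, gend))
            n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
            ex_slot = glen // n_ex
            for e in range(n_ex):
                elen = int(rng.integers(max(ex_slot // 3, 10), max(ex_slot - 1, 11)))
                estart = gstart + e * ex_slot + int(rng.integers(0, max(ex_slot - elen, 1)))
                eend = min(estart + elen - 1, gend)
                exon_id = f"{gene_id}.exon{e + 1}"
                features.append(GenomeFeature(exon_id, "exon", chrom, estart, eend))
                features.extend(_split_exon(exon_id, chrom, estart, eend,
                                            first=(e == 0), last=(e == n_ex - 1)))
    return features


def _split_exon(exon_id: str, chrom: str, start: int, end: int,
                first: bool, last: bool) -> list[GenomeFeature]:
    """Partition an exon into UTR and CDS pieces (UTR ~30% at gene ends)."""
    length = end - start + 1
    utr = max(1, int(0.3 * length))
    out: list[GenomeFeature] = []
    cds_start, cds_end = start, end
    if length < 3 or (first and last and length < 2 * utr + 1):
        # too short to split: call it all CDS
        return [GenomeFeature(f"{exon_id}.cds", "CDS", chrom, start, end)]
    if first:
        out.append(GenomeFeature(f"{exon_id}.utr5", "UTR", chrom, start, start + utr - 1))
        cds_start = start + utr
    if last:
        out.append(GenomeFeature(f"{exon_id}.utr3", "UTR", chrom, end - utr + 1, end))
        cds_end = end - utr
    if cds_start <= cds_end:
        out.append(GenomeFeature(f"{exon_id}.cds", "CDS", chrom, cds_start, cds_end))
    return out


def chrom_lengths_of(cfg: SimulationConfig) -> dict[str, int]:
    return {f"chr{c + 1}": cfg.chrom_length for c in range(cfg.n_chromosomes)}


def _gene_marker_mask(g: PhasedGenotypes,
                      features: list[GenomeFeature]) -> np.ndarray:
    """Boolean mask of markers lying inside any (merged) gene interval."""
    mask = np.zeros(g.n_markers, dtype=bool)
    genes = [f for f in features if f.genomic_class == "gene"]
    for chrom in dict.fromkeys(f.chromosome for f in genes):
        starts, ends = merge_intervals(
            np.array([f.start for f in genes if f.chromosome == chrom]),
            np.array([f.end for f in genes if f.chromosome == chrom]),
        )
        on_chrom = g.markers.chromosome == chrom
        pos = g.markers.position[on_chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos <= ends[np.clip(idx, 0, len(ends) - 1)])
        mask[np.where(on_chrom)[0][inside]] = True
    return mask


def _pick_qtl_markers(g: PhasedGenotypes, features: list[GenomeFeature],
                      cfg: SimulationConfig, rng: np.random.Generator,
                      n_qtl: int) -> np.ndarray:
    """QTL marker indices, a qtl_class_bias fraction inside genes."""
    in_gene = _gene_marker_mask(g, features) if features else np.zeros(g.n_markers, bool)
    n_in = int(round(cfg.qtl_class_bias * n_qtl))
    gene_pool = np.where(in_gene)[0]
    other_pool = np.where(~in_gene)[0] if n_in < n_qtl else np.array([], dtype=np.int64)
    if n_in > len(gene_pool):
        raise ValueError(
            f"qtl_class_bias requires {n_in} genic markers, only {len(gene_pool)} exist"
        )
    chosen = [rng.choice(gene_pool, size=n_in, replace=False)] if n_in else []
    n_out = n_qtl - n_in
    if n_out:
        pool = other_pool if len(other_pool) >= n_out else np.arange(g.n_markers)
        chosen.append(rng.choice(pool, size=n_out, replace=False))
    return np.sort(np.concatenate(chosen).astype(np.int64))


def _pick_qtl_windows(g: PhasedGenotypes, features: list[GenomeFeature],
                      cfg: SimulationConfig, rng: np.random.Generator,
                      n_qtl: int) -> list[np.ndarray]:
    """Windows of consecutive markers for haplotype QTL.

    Biased windows sit fully inside a (merged) gene; each window has
    qtl_block_size markers where the gene holds enough, at least two
    otherwise.
    """
    k = cfg.qtl_block_size
    in_gene = _gene_marker_mask(g, features) if features else np.zeros(g.n_markers, bool)
    chrom = g.markers.chromosome

    def runs(mask: np.ndarray) -> list[np.ndarray]:
        out = []
        idx = np.where(mask)[0]
        if len(idx) == 0:
            return out
        breaks = np.where((np.diff(idx) != 1)
                          | (chrom[idx[1:]] != chrom[idx[:-1]]))[0]
        for seg in np.split(idx, breaks + 1):
            if len(seg) >= 2:
                out.append(seg)
        return out

    n_in = int(round(cfg.qtl_class_bias * n_qtl))
    windows: list[np.ndarray] = []
    genic_runs = runs(in_gene)
    if n_in > 0 and not genic_runs:
        raise ValueError("qtl_class_bias > 0 but no gene holds >= 2 consecutive markers")
    for pool, count in ((genic_runs, n_in), (runs(np.ones_like(in_gene)), n_qtl - n_in)):
        if count == 0:
            continue
        picks = rng.choice(len(pool), size=count, replace=len(pool) < count)
        for r in picks:
            seg = pool[r]
            size = min(k, len(seg))
            start = int(rng.integers(0, len(seg) - size + 1))
            windows.append(seg[start:start + size])
    return windows


def simulate_phenotypes(
    g: PhasedGenotypes,
    features: list[GenomeFeature],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[PhenotypeTable, SimTruth]:
    """Phenotypes = fixed effects + architecture-specific genetic value + noise.

    Effects are drawn standard normal; the residual variance is then set
    from the realized genetic variance so that
    var(g) / (var(g) + sigma2_e) equals h2_target.  Fixed effects are
    rescaled to contribute ``fixed_var_fraction`` of the total phenotypic
    variance.
    """
    n = g.n_individuals
    gval, qtl_rows = _genetic_values(g, features, cfg, rng)
    var_g = float(np.var(gval))
    if var_g <= 0:
        raise ValueError("zero genetic variance after QTL placement")
    gval = gval - gval.mean()
    sigma2_e = var_g * (1.0 - cfg.h2_target) / cfg.h2_target
    resid = rng.normal(0.0, np.sqrt(sigma2_e), size=n)

    sex = rng.integers(0, cfg.sex_levels, size=n)
    year = rng.integers(0, cfg.year_levels, size=n)
    entry_weight = rng.normal(250.0, 25.0, size=n)
    fattening_days = rng.normal(150.0, 15.0, size=n)
    raw_fixed = (
        rng.normal(0, 1, cfg.sex_levels)[sex]
        + rng.normal(0, 1, cfg.year_levels)[year]
        + rng.normal(0, 1) * (entry_weight - entry_weight.mean()) / entry_weight.std()
        + rng.normal(0, 1) * (fattening_days - fattening_days.mean()) / fattening_days.std()
    )
    var_ge = float(np.var(gval + resid))
    sd_raw = float(np.std(raw_fixed))
    target_sd = np.sqrt(cfg.fixed_var_fraction / (1 - cfg.fixed_var_fraction) * var_ge)
    fixed = (raw_fixed - raw_fixed.mean()) * (target_sd / sd_raw if sd_raw > 0 else 0.0)

    trait = 100.0 + fixed + gval + resid
    frame = pd.DataFrame({
        "individual": g.individuals,
        "trait": trait,
        "sex": np.array(["M", "F", "X", "Y"])[sex % 4],
        "year": (2013 + year).astype(str),
        "entry_weight": entry_weight,
        "fattening_days": fattening_days,
    })
    realized_h2 = float(np.var(gval) / np.var(gval + resid))
    truth = SimTruth(gval, fixed, resid, sigma2_e, realized_h2,
                     pd.DataFrame(qtl_rows))
    return PhenotypeTable(frame), truth


def _genetic_values(g, features, cfg, rng) -> tuple[np.ndarray, list[dict]]:
    arch = cfg.architecture
    if arch == "mixed":
        g1, r1 = _additive_values(g, features, cfg, rng, cfg.n_qtl // 2)
        g2, r2 = _haplotype_values(g, features, cfg, rng, cfg.n_qtl - cfg.n_qtl // 2)
        s1, s2 = np.std(g1), np.std(g2)
        return (g1 / s1 if s1 > 0 else g1) + (g2 / s2 if s2 > 0 else g2), r1 + r2
    if arch == "snp_additive":
        return _additive_values(g, features, cfg, rng, cfg.n_qtl)
    if arch == "haplotype_qtl":
        return _haplotype_values(g, features, cfg, rng, cfg.n_qtl)
    return _epistatic_values(g, cfg, rng, cfg.n_qtl)


def _additive_values(g, features, cfg, rng, n_qtl):
    qtl = _pick_qtl_markers(g, features, cfg, rng, n_qtl)
    beta = rng.normal(0, 1, size=len(qtl))
    gval = g.dosage[:, qtl].astype(np.float64) @ beta
    rows = [{"type": "snp", "markers": g.markers.marker_id[j], "effect": b}
            for j, b in zip(qtl, beta)]
    return gval, rows


def _haplotype_values(g, features, cfg, rng, n_qtl):
    windows = _pick_qtl_windows(g, features, cfg, rng, n_qtl)
    n = g.n_individuals
    gval = np.zeros(n)
    rows = []
    for w in windows:
        haps = g.haplotypes[:, w, :]  # (n, k, 2)
        strings = haps.transpose(0, 2, 1).reshape(2 * n, -1)
        keys = np.array(["".join(map(str, row)) for row in strings])
        alleles, ids = np.unique(keys, return_inverse=True)
        eff = rng.normal(0, 1, size=len(alleles))
        per_hap = eff[ids].reshape(n, 2)
        gval += per_hap.sum(axis=1)
        rows.append({"type": "haplotype",
                     "markers": ",".join(g.markers.marker_id[w]),
                     "n_alleles": len(alleles),
                     "effect": ";".join(f"{a}:{e:.4f}" for a, e in zip(alleles, eff))})
    return gval, rows


def _epistatic_values(g, cfg, rng, n_qtl):
    """Effects on unordered state pairs of whole-genome haploblock pairs."""
    blocks = build_blocks_genomewide(g)
    codes = categorical_encode(blocks).codes
    q = codes.shape[1]
    if q < 2:
        raise ValueError("need at least two haploblocks for epistatic QTL")
    n = g.n_individuals
    gval = np.zeros(n)
    rows = []
    for _ in range(n_qtl):
        b1, b2 = rng.choice(q, size=2, replace=False)
        state = codes[:, b1].astype(np.int64) * (codes[:, b2].max() + 1) + codes[:, b2]
        uniq, ids = np.unique(state, return_inverse=True)
        eff = rng.normal(0, 1, size=len(uniq))
        gval += eff[ids]
        rows.append({"type": "epistatic_pair", "markers": f"block{b1}|block{b2}",
                     "n_states": len(uniq), "effect": ""})
    return gval, rows


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Full cohort from one seed: genotypes, annotation, phenotypes, truth."""
    rng = np.random.default_rng(cfg.seed)
    g = simulate_haplotypes(cfg, rng)
    features = simulate_annotation(cfg, rng) if cfg.n_genes > 0 else []
    phenotypes, truth = simulate_phenotypes(g, features, cfg, rng)
    return SimulatedDataset(g, features, chrom_lengths_of(cfg), phenotypes, truth)


def write_dataset(ds: SimulatedDataset, prefix: str) -> None:
    """Emit VCF, GFF3, phenotype TSV and truth TSV under a path prefix."""
    from .annotation import write_gff3
    from .io_qc import write_phased_vcf, write_phenotypes

    write_phased_vcf(ds.genotypes, f"{prefix}.vcf")
    write_gff3(ds.features, f"{prefix}.gff3", ds.chrom_lengths)
    write_phenotypes(ds.phenotypes, f"{prefix}.pheno.tsv")
    truth = pd.DataFrame({
        "individual": ds.genotypes.individuals,
        "genetic_value": ds.truth.genetic_values,
        "fixed_part": ds.truth.fixed_part,
        "residual": ds.truth.residuals,
    })
    truth.to_csv(f"{prefix}.truth.tsv", sep="\t", index=False)
    ds.truth.qtl.to_csv(f"{prefix}.qtl.tsv", sep="\t", index=False)
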