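"""The synthetic cohort generator: LD structure, annotation geometry,
phenotype architectures and determinism."""

import numpy as np
import pytest
from scipy import stats

import hapgp as hp
from hapgp.synthetic_data import _gene_marker_mask


def small_cfg(**kw):
    base = dict(n_individuals=150, n_chromosomes=2, markers_per_chrom=120,
                chrom_length=600_000, n_genes=16, n_qtl=15, seed=1)
    base.update(kw)
    return hp.SimulationConfig(**base)


def pairwise_r2(dosage, j, k):
    return np.corrcoef(dosage[:, j], dosage[:, k])[0, 1] ** 2


# ------------------------------------------------------------- haplotypes

def test_ld_decays_with_distance():
    """Mean r2 binned by inter-marker distance is monotonically
    decreasing in rank (Spearman over bins)."""
    cfg = small_cfg(n_individuals=300, seed=2)
    g = hp.simulate_haplotypes(cfg, np.random.default_rng(cfg.seed))
    d = g.dosage.astype(float)
    chrom1 = g.markers.chromosome == "chr1"
    idx = np.where(chrom1)[0]
    pos = g.markers.position[idx]
    dists, r2s = [], []
    rng = np.random.default_rng(0)
    for _ in range(1500):
        a, b = rng.choice(len(idx), 2, replace=False)
        dist = abs(pos[a] - pos[b])
        if dist < 150_000:
            dists.append(dist)
            r2s.append(pairwise_r2(d, idx[a], idx[b]))
    bins = np.digitize(dists, np.linspace(0, 150_000, 8))
    means = [np.mean([r for r, bb in zip(r2s, bins) if bb == b]) for b in range(1, 8)]
    rho = stats.spearmanr(np.arange(len(means)), means).statistic
    assert rho < -0.8
    # close pairs carry real LD, far pairs little
    assert means[0] > 0.1
    assert means[-1] < means[0] / 2


def test_no_recombination_limit_copies_founders():
    cfg = small_cfg(ld_decay=0.0, n_individuals=100, seed=3)
    g = hp.simulate_haplotypes(cfg, np.random.default_rng(cfg.seed))
    chrom1 = np.where(g.markers.chromosome == "chr1")[0]
    haps = g.haplotypes[:, chrom1, :].transpose(0, 2, 1).reshape(200, -1)
    # at most n_founders distinct haplotypes per chromosome (minus dropped
    # monomorphic columns, which cannot increase the count)
    distinct = {tuple(h) for h in haps}
    assert len(distinct) <= cfg.n_founders


def test_free_recombination_limit_kills_ld():
    cfg = small_cfg(ld_decay=10.0, n_individuals=400, seed=4)
    g = hp.simulate_haplotypes(cfg, np.random.default_rng(cfg.seed))
    d = g.dosage.astype(float)
    idx = np.where(g.markers.chromosome == "chr1")[0]
    r2 = [pairwise_r2(d, idx[j], idx[j + 1]) for j in range(len(idx) - 1)]
    assert np.mean(r2) < 0.05


def test_genotypes_are_minor_oriented_and_polymorphic():
    g = hp.simulate_haplotypes(small_cfg(), np.random.default_rng(1))
    freq = g.haplotypes.mean(axis=(0, 2))
    assert np.all(freq > 0)
    assert np.all(freq <= 0.5 + 1e-12)


# ------------------------------------------------------------- annotation

def test_annotation_counts_and_nesting():
    cfg = small_cfg()
    feats = hp.simulate_annotation(cfg, np.random.default_rng(7))
    genes = [f for f in feats if f.genomic_class == "gene"]
    assert len(genes) == cfg.n_genes
    # genes non-overlapping per chromosome
    for chrom in {g.chromosome for g in genes}:
        gs = sorted([g for g in genes if g.chromosome == chrom], key=lambda f: f.start)
        assert all(a.end < b.start for a, b in zip(gs, gs[1:]))
    # every exon inside its gene; every CDS/UTR inside an exon
    exons = [f for f in feats if f.genomic_class == "exon"]
    for e in exons:
        assert any(g.start <= e.start and e.end <= g.end and g.chromosome == e.chromosome
                   for g in genes)
    for f in feats:
        if f.genomic_class in ("CDS", "UTR"):
            assert any(e.start <= f.start and f.end <= e.end and e.chromosome == f.chromosome
                       for e in exons)


def test_igr_count_complement(tmp_path):
    cfg = small_cfg(n_chromosomes=1, n_genes=2)
    feats = hp.simulate_annotation(cfg, np.random.default_rng(8))
    genes = [f for f in feats if f.genomic_class == "gene"]
    igrs = hp.derive_igr(genes, {"chr1": cfg.chrom_length})
    assert len(igrs) == 3


def test_infeasible_gene_packing_rejected():
    cfg = small_cfg(n_genes=100, n_chromosomes=1, chrom_length=300_000,
                    gene_length=(10_000, 30_000))
    with pytest.raises(ValueError, match="pack"):
        hp.simulate_annotation(cfg, np.random.default_rng(1))


# ------------------------------------------------------------- phenotypes

def test_realized_h2_close_to_target_across_replicates():
    h2s = []
    for rep in range(20):
        ds = hp.simulate_dataset(small_cfg(n_individuals=400, seed=200 + rep))
        h2s.append(ds.truth.realized_h2)
    assert abs(np.mean(h2s) - 0.4) < 0.03


def test_near_null_heritability():
    h2s = [hp.simulate_dataset(small_cfg(h2_target=0.01, seed=300 + r)).truth.realized_h2
           for r in range(10)]
    assert np.mean(h2s) < 0.05


def test_fixed_effects_variance_share():
    ds = hp.simulate_dataset(small_cfg(n_individuals=500, seed=5))
    t = ds.truth
    total = np.var(t.fixed_part + t.genetic_values + t.residuals)
    share = np.var(t.fixed_part) / total
    assert 0.1 < share < 0.3


def test_qtl_class_bias_places_qtl_in_genes():
    cfg = small_cfg(architecture="haplotype_qtl", qtl_class_bias=1.0, seed=6)
    ds = hp.simulate_dataset(cfg)
    in_gene = _gene_marker_mask(ds.genotypes, ds.features)
    id_to_idx = {mid: i for i, mid in enumerate(ds.genotypes.markers.marker_id)}
    for row in ds.truth.qtl.itertuples():
        for mid in row.markers.split(","):
            assert in_gene[id_to_idx[mid]]


def test_haplotype_qtl_in_complete_ld_with_alleles_not_snps():
    """Each multi-allelic QTL window is in complete LD with its haplotype
    alleles (their counts reproduce the window's genetic contribution
    exactly) while no single SNP is: the premise haplotype models rely on."""
    cfg = small_cfg(architecture="haplotype_qtl", n_qtl=3, qtl_block_size=4,
                    n_individuals=400, seed=13)
    ds = hp.simulate_dataset(cfg)
    g = ds.genotypes
    d = g.dosage.astype(float)
    id_to_idx = {mid: i for i, mid in enumerate(g.markers.marker_id)}
    checked = 0
    for row in ds.truth.qtl.itertuples():
        w = np.array([id_to_idx[mid] for mid in row.markers.split(",")])
        eff = dict(pair.split(":") for pair in row.effect.split(";"))
        haps = g.haplotypes[:, w, :]
        strings = haps.transpose(0, 2, 1).reshape(2 * g.n_individuals, -1)
        keys = np.array(["".join(map(str, r)) for r in strings])
        window_val = np.array([float(eff[k]) for k in keys]).reshape(-1, 2).sum(axis=1)
        if row.n_alleles < 6:  # few alleles can be dosage-spanned; skip
            continue
        checked += 1
        # allele counts reproduce the window value exactly ...
        counts = np.stack([(keys == a).reshape(-1, 2).sum(axis=1)
                           for a in np.unique(keys)], axis=1).astype(float)
        coef, *_ = np.linalg.lstsq(counts, window_val, rcond=None)
        assert np.allclose(counts @ coef, window_val, atol=1e-8)
        # ... while no single SNP anywhere does
        best_snp = max(np.corrcoef(d[:, j], window_val)[0, 1] ** 2
                       for j in range(d.shape[1]) if np.std(d[:, j]) > 0)
        assert best_snp < 0.95
    assert checked >= 1


def test_epistatic_architecture_produces_variance():
    ds = hp.simulate_dataset(small_cfg(architecture="epistatic", n_qtl=10, seed=9))
    assert np.var(ds.truth.genetic_values) > 0
    assert (ds.truth.qtl["type"] == "epistatic_pair").all()


# ------------------------------------------------------------ determinism

def test_datasets_byte_identical_given_seed(tmp_path):
    cfg = small_cfg(seed=42)
    for sub in ("a", "b"):
        (tmp_path / sub).mkdir()
        hp.write_dataset(hp.simulate_dataset(cfg), str(tmp_path / sub / "d"))
    for name in ("d.vcf", "d.gff3", "d.pheno.tsv", "d.truth.tsv", "d.qtl.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == \
               (tmp_path / "b" / name).read_bytes()


def test_config_validation():
    with pytest.raises(ValueError, match="h2_target"):
        hp.SimulationConfig(h2_target=0.0)
    with pytest.raises(ValueError, match="architecture"):
        hp.SimulationConfig(architecture="polygenic")
    with pytest.raises(ValueError, match="qtl_class_bias"):
        hp.SimulationConfig(qtl_class_bias=1.5)
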