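"""Genome-annotation handling: five genomic classes and SNP-set assignment.

The genome is partitioned by annotation context into five classes —
intergenic regions (IGR), gene, exon, CDS and UTR — with the nesting
UTR/CDS within exon within gene, and IGR defined as the intervals between
adjacent (merged) genes.  Markers are assigned to the features containing
them; the SNPs of one feature form a "SNP set", the unit within which
haploblocks are later constructed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_qc import MarkerSet

GENOMIC_CLASSES = ("IGR", "gene", "exon", "CDS", "UTR")

_GFF_TYPE_MAP = {
    "gene": "gene",
    "exon": "exon",
    "CDS": "CDS",
    "five_prime_UTR": "UTR",
    "three_prime_UTR": "UTR",
}


@dataclass(frozen=True)
class GenomeFeature:
    feature_id: str
    genomic_class: str  # one of GENOMIC_CLASSES
    chromosome: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.feature_id}: start {self.start} > end {self.end}")
        if self.genomic_class not in GENOMIC_CLASSES:
            raise ValueError(f"unknown genomic class {self.genomic_class!r}")


@dataclass
class SnpSet:
    feature: GenomeFeature
    marker_indices: np.ndarray  # strictly increasing positions into a MarkerSet

    def __len__(self) -> int:
        return len(self.marker_indices)


@dataclass
class ClassPartition:
    genomic_class: str
    snp_sets: list[SnpSet]  # only non-empty sets

    @property
    def n_snps(self) -> int:
        if not self.snp_sets:
            return 0
        return len(np.unique(np.concatenate([s.marker_indices for s in self.snp_sets])))

    @property
    def n_represented_features(self) -> int:
        return sum(1 for s in self.snp_sets if len(s) > 0)

    @property
    def marker_indices(self) -> np.ndarray:
        if not self.snp_sets:
            return np.array([], dtype=np.int64)
        return np.unique(np.concatenate([s.marker_indices for s in self.snp_sets]))


def read_gff3(path: str) -> list[GenomeFeature]:
    """Parse gene/exon/CDS/UTR features from a GFF3 file.

    Both UTR types collapse into the single UTR class; strand is ignored.
    A record with start > end raises with its line number.
    """
    import gffutils.iterators

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) >= 5 and cols[2] in _GFF_TYPE_MAP:
                try:
                    start, end = int(cols[3]), int(cols[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from exc
                if start > end:
                    raise ValueError(
                        f"{path}:{lineno}: malformed coordinates start {start} > end {end}"
                    )

    features: list[GenomeFeature] = []
    counters: dict[str, int] = {}
    for rec in gffutils.iterators.DataIterator(path):
        cls = _GFF_TYPE_MAP.get(rec.featuretype)
        if cls is None:
            continue
        fid = rec.attributes.get("ID", [None])[0]
        if fid is None:
            counters[cls] = counters.get(cls, 0) + 1
            fid = f"{cls}_{counters[cls]}"
        features.append(GenomeFeature(fid, cls, rec.seqid, rec.start, rec.end))
    return features


def write_gff3(features: list[GenomeFeature], path: str,
               chrom_lengths: dict[str, int] | None = None) -> None:
    """Write features as GFF3; the UTR class is emitted as five_prime_UTR."""
    type_map = {"gene": "gene", "exon": "exon", "CDS": "CDS", "UTR": "five_prime_UTR"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths:
            for chrom, length in chrom_lengths.items():
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for f in features:
            if f.genomic_class == "IGR":
                continue
            fh.write(f"{f.chromosome}\tsim\t{type_map[f.genomic_class]}\t{f.start}\t"
                     f"{f.end}\t.\t+\t.\tID={f.feature_id}\n")


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of 1-based inclusive intervals, returned sorted and disjoint."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = np.asarray(starts)[order], np.asarray(ends)[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1] + 1:  # adjacent intervals merge: no empty IGR between them
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)


def derive_igr(genes: list[GenomeFeature],
               chrom_lengths: dict[str, int]) -> list[GenomeFeature]:
    """Intergenic regions: per-chromosome complement of merged gene intervals."""
    igrs: list[GenomeFeature] = []
    for chrom, length in chrom_lengths.items():
        g = [f for f in genes if f.chromosome == chrom]
        for f in g:
            if f.end > length:
                raise ValueError(
                    f"gene {f.feature_id} ends at {f.end}, beyond chromosome "
                    f"{chrom} length {length}"
                )
        starts, ends = merge_intervals(
            np.array([f.start for f in g], dtype=np.int64),
            np.array([f.end for f in g], dtype=np.int64),
        )
        bounds = [(1, (starts[0] - 1) if len(starts) else length)] if len(starts) else [(1, length)]
        for i in range(len(starts) - 1):
            bounds.append((ends[i] + 1, starts[i + 1] - 1))
        if len(starts):
            bounds.append((ends[-1] + 1, length))
        k = 0
        for s, e in bounds:
            if s <= e:
                k += 1
                igrs.append(GenomeFeature(f"IGR_{chrom}_{k}", "IGR", chrom, int(s), int(e)))
    return igrs


def assign_snps(markers: MarkerSet, features: list[GenomeFeature],
                merge_overlaps: bool = True) -> ClassPartition:
    """Assign markers to the SNP sets of one genomic class.

    Overlapping same-class features are merged into union intervals first
    (default), so a marker lands in at most one SNP set per class; pass
    ``merge_overlaps=False`` to keep per-feature duplication.  A marker on
    a feature boundary is inside the feature.
    """
    classes = {f.genomic_class for f in features}
    if len(classes) > 1:
        raise ValueError(f"features span multiple classes: {sorted(classes)}")
    cls = classes.pop() if classes else "gene"
    snp_sets: list[SnpSet] = []
    for chrom in dict.fromkeys(f.chromosome for f in features):
        feats = [f for f in features if f.chromosome == chrom]
        in_chrom = np.where(markers.chromosome == chrom)[0]
        pos = markers.position[in_chrom]
        if merge_overlaps:
            starts, ends = merge_intervals(
                np.array([f.start for f in feats], dtype=np.int64),
                np.array([f.end for f in feats], dtype=np.int64),
            )
            merged: list[GenomeFeature] = []
            for s, e in zip(starts, ends):
                members = sorted(f.feature_id for f in feats if f.start <= e and f.end >= s)
                merged.append(GenomeFeature("+".join(members), cls, chrom, int(s), int(e)))
            feats = merged
        for f in sorted(feats, key=lambda f: (f.start, f.end)):
            inside = in_chrom[(pos >= f.start) & (pos <= f.end)]
            if len(inside):
                snp_sets.append(SnpSet(f, inside))
    return ClassPartition(cls, snp_sets)


def build_class_partitions(
    markers: MarkerSet,
    features: list[GenomeFeature],
    chrom_lengths: dict[str, int],
    merge_overlaps: bool = True,
) -> dict[str, ClassPartition]:
    """SNP sets for all five classes, deriving IGR from the gene features."""
    genes = [f for f in features if f.genomic_class == "gene"]
    partitions: dict[str, ClassPartition] = {}
    for cls in ("gene", "exon", "CDS", "UTR"):
        feats = [f for f in features if f.genomic_class == cls]
        partitions[cls] = (assign_snps(markers, feats, merge_overlaps)
                           if feats else ClassPartition(cls, []))
    igr = derive_igr(genes, chrom_lengths)
    partitions["IGR"] = assign_snps(markers, igr, merge_overlaps) if igr else ClassPartition("IGR", [])
    return partitions


def export_class_bed(partition: ClassPartition, path: str) -> None:
    """BED-like TSV (chrom, start, end, feature_id, class, n_snps) for inspection."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tfeature_id\tclass\tn_snps\n")
        for s in partition.snp_sets:
            f = s.feature
            fh.write(f"{f.chromosome}\t{f.start}\t{f.end}\t{f.feature_id}\t"
                     f"{f.genomic_class}\t{len(s)}\n")
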