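"""Multi-sample SNP genotype container and VCF round-trip.

Genotypes are diploid-coded at the screening stage (conventional short-read
SNP calls): 0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing. Positions are
stored 0-based half-open internally; VCF is 1-based at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from .errors import DataError

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass
class VariantRecord:
    """One biallelic SNP with per-sample diploid-coded genotype calls."""

    contig: str
    position: int                 # 0-based
    ref_allele: str
    alt_allele: str
    genotypes: np.ndarray         # int8 codes, one per sample
    per_sample_depth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.position < 0:
            raise DataError("position must be >= 0 (0-based)")
        if self.ref_allele == self.alt_allele:
            raise DataError("ref and alt alleles must differ")


@dataclass
class GenotypeMatrix:
    """All SNPs of a cohort, sorted by (contig, position)."""

    contigs: np.ndarray           # str, one per variant
    positions: np.ndarray         # int64, 0-based
    ref: np.ndarray               # str
    alt: np.ndarray               # str
    genotypes: np.ndarray         # int8, shape (n_variants, n_samples)
    samples: list[str]
    contig_lengths: dict[str, int] = field(default_factory=dict)
    depths: Optional[np.ndarray] = None   # same shape as genotypes

    @property
    def n_variants(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def is_sorted(self) -> bool:
        keys = list(zip(self.contigs.tolist(), self.positions.tolist()))
        return keys == sorted(keys)

    def record(self, i: int) -> VariantRecord:
        depth = self.depths[i] if self.depths is not None else None
        return VariantRecord(str(self.contigs[i]), int(self.positions[i]),
                             str(self.ref[i]), str(self.alt[i]),
                             self.genotypes[i], depth)

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            contigs=self.contigs[mask],
            positions=self.positions[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            genotypes=self.genotypes[mask],
            samples=list(self.samples),
            contig_lengths=dict(self.contig_lengths),
            depths=None if self.depths is None else self.depths[mask],
        )

    def sort(self) -> "GenotypeMatrix":
        order = np.lexsort((self.positions, self.contigs))
        return self.subset(order)


_CODE_TO_GT = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1),
               MISSING: (None, None)}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as an uncompressed multi-sample VCF v4.2."""
    header = pysam.VariantHeader()
    for name, length in sorted(gm.contig_lengths.items()):
        header.contigs.add(name, length=length)
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"),
                                     ("Description", "Genotype")])
    if gm.depths is not None:
        header.add_meta("FORMAT", items=[("ID", "DP"), ("Number", "1"),
                                         ("Type", "Integer"),
                                         ("Description", "Read depth")])
    for sample in gm.samples:
        header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i in range(gm.n_variants):
            rec = vcf.new_record(
                contig=str(gm.contigs[i]),
                start=int(gm.positions[i]),
                alleles=(str(gm.ref[i]), str(gm.alt[i])),
            )
            for j, sample in enumerate(gm.samples):
                rec.samples[sample]["GT"] = _CODE_TO_GT[int(gm.genotypes[i, j])]
                if gm.depths is not None:
                    rec.samples[sample]["DP"] = int(gm.depths[i, j])
            vcf.write(rec)


def _gt_code(gt: tuple) -> int:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return MISSING
    if any(a not in (0, 1) for a in alleles):
        raise DataError("only biallelic SNP genotypes are supported")
    if len(alleles) == 1:
        return HOM_REF if alleles[0] == 0 else HOM_ALT
    total = sum(alleles)
    return (HOM_REF, HET, HOM_ALT)[min(total, 2)] if total <= 2 else HOM_ALT


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a multi-sample VCF of biallelic SNPs into a GenotypeMatrix."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"VCF not found: {path}")
    contigs, positions, refs, alts, codes, depths = [], [], [], [], [], []
    has_depth = True
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        contig_lengths = {name: ctg.length
                          for name, ctg in vcf.header.contigs.items()
                          if ctg.length is not None}
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise DataError(
                    f"multi-allelic or ALT-less record at "
                    f"{rec.contig}:{rec.pos}; split upstream")
            contigs.append(rec.contig)
            positions.append(rec.start)
            refs.append(rec.ref)
            alts.append(rec.alts[0])
            row = [_gt_code(rec.samples[s].get("GT", (None, None)))
                   for s in samples]
            codes.append(row)
            drow = [rec.samples[s].get("DP") for s in samples]
            if any(d is None for d in drow):
                has_depth = False
            depths.append(drow)
    gm = GenotypeMatrix(
        contigs=np.array(contigs, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=np.array(codes, dtype=np.int8).reshape(len(codes),
                                                         len(samples)),
        samples=samples,
        contig_lengths=contig_lengths,
        depths=(np.array(depths, dtype=np.int64) if has_depth and depths
                else None),
    )
    return gm
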