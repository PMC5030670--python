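"""Plain-text VCF and loci-table output.

Datasets are written as minimal VCF 4.2 with one contig per locus, GT and
DP FORMAT fields and unphased genotypes, alongside a tab-separated loci
table (locus id, length in bp).  Reading goes through cyvcf2
(:func:`metapopabc.sumstats.read_vcf_records`), so everything written here
round-trips through standard tooling.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .simulate import SnpDataset
from .sumstats import SiteRecord

__all__ = ["write_vcf", "write_vcf_records", "write_loci_table", "read_loci_table"]


def write_vcf_records(
    records: Sequence[SiteRecord],
    contigs: Sequence[tuple[str, int]],
    path: str | Path,
    sample_names: Sequence[str],
) -> None:
    """Write SiteRecords as a VCF file (the low-level writer)."""
    lines = ["##fileformat=VCFv4.2", "##source=metapopabc"]
    for cid, length in contigs:
        lines.append(f"##contig=<ID={cid},length={int(length)}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names)
    )
    for rec in records:
        depths = rec.depths if rec.depths is not None else np.full(rec.n_samples, 30)
        cells = []
        for (a, b), dp in zip(rec.genotypes, depths):
            gt = "./." if a < 0 or b < 0 else f"{a}/{b}"
            cells.append(f"{gt}:{int(dp)}")
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{','.join(rec.alts)}\t.\tPASS\t.\tGT:DP\t"
            + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def dataset_to_records(dataset: SnpDataset, depth: int = 30) -> list[SiteRecord]:
    """Expand 0/1/2 genotypes into unphased allele pairs (1 -> 0/1)."""
    records = []
    for locus_id, g, pos in zip(dataset.locus_ids, dataset.genotypes, dataset.positions):
        for row, p in zip(g, pos):
            pairs = np.zeros((len(row), 2), dtype=int)
            pairs[row == 1, 1] = 1
            pairs[row == 2] = 1
            records.append(
                SiteRecord(
                    locus_id,
                    int(p),
                    "A",
                    ("T",),
                    pairs,
                    np.full(len(row), depth, dtype=int),
                )
            )
    return records


def write_vcf(
    dataset: SnpDataset,
    path: str | Path,
    sample_names: Sequence[str] | None = None,
    depth: int = 30,
) -> None:
    """Write a dataset as VCF (biallelic SNPs, GT+DP, one contig per locus)."""
    if sample_names is None:
        sample_names = [f"{dataset.scheme}_{i:02d}" for i in range(dataset.n_individuals)]
    contigs = list(zip(dataset.locus_ids, (int(v) for v in dataset.lengths)))
    write_vcf_records(dataset_to_records(dataset, depth), contigs, path, sample_names)


def write_loci_table(dataset_or_pairs, path: str | Path) -> None:
    """Tab-separated loci table: locus_id <tab> length_bp."""
    if isinstance(dataset_or_pairs, SnpDataset):
        pairs = zip(dataset_or_pairs.locus_ids, dataset_or_pairs.lengths)
    else:
        pairs = dataset_or_pairs
    with open(path, "w") as fh:
        fh.write("locus_id\tlength_bp\n")
        for cid, length in pairs:
            fh.write(f"{cid}\t{int(length)}\n")


def read_loci_table(path: str | Path) -> list[tuple[str, float]]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("locus_id"):
            raise ValueError("loci table must have a locus_id/length_bp header")
        for line in fh:
            cid, length = line.split("\t")
            out.append((cid, float(length)))
    return out
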