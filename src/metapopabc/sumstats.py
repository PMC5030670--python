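"""Folded-SFS summary statistics and site filtering.

The ABC summary vector is the folded site frequency spectrum — counts of
sites by minor-allele copy number among the 2n chromosomes of n diploids,
classes 1..n — together with the total number of segregating sites S.
Folding avoids both ancestral-state and phasing assumptions.  The default
vector handed to the ABC machinery is the normalised spectrum
(proportions) concatenated with S; raw counts are available as a switch.

Raw-style VCFs are ingested through the same site filters applied to the
study's capture data: minimum depth 6x in every sample, removal of
triallelic sites, removal of sites heterozygous in more than 80% of
samples, and removal of sites with any missing call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .simulate import SnpDataset

__all__ = [
    "SummaryVector",
    "FilterPolicy",
    "SiteRecord",
    "filter_sites",
    "folded_sfs",
    "summarize_dataset",
    "snp_density",
    "read_vcf_records",
    "records_to_dataset",
]


@dataclass(frozen=True)
class SummaryVector:
    """Folded SFS counts (classes 1..n individuals) plus S = sum of counts."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if (c < 0).any():
            raise ValueError("SFS counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n_individuals(self) -> int:
        return len(self.counts)

    @property
    def s(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        s = self.s
        if s == 0:
            return np.zeros(len(self.counts))
        return self.counts / s

    def vector(self, kind: str = "proportions") -> np.ndarray:
        """ABC summary vector: folded SFS (proportions or counts) + S."""
        if kind == "proportions":
            return np.concatenate([self.proportions, [float(self.s)]])
        if kind == "counts":
            return np.concatenate([self.counts.astype(float), [float(self.s)]])
        raise ValueError(f"unknown summary kind {kind!r}")


@dataclass(frozen=True)
class SiteRecord:
    """One VCF site: genotype allele pairs (-1 = missing) and per-sample depth."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: np.ndarray  # (n_samples, 2) allele indices, -1 missing
    depths: np.ndarray | None = None  # per-sample DP

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]


@dataclass(frozen=True)
class FilterPolicy:
    """The study's site filters, applied in a fixed order.

    Order: depth -> triallelic -> heterozygosity -> missing; a removed
    site is attributed to the first filter it fails.  ``strand_bias`` is a
    pass-through hook (record -> keep?) for pipelines that carry strand
    information; simulations do not, so it defaults to a no-op.
    """

    min_depth: int = 6
    drop_triallelic: bool = True
    max_het_fraction: float = 0.80
    drop_any_missing: bool = True
    strand_bias: Callable[[SiteRecord], bool] | None = None

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0 <= self.max_het_fraction <= 1:
            raise ValueError("max_het_fraction must be a proportion")


FILTER_ORDER = ("strand_bias", "depth", "triallelic", "heterozygosity", "missing")


def _first_failure(rec: SiteRecord, policy: FilterPolicy) -> str | None:
    if policy.strand_bias is not None and not policy.strand_bias(rec):
        return "strand_bias"
    if policy.min_depth > 0:
        if rec.depths is None:
            raise ValueError(
                f"site {rec.chrom}:{rec.pos} lacks per-sample depth but min_depth is active"
            )
        if (np.asarray(rec.depths) < policy.min_depth).any():
            return "depth"
    if policy.drop_triallelic and len(rec.alts) > 1:
        return "triallelic"
    g = rec.genotypes
    called = (g >= 0).all(axis=1)
    if policy.max_het_fraction < 1:
        het = called & (g[:, 0] != g[:, 1])
        if het.sum() > policy.max_het_fraction * rec.n_samples:
            return "heterozygosity"
    if policy.drop_any_missing and not called.all():
        return "missing"
    return None


def filter_sites(
    records: Iterable[SiteRecord], policy: FilterPolicy | None = None
) -> tuple[list[SiteRecord], dict[str, int]]:
    """Apply the site filters; return survivors and per-filter removal counts.

    Removal counts partition the removed sites by the first filter each
    fails, so they sum to the number of sites removed.
    """
    policy = policy or FilterPolicy()
    removed = {name: 0 for name in FILTER_ORDER}
    kept: list[SiteRecord] = []
    for rec in records:
        fail = _first_failure(rec, policy)
        if fail is None:
            kept.append(rec)
        else:
            removed[fail] += 1
    return kept, removed


def folded_sfs(
    dataset: SnpDataset | Sequence[np.ndarray],
    individuals: Sequence[int] | None = None,
) -> SummaryVector:
    """Folded SFS of a dataset (optionally of a subset of its individuals).

    Class i counts sites whose minor allele appears i times among the 2n
    chromosomes of the subset, i in [1, n]; monomorphic sites contribute
    nothing.  Missing genotypes are an error — the filters remove them.
    """
    matrices = dataset.genotypes if isinstance(dataset, SnpDataset) else list(dataset)
    if not matrices:
        raise ValueError("empty dataset")
    n_ind_full = matrices[0].shape[1]
    idx = np.arange(n_ind_full) if individuals is None else np.asarray(individuals, dtype=int)
    n = len(idx)
    two_n = 2 * n
    counts = np.zeros(n, dtype=np.int64)
    for g in matrices:
        sub = g[:, idx]
        if (sub < 0).any():
            raise ValueError("missing genotypes in the requested subset")
        alt = sub.sum(axis=1)
        minor = np.minimum(alt, two_n - alt)
        minor = minor[minor > 0]
        if minor.size:
            counts += np.bincount(minor, minlength=n + 1)[1 : n + 1]
    return SummaryVector(counts)


def snp_density(s: int, total_bp: float) -> float:
    """SNPs per kilobase, reported to one decimal (e.g. 2605 / 606,647 bp -> 4.3)."""
    if total_bp <= 0:
        raise ValueError("total length must be positive")
    return round(s / (total_bp / 1000.0), 1)


def summarize_dataset(dataset: SnpDataset) -> tuple[SummaryVector, float]:
    """Folded SFS plus SNP density per kb over the dataset's loci."""
    sv = folded_sfs(dataset)
    return sv, snp_density(sv.s, dataset.total_bp)


# ---------------------------------------------------------------------------
# VCF ingestion


def read_vcf_records(path: str) -> list[SiteRecord]:
    """Read a (plain or gzipped) VCF into SiteRecords via cyvcf2."""
    from cyvcf2 import VCF

    records = []
    vcf = VCF(str(path), gts012=False)
    for v in vcf:
        gts = np.array([[g[0], g[1]] for g in v.genotypes], dtype=int)
        try:
            depths = v.format("DP")
            depths = None if depths is None else depths.reshape(-1).astype(int)
        except KeyError:
            depths = None
        records.append(
            SiteRecord(v.CHROM, v.POS, v.REF, tuple(v.ALT), gts, depths)
        )
    vcf.close()
    return records


def records_to_dataset(
    records: Sequence[SiteRecord],
    loci: Sequence[tuple[str, float]],
    scheme: str = "SID",
) -> SnpDataset:
    """Assemble filtered biallelic records into an SnpDataset.

    ``loci`` is the loci table: (locus id, length in bp) for every locus,
    including loci without surviving SNPs.
    """
    if not records and not loci:
        raise ValueError("need at least a loci table")
    n_samples = records[0].n_samples if records else 0
    by_locus: dict[str, list[SiteRecord]] = {}
    for rec in records:
        if len(rec.alts) != 1:
            raise ValueError(f"site {rec.chrom}:{rec.pos} is not biallelic; filter first")
        if (rec.genotypes < 0).any():
            raise ValueError(f"site {rec.chrom}:{rec.pos} has missing calls; filter first")
        by_locus.setdefault(rec.chrom, []).append(rec)
    genotypes, positions, ids, lengths = [], [], [], []
    for locus_id, length in loci:
        recs = by_locus.get(locus_id, [])
        if recs:
            g = np.stack([r.genotypes.sum(axis=1).astype(np.int8) for r in recs])
            pos = np.array([r.pos for r in recs], dtype=int)
        else:
            g = np.zeros((0, n_samples), dtype=np.int8)
            pos = np.zeros(0, dtype=int)
        genotypes.append(g)
        positions.append(pos)
        ids.append(locus_id)
        lengths.append(float(length))
    return SnpDataset(genotypes, ids, np.array(lengths), scheme, n_samples, positions)
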