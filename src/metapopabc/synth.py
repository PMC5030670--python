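"""Synthetic fixtures with the statistical shape of the capture data.

The study's VCF has no public accession, so everything downstream is
exercised on generated data: coalescent-simulated datasets with the
single-deme (11 diploids, 998 loci) and scatter (9 diploids, 995 loci)
shapes, and VCFs with planted filter violations whose ground truth is
recorded in a JSON manifest.  All fixture outputs here are synthetic
stand-ins for the unpublished study data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import ParameterDraw, build_schedule
from .simulate import SamplingScheme, draw_locus_panel, simulate_dataset
from .sumstats import SiteRecord, SummaryVector, folded_sfs
from .vcfio import dataset_to_records, write_loci_table, write_vcf_records

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "plant_violations",
    "make_observed_like",
    "observed_like_draw",
    "gamma_length_prior",
]

#: point estimates of the finite island model fitted to the shark data,
#: used as the generating truth of "observed-like" fixtures.
OBSERVED_LIKE_PARAMS = {"Nm": 40.0, "N_anc": 31_000.0, "T_i": 59_000.0}

#: an SCD-like step-change truth for unstructured bottleneck studies: a
#: ~4-fold expansion (resize ~ 0.27) detected around 90,000 generations ago,
#: the pattern the scatter sample shows under the one-change model.
CHG1_SCD_LIKE_PARAMS = {"N_mod": 30_000.0, "N_anc": 8_000.0, "T_c": 90_000.0}


def observed_like_draw(deme_size: float = 3000.0) -> ParameterDraw:
    return ParameterDraw("FIM", dict(OBSERVED_LIKE_PARAMS), {"N_deme": deme_size})


def gamma_length_prior(mean: float = 600.0, shape: float = 20.0):
    """Per-locus length distribution: gamma with ~600 bp mean.

    A stand-in for the study's unpublished empirical length distribution;
    shape 20 gives a ~22% coefficient of variation.
    """
    class _Gamma:
        distribution = "gamma"
        params = (mean, shape)

        def sample(self, rng: np.random.Generator, size=None):
            return rng.gamma(shape, mean / shape, size)

    return _Gamma()


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic dataset.

    ``planted`` maps filter name ('depth', 'triallelic', 'heterozygosity',
    'missing') to the number of sites to corrupt; the corrupted subsets
    are disjoint by construction.
    """

    scheme: str = "SCD"
    n_loci: int = 995
    locus_length: float = 600.0
    draw: ParameterDraw | None = None
    planted: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def resolved_draw(self) -> ParameterDraw:
        return self.draw if self.draw is not None else observed_like_draw()


def plant_violations(
    records: list[SiteRecord], planted: dict[str, int], rng: np.random.Generator
) -> list[SiteRecord]:
    total = sum(planted.values())
    if total > len(records):
        raise ValueError(
            f"cannot plant {total} violations on {len(records)} sites; simulate more loci"
        )
    unknown = set(planted) - {"depth", "triallelic", "heterozygosity", "missing"}
    if unknown:
        raise ValueError(f"unknown violation kinds {sorted(unknown)}")
    chosen = rng.choice(len(records), size=total, replace=False)
    cursor = 0
    for kind in ("depth", "triallelic", "heterozygosity", "missing"):
        for idx in chosen[cursor : cursor + planted.get(kind, 0)]:
            rec = records[idx]
            genotypes = rec.genotypes.copy()
            depths = rec.depths.copy() if rec.depths is not None else None
            alts = rec.alts
            if kind == "depth":
                depths[int(rng.integers(rec.n_samples))] = 3
            elif kind == "triallelic":
                alts = ("T", "G")
                genotypes[int(rng.integers(rec.n_samples))] = (0, 2)
            elif kind == "heterozygosity":
                n_het = int(np.floor(0.8 * rec.n_samples)) + 1
                het_idx = rng.choice(rec.n_samples, size=n_het, replace=False)
                genotypes[het_idx] = (0, 1)
            elif kind == "missing":
                genotypes[int(rng.integers(rec.n_samples))] = (-1, -1)
            records[idx] = SiteRecord(rec.chrom, rec.pos, rec.ref, alts, genotypes, depths)
        cursor += planted.get(kind, 0)
    return records


def make_fixture(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Simulate a dataset, write VCF + loci table + manifest, return the manifest.

    The manifest records the generating truth (model, parameters, seed) and
    the planted violation counts, so tests can verify that the pipeline
    recovers exactly what was planted.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    draw = spec.resolved_draw()
    schedule = build_schedule(draw)
    scheme = SamplingScheme.by_name(spec.scheme)
    panel = draw_locus_panel(spec.n_loci, spec.locus_length, seed=rng)
    dataset = simulate_dataset(schedule, panel, scheme, rng)
    records = dataset_to_records(dataset)
    n_clean = len(records)
    records = plant_violations(records, spec.planted, rng)
    names = [f"{spec.scheme}_{i:02d}" for i in range(scheme.n_individuals)]
    contigs = list(zip(dataset.locus_ids, (int(v) for v in dataset.lengths)))
    vcf_path = outdir / f"{spec.scheme.lower()}_fixture.vcf"
    loci_path = outdir / f"{spec.scheme.lower()}_loci.tsv"
    write_vcf_records(records, contigs, vcf_path, names)
    write_loci_table(zip(dataset.locus_ids, dataset.lengths), loci_path)
    manifest = {
        "synthetic": True,
        "model": draw.model,
        "parameters": draw.values,
        "nuisance": draw.nuisance,
        "scheme": spec.scheme,
        "n_loci": spec.n_loci,
        "total_bp": dataset.total_bp,
        "seed": spec.seed,
        "n_sites": len(records),
        "planted": {k: int(v) for k, v in spec.planted.items()},
        "n_sites_clean": n_clean - sum(spec.planted.values()),
        "vcf": vcf_path.name,
        "loci_table": loci_path.name,
    }
    (outdir / f"{spec.scheme.lower()}_manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n"
    )
    return manifest


def make_observed_like(
    seed: int = 0,
    n_loci_scd: int = 995,
    n_loci_sid: int = 998,
    mu_hyperprior=None,
) -> tuple[SummaryVector, SummaryVector]:
    """Summary vectors (SID, SCD) of datasets generated at the fitted optimum.

    One dataset per sampling scheme under the finite island model at the
    study's point estimates; an end-to-end "observed-like" target for
    demos and calibration runs.
    """
    rng = np.random.default_rng(seed)
    draw = observed_like_draw()
    schedule = build_schedule(draw)
    panel_sid = draw_locus_panel(n_loci_sid, 600.0, mu_hyperprior=mu_hyperprior, seed=rng)
    panel_scd = draw_locus_panel(n_loci_scd, 600.0, mu_hyperprior=mu_hyperprior, seed=rng)
    ds_sid = simulate_dataset(schedule, panel_sid, SamplingScheme.sid(), rng)
    ds_scd = simulate_dataset(schedule, panel_scd, SamplingScheme.scd(), rng)
    return folded_sfs(ds_sid), folded_sfs(ds_scd)
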