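"""Small reporting helpers for dataset and estimate summaries."""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .models import DEFAULT_GENERATION_TIME_YEARS
from .simulate import SnpDataset
from .sumstats import summarize_dataset

__all__ = ["dataset_summary_row", "average_point_estimate", "generations_to_years"]


def dataset_summary_row(dataset: SnpDataset) -> dict:
    """One summary row per dataset: samples, regions, bp, SNPs, density/kb."""
    sv, density = summarize_dataset(dataset)
    return {
        "dataset": dataset.scheme,
        "n_samples": dataset.n_individuals,
        "n_regions": dataset.n_loci,
        "bp_sequenced": int(dataset.total_bp),
        "n_snps": sv.s,
        "snp_density_kb": density,
    }


def average_point_estimate(values: Iterable[float]) -> float:
    """Average of per-dataset point estimates (e.g. the T_i modes of the
    single-deme and scatter fits, whose mean is the reported onset time)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no estimates given")
    return float(arr.mean())


def generations_to_years(
    generations: float, generation_time: float = DEFAULT_GENERATION_TIME_YEARS
) -> float:
    return generations * generation_time
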