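"""Validation and power studies on pseudo-observed datasets (pods).

Reference tables are built by simulating from each model's joint prior;
pods are datasets simulated with known (fixed or prior-drawn) parameters
and re-analysed exactly like real data.  Three studies are provided:

* cross-validation of parameter estimation (bias of the posterior mode and
  median, relative to truth) and of model choice (confusion matrix);
* posterior predictive checks on the number of segregating sites
  (Bayesian p-values);
* the bottleneck-detectability grid: pods under the island model with a
  recent reduction in connectivity (FIM_BOTT; 100x and 1000x at 10..1000
  generations ago) and under the matched unstructured model (CHG1_BOTT),
  re-analysed with the CHG2 skyline and with the island-model Nm
  estimation, against no-bottleneck baselines.

Everything runs at a reduced desk scale by default (see docs/methods.md);
the full-scale study sizes are reachable through the same knobs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .inference import (
    PosteriorSample,
    ReferenceTable,
    loclinear_adjust,
    model_choice,
    posterior_summary,
    reject,
)
from .models import ModelSpec, ParameterDraw, build_schedule, draw_parameters, get_model
from .simulate import SamplingScheme, draw_locus_panel, simulate_sfs_counts
from .skyline import TimeGrid, skyline_curve
from .sumstats import SummaryVector

__all__ = [
    "BOTTLENECK_GRID",
    "PodsConfig",
    "CrossValReport",
    "build_reference_table",
    "simulate_pod",
    "run_pods",
    "crossval_estimation",
    "crossval_modelchoice",
    "posterior_predictive",
    "power_cell",
    "bottleneck_power",
    "power_grid_times",
]

#: the twelve bottleneck combinations: {100x, 1000x} intensity at six times
BOTTLENECK_GRID: tuple[tuple[float, float], ...] = tuple(
    (i_bott, t_bott) for i_bott in (100.0, 1000.0) for t_bott in (10.0, 50.0, 100.0, 200.0, 500.0, 1000.0)
)

SUMMARY_KIND = "proportions"


def _stat_names(n_ind: int) -> list[str]:
    return [f"sfs_{i}" for i in range(1, n_ind + 1)] + ["S"]


def build_reference_table(
    spec: ModelSpec | str,
    scheme: SamplingScheme | str,
    n_sims: int,
    n_loci: int,
    seed: int | np.random.Generator | None = None,
    locus_length: float = 600.0,
    mu_hyperprior=None,
    summary_kind: str = SUMMARY_KIND,
) -> ReferenceTable:
    """Simulate ``n_sims`` prior draws and summarise each into a table row.

    A fresh locus panel (per-locus mutation rates from the hyperprior) is
    drawn for every simulation, so rate heterogeneity is integrated over.
    """
    spec = get_model(spec) if isinstance(spec, str) else spec
    scheme = SamplingScheme.by_name(scheme) if isinstance(scheme, str) else scheme
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = draw_parameters(spec, n_sims, rng)
    rows = np.empty((n_sims, scheme.n_individuals + 1))
    records = []
    for i, draw in enumerate(draws):
        panel = draw_locus_panel(
            n_loci, locus_length, mu_hyperprior=mu_hyperprior, seed=rng
        )
        schedule = build_schedule(draw)
        counts = simulate_sfs_counts(schedule, panel, scheme, rng)
        rows[i] = SummaryVector(counts).vector(summary_kind)
        records.append({**draw.values, **draw.nuisance})
    params = pd.DataFrame(records)
    table = ReferenceTable(
        spec.name,
        params,
        rows,
        _stat_names(scheme.n_individuals),
        provenance={
            "scheme": scheme.name,
            "n_loci": n_loci,
            "locus_length": locus_length,
            "summary_kind": summary_kind,
        },
    )
    return table


@dataclass(frozen=True)
class PodsConfig:
    """A batch of pseudo-observed datasets with known generating truth."""

    model: str
    scheme: str
    n_pods: int
    params: dict | None = None  # fixed values; unspecified ones come from the prior
    i_bott: float | None = None
    t_bott: float | None = None
    n_loci: int = 120
    locus_length: float = 600.0
    seed: int = 0

    def model_spec(self) -> ModelSpec:
        spec = get_model(self.model)
        fixed = dict(self.params or {})
        if self.i_bott is not None:
            fixed["I_bott"] = self.i_bott
        if self.t_bott is not None:
            fixed["T_bott"] = self.t_bott
        return spec.fixed_at(**fixed) if fixed else spec


def simulate_pod(
    draw: ParameterDraw,
    scheme: SamplingScheme,
    n_loci: int,
    rng: np.random.Generator,
    locus_length: float = 600.0,
    mu_hyperprior=None,
) -> SummaryVector:
    panel = draw_locus_panel(n_loci, locus_length, mu_hyperprior=mu_hyperprior, seed=rng)
    return SummaryVector(
        simulate_sfs_counts(build_schedule(draw), panel, scheme, rng)
    )


def _estimate(
    table: ReferenceTable,
    observed: np.ndarray,
    k_retain: int,
    priors: dict | None,
) -> PosteriorSample:
    sample = reject(table, observed, k_retain)
    return loclinear_adjust(sample, observed, priors)


def run_pods(
    config: PodsConfig,
    tables: dict[str, ReferenceTable],
    k_retain: int = 500,
    grid: TimeGrid | None = None,
    outdir: str | Path | None = None,
) -> list[dict]:
    """Simulate and re-analyse each pod; return per-pod posterior artifacts.

    ``tables`` maps an analysis model name (e.g. "FIM", "CHG2") to its
    reference table for the pod's sampling scheme.  For FIM-style tables
    the per-pod record carries the Nm posterior summary; for step-change
    tables it carries the skyline on ``grid``.
    """
    scheme = SamplingScheme.by_name(config.scheme)
    spec = config.model_spec()
    rng = np.random.default_rng(config.seed)
    results = []
    for p in range(config.n_pods):
        draw = draw_parameters(spec, 1, rng)[0]
        sv = simulate_pod(draw, scheme, config.n_loci, rng, config.locus_length)
        observed = sv.vector(SUMMARY_KIND)
        record: dict = {"truth": dict(draw.values), "S": sv.s, "pod": p}
        for name, table in tables.items():
            priors = get_model(table.model).priors
            sample = _estimate(table, observed, k_retain, priors)
            if table.model.startswith("FIM"):
                summ = posterior_summary(sample, include_resize=False)
                record[f"{name}_Nm_median"] = float(summ.loc["Nm", "median"])
                record[f"{name}_Nm_mode"] = float(summ.loc["Nm", "mode"])
                record[f"{name}_Nm_q025"] = float(summ.loc["Nm", "q025"])
                record[f"{name}_Nm_q975"] = float(summ.loc["Nm", "q975"])
            else:
                if grid is None:
                    raise ValueError("skyline analyses need a TimeGrid")
                curve = skyline_curve(sample, grid)
                record[f"{name}_skyline"] = curve.table
                record[f"{name}_ne0"] = float(curve.table["median"].iloc[0])
        results.append(record)
    if outdir is not None:
        _write_manifest(Path(outdir), config, k_retain, results)
    return results


def _write_manifest(outdir: Path, config: PodsConfig, k_retain: int, results: list[dict]) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    scalars = [
        {k: v for k, v in r.items() if not isinstance(r[k], (pd.DataFrame, dict))}
        for r in results
    ]
    pd.DataFrame(scalars).to_csv(outdir / "pods.tsv", sep="\t", index=False)
    manifest = {"config": asdict(config), "k_retain": k_retain, "n_pods": len(results)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


@dataclass
class CrossValReport:
    """Per-parameter relative bias of mode and median over pods."""

    model: str
    bias: pd.DataFrame  # index: parameter; columns: bias_mode, bias_median
    n_pods: int


def crossval_estimation(
    spec: ModelSpec | str,
    scheme: SamplingScheme | str,
    table: ReferenceTable,
    n_pods: int,
    k_retain: int = 500,
    n_loci: int = 120,
    seed: int = 0,
    estimator=None,
) -> CrossValReport:
    """Bias of the posterior mode/median: median over pods of (est-truth)/truth.

    Pods are drawn from the model's prior and pushed through the same
    inferential procedure as observed data.  ``estimator`` can override
    the procedure (pod summary vector, truth -> {param: (mode, median)});
    the default is rejection + local linear regression on ``table``.
    """
    spec = get_model(spec) if isinstance(spec, str) else spec
    scheme = SamplingScheme.by_name(scheme) if isinstance(scheme, str) else scheme
    rng = np.random.default_rng(seed)
    draws = draw_parameters(spec, n_pods, rng)
    names = list(spec.parameter_names)
    rel_mode = {p: [] for p in names}
    rel_median = {p: [] for p in names}
    for draw in draws:
        sv = simulate_pod(draw, scheme, n_loci, rng)
        observed = sv.vector(SUMMARY_KIND)
        if estimator is not None:
            est = estimator(observed, draw)
        else:
            sample = _estimate(table, observed, k_retain, spec.priors)
            summ = posterior_summary(sample, include_resize=False)
            est = {p: (float(summ.loc[p, "mode"]), float(summ.loc[p, "median"])) for p in names}
        for p in names:
            mode, median = est[p]
            rel_mode[p].append((mode - draw.values[p]) / draw.values[p])
            rel_median[p].append((median - draw.values[p]) / draw.values[p])
    bias = pd.DataFrame(
        {
            "bias_mode": {p: float(np.median(rel_mode[p])) for p in names},
            "bias_median": {p: float(np.median(rel_median[p])) for p in names},
        }
    )
    return CrossValReport(spec.name, bias, n_pods)


def crossval_modelchoice(
    specs: dict[str, ModelSpec],
    scheme: SamplingScheme | str,
    tables: dict[str, ReferenceTable],
    n_pods_per_model: int,
    k_total: int = 2000,
    n_loci: int = 120,
    seed: int = 0,
) -> pd.DataFrame:
    """Confusion matrix of argmax model choice over prior-drawn pods.

    Rows are the generating model, columns the chosen model; each row sums
    to ``n_pods_per_model``.
    """
    scheme = SamplingScheme.by_name(scheme) if isinstance(scheme, str) else scheme
    rng = np.random.default_rng(seed)
    names = list(specs)
    confusion = pd.DataFrame(0, index=names, columns=names)
    for true_model, spec in specs.items():
        for draw in draw_parameters(spec, n_pods_per_model, rng):
            sv = simulate_pod(draw, scheme, n_loci, rng)
            probs = model_choice(tables, sv.vector(SUMMARY_KIND), k_total)
            chosen = max(probs, key=probs.get)
            confusion.loc[true_model, chosen] += 1
    return confusion


def posterior_predictive(
    sample: PosteriorSample,
    observed_s: int,
    scheme: SamplingScheme | str,
    n_loci: int,
    n_reps: int = 200,
    locus_length: float = 600.0,
    seed: int = 0,
) -> float:
    """Bayesian p-value for the number of segregating sites.

    Draw parameters from the (weighted) posterior, re-simulate S, and
    report the two-sided min-tail-doubled fraction of replicates at least
    as extreme as the observation.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a stable p-value")
    if sample.n == 0:
        raise ValueError("empty posterior sample")
    scheme = SamplingScheme.by_name(scheme) if isinstance(scheme, str) else scheme
    rng = np.random.default_rng(seed)
    idx = rng.choice(sample.n, size=n_reps, replace=True, p=sample.weights)
    reps = np.empty(n_reps)
    cols = sample.params.columns
    for r, i in enumerate(idx):
        row = sample.params.iloc[int(i)]
        values = {k: float(row[k]) for k in cols if k != "N_deme"}
        nuisance = {"N_deme": float(row["N_deme"])} if "N_deme" in cols else {}
        draw = ParameterDraw(sample.model, values, nuisance)
        reps[r] = simulate_pod(draw, scheme, n_loci, rng, locus_length).s
    p_hi = (1 + np.sum(reps >= observed_s)) / (n_reps + 1)
    p_lo = (1 + np.sum(reps <= observed_s)) / (n_reps + 1)
    return float(min(1.0, 2 * min(p_hi, p_lo)))


def power_grid_times(oldest: float = 100_000.0) -> TimeGrid:
    """Fixed comparison grid for the power study (no random points)."""
    times = np.array(
        [0, 25, 50, 100, 200, 300, 400, 500, 1000, 2000, 5000, 10_000, 20_000, 50_000, oldest]
    , dtype=float)
    return TimeGrid(times, bound=float(oldest), rate=3.0 / oldest)


def power_cell(
    config: PodsConfig,
    tables: dict[str, ReferenceTable],
    k_retain: int = 500,
    grid: TimeGrid | None = None,
) -> dict:
    """Run one grid cell: per-pod Nm medians and skyline Ne(0) medians."""
    grid = grid or power_grid_times()
    results = run_pods(config, tables, k_retain=k_retain, grid=grid)
    out: dict = {"config": config}
    if any(t.startswith("FIM") for t in (tb.model for tb in tables.values())):
        key = next(n for n, tb in tables.items() if tb.model.startswith("FIM"))
        out["nm_medians"] = np.array([r[f"{key}_Nm_median"] for r in results])
    sky_keys = [n for n, tb in tables.items() if not tb.model.startswith("FIM")]
    if sky_keys:
        key = sky_keys[0]
        out["ne0"] = np.array([r[f"{key}_ne0"] for r in results])
        curves = np.stack([r[f"{key}_skyline"]["median"].to_numpy() for r in results])
        out["skyline_avg"] = pd.DataFrame(
            {"time": grid.times, "mean_median_ne": curves.mean(axis=0)}
        )
    return out


def bottleneck_power(
    cells: list[dict],
    baselines: dict[str, dict],
) -> pd.DataFrame:
    """Compare bottleneck cells against matched no-bottleneck baselines.

    ``cells`` and ``baselines`` are outputs of :func:`power_cell`;
    baselines are keyed by sampling scheme (or scheme+model).  Each row
    reports, per cell: the shift in per-pod Nm medians and/or recent Ne
    relative to baseline, a one-sided Mann-Whitney p-value for a
    reduction, and the skyline detection flag (median recent Ne of the
    cell below the 2.5% quantile of the baseline's per-pod recent Ne).
    """
    rows = []
    for cell in cells:
        cfg: PodsConfig = cell["config"]
        base = baselines.get(cfg.scheme) or baselines.get(f"{cfg.scheme}:{cfg.model}")
        if base is None:
            raise ValueError(f"missing baseline for scheme {cfg.scheme}")
        row: dict = {
            "model": cfg.model,
            "scheme": cfg.scheme,
            "i_bott": cfg.i_bott,
            "t_bott": cfg.t_bott,
            "n_pods": cfg.n_pods,
        }
        if "nm_medians" in cell and "nm_medians" in base:
            x, b = cell["nm_medians"], base["nm_medians"]
            row["nm_median"] = float(np.median(x))
            row["nm_median_baseline"] = float(np.median(b))
            row["nm_delta"] = row["nm_median"] - row["nm_median_baseline"]
            row["nm_pvalue_less"] = float(mannwhitneyu(x, b, alternative="less").pvalue)
        if "ne0" in cell and "ne0" in base:
            x, b = cell["ne0"], base["ne0"]
            row["ne0_median"] = float(np.median(x))
            row["ne0_median_baseline"] = float(np.median(b))
            row["ne0_pvalue_less"] = float(mannwhitneyu(x, b, alternative="less").pvalue)
            row["detected"] = bool(np.median(x) < np.quantile(b, 0.025))
        rows.append(row)
    return pd.DataFrame(rows)
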