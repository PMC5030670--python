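"""ABC-skyline reconstruction of effective size through time.

Every retained posterior draw of a step-change model defines a step
function Ne(t); evaluating all draws on a common time grid and taking
weighted pointwise medians and 95% intervals gives the skyline.  The
grid mixes fixed recent points (0, 25, 50, 100, 200, 300, 400, 500
generations ago, for resolution towards the present) with random draws
from a truncated exponential whose upper bound is the 97.5% quantile of
the mean TMRCA across loci, so the reconstruction never extends beyond
the timescale the data inform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorSample, weighted_quantile
from .models import ParameterDraw
from .simulate import LocusPanel, SamplingScheme, mean_tmrca

__all__ = [
    "FIXED_RECENT_POINTS",
    "TimeGrid",
    "SkylineCurve",
    "make_timegrid",
    "ne_at_time",
    "skyline_curve",
    "tmrca_bound",
]

FIXED_RECENT_POINTS = (0.0, 25.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0)


@dataclass(frozen=True)
class TimeGrid:
    """Sorted evaluation times (generations ago) with provenance."""

    times: np.ndarray
    bound: float
    rate: float
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if (np.diff(t) < 0).any():
            raise ValueError("grid times must be sorted ascending")
        if t.max(initial=0.0) > self.bound:
            raise ValueError("grid extends beyond the TMRCA bound")


@dataclass(frozen=True)
class SkylineCurve:
    """Pointwise weighted median Ne and 95% interval."""

    table: pd.DataFrame  # columns: time, median, lo, hi

    def __post_init__(self) -> None:
        t = self.table
        if not ((t["lo"] <= t["median"]) & (t["median"] <= t["hi"])).all():
            raise ValueError("interval bounds must bracket the median")

    @property
    def times(self) -> np.ndarray:
        return self.table["time"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def make_timegrid(
    tmrca_bound: float,
    n_random: int = 50,
    rate: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> TimeGrid:
    """Fixed recent points + truncated-exponential random points up to the bound.

    The exponential rate defaults to 3 / bound, concentrating points
    towards the present; draws are from the exponential truncated at the
    bound.  Fixed points beyond the bound are dropped (with a warning) so
    the grid never exceeds the calibration.
    """
    if tmrca_bound <= 0:
        raise ValueError("tmrca_bound must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = rate if rate is not None else 3.0 / tmrca_bound
    # inverse-CDF sampling of Exp(rate) truncated to [0, bound]
    u = rng.random(n_random)
    cap = 1.0 - np.exp(-rate * tmrca_bound)
    draws = -np.log1p(-u * cap) / rate
    fixed = np.array([t for t in FIXED_RECENT_POINTS if t <= tmrca_bound])
    if len(fixed) < len(FIXED_RECENT_POINTS):
        warnings.warn(
            "TMRCA bound below 500 generations truncates the fixed recent points",
            RuntimeWarning,
        )
    times = np.unique(np.concatenate([fixed, draws]))
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return TimeGrid(times, float(tmrca_bound), float(rate), seed_val)


def ne_at_time(draw: ParameterDraw, t: float) -> float:
    """Effective size of a step-change model at time t generations ago."""
    if t < 0:
        raise ValueError("t must be >= 0")
    v = draw.values
    if draw.model == "COS":
        return v["N"]
    if draw.model == "CHG1":
        return v["N_mod"] if t < v["T_c"] else v["N_anc"]
    if draw.model == "CHG1_BOTT":
        if t < v["T_bott"] and v["I_bott"] > 1:
            return v["N_mod"] / v["I_bott"]
        return v["N_mod"] if t < v["T_c"] else v["N_anc"]
    if draw.model == "CHG2":
        if t < v["T_c2"]:
            return v["N_mod"]
        return v["N_int"] if t < v["T_c1"] else v["N_anc"]
    raise ValueError(
        f"model {draw.model} has no single-population size trajectory; "
        "the skyline is defined for COS/CHG1/CHG2-style models"
    )


def _ne_matrix(sample: PosteriorSample, times: np.ndarray) -> np.ndarray:
    p = sample.params
    nt = len(times)
    if sample.model == "COS":
        return np.tile(p["N"].to_numpy()[:, None], (1, nt))
    if sample.model in ("CHG1", "CHG1_BOTT"):
        n_mod = p["N_mod"].to_numpy()[:, None]
        n_anc = p["N_anc"].to_numpy()[:, None]
        t_c = p["T_c"].to_numpy()[:, None]
        ne = np.where(times[None, :] < t_c, n_mod, n_anc)
        if sample.model == "CHG1_BOTT":
            ib = p["I_bott"].to_numpy()[:, None]
            tb = p["T_bott"].to_numpy()[:, None]
            ne = np.where((times[None, :] < tb) & (ib > 1), n_mod / ib, ne)
        return ne
    if sample.model == "CHG2":
        n_mod = p["N_mod"].to_numpy()[:, None]
        n_int = p["N_int"].to_numpy()[:, None]
        n_anc = p["N_anc"].to_numpy()[:, None]
        t1 = p["T_c1"].to_numpy()[:, None]
        t2 = p["T_c2"].to_numpy()[:, None]
        return np.where(
            times[None, :] < t2, n_mod, np.where(times[None, :] < t1, n_int, n_anc)
        )
    raise ValueError(f"model {sample.model} has no size trajectory")


def _hpd(values: np.ndarray, weights: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    order = np.argsort(values)
    v, w = values[order], np.asarray(weights)[order] / np.sum(weights)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    n = len(v)
    best = (v[0], v[-1])
    width = np.inf
    j = 0
    for i in range(n):
        j = max(j, i)
        while j < n and cw[j + 1] - cw[i] < mass:
            j += 1
        if j == n:
            break
        if v[j] - v[i] < width:
            width = v[j] - v[i]
            best = (v[i], v[j])
    return float(best[0]), float(best[1])


def skyline_curve(
    sample: PosteriorSample, grid: TimeGrid, interval: str = "quantile"
) -> SkylineCurve:
    """Weighted pointwise median Ne with 95% interval along the grid.

    ``interval`` is ``"quantile"`` (equal-tailed 2.5/97.5%) or ``"hpd"``
    (highest posterior density).
    """
    if sample.n == 0:
        raise ValueError("empty posterior sample")
    if sample.n < 100:
        warnings.warn(
            f"only {sample.n} retained draws; skyline quantiles may be unstable",
            RuntimeWarning,
        )
    ne = _ne_matrix(sample, grid.times)
    rows = []
    for j, t in enumerate(grid.times):
        col = ne[:, j]
        med = weighted_quantile(col, sample.weights, 0.5)[0]
        if interval == "hpd":
            lo, hi = _hpd(col, sample.weights)
        elif interval == "quantile":
            lo, hi = weighted_quantile(col, sample.weights, [0.025, 0.975])
        else:
            raise ValueError(f"unknown interval kind {interval!r}")
        rows.append((t, med, lo, hi))
    return SkylineCurve(pd.DataFrame(rows, columns=["time", "median", "lo", "hi"]))


def tmrca_bound(
    sample: PosteriorSample,
    scheme: SamplingScheme,
    n_loci: int = 10,
    n_draws: int = 200,
    seed: int | np.random.Generator | None = None,
) -> float:
    """97.5% quantile of the mean TMRCA across loci over posterior draws.

    Re-simulates genealogies (mutation-free) under a subsample of the
    retained draws; this calibrates how far back the skyline may extend.
    """
    from .models import build_schedule

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(sample.n, size=min(n_draws, sample.n), replace=False, p=None)
    panel = LocusPanel(np.full(n_loci, 600.0), np.zeros(n_loci), np.zeros(n_loci))
    vals = []
    for i in idx:
        row = sample.params.iloc[int(i)]
        draw = ParameterDraw(sample.model, {k: float(row[k]) for k in sample.params.columns})
        sched = build_schedule(draw)
        vals.append(mean_tmrca(sched, panel, scheme, 1, rng)[0])
    return float(np.quantile(vals, 0.975))
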