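"""ABC engine: rejection, regression adjustment, model choice, summaries.

Rejection retains the k reference simulations closest to the observed
summary vector in Euclidean distance after per-statistic robust
standardisation (median/MAD across the reference table).  Parameter
posteriors are sharpened with the local linear regression adjustment of
Beaumont et al.: each parameter (log-transformed when strictly positive)
is regressed on the summary deviations with Epanechnikov kernel weights,
and the fitted relationship is used to project every retained draw to the
observed point.  Model posterior probabilities come from a weighted
multinomial logistic regression of the model label on the summaries over
the pooled closest simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .models import PriorSpec

__all__ = [
    "ReferenceTable",
    "PosteriorSample",
    "reject",
    "loclinear_adjust",
    "model_choice",
    "posterior_summary",
    "weighted_quantile",
]


@dataclass
class ReferenceTable:
    """Rows of (model label, parameter draw, summary vector)."""

    model: str
    params: pd.DataFrame
    stats: np.ndarray
    stat_names: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if len(self.params) != len(self.stats):
            raise ValueError("params and stats must have the same number of rows")
        if len(self.params) < 1:
            raise ValueError("reference table needs at least one row")
        if not self.stat_names:
            self.stat_names = [f"stat_{j}" for j in range(self.stats.shape[1])]

    @property
    def n(self) -> int:
        return len(self.params)

    def to_tsv(self, path: str | Path) -> None:
        df = self.params.copy()
        df.insert(0, "model", self.model)
        for j, name in enumerate(self.stat_names):
            df[name] = self.stats[:, j]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, n_params: int | None = None) -> "ReferenceTable":
        df = pd.read_csv(path, sep="\t")
        model = str(df.pop("model").iloc[0])
        if n_params is None:
            # statistics columns are the trailing sfs_*/S block written by to_tsv
            stat_cols = [c for c in df.columns if c.startswith("sfs_") or c == "S"]
        else:
            stat_cols = list(df.columns[n_params:])
        params = df[[c for c in df.columns if c not in stat_cols]]
        return cls(model, params, df[stat_cols].to_numpy(), stat_cols)


@dataclass
class PosteriorSample:
    """Retained (possibly regression-adjusted) parameter draws with weights."""

    model: str
    params: pd.DataFrame
    stats: np.ndarray
    distances: np.ndarray
    weights: np.ndarray
    indices: np.ndarray
    adjusted: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("weights must not all vanish")
        self.weights = self.weights / total

    @property
    def n(self) -> int:
        return len(self.params)


def _robust_scale(stats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = np.median(stats, axis=0)
    scale = np.median(np.abs(stats - center), axis=0)
    sd = stats.std(axis=0)
    scale = np.where(scale > 0, scale, np.where(sd > 0, sd, 1.0))
    return center, scale


def _distances(stats: np.ndarray, observed: np.ndarray) -> np.ndarray:
    center, scale = _robust_scale(stats)
    z = (stats - center) / scale
    z_obs = (np.asarray(observed, dtype=float) - center) / scale
    return np.sqrt(((z - z_obs) ** 2).sum(axis=1))


def _epanechnikov(d: np.ndarray) -> np.ndarray:
    delta = d.max()
    if delta == 0:
        return np.ones_like(d)
    return 1.0 - (d / delta) ** 2


def reject(table: ReferenceTable, observed: np.ndarray, k: int) -> PosteriorSample:
    """Retain the k rows closest to the observed summaries.

    Distances are Euclidean on per-statistic standardized summaries
    (median/MAD over the table), so the result is invariant to affine
    rescaling of any statistic.  Ties are broken by row order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > table.n:
        raise ValueError(f"k={k} exceeds table size {table.n}")
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (table.stats.shape[1],):
        raise ValueError(
            f"observed vector length {observed.shape} does not match table "
            f"({table.stats.shape[1]} statistics)"
        )
    d = _distances(table.stats, observed)
    order = np.argsort(d, kind="stable")[:k]
    dk = d[order]
    # Epanechnikov weights over the retained distances; at delta the weight
    # vanishes, so give the boundary rows the smallest positive weight instead
    w = _epanechnikov(dk)
    w = np.where(w > 0, w, np.min(w[w > 0]) if (w > 0).any() else 1.0)
    return PosteriorSample(
        table.model,
        table.params.iloc[order].reset_index(drop=True),
        table.stats[order],
        dk,
        w,
        order,
    )


def _transforms(params: pd.DataFrame, priors: dict[str, PriorSpec] | None):
    """Log-transform strictly positive parameters (sizes, times, Nm)."""
    use_log = {}
    for col in params.columns:
        lo = priors[col].support[0] if priors and col in priors else None
        positive = (params[col] > 0).all() if lo is None else lo > 0
        use_log[col] = bool(positive)
    return use_log


def loclinear_adjust(
    sample: PosteriorSample,
    observed: np.ndarray,
    priors: dict[str, PriorSpec] | None = None,
) -> PosteriorSample:
    """Beaumont-style local linear regression adjustment.

    Each parameter is regressed on the summary deviations (s_i - s_obs)
    with the sample's kernel weights; the adjusted draw is the fitted
    value at the observed summaries plus the residual.  Strictly positive
    parameters are adjusted on the log scale and the result is mapped back
    inside the prior support.
    """
    observed = np.asarray(observed, dtype=float)
    n, p = sample.stats.shape
    if n < p + 2:
        raise ValueError(f"need at least p+2={p + 2} retained points, got {n}")
    center, scale = _robust_scale(sample.stats)
    X = (sample.stats - observed) / scale
    keep = X.std(axis=0) > 0  # constant columns carry no local information
    X = X[:, keep]
    sw = np.sqrt(sample.weights)
    if X.shape[1]:
        # the folded-SFS proportions sum to one, so drop exactly collinear
        # columns (pivoted QR) before solving the weighted least squares
        from scipy.linalg import qr as _qr

        _, R, piv = _qr(X * sw[:, None], mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
        X = X[:, np.sort(piv[: int((diag > tol).sum())])]
    design = np.column_stack([np.ones(n), X])
    A = design * sw[:, None]
    use_log = _transforms(sample.params, priors)
    adjusted = {}
    for col in sample.params.columns:
        y = sample.params[col].to_numpy(dtype=float)
        ylog = use_log[col]
        yt = np.log(y) if ylog else y
        beta, _, rank, _ = np.linalg.lstsq(A, yt * sw, rcond=None)
        if rank < design.shape[1]:
            warnings.warn(
                f"singular local-linear design for {col!r}; returning unadjusted values",
                RuntimeWarning,
            )
            adjusted[col] = y
            continue
        fitted = design @ beta
        adj = beta[0] + (yt - fitted)  # fitted value at observed + residual
        if ylog:
            adj = np.exp(adj)
        if priors and col in priors:
            lo, hi = priors[col].support
            adj = np.clip(adj, lo, hi)
        adjusted[col] = adj
    return replace(
        sample, params=pd.DataFrame(adjusted, columns=sample.params.columns), adjusted=True
    )


def model_choice(
    tables: dict[str, ReferenceTable],
    observed: np.ndarray,
    k_total: int,
) -> dict[str, float]:
    """Posterior model probabilities by weighted multinomial logistic regression.

    All models' simulations are pooled, the ``k_total`` rows closest to the
    observed summaries are retained, and a multinomial logistic regression
    of the model label on the standardized summaries (Epanechnikov weights
    over distance) is evaluated at the observed point.
    """
    if len(tables) < 2:
        raise ValueError("model choice needs at least two models")
    names = list(tables)
    stats = np.vstack([tables[m].stats for m in names])
    labels = np.concatenate([np.full(tables[m].n, i) for i, m in enumerate(names)])
    if k_total <= 0 or k_total > len(stats):
        raise ValueError(f"k_total must be in [1, {len(stats)}]")
    observed = np.asarray(observed, dtype=float)
    center, scale = _robust_scale(stats)
    z = (stats - center) / scale
    z_obs = (observed - center) / scale
    d = np.sqrt(((z - z_obs) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:k_total]
    zk, lk, dk = z[order], labels[order], d[order]
    w = _epanechnikov(dk)
    w = np.where(w > 0, w, np.min(w[w > 0]) if (w > 0).any() else 1.0)
    present = np.unique(lk)
    probs = dict.fromkeys(names, 0.0)
    missing = [names[i] for i in range(len(names)) if i not in present]
    if missing:
        warnings.warn(
            f"models absent from the retained set get probability 0: {missing}",
            RuntimeWarning,
        )
    if len(present) == 1:
        probs[names[int(present[0])]] = 1.0
        return probs
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(max_iter=2000, C=1e6)
    clf.fit(zk, lk, sample_weight=w)
    p = clf.predict_proba(z_obs[None, :])[0]
    for cls, pi in zip(clf.classes_, p):
        probs[names[int(cls)]] = float(pi)
    total = sum(probs.values())
    return {m: v / total for m, v in probs.items()}


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q) -> np.ndarray:
    """Weighted quantiles with midpoint interpolation.

    With uniform weights on {1..100} this gives median 50.5 and 2.5%/97.5%
    quantiles 3 and 98, matching the unweighted convention.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    pos = weights > 0
    values, weights = values[pos], weights[pos]
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    p = (cw - 0.5 * w) / cw[-1]
    return np.interp(np.atleast_1d(q), p, v)


def _kde_mode(values: np.ndarray, weights: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        return float(values[0])
    from scipy.stats import gaussian_kde

    try:
        kde = gaussian_kde(values, bw_method="silverman", weights=weights)
    except np.linalg.LinAlgError:
        return float(weighted_quantile(values, weights, 0.5)[0])
    grid = np.linspace(values.min(), values.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def posterior_summary(
    sample: PosteriorSample, include_resize: bool | None = None
) -> pd.DataFrame:
    """Weighted median, KDE mode and 95% equal-tailed interval per parameter.

    Adds the ancestral/modern size ratio (``resize``) for the step-change
    models where both sizes are present.
    """
    if sample.n == 0:
        raise ValueError("empty posterior sample")
    cols = dict(sample.params.items())
    if include_resize is None:
        include_resize = sample.model in ("CHG1", "CHG1_BOTT")
    if include_resize:
        if not {"N_anc", "N_mod"} <= set(sample.params.columns):
            raise ValueError("resize needs both N_anc and N_mod")
        cols["resize"] = sample.params["N_anc"] / sample.params["N_mod"]
    rows = {}
    for name, series in cols.items():
        v = np.asarray(series, dtype=float)
        med, lo, hi = weighted_quantile(v, sample.weights, [0.5, 0.025, 0.975])
        rows[name] = {
            "median": med,
            "mode": _kde_mode(v, sample.weights),
            "q025": lo,
            "q975": hi,
        }
    return pd.DataFrame(rows).T[["median", "mode", "q025", "q975"]]
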