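"""Demographic models and their priors.

Six models are registered:

``COS``
    Constant-size panmictic population, one parameter ``N``.
``CHG1``
    One instantaneous size change at ``T_c`` generations ago, from ancestral
    ``N_anc`` to modern ``N_mod``.  The ratio ``resize = N_anc / N_mod``
    summarises the direction of the change (< 1 expansion, > 1 contraction).
``CHG2``
    Two size changes at ``T_c1 > T_c2``, sizes ``N_anc``, ``N_int``, ``N_mod``.
``FIM``
    Non-equilibrium finite island model: ``n_demes`` demes of size ``N_deme``
    exchanging migrants symmetrically so that the composite parameter
    ``Nm = N_deme * m`` controls the genealogy shape; the island was founded
    at ``T_i`` generations ago from a single ancestral deme of size ``N_anc``.
``FIM_BOTT``
    FIM with a recent instantaneous reduction in connectivity at ``T_bott``
    of intensity ``I_bott`` (fold reduction of ``Nm``); reduces to FIM when
    ``I_bott == 1``.
``CHG1_BOTT``
    CHG1 with a recent instantaneous ``I_bott``-fold reduction of the modern
    effective size at ``T_bott``; reduces to CHG1 when ``I_bott == 1``.

Times are in generations, backwards from the present; sizes are diploid
effective sizes.  Conversion to years (generation time 7 y for the blacktip
reef shark) happens only when reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PriorSpec",
    "ModelSpec",
    "ParameterDraw",
    "Event",
    "EventSchedule",
    "MODEL_NAMES",
    "get_model",
    "draw_parameters",
    "build_schedule",
]

MODEL_NAMES = ("COS", "CHG1", "CHG2", "FIM", "FIM_BOTT", "CHG1_BOTT")

#: number of demes used for all island models; large enough that the
#: scattering/collecting decomposition of the genealogy applies.
N_DEMES_ISLAND = 100

DEFAULT_GENERATION_TIME_YEARS = 7.0


@dataclass(frozen=True)
class PriorSpec:
    """A univariate prior in natural units.

    ``distribution`` is one of ``uniform``, ``loguniform``, ``lognormal``
    or ``fixed``.  ``params`` holds ``(low, high)`` for the interval
    families, ``(median, sigma_log)`` for ``lognormal`` and ``(value,)``
    for ``fixed``.
    """

    name: str
    distribution: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.distribution not in ("uniform", "loguniform", "lognormal", "fixed"):
            raise ValueError(f"unknown prior family {self.distribution!r}")
        if self.distribution == "fixed":
            if len(self.params) != 1:
                raise ValueError("fixed prior takes exactly one value")
        elif len(self.params) != 2:
            raise ValueError(f"{self.distribution} prior takes two parameters")
        if self.distribution in ("uniform", "loguniform"):
            lo, hi = self.params
            if not lo < hi:
                raise ValueError(f"prior {self.name}: need lower < upper, got {self.params}")
            if self.distribution == "loguniform" and lo <= 0:
                raise ValueError(f"prior {self.name}: loguniform needs positive support")
        if self.distribution == "lognormal":
            med, sig = self.params
            if med <= 0 or sig < 0:
                raise ValueError(f"prior {self.name}: invalid lognormal parameters")

    @property
    def support(self) -> tuple[float, float]:
        if self.distribution == "fixed":
            v = self.params[0]
            return (v, v)
        if self.distribution == "lognormal":
            return (0.0, math.inf)
        return (self.params[0], self.params[1])

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        if self.distribution == "uniform":
            return rng.uniform(self.params[0], self.params[1], size)
        if self.distribution == "loguniform":
            lo, hi = np.log(self.params[0]), np.log(self.params[1])
            return np.exp(rng.uniform(lo, hi, size))
        if self.distribution == "lognormal":
            med, sig = self.params
            return np.exp(rng.normal(np.log(med), sig, size))
        # fixed
        v = self.params[0]
        return v if size is None else np.full(size, v, dtype=float)


# parameter sets are exact per model; validation relies on this mapping
_MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "COS": ("N",),
    "CHG1": ("N_mod", "N_anc", "T_c"),
    "CHG2": ("N_mod", "N_int", "N_anc", "T_c1", "T_c2"),
    "FIM": ("Nm", "N_anc", "T_i"),
    "FIM_BOTT": ("Nm", "N_anc", "T_i", "I_bott", "T_bott"),
    "CHG1_BOTT": ("N_mod", "N_anc", "T_c", "I_bott", "T_bott"),
}


@dataclass(frozen=True)
class ModelSpec:
    """A demographic model plus named priors for each of its parameters."""

    name: str
    priors: dict[str, PriorSpec]
    n_demes: int = 1
    generation_time_years: float = DEFAULT_GENERATION_TIME_YEARS
    #: nuisance hyperprior for the per-deme size of island models; the
    #: composite Nm is the inferential quantity, m = Nm / N_deme.
    deme_size_prior: PriorSpec | None = None

    def __post_init__(self) -> None:
        if self.name not in _MODEL_PARAMS:
            raise ValueError(f"unknown model {self.name!r}")
        expected = set(_MODEL_PARAMS[self.name])
        got = set(self.priors)
        if got != expected:
            raise ValueError(
                f"model {self.name} requires parameters {sorted(expected)}, got {sorted(got)}"
            )
        if self.name.startswith("FIM") and self.deme_size_prior is None:
            object.__setattr__(
                self, "deme_size_prior", PriorSpec("N_deme", "loguniform", (100.0, 10_000.0))
            )

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return _MODEL_PARAMS[self.name]

    @property
    def is_island(self) -> bool:
        return self.n_demes > 1

    def with_priors(self, **overrides: PriorSpec | tuple) -> "ModelSpec":
        """Return a copy with some priors replaced.

        A bare tuple is interpreted as uniform bounds for convenience.
        """
        new = dict(self.priors)
        for key, value in overrides.items():
            if not isinstance(value, PriorSpec):
                value = PriorSpec(key, "uniform", tuple(float(v) for v in value))
            new[key] = value
        return replace(self, priors=new)

    def fixed_at(self, **values: float) -> "ModelSpec":
        """Return a copy with the given parameters pinned to fixed values."""
        new = dict(self.priors)
        for key, value in values.items():
            if key not in new:
                raise ValueError(f"model {self.name} has no parameter {key!r}")
            new[key] = PriorSpec(key, "fixed", (float(value),))
        return replace(self, priors=new)


def _u(name: str, lo: float, hi: float) -> PriorSpec:
    return PriorSpec(name, "uniform", (lo, hi))


def get_model(name: str) -> ModelSpec:
    """Return the registered model with its default priors.

    FIM priors follow the study design (Nm ~ U(0.05, 250),
    N_anc ~ U(100, 100000), T_i ~ U(100, 200000)); size/time priors of the
    unstructured models are package defaults on the same scales.
    """
    name = name.upper().replace("-", "_")
    if name == "COS":
        return ModelSpec("COS", {"N": _u("N", 100, 100_000)})
    if name == "CHG1":
        return ModelSpec(
            "CHG1",
            {
                "N_mod": _u("N_mod", 100, 100_000),
                "N_anc": _u("N_anc", 100, 100_000),
                "T_c": _u("T_c", 100, 200_000),
            },
        )
    if name == "CHG2":
        return ModelSpec(
            "CHG2",
            {
                "N_mod": _u("N_mod", 100, 100_000),
                "N_int": _u("N_int", 100, 100_000),
                "N_anc": _u("N_anc", 100, 100_000),
                "T_c1": _u("T_c1", 100, 200_000),
                "T_c2": _u("T_c2", 100, 200_000),
            },
        )
    if name == "FIM":
        return ModelSpec(
            "FIM",
            {
                "Nm": _u("Nm", 0.05, 250),
                "N_anc": _u("N_anc", 100, 100_000),
                "T_i": _u("T_i", 100, 200_000),
            },
            n_demes=N_DEMES_ISLAND,
        )
    if name == "FIM_BOTT":
        return ModelSpec(
            "FIM_BOTT",
            {
                "Nm": _u("Nm", 0.05, 250),
                "N_anc": _u("N_anc", 100, 100_000),
                "T_i": _u("T_i", 100, 200_000),
                "I_bott": PriorSpec("I_bott", "loguniform", (1.0, 1000.0)),
                "T_bott": _u("T_bott", 10, 1000),
            },
            n_demes=N_DEMES_ISLAND,
        )
    if name == "CHG1_BOTT":
        return ModelSpec(
            "CHG1_BOTT",
            {
                "N_mod": _u("N_mod", 100, 100_000),
                "N_anc": _u("N_anc", 100, 100_000),
                "T_c": _u("T_c", 100, 200_000),
                "I_bott": PriorSpec("I_bott", "loguniform", (1.0, 1000.0)),
                "T_bott": _u("T_bott", 10, 1000),
            },
        )
    raise ValueError(f"unknown model {name!r}")


@dataclass(frozen=True)
class ParameterDraw:
    """One draw from a model's joint prior (plus recorded nuisances)."""

    model: str
    values: dict[str, float]
    nuisance: dict[str, float] = field(default_factory=dict)

    @property
    def resize(self) -> float:
        """Ancestral/modern size ratio; defined for CHG1 and CHG1_BOTT only."""
        if self.model not in ("CHG1", "CHG1_BOTT"):
            raise ValueError(f"resize is not defined for model {self.model}")
        return self.values["N_anc"] / self.values["N_mod"]

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def draw_parameters(
    spec: ModelSpec, n: int, seed: int | np.random.Generator | None = None
) -> list[ParameterDraw]:
    """Draw ``n`` parameter vectors from the model's joint prior.

    Ordering constraints (CHG2: T_c1 > T_c2; *_BOTT: event older than the
    bottleneck where required) are enforced by rejection sampling, which
    preserves the marginal supports.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    names = spec.parameter_names
    cols = {p: np.asarray(spec.priors[p].sample(rng, n), dtype=float) for p in names}

    def _resample_where(bad: np.ndarray, pair: tuple[str, str], cond) -> None:
        # redraw only the offending rows until the constraint holds
        while bad.any():
            idx = np.flatnonzero(bad)
            for p in pair:
                cols[p][idx] = np.asarray(spec.priors[p].sample(rng, idx.size), dtype=float)
            bad = np.zeros(n, dtype=bool)
            bad[idx] = cond(idx)

    if spec.name == "CHG2":
        cond = lambda idx: ~(cols["T_c1"][idx] > cols["T_c2"][idx])
        _resample_where(cond(np.arange(n)) | np.zeros(n, bool), ("T_c1", "T_c2"), cond)
    if spec.name == "FIM_BOTT":
        cond = lambda idx: ~(cols["T_i"][idx] > cols["T_bott"][idx])
        _resample_where(cond(np.arange(n)) | np.zeros(n, bool), ("T_i", "T_bott"), cond)
    if spec.name == "CHG1_BOTT":
        cond = lambda idx: ~(cols["T_c"][idx] > cols["T_bott"][idx])
        _resample_where(cond(np.arange(n)) | np.zeros(n, bool), ("T_c", "T_bott"), cond)

    nuis = None
    if spec.is_island and spec.deme_size_prior is not None:
        nuis = np.asarray(spec.deme_size_prior.sample(rng, n), dtype=float)

    draws = []
    for i in range(n):
        values = {p: float(cols[p][i]) for p in names}
        nuisance = {"N_deme": float(nuis[i])} if nuis is not None else {}
        draws.append(ParameterDraw(spec.name, values, nuisance))
    return draws


# ---------------------------------------------------------------------------
# event schedules


@dataclass(frozen=True)
class Event:
    """A single backward-in-time demographic event.

    kinds: ``set_size`` (new per-deme or population size), ``merge_demes``
    (collect all lineages into one ancestral deme of ``size``), ``scale``
    (multiply deme size and/or migration rate by factors).
    """

    time: float
    kind: str
    size: float | None = None
    size_factor: float | None = None
    mig_factor: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("set_size", "merge_demes", "scale"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.time < 0:
            raise ValueError("event times must be non-negative")


@dataclass(frozen=True)
class EventSchedule:
    """A time-ordered schedule the simulator consumes.

    ``initial_size`` is the per-deme (island) or population (unstructured)
    diploid size on ``[0, first event)``; ``migration_rate`` the backwards
    per-lineage per-generation migration rate (0 when unstructured).
    """

    n_demes: int
    initial_size: float
    migration_rate: float
    events: tuple[Event, ...] = ()

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing backward in time")
        if self.initial_size <= 0:
            raise ValueError("initial size must be positive")
        if self.migration_rate < 0:
            raise ValueError("migration rate must be non-negative")
        merges = [e for e in self.events if e.kind == "merge_demes"]
        if self.n_demes > 1 and (not merges or merges[-1] is not self.events[-1]):
            raise ValueError("island schedules must end by merging into the ancestral deme")

    @property
    def is_island(self) -> bool:
        return self.n_demes > 1

    def epochs(self) -> list[tuple[float, float, float, float, int]]:
        """Piecewise-constant view: (t0, t1, size, migration rate, n_demes)."""
        out = []
        t0, size, mig, nd = 0.0, self.initial_size, self.migration_rate, self.n_demes
        for ev in self.events:
            if ev.time > t0:
                out.append((t0, ev.time, size, mig, nd))
                t0 = ev.time
            if ev.kind == "set_size":
                size = float(ev.size)
            elif ev.kind == "scale":
                if ev.size_factor is not None:
                    size *= ev.size_factor
                if ev.mig_factor is not None:
                    mig *= ev.mig_factor
            elif ev.kind == "merge_demes":
                size, mig, nd = float(ev.size), 0.0, 1
        out.append((t0, math.inf, size, mig, nd))
        return out

    def size_at(self, t: float) -> float:
        """Per-deme (or population) size at time ``t`` generations ago."""
        for t0, t1, size, _mig, _nd in self.epochs():
            if t0 <= t < t1:
                return size
        return self.epochs()[-1][2]

    def simplify(self) -> "EventSchedule":
        """Drop events that change nothing (e.g. a size change to the same size)."""
        kept = []
        size = self.initial_size
        for ev in self.events:
            if ev.kind == "set_size" and ev.size == size:
                continue
            if ev.kind == "scale" and (ev.size_factor in (None, 1.0)) and (
                ev.mig_factor in (None, 1.0)
            ):
                continue
            if ev.kind == "set_size":
                size = float(ev.size)
            elif ev.kind == "scale" and ev.size_factor is not None:
                size *= ev.size_factor
            kept.append(ev)
        return EventSchedule(self.n_demes, self.initial_size, self.migration_rate, tuple(kept))


def build_schedule(
    draw: ParameterDraw,
    *,
    deme_size: float | None = None,
    n_demes: int = N_DEMES_ISLAND,
    bottleneck_mode: str = "migration",
) -> EventSchedule:
    """Convert a parameter draw into a simulator-ready event schedule.

    For island models the per-deme size ``N_deme`` (a recorded nuisance of
    the draw, or given explicitly) defines the migration rate m = Nm/N_deme.
    ``bottleneck_mode`` selects how an Nm reduction is realised for
    FIM_BOTT: a reduction of the migration rate (default), of deme size,
    or of both (each by sqrt(I_bott)).  The migration interpretation is
    the default because a deme-size reduction lets scatter samples detect
    the bottleneck instantly through within-individual pair coalescence,
    the opposite of the resilience a metapopulation actually shows.
    """
    v = draw.values
    model = draw.model
    if model in ("FIM_BOTT", "CHG1_BOTT"):
        if v["I_bott"] < 1:
            raise ValueError(
                "I_bott < 1 is not a bottleneck; I_bott = 1 reduces exactly to the "
                "un-bottlenecked model"
            )
    if model == "COS":
        return EventSchedule(1, v["N"], 0.0)
    if model == "CHG1":
        return EventSchedule(1, v["N_mod"], 0.0, (Event(v["T_c"], "set_size", size=v["N_anc"]),))
    if model == "CHG1_BOTT":
        events = []
        if v["I_bott"] > 1:
            initial = v["N_mod"] / v["I_bott"]
            events.append(Event(v["T_bott"], "set_size", size=v["N_mod"]))
        else:
            initial = v["N_mod"]
        if not v["T_c"] > v["T_bott"]:
            raise ValueError("CHG1_BOTT requires T_c > T_bott")
        events.append(Event(v["T_c"], "set_size", size=v["N_anc"]))
        return EventSchedule(1, initial, 0.0, tuple(events))
    if model == "CHG2":
        if not v["T_c1"] > v["T_c2"] >= 0:
            raise ValueError("CHG2 requires T_c1 > T_c2 >= 0")
        return EventSchedule(
            1,
            v["N_mod"],
            0.0,
            (
                Event(v["T_c2"], "set_size", size=v["N_int"]),
                Event(v["T_c1"], "set_size", size=v["N_anc"]),
            ),
        )
    if model in ("FIM", "FIM_BOTT"):
        nd = float(deme_size if deme_size is not None else draw.nuisance.get("N_deme", 0.0))
        if nd <= 0:
            raise ValueError("island schedules need a positive deme size (N_deme)")
        m = v["Nm"] / nd
        events: list[Event] = []
        initial, mig = nd, m
        if model == "FIM_BOTT" and v["I_bott"] > 1:
            if not v["T_i"] > v["T_bott"]:
                raise ValueError("FIM_BOTT requires T_i > T_bott")
            ib = v["I_bott"]
            if bottleneck_mode == "deme_size":
                initial = nd / ib
                events.append(Event(v["T_bott"], "set_size", size=nd))
            elif bottleneck_mode == "migration":
                # scale events multiply backward in time: start reduced, restore at T_bott
                mig = m / ib
                events.append(Event(v["T_bott"], "scale", mig_factor=ib))
            elif bottleneck_mode == "both":
                root = math.sqrt(ib)
                initial, mig = nd / root, m / root
                events.append(Event(v["T_bott"], "scale", size_factor=root, mig_factor=root))
            else:
                raise ValueError(f"unknown bottleneck_mode {bottleneck_mode!r}")
        events.append(Event(v["T_i"], "merge_demes", size=v["N_anc"]))
        return EventSchedule(n_demes, initial, mig, tuple(events))
    raise ValueError(f"unknown model {model!r}")
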