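"""The six demographic models and their priors.

Two biogeographic scenarios for a three-population system (North, South,
West), each with three alternative models:

Scenario 1 (riverine barrier; deep divergence, no growth)
    1. simple vicariance: North and West both split from South at T1;
    2. North/South split at T1, West founded from South at T2 < T1;
    3. North/South split at T1, West founded from North at T2 < T1.

Scenario 2 (glacial refugia; every event inside the last 21 kyr,
post-glacial exponential growth in every population)
    4. single refugium (South); North and West both founded from South;
    5. two refugia (North and South); West founded from South;
    6. two refugia (North and South); West founded from North.

Founder events in scenario 1 leave the colonist population at its
founder size N_f; in scenario 2 founded populations grow exponentially
from N_f at founding to their present size (backward rate
ln(Ne/N_f)/T, floored at zero), while persistent populations grow at a
rate drawn from the prior.  All times are uniform a priori: the main
divergence T1 spans the Plio-Pleistocene window (0.12-5.33 Myr) in
scenario 1 and sits inside (0, 21 kyr] in scenario 2; the western
colonization T2 is a recent (LGM-to-present) founding in both
scenarios, and T2 < T1 is enforced by rejection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NORTH",
    "SOUTH",
    "WEST",
    "GROUPS",
    "PopulationSpec",
    "DemographicEvent",
    "ModelSpec",
    "PriorSet",
    "ParameterDraw",
    "build_model_catalog",
    "draw_parameters",
    "restrict_priors",
]

NORTH, SOUTH, WEST = "North", "South", "West"
GROUPS = (NORTH, SOUTH, WEST)

#: Last Glacial Maximum, years before present; upper bound of every
#: scenario-2 event time.
LGM_YEARS = 21_000.0


@dataclass(frozen=True)
class PopulationSpec:
    """Present-day state of one population.

    ``alpha`` is the per-generation exponential growth rate; backward in
    time the size declines as N(t) = Ne * exp(-alpha * t).
    """

    name: str
    ne: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise ValueError(f"{self.name}: Ne must be positive")
        if self.alpha < 0:
            raise ValueError(f"{self.name}: growth rate must be >= 0")


@dataclass(frozen=True)
class DemographicEvent:
    """One backward-time event: a join, size change, or growth change."""

    time: float  # years before present
    kind: str    # "join" | "size_change" | "growth_change"
    pop: str     # affected population (join: the source, removed)
    sink: str | None = None      # join target
    size: float | None = None    # size_change payload (diploid individuals)
    alpha: float | None = None   # growth_change payload (per generation)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("event times must be positive")
        if self.kind not in ("join", "size_change", "growth_change"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    """One demographic model: identity, scenario and structural choices."""

    model_id: int
    scenario: int
    name: str
    founder_source: str | None  # who founds West (None: simple vicariance)
    north_founded: bool = False  # scenario-2 model 4: North also founded

    @property
    def has_t2(self) -> bool:
        return self.founder_source is not None

    def concrete(
        self, draw: "ParameterDraw"
    ) -> tuple[tuple[PopulationSpec, ...], tuple[DemographicEvent, ...]]:
        """Populations and time-ordered events for one parameter draw.

        Ties at the final divergence (model 1's simultaneous split) keep
        a deterministic order: the West join is applied before the North
        join, then the ancestral size change.
        """
        v = draw.values
        g = v["gen_time"]
        growth = self.scenario == 2

        def implied_alpha(ne: float, nf: float, t_years: float) -> float:
            # backward rate taking a founded population from Ne today to
            # N_f at founding; floored at 0 if the draw has N_f >= Ne
            gens = t_years / g
            return max(math.log(ne / nf) / gens, 0.0) if nf < ne else 0.0

        pops: list[PopulationSpec] = []
        events: list[DemographicEvent] = []
        t1, t2 = v["t1"], v.get("t2", math.nan)

        # --- South: always persistent, ancestral side
        pops.append(
            PopulationSpec(SOUTH, v["ne_south"], v["alpha_south"] if growth else 0.0)
        )
        # --- North
        if self.north_founded:  # model 4
            a_n = implied_alpha(v["ne_north"], v["nf_north"], t1)
            pops.append(PopulationSpec(NORTH, v["ne_north"], a_n))
        else:
            pops.append(
                PopulationSpec(
                    NORTH, v["ne_north"], v["alpha_north"] if growth else 0.0
                )
            )
        # --- West
        if self.founder_source is None:  # model 1
            pops.append(PopulationSpec(WEST, v["ne_west"], 0.0))
            events.append(DemographicEvent(t1, "join", WEST, sink=SOUTH))
        elif not growth:  # models 2-3: constant at founder size
            pops.append(PopulationSpec(WEST, v["nf_west"], 0.0))
            events.append(
                DemographicEvent(t2, "join", WEST, sink=self.founder_source)
            )
        else:  # models 4-6: founder bottleneck plus growth to present
            a_w = implied_alpha(v["ne_west"], v["nf_west"], t2)
            pops.append(PopulationSpec(WEST, v["ne_west"], a_w))
            events.append(
                DemographicEvent(t2, "join", WEST, sink=self.founder_source)
            )

        # --- final North/South divergence and the ancestral population
        events.append(DemographicEvent(t1, "join", NORTH, sink=SOUTH))
        events.append(
            DemographicEvent(t1, "size_change", SOUTH, size=v["ne_anc"])
        )
        if growth:
            events.append(
                DemographicEvent(t1, "growth_change", SOUTH, alpha=0.0)
            )
        events.sort(key=lambda e: e.time)  # stable: tie order preserved
        return tuple(pops), tuple(events)

    def satisfies(self, values: dict[str, float]) -> bool:
        """Ordering constraints for a candidate draw (T2 < T1)."""
        if self.has_t2:
            return values["t2"] < values["t1"]
        return True


@dataclass(frozen=True)
class PriorSet:
    """Uniform prior windows for every model parameter.

    ``mu`` maps locus name to a (low, high) window of per-site,
    per-generation mutation rates.  Founder sizes are conditionally
    uniform on (nf_min, nf_frac * Ne_source).  Times are years before
    present.
    """

    ne: tuple[float, float] = (1e4, 1e6)
    mu: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            # mitochondrial windows: calibration rates +/- 20%
            "16S": (2.24e-9, 3.36e-9),
            "ND2": (7.656e-9, 1.1484e-8),
            # nuclear rates: broad window around typical nuclear rates
            "SiaH": (1e-9, 5e-9),
            "Rhod": (1e-9, 5e-9),
        }
    )
    t1_scenario1: tuple[float, float] = (0.12e6, 5.33e6)
    t2_scenario1: tuple[float, float] = (0.0, LGM_YEARS)
    t1_scenario2: tuple[float, float] = (0.0, LGM_YEARS)
    t2_scenario2: tuple[float, float] = (0.0, LGM_YEARS)
    alpha: tuple[float, float] = (0.0, 1e-3)
    nf_min: float = 10.0
    nf_frac: float = 0.5
    gen_time: float = 1.0

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.intervals().items():
            if not lo < hi:
                raise ValueError(f"prior {name}: need lower < upper")
        if not 0 < self.nf_frac <= 1:
            raise ValueError("nf_frac must be in (0, 1]")

    def intervals(self) -> dict[str, tuple[float, float]]:
        out = {
            "ne": self.ne,
            "t1_scenario1": self.t1_scenario1,
            "t2_scenario1": self.t2_scenario1,
            "t1_scenario2": self.t1_scenario2,
            "t2_scenario2": self.t2_scenario2,
            "alpha": self.alpha,
        }
        for locus, w in self.mu.items():
            out[f"mu_{locus}"] = w
        return out

    def t_windows(self, scenario: int) -> tuple[tuple, tuple]:
        if scenario == 1:
            return self.t1_scenario1, self.t2_scenario1
        return self.t1_scenario2, self.t2_scenario2


@dataclass(frozen=True)
class ParameterDraw:
    """One realized parameter set for one model."""

    model_id: int
    values: dict[str, float]
    seed: int | None = None

    def theta(self, locus: str, length: int, inheritance_scale: float) -> float:
        """Per-locus mutation intensity 4*Ne_ref*c*mu*L.

        With c = 1 this is the standard nuclear theta 4*Ne*mu*L; with
        c = 0.25 (mitochondrial) it reduces to Ne*mu*L.
        """
        ne_ref = self.values["ne_south"]
        return 4.0 * ne_ref * inheritance_scale * self.values[f"mu_{locus}"] * length


_CATALOG_DEF = (
    (1, 1, "S1 simple vicariance", None, False),
    (2, 1, "S1 West founded from South", SOUTH, False),
    (3, 1, "S1 West founded from North", NORTH, False),
    (4, 2, "S2 single refugium (South)", SOUTH, True),
    (5, 2, "S2 two refugia, West from South", SOUTH, False),
    (6, 2, "S2 two refugia, West from North", NORTH, False),
)


def build_model_catalog(priors: PriorSet | None = None) -> tuple[ModelSpec, ...]:
    """The six-model catalog: scenarios (1,1,1,2,2,2)."""
    if priors is not None and not isinstance(priors, PriorSet):
        raise ValueError("priors must be a PriorSet")
    return tuple(
        ModelSpec(mid, scen, name, src, nf)
        for mid, scen, name, src, nf in _CATALOG_DEF
    )


_MAX_REJECTIONS = 10**6


def draw_parameters(
    model: ModelSpec,
    priors: PriorSet,
    rng: np.random.Generator | int | None = None,
) -> ParameterDraw:
    """Draw one parameter set from the priors, rejecting constraint
    violations (T2 < T1) by redrawing the whole set."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    t1w, t2w = priors.t_windows(model.scenario)

    for attempt in range(_MAX_REJECTIONS):
        u = rng.uniform
        v: dict[str, float] = {
            "ne_north": u(*priors.ne),
            "ne_south": u(*priors.ne),
            "ne_west": u(*priors.ne),
            "ne_anc": u(*priors.ne),
            "t1": u(*t1w),
            "t2": u(*t2w),
            "alpha_north": u(*priors.alpha),
            "alpha_south": u(*priors.alpha),
            "gen_time": priors.gen_time,
        }
        for locus, w in priors.mu.items():
            v[f"mu_{locus}"] = u(*w)
        # conditional founder-size priors
        src = model.founder_source or SOUTH
        v["nf_west"] = u(priors.nf_min, priors.nf_frac * v[f"ne_{src.lower()}"])
        v["nf_north"] = u(priors.nf_min, priors.nf_frac * v["ne_south"])
        if model.satisfies(v):
            return ParameterDraw(model.model_id, v)
    raise RuntimeError(
        f"model {model.model_id}: {_MAX_REJECTIONS} consecutive "
        "constraint rejections; check prior configuration"
    )


def restrict_priors(
    priors: PriorSet,
    retained,
    quantiles: tuple[float, float] = (0.025, 0.975),
    scenario: int = 1,
) -> PriorSet:
    """Narrow each prior window to the quantile range of retained draws.

    ``retained`` is a non-empty sequence of :class:`ParameterDraw` or a
    DataFrame of their values.  New windows are clipped to the original
    ones; parameters absent from the retained draws keep their priors.
    """
    import pandas as pd

    if retained is None or len(retained) == 0:
        raise ValueError("retained draw set is empty")
    if not isinstance(retained, pd.DataFrame):
        retained = pd.DataFrame([d.values for d in retained])
    lo_q, hi_q = quantiles

    def shrink(window: tuple[float, float], col: str) -> tuple[float, float]:
        if col not in retained.columns:
            return window
        lo = max(float(retained[col].quantile(lo_q)), window[0])
        hi = min(float(retained[col].quantile(hi_q)), window[1])
        if not lo < hi:  # degenerate: keep the original window
            return window
        return (lo, hi)

    ne_cols = [c for c in ("ne_north", "ne_south", "ne_west", "ne_anc")
               if c in retained.columns]
    if ne_cols:
        pooled = retained[ne_cols].to_numpy().ravel()
        ne = (
            max(float(np.quantile(pooled, lo_q)), priors.ne[0]),
            min(float(np.quantile(pooled, hi_q)), priors.ne[1]),
        )
        if not ne[0] < ne[1]:
            ne = priors.ne
    else:
        ne = priors.ne

    mu = {
        locus: shrink(w, f"mu_{locus}") for locus, w in priors.mu.items()
    }
    kwargs = dict(ne=ne, mu=mu, alpha=shrink(priors.alpha, "alpha_south"))
    if scenario == 1:
        kwargs["t1_scenario1"] = shrink(priors.t1_scenario1, "t1")
        kwargs["t2_scenario1"] = shrink(priors.t2_scenario1, "t2")
    else:
        kwargs["t1_scenario2"] = shrink(priors.t1_scenario2, "t1")
        kwargs["t2_scenario2"] = shrink(priors.t2_scenario2, "t2")
    return replace(priors, **kwargs)
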