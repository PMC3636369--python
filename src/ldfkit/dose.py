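"""Exposure pathways, annual dose and Landscape Dose conversion Factors.

Inventories from the transport solution are converted to concentrations in
environmental media (water, soil/sediment, air), then to concentrations in
foods via concentration ratios, and finally to the annual effective dose of
a representative individual of the most exposed group — a person who spends
all time on one biosphere object and draws all food and water from it,
subject to the object's production capacity.  The LDF of a nuclide is the
maximum of this dose over all objects and times within a climate period for
a constant unit release (Sv a-1 per Bq a-1); the pulse variant normalises
by a unit pulse (Sv a-1 per Bq).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .landscape import LandscapeGraph, LandscapeSystem, stage_weights
from .nuclides import ElementProperties, NuclideLibrary, ValidationError
from .object_model import ATM, TRU, WAT, CompartmentGeometry
from .series import TimeSeries
from .solver import ReleaseScenario, SystemSolution, integrate

log = logging.getLogger(__name__)

#: Food types, the medium each derives from, and the succession stages in
#: which each can actually be produced on the object.
FOOD_MEDIUM = {"crops": "soil", "game": "soil", "fish": "water"}
FOOD_STAGES = {
    "crops": ("agricultural",),
    "game": ("wetland",),
    "fish": ("sea", "lake"),
}
#: Edible fraction of primary production harvestable as each food type
#: (kg C food per kg C net primary production).
EDIBLE_FRACTION = {"crops": 0.5, "game": 0.02, "fish": 0.1}

PATHWAYS = ("ingestion_water", "ingestion_food", "inhalation", "external")


class ExposureHabits(BaseModel):
    """Intake and occupancy assumptions for the representative individual."""

    water_intake: float = Field(default=0.6, ge=0.0, description="m3 a-1")
    carbon_intake: float = Field(default=110.0, ge=0.0, description="kg C a-1")
    diet_fractions: dict[str, float] = Field(
        default_factory=lambda: {"crops": 0.6, "game": 0.1, "fish": 0.3}
    )
    breathing_rate: float = Field(default=8100.0, ge=0.0, description="m3 a-1")
    occupancy: float = Field(default=1.0, ge=0.0, le=1.0)
    water_occupancy: float = Field(default=0.02, ge=0.0, le=1.0)
    dust_load: float = Field(default=5e-8, ge=0.0, description="kg m-3")

    @model_validator(mode="after")
    def _check(self) -> "ExposureHabits":
        total = sum(self.diet_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"diet fractions sum to {total}, expected 1")
        unknown = set(self.diet_fractions) - set(FOOD_MEDIUM)
        if unknown:
            raise ValueError(f"unknown food types {sorted(unknown)}")
        return self


def media_concentrations(
    inventories: np.ndarray, geometry: list[CompartmentGeometry]
) -> dict[str, float]:
    """Concentrations in water (Bq m-3), soil (Bq kg-1 dw) and air (Bq m-3).

    ``inventories`` is the length-10 compartment vector of one object for
    one nuclide at one time.
    """

    def conc(inv: float, denom: float, what: str) -> float:
        if inv <= 0.0:
            return 0.0
        if denom <= 0.0:
            raise ValidationError(f"nonzero inventory in zero-size {what} compartment")
        return inv / denom

    return {
        "water": conc(inventories[WAT], geometry[WAT].water_volume, "WATER"),
        "soil": conc(inventories[TRU], geometry[TRU].solid_mass, "TER_REGOLITH_UP"),
        "air": conc(inventories[ATM], geometry[ATM].water_volume, "ATMOSPHERE"),
    }


def food_concentrations(
    media: dict[str, float],
    element: ElementProperties,
    weights: dict[str, float],
    foods: tuple[str, ...] = ("crops", "game", "fish"),
) -> dict[str, tuple[float, float]]:
    """Per-food (concentration Bq (kg C)-1, availability weight) pairs.

    The concentration uses the food's CR against its source medium; the
    availability weight is the summed stage weight of the stages in which
    the food exists on the object (a food absent in the current stage
    contributes no intake).
    """
    out: dict[str, tuple[float, float]] = {}
    for food in foods:
        cr = element.cr_for(food)
        conc = media[FOOD_MEDIUM[food]] * cr
        avail = sum(weights[stage] for stage in FOOD_STAGES[food])
        out[food] = (conc, avail)
    return out


def _effective_diet(
    habits: ExposureHabits,
    foods: dict[str, tuple[float, float]],
    supplies: Optional[dict[str, float]] = None,
) -> dict[str, float]:
    """Diet fractions renormalised to the foods available in this stage,
    capped by the object's production-derived supply."""
    raw = {f: habits.diet_fractions.get(f, 0.0) * foods[f][1] for f in foods}
    total = sum(raw.values())
    if total <= 0.0:
        return {f: 0.0 for f in foods}
    eff = {f: v / total for f, v in raw.items()}
    if supplies is None or habits.carbon_intake <= 0.0:
        return eff
    caps = {f: supplies.get(f, np.inf) / habits.carbon_intake for f in eff}
    capped: set[str] = set()
    for _ in range(len(eff) + 1):
        over = {f for f in eff if f not in capped and eff[f] > caps[f] + 1e-12}
        if not over:
            break
        capped |= over
        for f in over:
            eff[f] = caps[f]
        free = [f for f in eff if f not in capped and eff[f] > 0.0]
        remaining = 1.0 - sum(eff[f] for f in capped)
        free_sum = sum(eff[f] for f in free)
        if free_sum > 0.0 and remaining > 0.0:
            scale = remaining / free_sum
            for f in free:
                eff[f] *= scale
        else:
            log.warning(
                "food supply cap binds with no substitute foods; total intake reduced"
            )
            break
    return eff


def annual_dose(
    media: dict[str, float],
    foods: dict[str, tuple[float, float]],
    habits: ExposureHabits,
    dc,
    supplies: Optional[dict[str, float]] = None,
) -> dict[str, float]:
    """Pathway-resolved annual effective dose (Sv a-1) for one nuclide.

    ingestion = (water intake * C_water + carbon intake * sum f_i C_i) DC_ing,
    inhalation = breathing * occupancy * (C_air + dust * C_soil) DC_inh,
    external = occupancy * (C_soil DC_ext + water-occupancy immersion term).
    """
    eff = _effective_diet(habits, foods, supplies)
    d_water = habits.water_intake * media["water"] * dc.ingestion
    d_food = (
        habits.carbon_intake
        * sum(eff[f] * foods[f][0] for f in foods)
        * dc.ingestion
    )
    d_inh = (
        habits.breathing_rate
        * habits.occupancy
        * (media["air"] + habits.dust_load * media["soil"])
        * dc.inhalation
    )
    d_ext = habits.occupancy * (
        (1.0 - habits.water_occupancy) * media["soil"] * dc.external_soil
        + habits.water_occupancy * media["water"] * dc.external_water_immersion
    )
    return {
        "ingestion_water": d_water,
        "ingestion_food": d_food,
        "inhalation": d_inh,
        "external": d_ext,
    }


# ---------------------------------------------------------------------------
# Dose series and LDF
# ---------------------------------------------------------------------------


@dataclass
class DoseResult:
    """LDF endpoint plus the underlying dose time series."""

    nuclide: str
    mode: str  # "constant" or "pulse"
    period: str  # climate period the maximum was taken over
    ldf: float  # Sv a-1 per Bq a-1 (constant) or per Bq (pulse)
    argmax_object: str
    argmax_time: float
    doses: pd.DataFrame  # tidy: time, object, pathway, dose_Sv_per_a
    solution: SystemSolution = field(repr=False, default=None)

    @property
    def total_by_time_object(self) -> pd.DataFrame:
        return (
            self.doses.groupby(["time", "object"], sort=False)["dose_Sv_per_a"]
            .sum()
            .reset_index()
        )


def compute_dose_series(
    graph: LandscapeGraph,
    library: NuclideLibrary,
    solution: SystemSolution,
    habits: Optional[ExposureHabits] = None,
) -> pd.DataFrame:
    """Tidy per-(time, object, pathway) dose series, summed over the chain.

    The dose from daughters grown in during transport is attributed to the
    released parent.
    """
    habits = habits or ExposureHabits()
    system = solution.system
    records: list[tuple[float, str, str, float]] = []
    for it, t in enumerate(solution.times):
        for oid in system.object_ids:
            params = graph.objects[oid]
            geometry = params.geometry_at(t)
            weights = stage_weights(graph.schedules[oid], t)
            aq_area = geometry[WAT].area
            ter_area = params.area_total - aq_area
            p_ter = params.production_ter.at(t) * ter_area
            p_aq = params.production_aq.at(t) * aq_area
            supplies = {
                "crops": p_ter * EDIBLE_FRACTION["crops"],
                "game": p_ter * EDIBLE_FRACTION["game"],
                "fish": p_aq * EDIBLE_FRACTION["fish"],
            }
            totals = dict.fromkeys(PATHWAYS, 0.0)
            o = system.obj_index[oid]
            for m, spec in enumerate(system.chain):
                base = system.idx_inv(m, o, 0)
                inv = solution.states[it, base : base + len(geometry)]
                media = media_concentrations(inv, geometry)
                element = library.elements[spec.element]
                foods = food_concentrations(media, element, weights)
                doses = annual_dose(media, foods, habits, spec.dose_coefficients, supplies)
                for key, value in doses.items():
                    totals[key] += value
            for key, value in totals.items():
                records.append((t, oid, key, value))
    return pd.DataFrame(records, columns=["time", "object", "pathway", "dose_Sv_per_a"])


def _ldf_from_doses(doses: pd.DataFrame, window: tuple[float, float]) -> tuple[float, str, float]:
    totals = doses.groupby(["time", "object"], sort=False)["dose_Sv_per_a"].sum().reset_index()
    mask = (totals["time"] >= window[0] - 1e-9) & (totals["time"] <= window[1] + 1e-9)
    inside = totals[mask]
    if inside.empty:
        raise ValidationError(f"no dose samples inside period window {window}")
    best = inside.loc[inside["dose_Sv_per_a"].idxmax()]
    return float(best["dose_Sv_per_a"]), str(best["object"]), float(best["time"])


def _default_targets(graph: LandscapeGraph) -> dict[str, float]:
    """Release into the most upstream object: no incoming drainage edges,
    preferring objects that are not themselves coastal exchange basins."""
    incoming = {edge.target for edge in graph.downstream_edges}
    candidates = [oid for oid in graph.object_ids if oid not in incoming]
    partners = {ex.partner for ex in graph.sea_exchange.values()}
    upstream = [oid for oid in candidates if oid not in partners] or candidates
    if not upstream:
        raise ValidationError("no upstream object available as default release target")
    return {sorted(upstream)[0]: 1.0}


def compute_ldf(
    graph: LandscapeGraph,
    library: NuclideLibrary,
    nuclide: str,
    period: str = "temperate",
    habits: Optional[ExposureHabits] = None,
    target_objects: Optional[dict[str, float]] = None,
    release_rate: float = 1.0,
    output_step: float = 10.0,
    refresh: float = 1.0,
    periglacial_release_factor: float = 0.0,
) -> DoseResult:
    """LDF for a constant release of ``release_rate`` Bq a-1 (default unit).

    Runs the full landscape transport for the requested climate period,
    computes the dose series for every object and returns the maximum over
    objects and times, normalised per unit release rate.  ``glacial`` and
    ``periglacial`` follow the scenario conventions: glacial exposure uses
    the open-sea (submerged) stage of the temperate run, and during
    periglacial conditions the geosphere release is scaled by
    ``periglacial_release_factor`` (default fully suppressed) while doses
    come from the inventory carried over from the temperate period.
    """
    targets = target_objects or _default_targets(graph)
    primary = next(iter(targets))
    schedule = graph.schedules[primary]
    t_start, t_temp_end = schedule.period("temperate")

    if period in ("temperate", "glacial"):
        span = (t_start, t_temp_end)
        scenario = ReleaseScenario(
            mode="constant", nuclide=nuclide, target_objects=targets,
            rate=release_rate, start=t_start,
        )
    elif period == "periglacial":
        _, t_peri_end = schedule.period("periglacial")
        span = (t_start, t_peri_end)
        scenario = ReleaseScenario(
            mode="table", nuclide=nuclide, target_objects=targets,
            rate_series=TimeSeries(
                t=[t_start, t_temp_end, t_temp_end + 1.0],
                v=[release_rate, release_rate, release_rate * periglacial_release_factor],
            ),
        )
    elif period == "global_warming":
        _, t_peri_end = schedule.period("periglacial")
        span = (t_start, t_peri_end)
        scenario = ReleaseScenario(
            mode="constant", nuclide=nuclide, target_objects=targets,
            rate=release_rate, start=t_start,
        )
    else:
        raise ValidationError(f"unknown climate period {period!r}")

    system = LandscapeSystem(graph, library, nuclide)
    grid = np.arange(span[0], span[1] + output_step / 2, output_step)
    solution = integrate(system, scenario, span, output_grid=grid, refresh=refresh)
    doses = compute_dose_series(graph, library, solution, habits)

    if period == "glacial":
        sea_times = [
            t for t in solution.times
            if stage_weights(schedule, t)["sea"] >= 1.0 - 1e-12
        ]
        if not sea_times:
            raise ValidationError("no fully submerged samples for the glacial period")
        window = (min(sea_times), max(sea_times))
    elif period == "periglacial":
        window = schedule.period("periglacial")
    else:
        window = span

    peak, obj, when = _ldf_from_doses(doses, window)
    return DoseResult(
        nuclide=nuclide,
        mode="constant",
        period=period,
        ldf=peak / release_rate,
        argmax_object=obj,
        argmax_time=when,
        doses=doses,
        solution=solution,
    )


def compute_ldf_pulse(
    graph: LandscapeGraph,
    library: NuclideLibrary,
    nuclide: str,
    pulse_amount: float = 1.0,
    pulse_start: Optional[float] = None,
    pulse_duration: float = 1.0,
    habits: Optional[ExposureHabits] = None,
    target_objects: Optional[dict[str, float]] = None,
    output_step: float = 10.0,
    refresh: float = 1.0,
) -> DoseResult:
    """LDF for a unit pulse release (Sv a-1 per Bq).

    The pulse (default 1 Bq over one year) starts at ``pulse_start``
    (default: beginning of the temperate period); the maximum annual dose
    over all objects and the rest of the temperate period is normalised by
    the released amount.
    """
    targets = target_objects or _default_targets(graph)
    schedule = graph.schedules[next(iter(targets))]
    span = schedule.period("temperate")
    start = span[0] if pulse_start is None else pulse_start
    scenario = ReleaseScenario(
        mode="pulse", nuclide=nuclide, target_objects=targets,
        amount=pulse_amount, start=start, duration=pulse_duration,
    )
    system = LandscapeSystem(graph, library, nuclide)
    grid = np.arange(span[0], span[1] + output_step / 2, output_step)
    solution = integrate(system, scenario, span, output_grid=grid, refresh=refresh)
    doses = compute_dose_series(graph, library, solution, habits)
    peak, obj, when = _ldf_from_doses(doses, span)
    return DoseResult(
        nuclide=nuclide,
        mode="pulse",
        period="temperate",
        ldf=peak / pulse_amount,
        argmax_object=obj,
        argmax_time=when,
        doses=doses,
        solution=solution,
    )
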