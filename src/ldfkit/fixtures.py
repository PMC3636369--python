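"""Synthetic landscape, nuclide library and release scenarios.

Everything here is synthetic: the landscape emulates the structure of a
Baltic-coast uplift setting — a chain of biosphere objects that start as
submerged sea bays, are isolated over a ~500-year window into lakes,
infill to wetlands and may be converted to agricultural land, all draining
through an outer coastal basin to an open-sea outlet — but every parameter
value is an order-of-magnitude-plausible invention, not site data.  The
two reference nuclides are an iodine-129-like mobile, very long-lived
tracer and a radium-226-like strongly sorbing, shorter-lived one.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field

from .landscape import (
    ISOLATION_WINDOW,
    TEMPERATE_START,
    DownstreamEdge,
    LandscapeGraph,
    SeaExchange,
    SuccessionSchedule,
)
from .nuclides import (
    DoseCoefficients,
    ElementProperties,
    NuclideLibrary,
    RadionuclideSpec,
)
from .object_model import ObjectParameterSet, RegolithLayer
from .series import TimeSeries, constant

#: Specific runoff used for drainage fluxes, m a-1 (m3 m-2 a-1).
SPECIFIC_RUNOFF = 0.2
#: Vertical advective flux through the lower regolith under terrestrial
#: conditions, m a-1; suppressed by SEA_FLUX_FACTOR while submerged
#: (vertical fluxes under sea basins are minute).
UPWARD_FLUX_TERRESTRIAL = 0.03
SEA_FLUX_FACTOR = 1e-3


class FixtureSpec(BaseModel):
    """Knobs of the synthetic landscape generator."""

    n_objects: int = Field(default=3, ge=1)
    seed: int = 42
    area_range: tuple[float, float] = (1e5, 3e5)  # m2, log-uniform draw
    first_isolation_start: float = -8000.0
    isolation_stagger: float = 1500.0
    isolation_window: float = ISOLATION_WINDOW
    infill_duration: float = 1000.0  # lake -> wetland
    agricultural_delay: float | None = 2000.0  # after wetland_by; None = never
    coast_area: float = 1e7  # m2
    coast_depth: float = 10.0  # m
    sea_depth: float = 5.0  # m
    lake_depth: float = 2.0  # m


def _regolith_layers() -> dict[str, RegolithLayer]:
    return {
        "regolith_low": RegolithLayer(thickness=4.0, bulk_density=2000.0, porosity=0.25),
        "regolith_mid": RegolithLayer(thickness=1.5, bulk_density=500.0, porosity=0.7),
        "regolith_up": RegolithLayer(thickness=0.3, bulk_density=150.0, porosity=0.85),
    }


def _make_object(
    oid: str, area: float, spec: FixtureSpec, schedule: SuccessionSchedule
) -> ObjectParameterSet:
    iso0, iso1 = schedule.isolation_start, schedule.isolation_end
    grown = float(schedule.wetland_by)
    lake_area = 0.3 * area
    stream_area = max(0.005 * area, 1e3)
    q_ter = UPWARD_FLUX_TERRESTRIAL * area
    layers = _regolith_layers()
    return ObjectParameterSet(
        object_id=oid,
        area_total=area,
        aquatic_area=TimeSeries(t=[iso0, iso1, grown], v=[area, lake_area, stream_area]),
        water_depth=TimeSeries(
            t=[iso0, iso1, grown], v=[spec.sea_depth, spec.lake_depth, 0.5]
        ),
        **layers,
        upward_water_flux=TimeSeries(
            t=[iso0, iso1], v=[SEA_FLUX_FACTOR * q_ter, q_ter]
        ),
        runoff_terrestrial=TimeSeries(
            t=[iso0, iso1, grown],
            v=[
                0.0,
                SPECIFIC_RUNOFF * (area - lake_area),
                SPECIFIC_RUNOFF * (area - stream_area),
            ],
        ),
        sedimentation_flux=TimeSeries(t=[iso0, iso1], v=[0.5, 0.2]),
        resuspension_flux=TimeSeries(t=[iso0, iso1], v=[0.1, 0.02]),
        suspended_solids=TimeSeries(t=[iso0, iso1], v=[0.01, 0.005]),
        production_ter=constant(0.2),
        production_aq=constant(0.05),
        biomass_ter=constant(1.0),
        biomass_aq=constant(0.1),
    )


def _make_coast(spec: FixtureSpec) -> tuple[ObjectParameterSet, SuccessionSchedule]:
    # The outer coastal basin stays a sea basin for the whole simulated span.
    schedule = SuccessionSchedule(
        submerged_until=1e6, isolation_start=1e6, isolation_end=1e6 + spec.isolation_window
    )
    layers = _regolith_layers()
    params = ObjectParameterSet(
        object_id="coast",
        area_total=spec.coast_area,
        aquatic_area=constant(spec.coast_area),
        water_depth=constant(spec.coast_depth),
        **layers,
        upward_water_flux=constant(
            SEA_FLUX_FACTOR * UPWARD_FLUX_TERRESTRIAL * spec.coast_area
        ),
        runoff_terrestrial=constant(0.0),
        sedimentation_flux=constant(0.5),
        resuspension_flux=constant(0.1),
        suspended_solids=constant(0.01),
        production_ter=constant(0.0),
        production_aq=constant(0.05),
        biomass_ter=constant(1.0),
        biomass_aq=constant(0.1),
    )
    return params, schedule


def generate_landscape(spec: FixtureSpec) -> LandscapeGraph:
    """Chain of objects draining to a coastal basin and an open-sea outlet.

    Object isolation times are staggered downstream (land emerges from the
    sea uplift-first at the top of the drainage chain); the first object is
    optionally converted to agricultural land.  Deterministic for a given
    spec (areas drawn log-uniformly from ``spec.area_range`` with
    ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    objects: dict[str, ObjectParameterSet] = {}
    schedules: dict[str, SuccessionSchedule] = {}
    edges: list[DownstreamEdge] = []
    exchange: dict[str, SeaExchange] = {}

    lo, hi = spec.area_range
    areas = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_objects))
    cumulative_area = 0.0
    for i in range(spec.n_objects):
        oid = f"obj{i + 1}"
        iso0 = spec.first_isolation_start + i * spec.isolation_stagger
        iso1 = iso0 + spec.isolation_window
        grown = iso1 + spec.infill_duration
        agri = None
        if i == 0 and spec.agricultural_delay is not None:
            agri = grown + spec.agricultural_delay
        schedule = SuccessionSchedule(
            submerged_until=iso0,
            isolation_start=iso0,
            isolation_end=iso1,
            wetland_by=grown,
            agricultural_from=agri,
        )
        area = float(areas[i])
        objects[oid] = _make_object(oid, area, spec, schedule)
        schedules[oid] = schedule
        cumulative_area += area
        downstream = f"obj{i + 2}" if i + 1 < spec.n_objects else "coast"
        edges.append(
            DownstreamEdge(
                source=oid,
                target=downstream,
                flux=constant(SPECIFIC_RUNOFF * cumulative_area),
            )
        )
        sea_volume = area * spec.sea_depth
        exchange[oid] = SeaExchange(
            partner="coast",
            to_partner=constant(10.0 * sea_volume),
            from_partner=constant(10.0 * sea_volume),
        )

    coast_params, coast_schedule = _make_coast(spec)
    objects["coast"] = coast_params
    schedules["coast"] = coast_schedule
    coast_volume = spec.coast_area * spec.coast_depth
    edges.append(
        DownstreamEdge(source="coast", target="outlet", flux=constant(10.0 * coast_volume))
    )
    return LandscapeGraph(
        objects=objects,
        schedules=schedules,
        downstream_edges=edges,
        sea_exchange=exchange,
        outlet="outlet",
    )


# ---------------------------------------------------------------------------
# Reference nuclides (synthetic)
# ---------------------------------------------------------------------------


def reference_nuclides() -> NuclideLibrary:
    """Two-nuclide synthetic library: I-129-like mobile and Ra-226-like sorbing.

    Half-lives carry the real order of magnitude (1.57e7 a and 1600 a); all
    Kd/CR and dose-coefficient values are synthetic, order-of-magnitude
    plausible inventions for testing and demonstration.
    """
    iodine = ElementProperties(
        name="I-syn",
        kd={
            "regolith_low": 1e-3,
            "regolith_mid": 3e-3,
            "regolith_up": 1e-2,
            "water": 3e-4,
        },
        cr={
            "ter_producer": 0.05,
            "aqu_producer": 0.3,
            "crops": 0.05,
            "game": 0.1,
            "fish": 0.3,
        },
    )
    radium = ElementProperties(
        name="Ra-syn",
        kd={
            "regolith_low": 0.5,
            "regolith_mid": 2.0,
            "regolith_up": 5.0,
            "water": 5.0,
        },
        cr={
            "ter_producer": 0.1,
            "aqu_producer": 1.0,
            "crops": 0.04,
            "game": 0.05,
            "fish": 0.4,
        },
    )
    nuclides = {
        "I129syn": RadionuclideSpec(
            name="I129syn",
            half_life=1.57e7,
            element="I-syn",
            dose_coefficients=DoseCoefficients(
                ingestion=1.1e-7,
                inhalation=3.6e-8,
                external_soil=5e-10,
                external_water_immersion=1e-11,
            ),
        ),
        "Ra226syn": RadionuclideSpec(
            name="Ra226syn",
            half_life=1600.0,
            element="Ra-syn",
            dose_coefficients=DoseCoefficients(
                ingestion=2.8e-7,
                inhalation=9.5e-6,
                external_soil=1.5e-6,
                external_water_immersion=2e-10,
            ),
        ),
    }
    return NuclideLibrary(
        nuclides=nuclides, elements={"I-syn": iodine, "Ra-syn": radium}
    )


def synthetic_chain(half_lives: tuple[float, ...] = (100.0, 1000.0, 10000.0)) -> NuclideLibrary:
    """Linear synthetic decay chain A -> B -> C with inert chemistry.

    Used for analytic (Bateman) cross-checks: all Kd and CR are zero so the
    chain is chemically inert, and dose coefficients are unit-free
    placeholders.
    """
    element = ElementProperties(
        name="Syn",
        kd={k: 0.0 for k in ("regolith_low", "regolith_mid", "regolith_up", "water")},
        cr={k: 0.0 for k in ("ter_producer", "aqu_producer", "crops", "game", "fish")},
    )
    nuclides: dict[str, RadionuclideSpec] = {}
    previous = None
    for i, hl in enumerate(half_lives):
        name = f"Syn{i + 1}"
        nuclides[name] = RadionuclideSpec(
            name=name,
            half_life=hl,
            element="Syn",
            parent=previous,
            dose_coefficients=DoseCoefficients(ingestion=1e-8, inhalation=1e-8),
        )
        previous = name
    return NuclideLibrary(nuclides=nuclides, elements={"Syn": element})


def pure_decay_landscape() -> LandscapeGraph:
    """One inert, permanently submerged object with no transport at all.

    Every flux, production and exchange is zero and the atmosphere vent is
    off, so a release into the lower regolith evolves by radioactive decay
    alone — the configuration against which the Bateman solution is an
    exact oracle.
    """
    layers = _regolith_layers()
    schedule = SuccessionSchedule(
        submerged_until=1e6, isolation_start=1e6, isolation_end=1e6 + 500.0
    )
    params = ObjectParameterSet(
        object_id="obj1",
        area_total=1e5,
        aquatic_area=constant(1e5),
        water_depth=constant(5.0),
        **layers,
        upward_water_flux=constant(0.0),
        runoff_terrestrial=constant(0.0),
        diffusivity=0.0,
        sedimentation_flux=constant(0.0),
        resuspension_flux=constant(0.0),
        suspended_solids=constant(0.0),
        production_ter=constant(0.0),
        production_aq=constant(0.0),
        biomass_ter=constant(1.0),
        biomass_aq=constant(0.1),
        atmosphere_turnover=0.0,
    )
    return LandscapeGraph(
        objects={"obj1": params},
        schedules={"obj1": schedule},
        downstream_edges=[
            DownstreamEdge(source="obj1", target="outlet", flux=constant(0.0))
        ],
        sea_exchange={},
        outlet="outlet",
    )
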