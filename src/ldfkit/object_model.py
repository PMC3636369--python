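"""Per-object compartment structure and first-order transfer coefficients.

One biosphere object is a ten-compartment system with an aquatic and a
terrestrial side sharing a common lower regolith and atmosphere:

==================  ====================================================
REGOLITH_LOW        lower regolith over bedrock (glacial till)
AQU_REGOLITH_MID    middle aquatic regolith (glacial/postglacial clay, gyttja)
AQU_REGOLITH_UP     biologically active upper aquatic sediment (~5-10 cm)
TER_REGOLITH_MID    middle terrestrial regolith
TER_REGOLITH_UP     upper terrestrial regolith (peat / plough layer)
LITTER              dead plant material on the regolith
WATER               surface water (sea bay, lake or stream)
AQU_PP              aquatic primary producers + consumers (kg C basis)
TER_PP              terrestrial primary producers (kg C basis)
ATMOSPHERE          lower atmosphere, fully mixed
==================  ====================================================

All transfers are strictly first-order rates (a-1) acting on total
compartment inventories (Bq), with equilibrium Kd partitioning between
pore water and solids deciding which share of an inventory is mobile, and
CR-based uptake into newly produced biomass.  A fully submerged object has
zero-size terrestrial compartments and routes the entire deep-regolith flux
to the aquatic sediments; succession is expressed purely through the
time series of areas, masses and fluxes, so the rate matrix evolves
continuously (no discrete ecosystem switching).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field

from .nuclides import ElementProperties, RadionuclideSpec, ValidationError
from .series import TimeSeriesLike

# ---------------------------------------------------------------------------
# Compartment indexing
# ---------------------------------------------------------------------------

COMPARTMENTS: tuple[str, ...] = (
    "REGOLITH_LOW",
    "AQU_REGOLITH_MID",
    "AQU_REGOLITH_UP",
    "TER_REGOLITH_MID",
    "TER_REGOLITH_UP",
    "LITTER",
    "WATER",
    "AQU_PP",
    "TER_PP",
    "ATMOSPHERE",
)
N_COMPARTMENTS = len(COMPARTMENTS)

RL, ARM, ARU, TRM, TRU, LIT, WAT, APP, TPP, ATM = range(N_COMPARTMENTS)

#: Kd medium key looked up in ElementProperties.kd for each solid-bearing
#: compartment.  LITTER is treated as upper-regolith material (it carries the
#: same Kd); WATER uses the suspended-particle Kd.
KD_MEDIUM: dict[int, str] = {
    RL: "regolith_low",
    ARM: "regolith_mid",
    ARU: "regolith_up",
    TRM: "regolith_mid",
    TRU: "regolith_up",
    LIT: "regolith_up",
    WAT: "water",
}

#: Capacity below which a compartment is considered absent (e.g. terrestrial
#: compartments of a submerged object).
CAPACITY_EPS = 1e-9


@dataclass(frozen=True)
class CompartmentGeometry:
    """Size of one compartment at one instant.

    ``solid_mass`` is kg dw for mineral/organic compartments and kg C for
    the producer compartments; ``water_volume`` is the pore/free water in
    m3 (the full air volume for ATMOSPHERE).
    """

    id: str
    solid_mass: float = 0.0
    water_volume: float = 0.0
    area: float = 0.0
    thickness: float = 0.0

    @property
    def capacity_volume(self) -> float:
        return self.solid_mass + self.water_volume


class RegolithLayer(BaseModel):
    """Constant physical description of one regolith layer."""

    thickness: float = Field(gt=0.0, description="m")
    bulk_density: float = Field(gt=0.0, description="kg dw m-3")
    porosity: float = Field(ge=0.0, le=1.0)


class ObjectParameterSet(BaseModel):
    """Time-resolved geometry, hydrology and ecology of one biosphere object.

    Geometry derives from the total object area and the aquatic-area series:
    the terrestrial area is the complement, so lake infilling and wetland
    expansion are encoded by a single shrinking series.
    """

    object_id: str
    area_total: float = Field(gt=0.0, description="m2")
    aquatic_area: TimeSeriesLike
    water_depth: TimeSeriesLike

    regolith_low: RegolithLayer
    regolith_mid: RegolithLayer
    regolith_up: RegolithLayer

    litter_mass_per_area: float = Field(default=1.0, ge=0.0, description="kg dw m-2")
    atmosphere_height: float = Field(default=1000.0, gt=0.0, description="m")

    # hydrology
    upward_water_flux: TimeSeriesLike  # m3 a-1, geosphere-driven vertical advection
    runoff_terrestrial: TimeSeriesLike  # m3 a-1, TER_REGOLITH_UP -> WATER
    diffusivity: float = Field(default=0.01, ge=0.0, description="m2 a-1 effective")

    # particles
    sedimentation_flux: TimeSeriesLike  # kg m-2 a-1
    resuspension_flux: TimeSeriesLike  # kg m-2 a-1
    suspended_solids: TimeSeriesLike  # kg m-3

    # ecology
    production_ter: TimeSeriesLike  # kg C m-2 a-1
    production_aq: TimeSeriesLike  # kg C m-2 a-1
    biomass_ter: TimeSeriesLike  # kg C m-2
    biomass_aq: TimeSeriesLike  # kg C m-2
    litter_decomposition_rate: float = Field(default=0.1, ge=0.0, description="a-1")
    aq_return_to_water_fraction: float = Field(default=0.5, ge=0.0, le=1.0)

    # gas
    atmosphere_turnover: float = Field(default=1e3, ge=0.0, description="a-1")

    _SERIES_FIELDS = (
        "aquatic_area",
        "water_depth",
        "upward_water_flux",
        "runoff_terrestrial",
        "sedimentation_flux",
        "resuspension_flux",
        "suspended_solids",
        "production_ter",
        "production_aq",
        "biomass_ter",
        "biomass_aq",
    )

    def series_breakpoints(self) -> list[float]:
        points: set[float] = set()
        for name in self._SERIES_FIELDS:
            points.update(getattr(self, name).breakpoints)
        return sorted(points)

    def is_constant_between(self, t0: float, t1: float) -> bool:
        return all(
            getattr(self, name).is_constant_between(t0, t1)
            for name in self._SERIES_FIELDS
        )

    # -- geometry -----------------------------------------------------------

    def geometry_at(self, t: float) -> list[CompartmentGeometry]:
        aq_area = max(0.0, min(self.aquatic_area.at(t), self.area_total))
        ter_area = self.area_total - aq_area
        depth = max(0.0, self.water_depth.at(t))

        def layer(name: str, layer_def: RegolithLayer, area: float) -> CompartmentGeometry:
            return CompartmentGeometry(
                id=name,
                solid_mass=area * layer_def.thickness * layer_def.bulk_density,
                water_volume=area * layer_def.thickness * layer_def.porosity,
                area=area,
                thickness=layer_def.thickness,
            )

        geo = [None] * N_COMPARTMENTS
        geo[RL] = layer("REGOLITH_LOW", self.regolith_low, self.area_total)
        geo[ARM] = layer("AQU_REGOLITH_MID", self.regolith_mid, aq_area)
        geo[ARU] = layer("AQU_REGOLITH_UP", self.regolith_up, aq_area)
        geo[TRM] = layer("TER_REGOLITH_MID", self.regolith_mid, ter_area)
        geo[TRU] = layer("TER_REGOLITH_UP", self.regolith_up, ter_area)
        geo[LIT] = CompartmentGeometry(
            id="LITTER", solid_mass=ter_area * self.litter_mass_per_area, area=ter_area
        )
        geo[WAT] = CompartmentGeometry(
            id="WATER", water_volume=aq_area * depth, area=aq_area, thickness=depth
        )
        geo[APP] = CompartmentGeometry(
            id="AQU_PP", solid_mass=aq_area * self.biomass_aq.at(t), area=aq_area
        )
        geo[TPP] = CompartmentGeometry(
            id="TER_PP", solid_mass=ter_area * self.biomass_ter.at(t), area=ter_area
        )
        geo[ATM] = CompartmentGeometry(
            id="ATMOSPHERE",
            water_volume=self.area_total * self.atmosphere_height,
            area=self.area_total,
            thickness=self.atmosphere_height,
        )
        return geo


# ---------------------------------------------------------------------------
# Rate-coefficient primitives
# ---------------------------------------------------------------------------


def dissolved_fraction(kd: float, solid_mass: float, water_volume: float) -> float:
    """Share of a compartment inventory residing in (pore) water.

    Equilibrium Kd partitioning: dissolved = Vw / (Vw + Kd * M); the sorbed
    fraction is the complement.
    """
    if kd < 0.0:
        raise ValidationError(f"kd must be >= 0, got {kd}")
    capacity = water_volume + kd * solid_mass
    if capacity <= 0.0:
        raise ValidationError("compartment has zero sorption+water capacity")
    return water_volume / capacity


def sorption_capacity(kd: float, solid_mass: float, water_volume: float) -> float:
    """Effective pore-water-equivalent capacity Vw + Kd*M (m3)."""
    return water_volume + kd * solid_mass


def advective_rate(flux: float, water_volume: float, kd: float, solid_mass: float) -> float:
    """First-order rate for a water flux leaving a compartment (a-1).

    Only the dissolved share moves, so the rate on the total inventory is
    retarded by sorption: k = Q / (Vw + Kd * M).
    """
    if flux < 0.0:
        raise ValidationError(f"water flux must be >= 0, got {flux}")
    if flux == 0.0:
        return 0.0
    capacity = sorption_capacity(kd, solid_mass, water_volume)
    if capacity <= 0.0:
        raise ValidationError("advection from a zero-capacity compartment")
    return flux / capacity


def diffusive_rates(
    diffusivity: float,
    area: float,
    length: float,
    capacity_i: float,
    capacity_j: float,
) -> tuple[float, float]:
    """Symmetric pore-water diffusion between two adjacent compartments.

    Conductance G = D*A/L (m3 a-1) acts on the pore-water concentration
    difference; expressed on total inventories the pair of first-order
    rates is (G/cap_i, G/cap_j) with cap = Vw + Kd*M.  At equal pore-water
    concentrations the net flux vanishes.
    """
    if length <= 0.0:
        raise ValidationError("diffusion path length must be > 0")
    if diffusivity == 0.0 or area == 0.0:
        return 0.0, 0.0
    if capacity_i <= 0.0 or capacity_j <= 0.0:
        raise ValidationError("diffusion between zero-capacity compartments")
    conductance = diffusivity * area / length
    return conductance / capacity_i, conductance / capacity_j


def particle_rates(
    sedimentation_flux: float,
    resuspension_flux: float,
    area: float,
    water_volume: float,
    suspended_mass: float,
    sediment_mass: float,
    sediment_water_volume: float,
    kd_water: float,
    kd_sediment: float,
) -> tuple[float, float]:
    """Sedimentation and resuspension rates between WATER and upper sediment.

    Settling removes the particle-bound share of the water column:
    k_sed = F_sed*A*Kd_w / (Vw + Kd_w*M_susp).  Resuspension returns the
    sorbed share of the upper sediment: k_res = F_res*A/M_sed * f_sorbed.
    """
    if sedimentation_flux < 0.0 or resuspension_flux < 0.0:
        raise ValidationError("particle fluxes must be >= 0")
    k_sed = 0.0
    if sedimentation_flux > 0.0 and kd_water > 0.0:
        cap_w = sorption_capacity(kd_water, suspended_mass, water_volume)
        if cap_w > 0.0:
            k_sed = sedimentation_flux * area * kd_water / cap_w
    k_res = 0.0
    if resuspension_flux > 0.0:
        if sediment_mass <= 0.0:
            raise ValidationError("resuspension from a sediment with zero solids")
        sorbed = 1.0 - dissolved_fraction(kd_sediment, sediment_mass, sediment_water_volume)
        k_res = resuspension_flux * area / sediment_mass * sorbed
    return k_sed, k_res


def biota_rates(
    production: float,
    biomass: float,
    cr: float,
    medium_capacity_for_cr: float,
) -> tuple[float, float]:
    """Production-driven uptake into, and turnover out of, a producer pool.

    Newly produced biomass equilibrates with its medium at the concentration
    ratio CR, so uptake is a flux P*CR*C_medium; expressed on the medium
    inventory it is first order with k = P*CR / X where X is the medium's
    denominator for the CR basis (solid mass for soil, water volume for
    water).  Turnover returns biomass at rate P/B.
    """
    if cr < 0.0:
        raise ValidationError(f"cr must be >= 0, got {cr}")
    if production < 0.0:
        raise ValidationError("production must be >= 0")
    if production == 0.0:
        return 0.0, 0.0
    if biomass <= 0.0:
        raise ValidationError("nonzero production requires positive biomass")
    k_uptake = 0.0
    if cr > 0.0:
        if medium_capacity_for_cr <= 0.0:
            raise ValidationError("uptake from an empty medium")
        k_uptake = production * cr / medium_capacity_for_cr
    return k_uptake, production / biomass


def gas_rates(degassing_rate: float, atmosphere_turnover: float) -> tuple[float, float]:
    """(surface -> atmosphere, atmosphere -> external sink) rates, a-1."""
    if degassing_rate < 0.0 or atmosphere_turnover < 0.0:
        raise ValidationError("gas rates must be >= 0")
    return degassing_rate, atmosphere_turnover


def wetland_growth_rate(aquatic_area: float, daq_dt: float) -> float:
    """Transfer rate of aquatic regolith annexed by the expanding wetland.

    When the aquatic area shrinks, the annexed bed fraction per year carries
    its inventory from the aquatic to the terrestrial regolith:
    k = max(0, -dA/dt) / A; zero while the area is constant or growing.
    """
    if aquatic_area <= 0.0:
        return 0.0
    return max(0.0, -daq_dt) / aquatic_area


# ---------------------------------------------------------------------------
# Object matrix assembly
# ---------------------------------------------------------------------------

#: Diffusion-coupled compartment pairs (vertical stratigraphy).
DIFFUSION_PAIRS = ((RL, ARM), (ARM, ARU), (ARU, WAT), (RL, TRM), (TRM, TRU))


def assemble_object_matrix(
    params: ObjectParameterSet,
    element: ElementProperties,
    nuclide: RadionuclideSpec,
    t: float,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Rate matrix over the ten compartments of one object at time ``t``.

    Returns ``(K, exports)``: ``K[j, i]`` is the i->j transfer rate (a-1),
    the diagonal collects -(outgoing + decay + exports); ``exports`` maps
    sink names (``"atmosphere"``) to length-10 vectors of first-order loss
    rates already included in the diagonal.  Inter-object water transport is
    added at the landscape level.
    """
    geo = params.geometry_at(t)
    kd = np.zeros(N_COMPARTMENTS)
    for idx, medium in KD_MEDIUM.items():
        kd[idx] = element.kd_for(medium)

    # Suspended solids replace the (zero) bed mass of the WATER compartment
    # in its sorption capacity.
    vw_wat = geo[WAT].water_volume
    m_susp = params.suspended_solids.at(t) * vw_wat

    cap = np.zeros(N_COMPARTMENTS)
    for i in range(N_COMPARTMENTS):
        if i == WAT:
            cap[i] = vw_wat + kd[WAT] * m_susp
        elif i in (APP, TPP):
            cap[i] = geo[i].solid_mass  # kg C; used only for activity bookkeeping
        elif i == ATM:
            cap[i] = geo[i].water_volume
        else:
            cap[i] = geo[i].water_volume + kd[i] * geo[i].solid_mass

    active = cap > CAPACITY_EPS

    K = np.zeros((N_COMPARTMENTS, N_COMPARTMENTS))
    exports: dict[str, np.ndarray] = {"atmosphere": np.zeros(N_COMPARTMENTS)}

    def add(i: int, j: int, rate: float) -> None:
        # transfer i -> j
        if rate == 0.0:
            return
        if rate < 0.0:
            raise AssertionError(f"negative transfer rate {rate} for {i}->{j}")
        if not active[i]:
            return
        if not active[j]:
            raise ValidationError(
                f"flux directed into inactive compartment {COMPARTMENTS[j]} "
                f"of object {params.object_id!r} at t={t}"
            )
        K[j, i] += rate
        K[i, i] -= rate

    # --- water advection (flux class 2) ------------------------------------
    aq_area = geo[WAT].area
    f_aq = aq_area / params.area_total
    q_up = params.upward_water_flux.at(t)
    q_aq = q_up * f_aq
    q_ter = q_up * (1.0 - f_aq)

    def adv(i: int, j: int, flux: float) -> None:
        if flux > 0.0 and active[i]:
            m = geo[i].solid_mass if i != WAT else m_susp
            add(i, j, advective_rate(flux, geo[i].water_volume, kd[i], m))

    adv(RL, ARM, q_aq)
    adv(ARM, ARU, q_aq)
    adv(ARU, WAT, q_aq)
    adv(RL, TRM, q_ter)
    adv(TRM, TRU, q_ter)
    adv(TRU, WAT, q_ter + params.runoff_terrestrial.at(t))

    # --- pore-water diffusion ----------------------------------------------
    if params.diffusivity > 0.0:
        for i, j in DIFFUSION_PAIRS:
            if not (active[i] and active[j]):
                continue
            contact = min(geo[i].area, geo[j].area)
            if contact <= 0.0:
                continue
            th_i = geo[i].thickness if geo[i].thickness > 0 else geo[j].thickness
            th_j = geo[j].thickness if geo[j].thickness > 0 else geo[i].thickness
            length = 0.5 * (th_i + th_j)
            if length <= 0.0:
                continue
            k_ij, k_ji = diffusive_rates(params.diffusivity, contact, length, cap[i], cap[j])
            add(i, j, k_ij)
            add(j, i, k_ji)

    # --- sedimentation / resuspension (flux class 4) ------------------------
    if active[WAT] and active[ARU]:
        k_sed, k_res = particle_rates(
            params.sedimentation_flux.at(t),
            params.resuspension_flux.at(t),
            aq_area,
            vw_wat,
            m_susp,
            geo[ARU].solid_mass,
            geo[ARU].water_volume,
            kd[WAT],
            kd[ARU],
        )
        add(WAT, ARU, k_sed)
        add(ARU, WAT, k_res)

    # --- biological uptake / turnover (flux class 6) ------------------------
    p_ter = params.production_ter.at(t) * geo[TPP].area
    if p_ter > 0.0 and active[TPP] and active[TRU]:
        k_up, k_ret = biota_rates(
            p_ter, geo[TPP].solid_mass, element.cr_for("ter_producer"), geo[TRU].solid_mass
        )
        add(TRU, TPP, k_up)
        add(TPP, LIT, k_ret)
    p_aq = params.production_aq.at(t) * geo[APP].area
    if p_aq > 0.0 and active[APP] and active[WAT]:
        k_up, k_ret = biota_rates(
            p_aq, geo[APP].solid_mass, element.cr_for("aqu_producer"), vw_wat
        )
        add(WAT, APP, k_up)
        f_w = params.aq_return_to_water_fraction
        add(APP, WAT, k_ret * f_w)
        if active[ARU]:
            add(APP, ARU, k_ret * (1.0 - f_w))
        else:
            add(APP, WAT, k_ret * (1.0 - f_w))
    if active[LIT]:
        add(LIT, TRU, params.litter_decomposition_rate)

    # --- gas fluxes (flux class 3) ------------------------------------------
    k_gas, k_vent = gas_rates(element.degassing_rate, params.atmosphere_turnover)
    if k_gas > 0.0 and active[ATM]:
        if active[WAT]:
            add(WAT, ATM, k_gas)
        if active[TRU]:
            add(TRU, ATM, k_gas)
    if active[ATM] and k_vent > 0.0:
        K[ATM, ATM] -= k_vent
        exports["atmosphere"][ATM] = k_vent

    # --- wetland growth (flux class 5) ---------------------------------------
    k_wg = wetland_growth_rate(aq_area, params.aquatic_area.slope_at(t))
    if k_wg > 0.0:
        if active[ARM] and active[TRM]:
            add(ARM, TRM, k_wg)
        if active[ARU] and active[TRU]:
            add(ARU, TRU, k_wg)

    # --- radioactive decay ---------------------------------------------------
    lam = nuclide.decay_constant
    for i in range(N_COMPARTMENTS):
        if active[i]:
            K[i, i] -= lam

    # Inactive compartments are fully decoupled.
    for i in range(N_COMPARTMENTS):
        if not active[i]:
            K[i, :] = 0.0
            K[:, i] = 0.0

    return K, exports
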