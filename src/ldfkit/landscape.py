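"""Landscape graph: coupled biosphere objects and ecosystem succession.

Objects are linked by surface-water fluxes.  While an object is still a sea
basin it exchanges water bidirectionally with the outer coastal object only;
once isolated (sea -> lake -> wetland) its outflow follows the downstream
drainage edges; everything ultimately discharges through the coastal object
into an absorbing outlet sink (the open sea).  Succession is continuous:
stage weights ramp linearly across the isolation window instead of switching
models at discrete events, which keeps inventories and the mass balance
continuous through every transition.
"""

from __future__ import annotations

from typing import Optional

import networkx as nx
import numpy as np
from pydantic import BaseModel, Field, model_validator

from .nuclides import NuclideLibrary, ValidationError
from .object_model import (
    N_COMPARTMENTS,
    WAT,
    ObjectParameterSet,
    assemble_object_matrix,
)
from .series import TimeSeries, TimeSeriesLike, interpolate_parameters  # noqa: F401

#: Scenario-schedule defaults for the reference glacial cycle (years).
TEMPERATE_LENGTH = 18_400.0
PERIGLACIAL_LENGTH = 50_200.0
ISOLATION_WINDOW = 500.0
TEMPERATE_START = -9000.0
TEMPERATE_END = TEMPERATE_START + TEMPERATE_LENGTH  # 9400
PERIGLACIAL_END = TEMPERATE_END + PERIGLACIAL_LENGTH  # 59600

#: Duration of the ramp used when a wetland is converted to agricultural
#: land; short but nonzero so stage weights stay continuous.
AGRICULTURAL_RAMP = 1.0

CLIMATE_LABELS = ("temperate", "periglacial", "glacial", "global_warming")


def default_climate_periods() -> list[tuple[str, float, float]]:
    return [
        ("temperate", TEMPERATE_START, TEMPERATE_END),
        ("periglacial", TEMPERATE_END, PERIGLACIAL_END),
    ]


class SuccessionSchedule(BaseModel):
    """Sea -> lake -> wetland -> (optional) agriculture timing of one object."""

    submerged_until: float
    isolation_start: float
    isolation_end: float
    wetland_by: Optional[float] = None
    agricultural_from: Optional[float] = None
    climate_periods: list[tuple[str, float, float]] = Field(
        default_factory=default_climate_periods
    )

    @model_validator(mode="after")
    def _check(self) -> "SuccessionSchedule":
        if not (self.submerged_until <= self.isolation_start < self.isolation_end):
            raise ValueError(
                "schedule must satisfy submerged_until <= isolation_start < isolation_end"
            )
        if self.wetland_by is None:
            self.wetland_by = self.isolation_end + 1000.0
        if self.wetland_by < self.isolation_end:
            raise ValueError("wetland_by must be >= isolation_end")
        if self.agricultural_from is not None and (
            self.agricultural_from < self.isolation_start
        ):
            raise ValueError("agricultural conversion cannot precede isolation")
        for label, start, end in self.climate_periods:
            if label not in CLIMATE_LABELS:
                raise ValueError(f"unknown climate period label {label!r}")
            if not end > start:
                raise ValueError(f"climate period {label!r} has end <= start")
        return self

    def breakpoints(self) -> list[float]:
        points = [self.isolation_start, self.isolation_end, float(self.wetland_by)]
        if self.agricultural_from is not None:
            points += [self.agricultural_from, self.agricultural_from + AGRICULTURAL_RAMP]
        return points

    def period(self, label: str) -> tuple[float, float]:
        for name, start, end in self.climate_periods:
            if name == label:
                return start, end
        raise ValidationError(f"no climate period labelled {label!r} in schedule")


def _ramp01(t: float, t0: float, t1: float) -> float:
    if t <= t0:
        return 0.0
    if t >= t1:
        return 1.0
    return (t - t0) / (t1 - t0)


def stage_weights(schedule: SuccessionSchedule, t: float) -> dict[str, float]:
    """Continuous, piecewise-linear ecosystem-stage weights summing to one.

    ``sea`` is 1 before the isolation window and ramps to 0 across it; the
    complement splits between ``lake`` and ``wetland`` as the wetland grows
    in (complete at ``wetland_by``); after the optional agricultural
    conversion the ``agricultural`` weight takes over via a short ramp.
    """
    sea = 1.0 - _ramp01(t, schedule.isolation_start, schedule.isolation_end)
    grown = _ramp01(t, schedule.isolation_start, float(schedule.wetland_by))
    lake = (1.0 - sea) * (1.0 - grown)
    wetland = (1.0 - sea) * grown
    agri = 0.0
    if schedule.agricultural_from is not None:
        a = _ramp01(
            t, schedule.agricultural_from, schedule.agricultural_from + AGRICULTURAL_RAMP
        )
        sea, lake, wetland = sea * (1 - a), lake * (1 - a), wetland * (1 - a)
        agri = a
    return {"sea": sea, "lake": lake, "wetland": wetland, "agricultural": agri}


# ---------------------------------------------------------------------------
# Graph
# ---------------------------------------------------------------------------


class DownstreamEdge(BaseModel):
    source: str
    target: str
    flux: TimeSeriesLike  # m3 a-1


class SeaExchange(BaseModel):
    partner: str
    to_partner: TimeSeriesLike  # m3 a-1
    from_partner: TimeSeriesLike  # m3 a-1


class LandscapeGraph(BaseModel):
    """Objects, drainage edges, sea-stage exchange pairs and the outlet sink."""

    objects: dict[str, ObjectParameterSet]
    schedules: dict[str, SuccessionSchedule]
    downstream_edges: list[DownstreamEdge] = Field(default_factory=list)
    sea_exchange: dict[str, SeaExchange] = Field(default_factory=dict)
    outlet: str = "outlet"

    @model_validator(mode="after")
    def _check(self) -> "LandscapeGraph":
        if self.outlet in self.objects:
            raise ValueError("outlet must be an external sink, not a modelled object")
        for oid, params in self.objects.items():
            if params.object_id != oid:
                raise ValueError(f"object key {oid!r} != object_id {params.object_id!r}")
            if oid not in self.schedules:
                raise ValueError(f"object {oid!r} has no succession schedule")
        known = set(self.objects) | {self.outlet}
        digraph = nx.DiGraph()
        digraph.add_nodes_from(known)
        for edge in self.downstream_edges:
            for end, label in ((edge.source, "source"), (edge.target, "target")):
                if end not in known:
                    raise ValueError(f"edge {label} {end!r} is not a known object")
            if edge.source == self.outlet:
                raise ValueError("the outlet sink cannot be an edge source")
            digraph.add_edge(edge.source, edge.target)
        if not nx.is_directed_acyclic_graph(digraph):
            raise ValueError(f"downstream edges contain a cycle: {nx.find_cycle(digraph)}")
        for oid, ex in self.sea_exchange.items():
            if oid not in self.objects:
                raise ValueError(f"sea_exchange key {oid!r} is not a known object")
            if ex.partner not in self.objects:
                raise ValueError(
                    f"sea_exchange partner {ex.partner!r} of {oid!r} is not a known object"
                )
            digraph.add_edge(oid, ex.partner)
        for oid in self.objects:
            if not nx.has_path(digraph, oid, self.outlet):
                raise ValueError(f"object {oid!r} has no drainage path to the outlet")
        return self

    @property
    def object_ids(self) -> list[str]:
        return list(self.objects)


# ---------------------------------------------------------------------------
# Assembled system
# ---------------------------------------------------------------------------

SINKS = ("outlet", "atmosphere")


class LandscapeSystem:
    """Index bookkeeping and matrix assembly for one release chain.

    State vector layout: all inventories (member-major, then object, then
    compartment), followed by per-member ledger states — cumulative decayed
    activity, cumulative activity grown in from the parent, and cumulative
    exports per sink.  The ledgers are linear functions of the inventories,
    so the full system stays a linear ODE and the mass-balance audit is an
    exact by-product of the integration.
    """

    def __init__(self, graph: LandscapeGraph, library: NuclideLibrary, head: str):
        self.graph = graph
        self.library = library
        self.chain = library.build_chain(head)
        self.head = head
        self.object_ids = graph.object_ids
        self.n_obj = len(self.object_ids)
        self.n_mem = len(self.chain)
        self.obj_index = {oid: i for i, oid in enumerate(self.object_ids)}
        self.mem_index = {spec.name: m for m, spec in enumerate(self.chain)}
        self.n_inv = self.n_mem * self.n_obj * N_COMPARTMENTS
        self.n_aux_per_mem = 2 + len(SINKS)
        self.n_tot = self.n_inv + self.n_mem * self.n_aux_per_mem

    # -- indexing -----------------------------------------------------------

    def idx_inv(self, member: int, obj: int, comp: int) -> int:
        return (member * self.n_obj + obj) * N_COMPARTMENTS + comp

    def member_slice(self, member: int) -> slice:
        width = self.n_obj * N_COMPARTMENTS
        return slice(member * width, (member + 1) * width)

    def idx_decayed(self, member: int) -> int:
        return self.n_inv + member

    def idx_ingrown(self, member: int) -> int:
        return self.n_inv + self.n_mem + member

    def idx_exported(self, member: int, sink: str) -> int:
        s = SINKS.index(sink)
        return self.n_inv + (2 + s) * self.n_mem + member

    # -- time structure ------------------------------------------------------

    def breakpoints(self) -> list[float]:
        points: set[float] = set()
        for oid in self.object_ids:
            points.update(self.graph.objects[oid].series_breakpoints())
            points.update(self.graph.schedules[oid].breakpoints())
        for edge in self.graph.downstream_edges:
            points.update(edge.flux.breakpoints)
        for ex in self.graph.sea_exchange.values():
            points.update(ex.to_partner.breakpoints)
            points.update(ex.from_partner.breakpoints)
        return sorted(points)

    def is_constant_between(self, t0: float, t1: float) -> bool:
        for oid in self.object_ids:
            if not self.graph.objects[oid].is_constant_between(t0, t1):
                return False
            sched = self.graph.schedules[oid]
            if stage_weights(sched, t0) != stage_weights(sched, t1):
                return False
        for edge in self.graph.downstream_edges:
            if not edge.flux.is_constant_between(t0, t1):
                return False
        for ex in self.graph.sea_exchange.values():
            if not ex.to_partner.is_constant_between(t0, t1):
                return False
            if not ex.from_partner.is_constant_between(t0, t1):
                return False
        return True

    # -- assembly ------------------------------------------------------------

    def matrix_at(self, t: float) -> np.ndarray:
        """Full first-order rate matrix (inventories + ledger rows) at ``t``."""
        M = np.zeros((self.n_tot, self.n_tot))
        water_volume = {
            oid: self.graph.objects[oid].geometry_at(t)[WAT].water_volume
            for oid in self.object_ids
        }
        sea_w = {
            oid: stage_weights(self.graph.schedules[oid], t)["sea"]
            for oid in self.object_ids
        }

        for m, spec in enumerate(self.chain):
            element = self.library.elements[spec.element]
            lam = spec.decay_constant
            for oid in self.object_ids:
                o = self.obj_index[oid]
                K, exports = assemble_object_matrix(
                    self.graph.objects[oid], element, spec, t
                )
                base = self.idx_inv(m, o, 0)
                M[base : base + N_COMPARTMENTS, base : base + N_COMPARTMENTS] += K
                for sink, rates in exports.items():
                    row = self.idx_exported(m, sink)
                    M[row, base : base + N_COMPARTMENTS] += rates

            # inter-object surface-water transport, stage-gated
            for edge in self.graph.downstream_edges:
                o_from = self.obj_index[edge.source]
                weight = 1.0 if edge.target == self.graph.outlet else 1.0 - sea_w[edge.source]
                flux = edge.flux.at(t) * weight
                if flux <= 0.0:
                    continue
                vw = water_volume[edge.source]
                if vw <= 0.0:
                    raise ValidationError(
                        f"water export from {edge.source!r} with empty WATER at t={t}"
                    )
                # total water-column concentration (dissolved + suspended) moves
                rate = flux / vw
                i = self.idx_inv(m, o_from, WAT)
                M[i, i] -= rate
                if edge.target == self.graph.outlet:
                    M[self.idx_exported(m, "outlet"), i] += rate
                else:
                    j = self.idx_inv(m, self.obj_index[edge.target], WAT)
                    M[j, i] += rate
            for oid, ex in self.graph.sea_exchange.items():
                w = sea_w[oid]
                if w <= 0.0:
                    continue
                o = self.obj_index[oid]
                p = self.obj_index[ex.partner]
                for flux, src, dst in (
                    (ex.to_partner.at(t) * w, o, p),
                    (ex.from_partner.at(t) * w, p, o),
                ):
                    if flux <= 0.0:
                        continue
                    vw = water_volume[self.object_ids[src]]
                    if vw <= 0.0:
                        raise ValidationError(
                            f"sea exchange from {self.object_ids[src]!r} with empty WATER"
                        )
                    rate = flux / vw
                    i = self.idx_inv(m, src, WAT)
                    M[i, i] -= rate
                    M[self.idx_inv(m, dst, WAT), i] += rate

            # ledger rows: decayed activity of this member
            sl = self.member_slice(m)
            M[self.idx_decayed(m), sl] += lam

            # chain ingrowth: daughter activity grows at b * lambda_d per unit
            # parent activity, in the same compartment
            if spec.parent is not None and spec.parent in self.mem_index:
                mp = self.mem_index[spec.parent]
                coeff = spec.branching_fraction * lam
                for o in range(self.n_obj):
                    for c in range(N_COMPARTMENTS):
                        M[self.idx_inv(m, o, c), self.idx_inv(mp, o, c)] += coeff
                M[self.idx_ingrown(m), self.member_slice(mp)] += coeff

        return M


def assemble_landscape_matrix(
    graph: LandscapeGraph, library: NuclideLibrary, head: str, t: float
) -> np.ndarray:
    """Inventory-block rate matrix over all objects x compartments x members.

    Convenience wrapper returning only the inventory block (no ledger rows)
    of :meth:`LandscapeSystem.matrix_at`.
    """
    system = LandscapeSystem(graph, library, head)
    return system.matrix_at(t)[: system.n_inv, : system.n_inv]
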