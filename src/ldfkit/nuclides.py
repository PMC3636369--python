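"""Radionuclide and element property model.

Decay chains, decay constants, sorption (Kd) and biological uptake (CR)
catalogues, and dose coefficients.  Global unit conventions used throughout
the package:

* time in years (a), activity in Bq
* volume in m3, solid mass in kg dry weight (dw)
* concentration in Bq m-3 (water, air), Bq kg-1 dw (solids),
  Bq (kg C)-1 (foods and producer biomass)
* Kd in m3 kg-1 dw; CR in kg dw (kg C)-1 for terrestrial producers
  (soil-to-biomass) and m3 (kg C)-1 for aquatic producers (water-to-biomass)
* dose coefficients in Sv Bq-1 (intake) and (Sv a-1)/(Bq kg-1 dw) or
  (Sv a-1)/(Bq m-3) (external)
"""

from __future__ import annotations

import math
from typing import Optional

import networkx as nx
from pydantic import BaseModel, Field, model_validator

LN2 = math.log(2.0)


class ValidationError(ValueError):
    """Raised when a configuration violates a model contract."""


def decay_constant(half_life: float) -> float:
    """Radioactive decay constant ``ln(2) / T_half`` in a-1.

    Parameters
    ----------
    half_life
        Physical half-life in years; must be strictly positive.
    """
    if not half_life > 0.0:
        raise ValidationError(f"half_life must be > 0, got {half_life!r}")
    return LN2 / half_life


class DoseCoefficients(BaseModel):
    """Dose-per-unit-exposure constants for one radionuclide.

    Treated as fixed constants in both deterministic and probabilistic
    simulations (no PDF is ever attached to them).
    """

    ingestion: float = Field(ge=0.0, description="Sv Bq-1 ingested")
    inhalation: float = Field(ge=0.0, description="Sv Bq-1 inhaled")
    external_soil: float = Field(
        default=0.0, ge=0.0, description="(Sv a-1) per (Bq kg-1 dw) ground"
    )
    external_water_immersion: float = Field(
        default=0.0, ge=0.0, description="(Sv a-1) per (Bq m-3) water"
    )


class ElementProperties(BaseModel):
    """Element-specific sorption and uptake parameters.

    ``kd`` maps medium identifiers (e.g. ``regolith_low``, ``water``) to
    distribution coefficients in m3 kg-1 dw.  ``cr`` maps biota or food
    type identifiers to concentration ratios (see module docstring for the
    per-type units).  ``degassing_rate`` is a first-order volatilisation
    rate (a-1), zero for non-volatile elements.
    """

    name: str
    kd: dict[str, float] = Field(default_factory=dict)
    cr: dict[str, float] = Field(default_factory=dict)
    degassing_rate: float = Field(default=0.0, ge=0.0)

    @model_validator(mode="after")
    def _non_negative_maps(self) -> "ElementProperties":
        for label, table in (("kd", self.kd), ("cr", self.cr)):
            for key, value in table.items():
                if value < 0.0:
                    raise ValueError(f"{label}[{key!r}] must be >= 0, got {value}")
        return self

    def kd_for(self, medium: str) -> float:
        try:
            return self.kd[medium]
        except KeyError:
            raise ValidationError(
                f"element {self.name!r} has no Kd entry for medium {medium!r}"
            ) from None

    def cr_for(self, biota: str) -> float:
        try:
            return self.cr[biota]
        except KeyError:
            raise ValidationError(
                f"element {self.name!r} has no CR entry for biota/food {biota!r}"
            ) from None


class RadionuclideSpec(BaseModel):
    """One radionuclide: half-life, chain link and dose coefficients."""

    name: str
    half_life: float = Field(gt=0.0, description="years")
    element: str
    parent: Optional[str] = None
    branching_fraction: float = Field(default=1.0, gt=0.0, le=1.0)
    dose_coefficients: DoseCoefficients

    @property
    def decay_constant(self) -> float:
        return decay_constant(self.half_life)


class NuclideLibrary(BaseModel):
    """A set of radionuclides plus the element catalogue they reference.

    Validates that parent links resolve, that the chain graph is acyclic,
    that branching fractions out of any parent sum to at most one, and that
    every referenced element exists.
    """

    nuclides: dict[str, RadionuclideSpec]
    elements: dict[str, ElementProperties]

    @model_validator(mode="after")
    def _validate_links(self) -> "NuclideLibrary":
        graph = nx.DiGraph()
        graph.add_nodes_from(self.nuclides)
        branching_out: dict[str, float] = {}
        for name, spec in self.nuclides.items():
            if spec.name != name:
                raise ValueError(f"library key {name!r} != spec name {spec.name!r}")
            if spec.element not in self.elements:
                raise ValueError(
                    f"nuclide {name!r} references unknown element {spec.element!r}"
                )
            if spec.parent is not None:
                if spec.parent not in self.nuclides:
                    raise ValueError(
                        f"nuclide {name!r} names missing parent {spec.parent!r}"
                    )
                graph.add_edge(spec.parent, name)
                branching_out[spec.parent] = (
                    branching_out.get(spec.parent, 0.0) + spec.branching_fraction
                )
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"decay chain contains a cycle: {cycle}")
        for parent, total in branching_out.items():
            if total > 1.0 + 1e-12:
                raise ValueError(
                    f"branching fractions out of {parent!r} sum to {total} > 1"
                )
        return self

    def element_for(self, nuclide: str) -> ElementProperties:
        return self.elements[self.nuclides[nuclide].element]

    def build_chain(self, head: str) -> list[RadionuclideSpec]:
        """Head nuclide plus all its descendants, parent-before-daughter.

        The returned order is a topological sort of the sub-chain rooted at
        ``head``; each member appears exactly once.
        """
        if head not in self.nuclides:
            raise ValidationError(f"unknown chain head {head!r}")
        children: dict[str, list[str]] = {name: [] for name in self.nuclides}
        for name, spec in self.nuclides.items():
            if spec.parent is not None:
                children[spec.parent].append(name)
        # BFS from the head collects the reachable sub-chain; library-level
        # validation already guarantees acyclicity.
        members: list[str] = []
        seen: set[str] = set()
        queue = [head]
        while queue:
            current = queue.pop(0)
            if current in seen:
                continue
            seen.add(current)
            members.append(current)
            queue.extend(sorted(children[current]))
        sub = nx.DiGraph()
        sub.add_nodes_from(members)
        for name in members:
            parent = self.nuclides[name].parent
            if parent in seen:
                sub.add_edge(parent, name)
        ordered = list(nx.topological_sort(sub))
        # Stable: keep BFS discovery order among incomparable members.
        rank = {name: i for i, name in enumerate(members)}
        ordered.sort(key=lambda n: rank[n])
        return [self.nuclides[n] for n in ordered]
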