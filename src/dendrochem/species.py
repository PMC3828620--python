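"""Actors of the chemistry: diffusible Species, fixed States, Parameters.

A :class:`Species` lives on one or more Regions and may diffuse (coefficient
``d`` in µm²/ms); a :class:`State` is a non-diffusing dynamic variable (e.g.
a gating variable); a :class:`Parameter` is a constant that never changes
under integration.  Concentrations are in mM throughout, time in ms, space
in µm.

When a model is initialized, one :class:`Node` is materialized per
(species, region, section, segment) — the addressable unit holding a volume
and a concentration — plus zero-volume junction entries at section
boundaries for each diffusing species block.  All node values live in a
single flat state vector, contiguous per (species, region), ordered along
each section by segment with sections in registration order and junction
entries appended per block.  Nodes are live views into that vector, so
gather/scatter round trips are exact by construction.

``species[region]`` restricts a species to one region — required for
multi-compartment reactions and handy for bulk assignment, e.g.
``ca[er].concentration = 0.0009``.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Union

import numpy as np

from .expressions import Arithmetic
from .morphology import Section
from .regions import Region

__all__ = ["SpeciesError", "Species", "State", "Parameter", "SpeciesOnRegion", "Node"]


class SpeciesError(ValueError):
    """Invalid species/state/parameter construction or addressing."""


class _Actor(Arithmetic):
    """Common base for model actors participating in rate expressions."""

    _is_parameter = False

    def __init__(self, name: Optional[str]):
        super().__init__()
        self.name = name
        self._model = None  # set by Model.initialize

    def _bound_model(self):
        if self._model is None or not self._model._initialized:
            raise SpeciesError(
                f"{self!r} is not part of an initialized model"
            )
        return self._model

    def __repr__(self) -> str:
        label = self.name or f"#{self._ref_id}"
        return f"{type(self).__name__}({label})"

    def __hash__(self):
        return id(self)

    def __eq__(self, other):
        return self is other


class Species(_Actor):
    """A diffusible chemical species on a list of regions.

    Parameters
    ----------
    regions:
        Region or list of Regions where the species exists (mandatory).
    d:
        Diffusion coefficient, µm²/ms (default 0: no diffusion).
    name:
        Optional identifier used in reprs and serialized expressions.
    charge:
        Integer valence; required (not None) for species whose membrane flux
        induces a current.
    initial:
        Initial concentration in mM — a constant or a function of Node.
    """

    def __init__(
        self,
        regions: Union[Region, Sequence[Region]],
        d: float = 0.0,
        name: Optional[str] = None,
        charge: Optional[int] = None,
        initial: Union[float, Callable, None] = None,
    ):
        super().__init__(name)
        if isinstance(regions, Region):
            regions = [regions]
        regions = list(regions)
        if not regions:
            raise SpeciesError("a Species requires at least one region")
        if not all(isinstance(r, Region) for r in regions):
            raise SpeciesError("regions must be Region instances")
        if d < 0:
            raise SpeciesError(f"diffusion coefficient must be >= 0, got {d}")
        self.regions = regions
        self.d = float(d)
        self.charge = charge
        self.initial = initial
        self._on_region: dict[int, "SpeciesOnRegion"] = {}

    def __getitem__(self, region: Region) -> "SpeciesOnRegion":
        if region not in self.regions:
            raise SpeciesError(
                f"{self!r} does not exist on region {region.name!r}"
            )
        key = id(region)
        if key not in self._on_region:
            self._on_region[key] = SpeciesOnRegion(self, region)
        return self._on_region[key]

    @property
    def nodes(self) -> list["Node"]:
        model = self._bound_model()
        return [n for r in self.regions for n in model._nodes_of(self, r)]

    @property
    def concentration(self) -> np.ndarray:
        return np.array([n.concentration for n in self.nodes])

    @concentration.setter
    def concentration(self, value) -> None:
        nodes = self.nodes
        values = np.broadcast_to(np.asarray(value, float), (len(nodes),))
        for n, v in zip(nodes, values):
            n.concentration = v


class State(_Actor):
    """A non-diffusing, unitless dynamic variable on a list of regions."""

    def __init__(
        self,
        regions: Union[Region, Sequence[Region]],
        initial: Union[float, Callable, None] = 0.0,
        name: Optional[str] = None,
    ):
        super().__init__(name)
        if isinstance(regions, Region):
            regions = [regions]
        regions = list(regions)
        if not regions:
            raise SpeciesError("a State requires at least one region")
        self.regions = regions
        self.d = 0.0
        self.charge = None
        self.initial = initial
        self._on_region: dict[int, "SpeciesOnRegion"] = {}

    __getitem__ = Species.__getitem__
    nodes = Species.nodes


class Parameter(_Actor):
    """A constant: usable in rate expressions, untouched by integration."""

    _is_parameter = True

    def __init__(
        self,
        value: float,
        regions: Union[Region, Sequence[Region], None] = None,
        name: Optional[str] = None,
    ):
        super().__init__(name)
        if isinstance(regions, Region):
            regions = [regions]
        self.regions = None if regions is None else list(regions)
        self.value = float(value)


class SpeciesOnRegion(Arithmetic):
    """A species restricted to a single region (``ca[cyt]``-style handle)."""

    def __init__(self, species: Species, region: Region):
        super().__init__()
        self.species = species
        self.region = region

    @property
    def name(self) -> Optional[str]:
        base = self.species.name or f"species#{self.species._ref_id}"
        return f"{base}[{self.region.name}]"

    @property
    def nodes(self) -> list["Node"]:
        model = self.species._bound_model()
        return model._nodes_of(self.species, self.region)

    @property
    def concentration(self) -> np.ndarray:
        return np.array([n.concentration for n in self.nodes])

    @concentration.setter
    def concentration(self, value) -> None:
        nodes = self.nodes
        values = np.broadcast_to(np.asarray(value, float), (len(nodes),))
        for n, v in zip(nodes, values):
            n.concentration = v

    def __repr__(self) -> str:
        return f"SpeciesOnRegion({self.name})"


class Node:
    """One finite-volume location of one species on one region.

    A live view into the model's state vector: reading or assigning
    ``concentration`` touches exactly one state entry.
    """

    __slots__ = ("species", "region", "section", "segment", "x", "volume",
                 "index", "_model")

    def __init__(self, species, region: Region, section: Section, segment: int,
                 volume: float, index: int, model):
        self.species = species
        self.region = region
        self.section = section
        self.segment = segment
        self.x = (segment + 0.5) / section.nseg
        self.volume = volume
        self.index = index
        self._model = model

    @property
    def concentration(self) -> float:
        return float(self._model.state[self.index])

    @concentration.setter
    def concentration(self, value: float) -> None:
        self._model.state[self.index] = float(value)

    @property
    def surface_area(self) -> float:
        return self.region.surface_area(self.section, self.segment)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Node({self.species!r}, {self.region.name}, "
            f"{self.section.name}({self.x:.3f}))"
        )
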