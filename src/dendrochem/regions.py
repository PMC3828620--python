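"""Where chemistry lives: Regions and cross-sectional geometries.

A :class:`Region` is a set of sections together with a :class:`Geometry`
describing which part of the circular cross-section the region occupies.
The geometry supplies the three quantities the solver needs per segment:

* ``volume`` (µm³) — the finite-volume cell size,
* ``neighbor_area`` (µm²) — cross-sectional area available for longitudinal
  diffusive flux at a segment boundary,
* ``surface_area`` (µm²) — membrane-adjacent (lateral) area.

Built-in geometries cover the full cross-section, annular shells (e.g. the
submembrane shell between 90 and 100% of the radius), and fractional volumes
(an organelle such as the ER occupying a fraction fe of the cross-section).
Users may plug in their own geometry by implementing the same three
accessors.

Shells that do not reach the outer radius get zero plasma-membrane surface
area by default; a conceptual boundary between two adjacent shells is
expressed with a :class:`Membrane` at the dividing radius fraction, whose
area is that of the dividing cylinder.
"""

from __future__ import annotations

import abc
import math
from typing import Optional, Sequence

from .morphology import Section

__all__ = [
    "GeometryError",
    "Geometry",
    "FullCrossSection",
    "Shell",
    "FractionalVolume",
    "Region",
    "Membrane",
]


class GeometryError(ValueError):
    """Invalid geometry parameters or out-of-range segment/boundary index."""


def _check_segment(sec: Section, index: int) -> None:
    if not (0 <= index < sec.nseg):
        raise GeometryError(
            f"segment index {index} out of range for section {sec.name!r} "
            f"(nseg={sec.nseg})"
        )


def _check_boundary(sec: Section, boundary: int) -> None:
    if not (0 <= boundary <= sec.nseg):
        raise GeometryError(
            f"boundary index {boundary} out of range for section {sec.name!r} "
            f"(valid 0..{sec.nseg})"
        )


class Geometry(abc.ABC):
    """Cross-sectional geometry interface; all accessors return values ≥ 0."""

    @abc.abstractmethod
    def volume(self, sec: Section, index: int) -> float:
        """Volume (µm³) of segment ``index``."""

    @abc.abstractmethod
    def neighbor_area(self, sec: Section, boundary: int) -> float:
        """Cross-sectional flux area (µm²) at segment boundary ``boundary``."""

    @abc.abstractmethod
    def surface_area(self, sec: Section, index: int) -> float:
        """Membrane-adjacent area (µm²) of segment ``index``."""


class FullCrossSection(Geometry):
    """The whole circular cross-section π(d/2)²."""

    def volume(self, sec: Section, index: int) -> float:
        _check_segment(sec, index)
        return math.pi * (sec.diam / 2.0) ** 2 * sec.dx

    def neighbor_area(self, sec: Section, boundary: int) -> float:
        _check_boundary(sec, boundary)
        return math.pi * (sec.diam / 2.0) ** 2

    def surface_area(self, sec: Section, index: int) -> float:
        _check_segment(sec, index)
        return math.pi * sec.diam * sec.dx


class Shell(Geometry):
    """Annulus between radial fractions ``lo`` and ``hi`` of the radius.

    Only shells with ``hi == 1`` touch the plasma membrane and report a
    nonzero surface area.
    """

    def __init__(self, lo: float, hi: float):
        if not (0.0 <= lo < hi <= 1.0):
            raise GeometryError(f"require 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
        self.lo = float(lo)
        self.hi = float(hi)

    def neighbor_area(self, sec: Section, boundary: int) -> float:
        _check_boundary(sec, boundary)
        r = sec.diam / 2.0
        return math.pi * ((self.hi * r) ** 2 - (self.lo * r) ** 2)

    def volume(self, sec: Section, index: int) -> float:
        _check_segment(sec, index)
        return self.neighbor_area(sec, 0) * sec.dx

    def surface_area(self, sec: Section, index: int) -> float:
        _check_segment(sec, index)
        if self.hi == 1.0:
            return math.pi * sec.diam * sec.dx
        return 0.0

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Shell({self.lo}, {self.hi})"


class FractionalVolume(Geometry):
    """A fraction fe of the cross-sectional area (hence fe of the volume).

    Intended for complexly-shaped subsets of the cross-section (e.g. the ER
    network).  ``neighbor_areas_fraction`` defaults to the volume fraction;
    ``surface_fraction`` (of the lateral cylinder area) defaults to 0.
    """

    def __init__(
        self,
        volume_fraction: float,
        neighbor_areas_fraction: Optional[float] = None,
        surface_fraction: float = 0.0,
    ):
        if not (0.0 < volume_fraction <= 1.0):
            raise GeometryError(
                f"volume_fraction must be in (0, 1], got {volume_fraction}"
            )
        if neighbor_areas_fraction is None:
            neighbor_areas_fraction = volume_fraction
        for label, frac in (
            ("neighbor_areas_fraction", neighbor_areas_fraction),
            ("surface_fraction", surface_fraction),
        ):
            if not (0.0 <= frac <= 1.0):
                raise GeometryError(f"{label} must be in [0, 1], got {frac}")
        self.volume_fraction = float(volume_fraction)
        self.neighbor_areas_fraction = float(neighbor_areas_fraction)
        self.surface_fraction = float(surface_fraction)

    def volume(self, sec: Section, index: int) -> float:
        _check_segment(sec, index)
        return self.volume_fraction * math.pi * (sec.diam / 2.0) ** 2 * sec.dx

    def neighbor_area(self, sec: Section, boundary: int) -> float:
        _check_boundary(sec, boundary)
        return self.neighbor_areas_fraction * math.pi * (sec.diam / 2.0) ** 2

    def surface_area(self, sec: Section, index: int) -> float:
        _check_segment(sec, index)
        return self.surface_fraction * math.pi * sec.diam * sec.dx


class Region:
    """A set of sections plus a geometry: the domain where species live.

    ``nrn_region`` is a semantic tag ('i' for just inside the plasma
    membrane, 'o' for just outside, or None); it identifies the compartment
    for membrane-current bookkeeping but carries no other mechanics here.
    """

    _counter = 0

    def __init__(
        self,
        sections: Sequence[Section],
        nrn_region: Optional[str] = None,
        geometry: Optional[Geometry] = None,
        name: Optional[str] = None,
    ):
        sections = list(sections)
        if not sections:
            raise GeometryError("a Region requires at least one section")
        if nrn_region not in (None, "i", "o"):
            raise GeometryError(f"nrn_region must be 'i', 'o' or None, got {nrn_region!r}")
        self.sections = sections
        self.nrn_region = nrn_region
        self.geometry = geometry if geometry is not None else FullCrossSection()
        Region._counter += 1
        self.name = name if name is not None else f"region{Region._counter}"

    def __contains__(self, sec: Section) -> bool:
        return sec in self.sections

    def _require(self, sec: Section) -> None:
        if sec not in self.sections:
            raise GeometryError(
                f"section {sec.name!r} is not part of region {self.name!r}"
            )

    def volume(self, sec: Section, index: int) -> float:
        self._require(sec)
        return self.geometry.volume(sec, index)

    def neighbor_area(self, sec: Section, boundary: int) -> float:
        self._require(sec)
        return self.geometry.neighbor_area(sec, boundary)

    def surface_area(self, sec: Section, index: int) -> float:
        self._require(sec)
        return self.geometry.surface_area(sec, index)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Region({self.name!r}, {len(self.sections)} sections)"


class Membrane:
    """A two-dimensional surface separating two compartments.

    With ``radius_fraction=1`` (default) this is the plasma membrane with the
    lateral cylinder area π·d·L/nseg per segment; smaller fractions describe
    the dividing cylinder between adjacent shells (area π·f·d·L/nseg).
    ``sections=None`` means the membrane exists on every section.
    """

    def __init__(
        self,
        sections: Optional[Sequence[Section]] = None,
        radius_fraction: float = 1.0,
        name: Optional[str] = None,
    ):
        if not (0.0 < radius_fraction <= 1.0):
            raise GeometryError(
                f"radius_fraction must be in (0, 1], got {radius_fraction}"
            )
        self.sections = None if sections is None else list(sections)
        self.radius_fraction = float(radius_fraction)
        self.name = name or "membrane"

    def covers(self, sec: Section) -> bool:
        return self.sections is None or sec in self.sections

    def area(self, sec: Section, index: int) -> float:
        _check_segment(sec, index)
        if not self.covers(sec):
            return 0.0
        return math.pi * self.radius_fraction * sec.diam * sec.dx
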