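"""Reaction kinetics: Rate, Reaction, and MultiCompartmentReaction.

All three schemes implement the :class:`GeneralizedReaction` interface the
integrator consumes: a rate (flux) expression, a stoichiometry (source and
destination multiplicities), and a localization rule.  New kinds of kinetics
can be added by subclassing the same interface.

* :class:`Rate` adds an expression directly to the right-hand side of one
  variable's ODE (mM/ms for a Species, 1/ms for a unitless State).
* :class:`Reaction` is a single-compartment scheme like
  ``2*hydrogen + oxygen <-> water``.  With mass-action kinetics (default)
  the flux is kf·Πs^n − kb·Πp^m with the stoichiometric coefficients
  implicit, so d[hydrogen]/dt = −2·kf·hydrogen²·oxygen + 2·kb·water.  With
  ``mass_action=False`` kf and kb are the full forward/backward rates and
  d[oxygen]/dt = kb − kf, d[hydrogen]/dt = 2·(kb − kf).
* :class:`MultiCompartmentReaction` spans two compartments across a
  :class:`~dendrochem.regions.Membrane`: every reference must be
  region-qualified (``ca[cyt]``, not ``ca``), the flux carries
  molecules/(µm²·ms), is scaled by membrane area by default, and is
  converted to a per-compartment concentration rate by each compartment's
  volume.  With ``membrane_flux=True`` the molecular flux of each (charged)
  moving species is also reported as a membrane current density.

Unit-conversion constants live here as single named values so any
convention change is a one-line edit.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

from .expressions import (
    Arithmetic,
    Expression,
    as_expression,
    reactant_scheme,
    references,
)
from .regions import Membrane, Region
from .species import Parameter, Species, SpeciesOnRegion, State

__all__ = [
    "ReactionError",
    "GeneralizedReaction",
    "Rate",
    "Reaction",
    "MultiCompartmentReaction",
    "membrane_current_density",
    "MOLECULES_PER_UM3_PER_MM",
    "MM_PER_MOLECULE_PER_UM3",
    "ELEMENTARY_CHARGE",
    "CURRENT_PER_MOLECULAR_FLUX",
]

#: 1 mM expressed in molecules/µm³ (Avogadro·1e-3 mol/L · 1e-15 L/µm³)
MOLECULES_PER_UM3_PER_MM = 602214.129

#: converts molecules/µm³ to mM
MM_PER_MOLECULE_PER_UM3 = 1.0 / MOLECULES_PER_UM3_PER_MM

#: elementary charge, coulomb
ELEMENTARY_CHARGE = 1.602176634e-19

#: mA/cm² carried by a molecular flux of 1 molecule/(µm²·ms) at valence 1:
#: e [C] · 1e3 [ms→s] · 1e8 [µm⁻²→cm⁻²] · 1e3 [A→mA]
CURRENT_PER_MOLECULAR_FLUX = ELEMENTARY_CHARGE * 1e14


class ReactionError(ValueError):
    """Invalid kinetics specification."""


def membrane_current_density(flux, charge) -> np.ndarray:
    """Current density (mA/cm², outward positive) from a molecular flux.

    ``flux`` is in molecules/(µm²·ms) moving outward; ``charge`` is the
    species valence.
    """
    return np.asarray(flux, float) * float(charge) * CURRENT_PER_MOLECULAR_FLUX


def _scheme(expr) -> dict:
    return reactant_scheme(as_expression(expr))


class GeneralizedReaction:
    """Interface consumed by the integrator.

    Concrete kinetics expose:

    ``sources`` / ``dests``
        lists of (reference, multiplicity) pairs,
    ``flux_expression()``
        the Expression for the reaction flux,
    ``species_rhs()``
        map reference -> Expression contributed to that variable's RHS
        (before any geometric scaling),
    ``regions``
        optional localization override (None: wherever all actors coexist).
    """

    sources: list
    dests: list
    regions: Optional[Sequence[Region]] = None

    def flux_expression(self) -> Expression:
        raise NotImplementedError

    def species_rhs(self) -> dict:
        """Net contribution per reference: (dest − source multiplicity)·flux."""
        flux = self.flux_expression()
        mult: dict = {}
        for ref, m in self.sources:
            mult[ref] = mult.get(ref, 0) - m
        for ref, m in self.dests:
            mult[ref] = mult.get(ref, 0) + m
        return {ref: as_expression(m) * flux for ref, m in mult.items() if m != 0}

    def net_stoichiometry(self) -> dict:
        """Map reference -> net integer multiplicity (dests − sources)."""
        mult: dict = {}
        for ref, m in self.sources:
            mult[ref] = mult.get(ref, 0) - m
        for ref, m in self.dests:
            mult[ref] = mult.get(ref, 0) + m
        return mult


def _check_regions_arg(regions):
    if regions is None:
        return None
    if isinstance(regions, Region):
        return [regions]
    return list(regions)


class Rate(GeneralizedReaction):
    """Add ``expr`` directly to the RHS of ``target``'s differential equation."""

    def __init__(self, target, expr, regions=None):
        if not isinstance(target, (Species, State, SpeciesOnRegion)):
            raise ReactionError(
                "Rate target must be a Species, State or region-restricted species"
            )
        self.target = target
        self.expr = as_expression(expr)
        self.sources = []
        self.dests = [(target, 1)]
        self.regions = _check_regions_arg(regions)

    def flux_expression(self) -> Expression:
        return self.expr


class Reaction(GeneralizedReaction):
    """A single-compartment reaction scheme ``lhs <-> rhs``."""

    def __init__(self, lhs, rhs, kf, kb=0.0, mass_action: bool = True,
                 regions=None):
        self.lhs = _scheme(lhs)
        self.rhs = _scheme(rhs)
        for ref in list(self.lhs) + list(self.rhs):
            if isinstance(ref, Parameter):
                raise ReactionError("parameters cannot appear in reactant schemes")
        self.kf = as_expression(kf)
        self.kb = as_expression(kb)
        self.mass_action = bool(mass_action)
        self.regions = _check_regions_arg(regions)
        self.sources = sorted(self.lhs.items(), key=lambda kv: kv[0]._ref_id)
        self.dests = sorted(self.rhs.items(), key=lambda kv: kv[0]._ref_id)

    def flux_expression(self) -> Expression:
        if not self.mass_action:
            return self.kf - self.kb
        fwd = self.kf
        for ref, m in self.sources:
            fwd = fwd * (as_expression(ref) ** m if m > 1 else as_expression(ref))
        back = self.kb
        for ref, m in self.dests:
            back = back * (as_expression(ref) ** m if m > 1 else as_expression(ref))
        return fwd - back


class MultiCompartmentReaction(Reaction):
    """A reaction spanning compartments, scaled by membrane area.

    Every reference must be region-qualified.  The flux expression carries
    molecules/(µm²·ms); per compartment k the concentration rate is
    flux · area / V_k · U with U = :data:`MM_PER_MOLECULE_PER_UM3`
    (``scale_by_area=False`` replaces the area factor by 1).  For the
    default mass-action case the rate constants are interpreted so that the
    flux still carries molecules/(µm²·ms) after multiplying by mM
    concentration powers, i.e. kf has units molecules·µm^(3n−2)·mM^(−n)/ms
    for total source multiplicity n.
    """

    def __init__(self, lhs, rhs, kf, kb=0.0, *, membrane: Membrane,
                 mass_action: bool = True, membrane_flux: bool = False,
                 scale_by_area: bool = True, regions=None):
        super().__init__(lhs, rhs, kf, kb, mass_action=mass_action,
                         regions=regions)
        for ref in list(self.lhs) + list(self.rhs):
            if not isinstance(ref, SpeciesOnRegion):
                raise ReactionError(
                    "all MultiCompartmentReaction references must be "
                    "region-qualified (write ca[cyt], not ca)"
                )
        if not isinstance(membrane, Membrane):
            raise ReactionError("membrane= must be a Membrane instance")
        self.membrane = membrane
        self.membrane_flux = bool(membrane_flux)
        self.scale_by_area = bool(scale_by_area)
        if self.membrane_flux:
            for sp in self.moving_species():
                if sp.charge is None:
                    raise ReactionError(
                        "membrane_flux=True: the charge of an individual ion "
                        f"must be specified ({sp!r} has none)"
                    )

    def moving_species(self) -> list:
        """Species with a nonzero net multiplicity (they cross the membrane)."""
        seen = []
        for ref, m in self.net_stoichiometry().items():
            if m != 0 and ref.species not in seen:
                seen.append(ref.species)
        return seen

    def outward_sign(self, ref: SpeciesOnRegion) -> int:
        """+1 if net production at ``ref`` is on the outward side.

        The inward compartment is the one tagged ``nrn_region='i'`` if any
        side carries the tag; otherwise the source side is taken as inward.
        """
        regions = {r.region for r, _ in self.sources} | {
            r.region for r, _ in self.dests
        }
        inside = [r for r in regions if r.nrn_region == "i"]
        if inside:
            return -1 if ref.region in inside else 1
        source_regions = {r.region for r, _ in self.sources}
        return -1 if ref.region in source_regions else 1

    def current_density_factor(self) -> float:
        """Σ z·m·direction over moving references — current density per unit
        molecular flux (mA/cm² per molecule/(µm²·ms))."""
        total = 0.0
        for ref, m in self.net_stoichiometry().items():
            if m <= 0:  # count each transfer once, on its production side
                continue
            z = ref.species.charge
            if z is None:
                continue
            total += z * m * self.outward_sign(ref)
        return total * CURRENT_PER_MOLECULAR_FLUX
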