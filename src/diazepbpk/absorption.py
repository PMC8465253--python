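"""Route-specific dose inputs and bioavailability accounting.

Turns a study arm into the dosing terms of the whole-body ODE system:
an IV bolus or zero-order infusion into venous blood, a first-order
depot (intranasal, rectal), or a linear transit chain of intestinal
segments (oral) whose per-segment absorption rate constant derives from
the effective jejunal permeability.  The transit chain is a deliberate
structural simplification of segmented gut absorption models: diazepam
doses are small and the compound highly permeable, so dissolution is
not rate-limiting and absorption reduces to permeability vs transit
competition.

Bioavailability is decomposed per F = Fa * Fg * Fh from the
simulation's flux ledgers: Fa from lumen/depot accounting, Fg from
gut-wall metabolism (1 when disabled, the default), and Fh from the
liver's extraction of the portally delivered stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np

from .config import (
    DrugParameters, FirstPassTarget, Route, RouteParameters, StudyDesign,
    SMALL_INTESTINE_RADIUS_CM,
)

if TYPE_CHECKING:  # pragma: no cover
    from .engine import SimulationResult

__all__ = [
    "BolusEvent", "ZeroOrderRate", "FirstOrderDepot", "TransitState",
    "DoseInput", "BioavailabilityComponents", "build_dose_input",
    "segment_ka_from_peff", "oral_transit_step", "fraction_absorbed_closed_form",
    "bioavailability_components", "N_SEGMENTS", "SMALL_INTESTINE_TRANSIT_H",
]

N_SEGMENTS = 7
#: mean small-intestinal transit time, h
SMALL_INTESTINE_TRANSIT_H = 3.32
MG_TO_NG = 1e6


def segment_ka_from_peff(peff: float, radius_cm: float = SMALL_INTESTINE_RADIUS_CM) -> float:
    """Per-segment absorption rate constant (1/h) from Peff (1e-4 cm/s)."""
    return 2.0 * peff * 1e-4 / radius_cm * 3600.0


@dataclass(frozen=True)
class BolusEvent:
    time: float          # h
    amount: float        # ng
    compartment: str     # 'venous'


@dataclass(frozen=True)
class ZeroOrderRate:
    start: float         # h
    end: float           # h
    rate: float          # ng/h
    compartment: str


@dataclass(frozen=True)
class FirstOrderDepot:
    depot_id: str
    amount: float        # ng, initial
    ka: float            # 1/h
    fa: float
    target: FirstPassTarget


@dataclass
class TransitState:
    """State of the linear intestinal transit chain."""

    n_segments: int = N_SEGMENTS
    segment_amounts: np.ndarray = field(
        default_factory=lambda: np.zeros(N_SEGMENTS))
    transit_rate: float = N_SEGMENTS / SMALL_INTESTINE_TRANSIT_H  # 1/h per segment
    segment_ka: float = 0.0  # 1/h, same in every segment

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.transit_rate <= 0:
            raise ValueError("transit_rate must be > 0")
        self.segment_amounts = np.asarray(self.segment_amounts, dtype=float)
        if self.segment_amounts.shape != (self.n_segments,):
            raise ValueError("segment_amounts length must equal n_segments")


@dataclass(frozen=True)
class TransitFluxes:
    d_segments: np.ndarray   # ng/h per segment
    absorbed_flux: float     # ng/h into the portal stream
    exit_flux: float         # ng/h unabsorbed loss from the last segment


@dataclass(frozen=True)
class DoseInput:
    route: Route
    dose: float                              # ng, scheduled study dose
    bolus_events: tuple[BolusEvent, ...] = ()
    zero_order_rates: tuple[ZeroOrderRate, ...] = ()
    first_order_depots: tuple[FirstOrderDepot, ...] = ()
    transit: Optional[TransitState] = None
    unscheduled_loss: float = 0.0            # ng lost before absorption (1-fa)

    def __post_init__(self) -> None:
        scheduled = self.unscheduled_loss
        scheduled += sum(b.amount for b in self.bolus_events)
        scheduled += sum(z.rate * (z.end - z.start) for z in self.zero_order_rates)
        scheduled += sum(d.amount for d in self.first_order_depots)
        if self.transit is not None:
            scheduled += float(self.transit.segment_amounts.sum())
        if abs(scheduled - self.dose) > 1e-6 * max(self.dose, 1.0):
            raise ValueError(
                f"schedulable dose {scheduled} ng does not match study dose {self.dose} ng")


def build_dose_input(study: StudyDesign, drug: DrugParameters) -> DoseInput:
    """Dose-input terms of the ODE system for one study arm."""
    rp: RouteParameters = study.route_parameters
    dose_ng = study.dose * MG_TO_NG
    route = rp.route
    if route is Route.IV_BOLUS:
        return DoseInput(route=route, dose=dose_ng,
                         bolus_events=(BolusEvent(0.0, dose_ng, "venous"),))
    if route is Route.IV_INFUSION:
        t_inf = rp.infusion_duration or 1.0
        return DoseInput(route=route, dose=dose_ng, zero_order_rates=(
            ZeroOrderRate(0.0, t_inf, dose_ng / t_inf, "venous"),))
    if route is Route.ORAL:
        seg_ka = segment_ka_from_peff(drug.peff)
        amounts = np.zeros(N_SEGMENTS)
        amounts[0] = rp.fa * dose_ng
        transit = TransitState(segment_amounts=amounts, segment_ka=seg_ka)
        return DoseInput(route=route, dose=dose_ng, transit=transit,
                         unscheduled_loss=(1.0 - rp.fa) * dose_ng)
    if route is Route.INTRANASAL:
        depot = FirstOrderDepot("nasal", rp.fa * dose_ng, rp.ka, rp.fa,
                                FirstPassTarget.SYSTEMIC)
        return DoseInput(route=route, dose=dose_ng, first_order_depots=(depot,),
                         unscheduled_loss=(1.0 - rp.fa) * dose_ng)
    if route is Route.RECTAL:
        bypass = rp.portal_bypass_fraction
        depots = []
        portal_amount = rp.fa * dose_ng * (1.0 - bypass)
        systemic_amount = rp.fa * dose_ng * bypass
        if portal_amount > 0:
            depots.append(FirstOrderDepot("rectal_portal", portal_amount, rp.ka,
                                          rp.fa, FirstPassTarget.PORTAL))
        if systemic_amount > 0:
            depots.append(FirstOrderDepot("rectal_systemic", systemic_amount, rp.ka,
                                          rp.fa, FirstPassTarget.SYSTEMIC))
        return DoseInput(route=route, dose=dose_ng, first_order_depots=tuple(depots),
                         unscheduled_loss=(1.0 - rp.fa) * dose_ng)
    raise ValueError(f"unknown route/formulation combination: {route}, {rp.formulation}")


def oral_transit_step(state: TransitState, peff: Optional[float] = None) -> TransitFluxes:
    """Instantaneous fluxes of the transit chain.

    Every segment loses drug at (segment_ka + transit_rate); upstream
    transit feeds the next segment; the final segment's transit flux
    leaves the gut unabsorbed.
    """
    ka = segment_ka_from_peff(peff) if peff is not None else state.segment_ka
    kt = state.transit_rate
    a = state.segment_amounts
    d = np.empty_like(a)
    d[0] = -(ka + kt) * a[0]
    if state.n_segments > 1:
        d[1:] = kt * a[:-1] - (ka + kt) * a[1:]
    absorbed = float(ka * a.sum())
    exit_flux = float(kt * a[-1])
    return TransitFluxes(d_segments=d, absorbed_flux=absorbed, exit_flux=exit_flux)


def fraction_absorbed_closed_form(ka: float, kt: float, n: int = N_SEGMENTS) -> float:
    """Analytic Fa of the n-segment chain with uniform ka and kt.

    Each segment absorbs ka/(ka+kt) of what enters it, so
    Fa = 1 - (kt/(ka+kt))^n.
    """
    if ka < 0 or kt < 0 or (ka + kt) == 0:
        raise ValueError("rates must be non-negative with ka + kt > 0")
    return 1.0 - (kt / (ka + kt)) ** n


@dataclass(frozen=True)
class BioavailabilityComponents:
    fa: float
    fg: float
    fh: float
    f: float


def bioavailability_components(sim: "SimulationResult") -> BioavailabilityComponents:
    """Decompose systemic availability F = Fa * Fg * Fh from flux ledgers.

    Fa is total absorbed drug over the scheduled dose.  Fg uses gut-wall
    metabolism (zero by default, so Fg = 1).  Fh = 1 - E_h with E_h the
    liver's cumulative extraction ratio, applied to the portally
    absorbed share of the dose; drug absorbed directly into venous
    blood escapes first pass by construction.  IV routes return all
    ones.
    """
    acct = sim.flux_accounting
    dose = acct["dose_ng"]
    if sim.route in (Route.IV_BOLUS, Route.IV_INFUSION):
        return BioavailabilityComponents(1.0, 1.0, 1.0, 1.0)
    absorbed_portal = acct["absorbed_portal_ng"]
    absorbed_systemic = acct["absorbed_systemic_ng"]
    absorbed = absorbed_portal + absorbed_systemic
    fa = absorbed / dose
    gut_met = acct.get("gut_metabolized_ng", 0.0)
    fg = 1.0 - gut_met / absorbed if absorbed > 0 else 1.0
    throughput = acct["liver_throughput_ng"]
    eliminated = acct["hepatic_eliminated_ng"]
    e_h = eliminated / throughput if throughput > 0 else 0.0
    if absorbed > 0:
        portal_share = absorbed_portal / absorbed
    else:
        portal_share = 0.0
    # first-pass escape applies only to the portally routed stream
    fh = 1.0 - portal_share * e_h
    return BioavailabilityComponents(fa=fa, fg=fg, fh=fh, f=fa * fg * fh)
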