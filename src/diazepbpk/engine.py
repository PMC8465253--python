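"""Whole-body perfusion-limited PBPK engine.

One individual is a set of twelve well-stirred tissue compartments
(adipose, bone, brain, gut, heart, kidney, liver, lung, muscle,
pancreas, skin, spleen) connected by blood flows, with venous and
arterial blood pools and the lung in series with cardiac output.  Gut,
pancreas and spleen drain into the portal vein and hence through the
liver, where drug is eliminated by saturable microsomal metabolism
driven by the unbound concentration of the liver's emergent plasma.
All amounts are in ng, volumes in L, flows in L/h, time in h; plasma
concentrations are reported in ng/mL.

Virtual populations are sampled around a reference adult: organ volumes
scale linearly with body weight, blood flows allometrically
(weight^0.75), enzyme abundances and flows carry lognormal
between-subject variability, and female subjects get a 15% reduction in
liver weight and cardiac output.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .absorption import DoseInput, build_dose_input, oral_transit_step
from .clearance import (DEFAULT_ABUNDANCES, DEFAULT_LIVER_WEIGHT_G,
                        DEFAULT_MPPGL, LiverScaling)
from .config import (DrugParameters, FirstPassTarget, Route, StudyDesign)
from .partition import TISSUES, predict_all_kp

__all__ = [
    "IndividualPhysiology", "SimulationResult", "PopulationSummary",
    "PopulationVariability", "SolverOptions", "load_reference_physiology",
    "reference_individual", "sample_individual", "simulate_profile",
    "run_trial", "ReferencePhysiology",
]

PORTAL_TISSUES = ("gut", "pancreas", "spleen")
SYSTEMIC_TISSUES = tuple(t for t in TISSUES if t not in PORTAL_TISSUES + ("liver", "lung"))
REFERENCE_BODY_WEIGHT = 70.0


@dataclass(frozen=True)
class ReferencePhysiology:
    body_weight: float
    volumes: Mapping[str, float]       # L, 12 tissues
    flows: Mapping[str, float]         # L/h, 11 systemic tissues (liver = arterial)
    venous_volume: float
    arterial_volume: float
    plasma_volume: float
    erythrocyte_volume: float

    @property
    def blood_volume(self) -> float:
        return self.venous_volume + self.arterial_volume

    @property
    def hematocrit(self) -> float:
        return self.erythrocyte_volume / (self.erythrocyte_volume + self.plasma_volume)


_REFERENCE_CACHE: Optional[ReferencePhysiology] = None


def load_reference_physiology(path=None) -> ReferencePhysiology:
    """Reference adult volumes/flows from the packaged (or a user) CSV."""
    global _REFERENCE_CACHE
    if path is None and _REFERENCE_CACHE is not None:
        return _REFERENCE_CACHE
    if path is None:
        text = resources.files("diazepbpk.data").joinpath("reference_physiology.csv").read_text()
        df = pd.read_csv(io.StringIO(text), comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    df = df.set_index("compartment")
    volumes = {t: float(df.loc[t, "volume_L"]) for t in TISSUES}
    flows = {t: float(df.loc[t, "flow_L_per_h"]) for t in TISSUES if t != "lung"}
    ref = ReferencePhysiology(
        body_weight=REFERENCE_BODY_WEIGHT,
        volumes=volumes,
        flows=flows,
        venous_volume=float(df.loc["venous_blood", "volume_L"]),
        arterial_volume=float(df.loc["arterial_blood", "volume_L"]),
        plasma_volume=float(df.loc["plasma", "volume_L"]),
        erythrocyte_volume=float(df.loc["erythrocytes", "volume_L"]),
    )
    if path is None:
        _REFERENCE_CACHE = ref
    return ref


@dataclass(frozen=True)
class IndividualPhysiology:
    body_weight: float                     # kg
    sex: str                               # 'male' | 'female'
    age: float                             # years
    tissue_volumes: Mapping[str, float]    # L
    blood_flows: Mapping[str, float]       # L/h; 'liver' is hepatic arterial
    cardiac_output: float                  # L/h
    plasma_volume: float                   # L
    blood_volume: float                    # L
    venous_volume: float
    arterial_volume: float
    hematocrit: float
    liver_scaling: LiverScaling

    def __post_init__(self) -> None:
        total = sum(self.blood_flows.values())
        if not math.isclose(total, self.cardiac_output, rel_tol=1e-6):
            raise ValueError(
                f"systemic flows sum to {total} L/h but cardiac_output is {self.cardiac_output}")
        if any(v <= 0 for v in self.tissue_volumes.values()) or any(
                q <= 0 for q in self.blood_flows.values()):
            raise ValueError("volumes and flows must all be > 0")

    @property
    def liver_blood_flow(self) -> float:
        return self.blood_flows["liver"] + sum(self.blood_flows[t] for t in PORTAL_TISSUES)


def reference_individual(sex: str = "male", age: float = 30.0) -> IndividualPhysiology:
    ref = load_reference_physiology()
    return IndividualPhysiology(
        body_weight=ref.body_weight, sex=sex, age=age,
        tissue_volumes=dict(ref.volumes), blood_flows=dict(ref.flows),
        cardiac_output=sum(ref.flows.values()),
        plasma_volume=ref.plasma_volume, blood_volume=ref.blood_volume,
        venous_volume=ref.venous_volume, arterial_volume=ref.arterial_volume,
        hematocrit=ref.hematocrit,
        liver_scaling=LiverScaling(
            hepatic_blood_flow=ref.flows["liver"] + sum(ref.flows[t] for t in PORTAL_TISSUES)),
    )


@dataclass(frozen=True)
class PopulationVariability:
    """Between-subject variability settings (lognormal CVs)."""

    cv_abundance: float = 0.30
    cv_flow: float = 0.20
    cv_kp: float = 0.0
    cv_weight_when_mean_only: float = 0.15
    female_liver_factor: float = 0.85
    female_co_factor: float = 0.85


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    if cv <= 0:
        return np.ones(size) if size else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def sample_individual(study: StudyDesign, rng: np.random.Generator,
                      variability: PopulationVariability | None = None) -> IndividualPhysiology:
    """Draw one virtual subject consistent with the study demographics."""
    import warnings

    var = variability or PopulationVariability()
    ref = load_reference_physiology()
    female = rng.random() < study.female_proportion
    age = float(rng.uniform(*study.age_range))
    if study.weight_range is None:
        warnings.warn(f"study {study.label}: no weight information, "
                      "sampling around the reference adult", UserWarning, stacklevel=2)
        weight = float(ref.body_weight * _lognormal_factor(rng, var.cv_weight_when_mean_only))
    elif study.weight_range[0] == study.weight_range[1]:
        weight = float(study.weight_range[0] * _lognormal_factor(
            rng, var.cv_weight_when_mean_only))
    else:
        weight = float(rng.uniform(*study.weight_range))
    wr = weight / ref.body_weight
    volumes = {t: v * wr for t, v in ref.volumes.items()}
    co_factor = var.female_co_factor if female else 1.0
    flows = {}
    for t, q in ref.flows.items():
        flows[t] = q * wr ** 0.75 * co_factor * float(_lognormal_factor(rng, var.cv_flow))
    liver_factor = var.female_liver_factor if female else 1.0
    liver_weight = DEFAULT_LIVER_WEIGHT_G * wr * liver_factor
    volumes["liver"] = ref.volumes["liver"] * wr * liver_factor
    abundances = {iso: ab * float(_lognormal_factor(rng, var.cv_abundance))
                  for iso, ab in DEFAULT_ABUNDANCES.items()}
    q_liver_total = flows["liver"] + sum(flows[t] for t in PORTAL_TISSUES)
    return IndividualPhysiology(
        body_weight=weight, sex="female" if female else "male", age=age,
        tissue_volumes=volumes, blood_flows=flows,
        cardiac_output=sum(flows.values()),
        plasma_volume=ref.plasma_volume * wr, blood_volume=ref.blood_volume * wr,
        venous_volume=ref.venous_volume * wr, arterial_volume=ref.arterial_volume * wr,
        hematocrit=ref.hematocrit,
        liver_scaling=LiverScaling(abundances=abundances, mppgl=DEFAULT_MPPGL,
                                   liver_weight=liver_weight,
                                   hepatic_blood_flow=q_liver_total),
    )


@dataclass(frozen=True)
class SolverOptions:
    rtol: float = 1e-8
    atol: float = 1e-2          # ng
    method: str = "LSODA"
    max_step: float = np.inf


@dataclass
class SimulationResult:
    times: np.ndarray                      # h
    plasma_conc: np.ndarray                # ng/mL (venous plasma)
    compartment_amounts: dict[str, np.ndarray]  # ng
    eliminated: np.ndarray                 # ng, cumulative
    flux_accounting: dict[str, float]
    mass_balance_residual: float           # max relative residual
    route: Route
    dose: float                            # ng
    subject_index: int = 0

    def __post_init__(self) -> None:
        if np.any(self.plasma_conc < -1e-9):
            raise ValueError("negative plasma concentrations beyond tolerance")
        self.plasma_conc = np.maximum(self.plasma_conc, 0.0)
        if np.any(np.diff(self.eliminated) < -1e-6 * max(self.dose, 1.0)):
            raise ValueError("cumulative elimination must be non-decreasing")
        if self.mass_balance_residual >= 1e-6:
            raise ValueError(
                f"mass-balance residual {self.mass_balance_residual:.3e} exceeds 1e-6")


class _ModelLayout:
    """State-vector layout and right-hand side for one subject."""

    def __init__(self, individual: IndividualPhysiology, drug: DrugParameters,
                 kp: Mapping[str, float], dose_input: DoseInput,
                 linear_clearance: Optional[float] = None):
        self.ind = individual
        self.drug = drug
        self.kp = dict(kp)
        self.dose_input = dose_input
        # optional first-order hepatic clearance (unbound intrinsic, L/h)
        # replacing the saturable microsomal rate; used by oracle tests
        self.linear_clearance = linear_clearance

        names = ["venous", "arterial", "lung"] + list(t for t in TISSUES if t != "lung")
        self.tissue_names = names[3:]
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        self.i_elim = n; n += 1
        self.i_liver_in = n; n += 1       # cumulative liver inflow, ng
        self.i_abs_portal = n; n += 1
        self.i_abs_systemic = n; n += 1
        self.i_transit_out = n; n += 1
        self.i_lumen = None
        if dose_input.transit is not None:
            self.i_lumen = n
            n += dose_input.transit.n_segments
        self.i_depots = {}
        for depot in dose_input.first_order_depots:
            self.i_depots[depot.depot_id] = n
            n += 1
        self.idx = idx
        self.n_states = n

        ind = individual
        self.v = np.array([ind.venous_volume, ind.arterial_volume,
                           ind.tissue_volumes["lung"]] +
                          [ind.tissue_volumes[t] for t in self.tissue_names])
        self.q = {t: ind.blood_flows[t] for t in ind.blood_flows}
        self.co = ind.cardiac_output
        self.q_liver_total = ind.liver_blood_flow
        self.bp = drug.bp_ratio
        # blood-basis partition: C_out,blood = C_tissue * bp / Kp
        self.out_factor = np.array(
            [1.0, 1.0, self.bp / self.kp["lung"]] +
            [self.bp / self.kp[t] for t in self.tissue_names])
        # hepatic elimination scale: vmax per entry in ng/h
        ls = ind.liver_scaling
        ls.require_isoforms(drug.enzyme_kinetics)
        self.mm_vmax = np.array([
            k.vmax * ls.abundances[k.isoform] * ls.mppgl * ls.liver_weight
            * 60.0 * drug.molecular_weight / 1000.0
            for k in drug.enzyme_kinetics])   # ng/h
        self.mm_km = np.array([k.km for k in drug.enzyme_kinetics])  # uM
        self.fu_mic = drug.fu_mic
        self.i_liver_state = idx["liver"]
        self.v_liver = ind.tissue_volumes["liver"]
        self.kp_liver = self.kp["liver"]

    def hepatic_rate(self, a_liver: float) -> float:
        """Metabolic elimination rate (ng/h) from the liver amount."""
        c_liver = a_liver / self.v_liver               # ng/L
        c_plasma_eq = c_liver / self.kp_liver          # ng/L emergent plasma
        cu_ngl = self.drug.fu_plasma * c_plasma_eq     # ng/L unbound
        if self.linear_clearance is not None:
            return self.linear_clearance * cu_ngl  # L/h * ng/L = ng/h
        cu_um = cu_ngl / 1000.0 / self.drug.molecular_weight  # ug/L -> uM
        c_eff = cu_um / self.fu_mic
        return float(np.sum(self.mm_vmax * c_eff / (self.mm_km + c_eff)))

    def rhs(self, t: float, y: np.ndarray, infusion_rate: float) -> np.ndarray:
        dy = np.zeros_like(y)
        idx = self.idx
        c = y[:len(self.v)] / self.v          # compartment concentrations
        c_out = c * self.out_factor           # emergent blood concentrations
        c_vb = c_out[idx["venous"]]
        c_ab = c_out[idx["arterial"]]

        venous_in = 0.0
        for t_name in SYSTEMIC_TISSUES:
            i = idx[t_name]
            qi = self.q[t_name]
            dy[i] = qi * (c_ab - c_out[i])
            venous_in += qi * c_out[i]

        # portal organs feed the liver
        portal_in = 0.0
        for t_name in PORTAL_TISSUES:
            i = idx[t_name]
            qi = self.q[t_name]
            dy[i] = qi * (c_ab - c_out[i])
            portal_in += qi * c_out[i]

        # absorption inputs
        abs_portal_flux = 0.0
        abs_systemic_flux = 0.0
        if self.dose_input.transit is not None:
            chain = self.dose_input.transit
            lum = y[self.i_lumen:self.i_lumen + chain.n_segments]
            state = replace(chain, segment_amounts=lum)
            fluxes = oral_transit_step(state)
            dy[self.i_lumen:self.i_lumen + chain.n_segments] = fluxes.d_segments
            abs_portal_flux += fluxes.absorbed_flux
            dy[self.i_transit_out] = fluxes.exit_flux
        for depot in self.dose_input.first_order_depots:
            i = self.i_depots[depot.depot_id]
            release = depot.ka * y[i]
            dy[i] = -release
            if depot.target is FirstPassTarget.PORTAL:
                abs_portal_flux += release
            else:
                abs_systemic_flux += release

        # liver
        i_liv = idx["liver"]
        liver_in = self.q["liver"] * c_ab + portal_in + abs_portal_flux
        elim = self.hepatic_rate(y[i_liv])
        dy[i_liv] = liver_in - self.q_liver_total * c_out[i_liv] - elim
        dy[self.i_elim] = elim
        dy[self.i_liver_in] = liver_in
        dy[self.i_abs_portal] = abs_portal_flux
        dy[self.i_abs_systemic] = abs_systemic_flux + infusion_rate
        venous_in += self.q_liver_total * c_out[i_liv]

        # lung in series between venous and arterial pools
        i_lu = idx["lung"]
        dy[i_lu] = self.co * (c_vb - c_out[i_lu])
        dy[idx["venous"]] = venous_in + abs_systemic_flux + infusion_rate - self.co * c_vb
        dy[idx["arterial"]] = self.co * (c_out[i_lu] - c_ab)
        return dy

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(self.n_states)
        for b in self.dose_input.bolus_events:
            if b.time != 0.0:
                raise NotImplementedError("only t=0 boluses are supported")
            y0[self.idx[b.compartment]] += b.amount
            y0[self.i_abs_systemic] += b.amount
        if self.dose_input.transit is not None:
            chain = self.dose_input.transit
            y0[self.i_lumen:self.i_lumen + chain.n_segments] = chain.segment_amounts
        for depot in self.dose_input.first_order_depots:
            y0[self.i_depots[depot.depot_id]] = depot.amount
        return y0


def simulate_profile(individual: IndividualPhysiology, drug: DrugParameters,
                     dose_input: DoseInput, sampling_times: Sequence[float],
                     kp: Optional[Mapping[str, float]] = None,
                     solver_options: Optional[SolverOptions] = None,
                     linear_clearance: Optional[float] = None,
                     subject_index: int = 0) -> SimulationResult:
    """Integrate the whole-body system for one subject.

    ``linear_clearance`` (unbound intrinsic clearance, L/h) replaces the
    saturable microsomal rate with a first-order one; it exists for
    closed-form cross-checks.
    """
    opts = solver_options or SolverOptions()
    if kp is None:
        kp = predict_all_kp(drug)
    layout = _ModelLayout(individual, drug, kp, dose_input, linear_clearance)
    times = np.asarray(sampling_times, dtype=float)
    if times[0] < 0:
        raise ValueError("sampling times must be >= 0")

    # piecewise integration across zero-order-rate breakpoints
    breaks = sorted({0.0, float(times[-1])} | {
        tt for z in dose_input.zero_order_rates for tt in (z.start, z.end)
        if 0.0 < tt < times[-1]})
    y = layout.initial_state()
    collected_t = [0.0]
    collected_y = [y.copy()]
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        rate = sum(z.rate for z in dose_input.zero_order_rates
                   if z.start <= t0 and z.end >= t1 - 1e-12 and z.start < z.end)
        t_eval = times[(times > t0 + 1e-15) & (times <= t1 + 1e-15)]
        t_eval = np.unique(np.concatenate([t_eval, [t1]]))
        sol = solve_ivp(layout.rhs, (t0, t1), y, t_eval=t_eval,
                        args=(rate,), method=opts.method,
                        rtol=opts.rtol, atol=opts.atol, max_step=opts.max_step)
        if not sol.success:
            raise RuntimeError(f"ODE solver failed: {sol.message}")
        y = sol.y[:, -1].copy()
        for i, tt in enumerate(sol.t):
            if tt > collected_t[-1] + 1e-15:
                collected_t.append(float(tt))
                collected_y.append(sol.y[:, i].copy())
    grid_t = np.array(collected_t)
    grid_y = np.array(collected_y).T
    # interpolate back onto requested sampling times
    out = np.empty((layout.n_states, times.size))
    for i in range(layout.n_states):
        out[i] = np.interp(times, grid_t, grid_y[i])

    idx = layout.idx
    c_venous_blood = out[idx["venous"]] / individual.venous_volume  # ng/L
    plasma_conc = c_venous_blood / drug.bp_ratio / 1000.0           # ng/mL

    # mass balance: everything scheduled so far must be accounted for
    scheduled = np.full(times.size, dose_input.unscheduled_loss)
    scheduled += sum(b.amount for b in dose_input.bolus_events)
    scheduled += sum(d.amount for d in dose_input.first_order_depots)
    if dose_input.transit is not None:
        scheduled += dose_input.transit.segment_amounts.sum()
    for z in dose_input.zero_order_rates:
        scheduled += z.rate * np.clip(times, z.start, z.end) - z.rate * z.start
    in_system = out[:len(layout.v)].sum(axis=0) + out[layout.i_elim] + out[layout.i_transit_out]
    if layout.i_lumen is not None:
        nseg = dose_input.transit.n_segments
        in_system += out[layout.i_lumen:layout.i_lumen + nseg].sum(axis=0)
    for i in layout.i_depots.values():
        in_system += out[i]
    in_system += dose_input.unscheduled_loss
    residual = float(np.max(np.abs(in_system - scheduled)) / max(dose_input.dose, 1.0))

    amounts = {name: out[idx[name]] for name in idx}
    flux = {
        "dose_ng": dose_input.dose,
        "absorbed_portal_ng": float(out[layout.i_abs_portal, -1]),
        "absorbed_systemic_ng": float(out[layout.i_abs_systemic, -1]),
        "hepatic_eliminated_ng": float(out[layout.i_elim, -1]),
        "liver_throughput_ng": float(out[layout.i_liver_in, -1]),
        "gut_metabolized_ng": 0.0,
        "unabsorbed_ng": float(out[layout.i_transit_out, -1]) + dose_input.unscheduled_loss,
    }
    return SimulationResult(
        times=times, plasma_conc=plasma_conc, compartment_amounts=amounts,
        eliminated=out[layout.i_elim], flux_accounting=flux,
        mass_balance_residual=residual, route=dose_input.route,
        dose=dose_input.dose, subject_index=subject_index)


@dataclass
class PopulationSummary:
    times: np.ndarray
    mean: np.ndarray
    p5: np.ndarray
    p95: np.ndarray
    minimum: np.ndarray
    maximum: np.ndarray
    n: int
    seed: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        tol = 1e-9 * (1.0 + np.abs(self.maximum))
        ok = (
            np.all(self.minimum <= self.p5 + tol)
            and np.all(self.p5 <= self.p95 + tol)
            and np.all(self.p95 <= self.maximum + tol)
            and np.all(self.minimum <= self.mean + tol)
            and np.all(self.mean <= self.maximum + tol)
        )
        if not ok:
            raise ValueError("summary ordering invariant violated")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.times, "mean": self.mean, "p5": self.p5,
            "p95": self.p95, "min": self.minimum, "max": self.maximum})


def run_trial(study: StudyDesign, drug: DrugParameters,
              n_virtual: Optional[int] = None, seed: Optional[int] = None,
              variability: Optional[PopulationVariability] = None,
              solver_options: Optional[SolverOptions] = None,
              kp: Optional[Mapping[str, float]] = None,
              ) -> tuple[PopulationSummary, list[SimulationResult]]:
    """Simulate a virtual population for one study arm.

    Fully reproducible: subject i is driven by the i-th spawn of the
    seed sequence, so the same (study, seed, n) always yields identical
    populations.
    """
    n = n_virtual if n_virtual is not None else study.n_virtual
    if n < 1:
        raise ValueError("n_virtual must be >= 1")
    seed_val = study.seed if seed is None else seed
    streams = np.random.SeedSequence(seed_val).spawn(n)
    if kp is None:
        kp = predict_all_kp(drug)
    results = []
    conc = np.empty((n, len(study.sampling_times)))
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        individual = sample_individual(study, rng, variability)
        dose_input = build_dose_input(study, drug)
        res = simulate_profile(individual, drug, dose_input, study.sampling_times,
                               kp=kp, solver_options=solver_options, subject_index=i)
        results.append(res)
        conc[i] = res.plasma_conc
    summary = PopulationSummary(
        times=np.asarray(study.sampling_times, dtype=float),
        mean=conc.mean(axis=0),
        p5=np.quantile(conc, 0.05, axis=0, method="linear"),
        p95=np.quantile(conc, 0.95, axis=0, method="linear"),
        minimum=conc.min(axis=0), maximum=conc.max(axis=0),
        n=n, seed=seed_val)
    return summary, results


def plot_trial_summary(summary: PopulationSummary, observed: Optional[pd.DataFrame] = None,
                       ax=None, title: str = ""):
    """Overlay-style plot: mean, 5th/95th percentile and min/max envelopes."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(summary.times, summary.mean, "-", color="k", label="mean")
    ax.plot(summary.times, summary.p5, ":", color="k", label="5th/95th pct")
    ax.plot(summary.times, summary.p95, ":", color="k")
    ax.plot(summary.times, summary.minimum, "--", color="gray", label="min/max")
    ax.plot(summary.times, summary.maximum, "--", color="gray")
    if observed is not None:
        ax.plot(observed["time_h"], observed["conc_ng_ml"], "o", color="red",
                label="observed")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("plasma concentration (ng/mL)")
    ax.set_yscale("log")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    return ax
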