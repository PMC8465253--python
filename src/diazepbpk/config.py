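"""Drug-parameter and study-design configuration.

Defines the validated domain types for the compound-specific inputs
(physicochemistry, protein binding, per-isoform Michaelis-Menten kinetics,
route-specific absorption parameters) and for the clinical study arms that
the virtual trials emulate, plus YAML loaders for both.  The effective
human jejunal permeability can be predicted from polar surface area and
hydrogen-bond-donor count when no measured value is supplied.
"""

from __future__ import annotations

import enum
import math
import warnings
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator


class ConfigError(ValueError):
    """A configuration document violated the schema."""


class IonizationClass(str, enum.Enum):
    NEUTRAL = "neutral"
    MONOPROTIC_BASE = "monoprotic_base"
    MONOPROTIC_ACID = "monoprotic_acid"


class Isoform(str, enum.Enum):
    CYP2B6 = "CYP2B6"
    CYP2C19 = "CYP2C19"
    CYP3A4 = "CYP3A4"
    CYP3A5 = "CYP3A5"


class Pathway(str, enum.Enum):
    N_DEMETHYLATION = "n_demethylation"
    HYDROXYLATION_3 = "hydroxylation_3"


class Route(str, enum.Enum):
    IV_BOLUS = "iv_bolus"
    IV_INFUSION = "iv_infusion"
    ORAL = "oral"
    INTRANASAL = "intranasal"
    RECTAL = "rectal"


class FirstPassTarget(str, enum.Enum):
    PORTAL = "portal"
    SYSTEMIC = "systemic"


# Log-linear correlation between jejunal permeability and the two
# hydrogen-bonding descriptors.  The intercept/slopes reproduce the
# reference permeability of diazepam (12.434e-4 cm/s at PSA 32.67 A^2,
# HBD 0) to the printed precision.
PEFF_INTERCEPT = -2.54602
PEFF_PSA_SLOPE = -0.011
PEFF_HBD_SLOPE = -0.278

#: Small-intestinal radius (cm) used to convert permeability into a
#: first-order absorption rate constant, ka = 2*Peff/R.
SMALL_INTESTINE_RADIUS_CM = 1.75


def predict_peff(psa: float, hbd: float) -> float:
    """Predict effective human jejunal permeability from PSA and HBD.

    Parameters
    ----------
    psa : polar surface area, A^2 (>= 0).
    hbd : hydrogen-bond donor count (>= 0).

    Returns
    -------
    Peff in units of 1e-4 cm/s.  The underlying correlation is
    ``log10(Peff[cm/s]) = -2.54602 - 0.011*PSA - 0.278*HBD``; the result
    is strictly decreasing in both descriptors.
    """
    if psa < 0:
        raise ConfigError(f"psa must be non-negative, got {psa}")
    if hbd < 0:
        raise ConfigError(f"hbd must be non-negative, got {hbd}")
    log_peff_cm_s = PEFF_INTERCEPT + PEFF_PSA_SLOPE * psa + PEFF_HBD_SLOPE * hbd
    return 10.0 ** log_peff_cm_s * 1e4


def ka_from_peff(peff: float, radius_cm: float = SMALL_INTESTINE_RADIUS_CM) -> float:
    """First-order absorption rate constant (1/h) from Peff (1e-4 cm/s)."""
    return 2.0 * peff * 1e-4 / radius_cm * 3600.0


class EnzymeKinetics(BaseModel):
    """Michaelis-Menten kinetics of one CYP isoform/pathway pair.

    vmax is expressed per pmol of isoform (pmol product/min/pmol enzyme),
    km in uM; both refer to the unbound substrate in the microsomal
    incubation once corrected by fu_mic.
    """

    model_config = ConfigDict(frozen=True)

    isoform: Isoform
    pathway: Pathway
    vmax: float = Field(ge=0.0, description="pmol/min per pmol isoform")
    km: float = Field(gt=0.0, description="uM")


class RouteParameters(BaseModel):
    model_config = ConfigDict(frozen=True)

    route: Route
    formulation: Optional[str] = None
    fa: float = Field(default=1.0, ge=0.0, le=1.0)
    ka: Optional[float] = None  # 1/h; None for IV routes
    infusion_duration: Optional[float] = None  # h, iv_infusion only
    first_pass_target: FirstPassTarget = FirstPassTarget.PORTAL
    portal_bypass_fraction: float = Field(default=0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "RouteParameters":
        if self.route not in (Route.IV_BOLUS, Route.IV_INFUSION):
            if self.ka is None or self.ka <= 0:
                raise ValueError(f"ka must be > 0 for route {self.route.value}")
        if self.route is Route.IV_INFUSION:
            if self.infusion_duration is None or self.infusion_duration <= 0:
                raise ValueError("infusion_duration must be > 0 for iv_infusion")
        return self


class DrugParameters(BaseModel):
    """Compound-specific model inputs (one document per drug)."""

    model_config = ConfigDict(frozen=True)

    name: str = "drug"
    molecular_weight: float = Field(gt=0.0, description="g/mol")
    log_p: float
    pka: float
    ionization_class: IonizationClass
    bp_ratio: float = Field(gt=0.0, description="blood:plasma concentration ratio")
    fu_plasma: float = Field(gt=0.0, le=1.0)
    fu_mic: float = Field(gt=0.0, le=1.0)
    psa: float = Field(ge=0.0, description="A^2")
    hbd: int = Field(ge=0)
    peff: Optional[float] = Field(default=None, gt=0.0, description="1e-4 cm/s")
    vss_reference: Optional[float] = Field(default=None, gt=0.0, description="L/kg")
    enzyme_kinetics: tuple[EnzymeKinetics, ...]
    routes: tuple[RouteParameters, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "DrugParameters":
        if not self.enzyme_kinetics:
            raise ValueError("enzyme_kinetics must be non-empty")
        pairs = [(k.isoform, k.pathway) for k in self.enzyme_kinetics]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (isoform, pathway) in enzyme_kinetics")
        if self.peff is None:
            object.__setattr__(self, "peff", predict_peff(self.psa, self.hbd))
        return self

    def route_parameters(self, route: Route, formulation: Optional[str] = None) -> RouteParameters:
        """Resolve route defaults, preferring an exact formulation match."""
        candidates = [r for r in self.routes if r.route is route]
        if formulation is not None:
            exact = [r for r in candidates if r.formulation == formulation]
            if exact:
                return exact[0]
        generic = [r for r in candidates if r.formulation is None]
        if generic:
            return generic[0]
        if candidates:
            return candidates[0]
        return default_route_parameters(self, route, formulation)


def default_route_parameters(
    drug: DrugParameters, route: Route, formulation: Optional[str] = None
) -> RouteParameters:
    """Built-in route defaults for a permeable, small-dose compound.

    Oral: complete availability for absorption with ka derived from Peff
    (ka = 2*Peff/R_si).  Rectal: fa 0.9, ka 1.5 1/h, absorbed drug split
    between the portal vein and the systemic circulation (bypass 0.5).
    Intranasal: fa 0.7, ka 1.6 1/h (3.2 for a supersaturated solution),
    absorbed directly into venous blood.
    """
    if route in (Route.IV_BOLUS, Route.IV_INFUSION):
        return RouteParameters(
            route=route,
            formulation=formulation,
            fa=1.0,
            first_pass_target=FirstPassTarget.SYSTEMIC,
            infusion_duration=1.0 if route is Route.IV_INFUSION else None,
        )
    if route is Route.ORAL:
        return RouteParameters(
            route=route,
            formulation=formulation,
            fa=1.0,
            ka=ka_from_peff(drug.peff),
            first_pass_target=FirstPassTarget.PORTAL,
        )
    if route is Route.INTRANASAL:
        ka = 3.2 if formulation == "supersaturated_solution" else 1.6
        return RouteParameters(
            route=route,
            formulation=formulation,
            fa=0.7,
            ka=ka,
            first_pass_target=FirstPassTarget.SYSTEMIC,
        )
    if route is Route.RECTAL:
        return RouteParameters(
            route=route,
            formulation=formulation,
            fa=0.9,
            ka=1.5,
            first_pass_target=FirstPassTarget.PORTAL,
            portal_bypass_fraction=0.5,
        )
    raise ConfigError(f"unknown route {route}")


class StudyDesign(BaseModel):
    model_config = ConfigDict(frozen=True)

    label: str
    reference: str = ""
    n_subjects_observed: int = Field(ge=1)
    n_virtual: int = Field(default=100, ge=1)
    dose: float = Field(gt=0.0, description="mg")
    route_parameters: RouteParameters
    age_range: tuple[float, float]
    weight_range: Optional[tuple[float, float]] = None  # kg; None -> reference adult
    female_proportion: float = Field(ge=0.0, le=1.0)
    duration: float = Field(gt=0.0, description="h")
    sampling_times: tuple[float, ...]
    seed: int = 2021
    notes: str = ""

    @model_validator(mode="after")
    def _check(self) -> "StudyDesign":
        t = np.asarray(self.sampling_times, dtype=float)
        if t.size < 2:
            raise ValueError("sampling_times needs at least two points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling_times must be strictly increasing")
        if t[0] < 0 or t[-1] > self.duration * (1 + 1e-12):
            raise ValueError("sampling_times must lie within [0, duration]")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range min > max")
        if self.weight_range is not None and self.weight_range[0] > self.weight_range[1]:
            raise ValueError("weight_range min > max")
        return self

    @property
    def route(self) -> Route:
        return self.route_parameters.route


def default_sampling_times(duration: float, n: int = 49) -> tuple[float, ...]:
    """Geometric sampling grid over [0, duration], dense at early times."""
    start = min(0.05, duration / 50.0)
    grid = np.geomspace(start, duration, n - 1)
    return tuple(np.concatenate(([0.0], grid)))


# ---------------------------------------------------------------------------
# Document loaders
# ---------------------------------------------------------------------------

def _read_document(document: Any) -> Mapping[str, Any]:
    if isinstance(document, Mapping):
        return document
    path = Path(document)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return data


def _range_from(doc: Any, field: str) -> Optional[tuple[float, float]]:
    """Accept {min, max}, {mean}, a scalar, or a 2-sequence."""
    if doc is None:
        return None
    if isinstance(doc, Mapping):
        if "min" in doc and "max" in doc:
            return (float(doc["min"]), float(doc["max"]))
        if "mean" in doc:
            m = float(doc["mean"])
            return (m, m)
        raise ConfigError(f"{field}: expected min/max or mean keys, got {sorted(doc)}")
    if isinstance(doc, (int, float)):
        return (float(doc), float(doc))
    if isinstance(doc, Sequence) and len(doc) == 2:
        return (float(doc[0]), float(doc[1]))
    raise ConfigError(f"{field}: cannot interpret {doc!r} as a range")


def load_drug_parameters(document: Any) -> DrugParameters:
    """Load and validate a drug document (path, or already-parsed mapping)."""
    data = dict(_read_document(document))
    kinetics_doc = data.pop("enzyme_kinetics", None)
    if not kinetics_doc:
        raise ConfigError("enzyme_kinetics: missing or empty")
    routes_doc = data.pop("routes", {}) or {}
    routes: list[RouteParameters] = []
    try:
        kinetics = tuple(EnzymeKinetics(**entry) for entry in kinetics_doc)
        for route_key, entries in routes_doc.items():
            if isinstance(entries, Mapping):
                entries = [entries]
            for entry in entries:
                routes.append(RouteParameters(route=Route(route_key), **entry))
        return DrugParameters(enzyme_kinetics=kinetics, routes=tuple(routes), **data)
    except (ValidationError, ValueError) as exc:
        raise ConfigError(f"invalid drug document: {exc}") from exc


def drug_to_document(drug: DrugParameters) -> dict:
    """Serialize a DrugParameters back to a plain round-trippable mapping."""
    doc = drug.model_dump(mode="json", exclude={"enzyme_kinetics", "routes"}, exclude_none=True)
    doc["enzyme_kinetics"] = [k.model_dump(mode="json") for k in drug.enzyme_kinetics]
    routes: dict[str, list] = {}
    for r in drug.routes:
        entry = r.model_dump(mode="json", exclude={"route"}, exclude_none=True)
        routes.setdefault(r.route.value, []).append(entry)
    if routes:
        doc["routes"] = routes
    return doc


def load_study_design(document: Any, drug: Optional[DrugParameters] = None,
                      label: Optional[str] = None) -> StudyDesign:
    """Load one study-arm document.

    Route parameters are resolved from (in order) an explicit
    ``route_parameters`` block, the drug document's route defaults, or the
    built-in defaults.  Sampling times default to a geometric grid.
    """
    data = dict(_read_document(document))
    if label is not None:
        data.setdefault("label", label)
    anomaly = data.pop("anomaly", None)
    if anomaly:
        warnings.warn(f"study {data.get('label', '?')}: {anomaly}", UserWarning, stacklevel=2)
        data["notes"] = (data.get("notes", "") + " " + anomaly).strip()
    try:
        route = Route(data.pop("route"))
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"study document: invalid or missing route ({exc})") from exc
    formulation = data.pop("formulation", None)
    rp_doc = data.pop("route_parameters", None)
    try:
        if rp_doc is not None:
            rp_kwargs = {"formulation": formulation, **rp_doc}
            rp = RouteParameters(route=route, **rp_kwargs)
        elif drug is not None:
            rp = drug.route_parameters(route, formulation)
            if formulation is not None and rp.formulation != formulation:
                rp = rp.model_copy(update={"formulation": formulation})
        else:
            rp = RouteParameters(
                route=route, formulation=formulation,
                **_builtin_route_kwargs(route, formulation))
        duration = float(data.pop("duration_h", data.pop("duration", 24.0)))
        sampling = data.pop("sampling_times", None)
        if sampling is None:
            sampling = default_sampling_times(duration)
        return StudyDesign(
            route_parameters=rp,
            duration=duration,
            sampling_times=tuple(float(t) for t in sampling),
            dose=float(data.pop("dose_mg", data.pop("dose", 0.0))),
            age_range=_range_from(data.pop("age", data.pop("age_range", None)), "age") or (18.0, 65.0),
            weight_range=_range_from(data.pop("weight", data.pop("weight_range", None)), "weight"),
            **data,
        )
    except (ValidationError, ValueError) as exc:
        raise ConfigError(f"invalid study document: {exc}") from exc


def _builtin_route_kwargs(route: Route, formulation: Optional[str]) -> dict:
    # Fallback when no drug document is supplied: mirror
    # default_route_parameters for a generic permeable compound.
    if route in (Route.IV_BOLUS, Route.IV_INFUSION):
        kw: dict = {"fa": 1.0, "first_pass_target": FirstPassTarget.SYSTEMIC}
        if route is Route.IV_INFUSION:
            kw["infusion_duration"] = 1.0
        return kw
    if route is Route.ORAL:
        return {"fa": 1.0, "ka": 5.0, "first_pass_target": FirstPassTarget.PORTAL}
    if route is Route.INTRANASAL:
        return {"fa": 0.7, "ka": 3.2 if formulation == "supersaturated_solution" else 1.6,
                "first_pass_target": FirstPassTarget.SYSTEMIC}
    return {"fa": 0.9, "ka": 1.5, "first_pass_target": FirstPassTarget.PORTAL,
            "portal_bypass_fraction": 0.5}


def study_to_document(study: StudyDesign) -> dict:
    doc = study.model_dump(mode="json", exclude={"route_parameters"}, exclude_none=True)
    doc["route_parameters"] = study.route_parameters.model_dump(mode="json", exclude={"route"},
                                                                exclude_none=True)
    doc["route"] = study.route.value
    return doc


def _data_path(name: str):
    return resources.files("diazepbpk.data").joinpath(name)


def load_default_drug() -> DrugParameters:
    """The packaged diazepam parameter document."""
    with resources.as_file(_data_path("diazepam.yaml")) as path:
        return load_drug_parameters(path)


def load_study_library(drug: Optional[DrugParameters] = None) -> dict[str, StudyDesign]:
    """All shipped study arms, keyed by label."""
    if drug is None:
        drug = load_default_drug()
    with resources.as_file(_data_path("studies.yaml")) as path:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    arms = data.get("arms", {})
    return {label: load_study_design(doc, drug=drug, label=label) for label, doc in arms.items()}
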