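"""Synthetic observed-like concentration-time data with known truth.

Clinical reference profiles for this model were digitized from
published figures and cannot be redistributed; this module stands in
for them with noisy two-compartment profiles whose ground truth is
known exactly, so the NCA/evaluation pipeline can be tested end to
end.  Disposition is a closed-form two-compartment model (no numerical
integration): bi-exponential after an IV bolus, tri-exponential
(first-order absorption) for extravascular routes.  Between-subject
variability is lognormal on CL, V and ka; residual assay error is
multiplicative lognormal, the standard model for concentration assays.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .nca import ConcentrationTimeProfile

__all__ = ["SyntheticStudySpec", "two_compartment_conc", "generate_dataset"]

MG_TO_NG = 1e6


class SyntheticStudySpec(BaseModel):
    """Design of one synthetic study arm (diazepam-like defaults)."""

    model_config = ConfigDict(frozen=True)

    cl_true: float = Field(default=3.0, gt=0, description="L/h")
    vc: float = Field(default=30.0, gt=0, description="L, central volume")
    vp2: float = Field(default=40.0, ge=0, description="L, peripheral volume")
    q_inter: float = Field(default=20.0, ge=0, description="L/h")
    ka_true: float = Field(default=1.0, gt=0, description="1/h, extravascular")
    f_true: float = Field(default=1.0, gt=0, le=1.0)
    dose: float = Field(default=10.0, gt=0, description="mg")
    route: str = "iv"
    sampling_times: tuple[float, ...] = (
        0.083, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0,
        36.0, 48.0, 72.0)
    n_subjects: int = Field(default=12, ge=1)
    between_subject_cv: float = Field(default=0.30, ge=0)
    residual_cv: float = Field(default=0.15, ge=0)
    seed: int = 20210915

    @model_validator(mode="after")
    def _check(self) -> "SyntheticStudySpec":
        t = np.asarray(self.sampling_times)
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("sampling_times must be non-negative and increasing")
        return self


def _micro_constants(cl: float, vc: float, vp2: float, q: float):
    k10 = cl / vc
    k12 = q / vc if vc > 0 else 0.0
    k21 = q / vp2 if vp2 > 0 else 0.0
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return k10, k21, alpha, beta


def two_compartment_conc(spec: SyntheticStudySpec, t,
                         cl: Optional[float] = None, vc: Optional[float] = None,
                         ka: Optional[float] = None) -> np.ndarray:
    """Exact concentration (ng/mL) of the two-compartment model at t (h).

    IV bolus: C = (D/Vc) [(alpha-k21)/(alpha-beta) e^-alpha t
                          + (k21-beta)/(alpha-beta) e^-beta t].
    Extravascular: first-order absorption superposed (three
    exponentials).  No numerical integration is involved.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    cl = spec.cl_true if cl is None else cl
    vc = spec.vc if vc is None else vc
    ka = spec.ka_true if ka is None else ka
    _, k21, alpha, beta = _micro_constants(cl, vc, spec.vp2, spec.q_inter)
    dose_ng = spec.dose * MG_TO_NG
    c0 = dose_ng / (vc * 1000.0)   # ng/mL
    if spec.route == "iv":
        if alpha == beta:
            return c0 * np.exp(-alpha * t)
        a = (alpha - k21) / (alpha - beta)
        b = (k21 - beta) / (alpha - beta)
        return c0 * (a * np.exp(-alpha * t) + b * np.exp(-beta * t))
    # extravascular: guard against degenerate ka == alpha or beta
    for pole in (alpha, beta):
        if abs(ka - pole) < 1e-9 * max(ka, 1.0):
            ka = ka * (1.0 + 1e-7) + 1e-12
    scale = spec.f_true * c0 * ka
    term_a = (k21 - alpha) / ((ka - alpha) * (beta - alpha)) * np.exp(-alpha * t)
    term_b = (k21 - beta) / ((ka - beta) * (alpha - beta)) * np.exp(-beta * t)
    term_ka = (k21 - ka) / ((alpha - ka) * (beta - ka)) * np.exp(-ka * t)
    return scale * (term_a + term_b + term_ka)


def generate_dataset(spec: SyntheticStudySpec):
    """Simulate a study: per-subject noisy profiles plus ground truth.

    Returns (profiles, truth) where truth is a DataFrame with each
    subject's realized CL (or CL/F), central volume, ka and the exact
    AUCinf = F*dose/CL.  Reproducible from spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.sampling_times)
    profiles: list[ConcentrationTimeProfile] = []
    records = []
    bsv = spec.between_subject_cv
    sigma = math.sqrt(math.log(1.0 + bsv * bsv)) if bsv > 0 else 0.0
    res = spec.residual_cv
    sigma_res = math.sqrt(math.log(1.0 + res * res)) if res > 0 else 0.0
    for i in range(spec.n_subjects):
        eta = rng.normal(0.0, 1.0, size=3) if sigma > 0 else np.zeros(3)
        cl_i = spec.cl_true * math.exp(sigma * eta[0] - 0.5 * sigma * sigma)
        vc_i = spec.vc * math.exp(sigma * eta[1] - 0.5 * sigma * sigma)
        ka_i = spec.ka_true * math.exp(sigma * eta[2] - 0.5 * sigma * sigma)
        c = two_compartment_conc(spec, times, cl=cl_i, vc=vc_i, ka=ka_i)
        if sigma_res > 0:
            eps = rng.normal(-0.5 * sigma_res * sigma_res, sigma_res, size=times.size)
            c = c * np.exp(eps)
        c = np.maximum(c, 0.0)
        label = f"synthetic_{spec.route}_{i:03d}"
        profiles.append(ConcentrationTimeProfile(
            times=times, conc=c, dose=spec.dose, route=spec.route, label=label))
        f = 1.0 if spec.route == "iv" else spec.f_true
        records.append({
            "label": label, "subject": i, "cl_true": cl_i, "vc_true": vc_i,
            "ka_true": ka_i, "f_true": f,
            "auc_inf_true": f * spec.dose * MG_TO_NG / cl_i / 1000.0,
            "cl_over_f_true": cl_i / f,
        })
    return profiles, pd.DataFrame.from_records(records)


def profiles_to_frame(profiles: Sequence[ConcentrationTimeProfile]) -> pd.DataFrame:
    """Long-format table (label, subject, time_h, conc_ng_ml, dose_mg, route)."""
    frames = []
    for i, p in enumerate(profiles):
        frames.append(pd.DataFrame({
            "label": p.label, "subject": i, "time_h": p.times,
            "conc_ng_ml": p.conc, "dose_mg": p.dose, "route": p.route}))
    return pd.concat(frames, ignore_index=True)
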