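"""Tissue-to-plasma partition coefficients and steady-state volume.

Implements the tissue-composition partition method for neutral compounds
and very weak monoprotic bases/acids: drug distributes into tissue water
according to the ionized:un-ionized ratio at each compartment's pH, into
neutral lipid and neutral phospholipid according to lipophilicity, and
binds to extravascular proteins with an association constant
back-calculated from the measured plasma fraction unbound, so the method
is self-consistent with the plasma binding input.  Adipose partitioning
uses the vegetable-oil:water distribution coefficient instead of the
octanol:water one, the standard correction for neutral-lipid-dominated
tissue.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import pandas as pd

from .config import DrugParameters, IonizationClass

__all__ = [
    "TissueComposition", "PlasmaComposition", "PartitionResult",
    "fraction_unionized", "predict_kp", "predict_all_kp", "compute_vss",
    "load_tissue_compositions", "erythrocyte_partition", "predict_partition",
]

TISSUES = (
    "adipose", "bone", "brain", "gut", "heart", "kidney",
    "liver", "lung", "muscle", "pancreas", "skin", "spleen",
)


@dataclass(frozen=True)
class TissueComposition:
    tissue: str
    f_ew: float        # fractional extracellular water volume
    f_iw: float        # fractional intracellular water volume
    f_nl: float        # fractional neutral lipid volume
    f_np: float        # fractional neutral phospholipid volume
    ap_conc: float     # acidic phospholipid concentration, mg/g tissue
    ph_iw: float       # intracellular water pH
    protein_ratio: float  # tissue:plasma albumin ratio

    def __post_init__(self) -> None:
        for name in ("f_ew", "f_iw", "f_nl", "f_np"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.tissue}.{name} = {v} outside [0, 1]")
        if self.f_ew + self.f_iw > 1.0 + 1e-12:
            raise ValueError(f"{self.tissue}: f_ew + f_iw > 1")
        if self.ap_conc < 0:
            raise ValueError(f"{self.tissue}: ap_conc < 0")
        if self.protein_ratio < 0:
            raise ValueError(f"{self.tissue}: protein_ratio < 0")


@dataclass(frozen=True)
class PlasmaComposition:
    f_nl_p: float = 0.0023
    f_np_p: float = 0.0013
    ph_p: float = 7.4

    def __post_init__(self) -> None:
        if self.f_nl_p < 0 or self.f_np_p < 0:
            raise ValueError("plasma lipid fractions must be >= 0")
        if not 6.5 < self.ph_p < 8.0:
            raise ValueError(f"plasma pH {self.ph_p} outside (6.5, 8.0)")


@dataclass(frozen=True)
class PartitionResult:
    kp: Mapping[str, float]   # tissue -> Kp (tissue:plasma, total)
    vss: float                # L/kg body weight


def load_tissue_compositions(path=None) -> dict[str, TissueComposition]:
    """Read the composition table (packaged default or a user CSV)."""
    if path is None:
        text = resources.files("diazepbpk.data").joinpath("tissue_composition.csv").read_text()
        df = pd.read_csv(io.StringIO(text), comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    out = {}
    for rec in df.to_dict("records"):
        out[str(rec["tissue"])] = TissueComposition(**{k: rec[k] for k in (
            "tissue", "f_ew", "f_iw", "f_nl", "f_np", "ap_conc", "ph_iw", "protein_ratio")})
    return out


def _ionized_ratio(pka: float, ionization_class: IonizationClass, ph: float) -> float:
    if ionization_class is IonizationClass.NEUTRAL:
        return 0.0
    if ionization_class is IonizationClass.MONOPROTIC_BASE:
        return 10.0 ** (pka - ph)
    return 10.0 ** (ph - pka)


def fraction_unionized(pka: float, ionization_class: IonizationClass, ph: float) -> float:
    """Henderson-Hasselbalch un-ionized fraction at the given pH."""
    if not 0.0 < ph < 14.0:
        raise ValueError(f"ph {ph} outside (0, 14)")
    return 1.0 / (1.0 + _ionized_ratio(pka, ionization_class, ph))


def _lipid_term(p: float, f_nl: float, f_np: float) -> float:
    return p * f_nl + (0.3 * p + 0.7) * f_np


def _octanol_p(drug: DrugParameters) -> float:
    return 10.0 ** drug.log_p


def _oil_p(drug: DrugParameters) -> float:
    # vegetable-oil:water distribution of the neutral species
    return 10.0 ** (1.115 * drug.log_p - 1.35)


def plasma_protein_association(drug: DrugParameters,
                               plasma: PlasmaComposition) -> float:
    """Protein association term Ka*[PR]_plasma back-calculated from fu.

    From 1/fu = 1 + lipid partitioning in plasma + Ka*[PR]p.  Clamped at
    zero when the lipid terms alone already explain the plasma binding.
    """
    if drug.fu_plasma <= 0:
        raise ValueError("fu_plasma must be > 0 to back-calculate protein binding")
    y = 1.0 + _ionized_ratio(drug.pka, drug.ionization_class, plasma.ph_p)
    lipid_p = _lipid_term(_octanol_p(drug), plasma.f_nl_p, plasma.f_np_p) / y
    return max(0.0, 1.0 / drug.fu_plasma - 1.0 - lipid_p)


def predict_kp(drug: DrugParameters, tissue: TissueComposition,
               plasma: Optional[PlasmaComposition] = None) -> float:
    """Tissue:plasma partition coefficient (total concentrations).

    Kp = fu * Kpu with
    Kpu = f_ew + (X_iw/X_p) f_iw + (P f_nl + (0.3P+0.7) f_np)/X_p
          + Ka*[PR]_p * protein_ratio,
    X = 1 + ionized:un-ionized ratio at the compartment pH.
    """
    plasma = plasma or PlasmaComposition()
    x_iw = 1.0 + _ionized_ratio(drug.pka, drug.ionization_class, tissue.ph_iw)
    x_p = 1.0 + _ionized_ratio(drug.pka, drug.ionization_class, plasma.ph_p)
    p = _oil_p(drug) if tissue.tissue == "adipose" else _octanol_p(drug)
    kpu = (
        tissue.f_ew
        + (x_iw / x_p) * tissue.f_iw
        + _lipid_term(p, tissue.f_nl, tissue.f_np) / x_p
        + plasma_protein_association(drug, plasma) * tissue.protein_ratio
    )
    return drug.fu_plasma * kpu


def predict_all_kp(drug: DrugParameters,
                   compositions: Optional[Mapping[str, TissueComposition]] = None,
                   plasma: Optional[PlasmaComposition] = None) -> dict[str, float]:
    compositions = compositions or load_tissue_compositions()
    return {name: predict_kp(drug, comp, plasma) for name, comp in compositions.items()}


def erythrocyte_partition(bp_ratio: float, hematocrit: float) -> float:
    """Erythrocyte:plasma partition from the blood:plasma ratio.

    B:P = (1 - Hct) + Hct * Kp_rbc; clamped at zero when the drug is
    excluded from blood cells (B:P < 1 - Hct).
    """
    if not 0.0 < hematocrit < 1.0:
        raise ValueError("hematocrit outside (0, 1)")
    return max(0.0, (bp_ratio - (1.0 - hematocrit)) / hematocrit)


def compute_vss(kp: Mapping[str, float], tissue_volumes: Mapping[str, float],
                plasma_volume: float,
                erythrocyte_term: Optional[tuple[float, float, float]] = None) -> float:
    """Vss (same per-kg or absolute units as the volumes supplied).

    vss = Vp + sum_t Kp_t V_t, optionally + V_rbc * Kp_rbc where the
    erythrocyte term is (bp_ratio, hematocrit, erythrocyte volume).
    """
    missing = [t for t in tissue_volumes if t not in kp]
    if missing:
        raise KeyError(f"no Kp for tissue volume entries: {missing}")
    vss = plasma_volume + sum(kp[t] * v for t, v in tissue_volumes.items())
    if erythrocyte_term is not None:
        bp, hct, v_rbc = erythrocyte_term
        vss += v_rbc * erythrocyte_partition(bp, hct)
    return vss


def predict_partition(drug: DrugParameters,
                      tissue_volumes_per_kg: Optional[Mapping[str, float]] = None,
                      plasma_volume_per_kg: Optional[float] = None,
                      erythrocyte_volume_per_kg: Optional[float] = None,
                      hematocrit: Optional[float] = None,
                      compositions: Optional[Mapping[str, TissueComposition]] = None,
                      plasma: Optional[PlasmaComposition] = None) -> PartitionResult:
    """Full distribution pipeline: Kp set for every tissue plus Vss (L/kg).

    Defaults to the packaged reference-adult volumes normalized per kg.
    """
    from .engine import load_reference_physiology  # late import, no cycle at module load

    if tissue_volumes_per_kg is None or plasma_volume_per_kg is None:
        ref = load_reference_physiology()
        bw = ref.body_weight
        tissue_volumes_per_kg = {t: ref.volumes[t] / bw for t in TISSUES}
        plasma_volume_per_kg = ref.plasma_volume / bw
        if erythrocyte_volume_per_kg is None:
            erythrocyte_volume_per_kg = ref.erythrocyte_volume / bw
        if hematocrit is None:
            hematocrit = ref.hematocrit
    kp = predict_all_kp(drug, compositions, plasma)
    ery = None
    if erythrocyte_volume_per_kg is not None and hematocrit is not None:
        ery = (drug.bp_ratio, hematocrit, erythrocyte_volume_per_kg)
    vss = compute_vss(kp, tissue_volumes_per_kg, plasma_volume_per_kg, ery)
    return PartitionResult(kp=kp, vss=vss)
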