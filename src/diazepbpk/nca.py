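"""Non-compartmental analysis and model-qualification statistics.

NCA: Cmax/Tmax from the sampled maximum, AUC0-t by the linear
trapezoid, AUCinf by terminal log-linear extrapolation when an adequate
terminal fit exists (>= 3 points, r^2 >= 0.9), and CL = dose/AUC0-t
(CL/F for extravascular routes).

Qualification: observed/predicted ratios, their arithmetic mean with a
two-sided t-interval, the average fold error AFE = 10^mean(log10 R)
(the geometric mean ratio), and the two-fold acceptance range
[0.5, 2.0].  Ratios are always recomputed from observed and predicted
values at full precision, never from pre-rounded ratio columns.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcentrationTimeProfile", "PKParameters", "EvaluationRow",
    "EvaluationSummary", "nca", "obs_pred_ratio", "afe", "mean_ratio_ci",
    "twofold_check", "build_summary_table", "load_observed_predicted",
    "rows_from_table", "summaries_to_frame",
]

MG_TO_NG = 1e6


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    times: np.ndarray           # h, strictly increasing
    conc: np.ndarray            # ng/mL
    dose: float                 # mg
    route: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)
        if t.shape != c.shape:
            raise ValueError("times and conc lengths differ")
        if t.size < 3:
            raise ValueError("at least 3 points are required for NCA")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if self.dose <= 0:
            raise ValueError("dose must be > 0")


@dataclass(frozen=True)
class PKParameters:
    cmax: float                 # ng/mL
    tmax: float                 # h
    auc_0_t: float              # ng.h/mL
    cl: float                   # L/h (CL/F for extravascular routes)
    auc_inf: Optional[float] = None
    t_half: Optional[float] = None
    lambda_z: Optional[float] = None
    r_squared: Optional[float] = None


def _terminal_fit(times: np.ndarray, conc: np.ndarray,
                  min_points: int = 3, r2_threshold: float = 0.9):
    """Best terminal log-linear fit after Tmax; None when inadequate."""
    i_max = int(np.argmax(conc))
    t = times[i_max:]
    c = conc[i_max:]
    mask = c > 0
    t, c = t[mask], c[mask]
    best = None
    for k in range(min_points, len(t) + 1):
        tt, cc = t[-k:], np.log(c[-k:])
        if len(tt) < min_points:
            continue
        res = stats.linregress(tt, cc)
        if res.slope >= 0:
            continue
        r2 = res.rvalue ** 2
        n = len(tt)
        adj = 1 - (1 - r2) * (n - 1) / (n - 2)
        if r2 >= r2_threshold and (best is None or adj > best[0]):
            best = (adj, -res.slope, r2)
    if best is None:
        return None
    _, lambda_z, r2 = best
    return lambda_z, r2


def nca(profile: ConcentrationTimeProfile) -> PKParameters:
    """Non-compartmental PK summary of one concentration-time profile."""
    t, c = profile.times, profile.conc
    i_max = int(np.argmax(c))
    cmax = float(c[i_max])
    tmax = float(t[i_max])
    auc = float(np.trapezoid(c, t))
    if auc <= 0:
        raise ValueError("non-positive AUC0-t")
    cl = profile.dose * MG_TO_NG / auc / 1000.0   # ng / (ng.h/mL) -> mL/h -> L/h
    auc_inf = t_half = lambda_z = r2 = None
    fit = _terminal_fit(t, c)
    if fit is not None:
        lambda_z, r2 = fit
        c_last = float(c[c > 0][-1]) if np.any(c > 0) else 0.0
        auc_inf = auc + c_last / lambda_z
        t_half = math.log(2.0) / lambda_z
    return PKParameters(cmax=cmax, tmax=tmax, auc_0_t=auc, cl=cl,
                        auc_inf=auc_inf, t_half=t_half,
                        lambda_z=lambda_z, r_squared=r2)


def obs_pred_ratio(observed: float, predicted: float) -> float:
    if observed <= 0 or predicted <= 0:
        raise ValueError("observed and predicted must be > 0")
    return observed / predicted


def afe(ratios: Sequence[float]) -> float:
    """Average fold error: 10^(mean of log10 ratios)."""
    r = np.asarray(list(ratios), dtype=float)
    if r.size == 0:
        raise ValueError("ratios must be non-empty")
    if np.any(r <= 0):
        raise ValueError("ratios must be > 0")
    return float(10.0 ** np.mean(np.log10(r)))


def mean_ratio_ci(ratios: Sequence[float], level: float = 0.95):
    """Arithmetic mean with a two-sided t-interval (sample sd, n-1 df)."""
    r = np.asarray(list(ratios), dtype=float)
    if r.size < 2:
        raise ValueError("confidence interval needs n >= 2")
    mean = float(r.mean())
    sd = float(r.std(ddof=1))
    half = stats.t.ppf(0.5 + level / 2.0, r.size - 1) * sd / math.sqrt(r.size)
    return mean, mean - half, mean + half


def twofold_check(ratios: Sequence[float]) -> tuple[bool, float]:
    """(all ratios within [0.5, 2.0] inclusive, max fold deviation)."""
    r = np.asarray(list(ratios), dtype=float)
    if np.any(r <= 0):
        raise ValueError("ratios must be > 0")
    folds = np.maximum(r, 1.0 / r)
    return bool(np.all((r >= 0.5) & (r <= 2.0))), float(folds.max())


@dataclass(frozen=True)
class EvaluationRow:
    route: str
    parameter: str              # auc_0_t | cmax | cl
    observed: float
    predicted: float
    reference: str = ""
    dose: float = 0.0

    def __post_init__(self) -> None:
        if self.observed <= 0 or self.predicted <= 0:
            raise ValueError("observed and predicted must be > 0")

    @property
    def ratio(self) -> float:
        return self.observed / self.predicted

    @property
    def fold_deviation(self) -> float:
        r = self.ratio
        return max(r, 1.0 / r)


@dataclass(frozen=True)
class EvaluationSummary:
    parameter: str
    route: str
    n: int
    mean_ratio: float
    afe: float
    within_twofold: bool
    ci95_low: Optional[float] = None
    ci95_high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.afe <= 0:
            raise ValueError("afe must be > 0")
        if self.ci95_low is not None and not (
                self.ci95_low <= self.mean_ratio <= self.ci95_high):
            raise ValueError("mean ratio outside its own confidence interval")


def build_summary_table(rows: Iterable[EvaluationRow]) -> list[EvaluationSummary]:
    """One summary per (route, parameter) group, in first-seen order.

    Groups with a single member keep empty CI fields rather than
    erroring.
    """
    groups: dict[tuple[str, str], list[EvaluationRow]] = {}
    for row in rows:
        groups.setdefault((row.route, row.parameter), []).append(row)
    out = []
    for (route, parameter), members in groups.items():
        ratios = [m.ratio for m in members]
        ok, _ = twofold_check(ratios)
        lo = hi = None
        mean = float(np.mean(ratios))
        if len(ratios) >= 2:
            mean, lo, hi = mean_ratio_ci(ratios)
        out.append(EvaluationSummary(
            parameter=parameter, route=route, n=len(ratios), mean_ratio=mean,
            afe=afe(ratios), within_twofold=ok, ci95_low=lo, ci95_high=hi))
    return out


def summaries_to_frame(summaries: Iterable[EvaluationSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "route": s.route, "parameter": s.parameter, "n": s.n,
        "mean_ratio": s.mean_ratio, "afe": s.afe,
        "ci95_low": s.ci95_low, "ci95_high": s.ci95_high,
        "within_twofold": s.within_twofold} for s in summaries])


def load_observed_predicted(path=None) -> pd.DataFrame:
    """Observed/predicted PK table (packaged compilation by default)."""
    if path is None:
        text = resources.files("diazepbpk.data").joinpath(
            "observed_predicted_pk.csv").read_text()
        return pd.read_csv(io.StringIO(text), comment="#")
    return pd.read_csv(path, comment="#")


def rows_from_table(df: pd.DataFrame) -> list[EvaluationRow]:
    return [EvaluationRow(route=str(r.route), parameter=str(r.parameter),
                          observed=float(r.observed), predicted=float(r.predicted),
                          reference=str(getattr(r, "reference", "")),
                          dose=float(getattr(r, "dose_mg", 0.0)))
            for r in df.itertuples()]
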