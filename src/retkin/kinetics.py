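"""Derived kinetic parameters from a fitted coefficient set.

Given the fractional transfer coefficients of the plasma/extravascular
exchange (plasma retinol-RBP = compartment 5, the extravascular pool =
compartment 6, irreversible loss L(0,6)), closed forms give:

* **transit time** t(I) = 1 / (total fractional exit rate from I) — the mean
  time one molecule spends in I during a single pass;
* **residence time** T(5,5) = expected number of plasma visits × per-visit
  duration = [(L(5,6)+L(0,6))/L(0,6)] / L(6,5) — the total plasma time
  before irreversible loss;
* **FCR** = 1/T(5,5), the fraction of the plasma pool utilized per day;
* **recycling number** ν(5) = T(5,5)/t(5), the expected number of plasma
  passes;
* **traced mass** M(5) = plasma retinol concentration × plasma volume, with
  plasma volume estimated as 0.035 ml per g body weight;
* **turnover** R(6,5) = L(6,5)·M(5) and **disposal** DR = R(0,6), obtained
  from turnover via the extravascular steady-state ratio
  L(0,6)/(L(5,6)+L(0,6)).

When a time interrupt switches L(0,6) at day 8, residence-based quantities
are reported per segment (before/after), never time-averaged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .model import CompartmentalModel

__all__ = [
    "transit_time",
    "residence_time_plasma",
    "recycling_number",
    "plasma_pool_mass",
    "turnover_rate",
    "disposal_rate",
    "scale_disposal_to_body_weight",
    "kinetic_summary",
    "KineticSummary",
    "PLASMA_ML_PER_G",
]

#: Estimated plasma volume per gram body weight (ml/g).
PLASMA_ML_PER_G = 0.035

_CoeffSource = "CompartmentalModel | Mapping[tuple[int, int], float]"


def _coeff_map(source, t: float = 0.0) -> dict[tuple[int, int], float]:
    if isinstance(source, CompartmentalModel):
        return source.coefficient_map(t)
    return {tuple(k): float(v) for k, v in source.items()}


def transit_time(coefficients, compartment: int, t: float = 0.0) -> float:
    """Mean single-pass transit time of ``compartment``, in days.

    The reciprocal of the summed fractional exit rates from the
    compartment (to anywhere: other compartments, delays, or the outside).
    """
    cmap = _coeff_map(coefficients, t)
    total = sum(v for (i, j), v in cmap.items() if j == compartment)
    if total <= 0:
        raise ValueError(f"compartment {compartment} has zero total exit rate")
    return 1.0 / total


def residence_time_plasma(
    coefficients,
    t: float = 0.0,
    *,
    plasma: int = 5,
    tissue: int = 6,
) -> float:
    """Mean residence time T(5,5) of retinol in plasma, in days.

    Assumes the exchange topology plasma ⇄ tissue with the sole
    irreversible exit L(0,tissue): the expected number of plasma visits is
    (L(plasma,tissue) + L(0,tissue)) / L(0,tissue) and each visit lasts
    1/L(tissue,plasma) on average.  Returns ``inf`` when there is no
    irreversible exit (a molecule never leaves; the residence-time
    distribution has no mean).
    """
    cmap = _coeff_map(coefficients, t)
    l_ts = cmap[(tissue, plasma)]
    l_st = cmap.get((plasma, tissue), 0.0)
    l_0t = cmap.get((0, tissue), 0.0)
    if l_ts <= 0:
        raise ValueError(f"L({tissue},{plasma}) must be positive")
    if l_0t == 0:
        return math.inf
    visits = (l_st + l_0t) / l_0t
    return visits / l_ts


def recycling_number(T55: float, t5: float) -> float:
    """Recycling number ν = T(5,5)/t(5): expected number of plasma passes.

    Both arguments must share a time unit.
    """
    if t5 <= 0:
        raise ValueError("transit time must be positive")
    if T55 < 0:
        raise ValueError("residence time must be non-negative")
    return T55 / t5


def plasma_pool_mass(
    retinol_concentration_uM: float, body_weight_g: float
) -> float:
    """Plasma retinol pool M(5) in nmol.

    Plasma volume is body weight × 0.035 ml/g; 1 µmol/L ≡ 1 nmol/ml, so
    M(5) [nmol] = concentration [µM] × body weight [g] × 0.035 [ml/g].
    """
    if retinol_concentration_uM <= 0 or body_weight_g <= 0:
        raise ValueError("concentration and body weight must be positive")
    return retinol_concentration_uM * body_weight_g * PLASMA_ML_PER_G


def turnover_rate(M5_nmol: float, L65_per_day: float) -> float:
    """Plasma-to-tissue turnover R(6,5) = L(6,5) × M(5), nmol/day."""
    if M5_nmol < 0 or L65_per_day < 0:
        raise ValueError("inputs must be non-negative")
    return L65_per_day * M5_nmol


def disposal_rate(R65_nmol_per_day: float, coefficients, t: float = 0.0) -> float:
    """Irreversible disposal DR = R(0,6), nmol/day.

    Under quasi-steady state of the extravascular pool (inflow = outflow),
    the fraction of the turnover that is lost rather than recycled is
    L(0,6)/(L(5,6)+L(0,6)); coefficients are resolved at time ``t`` so the
    interrupt segment active at the evaluation time is used.
    """
    if R65_nmol_per_day < 0:
        raise ValueError("turnover must be non-negative")
    cmap = _coeff_map(coefficients, t)
    l56 = cmap.get((5, 6), 0.0)
    l06 = cmap.get((0, 6), 0.0)
    denom = l56 + l06
    if denom <= 0:
        raise ValueError("L(5,6) + L(0,6) must be positive")
    return R65_nmol_per_day * l06 / denom


def scale_disposal_to_body_weight(
    dr_nmol_per_day: float, bw_from_g: float, bw_to_g: float
) -> float:
    """Linearly rescale a disposal rate per gram body weight, in µmol/day."""
    if bw_from_g <= 0 or bw_to_g <= 0:
        raise ValueError("body weights must be positive")
    return dr_nmol_per_day * (bw_to_g / bw_from_g) / 1000.0


@dataclass
class KineticSummary:
    """Derived kinetic parameters for one group.

    Residence-based entries carry one value per interrupt segment
    (``"before"``/``"after"``); models without an interrupt report a single
    ``"all"`` segment.  ``mass_table`` holds the per-time M(5)/turnover/DR
    rows when plasma retinol concentrations and body weights were supplied.
    """

    group: str
    t5_hours: float
    t6_days: float
    T55_days: dict[str, float]
    fcr_per_day: dict[str, float]
    nu5: dict[str, float]
    mass_table: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"parameter": "t(5)", "units": "h", "segment": "all", "value": self.t5_hours},
            {"parameter": "t(6)", "units": "days", "segment": "all", "value": self.t6_days},
        ]
        for seg, v in self.T55_days.items():
            rows.append(
                {"parameter": "T(5,5)", "units": "days", "segment": seg, "value": v}
            )
        for seg, v in self.fcr_per_day.items():
            rows.append(
                {"parameter": "FCR(5,5)", "units": "day^-1", "segment": seg, "value": v}
            )
        for seg, v in self.nu5.items():
            rows.append(
                {"parameter": "nu(5)", "units": "recycles", "segment": seg, "value": v}
            )
        df = pd.DataFrame(rows)
        df.insert(0, "group", self.group)
        return df

    def to_json(self) -> str:
        payload = {
            "group": self.group,
            "t5_hours": self.t5_hours,
            "t6_days": self.t6_days,
            "T55_days": self.T55_days,
            "fcr_per_day": self.fcr_per_day,
            "nu5": self.nu5,
        }
        if self.mass_table is not None:
            payload["mass_table"] = self.mass_table.to_dict(orient="records")
        return json.dumps(payload, indent=2)


def _segment_times(model: CompartmentalModel) -> dict[str, float]:
    if model.interrupts:
        s = min(it.switch_time for it in model.interrupts)
        return {"before": 0.0, "after": s}
    return {"all": 0.0}


def kinetic_summary(
    model: CompartmentalModel,
    *,
    group: str | None = None,
    masses: pd.DataFrame | None = None,
) -> KineticSummary:
    """Full Table-2/Table-3-style kinetic summary for a fitted model.

    ``masses`` (optional) must carry columns ``time_days``,
    ``plasma_retinol_uM`` and ``body_weight_g``; the per-time pool mass,
    turnover and disposal rates are then tabulated with the interrupt
    segment active at each time.
    """
    segs = _segment_times(model)
    t5_d = transit_time(model, 5, t=0.0)
    t6_d = transit_time(model, 6, t=0.0)
    T55 = {seg: residence_time_plasma(model, t=t0) for seg, t0 in segs.items()}
    fcr = {
        seg: (1.0 / v if math.isfinite(v) and v > 0 else 0.0)
        for seg, v in T55.items()
    }
    nu = {seg: recycling_number(v, t5_d) for seg, v in T55.items()}
    table = None
    if masses is not None:
        needed = {"time_days", "plasma_retinol_uM", "body_weight_g"}
        if not needed <= set(masses.columns):
            raise ValueError(f"masses table needs columns {sorted(needed)}")
        rows = []
        for _, r in masses.sort_values("time_days").iterrows():
            t = float(r["time_days"])
            m5 = plasma_pool_mass(float(r["plasma_retinol_uM"]), float(r["body_weight_g"]))
            l65 = model.coefficient_value(6, 5, t)
            r65 = turnover_rate(m5, l65)
            dr = disposal_rate(r65, model, t=t)
            rows.append(
                {
                    "time_days": t,
                    "M5_nmol": m5,
                    "turnover_R65_nmol_per_day": r65,
                    "DR_nmol_per_day": dr,
                }
            )
        table = pd.DataFrame(rows)
    return KineticSummary(
        group=group or model.name or "",
        t5_hours=t5_d * 24.0,
        t6_days=t6_d,
        T55_days=T55,
        fcr_per_day=fcr,
        nu5=nu,
        mass_table=table,
    )
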