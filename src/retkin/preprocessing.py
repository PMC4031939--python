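"""From raw pup-level measurements to group-mean tracer curves.

Each pup is sampled once (cross-sectional design).  The fraction of the
ingested dose in plasma is

    fraction = plasma tracer concentration [dpm/ml] x plasma volume [ml]
               / ingested dose [dpm]

with plasma volume estimated as body weight x 0.035 ml/g, and the ingested
dose as the prepared dose minus the residue recovered from the pipette tip
and muzzle chip.  Group-mean ("super-pup") curves average the per-pup
fractions at each scheduled time and carry the default 0.05 weighting FSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kinetics import PLASMA_ML_PER_G
from .model import TracerCurve

__all__ = [
    "PupRecord",
    "PUP_CSV_COLUMNS",
    "ingested_dose",
    "fraction_of_dose",
    "superpup_curve",
    "records_to_frame",
    "frame_to_records",
]

#: Canonical pup-level CSV dialect.
PUP_CSV_COLUMNS = (
    "pup_id",
    "group",
    "time_days",
    "body_weight_g",
    "dose_dpm",
    "residue_dpm",
    "plasma_dpm_per_ml",
    "plasma_retinol_uM",
)


@dataclass(frozen=True)
class PupRecord:
    """One pup's measurements at its (single) sampling time."""

    pup_id: str
    group: str
    time_days: float
    body_weight_g: float
    dose_dpm: float
    residue_dpm: float
    plasma_dpm_per_ml: float
    plasma_retinol_uM: float

    def __post_init__(self) -> None:
        for f in (
            "time_days",
            "body_weight_g",
            "dose_dpm",
            "residue_dpm",
            "plasma_dpm_per_ml",
            "plasma_retinol_uM",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if self.residue_dpm > self.dose_dpm:
            raise ValueError("residue cannot exceed the prepared dose")


def ingested_dose(dose_total_dpm: float, residue_dpm: float) -> float:
    """Radioactivity actually ingested: prepared dose minus recovered residue."""
    if residue_dpm > dose_total_dpm:
        raise ValueError("residue cannot exceed the prepared dose")
    if dose_total_dpm < 0 or residue_dpm < 0:
        raise ValueError("dpm values must be non-negative")
    return dose_total_dpm - residue_dpm


def fraction_of_dose(rec: PupRecord) -> float:
    """Fraction of the ingested dose in this pup's plasma.

    Linear in both the plasma tracer concentration and the body weight.
    A value above 1 is physically implausible (more tracer in plasma than
    was ingested) and triggers a warning, but is still returned so the
    caller can inspect the offending record.
    """
    ingested = ingested_dose(rec.dose_dpm, rec.residue_dpm)
    if ingested <= 0:
        raise ValueError(f"pup {rec.pup_id}: ingested dose is zero")
    frac = rec.plasma_dpm_per_ml * rec.body_weight_g * PLASMA_ML_PER_G / ingested
    if frac > 1:
        warnings.warn(
            f"pup {rec.pup_id}: fraction of dose {frac:.3g} exceeds 1 "
            "(implausible measurement)",
            stacklevel=2,
        )
    return frac


def _round_time(t: float) -> float:
    # 6-decimal canonical grid (see the hours-to-days conversion convention)
    return round(float(t), 6)


def superpup_curve(
    records: Iterable[PupRecord],
    group: str,
    schedule: Sequence[float] | None = None,
    weight_fsd: float = 0.05,
) -> TracerCurve:
    """Group-mean tracer curve over the scheduled sampling times.

    The per-time arithmetic mean of the pup fractions ("super-pup" data);
    the number of contributing pups is recorded per point.  If ``schedule``
    is given, every scheduled time must have at least one record.
    """
    by_time: dict[float, list[float]] = {}
    for rec in records:
        if rec.group != group:
            continue
        by_time.setdefault(_round_time(rec.time_days), []).append(
            fraction_of_dose(rec)
        )
    if schedule is not None:
        missing = [t for t in schedule if _round_time(t) not in by_time]
        if missing:
            raise ValueError(
                f"group {group!r}: no records at scheduled times {missing}"
            )
        times = [_round_time(t) for t in schedule]
    else:
        times = sorted(by_time)
    if not times:
        raise ValueError(f"no records for group {group!r}")
    values = np.array([np.mean(by_time[t]) for t in times])
    ns = np.array([len(by_time[t]) for t in times])
    return TracerCurve(
        times=np.array(times, dtype=float),
        values=values,
        group=group,
        weight_fsd=weight_fsd,
        n=ns,
    )


def records_to_frame(records: Iterable[PupRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=PUP_CSV_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[PupRecord]:
    missing = set(PUP_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pup table missing columns {sorted(missing)}")
    return [
        PupRecord(
            pup_id=str(r.pup_id),
            group=str(r.group),
            time_days=float(r.time_days),
            body_weight_g=float(r.body_weight_g),
            dose_dpm=float(r.dose_dpm),
            residue_dpm=float(r.residue_dpm),
            plasma_dpm_per_ml=float(r.plasma_dpm_per_ml),
            plasma_retinol_uM=float(r.plasma_retinol_uM),
        )
        for r in df.itertuples(index=False)
    ]
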