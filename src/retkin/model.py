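"""Compartmental model definition for whole-body retinol tracer kinetics.

The model is a linear mammillary-style system of compartments connected by
fractional transfer coefficients L(I,J) — the fraction of the retinol in
compartment J moved to compartment I per day (I = 0 denotes irreversible
loss from the system).  Two special elements extend the plain linear ODE
system:

* **delay elements** — pure transport lags (chylomicron production and
  chylomicron metabolism): tracer entering a delay emerges unchanged at its
  downstream compartment after a fixed duration;
* **time interrupts** — a piecewise-constant switch of one coefficient at a
  fixed time (here the irreversible-loss coefficient L(0,6) switching at
  day 8);
* **time-varying hooks** — an arbitrary smooth function of time attached to
  one coefficient (used by the supplementation perturbation model).

Compartment ids follow the study's numbering (1, 2, 4, 5, 6, 10 with delay
elements 3 and 15) for traceability; they are never renumbered densely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OUTSIDE",
    "TransferCoefficient",
    "DelayElement",
    "TimeInterrupt",
    "CompartmentalModel",
    "TracerCurve",
    "build_rate_matrix",
    "parse_param_name",
    "format_param_name",
]

#: id of the environment sink; L(0,J) is irreversible loss from J.
OUTSIDE = 0


@dataclass(frozen=True)
class TransferCoefficient:
    """A fractional transfer coefficient L(I,J), in day^-1.

    ``to_compartment`` may be a compartment id, a delay-element id, or
    :data:`OUTSIDE` (0) for irreversible loss.  ``status`` records whether
    the value was fixed by convention or estimated; ``fsd`` is the
    fractional standard deviation attached after fitting.
    """

    to_compartment: int
    from_compartment: int
    value: float
    status: str = "fixed"  # "fixed" | "free"
    fsd: float | None = None

    def __post_init__(self) -> None:
        if self.to_compartment == self.from_compartment:
            raise ValueError(
                f"self-transfer L({self.to_compartment},{self.from_compartment}) "
                "is not allowed"
            )
        if self.value < 0:
            raise ValueError(
                f"L({self.to_compartment},{self.from_compartment}) must be "
                f"non-negative, got {self.value}"
            )
        if self.status not in ("fixed", "free"):
            raise ValueError(f"status must be 'fixed' or 'free', got {self.status!r}")
        if self.fsd is not None and self.fsd < 0:
            raise ValueError("fsd must be non-negative")

    @property
    def key(self) -> tuple[int, int]:
        return (self.to_compartment, self.from_compartment)

    @property
    def name(self) -> str:
        return f"L({self.to_compartment},{self.from_compartment})"


@dataclass(frozen=True)
class DelayElement:
    """A pure transport lag: inflow emerges downstream ``duration`` days later."""

    id: int
    duration: float
    upstream: int
    downstream: int
    status: str = "fixed"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"delay {self.id} duration must be > 0")
        if self.upstream == self.downstream:
            raise ValueError(f"delay {self.id} must connect distinct compartments")
        if self.status not in ("fixed", "free"):
            raise ValueError(f"status must be 'fixed' or 'free', got {self.status!r}")

    @property
    def name(self) -> str:
        return f"DT({self.id})"


@dataclass(frozen=True)
class TimeInterrupt:
    """Piecewise-constant switch of one coefficient at ``switch_time`` days."""

    coefficient: tuple[int, int]
    switch_time: float
    value_before: float
    value_after: float

    def __post_init__(self) -> None:
        if self.switch_time <= 0:
            raise ValueError("interrupt switch_time must be positive")
        if self.value_before < 0 or self.value_after < 0:
            raise ValueError("interrupt values must be non-negative")

    def value_at(self, t: float) -> float:
        return self.value_before if t < self.switch_time else self.value_after


def parse_param_name(name: str) -> tuple:
    """Parse ``"L(6,5)"``, ``"L(0,6):before"``/``":after"`` or ``"DT(3)"``.

    Returns ``("L", i, j, segment_or_None)`` or ``("DT", id)``.
    """
    name = name.strip()
    if name.startswith("DT(") and name.endswith(")"):
        return ("DT", int(name[3:-1]))
    seg = None
    base = name
    if ":" in name:
        base, seg = name.split(":", 1)
        if seg not in ("before", "after"):
            raise ValueError(f"unknown interrupt segment in {name!r}")
    if base.startswith("L(") and base.endswith(")"):
        i_s, j_s = base[2:-1].split(",")
        return ("L", int(i_s), int(j_s), seg)
    raise ValueError(f"cannot parse parameter name {name!r}")


def format_param_name(kind: str, *ids, segment: str | None = None) -> str:
    if kind == "DT":
        return f"DT({ids[0]})"
    base = f"L({ids[0]},{ids[1]})"
    return f"{base}:{segment}" if segment else base


@dataclass(frozen=True)
class CompartmentalModel:
    """Linear compartmental tracer system with delays and switching coefficients.

    Parameters
    ----------
    compartments
        Compartment ids (the environment sink 0 is implicit).
    coefficients
        Mapping ``(I, J) -> TransferCoefficient``; I may be a delay id or 0.
    delays
        Mapping ``id -> DelayElement``.
    interrupts
        Piecewise-constant coefficient switches.
    hooks
        ``(I, J) -> f(t)`` continuously time-varying coefficient values;
        a hook takes precedence over the static value and any interrupt.
    input_compartment
        Where the oral dose enters (compartment 1 in this study).
    observation
        Compartments whose summed contents form the observed quantity
        (plasma chylomicron retinyl esters + plasma retinol-RBP: {10, 5}).
    """

    compartments: frozenset[int]
    coefficients: Mapping[tuple[int, int], TransferCoefficient]
    delays: Mapping[int, DelayElement] = field(default_factory=dict)
    interrupts: tuple[TimeInterrupt, ...] = ()
    hooks: Mapping[tuple[int, int], Callable[[float], float]] = field(
        default_factory=dict
    )
    input_compartment: int = 1
    observation: frozenset[int] = frozenset({5, 10})
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "compartments", frozenset(self.compartments))
        object.__setattr__(self, "observation", frozenset(self.observation))
        object.__setattr__(self, "coefficients", dict(self.coefficients))
        object.__setattr__(self, "delays", dict(self.delays))
        object.__setattr__(self, "hooks", dict(self.hooks))
        self._validate()

    # ------------------------------------------------------------------ #
    # validation

    def _validate(self) -> None:
        comps = self.compartments
        if OUTSIDE in comps:
            raise ValueError("0 denotes the outside sink and cannot be a compartment")
        if comps & set(self.delays):
            raise ValueError("delay ids must not collide with compartment ids")
        if self.input_compartment not in comps:
            raise ValueError(f"input compartment {self.input_compartment} unknown")
        if not self.observation <= comps:
            raise ValueError("observation map references unknown compartments")
        valid_targets = comps | set(self.delays) | {OUTSIDE}
        for key, c in self.coefficients.items():
            if key != c.key:
                raise ValueError(f"coefficient stored under wrong key {key}")
            if c.from_compartment not in comps:
                raise ValueError(f"{c.name}: source compartment unknown")
            if c.to_compartment not in valid_targets:
                raise ValueError(f"{c.name}: target unknown")
        for d in self.delays.values():
            if d.upstream not in comps or d.downstream not in comps:
                raise ValueError(f"delay {d.id} must connect two model compartments")
            feeders = [
                k for k in self.coefficients if k[0] == d.id and k[1] == d.upstream
            ]
            if len(feeders) != 1:
                raise ValueError(
                    f"delay {d.id} needs exactly one feeding coefficient "
                    f"L({d.id},{d.upstream})"
                )
        for it in self.interrupts:
            if it.coefficient not in self.coefficients:
                raise ValueError(f"interrupt on unknown coefficient {it.coefficient}")
        seen = set()
        for it in self.interrupts:
            if it.coefficient in seen:
                raise ValueError(f"multiple interrupts on {it.coefficient}")
            seen.add(it.coefficient)
        for key in self.hooks:
            if key not in self.coefficients:
                raise ValueError(f"hook attached to unknown coefficient {key}")

    # ------------------------------------------------------------------ #
    # coefficient resolution

    def interrupt_for(self, key: tuple[int, int]) -> TimeInterrupt | None:
        for it in self.interrupts:
            if it.coefficient == key:
                return it
        return None

    def coefficient_value(self, i: int, j: int, t: float = 0.0) -> float:
        """Resolved value of L(i,j) at time ``t`` (hook > interrupt > static)."""
        key = (i, j)
        if key in self.hooks:
            v = float(self.hooks[key](t))
            if v < 0:
                raise ValueError(f"time-varying L{key} is negative at t={t}")
            return v
        it = self.interrupt_for(key)
        if it is not None:
            return it.value_at(t)
        try:
            return self.coefficients[key].value
        except KeyError:
            raise KeyError(f"no coefficient L({i},{j}) in model") from None

    def coefficient_map(self, t: float = 0.0) -> dict[tuple[int, int], float]:
        """All coefficient values resolved at time ``t``."""
        return {
            key: self.coefficient_value(*key, t=t) for key in self.coefficients
        }

    @property
    def switch_times(self) -> tuple[float, ...]:
        return tuple(sorted({it.switch_time for it in self.interrupts}))

    def total_exit_rate(self, j: int, t: float = 0.0) -> float:
        """Sum of all fractional exits from compartment ``j`` at time ``t``."""
        return sum(
            self.coefficient_value(i, src, t)
            for (i, src) in self.coefficients
            if src == j
        )

    # ------------------------------------------------------------------ #
    # parameter get/set by name (used by the fitter)

    def parameter_value(self, name: str) -> float:
        parsed = parse_param_name(name)
        if parsed[0] == "DT":
            return self.delays[parsed[1]].duration
        _, i, j, seg = parsed
        it = self.interrupt_for((i, j))
        if seg is not None:
            if it is None:
                raise KeyError(f"{name}: no interrupt on L({i},{j})")
            return it.value_before if seg == "before" else it.value_after
        if it is not None:
            raise KeyError(
                f"L({i},{j}) is interrupted; address it as "
                f"'L({i},{j}):before' or 'L({i},{j}):after'"
            )
        return self.coefficients[(i, j)].value

    def with_values(self, updates: Mapping[str, float]) -> "CompartmentalModel":
        """Return a copy with named parameters replaced (fitter work-horse)."""
        coeffs = dict(self.coefficients)
        delays = dict(self.delays)
        interrupts = list(self.interrupts)
        for name, value in updates.items():
            parsed = parse_param_name(name)
            if parsed[0] == "DT":
                did = parsed[1]
                delays[did] = replace(delays[did], duration=float(value))
                continue
            _, i, j, seg = parsed
            key = (i, j)
            idxs = [k for k, it in enumerate(interrupts) if it.coefficient == key]
            if seg is not None:
                if not idxs:
                    raise KeyError(f"{name}: no interrupt on L({i},{j})")
                idx = idxs[0]
                fieldname = "value_before" if seg == "before" else "value_after"
                interrupts[idx] = replace(interrupts[idx], **{fieldname: float(value)})
                if seg == "before":
                    coeffs[key] = replace(coeffs[key], value=float(value))
                continue
            if idxs:
                raise KeyError(
                    f"L({i},{j}) is interrupted; use ':before'/':after' segments"
                )
            coeffs[key] = replace(coeffs[key], value=float(value))
        return replace(
            self,
            coefficients=coeffs,
            delays=delays,
            interrupts=tuple(interrupts),
        )

    def with_hook(
        self, key: tuple[int, int], fn: Callable[[float], float]
    ) -> "CompartmentalModel":
        hooks = dict(self.hooks)
        hooks[key] = fn
        return replace(self, hooks=hooks)

    def without_hooks(self) -> "CompartmentalModel":
        return replace(self, hooks={})

    def freeze_interrupts(self, segment: str = "before") -> "CompartmentalModel":
        """Resolve every interrupt to one segment's constant value.

        Useful for closed-form calculus and impulse-response checks on a
        single coefficient regime (``segment`` is ``"before"`` or
        ``"after"``).
        """
        if segment not in ("before", "after"):
            raise ValueError("segment must be 'before' or 'after'")
        coeffs = dict(self.coefficients)
        for it in self.interrupts:
            value = it.value_before if segment == "before" else it.value_after
            coeffs[it.coefficient] = replace(coeffs[it.coefficient], value=value)
        return replace(self, coefficients=coeffs, interrupts=())

    # ------------------------------------------------------------------ #
    # serialization (lossless round-trip; hooks are runtime-only)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "compartments": sorted(self.compartments),
            "input_compartment": self.input_compartment,
            "observation": sorted(self.observation),
            "coefficients": [
                {
                    "to": c.to_compartment,
                    "from": c.from_compartment,
                    "value": c.value,
                    "status": c.status,
                    **({"fsd": c.fsd} if c.fsd is not None else {}),
                }
                for c in sorted(self.coefficients.values(), key=lambda c: c.key)
            ],
            "delays": [
                {
                    "id": d.id,
                    "duration": d.duration,
                    "upstream": d.upstream,
                    "downstream": d.downstream,
                    "status": d.status,
                }
                for d in sorted(self.delays.values(), key=lambda d: d.id)
            ],
            "interrupts": [
                {
                    "to": it.coefficient[0],
                    "from": it.coefficient[1],
                    "switch_time": it.switch_time,
                    "value_before": it.value_before,
                    "value_after": it.value_after,
                }
                for it in self.interrupts
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CompartmentalModel":
        coeffs = {
            (c["to"], c["from"]): TransferCoefficient(
                to_compartment=c["to"],
                from_compartment=c["from"],
                value=c["value"],
                status=c.get("status", "fixed"),
                fsd=c.get("fsd"),
            )
            for c in d.get("coefficients", [])
        }
        delays = {
            e["id"]: DelayElement(
                id=e["id"],
                duration=e["duration"],
                upstream=e["upstream"],
                downstream=e["downstream"],
                status=e.get("status", "fixed"),
            )
            for e in d.get("delays", [])
        }
        interrupts = tuple(
            TimeInterrupt(
                coefficient=(it["to"], it["from"]),
                switch_time=it["switch_time"],
                value_before=it["value_before"],
                value_after=it["value_after"],
            )
            for it in d.get("interrupts", [])
        )
        return cls(
            compartments=frozenset(d["compartments"]),
            coefficients=coeffs,
            delays=delays,
            interrupts=interrupts,
            input_compartment=d.get("input_compartment", 1),
            observation=frozenset(d.get("observation", [])),
            name=d.get("name", ""),
        )


def build_rate_matrix(model: CompartmentalModel, t: float = 0.0) -> pd.DataFrame:
    """Rate matrix of the linear system at time ``t`` (day^-1).

    Entry (I, J) holds L(I,J) for compartment-to-compartment transfers;
    the diagonal (J, J) holds minus the *total* fractional exit rate from J
    — including losses to the outside and flows into delay elements.  Delay
    emergences are intentionally absent: they are forcing terms handled by
    the solver, not instantaneous transfers.

    Returns a DataFrame indexed by compartment id (rows = destination,
    columns = source) so entries read as ``mat.loc[I, J]``.
    """
    ids = sorted(model.compartments)
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for (i, j) in model.coefficients:
        v = model.coefficient_value(i, j, t)
        mat.loc[j, j] -= v
        if i in model.compartments:
            mat.loc[i, j] += v
    return mat


@dataclass(frozen=True)
class TracerCurve:
    """Plasma tracer response: fraction of the ingested dose versus time.

    ``times`` are days after dose administration (strictly increasing);
    ``values`` are dimensionless fractions of the ingested dose.
    ``weight_fsd`` is the per-point fractional SD used for weighting
    (scalar broadcast or per-point array); ``n`` optionally records how
    many pups contributed to each group-mean point.
    """

    times: np.ndarray
    values: np.ndarray
    group: str | None = None
    weight_fsd: np.ndarray | float = 0.05
    n: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be matching 1-d arrays")
        if times.size and (np.any(np.diff(times) <= 0)):
            raise ValueError("times must be strictly increasing")
        if times.size and times[0] < 0:
            raise ValueError("times must be non-negative")
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("fraction-of-dose values must lie in [0, 1]")
        fsd = np.broadcast_to(
            np.asarray(self.weight_fsd, dtype=float), times.shape
        ).copy()
        if np.any(fsd <= 0):
            raise ValueError("weight FSDs must be positive")
        object.__setattr__(self, "weight_fsd", fsd)
        if self.n is not None:
            n = np.asarray(self.n)
            if n.shape != times.shape:
                raise ValueError("n must match times")
            object.__setattr__(self, "n", n)

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "group": self.group,
                "time_days": self.times,
                "fraction_of_dose": self.values,
                "weight_fsd": self.weight_fsd,
            }
        )
        if self.n is not None:
            df["n"] = self.n
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group: str | None = None) -> "TracerCurve":
        if group is not None and "group" in df.columns:
            df = df[df["group"] == group]
        order = np.argsort(df["time_days"].to_numpy())
        df = df.iloc[order]
        fsd = (
            df["weight_fsd"].to_numpy()
            if "weight_fsd" in df.columns
            else 0.05
        )
        grp = group
        if grp is None and "group" in df.columns and df["group"].nunique() == 1:
            grp = str(df["group"].iloc[0])
        return cls(
            times=df["time_days"].to_numpy(dtype=float),
            values=df["fraction_of_dose"].to_numpy(dtype=float),
            group=grp,
            weight_fsd=fsd,
            n=df["n"].to_numpy() if "n" in df.columns else None,
        )
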