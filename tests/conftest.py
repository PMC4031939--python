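"""Shared fixtures: small analytic models and an independent RK4 oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from retkin.model import (
    CompartmentalModel,
    DelayElement,
    TimeInterrupt,
    TransferCoefficient,
)
from retkin.presets import STUDY_TIMES_DAYS, table1_oil, table1_vara


def tc(i: int, j: int, v: float) -> tuple[tuple[int, int], TransferCoefficient]:
    return (i, j), TransferCoefficient(i, j, v)


@pytest.fixture
def single_pool():
    """One compartment with irreversible loss at 2/day."""
    return CompartmentalModel(
        compartments={1},
        coefficients=dict([tc(0, 1, 2.0)]),
        input_compartment=1,
        observation={1},
    )


@pytest.fixture
def closed_two_pool():
    """Loss-free plasma/tissue exchange (5 <-> 6); total content conserved."""
    return CompartmentalModel(
        compartments={5, 6},
        coefficients=dict([tc(6, 5, 60.3), tc(5, 6, 0.60)]),
        input_compartment=5,
        observation={5, 6},
    )


@pytest.fixture
def oil_model():
    return table1_oil()


@pytest.fixture
def oil_model_const():
    """Control model with the pre-day-8 loss held constant (no interrupt)."""
    return table1_oil(interrupt=False)


@pytest.fixture
def vara_model():
    return table1_vara()


@pytest.fixture
def schedule():
    return np.array(STUDY_TIMES_DAYS)


def lossless_oil():
    """Control topology with every loss to the outside removed."""
    d = table1_oil().to_dict()
    d["coefficients"] = [
        c for c in d["coefficients"] if c["to"] != 0
    ]
    d["interrupts"] = []
    return CompartmentalModel.from_dict(d)


# --------------------------------------------------------------------------- #
# independent oracle: naive fixed-step RK4 with linear-interp delay history


def rk4_simulate(model, dose, out_times, h=2.5e-4):
    """Fixed-step RK4 over the whole system, delays via history interpolation.

    Intentionally naive and independent of retkin.solver: one global state
    vector, a uniform step, and linear interpolation into the stored
    history for the delayed flows.  Accuracy ~1e-4 relative; used only as a
    cross-check oracle.
    """
    comps = sorted(model.compartments)
    idx = {c: k for k, c in enumerate(comps)}
    n = len(comps)
    t_end = float(max(out_times))
    n_steps = int(np.ceil(t_end / h)) + 1
    grid = np.arange(n_steps + 1) * h
    hist = np.zeros((n_steps + 1, n))
    y = np.zeros(n)
    y[idx[model.input_compartment]] = dose

    def hist_at(t, k_now):
        if t <= 0:
            return hist[0] * 0.0 if t < 0 else hist[0]
        j = min(int(t / h), k_now - 1)
        w = (t - grid[j]) / h
        return (1 - w) * hist[j] + w * hist[j + 1]

    def deriv(t, y_now, k_now):
        dy = np.zeros(n)
        for (i, j), coeff in model.coefficients.items():
            v = model.coefficient_value(i, j, t)
            q = y_now[idx[j]]
            dy[idx[j]] -= v * q
            if i in model.delays:
                d = model.delays[i]
                ts = t - d.duration
                if ts >= 0:
                    q_past = hist_at(ts, k_now)[idx[j]]
                    v_past = model.coefficient_value(i, j, ts)
                    dy[idx[d.downstream]] += v_past * q_past
            elif i in idx:
                dy[idx[i]] += v * q
        return dy

    hist[0] = y
    for k in range(n_steps):
        t = grid[k]
        k1 = deriv(t, y, k + 1)
        k2 = deriv(t + h / 2, y + h / 2 * k1, k + 1)
        k3 = deriv(t + h / 2, y + h / 2 * k2, k + 1)
        k4 = deriv(t + h, y + h * k3, k + 1)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        hist[k + 1] = y

    out = []
    for t in np.atleast_1d(out_times):
        row = hist_at(float(t), n_steps)
        out.append(sum(row[idx[c]] for c in model.observation))
    return np.array(out)
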