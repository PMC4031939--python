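"""Weighted nonlinear least-squares estimation of transfer coefficients.

The observed group-mean tracer curve is fit by minimizing

    WSS = sum_i [ (y_i - yhat_i) / (fsd_i * y_i) ]^2

i.e. relative (fractional-SD) weighting with the observed value in the
denominator — the convention of classical kinetic-modeling software, with a
default per-datum FSD of 0.05.  Uncertainties are reported as fractional
standard deviations (FSD = SE/estimate) from the inverse curvature at the
optimum; a coefficient is regarded as well-identified when its FSD is below
0.5.  Nested models are compared with an F statistic and the least-squares
form of the Akaike information criterion, AIC = n ln(WSS/n) + 2k.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .model import CompartmentalModel, TracerCurve, parse_param_name
from .solver import simulate_tracer

__all__ = [
    "FitResult",
    "ModelComparison",
    "TTestResult",
    "weighted_wss",
    "fit_model",
    "compare_models",
    "group_coefficient_ttest",
    "sensitivity_to_fixed",
    "IDENTIFIABILITY_FSD",
]

#: FSD threshold below which a coefficient counts as well-identified.
IDENTIFIABILITY_FSD = 0.5


def weighted_wss(curve: TracerCurve, predicted: TracerCurve) -> float:
    """Weighted sum of squares between observed and predicted curves.

    Weights are 1/(fsd_i * y_i)^2 with y_i the observed value and fsd_i the
    per-point FSD of the observed curve (default 0.05), making the loss
    invariant to rescaling both curves.
    """
    if len(curve) != len(predicted) or not np.allclose(
        curve.times, predicted.times, rtol=0, atol=1e-9
    ):
        raise ValueError("observed and predicted curves must share a time grid")
    y = curve.values
    if np.any(y == 0):
        raise ValueError(
            "relative weighting is undefined for zero observations; "
            "drop those points or supply absolute weights"
        )
    r = (y - predicted.values) / (curve.weight_fsd * y)
    return float(np.sum(r * r))


@dataclass
class FitResult:
    """Outcome of a weighted nonlinear least-squares fit."""

    estimates: dict[str, float]
    fsds: dict[str, float]
    covariance: np.ndarray
    param_names: list[str]
    wss: float
    n_obs: int
    n_free: int
    aic: float
    success: bool
    message: str
    n_eval: int = 0

    @property
    def identifiable(self) -> dict[str, bool]:
        """Well-identified flags: FSD below the 0.5 threshold."""
        return {
            k: (math.isfinite(v) and v < IDENTIFIABILITY_FSD)
            for k, v in self.fsds.items()
        }

    def to_frame(self, group: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "coefficient": self.param_names,
                "estimate_per_day": [self.estimates[k] for k in self.param_names],
                "fsd": [self.fsds[k] for k in self.param_names],
                "identifiable": [self.identifiable[k] for k in self.param_names],
            }
        )
        if group is not None:
            df.insert(0, "group", group)
        return df

    def to_json(self) -> str:
        return json.dumps(
            {
                "estimates": self.estimates,
                "fsds": {k: (v if math.isfinite(v) else None) for k, v in self.fsds.items()},
                "covariance": self.covariance.tolist(),
                "param_names": self.param_names,
                "wss": self.wss,
                "n_obs": self.n_obs,
                "n_free": self.n_free,
                "aic": self.aic,
                "success": self.success,
                "message": self.message,
            },
            indent=2,
        )


def _aic(wss: float, n: int, k: int) -> float:
    return n * math.log(wss / n) + 2 * k if wss > 0 else -math.inf


def _lower_bound(name: str) -> float:
    # delay durations and pulse rates must stay strictly positive
    if name.startswith("DT(") or name in ("P1", "dP"):
        return 1e-6 if name != "dP" else 0.0
    return 0.0


def fit_model(
    model: CompartmentalModel,
    curve: TracerCurve,
    free: Sequence[str],
    starts: Mapping[str, float] | None = None,
    *,
    multistart: bool = False,
    n_starts: int = 8,
    seed: int | None = None,
    model_builder: Callable[[dict[str, float]], CompartmentalModel] | None = None,
    sim_rtol: float = 1e-8,
    sim_atol: float = 1e-11,
    diff_step: float = 1e-4,
    ftol: float = 1e-12,
    xtol: float = 1e-12,
    max_nfev: int | None = None,
) -> FitResult:
    """Estimate the named free parameters against a tracer curve.

    Parameters are named ``"L(I,J)"`` (or ``"L(I,J):before"``/``":after"``
    for an interrupted coefficient, ``"DT(id)"`` for delay durations).
    Starting values default to the model's current values and must be
    positive.  Non-negativity is enforced by bounds; the optimizer is a
    derivative-based trust-region least-squares routine, deterministic for
    identical starts and data.  With ``multistart=True``, ``n_starts``
    seeded log-normally jittered starts are tried and the best optimum
    kept.

    ``model_builder`` (advanced) maps a parameter dict to a simulatable
    model; the perturbation module uses it to fit pulse constants that are
    not plain coefficients.
    """
    free = list(free)
    if not free:
        raise ValueError("at least one free parameter is required")
    if len(set(free)) != len(free):
        raise ValueError("duplicate free parameter names")
    n_obs = len(curve)
    if len(free) >= n_obs:
        raise ValueError("more free parameters than observations")
    if np.any(curve.values == 0):
        raise ValueError("cannot weight zero observations; drop those points")

    if model_builder is None:
        def model_builder(params: dict[str, float]) -> CompartmentalModel:
            return model.with_values(params)
        for name in free:
            parse_param_name(name)  # validate early

    x0 = np.array(
        [
            float(starts[name]) if starts and name in starts
            else model.parameter_value(name)
            for name in free
        ]
    )
    if np.any(x0 <= 0):
        bad = [n for n, v in zip(free, x0) if v <= 0]
        raise ValueError(f"starting values must be positive: {bad}")

    w = 1.0 / (curve.weight_fsd * curve.values)

    def residuals(x: np.ndarray) -> np.ndarray:
        params = dict(zip(free, x))
        m = model_builder(params)
        pred = simulate_tracer(
            m, 1.0, curve.times, rtol=sim_rtol, atol=sim_atol
        )
        return (curve.values - pred.values) * w

    lb = np.array([_lower_bound(n) for n in free])
    ub = np.full(len(free), np.inf)

    def solve_from(x_init: np.ndarray):
        return least_squares(
            residuals,
            np.clip(x_init, lb + 1e-12, None),
            bounds=(lb, ub),
            method="trf",
            diff_step=diff_step,
            ftol=ftol,
            xtol=xtol,
            gtol=1e-12,
            max_nfev=max_nfev,
        )

    candidates = [x0]
    if multistart and n_starts > 1:
        rng = np.random.default_rng(seed)
        for _ in range(n_starts - 1):
            candidates.append(x0 * np.exp(rng.normal(0.0, 0.7, size=x0.size)))

    best = None
    n_eval = 0
    for ci, x_init in enumerate(candidates):
        try:
            res = solve_from(x_init)
        except Exception:
            if ci == 0:  # the user-supplied start must be usable
                raise
            continue  # a wild jittered start may break the solver; skip it
        n_eval += res.nfev
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimization starts failed")
    res = best

    wss = float(2.0 * res.cost)
    k = len(free)
    dof = n_obs - k
    estimates = dict(zip(free, res.x))

    # FSDs from the inverse curvature (Gauss-Newton approximation).  A
    # parameter driven to its bound (typically 0) has no usable local
    # curvature: it is flagged unidentifiable and excluded from the
    # covariance so it cannot poison the FSDs of the others.
    J = res.jac
    s2 = wss / dof if dof > 0 else np.nan
    at_bound = res.x <= lb + 1e-12
    active = [i for i in range(k) if not at_bound[i]]
    cov = np.full((k, k), np.nan)
    singular = False
    if active:
        Jr = J[:, active]
        JtJ = Jr.T @ Jr
        try:
            covr = np.linalg.inv(JtJ) * s2
        except np.linalg.LinAlgError:
            covr = np.linalg.pinv(JtJ) * s2
            singular = True
        cov[np.ix_(active, active)] = covr
    with np.errstate(invalid="ignore"):
        variances = np.diag(cov).copy()
    fsds = {}
    for i, name in enumerate(free):
        v = variances[i]
        est = estimates[name]
        if at_bound[i] or singular or est == 0 or not np.isfinite(v) or v < 0:
            fsds[name] = math.inf  # unidentifiable
        else:
            fsds[name] = math.sqrt(v) / abs(est)

    message = res.message
    if singular:
        message += " [singular curvature: some FSDs unidentifiable]"
    if np.any(at_bound):
        bounded = [free[i] for i in range(k) if at_bound[i]]
        message += f" [at bound: {', '.join(bounded)}]"
    return FitResult(
        estimates=estimates,
        fsds=fsds,
        covariance=cov,
        param_names=free,
        wss=wss,
        n_obs=n_obs,
        n_free=k,
        aic=_aic(wss, n_obs, k),
        success=bool(res.success),
        message=message,
        n_eval=n_eval,
    )


@dataclass(frozen=True)
class ModelComparison:
    f_statistic: float
    p_value: float
    delta_aic: float
    verdict: str  # "justified" | "not justified"


def compare_models(fit_small: FitResult, fit_big: FitResult) -> ModelComparison:
    """Is the extra complexity of the bigger nested model justified?

    F = [(WSS_s - WSS_b)/(k_b - k_s)] / [WSS_b/(n - k_b)], tested against
    F(k_b - k_s, n - k_b); the verdict is "justified" only when the F test
    gives p < 0.05 *and* the bigger model lowers AIC by more than 2 units.
    The argument order is fixed (small, big): a call with the roles swapped
    is rejected rather than sign-flipped.
    """
    if fit_small.n_obs != fit_big.n_obs:
        raise ValueError("fits must be to the same data (n_obs differs)")
    if fit_big.n_free <= fit_small.n_free:
        raise ValueError(
            "the second argument must be the bigger nested model "
            f"(k_big={fit_big.n_free} <= k_small={fit_small.n_free})"
        )
    n = fit_big.n_obs
    dk = fit_big.n_free - fit_small.n_free
    dfd = n - fit_big.n_free
    if dfd <= 0:
        raise ValueError("no residual degrees of freedom in the big model")
    f_stat = ((fit_small.wss - fit_big.wss) / dk) / (fit_big.wss / dfd)
    p = float(stats.f.sf(f_stat, dk, dfd)) if f_stat > 0 else 1.0
    delta_aic = fit_big.aic - fit_small.aic
    verdict = "justified" if (p < 0.05 and delta_aic < -2.0) else "not justified"
    return ModelComparison(
        f_statistic=float(f_stat), p_value=p, delta_aic=float(delta_aic),
        verdict=verdict,
    )


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    p_value: float
    df: int
    significant: bool


def group_coefficient_ttest(
    v1: float, fsd1: float, v2: float, fsd2: float, df: int = 60
) -> TTestResult:
    """Between-group test of one coefficient from estimates and FSDs.

    t = (v1 - v2)/sqrt(SEM1^2 + SEM2^2) with SEM_i = v_i * fsd_i, referred
    to a Student t distribution (two-sided, default df = 60: the study's
    (3 pups/time x 14 times - 12 parameters) x 2 treatments convention).
    """
    if fsd1 < 0 or fsd2 < 0:
        raise ValueError("FSDs must be non-negative")
    sem2 = (v1 * fsd1) ** 2 + (v2 * fsd2) ** 2
    if sem2 == 0:
        if v1 == v2:
            return TTestResult(0.0, 1.0, df, False)
        raise ValueError("both SEMs are zero but the values differ")
    t = (v1 - v2) / math.sqrt(sem2)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(float(t), p, df, p < 0.05)


def sensitivity_to_fixed(
    model: CompartmentalModel,
    curve: TracerCurve,
    fixed: Sequence[str],
    free: Sequence[str],
    factor: float = 0.5,
    reference: FitResult | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Refit after scaling each fixed coefficient by (1 +/- factor).

    Returns a table indexed by (fixed coefficient, direction) whose columns
    hold the percent change of each free estimate relative to the reference
    fit.  A refit that fails to converge is recorded as NaN in its row, not
    raised.
    """
    if reference is None:
        reference = fit_model(model, curve, free, **fit_kwargs)
    ref = reference.estimates
    rows = []
    index = []
    if factor == 0:
        # the scaled model is identical to the reference model
        for name in fixed:
            for direction in ("+", "-"):
                index.append((name, direction))
                rows.append({k: 0.0 for k in free})
    else:
        for name in fixed:
            base = model.parameter_value(name)
            for direction, sgn in (("+", 1.0), ("-", -1.0)):
                scaled = base * (1.0 + sgn * factor)
                index.append((name, direction))
                if scaled <= 0:
                    rows.append({k: math.nan for k in free})
                    continue
                m_scaled = model.with_values({name: scaled})
                try:
                    refit = fit_model(
                        m_scaled, curve, free, starts=ref, **fit_kwargs
                    )
                    rows.append(
                        {
                            k: 100.0 * (refit.estimates[k] - ref[k]) / ref[k]
                            for k in free
                        }
                    )
                except Exception:
                    rows.append({k: math.nan for k in free})
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["fixed", "direction"]),
    )
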