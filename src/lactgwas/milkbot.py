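"""MilkBot lactation-curve model: evaluation, derived traits and fitting.

The MilkBot model describes daily milk yield as a function of days in milk
(DIM)::

    y(t) = a * (1 - exp((c - t)/b) / 2) * exp(-d*t)

with four interpretable parameters: ``a`` (scale, kg/day — the theoretical
maximum daily yield), ``b`` (ramp, days — how fast production rises in early
lactation), ``c`` (offset, days — lag between parturition and the start of
lactation) and ``d`` (decay, 1/day — rate of senescence of secretory
capacity; the inverse of persistency).

From a fitted curve three traits are derived and used as phenotypes
downstream: cumulative 305-day yield (M305, closed-form integral of the
curve), the time of peak lactation (t_peak, from dy/dt = 0) and the yield at
that peak.  Decay is stored in natural units (1/day) everywhere; the common
"decay x 1000" display convention is applied only when formatting reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "MilkBotParams",
    "DerivedTraits",
    "LactationFit",
    "evaluate",
    "peak_time",
    "peak_yield",
    "m305",
    "derived_traits",
    "fit_lactation",
    "fit_many",
]

DECAY_DISPLAY_SCALE = 1000.0  # presentation only; internals are 1/day


@dataclass(frozen=True)
class MilkBotParams:
    """One lactation's curve parameters.

    scale_a : kg/day, > 0
    ramp_b : days, > 0
    offset_c : days, unconstrained sign
    decay_d : 1/day, > 0 (natural units, not x1000)
    """

    scale_a: float
    ramp_b: float
    offset_c: float
    decay_d: float

    def validate(self) -> None:
        if not (self.scale_a >= 0):
            raise ValueError(f"scale a must be >= 0, got {self.scale_a}")
        if not (self.ramp_b > 0):
            raise ValueError(f"ramp b must be > 0, got {self.ramp_b}")
        if not (self.decay_d > 0):
            raise ValueError(f"decay d must be > 0, got {self.decay_d}")

    def as_array(self) -> np.ndarray:
        return np.array([self.scale_a, self.ramp_b, self.offset_c, self.decay_d])


@dataclass(frozen=True)
class DerivedTraits:
    """Traits derived from a MilkBot curve: M305 (kg), t_peak (days), peak yield (kg/day)."""

    m305: float
    t_peak: float
    peak_yield: float


@dataclass
class LactationFit:
    params: MilkBotParams
    derived: DerivedTraits
    n_testdays: int
    rss: float
    converged: bool


def evaluate(params: MilkBotParams, t) -> np.ndarray:
    """Daily yield y(t) = a(1 - exp((c-t)/b)/2) exp(-dt) at DIM ``t`` (scalar or array)."""
    params.validate()
    t = np.asarray(t, dtype=float)
    a, b, c, d = params.scale_a, params.ramp_b, params.offset_c, params.decay_d
    # exp((c-t)/b) can overflow for t << c; the curve is only meaningful for
    # t in lactation range, but guard anyway.
    z = np.clip((c - t) / b, None, 700.0)
    return a * (1.0 - 0.5 * np.exp(z)) * np.exp(-d * t)


def peak_time(params: MilkBotParams) -> float:
    """Time of peak lactation, t_peak = -b ln(2db/(db+1)) + c.

    Solves dy/dt = 0: the rise term and the decay term balance where
    exp((c-t)/b) = 2db/(db+1).  An interior maximum exists only when
    db < 1 (equivalently db/(db+1) < 1/2); otherwise decay dominates from
    the start and t_peak is undefined (ValueError).
    """
    params.validate()
    b, c, d = params.ramp_b, params.offset_c, params.decay_d
    db = d * b
    if db >= 1.0:
        raise ValueError(
            f"no interior peak: d*b = {db:.4g} >= 1 (curve declines from onset)"
        )
    return -b * np.log(2.0 * db / (db + 1.0)) + c


def peak_yield(params: MilkBotParams) -> float:
    """Yield at the lactation peak: the curve evaluated at t_peak."""
    return float(evaluate(params, peak_time(params)))


def m305(params: MilkBotParams) -> float:
    """Cumulative yield from calving to day 305, in kg (closed-form integral).

    M305 = (a - a e^{-305 d}) / d
           + a b e^{c/b} (e^{-305 (1/b + d)} - 1) / (2 + 2 b d)

    The second term requires e^{c/b}; offsets far beyond the biologically
    plausible range (c/b > ~700) would overflow and are rejected.
    """
    params.validate()
    a, b, c, d = params.scale_a, params.ramp_b, params.offset_c, params.decay_d
    if c / b > 700.0:
        raise OverflowError(f"offset/ramp ratio c/b = {c / b:.3g} too large for exp")
    term1 = (a - a * np.exp(-305.0 * d)) / d
    term2 = a * b * np.exp(c / b) * (np.exp(-305.0 * (1.0 / b + d)) - 1.0) / (2.0 + 2.0 * b * d)
    return float(term1 + term2)


def derived_traits(params: MilkBotParams) -> DerivedTraits:
    """M305, t_peak and peak yield for one parameter set."""
    return DerivedTraits(m305=m305(params), t_peak=peak_time(params), peak_yield=peak_yield(params))


def _residuals(theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, b, c, d = theta
    return a * (1.0 - 0.5 * np.exp(np.clip((c - t) / b, None, 50.0))) * np.exp(-d * t) - y


def _jacobian(theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, b, c, d = theta
    z = np.clip((c - t) / b, None, 50.0)
    e_z = np.exp(z)
    e_dt = np.exp(-d * t)
    base = (1.0 - 0.5 * e_z) * e_dt
    J = np.empty((t.size, 4))
    J[:, 0] = base
    J[:, 1] = a * e_dt * (0.5 * e_z * (c - t) / b**2)  # d/db of -(1/2)e^{(c-t)/b}
    J[:, 2] = a * e_dt * (-0.5 * e_z / b)
    J[:, 3] = -t * a * base
    return J


def _initial_values(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Heuristic starting point: a from the observed maximum, d from the late-lactation slope."""
    a0 = 1.05 * float(np.max(y))
    b0 = 20.0
    c0 = 0.0
    # decay from log-linear decline between the peak region and the last record
    i_pk = int(np.argmax(y))
    d0 = 1.5e-3
    if t[-1] > t[i_pk] + 30 and y[-1] > 0 and y[i_pk] > 0:
        slope = np.log(y[i_pk] / y[-1]) / (t[-1] - t[i_pk])
        if np.isfinite(slope) and slope > 1e-5:
            d0 = float(slope)
    return np.array([a0, b0, c0, d0])


def fit_lactation(
    dim,
    milk_kg,
    min_testdays: int = 5,
    min_span_dim: float = 100.0,
    max_restarts: int = 3,
    rng: np.random.Generator | None = None,
) -> LactationFit:
    """Fit the MilkBot curve to one lactation's test-day records by bounded
    nonlinear least squares (analytic Jacobian, trust-region reflective).

    Records must contain at least ``min_testdays`` test days spanning at least
    ``min_span_dim`` DIM; otherwise a ValueError is raised and the lactation
    should be excluded.  On solver failure the fit is restarted from up to
    ``max_restarts`` jittered starting points; a fit that never converges is
    returned with ``converged=False`` so callers can drop it.
    """
    t = np.asarray(dim, dtype=float)
    y = np.asarray(milk_kg, dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    if t.size < min_testdays:
        raise ValueError(f"too few test days: {t.size} < {min_testdays}")
    if t[-1] - t[0] < min_span_dim:
        raise ValueError(f"test days span {t[-1] - t[0]:.0f} DIM < {min_span_dim:.0f}")
    rng = rng or np.random.default_rng(0)

    lower = np.array([1e-6, 1e-2, -100.0, 1e-9])
    upper = np.array([300.0, 200.0, 100.0, 0.2])
    theta0 = np.clip(_initial_values(t, y), lower, upper)

    best = None
    start = theta0
    for attempt in range(max_restarts + 1):
        try:
            sol = least_squares(
                _residuals, start, jac=_jacobian, bounds=(lower, upper),
                args=(t, y), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            sol = None
        if sol is not None and (best is None or sol.cost < best.cost):
            best = sol
        if sol is not None and sol.success and sol.cost <= (best.cost if best else np.inf):
            if attempt == 0 or sol.cost <= best.cost:
                best = sol
                break
        # jittered restart
        jitter = rng.normal(0.0, 0.15, size=4)
        start = np.clip(theta0 * (1.0 + jitter) + np.array([0, 0, 1.0, 0]) * jitter[2], lower, upper)

    if best is None:
        raise RuntimeError("least-squares solver failed on all starts")
    a, b, c, d = best.x
    params = MilkBotParams(float(a), float(b), float(c), float(d))
    try:
        derived = derived_traits(params)
    except (ValueError, OverflowError):
        try:
            m = m305(params)
        except OverflowError:
            m = np.nan
        derived = DerivedTraits(m305=m, t_peak=np.nan, peak_yield=np.nan)
    return LactationFit(
        params=params,
        derived=derived,
        n_testdays=int(t.size),
        rss=float(2.0 * best.cost),
        converged=bool(best.success),
    )


def fit_many(
    records: pd.DataFrame,
    min_testdays: int = 5,
    min_span_dim: float = 100.0,
    animal_col: str = "animal",
    parity_col: str = "parity",
    dim_col: str = "dim",
    milk_col: str = "milk_kg",
) -> pd.DataFrame:
    """Fit every (animal, parity) lactation in a test-day table.

    Returns one row per lactation with the fitted parameters, derived traits
    and a ``status`` column: ``ok``, ``too_few_records`` or ``not_converged``.
    Lactations that cannot be fitted keep NaN parameter columns so exclusion
    counts are auditable.
    """
    rows = []
    rng = np.random.default_rng(12345)
    for (animal, parity), grp in records.groupby([animal_col, parity_col], sort=True):
        row = {"animal": animal, "parity": parity, "n_testdays": len(grp)}
        try:
            fit = fit_lactation(
                grp[dim_col].to_numpy(), grp[milk_col].to_numpy(),
                min_testdays=min_testdays, min_span_dim=min_span_dim, rng=rng,
            )
        except ValueError:
            row.update(status="too_few_records")
            rows.append(row)
            continue
        row.update(
            scale_a=fit.params.scale_a, ramp_b=fit.params.ramp_b,
            offset_c=fit.params.offset_c, decay_d=fit.params.decay_d,
            m305=fit.derived.m305, t_peak=fit.derived.t_peak,
            peak_yield=fit.derived.peak_yield, rss=fit.rss,
            status="ok" if fit.converged else "not_converged",
        )
        rows.append(row)
    return pd.DataFrame(rows)
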