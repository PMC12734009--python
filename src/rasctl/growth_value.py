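"""Specific growth rate (SGR) response surface and the cycle-value model.

The SGR of juvenile crucian carp is modelled as a quadratic surface in water
temperature ``T`` (°C) and dissolved oxygen ``DO`` (mg/L), fitted from a
3 x 3 full-factorial trial over {10, 20, 30} °C x {2.5, 5, 7.5} mg/L::

    SGR(T, DO) = b0 + bT*T + bD*DO + bTD*T*DO + bT2*T^2 + bD2*DO^2   [%/day]

The economic value a cycle adds (``Fn``, RMB) is affine in SGR,

    Fn(T, DO) = alpha * SGR(T, DO) - beta,

where ``alpha`` (RMB per SGR-percent) bundles biomass x market price x cycle
length / 100 and ``beta`` (RMB) is the fixed cycle cost (feed).  The affine
form is recovered from the published scenario sweeps: profit + control cost
is exactly an affine image of SGR at DO = 5 across all three ambient tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GrowthSurfaceParams",
    "SGRPoint",
    "ValueModelParams",
    "DEFAULT_GROWTH",
    "sgr",
    "sgr_point",
    "cycle_value_increment",
    "calibrate_value_model",
    "calibration_residuals",
    "default_value_params",
]

#: Factorial design ranges the surface was fitted on; outside them the
#: prediction is an extrapolation and is flagged as such.
DESIGN_T_RANGE = (10.0, 30.0)
DESIGN_DO_RANGE = (2.5, 7.5)
DESIGN_POINTS = [(t, d) for t in (10.0, 20.0, 30.0) for d in (2.5, 5.0, 7.5)]


@dataclass(frozen=True)
class GrowthSurfaceParams:
    """Coefficients of the quadratic SGR surface (defaults: fitted values)."""

    intercept: float = -1.355
    coef_t: float = 0.108            # %/day per °C
    coef_do: float = 0.479           # %/day per (mg/L)
    coef_t_do: float = 4.3e-3        # %/day per (°C·mg/L)
    coef_t2: float = -3.125e-3       # %/day per °C²
    coef_do2: float = -0.043         # %/day per (mg/L)²

    @property
    def concave(self) -> bool:
        """True when the surface is concave in each variable."""
        return self.coef_t2 < 0 and self.coef_do2 < 0


DEFAULT_GROWTH = GrowthSurfaceParams()


@dataclass(frozen=True)
class SGRPoint:
    """SGR prediction with an extrapolation flag."""

    value: float
    extrapolated: bool


def _check_finite(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


def sgr(temperature: float, oxygen: float, params: GrowthSurfaceParams = DEFAULT_GROWTH) -> float:
    """Specific growth rate (%/day) at the given water temperature and DO."""
    _check_finite(temperature=temperature, oxygen=oxygen)
    t, d = temperature, oxygen
    return (
        params.intercept
        + params.coef_t * t
        + params.coef_do * d
        + params.coef_t_do * t * d
        + params.coef_t2 * t * t
        + params.coef_do2 * d * d
    )


def sgr_point(temperature: float, oxygen: float, params: GrowthSurfaceParams = DEFAULT_GROWTH) -> SGRPoint:
    """Like :func:`sgr` but flags predictions outside the calibrated regime."""
    value = sgr(temperature, oxygen, params)
    extrapolated = not (
        DESIGN_T_RANGE[0] <= temperature <= DESIGN_T_RANGE[1]
        and DESIGN_DO_RANGE[0] <= oxygen <= DESIGN_DO_RANGE[1]
    )
    return SGRPoint(value=value, extrapolated=extrapolated)


class UncalibratedValueModelError(ValueError):
    """The cycle-value model was used before alpha/beta were supplied."""


@dataclass(frozen=True)
class ValueModelParams:
    """Affine cycle-value model ``Fn = alpha*SGR - beta``.

    alpha : RMB per SGR-percent (slope); must be > 0.
    beta : RMB, fixed cycle cost entered as the negative intercept.
    The optional decomposition (biomass x price x days / 100 = alpha,
    feed cost x days = beta) is checked for consistency when supplied.
    """

    alpha: float
    beta: float
    fish_biomass: float | None = None    # kg
    fish_price: float | None = None      # RMB/kg
    cycle_days: float | None = None      # days
    daily_feed_cost: float | None = None  # RMB/day

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha) or not math.isfinite(self.beta):
            raise ValueError("alpha and beta must be finite")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        decomp = (self.fish_biomass, self.fish_price, self.cycle_days)
        if all(v is not None for v in decomp):
            implied_alpha = self.fish_biomass * self.fish_price * self.cycle_days / 100.0
            if not math.isclose(implied_alpha, self.alpha, rel_tol=1e-6):
                raise ValueError(
                    f"decomposition inconsistent: biomass*price*days/100 = {implied_alpha:.4f} "
                    f"but alpha = {self.alpha:.4f}"
                )
            if self.daily_feed_cost is not None:
                implied_beta = self.daily_feed_cost * self.cycle_days
                if not math.isclose(implied_beta, self.beta, rel_tol=1e-6):
                    raise ValueError(
                        f"decomposition inconsistent: feed*days = {implied_beta:.4f} "
                        f"but beta = {self.beta:.4f}"
                    )


def cycle_value_increment(
    temperature: float,
    oxygen: float,
    value_params: ValueModelParams | None,
    growth: GrowthSurfaceParams = DEFAULT_GROWTH,
) -> float:
    """Cycle value increment Fn (RMB) at the given set-point."""
    if value_params is None:
        raise UncalibratedValueModelError(
            "value model not calibrated: pass ValueModelParams (e.g. default_value_params())"
        )
    return value_params.alpha * sgr(temperature, oxygen, growth) - value_params.beta


def calibrate_value_model(
    rows: Iterable[tuple[float, float, float]],
    growth: GrowthSurfaceParams = DEFAULT_GROWTH,
    oxygen: float = 5.0,
) -> ValueModelParams:
    """Fit (alpha, beta) from sweep rows ``(target_T, control_cost, profit)``.

    The gross cycle value is G = profit + cost; the model G = alpha*SGR - beta
    is solved exactly for two rows and by least squares for more.  Rows whose
    SGR values coincide are degenerate and rejected.
    """
    rows = list(rows)
    if len(rows) < 2:
        raise ValueError("need at least 2 calibration rows")
    s = np.array([sgr(t, oxygen, growth) for t, _, _ in rows])
    g = np.array([cost + profit for _, cost, profit in rows])
    if np.ptp(s) < 1e-9:
        raise ValueError("degenerate calibration rows: all SGR values equal")
    design = np.column_stack([s, -np.ones_like(s)])
    coef, *_ = np.linalg.lstsq(design, g, rcond=None)
    return ValueModelParams(alpha=float(coef[0]), beta=float(coef[1]))


def calibration_residuals(
    params: ValueModelParams,
    rows: Sequence[tuple[float, float, float]],
    growth: GrowthSurfaceParams = DEFAULT_GROWTH,
    oxygen: float = 5.0,
) -> np.ndarray:
    """Residuals G_observed - G_model (RMB) on validation rows."""
    s = np.array([sgr(t, oxygen, growth) for t, _, _ in rows])
    g = np.array([cost + profit for _, cost, profit in rows])
    return g - (params.alpha * s - params.beta)


def default_value_params(growth: GrowthSurfaceParams = DEFAULT_GROWTH) -> ValueModelParams:
    """Calibrated default value model (from the packaged ambient-8 anchor rows)."""
    from . import reference

    return calibrate_value_model(reference.value_calibration_rows(), growth)
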