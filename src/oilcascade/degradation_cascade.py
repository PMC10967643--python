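"""The degradation cascade: chained linear trends predicting viscosity from
processing time, TPC trend models, the composition-coupled b model, and
parity analysis.

The cascade is the core of the stability model.  Per-timepoint Lioumbas fits
give (a, b) pairs; empirically, over 32 h at 180 °C,

* b falls linearly with processing time t_P (hours), and
* a falls linearly with b (slopes near −42, i.e. a rises as heating makes
  b more negative),

so two chained straight lines b(t_P) and a(b), composed with the Lioumbas
law μ = exp(a + b·(ln T)²), forecast viscosity at any (t_P, T) without new
measurements.  Both trends are full-precision OLS fits; coefficients are
never rounded before being propagated, since the cascade's predictions are
sensitive to the second decimal of b.

Companion pieces: TPC grows linearly in t_P (one line per antioxidant
treatment), which turns the regulatory 27 % TPC ceiling into a predicted
"waste point" time; and b can alternatively be regressed on the chemistry
(ECN, TPC) as a plane, linking the rheological parameter to composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .core_types_io import (
    InsufficientDataError,
    LioumbasFit,
    NoCrossingError,
    OilCascadeError,
    SingularDesignError,
    TPCSeries,
)
from .viscosity_models import _ols_line

logger = logging.getLogger("oilcascade")

#: Regulatory TPC ceiling (%) used in China; the oil is waste beyond it.
TPC_WASTE_THRESHOLD = 27.0


@dataclass(frozen=True)
class TrendFit:
    """A straight-line OLS fit y = slope·x + intercept with original-scale r²."""

    slope: float
    intercept: float
    r2: float
    n: int

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class CascadeModel:
    """Chained trends b(t_P) and a(b) over a fitted processing-time range."""

    b_trend: TrendFit
    a_of_b: TrendFit
    t_P_range: tuple[float, float]


@dataclass(frozen=True)
class CascadePrediction:
    """A forecast μ(t_P, T) with the intermediate parameters made visible."""

    mu: float
    a: float
    b: float
    t_P: float
    temperature_c: float
    extrapolated: bool


@dataclass(frozen=True)
class ParityRecord:
    """One observed/calculated pair with residual and percent deviation."""

    observed: float
    calculated: float

    @property
    def residual(self) -> float:
        return self.observed - self.calculated

    @property
    def deviation_pct(self) -> float:
        return self.residual / self.observed * 100.0


@dataclass(frozen=True)
class ParitySummary:
    records: tuple[ParityRecord, ...]
    max_abs_residual: float
    max_abs_deviation_pct: float


@dataclass(frozen=True)
class PlaneFit:
    """Two-predictor OLS plane b = intercept + coef_ecn·ECN + coef_tpc·TPC."""

    intercept: float
    coef_ecn: float
    coef_tpc: float
    r2: float


@dataclass(frozen=True)
class WastePoint:
    """Processing time at which a TPC trend crosses the regulatory ceiling."""

    hours: float
    threshold: float
    already_exceeded: bool


def fit_linear_trend(x: Sequence[float], y: Sequence[float]) -> TrendFit:
    """OLS line of y on x; r² on the original scale, 1 if residuals vanish."""
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape:
        raise OilCascadeError(
            f"x and y lengths differ: {x_arr.size} vs {y_arr.size}"
        )
    if x_arr.size < 3:
        raise InsufficientDataError(
            f"linear trend needs >= 3 points, got {x_arr.size}"
        )
    slope, intercept, r2 = _ols_line(x_arr, y_arr)
    return TrendFit(slope=slope, intercept=intercept, r2=r2, n=x_arr.size)


def build_cascade(fits: Mapping[float, LioumbasFit]) -> CascadeModel:
    """Chain per-timepoint Lioumbas fits into b(t_P) and a(b) trends.

    ``fits`` maps processing time (hours) to the fit at that time; at least
    three distinct times are required.
    """
    if len(fits) < 3:
        raise InsufficientDataError(
            f"cascade needs >= 3 time points, got {len(fits)}"
        )
    times = sorted(fits)
    b_vals = [fits[t].b for t in times]
    a_vals = [fits[t].a for t in times]
    return CascadeModel(
        b_trend=fit_linear_trend(times, b_vals),
        a_of_b=fit_linear_trend(b_vals, a_vals),
        t_P_range=(times[0], times[-1]),
    )


def cascade_predict(model: CascadeModel, t_P: float,
                    temperature_c: float) -> CascadePrediction:
    """Forecast μ(t_P, T): b from the time trend, a from b, μ from Lioumbas.

    Predictions outside the fitted t_P range are returned but flagged as
    extrapolation (and logged) — the trends are empirical, not kinetic laws.
    """
    if temperature_c <= 0:
        raise OilCascadeError(
            f"Lioumbas model needs T > 0 degC, got {temperature_c}"
        )
    lo, hi = model.t_P_range
    extrapolated = not lo <= t_P <= hi
    if extrapolated:
        logger.warning(
            "cascade prediction at t_P=%.3g h extrapolates beyond the "
            "fitted range [%.3g, %.3g] h", t_P, lo, hi,
        )
    b = model.b_trend.predict(t_P)
    a = model.a_of_b.predict(b)
    mu = float(np.exp(a + b * np.log(temperature_c) ** 2))
    return CascadePrediction(mu=mu, a=a, b=b, t_P=t_P,
                             temperature_c=temperature_c,
                             extrapolated=extrapolated)


def parity_analysis(
    pairs: Sequence[tuple[float, float]],
) -> ParitySummary:
    """Observed-versus-calculated records with residual and deviation extrema.

    deviation% is the residual normalised by the *observed* value, the
    convention of experimental parity plots; an observed value of zero
    therefore has no defined deviation and is rejected.
    """
    records = []
    for i, (obs, calc) in enumerate(pairs):
        if obs == 0:
            raise OilCascadeError(
                f"pair {i} (observed=0, calculated={calc}): deviation% "
                "undefined for observed = 0"
            )
        records.append(ParityRecord(observed=float(obs), calculated=float(calc)))
    if not records:
        raise InsufficientDataError("parity analysis needs at least one pair")
    return ParitySummary(
        records=tuple(records),
        max_abs_residual=max(abs(r.residual) for r in records),
        max_abs_deviation_pct=max(abs(r.deviation_pct) for r in records),
    )


def fit_tpc_trend(series: TPCSeries) -> TrendFit:
    """Straight-line fit of a treatment's TPC (%) on processing time (h)."""
    return fit_linear_trend(series.times, series.values)


def fit_b_on_composition(b: Sequence[float], ecn: Sequence[float],
                         tpc: Sequence[float]) -> PlaneFit:
    """Regress the Lioumbas b parameter on (ECN, TPC) across all conditions.

    All (treatment × time) observations are pooled into one design — the
    model is a single global plane, not per-treatment planes.
    """
    b_arr = np.asarray(b, dtype=float)
    ecn_arr = np.asarray(ecn, dtype=float)
    tpc_arr = np.asarray(tpc, dtype=float)
    if not b_arr.size == ecn_arr.size == tpc_arr.size:
        raise OilCascadeError("b, ecn and tpc must have equal lengths")
    if b_arr.size < 4:
        raise InsufficientDataError(
            f"plane fit needs >= 4 observations, got {b_arr.size}"
        )
    design = sm.add_constant(np.column_stack([ecn_arr, tpc_arr]),
                             has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError(
            "rank-deficient design: ECN and TPC are collinear or constant"
        )
    result = sm.OLS(b_arr, design).fit()
    # zero-residual degenerate case (constant b): statsmodels reports
    # an uncentred/NaN r2; define it as 1 like the line fits
    if result.centered_tss == 0:
        r2 = 1.0 if result.ssr < 1e-24 else 0.0
    else:
        r2 = float(result.rsquared)
    return PlaneFit(
        intercept=float(result.params[0]),
        coef_ecn=float(result.params[1]),
        coef_tpc=float(result.params[2]),
        r2=max(0.0, min(1.0, r2)),
    )


def waste_point(trend: TrendFit,
                threshold: float = TPC_WASTE_THRESHOLD) -> WastePoint:
    """Solve the fitted TPC line for the time it reaches the waste threshold.

    Requires a rising trend (slope > 0).  If the intercept already sits at or
    above the threshold the crossing time is zero or negative and the result
    is flagged ``already_exceeded``.
    """
    if trend.slope <= 0:
        raise NoCrossingError(
            f"TPC trend with slope {trend.slope} never reaches {threshold}%"
        )
    hours = (threshold - trend.intercept) / trend.slope
    return WastePoint(hours=hours, threshold=threshold,
                      already_exceeded=hours <= 0)
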