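"""Aggregated time series, CUSUM, polynomial fits and inflection points.

The learning curve of a group of operators is summarized by the
per-serial-index mean procedure time x_1..x_n (one value per serial
procedure, averaged over the group's operators). Its CUSUM is the
running sum of deviations from the grand mean x̄:

    S_1 = x_1 − x̄,   S_i = S_{i−1} + (x_i − x̄),   so   S_n = 0.

While times decline, early values sit above the mean and the CUSUM
rises; once performance passes the mean the CUSUM turns over and
declines back to zero. The inflection point — the serial index where
the CUSUM peaks — therefore separates the initial (learning) phase from
the consolidation phase, and is reported as the LAST procedure of the
initial phase.

Two detection methods are provided: ``raw_argmax`` takes the maximum of
the CUSUM series directly (earliest index on ties, so training
requirements are never overstated); ``poly_peak`` fits a polynomial to
the CUSUM series and takes the continuous maximum of the fitted curve
over [1, n], rounded to the nearest serial index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from numpy.polynomial import polynomial as npoly

from .log_io import ProcedureLog

INFLECTION_METHODS = ("raw_argmax", "poly_peak")


@dataclass
class AggregatedSeries:
    """Mean procedure time per serial index for a group of operators."""

    group: str
    values: np.ndarray  # mean minutes at serial indices 1..n
    n_operators: int


@dataclass
class CusumSeries:
    """Running sum of deviations from the grand mean; S_n = 0 by construction."""

    values: np.ndarray
    source_mean: float


@dataclass
class PolyFit:
    degree: int
    coefficients: np.ndarray  # ascending powers
    fitted_values: np.ndarray
    r2_adjusted: float


@dataclass
class InflectionResult:
    """Detected change index (1-based; last procedure of the initial phase)."""

    index: int
    method: str
    cusum: CusumSeries
    fit: Optional[PolyFit] = None


def aggregate_times(log: ProcedureLog, group: str) -> AggregatedSeries:
    """Per-serial-index arithmetic mean of time over a group's operators.

    ``group`` is ``junior``/``senior``, ``all``, or an operator id. All
    selected operators must share the same number of procedures.
    """
    sub = log.select(group)
    if not sub.records:
        raise ValueError(f"no records for group {group!r}")
    by_op: dict[str, dict[int, float]] = {}
    for r in sub.records:
        by_op.setdefault(r.operator_id, {})[r.serial_index] = r.time_min
    lengths = {op: len(d) for op, d in by_op.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"operators have unequal series lengths: {lengths}")
    n = next(iter(lengths.values()))
    values = np.zeros(n)
    for d in by_op.values():
        if sorted(d) != list(range(1, n + 1)):
            raise ValueError("serial indices must be consecutive 1..n for every operator")
        values += [d[i] for i in range(1, n + 1)]
    values /= len(by_op)
    return AggregatedSeries(group=group, values=values, n_operators=len(by_op))


def cusum(series: Union[AggregatedSeries, Sequence[float]]) -> CusumSeries:
    """CUSUM of a time series: cumulative sum of deviations from its mean."""
    x = np.asarray(series.values if isinstance(series, AggregatedSeries) else series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute CUSUM of an empty series")
    xbar = float(x.mean())
    return CusumSeries(values=np.cumsum(x - xbar), source_mean=xbar)


def _adjusted_r2(y: np.ndarray, fitted: np.ndarray, n_params: int) -> float:
    n = y.size
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        # constant data: a fit that reproduces it is perfect
        return 1.0 if ss_res < 1e-12 else -np.inf
    r2 = 1.0 - ss_res / ss_tot
    if n - n_params - 1 <= 0:
        return -np.inf
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def fit_polynomial(series: Sequence[float], degree_policy: Union[int, str] = "auto") -> PolyFit:
    """Least-squares polynomial of the series against serial index 1..n.

    ``degree_policy`` is a fixed degree, or ``"auto"`` to fit degrees
    2–4 and keep the one maximizing adjusted R². Requires n > degree+1.
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    x = np.arange(1, n + 1, dtype=float)

    def fit_one(deg: int) -> PolyFit:
        if n <= deg + 1:
            raise ValueError(f"series length {n} too short for degree {deg} (need n > degree+1)")
        coef = npoly.polyfit(x, y, deg)
        fitted = npoly.polyval(x, coef)
        return PolyFit(deg, coef, fitted, _adjusted_r2(y, fitted, deg))

    if degree_policy == "auto":
        candidates = [fit_one(d) for d in (2, 3, 4) if n > d + 1]
        if not candidates:
            raise ValueError(f"series length {n} too short for any degree in 2-4")
        return max(candidates, key=lambda f: f.r2_adjusted)
    return fit_one(int(degree_policy))


def _poly_continuous_argmax(coef: np.ndarray, lo: float, hi: float) -> float:
    """Argmax of a polynomial (ascending coefficients) on [lo, hi]."""
    candidates = [lo, hi]
    deriv = npoly.polyder(coef)
    if deriv.size > 0 and np.any(deriv != 0):
        roots = npoly.polyroots(deriv)
        for r in roots:
            if abs(r.imag) < 1e-9 and lo <= r.real <= hi:
                candidates.append(float(r.real))
    vals = npoly.polyval(np.asarray(candidates), coef)
    return float(candidates[int(np.argmax(vals))])


def detect_inflection(
    cusum_series: CusumSeries,
    method: str = "raw_argmax",
    fit: Optional[PolyFit] = None,
    degree_policy: Union[int, str] = "auto",
) -> InflectionResult:
    """Locate the CUSUM peak separating initial and consolidation phases.

    ``raw_argmax``: index of the maximum CUSUM value, earliest on ties.
    ``poly_peak``: continuous maximum of a polynomial fitted to the
    CUSUM series (``fit`` if given, else fitted here under
    ``degree_policy``), rounded to the nearest integer in [1, n].
    """
    s = np.asarray(cusum_series.values, dtype=float)
    n = s.size
    if n < 3:
        raise ValueError(f"need at least 3 procedures to detect an inflection, got {n}")
    if method == "raw_argmax":
        return InflectionResult(int(np.argmax(s)) + 1, method, cusum_series, fit=None)
    if method == "poly_peak":
        if fit is None:
            fit = fit_polynomial(s, degree_policy)
        xstar = _poly_continuous_argmax(fit.coefficients, 1.0, float(n))
        index = int(min(max(round(xstar), 1), n))
        return InflectionResult(index, method, cusum_series, fit=fit)
    raise ValueError(f"unknown method {method!r}; expected one of {INFLECTION_METHODS}")


def segment_phases(n: int, inflection: Union[InflectionResult, int]) -> list[str]:
    """Phase label per serial index: 1..k 'initial', k+1..n 'consolidation'.

    k is the inflection index (included in the initial phase). An
    inflection at index n leaves no consolidation phase and is an error.
    """
    k = inflection.index if isinstance(inflection, InflectionResult) else int(inflection)
    if not 1 <= k < n:
        raise ValueError(f"inflection index {k} must satisfy 1 <= k < n={n}")
    return ["initial"] * k + ["consolidation"] * (n - k)


def analyze_group(
    log: ProcedureLog,
    group: str,
    method: str = "raw_argmax",
    degree_policy: Union[int, str] = "auto",
) -> dict:
    """Full learning-curve pass for one group.

    Aggregates times, computes the CUSUM, fits the polynomial to the
    CUSUM series, and detects the inflection. Returns a dict with keys
    ``series``, ``cusum``, ``fit``, ``inflection``.
    """
    series = aggregate_times(log, group)
    cs = cusum(series)
    fit = fit_polynomial(cs.values, degree_policy)
    infl = detect_inflection(cs, method=method, fit=fit if method == "poly_peak" else None,
                             degree_policy=degree_policy)
    return {"series": series, "cusum": cs, "fit": fit, "inflection": infl}


def learning_curve_frame(result: dict):
    """Per-serial-index table (serial_index, aggregated_time, cusum,
    fitted_cusum) for export/replotting."""
    import pandas as pd

    series: AggregatedSeries = result["series"]
    cs: CusumSeries = result["cusum"]
    fit: PolyFit = result["fit"]
    n = series.values.size
    return pd.DataFrame(
        {
            "serial_index": np.arange(1, n + 1),
            "aggregated_time": series.values,
            "cusum": cs.values,
            "fitted_cusum": fit.fitted_values,
        }
    )
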