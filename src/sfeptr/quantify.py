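"""Response curves, Poisson counting error, and amount estimation.

Ion counting on the TOF detector follows Poisson statistics, so the
relative quantitation error at N counts is 1/sqrt(N): 10% at 100 counts.
The limit of quantitation (LOQ) is defined as the analyte amount producing
100 counts, obtained from the slope of a response curve (peak area vs
amount, at two or more amounts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class ResponseCurve:
    label: str
    points: list[tuple[float, float]]  # (amount, area counts)
    slope: float  # counts per amount unit
    loq: float  # amount producing loq_counts
    loq_counts: float = 100.0
    intercept: float = 0.0


@dataclass
class QuantEstimate:
    counts: float
    amount: float
    relative_error: float | None  # 1/sqrt(counts); None when counts == 0


def fit_response(
    points: list[tuple[float, float]],
    label: str = "",
    loq_counts: float = 100.0,
    through_origin: bool = True,
) -> ResponseCurve:
    """Least-squares response line; LOQ = amount giving ``loq_counts``.

    Default is regression through the origin (slope = Σ a·y / Σ a²), the
    model consistent with a blank-corrected zero at zero amount; a free
    intercept is available as a switch.
    """
    amounts = np.array([p[0] for p in points], dtype=float)
    areas = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(amounts)) < 2:
        raise ValueError("need at least 2 distinct amounts to fit a response curve")
    if np.any(areas < 0):
        raise ValueError("areas must be nonnegative")
    if not np.any(areas > 0):
        raise ValueError("all areas are zero; no response")
    if through_origin:
        slope = float(np.sum(amounts * areas) / np.sum(amounts**2))
        intercept = 0.0
    else:
        slope, intercept = (float(v) for v in np.polyfit(amounts, areas, 1))
    if slope <= 0:
        raise ValueError(f"non-positive response slope ({slope:g})")
    loq = (loq_counts - intercept) / slope
    return ResponseCurve(
        label=label,
        points=[(float(a), float(y)) for a, y in points],
        slope=slope,
        loq=loq,
        loq_counts=loq_counts,
        intercept=intercept,
    )


def poisson_relative_error(counts: float) -> float:
    """Relative counting error sqrt(N)/N = 1/sqrt(N)."""
    if counts <= 0:
        raise ValueError("counts must be > 0")
    return 1.0 / math.sqrt(counts)


def estimate_amount(counts: float, curve: ResponseCurve) -> QuantEstimate:
    """Convert an ion-count area to an amount via the response slope."""
    if counts < 0:
        raise ValueError("counts must be >= 0")
    amount = (counts - curve.intercept) / curve.slope if counts > 0 else 0.0
    rel = poisson_relative_error(counts) if counts > 0 else None
    return QuantEstimate(counts=counts, amount=amount, relative_error=rel)


def replicate_summary(values: list[float], ddof: int = 1) -> tuple[float, float]:
    """Mean and relative standard deviation of replicate measurements.

    RSD is returned as a fraction (sample SD, n−1 denominator, by default).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = float(v.mean())
    if mean == 0:
        raise ValueError("mean of replicates is zero; RSD undefined")
    return mean, float(v.std(ddof=ddof) / mean)
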