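"""TOF mass calibration and lock-mass correction.

Calibration maps an abstract monotone flight-time axis t to m/z with a
third-order polynomial. The default functional form is sqrt(m/z) = p3(t),
since TOF physics gives m/z proportional to t squared; a direct
m/z = p3(t) form is available as a switch.

Lock-mass correction is single-point multiplicative: one reference
compound of known exact m/z is co-analyzed per run and the whole m/z axis
is scaled by exact/observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .annotate import theoretical_mz
from .spectra import SpectrumSeries, coadd, rescale_mz

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationModel:
    """Third-order polynomial mass calibration on a flight-time domain."""

    coefficients: np.ndarray  # ascending powers, length 4
    domain: tuple[float, float]
    form: str = "sqrt"  # "sqrt": sqrt(mz)=p3(t); "direct": mz=p3(t)
    residuals_mda: np.ndarray | None = None

    @property
    def calibrated_mz_range(self) -> tuple[float, float]:
        lo = apply_calibration(self, self.domain[0])
        hi = apply_calibration(self, self.domain[1])
        return (lo, hi)


@dataclass(frozen=True)
class LockMassReference:
    """A known reference ion used to rescale the m/z axis per run."""

    label: str
    formula: str
    species: str
    exact_mz: float

    @classmethod
    def from_formula(cls, label: str, formula: str, species: str) -> "LockMassReference":
        return cls(label, formula, species, theoretical_mz(formula, species))


#: Built-in lock-mass references; the phosphazine/phosphazene pair covers the
#: positive mode, tetracosenoic acid the negative mode.
LOCKMASS_REFERENCES: dict[str, LockMassReference] = {
    "P321": LockMassReference.from_formula("P321", "C6H18N3O6P3", "[M+H]+"),
    "P621": LockMassReference.from_formula("P621", "C12H18F12N3O6P3", "[M+H]+"),
    "tetracosenoic": LockMassReference.from_formula("tetracosenoic", "C24H46O2", "[M-H]-"),
}


def _poly_increasing(coeffs: np.ndarray, domain: tuple[float, float]) -> bool:
    t = np.linspace(domain[0], domain[1], 512)
    deriv = np.polynomial.polynomial.polyval(t, np.polynomial.polynomial.polyder(coeffs))
    return bool(np.all(deriv > 0))


def fit_tof_calibration(
    references: list[tuple[float, float]],
    form: str = "sqrt",
) -> CalibrationModel:
    """Least-squares third-order polynomial fit of (flight_time, known m/z).

    At exactly 4 references the fit interpolates (zero residuals). The
    fitted polynomial must be strictly increasing on the reference time
    span; otherwise the calibration is rejected.
    """
    if form not in ("sqrt", "direct"):
        raise ValueError(f"unknown calibration form {form!r}")
    if len(references) < 4:
        raise CalibrationError(f"need >= 4 calibration references, got {len(references)}")
    t = np.asarray([r[0] for r in references], dtype=float)
    mz = np.asarray([r[1] for r in references], dtype=float)
    if len(np.unique(t)) != len(t):
        raise CalibrationError("calibration flight times must be distinct")
    y = np.sqrt(mz) if form == "sqrt" else mz
    coeffs = np.polynomial.polynomial.polyfit(t, y, 3)
    domain = (float(t.min()), float(t.max()))
    if not _poly_increasing(coeffs, domain):
        raise CalibrationError("fitted calibration polynomial is not monotone on its domain")
    model = CalibrationModel(coefficients=coeffs, domain=domain, form=form)
    fitted = np.array([apply_calibration(model, ti) for ti in t])
    model.residuals_mda = (fitted - mz) * 1e3
    return model


def apply_calibration(model: CalibrationModel, flight_time: float) -> float:
    """m/z at one flight time; warns outside the calibrated domain."""
    if not (model.domain[0] <= flight_time <= model.domain[1]):
        logger.warning("flight time %g outside calibrated domain %s", flight_time, model.domain)
    val = float(np.polynomial.polynomial.polyval(flight_time, model.coefficients))
    if model.form == "sqrt":
        if val < 0:
            raise CalibrationError(f"calibration polynomial negative at t={flight_time}")
        return val * val
    return val


def invert_calibration(model: CalibrationModel, mz: float) -> float:
    """Flight time at which the model yields ``mz`` (bisection on the domain)."""
    from scipy.optimize import brentq

    lo, hi = model.domain
    f = lambda t: apply_calibration(model, t) - mz
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def find_reference_centroid(
    series: SpectrumSeries,
    reference: LockMassReference,
    search_window_mda: float = 20.0,
) -> tuple[float, int]:
    """Counts-weighted centroid of the reference ion in the co-added run.

    Returns (observed m/z, total counts). Raises if no counts fall inside
    the search window.
    """
    hw = search_window_mda * 1e-3
    spec = coadd(series, bin_width_mda=min(search_window_mda, 5.0))
    sel = np.abs(spec.mz - reference.exact_mz) <= hw
    total = int(spec.counts[sel].sum())
    if total == 0:
        raise ValueError(
            f"lock-mass reference {reference.label} ({reference.exact_mz:.4f}) "
            f"not found within ±{search_window_mda} mDa"
        )
    observed = float(np.average(spec.mz[sel], weights=spec.counts[sel]))
    return observed, total


def lock_mass_correct(
    series: SpectrumSeries,
    reference: LockMassReference,
    search_window_mda: float = 20.0,
) -> SpectrumSeries:
    """Rescale the m/z axis so the reference centroid lands on its exact m/z.

    The correction is a single multiplicative factor exact/observed applied
    to every centroid; the factor is stored in the run metadata. Applying
    the correction twice changes nothing beyond numerical precision.
    """
    observed, total = find_reference_centroid(series, reference, search_window_mda)
    factor = reference.exact_mz / observed
    corrected = rescale_mz(series, factor)
    corrected.metadata["lockmass_label"] = reference.label
    corrected.metadata["lockmass_factor"] = factor
    corrected.metadata["lockmass_observed_mz"] = observed
    corrected.metadata["lockmass_counts"] = total
    logger.info(
        "lock-mass %s: observed %.5f, factor %.9f (%d counts)",
        reference.label, observed, factor, total,
    )
    return corrected
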