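"""Wet-lab arithmetic: Surveyor cleavage, tumor volume, viability, IC50.

These are the bench-side calculations that accompany the in-silico
pipeline: densitometry-based cleavage efficiency for CRISPR editing
(Surveyor/mismatch-nuclease assay), caliper tumor volume for xenografts,
percent viability inhibition for endpoint drug assays, and four-parameter
log-logistic (4PL) dose-response fitting for IC50 estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "CleavageMeasurement",
    "TumorMeasurement",
    "DoseResponse",
    "IC50Fit",
    "fraction_cleaved",
    "cleavage_efficiency",
    "tumor_volume",
    "viability_inhibition",
    "fit_ic50",
]


@dataclass(frozen=True)
class CleavageMeasurement:
    """Band densitometry readings (arbitrary units) from a cleavage gel."""

    cleaved_intensities: tuple[float, ...]
    parental_intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = list(self.cleaved_intensities) + list(self.parental_intensities)
        if any(v < 0 for v in vals):
            raise ValueError("band intensities must be non-negative")
        if not any(v > 0 for v in vals):
            raise ValueError("all band intensities are zero")


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper length/width in mm; the larger measurement is Length."""

    length: float
    width: float

    def __post_init__(self) -> None:
        if self.length < 0 or self.width < 0:
            raise ValueError("caliper measurements must be non-negative")
        if self.width > self.length:
            # caliper convention: auto-order so length >= width
            length, width = self.width, self.length
            object.__setattr__(self, "length", length)
            object.__setattr__(self, "width", width)


@dataclass(frozen=True)
class DoseResponse:
    """Drug doses (uM, positive ascending) and normalized viability.

    ``responses`` are fractions of the vehicle-control signal; values a
    little above 1 are tolerated (assay noise).
    """

    doses: tuple[float, ...]
    responses: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if d.size != r.size:
            raise ValueError("doses and responses must have equal length")
        if d.size < 4:
            raise ValueError("dose-response fitting needs at least 4 dose levels")
        if (d <= 0).any():
            raise ValueError("doses must be positive")
        if (np.diff(d) <= 0).any():
            raise ValueError("doses must be strictly ascending")


@dataclass(frozen=True)
class IC50Fit:
    ic50: float
    top: float
    bottom: float
    hill: float
    residual_norm: float
    converged: bool


def fraction_cleaved(m: CleavageMeasurement) -> float:
    """sum(cleaved) / (sum(cleaved) + sum(parental)), in [0, 1]."""
    cleaved = float(sum(m.cleaved_intensities))
    total = cleaved + float(sum(m.parental_intensities))
    return cleaved / total


def cleavage_efficiency(fc: float) -> float:
    """Editing efficiency from the cleaved fraction: 1 - sqrt(1 - fc).

    The square root accounts for re-annealing: a duplex is cleavable when
    exactly one strand carries an indel, so the uncleaved fraction is the
    square of the unedited allele fraction.
    """
    if not (0.0 <= fc <= 1.0):
        raise ValueError(f"fraction cleaved must be in [0, 1], got {fc}")
    return 1.0 - math.sqrt(1.0 - fc)


def tumor_volume(m: TumorMeasurement) -> float:
    """Ellipsoid caliper volume (4/3) * pi * (L/2) * (W/2)^2, in mm^3."""
    return (4.0 / 3.0) * math.pi * (m.length / 2.0) * (m.width / 2.0) ** 2


def viability_inhibition(control_signal: float, treated_signal: float) -> float:
    """Percent inhibition (1 - treated/control) * 100.

    Negative values indicate growth stimulation (treated above control).
    """
    if control_signal <= 0:
        raise ValueError("control signal must be positive")
    return (1.0 - treated_signal / control_signal) * 100.0


def _four_pl(log_dose: np.ndarray, top: float, bottom: float,
             log_ic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (log_dose - log_ic50)))


def fit_ic50(d: DoseResponse, min_span: float = 0.3) -> IC50Fit:
    """Least-squares 4PL fit on log-dose; IC50 is the curve midpoint.

    response = bottom + (top - bottom) / (1 + (dose/ic50)^hill)

    Initialization comes from the data extremes and the dose closest to
    half-response; the Hill slope is bounded to (0.1, 10). Raises when the
    response span is below ``min_span`` of the dynamic range (degenerate,
    effectively flat curve) or the optimizer fails.
    """
    doses = np.asarray(d.doses, dtype=float)
    resp = np.asarray(d.responses, dtype=float)
    span = float(resp.max() - resp.min())
    if span < min_span:
        raise ValueError(
            f"response span {span:.3f} below {min_span}: flat or degenerate curve"
        )
    log_dose = np.log(doses)
    half = (resp.max() + resp.min()) / 2.0
    ic50_guess = float(doses[np.argmin(np.abs(resp - half))])
    p0 = [float(resp.max()), float(resp.min()), math.log(ic50_guess), 1.0]
    bounds = (
        [-np.inf, -np.inf, log_dose.min() - 10.0, 0.1],
        [np.inf, np.inf, log_dose.max() + 10.0, 10.0],
    )
    try:
        popt, _ = curve_fit(_four_pl, log_dose, resp, p0=p0, bounds=bounds,
                            maxfev=20000)
    except RuntimeError as exc:
        raise ValueError(f"dose-response fit did not converge: {exc}") from exc
    top, bottom, log_ic50, hill = (float(v) for v in popt)
    residual = float(np.linalg.norm(resp - _four_pl(log_dose, *popt)))
    return IC50Fit(ic50=math.exp(log_ic50), top=top, bottom=bottom, hill=hill,
                   residual_norm=residual, converged=True)
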