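"""Rate extraction from fluorogenic assays via a 6-aminoquinoline standard
curve.

Fluorescence traces are converted to product concentration through a fitted
linear standard curve, and enzyme specific activity is the linear slope of
product over a stated time window divided by the enzyme mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StandardCurve", "fit_standard_curve", "rate_from_timecourse"]

# default slope windows (min) per PLC isoform, matching the incubation
# protocol: early window for the fast gamma isoform
DEFAULT_WINDOWS = {"PLCb1": (0.0, 30.0), "PLCg1": (0.0, 10.0), "PLCd1": (0.0, 30.0)}
DEFAULT_ENDPOINTS_MIN = {"PLCb1": 90.0, "PLCg1": 12.0, "PLCd1": 60.0}


@dataclass(frozen=True)
class StandardCurve:
    """Linear fluorescence calibration: fluorescence = slope * conc + intercept."""

    slope: float          # AU per molar
    intercept: float      # AU
    r_squared: float
    concentrations: tuple[float, ...]
    fluorescences: tuple[float, ...]

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("standard-curve slope must be positive")
        if len(self.concentrations) < 3:
            raise ValueError("at least 3 calibration points are required")

    def to_concentration(self, fluorescence):
        """Invert the calibration: product concentration (molar) from AU."""
        return (np.asarray(fluorescence, dtype=float) - self.intercept) / self.slope


def fit_standard_curve(points) -> StandardCurve:
    """Ordinary least-squares line through (concentration, fluorescence)
    calibration points.

    ``points`` is an iterable of (concentration_molar, fluorescence_au)
    pairs; at least 3 points with at least 2 distinct concentrations.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (concentration, fluorescence) points")
    conc, fluo = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 2:
        raise ValueError("calibration points are degenerate (single concentration)")
    fit = stats.linregress(conc, fluo)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        concentrations=tuple(conc),
        fluorescences=tuple(fluo),
    )


def rate_from_timecourse(
    trace: pd.DataFrame,
    curve: StandardCurve,
    window: tuple[float, float],
    enzyme_mass_mg: float,
    volume_l: float = 20e-6,
) -> float:
    """Specific activity (mol product min-1 mg-1) from a fluorescence trace.

    Converts fluorescence to product via the standard-curve inverse, fits a
    linear slope of product concentration over ``window`` (min), multiplies
    by the reaction volume and divides by the enzyme mass.
    """
    if enzyme_mass_mg <= 0:
        raise ValueError("enzyme mass must be positive")
    start, end = window
    t = trace["time_min"].to_numpy(dtype=float)
    mask = (t >= start) & (t <= end)
    if mask.sum() < 2:
        raise ValueError(f"window {window} contains fewer than 2 samples")
    conc = curve.to_concentration(trace["fluorescence_au"].to_numpy()[mask])
    fit = stats.linregress(t[mask], conc)
    return float(fit.slope) * volume_l / enzyme_mass_mg
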